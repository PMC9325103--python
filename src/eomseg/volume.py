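"""In-memory containers for CT image volumes and aligned label volumes.

Arrays are ordered ``(slice, row, col)`` with coronal slices anterior to
posterior.  Intensities are Hounsfield units; in-plane spacing is ``(row_mm,
col_mm)`` and the slice-to-slice distance is ``slice_spacing`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import DEFAULT_SCHEME, ClassScheme

__all__ = ["CTVolume", "LabelVolume"]


@dataclass
class CTVolume:
    voxels: np.ndarray  # (n_slices, rows, cols), HU
    pixel_spacing: tuple[float, float]  # (row mm, col mm)
    slice_spacing: float  # mm
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume.voxels must be 3-D (slice, row, col)")
        r, c = self.pixel_spacing
        if not (r > 0 and c > 0):
            raise ValueError("pixel_spacing must be strictly positive")
        if not self.slice_spacing > 0:
            raise ValueError("slice_spacing must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelVolume:
    labels: np.ndarray  # (n_slices, rows, cols), integer class ids
    pixel_spacing: tuple[float, float]
    slice_spacing: float
    scheme: ClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume.labels must be 3-D (slice, row, col)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        lo, hi = self.labels.min(), self.labels.max()
        if lo < 0 or hi >= self.scheme.n_classes:
            raise ValueError(
                f"label values must lie in [0, {self.scheme.n_classes - 1}], "
                f"found range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def check_aligned(self, vol: CTVolume) -> None:
        if self.labels.shape != vol.voxels.shape:
            raise ValueError(
                f"label shape {self.labels.shape} does not match "
                f"volume shape {vol.voxels.shape}"
            )
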