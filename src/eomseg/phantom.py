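"""Synthetic contrast-enhanced orbital CT phantoms with ground-truth labels.

Each phantom is a coronal stack containing two orbits.  Every orbit holds a
high-attenuation bony rim, low-attenuation retro-ocular fat, a globe in the
anterior slices, and four rectus-muscle cross-sections modelled as rotated
ellipses that taper toward the muscle origin and insertion.  The analytic
ellipse parameters are returned alongside the rasterised volumes, so the
phantom doubles as an oracle for thickness/area recovery.

Muscle sizes default to the population means of contrast-enhanced orbital CT
morphometry (thickness ≈ 4.7–5.9 mm, belly cross-sectional area ≈
38–50 mm²).  Cross-section orientation follows anatomy as seen on coronal
slices: the medial and lateral recti are taller than wide (thickness is their
horizontal diameter), the superior group and inferior rectus wider than tall
(thickness vertical), each with a per-phantom ±15° orientation jitter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .scheme import DEFAULT_SCHEME
from .volume import CTVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "phantom_cohort",
    "TABLE_THICKNESS_MM",
    "TABLE_THICKNESS_SD",
    "TABLE_AREA_MM2",
    "TABLE_AREA_SD",
]

# Reference per-muscle belly sizes (classes 1..8 in canonical order):
# population mean (sd) thickness in mm and maximum cross-sectional area in mm²
# for contrast-enhanced orbital CT.
TABLE_THICKNESS_MM = {1: 4.87, 2: 5.50, 3: 4.79, 4: 5.23, 5: 4.74, 6: 5.62, 7: 4.85, 8: 5.13}
TABLE_THICKNESS_SD = {1: 0.84, 2: 1.13, 3: 0.93, 4: 1.07, 5: 0.66, 6: 1.41, 7: 1.04, 8: 1.08}
TABLE_AREA_MM2 = {1: 38.93, 2: 46.03, 3: 38.29, 4: 41.57, 5: 38.14, 6: 47.20, 7: 40.10, 8: 42.38}
TABLE_AREA_SD = {1: 8.54, 2: 10.03, 3: 9.66, 4: 11.78, 5: 6.88, 6: 14.29, 7: 13.79, 8: 14.24}

# Display window used throughout the pipeline (level 50, width 250 HU).
_WINDOW_LO, _WINDOW_HI = -75.0, 175.0

# Fixed orbital geometry in mm, relative to each orbit centre.
_MUSCLE_RING_MM = 16.0  # distance of muscle centres from the orbit centre
_CAVITY_RADIUS_MM = 23.0  # fat-filled orbital cavity
_BONE_OUTER_MM = 26.5  # bony rim outer radius
_GLOBE_RADIUS_MM = 9.0
_FOV_MM = 154.0  # in-plane field of view (square)


def _default_long_axis() -> dict[int, float]:
    """Belly long axis from the ellipse model A = (π/4)·t·l."""
    return {
        c: 4.0 * TABLE_AREA_MM2[c] / (np.pi * TABLE_THICKNESS_MM[c])
        for c in TABLE_THICKNESS_MM
    }


def default_taper_profile(n: int = 16) -> np.ndarray:
    """Fractional size multiplier per muscle-bearing slice.

    1.0 over the central third (the muscle belly) and a cosine fall-off to
    0.35 at the insertion/origin ends.
    """
    f = (np.arange(n) + 0.5) / n
    d = np.maximum(0.0, np.maximum(1 / 3 - f, f - 2 / 3)) * 3.0  # 0 in centre third
    return 0.35 + 0.65 * np.cos(np.clip(d, 0, 1) * np.pi / 2)


@dataclass
class PhantomSpec:
    n_slices: int = 20
    in_plane_spacing: tuple[float, float] = (0.4, 0.4)  # (row mm, col mm)
    slice_spacing: float = 3.0
    thickness_mm: dict[int, float] = field(
        default_factory=lambda: dict(TABLE_THICKNESS_MM)
    )
    long_axis_mm: dict[int, float] = field(default_factory=_default_long_axis)
    muscle_hu: float = 90.0
    fat_hu: float = -80.0
    bone_hu: float = 700.0
    globe_hu: float = 35.0
    tissue_hu: float = 30.0  # soft tissue outside the orbital rim
    noise_sd_hu: float = 5.0
    taper_profile: np.ndarray = field(
        default_factory=lambda: default_taper_profile(16)
    )
    seed: int = 0

    def validate(self) -> None:
        for ax, sp in zip(("row", "col"), self.in_plane_spacing):
            if not (0.3 <= sp <= 0.5):
                raise ValueError(
                    f"in_plane_spacing[{ax}]={sp} outside the supported [0.3, 0.5] mm"
                )
        if self.n_slices < 10:
            raise ValueError(f"n_slices={self.n_slices} too small (need ≥ 10)")
        for c in DEFAULT_SCHEME.muscle_classes():
            t = self.thickness_mm.get(c)
            l = self.long_axis_mm.get(c)
            if t is None or l is None:
                raise ValueError(f"thickness_mm/long_axis_mm missing class {c}")
            if not t <= l:
                raise ValueError(
                    f"thickness_mm[{c}]={t} exceeds long_axis_mm[{c}]={l}"
                )
            if t <= 0:
                raise ValueError(f"thickness_mm[{c}]={t} must be positive")
        if not (_WINDOW_LO <= self.muscle_hu <= _WINDOW_HI):
            raise ValueError(
                f"muscle_hu={self.muscle_hu} outside the display window "
                f"[{_WINDOW_LO}, {_WINDOW_HI}]"
            )
        prof = np.asarray(self.taper_profile, dtype=float)
        if prof.ndim != 1 or len(prof) < 3:
            raise ValueError("taper_profile must be a 1-D array of length ≥ 3")
        if np.any(prof <= 0) or np.any(prof > 1):
            raise ValueError("taper_profile values must lie in (0, 1]")
        n = len(prof)
        centre = prof[n // 3 : n - n // 3]
        if not np.isclose(centre.max(), 1.0):
            raise ValueError("taper_profile must reach 1.0 in its central third")
        if self.noise_sd_hu < 0:
            raise ValueError(f"noise_sd_hu={self.noise_sd_hu} must be ≥ 0")


@dataclass
class PhantomTruth:
    """Analytic per-muscle sizes: the oracle for parameter recovery."""

    thickness_mm: dict[int, float]
    area_mm2: dict[int, float]
    long_axis_mm: dict[int, float]
    belly_slice: dict[int, int]

    def to_json(self) -> str:
        def k2s(d):
            return {str(k): v for k, v in d.items()}

        return json.dumps(
            {
                "thickness_mm": k2s(self.thickness_mm),
                "area_mm2": k2s(self.area_mm2),
                "long_axis_mm": k2s(self.long_axis_mm),
                "belly_slice": k2s(self.belly_slice),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        d = json.loads(text)

        def s2k(m, cast):
            return {int(k): cast(v) for k, v in m.items()}

        return cls(
            thickness_mm=s2k(d["thickness_mm"], float),
            area_mm2=s2k(d["area_mm2"], float),
            long_axis_mm=s2k(d["long_axis_mm"], float),
            belly_slice=s2k(d["belly_slice"], int),
        )


def _muscle_layout(rng: np.random.Generator) -> dict[int, tuple[float, float, float]]:
    """Per-class (row_off_mm, col_off_mm, long-axis angle rad from vertical).

    Offsets are relative to the owning orbit centre; the medial rectus faces
    the image midline.  Angle 0 means the long axis runs along image rows
    (vertical on screen); superior/inferior classes are rotated by 90°.
    """
    jitter = lambda: np.deg2rad(rng.uniform(-15.0, 15.0))
    r = _MUSCLE_RING_MM
    layout = {}
    # Left orbit occupies the left half of the image; midline is to its right.
    layout[1] = (0.0, +r, jitter())  # L-medial: toward midline, long axis vertical
    layout[2] = (0.0, -r, jitter())  # L-lateral: outward
    layout[3] = (-r, 0.0, np.pi / 2 + jitter())  # L-superior: above, long axis horizontal
    layout[4] = (+r, 0.0, np.pi / 2 + jitter())  # L-inferior: below
    layout[5] = (0.0, -r, jitter())  # R-medial: toward midline (left of right orbit)
    layout[6] = (0.0, +r, jitter())  # R-lateral
    layout[7] = (-r, 0.0, np.pi / 2 + jitter())  # R-superior
    layout[8] = (+r, 0.0, np.pi / 2 + jitter())  # R-inferior
    return layout


def _ellipse_mask(
    rows_mm: np.ndarray,
    cols_mm: np.ndarray,
    centre: tuple[float, float],
    semi_long: float,
    semi_short: float,
    angle: float,
) -> np.ndarray:
    """Boolean raster: pixel centres inside the rotated ellipse.

    ``angle`` is measured from the row (vertical) axis toward the column axis;
    the long axis lies along that direction.
    """
    dr = rows_mm[:, None] - centre[0]
    dc = cols_mm[None, :] - centre[1]
    u = dr * np.cos(angle) + dc * np.sin(angle)  # along long axis
    v = -dr * np.sin(angle) + dc * np.cos(angle)  # along short axis
    return (u / semi_long) ** 2 + (v / semi_short) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelVolume, PhantomTruth]:
    """Rasterise one phantom; identical spec (incl. seed) gives identical arrays."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    row_mm, col_mm = spec.in_plane_spacing
    n_rows = int(round(_FOV_MM / row_mm))
    n_cols = int(round(_FOV_MM / col_mm))
    rows_mm = (np.arange(n_rows) + 0.5) * row_mm
    cols_mm = (np.arange(n_cols) + 0.5) * col_mm
    h_mm, w_mm = n_rows * row_mm, n_cols * col_mm

    orbit_centres = {
        "L": (h_mm / 2.0, 0.29 * w_mm),
        "R": (h_mm / 2.0, 0.71 * w_mm),
    }

    # Muscle-bearing slab: the central 80% of slices.
    margin = int(np.floor(0.1 * spec.n_slices))
    span_start = margin
    span_len = spec.n_slices - 2 * margin
    profile = np.interp(
        (np.arange(span_len) + 0.5) / span_len,
        (np.arange(len(spec.taper_profile)) + 0.5) / len(spec.taper_profile),
        np.asarray(spec.taper_profile, dtype=float),
    )
    # keep the central-third plateau exact after re-gridding
    profile = np.minimum(profile, 1.0)
    third = span_len // 3
    profile[third : span_len - third] = np.maximum(
        profile[third : span_len - third],
        np.asarray(spec.taper_profile)[
            len(spec.taper_profile) // 3 : -(len(spec.taper_profile) // 3) or None
        ].max(),
    )

    layout = _muscle_layout(rng)

    hu = np.full((spec.n_slices, n_rows, n_cols), spec.tissue_hu, dtype=np.float32)
    labels = np.zeros((spec.n_slices, n_rows, n_cols), dtype=np.uint8)

    rr = rows_mm[:, None]
    cc = cols_mm[None, :]
    for side, (ocr, occ) in orbit_centres.items():
        d2 = (rr - ocr) ** 2 + (cc - occ) ** 2
        cavity = d2 <= _CAVITY_RADIUS_MM**2
        bone = (d2 > _CAVITY_RADIUS_MM**2) & (d2 <= _BONE_OUTER_MM**2)
        globe = d2 <= _GLOBE_RADIUS_MM**2
        hu[:, cavity] = spec.fat_hu
        hu[:, bone] = spec.bone_hu
        # globe sits in the anterior third of the muscle-bearing slab
        globe_stop = span_start + max(1, span_len // 3)
        hu[:globe_stop, globe] = spec.globe_hu

    belly = span_start + span_len // 2
    truth = PhantomTruth(
        thickness_mm={}, area_mm2={}, long_axis_mm={}, belly_slice={}
    )
    for c in DEFAULT_SCHEME.muscle_classes():
        side = DEFAULT_SCHEME.side[c]
        ocr, occ = orbit_centres[side]
        off_r, off_c, angle = layout[c]
        centre = (ocr + off_r, occ + off_c)
        semi_long = spec.long_axis_mm[c] / 2.0
        semi_short = spec.thickness_mm[c] / 2.0
        for j in range(span_len):
            m = profile[j]
            mask = _ellipse_mask(
                rows_mm, cols_mm, centre, semi_long * m, semi_short * m, angle
            )
            s = span_start + j
            labels[s][mask] = c
            hu[s][mask] = spec.muscle_hu
        truth.thickness_mm[c] = spec.thickness_mm[c] * profile.max()
        truth.area_mm2[c] = (
            np.pi * semi_long * semi_short * profile.max() ** 2
        )
        truth.long_axis_mm[c] = spec.long_axis_mm[c] * profile.max()
        truth.belly_slice[c] = int(belly)

    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, hu.shape).astype(np.float32)

    source_id = f"phantom-{spec.seed}"
    vol = CTVolume(
        voxels=hu,
        pixel_spacing=(row_mm, col_mm),
        slice_spacing=spec.slice_spacing,
        source_id=source_id,
    )
    lab = LabelVolume(
        labels=labels,
        pixel_spacing=(row_mm, col_mm),
        slice_spacing=spec.slice_spacing,
        scheme=DEFAULT_SCHEME,
        source_id=source_id,
    )
    return vol, lab, truth


def draw_cohort_specs(
    n: int,
    base_spec: PhantomSpec | None = None,
    variability: dict | None = None,
    seed: int = 0,
) -> list[PhantomSpec]:
    """Draw ``n`` per-study phantom specs with sizes sampled around a base.

    Per-muscle thickness and belly area are drawn from normal distributions
    (defaults: the reference population sds); the long axis is re-derived from
    the ellipse model so thickness stays the minor axis.  In-plane pixel
    spacing is drawn anisotropically from [0.30, 0.40] mm per study, the
    native pixel-size range of the emulated acquisitions.
    """
    if n < 1:
        raise ValueError(f"cohort size must be ≥ 1, got {n}")
    base = base_spec if base_spec is not None else PhantomSpec()
    if variability is None:
        variability = {
            "thickness_sd": dict(TABLE_THICKNESS_SD),
            "area_sd": dict(TABLE_AREA_SD),
            "spacing_range": (0.30, 0.40),
        }
    t_sd = variability.get("thickness_sd", {})
    a_sd = variability.get("area_sd", {})
    sp_range = variability.get("spacing_range")

    root = np.random.SeedSequence(seed)
    specs = []
    for child in root.spawn(n):
        rng = np.random.default_rng(child)
        thickness, long_axis = {}, {}
        for c in DEFAULT_SCHEME.muscle_classes():
            t0 = base.thickness_mm[c]
            a0 = np.pi / 4.0 * base.thickness_mm[c] * base.long_axis_mm[c]
            t = float(np.clip(rng.normal(t0, t_sd.get(c, 0.0)), 2.5, 8.0))
            a = float(np.clip(rng.normal(a0, a_sd.get(c, 0.0)), 15.0, 75.0))
            l = float(np.clip(4.0 * a / (np.pi * t), 1.2 * t, 16.0))
            thickness[c] = t
            long_axis[c] = l
        spacing = base.in_plane_spacing
        if sp_range is not None:
            spacing = (
                float(rng.uniform(*sp_range)),
                float(rng.uniform(*sp_range)),
            )
        specs.append(
            replace(
                base,
                thickness_mm=thickness,
                long_axis_mm=long_axis,
                in_plane_spacing=spacing,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def phantom_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    variability: dict | None = None,
    seed: int = 0,
) -> list[tuple[CTVolume, LabelVolume, PhantomTruth]]:
    """Generate ``n`` independent phantoms (see :func:`draw_cohort_specs`)."""
    return [
        generate_phantom(spec)
        for spec in draw_cohort_specs(n, base_spec, variability, seed)
    ]
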