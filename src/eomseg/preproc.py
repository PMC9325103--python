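"""Preprocessing: isometric resampling, HU windowing, patch sampling, augmentation.

The pipeline order is: resample the HU volume in-plane to 1×1 mm with cubic
spline interpolation (labels with nearest neighbour), window to [0, 1] with a
soft-tissue window (level 50, width 250 HU), then draw 128×128 training
patches — half intersecting the orbit, half not — and augment them by
rotation, scaling, and Gaussian HU noise.  Horizontal flipping is never
applied anywhere in this module: left/right muscle identity must survive
augmentation, and no flip parameter exists by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CTVolume, LabelVolume

__all__ = [
    "WINDOW_LEVEL",
    "WINDOW_WIDTH",
    "PatchSet",
    "resample_isometric",
    "resample_labels",
    "window_hu",
    "unwindow",
    "sample_patches",
    "sample_patches_counts",
    "save_patchset",
    "load_patchset",
    "augment",
]

WINDOW_LEVEL = 50.0
WINDOW_WIDTH = 250.0
PATCH = 128
ORBIT_DILATION_PX = 8


def _target_dims(shape: tuple[int, int], spacing: tuple[float, float], target: float):
    """Round-half-away-from-zero on dim·spacing/target (fixed for reproducibility)."""
    out = []
    for dim, sp in zip(shape, spacing):
        x = dim * sp / target
        out.append(int(np.floor(x + 0.5)))
    return tuple(out)


def resample_isometric(vol: CTVolume, target_mm: float = 1.0) -> CTVolume:
    """Resample each coronal slice to square ``target_mm`` pixels (cubic spline).

    Slice spacing is untouched: resampling is in-plane only.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    n, r, c = vol.voxels.shape
    tr, tc = _target_dims((r, c), vol.pixel_spacing, target_mm)
    zoom = (1.0, tr / r, tc / c)
    out = ndimage.zoom(
        np.asarray(vol.voxels, dtype=np.float32),
        zoom,
        order=3,
        mode="nearest",
        grid_mode=True,
    )
    assert out.shape == (n, tr, tc)
    return CTVolume(
        voxels=out,
        pixel_spacing=(target_mm, target_mm),
        slice_spacing=vol.slice_spacing,
        source_id=vol.source_id,
    )


def resample_labels(lab: LabelVolume, target_mm: float = 1.0) -> LabelVolume:
    """Nearest-neighbour companion of :func:`resample_isometric`."""
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    n, r, c = lab.labels.shape
    tr, tc = _target_dims((r, c), lab.pixel_spacing, target_mm)
    out = ndimage.zoom(
        lab.labels, (1.0, tr / r, tc / c), order=0, mode="nearest", grid_mode=True
    )
    return LabelVolume(
        labels=out.astype(lab.labels.dtype),
        pixel_spacing=(target_mm, target_mm),
        slice_spacing=lab.slice_spacing,
        scheme=lab.scheme,
        source_id=lab.source_id,
    )


def window_hu(
    hu: np.ndarray | CTVolume,
    level: float = WINDOW_LEVEL,
    width: float = WINDOW_WIDTH,
) -> np.ndarray:
    """Clip HU to [level−width/2, level+width/2] and map affinely to [0, 1]."""
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    arr = hu.voxels if isinstance(hu, CTVolume) else np.asarray(hu)
    lo, hi = level - width / 2.0, level + width / 2.0
    return ((np.clip(arr, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def unwindow(
    normed: np.ndarray, level: float = WINDOW_LEVEL, width: float = WINDOW_WIDTH
) -> np.ndarray:
    """Inverse affine map from [0, 1] back to HU (clipping is not recoverable)."""
    lo = level - width / 2.0
    return np.asarray(normed, dtype=np.float32) * width + lo


@dataclass
class PatchSet:
    """Aligned windowed-image / label patches with sampling provenance."""

    image_patches: list[np.ndarray]
    label_patches: list[np.ndarray]
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.image_patches)

    def validate(self) -> None:
        if len(self.image_patches) != len(self.label_patches):
            raise ValueError("image and label patch lists differ in length")
        for im, lb in zip(self.image_patches, self.label_patches):
            if im.shape != lb.shape:
                raise ValueError("image/label patch shape mismatch")


def _orbit_boxes(labels: np.ndarray) -> list[tuple[int, int, int, int] | None]:
    """Per-slice bounding box of non-background labels, dilated by 8 px."""
    boxes = []
    for sl in labels:
        rr, cc = np.nonzero(sl)
        if rr.size == 0:
            boxes.append(None)
            continue
        boxes.append(
            (
                max(0, rr.min() - ORBIT_DILATION_PX),
                min(sl.shape[0], rr.max() + 1 + ORBIT_DILATION_PX),
                max(0, cc.min() - ORBIT_DILATION_PX),
                min(sl.shape[1], cc.max() + 1 + ORBIT_DILATION_PX),
            )
        )
    return boxes


def sample_patches(
    vol: CTVolume,
    lab: LabelVolume,
    n_patches: int,
    patch: int = PATCH,
    seed: int | np.random.Generator = 0,
) -> PatchSet:
    """Draw ``n_patches`` random patches, half orbit-flagged and half not.

    ``vol`` must already be windowed to [0, 1] on the isometric grid.  An
    orbit patch intersects the dilated bounding box of the slice's labels and
    contains at least one muscle pixel; a non-orbit patch is disjoint from
    every orbit box (in practice it comes from a muscle-free slice).
    """
    n_orbit = (n_patches + 1) // 2 if n_patches % 2 else n_patches // 2
    return sample_patches_counts(vol, lab, n_orbit, n_patches - n_orbit, patch, seed)


def sample_patches_counts(
    vol: CTVolume,
    lab: LabelVolume,
    n_orbit: int,
    n_non: int,
    patch: int = PATCH,
    seed: int | np.random.Generator = 0,
) -> PatchSet:
    """Like :func:`sample_patches` but with explicit orbit/non-orbit counts."""
    lab.check_aligned(vol)
    n, r, c = vol.voxels.shape
    if r < patch or c < patch:
        raise ValueError(f"in-plane dims {(r, c)} smaller than patch {patch}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    boxes = _orbit_boxes(lab.labels)

    images, lbls, prov = [], [], []

    def draw(want_orbit: bool) -> None:
        for _ in range(10_000):
            s = int(rng.integers(0, n))
            r0 = int(rng.integers(0, r - patch + 1))
            c0 = int(rng.integers(0, c - patch + 1))
            box = boxes[s]
            intersects = box is not None and not (
                r0 + patch <= box[0] or r0 >= box[1] or c0 + patch <= box[2] or c0 >= box[3]
            )
            lp = lab.labels[s, r0 : r0 + patch, c0 : c0 + patch]
            if want_orbit:
                if not intersects or not np.any(lp):
                    continue
            else:
                if intersects:
                    continue
            images.append(
                np.array(vol.voxels[s, r0 : r0 + patch, c0 : c0 + patch], copy=True)
            )
            lbls.append(np.array(lp, copy=True))
            prov.append(
                {
                    "source_id": vol.source_id,
                    "slice": s,
                    "row": r0,
                    "col": c0,
                    "orbit": want_orbit,
                }
            )
            return
        raise RuntimeError(
            f"could not draw a {'orbit' if want_orbit else 'non-orbit'} patch; "
            "volume may lack suitable slices"
        )

    for _ in range(n_orbit):
        draw(True)
    for _ in range(n_non):
        draw(False)
    ps = PatchSet(images, lbls, prov)
    ps.validate()
    return ps


def save_patchset(
    patchset: PatchSet, path, settings: dict | None = None
) -> None:
    """Cache a patch set: an .npz archive plus a JSON sidecar manifest.

    The manifest records per-patch provenance and any sampling settings so a
    cached archive can be audited without loading the arrays.
    """
    import json
    from pathlib import Path

    patchset.validate()
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        images=np.stack(patchset.image_patches) if patchset.image_patches else np.empty((0,)),
        labels=np.stack(patchset.label_patches) if patchset.label_patches else np.empty((0,)),
    )
    manifest = {"provenance": patchset.provenance, "settings": settings or {}}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_patchset(path) -> PatchSet:
    """Load a patch archive written by :func:`save_patchset`."""
    import json
    from pathlib import Path

    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    images = [im for im in data["images"]]
    labels = [lb for lb in data["labels"]]
    ps = PatchSet(images, labels, manifest["provenance"])
    ps.validate()
    return ps


def augment(
    patchset: PatchSet,
    seed: int | np.random.Generator = 0,
    rotation_deg_range: tuple[float, float] = (-10.0, 10.0),
    scale_range: tuple[float, float] = (0.9, 1.1),
    noise_sd_hu: float = 10.0,
) -> PatchSet:
    """Rotate, scale, and add Gaussian HU noise; labels follow geometrically.

    The geometric transform is identical for image and label (labels nearest
    neighbour).  Noise is added in HU — the window is inverted, noise applied,
    and the window re-applied — matching a pipeline where noise precedes
    windowing.  There is deliberately no flip: every transform here has
    positive determinant.
    """
    patchset.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    images, lbls = [], []
    for im, lb in zip(patchset.image_patches, patchset.label_patches):
        angle = float(rng.uniform(*rotation_deg_range))
        scale = float(rng.uniform(*scale_range))

        out_im, out_lb = im, lb
        if angle != 0.0 or scale != 1.0:
            h, w = im.shape
            centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
            th = np.deg2rad(angle)
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            # output→input map: x_in = R(-θ)/s · (x_out − centre) + centre
            mat = rot.T / scale
            offset = centre - mat @ centre
            out_im = ndimage.affine_transform(
                im, mat, offset=offset, order=1, mode="nearest"
            )
            out_lb = ndimage.affine_transform(
                lb, mat, offset=offset, order=0, mode="nearest"
            )
        if noise_sd_hu > 0:
            hu = unwindow(out_im)
            hu = hu + rng.normal(0.0, noise_sd_hu, hu.shape)
            out_im = window_hu(hu)
        images.append(np.asarray(out_im, dtype=np.float32))
        lbls.append(out_lb.astype(lb.dtype))
    return PatchSet(images, lbls, [dict(p) for p in patchset.provenance])
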