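"""Full-volume prediction: sliding-window patches with per-pixel majority vote.

Each slice is covered by 128×128 windows at a configurable stride (edge
windows are clamped to the border so every pixel receives at least one vote).
Each covering window casts one vote per pixel — its argmax class — and the
final label is the majority; ties are broken by the highest accumulated
softmax probability.  Predictions made on the 1 mm isometric grid can be
mapped back to the native acquisition grid by nearest-neighbour resampling.
"""

from __future__ import annotations

import logging

import numpy as np

from .unet import SegModel
from .volume import CTVolume, LabelVolume

__all__ = ["predict_volume", "restore_native_grid", "vote_slice"]

log = logging.getLogger(__name__)


def _window_offsets(dim: int, patch: int, stride: int) -> list[int]:
    offs = list(range(0, dim - patch + 1, stride))
    if offs[-1] != dim - patch:
        offs.append(dim - patch)  # clamp the last window to the border
    return offs


def vote_slice(
    model: SegModel, sl: np.ndarray, stride: int, patch: int | None = None
) -> np.ndarray:
    """Majority-vote label map for one windowed slice (2-D array in [0, 1])."""
    patch = patch or model.config.patch_size
    h, w = sl.shape
    pad_r = max(0, patch - h)
    pad_c = max(0, patch - w)
    if pad_r or pad_c:
        log.warning(
            "slice %s smaller than patch %d; padding reflectively", (h, w), patch
        )
        sl = np.pad(sl, ((0, pad_r), (0, pad_c)), mode="reflect")
    hh, ww = sl.shape
    offs_r = _window_offsets(hh, patch, stride)
    offs_c = _window_offsets(ww, patch, stride)

    windows = np.stack(
        [sl[r : r + patch, c : c + patch] for r in offs_r for c in offs_c]
    )
    probs = model.predict_patch(windows)

    n_classes = model.n_classes
    votes = np.zeros((hh, ww, n_classes), dtype=np.int32)
    psum = np.zeros((hh, ww, n_classes), dtype=np.float64)
    k = 0
    for r in offs_r:
        for c in offs_c:
            pr = probs[k]
            cls = pr.argmax(axis=-1)
            rr = np.arange(r, r + patch)[:, None]
            cc = np.arange(c, c + patch)[None, :]
            np.add.at(votes, (rr, cc, cls), 1)
            psum[r : r + patch, c : c + patch] += pr
            k += 1
    # majority vote; accumulated probability only separates tied vote counts
    total = len(offs_r) * len(offs_c)
    score = votes.astype(np.float64) + psum / (psum.max() * total + 1.0)
    out = score.argmax(axis=-1).astype(np.uint8)
    return out[:h, :w]


def predict_volume(model: SegModel, vol: CTVolume, stride: int = 64) -> LabelVolume:
    """Predict a multiclass label volume slice by slice.

    ``vol`` must be preprocessed exactly as in training: isometrically
    resampled and windowed to [0, 1].
    """
    patch = model.config.patch_size
    if not 1 <= stride <= patch:
        raise ValueError(f"stride must lie in [1, {patch}], got {stride}")
    out = np.stack([vote_slice(model, sl, stride, patch) for sl in vol.voxels])
    return LabelVolume(
        labels=out,
        pixel_spacing=vol.pixel_spacing,
        slice_spacing=vol.slice_spacing,
        scheme=model.scheme,
        source_id=vol.source_id,
    )


def restore_native_grid(pred: LabelVolume, original: CTVolume) -> LabelVolume:
    """Nearest-neighbour mapping of predicted labels back to the native grid.

    ``pred`` must have been produced from an isometric resampling of
    ``original``: slice counts must match and the in-plane dimensions must be
    consistent with the resampling ratio.
    """
    if pred.source_id and original.source_id and pred.source_id != original.source_id:
        raise ValueError(
            f"provenance mismatch: prediction from {pred.source_id!r}, "
            f"volume is {original.source_id!r}"
        )
    n_p, hp, wp = pred.labels.shape
    n_o, ho, wo = original.voxels.shape
    if n_p != n_o:
        raise ValueError(f"slice count mismatch: {n_p} vs {n_o}")
    if (hp, wp) == (ho, wo):
        return LabelVolume(
            labels=pred.labels.copy(),
            pixel_spacing=original.pixel_spacing,
            slice_spacing=original.slice_spacing,
            scheme=pred.scheme,
            source_id=pred.source_id,
        )

    def src_index(out_dim: int, in_dim: int) -> np.ndarray:
        # pixel-centre mapping, consistent with grid-mode zoom
        x = (np.arange(out_dim) + 0.5) * (in_dim / out_dim) - 0.5
        return np.clip(np.rint(x).astype(int), 0, in_dim - 1)

    ri = src_index(ho, hp)
    ci = src_index(wo, wp)
    out = pred.labels[:, ri[:, None], ci[None, :]]
    return LabelVolume(
        labels=out.astype(pred.labels.dtype),
        pixel_spacing=original.pixel_spacing,
        slice_spacing=original.slice_spacing,
        scheme=pred.scheme,
        source_id=pred.source_id,
    )
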