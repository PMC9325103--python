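"""Quantitative evaluation: overlap metrics, regional analysis, size errors.

Provides per-class Dice/IoU between predicted and ground-truth label volumes,
a three-region split of the muscle-bearing slab (insertion / central part /
origin — the anatomically hard ends versus the easy belly), MAE/MAPE between
paired size measurements, and a noise-robustness protocol that repeats the
evaluation with Gaussian HU noise added to the inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import measure_volume
from .scheme import DEFAULT_SCHEME
from .volume import CTVolume, LabelVolume

__all__ = [
    "RegionSplit",
    "MeasurementComparison",
    "EvalReport",
    "dice_iou",
    "split_regions",
    "regional_metrics",
    "mae_mape",
    "compare_measurements",
    "measurement_table",
    "welch_test",
    "evaluate_cohort",
    "noise_robustness",
]

log = logging.getLogger(__name__)

REGIONS = ("insertion", "central", "origin")


def dice_iou(
    pred: LabelVolume | np.ndarray, truth: LabelVolume | np.ndarray, cls: int
) -> tuple[float, float]:
    """(Dice, IoU) for one class over all voxels.

    A class empty in both volumes is undefined: returns (nan, nan) so callers
    can exclude it from averages.
    """
    p_arr = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    g_arr = truth.labels if isinstance(truth, LabelVolume) else np.asarray(truth)
    if p_arr.shape != g_arr.shape:
        raise ValueError(f"shape mismatch: {p_arr.shape} vs {g_arr.shape}")
    p = p_arr == cls
    g = g_arr == cls
    np_, ng = int(p.sum()), int(g.sum())
    if np_ + ng == 0:
        return float("nan"), float("nan")
    inter = int(np.logical_and(p, g).sum())
    dice = 2.0 * inter / (np_ + ng)
    iou = inter / (np_ + ng - inter)
    return float(dice), float(iou)


@dataclass
class RegionSplit:
    """Contiguous slice ranges (half-open) covering the muscle-bearing slab."""

    insertion: tuple[int, int]
    central: tuple[int, int]
    origin: tuple[int, int]

    def ranges(self) -> dict[str, tuple[int, int]]:
        return {"insertion": self.insertion, "central": self.central, "origin": self.origin}

    def lengths(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in (self.insertion, self.central, self.origin))


def split_regions(truth: LabelVolume) -> RegionSplit:
    """Split the muscle-bearing slab into three near-equal contiguous thirds.

    Slices are anterior→posterior, so the first third is the insertion and
    the last the origin.  A remainder of 1 goes to the central part; a
    remainder of 2 adds one slice to the central part and one to the origin.
    """
    bearing = np.nonzero(np.any(truth.labels > 0, axis=(1, 2)))[0]
    if bearing.size < 3:
        raise ValueError(
            f"need at least 3 muscle-bearing slices, found {bearing.size}"
        )
    lo, hi = int(bearing.min()), int(bearing.max()) + 1
    n = hi - lo
    base, rem = divmod(n, 3)
    lens = [base, base, base]
    if rem >= 1:
        lens[1] += 1
    if rem == 2:
        lens[2] += 1
    a = lo
    b = a + lens[0]
    c = b + lens[1]
    return RegionSplit(insertion=(a, b), central=(b, c), origin=(c, c + lens[2]))


def regional_metrics(
    pred: LabelVolume, truth: LabelVolume, split: RegionSplit
) -> dict[str, dict[int, tuple[float, float]]]:
    """Per-region per-class (Dice, IoU) computed over each region's slices."""
    out: dict[str, dict[int, tuple[float, float]]] = {}
    for name, (a, b) in split.ranges().items():
        out[name] = {
            c: dice_iou(pred.labels[a:b], truth.labels[a:b], c)
            for c in truth.scheme.muscle_classes()
        }
    return out


@dataclass
class MeasurementComparison:
    """Paired predicted/ground-truth sizes with their error statistics."""

    pairs: list[tuple[float, float]]  # (predicted, ground truth)
    mae: float
    mape_percent: float
    n: int
    n_excluded: int = 0


def mae_mape(
    predicted, ground_truth, as_percent: bool = True
) -> tuple[float, float]:
    """MAE = (1/n)Σ|x_pr − x_gt|; MAPE = (1/n)Σ|x_pr − x_gt|/|x_gt| (in %).

    Pairs with zero ground truth are excluded from the MAPE with a warning.
    """
    x_pr = np.asarray(predicted, dtype=float)
    x_gt = np.asarray(ground_truth, dtype=float)
    if x_pr.shape != x_gt.shape or x_pr.size == 0:
        raise ValueError("predicted/ground-truth vectors must match and be non-empty")
    err = np.abs(x_pr - x_gt)
    mae = float(err.mean())
    nz = x_gt != 0
    if not np.all(nz):
        warnings.warn(
            f"{int((~nz).sum())} pair(s) with zero ground truth excluded from MAPE"
        )
    if not np.any(nz):
        return mae, float("nan")
    mape = float((err[nz] / np.abs(x_gt[nz])).mean())
    return mae, mape * 100.0 if as_percent else mape


def compare_measurements(
    pred_reports, truth_reports, quantity: str
) -> MeasurementComparison:
    """Pool per-(study, class) size pairs and compute MAE/MAPE.

    ``quantity`` is "thickness" or "area".  A class absent from either report
    of a pair is excluded (counted in ``n_excluded``).
    """
    attr = {"thickness": "thickness_mm", "area": "area_mm2"}[quantity]
    pairs = []
    excluded = 0
    for pr, gt in zip(pred_reports, truth_reports):
        pd_, gd = getattr(pr, attr), getattr(gt, attr)
        for c in DEFAULT_SCHEME.muscle_classes():
            if c in pd_ and c in gd:
                pairs.append((pd_[c], gd[c]))
            else:
                excluded += 1
    if not pairs:
        raise ValueError("no comparable (study, class) pairs")
    x_pr, x_gt = zip(*pairs)
    mae, mape = mae_mape(x_pr, x_gt)
    return MeasurementComparison(
        pairs=pairs, mae=mae, mape_percent=mape, n=len(pairs), n_excluded=excluded
    )


def welch_test(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test on two per-study metric samples.

    Used to compare pooled per-study Dice between conditions (e.g. central
    versus end regions, or clean versus noisy inputs).  Returns (t, p).
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def measurement_table(pred_reports, truth_reports) -> pd.DataFrame:
    """Per-class MAE/MAPE of thickness and area, with a pooled "all" row."""
    rows = []
    for c in DEFAULT_SCHEME.muscle_classes() + [-1]:
        row = {"class": c, "name": "all" if c == -1 else DEFAULT_SCHEME.name(c)}
        for quantity, unit in (("thickness", "mm"), ("area", "mm2")):
            attr = {"thickness": "thickness_mm", "area": "area_mm2"}[quantity]
            pairs = []
            for pr, gt in zip(pred_reports, truth_reports):
                pd_, gd = getattr(pr, attr), getattr(gt, attr)
                classes = DEFAULT_SCHEME.muscle_classes() if c == -1 else [c]
                pairs += [
                    (pd_[k], gd[k]) for k in classes if k in pd_ and k in gd
                ]
            if pairs:
                x_pr, x_gt = zip(*pairs)
                mae, mape = mae_mape(x_pr, x_gt)
            else:
                mae = mape = float("nan")
            row[f"{quantity}_mae_{unit}"] = mae
            row[f"{quantity}_mape_percent"] = mape
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Cohort-level evaluation bundle."""

    per_class_dice: dict[int, tuple[float, float]]  # mean, sd over studies
    per_class_iou: dict[int, tuple[float, float]]
    pooled_dice: float
    pooled_iou: float
    regional: dict[str, dict[int, tuple[float, float]]]  # region → class → mean (d, i)
    thickness: MeasurementComparison | None = None
    area: MeasurementComparison | None = None
    noise_sd_hu: float = 0.0
    n_undefined_pairs: int = 0
    per_study_dice: list[float] = field(default_factory=list)

    def per_class_frame(self) -> pd.DataFrame:
        """Per-class Dice/IoU (mean ± sd over studies) plus a pooled row."""
        rows = []
        for c in sorted(self.per_class_dice):
            dm, dsd = self.per_class_dice[c]
            im, isd = self.per_class_iou[c]
            rows.append(
                {
                    "class": c,
                    "name": DEFAULT_SCHEME.name(c),
                    "dice_mean": dm,
                    "dice_sd": dsd,
                    "iou_mean": im,
                    "iou_sd": isd,
                }
            )
        rows.append(
            {
                "class": -1,
                "name": "all",
                "dice_mean": self.pooled_dice,
                "dice_sd": float(np.std(self.per_study_dice)),
                "iou_mean": self.pooled_iou,
                "iou_sd": float("nan"),
            }
        )
        return pd.DataFrame(rows)

    def regional_frame(self) -> pd.DataFrame:
        """Per-region per-class Dice/IoU table (insertion/central/origin)."""
        rows = []
        for c in DEFAULT_SCHEME.muscle_classes():
            row = {"class": c, "name": DEFAULT_SCHEME.name(c)}
            for r in REGIONS:
                d, i = self.regional[r].get(c, (float("nan"),) * 2)
                row[f"{r}_dice"] = d
                row[f"{r}_iou"] = i
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """Full report bundle as JSON."""
        import json

        def tup(d):
            return {str(k): list(v) for k, v in d.items()}

        bundle = {
            "pooled_dice": self.pooled_dice,
            "pooled_iou": self.pooled_iou,
            "per_class_dice": tup(self.per_class_dice),
            "per_class_iou": tup(self.per_class_iou),
            "regional": {r: tup(self.regional[r]) for r in REGIONS},
            "noise_sd_hu": self.noise_sd_hu,
            "n_undefined_pairs": self.n_undefined_pairs,
            "per_study_dice": self.per_study_dice,
        }
        if self.thickness is not None:
            bundle["thickness"] = {
                "mae_mm": self.thickness.mae,
                "mape_percent": self.thickness.mape_percent,
                "n": self.thickness.n,
            }
        if self.area is not None:
            bundle["area"] = {
                "mae_mm2": self.area.mae,
                "mape_percent": self.area.mape_percent,
                "n": self.area.n,
            }
        return json.dumps(bundle, indent=2)


def evaluate_cohort(
    pred_truth_pairs: list[tuple[LabelVolume, LabelVolume]],
    measure_pairs: list[tuple[LabelVolume, LabelVolume]] | None = None,
    noise_sd_hu: float = 0.0,
) -> EvalReport:
    """Per-class and pooled Dice/IoU across studies plus size-error tables.

    ``pred_truth_pairs`` are (prediction, ground truth) on the grid used for
    overlap metrics.  ``measure_pairs`` (defaults to the same pairs) are the
    volumes used for thickness/area measurement, typically on the native grid.
    """
    muscle = DEFAULT_SCHEME.muscle_classes()
    dice_by_class = {c: [] for c in muscle}
    iou_by_class = {c: [] for c in muscle}
    regional_acc: dict[str, dict[int, list]] = {
        r: {c: [] for c in muscle} for r in REGIONS
    }
    per_study = []
    undefined = 0
    for pred, truth in pred_truth_pairs:
        study_vals = []
        for c in muscle:
            d, i = dice_iou(pred, truth, c)
            if np.isnan(d):
                undefined += 1
                continue
            dice_by_class[c].append(d)
            iou_by_class[c].append(i)
            study_vals.append(d)
        if study_vals:
            per_study.append(float(np.mean(study_vals)))
        split = split_regions(truth)
        reg = regional_metrics(pred, truth, split)
        for r in REGIONS:
            for c in muscle:
                d, i = reg[r][c]
                if not np.isnan(d):
                    regional_acc[r][c].append((d, i))

    per_class_dice = {
        c: (float(np.mean(v)), float(np.std(v))) if v else (float("nan"),) * 2
        for c, v in dice_by_class.items()
    }
    per_class_iou = {
        c: (float(np.mean(v)), float(np.std(v))) if v else (float("nan"),) * 2
        for c, v in iou_by_class.items()
    }
    regional = {
        r: {
            c: tuple(np.mean(np.asarray(v), axis=0)) if v else (float("nan"),) * 2
            for c, v in regional_acc[r].items()
        }
        for r in REGIONS
    }
    pooled_dice = float(np.mean([v for vals in dice_by_class.values() for v in vals]))
    pooled_iou = float(np.mean([v for vals in iou_by_class.values() for v in vals]))

    thickness = area = None
    if measure_pairs is None:
        measure_pairs = pred_truth_pairs
    pred_reports = [measure_volume(p) for p, _ in measure_pairs]
    truth_reports = [measure_volume(t) for _, t in measure_pairs]
    thickness = compare_measurements(pred_reports, truth_reports, "thickness")
    area = compare_measurements(pred_reports, truth_reports, "area")

    return EvalReport(
        per_class_dice=per_class_dice,
        per_class_iou=per_class_iou,
        pooled_dice=pooled_dice,
        pooled_iou=pooled_iou,
        regional=regional,
        thickness=thickness,
        area=area,
        noise_sd_hu=noise_sd_hu,
        n_undefined_pairs=undefined,
        per_study_dice=per_study,
    )


def noise_robustness(
    model,
    cohort: list[tuple[CTVolume, LabelVolume]],
    sd_list: tuple[float, ...] = (0.0, 5.0, 10.0),
    stride: int = 64,
    seed: int = 0,
) -> dict[float, EvalReport]:
    """Repeat the full evaluation with Gaussian HU noise added to the inputs.

    ``cohort`` pairs are native-grid (HU) volumes with ground-truth labels;
    preprocessing (resample + window) runs inside, after noise injection, so
    the noise is applied in HU as during acquisition.
    """
    from .inference import predict_volume, restore_native_grid
    from .preproc import resample_isometric, resample_labels, window_hu
    from .volume import CTVolume as _CT

    out: dict[float, EvalReport] = {}
    for sd in sd_list:
        rng = np.random.default_rng(seed)
        overlap_pairs = []
        measure_pairs = []
        for vol, lab in cohort:
            hu = vol.voxels.astype(np.float32)
            if sd > 0:
                hu = hu + rng.normal(0.0, sd, hu.shape).astype(np.float32)
            noisy = _CT(hu, vol.pixel_spacing, vol.slice_spacing, vol.source_id)
            iso = resample_isometric(noisy)
            lab_iso = resample_labels(lab)
            windowed = _CT(
                window_hu(iso), iso.pixel_spacing, iso.slice_spacing, iso.source_id
            )
            pred = predict_volume(model, windowed, stride=stride)
            overlap_pairs.append((pred, lab_iso))
            measure_pairs.append((restore_native_grid(pred, vol), lab))
        out[sd] = evaluate_cohort(overlap_pairs, measure_pairs, noise_sd_hu=sd)
    return out
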