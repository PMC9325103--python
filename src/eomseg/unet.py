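"""2-D U-net for multiclass extraocular-muscle segmentation.

Encoder–decoder with four 2×2 max-pooling stages, channel count doubling from
``base_filters`` at each stage, skip connections by concatenation, 2×2
transposed-convolution upsampling, inverted dropout in the two deepest
encoder blocks, and a per-pixel 9-class softmax head.  Every convolution is
followed by instance normalisation then ReLU — without a normalisation layer
this depth of plain conv+ReLU attenuates activations so strongly that the
softmax never leaves uniform at practical learning rates.  Weights use
Glorot-normal (Xavier) initialisation; optimisation is Adam.

Training follows a patch regime: each step consumes ``batch_patches`` (20)
patches drawn from ``images_per_step`` (4) training volumes (5 patches per
volume, orbit / non-orbit balanced), augmented by rotation, scaling and
Gaussian HU noise.  One epoch is a pass in which every training volume is
drawn once as a member of a 4-volume step group.  Early stopping monitors the
validation macro-Dice with a configurable patience inside the epoch cap; an
optional wall-clock cap mirrors protocols that bound total training time.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .losses import (
    LossBatch,
    compound_loss,
    inverse_frequency_weights,
    signed_distance_map,
    LOSS_RECIPES,
)
from .preproc import PatchSet, augment, sample_patches_counts
from .scheme import DEFAULT_SCHEME, ClassScheme
from .volume import CTVolume, LabelVolume

__all__ = ["TrainConfig", "SegModel", "build_unet", "train", "crossvalidate"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_patches: int = 20
    images_per_step: int = 4
    max_epochs: int = 100
    dropout_keep_p: float = 0.8
    patch_size: int = 128
    pooling_stages: int = 4
    base_filters: int = 16
    loss_recipe: str = "wce+dice"
    seed: int = 0
    k_folds: int = 10
    # early stopping / budget
    patience: int = 10
    min_delta: float = 1e-4
    max_train_seconds: float | None = None
    val_patches: int = 32  # fixed validation patch budget for early stopping
    # augmentation
    rotation_deg_range: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_sd_hu: float = 10.0
    # boundary-term linear ramp from 0 to 1 over training (off by default)
    boundary_ramp: bool = False
    # tversky / focal parameters
    tversky_alpha: float = 0.7
    tversky_beta: float = 0.3
    gamma: float = 4.0 / 3.0
    verbose: bool = False

    def validate(self) -> None:
        div = 2**self.pooling_stages
        if self.patch_size % div != 0:
            raise ValueError(
                f"patch_size={self.patch_size} must be divisible by "
                f"2^{self.pooling_stages}={div} (four pooling stages halve "
                "the grid four times)"
            )
        if self.patch_size < 16:
            raise ValueError("patch_size must be ≥ 16 (the architectural minimum)")
        if not 0.0 < self.dropout_keep_p <= 1.0:
            raise ValueError("dropout_keep_p must lie in (0, 1]")
        if self.loss_recipe not in LOSS_RECIPES:
            raise ValueError(
                f"loss_recipe {self.loss_recipe!r} not one of {LOSS_RECIPES}"
            )


class SegModel:
    """Parameter container plus forward/backward passes."""

    def __init__(
        self,
        config: TrainConfig,
        scheme: ClassScheme = DEFAULT_SCHEME,
        params: dict[str, np.ndarray] | None = None,
    ):
        config.validate()
        self.config = config
        self.scheme = scheme
        self.n_classes = scheme.n_classes
        self._ws = nn.Workspace()
        self.log: list[dict] = []
        self.class_weights: np.ndarray | None = None
        self.params = params if params is not None else self._init_params()

    # -- architecture ----------------------------------------------------
    def _channels(self) -> list[int]:
        f = self.config.base_filters
        return [f * 2**l for l in range(self.config.pooling_stages + 1)]

    def _init_params(self) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(self.config.seed)
        ch = self._channels()
        p: dict[str, np.ndarray] = {}

        def conv(name, cin, cout):
            p[f"{name}_w"] = nn.glorot_normal(rng, (9 * cin, cout), 9 * cin, 9 * cout)
            p[f"{name}_b"] = np.zeros(cout, dtype=np.float32)
            p[f"{name}_g"] = np.ones(cout, dtype=np.float32)  # instance-norm scale
            p[f"{name}_beta"] = np.zeros(cout, dtype=np.float32)

        def up(name, cin, cout):
            p[f"{name}_w"] = nn.glorot_normal(rng, (2, 2, cin, cout), 4 * cin, 4 * cout)
            p[f"{name}_b"] = np.zeros(cout, dtype=np.float32)
            p[f"{name}_g"] = np.ones(cout, dtype=np.float32)
            p[f"{name}_beta"] = np.zeros(cout, dtype=np.float32)

        prev = 1
        for l, c in enumerate(ch[:-1], start=1):
            conv(f"enc{l}_conv1", prev, c)
            conv(f"enc{l}_conv2", c, c)
            prev = c
        conv("bott_conv1", prev, ch[-1])
        conv("bott_conv2", ch[-1], ch[-1])
        prev = ch[-1]
        for l in range(len(ch) - 1, 0, -1):
            c = ch[l - 1]
            up(f"dec{l}_up", prev, c)
            conv(f"dec{l}_conv1", 2 * c, c)
            conv(f"dec{l}_conv2", c, c)
            prev = c
        p["out_w"] = nn.glorot_normal(
            rng, (prev, self.n_classes), prev, self.n_classes
        )
        p["out_b"] = np.zeros(self.n_classes, dtype=np.float32)
        return p

    # -- forward / backward ----------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """x: (N, H, W) or (N, H, W, 1) in [0, 1] → probs (N, H, W, C)."""
        if x.ndim == 3:
            x = x[..., None]
        n, h, w, _ = x.shape
        div = 2**self.config.pooling_stages
        if h % div or w % div or h < 16 or w < 16:
            raise ValueError(
                f"input {h}×{w} must be ≥16 and divisible by {div} "
                f"({self.config.pooling_stages} pooling stages)"
            )
        x = np.ascontiguousarray(x, dtype=np.float32)
        p = self.params
        L = self.config.pooling_stages
        keep = self.config.dropout_keep_p if training else 1.0
        cache: dict = {}

        ws = self._ws

        def block(name, t):
            t, cache[f"{name}_c1"] = nn.conv3x3_forward(
                t, p[f"{name}_conv1_w"], p[f"{name}_conv1_b"], ws, f"{name}_c1"
            )
            t, cache[f"{name}_n1"] = nn.instnorm_forward(
                t, p[f"{name}_conv1_g"], p[f"{name}_conv1_beta"]
            )
            t, cache[f"{name}_r1"] = nn.relu_forward(t, inplace=True)
            t, cache[f"{name}_c2"] = nn.conv3x3_forward(
                t, p[f"{name}_conv2_w"], p[f"{name}_conv2_b"], ws, f"{name}_c2"
            )
            t, cache[f"{name}_n2"] = nn.instnorm_forward(
                t, p[f"{name}_conv2_g"], p[f"{name}_conv2_beta"]
            )
            t, cache[f"{name}_r2"] = nn.relu_forward(t, inplace=True)
            return t

        skips = {}
        t = x
        for l in range(1, L + 1):
            t = block(f"enc{l}", t)
            if l == L:  # deepest encoder block: dropout
                t, cache[f"enc{l}_drop"] = nn.dropout_forward(t, keep, rng or np.random.default_rng())
            skips[l] = t
            t, cache[f"pool{l}"] = nn.maxpool2_forward(t)
        t = block("bott", t)
        t, cache["bott_drop"] = nn.dropout_forward(t, keep, rng or np.random.default_rng())
        for l in range(L, 0, -1):
            t, cache[f"dec{l}_upc"] = nn.upconv2_forward(
                t, p[f"dec{l}_up_w"], p[f"dec{l}_up_b"]
            )
            t, cache[f"dec{l}_upn"] = nn.instnorm_forward(
                t, p[f"dec{l}_up_g"], p[f"dec{l}_up_beta"]
            )
            t, cache[f"dec{l}_upr"] = nn.relu_forward(t, inplace=True)
            cache[f"dec{l}_skipc"] = skips[l].shape[-1]
            t = np.concatenate([skips[l], t], axis=-1)
            t = block(f"dec{l}", t)
        logits, cache["out"] = nn.conv1x1_forward(t, p["out_w"], p["out_b"])
        probs = nn.softmax(logits)
        cache["probs"] = probs
        return probs, cache

    def backward(self, dprobs: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """dL/dprobs (N, H, W, C) → parameter gradients."""
        p = self.params
        L = self.config.pooling_stages
        grads: dict[str, np.ndarray] = {}

        d = nn.softmax_backward(dprobs.astype(np.float32), cache["probs"])
        d, grads["out_w"], grads["out_b"] = nn.conv1x1_backward(
            d, cache["out"], p["out_w"]
        )

        ws = self._ws

        def block_back(name, d, need_dx=True):
            d = nn.relu_backward(d, cache[f"{name}_r2"])
            d, grads[f"{name}_conv2_g"], grads[f"{name}_conv2_beta"] = nn.instnorm_backward(
                d, cache[f"{name}_n2"]
            )
            d, grads[f"{name}_conv2_w"], grads[f"{name}_conv2_b"] = nn.conv3x3_backward(
                d, cache[f"{name}_c2"], p[f"{name}_conv2_w"], ws, f"{name}_c2"
            )
            d = nn.relu_backward(d, cache[f"{name}_r1"])
            d, grads[f"{name}_conv1_g"], grads[f"{name}_conv1_beta"] = nn.instnorm_backward(
                d, cache[f"{name}_n1"]
            )
            d, grads[f"{name}_conv1_w"], grads[f"{name}_conv1_b"] = nn.conv3x3_backward(
                d, cache[f"{name}_c1"], p[f"{name}_conv1_w"], ws, f"{name}_c1",
                need_dx=need_dx,
            )
            return d

        dskips = {}
        for l in range(1, L + 1):
            d = block_back(f"dec{l}", d)
            csk = cache[f"dec{l}_skipc"]
            # d may live in shared scratch that later layers overwrite: copy
            # the skip gradient, which is consumed only in the encoder sweep
            dskips[l] = np.ascontiguousarray(d[..., :csk])
            d = d[..., csk:]
            d = nn.relu_backward(d, cache[f"dec{l}_upr"])
            d, grads[f"dec{l}_up_g"], grads[f"dec{l}_up_beta"] = nn.instnorm_backward(
                d, cache[f"dec{l}_upn"]
            )
            d, grads[f"dec{l}_up_w"], grads[f"dec{l}_up_b"] = nn.upconv2_backward(
                d, cache[f"dec{l}_upc"], p[f"dec{l}_up_w"]
            )
        d = nn.dropout_backward(d, cache["bott_drop"])
        d = block_back("bott", d)
        for l in range(L, 0, -1):
            d = nn.maxpool2_backward(d, cache[f"pool{l}"])
            d = d + dskips[l]
            if l == L:
                d = nn.dropout_backward(d, cache[f"enc{l}_drop"])
            d = block_back(f"enc{l}", d, need_dx=(l > 1))
        return grads

    def predict_patch(self, patches: np.ndarray, batch: int = 4) -> np.ndarray:
        """Inference forward pass (dropout off) in small minibatches."""
        patches = np.asarray(patches, dtype=np.float32)
        single = patches.ndim == 2
        if single:
            patches = patches[None]
        outs = []
        for i in range(0, len(patches), batch):
            probs, _ = self.forward(patches[i : i + batch], training=False)
            outs.append(probs)
        out = np.concatenate(outs, axis=0)
        return out[0] if single else out

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "scheme": self.scheme.to_json(),
            "log": self.log,
            "class_weights": None
            if self.class_weights is None
            else list(map(float, self.class_weights)),
        }
        np.savez_compressed(path, __meta__=json.dumps(meta), **self.params)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        data = np.load(str(path), allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg_d = meta["config"]
        for k in ("rotation_deg_range", "scale_range"):
            if isinstance(cfg_d.get(k), list):
                cfg_d[k] = tuple(cfg_d[k])
        config = TrainConfig(**cfg_d)
        scheme = ClassScheme.from_json(meta["scheme"])
        params = {k: data[k] for k in data.files if k != "__meta__"}
        model = cls(config, scheme, params=params)
        model.log = meta["log"]
        if meta["class_weights"] is not None:
            model.class_weights = np.asarray(meta["class_weights"])
        return model


def build_unet(config: TrainConfig, scheme: ClassScheme = DEFAULT_SCHEME) -> SegModel:
    """Fresh, Glorot-initialised model; identical seed ⇒ identical weights."""
    return SegModel(config, scheme)


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros(labels.shape + (n_classes,), dtype=np.float32)
    np.put_along_axis(out, labels[..., None].astype(np.intp), 1.0, axis=-1)
    return out


def _phi_for_patches(label_patches: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class signed distance maps, NaN where a class is degenerate."""
    n, h, w = label_patches.shape
    phi = np.full((n, h, w, n_classes), np.nan, dtype=np.float32)
    for i in range(n):
        for c in range(1, n_classes):
            m = label_patches[i] == c
            if m.any() and not m.all():
                phi[i, :, :, c] = signed_distance_map(m)
    return phi


def macro_dice(pred: np.ndarray, truth: np.ndarray, classes) -> float:
    """Hard macro-Dice over the given classes, pooled over all given pixels.

    Classes empty in both prediction and truth are excluded.
    """
    vals = []
    for c in classes:
        p = pred == c
        g = truth == c
        denom = p.sum() + g.sum()
        if denom == 0:
            continue
        vals.append(2.0 * np.logical_and(p, g).sum() / denom)
    return float(np.mean(vals)) if vals else float("nan")


def _draw_step_patches(
    volumes: list[tuple[CTVolume, LabelVolume]],
    idx: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> PatchSet:
    """Draw ``batch_patches`` patches from the volumes at ``idx``, balanced."""
    per = config.batch_patches // len(idx)
    images, lbls, prov = [], [], []
    for j, vi in enumerate(idx):
        vol, lab = volumes[vi]
        n_orbit = (per + 1) // 2 if j % 2 == 0 else per // 2
        ps = sample_patches_counts(
            vol, lab, n_orbit, per - n_orbit, config.patch_size, rng
        )
        images += ps.image_patches
        lbls += ps.label_patches
        prov += ps.provenance
    return PatchSet(images, lbls, prov)


def train(
    model: SegModel,
    train_data: list[tuple[CTVolume, LabelVolume]],
    val_data: list[tuple[CTVolume, LabelVolume]],
    config: TrainConfig | None = None,
) -> SegModel:
    """Train in place; returns the model with best-validation weights restored.

    ``train_data``/``val_data`` are preprocessed (isometric, windowed) volume /
    label pairs.  The training log gains one entry per epoch with the mean
    step loss, each compound member, and the per-class validation Dice.
    """
    config = config or model.config
    if not train_data or not val_data:
        raise ValueError("train_data and val_data must be non-empty")
    rng = np.random.default_rng(config.seed + 1)

    if model.class_weights is None:
        model.class_weights = inverse_frequency_weights(
            [lab.labels for _, lab in train_data], model.n_classes
        )
    w = model.class_weights

    opt = nn.Adam(config.learning_rate, config.adam_beta1, config.adam_beta2)
    need_phi = "boundary" in config.loss_recipe

    # fixed validation patches for early stopping
    per_val = max(1, config.val_patches // len(val_data))
    vx, vy = [], []
    for vol, lab in val_data:
        ps = sample_patches_counts(
            vol, lab, per_val, 0, config.patch_size, np.random.default_rng(config.seed + 2)
        )
        vx += ps.image_patches
        vy += ps.label_patches
    vx = np.stack(vx)
    vy = np.stack(vy)
    muscle = model.scheme.muscle_classes()

    steps_per_epoch = int(np.ceil(len(train_data) / config.images_per_step))
    total_steps = steps_per_epoch * config.max_epochs
    best = (-np.inf, None, -1)  # (val dice, params copy, epoch)
    t0 = time.monotonic()
    stop = False
    step_count = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_data))
        groups = [
            order[i : i + config.images_per_step]
            for i in range(0, len(order), config.images_per_step)
        ]
        epoch_loss, members_acc = [], {}
        for g_idx in groups:
            if len(g_idx) < config.images_per_step:
                pool = np.setdiff1d(order, g_idx)
                need = config.images_per_step - len(g_idx)
                if len(pool) >= need:
                    extra = rng.choice(pool, need, replace=False)
                else:  # tiny cohorts: allow repeated volumes within a step
                    extra = rng.choice(order, need, replace=True)
                g_idx = np.concatenate([g_idx, extra])
            ps = _draw_step_patches(train_data, g_idx, config, rng)
            ps = augment(
                ps,
                rng,
                config.rotation_deg_range,
                config.scale_range,
                config.noise_sd_hu,
            )
            x = np.stack(ps.image_patches)
            y = np.stack(ps.label_patches)
            probs, cache = model.forward(x, training=True, rng=rng)
            flat_probs = probs.reshape(-1, model.n_classes)
            flat_onehot = _onehot(y, model.n_classes).reshape(-1, model.n_classes)
            phi = (
                _phi_for_patches(y, model.n_classes).reshape(-1, model.n_classes)
                if need_phi
                else None
            )
            ramp = (step_count / max(total_steps - 1, 1)) if config.boundary_ramp else 1.0
            batch = LossBatch(
                probs=flat_probs,
                onehot=flat_onehot,
                class_weights=w,
                phi_g=phi,
                tversky_alpha=config.tversky_alpha,
                tversky_beta=config.tversky_beta,
                gamma=config.gamma,
                validate=False,
            )
            members: dict[str, float] = {}
            loss, dflat = compound_loss(
                batch, config.loss_recipe, boundary_weight=ramp, grad=True,
                members=members,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"loss diverged to {loss} at epoch {epoch}, step {step_count}; "
                    f"members={members}"
                )
            grads = model.backward(dflat.reshape(probs.shape), cache)
            opt.step(model.params, grads)
            epoch_loss.append(loss)
            for k, v in members.items():
                members_acc.setdefault(k, []).append(v)
            step_count += 1

        vpred = model.predict_patch(vx).argmax(axis=-1)
        per_class = {
            c: macro_dice(vpred, vy, [c]) for c in muscle
        }
        val = macro_dice(vpred, vy, muscle)
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(epoch_loss)),
            "val_dice": val,
            **{f"loss_{k}": float(np.mean(v)) for k, v in members_acc.items()},
            **{f"val_dice_{c}": per_class[c] for c in muscle},
        }
        model.log.append(entry)
        if config.verbose:
            print(
                f"epoch {epoch:3d}  loss {entry['loss']:.4f}  val Dice {val:.4f}",
                flush=True,
            )

        if val > best[0] + config.min_delta:
            best = (val, {k: v.copy() for k, v in model.params.items()}, epoch)
        elif epoch - best[2] >= config.patience:
            stop = True
        if (
            config.max_train_seconds is not None
            and time.monotonic() - t0 > config.max_train_seconds
        ):
            stop = True
        if stop:
            break

    if best[1] is not None:
        model.params = best[1]
    return model


def crossvalidate(
    cohort: list[tuple[CTVolume, LabelVolume]],
    config: TrainConfig,
    stride: int = 64,
) -> dict:
    """k-fold cross-validation; every volume validates exactly once.

    Returns per-fold per-class Dice plus the mean ± sd aggregate across folds.
    """
    from .evaluation import dice_iou
    from .inference import predict_volume

    k = config.k_folds
    if len(cohort) < k:
        raise ValueError(f"cohort of {len(cohort)} is smaller than k={k}")
    idx = np.arange(len(cohort))
    folds = np.array_split(idx, k)
    muscle = DEFAULT_SCHEME.muscle_classes()

    fold_records = []
    for fi, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(idx, val_idx)
        cfg = replace(config, seed=config.seed + fi)
        model = build_unet(cfg)
        val_pairs = [cohort[i] for i in val_idx]
        model = train(model, [cohort[i] for i in train_idx], val_pairs, cfg)
        per_class = {c: [] for c in muscle}
        for vol, lab in val_pairs:
            pred = predict_volume(model, vol, stride=stride)
            for c in muscle:
                d, _ = dice_iou(pred, lab, c)
                if not np.isnan(d):
                    per_class[c].append(d)
        fold_records.append(
            {
                "fold": fi,
                "val_indices": [int(i) for i in val_idx],
                "dice_per_class": {
                    c: float(np.mean(v)) if v else float("nan")
                    for c, v in per_class.items()
                },
            }
        )
    per_class_matrix = {
        c: np.array([f["dice_per_class"][c] for f in fold_records]) for c in muscle
    }
    aggregate = {
        c: (float(np.nanmean(v)), float(np.nanstd(v)))
        for c, v in per_class_matrix.items()
    }
    pooled = np.array([list(f["dice_per_class"].values()) for f in fold_records])
    return {
        "folds": fold_records,
        "aggregate_per_class": aggregate,
        "pooled_mean": float(np.nanmean(pooled)),
        "pooled_sd": float(np.nanstd(np.nanmean(pooled, axis=1))),
    }
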