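"""Training and evaluation of the bone-age regressor.

Targets are standardized bone ages, Y' = (Y - mu) / sigma with mu/sigma the
training split's mean and standard deviation; the network minimizes the mean
squared error on Y' by SGD with momentum 0.9, the learning rate decaying by
a factor of 10 every 30 epochs.  Reported errors are mean absolute errors in
months, after destandardization.

``BoneAgeModel`` / ``BoneAgeResults`` provide the model-object interface;
``train`` is the underlying procedural entry point.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize, rotate

from . import nn
from .architecture import BoneAgeNet, prepare_batch

__all__ = [
    "AgeStandardizer", "AugmentConfig", "TrainConfig", "SplitSpec",
    "standardize", "destandardize", "mse_loss", "split_dataset",
    "learning_rate_at", "train", "evaluate_mae",
    "BoneAgeModel", "BoneAgeResults",
]


@dataclass(frozen=True)
class AgeStandardizer:
    """Mean/std of the training split's bone ages, in months."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def fit(cls, ages) -> "AgeStandardizer":
        ages = np.asarray(ages, dtype=np.float64)
        sigma = float(ages.std())
        if sigma == 0.0:
            raise ValueError("cannot standardize: zero age variance in training split")
        return cls(mu=float(ages.mean()), sigma=sigma)


def standardize(age_months, s: AgeStandardizer):
    return (np.asarray(age_months, dtype=np.float64) - s.mu) / s.sigma


def destandardize(value, s: AgeStandardizer):
    return np.asarray(value, dtype=np.float64) * s.sigma + s.mu


def mse_loss(predictions, targets) -> float:
    """Mean of squared differences."""
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.shape != targets.shape:
        raise ValueError("prediction/target length mismatch")
    if predictions.size == 0:
        raise ValueError("empty prediction vector")
    return float(np.mean((predictions - targets) ** 2))


@dataclass(frozen=True)
class SplitSpec:
    """Random 7:2:1 train/validation/test partition."""

    train_fraction: float = 0.7
    val_fraction: float = 0.2
    test_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(n_records: int, spec: SplitSpec | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded shuffle then contiguous partition at the 70%/90% cut points."""
    spec = spec or SplitSpec()
    if n_records < 10:
        raise ValueError("need at least 10 records to split without empty sets")
    perm = np.random.default_rng(spec.seed).permutation(n_records)
    c1 = int(np.floor(spec.train_fraction * n_records + 1e-9))
    c2 = int(np.floor((spec.train_fraction + spec.val_fraction) * n_records + 1e-9))
    return perm[:c1], perm[c1:c2], perm[c2:]


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation ranges (identity when disabled)."""

    enabled: bool = True
    crop_fraction: tuple[float, float] = (0.9, 1.0)
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    contrast: tuple[float, float] = (0.9, 1.1)
    brightness: tuple[float, float] = (-0.1, 0.1)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 10
    epochs: int = 160
    base_lr: float = 0.01
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 30
    momentum: float = 0.9
    input_size: int = 224
    use_gender: bool = True
    use_preprocess: bool = True
    use_pretrained: bool = False
    pretrained_path: str | None = None
    seed: int = 0
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.lr_decay_every < 1:
            raise ValueError("counts must be >= 1")
        if not self.lr_decay_factor > 1:
            raise ValueError("decay factor must exceed 1")


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """lr(epoch) = base_lr / decay_factor ** floor(epoch / decay_every)."""
    return config.base_lr / config.lr_decay_factor ** (epoch // config.lr_decay_every)


def _augment(image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Random crop/resize, rotation, contrast and brightness jitter."""
    out = image
    frac = rng.uniform(*cfg.crop_fraction)
    if frac < 1.0:
        h, w = out.shape
        ch, cw = max(1, int(round(frac * h))), max(1, int(round(frac * w)))
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        out = resize(out[r0:r0 + ch, c0:c0 + cw], (h, w), anti_aliasing=True)
    angle = rng.uniform(*cfg.rotation_deg)
    if angle:
        out = rotate(out, angle, mode="edge")
    out = out * rng.uniform(*cfg.contrast) + rng.uniform(*cfg.brightness)
    return np.clip(out, 0.0, 1.0)


def _load_pretrained(model: BoneAgeNet, path: str) -> None:
    from .io import load_checkpoint_state

    state = load_checkpoint_state(path)
    model.load_state_dict(state)


@dataclass
class TrainHistory:
    epoch: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    train_mse: list = field(default_factory=list)
    val_mae_months: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"epoch": self.epoch, "lr": self.lr,
                             "train_mse": self.train_mse,
                             "val_mae_months": self.val_mae_months})


def train(images: np.ndarray, male: np.ndarray, ages: np.ndarray,
          config: TrainConfig, val_indices: np.ndarray | None = None,
          train_indices: np.ndarray | None = None, verbose: bool = False
          ) -> tuple[BoneAgeNet, AgeStandardizer, TrainHistory]:
    """Fit the regressor on pre-sized images.

    ``images``: (N, H, W) float in [0, 1] already at ``config.input_size``.
    The standardizer is fitted on the training indices only; augmentation is
    applied to training images only; the checkpoint with the best validation
    MAE is restored at the end (final parameters when no validation split).
    """
    images = np.asarray(images)
    male = np.asarray(male, dtype=bool)
    ages = np.asarray(ages, dtype=np.float64)
    n = len(images)
    if train_indices is None:
        train_indices = np.arange(n)
    standardizer = AgeStandardizer.fit(ages[train_indices])
    targets = standardize(ages, standardizer)

    rng = np.random.default_rng(config.seed)
    model = BoneAgeNet(use_gender=config.use_gender, rng=rng)
    if config.use_pretrained and config.pretrained_path:
        _load_pretrained(model, config.pretrained_path)
    opt = nn.SGD(model.parameters(), lr=config.base_lr, momentum=config.momentum)

    history = TrainHistory()
    best_val, best_state = np.inf, None
    aug = config.augmentation
    for epoch in range(config.epochs):
        opt.lr = learning_rate_at(epoch, config)
        order = rng.permutation(train_indices)
        model.train()
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = images[idx].astype(np.float64)
            if aug.enabled:
                batch = np.stack([_augment(im, aug, rng) for im in batch])
            x = nn.Tensor(prepare_batch(batch))
            g = nn.Tensor(male[idx].astype(np.float32).reshape(-1, 1)) \
                if config.use_gender else None
            pred = model.forward(x, g)
            diff = pred - nn.Tensor(targets[idx].astype(np.float32))
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}, "
                                   f"step {start // config.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        val_mae = np.nan
        if val_indices is not None and len(val_indices) > 0:
            val_mae = evaluate_mae(model, images[val_indices], male[val_indices],
                                   ages[val_indices], standardizer)
            if val_mae < best_val:
                best_val = val_mae
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
        history.epoch.append(epoch)
        history.lr.append(opt.lr)
        history.train_mse.append(float(np.mean(epoch_losses)))
        history.val_mae_months.append(val_mae)
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  "
                  f"train MSE {history.train_mse[-1]:.4f}  val MAE {val_mae:.2f}")

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, standardizer, history


def evaluate_mae(model: BoneAgeNet, images, male, ages,
                 standardizer: AgeStandardizer, batch_size: int = 10) -> float:
    """Mean absolute error in months over a record set."""
    images = np.asarray(images)
    ages = np.asarray(ages, dtype=np.float64)
    male = np.asarray(male, dtype=bool)
    if len(images) == 0:
        raise ValueError("empty record set")
    preds = []
    for start in range(0, len(images), batch_size):
        sl = slice(start, start + batch_size)
        preds.append(model.predict(images[sl].astype(np.float64),
                                   male[sl] if model.use_gender else None))
    months = destandardize(np.concatenate(preds), standardizer)
    return float(np.mean(np.abs(months - ages)))


# --------------------------------------------------------------------------
# model-object interface
# --------------------------------------------------------------------------

class BoneAgeModel:
    """Bone-age regression model bound to a dataset.

    Parameters
    ----------
    images : (N, H, W) array of model-input images in [0, 1]
    male : (N,) boolean gender flags
    ages : (N,) ground-truth bone ages in months
    config : TrainConfig
    splits : optional (train, val, test) index arrays; defaults to a seeded
        7:2:1 partition when the dataset is large enough, otherwise
        train-on-everything.
    """

    def __init__(self, images, male, ages, config: TrainConfig | None = None,
                 splits=None):
        self.images = np.asarray(images)
        self.male = np.asarray(male, dtype=bool)
        self.ages = np.asarray(ages, dtype=np.float64)
        if not (len(self.images) == len(self.male) == len(self.ages)):
            raise ValueError("images, male and ages must have equal length")
        self.config = config or TrainConfig()
        if splits is None and len(self.images) >= 10:
            splits = split_dataset(len(self.images), SplitSpec(seed=self.config.seed))
        self.splits = splits

    @classmethod
    def from_dataframe(cls, frame, images, config: TrainConfig | None = None,
                       splits=None) -> "BoneAgeModel":
        """Build from an ``id,boneage,male`` metadata frame plus an
        ``{id: image}`` mapping (images already at model input size)."""
        imgs = np.stack([images[i] for i in frame["id"]])
        return cls(imgs, frame["male"].to_numpy(dtype=bool),
                   frame["boneage"].to_numpy(dtype=np.float64), config, splits)

    def fit(self, verbose: bool = False) -> "BoneAgeResults":
        t0 = time.time()
        if self.splits is not None:
            tr, va, te = self.splits
        else:
            tr, va, te = np.arange(len(self.images)), None, None
        net, standardizer, history = train(
            self.images, self.male, self.ages, self.config,
            train_indices=np.asarray(tr),
            val_indices=None if va is None else np.asarray(va), verbose=verbose)
        return BoneAgeResults(model=self, net=net, standardizer=standardizer,
                              history=history, fit_seconds=time.time() - t0)


@dataclass
class BoneAgeResults:
    """Fitted regressor: network weights, age standardizer and history."""

    model: BoneAgeModel
    net: BoneAgeNet
    standardizer: AgeStandardizer
    history: TrainHistory
    fit_seconds: float

    def predict_months(self, images, male=None) -> np.ndarray:
        """Bone-age predictions in months (destandardized)."""
        preds = self.net.predict(np.asarray(images, dtype=np.float64), male)
        return destandardize(preds, self.standardizer)

    def mae(self, subset: str = "test") -> float:
        """MAE in months on one of the model's splits ('train'/'val'/'test')."""
        if self.model.splits is None:
            idx = np.arange(len(self.model.images))
        else:
            idx = dict(zip(("train", "val", "test"), self.model.splits))[subset]
        idx = np.asarray(idx)
        return evaluate_mae(self.net, self.model.images[idx], self.model.male[idx],
                            self.model.ages[idx], self.standardizer)

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        lines = [
            "Gender-embedded bone-age regression",
            "=" * 52,
            f"records              : {len(self.model.images)}",
            f"input size           : {cfg.input_size} x {cfg.input_size}",
            f"gender embedding     : {'on' if cfg.use_gender else 'off'}",
            f"parameters           : {self.net.n_parameters():,}",
            f"age standardizer     : mu = {self.standardizer.mu:.1f} mo, "
            f"sigma = {self.standardizer.sigma:.1f} mo",
            f"epochs               : {len(h.epoch)} "
            f"(batch {cfg.batch_size}, base lr {cfg.base_lr}, momentum {cfg.momentum})",
            f"final train MSE      : {h.train_mse[-1]:.4f} (standardized units)",
        ]
        vals = [v for v in h.val_mae_months if np.isfinite(v)]
        if vals:
            lines.append(f"best val MAE         : {min(vals):.1f} months")
        lines.append(f"fit time             : {self.fit_seconds:.1f} s")
        return "\n".join(lines)
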