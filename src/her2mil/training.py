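"""Stratified splitting, class-balanced sampling, flip augmentation and the
optimisation loop configuration shared by the MIL and whole-image models.

The split keeps 80/20 train/validation proportions within each IHC score,
and score-2 spots are additionally stratified by HER2 status so both the
equivocal-positive and equivocal-negative groups appear in both sets.
During training, spots are drawn with replacement with inverse-class-
frequency weights so every class is equally represented, and random
horizontal/vertical flips augment the images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import SpotLabel


@dataclass
class SplitPlan:
    """Disjoint train/validation spot-id lists plus the stratum of each id."""

    train_ids: list[str]
    val_ids: list[str]
    strata: dict[str, str] = field(default_factory=dict)


def stratified_indices(y, train_frac: float, seed: int,
                       round_mode: str = "floor") -> tuple[np.ndarray, np.ndarray]:
    """Per-stratum index split: train gets floor(train_frac * n) of each
    stratum (or round-to-nearest with ``round_mode="nearest"``), the
    remainder goes to validation.  Shuffling depends only on ``seed``."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train, val = [], []
    for stratum in sorted(np.unique(y).tolist()):
        idx = np.where(y == stratum)[0]
        idx = idx[rng.permutation(len(idx))]
        if round_mode == "floor":
            n_train = int(np.floor(train_frac * len(idx)))
        elif round_mode == "nearest":
            n_train = int(round(train_frac * len(idx)))
        else:
            raise ValueError(f"unknown round_mode {round_mode!r}")
        train.extend(idx[:n_train].tolist())
        val.extend(idx[n_train:].tolist())
    return np.array(sorted(train), dtype=int), np.array(sorted(val), dtype=int)


def _stratum_key(label: SpotLabel) -> str:
    # score-2 spots are split separately per HER2 status
    if label.ihc_score == 2:
        return f"2{'+' if label.her2_status == 1 else '-'}"
    return str(label.ihc_score)


def stratified_split(labels: list[SpotLabel], train_frac: float = 0.8,
                     seed: int = 0, round_mode: str = "floor") -> SplitPlan:
    """80/20 split within each IHC score (score 2 further keyed by status).

    Strata of a single spot send it to validation (floor(0.8 * 1) = 0) with
    a warning, so no stratum silently trains without evaluation data.
    """
    import warnings

    strata = {lab.spot_id: _stratum_key(lab) for lab in labels}
    if len(strata) != len(labels):
        raise ValueError("duplicate spot ids in labels")
    keys = np.array([_stratum_key(lab) for lab in labels])
    for stratum in np.unique(keys):
        if (keys == stratum).sum() == 1:
            warnings.warn(
                f"stratum {stratum!r} has a single spot; it goes to validation",
                stacklevel=2,
            )
    tr, va = stratified_indices(keys, train_frac, seed, round_mode)
    ids = [lab.spot_id for lab in labels]
    return SplitPlan(
        train_ids=[ids[i] for i in tr],
        val_ids=[ids[i] for i in va],
        strata=strata,
    )


def class_balance_weights(labels) -> np.ndarray:
    """Per-sample weights 1 / (count of the sample's class); under weighted
    sampling with replacement every class is equally represented."""
    y = np.asarray([lab.ihc_score if isinstance(lab, SpotLabel) else lab
                    for lab in labels])
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts == 0):  # pragma: no cover - unique() never yields 0
        raise ValueError("empty class")
    lookup = dict(zip(classes.tolist(), counts.tolist()))
    return np.array([1.0 / lookup[v] for v in y.tolist()])


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal and vertical flips, each applied with prob. 0.5."""
    out = image
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    return out


class PlateauScheduler:
    """Reduce-on-plateau bookkeeping for a maximised validation metric.

    ``update`` returns True exactly when the metric has failed to improve
    for ``patience`` consecutive epochs; the caller applies ``factor`` to
    its learning rate.  The bad-epoch counter resets after each reduction.
    """

    def __init__(self, factor: float, patience: int):
        if not 0 < factor < 1:
            raise ValueError("factor must lie in (0, 1)")
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.factor = factor
        self.patience = patience
        self.best = -np.inf
        self.bad_epochs = 0
        self.n_reductions = 0

    def update(self, metric: float) -> bool:
        if metric > self.best:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            self.bad_epochs = 0
            self.n_reductions += 1
            return True
        return False


@dataclass
class TrainConfig:
    """Optimisation settings for either classifier.

    The ``paper`` presets carry the full-scale configuration of record
    (MIL: lr 5e-9, factor 0.3, patience 40, batch 1; whole-image: lr 1e-5,
    factor 0.1, patience 20, batch 32; Adam weight decay 1e-8, betas
    0.9/0.999).  The ``desk`` presets keep the same optimiser but shrink the
    model and learning schedule so CPU runs on synthetic cohorts finish in
    minutes.
    """

    task: str = "status"  # "score" or "status"
    model: str = "mil"  # "mil" or "wholeimage"
    scale: str = "desk"  # "desk" or "paper"
    learning_rate: float | None = None
    scheduler_factor: float | None = None
    scheduler_patience: int | None = None
    weight_decay: float = 1e-8
    adam_betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int | None = None
    max_epochs: int = 40
    seed: int = 0

    _PRESETS = {
        ("mil", "paper"): dict(learning_rate=5e-9, scheduler_factor=0.3,
                               scheduler_patience=40, batch_size=1),
        ("mil", "desk"): dict(learning_rate=1e-4, scheduler_factor=0.3,
                              scheduler_patience=8, batch_size=1),
        ("wholeimage", "paper"): dict(learning_rate=1e-5, scheduler_factor=0.1,
                                      scheduler_patience=20, batch_size=32),
        ("wholeimage", "desk"): dict(learning_rate=1e-3, scheduler_factor=0.1,
                                     scheduler_patience=8, batch_size=8),
    }

    def __post_init__(self) -> None:
        if self.task not in ("score", "status"):
            raise ValueError(f"task must be 'score' or 'status', got {self.task!r}")
        if (self.model, self.scale) not in self._PRESETS:
            raise ValueError(f"unknown model/scale {(self.model, self.scale)!r}")
        preset = self._PRESETS[(self.model, self.scale)]
        for key, value in preset.items():
            if getattr(self, key) is None:
                setattr(self, key, value)
        if self.learning_rate <= 0 and self.learning_rate != 0:
            raise ValueError("learning_rate must be non-negative")
        if not all(0 < b < 1 for b in self.adam_betas):
            raise ValueError("adam betas must lie in (0, 1)")
        if self.scheduler_patience < 1:
            raise ValueError("scheduler_patience must be positive")

    @property
    def n_classes(self) -> int:
        return 4 if self.task == "score" else 2

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "adam_betas" in raw:
            raw["adam_betas"] = tuple(raw["adam_betas"])
        return cls(**raw)


def train_model(config: TrainConfig, bags, labels: list[SpotLabel],
                **estimator_overrides):
    """Fit the configured classifier on (bags, labels) and return
    ``(estimator, history)``.

    ``bags`` are TileBags / tile stacks for the MIL model, or downscaled
    images for the whole-image model.  The class-balancing sampler, flip
    augmentation and the plateau schedule on validation balanced accuracy
    are wired in by the estimators themselves.
    """
    if len(bags) == 0:
        raise ValueError("empty training set")
    y = np.array([
        lab.ihc_score if config.task == "score" else lab.her2_status
        for lab in labels
    ])
    common = dict(
        learning_rate=config.learning_rate,
        scheduler_factor=config.scheduler_factor,
        scheduler_patience=config.scheduler_patience,
        weight_decay=config.weight_decay,
        betas=config.adam_betas,
        max_epochs=config.max_epochs,
        random_state=config.seed,
    )
    common.update(estimator_overrides)
    if config.model == "mil":
        from .mil import AttentionMILClassifier

        est = AttentionMILClassifier(**common)
    else:
        from .wholeimage import WholeImageClassifier

        est = WholeImageClassifier(batch_size=config.batch_size, **common)
    est.fit(bags, y)
    return est, est.history_
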