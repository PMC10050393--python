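"""Whole-image residual CNN classifier on downscaled spots.

The alternative to MIL: downscale the full spot (5468 px at full scale) to a
fixed side and classify it with a residual CNN in one shot.  The full-scale
configuration mirrors a ResNet34 on 1024 px inputs; the desk preset is a
small 4-block residual network on 64 px inputs that trains on CPU.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .imaging import SpotImage
from .mil import _balanced_accuracy_labels


def _build_cnn(input_side: int, channels: int, n_blocks: int, n_classes: int,
               rng: np.random.Generator) -> _nn.Sequential:
    layers: list[_nn.Layer] = [_nn.Conv2d(3, channels, rng), _nn.ReLU(),
                               _nn.MaxPool2d()]
    side = input_side // 2
    for _ in range(n_blocks):
        layers.append(_nn.ResidualBlock(channels, rng))
        if side >= 8:
            layers.append(_nn.MaxPool2d())
            side //= 2
    layers += [_nn.GlobalAvgPool(), _nn.Linear(channels, n_classes, rng)]
    return _nn.Sequential(layers)


class WholeImageClassifier(BaseEstimator, ClassifierMixin):
    """Residual CNN over whole downscaled spot images.

    Input images must already be square with side ``input_side`` (use
    :func:`her2mil.imaging.downscale`).  Inference is deterministic: the same
    image always yields bit-identical probabilities.
    """

    def __init__(
        self,
        input_side: int = 64,
        channels: int = 16,
        n_blocks: int = 4,
        learning_rate: float = 1e-3,
        batch_size: int = 8,
        max_epochs: int = 30,
        scheduler_factor: float = 0.1,
        scheduler_patience: int = 8,
        max_lr_reductions: int = 2,
        weight_decay: float = 1e-8,
        betas: tuple[float, float] = (0.9, 0.999),
        balanced_sampling: bool = True,
        augment: bool = True,
        validation_fraction: float = 0.2,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.input_side = input_side
        self.channels = channels
        self.n_blocks = n_blocks
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.scheduler_factor = scheduler_factor
        self.scheduler_patience = scheduler_patience
        self.max_lr_reductions = max_lr_reductions
        self.weight_decay = weight_decay
        self.betas = betas
        self.balanced_sampling = balanced_sampling
        self.augment = augment
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    def _to_float(self, X) -> np.ndarray:
        imgs = []
        for im in X:
            px = im.pixels if isinstance(im, SpotImage) else np.asarray(im)
            if px.shape[0] != self.input_side or px.shape[1] != self.input_side:
                raise ValueError(
                    f"expected {self.input_side} px square input, got {px.shape[:2]}"
                )
            imgs.append(1.0 - px.astype(np.float64) / 255.0)
        return np.stack(imgs)

    def fit(self, X, y):
        from .training import PlateauScheduler, class_balance_weights, stratified_indices

        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        net = _build_cnn(self.input_side, self.channels, self.n_blocks,
                         len(self.classes_), rng)
        imgs = self._to_float(X)
        tr, va = stratified_indices(y_idx, 1.0 - self.validation_fraction,
                                    seed=int(rng.integers(2**31)))
        if len(va) == 0:
            va = tr
        w = (class_balance_weights(y_idx[tr]) if self.balanced_sampling
             else np.ones(len(tr)))
        p = w / w.sum()
        opt = _nn.Adam(net.params(), net.grads(), lr=self.learning_rate,
                       betas=self.betas, weight_decay=self.weight_decay)
        sched = PlateauScheduler(self.scheduler_factor, self.scheduler_patience)
        best = (-np.inf, copy.deepcopy(net))
        self.history_ = []
        for epoch in range(self.max_epochs):
            order = rng.choice(len(tr), size=len(tr), replace=True, p=p)
            losses = []
            for start in range(0, len(order), self.batch_size):
                idx = tr[order[start : start + self.batch_size]]
                xb = imgs[idx]
                if self.augment:
                    if rng.random() < 0.5:
                        xb = xb[:, :, ::-1, :]
                    if rng.random() < 0.5:
                        xb = xb[:, ::-1, :, :]
                logits = net.forward(np.ascontiguousarray(xb))
                probs = _nn.softmax(logits, axis=1)
                yb = y_idx[idx]
                loss = float(-np.mean(
                    np.log(np.maximum(probs[np.arange(len(yb)), yb], 1e-300))
                ))
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                dlogits = probs
                dlogits[np.arange(len(yb)), yb] -= 1.0
                net.backward(dlogits / len(yb))
                opt.step()
                losses.append(loss)
            val_probs = self._forward_probs(imgs[va], net)
            val_ba = _balanced_accuracy_labels(y_idx[va], val_probs.argmax(axis=1),
                                               len(self.classes_))
            if val_ba > best[0]:
                best = (val_ba, copy.deepcopy(net))
            if sched.update(val_ba):
                opt.lr *= self.scheduler_factor
            self.history_.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                                  "val_balanced_accuracy": val_ba, "lr": opt.lr})
            if self.verbose:
                print(f"epoch {epoch}: loss {np.mean(losses):.4f} val_ba {val_ba:.3f}")
            if sched.n_reductions >= self.max_lr_reductions:
                break
        self.best_val_balanced_accuracy_, self.net_ = best
        return self

    @staticmethod
    def _forward_probs(imgs: np.ndarray, net: _nn.Sequential,
                       chunk: int = 32) -> np.ndarray:
        out = []
        for start in range(0, len(imgs), chunk):
            logits = net.forward(imgs[start : start + chunk])
            out.append(_nn.softmax(logits, axis=1))
        return np.vstack(out)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self._forward_probs(self._to_float(X), self.net_)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def wholeimage_forward(image, classifier: WholeImageClassifier) -> np.ndarray:
    """Class probabilities for one downscaled spot image."""
    return classifier.predict_proba([image])[0]
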