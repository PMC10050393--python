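"""Staining-intensity baseline: one scalar per spot, logistic regression.

The comparator to the MIL model uses no morphology at all.  Each tile's mean
DAB concentration (after colour deconvolution) is computed and the spot's
descriptor is the *maximum* of those tile means — a max-aggregated MIL with
a single hand-crafted feature.  Logistic regression (multinomial for the
four IHC scores, binary for HER2 status) maps the descriptor to class
probabilities.  Whatever signal is carried only by staining *pattern* rather
than staining *amount* is invisible to this model, which is exactly the
contrast it exists to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .imaging import EmptyBagError, TileBag
from .stain import RUIFROK_HDAB, StainProfile, mean_tile_dab


@dataclass
class IntensityDescriptor:
    """Max-over-tiles mean DAB concentration of one spot (symbol d_max)."""

    spot_id: str
    d_max: float


def slide_descriptor(bag: TileBag, profile: StainProfile = RUIFROK_HDAB) -> IntensityDescriptor:
    """d_max = max over the bag's tiles of the mean DAB concentration."""
    if len(bag) == 0:
        raise EmptyBagError(f"spot {bag.spot_id!r}: empty bag")
    means = [mean_tile_dab(t, profile) for t in bag.tiles]
    return IntensityDescriptor(spot_id=bag.spot_id, d_max=float(max(means)))


class IntensityBaselineClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression on the single d_max feature.

    ``fit`` accepts either TileBags (descriptors are computed with the given
    stain profile) or a 1-d array of precomputed d_max values.  A small L2
    penalty (``C = 1 / penalty``) keeps the one-dimensional fit
    well-conditioned.
    """

    def __init__(self, profile: StainProfile | None = None, penalty: float = 1e-3,
                 max_iter: int = 1000, random_state: int = 0):
        self.profile = profile
        self.penalty = penalty
        self.max_iter = max_iter
        self.random_state = random_state

    def _features(self, X) -> np.ndarray:
        profile = self.profile if self.profile is not None else RUIFROK_HDAB
        if len(X) and isinstance(X[0], TileBag):
            return np.array([[slide_descriptor(b, profile).d_max] for b in X])
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[1] != 1:
            raise ValueError("expected bags or a single d_max feature column")
        return arr

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes")
        feats = self._features(X)
        self.model_ = LogisticRegression(
            C=1.0 / self.penalty if self.penalty > 0 else 1e6,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        self.model_.fit(feats, y)
        self.classes_ = self.model_.classes_
        self.d_max_train_ = feats[:, 0]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._features(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(self._features(X))


def fit_intensity_classifier(descriptors, labels, task: str = "status",
                             penalty: float = 1e-3) -> IntensityBaselineClassifier:
    """Fit the baseline from IntensityDescriptors (or raw d_max values) and
    SpotLabels; ``task`` selects the score (4-class) or status (binary)
    target."""
    from .evaluation import SpotLabel

    d = np.array([dd.d_max if isinstance(dd, IntensityDescriptor) else float(dd)
                  for dd in descriptors])
    y = np.array([
        (lab.ihc_score if task == "score" else lab.her2_status)
        if isinstance(lab, SpotLabel) else lab
        for lab in labels
    ])
    est = IntensityBaselineClassifier(penalty=penalty)
    return est.fit(d, y)
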