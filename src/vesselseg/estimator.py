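"""scikit-learn-style estimator facade over the dual-stream networks."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import SamplePair
from .exceptions import InputError
from .losses import dice_coefficient
from .network import NetworkSpec, SegmentationModel
from .train import TrainingConfig, train as _train

__all__ = ["DualStreamSegmenter"]


class DualStreamSegmenter(BaseEstimator):
    """Per-pixel vessel/background classifier with a fit/predict surface.

    Wraps a DSF-Net or DSA-Net: ``fit`` trains with Adam on the
    generalized Dice loss under the published regime (per-epoch shuffling,
    global L2 gradient clipping), ``predict`` returns binary vessel masks,
    ``predict_proba`` per-pixel class probabilities. Composes with sklearn
    model selection via ``get_params``/``set_params``/``clone``.

    Parameters
    ----------
    variant : {"dsa", "dsf"}
        Merge mode: dense aggregation (concatenation + bottleneck) or
        residual fusion (element-wise addition). Default "dsa", the
        stronger variant in ablation.
    learning_rate, epochs, batch_size, epsilon, clip_norm, shuffle
        Training hyperparameters (defaults follow the published regime:
        Adam lr 1e-4, eps 1e-6, 35 epochs, per-epoch shuffling, global L2
        clipping; batch 12).
    random_state : int
        Seeds weight initialization and shuffling.

    Attributes
    ----------
    model_ : SegmentationModel
    history_ : dict with per-iteration loss and per-epoch accuracy
    classes_ : array([0, 1]) (background, vessel)
    """

    def __init__(self, variant="dsa", learning_rate=1e-4, epochs=35,
                 batch_size=12, epsilon=1e-6, clip_norm=1.0, shuffle=True,
                 random_state=0):
        self.variant = variant
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.epsilon = epsilon
        self.clip_norm = clip_norm
        self.shuffle = shuffle
        self.random_state = random_state

    # ---- sklearn API
    def fit(self, X, y):
        """Fit on images X (n, H, W, 3), uint8 or float in [0,1], with
        binary masks y (n, H, W)."""
        X, y = self._validate(X, y)
        spec = NetworkSpec.reference(self.variant.upper())
        self.model_ = SegmentationModel(spec, seed=self.random_state)
        pairs = [SamplePair(id=str(i), image=X[i], mask=y[i]) for i in range(len(X))]
        cfg = TrainingConfig(learning_rate=self.learning_rate, epochs=self.epochs,
                             batch_size=self.batch_size, epsilon=self.epsilon,
                             clip_norm=self.clip_norm, shuffle=self.shuffle,
                             seed=self.random_state)
        self.history_ = _train(self.model_, pairs, cfg)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = self._validate(X)
        return self.model_.predict_proba(X.astype(self.model_.dtype) / 255.0)

    def predict(self, X):
        prob = self.predict_proba(X)
        return (prob[..., 1] > prob[..., 0]).astype(np.uint8)

    def score(self, X, y):
        """Mean Dice overlap over the images."""
        X, y = self._validate(X, y)
        pred = self.predict(X)
        return float(np.mean([dice_coefficient(pred[i], y[i]) for i in range(len(X))]))

    # ---- helpers
    def _validate(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise InputError(f"X must be (n, H, W, 3), got shape {X.shape}")
        if np.issubdtype(X.dtype, np.floating):
            X = (np.clip(X, 0, 1) * 255).astype(np.uint8)
        X = X.astype(np.uint8)
        if y is None:
            return X
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise InputError(f"y must be (n, H, W) matching X, got {y.shape}")
        if not np.isin(y, (0, 1)).all():
            raise InputError("y must be binary vessel masks (0/1)")
        return X, y.astype(np.uint8)
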