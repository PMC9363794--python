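"""Scikit-learn-style estimator wrapping the trainable segmentation stage.

``FundusSegmenter`` follows sklearn conventions (constructor stores
hyperparameters verbatim, ``fit`` learns and sets trailing-underscore
attributes, ``get_params``/``set_params`` work with model selection), so the
learnable stage composes with sklearn tooling.  The geometric and angular
stages of the pipeline are pure functions and stay outside the estimator.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import confusion_counts, iou_pa
from .models import ModelConfig, build_model
from .training import (
    TrainConfig,
    predict_mask,
    select_best_checkpoint,
    train_model,
)

__all__ = ["FundusSegmenter"]


class FundusSegmenter(BaseEstimator):
    """Three-class fundus segmenter (background / optic disc / virtual macula).

    Parameters
    ----------
    architecture : {'deeplabv3plus', 'unet', 'pspnet'}
        Network family; DeepLabv3+ with a MobileNetV2 encoder is the primary.
    input_size : int
        Square network input resolution (images are resized to it).
    width_multiplier : float
        Channel-width scale; 1.0 is publication scale, 0.25 desk scale.
    learning_rate, epochs, batch_size : training hyperparameters.
    val_fraction : float
        Fraction of the fitted data held out as the validation split used
        for lowest-validation-loss checkpoint selection (default 0.1, the
        9:1 protocol).
    seed : int
        Seeds initialization, the train/validation shuffle and batching.

    Attributes
    ----------
    model_ : the trained network (best-validation-loss checkpoint loaded).
    history_ : list of per-epoch records (train_loss, val_loss, state).
    best_epoch_ : int, 1-based epoch of the selected checkpoint.
    classes_ : ndarray [0, 1, 2].
    """

    def __init__(
        self,
        architecture: str = "deeplabv3plus",
        input_size: int = 512,
        width_multiplier: float = 1.0,
        atrous_rates: tuple = (6, 12, 18),
        output_stride: int = 16,
        learning_rate: float = 5e-5,
        epochs: int = 100,
        batch_size: int = 4,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.architecture = architecture
        self.input_size = input_size
        self.width_multiplier = width_multiplier
        self.atrous_rates = atrous_rates
        self.output_stride = output_stride
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.seed = seed

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            architecture=self.architecture,
            input_size=self.input_size,
            width_multiplier=self.width_multiplier,
            atrous_rates=tuple(self.atrous_rates),
            output_stride=self.output_stride,
        )

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on images ``X`` (n, H, W, 3) and label masks ``y`` (n, H, W).

        When no explicit validation set is given, ``val_fraction`` of the
        data is held out (seeded shuffle) for checkpoint selection.
        """
        X = np.asarray(X)
        y = np.asarray(y)
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be non-empty and of equal length")
        if X_val is None:
            n = len(X)
            n_val = max(1, int(round(n * self.val_fraction))) if n > 1 else 0
            if n_val == 0:
                X_val, y_val = X, y  # single sample: validate on it
            else:
                order = np.random.default_rng(self.seed).permutation(n)
                val_idx, train_idx = order[:n_val], order[n_val:]
                X, X_val = X[train_idx], X[val_idx]
                y, y_val = y[train_idx], y[val_idx]
        model = build_model(self._model_config(), seed=self.seed)
        history = train_model(
            model,
            (X, y),
            (np.asarray(X_val), np.asarray(y_val)),
            TrainConfig(
                learning_rate=self.learning_rate,
                epochs=self.epochs,
                batch_size=self.batch_size,
                seed=self.seed,
            ),
        )
        best = select_best_checkpoint(history)
        model.load_state_dict(best.state)
        model.eval()
        self.model_ = model
        self.history_ = history
        self.best_epoch_ = best.epoch
        self.classes_ = np.array([0, 1, 2])
        return self

    def predict(self, X) -> np.ndarray:
        """Segment images; returns (n, S, S) uint8 masks with values {0,1,2}."""
        self._check_fitted()
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[None]
        return np.stack([predict_mask(self.model_, img) for img in X])

    def score(self, X, y) -> float:
        """Mean per-image MIoU against reference masks resized to input size."""
        from .training import preprocess_masks

        self._check_fitted()
        preds = self.predict(X)
        refs = preprocess_masks(y, self.input_size)
        return float(
            np.mean([iou_pa(confusion_counts(p, t)).miou for p, t in zip(preds, refs)])
        )

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("FundusSegmenter is not fitted; call fit() first")
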