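"""sklearn-style estimator facade over the LSTM sequence regressor.

``LSTMLeadRegressor`` exposes fit/predict/get_params so the model
composes with sklearn tooling; defaults are the tuned 4-layer
architecture shipped as the package's reference configuration
(hidden units 27/22/23/46, minibatch 27, learning rate 0.028805,
no schedule, β1 = 0.90034, β2 = 0.9175, 100 epochs).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import lstm
from .lstm import NetworkSpec, TrainingConfig, Weights


def _stack(seqs) -> np.ndarray:
    """Stack a list of (S, C) sequences into (S, B, C); lengths must agree."""
    if isinstance(seqs, np.ndarray) and seqs.ndim == 3:
        return seqs
    lengths = {s.shape[0] for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths; window them first")
    return np.stack(list(seqs), axis=1)


class LSTMLeadRegressor(RegressorMixin, BaseEstimator):
    """Stacked-LSTM map from 3 input leads to 12 derived leads.

    Parameters
    ----------
    hidden_units : tuple of int
        Width of each LSTM layer (the tuned 4-layer default ships).
    minibatch, learning_rate, schedule, beta1, beta2, epochs
        Adam training configuration; ``schedule="piecewise"`` decays
        the learning rate by 0.1 every 10 epochs.
    random_state : int
        Seeds weight initialization and minibatch shuffling.
    warm_start_weights : Weights, optional
        Continue training from these weights instead of a fresh
        initialization (the transfer-learning entry point).

    Attributes
    ----------
    weights_ : Weights
    history_ : dict with per-epoch "train_loss" and (if a validation
        set was supplied) "val_rmse"; "objective" is the final
        validation RMSE used as the tuning objective.
    """

    def __init__(self, hidden_units: tuple[int, ...] = (27, 22, 23, 46),
                 minibatch: int = 27, learning_rate: float = 0.028805,
                 schedule: str = "none", beta1: float = 0.90034,
                 beta2: float = 0.9175, epochs: int = 100,
                 random_state: int = 0, warm_start_weights: Weights | None = None):
        self.hidden_units = hidden_units
        self.minibatch = minibatch
        self.learning_rate = learning_rate
        self.schedule = schedule
        self.beta1 = beta1
        self.beta2 = beta2
        self.epochs = epochs
        self.random_state = random_state
        self.warm_start_weights = warm_start_weights

    def _spec(self) -> NetworkSpec:
        return NetworkSpec(hidden_units=tuple(self.hidden_units))

    def _cfg(self) -> TrainingConfig:
        return TrainingConfig(minibatch=self.minibatch,
                              learning_rate=self.learning_rate,
                              schedule=self.schedule, beta1=self.beta1,
                              beta2=self.beta2, epochs=self.epochs,
                              seed=self.random_state)

    def fit(self, X, y, validation=None) -> "LSTMLeadRegressor":
        """Train on equal-length sequences.

        ``X``: list of (S, 3) arrays or a stacked (S, B, 3) array;
        ``y`` likewise with 12 channels.  ``validation`` is an optional
        (X_val, y_val) pair in the same form.
        """
        x_tr, y_tr = _stack(X), _stack(y)
        val = None
        if validation is not None:
            val = (_stack(validation[0]).astype(np.float32),
                   _stack(validation[1]).astype(np.float32))
        self.weights_, self.history_ = lstm.train(
            self._spec(), self._cfg(), (x_tr, y_tr), val,
            init=self.warm_start_weights)
        return self

    def predict(self, X) -> np.ndarray | list[np.ndarray]:
        """Derive the 12 target leads; accepts one (S, 3) sequence, a
        stacked (S, B, 3) batch, or a list of variable-length sequences."""
        check_is_fitted(self, "weights_")
        if isinstance(X, np.ndarray):
            return lstm.forward(self.weights_, X.astype(np.float32))
        return [lstm.forward(self.weights_, np.asarray(x, dtype=np.float32))
                for x in X]

    def validation_rmse(self, X, y) -> float:
        """Pooled RMSE in mV over all sequences, samples and leads."""
        check_is_fitted(self, "weights_")
        return lstm.pooled_rmse(self.weights_, _stack(X).astype(np.float32),
                                _stack(y).astype(np.float32))

    def save(self, path, meta: dict | None = None) -> None:
        check_is_fitted(self, "weights_")
        lstm.save_checkpoint(path, self.weights_, self._cfg(), meta=meta)

    @classmethod
    def load(cls, path) -> "LSTMLeadRegressor":
        w, cfg, _meta = lstm.load_checkpoint(path)
        est = cls(hidden_units=tuple(w.spec.hidden_units))
        if cfg is not None:
            est.set_params(minibatch=cfg.minibatch,
                           learning_rate=cfg.learning_rate,
                           schedule=cfg.schedule, beta1=cfg.beta1,
                           beta2=cfg.beta2, epochs=cfg.epochs,
                           random_state=cfg.seed)
        est.weights_ = w
        est.history_ = {}
        return est
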