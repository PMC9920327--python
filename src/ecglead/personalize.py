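"""Transfer-learning personalization of a generalized model.

A generalized model trained on the whole cohort is fine-tuned on one
patient's sliding-window-augmented data: the architecture, training
hyperparameters and weights are inherited, all layers keep training
(no freezing by default), and the loss is unchanged.  The augmented
windows are split 80/20 into fine-tuning and validation sets by
uniform randomization — literally over the overlapping windows; a
no-leakage variant that splits time-contiguous blocks is available
behind ``block_split=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import LSTMLeadRegressor
from .lstm import Weights
from .preprocess import WindowedDataset, make_windows, preprocess_record
from .signal_io import ECGRecord


class InsufficientDataError(ValueError):
    """A patient has no record long enough to window."""


def build_patient_dataset(records: list[ECGRecord], window_s: float = 17.0,
                          overlap_s: float = 16.0, train_frac: float = 0.8,
                          seed: int = 0, preprocess: bool = True,
                          block_split: bool = False,
                          ) -> tuple[WindowedDataset, WindowedDataset]:
    """Window one patient's records and split windows 80/20.

    Windows never span record boundaries.  The train size is the
    nearest integer to ``train_frac`` times the window count.
    """
    if not records:
        raise InsufficientDataError("no records supplied")
    pairs = []
    for rec in records:
        if preprocess:
            rec = preprocess_record(rec)
        if rec.duration < window_s:
            continue
        pairs.extend(make_windows(rec, window_s, overlap_s).pairs)
    if not pairs:
        raise InsufficientDataError(
            f"no record of patient {records[0].patient_id!r} reaches the "
            f"{window_s} s window length")
    n = len(pairs)
    n_train = int(round(train_frac * n))
    if block_split:
        idx = np.arange(n)
    else:
        idx = np.random.default_rng(seed).permutation(n)
    train = [pairs[i] for i in idx[:n_train]]
    val = [pairs[i] for i in idx[n_train:]]
    return (WindowedDataset(train, window_s, overlap_s),
            WindowedDataset(val, window_s, overlap_s))


@dataclass
class PersonalizedModel:
    """A fine-tuned model plus its provenance and validation numbers."""

    patient_id: str
    estimator: LSTMLeadRegressor
    parent_val_rmse: float
    val_rmse: float
    n_train_windows: int
    n_val_windows: int
    history: dict


def transfer_train(parent: LSTMLeadRegressor | Weights,
                   train_ds: WindowedDataset, val_ds: WindowedDataset,
                   patient_id: str = "", epochs: int = 100,
                   learning_rate: float | None = None,
                   seed: int = 0) -> PersonalizedModel:
    """Continue training the parent model on one patient's windows.

    The parent is never modified; its weights are copied into a fresh
    estimator.  The fine-tuning learning rate defaults to the parent's
    own rate.  Both the inherited (epoch-0) and the fine-tuned
    validation RMSE are recorded so the personalization gain is
    directly readable.
    """
    if isinstance(parent, LSTMLeadRegressor):
        parent_weights = parent.weights_
        params = parent.get_params()
        params.pop("warm_start_weights", None)
    else:
        parent_weights = parent
        params = {"hidden_units": tuple(parent.spec.hidden_units)}
    est = LSTMLeadRegressor(**params)
    est.set_params(epochs=epochs, random_state=seed,
                   warm_start_weights=parent_weights.copy())
    if learning_rate is not None:
        est.set_params(learning_rate=learning_rate)

    x_tr, y_tr = train_ds.stacked()
    x_val, y_val = val_ds.stacked()
    parent_est = LSTMLeadRegressor(hidden_units=tuple(parent_weights.spec.hidden_units))
    parent_est.weights_ = parent_weights
    parent_rmse = parent_est.validation_rmse(x_val, y_val)

    est.fit(x_tr, y_tr, validation=(x_val, y_val))
    tuned_rmse = est.history_.get("objective",
                                  est.validation_rmse(x_val, y_val))
    return PersonalizedModel(
        patient_id=patient_id, estimator=est,
        parent_val_rmse=parent_rmse, val_rmse=tuned_rmse,
        n_train_windows=len(train_ds), n_val_windows=len(val_ds),
        history=est.history_,
    )
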