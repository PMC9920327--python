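"""End-to-end study drivers on the synthetic cohort.

These functions wire the full pipeline together — cohort generation,
conditioning, generalized training, per-patient transfer learning and
the linear baseline — at configurable scale, and return the summary
numbers (per-patient validation RMSE for the generalized and
personalized models, cohort means, win counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baseline import LinearLeadRegressor
from .estimators import LSTMLeadRegressor
from .metrics import report
from .personalize import build_patient_dataset, transfer_train
from .preprocess import make_windows, preprocess_record, split_records
from .synth import generate_cohort


@dataclass
class PersonalizationStudy:
    """Results of one generalized-vs-personalized comparison."""

    patient_ids: list[str]
    generalized_rmse: list[float]      # parent model on each patient's val windows
    personalized_rmse: list[float]
    linear_rmse: list[float] = field(default_factory=list)
    generalized_history: dict = field(default_factory=dict)

    @property
    def n_wins(self) -> int:
        """Patients whose personalized RMSE beats the generalized one."""
        return int(sum(p < g for p, g in
                       zip(self.personalized_rmse, self.generalized_rmse)))

    @property
    def mean_generalized(self) -> float:
        return float(np.mean(self.generalized_rmse))

    @property
    def mean_personalized(self) -> float:
        return float(np.mean(self.personalized_rmse))


def _stack(pairs, dtype=np.float32):
    x = np.stack([p.x for p in pairs], axis=1).astype(dtype)
    y = np.stack([p.y for p in pairs], axis=1).astype(dtype)
    return x, y


def run_personalization_study(n_patients: int = 8,
                              heterogeneity: float = 0.5,
                              hidden_units: tuple[int, ...] = (16,),
                              epochs: int = 15,
                              seed: int = 0,
                              durations: tuple[float, ...] = (120.0, 120.0, 120.0),
                              minibatch: int = 27,
                              learning_rate: float = 0.028805,
                              window_s: float = 17.0,
                              overlap_s: float = 16.0,
                              with_linear: bool = False,
                              ) -> PersonalizationStudy:
    """Train one generalized model on the cohort, then personalize per patient.

    The generalized model trains on non-overlapping windows from the
    80% record split; personalization fine-tunes it on each patient's
    overlap-augmented windows (split 80/20) and is scored on the same
    held-out windows the inherited model is scored on.  Network size,
    epoch count and record durations are arguments so the study can run
    at full or desk scale.
    """
    cohort = generate_cohort(n_patients, heterogeneity, seed=seed,
                             durations=durations)
    clean: list[tuple[str, list]] = []
    for spec, records in cohort:
        clean.append((spec.patient_id,
                      [preprocess_record(r) for r in records]))

    all_records = [r for _pid, recs in clean for r in recs]
    train_recs, test_recs = split_records(all_records, 0.8, seed=seed)
    train_pairs = []
    for rec in train_recs:
        train_pairs.extend(make_windows(rec, window_s, overlap_s=0.0).pairs)
    val_pairs = []
    for rec in test_recs:
        val_pairs.extend(make_windows(rec, window_s, overlap_s=0.0).pairs)

    general = LSTMLeadRegressor(hidden_units=hidden_units,
                                minibatch=minibatch,
                                learning_rate=learning_rate,
                                epochs=epochs, random_state=seed)
    general.fit(*_stack(train_pairs), validation=_stack(val_pairs))

    study = PersonalizationStudy(patient_ids=[], generalized_rmse=[],
                                 personalized_rmse=[],
                                 generalized_history=general.history_)
    for k, (pid, records) in enumerate(clean):
        train_ds, val_ds = build_patient_dataset(
            records, window_s, overlap_s, 0.8, seed=seed + 17 * k + 1,
            preprocess=False)
        model = transfer_train(general, train_ds, val_ds, patient_id=pid,
                               epochs=epochs, seed=seed + 17 * k + 2)
        study.patient_ids.append(pid)
        study.generalized_rmse.append(model.parent_val_rmse)
        study.personalized_rmse.append(model.val_rmse)
        if with_linear:
            X = np.concatenate([p.x for p in train_ds.pairs])
            Y = np.concatenate([p.y for p in train_ds.pairs])
            lin = LinearLeadRegressor().fit(X, Y)
            resid = [lin.predict(p.x) - p.y for p in val_ds.pairs]
            study.linear_rmse.append(
                float(np.sqrt(np.mean(np.concatenate(resid) ** 2))))
    return study


def linear_anchor_metrics(seed: int = 0, duration: float = 60.0):
    """Fit the QR baseline on one noiseless, purely linear synthetic
    patient and return its per-lead metrics report (the sanity anchor:
    R² = 100 and ρ = 1 on every derived lead)."""
    from .preprocess import select_leads
    from .synth import SyntheticPatientSpec, generate_dipole, project_leads

    spec = SyntheticPatientSpec(nonlinearity=0.0, noise_sd=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    source = generate_dipole(spec, duration, rng)
    record = project_leads(source, spec, rng)
    pair = select_leads(record)
    est = LinearLeadRegressor().fit(pair.x, pair.y)
    return report([pair], [est.predict(pair.x)], tag="linear")
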