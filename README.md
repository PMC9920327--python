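# ecglead

**Derive a full 15-lead ECG (standard 12-lead + Frank XYZ) from just
three measured leads — II, V2 and V6 — with per-patient personalized
LSTM models.**

## The problem

A clinical 12-lead ECG needs 10 precisely placed electrodes; adding the
Frank vectorcardiographic leads (Vx, Vy, Vz) pushes that to 16.
Wearable long-term monitors can realistically carry only a handful of
electrodes.  Because the cardiac electrical source is (to first
approximation) a single rotating dipole, three *quasi-orthogonal* leads
— II, V2, V6 — nearly span the source space, so the remaining 12 leads
are largely redundant and can be **derived**: the task is to learn the
map

```
(II, V2, V6)(t)  →  (I, III, aVR, aVL, aVF, V1, V3, V4, V5, Vx, Vy, Vz)(t)
```

The torso is not a homogeneous conductor, so the true map is mildly
nonlinear and — crucially — differs between individuals.  This package
implements and compares three estimators of that map:

* **generalized LSTM** — a stacked-LSTM sequence-to-sequence regressor
  trained on a whole cohort, with training hyperparameters chosen by
  Gaussian-process Bayesian optimization (ARD Matérn 5/2 kernel,
  expected-improvement acquisition with a posterior-std exploration
  rule);
* **personalized LSTM** — the generalized model fine-tuned by transfer
  learning on one patient's own recordings;
* **linear baseline** — per-patient least squares via QR factorization,
  the classical lead-transformation approach.

Quality is scored per record and per derived lead with RMSE (mV), the
uncentered correlation ρ = Σŷy / √(Σy²·Σŷ²), and the uncentered
R² = (1 − Σ(ŷ−y)²/Σy²)·100.

Everything is testable offline: a synthetic 15-lead cohort generator
(dipole source → per-patient lead field → optional saturating
nonlinearity → noise) provides ground truth with controllable
inter-patient heterogeneity.

## Worked example

Train a tiny generalized model on a synthetic cohort with strong
inter-patient anatomy differences (heterogeneity 0.5), then personalize
it for each of the 8 patients:

```python
from ecglead.experiments import run_personalization_study

study = run_personalization_study(n_patients=8, heterogeneity=0.5,
                                  hidden_units=(16,), epochs=15, seed=1)
print(f"generalized  RMSE: {1000 * study.mean_generalized:.1f} µV")
print(f"personalized RMSE: {1000 * study.mean_personalized:.1f} µV")
print(f"patients improved: {study.n_wins}/8")
```

```
generalized  RMSE: 60.5 µV
personalized RMSE: 4.6 µV
patients improved: 8/8
```

The generalized model is stuck at the cohort-average anatomy, so each
patient's individual lead field leaves a residual of tens of µV;
fine-tuning on that patient's own windows removes most of it.  On a
purely linear, noiseless patient the QR baseline is exact
(R² = 100, ρ = 1 on all 12 derived leads) — the cohort's sanity anchor:

```python
from ecglead.experiments import linear_anchor_metrics
print(linear_anchor_metrics().per_cell[["lead", "r2", "rho"]].head(3))
```

```
  lead     r2  rho
0    I  100.0  1.0
1  III  100.0  1.0
2  aVR  100.0  1.0
```

The same pipeline is scriptable from the shell (`ecglead synth`,
`preprocess`, `tune`, `train-general`, `personalize`, `baseline`,
`evaluate`, `chart`); every subcommand writes a JSON run manifest, and
`chart` renders records on the conventional clinical grid
(10 mm = 1 mV, 25 mm = 1 s).

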