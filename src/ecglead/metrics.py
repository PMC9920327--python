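"""Derivation-error metrics: RMSE, correlation, and R² (as-defined forms).

The correlation and R² used throughout are the *uncentered* forms

    rho = Σ ŷ·y / sqrt(Σ y² · Σ ŷ²)
    R²  = (1 − Σ(ŷ − y)² / Σ y²) · 100

i.e. neither subtracts the mean.  For zero-mean (band-passed) ECG they
coincide with the conventional Pearson correlation and coefficient of
determination; in general they do not, and the reported magnitudes
depend on using the uncentered forms.  Conventional centered variants
are available behind an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import TARGET_LEADS


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error, in the units of the inputs (mV here)."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rho(y: np.ndarray, yhat: np.ndarray, centered: bool = False) -> float:
    """Correlation between derived and actual series.

    Default is the uncentered form; ``centered=True`` gives the
    conventional Pearson coefficient.  Both lie in [-1, 1] by
    Cauchy-Schwarz.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    if centered:
        y = y - y.mean()
        yhat = yhat - yhat.mean()
    ey, eh = np.sum(y ** 2), np.sum(yhat ** 2)
    if ey == 0 or eh == 0:
        raise ValueError("zero-energy series: correlation undefined")
    return float(np.sum(y * yhat) / np.sqrt(ey * eh))


def r2(y: np.ndarray, yhat: np.ndarray, centered: bool = False) -> float:
    """R² in percent; denominator is signal energy Σy² (uncentered).

    Can be negative when residual energy exceeds signal energy.
    ``centered=True`` uses the conventional variance denominator.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    denom = np.sum((y - y.mean()) ** 2) if centered else np.sum(y ** 2)
    if denom == 0:
        raise ValueError("zero-signal series: R² undefined")
    return float((1.0 - np.sum((yhat - y) ** 2) / denom) * 100.0)


_AGG_FUNCS = {
    "mean": np.mean,
    "sd": lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0,
    "median": np.median,
    "q1": lambda v: np.percentile(v, 25),
    "q3": lambda v: np.percentile(v, 75),
    "min": np.min,
    "max": np.max,
}


@dataclass
class MetricsReport:
    """Per-(record, lead) metrics with aggregation helpers.

    ``per_cell`` is a long-format DataFrame with columns
    record_id, lead, rmse, rho, r2.  Aggregates (mean, SD, median,
    quartiles, min, max) are computed over cells: per lead across
    records, and overall across all (record x lead) cells.
    """

    per_cell: pd.DataFrame
    model_tag: str = ""

    def per_lead(self) -> pd.DataFrame:
        rows = []
        for lead, grp in self.per_cell.groupby("lead", sort=False):
            row: dict = {"lead": lead}
            for metric in ("rmse", "rho", "r2"):
                v = grp[metric].to_numpy()
                for name, fn in _AGG_FUNCS.items():
                    row[f"{metric}_{name}"] = float(fn(v))
            rows.append(row)
        order = {lead: i for i, lead in enumerate(TARGET_LEADS)}
        rows.sort(key=lambda r: order.get(r["lead"], len(order)))
        return pd.DataFrame(rows)

    def overall(self) -> dict:
        """Cell-wise aggregates pooled over every (record, lead)."""
        out: dict = {"model": self.model_tag, "n_cells": len(self.per_cell)}
        for metric in ("rmse", "rho", "r2"):
            v = self.per_cell[metric].to_numpy()
            for name, fn in _AGG_FUNCS.items():
                out[f"{metric}_{name}"] = float(fn(v))
        return out

    def to_long_csv(self, path) -> None:
        long = self.per_cell.melt(id_vars=["record_id", "lead"],
                                  value_vars=["rmse", "rho", "r2"],
                                  var_name="metric", value_name="value")
        long.insert(0, "model", self.model_tag)
        long.to_csv(path, index=False)


def report(pairs, predictions, tag: str = "",
           lead_names=TARGET_LEADS) -> MetricsReport:
    """Score predictions against target pairs, per record and per lead.

    Parameters
    ----------
    pairs : sequence of SamplePair (or of (record_id, y) tuples)
        Actual targets, one entry per test record.
    predictions : sequence of ndarray, each (S, 12)
        Derived signals aligned with ``pairs``.
    tag : str
        Model label stored on the report ("generalized", "personalized",
        "linear", ...).
    """
    if len(pairs) != len(predictions):
        raise ValueError("pairs and predictions must align")
    rows = []
    for pair, yhat in zip(pairs, predictions):
        if hasattr(pair, "y"):
            rid, y = pair.origin[0], pair.y
        else:
            rid, y = pair
        yhat = np.asarray(yhat)
        if yhat.shape != y.shape:
            raise ValueError(f"prediction shape {yhat.shape} does not match "
                             f"target {y.shape} for record {rid!r}")
        for j, lead in enumerate(lead_names):
            rows.append({
                "record_id": rid,
                "lead": lead,
                "rmse": rmse(y[:, j], yhat[:, j]),
                "rho": rho(y[:, j], yhat[:, j]),
                "r2": r2(y[:, j], yhat[:, j]),
            })
    return MetricsReport(per_cell=pd.DataFrame(rows), model_tag=tag)
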