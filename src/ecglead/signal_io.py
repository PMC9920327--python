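"""Multi-lead ECG record I/O.

Records are exchanged in three dialects:

* **WFDB** — the PhysioNet header/signal pair (``.hea`` + ``.dat``,
  format 16: interleaved little-endian int16 with per-channel gain and
  baseline).  Only the subset of the header grammar needed for
  multi-lead biopotential records is supported.
* **CSV** — one column per lead with a header row of lead names; the
  first column is time in seconds.
* **HDF5** — datasets ``/signal`` ``/lead_names`` ``/fs`` and a
  ``/meta`` attribute group.

All signals are held in millivolts internally.  On load, lead order is
normalized to the canonical 15-lead order and records with NaN or
flat-line channels are rejected with a diagnostic, generalizing the
manual corpus exclusions (e.g. a record missing its V1 trace).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical lead order: standard 12-lead set followed by Frank XYZ.
CANONICAL_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
    "Vx", "Vy", "Vz",
)

#: The quasi-orthogonal input subset.
INPUT_LEADS: tuple[str, ...] = ("II", "V2", "V6")

#: Derivation targets, in fixed output order.
TARGET_LEADS: tuple[str, ...] = (
    "I", "III", "aVR", "aVL", "aVF",
    "V1", "V3", "V4", "V5",
    "Vx", "Vy", "Vz",
)

# Case-insensitive synonyms: PTB headers use lowercase ("i", "avr", "vx").
_LEAD_SYNONYMS = {name.lower(): name for name in CANONICAL_LEADS}
_LEAD_SYNONYMS.update({"avr": "aVR", "avl": "aVL", "avf": "aVF"})

_UNIT_TO_MV = {"mv": 1.0, "uv": 1e-3, "µv": 1e-3, "v": 1e3, "mV": 1.0}


class MissingLeadError(KeyError):
    """A required lead is absent from a record or file."""


class UnitError(ValueError):
    """Amplitude units cannot be resolved to millivolts."""


def normalize_lead_name(name: str) -> str | None:
    """Map a header label to its canonical lead name, or None if unknown."""
    return _LEAD_SYNONYMS.get(name.strip().lower())


@dataclass
class ECGRecord:
    """One patient recording: a lead-labelled signal matrix in mV.

    Attributes
    ----------
    patient_id, record_id : str
        Identifiers; a patient may own several records.
    fs : float
        Sampling rate in Hz.
    lead_names : tuple of str
        One label per signal column, canonical order after loading.
    signal : ndarray, shape (n_samples, n_leads)
        Amplitudes in millivolts.
    diagnosis : str or None
        Free-text diagnosis, if any.
    """

    patient_id: str
    record_id: str
    fs: float
    lead_names: tuple[str, ...]
    signal: np.ndarray
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        self.lead_names = tuple(self.lead_names)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D [n_samples x n_leads]")
        if self.signal.shape[1] != len(self.lead_names):
            raise ValueError(
                f"signal has {self.signal.shape[1]} columns but "
                f"{len(self.lead_names)} lead names"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.signal[:, self.lead_names.index(name)]
        except ValueError:
            raise MissingLeadError(f"lead {name!r} not present in record "
                                   f"{self.record_id!r}") from None

    def with_signal(self, signal: np.ndarray, fs: float | None = None) -> "ECGRecord":
        return replace(self, signal=signal, fs=self.fs if fs is None else fs)


def normalize_lead_order(record: ECGRecord) -> ECGRecord:
    """Reorder columns into the canonical 15-lead order (idempotent).

    Extra, non-canonical leads are dropped; a missing canonical lead
    raises :class:`MissingLeadError` naming the absent lead.
    """
    mapped: dict[str, int] = {}
    for idx, raw in enumerate(record.lead_names):
        canon = normalize_lead_name(raw)
        if canon is not None and canon not in mapped:
            mapped[canon] = idx
    for lead in CANONICAL_LEADS:
        if lead not in mapped:
            raise MissingLeadError(
                f"record {record.record_id!r} is missing lead {lead!r}")
    cols = [mapped[lead] for lead in CANONICAL_LEADS]
    return replace(record, lead_names=CANONICAL_LEADS,
                   signal=record.signal[:, cols])


def validate_record(record: ECGRecord) -> None:
    """Reject records with NaN or flat-line channels."""
    bad_nan = [n for i, n in enumerate(record.lead_names)
               if not np.all(np.isfinite(record.signal[:, i]))]
    if bad_nan:
        raise ValueError(
            f"record {record.record_id!r}: non-finite samples in leads {bad_nan}")
    if record.n_samples > 1:
        flat = [n for i, n in enumerate(record.lead_names)
                if np.ptp(record.signal[:, i]) == 0.0]
        if flat:
            raise ValueError(
                f"record {record.record_id!r}: flat-line leads {flat}")


# ---------------------------------------------------------------------------
# WFDB dialect (.hea + .dat, format 16)

_WFDB_GAIN = 2000.0  # adu per mV; 16-bit range then spans ±16.38 mV


def _write_wfdb(record: ECGRecord, path: Path) -> None:
    base = path.with_suffix("")
    dat_name = base.name + ".dat"
    n_sig = len(record.lead_names)
    adc = np.round(record.signal * _WFDB_GAIN)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("signal exceeds int16 range at gain "
                         f"{_WFDB_GAIN} adu/mV")
    adc = adc.astype("<i2")
    lines = [f"{base.name} {n_sig} {record.fs:g} {record.n_samples}"]
    for i, name in enumerate(record.lead_names):
        checksum = int(np.sum(adc[:, i], dtype=np.int64) % 65536)
        if checksum >= 32768:
            checksum -= 65536
        lines.append(
            f"{dat_name} 16 {_WFDB_GAIN:g}(0)/mV 16 0 "
            f"{int(adc[0, i])} {checksum} 0 {name}"
        )
    lines.append(f"# record_id: {record.record_id}")
    lines.append(f"# patient_id: {record.patient_id}")
    if record.diagnosis:
        lines.append(f"# diagnosis: {record.diagnosis}")
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.tofile(base.with_suffix(".dat"))


def _parse_gain_units(tok: str) -> tuple[float, float, str]:
    """Split a WFDB gain token ``gain(baseline)/units`` -> (gain, baseline, units)."""
    units = "mV"
    if "/" in tok:
        tok, units = tok.split("/", 1)
    baseline = 0.0
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    return gain, baseline, units


def _read_wfdb(path: Path) -> ECGRecord:
    base = path.with_suffix("")
    header = base.with_suffix(".hea").read_text().splitlines()
    body = [ln for ln in header if ln.strip() and not ln.startswith("#")]
    comments = [ln[1:].strip() for ln in header if ln.startswith("#")]
    rec_tok = body[0].split()
    record_id, n_sig = rec_tok[0], int(rec_tok[1])
    fs = float(rec_tok[2]) if len(rec_tok) > 2 else 250.0
    n_samples = int(rec_tok[3]) if len(rec_tok) > 3 else None

    names, gains, baselines, scales = [], [], [], []
    for ln in body[1:1 + n_sig]:
        tok = ln.split()
        fmt = tok[1].split("x")[0].split(":")[0]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB signal format {fmt!r}")
        gain, baseline, units = _parse_gain_units(tok[2]) if len(tok) > 2 else (200.0, 0.0, "mV")
        scale = _UNIT_TO_MV.get(units.lower())
        if scale is None:
            raise UnitError(f"cannot resolve amplitude units {units!r} to mV")
        # description = trailing tokens after the 8 numeric fields
        names.append(tok[8] if len(tok) > 8 else f"ch{len(names)}")
        gains.append(gain)
        baselines.append(baseline)
        scales.append(scale)

    adc = np.fromfile(base.with_suffix(".dat"), dtype="<i2")
    adc = adc.reshape(-1, n_sig)
    if n_samples is not None:
        adc = adc[:n_samples]
    signal = (adc - np.array(baselines)) / np.array(gains) * np.array(scales)

    patient_id, diagnosis = record_id, None
    for c in comments:
        if c.startswith("record_id:"):
            record_id = c.split(":", 1)[1].strip()
        elif c.startswith("patient_id:"):
            patient_id = c.split(":", 1)[1].strip()
        elif c.startswith("diagnosis:"):
            diagnosis = c.split(":", 1)[1].strip()
    return ECGRecord(patient_id=patient_id, record_id=record_id, fs=fs,
                     lead_names=tuple(names), signal=signal,
                     diagnosis=diagnosis)


# ---------------------------------------------------------------------------
# CSV dialect

def _write_csv(record: ECGRecord, path: Path) -> None:
    t = np.arange(record.n_samples) / record.fs
    header = ",".join(["time_s", *record.lead_names])
    data = np.column_stack([t, record.signal])
    meta = {"patient_id": record.patient_id, "record_id": record.record_id,
            "fs": record.fs, "diagnosis": record.diagnosis}
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        fh.write(header + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.9g")


def _read_csv(path: Path) -> ECGRecord:
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = json.loads(first[1:].strip())
            header = fh.readline()
        else:
            header = first
        names = [c.strip() for c in header.strip().split(",")]
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if names[0].lower() not in ("time_s", "time", "t"):
        raise ValueError("CSV dialect requires a leading time column")
    t, signal = data[:, 0], data[:, 1:]
    fs = float(meta.get("fs", 0.0))
    if not fs and len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    rid = meta.get("record_id", path.stem)
    return ECGRecord(patient_id=meta.get("patient_id", rid), record_id=rid,
                     fs=fs, lead_names=tuple(names[1:]), signal=signal,
                     diagnosis=meta.get("diagnosis"))


# ---------------------------------------------------------------------------
# HDF5 dialect

def _write_hdf5(record: ECGRecord, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=record.signal)
        f.create_dataset("lead_names",
                         data=np.array(record.lead_names, dtype="S8"))
        f.create_dataset("fs", data=float(record.fs))
        meta = f.create_group("meta")
        meta.attrs["patient_id"] = record.patient_id
        meta.attrs["record_id"] = record.record_id
        if record.diagnosis is not None:
            meta.attrs["diagnosis"] = record.diagnosis


def _read_hdf5(path: Path) -> ECGRecord:
    import h5py

    with h5py.File(path, "r") as f:
        signal = f["signal"][()]
        names = tuple(n.decode() for n in f["lead_names"][()])
        fs = float(f["fs"][()])
        meta = f["meta"].attrs
        return ECGRecord(patient_id=str(meta["patient_id"]),
                         record_id=str(meta["record_id"]), fs=fs,
                         lead_names=names, signal=signal,
                         diagnosis=str(meta["diagnosis"]) if "diagnosis" in meta else None)


# ---------------------------------------------------------------------------
# Public API

_DIALECTS = {"wfdb": (_read_wfdb, _write_wfdb),
             "csv": (_read_csv, _write_csv),
             "hdf5": (_read_hdf5, _write_hdf5)}


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".hea", ".dat"):
        return "wfdb"
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise ValueError(f"cannot infer dialect from {path.name!r}")


def read_record(path, dialect: str | None = None, *,
                validate: bool = True) -> ECGRecord:
    """Read one record, normalize it to the canonical 15-lead order in mV.

    Parameters
    ----------
    path : path-like
        File to read (``.hea``/``.dat`` pair for WFDB, else a single file).
    dialect : {"wfdb", "csv", "hdf5"}, optional
        Inferred from the suffix when omitted.
    validate : bool
        Reject records with NaN or flat-line channels (default True).

    Raises
    ------
    MissingLeadError
        If any of the 15 canonical leads is absent.
    UnitError
        If stored amplitude units cannot be resolved to mV.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    reader, _ = _DIALECTS[dialect]
    record = normalize_lead_order(reader(path))
    if validate:
        validate_record(record)
    return record


def write_record(record: ECGRecord, path, dialect: str | None = None) -> Path:
    """Write a record in the requested dialect; returns the path written."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    _, writer = _DIALECTS[dialect]
    writer(record, path)
    return path


def apply_exclusions(records: list[ECGRecord],
                     exclusions: list[str]) -> list[ECGRecord]:
    """Drop records whose record_id is on the exclusion list.

    Unknown exclusion ids are logged, not fatal; each removal is logged.
    """
    excl = set(exclusions)
    present = {r.record_id for r in records}
    for rid in excl - present:
        logger.warning("exclusion id %r does not match any record", rid)
    kept = []
    for r in records:
        if r.record_id in excl:
            logger.info("excluding record %r (patient %r)",
                        r.record_id, r.patient_id)
        else:
            kept.append(r)
    return kept
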