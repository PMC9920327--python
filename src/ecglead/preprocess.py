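"""Signal conditioning and dataset construction.

Pipeline order is fixed: band-pass filter -> downsample -> lead
selection -> sliding-window augmentation.  The band-pass (0.05-45 Hz,
4th-order Butterworth applied forward-backward for zero phase) also
anti-aliases for the 200 Hz target rate, so downsampling is plain
integer decimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal_io import (
    CANONICAL_LEADS,
    INPUT_LEADS,
    TARGET_LEADS,
    ECGRecord,
    MissingLeadError,
)


@dataclass
class SamplePair:
    """One input/target sequence pair.

    ``x`` holds the quasi-orthogonal inputs (II, V2, V6), ``y`` the 12
    derivation targets (I, III, aVR, aVL, aVF, V1, V3, V4, V5, Vx, Vy,
    Vz), both in mV, both of the same length S.
    """

    x: np.ndarray          # (S, 3)
    y: np.ndarray          # (S, 12)
    fs: float
    origin: tuple[str, int] = ("", 0)   # (record_id, start sample)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y must have equal length")
        if self.x.shape[0] < 1:
            raise ValueError("sequences must contain at least one sample")
        if self.x.shape[1] != len(INPUT_LEADS) or self.y.shape[1] != len(TARGET_LEADS):
            raise ValueError("x must be (S,3) and y must be (S,12)")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]


@dataclass
class WindowedDataset:
    """A collection of equal-provenance sequence pairs from windowing."""

    pairs: list[SamplePair] = field(default_factory=list)
    window_s: float = 17.0
    overlap_s: float = 16.0

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def stacked(self, dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
        """Stack equal-length pairs into (S, B, 3) and (S, B, 12) arrays."""
        lengths = {p.n_samples for p in self.pairs}
        if len(lengths) != 1:
            raise ValueError("pairs have unequal lengths; cannot stack")
        x = np.stack([p.x for p in self.pairs], axis=1).astype(dtype)
        y = np.stack([p.y for p in self.pairs], axis=1).astype(dtype)
        return x, y


def bandpass(record: ECGRecord, low: float = 0.05, high: float = 45.0) -> ECGRecord:
    """Zero-phase Butterworth band-pass; removes DC, preserves length and fs.

    A 4th-order filter is applied forward-backward (``sosfiltfilt``) so
    ECG morphology is not phase-distorted.
    """
    if not (0 < low < high < record.fs / 2):
        raise ValueError(
            f"invalid band [{low}, {high}] Hz for fs={record.fs} Hz")
    sos = butter(4, [low, high], btype="bandpass", fs=record.fs, output="sos")
    filtered = sosfiltfilt(sos, record.signal, axis=0)
    return record.with_signal(filtered)


def downsample(record: ECGRecord, target_fs: float = 200.0) -> ECGRecord:
    """Integer decimation to ``target_fs`` (band-pass already anti-aliases)."""
    ratio = record.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"fs={record.fs} is not an integer multiple of target {target_fs}")
    if factor == 1:
        return record
    return record.with_signal(record.signal[::factor], fs=float(target_fs))


def window_count(n_samples: int, win_n: int, step_n: int) -> int:
    """Number of full windows of win_n samples at stride step_n."""
    if n_samples < win_n:
        return 0
    return (n_samples - win_n) // step_n + 1


def select_leads(record: ECGRecord) -> SamplePair:
    """Split a canonical 15-lead record into (II, V2, V6) inputs and 12 targets.

    Order-invariant: records are looked up by lead name, so a shuffled
    record yields identical x, y.
    """
    x = np.column_stack([record.lead(name) for name in INPUT_LEADS])
    y = np.column_stack([record.lead(name) for name in TARGET_LEADS])
    return SamplePair(x=x, y=y, fs=record.fs, origin=(record.record_id, 0))


def make_windows(record: ECGRecord, window_s: float = 17.0,
                 overlap_s: float = 16.0) -> WindowedDataset:
    """Sliding-window augmentation of one record.

    Windows are ``window_s`` seconds long and start every
    ``window_s - overlap_s`` seconds (fractional-second durations floor
    to integer samples).  A record shorter than one window is an error.
    """
    if not 0 <= overlap_s < window_s:
        raise ValueError("require 0 <= overlap_s < window_s")
    win_n = int(np.floor(window_s * record.fs))
    step_n = int(np.floor((window_s - overlap_s) * record.fs))
    if step_n < 1:
        raise ValueError("window stride is below one sample")
    if record.n_samples < win_n:
        raise ValueError(
            f"record {record.record_id!r} ({record.duration:.6g} s) is "
            f"shorter than the {window_s} s window")
    pair = select_leads(record)
    pairs = []
    for k in range(window_count(record.n_samples, win_n, step_n)):
        start = k * step_n
        pairs.append(SamplePair(
            x=pair.x[start:start + win_n],
            y=pair.y[start:start + win_n],
            fs=record.fs,
            origin=(record.record_id, start),
        ))
    return WindowedDataset(pairs=pairs, window_s=window_s, overlap_s=overlap_s)


def split_records(records: list, train_frac: float = 0.8,
                  seed: int = 0, by_patient: bool = False) -> tuple[list, list]:
    """Uniform-random train/test partition of records.

    ``|train|`` is the nearest integer to ``train_frac * n`` (so 546
    records split 437/109 at 0.8).  The permutation is drawn from
    numpy's PCG64 ``default_rng`` seeded with ``seed``, making the
    partition reproducible across platforms.  With ``by_patient`` the
    split keys on patient_id so one patient's records never straddle
    the partition.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    if by_patient:
        patients = sorted({r.patient_id for r in records})
        perm = rng.permutation(len(patients))
        n_train = int(round(train_frac * len(patients)))
        train_pat = {patients[i] for i in perm[:n_train]}
        train = [r for r in records if r.patient_id in train_pat]
        test = [r for r in records if r.patient_id not in train_pat]
    else:
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        train = [records[i] for i in perm[:n_train]]
        test = [records[i] for i in perm[n_train:]]
    return train, test


def preprocess_record(record: ECGRecord, low: float = 0.05, high: float = 45.0,
                      target_fs: float = 200.0) -> ECGRecord:
    """Apply the fixed conditioning chain: band-pass then downsample."""
    return downsample(bandpass(record, low, high), target_fs)
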