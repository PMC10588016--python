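"""ECG record I/O, fixed-length segmentation, and stratified split planning.

Records are read either from single-column delimited text (one sample per
line, millivolts) or from WFDB header/signal pairs (the PhysioNet on-disk
format: a ``.hea`` text header plus a binary ``.dat``; formats 16 and 212
are supported, with gain/baseline scaling to physical millivolts).

Segmentation cuts contiguous, non-overlapping windows starting at sample 0.
Split planning reserves a fixed per-class test count first, then divides the
remainder train/validation at the requested fraction, per class, with a
seeded generator recorded in the plan for audit.  By default splitting is at
segment level (segments of one record can land in different partitions,
mirroring common practice but a leakage risk); ``group_by_record`` keeps
each record's segments in a single partition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ECGRecord", "Segment", "SplitPlan", "read_record", "segment_record", "make_split"]

CLASS_LABELS = ("ARR", "CHF", "NSR", "UNKNOWN")


@dataclass
class ECGRecord:
    """A single-channel ECG time series in millivolts."""

    samples: np.ndarray
    sampling_rate: float = 128.0
    record_id: str = ""
    label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.record_id!r} contains non-finite samples")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_interval(self) -> float:
        """Spacing between samples in seconds (0.0078125 s at 128 Hz)."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class Segment:
    """A fixed-length labeled excerpt of a record - the classification unit."""

    samples: np.ndarray
    parent_record: str
    index: int
    label: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def segment_id(self) -> str:
        return f"{self.parent_record}#{self.index}"


@dataclass
class SplitPlan:
    """Assignment of segment ids to train/validation/test partitions."""

    assignment: dict[str, str]
    seed: int
    per_class_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def ids(self, partition: str) -> list[str]:
        return [sid for sid, p in self.assignment.items() if p == partition]


def _read_csv_record(path: Path, sampling_rate: float, record_id: str, label: str) -> ECGRecord:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                rows.append(float(s))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {s!r} on line {lineno} "
                    "(expected one sample per line)"
                ) from None
    if not rows:
        raise ValueError(f"{path}: file contains no samples")
    return ECGRecord(np.array(rows), sampling_rate, record_id, label)


_HEA_SIGNAL_RE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)"
    r"(?:\s+(?P<gain>[\d.]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?)?"
    r"(?:\s+(?P<adcres>\d+))?(?:\s+(?P<adczero>-?\d+))?"
)


def _read_wfdb_record(path: Path, sampling_rate_override, record_id: str, label: str) -> ECGRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"{hea}: malformed record line {lines[0]!r}")
    name, n_sig, fs, n_samples = head[0], int(head[1]), float(head[2]), int(head[3])
    if sampling_rate_override is not None and sampling_rate_override != fs:
        raise ValueError(
            f"{hea}: header sampling rate {fs} Hz conflicts with explicit override "
            f"{sampling_rate_override} Hz"
        )
    if len(lines) < 1 + n_sig:
        raise ValueError(f"{hea}: header declares {n_sig} signals but lists {len(lines) - 1}")
    m = _HEA_SIGNAL_RE.match(lines[1])
    if m is None:
        raise ValueError(f"{hea}: malformed signal line {lines[1]!r}")
    fmt = int(m.group("fmt"))
    gain = float(m.group("gain") or 200.0) or 200.0
    baseline = int(m.group("baseline") or m.group("adczero") or 0)

    dat = hea.parent / m.group("file")
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = dat.read_bytes()

    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2").astype(float)
        adc = adc.reshape(-1, n_sig)[:, 0]
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(int)
        s0 = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        s1 = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        pairs = np.stack([s0, s1], axis=1).ravel()
        adc = np.where(pairs > 2047, pairs - 4096, pairs).astype(float)
        adc = adc.reshape(-1, n_sig)[:, 0] if n_sig > 1 else adc
    else:
        raise ValueError(f"{hea}: unsupported WFDB format {fmt} (formats 16 and 212 supported)")

    if len(adc) < n_samples:
        raise ValueError(
            f"{dat}: signal file holds {len(adc)} samples per channel but header "
            f"declares {n_samples}"
        )
    adc = adc[:n_samples]
    return ECGRecord((adc - baseline) / gain, fs, record_id or name, label)


def read_record(
    path,
    format: str = "csv",
    sampling_rate: float = 128.0,
    sampling_rate_override: float | None = None,
    record_id: str = "",
    label: str = "UNKNOWN",
) -> ECGRecord:
    """Read a single-channel ECG record from disk.

    Parameters
    ----------
    path : path-like
        For ``csv``, a single-column text file of samples in millivolts.
        For ``wfdb``, the record path or its ``.hea`` header.
    format : {"csv", "wfdb"}
    sampling_rate : float
        Sampling rate assumed for csv input (default 128 Hz).
    sampling_rate_override : float, optional
        For wfdb input: assert the header matches this rate; a conflict is an
        error naming both values.
    label : str
        Class label to attach ({ARR, CHF, NSR, UNKNOWN}).
    """
    path = Path(path)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(f"record file not found: {path}")
        rid = record_id or path.stem
        return _read_csv_record(path, sampling_rate, rid, label)
    if format == "wfdb":
        return _read_wfdb_record(path, sampling_rate_override, record_id, label)
    raise ValueError(f"format must be 'csv' or 'wfdb', got {format!r}")


def write_wfdb_record(record: ECGRecord, basepath, gain: float = 200.0) -> None:
    """Write a record as a minimal WFDB format-16 header/signal pair.

    Intended for round-trip tests and small exports; ADC values are
    ``round(mV * gain)`` clipped to int16 range.
    """
    base = Path(basepath)
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    fs = record.sampling_rate
    fs_str = f"{int(fs)}" if float(fs).is_integer() else f"{fs}"
    base.with_suffix(".hea").write_text(
        f"{base.name} 1 {fs_str} {len(adc)}\n"
        f"{base.name}.dat 16 {gain:g}(0)/mV 16 0 {adc[0]} 0 0 ECG\n"
    )
    base.with_suffix(".dat").write_bytes(adc.tobytes())


def segment_record(
    record: ECGRecord, seg_len: int = 500, n_segments: int | None = None
) -> list[Segment]:
    """Cut contiguous non-overlapping fixed-length segments from sample 0.

    If ``n_segments`` is omitted, yields ``floor(N / seg_len)`` segments.
    Each segment inherits the record's label.
    """
    if seg_len < 1:
        raise ValueError(f"seg_len must be >= 1, got {seg_len}")
    n_avail = len(record) // seg_len
    if n_segments is None:
        n_segments = n_avail
    if n_segments < 1 or n_avail < n_segments:
        raise ValueError(
            f"record {record.record_id!r} too short: {len(record)} samples available, "
            f"{seg_len * max(n_segments, 1)} required for {n_segments} segments of {seg_len}"
        )
    return [
        Segment(
            samples=record.samples[i * seg_len : (i + 1) * seg_len].copy(),
            parent_record=record.record_id,
            index=i,
            label=record.label,
        )
        for i in range(n_segments)
    ]


def make_split(
    segments: list[Segment],
    train_frac: float = 0.8,
    test_per_class: int = 0,
    seed: int = 0,
    group_by_record: bool = False,
) -> SplitPlan:
    """Plan a stratified train/validation/test split over labeled segments.

    Per class, ``test_per_class`` segments are reserved for test first; the
    remainder is divided ``train_frac`` / ``1 - train_frac`` between train
    and validation.  All selections are drawn with the stated seed
    (deterministic given inputs and seed).  With ``group_by_record`` the
    sampling unit is the parent record, so no record straddles partitions.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    if test_per_class < 0:
        raise ValueError(f"test_per_class must be >= 0, got {test_per_class}")
    ids = [s.segment_id for s in segments]
    if len(set(ids)) != len(ids):
        raise ValueError("segment ids are not unique")

    rng = np.random.default_rng(seed)
    by_class: dict[str, list[Segment]] = {}
    for s in segments:
        by_class.setdefault(s.label, []).append(s)

    assignment: dict[str, str] = {}
    per_class_counts: dict[str, dict[str, int]] = {}
    for label in sorted(by_class):
        segs = by_class[label]
        if group_by_record:
            units = sorted({s.parent_record for s in segs})
        else:
            units = sorted(s.segment_id for s in segs)
        if len(units) <= test_per_class:
            raise ValueError(
                f"class {label!r} has only {len(units)} "
                f"{'records' if group_by_record else 'segments'}, need more than "
                f"test_per_class={test_per_class}"
            )
        order = rng.permutation(len(units))
        shuffled = [units[i] for i in order]
        test_units = set(shuffled[:test_per_class])
        rest = shuffled[test_per_class:]
        n_train = int(round(train_frac * len(rest)))
        train_units = set(rest[:n_train])

        counts = {"train": 0, "validation": 0, "test": 0}
        for s in segs:
            unit = s.parent_record if group_by_record else s.segment_id
            part = (
                "test" if unit in test_units else "train" if unit in train_units else "validation"
            )
            assignment[s.segment_id] = part
            counts[part] += 1
        per_class_counts[label] = counts

    return SplitPlan(assignment=assignment, seed=seed, per_class_counts=per_class_counts)
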