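"""Recording I/O and the preprocessing chain.

A phonocardiogram (PCG) arrives as a single-channel WAV file.  Before any
segmentation or feature extraction the signal is passed through a fixed
three-step chain:

1. zero-phase high-pass at 10 Hz (removes baseline drift without shifting
   heart-sound boundaries),
2. spike removal (suppresses isolated transients such as stethoscope bumps),
3. normalization to zero mean and unit standard deviation.

All sample indices in annotation files are 0-based and intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "PcgRecording",
    "FeatureTable",
    "WORKING_RATE",
    "read_wav",
    "write_wav",
    "highpass_10hz",
    "remove_spikes",
    "normalize",
    "preprocess",
    "read_annotations",
    "write_annotations",
    "read_labels",
    "write_labels",
    "read_feature_table",
    "write_feature_table",
]

#: Default working sampling rate in Hz.  Features reach 820 Hz, so the
#: Nyquist frequency must exceed that; 2000 Hz is the convention of the
#: public heart-sound challenge data.
WORKING_RATE = 2000


@dataclass
class PcgRecording:
    """A single-channel heart-sound recording.

    Parameters
    ----------
    record_id : str
        Identifier used to join recordings with labels and annotations.
    samples : ndarray
        Signal samples (dimensionless after normalization).
    sampling_rate : float
        Sampling rate in Hz.
    diagnosis : int, optional
        +1 abnormal, -1 normal.
    quality : int, optional
        1 clean, 0 noisy.
    """

    record_id: str
    samples: np.ndarray
    sampling_rate: float
    diagnosis: int | None = None
    quality: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(
                f"recording {self.record_id!r}: expected a 1-D signal, "
                f"got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"recording {self.record_id!r}: non-finite samples")

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return len(self.samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "PcgRecording":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass
class FeatureTable:
    """Per-recording feature matrix with canonical, domain-tagged columns."""

    record_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # shape (n_records, n_features); NaN marks missing
    domains: list[str] = field(default_factory=list)  # one tag per feature

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.record_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.record_ids)} records x {len(self.feature_names)} features"
            )
        if self.domains and len(self.domains) != len(self.feature_names):
            raise ValueError("one domain tag per feature required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.record_ids, columns=self.feature_names
        )


def read_wav(path: str | Path, working_rate: int = WORKING_RATE) -> PcgRecording:
    """Read a single-channel WAV file, resampling to the working rate.

    Integer PCM samples are scaled to [-1, 1].  A sampling rate differing
    from *working_rate* is converted by polyphase resampling, which
    preserves tone frequencies and total duration to within one sample.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(f"{path}: expected a single channel, got {data.ndim} channels")
    if data.size == 0:
        raise ValueError(f"{path}: empty WAV file")
    samples = np.asarray(data, dtype=np.float64)
    if np.issubdtype(data.dtype, np.integer):
        samples /= float(np.iinfo(data.dtype).max)
    if rate != working_rate:
        from fractions import Fraction

        frac = Fraction(working_rate, int(rate)).limit_denominator(1000)
        samples = signal.resample_poly(samples, frac.numerator, frac.denominator)
    return PcgRecording(record_id=path.stem, samples=samples, sampling_rate=working_rate)


def write_wav(recording: PcgRecording, path: str | Path, dtype: str = "int16") -> None:
    """Write a recording as PCM16 (default) or float32 WAV."""
    path = Path(path)
    x = recording.samples
    if dtype == "int16":
        peak = np.max(np.abs(x)) if len(x) else 0.0
        scaled = x / peak if peak > 0 else x
        data = np.round(scaled * 32767).astype(np.int16)
    elif dtype == "float32":
        data = x.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    wavfile.write(path, int(recording.sampling_rate), data)


def highpass_10hz(recording: PcgRecording, cutoff: float = 10.0, order: int = 2) -> PcgRecording:
    """High-pass filter removing baseline drift below *cutoff* Hz.

    Order-2 Butterworth applied forward-backward (zero phase) so that state
    boundaries are not shifted.
    """
    sos = signal.butter(order, cutoff, btype="highpass", fs=recording.sampling_rate, output="sos")
    return recording.with_samples(signal.sosfiltfilt(sos, recording.samples))


def remove_spikes(
    recording: PcgRecording,
    window_s: float = 0.5,
    threshold_factor: float = 3.0,
) -> PcgRecording:
    """Suppress isolated high-amplitude transients.

    The signal is split into windows of *window_s* seconds; a window whose
    maximum absolute amplitude exceeds ``threshold_factor`` times the median
    of the window maxima is treated as containing a spike.  Within such a
    window the samples between the last zero-crossing before the peak and
    the first zero-crossing after it are zeroed.  Clean recordings pass
    through unchanged.
    """
    x = recording.samples.copy()
    n = len(x)
    win = max(1, int(round(window_s * recording.sampling_rate)))
    if n == 0:
        return recording.with_samples(x)
    n_win = int(np.ceil(n / win))
    maxima = np.array(
        [np.max(np.abs(x[i * win : min((i + 1) * win, n)])) for i in range(n_win)]
    )
    med = np.median(maxima)
    if med == 0:
        return recording.with_samples(x)
    # iterate: removing the worst spike can expose the next one
    for _ in range(n_win):
        maxima = np.array(
            [np.max(np.abs(x[i * win : min((i + 1) * win, n)])) for i in range(n_win)]
        )
        med = np.median(maxima)
        worst = int(np.argmax(maxima))
        if maxima[worst] <= threshold_factor * med:
            break
        lo, hi = worst * win, min((worst + 1) * win, n)
        seg = x[lo:hi]
        peak = lo + int(np.argmax(np.abs(seg)))
        signs = np.signbit(x)
        crossings = np.nonzero(np.diff(signs.astype(np.int8)))[0]
        before = crossings[crossings < peak]
        after = crossings[crossings >= peak]
        start = int(before[-1]) + 1 if len(before) else lo
        end = int(after[0]) + 1 if len(after) else hi
        x[start:end] = 0.0
    return recording.with_samples(x)


def normalize(recording: PcgRecording) -> PcgRecording:
    """Scale to zero mean and unit standard deviation."""
    x = recording.samples
    sd = np.std(x)
    if sd == 0:
        raise ValueError(
            f"recording {recording.record_id!r}: constant signal cannot be normalized"
        )
    return recording.with_samples((x - np.mean(x)) / sd)


def preprocess(recording: PcgRecording) -> PcgRecording:
    """The full fixed-order chain: high-pass, spike removal, normalization."""
    return normalize(remove_spikes(highpass_10hz(recording)))


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_ANNOT_HEADER = ["state", "start_sample", "end_sample"]
_LABEL_HEADER = ["record_id", "diagnosis", "quality"]


def write_annotations(segmentation, path: str | Path) -> None:
    """Write a segmentation as CSV ``state,start_sample,end_sample``.

    Indices are 0-based, intervals half-open.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOT_HEADER)
        for state, start, end in segmentation.intervals:
            writer.writerow([state, start, end])


def read_annotations(path: str | Path):
    """Read an annotation CSV into a :class:`~pcgkit.segmentation.StateSegmentation`.

    Raises ``ValueError`` naming the offending line for malformed rows or
    out-of-order / overlapping intervals.
    """
    from .segmentation import VALID_STATES, StateSegmentation

    intervals: list[tuple[str, int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _ANNOT_HEADER:
            raise ValueError(f"{path}: bad header {header!r}, expected {_ANNOT_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            state, start_s, end_s = row
            if state not in VALID_STATES:
                raise ValueError(f"{path}:{lineno}: unknown state {state!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer sample index") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            if intervals and start < intervals[-1][2]:
                raise ValueError(f"{path}:{lineno}: interval overlaps or precedes the previous one")
            intervals.append((state, start, end))
    return StateSegmentation(intervals)


def write_labels(records: list[PcgRecording], path: str | Path) -> None:
    """Write ``record_id,diagnosis,quality`` rows (diagnosis +1/-1, quality 1/0)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LABEL_HEADER)
        for rec in records:
            writer.writerow([rec.record_id, rec.diagnosis, rec.quality])


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a label CSV, indexed by record_id."""
    df = pd.read_csv(path, dtype={"record_id": str})
    missing = [c for c in _LABEL_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_d = set(df["diagnosis"].unique()) - {1, -1}
    bad_q = set(df["quality"].unique()) - {1, 0}
    if bad_d:
        raise ValueError(f"{path}: invalid diagnosis values {sorted(bad_d)}")
    if bad_q:
        raise ValueError(f"{path}: invalid quality values {sorted(bad_q)}")
    return df.set_index("record_id")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with the canonical column order."""
    df = table.to_frame()
    df.index.name = "record_id"
    df.to_csv(path, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    from .features import domain_of_feature

    df = pd.read_csv(path, index_col="record_id")
    names = list(df.columns)
    return FeatureTable(
        record_ids=[str(i) for i in df.index],
        feature_names=names,
        values=df.to_numpy(dtype=np.float64),
        domains=[domain_of_feature(n) for n in names],
    )
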