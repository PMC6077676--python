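"""Four-state heart-sound segmentation.

A heart-sound recording is decomposed into repeating cardiac cycles, each
consisting of four ordered states: the first heart sound (S1), the systolic
interval, the second heart sound (S2), and the diastolic interval.  Every
feature extractor downstream consumes only this decomposition, so the
segmentation source is pluggable: reference annotations can be supplied, or
the built-in segmenter can be used.

The built-in segmenter is a duration-constrained Viterbi decoder over a
smoothed Hilbert envelope:

1. compute the homomorphic envelope (low-pass filtered log magnitude of the
   analytic signal) and decimate it to a 50 Hz frame rate;
2. estimate the cardiac cycle period from the envelope autocorrelation peak
   in the physiological 30-200 bpm band, and the S1-to-S2 spacing from the
   autocorrelation peak below half a cycle;
3. decode the most likely frame-state sequence under Gaussian envelope
   emissions (high mean for S1/S2, low for systole/diastole) and
   truncated-Gaussian state-duration priors, with the cyclic state order
   hard-wired into the transition structure.

This is deliberately simpler than a trained hidden semi-Markov model; it is
deterministic, has no learned parameters, and recovers state boundaries
accurately on signals with a clear envelope structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_prep import PcgRecording

__all__ = [
    "VALID_STATES",
    "StateSegmentation",
    "CardiacCycle",
    "SegmentationError",
    "segment",
    "cycles",
    "state_sequence",
]

#: Canonical cyclic state order.
VALID_STATES = ("S1", "systole", "S2", "diastole")

_NEXT = {"S1": "systole", "systole": "S2", "S2": "diastole", "diastole": "S1"}


class SegmentationError(ValueError):
    """Raised when no plausible segmentation can be produced."""


@dataclass
class StateSegmentation:
    """Ordered, non-overlapping state intervals partitioning the usable signal.

    Intervals are ``(state, start_sample, end_sample)`` with 0-based,
    half-open indices.  Within the segmented span the states must follow the
    cyclic order S1 -> systole -> S2 -> diastole; the sequence may start and
    end at any phase of the cycle.
    """

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        prev_end = None
        prev_state = None
        for i, (state, start, end) in enumerate(self.intervals):
            if state not in VALID_STATES:
                raise ValueError(f"interval {i}: unknown state {state!r}")
            if end <= start:
                raise ValueError(f"interval {i}: empty or inverted interval ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"interval {i}: overlaps the previous interval")
            if prev_state is not None and state != _NEXT[prev_state]:
                raise ValueError(
                    f"interval {i}: state {state!r} breaks the cyclic order "
                    f"(expected {_NEXT[prev_state]!r} after {prev_state!r})"
                )
            prev_end, prev_state = end, state

    @property
    def n_cycles(self) -> int:
        """Number of complete S1 -> systole -> S2 -> diastole sequences."""
        count = 0
        run = 0
        for state, _, _ in self.intervals:
            if state == VALID_STATES[run]:
                run += 1
                if run == 4:
                    count += 1
                    run = 0
            else:
                run = 1 if state == "S1" else 0
        return count

    @property
    def span(self) -> tuple[int, int]:
        """(first_start, last_end) of the segmented region."""
        return self.intervals[0][1], self.intervals[-1][2]


@dataclass
class CardiacCycle:
    """One cardiac cycle's four state slices of the underlying signal.

    The ``cycle`` array is exactly the concatenation of the four slices.
    """

    s1: np.ndarray
    systole: np.ndarray
    s2: np.ndarray
    diastole: np.ndarray
    cycle: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("s1", "systole", "s2", "diastole"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"cycle has an empty {name} slice")
        self.cycle = np.concatenate([self.s1, self.systole, self.s2, self.diastole])

    def slice_of(self, state: str) -> np.ndarray:
        return {
            "S1": self.s1,
            "systole": self.systole,
            "S2": self.s2,
            "diastole": self.diastole,
        }[state]


def cycles(segmentation: StateSegmentation, recording: PcgRecording) -> list[CardiacCycle]:
    """Cut the recording into complete cardiac cycles.

    Incomplete leading or trailing cycles are dropped silently.
    """
    n = len(recording.samples)
    if segmentation.intervals and segmentation.intervals[-1][2] > n:
        raise ValueError("segmentation extends past the end of the recording")
    out: list[CardiacCycle] = []
    ivs = segmentation.intervals
    i = 0
    while i + 3 < len(ivs):
        if ivs[i][0] != "S1":
            i += 1
            continue
        # contiguity within a cycle is not required (spike-removal gaps are
        # not produced by our sources, but annotations may skip samples)
        states = [ivs[i + k][0] for k in range(4)]
        if states != list(VALID_STATES):
            i += 1
            continue
        slices = [recording.samples[ivs[i + k][1] : ivs[i + k][2]] for k in range(4)]
        out.append(CardiacCycle(*slices))
        i += 4
    return out


def state_sequence(segmentation: StateSegmentation, n_samples: int) -> np.ndarray:
    """Per-sample state index array (-1 outside the segmented span)."""
    seq = np.full(n_samples, -1, dtype=np.int8)
    idx = {s: i for i, s in enumerate(VALID_STATES)}
    for state, start, end in segmentation.intervals:
        seq[start:end] = idx[state]
    return seq


# ---------------------------------------------------------------------------
# Built-in segmenter
# ---------------------------------------------------------------------------

_FRAME_RATE = 50  # Hz; 20 ms frames

# duration priors in seconds (mean, sd); systole/diastole means are derived
# from the estimated cycle period at run time
_S1_DUR = (0.122, 0.049)
_S2_DUR = (0.092, 0.035)


def _homomorphic_envelope(x: np.ndarray, fs: float, lp_cutoff: float = 8.0) -> np.ndarray:
    analytic = signal.hilbert(x)
    env = np.abs(analytic)
    sos = signal.butter(2, lp_cutoff, btype="lowpass", fs=fs, output="sos")
    log_env = np.log(env + 1e-12)
    smooth = signal.sosfiltfilt(sos, log_env)
    return np.exp(smooth)


def _estimate_periods(env_f: np.ndarray, frame_rate: float) -> tuple[float, float]:
    """Cycle period and S1-start-to-S2-start spacing, in seconds."""
    e = env_f - np.mean(env_f)
    ac = signal.correlate(e, e, mode="full")[len(e) - 1 :]
    ac = ac / ac[0] if ac[0] > 0 else ac
    lo = int(round(60.0 / 200.0 * frame_rate))  # 200 bpm
    hi = int(round(60.0 / 30.0 * frame_rate))  # 30 bpm
    hi = min(hi, len(ac) - 1)
    if hi <= lo:
        raise SegmentationError("recording too short to estimate a heart rate")
    band = ac[lo : hi + 1]
    peaks, _ = signal.find_peaks(band)
    if len(peaks) == 0:
        raise SegmentationError(
            "no envelope autocorrelation peak in the 30-200 bpm band; "
            "cannot estimate a plausible heart rate"
        )
    cycle_lag = lo + peaks[np.argmax(band[peaks])]
    period = cycle_lag / frame_rate
    # S1->S2 spacing: strongest autocorrelation peak strictly below half a
    # cycle.  Systole is the shorter half of the cycle, so the S1-S2 lag
    # lies below period/2 while the S2-S1 lag lies above it; searching only
    # below excludes the phase-swapped solution.
    s_hi = max(3, int(np.floor(0.5 * cycle_lag)) - 1)
    sband = ac[2 : s_hi + 1]
    speaks, _ = signal.find_peaks(sband)
    if len(speaks):
        spacing = (2 + speaks[np.argmax(sband[speaks])]) / frame_rate
    else:
        spacing = 0.35 * period
    spacing = float(np.clip(spacing, 0.15, 0.5 * period))
    return float(period), spacing


def _duration_logpmf(mean_s: float, sd_s: float, frame_rate: float, max_frames: int) -> np.ndarray:
    """Log-probabilities over durations 1..max_frames (truncated Gaussian)."""
    d = np.arange(1, max_frames + 1) / frame_rate
    sd = max(sd_s, 1.5 / frame_rate)
    # soft prior: a plain Gaussian log-density, so an atypically long run
    # (e.g. a terminal diastole covering an unsegmentable tail) pays a
    # quadratic penalty instead of being forbidden outright
    logp = -0.5 * ((d - mean_s) / sd) ** 2
    m = np.max(logp)
    p = np.exp(logp - m)
    with np.errstate(divide="ignore"):
        return np.log(p / np.sum(p))


def _refine_boundaries(
    intervals: list[tuple[str, int, int]],
    env: np.ndarray,
    n_samples: int,
    frac: float = 0.05,
    floor_mult: float = 4.0,
) -> list[tuple[str, int, int]]:
    """Grow S1/S2 intervals outward to the envelope's low-amplitude tails.

    The frame-rate Viterbi places sound-state boundaries where the envelope
    crosses the mid level, clipping the quiet onset/offset of each
    transient.  Each sound interval is expanded while the sample-rate
    envelope exceeds a stop threshold, limited to the midpoint of the
    adjacent silence interval so the partition survives.  The threshold is
    the larger of ``frac`` times the state's median peak (so a spuriously
    quiet run cannot balloon into its neighbours) and ``floor_mult`` times
    the median silence-state envelope (the ambient noise floor, which marks
    where a transient genuinely ends).
    """
    grown: list[list] = [list(iv) for iv in intervals]
    silence = [env[a:b] for st, a, b in intervals if st in ("systole", "diastole")]
    floor = float(np.median(np.concatenate(silence))) if silence else 0.0
    peaks: dict[str, float] = {}
    for sound in ("S1", "S2"):
        vals = [float(np.max(env[a:b])) for st, a, b in intervals if st == sound]
        peaks[sound] = float(np.median(vals)) if vals else 0.0
    for i, (state, a, b) in enumerate(intervals):
        if state not in ("S1", "S2"):
            continue
        thr = max(frac * peaks[state], floor_mult * floor)
        left_floor = (intervals[i - 1][1] + intervals[i - 1][2]) // 2 + 1 if i > 0 else 0
        right_ceil = (
            (intervals[i + 1][1] + intervals[i + 1][2]) // 2
            if i + 1 < len(intervals)
            else n_samples
        )
        a2, b2 = a, b
        while a2 > left_floor and env[a2 - 1] > thr:
            a2 -= 1
        while b2 < right_ceil and env[b2] > thr:
            b2 += 1
        grown[i][1], grown[i][2] = a2, b2
    # silence intervals shrink to the gaps between their grown neighbours
    out: list[tuple[str, int, int]] = []
    for i, (state, a, b) in enumerate(grown):
        if state in ("S1", "S2"):
            out.append((state, a, b))
            continue
        start = grown[i - 1][2] if i > 0 else a
        end = grown[i + 1][1] if i + 1 < len(grown) else b
        if end > start:
            out.append((state, start, end))
        elif 0 < i < len(grown) - 1:
            # interior silence must survive for the cyclic order; keep 1 sample
            out.append((state, start, start + 1))
    return out


def segment(
    recording: PcgRecording,
    annotations: StateSegmentation | None = None,
) -> StateSegmentation:
    """Segment a preprocessed recording into the four cardiac states.

    If *annotations* is given it is validated against the recording and
    returned unchanged (the external-annotation path); otherwise the
    built-in envelope/Viterbi segmenter runs.  Deterministic for a fixed
    input.
    """
    if annotations is not None:
        if annotations.intervals[-1][2] > len(recording.samples):
            raise ValueError("annotations extend past the end of the recording")
        return annotations

    x = recording.samples
    fs = recording.sampling_rate
    if len(x) / fs < 2.0:
        raise SegmentationError(
            f"recording {recording.record_id!r} is {len(x) / fs:.2f} s long; "
            "at least 2 s are required for segmentation"
        )

    env = _homomorphic_envelope(x, fs)
    step = int(round(fs / _FRAME_RATE))
    env_f = signal.resample_poly(env, 1, step)
    env_f = np.maximum(env_f, 0.0)
    scale = np.max(env_f)
    if scale <= 0:
        raise SegmentationError("flat envelope: cannot segment")
    env_f = env_f / scale

    period, spacing = _estimate_periods(env_f, _FRAME_RATE)

    # emission models: sound states sit on the high envelope level,
    # silence states on the low one
    hi_mu = float(np.mean(env_f[env_f >= np.quantile(env_f, 0.85)]))
    lo_mu = float(np.mean(env_f[env_f <= np.quantile(env_f, 0.5)]))
    sd = max(0.25 * (hi_mu - lo_mu), 0.02)
    means = np.array([hi_mu, lo_mu, hi_mu, lo_mu])  # S1, systole, S2, diastole

    n_frames = len(env_f)
    logB = -0.5 * ((env_f[None, :] - means[:, None]) / sd) ** 2  # (4, T)
    cumB = np.concatenate([np.zeros((4, 1)), np.cumsum(logB, axis=1)], axis=1)

    sys_mean = max(spacing - _S1_DUR[0], 0.08)
    dia_mean = max(period - _S1_DUR[0] - sys_mean - _S2_DUR[0], 0.10)
    dur_specs = [
        _S1_DUR,
        (sys_mean, max(0.2 * sys_mean, 0.02)),
        _S2_DUR,
        (dia_mean, max(0.25 * dia_mean, 0.03)),
    ]
    max_frames = min(n_frames, int(np.ceil(1.6 * period * _FRAME_RATE)))
    logdur = [_duration_logpmf(m, s, _FRAME_RATE, max_frames) for m, s in dur_specs]
    # survival log-prob for boundary-truncated runs: P(D >= d)
    logsurv = []
    for ld in logdur:
        p = np.exp(ld)
        surv = np.clip(1.0 - np.concatenate([[0.0], np.cumsum(p)[:-1]]), 1e-300, None)
        logsurv.append(np.log(surv))

    prev_state = np.array([3, 0, 1, 2])  # predecessor in the cyclic order

    NEG = -np.inf
    delta = np.full((n_frames, 4), NEG)
    psi_d = np.zeros((n_frames, 4), dtype=np.int32)

    durs = np.arange(1, max_frames + 1)
    for t in range(n_frames):
        d_ok = durs[durs <= t + 1]
        starts = t + 1 - d_ok  # run covers frames [start, t]
        for s in range(4):
            emit = cumB[s, t + 1] - cumB[s, starts]
            ld = logdur[s][d_ok - 1].copy()
            # a run starting at frame 0 may be the truncated tail of a state
            ld[starts == 0] = logsurv[s][d_ok[starts == 0] - 1]
            prev_scores = np.where(starts == 0, 0.0, np.where(starts > 0, delta[starts - 1, prev_state[s]], NEG))
            cand = prev_scores + ld + emit
            best = int(np.argmax(cand))
            delta[t, s] = cand[best]
            psi_d[t, s] = d_ok[best]

    # terminal run may also be truncated: rescore the last run with survival
    final = np.full(4, NEG)
    final_d = np.zeros(4, dtype=np.int32)
    t = n_frames - 1
    d_ok = durs[durs <= t + 1]
    starts = t + 1 - d_ok
    for s in range(4):
        emit = cumB[s, t + 1] - cumB[s, starts]
        ld = logsurv[s][d_ok - 1].copy()
        ld[starts == 0] = logsurv[s][d_ok[starts == 0] - 1]
        prev_scores = np.where(starts == 0, 0.0, np.where(starts > 0, delta[starts - 1, prev_state[s]], NEG))
        cand = prev_scores + ld + emit
        best = int(np.argmax(cand))
        final[s] = cand[best]
        final_d[s] = d_ok[best]

    if np.all(np.isinf(final)):
        raise SegmentationError("Viterbi decoding failed: no admissible state path")

    # backtrack
    s = int(np.argmax(final))
    t = n_frames - 1
    runs: list[tuple[int, int, int]] = []  # (state, start_frame, end_frame_excl)
    d = int(final_d[s])
    while True:
        start = t + 1 - d
        runs.append((s, start, t + 1))
        if start == 0:
            break
        t = start - 1
        s = int(prev_state[s])
        d = int(psi_d[t, s])
    runs.reverse()

    intervals = [
        (VALID_STATES[s], int(a * step), int(min(b * step, len(x))))
        for s, a, b in runs
    ]
    intervals = [(st, a, b) for st, a, b in intervals if b > a]
    intervals = _refine_boundaries(intervals, env, len(x))
    seg = StateSegmentation(intervals)
    if seg.n_cycles < 1:
        raise SegmentationError(
            f"recording {recording.record_id!r}: no complete cardiac cycle found"
        )
    return seg
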