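"""The 515 multidomain heart-sound features.

Nine feature domains are computed from a preprocessed recording and its
four-state segmentation, concatenated in a fixed canonical order:

==================  =====  ====================================================
domain              count  summary
==================  =====  ====================================================
time_interval          20  means/SDs of RR, state intervals, per-beat ratios
freq_state            308  mean Gaussian-windowed magnitude spectrum per state,
                           sampled at 30..790 Hz in 10 Hz steps (77 x 4)
amplitude              12  per-beat mean-absolute-amplitude ratios between states
energy                 47  27 band-energy ratios (10-820 Hz in 30 Hz bands) +
                           20 state-energy ratio statistics
freq_record            27  whole-record spectrum mass per band
cepstrum               65  first 13 real cepstral coefficients of the record and
                           of each joined state sequence
cyclostationarity       4  degree of cyclostationarity and peak sharpness of the
                           cycle-frequency spectral density (mean/SD)
hos                    16  per-state skewness and kurtosis statistics
entropy                16  per-state sample entropy and fuzzy measure entropy
==================  =====  ====================================================

Features that cannot be computed (too few cycles, empty state, zero-energy
denominator) are marked NaN, never silently zeroed; imputation happens at
model-fitting time.  All amplitude and energy features are ratios and hence
invariant to global signal scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .io_prep import FeatureTable, PcgRecording
from .segmentation import CardiacCycle, StateSegmentation, cycles

__all__ = [
    "DOMAINS",
    "DOMAIN_SIZES",
    "BAND_SPEC",
    "STATE_GRID",
    "FeatureVector",
    "feature_names",
    "feature_domains",
    "domain_of_feature",
    "time_interval_features",
    "state_spectrum_features",
    "amplitude_features",
    "band_energy_features",
    "state_energy_features",
    "record_spectrum_features",
    "cepstrum",
    "cepstrum_features",
    "cyclostationarity_features",
    "hos_features",
    "sample_entropy",
    "fuzzy_measure_entropy",
    "entropy_features",
    "extract_all",
    "extract_table",
]

DOMAINS = (
    "time_interval",
    "freq_state",
    "amplitude",
    "energy",
    "freq_record",
    "cepstrum",
    "cyclostationarity",
    "hos",
    "entropy",
)

DOMAIN_SIZES = {
    "time_interval": 20,
    "freq_state": 308,
    "amplitude": 12,
    "energy": 47,
    "freq_record": 27,
    "cepstrum": 65,
    "cyclostationarity": 4,
    "hos": 16,
    "entropy": 16,
}

#: 27 contiguous analysis bands: [10,40], [40,70], ..., [790,820] Hz
BAND_SPEC: list[tuple[float, float]] = [(10.0 + 30.0 * i, 40.0 + 30.0 * i) for i in range(27)]

#: 77 spectral sample frequencies for the per-state spectra: 30, 40, ..., 790 Hz
STATE_GRID = np.arange(30.0, 791.0, 10.0)

_STATE_KEYS = ("S1", "sys", "S2", "dia")  # short names used in feature labels

_N_CEPS = 13


def _names_time_interval() -> list[str]:
    names = []
    for base in ("RR", "IntS1", "IntS2", "IntSys", "IntDia"):
        names += [f"m_{base}", f"sd_{base}"]
    for base in ("Ratio_SysRR", "Ratio_DiaRR", "Ratio_SysDia", "Ratio_S1RR", "Ratio_S2RR"):
        names += [f"m_{base}", f"sd_{base}"]
    return names


def _names_amplitude() -> list[str]:
    pairs = ("SysS1", "DiaS2", "S1S2", "S1Dia", "SysDia", "S2Sys")
    return [f"{p}_Amp_{pair}" for pair in pairs for p in ("m", "sd")]


_ENERGY_PAIRS = (
    "S1_cycle",
    "S2_cycle",
    "sys_cycle",
    "dia_cycle",
    "S1_S2",
    "S1_sys",
    "S1_dia",
    "S2_sys",
    "S2_dia",
    "dia_sys",
)


def feature_names() -> list[str]:
    """The canonical 515 feature names, in extraction order."""
    names = _names_time_interval()
    names += [f"FreqState_{s}_{int(f)}Hz" for s in _STATE_KEYS for f in STATE_GRID]
    names += _names_amplitude()
    names += [f"Ratio_band_energy_{i + 1}" for i in range(27)]
    names += [f"{p}_Ratio_state_energy_{pair}" for pair in _ENERGY_PAIRS for p in ("m", "sd")]
    names += [f"Ratio_spectrum_{int(lo)}_{int(hi)}" for lo, hi in BAND_SPEC]
    names += [f"Ceps_{seq}_{k + 1}" for seq in ("record", "S1", "sys", "S2", "dia") for k in range(_N_CEPS)]
    names += [
        "m_cyclostationarity_1",
        "sd_cyclostationarity_1",
        "m_cyclostationarity_2",
        "sd_cyclostationarity_2",
    ]
    names += [
        f"{p}_{s}_{m}" for s in ("S1", "S2", "sys", "dia") for m in ("skewness", "kurtosis") for p in ("m", "sd")
    ]
    names += [f"{p}_{e}_{s}" for e in ("SampEn", "FuzzyMEn") for s in ("S1", "S2", "sys", "dia") for p in ("m", "sd")]
    assert len(names) == 515
    return names


def feature_domains() -> list[str]:
    """Domain tag for each canonical feature, aligned with feature_names()."""
    tags: list[str] = []
    for dom in DOMAINS:
        tags += [dom] * DOMAIN_SIZES[dom]
    return tags


_DOMAIN_BY_NAME: dict[str, str] | None = None


def domain_of_feature(name: str) -> str:
    global _DOMAIN_BY_NAME
    if _DOMAIN_BY_NAME is None:
        _DOMAIN_BY_NAME = dict(zip(feature_names(), feature_domains()))
    return _DOMAIN_BY_NAME[name]


@dataclass
class FeatureVector:
    """515 named, domain-tagged values for one recording (NaN = missing)."""

    names: list[str]
    values: np.ndarray
    domains: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (len(self.names) == len(self.values) == len(self.domains)):
            raise ValueError("names, values and domains must be aligned")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _mean_sd(values: list[float] | np.ndarray) -> tuple[float, float]:
    """Mean and sample SD; NaN where undefined."""
    v = np.asarray([x for x in np.atleast_1d(values) if np.isfinite(x)], dtype=np.float64)
    if len(v) == 0:
        return np.nan, np.nan
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan
    return mean, sd


# ---------------------------------------------------------------------------
# time-interval domain (20)
# ---------------------------------------------------------------------------


def time_interval_features(segmentation: StateSegmentation, sampling_rate: float) -> np.ndarray:
    """Means and SDs of RR, state intervals, and per-beat interval ratios.

    RR is the spacing between the onsets of adjacent S1 sounds.  Per-beat
    ratios divide a beat's interval by that beat's RR, so they exist only
    for beats followed by another S1.
    """
    ivs = segmentation.intervals
    # collect complete cycles as (s1, sys, s2, dia) interval quadruples
    quads: list[list[tuple[int, int]]] = []
    i = 0
    order = ("S1", "systole", "S2", "diastole")
    while i + 3 < len(ivs):
        if [ivs[i + k][0] for k in range(4)] == list(order):
            quads.append([(ivs[i + k][1], ivs[i + k][2]) for k in range(4)])
            i += 4
        else:
            i += 1
    if len(quads) < 2:
        return np.full(20, np.nan)

    fs = sampling_rate
    s1 = np.array([(b - a) / fs for (a, b), *_ in quads])
    sys_ = np.array([(q[1][1] - q[1][0]) / fs for q in quads])
    s2 = np.array([(q[2][1] - q[2][0]) / fs for q in quads])
    dia = np.array([(q[3][1] - q[3][0]) / fs for q in quads])
    s1_starts = np.array([q[0][0] for q in quads])
    rr = np.diff(s1_starts) / fs  # length n_cycles - 1

    out: list[float] = []
    out += _mean_sd(rr)
    out += _mean_sd(s1)
    out += _mean_sd(s2)
    out += _mean_sd(sys_)
    out += _mean_sd(dia)
    n = len(rr)
    out += _mean_sd(sys_[:n] / rr)
    out += _mean_sd(dia[:n] / rr)
    out += _mean_sd(sys_ / dia)
    out += _mean_sd(s1[:n] / rr)
    out += _mean_sd(s2[:n] / rr)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# per-state frequency spectrum (308)
# ---------------------------------------------------------------------------


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def state_spectrum_features(
    recording: PcgRecording, cardiac_cycles: list[CardiacCycle]
) -> np.ndarray:
    """Mean Gaussian-windowed magnitude spectrum per state on the 30-790 Hz grid.

    Each cycle's state slice is windowed (Gaussian, SD = length/6),
    zero-padded to a per-state common FFT length giving at most 10 Hz bin
    spacing, and amplitude-normalized by the window sum; magnitudes are
    averaged over cycles and read at the grid point's nearest bin.
    """
    fs = recording.sampling_rate
    out = np.full((4, len(STATE_GRID)), np.nan)
    min_nfft = _next_pow2(int(np.ceil(fs / 10.0)))
    for si, state in enumerate(("S1", "systole", "S2", "diastole")):
        slices = [c.slice_of(state) for c in cardiac_cycles]
        slices = [s for s in slices if len(s) > 0]
        if not slices:
            continue
        nfft = max(min_nfft, _next_pow2(max(len(s) for s in slices)))
        freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
        bin_idx = np.array([int(np.argmin(np.abs(freqs - f))) for f in STATE_GRID])
        acc = np.zeros(len(STATE_GRID))
        for s in slices:
            win = signal.windows.gaussian(len(s), std=len(s) / 6.0)
            spec = np.abs(np.fft.rfft(s * win, n=nfft)) / np.sum(win)
            acc += spec[bin_idx]
        out[si] = acc / len(slices)
    return out.ravel()


# ---------------------------------------------------------------------------
# normalized amplitude (12)
# ---------------------------------------------------------------------------


def amplitude_features(cardiac_cycles: list[CardiacCycle]) -> np.ndarray:
    """Per-beat ratios of mean absolute amplitude between states.

    Cycles whose denominator state has zero mean amplitude are excluded
    from that ratio's statistics.
    """
    pairs = (
        ("systole", "S1"),
        ("diastole", "S2"),
        ("S1", "S2"),
        ("S1", "diastole"),
        ("systole", "diastole"),
        ("S2", "systole"),
    )
    out: list[float] = []
    for num, den in pairs:
        ratios = []
        for c in cardiac_cycles:
            d = float(np.mean(np.abs(c.slice_of(den))))
            if d > 0:
                ratios.append(float(np.mean(np.abs(c.slice_of(num)))) / d)
        out += _mean_sd(ratios)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# energy domain (27 + 20)
# ---------------------------------------------------------------------------

_BAND_SOS_CACHE: dict[tuple[float, int], list[np.ndarray]] = {}


def _band_filters(fs: float, order: int = 5) -> list[np.ndarray]:
    key = (fs, order)
    if key not in _BAND_SOS_CACHE:
        _BAND_SOS_CACHE[key] = [
            signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
            for lo, hi in BAND_SPEC
        ]
    return _BAND_SOS_CACHE[key]


def band_energy_features(recording: PcgRecording) -> np.ndarray:
    """Energy ratio of each 30 Hz band-pass output to the raw signal.

    Each band filter is a fifth-order Butterworth band-pass applied in one
    direction, and the ratio is sum(y^2) / sum(x^2).
    """
    x = recording.samples
    total = float(np.sum(x**2))
    if total == 0:
        raise ValueError(f"recording {recording.record_id!r} has zero energy")
    if recording.sampling_rate / 2 <= BAND_SPEC[-1][1]:
        raise ValueError(
            f"sampling rate {recording.sampling_rate} Hz cannot cover the "
            f"{BAND_SPEC[-1][1]} Hz band"
        )
    out = np.empty(27)
    for i, sos in enumerate(_band_filters(recording.sampling_rate)):
        y = signal.sosfilt(sos, x)
        out[i] = float(np.sum(y**2)) / total
    return out


def state_energy_features(cardiac_cycles: list[CardiacCycle]) -> np.ndarray:
    """Mean/SD over cycles of the 10 per-cycle state-energy ratios.

    Four state-to-cycle ratios (summing to 1 within each cycle, since the
    cycle is exactly the concatenation of its states) and six
    state-to-state ratios.
    """
    per_pair: dict[str, list[float]] = {p: [] for p in _ENERGY_PAIRS}
    for c in cardiac_cycles:
        e = {
            "S1": float(np.sum(c.s1**2)),
            "sys": float(np.sum(c.systole**2)),
            "S2": float(np.sum(c.s2**2)),
            "dia": float(np.sum(c.diastole**2)),
        }
        e["cycle"] = e["S1"] + e["sys"] + e["S2"] + e["dia"]
        for pair in _ENERGY_PAIRS:
            num, den = pair.split("_")
            if e[den] > 0:
                per_pair[pair].append(e[num] / e[den])
    out: list[float] = []
    for pair in _ENERGY_PAIRS:
        out += _mean_sd(per_pair[pair])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# whole-record spectrum (27)
# ---------------------------------------------------------------------------


def record_spectrum_features(recording: PcgRecording) -> np.ndarray:
    """Per-band share of the whole-record spectrum magnitude.

    The "whole band" is 10-820 Hz (the union of the 27 analysis bands); a
    DFT bin belongs to the half-open band [lo, hi), so the 27 ratios
    partition the mass and sum to 1.
    """
    x = recording.samples
    if not np.any(x):
        raise ValueError(f"recording {recording.record_id!r} is identically zero")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / recording.sampling_rate)
    lo_all, hi_all = BAND_SPEC[0][0], BAND_SPEC[-1][1]
    in_whole = (freqs >= lo_all) & (freqs < hi_all)
    total = float(np.sum(mag[in_whole]))
    if total == 0:
        raise ValueError(f"recording {recording.record_id!r} has no 10-820 Hz content")
    out = np.empty(27)
    for i, (lo, hi) in enumerate(BAND_SPEC):
        band = (freqs >= lo) & (freqs < hi)
        out[i] = float(np.sum(mag[band])) / total
    return out


# ---------------------------------------------------------------------------
# cepstrum (65)
# ---------------------------------------------------------------------------


def cepstrum(sequence: np.ndarray, n_coeffs: int = _N_CEPS) -> np.ndarray:
    """First *n_coeffs* real cepstral coefficients of a sequence.

    The real cepstrum is the inverse DFT of the natural-log magnitude
    spectrum.  Zero spectral magnitudes are floored at 1e-12 times the peak
    magnitude so the log never diverges.
    """
    p = np.asarray(sequence, dtype=np.float64)
    if len(p) < 2 * n_coeffs:
        raise ValueError(f"sequence of length {len(p)} too short for {n_coeffs} coefficients")
    spec = np.abs(np.fft.fft(p))
    peak = np.max(spec)
    if peak == 0:
        return np.zeros(n_coeffs)
    spec = np.maximum(spec, 1e-12 * peak)
    ceps = np.real(np.fft.ifft(np.log(spec)))
    return ceps[:n_coeffs]


def cepstrum_features(
    recording: PcgRecording, segmentation: StateSegmentation
) -> np.ndarray:
    """13 cepstral coefficients for the record and each joined state sequence.

    All intervals of a given state are concatenated in temporal order
    before the cepstrum is taken.  Order: record, S1, systole, S2, diastole.
    """
    seqs: list[np.ndarray] = [recording.samples]
    for state in ("S1", "systole", "S2", "diastole"):
        parts = [
            recording.samples[a:b] for st, a, b in segmentation.intervals if st == state
        ]
        seqs.append(np.concatenate(parts) if parts else np.empty(0))
    out = np.full((5, _N_CEPS), np.nan)
    for i, seq in enumerate(seqs):
        if len(seq) >= 2 * _N_CEPS:
            out[i] = cepstrum(seq)
    return out.ravel()


# ---------------------------------------------------------------------------
# cyclostationarity (4)
# ---------------------------------------------------------------------------


def cycle_frequency_spectral_density(
    subsequence: np.ndarray, fs: float, beta: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the cycle-frequency spectral density of a subsequence.

    The estimate is the magnitude spectrum of the mean-removed squared
    Hilbert envelope, restricted to cycle frequencies in (0, beta] Hz.
    Returns ``(alphas, gamma)``.
    """
    env2 = np.abs(signal.hilbert(subsequence)) ** 2
    env2 = env2 - np.mean(env2)
    gamma = np.abs(np.fft.rfft(env2))
    alphas = np.fft.rfftfreq(len(env2), d=1.0 / fs)
    keep = (alphas > 0) & (alphas <= beta)
    return alphas[keep], gamma[keep]


def _cyclo_indicators(
    alphas: np.ndarray, gamma: np.ndarray, hr_band: tuple[float, float] = (0.5, 2.5)
) -> tuple[float, float]:
    """Degree of cyclostationarity d(eta) and peak sharpness of one CFSD."""
    if len(gamma) == 0 or not np.any(gamma > 0):
        return np.nan, np.nan
    d_alpha = alphas[1] - alphas[0] if len(alphas) > 1 else 1.0
    in_band = (alphas >= hr_band[0]) & (alphas <= hr_band[1])
    cand = np.nonzero(in_band)[0] if np.any(in_band) else np.arange(len(gamma))
    eta_idx = cand[int(np.argmax(gamma[cand]))]
    integral = float(np.sum(gamma) * d_alpha)  # rectangle rule over (0, beta]
    d_eta = float(gamma[eta_idx]) / integral if integral > 0 else np.nan
    med = float(np.median(gamma))
    sharp = float(np.max(gamma)) / med if med > 0 else np.nan
    return d_eta, sharp


def cyclostationarity_features(
    recording: PcgRecording, subsequence_s: float = 3.0, beta: float = 10.0
) -> np.ndarray:
    """Mean/SD over subsequences of the cyclostationarity indicators.

    The recording is split into non-overlapping subsequences; for each, the
    cycle-frequency spectral density is estimated, its main peak in the
    physiological heart-rate band (0.5-2.5 Hz) located, and two indicators
    computed: the normalized peak density d(eta) and the peak sharpness
    max/median.  Strictly periodic beating yields large values of both.
    """
    fs = recording.sampling_rate
    sub_n = int(round(subsequence_s * fs))
    n_subs = len(recording.samples) // sub_n
    d_vals: list[float] = []
    s_vals: list[float] = []
    for k in range(n_subs):
        seg = recording.samples[k * sub_n : (k + 1) * sub_n]
        alphas, gamma = cycle_frequency_spectral_density(seg, fs, beta)
        d_eta, sharp = _cyclo_indicators(alphas, gamma)
        d_vals.append(d_eta)
        s_vals.append(sharp)
    m_d, sd_d = _mean_sd(d_vals)
    m_s, sd_s = _mean_sd(s_vals)
    return np.array([m_d, sd_d, m_s, sd_s])


# ---------------------------------------------------------------------------
# high-order statistics (16)
# ---------------------------------------------------------------------------


def hos_features(cardiac_cycles: list[CardiacCycle]) -> np.ndarray:
    """Per-state skewness (Fisher g1) and kurtosis (non-excess; Gaussian -> 3)."""
    out: list[float] = []
    for state in ("S1", "S2", "sys", "dia"):
        full = {"S1": "S1", "S2": "S2", "sys": "systole", "dia": "diastole"}[state]
        skews, kurts = [], []
        for c in cardiac_cycles:
            s = c.slice_of(full)
            if len(s) >= 4 and np.std(s) > 0:
                skews.append(float(stats.skew(s)))
                kurts.append(float(stats.kurtosis(s, fisher=False)))
        out += _mean_sd(skews)
        out += _mean_sd(kurts)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# entropy (16)
# ---------------------------------------------------------------------------


def _chebyshev_distances(x: np.ndarray, m: int, n_templates: int) -> np.ndarray:
    """Pairwise Chebyshev distances between the length-m templates of x.

    Uses the identity max_k |x[i+k]-x[j+k]| = running max of shifted
    difference matrices, avoiding the (n, n, m) intermediate.
    """
    diff = np.abs(x[:, None] - x[None, :])
    d = diff[:n_templates, :n_templates].copy()
    for k in range(1, m):
        np.maximum(d, diff[k : k + n_templates, k : k + n_templates], out=d)
    return d


def sample_entropy(sequence: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev template matching.

    *r* defaults to 0.2 times the sequence SD.  Template pairs are counted
    at length m (B) and m+1 (A) over the same template index range,
    excluding self-matches.  Returns NaN when no length-m or length-(m+1)
    pair matches (the statistic is undefined, not infinite).
    """
    x = np.asarray(sequence, dtype=np.float64)
    if len(x) <= m + 1:
        raise ValueError(f"sequence length {len(x)} too short for m={m}")
    if r is None:
        r = 0.2 * float(np.std(x))
    n_t = len(x) - m  # common template range for both lengths
    diff = np.abs(x[:, None] - x[None, :])
    d_m = diff[:n_t, :n_t].copy()
    for k in range(1, m):
        np.maximum(d_m, diff[k : k + n_t, k : k + n_t], out=d_m)
    d_m1 = np.maximum(d_m, diff[m : m + n_t, m : m + n_t])
    b = int((np.sum(d_m <= r) - n_t) // 2)
    a = int((np.sum(d_m1 <= r) - n_t) // 2)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def fuzzy_measure_entropy(
    sequence: np.ndarray,
    m: int = 2,
    r_local: float | None = None,
    r_global: float | None = None,
    n_fuzzy: float = 2.0,
) -> float:
    """Fuzzy measure entropy: local plus global fuzzy entropy.

    Hard template matching is replaced by the fuzzy membership
    exp(-(d/r)^n) of the Chebyshev distance d.  Local similarity compares
    segments with their own means removed; global similarity compares
    segments with the whole-sequence mean removed (a shared offset, so the
    global distances equal the raw template distances).  The returned
    value is the sum of the local and global fuzzy entropies.
    """
    x = np.asarray(sequence, dtype=np.float64)
    if len(x) <= m + 1:
        raise ValueError(f"sequence length {len(x)} too short for m={m}")
    sd = float(np.std(x))
    if r_local is None:
        r_local = 0.2 * sd
    if r_global is None:
        r_global = 0.2 * sd
    if r_local <= 0 or r_global <= 0:
        return np.nan
    n_t = len(x) - m

    def _phi_from_d(d: np.ndarray, r: float) -> float:
        sim = np.exp(-((d / r) ** n_fuzzy))
        total = float(np.sum(sim)) - float(np.trace(sim))
        return total / (d.shape[0] * (d.shape[0] - 1))

    def _local_d(length: int) -> np.ndarray:
        # segment means differ pairwise, so subtract the mean-difference
        # matrix from each shifted signed-difference layer
        mu = np.convolve(x, np.ones(length) / length, mode="valid")[:n_t]
        signed = x[:, None] - x[None, :]
        mu_diff = mu[:, None] - mu[None, :]
        d = np.abs(signed[:n_t, :n_t] - mu_diff)
        for k in range(1, length):
            np.maximum(d, np.abs(signed[k : k + n_t, k : k + n_t] - mu_diff), out=d)
        return d

    d_g_m = _chebyshev_distances(x, m, n_t)
    diff_m = np.abs(x[m : m + n_t, None] - x[None, m : m + n_t])
    d_g_m1 = np.maximum(d_g_m, diff_m)

    phi_l_m = _phi_from_d(_local_d(m), r_local)
    phi_l_m1 = _phi_from_d(_local_d(m + 1), r_local)
    phi_g_m = _phi_from_d(d_g_m, r_global)
    phi_g_m1 = _phi_from_d(d_g_m1, r_global)
    if min(phi_l_m, phi_l_m1, phi_g_m, phi_g_m1) <= 0:
        return np.nan
    return float(np.log(phi_l_m / phi_l_m1) + np.log(phi_g_m / phi_g_m1))


def entropy_features(
    cardiac_cycles: list[CardiacCycle],
    sampling_rate: float,
    entropy_rate: float = 1000.0,
    m: int = 2,
) -> np.ndarray:
    """Per-state per-cycle SampEn and FuzzyMEn statistics.

    State slices are downsampled to *entropy_rate* (default 1000 Hz) before
    the quadratic-cost entropy estimators run; tolerances are 0.2 times the
    downsampled slice SD.
    """
    factor = max(1, int(round(sampling_rate / entropy_rate)))
    per_state: dict[str, tuple[list[float], list[float]]] = {
        s: ([], []) for s in ("S1", "S2", "sys", "dia")
    }
    full = {"S1": "S1", "S2": "S2", "sys": "systole", "dia": "diastole"}
    for c in cardiac_cycles:
        for state in per_state:
            s = c.slice_of(full[state])
            if factor > 1:
                s = signal.resample_poly(s, 1, factor)
            if len(s) <= m + 1 or np.std(s) == 0:
                continue
            se = sample_entropy(s, m=m)
            fe = fuzzy_measure_entropy(s, m=m)
            if np.isfinite(se):
                per_state[state][0].append(se)
            if np.isfinite(fe):
                per_state[state][1].append(fe)
    out: list[float] = []
    for state in ("S1", "S2", "sys", "dia"):
        out += _mean_sd(per_state[state][0])
    for state in ("S1", "S2", "sys", "dia"):
        out += _mean_sd(per_state[state][1])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def extract_all(recording: PcgRecording, segmentation: StateSegmentation) -> FeatureVector:
    """Concatenate the nine domain extractors in canonical order (515 values)."""
    if not segmentation.intervals:
        raise ValueError("empty segmentation")
    ccs = cycles(segmentation, recording)
    fs = recording.sampling_rate
    parts = [
        time_interval_features(segmentation, fs),
        state_spectrum_features(recording, ccs),
        amplitude_features(ccs),
        np.concatenate([band_energy_features(recording), state_energy_features(ccs)]),
        record_spectrum_features(recording),
        cepstrum_features(recording, segmentation),
        cyclostationarity_features(recording),
        hos_features(ccs),
        entropy_features(ccs, fs),
    ]
    values = np.concatenate(parts)
    names = feature_names()
    domains = feature_domains()
    if len(values) != 515:
        raise AssertionError(f"feature vector has length {len(values)}, expected 515")
    return FeatureVector(names=names, values=values, domains=domains)


def extract_table(
    recordings: list[PcgRecording],
    segmentations: list[StateSegmentation],
) -> FeatureTable:
    """Extract features for a cohort into a FeatureTable (one row per record)."""
    if len(recordings) != len(segmentations):
        raise ValueError("one segmentation per recording required")
    rows = [extract_all(r, s).values for r, s in zip(recordings, segmentations)]
    return FeatureTable(
        record_ids=[r.record_id for r in recordings],
        feature_names=feature_names(),
        values=np.vstack(rows) if rows else np.empty((0, 515)),
        domains=feature_domains(),
    )
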