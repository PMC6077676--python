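"""Synthetic phonocardiogram generator with ground truth.

Every downstream stage (preprocessing, segmentation, feature extraction,
classification, scoring) is testable against recordings whose state
boundaries and class labels are known by construction.  A synthetic
recording is a quasi-periodic train of cardiac cycles:

* S1 and S2 are rendered as Hanning-windowed two-tone bursts in the
  low-frequency band where real heart sounds live (roughly 50-150 Hz);
* an optional murmur is band-limited Gaussian noise (default 150-600 Hz)
  confined to the systolic and/or diastolic interval, because pathological
  murmurs extend to far higher frequencies than normal sounds;
* cycle-to-cycle timing jitter is multiplicative Gaussian on the period,
  truncated so the three transient states always fit inside the cycle;
* a faint low-frequency ambient floor (sensor/room rumble below ~100 Hz)
  underlies every recording so no state is ever exactly silent;
* "noisy" recordings additionally receive broadband white noise and/or
  spikes.

The generator does not attempt hemodynamic realism; it reproduces exactly
the signal properties the feature set exploits (state timing, band-limited
transients, high-frequency murmur energy, cyclostationarity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io_prep import PcgRecording
from .segmentation import StateSegmentation

__all__ = ["SynthConfig", "SynthRecording", "generate_recording", "generate_dataset"]

#: a recording is labeled noisy (quality 0) when its additive-noise SNR is
#: below this threshold or spikes are injected
QUALITY_SNR_THRESHOLD_DB = 15.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.  The seed fully determines it."""

    sampling_rate: int = 2000  # Hz; Nyquist must exceed the 820 Hz feature band
    duration: float = 10.0  # s
    heart_rate_mean: float = 75.0  # bpm
    heart_rate_jitter: float = 0.03  # fractional SD of the cycle period
    s1_duration: float = 0.12  # s
    s2_duration: float = 0.09  # s
    systole_fraction: float = 0.30  # systolic interval as a fraction of the cycle
    murmur: str = "none"  # none | systolic | diastolic | both
    murmur_band: tuple[float, float] = (150.0, 600.0)  # Hz
    murmur_snr: float = 0.0  # dB of murmur RMS relative to S1 RMS
    ambient_snr: float = 30.0  # dB of signal over the low-frequency ambient floor
    noise_snr: float = math.inf  # dB of signal over broadband noise; inf = none
    spike_rate: float = 0.0  # events / s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.murmur not in ("none", "systolic", "diastolic", "both"):
            raise ValueError(f"unknown murmur type {self.murmur!r}")
        for name in ("duration", "s1_duration", "s2_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must be in (0, 1)")
        period = 60.0 / self.heart_rate_mean
        occupied = self.s1_duration + self.s2_duration + self.systole_fraction * period
        if occupied >= period:
            raise ValueError(
                f"S1 ({self.s1_duration}s) + systole "
                f"({self.systole_fraction * period:.3f}s) + S2 ({self.s2_duration}s) "
                f"do not fit in a {period:.3f}s cycle; reduce durations or heart rate"
            )

    @property
    def quality_label(self) -> int:
        noisy = self.noise_snr < QUALITY_SNR_THRESHOLD_DB or self.spike_rate > 0
        return 0 if noisy else 1

    @property
    def diagnosis_label(self) -> int:
        return 1 if self.murmur != "none" else -1


@dataclass
class SynthRecording:
    """A generated recording plus its ground truth."""

    recording: PcgRecording
    truth_segmentation: StateSegmentation
    diagnosis_label: int
    quality_label: int


def _tone_burst(n: int, fs: float, freqs: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Hanning-windowed sum of two tones with a random phase."""
    t = np.arange(n) / fs
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    burst = np.sin(2 * np.pi * freqs[0] * t + phase1) + 0.6 * np.sin(
        2 * np.pi * freqs[1] * t + phase2
    )
    return burst * np.hanning(n)


def _band_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x


def generate_recording(config: SynthConfig, record_id: str = "synth") -> SynthRecording:
    """Generate one recording with ground-truth boundaries and labels."""
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)
    n_total = int(round(config.duration * fs))
    x = np.zeros(n_total)

    base_period = 60.0 / config.heart_rate_mean
    s1_n = int(round(config.s1_duration * fs))
    s2_n = int(round(config.s2_duration * fs))
    min_period = (config.s1_duration + config.s2_duration) / (1 - config.systole_fraction) * 1.05

    intervals: list[tuple[str, int, int]] = []
    pos = 0
    s1_rms_acc: list[float] = []
    murmur_spans: list[tuple[int, int]] = []  # filled after amplitudes known

    while True:
        # multiplicative Gaussian jitter, truncated so states stay feasible
        period = base_period * (1.0 + config.heart_rate_jitter * rng.standard_normal())
        period = max(period, min_period)
        sys_n = int(round(config.systole_fraction * period * fs))
        cyc_n = int(round(period * fs))
        dia_n = cyc_n - s1_n - sys_n - s2_n
        if dia_n < 1:
            dia_n = 1
            cyc_n = s1_n + sys_n + s2_n + dia_n
        last = pos + cyc_n > n_total  # final cycle is truncated at the signal end

        s1 = _tone_burst(s1_n, fs, (70.0, 110.0), rng)
        s2 = 0.8 * _tone_burst(s2_n, fs, (90.0, 140.0), rng)
        s1_end = min(pos + s1_n, n_total)
        x[pos:s1_end] = s1[: s1_end - pos]
        s2_start = pos + s1_n + sys_n
        if s2_start < n_total:
            s2_end = min(s2_start + s2_n, n_total)
            x[s2_start:s2_end] = s2[: s2_end - s2_start]
        s1_rms_acc.append(float(np.sqrt(np.mean(s1**2))))

        bounds = [pos, pos + s1_n, pos + s1_n + sys_n, s2_start + s2_n, pos + cyc_n]
        for state, a, b in zip(("S1", "systole", "S2", "diastole"), bounds, bounds[1:]):
            a, b = min(a, n_total), min(b, n_total)
            if b > a:
                intervals.append((state, a, b))
        if config.murmur in ("systolic", "both") and min(bounds[2], n_total) > bounds[1]:
            murmur_spans.append((bounds[1], min(bounds[2], n_total)))
        if config.murmur in ("diastolic", "both") and min(bounds[4], n_total) > bounds[3]:
            murmur_spans.append((bounds[3], min(bounds[4], n_total)))
        pos += cyc_n
        if last or pos >= n_total:
            break

    truth = StateSegmentation(intervals)
    if truth.n_cycles < 1:
        raise ValueError(
            f"duration {config.duration}s cannot contain a single complete "
            f"{base_period:.2f}s cardiac cycle"
        )

    s1_rms = float(np.mean(s1_rms_acc))
    if config.murmur != "none":
        target_rms = s1_rms * 10.0 ** (config.murmur_snr / 20.0)
        for start, end in murmur_spans:
            noise = _band_noise(end - start, fs, config.murmur_band, rng)
            rms = np.sqrt(np.mean(noise**2))
            if rms > 0:
                seg = noise * (target_rms / rms)
                # brief edge taper only: heavier tapering would amplitude-
                # modulate the murmur and suppress its sample entropy
                seg *= signal.windows.tukey(end - start, alpha=0.1)
                x[start:end] += seg

    sig_rms = np.sqrt(np.mean(x**2))
    if math.isfinite(config.ambient_snr):
        # smooth rumble: low-pass filtered noise, so quiet states carry a
        # regular (low-entropy) floor rather than white noise
        sos = signal.butter(2, 80.0, btype="lowpass", fs=fs, output="sos")
        rumble = signal.sosfilt(sos, rng.standard_normal(n_total))
        rumble_rms = np.sqrt(np.mean(rumble**2))
        if rumble_rms > 0:
            x += rumble * (sig_rms * 10.0 ** (-config.ambient_snr / 20.0) / rumble_rms)

    if math.isfinite(config.noise_snr):
        noise_rms = sig_rms * 10.0 ** (-config.noise_snr / 20.0)
        x += noise_rms * rng.standard_normal(n_total)

    if config.spike_rate > 0:
        n_spikes = rng.poisson(config.spike_rate * config.duration)
        peak = np.max(np.abs(x)) if np.any(x) else 1.0
        for _ in range(n_spikes):
            center = int(rng.integers(0, n_total))
            width = int(rng.integers(3, 12))
            lo = max(0, center - width)
            hi = min(n_total, center + width)
            x[lo:hi] += 10.0 * peak * np.hanning(hi - lo) * rng.choice([-1.0, 1.0])

    rec = PcgRecording(
        record_id=record_id,
        samples=x,
        sampling_rate=fs,
        diagnosis=config.diagnosis_label,
        quality=config.quality_label,
    )
    return SynthRecording(
        recording=rec,
        truth_segmentation=truth,
        diagnosis_label=config.diagnosis_label,
        quality_label=config.quality_label,
    )


def derive_seed(master: int, index: int) -> int:
    """Deterministic per-item seed below 2**31 from a master seed."""
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    noisy_fraction: float,
    seed: int,
    base_config: SynthConfig | None = None,
    noisy_snr: float = 6.0,
    noisy_spike_rate: float = 0.5,
) -> list[SynthRecording]:
    """Generate a labeled cohort with exact class counts.

    ``round(noisy_fraction * n_total)`` recordings are made noisy (low SNR
    plus spikes), assigned deterministically across the cohort.  Per-record
    seeds derive from *seed*, so two calls with identical arguments yield
    identical datasets.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be non-negative")
    base = base_config if base_config is not None else SynthConfig()
    n_total = n_normal + n_abnormal
    if n_total == 0:
        return []
    n_noisy = int(round(noisy_fraction * n_total))
    order_rng = np.random.default_rng(derive_seed(seed, 0))
    noisy_idx = set(order_rng.choice(n_total, size=n_noisy, replace=False).tolist())

    out: list[SynthRecording] = []
    for i in range(n_total):
        murmur = base.murmur if base.murmur != "none" else "systolic"
        kwargs = dict(seed=derive_seed(seed, i + 1))
        if i < n_normal:
            kwargs["murmur"] = "none"
        else:
            kwargs["murmur"] = murmur
        if i in noisy_idx:
            kwargs["noise_snr"] = noisy_snr
            kwargs["spike_rate"] = noisy_spike_rate
        else:
            kwargs["noise_snr"] = base.noise_snr
            kwargs["spike_rate"] = 0.0
        cfg = replace(base, **kwargs)
        out.append(generate_recording(cfg, record_id=f"synth_{i:04d}"))
    return out
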