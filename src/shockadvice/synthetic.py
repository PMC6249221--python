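"""Synthetic single-channel ECG with the spectral structure the SAA assumes.

The generator is the test bed for the whole pipeline: non-shockable (NSH)
segments are QRS-complex trains whose magnitude-spectrum maximum falls in the
4-20 Hz band, shockable (SH) segments are VF-like oscillations whose spectral
maximum sits near 4 Hz with negligible power above 10 Hz, or VT-like
monomorphic wide-complex trains at >= 150 beats/min.  These are exactly the
spectral contracts the MVMD channel construction exploits, so a pipeline that
works here is exercising the same separation mechanism it would use on real
rhythms — not their physiology.

Waveform models (deliberately simple):

* QRS complex: Mexican-hat wavelet, ~80 ms main lobe, 1 mV peak-to-peak, with
  small Gaussian P/T bumps; beat-to-beat interval jittered a few percent.
* VF: a sinusoid whose instantaneous frequency follows an Ornstein-Uhlenbeck
  walk around the dominant frequency (default 4 Hz) with slow amplitude
  modulation, ~0.5 mV peak-to-peak.
* VT: an exactly periodic biphasic wide-complex train (default 180 beats/min).

All amplitudes are in millivolts and sit above the 200 uV exclusion floor
unless the caller lowers them on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .records import EcgRecord, NSH, RhythmAnnotation, Segment, SH

__all__ = [
    "SynthParams",
    "gen_nsh_segment",
    "gen_sh_segment",
    "gen_record_set",
]


@dataclass
class SynthParams:
    """Generator settings; defaults match the study conditions (250 Hz, 8 s)."""

    fs: float = 250.0
    seg_len_s: float = 8.0
    nsh_rate_bpm: float = 75.0
    sh_center_hz: float = 4.0
    sh_kind: str = "vf"            # "vf" or "vt"
    vt_rate_bpm: float = 180.0
    qrs_amp_mv: float = 1.0        # NSH QRS peak-to-peak
    vf_amp_mv: float = 0.5         # VF peak-to-peak
    noise_sd: float = 0.02         # additive Gaussian noise (mV)
    wander_amp: float = 0.05       # baseline wander amplitude (mV)
    wander_freq: float = 0.3       # baseline wander frequency (< 1 Hz)
    rr_jitter: float = 0.03        # RR-interval jitter, fraction of RR
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.fs * self.seg_len_s
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"fs*seg_len_s must be a positive integer number of samples, got {n}"
            )
        if not 2.0 < self.sh_center_hz < 8.0:
            raise ValueError(f"sh_center_hz must lie in (2, 8), got {self.sh_center_hz}")
        if self.nsh_rate_bpm < 40:
            raise ValueError(f"nsh_rate_bpm must be >= 40, got {self.nsh_rate_bpm}")
        if self.sh_kind not in ("vf", "vt"):
            raise ValueError(f"sh_kind must be 'vf' or 'vt', got {self.sh_kind!r}")
        if not 0.0 <= self.wander_freq < 1.0:
            raise ValueError("baseline wander frequency must be below 1 Hz")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.seg_len_s))


def _mexican_hat(t: np.ndarray, width: float) -> np.ndarray:
    """Mexican-hat (Ricker) wavelet; spectral peak at sqrt(2)/(2*pi*width) Hz."""
    z = (t / width) ** 2
    return (1.0 - z) * np.exp(-z / 2.0)


def _gauss(t: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (t / sigma) ** 2)


def _time_axis(params: SynthParams) -> np.ndarray:
    return np.arange(params.n_samples) / params.fs


def _background(t: np.ndarray, params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Baseline wander plus broadband sensor noise."""
    out = np.zeros_like(t)
    if params.wander_amp > 0 and params.wander_freq > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out += params.wander_amp * np.sin(2 * np.pi * params.wander_freq * t + phase)
    if params.noise_sd > 0:
        out += rng.normal(0.0, params.noise_sd, size=t.shape)
    return out


def _beat_times(duration: float, rate_bpm: float, jitter: float,
                rng: np.random.Generator) -> np.ndarray:
    """Beat centers at (k + 1/2) * RR, jittered, clipped inside the window.

    Placing the first beat half an interval in keeps floor(duration * rate)
    beats fully inside the window, so the clean-signal beat count is exact.
    """
    rr = 60.0 / rate_bpm
    n_beats = int(np.floor(duration / rr))
    centers = (np.arange(n_beats) + 0.5) * rr
    if jitter > 0:
        centers = centers + rng.normal(0.0, jitter * rr, size=n_beats)
        centers = np.clip(centers, 0.3 * rr, duration - 0.3 * rr)
    return centers


def _wave_train(t: np.ndarray, centers: np.ndarray, wave, half_support: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c in centers:
        lo = np.searchsorted(t, c - half_support)
        hi = np.searchsorted(t, c + half_support)
        out[lo:hi] += wave(t[lo:hi] - c)
    return out


def gen_nsh_segment(params: SynthParams, rng: np.random.Generator | None = None) -> Segment:
    """One non-shockable segment: a QRS train with P/T bumps, wander and noise.

    The QRS wavelet width (~20 ms scale parameter) puts the train's spectral
    maximum near 11 Hz, inside the 4-20 Hz band characteristic of QRS
    complexes.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = _time_axis(params)
    beats = _beat_times(params.seg_len_s, params.nsh_rate_bpm, params.rr_jitter, rng)

    qrs_w = 0.02  # s; main lobe ~80 ms, spectral peak ~11 Hz
    amp = params.qrs_amp_mv / (1.0 + 2.0 * np.exp(-1.5))  # peak-to-peak -> peak scale
    x = _wave_train(t, beats, lambda u: amp * _mexican_hat(u, qrs_w), 6 * qrs_w)
    # low, broad P and T bumps around each QRS
    x += _wave_train(t, beats - 0.16, lambda u: 0.08 * _gauss(u, 0.025), 0.1)
    x += _wave_train(t, beats + 0.30, lambda u: 0.12 * _gauss(u, 0.05), 0.2)
    x += _background(t, params, rng)
    return Segment(record_id="synth", start=0, samples=x, label=NSH, rhythm="N")


def gen_sh_segment(params: SynthParams, rng: np.random.Generator | None = None) -> Segment:
    """One shockable segment: VF-like oscillation or VT-like wide-complex train."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = _time_axis(params)
    if params.sh_kind == "vf":
        x = _vf_waveform(t, params, rng)
        rhythm = "VF"
    else:
        x = _vt_waveform(t, params, rng)
        rhythm = "VT"
    x += _background(t, params, rng)
    return Segment(record_id="synth", start=0, samples=x, label=SH, rhythm=rhythm)


def _vf_waveform(t: np.ndarray, params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """FM sinusoid: instantaneous frequency is an OU walk around sh_center_hz."""
    dt = 1.0 / params.fs
    theta, sigma = 2.0, 1.0          # mean-reversion rate (1/s), diffusion (Hz/sqrt(s))
    n = t.size
    f = np.empty(n)
    f[0] = params.sh_center_hz
    shocks = rng.normal(0.0, sigma * np.sqrt(dt), size=n - 1)
    for i in range(1, n):
        f[i] = f[i - 1] + theta * (params.sh_center_hz - f[i - 1]) * dt + shocks[i - 1]
    f = np.clip(f, 2.0, 8.0)
    phase = 2 * np.pi * np.cumsum(f) * dt + rng.uniform(0, 2 * np.pi)
    am = 1.0 + 0.25 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    return 0.5 * params.vf_amp_mv * am * np.sin(phase)


def _vt_waveform(t: np.ndarray, params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Exactly periodic biphasic wide-complex train (monomorphic VT)."""
    rr = 60.0 / params.vt_rate_bpm
    n_beats = int(np.floor(params.seg_len_s / rr))
    centers = (np.arange(n_beats) + 0.5) * rr
    w = 0.05  # s; total complex ~0.2 s (wide)

    def wave(u: np.ndarray) -> np.ndarray:
        # Gaussian first derivative: biphasic, zero mean
        return -0.8 * (u / w) * np.exp(0.5 - 0.5 * (u / w) ** 2)

    return _wave_train(t, centers, wave, 5 * w)


def gen_record_set(
    n_records: int,
    segs_per_record: int,
    sh_fraction: float,
    params: SynthParams | None = None,
) -> list[EcgRecord]:
    """A multi-patient dataset: each record concatenates labeled segments.

    Each record gets exactly ``round(segs_per_record * sh_fraction)`` shockable
    segments at seeded-random positions, with a rhythm annotation at every
    segment onset, mirroring the record-per-patient structure of the public
    arrhythmia databases.
    """
    if params is None:
        params = SynthParams()
    if n_records < 2:
        raise ValueError("need at least 2 records for record-wise workflows")
    if not 0.0 <= sh_fraction <= 1.0:
        raise ValueError(f"sh_fraction must be in [0, 1], got {sh_fraction}")

    ss = np.random.SeedSequence(params.seed if params.seed is not None else 0)
    record_seeds = ss.spawn(n_records)
    n_sh = int(round(segs_per_record * sh_fraction))
    seg_n = params.n_samples
    records = []
    for r, rseed in enumerate(record_seeds):
        rng = np.random.default_rng(rseed)
        labels = np.zeros(segs_per_record, dtype=int)
        labels[rng.permutation(segs_per_record)[:n_sh]] = SH
        samples = np.empty(segs_per_record * seg_n)
        annotations = []
        for i, lab in enumerate(labels):
            seg = (gen_sh_segment if lab == SH else gen_nsh_segment)(params, rng)
            samples[i * seg_n:(i + 1) * seg_n] = seg.samples
            annotations.append(RhythmAnnotation(onset=i * seg_n, label=seg.rhythm))
        records.append(
            EcgRecord(
                record_id=f"synth-{r:03d}",
                samples=samples,
                fs=params.fs,
                annotations=annotations,
            )
        )
    return records
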