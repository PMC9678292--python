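"""Synthetic compound-electrode sessions with known ground truth.

The generator follows the two-channel signal model of the compound
electrode: the inner channel carries signal plus noise,

    d~[n] = b[n] + m[n] + c[n],        r[n] = b[n] + m[n],

where b is background EEG, m is muscle (EMG) activity and c the evoked
signal of interest; the outer ring carries a filtered copy of the noise
plus a small crosstalk fraction of the signal,

    x~[n] = h * (r[n] + alpha * c[n]),     0 <= alpha << 1.

Two canonical sessions mirror the experimental protocol: a jaw-clench
session (500 Hz, 2 min, an EMG burst every 15 s) used to measure band
noise power, and an oddball session (250 Hz, 5 min, a P300-like bump
0.3-0.5 s after each rare stimulus, gaps uniform on 7-13 s) used to
measure evoked signal power.  All components are band-limited below the
Nyquist frequency, standing in for the acquisition hardware's anti-alias
roll-off.  An optional white sensor-noise term (off by default, so the
decomposition d~ = b + m + c holds exactly) models ADC/thermal noise that
is uncorrelated between the channels and that no reference-based canceller
can remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sig

from .signal_io import Recording


@dataclass
class SyntheticSpec:
    """All generator parameters for one synthetic session.

    Amplitudes are volts; the defaults put the inner-channel SNR in the
    range observed for real jaw-clench sessions (roughly -20 to -5 dB).
    """

    fs: float = 500.0
    duration_s: float = 120.0
    eeg_band: Tuple[float, float] = (0.5, 30.0)
    eeg_rms: float = 10e-6
    emg_band: Optional[Tuple[float, float]] = None  # default (20, min(125, 0.475 fs))
    emg_tonic_rms: float = 5e-6
    emg_burst_rms: float = 50e-6
    burst_period_s: float = 15.0
    burst_duration_s: float = 2.0
    oddball_gap_s: Tuple[float, float] = (7.0, 13.0)
    p300_amp: float = 10e-6
    p300_center_s: float = 0.4
    p300_width_s: float = 0.2
    alpha: float = 0.1
    h_cutoff: float = 100.0           # first-order low-pass of the reference path
    sensor_noise_rms: float = 0.0     # optional uncorrelated per-channel ADC noise
    events_from: str = "oddball"      # which schedule Recording.events carries
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.emg_band is None:
            self.emg_band = (20.0, min(125.0, 0.475 * self.fs))
        for lo, hi in (self.eeg_band, self.emg_band):
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError("component bands must lie within (0, fs/2)")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        for v in (self.eeg_rms, self.emg_tonic_rms, self.emg_burst_rms,
                  self.p300_amp, self.sensor_noise_rms):
            if v < 0:
                raise ValueError("amplitudes must be non-negative")
        if self.events_from not in ("oddball", "burst"):
            raise ValueError("events_from must be 'oddball' or 'burst'")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class GroundTruth:
    """Component streams underlying a synthetic recording."""

    b: np.ndarray                       # background EEG
    m: np.ndarray                       # EMG (tonic + bursts)
    c: np.ndarray                       # evoked signal
    r: np.ndarray                       # total noise b + m
    oddball_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    burst_times: np.ndarray = field(default_factory=lambda: np.empty(0))


def _band_noise(n: int, band: Tuple[float, float], fs: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise normalised to the requested RMS.

    Band-limiting is done by zeroing Fourier bins outside ``band``, so the
    realised spectrum is exactly confined (no filter skirts) and the
    per-seed draw count is independent of the band.
    """
    w = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    spectrum = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spectrum[(freqs < band[0]) | (freqs > band[1])] = 0.0
    v = np.fft.irfft(spectrum, n)
    realised = np.sqrt(np.mean(v**2))
    return v * (rms / realised)


def gen_background_eeg(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Background EEG b[n]: Gaussian noise in ``eeg_band`` at ``eeg_rms``."""
    return _band_noise(spec.n_samples, spec.eeg_band, spec.fs, spec.eeg_rms, rng)


def burst_schedule(spec: SyntheticSpec) -> np.ndarray:
    """Burst centre times: one burst per period, centred mid-period."""
    n_bursts = int(np.floor(spec.duration_s / spec.burst_period_s))
    return (np.arange(n_bursts) + 0.5) * spec.burst_period_s


def gen_emg(spec: SyntheticSpec, rng: np.random.Generator):
    """EMG m[n]: band-limited noise with a smooth burst envelope.

    A single carrier noise stream is amplitude-modulated so that the
    instantaneous RMS is ``emg_tonic_rms`` between bursts and rises to
    ``emg_burst_rms`` at each burst peak (Hann-shaped envelope of
    ``burst_duration_s``); equal tonic and burst RMS therefore yield
    constant power.  Returns (m, burst_onset_times).
    """
    n = spec.n_samples
    centres = burst_schedule(spec)
    t = np.arange(n) / spec.fs
    env2 = np.zeros(n)  # squared burst envelope
    half = spec.burst_duration_s / 2.0
    for tc in centres:
        mask = np.abs(t - tc) <= half
        if spec.burst_duration_s > 0:
            hann = 0.5 * (1.0 + np.cos(np.pi * (t[mask] - tc) / half))
            env2[mask] = np.maximum(env2[mask], hann**2)
    if spec.emg_tonic_rms == 0 and spec.emg_burst_rms == 0:
        return np.zeros(n), centres - half
    carrier = _band_noise(n, spec.emg_band, spec.fs, 1.0, rng)
    amp = np.sqrt(spec.emg_tonic_rms**2
                  + env2 * (spec.emg_burst_rms**2 - spec.emg_tonic_rms**2))
    return carrier * amp, centres - half


def p300_template(spec: SyntheticSpec) -> np.ndarray:
    """Raised-cosine bump sampled at fs: amplitude p300_amp, full width p300_width_s."""
    half = spec.p300_width_s / 2.0
    n_half = int(round(half * spec.fs))
    k = np.arange(-n_half, n_half + 1)
    return spec.p300_amp * 0.5 * (1.0 + np.cos(np.pi * k / n_half))


def gen_evoked(spec: SyntheticSpec, rng: np.random.Generator):
    """Evoked stream c[n] and oddball times (gaps uniform on oddball_gap_s).

    Each oddball adds one raised-cosine bump centred ``p300_center_s``
    after the event.  Events are scheduled so every bump lies fully inside
    the stream.  Times are returned even when ``p300_amp`` is zero.
    """
    n = spec.n_samples
    lo, hi = spec.oddball_gap_s
    margin = spec.p300_center_s + spec.p300_width_s / 2.0
    times = []
    t = float(rng.uniform(lo, hi))
    while t + margin < spec.duration_s:
        times.append(t)
        t += float(rng.uniform(lo, hi))
    times = np.asarray(times)
    c = np.zeros(n)
    if spec.p300_amp > 0 and times.size:
        tmpl = p300_template(spec)
        n_half = (tmpl.size - 1) // 2
        for te in times:
            i0 = int(round((te + spec.p300_center_s) * spec.fs))
            c[i0 - n_half: i0 + n_half + 1] += tmpl
    return c, times


def synthesize_recording(spec: SyntheticSpec):
    """Generate one session: Recording plus full GroundTruth.

    The same seed always yields bitwise-identical output.  The reference
    path h is a causal first-order low-pass at ``h_cutoff`` Hz.
    """
    rng = np.random.default_rng(spec.seed)
    b = gen_background_eeg(spec, rng)
    m, burst_onsets = gen_emg(spec, rng)
    c, oddball_times = gen_evoked(spec, rng)
    r = b + m
    inner = r + c
    ref = r + spec.alpha * c
    if spec.h_cutoff and 0 < spec.h_cutoff < spec.fs / 2:
        bh, ah = sig.butter(1, spec.h_cutoff, btype="lowpass", fs=spec.fs)
        outer = sig.lfilter(bh, ah, ref)
    else:  # h = identity
        outer = ref.copy()
    if spec.sensor_noise_rms > 0:
        inner = inner + spec.sensor_noise_rms * rng.standard_normal(inner.size)
        outer = outer + spec.sensor_noise_rms * rng.standard_normal(outer.size)
    events = oddball_times if spec.events_from == "oddball" else burst_onsets
    rec = Recording(inner, outer, fs=spec.fs, events=events, label=spec.label)
    truth = GroundTruth(b=b, m=m, c=c, r=r, oddball_times=oddball_times,
                        burst_times=burst_onsets)
    return rec, truth


def session1_spec(seed: int = 0) -> SyntheticSpec:
    """Jaw-clench EMG session: 500 Hz, 2 min, a burst every 15 s, no oddballs."""
    return SyntheticSpec(fs=500.0, duration_s=120.0, p300_amp=0.0,
                         events_from="burst", seed=seed, label="session1")


def session2_spec(seed: int = 0) -> SyntheticSpec:
    """P300 oddball session: 250 Hz, 5 min, tonic EMG only, oddballs every 7-13 s."""
    return SyntheticSpec(fs=250.0, duration_s=300.0, emg_burst_rms=0.0,
                         events_from="oddball", seed=seed, label="session2")


def synthetic_subject(seed: int):
    """One synthetic 'subject': (noise_session, truth1, p300_session, truth2).

    Independent sub-seeds for the two sessions are derived from ``seed``.
    """
    s1, s2 = np.random.SeedSequence(seed).generate_state(2)
    rec1, truth1 = synthesize_recording(session1_spec(int(s1 % 2**31)))
    rec2, truth2 = synthesize_recording(session2_spec(int(s2 % 2**31)))
    return rec1, truth1, rec2, truth2
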