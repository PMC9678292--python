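"""Causal signal conditioning for the two electrode channels.

The raw inner and outer channels are conditioned before they reach any
adaptive filter: a 2nd-order Butterworth band-stop removes 50 Hz mains
interference, a 2nd-order Butterworth high-pass removes DC/drift (0.5 Hz
for the inner channel, 5 Hz for the noise-reference channel so that it
carries the EMG spectrum and not EOG/baseline wander), and a dimensionless
gain ``gamma`` scales physiological microvolt amplitudes into the working
range of a tanh network (roughly +/-0.2 for typical jaw-clench EMG).

Everything here is strictly causal and operates either sample-by-sample
(for real-time use) or on whole arrays (mathematically identical, via the
filters' carried internal state).
"""

from __future__ import annotations

import numpy as np
from scipy import signal


class FilterCoefficients:
    """A causal rational (IIR) filter with carried internal state.

    Parameters
    ----------
    b, a : array-like
        Numerator / denominator coefficients. ``a[0]`` must be 1 after
        normalisation; all poles must lie strictly inside the unit circle.
    """

    def __init__(self, b, a):
        b = np.atleast_1d(np.asarray(b, dtype=float))
        a = np.atleast_1d(np.asarray(a, dtype=float))
        if a[0] == 0:
            raise ValueError("leading denominator coefficient must be nonzero")
        b = b / a[0]
        a = a / a[0]
        if a.size > 1:
            poles = np.roots(a)
            if poles.size and np.max(np.abs(poles)) >= 1.0:
                raise ValueError("unstable filter: pole on or outside the unit circle")
        self.b = b
        self.a = a
        self.reset()

    def reset(self) -> None:
        """Zero the delay memory (deterministic startup)."""
        self.state = np.zeros(max(self.b.size, self.a.size) - 1)

    def process(self, sample: float) -> float:
        """Filter one sample, advancing the internal state."""
        if not np.isfinite(sample):
            raise ValueError("non-finite input sample")
        out, self.state = signal.lfilter(self.b, self.a, [float(sample)], zi=self.state)
        return float(out[0])

    def process_block(self, samples) -> np.ndarray:
        """Filter a whole array; identical to repeated :meth:`process`."""
        x = np.asarray(samples, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input samples")
        out, self.state = signal.lfilter(self.b, self.a, x, zi=self.state)
        return out

    def frequency_response(self, freqs, fs: float) -> np.ndarray:
        """Complex response at ``freqs`` (Hz) for sampling rate ``fs``."""
        _, h = signal.freqz(self.b, self.a, worN=np.atleast_1d(freqs), fs=fs)
        return h


def filter_sample(coefs: FilterCoefficients, sample: float) -> float:
    """Functional alias for :meth:`FilterCoefficients.process`."""
    return coefs.process(sample)


def design_highpass(order: int, fc: float, fs: float) -> FilterCoefficients:
    """Butterworth high-pass (-3 dB at ``fc``), default realisation of HP_fc."""
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0 < fc < fs / 2:
        raise ValueError(f"cutoff {fc} Hz must lie in (0, fs/2) = (0, {fs / 2})")
    b, a = signal.butter(order, fc, btype="highpass", fs=fs)
    return FilterCoefficients(b, a)


def design_notch50(fs: float, half_width: float = 2.5) -> FilterCoefficients:
    """2nd-order Butterworth band-stop around 50 Hz mains.

    The stopband is ``50 +/- half_width`` Hz; attenuation at exactly 50 Hz is
    essentially complete (the band-stop places transmission zeros there).
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if 50.0 + half_width >= fs / 2:
        raise ValueError("notch stopband must lie below the Nyquist frequency")
    b, a = signal.butter(2, [50.0 - half_width, 50.0 + half_width], btype="bandstop", fs=fs)
    return FilterCoefficients(b, a)


class Conditioner:
    """Notch -> high-pass -> gain chain with carried state.

    The two linear stages commute in exact arithmetic; the order is fixed
    (notch first) for bit-reproducibility.
    """

    def __init__(self, fc: float, fs: float, gain: float, notch_half_width: float = 2.5):
        if gain <= 0:
            raise ValueError("gain must be positive")
        self.notch = design_notch50(fs, notch_half_width)
        self.highpass = design_highpass(2, fc, fs)
        self.gain = float(gain)

    def process(self, sample: float) -> float:
        return self.gain * self.highpass.process(self.notch.process(sample))

    def process_block(self, samples) -> np.ndarray:
        return self.gain * self.highpass.process_block(self.notch.process_block(samples))


def condition_channel(raw, fc: float, fs: float, gain: float,
                      notch_half_width: float = 2.5) -> np.ndarray:
    """Condition a whole raw channel: 50 Hz notch, high-pass at ``fc``, gain."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty stream")
    return Conditioner(fc, fs, gain, notch_half_width).process_block(raw)


def delay_stream(stream, n: int) -> np.ndarray:
    """Delay by ``n`` samples, zero-padded at the start; length preserved."""
    if n < 0:
        raise ValueError("delay must be non-negative")
    stream = np.asarray(stream, dtype=float)
    if n == 0:
        return stream.copy()
    out = np.zeros_like(stream)
    out[n:] = stream[: stream.size - n]
    return out


class StreamDelay:
    """Sample-by-sample delay with carried buffer (streaming delay_stream)."""

    def __init__(self, n: int):
        if n < 0:
            raise ValueError("delay must be non-negative")
        self.n = int(n)
        self.buf = np.zeros(self.n)

    def process_block(self, samples) -> np.ndarray:
        x = np.asarray(samples, dtype=float)
        if self.n == 0:
            return x.copy()
        joined = np.concatenate([self.buf, x])
        self.buf = joined[joined.size - self.n:].copy()
        return joined[: x.size]


class DelayLine:
    """Fixed-length tapped delay line, newest sample first."""

    def __init__(self, ntaps: int):
        if ntaps < 1:
            raise ValueError("ntaps must be >= 1")
        self.ntaps = int(ntaps)
        self.buffer = np.zeros(self.ntaps)

    def push(self, sample: float) -> np.ndarray:
        """Insert ``sample`` and return the tap vector (x[n], ..., x[n-ntaps+1])."""
        self.buffer[1:] = self.buffer[:-1]
        self.buffer[0] = sample
        return self.buffer.copy()


def push_tap(line: DelayLine, sample: float) -> np.ndarray:
    """Functional alias for :meth:`DelayLine.push`."""
    return line.push(sample)
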