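"""Comparison filters: LMS-tuned adaptive FIR and the surface-Laplacian subtraction.

The LMS filter shares the DNF's geometry exactly — same conditioning, same
tap count over the reference channel, same floor(ntaps/2) compensation
delay of the inner channel — so that any performance difference is due to
the filter itself.  The Laplace operator is the hard-wired alternative:
subtract the raw outer-ring channel from the raw inner channel and clean up
(DC and 50 Hz removal) afterwards.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _kernel
from .dnf_core import DNFResult
from .preprocessing import Conditioner, DelayLine, StreamDelay, condition_channel
from .signal_io import Recording, RunConfig


class LMSState:
    """Adaptive FIR state: weight vector, step size, tapped delay line.

    Weights start at zero (standard LMS initialisation).
    """

    def __init__(self, ntaps: int, mu: float):
        if ntaps < 1:
            raise ValueError("ntaps must be >= 1")
        self.ntaps = int(ntaps)
        self.mu = float(mu)
        self.weights = np.zeros(self.ntaps)
        self.line = DelayLine(self.ntaps)


def lms_step(state: LMSState, d_delayed: float, x: float) -> float:
    """One LMS sample: y = w.taps, e = d - y, w += mu * taps * e."""
    if not (np.isfinite(d_delayed) and np.isfinite(x)):
        raise ValueError("non-finite input sample")
    taps = state.line.push(x)
    y = float(state.weights @ taps)
    e = float(d_delayed) - y
    state.weights += state.mu * taps * e
    return e


class LMSFilter(BaseEstimator, TransformerMixin):
    """Adaptive FIR noise canceller tuned by least-mean-squares.

    Same two-column input contract and conditioning chain as
    :class:`~dnfilter.dnf_core.DeepNeuralFilter`.  The default step size
    ``mu`` is matched to the DNF's learning rate (for a linear single-layer
    network the two update rules coincide), rather than normalised by the
    reference power.
    """

    def __init__(self, fs: float = 500.0, ntaps: int = 50, mu: float = 2.5,
                 fcd: float = 0.5, fcx: float = 5.0, gain: float = 1000.0,
                 notch_half_width: float = 2.5):
        self.fs = fs
        self.ntaps = ntaps
        self.mu = mu
        self.fcd = fcd
        self.fcx = fcx
        self.gain = gain
        self.notch_half_width = notch_half_width

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be a (n_samples, 2) array [inner, outer]")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _init_state(self) -> None:
        self.weights_ = np.zeros(self.ntaps)
        self._taps = np.zeros(self.ntaps)
        self.delay_ = self.ntaps // 2
        self._cond_d = Conditioner(self.fcd, self.fs, self.gain, self.notch_half_width)
        self._cond_x = Conditioner(self.fcx, self.fs, self.gain, self.notch_half_width)
        self._delay_d = StreamDelay(self.delay_)
        self.n_features_in_ = 2

    def _process(self, X) -> DNFResult:
        X = self._validate(X)
        d = self._delay_d.process_block(self._cond_d.process_block(X[:, 0]))
        x = self._cond_x.process_block(X[:, 1])
        e, y, self._taps = _kernel.lms_loop(d, x, self.weights_, float(self.mu),
                                            self._taps)
        wdist = np.linalg.norm(self.weights_)  # distance from the zero init
        return DNFResult(e=e, y=y, weight_distance=np.array([[wdist]]),
                         config=self.get_params())

    def fit(self, X, y=None):
        self._init_state()
        result = self._process(X)
        self.output_ = result.e
        self.remover_ = result.y
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("LMSFilter must be fitted before transform")
        return self._process(X).e[:, None]

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).output_[:, None]


class LaplacianFilter(BaseEstimator, TransformerMixin):
    """Hard-wired surface Laplacian: raw inner minus raw outer.

    DC (0.5 Hz high-pass) and 50 Hz are removed *after* the subtraction and
    the conditioning gain is applied last so the output lives on the same
    scale as the adaptive variants.  Being a fixed LTI operation it needs
    no fitting; it also removes any signal component shared between the
    electrodes, evoked potentials included.
    """

    def __init__(self, fs: float = 500.0, fc: float = 0.5, gain: float = 1000.0,
                 notch_half_width: float = 2.5):
        self.fs = fs
        self.fc = fc
        self.gain = gain
        self.notch_half_width = notch_half_width

    def fit(self, X, y=None):
        self.n_features_in_ = 2
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be a (n_samples, 2) array [inner, outer]")
        s = X[:, 0] - X[:, 1]
        out = condition_channel(s, self.fc, self.fs, self.gain,
                                self.notch_half_width)
        return out[:, None]

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X).transform(X)


def run_lms(recording: Recording, config: RunConfig) -> DNFResult:
    """LMS baseline with identical conditioning and delay as the DNF."""
    if config.variant != "lms":
        raise ValueError("run_lms requires config.variant == 'lms'")
    mu = config.eta if config.mu is None else config.mu
    est = LMSFilter(fs=recording.fs, ntaps=config.ntaps, mu=mu,
                    fcd=config.fcd, fcx=config.fcx, gain=config.gain,
                    notch_half_width=config.notch_half_width)
    est.fit(recording.as_array())
    return DNFResult(e=est.output_, y=est.remover_,
                     weight_distance=np.array([[np.linalg.norm(est.weights_)]]),
                     config=config.to_dict())


def run_laplace(recording: Recording, config: Optional[RunConfig] = None) -> np.ndarray:
    """Laplace operator on the raw channels, cleaned up after subtraction."""
    config = config or RunConfig(variant="laplace")
    est = LaplacianFilter(fs=recording.fs, fc=config.fcd, gain=config.gain,
                          notch_half_width=config.notch_half_width)
    return est.fit_transform(recording.as_array())[:, 0]
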