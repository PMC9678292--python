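"""Jitted per-sample loops for the adaptive filters.

The funnel network is tiny (a few thousand weights), so per-sample Python
overhead, not arithmetic, dominates; the loops are compiled with numba when
available and fall back to plain Python otherwise.  The padded-array layout
used here is cross-checked in the test suite against the plain-numpy
reference implementation in :mod:`dnfilter.dnf_core`.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


def pack_weights(weights):
    """Pack a list of per-layer matrices into a padded (L, nmax, nmax) array."""
    nmax = max(max(w.shape) for w in weights)
    packed = np.zeros((len(weights), nmax, nmax))
    for l, w in enumerate(weights):
        packed[l, : w.shape[0], : w.shape[1]] = w
    return packed


def unpack_weights(packed, sizes_ext):
    """Inverse of :func:`pack_weights`; ``sizes_ext[0]`` is the input width."""
    return [
        packed[l, : sizes_ext[l + 1], : sizes_ext[l]].copy()
        for l in range(len(sizes_ext) - 1)
    ]


@njit(cache=False)
def dnf_loop(d, x, w, sizes, eta, out_deriv, log_every, taps_init):
    """Always-on adaptive loop: forward pass, e = d - y, backprop, update.

    ``sizes`` is the extended size vector (n_inputs, I1, .., IL); ``w`` the
    padded weight array, updated in place.  ``taps_init`` carries the delay
    line across calls (newest first).  Weight distance from the entry
    weights is logged every ``log_every`` samples, before that sample's
    update, so the trace starts at the caller's reference point.
    """
    n_layers = sizes.shape[0] - 1
    n_samples = d.shape[0]
    nmax = w.shape[1]
    ntaps = sizes[0]
    acts = np.zeros((n_layers + 1, nmax))
    for k in range(ntaps):
        acts[0, k] = taps_init[k]
    delta = np.zeros((n_layers, nmax))
    w0 = w.copy()
    e_out = np.empty(n_samples)
    y_out = np.empty(n_samples)
    n_log = (n_samples + log_every - 1) // log_every
    wdist = np.zeros((n_log, n_layers))
    for n in range(n_samples):
        if n % log_every == 0:
            r = n // log_every
            for l in range(n_layers):
                s = 0.0
                for j in range(sizes[l + 1]):
                    for i in range(sizes[l]):
                        dv = w[l, j, i] - w0[l, j, i]
                        s += dv * dv
                wdist[r, l] = math.sqrt(s)
        for k in range(ntaps - 1, 0, -1):
            acts[0, k] = acts[0, k - 1]
        acts[0, 0] = x[n]
        for l in range(n_layers):
            for j in range(sizes[l + 1]):
                s = 0.0
                for i in range(sizes[l]):
                    s += w[l, j, i] * acts[l, i]
                acts[l + 1, j] = math.tanh(s)
        y = acts[n_layers, 0]
        e = d[n] - y
        e_out[n] = e
        y_out[n] = y
        if out_deriv:
            delta[n_layers - 1, 0] = e * (1.0 - y * y)
        else:
            delta[n_layers - 1, 0] = e
        for l in range(n_layers - 2, -1, -1):
            for j in range(sizes[l + 1]):
                s = 0.0
                for k2 in range(sizes[l + 2]):
                    s += w[l + 1, k2, j] * delta[l + 1, k2]
                aj = acts[l + 1, j]
                delta[l, j] = s * (1.0 - aj * aj)
        for l in range(n_layers):
            for j in range(sizes[l + 1]):
                dj = eta * delta[l, j]
                for i in range(sizes[l]):
                    w[l, j, i] += dj * acts[l, i]
    taps_out = np.empty(ntaps)
    for k in range(ntaps):
        taps_out[k] = acts[0, k]
    return e_out, y_out, wdist, taps_out


@njit(cache=False)
def lms_loop(d, x, w, mu, taps_init):
    """Classic LMS adaptive FIR: y = w.x_taps, e = d - y, w += mu*e*x_taps."""
    ntaps = w.shape[0]
    n_samples = d.shape[0]
    buf = taps_init.copy()
    e_out = np.empty(n_samples)
    y_out = np.empty(n_samples)
    for n in range(n_samples):
        for k in range(ntaps - 1, 0, -1):
            buf[k] = buf[k - 1]
        buf[0] = x[n]
        y = 0.0
        for k in range(ntaps):
            y += w[k] * buf[k]
        e = d[n] - y
        e_out[n] = e
        y_out[n] = y
        g = mu * e
        for k in range(ntaps):
            w[k] += g * buf[k]
    return e_out, y_out, buf
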