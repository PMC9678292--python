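# dnfilter

Real-time removal of muscle (EMG) artefacts from EEG recorded with a
compound electrode — an inner disc carrying signal + noise and a
concentric outer ring carrying a noise reference — using a **deep neural
filter (DNF)**: a funnel-shaped, bias-free tanh network that learns
*while the data streams* to synthesise a "remover" signal from the
reference channel and subtract it from the contaminated channel.

It is aimed at researchers in EEG/BCI signal processing who want an
adaptive-noise-cancellation stack that runs causally, sample by sample,
with no separate training phase, together with the classic baselines
(LMS-tuned adaptive FIR, surface-Laplacian subtraction), a Welch/P300
SNR evaluation protocol, and a synthetic two-channel session generator
so the whole pipeline is testable without any data downloads.

## The method

The inner and outer channels are modelled as

```
d̃[n] = b[n] + m[n] + c[n]            inner:  signal + noise
x̃[n] = h[n] * (r[n] + α·c[n])        outer:  noise reference
```

with `b` background EEG, `m` EMG, `c` the evoked signal of interest,
`r = b + m`, crosstalk `0 ≤ α ≪ 1`, and `h` the (unknown) transfer from
the noise source to the ring.  Both channels are conditioned causally —
50 Hz notch, 2nd-order Butterworth high-pass (0.5 Hz for the inner
channel, 5 Hz for the reference so it carries the EMG spectrum rather
than EOG/drift), gain γ = 1000 — and the reference feeds a tapped delay
line of `ntaps = 50` samples into a network whose layer widths shrink
geometrically to one neuron:

```
I(ℓ) = ⌊ntaps / b^(ℓ-1)⌋,   b = ntaps^(1/(L-1))       → 50, 22, 10, 4, 2, 1
```

The forward pass is bias-free tanh throughout (zero in → exactly zero
out), producing the remover `y[n]`; the output

```
e[n] = d[n] − y[n]
```

is simultaneously the denoised EEG and the error that is backpropagated
(output delta `δ = e[n]`, hidden deltas via `tanh′(z) = 1 − tanh²(z)`,
update `Δω = η·a·δ`) — one weight update per sample, learning always on.
Learning converges when `e` and the reference `x` decorrelate.

Performance is measured per subject as

```
SNR = median(v²_P300, 300–500 ms) / Σ_{5 Hz}^{125 Hz} Welch(v)[k]
```

with the numerator from the event-triggered average of an oddball
session and the denominator the summed 1 Hz-bin Welch density of a
jaw-clench session; improvements are differences of SNR in dB against
the unfiltered inner channel, compared across subjects with a paired
t-test.

## Worked example

```python
import dnfilter as dn

# one synthetic "subject": a 2-min jaw-clench session at 500 Hz and a
# 5-min P300 oddball session at 250 Hz, with known ground truth
noise_rec, _, p300_rec, _ = dn.synthetic_subject(seed=1)

for variant in ("none", "dnf", "lms"):
    cfg = dn.RunConfig(variant=variant, seed=1)
    rep = dn.evaluate_variant(noise_rec, p300_rec, cfg)
    print(f"{variant:5s}  signal {rep.signal_power:.2e} V^2   "
          f"noise {rep.noise_power:.2e} V^2   SNR {rep.snr_db:+.1f} dB")
```

prints

```
none   signal 1.41e-05 V^2   noise 2.28e-04 V^2   SNR -12.1 dB
dnf    signal 1.06e-05 V^2   noise 1.61e-05 V^2   SNR -1.8 dB
lms    signal 9.42e-06 V^2   noise 5.02e-06 V^2   SNR +2.7 dB
```

The unfiltered inner channel sits at −12.1 dB (EMG bursts dominate the
5–125 Hz noise band).  The deep neural filter removes most of the band
noise (2.3·10⁻⁴ → 1.6·10⁻⁵ on the conditioned scale, a +10.3 dB SNR
improvement) while attenuating the evoked P300 power only mildly
(crosstalk removal).  The LMS-FIR baseline — same taps, delay and
conditioning — converges faster on this strictly linear synthetic
coupling and reaches +2.7 dB.  Powers are on the conditioned scale
(γ² × physical volts²); the SNR is scale-free.

The filters are scikit-learn style transformers if you prefer that
surface:

```python
est = dn.DeepNeuralFilter(fs=500.0, eta=2.5, random_state=1)
clean = est.fit_transform(noise_rec.as_array())   # (n_samples, 1)
est.layer_sizes_     # (50, 22, 10, 4, 2, 1)
est.weight_distance_ # per-layer distance from the initial weights
```

A CLI covers the same ground: `dnfilter simulate`, `dnfilter filter
--variant dnf|lms|laplace|none`, `dnfilter evaluate`, `dnfilter compare`
(TSV signals, flat YAML configs/reports).

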