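# Methods

## Signal model and scope

The package treats a two-channel compound-electrode recording: the inner
disc sees `d̃ = b + m + c` (background EEG `b`, EMG `m`, evoked signal
`c`), the outer ring sees `x̃ = h ∗ (r + α·c)` with `r = b + m`, a
crosstalk fraction `α` and an unknown linear path `h`.  Everything
operates causally and sample-by-sample: there is no zero-phase
(forward–backward) filtering anywhere, because the system is meant to
run while the data is being acquired.

Hardware concerns (electrode fabrication, acquisition devices, the ADC's
anti-alias roll-off) are out of scope; the synthetic generator simply
band-limits all of its components below the Nyquist frequency instead of
modelling an ADC low-pass, and the software conditioning chain applies
only the notch and high-pass stages — re-applying an anti-alias roll-off
to already-sampled data would double-count it.

## Conditioning

Each channel passes a 2nd-order Butterworth 50 Hz band-stop (stopband
47.5–52.5 Hz; the bandwidth is a free choice — ±2.5 Hz rejects mains
drift while sparing EEG beta/gamma), then a 2nd-order Butterworth
high-pass (0.5 Hz on the inner channel, merely DC removal; 5 Hz on the
reference channel so that the network is steered toward the EMG spectrum
and not toward EOG or electrode drift), then a gain γ = 1000 that maps
tens-of-microvolt physiology to roughly ±0.2 — inside tanh's gently
nonlinear region, far from saturation.  Notch and high-pass commute in
exact arithmetic; the order (notch first) is fixed only for
bit-reproducibility.  All filters start from zero state, so runs are
deterministic; startup transients decay within seconds and are dominated
by early learning anyway.

## The deep neural filter

The conditioned reference feeds a tapped delay line of `ntaps` samples
(operating value 50; the `fs/fcx` rule of thumb is exposed as
`suggested_ntaps` but not enforced, since the canonical funnel
50, 22, 10, 4, 2, 1 is defined at 50 taps).  The inner channel is
delayed by `⌊ntaps/2⌋` samples so the network sees pulse-like artefacts
before it must cancel them; for odd `ntaps` the floor is the
conservative generalisation.

Layer widths follow `I(ℓ) = ⌊ntaps/b^(ℓ-1)⌋` with
`b = ntaps^(1/(L-1))`, guarded against floating-point floor underflow so
the last layer is exactly one neuron.  The network is bias-free — a
deliberate property, since the signals are DC-free and zero input must
produce exactly zero output — and tanh throughout, which bounds the
remover to |y| < 1.

Learning is always on: every sample does forward pass, `e = d − y`,
backpropagation, weight update, unconditionally.  The output-layer delta
is the raw error `e[n]` with no `tanh′(z_L)` factor, exactly as the
update rule is published; the conventional derivative-included rule is
available behind `output_delta_derivative=True` (default off).  Hidden
deltas use `tanh′(z) = 1 − a²` from cached activations; weights move by
`+η·a·δ` with no clipping.  The per-layer Euclidean distance of the
weights from their initial snapshot is logged (every sample by default,
decimatable) as the standard convergence trace.

Learning rates: η = 2.5 for jaw-clench (noise) sessions and η = 10 for
oddball sessions.  The effective rate scales with the reference
amplitude (the update is ≡ η·x·e), and these two values equalise it
across the two tasks' very different reference amplitudes; no automatic
normalisation of x is applied.

**Weight initialisation (a deliberate deviation).**  Published practice
for this filter draws every weight uniformly from (0, 1].  With
all-positive weights each layer passes a common-mode signal with gain
≈ fan_in/2, so on ±0.2 inputs the deep layers' pre-activations exceed 1
immediately: tanh saturates, y rails at ±1, and with learning always on
at η = 2.5 the weights random-walk to enormous magnitudes — we measured
per-layer weight distances of ~10⁴ and no noise reduction at all.  A
single global small scale (e.g. 1/ntaps) fixes saturation but collapses
the forward signal to ~10⁻⁵ at the output and learning stalls.  The
default here is therefore per-layer uniform on (0, 2/fan_in], which
makes the common-mode gain of every layer one: the funnel neither
saturates nor vanishes, and learning engages immediately.  The global
(0, 1] init remains available via `init_scale=1.0`.

## Baselines

The LMS-FIR baseline shares the DNF's geometry exactly — same
conditioning, same 50 taps over the reference, same inner-channel delay
— so differences are attributable to the filter itself.  Weights start
at zero (standard for LMS).  The step size defaults to the DNF's η
("matched rates"): for a single linear neuron the two update rules are
literally identical, which the test suite exploits as a cross-module
oracle.  The surface Laplacian subtracts the raw ring from the raw disc
and removes DC and 50 Hz afterwards, with γ applied last so its output
is scale-comparable; being a fixed subtraction it also removes any
evoked component common to both electrodes.

## Evaluation protocol

Noise power: Welch PSD with segment length = fs samples (1 Hz bins),
Hann window, 50% overlap (window/overlap are not dictated by the
protocol; Hann/50% is standard practice and configurable), density
normalised so that the bin sum approximates the stream's variance;
bins 5–125 Hz inclusive are summed — also at fs = 500, where the band
deliberately stops at 125 Hz.  Signal power: event-triggered average of
the oddball session (epochs exceeding the stream are dropped and
counted; alignment is corrected for the variant's internal delay and any
acquisition latency), then the **median** squared amplitude over the
closed 300–500 ms window (equivalently 400 ± 100 ms) — the median
deliberately under-estimates the peak, mimicking what short-averaging
real-time BCIs can use.  SNR = 10·log₁₀(signal/noise).

ΔSNR is reported as filtered − inner, so improvements are positive; the
opposite orientation is available.  Significance across subjects uses a
two-sided paired t-test by default (Wilcoxon selectable); all-zero
differences return p = 1, zero-variance nonzero differences return the
underflow floor 0.  The Johnson-noise helper `thermal_noise_rms`
(√(4·k_B·T·R·B); ≈ 65 nV at 310 K, 1 kΩ, 250 Hz) quantifies the
uncorrelated floor that no reference-based canceller can remove.

For the DNF the network is re-initialised from scratch for every
session (fresh random weights per subject and per task), as the method
prescribes for multi-subject comparisons.

## Synthetic sessions

Two canonical sessions mirror the experimental protocol and are the
frozen study conditions for all end-to-end tests:

* **session1** (noise): 500 Hz, 120 s; a jaw-clench EMG burst every
  15 s (Hann envelope, 2 s), tonic EMG 5 μV RMS rising to 50 μV RMS at
  burst peaks, EMG band 20–125 Hz; background EEG 10 μV RMS in
  0.5–30 Hz; no oddballs.
* **session2** (evoked): 250 Hz, 300 s; tonic EMG only; oddballs with
  gaps uniform on 7–13 s, each adding a 10 μV raised-cosine bump of
  200 ms full width centred 400 ms post-stimulus.

Components are synthesised as Gaussian noise band-limited by zeroing
Fourier bins outside the band (exact confinement, and the per-seed draw
count does not depend on band choices), normalised to the target RMS.
The burst envelope modulates a single carrier's instantaneous RMS
between the tonic and burst levels, so equal levels yield exactly
constant power.  The reference path `h` defaults to a causal
first-order low-pass at 100 Hz and the crosstalk to α = 0.1 — neither is
prescribed anywhere, so both are stated assumptions surfaced in
`SyntheticSpec`.  The decomposition `inner = b + m + c` holds exactly
(an optional uncorrelated sensor-noise term exists but defaults to 0 to
preserve that identity).  Identical specs, including the seed, produce
bitwise-identical recordings.  These amplitudes land the unfiltered
inner-channel SNR in the −20…−5 dB range observed for real jaw-clench
subjects.

What the generator does **not** emulate: physiological EEG rhythms
(alpha spindles, 1/f background), eye-blink/EOG and electrode drift
(excluded from the learning target by the 5 Hz reference high-pass
anyway), nonlinear or time-varying electrode coupling, and volume
conduction.  The coupling point matters for interpretation, below.

## What the synthetic study shows — and does not

Across ten seeded synthetic subjects the DNF improves SNR on 10/10
(mean +9.6 ± 1.6 dB) and the LMS baseline also improves it
(+16.7 ± 1.9 dB); both are hugely significant against zero.  The LMS
mean exceeding the DNF mean is a property of the generator, not of real
recordings: the synthetic reference path is a fixed linear filter, so a
50-tap FIR is the exactly-correct model class, both filters converge to
the *same* steady-state residual, and the full-session Welch noise power
then only reflects the learning transient — ~2 s for LMS at the matched
step versus ~20–30 s for the deep network.  On real electrodes, where
the coupling is nonlinear and drifts, the deep filter's advantage is
precisely what the linear generator cannot express.  Passing the
synthetic study therefore validates the machinery (conditioning,
learning dynamics, decorrelation-driven convergence, SNR protocol), not
a claim that the DNF dominates LMS under linear time-invariant coupling.

## Numerical choices

* Double precision throughout; the jitted per-sample loops are
  cross-checked against a plain-numpy reference network to 1e-10 over
  hundreds of samples, and backprop against central differences
  (step 1e-6, relative 1e-5).
* Degenerate funnel L = 1 is a single neuron over the full tap vector;
  in the small-signal regime its trajectory matches LMS to 1e-3 over
  1000 samples (matched init and rates).
* Problem sizes in the test suite (session lengths 120 s/300 s, ten
  seeds, 1 kHz-scale short fixtures elsewhere) are the canonical study
  conditions; the whole suite runs in well under a minute on one core.
* Filters validate stability (poles strictly inside the unit circle)
  at construction; non-finite samples raise immediately rather than
  propagating NaNs into the adaptive loop.

## Known limitations

* No RLS/NLMS/variable-step-size baselines; no alternative activations;
  no batch or GPU path — the method is defined as a real-time
  sample-by-sample filter.
* The optional reader for real deposited datasets is limited to the
  generic TSV adapter (`read_recording` with a column map); no
  device-specific formats.
* The evaluation assumes the 5–125 Hz noise band and the 300–500 ms
  P300 window; other paradigms need different windows, which are
  arguments, not constants.
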