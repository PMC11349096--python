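# Methods

## Data model and conventions

All point-wise arrays use one canonical order: the 24-2 grid in right-eye
orientation, row-major from the superior row down (row sizes 4, 6, 8, 9, 9,
8, 6, 4), with the physiologic blind spot at (15°, ±3°) and the extra nasal
points of the 9-point rows at x = −27°. Left-eye data are mirrored about the
vertical axis on ingestion (a per-row reversal), so everything downstream is
laterality-independent; writers mirror back, so files keep native
orientation. 30-2 exams are projected onto the 54 spatially coincident
locations on read. Blind-spot entries are stored as 0 dB — they carry no
sensitivity information and the encoder expects zeros there — which is also
why the subsetting projection zeroes them even when the source 30-2 exam
carries values at those positions.

Dates are calendar dates and all intervals are exact day differences.
Severity staging is a total function of MD with the boundary cases −6 dB →
moderate and −12 dB → advanced; reliability screening is strict (< 33 % for
each of FP, FN, FL) and is applied at ingestion by default (`reliable_only`
flag on the readers).

## Input encoding

An eye's history plus a forecast date become an 80 × 115 matrix. Data rows
are newest-first; row i > 0 carries the day gap to the exam in row i − 1,
and row 0 carries the gap to the forecast date — the single scalar through
which the requested horizon reaches the model. Divisors: days/1000,
reliability/100, MD and PSD/50, VFI/100, PD and TD/50. For fields within the
instrument range (−38 to +6 dB) every entry stays inside (−1, 1), matching
the tanh output head; the one boundary case is VFI = 100 % (a fully normal
field), whose target is exactly 1.0 and can only be approached by tanh.

Padding rows are appended *after* the data rows (the conventional pairing
with masking; only the masked result is contractually fixed). An all-zero
data row can never collide with padding: strict date ordering makes every
interval entry positive, and the encoder additionally validates this.
Series longer than 80 exams keep their 80 most recent exams, with a logged
warning.

## Network and training

Masking → bidirectional GRU (128 units per direction, final states
concatenated to 256) → dense(64, tanh) → dropout(0.1) → dense(57, tanh).
"128 units" is read as per-direction; the width is configurable. The GRU
update is `h_t = (1 − z)·h_{t−1} + z·c` with logistic gates z, r and tanh
candidate c (reset gate applied to the recurrent term). A masked time step
carries the hidden state through unchanged; the backward direction reads
each sample's valid prefix in reverse. Predictions are therefore exactly
invariant to trailing padding — verified to 1e−6 in the tests, and in
practice to machine precision.

The forward pass, backpropagation through time and Adam are written directly
in NumPy (`model.py`); the gradient implementation is checked against
central finite differences in the test suite. At these layer sizes the
network trains at a few milliseconds per batch on one CPU, so no framework
is needed. Kernel weights are Glorot-uniform, recurrent matrices orthogonal,
biases zero.

Training minimizes MSE over the 57 outputs with Adam (lr 0.001, β₁ 0.9,
β₂ 0.999, ε 1e−7), batch size 20, a 9:1 random train/validation split by
sample, and early stopping monitoring validation loss with patience 20 and
best-weight restoration — the monitored quantity and restoration are the
standard choices. A `max_epochs` cap (default 500) bounds runtime; early
stopping governs in practice. Training pairs are enumerated either as one
pair per eye (hold out the final exam; the default) or as all prefixes of
length ≥ 3; the split is by pair, with by-eye splitting left to the caller's
enumeration. With a fixed seed, training is deterministic to the bit on a
fixed BLAS configuration.

## Synthetic cohorts

The simulator emulates a tertiary glaucoma-clinic population rather than any
particular archive. Each eye draws an archetype — normal, superior or
inferior arcuate (Gaussian profile around 15° eccentricity in one
hemifield), diffuse depression, or advanced tunnel (deep loss outside 10°
with relative central sparing) — then a baseline field scaled so its MD
lands uniformly in the archetype's band (normal −1.5…0.5 dB, arcuate −7…−1,
diffuse −11…−5, tunnel −24…−13), per-point jitter of 0.8 dB SD, and
per-point linear progression rates (affected points: archetype profile ×
N(−0.6, 0.4²) dB/year; normal eyes do not progress). True fields are clamped
to the instrument range [−38, +6] dB.

Observed fields add Gaussian test–retest noise with SD = min(1.0 + 0.15 ×
defect depth, 6.0) dB — variability grows with damage, which is what makes
forecasts of severe eyes harder and drives the severity trend the
evaluation reproduces. Visit counts are uniform on [4, 9], so input-exam
counts (history minus the held-out target) span 3–8 with half in the 3–5
bin, mirroring an early-stage-dominated clinic mix; visit gaps are uniform
on [90, 365] days and the final gap (the natural forecast horizon) uniform
on [60, 420] days, mean ≈ 240 days. Reliability rates are uniform on
[0, 33) so every simulated exam passes screening.

Global indices use documented surrogates (MD = unweighted seeing-point mean;
general height = 7th-largest TD; PD = TD − GH; PSD = population SD of TD;
VFI = clamp(100·(1 + MD/30), 0, 100)) instead of the instrument's
proprietary eccentricity-weighted formulas — the network consumes them as
opaque features, so only internal consistency matters. Consequences for
interpretation: simulated truths are linear in time (only the clamp and the
noise model create nonlinearity in observation space), there are no learning
effects, media opacities or treatment changes, and passing tests demonstrate
that the pipeline learns and evaluates correctly under these assumptions —
not clinical-grade accuracy on real perimetry.

## Evaluation

Per-eye TDV RMSE and MAE use the 54-point denominator, blind-spot entries
included as zero-in-both (an option drops them for a 52-point variant).
Horizon bins use 1 month = 30.44 days. Severity labels come from the
prediction-target exam's true MD (configurable by the caller building the
records). The default omnibus test is Kruskal-Wallis with Mann-Whitney for
pairwise contrasts; one-way ANOVA is available, and reports state which was
used. For pooled samples of ≤ 12 observations the Kruskal-Wallis p is the
exact permutation tail (the χ² approximation is unreliable there);
Mann-Whitney p-values are exact for tie-free samples up to size 8 and
tie-corrected normal otherwise (scipy's small-sample policy). Raw p-values
are reported without multiplicity correction, with 0.05 as the significance
convention.

Baselines: last-observation-carried-forward, and per-point ordinary least
squares of TD against time extrapolated to the forecast date, clamped to the
instrument range, with surrogate indices derived from the extrapolated
field. On noise-free linear series the OLS baseline is exact by
construction, so learned-model comparisons against it are only informative
on noisy or clamped (nonlinear-in-observation) eyes.

## Problem sizes

The shipped verification runs train on 1,800 simulated eyes (one window →
target pair each, ≤ 50 epochs), forecast 200 held-out eyes, and evaluate the
severity trend on a separate 1,500-eye cohort — sizes chosen to give stable
strata (≥ 200 eyes each) while keeping a full from-scratch run to a couple
of minutes on a single CPU. Under these defaults the trained network's
held-out point-wise MAE beats both baselines, and stratum MAE rises
monotonically with severity with a Kruskal-Wallis p far below 0.05; the
exact numbers for a given seed are produced by `scripts/acceptance.py`.

## Known limitations

* The simulator's linear-progression truth flatters trend-following models;
  real fields fluctuate, regress to the mean, and progress episodically.
* Surrogate global indices differ numerically from Humphrey's MD/PSD/VFI, so
  absolute index errors are not comparable with instrument printouts.
* No uncertainty quantification; the network emits point forecasts.
* The 30-2 ingestion path assumes the documented canonical orders; no
  proprietary instrument formats are parsed.
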