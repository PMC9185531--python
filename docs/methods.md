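# Methods

## The measurement problem

A 77 GHz FMCW radar stares at a thin, metal-backed container of aqueous
glucose solution. After dechirping, a static target reduces to a single
low-frequency complex tone (the *beat signal*), whose complex amplitude is
the echo of the scene. Because the real permittivity ε′ of aqueous glucose
increases with concentration while the loss tangent tan δ decreases over
the physiological range, both the front-interface Fresnel reflection and
the back-plate return grow with concentration; the spectral energy of the
beat signal is therefore a monotone proxy for concentration. The package
implements that measurement chain, and the classifier that rescues it when
the radar's gain drifts between power-on sessions.

## Echo model (simulate)

The echo amplitude is a two-path model:

    echo(c) = r_s(c) + (1 − r_s(c)²) · R_b · exp(−α(c) L) · exp(−i β(c) L)

* `r_s` — s-polarised Fresnel magnitude at the air/solution interface,
  evaluated in the refractive-index form `|n1 cosθi − n2 cosθt| /
  (n1 cosθi + n2 cosθt)`, which equals the sine form at oblique incidence
  and stays regular at normal incidence. The refraction angle comes from
  the permittivity ratio (`sinθi / sinθt = √(ε2/ε1)`).
* `α, β` — the standard attenuation/phase constants of a lossy dielectric;
  `β² − α² = ω² μ ε` holds identically (a property test).
* `L` — the two-way path through the solution along the refracted ray;
  `R_b` — back-plate reflectivity.

The dielectric law is affine, the simplest law reproducing the measured
trends: `ε′(c) = a0 + a1 c` (a1 > 0) and `tan δ(c) = b0 − b1 c` (b1 > 0).

**Default coefficients.** a0 = 6.0, a1 = 0.4 mL/mg, b0 = 0.050,
b1 = 0.025 mL/mg, solution path 6 mm, R_b = 0.9, normal incidence. These
are bench assumptions, not literature values — real saline is far lossier
at 77 GHz, but a realistic tan δ would extinguish the back-plate return
entirely and with it the interference physics of interest. The
coefficients were chosen by scanning the two-path model once, before any
learning experiment, for the combination that makes |echo| *strictly*
monotone over the entire validity range [0.5, 1.5] mg/mL (larger a1 or a
thicker path makes the rotating back-plate phase overpower the magnitude
trend and breaks monotonicity). At the five bench concentrations
(0.69, 0.81, 0.91, 1.03, 1.08 mg/mL) the defaults give magnitude steps of
13.4 / 10.0 / 11.0 / 4.1 % and phase steps of 0.035–0.058 rad between
adjacent classes. The phase steps matter: they are invariant to the
(real) drift gain and are what makes the classification task solvable
across power cycles.

**Beat record.** Length N = 64 complex samples; a tone at 3.3 DFT bins —
deliberately off the coarse grid so the 16× zero-padding has something to
resolve, and inside the lowest eighth of the band so the 3-level DWT
approximation band contains it. Additive complex white Gaussian noise is
band-limited to |f| ≥ fs/4 (thermal noise sits above the beat tone) at a
per-record SNR of 20 dB.

**Power-cycle drift.** Each power-on session draws, once, a multiplicative
gain ~ lognormal(0, 0.05) and a complex DC offset ~ CN(0, 0.02²), applied
to every record of that session. Gain changes the slope of the
energy-vs-concentration line, the offset its intercept — the two failure
modes a single calibration line cannot survive. Three transmit antennas
carry small fixed gain offsets (1.00 / 0.97 / 1.03) and are treated
independently by the energy analysis.

What the generator does *not* emulate: skin or tissue layers, antenna
patterns, range migration, interference from other emitters, temperature
dynamics of the drift (drift is phenomenological, not mechanistic). A
green test suite therefore shows the algorithms behave as specified on
signals with this structure, not that the bench instrument is validated.

## Spectral chain (spectral)

Package-wide DFT convention: forward unnormalised, inverse carries 1/N.
Records are zero-padded ×16 (the padded record keeps the first N samples
bit-identical and appends 15N zeros), FFT'd, and summarised by the PSD
`P(k) = |S(k)|²/N`, its peak, and the total energy `E = Σ_k P(k)` over all
16N bins. With this normalisation Parseval gives `E = 16 Σ_n |x(n)|²` for
every input — a fixed proportionality the suite checks on random signals.
DC is included in the energy by default (`drop_dc` excludes it); the clean
simulated tone carries no DC, so the flag matters only for drifted
records.

## Denoising (denoise)

**EMD.** Sifting uses cubic-spline envelopes through the interior extrema
with the record endpoints pinned as envelope knots plus one mirrored
extremum beyond each end (unpinned envelopes overshoot catastrophically on
64-sample records), the standard-deviation stop criterion at 0.2, at most
10 sifting passes per IMF and at most 8 IMFs. An IMF is discarded iff its
zero-crossing count reaches three times the raw record's count
(`f_i ≥ 3 f_0`, boundary removed). Zero samples are transparent to the
crossing counter: a zero run counts one crossing when its neighbours have
opposite signs. Complex records are processed part-wise (real and
imaginary independently), with `f_0` counted on each raw part.

**DWT.** 3-level db10 with symmetric extension (64-sample records are
shorter than the usual max-level rule for a 20-tap filter; symmetric
extension keeps the transform exactly invertible, which the suite checks
at zero threshold). The universal soft threshold `σ̂ √(2 ln n)`, with σ̂
from the median absolute deviation of the level-1 details, is applied to
the finest two detail levels only — the bands covering the upper half of
the spectrum where the noise lives. The level-3 detail band borders the
beat tone; thresholding it biases the low-frequency PSD away from the
clean signal's (relative L2 error ≈ 0.11 vs ≈ 0.007 with the default),
which would defeat the point of choosing the DWT over EMD in the first
place. EMD's low-band error is bimodal (≈ 0.004 when the tone survives as
one IMF, ≈ 0.3–0.4 when the rejection rule takes part of it), averaging
≈ 0.11 — the quantitative form of the comparison that motivates DWT as
the default method.

Neither decomposition is an orthogonal projection on short records, so a
denoised record can gain a fraction of a percent of energy from cross
terms; the suite asserts a ≤ 1 % per-record bound and a strict decrease
on average rather than an exact non-increase.

## Calibration and drift (calibrate)

Per-class mean energies are fitted with the closed-form least-squares
line (slope from centred cross-products, intercept `ȳ − k x̄`); the
inverse map `(E − b)/k` extrapolates a concentration from a measured
energy. Only degree-1 fitting is offered: the mild nonlinearity at the top
of the range would invite overfitting of a five-point calibration.
`drift_report` fits two sessions separately and reports slope/intercept
deltas plus the cross-session prediction error — the diagnostic showing
why a single line cannot serve across power cycles.

## Features (features)

The complex record is analysed with an analytic Morlet wavelet
(`cmor1.5-1.0`) at 32 logarithmically spaced scales from 2 to 40 samples,
a span whose centre frequencies bracket the beat tone. The positive-scale
(counterclockwise) half is the CWT of the record; the negative-scale
(clockwise) half is the CWT of the conjugated record. The four real pages
— Re(+), Im(+), Re(−), Im(−) — are stacked into a (32, 64, 4) tensor and
zero-mean normalised globally (variance scaling available but off).
Keeping real and imaginary pages separately is what carries the echo
*phase* into the network.

## Classifier (nn, learn)

A compact numpy engine implements the network with explicit
forward/backward passes (finite-difference gradient checks to ~1e-8 in
the suite): 2-D convolutions via im2col, batch normalisation, residual
blocks, average pooling, bidirectional LSTM layers (gate order i, f, g, o,
forget bias 1) and a linear softmax head.

Architecture: a stem convolution (tunable kernel and stride; a stride-1
stem keeps full resolution and a 2×2 average pool then restores the
downstream grid, so the stride trades local detail against aliasing at
constant cost) feeds a residual backbone — either the `full` 18-layer
configuration (four stages of two blocks, 64/128/256/512 channels) or the
`reduced` 4-block variant (one block per stage, 16/16/32/64 channels) used
for desk-scale experiments. The feature map is averaged over the scale
axis and read along the time axis by two bidirectional LSTM layers
(tunable width); the time-averaged output feeds the 5-class softmax.

Training: momentum SGD (lr 0.01, momentum 0.9, batch 32), step decay ×0.2
at 60 % and 85 % of the epoch budget. Before each held-out evaluation the
batch-norm running statistics are re-estimated at the current weights from
two 192-sample forward passes ("precise BN") — without it the
exponential running averages lag the moving weights and the validation
curve is noise. Training set expansion by white-noise copies (default 3
copies at 5 % of the tensor standard deviation) is available but not part
of the benchmark protocol. The dataset splits 85/10/5 with validation and
test sizes rounded and the remainder assigned to training, so 1000 records
split exactly 850/100/50. The classifier only accepts the concentrations
it was trained on; unseen labels are an error by design. Single-precision
arithmetic is used for benchmark training (half the cost, no measurable
accuracy difference); the engine defaults to double precision, which the
gradient checks require.

## Hyperparameter search (ssa)

The sparrow search algorithm maximises validation accuracy over stem
kernel size {3, 5, 7}, stem stride {1, 2} and LSTM width 8–64 (searched on
a step-8 grid: widths within a step train indistinguishably, and the
coarser grid lets the evaluation cache absorb revisits). Flock constants
follow the published algorithm: producer fraction 0.2, danger-aware
fraction 0.1, safety threshold 0.8; producers contract or take Gaussian
steps depending on the alarm value, scroungers follow the best producer or
scatter toward the worst position, and danger-aware individuals jump
toward the incumbent. Positions are clipped to the box after every move
and decoded to the integer grid (kernel sizes snap to the nearest odd
value, ties upward) for evaluation. Evaluations are cached per decoded
vector; an objective that raises is demoted to worst fitness and the run
continues. The incumbent is monotone by construction.

**Benchmark protocol** (also what `scripts/acceptance.py` runs): the
default campaign is 5 classes × 200 records over 8 power cycles with
drift enabled, denoised by DWT and encoded as tensors. Search uses a
cheap ranking proxy — 10 epochs on a fixed 200-record subset of the
training indices — and seeds the default configuration (kernel 3, stride
2, width 16) into every initial flock, so the search incumbent cannot rank
below it. Each of the 3 optimiser seeds then retrains its best setting on
the full 850-record training split for 16 epochs; that retrained
validation accuracy is the reported number, best of the three seeds, with
the default configuration put through the identical full protocol as the
baseline. These problem sizes (subset, epoch budgets) are the package's
desk-scale defaults; the deterministic objective makes the whole benchmark
a pure function of its seed.

## Numerical and degenerate-input policy

* PSD peak ties break to the lowest bin (documented, tested).
* Monotone records produce zero IMFs and pass through EMD unchanged.
* Total internal reflection, out-of-range concentrations, invalid SNRs,
  degenerate calibration designs (all-equal abscissae), zero calibration
  slopes, empty evaluation sets and unknown class labels all raise with
  specific messages rather than propagating NaNs.
* Divergent training (non-finite loss) raises a `TrainingError` carrying
  the epoch, batch and learning rate.

## Known limitations

* The dielectric law is affine and the drift phenomenological; neither is
  fitted to measured material data.
* EMD on 64-sample records keeps at most a handful of IMFs; the rejection
  rule can remove part of the tone when the noise draws badly (visible as
  the bimodal low-band error above).
* The classifier is a closed-set five-class device: it cannot interpolate
  between concentrations (a regression head is the natural extension).
* Accuracy numbers from the synthetic benchmark characterise the
  algorithms on the simulator's signal family, not hardware performance.
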