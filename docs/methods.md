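# Methods

## Forward model

A TCSPC decay histogram is modelled on `n_bins` half-open time bins
spanning one laser repetition period `T` (defaults: 256 bins, `T` =
12.5 ns, i.e. an 80 MHz oscillator), with bin 0 starting at the laser
sync. The expected count profile of an exponential mixture is built in
three discrete steps shared verbatim by the generator and the fitters:

1. closed-form per-bin integrals of each component,
   `g_k(τ) = τ·(e^(−t_k/τ) − e^(−t_{k+1}/τ))`, weighted by the relative
   amplitudes (so the photon share of component *i* is
   `a_i·τ_i / Σ_j a_j·τ_j`);
2. discrete convolution with the discretized IRF, truncated at the window
   (or wrapped circularly when the incomplete-decay correction is on);
3. normalization to unit sum, so scaling by a photon budget conserves
   photons exactly regardless of truncation.

The IRF is a Gaussian integrated over bins (cumulative-normal
differences), default FWHM 0.2 ns — detector-limited; the femtosecond
excitation pulse is negligible — centred at 10% of the window to leave a
pre-trigger baseline. Incomplete-decay wrap-around is off by default: at
the lifetimes of interest the residual at the window end is ≈1%
(`e^(−12.5/2.7)`), below fitting precision at single-cell photon budgets;
a `wrap=True` flag enables the periodic correction symmetrically in
generator and fitter.

Dark counts are uniform in time at 1% of the photon budget by default
(0–5% supported). A small flat floor keeps the χ² statistic honest for
fits that model background.

## Phantom scenes

`render_phantom_scene` emulates one field of view: non-overlapping
elliptical cells (semi-axes ~14–20 × 10–14 px, seeded rejection sampling
with a ≥6 px gap), each with a concentric nucleus at half the cell's
semi-axes. The field's photon budget is `photon_rate × collection_time`
(default 1.5×10⁵ photons/s × 60 s = 9×10⁶ photons), split across cell
pixels by a smooth radial profile (full intensity at the centre, half at
the rim); nuclei receive 40% of the cytoplasmic per-pixel budget,
mirroring NAD(P)H images in which mitochondria-rich cytoplasm dominates.
Per-bin Poisson sampling is optional (`sample=False` returns expectations
for noise-free oracles). The manifest records every generation parameter,
per-compartment photon budgets and the seed; regeneration from the same
configuration is bit-identical.

What the phantoms do **not** emulate: optical PSF blur, detector
afterpulsing and pile-up, cell-shape irregularity, intra-compartment
lifetime heterogeneity, and between-cell biological variability of decay
parameters (every cell in a group shares one ground truth; between-cell
spread enters the statistics tests as an explicit per-cell noise term).
Passing recovery tests on phantoms therefore demonstrates correctness of
the estimators under counting noise, not robustness to every real-world
artifact.

## Fitting

Estimation is Poisson maximum likelihood, not least squares: aggregated
single-cell histograms have many low-count bins where Gaussian weighting
is biased. The likelihood is maximized by L-BFGS-B within bounds
(τ ∈ [0.05, 6] ns mono; τ₁ ∈ [0.05, 1.5], τ₂ ∈ [1.0, 6.0] ns, p ∈ [0, 1]
biexp), followed by a Nelder–Mead refinement (`polish=False` disables it
for large simulation campaigns; the two differ by ~10⁻⁶ ns).
Initialization: mono from a log-linear regression on the post-peak tail
(bins with ≥5 counts); biexp from typical NAD(P)H values
(0.4 ns, 2.5 ns, p = 0.7). Amplitude and background are parameterized as
fractions of the observed total so all parameters are O(1) for the
optimizer. Components are always reported with τ₁ < τ₂, amplitudes
following any swap; a₁ = 100·p and a₂ = 100 − a₁ by construction, so the
normalization identity is exact. A fitted ratio τ₁/τ₂ > 0.8 sets an
`identifiability` flag (the split is unreliable); any parameter on a
bound clears `converged`.

Goodness of fit is the reduced Pearson χ²,
`Σ (obs − model)²/model / (bins − n_params)`, excluding bins with model
expectation < 1 (their count is reported). Pearson weighting was chosen
over Neyman because its per-bin expectation equals 1 for Poisson data at
any count level; the 0.8–1.2 window is treated as a gate on correctly
specified fits, and simulation shows the mean lands at 1.00 ± 0.01 with
~96% of replicates inside the window at 10⁵ photons.

A tail-fit mode (pure exponential from just after the histogram peak) is
available for curves whose IRF is unknown; it trades bias for
IRF-independence and is not used by default.

Minimum-signal gates: 1000 photons for mono, 5000 for biexp fits —
below these, component estimates degrade sharply, and a hard error is
more honest than a silently bad fit.

## Segmentation

The pipeline is mask-agnostic: externally produced masks are first-class
inputs, and the bundled classical fallback covers phantoms and
high-contrast fields. Cells: Gaussian smoothing (σ = 2 px), Otsu
threshold, hole filling, then watershed on the distance transform seeded
by the connected regions above 60% of each component's distance maximum —
one seed per convex object, two per touching pair, avoiding the oversplit
that per-pixel peak detection produces on elongated cells. Objects below
50 px are dropped; border-touching objects are flagged but kept (the
default is inclusion; flags let downstream analysis exclude them).
Nuclei: within each cell, pixels below 60% of the cell's median intensity
(the dark interior of NAD(P)H images), largest connected region, ≥20 px.
Nucleus–cell pairing is by majority (>50%) area overlap; a nucleus with
no majority owner is a hard error, a cell with no nucleus keeps its whole
footprint as cytoplasm and is flagged out of nuclear metrics.

## Statistics

Group comparison follows a fixed procedure: (1) trim values strictly
below the 1st and strictly above the 99th percentile
(linear-interpolation percentile definition; strictness means tied
boundary values are kept); (2) record Shapiro–Wilk W and p per group —
reported, never used to switch the test family; (3) Welch's
unequal-variance t-test with Welch–Satterthwaite degrees of freedom,
two-sided; Bonferroni adjustment (p × number of pairwise comparisons,
capped at 1) only when more than two groups are compared. Note that with
very small groups (n ≤ ~5) of continuous values the strict trimming rule
removes the extremes — group sizes in the tens are the intended regime.

Colocalization within a mask: Pearson r over in-mask pixel pairs and
Manders `M1 = Σ A_i [B_i > thr_B] / Σ A_i`, thresholds defaulting to
per-channel Otsu inside the mask and recorded in the result. A constant
channel makes r undefined and raises; M1 remains available separately.

## Problem sizes

Simulation-backed checks use sizes chosen to make their statistical
tolerances meaningful at interactive runtimes: 200 replicates for
parameter-recovery medians (10⁵ photons/cell — the budget of a
~5–7-cell field at 1–2×10⁵ photons/s for 60 s), 300 replicates for χ²
calibration, 50 seeds × 40 cells/group for the lifetime-discrimination
power check, 2000 replicates for Welch type-I calibration, and 5-cell
192–256 px phantoms for segmentation scoring.

## Known limitations

* Two decay components at most; no phasor analysis or global fitting.
* The classical segmenter is tuned to convex, well-separated cells on a
  dark background; dense or irregular cultures need external masks.
* The χ² gate reflects this package's Pearson weighting; commercial
  fitting packages may weight differently, so the window — not the exact
  value — is the comparable quantity.
* Lifetime bounds assume nanosecond-scale fluorophores (NAD(P)H, DOX);
  picosecond components would hit the lower τ bound.
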