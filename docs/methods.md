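# Methods

## The lattice model

The microtubule is a 2-D array of tubulin dimers: 13 protofilament stacks
with periodic lateral wrap. Three reactions are possible at any moment:

* **Association** at the end of each protofilament (one landing site,
  directly atop the terminal dimer; pure lateral associations are not
  allowed), at rate `k_on·[tubulin]`. Incoming dimers carry GTP.
* **Dissociation** of terminal dimers only, at rate `k_on·K_D(site)`.
  Contact free energies add, so a site with one longitudinal and `n`
  lateral contacts has `K_D = K_D_long·(K_D_corner/K_D_long)^n`
  (`n ∈ {0,1,2}`: longitudinal, corner, bucket). Dimers with a neighbour
  above them cannot leave; at the fitted affinities their two-longitudinal-
  bond off-rates would be negligible anyway, and removing interior dimers
  would create vacancy semantics the model deliberately avoids.
* **Hydrolysis** (GTP → GDP) of any non-terminal, non-seed GTP dimer at
  rate `k_GTPase`. Terminal dimers are exempt because the GTPase machinery
  requires a longitudinal interface formed above the nucleotide.

The nucleotide acts in **trans**: the interface between dimers `i−1` and
`i` takes the nucleotide of the lower dimer, and a GDP interface is weaker
by the factor `X` (`K_D(GDP) = X·K_D(GTP)`, applied to the longitudinal
term only). A protofilament is "GDP-exposed" when its terminal dimer's own
nucleotide — the interface offered to incoming tubulin — is GDP. This is
what `terminal_gdp_count` counts and what transiently poisons elongation:
a dimer landing on a GDP interface unbinds `X`-fold faster.

**Seam.** Lateral neighbours are `(pf±1, same index)` with periodic wrap;
across the 13↔1 boundary the index is staggered by `seam_offset` dimers
(default 2, configurable to 1 or 0). The true 3-start-helix rise of 1.5
dimers per turn is not representable at dimer resolution; 2 was chosen as
the conservative rounding. Growth rates shift by roughly ±10% between
stagger conventions (measured: 1.91 / 2.04 / 2.27 / 2.55 nm/s for offsets
0/1/2/3 at the 1.5-μM reference condition), which bounds the convention
uncertainty of the model.

**Seed.** Simulations start from a blunt, immutable template (default 10
layers) standing in for a stabilized nucleation seed: seed dimers never
dissociate or hydrolyze and present GTP interfaces upward.

**Scheduler.** Events are sampled by the rate-sum (direct) method: waiting
times exponential in the total rate, event `i` with probability
`rate_i/Σrates` — statistically identical to racing independent exponential
execution times per event and taking the fastest. The contract is the
statistical law, verified by χ² (event frequencies) and Kolmogorov–Smirnov
(waiting times) tests on a frozen three-event system. Production runs use a
compiled numba kernel; a pure-Python event enumeration with the same rules
serves as the cross-checked reference. One seed drives each episode;
replicate `r` of a batch uses `base_seed + r`. Internal units are nm, s,
μM; dissociation rates are `k_on(μM⁻¹s⁻¹)·K_D(μM)`.

**Site-dependent on-rates (variant).** Optionally the on-rate constant
depends on the landing-site class: corner sites use the global `k_on`,
longitudinal sites 1.67×, bucket sites 1/4.62×. Off-rates use the same
site's on-rate constant, preserving detailed balance with the site's K_D.

**Default parameters** are the published best fits: `k_on = 0.74 μM⁻¹s⁻¹`
with `K_D_corner = 25 nM / K_D_long = 87 μM` (GMPCPP-like, no GTPase) and
`K_D_corner = 2.9 μM / K_D_long = 1.7 mM` (GTP). Where a source prints both
87 and 86 μM for the longitudinal affinity we default to 87 and expose it
as configuration.

## Growth-fluctuation estimation

Tip traces (10 frames/s; episodes ≥ 90 s) are block-averaged over windows
of `n` frames at all `n−1` phase offsets (n = 2…300, lags 0.2–30 s), and
frame-to-frame displacements of the averaged traces are pooled into one
distribution per lag. The "normal fit" to that distribution is its sample
mean and variance (the MLE), with no outlier trimming. The growth rate is
the through-origin slope of mean displacement vs lag. The displacement
variance is biphasic, `2DΔt + σ_i²/Δt^f`: a straight line fitted at lags
≥ 10 s gives `D` (slope/2; negative fits are clipped to zero and flagged),
and the residual short-lag decay (lags ≤ 2 s, `f` fixed at 1 — the iid
prediction) gives the noise amplitude.

Two convention notes, both verified against closed forms in the test suite:

* **Block-mean factor.** For a pure Brownian path the pooled variance of
  adjacent-block-mean differences is `(2n²+1)/(3n²) · 2DΔt → (2/3)·2DΔt`,
  so the procedure's fitted D is asymptotically 2/3 of the generating
  Brownian D. The procedure is kept verbatim — simulated and measured
  traces pass through the same pipeline, so comparisons are internally
  consistent — and the 2/3 factor is frozen into the estimator-recovery
  oracles rather than "corrected".
* **σ_i units.** The fitted 1/Δt amplitude `A` is reported as the
  per-frame noise SD `σ_i = √(A/(2·t_exp))`, because iid frame noise of SD
  s produces raw displacement variance `2s²` and pooled block-mean
  variance `2s²/n`. This makes the generator round trip unit-consistent.

Phase-offset traces are pooled, not averaged (the analysis choice was open;
pooling uses every displacement). Concentration-series fits are weighted
least squares with weights `1/SEM` — deliberately not `1/SEM²`, matching
the convention of the experimental fits. Apparent on-rate constants are
series slopes converted from nm/s/μM to subunits/s/μM (one dimer advances
the lattice by 8.2/13 nm). For comparison with imaging data, the static-
seed noise floor of 0.97 nm²/s can be added to simulated variances (a
flag/helper, never automatic).

## Tip tracking and drift correction

Backbones are localized per image column by Gaussian fits inside a region
of interest (half-width 5 pixels, re-centred from the previous frame's
tip); a straight line through the centers defines the backbone angle Θ and
a 1-D arclength axis sampled every pixel (58 nm), with each profile sample
the average of the 5 pixels nearest the backbone in y. The tip is the
midpoint of an erfc fit to that profile; its spread σ_MT reflects the PSF
broadened by protofilament-length taper. Columns whose Gaussian fit
diverges, or whose amplitude falls below 30% of the on-lattice median, are
excluded from the line fit; frames whose tip fit fails are flagged, and
episodes with > 5% flagged frames are rejected. Nonlinear fits initialize
from quantile/crossing heuristics with non-negative amplitudes.

Stage drift is removed with the averaged track of stationary fiduciary
marks (10 by default): x-drift is subtracted directly; y-drift is absorbed
by the per-frame backbone re-fit, leaving only the `sinΘ·Fid_x` coupling
term. For rigid translation at Θ = 0 the correction is an exact inverse
(property-tested). The tracker assumes a single, near-horizontal
microtubule per region; it is not a general filament tracer.

## Model convolution

Each dimer is a point source at its lattice position (13 protofilaments on
a 25-nm-radius cylinder, 8.2-nm axial rise, 3-start-helix stagger of
1.5·8.2/13 ≈ 0.95 nm per protofilament, included in rendering even though
the contact topology discretizes it). Sources are deposited bilinearly on
the 58-nm pixel grid, blurred with the Gaussian PSF (FWHM 250 nm), and
scaled so a fully formed backbone cross-section peaks at 1160 counts above
the 22,300-count background on the 16-bit scale — the "1160" calibration is
interpreted as that peak contrast (5.2%), with the per-dimer photon budget
back-computed from it. Noise is additive Gaussian with SD 181 (matching the
background-SD calibration) rather than Poisson. The experimental
post-processing — invert, min–max scale to 8 bits per stack — is provided
and used before tracking. Tapered ends follow the linear rule: lengths
step up from protofilaments 1 and 13 to the center one (max − min = taper,
rounded to dimers).

**Taper detection threshold.** Rendered images over a taper grid are
tracked with the full backbone + erfc pipeline; the threshold is where the
mean σ_MT curve crosses the blunt-end mean + 2 blunt-end SD, interpolated
between grid points. The "2 SD above blunt" rule is this package's
formalization of "distinguishable above the point spread function". At the
printed calibration this lands near 265 nm; the value scales with the
per-image σ_MT scatter, which in turn depends on the profile length used
in the fit (the calibration uses an ~80-pixel backbone plateau).

## Parameter fitting

The objective simulates `replicates` episodes per concentration, analyzes
them exactly as data, and accumulates `(1/SEM)·(sim − target)²` over
concentrations (rates, plus variances when enabled — the SEM-weighted
squared error form was an open choice, made to match the 1/SEM fit
convention). Replicate seeds are frozen across evaluations (common random
numbers), so the objective is deterministic given parameters; final
statistics are re-simulated with fresh seeds. Optimization is nested: for
each corner affinity on a log grid, the longitudinal affinity is optimized
by a bounded 1-D search — the objective basin is far narrower in K_D_long
(roughly ±20%) than in K_D_corner, so a joint coarse grid misses it — and
the best pair gets a short Nelder–Mead polish on
`(log K_D_long, log K_D_corner)`; optima at a range boundary are flagged. Inside fitting loops a reduced lag set
(16 windows spanning 0.2–30 s) replaces the full n = 2…300 grid for speed;
the estimates agree, only their per-episode noise differs slightly.

The GDP weakening factor is calibrated by bisection on log X against the
mean shrinkage speed of an all-GDP lattice (400 layers above the seed, zero
tubulin, slope of mean length vs time until the lattice nears the seed).
The measured shrinkage target is deliberately a configuration input; the
package default of 500 nm/s is a typical depolymerization speed
(~30 μm/min) for dynamic mammalian-brain microtubules. GTPase scans then
sweep `k_GTPase` at fixed concentration, reporting growth rate, growth
variance, mean GDP exposure, and the fraction of episodes that collapse
back to the seed (a point where most do is flagged).

## Synthetic data

`gen_trace` produces `L(t) = v·t + W(t) + ε` with Brownian `W`
(`Var W(t) = 2Dt`), iid frame noise ε (SD σ_i), and optional linear +
sinusoidal stage drift; `gen_fiduciaries` makes noisy copies of the drift
path and their average; `gen_bundle` assembles a whole concentration-series
"experiment" (manifest + trace files) from linear rate/variance laws. The
generator emulates the statistical structure of tip recordings — drift,
diffusion-like growth fluctuation, frame noise — but not catastrophes,
tracking dropouts, or temporally correlated noise; iid noise is exactly the
assumption behind the 1/Δt decay of the short-lag variance, so passing
round trips validate the estimators under the model's own assumptions, not
against every pathology of real movies.

## Problem sizes and numerical choices

Headline recomputations (`scripts/acceptance.py`) use the full protocol of
50 × 600-s episodes per condition; the test suite runs the same pipelines
at 8–16 replicates and 300–600 s, with tolerances that widen with the
replicate SEM. The taper calibration uses 256² crops (the full 1024² frame
adds only empty background), 50-nm grid and 30 replicates in the headline
run. Nonlinear fits use `scipy.optimize.curve_fit` with bounded
parameters; lattice capacity is pre-allocated from the association-rate
upper bound `k_on·[tub]·t` and doubled on overflow; all simulations are
reproducible from a single integer seed.

## Known limitations

No GDP→GTP exchange, no GDP·Pi intermediate, no beyond-nearest-neighbour
or mechanochemical (bending-spring) energetics, no minus-end dynamics, and
no catastrophe/rescue frequency statistics — the model targets elongation
and its fluctuations. The seam stagger and several tracker details (ROI
half-width, re-centering) are conventions exposed as configuration, with
measured sensitivities noted above. Growth variance at the GMPCPP-like
best-fit parameter set comes out near 1.2 nm²/s by this implementation's
event rules, lower than the ~3.1 nm²/s the same estimator reports for the
original simulation code at the printed parameters; the discrepancy is
documented rather than absorbed into re-tuned parameters, and the
concentration-series intercepts inherit a related low-concentration
suppression.
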