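# mtgrowth

Kinetic Monte Carlo simulation and fluctuation analysis of microtubule
growth.

Microtubules elongate by addition of αβ-tubulin dimers to the ends of their
13 protofilaments. Mean growth rates alone cannot distinguish between
"fast-binding / weakly-bound" and "slow-binding / strongly-bound" pictures
of tip biochemistry — very different rate constants predict the same
concentration dependence. Fluctuations *around* the mean growth rate break
that degeneracy. This package implements, end to end, the computational
machinery needed to exploit them:

* **`lattice` / `kernel` / `sim`** — a kinetic Monte Carlo model of the
  13-protofilament lattice. Association onto each protofilament end occurs
  at `k_on·[tubulin]`; dissociation of a terminal dimer at `k_on·K_D`, where
  free energies of contacts add:
  `K_D = K_D^long · (K_D^corner / K_D^long)^n_lat` for `n_lat` lateral
  neighbours. The nucleotide acts in *trans*: a GDP at a longitudinal
  interface weakens it by a factor `X ≥ 1` (`K_D(GDP) = X·K_D(GTP)`), and
  hydrolysis (rate `k_GTPase`) only targets dimers buried under a
  longitudinal neighbour. A compiled (numba) core simulates hundreds of
  600-s episodes per minute; a readable pure-Python reference implementation
  of the same event rules backs it in the test suite.
* **`trace_stats`** — growth-rate and growth-variance estimators for tip
  traces sampled at 10 frames/s: block-mean downsampling at windows
  n = 2…300, pooled displacement distributions per lag Δt = n·t_exp, a
  through-origin line `μ_ΔL = v·Δt` for the rate, and the biphasic variance
  fit `σ²_ΔL(Δt) = 2DΔt + σ_i²/Δt` separating diffusion-like growth
  variance *D* (lags ≥ 10 s) from per-frame measurement noise σ_i.
* **`tip_tracking`** — sub-pixel tip localization in image stacks:
  per-column Gaussian backbone fits, an erfc (Gaussian survival function)
  fit `I(x) = ½·I_MT·erfc((x−μ_MT)/√2σ_MT) + I_bg` for the tip position and
  spread, and fiduciary-based stage-drift correction
  (`ΔLx = μ_x − B_x − Fid_x`, `ΔLy = μ_y − B_y − sinΘ·Fid_x`).
* **`render`** — model convolution: synthetic IRM-like images of
  microtubules with defined end tapers (13 protofilaments, 25-nm radius,
  8.2-nm dimers, 3-start helix), rendered with the calibrated point spread
  function (250 nm FWHM), contrast (5.2%) and noise (SD 181/65535), used to
  benchmark the tracker and calibrate taper detection.
* **`param_fit`** — SEM-weighted fitting of the two affinities to
  growth-rate (and optionally fluctuation) data with common random numbers,
  calibration of the GDP weakening factor against a target shrinkage speed,
  and GTPase-rate scans.
* **`synthetic`** — drift-diffusion tip-trace generator (known v, D, σ_i,
  optional stage drift) so every analysis stage is testable against ground
  truth.

## Worked example

Estimating growth statistics from a synthetic 900-s recording
(`examples/02_fluctuation_analysis.py`):

```
ground truth: v = 5.0 nm/s, D = 10.0 nm^2/s, sigma_i = 3.5 nm
estimated:    v = 4.81 nm/s
              D = 8.34 nm^2/s (expected ~6.7 under the block-mean convention)
      sigma_i = 2.73 nm  (R^2 of linear regime: 1.000)
```

The rate comes back within a few percent. The printed D follows the
block-mean convention of the published procedure (differencing adjacent
block means of a Brownian path recovers 2/3 of the generating D — see
`docs/methods.md`), so ~6.7 is the expected readout for a generating D of
10; single 900-s episodes scatter around it by roughly ±30%.

A simulated concentration series (`examples/03_concentration_series.py`,
8 × 300-s episodes per concentration at the GMPCPP-condition best-fit
parameters):

```
 concentration  mean    sd   sem  n
           0.5 0.505 0.028 0.010  8
           0.7 0.803 0.038 0.013  8
           1.1 1.468 0.084 0.030  8
           1.3 1.875 0.072 0.026  8
           1.5 2.271 0.094 0.033  8

weighted fit: slope 1.74 nm/s/uM -> k_on_app 2.76 uM^-1 s^-1
x-intercept (apparent critical concentration): 223 nM
```

Growth rates rise linearly with tubulin concentration; the slope converted
to subunits/s/μM is the apparent on-rate constant, the x-intercept the
apparent critical concentration. The other scripts in `examples/` cover
single-episode simulation, rendering + tracking, taper calibration, and the
GTPase scan, each printing what the numbers mean.

A thin CLI mirrors the main workflows
(`mtgrowth simulate|analyze-trace|synth|render|track|fit|scan-gtpase`);
see `mtgrowth --help`.

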