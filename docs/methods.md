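# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `npckinetics`, in the order a user meets them.

## Count table and densities

The bundled tomography table (`npckinetics/data/table1_counts.tsv`) holds
one row per cell × envelope region: analyzed surface area (µm²,
shrinkage-corrected), counts of mature pores, assembly intermediates and
ONM/INM fusion events, at a known time after anaphase onset (tAO). The
table was transcribed from a typeset summary table whose plain-text
rendering concatenates digits; the fixture header documents the two
residual ambiguities (one intermediate-count digit, restored uniquely from
the caption totals and the quoted ~50% early-G1 inner-core intermediate
fraction; and the column placement of the five fusion events, which no
analysis depends on).

Densities are counts/area. Pooling is ratio-of-sums (counts and areas
summed before division) with the across-cell standard deviation reported
separately; for a partition of a selection, area-weighted pooling of the
parts equals pooling the union, which the tests assert. The "early G1"
window for intermediate fractions defaults to tAO ≤ 60 min — the first
hour, i.e. the six cells at 19.2–53.2 min; with this convention the
non-core and inner-core fractions are 7.8% and 50.9%, matching the rounded
published 8%/50%. Both ratio-of-sums and mean-of-per-cell-fractions are
offered (they differ by <6% here); ratio-of-sums is the default.

Shrinkage: plastic-section lengths divide by (1 − s), areas by (1 − s)²,
with s estimated from mature-pore diameters in plastic vs cryo tomograms
(observed values ~22% for Lowicryl, ~15% for EPON). The bundled areas are
already corrected.

## Nuclear surface growth

`A(tAO) = a0 + a1(1 − exp(−kg1·tAO)) + kg2·tAO` (µm², tAO in min) captures
a fast G1 expansion on top of slow linear growth. Published parameters
(a0 = 424 µm², a1 = 161 µm², kg1 = 0.0722/min, kg2 = 0.397 µm²/min) ship
as `PRINTED_GROWTH`. Fitting excludes data beyond 17 hr (second mitosis),
uses ≥10 multi-starts over log-scaled (a1, kg1, kg2) to avoid the a1/kg1
trade-off, and reports profile-likelihood CIs. All regions are assumed to
grow isometrically, so the same A(t) shape applies per region and cancels
out of densities.

## Delay-equation maturation model

State variables per region, in counts over the region surface: I (not yet
maturing), Im (inside the maturation delay), M (mature); IT = I + Im is
what tomograms count. Equations and variants are in the README. Fixed
constants: τS = 10 min (sealing; a 0–15 min sweep changes τS + τM by <1%,
asserted in the tests), kd = 1/(40 hr) ≈ 0.00042/min (pore lifetime),
σ² = 2.18 pores²/µm⁴ (mean measurement variance, scaling the objective),
and the basal initiation rate v0 = 0.015 intermediates/µm²/min. The v0
value is fixed by the steady-state identity iT* = v0·TM together with the
observed mature-envelope intermediate density (~0.7/µm²; the model then
also reproduces the published mature-envelope statistics 11.5 ± 1.3
NPCs/µm² and ~0.65 intermediates/µm² over 3–20 hr, weighting inner:outer
core 0.68:0.32 by surface-area share).

### Integration

Each compartment is linear with a known decay constant, so the integrator
advances it with the exact decay factor and a piecewise-linear quadrature
of its forcing (exponential integrator; second order, unconditionally
stable), implemented as a constant-coefficient recursion
(`scipy.signal.lfilter`). Three refinements matter in practice:

* the internal step (default ≤ 0.25 min) also resolves the 1/kM initial
  transient of burst runs, floored at 1e-3 min to bound the grid; stiff
  decay beyond that floor is handled exactly by the decay factor;
* delayed values I(t − τM) are looked up by monotone (PCHIP)
  interpolation — global cubic splines ring on the sharp initial transient
  and linear interpolation puts derivative kinks in the fitting objective
  at every grid node, both of which visibly corrupt optimization;
* for burst initial conditions the homogeneous component I0·exp(−kM·t)
  makes the delayed forcing jump discontinuously at t = τM; its
  mature-pore response is superposed in closed form, and only the
  continuous production-driven part is integrated numerically. Im is
  computed from the exact balance ∫I = (I(0) − I(t) + ∫V)/kM rather than
  by quadrature of the near-singular integrand.

A brute-force explicit-Euler history-buffer solver lives in the test suite
as an independent oracle; agreement is asserted to <0.1% on full burst
trajectories. The multi-step chain (N − 1 equal-rate compartments,
TM = (N − 1)/kM, Erlang-distributed maturation) reduces exactly to the
τM = 0 delay model at N = 2 and converges to the fixed-delay solution as N
grows; the distributed-delay model (uniform τM ± w, composite Simpson over
the support) reduces exactly to the fixed delay at w = 0.

### Fitting

At fixed nonlinear rates (kM, τM, and kv for the decaying variant) the
trajectories are linear in the initial densities and production
amplitudes, so those are solved exactly by bounded linear least squares
(variable projection); the outer problem — multi-start bounded least
squares in log/linear coordinates (bounds kM ∈ [1e-3, 20], τM ∈ [0, 120])
— is then 2–3 dimensional and converges to the same optimum from 16 starts
across seeds. The objective is the variance-scaled sum of squared
residuals over both observables and both core regions (n = 48 residuals
for the bundled table). On these data the likelihood is flat in kM above
~1/min (the published fit reports the same: its kM interval runs into the
bound 20), while TM = 1/kM + τM is well determined: the refit gives
TM = 43.2 min for burst initiation and 18.4 min for constant production.
m(τS) is fitted per region for every variant; i(τS) only for the burst
variant (zero otherwise).

### Confidence intervals

95% CIs use the profile likelihood: φ(p) = n·log(F(p)/F_min) < 3.84, the
scanned parameter moved on a monotone grid (60 points per side by
default), nuisance parameters re-optimized warm-started at every point,
and the crossing located by root refinement with re-optimization inside
the bracket. Intervals that run into a parameter bound are flagged open
rather than failing. The CI for TM is profiled directly through the
reparametrization τM = TM·s, kM = 1/(TM(1 − s)) with s ∈ [0, 1) — tracing
the per-parameter profile paths instead systematically under-covers, which
the parameter-recovery test demonstrated. On a linear-Gaussian toy problem
the profile CI matches the closed-form endpoint
SSR = SSR_min·exp(3.84/n) to the root-finder tolerance and the classic
1.96·SE interval to O(1/n).

## Sequential recruitment model

Each NPC passes irreversibly through (no marker) → (Nup107) → (Nup107 +
Nup358) with rate constants k, l per pool; the postmitotic pool starts at
4 min, the interphase pool at sealing (10 min); degradation and new
production are neglected over 0–125 min. The chain is solved in closed
form (with the degenerate k = l limit handled explicitly) and verified
against a numeric ODE oracle to 1e-6. Region curves mix pools with the
postmitotic fraction f_pm (0.92 non-core, 0.5 inner-core, from the density
data). The four rates are fitted jointly to the four intensity tracks
(Nup107/Nup358 × non-core/inner-core, 4–125 min); each model curve is
multiplied by a fitted per-track normalization coefficient bounded in
[1, 1.1] before comparison — the data normalization puts the observed
plateau near 1 while the model plateau is exactly 1, and applying the
coefficient to the model rather than the data keeps the noise model on the
data side. Half-times are reported for both reference conventions
(pool start and anaphase onset) because the published t1/2 values (15 min
for Nup107, 51 min for Nup358) do not state theirs; the closed-form
reproduction lands at ln2/k_ip ≈ 18.5 min and ~52.6 min from pool start,
near but not exactly on the published values, and no attempt is made to
force agreement.

## Morphometry

INM traces are rigidly aligned so the flat flanking membrane (least-squares
line through the outer 25% of points per flank) becomes the x-axis with
the evagination pointing +y; a flank RMS above 5 nm means no identifiable
baseline and is an error. Traces are interpolated to a 1-nm grid with an
Akima local spline — exact on uniformly sampled parabolas, and free of the
ringing a global cubic spline produces at the sharp dome–flank junction —
then smoothed with a moving local second-degree polynomial
(Savitzky–Golay), window 15 nm by default (configurable; the cited
upstream method does not state its parameters). Depth is the maximum
height above the baseline. Width (diameter) is the distance between the
outermost crossings of a near-baseline threshold (default 2 nm) and is
measured on the unsmoothed interpolation (`window_nm=0`): the moving
window smears width outward by half its length. This profile-based width
is a documented stand-in for the study's manual top-view diameters; tables
of manual values are accepted and never silently mixed with profile-based
ones. The threshold sits in the flank-noise floor for ±1 nm click jitter;
the tests use 3 nm there and compare against the cap chord at that height.
ONM/INM distance is the median foot-of-normal distance from INM to ONM at
50 stations placed 45–90 nm from the pore edge (both sides when
available), robust to local bumps. Averaged profiles are apex-centered,
resampled on the common grid, and reported with pointwise s.d.; by
convexity the depth of the mean never exceeds the mean depth.

## Line-scan ratio analysis

Two-channel NE line scans at 20 nm/pixel are summed in 15-pixel (300 nm)
segments, the trailing partial segment dropped. The Nup358 channel is
rescaled so the median (optionally mean) Nup107/Nup358 ratio over non-core
reference segments — essentially all mature, double-labelled pores — is 1.
The intermediate frequency is the fraction of segments with ratio strictly
above 2.0; zero-Nup358 segments count as high with a warning. An optional
5th-percentile background subtraction is off by default (the upstream
quantification does not mention one). The frequency is invariant under
common rescaling of both channels and non-increasing in the threshold.

## Synthetic data

The generators produce every input the pipeline consumes, deterministic
per seed (one `numpy` Generator per call):

* **Counts**: Poisson draws, `n ~ Poisson(density × area)`, independently
  per tomogram, on the bundled table's design (12 times at 19.2–116 min,
  inner + outer core, areas uniform in 2.5–7 µm²); fusion counts are rare
  Poisson events. Ground-truth defaults are the burst-variant model at the
  published rates (kM = 1.357/min, τM = 43.03 min) with initial densities
  from the fit to the bundled table.
* **Intensity tracks**: closed-form recruitment curves at the published
  rates × (1 + ε), ε ~ N(0, 0.02), f_pm mixing per region.
* **Profiles**: circular-arc caps on flat baselines with isotropic
  Gaussian click jitter (default 1 nm), plus a flat ONM at a stated
  separation; the depth/diameter schedules default to the published
  medians (16/22 nm at 19/28 min; 51/58 nm at 19/53 min; 28/61 nm for
  fusion events).
* **Line scans**: 1-D Poisson pore positions, Gaussian spots of 60 nm
  effective PSF width, log-normal amplitudes, a Bernoulli fraction of
  intermediates dark in the Nup358 channel, channel gains and additive
  noise.
* **Growth series**: the growth law × (1 + ε), ε ~ N(0, 0.05), every
  10 min to 17 hr (the live-imaging acquisition design).

What the emulation does not capture: spatial correlation between
neighbouring tomograms of one cell, non-Poisson clustering of pores,
bleaching and segmentation errors in the intensity curves, anisotropic
click jitter, and membrane undulations under the dome. Passing the
recovery tests therefore shows the estimators are correct under the
analysis' own statistical assumptions, not that those assumptions hold for
any particular microscope.

## Problem sizes used by the test suite

The suite fits the bundled table with 16 multi-starts (the optimum is
reached from many fewer), runs the parameter-recovery study at 20
replicates of the table-cloned design with a 12-point-per-side TM profile,
uses 20 replicates for the growth-recovery study and 5–39 synthetic
profiles/line scans per morphometry statistic. These sizes give stable
medians and coverage estimates while keeping the whole suite around three
minutes on one CPU.

## Known limitations

* The bundled table inherits one transcribed digit restored by arithmetic
  (documented in the fixture header); the burst-variant TM estimate is the
  quantity most sensitive to it, and moves by a few minutes — within the
  published confidence interval — under the alternative repair.
* kM is effectively unidentifiable above ~1/min on these data; only
  TM = 1/kM + τM should be interpreted.
* The profile-based diameter is a different measurement from manual
  top-view diameters (it estimates the cap chord at the threshold height);
  compare like with like.
* Recruitment normalization coefficients are bounded in [1, 1.1] by
  convention; data normalized differently need rescaling first.
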