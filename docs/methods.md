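# Methods

This note documents the models behind `dsbquant`'s generators and
estimators, the defaults and why they were chosen, and what the synthetic
data do and do not establish about real assays.

## The resection model and its estimator

A culture of cells arrested in G2/M (nocodazole) carries a single inducible
DSB. The generator models each cell independently:

- with probability `cut_fraction` (default 0.95) the cell is ever cut; cut
  times are Exponential(`cut_rate`) with rate 3/h (instantaneous cutting,
  `cut_rate = inf`, is supported for analysis of the estimator itself);
- resection starts `init_delay_h` after cutting (default 0) and proceeds
  unidirectionally at a per-cell speed V ~ Gamma(mean `speed_mean_kb_h`,
  CV `speed_cv`); the presets use CV = 0 (a single population speed), the
  parameter exists so estimator bias under speed heterogeneity can be
  studied;
- an amplicon at distance d > 0 has lost its signal in a cell once
  V·(t − T − delay) ≥ d; the emitted quantity is the unresected fraction
  across `n_cells` cells (the same cells at every timepoint, as when one
  culture is sampled repeatedly), times multiplicative lognormal noise
  (σ = 0.05 — qPCR quantities are ratio-scale, so noise is multiplicative);
- the control amplicon at an uninvolved locus emits 1 × noise.

Arrest is modelled as the complete absence of cell-cycle dynamics: no
division, no phase change, resection continues indefinitely. The generator
equates normalized qPCR signal with the double-stranded (unresected)
fraction directly; it does not model the assay chemistry (e.g. a
restriction-digest step) that produces that proportionality in practice.

`expected_unresected_fraction` gives the noise-free population expectation
1 − p_cut·P(T + delay + d/V ≤ t): closed-form for CV = 0, Gauss quadrature
over the Gamma speed density otherwise. It is the oracle against which the
Monte-Carlo generator is tested (agreement within 3 binomial standard
errors across the distance × time grid).

The estimator mirrors standard practice for this assay:

1. double normalization to control locus and t = 0 (Cq input converted with
   a fixed efficiency of 2, i.e. perfect doubling; per-amplicon efficiencies
   are out of scope);
2. threshold crossing at θ = 0.75 (a default, exposed as `--threshold`) on
   each timepoint's signal-vs-distance curve, linearly interpolated between
   the nearest amplicons. Crossing detection is direction-agnostic: it
   first detects the curve's orientation (signal may be presented rising
   away from the break, as the population model produces, or falling, as
   some plots are drawn) and then takes the **last** bracketing pair of
   adjacent amplicons in that orientation. Curves that never bracket the
   threshold are dropped and logged; no extrapolation beyond the amplicon
   grid or time range. The transposed orientation (`time_at_distance`) is
   available as an option.
3. OLS of crossing distance on time. Slope = front velocity (kb/h);
   x-intercept = onset lag. The threshold is applied to the replicate-mean
   (geometric mean) curve; per-replicate fits are computed alongside and
   their min–max range reported, matching the field's range bars.

Properties of this estimator, verified in the test suite:

- deterministic limit: with no noise, no speed dispersion, instantaneous
  cutting and amplicon spacing δ, |slope − v| ≤ δ/(t_last − t_first);
- with per-cell speed dispersion and instantaneous cutting, the fitted
  slope converges to the q-quantile of the speed distribution with
  q = 1 − (1 − θ)/p_cut — the estimator reads out a population quantile,
  not the mean, which is why `speed_cv` is exposed;
- plate-scale effects cancel exactly (control-locus division), and the fit
  is equivariant under distance scaling and time shifts.

With the preset study conditions (10⁴ cells, amplicons at 0.7–30 kb, hourly
samples over 0–8 h), single-run recoveries are within 10% of the generative
speed and 25-seed medians within ~5%. The residual 2–5% systematic
deviation is interpolation bias: the population signal curve is convex
between amplicons, so the chord crossing sits slightly off the true front,
by an amount set by the grid geometry relative to the front speed. This
bias is a property of the published quantification procedure itself, not of
the implementation; an optional isotonic pre-smoothing flag was considered
and rejected as it does not address the chord geometry.

## ChIP enrichment model

Fold-enrichment around the break follows

E(x, t) = 1 + (E_max − 1)·(1 − e^(−t/τ_on))·1[|x| ≤ spread],

with E_max = 40, τ_on = 1 h and spread = 30 kb in the presets, so the mark
peaks at 1–2 h and reaches the 30 kb amplicon. Two terminal behaviours are
mutually exclusive per locus: after repair at `repair_time_h` the excess
enrichment decays as e^(−(t−t_rep)/τ_off) (τ_off = 0.5 h); after
checkpoint-kinase inhibition at `caffeine_time_h` the establishment term is
frozen and multiplied by `decay_factor_per_h`^(t−t_caf) (0.99/h — a mild
loss, as continued maintenance no longer requires kinase activity). The
plateau value 40 is a configuration choice: it is large enough that the
kinase-inhibited locus stays above 30-fold at 5 h (the generated value is
33.7-fold) while the repaired locus falls below 2-fold within 2 h of repair.

The analysis stage reconstructs E as the double ratio
[(IP/input)_locus / (IP/input)_control] / [same at t=0]; a percent-of-input
mode (no control-locus division) is available as a flag. Spreading extent
uses grid positions only — the underlying claim ("more than 30 kb") is
qualitative, so interpolating beyond the outermost amplicon would
manufacture precision.

## Blot model and presets

The untreated band level rises linearly from 1 to `induction_fold` by
`ref_time_h` (default: the last lane); the treated level follows it until
`treat_time_h` and then decays exponentially with `half_life_h`. Lane
intensity multiplies in a loading level, a global exposure factor and
lognormal noise, so all reported quantities are exposure-invariant by
construction.

Preset half-lives are solved in closed form from the fold-change
constraints they must reproduce: `sae2_caffeine` (induction 2-fold by 4 h,
treatment at 0.5 h) requires level(4 h) = t0/3, giving
t_half = 3.5/log₂(3.375) ≈ 1.99 h and automatically a 6-fold deficit
against the untreated lane; `dna2_caffeine` requires a 5-fold deficit,
giving t_half ≈ 2.35 h; `sae2_chx_cycling` uses t_half = 0.25 h, consistent
with complete loss within one hour of translation shutoff.

Half-life fitting is log-linear least squares over lanes at t ≥ treatment —
robust at the 3–6 timepoints these chases have; a nonlinear refinement
would add parameters the data cannot constrain. A non-decaying series
produces a warning and a signed rate rather than an error. Fold-changes
below 1 are reported as "x-fold reduction" (the reciprocal), matching how
gel results are phrased. The SSA repair fraction scales the
loading-normalized product band to the untreated plateau (final untreated
lane = 1); the product band may legitimately be zero.

## Foci and the rank-sum test

Counts per nucleus are negative-binomial (size 5 in the presets — visibly
overdispersed relative to Poisson, as focus counts are), 75 nuclei per
experiment × 3 experiments, pooled across experiments for testing (the
stratified per-experiment test is out of scope). Preset means (20 RPA, 15
Rad51 foci) are configuration choices; the treated presets divide the mean
by the generative suppression folds 7 and 3.

The Wilcoxon rank-sum test is implemented directly. Midranks are assigned
over the pooled sample. For pooled n ≤ 16 the null distribution of the
smaller sample's rank sum W is enumerated exactly over all C(n, n₁)
assignments (≤ 12 870 configurations); this is an exact permutation test
and remains exact under ties. Otherwise the normal approximation is used
with continuity correction and tie-corrected variance
n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))]. The two-sided p doubles the smaller
tail, capped at 1 (one-sided alternatives are available); fully degenerate
pooled samples return p = 1 with a flag. At n = 8+8 the one-sided exact and
normal p agree within 0.0055 everywhere; the two-sided p, which doubles the
approximation error, agrees within 0.01 outside the null distribution's
centre and 0.011 globally — doubling the tail necessarily doubles the
worst-case deviation, so 0.011 is the attainable global bound. Exhaustive
comparison against an independent implementation (scipy) is part of the
test suite; the exact test's type-I error at α = 0.05 is calibrated to
5% ± 1.5% under the negative-binomial null.

## Problem sizes

The defaults throughout — 10⁴ simulated cells, 9 amplicons, 9 timepoints,
25 seeds for medians, 2 000 null simulations for type-I calibration, 10⁵–10⁶
cells/draws for Monte-Carlo-vs-closed-form checks — were chosen so each
check resolves its target tolerance with margin (e.g. binomial standard
errors an order of magnitude below the tolerance being asserted) while the
full suite runs in well under a minute.

## Limitations

- The generator equates normalized signal with the unresected fraction; real
  qPCR adds amplification-efficiency variation per amplicon, which the
  estimator deliberately ignores (efficiency fixed at 2).
- Resection is single-sided and linear in time; no nuclease identity, no
  two-sided fitting, no nonlinear front models.
- ChIP is locus-directed; there is no peak calling or genome-wide mode.
- Band intensities are taken as given; image densitometry is upstream.
- Passing tests demonstrate correctness of the quantification procedures
  under the stated generative models, not the biological claims themselves:
  the synthetic data lack plate-position effects, amplicon-specific
  efficiencies, chromatin-context ChIP biases and segmentation errors in
  focus counting.
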