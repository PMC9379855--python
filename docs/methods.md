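# Methods

## metAFLP event coding

The two platforms differ only in methylation sensitivity: KpnI cuts its site
whenever the sequence is intact, Acc65I only when it is also unmethylated.
Two consequences fix the classification of the 4-digit code
`(aD, aR, kD, kR)`:

* within one plant, an Acc65I band without the KpnI band (`a=1, k=0`) is
  physically contradictory → INCONSISTENT (7 of the 16 codes);
* a KpnI difference between donor and regenerant means the site sequence
  changed → SV (codes 0001, 0010, 0101, 1010); with the sequence intact in
  both plants, the Acc65I difference reads out methylation: 1011 = DNMV
  (band lost in the regenerant, methylation gained), 0111 = DMV. 1111/0011
  are unmethylated/methylated no-change, 0000 is uninformative.

This table is a reconstruction from the stated enzyme logic; published
scoring schemes that deviate can be mirrored through the `reassignment`
mapping accepted by `classify_code`.

Percentages are taken over *informative* loci — every code except 0000.
INCONSISTENT codes stay in the denominator but belong to no event class;
`inconsistent_as_sv=True` folds them into SV, since some scoring traditions
treat any regenerant-side contradiction as a sequence change. TCIV is the
sum SV% + DMV% + DNMV%.

Context assignment from the selective primer 3′ extension uses
longest-suffix precedence: `C-H-G` (H ∈ {A,C,T}) → CHG, then `CG` → CG, then
two bases from {A,T} → CHH; anything else is reported and the locus
excluded. Technical replicates of one plant can be merged by logical OR
(default; a band seen in either replicate is real) or AND (strict).

## FTIR preprocessing

Processing order: baseline correction → unit-area normalization → band
integration. The default baseline is the rubberband (lower convex hull);
linear-endpoints and asymmetric least squares (second-difference penalty
λ = 1e7, asymmetry p = 0.01) are alternatives — the instrument vendor's
algorithm is proprietary, so no bit-level match with any instrument output is
attempted. Normalization scales the *whole* spectrum by the factor that
makes the 900–1,800 cm⁻¹ trapezoid area 1, so the 2,540–2,550 cm⁻¹ thiol
feature is measured on the normalized spectrum; whether to normalize at all
is a pipeline switch (`--no-normalize`).

All integrals are trapezoid rules with interpolated window edges; the
quadrature error is O(h²/σ²) in the grid step h and band width σ, so values
are stable under grid refinement. Binning tiles 600–1,780 and
2,450–3,700 cm⁻¹ into half-open [lo, hi) 10 cm⁻¹ bins (final bin closed);
the 1,800–2,450 cm⁻¹ region is excluded throughout because atmospheric CO₂
and water vapour dominate it. The default bin statistic is the bin integral
(absorbance·cm⁻¹), with `mean` and `sum` options since plain per-bin
summaries are also in use. Bins not fully covered by the grid are flagged
missing (NaN), never zero-filled. Trial-level SD/mean curves interpolate all
spectra of a trial to a common 1 cm⁻¹ grid, use the n−1 SD, and mark
zero-mean points as undefined rather than infinite.

## Path-model engine

Scope: observed variables only, acyclic directed paths, uncorrelated
residuals, no mean structure (covariance-only fitting). Degrees of freedom
are p(p+1)/2 − (paths + p variances).

Conventions, all chosen to match the mainstream SEM-software defaults and
configurable where noted:

* sample covariance with denominator **n−1** (`ddof` argument);
* χ² = **(n−1)**·F_min (`chi2_multiplier="n"` available);
* parameter covariance = inverse information matrix of ((n−1)/2)·F_ML,
  Hessian taken by central differences at the optimum; critical ratio =
  estimate/SE with two-sided normal p-values, no multiplicity adjustment.
  A closed-form consequence used as a self-check: every variance
  parameter's critical ratio equals √((n−1)/2);
* standardized coefficients use **model-implied** SDs:
  β = b·SD(source)/SD(target);
* incremental indices use the independence baseline (free variances, zero
  covariances), whose discrepancy is −ln|R| in closed form; SRMR is computed
  on correlation-metric residuals, RMR on raw covariance residuals;
* at df = 0, RMSEA, RFI and AGFI are undefined and reported as NaN.

Numerics: variables are rescaled internally to unit sample variance, which
keeps all free parameters O(1) even when raw scales differ by 10⁵ (the thiol
integral is ~0.005 while Cu spans 0.1–10 µM, putting its GPRE coefficient
near 750 on the raw scale). The optimizer is BFGS with an analytic gradient,
started at the per-equation OLS solution. For this model class the
likelihood factorizes over equations, so the OLS start *is* the ML optimum
and the polish step normally converges in zero iterations; the optimizer
still runs so that configurations outside the closed-form case (or
user-fixed parameters in the future) are handled. Convergence requires
gradient norm < 1e-8; non-convergence is flagged and warned, never silent.

Effects: the total-effect matrix is (I−A)⁻¹ − I. The reported total is
recomposed as direct + indirect so the additivity identity holds bit-exactly
in floating point.

On the packaged 37-regenerant table the five-variable model gives χ² = 0.110
on 2 df (p = 0.95), GFI 0.999, SRMR 0.014 — values the test suite and
`scripts/acceptance.py` recompute from scratch. Two internal inconsistencies
of that observation table's published context are worth noting for users
comparing against other software: the correlation between Cu and CHH_DNMV
necessarily equals the standardized Cu→CHH_DNMV coefficient (+0.32, the only
path into it from the sole exogenous variable), and the sign of the Cu→GSH
critical ratio follows the positive Cu–GSH correlation.

## Synthetic data

* **Markers**: every donor locus carries a KpnI band (loci enter the panel by
  being scored in the donor) and is methylated with probability
  `meth_share = 0.3`. Events are drawn per regenerant with the *unconditional*
  rates requested — DMV can only occur at methylated and DNMV only at
  unmethylated donor loci, so the conditional probabilities are rescaled
  accordingly — which makes generator → quantification round trips unbiased
  to binomial error. Default rates are the study's per-context means (CHH:
  SV 8.65%, DNMV 0.58%; CHG: 23.64/2.90/1.82%; CG: 11.66/1.42/1.11%;
  CHH DMV unreported, default 0) at 10,000 sites per context with a 1%
  inconsistency rate. The published per-regenerant CHH_SV values span only
  8.48–8.91% with 0.01-pp granularity, i.e. a sampling SE near 0.09 pp; the
  dispersion-matching tests therefore run at 100,000 CHH sites, the
  effective site count implied by that spread.
* **Spectra**: Gaussian band library at the canonical leaf positions (broad
  3,324 cm⁻¹ O–H/N–H, 2,925 C–H, Amide I/II, 1,399, and the carbohydrate
  fingerprint at 1,048 cm⁻¹) plus an S–H band at 2,545 cm⁻¹ whose amplitude
  is calibrated in closed form (erf) so the unit-area-normalized
  2,540–2,550 cm⁻¹ integral equals the configured per-trial level; defaults
  are the per-trial means of the packaged table (0.0046–0.0055). Noise is
  white Gaussian (SD 5e-4), drift a slow random-phase sinusoid (amplitude
  0.01), and band amplitudes jitter by 3% between regenerants. What this
  does *not* emulate: instrument line shapes, ATR penetration-depth effects,
  correlated noise, water-vapour fine structure — so passing tests
  demonstrate correctness of the processing algebra, not robustness to every
  real-instrument artifact.
* **Observations**: exogenous Cu is drawn from the design levels
  {0.1, 5, 10} µM with the empirical trial multiplicities; endogenous
  variables follow in topological order with Gaussian residuals (uniform
  residuals available as a robustness stress; asymptotic-normality arguments
  make Gaussian the reference case). `study_sem_config()` builds the
  configuration by *fitting* the packaged table, so simulation truth is
  computed, never transcribed. Rows are independent, mirroring the published
  analysis even though GPRE is constant within a trial in the real design.

## Problem sizes in the test suite

Property tests use 100 random acyclic models (p ≤ 5, n = 200) for the
ML-equals-OLS and path-enumeration checks, 50 replicates at n = 5,000 for
parameter recovery at the study coefficients, and 100 seeded generator runs
for the marker dispersion check. These sizes put Monte-Carlo error well
below the asserted tolerances while the whole suite stays in the
low-minutes range.

## Known limitations

* No latent variables, mean/intercept structures, residual covariances,
  missing-data (FIML) estimation, bootstrap intervals or modification
  indices; cyclic (non-recursive in the econometric sense) systems are
  rejected by design.
* The metAFLP truth table is a principled reconstruction of the enzyme
  logic, not a verified copy of any particular lab's scoring spreadsheet;
  the reassignment hook exists precisely because conventions differ.
* The JCAMP-DX reader covers the common AFFN forms (XYPOINTS, X++(Y..Y));
  compressed (DIFDUP) encodings are not supported.
* n = 37 is small for asymptotic SEs and χ² calibration; the engine reports
  the conventional asymptotics and leaves small-sample corrections to the
  user.
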