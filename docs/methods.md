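# Methods

This note documents the statistical choices behind `epivuln`: the model
each stage implements, the defaults and why, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## The pipeline

### Screening (`epivuln.screening`)

The coefficient of variation uses the sample standard deviation (n−1
denominator) over the **absolute** mean. Indicators such as migration
balances are centred near zero; the |mean| convention makes their CV large
(or infinite at mean exactly 0), which correctly keeps them — a
near-zero-mean indicator with real spread is informative, not
quasi-constant. An indicator is removed when CV ≤ 0.1 (the boundary is
removed: "does not exceed").

Collinearity pruning is greedy: while any kept pair has Pearson
|r| > 0.6, the member of an offending pair with the largest mean absolute
correlation to all currently kept indicators is dropped; exact ties drop
the later column. This keeps the more independent member of each cluster
and is fully deterministic. The kept set always satisfies max |r| ≤ 0.6
(asserted at run time). Which member of a near-duplicate pair survives
depends on sampling noise in its correlations to third indicators; only
the *set-level* guarantee is contractual.

Missing values are resolved before screening: the default drops districts
with any missing indicator (counts logged); mean imputation is available
(`missing="impute"`). Neither is a substantive model — real registries
should be cleaned upstream.

### Unitarization and aggregation (`epivuln.indexing`)

Zero unitarization is computed within the analysed district set; no
external reference values exist for these indicators. Consequences worth
knowing: every column attains 0 and 1; indices are invariant to positive
affine rescaling of raw indicators (unit changes are harmless); and adding
or removing districts changes the normalization of all others.

The Perkal index is the unweighted mean of the group's unitized columns.
Equal weights follow from the standardized-sums definition; a weighted
variant would be a different instrument and is deliberately not a default.
Because every column is unitized to the same orientation (high = safe),
**a low index always means high vulnerability**; the convention is pinned
by a test in which the district with the worst value of every indicator
scores WO = 0.

WO is algebraically the size-weighted mean of the four nature components
(each indicator has exactly one nature), and that identity is asserted in
tests. The relation components Wz and Wn are *not* a partition: an
indicator tagged with both intended and unintended contacts contributes to
both.

### Classification (`epivuln.classify`)

Cutoffs are Rav ± s with the sample (n−1) standard deviation, consistent
with the CV convention. The printed four-interval rule leaves boundary
values unassigned if read with strict inequalities on both sides; here
boundaries are closed *downward* (a district exactly on a cutoff goes to
the more vulnerable class) — conservative for a screening instrument. With
s = 0 every district sits on all three cutoffs simultaneously; the
implementation assigns class III everywhere and warns.

Whether the rule should be applied to index values or to their ranks is
genuinely ambiguous in the methodology this package follows; both modes
are implemented (`method="values"` default, `method="ranks"`), and they
coincide for evenly spaced values.

### Temporal correlation (`epivuln.correlate`)

Cumulative counts are correlated raw (no per-capita scaling, no log); a
`log1p` flag exists but is off by default so the default matches the
method as published. Alignment is by exact district id and exact snapshot
date; districts absent from either source are dropped pairwise and the
exclusion counts logged, and each reported correlation carries its own n.

### Stepwise refinement (`epivuln.regress`)

Entry/removal thresholds default to 0.05/0.10. The selection loop is
purely deterministic: the candidate with the smallest p-value enters
(ties broken by column order), then included terms with p ≥ 0.10 are
removed largest-first; revisited models terminate the search. OLS fitting,
standard errors, t/p-values and F come from statsmodels; the tests
cross-check the whole path against an independent numpy-only brute-force
implementation of the same rules, and OLS against closed forms. Per-candidate
entry at α = 0.05 is anti-conservative across ~20 null candidates —
typically one or two spurious terms enter; this is a property of classical
stepwise selection, not a defect of the implementation, and the recovery
experiment budgets for it (≤ 2 spurious).

The refined index WO(pop) re-runs unitarization and the Perkal mean over
exactly the selected codes. Univariate attribute–index relations are
reported in **both** directions (attribute-on-index and
index-on-attribute) with the shared r², because slope interpretation
depends on which variable is treated as the response and the published
interpretations mix both conventions.

## The synthetic-data generator (`epivuln.simulate`)

One latent vulnerability factor V_i ~ N(0,1) per district drives
everything:

* indicator j: x_ij = m_j + s_j (d_j λ_j V_i + √(1−λ_j²) ε_ij), with
  direction d_j = +1 for destimulants and −1 for stimulants, so high
  vulnerability raises destimulants, lowers stimulants, and hence lowers
  WO;
* new cases in period t: N_it = round(exp(α_t + β_t V_i + σ_ε η_it));
  the panel reports cumulative sums C_it = Σ_{u≤t} N_iu (non-decreasing by
  construction).

The reference scenario (`default_scenario`) mirrors the study design the
pipeline is built for: 314 districts, the packaged 33-indicator registry,
8 monthly snapshots (30 Apr – 30 Nov), 11 designated informative
indicators at λ = 0.7, two injected collinear pairs (X3 from X2, X31 from
X10 — both otherwise uninformative, so the injections exercise pruning
without touching the recovery experiment), and two quasi-constant columns
(X30, X33, scale forced to 0.2 % of location). The coupling ramps
linearly, β_t: 0.1 → 1.0, emulating an epidemic whose spatial pattern
locks onto the socio-economic structure as it unfolds.

**Baseline and dispersion.** The per-period baseline is
α = [6.6, 5.6, 4.6, 3.6, 2.4, 2.4, 2.4, 2.4] — a first wave that spikes
early and settles on a low plateau — and σ_ε = 0.105. These two defaults
were fixed by a design-phase power analysis of the generator itself, for a
reason intrinsic to the count model: counts are log-normal in V, and the
Pearson correlation between a normal variable and exp(βV + ση) is
β/√(e^{β²+σ²} − 1), which *decreases* in β once β is large. If cumulative
counts were dominated by the late, strongly coupled periods (a
late-surging α), the raw-scale correlation trend would bend downward at
the tail and the heavy-tailed final counts would destroy the partial
power of the stepwise stage. Front-loading the wave keeps the effective
coupling of the *cumulative* count in the monotone regime at every
snapshot while the plateau keeps late increments alive, and the small
per-period dispersion is averaged further by accumulation. With these
defaults the generator meets its design contract — WO–cases correlation
negative at every snapshot, magnitude non-decreasing (at most one
inversion per seed), and stepwise recovery of ≥ 9 of the 11 informative
indicators with ≤ 2 spurious terms in ≥ 80 % of seeds — verified over a
20-seed panel in the acceptance tests.

**What the generator does not emulate.** Real waves surge late as well as
early; the front-loaded profile is a stylization, and the absolute count
level is arbitrary (no population offsets). There is no spatial
autocorrelation, no multi-factor structure by default (a per-nature
latent-factor hook exists but is not the reference condition), no
reporting artefacts, and indicator noise is Gaussian. Passing tests
therefore show that the pipeline recovers structure *of the assumed
single-factor form*; they do not certify behaviour under spatially
clustered confounding or reporting bias. The early-snapshot correlation
in the reference scenario (≈ −0.5) is also stronger than a real early
epidemic would show; the contract tested is the monotone strengthening
and its sign, not the dynamic range.

All randomness flows from one `master_seed` through
`numpy.random.default_rng`; identical scenarios generate bit-identical
data.

## Numerical conventions and degenerate inputs

* Sample (n−1) standard deviations everywhere (CV, classification, OLS).
* Unitizing a constant column is an error by design — screening must run
  first.
* Correlation and univariate relations require n ≥ 3 and non-constant
  inputs; rank-deficient design matrices raise an error naming the
  dependent columns.
* Classification requires n ≥ 2 finite values.
* Stepwise never randomizes; all tie-breaks are by column order.

## Problem sizes used in tests

Unit tests run on tables of 3–500 rows; the acceptance suite uses the full
reference scenario (314 × 33, 8 snapshots) with 20 generator seeds for the
recovery/trend experiment and 50 random small instances for the stepwise
oracle comparison. The whole suite completes in well under a minute of CPU
apart from the 20-seed experiment (~25 s).

## Known limitations

* The accept/reject outcome recorded in the packaged registry is
  provenance from the original Polish 2019 application; this package's own
  screening on synthetic data will generally keep a different subset.
* Stepwise p-value selection inherits all classical caveats
  (post-selection inference is not valid; reported p-values are
  conditional on selection).
* The mean ± SD class scheme assumes a roughly symmetric index
  distribution; heavily skewed indices concentrate districts in the middle
  classes.
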