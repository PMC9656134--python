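# epivuln

Composite socio-economic vulnerability indices for district-level epidemic
screening.

`epivuln` implements a multi-stage small-area analysis used to classify
rural districts by their vulnerability to droplet-borne epidemic threats
from routinely published statistics, and to validate that classification
against observed incidence. It is aimed at spatial epidemiologists and
regional scientists who build composite indicators over administrative
units (e.g. LAU-1 districts) and need the whole chain — screening,
normalization, aggregation, classification, temporal validation,
regression refinement — as tested, scriptable building blocks.

## Method

Given a raw table of indicators x_ij (district i, indicator j), each tagged
as a **stimulant** (higher value favourable) or **destimulant** (higher
value unfavourable), the pipeline runs:

1. **Screening.** Quasi-constant indicators are dropped by the coefficient
   of variation (CV = s/|x̄| ≤ 0.1), then collinear indicators are pruned
   greedily until all pairwise Pearson |r| ≤ 0.6.
2. **Zero unitarization.** Stimulants map to
   v_ij = (x_ij − min_i x_ij) / (max_i x_ij − min_i x_ij), destimulants to
   v_ij = (max_i x_ij − x_ij) / (max_i x_ij − min_i x_ij), so v_ij ∈ [0, 1]
   and *low* values always mean *high* vulnerability.
3. **Perkal standardized sums.** The synthetic index of a group of
   indicators is w_i = Σ_j v_ij / n. The general index **WO** aggregates
   all kept indicators; component indices aggregate by indicator nature
   (**Wd** demographic, **Ws** social, **Wg** economic, **Wzp** spatial
   development) and by contact type (**Wz** intended, **Wn** unintended
   interpersonal relations).
4. **Classification.** Districts split into four classes from the mean
   (Rav) and standard deviation (s) of the index: I (low vulnerability)
   Ri > Rav+s; II Rav < Ri ≤ Rav+s; III Rav−s < Ri ≤ Rav; IV (high)
   Ri ≤ Rav−s.
5. **Temporal validation.** Pearson correlation of each index with
   cumulative registered cases at ~30-day snapshots; a vulnerability-driven
   epidemic gives negative correlations that strengthen over time.
6. **Stepwise refinement.** Bidirectional stepwise OLS
   (Y = a0 + a1·x1 + … + ak·xk, enter at p < 0.05, remove at p ≥ 0.10)
   selects the indicators that explain incidence; the refined index
   **WO(pop)** re-runs unitarization + Perkal over exactly the selected
   subset, and each selected attribute is related to WO(pop) by a
   univariate line (x = b0 + b1·Y, reported in both directions).

A latent-factor generator (`epivuln.simulate`) produces synthetic studies
with known ground truth — 314 districts, 33 indicators loading on one
vulnerability factor, injected quasi-constant and collinear defects, and
cumulative case panels whose coupling to the factor strengthens over
time — so every stage is testable end to end.

## Worked example

The `epivuln` CLI chains the stages on CSV files:

```bash
epivuln simulate --seed 7 --outdir .
epivuln screen indicators.csv --outdir .
epivuln indices screened.csv --out indices.csv
epivuln classify indices.csv --out classes.csv
epivuln correlate indices.csv incidence.csv
epivuln stepwise indicators.csv incidence.csv --outdir .
```

which prints:

```text
kept 29 indicators (CV removed 2, correlation removed 2)
wrote indices.csv with columns ['WO', 'Wd', 'Ws', 'Wg', 'Wzp', 'Wz', 'Wn']
Rav=0.5044 s=0.0538; class counts: I=54, II=101, III=110, IV=49
index       date      r     p   n
   WO 2020-04-30 -0.535 0.000 314
   WO 2020-05-30 -0.684 0.000 314
   ...
   WO 2020-11-30 -0.760 0.000 314
selected: X28, X21, X1, X16, X15, X8, X5, X18, X14, X29, X13
R=0.883 R2=0.779 adjR2=0.771 F(11,302)=96.87 n=314
```

Reading the output: screening removed the two near-constant indicators and
one member of each injected collinear pair; the four vulnerability classes
partition the 314 districts (I = least, IV = most vulnerable); the WO–cases
correlation is negative at every snapshot and strengthens monotonically
from −0.535 to −0.760 as the epidemic couples to the vulnerability
structure; and stepwise refinement recovers exactly the 11 indicators that
the generator made informative (`ground_truth.json` lists them), with the
fit explaining ~78 % of incidence variance.

The same chain is available as a library (`epivuln.run_pipeline`); see the
docstrings and `docs/methods.md`.

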