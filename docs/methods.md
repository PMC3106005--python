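# Methods

## Problem and approach

Psoriasis severity instruments mix measurement scales: percent body
surface areas (continuous), 0–4 ordinal severities, 1–5 questionnaire
answers, per-digit binary flags — and, for one assessor, regional
extents that are only interval-identified from a total-body percentage.
`psoriastat` analyses such cohorts with a single rank framework: every
item is mapped to **u-scores** under a partial order, and association
between items is the Pearson correlation of their u-scores.  On top of
the quantitative analysis, 2×2 odds ratios measure the weaker,
qualitative question of whether any involvement in one domain
co-occurs with any involvement in another.

## Instruments

| Tool | Items | Tool score | Range |
|---|---|---|---|
| PASI | global extent category 0–6; erythema, scaling, thickness 0–4 | category × (E+S+T) | 0–72 |
| XL-PASI | per 10 areas: extent %, E/T/S 0–4, arthritis 0–4; globals QoL/pain/itch 0–4 | see below | 0–148 |
| PWESI | per 10 areas: extent 0–4, severity 0–4 | 50·Σ(extent+severity)/80 | 0–50 |
| LS-PGA | single global rating | carried as an ordinal | 0–7 |
| PASE | 7 symptom + 8 function answers, 1–5 | sums | 15–75 |
| PsAA | 2 binary history + 6 exam components 0–4 | weighted sum (unit map) | 0–26 |
| NA / JA | 10 binary digit flags | count | 0–10 |

The PASI here is the single-category variant (global extent category ×
global severity sum), not the classical four-region-weighted index.

**XL-PASI aggregation.**  The instrument's item inventory and its
0–148 endpoint are fixed, but no unique aggregation follows from them.
We define raw = Σ_areas (extent/100)·(E+T+S) plus the four global items
(arthritis, QoL, pain, itch, each 0–4), linearly rescaled by 148/136 so
the maximum is exactly 148.  Because all downstream association is
rank-based, any strictly increasing rescale yields identical analysis
results (asserted by a test that toggles the rescale); only the
ordering and the printed endpoint are binding.

For **tool-level correlation** the XL-PASI score is computed from the
skin dimensions only (`include_globals=False`, linearized to the same
0–148 endpoint).  A skin-severity score containing an arthritis item
would correlate with the joint instruments by construction
(measured effect ≈ +0.13 r at n = 2000 in an otherwise independent
world), confounding exactly the question the analysis asks.  The
extension items remain in the record and in the full-instrument
composite.

The XL-PASI global arthritis indicator is derived as the maximum of
the per-region arthritis scores, since arthritis is recorded
per region.

**Body-area weights.**  Rule-of-nines-inspired fractions (scalp 0.05,
face/neck 0.05, arms 0.15, hands 0.05, chest/abdomen 0.15,
back/shoulders 0.15, genitalia 0.01, buttocks/thighs 0.14, knees/lower
legs 0.15, feet 0.10; sum 1).  They enter only the interval
reconstruction and the synthetic total; rank-based analyses are
insensitive to reasonable alternatives.  Configurable via
`GeneratorConfig.area_weights` / the weights mapping accepted by
`region_intervals_from_total`.

**Extent categories.**  The printed closed integer ranges (1–9 %,
10–29 %, …) are treated as half-open at the upper edge for fractional
inputs, with 100 % in the top category; the map is a monotone step
function surjective onto {0..6}.

## Interval censoring

An assessor who records only the total involved fraction T (with area
weights w_r) constrains region r to

    lo_r = max(0, (T − (1 − w_r)) / w_r),   hi_r = min(1, T / w_r),

the sharpest interval consistent with the total: the other regions can
absorb at most 1 − w_r of the body, and the region cannot hold more
than min(w_r, T).  Both bounds are attainable, every feasible
allocation lies inside (verified against a brute-force sampling
oracle), and the intervals collapse to points at T ∈ {0, 1}.  Bounds
are rounded to 10⁻⁹ % so that CSV round trips are bit-identical.

## u-scores and correlation

For observations x_i (scalars are degenerate intervals [x, x]):

    u_i = Σ_j sign(x_i, x_j),   sign = +1 if lo_i > hi_j, −1 if hi_i < lo_j, else 0.

Scores sum to zero and satisfy u_i = 2·midrank_i − (n+1) for totally
ordered data, so the Pearson correlation of u-scores **equals midrank
Spearman exactly** on scalar data with arbitrary ties (tested to
1e-12 against rank-based computation) and extends it to
interval-censored data, where overlapping intervals simply contribute
no comparison.  Computation is O(n log n) per item via two sorted-array
rank queries; an O(n²) literal pairwise sum serves as the oracle in
tests.

Numerical/degenerate choices:

* missing values: pairwise-complete deletion per item pair, with
  u-scores recomputed on each complete subset (u-scores are
  cohort-relative);
* a constant item has zero u-score variance: its correlations are
  reported as missing (NaN / blank cells), never coerced to 0;
* no per-cell P-values or multiplicity correction — the matrix is
  descriptive;
* matrix rows follow the input inventory order; no reordering for
  display.

The default item inventory has 81 items (10 JA + 10 NA + 15 PASE +
6 PsAA exam + 10 XL-PASI extents + 10 XL-PASI activities (mean E/T/S)
+ 10 PWESI extents + 10 PWESI severities); it is configurable and is a
package default, not a claim about any particular published item set.

## Odds ratios

Involvement is dichotomized as any nonzero regional extent (interval
midpoint > 0 for censored patients).  OR = ad/bc with a
Haldane–Anscombe +0.5 on every cell iff any cell is zero; two-sided
Fisher exact P on the raw counts (sparse cells are expected at n ≈
180); Woolf log-OR 95 % CI from the (corrected) counts.  Finger-level
and toe-level comparisons are emitted separately, and the nail/joint
outcomes both separately and pooled, since either pooling convention
is defensible.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with
defaults set to the study conditions: **180 patients**, four assessors,
one of whom (25 % of the cohort) is interval-censored.

* Latents (S, J, N) ~ N(0, Σ), Σ a configurable correlation matrix
  (default: identity — the independent-axes world).
* Region involvement latents z_r = 0.95·S + λ_c·C_c + 0.3·ε,
  standardized; C_c are per-patient cluster effects for acral
  (hands+feet), head (face+scalp) and trunk (buttocks+chest+back)
  clusters, default loadings λ = 0.5.
* Percent extent: 0 below the involvement threshold (default marginal
  involvement rate 0.6 per region), else a monotone map of the latent
  onto (0, 100], rounded to 0.1 %.
* Ordinal severities: normal-quantile cuts (0.25, 0.8, 1.4, 2.0)
  applied to the region latent plus item noise (sd 0.25), giving
  right-skewed item distributions; severities are 0 iff the region is
  uninvolved and ≥ 1 otherwise.
* Digit flags: Bernoulli with logit = intercept + 3.2·latent (N for
  nails, J for joints) + 0.6·patient-digit noise.
* PASE/PsAA items: quantile maps of 0.95·J plus item noise; LS-PGA: a
  monotone map of the mean region latent onto 0–7.
* Toe flags share the acral cluster effect (log-odds gain, default
  1.5) with foot skin extent, so a *qualitative* skin–toe association
  is reachable by config even with independent latents.

Loadings were chosen so that latent correlations pass through the
ordinal discretization with limited attenuation — the generator's
contract is that the pipeline can read the generating structure back
out: with independent latents the skin↔joint item-block mean |r| is
≈ 0.02 and every skin↔joint tool |r| < 0.05 at n = 2000, while with
latent corr(S, J) = 0.8 the block mean r is ≈ 0.53.  The cost of this
fidelity is idealization: items are high-fidelity indicators of their
latent, inter-item noise is independent, and there are no assessor
biases, no instrument-wording artifacts (e.g. nail disease inflating
hand-skin scores), and no demographic structure.  Passing recovery
tests therefore show that the *pipeline* is faithful, not that real
instruments are this clean.

Reproducibility: one `numpy` Generator seeded from the config; the
censored subset is drawn from seed + 1.  Identical config ⇒ identical
cohort, byte-identical CSV.

## Problem sizes

Recovery tests and examples use n = 2000 patients (Monte-Carlo error
≈ 1/√2000 ≈ 0.022 per correlation), the OR convergence test n = 5000,
and shape/validity tests n = 180, the cohort size the generator
defaults to.  The whole suite runs in well under a minute on one CPU.

## Known limitations

* The XL-PASI and PWESI composite aggregations are package design
  decisions constrained only by the printed endpoints; published
  per-item weightings, if any exist, are not recoverable from the
  instrument descriptions.
* The PsAA item map is structural (2 history + 6 exam, unit weights by
  default); the true instrument weighting is not public.
* NA/JA cover the ten fingers; toe involvement is carried only as
  any-involvement flags.
* No confidence intervals on rank correlations, no stratified or
  regression-adjusted odds ratios (crude 2×2 only).
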