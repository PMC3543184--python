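# Methods

## Scope and assumptions

The package quantifies the translational status of each mRNA species
from pooled sucrose-gradient fractions hybridized to microarrays. It
assumes: (i) fraction roles (free RNA, 30S, 50S, monosome, polysome
ranks) are assigned experimentally and supplied as input — no peak
detection or deconvolution is attempted; (ii) intensities are
post-background spot means with duplicate spots already averaged;
(iii) arrays B–H hold the seven pooled fractions of an 11-fraction
gradient (elution fractions 1–2 pooled into B, 3 into C, 4–7 into D–G,
8–11 into H) and array A the unfractionated reference.

## Ribosome-number calibration

`ln(elution time) = a · ln(polysome size) + b`, fitted per replicate by
least squares on resolved polysome peaks; `a` is the replicate-averaged
slope, and `b` is anchored analytically at each replicate's monosome
elution time (`b = ln t_monosome`), not co-fitted — the monosome is the
one particle whose ribosome number is known exactly. Fraction boundary
times are inverted through the calibration to ribosome-number ranges.

The representative ribosome number per fraction is the arithmetic
midpoint of the inverted bounds, reported to one decimal; fraction D is
forced to exactly 1. Rounding is half-up with a 1e-9 guard so exact .X5
midpoints coming out of log/exp round trips land deterministically on
the upper value (9.6–17.9 → 13.8). Published per-replicate averages can
differ from the midpoint by up to one rounding unit; no attempt is made
to emulate them.

The engaged-ribosome percentage is the composite-trapezoid A254 area
over elution fractions 4–11 divided by the area over 2–11. Boundary
ordinates are linearly interpolated, so the integral is exact for
piecewise-linear traces and invariant under uniform rescaling of the
absorbance.

## Normalization

The three stages (reference scaling by the kept-gene mean of array A,
RNA-quantity correction, inter-series center/reduce) are described in
the README. Two deliberate choices:

* The inter-series replicate mean is computed from the same data being
  corrected; the resulting mild statistical circularity is accepted as
  part of the procedure. A consequence used by the tests: when the
  replicates are exact affine images of a common profile, every
  corrected replicate equals the replicate mean (not the latent
  profile), and regressing corrected values on the mean gives slope 1,
  intercept 0 by construction.
* Centering by b̂ can push low-signal values negative; they are clipped
  to 0 for proportion computation and flagged per (gene, array,
  replicate) in the QC output, since proportions require nonnegative
  input.

## Bootstrap peak fraction

Residuals of each replicate's proportion vector from the per-fraction
mean are pooled **within the gene** across all seven fractions and all
replicates (cross-gene pooling would mix scales). Each of the 10 000
bootstrap data sets redraws one residual per (fraction, replicate) cell
with replacement and adds it to the per-fraction mean; the argmax over
D–H of the bootstrap mean proportions is recorded, with exact ties
broken toward the lower fraction and flagged. A fraction modal in ≥ 95%
of sets is the peak.

Widening: when no single fraction reaches 95% support, the candidate
categories become the adjacent windows of width 2 (D+E, E+F, F+G, G+H),
then width 3, and so on up to the full D–H window (which always
succeeds). Because adjacent windows overlap, they do not form a
partition, so "merging" is operationalized as the window-summed
per-fraction bootstrap means, with fresh bootstrap draws from the
original residual pool at each level. Per-gene bootstrap streams are
derived from (seed, gene index), so assignments are reproducible and
independent of how many genes precede a gene.

Density is only defined for single-fraction peaks; widened or
unassigned genes carry NaN density and are excluded from modeling, as
are genes strictly above the 100/30 ceiling (the comparison is strict:
a gene exactly at 3.33 is retained).

## Covariance models

Responses (occupancy, density, protein level) are log-transformed;
quantitative covariates are log-transformed when strictly positive and
right-skewed (concentration, half-life, CDS length, CAI, aromaticity)
and left raw when they can be negative (chromosome position, GRAVY,
folding energies), then all are centered and reduced so coefficients
are comparable effect sizes. Functional categories enter as centered
level indicators, each level individually selectable.

Selection is bidirectional stepwise AIC starting from the full model
(an exhaustive all-subsets search is available for ≤ 12 covariates; on
the simulated worlds both agree). The search uses a fast closed-form
AIC, `n·ln(RSS/n) + 2(p+2)`, identical to the statsmodels OLS AIC up to
an additive constant (verified in a test); RSS is floored at
`1e-20 × TSS` so numerically perfect fits tie and the penalty alone
selects the minimal model. The final reported coefficients, t-test
p-values and adjusted R² come from a statsmodels OLS fit of the
selected terms. Near-duplicate quantitative covariates (|r| > 0.999)
abort with a diagnostic naming the pair.

A known property worth stating: at any sample size, stepwise AIC
retains a pure-noise covariate whenever its deletion chi-square exceeds
2, i.e. with probability P(χ²₁ > 2) ≈ 0.157 (measured 0.14–0.23 on the
simulated worlds). AIC therefore controls prediction error, not the
false-selection rate; readers who need conservative selection should
use the exhaustive search with a BIC-style penalty or validate selected
terms by their p-values.

## The synthetic world

Defaults are the stated experimental regime, chosen once:

| quantity | default | note |
|---|---|---|
| occupancy | truncated N(0.66, 0.06) on [0, 1] | population marginal |
| peak classes | D: 0.17, H: 0.83 | two-class mixture |
| fraction recovery | N(0.60, 0.16) per (fraction, replicate), clipped to [0.05, 1] | constant across genes |
| fraction total RNA | log-spaced means 29.7→436.3 µg across B–H, ×lognormal(0, 0.25) | reference A: 400–600 µg |
| intensity noise | multiplicative lognormal, CV 0.10 | positive, right-skewed |
| replicate distortion | r ∈ [0.8, 1.25], b ∈ [0, 25] intensity units | applied to arrays B–H |
| below-cutoff genes | fraction 1 − 1619/1948 ≈ 0.169 | cutoff placed at that quantile |
| calibration | a = 0.4, monosome at 7 min | boundaries placed so inverted ranges are 1.4/2.9/5.4/9.6/17.9 |
| CDS length | lognormal, median 900 nt | min 90 nt |
| ANCOVA residual SD | 0.84 | calibrated so adjusted R² ≈ 0.34 with the default effects |

Within-gene proportions put the non-translating mass (1 − occupancy)
half in B and half in C, and spread the translating mass over D–H with
a discretized Gaussian kernel (width 0.75 fractions) centered on the
peak — the real within-gene shape is unknown, and this kernel is a
modeling convenience that guarantees a strict maximum at the peak.
Occupancy is coupled to the feature table through a Gaussian copula
whose linear score uses the configured standardized effects, so the
marginal stays exactly truncated-Gaussian while correlations match the
effect structure; `ancova_dataset` instead generates the response in
the model's own exp-linear form for clean parameter-recovery checks.

What the generator does **not** emulate: spot-level image artifacts,
print-tip or spatial effects, polycistronic coupling between genes,
5'UTR contributions to density, or fraction cross-contamination. A
green round-trip test therefore establishes that the estimator chain
inverts the stated forward model — not that it is robust to every
artifact of real nylon-array data.

Two regimes matter for interpretation:

* **Noiseless world** (noise 0, identity distortions, recovery constant
  across fractions): the pipeline returns occupancy, peak fraction and
  density exactly equal to truth — the estimator chain is an exact
  inverse of the forward model.
* **Default noisy world**: per-(fraction, replicate) recovery jitter
  perturbs proportions *systematically* (it multiplies whole fractions,
  not individual genes), so estimated occupancy correlates with truth
  at r ≈ 0.85 under the full 60 ± 16% jitter and r ≥ 0.95 when recovery
  is constant, while peak-fraction accuracy stays ≥ 0.95 throughout.
  The noise-robustness test is run in the constant-recovery regime,
  which also matches the experimental observation that the loss was
  constant between genes and repetitions.

## Numerical choices

* Proportion vectors must sum to 1 within 1e-9; all-zero gene-replicates
  yield NaN, are excluded from averaging, and a gene needs ≥ 2 valid
  replicates for a bootstrap assignment.
* Occupancy averaging runs over valid replicates only.
* Degenerate inter-series regressions (r̂ = 0 or constant replicate
  means) abort with the offending (array, replicate) named.
* The enrichment p-value uses the strict inequality P(N > N_obs); the
  most extreme attainable count has p = 0 by that convention.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bitwise-identical
  outputs, including TSV bytes.

## Known limitations

* The representative-ribosome midpoint convention differs from
  published per-replicate averages by up to one rounding unit.
* Density inherits the CDS-length proxy for transcript length; genes
  with long 5'UTRs are over-estimated, which is why the > 3.33 filter
  exists rather than a UTR correction.
* Stepwise AIC's ~16% noise-retention rate (above) bounds how reliably
  null covariates are excluded.
* The widened-peak re-bootstrap is one of several defensible readings
  of "merge adjacent fractions and search again"; alternatives (e.g.
  re-deriving residuals from merged vectors) would differ only when
  support is already borderline.
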