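# Methods

This note records the models, estimators, defaults and numerical choices behind
`hcrquant`, and what the synthetic-data generators do and do not emulate.

## qPCR quantification

**Model.** Baseline-subtracted amplification curves are fit by nonlinear least
squares with the Richards (generalised logistic) sigmoid

    F(x) = Fmax / (1 + exp(-(x - c)/b))^d ,

which subsumes the plain logistic (d = 1). Fitting uses multi-start
initialization from curve landmarks (maximum fluorescence, half-maximum
crossing, 25–75% rise width), box bounds keeping Fmax, b, d positive, and a
logistic (fixed d = 1) fallback if the full fit fails. Curves with no positive
signal or with fit R² < 0.8 are reported `converged = False` — never an
exception — and plate quantification logs them as exclusions.

**Cy0.** The quantification cycle is the abscissa intercept of the tangent at
the fitted curve's inflection. For the Richards family this has the closed form
`Cy0 = c + b·ln d − b(1 + 1/d)` (inflection at `x* = c + b·ln d`, where
`F = Fmax (1+1/d)^{-d}` and `F' = (Fmax/b)(1+1/d)^{-(d+1)}`). The test suite
checks this algebra against a brute-force oracle that locates the inflection by
maximizing the first difference of the curve on a fine grid.

**Efficiency.** Per reaction, `Eff = 2^m` with `m` the least-squares slope of
log₂ fluorescence over five cycles: the cycle nearest Cy0 plus the two before
and two after. Per amplicon and plate, `Eff` is the mean over converged
reactions (plate-average correction in the LinRegPCR spirit), and relative
expression is `Eff^(−Cy0)`. The antilog reading of the slope is used so that
perfect doubling gives `Eff = 2` and `Eff^(−Cy0)` is a standard relative
quantity. The plate mean is required to lie in the sanity band (1, 2.2].

**Known bias.** On sigmoid-generated data the five-cycle window unavoidably
overlaps the curve's bend: its upper cycles lie where the per-cycle fold has
already declined, so the window slope underestimates the exponential-phase
efficiency — by about 0.02 at Eff = 1.8 up to about 0.04 at Eff = 2.0 for
realistic shapes, with per-well wobble of ±0.03 from where Cy0 falls between
integer cycles. This is a property of window-of-linearity estimation, not of
the implementation; plate-level means (tens of reactions) absorb the wobble.
Consequently expression-fold estimates carry a mild compression (an 8-fold
input difference reads as ~7.4–7.7-fold at Eff = 2).

## Combination-ratio normalization

GFP (transfection control) expression is gamma-distributed with shape < 2, so
1/GFP has no finite variance in the worst case and simple RFP/GFP ratios have a
heavy-tailed, multimodal error distribution at n of a few. The normalization
therefore forms, for every unordered pair {i, j} of measurements in a
condition, the combination ratio `(R_i + R_j)/(G_i + G_j)` — pair sums have
gamma shape 2k > 2, giving the denominator's inverse a finite variance and a
unimodal error distribution. All C(n, 2) ratios are produced in lexicographic
index order.

Downstream statistics treat the combination ratios as the observation unit for
means and variances, but the information count is the number of measurements n,
not C(n, 2): the pairs are correlated, so standard errors and test sample sizes
use n. Time courses are scaled within each cell line so that 100% equals the
maximum over time of the control's mean combination ratio — the only reading
under which the control curve peaks at exactly 100%. The standard error of a
single combination ratio (n = 2) is reported as missing, not zero.

## SMCV contrasts

For group summaries (Ȳᵢ, sᵢ, nᵢ) and a zero-sum contrast c₁..c_t the SMCV
estimate is the method-of-moments form

    λ̂ = Σ cᵢ Ȳᵢ / sqrt(Σ cᵢ² sᵢ),

with sᵢ the group *variance* (a switch allows the SD reading for sensitivity
analysis). The c⁺-probability — the probability that the contrast variable is
positive — is Φ(λ̂) under a normal model; it is 0.5 exactly at λ̂ = 0.

**p-values.** The test of the one-sided null "SMCV ≤ 0" uses the sampling
distribution of λ̂: its standard error is `sqrt(Σ cᵢ² sᵢ / nᵢ) / sqrt(Σ cᵢ² sᵢ)`,
and `p = Φ(−λ̂ / se)`. For unit group sizes this reduces to the asymptotic
relation `p = 1 − c⁺` (exposed directly as `smcv_pvalue`); for real group sizes
the asymptotic relation is badly anticalibrated (with n = 6 per group it would
reject a true null at ~3·10⁻⁵ instead of ~0.05), which is why the
finite-sample form is the one the pipeline reports. Under the null with two
groups of n = 6 the observed rejection rate is ~0.065 — slightly above nominal
because the normal reference ignores the t-tails at 10 degrees of freedom.
Significance uses the strict boundary p < 0.050. No multiple-testing
correction is applied. Shipped contrasts compare lesion vs control and lesion
vs lesion within a cell line, and the same lesion across cell lines after
within-cell-line scaling.

## Flow-cytometry gating

Observed channel intensities are modelled as `observed = true @ S` with S the
spillover matrix (rows = fluorophores, unit diagonal); compensation multiplies
by S⁻¹ and is exact to numerical precision. Negative compensated values are
preserved — the log-ratio stage excludes non-positive events explicitly and
counts them.

The induced population is isolated on `ln(RFP/GFP)` by a two-component normal
mixture fit with EM: k-means initialization, 10 seeded restarts, convergence at
Δlog-likelihood < 1e-8, a variance floor of 1e-8 times the data variance, and
a per-iteration assertion that the log-likelihood never decreases. The induced
component is the one with the larger mean (deterministic under relabeling);
events are assigned by maximum responsibility. Effectively single-component
data are flagged degenerate — minor weight < 0.01, mean separation < 0.1
pooled SD, or a single-normal fit preferred by BIC. The BIC clause is needed
because on genuinely unimodal data EM converges to two overlapping
half-components about one SD apart, which the separation rule cannot catch.
Degenerate gating passes every event through (there is no non-responder
population to remove).

Condition summaries express each population's induced-cell signal as percent
of the control condition, by default on the geometric scale (back-transformed
mean log-ratio, matching the log-ratio normalization; arithmetic scale by
flag). ANOVA and linear contrasts run on the log scale, where population
values are closest to normal, with contrast t-statistics using the pooled
residual mean square. Hand-drawn autofluorescence gates from interactive
workflows are replaced by a programmatic quantile rule against an optional
unstained control — hand gating is not reproducible.

## Transcript-error classification

Reads are globally aligned to the expected transcript (RNA alphabet; T→U on
ingestion) with a banded affine-gap Gotoh aligner: match +1, mismatch −1, gap
open −2 (first gapped base), gap extend −1, band |i−j| ≤ 5; traceback ties are
broken deterministically. Reads with more than 3 total differences (mismatches
plus gapped bases) are set aside as unclassifiable; classified plus
unclassifiable always equals total. The aligned column at the lesion-opposite
position yields the class — gap in read → deletion; non-reference base →
misincorporation; reference base with an inserted read base immediately
adjacent → insertion; else match. Off-site substitutions count toward the edit
budget but are not reported as lesion events. A class is retained when its
frequency among classified reads is ≥ fold × background (defaults 10 × 0.001),
boundary inclusive. The default reference embeds the genuine 11-nt transcript
context around the lesion-opposite U (`GAGCGUACGAG`, the reverse complement of
the template-strand 11-mer whose sole adenine carries the adduct) in synthetic
15-nt flanks.

## Synthetic-data generators

All generators take explicit seeds (never global state) and are bitwise
deterministic. What they emulate, and the defaults:

- **qPCR plates.** Noiseless curves are Richards sigmoids whose exponential
  phase multiplies fluorescence by the true efficiency each cycle; this ties
  the slope scale to the asymmetry, `b = d / ln Eff`, so both cannot be set
  independently (a contradictory b is rejected). A well with input Q is placed
  at `c = ln(Fmax/Q)/ln Eff`, so fold differences in input shift Cy0 by exactly
  `log_Eff(fold)` cycles. Defaults: Fmax = 1000 (arbitrary units), d = 0.25 —
  baseline-subtracted real traces stay log-linear through the takeoff and bend
  over few cycles, which in this family means d well below 1 — and additive
  Gaussian noise with sd 2.0 (0.2% of the plateau, typical of current
  instruments). Cycle indices are 1-based; inputs are already
  baseline-subtracted. The additive-Gaussian noise model is an assumption; the
  generating instrument's true noise is not documented.
- **Expression experiments.** GFP ~ Gamma(shape 1.5, scale 1.0) — shape below
  2, reproducing the heavy-tailed 1/GFP regime — and RFP = GFP × effect ×
  exp(N(−σ²/2, σ²)) with σ² = ln(1 + cv²) and cv = 0.2, so E[RFP|GFP] is exact.
  The condition-effect surface maps (cell line, vector, time) to a fraction of
  control in [0, 1]; unlisted conditions default to 1. At least 3 replicates
  per condition.
- **Flow events.** Log-ratio components N(−2, 0.5²) (non-induced) and
  N(1, 0.5²) (induced) — six SDs apart; GFP log-normal around baseline 500,
  APC around 50; observed channels are the true signals pushed through the
  spillover matrix. With identity spillover, observed equals true.
- **Amplicon reads.** The reference with independent background substitutions
  at 0.1% per non-lesion base, plus at most one lesion-site event drawn from a
  class-probability profile (misincorporation:X replaces the lesion base,
  deletion removes it, insertion:X inserts immediately 3′ of it). The lesion
  site itself is governed solely by the profile so that lesion-site tallies
  are directly interpretable.

What the generators do **not** emulate: polymerase chemistry and product
inhibition (real late-exponential efficiency decline differs from any fixed
sigmoid), repair kinetics (effects enter only through the condition-effect
surface), plasmid chromatinization, cytometer saturation and doublets,
sequencing quality variation, and batch structure across plates. Passing tests
therefore show that the estimators recover the truth of *this* statistical
structure at the stated sizes; they do not certify instrument-specific biases.

## Problem sizes and numerical defaults

The test and acceptance runs use: 200 random Richards shapes for the Cy0
oracle sweep; 3 dilution-series plates of 32 wells per amplicon per efficiency
(with an 8-fold duplicate pair) for recovery; 1000 simulated n = 6 experiments
for the variance comparison; 2000 null replicates for calibration; 10,000
events per induced fraction for mixture recovery; 300 single-edit reads for
the alignment oracle; and 50 seeded pipeline runs for power. Optimizer
tolerances are 1e-10 (curve fit xtol/ftol) and 1e-8 (EM log-likelihood);
spillover matrices are rejected as singular below |det| = 1e-12.

## Known limitations

- The window-of-linearity efficiency estimator's downward bias (above) is
  inherited by everything downstream of `Eff^(−Cy0)`; comparisons of ratios
  across conditions on the same plate are unaffected to first order because
  the same plate-mean efficiency is used.
- The normal-theory p-value is mildly anticonservative at very small group
  sizes (t-tails); with n ≥ 6 the excess is about 1.5 percentage points at the
  5% level.
- Combination ratios are correlated; their sample variance underestimates the
  sampling variance of their mean, which is why n (measurements) rather than
  C(n, 2) enters all standard errors.
- The banded aligner requires read length within ±5 of the reference and is
  intended for amplicon reads spanning the lesion; it is not a general-purpose
  variant caller.
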