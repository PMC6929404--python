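# Methods

This note documents the statistical model behind `bin1meta`, the design
choices that were genuinely open, the numerical conventions, and the known
limitations — in particular what can and cannot be recovered from the
bundled summary-level roster.

## Data model

A *study roster* has one row per case-control study: label, ancestry group
(`east_asian` / `caucasian`), case and control sample sizes, the frequency
of the rs744373 C allele (MAF), and the study's published allelic odds
ratio, optionally with per-arm genotype counts (CC/CT/TT). The bundled
roster transcribes a 37-study collection (11 East Asian, 26 Caucasian;
22,395 cases, 48,773 controls). Row order is preserved everywhere; labels
may repeat because multi-cohort articles contribute one row per cohort.

### Effect-allele harmonisation

The roster's OR column is not allele-consistent across the two
literatures. The East Asian rows report the OR for the C allele: pooled on
their own they give ≈1.05–1.08, in line with the stratum-level results
reported for these studies. The Caucasian rows, which mostly descend from
GWAS reports, have 22 of 26 ORs ≤ 1.00 and pool to ≈0.90 — the reciprocal
of the well-replicated Caucasian risk estimate for the C allele (≈1.16).
The only coherent reading is that the Caucasian rows tabulate the odds
ratio for the opposite allele (the major allele T, equivalently the
complementary strand's G). The bundled file therefore carries an explicit
`or_allele` column (`C` for the 11 East Asian rows, `T` for the 26
Caucasian rows), and `build_effects(harmonize=True)` (the default) inverts
rows whose OR refers to T so every effect is C-vs-T. The between-ancestry
OR comparison deliberately uses the column as published, because the
question there is whether the tabulated values differ.

## Per-study effects

**Genotype path.** Genotype counts give the 2×2 contrast directly:
additive uses allele counts (a = 2·CC + CT etc., totals 2N per arm);
dominant and recessive use carrier counts (totals N per arm). The Woolf
estimator supplies θ̂ = ln(ad/bc) and se = √(1/a+1/b+1/c+1/d). If any cell
is zero, 0.5 is added to all four cells (Haldane–Anscombe) and the table is
flagged; no correction is applied otherwise. Dominant and recessive
contrasts are only defined for genotype-bearing rows; summary-only rows are
dropped from those analyses with a log message.

**Reconstruction path.** Summary rows carry only (N_case, N_control, MAF,
OR). Writing p₀, p₁ for the control/case C-allele frequencies, the OR
fixes p₁ = OR·p₀ / (1 − p₀ + OR·p₀), and the combined frequency
(N₁p₁ + N₀p₀)/(N₁+N₀) is strictly increasing in p₀, so the pair
reproducing the MAF is unique; it is found by bracketed root-finding on
p₀ ∈ (0,1) to absolute tolerance 1e-12. The implied allele table
(2N₁p₁, 2N₁(1−p₁), 2N₀p₀, 2N₀(1−p₀)) keeps fractional cells — rounding
would inject avoidable error relative to the reported OR — and by
construction its odds ratio equals the input OR to ~1e-12.

The MAF column is interpreted as the **combined** (case+control) frequency
by default, since the roster does not mark it as arm-specific;
`maf_scope="control"` switches to the control-only reading (then p₀ = MAF
directly). Both readings give nearly identical pooled results on the
bundled roster.

A third path accepts a published OR with 95 % CI:
se = (ln CI_high − ln CI_low)/(2·1.959964).

## Pooling and heterogeneity

With wᵢ = 1/seᵢ² and θ̂ the fixed-effect mean, Cochran's
Q = Σwᵢ(θᵢ − θ̂)² is referred to χ²(k−1), and
I² = (Q − (k−1))/Q × 100 %, clamped to [0, 100] (0 at Q = 0 by the limit
convention). DerSimonian–Laird estimates
τ̂² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)) from the untruncated Q and
re-weights by 1/(seᵢ² + τ̂²); at τ̂² = 0 it reduces exactly to
inverse-variance fixed effect. Mantel–Haenszel pooling is provided for
count-level data, with the Robins–Breslow–Greenland variance for
ln(OR_MH); since the bundled roster is summary-level, the fixed-effect
branch there is inverse-variance.

The pooling model per stratum follows the rule: random effects when the Q
test has p < 0.05 **and** I² > 50 %, fixed effect otherwise. A looser
"p < 0.05 or I² > 50 %" flag for *declaring* heterogeneity is carried on
every heterogeneity result, because the two conventions disagree on
borderline strata. For the bundled roster all strata satisfy both, and the
reported analyses pin random effects everywhere (`force_random=True`),
matching how this roster was originally analysed. The pooled effect is
tested with Z = θ̂/se, two-sided normal p, computed in double precision and
never truncated to zero. All 95 % intervals use the normal quantile
1.959964 on the log-odds scale (bit-stable round trips, rather than the
rounded 1.96).

## Sensitivity and publication bias

Leave-one-out re-runs heterogeneity plus **random-effects** pooling on each
k−1 subset (τ² re-estimated per subset), in roster order. Egger's test is
the classic unweighted OLS of the standard normal deviate θᵢ/seᵢ on
precision 1/seᵢ (statsmodels OLS behind the scenes); the intercept is
tested against t(k−2). A weighted variant is available behind a flag. A
perfect fit with zero intercept returns p = 1; a perfect fit with non-zero
intercept is reported as a degenerate regression error. Begg's test
standardises deviates from the fixed-effect mean by
vᵢ = seᵢ² − 1/Σw (falling back to seᵢ² with a logged warning if any
vᵢ ≤ 0), computes Kendall's τ between deviates and variances, and refers
|S| − 1 (continuity correction) to the exact null variance
k(k−1)(2k+5)/18 with the standard tie reduction. The significance level
for both bias tests is 0.01, and raw p-values are always reported. Both
tests, and DerSimonian–Laird pooling itself, are cross-validated against
R's `metafor` in the test suite.

## Ancestry comparison

Welch's unequal-variance t (East Asian minus Caucasian, two-sided, studies
as units) on the MAF and the published-OR columns. Welch rather than
pooled-variance Student is the deliberate choice: the two groups differ in
size (11 vs 26) and spread, and the pooled form would roughly halve the MAF
statistic. No weighting by study size: the comparison treats studies as
exchangeable units.

## Synthetic-data generator

`simulate_studies` draws, per study: θᵢ ~ N(ln OR_true, τ²); a control
allele frequency p₀ ~ U(p₀ range); the case frequency from θᵢ by the odds
transform at the allele level; arm sizes uniform over the n range; and
genotype counts multinomially under Hardy–Weinberg equilibrium within each
arm at that arm's allele frequency (an optional disequilibrium coefficient
exists, default 0). Dominant/recessive truths are therefore emergent from
the allele-level model, not separately parameterised. The roster each
study writes (N, combined MAF, empirical OR) is computed from its own
genotype counts, so summary-level reconstruction closes the loop exactly.
Defaults mirror the bundled roster: k = 37 with an 11:26 ancestry split,
OR_true = 1.12, τ² = 0.02, 300–3,000 persons per arm, control MAF in
0.2–0.4. A single named generator is seeded once per run, and
`simulate_null_funnel` pins OR_true = 1, τ² = 0 for type-I-error studies.
Validation at these defaults (1,000 replicates): DerSimonian–Laird recovers
ln OR_true within 2 Monte-Carlo standard errors and mean τ̂² within 15 % of
truth; on null funnels with k = 20 the Q test rejects at ≈4–5 % (α = 0.05)
and Egger's test at ≈1–2 % (α = 0.01).

What the generator does **not** emulate: publication selection (beyond an
optional se-dependent filter), covariate adjustment in the source studies,
genotyping error, population stratification within a study, or
Hardy–Weinberg departures in cases caused by strong true effects under
non-multiplicative penetrance. Passing simulation checks therefore
validates the estimators under the random-effects model's own assumptions,
not the field realism of any particular roster.

## Limitations of the bundled roster

The roster is a faithful transcription of a published summary table, and
its internal checks pass exactly (sample totals 22,395/48,773; the Welch t
on the published OR column reproduces the reported 1.75). But several of
its OR entries are inconsistent with the significance levels the source
studies themselves reported (e.g. rows whose printed OR would imply |Z| > 5
for studies that reported p ≈ 0.2–0.9), i.e. the printed column does not
equal the per-study effects that produced the originally reported pooled
numbers. Reconstruction from the printed rows consequently yields more
between-study dispersion (overall I² ≈ 79.5 % vs the reported 57.2 %) and
slightly different pooled estimates (overall OR 1.101 vs 1.12; Caucasian
1.116 vs 1.16), with the East Asian stratum (OR 1.084, p = 0.38) agreeing
with the reported non-significance. The qualitative conclusions —
significant Caucasian and pooled association, no East Asian association,
significant heterogeneity in all strata, no publication bias, leave-one-out
stability with every interval excluding 1 — all reproduce. The Welch t on
the MAF column is 5.81 from the 2-decimal printed values (the reported 5.89
evidently used unrounded frequencies). Exact recovery of the original
per-study effects would require the underlying genotype data, which was
never deposited.

Other limitations: biallelic SNPs only; no REML/Paule–Mandel/
Hartung–Knapp alternatives to DerSimonian–Laird (deliberate — the rule set
implemented here is the classical one this roster was analysed with); no
meta-regression; no trim-and-fill.
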