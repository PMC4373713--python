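# Methods

## Setting

A diallelic SNP observed in `s` subpopulations is held as genotype counts
`(n_AA, n_Aa, n_aa)` per population, where `A` is the counted allele with
sample frequency `p_hat = (2 n_AA + n_Aa) / (2n)`. Population
differentiation (PD) is any divergence of the `p_hat_i` beyond sampling
noise. The package implements four per-SNP PD measures, a simulation
benchmark of their sensitivity and specificity, and an
F_st-classification plus gene-set-enrichment pipeline.

## The four measures

**Weir–Cockerham F_st (`fst_weir`).** The moment estimator
`theta_hat = (MSP − MSG) / (MSP + (n_c − 1) MSG)` with the mean squares
and `n_c` as printed in the README. Because the ANOVA underlying the
estimator is over *allele indicators*, `n_i` is counted in alleles
(2 × individuals for diploids); the conversion from genotype counts is
internal. Conventions:

- `theta_hat` is reported raw — it is legitimately slightly negative near
  zero differentiation (the estimator is unbiased around 0) and is never
  clamped. With `MSP = 0` and balanced sizes it equals `−1/(n_c − 1)`.
- A locus monomorphic in every population has `MSP = MSG = 0`;
  `theta_hat` is NaN (0/0 carries no information about differentiation),
  propagates, and such SNPs are excluded from group summaries and never
  rejected by benchmark rules.
- `theta_hat ≤ 1` always, with equality exactly when `MSG = 0 < MSP`
  (complete fixation of different alleles).

**Chi-square homogeneity (`chisq_homogeneity`).** Pearson X² on the
`2 × s` allele-count table, `df = s − 1`, no continuity correction —
the table form that matches the null `p_1 = … = p_s` stated on allele
frequencies. A `3 × s` genotype-table variant exists behind the `table`
switch (empty genotype classes dropped, df adjusted). If one allele is
absent everywhere, `X² = 0, p = 1`.

**Dosage ANOVA (`anova_f`).** One-way fixed-effects ANOVA on dosages
(0/1/2 per individual), `F = MS_between / MS_within` with
`df = (s − 1, n − s)` in individual units. Degenerate draws are not
errors, so simulation loops never abort: zero within-variance with
unequal means gives `F = +inf, p = 0`; all values identical gives
`F = NaN, p = 1`.

**NSCM standardized distance (`nscm_ssd`).**
`d_ik = (a_ik − a_k) / (m_i (s_0 + s_k))` and `SS_d = Σ_i d_ik²`, with
population means `a_ik` and overall mean `a_k` on the frequency scale
(dosage/2), the pooled within-population SD `s_k` (denominator `n − s`;
the unbiased pooled variance — the source formulation does not fix a
denominator), and `s_0` the median `s_k` over the SNP panel, which keeps
distances from exploding when `s_k` is tiny. `m_i = sqrt(1/n_i + 1/n)`
in individuals: the scaling is sometimes printed without the radical,
but only the square root makes `m_i · s_k` the standard error of the
numerator, so `sqrt` is the default and the literal form is a
documented option (`m_mode="literal"`). A single-SNP panel is allowed
(its own `s_k` serves as `s_0`).

## Simulation design

`make_p_vector(d)` draws `p_1 ~ Uniform[0, min(0.5, 1 − 2d)]` and sets
`p_2 = p_1 + d`, `p_3 = p_1 + 2d`. The 0.5 cap uses the `p → 1 − p`
symmetry of every measure: frequency triples above 0.5 are mirror images
of triples below it. `d = 0` is the null.

`draw_snp_dataset` draws each population's genotype vector as a **single
multinomial** with cell probabilities `(p², 2pq, q²)`. Three independent
binomials with those marginals cannot sum to `n_i`; the multinomial is
the only closure-consistent model with the same three marginals.

`scenario_grid` reproduces the published grid literally: balanced sizes
(100,100,100)/(200,200,200)/(400,400,400) and unbalanced
(200,100,100)/(100,200,100)/(100,100,200) individuals; the distribution
study crosses them with `d ∈ {0.1, 0.2, 0.3}` at 200 datasets, the
sensitivity/specificity study with `d ∈ {0, 0.05, …, 0.3}` at 100
datasets × 100 repetitions (the published replication, also the default
problem size of the acceptance runs; one full condition takes well under
a second via the vectorized kernels in `_engine`, which are tested for
exact agreement with the scalar implementations). Seeding is strictly
hierarchical: one master seed, per-scenario sub-seeds derived by
position through `SeedSequence`, per-repetition streams derived from the
scenario seed — repetitions are independent and every run is bit
reproducible.

## Decision rules and their calibration

The chi-square and ANOVA tests reject at `p ≤ alpha` (default 0.05; each
simulated SNP is one test — a BH variant across a repetition's datasets
exists behind `use_bh`). F_st and SS_d have no inherent test, and the
choice of their thresholds is the one genuinely open design decision in
the benchmark; published comparisons of this kind do not state it.

- **SS_d** rejects above its null 0.99 quantile, calibrated once at the
  reference configuration (100,100,100) and held fixed across scenarios.
  Since `d_ik` is standardized, the null distribution of `SS_d` barely
  moves with sample size, so the held threshold keeps specificity ≈ 0.99
  everywhere while making the rule deliberately conservative.
- **F_st** defaults to a Monte-Carlo critical value: the null 0.95
  quantile of `theta_hat` calibrated *per sample-size configuration*
  (20 000 null draws). Rationale: sensitivities are only comparable at
  matched size — a fixed value threshold such as Wright's 0.05 boundary
  is a *classification* rule whose power at small effect sizes is
  essentially zero (at `d = 0.05`, n = 100/pop, `theta ≈ 0.008` while
  the fixed boundary sits six null-SDs away), which says nothing about
  the estimator's discriminating ability. The fixed Wright rule remains
  available (`fst_rule="wright"`) and is what the specificity-stability
  analysis uses, since that claim is about the fixed-threshold behavior.

Under these defaults the benchmark reproduces the qualitative published
picture: matched-size power of chi-square, ANOVA and F_st is nearly
identical and F_st is weakly ahead at small n and small d; the
conservative SS_d rule is the least sensitive everywhere; specificity of
the fixed-threshold F_st and SS_d rules is stable in sample size; and
the middle-oversampled unbalanced design (100,200,100) is the least
sensitive, because the extreme-frequency populations carry most of the
signal. One published number the simulation does *not* reproduce: the
claimed drop of chi-square/ANOVA specificity to ~92% at (400,400,400).
Under every coherent reading tried (allele or genotype table,
multinomial or independent-binomial generation) the measured null
specificity is ~95% and essentially flat in n — as expected for a
calibrated test whose null model is exactly the generating model. The
package reports what it measures.

## Classification and enrichment

`fst_from_frequencies` applies the estimator to frequency-table input
(`n_i = n_alleles` as given); SNPs seen in fewer than two populations are
dropped with a logged count. Wright's categories with **strict**
inequalities assign SNPs: HD above 0.25, LD below 0.05, boundaries and
NaN to neither. Gene level: HD if *at least one* mapped SNP is HD; LD
only if *all* mapped SNPs are below 0.05 (the published phrasing is
ambiguous; the all-SNP rule is the default because an any-SNP rule would
let one gene satisfy both definitions — the `any` variant exists behind
`ld_rule`). Multi-gene SNPs contribute to every mapped gene. Highlight
SNPs are `theta > 0.5`, descending, ties by id. Population pooling
(e.g. CHB + JPT → EA) is an explicit pre-processing transform: count-
weighted mean frequency, summed allele counts.

Enrichment is the explicit DAVID-style statistic: hypergeometric upper
tail `P(X ≥ k)` for `k` of `n` annotated input genes in a term with `K`
of `N` annotated background genes; fold `(k/n)/(K/N)`; BH q-values
jointly across all tested terms (per-category correction behind a flag);
significant at `q ≤ 0.05`. Only genes annotated to ≥ 1 term count toward
`n` and `N`; terms with `K < 2` are untestable and dropped; DAVID's
EASE-adjusted tail (`k − 1`) is available behind `ease=True` but is not
the default, since the plain hypergeometric test is the named statistic.
BH itself is delegated to `statsmodels.multipletests` and checked
against a hand-rolled step-up in the tests. The `compare_backgrounds`
layout joins three runs (input vs all, family vs all, input vs family)
per term.

## Synthetic fixtures and what they show

`make_annotation_fixture` emulates the shape of a
HapMap-frequencies-plus-PharmGKB input: ~900 SNPs on ~600 genes in three
populations of 500 individuals (1000 alleles), every SNP mapped to a
gene, gene sets in GMT form. Differentiation is planted generatively:
each gene is HD with probability `frac_hd` (default 0.25), an HD gene's
first SNP is drawn at spacing `d = 0.4` (true `theta ≈ 0.5`, comfortably
above 0.25 at this sample size), all other SNPs at `d = 0`. One term is
planted enriched at fold 5 with 20 genes: since fold enrichment of an
input of `n` genes against `N` background genes cannot exceed `N/n`, the
annotation pool covers half the genes with HD genes held at ~15% of the
pool, and the term's HD membership `k = round(5 · 20 · n/N)` is solved
from the realized annotated counts, making the planted fold exact up to
rounding. `planted_truth` records all generating labels.

What the fixtures do **not** emulate: linkage disequilibrium between
SNPs (all independent), phase-dependent missingness and per-SNP sample
size variation of real HapMap releases, multi-allelic sites, GO term
hierarchy (annotations are flat sets), and real annotation sparsity.
Passing recovery tests therefore shows the pipeline's statistics and
bookkeeping are correct under the generating model — not that real-data
gene lists would be reproduced; the published real-data counts (654
SNPs, 160/173 HD/LD, the specific rs-number F_st values and enrichment
tables) depend on external database versions and are out of scope.

## Numerical conventions

- Strict threshold inequalities everywhere; boundary values are never
  group members.
- NaN statistics never reject, never enter summaries, and serialize as
  `NA`; floats serialize with six significant digits.
- Frequency-table validation accepts `freq · n_alleles` within
  `5e-3 · n` of an integer (two-decimal printing precision).
- All randomness flows from explicit `numpy` generators; library-level
  functions never touch global random state.
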