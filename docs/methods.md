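# Methods

This note records the models the package implements, the choices made where
the design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Synthetic data

**Genotypes.** Haplotypes are drawn through a Gaussian copula: each LD block
carries a latent AR(1) Gaussian with per-step correlation ρ
(`correlation_decay`), and an allele is present when the latent falls below
Φ⁻¹(MAF). Dosages are the sum of two independent haplotypes, so variants are
in Hardy-Weinberg proportions, blocks are exactly independent, and
within-block LD decays geometrically. Two caveats follow from the
construction: genotype correlation is attenuated relative to the latent
correlation (a threshold-variable effect), and the maximum attainable r²
between two variants is capped by the difference of their allele
frequencies. Tests that need r² > 0.8 proxies therefore plant equal MAFs
with ρ ≥ 0.995; tests that need LD-free pools use ρ ≤ 0.3.

**Traits.** A trait is Σ β_j·g_j + covariate effects + N(0, σ²) on the
natural-log-residual scale. The default study conditions mirror the emulated
design: 16 cohorts totalling 45,861 samples with the two largest at 10,070
and 8,925; analyses run per cohort and are pooled by meta-analysis only.
Planted betas are interpreted on the *adjusted-residual* scale: the two-step
adjustment (residualize on covariates, Blom inverse-normal transform
(rank − 3/8)/(n + 1/4), residualize again) standardizes the trait variance
to 1, so a planted beta is recovered unbiasedly when the noise is balanced
so that total variance is 1 (as the variance-explained worked example does);
otherwise estimates shrink by 1/sd(trait), which is a property of
rank-normalized GWAS generally, not of this implementation. Population
structure is represented by generic covariates rather than principal
components, since the pipeline consumes residualized traits either way.

**QC columns.** Imputation quality, HWE p, and call rate are drawn
independently of the genotypes. They exist to exercise the QC filters, which
is the logic under test; imputation itself is out of scope.

**Annotations.** The planted enrichment `fold` is defined on the estimand of
matched-control enrichment: the probability that an index variant *or one of
its r² > 0.8 proxies* overlaps the annotation, relative to the same
probability for a background variant with the same proxy count. Covered
causal indexes get an interval at the lead; uncovered ones have their whole
proxy neighbourhood forced off. With heterogeneous proxy counts the matched
bins ({0}, 1–4, 5–9, 10–24, ≥25) mix counts within a bin and the recovered
fold attenuates toward the bin average; with very sparse annotations the
per-replicate ratio observed/expected is inflated by E[1/expected]. The
calibration tests use a proxy-free pool and a 5% background so neither
estimator artefact dominates; both are visible (and expected) outside that
regime.

## Meta-analysis

Fixed-effects IVW with per-study and post-meta genomic control. λ is the
median χ² over 0.455936; correction only ever inflates standard errors
(λ ≤ 1 is reported but not applied). The meta-level λ is computed on pooled
z-scores *after* per-study correction. EAF is pooled as the sample-size
weighted mean. QC exclusion logs use first-failing-rule precedence in the
order MAC, MAF, call rate, HWE, info, SE, so reason codes are deterministic.
Lead selection ties break by smaller SE then marker name. Strand-ambiguous
A/T and C/G records are dropped only when MAF > 0.4; otherwise match/swap
and strand-complement reconciliation apply.

The bundled demo genome is small and signal-dense (3 of 7 blocks carry
causal variants), so the post-meta λ lands around 1.3–1.4 and the double-GC
correction is conservative there; the λ-calibration property is instead
asserted on a null genome in the test suite, where λ = 1.00 ± 0.03.

## Approximate conditional analysis

For selected set S the normal equations are B β = X'y with
B_jk = r_jk √(d_j d_k N_j N_k) and (X'y)_j = d_j N_j b_j, where r comes from
the reference panel, d_j is the panel's *empirical* dosage variance, and b_j
the marginal beta. Using empirical variance rather than 2f(1−f) makes the
joint solution exactly equal multiple-regression OLS when the panel is the
generating sample, which is the oracle test; under HWE the two agree to
O(1/n). The phenotypic variance is the median across window variants of
d_j N_j se_j² + d_j b_j², and the residual variance for conditional SEs uses
the median window N. Stepwise selection seeds with the smallest p, skips
candidates whose multiple-regression r² on the selected set exceeds 0.8,
stops at three signals, and reports each signal's statistics from the final
joint fit (a lone signal keeps its marginal statistics, so conditioning on
nothing is exactly the identity). Singular systems drop the offending
candidate and continue. A signal is *consensus* when at least two of the
panels report it at mutually-proxy variants (r² > 0.8 in a designated LD
source — default the largest panel, since the proxy source is an open
choice); the representative is the group member with the smallest
conditional p. The MAF screen excludes a signal when |meta MAF − panel MAF|
exceeds 0.05 (absolute, config-exposed) in a majority of panels carrying the
variant, or when no panel carries it.

## Fine-mapping

ln BF = z²/2 exactly — the proportionality constant in the underlying
Gaussian-ABF derivation cancels under normalization, so no prior-variance
shrinkage term is applied. Posteriors are normalized in log domain. The
credible set is the smallest posterior-sorted prefix reaching 0.99 with
deterministic tie order (posterior descending, then marker); a uniform
100-variant window yields a 99-variant set. Multi-signal loci are fine-mapped
on conditional estimates (conditioning on the locus's other accepted
signals, nearly-collinear variants dropped at r² > 0.99). The extension adds
panel variants with r² ≥ 0.8 with the lead — inclusive boundary by default,
strict mode available, window-restricted to ±500 kb — flagged
`extension_only` with *absent* posteriors, since they were never scored.

## Colocalization

Pairwise: the standard five-hypothesis sum over Wakefield ABFs
(W = 0.15² for quantitative traits, 0.2² for case-control), computed in log
domain; an O(n²) brute-force enumeration oracle pins it to 1e-10 in tests.
Multi-trait: for every subset of traits, a shared-variant configuration mass
(prior p1·γ^(m−1), γ = prior.2) competes with an all-associated-but-not-
aligned mass (prior p1^m, computed as the product of per-trait sums minus
the shared term). PR is the posterior that all traits in the set are
associated, PA the posterior that they align on one variant given
association, PPFC = PR·PA. Configurations with partial sharing inside the
non-aligned mass are approximated by that product construction; this is the
deliberate simplification relative to the full hierarchical enumeration, and
two-trait calls agree with the pairwise engine on ≥95% of mixed
truth scenarios in the test suite. When PR or PA miss their thresholds
(default 0.6, the low end of the sensitivity grid) the trait whose removal
most improves PPFC is dropped and the remainder re-evaluated. Sensitivity
scores are pass fractions over a 100-point log-uniform p12 grid
(10⁻⁸..10⁻⁴) for the pairwise engine and the regional/alignment/prior.2
grid (0.6–0.9 × 0.6–0.9 × 0.98–0.995) for the multi-trait engine. The
composite call is posterior > 0.6 AND (sensitivity > 0.4 OR lead r² > 0.8);
missing lead r² counts as 0 with a log entry.

## Enrichment

Overlap is proxy-inclusive (lead or any r² > 0.8 proxy inside an interval;
BED intervals are 0-based half-open and merged per chromosome). Controls
are drawn without replacement from the same proxy-count × MAF-decile ×
gene-distance-quartile cell as the index, excluding the index, its proxies,
and every other index variant — the last exclusion matters only because the
synthetic pool is thousands of variants rather than millions. Undersized
cells relax to neighbouring bins (expanding Chebyshev distance) with a
warning. The p-value is the exact upper tail of the Poisson-binomial
distribution of per-index control rates, by dynamic-programming convolution;
500 controls per index stabilize each rate to about ±0.02. Calibration
tests assess the discrete tail through its randomized probability integral
transform, which is exactly uniform when the model holds; the reported
p-value itself remains the conservative tail (a mid-p variant is exposed on
the result object).

## SMR and HEIDI

Single-instrument SMR at the strongest cis-eQTL variant (instrument
threshold 5×10⁻⁸); the Bonferroni threshold defaults to 0.0029 and is
recomputed as 0.05/(genes tested) when a count is given. HEIDI eligibility:
eQTL p < 1.57×10⁻³ (χ² > 10, the cited method's default), LD r² with the
top variant in [0.05, 0.9], at most 20 SNPs strongest-first. The deviation
vector d_i = b_xy(i) − b_xy(top) gets a delta-method covariance in which
within-study errors correlate through panel LD and the two studies are
independent; the statistic Σ(d_i/sd_i)² is referred to a weighted sum of
χ²₁ with weights the eigenvalues of the deviation correlation matrix,
evaluated by Imhof integration (validated against Monte Carlo and the
equal-weights χ² special case). HEIDI's delta-method is a large-z
approximation: with weak instruments among the eligible SNPs its type-I
error inflates, so the calibration simulations use strongly-powered eQTL
studies — the regime the method assumes. Calibration simulations also draw
fresh genotypes each replicate; re-using one genotype draw across
replicates turns that draw's LD noise into a shared bias and makes the
measured error rate unstable.

## Pipeline and problem sizes

The pipeline stages are simulate → QC → meta → loci → conditional → finemap
→ coloc → direction → enrich → SMR, each writing TSVs plus a JSON manifest
(seed, config hash, thresholds, per-stage counts) and a JSON-lines audit log
of per-variant exclusions. Configuration is validated strictly (unknown keys
rejected). Reruns with the same config are bit-identical.

The bundled demo uses 16 cohorts of 800 samples (12,800 total), 660
variants in 7 blocks, three reference panels of 2,000/1,800/1,500 samples,
companion traits as single 20,000-sample studies, and 420-sample eQTL
studies — sizes chosen so the planted effects (0.14–0.18 SD per allele) sit
comfortably past genome-wide significance while the full run stays in the
tens of seconds. Simulation-based tests use 100–1,000 replicates at
problem sizes (panels of 25–500 variants, studies of 400–6,000 samples)
where the Monte-Carlo error of each checked quantity is several times
smaller than its tolerance.

## Known limitations

- LD is block-diagonal AR(1); no realistic human LD maps, no imputation,
  no mixed-model association, no X chromosome.
- The multi-trait colocalization engine enumerates trait subsets, fine for
  the ≤6 traits considered here, and approximates partial-sharing priors as
  described; it is not a reimplementation of the branch-and-bound
  hierarchical search.
- Fine-mapping assumes one causal variant per signal after conditioning;
  no SuSiE/FINEMAP-style model averaging, no functional priors.
- Cohort heterogeneity is modelled only through size and noise scale.
- BMI-adjusted vs unadjusted analyses are two configurations of the same
  pipeline; the union of their loci is a report-level merge, not a joint
  model.
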