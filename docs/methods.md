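# Methods

`candex` is a relational-style integration layer over cancer cell-line
multi-omic tables, plus four analysis procedures built on it. This note
documents the statistical procedures, the parameters that matter, the
synthetic study conditions every guarantee is measured under, and the
numerical choices made where the design was genuinely open.

## Data model and identifier canon

All tables are joined on two canonical keys: a gene `stable_id` (an
Entrez-style numeric string) and a cell-line `line_id` (`ACH-…`). Two index
tables translate everything else — gene symbols and aliases
(case-insensitively), cell-line display names — into those keys, and every
reader pushes incoming identifiers through the translators, dropping and
counting whatever fails to translate (`rows_in == rows_kept + rows_dropped`
always). Analysis modules never see a raw symbol. Sex annotations pass
through an explicit mapping (`{Male, M, male} → male`, etc.); anything
unmapped is an error, and `unknown` lines are excluded from sex-stratified
analyses rather than imputed.

Entity classes (`Gene`, `CellLine`, `Cancer`, `Organelle`, `GeneCluster`,
`CellLineCluster`) are read-only views: every accessor is, by contract,
equivalent to directly subsetting the underlying tables, and that
equivalence is property-tested against brute-force table scans. Clusters
are deduplicated and sorted by ID so every downstream statistic is
deterministic in the input order.

**Mutant/wildtype semantics.** A line is *mutant* for a gene if it carries
at least one record from a documented protein-altering class list
(missense, nonsense, frameshifts, in-frame indels, splice site, start/stop
disruptions); *wildtype* means no protein-altering record. Silent and
intronic records therefore neither make a line mutant nor void its wildtype
status, and mutant/wildtype is a true partition of any cluster. An explicit
variant class or protein change (normalized by stripping a leading `p.` and
uppercasing) narrows the match.

## Differential essentiality

Given two disjoint groups of lines, each gene's CERES gene-effect scores are
compared with a two-sided Mann–Whitney U test; the effect magnitude is the
difference in group mean CERES, with Cohen's d (pooled-SD form) alongside.
Missing scores are excluded pairwise; genes with fewer than two usable
observations in either group are flagged untestable.

*Hypothesis-reduction filter.* Before testing, each gene can be scored by
the mutual information between its essentiality profile and a discrete
covariate, and genes with MI strictly greater than median + 1 sample
standard deviation (across genes) are removed. The MI estimator is the
plug-in histogram estimator in nats on equal-frequency-binned values
(default 8 bins) — deterministic, unlike nearest-neighbour estimators. The
covariate defaults to the comparison grouping itself but is configurable,
and the filter can be disabled: MI against the comparison label removes
exactly the strongest candidates, so the scientifically useful covariate is
usually a *confounder* (e.g. lineage), and the recovery guarantees below
are stated with the filter off.

*Mann–Whitney mode.* `auto` uses the exact null distribution whenever both
groups are tie-free with at most 25 observations, and the tie-corrected,
continuity-corrected normal approximation otherwise. The exact distribution
is cheap at these sizes and noticeably better calibrated in the far tail:
at 15 vs 15 lines the exact test's null rejection rate at p < 0.01 is
≈ 0.011, where the continuity-corrected approximation is conservative
(≈ 0.008). Exactness for tie-free inputs up to n = 6 is verified against
full enumeration of all rank labelings.

*Significance.* The headline flag is raw p < α (default α = 0.01) — no
multiplicity adjustment, matching the procedure's stated threshold — and a
BH-adjusted `p_adj` column is always emitted alongside. The two columns
answer different questions: raw p for per-gene screening sensitivity,
`p_adj` for a false-discovery-controlled hit list. Measured at the standard
conditions (below), raw-p flagging gives recall 1.0 on planted effects with
the expected ≈ 1% false-positive background; the BH flag trades a little
recall headroom for FDR ≈ 0–2%.

## Pan-cancer mutation × essentiality screen

Bayes-factor essentiality profiles are binarized at BF > 5 (strictly: a BF
of exactly 5 is non-essential; missing stays missing). Genes are ranked by
the sample variance of their binary profile (ties broken by gene ID) and
the 85th–95th percentile band is kept: over G testable genes the band
[l, u) selects ranks `floor(l·G)` to `floor(u·G)`, so 1000 genes yield
exactly 100. Each (band gene, driver) pair gets a Pearson chi-square test
(df = 1, **no** Yates correction — the uncorrected statistic equals the
closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) and is verified against it to
1e-9) on the 2×2 essentiality × mutation table over lines with non-missing
essentiality. The smallest expected cell is reported so users can filter
low-count pairs; a zero margin flags the pair untestable rather than
raising. Drivers come in two groups — tumor suppressors matched by any
nonsense mutation, oncogenes matched by specific missense protein changes —
and self-pairs (gene == driver) are retained and labeled, since oncogene
self-essentiality is a finding, not an artifact. Significant pairs are
followed up on the continuous CERES scale (Mann–Whitney, mean difference,
Cohen's d, mutant vs wildtype lines) and reported as onco-only, tsg-only
and combined groups. Raw chi-square p-values are reported; no
multiple-testing correction is applied across pairs.

## Differential expression

External raw-count matrices are inner-joined with panel counts on canonical
gene IDs (a join report lists genes dropped from each side; disjoint gene
sets are fatal). Normalization is median-of-ratios: per-sample factor =
median over reference genes (rows positive in every sample) of
count/geometric-mean. These factors are defined up to a common scale —
multiplying one sample by c multiplies its factor *relative to every other
sample* by exactly c and leaves the factors' geometric mean unchanged —
and a pseudo-reference fallback (geometric means over positive entries
only) is available when no all-positive gene exists.

The test engine is a deliberately simple negative-binomial Wald test:
per-gene method-of-moments dispersion from pooled within-group moments
(floored at 1e-8), group means on the normalized scale, delta-method
standard error of the log2 fold change, and a two-sided p-value from a
**t reference with residual degrees of freedom** (n₁+n₂−2). The t reference
is the engine's key small-sample calibration choice: with a plug-in
dispersion the Wald statistic is t-like, not normal, and at 10 vs 10
samples the normal reference inflates the far tail enough to double the
realized FDR. The log2 fold change is computed as a difference of logs so
that swapping condition labels negates it bitwise-exactly. There is no
dispersion shrinkage toward a trend, no Cox–Reid adjustment, no independent
filtering and no LFC shrinkage, so per-gene outputs will differ from a full
GLM fit; one test cross-checks fold changes and hit sets against an
independent NB-GLM implementation on a planted fixture, and the package's
own guarantees are the calibration and recovery numbers below. All-zero
genes are excluded before testing (and therefore before BH, which changes
m). BH adjustment is the standard step-up rule; significance is
padj < α (default 0.01). When condition labels coincide exactly with data
sources (panel vs external), a confounding warning is logged — that design
cannot separate biology from batch, and no batch correction is attempted.

## Localization confidence and target nomination

Three localization resources annotate (gene, compartment) pairs with
categorical confidences. Each source's categories map to an integer 0–4
via an explicit `ConfidenceMap`; the mapping is a required input with a
shipped generic 4-tier default (validated/enhanced = 4 down to
unreliable = 0), because the per-source tier vocabularies vary by release —
an unmapped category is an error, never a silent zero. Scores are summed
over sources per (gene, compartment) to a 0–12 total; an absent source
contributes 0. "Cell membrane" aliases to "plasma membrane".

A gene is nominated as a surface target iff padj < α, log2fc > 0, it has a
plasma-membrane annotation with total score ≥ `min_score` (default 6 — a
score of exactly 6 passes), and it is not on the user-supplied manual
exclusion list (recorded in output provenance, never hard-coded). Every
input gene appears exactly once in the output, either nominated or with the
first failing reason in the fixed order `not_significant, not_upregulated,
no_membrane_annotation, low_score, manual_exclusion`; the nomination set
shrinks monotonically as `min_score` rises.

## Synthetic study conditions

The generator (`candex.synthdata`) emits the full panel-schema file set —
CERES and Bayes-factor matrices, counts (panel plus external benign
samples), MAF-like mutations, sample info, three-source localization,
complexes — with planted signals enumerated in a `truth.csv`. One global
seed drives every stream through `SeedSequence` children in a fixed order,
so identical (spec, seed) runs are byte-identical.

Default conditions: non-essential genes at CERES 0 and an essential
backbone (first 10% of genes) at −1, both with σ₀ = 0.15; Bayes factors
BF = 10·(−CERES) + N(0, 1); counts NB with log-normal base means (median
≈ 100, log-sd 1), dispersion 0.1, per-sample size-factor multipliers in
[0.7, 1.4]; driver mutations Bernoulli per line with specified protein
changes plus a 5% silent background. These are the conditions under which
planted effects at the standard thresholds are detectable with 10–15
samples per group. The standard fixtures used by the acceptance checks:

- *Essentiality recovery*: 2000 genes × 30 lines (15 vs 15 by sex), 50
  non-backbone genes shifted by Δ = −0.6. Recall ≥ 0.9 at raw p < 0.01
  (measured: 1.0) and FDR ≤ 0.1 on the BH flag (measured ≈ 0–2%); the
  matching null fixture's rejection rate at p < 0.01 lies in [0.005, 0.02].
- *Expression recovery*: 3000 genes, 10 vs 10 samples, 100 genes at
  log2fc = 2, dispersion 0.1. Recall ≥ 0.9 and FDR ≤ 0.05 at padj < 0.01
  (measured: 1.0 and ≈ 1–3%).
- *Pan-screen*: 600 genes × 60 lines, one gene conditionally essential
  exactly in driver-mutant lines among forty lineage-conditional
  high-variance genes; the screen's minimal-p pair is the planted one.
- *Surface targets*: 500 genes, 20 malignant vs 4 benign samples, 3 planted
  upregulated membrane genes (guaranteed score ≥ 6); exactly those 3 are
  nominated.

What the generator does **not** emulate — and what passing these tests
therefore does not show about real data: gene–gene correlation and
co-essentiality structure, copy-number effects on CERES, realistic mutation
spectra or mutual exclusivity, batch structure beyond scalar size factors,
and annotation-version mismatches between merged count sets. Problem sizes
were chosen as the smallest at which the planted-signal geometry is
comfortably identified; they are the package's standard desk-scale study
conditions, not estimates of real-panel power.

## Degenerate inputs and tie-breaks, collected

- Mann–Whitney with an empty group → untestable flag (NaN), not an error.
- Cohen's d with < 2 observations per group or zero pooled SD → NaN,
  excluded from rankings.
- MI with constant values, a single covariate label, or < 2 observations →
  0 with a degenerate flag; MI-filter threshold uses the sample (n−1) SD
  and a strict inequality, so a constant MI field removes nothing.
- Chi-square with a zero margin → untestable flag.
- Variance-band ties → broken by gene ID; result tables sort by
  (p, |effect| descending, gene ID).
- Counts matrices reject non-integer or negative cells with coordinates;
  CERES/BF matrices propagate NaN and all statistics exclude it pairwise.
- "Top 7 / bottom 3" reporting uses the same (p, |mean_diff|, gene ID) key.

## Known limitations

- The NB engine is two-condition only (no covariates, no multi-factor
  designs) and is not a drop-in replacement for a full GLM fitter.
- Live retrieval of public releases is a registry stub (URL + checksum
  contract); nothing downloads at analysis time.
- The shipped confidence-map default is a generic 4-tier stand-in; real
  analyses should supply the mapping matching their annotation release.
- Raw p-values in the essentiality and screen modules are intentionally
  unadjusted (the BH column is informational there); users scanning many
  strata should adjust across their own hypothesis family.
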