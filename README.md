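# candex — cancer dependency explorer

Large public panels of cancer cell lines now come with genome-scale CRISPR
knockout dependency screens (CERES gene-effect scores, Bayes factors),
RNA-seq counts, somatic mutation calls, protein localization annotations and
curated complex membership — but each table lives behind its own identifier
scheme, and the questions biologists actually ask span several tables at
once: *which genes become essential only in KRAS-mutant lung lines? do male
and female KRAS-driven tumors depend on different genes? which upregulated
genes encode cell-surface proteins an antibody could reach?*

`candex` is a query layer plus four analysis procedures for exactly those
questions, aimed at cancer functional-genomics analysts working with
DepMap/CCLE-style exports. Two index tables translate gene symbols/aliases
and cell-line names to canonical keys; entity classes (`Gene`, `CellLine`,
`Cancer`, `Organelle`, `GeneCluster`, `CellLineCluster`) wrap filtered views
of every dataset so a three-way stratification (disease × mutation status ×
sex) is one method call. A seeded synthetic-data generator emits the full
file schema with planted signals, so every statistical guarantee in the test
suite is measured against known ground truth.

## The statistics at the core

- **Differential essentiality** — per gene, a two-sided Mann–Whitney U test
  of CERES scores between two line groups (exact null distribution for
  tie-free groups up to n = 25), effect size as the difference in group
  mean CERES (Δ = mean₁ − mean₂) and Cohen's d; optional
  hypothesis-reduction filter that removes genes whose mutual information
  with a covariate exceeds median + 1 SD (plug-in histogram MI, nats,
  quantile bins). Significance: raw p < 0.01, with BH-adjusted values
  emitted alongside.
- **Pan-cancer screen** — Bayes factors binarized at BF > 5, genes kept in
  the 85th–95th variance percentile band, then a Pearson chi-square
  (df = 1, uncorrected) per (gene, driver-mutation) pair, tumor-suppressor
  nonsense and oncogene missense driver groups, with Mann–Whitney and
  Cohen's d follow-up on the continuous scale.
- **Differential expression** — median-of-ratios size factors
  (sⱼ = medianᵍ kᵍⱼ/(∏ᵢ kᵍᵢ)^(1/m)), a negative-binomial Wald test with
  method-of-moments dispersion and a t reference with residual df, BH
  adjustment; external raw-count sets are inner-joined on canonical gene
  IDs before testing.
- **Surface-target nomination** — categorical localization confidences from
  three sources mapped to 0–4 and summed to a 0–12 score; nominated =
  significantly upregulated (padj < 0.01, log2FC > 0) ∧ plasma-membrane
  score ≥ 6 ∧ not manually excluded, with a reasoned exclusion for every
  non-nominated gene.

See `docs/methods.md` for assumptions, calibration choices and degenerate-
input handling.

## Worked example

Generate a 500-gene × 40-line fixture in which the driver gene `G0001` is
self-essential in its own mutants (Δ = −1.0) and `G0200` is synthetically
lethal with it (Δ = −0.7), then run the differential-essentiality pipeline:

```python
from candex import (CellLineCluster, DataStore, DriverModel, FixtureSpec,
                    MIFilterParams, PlantedEssentiality,
                    differential_essentiality, generate)

spec = FixtureSpec(
    n_genes=500, n_lines=40, seed=7, lineages=("lung",), lineage_probs=(1.0,),
    drivers=(DriverModel(gene="G0001", rate=0.45,
                         protein_changes=("G12D", "G12V")),),
    planted_essentiality=(
        PlantedEssentiality("G0001", {"mutated": "G0001"}, -1.0),
        PlantedEssentiality("G0200", {"mutated": "G0001"}, -0.7)))
generate(spec, "demo_fixture")

store = DataStore.from_directory("demo_fixture")
lines = CellLineCluster.all_lines(store)
mutant = lines.filter_lines(mutated="G0001")
wildtype = lines.filter_lines(wildtype="G0001")
print(f"{len(mutant)} mutant vs {len(wildtype)} wildtype lines")

res = differential_essentiality(
    store.ceres.df, mutant.line_ids, wildtype.line_ids,
    alpha=0.01, mi_params=MIFilterParams(enabled=False))
print(res.head(3)[["gene", "U", "p", "p_adj", "mean_diff", "cohens_d"]]
      .to_string(index=False))
```

Output:

```
14 mutant vs 26 wildtype lines
 gene     U            p    p_adj  mean_diff  cohens_d
10001   0.0 2.651795e-07 0.000077  -0.970390 -7.911569
10200   1.0 3.083121e-07 0.000077  -0.686457 -3.894226
10036 282.0 4.780832e-03 0.501134   0.132298  0.962908
```

The two planted genes head the table: `U = 0` means every mutant line is
more dependent than every wildtype line, the recovered mean-CERES
differences (−0.97, −0.69) match the planted shifts, and both survive BH
adjustment while the best background gene (third row) does not. The same
analysis is available from the shell:

```bash
candex diff-ess --data-dir demo_fixture \
    --group-a mutated=G0001 --group-b wildtype=G0001 \
    --no-mi-filter --out hits.csv
```

Other subcommands: `candex validate-config`, `candex query`,
`candex pan-screen`, `candex diff-exp`, `candex surface-targets`,
`candex make-fixture`, and `candex run <workflow>` for the four end-to-end
workflows (stratified heat-map tables, driver synthetic lethality,
sex-disparity, surface targets), each of which writes CSV tables plus a
JSON report of thresholds, group sizes and provenance.

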