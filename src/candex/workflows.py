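"""End-to-end analysis workflows composed from the other modules.

Each workflow is a pure function of (store, parameters): re-running with the
same inputs reproduces identical tables, and each returns a
:class:`WorkflowReport` carrying the thresholds actually applied, group
sizes, provenance, and the result tables.  Tables — not plots — are the
output contract.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datastore import DataStore
from .entities import Cancer, CellLineCluster
from .errors import NotFoundError
from .essentiality import (
    MIFilterParams,
    differential_essentiality,
    mean_essentiality_by_group,
)
from .expression import merge_counts, nb_wald_test
from .localization import (
    ConfidenceMap,
    LocalizationTable,
    apply_confidence_map,
    nominate_surface_targets,
)

logger = logging.getLogger(__name__)

TABLE_FLOAT_FORMAT = "%.6g"


@dataclass
class WorkflowReport:
    """Inputs, thresholds, group sizes and result tables of one workflow run."""

    workflow: str
    thresholds: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "workflow": self.workflow,
            "thresholds": self.thresholds,
            "group_sizes": self.group_sizes,
            "provenance": self.provenance,
            "warnings": self.warnings,
            "tables": {name: len(df) for name, df in self.tables.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all tables as CSV plus the report JSON, deterministically."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in self.tables.items():
            path = out_dir / f"{self.workflow}_{name}.csv"
            df.to_csv(path, index=False, float_format=TABLE_FLOAT_FORMAT)
            paths[name] = path
        report_path = out_dir / f"{self.workflow}_report.json"
        report_path.write_text(self.to_json() + "\n")
        paths["report"] = report_path
        return paths


def _provenance(store: DataStore, seed: int | None = None) -> dict:
    prov = {}
    if store.config is not None:
        prov["config_hash"] = store.config.content_hash()
        prov["releases"] = {
            name: entry.release_label for name, entry in store.config.datasets.items()
        }
    if seed is not None:
        prov["seed"] = seed
    return prov


def wf_strata_heatmap(
    store: DataStore,
    gene_list: Sequence[str],
    diseases: Sequence[str],
    stratify_gene: str | None = None,
    stratify_class: str | None = None,
    seed: int | None = None,
) -> WorkflowReport:
    """CERES submatrix for a gene list across disease cohorts, with lines
    grouped by (disease x mutant/wildtype of the stratifying gene) and
    per-group per-gene means appended.

    Unresolvable gene symbols are reported and skipped; the workflow
    continues with the rest.
    """
    report = WorkflowReport(workflow="strata_heatmap",
                            provenance=_provenance(store, seed))
    resolved, bad = [], []
    for q in gene_list:
        try:
            resolved.append(store.gene_index.translate(q))
        except NotFoundError:
            bad.append(str(q))
    if bad:
        report.warnings.append(f"unresolvable gene symbols skipped: {bad}")
    if not resolved:
        raise ValueError("no gene in the list could be resolved")

    groups: dict[str, list[str]] = {}
    for disease in diseases:
        cohort = Cancer(store, disease)
        if len(cohort) == 0:
            raise ValueError(f"disease {disease!r} resolves to no cell lines")
        if stratify_gene is None:
            groups[str(disease)] = list(cohort.line_ids)
            report.group_sizes[str(disease)] = len(cohort)
        else:
            if stratify_class is not None:
                mutant = cohort.filter_lines(
                    mutated={"gene": stratify_gene, "variant_class": stratify_class})
            else:
                mutant = cohort.filter_lines(mutated=stratify_gene)
            wildtype = CellLineCluster(
                store, set(cohort.line_ids) - set(mutant.line_ids))
            groups[f"{disease}|mutant"] = list(mutant.line_ids)
            groups[f"{disease}|wildtype"] = list(wildtype.line_ids)
            report.group_sizes[f"{disease}|mutant"] = len(mutant)
            report.group_sizes[f"{disease}|wildtype"] = len(wildtype)

    matrix = store.ceres.df
    present = [g for g in resolved if g in matrix.index]
    missing = sorted(set(resolved) - set(present))
    if missing:
        report.warnings.append(f"genes absent from the essentiality matrix: {missing}")
    all_lines = [l for lines in groups.values() for l in lines]
    sub = matrix.loc[present, [l for l in dict.fromkeys(all_lines)]]
    means = pd.DataFrame({
        label: matrix.loc[present, lines].mean(axis=1, skipna=True)
        for label, lines in groups.items() if lines
    })
    report.thresholds["stratify_gene"] = stratify_gene
    report.thresholds["stratify_class"] = stratify_class
    report.tables["scores"] = sub.reset_index(names="gene")
    report.tables["group_means"] = means.reset_index(names="gene")
    return report


def wf_driver_sl(
    store: DataStore,
    disease: str,
    driver: str,
    exclude_other: str | None = None,
    seed: int | None = None,
) -> WorkflowReport:
    """Mean essentiality of every gene in driver-mutant vs wildtype lines.

    ``exclude_other`` removes lines mutant for a second driver from both
    groups before averaging (the with/without-removal runs over two drivers
    realize the full 8-way binning).  The deviation column is
    mean(mutant) - mean(wildtype), the shift off the y = x identity line;
    the table covers every gene in the matrix (untestable genes keep missing
    cells) and is sorted by |deviation| descending.
    """
    cohort = Cancer(store, disease)
    if exclude_other is not None:
        cohort = cohort.filter_lines(wildtype=exclude_other)
    mutant = cohort.filter_lines(mutated=driver)
    wildtype = CellLineCluster(store, set(cohort.line_ids) - set(mutant.line_ids))
    if len(mutant) == 0:
        raise ValueError(
            f"no {driver}-mutant line in {disease!r} "
            f"(cohort size {len(cohort)}, wildtype {len(wildtype)})"
        )
    means = mean_essentiality_by_group(
        store.ceres.df,
        {"mean_mutant": mutant.line_ids, "mean_wt": wildtype.line_ids},
    )
    means = means.rename(columns={"deviation": "deviation"})
    means["abs_deviation"] = means["deviation"].abs()
    means = means.sort_values(["abs_deviation", "mean_mutant"],
                              ascending=[False, True], kind="mergesort")
    means = means.drop(columns="abs_deviation").reset_index(names="gene")

    report = WorkflowReport(workflow="driver_sl", provenance=_provenance(store, seed))
    report.thresholds.update(driver=driver, exclude_other=exclude_other)
    report.group_sizes.update(
        cohort=len(cohort), mutant=len(mutant), wildtype=len(wildtype))
    report.tables["means"] = means
    return report


def _top_bottom(ess: pd.DataFrame, n_top: int = 7, n_bottom: int = 3) -> pd.DataFrame:
    """Top-n most significant and bottom-n least significant tested genes.

    Ranking key: ascending p, ties by |mean_diff| descending, then gene id
    (the table is already sorted that way).
    """
    tested = ess[ess["p"].notna()]
    top = tested.head(n_top).copy()
    top["rank_group"] = "top"
    bottom = tested.tail(n_bottom).iloc[::-1].copy()
    bottom["rank_group"] = "bottom"
    return pd.concat([top, bottom], ignore_index=True)


def wf_sex_disparity(
    store: DataStore,
    disease: str,
    require_mutated: str | None = "KRAS",
    de_alpha: float = 0.01,
    ess_alpha: float = 0.05,
    mi_params: MIFilterParams | None = None,
    seed: int | None = None,
) -> WorkflowReport:
    """Male-vs-female differential expression and essentiality in one disease.

    Lines are restricted to the disease (and to carriers of a driver
    mutation when ``require_mutated`` is set), then split by sex; unknown-sex
    lines are excluded and counted.  Differential expression runs at
    BH-adjusted ``de_alpha``; differential essentiality at raw ``ess_alpha``.
    The report highlights the top 7 differentially essential genes with the
    bottom 3 as a negative control, and the overlap of the two significant
    gene sets.  The two analyses use whichever lines each data type covers,
    so their Ns are reported separately.
    """
    cohort = Cancer(store, disease)
    if require_mutated:
        cohort = cohort.filter_lines(mutated=require_mutated)
    parts, unknown = cohort.split_by("sex")
    male = parts.get("male", CellLineCluster(store, []))
    female = parts.get("female", CellLineCluster(store, []))
    if len(male) == 0 or len(female) == 0:
        raise ValueError(
            f"both sexes must be represented: male={len(male)}, female={len(female)}"
        )
    report = WorkflowReport(workflow="sex_disparity", provenance=_provenance(store, seed))
    report.thresholds.update(de_alpha=de_alpha, ess_alpha=ess_alpha,
                             require_mutated=require_mutated)
    report.group_sizes.update(male=len(male), female=len(female),
                              unknown_sex=len(unknown))

    # essentiality: male vs female on whichever lines the CERES matrix covers
    ceres = store.ceres.df
    ess_male = [l for l in male.line_ids if l in ceres.columns]
    ess_female = [l for l in female.line_ids if l in ceres.columns]
    ess = differential_essentiality(
        ceres, ess_male, ess_female, alpha=ess_alpha,
        mi_params=mi_params or MIFilterParams(enabled=False),
    )
    report.group_sizes.update(ess_male=len(ess_male), ess_female=len(ess_female))
    report.tables["essentiality"] = ess
    report.tables["top_bottom"] = _top_bottom(ess)

    # expression: male vs female on whichever samples the counts matrix covers
    de_table = pd.DataFrame()
    if store.has("counts"):
        counts = store.counts.df
        expr_male = [l for l in male.line_ids if l in counts.columns]
        expr_female = [l for l in female.line_ids if l in counts.columns]
        report.group_sizes.update(de_male=len(expr_male), de_female=len(expr_female))
        if len(expr_male) >= 2 and len(expr_female) >= 2:
            sub = counts[expr_male + expr_female]
            condition = pd.Series(
                ["female"] * len(expr_female) + ["male"] * len(expr_male),
                index=expr_female + expr_male)
            de_table = nb_wald_test(sub, condition, alpha=de_alpha)
            report.tables["expression"] = de_table
        else:
            report.warnings.append("too few expression samples per sex; DE skipped")
    else:
        report.warnings.append("no counts matrix loaded; DE skipped")

    sig_ess = set(ess.loc[ess["significant"], "gene"])
    sig_de = (set(de_table.loc[de_table["significant"], "gene"])
              if len(de_table) else set())
    overlap = sorted(sig_ess & sig_de)
    report.tables["overlap"] = pd.DataFrame({"gene": overlap})
    report.group_sizes["overlap"] = len(overlap)
    return report


def wf_surface_targets(
    store: DataStore,
    external_counts: pd.DataFrame,
    conf_map: ConfidenceMap | None = None,
    line_filter: dict | None = None,
    de_alpha: float = 0.01,
    min_score: int = 6,
    exclusions: Iterable[str] = (),
    seed: int | None = None,
) -> WorkflowReport:
    """Nominate upregulated cell-surface targets vs an external benign set.

    Panel counts (restricted by ``line_filter``, e.g. a disease or driver
    predicate) are merged with the external counts, tested malignant vs
    benign with the NB Wald engine, and filtered through the localization
    confidence rules.
    """
    panel = store.counts.df
    known = [c for c in panel.columns if c in store.line_index]
    if known:  # keep only true cell-line samples on the malignant side
        panel = panel[known]
    if line_filter:
        cluster = CellLineCluster.all_lines(store).filter_lines(**line_filter)
        keep = [c for c in panel.columns if c in set(cluster.line_ids)]
        panel = panel[keep]
    if panel.shape[1] < 2:
        raise ValueError("need at least two malignant samples after filtering")

    merged, source, merge_report = merge_counts(panel, external_counts)
    condition = pd.Series(
        ["malignant" if s == "panel" else "benign" for s in source],
        index=source.index)
    de = nb_wald_test(merged, condition, alpha=de_alpha, source=source)
    # labels sort benign < malignant, so log2fc is malignant over benign

    conf_map = conf_map or ConfidenceMap.default()
    scored = apply_confidence_map(store.localization, conf_map)
    nominations = nominate_surface_targets(
        de[de["tested"]], LocalizationTable(scored),
        de_alpha=de_alpha, min_score=min_score, exclusions=exclusions,
    )

    report = WorkflowReport(workflow="surface_targets",
                            provenance=_provenance(store, seed))
    report.thresholds.update(de_alpha=de_alpha, min_score=min_score,
                             exclusions=sorted(str(g) for g in exclusions))
    report.group_sizes.update(
        malignant=int((condition == "malignant").sum()),
        benign=int((condition == "benign").sum()),
        genes_merged=merge_report.genes_merged,
        genes_dropped_panel=len(merge_report.dropped_panel),
        genes_dropped_external=len(merge_report.dropped_external),
        nominated=int(nominations["nominated"].sum()),
    )
    report.tables["de"] = de
    report.tables["nominations"] = nominations
    return report
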