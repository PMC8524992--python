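"""Localization confidence scoring and surface-target nomination.

Three independent localization resources annotate each gene/compartment pair
with a categorical confidence.  Each source's categories map onto an integer
0-4 scale via an explicit, swappable :class:`ConfidenceMap` (the mapping is
input, never guessed: an unmapped category is an error, not a silent zero).
Per (gene, compartment) the three source scores are summed to a 0-12 total.
Candidate immunotherapy targets are the significantly upregulated genes with
a plasma-membrane total score of at least ``min_score`` (default 6) that are
not on a user-supplied manual exclusion list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ValidationError

SOURCES = ("cell_atlas", "map_of_cell", "surfaceome")

#: "plasma membrane" and "cell membrane" are the same compartment in the
#: three source vocabularies; both normalize to "plasma membrane".
COMPARTMENT_ALIASES = {"cell membrane": "plasma membrane"}

#: Shipped default mapping for common 4-tier reliability vocabularies.  The
#: sources' own published tier names differ; this default covers the generic
#: tiers and the synthetic fixtures, and real analyses should supply the
#: mapping that matches their annotation release.
DEFAULT_CATEGORIES = {
    "validated": 4, "enhanced": 4, "very high": 4,
    "supported": 3, "high": 3,
    "approved": 2, "medium": 2,
    "uncertain": 1, "low": 1,
    "unreliable": 0, "none": 0,
}


def normalize_compartment(name: str) -> str:
    key = str(name).strip().lower()
    return COMPARTMENT_ALIASES.get(key, key)


@dataclass(frozen=True)
class ConfidenceMap:
    """Per-source category -> integer 0-4 mapping."""

    by_source: Mapping[str, Mapping[str, int]]

    def __post_init__(self):
        for source, table in self.by_source.items():
            for category, score in table.items():
                if not (isinstance(score, int) and 0 <= score <= 4):
                    raise ValidationError(
                        f"confidence map {source!r}/{category!r}: score {score!r} "
                        "must be an integer in 0..4"
                    )

    def score(self, source: str, category: str) -> int:
        table = self.by_source.get(source)
        if table is None or category not in table:
            raise ValidationError(
                f"unmapped confidence category {category!r} for source {source!r}"
            )
        return table[category]

    @classmethod
    def default(cls, sources: Iterable[str] = SOURCES) -> "ConfidenceMap":
        lowered = {k.lower(): v for k, v in DEFAULT_CATEGORIES.items()}

        class _CI(dict):
            def __contains__(self, key):
                return str(key).lower() in lowered

            def __getitem__(self, key):
                return lowered[str(key).lower()]

        return cls(by_source={s: _CI(lowered) for s in sources})

    @classmethod
    def from_yaml(cls, path) -> "ConfidenceMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError("confidence map file must be a mapping source -> {category: score}")
        return cls(by_source=raw)


def apply_confidence_map(
    annotations: pd.DataFrame, conf_map: ConfidenceMap
) -> pd.DataFrame:
    """Score raw annotations (gene, compartment, source, category).

    Returns one record per (gene, compartment, source) with an integer
    ``score`` column; compartment names are normalized.  Any category the
    map does not cover raises, naming the category and its source.
    """
    for col in ("gene", "compartment", "source", "category"):
        if col not in annotations.columns:
            raise ValidationError(f"localization annotations lack column {col!r}")
    out = annotations.copy()
    out["compartment"] = out["compartment"].map(normalize_compartment)
    out["score"] = [
        conf_map.score(src, cat)
        for src, cat in zip(out["source"], out["category"])
    ]
    return out.reset_index(drop=True)


class LocalizationTable:
    """Scored localization records with total-score queries."""

    def __init__(self, records: pd.DataFrame):
        if "score" not in records.columns:
            raise ValidationError("records must carry a 'score' column; apply a confidence map first")
        self.records = records
        self._totals = (
            records.groupby(["gene", "compartment"])["score"].sum().to_dict()
        )

    def total_score(self, gene: str, compartment: str) -> int:
        """Summed 0-12 confidence over sources; unannotated pairs score 0."""
        return int(self._totals.get((str(gene), normalize_compartment(compartment)), 0))

    def membrane_score(self, gene: str) -> int:
        return self.total_score(gene, "plasma membrane")

    def membrane_annotated(self, gene: str) -> bool:
        return (str(gene), "plasma membrane") in self._totals

    def compartments(self, gene: str) -> list[str]:
        sel = self.records[self.records["gene"] == str(gene)]
        return sorted(set(sel["compartment"]))


@dataclass
class TargetNomination:
    gene: str
    log2fc: float
    padj: float
    total_membrane_score: int
    nominated: bool
    reason: str = ""  # empty for nominated genes


EXCLUSION_REASONS = (
    "not_significant", "not_upregulated", "no_membrane_annotation",
    "low_score", "manual_exclusion",
)


def nominate_surface_targets(
    de_results: pd.DataFrame,
    localization: LocalizationTable,
    de_alpha: float = 0.01,
    min_score: int = 6,
    exclusions: Iterable[str] = (),
) -> pd.DataFrame:
    """Filter DE results down to plausible cell-surface targets.

    A gene is nominated iff padj < de_alpha, log2fc > 0, it is annotated to
    the plasma membrane with total confidence >= min_score ("lower than 6"
    scores are removed, so exactly 6 passes at the default), and it is not
    manually excluded.  Every input gene appears exactly once in the output,
    either nominated or with the first failing reason in the documented
    order.  Nominations are sorted by log2fc descending.
    """
    excluded = {str(g) for g in exclusions}
    rows = []
    for _, de in de_results.iterrows():
        gene = str(de["gene"])
        score = localization.membrane_score(gene)
        padj = float(de["padj"]) if pd.notna(de["padj"]) else float("nan")
        log2fc = float(de["log2fc"])
        reason = ""
        if not (padj < de_alpha):
            reason = "not_significant"
        elif not (log2fc > 0):
            reason = "not_upregulated"
        elif not localization.membrane_annotated(gene):
            reason = "no_membrane_annotation"
        elif score < min_score:
            reason = "low_score"
        elif gene in excluded:
            reason = "manual_exclusion"
        rows.append({
            "gene": gene, "log2fc": log2fc, "padj": padj,
            "total_membrane_score": score,
            "nominated": reason == "", "reason": reason,
        })
    out = pd.DataFrame(rows, columns=[
        "gene", "log2fc", "padj", "total_membrane_score", "nominated", "reason",
    ])
    out = out.sort_values(["nominated", "log2fc"], ascending=[False, False],
                          kind="mergesort").reset_index(drop=True)
    return out
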