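"""Biological query abstractions over the data store.

``Gene``, ``CellLine``, ``Cancer``, ``Organelle`` and the two cluster classes
are thin, read-only views: every accessor is equivalent to directly
subsetting the underlying tables (that equivalence is property-tested), and
nothing here mutates the store.  Clusters are deduplicated and sorted by ID
so downstream statistics are order-stable.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .datastore import PROTEIN_ALTERING_CLASSES, DataStore, normalize_protein_change
from .errors import NotFoundError

logger = logging.getLogger(__name__)


def _unique_sorted(ids: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(dict.fromkeys(str(i) for i in ids)))


class Entity:
    """Base class: a handle to the store plus a fixed scope."""

    def __init__(self, store: DataStore):
        self._store = store

    @property
    def store(self) -> DataStore:
        return self._store


class Gene(Entity):
    """A single gene, addressed by symbol, alias or stable id."""

    def __init__(self, store: DataStore, query: str):
        super().__init__(store)
        self.stable_id = store.gene_index.translate(query)

    @property
    def symbol(self) -> str:
        return self._store.gene_index.symbol_of(self.stable_id)

    def essentiality(self, lines: "CellLineCluster | None" = None) -> pd.Series:
        """CERES gene-effect scores keyed by line_id.

        Missing entries stay NaN (flagged, never silently dropped).  Raises
        :class:`NotFoundError` if the gene has no row in the matrix.
        """
        matrix = self._store.ceres
        if self.stable_id not in matrix.df.index:
            raise NotFoundError(self.stable_id)
        row = matrix.df.loc[self.stable_id]
        if lines is not None:
            row = row.reindex(list(lines.line_ids))
        return row

    def expression(self, samples: list[str] | None = None) -> pd.Series:
        counts = self._store.counts
        if self.stable_id not in counts.df.index:
            raise NotFoundError(self.stable_id)
        row = counts.df.loc[self.stable_id]
        return row if samples is None else row.reindex(samples)

    def mutations(self) -> pd.DataFrame:
        muts = self._store.mutations
        return muts[muts["gene"] == self.stable_id].reset_index(drop=True)

    def complexes(self) -> list[str]:
        """Names of all complexes whose member list contains this gene."""
        table = self._store.complexes
        return [
            row["complex_name"]
            for _, row in table.iterrows()
            if self.stable_id in row["members"]
        ]

    def locations(self) -> pd.DataFrame:
        loc = self._store.localization
        return loc[loc["gene"] == self.stable_id].reset_index(drop=True)

    def compartments(self) -> tuple[str, ...]:
        return _unique_sorted(self.locations()["compartment"])


class GeneCluster(Entity):
    """An ordered, deduplicated set of genes."""

    def __init__(self, store: DataStore, queries: Iterable[str]):
        super().__init__(store)
        self.stable_ids = _unique_sorted(
            store.gene_index.translate(q) for q in queries
        )

    def __len__(self) -> int:
        return len(self.stable_ids)

    def __iter__(self):
        return iter(self.stable_ids)

    def __contains__(self, query: object) -> bool:
        try:
            return self._store.gene_index.translate(str(query)) in self.stable_ids
        except NotFoundError:
            return False

    def essentiality(self, lines: "CellLineCluster | None" = None) -> pd.DataFrame:
        matrix = self._store.ceres.df
        present = [g for g in self.stable_ids if g in matrix.index]
        sub = matrix.loc[present]
        if lines is not None:
            sub = sub.reindex(columns=list(lines.line_ids))
        return sub


class CellLine(Entity):
    """A single cell line, addressed by name or line_id."""

    def __init__(self, store: DataStore, query: str):
        super().__init__(store)
        self.line_id = store.line_index.translate_line(query)

    def attribute(self, attr: str) -> str:
        return self._store.line_index.attribute(self.line_id, attr)

    def mutations(self) -> pd.DataFrame:
        muts = self._store.mutations
        return muts[muts["line_id"] == self.line_id].reset_index(drop=True)

    def essentiality(self) -> pd.Series:
        matrix = self._store.ceres
        if self.line_id not in matrix.df.columns:
            raise NotFoundError(self.line_id)
        return matrix.df[self.line_id]


class CellLineCluster(Entity):
    """An ordered, deduplicated set of cell lines with filter/split queries."""

    def __init__(self, store: DataStore, queries: Iterable[str]):
        super().__init__(store)
        self.line_ids = _unique_sorted(
            store.line_index.translate_line(q) for q in queries
        )

    @classmethod
    def all_lines(cls, store: DataStore) -> "CellLineCluster":
        return cls(store, store.line_index.line_ids)

    def __len__(self) -> int:
        return len(self.line_ids)

    def __iter__(self):
        return iter(self.line_ids)

    def _annotations(self) -> pd.DataFrame:
        tbl = self._store.line_index.table
        return tbl[tbl["line_id"].isin(self.line_ids)]

    def _mutant_lines(
        self,
        gene: str,
        variant_class: str | None = None,
        protein_change: str | None = None,
    ) -> set[str]:
        """Lines with >=1 qualifying mutation record for ``gene``.

        Without an explicit class, only protein-altering classes qualify.
        """
        muts = self._store.mutations
        gid = self._store.gene_index.translate(gene)
        sel = muts[muts["gene"] == gid]
        if variant_class is not None:
            sel = sel[sel["variant_class"] == variant_class]
        else:
            sel = sel[sel["variant_class"].isin(PROTEIN_ALTERING_CLASSES)]
        if protein_change is not None:
            sel = sel[sel["protein_change"] == normalize_protein_change(protein_change)]
        return set(sel["line_id"])

    def filter_lines(
        self,
        lineage: str | None = None,
        disease: str | None = None,
        sex: str | None = None,
        mutated: Mapping[str, str | None] | str | None = None,
        wildtype: Mapping[str, str] | str | None = None,
    ) -> "CellLineCluster":
        """Conjunction of the provided predicates.

        ``mutated`` is a gene name or ``{"gene": g, "variant_class": c,
        "protein_change": p}``; ``wildtype`` is a gene name or ``{"gene": g}``
        and means the line has no protein-altering record for that gene.  An
        empty result is a warning, not an error.
        """
        ann = self._annotations()
        mask = pd.Series(True, index=ann.index)
        if lineage is not None:
            mask &= ann["lineage"] == str(lineage).strip().lower()
        if disease is not None:
            mask &= ann["disease"] == str(disease).strip().lower()
        if sex is not None:
            mask &= ann["sex"] == str(sex).strip().lower()
        kept = set(ann.loc[mask, "line_id"])
        if mutated is not None:
            if isinstance(mutated, str):
                mutated = {"gene": mutated}
            kept &= self._mutant_lines(
                mutated["gene"],
                mutated.get("variant_class"),
                mutated.get("protein_change"),
            )
        if wildtype is not None:
            if isinstance(wildtype, str):
                wildtype = {"gene": wildtype}
            kept -= self._mutant_lines(wildtype["gene"])
        if not kept:
            logger.warning("filter_lines produced an empty cluster")
        return CellLineCluster(self._store, kept)

    def split_by(self, attribute: str, gene: str | None = None
                 ) -> tuple[dict[str, "CellLineCluster"], "CellLineCluster"]:
        """Partition the cluster by an attribute.

        ``attribute`` is ``sex``, ``lineage``, ``disease`` or ``mutation``
        (the latter needs ``gene`` and yields ``mutant``/``wildtype``).
        Returns ``(partitions, unknown)``: partitions are disjoint and cover
        every line whose attribute is known; lines with unknown attribute go
        in the separately reported remainder.
        """
        if attribute == "mutation":
            if gene is None:
                raise ValueError("split_by('mutation') requires a gene")
            mutant = self._mutant_lines(gene)
            parts = {
                "mutant": CellLineCluster(self._store, set(self.line_ids) & mutant),
                "wildtype": CellLineCluster(self._store, set(self.line_ids) - mutant),
            }
            return parts, CellLineCluster(self._store, [])
        ann = self._annotations()
        if attribute not in ann.columns:
            raise ValueError(f"unknown attribute {attribute!r}")
        parts: dict[str, CellLineCluster] = {}
        unknown: list[str] = []
        for label, group in ann.groupby(attribute):
            if str(label) in ("unknown", ""):
                unknown.extend(group["line_id"])
            else:
                parts[str(label)] = CellLineCluster(self._store, group["line_id"])
        return parts, CellLineCluster(self._store, unknown)

    def essentiality(self, genes: GeneCluster | None = None) -> pd.DataFrame:
        matrix = self._store.ceres.df
        sub = matrix.reindex(columns=list(self.line_ids))
        if genes is not None:
            sub = sub.loc[[g for g in genes.stable_ids if g in sub.index]]
        return sub

    def annotations(self) -> pd.DataFrame:
        return self._annotations().reset_index(drop=True)


class Cancer(CellLineCluster):
    """All lines whose disease OR lineage equals a label (exact, lowercased)."""

    def __init__(self, store: DataStore, label: str):
        key = str(label).strip().lower()
        tbl = store.line_index.table
        hit = tbl[(tbl["disease"] == key) | (tbl["lineage"] == key)]
        super().__init__(store, hit["line_id"])
        self.label = key


class Organelle(Entity):
    """A subcellular compartment; membership comes only from localization data."""

    def __init__(self, store: DataStore, compartment: str):
        super().__init__(store)
        self.compartment = str(compartment).strip().lower()

    def genes(self) -> GeneCluster:
        loc = self._store.localization
        hits = loc.loc[loc["compartment"] == self.compartment, "gene"]
        return GeneCluster(self._store, hits)
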