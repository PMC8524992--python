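"""Index tables, file readers, and the unified data store.

All analysis modules operate on two canonical identifier systems: gene
``stable_id`` (an Entrez-style numeric string) and cell-line ``line_id``
(DepMap-style ``ACH-...``).  The index tables loaded here translate symbols,
aliases and display names into those canonical keys; readers push every
incoming identifier through the translators and count what they had to drop.

CSV dialect everywhere: comma-separated, UTF-8, first row is the header,
quoted fields allowed — the convention of public DepMap/CCLE exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config
from .errors import (
    CapabilityMissingError,
    DuplicateIDError,
    NotFoundError,
    ParseError,
    SchemaError,
)

#: Explicit sex normalization.  Unknowns stay "unknown" and are excluded from
#: sex-stratified analyses rather than guessed.
SEX_MAP = {
    "male": "male", "m": "male",
    "female": "female", "f": "female",
    "unknown": "unknown", "": "unknown", "nan": "unknown", "na": "unknown",
}

#: Default "protein-altering" variant classes: a line counts as mutant for a
#: gene only via one of these; silent/intronic records neither make a line
#: mutant nor void its wildtype status.
PROTEIN_ALTERING_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site", "Translation_Start_Site", "Start_Codon_SNP",
    "De_novo_Start_OutOfFrame",
})

MATRIX_FLOAT_FORMAT = "%.6g"  # round-trip precision for matrix writers


@dataclass
class LoadReport:
    """Bookkeeping for a reader: rows_in == rows_kept + rows_dropped."""

    rows_in: int = 0
    rows_kept: int = 0
    dropped_rows: list[str] = field(default_factory=list)
    dropped_cols: list[str] = field(default_factory=list)

    @property
    def rows_dropped(self) -> int:
        return len(self.dropped_rows)


def _prefix_suggestions(query: str, universe) -> list[str]:
    q = str(query).lower()
    hits = [u for u in universe if str(u).lower().startswith(q[:3])] if q else []
    return sorted(hits)[:5]


class GeneIndex:
    """Symbol/alias/stable-id translation table for genes.

    Expected columns: ``symbol``, ``stable_id``, ``aliases`` (semicolon- or
    pipe-separated, may be empty).  Symbol and alias lookup is
    case-insensitive; stable_id lookup is exact.
    """

    REQUIRED = ("symbol", "stable_id")

    def __init__(self, table: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in table.columns:
                raise SchemaError(f"gene index lacks required column {col!r}")
        table = table.copy()
        table["stable_id"] = table["stable_id"].astype(str)
        table["symbol"] = table["symbol"].astype(str)
        if table["symbol"].eq("").any():
            raise SchemaError("gene index contains an empty symbol")
        dup = table["stable_id"][table["stable_id"].duplicated()]
        if len(dup):
            raise DuplicateIDError(f"duplicate gene stable_id(s): {sorted(set(dup))}")
        self.table = table.reset_index(drop=True)
        self._by_id: dict[str, str] = {}
        self._by_name: dict[str, str] = {}
        for _, row in self.table.iterrows():
            sid = row["stable_id"]
            self._by_id[sid] = sid
            self._by_name[row["symbol"].lower()] = sid
            aliases = row.get("aliases", "")
            if isinstance(aliases, str) and aliases:
                for alias in aliases.replace("|", ";").split(";"):
                    alias = alias.strip()
                    if alias:
                        self._by_name.setdefault(alias.lower(), sid)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, query: object) -> bool:
        q = str(query)
        return q in self._by_id or q.lower() in self._by_name

    def translate(self, query: str) -> str:
        """Resolve a symbol, alias, or stable_id to the canonical stable_id."""
        q = str(query)
        if q in self._by_id:
            return q
        hit = self._by_name.get(q.lower())
        if hit is not None:
            return hit
        raise NotFoundError(q, _prefix_suggestions(q, self.table["symbol"]))

    def symbol_of(self, stable_id: str) -> str:
        row = self.table[self.table["stable_id"] == str(stable_id)]
        if row.empty:
            raise NotFoundError(str(stable_id))
        return row["symbol"].iloc[0]

    @property
    def stable_ids(self) -> list[str]:
        return list(self.table["stable_id"])


class CellLineIndex:
    """Name/ID translation plus annotations (lineage, disease, sex) for lines.

    Expected columns: ``line_id``, ``ccle_name``, ``lineage``, ``disease``,
    optional ``subtype``, ``sex``.  Sex is normalized through an explicit
    mapping table; anything unmapped is an error rather than a silent guess.
    """

    REQUIRED = ("line_id", "ccle_name", "lineage", "disease")

    def __init__(self, table: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in table.columns:
                raise SchemaError(f"cell-line index lacks required column {col!r}")
        table = table.copy()
        table["line_id"] = table["line_id"].astype(str)
        dup = table["line_id"][table["line_id"].duplicated()]
        if len(dup):
            raise DuplicateIDError(f"duplicate line_id(s): {sorted(set(dup))}")
        if "sex" not in table.columns:
            table["sex"] = "unknown"
        norm = []
        for raw in table["sex"]:
            key = str(raw).strip().lower()
            if key not in SEX_MAP:
                raise SchemaError(f"unmappable sex value {raw!r} in cell-line index")
            norm.append(SEX_MAP[key])
        table["sex"] = norm
        if "subtype" not in table.columns:
            table["subtype"] = ""
        for col in ("lineage", "disease", "subtype"):
            table[col] = table[col].astype(str).str.strip().str.lower()
        self.table = table.reset_index(drop=True)
        self._by_id = {lid: lid for lid in self.table["line_id"]}
        self._by_name = {
            str(name).lower(): lid
            for name, lid in zip(self.table["ccle_name"], self.table["line_id"])
        }

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, query: object) -> bool:
        q = str(query)
        return q in self._by_id or q.lower() in self._by_name

    def translate_line(self, query: str) -> str:
        q = str(query)
        if q in self._by_id:
            return q
        hit = self._by_name.get(q.lower())
        if hit is not None:
            return hit
        raise NotFoundError(q, _prefix_suggestions(q, self.table["ccle_name"]))

    def attribute(self, line_id: str, attr: str) -> str:
        row = self.table[self.table["line_id"] == str(line_id)]
        if row.empty:
            raise NotFoundError(str(line_id))
        return row[attr].iloc[0]

    @property
    def line_ids(self) -> list[str]:
        return list(self.table["line_id"])


def load_gene_index(path: str | Path) -> GeneIndex:
    return GeneIndex(pd.read_csv(path, dtype=str, keep_default_na=False))


def load_cell_line_index(path: str | Path) -> CellLineIndex:
    return CellLineIndex(pd.read_csv(path, dtype=str, keep_default_na=False))


@dataclass
class Matrix:
    """A genes x lines (or genes x samples) numeric table.

    ``kind`` distinguishes CERES gene-effect scores, Bayes factors, raw
    counts and TPM.  Counts must be non-negative integers with no missing
    cells; the other kinds may contain NaN.
    """

    df: pd.DataFrame
    kind: str = "ceres"

    KINDS = ("ceres", "bayes_factor", "counts", "tpm")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise SchemaError(f"unknown matrix kind {self.kind!r}")
        if self.df.index.duplicated().any() or self.df.columns.duplicated().any():
            raise DuplicateIDError("matrix row or column identifiers are not unique")

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.df.columns)


def read_matrix(
    path: str | Path,
    kind: str = "ceres",
    gene_index: GeneIndex | None = None,
    line_index: CellLineIndex | None = None,
    transpose: bool = False,
) -> tuple[Matrix, LoadReport]:
    """Read a CSV matrix (first column = row ids, header = column ids).

    On-disk orientation is normalized to genes x lines: pass
    ``transpose=True`` for lines-x-genes exports.  When indexes are given,
    identifiers are translated to canonical form; untranslatable rows and
    columns are dropped and counted in the report.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transpose:
        df = df.T
    report = LoadReport(rows_in=len(df))

    if kind == "counts":
        for j, col in enumerate(df.columns):
            values = df[col]
            bad = values.isna() | (values != np.floor(values)) | (values < 0)
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ParseError(
                    f"counts matrix cell at row {df.index[i]!r}, column {col!r} "
                    f"(position {i},{j}) is not a non-negative integer: {values.iloc[i]!r}"
                )
        df = df.astype(np.int64)
    else:
        df = df.astype(float)

    if gene_index is not None:
        keep, translated = [], []
        for rid in df.index:
            try:
                translated.append(gene_index.translate(rid))
                keep.append(rid)
            except NotFoundError:
                report.dropped_rows.append(rid)
        df = df.loc[keep]
        df.index = translated
    if line_index is not None:
        keep, translated = [], []
        for cid in df.columns:
            try:
                translated.append(line_index.translate_line(cid))
                keep.append(cid)
            except NotFoundError:
                report.dropped_cols.append(cid)
        df = df[keep]
        df.columns = translated

    if df.index.duplicated().any():
        raise DuplicateIDError("matrix rows map to duplicate canonical gene ids")
    report.rows_kept = len(df)
    return Matrix(df=df, kind=kind), report


def write_matrix(matrix: Matrix, path: str | Path) -> None:
    """Write at documented precision so a read-back round-trips exactly."""
    if matrix.kind == "counts":
        matrix.df.to_csv(path)
    else:
        matrix.df.to_csv(path, float_format=MATRIX_FLOAT_FORMAT)


MUTATION_COLUMNS = ("gene", "line_id", "variant_class", "protein_change")


def normalize_protein_change(raw: str) -> str:
    """Strip a leading ``p.`` and uppercase, so ``p.G12d`` == ``G12D``."""
    s = str(raw).strip()
    if s.lower().startswith("p."):
        s = s[2:]
    return s.upper()


def read_mutation_table(
    path: str | Path,
    gene_index: GeneIndex | None = None,
    line_index: CellLineIndex | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a long-format (MAF-like) mutation table.

    Required columns: gene, line_id (or ccle_name), variant_class,
    protein_change.  Protein changes are normalized; gene and line
    identifiers are translated when indexes are supplied; untranslatable
    records are dropped and counted.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "line_id" not in df.columns and "ccle_name" in df.columns:
        df = df.rename(columns={"ccle_name": "line_id"})
    for col in MUTATION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mutation table lacks required column {col!r}")
    report = LoadReport(rows_in=len(df))
    if (df["variant_class"].str.strip() == "").any():
        raise SchemaError("mutation table contains an empty variant_class")
    df["protein_change"] = df["protein_change"].map(normalize_protein_change)

    keep = np.ones(len(df), dtype=bool)
    if gene_index is not None:
        genes = []
        for i, g in enumerate(df["gene"]):
            try:
                genes.append(gene_index.translate(g))
            except NotFoundError:
                genes.append(g)
                keep[i] = False
        df["gene"] = genes
    if line_index is not None:
        lines = []
        for i, l in enumerate(df["line_id"]):
            try:
                lines.append(line_index.translate_line(l))
            except NotFoundError:
                lines.append(l)
                keep[i] = False
        df["line_id"] = lines
    report.dropped_rows = list(df.index[~keep].astype(str))
    df = df[keep].reset_index(drop=True)
    report.rows_kept = len(df)
    return df[list(MUTATION_COLUMNS)], report


LOCALIZATION_COLUMNS = ("gene", "compartment", "source", "category")


def read_localization_table(
    path: str | Path, gene_index: GeneIndex | None = None
) -> tuple[pd.DataFrame, LoadReport]:
    """Read raw localization annotations (gene, compartment, source, category)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in LOCALIZATION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"localization table lacks required column {col!r}")
    df["compartment"] = df["compartment"].str.strip().str.lower()
    report = LoadReport(rows_in=len(df))
    keep = np.ones(len(df), dtype=bool)
    if gene_index is not None:
        genes = []
        for i, g in enumerate(df["gene"]):
            try:
                genes.append(gene_index.translate(g))
            except NotFoundError:
                genes.append(g)
                keep[i] = False
        df["gene"] = genes
    report.dropped_rows = list(df.index[~keep].astype(str))
    df = df[keep].reset_index(drop=True)
    report.rows_kept = len(df)
    return df[list(LOCALIZATION_COLUMNS)], report


def read_complex_table(
    path: str | Path, gene_index: GeneIndex | None = None
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a complex-membership table (complex_name, members ';'-separated).

    Members are translated to stable ids; members that fail translation are
    removed from the complex (counted per-member in the report).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("complex_name", "members"):
        if col not in df.columns:
            raise SchemaError(f"complex table lacks required column {col!r}")
    report = LoadReport(rows_in=len(df))
    out_rows = []
    for _, row in df.iterrows():
        members = [m.strip() for m in row["members"].split(";") if m.strip()]
        if gene_index is not None:
            translated = []
            for m in members:
                try:
                    translated.append(gene_index.translate(m))
                except NotFoundError:
                    report.dropped_rows.append(f"{row['complex_name']}:{m}")
            members = translated
        out_rows.append({"complex_name": row["complex_name"], "members": members})
    report.rows_kept = len(out_rows)
    report.rows_in = report.rows_kept + report.rows_dropped
    return pd.DataFrame(out_rows, columns=["complex_name", "members"]), report


class DataStore:
    """The unified handle every entity and workflow operates through.

    Holds the two index tables plus whichever datasets are loaded.  Missing
    datasets raise :class:`CapabilityMissingError` on access instead of
    returning empty tables, so a query can never silently see no data.
    """

    def __init__(
        self,
        gene_index: GeneIndex,
        line_index: CellLineIndex,
        ceres: Matrix | None = None,
        bayes: Matrix | None = None,
        counts: Matrix | None = None,
        mutations: pd.DataFrame | None = None,
        localization: pd.DataFrame | None = None,
        complexes: pd.DataFrame | None = None,
        config: Config | None = None,
    ):
        self.gene_index = gene_index
        self.line_index = line_index
        self._ceres = ceres
        self._bayes = bayes
        self._counts = counts
        self._mutations = mutations
        self._localization = localization
        self._complexes = complexes
        self.config = config
        self.load_reports: dict[str, LoadReport] = {}

    def _require(self, value, name: str):
        if value is None:
            raise CapabilityMissingError(f"dataset {name!r} is not loaded in this store")
        return value

    @property
    def ceres(self) -> Matrix:
        return self._require(self._ceres, "ceres")

    @property
    def bayes(self) -> Matrix:
        return self._require(self._bayes, "bayes")

    @property
    def counts(self) -> Matrix:
        return self._require(self._counts, "counts")

    @property
    def mutations(self) -> pd.DataFrame:
        return self._require(self._mutations, "mutations")

    @property
    def localization(self) -> pd.DataFrame:
        return self._require(self._localization, "localization")

    @property
    def complexes(self) -> pd.DataFrame:
        return self._require(self._complexes, "complexes")

    def has(self, name: str) -> bool:
        return getattr(self, f"_{name}") is not None

    @classmethod
    def from_directory(cls, data_dir: str | Path, config: Config | None = None) -> "DataStore":
        """Load a fixture directory using the generator's standard file names."""
        data_dir = Path(data_dir)
        gi = load_gene_index(data_dir / "gene_index.csv")
        ci = load_cell_line_index(data_dir / "sample_info.csv")
        store = cls(gene_index=gi, line_index=ci, config=config)

        def maybe(fname):
            p = data_dir / fname
            return p if p.is_file() else None

        if maybe("ceres.csv"):
            store._ceres, store.load_reports["ceres"] = read_matrix(
                data_dir / "ceres.csv", "ceres", gi, ci)
        if maybe("bayes.csv"):
            store._bayes, store.load_reports["bayes"] = read_matrix(
                data_dir / "bayes.csv", "bayes_factor", gi, ci)
        if maybe("counts.csv"):
            store._counts, store.load_reports["counts"] = read_matrix(
                data_dir / "counts.csv", "counts", gi, None)
        if maybe("mutations.csv"):
            store._mutations, store.load_reports["mutations"] = read_mutation_table(
                data_dir / "mutations.csv", gi, ci)
        if maybe("localization.csv"):
            store._localization, store.load_reports["localization"] = read_localization_table(
                data_dir / "localization.csv", gi)
        if maybe("complexes.csv"):
            store._complexes, store.load_reports["complexes"] = read_complex_table(
                data_dir / "complexes.csv", gi)
        return store

    @classmethod
    def from_config(cls, config: Config) -> "DataStore":
        """Load the datasets named in a config's registry."""
        by_kind: dict[str, list] = {}
        for name, entry in config.datasets.items():
            by_kind.setdefault(entry.schema_kind, []).append(entry)
        gi_entry = next((e for e in config.datasets.values() if e.name == "gene_index"), None)
        if gi_entry is None:
            raise CapabilityMissingError("config must register a 'gene_index' dataset")
        si = by_kind.get("sample_info")
        if not si:
            raise CapabilityMissingError("config must register a sample_info dataset")
        gi = load_gene_index(gi_entry.path)
        ci = load_cell_line_index(si[0].path)
        store = cls(gene_index=gi, line_index=ci, config=config)
        for entry in config.datasets.values():
            if entry.name in ("ceres", "bayes", "counts") and entry.schema_kind == "matrix":
                kind = {"ceres": "ceres", "bayes": "bayes_factor", "counts": "counts"}[entry.name]
                matrix, report = read_matrix(
                    entry.path, kind, gi, None if kind == "counts" else ci)
                setattr(store, f"_{entry.name}", matrix)
                store.load_reports[entry.name] = report
            elif entry.schema_kind == "mutations":
                store._mutations, store.load_reports[entry.name] = read_mutation_table(
                    entry.path, gi, ci)
            elif entry.schema_kind == "localization":
                store._localization, store.load_reports[entry.name] = read_localization_table(
                    entry.path, gi)
            elif entry.schema_kind == "complexes":
                store._complexes, store.load_reports[entry.name] = read_complex_table(
                    entry.path, gi)
        return store
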