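"""Seeded generator of panel-schema fixtures with planted signals.

Every analysis module in this package is exercised on synthetic data that
follows the public DepMap/CCLE export schemas: a CERES gene-effect matrix, a
Bayes-factor matrix, a raw RNA-seq counts matrix (panel plus an "external"
benign set), a long-format mutation table, a sample-info table, localization
annotations from three sources, and a complex-membership table.  Signals are
planted with known parameters and emitted in a ``truth.csv`` alongside the
data, so recovery and calibration can be measured exactly.

One global seed drives everything through a documented stream-splitting
scheme (:class:`numpy.random.SeedSequence` children, one per data stream in
a fixed order), so the same spec + seed yields byte-identical files while
individual streams stay reproducible in isolation.

Default noise levels: CERES noise sigma0 = 0.15 around a non-essential mean
of 0 (essential backbone genes sit at -1), NB dispersion 0.1 for counts.
These are the desk-scale conditions under which planted effects at the
standard thresholds are detectable with 10-15 lines per group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

STREAMS = (
    "genes", "lines", "ceres", "bayes", "counts", "mutations",
    "localization", "complexes",
)

ONCO_CHANGES = ("G12D", "G12V", "G13D", "L858R", "V600E")


@dataclass(frozen=True)
class PlantedEssentiality:
    """A conditional-essentiality effect: gene shifted by ``delta`` in the
    lines matching ``predicate`` (a sample_info column -> value mapping, or
    ``{"mutated": driver_gene}``)."""

    gene: str
    predicate: dict
    delta: float = -0.6


@dataclass(frozen=True)
class PlantedExpression:
    """A differential-expression effect: counts multiplied by 2**log2fc in
    condition-B samples."""

    gene: str
    log2fc: float = 2.0


@dataclass(frozen=True)
class DriverModel:
    """A driver gene mutated at ``rate`` per line, with the given class and
    protein changes drawn uniformly.  ``fixed_lines`` plants the lesion in an
    exact line set instead of Bernoulli draws."""

    gene: str
    rate: float = 0.3
    variant_class: str = "Missense_Mutation"
    protein_changes: tuple[str, ...] = ONCO_CHANGES[:2]
    fixed_lines: tuple[str, ...] = ()


@dataclass
class FixtureSpec:
    """Everything the generator needs; defaults are the standard study
    conditions used throughout the test suite."""

    n_genes: int = 200
    n_lines: int = 30
    seed: int = 0

    # sample annotations
    lineages: tuple[str, ...] = ("lung", "ovary", "pancreas")
    lineage_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    diseases: dict = field(default_factory=lambda: {
        "lung": "nsclc", "ovary": "ovarian cancer", "pancreas": "pdac"})
    sex_probs: tuple[float, float, float] = (0.475, 0.475, 0.05)  # male, female, unknown

    # CERES model
    ceres_sigma: float = 0.15
    essential_fraction: float = 0.1   # backbone genes at mean -1
    planted_essentiality: tuple[PlantedEssentiality, ...] = ()

    # Bayes-factor model: BF = bf_scale * (-ceres) + noise
    bf_scale: float = 10.0
    bf_noise: float = 1.0

    # counts model
    n_counts_samples: int = 20        # panel samples (drawn from the lines)
    n_external_samples: int = 4
    counts_mean_log: float = float(np.log(100.0))
    counts_sigma_log: float = 1.0
    nb_dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    planted_expression: tuple[PlantedExpression, ...] = ()

    # mutation model
    drivers: tuple[DriverModel, ...] = ()
    background_mutation_rate: float = 0.05

    # localization model
    compartments: tuple[str, ...] = (
        "plasma membrane", "nucleus", "cytosol", "mitochondria")
    surface_genes: tuple[str, ...] = ()   # guaranteed membrane score >= 6
    localization_rate: float = 0.6

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_lines <= 0:
            raise ValidationError("n_genes and n_lines must be positive")
        for name, probs in (("lineage_probs", self.lineage_probs),
                            ("sex_probs", self.sex_probs)):
            if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValidationError(f"{name} must be probabilities summing to 1")
        if len(self.lineage_probs) != len(self.lineages):
            raise ValidationError("lineage_probs must match lineages in length")
        if not (0 <= self.background_mutation_rate <= 1):
            raise ValidationError("background_mutation_rate must lie in [0, 1]")
        for d in self.drivers:
            if not (0 <= d.rate <= 1):
                raise ValidationError(f"driver {d.gene}: rate must lie in [0, 1]")
        if self.ceres_sigma <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("noise parameters must be positive")

    def gene_ids(self) -> list[str]:
        return [f"{10001 + i}" for i in range(self.n_genes)]

    def gene_symbols(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def line_ids(self) -> list[str]:
        return [f"ACH-{i + 1:06d}" for i in range(self.n_lines)]


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(STREAMS, children)}


@dataclass
class FixtureTables:
    gene_index: pd.DataFrame
    sample_info: pd.DataFrame
    ceres: pd.DataFrame
    bayes: pd.DataFrame
    counts: pd.DataFrame          # panel + external samples, genes x samples
    counts_samples: pd.DataFrame  # sample, condition, source
    mutations: pd.DataFrame
    localization: pd.DataFrame
    complexes: pd.DataFrame
    truth: pd.DataFrame


def _assign_categorical(rng, n: int, labels: Sequence[str], probs: Sequence[float]) -> list[str]:
    return list(rng.choice(labels, size=n, p=list(probs)))


def generate_tables(spec: FixtureSpec) -> FixtureTables:
    """Generate all fixture tables in memory.  Deterministic in (spec, seed)."""
    spec.validate()
    rngs = _rngs(spec.seed)
    gene_ids = spec.gene_ids()
    symbols = spec.gene_symbols()
    line_ids = spec.line_ids()
    symbol_of = dict(zip(gene_ids, symbols))
    id_of_symbol = dict(zip(symbols, gene_ids))
    truth_rows: list[dict] = []

    # --- gene index ---------------------------------------------------------
    gene_index = pd.DataFrame({
        "symbol": symbols,
        "stable_id": gene_ids,
        "aliases": [f"{s}-ALT" for s in symbols],
    })

    # --- sample info --------------------------------------------------------
    rng = rngs["lines"]
    lineages = _assign_categorical(rng, spec.n_lines, spec.lineages, spec.lineage_probs)
    # deterministic sex assignment by proportion, then shuffled: guarantees
    # the requested male/female balance exactly for balanced specs
    n_male = int(round(spec.sex_probs[0] * spec.n_lines))
    n_female = int(round(spec.sex_probs[1] * spec.n_lines))
    n_unknown = spec.n_lines - n_male - n_female
    sexes = ["male"] * n_male + ["female"] * n_female + ["unknown"] * max(n_unknown, 0)
    sexes = sexes[: spec.n_lines]
    rng.shuffle(sexes)
    sample_info = pd.DataFrame({
        "line_id": line_ids,
        "ccle_name": [f"LINE{i + 1}_{lineages[i].upper()}" for i in range(spec.n_lines)],
        "lineage": lineages,
        "disease": [spec.diseases.get(l, l) for l in lineages],
        "subtype": ["" for _ in line_ids],
        "sex": sexes,
    })

    # --- mutations ----------------------------------------------------------
    rng = rngs["mutations"]
    mut_rows = []
    for driver in spec.drivers:
        gid = id_of_symbol.get(driver.gene, driver.gene)
        if driver.fixed_lines:
            carriers = [l for l in line_ids if l in set(driver.fixed_lines)]
        else:
            carriers = [l for l in line_ids if rng.random() < driver.rate]
        for line in carriers:
            change = (str(rng.choice(driver.protein_changes))
                      if driver.protein_changes else "")
            mut_rows.append({"gene": gid, "line_id": line,
                             "variant_class": driver.variant_class,
                             "protein_change": change})
    if spec.background_mutation_rate > 0:
        for gid in gene_ids:
            for line in line_ids:
                if rng.random() < spec.background_mutation_rate:
                    mut_rows.append({
                        "gene": gid, "line_id": line,
                        "variant_class": "Silent",
                        "protein_change": "",
                    })
    mutations = pd.DataFrame(
        mut_rows, columns=["gene", "line_id", "variant_class", "protein_change"])

    mutant_lines_of = {}
    for driver in spec.drivers:
        gid = id_of_symbol.get(driver.gene, driver.gene)
        sel = mutations[(mutations["gene"] == gid)
                        & (mutations["variant_class"] == driver.variant_class)]
        mutant_lines_of[gid] = set(sel["line_id"])

    # --- CERES --------------------------------------------------------------
    rng = rngs["ceres"]
    essential_cut = int(round(spec.essential_fraction * spec.n_genes))
    base_mean = np.zeros(spec.n_genes)
    base_mean[:essential_cut] = -1.0
    ceres_values = rng.normal(base_mean[:, None], spec.ceres_sigma,
                              size=(spec.n_genes, spec.n_lines))
    info_by_line = sample_info.set_index("line_id")

    def lines_matching(predicate: dict) -> list[str]:
        hit = []
        for line in line_ids:
            ok = True
            for key, value in predicate.items():
                if key == "mutated":
                    gid = id_of_symbol.get(value, value)
                    ok &= line in mutant_lines_of.get(gid, set())
                elif key == "line_ids":
                    ok &= line in set(value)
                else:
                    ok &= str(info_by_line.loc[line, key]) == str(value)
            if ok:
                hit.append(line)
        return hit

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for effect in spec.planted_essentiality:
        gid = id_of_symbol.get(effect.gene, effect.gene)
        target = lines_matching(effect.predicate)
        cols = [line_ids.index(l) for l in target]
        ceres_values[gene_pos[gid], cols] += effect.delta
        truth_rows.append({"kind": "essentiality", "gene": gid,
                           "target": json.dumps(effect.predicate, sort_keys=True),
                           "param": "delta", "value": effect.delta})
    ceres = pd.DataFrame(ceres_values, index=gene_ids, columns=line_ids)

    # --- Bayes factors ------------------------------------------------------
    rng = rngs["bayes"]
    bayes = pd.DataFrame(
        spec.bf_scale * (-ceres_values)
        + rng.normal(0.0, spec.bf_noise, size=ceres_values.shape),
        index=gene_ids, columns=line_ids,
    )

    # --- counts -------------------------------------------------------------
    rng = rngs["counts"]
    n_panel = min(spec.n_counts_samples, spec.n_lines)
    panel_samples = line_ids[:n_panel]
    external_samples = [f"EXT-{i + 1:03d}" for i in range(spec.n_external_samples)]
    samples = panel_samples + external_samples
    condition = ["malignant"] * n_panel + ["benign"] * spec.n_external_samples
    source = ["panel"] * n_panel + ["external"] * spec.n_external_samples
    base = rng.lognormal(spec.counts_mean_log, spec.counts_sigma_log, size=spec.n_genes)
    mu = np.tile(base[:, None], (1, len(samples)))
    for effect in spec.planted_expression:
        gid = id_of_symbol.get(effect.gene, effect.gene)
        # planted fold change: malignant (panel) over benign (external)
        mu[gene_pos[gid], :n_panel] *= 2.0 ** effect.log2fc
        truth_rows.append({"kind": "expression", "gene": gid, "target": "malignant",
                           "param": "log2fc", "value": effect.log2fc})
    sf = rng.uniform(*spec.size_factor_range, size=len(samples))
    lam = rng.gamma(shape=1.0 / spec.nb_dispersion,
                    scale=mu * spec.nb_dispersion * sf[None, :])
    counts = pd.DataFrame(rng.poisson(lam).astype(np.int64),
                          index=gene_ids, columns=samples)
    counts_samples = pd.DataFrame({
        "sample": samples, "condition": condition, "source": source})

    # --- localization -------------------------------------------------------
    rng = rngs["localization"]
    categories_by_score = {4: "validated", 3: "supported", 2: "approved", 1: "uncertain"}
    loc_rows = []
    surface_ids = {id_of_symbol.get(g, g) for g in spec.surface_genes}
    sources = ("cell_atlas", "map_of_cell", "surfaceome")
    for gid in gene_ids:
        if gid in surface_ids:
            # guaranteed high-confidence plasma-membrane annotation (>= 3+3)
            for src in sources[:2]:
                loc_rows.append({"gene": gid, "compartment": "plasma membrane",
                                 "source": src, "category": "validated"})
            loc_rows.append({"gene": gid, "compartment": "plasma membrane",
                             "source": sources[2], "category": "supported"})
            truth_rows.append({"kind": "localization", "gene": gid,
                               "target": "plasma membrane", "param": "score",
                               "value": 11})
            continue
        for src in sources:
            if rng.random() < spec.localization_rate:
                compartment = str(rng.choice(spec.compartments))
                score = int(rng.integers(1, 5))
                loc_rows.append({"gene": gid, "compartment": compartment,
                                 "source": src,
                                 "category": categories_by_score[score]})
    localization = pd.DataFrame(
        loc_rows, columns=["gene", "compartment", "source", "category"])

    # --- complexes ----------------------------------------------------------
    rng = rngs["complexes"]
    complex_rows = []
    n_complexes = max(2, spec.n_genes // 50)
    for c in range(n_complexes):
        size = int(rng.integers(2, 6))
        members = rng.choice(gene_ids, size=size, replace=False)
        complex_rows.append({
            "complex_name": f"CPX-{c + 1:03d}",
            "members": ";".join(symbol_of[g] for g in members),
        })
    complexes = pd.DataFrame(complex_rows, columns=["complex_name", "members"])

    truth = pd.DataFrame(truth_rows,
                         columns=["kind", "gene", "target", "param", "value"])
    return FixtureTables(
        gene_index=gene_index, sample_info=sample_info, ceres=ceres,
        bayes=bayes, counts=counts, counts_samples=counts_samples,
        mutations=mutations, localization=localization, complexes=complexes,
        truth=truth,
    )


FILE_NAMES = (
    "gene_index.csv", "sample_info.csv", "ceres.csv", "bayes.csv",
    "counts.csv", "counts_samples.csv", "mutations.csv", "localization.csv",
    "complexes.csv", "truth.csv",
)


def generate(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture file set; returns name -> path.

    The spec is validated before anything is written.  Floats are formatted
    at fixed precision so identical (spec, seed) runs are byte-identical.
    """
    spec.validate()
    tables = generate_tables(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    paths = {}
    writers = {
        "gene_index.csv": lambda p: tables.gene_index.to_csv(p, index=False),
        "sample_info.csv": lambda p: tables.sample_info.to_csv(p, index=False),
        "ceres.csv": lambda p: tables.ceres.to_csv(p, float_format=fmt),
        "bayes.csv": lambda p: tables.bayes.to_csv(p, float_format=fmt),
        "counts.csv": lambda p: tables.counts.to_csv(p),
        "counts_samples.csv": lambda p: tables.counts_samples.to_csv(p, index=False),
        "mutations.csv": lambda p: tables.mutations.to_csv(p, index=False),
        "localization.csv": lambda p: tables.localization.to_csv(p, index=False),
        "complexes.csv": lambda p: tables.complexes.to_csv(p, index=False),
        "truth.csv": lambda p: tables.truth.to_csv(p, index=False, float_format=fmt),
    }
    for name in FILE_NAMES:
        path = out_dir / name
        writers[name](path)
        paths[name] = path
    return paths


def null_spec(spec: FixtureSpec) -> FixtureSpec:
    """The same study conditions with every planted signal removed."""
    clean = asdict(spec)
    clean["planted_essentiality"] = ()
    clean["planted_expression"] = ()
    clean["surface_genes"] = ()
    clean["drivers"] = tuple(
        DriverModel(**d) for d in clean.pop("drivers")
    )
    clean["planted_essentiality"] = ()
    return FixtureSpec(**{k: v for k, v in clean.items()})


def null_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate the matching no-signal fixture (empty truth table)."""
    return generate(null_spec(spec), out_dir)
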