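"""Shared fixtures: small hand-written tables and generated stores."""

from __future__ import annotations

import pandas as pd
import pytest

from candex.datastore import CellLineIndex, DataStore, GeneIndex, Matrix
from candex.synthdata import (
    DriverModel,
    FixtureSpec,
    PlantedEssentiality,
    generate_tables,
)


@pytest.fixture
def gene_index() -> GeneIndex:
    return GeneIndex(pd.DataFrame({
        "symbol": ["KRAS", "TP53", "EGFR", "VHL", "ELOB"],
        "stable_id": ["3845", "7157", "1956", "7428", "6921"],
        "aliases": ["KRAS2;C-K-RAS", "P53", "ERBB1", "", "TCEB2"],
    }))


@pytest.fixture
def line_index() -> CellLineIndex:
    return CellLineIndex(pd.DataFrame({
        "line_id": ["ACH-000001", "ACH-000002", "ACH-000003", "ACH-000004"],
        "ccle_name": ["A549_LUNG", "H358_LUNG", "PC9_LUNG", "SKOV3_OVARY"],
        "lineage": ["lung", "lung", "lung", "ovary"],
        "disease": ["NSCLC", "NSCLC", "NSCLC", "ovarian cancer"],
        "sex": ["Male", "F", "male", "Female"],
    }))


@pytest.fixture
def mutation_table() -> pd.DataFrame:
    """Two KRAS-missense lines, one EGFR line, one silent-only line."""
    return pd.DataFrame({
        "gene": ["3845", "3845", "1956", "3845"],
        "line_id": ["ACH-000001", "ACH-000002", "ACH-000003", "ACH-000004"],
        "variant_class": ["Missense_Mutation", "Missense_Mutation",
                          "Missense_Mutation", "Silent"],
        "protein_change": ["G12D", "G12C", "L858R", ""],
    })


@pytest.fixture
def small_store(gene_index, line_index, mutation_table) -> DataStore:
    ceres = pd.DataFrame(
        [[-1.2, -0.9, -0.1, 0.0],
         [0.1, -0.2, 0.05, -0.05],
         [-0.3, -0.1, -1.5, 0.2],
         [0.0, 0.1, -0.1, 0.05],
         [0.02, 0.0, -0.05, 0.1]],
        index=["3845", "7157", "1956", "7428", "6921"],
        columns=["ACH-000001", "ACH-000002", "ACH-000003", "ACH-000004"],
    )
    localization = pd.DataFrame({
        "gene": ["3845", "3845", "7428", "1956"],
        "compartment": ["plasma membrane", "cytosol", "nucleus", "plasma membrane"],
        "source": ["cell_atlas", "map_of_cell", "cell_atlas", "surfaceome"],
        "category": ["validated", "supported", "approved", "supported"],
    })
    complexes = pd.DataFrame({
        "complex_name": ["VHL-elongin", "RAS-module"],
        "members": [["7428", "6921"], ["3845", "1956"]],
    })
    return DataStore(
        gene_index=gene_index, line_index=line_index,
        ceres=Matrix(df=ceres, kind="ceres"),
        mutations=mutation_table, localization=localization,
        complexes=complexes,
    )


@pytest.fixture(scope="session")
def planted_spec() -> FixtureSpec:
    """Mid-size fixture with one driver and conditional essentiality."""
    planted = tuple(
        PlantedEssentiality(gene=f"G{i + 1:04d}", predicate={"mutated": "G0001"},
                            delta=-0.8)
        for i in range(50, 55)
    )
    return FixtureSpec(
        n_genes=120, n_lines=24, seed=42, sex_probs=(0.5, 0.5, 0.0),
        drivers=(DriverModel(gene="G0001", rate=0.5,
                             protein_changes=("G12D", "G12V")),),
        planted_essentiality=planted,
        surface_genes=("G0010", "G0011"),
    )


@pytest.fixture(scope="session")
def planted_tables(planted_spec):
    return generate_tables(planted_spec)


@pytest.fixture(scope="session")
def fixture_store(planted_spec, tmp_path_factory) -> DataStore:
    from candex.synthdata import generate

    out = tmp_path_factory.mktemp("fixture")
    generate(planted_spec, out)
    return DataStore.from_directory(out)
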