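"""Pan-cancer conditional-essentiality screen.

Bayes-factor essentiality profiles are binarized (BF > 5 = essential), genes
in a variance-percentile band (default 85th-95th) are kept as the "variably
essential" core set, and each (gene, driver mutation) pair gets a 2x2
Pearson chi-square test of essentiality x mutation status.  Drivers come in
two groups: tumor suppressors hit by nonsense mutations, and oncogenes hit
by specific missense driver protein changes.  Significant pairs are followed
up on the continuous CERES scale with Mann-Whitney and Cohen's d, reported
as onco-only, tsg-only and combined groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .essentiality import cohens_d, mann_whitney


@dataclass(frozen=True)
class DriverSpec:
    """One driver mutation definition.

    ``tsg_nonsense`` drivers match any nonsense mutation in the gene;
    ``onco_missense`` drivers match missense mutations with one of the named
    protein changes (required, non-empty).
    """

    gene: str
    group: str  # "tsg_nonsense" | "onco_missense"
    protein_changes: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.group not in ("tsg_nonsense", "onco_missense"):
            raise ValueError(f"unknown driver group {self.group!r}")
        if self.group == "onco_missense" and not self.protein_changes:
            raise ValueError(f"onco_missense driver {self.gene} needs protein changes")
        if self.group == "tsg_nonsense" and self.protein_changes:
            raise ValueError(f"tsg_nonsense driver {self.gene} must not list protein changes")


def load_driver_table(path) -> list[DriverSpec]:
    """Driver list CSV: columns gene, group, protein_changes (';'-separated)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    drivers = []
    for _, row in df.iterrows():
        changes = tuple(
            c.strip().upper() for c in row.get("protein_changes", "").split(";") if c.strip()
        )
        drivers.append(DriverSpec(gene=row["gene"], group=row["group"],
                                  protein_changes=changes))
    return drivers


def binarize_bayes_factors(bayes: pd.DataFrame, cutoff: float = 5.0) -> pd.DataFrame:
    """1 = essential iff BF strictly exceeds the cutoff; BF == cutoff is 0.

    Missing values stay missing.
    """
    out = (bayes > cutoff).astype(float)
    out[bayes.isna()] = np.nan
    return out


def select_variable_genes(
    bin_matrix: pd.DataFrame, band: tuple[float, float] = (0.85, 0.95)
) -> list[str]:
    """Genes whose binary-essentiality variance rank falls in the band.

    Genes need >= 2 non-missing values to be testable.  Genes are ranked
    ascending by (sample variance, gene id) — the id breaks ties
    deterministically — and ranks in ``[floor(lower*G), floor(upper*G))`` are
    selected, so a [0.85, 0.95) band over G testable genes returns exactly
    ``floor(0.95 G) - floor(0.85 G)`` genes.
    """
    lo, hi = float(band[0]), float(band[1])
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"variance band must satisfy 0 <= lower < upper <= 1, got {band}")
    testable = bin_matrix.index[bin_matrix.notna().sum(axis=1) >= 2]
    variances = bin_matrix.loc[testable].var(axis=1, ddof=1)
    order = sorted(testable, key=lambda g: (variances[g], str(g)))
    g = len(order)
    return sorted(order[math.floor(lo * g): math.floor(hi * g)])


def mutation_indicator(
    driver: DriverSpec, line_ids: Sequence[str], mutations: pd.DataFrame,
    gene_id: str | None = None,
) -> pd.Series:
    """0/1 per line: does the line carry the driver lesion?

    ``gene_id`` overrides ``driver.gene`` when the mutation table uses
    canonical stable ids and the driver was specified by symbol.
    """
    gid = gene_id if gene_id is not None else driver.gene
    sel = mutations[mutations["gene"] == gid]
    if driver.group == "tsg_nonsense":
        sel = sel[sel["variant_class"] == "Nonsense_Mutation"]
    else:
        sel = sel[
            (sel["variant_class"] == "Missense_Mutation")
            & sel["protein_change"].isin([c.upper() for c in driver.protein_changes])
        ]
    hit = set(sel["line_id"])
    return pd.Series([1 if l in hit else 0 for l in line_ids],
                     index=list(line_ids), dtype=int)


def chi_square_2x2(table: np.ndarray | Sequence[Sequence[float]]
                   ) -> tuple[float, float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

    Returns (chi2, p, expected_min).  A zero row or column margin makes the
    test undefined: (nan, nan, expected_min) — an untestable flag, not an
    exception.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("chi_square_2x2 needs a 2x2 table of non-negative counts")
    n = t.sum()
    if n <= 0:
        raise ValueError("chi_square_2x2 needs a positive total count")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    expected = np.outer(rows, cols) / n
    if (rows == 0).any() or (cols == 0).any():
        return (math.nan, math.nan, float(expected.min()))
    chi2, p, _, expected = stats.chi2_contingency(t, correction=False)[:4]
    return float(chi2), float(p), float(expected.min())


def run_pair_screen(
    bin_matrix: pd.DataFrame,
    drivers: Iterable[DriverSpec],
    gene_cluster: Sequence[str],
    mutations: pd.DataFrame,
    alpha: float = 0.01,
    driver_gene_ids: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Chi-square screen over every (variable gene, driver) pair.

    One test per pair, over lines with non-missing binarized essentiality.
    Pairs with a zero margin (e.g. a driver with no mutant line among usable
    lines) are retained with ``testable=False``.  Self-pairs (the essential
    gene is the driver gene) are kept and labeled: oncogene self-essentiality
    is a result, not an artifact.

    Returns one row per pair: ess_gene, driver_gene, driver_group, the four
    contingency counts (a=mut&ess, b=mut&non, c=wt&ess, d=wt&non), chi2, p,
    expected_min, testable, significant, self_pair.
    """
    genes = [g for g in gene_cluster if g in bin_matrix.index]
    line_ids = list(bin_matrix.columns)
    rows = []
    for driver in drivers:
        gid = (driver_gene_ids or {}).get(driver.gene, driver.gene)
        indicator = mutation_indicator(driver, line_ids, mutations, gene_id=gid).to_numpy()
        for gene in genes:
            ess = bin_matrix.loc[gene].to_numpy(dtype=float)
            ok = ~np.isnan(ess)
            e, m = ess[ok].astype(int), indicator[ok]
            a = int(((m == 1) & (e == 1)).sum())
            b = int(((m == 1) & (e == 0)).sum())
            c = int(((m == 0) & (e == 1)).sum())
            d = int(((m == 0) & (e == 0)).sum())
            if a + b + c + d == 0:
                chi2 = p = emin = math.nan
            else:
                chi2, p, emin = chi_square_2x2([[a, b], [c, d]])
            rows.append({
                "ess_gene": gene, "driver_gene": gid, "driver_group": driver.group,
                "mut_ess": a, "mut_non": b, "wt_ess": c, "wt_non": d,
                "chi2": chi2, "p": p, "expected_min": emin,
                "testable": not math.isnan(p),
                "significant": (not math.isnan(p)) and p < alpha,
                "self_pair": gene == gid,
            })
    out = pd.DataFrame(rows)
    return out.sort_values(["driver_group", "p", "ess_gene", "driver_gene"],
                           na_position="last").reset_index(drop=True)


def followup_effect_sizes(
    screen: pd.DataFrame,
    ceres: pd.DataFrame,
    drivers: Iterable[DriverSpec],
    mutations: pd.DataFrame,
    driver_gene_ids: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Continuous-scale follow-up of the screen's significant pairs.

    For each significant pair, compares CERES scores of driver-mutant vs
    wildtype lines: Mann-Whitney p, mean difference (mutant - wildtype) and
    Cohen's d.  Pairs with < 2 usable lines on either side keep NaN effect
    sizes and are flagged.  Returns three reporting groups: ``onco`` (pairs
    from the missense screen), ``tsg`` (nonsense screen), and ``combined``
    (both, mutation type not discriminated).
    """
    driver_by_gid = {}
    for driver in drivers:
        gid = (driver_gene_ids or {}).get(driver.gene, driver.gene)
        driver_by_gid[(gid, driver.group)] = driver
    sig = screen[screen["significant"]]
    rows = []
    line_ids = list(ceres.columns)
    indicators: dict[tuple[str, str], np.ndarray] = {}
    for _, pair in sig.iterrows():
        key = (pair["driver_gene"], pair["driver_group"])
        if key not in indicators:
            indicators[key] = mutation_indicator(
                driver_by_gid[key], line_ids, mutations, gene_id=key[0]
            ).to_numpy()
        ind = indicators[key]
        if pair["ess_gene"] not in ceres.index:
            continue
        values = ceres.loc[pair["ess_gene"]].to_numpy(dtype=float)
        mut, wt = values[ind == 1], values[ind == 0]
        mut, wt = mut[~np.isnan(mut)], wt[~np.isnan(wt)]
        defined = len(mut) >= 2 and len(wt) >= 2
        mw_p = mann_whitney(mut, wt)[1] if defined else math.nan
        rows.append({
            "ess_gene": pair["ess_gene"], "driver_gene": pair["driver_gene"],
            "driver_group": pair["driver_group"],
            "chi2": pair["chi2"], "chi2_p": pair["p"],
            "mw_p": mw_p,
            "mean_diff": float(mut.mean() - wt.mean()) if (len(mut) and len(wt)) else math.nan,
            "cohens_d": cohens_d(mut, wt) if defined else math.nan,
            "n_mut": len(mut), "n_wt": len(wt),
            "effect_defined": defined,
            "self_pair": pair["self_pair"],
        })
    combined = pd.DataFrame(rows, columns=[
        "ess_gene", "driver_gene", "driver_group", "chi2", "chi2_p", "mw_p",
        "mean_diff", "cohens_d", "n_mut", "n_wt", "effect_defined", "self_pair",
    ]).reset_index(drop=True)
    return {
        "onco": combined[combined["driver_group"] == "onco_missense"].reset_index(drop=True),
        "tsg": combined[combined["driver_group"] == "tsg_nonsense"].reset_index(drop=True),
        "combined": combined,
    }
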