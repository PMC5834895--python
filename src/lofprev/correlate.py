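"""Spearman correlations of LoF prevalence with life-history traits.

Species-mean LoF proportions (all / core / hardcore genes) are correlated
against lifetime fecundity, longevity, adult size, body mass, propagule
size, genome size and synonymous diversity (pi_S) using midrank Spearman
rho with the two-sided t-approximation, and the whole emitted grid of tests
is corrected with the Benjamini-Hochberg step-up procedure.  Missing trait
values are handled by pairwise deletion, never imputed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

TRAIT_COLUMNS = [
    "species_id",
    "phylum",
    "adult_size",
    "body_mass",
    "longevity",
    "lifetime_fecundity",
    "propagule_size",
    "genome_size",
    "pi_s",
    "haplodiploid",
]

DEFAULT_TRAITS = [
    "adult_size",
    "body_mass",
    "longevity",
    "lifetime_fecundity",
    "propagule_size",
    "genome_size",
    "pi_s",
]


@dataclass
class SpeciesRecord:
    """One species' traits plus its mean LoF proportions.

    ``mean_p`` maps (gene_set, variant_type, region) to a proportion or None.
    Trait values may be missing (None/NaN); lifetime fecundity, when present,
    must be positive.
    """

    species_id: str
    phylum: str = ""
    adult_size: Optional[float] = None
    body_mass: Optional[float] = None
    longevity: Optional[float] = None
    lifetime_fecundity: Optional[float] = None
    propagule_size: Optional[float] = None
    genome_size: Optional[float] = None
    pi_s: Optional[float] = None
    haplodiploid: bool = False
    mean_p: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mean_p is None:
            self.mean_p = {}
        if self.lifetime_fecundity is not None and not (
            math.isnan(self.lifetime_fecundity) or self.lifetime_fecundity > 0
        ):
            raise ValueError(f"{self.species_id}: lifetime_fecundity must be > 0")
        if self.pi_s is not None and not (math.isnan(self.pi_s) or self.pi_s >= 0):
            raise ValueError(f"{self.species_id}: pi_s must be >= 0")


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    n_pairs: int
    rho: Optional[float]
    p_raw: Optional[float]
    p_bh: Optional[float] = None
    significant: Optional[bool] = None
    reason: str = ""


def _pairwise_complete(x: Sequence, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray([np.nan if v is None else float(v) for v in x])
    ya = np.asarray([np.nan if v is None else float(v) for v in y])
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(xa) | np.isnan(ya))
    return xa[ok], ya[ok]


def spearman(
    x: Sequence, y: Sequence, exact: bool = False
) -> tuple[Optional[float], Optional[float], int, str]:
    """Midrank Spearman rho with a two-sided t-approximation p-value.

    Returns (rho, p, n_used, reason); rho/p are None with a reason when
    fewer than 3 complete pairs remain or either vector is constant.  With
    ``exact=True`` (n <= 10) the p-value is the exhaustive permutation tail
    probability of |rho|.
    """
    xa, ya = _pairwise_complete(x, y)
    n = xa.size
    if n < 3:
        return None, None, n, "fewer than 3 complete pairs"
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return None, None, n, "zero variance"
    rho, p = sps.spearmanr(xa, ya)
    rho = float(rho)
    if abs(rho) >= 1.0 - 1e-12:
        return float(np.sign(rho)), 0.0, n, ""
    if exact:
        p = _exact_permutation_p(xa, ya, rho)
    return rho, float(p), n, ""


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    n = x.size
    if n > 10:
        raise ValueError("exact permutation p-value supported only for n <= 10")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    xc = xr - xr.mean()
    denom_x = np.sqrt((xc**2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        yp = yr[list(perm)]
        yc = yp - yp.mean()
        denom = denom_x * np.sqrt((yc**2).sum())
        r = float(xc @ yc) / denom
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_adjust(p_values: Sequence[Optional[float]]) -> list[Optional[float]]:
    """Benjamini-Hochberg step-up adjustment, missing entries passed through."""
    vals = [None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v) for v in p_values]
    for v in vals:
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError(f"p-value {v} outside [0, 1]")
    present = [v for v in vals if v is not None]
    if not present:
        return list(vals)
    _, adj, _, _ = multipletests(present, method="fdr_bh")
    it = iter(adj)
    return [None if v is None else float(next(it)) for v in vals]


def records_to_frame(
    records: Sequence[SpeciesRecord],
    measures: Sequence[tuple[str, str, str]],
    traits: Sequence[str] = tuple(DEFAULT_TRAITS),
) -> pd.DataFrame:
    """Wide per-species table of measure and trait columns.

    A measure is a (gene_set, variant_type, region) triple, labelled
    ``p_<gene_set>`` for the primary all_lof/full_cds strata and fully
    qualified otherwise.
    """
    data: dict[str, list] = {"species_id": [r.species_id for r in records]}
    for m in measures:
        data[measure_label(m)] = [r.mean_p.get(m) for r in records]
    for t in traits:
        data[t] = [getattr(r, t) for r in records]
    return pd.DataFrame(data)


def measure_label(measure: tuple[str, str, str]) -> str:
    gene_set, variant_type, region = measure
    if variant_type == "all_lof" and region == "full_cds":
        return f"p_{gene_set}"
    return f"p_{gene_set}_{variant_type}_{region}"


def correlation_matrix(
    records: Sequence[SpeciesRecord],
    measures: Sequence[tuple[str, str, str]],
    traits: Sequence[str] = tuple(DEFAULT_TRAITS),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise Spearman tests over measures and traits, BH-corrected.

    Every unordered pair of distinct variables (measure-trait, trait-trait
    and measure-measure, as in a full correlation heatmap) is tested; the BH
    family is the entire emitted grid.  Returns a long-format table with
    columns x, y, n, rho, p_raw, p_bh, significant, reason.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 species")
    frame = records_to_frame(records, measures, traits)
    variables = [measure_label(m) for m in measures] + list(traits)
    rows = []
    for xl, yl in itertools.combinations(variables, 2):
        rho, p, n, reason = spearman(frame[xl], frame[yl])
        rows.append({"x": xl, "y": yl, "n": n, "rho": rho, "p_raw": p, "reason": reason})
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(list(out["p_raw"]))
    out["significant"] = [
        (None if p is None else bool(p < alpha)) for p in out["p_bh"]
    ]
    return out


# ---------------------------------------------------------------------------
# Trait table I/O

def read_trait_table(path: str | Path) -> list[SpeciesRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trait columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in TRAIT_COLUMNS:
            val = row[col]
            if col in ("species_id", "phylum"):
                kwargs[col] = str(val)
            elif col == "haplodiploid":
                kwargs[col] = bool(val) and str(val).lower() not in ("false", "0")
            else:
                kwargs[col] = None if pd.isna(val) else float(val)
        records.append(SpeciesRecord(**kwargs))
    return records


def write_trait_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "phylum": r.phylum,
                "adult_size": r.adult_size,
                "body_mass": r.body_mass,
                "longevity": r.longevity,
                "lifetime_fecundity": r.lifetime_fecundity,
                "propagule_size": r.propagule_size,
                "genome_size": "" if r.genome_size is None else r.genome_size,
                "pi_s": "" if r.pi_s is None else r.pi_s,
                "haplodiploid": r.haplodiploid,
            }
        )
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_correlation_table(grid: pd.DataFrame, path: str | Path) -> None:
    grid.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Recomputation from species-level tables

def grand_means_from_species_table(
    species_means: pd.DataFrame, region: str = "full_cds", variant_type: str = "all_lof"
) -> dict[str, float]:
    """Across-species grand mean of the species-mean proportions per gene set.

    ``species_means`` is the per-species long table (columns species,
    gene_set, variant_type, region, mean_p), i.e. the shape of the published
    per-species supplement.
    """
    sub = species_means[
        (species_means.region == region) & (species_means.variant_type == variant_type)
    ]
    return {
        gs: float(grp["mean_p"].dropna().mean())
        for gs, grp in sub.groupby("gene_set")
    }


def fecundity_correlations(
    species_means: pd.DataFrame,
    records: Sequence[SpeciesRecord],
    gene_sets: Sequence[str] = ("all", "hardcore"),
    region: str = "full_cds",
) -> dict[str, CorrelationResult]:
    """Species-mean LoF proportion vs lifetime fecundity, per gene set.

    This is the headline scatter computation: one Spearman test per gene set,
    raw p-values (no family correction within this pair of tests).
    """
    fec = {r.species_id: r.lifetime_fecundity for r in records}
    out = {}
    sub = species_means[
        (species_means.region == region) & (species_means.variant_type == "all_lof")
    ]
    for gs in gene_sets:
        g = sub[sub.gene_set == gs]
        x = [fec.get(s) for s in g["species"]]
        y = list(g["mean_p"])
        rho, p, n, reason = spearman(x, y)
        out[gs] = CorrelationResult(
            x_label="lifetime_fecundity", y_label=f"p_{gs}", n_pairs=n,
            rho=rho, p_raw=p, reason=reason,
        )
    return out
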