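"""The LoF proportion statistic and its species-level summaries.

For an individual, the proportion of LoF alleles is

    p = (N_LoFHet + 2 * N_LoFHom) / (2 * N)

where N is the number of ORFs fully sequenced for the individual and
N_LoFHet / N_LoFHom count genes carrying a heterozygous / homozygous LoF
allele.  The statistic is computed per gene set (all / core / hardcore),
per variant type (all_lof / nonsense / frameshift / stoploss) and per region
(full CDS or the last-100-nt NMD-escape window); species values are
unweighted means over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .qc import GENE_SETS, GeneSetPartition, IndividualProfile

VARIANT_TYPES = ("all_lof", "nonsense", "frameshift", "stoploss")
REGIONS = ("full_cds", "last100nt")


@dataclass(frozen=True)
class LoFProportion:
    """One individual's LoF allele proportion for one stratum.

    ``p`` is None (missing, distinct from zero) when the gene set restricted
    to the individual's fully sequenced ORFs is empty.
    """

    individual_id: str
    species_id: str
    gene_set: str
    variant_type: str
    region: str
    n_total: int
    n_het: int
    n_hom: int
    p: Optional[float]


@dataclass(frozen=True)
class SummaryRow:
    """Min/max/mean of species-level proportions, in percent (2 decimals)."""

    variant_type: str
    min: float
    max: float
    mean: float


def lof_proportion(n_total: int, n_het: int, n_hom: int) -> Optional[float]:
    """Evaluate p = (N_het + 2 N_hom) / (2 N); None when N = 0 (missing)."""
    if n_total < 0 or n_het < 0 or n_hom < 0:
        raise ValueError("counts must be non-negative")
    if n_het + n_hom > n_total:
        raise ValueError("LoF gene counts exceed the number of sequenced genes")
    if n_total == 0:
        return None
    return (n_het + 2 * n_hom) / (2 * n_total)


def individual_statistics(
    profile: IndividualProfile,
    partition: GeneSetPartition,
    gene_set: str = "all",
    variant_type: str = "all_lof",
    region: str = "full_cds",
) -> LoFProportion:
    """Compute the proportion for one individual and one stratum.

    N counts the individual's fully sequenced ORFs within the gene set; a
    gene enters the het/hom counts only through LoF variants of the requested
    type falling in the requested region.  N itself does not depend on the
    type or region.
    """
    if variant_type not in VARIANT_TYPES:
        raise ValueError(f"unknown variant type {variant_type!r}")
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    genes = profile.covered_orfs & partition.get(gene_set)
    n_het = n_hom = 0
    for g in genes:
        gl = profile.gene_lof.get(g)
        if gl is None:
            continue
        state = gl.state(region=region, variant_type=variant_type)
        if state == "hom_lof":
            n_hom += 1
        elif state == "het_lof":
            n_het += 1
    return LoFProportion(
        individual_id=profile.individual_id,
        species_id=profile.species_id,
        gene_set=gene_set,
        variant_type=variant_type,
        region=region,
        n_total=len(genes),
        n_het=n_het,
        n_hom=n_hom,
        p=lof_proportion(len(genes), n_het, n_hom),
    )


def all_individual_statistics(
    profiles: Sequence[IndividualProfile],
    partition: GeneSetPartition,
    gene_sets: Sequence[str] = GENE_SETS,
    variant_types: Sequence[str] = VARIANT_TYPES,
    regions: Sequence[str] = REGIONS,
) -> list[LoFProportion]:
    out = []
    for prof in profiles:
        for gs in gene_sets:
            for vt in variant_types:
                for rg in regions:
                    out.append(individual_statistics(prof, partition, gs, vt, rg))
    return out


def individual_table(stats: Sequence[LoFProportion]) -> pd.DataFrame:
    """Per-individual long table (individual, species, stratum, counts, p)."""
    return pd.DataFrame(
        {
            "individual": [s.individual_id for s in stats],
            "species": [s.species_id for s in stats],
            "gene_set": [s.gene_set for s in stats],
            "variant_type": [s.variant_type for s in stats],
            "region": [s.region for s in stats],
            "N": [s.n_total for s in stats],
            "N_het": [s.n_het for s in stats],
            "N_hom": [s.n_hom for s in stats],
            "p": [s.p for s in stats],
        }
    )


def species_means(stats: Sequence[LoFProportion]) -> pd.DataFrame:
    """Unweighted per-species mean of p for every stratum.

    Missing individual values (empty restricted gene set) propagate as
    missing and are excluded from the mean; a species whose individuals are
    all missing stays missing.
    """
    df = individual_table(stats)
    return (
        df.groupby(["species", "gene_set", "variant_type", "region"], sort=True)["p"]
        .mean()
        .reset_index()
        .rename(columns={"p": "mean_p"})
    )


def summary_table(
    means: pd.DataFrame, gene_set: str = "all", region: str = "full_cds"
) -> list[SummaryRow]:
    """Min/max/mean across species per variant type, in percent (2 dp)."""
    rows = []
    sub = means[(means.gene_set == gene_set) & (means.region == region)]
    for vt in VARIANT_TYPES:
        vals = sub.loc[sub.variant_type == vt, "mean_p"].dropna()
        if vals.empty:
            continue
        rows.append(
            SummaryRow(
                variant_type=vt,
                min=round(100 * vals.min(), 2),
                max=round(100 * vals.max(), 2),
                mean=round(100 * vals.mean(), 2),
            )
        )
    return rows


def write_summary_table(rows: Iterable[SummaryRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_type\tmin_pct\tmax_pct\tmean_pct\n")
        for r in rows:
            fh.write(f"{r.variant_type}\t{r.min:.2f}\t{r.max:.2f}\t{r.mean:.2f}\n")


def format_percent(p: float) -> str:
    """Render a proportion as the tables print it (percent, 2 decimals)."""
    return f"{100 * p:.2f}%"


def parse_percent(s: str) -> float:
    return float(s.rstrip("%")) / 100
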