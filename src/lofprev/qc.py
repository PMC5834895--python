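"""Site-, individual- and species-level exclusion rules and gene sets.

Wording of the filters is encoded literally: site validity uses strict
inequalities ("more than 5x", "over 20"), while individual/species floors
use "below X excluded", i.e. boundary values are kept.  The core set is the
intersection with a provided essential-gene list; the hard-core set removes
every core gene with a homozygous LoF allele in any individual of any
species (a global exclusion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consequence import GeneLoF, GeneZygosity, VariantCall
from .orf import OrfAnnotation


@dataclass(frozen=True)
class SiteThresholds:
    """Validity floors for a variant site (all strict inequalities)."""

    min_depth_exclusive: int = 5
    min_qual_exclusive: float = 20.0
    min_mapq_exclusive: float = 20.0

    def __post_init__(self) -> None:
        if (
            self.min_depth_exclusive < 0
            or self.min_qual_exclusive < 0
            or self.min_mapq_exclusive < 0
        ):
            raise ValueError("thresholds must be non-negative")


#: Robustness preset: "at least 20X coverage" with integer depths is depth > 19.
STRICT_20X = SiteThresholds(min_depth_exclusive=19)

MODE_THRESHOLDS = {
    "default": SiteThresholds(),
    "strict20x": STRICT_20X,
    "last100nt": SiteThresholds(),
}


@dataclass(frozen=True)
class IndividualThresholds:
    """Floors for keeping an individual (boundary values kept)."""

    min_mean_coverage: float = 10.0
    min_alignment_rate: float = 0.80
    min_covered_orfs: int = 5000
    min_covered_core: int = 100


@dataclass(frozen=True)
class SpeciesThresholds:
    """Floors for keeping a species (boundary values kept)."""

    min_alignment_rate: float = 0.70
    min_orfs: int = 5000
    min_core: int = 100


@dataclass
class IndividualProfile:
    """Per-individual QC metrics and gene-level LoF evidence.

    ``covered_orfs`` is the set of genes fully sequenced for the individual
    (this is the N of the proportion statistic); ``n_partial_orfs`` /
    ``n_partial_core`` count at-least-partially covered genes and feed the
    individual-level exclusion rule.
    """

    individual_id: str
    species_id: str
    mean_coverage: float
    alignment_rate: float
    covered_orfs: frozenset[str]
    n_partial_orfs: int
    n_partial_core: int
    gene_lof: dict[str, GeneLoF] = field(default_factory=dict)

    @property
    def gene_zygosities(self) -> dict[str, GeneZygosity]:
        return {g: GeneZygosity(g, gl.state()) for g, gl in self.gene_lof.items()}


@dataclass(frozen=True)
class SpeciesQC:
    species_id: str
    alignment_rate: float
    n_orfs: int
    n_core: int
    haplodiploid: bool = False


@dataclass(frozen=True)
class GeneSetPartition:
    all_genes: frozenset[str]
    core_genes: frozenset[str]
    hardcore_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.hardcore_genes <= self.core_genes <= self.all_genes:
            raise ValueError("gene sets must nest: hardcore <= core <= all")

    def get(self, label: str) -> frozenset[str]:
        try:
            return {
                "all": self.all_genes,
                "core": self.core_genes,
                "hardcore": self.hardcore_genes,
            }[label]
        except KeyError:
            raise KeyError(f"unknown gene set {label!r}") from None


GENE_SETS = ("all", "core", "hardcore")


# ---------------------------------------------------------------------------
# Filters

def filter_variant_calls(
    calls: Iterable[VariantCall], t: SiteThresholds = SiteThresholds()
) -> list[VariantCall]:
    """Keep calls at valid sites: depth > 5x, variant and mapping quality > 20."""
    return [
        v
        for v in calls
        if v.depth > t.min_depth_exclusive
        and v.variant_qual > t.min_qual_exclusive
        and v.mapping_qual > t.min_mapq_exclusive
    ]


def fully_sequenced_orfs(
    depth_by_transcript: Mapping[str, np.ndarray],
    orfs: Iterable[OrfAnnotation],
    t: SiteThresholds = SiteThresholds(),
) -> frozenset[str]:
    """Genes whose every CDS position clears the site depth floor.

    This is the strictest reading of "fully sequenced"; it defines the N of
    the proportion statistic when per-site depth tracks are available.
    """
    kept = []
    for orf in orfs:
        track = depth_by_transcript.get(orf.transcript_id)
        if track is None:
            continue
        cds = np.asarray(track)[orf.cds_start : orf.cds_end]
        if cds.size == orf.cds_length and np.all(cds > t.min_depth_exclusive):
            kept.append(orf.transcript_id)
    return frozenset(kept)


@dataclass(frozen=True)
class Exclusion:
    level: str
    id: str
    failed_criterion: str
    value: float
    threshold: float


def filter_individuals(
    profiles: Sequence[IndividualProfile],
    t: IndividualThresholds = IndividualThresholds(),
) -> tuple[list[IndividualProfile], list[Exclusion]]:
    """Apply the individual-level exclusion rules; boundary values are kept."""
    kept: list[IndividualProfile] = []
    log: list[Exclusion] = []
    for p in profiles:
        if p.mean_coverage < t.min_mean_coverage:
            log.append(
                Exclusion("individual", p.individual_id, "coverage", p.mean_coverage, t.min_mean_coverage)
            )
        elif p.alignment_rate < t.min_alignment_rate:
            log.append(
                Exclusion("individual", p.individual_id, "alignment_rate", p.alignment_rate, t.min_alignment_rate)
            )
        elif p.n_partial_orfs < t.min_covered_orfs:
            log.append(
                Exclusion("individual", p.individual_id, "covered_orfs", p.n_partial_orfs, t.min_covered_orfs)
            )
        elif p.n_partial_core < t.min_covered_core:
            log.append(
                Exclusion("individual", p.individual_id, "covered_core", p.n_partial_core, t.min_covered_core)
            )
        else:
            kept.append(p)
    return kept, log


def filter_species(
    stats: Sequence[SpeciesQC], t: SpeciesThresholds = SpeciesThresholds()
) -> tuple[list[SpeciesQC], list[Exclusion]]:
    """Apply the species-level exclusion rules, including haplodiploidy."""
    kept: list[SpeciesQC] = []
    log: list[Exclusion] = []
    for s in stats:
        if s.alignment_rate < t.min_alignment_rate:
            log.append(Exclusion("species", s.species_id, "alignment_rate", s.alignment_rate, t.min_alignment_rate))
        elif s.n_orfs < t.min_orfs:
            log.append(Exclusion("species", s.species_id, "n_orfs", s.n_orfs, t.min_orfs))
        elif s.n_core < t.min_core:
            log.append(Exclusion("species", s.species_id, "n_core", s.n_core, t.min_core))
        elif s.haplodiploid:
            log.append(Exclusion("species", s.species_id, "haplodiploid", 1, 0))
        else:
            kept.append(s)
    return kept, log


# ---------------------------------------------------------------------------
# Gene sets

def build_core_set(all_genes: set[str], essential_ids: set[str]) -> frozenset[str]:
    """Core genes: predicted ORFs present in the essential-gene catalogue."""
    if not essential_ids:
        warnings.warn("essential-gene list is empty; core set will be empty")
    return frozenset(all_genes) & frozenset(essential_ids)


def build_hardcore_set(
    core: frozenset[str] | set[str],
    zygosities_by_species: Mapping[str, Mapping[str, GeneZygosity]],
) -> frozenset[str]:
    """Hard-core genes: core minus genes homozygous-LoF anywhere in the panel."""
    excluded = {
        gene_id
        for per_gene in zygosities_by_species.values()
        for gene_id, z in per_gene.items()
        if z.state == "hom_lof"
    }
    return frozenset(core) - excluded


def write_exclusion_log(log: Sequence[Exclusion], path) -> None:
    with open(path, "w") as fh:
        fh.write("level\tid\tfailed_criterion\tvalue\tthreshold\n")
        for e in log:
            fh.write(f"{e.level}\t{e.id}\t{e.failed_criterion}\t{e.value:g}\t{e.threshold:g}\n")
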