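"""Codon-aware variant consequence classification against a chosen ORF.

Loss-of-function (LoF) variants are stopgain and stoploss substitutions and
frameshift indels.  Classification is strand-aware: the variant is projected
into the reading frame of the annotated ORF and its reference and alternate
codons are compared.  A translation-comparison oracle (apply the edit,
re-translate, compare proteins) provides an independent reference
implementation for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from Bio.Data.CodonTable import standard_dna_table

from .orf import OrfAnnotation, TranscriptSeq, STOP_CODONS, reverse_complement

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASES = frozenset("ACGT")


class ConsequenceClass(str, Enum):
    synonymous = "synonymous"
    missense = "missense"
    stopgain = "stopgain"
    stoploss = "stoploss"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    noncoding = "noncoding"


#: Classes counted as loss-of-function.
LOF_CLASSES = frozenset(
    {ConsequenceClass.stopgain, ConsequenceClass.stoploss, ConsequenceClass.frameshift}
)

#: Reporting names used in the per-type summary rows.
LOF_TYPE_NAMES = {
    ConsequenceClass.stopgain: "nonsense",
    ConsequenceClass.frameshift: "frameshift",
    ConsequenceClass.stoploss: "stoploss",
}


class ReferenceMismatchError(ValueError):
    """The VCF REF allele disagrees with the reference transcript sequence."""


class CoordinateError(ValueError):
    """A variant coordinate falls outside its transcript."""


@dataclass(frozen=True)
class VariantCall:
    """One SNV or simple indel in transcript coordinates (POS is 1-based)."""

    transcript_id: str
    pos: int
    ref: str
    alt: str
    zygosity: str
    depth: int
    variant_qual: float
    mapping_qual: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.transcript_id}:{self.pos}: ref == alt")
        if not self.ref or not self.alt:
            raise ValueError(f"{self.transcript_id}:{self.pos}: empty allele")
        for allele in (self.ref, self.alt):
            if set(allele) - _BASES:
                raise ValueError(
                    f"{self.transcript_id}:{self.pos}: allele {allele!r} not over ACGT"
                )
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be 'het' or 'hom', got {self.zygosity!r}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class GeneZygosity:
    """Collapsed per-gene LoF allele state for one individual."""

    gene_id: str
    state: str  # none | het_lof | hom_lof

    def __post_init__(self) -> None:
        if self.state not in ("none", "het_lof", "hom_lof"):
            raise ValueError(f"invalid state {self.state!r}")


def translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return _CODON_TO_AA[codon]


def cds_sequence(seq: TranscriptSeq, orf: OrfAnnotation) -> str:
    """The coding sequence in reading direction (5'->3' on the ORF strand)."""
    region = seq.sequence[orf.cds_start : orf.cds_end]
    return region if orf.strand == "+" else reverse_complement(region)


# ---------------------------------------------------------------------------
# Edit normalization

def _check_ref(seq: TranscriptSeq, v: VariantCall) -> None:
    pos0 = v.pos - 1
    if pos0 < 0 or pos0 + len(v.ref) > len(seq.sequence):
        raise CoordinateError(
            f"{v.transcript_id}: position {v.pos} (+{len(v.ref)} bp) outside "
            f"transcript of length {len(seq.sequence)}"
        )
    observed = seq.sequence[pos0 : pos0 + len(v.ref)]
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"{v.transcript_id}:{v.pos}: REF {v.ref!r} does not match reference "
            f"sequence {observed!r}"
        )


def normalized_edit(seq: TranscriptSeq, v: VariantCall) -> tuple[int, str, str]:
    """Reduce a variant to ``(g, removed, inserted)`` on the forward strand.

    ``removed`` occupies forward positions ``[g, g + len(removed))``;
    ``inserted`` replaces it at ``g``.  Shared leading/trailing bases
    (e.g. the VCF anchor base) are stripped and pure indels are left-aligned
    against the reference.  Raises on REF mismatch or unsupported complex
    (multi-base substitution) alleles.
    """
    _check_ref(seq, v)
    s = seq.sequence
    g = v.pos - 1
    ref, alt = v.ref, v.alt
    while ref and alt and ref[0] == alt[0]:
        ref, alt, g = ref[1:], alt[1:], g + 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    if ref and alt and (len(ref) > 1 or len(alt) > 1):
        raise ValueError(
            f"{v.transcript_id}:{v.pos}: complex substitution {v.ref}>{v.alt} unsupported"
        )
    # left-align pure indels
    if not alt and ref:  # deletion
        while g > 0 and s[g - 1] == ref[-1]:
            ref = s[g - 1] + ref[:-1]
            g -= 1
    elif not ref and alt:  # insertion
        while g > 0 and s[g - 1] == alt[-1]:
            alt = s[g - 1] + alt[:-1]
            g -= 1
    return g, ref, alt


def _edit_is_coding(
    orf: OrfAnnotation, g: int, removed: str, inserted: str
) -> bool:
    a, b = orf.cds_start, orf.cds_end
    if removed:  # substitution or deletion: any changed base inside the CDS
        return g < b and g + len(removed) > a
    # pure insertion: frame shifts only when bases land strictly between
    # CDS positions; an insertion flush with either CDS boundary leaves the
    # reading frame of the annotated ORF intact
    return a < g < b


# ---------------------------------------------------------------------------
# Classifiers

def classify_snv(
    orf: OrfAnnotation, seq: TranscriptSeq, v: VariantCall
) -> ConsequenceClass:
    """Classify a single-nucleotide substitution against the ORF.

    A sense codon turning into a stop before the natural terminator is a
    stopgain; the natural stop turning into a sense codon is a stoploss; a
    stop-to-stop change at the terminator is synonymous.
    """
    if not v.is_snv:
        raise ValueError(f"{v.transcript_id}:{v.pos}: not an SNV")
    _check_ref(seq, v)
    pos0 = v.pos - 1
    if not (orf.cds_start <= pos0 < orf.cds_end):
        return ConsequenceClass.noncoding
    if orf.strand == "+":
        c = pos0 - orf.cds_start
        alt_read = v.alt
    else:
        c = (orf.cds_end - 1) - pos0
        alt_read = _COMP[v.alt]
    codon_i, off = divmod(c, 3)
    cds = cds_sequence(seq, orf)
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_codon = codon[:off] + alt_read + codon[off + 1 :]
    last = len(cds) // 3 - 1
    if codon_i == last:
        if alt_codon in STOP_CODONS:
            return ConsequenceClass.synonymous  # stop-to-stop at the terminator
        return ConsequenceClass.stoploss
    if alt_codon in STOP_CODONS:
        return ConsequenceClass.stopgain
    if "N" in codon or "N" in alt_codon:
        return ConsequenceClass.missense  # amino acid unknown; never LoF
    if translate_codon(codon) == translate_codon(alt_codon):
        return ConsequenceClass.synonymous
    return ConsequenceClass.missense


def classify_indel(
    orf: OrfAnnotation, seq: TranscriptSeq, v: VariantCall
) -> ConsequenceClass:
    """Classify a simple insertion or deletion against the ORF.

    Coding indels whose length is not a multiple of three shift the reading
    frame (frameshift, LoF); multiples of three are in-frame.
    """
    if v.is_snv:
        raise ValueError(f"{v.transcript_id}:{v.pos}: not an indel")
    g, removed, inserted = normalized_edit(seq, v)
    if removed and inserted:
        raise ValueError(f"{v.transcript_id}:{v.pos}: not a simple indel")
    if not _edit_is_coding(orf, g, removed, inserted):
        return ConsequenceClass.noncoding
    if abs(len(removed) - len(inserted)) % 3 != 0:
        return ConsequenceClass.frameshift
    return ConsequenceClass.inframe_indel


def classify(orf: OrfAnnotation, seq: TranscriptSeq, v: VariantCall) -> ConsequenceClass:
    return classify_snv(orf, seq, v) if v.is_snv else classify_indel(orf, seq, v)


def is_lof(c: ConsequenceClass) -> bool:
    return c in LOF_CLASSES


# ---------------------------------------------------------------------------
# Translation-comparison oracle

def _translate_from(s: str, anchor: int, strand: str) -> str:
    """Translate in reading direction from the first base of the start codon."""
    region = s[anchor:] if strand == "+" else reverse_complement(s[: anchor + 1])
    prot = []
    for i in range(0, len(region) - 2, 3):
        aa = translate_codon(region[i : i + 3])
        prot.append(aa)
        if aa == "*":
            break
    return "".join(prot)


def _map_position(p: int, g: int, removed: str, inserted: str) -> int:
    d = len(inserted) - len(removed)
    if p >= g + len(removed):
        return p + d
    if p < g:
        return p
    raise ValueError("edit destroys the mapped reference position")


def translation_oracle(
    seq: TranscriptSeq, orf: OrfAnnotation, v: VariantCall
) -> ConsequenceClass:
    """Brute-force classifier: apply the edit, re-translate, compare proteins.

    Independent of the codon-index arithmetic in :func:`classify_snv` /
    :func:`classify_indel`; used as the reference implementation in tests.
    Indels that destroy the start or stop codon itself are rejected.
    """
    if v.ref == v.alt:
        raise ValueError("identity edit")
    g, removed, inserted = normalized_edit(seq, v)
    if not _edit_is_coding(orf, g, removed, inserted):
        return ConsequenceClass.noncoding
    s = seq.sequence
    edited = s[:g] + inserted + s[g + len(removed) :]
    anchor = orf.cds_start if orf.strand == "+" else orf.cds_end - 1

    if len(removed) == 1 and len(inserted) == 1:  # substitution
        prot_ref = _translate_from(s, anchor, orf.strand)
        prot_alt = _translate_from(edited, anchor, orf.strand)
        if prot_alt == prot_ref:
            return ConsequenceClass.synonymous
        if (
            prot_alt.endswith("*")
            and len(prot_alt) < len(prot_ref)
            and prot_ref.startswith(prot_alt[:-1])
        ):
            return ConsequenceClass.stopgain
        if not prot_alt.endswith("*") or len(prot_alt) > len(prot_ref):
            return ConsequenceClass.stoploss
        return ConsequenceClass.missense

    # indel: is the original terminator still reached in frame?
    stop_first = orf.cds_end - 3 if orf.strand == "+" else orf.cds_start + 2
    anchor_new = _map_position(anchor, g, removed, inserted)
    stop_new = _map_position(stop_first, g, removed, inserted)
    dist = (stop_new - anchor_new) if orf.strand == "+" else (anchor_new - stop_new)
    if dist % 3 != 0:
        return ConsequenceClass.frameshift
    return ConsequenceClass.inframe_indel


# ---------------------------------------------------------------------------
# Per-gene collapsing

def collapse_gene_alleles(
    gene_id: str, lof_variants: Iterable[VariantCall]
) -> GeneZygosity:
    """Collapse a gene's LoF variants into a single allele state.

    Any homozygous LoF variant makes the gene hom_lof; otherwise one or more
    heterozygous LoF variants make it het_lof (unphased genotypes: multiple
    het variants are conservatively counted as one het allele).
    """
    state = "none"
    for v in lof_variants:
        if v.zygosity == "hom":
            return GeneZygosity(gene_id, "hom_lof")
        state = "het_lof"
    return GeneZygosity(gene_id, state)


def edit_overlaps_interval(
    seq: TranscriptSeq, v: VariantCall, interval: tuple[int, int]
) -> bool:
    """Whether the variant's edited bases fall inside a forward interval.

    Used for the last-100-nt NMD-escape window.  Insertions count when the
    insertion point lies strictly inside the interval.
    """
    a, b = interval
    g, removed, inserted = normalized_edit(seq, v)
    if removed:
        return g < b and g + len(removed) > a
    return a < g < b


@dataclass(frozen=True)
class GeneLoF:
    """Per-gene LoF evidence for one individual, with window/type detail.

    ``variants`` holds (lof_type, zygosity, in_window) triples where
    lof_type is one of nonsense/frameshift/stoploss.
    """

    gene_id: str
    variants: tuple[tuple[str, str, bool], ...]

    def state(self, region: str = "full_cds", variant_type: str = "all_lof") -> str:
        sel = [
            (t, z)
            for t, z, in_w in self.variants
            if (region == "full_cds" or in_w)
            and (variant_type == "all_lof" or t == variant_type)
        ]
        if any(z == "hom" for _, z in sel):
            return "hom_lof"
        if sel:
            return "het_lof"
        return "none"

    def types(self, region: str = "full_cds") -> frozenset[str]:
        return frozenset(
            t for t, _, in_w in self.variants if region == "full_cds" or in_w
        )


def gene_lof_evidence(
    lof_calls: Iterable[tuple[VariantCall, ConsequenceClass, bool]]
) -> dict[str, GeneLoF]:
    """Group classified LoF calls into per-gene evidence records.

    Input triples are (variant, consequence, in_last100_window); only LoF
    consequences are accepted.
    """
    acc: dict[str, list[tuple[str, str, bool]]] = {}
    for v, c, in_w in lof_calls:
        if not is_lof(c):
            raise ValueError(f"{v.transcript_id}:{v.pos}: {c.value} is not LoF")
        acc.setdefault(v.transcript_id, []).append(
            (LOF_TYPE_NAMES[c], v.zygosity, in_w)
        )
    return {g: GeneLoF(g, tuple(vs)) for g, vs in sorted(acc.items())}
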