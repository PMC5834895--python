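"""Open-reading-frame discovery and selection in transcript space.

Each de novo assembled contig is treated as a single transcript; the analysis
interprets variants against one coding region per transcript, chosen as the
longest complete ORF (ATG to in-frame stop) with a protein of at least 100
amino acids.  Internal coordinates are 0-based half-open on the forward
strand of the stored sequence; serialized coordinates (FASTA headers, TSV)
are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
_VALID = frozenset("ACGTN")

# An ORF: ATG, any number of codons (non-greedy, so the first in-frame stop
# wins), then a stop.  Codons containing N match the body but never the stop
# or the start, which encodes the N policy directly.  The lookahead makes
# nested/overlapping ATGs visible.
_ORF_RE = re.compile(r"(?=(ATG(?:[ACGTN]{3})*?(?:TAA|TAG|TGA)))")


@dataclass(frozen=True)
class TranscriptSeq:
    """A transcript (contig) sequence over the alphabet A, C, G, T, N."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)!r}; "
                "sequences must be uppercase A/C/G/T/N"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfAnnotation:
    """The chosen coding region of a transcript.

    ``cds_start``/``cds_end`` delimit the CDS (including the stop codon) as a
    0-based half-open interval on the forward strand of the stored sequence,
    regardless of ``strand``.  ``protein_length_aa`` counts residues from the
    initial Met up to, but excluding, the stop.
    """

    transcript_id: str
    cds_start: int
    cds_end: int
    strand: str
    protein_length_aa: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        length = self.cds_end - self.cds_start
        if length <= 0 or length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {length} not a positive multiple of 3"
            )
        if self.protein_length_aa != length // 3 - 1:
            raise ValueError(
                f"{self.transcript_id}: protein_length_aa inconsistent with CDS interval"
            )

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_forward(seq: str, min_nt: int) -> Iterable[tuple[int, int]]:
    for m in _ORF_RE.finditer(seq):
        orf = m.group(1)
        if len(orf) >= min_nt:
            yield m.start(1), m.start(1) + len(orf)


def find_orfs(seq: TranscriptSeq, min_protein_aa: int = 100) -> list[OrfAnnotation]:
    """Return every complete ORF in all six frames.

    An ORF runs from an ATG to the first in-frame stop; nested ORFs (an ATG
    inside another ORF) are reported separately.  Only ORFs whose protein
    (Met included, stop excluded) has at least ``min_protein_aa`` residues
    are returned.  Codons containing N neither start nor terminate an ORF.
    """
    if min_protein_aa < 0:
        raise ValueError("min_protein_aa must be non-negative")
    s = seq.sequence
    min_nt = 3 * (min_protein_aa + 1)
    out: list[OrfAnnotation] = []
    for a, b in _scan_forward(s, min_nt):
        out.append(
            OrfAnnotation(seq.id, a, b, "+", (b - a) // 3 - 1)
        )
    rc = reverse_complement(s)
    n = len(s)
    for a, b in _scan_forward(rc, min_nt):
        out.append(
            OrfAnnotation(seq.id, n - b, n - a, "-", (b - a) // 3 - 1)
        )
    out.sort(key=lambda o: (o.cds_start, o.cds_end, o.strand))
    return out


def select_longest_orf(orfs: list[OrfAnnotation]) -> Optional[OrfAnnotation]:
    """Pick the single ORF the analysis uses for a transcript.

    Longest protein wins; ties prefer the + strand, then the smallest
    ``cds_start``.  Returns None for an empty list.
    """
    if not orfs:
        return None
    ids = {o.transcript_id for o in orfs}
    if len(ids) > 1:
        raise ValueError(f"ORFs from multiple transcripts: {sorted(ids)}")
    return max(
        orfs,
        key=lambda o: (o.protein_length_aa, o.strand == "+", -o.cds_start),
    )


def last_n_window(orf: OrfAnnotation, n: int = 100) -> tuple[int, int]:
    """The final ``n`` nucleotides of the CDS in reading direction.

    Used as a proxy for the last exon, where nonsense-mediated decay does not
    act.  Includes the stop codon; clamped to the CDS length.  Returned as a
    0-based half-open interval on the stored (forward) sequence.
    """
    if n < 0:
        raise ValueError("window size must be non-negative")
    w = min(n, orf.cds_length)
    if orf.strand == "+":
        return orf.cds_end - w, orf.cds_end
    return orf.cds_start, orf.cds_start + w


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> list[TranscriptSeq]:
    """Read transcripts from a (possibly wrapped) FASTA file.

    Raises ``DuplicateIdError`` on repeated record IDs.
    """
    from .pipeline import DuplicateIdError  # local import avoids a cycle

    seen: set[str] = set()
    out: list[TranscriptSeq] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(TranscriptSeq(rec.id, str(rec.seq).upper()))
    return out


_HDR_ORF = re.compile(r"orf=(\d+)-(\d+);strand=([+-])")


def parse_orf_header(description: str, transcript_id: str) -> Optional[OrfAnnotation]:
    """Parse an ``orf=<start>-<end>;strand=<+|->`` FASTA description field.

    Header coordinates are 1-based inclusive; returns the 0-based half-open
    annotation, or None when the description carries no ORF tag.
    """
    m = _HDR_ORF.search(description)
    if m is None:
        return None
    start1, end1, strand = int(m.group(1)), int(m.group(2)), m.group(3)
    a, b = start1 - 1, end1
    return OrfAnnotation(transcript_id, a, b, strand, (b - a) // 3 - 1)


ORF_TABLE_COLUMNS = ["transcript_id", "cds_start", "cds_end", "strand", "protein_length_aa"]


def write_orf_table(orfs: Iterable[OrfAnnotation], path: str | Path) -> None:
    """Write the per-transcript ORF table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(ORF_TABLE_COLUMNS) + "\n")
        for o in orfs:
            fh.write(
                f"{o.transcript_id}\t{o.cds_start + 1}\t{o.cds_end}\t"
                f"{o.strand}\t{o.protein_length_aa}\n"
            )


def read_orf_table(path: str | Path) -> dict[str, OrfAnnotation]:
    out: dict[str, OrfAnnotation] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ORF_TABLE_COLUMNS:
            raise ValueError(f"unexpected ORF table header in {path}: {header}")
        for line in fh:
            tid, s1, e1, strand, plen = line.rstrip("\n").split("\t")
            out[tid] = OrfAnnotation(tid, int(s1) - 1, int(e1), strand, int(plen))
    return out
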