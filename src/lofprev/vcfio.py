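"""VCF v4.2 reading/writing in transcript coordinates.

CHROM is a transcript ID, POS is 1-based on the stored sequence.  Genotypes
are diploid (0/1 het, 1/1 hom); DP is carried in the sample column, MQ in
INFO, and the variant-calling quality in QUAL.  Reading goes through pysam;
multi-allelic records are decomposed into one call per alternate allele.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .consequence import VariantCall

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=lofprev
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    sample: str,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write calls as an uncompressed VCF v4.2 file (sorted by CHROM, POS)."""
    lines = [_VCF_HEADER]
    if contig_lengths:
        for cid in sorted(contig_lengths):
            lines.append(f"##contig=<ID={cid},length={contig_lengths[cid]}>\n")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
    for v in sorted(calls, key=lambda c: (c.transcript_id, c.pos, c.alt)):
        gt = "0/1" if v.zygosity == "het" else "1/1"
        lines.append(
            f"{v.transcript_id}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t"
            f"{v.variant_qual:.6g}\t.\tMQ={v.mapping_qual:.6g}\tGT:DP\t{gt}:{v.depth}\n"
        )
    Path(path).write_text("".join(lines))


def _zygosity_for_allele(gt: tuple, allele_index: int) -> str | None:
    alleles = [a for a in gt if a is not None]
    if allele_index not in alleles:
        return None
    return "hom" if all(a == allele_index for a in alleles) and len(alleles) == 2 else "het"


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read one individual's VCF into VariantCalls.

    Multi-allelic records are decomposed; each alternate allele carried by
    the genotype becomes one call (an allele is hom only when both genotype
    alleles match it).
    """
    calls: list[VariantCall] = []
    with warnings.catch_warnings():
        # pysam warns when contigs are declared on the fly; harmless here
        warnings.simplefilter("ignore")
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            if len(samples) != 1:
                raise ValueError(f"{path}: expected a single-sample VCF, got {samples}")
            for rec in vf:
                sample = rec.samples[samples[0]]
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                depth = sample.get("DP")
                if depth is None:
                    depth = rec.info.get("DP", 0)
                mq = rec.info.get("MQ", 0.0)
                qual = rec.qual if rec.qual is not None else 0.0
                for i, alt in enumerate(rec.alts or (), start=1):
                    zyg = _zygosity_for_allele(gt, i)
                    if zyg is None:
                        continue
                    calls.append(
                        VariantCall(
                            transcript_id=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=str(alt),
                            zygosity=zyg,
                            depth=int(depth),
                            variant_qual=float(qual),
                            mapping_qual=float(mq),
                        )
                    )
    return calls


ANNOTATED_COLUMNS = [
    "transcript_id",
    "pos",
    "ref",
    "alt",
    "zygosity",
    "class",
    "in_last100",
]


def write_annotated_variants(
    rows: Iterable[tuple[VariantCall, str, bool]], path: str | Path
) -> None:
    """Write the annotated-variant table: one row per (call, class, window flag)."""
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATED_COLUMNS) + "\n")
        for v, cls, in_w in rows:
            fh.write(
                f"{v.transcript_id}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.zygosity}\t"
                f"{cls}\t{int(in_w)}\n"
            )
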