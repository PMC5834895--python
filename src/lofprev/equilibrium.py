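"""Deterministic mutation-selection balance arithmetic.

A deleterious allele recurrently produced at rate u per gene per generation
and removed by selection of strength s against heterozygous carriers reaches
the deterministic equilibrium frequency q = u/s.  Because s for heterozygous
LoF alleles of essential genes is around 1% — far above 1/Ne in natural
populations — this equilibrium is essentially independent of drift, which is
why observed LoF prevalence can be inverted into an implied mutation rate.
"""

from __future__ import annotations

#: Typical coding length used when converting per-gene rates to per-nucleotide
#: rates; matches the generator's default gene length (~1.1 kb CDS).
DEFAULT_CDS_LENGTH_NT = 1101


def equilibrium_frequency(u: float, s: float) -> float:
    """Expected deleterious allele frequency q = u/s, clipped at 1."""
    if u < 0:
        raise ValueError("mutation rate must be non-negative")
    if u == 0:
        return 0.0
    if s <= 0:
        raise ValueError("equilibrium undefined for non-positive selection with u > 0")
    return min(1.0, u / s)


def implied_mutation_rate_per_gene(q: float, s: float) -> float:
    """Invert the equilibrium: u = q * s (per gene per generation)."""
    if not 0 <= q <= 1:
        raise ValueError("q must be a frequency in [0, 1]")
    if s <= 0:
        raise ValueError("selection coefficient must be positive")
    return q * s


def implied_mutation_rate_per_nt(
    q: float, s: float, cds_length_nt: int = DEFAULT_CDS_LENGTH_NT
) -> float:
    """Per-nucleotide LoF mutation rate implied by an observed prevalence q."""
    if cds_length_nt <= 0:
        raise ValueError("CDS length must be positive")
    return implied_mutation_rate_per_gene(q, s) / cds_length_nt


def round_sig(x: float, digits: int = 1) -> float:
    """Round to significant digits, as rates are quoted (e.g. 2e-8)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    exp = floor(log10(abs(x)))
    return round(x, -exp + digits - 1)
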