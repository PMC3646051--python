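"""Gamete enumeration for trisomic trios.

A trisomic child receives a *diploid* gamete (two alleles) from the
non-disjoining parent (NDJP) and a single allele from the correctly
disjoining parent (CDJP).  A heterozygous NDJP can transmit Aa (no
reduction), or AA / aa when the meiotic error reduces the two
chromosomes to homozygosity.  All genotypes are encoded as minor-allele
dosages: parents in {0,1,2}, trisomic children in {0,1,2,3}.
"""

from __future__ import annotations

from functools import lru_cache

__all__ = [
    "diploid_gametes",
    "haploid_alleles",
    "enumerate_trio_configs",
    "is_mendelian_consistent",
]


def diploid_gametes(dosage: int) -> tuple[int, ...]:
    """Possible minor-allele dosages of a diploid (non-disjoined) gamete.

    A homozygote has a single gamete type carrying both its alleles; a
    heterozygote yields dosage 1 without reduction to homozygosity and
    dosages 0 or 2 with it.
    """
    if dosage == 0:
        return (0,)
    if dosage == 1:
        return (0, 1, 2)
    if dosage == 2:
        return (2,)
    raise ValueError(f"parental dosage must be in {{0,1,2}}, got {dosage}")


def haploid_alleles(dosage: int) -> tuple[int, ...]:
    """Possible transmitted-allele dosages (0 or 1) of a disjoining parent."""
    if dosage == 0:
        return (0,)
    if dosage == 1:
        return (0, 1)
    if dosage == 2:
        return (1,)
    raise ValueError(f"parental dosage must be in {{0,1,2}}, got {dosage}")


@lru_cache(maxsize=None)
def enumerate_trio_configs(ndjp_dosage: int, cdjp_dosage: int) -> frozenset[int]:
    """Admissible trisomic child dosages for a given NDJP/CDJP dosage pair.

    The child dosage is gamete + allele over every combination of the
    NDJP's diploid gametes and the CDJP's transmitted alleles.
    """
    return frozenset(
        g + a
        for g in diploid_gametes(ndjp_dosage)
        for a in haploid_alleles(cdjp_dosage)
    )


def is_mendelian_consistent(ndjp_dosage: int, cdjp_dosage: int, child_dosage: int) -> bool:
    return child_dosage in enumerate_trio_configs(ndjp_dosage, cdjp_dosage)
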