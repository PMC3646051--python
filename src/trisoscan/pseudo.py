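"""Case / pseudo-control construction.

For each trio at each SNP the pseudo-control is the genotype assembled
from the alleles the parents did *not* transmit to the case.  With x
the non-disjoining parent's minor-allele dosage, y the correctly
disjoining parent's, and z1 the trisomic case's, the pseudo-control is

    z2 = 2*x + y - z1

(the NDJP contributes its untransmitted diploid gamete, the CDJP its
untransmitted allele).  Writing x for the NDJP regardless of side
unifies the maternal- and paternal-nondisjunction formulas.  For
disomic trios the standard untransmitted construction applies:
z2 = mother + father - z1.  Under no association z1 - z2 is symmetric
about zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .mendel import is_mendelian_consistent

__all__ = [
    "trisomic_pseudo",
    "disomic_pseudo",
    "build_pairs",
    "PseudoControlBuilder",
    "MendelianInconsistencyError",
]

logger = logging.getLogger(__name__)


class MendelianInconsistencyError(ValueError):
    """Raised when a case genotype is impossible given the parental pair."""


def trisomic_pseudo(x: int, y: int, z1: int) -> int:
    """Pseudo-control dosage for a trisomic trio; x is the NDJP dosage.

    z1 must be admissible given (x, y); the returned z2 = 2x + y - z1
    is then itself admissible (the construction is an involution).
    """
    if not is_mendelian_consistent(x, y, z1):
        raise MendelianInconsistencyError(
            f"case dosage {z1} impossible for NDJP dosage {x}, CDJP dosage {y}"
        )
    return 2 * x + y - z1


def disomic_pseudo(mother_dosage: int, father_dosage: int, z1: int) -> int:
    """Pseudo-control dosage for a disomic trio (untransmitted alleles)."""
    for d, who in ((mother_dosage, "mother"), (father_dosage, "father")):
        if d not in (0, 1, 2):
            raise ValueError(f"{who} dosage must be in {{0,1,2}}, got {d}")
    lo = max(0, (mother_dosage - 1)) + max(0, (father_dosage - 1))
    hi = min(1, mother_dosage) + min(1, father_dosage)
    if not lo <= z1 <= hi:
        raise MendelianInconsistencyError(
            f"case dosage {z1} impossible for parental dosages "
            f"({mother_dosage}, {father_dosage})"
        )
    return mother_dosage + father_dosage - z1


def build_pairs(trios: pd.DataFrame, on_inconsistent: str = "drop") -> pd.DataFrame:
    """One (z1, z2) pair per trio x SNP from a trio genotype table.

    ``trios`` uses the trio-table layout (see :mod:`trisoscan.io`):
    either ndjp_dosage/cdjp_dosage columns, or father_dosage/
    mother_dosage plus ndjp_side.  Rows whose case genotype is
    Mendelian-impossible for the parental pair — which unconstrained
    calling can produce — are dropped with a log entry (the default) or
    raise when ``on_inconsistent='raise'``.
    """
    if on_inconsistent not in ("drop", "raise"):
        raise ValueError("on_inconsistent must be 'drop' or 'raise'")
    df = resolve_roles(trios)
    z2 = np.empty(len(df), dtype=int)
    bad = np.zeros(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            if row.ploidy == 3:
                z2[i] = trisomic_pseudo(row.ndjp_dosage, row.cdjp_dosage, row.child_dosage)
            else:
                z2[i] = disomic_pseudo(row.mother_dosage, row.father_dosage,
                                       row.child_dosage)
        except MendelianInconsistencyError as exc:
            if on_inconsistent == "raise":
                raise MendelianInconsistencyError(
                    f"trio {row.trio_id}, SNP {row.snp_id}: {exc}"
                ) from exc
            bad[i] = True
    if bad.any():
        logger.warning("dropped %d Mendelian-inconsistent trio x SNP records", bad.sum())
    pairs = pd.DataFrame(
        {
            "trio_id": df["trio_id"].to_numpy(),
            "snp_id": df["snp_id"].to_numpy(),
            "z1": df["child_dosage"].to_numpy(),
            "z2": z2,
        }
    )
    return pairs.loc[~bad].reset_index(drop=True)


def resolve_roles(trios: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize a trio table to carry both role layouts.

    Ensures ndjp_dosage/cdjp_dosage columns exist (derived from
    father/mother + ndjp_side when needed) and, conversely, father/
    mother columns when only roles are given (disomic rows need them).
    """
    df = trios.copy()
    if "ploidy" not in df.columns:
        df["ploidy"] = 3
    has_roles = {"ndjp_dosage", "cdjp_dosage"}.issubset(df.columns)
    has_sides = {"father_dosage", "mother_dosage", "ndjp_side"}.issubset(df.columns)
    if not has_roles and not has_sides:
        raise ValueError(
            "trio table needs either ndjp_dosage/cdjp_dosage or "
            "father_dosage/mother_dosage/ndjp_side columns"
        )
    if not has_roles:
        maternal = df["ndjp_side"].to_numpy() == "maternal"
        df["ndjp_dosage"] = np.where(maternal, df["mother_dosage"], df["father_dosage"])
        df["cdjp_dosage"] = np.where(maternal, df["father_dosage"], df["mother_dosage"])
    if "mother_dosage" not in df.columns:
        if (df["ploidy"] == 2).any():
            raise ValueError("disomic rows require father_dosage/mother_dosage columns")
        # sides unknown: parental roles suffice for every trisomic statistic
        df["mother_dosage"] = df["ndjp_dosage"]
        df["father_dosage"] = df["cdjp_dosage"]
    return df


class PseudoControlBuilder(BaseEstimator, TransformerMixin):
    """Transformer facade over :func:`build_pairs` for pipeline use."""

    def __init__(self, on_inconsistent: str = "drop"):
        self.on_inconsistent = on_inconsistent

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return build_pairs(X, on_inconsistent=self.on_inconsistent)
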