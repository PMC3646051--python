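"""Nondisjunction parent-of-origin inference.

Pedigree-blind calling deliberately emits trio configurations that are
impossible under Mendelian segregation for one parental origin of the
extra chromosome but possible for the other.  A configuration with a
heterozygous mother, a homozygous father, and a child carrying two
copies of the allele the father lacks can arise genuinely only when the
mother contributed the diploid gamete (reduced to homozygosity); its
mirror image is diagnostic of paternal nondisjunction.  Comparing the
rates of the two diagnostic classes across SNPs identifies the
non-disjoining parent of each trio — nondisjunction being a single
meiotic event, one label applies to all of a trio's SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "classify_config",
    "classify_configs",
    "infer_ndjp",
    "NDJPEvidence",
    "ParentOfOriginInference",
]

logger = logging.getLogger(__name__)

MATERNAL_DIAGNOSTIC = "maternal_diagnostic"
PATERNAL_DIAGNOSTIC = "paternal_diagnostic"
NEUTRAL = "neutral"

# counts above which the exact two-proportion test falls back to chi-square
_EXACT_LIMIT = 10_000


@dataclass
class NDJPEvidence:
    """Per-trio diagnostic-configuration counts and the resulting decision.

    Denominators are SNPs with one heterozygous and one homozygous
    parent (the only configurations in which a diagnostic call can
    occur).  ``decision`` is 'undetermined' when the two-proportion
    test is not significant at ``alpha``.
    """

    trio_id: str
    n_maternal_diagnostic: int
    n_het_mother: int
    n_paternal_diagnostic: int
    n_het_father: int
    p_value: float
    decision: str


def classify_config(father_dosage: int, mother_dosage: int, child_dosage: int) -> str:
    """Classify one called trio configuration.

    maternal_diagnostic: mother heterozygous, father homozygous, child
    carrying two copies of the allele the father lacks — i.e. (f, m, z)
    in {(2,1,1), (0,1,2)}.  paternal_diagnostic is the mirror image.
    Everything else is neutral (possible under either origin).
    """
    f, m, z = father_dosage, mother_dosage, child_dosage
    if f not in (0, 1, 2) or m not in (0, 1, 2):
        raise ValueError(f"parental dosages must be in {{0,1,2}}, got f={f}, m={m}")
    if z not in (0, 1, 2, 3):
        raise ValueError(f"child dosage must be in {{0,1,2,3}}, got {z}")
    if m == 1 and f in (0, 2) and z == (1 if f == 2 else 2):
        return MATERNAL_DIAGNOSTIC
    if f == 1 and m in (0, 2) and z == (1 if m == 2 else 2):
        return PATERNAL_DIAGNOSTIC
    return NEUTRAL


def classify_configs(father: np.ndarray, mother: np.ndarray, child: np.ndarray):
    """Vectorized :func:`classify_config`; returns two boolean arrays
    (maternal_diagnostic, paternal_diagnostic)."""
    f = np.asarray(father)
    m = np.asarray(mother)
    z = np.asarray(child)
    mat = (m == 1) & ((f == 2) & (z == 1) | (f == 0) & (z == 2))
    pat = (f == 1) & ((m == 2) & (z == 1) | (m == 0) & (z == 2))
    return mat, pat


def _two_proportion_pvalue(k1: int, n1: int, k2: int, n2: int) -> float:
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if n1 + n2 <= _EXACT_LIMIT:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    res = stats.chi2_contingency(table, correction=True)
    return float(res.pvalue)


def infer_ndjp(
    father: np.ndarray,
    mother: np.ndarray,
    child: np.ndarray,
    alpha: float = 0.05,
    trio_id: str = "",
) -> NDJPEvidence:
    """Infer the non-disjoining parent of one trio from unconstrained calls.

    The maternal-diagnostic rate among het-mother/hom-father SNPs is
    compared with the paternal-diagnostic rate among het-father/
    hom-mother SNPs by a two-sided exact two-proportion test; the NDJP
    is the mother if the former is significantly greater, the father if
    significantly smaller, undetermined otherwise.  Calls must come
    from the pedigree-blind caller: family-constrained calling erases
    the diagnostic configurations.
    """
    f = np.asarray(father)
    m = np.asarray(mother)
    z = np.asarray(child)
    ok = (f >= 0) & (m >= 0) & (z >= 0)
    f, m, z = f[ok], m[ok], z[ok]
    mat, pat = classify_configs(f, m, z)
    den_m = int(np.sum((m == 1) & ((f == 0) | (f == 2))))
    den_f = int(np.sum((f == 1) & ((m == 0) | (m == 2))))
    k_m = int(mat.sum())
    k_f = int(pat.sum())
    if den_m == 0 or den_f == 0:
        logger.warning("trio %s: empty diagnostic denominator; NDJP undetermined", trio_id)
        return NDJPEvidence(trio_id, k_m, den_m, k_f, den_f, float("nan"), "undetermined")
    p = _two_proportion_pvalue(k_m, den_m, k_f, den_f)
    if p < alpha:
        decision = "maternal" if k_m / den_m > k_f / den_f else "paternal"
    else:
        decision = "undetermined"
    return NDJPEvidence(trio_id, k_m, den_m, k_f, den_f, p, decision)


class ParentOfOriginInference(BaseEstimator):
    """Parent-of-origin inference over a set of trios.

    Parameters
    ----------
    alpha : significance level of the per-trio two-proportion test.

    Attributes
    ----------
    evidence_ : list of :class:`NDJPEvidence`, one per trio.
    decisions_ : array of 'maternal' / 'paternal' / 'undetermined'.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, father: np.ndarray, mother: np.ndarray, child: np.ndarray,
            trio_ids=None):
        """``father``, ``mother``, ``child`` are (n_trios, n_snps) call matrices."""
        father = np.atleast_2d(father)
        mother = np.atleast_2d(mother)
        child = np.atleast_2d(child)
        if trio_ids is None:
            trio_ids = [f"trio{i:04d}" for i in range(father.shape[0])]
        self.evidence_ = [
            infer_ndjp(father[i], mother[i], child[i], alpha=self.alpha,
                       trio_id=str(trio_ids[i]))
            for i in range(father.shape[0])
        ]
        self.decisions_ = np.array([e.decision for e in self.evidence_])
        return self
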