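"""Genotype calling from normalized allele-intensity ratios.

Two callers are provided.  ``KMeansCaller`` clusters each individual's
ratios across SNPs into ploidy+1 one-dimensional clusters and maps them
to dosages by ascending center — pedigree-blind, so Mendelian-impossible
trio configurations can be (and deliberately are) emitted; those calls
feed the nondisjunction parent-of-origin inference.  ``TrioConstrainedCaller``
updates all three members of a family together, restricting each SNP's
(father, mother, child) assignment to configurations admissible under
the trio's known parent of origin.

SNP-level QC: an exact Hardy–Weinberg test on parental genotype counts
and a filter on the fraction of children whose two calls disagree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .mendel import enumerate_trio_configs

__all__ = [
    "normalize",
    "normalize_many",
    "KMeansCaller",
    "TrioConstrainedCaller",
    "kmeans_independent",
    "kmeans_trio",
    "discrepancy_filter",
    "hwe_exact_pvalue",
    "hwe_chisq_pvalue",
    "hwe_filter",
]

logger = logging.getLogger(__name__)

MISSING = -1


def normalize(raw) -> float:
    """Allele-A intensity ratio from the six raw probe intensities.

    ratio = mean(A-probes) / (mean(A-probes) + mean(B-probes)), so that
    noiseless clusters sit at allele fractions dosage/ploidy and the
    ratio is invariant under a common rescaling of all probes.  The
    first half of ``raw`` are A-probes, the second half B-probes (or
    pass a (2, k) array).  Zero total intensity yields NaN (missing).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        if raw.size % 2:
            raise ValueError("expected an even number of probe intensities")
        raw = raw.reshape(2, -1)
    if np.any(raw < 0):
        raise ValueError("probe intensities must be non-negative")
    mean_a = raw[0].mean()
    mean_b = raw[1].mean()
    total = mean_a + mean_b
    if total <= 0:
        logger.warning("zero total intensity; ratio set to missing")
        return float("nan")
    return float(mean_a / total)


def normalize_many(raw: np.ndarray) -> np.ndarray:
    """Vectorized ``normalize`` over an array of shape (..., 2, k)."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("probe intensities must be non-negative")
    means = raw.mean(axis=-1)            # (..., 2)
    total = means.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, means[..., 0] / total, np.nan)
    n_zero = int(np.sum(total <= 0))
    if n_zero:
        logger.warning("%d observations with zero total intensity set to missing", n_zero)
    return ratio


def _canonical_centers(ploidy: int) -> np.ndarray:
    return np.arange(ploidy + 1) / ploidy


def _kmeans_1d(values: np.ndarray, centers: np.ndarray, max_iter: int = 100):
    """Lloyd's algorithm in 1-D with fixed initial centers.

    Ties go to the lower dosage; empty clusters keep their previous
    center (so monomorphic SNP sets converge sensibly).
    """
    labels = np.full(values.shape, MISSING, dtype=int)
    centers = centers.astype(float).copy()
    ok = np.isfinite(values)
    v = values[ok]
    lab = np.zeros(v.shape, dtype=int)
    for it in range(max_iter):
        d = np.abs(v[:, None] - centers[None, :])
        new_lab = np.argmin(d, axis=1)  # argmin takes the first (lowest dosage) on ties
        if it > 0 and np.array_equal(new_lab, lab):
            break
        lab = new_lab
        for j in range(centers.size):
            sel = lab == j
            if sel.any():
                centers[j] = v[sel].mean()
    labels[ok] = lab
    return labels, centers


class KMeansCaller(BaseEstimator):
    """Pedigree-blind genotype caller: per-individual 1-D K-means.

    Each individual's ratios across SNPs are clustered into ploidy+1
    groups initialized at the canonical allele fractions (0, 1/2, 1) or
    (0, 1/3, 2/3, 1); clusters map to dosages by ascending center.

    Parameters
    ----------
    ploidy : 2 for disomic individuals, 3 for trisomic children.
    max_iter : Lloyd iteration cap per individual.

    Attributes
    ----------
    calls_ : (n_individuals, n_snps) int dosages, -1 for missing.
    centers_ : (n_individuals, ploidy+1) fitted cluster centers.
    """

    def __init__(self, ploidy: int = 3, max_iter: int = 100):
        self.ploidy = ploidy
        self.max_iter = max_iter

    def fit(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.ploidy not in (2, 3):
            raise ValueError(f"ploidy must be 2 or 3, got {self.ploidy!r}")
        k = self.ploidy + 1
        init = _canonical_centers(self.ploidy)
        calls = np.full(X.shape, MISSING, dtype=int)
        centers = np.tile(init, (X.shape[0], 1))
        for i, row in enumerate(X):
            finite = row[np.isfinite(row)]
            if np.unique(finite).size < k:
                logger.warning(
                    "individual %d has fewer than %d distinct ratios; all calls missing",
                    i, k,
                )
                continue
            calls[i], centers[i] = _kmeans_1d(row, init, self.max_iter)
        self.calls_ = calls
        self.centers_ = centers
        return self

    def fit_predict(self, X):
        return self.fit(X).calls_


# admissible (father, mother, child) triples given the NDJP side,
# ordered lowest-dosage-first so cost ties break toward lower dosages
def _admissible_triples(ndjp_side: str) -> np.ndarray:
    triples = []
    for f in range(3):
        for m in range(3):
            x, y = (m, f) if ndjp_side == "maternal" else (f, m)
            for z in sorted(enumerate_trio_configs(x, y)):
                triples.append((f, m, z))
    return np.array(sorted(triples), dtype=int)


class TrioConstrainedCaller(BaseEstimator):
    """Family-based genotype caller for one trio across SNPs.

    Iterates between (1) assigning each SNP the admissible
    (father, mother, child) dosage configuration — admissibility per the
    trio's parent of origin — that minimizes the summed squared distance
    of the three members' ratios to their current per-dosage centers,
    and (2) recomputing each member's centers as the means of the ratios
    assigned to each dosage.  Parents are disomic (3 centers), the child
    trisomic (4 centers); centers start at the canonical fractions and
    empty dosage classes keep their previous center.

    Attributes
    ----------
    calls_ : (3, n_snps) int dosages, rows = father, mother, child.
    centers_ : list of 3 center arrays (father, mother, child).
    converged_ : False if the assignment was still changing at max_iter.
    """

    def __init__(self, ndjp_side: str = "maternal", max_iter: int = 100):
        self.ndjp_side = ndjp_side
        self.max_iter = max_iter

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != 3:
            raise ValueError("expected a (3, n_snps) ratio matrix: father, mother, child")
        if self.ndjp_side not in ("maternal", "paternal"):
            raise ValueError(f"ndjp_side must be 'maternal' or 'paternal', got {self.ndjp_side!r}")
        triples = _admissible_triples(self.ndjp_side)
        centers = [
            _canonical_centers(2).copy(),
            _canonical_centers(2).copy(),
            _canonical_centers(3).copy(),
        ]
        ok = np.all(np.isfinite(X), axis=0)
        assign = np.zeros(X.shape[1], dtype=int)  # index into triples
        converged = False
        for it in range(self.max_iter):
            cost = np.zeros((len(triples), X.shape[1]))
            for member in range(3):
                member_cost = (X[member][None, :] - centers[member][:, None]) ** 2
                cost += member_cost[triples[:, member]]
            new_assign = np.argmin(cost, axis=0)
            if it > 0 and np.array_equal(new_assign, assign):
                converged = True
                break
            assign = new_assign
            dosages = triples[assign].T  # (3, n_snps)
            for member in range(3):
                for d in range(centers[member].size):
                    sel = ok & (dosages[member] == d)
                    if sel.any():
                        centers[member][d] = X[member][sel].mean()
        if not converged:
            warnings.warn("trio-constrained calling did not converge; returning last iterate")
        calls = triples[assign].T.copy()
        calls[:, ~ok] = MISSING
        self.calls_ = calls
        self.centers_ = centers
        self.converged_ = converged
        self.triples_ = triples
        return self

    def fit_predict(self, X):
        return self.fit(X).calls_


def kmeans_independent(ratios: np.ndarray, ploidy: int = 3, max_iter: int = 100) -> np.ndarray:
    """Functional wrapper over :class:`KMeansCaller`."""
    return KMeansCaller(ploidy=ploidy, max_iter=max_iter).fit_predict(ratios)


def kmeans_trio(ratios: np.ndarray, ndjp_side: str = "maternal", max_iter: int = 100) -> np.ndarray:
    """Functional wrapper over :class:`TrioConstrainedCaller`."""
    return TrioConstrainedCaller(ndjp_side=ndjp_side, max_iter=max_iter).fit_predict(ratios)


@dataclass
class FilterResult:
    kept: np.ndarray         # boolean per SNP
    stat: np.ndarray         # n_discrepant or HWE p per SNP


def discrepancy_filter(
    calls_independent: np.ndarray,
    calls_trio: np.ndarray,
    n_trios: int,
    max_fraction: float = 0.25,
) -> FilterResult:
    """Discard SNPs where the two callers disagree in too many children.

    Both inputs are (n_children, n_snps) dosage matrices.  A SNP is
    discarded when the number of children whose calls differ exceeds
    max_fraction * n_trios (for 26 trios: more than 6.5, i.e. >= 7
    discordant children).  Missing calls count as non-discrepant.
    """
    a = np.asarray(calls_independent)
    b = np.asarray(calls_trio)
    if a.shape != b.shape:
        raise ValueError("call matrices must have the same shape")
    observed = (a != MISSING) & (b != MISSING)
    n_missing = int(np.sum(~observed))
    if n_missing:
        logger.info("%d missing child calls counted as non-discrepant", n_missing)
    n_disc = np.sum((a != b) & observed, axis=0)
    kept = n_disc <= max_fraction * n_trios
    return FilterResult(kept=kept, stat=n_disc)


def hwe_exact_pvalue(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy–Weinberg test, two-sided by probability mass.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the probabilities of all outcomes no more
    likely than the observed one.  Monomorphic SNPs return p = 1.
    """
    for c in (n_hom_minor, n_het, n_hom_major):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom_minor + n_het + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n == 0 or n_minor == 0 or n_major == 0:
        return 1.0
    rare = min(n_minor, n_major)
    hets = np.arange(rare % 2, rare + 1, 2)
    # P(het = h | allele counts) via the exact conditional distribution
    logp = (
        gammaln(n + 1)
        - gammaln((n_minor - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_major - hets) / 2 + 1)
        + hets * np.log(2)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq_pvalue(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """One-degree-of-freedom chi-square Hardy–Weinberg test (no continuity correction)."""
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    p = (2 * n_hom_minor + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_hom_minor, n_het, n_hom_major], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(stat, df=1))


def hwe_filter(
    counts: np.ndarray | pd.DataFrame,
    alpha: float = 1e-4,
    method: str = "exact",
) -> FilterResult:
    """Keep SNPs whose parental genotype counts are compatible with HWE.

    ``counts`` holds one row per SNP: (n_hom_minor, n_het, n_hom_major).
    SNPs with p < alpha are discarded.
    """
    arr = np.asarray(counts, dtype=int)
    if arr.ndim == 1:
        arr = arr[None, :]
    test = {"exact": hwe_exact_pvalue, "chisq": hwe_chisq_pvalue}[method]
    pvals = np.array([test(*row) for row in arr])
    return FilterResult(kept=pvals >= alpha, stat=pvals)
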