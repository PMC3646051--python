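"""Per-SNP association testing on case / pseudo-control pairs.

The association statistic is a two-sided Wilcoxon signed-rank test on
the paired dosage differences d = z1 - z2 (zero differences dropped,
mid-ranks for ties; normal approximation with tie-corrected variance
n(n+1)(2n+1)/24 - sum(t^3 - t)/48 and a 0.5 continuity correction
whenever ties or zeros occur, the exact null distribution otherwise).
Transmission counts T/U of minor alleles transmitted/untransmitted
from heterozygous parents follow from the identities T + U = S and
T - U = sum(d), where S counts one informative transmission per
heterozygous CDJP and two per heterozygous NDJP.  Odds ratios and 95%
confidence intervals use the transmission-count formulas
OR = T/U, CI = exp(ln(T/U) +/- 1.96*sqrt(1/T + 1/U)).  Family-wise
error over a scan is controlled by min-p permutation: a fair coin per
trio swaps case and pseudo-control at all SNPs simultaneously,
preserving inter-SNP correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .pseudo import build_pairs, resolve_roles

__all__ = [
    "WilcoxonResult",
    "wilcoxon_paired",
    "transmission_counts",
    "kazeem_farrall",
    "minor_allele_frequency",
    "AssociationScan",
    "scan",
    "permutation_adjust",
]

logger = logging.getLogger(__name__)


@dataclass
class WilcoxonResult:
    p_value: float
    v_statistic: float       # sum of ranks of positive differences
    n_nonzero: int


def wilcoxon_paired(z1, z2=None) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired dosages.

    Pass (z1, z2) or a precomputed difference vector.  All-zero
    differences give p = 1 by convention (no informative pair).
    """
    z1 = np.asarray(z1, dtype=float)
    d = z1 if z2 is None else z1 - np.asarray(z2, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one pair")
    nz = d[d != 0]
    if nz.size == 0:
        logger.info("all case/pseudo-control differences zero; p = 1")
        return WilcoxonResult(1.0, 0.0, 0)
    ranks = stats.rankdata(np.abs(nz))
    v_pos = float(ranks[nz > 0].sum())
    has_ties = np.unique(np.abs(nz)).size < nz.size
    has_zeros = nz.size < d.size
    method = "approx" if (has_ties or has_zeros) else "exact"
    res = stats.wilcoxon(nz, zero_method="wilcox", correction=True, method=method)
    return WilcoxonResult(float(res.pvalue), v_pos, int(nz.size))


def transmission_counts(ndjp, cdjp, z1, z2, ploidy: int = 3) -> tuple[int, int]:
    """Minor alleles transmitted (T) / untransmitted (U) from heterozygous parents.

    Uses the decomposition-free identities T + U = S and T - U = sum(z1 - z2),
    where S = #het CDJP + 2 * #het NDJP for trisomic trios (a heterozygous
    NDJP transmits a two-allele gamete) and S = #het parents for disomic
    trios (pass the two parents as ndjp/cdjp; order is immaterial).
    """
    ndjp = np.asarray(ndjp)
    cdjp = np.asarray(cdjp)
    d = np.asarray(z1) - np.asarray(z2)
    if ploidy == 3:
        s = int(np.sum(cdjp == 1) + 2 * np.sum(ndjp == 1))
    elif ploidy == 2:
        s = int(np.sum(cdjp == 1) + np.sum(ndjp == 1))
    else:
        raise ValueError(f"ploidy must be 2 or 3, got {ploidy!r}")
    dd = int(d.sum())
    if (s + dd) % 2:
        raise ValueError(
            "transmission identity violated (S + sum(d) odd); "
            "input is not Mendelian-consistent"
        )
    t = (s + dd) // 2
    u = (s - dd) // 2
    if t < 0 or u < 0:
        raise ValueError("negative transmission count; input is not Mendelian-consistent")
    return t, u


def kazeem_farrall(t: int, u: int) -> tuple[float, float, float]:
    """Transmission odds ratio with 95% CI from T/U counts.

    OR = T/U; CI = exp(ln(T/U) +/- 1.96*sqrt(1/T + 1/U)).  A zero count
    gives a degenerate estimate (0 or inf) with an undefined interval.
    """
    if t < 0 or u < 0:
        raise ValueError("transmission counts must be non-negative")
    if t == 0 and u == 0:
        return float("nan"), float("nan"), float("nan")
    if t == 0:
        return 0.0, float("nan"), float("nan")
    if u == 0:
        return float("inf"), float("nan"), float("nan")
    log_or = math.log(t / u)
    half = 1.96 * math.sqrt(1 / t + 1 / u)
    return t / u, math.exp(log_or - half), math.exp(log_or + half)


def minor_allele_frequency(dosages, ploidy: int) -> float:
    """Minor-allele frequency: sum of dosages over ploidy * n alleles."""
    dosages = np.asarray(dosages, dtype=float)
    dosages = dosages[np.isfinite(dosages)]
    if dosages.size == 0:
        return float("nan")
    if dosages.max() > ploidy or dosages.min() < 0:
        raise ValueError(f"dosage outside [0, {ploidy}]")
    return float(dosages.sum() / (ploidy * dosages.size))


def _pivot_pairs(pairs: pd.DataFrame):
    """Wide (n_trios, n_snps) z1/z2 matrices, NaN where a pair was dropped."""
    z1 = pairs.pivot(index="trio_id", columns="snp_id", values="z1")
    z2 = pairs.pivot(index="trio_id", columns="snp_id", values="z2")
    z2 = z2.reindex(index=z1.index, columns=z1.columns)
    return z1.to_numpy(dtype=float), z2.to_numpy(dtype=float), list(z1.columns)


def _nominal_pvalues(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    p = np.empty(z1.shape[1])
    for j in range(z1.shape[1]):
        ok = np.isfinite(z1[:, j]) & np.isfinite(z2[:, j])
        p[j] = wilcoxon_paired(z1[ok, j], z2[ok, j]).p_value if ok.any() else np.nan
    return p


def permutation_adjust(
    z1: np.ndarray,
    z2: np.ndarray,
    p_nominal: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Min-p permutation-adjusted p-values.

    Each permutation flips a fair coin per trio and swaps (z1, z2) at
    every SNP of that trio simultaneously; the chromosome-wide minimum
    nominal p of each permutation is compared with each SNP's observed
    p: p_adj = (1 + #{b : minp_b <= p_obs}) / (B + 1), computed
    streaming (no B x S matrix) and clipped from below at the nominal p
    so adjusted values are never anti-conservative relative to nominal.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    p_nominal = np.asarray(p_nominal, dtype=float)
    count = np.zeros_like(p_nominal)
    n_trios = z1.shape[0]
    for _ in range(n_permutations):
        flip = rng.random(n_trios) < 0.5
        z1p = np.where(flip[:, None], z2, z1)
        z2p = np.where(flip[:, None], z1, z2)
        minp = np.nanmin(_nominal_pvalues(z1p, z2p))
        count += minp <= p_nominal
    adjusted = (1.0 + count) / (n_permutations + 1.0)
    return np.maximum(adjusted, p_nominal)


class AssociationScan(BaseEstimator):
    """Per-SNP case/pseudo-control association scan over a trio table.

    Parameters
    ----------
    permutations : number of min-p permutations for family-wise
        adjustment; 0 skips adjustment (p_adjusted is NaN).
    random_state : seed for the permutation coin flips (required when
        permutations > 0; recorded in ``results_.attrs['seed']``).
    on_inconsistent : 'drop' (default) or 'raise' for Mendelian-
        impossible case genotypes.

    Attributes
    ----------
    results_ : DataFrame, one row per SNP — n_pairs, p_nominal, T, U,
        or_hat, ci_low/ci_high, maf_cases, maf_pseudos, p_adjusted, flag.
    pairs_ : the (trio_id, snp_id, z1, z2) pair table used.
    """

    def __init__(self, permutations: int = 0, random_state: int | None = None,
                 on_inconsistent: str = "drop"):
        self.permutations = permutations
        self.random_state = random_state
        self.on_inconsistent = on_inconsistent

    def fit(self, trios: pd.DataFrame):
        df = resolve_roles(trios)
        pairs = build_pairs(df, on_inconsistent=self.on_inconsistent)
        self.pairs_ = pairs
        merged = pairs.merge(
            df, on=["trio_id", "snp_id"], how="left", validate="one_to_one"
        )
        rows = []
        order_cols = [c for c in ("position", "snp_id") if c in df.columns]
        for snp_id, grp in merged.groupby("snp_id", sort=True):
            rows.append(self._one_snp(snp_id, grp))
        results = pd.DataFrame(rows)
        if not results.empty and order_cols:
            results = results.sort_values(order_cols, kind="stable").reset_index(drop=True)
        if self.permutations > 0 and not results.empty:
            if self.random_state is None:
                raise ValueError("random_state is required when permutations > 0")
            rng = np.random.default_rng(self.random_state)
            z1, z2, snp_order = _pivot_pairs(pairs)
            p_nom = results.set_index("snp_id").loc[snp_order, "p_nominal"].to_numpy()
            p_adj = permutation_adjust(z1, z2, p_nom, self.permutations, rng)
            adj = pd.Series(p_adj, index=snp_order)
            results["p_adjusted"] = results["snp_id"].map(adj)
            results.attrs["seed"] = self.random_state
        else:
            results["p_adjusted"] = np.nan
        self.results_ = results
        return self

    @staticmethod
    def _one_snp(snp_id: str, grp: pd.DataFrame) -> dict:
        ploidy = int(grp["ploidy"].iloc[0])
        out = {
            "snp_id": snp_id,
            "position": grp["position"].iloc[0] if "position" in grp else np.nan,
            "minor_allele": grp["minor_allele"].iloc[0] if "minor_allele" in grp else "",
            "major_allele": grp["major_allele"].iloc[0] if "major_allele" in grp else "",
            "n_pairs": len(grp),
            "n_het_parents": 0,
            "p_nominal": np.nan, "v_statistic": np.nan, "T": np.nan, "U": np.nan,
            "or_hat": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "maf_cases": np.nan, "maf_pseudos": np.nan, "flag": "",
        }
        try:
            wres = wilcoxon_paired(grp["z1"].to_numpy(), grp["z2"].to_numpy())
            out["p_nominal"] = wres.p_value
            out["v_statistic"] = wres.v_statistic
            if ploidy == 3:
                out["n_het_parents"] = int(
                    (grp["ndjp_dosage"] == 1).sum() + (grp["cdjp_dosage"] == 1).sum()
                )
                t, u = transmission_counts(
                    grp["ndjp_dosage"], grp["cdjp_dosage"],
                    grp["z1"], grp["z2"], ploidy=3,
                )
            else:
                out["n_het_parents"] = int(
                    (grp["mother_dosage"] == 1).sum() + (grp["father_dosage"] == 1).sum()
                )
                t, u = transmission_counts(
                    grp["mother_dosage"], grp["father_dosage"],
                    grp["z1"], grp["z2"], ploidy=2,
                )
            out["T"], out["U"] = t, u
            or_hat, lo, hi = kazeem_farrall(t, u)
            out["or_hat"], out["ci_low"], out["ci_high"] = or_hat, lo, hi
            if t == 0 or u == 0:
                out["flag"] = "degenerate_or"
            out["maf_cases"] = minor_allele_frequency(grp["z1"], ploidy)
            out["maf_pseudos"] = minor_allele_frequency(grp["z2"], ploidy)
        except (ValueError, KeyError) as exc:
            out["flag"] = f"error: {exc}"
            logger.error("SNP %s failed: %s", snp_id, exc)
        return out


def scan(trios: pd.DataFrame, permutations: int = 0,
         random_state: int | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`AssociationScan`; returns ``results_``."""
    return AssociationScan(
        permutations=permutations, random_state=random_state
    ).fit(trios).results_
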