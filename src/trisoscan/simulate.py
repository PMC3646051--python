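"""Synthetic trisomic-trio generator.

Emulates a SNP-array study of trios with a trisomic child: parents are
drawn under Hardy–Weinberg equilibrium at given minor-allele
frequencies, one parent per trio undergoes nondisjunction (a single
meiotic event, so the same parent at every SNP), heterozygous
non-disjoining parents are optionally reduced to homozygosity, the
child is ascertained as a case under a multiplicative per-allele
disease risk, and raw probe intensities are generated around
allele-ratio cluster means with Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mendel import enumerate_trio_configs

__all__ = [
    "SimConfig",
    "SimulatedTrioSet",
    "simulate_parents",
    "simulate_trisomic_child",
    "ascertain_cases",
    "simulate_trio_dataset",
    "simulate_intensities",
]

_MAX_REJECTION_ROUNDS = 10_000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the trio simulator.

    Defaults mirror the design the analysis targets: 26 case triads
    with a trisomic (ploidy-3) child, common variants, nondisjunction
    almost always maternal, and a 50% chance that a heterozygous
    non-disjoining parent's diploid gamete is reduced to homozygosity.
    """

    n_trios: int = 26
    n_snps: int = 100
    maf: float | np.ndarray = 0.3
    maternal_ndj_prob: float = 25 / 26
    reduction_prob: float = 0.5
    relative_risk: float = 1.0
    causal_index: int | None = None
    intensity_sigma: float = 0.03
    n_probes_per_allele: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.n_trios, (int, np.integer)) and self.n_trios > 0):
            raise ValueError(f"n_trios must be a positive integer, got {self.n_trios!r}")
        if not (isinstance(self.n_snps, (int, np.integer)) and self.n_snps > 0):
            raise ValueError(f"n_snps must be a positive integer, got {self.n_snps!r}")
        maf = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if maf.size not in (1, self.n_snps):
            raise ValueError("maf must be a scalar or one value per SNP")
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf!r}")
        for name in ("maternal_ndj_prob", "reduction_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.relative_risk < 0:
            raise ValueError(f"relative_risk must be >= 0, got {self.relative_risk!r}")
        if self.causal_index is not None and not 0 <= self.causal_index < self.n_snps:
            raise ValueError(f"causal_index out of range, got {self.causal_index!r}")
        if self.intensity_sigma < 0:
            raise ValueError(f"intensity_sigma must be >= 0, got {self.intensity_sigma!r}")
        if self.n_probes_per_allele < 1:
            raise ValueError(
                f"n_probes_per_allele must be >= 1, got {self.n_probes_per_allele!r}"
            )

    @property
    def maf_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.maf, dtype=float)), (self.n_snps,)
        ).copy()


@dataclass
class SimulatedTrioSet:
    """Arrays of shape (n_trios, n_snps), minor-allele dosage encoded.

    ``true_ndjp`` holds the simulated parent of origin per trio and
    ``true_gamete`` the diploid gamete the NDJP actually transmitted,
    so that child = gamete + CDJP allele at every SNP.
    """

    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    true_ndjp: np.ndarray          # per-trio label, "maternal" | "paternal"
    true_gamete: np.ndarray        # (n_trios, n_snps) NDJP gamete dosage
    config: SimConfig
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.snp_ids:
            self.snp_ids = [f"snp{j:05d}" for j in range(self.father.shape[1])]

    @property
    def n_trios(self) -> int:
        return self.father.shape[0]

    @property
    def n_snps(self) -> int:
        return self.father.shape[1]

    @property
    def ndjp_dosage(self) -> np.ndarray:
        maternal = self.true_ndjp == "maternal"
        return np.where(maternal[:, None], self.mother, self.father)

    @property
    def cdjp_dosage(self) -> np.ndarray:
        maternal = self.true_ndjp == "maternal"
        return np.where(maternal[:, None], self.father, self.mother)

    def to_frame(self) -> pd.DataFrame:
        """Long trio-table layout (one row per trio x SNP)."""
        n, s = self.n_trios, self.n_snps
        return pd.DataFrame(
            {
                "trio_id": np.repeat([f"trio{i:04d}" for i in range(n)], s),
                "snp_id": np.tile(self.snp_ids, n),
                "position": np.tile(np.arange(1, s + 1) * 1000, n),
                "minor_allele": "A",
                "major_allele": "B",
                "father_dosage": self.father.ravel(),
                "mother_dosage": self.mother.ravel(),
                "ndjp_side": np.repeat(self.true_ndjp, s),
                "child_dosage": self.child.ravel(),
                "ploidy": 3,
            }
        )


def simulate_parents(config: SimConfig, rng: np.random.Generator | None = None,
                     n_trios: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (father, mother) dosage matrices under HWE and linkage equilibrium.

    Each parental dosage is Binomial(2, maf) independently per SNP.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trios if n_trios is None else n_trios
    maf = config.maf_array
    father = rng.binomial(2, maf, size=(n, config.n_snps))
    mother = rng.binomial(2, maf, size=(n, config.n_snps))
    return father, mother


def simulate_trisomic_child(
    ndjp_dosage: np.ndarray,
    cdjp_dosage: np.ndarray,
    reduction_prob: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Form trisomic children from one NDJP gamete plus one CDJP allele.

    A heterozygous NDJP transmits both chromosomes (gamete dosage 1)
    unless reduced to homozygosity, in which case it transmits AA or aa
    with equal probability; homozygotes have a single gamete type whose
    dosage equals the parental dosage.  Returns (child, gamete).
    """
    ndjp = np.asarray(ndjp_dosage)
    cdjp = np.asarray(cdjp_dosage)
    for arr, who in ((ndjp, "NDJP"), (cdjp, "CDJP")):
        if arr.min() < 0 or arr.max() > 2:
            raise ValueError(f"{who} dosages must lie in {{0,1,2}}")
    if not 0.0 <= reduction_prob <= 1.0:
        raise ValueError(f"reduction_prob must lie in [0, 1], got {reduction_prob!r}")

    gamete = ndjp.copy()
    het = ndjp == 1
    reduced = het & (rng.random(ndjp.shape) < reduction_prob)
    # reduced heterozygote: AA or aa, equally likely
    gamete[reduced] = 2 * rng.integers(0, 2, size=int(reduced.sum()))

    allele = np.zeros_like(cdjp)
    allele[cdjp == 2] = 1
    het_c = cdjp == 1
    allele[het_c] = rng.integers(0, 2, size=int(het_c.sum()))
    return gamete + allele, gamete


def _simulate_batch(config: SimConfig, rng: np.random.Generator,
                    n: int) -> SimulatedTrioSet:
    father, mother = simulate_parents(config, rng, n_trios=n)
    maternal = rng.random(n) < config.maternal_ndj_prob
    ndjp_label = np.where(maternal, "maternal", "paternal")
    ndjp = np.where(maternal[:, None], mother, father)
    cdjp = np.where(maternal[:, None], father, mother)
    child, gamete = simulate_trisomic_child(ndjp, cdjp, config.reduction_prob, rng)
    return SimulatedTrioSet(father, mother, child, ndjp_label, gamete, config)


def ascertain_cases(
    trio_set: SimulatedTrioSet,
    causal_index: int,
    relative_risk: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask of trios retained as cases by rejection sampling.

    Acceptance probability is relative_risk**z / max_z relative_risk**z
    with z the child dosage at the causal SNP — the exact conditional
    retention under a multiplicative per-allele risk model.
    """
    if relative_risk < 0:
        raise ValueError(f"relative_risk must be >= 0, got {relative_risk!r}")
    z = trio_set.child[:, causal_index].astype(float)
    rr = float(relative_risk)
    if rr == 0.0:
        accept_prob = (z == 0).astype(float)
    else:
        logw = z * np.log(rr)
        accept_prob = np.exp(logw - max(0.0, 3 * np.log(rr)))
    return rng.random(trio_set.n_trios) < accept_prob


def simulate_trio_dataset(config: SimConfig) -> SimulatedTrioSet:
    """Simulate a full case-trio dataset under the configured conditions.

    Under a non-null disease model (relative_risk != 1 with a causal
    SNP) trios are generated in rounds and case-ascertained until
    exactly ``n_trios`` are retained.
    """
    rng = np.random.default_rng(config.seed)
    if config.causal_index is None or config.relative_risk == 1.0:
        return _simulate_batch(config, rng, config.n_trios)

    kept: list[SimulatedTrioSet] = []
    kept_n = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        batch = _simulate_batch(config, rng, config.n_trios)
        mask = ascertain_cases(batch, config.causal_index, config.relative_risk, rng)
        if mask.any():
            kept.append(
                SimulatedTrioSet(
                    batch.father[mask], batch.mother[mask], batch.child[mask],
                    batch.true_ndjp[mask], batch.true_gamete[mask], config,
                )
            )
            kept_n += int(mask.sum())
        if kept_n >= config.n_trios:
            break
    else:
        raise RuntimeError(
            "case ascertainment did not retain enough trios after "
            f"{_MAX_REJECTION_ROUNDS} rounds (relative_risk={config.relative_risk})"
        )
    father = np.concatenate([b.father for b in kept])[: config.n_trios]
    mother = np.concatenate([b.mother for b in kept])[: config.n_trios]
    child = np.concatenate([b.child for b in kept])[: config.n_trios]
    ndjp = np.concatenate([b.true_ndjp for b in kept])[: config.n_trios]
    gamete = np.concatenate([b.true_gamete for b in kept])[: config.n_trios]
    return SimulatedTrioSet(father, mother, child, ndjp, gamete, config)


def simulate_intensities(
    dosages: np.ndarray,
    ploidy: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raw probe intensities whose normalized allele ratio is noisy dosage/ploidy.

    Returns an array of shape dosages.shape + (2, n_probes_per_allele):
    axis -2 indexes the two alleles (A then B).  The A-allele ratio
    mean(A)/(mean(A)+mean(B)) equals dosage/ploidy plus Gaussian noise
    of sd ``intensity_sigma``, truncated to [0, 1]; the overall probe
    scale varies per observation so callers must be scale-invariant.
    """
    if ploidy not in (2, 3):
        raise ValueError(f"ploidy must be 2 or 3, got {ploidy!r}")
    dosages = np.asarray(dosages)
    if dosages.min() < 0 or dosages.max() > ploidy:
        raise ValueError(f"dosage exceeds ploidy {ploidy}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ratio = dosages / ploidy + config.intensity_sigma * rng.standard_normal(dosages.shape)
    ratio = np.clip(ratio, 0.0, 1.0)
    scale = rng.uniform(800.0, 1200.0, size=dosages.shape)
    k = config.n_probes_per_allele
    raw = np.empty(dosages.shape + (2, k))
    raw[..., 0, :] = (ratio * scale)[..., None]
    raw[..., 1, :] = ((1.0 - ratio) * scale)[..., None]
    return raw
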