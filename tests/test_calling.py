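"""Intensity normalization, K-means callers, and SNP-level QC filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisoscan.calling import (
    MISSING,
    KMeansCaller,
    TrioConstrainedCaller,
    discrepancy_filter,
    hwe_chisq_pvalue,
    hwe_exact_pvalue,
    hwe_filter,
    kmeans_independent,
    normalize,
    normalize_many,
)
from trisoscan.mendel import enumerate_trio_configs
from trisoscan.simulate import SimConfig, simulate_intensities, simulate_trio_dataset


class TestNormalize:
    def test_all_signal_on_one_allele(self):
        assert normalize([2, 2, 2, 0, 0, 0]) == 1.0

    def test_symmetric_input_is_half(self):
        assert normalize([1, 1, 1, 1, 1, 1]) == 0.5
        assert normalize([5, 5, 5, 5, 5, 5]) == 0.5

    def test_zero_total_is_missing(self):
        assert np.isnan(normalize([0, 0, 0, 0, 0, 0]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize([1, 1, -1, 1, 1, 1])

    @settings(derandomize=True, max_examples=50)
    @given(
        probes=st.lists(st.floats(0.01, 1e4), min_size=6, max_size=6),
        scale=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, probes, scale):
        r1 = normalize(probes)
        r2 = normalize([p * scale for p in probes])
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_vectorized_matches_scalar(self, rng):
        raw = rng.uniform(0, 100, size=(20, 2, 3))
        many = normalize_many(raw)
        each = [normalize(r.ravel()) for r in raw]
        np.testing.assert_allclose(many, each)


class TestIndependentCaller:
    def test_noiseless_trisomic_exact(self):
        ratios = np.array([0, 1 / 3, 2 / 3, 1, 1 / 3, 0, 1, 2 / 3] * 3)
        assert np.array_equal(
            kmeans_independent(ratios, ploidy=3)[0],
            np.array([0, 1, 2, 3, 1, 0, 3, 2] * 3),
        )

    def test_noiseless_disomic_exact(self):
        ratios = np.array([0, 0.5, 1, 0.5, 0, 1] * 2)
        assert np.array_equal(
            kmeans_independent(ratios, ploidy=2)[0],
            np.array([0, 1, 2, 1, 0, 2] * 2),
        )

    def test_too_few_distinct_values_all_missing(self):
        calls = kmeans_independent(np.full(30, 0.5), ploidy=3)
        assert np.all(calls == MISSING)

    def test_high_concordance_on_noisy_simulation(self):
        cfg = SimConfig(n_trios=4, n_snps=1000, maf=0.3, intensity_sigma=0.03, seed=21)
        ds = simulate_trio_dataset(cfg)
        rng = np.random.default_rng(22)
        ratios = normalize_many(simulate_intensities(ds.child, 3, cfg, rng))
        calls = KMeansCaller(ploidy=3).fit_predict(ratios)
        assert (calls == ds.child).mean() >= 0.99

    def test_sklearn_param_interface(self):
        est = KMeansCaller(ploidy=2)
        assert est.get_params() == {"ploidy": 2, "max_iter": 100}
        est.set_params(ploidy=3)
        assert est.ploidy == 3


class TestTrioConstrainedCaller:
    def _ratios(self, dosages, ploidy):
        return np.asarray(dosages) / ploidy

    def test_noiseless_matches_independent(self):
        cfg = SimConfig(n_trios=1, n_snps=300, maf=0.4, maternal_ndj_prob=1.0, seed=23)
        ds = simulate_trio_dataset(cfg)
        R = np.vstack([
            self._ratios(ds.father[0], 2),
            self._ratios(ds.mother[0], 2),
            self._ratios(ds.child[0], 3),
        ])
        trio_calls = TrioConstrainedCaller(ndjp_side="maternal").fit_predict(R)
        indep = np.vstack([
            kmeans_independent(R[0], ploidy=2),
            kmeans_independent(R[1], ploidy=2),
            kmeans_independent(R[2], ploidy=3),
        ])
        assert np.array_equal(trio_calls, indep)
        assert np.array_equal(trio_calls[2], ds.child[0])

    def test_constraint_binds_ambiguous_child(self):
        # clean background SNPs keep centers canonical; the last SNP has
        # hom-ref x hom-ref parents and a child ratio midway between the
        # dosage-1 and dosage-2 centers -> the only admissible child is 0
        father = np.array([0, 0.5, 1, 0, 0.5, 1, 0.0])
        mother = np.array([0, 0.5, 1, 0.5, 0, 1, 0.0])
        child = np.array([0, 1 / 3, 3 / 3, 1 / 3, 1 / 3, 3 / 3, 0.5])
        calls = TrioConstrainedCaller(ndjp_side="maternal").fit_predict(
            np.vstack([father, mother, child]))
        assert calls[2, -1] == 0
        indep_child = kmeans_independent(child, ploidy=3)[0]
        assert indep_child[-1] != 0  # the unconstrained call differs

    def test_never_emits_inadmissible_configuration(self):
        cfg = SimConfig(n_trios=3, n_snps=400, maf=0.3, maternal_ndj_prob=1.0,
                        intensity_sigma=0.08, seed=24)
        ds = simulate_trio_dataset(cfg)
        rng = np.random.default_rng(25)
        for i in range(ds.n_trios):
            R = np.vstack([
                normalize_many(simulate_intensities(ds.father[i], 2, cfg, rng)),
                normalize_many(simulate_intensities(ds.mother[i], 2, cfg, rng)),
                normalize_many(simulate_intensities(ds.child[i], 3, cfg, rng)),
            ])
            f, m, z = TrioConstrainedCaller(ndjp_side="maternal").fit_predict(R)
            for j in range(R.shape[1]):
                assert z[j] in enumerate_trio_configs(m[j], f[j])

    def test_converged_assignment_is_per_snp_optimum(self):
        """Exhaustive oracle: with the fitted centers fixed, every SNP's
        assigned configuration attains the minimal summed squared distance
        over all admissible configurations."""
        cfg = SimConfig(n_trios=1, n_snps=8, maf=0.4, maternal_ndj_prob=1.0,
                        intensity_sigma=0.05, seed=26)
        ds = simulate_trio_dataset(cfg)
        rng = np.random.default_rng(27)
        R = np.vstack([
            normalize_many(simulate_intensities(ds.father[0], 2, cfg, rng)),
            normalize_many(simulate_intensities(ds.mother[0], 2, cfg, rng)),
            normalize_many(simulate_intensities(ds.child[0], 3, cfg, rng)),
        ])
        est = TrioConstrainedCaller(ndjp_side="maternal").fit(R)
        cf, cm, cz = est.centers_
        for j in range(R.shape[1]):
            best = min(
                ((cf[f] - R[0, j]) ** 2 + (cm[m] - R[1, j]) ** 2 + (cz[z] - R[2, j]) ** 2
                 for f in range(3) for m in range(3)
                 for z in enumerate_trio_configs(m, f)),
            )
            f, m, z = est.calls_[:, j]
            got = (cf[f] - R[0, j]) ** 2 + (cm[m] - R[1, j]) ** 2 + (cz[z] - R[2, j]) ** 2
            assert got == pytest.approx(best)

    def test_trio_concordance_at_least_independent(self):
        cfg = SimConfig(n_trios=8, n_snps=600, maf=0.3, maternal_ndj_prob=1.0,
                        intensity_sigma=0.08, seed=28)
        ds = simulate_trio_dataset(cfg)
        rng = np.random.default_rng(29)
        indep_acc, trio_acc = [], []
        for i in range(ds.n_trios):
            R = np.vstack([
                normalize_many(simulate_intensities(ds.father[i], 2, cfg, rng)),
                normalize_many(simulate_intensities(ds.mother[i], 2, cfg, rng)),
                normalize_many(simulate_intensities(ds.child[i], 3, cfg, rng)),
            ])
            truth = np.vstack([ds.father[i], ds.mother[i], ds.child[i]])
            indep = np.vstack([
                kmeans_independent(R[0], ploidy=2),
                kmeans_independent(R[1], ploidy=2),
                kmeans_independent(R[2], ploidy=3),
            ])
            trio = TrioConstrainedCaller(ndjp_side="maternal").fit_predict(R)
            indep_acc.append((indep == truth).mean())
            trio_acc.append((trio == truth).mean())
        assert np.mean(trio_acc) >= np.mean(indep_acc)


class TestDiscrepancyFilter:
    def _calls(self, n_disc, n_children=26, n_snps=1):
        a = np.zeros((n_children, n_snps), dtype=int)
        b = a.copy()
        b[:n_disc, 0] = 1
        return a, b

    @pytest.mark.parametrize("n_disc, kept", [(7, False), (6, True), (0, True)])
    def test_quarter_threshold_for_26_children(self, n_disc, kept):
        a, b = self._calls(n_disc)
        res = discrepancy_filter(a, b, n_trios=26)
        assert res.kept[0] == kept
        assert res.stat[0] == n_disc

    def test_missing_calls_not_discrepant(self):
        a, b = self._calls(7)
        a[0, 0] = MISSING  # one of the 7 discordant children becomes missing
        res = discrepancy_filter(a, b, n_trios=26)
        assert res.kept[0]


class TestHardyWeinberg:
    def test_perfect_proportions_chisq(self):
        assert hwe_chisq_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_het_deficit_discarded(self):
        assert hwe_exact_pvalue(50, 0, 50) < 1e-4

    def test_parental_counts_of_top_snp_kept(self):
        # parental genotype counts reconstructed from the 26-triad table
        assert hwe_exact_pvalue(11, 24, 17) >= 1e-4
        res = hwe_filter(np.array([[11, 24, 17]]))
        assert res.kept[0]

    def test_monomorphic_kept_by_convention(self):
        assert hwe_exact_pvalue(0, 0, 40) == 1.0
        assert hwe_chisq_pvalue(0, 0, 40) == 1.0

    def test_exact_matches_enumeration_oracle(self):
        """Independent oracle: enumerate het counts directly with exact
        rational arithmetic via the multinomial/hypergeometric form."""
        from math import comb

        def oracle(naa, nab, nbb):
            n = naa + nab + nbb
            na = 2 * naa + nab
            probs = {}
            for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
                a_hom = (na - h) // 2
                b_hom = n - a_hom - h
                probs[h] = (
                    comb(n, a_hom) * comb(n - a_hom, h) * 2**h
                    / comb(2 * n, na)
                )
            p_obs = probs[nab]
            return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))

        for counts in [(11, 24, 17), (5, 5, 5), (2, 10, 2), (10, 1, 10)]:
            assert hwe_exact_pvalue(*counts) == pytest.approx(oracle(*counts), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(-1, 2, 3)
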