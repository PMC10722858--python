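import numpy as np
import pytest

from cassava_mgwas import domestication as dom
from cassava_mgwas.simulate import DamSpec, SimulationConfig, simulate_genotypes, simulate_metabolome
from cassava_mgwas.types import (
    CULTIVATED,
    WILD,
    GenotypeMatrix,
    MetaboliteMatrix,
    PopulationLabels,
    SnpRecord,
)


class TestVip:
    def test_single_variable_vip_is_one(self, rng):
        X = rng.normal(size=(12, 1))
        y = np.r_[np.zeros(6), np.ones(6)]
        v = dom.pls_da_vip(X, y, 1)
        assert np.asarray(v)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("p,a", [(5, 1), (10, 2), (20, 3)])
    def test_sum_of_squares_equals_variable_count(self, rng, p, a):
        X = rng.normal(size=(30, p))
        y = np.r_[np.zeros(15), np.ones(15)]
        X[:, 0] += y
        v = np.asarray(dom.pls_da_vip(X, y, a))
        assert np.sum(v**2) == pytest.approx(p, abs=1e-8)

    def test_informative_variable_ranks_above_noise(self, rng):
        n = 40
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = np.column_stack([y * 4 + 0.05 * rng.standard_normal(n),
                             rng.standard_normal(n)])
        v = np.asarray(dom.pls_da_vip(X, y, 1))
        assert v[0] > 1 > v[1]

    def test_matches_formula_from_sklearn_fit(self, rng):
        # independent oracle: evaluate the VIP formula on weights fitted by
        # sklearn's NIPALS PLS implementation
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 8))
        y = np.r_[np.zeros(15), np.ones(15)]
        X[:, 0] += y * 3
        A = 2
        v = np.asarray(dom.pls_da_vip(X, y, A))
        pls = sklearn.PLSRegression(n_components=A, scale=True).fit(X, y - y.mean())
        W = pls.x_weights_
        T = pls.x_scores_
        q = pls.y_loadings_.ravel()
        ssy = np.array([q[a] ** 2 * (T[:, a] @ T[:, a]) for a in range(A)])
        expected = np.sqrt(X.shape[1] * ((W**2) @ ssy) / ssy.sum())
        np.testing.assert_allclose(v, expected, atol=1e-10)

    def test_components_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(2, 5))
        with pytest.raises(ValueError, match="rank"):
            dom.pls_da_vip(X, np.array([0, 1]), 2)


class TestFoldChange:
    def test_equal_means_not_flagged(self):
        X = np.tile([[2.0, 8.0]], (10, 1))
        out = dom.fold_change(X, np.r_[np.zeros(5), np.ones(5)])
        assert (out["fc"] == 1.0).all() and not out["flagged"].any()

    def test_fc_exactly_one_point_five_is_flagged(self):
        X = np.array([[2.0]] * 5 + [[3.0]] * 5)
        out = dom.fold_change(X, np.r_[np.zeros(5), np.ones(5)])
        assert out["fc"].iloc[0] == pytest.approx(1.5)
        assert out["flagged"].iloc[0]

    def test_planted_log2fc_two_recovers_ratio_four(self):
        cfg = SimulationConfig(
            n_cultivated=200, n_wild=200, n_chrom=1, chrom_length_bp=500_000,
            n_snps=200, n_metabolites=3, h2_spec=0.2, seed=21,
            dam_spec=[DamSpec("M0001", 2.0)],
        )
        g, labels = simulate_genotypes(cfg)
        m, _ = simulate_metabolome(cfg, g, labels)
        cls = np.array([labels.labels[s] == CULTIVATED for s in m.samples])
        out = dom.fold_change(m.replicate_means(), cls)
        assert np.log2(out["fc"].iloc[0]) == pytest.approx(2.0, abs=0.3)
        assert out["direction"].iloc[0] == "up-in-cultivated"

    def test_zero_wild_mean_gives_inf_flagged_up(self):
        X = np.array([[0.0]] * 4 + [[5.0]] * 4)
        out = dom.fold_change(X, np.r_[np.zeros(4), np.ones(4)])
        assert np.isinf(out["fc"].iloc[0]) and out["flagged"].iloc[0]
        assert out["direction"].iloc[0] == "up-in-cultivated"


def dam_matrix(rng, n_cult=60, n_wild=5, log2fc=(2.0, 0.0), sd=0.25):
    names = [f"M{j+1}" for j in range(len(log2fc))]
    samples = [f"C{i}" for i in range(n_cult)] + [f"W{i}" for i in range(n_wild)]
    labels = PopulationLabels(
        {s: (CULTIVATED if s.startswith("C") else WILD) for s in samples}
    )
    base = 10.0
    log_vals = np.empty((len(samples), len(log2fc), 2))
    for j, fc in enumerate(log2fc):
        mu = np.full(len(samples), base)
        mu[:n_cult] += fc
        log_vals[:, j, :] = mu[:, None] + rng.normal(0, sd, (len(samples), 2))
    return MetaboliteMatrix(samples, names, 2.0**log_vals), labels


class TestDamClassifier:
    def test_zero_effect_metabolite_never_flagged(self, rng):
        m, labels = dam_matrix(rng, log2fc=(0.0,), sd=0.0)
        d = dom.dam_classifier(m, labels, seed=1)
        assert d.per_repeat_flag.sum() == 0 and not d.is_dam.any()

    def test_planted_effect_is_dam_in_most_seeded_runs(self, rng):
        hits = 0
        for seed in range(20):
            m, labels = dam_matrix(rng, log2fc=(2.0, 0.0), sd=0.25)
            d = dom.dam_classifier(m, labels, seed=seed)
            hits += bool(d.is_dam[0])
            assert not d.is_dam[1]
        assert hits >= 19

    def test_dam_requires_all_repeats_with_consistent_direction(self, rng):
        # moderate effect + noise: some metabolites flag in 1-9 repeats only
        m, labels = dam_matrix(
            rng, n_cult=60, log2fc=(2.0, 0.7, 0.6, 0.65, 0.0), sd=0.4
        )
        d = dom.dam_classifier(m, labels, seed=3)
        n_flagged = d.per_repeat_flag.sum(axis=1)
        consistent = (d.per_repeat_direction == d.per_repeat_direction[:, [0]]).all(axis=1)
        np.testing.assert_array_equal(d.is_dam, (n_flagged == 10) & consistent)
        assert ((n_flagged > 0) & (n_flagged < 10)).any()  # partial flags occurred
        assert not d.is_dam[(n_flagged > 0) & (n_flagged < 10)].any()

    def test_seed_reproducibility(self, rng):
        m, labels = dam_matrix(rng)
        a = dom.dam_classifier(m, labels, seed=9)
        b = dom.dam_classifier(m, labels, seed=9)
        np.testing.assert_array_equal(a.per_repeat_flag, b.per_repeat_flag)

    def test_effect_size_monotonicity(self, rng):
        # larger |log2FC| with matched noise never reduces the flag count
        counts = []
        for fc in (0.5, 1.0, 2.0):
            m, labels = dam_matrix(np.random.default_rng(42), log2fc=(fc,), sd=0.25)
            d = dom.dam_classifier(m, labels, seed=11)
            counts.append(int(d.per_repeat_flag.sum()))
        assert counts == sorted(counts)

    def test_insufficient_cultivated_rejected(self, rng):
        m, labels = dam_matrix(rng, n_cult=3)
        with pytest.raises(ValueError, match="cultivated"):
            dom.dam_classifier(m, labels, n_sub=5)


class TestWindowedPi:
    def test_hand_computed_single_site_window(self):
        g = GenotypeMatrix(
            ["a", "b", "c", "d"],
            [SnpRecord("Chr1", 5000)],
            np.array([[1], [1], [1], [1]], dtype=np.int8),
        )
        labels = PopulationLabels({s: CULTIVATED for s in "abcd"})
        pi = dom.windowed_pi(g, labels, 10_000, 10_000, {"Chr1": 10_000})
        # c = 4 of n = 8 alleles: site diversity 32/56; per-bp over 10 kb
        assert pi["pi"].iloc[0] == pytest.approx(2 * 4 * 4 / (8 * 7) / 10_000, abs=1e-9)
        assert pi["pi"].iloc[0] == pytest.approx(5.71429e-5, abs=1e-9)

    def test_monomorphic_window_has_zero_pi(self):
        g = GenotypeMatrix(
            ["a", "b"], [SnpRecord("Chr1", 100)], np.zeros((2, 1), dtype=np.int8)
        )
        labels = PopulationLabels({"a": CULTIVATED, "b": CULTIVATED})
        pi = dom.windowed_pi(g, labels, 1000, 1000, {"Chr1": 1000})
        assert pi["pi"].iloc[0] == 0.0

    def test_site_diversity_symmetric_in_allele_labels(self):
        n = np.full(5, 20)
        c = np.arange(5)
        np.testing.assert_allclose(
            dom.site_diversity(c, n), dom.site_diversity(n - c, n)
        )

    def test_windows_match_brute_force_on_toy(self, rng):
        n_sites = 15
        pos = np.sort(rng.choice(np.arange(1, 200_001), n_sites, replace=False))
        calls = rng.integers(0, 3, size=(6, n_sites)).astype(np.int8)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(6)],
            [SnpRecord("Chr1", int(p)) for p in pos],
            calls,
        )
        labels = PopulationLabels({f"s{i}": CULTIVATED for i in range(6)})
        window, step, length = 50_000, 10_000, 200_000
        table = dom.windowed_pi(g, labels, window, step, {"Chr1": length})
        for row in table.itertuples():
            total = 0.0
            nsites = 0
            for j, p in enumerate(pos):
                if row.start <= p < row.start + window:
                    col = calls[:, j]
                    nn = 2 * (col != -1).sum()
                    cc = col[col != -1].sum()
                    total += 2 * cc * (nn - cc) / (nn * (nn - 1))
                    nsites += 1
            assert row.pi == pytest.approx(total / window, abs=1e-12)
            assert row.n_sites == nsites

    def test_missing_calls_shrink_allele_count(self):
        g = GenotypeMatrix(
            ["a", "b", "c"],
            [SnpRecord("Chr1", 10)],
            np.array([[2], [0], [-1]], dtype=np.int8),
        )
        labels = PopulationLabels({s: WILD for s in "abc"})
        pi = dom.windowed_pi(g, labels, 100, 100, {"Chr1": 100})
        assert pi["pi"].iloc[0] == pytest.approx(2 * 2 * 2 / (4 * 3) / 100)

    def test_invalid_window_rejected(self, toy_genotypes, two_pop_labels):
        with pytest.raises(ValueError):
            dom.windowed_pi(toy_genotypes, two_pop_labels, 0, 10)


class TestAlleleFreqContrast:
    def test_fixed_difference_equals_one(self):
        calls = np.array([[2], [2], [0], [0]], dtype=np.int8)
        g = GenotypeMatrix(["c1", "c2", "w1", "w2"], [SnpRecord("Chr1", 5)], calls)
        labels = PopulationLabels(
            {"c1": CULTIVATED, "c2": CULTIVATED, "w1": WILD, "w2": WILD}
        )
        out = dom.allele_freq_contrast(g, labels)
        assert out["freq_cultivated"].iloc[0] == 1.0
        assert out["freq_wild"].iloc[0] == 0.0
        assert out["difference"].iloc[0] == 1.0

    def test_identical_groups_have_zero_difference(self, rng):
        calls = rng.integers(0, 3, size=(4, 10)).astype(np.int8)
        calls[2:] = calls[:2]
        pos = np.arange(1, 11) * 7
        g = GenotypeMatrix(
            ["c1", "c2", "w1", "w2"],
            [SnpRecord("Chr1", int(p)) for p in pos],
            calls,
        )
        labels = PopulationLabels(
            {"c1": CULTIVATED, "c2": CULTIVATED, "w1": WILD, "w2": WILD}
        )
        out = dom.allele_freq_contrast(g, labels)
        np.testing.assert_allclose(out["difference"], 0.0)

    def test_matches_brute_force_counting(self, rng, toy_genotypes, two_pop_labels):
        out = dom.allele_freq_contrast(toy_genotypes, two_pop_labels)
        for j in range(toy_genotypes.n_snps):
            for pop, col in (("cultivated", "freq_cultivated"), ("wild", "freq_wild")):
                rows = [i for i, s in enumerate(toy_genotypes.samples)
                        if two_pop_labels.labels[s] == pop]
                calls = toy_genotypes.calls[rows, j]
                called = calls[calls != -1]
                expected = called.sum() / (2 * len(called)) if len(called) else np.nan
                got = out[col].iloc[j]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)
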