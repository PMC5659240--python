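import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tutag.diffexp import (
    bh_adjust,
    cpm,
    estimate_dispersions,
    filter_low_counts,
    nb_exact_test,
    run_comparison,
    size_factors,
)
from tutag.io import CountMatrix, SampleSheet
from tutag.simulate import SimulationConfig, generate_catalog, simulate_counts


def _matrix(values, samples=None):
    values = np.asarray(values)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestCPM:
    def test_single_sample_proportions(self):
        m = _matrix([[1], [3]])
        assert np.allclose(cpm(m).to_numpy().ravel(), [250_000, 750_000])

    def test_all_zero_gene_stays_zero(self):
        m = _matrix([[0, 0], [10, 20]])
        assert (cpm(m).loc["g0"] == 0).all()

    def test_zero_library_errors_with_sample_name(self):
        m = _matrix([[0, 1]], samples=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            cpm(m)

    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(2, 8), st.integers(2, 5)),
            elements=st.integers(0, 1000),
        )
    )
    def test_columns_sum_to_one_million(self, values):
        if (values.sum(axis=0) == 0).any():
            return
        c = cpm(_matrix(values))
        assert np.allclose(c.sum(axis=0), 1e6)


class TestFilter:
    def test_rule_boundaries_at_three_low_samples(self):
        # library carrier keeps per-sample totals at 2e6, so 1 count = 0.5 CPM
        carrier = [2_000_000 - 5000] * 6
        ok = [5000] * 6  # well above 1 CPM everywhere -> kept
        two_low = [1, 1, 5000, 5000, 5000, 4998]  # below in exactly 2 -> kept
        three_low = [0, 1, 1, 5000, 5000, 4993]  # below in exactly 3 -> removed
        m = _matrix([carrier, ok, two_low, three_low])
        out = filter_low_counts(m, m.sample_ids)
        assert list(out.counts.index) == ["g0", "g1", "g2"]

    def test_idempotent(self, small_sim):
        _, _, matrix, _, _ = small_sim
        once = filter_low_counts(matrix, matrix.sample_ids)
        twice = filter_low_counts(once, once.sample_ids)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_preserves_gene_order(self, small_sim):
        _, _, matrix, _, _ = small_sim
        out = filter_low_counts(matrix, matrix.sample_ids)
        kept = [g for g in matrix.gene_ids if g in set(out.gene_ids)]
        assert out.gene_ids == kept

    def test_empty_comparison_errors(self, small_sim):
        _, _, matrix, _, _ = small_sim
        with pytest.raises(ValueError, match="empty"):
            filter_low_counts(matrix, [])


class TestSizeFactors:
    def test_identical_columns_are_unity(self):
        m = _matrix([[4, 4], [7, 7], [1, 1]])
        assert np.allclose(size_factors(m), [1.0, 1.0])

    def test_two_sample_closed_form(self):
        # column B = 2 x column A  ->  factors (1/sqrt(2), sqrt(2))
        a = np.array([3, 10, 50, 7])
        m = _matrix(np.column_stack([a, 2 * a]))
        assert np.allclose(size_factors(m), [2 ** -0.5, 2 ** 0.5])

    @pytest.mark.parametrize("c", [3.0, 0.5, 10.0])
    def test_scale_equivariance_two_samples(self, c):
        a = np.array([12, 40, 9, 100, 3])
        m = _matrix(np.column_stack([a, np.round(c * a).astype(int)]))
        sf = size_factors(m).to_numpy()
        # median-of-ratios closed form: (c'^-1/2, c'^1/2) for exact multiples
        cc = np.median(np.round(c * a) / a)
        assert np.allclose(sf, [cc ** -0.5, cc ** 0.5], rtol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 0.05, size=(50, 4))
        m = _matrix(counts)
        sf = size_factors(m).to_numpy()
        # independent brute force with plain python loops
        oracle = []
        for j in range(4):
            ratios = []
            for i in range(50):
                row = counts[i]
                if (row > 0).all():
                    geo = np.prod([float(x) ** (1 / 4) for x in row])
                    ratios.append(row[j] / geo)
            oracle.append(np.median(ratios))
        assert np.allclose(sf, oracle, rtol=1e-9)

    def test_no_common_gene_errors(self):
        m = _matrix([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(m)


class TestDispersions:
    @staticmethod
    def _nb_matrix(rng, mu, phi, m_samples):
        if phi == 0:
            counts = rng.poisson(mu[:, None], size=(len(mu), m_samples))
        else:
            size = 1 / phi
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p[:, None], size=(len(mu), m_samples))
        return _matrix(counts)

    @staticmethod
    def _sheet(matrix, split):
        return SampleSheet(
            {s: ("A" if j < split else "B") for j, s in enumerate(matrix.sample_ids)}
        )

    def test_poisson_data_gives_near_zero_dispersion(self):
        rng = np.random.default_rng(1)
        mu = 500 * np.exp(rng.normal(0, 1, 4000))
        m = self._nb_matrix(rng, mu, 0.0, 12)
        sf = size_factors(m)
        phi, (a0, a1) = estimate_dispersions(m, sf, self._sheet(m, 6))
        assert a0 < 5e-3
        assert float(phi.median()) < 0.01

    def test_constant_counts_fall_back_to_trend_floor(self):
        m = _matrix(np.tile([[50, 50, 50, 80, 80, 80]], (10, 1)))
        sf = size_factors(m)
        phi, trend = estimate_dispersions(m, sf, self._sheet(m, 3))
        # zero within-condition variance: raw <= 0, trend empty -> floor
        assert np.allclose(phi, 1e-8)

    def test_recovers_known_dispersion_within_20_percent(self):
        rng = np.random.default_rng(3)
        mu = 500 * np.exp(rng.normal(0, 1, 2000))
        m = self._nb_matrix(rng, mu, 0.05, 12)
        sf = size_factors(m)
        phi, _ = estimate_dispersions(m, sf, self._sheet(m, 6))
        assert abs(float(phi.median()) - 0.05) / 0.05 < 0.2

    def test_no_replication_anywhere_errors(self):
        m = _matrix([[5, 6], [7, 8]])
        sheet = SampleSheet({"s0": "A", "s1": "B"})
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(m, size_factors(m), sheet)


def _enumeration_oracle(k_a, k_b, sf_a, sf_b, phi):
    """Brute-force split enumeration in linear probability space."""
    K = int(np.sum(k_a) + np.sum(k_b))
    if K == 0:
        return 1.0
    SA, SB = float(np.sum(sf_a)), float(np.sum(sf_b))
    q0 = (np.sum(np.asarray(k_a) / sf_a) + np.sum(np.asarray(k_b) / sf_b)) / (
        len(k_a) + len(k_b)
    )
    if q0 <= 0:
        q0 = K / (SA + SB)

    def pmf(side_sf, k):
        S = float(np.sum(side_sf))
        S2 = float(np.sum(np.asarray(side_sf) ** 2))
        mean = q0 * S
        var = mean + phi * q0**2 * S2
        if var <= mean * (1 + 1e-12):
            return stats.poisson.pmf(k, mean)
        size = mean**2 / (var - mean)
        return stats.nbinom.pmf(k, size, size / (size + mean))

    probs = [pmf(sf_a, a) * pmf(sf_b, K - a) for a in range(K + 1)]
    p_obs = probs[int(np.sum(k_a))]
    num = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
    return min(1.0, num / sum(probs))


class TestExactTest:
    def test_symmetric_split_gives_p_one(self):
        p = nb_exact_test([10, 10], [10, 10], [1.0, 1.0], [1.0, 1.0], 0.1)
        assert p == pytest.approx(1.0)

    def test_all_zero_gives_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], [1, 1], [1, 1], 0.1) == 1.0

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.5])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, phi, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            k_a = rng.integers(0, 15, size=3)
            k_b = rng.integers(0, 15, size=3)
            sf_a = rng.uniform(0.5, 1.5, size=3)
            sf_b = rng.uniform(0.5, 1.5, size=3)
            expected = _enumeration_oracle(k_a, k_b, sf_a, sf_b, phi)
            got = nb_exact_test(k_a, k_b, sf_a, sf_b, phi)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_poisson_limit_is_two_sided_binomial(self):
        # phi -> 0 with equal size factors: conditioning gives Binomial(K, 1/2)
        k_a, k_b = [13, 9], [5, 7]
        K = sum(k_a) + sum(k_b)
        p_nb = nb_exact_test(k_a, k_b, [1, 1], [1, 1], 0.0)
        p_binom = stats.binomtest(sum(k_a), K, 0.5).pvalue
        assert p_nb == pytest.approx(p_binom, rel=1e-9)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            nb_exact_test([1], [1], [1.0], [1.0], -0.1)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_hand_step_up_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60)
    )
    def test_matches_statsmodels_and_dominates_p(self, pvals):
        ours = bh_adjust(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(ours, ref, atol=1e-12)
        assert np.all(ours >= np.asarray(pvals) - 1e-15)
        assert np.all(ours <= 1.0)


class TestRunComparison:
    def test_relabeled_copies_yield_no_enrichment(self):
        rng = np.random.default_rng(8)
        base = rng.negative_binomial(10, 0.05, size=(100, 2))
        values = np.column_stack([base, base])  # B is a copy of A
        m = _matrix(values, samples=["a1", "a2", "b1", "b2"])
        sheet = SampleSheet({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        de = run_comparison(m, sheet, "A", "B")
        assert de.enriched_genes == []
        assert np.allclose(de.table["fold_enrichment"].dropna(), 1.0)

    def test_requires_two_samples_per_type(self, small_sim):
        _, _, matrix, sheet, _ = small_sim
        broken = SampleSheet(dict(sheet.types))
        lone = sheet.samples_of_type("WT")[0]
        for s in sheet.samples_of_type("WT")[1:]:
            broken.types[s] = "other"
        with pytest.raises(ValueError, match="WT"):
            run_comparison(matrix, broken, "Sepw1", "WT")

    def test_result_invariants(self, small_sim):
        _, _, matrix, sheet, _ = small_sim
        de = run_comparison(matrix, sheet, "Sepw1", "Nr5a1")
        t = de.table
        assert ((t["pval"] >= 0) & (t["pval"] <= 1)).all()
        assert (t["padj"] >= t["pval"] - 1e-12).all()
        # padj nondecreasing along the pval order
        ordered = t.sort_values("pval", kind="stable")["padj"].to_numpy()
        assert np.all(np.diff(ordered) >= -1e-12)
        flagged = t[t["enriched"]]
        assert (flagged["padj"] < de.alpha).all()
        assert (flagged["fold_enrichment"] > 1).all()

    def test_global_null_false_positive_rate(self):
        """No planted signal: the fraction of genes at padj < 0.1 stays
        far below the nominal FDR over 20 simulations."""
        fractions = []
        for seed in range(20):
            cfg = SimulationConfig(n_genes=300, effect_size=1.0, seed=seed)
            cat = generate_catalog(cfg)
            matrix, sheet, _ = simulate_counts(cat, cfg)
            de = run_comparison(matrix, sheet, "Sepw1", "Nr5a1")
            fractions.append(len(de.enriched_genes) / len(de.universe))
        assert np.mean(fractions) <= 0.15
        assert np.mean(fractions) < 0.02
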