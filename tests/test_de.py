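import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualnod import (
    ValidationError,
    bh_adjust,
    call_degs,
    estimate_dispersion,
    log2fc,
    nb_exact_test,
    pca_samples,
    sample_nb,
)

from conftest import make_counts, make_samples
from oracles import bh_stepup_bruteforce, conditional_binomial_pvalue


class TestDispersion:
    def test_constant_gene_shrinks_to_common_floor(self):
        """A zero-variance gene has phi_g = 0 and lands on the shrinkage floor."""
        rng = np.random.default_rng(1)
        noisy = sample_nb(rng, 200.0, 0.4, size=(100, 6))
        const = np.full((1, 6), 150)
        mat = np.vstack([noisy, const])
        # a filler gene equalizes column sums so effective sizes are identical
        sums = mat.sum(axis=0)
        filler = (sums.max() - sums)[None, :] + 10
        cm = make_counts(np.vstack([mat, filler]))
        est = estimate_dispersion(cm, make_samples())
        gene = cm.gene_ids[100]
        assert est.per_gene[gene] == 0.0
        assert est.common > 0
        assert est.shrunk[gene] == pytest.approx(0.3 * est.common)

    def test_poisson_genes_estimate_near_zero(self):
        rng = np.random.default_rng(2)
        cm = make_counts(rng.poisson(50, size=(2000, 6)))
        est = estimate_dispersion(cm, make_samples())
        assert est.shrunk.mean() <= 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(3)
        cm = make_counts(sample_nb(rng, 50.0, 0.4, size=(2000, 6)))
        est = estimate_dispersion(cm, make_samples())
        assert 0.2 <= np.median(est.shrunk) <= 0.6

    def test_single_replicate_group_rejected(self):
        samples = make_samples().iloc[[0, 1, 3]].reset_index(drop=True)
        cm = make_counts([[5, 6, 7], [1, 2, 3]], samples=samples)
        with pytest.raises(ValidationError, match="fewer than 2"):
            estimate_dispersion(cm, samples)


class TestExactTest:
    def test_symmetric_split_gives_one(self):
        assert nb_exact_test([5, 5, 5], [5, 5, 5], 0.2) == pytest.approx(1.0)

    def test_zero_total_gives_one(self):
        assert nb_exact_test([0, 0, 0], [0, 0, 0], 0.1) == 1.0

    def test_extreme_split_enumeration(self):
        # t = 6 all in group A: p = P(0) + P(6) of Binomial(6, 1/2) = 2/64
        p = nb_exact_test([6, 0, 0], [0, 0, 0], 0.0)
        assert p == pytest.approx(2 / 64, abs=1e-12)

    def test_poisson_limit_matches_binomial_oracle(self):
        for t in range(0, 21):
            for a_sum in range(t + 1):
                p = nb_exact_test([a_sum, 0, 0], [t - a_sum, 0, 0], 0.0)
                expected = conditional_binomial_pvalue(a_sum, t, 3, 3)
                assert abs(p - expected) < 1e-10

    def test_library_equalization_uses_effective_sizes(self):
        # same per-CPM expression at 2x depth in group A should not look DE
        p_unbalanced = nb_exact_test(
            [100, 100, 100], [50, 50, 50], 0.05,
            sizes_a=[2e6, 2e6, 2e6], sizes_b=[1e6, 1e6, 1e6],
        )
        assert p_unbalanced == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            nb_exact_test([-1, 2, 3], [1, 2, 3], 0.1)
        with pytest.raises(ValidationError):
            nb_exact_test([1, 2, 3], [1, 2, 3], 0.1, sizes_a=[0, 1, 1])


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_bruteforce(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        for _ in range(20):
            p = rng.random(30)
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_in_p(self, pvals):
        q = bh_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestDEGCalls:
    def test_effect_size_gate(self):
        table = pd.DataFrame(
            {"log2FC": [-0.9, -1.0, 2.5], "FDR": [1e-20, 0.049, 0.051]},
            index=["a", "b", "c"],
        )
        labeled, summary = call_degs(table)
        assert labeled.loc["a", "status"] == "ns"  # strong FDR but |lfc| < 1
        assert labeled.loc["b", "status"] == "higher_in_WE2"  # inclusive >= 1
        assert labeled.loc["c", "status"] == "ns"  # FDR not < 0.05
        assert summary.n_total == 1

    def test_threshold_tightening_shrinks_calls(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {"log2FC": rng.normal(0, 2, 300), "FDR": rng.random(300)}
        )
        loose, _ = call_degs(table, fdr_threshold=0.05)
        tight, _ = call_degs(table, fdr_threshold=0.01)
        loose_set = set(loose.index[loose["status"] != "ns"])
        tight_set = set(tight.index[tight["status"] != "ns"])
        assert tight_set <= loose_set


class TestLog2FC:
    def test_examples(self):
        assert log2fc(10.0, 10.0) == pytest.approx(0.0)
        assert log2fc(100.0, 400.0) == pytest.approx(2.0, abs=0.01)
        assert log2fc(0.0, 0.0) == pytest.approx(0.0)
        # orientation: B (WWL2) in the numerator
        assert log2fc(100.0, 25.0) < 0


class TestPCA:
    def test_rank_one_data(self):
        base = np.arange(10, dtype=float)
        X = pd.DataFrame(
            np.column_stack([base, 2 * base, 3 * base]), columns=["a", "b", "c"]
        )
        coords, pct = pca_samples(X)
        assert pct[0] == pytest.approx(100.0)

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        _, pct = pca_samples(X)
        assert pct.sum() == pytest.approx(100.0)
        assert (pct >= 0).all()

    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(10)
        col = rng.normal(size=30)
        X = pd.DataFrame(
            np.column_stack([col, col, rng.normal(size=30)]), columns=["a", "b", "c"]
        )
        coords, _ = pca_samples(X)
        np.testing.assert_allclose(
            coords.loc["a"].to_numpy(), coords.loc["b"].to_numpy(), atol=1e-8
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            pca_samples(pd.DataFrame({"a": [1.0, 2.0]}))
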