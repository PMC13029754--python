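import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualnod import (
    ValidationError,
    ara_rate,
    concordance,
    ddct,
    qpcr_log2_ratio,
    welch_t,
)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_clear_shift_is_significant(self):
        t, df, p = welch_t([1.0, 2, 3], [11.0, 12, 13])
        assert p < 0.01
        assert t < 0

    def test_swapping_groups_negates_t(self):
        a, b = [0.9, 1.0, 0.89], [-0.9, -1.0, -0.89]
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_matches_scipy_and_satterthwaite(self):
        from oracles import welch_bruteforce

        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(2, 10))
            b = rng.normal(0.5, 2, rng.integers(2, 10))
            t, df, p = welch_t(a, b)
            t_ref, df_ref = welch_bruteforce(a, b)
            assert t == pytest.approx(t_ref, abs=1e-12)
            assert df == pytest.approx(df_ref, abs=1e-12)
            res = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(res.statistic, abs=1e-10)
            assert p == pytest.approx(res.pvalue, abs=1e-10)

    def test_degenerate_zero_variance(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0])[2] == 1.0
        assert welch_t([2.0, 2.0], [3.0, 3.0])[2] == 0.0

    def test_needs_two_per_group(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])


class TestAraRate:
    def test_printed_magnitude_from_tenth_gram_assay(self):
        # 2.34 units of ethylene over 1 h from the standard 0.10 g nodule assay
        assert ara_rate(2.34, 1.0, 0.10) == pytest.approx(23.4)

    def test_proportionality(self):
        base = ara_rate(10.0, 2.0, 0.5)
        assert ara_rate(10.0, 2.0, 1.0) == pytest.approx(base / 2)
        assert ara_rate(10.0, 4.0, 0.5) == pytest.approx(base / 2)
        assert ara_rate(20.0, 2.0, 0.5) == pytest.approx(base * 2)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ara_rate(1.0, 0.0, 0.1)
        with pytest.raises(ValidationError):
            ara_rate(1.0, 1.0, -0.1)


def _qpcr_table(target_cts: dict[str, dict[tuple[str, int], float]],
                ref_ct: float = 18.0, ref_gene: str = "ref") -> pd.DataFrame:
    rows = []
    keys = [("WE2", r) for r in (1, 2, 3)] + [("WWL2", r) for r in (1, 2, 3)]
    for gene, cts in target_cts.items():
        for key in keys:
            ct = cts[key]
            rows.append({"target_gene": gene, "reference_gene": ref_gene,
                         "treatment": key[0], "replicate": key[1],
                         "ct1": ct, "ct2": ct, "ct3": ct})
    for key in keys:
        rows.append({"target_gene": ref_gene, "reference_gene": ref_gene,
                     "treatment": key[0], "replicate": key[1],
                     "ct1": ref_ct, "ct2": ref_ct, "ct3": ref_ct})
    return pd.DataFrame(rows)


class TestDdct:
    def test_calibrator_has_unit_expression(self):
        cts = {("WE2", r): 20.0 for r in (1, 2, 3)}
        cts.update({("WWL2", r): 20.0 for r in (1, 2, 3)})
        rq = ddct(_qpcr_table({"gene": cts}))
        np.testing.assert_allclose(rq["mean_rq"].to_numpy(), 1.0, atol=1e-12)

    def test_one_cycle_doubles(self):
        cts = {("WE2", r): 20.0 for r in (1, 2, 3)}
        cts.update({("WWL2", r): 19.0 for r in (1, 2, 3)})  # ddCt = -1
        rq = ddct(_qpcr_table({"gene": cts}))
        wwl2 = rq[rq["treatment"] == "WWL2"]["mean_rq"].iloc[0]
        assert wwl2 == pytest.approx(2.0)

    def test_two_cycle_gap_gives_fourfold_ratio(self):
        cts = {("WE2", r): 20.0 for r in (1, 2, 3)}
        cts.update({("WWL2", r): 22.0 for r in (1, 2, 3)})
        rq = ddct(_qpcr_table({"gene": cts}))
        we2 = rq[rq["treatment"] == "WE2"]["mean_rq"].iloc[0]
        wwl2 = rq[rq["treatment"] == "WWL2"]["mean_rq"].iloc[0]
        assert we2 / wwl2 == pytest.approx(4.0)

    def test_machine_offset_cancels(self):
        rng = np.random.default_rng(1)
        cts = {k: float(rng.uniform(18, 26)) for k in
               [("WE2", r) for r in (1, 2, 3)] + [("WWL2", r) for r in (1, 2, 3)]}
        base = ddct(_qpcr_table({"gene": cts}))
        shifted_tbl = _qpcr_table({"gene": {k: v + 3.0 for k, v in cts.items()}},
                                  ref_ct=18.0 + 3.0)
        shifted = ddct(shifted_tbl)
        np.testing.assert_allclose(base["mean_rq"], shifted["mean_rq"], atol=1e-12)

    def test_missing_reference_is_error(self):
        table = _qpcr_table({"gene": {k: 20.0 for k in
                             [("WE2", r) for r in (1, 2, 3)] +
                             [("WWL2", r) for r in (1, 2, 3)]}})
        table = table[~((table["target_gene"] == "ref") & (table["replicate"] == 2))]
        with pytest.raises(ValidationError, match="reference gene"):
            ddct(table)

    def test_ct_range_validated(self):
        table = _qpcr_table({"gene": {k: 50.0 for k in
                             [("WE2", r) for r in (1, 2, 3)] +
                             [("WWL2", r) for r in (1, 2, 3)]}})
        with pytest.raises(ValidationError, match="Ct values"):
            ddct(table)


class TestConcordance:
    def test_perfect_and_opposite_agreement(self):
        ratios = pd.Series([1.5, -2.0, 0.7], index=["a", "b", "c"])
        rnaseq = pd.Series([-2.0, 1.0, -0.5], index=["a", "b", "c"])
        assert concordance(ratios, rnaseq) == 1.0
        assert concordance(ratios, -rnaseq) == 0.0

    def test_no_shared_genes_is_error(self):
        with pytest.raises(ValidationError):
            concordance(pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"]))

    def test_simulated_qpcr_recovers_planted_directions(self, small_sim):
        """Generated Ct values agree in sign with the planted fold changes."""
        rq = ddct(small_sim.qpcr.drop(columns=["partner"]))
        ratios = qpcr_log2_ratio(rq)  # WE2 / WWL2
        truth = small_sim.truth.true_log2fc.loc[ratios.index]
        agreement = concordance(ratios, truth)
        assert agreement >= 0.9
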