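import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from gbmscreen.exceptions import ValidationError
from gbmscreen.expression import (
    PairedExpressionSet,
    adjust_q,
    correlate,
    ddct_fold_change,
    paired_t_test,
    top_n_genes,
)


def _pairs(control: np.ndarray, treated: np.ndarray) -> PairedExpressionSet:
    idx = pd.Index([f"g{i}" for i in range(control.shape[0])], name="gene")
    cols = [f"rep{j}" for j in range(control.shape[1])]
    return PairedExpressionSet(pd.DataFrame(control, idx, cols), pd.DataFrame(treated, idx, cols))


class TestPairedT:
    def test_null_gene_has_t0_p1(self):
        c = np.array([[5.0, 6.0, 7.0]])
        res = paired_t_test(_pairs(c, c.copy()))
        assert res["t_stat"].iloc[0] == 0.0 and res["p_value"].iloc[0] == 1.0

    def test_hand_computed_example(self):
        c = np.array([[0.0, 0.0, 0.0]])
        t = np.array([[1.0, 2.0, 3.0]])
        res = paired_t_test(_pairs(c, t))
        assert res["t_stat"].iloc[0] == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res["p_value"].iloc[0] == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), 2), abs=1e-12)

    def test_antisymmetry_under_arm_swap(self, rng):
        c, t = rng.normal(5, 1, (20, 4)), rng.normal(5, 1, (20, 4))
        fwd = paired_t_test(_pairs(c, t))
        rev = paired_t_test(_pairs(t, c))
        assert np.allclose(fwd["t_stat"], -rev["t_stat"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_matches_closed_form_on_random_input(self, rng):
        c, t = rng.normal(0, 1, (50, 5)), rng.normal(0.3, 1, (50, 5))
        res = paired_t_test(_pairs(c, t))
        d = t - c
        tt = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(5))
        assert np.allclose(res["t_stat"], tt, atol=1e-12)
        assert np.allclose(res["p_value"], 2 * stats.t.sf(np.abs(tt), 4), atol=1e-12)

    def test_exact_constant_shift_hits_zero_variance_limit(self):
        c = np.zeros((1, 6))
        res = paired_t_test(_pairs(c, c + 2.0))
        # all differences equal 2 -> zero variance, p -> 0 limit, flagged
        assert res["zero_variance"].iloc[0]
        assert res["p_value"].iloc[0] == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(Exception):
            _pairs(np.zeros((3, 1)), np.ones((3, 1)))


class TestAdjustQ:
    def test_all_ones_stay_ones(self):
        assert np.allclose(adjust_q(np.ones(7)), 1.0)

    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_q([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=100))
    def test_matches_brute_force_definition(self, pvals):
        p = np.asarray(pvals)
        q = adjust_q(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
            brute[idx] = min(1.0, min(candidates))
        assert np.allclose(q, brute, atol=1e-12)

    def test_sorted_q_nondecreasing(self, rng):
        q = adjust_q(rng.uniform(0, 1, 200))
        p = np.sort(rng.uniform(0, 1, 200))
        assert np.all(np.diff(np.sort(q)) >= -1e-15)
        del p

    def test_storey_no_larger_than_bh(self, rng):
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(0, 1, 500)])
        assert np.all(adjust_q(p, "storey") <= adjust_q(p, "bh") + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_q([0.5, 1.5])


class TestTopN:
    def _results(self, rng, n=30):
        c = rng.normal(0, 1, (n, 4))
        t = c + rng.normal(0, 1, (n, 4))
        res = paired_t_test(_pairs(c, t))
        res["q_value"] = adjust_q(res["p_value"].to_numpy())
        return res

    def test_exhaustion_flagged(self, rng):
        res = self._results(rng)
        n_up = int((res["direction"] == "up").sum())
        genes, short = top_n_genes(res, n_up + 10, "up")
        assert len(genes) == n_up and short

    def test_matches_full_sort_oracle(self, rng):
        res = self._results(rng, 100)
        genes, _ = top_n_genes(res, 20, "down")
        sub = res[res["direction"] == "down"]
        expected = sorted(
            sub.index, key=lambda gg: (sub.loc[gg, "q_value"], -abs(sub.loc[gg, "t_stat"]), gg)
        )[:20]
        assert genes == expected

    def test_tie_breaks_by_abs_t_then_name(self):
        res = pd.DataFrame(
            {"mean_diff": [1, 1, 1], "t_stat": [3.0, 5.0, 5.0],
             "p_value": [0.01, 0.01, 0.01], "q_value": [0.03, 0.03, 0.03],
             "direction": ["up"] * 3},
            index=pd.Index(["gB", "gC", "gA"], name="gene"),
        )
        genes, _ = top_n_genes(res, 3, "up")
        assert genes == ["gA", "gC", "gB"]

    def test_up_and_down_lists_disjoint(self, rng):
        res = self._results(rng, 200)
        up, _ = top_n_genes(res, 50, "up")
        down, _ = top_n_genes(res, 50, "down")
        assert not set(up) & set(down)


class TestCorrelate:
    def test_exact_linearity(self):
        x = np.arange(5.0)
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_spearman_rank_invariance(self):
        x = np.arange(1.0, 9.0)
        y = np.exp(x)
        rs, _ = correlate(x, y, "spearman")
        rp, _ = correlate(x, y, "pearson")
        assert rs == pytest.approx(1.0) and rp < 1.0

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        r, _ = correlate(x, y)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDdct:
    @pytest.mark.parametrize(
        "dct_sample,dct_calib,fold",
        [((20.0, 20.0), (18.0, 18.0), 1.0), ((18.0, 20.0), (20.0, 20.0), 4.0),
         ((21.0, 20.0), (20.0, 20.0), 0.5)],
    )
    def test_fold_change(self, dct_sample, dct_calib, fold):
        assert ddct_fold_change(dct_sample[0], dct_sample[1], dct_calib[0], dct_calib[1]) == pytest.approx(fold)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            ddct_fold_change(20.0, float("nan"), 18.0, 18.0)
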