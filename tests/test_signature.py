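import numpy as np
import pandas as pd
import pytest

from gbmscreen.exceptions import InsufficientDataError, UnusableSignatureError, ValidationError
from gbmscreen.signature import (
    SignatureVector,
    classify_cohort_by_subtype,
    derive_signature,
    intersect_with_cohort,
    score_samples,
    zscore_cohort,
)
from gbmscreen.synthetic import simulate_cell_line_expression


@pytest.fixture
def toy_sig():
    return SignatureVector(pd.Series({"GA": 1, "GB": 1, "GC": -1}))


def _zmatrix(profiles: dict[str, list[float]], genes=("GA", "GB", "GC")) -> pd.DataFrame:
    return pd.DataFrame(profiles, index=list(genes))


class TestDeriveSignature:
    def test_planted_signal_recovered(self):
        expr, labels = simulate_cell_line_expression(
            n_up_per_class=50, effect_size=3.0, noise_sd=0.5, seed=11
        )
        sig = derive_signature(expr, labels, n_per_class=50)
        planted_s = {f"SIG_S_{i+1:03d}" for i in range(50)}
        planted_r = {f"SIG_R_{i+1:03d}" for i in range(50)}
        got_s = {g for g in sig.genes if sig.weights[g] == 1}
        got_r = {g for g in sig.genes if sig.weights[g] == -1}
        assert len(got_s & planted_s) >= 45
        assert len(got_r & planted_r) >= 45

    def test_size_bounded_by_construction(self):
        expr, labels = simulate_cell_line_expression(seed=2)
        sig = derive_signature(expr, labels, n_per_class=50)
        assert len(sig.genes) <= 100

    def test_label_swap_flips_weights(self):
        expr, labels = simulate_cell_line_expression(seed=5, n_background=100)
        swapped = {k: ("resistant" if v == "sensitive" else "sensitive") for k, v in labels.items()}
        a = derive_signature(expr, labels, 20)
        b = derive_signature(expr, swapped, 20)
        common = [g for g in a.genes if g in b.weights.index]
        assert common and all(a.weights[g] == -b.weights[g] for g in common)

    def test_small_class_rejected(self):
        expr, labels = simulate_cell_line_expression(seed=1, n_background=10)
        labels = {k: ("sensitive" if k == "S01" else "resistant") for k in labels}
        with pytest.raises(InsufficientDataError):
            derive_signature(expr, labels)


class TestIntersect:
    def test_full_cohort_is_identity(self, toy_sig):
        out = intersect_with_cohort(toy_sig, ["GA", "GB", "GC", "GX"])
        assert out.weights.equals(toy_sig.weights)

    def test_hundred_gene_signature_drops_to_79(self):
        w = pd.Series({**{f"S{i:03d}": 1 for i in range(50)}, **{f"R{i:03d}": -1 for i in range(50)}})
        sig = SignatureVector(w)
        cohort = [f"S{i:03d}" for i in range(41)] + [f"R{i:03d}" for i in range(38)]
        out = intersect_with_cohort(sig, cohort)
        assert len(out.genes) == 79
        assert out.provenance["retained_up_sensitive"] == 41
        assert out.provenance["retained_up_resistant"] == 38
        assert out.provenance["requested_up_sensitive"] == 50

    def test_emptied_sign_class_rejected(self, toy_sig):
        with pytest.raises(UnusableSignatureError):
            intersect_with_cohort(toy_sig, ["GC"])


class TestZscore:
    def test_rows_have_zero_mean_unit_sd(self, rng):
        expr = pd.DataFrame(rng.normal(5, 2, (10, 8)))
        z = zscore_cohort(expr)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_constant_gene_dropped(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (4, 5)), index=list("abcd"))
        expr.loc["c"] = 7.0
        z = zscore_cohort(expr)
        assert "c" not in z.index and len(z) == 3

    def test_matches_hand_computation(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 6.0]], index=["g"])
        z = zscore_cohort(expr)
        x = np.array([1.0, 2.0, 3.0, 6.0])
        assert np.allclose(z.loc["g"], (x - 3.0) / x.std(ddof=1), atol=1e-12)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(InsufficientDataError):
            zscore_cohort(pd.DataFrame([[1.0, 2.0]]))


class TestScoreSamples:
    def test_self_profile_scores_one(self, toy_sig):
        z = _zmatrix({"s1": [1.0, 1.0, -1.0]})
        (score,) = score_samples(z, toy_sig)
        assert score.score == pytest.approx(1.0)
        assert score.call == "sensitive-like"

    def test_negated_profile_scores_minus_one(self, toy_sig):
        z = _zmatrix({"s1": [-1.0, -1.0, 1.0]})
        (score,) = score_samples(z, toy_sig)
        assert score.score == pytest.approx(-1.0)
        assert score.call == "resistant-like"

    def test_matches_covariance_formula(self, toy_sig):
        z = _zmatrix({"s1": [1.2, 0.3, -0.8]})
        (score,) = score_samples(z, toy_sig)
        x = np.array([1.2, 0.3, -0.8])
        w = np.array([1.0, 1.0, -1.0])
        manual = np.sum((x - x.mean()) * (w - w.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((w - w.mean()) ** 2)
        )
        assert score.score == pytest.approx(manual, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng, toy_sig):
        expr = pd.DataFrame(rng.normal(0, 1, (3, 30)), index=["GA", "GB", "GC"])
        scaled = expr.mul(rng.uniform(0.5, 4, 3), axis=0).add(rng.normal(0, 10, 3), axis=0)
        s1 = score_samples(zscore_cohort(expr), toy_sig)
        s2 = score_samples(zscore_cohort(scaled), toy_sig)
        assert np.allclose([a.score for a in s1], [b.score for b in s2], atol=1e-12)

    def test_weight_flip_negates_scores_and_swaps_calls(self, rng, toy_sig):
        expr = pd.DataFrame(rng.normal(0, 1, (3, 40)), index=["GA", "GB", "GC"])
        z = zscore_cohort(expr)
        fwd = score_samples(z, toy_sig)
        rev = score_samples(z, toy_sig.flipped())
        swap = {"sensitive-like": "resistant-like", "resistant-like": "sensitive-like",
                "unclassified": "unclassified"}
        for a, b in zip(fwd, rev):
            assert b.score == pytest.approx(-a.score, abs=1e-12)
            assert b.call == swap[a.call]

    def test_mean_difference_identity(self, rng, toy_sig):
        # with +-1 weights the score is the +1/-1 group z-mean difference
        # rescaled by the profile and weight standard deviations
        expr = pd.DataFrame(rng.normal(0, 1, (3, 10)), index=["GA", "GB", "GC"])
        z = zscore_cohort(expr)
        w = toy_sig.weights.to_numpy(dtype=float)
        n_pos, n_neg, n = 2, 1, 3
        sww = np.sum((w - w.mean()) ** 2)
        for s in score_samples(z, toy_sig):
            x = z[s.sample].to_numpy()
            diff = x[:n_pos].mean() - x[n_pos:].mean()
            expected = (2.0 * n_pos * n_neg / n) * diff / np.sqrt(np.sum((x - x.mean()) ** 2) * sww)
            assert s.score == pytest.approx(expected, abs=1e-12)

    def test_flat_sample_unclassified(self, toy_sig):
        z = _zmatrix({"s1": [0.5, 0.5, 0.5]})
        (score,) = score_samples(z, toy_sig)
        assert score.call == "unclassified" and score.degenerate

    def test_missing_signature_gene_rejected(self, toy_sig):
        z = pd.DataFrame({"s1": [0.1]}, index=["GA"])
        with pytest.raises(ValidationError):
            score_samples(z, toy_sig)


class TestClassifyBySubtype:
    def _scores_and_clinical(self, calls):
        from gbmscreen.signature import CohortScore

        scores = [CohortScore(f"s{i}", None, 0.0, c, 0.2) for i, c in enumerate(calls)]
        clinical = pd.DataFrame(
            {"subtype": ["proneural" if i % 2 == 0 else "mesenchymal" for i in range(len(calls))]},
            index=[f"s{i}" for i in range(len(calls))],
        )
        return scores, clinical

    def test_all_unclassified_gives_zero_call_counts(self):
        scores, clinical = self._scores_and_clinical(["unclassified"] * 6)
        counts, flagged = classify_cohort_by_subtype(scores, clinical)
        assert counts["sensitive-like"].sum() == 0
        assert counts["resistant-like"].sum() == 0
        assert set(flagged) == {"proneural", "mesenchymal"}

    def test_counts_partition_cohort(self):
        calls = ["sensitive-like", "resistant-like", "unclassified"] * 4
        scores, clinical = self._scores_and_clinical(calls)
        counts, _ = classify_cohort_by_subtype(scores, clinical)
        assert int(counts.to_numpy().sum()) == len(calls)

    def test_unlabeled_sample_rejected(self):
        scores, clinical = self._scores_and_clinical(["sensitive-like"] * 4)
        with pytest.raises(KeyError):
            classify_cohort_by_subtype(scores, clinical.iloc[:2])
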