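"""The three generic enrichment engines, original archetypes and parallelism."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigscore.core import (
    SAMPLE_ID,
    DegenerateInputError,
    GeneSet,
    InputError,
    MethodParams,
    SignatureDefinition,
    UsageError,
)
from sigscore.methods import (
    parallel_score,
    rank_sample,
    score_original,
    score_singscore,
    score_ssgsea,
    score_zscore,
    zscore_matrix,
)


def _rand_expr(rng, n_genes, n_samples):
    return pd.DataFrame(
        rng.normal(6, 1, size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )


class TestRankSample:
    @pytest.mark.parametrize(
        "values,tie_rule,expected",
        [
            ([5.0, 1.0, 3.0], "average", [3, 1, 2]),
            ([2.0, 2.0, 1.0], "average", [2.5, 2.5, 1]),
            ([7.0, 7.0, 7.0, 7.0], "average", [2.5, 2.5, 2.5, 2.5]),
            ([2.0, 2.0, 1.0], "min", [2, 2, 1]),
            ([2.0, 2.0, 1.0], "max", [3, 3, 1]),
        ],
    )
    def test_examples(self, values, tie_rule, expected):
        assert rank_sample(values, tie_rule).tolist() == expected

    def test_short_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            rank_sample([1.0])

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30))
    def test_average_rank_sum_invariant(self, values):
        ranks = rank_sample(values, "average")
        n = len(values)
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)


class TestCombinedZscore:
    def test_worked_two_by_two(self):
        expr = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 6.0]}, index=["g1", "g2"])
        out = score_zscore(expr, {"S": ["g1", "g2"]})
        assert out["S"].to_numpy() == pytest.approx([-1.0, 1.0])

    def test_singleton_set_equals_z_row(self, random_expr):
        z = zscore_matrix(random_expr)
        out = score_zscore(random_expr, {"solo": [random_expr.index[5]]})
        assert out["solo"].to_numpy() == pytest.approx(
            z.iloc[5].to_numpy(), abs=1e-12
        )

    def test_shift_invariance(self, random_expr):
        sets = {"S": list(random_expr.index[:7])}
        a = score_zscore(random_expr, sets)
        b = score_zscore(random_expr + 11.5, sets)
        assert a["S"].to_numpy() == pytest.approx(b["S"].to_numpy(), abs=1e-9)

    def test_z_rows_standardized(self, random_expr):
        z = zscore_matrix(random_expr).to_numpy()
        assert z.mean(axis=1) == pytest.approx(np.zeros(z.shape[0]), abs=1e-12)
        assert z.std(axis=1, ddof=1) == pytest.approx(np.ones(z.shape[0]), abs=1e-12)

    def test_zero_variance_gene_scores_zero(self, caplog):
        expr = pd.DataFrame(
            {"a": [5.0, 1.0], "b": [5.0, 2.0], "c": [5.0, 3.0]},
            index=["flat", "vary"],
        )
        with caplog.at_level(logging.WARNING, logger="sigscore"):
            out = score_zscore(expr, {"S": ["flat"]})
        assert out["S"].to_numpy() == pytest.approx([0.0, 0.0, 0.0])
        assert "zero-variance" in caplog.text

    def test_absent_set_gives_na_column(self, random_expr, caplog):
        with caplog.at_level(logging.WARNING, logger="sigscore"):
            out = score_zscore(random_expr, {"ghost": ["NOPE1", "NOPE2"]})
        assert out["ghost"].isna().all()
        assert "no genes present" in caplog.text


class TestSsgsea:
    def test_worked_three_gene_example(self):
        # ranks g1=3, g2=2, g3=1; S={g1}, alpha=1 -> ES = 1 + 0.5 + 0 = 1.5
        expr = pd.DataFrame({"s1": [3.0, 2.0, 1.0], "s2": [3.0, 2.0, 1.0]},
                            index=["g1", "g2", "g3"])
        out = score_ssgsea(expr, {"S": ["g1"]},
                           MethodParams(method="ssgsea", ssgsea_exponent=1.0))
        assert out["S"].to_numpy() == pytest.approx([1.5, 1.5])

    def test_singleton_set_alpha_independent(self):
        expr = pd.DataFrame({"s1": [3.0, 2.0, 1.0]} , index=["g1", "g2", "g3"])
        expr["s2"] = expr["s1"]
        es = {
            a: score_ssgsea(
                expr, {"S": ["g1"]}, MethodParams(method="ssgsea", ssgsea_exponent=a)
            )["S"].iloc[0]
            for a in (0.0, 0.25, 1.0)
        }
        assert es[0.0] == es[0.25] == es[1.0] == pytest.approx(1.5)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_brute_force_oracle(self, ssgsea_oracle, alpha):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(5, 50))
            k = int(rng.integers(1, min(10, n - 1) + 1))
            expr = _rand_expr(rng, n, 3)
            members = list(rng.choice(expr.index, size=k, replace=False))
            out = score_ssgsea(
                expr, {"S": members}, MethodParams(method="ssgsea", ssgsea_exponent=alpha)
            )
            mask = expr.index.isin(members)
            for j, col in enumerate(expr.columns):
                expected = ssgsea_oracle(expr[col].to_numpy(), mask, alpha)
                assert out["S"].iloc[j] == pytest.approx(expected, abs=1e-9)

    def test_monotone_transform_invariance(self, random_expr):
        sets = {"S": list(random_expr.index[:8])}
        a = score_ssgsea(random_expr, sets)
        b = score_ssgsea(np.exp(random_expr / 4.0), sets)
        assert a["S"].to_numpy() == pytest.approx(b["S"].to_numpy(), abs=1e-12)

    def test_set_covering_all_genes_rejected(self, toy_expr):
        with pytest.raises(InputError, match="every gene"):
            score_ssgsea(toy_expr, {"S": list(toy_expr.index)})

    def test_separate_normalization_unit_range(self, random_expr):
        params = MethodParams(method="ssgsea", ssgsea_norm="separate")
        out = score_ssgsea(
            random_expr,
            {"A": list(random_expr.index[:5]), "B": list(random_expr.index[10:20])},
            params,
        )
        for c in ("A", "B"):
            col = out[c].to_numpy()
            assert col.max() - col.min() == pytest.approx(1.0)

    def test_all_normalization_uses_global_range(self, random_expr):
        raw = score_ssgsea(
            random_expr, {"A": list(random_expr.index[:5]), "B": list(random_expr.index[5:9])}
        )
        out = score_ssgsea(
            random_expr,
            {"A": list(random_expr.index[:5]), "B": list(random_expr.index[5:9])},
            MethodParams(method="ssgsea", ssgsea_norm="all"),
        )
        vals = raw[["A", "B"]].to_numpy()
        rng_ = vals.max() - vals.min()
        assert out[["A", "B"]].to_numpy() == pytest.approx(vals / rng_)

    def test_zero_range_normalization_rejected(self):
        # identical samples -> identical scores -> zero range
        expr = pd.DataFrame(
            {"a": [3.0, 2.0, 1.0], "b": [3.0, 2.0, 1.0]}, index=["g1", "g2", "g3"]
        )
        with pytest.raises(InputError, match="zero score range"):
            score_ssgsea(
                expr, {"S": ["g1"]}, MethodParams(method="ssgsea", ssgsea_norm="separate")
            )


class TestSingscore:
    def _expr5(self):
        expr = pd.DataFrame({"s1": [5.0, 4.0, 3.0, 2.0, 1.0]}, index=list("abcde"))
        expr["s2"] = expr["s1"]
        return expr

    def test_top_two_genes_score_one_uncentered(self):
        out = score_singscore(
            self._expr5(), {"S": ["a", "b"]},
            MethodParams(method="singscore", singscore_center=False),
        )
        assert out["S"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_bottom_two_genes_score_zero_uncentered(self):
        out = score_singscore(
            self._expr5(), {"S": ["d", "e"]},
            MethodParams(method="singscore", singscore_center=False),
        )
        assert out["S"].to_numpy() == pytest.approx([0.0, 0.0])

    def test_bidirectional_extremes_total_one_centered(self):
        # up = top-2, down = bottom-2 -> 0.5 + 0.5
        out = score_singscore(
            self._expr5(), {"S": (["a", "b"], ["d", "e"])},
            MethodParams(method="singscore", singscore_center=True),
        )
        assert out["S"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_centering_shifts_by_half(self, random_expr):
        sets = {"S": list(random_expr.index[:6])}
        c = score_singscore(random_expr, sets, MethodParams(method="singscore"))
        u = score_singscore(
            random_expr, sets, MethodParams(method="singscore", singscore_center=False)
        )
        assert (u["S"] - c["S"]).to_numpy() == pytest.approx(np.full(8, 0.5))

    def test_matches_mean_rank_oracle(self, singscore_oracle):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            k = int(rng.integers(1, n))
            expr = _rand_expr(rng, n, 2)
            idx = rng.choice(n, size=k, replace=False)
            members = [expr.index[i] for i in idx]
            out = score_singscore(
                expr, {"S": members},
                MethodParams(method="singscore", singscore_center=False),
            )
            for j, col in enumerate(expr.columns):
                expected = singscore_oracle(expr[col].to_numpy(), idx, center=False)
                assert out["S"].iloc[j] == pytest.approx(expected, abs=1e-12)

    def test_set_spanning_all_genes_rejected(self, toy_expr):
        with pytest.raises(InputError, match="spanning"):
            score_singscore(toy_expr, {"S": list(toy_expr.index)})

    def test_monotone_transform_invariance(self, random_expr):
        sets = {"S": (list(random_expr.index[:5]), list(random_expr.index[40:44]))}
        a = score_singscore(random_expr, sets)
        b = score_singscore(random_expr ** 3, sets)  # values > 0, strictly monotone
        assert a["S"].to_numpy() == pytest.approx(b["S"].to_numpy(), abs=1e-12)

    def test_abs_median_centered_mode(self, random_expr):
        sets = {"S": list(random_expr.index[:6])}
        params = MethodParams(
            method="singscore", singscore_undirected_mode="abs_median_centered"
        )
        out = score_singscore(random_expr, sets, params)
        default = score_singscore(random_expr, sets)
        assert out.shape == default.shape
        assert not np.allclose(out["S"], default["S"])  # a genuinely different ranking

    def test_missing_down_genes_scores_up_only(self, random_expr, caplog):
        sets = {"S": (list(random_expr.index[:5]), ["NOPE"])}
        with caplog.at_level(logging.WARNING, logger="sigscore"):
            out = score_singscore(random_expr, sets)
        up_only = score_singscore(random_expr, {"S": list(random_expr.index[:5])})
        assert out["S"].to_numpy() == pytest.approx(up_only["S"].to_numpy())
        assert "no down genes present" in caplog.text


class TestScoreOriginal:
    def test_mean_archetype(self):
        expr = pd.DataFrame({"s": [2.0, 4.0]}, index=["g1", "g2"])
        expr["t"] = [1.0, 3.0]
        sig = SignatureDefinition(id="m", up_genes=("g1", "g2"), original_method="mean")
        out = score_original(expr, sig)
        assert out["m"].to_numpy() == pytest.approx([3.0, 2.0])

    def test_weighted_sum_archetype(self):
        expr = pd.DataFrame({"s": [5.0, 3.0]}, index=["g1", "g2"])
        sig = SignatureDefinition(
            id="w", up_genes=("g1", "g2"), original_method="weighted_sum",
            coefficients={"g1": 1.0, "g2": -1.0},
        )
        assert score_original(expr, sig)["w"].to_numpy() == pytest.approx([2.0])

    def test_all_zero_coefficients_give_zero(self, random_expr):
        genes = tuple(random_expr.index[:3])
        sig = SignatureDefinition(
            id="z", up_genes=genes, original_method="weighted_sum",
            coefficients={g: 0.0 for g in genes},
        )
        assert score_original(random_expr, sig)["z"].to_numpy() == pytest.approx(
            np.zeros(8)
        )

    def test_absent_gene_term_dropped_with_warning(self, caplog):
        expr = pd.DataFrame({"s": [5.0]}, index=["g1"])
        sig = SignatureDefinition(
            id="w", up_genes=("g1", "gX"), original_method="weighted_sum",
            coefficients={"g1": 2.0, "gX": 100.0},
        )
        with caplog.at_level(logging.WARNING, logger="sigscore"):
            out = score_original(expr, sig)
        assert out["w"].to_numpy() == pytest.approx([10.0])
        assert "absent" in caplog.text

    def test_dedicated_method_rejected(self, random_expr):
        sig = SignatureDefinition(
            id="d", up_genes=("g1",), original_method="dedicated_cinsarc"
        )
        with pytest.raises(UsageError):
            score_original(random_expr, sig)


class TestPermutationInvariance:
    @pytest.mark.parametrize("engine", [score_zscore, score_ssgsea, score_singscore])
    def test_gene_row_permutation_leaves_scores_unchanged(self, random_expr, engine):
        members = list(random_expr.index[3:9])
        rng = np.random.default_rng(0)
        perm = rng.permutation(random_expr.shape[0])
        shuffled = random_expr.iloc[perm]
        a = engine(random_expr, {"S": members})
        b = engine(shuffled, {"S": members[::-1]})  # set order permuted too
        assert a["S"].to_numpy() == pytest.approx(b["S"].to_numpy(), abs=1e-12)

    @pytest.mark.parametrize("engine", [score_zscore, score_ssgsea, score_singscore])
    def test_sample_permutation_permutes_rows(self, random_expr, engine):
        members = list(random_expr.index[3:9])
        perm = [5, 2, 7, 0, 1, 6, 3, 4]
        a = engine(random_expr, {"S": members})
        b = engine(random_expr.iloc[:, perm], {"S": members})
        assert b[SAMPLE_ID].tolist() == [a[SAMPLE_ID].iloc[i] for i in perm]
        assert b["S"].to_numpy() == pytest.approx(
            a["S"].to_numpy()[perm], abs=1e-12
        )


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(3)
    expr = _rand_expr(rng, 120, 9)
    sets = {
        "A": list(expr.index[:10]),
        "B": (list(expr.index[20:28]), list(expr.index[30:35])),
    }
    return expr, sets


class TestParallelScore:
    @pytest.mark.parametrize("method", ["zscore", "ssgsea", "singscore"])
    def test_workers_do_not_change_results(self, cohort, method):
        expr, sets = cohort
        params = MethodParams(method=method)
        serial = parallel_score(expr, sets, params, n_workers=1)
        parallel = parallel_score(expr, sets, params, n_workers=4)
        pd.testing.assert_frame_equal(serial, parallel)

    def test_more_workers_than_samples(self, cohort):
        expr, sets = cohort
        params = MethodParams(method="ssgsea")
        a = parallel_score(expr, sets, params, n_workers=1)
        b = parallel_score(expr, sets, params, n_workers=32)
        pd.testing.assert_frame_equal(a, b)

    def test_single_sample_any_workers(self, cohort):
        expr, sets = cohort
        one = expr.iloc[:, [0]]
        params = MethodParams(method="singscore")
        a = parallel_score(one, sets, params, n_workers=1)
        b = parallel_score(one, sets, params, n_workers=4)
        pd.testing.assert_frame_equal(a, b)

    def test_normalized_ssgsea_parallel_matches_serial(self, cohort):
        expr, sets = cohort
        params = MethodParams(method="ssgsea", ssgsea_norm="all")
        a = parallel_score(expr, sets, params, n_workers=1)
        b = parallel_score(expr, sets, params, n_workers=3)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_worker_count_rejected(self, cohort):
        expr, sets = cohort
        with pytest.raises(InputError):
            parallel_score(expr, sets, MethodParams(method="ssgsea"), n_workers=0)
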