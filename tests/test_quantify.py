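"""Label-free quantification statistics: filtering, normalization,
downshifted imputation, and the two-sample test."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_quant_table
from hdlstruct import quantify as Q


def two_group_design(n=5):
    groups = {f"a{i}": "A" for i in range(n)}
    groups.update({f"b{i}": "B" for i in range(n)})
    return groups


class TestFilterMissingness:
    def test_group_wise_rule(self):
        nan = float("nan")
        table = make_quant_table(
            {
                "kept_partial": [20, 21, 20, nan, nan, nan, nan, nan, nan, nan],
                "dropped": [20, 21, nan, nan, nan, 20, 21, nan, nan, nan],
                "kept_full": [20] * 10,
            },
            two_group_design(),
        )
        out = Q.filter_missingness(table, 0.5)
        assert set(out.values.index) == {"kept_partial", "kept_full"}

    def test_empty_table_errors(self):
        table = make_quant_table({"f": [20, 20, 20, 20]},
                                 {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        table.values = table.values.iloc[0:0]
        with pytest.raises(ValueError, match="empty"):
            Q.filter_missingness(table)


class TestMedianNormalize:
    def test_equalizes_to_grand_median(self):
        table = make_quant_table(
            {"f1": [19, 21], "f2": [20, 22], "f3": [21, 23]},
            {"s1": "A", "s2": "B"},
        )
        out = Q.median_normalize(table)
        medians = out.values.median(axis=0)
        assert np.allclose(medians, 21.0, atol=1e-12)

    def test_idempotent_and_single_column(self):
        rng = np.random.default_rng(0)
        table = make_quant_table(
            {f"f{i}": list(rng.normal(20, 2, 4)) for i in range(30)},
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        once = Q.median_normalize(table)
        twice = Q.median_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        single = make_quant_table({"f1": [20.0], "f2": [22.0]}, {"s1": "A"})
        pd.testing.assert_frame_equal(
            Q.median_normalize(single).values, single.values)

    def test_all_missing_column_errors(self):
        nan = float("nan")
        table = make_quant_table({"f1": [20, nan], "f2": [21, nan]},
                                 {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="s2"):
            Q.median_normalize(table)


class TestImputeDownshift:
    def test_complete_table_is_identity(self):
        table = make_quant_table(
            {"f1": [20, 21, 22, 23], "f2": [19, 20, 21, 22]},
            {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        )
        out = Q.impute_downshift(table, seed=1)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_deterministic_and_preserves_observed(self):
        rng = np.random.default_rng(3)
        values = {f"f{i}": list(rng.normal(22, 2, 6)) for i in range(50)}
        table = make_quant_table(values, {f"s{i}": "AB"[i % 2]
                                          for i in range(6)})
        mask = rng.random(table.values.shape) < 0.2
        table.values = table.values.mask(mask)
        out1 = Q.impute_downshift(table, seed=7)
        out2 = Q.impute_downshift(table, seed=7)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        assert not out1.values.isna().any().any()
        observed = ~table.values.isna()
        assert (out1.values.to_numpy()[observed.to_numpy()]
                == table.values.to_numpy()[observed.to_numpy()]).all()

    def test_draws_match_stated_distribution(self):
        """Monte-Carlo check: with observed mean 25 and sd 1, imputations
        follow Normal(25 - 1.8, 0.3^2)."""
        rng = np.random.default_rng(11)
        n_obs, n_missing = 2000, 10000
        obs = rng.normal(0, 1, n_obs)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 1.0 + 25.0  # exact moments
        col = np.concatenate([obs, np.full(n_missing, np.nan)])
        table = make_quant_table({f"f{i}": [v] for i, v in enumerate(col)},
                                 {"s1": "A"})
        table.design["group"] = "A"
        out = Q.impute_downshift(table, seed=5)
        imputed = out.values.to_numpy().ravel()[n_obs:]
        assert imputed.mean() == pytest.approx(23.2, abs=0.02)
        assert imputed.std(ddof=1) == pytest.approx(0.3, abs=0.02)

    def test_too_few_observed_errors(self):
        nan = float("nan")
        table = make_quant_table({"f1": [20, nan], "f2": [nan, nan]},
                                 {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="fewer than 2"):
            Q.impute_downshift(table, seed=0)


class TestDifferential:
    def test_identical_groups_are_null(self):
        table = make_quant_table({"f1": [4, 5, 6, 4, 5, 6]},
                                 {"c1": "C", "c2": "C", "c3": "C",
                                  "e1": "E", "e2": "E", "e3": "E"})
        res = Q.differential(table, "C", "E", alpha=0.999)
        assert res.loc[0, "log2fc"] == 0.0
        assert res.loc[0, "p_value"] == pytest.approx(1.0)
        assert not res.loc[0, "significant"]

    def test_planted_shift_recovered(self):
        """A +1 log2 shift at sd 0.1 and n = 5/5 is detected at p < 0.01 in
        >= 99% of seeds, and the fold-change estimate lands in [0.9, 1.1]
        at the rate predicted by the closed-form sampling distribution."""
        from scipy import stats
        sig = in_band = 0
        estimates = []
        n_seeds = 400
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ctrl = rng.normal(20.0, 0.1, 5)
            expt = rng.normal(21.0, 0.1, 5)
            table = make_quant_table(
                {"f": list(ctrl) + list(expt)},
                {**{f"c{i}": "C" for i in range(5)},
                 **{f"e{i}": "E" for i in range(5)}},
            )
            res = Q.differential(table, "C", "E", alpha=0.01)
            sig += bool(res.loc[0, "significant"])
            in_band += 0.9 <= res.loc[0, "log2fc"] <= 1.1
            estimates.append(res.loc[0, "log2fc"])
        assert sig / n_seeds >= 0.99
        assert np.mean(estimates) == pytest.approx(1.0, abs=0.02)
        # closed-form oracle: difference of means ~ N(1, 0.1^2 * 2/5)
        se = 0.1 * np.sqrt(2 / 5)
        expected_coverage = 2 * stats.norm.cdf(0.1 / se) - 1
        assert in_band / n_seeds == pytest.approx(expected_coverage, abs=0.06)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        table = make_quant_table(
            {f"f{i}": list(rng.normal(20, 1, 10)) for i in range(20)},
            two_group_design(),
        )
        ab = Q.differential(table, "A", "B")
        ba = Q.differential(table, "B", "A")
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p_value"], ba["p_value"])

    def test_small_group_errors(self):
        table = make_quant_table({"f": [1, 2, 3]},
                                 {"c1": "C", "c2": "C", "e1": "E"})
        with pytest.raises(ValueError, match=">= 2 samples"):
            Q.differential(table, "C", "E")


def test_benjamini_hochberg_monotone():
    res = pd.DataFrame({"feature_id": list("abcd"),
                        "log2fc": [1, 2, 3, 4],
                        "p_value": [0.001, 0.01, 0.02, 0.9],
                        "significant": [True] * 4})
    out = Q.benjamini_hochberg(res, alpha=0.05)
    assert (out.sort_values("p_value")["q_value"].diff().dropna() >= 0).all()
    assert (out["q_value"] >= out["p_value"]).all()
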