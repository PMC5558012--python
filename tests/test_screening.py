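"""Correlation analysis, outlier flagging, and 2D candidate ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from solscreen.screening import (
    correlate,
    flag_outliers,
    load_reference_panel,
    pearson,
    rank_agreement,
    rank_candidates,
)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_vh_score_tracks_measured_solubility(self, reference_panel):
        """VH score vs PEG midpoint without the known outlier: R = 0.97."""
        df = reference_panel[reference_panel.index != "mAb3"]
        res = pearson(df["score_vh"], df["peg_half"])
        assert res.n == 8
        assert res.r == pytest.approx(0.97, abs=0.005)
        assert res.p_value < 1e-4

    def test_combined_score_tracks_measured_solubility(self, reference_panel):
        df = reference_panel[reference_panel.index != "mAb3"]
        res = pearson(df["score_combined"], df["peg_half"])
        assert res.r == pytest.approx(0.93, abs=0.005)
        assert res.p_value < 1e-3

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r0 = pearson(x, y).r
        assert pearson(3 * x + 2, y).r == pytest.approx(r0)
        assert pearson(-x, y).r == pytest.approx(-r0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])


class TestCorrelate:
    def test_without_exclusion_correlation_degrades(self, reference_panel):
        vh = correlate(reference_panel, "score_vh", "peg_half")
        comb = correlate(reference_panel, "score_combined", "peg_half")
        assert vh.r == pytest.approx(0.79, abs=0.005)
        assert comb.r == pytest.approx(0.68, abs=0.005)
        assert vh.excluded == ()

    def test_exclusion_recorded_and_equivalent_to_manual_filter(
        self, reference_panel
    ):
        res = correlate(
            reference_panel, "score_vh", "peg_half", exclude={"mAb3"}
        )
        manual = reference_panel[reference_panel.index != "mAb3"]
        expected = pearson(manual["score_vh"], manual["peg_half"])
        assert res.excluded == ("mAb3",)
        assert res.r == pytest.approx(expected.r)
        assert res.p_value == pytest.approx(expected.p_value)

    def test_log_response_option(self, reference_panel):
        res = correlate(
            reference_panel,
            "peg_half",
            "apparent_solubility",
            log_response=True,
        )
        lin = correlate(reference_panel, "peg_half", "apparent_solubility")
        assert res.r > lin.r

    def test_unknown_exclusion_warns(self, reference_panel):
        with pytest.warns(UserWarning, match="not in table"):
            correlate(
                reference_panel, "score_vh", "peg_half", exclude={"nope"}
            )

    def test_too_few_rows_after_exclusion(self, reference_panel):
        too_many = set(reference_panel.index[:-2])
        with pytest.raises(ValueError, match=">= 3"):
            correlate(
                reference_panel, "score_vh", "peg_half", exclude=too_many
            )

    def test_missing_column_rejected(self, reference_panel):
        with pytest.raises(ValueError, match="not in table"):
            correlate(reference_panel, "nope", "peg_half")


class TestFlagOutliers:
    def test_reference_panel_flags_the_known_outlier(self, reference_panel):
        assert flag_outliers(reference_panel, "score_vh", "peg_half") == {"mAb3"}

    def test_collinear_data_flags_nothing(self):
        x = np.arange(6.0)
        df = pd.DataFrame({"x": x, "y": 2 * x}, index=[f"v{i}" for i in range(6)])
        assert flag_outliers(df, "x", "y") == set()

    def test_infinite_threshold_flags_nothing(self, reference_panel):
        assert (
            flag_outliers(
                reference_panel, "score_vh", "peg_half", threshold=np.inf
            )
            == set()
        )

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            flag_outliers(df, "x", "y")


def brute_force_pareto(table, b_col, s_col):
    ids = list(table.index)
    b = table[b_col].to_numpy(float)
    s = table[s_col].to_numpy(float)
    front = set()
    for i in range(len(ids)):
        dominated = any(
            (b[j] >= b[i] and s[j] >= s[i]) and (b[j] > b[i] or s[j] > s[i])
            for j in range(len(ids))
            if j != i
        )
        if not dominated:
            front.add(ids[i])
    return front


class TestRankCandidates:
    def test_orientation_must_be_declared(self, reference_panel):
        with pytest.raises(ValueError, match="orientation"):
            rank_candidates(reference_panel, "score_vh", "peg_half")

    def test_dominating_variant_ranks_first(self):
        df = pd.DataFrame(
            {"bind": [5.0, 3, 1], "sol": [2.0, 1, 0]}, index=["a", "b", "c"]
        )
        res = rank_candidates(
            df, "bind", "sol",
            binding_higher_is_better=True, solubility_higher_is_better=True,
        )
        assert res.pareto_front == {"a"}
        assert res.order[0] == "a"

    def test_tied_solubility_better_binder_first(self):
        df = pd.DataFrame(
            {"bind": [3.0, 5.0], "sol": [1.0, 1.0]}, index=["x", "y"]
        )
        res = rank_candidates(
            df, "bind", "sol",
            binding_higher_is_better=True, solubility_higher_is_better=True,
        )
        assert res.order == ["y", "x"]

    def test_lower_is_better_orientation(self):
        # off-rates: smaller = tighter binder
        df = pd.DataFrame(
            {"koff": [1e-4, 1e-2], "sol": [1.0, 1.0]}, index=["tight", "loose"]
        )
        res = rank_candidates(
            df, "koff", "sol",
            binding_higher_is_better=False, solubility_higher_is_better=True,
        )
        assert res.order[0] == "tight"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_front_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        df = pd.DataFrame(
            {"bind": rng.normal(size=n), "sol": rng.normal(size=n)},
            index=[f"v{i}" for i in range(n)],
        )
        res = rank_candidates(
            df, "bind", "sol",
            binding_higher_is_better=True, solubility_higher_is_better=True,
        )
        assert res.pareto_front == brute_force_pareto(df, "bind", "sol")

    def test_front_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            {"bind": rng.normal(size=15), "sol": rng.normal(size=15)},
            index=[f"v{i}" for i in range(15)],
        )
        transformed = df.assign(bind=np.exp(df["bind"]), sol=df["sol"] ** 3)
        kw = dict(binding_higher_is_better=True, solubility_higher_is_better=True)
        assert (
            rank_candidates(df, "bind", "sol", **kw).pareto_front
            == rank_candidates(transformed, "bind", "sol", **kw).pareto_front
        )


class TestRankAgreement:
    def test_identical_rankings(self):
        assert rank_agreement([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_reversed_rankings(self):
        assert rank_agreement([1, 2, 3, 4], [9, 7, 5, 3]) == -1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_kendall_tau_for_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.permutation(12).astype(float)
        o = rng.permutation(12).astype(float)
        tau = stats.kendalltau(p, o).statistic
        assert rank_agreement(p, o) == pytest.approx(tau)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_agreement([1, 2], [1, 2, 3])


class TestReferencePanel:
    def test_shape_and_ids(self, reference_panel):
        assert len(reference_panel) == 9
        assert list(reference_panel.index) == [f"mAb{i}" for i in range(1, 10)]

    def test_ci_bounds_bracket_estimates(self, reference_panel):
        assert (
            (reference_panel["peg_half_lo"] <= reference_panel["peg_half"])
            & (reference_panel["peg_half"] <= reference_panel["peg_half_hi"])
        ).all()

    def test_checksum_verification(self):
        import hashlib
        from importlib import resources

        raw = resources.files("solscreen.data").joinpath("reference_panel.tsv").read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        assert load_reference_panel(checksum=digest) is not None
        with pytest.raises(ValueError, match="checksum"):
            load_reference_panel(checksum="0" * 64)
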