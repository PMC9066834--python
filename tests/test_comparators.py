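"""Bootstrap-imputation, RFE, MIA and complete-case selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rrbart.bart import BartParams
from rrbart.comparators import (
    BootstrapSelectionConfig,
    _mia_encode,
    bi_select,
    complete_case_select,
    mia_select,
    select_complete,
    votes_to_selection,
    xgb_rfe,
)
from rrbart.simulation import (
    IncompleteDataset,
    ScenarioConfig,
    ampute,
    default_amputation_config,
    generate_complete,
)

FAST_IMP = dict(rf_params={"n_estimators": 15}, max_iter=2)
FAST_XGB = {"n_estimators": 40}


class TestVoteThreshold:
    def test_ceiling_arithmetic(self):
        votes = {"a": 10, "b": 9}
        assert votes_to_selection(votes, B=100, pi=0.1) == ["a"]

    def test_pi_one_is_intersection(self):
        votes = {"a": 5, "b": 4}
        assert votes_to_selection(votes, B=5, pi=1.0) == ["a"]

    def test_pi_monotonicity_on_fixed_votes(self):
        rng = np.random.default_rng(0)
        votes = {f"v{i}": int(rng.integers(0, 21)) for i in range(15)}
        prev = None
        for pi in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
            cur = set(votes_to_selection(votes, B=20, pi=pi))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_config_validation(self):
        with pytest.raises(ValueError, match="pi"):
            BootstrapSelectionConfig(B=10, pi=0.0)
        with pytest.raises(ValueError, match="B"):
            BootstrapSelectionConfig(B=0, pi=0.5)
        with pytest.raises(ValueError, match="method"):
            BootstrapSelectionConfig(B=5, pi=0.5, method="lasso")


class TestXgbRfe:
    def test_single_feature_returned(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"only": rng.standard_normal(200)})
        y = (rng.random(200) < expit(2 * X["only"])).astype(float)
        assert xgb_rfe(X, y, xgb_params=FAST_XGB, seed=2) == ["only"]

    def test_dominant_feature_retained(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(10 + seed)
            X = pd.DataFrame(rng.standard_normal((300, 6)),
                             columns=[f"v{i}" for i in range(6)])
            y = (rng.random(300) < expit(-1 + 3 * X["v0"])).astype(float)
            sel = xgb_rfe(X, y, xgb_params=FAST_XGB, n_folds=3, seed=seed)
            hits += int("v0" in sel)
        assert hits >= 4

    def test_duplicated_feature_one_copy_survives(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(300)
        X = pd.DataFrame({"orig": base, "copy": base.copy(),
                          "junk": rng.standard_normal(300)})
        y = (rng.random(300) < expit(2 * base)).astype(float)
        sel = xgb_rfe(X, y, xgb_params=FAST_XGB, n_folds=3, seed=4)
        assert ("orig" in sel) or ("copy" in sel)

    def test_constant_outcome_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            xgb_rfe(X, np.zeros(10))


class TestMia:
    def test_encoding_reduces_to_identity_without_missingness(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        enc, parent = _mia_encode(X, for_bart=True)
        pd.testing.assert_frame_equal(enc, X)
        assert parent == {"a": "a", "b": "b"}

    def test_encoding_realizes_three_rules(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        enc, parent = _mia_encode(X, for_bart=True)
        assert set(enc.columns) == {"a__mlo", "a__mhi", "a__miss"}
        assert enc["a__mlo"][1] < enc["a__mlo"].drop(1).min()
        assert enc["a__mhi"][1] > enc["a__mhi"].drop(1).max()
        assert enc["a__miss"].tolist() == [0.0, 1.0, 0.0]
        assert all(v == "a" for v in parent.values())

    def test_missingness_indicator_signal_is_detected(self):
        # y is driven (almost) solely by whether the covariate is missing
        rng = np.random.default_rng(5)
        n = 400
        miss = rng.random(n) < 0.5
        a = rng.standard_normal(n)
        a[miss] = np.nan
        y = (rng.random(n) < np.where(miss, 0.9, 0.1)).astype(float)
        data = IncompleteDataset(
            X=pd.DataFrame({"a": a, "b": rng.standard_normal(n)}),
            y=pd.Series(y, name="y"), binary_cols=[])
        sel = mia_select(data, method="xgb", xgb_params=FAST_XGB, seed=6)
        assert "a" in sel

    def test_exclude_missing_y_equals_subset_analysis(self):
        d = generate_complete(ScenarioConfig(n=300, n_noise=0, seed=7))
        inc = ampute(d, default_amputation_config("high"), seed=8)
        keep = ~inc.y.isna()
        subset = IncompleteDataset(
            X=inc.X.loc[keep].reset_index(drop=True),
            y=inc.y.loc[keep].reset_index(drop=True),
            truth=inc.truth, binary_cols=inc.binary_cols)
        a = mia_select(inc, method="xgb", y_mode="exclude_missing_y",
                       xgb_params=FAST_XGB, seed=9)
        b = mia_select(subset, method="xgb", y_mode="impute_y",
                       xgb_params=FAST_XGB, seed=9)
        assert a == b

    def test_bad_y_mode(self):
        d = generate_complete(ScenarioConfig(n=60, n_noise=0, seed=1))
        inc = IncompleteDataset(X=d.X, y=d.y, binary_cols=d.binary_cols)
        with pytest.raises(ValueError, match="y_mode"):
            mia_select(inc, y_mode="drop")


class TestCompleteCase:
    def test_empty_mask_equals_complete_selection(self):
        d = generate_complete(ScenarioConfig(n=250, n_noise=0, seed=11))
        inc = IncompleteDataset(X=d.X, y=d.y, truth=d.truth,
                                binary_cols=d.binary_cols)
        a = complete_case_select(inc, method="xgb", xgb_params=FAST_XGB, seed=12)
        b = select_complete(d.X, d.y.to_numpy(float), method="xgb",
                            xgb_params=FAST_XGB, seed=12)
        assert a == b

    def test_complete_rows_match_overall_missingness(self):
        d = generate_complete(ScenarioConfig(n=2000, n_noise=0, seed=13))
        inc = ampute(d, default_amputation_config("high"), seed=14)
        keep = ~(inc.X.isna().any(axis=1) | inc.y.isna())
        assert keep.mean() == pytest.approx(1 - inc.meta["realized_overall"],
                                            abs=1e-12)
        assert keep.mean() == pytest.approx(0.4, abs=0.03)

    def test_no_complete_rows_rejected(self):
        X = pd.DataFrame({"a": [np.nan, 1.0], "b": [1.0, np.nan]})
        y = pd.Series([0.0, 1.0], name="y")
        with pytest.raises(ValueError, match="complete cases"):
            complete_case_select(IncompleteDataset(X=X, y=y, binary_cols=[]),
                                 method="xgb")


class TestBiSelect:
    def test_bootstrap_votes_and_determinism(self):
        d = generate_complete(ScenarioConfig(n=250, n_noise=0, seed=15))
        inc = ampute(d, default_amputation_config("high"), seed=16)
        cfg = BootstrapSelectionConfig(
            B=4, pi=0.5, method="xgb", xgb_params=FAST_XGB,
            impute_params=FAST_IMP, seed=17)
        sel1, votes1 = bi_select(inc, cfg)
        sel2, votes2 = bi_select(inc, cfg)
        assert votes1 == votes2 and sel1 == sel2
        assert set(votes1) == set(inc.X.columns)
        assert all(0 <= v <= 4 for v in votes1.values())
        # the strongest predictor should receive at least one vote
        assert votes1["X1"] >= 1

    def test_bart_variant_runs(self, small_incomplete):
        _, inc = small_incomplete
        cfg = BootstrapSelectionConfig(
            B=2, pi=0.5, method="bart", n_perm=5,
            bart_params=BartParams(m=10, n_draws=50, burn_in=50),
            impute_params=FAST_IMP, seed=18)
        sel, votes = bi_select(inc, cfg)
        assert set(votes) == set(inc.X.columns)
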