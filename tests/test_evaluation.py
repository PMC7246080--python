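"""Feature ranking, cross-validation protocols and residual summaries."""

import numpy as np
import pandas as pd
import pytest

from ctvshift import (rank_features, residual_summary, run_lcv, run_validation)
from ctvshift.features import FEATURE_COLUMNS


def _table_from_arrays(X: np.ndarray, si: np.ndarray, ap: np.ndarray,
                       n_patients: int) -> pd.DataFrame:
    n = len(si)
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df.insert(0, "patient_id", [f"P{i % n_patients}" for i in range(n)])
    df.insert(1, "fraction", np.arange(n))
    df["si"] = si
    df["ap"] = ap
    return df


@pytest.fixture(scope="module")
def linear_f3_table():
    """380 fractions over 10 patients; shifts are noiseless linear in f3."""
    r = np.random.default_rng(77)
    X = r.normal(0, 3, size=(380, 9))
    y = -0.4 * X[:, 2]
    return _table_from_arrays(X, y, y, 10)


class TestRanking:
    def test_dominant_feature_ranked_first(self, linear_f3_table):
        assert rank_features(linear_f3_table).order[0] == "f3"

    def test_null_features_show_no_correlation(self):
        r = np.random.default_rng(11)
        X = r.normal(size=(380, 9))
        tab = _table_from_arrays(X, r.normal(size=380), r.normal(size=380), 10)
        ranking = rank_features(tab)
        assert max(ranking.mean_abs_rho.values()) < 0.2

    def test_duplicate_feature_tie_broken_by_index(self):
        r = np.random.default_rng(12)
        X = r.normal(size=(60, 9))
        X[:, 6] = X[:, 2]   # f7 duplicates f3
        y = X[:, 2] + r.normal(0, 0.1, 60)
        ranking = rank_features(_table_from_arrays(X, y, y, 3))
        assert ranking.order.index("f3") < ranking.order.index("f7")

    def test_nested_subsets(self, linear_f3_table):
        ranking = rank_features(linear_f3_table)
        for k in range(1, 10):
            assert ranking.subset(k) == ranking.order[:k]
        with pytest.raises(ValueError):
            ranking.subset(0)


class TestLCV:
    def test_noiseless_linear_recovery(self, linear_f3_table):
        table = run_lcv(linear_f3_table, "svr", 1,
                        hyperparameters={"epsilon": 0.01}, seed=0)
        assert residual_summary(table)["pooled"]["mean"] < 0.1

    def test_each_fraction_predicted_exactly_once(self, linear_f3_table):
        two = linear_f3_table[linear_f3_table["patient_id"].isin(["P0", "P1"])]
        table = run_lcv(two, "rf", 1, seed=0)
        per_dir = table[table["direction"] == "si"]
        assert len(per_dir) == len(two)
        assert set(map(tuple, per_dir[["patient_id", "fraction"]].to_numpy())) \
            == set(map(tuple, two[["patient_id", "fraction"]].to_numpy()))

    def test_single_patient_rejected(self, linear_f3_table):
        one = linear_f3_table[linear_f3_table["patient_id"] == "P0"]
        with pytest.raises(ValueError, match="2 patients"):
            run_lcv(one, "svr", 1)

    def test_out_of_sample_not_better_than_training(self, small_features):
        # with noisy targets, held-out residuals exceed training residuals
        from ctvshift.regressors import train
        cols = rank_features(small_features).subset(1)
        lcv = residual_summary(run_lcv(small_features, "rf", 1, seed=1))
        model = train(small_features[cols].to_numpy(),
                      small_features["si"].to_numpy(), "rf", seed=1,
                      direction="si")
        train_mae = np.mean(np.abs(
            small_features["si"].to_numpy()
            - model.predict(small_features[cols].to_numpy())))
        assert lcv["si"]["mean"] >= train_mae


class TestValidation:
    def test_held_out_cohort_recovery(self, linear_f3_table):
        train_tab = linear_f3_table[~linear_f3_table["patient_id"].isin(["P8", "P9"])]
        val_tab = linear_f3_table[linear_f3_table["patient_id"].isin(["P8", "P9"])]
        table = run_validation(train_tab, val_tab, "svr", 1,
                               hyperparameters={"epsilon": 0.01}, seed=0)
        assert residual_summary(table)["pooled"]["mean"] < 0.1

    def test_patient_overlap_rejected(self, linear_f3_table):
        with pytest.raises(ValueError, match="overlap"):
            run_validation(linear_f3_table, linear_f3_table.head(40), "svr", 1)


class TestResidualSummary:
    def test_constant_residuals(self):
        tab = pd.DataFrame({"direction": ["si"] * 3, "residual": [1.0, 1.0, 1.0]})
        s = residual_summary(tab)
        assert s["si"] == {"mean": 1.0, "sd": 0.0, "max": 1.0, "n": 3}

    def test_sample_standard_deviation(self):
        tab = pd.DataFrame({"direction": ["ap", "ap"], "residual": [0.0, 2.0]})
        s = residual_summary(tab)["ap"]
        assert s["mean"] == 1.0
        assert s["sd"] == pytest.approx(np.sqrt(2))   # (n-1) denominator
        assert s["max"] == 2.0

    def test_population_sd_option(self):
        tab = pd.DataFrame({"direction": ["ap", "ap"], "residual": [0.0, 2.0]})
        assert residual_summary(tab, ddof=0)["ap"]["sd"] == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            residual_summary(pd.DataFrame({"direction": [], "residual": []}))
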