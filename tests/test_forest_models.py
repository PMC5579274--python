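"""Partition-ensemble forests, tuning, importance, Cox baseline, risk groups."""

import numpy as np
import pandas as pd
import pytest

from radrisk.forest_models import (
    ClinicalRecord,
    assess_risk,
    encode_features,
    fit_cox_linear,
    permutation_importance,
    select_staging,
    stratified_subsample,
    train_forest,
    train_unadjusted_forest,
    tune_weight,
)
from radrisk.stats_core import roc_metrics
from radrisk.synthetic_gen import CohortSpec, make_cohort


def _cohort(seed=0, n=200, rate=0.15, coeffs=None, **kw):
    spec = CohortSpec(
        n=n, event_rate=rate,
        coefficients=coeffs or {"f1": 2.0, "f2": 1.5, "f3": 1.0},
        rng_seed=seed, **kw,
    )
    return make_cohort(spec).df


class TestClinicalRecord:
    def test_valid_record(self):
        r = ClinicalRecord(63.0, "oropharynx", 2, 1, 3)
        assert r.age == 63.0

    def test_invalid_type_rejected(self):
        with pytest.raises(ValueError):
            ClinicalRecord(63.0, "lung", 2, 1, 3)
        with pytest.raises(ValueError):
            ClinicalRecord(-1.0, "larynx", 2, 1, 3)


class TestEncodeFeatures:
    def test_one_hot_categorical_passthrough_continuous(self):
        df = _cohort(seed=1, coeffs={"f1": 2.0, "n_stage": 1.0})
        enc = encode_features(df, ("f1", "age", "hn_type", "n_stage"))
        assert "f1" in enc.columns and "age" in enc.columns
        assert sum(c.startswith("hn_type_") for c in enc.columns) == 4
        assert all(enc.dtypes == float)


class TestTrainForest:
    def test_prob_is_exact_mean_of_tree_votes(self):
        df = _cohort(seed=2)
        fo = train_forest(df, "event", ("f1", "f2"), n_boot=5, rng_seed=0)
        votes = fo.tree_votes(df)
        np.testing.assert_allclose(fo.predict_proba(df), votes.mean(axis=0))
        assert set(np.unique(votes)) <= {0.0, 1.0}

    def test_tree_count_equals_sum_of_partitions(self):
        df = _cohort(seed=3)
        fo = train_forest(df, "event", ("f1",), n_boot=7, rng_seed=1)
        boots = {b for b, _ in fo.tree_partition_ids}
        assert len(boots) == 7
        assert fo.n_trees == len(fo.tree_partition_ids)
        # ~15% events => P ~ 6 partitions per bootstrap
        assert fo.n_trees >= 7 * 3

    def test_nboot2_forced_partition_count(self):
        # 30 subjects, 10 events -> P = 2 per bootstrap (stratified draws keep
        # class counts) -> 2 bootstraps yield exactly 4 trees
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"x": rng.normal(size=30), "event": np.r_[np.ones(10, int), np.zeros(20, int)]},
            index=[f"p{i}" for i in range(30)],
        )
        fo = train_forest(df, "event", ("x",), n_boot=2, rng_seed=0)
        assert fo.n_trees == 4

    def test_no_events_errors(self):
        df = _cohort(seed=4).copy()
        df["event"] = 0
        with pytest.raises(ValueError, match="events"):
            train_forest(df, "event", ("f1",), n_boot=2, rng_seed=0)

    def test_determinism_under_seed(self):
        df = _cohort(seed=6)
        p1 = train_forest(df, "event", ("f1", "f2"), n_boot=5, rng_seed=9).predict_proba(df)
        p2 = train_forest(df, "event", ("f1", "f2"), n_boot=5, rng_seed=9).predict_proba(df)
        np.testing.assert_array_equal(p1, p2)

    def test_separable_cohort_high_auc_balanced(self):
        df = _cohort(seed=7, n=200, rate=0.15)
        te = _cohort(seed=7000, n=300, rate=0.15)
        fo = train_forest(df, "event", ("f1", "f2", "f3"), n_boot=40, rng_seed=2)
        r = roc_metrics(fo.predict_proba(te), te["event"].to_numpy())
        assert r.auc >= 0.85
        assert abs(r.sensitivity - r.specificity) <= 0.25


class TestImbalanceBenefit:
    def test_partition_ensemble_balances_sens_spec(self):
        """The adjustment shrinks |sens - spec| vs a plain bootstrap forest."""
        gaps_adj, gaps_un = [], []
        for s in range(6):
            tr = _cohort(seed=300 + s, n=200, rate=0.12)
            te = _cohort(seed=8000 + s, n=300, rate=0.12)
            y = te["event"].to_numpy()
            fo = train_forest(tr, "event", ("f1", "f2", "f3"), n_boot=30, rng_seed=s)
            r = roc_metrics(fo.predict_proba(te), y)
            un = train_unadjusted_forest(
                tr, "event", ("f1", "f2", "f3"), n_boot=fo.n_trees, rng_seed=s
            )
            ru = roc_metrics(un.predict_proba(te), y)
            gaps_adj.append(abs(r.sensitivity - r.specificity))
            gaps_un.append(abs(ru.sensitivity - ru.specificity))
        assert np.mean(gaps_adj) < np.mean(gaps_un)


class TestSubsampling:
    def test_split_preserves_event_proportion(self, rng):
        y = np.r_[np.ones(30, int), np.zeros(90, int)]
        tr, te = stratified_subsample(y, rng)
        assert len(tr) + len(te) == 120
        assert y[tr].sum() == 20 and y[te].sum() == 10  # exact 2:1 per class

    def test_select_staging_recovers_n_stage_signal(self):
        picks = []
        for s in range(5):
            df = _cohort(
                seed=500 + s, n=300, rate=0.25,
                coeffs={"n_stage": 2.5}, include_clinical=True,
            )
            picks.append(
                select_staging(df, "event", splits=10, n_boot=25, rng_seed=s)
            )
        assert sum(p == ("n_stage",) for p in picks) >= 4

    def test_select_staging_single_split_allowed(self):
        df = _cohort(seed=10, coeffs={"n_stage": 2.0}, include_clinical=True)
        out = select_staging(df, "event", splits=1, n_boot=4, rng_seed=0)
        assert out in (("t_stage",), ("n_stage",), ("t_stage", "n_stage"), ("tnm_stage",))

    def test_missing_stage_column_skipped_with_warning(self):
        df = _cohort(seed=11, coeffs={"n_stage": 2.0}, include_clinical=True)
        df = df.drop(columns=["tnm_stage"])
        with pytest.warns(UserWarning, match="tnm_stage"):
            out = select_staging(df, "event", splits=2, n_boot=4, rng_seed=0)
        assert "tnm_stage" not in out


class TestTuneWeight:
    def test_grid_of_length_one(self):
        df = _cohort(seed=12)
        w = tune_weight(df, "event", ("f1",), grid=[1.3], splits=2, n_boot=4, rng_seed=0)
        assert w == 1.3

    def test_returns_weight_from_grid(self):
        df = _cohort(seed=13)
        w = tune_weight(
            df, "event", ("f1", "f2"), grid=[0.8, 1.0, 1.2], splits=2, n_boot=5, rng_seed=1
        )
        assert w in (0.8, 1.0, 1.2)

    def test_balanced_data_keeps_near_identity_weight(self):
        import warnings as _w

        ws = []
        for s in range(5):
            df = _cohort(
                seed=600 + s, n=200, rate=0.5, coeffs={"f1": 1.5, "f2": 1.0}
            )
            with _w.catch_warnings():
                # balanced bootstraps may swap majority/minority roles
                _w.simplefilter("ignore", UserWarning)
                ws.append(
                    tune_weight(df, "event", ("f1", "f2"), splits=10, n_boot=15, rng_seed=s)
                )
        assert sum(0.8 <= w <= 1.3 for w in ws) >= 4

    def test_empty_grid_errors(self):
        df = _cohort(seed=14)
        with pytest.raises(ValueError):
            tune_weight(df, "event", ("f1",), grid=[], rng_seed=0)


class TestPermutationImportance:
    def test_noise_near_zero_signal_dominant(self):
        # importance is measured out of sample: on the training table itself a
        # forest rewards even pure-noise columns it overfitted on
        tr = _cohort(seed=15, n=250, rate=0.2, coeffs={"f1": 2.5})
        te = _cohort(seed=9151, n=250, rate=0.2, coeffs={"f1": 2.5})
        rng = np.random.default_rng(1)
        tr["pure_noise"] = rng.normal(size=len(tr))
        te["pure_noise"] = rng.normal(size=len(te))
        fo = train_forest(tr, "event", ("f1", "pure_noise"), n_boot=25, rng_seed=0)
        imp = permutation_importance(fo, te, "event", n_perm=50, rng_seed=0)
        assert imp["f1"] > imp["pure_noise"]
        assert abs(imp["pure_noise"]) <= 0.02

    def test_permuting_all_variables_destroys_auc(self):
        df = _cohort(seed=16, n=250, rate=0.2, coeffs={"f1": 2.5})
        fo = train_forest(df, "event", ("f1",), n_boot=25, rng_seed=0)
        rng = np.random.default_rng(0)
        aucs = []
        from radrisk.stats_core import auc_mann_whitney

        y = df.sort_index()["event"].to_numpy()
        for _ in range(30):
            shuffled = df.sort_index().copy()
            shuffled["f1"] = rng.permutation(shuffled["f1"].to_numpy())
            aucs.append(auc_mann_whitney(fo.predict_proba(shuffled), y))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestCox:
    def test_binary_covariate_recovers_log2_hazard(self):
        rng = np.random.default_rng(20)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        lam = 0.02 * np.exp(np.log(2.0) * x)
        t = rng.exponential(1.0 / lam)
        cens = rng.exponential(80, n)
        e = (t <= cens).astype(int)
        tt = np.minimum(t, cens)
        df = pd.DataFrame(
            {"x": x, "time_months": tt, "event": e},
            index=[f"p{i}" for i in range(n)],
        )
        model = fit_cox_linear(df, ["x"])
        assert model.coefficients[0] == pytest.approx(np.log(2.0), abs=0.1)

    def test_zero_variance_covariate_zero_coef(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=100),
                "flat": 1.0,
                "time_months": rng.exponential(20, 100),
                "event": rng.integers(0, 2, 100),
            },
            index=[f"p{i}" for i in range(100)],
        )
        df.loc[df.index[0], "event"] = 1
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_cox_linear(df, ["x", "flat"])
        assert model.coefficients[1] == 0.0

    def test_median_threshold_splits_groups_evenly(self):
        rng = np.random.default_rng(22)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=101),
                "time_months": rng.exponential(20, 101),
                "event": rng.integers(0, 2, 101),
            },
            index=[f"p{i}" for i in range(101)],
        )
        df.loc[df.index[0], "event"] = 1
        model = fit_cox_linear(df, ["x"])
        groups = model.risk_groups(df)
        lo, hi = (groups == "low").sum(), (groups == "high").sum()
        assert abs(lo - hi) <= 1


class TestAssessRisk:
    @pytest.mark.parametrize(
        "prob,mode,expected",
        [
            (0.2, "three", "low"),
            (1.0 / 3.0, "three", "medium"),
            (0.5, "three", "medium"),
            (2.0 / 3.0, "three", "high"),
            (1.0, "three", "high"),
            (0.5, "two", "low"),
            (0.500001, "two", "high"),
            (0.0, "two", "low"),
        ],
    )
    def test_boundaries(self, prob, mode, expected):
        assert assess_risk(prob, mode).risk_group == expected

    def test_vector_mode_partition(self, rng):
        probs = rng.random(50)
        g = assess_risk(probs, "three")
        assert len(g) == 50
        assert set(g) <= {"low", "medium", "high"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assess_risk(1.2, "two")
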