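import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pbsig import PlantConfig, generate_study
from pbsig.signature import (
    MetageneModel,
    PredictionSet,
    Signature,
    cross_predict,
    fit_metagene_model,
    labels_from_groups,
    loocv,
    predict_matrix,
    predict_probability,
    roc_summary,
    select_probes,
)
from pbsig.signature import _fit_probit_map

from conftest import make_matrix


# ---------------------------------------------------------------------------
# probe selection
# ---------------------------------------------------------------------------

class TestSelectProbes:
    def test_label_identical_probe_ranked_first(self):
        mx = make_matrix([[0.0, 0.0, 1.0, 1.0], [5.0, 1.0, 3.0, 2.0]])
        sig = select_probes(mx, [0, 0, 1, 1], k=2)
        assert sig.entries.iloc[0]["probe_id"] == "p0"
        assert sig.entries.iloc[0]["statistic"] == pytest.approx(1.0)
        assert sig.entries.iloc[0]["direction"] == "up"

    def test_hand_computed_toy_ranking(self):
        """Five probes with hand-computed Pearson r against (0,0,1,1)."""
        values = [
            [1.0, 2.0, 3.0, 4.0],    # r = 0.894
            [4.0, 3.0, 2.0, 1.0],    # r = -0.894
            [1.0, 1.0, 1.0, 2.0],    # r = 0.577
            [3.0, 1.0, 2.0, 1.0],    # r = -0.302
            [5.0, 5.0, 5.0, 5.0],    # constant, r = 0
        ]
        y = [0, 0, 1, 1]
        mx = make_matrix(values)
        full = select_probes(mx, y, k=5)
        expected_r = {"p0": 0.8944, "p1": -0.8944, "p2": 0.5774, "p3": -0.3015, "p4": 0.0}
        for _, row in full.entries.iterrows():
            assert row["statistic"] == pytest.approx(expected_r[row["probe_id"]], abs=1e-4)
        top2 = select_probes(mx, y, k=2)
        # |r| tie between p0 and p1 broken by probe id ascending
        assert top2.probe_ids == ["p0", "p1"]

    def test_constant_probe_statistic_zero(self):
        mx = make_matrix([[3.0, 3.0, 3.0, 3.0]])
        sig = select_probes(mx, [0, 1, 0, 1], k=1)
        assert sig.entries.iloc[0]["statistic"] == 0.0

    def test_default_k_on_study(self, exposure_cohorts):
        cohort, y = exposure_cohorts["high"]
        assert select_probes(cohort, y, k=250).k == 250

    def test_errors(self):
        mx = make_matrix([[1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError):
            select_probes(mx, [0, 0, 1, 1], k=2)
        with pytest.raises(ValueError):
            select_probes(mx, [1, 1, 1, 1], k=1)


# ---------------------------------------------------------------------------
# probit fitting
# ---------------------------------------------------------------------------

def _penalized_nll(beta0, beta1, scores, y, ridge):
    eta = beta0 + beta1 * np.asarray(scores)
    ll = np.sum(
        np.where(np.asarray(y) == 1, stats.norm.logcdf(eta), stats.norm.logcdf(-eta))
    )
    return -(ll - ridge * beta1**2)


def _grid_minimize(scores, y, ridge):
    """Independent oracle: iteratively refined grid search over (b0, b1)."""
    lo = np.array([-5.0, -5.0])
    hi = np.array([5.0, 5.0])
    best = None
    for _ in range(8):
        b0s = np.linspace(lo[0], hi[0], 41)
        b1s = np.linspace(lo[1], hi[1], 41)
        vals = np.array(
            [[_penalized_nll(a, b, scores, y, ridge) for b in b1s] for a in b0s]
        )
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = (b0s[i], b1s[j])
        span0 = (hi[0] - lo[0]) / 8
        span1 = (hi[1] - lo[1]) / 8
        lo = np.array([best[0] - span0, best[1] - span1])
        hi = np.array([best[0] + span0, best[1] + span1])
    return best


class TestProbitFit:
    def test_symmetric_separable_case(self):
        Z = np.column_stack([np.ones(4), [-1.0, -1.0, 1.0, 1.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        coef, diag = _fit_probit_map(Z, y)
        assert diag["converged"]
        probs = stats.norm.cdf(Z @ coef)
        assert (probs[:2] < 0.5).all() and (probs[2:] > 0.5).all()
        # symmetry puts the decision boundary exactly at score 0
        assert stats.norm.cdf(coef[0]) == pytest.approx(0.5, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        scores = [-2.0, -1.0, 1.0, 2.0]
        y = [0, 0, 1, 1]
        Z = np.column_stack([np.ones(4), scores])
        coef, _ = _fit_probit_map(Z, np.asarray(y, dtype=float), ridge=0.5)
        b0, b1 = _grid_minimize(scores, y, ridge=0.5)
        assert coef[0] == pytest.approx(b0, abs=1e-3)
        assert coef[1] == pytest.approx(b1, abs=1e-3)

    def test_single_class_labels_rejected(self):
        mx = make_matrix(np.random.default_rng(0).normal(size=(10, 6)))
        with pytest.raises(ValueError):
            fit_metagene_model(mx, [1, 1, 1, 1, 1, 1], k=5, m=1)

    def test_map_fit_is_deterministic(self, exposure_cohorts):
        cohort, y = exposure_cohorts["high"]
        a = fit_metagene_model(cohort, y, k=50, m=2)
        b = fit_metagene_model(cohort, y, k=50, m=2)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_bayes_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        mx = make_matrix(rng.normal(size=(30, 12)))
        y = [0] * 6 + [1] * 6
        a = fit_metagene_model(mx, y, k=10, m=2, mode="bayes", seed=11)
        b = fit_metagene_model(mx, y, k=10, m=2, mode="bayes", seed=11)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_m_too_large_rejected(self):
        mx = make_matrix(np.random.default_rng(1).normal(size=(8, 4)))
        with pytest.raises(ValueError):
            fit_metagene_model(mx, [0, 0, 1, 1], k=4, m=4)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

class TestPredict:
    def test_training_sample_projection_is_its_score_row(self):
        """x* = column j of the training matrix projects to row j of V_m."""
        rng = np.random.default_rng(7)
        mx = make_matrix(rng.normal(size=(40, 10)))
        y = [0] * 5 + [1] * 5
        model = fit_metagene_model(mx, y, k=20, m=3)
        X = mx.data.loc[model.signature.probe_ids].to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        V = Vt[:3].T
        proj = model.project(mx)
        # singular vectors are sign-ambiguous; compare up to the model's own basis
        np.testing.assert_allclose(np.abs(proj), np.abs(V), atol=1e-8)

    def test_zero_coefficients_give_half(self):
        rng = np.random.default_rng(0)
        mx = make_matrix(rng.normal(size=(10, 6)))
        model = fit_metagene_model(mx, [0, 0, 0, 1, 1, 1], k=5, m=2)
        model.coefficients = np.zeros_like(model.coefficients)
        assert predict_probability(model, mx.data.iloc[:, 0]) == pytest.approx(0.5)

    def test_missing_probe_listed(self, high_model):
        sample = pd.Series({"not_a_probe": 1.0})
        with pytest.raises(KeyError, match="probe"):
            predict_probability(high_model, sample)

    def test_fresh_exposed_sample_scores_high(self, default_study, high_model):
        """A new exposed sample built from the ground truth scores > 0.5."""
        matrix, truth = default_study
        rng = np.random.default_rng(123)
        sample = pd.Series(
            rng.normal(7.0, 1.5) + rng.normal(0, 1.0, size=matrix.n_probes),
            index=matrix.probe_ids,
        )
        # plant the high-dose effects
        for _, row in truth.iterrows():
            for part in row["direction"].split(";"):
                dose, direction = part.split(":")
                if dose == "high":
                    sample[row["probe_id"]] += 3.0 if direction == "up" else -3.0
        assert predict_probability(high_model, sample) > 0.5

    def test_global_constant_shift_invariance(self):
        """Adding one constant to every value (train and test) changes nothing."""
        rng = np.random.default_rng(5)
        values = rng.normal(size=(30, 8))
        y = [0] * 4 + [1] * 4
        m1 = fit_metagene_model(make_matrix(values), y, k=10, m=2)
        m2 = fit_metagene_model(make_matrix(values + 3.7), y, k=10, m=2)
        test = rng.normal(size=(30, 3))
        p1 = predict_matrix(m1, make_matrix(test))
        p2 = predict_matrix(m2, make_matrix(test + 3.7))
        np.testing.assert_allclose(p1, p2, atol=1e-9)


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

class TestLoocv:
    def test_one_prediction_per_sample(self, exposure_cohorts):
        cohort, y = exposure_cohorts["low"]
        assert cohort.n_samples == 22  # 15 exposed + 7 controls
        preds = loocv(cohort, y, k=250, m=2)
        assert len(preds.table) == 22
        assert preds.table["probability"].notna().all()

    def test_separable_study_classifies_every_fold(self, exposure_cohorts):
        cohort, y = exposure_cohorts["high"]
        preds = loocv(cohort, y, k=250, m=2, seed=42)
        tab = preds.table
        assert (tab.loc[tab["true_class"] == 1, "probability"] > 0.5).all()
        assert (tab.loc[tab["true_class"] == 0, "probability"] < 0.5).all()

    def test_permuted_labels_give_no_positive_signal(self, exposure_cohorts):
        """No-signal oracle: label permutation yields no genuine discrimination.

        Honest LOOCV with per-fold selection is pessimistically biased under
        the null — the held-out sample never follows the chance-selected
        probes, so null AUCs fall at or well below 0.5, never above it
        systematically.
        """
        cohort, y = exposure_cohorts["low"]
        aucs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(y)
            preds = loocv(cohort, y_perm, k=250, m=2, seed=seed)
            aucs.append(roc_summary(preds).auc)
        assert np.mean(aucs) < 0.6

    def test_single_probe_loocv_reduces_to_thresholding(self):
        """k = all probes, m = 1 on one probe ranks samples like the probe."""
        values = [[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]]
        y = [0, 0, 0, 1, 1, 1]
        preds = loocv(make_matrix(values), y, k=1, m=1)
        order = np.argsort(preds.table["probability"].to_numpy())
        np.testing.assert_array_equal(order, np.argsort(values[0]))

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            loocv(make_matrix([[1.0, 2.0]]), [0, 1], k=1, m=1)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _preds(pos, neg):
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(pos) + len(neg))],
            "true_class": [1] * len(pos) + [0] * len(neg),
            "probability": list(pos) + list(neg),
            "fold": "train",
        }
    )
    return PredictionSet(table)


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_summary(_preds([0.9, 0.8], [0.1, 0.2]))
        assert roc.auc == 1.0 and roc.sensitivity == 1.0 and roc.specificity == 1.0
        assert roc.p_value > 0

    def test_exhaustive_pair_counting_example(self):
        roc = roc_summary(_preds([0.9, 0.4], [0.6, 0.1]))
        assert roc.auc == pytest.approx(0.75)

    def test_threshold_counts(self):
        roc = roc_summary(_preds([0.9, 0.4], [0.1, 0.2]), threshold=0.5)
        assert roc.sensitivity == pytest.approx(0.5)
        assert roc.specificity == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_summary(_preds([0.9], []))

    @settings(max_examples=100, deadline=None)
    @given(
        pos=st.lists(st.integers(0, 4), min_size=1, max_size=6),
        neg=st.lists(st.integers(0, 4), min_size=1, max_size=6),
    )
    def test_auc_equals_brute_force_enumeration(self, pos, neg):
        """Mann-Whitney AUC agrees with counting all (pos, neg) pairs."""
        scale = [0.1, 0.3, 0.5, 0.7, 0.9]
        p = [scale[i] for i in pos]
        n = [scale[i] for i in neg]
        roc = roc_summary(_preds(p, n))
        wins = sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a, b in itertools.product(p, n)
        )
        assert roc.auc == pytest.approx(wins / (len(p) * len(n)))

    def test_hanley_mcneil_se_hand_value(self):
        # AUC=0.75, n_pos=n_neg=2: var = (A(1-A) + (Q1-A^2) + (Q2-A^2))/4
        roc = roc_summary(_preds([0.9, 0.4], [0.6, 0.1]))
        a = 0.75
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + (q1 - a * a) + (q2 - a * a)) / 4
        assert roc.auc_se == pytest.approx(np.sqrt(var))


# ---------------------------------------------------------------------------
# cross-prediction
# ---------------------------------------------------------------------------

class TestCrossPredict:
    def test_resubstitution_on_separable_training(self, exposure_cohorts, high_model):
        cohort, y = exposure_cohorts["high"]
        _, roc = cross_predict(high_model, cohort, y)
        assert roc.auc == 1.0

    def test_independent_null_cohorts_near_chance(self, high_model):
        """Cohorts whose planted probes are unrelated to the frozen model
        average out to chance-level discrimination."""
        aucs = []
        for seed in (100, 101, 102, 103, 104):
            mx, _ = generate_study(plant=PlantConfig(seed=seed))
            lo = mx.select_samples(timepoint="exposure").select_samples(
                group=["control", "low"]
            )
            _, roc = cross_predict(high_model, lo, labels_from_groups(lo, "low"))
            aucs.append(roc.auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.2

    def test_same_planted_probes_fully_recovered(self, default_study, high_model):
        """A fresh cohort with the same planted high-dose effects separates
        perfectly under the frozen model."""
        matrix, truth = default_study
        rng = np.random.default_rng(77)
        n = matrix.n_probes
        effect = np.zeros(n)
        lookup = {p: i for i, p in enumerate(matrix.probe_ids)}
        for _, row in truth.iterrows():
            for part in row["direction"].split(";"):
                dose, direction = part.split(":")
                if dose == "high":
                    effect[lookup[row["probe_id"]]] = 3.0 if direction == "up" else -3.0
        cols = {}
        y = []
        for j in range(14):
            exposed = j >= 7
            base = rng.normal(7.0, 1.5, size=n) + rng.normal(0, 1.0, size=n)
            cols[f"fresh_{j}"] = base + (effect if exposed else 0.0)
            y.append(int(exposed))
        fresh = make_matrix(
            np.column_stack(list(cols.values())),
            probe_ids=matrix.probe_ids,
            sample_ids=list(cols),
        )
        _, roc = cross_predict(high_model, fresh, y)
        assert roc.auc == 1.0

    def test_missing_probes_error(self, high_model):
        small = make_matrix([[1.0, 2.0]], probe_ids=["only_probe"])
        with pytest.raises(KeyError):
            cross_predict(high_model, small, [0, 1])


# ---------------------------------------------------------------------------
# serialization / planted recovery
# ---------------------------------------------------------------------------

class TestModelPersistence:
    def test_model_json_round_trip(self, tmp_path, exposure_cohorts, high_model):
        path = tmp_path / "model.json"
        high_model.to_json(path)
        again = MetageneModel.from_json(path)
        cohort, _ = exposure_cohorts["high"]
        np.testing.assert_allclose(
            predict_matrix(again, cohort), predict_matrix(high_model, cohort), atol=1e-12
        )

    def test_signature_tsv_round_trip(self, tmp_path, high_model):
        path = tmp_path / "sig.tsv"
        high_model.signature.save_tsv(path)
        again = Signature.load_tsv(path)
        assert again.probe_ids == high_model.signature.probe_ids


class TestPlantedRecovery:
    def test_signature_recovers_planted_probes(self, default_study, exposure_cohorts):
        """At delta = 3 sigma the 250-probe signature recovers >= 95% of the
        probes planted for its dose."""
        _, truth = default_study
        for dose in ("low", "high"):
            cohort, y = exposure_cohorts[dose]
            sig = select_probes(cohort, y, k=250)
            planted = set(
                truth.loc[truth["direction"].str.contains(f"{dose}:"), "probe_id"]
            )
            assert len(planted) == 250
            assert len(planted & set(sig.probe_ids)) >= 0.95 * 250
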