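"""ROC/AUC, group t-tests, logistic odds ratios, ANOVA/Tukey."""

import numpy as np
import pandas as pd
import pytest

from targetindex import (
    IndexScores,
    SimConfig,
    compare_groups,
    compare_predictors,
    generate_multi_cohort,
    logistic_fit,
    roc_auc,
    score_index,
    standardize,
    validate_index,
)
from targetindex.discovery import TargetIndexDefinition
from targetindex.validation import SeparationError

from conftest import make_clinical


def scores_of(values, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return IndexScores("idx", pd.Series(np.asarray(values, dtype=float), index=samples))


def pair_counting_auc(scores, labels):
    """Exhaustive concordant-pair counting oracle (ties count 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == "pCR"]
    neg = [s for s, l in zip(scores, labels) if l == "RD"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        s = scores_of(list(range(10)) + list(range(100, 110)))
        labels = make_clinical(["RD"] * 10 + ["pCR"] * 10)
        auc, p = roc_auc(s, labels)
        assert auc == 1.0
        assert p < 0.05

    def test_exhaustive_pair_counting_case(self):
        """(1,2,3,4) with (RD,pCR,RD,pCR): 3 of 4 pairs concordant -> 0.75."""
        s = scores_of([1, 2, 3, 4])
        labels = make_clinical(["RD", "pCR", "RD", "pCR"])
        auc, _ = roc_auc(s, labels)
        assert auc == pytest.approx(0.75, abs=1e-15)

    def test_null_labels_near_half(self, rng):
        vals = rng.normal(size=2000)
        resp = rng.permutation(["pCR"] * 400 + ["RD"] * 1600)
        auc, _ = roc_auc(scores_of(vals), make_clinical(list(resp)))
        assert 0.45 <= auc <= 0.55

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=60)
        labels = make_clinical(list(rng.permutation(["pCR"] * 15 + ["RD"] * 45)))
        auc1, _ = roc_auc(scores_of(vals), labels)
        auc2, _ = roc_auc(scores_of(np.exp(3 * vals) + 7), labels)
        assert auc1 == auc2

    def test_negation_complements(self, rng):
        vals = rng.normal(size=40)
        labels = make_clinical(list(rng.permutation(["pCR"] * 10 + ["RD"] * 30)))
        auc1, _ = roc_auc(scores_of(vals), labels)
        auc2, _ = roc_auc(scores_of(-vals), labels)
        assert auc1 + auc2 == pytest.approx(1.0, abs=1e-15)

    def test_matches_pair_counting_with_ties(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 9))
            vals = rng.integers(0, 4, size=n).astype(float)  # deliberate ties
            labels = ["pCR"] * (n // 2) + ["RD"] * (n - n // 2)
            auc, _ = roc_auc(scores_of(vals), make_clinical(labels))
            assert auc == pytest.approx(pair_counting_auc(vals, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="each response class"):
            roc_auc(scores_of([1, 2]), make_clinical(["pCR", "pCR"]))


class TestCompareGroups:
    def test_identical_groups(self):
        s = scores_of([1, 2, 3, 1, 2, 3])
        labels = make_clinical(["pCR"] * 3 + ["RD"] * 3)
        mean_rd, mean_pcr, t, p, _ = compare_groups(s, labels, "student")
        assert mean_rd == mean_pcr == 2.0
        assert t == 0.0 and p == 1.0

    def test_hand_computed_student_t(self):
        """(1,2,3) vs (4,5,6): pooled var 1, se sqrt(2/3) -> |t| = 3/0.8165."""
        s = scores_of([4, 5, 6, 1, 2, 3])
        labels = make_clinical(["pCR"] * 3 + ["RD"] * 3)
        mean_rd, mean_pcr, t, p, welch = compare_groups(s, labels, "student")
        assert (mean_rd, mean_pcr) == (2.0, 5.0)
        assert abs(t) == pytest.approx(3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=5e-4)
        assert not welch

    def test_label_swap_negates_t(self, rng):
        vals = rng.normal(size=30)
        resp = ["pCR"] * 10 + ["RD"] * 20
        s = scores_of(vals)
        _, _, t1, p1, _ = compare_groups(s, make_clinical(resp), "student")
        flipped = ["RD" if r == "pCR" else "pCR" for r in resp]
        _, _, t2, p2, _ = compare_groups(s, make_clinical(flipped), "student")
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_auto_rule_switches_to_welch(self, rng):
        tight = rng.normal(0, 0.1, size=40)
        wide = rng.normal(0, 5.0, size=40)
        s = scores_of(np.concatenate([tight, wide]))
        labels = make_clinical(["pCR"] * 40 + ["RD"] * 40)
        *_, welch = compare_groups(s, labels, "auto")
        assert welch
        s2 = scores_of(np.concatenate([tight, rng.normal(0, 0.1, size=40)]))
        *_, welch2 = compare_groups(s2, labels, "auto")
        assert not welch2

    def test_signal_detected_across_replicates(self):
        """With a real latent effect the pCR group mean exceeds RD nearly always."""
        wins = 0
        for rep in range(100):
            cfg = SimConfig(n_cohorts=1, n_samples=300, n_genes=100, n_pos=10, n_neg=5,
                            outcome_slope=1.0, seed=5000 + rep)
            (expr, clin), = generate_multi_cohort(cfg)[0]
            truth = generate_multi_cohort(cfg)[1][0]
            zm, _ = standardize(expr)
            idx = TargetIndexDefinition(
                truth.target_probe_id,
                frozenset(truth.true_positive_set) | {truth.target_probe_id},
                frozenset(truth.true_negative_set),
            )
            s = score_index(zm, idx)
            mean_rd, mean_pcr, *_ = compare_groups(s, clin, "auto")
            wins += mean_pcr > mean_rd
        assert wins >= 95


class TestLogisticFit:
    def test_null_predictor_odds_near_one(self, rng):
        resp = list(rng.permutation(["pCR"] * 400 + ["RD"] * 1600))
        labels = make_clinical(resp)
        preds = pd.DataFrame({"score": rng.normal(size=2000)}, index=labels.data.index)
        rows, _ = logistic_fit(labels, preds)
        assert 0.9 < rows[0].odds_ratio < 1.1

    def test_binary_cross_product_identity(self):
        """Single binary predictor: OR equals the 2x2 cross-product ratio."""
        x = [1] * 50 + [0] * 50
        y = ["pCR"] * 30 + ["RD"] * 20 + ["pCR"] * 10 + ["RD"] * 40
        labels = make_clinical(y)
        preds = pd.DataFrame({"x": x}, index=labels.data.index)
        rows, _ = logistic_fit(labels, preds)
        assert rows[0].odds_ratio == pytest.approx(6.0, abs=1e-6)
        assert rows[0].ci_low < 6.0 < rows[0].ci_high

    def test_rescaling_invariance(self, rng):
        vals = rng.normal(size=500)
        prob = 1 / (1 + np.exp(-(-1.4 + 0.8 * vals)))
        resp = np.where(rng.random(500) < prob, "pCR", "RD")
        labels = make_clinical(list(resp))
        p1 = pd.DataFrame({"score": vals}, index=labels.data.index)
        p2 = pd.DataFrame({"score": 10 * vals}, index=labels.data.index)
        r1, _ = logistic_fit(labels, p1)
        r2, _ = logistic_fit(labels, p2)
        assert np.log(r1[0].odds_ratio) == pytest.approx(10 * np.log(r2[0].odds_ratio), rel=1e-6)

    def test_age_entered_per_decade(self, rng):
        resp = list(rng.permutation(["pCR"] * 60 + ["RD"] * 240))
        age = rng.normal(50, 10, size=300)
        labels = make_clinical(resp, age=age)
        direct = pd.DataFrame({"score": age / 10.0}, index=labels.data.index)
        via_age = pd.DataFrame({"age": age}, index=labels.data.index)
        r_direct, _ = logistic_fit(labels, direct)
        r_age, _ = logistic_fit(labels, via_age)
        assert r_age[0].odds_ratio == pytest.approx(r_direct[0].odds_ratio, rel=1e-8)

    def test_multivariate_reports_model_auc(self, rng):
        cfg = SimConfig(n_cohorts=1, n_samples=400, n_genes=50, n_pos=5, n_neg=3,
                        outcome_slope=1.5, seed=77)
        (expr, clin), = generate_multi_cohort(cfg)[0]
        truth = generate_multi_cohort(cfg)[1][0]
        preds = pd.DataFrame(
            {"activity": truth.latent_activity, "noise": rng.normal(size=400)},
            index=clin.data.index,
        )
        rows, model_auc = logistic_fit(clin, preds, multivariate=True)
        assert {r.term for r in rows} == {"activity", "noise"}
        assert model_auc is not None and model_auc > 0.7
        for r in rows:
            assert r.ci_low <= r.odds_ratio <= r.ci_high

    def test_perfect_separation_raises(self):
        y = ["pCR"] * 10 + ["RD"] * 10
        labels = make_clinical(y)
        preds = pd.DataFrame({"x": [1.0] * 10 + [0.0] * 10}, index=labels.data.index)
        with pytest.raises(SeparationError):
            logistic_fit(labels, preds)

    def test_missing_covariate_rows_dropped(self, rng):
        resp = ["pCR"] * 20 + ["RD"] * 80
        age = list(rng.normal(50, 10, size=95)) + [np.nan] * 5
        labels = make_clinical(resp, age=age)
        rows, _ = logistic_fit(labels, pd.DataFrame({"age": age}, index=labels.data.index))
        assert np.isfinite(rows[0].odds_ratio)


class TestComparePredictors:
    def test_identical_constant_groups(self):
        f, p, pairs = compare_predictors({"a": [1, 1, 1], "b": [1, 1, 1]})
        assert f == 0.0 and p == 1.0

    def test_hand_anova_tukey(self):
        """(1,2,3), (1,2,3), (7,8,9): only pairs against the third group differ."""
        f, p, pairs = compare_predictors({"a": [1, 2, 3], "b": [1, 2, 3], "c": [7, 8, 9]})
        assert p < 0.05
        flags = {frozenset((g1, g2)): rej for g1, g2, _, _, rej in pairs}
        assert flags[frozenset(("a", "b"))] is False
        assert flags[frozenset(("a", "c"))] is True
        assert flags[frozenset(("b", "c"))] is True

    def test_separated_aucs_flagged(self):
        """Predictors whose per-dataset AUCs sit far apart get flagged."""
        weak = [0.52, 0.55, 0.50, 0.53, 0.51]
        strong = [0.74, 0.77, 0.72, 0.76, 0.75]
        f, p, pairs = compare_predictors({"weak": weak, "strong": strong})
        assert p < 0.05
        assert all(rej for *_, rej in pairs)

    def test_underpowered_group_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            compare_predictors({"a": [1, 2], "b": [3]})


class TestValidateIndex:
    def test_full_report_on_synthetic_cohort(self):
        cfg = SimConfig(n_cohorts=1, n_samples=300, n_genes=200, n_pos=20, n_neg=10,
                        outcome_slope=1.5, seed=9)
        (expr, clin), = generate_multi_cohort(cfg)[0]
        truth = generate_multi_cohort(cfg)[1][0]
        zm, _ = standardize(expr)
        idx = TargetIndexDefinition(
            truth.target_probe_id,
            frozenset(truth.true_positive_set) | {truth.target_probe_id},
            frozenset(truth.true_negative_set),
        )
        rep = validate_index(score_index(zm, idx), clin)
        assert rep.auc > 0.7 and rep.auc_p < 0.001
        assert rep.mean_pcr > rep.mean_rd
        assert rep.n_pcr + rep.n_rd == 300
        assert rep.or_table[0].odds_ratio > 1.0
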