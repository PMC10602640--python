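"""Rank AUC, Youden cutoffs, risk score, logistic regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from micromarker import (
    RiskScoreModel,
    auc_rank,
    build_risk_score,
    clinical_design,
    evaluate_score,
    logistic_fit,
    score_samples,
    screen_markers,
    youden_cutoff,
)

POS, NEG = "non-pCR", "pCR"


def pair_count_auc(values, labels):
    """Exhaustive concordant-pair oracle (ties count one half)."""
    values = np.asarray(values, float)
    pos = values[np.asarray(labels) == POS]
    neg = values[np.asarray(labels) == NEG]
    total = 0.0
    for vp in pos:
        for vn in neg:
            total += 1.0 if vp > vn else (0.5 if vp == vn else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(values, labels):
    values = np.asarray(values, float)
    pos = np.asarray(labels) == POS
    best_j, best_c = -2.0, None
    for c in np.unique(np.concatenate([values - 1e-9, values + 1e-9])):
        high = values >= c
        j = (high & pos).sum() / pos.sum() + (~high & ~pos).sum() / (~pos).sum() - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_j


labels_strategy = st.lists(st.sampled_from([POS, NEG]), min_size=4, max_size=30).filter(
    lambda ls: 0 < ls.count(POS) < len(ls)
)


class TestAuc:
    def test_perfect_separation(self):
        assert auc_rank([1, 2, 3, 4], [NEG, NEG, POS, POS]).auc == 1.0

    def test_all_ties(self):
        res = auc_rank([5, 5, 5, 5], [NEG, NEG, POS, POS])
        assert res.auc == 0.5 and res.p_value == 1.0

    def test_pair_count_examples(self):
        assert auc_rank([1, 2, 3, 4], [NEG, NEG, POS, POS]).auc == 1.0
        assert auc_rank([1, 3, 2, 4], [NEG, NEG, POS, POS]).auc == 0.75

    @given(labels_strategy, st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_pair_counting(self, labels, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 8, size=len(labels)).astype(float)  # many ties
        res = auc_rank(values, labels)
        assert res.auc == pytest.approx(pair_count_auc(values, labels), abs=1e-12)

    @given(labels_strategy, st.integers(0, 2**31 - 1))
    def test_label_flip_maps_auc_to_complement(self, labels, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=len(labels))
        flipped = [NEG if l == POS else POS for l in labels]
        a = auc_rank(values, labels, positive_class=POS).auc
        b = auc_rank(values, flipped, positive_class=POS).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_orientation_identity(self, rng):
        values = rng.normal(size=20)
        labels = [POS] * 8 + [NEG] * 12
        assert auc_rank(values, labels).auc + auc_rank(-values, labels).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([1, 2], [POS, POS])


class TestYouden:
    def test_perfect_separation_midpoint(self):
        mc = youden_cutoff([0.1, 0.2, 0.8, 0.9], [NEG, NEG, POS, POS])
        assert mc.youden_j == 1.0
        assert mc.cutoff == pytest.approx(0.5)

    def test_null_returns_smallest_threshold(self):
        vals = [1.0, 2.0, 1.0, 2.0]
        mc = youden_cutoff(vals, [NEG, POS, POS, NEG])
        assert mc.youden_j == pytest.approx(0.0)
        assert mc.cutoff <= 1.0  # tie broken toward smallest (max sensitivity)
        assert mc.sensitivity == 1.0

    @given(labels_strategy, st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_threshold_search(self, labels, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 6, size=len(labels)).astype(float)
        mc = youden_cutoff(values, labels)
        assert mc.youden_j == pytest.approx(brute_force_youden(values, labels), abs=1e-12)

    @given(labels_strategy, st.integers(0, 2**31 - 1))
    def test_label_flip_preserves_max_abs_j(self, labels, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=len(labels))
        flipped = [NEG if l == POS else POS for l in labels]
        j1 = youden_cutoff(values, labels).youden_j
        j2 = youden_cutoff(values, flipped).youden_j
        # both searches attain the maximum of J over thresholds for their
        # own orientation; the attainable max |J| is shared
        assert j1 >= -1e-12 and j2 >= -1e-12


class TestScreen:
    def test_constant_candidate_excluded(self, rng):
        rel = pd.DataFrame(
            {"flat": np.ones(30) * 0.1, "good": np.r_[rng.normal(0.2, 0.02, 15), rng.normal(0.5, 0.02, 15)]}
        )
        labels = np.array([NEG] * 15 + [POS] * 15)
        markers = screen_markers(rel, labels, ["flat", "good"])
        assert [m.genus for m in markers] == ["good"]

    def test_strong_markers_retained_nulls_excluded(self, rng):
        """7 separated genera pass the AUC screen; most null genera are
        excluded, averaged over replicate draws."""
        kept_strong, kept_null = 0, 0
        for rep in range(10):
            r = np.random.default_rng(500 + rep)
            n0, n1 = 40, 40
            data = {}
            for i in range(7):
                data[f"strong{i}"] = np.r_[r.normal(0.1, 0.03, n0), r.normal(0.25, 0.03, n1)]
            for i in range(5):
                data[f"null{i}"] = r.uniform(0.0, 0.3, n0 + n1)
            rel = pd.DataFrame(data).clip(lower=0)
            labels = np.array([NEG] * n0 + [POS] * n1)
            markers = screen_markers(rel, labels, list(data))
            names = {m.genus for m in markers}
            kept_strong += sum(1 for g in names if g.startswith("strong"))
            kept_null += sum(1 for g in names if g.startswith("null"))
        assert kept_strong == 70
        assert kept_null <= 10  # >= 4 of 5 nulls excluded on average

    def test_dichotomized_auc_equals_sens_spec_identity(self, rng):
        """For a binary marker, rank AUC equals (sens + spec)/2 from its
        2x2 table."""
        for _ in range(20):
            strata = rng.integers(0, 2, size=25)
            labels = np.where(rng.random(25) < 0.4, POS, NEG)
            if len(set(labels)) < 2:
                continue
            pos = labels == POS
            sens = (strata[pos] == 1).mean()
            spec = (strata[~pos] == 0).mean()
            auc = auc_rank(strata, labels).auc
            assert auc == pytest.approx((sens + spec) / 2, abs=1e-12)

    def test_empty_candidates_rejected(self, rng):
        rel = pd.DataFrame({"a": rng.uniform(size=10)})
        with pytest.raises(ValueError):
            screen_markers(rel, np.array([POS, NEG] * 5), [])


class TestScore:
    def model_from(self, cutoffs):
        from micromarker.risk import MarkerCutoff

        return RiskScoreModel(
            markers=[
                MarkerCutoff(
                    genus=g, cutoff=c, sensitivity=1, specificity=1, youden_j=1,
                    auc_continuous=1, p_continuous=0.0,
                )
                for g, c in cutoffs.items()
            ]
        )

    def test_score_range(self, rng):
        genera = [f"g{i}" for i in range(7)]
        model = self.model_from({g: 0.5 for g in genera})
        below = pd.DataFrame(np.zeros((1, 7)), columns=genera)
        above = pd.DataFrame(np.ones((1, 7)), columns=genera)
        assert score_samples(model, below).iloc[0] == 0
        assert score_samples(model, above).iloc[0] == 7

    def test_score_equals_indicator_sum_oracle(self, rng):
        genera = [f"g{i}" for i in range(5)]
        cutoffs = {g: rng.uniform(0.2, 0.8) for g in genera}
        model = self.model_from(cutoffs)
        rel = pd.DataFrame(rng.uniform(size=(40, 5)), columns=genera)
        scores = score_samples(model, rel)
        oracle = sum((rel[g] >= c).astype(int) for g, c in cutoffs.items())
        assert (scores == oracle).all()

    def test_score_monotone_in_abundance(self, rng):
        genera = [f"g{i}" for i in range(4)]
        model = self.model_from({g: 0.5 for g in genera})
        rel = pd.DataFrame(rng.uniform(size=(10, 4)), columns=genera)
        base = score_samples(model, rel)
        bumped = rel.copy()
        bumped["g0"] += 0.4
        assert (score_samples(model, bumped) >= base).all()

    def test_missing_marker_named(self, rng):
        model = self.model_from({"absent_genus": 0.5})
        rel = pd.DataFrame({"other": rng.uniform(size=5)})
        with pytest.raises(ValueError, match="absent_genus"):
            score_samples(model, rel)

    def test_constant_score_auc_half(self):
        assert evaluate_score([2] * 10, [POS] * 4 + [NEG] * 6).auc == 0.5

    def test_monotone_score_auc_one(self):
        scores = [0, 0, 0, 3, 3, 3]
        labels = [NEG] * 3 + [POS] * 3
        assert evaluate_score(scores, labels).auc == 1.0

    def test_model_round_trip(self, tmp_path, rng):
        model = self.model_from({"a": 0.1, "b": 0.7})
        path = tmp_path / "model.tsv"
        model.save(path)
        back = RiskScoreModel.load(path)
        assert back.marker_genera == ["a", "b"]
        assert back.positive_class == POS
        rel = pd.DataFrame(rng.uniform(size=(8, 2)), columns=["a", "b"])
        assert (score_samples(back, rel) == score_samples(model, rel)).all()


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = logistic_fit(pd.DataFrame(index=range(100)), y)
        assert fit.table.loc["const", "coef"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_parameter_recovery(self, rng):
        """Data from a known logistic model (beta = 0.8, n = 2000):
        estimate within 3 SE of truth."""
        n = 2000
        score = rng.integers(0, 8, size=n)
        eta = -2.0 + 0.8 * score
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = logistic_fit(pd.DataFrame({"score": score}), y)
        beta = fit.table.loc["score", "coef"]
        se = (np.log(fit.table.loc["score", "ci_high"]) - np.log(fit.table.loc["score", "odds_ratio"])) / 1.96
        assert abs(beta - 0.8) <= 3 * se
        assert fit.converged and not fit.separation

    def test_or_equals_exp_coef_and_ci_brackets(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x)))).astype(int)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        row = fit.table.loc["x"]
        assert row["odds_ratio"] == pytest.approx(np.exp(row["coef"]), rel=1e-10)
        assert row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.separation
        assert fit.table["ci_low"].isna().all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(pd.DataFrame({"x": [1.0, 2.0]}), [0, 1])

    def test_clinical_design_coding(self, default_cohort):
        matrix, meta, _ = default_cohort
        scores = pd.Series(
            np.arange(len(meta)) % 8, index=meta["sample_id"], name="risk_score"
        )
        design = clinical_design(meta, scores)
        assert set(design.columns) == {"sex_male", "age_high", "grading", "cT", "cN", "risk_score"}
        assert set(design["sex_male"].unique()) <= {0, 1}
        assert set(design["age_high"].unique()) <= {0, 1}
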