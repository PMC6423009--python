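"""Survival models, ssGSEA scoring and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from clonarch import outcome, synthetic
from clonarch.io import ClinicalRecord


def _clinical(times, events, index=None):
    idx = index or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame(
        {
            "survival_time": times,
            "event_observed": events,
            "age": 60.0,
            "sex_num": 0,
            "t_stage_num": 1,
            "grade_num": 1,
        },
        index=idx,
    )


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        curve = outcome.km_survival([1.0, 2.0, 3.0], [1, 1, 1])
        s = curve.set_index("time")["survival"]
        assert s.loc[2.0] == pytest.approx((2 / 3) * (1 / 2))
        assert s.loc[3.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=50)
        curve = outcome.km_survival(t, np.ones(50))
        for time, surv in zip(curve["time"], curve["survival"]):
            if time == 0:
                continue
            assert surv == pytest.approx((t > time).mean(), abs=1e-12)

    def test_identical_groups_give_zero_chi_square(self):
        cl = _clinical([3.0, 5.0, 8.0, 3.0, 5.0, 8.0], [1, 0, 1, 1, 0, 1])
        groups = pd.Series(["x", "x", "x", "y", "y", "y"], index=cl.index)
        res, curves = outcome.km_logrank(groups, cl)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert set(curves["group"]) == {"x", "y"}

    def test_single_group_rejected(self):
        cl = _clinical([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            outcome.km_logrank(pd.Series(["a", "a"], index=cl.index), cl)

    def test_planted_hazard_detected(self):
        rng = np.random.default_rng(1)
        n = 400
        grp = np.repeat(["lo", "hi"], n // 2)
        rate = np.where(grp == "hi", 2.7, 1.0) / 60.0
        t = rng.exponential(1 / rate)
        c = rng.uniform(24, 120, n)
        cl = _clinical(np.minimum(t, c), (t <= c).astype(int))
        res, _ = outcome.km_logrank(pd.Series(grp, index=cl.index), cl)
        assert res.p_value < 0.01


class TestCox:
    def _planted(self, seed, n=500, hr=2.7):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        rate = np.where(x == 1, hr, 1.0) / 60.0
        t = rng.exponential(1 / rate)
        c = rng.uniform(24, 120, n)
        cl = _clinical(np.minimum(t, c), (t <= c).astype(int))
        return pd.DataFrame({"x": x}, index=cl.index), cl

    def test_recovers_planted_hazard_ratio(self):
        hits = 0
        for seed in range(10):
            terms, cl = self._planted(seed)
            res = outcome.cox_model(terms, cl)[0]
            hits += 2.0 <= res.hazard_ratio <= 3.6
            assert res.ci_low <= res.hazard_ratio <= res.ci_high
        assert hits >= 9

    def test_adjusted_model_reports_term(self):
        terms, cl = self._planted(0, n=300)
        cl = cl.assign(
            age=np.random.default_rng(1).normal(60, 8, len(cl)),
            sex_num=np.random.default_rng(2).integers(0, 2, len(cl)),
            t_stage_num=np.random.default_rng(3).integers(1, 5, len(cl)),
            grade_num=np.random.default_rng(4).integers(1, 5, len(cl)),
        )
        res = outcome.cox_model(terms, cl, adjusted=True)[0]
        assert res.model == "cox_multivariate"
        assert 1.5 <= res.hazard_ratio <= 4.5

    def test_constant_term_rejected(self):
        terms, cl = self._planted(0, n=50)
        terms["x"] = 1
        with pytest.raises(ValueError, match="constant"):
            outcome.cox_model(terms, cl)

    def test_null_term_p_roughly_uniform(self):
        ps = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            terms, cl = self._planted(seed, n=150, hr=1.0)
            res = outcome.cox_model(terms, cl)[0]
            ps.append(res.p_value)
        assert 0.1 <= np.mean(ps) <= 0.9
        assert min(ps) > 1e-4  # no spurious extreme significance

    def test_score_test_at_null_matches_logrank(self):
        """Classic identity: the Cox partial-likelihood score test at beta=0
        for a binary covariate equals the log-rank statistic (no ties)."""
        rng = np.random.default_rng(5)
        n = 40
        x = np.array([0, 1] * (n // 2))
        t = rng.exponential(np.where(x == 1, 5.0, 10.0))
        cl = _clinical(t, np.ones(n, dtype=int))
        res, _ = outcome.km_logrank(pd.Series(np.where(x == 1, "a", "b"), index=cl.index), cl)
        # hand-rolled score statistic U^2/I at beta=0
        order = np.argsort(t)
        U = I = 0.0
        for i, idx in enumerate(order):
            at_risk = x[order[i:]]
            xbar = at_risk.mean()
            U += x[idx] - xbar
            I += at_risk.var()
        assert U**2 / I == pytest.approx(res.statistic, rel=1e-6)


class TestUnivariateScreen:
    def _cohort(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        carriers = rng.choice(n, size=140, replace=False)
        clonality = np.array(["clonal", "subclonal"])[rng.integers(0, 2, 140)]
        hazard = np.ones(n)
        # only subclonal carriers have elevated hazard
        sub = carriers[clonality == "subclonal"]
        hazard[sub] = 2.5
        t = rng.exponential(60.0 / hazard)
        c = rng.uniform(24, 120, n)
        cl = _clinical(np.minimum(t, c), (t <= c).astype(int))
        calls = pd.DataFrame(
            {
                "sample_id": [cl.index[i] for i in carriers],
                "event_id": "del(14q)",
                "ccf": 0.5,
                "clonality": clonality,
            }
        )
        return calls, cl

    def test_stratified_screen_separates_subclonal_effect(self):
        calls, cl = self._cohort()
        out = outcome.univariate_screen(
            ["del(14q)"], calls, cl, stratify_clonality=True
        ).set_index("stratum")
        assert out.loc["subclonal", "p_value"] < 0.05
        assert out.loc["clonal", "p_value"] > 0.05

    def test_unstratified_prognostic_event_selected(self):
        calls, cl = self._cohort(seed=1)
        out = outcome.univariate_screen(["del(14q)"], calls, cl)
        assert bool(out.loc[0, "selected"])

    def test_rare_event_skipped_with_warning(self):
        calls, cl = self._cohort()
        rare = calls.head(2).assign(event_id="RARE")
        with pytest.warns(UserWarning, match="carriers"):
            out = outcome.univariate_screen(["RARE"], rare, cl)
        assert len(out) == 0


def _brute_force_ssgsea(expr: pd.Series, members: set, alpha: float) -> float:
    """Independent running-sum enumeration used as the scoring oracle."""
    order = sorted(expr.index, key=lambda g: (-expr[g], g))
    N = len(order)
    in_flags = [g in members for g in order]
    n_in = sum(in_flags)
    wsum = sum((N - i) ** alpha for i, f in enumerate(in_flags) if f)
    score, p_in, p_out = 0.0, 0.0, 0.0
    for i, f in enumerate(in_flags):
        if f:
            p_in += (N - i) ** alpha / wsum
        else:
            p_out += 1.0 / (N - n_in)
        score += p_in - p_out
    return score


class TestSsgsea:
    def _toy(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(
            rng.uniform(1, 100, size=(10, 4)),
            index=[f"g{i}" for i in range(10)],
            columns=list("abcd"),
        )
        sets = {"set3": ["g1", "g4", "g7"]}
        return expr, sets

    def test_matches_brute_force_oracle(self):
        expr, sets = self._toy()
        scores = outcome.ssgsea_scores(expr, sets, weight_exponent=0.25)
        for sample in expr.columns:
            oracle = _brute_force_ssgsea(expr[sample], set(sets["set3"]), 0.25)
            assert scores.raw.loc["set3", sample] == pytest.approx(oracle, abs=1e-9)

    def test_invariant_under_monotone_transformation(self):
        expr, sets = self._toy()
        a = outcome.ssgsea_scores(expr, sets).raw
        b = outcome.ssgsea_scores(np.log(expr) * 3 + 5, sets).raw
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_top_genes_positive_bottom_negative(self):
        expr, _ = self._toy()
        ranked = expr["a"].sort_values(ascending=False)
        top = {"top": list(ranked.index[:3])}
        bottom = {"bottom": list(ranked.index[-3:])}
        assert outcome.ssgsea_scores(expr, top).raw.loc["top", "a"] > 0
        assert outcome.ssgsea_scores(expr, bottom).raw.loc["bottom", "a"] < 0

    def test_unexpressed_set_is_na_with_warning(self):
        expr, _ = self._toy()
        with pytest.warns(UserWarning, match="no expressed member"):
            scores = outcome.ssgsea_scores(expr, {"ghost": ["nope1", "nope2"]})
        assert scores.raw.loc["ghost"].isna().all()


class TestImmuneRatios:
    def _scores(self, th17, th2, cd8, treg):
        raw = pd.DataFrame(
            [th17, th2, cd8, treg],
            index=["Th17", "Th2", "CD8", "Treg"],
            columns=[f"s{i}" for i in range(len(th17))],
        )
        raw.attrs["n_genes"] = 100
        return outcome.ImmuneScores(raw)

    def test_equal_scores_give_unit_ratio(self):
        s = self._scores([1.0, 2.0], [1.0, 2.0], [0.5, 0.5], [0.5, 0.5])
        ratios = outcome.immune_ratios(s)
        assert np.allclose(ratios["Th17/Th2"], 1.0)

    def test_invariant_to_common_shift(self):
        s1 = self._scores([1.0, 3.0], [2.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        s2 = self._scores([11.0, 13.0], [12.0, 11.0], [1.0, 1.0], [1.0, 1.0])
        r1 = outcome.immune_ratios(s1)["Th17/Th2"]
        r2 = outcome.immune_ratios(s2)["Th17/Th2"]
        assert np.allclose(r1, r2)

    def test_missing_set_errors(self):
        s = self._scores([1.0], [1.0], [1.0], [1.0])
        with pytest.raises(ValueError, match="missing"):
            outcome.immune_ratios(s, pairs=(("Th17", "NK"),))

    def test_planted_immune_shift_recovered(self, small_cohort):
        """The subtype with planted Th17/CD8 elevation has the highest median
        Th17/Th2 ratio."""
        scores = outcome.ssgsea_scores(small_cohort.expression, small_cohort.gene_sets)
        ratios = outcome.immune_ratios(scores)
        subtype = small_cohort.truth.subtypes.set_index("sample_id")["subtype"]
        med = ratios["Th17/Th2"].groupby(subtype).median()
        assert med.idxmax() == "B"


class TestCompareGroups:
    def test_identical_groups_mann_whitney(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["a"] * 3 + ["b"] * 3
        _, p = outcome.compare_groups(vals, labels, "mann_whitney")
        assert p == pytest.approx(1.0)

    def test_separated_groups_t_test(self):
        _, p = outcome.compare_groups(
            [1, 2, 3, 101, 102, 103], ["a"] * 3 + ["b"] * 3, "t_test"
        )
        assert p < 0.001

    def test_fisher_on_binaries(self):
        vals = [1] * 10 + [0] * 10
        labels = ["a"] * 10 + ["b"] * 10
        _, p = outcome.compare_groups(vals, labels, "fisher")
        assert p == pytest.approx(1.082e-5, rel=1e-3)

    def test_undersized_t_test_rejected(self):
        with pytest.raises(ValueError):
            outcome.compare_groups([1.0, 2.0, 3.0], ["a", "b", "b"], "t_test")


def test_clinical_frame_encodings():
    recs = [
        ClinicalRecord("s1", 12.0, True, 61.0, "F", "T3", "G2"),
        ClinicalRecord("s2", 30.0, False, 55.0, "M", "T1", "G4"),
    ]
    cl = outcome.clinical_frame(recs)
    assert cl.loc["s1", "t_stage_num"] == 3 and cl.loc["s2", "grade_num"] == 4
    assert set(cl["sex_num"]) == {0, 1}
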