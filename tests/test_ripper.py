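"""RIPPER: FOIL gain, grow/prune, description length, and full fits."""

import math

import numpy as np
import pandas as pd
import pytest
import sympy
from hypothesis import given, settings, strategies as st

import rulebench as rb
from rulebench.rules import Condition, CoverageStats, Op, Rule, coverage, predict_frame, rule_mask
from rulebench.ripper import (
    RIPPER_GRID,
    RipperSettings,
    fit_ripper,
    foil_gain,
    grow_rule,
    prune_rule,
    ruleset_description_length,
)
from tests.conftest import genotype_frame


def foil_gain_symbolic(p1, n1, p0, n0) -> float:
    """Arbitrary-precision transcription of the gain formula."""
    if p1 == 0:
        return 0.0
    expr = sympy.Integer(p1) * (
        sympy.log(sympy.Rational(p1, p1 + n1), 2) - sympy.log(sympy.Rational(p0, p0 + n0), 2)
    )
    return float(expr.evalf(40))


class TestFoilGain:
    @pytest.mark.parametrize(
        "cand,cur,expected",
        [
            ((2, 0), (2, 2), 2.0),
            ((1, 1), (2, 2), 0.0),
        ],
    )
    def test_closed_form(self, cand, cur, expected):
        assert foil_gain(CoverageStats(*cand), CoverageStats(*cur)) == pytest.approx(expected)

    def test_against_symbolic_formula(self):
        got = foil_gain(CoverageStats(3, 1), CoverageStats(5, 10))
        assert got == pytest.approx(foil_gain_symbolic(3, 1, 5, 10), rel=1e-12)

    def test_zero_positive_candidate(self):
        assert foil_gain(CoverageStats(0, 4), CoverageStats(5, 5)) == 0.0

    @given(
        st.integers(min_value=1, max_value=200),
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=0, max_value=200),
        st.integers(min_value=0, max_value=200),
    )
    @settings(derandomize=True, max_examples=1000)
    def test_matches_oracle_on_random_coverages(self, p0, n0, dp, dn):
        """Candidate coverage is a sub-coverage of the current one."""
        p1 = max(p0 - dp, 0)
        n1 = max(n0 - dn, 0)
        got = foil_gain(CoverageStats(p1, n1), CoverageStats(p0, n0))
        assert got == pytest.approx(foil_gain_symbolic(p1, n1, p0, n0), rel=1e-9, abs=1e-9)


def enumerate_first_conditions(frame, labels):
    """All single conditions with their FOIL gain, by brute force."""
    y = np.asarray(labels, dtype=object)
    current = CoverageStats(int((y == "Case").sum()), int((y == "Control").sum()))
    out = []
    for col in frame.columns:
        if pd.api.types.is_numeric_dtype(frame[col]):
            vals = np.sort(np.unique(frame[col].to_numpy(dtype=float)))
            mids = (vals[:-1] + vals[1:]) / 2
            for t in mids:
                for op in (Op.GT, Op.LE):
                    rule = Rule((Condition(col, op, float(t)),), "Case")
                    out.append((rule, foil_gain(coverage(rule, frame, y), current)))
        else:
            for v in ("AA", "AB", "BB"):
                rule = Rule((Condition(col, Op.EQ, v),), "Case")
                out.append((rule, foil_gain(coverage(rule, frame, y), current)))
    return out


class TestGrowRule:
    def test_perfect_separator_yields_single_condition(self):
        rng = np.random.default_rng(3)
        frame = genotype_frame(rng, 60, 3)
        labels = np.where(frame["rs1"] == "AA", "Case", "Control").astype(object)
        rule = grow_rule(frame, labels)
        assert rule.conditions == (Condition("rs1", Op.EQ, "AA"),)

    def test_first_condition_is_exhaustive_argmax(self):
        rng = np.random.default_rng(11)
        frame = genotype_frame(rng, 20, 3)
        frame["AUC"] = rng.uniform(90, 115, 20)
        labels = rng.choice(["Case", "Control"], 20, p=[0.4, 0.6]).astype(object)
        if (labels == "Case").sum() == 0:
            labels[0] = "Case"
        rule = grow_rule(frame, labels)
        best_gain = max(g for _, g in enumerate_first_conditions(frame, labels))
        first = Rule(rule.conditions[:1], "Case")
        got_gain = foil_gain(
            coverage(first, frame, labels),
            CoverageStats(int((labels == "Case").sum()), int((labels == "Control").sum())),
        )
        assert got_gain == pytest.approx(best_gain)

    def test_first_rule_on_interaction_data_is_pure(self, model_a_dataset):
        ds = model_a_dataset
        frame = ds.frame[["rs5", "rs10"]]
        rule = grow_rule(frame, ds.observed_labels)
        st_cov = coverage(rule, frame, ds.observed_labels)
        assert st_cov.n == 0
        true_masks = [
            rule_mask(r, ds.frame) for r in rb.true_model("A").rule_list.case_rules()
        ]
        got = rule_mask(rule, ds.frame)
        assert any(np.array_equal(got, t) for t in true_masks)


def brute_force_prune(rule, frame, labels):
    best_k, best_metric = 0, -math.inf
    for k in range(len(rule.conditions) + 1):
        truncated = Rule(rule.conditions[:k], rule.label)
        cov = coverage(truncated, frame, labels)
        metric = -1.0 if cov.total == 0 else (cov.p - cov.n) / cov.total
        if metric > best_metric + 1e-12:
            best_metric, best_k = metric, k
    return Rule(rule.conditions[:best_k], rule.label)


class TestPruneRule:
    def test_harmful_final_condition_dropped(self):
        frame = pd.DataFrame(
            {"rs1": pd.Categorical(["AA"] * 6, categories=["AA", "AB", "BB"]),
             "rs2": pd.Categorical(["AA", "AA", "AB", "AB", "AB", "AB"], categories=["AA", "AB", "BB"])}
        )
        labels = np.array(["Case", "Case", "Case", "Case", "Control", "Control"], dtype=object)
        # rs2=AA keeps 2 of 4 cases and no controls: dropping it trades 2
        # positives for 2 negatives, which the metric favors 4-2 over 2-0
        rule = Rule((Condition("rs1", Op.EQ, "AA"), Condition("rs2", Op.EQ, "AA")), "Case")
        pruned = prune_rule(rule, frame, labels)
        assert pruned == brute_force_prune(rule, frame, labels)

    def test_perfect_rule_unchanged(self):
        rng = np.random.default_rng(4)
        frame = genotype_frame(rng, 40, 2)
        labels = np.where(
            (frame["rs1"] == "AA") & (frame["rs2"] == "AB"), "Case", "Control"
        ).astype(object)
        rule = Rule((Condition("rs1", Op.EQ, "AA"), Condition("rs2", Op.EQ, "AB")), "Case")
        assert prune_rule(rule, frame, labels) == rule

    @pytest.mark.parametrize("seed", range(20))
    def test_truncation_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed)
        frame = genotype_frame(rng, 30, 4)
        labels = rng.choice(["Case", "Control"], 30).astype(object)
        conds = tuple(
            Condition(f"rs{j + 1}", Op.EQ, rng.choice(["AA", "AB", "BB"]))
            for j in range(3)
        )
        rule = Rule(conds, "Case")
        assert prune_rule(rule, frame, labels) == brute_force_prune(rule, frame, labels)


def dl_symbolic(rules, frame, labels):
    """Independent transcription of the MDL bits: 0.5-weighted rule cost
    (integer + binomial subset coding) plus binomial exception coding."""
    y = np.asarray(labels, dtype=object) == "Case"
    n_possible = 0
    for col in frame.columns:
        if pd.api.types.is_numeric_dtype(frame[col]):
            n_possible += 2 * (len(np.unique(frame[col])) - 1)
        else:
            n_possible += 3
    log2 = lambda x: sympy.log(x, 2)

    def subset(t, k):
        if t <= 0 or k <= 0 or k >= t:
            return sympy.Integer(0)
        p = sympy.Rational(k, t)
        return -k * log2(p) - (t - k) * log2(1 - p)

    theory = sympy.Integer(0)
    covered = np.zeros(len(frame), dtype=bool)
    for r in rules:
        k = len(r.conditions)
        if k:
            theory += sympy.Rational(1, 2) * ((log2(k) if k > 1 else 0) + subset(n_possible, k))
        covered |= rule_mask(r, frame)
    cover = int(covered.sum())
    uncover = len(frame) - cover
    fp = int((covered & ~y).sum())
    fn = int((~covered & y).sum())
    bits = theory + log2(cover + 1) + subset(cover, fp) + log2(uncover + 1) + subset(uncover, fn)
    return float(sympy.N(bits, 40))


class TestDescriptionLength:
    def test_empty_ruleset_on_all_controls_is_base_cost_only(self):
        frame = pd.DataFrame({"rs1": pd.Categorical(["AA"] * 20, categories=["AA", "AB", "BB"])})
        labels = np.array(["Control"] * 20, dtype=object)
        assert ruleset_description_length([], frame, labels) == pytest.approx(math.log2(21))

    def test_rule_covering_nothing_strictly_increases_dl(self):
        rng = np.random.default_rng(2)
        frame = genotype_frame(rng, 50, 2)
        labels = rng.choice(["Case", "Control"], 50).astype(object)
        frame.loc[:, "rs1"] = pd.Categorical(["AA"] * 50, categories=["AA", "AB", "BB"])
        dead = Rule((Condition("rs1", Op.EQ, "BB"),), "Case")
        base = ruleset_description_length([], frame, labels)
        assert ruleset_description_length([dead], frame, labels) > base

    def test_two_rule_fixture_matches_symbolic_transcription(self):
        rng = np.random.default_rng(9)
        frame = genotype_frame(rng, 40, 3)
        frame["AUC"] = rng.uniform(90, 115, 40)
        labels = rng.choice(["Case", "Control"], 40, p=[1 / 3, 2 / 3]).astype(object)
        rules = [
            Rule((Condition("rs1", Op.EQ, "AA"), Condition("AUC", Op.GT, 100.0)), "Case"),
            Rule((Condition("rs2", Op.EQ, "AB"),), "Case"),
        ]
        got = ruleset_description_length(rules, frame, labels)
        assert got == pytest.approx(dl_symbolic(rules, frame, labels), rel=1e-9)


class TestFitRipper:
    def test_all_controls_yields_default_only_model(self):
        rng = np.random.default_rng(0)
        frame = genotype_frame(rng, 30, 3)
        labels = np.array(["Control"] * 30, dtype=object)
        model = fit_ripper(frame.assign(**{"class": labels}))
        assert model.rules == ()
        assert model.default_label == "Control"

    def test_training_error_not_worse_than_default(self):
        ds = rb.generate_dataset(rb.SimulationConfig("A", 10, 300, 0.2, 0.2, seed=8))
        model = fit_ripper(ds, RipperSettings(3, 2, 10), seed=1)
        pred = predict_frame(model, ds.frame)
        default_errors = (ds.observed_labels == "Case").sum()
        assert (pred != ds.observed_labels).sum() <= default_errors

    def test_case_rules_cover_at_least_min_weight(self, model_a_dataset):
        for mw in (2.0, 10.0):
            model = fit_ripper(model_a_dataset, RipperSettings(3, mw, 10), seed=3)
            for rule in model.case_rules():
                st_cov = coverage(rule, model_a_dataset.frame, model_a_dataset.observed_labels)
                assert st_cov.total >= mw

    def test_deterministic_given_seed(self, model_b_dataset):
        a = fit_ripper(model_b_dataset, RipperSettings(3, 2, 10), seed=5)
        b = fit_ripper(model_b_dataset, RipperSettings(3, 2, 10), seed=5)
        assert a == b

    def test_zero_training_error_on_separable_fixture(self, single_snp_fixture):
        frame, labels = single_snp_fixture
        model = fit_ripper(frame.assign(**{"class": labels}), seed=2)
        pred = predict_frame(model, frame)
        assert (pred != labels).sum() == 0

    def test_recovers_interaction_rules_on_clean_data(self, model_a_dataset):
        ds = model_a_dataset
        model = fit_ripper(ds, RipperSettings(3, 2, 10), seed=7)
        true_masks = [rule_mask(r, ds.frame) for r in rb.true_model("A").rule_list.case_rules()]
        got_masks = [rule_mask(r, ds.frame) for r in model.case_rules()]
        for g in got_masks:
            assert any(np.array_equal(g, t) for t in true_masks)
        for t in true_masks:
            if t.sum() >= 4:  # below 2x min_weight a rule is unlearnable
                assert any(np.array_equal(g, t) for g in got_masks)

    def test_study_grid_has_18_settings(self):
        assert len(RIPPER_GRID) == 18
        assert {s.optimization_runs for s in RIPPER_GRID} == {10, 100}
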