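"""PART: gain-ratio splits, pessimistic pruning, partial trees, covering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

import rulebench as rb
from rulebench.part import (
    PART_GRID,
    PartSettings,
    best_split,
    build_partial_tree,
    fit_part,
    pessimistic_error,
)
from rulebench.rules import Op, predict_frame, rule_mask
from tests.conftest import genotype_frame


def entropy(p, n):
    out = 0.0
    for k in (p, n):
        if k > 0:
            f = k / (p + n)
            out -= f * math.log2(f)
    return out


def oracle_best_split(frame, labels, settings):
    """Exhaustive C4.5 split search: per attribute the max-gain split, then
    the mean-gain rule, then max gain ratio across attributes."""
    y = np.asarray(labels, dtype=object) == "Case"
    P, N = int(y.sum()), int((~y).sum())
    h_parent = entropy(P, N)
    candidates = []  # (gain, ratio, key, description)

    def stats(groups):
        gain = h_parent
        split_info = 0.0
        for mask in groups:
            w = mask.sum() / len(y)
            gain -= w * entropy(int((mask & y).sum()), int((mask & ~y).sum()))
            if w > 0:
                split_info -= w * math.log2(w)
        return gain, (gain / split_info if split_info > 1e-9 else -math.inf)

    for key, col in enumerate(frame.columns):
        if pd.api.types.is_numeric_dtype(frame[col]):
            vals = frame[col].to_numpy(dtype=float)
            uniq = np.sort(np.unique(vals))
            best = None
            for t in (uniq[:-1] + uniq[1:]) / 2:
                groups = [vals <= t, vals > t]
                if min(g.sum() for g in groups) < settings.min_obj:
                    continue
                gain, ratio = stats(groups)
                if gain > 1e-9 and (best is None or gain > best[0] + 1e-9):
                    best = (gain, ratio, key, ("num", col, t))
            if best:
                candidates.append(best)
        elif settings.binary_splits:
            col_v = frame[col].astype(str).to_numpy()
            best = None
            for v in ("AA", "AB", "BB"):
                groups = [col_v == v, col_v != v]
                if min(g.sum() for g in groups) < settings.min_obj:
                    continue
                gain, ratio = stats(groups)
                if gain > 1e-9 and (best is None or gain > best[0] + 1e-9):
                    best = (gain, ratio, key, ("bin", col, v))
            if best:
                candidates.append(best)
        else:
            col_v = frame[col].astype(str).to_numpy()
            groups = [col_v == v for v in ("AA", "AB", "BB")]
            if sum(g.sum() >= settings.min_obj for g in groups) < 2:
                continue
            gain, ratio = stats(groups)
            if gain > 1e-9:
                candidates.append((gain, ratio, key, ("nom", col, None)))

    if not candidates:
        return None
    mean_gain = sum(c[0] for c in candidates) / len(candidates)
    eligible = [c for c in candidates if c[0] + 1e-9 >= mean_gain]
    return max(eligible, key=lambda c: (c[1], -c[2]))[3]


def split_description(split):
    first = split.conditions[0]
    if first.op in (Op.GT, Op.LE):
        return ("num", first.attribute, float(first.value))
    if any(c.op is Op.NEQ for c in split.conditions):
        return ("bin", first.attribute, first.value)
    return ("nom", first.attribute, None)


class TestBestSplit:
    def test_perfect_separator_chosen(self, single_snp_fixture):
        frame, labels = single_snp_fixture
        split = best_split(frame, labels, PartSettings(binary_splits=True))
        assert split.conditions[0].attribute == "rs1"

    def test_pure_node_makes_leaf(self):
        rng = np.random.default_rng(0)
        frame = genotype_frame(rng, 20, 2)
        labels = np.array(["Control"] * 20, dtype=object)
        assert best_split(frame, labels, PartSettings()) is None

    @pytest.mark.parametrize("binary", [False, True])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_gain_ratio_oracle(self, seed, binary):
        rng = np.random.default_rng(seed)
        n = 12 + 2 * seed
        frame = genotype_frame(rng, n, 3)
        frame["AUC"] = rng.uniform(90, 115, n)
        labels = rng.choice(["Case", "Control"], n).astype(object)
        settings = PartSettings(min_obj=2, binary_splits=binary)
        got = best_split(frame, labels, settings)
        expected = oracle_best_split(frame, labels, settings)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert split_description(got) == expected


class TestPessimisticError:
    def test_reference_point_matches_wilson_style_bound(self):
        """(errors=2, total=10, C=0.25): upper bound solved independently
        from the Wilson equation with continuity correction."""
        N, e, C = 10, 2, 0.25
        z = norm.ppf(1 - C)
        f = (e + 0.5) / N
        upper = brentq(lambda r: (r - f) ** 2 - z * z * r * (1 - r) / N, f, 1.0)
        assert pessimistic_error(N, e, C) == pytest.approx(N * upper, rel=1e-9)

    @pytest.mark.parametrize("N,e,C", [(10, 1, 0.25), (50, 5, 0.1), (100, 30, 0.25), (7, 3, 0.4)])
    def test_matches_root_of_wilson_equation(self, N, e, C):
        z = norm.ppf(1 - C)
        f = (e + 0.5) / N
        upper = brentq(lambda r: (r - f) ** 2 - z * z * r * (1 - r) / N, f, 1.0 - 1e-12)
        assert pessimistic_error(N, e, C) == pytest.approx(N * upper, rel=1e-9)

    def test_zero_errors_closed_form(self):
        assert pessimistic_error(20, 0, 0.25) == pytest.approx(20 * (1 - 0.25 ** (1 / 20)))

    def test_monotone_in_confidence(self):
        assert pessimistic_error(30, 3, 0.1) > pessimistic_error(30, 3, 0.25)


class TestBuildPartialTree:
    def test_pure_set_is_single_leaf(self):
        rng = np.random.default_rng(1)
        frame = genotype_frame(rng, 15, 2)
        labels = np.array(["Case"] * 15, dtype=object)
        tree = build_partial_tree(frame, labels)
        assert tree.is_leaf
        assert tree.label == "Case"

    def test_separable_single_attribute_gives_one_split(self, single_snp_fixture):
        frame, labels = single_snp_fixture
        tree = build_partial_tree(frame, labels, PartSettings())
        assert not tree.is_leaf
        assert all(child.is_leaf for child in tree.children)
        assert tree.condition_edges[0].attribute == "rs1"


class TestFitPart:
    def test_all_controls_yields_default_only(self):
        rng = np.random.default_rng(2)
        frame = genotype_frame(rng, 25, 3)
        labels = np.array(["Control"] * 25, dtype=object)
        model = fit_part(frame.assign(**{"class": labels}))
        assert model.rules == ()
        assert model.default_label == "Control"

    def test_separable_fixture_two_rules_or_fewer_zero_error(self, single_snp_fixture):
        frame, labels = single_snp_fixture
        for binary in (False, True):
            model = fit_part(
                frame.assign(**{"class": labels}), PartSettings(binary_splits=binary), seed=3
            )
            assert len(model.rules) <= 2
            assert (predict_frame(model, frame) != labels).sum() == 0

    def test_rules_partition_training_instances(self, model_b_dataset):
        """Under first-match, every subject is claimed by exactly one rule
        (or falls through to the default)."""
        ds = model_b_dataset
        model = fit_part(ds, PartSettings(min_obj=5), seed=4)
        claimed = np.zeros(len(ds.frame), dtype=int)
        undecided = np.ones(len(ds.frame), dtype=bool)
        for rule in model.rules:
            hit = rule_mask(rule, ds.frame) & undecided
            claimed[hit] += 1
            undecided &= ~hit
        assert ((claimed == 1) | undecided).all()

    def test_covering_loop_strictly_decreases_remainder(self, model_b_dataset):
        ds = model_b_dataset
        model = fit_part(ds, PartSettings(), seed=5)
        remaining = np.ones(len(ds.frame), dtype=bool)
        for rule in model.rules:
            covered = rule_mask(rule, ds.frame) & remaining
            assert covered.sum() > 0
            remaining &= ~covered

    def test_deterministic_given_seed(self, model_b_dataset):
        a = fit_part(model_b_dataset, PartSettings(reduced_error=True), seed=6)
        b = fit_part(model_b_dataset, PartSettings(reduced_error=True), seed=6)
        assert a == b

    def test_recovers_gene_environment_rule_on_clean_data(self, model_b_dataset):
        """The rs15/AUC interaction surfaces as a rule whose effective
        first-match coverage equals the true rule's."""
        ds = model_b_dataset
        tmask = rule_mask(rb.true_model("B").rule_list.rules[1], ds.frame)
        hit = False
        for k, settings in enumerate(PART_GRID[18:22]):
            model = fit_part(ds, settings, seed=k)
            undecided = np.ones(len(ds.frame), dtype=bool)
            for rule in model.rules:
                gm = rule_mask(rule, ds.frame)
                eff = gm & undecided
                if rule.label == "Case" and eff.sum() and np.array_equal(eff, tmask & undecided):
                    hit = True
                undecided &= ~gm
        assert hit

    def test_study_grid_has_30_settings(self):
        assert len(PART_GRID) == 30
        assert sum(1 for s in PART_GRID if s.reduced_error) == 18
        assert sum(1 for s in PART_GRID if s.binary_splits) == 15
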