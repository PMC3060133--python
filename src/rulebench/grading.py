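"""Three-tier grading of recovered models against the generating truth.

Recovered rule lists are compared to the generating case-control model at
three levels, each on an ordinal A-D scale (A best, NONE = no meaningful
accordance):

* **model level** — the generated model's case rules are matched
  one-to-one to the true case rules by the assignment minimizing the total
  attribute-difference count; 0 differences is an A, 1 a B, 2 a C, 3 a D.
* **rule level** — each generated case rule individually gets the grade
  of its best match among the true case rules.
* **attribute level** — attribute occurrences are counted over all case
  rules of a model collection and competition-ranked; an A requires every
  true attribute to rank within the model's top-k (2 for the two-SNP
  model, 4 for the gene-environment model).

Numeric-threshold accordance is judged extensionally: a generated
threshold agrees with the true one when both induce the same subject
partition on the dataset (any cut inside the empty gap of the AUC mixture
is equivalent to the true cut at 105).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .rules import Condition, Op, Rule, RuleListModel
from .simulate import CASE, TrueModel

__all__ = [
    "Grade",
    "AttributeRanking",
    "rule_difference",
    "grade_rule",
    "grade_model",
    "rank_attributes",
    "grade_attributes",
]


class Grade(Enum):
    A = 4
    B = 3
    C = 2
    D = 1
    NONE = 0

    def __lt__(self, other: "Grade") -> bool:
        return self.value < other.value

    def __le__(self, other: "Grade") -> bool:
        return self.value <= other.value

    def __gt__(self, other: "Grade") -> bool:
        return self.value > other.value

    def __ge__(self, other: "Grade") -> bool:
        return self.value >= other.value


_DIFF_GRADE = {0: Grade.A, 1: Grade.B, 2: Grade.C, 3: Grade.D}


def _grade_from_difference(diff: int) -> Grade:
    return _DIFF_GRADE.get(diff, Grade.NONE)


def _graded_conditions(rule: Rule) -> dict[str, list[Condition]]:
    """Conditions grouped by attribute; NEQ (rest-branch) conditions have
    no counterpart in a generating rule and are skipped."""
    out: dict[str, list[Condition]] = {}
    for c in rule.conditions:
        if c.op is Op.NEQ:
            continue
        out.setdefault(c.attribute, []).append(c)
    return out


def _graded_attr_count(rule: Rule) -> int:
    return len(_graded_conditions(rule))


def _conditions_mask(conds: Sequence[Condition], column: pd.Series) -> np.ndarray:
    mask = np.ones(len(column), dtype=bool)
    for c in conds:
        if c.op is Op.EQ:
            mask &= (column == c.value).to_numpy()
        elif c.op is Op.GT:
            mask &= column.to_numpy(dtype=float) > float(c.value)
        else:
            mask &= column.to_numpy(dtype=float) <= float(c.value)
    return mask


def _in_accordance(
    gen: Sequence[Condition], true: Sequence[Condition], data: pd.DataFrame | None
) -> bool:
    gen_nominal = all(c.op is Op.EQ for c in gen)
    true_nominal = all(c.op is Op.EQ for c in true)
    if gen_nominal != true_nominal:
        return False
    if gen_nominal:
        return {c.value for c in gen} == {c.value for c in true}
    # numeric: same induced partition on the observed values
    attr = true[0].attribute
    if data is None or attr not in data.columns:
        # no data to judge extensionally: require identical thresholds
        return {(c.op, float(c.value)) for c in gen} == {(c.op, float(c.value)) for c in true}
    col = data[attr]
    return bool(np.array_equal(_conditions_mask(gen, col), _conditions_mask(true, col)))


def rule_difference(
    gen_rule: Rule, true_rule: Rule, data: pd.DataFrame | None = None
) -> int:
    """Attribute-difference count between a generated and a true case rule:
    one per attribute unique to either side, plus one per shared attribute
    whose condition is not in accordance."""
    g = _graded_conditions(gen_rule)
    t = _graded_conditions(true_rule)
    diff = len(set(g) - set(t)) + len(set(t) - set(g))
    for attr in set(g) & set(t):
        if not _in_accordance(g[attr], t[attr], data):
            diff += 1
    return diff


def grade_rule(
    gen_rule: Rule, true_model: TrueModel, data: pd.DataFrame | None = None
) -> Grade:
    """Best grade of ``gen_rule`` over the true model's case rules."""
    true_rules = true_model.rule_list.case_rules(CASE)
    if not true_rules:
        return Grade.NONE
    best = min(rule_difference(gen_rule, tr, data) for tr in true_rules)
    return _grade_from_difference(best)


def grade_model(
    gen_model: RuleListModel, true_model: TrueModel, data: pd.DataFrame | None = None
) -> Grade:
    """Model-level grade: total difference of the optimal one-to-one
    matching between generated and true case rules (unmatched rules on
    either side contribute their full attribute counts). The default
    labels must agree, else NONE."""
    if gen_model.default_label != true_model.rule_list.default_label:
        return Grade.NONE
    gen_rules = list(gen_model.case_rules(CASE))
    true_rules = list(true_model.rule_list.case_rules(CASE))
    if not gen_rules and not true_rules:
        return Grade.A
    if not gen_rules or not true_rules:
        total = sum(_graded_attr_count(r) for r in gen_rules + true_rules)
        return _grade_from_difference(total)

    cost = np.array(
        [[rule_difference(g, t, data) for t in true_rules] for g in gen_rules],
        dtype=float,
    )
    rows, cols = linear_sum_assignment(cost)
    total = int(cost[rows, cols].sum())
    for i, r in enumerate(gen_rules):
        if i not in rows:
            total += _graded_attr_count(r)
    for j, r in enumerate(true_rules):
        if j not in cols:
            total += _graded_attr_count(r)
    return _grade_from_difference(total)


# ---------------------------------------------------------------------------
# attribute level


@dataclass(frozen=True)
class AttributeRanking:
    """Occurrence counts over the case-rule conditions of a model
    collection, with competition ranks (1 = most frequent; ties broken by
    rs index, then name, AUC last)."""

    counts: dict[str, int]
    ranks: dict[str, int]

    def rank(self, attribute: str) -> int | None:
        return self.ranks.get(attribute)


_RS_RE = re.compile(r"^rs(\d+)$")


def _attr_sort_key(name: str) -> tuple[int, int, str]:
    m = _RS_RE.match(name)
    if m:
        return (0, int(m.group(1)), name)
    return (1, 0, name)


def rank_attributes(models: Iterable[RuleListModel]) -> AttributeRanking:
    """Count attribute occurrences per condition across all case rules of
    all models, then rank by descending count."""
    counts: dict[str, int] = {}
    for model in models:
        for rule in model.case_rules(CASE):
            for cond in rule.conditions:
                counts[cond.attribute] = counts.get(cond.attribute, 0) + 1
    ordered = sorted(counts, key=lambda a: (-counts[a],) + _attr_sort_key(a))
    ranks = {a: i + 1 for i, a in enumerate(ordered)}
    return AttributeRanking(counts, ranks)


def grade_attributes(ranking: AttributeRanking, true_model: TrueModel) -> Grade:
    """A: all true attributes detected and ranked within top-k; B: all
    detected but not all top-k; C: exactly one missing; D: exactly two
    missing; NONE otherwise (including an attribute-free null truth)."""
    truth = true_model.true_attributes
    if not truth:
        return Grade.NONE
    missing = [a for a in truth if a not in ranking.counts]
    if not missing:
        if all(ranking.ranks[a] <= true_model.top_k for a in truth):
            return Grade.A
        return Grade.B
    if len(missing) == 1:
        return Grade.C
    if len(missing) == 2:
        return Grade.D
    return Grade.NONE
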