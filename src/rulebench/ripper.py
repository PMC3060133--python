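"""RIPPER: repeated incremental pruning to produce error reduction.

Sequential-covering rule induction for the minority class in four phases:

1. **growth** — conditions are added greedily, each maximizing FOIL
   information gain over every (attribute, level) equality candidate and
   every numeric threshold at midpoints of adjacent observed values;
2. **pruning** — any final sequence of conditions may be dropped, keeping
   the truncation maximizing (p - n) / (p + n) on a held-out prune split;
3. **optimization** — each rule competes against a freshly grown
   *replacement* and a greedily extended *revision*, the winner chosen by
   total description length of the rule set;
4. **selection** — rules covering fewer than ``min_weight`` training
   instances are deleted, and the model falls back to the default-only
   rule set if that has lower training error.

Rule-set growth stops when the minimum-description-length (MDL) score
exceeds the best seen so far by more than 64 bits, when a new rule's
error on the prune split exceeds 50%, or when no positive instances
remain uncovered. The description-length accounting uses binomial
subset coding for both the rule antecedents (halved by the standard
redundancy factor) and the exception lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._encode import EncodedData, encode_table, minority_label, stratified_split
from .rules import Condition, CoverageStats, Op, Rule, RuleListModel

__all__ = [
    "RipperSettings",
    "RIPPER_GRID",
    "foil_gain",
    "grow_rule",
    "prune_rule",
    "ruleset_description_length",
    "fit_ripper",
]

logger = logging.getLogger(__name__)

#: MDL slack: stop adding rules once DL exceeds the best seen by this many bits
DL_STOP_SLACK = 64.0
#: Cohen's redundancy factor on theory (rule-encoding) bits
THEORY_REDUNDANCY = 0.5

_GAIN_EPS = 1e-9


@dataclass(frozen=True)
class RipperSettings:
    """-F (grow/prune split denominator), -N (minimum instances a rule must
    cover), -O (optimization passes)."""

    folds: int = 3
    min_weight: float = 2.0
    optimization_runs: int = 10

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.min_weight < 1:
            raise ValueError("min_weight must be >= 1")
        if self.optimization_runs < 0:
            raise ValueError("optimization_runs must be >= 0")


#: the 18-setting study grid: F x N at O=10, then the same at O=100
RIPPER_GRID: tuple[RipperSettings, ...] = tuple(
    RipperSettings(folds=f, min_weight=n, optimization_runs=o)
    for o in (10, 100)
    for f in (3, 10, 100)
    for n in (2.0, 5.0, 10.0)
)


def foil_gain(candidate: CoverageStats, current: CoverageStats) -> float:
    """FOIL information gain p1 * (log2(p1/(p1+n1)) - log2(p0/(p0+n0))).

    Zero when the candidate covers no positives.
    """
    if candidate.p == 0:
        return 0.0
    if current.p == 0:
        raise ValueError("current coverage must include at least one positive")
    base = math.log2(current.p / current.total)
    return candidate.p * (math.log2(candidate.p / candidate.total) - base)


# ---------------------------------------------------------------------------
# growth


def _gain_vector(p1: np.ndarray, n1: np.ndarray, base: float) -> np.ndarray:
    total = p1 + n1
    with np.errstate(divide="ignore", invalid="ignore"):
        g = p1 * (np.log2(np.where(total > 0, p1 / np.maximum(total, 1), 1.0)) - base)
    return np.where(p1 > 0, g, 0.0)


def _best_condition(
    enc: EncodedData, cov: np.ndarray, used_eq: set[int], p0: int, n0: int
) -> tuple[float, Condition] | None:
    """Argmax of FOIL gain over all candidate conditions on the covered
    subset; first candidate in canonical order wins ties."""
    base = math.log2(p0 / (p0 + n0))
    best_gain = -np.inf
    best_cond: Condition | None = None

    if enc.nom.shape[1]:
        Xc = enc.nom[cov]
        yc = enc.y[cov]
        Xp, Xn = Xc[yc], Xc[~yc]
        max_levels = max(len(lv) for lv in enc.nom_levels)
        gains = np.full((enc.nom.shape[1], max_levels), -np.inf)
        for v in range(max_levels):
            p1 = (Xp == v).sum(axis=0)
            n1 = (Xn == v).sum(axis=0)
            gains[:, v] = _gain_vector(p1, n1, base)
        for j, levels in enumerate(enc.nom_levels):
            gains[j, len(levels):] = -np.inf
        if used_eq:
            gains[sorted(used_eq), :] = -np.inf
        flat = int(np.argmax(gains))
        if gains.ravel()[flat] > best_gain:
            best_gain = float(gains.ravel()[flat])
            j, v = divmod(flat, max_levels)
            best_cond = enc.condition("nom", j, v)

    for j in range(enc.num.shape[1]):
        cand = _numeric_candidates(enc.num[cov, j], enc.y[cov], base)
        if cand is None:
            continue
        thresholds, gains_gt, gains_le = cand
        for t, g_gt, g_le in zip(thresholds, gains_gt, gains_le):
            if g_gt > best_gain:
                best_gain, best_cond = float(g_gt), enc.condition("num", j, t, Op.GT)
            if g_le > best_gain:
                best_gain, best_cond = float(g_le), enc.condition("num", j, t, Op.LE)

    if best_cond is None or best_gain <= _GAIN_EPS:
        return None
    return best_gain, best_cond


def _numeric_candidates(
    vals: np.ndarray, ypos: np.ndarray, base: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Thresholds at midpoints of adjacent distinct values, with the FOIL
    gain of the > and <= side of each."""
    order = np.argsort(vals, kind="stable")
    v = vals[order]
    yy = ypos[order]
    change = np.nonzero(np.diff(v) != 0)[0]
    if change.size == 0:
        return None
    cum_p = np.cumsum(yy)
    P = int(cum_p[-1])
    N = len(v) - P
    p_le = cum_p[change]
    n_le = (change + 1) - p_le
    thresholds = (v[change] + v[change + 1]) / 2.0
    gains_le = _gain_vector(p_le, n_le, base)
    gains_gt = _gain_vector(P - p_le, N - n_le, base)
    return thresholds, gains_gt, gains_le


def _grow_conditions(
    enc: EncodedData,
    grow_mask: np.ndarray,
    init_conds: Sequence[Condition] = (),
) -> list[Condition]:
    conds = list(init_conds)
    cov = grow_mask & enc.rule_mask(conds)
    used_eq = {
        enc.nom_names.index(c.attribute) for c in conds if c.op is Op.EQ
    }
    while True:
        p0 = int(enc.y[cov].sum())
        n0 = int(cov.sum()) - p0
        if p0 == 0 or n0 == 0:
            break
        best = _best_condition(enc, cov, used_eq, p0, n0)
        if best is None:
            break
        _, cond = best
        conds.append(cond)
        cov &= enc.condition_mask(cond)
        if cond.op is Op.EQ:
            used_eq.add(enc.nom_names.index(cond.attribute))
    return conds


def grow_rule(
    frame: pd.DataFrame,
    labels,
    positive_label: str = "Case",
    settings: RipperSettings | None = None,
) -> Rule:
    """Greedily grow one rule for ``positive_label`` on the full table."""
    enc = encode_table(frame, labels, positive_label)
    if not enc.y.any():
        raise ValueError("grow set contains no positive instances")
    conds = _grow_conditions(enc, np.ones(enc.n, dtype=bool))
    return Rule(tuple(conds), positive_label)


# ---------------------------------------------------------------------------
# pruning


def _prune_metric(p: int, n: int) -> float:
    if p + n == 0:
        return -1.0
    return (p - n) / (p + n)


def _prune_conditions(
    conds: Sequence[Condition], enc: EncodedData, prune_mask: np.ndarray
) -> list[Condition]:
    """Best truncation (dropping a final sequence of conditions) under the
    (p-n)/(p+n) metric on the prune split; ties favor the shorter rule."""
    cov = prune_mask.copy()
    best_k = 0
    p = int(enc.y[cov].sum())
    best_metric = _prune_metric(p, int(cov.sum()) - p)
    for k, cond in enumerate(conds, start=1):
        cov &= enc.condition_mask(cond)
        p = int(enc.y[cov].sum())
        metric = _prune_metric(p, int(cov.sum()) - p)
        if metric > best_metric + 1e-12:
            best_metric, best_k = metric, k
    return list(conds[:best_k])


def prune_rule(
    rule: Rule, frame: pd.DataFrame, labels, positive_label: str = "Case"
) -> Rule:
    """Prune ``rule`` against a held-out table."""
    enc = encode_table(frame, labels, positive_label)
    conds = _prune_conditions(rule.conditions, enc, np.ones(enc.n, dtype=bool))
    return Rule(tuple(conds), rule.label)


# ---------------------------------------------------------------------------
# description length


def _subset_bits(t: int, k: int) -> float:
    """Binomial-coding bits to identify a k-subset among t items."""
    if t <= 0 or k <= 0 or k >= t:
        return 0.0
    p = k / t
    return float(-k * math.log2(p) - (t - k) * math.log2(1.0 - p))


def _rule_theory_bits(k: int, n_possible: int) -> float:
    if k == 0:
        return 0.0
    bits = math.log2(k) if k > 1 else 0.0
    bits += _subset_bits(n_possible, k) if k < n_possible else 0.0
    return THEORY_REDUNDANCY * bits


def _n_possible_conditions(enc: EncodedData) -> int:
    n = sum(len(levels) for levels in enc.nom_levels)
    for j in range(enc.num.shape[1]):
        distinct = len(np.unique(enc.num[:, j]))
        n += 2 * max(distinct - 1, 0)
    return max(n, 1)


def _ruleset_dl(
    rule_conds: Sequence[Sequence[Condition]], enc: EncodedData, n_possible: int
) -> float:
    covered = np.zeros(enc.n, dtype=bool)
    theory = 0.0
    for conds in rule_conds:
        theory += _rule_theory_bits(len(conds), n_possible)
        covered |= enc.rule_mask(conds)
    cover = int(covered.sum())
    uncover = enc.n - cover
    fp = int((covered & ~enc.y).sum())
    fn = int((~covered & enc.y).sum())
    data_bits = (
        math.log2(cover + 1)
        + _subset_bits(cover, fp)
        + math.log2(uncover + 1)
        + _subset_bits(uncover, fn)
    )
    return theory + data_bits


def ruleset_description_length(
    rules: Sequence[Rule] | RuleListModel,
    frame: pd.DataFrame,
    labels,
    positive_label: str = "Case",
) -> float:
    """Total bits to encode the rules plus their exceptions on the data."""
    if isinstance(rules, RuleListModel):
        rules = rules.case_rules(positive_label)
    enc = encode_table(frame, labels, positive_label)
    n_possible = _n_possible_conditions(enc)
    return _ruleset_dl([r.conditions for r in rules], enc, n_possible)


# ---------------------------------------------------------------------------
# fitting


def _as_frame_labels(data) -> tuple[pd.DataFrame, np.ndarray]:
    if hasattr(data, "frame") and hasattr(data, "observed_labels"):
        return data.frame, np.asarray(data.observed_labels, dtype=object)
    frame = data
    if "class" not in frame.columns:
        raise ValueError("expected a Dataset or a DataFrame with a 'class' column")
    return frame.drop(columns=["class"]), frame["class"].to_numpy(dtype=object)


def _cover_positives(
    rules: list[list[Condition]],
    enc: EncodedData,
    settings: RipperSettings,
    rng: np.random.Generator,
    n_possible: int,
) -> None:
    """Extend ``rules`` in place to cover residual positives: grow/prune on
    a fresh stratified split per rule, stopping on the MDL slack, a
    prune-split error above 50%, or exhaustion of positives."""
    idx_all = np.arange(enc.n)
    covered = np.zeros(enc.n, dtype=bool)
    for conds in rules:
        covered |= enc.rule_mask(conds)
    remaining = ~covered
    min_dl = min(_ruleset_dl([], enc, n_possible), _ruleset_dl(rules, enc, n_possible))

    while enc.y[remaining].any():
        ridx = idx_all[remaining]
        grow_idx, prune_idx = stratified_split(ridx, enc.y, settings.folds, rng)
        if 0 < len(prune_idx) < 5:
            logger.debug(
                "prune split has only %d instances (F=%d)", len(prune_idx), settings.folds
            )
        grow_mask = np.zeros(enc.n, dtype=bool)
        grow_mask[grow_idx] = True
        if not enc.y[grow_mask].any():
            break
        conds = _grow_conditions(enc, grow_mask)
        if prune_idx.size:
            prune_mask = np.zeros(enc.n, dtype=bool)
            prune_mask[prune_idx] = True
            conds = _prune_conditions(conds, enc, prune_mask)
            if conds:
                cm = enc.rule_mask(conds) & prune_mask
                p = int(enc.y[cm].sum())
                t = int(cm.sum())
                if t > 0 and (t - p) > p:  # prune-split error above 50%
                    break
        if not conds:
            break
        dl = _ruleset_dl(rules + [conds], enc, n_possible)
        if dl > min_dl + DL_STOP_SLACK:
            break
        min_dl = min(min_dl, dl)
        rules.append(conds)
        remaining &= ~enc.rule_mask(conds)


def fit_ripper(data, settings: RipperSettings | None = None, seed: int = 0) -> RuleListModel:
    """Learn a rule list for the minority class; the default predicts the
    majority class. Deterministic given (data, settings, seed)."""
    frame, labels = _as_frame_labels(data)
    settings = settings or RipperSettings()
    pos = minority_label(labels)
    enc = encode_table(frame, labels, pos)
    neg = enc.negative_label
    if enc.y.all():
        return RuleListModel((), pos)
    if not enc.y.any():
        return RuleListModel((), neg)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if enc.n // settings.folds < 5:
        logger.warning(
            "F=%d leaves a %d-instance prune split on %d instances",
            settings.folds, enc.n // settings.folds, enc.n,
        )
    n_possible = _n_possible_conditions(enc)
    rules: list[list[Condition]] = []
    _cover_positives(rules, enc, settings, rng, n_possible)

    idx_all = np.arange(enc.n)
    for _ in range(settings.optimization_runs):
        for i in range(len(rules)):
            other_cov = np.zeros(enc.n, dtype=bool)
            for j, conds in enumerate(rules):
                if j != i:
                    other_cov |= enc.rule_mask(conds)
            scope = idx_all[~other_cov]
            if not enc.y[scope].any():
                continue
            grow_idx, prune_idx = stratified_split(scope, enc.y, settings.folds, rng)
            grow_mask = np.zeros(enc.n, dtype=bool)
            grow_mask[grow_idx] = True
            prune_mask = np.zeros(enc.n, dtype=bool)
            prune_mask[prune_idx] = True
            variants: list[list[Condition]] = [rules[i]]
            if enc.y[grow_mask].any():
                for v in (
                    _grow_conditions(enc, grow_mask),
                    _grow_conditions(enc, grow_mask, init_conds=rules[i]),
                ):
                    if prune_idx.size:
                        v = _prune_conditions(v, enc, prune_mask)
                    if v:
                        variants.append(v)
            dls = [
                _ruleset_dl(rules[:i] + [v] + rules[i + 1 :], enc, n_possible)
                for v in variants
            ]
            best = 0
            for k in range(1, len(variants)):
                if dls[k] < dls[best] - 1e-9:
                    best = k
            rules[i] = variants[best]
        # cover any positives the revised rules leave uncovered
        _cover_positives(rules, enc, settings, rng, n_possible)

    # selection: keep the best rules — drop, from the last rule backwards,
    # any whose removal does not increase the description length, then
    # enforce minimum coverage
    for i in range(len(rules) - 1, -1, -1):
        without = rules[:i] + rules[i + 1 :]
        if _ruleset_dl(without, enc, n_possible) <= _ruleset_dl(rules, enc, n_possible) + 1e-9:
            rules = without
    rules = [
        conds
        for conds in rules
        if conds and int(enc.rule_mask(conds).sum()) >= settings.min_weight
    ]

    model_rules = tuple(Rule(tuple(conds), pos) for conds in rules)
    covered = np.zeros(enc.n, dtype=bool)
    for conds in rules:
        covered |= enc.rule_mask(conds)
    errors = int((covered & ~enc.y).sum()) + int((~covered & enc.y).sum())
    if errors > int(enc.y.sum()):  # default-only model would be better
        return RuleListModel((), neg)
    return RuleListModel(model_rules, neg)
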