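"""RIDOR: ripple-down rule induction.

A default rule (the whole-data majority label) is refined by a tree of
exception rules: each exception predicts the opposite label of its parent
on the subset of instances it captures, and may itself carry exceptions.
Exception antecedents are found IREP-style — FOIL-gain growth on a grow
split, (p-n)/(p+n) pruning on a held-out split — reusing the machinery of
the RIPPER module. Recursion stops at label purity, when an exception
would capture fewer than ``min_weight`` instances, or when no exception
reduces the error count.

For grading, the exception tree is flattened into an ordered rule list:
deeper (more specific) exceptions are emitted before their ancestors so
that first-match prediction reproduces the tree semantics exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Mapping

import numpy as np

from ._encode import EncodedData, encode_table, stratified_split
from .ripper import _grow_conditions, _prune_conditions, _as_frame_labels
from .rules import Condition, Op, Rule, RuleListModel

__all__ = [
    "RidorSettings",
    "RIDOR_GRID",
    "ExceptionNode",
    "fit_ridor",
    "flatten_exceptions",
    "predict_tree",
]


@dataclass(frozen=True)
class RidorSettings:
    """-F (grow/prune split denominator), -S (shuffles per exception
    search), -N (minimum instances an exception must capture), -A (take
    the default label from the whole data)."""

    folds: int = 3
    shuffles: int = 1
    min_weight: float = 2.0
    whole_data_default: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.shuffles < 1:
            raise ValueError("shuffles must be >= 1")
        if self.min_weight < 1:
            raise ValueError("min_weight must be >= 1")


#: the 9-setting study grid: F in {3, 10, 20} x N in {2, 5, 10}
RIDOR_GRID: tuple[RidorSettings, ...] = tuple(
    RidorSettings(folds=f, min_weight=n)
    for f in (3, 10, 20)
    for n in (2.0, 5.0, 10.0)
)


@dataclass
class ExceptionNode:
    """One node of the ripple-down tree: an antecedent (empty at the
    root), the label predicted for captured instances, and exceptions."""

    conditions: tuple[Condition, ...]
    label: str
    children: list["ExceptionNode"] = field(default_factory=list)

    @property
    def is_root(self) -> bool:
        return not self.conditions


def predict_tree(root: ExceptionNode, subject: Mapping[str, object]) -> str:
    """Tree semantics: the first matching exception (in insertion order)
    takes over, recursively; otherwise the node's own label."""
    node = root
    while True:
        for child in node.children:
            if all(c.holds(subject) for c in child.conditions):
                node = child
                break
        else:
            return node.label


def fit_ridor(data, settings: RidorSettings | None = None, seed: int = 0) -> ExceptionNode:
    """Build the ripple-down exception tree. Deterministic given
    (data, settings, seed)."""
    frame, labels = _as_frame_labels(data)
    settings = settings or RidorSettings()
    values, counts = np.unique(labels.astype(str), return_counts=True)
    if len(values) == 1:
        return ExceptionNode((), str(values[0]))
    # whole-data default: the label minimizing training error (majority);
    # deterministic tie-break on label name
    order = np.lexsort((values, -counts))
    default = str(values[order[0]])
    other = str(values[order[1]])

    enc = encode_table(frame, labels, positive_label=other)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    root = ExceptionNode((), default)
    _grow_exceptions(root, enc, np.ones(enc.n, dtype=bool), settings, rng)
    return root


def _flip(enc: EncodedData) -> EncodedData:
    return _dc_replace(
        enc,
        y=~enc.y,
        positive_label=enc.negative_label,
        negative_label=enc.positive_label,
    )


def _grow_exceptions(
    node: ExceptionNode,
    enc: EncodedData,
    subset: np.ndarray,
    settings: RidorSettings,
    rng: np.random.Generator,
) -> None:
    """Attach exceptions to ``node`` on the instances it captures.

    ``enc.y`` must be True exactly for the exception target label, i.e.
    the label opposite to ``node.label``.
    """
    target = enc.positive_label
    idx_all = np.arange(enc.n)
    remaining = subset.copy()
    while True:
        if not enc.y[remaining].any():
            return  # pure: every captured instance agrees with the node
        best_conds: list[Condition] | None = None
        best_err = np.inf
        for _ in range(settings.shuffles):
            gi, pi = stratified_split(idx_all[remaining], enc.y, settings.folds, rng)
            grow_mask = np.zeros(enc.n, dtype=bool)
            grow_mask[gi] = True
            if not enc.y[grow_mask].any():
                continue
            conds = _grow_conditions(enc, grow_mask)
            if pi.size:
                prune_mask = np.zeros(enc.n, dtype=bool)
                prune_mask[pi] = True
                conds = _prune_conditions(conds, enc, prune_mask)
            if not conds:
                continue
            eval_mask = prune_mask if pi.size else remaining
            cm = enc.rule_mask(conds) & eval_mask
            err = int((cm & ~enc.y).sum())  # captured instances the exception mislabels
            if err < best_err:
                best_err, best_conds = err, conds
        if best_conds is None:
            return
        cov = enc.rule_mask(best_conds) & remaining
        total = int(cov.sum())
        if total < settings.min_weight:
            return
        p = int(enc.y[cov].sum())
        if p <= total - p:  # the exception does not reduce the error count
            return
        child = ExceptionNode(tuple(best_conds), target)
        _grow_exceptions(child, _flip(enc), cov, settings, rng)
        node.children.append(child)
        remaining &= ~cov


def flatten_exceptions(root: ExceptionNode) -> RuleListModel:
    """Flatten the tree to a first-match rule list.

    Each non-root node becomes a rule whose antecedent is the
    concatenation of conditions along its path; descendants are emitted
    before their ancestors, and earlier siblings (with their subtrees)
    before later ones, so list prediction equals tree prediction.
    """
    rules: list[Rule] = []

    def emit(node: ExceptionNode, path: tuple[Condition, ...]) -> None:
        for child in node.children:
            child_path = _merge_path(path, child.conditions)
            emit(child, child_path)
            rules.append(Rule(child_path, child.label))

    emit(root, ())
    return RuleListModel(tuple(rules), root.label)


def _merge_path(
    path: tuple[Condition, ...], conds: tuple[Condition, ...]
) -> tuple[Condition, ...]:
    merged = list(path)
    for c in conds:
        if c not in merged:
            merged.append(c)
    return tuple(merged)
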