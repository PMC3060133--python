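"""PART: rules from repeated partial C4.5 decision trees.

Each iteration builds a *partial* pruned decision tree on the instances
not yet covered: subsets are expanded lowest-entropy-first; a fully
expanded subtree is collapsed back to a leaf when its estimated error is
no better than a leaf's (C4.5 pessimistic error at confidence ``C``, or
reduced-error pruning on a held-out fold with ``-R``), and construction
stops as soon as such a stable leaf emerges — subsets not yet visited
stay behind as frontier leaves. The explored leaf covering the most
instances becomes a rule (its root-to-leaf path as the antecedent),
covered instances are removed, and the loop repeats.

Splits maximize C4.5 gain ratio, guarded by the mean-gain eligibility
rule; nominal attributes split multiway, or value-vs-rest when
``binary_splits`` is on (the rest branch is recorded as a NEQ condition);
numeric attributes split at midpoints of adjacent distinct values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._encode import EncodedData, encode_table, stratified_split
from .ripper import _as_frame_labels
from .rules import Condition, Op, Rule, RuleListModel

__all__ = [
    "PartSettings",
    "PART_GRID",
    "TreeNode",
    "best_split",
    "pessimistic_error",
    "build_partial_tree",
    "fit_part",
]

_EPS = 1e-9


@dataclass(frozen=True)
class PartSettings:
    """-M (minimum instances per leaf), -C (pruning confidence) or
    -R/-N (reduced-error pruning on 1/N held out), -B (binary splits)."""

    min_obj: int = 2
    confidence: float = 0.25
    reduced_error: bool = False
    folds: int = 3
    binary_splits: bool = False

    def __post_init__(self) -> None:
        if self.min_obj < 1:
            raise ValueError("min_obj must be >= 1")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


#: the 30-setting study grid: reduced-error (with/without binary splits)
#: crossed with M x N, then confidence pruning crossed with M x C
PART_GRID: tuple[PartSettings, ...] = tuple(
    [
        PartSettings(min_obj=m, reduced_error=True, folds=n, binary_splits=b)
        for b in (True, False)
        for n in (3, 10, 100)
        for m in (2, 5, 10)
    ]
    + [
        PartSettings(min_obj=m, confidence=c, binary_splits=b)
        for b in (True, False)
        for m in (2, 5, 10)
        for c in (0.25, 0.1)
    ]
)


@dataclass
class TreeNode:
    """A (partial) decision-tree node.

    ``condition_edges[i]`` is the condition leading to ``children[i]``.
    ``expanded`` is False for frontier leaves the partial-tree build never
    visited.
    """

    counts: dict[str, int]
    label: str
    condition_edges: tuple[Condition, ...] = ()
    children: tuple["TreeNode", ...] = ()
    expanded: bool = False
    error_estimate: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class Split:
    """A chosen split: the conditions of its branches, with gain stats."""

    conditions: tuple[Condition, ...]
    gain: float
    gain_ratio: float


def _entropy_vec(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    t = p + n
    with np.errstate(divide="ignore", invalid="ignore"):
        fp = np.where(t > 0, p / np.maximum(t, 1), 0.0)
        fn = np.where(t > 0, n / np.maximum(t, 1), 0.0)
        h = -np.where(p > 0, fp * np.log2(np.maximum(fp, 1e-300)), 0.0) - np.where(
            n > 0, fn * np.log2(np.maximum(fn, 1e-300)), 0.0
        )
    return h


def _split_stats(p_children: np.ndarray, n_children: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(gain, gain_ratio) for splits given per-child (…, k) count arrays."""
    t_children = p_children + n_children
    total = t_children.sum(axis=-1, keepdims=True)
    P = p_children.sum(axis=-1, keepdims=True)
    N = n_children.sum(axis=-1, keepdims=True)
    h_parent = _entropy_vec(P, N)[..., 0]
    w = t_children / np.maximum(total, 1)
    h_children = (_entropy_vec(p_children, n_children) * w).sum(axis=-1)
    gain = h_parent - h_children
    with np.errstate(divide="ignore", invalid="ignore"):
        split_info = -(w * np.log2(np.where(w > 0, w, 1.0))).sum(axis=-1)
    ratio = np.where(split_info > _EPS, gain / np.maximum(split_info, _EPS), -np.inf)
    return gain, ratio


def _candidate_splits(
    enc: EncodedData, mask: np.ndarray, settings: PartSettings
) -> list[Split]:
    """All eligible splits in canonical order (nominal attributes in column
    order — levels in level order under binary splits — then numeric
    thresholds ascending)."""
    out: list[Split] = []
    yc = enc.y[mask]
    n_here = int(mask.sum())
    if enc.nom.shape[1]:
        Xc = enc.nom[mask]
        Xp, Xn = Xc[yc], Xc[~yc]
        max_levels = max(len(lv) for lv in enc.nom_levels)
        p_cnt = np.stack([(Xp == v).sum(axis=0) for v in range(max_levels)], axis=1)
        n_cnt = np.stack([(Xn == v).sum(axis=0) for v in range(max_levels)], axis=1)
        if settings.binary_splits:
            # one split per attribute: the value-vs-rest cut with maximal
            # information gain (gain ratio only arbitrates across attributes)
            for j, levels in enumerate(enc.nom_levels):
                best: Split | None = None
                for v in range(len(levels)):
                    pc = np.array([p_cnt[j, v], p_cnt[j].sum() - p_cnt[j, v]])
                    nc = np.array([n_cnt[j, v], n_cnt[j].sum() - n_cnt[j, v]])
                    if (pc + nc).min() < settings.min_obj:
                        continue
                    gain, ratio = _split_stats(pc[None, :], nc[None, :])
                    if gain[0] > _EPS and (best is None or gain[0] > best.gain + _EPS):
                        best = Split(
                            (
                                enc.condition("nom", j, v, Op.EQ),
                                enc.condition("nom", j, v, Op.NEQ),
                            ),
                            float(gain[0]),
                            float(ratio[0]),
                        )
                if best is not None:
                    out.append(best)
        else:
            gain, ratio = _split_stats(p_cnt.astype(float), n_cnt.astype(float))
            child_sizes = p_cnt + n_cnt
            for j, levels in enumerate(enc.nom_levels):
                # C4.5 eligibility: at least two branches of adequate size
                if (child_sizes[j, : len(levels)] >= settings.min_obj).sum() < 2:
                    continue
                if gain[j] > _EPS:
                    out.append(
                        Split(
                            tuple(
                                enc.condition("nom", j, v, Op.EQ)
                                for v in range(len(levels))
                            ),
                            float(gain[j]),
                            float(ratio[j]),
                        )
                    )

    for j in range(enc.num.shape[1]):
        vals = enc.num[mask, j]
        order = np.argsort(vals, kind="stable")
        v = vals[order]
        yy = yc[order]
        change = np.nonzero(np.diff(v) != 0)[0]
        if change.size == 0:
            continue
        cum_p = np.cumsum(yy)
        P = int(cum_p[-1])
        p_le = cum_p[change].astype(float)
        t_le = (change + 1).astype(float)
        n_le = t_le - p_le
        thresholds = (v[change] + v[change + 1]) / 2.0
        pc = np.stack([p_le, P - p_le], axis=1)
        nc = np.stack([n_le, (n_here - P) - n_le], axis=1)
        gain, ratio = _split_stats(pc, nc)
        sizes = pc + nc
        # the attribute's threshold is the one maximizing information gain
        eligible = (sizes.min(axis=1) >= settings.min_obj) & (gain > _EPS)
        if not eligible.any():
            continue
        gain = np.where(eligible, gain, -np.inf)
        i = int(np.argmax(gain))
        out.append(
            Split(
                (
                    enc.condition("num", j, thresholds[i], Op.LE),
                    enc.condition("num", j, thresholds[i], Op.GT),
                ),
                float(gain[i]),
                float(ratio[i]),
            )
        )
    return out


def _best_split(enc: EncodedData, mask: np.ndarray, settings: PartSettings) -> Split | None:
    candidates = _candidate_splits(enc, mask, settings)
    if not candidates:
        return None
    mean_gain = sum(c.gain for c in candidates) / len(candidates)
    best: Split | None = None
    for c in candidates:
        if c.gain + _EPS < mean_gain:
            continue
        if best is None or c.gain_ratio > best.gain_ratio + _EPS:
            best = c
    return best


def best_split(
    frame: pd.DataFrame,
    labels,
    settings: PartSettings | None = None,
    positive_label: str = "Case",
) -> Split | None:
    """The gain-ratio-maximizing eligible split, or None ("make leaf")."""
    settings = settings or PartSettings()
    enc = encode_table(frame, labels, positive_label)
    return _best_split(enc, np.ones(enc.n, dtype=bool), settings)


# ---------------------------------------------------------------------------
# pruning estimates


def pessimistic_error(total: int, errors: int, confidence: float) -> float:
    """C4.5's pessimistic error count for a leaf: observed errors plus the
    one-sided Wilson-style upper-bound correction at the given confidence
    (with the 0.5 continuity correction)."""
    N = float(total)
    e = float(errors)
    if N <= 0:
        return 0.0
    if e >= N:
        return N
    if e == 0:
        return N * (1.0 - confidence ** (1.0 / N))
    z = float(norm.ppf(1.0 - confidence))
    f = (e + 0.5) / N
    r = (f + z * z / (2 * N) + z * math.sqrt(f / N - f * f / N + z * z / (4 * N * N))) / (
        1.0 + z * z / N
    )
    return min(r * N, N)  # upper-bound error count


# ---------------------------------------------------------------------------
# partial-tree construction


def _majority(p: int, n: int, enc: EncodedData) -> str:
    # ties go to the negative (majority-class) label
    return enc.positive_label if p > n else enc.negative_label


def _leaf(enc: EncodedData, grow: np.ndarray, prune: np.ndarray | None, settings: PartSettings) -> TreeNode:
    p = int(enc.y[grow].sum())
    n = int(grow.sum()) - p
    label = _majority(p, n, enc)
    err_grow = n if label == enc.positive_label else p
    if settings.reduced_error and prune is not None:
        yp = enc.y[prune]
        est = float((yp != (label == enc.positive_label)).sum())
    else:
        est = pessimistic_error(p + n, err_grow, settings.confidence)
    return TreeNode(
        counts={enc.positive_label: p, enc.negative_label: n},
        label=label,
        error_estimate=est,
    )


def _expand(
    enc: EncodedData,
    grow: np.ndarray,
    prune: np.ndarray | None,
    settings: PartSettings,
) -> tuple[TreeNode, bool]:
    """Recursive partial expansion.

    Children are expanded lowest-entropy-first. The boolean in the return
    value signals that somewhere below a fully expanded subtree was pruned
    back to a leaf — the *stable leaf* that ends partial-tree construction;
    once it appears, remaining siblings stay frontier leaves all the way up.
    """
    p = int(enc.y[grow].sum())
    n = int(grow.sum()) - p
    if p == 0 or n == 0 or p + n < 2 * settings.min_obj:
        return _leaf(enc, grow, prune, settings), False
    split = _best_split(enc, grow, settings)
    if split is None:
        return _leaf(enc, grow, prune, settings), False

    edge_masks = [enc.condition_mask(c) for c in split.conditions]
    child_grow = [grow & m for m in edge_masks]
    child_prune = [prune & m for m in edge_masks] if prune is not None else [None] * len(edge_masks)

    ent = []
    for g in child_grow:
        cp = int(enc.y[g].sum())
        cn = int(g.sum()) - cp
        ent.append(float(_entropy_vec(np.array([cp]), np.array([cn]))[0]))
    order = np.argsort(np.array(ent), kind="stable")

    children: list[TreeNode | None] = [None] * len(edge_masks)
    stopped = False
    for k in order:
        child, child_stopped = _expand(enc, child_grow[k], child_prune[k], settings)
        children[k] = child
        if child_stopped:
            stopped = True
            break
    for k in range(len(children)):
        if children[k] is None:
            leaf = _leaf(enc, child_grow[k], child_prune[k], settings)
            children[k] = leaf
        else:
            children[k].expanded = True  # type: ignore[union-attr]

    node_as_leaf = _leaf(enc, grow, prune, settings)
    subtree_error = float(sum(c.error_estimate for c in children))  # type: ignore[union-attr]
    all_leaves = all(c.is_leaf for c in children)  # type: ignore[union-attr]
    if not stopped and all_leaves and node_as_leaf.error_estimate <= subtree_error + 1e-9:
        # the split does not pay for itself: prune back, which is exactly
        # the event that ends partial-tree construction
        return node_as_leaf, True

    node = TreeNode(
        counts=node_as_leaf.counts,
        label=node_as_leaf.label,
        condition_edges=split.conditions,
        children=tuple(children),  # type: ignore[arg-type]
        expanded=True,
        error_estimate=subtree_error,
    )
    return node, stopped


def build_partial_tree(
    frame: pd.DataFrame,
    labels,
    settings: PartSettings | None = None,
    seed: int = 0,
    positive_label: str = "Case",
) -> TreeNode:
    """Build one partial pruned tree on the full table."""
    settings = settings or PartSettings()
    enc = encode_table(frame, labels, positive_label)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    grow, prune = _split_for_pruning(enc, np.ones(enc.n, dtype=bool), settings, rng)
    return _expand(enc, grow, prune, settings)[0]


def _split_for_pruning(
    enc: EncodedData,
    mask: np.ndarray,
    settings: PartSettings,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    if not settings.reduced_error:
        return mask, None
    idx = np.arange(enc.n)[mask]
    gi, pi = stratified_split(idx, enc.y, settings.folds, rng)
    grow = np.zeros(enc.n, dtype=bool)
    grow[gi] = True
    prune = np.zeros(enc.n, dtype=bool)
    prune[pi] = True
    return grow, prune


# ---------------------------------------------------------------------------
# the covering loop


def fit_part(data, settings: PartSettings | None = None, seed: int = 0) -> RuleListModel:
    """Sequential covering with partial trees. Deterministic given
    (data, settings, seed)."""
    frame, labels = _as_frame_labels(data)
    settings = settings or PartSettings()
    from ._encode import minority_label

    pos = minority_label(labels)
    enc = encode_table(frame, labels, pos)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    remaining = np.ones(enc.n, dtype=bool)
    rules: list[Rule] = []
    default: str | None = None
    while remaining.any():
        p = int(enc.y[remaining].sum())
        n = int(remaining.sum()) - p
        if p == 0 or n == 0:
            default = _majority(p, n, enc)
            break
        grow, prune = _split_for_pruning(enc, remaining, settings, rng)
        tree = _expand(enc, grow, prune, settings)[0]
        if tree.is_leaf:
            default = tree.label
            break
        path, label, leaf_mask = _best_leaf(enc, tree, remaining)
        rules.append(Rule(path, label))
        remaining &= ~leaf_mask

    if default is None:
        # the loop consumed everything: fall back to the global majority
        default = _majority(int(enc.y.sum()), int((~enc.y).sum()), enc)
    return RuleListModel(tuple(rules), default)


def _best_leaf(
    enc: EncodedData, tree: TreeNode, remaining: np.ndarray
) -> tuple[tuple[Condition, ...], str, np.ndarray]:
    """The rule-producing leaf: maximum coverage of ``remaining`` among the
    leaves the partial expansion actually visited; ties go to fewer
    misclassified instances, then to DFS (canonical split) order.

    Frontier leaves (subsets construction never explored) are considered
    only if no explored leaf exists — their majority labels were never
    vetted by pruning, and their subsets are better served by later
    covering iterations.
    """
    best: tuple[bool, int, int, int] | None = None
    best_out: tuple[tuple[Condition, ...], str, np.ndarray] | None = None
    counter = [0]

    def walk(node: TreeNode, path: tuple[Condition, ...], mask: np.ndarray) -> None:
        nonlocal best, best_out
        if node.is_leaf:
            cov = int(mask.sum())
            err = int((enc.y[mask] != (node.label == enc.positive_label)).sum())
            frontier = bool(path) and not node.expanded
            key = (frontier, -cov, err, counter[0])
            counter[0] += 1
            if best is None or key < best:
                best = key
                best_out = (path, node.label, mask.copy())
            return
        for cond, child in zip(node.condition_edges, node.children):
            walk(child, path + (cond,), mask & enc.condition_mask(cond))

    walk(tree, (), remaining.copy())
    assert best_out is not None
    return best_out
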