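"""Internal numeric encoding of subject tables for the rule learners.

Nominal columns become int8 code matrices (one code per level, level order
fixed by the column's categories), numeric columns a float matrix. All
learners share this representation and the canonical candidate-condition
order it defines: nominal attributes in column order (levels in level
order), then numeric attributes in column order. Deterministic tie-breaks
everywhere refer to this order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rules import Condition, Op


@dataclass
class EncodedData:
    nom: np.ndarray                 # (n, p_nom) int8 codes
    nom_names: list[str]
    nom_levels: list[tuple[str, ...]]
    num: np.ndarray                 # (n, p_num) float64
    num_names: list[str]
    y: np.ndarray                   # bool, True = positive class
    positive_label: str
    negative_label: str

    @property
    def n(self) -> int:
        return len(self.y)

    def condition(self, kind: str, j: int, value: int | float, op: Op = Op.EQ) -> Condition:
        if kind == "nom":
            return Condition(self.nom_names[j], op, self.nom_levels[j][int(value)])
        return Condition(self.num_names[j], op, float(value))

    def condition_mask(self, cond: Condition) -> np.ndarray:
        if cond.op in (Op.EQ, Op.NEQ):
            j = self.nom_names.index(cond.attribute)
            code = self.nom_levels[j].index(str(cond.value))
            eq = self.nom[:, j] == code
            return eq if cond.op is Op.EQ else ~eq
        j = self.num_names.index(cond.attribute)
        col = self.num[:, j]
        return col > float(cond.value) if cond.op is Op.GT else col <= float(cond.value)

    def rule_mask(self, conditions) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        for c in conditions:
            mask &= self.condition_mask(c)
        return mask


def encode_table(
    frame: pd.DataFrame,
    labels,
    positive_label: str,
    negative_label: str | None = None,
) -> EncodedData:
    nom_cols: list[str] = []
    num_cols: list[str] = []
    for col in frame.columns:
        if pd.api.types.is_numeric_dtype(frame[col]):
            num_cols.append(col)
        else:
            nom_cols.append(col)

    nom_levels: list[tuple[str, ...]] = []
    nom = np.empty((len(frame), len(nom_cols)), dtype=np.int8)
    for j, col in enumerate(nom_cols):
        s = frame[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            levels = tuple(str(c) for c in s.cat.categories)
            codes = s.cat.codes.to_numpy()
        else:
            levels_arr, codes = np.unique(s.astype(str).to_numpy(), return_inverse=True)
            levels = tuple(sorted(levels_arr))
            remap = np.array([levels.index(v) for v in levels_arr])
            codes = remap[codes]
        nom_levels.append(levels)
        nom[:, j] = codes.astype(np.int8)

    num = frame[num_cols].to_numpy(dtype=np.float64) if num_cols else np.zeros((len(frame), 0))

    y_arr = np.asarray(labels, dtype=object)
    y = y_arr == positive_label
    if negative_label is None:
        others = sorted({str(v) for v in y_arr[~y]})
        negative_label = others[0] if others else ("Control" if positive_label != "Control" else "Case")

    return EncodedData(nom, nom_cols, nom_levels, num, num_cols, y, positive_label, negative_label)


def minority_label(labels, tie: str = "Case") -> str:
    """The rarer of the two labels; prefers ``tie`` on a tie."""
    vals, counts = np.unique(np.asarray(labels, dtype=object).astype(str), return_counts=True)
    order = np.argsort(counts, kind="stable")
    least = counts.min()
    tied = [v for v, c in zip(vals, counts) if c == least]
    if tie in tied:
        return tie
    return str(vals[order[0]])


def stratified_split(
    idx: np.ndarray, y: np.ndarray, folds: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split instance indices into grow ((folds-1)/folds) and prune (1/folds)
    sets, stratified by class. A class with fewer than ``folds`` members
    contributes nothing to the prune set."""
    grow: list[np.ndarray] = []
    prune: list[np.ndarray] = []
    for cls in (True, False):
        members = idx[y[idx] == cls]
        perm = rng.permutation(len(members))
        k = len(members) // folds
        prune.append(members[perm[:k]])
        grow.append(members[perm[k:]])
    return np.sort(np.concatenate(grow)), np.sort(np.concatenate(prune))
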