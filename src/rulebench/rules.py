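"""Conjunction-rule lists: the common output language of the rule learners.

A :class:`RuleListModel` is an ordered list of IF-THEN rules over nominal
(genotype) and numeric (environmental) attributes, plus a default label.
Prediction is first-match with fall-through to the default — the semantics
of classical sequential-covering rule learners.

The canonical text form mirrors the way such models are written in the
epidemiological literature::

    If rs5 = AA and rs10 = AB then Case
    If rs15 = AA and AUC > 105 then Case
    Else Control
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Op",
    "Condition",
    "Rule",
    "RuleListModel",
    "CoverageStats",
    "matches",
    "predict",
    "rule_mask",
    "coverage",
    "to_text",
    "parse_text",
    "RuleParseError",
]


class Op(str, Enum):
    """Condition operator.

    EQ / NEQ apply to nominal attributes, GT / LE to numeric thresholds
    (binary splits; numeric equality is deliberately not representable).
    NEQ arises only from the rest-branch of a binary nominal split.
    """

    EQ = "="
    NEQ = "!="
    GT = ">"
    LE = "<="


_NUMERIC_OPS = (Op.GT, Op.LE)


@dataclass(frozen=True)
class Condition:
    attribute: str
    op: Op
    value: str | float

    def __post_init__(self) -> None:
        if self.op in _NUMERIC_OPS and not isinstance(self.value, (int, float)):
            raise ValueError(f"numeric operator {self.op.value!r} needs a numeric threshold")
        if self.op in (Op.EQ, Op.NEQ) and not isinstance(self.value, str):
            raise ValueError(f"nominal operator {self.op.value!r} needs a nominal level")

    def holds(self, subject: Mapping[str, object]) -> bool:
        if self.attribute not in subject:
            raise KeyError(f"subject lacks attribute {self.attribute!r}")
        v = subject[self.attribute]
        if self.op is Op.EQ:
            return v == self.value
        if self.op is Op.NEQ:
            return v != self.value
        if self.op is Op.GT:
            return float(v) > float(self.value)  # type: ignore[arg-type]
        return float(v) <= float(self.value)  # type: ignore[arg-type]

    def __str__(self) -> str:
        return f"{self.attribute} {self.op.value} {_fmt_value(self.value)}"


def _fmt_value(v: str | float) -> str:
    if isinstance(v, str):
        return v
    f = float(v)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


@dataclass(frozen=True)
class Rule:
    """A conjunction of conditions with a predicted label.

    An empty conjunction matches every subject.
    """

    conditions: tuple[Condition, ...]
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        seen_eq: set[str] = set()
        for c in self.conditions:
            if c.op is Op.EQ:
                if c.attribute in seen_eq:
                    raise ValueError(f"attribute {c.attribute!r} constrained twice with '='")
                seen_eq.add(c.attribute)

    @property
    def attributes(self) -> tuple[str, ...]:
        """Distinct attribute names, in first-occurrence order."""
        out: list[str] = []
        for c in self.conditions:
            if c.attribute not in out:
                out.append(c.attribute)
        return tuple(out)

    def __str__(self) -> str:
        if not self.conditions:
            return f"If true then {self.label}"
        body = " and ".join(str(c) for c in self.conditions)
        return f"If {body} then {self.label}"


@dataclass(frozen=True)
class RuleListModel:
    rules: tuple[Rule, ...]
    default_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))

    @property
    def attributes(self) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.rules:
            for a in r.attributes:
                if a not in out:
                    out.append(a)
        return tuple(out)

    def case_rules(self, positive_label: str = "Case") -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.label == positive_label)

    def __str__(self) -> str:
        return to_text(self)


@dataclass(frozen=True)
class CoverageStats:
    """Covered positive (p) and negative (n) instance counts."""

    p: int
    n: int

    def __post_init__(self) -> None:
        if self.p < 0 or self.n < 0:
            raise ValueError("coverage counts must be non-negative")

    @property
    def total(self) -> int:
        return self.p + self.n


def matches(rule: Rule, subject: Mapping[str, object]) -> bool:
    """True iff every condition of ``rule`` holds for ``subject``."""
    return all(c.holds(subject) for c in rule.conditions)


def predict(model: RuleListModel, subject: Mapping[str, object]) -> str:
    """First-match prediction with fall-through to the default label."""
    for rule in model.rules:
        if matches(rule, subject):
            return rule.label
    return model.default_label


def rule_mask(rule: Rule, frame: pd.DataFrame) -> np.ndarray:
    """Boolean vector of the subjects in ``frame`` matched by ``rule``."""
    mask = np.ones(len(frame), dtype=bool)
    for c in rule.conditions:
        col = frame[c.attribute]
        if c.op is Op.EQ:
            mask &= (col == c.value).to_numpy()
        elif c.op is Op.NEQ:
            mask &= (col != c.value).to_numpy()
        elif c.op is Op.GT:
            mask &= (col.to_numpy(dtype=float) > float(c.value))
        else:
            mask &= (col.to_numpy(dtype=float) <= float(c.value))
    return mask


def predict_frame(model: RuleListModel, frame: pd.DataFrame) -> np.ndarray:
    """Vectorized first-match prediction over a subject table."""
    out = np.full(len(frame), model.default_label, dtype=object)
    undecided = np.ones(len(frame), dtype=bool)
    for rule in model.rules:
        hit = rule_mask(rule, frame) & undecided
        out[hit] = rule.label
        undecided &= ~hit
        if not undecided.any():
            break
    return out


def coverage(
    rule: Rule,
    frame: pd.DataFrame,
    labels: Sequence[str] | np.ndarray | pd.Series,
    positive_label: str = "Case",
) -> CoverageStats:
    """Count covered positives/negatives of ``rule`` on a labelled table."""
    mask = rule_mask(rule, frame)
    y = np.asarray(labels, dtype=object) == positive_label
    p = int((mask & y).sum())
    n = int(mask.sum()) - p
    return CoverageStats(p, n)


# ---------------------------------------------------------------------------
# canonical text serialization


class RuleParseError(ValueError):
    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        prefix = f"line {line_no}: " if line_no is not None else ""
        super().__init__(prefix + message)


def to_text(model: RuleListModel) -> str:
    lines = [str(r) for r in model.rules]
    lines.append(f"Else {model.default_label}")
    return "\n".join(lines)


_COND_RE = re.compile(r"^\s*(\S+)\s*(<=|!=|=|>)\s*(\S+)\s*$")
_RULE_RE = re.compile(r"^If\s+(.*\S)\s+then\s+(\S+)$", re.IGNORECASE)
_ELSE_RE = re.compile(r"^Else\s+(\S+)$", re.IGNORECASE)
_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_condition(text: str, line_no: int) -> Condition:
    m = _COND_RE.match(text)
    if m is None:
        raise RuleParseError(f"cannot parse condition {text!r}", line_no)
    attr, op_s, val_s = m.groups()
    op = Op(op_s)
    if op in _NUMERIC_OPS:
        if not _NUM_RE.match(val_s):
            raise RuleParseError(f"numeric operator with non-numeric value {val_s!r}", line_no)
        return Condition(attr, op, float(val_s))
    return Condition(attr, op, val_s)


def parse_text(text: str) -> RuleListModel:
    """Parse the canonical grammar: ``If <attr> <op> <value> [and ...] then
    <label>`` lines followed by a final ``Else <label>`` line."""
    rules: list[Rule] = []
    default: str | None = None
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if default is not None:
            raise RuleParseError("content after the Else line", line_no)
        m = _ELSE_RE.match(line)
        if m:
            default = m.group(1)
            continue
        m = _RULE_RE.match(line)
        if m is None:
            raise RuleParseError(f"cannot parse rule {line!r}", line_no)
        body, label = m.groups()
        if body.strip().lower() == "true":
            conds: tuple[Condition, ...] = ()
        else:
            conds = tuple(
                _parse_condition(part, line_no) for part in re.split(r"\s+and\s+", body)
            )
        rules.append(Rule(conds, label))
    if default is None:
        raise RuleParseError("missing final 'Else <label>' line")
    return RuleListModel(tuple(rules), default)


# ---------------------------------------------------------------------------
# JSON export


def model_to_json(
    model: RuleListModel,
    frame: pd.DataFrame | None = None,
    labels: Sequence[str] | None = None,
    positive_label: str = "Case",
) -> str:
    """JSON export, optionally annotated with per-rule training coverage."""
    rules = []
    for r in model.rules:
        entry: dict[str, object] = {
            "conditions": [
                {"attribute": c.attribute, "op": c.op.value, "value": c.value}
                for c in r.conditions
            ],
            "label": r.label,
        }
        if frame is not None and labels is not None:
            st = coverage(r, frame, labels, positive_label)
            entry["coverage"] = {"p": st.p, "n": st.n}
        rules.append(entry)
    return json.dumps({"rules": rules, "default_label": model.default_label}, indent=1)


def model_from_json(text: str) -> RuleListModel:
    obj = json.loads(text)
    rules = tuple(
        Rule(
            tuple(
                Condition(c["attribute"], Op(c["op"]), c["value"])
                for c in r["conditions"]
            ),
            r["label"],
        )
        for r in obj["rules"]
    )
    return RuleListModel(rules, obj["default_label"])
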