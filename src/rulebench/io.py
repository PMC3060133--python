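"""Reading and writing simulated datasets as ARFF or CSV.

The ARFF dialect is the classic WEKA one: ``@relation``, one
``@attribute`` line per column (nominal genotype domains ``{AA,AB,BB}``,
``numeric`` for AUC, ``{Case,Control}`` for the class), then ``@data``
with comma-separated rows.

The pre-noise (true) labels and the generating configuration are stored
in a JSON sidecar next to the data file (``<path>.meta.json``) so the
classifier-visible table never leaks the truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CASE, CONTROL, GENOTYPES, Dataset, SimulationConfig, SnpSpec

__all__ = ["write_dataset", "read_dataset", "DatasetParseError", "sidecar_path"]


class DatasetParseError(ValueError):
    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        prefix = f"line {line_no}: " if line_no is not None else ""
        super().__init__(prefix + message)


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.json")


def write_dataset(dataset: Dataset, path: str | Path, format: str | None = None) -> Path:
    """Serialize ``dataset`` to ``path`` plus a ``.meta.json`` sidecar."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    table = dataset.table()
    if fmt == "arff":
        _write_arff(table, path)
    elif fmt == "csv":
        table.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'arff' or 'csv')")

    meta: dict[str, object] = {
        "snps": [asdict(s) for s in dataset.snps],
    }
    if dataset.config is not None:
        meta["config"] = asdict(dataset.config)
    if dataset.true_labels is not None:
        meta["true_labels"] = [str(x) for x in dataset.true_labels]
    sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_dataset(path: str | Path, format: str | None = None) -> Dataset:
    """Parse a dataset written by :func:`write_dataset`.

    The sidecar is optional: without it the true labels and configuration
    are simply absent.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "arff":
        table = _read_arff(path)
    elif fmt == "csv":
        table = _read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'arff' or 'csv')")

    if "class" not in table.columns:
        raise DatasetParseError("dataset has no 'class' column")
    observed = table.pop("class").to_numpy(dtype=object)

    config = None
    snps: tuple[SnpSpec, ...] = ()
    true_labels = None
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
        if "config" in meta:
            cfg = dict(meta["config"])
            for key in ("auc_low_range", "auc_high_range"):
                if key in cfg and cfg[key] is not None:
                    cfg[key] = tuple(cfg[key])
            config = SimulationConfig(**cfg)
        snps = tuple(SnpSpec(**s) for s in meta.get("snps", []))
        if "true_labels" in meta:
            true_labels = np.array(meta["true_labels"], dtype=object)

    for col in table.columns:
        if table[col].dtype == object:
            table[col] = pd.Categorical(table[col], categories=list(GENOTYPES))
    return Dataset(config, snps, table, observed, true_labels)


# ---------------------------------------------------------------------------
# ARFF


def _write_arff(table: pd.DataFrame, path: Path) -> None:
    lines = [f"@relation {path.stem}"]
    for col in table.columns:
        if col == "class":
            lines.append(f"@attribute class {{{CASE},{CONTROL}}}")
        elif pd.api.types.is_numeric_dtype(table[col]):
            lines.append(f"@attribute {col} numeric")
        else:
            lines.append(f"@attribute {col} {{{','.join(GENOTYPES)}}}")
    lines.append("@data")
    cols = [table[c].astype(object).to_numpy() for c in table.columns]
    for i in range(len(table)):
        lines.append(",".join(_fmt_cell(c[i]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def _fmt_cell(v: object) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _read_arff(path: Path) -> pd.DataFrame:
    names: list[str] = []
    domains: list[set[str] | None] = []  # None marks a numeric attribute
    rows: list[list[object]] = []
    in_data = False
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if not in_data:
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                rest = line[len("@attribute"):].strip()
                if "{" in rest:
                    name, _, dom = rest.partition("{")
                    levels = {t.strip() for t in dom.rstrip("}").split(",")}
                    names.append(name.strip())
                    domains.append(levels)
                else:
                    parts = rest.split()
                    if len(parts) != 2 or parts[1].lower() not in ("numeric", "real", "integer"):
                        raise DatasetParseError(f"unsupported attribute declaration {line!r}", line_no)
                    names.append(parts[0])
                    domains.append(None)
                continue
            if low.startswith("@data"):
                if not names:
                    raise DatasetParseError("@data before any @attribute", line_no)
                in_data = True
                continue
            raise DatasetParseError(f"unexpected header line {line!r}", line_no)
        tokens = [t.strip() for t in line.split(",")]
        if len(tokens) != len(names):
            raise DatasetParseError(
                f"expected {len(names)} values, got {len(tokens)}", line_no
            )
        row: list[object] = []
        for tok, dom in zip(tokens, domains):
            if dom is None:
                try:
                    row.append(float(tok))
                except ValueError:
                    raise DatasetParseError(f"non-numeric value {tok!r}", line_no) from None
            else:
                if tok not in dom:
                    raise DatasetParseError(
                        f"value {tok!r} outside declared domain {sorted(dom)}", line_no
                    )
                row.append(tok)
        rows.append(row)
    if not in_data:
        raise DatasetParseError("no @data section found")
    return pd.DataFrame(rows, columns=names)


# ---------------------------------------------------------------------------
# CSV


def _read_csv(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype=object)
    valid_geno = set(GENOTYPES)
    for col in table.columns:
        if col == "class":
            bad = ~table[col].isin((CASE, CONTROL))
            if bad.any():
                line_no = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
                raise DatasetParseError(
                    f"illegal class label {table[col][bad].iloc[0]!r}", line_no
                )
            continue
        values = table[col]
        if values.isin(valid_geno).all():
            continue
        try:
            table[col] = values.astype(float)
        except ValueError:
            bad = ~values.isin(valid_geno)
            line_no = int(np.argmax(bad.to_numpy())) + 2
            raise DatasetParseError(
                f"illegal genotype token {values[bad].iloc[0]!r} in column {col!r}", line_no
            ) from None
    return table
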