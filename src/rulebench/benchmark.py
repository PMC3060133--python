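"""Study driver: enumerate the dataset x learner-setting matrix, execute
runs, grade every result against the generating truth, and summarize.

The full study crosses the 42 simulated datasets with 18 RIPPER, 9 RIDOR
and 30 PART option settings (57 per dataset, 2394 runs). Each run gets a
seed derived deterministically from the master seed and its coordinates,
so the matrix is reproducible and resumable run by run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grading import Grade, grade_model, grade_rule, grade_attributes, rank_attributes
from .part import PART_GRID, PartSettings, fit_part
from .ridor import RIDOR_GRID, RidorSettings, fit_ridor, flatten_exceptions
from .ripper import RIPPER_GRID, RipperSettings, fit_ripper
from .rules import RuleListModel, parse_text, to_text
from .simulate import (
    CASE,
    Dataset,
    SimulationConfig,
    TrueModel,
    generate_dataset,
    table2_configs,
    true_model,
)

__all__ = [
    "ALGORITHMS",
    "RunSpec",
    "ResultRecord",
    "BenchmarkConfig",
    "enumerate_runs",
    "fit_algorithm",
    "run_benchmark",
    "summarize_statistics",
    "summarize_qualitative",
    "summarize_quantitative",
]

logger = logging.getLogger(__name__)

#: algorithm name -> (settings grid, fitting function returning a RuleListModel)
ALGORITHMS: dict[str, tuple[tuple, Callable]] = {
    "ripper": (RIPPER_GRID, fit_ripper),
    "ridor": (RIDOR_GRID, lambda data, s, seed: flatten_exceptions(fit_ridor(data, s, seed))),
    "part": (PART_GRID, fit_part),
}


@dataclass(frozen=True)
class RunSpec:
    dataset_id: int
    algorithm: str
    setting_index: int
    seed: int

    @property
    def key(self) -> str:
        return f"ds{self.dataset_id:02d}_{self.algorithm}_s{self.setting_index:02d}"


def _run_seed(master_seed: int, dataset_id: int, algorithm: str, setting_index: int) -> int:
    algo_idx = sorted(ALGORITHMS).index(algorithm)
    ss = np.random.SeedSequence([master_seed, dataset_id, algo_idx, setting_index])
    return int(ss.generate_state(1)[0] % (2**31))


def enumerate_runs(
    dataset_ids: Sequence[int],
    settings_grids: Mapping[str, Sequence] | None = None,
    master_seed: int = 0,
) -> list[RunSpec]:
    """One RunSpec per (dataset, algorithm setting), in deterministic
    order: datasets outer, algorithms alphabetical, settings by grid index."""
    grids = settings_grids if settings_grids is not None else {
        name: grid for name, (grid, _) in ALGORITHMS.items()
    }
    runs: list[RunSpec] = []
    for ds in dataset_ids:
        for algo in sorted(grids):
            for k in range(len(grids[algo])):
                runs.append(RunSpec(ds, algo, k, _run_seed(master_seed, ds, algo, k)))
    return runs


@dataclass
class ResultRecord:
    run: RunSpec
    model_text: str
    n_rules: int                    # emitted rules plus the default rule
    n_unique_attributes: int
    model_grades: dict[str, str]    # truth id -> grade letter
    rule_grades: dict[str, list[str]]  # truth id -> per case rule
    elapsed: float = 0.0
    error: str | None = None

    @property
    def model(self) -> RuleListModel:
        return parse_text(self.model_text)

    def to_json(self) -> str:
        return json.dumps(
            {
                "dataset_id": self.run.dataset_id,
                "algorithm": self.run.algorithm,
                "setting_index": self.run.setting_index,
                "seed": self.run.seed,
                "model_text": self.model_text,
                "n_rules": self.n_rules,
                "n_unique_attributes": self.n_unique_attributes,
                "model_grades": self.model_grades,
                "rule_grades": self.rule_grades,
                "elapsed": self.elapsed,
                "error": self.error,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ResultRecord":
        d = json.loads(text)
        run = RunSpec(d["dataset_id"], d["algorithm"], d["setting_index"], d["seed"])
        return cls(
            run,
            d["model_text"],
            d["n_rules"],
            d["n_unique_attributes"],
            d["model_grades"],
            {k: list(v) for k, v in d["rule_grades"].items()},
            d.get("elapsed", 0.0),
            d.get("error"),
        )


@dataclass
class BenchmarkConfig:
    """Which datasets and learner settings to run.

    ``dataset_configs`` defaults to the full 42-dataset study grid;
    ``settings`` maps algorithm name to the settings subset to run (grid
    defaults). ``out_dir`` enables one-JSON-per-run persistence with
    resume-by-key.
    """

    dataset_configs: list[SimulationConfig] = field(default_factory=table2_configs)
    settings: dict[str, Sequence] = field(
        default_factory=lambda: {name: grid for name, (grid, _) in ALGORITHMS.items()}
    )
    master_seed: int = 0
    out_dir: Path | None = None


def _truth_ids(model_id: str) -> list[str]:
    # null-model datasets are graded against both real truths: any
    # accordance found there is a false positive
    return ["A", "B"] if model_id == "C" else [model_id]


def fit_algorithm(algorithm: str, data, settings=None, seed: int = 0) -> RuleListModel:
    """Fit one learner by name, returning the flattened rule-list model."""
    grid, fitter = ALGORITHMS[algorithm]
    return fitter(data, settings, seed)


def _grade_run(model: RuleListModel, dataset: Dataset) -> tuple[dict[str, str], dict[str, list[str]]]:
    model_grades: dict[str, str] = {}
    rule_grades: dict[str, list[str]] = {}
    for tid in _truth_ids(dataset.config.model_id):
        tm = true_model(tid)
        model_grades[tid] = grade_model(model, tm, dataset.frame).name
        rule_grades[tid] = [
            grade_rule(r, tm, dataset.frame).name for r in model.case_rules(CASE)
        ]
    return model_grades, rule_grades


def run_benchmark(config: BenchmarkConfig) -> list[ResultRecord]:
    """Execute every run in the config's matrix; failures are recorded and
    the benchmark continues."""
    records: list[ResultRecord] = []
    run_dir = None
    if config.out_dir is not None:
        run_dir = Path(config.out_dir) / "runs"
        run_dir.mkdir(parents=True, exist_ok=True)

    for ds_config in config.dataset_configs:
        ds_id = ds_config.dataset_id or 0
        dataset: Dataset | None = None
        for algo in sorted(config.settings):
            grid = config.settings[algo]
            for k, setting in enumerate(grid):
                seed = _run_seed(config.master_seed, ds_id, algo, k)
                run = RunSpec(ds_id, algo, k, seed)
                if run_dir is not None:
                    path = run_dir / f"{run.key}.json"
                    if path.exists():
                        records.append(ResultRecord.from_json(path.read_text()))
                        continue
                if dataset is None:
                    dataset = generate_dataset(ds_config)
                t0 = time.perf_counter()
                try:
                    model = fit_algorithm(algo, dataset, setting, seed)
                    model_grades, rule_grades = _grade_run(model, dataset)
                    record = ResultRecord(
                        run,
                        to_text(model),
                        len(model.rules) + 1,
                        len(model.attributes),
                        model_grades,
                        rule_grades,
                        elapsed=time.perf_counter() - t0,
                    )
                except Exception as exc:  # keep the matrix going
                    logger.exception("run %s failed", run.key)
                    record = ResultRecord(
                        run, "Else Control", 1, 0, {}, {},
                        elapsed=time.perf_counter() - t0, error=str(exc),
                    )
                records.append(record)
                if run_dir is not None:
                    (run_dir / f"{run.key}.json").write_text(record.to_json())
    return records


# ---------------------------------------------------------------------------
# summaries


def _dataset_model_map(dataset_configs: Sequence[SimulationConfig]) -> dict[int, str]:
    return {c.dataset_id or 0: c.model_id for c in dataset_configs}


_STATISTICS = ("min", "5th percentile", "median", "95th percentile", "max")


def _five_number(values: Sequence[float]) -> list[float]:
    arr = np.asarray(values, dtype=float)
    return [
        float(arr.min()),
        float(np.percentile(arr, 5)),
        float(np.percentile(arr, 50)),
        float(np.percentile(arr, 95)),
        float(arr.max()),
    ]


def summarize_statistics(
    records: Sequence[ResultRecord], dataset_models: Mapping[int, str]
) -> pd.DataFrame:
    """Per algorithm x generating model: five-number summaries of the
    attribute and rule counts per model (percentiles by linear
    interpolation)."""
    rows = []
    frame = pd.DataFrame(
        {
            "algorithm": [r.run.algorithm for r in records],
            "model": [dataset_models[r.run.dataset_id] for r in records],
            "n_attributes": [r.n_unique_attributes for r in records],
            "n_rules": [r.n_rules for r in records],
        }
    )
    for (algo, model), grp in frame.groupby(["algorithm", "model"], sort=True):
        for metric in ("n_attributes", "n_rules"):
            values = _five_number(grp[metric].to_list())
            for stat, v in zip(_STATISTICS, values):
                rows.append(
                    {
                        "algorithm": algo,
                        "model": model,
                        "metric": metric,
                        "statistic": stat,
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)


def _dataset_grades(
    records: Sequence[ResultRecord], dataset_models: Mapping[int, str]
) -> pd.DataFrame:
    """Tidy per-(dataset, algorithm) grade tallies at all three levels."""
    by_group: dict[tuple[int, str], list[ResultRecord]] = {}
    for r in records:
        by_group.setdefault((r.run.dataset_id, r.run.algorithm), []).append(r)

    rows = []
    for (ds, algo), recs in sorted(by_group.items()):
        model_letter = dataset_models[ds]
        tids = _truth_ids(model_letter)
        model_counts = {g.name: 0 for g in Grade}
        rule_counts = {g.name: 0 for g in Grade}
        for r in recs:
            best_model = max(
                (Grade[r.model_grades[t]] for t in tids if t in r.model_grades),
                default=Grade.NONE,
            )
            model_counts[best_model.name] += 1
            per_rule: dict[int, Grade] = {}
            for t in tids:
                for i, g in enumerate(r.rule_grades.get(t, [])):
                    g = Grade[g]
                    if i not in per_rule or g > per_rule[i]:
                        per_rule[i] = g
            for g in per_rule.values():
                rule_counts[g.name] += 1
        models = [r.model for r in recs if r.error is None]
        ranking = rank_attributes(models)
        attr_grade = max(grade_attributes(ranking, true_model(t)) for t in tids)
        for g in Grade:
            rows.append(
                {
                    "dataset_id": ds,
                    "model": model_letter,
                    "algorithm": algo,
                    "grade": g.name,
                    "models": model_counts[g.name],
                    "rules": rule_counts[g.name],
                    "attributes": int(attr_grade is g),
                }
            )
    return pd.DataFrame(rows)


def summarize_quantitative(
    records: Sequence[ResultRecord], dataset_models: Mapping[int, str]
) -> pd.DataFrame:
    """Per-dataset grade counts: settings achieving each model-level grade,
    emitted case rules achieving each rule-level grade, and a 0/1
    attribute-level indicator."""
    return _dataset_grades(records, dataset_models)


def summarize_qualitative(
    records: Sequence[ResultRecord], dataset_models: Mapping[int, str]
) -> pd.DataFrame:
    """Per (level, grade, algorithm, generating model): the percentage
    (and count) of datasets where the grade occurred at least once."""
    tidy = _dataset_grades(records, dataset_models)
    rows = []
    for (algo, model), grp in tidy.groupby(["algorithm", "model"], sort=True):
        n_datasets = grp["dataset_id"].nunique()
        for level in ("models", "rules", "attributes"):
            for g in ("A", "B", "C", "D"):
                sub = grp[grp["grade"] == g]
                count = int((sub.groupby("dataset_id")[level].sum() > 0).sum())
                rows.append(
                    {
                        "level": level,
                        "grade": g,
                        "algorithm": algo,
                        "model": model,
                        "datasets": count,
                        "n_datasets": n_datasets,
                        "pct": round(100.0 * count / n_datasets) if n_datasets else 0,
                    }
                )
    return pd.DataFrame(rows)
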