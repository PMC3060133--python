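"""Simulation of SNP case-control datasets with rule-defined interactions.

Genotypes (AA/AB/BB) are drawn independently per SNP under Hardy-Weinberg
equilibrium with minor allele frequencies drawn Uniform(0, 0.5) and a
randomly chosen minor allele. Case/control status is assigned by one of
three generating models:

* **Model A** — a pure gene-gene interaction: four two-SNP genotype
  combinations of rs5 and rs10 label a subject Case.
* **Model B** — a gene-gene plus a gene-environment rule: rs5/rs10
  interaction or rs15 combined with high drug exposure (AUC > 105).
* **Model C** — a null model: Case status is random, unrelated to any
  attribute.

The environmental covariate AUC (area under the concentration-time curve
of a hypothetical compound) is an equal-weight two-component uniform
mixture with medians 95 and 110, so the decision threshold 105 falls in
the empty gap between components.

A 2:1 control:case design ratio is enforced by quota rejection sampling:
candidate subjects are drawn and evaluated under the generating model
until the case and control quotas fill. Label noise (false-positive /
false-negative mislabeling) is applied afterwards, so the observed class
ratio is approximate while the pre-noise ratio is exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .rules import Condition, Op, Rule, RuleListModel, predict

__all__ = [
    "CASE",
    "CONTROL",
    "GENOTYPES",
    "SnpSpec",
    "SimulationConfig",
    "TrueModel",
    "Dataset",
    "SimulationError",
    "genotype_probabilities",
    "true_model",
    "evaluate_true_model",
    "apply_noise",
    "generate_dataset",
    "table2_configs",
]

logger = logging.getLogger(__name__)

CASE = "Case"
CONTROL = "Control"
GENOTYPES = ("AA", "AB", "BB")

#: redraw the MAFs of a generating rule's SNPs when the rule's satisfaction
#: probability falls below this, to bound quota-rejection time
MIN_RULE_PROBABILITY = 0.005

#: give up on the quota after this many candidate draws per requested subject
MAX_CANDIDATE_FACTOR = 5000


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SnpSpec:
    """A simulated SNP: name, minor allele frequency, and which allele
    (A or B) is the minor one."""

    name: str
    maf: float
    minor_allele: str = "B"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF must lie in [0, 0.5], got {self.maf}")
        if self.minor_allele not in ("A", "B"):
            raise ValueError("minor_allele must be 'A' or 'B'")

    def probabilities(self) -> tuple[float, float, float]:
        """HWE genotype probabilities in (AA, AB, BB) order."""
        return genotype_probabilities(self.maf, self.minor_allele)


def genotype_probabilities(maf: float, minor_allele: str = "B") -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2).

    Returned in fixed (AA, AB, BB) order; when the minor allele is A the
    homozygote probabilities swap accordingly.
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    q = float(maf)
    hom_major = (1.0 - q) ** 2
    het = 2.0 * q * (1.0 - q)
    hom_minor = q * q
    if minor_allele == "B":
        return (hom_major, het, hom_minor)
    return (hom_minor, het, hom_major)


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid.

    ``n_subjects`` is the total cohort size (for model B this is split
    half and half between the low and high AUC exposure components).
    """

    model_id: str
    n_snps: int
    n_subjects: int
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    control_case_ratio: float = 2.0
    auc_low_range: tuple[float, float] = (90.0, 100.0)
    auc_high_range: tuple[float, float] = (105.0, 115.0)
    case_probability: float = 1.0 / 3.0
    seed: int = 0
    dataset_id: int | None = None

    def __post_init__(self) -> None:
        if self.model_id not in ("A", "B", "C"):
            raise ValueError(f"unknown model {self.model_id!r}")
        for name in ("fp_rate", "fn_rate", "case_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_snps < 1 or self.n_subjects < 1:
            raise ValueError("n_snps and n_subjects must be positive")
        if self.control_case_ratio <= 0:
            raise ValueError("control_case_ratio must be positive")
        if self.auc_low_range[1] > 105.0 or self.auc_high_range[0] < 105.0:
            raise ValueError("AUC components must lie entirely below/above the 105 threshold")

    @property
    def n_cases(self) -> int:
        """Pre-noise case quota: round(n_subjects / (1 + ratio))."""
        return round(self.n_subjects / (1.0 + self.control_case_ratio))

    @property
    def n_controls(self) -> int:
        return self.n_subjects - self.n_cases

    @property
    def has_auc(self) -> bool:
        return self.model_id == "B"


@dataclass(frozen=True)
class TrueModel:
    """A generating case-control model plus its grading metadata."""

    model_id: str
    rule_list: RuleListModel
    true_attributes: tuple[str, ...]
    top_k: int
    case_probability: float | None = None


_MODEL_A_PAIRS = (("AA", "AB"), ("AB", "AA"), ("AB", "BB"), ("BB", "AB"))


def true_model(model_id: str, case_probability: float = 1.0 / 3.0) -> TrueModel:
    """The generating rule list for model A, B, or C."""
    if model_id == "A":
        rules = tuple(
            Rule((Condition("rs5", Op.EQ, g5), Condition("rs10", Op.EQ, g10)), CASE)
            for g5, g10 in _MODEL_A_PAIRS
        )
        return TrueModel("A", RuleListModel(rules, CONTROL), ("rs5", "rs10"), top_k=2)
    if model_id == "B":
        rules = (
            Rule((Condition("rs5", Op.EQ, "BB"), Condition("rs10", Op.EQ, "AA")), CASE),
            Rule((Condition("rs15", Op.EQ, "AA"), Condition("AUC", Op.GT, 105.0)), CASE),
        )
        return TrueModel(
            "B", RuleListModel(rules, CONTROL), ("rs5", "rs10", "rs15", "AUC"), top_k=4
        )
    if model_id == "C":
        return TrueModel(
            "C", RuleListModel((), CONTROL), (), top_k=0, case_probability=case_probability
        )
    raise ValueError(f"unknown model {model_id!r}")


def evaluate_true_model(
    tm: TrueModel,
    subject: Mapping[str, object],
    rng: np.random.Generator | None = None,
) -> str:
    """Label a subject under the generating model.

    Model C draws Case with probability ``case_probability`` and therefore
    requires an ``rng``.
    """
    if tm.model_id == "C":
        if rng is None:
            raise ValueError("model C labelling needs a random generator")
        return CASE if rng.random() < float(tm.case_probability or 0.0) else CONTROL
    return predict(tm.rule_list, subject)


def apply_noise(
    labels: Sequence[str] | np.ndarray,
    fp_rate: float,
    fn_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independently mislabel controls (prob ``fp_rate``) and cases
    (prob ``fn_rate``)."""
    if not 0.0 <= fp_rate <= 1.0 or not 0.0 <= fn_rate <= 1.0:
        raise ValueError("noise rates must lie in [0, 1]")
    y = np.asarray(labels, dtype=object).copy()
    u = rng.random(len(y))
    is_case = y == CASE
    y[~is_case & (u < fp_rate)] = CASE
    y[is_case & (u < fn_rate)] = CONTROL
    return y


@dataclass
class Dataset:
    """A simulated cohort.

    ``frame`` is the classifier-visible attribute table (genotype columns,
    plus AUC for model B); the pre-noise labels live only in
    ``true_labels`` and are never exposed to a learner.
    """

    config: SimulationConfig
    snps: tuple[SnpSpec, ...]
    frame: pd.DataFrame
    observed_labels: np.ndarray
    true_labels: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def table(self) -> pd.DataFrame:
        """Classifier-visible table including the observed class column."""
        out = self.frame.copy()
        out["class"] = self.observed_labels
        return out

    def subject(self, i: int) -> dict[str, object]:
        return {k: v for k, v in zip(self.frame.columns, self.frame.iloc[i])}

    def equals(self, other: "Dataset") -> bool:
        if list(self.frame.columns) != list(other.frame.columns):
            return False
        if not np.array_equal(self.observed_labels, other.observed_labels):
            return False
        for col in self.frame.columns:
            a = self.frame[col].to_numpy()
            b = other.frame[col].to_numpy()
            if a.dtype.kind == "f" or b.dtype.kind == "f":
                if not np.allclose(a.astype(float), b.astype(float)):
                    return False
            elif not np.array_equal(a.astype(object), b.astype(object)):
                return False
        return True


# ---------------------------------------------------------------------------
# generation


def _rule_probability(rule: Rule, specs: Mapping[str, SnpSpec]) -> float:
    """Probability a random subject satisfies a generating case rule."""
    prob = 1.0
    for c in rule.conditions:
        if c.op is Op.EQ:
            p = specs[c.attribute].probabilities()[GENOTYPES.index(str(c.value))]
            prob *= p
        else:
            # the AUC > 105 predicate selects exactly the high exposure
            # component, half the cohort by design
            prob *= 0.5
    return prob


def _draw_specs(names: Sequence[str], rng: np.random.Generator) -> list[SnpSpec]:
    mafs = rng.uniform(0.0, 0.5, size=len(names))
    minors = rng.choice(["A", "B"], size=len(names))
    return [SnpSpec(n, float(m), str(a)) for n, m, a in zip(names, mafs, minors)]


def _sample_genotype_codes(
    specs: Sequence[SnpSpec], n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, len(specs)) int8 codes 0=AA 1=AB 2=BB, i.i.d. HWE per SNP."""
    probs = np.array([s.probabilities() for s in specs])  # (p, 3)
    cum = probs.cumsum(axis=1)
    u = rng.random((n, len(specs)))
    codes = (u[:, :, None] > cum[None, :, :2]).sum(axis=2)
    return codes.astype(np.int8)


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Simulate one dataset under ``config``.

    SNPs are named rs1..rsN. Sub-streams for MAF draws, genotypes, AUC,
    model-C labels and label noise are derived deterministically from
    ``config.seed``, so regeneration with the same config is reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    maf_rng, geno_rng, auc_rng, label_rng, noise_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    tm = true_model(config.model_id, config.case_probability)
    rule_rs = [int(a[2:]) for a in tm.true_attributes if a.startswith("rs")]
    if rule_rs and config.n_snps < max(rule_rs):
        raise ValueError(
            f"model {config.model_id} uses rs{max(rule_rs)}; n_snps={config.n_snps} is too small"
        )
    names = [f"rs{i}" for i in range(1, config.n_snps + 1)]
    specs = _draw_specs(names, maf_rng)
    spec_by_name = {s.name: s for s in specs}

    rule_snps = [a for a in tm.true_attributes if a != "AUC"]
    for r in tm.rule_list.case_rules(CASE):
        attempts = 0
        while _rule_probability(r, spec_by_name) < MIN_RULE_PROBABILITY:
            attempts += 1
            if attempts > 1000:
                raise SimulationError(f"cannot reach viable MAFs for rule {r}")
            snps_in_rule = [a for a in r.attributes if a != "AUC"]
            logger.info("redrawing MAFs for rule %s (probability below %.3f)", r, MIN_RULE_PROBABILITY)
            for s in _draw_specs(snps_in_rule, maf_rng):
                spec_by_name[s.name] = s
    specs = [spec_by_name[n] for n in names]

    subjects = _quota_sample(config, tm, spec_by_name, rule_snps, geno_rng, auc_rng, label_rng)
    rule_codes, auc_values, true_labels = subjects

    # fill the non-informative SNP columns for the accepted subjects only;
    # they are independent of acceptance so the joint law is unchanged
    codes = _sample_genotype_codes(specs, config.n_subjects, geno_rng)
    for j, name in enumerate(rule_snps):
        codes[:, names.index(name)] = rule_codes[:, j]

    geno = np.array(GENOTYPES, dtype=object)[codes]
    data: dict[str, object] = {
        name: pd.Categorical(geno[:, i], categories=list(GENOTYPES))
        for i, name in enumerate(names)
    }
    frame = pd.DataFrame(data)
    if config.has_auc:
        frame["AUC"] = auc_values

    observed = apply_noise(true_labels, config.fp_rate, config.fn_rate, noise_rng)
    return Dataset(config, tuple(specs), frame, observed, true_labels)


def _quota_sample(
    config: SimulationConfig,
    tm: TrueModel,
    spec_by_name: Mapping[str, SnpSpec],
    rule_snps: Sequence[str],
    geno_rng: np.random.Generator,
    auc_rng: np.random.Generator,
    label_rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Accept candidate subjects until the case/control (and, for model B,
    AUC-component) quotas fill."""
    need = {CASE: config.n_cases, CONTROL: config.n_controls}
    n_high = config.n_subjects // 2
    comp_need = [config.n_subjects - n_high, n_high]  # [low, high]
    use_auc = config.has_auc

    rule_specs = [spec_by_name[n] for n in rule_snps]
    acc_codes: list[np.ndarray] = []
    acc_auc: list[float] = []
    acc_labels: list[str] = []

    block = max(256, config.n_subjects)
    drawn = 0
    budget = MAX_CANDIDATE_FACTOR * config.n_subjects
    while need[CASE] > 0 or need[CONTROL] > 0:
        if drawn > budget:
            mafs = {s.name: round(s.maf, 4) for s in rule_specs}
            raise SimulationError(
                f"case/control quota unreachable after {drawn} candidates; "
                f"generating-rule SNP MAFs: {mafs}"
            )
        codes = _sample_genotype_codes(rule_specs, block, geno_rng) if rule_specs else np.zeros((block, 0), np.int8)
        drawn += block

        if use_auc:
            total_comp = comp_need[0] + comp_need[1]
            p_high = comp_need[1] / total_comp if total_comp else 0.5
            comp = (auc_rng.random(block) < p_high).astype(np.int8)
            lo, hi = config.auc_low_range, config.auc_high_range
            auc = np.where(
                comp == 1,
                auc_rng.uniform(hi[0], hi[1], block),
                auc_rng.uniform(lo[0], lo[1], block),
            )
            # keep the 105 threshold strictly inside the gap
            auc[auc == 105.0] = np.nextafter(105.0, 116.0)
        else:
            comp = np.zeros(block, np.int8)
            auc = None

        labels = _evaluate_block(tm, rule_snps, codes, auc, label_rng, block)

        for i in range(block):
            lab = labels[i]
            if need[lab] <= 0:
                continue
            if use_auc and comp_need[comp[i]] <= 0:
                continue
            need[lab] -= 1
            if use_auc:
                comp_need[comp[i]] -= 1
                acc_auc.append(float(auc[i]))
            acc_codes.append(codes[i])
            acc_labels.append(lab)
            if need[CASE] == 0 and need[CONTROL] == 0:
                break

    rule_codes = np.array(acc_codes, dtype=np.int8) if rule_snps else np.zeros(
        (config.n_subjects, 0), np.int8
    )
    auc_out = np.array(acc_auc) if use_auc else None
    return rule_codes, auc_out, np.array(acc_labels, dtype=object)


def _evaluate_block(
    tm: TrueModel,
    rule_snps: Sequence[str],
    codes: np.ndarray,
    auc: np.ndarray | None,
    label_rng: np.random.Generator,
    block: int,
) -> np.ndarray:
    """Vectorized generating-model labels for a candidate block."""
    if tm.model_id == "C":
        is_case = label_rng.random(block) < float(tm.case_probability or 0.0)
    else:
        col = {name: codes[:, j] for j, name in enumerate(rule_snps)}
        is_case = np.zeros(block, dtype=bool)
        for r in tm.rule_list.case_rules(CASE):
            hit = np.ones(block, dtype=bool)
            for c in r.conditions:
                if c.op is Op.EQ:
                    hit &= col[c.attribute] == GENOTYPES.index(str(c.value))
                elif c.op is Op.GT:
                    hit &= auc > float(c.value)
                else:
                    hit &= auc <= float(c.value)
            is_case |= hit
    return np.where(is_case, CASE, CONTROL).astype(object)


# ---------------------------------------------------------------------------
# the 42-dataset study grid


def table2_configs(master_seed: int = 20110301) -> list[SimulationConfig]:
    """The full simulation grid: 18 model-A, 18 model-B and 6 model-C
    datasets crossing SNP panel size, cohort size and noise level.

    Per-dataset seeds are derived deterministically from ``master_seed``.
    """
    configs: list[SimulationConfig] = []
    dataset_id = 0

    def ds_seed(i: int) -> int:
        return int(np.random.SeedSequence([master_seed, i]).generate_state(1)[0] % (2**31))

    for model in ("A", "B"):
        for noise in (0.05, 0.10, 0.20):
            for n_subjects in (300, 600):
                for n_snps in (500, 1500, 3000):
                    dataset_id += 1
                    configs.append(
                        SimulationConfig(
                            model_id=model,
                            n_snps=n_snps,
                            n_subjects=n_subjects,
                            fp_rate=noise,
                            fn_rate=noise,
                            seed=ds_seed(dataset_id),
                            dataset_id=dataset_id,
                        )
                    )
    for n_subjects in (300, 600):
        for n_snps in (500, 1500, 3000):
            dataset_id += 1
            configs.append(
                SimulationConfig(
                    model_id="C",
                    n_snps=n_snps,
                    n_subjects=n_subjects,
                    fp_rate=0.0,
                    fn_rate=0.0,
                    seed=ds_seed(dataset_id),
                    dataset_id=dataset_id,
                )
            )
    return configs
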