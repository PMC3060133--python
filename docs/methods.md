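# Methods

This note records the models implemented in `rulebench`, the choices made
where the design was genuinely open, and what the synthetic benchmark can
and cannot show about real genetic association data.

## Simulated cohorts

Each dataset is a subjects × attributes table of nominal genotypes
(`AA/AB/BB`), an optional continuous exposure (`AUC`), and a binary
class label (`Case`/`Control`).

**Genotypes.** SNPs are independent (no linkage disequilibrium, no
population structure, no missingness). Each SNP draws a minor allele
frequency `q ~ Uniform(0, 0.5)` and a minor allele (A or B with equal
probability); genotypes are i.i.d. from the Hardy-Weinberg frequencies
`(1−q)², 2q(1−q), q²`. Only rs5, rs10 (and rs15 plus AUC in the
gene-environment model) carry signal; all other SNPs are pure noise.

**Exposure.** `AUC` (area under a concentration-time curve of a
hypothetical compound) is an equal-weight mixture of `Uniform(90, 100)`
and `Uniform(105, 115)` — medians 95 and 110 — assigned half-and-half
per cohort with an exact per-component quota. The decision threshold 105
lies strictly inside the empty gap between components, so the predicate
`AUC > 105` is extensionally the high-exposure indicator. The component
widths are a modeling choice (only the medians are fixed by the study
design); any shapes that keep the components separated by 105 yield the
same labels.

**Labels and the design ratio.** The generating models are first-match
rule lists with default `Control`:

* model A (gene-gene): Case iff (rs5, rs10) ∈ {(AA,AB), (AB,AA), (AB,BB), (BB,AB)};
* model B (gene-gene + gene-environment): Case iff rs5=BB ∧ rs10=AA, or
  rs15=AA ∧ AUC>105;
* model C (null): Case with probability 1/3, independent of all attributes.

The 2:1 control:case ratio is enforced exactly by quota rejection
sampling: candidate subjects are drawn, labelled by the generating model,
and accepted until `round(n/(1+ratio))` cases and the complementary
controls are collected. Only the rule-relevant columns are drawn during
candidate screening; noise SNP columns are filled in afterwards for
accepted subjects (they are independent of acceptance, so the joint
distribution is unchanged — this is what makes 3000-SNP panels cheap).
If a drawn MAF combination makes any single generating rule's
satisfaction probability fall below 0.005, that rule's SNPs redraw their
MAFs; this bounds rejection time without touching noise SNPs. Label
noise (Control→Case with probability FP, Case→Control with probability
FN, independent per subject) is applied after the quota, so the observed
class ratio is approximate while the pre-noise ratio is exact.

**Randomness.** One seed per dataset; sub-streams for MAF draws,
genotypes, exposure, null-model labels and noise are spawned
deterministically from it, so regeneration is exactly reproducible.

**What this does not emulate.** Real panels have LD, stratification,
genotyping error, missing calls, and effect sizes far below deterministic
rules. Passing benchmarks here demonstrates that a learner can find
clean, fully penetrant interactions against multiple-testing noise — a
necessary, not sufficient, condition for usefulness on real data.

## Rule-list language

All learners emit the same model type: an ordered list of conjunctive
rules over `=` (nominal), `>` / `<=` (numeric) — plus `!=` for the
rest-branch of a binary nominal split — with first-match prediction and a
default label. The canonical text form (`If rs5 = AA and rs10 = AB then
Case` / `Else Control`) round-trips through the parser; an empty
antecedent is written `If true then …`.

## RIPPER

Rules are learned for the minority class (Case under the 2:1 design).
Per rule, the not-yet-covered instances are split stratified into
(F−1)/F grow and 1/F prune sets. Growth adds the condition maximizing
FOIL gain `p₁·(log₂(p₁/(p₁+n₁)) − log₂(p₀/(p₀+n₀)))` over all
(attribute, level) equalities and all numeric thresholds at midpoints of
adjacent distinct observed values, until the rule covers no negatives or
no candidate has positive gain. Pruning drops the final sequence of
conditions maximizing `(p−n)/(p+n)` on the prune set (ties to the shorter
rule; empty coverage scores −1). Rule-set growth stops when the total
description length exceeds the best seen by 64 bits, when a rule's
prune-set error exceeds 50%, or when no positives remain.

Description length uses binomial subset coding: a k-condition rule costs
`½·(log₂ k + log₂-binomial(n_possible, k))` bits (the ½ is the standard
redundancy discount), and the data cost identifies the false positives
among covered and false negatives among uncovered instances, plus
`log₂(cover+1) + log₂(uncover+1)` bits for the counts. Exact agreement
with any particular Java implementation's DL constants is not promised;
the accounting follows the published scheme and is frozen by tests
against a symbolic transcription.

Each of the O optimization passes lets every rule compete against a
freshly grown replacement and a greedily extended revision (winner by
total DL), then re-covers any residual positives with additional rules.
Re-covering matters: a single unlucky grow/prune split otherwise aborts
rule finding for good, which we observed as degenerate default-only
models on cleanly separable data. Selection finally removes, from the
last rule backwards, any rule whose deletion does not increase DL,
deletes rules covering fewer than `min_weight` training instances, and
falls back to the default-only model if that has lower training error.

A consequence of `min_weight` worth naming: a generating rule realized in
fewer than about `2·min_weight` training subjects is below the learner's
representational floor (it cannot survive selection, and rarely survives
a grow/prune split). Under `MAF ~ Uniform(0, 0.5)` the rarest of the four
gene-gene rules regularly lands there; recovery claims in the tests
therefore exempt such rules.

## RIDOR

The root predicts the whole-data majority label. Exceptions are searched
IREP-style with the flipped target (same FOIL growth and (p−n)/(p+n)
pruning as RIPPER) on the instances a node captures, across S independent
stratified splits keeping the least-error candidate (S=1 in the study
grid); an exception is accepted if it captures at least `min_weight`
instances and strictly reduces the error count, then recursively acquires
its own exceptions. Flattening emits each node as a rule whose antecedent
is its root-to-node path, descendants before ancestors and earlier
siblings first, so the flat list reproduces tree semantics exactly (a
property test checks this on exhaustive genotype grids). Control-predicting
exceptions inside a Case branch appear as higher-priority guard rules;
only Case rules are graded.

## PART

Each covering iteration builds a partial C4.5 tree on the remaining
instances. Splits maximize gain ratio subject to the mean-gain
eligibility rule, with the threshold of a numeric attribute (and the
value of a binary value-vs-rest split) chosen *within* the attribute by
information gain — gain ratio only arbitrates across attributes, which is
what keeps the exposure cut inside the empty mixture gap. A nominal
attribute splits multiway, or value-vs-rest under `binary_splits`.
Eligibility requires at least two branches with `min_obj` instances.

Subsets are expanded lowest-entropy-first. When a fully expanded subtree
estimates no better than a leaf — C4.5's pessimistic error (Wilson-style
upper bound with continuity correction at confidence C) or held-out
errors under reduced-error pruning — it collapses back to a leaf, and
that *stable leaf* ends construction for the whole tree; unvisited
subsets remain frontier leaves. The published pseudocode for partial
trees stops, instead, when a subtree *fails* to collapse; on clean data
that variant freezes construction at the first internal subtree and the
extracted rules degrade to one-condition frontier paths, which is
irreconcilable with the recovery behavior this benchmark measures, so the
stop-at-collapse reading is used.

The emitted rule is the maximum-coverage leaf **among leaves the
expansion actually visited** (ties: fewer errors, then canonical order);
frontier leaves are eligible only when nothing else exists. A frontier
leaf's majority label was never vetted by pruning, and rules taken from
frontier leaves (e.g. `rs10 = AA → Case` covering a third of a cohort)
both misclassify heavily and starve later iterations.

Because covered instances are removed between iterations, a later rule's
antecedent is implicitly conditioned on the rules before it; its
*effective* coverage under first-match semantics — not the bare
conjunction — is the meaningful extension. The recovery tests compare
effective coverages for this reason. Subtree raising and C4.5's
MDL numeric-split penalty are not implemented.

## Grading

Rule difference counts attributes unique to either side plus shared
attributes whose conditions disagree: nominal disagreement is a different
level; numeric disagreement is judged extensionally (the generated
conditions on that attribute select a different subject set than the true
ones — a learner can only cut at observed midpoints, so the literal 105
is unattainable and irrelevant). `!=` conditions have no counterpart in a
generating rule and are skipped at the rule level, but counted in
attribute rankings. Model-level grading matches generated to true case
rules by a minimum-cost assignment (solved exactly with the Hungarian
algorithm at any size; unmatched rules contribute their attribute
counts), requires the default labels to agree, and maps the total
difference through 0→A … 3→D. Attribute grading competition-ranks
per-condition occurrence counts across a model collection (ties by rs
index, AUC last): A needs all true attributes within the top k (2 for
the gene-gene model, 4 for the gene-environment model), B all present,
C one missing, D two missing — the rank requirement is not applied to C
and D. Null-model datasets are graded against both real truths; any
non-NONE grade there is a false positive.

## Benchmark driver and problem sizes

Run seeds derive from (master seed, dataset id, algorithm, setting
index), so the matrix is order-independent and resumable. Summaries are
exact recounts of the stored per-run records. Percentiles use linear
interpolation.

The test suite exercises the full 42-dataset grid for simulator
invariants, 10-to-15-SNP × 600-subject cohorts for learner recovery (20
seeds each), and a scaled-down sweep — the fourteen 500-SNP datasets ×
the 18 RIPPER settings — for the end-to-end qualitative ordering
(rule-level recovery at least as frequent as model-level; no grade-A
findings on null-model datasets). The complete 2394-run matrix including
the 3000-SNP panels is left to the CLI (`rulebench bench`).

## Known limitations

* WEKA bit-for-bit fidelity is out of scope; stopping constants,
  stratification details and tie-breaks follow the published algorithm
  descriptions and are frozen by this package's own tests.
* RIDOR's internal criterion for choosing among candidate exceptions is
  assumed to be prune-split error.
* PART emits decision-list rules; graded in isolation, late rules lose
  their context conditions, which depresses rule-level grades relative to
  a learner that emits self-contained rules (RIPPER).
* The simulator's deterministic rules and exact quotas are idealizations;
  see the simulator section for the gap to real data.
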