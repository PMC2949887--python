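"""Synthetic two-class expression data and the two study workflows.

The default generative design draws 2002 genes with independent normal
distributions: 2000 non-informative genes with mean 0 and SD 5 in both
classes, and 2 informative genes with mean 0 / SD 5 in class 0 and mean 2 /
SD 1 in class 1 (the informative genes occupy the last row indices).  The
informative genes thus differ between classes in both location and spread,
which is the regime where the Swirls score can beat Ripples under a pooled
variance.

Two workflows operate on a dataset:

* **Goal 1** (rule discovery and testing): one stratified 70/30
  training/test split, full rule selection on the training sample, then a
  20-iteration bootstrap ROC band on the test sample and a relative-utility
  curve from the concave envelope of the mean ROC.
* **Goal 2** (gene discovery): 100 independent stratified 70/30 splits,
  rule selection on each training sample, and a table of per-gene selection
  frequencies, with the per-split test ROC curves retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionData, InvalidInputError, RuleComponents, score_specimens
from .evaluation import (
    RelativeUtilityCurve,
    RocBand,
    RocCurve,
    bootstrap_roc_from_scores,
    concave_envelope,
    empirical_roc,
    relative_utility_curve_or_none,
)
from .selection import SelectionConfig, SelectionTrace, select_rule

__all__ = [
    "SimulationDesign",
    "GeneFrequencyTable",
    "Goal1Result",
    "generate_dataset",
    "stratified_split",
    "goal1_run",
    "goal2_run",
]

#: Per-class (mean, sd) of one informative gene: class 0 N(0, 5), class 1 N(2, 1).
DEFAULT_INFORMATIVE = ((0.0, 5.0), (2.0, 1.0))


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of the synthetic two-class design.

    ``informative_genes`` lists, per informative gene, the ((mean, sd) in
    class 0, (mean, sd) in class 1); the defaults are two identically
    distributed informative genes appended after the noise genes.
    """

    n_per_class: int = 100
    n_noise_genes: int = 2000
    noise_mean: float = 0.0
    noise_sd: float = 5.0
    informative_genes: tuple = (DEFAULT_INFORMATIVE, DEFAULT_INFORMATIVE)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise InvalidInputError("n_per_class must be >= 2")
        if self.n_noise_genes < 0:
            raise InvalidInputError("n_noise_genes must be >= 0")
        if self.noise_sd <= 0:
            raise InvalidInputError("noise_sd must be > 0")
        for gene in self.informative_genes:
            for _, sd in gene:
                if sd <= 0:
                    raise InvalidInputError("informative gene sd must be > 0")
        if self.n_noise_genes + len(self.informative_genes) < 1:
            raise InvalidInputError("design has no genes")

    @property
    def n_genes(self) -> int:
        return self.n_noise_genes + len(self.informative_genes)

    @property
    def informative_indices(self) -> tuple[int, ...]:
        """Row indices of the informative genes (the last rows)."""
        return tuple(range(self.n_noise_genes, self.n_genes))


def _gene_ids(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"g{i + 1:0{width}d}" for i in range(n))


def generate_dataset(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> ExpressionData:
    """Draw one dataset from the design; reproducible given the seed.

    Noise genes first, informative genes last, matching the convention that
    the informative genes sit at the highest indices.
    """
    if rng is None:
        rng = np.random.default_rng(design.rng_seed)
    n = design.n_per_class
    blocks0 = [rng.normal(design.noise_mean, design.noise_sd, (design.n_noise_genes, n))]
    blocks1 = [rng.normal(design.noise_mean, design.noise_sd, (design.n_noise_genes, n))]
    for (m0, sd0), (m1, sd1) in design.informative_genes:
        blocks0.append(rng.normal(m0, sd0, (1, n)))
        blocks1.append(rng.normal(m1, sd1, (1, n)))
    return ExpressionData(
        np.vstack(blocks0), np.vstack(blocks1), _gene_ids(design.n_genes)
    )


def stratified_split(
    data: ExpressionData, train_fraction: float, rng: np.random.Generator
) -> tuple[ExpressionData, ExpressionData]:
    """Random stratified split keeping ``train_fraction`` of each class."""
    if not 0 < train_fraction < 1:
        raise InvalidInputError("train_fraction must lie in (0, 1)")
    parts = []
    for n in (data.n0, data.n1):
        n_train = int(round(n * train_fraction))
        if n_train < 2 or n - n_train < 1:
            raise InvalidInputError(
                f"class of size {n} too small for a {train_fraction:.0%} split"
            )
        perm = rng.permutation(n)
        parts.append((perm[:n_train], perm[n_train:]))
    (tr0, te0), (tr1, te1) = parts
    return data.subset_specimens(tr0, tr1), data.subset_specimens(te0, te1)


@dataclass(eq=False)
class Goal1Result:
    """Output of the single-split discovery-and-testing workflow."""

    rule: RuleComponents
    trace: SelectionTrace
    roc_band: RocBand
    ru_curve: RelativeUtilityCurve | None
    prevalence: float
    test_scores0: np.ndarray
    test_scores1: np.ndarray


def goal1_run(
    data: ExpressionData,
    config: SelectionConfig | None = None,
    train_fraction: float = 0.7,
    n_bootstrap: int = 20,
    seed=0,
    prevalence: float | None = None,
) -> Goal1Result:
    """Single stratified split, rule selection, bootstrap ROC band, RU curve.

    ``prevalence`` (the class-0 probability in the target population)
    defaults to the test-sample class-0 proportion.  When the concave
    envelope of the mean ROC is too sparse, a warning is issued and the RU
    curve is omitted (None).
    """
    config = config or SelectionConfig()
    ss = np.random.SeedSequence(seed)
    split_ss, select_ss, boot_ss = ss.spawn(3)
    train, test = stratified_split(data, train_fraction, np.random.default_rng(split_ss))
    rule, trace = select_rule(train, config, np.random.default_rng(select_ss))
    s0 = score_specimens(test.class0, rule)
    s1 = score_specimens(test.class1, rule)
    band = bootstrap_roc_from_scores(s0, s1, n_bootstrap, boot_ss)
    if prevalence is None:
        prevalence = test.n0 / (test.n0 + test.n1)
    hull = concave_envelope(band.mean_curve())
    ru = relative_utility_curve_or_none(hull, prevalence)
    return Goal1Result(rule, trace, band, ru, prevalence, s0, s1)


@dataclass(eq=False)
class GeneFrequencyTable:
    """Per-gene selection frequencies over repeated training/test splits.

    ``table`` has one row per gene, sorted by descending selection
    fraction (ties by gene index): columns ``gene_index``, ``gene_id``,
    ``informative``, ``fraction``.  The per-split selected gene sets and
    test-sample ROC curves are retained for downstream summaries.
    """

    table: pd.DataFrame
    n_splits: int
    gene_sets: list[tuple[int, ...]] = field(default_factory=list)
    roc_curves: list[RocCurve] = field(default_factory=list)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def goal2_run(
    data: ExpressionData,
    config: SelectionConfig | None = None,
    n_splits: int = 100,
    train_fraction: float = 0.7,
    seed=0,
    informative: tuple[int, ...] | None = None,
) -> GeneFrequencyTable:
    """Repeated-split gene discovery: tabulate selection frequencies.

    Runs ``n_splits`` independent stratified splits from per-split RNG
    substreams of ``seed``; each split's training sample goes through the
    full rule selection, and the final rule's gene set is tabulated.  The
    ``informative`` indices only annotate the output table.
    """
    config = config or SelectionConfig()
    if n_splits < 1:
        raise InvalidInputError("n_splits must be >= 1")
    counts = np.zeros(data.n_genes, dtype=int)
    gene_sets: list[tuple[int, ...]] = []
    rocs: list[RocCurve] = []
    children = np.random.SeedSequence(seed).spawn(n_splits)
    for child in children:
        rng = np.random.default_rng(child)
        train, test = stratified_split(data, train_fraction, rng)
        rule, _ = select_rule(train, config, rng)
        gene_sets.append(rule.genes)
        counts[list(rule.genes)] += 1
        rocs.append(
            empirical_roc(
                score_specimens(test.class0, rule), score_specimens(test.class1, rule)
            )
        )
    informative = tuple(informative) if informative is not None else ()
    flags = np.zeros(data.n_genes, dtype=bool)
    if informative:
        flags[list(informative)] = True
    df = pd.DataFrame(
        {
            "gene_index": np.arange(data.n_genes),
            "gene_id": list(data.gene_ids),
            "informative": flags,
            "fraction": counts / n_splits,
        }
    )
    df = df.sort_values(
        ["fraction", "gene_index"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return GeneFrequencyTable(df, n_splits, gene_sets, rocs)
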