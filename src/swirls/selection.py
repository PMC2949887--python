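"""Training-sample selection of the gene set, distance measure, and score.

The selection procedure, run on a training sample:

1. **Prefilter** — for a given score formula ``S`` and distance measure
   ``D``, rank every eligible gene by the binormal AUC of its single-gene
   score and keep the top 50 (ties broken toward the lower gene index).
   Genes whose required variance is not strictly positive are ineligible.
2. **Gene-set search** over the 50 candidates, either

   * *greedy* (forward stepwise): start from the best single gene, then
     repeatedly add the candidate that maximizes the AUC of the multi-gene
     score, accepting an addition only if the AUC increases by at least
     0.02; centroids and AUC both come from the full training sample; or
   * *wrapper*: five random stratified 50/50 splits of the training sample;
     on each split run the greedy search with centroids from the
     training-training half and AUC evaluated on the held-out
     training-test half, with acceptance threshold 0.01 (the honest inner
     test split tolerates the smaller threshold); keep the gene set of the
     split with the highest inner-test AUC.  The returned AUC and the
     final rule's centroids are recomputed on the full training sample.

3. **Distance-measure selection** — per score formula, keep ``D = 1``
   (pooled) unless ``D = 2`` improves the AUC by at least 0.02.
4. **Score-formula selection** — keep the ``S`` with the highest AUC
   (ties toward ``S = 1``, the simpler boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .auc import _binormal_auc_rows, binormal_auc
from .core import (
    CLASS_SPECIFIC,
    POOLED,
    RIPPLES,
    SWIRLS,
    CentroidSet,
    ExpressionData,
    InvalidInputError,
    RuleComponents,
    compute_centroid_set,
    score_specimens,
    scores_from_squared,
)

__all__ = [
    "SelectionConfig",
    "TraceStep",
    "SelectionTrace",
    "EmptyCandidateError",
    "InvalidSplitError",
    "prefilter_genes",
    "greedy_select",
    "wrapper_select",
    "select_rule",
]


class EmptyCandidateError(ValueError):
    """No gene is eligible for selection (all have degenerate variance)."""


class InvalidSplitError(ValueError):
    """A class is too small to be split while keeping >= 2 specimens per half."""


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable parameters of the selection procedure.

    Defaults are the procedure's standard operating values: a 50-gene
    prefilter, AUC-increase thresholds of 0.02 (greedy) and 0.01 (wrapper),
    five stratified 50/50 wrapper splits, and a 0.02 threshold for
    preferring the class-specific distance.
    """

    n_prefilter: int = 50
    greedy_delta: float = 0.02
    wrapper_delta: float = 0.01
    wrapper_splits: int = 5
    wrapper_fraction: float = 0.5
    d_delta: float = 0.02
    algorithm: str = "greedy"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("greedy_delta", "wrapper_delta", "d_delta"):
            v = getattr(self, name)
            if not 0 < v < 0.5:
                raise InvalidInputError(f"{name} must lie in (0, 0.5), got {v}")
        if not 0 < self.wrapper_fraction < 1:
            raise InvalidInputError("wrapper_fraction must lie in (0, 1)")
        if self.n_prefilter < 1:
            raise InvalidInputError("n_prefilter must be >= 1")
        if self.wrapper_splits < 1:
            raise InvalidInputError("wrapper_splits must be >= 1")
        if self.algorithm not in ("greedy", "wrapper"):
            raise InvalidInputError("algorithm must be 'greedy' or 'wrapper'")


@dataclass(frozen=True)
class TraceStep:
    """One candidate evaluation during the gene-set search."""

    score_formula: int
    distance_measure: int
    gene: int
    auc_before: float | None
    auc_after: float
    accepted: bool
    split: int | None = None  # wrapper inner-split index, None for greedy


@dataclass
class SelectionTrace:
    """Log of the search: per-step candidate AUCs and per-(S, D) final AUCs."""

    steps: list[TraceStep] = field(default_factory=list)
    combo_aucs: dict[tuple[int, int], float] = field(default_factory=dict)
    combo_genes: dict[tuple[int, int], tuple[int, ...]] = field(default_factory=dict)
    chosen: tuple[int, int] | None = None  # (S, D) of the selected rule

    def extend(self, other: "SelectionTrace") -> None:
        self.steps.extend(other.steps)
        self.combo_aucs.update(other.combo_aucs)
        self.combo_genes.update(other.combo_genes)


# ---------------------------------------------------------------------------
# vectorized score machinery


def _eligible_mask(cset: CentroidSet, d_measure: int) -> np.ndarray:
    var0, var1 = cset.variances(d_measure)
    return (var0 > 0) & (var1 > 0)


def _single_gene_scores(
    X: np.ndarray, cset: CentroidSet, s_formula: int, d_measure: int
) -> np.ndarray:
    """Per-gene single-gene scores for every specimen column; rows with
    degenerate variance contain garbage and must be masked by the caller."""
    var0, var1 = cset.variances(d_measure)
    with np.errstate(divide="ignore", invalid="ignore"):
        sq0 = (X - cset.c0[:, None]) ** 2 / var0[:, None]
        sq1 = (X - cset.c1[:, None]) ** 2 / var1[:, None]
        return scores_from_squared(sq0, sq1, s_formula)


def prefilter_genes(
    train: ExpressionData,
    s_formula: int,
    d_measure: int,
    config: SelectionConfig | None = None,
) -> list[int]:
    """Top genes by single-gene binormal AUC of the (S, D) score.

    Returns at most ``config.n_prefilter`` gene indices, sorted by AUC
    descending with ties broken by ascending index.  Genes with
    non-positive required variance are excluded before ranking.
    """
    config = config or SelectionConfig()
    cset = compute_centroid_set(train)
    ok = _eligible_mask(cset, d_measure)
    if not ok.any():
        raise EmptyCandidateError("no gene has strictly positive required variance")
    s0 = _single_gene_scores(train.class0, cset, s_formula, d_measure)
    s1 = _single_gene_scores(train.class1, cset, s_formula, d_measure)
    idx = np.flatnonzero(ok)
    aucs = _binormal_auc_rows(s0[idx], s1[idx])
    order = np.lexsort((idx, -aucs))
    return [int(idx[i]) for i in order[: config.n_prefilter]]


def _candidate_moments(
    X0: np.ndarray, X1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Means, class variances, and pooled variance for candidate gene rows."""
    n0, n1 = X0.shape[1], X1.shape[1]
    c0 = X0.mean(axis=1)
    c1 = X1.mean(axis=1)
    v0 = X0.var(axis=1, ddof=1)
    v1 = X1.var(axis=1, ddof=1)
    vp = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    return c0, c1, v0, v1, vp


def _greedy_core(
    gene_idx: np.ndarray,
    c0: np.ndarray,
    c1: np.ndarray,
    var0: np.ndarray,
    var1: np.ndarray,
    E0: np.ndarray,
    E1: np.ndarray,
    s_formula: int,
    d_measure: int,
    delta: float,
    split: int | None = None,
) -> tuple[list[int], float, list[TraceStep]]:
    """Forward stepwise search over candidate genes.

    ``gene_idx`` holds the candidates' original gene indices; ``c*``/``var*``
    their fitted moments; ``E0``/``E1`` the evaluation matrices (candidate
    rows x specimens) on which the score AUC is measured.  The first gene is
    accepted unconditionally; later additions need an AUC gain >= ``delta``.
    """
    valid = (var0 > 0) & (var1 > 0)
    if not valid.any():
        raise EmptyCandidateError("no candidate gene has positive variance in the fit sample")
    with np.errstate(divide="ignore", invalid="ignore"):
        T00 = (E0 - c0[:, None]) ** 2 / var0[:, None]  # eval class 0 vs centroid 0
        T10 = (E0 - c1[:, None]) ** 2 / var1[:, None]
        T01 = (E1 - c0[:, None]) ** 2 / var0[:, None]
        T11 = (E1 - c1[:, None]) ** 2 / var1[:, None]
    cum00 = np.zeros(E0.shape[1])
    cum10 = np.zeros(E0.shape[1])
    cum01 = np.zeros(E1.shape[1])
    cum11 = np.zeros(E1.shape[1])
    pool = np.flatnonzero(valid)
    selected: list[int] = []
    cur_auc: float | None = None
    steps: list[TraceStep] = []
    while pool.size:
        S0 = scores_from_squared(cum00 + T00[pool], cum10 + T10[pool], s_formula)
        S1 = scores_from_squared(cum01 + T01[pool], cum11 + T11[pool], s_formula)
        aucs = _binormal_auc_rows(S0, S1)
        best_auc = aucs.max()
        ties = pool[aucs == best_auc]
        best = ties[np.argmin(gene_idx[ties])]
        accepted = cur_auc is None or best_auc - cur_auc >= delta
        steps.append(
            TraceStep(
                s_formula, d_measure, int(gene_idx[best]),
                cur_auc, float(best_auc), accepted, split,
            )
        )
        if not accepted:
            break
        selected.append(int(gene_idx[best]))
        cum00 += T00[best]
        cum10 += T10[best]
        cum01 += T01[best]
        cum11 += T11[best]
        cur_auc = float(best_auc)
        pool = pool[pool != best]
    assert cur_auc is not None
    return selected, cur_auc, steps


def _training_auc(
    train: ExpressionData, genes, s_formula: int, d_measure: int
) -> float:
    """Resubstitution binormal AUC of the multi-gene score on the full sample."""
    cset = compute_centroid_set(train)
    rule = RuleComponents(cset, tuple(genes), d_measure, s_formula)
    return binormal_auc(
        score_specimens(train.class0, rule), score_specimens(train.class1, rule)
    )


# ---------------------------------------------------------------------------
# public selection algorithms


def greedy_select(
    train: ExpressionData,
    s_formula: int,
    d_measure: int,
    config: SelectionConfig | None = None,
) -> tuple[tuple[int, ...], float, SelectionTrace]:
    """Forward stepwise gene selection on the full training sample."""
    config = config or SelectionConfig()
    candidates = np.array(prefilter_genes(train, s_formula, d_measure, config))
    cset = compute_centroid_set(train)
    var0, var1 = cset.variances(d_measure)
    genes, auc, steps = _greedy_core(
        candidates,
        cset.c0[candidates],
        cset.c1[candidates],
        var0[candidates],
        var1[candidates],
        train.class0[candidates],
        train.class1[candidates],
        s_formula,
        d_measure,
        config.greedy_delta,
    )
    trace = SelectionTrace(
        steps=steps,
        combo_aucs={(s_formula, d_measure): auc},
        combo_genes={(s_formula, d_measure): tuple(genes)},
    )
    return tuple(genes), auc, trace


def _stratified_half_split(
    n: int, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_fit = int(round(n * fraction))
    if n_fit < 2 or n - n_fit < 2:
        raise InvalidSplitError(
            f"class of size {n} cannot be split {fraction:.0%} with >= 2 per half"
        )
    perm = rng.permutation(n)
    return perm[:n_fit], perm[n_fit:]


def wrapper_select(
    train: ExpressionData,
    s_formula: int,
    d_measure: int,
    config: SelectionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, ...], float, SelectionTrace]:
    """Gene selection via nested train-train / train-test splits.

    Runs the greedy search on each of ``config.wrapper_splits`` stratified
    50/50 splits (centroids from the inner training half, AUC on the inner
    test half, threshold ``config.wrapper_delta``) and keeps the gene set of
    the best-performing split (ties toward the earliest split).  The
    returned AUC is recomputed on the full training sample, which also
    parameterizes any downstream rule.
    """
    config = config or SelectionConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    candidates = np.array(prefilter_genes(train, s_formula, d_measure, config))
    X0 = train.class0[candidates]
    X1 = train.class1[candidates]
    best: tuple[float, int, list[int]] | None = None  # (auc, split, genes)
    steps: list[TraceStep] = []
    for s in range(config.wrapper_splits):
        fit0, eval0 = _stratified_half_split(train.n0, config.wrapper_fraction, rng)
        fit1, eval1 = _stratified_half_split(train.n1, config.wrapper_fraction, rng)
        c0, c1, v0, v1, vp = _candidate_moments(X0[:, fit0], X1[:, fit1])
        if d_measure == POOLED:
            var0 = var1 = vp
        else:
            var0, var1 = v0, v1
        try:
            genes, auc, split_steps = _greedy_core(
                candidates, c0, c1, var0, var1,
                X0[:, eval0], X1[:, eval1],
                s_formula, d_measure, config.wrapper_delta, split=s,
            )
        except EmptyCandidateError:
            continue
        steps.extend(split_steps)
        if best is None or auc > best[0]:
            best = (auc, s, genes)
    if best is None:
        raise EmptyCandidateError("every wrapper split had only degenerate candidates")
    genes = tuple(best[2])
    full_auc = _training_auc(train, genes, s_formula, d_measure)
    trace = SelectionTrace(
        steps=steps,
        combo_aucs={(s_formula, d_measure): full_auc},
        combo_genes={(s_formula, d_measure): genes},
    )
    return genes, full_auc, trace


def select_rule(
    train: ExpressionData,
    config: SelectionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RuleComponents, SelectionTrace]:
    """Full rule selection: gene sets per (S, D), then D, then S.

    For each of the four (score formula, distance measure) combinations the
    configured algorithm picks a gene set and its training AUC.  Per score
    formula, the pooled distance is kept unless the class-specific distance
    improves the AUC by at least ``config.d_delta``.  The score formula with
    the highest AUC wins (ties toward Ripples).  The returned rule carries
    centroids estimated on the full training sample and the default
    cutpoint for its score formula.
    """
    config = config or SelectionConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    trace = SelectionTrace()
    for s_formula in (RIPPLES, SWIRLS):
        for d_measure in (POOLED, CLASS_SPECIFIC):
            if config.algorithm == "greedy":
                _, _, t = greedy_select(train, s_formula, d_measure, config)
            else:
                _, _, t = wrapper_select(train, s_formula, d_measure, config, rng)
            trace.extend(t)
    chosen_per_s: dict[int, tuple[int, float]] = {}
    for s_formula in (RIPPLES, SWIRLS):
        auc1 = trace.combo_aucs[(s_formula, POOLED)]
        auc2 = trace.combo_aucs[(s_formula, CLASS_SPECIFIC)]
        d_measure = CLASS_SPECIFIC if auc2 - auc1 >= config.d_delta else POOLED
        chosen_per_s[s_formula] = (d_measure, trace.combo_aucs[(s_formula, d_measure)])
    # ties go to Ripples, the simpler boundary
    if chosen_per_s[SWIRLS][1] > chosen_per_s[RIPPLES][1]:
        s_formula = SWIRLS
    else:
        s_formula = RIPPLES
    d_measure, _ = chosen_per_s[s_formula]
    genes = trace.combo_genes[(s_formula, d_measure)]
    trace.chosen = (s_formula, d_measure)
    rule = RuleComponents(
        compute_centroid_set(train), genes, d_measure, s_formula
    )
    return rule, trace
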