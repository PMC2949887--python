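"""Two-class nearest-centroid classification with Swirls and Ripples scores.

The classifier summarizes each class by per-gene means and variances (the
*centroid set*), measures a variance-standardized Euclidean distance from a
specimen to each class centroid over a selected gene set, and combines the
two distances into a scalar score.

Two distance standardizations are supported:

* ``D = 1`` divides each gene's squared deviation by the **pooled** variance
  (the diagonal *linear* discriminant analogue);
* ``D = 2`` divides by the **class-specific** variance (the diagonal
  *quadratic* discriminant analogue).

Two score formulas are supported:

* ``S = 1`` (*Ripples*): the difference of squared distances,
  ``d0**2 - d1**2``; its level sets are lines and conics, and with ``D = 1``
  it reproduces diagonal linear discriminant analysis exactly;
* ``S = 2`` (*Swirls*): the fraction ``d0 / (d0 + d1)`` in ``[0, 1]``; its
  level sets are smooth closed curves encircling a centroid, which can
  dramatically outperform Ripples when class variances differ but a pooled
  variance is used.

Both scores are oriented so that larger values indicate class 1.  A specimen
is assigned to class 1 when its score is at least the cutpoint ``u``
(default 0 for Ripples, 0.5 for Swirls — the scores' natural indifference
points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POOLED",
    "CLASS_SPECIFIC",
    "RIPPLES",
    "SWIRLS",
    "InvalidInputError",
    "DegenerateGeneError",
    "ExpressionData",
    "CentroidSet",
    "RuleComponents",
    "compute_centroid_set",
    "distance",
    "score",
    "score_specimens",
    "classify",
    "classify_specimens",
]

#: Distance measure 1: standardize by the pooled variance (DLDA analogue).
POOLED = 1
#: Distance measure 2: standardize by the class-specific variance (DQDA analogue).
CLASS_SPECIFIC = 2
#: Score formula 1: difference of squared distances; linear/conic boundaries.
RIPPLES = 1
#: Score formula 2: fraction of total distance; boundaries encircle a centroid.
SWIRLS = 2


class InvalidInputError(ValueError):
    """Input data violate a structural requirement (shape, size, finiteness)."""


class DegenerateGeneError(ValueError):
    """A gene in the active gene set has non-positive required variance."""


def _as_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError(f"{name} must be a 2-D (genes x specimens) matrix")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass(eq=False)
class ExpressionData:
    """Per-class expression matrices with shared gene rows.

    Parameters
    ----------
    class0, class1:
        Real matrices of shape ``(n_genes, n_k)``; rows are genes in the same
        order in both classes, columns are specimens.
    gene_ids:
        Ordered gene identifiers, one per row.
    class_labels:
        Display names for the two classes.
    """

    class0: np.ndarray
    class1: np.ndarray
    gene_ids: tuple[str, ...]
    class_labels: tuple[str, str] = ("class0", "class1")

    def __post_init__(self) -> None:
        self.class0 = _as_matrix(self.class0, "class0")
        self.class1 = _as_matrix(self.class1, "class1")
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        if self.class0.shape[0] != self.class1.shape[0]:
            raise InvalidInputError(
                "class matrices have different gene counts: "
                f"{self.class0.shape[0]} vs {self.class1.shape[0]}"
            )
        if len(self.gene_ids) != self.class0.shape[0]:
            raise InvalidInputError("gene_ids length does not match matrix rows")
        if self.class0.shape[1] < 2 or self.class1.shape[1] < 2:
            raise InvalidInputError(
                "each class needs at least 2 specimens (variance uses n_k - 1)"
            )

    @property
    def n_genes(self) -> int:
        return self.class0.shape[0]

    @property
    def n0(self) -> int:
        return self.class0.shape[1]

    @property
    def n1(self) -> int:
        return self.class1.shape[1]

    def subset_specimens(self, idx0, idx1) -> "ExpressionData":
        """New dataset keeping the given specimen columns of each class."""
        return ExpressionData(
            self.class0[:, np.asarray(idx0, dtype=int)],
            self.class1[:, np.asarray(idx1, dtype=int)],
            self.gene_ids,
            self.class_labels,
        )


@dataclass(eq=False)
class CentroidSet:
    """Per-gene class means and variances estimated on a training sample.

    ``c0``/``c1`` are the class centroids (mean expression per gene), ``v0``/
    ``v1`` the sample variances (denominator ``n_k - 1``), and ``v_pooled``
    the size-weighted pooled variance with denominator ``n0 + n1 - 2``.
    """

    c0: np.ndarray
    c1: np.ndarray
    v0: np.ndarray
    v1: np.ndarray
    v_pooled: np.ndarray
    n0: int
    n1: int
    gene_ids: tuple[str, ...] = field(default=())

    @property
    def n_genes(self) -> int:
        return self.c0.shape[0]

    def variances(self, d_measure: int) -> tuple[np.ndarray, np.ndarray]:
        """Variances used against centroid 0 and centroid 1 under ``d_measure``."""
        if d_measure == POOLED:
            return self.v_pooled, self.v_pooled
        if d_measure == CLASS_SPECIFIC:
            return self.v0, self.v1
        raise ValueError(f"distance measure must be 1 or 2, got {d_measure}")

    def subset(self, genes) -> "CentroidSet":
        g = np.asarray(genes, dtype=int)
        ids = tuple(self.gene_ids[i] for i in g) if self.gene_ids else ()
        return CentroidSet(
            self.c0[g], self.c1[g], self.v0[g], self.v1[g], self.v_pooled[g],
            self.n0, self.n1, ids,
        )


def compute_centroid_set(data: ExpressionData) -> CentroidSet:
    """Estimate centroids, class variances, and pooled variances.

    Means use denominator ``n_k``; variances use ``n_k - 1``; the pooled
    variance is ``((n0-1) v0 + (n1-1) v1) / (n0 + n1 - 2)``.
    """
    c0 = data.class0.mean(axis=1)
    c1 = data.class1.mean(axis=1)
    v0 = data.class0.var(axis=1, ddof=1)
    v1 = data.class1.var(axis=1, ddof=1)
    n0, n1 = data.n0, data.n1
    v_pooled = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    return CentroidSet(c0, c1, v0, v1, v_pooled, n0, n1, data.gene_ids)


@dataclass(eq=False)
class RuleComponents:
    """A fitted classification rule: centroids, gene set, D, S, and cutpoint.

    ``genes`` are row indices into ``centroids``.  ``cutpoint`` defaults to
    the score's indifference point (0 for Ripples, 0.5 for Swirls) when not
    given.
    """

    centroids: CentroidSet
    genes: tuple[int, ...]
    distance_measure: int = POOLED
    score_formula: int = RIPPLES
    cutpoint: float | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(int(g) for g in self.genes)
        if not self.genes:
            raise InvalidInputError("gene set G is empty")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidInputError("gene set G contains duplicate indices")
        if min(self.genes) < 0 or max(self.genes) >= self.centroids.n_genes:
            raise InvalidInputError("gene index out of range for the centroid set")
        if self.distance_measure not in (POOLED, CLASS_SPECIFIC):
            raise InvalidInputError("distance measure must be 1 or 2")
        if self.score_formula not in (RIPPLES, SWIRLS):
            raise InvalidInputError("score formula must be 1 or 2")
        g = np.asarray(self.genes)
        var0, var1 = self.centroids.variances(self.distance_measure)
        if np.any(var0[g] <= 0) or np.any(var1[g] <= 0):
            raise DegenerateGeneError(
                "gene set contains a gene with non-positive required variance"
            )
        if self.cutpoint is None:
            self.cutpoint = 0.0 if self.score_formula == RIPPLES else 0.5
        self.cutpoint = float(self.cutpoint)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        ids = self.centroids.gene_ids
        return tuple(ids[g] for g in self.genes) if ids else ()


def _squared_distances(
    X: np.ndarray, centroids: CentroidSet, genes, d_measure: int
) -> tuple[np.ndarray, np.ndarray]:
    """Squared standardized distances to both centroids, per specimen column."""
    g = np.asarray(genes, dtype=int)
    var0, var1 = centroids.variances(d_measure)
    var0, var1 = var0[g], var1[g]
    if np.any(var0 <= 0) or np.any(var1 <= 0):
        raise DegenerateGeneError(
            "zero or negative variance for a gene in the active gene set"
        )
    Xg = X[g]
    sq0 = ((Xg - centroids.c0[g][:, None]) ** 2 / var0[:, None]).sum(axis=0)
    sq1 = ((Xg - centroids.c1[g][:, None]) ** 2 / var1[:, None]).sum(axis=0)
    return sq0, sq1


def scores_from_squared(sq0: np.ndarray, sq1: np.ndarray, score_formula: int) -> np.ndarray:
    """Combine squared distances into scores; works on arrays of any shape."""
    if score_formula == RIPPLES:
        return sq0 - sq1
    if score_formula == SWIRLS:
        d0 = np.sqrt(sq0)
        d1 = np.sqrt(sq1)
        total = d0 + d1
        # A specimen sitting on both centroids is class-indifferent.
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(total > 0, d0 / np.where(total > 0, total, 1.0), 0.5)
    raise ValueError(f"score formula must be 1 or 2, got {score_formula}")


def distance(specimen, centroids: CentroidSet, genes, d_measure: int, k: int) -> float:
    """Standardized Euclidean distance from one specimen to centroid ``k``.

    ``specimen`` is a vector over the gene set ``genes`` (same order).
    """
    g = np.asarray(genes, dtype=int)
    z = np.asarray(specimen, dtype=float).ravel()
    if z.shape[0] != g.shape[0]:
        raise InvalidInputError("specimen vector length does not match gene set")
    if k not in (0, 1):
        raise ValueError("class index k must be 0 or 1")
    var0, var1 = centroids.variances(d_measure)
    var = (var0 if k == 0 else var1)[g]
    if np.any(var <= 0):
        raise DegenerateGeneError("zero or negative variance in the gene set")
    c = (centroids.c0 if k == 0 else centroids.c1)[g]
    return float(np.sqrt(np.sum((z - c) ** 2 / var)))


def score_specimens(X: np.ndarray, rule: RuleComponents) -> np.ndarray:
    """Scores for every specimen column of ``X`` (full gene rows) under ``rule``."""
    X = _as_matrix(X, "X")
    if X.shape[0] != rule.centroids.n_genes:
        raise InvalidInputError(
            "matrix rows do not match the rule's centroid set; align genes first"
        )
    sq0, sq1 = _squared_distances(X, rule.centroids, rule.genes, rule.distance_measure)
    return scores_from_squared(sq0, sq1, rule.score_formula)


def score(specimen, rule: RuleComponents) -> float:
    """Score of a single specimen given as a vector over the rule's gene set."""
    z = np.asarray(specimen, dtype=float).ravel()
    if z.shape[0] != len(rule.genes):
        raise InvalidInputError("specimen vector length does not match gene set")
    d0 = distance(z, rule.centroids, rule.genes, rule.distance_measure, 0)
    d1 = distance(z, rule.centroids, rule.genes, rule.distance_measure, 1)
    return float(scores_from_squared(np.array(d0**2), np.array(d1**2), rule.score_formula))


def classify(specimen, rule: RuleComponents, u: float | None = None) -> int:
    """Assign class 1 iff the score is at least the cutpoint ``u``."""
    u = rule.cutpoint if u is None else float(u)
    return int(score(specimen, rule) >= u)


def classify_specimens(X: np.ndarray, rule: RuleComponents, u: float | None = None) -> np.ndarray:
    """Vectorized :func:`classify` over specimen columns of ``X``."""
    u = rule.cutpoint if u is None else float(u)
    return (score_specimens(X, rule) >= u).astype(int)
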