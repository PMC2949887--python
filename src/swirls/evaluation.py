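"""Test-sample evaluation: decile ROC curves, bootstrap bands, concave
envelopes, and relative-utility curves.

Orientation note (unconventional but deliberate): class 0 is the "positive"
class.  At a cutpoint ``u``, the true positive rate is the fraction of
class-0 specimens whose *score is below* ``u`` (they would be assigned to
class 0), and the false positive rate is the fraction of class-1 specimens
with score below ``u``.  The prevalence ``pi`` in the relative-utility
formulas is therefore the class-0 probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ExpressionData, InvalidInputError, RuleComponents, score_specimens

__all__ = [
    "RocCurve",
    "RocBand",
    "RelativeUtilityCurve",
    "InsufficientDataError",
    "empirical_roc",
    "bootstrap_roc",
    "bootstrap_roc_from_scores",
    "concave_envelope",
    "relative_utility",
    "relative_utility_curve",
]

DEFAULT_FPR_GRID = np.arange(1, 10) / 10.0


class InsufficientDataError(ValueError):
    """The concave ROC has too few interior points for a relative-utility curve."""


@dataclass(eq=False)
class RocCurve:
    """Ordered ROC operating points; class 0 is the positive class."""

    fpr: np.ndarray
    tpr: np.ndarray
    cutpoints: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        if self.fpr.shape != self.tpr.shape:
            raise InvalidInputError("fpr and tpr must have equal length")
        if np.any((self.fpr < 0) | (self.fpr > 1) | (self.tpr < 0) | (self.tpr > 1)):
            raise InvalidInputError("ROC coordinates must lie in [0, 1]")
        if self.cutpoints is not None:
            self.cutpoints = np.asarray(self.cutpoints, dtype=float)
            if self.cutpoints.shape != self.fpr.shape:
                raise InvalidInputError("cutpoints must match fpr/tpr length")

    def auc(self) -> float:
        """Trapezoidal area under the curve."""
        order = np.argsort(self.fpr, kind="stable")
        return float(np.trapezoid(self.tpr[order], self.fpr[order]))


@dataclass(eq=False)
class RocBand:
    """Bootstrap mean +/- SD of TPR on a fixed FPR grid."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    sd_tpr: np.ndarray
    n_bootstrap: int

    @property
    def lower(self) -> np.ndarray:
        return np.clip(self.mean_tpr - self.sd_tpr, 0.0, 1.0)

    @property
    def upper(self) -> np.ndarray:
        return np.clip(self.mean_tpr + self.sd_tpr, 0.0, 1.0)

    def mean_curve(self) -> RocCurve:
        """Mean ROC with the (0,0) and (1,1) anchors attached."""
        fpr = np.concatenate([[0.0], self.fpr_grid, [1.0]])
        tpr = np.concatenate([[0.0], np.clip(self.mean_tpr, 0.0, 1.0), [1.0]])
        return RocCurve(fpr, tpr)


@dataclass(eq=False)
class RelativeUtilityCurve:
    """(risk threshold, relative utility) pairs at a given class-0 prevalence."""

    risk_thresholds: np.ndarray
    ru: np.ndarray
    prevalence: float

    def __post_init__(self) -> None:
        self.risk_thresholds = np.asarray(self.risk_thresholds, dtype=float)
        self.ru = np.asarray(self.ru, dtype=float)


def empirical_roc(test_scores0, test_scores1, cutpoints=None) -> RocCurve:
    """Empirical ROC at decile cutpoints of the pooled score distribution.

    At each cutpoint ``u``, TPR is the fraction of class-0 scores below
    ``u`` and FPR the fraction of class-1 scores below ``u``; sentinel
    cutpoints at -inf and +inf supply the (0, 0) and (1, 1) endpoints.
    Custom ``cutpoints`` may be given (they are used verbatim, plus the
    sentinels).
    """
    s0 = np.asarray(test_scores0, dtype=float).ravel()
    s1 = np.asarray(test_scores1, dtype=float).ravel()
    if s0.size == 0 or s1.size == 0:
        raise InvalidInputError("each class needs at least one test specimen")
    if cutpoints is None:
        pooled = np.concatenate([s0, s1])
        cutpoints = np.percentile(pooled, np.arange(10, 100, 10))
    cut = np.concatenate([[-np.inf], np.sort(np.asarray(cutpoints, dtype=float)), [np.inf]])
    tpr = np.array([(s0 < u).mean() for u in cut])
    fpr = np.array([(s1 < u).mean() for u in cut])
    return RocCurve(fpr, tpr, cut)


def _interp_tpr(roc: RocCurve, fpr_grid: np.ndarray) -> np.ndarray:
    """TPR at the grid by linear interpolation, anchored at (0,0) and (1,1).

    Duplicate FPR values (flat segments) keep the maximal TPR.
    """
    fpr = np.concatenate([[0.0], roc.fpr, [1.0]])
    tpr = np.concatenate([[0.0], roc.tpr, [1.0]])
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    keep_x, keep_y = [], []
    for x, y in zip(fpr, tpr):
        if keep_x and x == keep_x[-1]:
            keep_y[-1] = max(keep_y[-1], y)
        else:
            keep_x.append(x)
            keep_y.append(y)
    return np.interp(fpr_grid, np.array(keep_x), np.array(keep_y))


def bootstrap_roc_from_scores(
    test_scores0,
    test_scores1,
    n_bootstrap: int = 20,
    seed=None,
    fpr_grid: np.ndarray = DEFAULT_FPR_GRID,
) -> RocBand:
    """Bootstrap ROC band from precomputed test scores.

    Each bootstrap draw resamples scores with replacement within each class
    (class sizes preserved), computes the decile ROC, and interpolates TPR
    at the FPR grid.  The band is the per-grid mean +/- one SD.
    """
    s0 = np.asarray(test_scores0, dtype=float).ravel()
    s1 = np.asarray(test_scores1, dtype=float).ravel()
    if s0.size == 0 or s1.size == 0:
        raise InvalidInputError("each class needs at least one test specimen")
    if n_bootstrap < 1:
        raise InvalidInputError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.asarray(fpr_grid, dtype=float)
    tprs = np.empty((n_bootstrap, grid.size))
    for b in range(n_bootstrap):
        r0 = s0[rng.integers(0, s0.size, s0.size)]
        r1 = s1[rng.integers(0, s1.size, s1.size)]
        tprs[b] = _interp_tpr(empirical_roc(r0, r1), grid)
    return RocBand(grid, tprs.mean(axis=0), tprs.std(axis=0, ddof=0), n_bootstrap)


def bootstrap_roc(
    test: ExpressionData,
    rule: RuleComponents,
    n_bootstrap: int = 20,
    seed=None,
    fpr_grid: np.ndarray = DEFAULT_FPR_GRID,
) -> RocBand:
    """Bootstrap ROC band for a fitted rule applied to a test sample."""
    s0 = score_specimens(test.class0, rule)
    s1 = score_specimens(test.class1, rule)
    return bootstrap_roc_from_scores(s0, s1, n_bootstrap, seed, fpr_grid)


def concave_envelope(roc: RocCurve) -> RocCurve:
    """Upper concave hull of the ROC points plus the (0,0) and (1,1) anchors.

    The result majorizes every input point and has strictly decreasing
    segment slopes (collinear interior points are dropped); applying the
    envelope twice is a no-op.
    """
    pts = np.column_stack([
        np.concatenate([roc.fpr, [0.0, 1.0]]),
        np.concatenate([roc.tpr, [0.0, 1.0]]),
    ])
    # sort by x, then y; for equal x keep only the highest point
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    xs: list[float] = []
    ys: list[float] = []
    for x, y in pts:
        if xs and x == xs[-1]:
            ys[-1] = max(ys[-1], y)
        else:
            xs.append(float(x))
            ys.append(float(y))
    hull_x: list[float] = []
    hull_y: list[float] = []
    for x, y in zip(xs, ys):
        while len(hull_x) >= 2:
            cross = (hull_x[-1] - hull_x[-2]) * (y - hull_y[-2]) - (
                hull_y[-1] - hull_y[-2]
            ) * (x - hull_x[-2])
            if cross >= 0:  # middle point on or below the chord
                hull_x.pop()
                hull_y.pop()
            else:
                break
        hull_x.append(x)
        hull_y.append(y)
    return RocCurve(np.array(hull_x), np.array(hull_y))


def relative_utility(
    tpr: float, fpr: float, prevalence: float, risk_threshold: float
) -> float:
    """Relative utility of operating at (FPR, TPR) for a given risk threshold.

    The maximum expected utility of classification, as a fraction of the
    utility of perfect prediction.  For thresholds at or above the
    prevalence the comparison is against treat-none; below, against
    treat-all.  The two branches agree at ``risk_threshold == prevalence``.
    """
    pi = float(prevalence)
    r = float(risk_threshold)
    if not 0 < pi < 1:
        raise InvalidInputError("prevalence must lie in (0, 1)")
    if not 0 < r < 1:
        raise InvalidInputError("risk threshold must lie in (0, 1)")
    if r >= pi:
        return float(tpr - ((1 - pi) / pi) * (r / (1 - r)) * fpr)
    return float((1 - fpr) - (pi / (1 - pi)) * ((1 - r) / r) * (1 - tpr))


def relative_utility_curve(
    concave_roc: RocCurve, prevalence: float
) -> RelativeUtilityCurve:
    """Relative-utility curve from a concave ROC.

    Each hull segment of slope ``s`` maps to the risk threshold
    ``R = s*pi / (s*pi + 1 - pi)``; the RU at that threshold is evaluated at
    the segment's vertex (both segment endpoints give the same value there).
    Requires at least two hull vertices strictly between (0, 0) and (1, 1);
    otherwise there are insufficient data for a curve.
    """
    pi = float(prevalence)
    if not 0 < pi < 1:
        raise InvalidInputError("prevalence must lie in (0, 1)")
    x = concave_roc.fpr
    y = concave_roc.tpr
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    interior = (x > 0) | (y > 0)
    interior &= (x < 1) | (y < 1)
    if int(interior.sum()) < 2:
        raise InsufficientDataError(
            "concave ROC has fewer than two points strictly between (0,0) and (1,1)"
        )
    thresholds: list[float] = []
    rus: list[float] = []
    for i in range(len(x) - 1):
        dx = x[i + 1] - x[i]
        dy = y[i + 1] - y[i]
        if dx <= 0:
            continue  # vertical jump: infinite slope, R -> 1
        s = dy / dx
        if s <= 0:
            continue  # flat or decreasing: R -> 0
        r = s * pi / (s * pi + 1 - pi)
        rus.append(relative_utility(y[i + 1], x[i + 1], pi, r))
        thresholds.append(r)
    order = np.argsort(thresholds)
    return RelativeUtilityCurve(
        np.asarray(thresholds)[order], np.asarray(rus)[order], pi
    )


def relative_utility_curve_or_none(
    concave_roc: RocCurve, prevalence: float
) -> RelativeUtilityCurve | None:
    """As :func:`relative_utility_curve`, but warn and return None when the
    hull is too sparse (the Goal-1 workflow then omits the RU output)."""
    try:
        return relative_utility_curve(concave_roc, prevalence)
    except InsufficientDataError as exc:
        warnings.warn(f"insufficient data to compute a RU curve: {exc}", stacklevel=2)
        return None
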