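"""Binormal AUC of a classification score, plus a rank-based cross-check.

Gene and rule selection rank candidates by the area under the ROC curve of
the score, computed under a binormal assumption: with per-class score means
``m_k`` and sample variances ``w_k`` (denominator ``n_k - 1``),

    AUC = Phi((m_1 - m_0) / sqrt(w_0 + w_1)),

where ``Phi`` is the standard normal CDF.  Scores are oriented so that class
1 is higher, hence an informative score gives AUC >= 0.5.  The binormal form
is used because it is cheap to evaluate inside the selection loops; the
nonparametric Wilcoxon AUC is provided only as an independent check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

from .core import InvalidInputError

__all__ = ["binormal_auc", "wilcoxon_auc"]


def binormal_auc(scores0, scores1) -> float:
    """Binormal AUC of class-1-high scores; in [0, 1].

    Degenerate case ``w_0 + w_1 = 0`` (both score samples constant) returns
    the limit of the formula: 0.5 if the means are equal, else 1 or 0
    according to the sign of ``m_1 - m_0``.
    """
    s0 = np.asarray(scores0, dtype=float).ravel()
    s1 = np.asarray(scores1, dtype=float).ravel()
    if s0.size < 2 or s1.size < 2:
        raise InvalidInputError("each score vector needs at least 2 values")
    return float(_binormal_auc_rows(s0[None, :], s1[None, :])[0])


def _binormal_auc_rows(S0: np.ndarray, S1: np.ndarray) -> np.ndarray:
    """Row-wise binormal AUC for score matrices of shape (m, n_k)."""
    m0 = S0.mean(axis=1)
    m1 = S1.mean(axis=1)
    w0 = S0.var(axis=1, ddof=1)
    w1 = S1.var(axis=1, ddof=1)
    denom = w0 + w1
    out = np.empty(m0.shape[0], dtype=float)
    ok = denom > 0
    out[ok] = ndtr((m1[ok] - m0[ok]) / np.sqrt(denom[ok]))
    if not ok.all():
        bad = ~ok
        diff = m1[bad] - m0[bad]
        out[bad] = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    return out


def wilcoxon_auc(scores0, scores1) -> float:
    """Empirical (Mann-Whitney) AUC: P(class-1 score > class-0 score), ties 1/2."""
    s0 = np.asarray(scores0, dtype=float).ravel()
    s1 = np.asarray(scores1, dtype=float).ravel()
    if s0.size == 0 or s1.size == 0:
        raise InvalidInputError("each score vector needs at least 1 value")
    ranks = rankdata(np.concatenate([s0, s1]))
    r1 = ranks[s0.size :].sum()
    n1 = s1.size
    return float((r1 - n1 * (n1 + 1) / 2) / (s0.size * n1))
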