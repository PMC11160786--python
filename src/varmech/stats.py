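"""Generic statistics primitives shared by all analysis stages.

These wrap established implementations (scipy, statsmodels, scikit-learn)
behind a uniform error contract: degenerate inputs raise package errors
instead of returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, UndefinedAUCError, ValidationError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table, row-major: [[a, b], [c, d]].

    Convention used throughout: rows split by the property being tested
    (e.g. carries a pathogenic variant), columns by the annotation
    (e.g. pocket-associated).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"count {name}={v} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact(
    table: ContingencyTable2x2, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns the sample odds ratio (a*d)/(b*c) — infinite when b*c = 0 and
    a*d > 0 — and the exact hypergeometric p-value.  ``alternative`` is
    ``two-sided`` (default, minimum-likelihood method), ``greater`` or
    ``less``; enrichment tests that are directional use ``greater``.
    """
    if table.total == 0:
        raise DegenerateInputError("all-zero contingency table")
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        odds = np.inf if ad > 0 else np.nan
    else:
        odds = ad / bc
    _, p = scipy.stats.fisher_exact(table.as_array(), alternative=alternative)
    return float(odds), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve with ties counted 1/2 (the Mann-Whitney
    U-statistic divided by n1*n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("labels contain a single class; AUC undefined")
    return float(roc_auc_score(labels, scores))


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have the same length")
    if x.size < 3:
        raise DegenerateInputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input; correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
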