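"""LDA leave-one-out discrimination on recomputed PC loadings.

Validation of a selected feature set: PC loadings are recomputed on the
submatrix of selected features (re-normalized over that restricted set),
the first L loadings per sample form the embedding, and a linear
discriminant with pooled within-class covariance and equal class priors
(1/2, 1/2) classifies each sample under leave-one-out cross-validation.
The embedding itself is computed once on all samples; only the classifier
is refit per fold.  The resulting 2x2 confusion matrix (rows predicted,
columns true, case first) is scored with Fisher's exact test, reporting
the two-sided minimum-likelihood p-value and the conditional-MLE odds
ratio of the noncentral hypergeometric model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data_io import ExpressionMatrix, CASE, CONTROL, normalize_samples
from .pca_fe import PCADecomposition, decompose

#: relative tolerance of the conditional-MLE root find
CMLE_RTOL = 1e-8


@dataclass
class DiscriminationResult:
    """LOOCV confusion matrix plus Fisher's exact test statistics.

    ``confusion[pred, true]`` with class order (case, control); ``L`` is
    the number of leading PC loadings fed to the discriminant.
    """

    L: int
    confusion: np.ndarray
    p_value: float
    odds_ratio: float

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def recompute_loadings(
    m: ExpressionMatrix, selected: list[str]
) -> tuple[np.ndarray, PCADecomposition]:
    """Per-sample embedding from a PCA restricted to the selected features.

    The submatrix is re-normalized column-wise over the restricted feature
    set before decomposition.  Returns ``(embedding, decomposition)`` where
    ``embedding`` is ``(n_samples, n_components)`` — sample j's coordinates
    are the loadings v_kj, components ordered by eigenvalue.
    """
    if len(selected) < 2:
        raise ValueError("need at least 2 selected features to recompute loadings")
    sub = normalize_samples(m.subset_features(list(selected)))
    d = decompose(sub)
    return d.loadings.T.copy(), d


def lda_loocv(embedding: np.ndarray, labels: np.ndarray, L: int) -> np.ndarray:
    """Leave-one-out LDA on the first L embedding coordinates.

    Equal priors (1/2, 1/2) regardless of class imbalance.  Returns the
    2x2 integer confusion matrix, rows = predicted, columns = true, class
    order (case, control).

    Raises
    ------
    ValueError
        If L exceeds the embedding dimension or the pooled within-class
        covariance on L coordinates is singular (reduce L).
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if L < 1 or L > embedding.shape[1]:
        raise ValueError(f"L={L} outside [1, {embedding.shape[1]}]")
    y = (labels == CASE).astype(int)  # 1 = case
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("both classes need >= 2 samples")
    Z = embedding[:, :L]

    pooled = sum(np.cov(Z[y == c].T, ddof=1).reshape(L, L) * ((y == c).sum() - 1)
                 for c in (0, 1)) / (len(y) - 2)
    if np.linalg.matrix_rank(pooled) < L:
        raise ValueError(
            f"singular pooled within-class covariance at L={L}; use a smaller L"
        )

    classes = [CASE, CONTROL]
    confusion = np.zeros((2, 2), dtype=int)
    n = len(y)
    for held in range(n):
        train = np.ones(n, dtype=bool)
        train[held] = False
        clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        clf.fit(Z[train], labels[train].astype(str))
        pred = clf.predict(Z[held][None, :])[0]
        confusion[classes.index(pred), classes.index(labels[held])] += 1
    return confusion


def _log_support(table: np.ndarray):
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    sup = np.arange(lo, hi + 1)
    logc = (
        gammaln(r1 + 1) - gammaln(sup + 1) - gammaln(r1 - sup + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - sup + 1) - gammaln(n - r1 - c1 + sup + 1)
    )
    return int(a), sup, logc, lo, hi


def conditional_mle_odds_ratio(table: np.ndarray) -> float:
    """Conditional-MLE odds ratio of a 2x2 table (Fisher's noncentral model).

    The estimate solves the score equation E_psi[x11 | margins] = x11 by
    bracketed root-finding on log(psi) to relative tolerance ``CMLE_RTOL``.
    Returns +inf when x11 sits at the top of its conditional support
    (e.g. a zero off-diagonal cell with concordant diagonal) and 0 in the
    symmetric bottom-of-support case.
    """
    a, sup, logc, lo, hi = _log_support(np.asarray(table))
    if a == hi:
        return float("inf")
    if a == lo:
        return 0.0

    def score(logpsi: float) -> float:
        w = logc + sup * logpsi
        w = np.exp(w - w.max())
        return float((sup * w).sum() / w.sum()) - a

    left, right = -1.0, 1.0
    while score(left) > 0:
        left *= 2
    while score(right) < 0:
        right *= 2
    # xtol on log(psi) is a relative tolerance on psi; 1e-12 < CMLE_RTOL
    root = brentq(score, left, right, xtol=1e-12)
    return float(np.exp(root))


def fisher_exact(confusion: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact p-value and conditional-MLE odds ratio.

    The two-sided p sums hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's (the minimum-likelihood rule).
    """
    table = np.asarray(confusion)
    if not np.issubdtype(table.dtype, np.integer):
        as_int = np.asarray(confusion, dtype=float)
        if not np.all(as_int == np.round(as_int)):
            raise ValueError("confusion matrix entries must be integers")
        table = as_int.astype(int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("expected a nonnegative 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("both margins of the table must be positive")
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return p, conditional_mle_odds_ratio(table)


def discriminate(
    m: ExpressionMatrix, selected: list[str], L: int
) -> DiscriminationResult:
    """Recompute loadings on the selected features, run LOOCV LDA, score."""
    m.require_labels()
    embedding, _ = recompute_loadings(m, selected)
    confusion = lda_loocv(embedding, m.labels, L)
    p, orr = fisher_exact(confusion)
    return DiscriminationResult(L=L, confusion=confusion, p_value=p, odds_ratio=orr)


def scan_L(
    m: ExpressionMatrix, selected: list[str], L_max: int | None = None
) -> DiscriminationResult:
    """Trial-and-error choice of L: maximize LOOCV accuracy over 1..L_max.

    Ties break toward the smallest L.  Components whose pooled covariance
    is singular are skipped.
    """
    m.require_labels()
    embedding, d = recompute_loadings(m, selected)
    limit = min(L_max or embedding.shape[1], embedding.shape[1])
    best: DiscriminationResult | None = None
    for L in range(1, limit + 1):
        try:
            confusion = lda_loocv(embedding, m.labels, L)
        except ValueError:
            continue
        p, orr = fisher_exact(confusion)
        result = DiscriminationResult(L=L, confusion=confusion, p_value=p, odds_ratio=orr)
        if best is None or result.accuracy > best.accuracy:
            best = result
    if best is None:
        raise ValueError("no usable L in range")
    return best
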