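"""PCA-based unsupervised feature extraction.

Unlike standard PCA, which embeds the samples, this procedure embeds the
*features* (genes or miRNAs): the k-th principal-component score u_ki of
feature i is an element of the k-th eigenvector u_k of the gram matrix
X X^T, and the loading v_kj attributed to sample j is the j-th element of
v_k = X^T u_k (an eigenvector of X^T X).  The embedding itself uses no
class labels; labels enter only afterwards, to pick the component set
Omega whose loadings differ between cases and controls (two-sample t-test).

A feature is an outlier when its summed squared standardized scores over
Omega,

    T_i = sum_{k in Omega} (u_ki / sigma_k)^2,

is improbably large under a Gaussian score model: P_i is the upper tail of
the chi-squared distribution with |Omega| degrees of freedom at T_i, and
features with Benjamini-Hochberg-adjusted P_i below a threshold (default
0.01) are selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix, CASE, CONTROL

#: components with eigenvalue below this fraction of the leading one are dropped
EIGENVALUE_RTOL = 1e-10


@dataclass
class PCADecomposition:
    """Gene-side PCA of a normalized expression matrix.

    Attributes
    ----------
    scores
        ``(n_components, n_features)``; row k is the unit-norm eigenvector
        u_k of X X^T, so ``scores[k, i]`` is the PC score of feature i.
    loadings
        ``(n_components, n_samples)``; row k is v_k = X^T u_k, the PC
        loading attributed to each sample.
    eigenvalues
        Nonnegative, descending.
    sigma
        Standard deviation of the scores of each component over features
        (mean subtracted, denominator n-1).
    """

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    sigma: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[0]


@dataclass
class PCSelection:
    """Components whose loadings separate cases from controls."""

    omega: list[int]
    pvalues: np.ndarray
    alpha: float = 0.05


@dataclass
class FeatureOutlierResult:
    """Per-feature chi-squared outlier call."""

    feature_ids: list[str]
    statistic: np.ndarray
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    selected: np.ndarray
    threshold: float
    selection: PCSelection
    decomposition: PCADecomposition

    @property
    def selected_ids(self) -> list[str]:
        return [f for f, s in zip(self.feature_ids, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "statistic": self.statistic,
                "raw_p": self.raw_p,
                "adjusted_p": self.adjusted_p,
                "selected": self.selected,
            }
        )

    def component_frame(self) -> pd.DataFrame:
        omega = set(self.selection.omega)
        return pd.DataFrame(
            {
                "component": np.arange(self.decomposition.n_components),
                "eigenvalue": self.decomposition.eigenvalues,
                "t_p": self.selection.pvalues,
                "in_omega": [k in omega for k in range(self.decomposition.n_components)],
            }
        )


class NoDiscriminativeComponentsError(ValueError):
    """Omega is empty: no component's loadings separate the classes."""


def decompose(m: ExpressionMatrix) -> PCADecomposition:
    """Eigendecompose the gram matrix X X^T via thin SVD of X.

    Works through the sample-side problem (n_samples x n_samples), never
    materializing the n_features x n_features gram matrix.  Components
    with eigenvalue below ``EIGENVALUE_RTOL`` times the leading eigenvalue
    are dropped.  Expects a column-normalized matrix (each sample column
    centered over features); on such input every retained score vector is
    orthogonal to the all-ones direction.

    The sign of each component is fixed deterministically by making the
    score entry of largest magnitude positive.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to decompose")
    X = m.values
    # thin SVD: X = U diag(s) Vt; columns of U are eigenvectors of X X^T
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2
    if eigenvalues[0] <= 0:
        raise ValueError("matrix is identically zero")
    keep = eigenvalues > EIGENVALUE_RTOL * eigenvalues[0]
    U, eigenvalues = U[:, keep], eigenvalues[keep]

    anchor = np.argmax(np.abs(U), axis=0)
    flip = np.sign(U[anchor, np.arange(U.shape[1])])
    U = U * flip

    scores = U.T  # (K, N)
    loadings = scores @ X  # v_k = X^T u_k, shape (K, S)
    sigma = scores.std(axis=1, ddof=1)
    return PCADecomposition(scores, loadings, eigenvalues, sigma)


def select_pcs(
    d: PCADecomposition, labels: np.ndarray, alpha: float = 0.05
) -> PCSelection:
    """Pick Omega: components whose loadings differ between the classes.

    Per component, a two-sample unequal-variance (Welch) t-test compares
    case vs. control loadings; components with unadjusted p < ``alpha``
    enter Omega.  Omega may come out empty; downstream stages must handle
    that explicitly.
    """
    labels = np.asarray(labels, dtype=object)
    case = labels == CASE
    control = labels == CONTROL
    if case.sum() < 2 or control.sum() < 2:
        raise ValueError("both classes need >= 2 samples for the loading t-test")
    res = stats.ttest_ind(
        d.loadings[:, case], d.loadings[:, control], axis=1, equal_var=False
    )
    pvalues = np.asarray(res.pvalue)
    omega = [int(k) for k in np.flatnonzero(pvalues < alpha)]
    return PCSelection(omega=omega, pvalues=pvalues, alpha=alpha)


def chi2_outlier_statistic(d: PCADecomposition, s: PCSelection) -> np.ndarray:
    """T_i = sum over Omega of (u_ki / sigma_k)^2."""
    if not s.omega:
        raise NoDiscriminativeComponentsError(
            "no discriminative components: Omega is empty"
        )
    z = d.scores[s.omega, :] / d.sigma[s.omega, None]
    return np.sum(z**2, axis=0)


def chi2_outlier_pvalues(d: PCADecomposition, s: PCSelection) -> np.ndarray:
    """Upper-tail chi-squared probability of T_i with |Omega| df."""
    t = chi2_outlier_statistic(d, s)
    return stats.chi2.sf(t, df=len(s.omega))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1 or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def select_features(
    m: ExpressionMatrix,
    alpha_pc: float = 0.05,
    threshold: float = 0.01,
) -> FeatureOutlierResult:
    """Full unsupervised feature extraction on a normalized labelled matrix.

    decompose -> select_pcs -> chi-squared outlier p-values -> BH -> flag
    adjusted p below ``threshold``.
    """
    m.require_labels()
    d = decompose(m)
    sel = select_pcs(d, m.labels, alpha=alpha_pc)
    statistic = chi2_outlier_statistic(d, sel)
    raw_p = stats.chi2.sf(statistic, df=len(sel.omega))
    adjusted = bh_adjust(raw_p)
    return FeatureOutlierResult(
        feature_ids=list(m.feature_ids),
        statistic=statistic,
        raw_p=raw_p,
        adjusted_p=adjusted,
        selected=adjusted < threshold,
        threshold=threshold,
        selection=sel,
        decomposition=d,
    )
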