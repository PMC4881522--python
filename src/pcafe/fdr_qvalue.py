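"""Storey q-values as a secondary significance criterion.

The chi-squared outlier p-values are converted to q-values: the null
proportion pi0 is estimated by Storey's smoother over a lambda grid, and

    q_(r) = min_{r' >= r} pi0 * m * p_(r') / r'

With pi0 pinned to 1 the q-values coincide exactly with
Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: lambda grid for Storey's pi0 smoother
PI0_LAMBDAS = np.arange(0.05, 0.96, 0.05)

#: minimum vector length for pi0 estimation
MIN_M_FOR_PI0 = 20


@dataclass
class QValueResult:
    qvalues: np.ndarray
    pi0: float
    threshold: float = 0.01

    @property
    def significant(self) -> np.ndarray:
        return self.qvalues < self.threshold


def estimate_pi0(p: np.ndarray) -> float:
    """Storey's smoother estimate of the null proportion.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    0.05..0.95 and smoothed with a cubic polynomial; the smoothed value at
    the largest lambda, clipped to (0, 1], is returned.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m < MIN_M_FOR_PI0:
        raise ValueError(
            f"need >= {MIN_M_FOR_PI0} p-values to estimate pi0 (got {m}); "
            "pass pi0 explicitly for short vectors"
        )
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in PI0_LAMBDAS])
    coeffs = np.polyfit(PI0_LAMBDAS, pi0_lam, deg=3)
    pi0 = float(np.polyval(coeffs, PI0_LAMBDAS[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(
    p: np.ndarray, pi0: float | None = None, threshold: float = 0.01
) -> QValueResult:
    """Storey q-values for a p-value vector.

    ``pi0=None`` estimates the null proportion with :func:`estimate_pi0`;
    passing ``pi0=1.0`` reproduces Benjamini-Hochberg adjustment exactly.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.min(p) < 0 or np.max(p) > 1 or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    elif not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    # pi0 * p / (r/m): with pi0 = 1 this is arithmetically identical to
    # the BH step-up adjustment, so the regression identity holds exactly
    raw = pi0 * (p[order] / (ranks / m))
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(qvalues=q, pi0=float(pi0), threshold=threshold)


def qvalue_frame(feature_ids, p, result: QValueResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "p": np.asarray(p, dtype=float),
            "q": result.qvalues,
            "significant": result.significant,
        }
    )
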