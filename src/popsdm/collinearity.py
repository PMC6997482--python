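"""Variance-inflation-factor screening of collinear climate variables.

VIF_j = 1 / (1 - R2_j), with R2_j the coefficient of determination of
variable j regressed (OLS with intercept) on all the others. Variables are
eliminated greedily — drop the largest-VIF variable, recompute, repeat —
until every remaining VIF falls below the threshold (default 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("popsdm")

_R2_EPS = 1e-12


def vif(X: pd.DataFrame) -> pd.Series:
    """Per-variable variance inflation factors.

    Near-perfect collinearity (R2 >= 1 - 1e-12) and constant columns are
    reported as +inf.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two variables")
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("VIF needs more rows than variables")
    A = X.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(X.columns):
        y = A[:, j]
        if np.ptp(y) == 0:
            logger.warning("vif: column %r is constant; VIF = inf", name)
            out[name] = np.inf
            continue
        others = np.delete(A, j, axis=1)
        design = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - resid @ resid / ss_tot
        out[name] = np.inf if r2 >= 1.0 - _R2_EPS else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


@dataclass
class VifReport:
    """Elimination trace: VIFs per round, what was dropped, what survived."""

    threshold: float
    rounds: list[pd.Series] = field(default_factory=list)
    eliminated: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f"round_{i}": r for i, r in enumerate(self.rounds)})


def vif_eliminate(X: pd.DataFrame, threshold: float = 10.0) -> tuple[pd.DataFrame, VifReport]:
    """Iteratively drop the max-VIF variable until all VIFs < threshold.

    Ties are broken by column order (first wins). Returns the reduced matrix
    (original column order preserved) and the full elimination trace.
    """
    if threshold <= 1:
        raise ValueError("VIF threshold must exceed 1")
    X = pd.DataFrame(X)
    report = VifReport(threshold=threshold)
    current = X.copy()
    while current.shape[1] >= 2:
        v = vif(current)
        report.rounds.append(v)
        worst = v.idxmax()  # first max in column order
        if v[worst] < threshold:
            break
        report.eliminated.append(worst)
        logger.info("vif_eliminate: dropping %r (VIF %.3g)", worst, v[worst])
        current = current.drop(columns=[worst])
    report.retained = list(current.columns)
    return current, report
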