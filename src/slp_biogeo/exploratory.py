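"""Non-phylogenetic association tests and collinearity diagnostics.

These are the exploratory checks run before any phylogenetic correction:
a 2x2 chi-square for SLP against each geographic coding, a Welch t-test
comparing species richness between trait states, and VIF / phi-coefficient
diagnostics for the predictor set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "CollinearityReport",
    "chi_square_2x2",
    "phi_coefficient",
    "welch_t",
    "vif",
    "contingency_2x2",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    method: str

    def as_dict(self):
        return {"statistic": self.statistic, "df": self.df, "p": self.p,
                "method": self.method}


@dataclass(frozen=True)
class CollinearityReport:
    vif: dict[str, float]
    phi: dict[tuple[str, str], TestResult]


def contingency_2x2(x, y) -> np.ndarray:
    """Cross-tabulate two aligned binary vectors into [[a, b], [c, d]]."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    table = np.array(
        [[np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
         [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))]],
        dtype=np.int64,
    )
    return table


def _check_table(table) -> tuple[float, float, float, float]:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of nonnegative counts")
    a, b, c, d = t.ravel()
    if a + b + c + d <= 0:
        raise ValueError("empty table")
    for m in (a + b, c + d, a + c, b + d):
        if m == 0:
            raise ValueError("zero marginal: statistic undefined")
    return a, b, c, d


def chi_square_2x2(table, correction: bool = True) -> TestResult:
    """Pearson chi-square for a 2x2 table, closed form.

    With Yates continuity correction, |ad - bc| is shrunk by n/2 (floored
    at zero).  p from the chi-square distribution with 1 df.
    """
    a, b, c, d = _check_table(table)
    n = a + b + c + d
    cross = abs(a * d - b * c)
    if correction:
        cross = max(0.0, cross - n / 2.0)
    stat = n * cross ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(float(stat), 1.0, p,
                      "chi-square (Yates)" if correction else "chi-square")


def phi_coefficient(table) -> TestResult:
    """Phi association coefficient for a 2x2 table; p via chi2 = n*phi^2."""
    a, b, c, d = _check_table(table)
    n = a + b + c + d
    phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(n * phi ** 2, df=1))
    return TestResult(float(phi), 1.0, p, "phi")


def welch_t(x, y) -> TestResult:
    """Welch two-sample t-test (unequal variances), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      "welch-t")


def vif(design, columns=None) -> dict[str, float]:
    """Variance inflation factor per predictor.

    Each column is regressed (with intercept) on the remaining columns;
    VIF = 1 / (1 - R^2).  Exactly collinear columns report +inf with a
    warning.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 predictor columns")
    if columns is None:
        columns = (list(design.columns) if hasattr(design, "columns")
                   else [f"x{j}" for j in range(X.shape[1])])
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant predictor column")
    out = {}
    n, p = X.shape
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {columns[j]!r} is exactly collinear")
            out[columns[j]] = float("inf")
        else:
            out[columns[j]] = 1.0 / (1.0 - r2)
    return out


def collinearity_report(design) -> CollinearityReport:
    """VIFs for all columns plus phi coefficients for binary column pairs."""
    cols = list(design.columns)
    vifs = vif(design, columns=cols)
    phis = {}
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            xi = design[cols[i]].to_numpy()
            xj = design[cols[j]].to_numpy()
            if set(np.unique(xi)) <= {0, 1} and set(np.unique(xj)) <= {0, 1}:
                phis[(cols[i], cols[j])] = phi_coefficient(contingency_2x2(xi, xj))
    return CollinearityReport(vif=vifs, phi=phis)
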