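"""Linear-quadratic (LQ) regression of clonogenic survival.

The LQ model regresses the log surviving fraction on dose with a
second-degree polynomial without intercept,

    ln SF = alpha * D + beta * D**2 + eps,    eps ~ N(0, sigma**2),

so the fitted curve is anchored at SF(0) = 1.  ``alpha`` (per Gy) and
``beta`` (per Gy^2) are both negative for decaying survival; their raw
quotient alpha/beta (in Gy) is the dose at which the linear and quadratic
contributions to log-kill are equal and is the traditional radiosensitivity
summary.

Fitting is ordinary least squares on the log scale; dose-0 rows (ln SF = 0,
fitted value 0) carry zero residual and leave the coefficients untouched
but are counted in the residual degrees of freedom by default, keeping
observation counts aligned with the non-linear module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .dataio import SurvivalDataset
from .errors import FitError, ValidationError


@dataclass(frozen=True)
class LQFit:
    """Per-cell-line LQ estimates and fit statistics (log scale)."""

    cell_line: str
    alpha: float            # per Gy
    beta: float             # per Gy^2
    se_alpha: float
    se_beta: float
    p_alpha: float
    p_beta: float
    ab_ratio: float         # alpha/beta, Gy
    r_squared: float        # uncentered (no-intercept) R^2
    r_squared_centered: float
    rss: float
    df: int
    sigma_hat: float
    cov_alpha_beta: float   # off-diagonal of the coefficient covariance

    def to_dict(self) -> dict:
        return {
            "cell_line": self.cell_line,
            "alpha": self.alpha,
            "beta": self.beta,
            "se_alpha": self.se_alpha,
            "se_beta": self.se_beta,
            "p_alpha": self.p_alpha,
            "p_beta": self.p_beta,
            "ab_ratio": self.ab_ratio,
            "r_squared": self.r_squared,
            "r_squared_centered": self.r_squared_centered,
            "rss": self.rss,
            "df": self.df,
            "sigma_hat": self.sigma_hat,
        }


def fit_lq(
    ds: SurvivalDataset, cell_line: str, include_dose0: bool = True
) -> LQFit:
    """Fit the no-intercept LQ model to one cell line.

    Parameters
    ----------
    ds:
        Survival dataset; all surviving fractions must be positive.
    cell_line:
        Label of the line to fit.
    include_dose0:
        Keep dose-0 rows (default).  They have zero residual and do not
        move the coefficients but enter the degrees of freedom and hence
        ``sigma_hat``.

    Returns
    -------
    LQFit
        Coefficients with t-tests on ``N - 2`` degrees of freedom, the
        alpha/beta ratio, uncentered and centered R^2, and the residual
        standard error on the log scale.
    """
    sub = ds.for_line(cell_line)
    if not include_dose0:
        sub = sub[sub["dose_gy"] > 0]
    x = sub["dose_gy"].to_numpy(float)
    sf = sub["sf"].to_numpy(float)
    if np.any(sf <= 0):
        raise ValidationError(
            f"cell line {cell_line!r} has non-positive surviving fractions; "
            "log transform undefined"
        )
    nonzero = np.unique(x[x > 0])
    if len(nonzero) < 2:
        raise FitError(
            f"cell line {cell_line!r}: need >= 2 distinct nonzero doses, "
            f"got {len(nonzero)} (design is rank deficient)"
        )
    if len(x) < 3:
        raise FitError(
            f"cell line {cell_line!r}: need >= 3 observations, got {len(x)}"
        )
    y = np.log(sf)
    X = np.column_stack([x, x**2])
    res = sm.OLS(y, X).fit()
    alpha, beta = res.params
    rss = float(res.ssr)
    df = int(res.df_resid)
    tss_c = float(np.sum((y - y.mean()) ** 2))
    r2_centered = 1.0 - rss / tss_c if tss_c > 0 else float("nan")
    return LQFit(
        cell_line=cell_line,
        alpha=float(alpha),
        beta=float(beta),
        se_alpha=float(res.bse[0]),
        se_beta=float(res.bse[1]),
        p_alpha=float(res.pvalues[0]),
        p_beta=float(res.pvalues[1]),
        ab_ratio=float(alpha / beta) if beta != 0 else float("inf"),
        r_squared=float(res.rsquared),  # uncentered for the no-intercept model
        r_squared_centered=r2_centered,
        rss=rss,
        df=df,
        sigma_hat=math.sqrt(rss / df) if df > 0 else float("nan"),
        cov_alpha_beta=float(res.cov_params()[0, 1]),
    )


def fit_lq_all(ds: SurvivalDataset, include_dose0: bool = True) -> list[LQFit]:
    """Fit every cell line of the dataset; order follows the panel."""
    return [fit_lq(ds, line, include_dose0) for line in ds.cell_lines]


def alpha_beta_ratio(fit: LQFit, beta_tol: float = 1e-12) -> tuple[float, float]:
    """alpha/beta ratio (Gy) with its delta-method standard error.

    The first-order (delta-method) variance of the quotient g = a/b is

        var(g) = (1/b)^2 var(a) + (a/b^2)^2 var(b) - 2 (a/b^3) cov(a, b).

    When |beta| falls below ``beta_tol`` the ratio is numerically
    unstable and the standard error is reported as infinite.
    """
    if fit.beta == 0:
        raise ValidationError("beta is exactly zero; ratio undefined")
    ratio = fit.alpha / fit.beta
    if abs(fit.beta) < beta_tol:
        return ratio, float("inf")
    a, b = fit.alpha, fit.beta
    var = (
        (1.0 / b) ** 2 * fit.se_alpha**2
        + (a / b**2) ** 2 * fit.se_beta**2
        - 2.0 * (a / b**3) * fit.cov_alpha_beta
    )
    se = math.sqrt(var) if var >= 0 else float("nan")
    return ratio, se


def predict_lq(fit: LQFit, dose) -> np.ndarray | float:
    """Surviving fraction exp(alpha*D + beta*D^2); equals 1 at dose 0."""
    d = np.asarray(dose, dtype=float)
    out = np.exp(fit.alpha * d + fit.beta * d**2)
    return float(out) if out.ndim == 0 else out


def pooled_lq_sigma(fits: Iterable[LQFit] | Sequence[LQFit]) -> float:
    """Residual standard error pooled across cell lines,
    sqrt(sum RSS / sum df)."""
    fits = list(fits)
    if not fits:
        raise ValidationError("need at least one fit to pool")
    rss = sum(f.rss for f in fits)
    df = sum(f.df for f in fits)
    if df <= 0:
        raise ValidationError("pooled degrees of freedom must be positive")
    return math.sqrt(rss / df)
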