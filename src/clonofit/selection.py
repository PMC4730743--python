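"""AIC-based model selection and lack-of-fit testing.

The nested log-logistic family members are compared by the Akaike
information criterion

    AIC = 2 (p + 1) - 2 ln L,

where p is the total number of mean-function parameters across the panel
and the +1 counts the shared error variance; the preferred model has the
minimal AIC.  The chosen model is additionally tested against the
saturated cell-means (ANOVA) model — one free mean per (cell line, dose)
cell, in which any of the parametric fits is nested — by the standard
lack-of-fit F-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import SurvivalDataset
from .errors import FitError, ValidationError
from .loglogistic import (
    LLFamilyFit,
    LLModelSpec,
    fit_family,
    get_spec,
    mean_function,
)
from .lq import LQFit


def aic(loglik: float, n_params_incl_variance: int) -> float:
    """Akaike information criterion, ``2*k - 2*lnL`` with ``k`` counting
    every estimated parameter including the error variance."""
    if n_params_incl_variance < 1:
        raise ValidationError("parameter count must be >= 1")
    return 2.0 * n_params_incl_variance - 2.0 * loglik


@dataclass(frozen=True)
class SelectionEntry:
    spec_name: str
    loglik: float
    n_params: int  # p_total + 1 (shared variance included)
    aic: float
    sigma_hat: float
    fit: LLFamilyFit
    error: str | None = None


@dataclass(frozen=True)
class SelectionReport:
    """AIC ranking of a set of family members.

    ``recommended`` equals ``best_by_aic`` unless the free-asymptote
    preference rule is active, in which case a three-parameter member
    (free lower asymptote) is recommended over a lower-AIC two-parameter
    one: a lower asymptote pinned at zero forbids any radioresistant
    subpopulation surviving arbitrary doses, which is a biological prior
    the data cannot assert.
    """

    entries: tuple[SelectionEntry, ...]  # sorted ascending by AIC
    best_by_aic: str
    recommended: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": e.spec_name,
                    "loglik": e.loglik,
                    "n_params": e.n_params,
                    "aic": e.aic,
                    "sigma_hat": e.sigma_hat,
                }
                for e in self.entries
            ]
        )


def select_models(
    ds: SurvivalDataset,
    specs: Sequence[LLModelSpec | str],
    prefer_free_asymptote: bool = False,
    include_dose0: bool = True,
    seed: int = 0,
) -> SelectionReport:
    """Fit each candidate spec and rank by AIC (ascending).

    Unfittable specs are dropped from the ranking.  With
    ``prefer_free_asymptote`` the recommendation moves to the best-ranked
    member whose lower asymptote is free (when any exists), even if a
    fixed-asymptote member has a lower AIC.
    """
    if len(specs) < 2:
        raise ValidationError("need at least two candidate models")
    entries = []
    for spec in specs:
        spec = get_spec(spec) if isinstance(spec, str) else spec
        try:
            fit = fit_family(ds, spec, include_dose0=include_dose0, seed=seed)
        except FitError as exc:
            entries.append(
                SelectionEntry(spec.name, math.nan, 0, math.inf, math.nan, None, str(exc))
            )
            continue
        entries.append(
            SelectionEntry(
                spec.name, fit.loglik, fit.p_total + 1, fit.aic, fit.sigma_hat, fit
            )
        )
    ranked = sorted(
        [e for e in entries if e.error is None], key=lambda e: (e.aic, e.spec_name)
    )
    if not ranked:
        raise FitError("no candidate model could be fitted")
    failed = tuple(e for e in entries if e.error is not None)
    best = ranked[0].spec_name
    recommended = best
    if prefer_free_asymptote:
        for e in ranked:
            if "phi1" in e.fit.spec.free:
                recommended = e.spec_name
                break
    return SelectionReport(
        entries=tuple(ranked) + failed, best_by_aic=best, recommended=recommended
    )


@dataclass(frozen=True)
class LackOfFitResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    rss_model: float
    rss_anova: float


def _anova_rss(ds: SurvivalDataset, include_dose0: bool = True) -> tuple[float, int]:
    """RSS and cell count of the saturated (cell line x dose) means model."""
    df = ds.data if include_dose0 else ds.data[ds.data["dose_gy"] > 0]
    grouped = df.groupby(["cell_line", "dose_gy"])["sf"]
    rss = float(((df["sf"] - grouped.transform("mean")) ** 2).sum())
    return rss, grouped.ngroups


def lack_of_fit_test(
    fit: LLFamilyFit, ds: SurvivalDataset, include_dose0: bool = True
) -> LackOfFitResult:
    """F-test of the parametric fit against the saturated ANOVA model.

    The full model places one free mean on every (cell line, dose) cell
    on the SF scale, so the parametric family is nested within it:

        F = [(RSS_sub - RSS_full) / (df_sub - df_full)] / (RSS_full / df_full),

    with the p-value from the upper tail of F(df_num, df_den).  A small
    p-value means the parametric mean function misses structure that the
    cell means capture.
    """
    rss_full, n_cells = _anova_rss(ds, include_dose0)
    n = fit.n_obs
    df_full = n - n_cells
    if df_full <= 0:
        raise ValidationError(
            "ANOVA residual df is zero (no replicated (line, dose) cell); "
            "lack-of-fit test undefined"
        )
    df_sub = n - fit.p_total
    df_num = df_sub - df_full
    if df_num <= 0:
        raise ValidationError("parametric model is not nested below the ANOVA model")
    num = max(fit.rss - rss_full, 0.0) / df_num
    den = rss_full / df_full
    f_stat = num / den
    p = float(stats.f.sf(f_stat, df_num, df_full))
    return LackOfFitResult(
        f_stat=float(f_stat),
        df_num=int(df_num),
        df_den=int(df_full),
        p_value=p,
        rss_model=fit.rss,
        rss_anova=rss_full,
    )


def residual_summary(fit, ds: SurvivalDataset, include_dose0: bool = True) -> tuple[pd.DataFrame, float]:
    """Residual table and overall residual standard error.

    ``fit`` is either an :class:`LLFamilyFit` (residuals on the SF scale)
    or a collection of :class:`LQFit` (residuals on the log scale).
    Returns ``(table, sigma_hat)`` where the table has columns
    ``cell_line, dose_gy, observed, fitted, residual``.
    """
    rows = []
    if isinstance(fit, LLFamilyFit):
        fmean = mean_function(fit.spec)
        for lf in fit.lines:
            sub = ds.for_line(lf.cell_line)
            if not include_dose0:
                sub = sub[sub["dose_gy"] > 0]
            dose = sub["dose_gy"].to_numpy(float)
            obs = sub["sf"].to_numpy(float)
            pred = np.atleast_1d(fmean(dose, lf.params))
            for d, o, f in zip(dose, obs, pred):
                rows.append((lf.cell_line, d, o, f, o - f))
        df_resid = fit.n_obs - fit.p_total
    else:
        fits: Iterable[LQFit] = fit
        df_resid = 0
        for lf in fits:
            sub = ds.for_line(lf.cell_line)
            if not include_dose0:
                sub = sub[sub["dose_gy"] > 0]
            dose = sub["dose_gy"].to_numpy(float)
            obs = np.log(sub["sf"].to_numpy(float))
            pred = lf.alpha * dose + lf.beta * dose**2
            for d, o, f in zip(dose, obs, pred):
                rows.append((lf.cell_line, d, o, f, o - f))
            df_resid += lf.df
    table = pd.DataFrame(
        rows, columns=["cell_line", "dose_gy", "observed", "fitted", "residual"]
    )
    rss = float((table["residual"] ** 2).sum())
    sigma = math.sqrt(rss / df_resid) if df_resid > 0 else float("nan")
    return table, sigma
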