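"""Constrained log-logistic dose-response regression.

Survival is modelled on the raw surviving-fraction scale,

    SF = f(D; phi) + eps,    eps ~ N(0, sigma**2),

with the log-logistic mean function

    f(D) = phi1 + (1 - phi1) / (1 + exp{phi3 [ln D - ln phi2]})**phi4,

which equals 1 at D = 0 Gy by continuity.  ``phi1`` is the lower
asymptote (surviving fraction at infinite dose), ``phi2`` the dose at the
curve's relative midpoint in Gy (the median effective dose ED50 when
phi1 = 0 and phi4 = 1), ``phi3`` a dimensionless slope factor on the
log-dose axis, and ``phi4`` an asymmetry parameter (1 = symmetric on the
log-dose scale).

A nested family is obtained by fixing parameters in the order
phi4 = 1 (ll3), additionally phi1 = 0 (ll2), additionally phi3 = 1 (ll1);
a three-parameter Weibull mean (decreasing extreme-value curve on
log dose) serves as a comparator with the same bookkeeping.

``fit_family`` fits one family member jointly across all cell lines:
every line gets its own mean-function parameters (their least-squares
problems are separable and are solved per line), while the Gaussian
likelihood uses a single error variance shared by the whole panel, so a
panel of n lines with q free parameters each has p = n*q mean parameters
and p + 1 estimated parameters in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .dataio import SurvivalDataset
from .errors import FitError, ValidationError

_PARAM_NAMES = ("phi1", "phi2", "phi3", "phi4")


@dataclass(frozen=True)
class LLParams:
    """Parameters of the (log-logistic or Weibull) mean function."""

    phi1: float  # lower asymptote, 0 <= phi1 < 1
    phi2: float  # midpoint dose, Gy, > 0
    phi3: float  # slope factor, > 0
    phi4: float = 1.0  # asymmetry, > 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi1 < 1.0):
            raise ValidationError(f"phi1 must be in [0, 1), got {self.phi1}")
        if not self.phi2 > 0:
            raise ValidationError(f"phi2 must be > 0, got {self.phi2}")
        if not self.phi3 > 0:
            raise ValidationError(f"phi3 must be > 0, got {self.phi3}")
        if not self.phi4 > 0:
            raise ValidationError(f"phi4 must be > 0, got {self.phi4}")

    def as_array(self) -> np.ndarray:
        return np.array([self.phi1, self.phi2, self.phi3, self.phi4])


@dataclass(frozen=True)
class LLModelSpec:
    """One member of the nested mean-function family.

    ``free`` lists the estimated parameters; the rest are fixed at
    phi4 = 1, phi1 = 0, phi3 = 1 following the nesting
    4p > 3p > 2p > 1p.
    """

    name: str
    mean_family: str  # "loglogistic" | "weibull"
    free: tuple[str, ...]

    @property
    def n_free(self) -> int:
        return len(self.free)

    def fixed_values(self) -> dict[str, float]:
        fixed = {"phi1": 0.0, "phi3": 1.0, "phi4": 1.0}
        return {k: v for k, v in fixed.items() if k not in self.free}

    def build_params(self, theta: np.ndarray) -> LLParams:
        """Assemble full LLParams from the free-parameter vector."""
        vals = self.fixed_values()
        vals.update(dict(zip(self.free, theta)))
        return LLParams(**vals)


#: the canonical nested family plus the Weibull comparator
MODEL_SPECS: dict[str, LLModelSpec] = {
    "ll4": LLModelSpec("ll4", "loglogistic", ("phi1", "phi2", "phi3", "phi4")),
    "ll3": LLModelSpec("ll3", "loglogistic", ("phi1", "phi2", "phi3")),
    "ll2": LLModelSpec("ll2", "loglogistic", ("phi2", "phi3")),
    "ll1": LLModelSpec("ll1", "loglogistic", ("phi2",)),
    "w3": LLModelSpec("w3", "weibull", ("phi1", "phi2", "phi3")),
}


def get_spec(name: str) -> LLModelSpec:
    try:
        return MODEL_SPECS[name]
    except KeyError:
        raise ValidationError(
            f"unknown model {name!r}; choose from {sorted(MODEL_SPECS)}"
        ) from None


def ll_mean(dose, p: LLParams) -> np.ndarray | float:
    """Log-logistic mean surviving fraction; f(0) = 1 by continuity."""
    d = np.asarray(dose, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.ones_like(d)
    pos = d > 0
    t = p.phi3 * (np.log(d[pos]) - math.log(p.phi2))
    # (1+e^t)^-phi4 via logaddexp: stable for extreme slopes/doses
    out[pos] = p.phi1 + (1.0 - p.phi1) * np.exp(-p.phi4 * np.logaddexp(0.0, t))
    return float(out[0]) if scalar else out


def weibull_mean(dose, p: LLParams) -> np.ndarray | float:
    """Weibull (decreasing extreme-value on log dose) mean; f(0) = 1."""
    d = np.asarray(dose, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.ones_like(d)
    pos = d > 0
    t = p.phi3 * (np.log(d[pos]) - math.log(p.phi2))
    z = np.exp(np.clip(t, None, 700.0))  # exp(-z) underflows to 0 anyway
    out[pos] = p.phi1 + (1.0 - p.phi1) * np.exp(-z)
    return float(out[0]) if scalar else out


def mean_function(spec: LLModelSpec):
    return weibull_mean if spec.mean_family == "weibull" else ll_mean


@dataclass(frozen=True)
class SelfStart:
    params: LLParams
    phi2_fallback_used: bool = False


def self_start(
    ds: SurvivalDataset, cell_line: str, spec: LLModelSpec
) -> SelfStart:
    """Data-driven starting values for one cell line.

    * phi1: just below the smallest observed SF, clipped to [0, 0.5];
    * phi2: the dose where the per-dose mean SF crosses 0.5, found by
      linear interpolation between the bracketing doses (fallback: the
      median nonzero dose when no crossing exists);
    * phi3: slope of logit(mean SF) regressed on ln(dose);
    * phi4: 1.
    """
    sub = ds.for_line(cell_line)
    means = sub[sub["dose_gy"] > 0].groupby("dose_gy")["sf"].mean()
    doses = means.index.to_numpy(float)
    msf = means.to_numpy(float)
    if len(doses) < 2:
        raise FitError(
            f"cell line {cell_line!r}: need >= 2 nonzero doses to self-start"
        )

    phi1 = float(np.clip(msf.min() - 0.01, 0.0, 0.5))

    # dose where survival drops through 0.5 (include the dose-0 anchor)
    grid = np.concatenate([[0.0], doses])
    vals = np.concatenate([[1.0], msf])
    fallback = False
    phi2 = None
    for a in range(len(grid) - 1):
        lo, hi = vals[a + 1], vals[a]
        if hi >= 0.5 >= lo:
            if hi == lo:
                phi2 = grid[a + 1]
            else:
                frac = (hi - 0.5) / (hi - lo)
                phi2 = grid[a] + frac * (grid[a + 1] - grid[a])
            break
    if phi2 is None or phi2 <= 0:
        phi2 = float(np.median(doses))
        fallback = True

    # logit-slope estimate of phi3: logit(1 - f) is linear in ln dose for
    # the reduced (phi1 = 0, phi4 = 1) member
    f = np.clip(msf, 1e-6, 1.0 - 1e-6)
    logit = np.log((1.0 - f) / f)
    slope = np.polyfit(np.log(doses), logit, 1)[0]
    phi3 = float(np.clip(slope, 0.1, 50.0))

    return SelfStart(
        LLParams(phi1=phi1, phi2=float(phi2), phi3=phi3, phi4=1.0),
        phi2_fallback_used=fallback,
    )


@dataclass(frozen=True)
class LineFit:
    """Per-line component of a family fit."""

    cell_line: str
    params: LLParams
    rss: float
    n_obs: int
    converged: bool
    phi2_fallback_used: bool
    se: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class LLFamilyFit:
    """Joint fit of one family member across all cell lines.

    The Gaussian log-likelihood is evaluated at the maximum-likelihood
    variance RSS/N of the pooled residuals, and the AIC counts the shared
    variance as one extra parameter: AIC = 2 (p_total + 1) - 2 ln L.
    """

    spec: LLModelSpec
    lines: tuple[LineFit, ...]
    rss: float
    n_obs: int
    p_total: int
    loglik: float
    aic: float
    sigma_hat: float

    @property
    def params(self) -> dict[str, LLParams]:
        return {lf.cell_line: lf.params for lf in self.lines}

    @property
    def converged(self) -> dict[str, bool]:
        return {lf.cell_line: lf.converged for lf in self.lines}

    def line(self, cell_line: str) -> LineFit:
        for lf in self.lines:
            if lf.cell_line == cell_line:
                return lf
        raise KeyError(f"unknown cell line {cell_line!r}")


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood at the ML variance RSS/N."""
    if rss <= 0:
        # exact interpolation: likelihood diverges; report a large finite value
        rss = np.finfo(float).tiny
    return -0.5 * n * (math.log(2.0 * math.pi) + math.log(rss / n) + 1.0)


_BOUNDS = {
    "phi1": (0.0, 1.0 - 1e-9),
    "phi2": (1e-9, np.inf),
    "phi3": (1e-9, np.inf),
    "phi4": (1e-9, np.inf),
}


def _fit_line(
    dose: np.ndarray,
    sf: np.ndarray,
    spec: LLModelSpec,
    start: LLParams,
    rng: np.random.Generator,
    max_restarts: int,
) -> tuple[np.ndarray, float, bool, optimize.OptimizeResult]:
    fmean = mean_function(spec)

    def resid(theta: np.ndarray) -> np.ndarray:
        return fmean(dose, spec.build_params(theta)) - sf

    lo = np.array([_BOUNDS[k][0] for k in spec.free])
    hi = np.array([_BOUNDS[k][1] for k in spec.free])
    x0 = np.array([getattr(start, k) for k in spec.free])
    x0 = np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, hi))

    best = None
    for attempt in range(max_restarts + 1):
        if attempt > 0:
            jitter = np.exp(rng.normal(0.0, 0.3, size=x0.shape))
            xj = np.clip(
                x0 * jitter, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, hi)
            )
            # phi1 starts at 0 for many lines; jitter additively there
            for i, name in enumerate(spec.free):
                if name == "phi1":
                    xj[i] = float(np.clip(abs(rng.normal(0.0, 0.05)), 0.0, 0.5))
        else:
            xj = x0
        res = optimize.least_squares(
            resid,
            xj,
            bounds=(lo, hi),
            ftol=1e-10,
            xtol=1e-8,
            gtol=1e-12,
            max_nfev=500 * (len(x0) + 1),
        )
        rss = float(2.0 * res.cost)
        if best is None or rss < best[1] - 1e-15:
            best = (res.x, rss, bool(res.success), res)
        if res.success and attempt >= 1:
            break
        if res.success and attempt == 0:
            break
    return best


def fit_family(
    ds: SurvivalDataset,
    spec: LLModelSpec | str,
    include_dose0: bool = True,
    seed: int = 0,
    max_restarts: int = 20,
    wald: bool = True,
) -> LLFamilyFit:
    """Fit one family member jointly across all cell lines.

    Each line is fitted by bounded nonlinear least squares on the raw SF
    scale (its RSS contribution is separable); totals are pooled into a
    single Gaussian likelihood with one shared variance.  Starting values
    come from :func:`self_start` with up to ``max_restarts`` jittered
    restarts on failure (jitter stream seeded by ``seed``).

    Wald standard errors and two-sided p-values for the per-line
    parameters use the shared variance estimate RSS/(N - p_total) and the
    per-line Jacobian at the solution.
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    rng = np.random.default_rng(seed)

    line_sols = []
    n_total = 0
    rss_total = 0.0
    for line in ds.cell_lines:
        sub = ds.for_line(line)
        if not include_dose0:
            sub = sub[sub["dose_gy"] > 0]
        dose = sub["dose_gy"].to_numpy(float)
        sf = sub["sf"].to_numpy(float)
        if len(dose) < spec.n_free:
            raise FitError(
                f"cell line {line!r}: {len(dose)} observations cannot support "
                f"{spec.n_free} free parameters"
            )
        start = self_start(ds, line, spec)
        theta, rss, ok, res = _fit_line(dose, sf, spec, start.params, rng, max_restarts)
        line_sols.append((line, theta, rss, ok, start.phi2_fallback_used, res, len(dose)))
        n_total += len(dose)
        rss_total += rss

    p_total = spec.n_free * ds.n_lines
    loglik = gaussian_loglik(rss_total, n_total)
    aic = 2.0 * (p_total + 1) - 2.0 * loglik
    df = n_total - p_total
    sigma_hat = math.sqrt(rss_total / df) if df > 0 else float("nan")

    lines = []
    for line, theta, rss, ok, fb, res, n_line in line_sols:
        se: dict[str, float] = {}
        pv: dict[str, float] = {}
        if wald and df > 0:
            J = res.jac
            try:
                cov = sigma_hat**2 * np.linalg.inv(J.T @ J)
                ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
                for i, name in enumerate(spec.free):
                    se[name] = float(ses[i])
                    t = theta[i] / ses[i] if ses[i] > 0 else np.inf
                    pv[name] = float(2.0 * stats.t.sf(abs(t), df))
            except np.linalg.LinAlgError:
                pass
        lines.append(
            LineFit(
                cell_line=line,
                params=spec.build_params(theta),
                rss=rss,
                n_obs=n_line,
                converged=ok,
                phi2_fallback_used=fb,
                se=se,
                p_values=pv,
            )
        )
    return LLFamilyFit(
        spec=spec,
        lines=tuple(lines),
        rss=rss_total,
        n_obs=n_total,
        p_total=p_total,
        loglik=loglik,
        aic=aic,
        sigma_hat=sigma_hat,
    )


def effective_dose(p: LLParams, level: float = 0.5) -> float:
    """Dose (Gy) at which the log-logistic curve reaches a given SF level.

    Closed-form inversion of the mean function:

        ED = phi2 * [ ((1 - phi1)/(level - phi1))**(1/phi4) - 1 ]**(1/phi3).

    ``level`` must lie strictly between phi1 (the asymptote, unreachable)
    and 1.  For phi1 = 0, phi4 = 1, level 0.5 this returns phi2 exactly.
    """
    if not (p.phi1 < level < 1.0):
        raise ValidationError(
            f"level must be strictly between phi1={p.phi1} and 1, got {level}"
        )
    inner = ((1.0 - p.phi1) / (level - p.phi1)) ** (1.0 / p.phi4) - 1.0
    return float(p.phi2 * inner ** (1.0 / p.phi3))
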