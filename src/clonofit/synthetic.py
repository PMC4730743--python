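"""Synthetic clonogenic-survival panels for testing and calibration.

The generator reproduces the statistical structure of a multi-line
colony-formation study: a handful of cell lines measured at a common
dose grid (default 0, 1, 2, 4, 6, 8, 10 Gy) in 3-4 independent
replicates, with survival decaying according to a known truth curve.

Two truth families are supported, matching the two regression
frameworks:

* ``lq`` truth adds Gaussian noise on the log scale,
  SF = exp(alpha*D + beta*D^2 + eps);
* ``loglogistic`` truth adds Gaussian noise on the raw SF scale,
  SF = f(D; phi) + eps, resampled when a draw would be non-positive
  (surviving fractions must stay > 0 for downstream log and percent
  operations; at realistic noise levels the truncation is rare except at
  the highest doses).

Dose-0 records are pinned to SF = 1 exactly, mirroring per-replicate
plating-efficiency normalization.  The default noise scale 0.075 is of
the order of the residual scatter a well-behaved panel shows on the SF
scale.  ``paper_like_panel`` builds a 9-line panel with a 3-line
sensitive group (ED50 1.0-1.5 Gy) and a 6-line resistant group (ED50
2.3-2.8 Gy), the configuration used throughout the test-suite
simulations.

An optional count mode emits raw colony counts: for each record the
colony count is drawn as Poisson(n_seeded * PE * mean SF) and the dose-0
control defines the replicate's plating efficiency, exercising the
normalization path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import (
    COUNT_COLUMNS,
    SF_COLUMNS,
    SurvivalDataset,
    normalize_counts,
)
from .errors import ValidationError
from .loglogistic import LLParams, ll_mean

DEFAULT_DOSES = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class LineTruth:
    """Generating model for one cell line."""

    kind: Literal["lq", "loglogistic"]
    group: Literal["resistant", "sensitive"] = "resistant"
    alpha: float | None = None  # lq: per Gy (negative)
    beta: float | None = None  # lq: per Gy^2 (negative)
    params: LLParams | None = None  # loglogistic truth

    def __post_init__(self) -> None:
        if self.kind == "lq":
            if self.alpha is None or self.beta is None:
                raise ValidationError("lq truth needs alpha and beta")
        elif self.kind == "loglogistic":
            if self.params is None:
                raise ValidationError("loglogistic truth needs LLParams")
        else:
            raise ValidationError(f"unknown truth kind {self.kind!r}")

    def mean_sf(self, dose) -> np.ndarray:
        d = np.atleast_1d(np.asarray(dose, dtype=float))
        if self.kind == "lq":
            return np.exp(self.alpha * d + self.beta * d**2)
        return np.atleast_1d(ll_mean(d, self.params))


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated panel.

    ``replicates`` is either a single count for every line or a per-line
    mapping.  ``noise_scale`` is the error SD on the log scale for lq
    truths and on the SF scale for log-logistic truths.  ``count_mode``
    switches on Poisson colony-count simulation with ``n_seeded`` cells
    per well and plating efficiency ``plating_efficiency``.
    """

    truths: Mapping[str, LineTruth]
    doses: Sequence[float] = DEFAULT_DOSES
    replicates: int | Mapping[str, int] = 3
    noise_scale: float = 0.075
    seed: int = 0
    count_mode: Literal["off", "poisson"] = "off"
    n_seeded: int = 500
    plating_efficiency: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be >= 0")
        if 0.0 not in [float(d) for d in self.doses]:
            raise ValidationError("dose grid must include 0 Gy")
        if not self.truths:
            raise ValidationError("need at least one cell line truth")

    def reps_for(self, line: str) -> int:
        if isinstance(self.replicates, Mapping):
            return int(self.replicates[line])
        return int(self.replicates)

    @property
    def groups(self) -> dict[str, str]:
        return {line: t.group for line, t in self.truths.items()}


def _draw_sf(mean: float, sigma: float, kind: str, rng: np.random.Generator) -> float:
    if sigma == 0:
        return float(mean)
    if kind == "lq":
        return float(mean * np.exp(rng.normal(0.0, sigma)))
    # SF-scale noise, resampled to keep SF strictly positive
    for _ in range(1000):
        sf = mean + rng.normal(0.0, sigma)
        if sf > 0:
            return float(sf)
    raise ValidationError(
        "could not draw a positive surviving fraction; noise_scale too large "
        "relative to the mean"
    )


def simulate_panel(cfg: SimConfig) -> SurvivalDataset:
    """Draw one panel; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for line, truth in cfg.truths.items():
        means = truth.mean_sf(list(cfg.doses))
        for rep in range(1, cfg.reps_for(line) + 1):
            for dose, mean in zip(cfg.doses, means):
                if float(dose) == 0.0:
                    sf = 1.0  # normalization convention
                else:
                    sf = _draw_sf(mean, cfg.noise_scale, truth.kind, rng)
                records.append((line, f"R{rep}", float(dose), sf))
    return SurvivalDataset(pd.DataFrame(records, columns=list(SF_COLUMNS)))


def simulate_counts(cfg: SimConfig) -> pd.DataFrame:
    """Draw raw colony counts: Poisson(n_seeded * PE * mean SF)."""
    if cfg.count_mode != "poisson":
        raise ValidationError("simulate_counts requires count_mode='poisson'")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for line, truth in cfg.truths.items():
        means = truth.mean_sf(list(cfg.doses))
        for rep in range(1, cfg.reps_for(line) + 1):
            for dose, mean in zip(cfg.doses, means):
                lam = cfg.n_seeded * cfg.plating_efficiency * float(mean)
                n_col = int(rng.poisson(lam))
                if float(dose) == 0.0 and n_col == 0:
                    n_col = 1  # a usable control must have colonies
                rows.append((line, f"R{rep}", float(dose), cfg.n_seeded, n_col))
    return pd.DataFrame(rows, columns=list(COUNT_COLUMNS))


def paper_like_config(seed: int = 0, noise_scale: float = 0.075) -> SimConfig:
    """Study-design preset: 9 lines, 3 sensitive + 6 resistant.

    Sensitive lines get midpoint doses (ED50) drawn uniformly from
    1.0-1.5 Gy, resistant lines from 2.3-2.8 Gy; slope factors are
    uniform on 1.3-2.3 (sensitive) and 2.0-3.5 (resistant), all curves
    decaying to a zero asymptote.  Each line runs 3 or 4 replicates at
    doses 0-10 Gy with SF-scale noise (default SD 0.075).
    """
    rng = np.random.default_rng(seed)
    truths: dict[str, LineTruth] = {}
    for i in range(3):
        truths[f"SEN-{i + 1}"] = LineTruth(
            kind="loglogistic",
            group="sensitive",
            params=LLParams(
                phi1=0.0,
                phi2=float(rng.uniform(1.0, 1.5)),
                phi3=float(rng.uniform(1.3, 2.3)),
                phi4=1.0,
            ),
        )
    for i in range(6):
        truths[f"RES-{i + 1}"] = LineTruth(
            kind="loglogistic",
            group="resistant",
            params=LLParams(
                phi1=0.0,
                phi2=float(rng.uniform(2.3, 2.8)),
                phi3=float(rng.uniform(2.0, 3.5)),
                phi4=1.0,
            ),
        )
    replicates = {line: int(rng.integers(3, 5)) for line in truths}
    return SimConfig(
        truths=truths,
        doses=DEFAULT_DOSES,
        replicates=replicates,
        noise_scale=noise_scale,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def paper_like_panel(seed: int = 0) -> SurvivalDataset:
    """One draw of the 9-line two-group study-design panel."""
    return simulate_panel(paper_like_config(seed))
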