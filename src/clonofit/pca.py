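"""Correlation-matrix PCA of the survival panel and radioresistance scores.

The cell-line x dose matrix of mean surviving fractions is column-
standardized (mean 0, unit sample variance with denominator n-1), its
m x m correlation matrix C = Xs' Xs / (n-1) is eigendecomposed as
C = V L V', and each cell line receives component scores z_r = Xs v_r.
Because survival at the different doses is positively correlated, the
first component is a weighted average of survival over the whole dose
range: its score is a quantitative radioresistance index (high score =
high survival at every dose).  Components with eigenvalue > 1 are
retained (Kaiser's rule for standardized data), and loadings rescaled by
sqrt(lambda_r) are the component-variable correlations.

Eigenvector signs are fixed so each vector's entry sum is non-negative
(first nonzero entry positive on ties); with all-positive inter-dose
correlations this orients PC1 so that resistant lines score high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


def standardize(X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Column-standardize: mean 0, sample variance 1 (denominator n-1)."""
    X = pd.DataFrame(X)
    if X.shape[0] < 2:
        raise ValidationError("need at least two rows to standardize")
    sd = X.std(axis=0, ddof=1)
    dead = sd.index[sd == 0]
    if len(dead):
        raise ValidationError(
            f"constant column(s) {list(dead)} cannot be scaled to unit variance"
        )
    return (X - X.mean(axis=0)) / sd


def correlation_matrix(Xs: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Sample correlation matrix C = Xs' Xs / (n-1) of standardized data."""
    arr = np.asarray(Xs, dtype=float)
    n = arr.shape[0]
    return arr.T @ arr / (n - 1)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Orient each eigenvector so its entry sum is >= 0 (ties: first
    nonzero entry positive)."""
    V = V.copy()
    for r in range(V.shape[1]):
        s = V[:, r].sum()
        if abs(s) < 1e-12:
            nz = np.nonzero(np.abs(V[:, r]) > 1e-12)[0]
            s = V[nz[0], r] if len(nz) else 1.0
        if s < 0:
            V[:, r] = -V[:, r]
    return V


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # descending
    proportions: np.ndarray  # lambda_r / sum(lambda)
    loadings: np.ndarray = field(repr=False)  # orthonormal eigenvectors, columns
    rescaled_loadings: np.ndarray = field(repr=False)  # sqrt(lambda_r) * v_r
    retained: int  # Kaiser count (eigenvalues > 1)
    scores: pd.DataFrame | None = field(default=None, repr=False)  # lines x PCs
    columns: tuple = ()

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.proportions)


def kaiser_retained(eigenvalues) -> int:
    """Number of components with eigenvalue strictly greater than 1."""
    return int(np.sum(np.asarray(eigenvalues) > 1.0))


def eigen_pca(
    C: np.ndarray,
    Xs: pd.DataFrame | np.ndarray | None = None,
    columns=None,
) -> PCAResult:
    """Eigendecompose a correlation matrix; optionally attach scores.

    ``C`` must be symmetric (within 1e-8).  When the standardized data
    ``Xs`` is supplied, per-row component scores z_r = Xs v_r are
    computed; their sample variance equals lambda_r.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValidationError("correlation matrix must be symmetric")
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_signs(evecs[:, order])
    total = evals.sum()
    proportions = evals / total
    rescaled = evecs * np.sqrt(np.clip(evals, 0.0, None))
    scores = None
    if Xs is not None:
        Xs = pd.DataFrame(Xs)
        z = Xs.to_numpy(float) @ evecs
        scores = pd.DataFrame(
            z,
            index=Xs.index,
            columns=[f"PC{r + 1}" for r in range(z.shape[1])],
        )
    return PCAResult(
        eigenvalues=evals,
        proportions=proportions,
        loadings=evecs,
        rescaled_loadings=rescaled,
        retained=kaiser_retained(evals),
        scores=scores,
        columns=tuple(columns) if columns is not None else (),
    )


def panel_pca(X: pd.DataFrame) -> PCAResult:
    """Standardize a mean-SF matrix, then run correlation-matrix PCA
    with scores attached."""
    Xs = standardize(X)
    C = correlation_matrix(Xs)
    return eigen_pca(C, Xs=Xs, columns=X.columns)


def radioresistance_scores(pca: PCAResult) -> pd.Series:
    """First-PC score per cell line (higher = more radioresistant)."""
    if pca.scores is None:
        raise ValidationError("PCA was run without attached data; no scores")
    if pca.retained < 1:
        raise ValidationError("no component retained by Kaiser's rule")
    return pca.scores["PC1"]


@dataclass(frozen=True)
class ScoreCorrelation:
    pairs: tuple[tuple[str, float, float], ...]  # (name, Pearson r, two-sided p)

    def as_dict(self) -> dict:
        return {name: {"r": r, "p": p} for name, r, p in self.pairs}


def correlate_scores(scores: pd.Series, params: dict[str, pd.Series]) -> ScoreCorrelation:
    """Pearson correlation of the radioresistance score with fitted
    model parameters (e.g. the alpha/beta ratio, ED50 phi2, slope phi3).

    p-values are two-sided from the t transform with n-2 degrees of
    freedom; every parameter series must cover the same cell lines.
    """
    pairs = []
    for name, vals in params.items():
        vals = pd.Series(vals)
        if set(vals.index) != set(scores.index):
            raise ValidationError(
                f"parameter {name!r} does not cover the same cell lines as the scores"
            )
        v = vals.reindex(scores.index).to_numpy(float)
        z = scores.to_numpy(float)
        if len(z) < 3:
            raise ValidationError("need at least three cell lines to correlate")
        if np.std(v) == 0 or np.std(z) == 0:
            raise ValidationError(f"zero variance in {name!r} or scores")
        r, p = stats.pearsonr(z, v)
        pairs.append((name, float(r), float(p)))
    return ScoreCorrelation(pairs=tuple(pairs))
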