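"""Standardized PCA, multiple linear regression with variable impact, and
bivariate mean-confidence ellipses.

Conventions used throughout:

* Standardization is mean-centering plus scaling by the sample standard
  deviation (ddof = 1).  PCA operates on standardized data, i.e. it is the
  eigendecomposition of the correlation matrix; loadings are unit-norm
  eigenvectors, scores are ``standardized data @ loadings``.
* Eigenvector signs are arbitrary; each component is oriented so that its
  largest-magnitude loading is positive, which makes loading tables comparable
  across runs.
* MLR is ordinary least squares with intercept on *raw-scale* (unprocessed)
  data.  The relative impact of a predictor is
  ``I_v,j = |beta_j * sd_j| / sum_m |beta_m * sd_m|`` — the coefficient scaled
  by its predictor's spread, normalized to sum to one — which is unit-free and
  comparable across predictors of different units.
* Measured zeta potentials are negative (anionic latexes); multivariate runs
  use the sign-flipped -z so that all variables enter with positive values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "MLRResult",
    "Ellipse",
    "TrendSign",
    "standardize",
    "pca",
    "transform_zeta",
    "mlr_fit",
    "simple_fit",
    "mean_confidence_ellipse",
]


def transform_zeta(z):
    """Sign flip z -> -z used to feed zeta potentials into PCA/MLR."""
    return np.negative(z)


def standardize(
    table: pd.DataFrame, variables: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Mean-center and scale columns to unit sample sd (ddof=1).

    Rows with any missing value in ``variables`` are dropped (complete-case)
    and the count is logged.  Returns ``(standardized, means, sds)``.
    """
    variables = list(variables) if variables is not None else list(table.columns)
    sub = table[variables].astype(float)
    n0 = len(sub)
    sub = sub.dropna()
    if n0 - len(sub):
        logger.info("standardize: dropped %d incomplete rows of %d", n0 - len(sub), n0)
    if len(sub) < 2:
        raise ValueError(f"need >= 2 complete rows, have {len(sub)}")
    means = sub.mean()
    sds = sub.std(ddof=1)
    dead = sds.index[sds == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    return (sub - means) / sds, means, sds


@dataclass
class PCAResult:
    """PCA of standardized data.

    ``loadings`` is variables x components (unit-norm eigenvector columns of
    the correlation matrix, descending eigenvalue order); ``scores`` is
    samples x components; ``explained_fraction`` sums to 1 over all
    components.  Components beyond the data rank carry (numerically) zero
    variance and are listed in ``zero_variance_components``.
    """

    variable_names: list[str]
    loadings: np.ndarray
    scores: np.ndarray
    explained_fraction: np.ndarray
    centering_means: pd.Series
    scaling_sds: pd.Series
    eigenvalues: np.ndarray
    zero_variance_components: list[int] = field(default_factory=list)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.variable_names, columns=cols)

    def scores_frame(self, index=None) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=index, columns=cols)


def _orient_components(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| coefficient is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca(standardized: pd.DataFrame) -> PCAResult:
    """PCA via eigendecomposition of the correlation matrix.

    ``standardized`` must come from :func:`standardize` (each column mean 0,
    sd 1); the covariance of standardized data *is* the correlation matrix.
    """
    X = standardized.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need >= 2 rows")
    if n < p:
        logger.warning("pca: fewer rows (%d) than variables (%d)", n, p)
    corr = (X.T @ X) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _orient_components(eigvecs[:, order])
    total = eigvals.sum()
    explained = eigvals / total if total > 0 else np.zeros_like(eigvals)
    zero = [j for j, v in enumerate(eigvals) if v < 1e-10 * max(total, 1.0)]
    if zero:
        logger.info("pca: components %s carry ~zero variance (rank-deficient data)",
                    [f"PC{j + 1}" for j in zero])
    means = getattr(standardized, "attrs", {}).get("centering_means")
    return PCAResult(
        variable_names=list(standardized.columns),
        loadings=eigvecs,
        scores=X @ eigvecs,
        explained_fraction=explained,
        centering_means=pd.Series(0.0, index=standardized.columns)
        if means is None
        else means,
        scaling_sds=pd.Series(1.0, index=standardized.columns),
        eigenvalues=eigvals,
        zero_variance_components=zero,
    )


@dataclass
class MLRResult:
    """Ordinary least squares on raw-scale data with relative variable impact.

    ``impact`` maps each predictor to I_v in [0, 1]; the values sum to 1.
    ``rmspe`` is the in-sample root-mean-square residual in response units.
    """

    intercept: float
    coefficients: Mapping[str, float]
    rmspe: float
    impact: Mapping[str, float]
    r_squared: float
    n_used: int
    predictor_sds: Mapping[str, float]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        y = np.full(len(table), self.intercept)
        for name, beta in self.coefficients.items():
            y = y + beta * table[name].to_numpy(dtype=float)
        return y


def mlr_fit(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str,
    square: Sequence[str] = (),
    cond_threshold: float = 1e10,
) -> MLRResult:
    """OLS of ``response`` on ``predictors`` (unprocessed data, with intercept).

    ``square`` lists predictors to replace by their squares (renamed
    ``<name>^2``), e.g. Mn -> Mn^2 where the squared molecular weight is the
    physically motivated regressor.  Collinear designs (condition number above
    ``cond_threshold``) are an error.
    """
    predictors = list(predictors)
    work = table[predictors + [response]].astype(float).dropna()
    names = []
    for p in predictors:
        if p in square:
            work[f"{p}^2"] = work[p] ** 2
            names.append(f"{p}^2")
        else:
            names.append(p)
    if len(work) < len(names) + 2:
        raise ValueError(
            f"need >= {len(names) + 2} complete rows for {len(names)} predictors, "
            f"have {len(work)}"
        )
    X = sm.add_constant(work[names].to_numpy(dtype=float))
    cond = np.linalg.cond(X)
    if cond > cond_threshold:
        raise ValueError(
            f"collinear predictors: design matrix condition number {cond:.3g} "
            f"exceeds {cond_threshold:.3g}"
        )
    y = work[response].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    betas = dict(zip(names, fit.params[1:]))
    sds = {n: float(work[n].std(ddof=1)) for n in names}
    weights = {n: abs(betas[n]) * sds[n] for n in names}
    total = sum(weights.values())
    impact = {n: (w / total if total > 0 else 0.0) for n, w in weights.items()}
    return MLRResult(
        intercept=float(fit.params[0]),
        coefficients={n: float(b) for n, b in betas.items()},
        rmspe=float(np.sqrt(np.mean(fit.resid**2))),
        impact=impact,
        r_squared=float(fit.rsquared),
        n_used=len(work),
        predictor_sds=sds,
    )


def simple_fit(
    x: Sequence[float],
    y: Sequence[float],
    group_means: bool = False,
    groups: Sequence | None = None,
) -> dict[str, float]:
    """OLS line through (x, y); optionally on within-group means.

    With ``group_means`` set, ``groups`` keys each point (e.g. the nominal Sty
    feed), x and y are first averaged within each group, and the line is fit
    to the group means — the averaging cancels the complementary influence of
    other particle parameters.  Returns slope, intercept and R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if group_means:
        if groups is None:
            raise ValueError("group_means requires groups")
        df = pd.DataFrame({"g": list(groups), "x": x, "y": y}).dropna()
        agg = df.groupby("g", sort=True).mean()
        x, y = agg["x"].to_numpy(), agg["y"].to_numpy()
    else:
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 points (after grouping), have {len(x)}")
    res = scipy.stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "n": int(len(x)),
    }


class TrendSign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"


@dataclass
class Ellipse:
    """Confidence ellipse for a bivariate *mean* (Hotelling T^2, F-based).

    ``semi_axes`` are the (major, minor) half-lengths; ``angle_deg`` the
    orientation of the major axis from the x-axis, in (-90, 90].
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float
    level: float
    trend_sign: TrendSign

    def contains(self, point: tuple[float, float]) -> bool:
        t = math.radians(self.angle_deg)
        dx, dy = point[0] - self.center[0], point[1] - self.center[1]
        u = dx * math.cos(t) + dy * math.sin(t)
        v = -dx * math.sin(t) + dy * math.cos(t)
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def mean_confidence_ellipse(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
    trend_rho_min: float = 0.1,
) -> Ellipse:
    """Hotelling-T^2 confidence ellipse for the mean of (x, y).

    The ellipse is {m : n (m - xbar)' S^-1 (m - xbar) <= T^2_crit} with S the
    sample covariance and T^2_crit = p(n-1)/(n-p) * F_{p, n-p}(level), p = 2.
    ``trend_sign`` is the sign of the sample correlation, ``none`` when
    |rho| < ``trend_rho_min``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 points, have {n}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    S = np.cov(x, y, ddof=1)
    if S[0, 0] <= 0 or S[1, 1] <= 0:
        raise ValueError("degenerate covariance: a coordinate has zero variance")
    p = 2
    t2 = p * (n - 1) / (n - p) * scipy.stats.f.ppf(level, p, n - p)
    # covariance of the mean is S/n; axes from its eigendecomposition
    eigvals, eigvecs = np.linalg.eigh(S / n)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[1] < 0:
        eigvals[1] = 0.0
    semi = np.sqrt(eigvals * t2)
    angle = math.degrees(math.atan2(eigvecs[1, 0], eigvecs[0, 0]))
    if angle <= -90:
        angle += 180
    elif angle > 90:
        angle -= 180
    rho = float(np.corrcoef(x, y)[0, 1])
    if abs(rho) < trend_rho_min:
        trend = TrendSign.NONE
    else:
        trend = TrendSign.POSITIVE if rho > 0 else TrendSign.NEGATIVE
    return Ellipse(
        center=(float(np.mean(x)), float(np.mean(y))),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle_deg=angle,
        level=level,
        trend_sign=trend,
    )
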