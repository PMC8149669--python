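"""Latitudinal gradient models for proportion-valued beta metrics.

Beta-diversity metrics live in [0, 1], so latitudinal trends are fitted by
beta regression: a GLM with a beta-distributed response, logit mean link and
constant precision phi. Plots differing in elevation are placed on a common
thermal scale via the adjusted latitude

    adjusted_latitude = elevation / 111 + |latitude|

(100 m of elevation ~ 100 km poleward ~ 1/1.11 degree of latitude). Exact
zeros and ones are squeezed to 0.005 / 0.995 before fitting. Group
contrasts (e.g. explained-variation distributions of environment vs space)
use the two-sided Mann-Whitney U test with the rank-sum-based W statistic
(number of pairs with a > b, ties counted 1/2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit
from statsmodels.othermod.betareg import BetaModel

logger = logging.getLogger(__name__)


def adjusted_latitude(elevation, latitude):
    """Elevation-adjusted absolute latitude, degrees: elev/111 + |lat|."""
    return np.asarray(elevation, dtype=float) / 111.0 + np.abs(
        np.asarray(latitude, dtype=float)
    )


def squeeze_boundaries(y, lo: float = 0.005, hi: float = 0.995):
    """Map exact 0 -> 0.005 and exact 1 -> 0.995; all else unchanged."""
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or (y > 1).any():
        raise ValueError("proportions must lie in [0, 1]")
    out = y.copy()
    out[y == 0] = lo
    out[y == 1] = hi
    return out


@dataclass
class GradientFit:
    """Beta-regression fit of one metric against one covariate."""

    intercept: float
    slope: float
    precision: float
    pseudo_r2: float
    p_slope: float
    slope_se: float
    n: int
    x: np.ndarray
    fitted: np.ndarray      # fitted means, strictly inside (0, 1)
    band_low: np.ndarray    # delta-method 95% confidence band on the mean
    band_high: np.ndarray


class FitError(RuntimeError):
    """Beta regression failed to converge; diagnostics in the message."""


def beta_regression(y, x) -> GradientFit:
    """Maximum-likelihood beta regression of proportions ``y`` on ``x``.

    Mean submodel ``logit(mu) = b0 + b1 x`` with constant precision phi.
    The pseudo-R^2 is the squared Pearson correlation between logit(y) and
    the fitted linear predictor (the convention of the reference beta
    regression implementation); the slope p-value is a Wald z-test; the 95%
    confidence band on the mean is delta-method on the link scale.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-d arrays of equal length")
    if len(y) < 5:
        raise ValueError(f"need n >= 5 plots, have {len(y)}")
    if (y <= 0).any() or (y >= 1).any():
        raise ValueError("y must lie strictly in (0, 1); apply squeeze_boundaries first")

    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = BetaModel(y, X).fit(disp=False)
    if not np.isfinite(res.params).all():
        raise FitError(f"beta regression did not converge: params {res.params}")

    b0, b1, = res.params[0], res.params[1]
    eta = b0 + b1 * x
    lp_corr = np.corrcoef(logit(y), eta)[0, 1]
    pseudo_r2 = float(lp_corr**2) if np.isfinite(lp_corr) else 0.0

    # delta method on the link scale for the mean confidence band
    cov = res.cov_params()[:2, :2]
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    z = stats.norm.ppf(0.975)
    return GradientFit(
        intercept=float(b0),
        slope=float(b1),
        precision=float(np.exp(res.params[-1])),  # precision is log-linked
        pseudo_r2=pseudo_r2,
        p_slope=float(res.pvalues[1]),
        slope_se=float(res.bse[1]),
        n=len(y),
        x=x,
        fitted=expit(eta),
        band_low=expit(eta - z * se_eta),
        band_high=expit(eta + z * se_eta),
    )


def mann_whitney_u(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; W counts pairs with a > b (ties 1/2).

    Exact null enumeration when n_a + n_b <= 20 and there are no ties,
    otherwise the normal approximation with tie correction — matching the
    common rank-test implementations. All values tied across both samples
    gives p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        logger.warning("all values tied across both samples; p = 1")
        return (len(a) * len(b) / 2.0, 1.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(a) + len(b) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return (float(res.statistic), float(res.pvalue))
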