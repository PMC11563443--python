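"""Weighted fractional ranks and concentration indices.

The concentration index (C) measures socioeconomic inequality in a health
variable h as twice the weighted covariance between h and the fractional
rank r of each person in the living-standards (wealth) distribution, divided
by the mean of h.  C > 0 is pro-rich (h concentrated among the wealthy),
C < 0 pro-poor.

Two estimators are provided:

* :func:`cindex_direct` — the covariance identity, C = 2 cov_w(h, r) / mu_h.
* :func:`cindex_regression` — the "convenient regression": the slope of a
  weighted least-squares fit of the transformed outcome
  2 sigma_r^2 h_i / mu_h on the fractional rank r_i equals C.  This route
  also yields a heteroskedasticity-robust standard error for the slope
  (advisory; design-aware inference belongs to the bootstrap module).

Both agree to floating-point precision by construction; the regression form
is what applied work typically reports, the direct form serves as the oracle
in tests.

No normalisation (Wagstaff/Erreygers) is applied to C for binary outcomes:
the standard, unnormalised index is the quantity of interest here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm

__all__ = [
    "RankedDataset",
    "CIndexResult",
    "weighted_fractional_rank",
    "cindex_direct",
    "cindex_regression",
    "generalized_cindex",
]


@dataclass
class RankedDataset:
    """Fractional ranks of a sample in its wealth distribution.

    Attributes
    ----------
    ranks : ndarray
        Per-record fractional rank r_i in (0, 1); tied wealth scores share
        the tie group's cumulative-weight midpoint.  The weighted mean of
        the ranks is exactly 0.5.
    normalized_weights : ndarray
        Sampling weights rescaled to sum to one.
    rank_variance : float
        Weighted (population) variance of the ranks, sigma_r^2.
    """

    ranks: np.ndarray
    normalized_weights: np.ndarray
    rank_variance: float

    @property
    def n(self) -> int:
        return self.ranks.shape[0]


@dataclass
class CIndexResult:
    """A concentration index estimate with optional inference."""

    C: float
    mu_h: float
    estimator: str
    n: int
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    extra: dict = field(default_factory=dict, repr=False)


def _as_weights(weights: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have shape ({n},), got {w.shape}")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("sampling weights must be finite and strictly positive")
    return w / w.sum()


def weighted_fractional_rank(wealth_scores, weights) -> RankedDataset:
    """Cumulative-weight midpoint ranks on the wealth score.

    With weights normalised to sum to one and records ordered by wealth
    score, each tie group of equal scores receives the rank

        r = (cumulative weight of strictly poorer records) + w_group / 2,

    so all members of a tie group share one rank and the weighted mean of
    the ranks equals 0.5 exactly.

    Raises
    ------
    ValueError
        If any weight is nonpositive, fewer than two records are supplied,
        or all wealth scores are tied (ranks then carry no information).
    """
    s = np.asarray(wealth_scores, dtype=float)
    if s.ndim != 1 or s.shape[0] < 2:
        raise ValueError("need a 1-d array of at least two wealth scores")
    if not np.all(np.isfinite(s)):
        raise ValueError("wealth scores must be finite")
    wn = _as_weights(weights, s.shape[0])

    uniq, inverse = np.unique(s, return_inverse=True)
    if uniq.shape[0] < 2:
        raise ValueError("all wealth scores are tied; fractional ranks undefined")
    group_w = np.bincount(inverse, weights=wn, minlength=uniq.shape[0])
    group_rank = np.cumsum(group_w) - group_w / 2.0
    ranks = group_rank[inverse]

    rbar = float(wn @ ranks)  # == 0.5 up to rounding
    var_r = float(wn @ (ranks - rbar) ** 2)
    return RankedDataset(ranks=ranks, normalized_weights=wn, rank_variance=var_r)


def _check_h(h, ranked: RankedDataset) -> np.ndarray:
    hv = np.asarray(h, dtype=float)
    if hv.shape != ranked.ranks.shape:
        raise ValueError("h must align with the ranked dataset")
    if not np.all(np.isfinite(hv)):
        raise ValueError("h contains missing or non-finite values")
    return hv


def cindex_direct(h, ranked: RankedDataset) -> CIndexResult:
    """Concentration index by the covariance identity.

    C = (2 / mu_h) * sum_i w~_i (h_i - mu_h)(r_i - 0.5), with w~ the
    normalised weights.  No standard error is attached.
    """
    hv = _check_h(h, ranked)
    wn = ranked.normalized_weights
    mu = float(wn @ hv)
    if mu == 0.0:
        raise ValueError("concentration index undefined for all-zero outcome")
    C = 2.0 * float(wn @ ((hv - mu) * (ranked.ranks - 0.5))) / mu
    return CIndexResult(C=C, mu_h=mu, estimator="direct", n=ranked.n)


def cindex_regression(h, ranked: RankedDataset) -> CIndexResult:
    """Concentration index via the convenient regression.

    Weighted least squares of (2 sigma_r^2 / mu_h) h_i on an intercept and
    the fractional rank r_i, using the sampling weights; the slope is C and
    its HC1 (sandwich) standard error is returned as an advisory measure of
    precision.  Identical to :func:`cindex_direct` up to floating point.
    """
    hv = _check_h(h, ranked)
    wn = ranked.normalized_weights
    mu = float(wn @ hv)
    if mu == 0.0:
        raise ValueError("concentration index undefined for all-zero outcome")
    if ranked.rank_variance <= 0.0:
        raise ValueError("rank variance is zero; regression undefined")

    y = 2.0 * ranked.rank_variance * hv / mu
    X = sm.add_constant(ranked.ranks)
    fit = sm.WLS(y, X, weights=wn).fit(cov_type="HC1")
    C = float(fit.params[1])
    se = float(fit.bse[1])
    ci = fit.conf_int()
    return CIndexResult(
        C=C,
        mu_h=mu,
        estimator="regression",
        n=ranked.n,
        se=se,
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
    )


def generalized_cindex(x, ranked: RankedDataset) -> float:
    """Generalised concentration index GC = 2 sum_i w~_i (x_i - xbar)(r_i - 0.5).

    The covariance form without division by the mean, so it is defined for
    zero-mean variables such as regression residuals.
    """
    xv = _check_h(x, ranked)
    wn = ranked.normalized_weights
    xbar = float(wn @ xv)
    return 2.0 * float(wn @ ((xv - xbar) * (ranked.ranks - 0.5)))
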