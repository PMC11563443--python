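"""Wagstaff decomposition of the concentration index.

Given a linear probability model h_i = alpha + sum_k beta_k x_ki + eps_i,
the concentration index of h decomposes exactly as

    C = sum_k eta_k * C_k  +  GC_eps / mu_h,

where eta_k = beta_k * xbar_k / mu_h is the elasticity of h with respect to
factor k at the weighted means, C_k is the concentration index of the factor
itself, and the residual term is the inequality the factors cannot
systematically explain (GC_eps is the generalised concentration index of
the regression residuals).

The residual is computed as the remainder C - sum_k eta_k C_k so additivity
holds exactly under floating point; its agreement with GC_eps / mu_h is an
identity verified in the test suite, not the computation path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rank_cindex import RankedDataset, cindex_direct, generalized_cindex
from .survey_data import DesignMatrix

__all__ = [
    "LPMFit",
    "DecompositionResult",
    "fit_lpm",
    "decompose",
    "group_contributions",
    "percent_contributions",
]

# |C| below this is treated as too small for stable percent shares.
DEFAULT_INSTABILITY_FLOOR = 1e-4


@dataclass
class LPMFit:
    """A weighted least-squares fit of the linear probability model."""

    alpha: float
    betas: pd.Series
    residuals: np.ndarray
    weighted_means: pd.Series
    fitted: np.ndarray


@dataclass
class DecompositionResult:
    """Per-factor contributions to the concentration index.

    ``table`` has one row per design column (or per group after grouping)
    with columns: beta, mean, elasticity, factor_index, contribution and —
    after :func:`percent_contributions` — percent.  Contributions plus the
    residual sum to ``total_C`` exactly.
    """

    table: pd.DataFrame
    residual_contribution: float
    total_C: float
    mu_h: float
    n: int
    residual_percent: Optional[float] = None
    unstable: bool = False
    group_map: dict[str, list[str]] = field(default_factory=dict, repr=False)
    grouped: bool = False

    @property
    def contributions(self) -> pd.Series:
        return self.table["contribution"]

    def write(self, path) -> None:
        out = self.table.copy()
        resid = {c: np.nan for c in out.columns}
        resid["contribution"] = self.residual_contribution
        if "percent" in out.columns:
            resid["percent"] = self.residual_percent
        out.loc["residual"] = pd.Series(resid)
        out.to_csv(path, index_label="factor")


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # flag columns whose QR pivot is (numerically) dependent on earlier ones
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[i - 1] for i in range(1, len(diag)) if diag[i] <= tol]


def fit_lpm(h, design: DesignMatrix, weights) -> LPMFit:
    """Weighted least squares of the binary outcome on the design columns.

    Coefficients are probability differences per unit of each column; the
    fit includes an intercept, so weighted residuals average zero exactly.
    """
    hv = np.asarray(h, dtype=float)
    X = design.values.to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wn = w / w.sum()

    Xc = sm.add_constant(X, has_constant="raise")
    sq = np.sqrt(wn)[:, None]
    if np.linalg.matrix_rank(Xc * sq) < Xc.shape[1]:
        bad = _collinear_columns(Xc * sq, design.column_names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    fit = sm.WLS(hv, Xc, weights=wn).fit()
    params = np.asarray(fit.params)
    fitted = Xc @ params
    means = pd.Series(wn @ X, index=design.column_names, name="mean")
    return LPMFit(
        alpha=float(params[0]),
        betas=pd.Series(params[1:], index=design.column_names, name="beta"),
        residuals=hv - fitted,
        weighted_means=means,
        fitted=fitted,
    )


def decompose(
    h,
    design: DesignMatrix,
    ranked: RankedDataset,
    weights=None,
    *,
    lpm: Optional[LPMFit] = None,
) -> DecompositionResult:
    """Decompose C(h) into per-factor elasticity x factor-index contributions.

    For each design column k: elasticity eta_k = beta_k * xbar_k / mu_h,
    factor index C_k = 2 cov_w(x_k, r) / xbar_k, contribution eta_k * C_k.
    A column with zero weighted mean has an undefined C_k; its contribution
    is set to 0 with a warning (its effect then lands in the residual).
    The residual is the exact remainder, equal to GC_eps / mu_h.
    """
    if weights is None:
        weights = ranked.normalized_weights
    if lpm is None:
        lpm = fit_lpm(h, design, weights)

    hv = np.asarray(h, dtype=float)
    wn = ranked.normalized_weights
    mu_h = float(wn @ hv)
    if mu_h == 0.0:
        raise ValueError("decomposition undefined for all-zero outcome")
    total_C = cindex_direct(hv, ranked).C

    rows = []
    for name in design.column_names:
        xk = design.values[name].to_numpy(dtype=float)
        beta = float(lpm.betas[name])
        xbar = float(lpm.weighted_means[name])
        scale = float(np.max(np.abs(xk))) or 1.0
        if abs(xbar) < 1e-12 * scale:  # zero-mean column: C_k undefined
            if beta != 0.0:
                warnings.warn(
                    f"column {name!r} has zero weighted mean; its contribution is set to 0",
                    stacklevel=2,
                )
            eta = 0.0
            ck = np.nan
            contrib = 0.0
        else:
            eta = beta * xbar / mu_h
            ck = generalized_cindex(xk, ranked) / xbar
            contrib = eta * ck
        rows.append((name, beta, xbar, eta, ck, contrib))

    table = pd.DataFrame(
        rows, columns=["factor", "beta", "mean", "elasticity", "factor_index", "contribution"]
    ).set_index("factor")
    residual = total_C - float(table["contribution"].sum())
    return DecompositionResult(
        table=table,
        residual_contribution=residual,
        total_C=total_C,
        mu_h=mu_h,
        n=ranked.n,
        group_map=dict(design.group_map),
    )


def group_contributions(
    result: DecompositionResult, group_map: Optional[dict[str, list[str]]] = None
) -> DecompositionResult:
    """Sum contributions within factor groups (e.g. all SES quintile dummies).

    Every design column must belong to exactly one group; the residual and
    total are unchanged, so additivity is preserved.
    """
    gm = group_map if group_map is not None else result.group_map
    if not gm:
        raise ValueError("no group map available")
    assigned = [c for cols in gm.values() for c in cols]
    missing = set(result.table.index) - set(assigned)
    if missing:
        raise ValueError(f"columns not assigned to any group: {sorted(missing)}")
    dupes = {c for c in assigned if assigned.count(c) > 1}
    if dupes:
        raise ValueError(f"columns assigned to multiple groups: {sorted(dupes)}")

    rows = {
        group: result.table.loc[cols, "contribution"].sum()
        for group, cols in gm.items()
        if cols
    }
    table = pd.DataFrame({"contribution": pd.Series(rows)})
    table.index.name = "factor"
    out = DecompositionResult(
        table=table,
        residual_contribution=result.residual_contribution,
        total_C=result.total_C,
        mu_h=result.mu_h,
        n=result.n,
        group_map=gm,
        grouped=True,
    )
    if "percent" in result.table.columns:
        out = percent_contributions(out)
    return out


def percent_contributions(
    result: DecompositionResult, floor: float = DEFAULT_INSTABILITY_FLOOR
) -> DecompositionResult:
    """Express contributions as percent of total C (summing to 100 with the
    residual).  When |C| is below the instability floor the shares explode;
    they are still reported but flagged ``unstable``."""
    table = result.table.copy()
    table["percent"] = 100.0 * table["contribution"] / result.total_C
    return DecompositionResult(
        table=table,
        residual_contribution=result.residual_contribution,
        total_C=result.total_C,
        mu_h=result.mu_h,
        n=result.n,
        residual_percent=100.0 * result.residual_contribution / result.total_C,
        unstable=bool(abs(result.total_C) < floor),
        group_map=result.group_map,
        grouped=result.grouped,
    )
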