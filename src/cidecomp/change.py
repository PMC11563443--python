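"""Oaxaca-type decomposition of the change in the concentration index.

The change between two survey waves, Delta C = C_t - C_{t-1}, splits per
factor into an index-change term weighted by the current-period elasticity
and an elasticity-change term weighted by the base-period factor index:

    Delta C = sum_k eta_kt (C_kt - C_k,t-1)
            + sum_k C_k,t-1 (eta_kt - eta_k,t-1)
            + residual change,

with the residual change taken as the exact remainder (the change in the
unexplained component GC_eps / mu_h).  The weighting is asymmetric by
construction, so per-factor terms are not antisymmetric under swapping the
waves, though Delta C itself is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .decomposition import DEFAULT_INSTABILITY_FLOOR, DecompositionResult

__all__ = ["ChangeDecompositionResult", "change_decomposition", "change_percent_and_grouping"]


@dataclass
class ChangeDecompositionResult:
    """Per-factor contributions to Delta C between two waves.

    ``table`` rows carry eta and C_k for both waves, the two Oaxaca terms
    (term_dC, term_dEta), their sum ``total`` and, after percent reporting,
    ``percent`` relative to Delta C.  Totals plus residual_change equal
    delta_C exactly.
    """

    table: pd.DataFrame
    residual_change: float
    delta_C: float
    C_t: float
    C_t0: float
    residual_percent: Optional[float] = None
    unstable: bool = False
    group_map: dict[str, list[str]] = field(default_factory=dict, repr=False)
    grouped: bool = False

    def write(self, path) -> None:
        out = self.table.copy()
        resid = {c: np.nan for c in out.columns}
        resid["total"] = self.residual_change
        if "percent" in out.columns:
            resid["percent"] = self.residual_percent
        out.loc["residual"] = pd.Series(resid)
        out.to_csv(path, index_label="factor")


def change_decomposition(
    decomp_t: DecompositionResult,
    decomp_t0: DecompositionResult,
    *,
    reverse_weighting: bool = False,
) -> ChangeDecompositionResult:
    """Oaxaca-type split of Delta C = C_t - C_{t-1} into factor terms.

    Parameters
    ----------
    decomp_t, decomp_t0
        Ungrouped single-wave decompositions for the current (t) and base
        (t-1) periods, fitted with an identical design specification.
    reverse_weighting
        Use the alternative convention (base-period elasticities weight the
        index changes, current-period indices weight the elasticity
        changes).  The default follows the standard form: current-period
        elasticities weight Delta C_k, base-period indices weight Delta
        eta_k.

    Raises
    ------
    ValueError
        If the two waves' factor sets differ.
    """
    if decomp_t.grouped or decomp_t0.grouped:
        raise ValueError("change decomposition needs ungrouped per-column results")
    cols_t, cols_t0 = list(decomp_t.table.index), list(decomp_t0.table.index)
    if cols_t != cols_t0:
        diff = sorted(set(cols_t) ^ set(cols_t0))
        raise ValueError(f"factor sets differ between waves: {diff or 'same names, different order'}")

    eta_t = decomp_t.table["elasticity"]
    eta_t0 = decomp_t0.table["elasticity"]
    ck_t = decomp_t.table["factor_index"].fillna(0.0)
    ck_t0 = decomp_t0.table["factor_index"].fillna(0.0)

    if reverse_weighting:
        term_dC = eta_t0 * (ck_t - ck_t0)
        term_dEta = ck_t * (eta_t - eta_t0)
    else:
        term_dC = eta_t * (ck_t - ck_t0)
        term_dEta = ck_t0 * (eta_t - eta_t0)

    table = pd.DataFrame(
        {
            "eta_t": eta_t,
            "eta_t0": eta_t0,
            "C_k_t": ck_t,
            "C_k_t0": ck_t0,
            "term_dC": term_dC,
            "term_dEta": term_dEta,
            "total": term_dC + term_dEta,
        }
    )
    table.index.name = "factor"
    delta_C = decomp_t.total_C - decomp_t0.total_C
    residual = delta_C - float(table["total"].sum())
    return ChangeDecompositionResult(
        table=table,
        residual_change=residual,
        delta_C=delta_C,
        C_t=decomp_t.total_C,
        C_t0=decomp_t0.total_C,
        group_map=dict(decomp_t.group_map),
    )


def change_percent_and_grouping(
    result: ChangeDecompositionResult,
    group_map: Optional[dict[str, list[str]]] = None,
    floor: float = DEFAULT_INSTABILITY_FLOOR,
) -> ChangeDecompositionResult:
    """Group factor terms into blocks and express them as percent of Delta C.

    A positive percent means the factor pushed inequality in the pro-rich
    direction between the waves.  Percents (including the residual) sum to
    100; when |Delta C| is below the floor the result is flagged unstable.
    """
    gm = group_map if group_map is not None else result.group_map
    if gm:
        assigned = [c for cols in gm.values() for c in cols]
        missing = set(result.table.index) - set(assigned)
        if missing:
            raise ValueError(f"columns not assigned to any group: {sorted(missing)}")
        rows = {g: result.table.loc[cols, "total"].sum() for g, cols in gm.items() if cols}
        table = pd.DataFrame({"total": pd.Series(rows)})
        table.index.name = "factor"
        grouped = True
    else:
        table = result.table.copy()
        grouped = result.grouped

    table["percent"] = 100.0 * table["total"] / result.delta_C
    return ChangeDecompositionResult(
        table=table,
        residual_change=result.residual_change,
        delta_C=result.delta_C,
        C_t=result.C_t,
        C_t0=result.C_t0,
        residual_percent=100.0 * result.residual_change / result.delta_C,
        unstable=bool(abs(result.delta_C) < floor),
        group_map=gm,
        grouped=grouped,
    )
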