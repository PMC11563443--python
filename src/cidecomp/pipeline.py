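"""Convenience wrappers chaining the full estimation pipeline on one table.

These are thin glue over the module-level primitives so that a bootstrap
statistic, a script, or an interactive session can go from a survey
DataFrame to a concentration index or a full decomposition in one call.
Ranks (and hence quintiles, fits and decompositions) are always recomputed
from the data passed in — required inside bootstrap replicates.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .decomposition import DecompositionResult, decompose, percent_contributions
from .rank_cindex import CIndexResult, cindex_regression, weighted_fractional_rank
from .survey_data import FactorSpec, build_design_matrix

__all__ = ["wave_cindex", "wave_decomposition"]


def wave_cindex(df: pd.DataFrame, outcome: str) -> CIndexResult:
    """Concentration index of ``outcome`` in one survey wave (convenient
    regression, with advisory robust SE)."""
    ranked = weighted_fractional_rank(df["wealth_score"], df["weight"])
    return cindex_regression(df[outcome].to_numpy(dtype=float), ranked)


def wave_decomposition(
    df: pd.DataFrame,
    outcome: str,
    factor_spec: Sequence[FactorSpec],
    *,
    with_percent: bool = True,
    subpopulation: Optional[pd.Series] = None,
) -> DecompositionResult:
    """Rank, fit and decompose C(outcome) for one wave.

    ``subpopulation`` (a boolean mask, e.g. urban residence) restricts the
    analysis; fractional ranks are recomputed within the subpopulation.
    """
    if subpopulation is not None:
        df = df[subpopulation.to_numpy(dtype=bool)].reset_index(drop=True)
    ranked = weighted_fractional_rank(df["wealth_score"], df["weight"])
    design = build_design_matrix(df, factor_spec)
    result = decompose(df[outcome].to_numpy(dtype=float), design, ranked)
    return percent_contributions(result) if with_percent else result
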