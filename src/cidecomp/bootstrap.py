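"""Design-aware bootstrap inference for inequality statistics.

Standard errors for the concentration index, its decomposition components
and change-decomposition components come from a nonparametric bootstrap:
each replicate resamples the survey data and re-runs the *entire* pipeline
(fractional ranks, quintiles, model fit, decomposition), since the ranks
themselves are estimate-dependent.

Two resampling schemes:

* ``psu_within_stratum`` (default) — primary sampling units are resampled
  with replacement within each design stratum, respecting the complex
  survey design.
* ``record`` — simple case resampling, appropriate for simple random
  samples and for calibration studies against simulation truth.

Intervals are percentile intervals at 2.5/97.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["BootstrapResult", "bootstrap"]

Datasets = Union[pd.DataFrame, Sequence[pd.DataFrame]]


@dataclass
class BootstrapResult:
    """Point estimate plus B bootstrap re-estimates of a statistic.

    For a scalar statistic, ``estimate``/``se``/``ci_low``/``ci_high`` are
    floats and ``replicates`` a 1-d array; for a vector-valued statistic
    (a mapping or Series) they are Series aligned on the statistic's names
    and ``replicates`` a (B_ok, k) DataFrame.
    """

    name: str
    estimate: Union[float, pd.Series]
    replicates: Union[np.ndarray, pd.DataFrame]
    se: Union[float, pd.Series]
    ci_low: Union[float, pd.Series]
    ci_high: Union[float, pd.Series]
    B: int
    seed: Optional[int]
    failed_replicates: int = 0
    extra: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """One row per statistic: estimate, se, ci bounds, B, seed."""
        est = self.estimate if isinstance(self.estimate, pd.Series) else pd.Series(
            {self.name: self.estimate}
        )
        se = self.se if isinstance(self.se, pd.Series) else pd.Series({self.name: self.se})
        lo = self.ci_low if isinstance(self.ci_low, pd.Series) else pd.Series(
            {self.name: self.ci_low}
        )
        hi = self.ci_high if isinstance(self.ci_high, pd.Series) else pd.Series(
            {self.name: self.ci_high}
        )
        out = pd.DataFrame({"estimate": est, "se": se, "ci_low": lo, "ci_high": hi})
        out["B"] = self.B
        out["seed"] = self.seed
        out.index.name = "statistic"
        return out


def _psu_plan(df: pd.DataFrame) -> list[list[np.ndarray]]:
    """Row positions per PSU, grouped by stratum."""
    if "stratum" not in df.columns or "psu" not in df.columns:
        raise ValueError("design resampling needs 'stratum' and 'psu' columns")
    pos = np.arange(len(df))
    plan: list[list[np.ndarray]] = []
    for _, stratum_rows in pd.Series(pos).groupby(df["stratum"].to_numpy()):
        sub = stratum_rows.to_numpy()
        psus = df["psu"].to_numpy()[sub]
        plan.append([sub[psus == p] for p in pd.unique(psus)])
    return plan


def _resample_record(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    idx = rng.integers(0, len(df), len(df))
    return df.iloc[idx].reset_index(drop=True)


def _resample_design(
    df: pd.DataFrame, plan: list[list[np.ndarray]], rng: np.random.Generator
) -> pd.DataFrame:
    parts = []
    for stratum in plan:
        m = len(stratum)
        picks = rng.integers(0, m, m)
        parts.extend(stratum[p] for p in picks)
    return df.iloc[np.concatenate(parts)].reset_index(drop=True)


def bootstrap(
    data: Datasets,
    statistic: Callable[..., Union[float, Mapping[str, float], pd.Series]],
    *,
    B: int = 1000,
    seed: Optional[int] = None,
    resample_unit: str = "psu_within_stratum",
    name: str = "statistic",
    max_failure_rate: float = 0.05,
) -> BootstrapResult:
    """Bootstrap a statistic of one or several survey datasets.

    Parameters
    ----------
    data
        A DataFrame, or a sequence of DataFrames (e.g. two survey waves,
        resampled independently) passed to ``statistic`` positionally.
    statistic
        Callable evaluating the full estimation pipeline on (re)sampled
        data; may return a float or a name -> value mapping.
    B
        Number of bootstrap replicates (the conventional default is 1000).
    resample_unit
        ``psu_within_stratum`` or ``record``.
    max_failure_rate
        Replicates raising an exception (e.g. a rank-deficient design after
        resampling) are dropped and counted; exceeding this fraction of B
        is an error.

    The same seed always yields the identical result.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if resample_unit not in ("psu_within_stratum", "record"):
        raise ValueError(f"unknown resample_unit {resample_unit!r}")
    dfs = [data] if isinstance(data, pd.DataFrame) else list(data)
    if not dfs:
        raise ValueError("no datasets supplied")

    plans = [_psu_plan(df) if resample_unit == "psu_within_stratum" else None for df in dfs]
    rng = np.random.default_rng(seed)

    point = statistic(*dfs)
    vector = isinstance(point, (Mapping, pd.Series))
    point_s = pd.Series(dict(point) if isinstance(point, Mapping) else point, dtype=float) if vector else None

    rows = []
    failed = 0
    for _ in range(B):
        res = [
            _resample_record(df, rng) if plan is None else _resample_design(df, plan, rng)
            for df, plan in zip(dfs, plans)
        ]
        try:
            val = statistic(*res)
        except Exception:
            failed += 1
            continue
        rows.append(pd.Series(dict(val) if isinstance(val, Mapping) else val, dtype=float) if vector else float(val))

    if failed > max_failure_rate * B:
        raise ValueError(f"{failed}/{B} bootstrap replicates failed (> {max_failure_rate:.0%})")

    if vector:
        reps = pd.DataFrame(rows).reindex(columns=point_s.index)
        se = reps.std(ddof=1)
        lo = reps.quantile(0.025)
        hi = reps.quantile(0.975)
        return BootstrapResult(
            name=name, estimate=point_s, replicates=reps, se=se, ci_low=lo, ci_high=hi,
            B=B, seed=seed, failed_replicates=failed,
        )

    reps_a = np.asarray(rows, dtype=float)
    return BootstrapResult(
        name=name,
        estimate=float(point),
        replicates=reps_a,
        se=float(reps_a.std(ddof=1)),
        ci_low=float(np.quantile(reps_a, 0.025)),
        ci_high=float(np.quantile(reps_a, 0.975)),
        B=B,
        seed=seed,
        failed_replicates=failed,
    )
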