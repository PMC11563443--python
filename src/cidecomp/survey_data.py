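"""Ingest and prepare person-level survey data for inequality analysis.

This module turns a raw one-row-per-woman survey extract (DHS-style) into
the analytical dataset the estimators consume:

* :func:`load_survey_table` — read a delimited file under a column-name
  schema mapping, coercing numerics and logging parse failures.
* :func:`derive_outcomes` — BMI from height/weight where not supplied;
  overweight (BMI >= 25 kg/m^2) and obesity (BMI >= 30 kg/m^2) flags.
* :func:`apply_exclusions` — the cleaning flow: women of childbearing age
  (15-49 years), non-pregnant, nonmissing and plausible BMI, applied in a
  fixed order so exclusion counts are reproducible.
* :func:`build_design_matrix` — dummy-coded covariates with configurable
  reference levels and a factor -> columns map for grouped reporting.
* :func:`assign_wealth_quintiles` — weighted national wealth quintiles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "NUMERIC_FIELDS",
    "CORE_FIELDS",
    "LoadResult",
    "ExclusionRules",
    "AnalyticalDataset",
    "FactorSpec",
    "DesignMatrix",
    "QuintileAssignment",
    "DEFAULT_REFERENCES",
    "load_survey_table",
    "derive_outcomes",
    "apply_exclusions",
    "build_design_matrix",
    "assign_wealth_quintiles",
    "weighted_mean",
    "weighted_proportions",
]

# Canonical numeric fields coerced at load time.
NUMERIC_FIELDS = ("weight", "wealth_score", "height_cm", "weight_kg", "bmi", "age_years")
# Canonical non-covariate fields; anything else in the schema is a covariate.
CORE_FIELDS = NUMERIC_FIELDS + ("person_id", "wave", "stratum", "psu", "pregnant")
MANDATORY_FIELDS = ("weight", "wealth_score", "age_years")

# Reference (omitted) level per categorical factor, following the usual
# convention of taking the largest or most disadvantaged category as base.
DEFAULT_REFERENCES = {
    "race": "black_african",
    "education": "no_schooling",
    "employment": "unemployed",
    "marital": "single_never_married",
    "residence": "rural",
    "smoking": "non_smoker",
    "ses_quintile": "Q1",
}

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}
_FALSE_STRINGS = {"0", "false", "no", "n", "f"}


@dataclass
class LoadResult:
    """A loaded survey table plus a per-column parse report."""

    records: pd.DataFrame
    parse_report: dict[str, int]

    def __len__(self) -> int:
        return len(self.records)


def _parse_pregnant(col: pd.Series) -> pd.Series:
    def one(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUE_STRINGS:
            return True
        if s in _FALSE_STRINGS:
            return False
        return pd.NA

    return col.map(one).astype("boolean")


def load_survey_table(
    path: Union[str, os.PathLike],
    schema: Union[Mapping[str, str], str, os.PathLike],
    *,
    sep: str = ",",
    na_values: Optional[Sequence[str]] = None,
) -> LoadResult:
    """Read a delimited survey table under a canonical-name schema mapping.

    Parameters
    ----------
    path
        CSV (or other delimited) file, one row per respondent.
    schema
        Mapping from canonical field names (``weight``, ``wealth_score``,
        ``age_years``, ``height_cm``, ``weight_kg``, ``bmi``, ``pregnant``,
        ``person_id``, ``wave``, ``stratum``, ``psu``, plus arbitrary
        covariate names) to the column names in the file — or a path to a
        YAML file holding that mapping.
    na_values
        Extra sentinel strings to treat as missing (empty cells always are).

    Returns
    -------
    LoadResult
        Records renamed to canonical names, numerics coerced (unparseable
        entries become missing and are counted per column in
        ``parse_report``).  Loading never filters rows; range checks happen
        in :func:`apply_exclusions`.
    """
    if not isinstance(schema, Mapping):
        import yaml

        with open(schema) as fh:
            schema = yaml.safe_load(fh)
        if not isinstance(schema, Mapping):
            raise ValueError("schema file must contain a mapping of canonical -> column names")

    for fieldname in MANDATORY_FIELDS:
        if fieldname not in schema:
            raise ValueError(f"schema missing mandatory field {fieldname!r}")

    raw = pd.read_csv(path, sep=sep, na_values=na_values, dtype="object")
    if raw.empty:
        raise ValueError(f"survey table {path} is empty")

    missing_cols = [src for src in schema.values() if src not in raw.columns]
    if missing_cols:
        raise ValueError(f"mapped columns absent from {path}: {missing_cols}")

    df = raw[[schema[k] for k in schema]].copy()
    df.columns = list(schema.keys())

    parse_report: dict[str, int] = {}
    for col in NUMERIC_FIELDS:
        if col not in df.columns:
            continue
        before = df[col].notna()
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_bad = int((before & coerced.isna()).sum())
        if n_bad:
            parse_report[col] = n_bad
        df[col] = coerced

    if "pregnant" in df.columns:
        df["pregnant"] = _parse_pregnant(df["pregnant"])

    if df["weight"].isna().all():
        raise ValueError("weight column contains no numeric values")
    return LoadResult(records=df, parse_report=parse_report)


def derive_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Add BMI (kg/m^2) and the overweight/obesity flags.

    BMI is weight_kg / (height_cm/100)^2 where not already supplied.
    Overweight is BMI >= 25, obesity BMI >= 30; both cutoffs inclusive, so
    a BMI of exactly 25.0 or 30.0 is a positive case.  Missing BMI leaves
    both flags missing; nothing is filtered here.
    """
    df = records.copy()
    if "bmi" not in df.columns:
        df["bmi"] = np.nan
    if {"height_cm", "weight_kg"}.issubset(df.columns):
        computable = df["bmi"].isna() & df["height_cm"].notna() & df["weight_kg"].notna()
        # 1e4 * kg / cm^2 avoids the rounding that kg / (cm/100)^2 puts on
        # records sitting exactly at a BMI cutoff
        df.loc[computable, "bmi"] = (
            1e4 * df.loc[computable, "weight_kg"] / df.loc[computable, "height_cm"] ** 2
        )

    bmi = df["bmi"]
    df["overweight"] = pd.array(np.where(bmi.isna(), None, bmi >= 25.0), dtype="boolean")
    df["obese"] = pd.array(np.where(bmi.isna(), None, bmi >= 30.0), dtype="boolean")
    return df


@dataclass
class ExclusionRules:
    """Sample-cleaning rules, applied in a fixed order.

    age_range
        Closed interval of eligible ages in years (childbearing age).
    exclude_pregnant / exclude_missing_pregnancy
        Pregnancy inflates BMI, so pregnant women are dropped; records with
        unknown pregnancy status are dropped too by default (conservative,
        complete-case).
    bmi_bounds
        Closed plausibility interval for BMI; values outside are treated as
        measurement error.
    """

    age_range: tuple[float, float] = (15.0, 49.0)
    exclude_pregnant: bool = True
    exclude_missing_pregnancy: bool = True
    bmi_bounds: tuple[float, float] = (12.0, 60.0)


@dataclass
class AnalyticalDataset:
    """Records surviving the exclusion flow, with a per-rule count log."""

    records: pd.DataFrame
    exclusion_log: dict[str, int]
    n_input: int

    def __len__(self) -> int:
        return len(self.records)

    def write(self, table_path, log_path=None) -> None:
        self.records.to_csv(table_path, index=False)
        if log_path is not None:
            pd.DataFrame(
                {"rule": list(self.exclusion_log), "n_excluded": list(self.exclusion_log.values())}
            ).to_csv(log_path, index=False)


def apply_exclusions(
    records: pd.DataFrame, rules: ExclusionRules = ExclusionRules()
) -> AnalyticalDataset:
    """Apply the cleaning flow and log the count removed at each step.

    Order is fixed — (1) age outside range, (2) pregnant (and, per rules,
    unknown pregnancy status), (3) missing BMI, (4) implausible BMI — so a
    record failing several rules is counted once, at the first.
    """
    if "overweight" not in records.columns:
        raise ValueError("derive outcomes before applying exclusions")
    df = records
    n_input = len(df)
    log: dict[str, int] = {}

    lo, hi = rules.age_range
    keep = df["age_years"].notna() & df["age_years"].between(lo, hi)
    log["age_out_of_range"] = int((~keep).sum())
    df = df[keep]

    if "pregnant" in df.columns:
        preg = df["pregnant"]
        drop = pd.Series(False, index=df.index)
        if rules.exclude_pregnant:
            drop |= preg.fillna(False).astype(bool)
        if rules.exclude_missing_pregnancy:
            drop |= preg.isna()
        log["pregnant"] = int(drop.sum())
        df = df[~drop]
    else:
        log["pregnant"] = 0

    keep = df["bmi"].notna()
    log["missing_bmi"] = int((~keep).sum())
    df = df[keep]

    blo, bhi = rules.bmi_bounds
    keep = df["bmi"].between(blo, bhi)
    log["implausible_bmi"] = int((~keep).sum())
    df = df[keep]

    if df.empty:
        raise ValueError(f"all {n_input} records excluded; exclusion log: {log}")
    return AnalyticalDataset(records=df.reset_index(drop=True), exclusion_log=log, n_input=n_input)


@dataclass
class FactorSpec:
    """One explanatory factor of the outcome model.

    kind is "categorical" (dummy-coded against a reference level) or
    "continuous" (enters as-is, e.g. age in years).  group names the block
    used for grouped contribution reporting; defaults to the factor name.
    """

    name: str
    kind: str = "categorical"
    reference: Optional[str] = None
    group: Optional[str] = None


DEFAULT_FACTOR_SPEC = (
    FactorSpec("age_years", kind="continuous", group="age"),
    FactorSpec("race"),
    FactorSpec("education"),
    FactorSpec("employment"),
    FactorSpec("marital"),
    FactorSpec("residence"),
    FactorSpec("smoking"),
    FactorSpec("ses_quintile", group="ses"),
)


@dataclass
class DesignMatrix:
    """Numeric covariate columns plus the bookkeeping for grouped reporting."""

    values: pd.DataFrame
    reference_levels: dict[str, str]
    group_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)


def build_design_matrix(
    data: Union[pd.DataFrame, AnalyticalDataset],
    factor_spec: Sequence[FactorSpec] = DEFAULT_FACTOR_SPEC,
) -> DesignMatrix:
    """Dummy-code the covariates into the regression design.

    Each categorical factor contributes one 0/1 column per non-reference
    observed level, named ``factor[level]``; the reference level (from the
    spec, falling back to conventional defaults, then the most frequent
    level) is omitted.  Continuous factors enter unchanged.

    Raises
    ------
    ValueError
        If a factor has fewer than two observed levels, a continuous factor
        is constant, or a named factor is absent from the data.
    """
    df = data.records if isinstance(data, AnalyticalDataset) else data
    cols: dict[str, np.ndarray] = {}
    refs: dict[str, str] = {}
    group_map: dict[str, list[str]] = {}

    for spec in factor_spec:
        if spec.name not in df.columns:
            raise ValueError(f"factor {spec.name!r} not found in data")
        group = spec.group or spec.name
        series = df[spec.name]
        if series.isna().any():
            raise ValueError(f"factor {spec.name!r} has missing values (complete-case required)")

        if spec.kind == "continuous":
            x = series.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValueError(f"continuous factor {spec.name!r} is constant")
            cols[spec.name] = x
            group_map.setdefault(group, []).append(spec.name)
            continue

        levels = series.astype(str)
        counts = levels.value_counts()
        if len(counts) < 2:
            raise ValueError(f"categorical factor {spec.name!r} has a single observed level")
        ref = spec.reference or DEFAULT_REFERENCES.get(spec.name)
        if ref is None or ref not in counts.index:
            ref = counts.index[0]  # most frequent level as fallback base
        refs[spec.name] = ref
        for level in sorted(counts.index):
            if level == ref:
                continue
            colname = f"{spec.name}[{level}]"
            cols[colname] = (levels == level).to_numpy(dtype=float)
            group_map.setdefault(group, []).append(colname)

    values = pd.DataFrame(cols, index=df.index)
    return DesignMatrix(values=values, reference_levels=refs, group_map=group_map)


@dataclass
class QuintileAssignment:
    """Weighted wealth quintile labels Q1 (poorest) .. Q5 (richest)."""

    labels: pd.Series
    cutpoints: np.ndarray


def assign_wealth_quintiles(
    data: Union[pd.DataFrame, AnalyticalDataset],
    *,
    score_col: str = "wealth_score",
    weight_col: str = "weight",
) -> QuintileAssignment:
    """National wealth quintiles from weighted quantiles of the wealth score.

    Cutpoints sit at cumulative normalised-weight shares 0.2, 0.4, 0.6 and
    0.8 of the score distribution; records tied at a cutpoint all fall in
    the lower quintile, so each quintile's weighted share is 20% up to
    tie-induced deviation.
    """
    df = data.records if isinstance(data, AnalyticalDataset) else data
    s = df[score_col].to_numpy(dtype=float)
    w = df[weight_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(s)) or np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("wealth scores must be finite and weights positive")

    uniq, inverse = np.unique(s, return_inverse=True)
    if uniq.shape[0] < 2:
        raise ValueError("all wealth scores identical; quintiles undefined")
    cumw = np.cumsum(np.bincount(inverse, weights=w / w.sum(), minlength=uniq.shape[0]))
    # smallest score whose cumulative share reaches each 20% boundary
    cut_idx = np.searchsorted(cumw, [0.2, 0.4, 0.6, 0.8], side="left")
    cutpoints = uniq[np.minimum(cut_idx, uniq.shape[0] - 1)]
    q = 1 + (s[:, None] > cutpoints[None, :]).sum(axis=1)
    labels = pd.Series([f"Q{i}" for i in q], index=df.index, name="ses_quintile")
    return QuintileAssignment(labels=labels, cutpoints=cutpoints)


def weighted_mean(x, weights) -> float:
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    return float((w @ x) / w.sum())


def weighted_proportions(labels, weights) -> pd.Series:
    """Survey-weighted category shares (sums to 1)."""
    df = pd.DataFrame({"g": np.asarray(labels), "w": np.asarray(weights, dtype=float)})
    out = df.groupby("g", sort=True)["w"].sum()
    return out / out.sum()
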