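"""Two-wave DHS-like synthetic survey data with known inequality truth.

The restricted microdata this methodology is normally applied to (household
surveys with wealth indices, such as the South Africa DHS) are
registration-gated, so every pipeline stage is exercised against generated
data whose ground truth is known by construction:

* a continuous wealth score (standard normal, optionally clustered within
  PSUs) whose population rank u = Phi(score) drives everything else;
* categorical covariates drawn from multinomial-logistic level
  probabilities in the rank, P(level l | u) ∝ exp(a_l + b_l (u - 1/2)),
  giving controllable monotone rank gradients; age is Gaussian with a
  chosen rank correlation;
* a binary outcome h ~ Bernoulli(clip(alpha + sum_k beta_k x_k)) from a
  linear probability model with known coefficients.

Ground truth (true C, per-factor C_k, elasticities and contributions) is
computed by an independent brute-force oracle: a fresh draw of 10^6 records
under a *separate, fixed* seed, evaluated with the direct covariance formula
on the conditional outcome probabilities — never through the estimation
pipeline under test.  Accuracy is ~1e-3, adequate for the stated test
tolerances.

What this emulates — and what it does not: the generator reproduces the
survey's weighting, stratification/clustering, rank-graded covariates and a
linear outcome process.  It does not emulate DHS multistage selection
probabilities, nonresponse, measurement error in anthropometry, or model
misspecification; recovery results therefore validate the estimators, not
the substantive epidemiology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .survey_data import FactorSpec

__all__ = [
    "CategoricalFactor",
    "AgeSpec",
    "OutcomeSpec",
    "SyntheticConfig",
    "OutcomeTruth",
    "SyntheticTruth",
    "TwoWaveResult",
    "generate_wave",
    "generate_two_waves",
    "true_change_terms",
    "sadhs_like_configs",
]

# Oracle seed stream is fixed and distinct from any data seed, so the stored
# truth is never correlated with the dataset it accompanies.
ORACLE_SEED = 20160415
DEFAULT_N_ORACLE = 1_000_000


@dataclass(frozen=True)
class CategoricalFactor:
    """A categorical covariate with logistic-in-rank level probabilities.

    P(level l | rank u) = softmax_l( base_logits[l] + rank_slopes[l] * (u - 0.5) ).
    The first level is the dummy-coding reference unless stated otherwise.
    """

    name: str
    levels: tuple[str, ...]
    base_logits: tuple[float, ...]
    rank_slopes: tuple[float, ...]
    reference: Optional[str] = None

    def __post_init__(self):
        if not (len(self.levels) == len(self.base_logits) == len(self.rank_slopes)):
            raise ValueError(f"factor {self.name!r}: levels/logits/slopes lengths differ")
        if len(self.levels) < 2:
            raise ValueError(f"factor {self.name!r} needs at least two levels")

    @property
    def ref(self) -> str:
        return self.reference or self.levels[0]

    def probs(self, u: np.ndarray) -> np.ndarray:
        logits = np.asarray(self.base_logits) + np.outer(u - 0.5, np.asarray(self.rank_slopes))
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class AgeSpec:
    """Age in years: Gaussian, truncated to the eligible range, with a
    chosen correlation between its latent normal and the wealth rank's
    normal score."""

    mean: float = 29.2
    sd: float = 9.7
    rank_corr: float = 0.0
    lo: float = 15.0
    hi: float = 49.0


@dataclass(frozen=True)
class OutcomeSpec:
    """A binary outcome from a linear probability model with known
    coefficients, keyed by design-column name (e.g. ``race[white]``,
    ``age_years``, ``ses_quintile[Q5]``)."""

    name: str
    alpha: float
    betas: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to draw one survey wave and to derive its truth."""

    n: int
    wave: str = "t"
    factors: tuple[CategoricalFactor, ...] = ()
    age: Optional[AgeSpec] = None
    outcomes: tuple[OutcomeSpec, ...] = (OutcomeSpec("h", alpha=0.3),)
    include_ses_quintiles: bool = True
    n_strata: int = 10
    psus_per_stratum: int = 20
    weight_dist: str = "equal"  # or "gamma" (mean-1 gamma weights)
    gamma_shape: float = 4.0
    wealth_icc: float = 0.0  # share of wealth-score variance at PSU level
    clip_bounds: tuple[float, float] = (0.02, 0.98)
    max_clip_frac: float = 0.05
    couple_outcomes: bool = True  # one shared uniform drives all outcomes

    def design_columns(self) -> list[str]:
        cols: list[str] = []
        if self.age is not None:
            cols.append("age_years")
        for f in self.factors:
            cols.extend(f"{f.name}[{lvl}]" for lvl in sorted(f.levels) if lvl != f.ref)
        if self.include_ses_quintiles:
            cols.extend(f"ses_quintile[Q{i}]" for i in range(2, 6))
        return cols

    def factor_spec(self) -> list[FactorSpec]:
        """The matching design specification for build_design_matrix, so a
        pipeline fit aligns column-for-column with the stored truth."""
        spec: list[FactorSpec] = []
        if self.age is not None:
            spec.append(FactorSpec("age_years", kind="continuous", group="age"))
        spec.extend(FactorSpec(f.name, reference=f.ref) for f in self.factors)
        if self.include_ses_quintiles:
            spec.append(FactorSpec("ses_quintile", reference="Q1", group="ses"))
        return spec


def _draw_wave(config: SyntheticConfig, rng: np.random.Generator):
    """Draw scores, design, covariates and outcome probabilities (no h)."""
    n = config.n
    n_psu = config.n_strata * config.psus_per_stratum
    psu_idx = rng.integers(0, n_psu, n)
    stratum_idx = psu_idx // config.psus_per_stratum

    icc = config.wealth_icc
    psu_eff = rng.standard_normal(n_psu)
    score = np.sqrt(icc) * psu_eff[psu_idx] + np.sqrt(1.0 - icc) * rng.standard_normal(n)
    u = norm.cdf(score)

    if config.weight_dist == "equal":
        weights = np.ones(n)
    elif config.weight_dist == "gamma":
        weights = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape, n)
    else:
        raise ValueError(f"unknown weight_dist {config.weight_dist!r}")

    covars: dict[str, np.ndarray] = {}
    X: dict[str, np.ndarray] = {}

    if config.age is not None:
        a = config.age
        z = a.rank_corr * norm.ppf(u) + np.sqrt(1 - a.rank_corr**2) * rng.standard_normal(n)
        age = np.clip(a.mean + a.sd * z, a.lo, a.hi)
        covars["age_years"] = age
        X["age_years"] = age

    for f in config.factors:
        p = f.probs(u)
        draws = (rng.random(n)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        lvl = np.asarray(f.levels, dtype=object)[draws]
        covars[f.name] = lvl
        for level in sorted(f.levels):
            if level != f.ref:
                X[f"{f.name}[{level}]"] = (lvl == level).astype(float)

    if config.include_ses_quintiles:
        q = np.minimum(np.floor(u * 5).astype(int) + 1, 5)
        covars["ses_quintile"] = np.array([f"Q{i}" for i in q], dtype=object)
        for i in range(2, 6):
            X[f"ses_quintile[Q{i}]"] = (q == i).astype(float)

    lo, hi = config.clip_bounds
    probs: dict[str, np.ndarray] = {}
    for out in config.outcomes:
        unknown = set(out.betas) - set(X)
        if unknown:
            raise ValueError(f"outcome {out.name!r} references unknown columns: {sorted(unknown)}")
        p = np.full(n, out.alpha)
        for c, b in out.betas.items():
            p = p + b * X[c]
        clipped = (p < lo) | (p > hi)
        frac = float(clipped.mean())
        if frac > config.max_clip_frac:
            raise ValueError(
                f"outcome {out.name!r}: {frac:.1%} of probabilities escape clip bounds "
                f"{config.clip_bounds}; reduce |alpha| / |beta| in the config"
            )
        probs[out.name] = np.clip(p, lo, hi)

    return score, u, weights, stratum_idx, psu_idx, covars, X, probs


def _synthesize_anthropometry(df: pd.DataFrame, rng: np.random.Generator) -> None:
    """BMI/height/weight consistent with overweight & obese flags, so the
    survey_data derivation path reproduces the generated outcomes."""
    n = len(df)
    u2 = rng.random(n)
    ow = df["overweight"].to_numpy(dtype=bool)
    ob = df["obese"].to_numpy(dtype=bool)
    bmi = np.where(ob, 30.5 + 11.0 * u2, np.where(ow, 25.1 + 4.7 * u2, 17.0 + 7.7 * u2))
    height = np.clip(rng.normal(160.0, 7.0, n), 140.0, 185.0)
    df["height_cm"] = np.round(height, 1)
    df["bmi"] = bmi
    df["weight_kg"] = np.round(bmi * (height / 100.0) ** 2, 1)
    df["pregnant"] = False


@dataclass
class OutcomeTruth:
    """Oracle-derived truth for one outcome: population-level mean, C, and
    the analytic decomposition implied by the generator's coefficients."""

    mu: float
    C: float
    table: pd.DataFrame  # index: design column; columns: beta, mean, factor_index, elasticity, contribution
    residual: float


@dataclass
class SyntheticTruth:
    """Ground truth bundle stored alongside a generated dataset."""

    outcomes: dict[str, OutcomeTruth]
    design_columns: list[str]
    n_oracle: int
    oracle_seed: int
    config_echo: dict

    def to_json(self, path) -> None:
        payload = {
            "design_columns": self.design_columns,
            "n_oracle": self.n_oracle,
            "oracle_seed": self.oracle_seed,
            "config_echo": self.config_echo,
            "outcomes": {
                name: {
                    "mu": t.mu,
                    "C": t.C,
                    "residual": t.residual,
                    "table": t.table.to_dict(orient="index"),
                }
                for name, t in self.outcomes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        outcomes = {}
        for name, t in payload["outcomes"].items():
            table = pd.DataFrame.from_dict(t["table"], orient="index")
            table = table.reindex(payload["design_columns"])
            table.index.name = "factor"
            outcomes[name] = OutcomeTruth(mu=t["mu"], C=t["C"], table=table, residual=t["residual"])
        return cls(
            outcomes=outcomes,
            design_columns=payload["design_columns"],
            n_oracle=payload["n_oracle"],
            oracle_seed=payload["oracle_seed"],
            config_echo=payload["config_echo"],
        )


def _oracle_truth(config: SyntheticConfig, oracle_seed: int, n_oracle: int) -> SyntheticTruth:
    """Brute-force truth on an independent large draw.

    Uses the conditional outcome probabilities in place of Bernoulli draws
    (the index is linear in h, so this only removes Monte-Carlo noise) and
    the direct covariance formula throughout — never the estimators under
    test.
    """
    big = replace(config, n=n_oracle)
    rng = np.random.default_rng(oracle_seed)
    score, _, weights, _, _, _, X, probs = _draw_wave(big, rng)

    # weighted fractional rank, written out longhand (independent of the
    # pipeline's implementation)
    wn = weights / weights.sum()
    order = np.argsort(score, kind="mergesort")
    r = np.empty_like(wn)
    cw = np.cumsum(wn[order])
    r[order] = cw - wn[order] / 2.0  # scores are continuous: ties have measure zero
    dev = r - 0.5

    cols = big.design_columns()
    outcomes: dict[str, OutcomeTruth] = {}
    for out in config.outcomes:
        p = probs[out.name]
        mu = float(wn @ p)
        C = 2.0 * float(wn @ ((p - mu) * dev)) / mu
        rows = []
        for c in cols:
            x = X[c]
            beta = float(out.betas.get(c, 0.0))
            xbar = float(wn @ x)
            ck = 2.0 * float(wn @ ((x - xbar) * dev)) / xbar if xbar != 0 else 0.0
            eta = beta * xbar / mu
            rows.append((c, beta, xbar, ck, eta, eta * ck))
        table = pd.DataFrame(
            rows, columns=["factor", "beta", "mean", "factor_index", "elasticity", "contribution"]
        ).set_index("factor")
        residual = C - float(table["contribution"].sum())
        outcomes[out.name] = OutcomeTruth(mu=mu, C=C, table=table, residual=residual)

    return SyntheticTruth(
        outcomes=outcomes,
        design_columns=cols,
        n_oracle=n_oracle,
        oracle_seed=oracle_seed,
        config_echo=asdict(config),
    )


def generate_wave(
    config: SyntheticConfig,
    seed: int,
    *,
    compute_truth: bool = True,
    oracle_seed: int = ORACLE_SEED,
    n_oracle: int = DEFAULT_N_ORACLE,
) -> tuple[pd.DataFrame, Optional[SyntheticTruth]]:
    """Draw one survey wave; optionally compute its oracle ground truth.

    Returns a DataFrame in the survey_data schema (person_id, wave, weight,
    stratum, psu, wealth_score, age_years, covariate columns, outcome
    columns; plus BMI/height/weight/pregnant when the outcomes are named
    ``overweight``/``obese`` and nested) and the truth bundle.
    """
    rng = np.random.default_rng(seed)
    score, _, weights, stratum_idx, psu_idx, covars, X, probs = _draw_wave(config, rng)
    n = config.n

    df = pd.DataFrame(
        {
            "person_id": [f"{config.wave}-{i:07d}" for i in range(n)],
            "wave": config.wave,
            "weight": weights,
            "stratum": [f"S{s:02d}" for s in stratum_idx],
            "psu": [f"S{s:02d}_P{p:03d}" for s, p in zip(stratum_idx, psu_idx)],
            "wealth_score": score,
        }
    )
    for name, vals in covars.items():
        df[name] = vals

    names = [o.name for o in config.outcomes]
    if config.couple_outcomes:
        v = rng.random(n)
        for name in names:
            df[name] = (v < probs[name]).astype(int)
    else:
        for name in names:
            df[name] = (rng.random(n) < probs[name]).astype(int)

    if {"overweight", "obese"}.issubset(names) and config.couple_outcomes:
        if np.any(probs["obese"] > probs["overweight"]):
            raise ValueError("obesity probability exceeds overweight probability for some records")
        _synthesize_anthropometry(df, rng)

    truth = _oracle_truth(config, oracle_seed, n_oracle) if compute_truth else None
    return df, truth


@dataclass
class TwoWaveResult:
    data_t0: pd.DataFrame
    truth_t0: SyntheticTruth
    data_t: pd.DataFrame
    truth_t: SyntheticTruth

    def true_change(self, outcome: str) -> tuple[pd.DataFrame, float, float]:
        return true_change_terms(self.truth_t0, self.truth_t, outcome)


def generate_two_waves(
    config_t0: SyntheticConfig,
    config_t: SyntheticConfig,
    seed: int,
    *,
    compute_truth: bool = True,
    oracle_seed: int = ORACLE_SEED,
    n_oracle: int = DEFAULT_N_ORACLE,
) -> TwoWaveResult:
    """Two independent waves sharing a design, plus both truth bundles."""
    if config_t0.design_columns() != config_t.design_columns():
        raise ValueError("wave configs must share identical design columns")
    ss = np.random.SeedSequence(seed).spawn(2)
    data0, truth0 = generate_wave(
        config_t0, int(ss[0].generate_state(1)[0] % 2**31),
        compute_truth=compute_truth, oracle_seed=oracle_seed, n_oracle=n_oracle,
    )
    data1, truth1 = generate_wave(
        config_t, int(ss[1].generate_state(1)[0] % 2**31),
        compute_truth=compute_truth, oracle_seed=oracle_seed + 1, n_oracle=n_oracle,
    )
    return TwoWaveResult(data_t0=data0, truth_t0=truth0, data_t=data1, truth_t=truth1)


def true_change_terms(
    truth_t0: SyntheticTruth, truth_t: SyntheticTruth, outcome: str
) -> tuple[pd.DataFrame, float, float]:
    """Evaluate the Oaxaca-type change terms directly on two truth bundles.

    Returns (per-factor table with term_dC / term_dEta / total, residual
    change as remainder, delta_C)."""
    t0 = truth_t0.outcomes[outcome]
    t1 = truth_t.outcomes[outcome]
    eta_t, eta_t0 = t1.table["elasticity"], t0.table["elasticity"]
    ck_t, ck_t0 = t1.table["factor_index"], t0.table["factor_index"]
    table = pd.DataFrame(
        {
            "term_dC": eta_t * (ck_t - ck_t0),
            "term_dEta": ck_t0 * (eta_t - eta_t0),
        }
    )
    table["total"] = table["term_dC"] + table["term_dEta"]
    delta_C = t1.C - t0.C
    residual = delta_C - float(table["total"].sum())
    return table, residual, delta_C


# ---------------------------------------------------------------------------
# A two-wave preset patterned on the 1998/2016 SADHS sample structure:
# covariate mixes shift between waves (rising secondary education, falling
# smoking, growing black-African share), outcome prevalences rise, and the
# coefficient/gradient choices put the preset's own oracle concentration
# indices near chosen targets for overweight (0.02 -> 0.04) and
# obesity (0.06 -> 0.08).  The preset's truth is the generator's, computed
# by its oracle — it stands in for, and is not, the restricted survey data.
# ---------------------------------------------------------------------------


def _logits(shares: dict[str, float]) -> tuple[tuple[str, ...], tuple[float, ...]]:
    levels = tuple(shares)
    base = np.log(np.asarray([shares[l] for l in levels], dtype=float))
    return levels, tuple(float(b - base[0]) for b in base)


def _factor(name, shares, slopes, reference):
    levels, base = _logits(shares)
    return CategoricalFactor(
        name=name,
        levels=levels,
        base_logits=base,
        rank_slopes=tuple(slopes[l] for l in levels),
        reference=reference,
    )


def sadhs_like_configs(n_t0: int = 4939, n_t: int = 3144) -> tuple[SyntheticConfig, SyntheticConfig]:
    """The default two-wave study preset (sample sizes 4,939 and 3,144).

    Wealth gradients: education, employment, urban residence, white race and
    smoking all rise with the wealth rank; outcome coefficients are positive
    for age, SES quintiles and urban residence, patterned so overweight is
    weakly pro-rich and obesity more strongly so, increasing between waves.
    """
    slopes_race = {"black_african": 0.0, "coloured": 0.8, "indian_asian": 2.5, "white": 5.0}
    slopes_edu = {"no_schooling": 0.0, "primary": 0.8, "secondary": 2.2, "tertiary": 5.0}
    slopes_emp = {"unemployed": 0.0, "employed": 1.2}
    slopes_mar = {"single_never_married": 0.0, "married_living_together": 0.4, "widowed_divorced": 0.2}
    slopes_res = {"rural": 0.0, "urban": 3.0}
    slopes_smk = {"non_smoker": 0.0, "smoker": 1.0}

    factors_t0 = (
        _factor("race", {"black_african": 0.776, "coloured": 0.102, "indian_asian": 0.042, "white": 0.080},
                slopes_race, "black_african"),
        _factor("education", {"no_schooling": 0.065, "primary": 0.339, "secondary": 0.524, "tertiary": 0.073},
                slopes_edu, "no_schooling"),
        _factor("employment", {"unemployed": 0.629, "employed": 0.371}, slopes_emp, "unemployed"),
        _factor("marital", {"single_never_married": 0.532, "married_living_together": 0.423,
                            "widowed_divorced": 0.045}, slopes_mar, "single_never_married"),
        _factor("residence", {"rural": 0.370, "urban": 0.630}, slopes_res, "rural"),
        _factor("smoking", {"non_smoker": 0.885, "smoker": 0.115}, slopes_smk, "non_smoker"),
    )
    factors_t = (
        _factor("race", {"black_african": 0.906, "coloured": 0.058, "indian_asian": 0.015, "white": 0.021},
                slopes_race, "black_african"),
        _factor("education", {"no_schooling": 0.022, "primary": 0.100, "secondary": 0.776, "tertiary": 0.102},
                slopes_edu, "no_schooling"),
        _factor("employment", {"unemployed": 0.670, "employed": 0.330}, slopes_emp, "unemployed"),
        _factor("marital", {"single_never_married": 0.633, "married_living_together": 0.338,
                            "widowed_divorced": 0.029}, slopes_mar, "single_never_married"),
        _factor("residence", {"rural": 0.367, "urban": 0.633}, slopes_res, "rural"),
        _factor("smoking", {"non_smoker": 0.956, "smoker": 0.044}, slopes_smk, "non_smoker"),
    )

    betas_ow_t0 = {
        "age_years": 0.0105,
        "race[coloured]": -0.06, "race[indian_asian]": -0.05, "race[white]": -0.12,
        "education[primary]": 0.02, "education[secondary]": 0.03, "education[tertiary]": 0.02,
        "employment[employed]": 0.02,
        "marital[married_living_together]": 0.05, "marital[widowed_divorced]": 0.04,
        "residence[urban]": 0.05,
        "smoking[smoker]": -0.10,
        "ses_quintile[Q2]": 0.007, "ses_quintile[Q3]": 0.022,
        "ses_quintile[Q4]": 0.037, "ses_quintile[Q5]": 0.051,
    }
    betas_ow_t = {
        "age_years": 0.0110,
        "race[coloured]": -0.05, "race[indian_asian]": -0.04, "race[white]": -0.06,
        "education[primary]": 0.02, "education[secondary]": 0.03, "education[tertiary]": 0.02,
        "employment[employed]": 0.02,
        "marital[married_living_together]": 0.05, "marital[widowed_divorced]": 0.04,
        "residence[urban]": 0.03,
        "smoking[smoker]": -0.10,
        "ses_quintile[Q2]": 0.021, "ses_quintile[Q3]": 0.042,
        "ses_quintile[Q4]": 0.071, "ses_quintile[Q5]": 0.099,
    }
    betas_ob_t0 = {
        "age_years": 0.0060,
        "race[coloured]": -0.04, "race[indian_asian]": -0.03, "race[white]": -0.06,
        "education[primary]": -0.02, "education[secondary]": -0.04, "education[tertiary]": -0.05,
        "employment[employed]": 0.01,
        "marital[married_living_together]": 0.04, "marital[widowed_divorced]": 0.03,
        "residence[urban]": 0.05,
        "smoking[smoker]": -0.06,
        "ses_quintile[Q2]": 0.013, "ses_quintile[Q3]": 0.033,
        "ses_quintile[Q4]": 0.052, "ses_quintile[Q5]": 0.072,
    }
    betas_ob_t = {
        "age_years": 0.0070,
        "race[coloured]": -0.04, "race[indian_asian]": -0.03, "race[white]": -0.04,
        "education[primary]": -0.02, "education[secondary]": -0.04, "education[tertiary]": -0.05,
        "employment[employed]": 0.01,
        "marital[married_living_together]": 0.04, "marital[widowed_divorced]": 0.03,
        "residence[urban]": 0.02,
        "smoking[smoker]": -0.06,
        "ses_quintile[Q2]": 0.029, "ses_quintile[Q3]": 0.059,
        "ses_quintile[Q4]": 0.095, "ses_quintile[Q5]": 0.132,
    }

    cfg_t0 = SyntheticConfig(
        n=n_t0,
        wave="1998",
        factors=factors_t0,
        age=AgeSpec(mean=29.2, sd=9.7, rank_corr=0.05),
        outcomes=(
            OutcomeSpec("overweight", alpha=0.122, betas=betas_ow_t0),
            OutcomeSpec("obese", alpha=0.031, betas=betas_ob_t0),
        ),
        weight_dist="gamma",
        wealth_icc=0.2,
        n_strata=9,
        psus_per_stratum=30,
    )
    cfg_t = SyntheticConfig(
        n=n_t,
        wave="2016",
        factors=factors_t,
        age=AgeSpec(mean=30.2, sd=9.9, rank_corr=0.05),
        outcomes=(
            OutcomeSpec("overweight", alpha=0.180, betas=betas_ow_t),
            OutcomeSpec("obese", alpha=0.091, betas=betas_ob_t),
        ),
        weight_dist="gamma",
        wealth_icc=0.2,
        n_strata=9,
        psus_per_stratum=30,
    )
    return cfg_t0, cfg_t
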