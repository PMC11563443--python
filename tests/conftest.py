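import numpy as np
import pandas as pd
import pytest

from cidecomp.synthetic import AgeSpec, CategoricalFactor, OutcomeSpec, SyntheticConfig


def random_cindex_fixture(rng, n, *, ties=False):
    """A random weighted sample with a rank-graded binary outcome.

    Returns (wealth_scores, weights, h).  Used wherever a generic survey-like
    input is needed; the outcome probability rises with the wealth score so
    C is typically nonzero.
    """
    scores = rng.normal(size=n)
    if ties:
        scores = np.round(scores, 1)  # induces tie groups
    weights = rng.gamma(3.0, 1.0 / 3.0, size=n) + 0.05
    p = np.clip(0.25 + 0.25 * (scores > 0) + 0.05 * scores, 0.02, 0.98)
    h = (rng.random(n) < p).astype(float)
    return scores, weights, h


def recovery_config(n=20_000, wave="t", shift=0.0):
    """A 10-column design whose linear-probability outcome never needs
    clipping, for parameter-recovery studies.  ``shift`` perturbs a couple
    of coefficients and covariate gradients to build a second wave."""
    factors = (
        CategoricalFactor(
            "race",
            levels=("black", "coloured", "white"),
            base_logits=(0.0, -1.8, -2.2),
            rank_slopes=(0.0, 1.0, 3.0 + 2.0 * shift),
        ),
        CategoricalFactor(
            "residence",
            levels=("rural", "urban"),
            base_logits=(0.0, 0.4),
            rank_slopes=(0.0, 2.0),
        ),
        CategoricalFactor(
            "education",
            levels=("low", "mid", "high"),
            base_logits=(0.0, 0.6, -1.2),
            rank_slopes=(0.0, 1.5, 3.5),
        ),
    )
    betas = {
        "age_years": 0.004,
        "race[coloured]": 0.05,
        "race[white]": -0.04 + 0.03 * shift,
        "residence[urban]": 0.06,
        "education[mid]": 0.03,
        "education[high]": -0.03,
        "ses_quintile[Q2]": 0.02,
        "ses_quintile[Q3]": 0.04,
        "ses_quintile[Q4]": 0.06,
        "ses_quintile[Q5]": 0.08 + 0.04 * shift,
    }
    return SyntheticConfig(
        n=n,
        wave=wave,
        factors=factors,
        age=AgeSpec(mean=30.0, sd=8.0, rank_corr=0.15),
        outcomes=(OutcomeSpec("h", alpha=0.20, betas=betas),),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def survey_frame(rng):
    """A small raw survey table in canonical column names."""
    n = 60
    df = pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n)],
            "wave": "w1",
            "weight": rng.gamma(4, 0.25, n) + 0.1,
            "stratum": rng.choice(["S1", "S2"], n),
            "psu": rng.choice([f"P{i}" for i in range(6)], n),
            "wealth_score": rng.normal(size=n),
            "height_cm": rng.normal(160, 6, n),
            "weight_kg": rng.normal(68, 12, n).clip(40, 130),
            "age_years": rng.uniform(16, 48, n),
            "pregnant": False,
            "race": rng.choice(["black_african", "coloured", "white"], n, p=[0.7, 0.2, 0.1]),
            "residence": rng.choice(["rural", "urban"], n),
        }
    )
    df["bmi"] = np.nan
    return df
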