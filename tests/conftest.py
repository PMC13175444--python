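import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pxmode import GeneratorConfig, OutcomeModel, generate_trial
from pxmode.dataset import AGE_LEVELS, CARE_LEVELS, HOSPITAL_LEVELS, SEX_LEVELS

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

UNIFORM_STRATA = {
    "sex": {l: 1 / len(SEX_LEVELS) for l in SEX_LEVELS},
    "age_group": {l: 1 / len(AGE_LEVELS) for l in AGE_LEVELS},
    "care_field": {l: 1 / len(CARE_LEVELS) for l in CARE_LEVELS},
    "hospital": {l: 1 / len(HOSPITAL_LEVELS) for l in HOSPITAL_LEVELS},
}


def simple_config(
    n_per_arm=400,
    arm_effect=-4.0,
    intercept=78.0,
    residual_sd=12.0,
    response_coefs=None,
    stratum_effects=None,
    mnar_shift=(0.0, 0.0),
    seed=0,
):
    """Small, uncalibrated trial configuration for unit tests."""
    if response_coefs is None:
        response_coefs = {
            "intercept": 0.2,
            "arm": {"telephone": -0.5},
            "age_group": {"70+": -0.6},
            "hospital": {"D": -0.3},
        }
    if stratum_effects is None:
        stratum_effects = {"age_group": {"70+": 4.0}, "hospital": {"D": -2.0}}
    return GeneratorConfig(
        n_per_arm=n_per_arm,
        strata_probs=UNIFORM_STRATA,
        response_logit_coefs=response_coefs,
        outcome=OutcomeModel(
            intercept=intercept,
            arm_effect=arm_effect,
            stratum_effects=stratum_effects,
            residual_sd=residual_sd,
        ),
        mnar_shift=mnar_shift,
        seed=seed,
    )


@pytest.fixture(scope="session")
def calibrated_config():
    from pxmode import table1_margins_config

    return table1_margins_config(seed=915001)


@pytest.fixture(scope="session")
def calibrated_trial(calibrated_config):
    return generate_trial(calibrated_config)


@pytest.fixture(scope="session")
def calibrated_scores(calibrated_trial):
    from pxmode import score_dataset

    return score_dataset(calibrated_trial)


@pytest.fixture(scope="session")
def calibrated_total(calibrated_trial, calibrated_scores):
    from pxmode import outcome_series

    return outcome_series(calibrated_trial, calibrated_scores, "total")


def hand_frame(rows):
    """Bare analysis frame from (arm, strata..., responded) dicts."""
    df = pd.DataFrame(rows)
    defaults = {
        "sex": "female",
        "age_group": "40-59",
        "care_field": "medical",
        "hospital": "A",
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    if "patient_id" not in df.columns:
        df["patient_id"] = [f"H{i:04d}" for i in range(len(df))]
    return df


def ipw_fixture():
    """16-record two-stratum fixture with exact cell response rates 1/2, 1/4.

    Within each (arm, care_field) cell: stratum ``medical`` has 4 patients
    with 2 respondents, ``surgical_other`` 4 patients with 1 respondent, so
    a logistic fit on arm + care_field reproduces 0.5 / 0.25 exactly and
    hand-computed Hajek means are available.
    """
    rows = []
    outcomes = {
        ("telephone", "medical"): [80.0, 90.0],
        ("telephone", "surgical_other"): [70.0],
        ("mobile_web", "medical"): [60.0, 70.0],
        ("mobile_web", "surgical_other"): [60.0],
    }
    for arm in ("telephone", "mobile_web"):
        for stratum, n_resp in (("medical", 2), ("surgical_other", 1)):
            vals = outcomes[(arm, stratum)]
            for i in range(4):
                responded = i < n_resp
                rows.append(
                    dict(
                        arm=arm,
                        care_field=stratum,
                        responded=responded,
                        y=vals[i] if responded else np.nan,
                    )
                )
    df = hand_frame(rows)
    y = df.pop("y")
    return df, pd.Series(y.to_numpy(), index=df.index, name="total")
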