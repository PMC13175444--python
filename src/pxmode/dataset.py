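"""Trial data container and plain-text I/O.

A trial dataset is one row per randomized patient: survey-mode arm, the four
stratification variables used for sampling (sex, age group, field of care,
hospital of origin), a response indicator, and the 21 questionnaire items,
present iff the patient responded. Synthetic datasets additionally carry the
generating configuration and per-patient latent outcomes for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import TruthUnavailableError, ValidationError

ARM_LEVELS = ("mobile_web", "telephone")
SEX_LEVELS = ("female", "male")
AGE_LEVELS = ("19-39", "40-59", "60-69", "70+")
CARE_LEVELS = ("medical", "surgical_other")
HOSPITAL_LEVELS = ("A", "B", "C", "D")

STRATA_FACTORS = ("sex", "age_group", "care_field", "hospital")
FACTOR_LEVELS = {
    "arm": ARM_LEVELS,
    "sex": SEX_LEVELS,
    "age_group": AGE_LEVELS,
    "care_field": CARE_LEVELS,
    "hospital": HOSPITAL_LEVELS,
}

ITEM_COLUMNS = tuple(f"q{i}" for i in range(1, 22))
BASE_COLUMNS = ("patient_id", "arm", *STRATA_FACTORS, "responded")


@dataclass
class SimulationTruth:
    """Generator-side ground truth kept with synthetic datasets.

    ``y_true`` is the observable-scale outcome each patient would contribute:
    the clipped latent total, shifted by the arm's MNAR delta for
    nonrespondents. It is never written to the patient-level file.
    """

    config: "object"  # GeneratorConfig; typed loosely to avoid a cycle
    y_true: Optional[np.ndarray] = None
    latent: Optional[np.ndarray] = None


@dataclass
class TrialDataset:
    """A collection of randomized-patient records plus factor coding."""

    df: pd.DataFrame
    truth: Optional[SimulationTruth] = None

    def __post_init__(self) -> None:
        missing = [c for c in BASE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"trial data lacks required columns: {missing}")
        for factor, levels in FACTOR_LEVELS.items():
            bad = set(self.df[factor].dropna().unique()) - set(levels)
            if bad:
                raise ValidationError(
                    f"unknown {factor} value(s) {sorted(bad)}; expected {levels}"
                )
            self.df[factor] = pd.Categorical(self.df[factor], categories=levels)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def responded(self) -> pd.Series:
        return self.df["responded"].astype(bool)

    def arm_mask(self, arm: str) -> pd.Series:
        return self.df["arm"] == arm

    def n_per_arm(self) -> dict:
        return self.df.groupby("arm", observed=False).size().to_dict()


def as_frame(data) -> pd.DataFrame:
    """Accept a TrialDataset or a bare DataFrame."""
    return data.df if isinstance(data, TrialDataset) else data


def ground_truth(dataset: TrialDataset):
    """Return ``(arm_effect, delta1, delta2)`` used to generate the data.

    ``arm_effect`` is the latent-scale mobile-web-minus-telephone shift;
    ``delta1``/``delta2`` are the MNAR shifts applied to telephone and
    mobile-web nonrespondents. Raises TruthUnavailableError for real-shaped
    data without simulation metadata.
    """
    if not isinstance(dataset, TrialDataset) or dataset.truth is None:
        raise TruthUnavailableError(
            "dataset carries no simulation metadata; ground truth is only "
            "available for synthetic datasets"
        )
    cfg = dataset.truth.config
    d1, d2 = cfg.mnar_shift
    return (cfg.outcome.arm_effect, d1, d2)


def save_trial(dataset: TrialDataset, path) -> None:
    """Write the patient table as CSV plus a YAML sidecar with the config.

    Missing item cells are written empty. The sidecar (``<path>.meta.yaml``)
    records the generating configuration and truth parameters when present.
    """
    path = Path(path)
    out = dataset.df.copy()
    out["responded"] = out["responded"].astype(bool)
    out.to_csv(path, index=False)
    meta = {"format": "pxmode-trial", "version": 1, "synthetic": dataset.truth is not None}
    if dataset.truth is not None:
        meta["config"] = dataset.truth.config.to_dict()
    with open(str(path) + ".meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_trial(path) -> TrialDataset:
    """Read a trial CSV (and sidecar metadata if present).

    Per-patient latent truth is not persisted; a loaded synthetic dataset
    supports ``ground_truth`` but not latent-level validation.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"q13": "object"})
    df["responded"] = df["responded"].astype(bool)
    truth = None
    meta_path = Path(str(path) + ".meta.yaml")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        if meta.get("synthetic") and "config" in meta:
            from .synthetic import GeneratorConfig

            truth = SimulationTruth(config=GeneratorConfig.from_dict(meta["config"]))
    return TrialDataset(df=df, truth=truth)
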