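"""Food-web baseline classification from bulk isotope values.

The beta term in the trophic-position equation is the difference between
glutamic-acid and phenylalanine d15N in the autotrophs at the base of the
consumer's food web, and differs among marine/aquatic producers, terrestrial
C4 plants, and terrestrial C3 plants. Bulk-tissue d13C and d15N of hair
separate consumers feeding on these three kinds of food web, so each
individual is assigned a baseline class — and with it a beta value — from
its bulk values alone:

* marine:          d13C > -19 per mil AND d15N > 12 per mil, beta = -3.4 +/- 0.9
* C4 terrestrial:  d13C > -15 per mil AND d15N < 12 per mil, beta = -0.4 +/- 1.7
* C3 terrestrial:  everything else,                          beta = +8.4 +/- 1.6

Inequalities are strict; boundary values fall through to the C3 default and
are flagged as anomalies rather than rejected, because the thresholds are
approximate and inputs between the observed clusters deserve scrutiny.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

from .errors import ValidationError
from .samples import Dataset


class FoodWebLabel(str, Enum):
    MARINE = "MARINE"
    C4_TERRESTRIAL = "C4_TERRESTRIAL"
    C3_TERRESTRIAL = "C3_TERRESTRIAL"


class Rule(str, Enum):
    MARINE_RULE = "MARINE_RULE"
    C4_RULE = "C4_RULE"
    DEFAULT_C3 = "DEFAULT_C3"


@dataclass(frozen=True)
class FoodWebClass:
    """A baseline class with its beta value (per mil, mean and 1 sigma)."""

    label: FoodWebLabel
    beta_mean: float
    beta_sigma: float

    def __post_init__(self) -> None:
        if self.beta_sigma < 0:
            raise ValidationError(f"{self.label}: beta_sigma must be >= 0")


#: Literature beta constants per class (per mil, mean and 1 sigma).
DEFAULT_BETAS: dict[FoodWebLabel, tuple[float, float]] = {
    FoodWebLabel.MARINE: (-3.4, 0.9),
    FoodWebLabel.C4_TERRESTRIAL: (-0.4, 1.7),
    FoodWebLabel.C3_TERRESTRIAL: (8.4, 1.6),
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds (per mil) and beta constants; defaults are the published values."""

    d13c_marine: float = -19.0
    d15n_marine: float = 12.0
    d13c_c4: float = -15.0
    d15n_c4: float = 12.0
    betas: Mapping[FoodWebLabel, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BETAS)
    )

    def food_web(self, label: FoodWebLabel) -> FoodWebClass:
        mean, sigma = self.betas[label]
        return FoodWebClass(label, mean, sigma)


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class FoodWebAssignment:
    """Result of classifying one individual's bulk isotope values."""

    sample_id: str
    food_web: FoodWebClass
    rule_fired: Rule
    anomaly_flag: bool


def classify(
    d13c: float,
    d15n: float,
    *,
    sample_id: str = "",
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> FoodWebAssignment:
    """Assign a food-web baseline class from bulk d13C and d15N (per mil).

    Rules are tested in the order marine -> C4 -> default C3, with strict
    inequalities exactly as published. The anomaly flag marks inputs in
    regions the observed clusters never occupied (intermediate d13C between
    -19 and -15, or a C3 fall-through with marine-like carbon or nitrogen);
    anomalous inputs are still classified, never rejected.
    """
    if not (math.isfinite(d13c) and math.isfinite(d15n)):
        raise ValidationError(f"sample {sample_id!r}: bulk values must be finite")

    if d13c > config.d13c_marine and d15n > config.d15n_marine:
        label, rule = FoodWebLabel.MARINE, Rule.MARINE_RULE
    elif d13c > config.d13c_c4 and d15n < config.d15n_c4:
        label, rule = FoodWebLabel.C4_TERRESTRIAL, Rule.C4_RULE
    else:
        label, rule = FoodWebLabel.C3_TERRESTRIAL, Rule.DEFAULT_C3

    anomaly = config.d13c_marine < d13c <= config.d13c_c4 or (
        label is FoodWebLabel.C3_TERRESTRIAL
        and not (d13c < config.d13c_marine and d15n < config.d15n_marine)
    )
    return FoodWebAssignment(sample_id, config.food_web(label), rule, anomaly)


def classify_dataset(
    ds: Dataset, *, config: ClassifierConfig = DEFAULT_CONFIG
) -> list[FoodWebAssignment]:
    """Classify every sample in a dataset (one assignment per sample)."""
    return [
        classify(s.d13c_bulk, s.d15n_bulk, sample_id=s.sample_id, config=config)
        for s in ds
    ]


def class_counts(assignments: Iterable[FoodWebAssignment]) -> Counter[FoodWebLabel]:
    """Per-class sample counts for reporting."""
    return Counter(a.food_web.label for a in assignments)


def config_from_mapping(raw: Mapping[str, object]) -> ClassifierConfig:
    """Build a classifier config from flat keys (as read from YAML).

    Recognized keys: ``d13c_marine``, ``d15n_marine``, ``d13c_c4``,
    ``d15n_c4`` and ``beta_{marine,c4,c3}_{mean,sigma}``. Unknown keys are
    ignored so one file can configure several stages.
    """
    cfg = ClassifierConfig()
    thresholds = {
        k: float(raw[k])  # type: ignore[arg-type]
        for k in ("d13c_marine", "d15n_marine", "d13c_c4", "d15n_c4")
        if k in raw
    }
    betas = dict(DEFAULT_BETAS)
    short = {
        "marine": FoodWebLabel.MARINE,
        "c4": FoodWebLabel.C4_TERRESTRIAL,
        "c3": FoodWebLabel.C3_TERRESTRIAL,
    }
    for name, label in short.items():
        mean, sigma = betas[label]
        mean = float(raw.get(f"beta_{name}_mean", mean))  # type: ignore[arg-type]
        sigma = float(raw.get(f"beta_{name}_sigma", sigma))  # type: ignore[arg-type]
        betas[label] = (mean, sigma)
    return replace(cfg, betas=betas, **thresholds)
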