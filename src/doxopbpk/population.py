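"""Virtual cancer-population sampling.

Subjects carry the physiology the simulation engine needs: demographics
(age, sex, weight, height, BSA), cardiac output and hepatic blood flow,
an expected GFR for renal-clearance individualisation, liver scaling
factors, and blood volume. Sampling is reproducible: the spec seed is
split into one child seed per trial group, so group-level parallelism
cannot change results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_CONSTANTS,
    FCO_LIVER,
    PopulationConstants,
    gfr_for_age,
)
from .derive import LiverScalars


@dataclass(frozen=True)
class PopulationSpec:
    """Design of a virtual trial population (groups x subjects per group)."""

    n_subjects: int = 10      # per group
    n_trials: int = 10        # number of groups
    age_range: tuple[float, float] = (42.0, 72.0)
    female_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be in [0, 1]")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be nonempty")

    @property
    def total_subjects(self) -> int:
        return self.n_subjects * self.n_trials


@dataclass(frozen=True)
class VirtualSubject:
    """One sampled subject's physiology."""

    id: str
    age: float                     # years
    sex: Literal["male", "female"]
    weight: float                  # kg
    height: float                  # cm
    bsa: float                     # m2
    cardiac_output: float          # L/h
    q_hepatic: float               # L/h
    gfr: float                     # mL/min
    liver: LiverScalars
    blood_volume: float            # L
    group: int = 0


def spec_from_file(path) -> PopulationSpec:
    """Load a PopulationSpec from a YAML or JSON file."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)  # JSON is a YAML subset
    if "age_range" in doc:
        doc["age_range"] = tuple(doc["age_range"])
    return PopulationSpec(**doc)


def cardiac_output(bsa: float, age: float) -> float:
    """Cardiac output (L/h) of a cancer-population subject.

    CO = BSA * 60 * (3 - (age - 20)/100); the population has a minimum
    age of 20 years.
    """
    if bsa < 0:
        raise ValueError("bsa must be nonnegative")
    factor = 3.0 - (age - 20.0) / 100.0
    if factor <= 0:
        raise ValueError(f"age {age} outside the model's domain")
    return bsa * 60.0 * factor


def hepatic_flow(co: float, sex: str = "average") -> float:
    """Hepatic blood flow as the sex-specific liver fraction of CO."""
    if co < 0:
        raise ValueError("cardiac output must be nonnegative")
    try:
        return co * FCO_LIVER[sex]
    except KeyError:
        raise ValueError(f"unknown sex label {sex!r}") from None


def _truncated_lognormal(rng, mean, cv, n, n_sd):
    """Log-normal with arithmetic mean/CV, truncated at +-n_sd log-SD."""
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    mu = np.log(mean) - 0.5 * sigma ** 2
    z = rng.standard_normal(n)
    z = np.clip(z, -n_sd, n_sd)
    return np.exp(mu + sigma * z)


def _du_bois_bsa(height_cm, weight_kg):
    return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425


def sample_population(
    spec: PopulationSpec,
    constants: PopulationConstants = DEFAULT_CONSTANTS,
) -> list[VirtualSubject]:
    """Sample the full population (all groups), deterministically per seed."""
    groups = np.random.SeedSequence(spec.seed).spawn(spec.n_trials)
    subjects: list[VirtualSubject] = []
    for g, ss in enumerate(groups):
        rng = np.random.default_rng(ss)
        n = spec.n_subjects
        ages = rng.uniform(*spec.age_range, size=n)
        female = rng.random(n) < spec.female_fraction
        weights = _truncated_lognormal(
            rng, constants.weight_mean, constants.weight_cv, n,
            constants.truncation_sd,
        )
        heights = np.empty(n)
        for i, f in enumerate(female):
            sex = "female" if f else "male"
            z = np.clip(rng.standard_normal(), -constants.truncation_sd,
                        constants.truncation_sd)
            heights[i] = constants.height_mean[sex] + constants.height_sd[sex] * z
        bsas = _du_bois_bsa(heights, weights)

        for i in range(n):
            sex = "female" if female[i] else "male"
            co = cardiac_output(bsas[i], ages[i])
            qh = hepatic_flow(co, sex)
            gfr = gfr_for_age(ages[i], constants.gfr_table) * bsas[i] / 1.73
            liver = LiverScalars(
                liver_weight=constants.liver_weight_per_kg * weights[i],
                hpgl=constants.hpgl,
                mppgl=constants.mppgl,
                cppgl=constants.cppgl,
            )
            subjects.append(VirtualSubject(
                id=f"g{g + 1}s{i + 1}",
                age=float(ages[i]), sex=sex, weight=float(weights[i]),
                height=float(heights[i]), bsa=float(bsas[i]),
                cardiac_output=co, q_hepatic=qh, gfr=float(gfr),
                liver=liver,
                blood_volume=float(constants.blood_per_kg * weights[i]),
                group=g + 1,
            ))
    return subjects


def population_to_frame(subjects) -> pd.DataFrame:
    """Export sampled subjects as a tidy DataFrame (one row per subject)."""
    return pd.DataFrame([{
        "id": s.id, "group": s.group, "age": s.age, "sex": s.sex,
        "weight_kg": s.weight, "height_cm": s.height, "bsa_m2": s.bsa,
        "cardiac_output_L_h": s.cardiac_output, "q_hepatic_L_h": s.q_hepatic,
        "gfr_mL_min": s.gfr, "liver_weight_g": s.liver.liver_weight,
        "blood_volume_L": s.blood_volume,
    } for s in subjects])


def representative_subject(
    spec: PopulationSpec,
    constants: PopulationConstants = DEFAULT_CONSTANTS,
) -> VirtualSubject:
    """Population-mean covariates (age midpoint, mean weight/height, no noise)."""
    age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    height = (
        spec.female_fraction * constants.height_mean["female"]
        + (1 - spec.female_fraction) * constants.height_mean["male"]
    )
    weight = constants.weight_mean
    bsa = _du_bois_bsa(height, weight)
    co = cardiac_output(bsa, age)
    sex = "female" if spec.female_fraction >= 0.5 else "male"
    qh = co * FCO_LIVER["average"]
    return VirtualSubject(
        id="representative", age=age, sex=sex, weight=weight, height=height,
        bsa=bsa, cardiac_output=co, q_hepatic=qh,
        gfr=gfr_for_age(age, constants.gfr_table) * bsa / 1.73,
        liver=LiverScalars(
            liver_weight=constants.liver_weight_per_kg * weight,
            hpgl=constants.hpgl, mppgl=constants.mppgl, cppgl=constants.cppgl,
        ),
        blood_volume=constants.blood_per_kg * weight,
    )
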