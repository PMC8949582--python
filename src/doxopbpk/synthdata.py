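"""Synthetic stand-ins for the training and validation clinical studies.

The source studies' per-patient data are not deposited, so every pipeline
stage is exercised against synthetic cohorts with known ground truth:

* training-like study: 42-72 y.o. cancer patients given a single
  60 mg/m2 IV bolus, with plasma profiles generated from a three-
  compartment mammillary linear model (hence tri-exponential in form)
  whose clearances are the per-patient truth;
* validation-like study: 20-67 y.o. patients given 30 mg/m2 every 24 h
  for three days, as a bolus or an 8-h infusion, with bi-exponential
  (two-compartment) kinetics and rich early sampling plus peak/trough
  samples.

Observation noise is proportional log-normal; values below the assay
quantification limit (1 ng/mL) are censored out of the profiles and
counted in the study's truth record. All sampling is reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, FCO_LIVER, PopulationConstants
from .derive import PatientRecord
from .engine import ConcentrationProfile, _propagate
from .population import cardiac_output, _du_bois_bsa, _truncated_lognormal

LLOQ_MG_L = 1e-3  # assay quantification limit: 1 ng/mL


@dataclass(frozen=True)
class ExponentialModelSpec:
    """Sum-of-exponentials concentration model with proportional noise."""

    coefficients: tuple          # ((amplitude mg/L, rate 1/h), ...)
    sampling_times: tuple        # h
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        rates = [r for _, r in self.coefficients]
        if any(a < 0 for a, _ in self.coefficients) or any(r <= 0 for r in rates):
            raise ValueError("amplitudes must be >= 0 and rates > 0")
        if len(set(rates)) != len(rates):
            raise ValueError("rates must be distinct")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")


@dataclass
class SyntheticStudy:
    """Cohort, profiles and per-patient ground truth, aligned by id."""

    cohort: list                      # PatientRecord
    profiles: list                    # ConcentrationProfile
    truth: dict                       # id -> dict of generating parameters
    regimen: dict = field(default_factory=dict)
    n_censored: int = 0


def exponential_profile(spec: ExponentialModelSpec) -> ConcentrationProfile:
    """Evaluate C(t) = sum_i A_i exp(-l_i t), with log-normal noise.

    noise_cv = 0 returns the exact curve. Noise multiplies each sample by
    an independent log-normal factor with unit mean and the given CV.
    """
    t = np.asarray(spec.sampling_times, dtype=float)
    c = np.zeros_like(t)
    for a, lam in spec.coefficients:
        c = c + a * np.exp(-lam * t)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log(1.0 + spec.noise_cv ** 2))
        c = c * rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=t.shape)
    return ConcentrationProfile(times=t, conc=c)


def exponential_auc(coefficients, t_end: float | None = None) -> float:
    """Closed-form AUC of a sum of exponentials, over [0, t_end] or [0, inf)."""
    total = 0.0
    for a, lam in coefficients:
        total += a / lam if t_end is None else a / lam * (1.0 - np.exp(-lam * t_end))
    return total


def _mammillary_exponentials(volumes, flows, cl, dose):
    """Bolus tri-/bi-exponential coefficients of a mammillary model.

    ``volumes`` = (V1, ...Vp) in L; ``flows`` = inter-compartmental
    clearances Q_1j in L/h, one per peripheral compartment; ``cl`` the
    central elimination clearance. Returns ((A_i, lambda_i), ...) for the
    central concentration after a bolus ``dose``.
    """
    p = len(volumes) - 1
    n = p + 1
    M = np.zeros((n, n))
    M[0, 0] = -(cl + sum(flows)) / volumes[0]
    for j in range(p):
        M[0, j + 1] = flows[j] / volumes[j + 1]
        M[j + 1, 0] = flows[j] / volumes[0]
        M[j + 1, j + 1] = -flows[j] / volumes[j + 1]
    w, v = np.linalg.eig(M)
    x0 = np.zeros(n)
    x0[0] = dose
    c = np.linalg.solve(v, x0)
    amps = (v[0, :] * c).real / volumes[0]
    lams = -w.real
    order = np.argsort(lams)[::-1]
    return tuple((float(max(amps[i], 0.0)), float(lams[i])) for i in order)


def _sample_patients(rng, n, age_range, constants, cl_mean, cl_cv,
                     fe_mean, fe_sd, scr_mean=88.0, scr_cv=0.15):
    """Common covariate/clearance sampler for both study kinds."""
    ages = rng.uniform(*age_range, size=n)
    weights = _truncated_lognormal(rng, constants.weight_mean,
                                   constants.weight_cv, n,
                                   constants.truncation_sd)
    heights = 170.0 + 7.0 * np.clip(rng.standard_normal(n), -3, 3)
    bsas = _du_bois_bsa(heights, weights)
    scrs = _truncated_lognormal(rng, scr_mean, scr_cv, n,
                                constants.truncation_sd)
    cls_, fes = np.empty(n), np.empty(n)
    for i in range(n):
        # rejection step: keep hepatic extraction below 1 for every patient
        q_h = cardiac_output(bsas[i], ages[i]) * FCO_LIVER["average"]
        for _ in range(1000):
            cl = _truncated_lognormal(rng, cl_mean, cl_cv, 1,
                                      constants.truncation_sd)[0]
            fe = float(np.clip(fe_mean + fe_sd * rng.standard_normal(),
                               0.02, 0.30))
            if (cl * (1 - fe)) / 1.15 < 0.95 * q_h:
                break
        else:  # pragma: no cover - parameters would have to be absurd
            raise RuntimeError("could not sample a feasible patient")
        cls_[i], fes[i] = cl, fe
    return ages, weights, bsas, scrs, cls_, fes


def make_training_study(
    n: int = 8,
    seed: int = 0,
    noise_cv: float = 0.15,
    constants: PopulationConstants = DEFAULT_CONSTANTS,
    cl_plasma_mean: float = 51.75,
    cl_plasma_cv: float = 0.18,
    fe_mean: float = 0.11,
    fe_sd: float = 0.02,
    vss_per_kg: float = 31.923,
    include_extraction_outlier: bool = False,
    sampling_times=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0, 96.0, 168.0),
) -> SyntheticStudy:
    """Training-like study: single 60 mg/m2 bolus, tri-exponential profiles.

    Per-patient true plasma and renal clearances are drawn so that the
    mean urinary fraction is ~``fe_mean`` and hepatic extraction stays
    below 1; an optional engineered outlier with extraction above 1
    exercises the exclusion path downstream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ages, weights, bsas, scrs, cls_, fes = _sample_patients(
        rng, n, (42.0, 72.0), constants, cl_plasma_mean, cl_plasma_cv,
        fe_mean, fe_sd)

    cohort, profiles, truth = [], [], {}
    n_censored = 0
    for i in range(n):
        pid = f"t{i + 1:02d}"
        dose = 60.0 * bsas[i]
        vss = vss_per_kg * weights[i]
        v1 = 0.5 * weights[i]
        v2 = 3.0 * weights[i]
        volumes = (v1, v2, vss - v1 - v2)
        coeffs = _mammillary_exponentials(volumes, (150.0, 40.0),
                                          cls_[i], dose)
        prof = exponential_profile(ExponentialModelSpec(
            coefficients=coeffs, sampling_times=tuple(sampling_times),
            noise_cv=noise_cv, seed=int(rng.integers(2 ** 31 - 1)),
        ))
        keep = prof.conc >= LLOQ_MG_L
        n_censored += int((~keep).sum())
        profiles.append(ConcentrationProfile(prof.times[keep],
                                             prof.conc[keep], pid))
        cohort.append(PatientRecord(
            id=pid, age=float(ages[i]), bsa=float(bsas[i]),
            scr=float(scrs[i]), weight=float(weights[i]),
            cl_plasma=float(cls_[i]), cl_renal=float(cls_[i] * fes[i]),
        ))
        truth[pid] = {"cl_plasma": float(cls_[i]),
                      "cl_renal": float(cls_[i] * fes[i]),
                      "fe": float(fes[i]), "vss_L": float(vss),
                      "dose_mg": float(dose), "coefficients": coeffs}

    if include_extraction_outlier:
        # hepatic blood clearance engineered to 1.05x the hepatic flow
        age, bsa, w = 55.0, 1.75, 70.0
        q_h = cardiac_output(bsa, age) * FCO_LIVER["average"]
        fe = 0.05
        cl_p = 1.05 * q_h * 1.15 / (1 - fe)
        cohort.append(PatientRecord(
            id="outlier", age=age, bsa=bsa, scr=88.0, weight=w,
            cl_plasma=cl_p, cl_renal=cl_p * fe,
        ))
        truth["outlier"] = {"cl_plasma": cl_p, "cl_renal": cl_p * fe,
                            "fe": fe, "engineered_extraction": 1.05}

    return SyntheticStudy(
        cohort=cohort, profiles=profiles, truth=truth,
        regimen={"dose_per_bsa": 60.0, "route": "IV",
                 "infusion_duration_h": 2.0 / 60.0, "start_times_h": (0.0,)},
        n_censored=n_censored,
    )


_VALIDATION_SAMPLING = (
    5 / 60, 10 / 60, 15 / 60, 30 / 60, 1.0, 2.0, 4.0,          # rich, dose 1
    23.9, 24.0 + 5 / 60, 47.9, 48.0 + 5 / 60, 72.0, 96.0, 120.0,  # peaks/troughs
)


def make_validation_study(
    arm: str,
    n: int = 7,
    seed: int = 0,
    noise_cv: float = 0.15,
    constants: PopulationConstants = DEFAULT_CONSTANTS,
    cl_plasma_mean: float = 56.0,
    cl_plasma_cv: float = 0.20,
    vss_per_kg: float = 20.0,
) -> SyntheticStudy:
    """Validation-like study: 30 mg/m2 on days 1-3, bolus or 8-h infusion.

    Profiles follow a two-compartment (bi-exponential) model; the bolus
    arm superposes bolus responses, the infusion arm integrates the
    zero-order input exactly. Sampling emulates rich 5-240 min draws after
    the first dose plus peak/trough samples around later doses.
    """
    if arm not in ("bolus", "infusion8h"):
        raise ValueError("arm must be 'bolus' or 'infusion8h'")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ages, weights, bsas, scrs, cls_, fes = _sample_patients(
        rng, n, (20.0, 67.0), constants, cl_plasma_mean, cl_plasma_cv,
        0.11, 0.02)
    duration = 8.0 if arm == "infusion8h" else 1.0 / 60.0
    starts = (0.0, 24.0, 48.0)

    cohort, profiles, truth = [], [], {}
    n_censored = 0
    for i in range(n):
        pid = f"v{i + 1:02d}"
        dose = 30.0 * bsas[i]
        v1 = 0.3 * weights[i]
        v2 = vss_per_kg * weights[i] - v1
        # two-compartment system with an elimination sink, solved exactly
        A = np.array([
            [-(cls_[i] + 150.0) / v1, 150.0 / v2, 0.0],
            [150.0 / v1, -150.0 / v2, 0.0],
            [cls_[i] / v1, 0.0, 0.0],
        ])
        tgrid = np.unique(np.concatenate(([0.0], _VALIDATION_SAMPLING)))
        events = [(t0, t0 + duration, dose / duration) for t0 in starts]
        states = _propagate(A, tgrid, events, 0)
        conc = states[:, 0] / v1
        prof = ConcentrationProfile(tgrid, conc)
        keep = prof.times > 0
        t_obs, c_obs = prof.times[keep], prof.conc[keep]
        if noise_cv > 0:
            sigma = np.sqrt(np.log(1.0 + noise_cv ** 2))
            c_obs = c_obs * rng.lognormal(-0.5 * sigma ** 2, sigma,
                                          size=c_obs.shape)
        quantified = c_obs >= LLOQ_MG_L
        n_censored += int((~quantified).sum())
        profiles.append(ConcentrationProfile(t_obs[quantified],
                                             c_obs[quantified], pid))
        cohort.append(PatientRecord(
            id=pid, age=float(ages[i]), bsa=float(bsas[i]),
            scr=float(scrs[i]), weight=float(weights[i]),
            cl_plasma=float(cls_[i]), cl_renal=float(cls_[i] * fes[i]),
        ))
        truth[pid] = {"cl_plasma": float(cls_[i]),
                      "cl_renal": float(cls_[i] * fes[i]),
                      "v1_L": float(v1), "v2_L": float(v2),
                      "dose_mg": float(dose)}

    return SyntheticStudy(
        cohort=cohort, profiles=profiles, truth=truth,
        regimen={"dose_per_bsa": 30.0, "route": "IV",
                 "infusion_duration_h": duration, "start_times_h": starts},
        n_censored=n_censored,
    )
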