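"""Plasma concentration-time simulation for virtual subjects.

Two distribution topologies are available:

* minimal PBPK: a systemic pool (blood plus rapidly equilibrating
  extracellular water) exchanging with a single adjusting compartment
  (SAC) of volume V_sac at flow Q_sac, with a well-stirred liver in series
  on the hepatic blood flow and linear renal elimination from the systemic
  pool;
* full PBPK: venous blood -> lung -> arterial blood feeding perfusion-
  limited tissues in parallel, with the liver receiving hepatic arterial
  plus portal (gut and spleen) flow, well-stirred hepatic elimination
  split into biliary and metabolic routes, and GFR-scaled renal
  elimination from the kidney.

Both systems are linear and time-invariant between dosing events, so each
segment is propagated with a matrix exponential (exact to machine
precision, with closed mass balance); infusions enter as piecewise-
constant source terms. Concentrations are tracked in whole blood and
reported as plasma via the blood:plasma ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .constants import (
    DEFAULT_CONSTANTS,
    HEPATIC_ARTERY_FRACTION,
    SPLEEN_FLOW_FRACTION,
    TISSUE_FLOW_FRACTIONS,
    TISSUE_VOLUMES_L_PER_KG,
    PopulationConstants,
)
from .derive import DrugModel, fraction_unbound_blood
from .partition import kp_rodgers_rowland
from .population import PopulationSpec, VirtualSubject, sample_population

MASS_BALANCE_RTOL = 1e-6


class SolverError(RuntimeError):
    """Simulation failure, annotated with the subject id."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DosingRegimen:
    """Intravenous dose events normalised to body surface area."""

    dose_per_bsa: float          # mg/m2 per dose
    infusion_duration: float     # h; 2-min bolus-infusion = 0.0333...
    start_times: tuple = (0.0,)  # h
    route: str = "IV"

    def __post_init__(self):
        if self.infusion_duration <= 0:
            raise ValueError("infusion_duration must be positive "
                             "(bolus doses are short zero-order infusions)")
        starts = tuple(self.start_times)
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("start_times must be strictly increasing")
        if self.route != "IV":
            raise ValueError("only intravenous dosing is supported")

    @property
    def n_doses(self) -> int:
        return len(self.start_times)

    def events(self, bsa: float):
        """(start, end, rate mg/h) triples for a subject of the given BSA."""
        amount = self.dose_per_bsa * bsa
        rate = amount / self.infusion_duration
        return [(t, t + self.infusion_duration, rate) for t in self.start_times]

    def total_dose(self, bsa: float) -> float:
        return self.dose_per_bsa * bsa * self.n_doses


@dataclass(frozen=True)
class ConcentrationProfile:
    """Plasma concentration (mg/L) on a strictly increasing time grid (h)."""

    times: np.ndarray
    conc: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < -1e-12):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", np.maximum(c, 0.0))


# ---------------------------------------------------------------------------
# piecewise-constant-input propagation of x' = A x + b(t)
# ---------------------------------------------------------------------------

def _propagate(A: np.ndarray, grid: np.ndarray, events, dose_index: int
               ) -> np.ndarray:
    """States at every grid time for the linear system with infusion events.

    ``events`` are (start, end, rate) infusions into state ``dose_index``.
    Exact within each segment via the augmented matrix exponential
    exp([[A, b], [0, 0]] * dt) = [[P, q], [0, 1]] with x(t+dt) = P x + q.
    """
    n = A.shape[0]
    edges = {float(t) for t in grid}
    for s, e, _ in events:
        edges.add(float(s))
        edges.add(float(e))
    t0, t_end = float(grid[0]), float(grid[-1])
    times = np.array(sorted(t for t in edges if t0 <= t <= t_end))

    grid_pos = np.searchsorted(times, grid)
    out = np.empty((len(grid), n))
    x = np.zeros(n)
    cache: dict = {}
    k_out = 0
    if grid_pos[0] == 0:
        out[0] = x
        k_out = 1
    for i in range(len(times) - 1):
        a, b = times[i], times[i + 1]
        dt = b - a
        rate = sum(r for s, e, r in events if s <= a + 1e-12 and b <= e + 1e-12)
        key = (round(dt, 12), rate)
        if key not in cache:
            m = np.zeros((n + 1, n + 1))
            m[:n, :n] = A * dt
            m[dose_index, n] = rate * dt
            em = expm(m)
            cache[key] = (em[:n, :n], em[:n, n])
        p, q = cache[key]
        x = p @ x + q
        if k_out < len(grid) and grid_pos[k_out] == i + 1:
            out[k_out] = x
            k_out += 1
    if k_out != len(grid):
        raise SolverError("internal grid alignment failure")
    return out


def _delivered(grid: np.ndarray, events) -> np.ndarray:
    """Cumulative dose (mg) delivered by each grid time."""
    total = np.zeros_like(grid, dtype=float)
    for s, e, r in events:
        total += r * np.clip(grid - s, 0.0, e - s)
    return total


# ---------------------------------------------------------------------------
# model matrices (blood-concentration referenced)
# ---------------------------------------------------------------------------

def _renal_cl_blood(subject: VirtualSubject, model: DrugModel,
                    constants: PopulationConstants) -> float:
    cl_plasma = model.ref_cl_renal * subject.gfr / constants.gfr_ref
    return cl_plasma / model.physchem.bp_ratio


def _mpbpk_matrix(subject, model, constants):
    bp = model.physchem.bp_ratio
    fu_b = fraction_unbound_blood(model.physchem.fu_plasma, bp)
    v_sys = constants.systemic_pool_per_kg * subject.weight
    v_sac = model.v_sac * subject.weight / bp   # plasma- to blood-referenced
    v_liv = subject.liver.liver_weight / 1050.0
    q_sac = model.q_sac
    q_h = subject.q_hepatic
    cl_r = _renal_cl_blood(subject, model, constants)
    cl_bile = fu_b * model.whole_liver_clint_bile(subject.liver)
    cl_met = fu_b * model.whole_liver_clint_met(subject.liver)

    # states: systemic, SAC, liver, bile sink, metabolite sink, urine sink
    A = np.zeros((6, 6))
    A[0, 0] = -(q_sac + q_h + cl_r) / v_sys
    A[0, 1] = q_sac / v_sac
    A[0, 2] = q_h / v_liv
    A[1, 0] = q_sac / v_sys
    A[1, 1] = -q_sac / v_sac
    A[2, 0] = q_h / v_sys
    A[2, 2] = -(q_h + cl_bile + cl_met) / v_liv
    A[3, 2] = cl_bile / v_liv
    A[4, 2] = cl_met / v_liv
    A[5, 0] = cl_r / v_sys
    return A, 0, v_sys


_FPBPK_TISSUES = ("adipose", "bone", "brain", "gut", "heart", "kidney",
                  "liver", "muscle", "skin", "spleen", "rest")


def _fpbpk_matrix(subject, model, constants, kps):
    bp = model.physchem.bp_ratio
    fu_b = fraction_unbound_blood(model.physchem.fu_plasma, bp)
    co = subject.cardiac_output
    w = subject.weight

    q = {t: TISSUE_FLOW_FRACTIONS[t] * co for t in TISSUE_FLOW_FRACTIONS}
    q["spleen"] = SPLEEN_FLOW_FRACTION * co
    q_ha = HEPATIC_ARTERY_FRACTION * co
    # split the subject's hepatic flow into arterial + portal supply
    q["gut"] = subject.q_hepatic - q_ha - q["spleen"]
    if q["gut"] <= 0:
        raise SolverError(f"subject {subject.id}: hepatic flow below the "
                          "arterial+splenic supply")
    q["rest"] = co - q_ha - sum(q.values())
    if q["rest"] <= 0:
        raise SolverError(f"subject {subject.id}: flow fractions exceed CO")
    q_liver_out = q_ha + q["gut"] + q["spleen"]

    v_ven = subject.blood_volume * constants.venous_fraction
    v_art = subject.blood_volume - v_ven
    # effective (Kp-scaled, blood-referenced) tissue volumes
    v_eff = {}
    for t in _FPBPK_TISSUES:
        vol = (subject.liver.liver_weight / 1050.0 if t == "liver"
               else TISSUE_VOLUMES_L_PER_KG[t] * w)
        v_eff[t] = vol * kps[t] / bp
    v_lung = TISSUE_VOLUMES_L_PER_KG["lung"] * w * kps["lung"] / bp

    cl_r = _renal_cl_blood(subject, model, constants)
    cl_bile = fu_b * model.whole_liver_clint_bile(subject.liver)
    cl_met = fu_b * model.whole_liver_clint_met(subject.liver)

    names = ["venous", "lung", "arterial", *_FPBPK_TISSUES,
             "bile", "metabolite", "urine"]
    idx = {name: i for i, name in enumerate(names)}
    n = len(names)
    A = np.zeros((n, n))

    A[idx["venous"], idx["venous"]] -= co / v_ven
    A[idx["lung"], idx["venous"]] += co / v_ven
    A[idx["lung"], idx["lung"]] -= co / v_lung
    A[idx["arterial"], idx["lung"]] += co / v_lung
    A[idx["arterial"], idx["arterial"]] -= co / v_art

    for t in _FPBPK_TISSUES:
        if t == "liver":
            continue
        A[idx[t], idx["arterial"]] += q[t] / v_art
        A[idx[t], idx[t]] -= q[t] / v_eff[t]
        dest = "liver" if t in ("gut", "spleen") else "venous"
        A[idx[dest], idx[t]] += q[t] / v_eff[t]

    A[idx["liver"], idx["arterial"]] += q_ha / v_art
    A[idx["liver"], idx["liver"]] -= (q_liver_out + cl_bile + cl_met) / v_eff["liver"]
    A[idx["venous"], idx["liver"]] += q_liver_out / v_eff["liver"]
    A[idx["bile"], idx["liver"]] += cl_bile / v_eff["liver"]
    A[idx["metabolite"], idx["liver"]] += cl_met / v_eff["liver"]

    A[idx["kidney"], idx["kidney"]] -= cl_r / v_eff["kidney"]
    A[idx["urine"], idx["kidney"]] += cl_r / v_eff["kidney"]
    return A, idx["venous"], v_ven


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def default_grid(duration: float = 168.0, n_samples: int = 10_000) -> np.ndarray:
    """The default virtual sampling grid: n_samples points over duration h."""
    return np.linspace(0.0, duration, n_samples)


def simulate(
    subject: VirtualSubject,
    model: DrugModel,
    regimen: DosingRegimen,
    grid: np.ndarray | None = None,
    constants: PopulationConstants = DEFAULT_CONSTANTS,
    kps: dict | None = None,
    check_mass_balance: bool = True,
) -> ConcentrationProfile:
    """Simulate one subject's plasma concentration profile.

    The per-subject dose is ``dose_per_bsa * bsa`` per event. Mass balance
    (compartments plus elimination sinks against delivered dose) is checked
    at every output time unless disabled.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    events = regimen.events(subject.bsa)

    if model.distribution_mode == "mPBPK":
        A, dose_index, v_obs = _mpbpk_matrix(subject, model, constants)
    else:
        if kps is None:
            kps = kp_rodgers_rowland(model.physchem, kp_scalar=model.kp_scalar)
        A, dose_index, v_obs = _fpbpk_matrix(subject, model, constants, kps)

    try:
        states = _propagate(A, grid, events, dose_index)
    except SolverError:
        raise
    except Exception as err:  # pragma: no cover - diagnostic wrapper
        raise SolverError(f"subject {subject.id}: {err}") from err

    if check_mass_balance:
        delivered = _delivered(grid, events)
        total_dose = regimen.total_dose(subject.bsa)
        gap = np.max(np.abs(states.sum(axis=1) - delivered)) / total_dose
        if gap > MASS_BALANCE_RTOL:
            raise SolverError(
                f"subject {subject.id}: mass balance violated "
                f"(relative gap {gap:.2e})"
            )

    conc_blood = states[:, dose_index] / v_obs
    conc_plasma = conc_blood / model.physchem.bp_ratio
    return ConcentrationProfile(times=grid, conc=conc_plasma,
                                subject_id=subject.id)


def simulate_amounts(subject, model, regimen, grid=None,
                     constants=DEFAULT_CONSTANTS, kps=None):
    """Low-level variant returning the full state trajectory (mg amounts).

    Returns (grid, states, state_names, delivered_dose). Useful for mass-
    balance and steady-state diagnostics.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    events = regimen.events(subject.bsa)
    if model.distribution_mode == "mPBPK":
        A, dose_index, _ = _mpbpk_matrix(subject, model, constants)
        names = ["systemic", "sac", "liver", "bile", "metabolite", "urine"]
    else:
        if kps is None:
            kps = kp_rodgers_rowland(model.physchem, kp_scalar=model.kp_scalar)
        A, dose_index, _ = _fpbpk_matrix(subject, model, constants, kps)
        names = ["venous", "lung", "arterial", *_FPBPK_TISSUES,
                 "bile", "metabolite", "urine"]
    states = _propagate(A, grid, events, dose_index)
    return grid, states, names, _delivered(grid, events)


def run_trial(
    population: PopulationSpec,
    model: DrugModel,
    regimen: DosingRegimen,
    grid: np.ndarray | None = None,
    constants: PopulationConstants = DEFAULT_CONSTANTS,
    window: tuple[float, float] | None = None,
):
    """Simulate a whole virtual trial and summarise it.

    Samples the population (deterministically from the spec seed), runs
    every subject under the regimen, and returns a
    :class:`doxopbpk.metrics.TrialResult` with the mean and 5th/95th
    percentile curves plus population mean AUC over ``window`` and Cmax.
    """
    from .metrics import summarize_population

    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    subjects = sample_population(population, constants)
    kps = None
    if model.distribution_mode == "fPBPK":
        kps = kp_rodgers_rowland(model.physchem, kp_scalar=model.kp_scalar)
    profiles = [
        simulate(s, model, regimen, grid, constants, kps=kps)
        for s in subjects
    ]
    return summarize_population(profiles, window=window)
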