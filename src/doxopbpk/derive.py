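"""Middle-out derivation of drug parameters from clinical PK summaries.

The derivation chain turns per-patient clinical summaries (age, body
surface area, serum creatinine, plasma and renal clearance) plus literature
constants into the drug-specific inputs a PBPK simulation needs:

* a reference renal clearance for a healthy 20-30 y.o. male, obtained by
  normalising each patient's renal clearance to a reference GFR;
* whole-liver intrinsic clearance, obtained by inverting the well-stirred
  liver model with each patient's hepatic blood flow and the fraction
  unbound in blood;
* a biliary/metabolic split of the hepatic intrinsic clearance from the
  mass-balance elimination fractions; and
* in vitro-system scaled intrinsic clearances (per 10^6 hepatocytes, per mg
  microsomal protein, per mg cytosolic protein) via the liver scaling
  factors, optionally distributed over in vitro systems according to the
  enzymology of the reductive metabolic pathways.

Patients whose back-calculated hepatic blood clearance reaches the hepatic
blood flow have an extraction ratio >= 1, which the well-stirred model
cannot represent; they are excluded with a logged reason.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_CONSTANTS,
    FCO_LIVER,
    PopulationConstants,
    gfr_for_age,
)

logger = logging.getLogger(__name__)

UL_PER_MIN_TO_L_PER_H = 60e-6  # 1 uL/min = 6e-5 L/h


class ExtractionExceedsFlowError(ValueError):
    """Hepatic blood clearance at or above hepatic blood flow."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinical summary (units: years, m2, umol/L, kg, L/h)."""

    id: str
    age: float
    bsa: float
    scr: float
    cl_plasma: float
    cl_renal: float
    weight: float | None = None

    def __post_init__(self):
        if self.age <= 0 or self.bsa <= 0:
            raise ValueError(f"patient {self.id}: age and bsa must be positive")
        if not (0.0 <= self.cl_renal <= self.cl_plasma):
            raise ValueError(
                f"patient {self.id}: need 0 <= cl_renal <= cl_plasma "
                f"(got {self.cl_renal}, {self.cl_plasma})"
            )


@dataclass(frozen=True)
class DrugPhysChem:
    """Physicochemical properties of the drug."""

    mw: float                 # g/mol
    logp: float
    drug_type: Literal["ampholyte", "acid", "base", "neutral"]
    fu_plasma: float          # fraction unbound in plasma
    bp_ratio: float           # blood:plasma concentration ratio
    pka_acid: float | None = None
    pka_base: float | None = None

    def __post_init__(self):
        if not (0.0 < self.fu_plasma <= 1.0):
            raise ValueError("fu_plasma must be in (0, 1]")
        if self.bp_ratio <= 0:
            raise ValueError("bp_ratio must be positive")


@dataclass(frozen=True)
class EliminationFractions:
    """Fractions of dose leaving by bile (unchanged), metabolism and urine."""

    f_bile: float
    f_met: float
    f_e: float

    def __post_init__(self):
        for name in ("f_bile", "f_met", "f_e"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(self.f_bile + self.f_met + self.f_e - 1.0) > 1e-9:
            raise ValueError("elimination fractions must sum to 1")


@dataclass(frozen=True)
class LiverScalars:
    """Absolute liver scaling factors for one subject."""

    liver_weight: float  # g
    hpgl: float          # 10^6 cells per g liver
    mppgl: float         # mg microsomal protein per g liver
    cppgl: float         # mg cytosolic protein per g liver

    def __post_init__(self):
        for name in ("liver_weight", "hpgl", "mppgl", "cppgl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class MetabolicSplit:
    """Relative contribution of each in vitro system to metabolism."""

    frac_hlm: float = 0.37  # microsomal (one-electron reduction)
    frac_hlc: float = 0.60  # cytosolic (two-electron reduction, AKR/CBR)
    frac_hep: float = 0.03  # residual pathways, per 10^6 hepatocytes

    def __post_init__(self):
        if abs(self.frac_hlm + self.frac_hlc + self.frac_hep - 1.0) > 1e-9:
            raise ValueError("metabolic split fractions must sum to 1")


@dataclass
class DrugModel:
    """All drug-specific constants for one simulation-ready model variant."""

    physchem: DrugPhysChem
    ref_cl_renal: float           # L/h (plasma), healthy 20-30 y.o. male
    clint_bile: float             # uL/min/10^6 cells
    metabolic_mode: Literal["HEP", "DIST"]
    clint_met_hep: float = 0.0    # uL/min/10^6 cells (HEP mode or DIST share)
    clint_met_hlm: float = 0.0    # uL/min/mg microsomal protein (DIST)
    clint_met_hlc: float = 0.0    # uL/min/mg cytosolic protein (DIST)
    distribution_mode: Literal["mPBPK", "fPBPK"] = "mPBPK"
    vss: float = 0.0              # L/kg, plasma-referenced
    kp_scalar: float | None = None  # fPBPK only
    v_sac: float | None = None    # L/kg, plasma-referenced (mPBPK only)
    q_sac: float | None = None    # L/h (mPBPK only)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.distribution_mode == "mPBPK":
            if self.v_sac is None or self.q_sac is None:
                raise ValueError("mPBPK model requires v_sac and q_sac")
            if self.kp_scalar is not None:
                raise ValueError("mPBPK model must not set kp_scalar")
        else:
            if self.kp_scalar is None:
                raise ValueError("fPBPK model requires kp_scalar")
            if self.v_sac is not None or self.q_sac is not None:
                raise ValueError("fPBPK model must not set v_sac/q_sac")
        for name in ("ref_cl_renal", "clint_bile", "clint_met_hep",
                     "clint_met_hlm", "clint_met_hlc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- whole-liver scale-up used by the simulation engine ----------------
    def whole_liver_clint_bile(self, liver: LiverScalars) -> float:
        """Biliary intrinsic clearance scaled back to the whole liver, L/h."""
        return unscale_intrinsic(self.clint_bile, liver, "HEP")

    def whole_liver_clint_met(self, liver: LiverScalars) -> float:
        """Metabolic intrinsic clearance scaled back to the whole liver, L/h."""
        if self.metabolic_mode == "HEP":
            return unscale_intrinsic(self.clint_met_hep, liver, "HEP")
        return (
            unscale_intrinsic(self.clint_met_hlm, liver, "HLM")
            + unscale_intrinsic(self.clint_met_hlc, liver, "HLC")
            + unscale_intrinsic(self.clint_met_hep, liver, "HEP")
        )

    def to_json(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DrugModel":
        with open(path) as fh:
            doc = json.load(fh)
        doc["physchem"] = DrugPhysChem(**doc["physchem"])
        return cls(**doc)


# ---------------------------------------------------------------------------
# renal clearance
# ---------------------------------------------------------------------------

def egfr_davies_shock(age: float, bsa: float, gfr_table=None) -> float:
    """Expected GFR (mL/min) from the per-age-group table, scaled to BSA.

    eGFR_i = GFR_group(age) * BSA_i / 1.73.
    """
    if bsa <= 0:
        raise ValueError("bsa must be positive")
    table = gfr_table if gfr_table is not None else DEFAULT_CONSTANTS.gfr_table
    return gfr_for_age(age, table) * bsa / 1.73


def egfr_wright(
    age: float, bsa: float, scr: float,
    sex: Literal["male", "female", "unknown"] = "unknown",
) -> float:
    """Expected GFR (mL/min) from age, BSA and serum creatinine (umol/L).

    eGFR = (6580 - 38.8*age) * BSA * (1 - 0.168*SEX) / SCr with SEX = 0 for
    males and 1 for females; unknown sex averages the two.
    """
    if scr <= 0:
        raise ValueError("serum creatinine must be positive")
    if 38.8 * age >= 6580:
        raise ValueError("age outside the validity range of the formula")
    base = (6580.0 - 38.8 * age) * bsa / scr
    if sex == "male":
        return base
    if sex == "female":
        return base * (1.0 - 0.168)
    if sex == "unknown":
        return base * (1.0 + (1.0 - 0.168)) / 2.0
    raise ValueError(f"unknown sex label {sex!r}")


def reference_renal_clearance(cl_renal: float, egfr: float, gfr_ref: float) -> float:
    """Normalise a patient's renal clearance to a healthy reference GFR.

    refCL_R = CL_R * GFR_ref / eGFR. Individualising a subject's renal
    clearance at simulation time applies the exact inverse.
    """
    if egfr <= 0 or gfr_ref <= 0:
        raise ValueError("GFR values must be positive")
    return cl_renal * gfr_ref / egfr


# ---------------------------------------------------------------------------
# hepatic clearance
# ---------------------------------------------------------------------------

def fraction_unbound_blood(fu_plasma: float, bp_ratio: float) -> float:
    """Map plasma-referenced binding to whole blood: fu_b = fu_p / R_B:P."""
    if fu_plasma <= 0 or bp_ratio <= 0:
        raise ValueError("fu_plasma and bp_ratio must be positive")
    return fu_plasma / bp_ratio


def blood_clearance(cl_plasma: float, bp_ratio: float) -> float:
    """Convert a plasma clearance to a blood clearance: CL_b = CL_p / R_B:P."""
    if bp_ratio <= 0:
        raise ValueError("bp_ratio must be positive")
    return cl_plasma / bp_ratio


def plasma_clearance(cl_blood: float, bp_ratio: float) -> float:
    """Inverse of :func:`blood_clearance`."""
    if bp_ratio <= 0:
        raise ValueError("bp_ratio must be positive")
    return cl_blood * bp_ratio


def well_stirred_clearance(q_h: float, fu_b: float, clint: float) -> float:
    """Hepatic blood clearance under the well-stirred liver model.

    CL_H,b = Q_H * fu_b * CLint / (Q_H + fu_b * CLint); always below Q_H.
    """
    if q_h < 0 or fu_b < 0 or clint < 0:
        raise ValueError("arguments must be nonnegative")
    if q_h == 0:
        return 0.0
    x = fu_b * clint
    return q_h * x / (q_h + x)


def intrinsic_from_blood_clearance(q_h: float, cl_blood: float, fu_b: float) -> float:
    """Invert the well-stirred model for the intrinsic unbound clearance.

    CLu_int = Q_H * CL_H,b / (fu_b * (Q_H - CL_H,b)). Raises
    :class:`ExtractionExceedsFlowError` when CL_H,b >= Q_H (extraction ratio
    at or above 1, outside the model's domain).
    """
    if fu_b <= 0:
        raise ValueError("fu_b must be positive")
    if cl_blood < 0:
        raise ValueError("cl_blood must be nonnegative")
    if cl_blood >= q_h:
        raise ExtractionExceedsFlowError(
            f"hepatic blood clearance {cl_blood:.3g} L/h >= hepatic blood "
            f"flow {q_h:.3g} L/h"
        )
    return q_h * cl_blood / (fu_b * (q_h - cl_blood))


def biliary_fraction_of_hepatic(f_bile: float, f_e: float) -> float:
    """Fraction of hepatic clearance that is biliary: f_bile / (1 - f_e)."""
    if not (0.0 <= f_e < 1.0):
        raise ValueError("f_e must be in [0, 1)")
    if f_bile < 0:
        raise ValueError("f_bile must be nonnegative")
    return f_bile / (1.0 - f_e)


# ---------------------------------------------------------------------------
# in vitro-in vivo scaling
# ---------------------------------------------------------------------------

_SYSTEM_FACTOR = {"HEP": "hpgl", "HLM": "mppgl", "HLC": "cppgl"}


def scale_intrinsic(clint_whole_liver: float, liver: LiverScalars,
                    system: str) -> float:
    """Scale a whole-liver intrinsic clearance (L/h) down to an in vitro unit.

    Converts L/h to uL/min and divides by liver weight times the per-gram
    factor of the chosen system (HEP -> uL/min/10^6 cells, HLM/HLC ->
    uL/min/mg protein).
    """
    factor = _system_factor(liver, system)
    return clint_whole_liver / UL_PER_MIN_TO_L_PER_H / (liver.liver_weight * factor)


def unscale_intrinsic(clint_per_unit: float, liver: LiverScalars,
                      system: str) -> float:
    """Exact inverse of :func:`scale_intrinsic` (back to whole-liver L/h)."""
    factor = _system_factor(liver, system)
    return clint_per_unit * liver.liver_weight * factor * UL_PER_MIN_TO_L_PER_H


def _system_factor(liver: LiverScalars, system: str) -> float:
    try:
        return getattr(liver, _SYSTEM_FACTOR[system])
    except KeyError:
        raise ValueError(f"unknown in vitro system {system!r}") from None


def distribute_metabolic(clint_total_per_system: dict, split: MetabolicSplit) -> dict:
    """Assign each in vitro system its share of the metabolic clearance.

    ``clint_total_per_system`` maps 'hep'/'hlm'/'hlc' to the whole-metabolism
    clearance expressed in that system's unit; each assigned value is the
    per-system value times the system's pathway fraction, so rescaling the
    three assigned values back to the whole liver reconstructs the total.
    """
    return {
        "hlm": clint_total_per_system["hlm"] * split.frac_hlm,
        "hlc": clint_total_per_system["hlc"] * split.frac_hlc,
        "hep": clint_total_per_system["hep"] * split.frac_hep,
    }


# ---------------------------------------------------------------------------
# full per-cohort derivation
# ---------------------------------------------------------------------------

@dataclass
class DerivationReport:
    """Per-patient derived values, cohort summaries and exclusions."""

    per_patient: pd.DataFrame
    summary: pd.DataFrame        # mean, sd, cv% per derived quantity
    excluded: list = field(default_factory=list)  # (id, reason)

    def mean(self, column: str) -> float:
        return float(self.per_patient[column].mean())


def derive_drug_model(
    cohort: Iterable[PatientRecord],
    physchem: DrugPhysChem,
    fractions: EliminationFractions,
    choices: dict,
    constants: PopulationConstants = DEFAULT_CONSTANTS,
    split: MetabolicSplit | None = None,
    vss_minimal: float | None = None,
    q_sac: float | None = None,
    kp_scalar: float | None = None,
) -> tuple[DrugModel, DerivationReport]:
    """Run the full middle-out chain on a cohort and emit one model variant.

    ``choices`` selects one approach per key point: ``renal`` 'A'
    (age-group GFR table) or 'B' (creatinine formula), ``metabolic`` 'C'
    (all metabolism per 10^6 hepatocytes) or 'D' (distributed over in vitro
    systems), ``distribution`` 'E' (minimal PBPK; requires ``vss_minimal``
    and ``q_sac``) or 'F' (full PBPK; requires ``kp_scalar``).

    Patients whose hepatic blood clearance reaches their hepatic blood flow
    are excluded with a logged reason and reported in the returned
    :class:`DerivationReport`.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be nonempty")
    renal = choices["renal"]
    metabolic = choices["metabolic"]
    distribution = choices["distribution"]
    if renal not in ("A", "B") or metabolic not in ("C", "D") \
            or distribution not in ("E", "F"):
        raise ValueError(f"invalid method choices {choices!r}")
    split = split or MetabolicSplit()

    fu_b = fraction_unbound_blood(physchem.fu_plasma, physchem.bp_ratio)
    f_bile_hepatic = biliary_fraction_of_hepatic(fractions.f_bile, fractions.f_e)

    rows, excluded = [], []
    for rec in cohort:
        if renal == "A":
            egfr = egfr_davies_shock(rec.age, rec.bsa, constants.gfr_table)
        else:
            egfr = egfr_wright(rec.age, rec.bsa, rec.scr, sex="unknown")
        ref_clr = reference_renal_clearance(rec.cl_renal, egfr, constants.gfr_ref)

        from .population import cardiac_output  # local import, no cycle at load
        co = cardiac_output(rec.bsa, rec.age)
        q_h = co * FCO_LIVER["average"]

        cl_h_plasma = rec.cl_plasma - rec.cl_renal
        cl_h_blood = blood_clearance(cl_h_plasma, physchem.bp_ratio)
        weight = rec.weight if rec.weight is not None else constants.weight_mean
        liver = LiverScalars(
            liver_weight=constants.liver_weight_per_kg * weight,
            hpgl=constants.hpgl, mppgl=constants.mppgl, cppgl=constants.cppgl,
        )
        try:
            clint = intrinsic_from_blood_clearance(q_h, cl_h_blood, fu_b)
        except ExtractionExceedsFlowError as err:
            logger.warning("excluding patient %s: %s", rec.id, err)
            excluded.append((rec.id, str(err)))
            continue

        clint_bile = clint * f_bile_hepatic
        clint_met = clint - clint_bile
        row = {
            "id": rec.id,
            "egfr_mL_min": egfr,
            "ref_cl_renal_L_h": ref_clr,
            "cardiac_output_L_h": co,
            "q_hepatic_L_h": q_h,
            "cl_hepatic_blood_L_h": cl_h_blood,
            "clint_whole_liver_L_h": clint,
            "clint_bile_whole_L_h": clint_bile,
            "clint_met_whole_L_h": clint_met,
            "fe_ratio": rec.cl_renal / rec.cl_plasma,
            "clint_bile_hep": scale_intrinsic(clint_bile, liver, "HEP"),
            "clint_met_hep": scale_intrinsic(clint_met, liver, "HEP"),
            "clint_met_hlm": scale_intrinsic(clint_met, liver, "HLM"),
            "clint_met_hlc": scale_intrinsic(clint_met, liver, "HLC"),
        }
        rows.append(row)

    if not rows:
        raise ValueError("all patients were excluded; no model can be derived")

    per_patient = pd.DataFrame(rows).set_index("id")
    numeric = per_patient.select_dtypes("number")
    summary = pd.DataFrame({
        "mean": numeric.mean(),
        "sd": numeric.std(ddof=1) if len(numeric) > 1 else 0.0,
    })
    summary["cv_pct"] = 100.0 * summary["sd"] / summary["mean"]

    mean = per_patient.mean(numeric_only=True)
    if metabolic == "C":
        met_kwargs = {
            "clint_met_hep": float(mean["clint_met_hep"]),
        }
    else:
        assigned = distribute_metabolic(
            {"hep": float(mean["clint_met_hep"]),
             "hlm": float(mean["clint_met_hlm"]),
             "hlc": float(mean["clint_met_hlc"])},
            split,
        )
        met_kwargs = {
            "clint_met_hep": assigned["hep"],
            "clint_met_hlm": assigned["hlm"],
            "clint_met_hlc": assigned["hlc"],
        }

    provenance = {
        "renal_method": renal,
        "metabolic_method": metabolic,
        "distribution_method": distribution,
        "gfr_ref_mL_min": constants.gfr_ref,
        "n_patients": len(per_patient),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "fco_liver": FCO_LIVER["average"],
        "biliary_fraction_of_hepatic": f_bile_hepatic,
    }

    if distribution == "E":
        if vss_minimal is None or q_sac is None:
            raise ValueError("distribution method E requires vss_minimal and q_sac")
        blood_liver = (
            constants.systemic_pool_per_kg
            + constants.liver_weight_per_kg / 1050.0
        ) * physchem.bp_ratio
        dist_kwargs = {
            "distribution_mode": "mPBPK",
            "vss": vss_minimal,
            "v_sac": vss_minimal - blood_liver,
            "q_sac": q_sac,
        }
    else:
        if kp_scalar is None:
            raise ValueError("distribution method F requires kp_scalar")
        from .partition import kp_rodgers_rowland, vss_from_kp
        kps = kp_rodgers_rowland(physchem, kp_scalar=kp_scalar)
        from .constants import TISSUE_VOLUMES_L_PER_KG
        volumes = dict(TISSUE_VOLUMES_L_PER_KG)
        volumes["liver"] = constants.liver_weight_per_kg / 1050.0
        vss = vss_from_kp(
            kps, volumes,
            blood_volume=constants.blood_per_kg * physchem.bp_ratio,
        )
        dist_kwargs = {"distribution_mode": "fPBPK", "vss": vss,
                       "kp_scalar": kp_scalar}

    model = DrugModel(
        physchem=physchem,
        ref_cl_renal=float(mean["ref_cl_renal_L_h"]),
        clint_bile=float(mean["clint_bile_hep"]),
        metabolic_mode="HEP" if metabolic == "C" else "DIST",
        provenance=provenance,
        **met_kwargs,
        **dist_kwargs,
    )
    return model, DerivationReport(per_patient=per_patient, summary=summary,
                                   excluded=excluded)


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["id", "age", "bsa", "scr", "weight", "cl_plasma", "cl_renal"]


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV with header id,age,bsa,scr,weight,cl_plasma,cl_renal."""
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        weight = None if pd.isna(row.weight) else float(row.weight)
        records.append(PatientRecord(
            id=str(row.id), age=float(row.age), bsa=float(row.bsa),
            scr=float(row.scr), cl_plasma=float(row.cl_plasma),
            cl_renal=float(row.cl_renal), weight=weight,
        ))
    return records


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    df = pd.DataFrame([{
        "id": r.id, "age": r.age, "bsa": r.bsa, "scr": r.scr,
        "weight": math.nan if r.weight is None else r.weight,
        "cl_plasma": r.cl_plasma, "cl_renal": r.cl_renal,
    } for r in cohort])
    df.to_csv(path, index=False)
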