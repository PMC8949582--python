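"""Doxorubicin reference parameterisation and reported comparison data.

The drug constants (physicochemistry, elimination-route fractions,
in vitro intrinsic clearances, fitted distribution parameters) are the
published values for doxorubicin; :func:`dox_model` assembles any of the
eight model variants arising from two choices at each of three key points
(renal-clearance method A/B, metabolic-clearance assignment C/D,
distribution model E/F).

``REPORTED_COMPARISONS`` transcribes the published predicted/observed
AUC and Cmax pairs for the training trial (single 60 mg/m2 bolus, AUC
window 0-168 h) and the two validation trials (30 mg/m2 q24h x3 as bolus
or 8-h infusion, AUC window 0-120 h). These are reference inputs for
comparison tables, kept separate from anything this package computes.
"""

from __future__ import annotations

import pandas as pd

from .derive import DrugModel, DrugPhysChem, EliminationFractions, MetabolicSplit

DOX_PHYSCHEM = DrugPhysChem(
    mw=543.51,
    logp=1.27,
    drug_type="ampholyte",
    pka_acid=9.53,
    pka_base=8.94,
    fu_plasma=0.25,
    bp_ratio=1.15,
)

DOX_ELIMINATION = EliminationFractions(f_bile=0.40, f_met=0.49, f_e=0.11)
DOX_METABOLIC_SPLIT = MetabolicSplit(frac_hlm=0.37, frac_hlc=0.60, frac_hep=0.03)

# Source-derived in vitro intrinsic clearances (cohort means).
DOX_CLINT_BILE_HEP = 24.80      # uL/min/10^6 cells
DOX_CLINT_MET_HEP = 30.38       # uL/min/10^6 cells (method C)
DOX_CLINT_MET_HLM_TOTAL = 86.29  # uL/min/mg microsomal protein
DOX_CLINT_MET_HLC_TOTAL = 38.74  # uL/min/mg cytosolic protein

DOX_REF_CL_RENAL = {"A": 7.04, "B": 8.67}  # L/h, healthy 20-30 y.o. male
DOX_VSS_MINIMAL = 31.923                   # L/kg, user input (minimal model)

# The eight variants: (renal, metabolic, distribution, kp_scalar,
# v_sac L/kg, q_sac L/h). Distribution parameters were estimated against
# the training profile with the original simulator's fitting tool and are
# carried as reference configuration, not refitted here.
MODEL_TABLE = {
    1: ("A", "C", "E", None, 31.5495, 151.3618),
    2: ("A", "C", "F", 5.3119, None, None),
    3: ("A", "D", "E", None, 31.3833, 212.3364),
    4: ("A", "D", "F", 5.3119, None, None),
    5: ("B", "C", "E", None, 31.2603, 237.3875),
    6: ("B", "C", "F", 5.237, None, None),
    7: ("B", "D", "E", None, 31.3827, 211.6487),
    8: ("B", "D", "F", 5.3119, None, None),
}


def dox_model(variant: int) -> DrugModel:
    """Assemble one of the eight doxorubicin model variants (1-8)."""
    try:
        renal, metabolic, dist, kp_scalar, v_sac, q_sac = MODEL_TABLE[variant]
    except KeyError:
        raise ValueError(f"model variant must be 1-8, got {variant!r}") from None

    if metabolic == "C":
        met_kwargs = {"clint_met_hep": DOX_CLINT_MET_HEP}
    else:
        s = DOX_METABOLIC_SPLIT
        met_kwargs = {
            "clint_met_hlm": DOX_CLINT_MET_HLM_TOTAL * s.frac_hlm,
            "clint_met_hlc": DOX_CLINT_MET_HLC_TOTAL * s.frac_hlc,
            "clint_met_hep": DOX_CLINT_MET_HEP * s.frac_hep,
        }

    if dist == "E":
        dist_kwargs = {"distribution_mode": "mPBPK", "vss": DOX_VSS_MINIMAL,
                       "v_sac": v_sac, "q_sac": q_sac}
    else:
        dist_kwargs = {"distribution_mode": "fPBPK", "kp_scalar": kp_scalar}

    model = DrugModel(
        physchem=DOX_PHYSCHEM,
        ref_cl_renal=DOX_REF_CL_RENAL[renal],
        clint_bile=DOX_CLINT_BILE_HEP,
        metabolic_mode="HEP" if metabolic == "C" else "DIST",
        provenance={"variant": variant, "renal_method": renal,
                    "metabolic_method": metabolic,
                    "distribution_method": dist},
        **met_kwargs,
        **dist_kwargs,
    )
    if dist == "F":
        from .constants import DEFAULT_CONSTANTS, TISSUE_VOLUMES_L_PER_KG
        from .partition import kp_rodgers_rowland, vss_from_kp
        kps = kp_rodgers_rowland(DOX_PHYSCHEM, kp_scalar=kp_scalar)
        volumes = dict(TISSUE_VOLUMES_L_PER_KG)
        volumes["liver"] = DEFAULT_CONSTANTS.liver_weight_per_kg / 1050.0
        model.vss = vss_from_kp(
            kps, volumes,
            blood_volume=DEFAULT_CONSTANTS.blood_per_kg * DOX_PHYSCHEM.bp_ratio,
        )
    return model


# Published predicted/observed pairs. Columns: model variant, predicted and
# observed Cmax (mg/L; the infusion trial's observed peak is 85 ug/L =
# 0.085 mg/L), printed Cmax Diff (%), predicted and observed AUC over the
# trial window (mg*h/L), printed AUC Diff (%).
_TRAINING = [
    (1, 6.085, 5.474, 11.2, 1.976, 1.939, 1.90),
    (2, 9.048, 5.474, 65.3, 1.942, 1.939, 0.16),
    (3, 4.963, 5.474, -9.3, 1.970, 1.939, 1.59),
    (4, 9.048, 5.474, 65.3, 1.940, 1.939, 0.07),
    (5, 4.582, 5.474, -16.3, 1.950, 1.939, 0.56),
    (6, 9.027, 5.474, 64.9, 1.909, 1.939, -1.56),
    (7, 4.957, 5.474, -9.4, 1.934, 1.939, -0.24),
    (8, 9.022, 5.474, 64.8, 1.904, 1.939, -1.79),
]
_VALIDATION_BOLUS = [
    (1, 4.331, 9.980, -56.6, 2.542, 2.300, 10.51),
    (2, 6.896, 9.980, -30.9, 2.574, 2.300, 11.89),
    (3, 3.787, 9.980, -62.1, 2.560, 2.300, 11.32),
    (4, 6.896, 9.980, -30.9, 2.563, 2.300, 11.45),
    (5, 3.560, 9.980, -64.3, 2.528, 2.300, 9.90),
    (6, 6.884, 9.980, -31.0, 2.538, 2.300, 10.33),
    (7, 3.784, 9.980, -62.1, 2.522, 2.300, 9.64),
    (8, 6.882, 9.980, -31.0, 2.521, 2.300, 9.59),
]
_VALIDATION_INFUSION = [
    (1, 0.032316, 0.085, -62.0, 2.518, 2.000, 25.91),
    (2, 0.034521, 0.085, -59.4, 2.566, 2.000, 28.31),
    (3, 0.030411, 0.085, -64.2, 2.532, 2.000, 26.62),
    (4, 0.034441, 0.085, -59.5, 2.556, 2.000, 27.79),
    (5, 0.029439, 0.085, -65.4, 2.502, 2.000, 25.08),
    (6, 0.034223, 0.085, -59.7, 2.531, 2.000, 26.56),
    (7, 0.030080, 0.085, -64.6, 2.494, 2.000, 24.71),
    (8, 0.034077, 0.085, -59.9, 2.513, 2.000, 25.67),
]

_COLUMNS = ["model", "pred_cmax", "obs_cmax", "diff_cmax_printed_pct",
            "pred_auc", "obs_auc", "diff_auc_printed_pct"]

REPORTED_COMPARISONS = {
    "training_bolus": pd.DataFrame(_TRAINING, columns=_COLUMNS),
    "validation_bolus": pd.DataFrame(_VALIDATION_BOLUS, columns=_COLUMNS),
    "validation_infusion8h": pd.DataFrame(_VALIDATION_INFUSION, columns=_COLUMNS),
}

AUC_WINDOWS = {
    "training_bolus": (0.0, 168.0),
    "validation_bolus": (0.0, 120.0),
    "validation_infusion8h": (0.0, 120.0),
}


def trial_regimen(trial: str):
    """The dosing regimen of a named trial."""
    from .engine import DosingRegimen

    if trial == "training_bolus":
        return DosingRegimen(dose_per_bsa=60.0, infusion_duration=2.0 / 60.0,
                             start_times=(0.0,))
    if trial == "validation_bolus":
        return DosingRegimen(dose_per_bsa=30.0, infusion_duration=1.0 / 60.0,
                             start_times=(0.0, 24.0, 48.0))
    if trial == "validation_infusion8h":
        return DosingRegimen(dose_per_bsa=30.0, infusion_duration=8.0,
                             start_times=(0.0, 24.0, 48.0))
    raise ValueError(f"unknown trial {trial!r}")


def trial_population(trial: str, seed: int = 0):
    """The population design of a named trial (10 groups of 10)."""
    from .population import PopulationSpec

    if trial == "training_bolus":
        return PopulationSpec(n_subjects=10, n_trials=10,
                              age_range=(42.0, 72.0),
                              female_fraction=0.5, seed=seed)
    if trial in ("validation_bolus", "validation_infusion8h"):
        return PopulationSpec(n_subjects=10, n_trials=10,
                              age_range=(20.0, 67.0),
                              female_fraction=0.445, seed=seed)
    raise ValueError(f"unknown trial {trial!r}")
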