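"""Population and system constants for the virtual cancer population.

Everything a simulated subject's physiology depends on lives here so that a
study can swap in its own values: the age-group GFR table, the hepatic
fraction of cardiac output, liver scaling factors (liver weight per kg body
weight, hepatocellularity, microsomal/cytosolic protein per gram liver),
blood volume, anthropometric sampling distributions, and the tissue
composition/volume/flow tables used by the full PBPK model.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Expected GFR by age decade, mL/min normalised to 1.73 m2 body surface area.
# Editable: studies that used different age-group values can pass their own
# table. Covers ages [20, 90).
DAVIES_SHOCK_GFR_TABLE: tuple[tuple[float, float, float], ...] = (
    (20.0, 30.0, 121.0),
    (30.0, 40.0, 114.0),
    (40.0, 50.0, 106.0),
    (50.0, 60.0, 97.0),
    (60.0, 70.0, 89.0),
    (70.0, 80.0, 79.0),
    (80.0, 90.0, 68.0),
)

# Fraction of cardiac output perfusing the liver (hepatic artery + portal
# vein). Sex-specific; "average" is the arithmetic mean of the sexes and is
# used when the source study does not report sex.
FCO_LIVER = {"male": 0.255, "female": 0.280, "average": 0.2675}

# Hepatic arterial / splanchnic split of the liver blood supply, as
# fractions of cardiac output. The portal vein drains gut and spleen.
HEPATIC_ARTERY_FRACTION = 0.065
SPLEEN_FLOW_FRACTION = 0.03
# gut fraction = FCO_LIVER[sex] - HEPATIC_ARTERY_FRACTION - SPLEEN_FLOW_FRACTION

# Tissue-level blood flow fractions of cardiac output (sex-independent
# except for the splanchnic flows above). "rest" absorbs the remainder so
# the arterial outflows always sum to the cardiac output.
TISSUE_FLOW_FRACTIONS = {
    "adipose": 0.05,
    "bone": 0.05,
    "brain": 0.12,
    "heart": 0.04,
    "kidney": 0.19,
    "muscle": 0.17,
    "skin": 0.05,
}

# Tissue volumes as L per kg body weight (perfusion-limited full model).
# Liver volume is derived from the sampled liver weight (density 1.05 g/mL)
# and is therefore not listed here.
TISSUE_VOLUMES_L_PER_KG = {
    "adipose": 0.200,
    "bone": 0.090,
    "brain": 0.020,
    "gut": 0.017,
    "heart": 0.005,
    "kidney": 0.0045,
    "lung": 0.008,
    "muscle": 0.400,
    "skin": 0.040,
    "spleen": 0.0026,
    "rest": 0.040,
}

# Mechanistic tissue composition used for tissue:plasma partition
# prediction: fractional extracellular water, intracellular water, neutral
# lipid, neutral phospholipid (v/v) and acidic phospholipid concentration
# (mg/g tissue). Standard rat-derived values commonly adopted for human
# perfusion-limited PBPK models.
TISSUE_COMPOSITION = {
    #            f_ew    f_iw    f_nl     f_np     AP mg/g
    "adipose": (0.135, 0.017, 0.8530, 0.0016, 0.40),
    "bone":    (0.100, 0.346, 0.0174, 0.0016, 0.67),
    "brain":   (0.162, 0.620, 0.0391, 0.0015, 0.40),
    "gut":     (0.282, 0.475, 0.0375, 0.0124, 2.41),
    "heart":   (0.320, 0.456, 0.0135, 0.0106, 2.25),
    "kidney":  (0.273, 0.483, 0.0121, 0.0240, 5.03),
    "liver":   (0.161, 0.573, 0.0135, 0.0238, 4.56),
    "lung":    (0.336, 0.446, 0.0215, 0.0123, 3.91),
    "muscle":  (0.118, 0.630, 0.0100, 0.0072, 1.53),
    "skin":    (0.382, 0.291, 0.0603, 0.0044, 1.32),
    "spleen":  (0.207, 0.579, 0.0077, 0.0113, 3.18),
    # "rest" is not a physical tissue; muscle composition is used for it.
    "rest":    (0.118, 0.630, 0.0100, 0.0072, 1.53),
}

# Blood-cell composition for deriving the acidic-phospholipid association
# constant from the blood:plasma ratio: f_iw, f_nl, f_np, AP mg/g.
BLOOD_CELL_COMPOSITION = (0.603, 0.0017, 0.0029, 0.50)
PLASMA_NEUTRAL_LIPID = 0.0023
PLASMA_NEUTRAL_PHOSPHOLIPID = 0.0013

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELL = 7.22
HEMATOCRIT = 0.45


@dataclass(frozen=True)
class PopulationConstants:
    """Defaults describing the simulated cancer population.

    Liver scaling factors are chosen within literature ranges so that the
    population-mean in vitro-in vivo scaling products are consistent with
    the whole-liver intrinsic clearances the derivation stage produces from
    the source clinical summaries (see docs/methods.md).
    """

    gfr_table: tuple[tuple[float, float, float], ...] = DAVIES_SHOCK_GFR_TABLE
    gfr_ref: float = 121.0              # mL/min, healthy 20-30 y.o. male
    liver_weight_per_kg: float = 18.3   # g liver per kg body weight
    hpgl: float = 99.0                  # 10^6 hepatocytes per g liver
    mppgl: float = 35.0                 # mg microsomal protein per g liver
    cppgl: float = 78.0                 # mg cytosolic protein per g liver
    blood_per_kg: float = 0.070         # L blood per kg body weight
    venous_fraction: float = 2.0 / 3.0  # share of blood volume that is venous
    systemic_pool_per_kg: float = 0.5   # L/kg, minimal-model systemic pool
    weight_mean: float = 70.0           # kg
    weight_cv: float = 0.15
    height_mean: dict = field(
        default_factory=lambda: {"male": 176.0, "female": 162.0}
    )                                   # cm
    height_sd: dict = field(default_factory=lambda: {"male": 7.0, "female": 6.0})
    truncation_sd: float = 3.0          # truncate sampled covariates at +-3 SD


DEFAULT_CONSTANTS = PopulationConstants()


def gfr_for_age(age: float, table=DAVIES_SHOCK_GFR_TABLE) -> float:
    """Expected GFR (mL/min/1.73 m2) for an age, from the decade table."""
    for lo, hi, gfr in table:
        if lo <= age < hi:
            return gfr
    raise ValueError(
        f"age {age} outside the covered range "
        f"[{table[0][0]}, {table[-1][1]}) of the GFR table"
    )
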