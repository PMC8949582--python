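"""Mechanistic tissue:plasma partition coefficient (Kp) prediction.

Implements the tissue-composition-based partitioning model for ionisable
drugs: the unbound tissue:plasma water ratio (Kpu) of each tissue is built
from partitioning into extracellular and intracellular water (with
pH-dependent ionisation), into neutral lipid and neutral phospholipid, and
- for compounds carrying a basic centre with pKa >= 7, such as doxorubicin
(an ampholyte whose amine pKa is 8.94) - electrostatic association of the
cationic species with tissue acidic phospholipids. The acidic-phospholipid
association constant is not measured directly; it is back-calculated from
the drug's blood-cell partitioning, itself obtained from the blood:plasma
concentration ratio and the haematocrit.

A single multiplicative Kp scalar applied to every tissue reconciles the
mechanistic prediction with an observed distribution volume.
"""

from __future__ import annotations

import numpy as np

from .constants import (
    BLOOD_CELL_COMPOSITION,
    HEMATOCRIT,
    PH_BLOOD_CELL,
    PH_INTRACELLULAR,
    PH_PLASMA,
    PLASMA_NEUTRAL_LIPID,
    PLASMA_NEUTRAL_PHOSPHOLIPID,
    TISSUE_COMPOSITION,
)
from .derive import DrugPhysChem


def _ionisation(pka_base, pka_acid, ph):
    """10^(pKa_b - pH) + 10^(pH - pKa_a): total ionised:neutral ratio."""
    y = 0.0
    if pka_base is not None:
        y += 10.0 ** (pka_base - ph)
    if pka_acid is not None:
        y += 10.0 ** (ph - pka_acid)
    return y


def _neutral_lipid_term(logp, f_nl, f_np):
    p = 10.0 ** logp
    return p * f_nl + (0.3 * p + 0.7) * f_np


def blood_cell_partition(fu_plasma: float, bp_ratio: float,
                         hematocrit: float = HEMATOCRIT) -> float:
    """Unbound blood-cell:plasma partition from the B:P ratio.

    Kpu_BC = (R_B:P - (1 - Hct)) / (Hct * fu_p).
    """
    kpu = (bp_ratio - (1.0 - hematocrit)) / (hematocrit * fu_plasma)
    if kpu <= 0:
        raise ValueError(
            "blood:plasma ratio inconsistent with haematocrit: no cell uptake"
        )
    return kpu


def acidic_phospholipid_ka(physchem: DrugPhysChem,
                           hematocrit: float = HEMATOCRIT) -> float:
    """Association constant to acidic phospholipids, from blood-cell data."""
    if physchem.pka_base is None:
        raise ValueError("acidic-phospholipid binding requires a basic pKa")
    f_iw, f_nl, f_np, ap = BLOOD_CELL_COMPOSITION
    y_bc = _ionisation(physchem.pka_base, physchem.pka_acid, PH_BLOOD_CELL)
    y_p = _ionisation(physchem.pka_base, physchem.pka_acid, PH_PLASMA)
    kpu_bc = blood_cell_partition(physchem.fu_plasma, physchem.bp_ratio,
                                  hematocrit)
    water = (1.0 + y_bc) / (1.0 + y_p) * f_iw
    lipid = _neutral_lipid_term(physchem.logp, f_nl, f_np) / (1.0 + y_p)
    cation_bc = 10.0 ** (physchem.pka_base - PH_BLOOD_CELL)
    ka = (kpu_bc - water - lipid) * (1.0 + y_p) / (ap * cation_bc)
    if ka < 0:
        raise ValueError(
            "derived acidic-phospholipid association constant is negative; "
            "blood-cell partitioning is explained by water/lipid alone"
        )
    return ka


def kp_rodgers_rowland(
    physchem: DrugPhysChem,
    tissue_composition: dict | None = None,
    kp_scalar: float = 1.0,
    tissues: list[str] | None = None,
) -> dict[str, float]:
    """Predict tissue:plasma Kp values for every tissue in the table.

    For drugs with a basic pKa >= 7 the cationic species binds tissue
    acidic phospholipids; otherwise partitioning is into tissue water and
    neutral lipids only. The returned Kp values are plasma-referenced
    (Kp = Kpu * fu_p) and multiplied by ``kp_scalar``.
    """
    if kp_scalar < 0:
        raise ValueError("kp_scalar must be nonnegative")
    comp = tissue_composition if tissue_composition is not None \
        else TISSUE_COMPOSITION
    wanted = tissues if tissues is not None else list(comp)

    basic = physchem.pka_base is not None and physchem.pka_base >= 7.0
    y_p = _ionisation(physchem.pka_base, physchem.pka_acid, PH_PLASMA)
    ka_ap = acidic_phospholipid_ka(physchem) if basic else 0.0

    kps = {}
    for tissue in wanted:
        try:
            f_ew, f_iw, f_nl, f_np, ap = comp[tissue]
        except KeyError:
            raise ValueError(f"tissue {tissue!r} missing from the "
                             "composition table") from None
        y_iw = _ionisation(physchem.pka_base, physchem.pka_acid,
                           PH_INTRACELLULAR)
        kpu = (
            f_ew
            + (1.0 + y_iw) / (1.0 + y_p) * f_iw
            + _neutral_lipid_term(physchem.logp, f_nl, f_np) / (1.0 + y_p)
        )
        if basic:
            cation_iw = 10.0 ** (physchem.pka_base - PH_INTRACELLULAR)
            kpu += ka_ap * ap * cation_iw / (1.0 + y_p)
        kps[tissue] = kp_scalar * kpu * physchem.fu_plasma
    return kps


def vss_from_kp(kps: dict[str, float], volumes: dict[str, float],
                blood_volume: float) -> float:
    """Steady-state distribution volume from per-tissue Kp and volumes.

    Vss = blood term + sum_t Kp_t * V_t, with all volumes in L/kg. Tissues
    present in ``volumes`` but absent from ``kps`` raise; extra Kp entries
    are ignored.
    """
    total = blood_volume
    for tissue, v in volumes.items():
        if tissue not in kps:
            raise ValueError(f"no Kp available for tissue {tissue!r}")
        total += kps[tissue] * v
    return float(total)
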