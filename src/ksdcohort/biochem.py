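"""Derived biochemical indices for genotype–phenotype correlation.

* tubular reabsorption of phosphate (TRP) and the tubular maximum
  phosphate reabsorption per unit GFR (TmP/GFR), via the Payne/Barth
  algebraic form of the Walton–Bijvoet nomogram;
* creatinine-normalized urinary ratios;
* a deliberately simplified urinary supersaturation index for calcium
  oxalate and brushite (Davies activity coefficients, pH-dependent
  phosphate speciation).  This surrogate is rank/direction-comparable
  only — it does not reproduce full iterative ion-speciation programs
  numerically;
* the cystinuria urinary amino-acid profile against configurable
  reference ranges.

All functions are pure; units are SI throughout (plasma phosphate and
urine concentrations in mmol/L, plasma creatinine in µmol/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

# branch point of the nomogram approximation: below this TRP the
# relation is linear, above it the hyperbolic correction applies
TRP_BRANCH_POINT = 0.86

# phosphoric acid pKa2 (H2PO4- / HPO4^2-) at 37 °C ionic conditions
PHOSPHATE_PKA2 = 6.8

# Davies A coefficient (mol^-1/2 L^1/2, 25 °C)
DAVIES_A = 0.509


def trp(
    plasma_phosphate: float,
    plasma_creatinine: float,
    urine_phosphate: float,
    urine_creatinine: float,
) -> float:
    """Tubular reabsorption of phosphate (fraction ≤ 1).

    TRP = 1 − (U_P · P_cr) / (U_cr · P_P) with plasma phosphate in
    mmol/L, plasma creatinine in µmol/L, urine phosphate and creatinine
    as concentrations in mmol/L (any consistent urine units cancel).
    """
    if plasma_phosphate <= 0:
        raise ValueError("plasma phosphate must be > 0")
    if plasma_creatinine <= 0:
        raise ValueError("plasma creatinine must be > 0")
    if urine_creatinine <= 0:
        raise ValueError("urine creatinine must be > 0")
    if urine_phosphate < 0:
        raise ValueError("urine phosphate must be >= 0")
    p_cr_mmol = plasma_creatinine / 1000.0
    return 1.0 - (urine_phosphate * p_cr_mmol) / (
        urine_creatinine * plasma_phosphate
    )


def tmp_gfr(trp_value: float, plasma_phosphate: float) -> float:
    """TmP/GFR in mmol/L from TRP and plasma phosphate.

    Linear below the branch point (TmP/GFR = TRP · P_P); above it the
    algebraic correction 0.3·TRP/(1 − 0.8·TRP) · P_P approximates the
    curved part of the nomogram.  The published approximation has a small
    discontinuity at the branch point (0.86·P_P vs ≈0.8269·P_P); the
    branch rule is applied exactly as stated.
    """
    if trp_value > 1.0:
        raise ValueError("TRP cannot exceed 1")
    if trp_value <= TRP_BRANCH_POINT:
        return trp_value * plasma_phosphate
    return (0.3 * trp_value / (1.0 - 0.8 * trp_value)) * plasma_phosphate


def tmp_gfr_from_raw(
    plasma_phosphate: float,
    plasma_creatinine: float,
    urine_phosphate: float,
    urine_creatinine: float,
) -> float:
    return tmp_gfr(
        trp(plasma_phosphate, plasma_creatinine, urine_phosphate,
            urine_creatinine),
        plasma_phosphate,
    )


def urinary_ratio(analyte: float, creatinine: float) -> float:
    """Creatinine-normalized ratio; both terms in the same amount units
    (e.g. mmol per 24 h), so the ratio is volume-invariant."""
    if creatinine <= 0:
        raise ValueError("creatinine must be > 0")
    if analyte < 0:
        raise ValueError("analyte must be >= 0")
    return analyte / creatinine


# ---------------------------------------------------------------------------
# simplified supersaturation surrogate
# ---------------------------------------------------------------------------


class Salt(str, Enum):
    CAOX = "CaOx"
    BRUSHITE = "brushite"


@dataclass(frozen=True)
class SupersaturationConfig:
    """Solubility products (mol²/L²) and ionic-strength model knobs."""

    ksp_caox: float = 2.32e-9  # calcium oxalate monohydrate
    ksp_brushite: float = 2.57e-7  # CaHPO4·2H2O
    background_ionic_strength: float = 0.15  # mol/L, NaCl-dominated urine
    ca_citrate_correction: bool = False
    ca_citrate_log_k: float = 3.5  # 1:1 association constant (log10, M^-1)


def _davies_log10_gamma(z: int, ionic_strength: float) -> float:
    if ionic_strength <= 0:
        return 0.0
    sqrt_i = math.sqrt(ionic_strength)
    return -DAVIES_A * z * z * (sqrt_i / (1 + sqrt_i) - 0.3 * ionic_strength)


def _hpo4_fraction(ph: float) -> float:
    """Fraction of inorganic phosphate present as HPO4^2- (pKa2 only;
    pKa1 and pKa3 are negligible in the urinary pH range 4–9)."""
    return 1.0 / (1.0 + 10.0 ** (PHOSPHATE_PKA2 - ph))


def supersaturation_index(
    calcium: float,
    oxalate: float,
    phosphate: float,
    magnesium: float = 0.0,
    citrate: float = 0.0,
    ph: Optional[float] = None,
    salt: Salt | str = Salt.CAOX,
    cfg: SupersaturationConfig = SupersaturationConfig(),
) -> float:
    """Ion-activity-product / solubility-product ratio for one salt.

    Inputs are urinary concentrations in mmol/L.  SS > 1 indicates
    supersaturation.  Brushite requires pH (phosphate speciation); the
    calcium oxalate index treats oxalate as fully dissociated.  An
    optional single calcium–citrate 1:1 binding correction reduces free
    calcium.  This is a documented simplification for rank and direction
    comparisons, not a speciation program.
    """
    salt = Salt(salt)
    for name, v in (
        ("calcium", calcium),
        ("oxalate", oxalate),
        ("phosphate", phosphate),
        ("magnesium", magnesium),
        ("citrate", citrate),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if salt is Salt.BRUSHITE and ph is None:
        raise ValueError("brushite supersaturation requires urine pH")
    if ph is not None and not 4.0 <= ph <= 9.0:
        raise ValueError(f"urine pH out of plausible range: {ph}")

    # mol/L
    ca = calcium / 1000.0
    ox = oxalate / 1000.0
    pi = phosphate / 1000.0
    mg = magnesium / 1000.0
    cit = citrate / 1000.0

    if cfg.ca_citrate_correction and cit > 0 and ca > 0:
        # free Ca from 1:1 CaCit binding: K·x² − K·(ca+cit)·x − x ... solve
        # x = free Ca of  K(ca_f)(cit − ca + ca_f) = ca − ca_f
        k = 10.0 ** cfg.ca_citrate_log_k
        b = cit - ca + 1.0 / k
        ca_free = (-b + math.sqrt(b * b + 4.0 * ca / k)) / 2.0
        ca = min(ca, max(ca_free, 0.0))

    if ph is None:
        hpo4 = 0.0
        h2po4 = pi
    else:
        f = _hpo4_fraction(ph)
        hpo4 = pi * f
        h2po4 = pi * (1.0 - f)

    ionic_strength = cfg.background_ionic_strength + 0.5 * (
        ca * 4 + mg * 4 + ox * 4 + cit * 9 + hpo4 * 4 + h2po4 * 1
    )
    gamma2 = 10.0 ** _davies_log10_gamma(2, ionic_strength)

    if salt is Salt.CAOX:
        iap = (gamma2 * ca) * (gamma2 * ox)
        return iap / cfg.ksp_caox
    iap = (gamma2 * ca) * (gamma2 * hpo4)
    return iap / cfg.ksp_brushite


# ---------------------------------------------------------------------------
# cystinuria amino-acid profile
# ---------------------------------------------------------------------------


class AminoAcidLevel(str, Enum):
    NORMAL = "normal"
    MODERATE_ELEVATION = "moderate_elevation"
    MARKED_ELEVATION = "marked_elevation"


@dataclass(frozen=True)
class CystinuriaReferenceRanges:
    """Upper reference limits, mmol analyte per mol creatinine (adult).

    Editable literature defaults; ``marked_fold`` is the multiple of the
    upper limit above which an elevation counts as marked.
    """

    cystine_upper: float = 25.0
    ornithine_upper: float = 15.0
    lysine_upper: float = 60.0
    arginine_upper: float = 8.0
    marked_fold: float = 5.0

    def upper(self, analyte: str) -> float:
        return {
            "cystine": self.cystine_upper,
            "ornithine": self.ornithine_upper,
            "lysine": self.lysine_upper,
            "arginine": self.arginine_upper,
        }[analyte]


DIBASIC_ANALYTES = ("ornithine", "lysine", "arginine")


@dataclass
class CystinuriaProfile:
    levels: dict[str, AminoAcidLevel]
    marked: bool = field(default=False)


def cystinuria_profile(
    ratios: Mapping[str, float],
    ranges: CystinuriaReferenceRanges = CystinuriaReferenceRanges(),
) -> CystinuriaProfile:
    """Classify urinary amino-acid ratios (mmol/mol creatinine).

    Missing analytes give a partial profile.  The summary flag is marked
    when cystine shows a marked elevation or at least two dibasic amino
    acids are elevated — the pattern of biallelic transporter loss.
    """
    levels: dict[str, AminoAcidLevel] = {}
    for analyte in ("cystine",) + DIBASIC_ANALYTES:
        if analyte not in ratios or ratios[analyte] is None:
            continue
        value = ratios[analyte]
        if value < 0:
            raise ValueError(f"{analyte} ratio must be >= 0")
        upper = ranges.upper(analyte)
        if value <= upper:
            levels[analyte] = AminoAcidLevel.NORMAL
        elif value <= ranges.marked_fold * upper:
            levels[analyte] = AminoAcidLevel.MODERATE_ELEVATION
        else:
            levels[analyte] = AminoAcidLevel.MARKED_ELEVATION
    dibasic_elevated = sum(
        1
        for a in DIBASIC_ANALYTES
        if levels.get(a)
        in (AminoAcidLevel.MODERATE_ELEVATION, AminoAcidLevel.MARKED_ELEVATION)
    )
    marked = (
        levels.get("cystine") is AminoAcidLevel.MARKED_ELEVATION
        or dibasic_elevated >= 2
    )
    return CystinuriaProfile(levels=levels, marked=marked)
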