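"""Synthetic cohort generator.

Produces complete, internally consistent inputs for the whole pipeline —
per-individual variant calls with ACMG evidence, a gene panel, per-visit
blood/urine biochemistry, and stone-recurrence histories — with the
statistical structure the analysis assumes: fixed diagnosis-category
counts per group, genotype-conditional biochemical effect directions,
and a two-group proportional-hazards recurrence process.

The default configuration plants, among 701 stone formers, 11 (presumed)
biallelic individuals, one XLR hemizygote, 24 monoallelic carriers in
dominant genes and 33 in dominant/recessive genes, 38 recessive-gene
carriers, 256 VUS carriers and 143 LB/B carriers, leaving 195 with no
rare variant; after demotion of the monoallelic genotypes without a
biochemical phenotype, 48 strong-risk individuals remain.  All planted
variants survive the filter cascade by construction.

Everything is driven by a single integer seed; the written fixture
bundle is byte-identical for identical configurations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .panel import SLC7A9_ALA182THR, GenePanel, default_panel
from .variants import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    write_variants_tsv,
)
from .diagnosis import Phase

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: genotype-class → analyte → shift in units of the analyte's total
#: log-scale SD.  Directions follow the observed genotype–phenotype
#: correlations; magnitudes are configuration, not measured values.
DEFAULT_EFFECT_SIZES: dict[str, dict[str, float]] = {
    "slc34a3_mono": {
        "plasma_phosphate": -1.5,
        "urine_phosphate": 1.5,
        "urine_calcium": 1.5,
    },
    "cystinuria_biallelic_slc3a1": {
        "ua_cystine": 12.0,
        "ua_ornithine": 8.5,
        "ua_lysine": 8.5,
        "ua_arginine": 8.5,
    },
    "cystinuria_biallelic_slc7a9": {
        "ua_cystine": 10.0,
        "ua_ornithine": 6.0,
        "ua_lysine": 6.0,
        "ua_arginine": 6.0,
    },
    "slc7a9_mono": {"ua_cystine": 3.0},
}


class SimConfig(BaseModel):
    """Study-condition parameters of the synthetic cohort."""

    n_ksf: int = Field(701, gt=0)
    n_nksf: int = Field(200, gt=0)
    seed: int = 0
    effect_sizes: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_EFFECT_SIZES.items()
        }
    )
    plant_lp_p: bool = True  # False: every individual in the "none" class
    n_visits_ksf: int = Field(7, ge=1, le=7)
    sigma_log: float = Field(0.25, gt=0)  # total log-scale SD per analyte
    between_individual_share: float = Field(0.6, ge=0.0, le=1.0)
    # recurrence process
    baseline_hazard_per_day: float = Field(2.0e-4, gt=0)
    hr_strong: float = Field(2.4506, gt=0)
    censor_days: float = 1095.0
    n_followup_no_risk: int = Field(302, gt=0)
    multi_recurrence_strong: int = Field(5, ge=0)
    multi_recurrence_other: int = Field(7, ge=0)


# mean reference values (log-normal medians); urinary amounts per 24 h
_BIOCHEM_REFERENCE: dict[str, float] = {
    "plasma_phosphate": 1.05,  # mmol/L
    "plasma_creatinine": 80.0,  # µmol/L
    "plasma_calcium_adj": 2.35,  # mmol/L
    "pth": 45.0,  # ng/L
    "fgf23": 80.0,  # RU/mL
    "vitd_1_25": 110.0,  # pmol/L
    "vitd_25": 60.0,  # nmol/L
    "urine_phosphate": 25.0,  # mmol/24h
    "urine_calcium": 5.0,  # mmol/24h
    "urine_creatinine": 12.0,  # mmol/24h
    "urine_oxalate": 0.35,  # mmol/24h
    "urine_citrate": 3.0,  # mmol/24h
    "urine_magnesium": 4.5,  # mmol/24h
    "ua_cystine": 8.0,  # mmol/mol creatinine
    "ua_ornithine": 5.0,
    "ua_lysine": 25.0,
    "ua_arginine": 4.0,
}


def site_key_str(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


# evidence recipes by target class
_EVIDENCE = {
    "P": ["PVS1", "PS3"],
    "LP": ["PVS1", "PM2"],
    "VUS": ["PM2"],
    "LB": ["BS1", "BP4"],
    "B": ["BS1", "BS2"],
}
_CONSEQUENCE_FOR = {
    "P": Consequence.FRAMESHIFT,
    "LP": Consequence.MISSENSE,
    "VUS": Consequence.MISSENSE,
    "LB": Consequence.MISSENSE,
    "B": Consequence.MISSENSE,
}

# fixed loci for recurrent alleles
_RECURRENT = {
    "SLC9A3R1_R153Q": ("17", 74_365_200, "G", "A", "p.(Arg153Gln)", 1e-4),
    "SLC7A9_A182T": ("19", 32_830_500, "C", "T", SLC7A9_ALA182THR, 8e-3),
}

_GENE_CHROM = {
    "SLC3A1": "2", "SLC7A9": "19", "SLC34A1": "5", "SLC34A3": "9",
    "SLC9A3R1": "17", "CYP24A1": "20", "SLC4A1": "17", "ALPL": "1",
    "CASR": "3", "AP2S1": "19", "GNA11": "19", "ADCY10": "1",
    "SLC2A9": "4", "AGXT": "2", "GRHPR": "9", "HOGA1": "10",
    "SLC26A1": "4", "ATP6V0A4": "7", "ATP6V1B1": "2", "CA2": "8",
    "SLC12A1": "15", "KCNJ1": "11", "CLCNKB": "1", "BSND": "1",
    "CLDN16": "3", "CLDN19": "1", "TRPM6": "9", "APRT": "16",
    "XDH": "2", "MOCS1": "6", "SLC22A12": "11", "FAM20A": "17",
    "CYP2R1": "11", "UMOD": "16", "CTNS": "17", "CLCN5": "X",
    "OCRL": "X", "HPRT1": "X", "FGF23": "12",
}


@dataclass
class _VariantPlan:
    gene: str
    target_class: str  # P/LP/VUS/LB/B
    genotype: Genotype = Genotype.HET
    recurrent: Optional[str] = None  # key into _RECURRENT
    hgvs_p: str = ""


@dataclass
class _IndividualPlan:
    group: str
    variants: list[_VariantPlan] = field(default_factory=list)
    phase: Optional[Phase] = None  # for the first same-gene pair
    sex: Optional[str] = None
    effect_class: str = "null"
    expected_category: str = "none"
    strong_risk: bool = False
    biochem_corroboration: Optional[bool] = None


def _mono(gene, n, cat, strong, effect="null", recurrent=None,
          target="LP") -> list[_IndividualPlan]:
    return [
        _IndividualPlan(
            group="KSF",
            variants=[_VariantPlan(gene, target, recurrent=recurrent)],
            effect_class=effect,
            expected_category=cat,
            strong_risk=strong,
        )
        for _ in range(n)
    ]


def _ksf_plan() -> list[_IndividualPlan]:
    plans: list[_IndividualPlan] = []
    # --- biallelic recessive / AD-AR disease (11) ---
    for _ in range(3):
        plans.append(
            _IndividualPlan(
                "KSF",
                [_VariantPlan("SLC3A1", "P", Genotype.HOM_ALT)],
                effect_class="cystinuria_biallelic_slc3a1",
                expected_category="biallelic_AR",
                strong_risk=True,
            )
        )
    plans.append(
        _IndividualPlan(
            "KSF",
            [_VariantPlan("SLC3A1", "P"), _VariantPlan("SLC3A1", "LP")],
            phase=Phase.TRANS_BY_READS,
            effect_class="cystinuria_biallelic_slc3a1",
            expected_category="biallelic_AR",
            strong_risk=True,
        )
    )
    plans.append(
        _IndividualPlan(
            "KSF",
            [_VariantPlan("SLC3A1", "P"), _VariantPlan("SLC3A1", "LP")],
            phase=Phase.UNKNOWN,
            effect_class="cystinuria_biallelic_slc3a1",
            expected_category="biallelic_AR",
            strong_risk=True,
            biochem_corroboration=True,
        )
    )
    # SLC7A9 biallelic (4); one proven-trans individual also carries the
    # recurrent SLC9A3R1 het (double-listed in the per-gene bar view)
    plans.append(
        _IndividualPlan(
            "KSF",
            [
                _VariantPlan("SLC7A9", "P"),
                _VariantPlan("SLC7A9", "LP"),
                _VariantPlan(
                    "SLC9A3R1", "LP", recurrent="SLC9A3R1_R153Q",
                ),
            ],
            phase=Phase.TRANS_BY_READS,
            effect_class="cystinuria_biallelic_slc7a9",
            expected_category="biallelic_AD_AR",
            strong_risk=True,
        )
    )
    plans.append(
        _IndividualPlan(
            "KSF",
            [_VariantPlan("SLC7A9", "P"), _VariantPlan("SLC7A9", "LP")],
            phase=Phase.TRANS_BY_READS,
            effect_class="cystinuria_biallelic_slc7a9",
            expected_category="biallelic_AD_AR",
            strong_risk=True,
        )
    )
    plans.append(
        _IndividualPlan(
            "KSF",
            [_VariantPlan("SLC7A9", "P"), _VariantPlan("SLC7A9", "LP")],
            phase=Phase.UNKNOWN,
            effect_class="cystinuria_biallelic_slc7a9",
            expected_category="biallelic_AD_AR",
            strong_risk=True,
            biochem_corroboration=True,
        )
    )
    # presumed compound het carrying the hypomorphic recurrent allele,
    # with discordant biochemistry (kept presumed biallelic)
    plans.append(
        _IndividualPlan(
            "KSF",
            [
                _VariantPlan("SLC7A9", "P", hgvs_p="p.(Ala354Thr)"),
                _VariantPlan("SLC7A9", "LP", recurrent="SLC7A9_A182T"),
            ],
            phase=Phase.UNKNOWN,
            effect_class="null",
            expected_category="biallelic_AD_AR",
            strong_risk=True,
            biochem_corroboration=False,
        )
    )
    for _ in range(2):
        plans.append(
            _IndividualPlan(
                "KSF",
                [_VariantPlan("CYP24A1", "P", Genotype.HOM_ALT)],
                expected_category="biallelic_AD_AR",
                strong_risk=True,
            )
        )
    # --- X-linked recessive (1) ---
    plans.append(
        _IndividualPlan(
            "KSF",
            [_VariantPlan("OCRL", "LP", Genotype.HEMI)],
            sex="M",
            expected_category="XLR_hemizygous",
            strong_risk=True,
        )
    )
    # --- monoallelic, AD genes (24) ---
    plans += _mono("SLC9A3R1", 5, "monoallelic_AD", strong=False,
                   recurrent="SLC9A3R1_R153Q")
    plans += _mono("ALPL", 8, "monoallelic_AD", strong=True)
    plans += _mono("CASR", 4, "monoallelic_AD", strong=True)
    plans += _mono("ADCY10", 4, "monoallelic_AD", strong=True)
    plans += _mono("SLC2A9", 3, "monoallelic_AD", strong=True)
    # --- monoallelic, AD/AR genes (33) ---
    plans += _mono("SLC7A9", 4, "monoallelic_AD_AR", strong=True,
                   effect="slc7a9_mono")
    plans += _mono("SLC7A9", 5, "monoallelic_AD_AR", strong=False,
                   recurrent="SLC7A9_A182T")
    plans += _mono("SLC34A3", 9, "monoallelic_AD_AR", strong=True,
                   effect="slc34a3_mono")
    plans += _mono("CYP24A1", 8, "monoallelic_AD_AR", strong=False)
    plans += _mono("SLC34A1", 3, "monoallelic_AD_AR", strong=False)
    plans += _mono("SLC4A1", 4, "monoallelic_AD_AR", strong=True)
    # --- carriers for recessive disease (38) ---
    for gene, n in (
        ("SLC3A1", 15), ("AGXT", 6), ("GRHPR", 5), ("HOGA1", 4),
        ("ATP6V1B1", 4), ("CLDN16", 4),
    ):
        plans += _mono(gene, n, "carrier_AR", strong=False)
    return plans


def _nksf_plan() -> list[_IndividualPlan]:
    plans: list[_IndividualPlan] = []

    def mono(gene, n, recurrent=None, effect="null", strong=False):
        for _ in range(n):
            plans.append(
                _IndividualPlan(
                    "NKSF",
                    [_VariantPlan(gene, "LP", recurrent=recurrent)],
                    effect_class=effect,
                    expected_category=(
                        "monoallelic_AD"
                        if gene == "SLC9A3R1"
                        else "monoallelic_AD_AR"
                    ),
                    strong_risk=strong,
                )
            )

    # non-demoted monoallelic SLC7A9 keeps the strong-risk flag even in
    # controls (the flag only drives the stone-former recurrence analysis)
    mono("SLC7A9", 3, effect="slc7a9_mono", strong=True)
    mono("SLC7A9", 1, recurrent="SLC7A9_A182T")
    # one control carries monoallelic LP variants in two genes
    plans.append(
        _IndividualPlan(
            "NKSF",
            [
                _VariantPlan("SLC9A3R1", "LP", recurrent="SLC9A3R1_R153Q"),
                _VariantPlan("SLC7A9", "LP"),
            ],
            effect_class="slc7a9_mono",
            expected_category="monoallelic_AD",
            strong_risk=True,
        )
    )
    mono("SLC9A3R1", 2, recurrent="SLC9A3R1_R153Q")
    mono("CYP24A1", 2)
    mono("SLC34A1", 2)
    for gene, n in (
        ("SLC3A1", 2), ("AGXT", 2), ("GRHPR", 1), ("CLDN16", 1),
        ("ATP6V1B1", 1),
    ):
        for _ in range(n):
            plans.append(
                _IndividualPlan(
                    "NKSF",
                    [_VariantPlan(gene, "LP")],
                    expected_category="carrier_AR",
                )
            )
    return plans


def _background_plan(group: str, n_vus: int, n_lb: int, n_b: int,
                     n_none: int, panel: GenePanel) -> list[_IndividualPlan]:
    plans = []
    symbols = sorted(panel.symbols() - {"OCRL", "CLCN5", "HPRT1"})
    for i in range(n_vus):
        plans.append(
            _IndividualPlan(
                group,
                [_VariantPlan(symbols[i % len(symbols)], "VUS")],
                expected_category="VUS_carrier",
            )
        )
    for i in range(n_lb):
        plans.append(
            _IndividualPlan(
                group,
                [_VariantPlan(symbols[i % len(symbols)], "LB")],
                expected_category="LB_B_carrier",
            )
        )
    for i in range(n_b):
        plans.append(
            _IndividualPlan(
                group,
                [_VariantPlan(symbols[i % len(symbols)], "B")],
                expected_category="LB_B_carrier",
            )
        )
    plans += [
        _IndividualPlan(group, expected_category="none")
        for _ in range(n_none)
    ]
    return plans


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    config: SimConfig
    demographics: pd.DataFrame  # individual_id, group, sex, age, corroboration
    variants: list[AnnotatedVariant]
    evidence: dict[str, dict[str, list[str]]]  # id -> site_key -> codes
    phase: dict[str, list[tuple[str, str, str]]]  # id -> (siteA, siteB, phase)
    ground_truth: pd.DataFrame  # id, group, category, strong_risk, effect

    @property
    def n_individuals(self) -> int:
        return len(self.demographics)


def generate_genotypes(cfg: SimConfig) -> SimulatedCohort:
    """Plant genotypes, ACMG evidence and phase reads per the category
    plan; ground truth is recorded for recovery testing."""
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel()

    if cfg.plant_lp_p:
        plans = _ksf_plan()
        n_rest = cfg.n_ksf - len(plans)
        if n_rest < 256 + 143:
            raise ValueError(
                f"n_ksf={cfg.n_ksf} too small for the planted categories"
            )
        plans += _background_plan(
            "KSF", 256, 100, 43, n_rest - 256 - 143, panel
        )
        nplans = _nksf_plan()
        n_rest = cfg.n_nksf - len(nplans)
        if n_rest < 90 + 34:
            raise ValueError(
                f"n_nksf={cfg.n_nksf} too small for the planted categories"
            )
        nplans += _background_plan(
            "NKSF", 90, 24, 10, n_rest - 90 - 34, panel
        )
        plans += nplans
    else:
        plans = [
            _IndividualPlan("KSF", expected_category="none")
            for _ in range(cfg.n_ksf)
        ] + [
            _IndividualPlan("NKSF", expected_category="none")
            for _ in range(cfg.n_nksf)
        ]

    # deterministic ids per group
    counters = {"KSF": 0, "NKSF": 0}
    next_pos: dict[str, int] = {}
    variants: list[AnnotatedVariant] = []
    evidence: dict[str, dict[str, list[str]]] = {}
    phase: dict[str, list[tuple[str, str, str]]] = {}
    demo_rows = []
    truth_rows = []

    for plan in plans:
        counters[plan.group] += 1
        iid = f"{plan.group}_{counters[plan.group]:04d}"
        sex = plan.sex or ("M" if rng.random() < 0.62 else "F")
        age_mean, age_sd = (53, 14) if plan.group == "KSF" else (46, 13)
        age = float(np.clip(rng.normal(age_mean, age_sd), 18, 90))

        sites: list[tuple[str, int, str, str]] = []
        for vp in plan.variants:
            if vp.recurrent:
                chrom, pos, ref, alt, hgvs, gaf = _RECURRENT[vp.recurrent]
            else:
                chrom = _GENE_CHROM[vp.gene]
                base = 1_000_000 + (
                    int(hashlib.sha1(vp.gene.encode()).hexdigest()[:6], 16)
                )
                # strictly increasing rng offsets: unique per gene within
                # a run, different variant identities across seeds
                next_pos[vp.gene] = next_pos.get(vp.gene, 0) + int(
                    rng.integers(1, 50)
                )
                pos = base + next_pos[vp.gene]
                ref, alt = "A", "G"
                hgvs = vp.hgvs_p
                gaf = (
                    None
                    if rng.random() < 0.3
                    else float(rng.uniform(0, 0.005))
                )
            if vp.genotype is Genotype.HET:
                af = float(np.clip(rng.normal(0.5, 0.05), 0.35, 0.65))
            else:
                af = float(rng.uniform(0.97, 1.0))
            variants.append(
                AnnotatedVariant(
                    individual_id=iid,
                    gene=vp.gene,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    genotype=vp.genotype,
                    allele_fraction=af,
                    site_quality=float(rng.uniform(40, 95)),
                    consequence=_CONSEQUENCE_FOR[vp.target_class],
                    splice_distance_bp=0,
                    gnomad_af=gaf,
                    hgvs_p=hgvs,
                )
            )
            sites.append((chrom, pos, ref, alt))
            evidence.setdefault(iid, {})[site_key_str(chrom, pos, ref, alt)] = (
                list(_EVIDENCE[vp.target_class])
            )
        if plan.phase is not None and plan.phase is not Phase.UNKNOWN:
            same_gene = [
                s
                for s, vp in zip(sites, plan.variants)
                if vp.gene == plan.variants[0].gene
            ]
            if len(same_gene) >= 2:
                phase.setdefault(iid, []).append(
                    (
                        site_key_str(*same_gene[0]),
                        site_key_str(*same_gene[1]),
                        plan.phase.value,
                    )
                )
        demo_rows.append(
            {
                "individual_id": iid,
                "group": plan.group,
                "sex": sex,
                "age": round(age, 1),
                "biochem_corroboration": plan.biochem_corroboration,
            }
        )
        truth_rows.append(
            {
                "individual_id": iid,
                "group": plan.group,
                "category": plan.expected_category,
                "strong_risk": plan.strong_risk,
                "effect_class": plan.effect_class,
            }
        )

    return SimulatedCohort(
        config=cfg,
        demographics=pd.DataFrame(demo_rows),
        variants=variants,
        evidence=evidence,
        phase=phase,
        ground_truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# biochemistry
# ---------------------------------------------------------------------------


def generate_biochem(cohort: SimulatedCohort) -> pd.DataFrame:
    """Per-visit biochemistry: log-normal baselines with a shared
    between-individual component plus genotype-conditional shifts.

    Stone formers attend visits V1..Vk; controls attend V1 only.  Urine
    pH is drawn on the natural scale (bounded), all other analytes
    log-normally.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 1)
    effects = cfg.effect_sizes
    truth = cohort.ground_truth.set_index("individual_id")

    sigma_b = cfg.sigma_log * np.sqrt(cfg.between_individual_share)
    sigma_w = cfg.sigma_log * np.sqrt(1 - cfg.between_individual_share)

    analytes = sorted(_BIOCHEM_REFERENCE)
    rows = []
    for rec in cohort.demographics.itertuples(index=False):
        iid = rec.individual_id
        n_visits = cfg.n_visits_ksf if rec.group == "KSF" else 1
        eclass = truth.loc[iid, "effect_class"]
        shifts = effects.get(eclass, {})
        base = {
            a: np.log(_BIOCHEM_REFERENCE[a])
            + cfg.sigma_log * shifts.get(a, 0.0)
            + rng.normal(0.0, sigma_b)
            for a in analytes
        }
        ph_base = float(np.clip(rng.normal(6.0, 0.45), 4.5, 8.0))
        vol_base = float(np.clip(rng.normal(2.0, 0.5), 0.8, 4.0))
        for visit in range(1, n_visits + 1):
            row = {"individual_id": iid, "group": rec.group,
                   "visit": f"V{visit}"}
            for a in analytes:
                row[a] = float(np.exp(base[a] + rng.normal(0.0, sigma_w)))
            row["urine_ph"] = float(
                np.clip(ph_base + rng.normal(0.0, 0.25), 4.0, 9.0)
            )
            row["urine_volume"] = float(
                np.clip(vol_base + rng.normal(0.0, 0.3), 0.5, 5.0)
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recurrence
# ---------------------------------------------------------------------------


def generate_recurrence(cohort: SimulatedCohort) -> pd.DataFrame:
    """Exponential recurrence times with a proportional hazard for the
    strong-risk group, administratively censored.

    The analysis set is every strong-risk stone former plus a random
    subset of ``n_followup_no_risk`` stone formers without strong risk
    factors (complete-follow-up subset).  Individuals with more than one
    recurrence are planted deterministically among those with an event.
    """
    cfg = cohort.config
    if cfg.censor_days <= 0:
        raise ValueError("censoring horizon must be > 0 days")
    rng = np.random.default_rng(cfg.seed + 2)
    truth = cohort.ground_truth
    demo = cohort.demographics.set_index("individual_id")

    ksf = truth[truth["group"] == "KSF"]
    strong_ids = list(ksf[ksf["strong_risk"]]["individual_id"])
    other_ids = list(ksf[~ksf["strong_risk"]]["individual_id"])
    if len(other_ids) < cfg.n_followup_no_risk:
        raise ValueError("not enough no-risk stone formers for follow-up set")
    followup_other = sorted(
        rng.choice(other_ids, size=cfg.n_followup_no_risk, replace=False)
    )

    rows = []
    for ids, is_strong in ((strong_ids, True), (followup_other, False)):
        hazard = cfg.baseline_hazard_per_day * (
            cfg.hr_strong if is_strong else 1.0
        )
        for iid in ids:
            t = float(rng.exponential(1.0 / hazard))
            event = t <= cfg.censor_days
            rows.append(
                {
                    "individual_id": iid,
                    "time_days": round(min(t, cfg.censor_days), 1),
                    "event": int(event),
                    "age": demo.loc[iid, "age"],
                    "sex": demo.loc[iid, "sex"],
                    "strong_risk_factor": int(is_strong),
                    "n_recurrences": int(event),
                }
            )
    df = pd.DataFrame(rows)

    for flag, n_multi in (
        (1, cfg.multi_recurrence_strong),
        (0, cfg.multi_recurrence_other),
    ):
        idx = df.index[(df["strong_risk_factor"] == flag) & (df["event"] == 1)]
        if len(idx) < n_multi:
            raise ValueError(
                "fewer events than requested multi-recurrence individuals"
            )
        df.loc[idx[:n_multi], "n_recurrences"] = 2
    return df


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------


def write_fixture_bundle(cfg: SimConfig, outdir: str | Path) -> Path:
    """Write the complete input bundle; byte-identical per (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_genotypes(cfg)
    biochem = generate_biochem(cohort)
    survival = generate_recurrence(cohort)
    panel = default_panel()

    fmt = "%.10g"
    write_variants_tsv(cohort.variants, outdir / "variants.tsv")
    panel.to_tsv(outdir / "panel.tsv")
    cohort.demographics.to_csv(
        outdir / "demographics.tsv", sep="\t", index=False
    )
    biochem.to_csv(
        outdir / "biochem.tsv", sep="\t", index=False, float_format=fmt
    )
    survival.to_csv(
        outdir / "survival.tsv", sep="\t", index=False, float_format=fmt
    )
    (outdir / "evidence.json").write_text(
        json.dumps(cohort.evidence, indent=1, sort_keys=True)
    )
    (outdir / "phase.json").write_text(
        json.dumps(cohort.phase, indent=1, sort_keys=True)
    )
    manifest = {
        "config": json.loads(cfg.model_dump_json()),
        "ground_truth": cohort.ground_truth.to_dict(orient="records"),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return outdir
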