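"""End-to-end orchestration: bundle I/O, filtering, classification,
diagnosis, and the derived-biochemistry table.

A *bundle* is the directory layout the synthetic generator writes
(``variants.tsv``, ``panel.tsv``, ``evidence.json``, ``phase.json``,
``demographics.tsv``, ``biochem.tsv``, ``survival.tsv``); real cohort
data in the same layout runs through the identical path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .acmg import AcmgClass, classify
from .biochem import (
    Salt,
    supersaturation_index,
    tmp_gfr_from_raw,
    trp,
    urinary_ratio,
)
from .diagnosis import (
    ClassifiedVariant,
    DiagnosisResult,
    IndividualGenotype,
    Phase,
    diagnose_cohort,
)
from .panel import GenePanel
from .simulate import SimulatedCohort, site_key_str
from .stats import SurvivalRecord
from .variants import (
    AnnotatedVariant,
    FilterConfig,
    FilterReport,
    load_variants_tsv,
    run_filter_cascade,
)


@dataclass
class Bundle:
    panel: GenePanel
    variants: list[AnnotatedVariant]
    evidence: dict[str, dict[str, list[str]]]
    phase: dict[str, list]
    demographics: pd.DataFrame
    biochem: pd.DataFrame
    survival: pd.DataFrame


def read_bundle(bundle_dir: str | Path) -> Bundle:
    d = Path(bundle_dir)
    panel = GenePanel.from_tsv(d / "panel.tsv")
    return Bundle(
        panel=panel,
        variants=load_variants_tsv(d / "variants.tsv", panel),
        evidence=json.loads((d / "evidence.json").read_text()),
        phase=json.loads((d / "phase.json").read_text()),
        demographics=pd.read_csv(d / "demographics.tsv", sep="\t"),
        biochem=pd.read_csv(d / "biochem.tsv", sep="\t"),
        survival=pd.read_csv(d / "survival.tsv", sep="\t"),
    )


def _site_str(v: AnnotatedVariant) -> str:
    return site_key_str(v.chrom, v.pos, v.ref, v.alt)


def build_genotypes(
    variants: Sequence[AnnotatedVariant],
    evidence: Mapping[str, Mapping[str, Sequence[str]]],
    demographics: pd.DataFrame,
    phase: Optional[Mapping[str, Sequence]] = None,
) -> list[IndividualGenotype]:
    """Classify each variant from its evidence codes and group calls by
    individual.  Variants without an evidence record are VUS (no
    evidence → uncertain)."""
    phase = phase or {}
    by_individual: dict[str, list[ClassifiedVariant]] = {}
    for v in variants:
        codes = evidence.get(v.individual_id, {}).get(_site_str(v))
        acmg_class = classify(codes) if codes else AcmgClass.VUS
        by_individual.setdefault(v.individual_id, []).append(
            ClassifiedVariant(v, acmg_class)
        )

    def parse_site(s: str):
        chrom, pos, ref, alt = s.rsplit(":", 3)
        return (chrom, int(pos), ref, alt)

    out = []
    for rec in demographics.itertuples(index=False):
        iid = rec.individual_id
        phase_evidence = {}
        for entry in phase.get(iid, []):
            a, b, ph = entry
            phase_evidence[frozenset({parse_site(a), parse_site(b)})] = Phase(
                ph
            )
        corro = getattr(rec, "biochem_corroboration", None)
        if pd.isna(corro):
            corro = None
        out.append(
            IndividualGenotype(
                individual_id=iid,
                sex=rec.sex,
                group=rec.group,
                variants=by_individual.get(iid, []),
                phase_evidence=phase_evidence,
                biochem_corroboration=corro,
            )
        )
    return out


def run_diagnosis_pipeline(
    bundle: Bundle,
    filter_config: Optional[FilterConfig] = None,
    reclassify: bool = True,
) -> tuple[list[DiagnosisResult], FilterReport]:
    """Filter cascade → ACMG classification → per-individual diagnosis."""
    cfg = filter_config or FilterConfig()
    n = len(bundle.demographics)
    filtered, report = run_filter_cascade(bundle.variants, cfg, n)
    genotypes = build_genotypes(
        filtered, bundle.evidence, bundle.demographics, bundle.phase
    )
    results = diagnose_cohort(genotypes, bundle.panel, reclassify=reclassify)
    return results, report


def diagnose_simulated(
    cohort: SimulatedCohort, reclassify: bool = True
) -> tuple[list[DiagnosisResult], FilterReport]:
    """In-memory equivalent of the bundle path for a simulated cohort."""
    from .panel import default_panel

    cfg = FilterConfig()
    filtered, report = run_filter_cascade(
        cohort.variants, cfg, cohort.n_individuals
    )
    genotypes = build_genotypes(
        filtered,
        cohort.evidence,
        cohort.demographics,
        cohort.phase,
    )
    results = diagnose_cohort(
        genotypes, default_panel(), reclassify=reclassify
    )
    return results, report


# ---------------------------------------------------------------------------
# derived biochemistry
# ---------------------------------------------------------------------------


def derive_biochem_frame(biochem: pd.DataFrame) -> pd.DataFrame:
    """Compute the derived indices per visit row.

    Expects the bundle biochemistry schema (24-h urinary amounts in mmol,
    volume in L, plasma phosphate mmol/L, plasma creatinine µmol/L,
    amino-acid ratios in mmol/mol creatinine).
    """
    out = biochem[["individual_id", "group", "visit"]].copy()
    vol = biochem["urine_volume"]
    trp_vals = [
        trp(r.plasma_phosphate, r.plasma_creatinine, r.urine_phosphate,
            r.urine_creatinine)
        for r in biochem.itertuples(index=False)
    ]
    out["trp"] = trp_vals
    out["tmp_gfr"] = [
        tmp_gfr_from_raw(
            r.plasma_phosphate, r.plasma_creatinine, r.urine_phosphate,
            r.urine_creatinine,
        )
        for r in biochem.itertuples(index=False)
    ]
    out["ca_crea_ratio"] = [
        urinary_ratio(r.urine_calcium, r.urine_creatinine)
        for r in biochem.itertuples(index=False)
    ]
    out["cystine_crea_ratio"] = biochem["ua_cystine"]
    out["ss_caox"] = [
        supersaturation_index(
            calcium=r.urine_calcium / r.urine_volume,
            oxalate=r.urine_oxalate / r.urine_volume,
            phosphate=r.urine_phosphate / r.urine_volume,
            magnesium=r.urine_magnesium / r.urine_volume,
            citrate=r.urine_citrate / r.urine_volume,
            ph=r.urine_ph,
            salt=Salt.CAOX,
        )
        for r in biochem.itertuples(index=False)
    ]
    out["ss_brushite"] = [
        supersaturation_index(
            calcium=r.urine_calcium / r.urine_volume,
            oxalate=r.urine_oxalate / r.urine_volume,
            phosphate=r.urine_phosphate / r.urine_volume,
            magnesium=r.urine_magnesium / r.urine_volume,
            citrate=r.urine_citrate / r.urine_volume,
            ph=r.urine_ph,
            salt=Salt.BRUSHITE,
        )
        for r in biochem.itertuples(index=False)
    ]
    out["urine_volume"] = vol
    return out


def select_visit(
    derived: pd.DataFrame, visit: str = "V2", control_visit: str = "V1"
) -> pd.DataFrame:
    """Explicit visit-selection policy: the stated visit for stone
    formers, the enrollment visit for controls (their only one)."""
    ksf = derived[(derived["group"] == "KSF") & (derived["visit"] == visit)]
    nksf = derived[
        (derived["group"] == "NKSF") & (derived["visit"] == control_visit)
    ]
    return pd.concat([ksf, nksf], ignore_index=True)


def survival_records(survival: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(
            individual_id=r.individual_id,
            time_days=float(r.time_days),
            event=bool(r.event),
            age=float(r.age),
            sex=str(r.sex),
            strong_risk_factor=bool(r.strong_risk_factor),
            n_recurrences=int(r.n_recurrences),
        )
        for r in survival.itertuples(index=False)
    ]
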