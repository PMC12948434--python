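"""Inheritance-mode-aware monogenic diagnosis.

Each individual receives exactly one diagnostic category, derived from
their classified panel variants and the inheritance mode of the genes
involved.  Biallelic status for two heterozygous LP/P variants in the
same gene is proven by read-backed trans phase, refuted by cis phase,
and presumed otherwise (optionally annotated with biochemical
corroboration, e.g. dibasic aminoaciduria for cystinuria genes).

The reclassification step demotes monoallelic LP/P genotypes in genes
(or individual alleles) without a biochemical phenotype, yielding the
"strong genetic risk factor" flag used in the recurrence analysis.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .acmg import AcmgClass
from .panel import GenePanel, Inheritance
from .variants import AnnotatedVariant, Genotype


class Phase(str, Enum):
    TRANS_BY_READS = "trans_by_reads"
    CIS_BY_READS = "cis_by_reads"
    UNKNOWN = "unknown"


class BiallelicStatus(str, Enum):
    PROVEN = "biallelic_proven"
    PRESUMED = "biallelic_presumed"
    MONOALLELIC = "monoallelic_only"


class Category(str, Enum):
    BIALLELIC_AR = "biallelic_AR"
    BIALLELIC_AD_AR = "biallelic_AD_AR"
    XLR_HEMIZYGOUS = "XLR_hemizygous"
    MONOALLELIC_AD = "monoallelic_AD"
    MONOALLELIC_AD_AR = "monoallelic_AD_AR"
    CARRIER_AR = "carrier_AR"
    VUS_CARRIER = "VUS_carrier"
    LB_B_CARRIER = "LB_B_carrier"
    NONE = "none"


#: categories counting as monogenic kidney stone disease
MONOGENIC_CATEGORIES = frozenset(
    {
        Category.BIALLELIC_AR,
        Category.BIALLELIC_AD_AR,
        Category.XLR_HEMIZYGOUS,
        Category.MONOALLELIC_AD,
        Category.MONOALLELIC_AD_AR,
    }
)

#: single-category precedence for the per-individual pie view
_CATEGORY_PRECEDENCE = [
    Category.BIALLELIC_AR,
    Category.BIALLELIC_AD_AR,
    Category.XLR_HEMIZYGOUS,
    Category.MONOALLELIC_AD,
    Category.MONOALLELIC_AD_AR,
    Category.CARRIER_AR,
    Category.VUS_CARRIER,
    Category.LB_B_CARRIER,
    Category.NONE,
]


@dataclass(frozen=True)
class ClassifiedVariant:
    """A filtered variant together with its 5-tier class."""

    variant: AnnotatedVariant
    acmg_class: AcmgClass


@dataclass
class IndividualGenotype:
    """All classified variants of one individual plus phase evidence.

    ``phase_evidence`` maps unordered same-gene site pairs to the read-
    backed phase call; pairs not listed are of unknown phase.
    """

    individual_id: str
    sex: str  # "M" | "F"
    group: str  # "KSF" | "NKSF"
    variants: list[ClassifiedVariant] = field(default_factory=list)
    phase_evidence: dict[frozenset, Phase] = field(default_factory=dict)
    biochem_corroboration: Optional[bool] = None

    def lp_p_variants(self, gene: str) -> list[ClassifiedVariant]:
        return [
            cv
            for cv in self.variants
            if cv.variant.gene == gene and cv.acmg_class.is_lp_p
        ]


@dataclass
class GeneFinding:
    """Per-gene zygosity-resolved finding (the bar-plot view)."""

    gene: str
    status: BiallelicStatus
    category: Category
    variants: list[ClassifiedVariant]


@dataclass
class DiagnosisResult:
    individual_id: str
    group: str
    category: Category
    monogenic_ksd: bool
    strong_risk_factor: bool
    presumed: bool
    supporting_variants: list[ClassifiedVariant]
    gene_findings: list[GeneFinding] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "individual_id": self.individual_id,
            "group": self.group,
            "category": self.category.value,
            "monogenic_ksd": self.monogenic_ksd,
            "strong_risk_factor": self.strong_risk_factor,
            "presumed": self.presumed,
            "supporting_variants": [
                {
                    "gene": cv.variant.gene,
                    "site": list(cv.variant.site),
                    "genotype": cv.variant.genotype.value,
                    "hgvs_p": cv.variant.hgvs_p,
                    "acmg_class": cv.acmg_class.value,
                }
                for cv in self.supporting_variants
            ],
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# biallelic resolution
# ---------------------------------------------------------------------------


def resolve_biallelic(
    gene_variants: Sequence[ClassifiedVariant],
    phase_evidence: Mapping[frozenset, Phase],
    biochem_corroboration: Optional[bool] = None,
) -> tuple[BiallelicStatus, list[str]]:
    """Resolve zygosity for the LP/P variants of one gene.

    A homozygous (or hemizygous) single variant is biallelic by itself;
    two heterozygotes are proven biallelic with read-backed trans phase,
    refuted (monoallelic) with cis phase, and presumed biallelic when the
    phase is unknown.  Biochemical corroboration is recorded as an
    annotation flag and does not change the category.  More than two LP/P
    variants are processed pairwise and flagged for review.
    """
    if not gene_variants:
        raise ValueError("resolve_biallelic requires >= 1 LP/P variant")
    flags: list[str] = []
    if any(
        cv.variant.genotype in (Genotype.HOM_ALT, Genotype.HEMI)
        for cv in gene_variants
    ):
        return BiallelicStatus.PROVEN, flags

    hets = [cv for cv in gene_variants if cv.variant.genotype is Genotype.HET]
    if len(hets) == 1:
        return BiallelicStatus.MONOALLELIC, flags
    if len(hets) > 2:
        flags.append("more_than_two_lp_p_variants_review")

    # pairwise: any read-proven trans pair wins; all-cis means one haplotype
    statuses = []
    for i in range(len(hets)):
        for j in range(i + 1, len(hets)):
            pair = frozenset({hets[i].variant.site, hets[j].variant.site})
            phase = phase_evidence.get(pair, Phase.UNKNOWN)
            if phase is Phase.TRANS_BY_READS:
                statuses.append(BiallelicStatus.PROVEN)
            elif phase is Phase.CIS_BY_READS:
                statuses.append(BiallelicStatus.MONOALLELIC)
            else:
                statuses.append(BiallelicStatus.PRESUMED)
    if BiallelicStatus.PROVEN in statuses:
        return BiallelicStatus.PROVEN, flags
    if BiallelicStatus.PRESUMED in statuses:
        if biochem_corroboration is True:
            flags.append("presumed_trans_supported_by_biochemistry")
        elif biochem_corroboration is False:
            flags.append("presumed_trans_discordant_biochemistry")
        return BiallelicStatus.PRESUMED, flags
    return BiallelicStatus.MONOALLELIC, flags


# ---------------------------------------------------------------------------
# category assignment
# ---------------------------------------------------------------------------


def _gene_category(
    inheritance: Inheritance, status: BiallelicStatus, sex: str
) -> Optional[Category]:
    """Category contributed by LP/P variants in one gene, or None."""
    if inheritance is Inheritance.XLR:
        # hemizygous males are resolved PROVEN via the hemi genotype
        if sex == "M" and status is BiallelicStatus.PROVEN:
            return Category.XLR_HEMIZYGOUS
        return None  # female carriers / unproven: not monogenic here
    biallelic = status in (BiallelicStatus.PROVEN, BiallelicStatus.PRESUMED)
    if inheritance is Inheritance.AR:
        return Category.BIALLELIC_AR if biallelic else Category.CARRIER_AR
    if inheritance is Inheritance.AD_AR:
        return (
            Category.BIALLELIC_AD_AR
            if biallelic
            else Category.MONOALLELIC_AD_AR
        )
    # AD gene: zygosity does not change the dominant category
    return Category.MONOALLELIC_AD


def assign_category(
    g: IndividualGenotype, panel: GenePanel
) -> DiagnosisResult:
    """Assign the single (pie-view) category and the per-gene findings.

    Individuals with qualifying variants in several genes take the
    highest-precedence category in the pie view; every qualifying gene is
    listed in ``gene_findings`` (the bar view).
    """
    findings: list[GeneFinding] = []
    all_flags: list[str] = []
    genes = sorted({cv.variant.gene for cv in g.variants})
    for gene in genes:
        lp_p = g.lp_p_variants(gene)
        if not lp_p:
            continue
        status, flags = resolve_biallelic(
            lp_p, g.phase_evidence, g.biochem_corroboration
        )
        all_flags.extend(flags)
        cat = _gene_category(panel[gene].inheritance, status, g.sex)
        if cat is not None:
            findings.append(GeneFinding(gene, status, cat, lp_p))

    if findings:
        best = min(
            findings, key=lambda f: _CATEGORY_PRECEDENCE.index(f.category)
        )
        category = best.category
        supporting = best.variants
        presumed = best.status is BiallelicStatus.PRESUMED
    else:
        classes = [cv.acmg_class for cv in g.variants]
        supporting = []
        presumed = False
        if AcmgClass.VUS in classes:
            category = Category.VUS_CARRIER
            supporting = [
                cv for cv in g.variants if cv.acmg_class is AcmgClass.VUS
            ]
        elif classes:
            category = Category.LB_B_CARRIER
            supporting = list(g.variants)
        else:
            category = Category.NONE

    return DiagnosisResult(
        individual_id=g.individual_id,
        group=g.group,
        category=category,
        monogenic_ksd=category in MONOGENIC_CATEGORIES,
        strong_risk_factor=category in MONOGENIC_CATEGORIES,
        presumed=presumed,
        supporting_variants=supporting,
        gene_findings=findings,
        flags=all_flags,
    )


# ---------------------------------------------------------------------------
# reclassification
# ---------------------------------------------------------------------------


def _monoallelic_demoted(
    gene: str, variants: Sequence[ClassifiedVariant], panel: GenePanel
) -> bool:
    """Is this monoallelic finding in the demotion set?"""
    pg = panel[gene]
    if pg.monoallelic_demoted:
        return True
    if pg.demoted_alleles:
        hgvs = {cv.variant.hgvs_p for cv in variants}
        if hgvs and hgvs <= pg.demoted_alleles:
            return True
    return False


def reclassify_strong_risk(
    d: DiagnosisResult, panel: GenePanel
) -> DiagnosisResult:
    """Demote monoallelic LP/P findings without biochemical support.

    The strong-risk-factor flag is cleared when the diagnostic category
    rests solely on a monoallelic genotype in a demoted gene, or on a
    demoted allele in the monoallelic state.  Biallelic and hemizygous
    categories are never demoted.  The category itself is unchanged; only
    the flag moves.
    """
    d = dataclasses.replace(d)
    if not d.monogenic_ksd:
        d.strong_risk_factor = False
        return d
    if d.category in (
        Category.MONOALLELIC_AD,
        Category.MONOALLELIC_AD_AR,
    ):
        # every monoallelic finding must be demoted for the flag to drop:
        # a second, non-demoted monoallelic gene keeps the individual a
        # strong-risk carrier
        monoallelic = [
            f
            for f in d.gene_findings
            if f.category
            in (Category.MONOALLELIC_AD, Category.MONOALLELIC_AD_AR)
        ]
        if monoallelic and all(
            _monoallelic_demoted(f.gene, f.variants, panel)
            for f in monoallelic
        ):
            d.strong_risk_factor = False
    return d


def diagnose_cohort(
    genotypes: Iterable[IndividualGenotype],
    panel: GenePanel,
    reclassify: bool = True,
) -> list[DiagnosisResult]:
    results = []
    for g in genotypes:
        d = assign_category(g, panel)
        if reclassify:
            d = reclassify_strong_risk(d, panel)
        results.append(d)
    return results


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------


def round_pct(n: int, total: int, decimals: int = 1) -> float:
    """100·n/total rounded half-up (printed-percentage convention)."""
    if total == 0:
        raise ZeroDivisionError("empty denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(n) / Decimal(total)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def cohort_counts(
    results: Sequence[DiagnosisResult], group: Optional[str] = None
) -> pd.DataFrame:
    """Category counts and printed percentages for one group.

    Every individual appears in exactly one category; duplicate ids fail.
    """
    if group is not None:
        results = [r for r in results if r.group == group]
    ids = [r.individual_id for r in results]
    dup = [i for i, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate individual ids: {sorted(dup)[:5]}")
    n = len(results)
    counts = Counter(r.category for r in results)
    rows = []
    for cat in _CATEGORY_PRECEDENCE:
        c = counts.get(cat, 0)
        rows.append(
            {
                "category": cat.value,
                "count": c,
                "percent": round_pct(c, n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows) if n else pd.DataFrame(
        columns=["category", "count", "percent"]
    )


def gene_bar_counts(
    results: Sequence[DiagnosisResult], group: Optional[str] = None
) -> pd.DataFrame:
    """Non-exclusive per-gene counts split by zygosity (bar view);
    multi-gene individuals appear once per qualifying gene."""
    if group is not None:
        results = [r for r in results if r.group == group]
    rows: Counter = Counter()
    for r in results:
        for f in r.gene_findings:
            zyg = (
                "biallelic"
                if f.status
                in (BiallelicStatus.PROVEN, BiallelicStatus.PRESUMED)
                else "monoallelic"
            )
            if f.category is Category.XLR_HEMIZYGOUS:
                zyg = "hemizygous"
            rows[(f.gene, zyg)] += 1
    return pd.DataFrame(
        [
            {"gene": g, "zygosity": z, "count": c}
            for (g, z), c in sorted(rows.items())
        ]
    )


def solve_rate(
    results: Sequence[DiagnosisResult],
    mode: str = "post_reclassification",
    group: str = "KSF",
) -> float:
    """Percentage of individuals with monogenic disease.

    ``pre_reclassification`` counts the monogenic category; the post mode
    counts only strong genetic risk factors left after demotion.
    """
    if mode not in ("pre_reclassification", "post_reclassification"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = [r for r in results if r.group == group]
    if not sub:
        raise ValueError(f"no individuals in group {group!r}")
    if mode == "pre_reclassification":
        n = sum(r.monogenic_ksd for r in sub)
    else:
        n = sum(r.strong_risk_factor for r in sub)
    return round_pct(n, len(sub))


# ---------------------------------------------------------------------------
# round-trip serialization
# ---------------------------------------------------------------------------


def write_results_jsonl(
    results: Sequence[DiagnosisResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for r in results:
            fh.write(json.dumps(r.to_record(), sort_keys=True) + "\n")


def read_results_jsonl(path: str | Path) -> pd.DataFrame:
    """Reload serialized results as a flat frame (category-level fields)."""
    records = [
        json.loads(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
    return pd.DataFrame.from_records(records)
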