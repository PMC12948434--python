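"""Panel-restricted variant ingestion and the quality/frequency/consequence
filter cascade.

Variant calls arrive either as an annotated flat table (TSV) or as a VCF
with conventional INFO/FORMAT fields; both are reduced to
:class:`AnnotatedVariant` records, one per individual per alt allele.
Filtering then proceeds site-wise in a fixed order:

1. quality — a site is dropped for all carriers when more than 60% of its
   carriers show a variant allele fraction below 0.3, or when its site
   quality is below 25;
2. cohort frequency — sites carried by more than 10% of cohort individuals
   are treated as artifacts or common polymorphisms and dropped;
3. population frequency — variants with gnomAD allele frequency above 1%
   are dropped (missing frequency counts as rare; whitelisted pathogenic
   intronic variants are always kept);
4. consequence — only nonsynonymous coding changes within 10 bp of the
   exon boundary, canonical splice-site variants, and whitelisted intronic
   variants are retained.

All frequency comparisons are strict (``>``), and the 60% low-allele-
fraction proportion is computed over the carriers of the site.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .panel import GenePanel


class Genotype(str, Enum):
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"


class Consequence(str, Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    CANONICAL_SPLICE = "canonical_splice"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    OTHER = "other"


#: consequence classes counting as nonsynonymous coding for the
#: region-of-interest filter (splice_region is included: it lies inside
#: the exon ± 10 bp window and is not demonstrably synonymous)
NONSYNONYMOUS_CODING = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.STOP_GAIN,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_REGION,
    }
)

SiteKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant call in one individual (VCF-convention coordinates)."""

    individual_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: Genotype
    allele_fraction: float
    site_quality: float
    consequence: Consequence
    splice_distance_bp: int = 0
    gnomad_af: Optional[float] = None
    whitelist_pathogenic_intronic: bool = False
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(
                f"allele_fraction out of [0,1]: {self.allele_fraction}"
            )
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError(f"gnomad_af out of [0,1]: {self.gnomad_af}")
        if self.site_quality < 0:
            raise ValueError(f"site_quality negative: {self.site_quality}")
        if self.splice_distance_bp < 0:
            raise ValueError("splice_distance_bp must be >= 0")

    @property
    def site(self) -> SiteKey:
        """Variant identity shared across individuals."""
        return (self.chrom, self.pos, self.ref, self.alt)


class FilterConfig(BaseModel):
    """Thresholds of the filter cascade (defaults follow the study design)."""

    min_allele_fraction: float = Field(0.3, ge=0.0, le=1.0)
    max_fraction_individuals_low_af: float = Field(0.6, ge=0.0, le=1.0)
    min_quality: float = Field(25.0, ge=0.0)
    max_cohort_carrier_fraction: float = Field(0.10, ge=0.0, le=1.0)
    max_gnomad_af: float = Field(0.01, ge=0.0, le=1.0)
    splice_window_bp: int = Field(10, ge=0)

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "individual_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "genotype",
    "allele_fraction",
    "site_quality",
    "consequence",
    "splice_distance_bp",
    "gnomad_af",
    "whitelist_pathogenic_intronic",
    "hgvs_p",
]


def variants_to_frame(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        d = dataclasses.asdict(v)
        d["genotype"] = v.genotype.value
        d["consequence"] = v.consequence.value
        rows.append(d)
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_variants_tsv(
    variants: Sequence[AnnotatedVariant], path: str | Path
) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def load_variants_tsv(
    path: str | Path, panel: GenePanel
) -> list[AnnotatedVariant]:
    """Read an annotated flat table, keeping only panel genes.

    Unknown gene symbols are dropped with a warning; malformed rows raise
    with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    unknown = sorted(set(df["gene"]) - panel.symbols())
    if unknown:
        warnings.warn(
            f"dropping variants in non-panel genes: {unknown}", stacklevel=2
        )
        df = df[df["gene"].isin(panel.symbols())]
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            gaf = row.gnomad_af
            out.append(
                AnnotatedVariant(
                    individual_id=str(row.individual_id),
                    gene=row.gene,
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    genotype=Genotype(row.genotype),
                    allele_fraction=float(row.allele_fraction),
                    site_quality=float(row.site_quality),
                    consequence=Consequence(row.consequence),
                    splice_distance_bp=int(row.splice_distance_bp),
                    gnomad_af=None if pd.isna(gaf) else float(gaf),
                    whitelist_pathogenic_intronic=bool(
                        row.whitelist_pathogenic_intronic
                    ),
                    hgvs_p="" if pd.isna(row.hgvs_p) else str(row.hgvs_p),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed variant table row {i + 2}: {exc}")
    return out


def load_variants_vcf(
    path: str | Path, panel: GenePanel
) -> list[AnnotatedVariant]:
    """Read a multi-sample VCF with the annotation convention below.

    INFO: ``GENE`` (symbol), ``CSQ_CLASS`` (controlled consequence
    vocabulary, per alt allele), ``SPLICE_DIST`` (bp into intron),
    ``GNOMAD_AF`` (per alt allele), ``WLPI`` (flag, whitelisted pathogenic
    intronic), ``HGVSP`` (optional).  FORMAT: ``GT`` and ``VAF`` (variant
    allele fraction, per alt allele).  Site quality is taken from QUAL.
    Multi-allelic records are decomposed into one record per alt allele.
    """
    import pysam

    def _per_alt(value, n_alt: int, i: int):
        if value is None:
            return None
        if isinstance(value, (tuple, list)):
            return value[i] if i < len(value) else value[0]
        return value

    def _info_get(rec, key):
        try:
            return rec.info.get(key)
        except (KeyError, ValueError):  # key absent from the VCF header
            return None

    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gene = _info_get(rec, "GENE")
            if gene is None or gene not in panel:
                continue
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                alt_index = i + 1
                csq = _per_alt(_info_get(rec, "CSQ_CLASS"), len(alts), i)
                gaf = _per_alt(_info_get(rec, "GNOMAD_AF"), len(alts), i)
                sdist = _per_alt(_info_get(rec, "SPLICE_DIST"), len(alts), i)
                hgvsp = _per_alt(_info_get(rec, "HGVSP"), len(alts), i)
                for sample, call in rec.samples.items():
                    gt = call.get("GT")
                    if gt is None or alt_index not in gt:
                        continue
                    non_missing = [a for a in gt if a is not None]
                    if len(non_missing) == 1:
                        genotype = Genotype.HEMI
                    elif all(a == alt_index for a in non_missing):
                        genotype = Genotype.HOM_ALT
                    else:
                        genotype = Genotype.HET
                    vaf = _per_alt(call.get("VAF"), len(alts), i)
                    try:
                        out.append(
                            AnnotatedVariant(
                                individual_id=sample,
                                gene=gene,
                                chrom=str(rec.chrom),
                                pos=int(rec.pos),
                                ref=rec.ref,
                                alt=alt,
                                genotype=genotype,
                                allele_fraction=float(vaf),
                                site_quality=float(rec.qual or 0.0),
                                consequence=Consequence(csq),
                                splice_distance_bp=int(sdist or 0),
                                gnomad_af=None if gaf is None else float(gaf),
                                whitelist_pathogenic_intronic=bool(
                                    _info_get(rec, "WLPI") or False
                                ),
                                hgvs_p=hgvsp or "",
                            )
                        )
                    except (ValueError, TypeError) as exc:
                        raise ValueError(
                            f"malformed VCF record {rec.chrom}:{rec.pos} "
                            f"sample {sample}: {exc}"
                        )
    return out


def load_variants(
    source: str | Path, panel: GenePanel
) -> list[AnnotatedVariant]:
    """Dispatch on file extension: ``.vcf``/``.vcf.gz`` or flat TSV."""
    name = str(source)
    if name.endswith((".vcf", ".vcf.gz")):
        return load_variants_vcf(source, panel)
    return load_variants_tsv(source, panel)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _group_by_site(
    variants: Sequence[AnnotatedVariant],
) -> dict[SiteKey, list[AnnotatedVariant]]:
    sites: dict[SiteKey, list[AnnotatedVariant]] = defaultdict(list)
    for v in variants:
        sites[v.site].append(v)
    return sites


def quality_filter(
    variants: Sequence[AnnotatedVariant],
    cfg: FilterConfig,
    n_individuals: int,
) -> list[AnnotatedVariant]:
    """Drop sites failing the allele-fraction or site-quality rule.

    A site fails when the fraction of its carriers with allele fraction
    below ``min_allele_fraction`` exceeds ``max_fraction_individuals_low_af``,
    or when its site quality (minimum across carrier records when they
    disagree) is below ``min_quality``.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be > 0")
    bad_sites = set()
    for site, calls in _group_by_site(variants).items():
        carriers = {c.individual_id for c in calls}
        low_af = {
            c.individual_id
            for c in calls
            if c.allele_fraction < cfg.min_allele_fraction
        }
        frac_low = len(low_af) / len(carriers)
        quality = min(c.site_quality for c in calls)
        if frac_low > cfg.max_fraction_individuals_low_af or (
            quality < cfg.min_quality
        ):
            bad_sites.add(site)
    return [v for v in variants if v.site not in bad_sites]


def cohort_frequency_filter(
    variants: Sequence[AnnotatedVariant],
    cfg: FilterConfig,
    n_individuals: int,
) -> list[AnnotatedVariant]:
    """Drop sites carried by more than ``max_cohort_carrier_fraction`` of
    the cohort."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be > 0")
    bad_sites = set()
    for site, calls in _group_by_site(variants).items():
        n_carriers = len({c.individual_id for c in calls})
        if n_carriers / n_individuals > cfg.max_cohort_carrier_fraction:
            bad_sites.add(site)
    return [v for v in variants if v.site not in bad_sites]


def population_frequency_filter(
    variants: Sequence[AnnotatedVariant], cfg: FilterConfig
) -> list[AnnotatedVariant]:
    """Drop variants above the gnomAD frequency cutoff.

    Missing frequency is treated as rare (novel variants must survive to
    classification); whitelisted pathogenic intronic variants are always
    retained.
    """
    return [
        v
        for v in variants
        if v.whitelist_pathogenic_intronic
        or v.gnomad_af is None
        or v.gnomad_af <= cfg.max_gnomad_af
    ]


def consequence_filter(
    variants: Sequence[AnnotatedVariant], cfg: FilterConfig
) -> list[AnnotatedVariant]:
    """Keep nonsynonymous coding variants in the exon ± splice window,
    canonical splice-site variants, and whitelisted intronic variants."""
    out = []
    for v in variants:
        if v.whitelist_pathogenic_intronic:
            out.append(v)
        elif v.consequence is Consequence.CANONICAL_SPLICE:
            out.append(v)
        elif (
            v.consequence in NONSYNONYMOUS_CODING
            and v.splice_distance_bp <= cfg.splice_window_bp
        ):
            out.append(v)
    return out


@dataclass
class FilterReport:
    """Per-stage removal counts (first-removing-stage attribution)."""

    n_input: int
    removed_quality: int
    removed_cohort_frequency: int
    removed_population_frequency: int
    removed_consequence: int
    n_output: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    def check_conservation(self) -> bool:
        removed = (
            self.removed_quality
            + self.removed_cohort_frequency
            + self.removed_population_frequency
            + self.removed_consequence
        )
        return self.n_input == self.n_output + removed


def run_filter_cascade(
    variants: Sequence[AnnotatedVariant],
    cfg: FilterConfig,
    n_individuals: int,
) -> tuple[list[AnnotatedVariant], FilterReport]:
    """Apply quality → cohort-frequency → population-frequency →
    consequence filters in order, reporting per-stage removals."""
    stage0 = list(variants)
    stage1 = quality_filter(stage0, cfg, n_individuals)
    stage2 = cohort_frequency_filter(stage1, cfg, n_individuals)
    stage3 = population_frequency_filter(stage2, cfg)
    stage4 = consequence_filter(stage3, cfg)
    report = FilterReport(
        n_input=len(stage0),
        removed_quality=len(stage0) - len(stage1),
        removed_cohort_frequency=len(stage1) - len(stage2),
        removed_population_frequency=len(stage2) - len(stage3),
        removed_consequence=len(stage3) - len(stage4),
        n_output=len(stage4),
    )
    return stage4, report


def filter_from_source(
    source: str | Path,
    panel: GenePanel,
    cfg: FilterConfig,
    n_individuals: int,
) -> tuple[list[AnnotatedVariant], FilterReport]:
    """Convenience: load from file and run the cascade."""
    return run_filter_cascade(load_variants(source, panel), cfg, n_individuals)
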