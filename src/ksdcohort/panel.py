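"""Gene panel model for monogenic kidney stone disease.

A :class:`PanelGene` couples a gene symbol with its reported Mendelian
inheritance mode and with the demotion flags used when monoallelic
(likely) pathogenic variants are reinterpreted as insufficient risk
factors.  The default panel holds 39 established nephrolithiasis genes
grouped by the solute-handling pathway they disturb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd


class Inheritance(str, Enum):
    AR = "AR"
    AD = "AD"
    AD_AR = "AD_AR"
    XLR = "XLR"


@dataclass(frozen=True)
class PanelGene:
    """One gene of the diagnostic panel.

    Parameters
    ----------
    symbol:
        HGNC gene symbol.
    inheritance:
        Reported inheritance mode for kidney stone disease.
    monoallelic_demoted:
        True when heterozygous LP/P variants in this gene are reclassified
        as insufficient to act as a strong monogenic risk factor (biallelic
        genotypes are never demoted).
    demoted_alleles:
        Protein-level identifiers (HGVS p.) of individual alleles demoted in
        the monoallelic state even though the gene as a whole is not.
    """

    symbol: str
    inheritance: Inheritance
    monoallelic_demoted: bool = False
    demoted_alleles: frozenset[str] = field(default_factory=frozenset)


class GenePanel:
    """An ordered, symbol-unique collection of :class:`PanelGene`."""

    def __init__(self, genes: Iterable[PanelGene]):
        genes = list(genes)
        symbols = [g.symbol for g in genes]
        if len(set(symbols)) != len(symbols):
            dup = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate panel gene symbols: {dup}")
        self._by_symbol = {g.symbol: g for g in genes}

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __iter__(self):
        return iter(self._by_symbol.values())

    def __getitem__(self, symbol: str) -> PanelGene:
        return self._by_symbol[symbol]

    def symbols(self) -> set[str]:
        return set(self._by_symbol)

    # ---- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "symbol": [g.symbol for g in self],
                "inheritance": [g.inheritance.value for g in self],
                "monoallelic_demoted": [g.monoallelic_demoted for g in self],
                "demoted_alleles": [
                    ";".join(sorted(g.demoted_alleles)) for g in self
                ],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenePanel":
        genes = []
        for row in df.itertuples(index=False):
            alleles = getattr(row, "demoted_alleles", "") or ""
            if isinstance(alleles, float):  # NaN from empty TSV cell
                alleles = ""
            genes.append(
                PanelGene(
                    symbol=row.symbol,
                    inheritance=Inheritance(row.inheritance),
                    monoallelic_demoted=bool(
                        getattr(row, "monoallelic_demoted", False)
                    ),
                    demoted_alleles=frozenset(
                        a for a in str(alleles).split(";") if a
                    ),
                )
            )
        return cls(genes)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenePanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenePanel":
        records = json.loads(Path(path).read_text())
        return cls.from_frame(pd.DataFrame.from_records(records))


# Alleles reinterpreted individually: the recurrent hypomorphic
# SLC7A9 p.(Ala182Thr) allele has no measurable effect on urinary
# cystine in the heterozygous state.
SLC7A9_ALA182THR = "p.(Ala182Thr)"

_AR = Inheritance.AR
_AD = Inheritance.AD
_AD_AR = Inheritance.AD_AR
_XLR = Inheritance.XLR

# 39 established kidney-stone-disease genes.  Monoallelic demotion flags
# mark genes whose heterozygous LP/P variants lack a biochemical phenotype
# and are as frequent in stone-free controls as in stone formers.
_DEFAULT_PANEL: list[PanelGene] = [
    # cystinuria
    PanelGene("SLC3A1", _AR),
    PanelGene(
        "SLC7A9", _AD_AR, demoted_alleles=frozenset({SLC7A9_ALA182THR})
    ),
    # phosphate and calcium handling
    PanelGene("SLC34A1", _AD_AR, monoallelic_demoted=True),
    PanelGene("SLC34A3", _AD_AR),
    PanelGene("SLC9A3R1", _AD, monoallelic_demoted=True),
    PanelGene("CYP24A1", _AD_AR, monoallelic_demoted=True),
    PanelGene("SLC4A1", _AD_AR),
    PanelGene("ALPL", _AD),
    PanelGene("CASR", _AD),
    PanelGene("AP2S1", _AD),
    PanelGene("GNA11", _AD),
    PanelGene("ADCY10", _AD),
    PanelGene("SLC2A9", _AD),
    # oxalate metabolism (primary hyperoxaluria)
    PanelGene("AGXT", _AR),
    PanelGene("GRHPR", _AR),
    PanelGene("HOGA1", _AR),
    PanelGene("SLC26A1", _AR),
    # renal tubular acidosis / Bartter spectrum
    PanelGene("ATP6V0A4", _AR),
    PanelGene("ATP6V1B1", _AR),
    PanelGene("CA2", _AR),
    PanelGene("SLC12A1", _AR),
    PanelGene("KCNJ1", _AR),
    PanelGene("CLCNKB", _AR),
    PanelGene("BSND", _AR),
    # magnesium handling
    PanelGene("CLDN16", _AR),
    PanelGene("CLDN19", _AR),
    PanelGene("TRPM6", _AR),
    # purine metabolism
    PanelGene("APRT", _AR),
    PanelGene("XDH", _AR),
    PanelGene("MOCS1", _AR),
    PanelGene("SLC22A12", _AR),
    # amelogenesis imperfecta / nephrocalcinosis
    PanelGene("FAM20A", _AR),
    # vitamin D metabolism
    PanelGene("CYP2R1", _AR),
    # uromodulin-associated disease
    PanelGene("UMOD", _AD),
    # cystinosis
    PanelGene("CTNS", _AR),
    # Dent disease / Lowe syndrome / purine salvage, X-linked
    PanelGene("CLCN5", _XLR),
    PanelGene("OCRL", _XLR),
    PanelGene("HPRT1", _XLR),
    # hereditary hypophosphatemia
    PanelGene("FGF23", _AD),
]

assert len(_DEFAULT_PANEL) == 39


def default_panel() -> GenePanel:
    """The default 39-gene kidney-stone-disease panel."""
    return GenePanel(_DEFAULT_PANEL)
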