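"""Diagnosis categories, phase resolution, reclassification, summaries."""

import pytest

from ksdcohort.acmg import AcmgClass
from ksdcohort.diagnosis import (
    BiallelicStatus,
    Category,
    ClassifiedVariant,
    DiagnosisResult,
    IndividualGenotype,
    Phase,
    assign_category,
    cohort_counts,
    diagnose_cohort,
    gene_bar_counts,
    read_results_jsonl,
    reclassify_strong_risk,
    resolve_biallelic,
    round_pct,
    solve_rate,
    write_results_jsonl,
)
from ksdcohort.variants import AnnotatedVariant, Consequence, Genotype

_POS = iter(range(1000, 100000, 7))


def cv(gene, genotype=Genotype.HET, cls=AcmgClass.LP, hgvs="", pos=None,
       chrom="1"):
    pos = pos if pos is not None else next(_POS)
    return ClassifiedVariant(
        AnnotatedVariant(
            individual_id="X",
            gene=gene,
            chrom=chrom,
            pos=pos,
            ref="A",
            alt="G",
            genotype=genotype,
            allele_fraction=0.5 if genotype is Genotype.HET else 1.0,
            site_quality=60.0,
            consequence=Consequence.MISSENSE,
            hgvs_p=hgvs,
        ),
        cls,
    )


def genotype_of(*cvs, sex="F", group="KSF", phase=None, corroboration=None):
    return IndividualGenotype(
        individual_id="X",
        sex=sex,
        group=group,
        variants=list(cvs),
        phase_evidence=phase or {},
        biochem_corroboration=corroboration,
    )


def pair_key(a, b):
    return frozenset({a.variant.site, b.variant.site})


class TestResolveBiallelic:
    def test_homozygous_is_proven(self):
        status, _ = resolve_biallelic([cv("SLC3A1", Genotype.HOM_ALT)], {})
        assert status is BiallelicStatus.PROVEN

    def test_two_hets_trans_by_reads_proven(self):
        a, b = cv("SLC7A9"), cv("SLC7A9")
        status, _ = resolve_biallelic(
            [a, b], {pair_key(a, b): Phase.TRANS_BY_READS}
        )
        assert status is BiallelicStatus.PROVEN

    def test_two_hets_cis_is_monoallelic(self):
        a, b = cv("SLC7A9"), cv("SLC7A9")
        status, _ = resolve_biallelic(
            [a, b], {pair_key(a, b): Phase.CIS_BY_READS}
        )
        assert status is BiallelicStatus.MONOALLELIC

    def test_unknown_phase_presumed(self):
        a, b = cv("SLC7A9"), cv("SLC7A9")
        status, _ = resolve_biallelic([a, b], {})
        assert status is BiallelicStatus.PRESUMED

    def test_single_het_monoallelic(self):
        status, _ = resolve_biallelic([cv("SLC3A1")], {})
        assert status is BiallelicStatus.MONOALLELIC

    def test_discordant_biochemistry_recorded_not_category_changing(self):
        # the presumed-biallelic call stands; the discordance is a flag
        a, b = cv("SLC7A9"), cv("SLC7A9")
        status, flags = resolve_biallelic(
            [a, b], {}, biochem_corroboration=False
        )
        assert status is BiallelicStatus.PRESUMED
        assert "presumed_trans_discordant_biochemistry" in flags

    def test_three_variants_flagged_for_review(self):
        vs = [cv("SLC3A1") for _ in range(3)]
        status, flags = resolve_biallelic(vs, {})
        assert status is BiallelicStatus.PRESUMED
        assert "more_than_two_lp_p_variants_review" in flags

    def test_requires_at_least_one_variant(self):
        with pytest.raises(ValueError):
            resolve_biallelic([], {})


class TestAssignCategory:
    def test_hemizygous_xlr_male(self, panel):
        g = genotype_of(cv("OCRL", Genotype.HEMI, chrom="X"), sex="M")
        assert assign_category(g, panel).category is Category.XLR_HEMIZYGOUS

    def test_multi_gene_takes_biallelic_in_pie_both_in_bars(self, panel):
        a, b = cv("SLC7A9"), cv("SLC7A9")
        g = genotype_of(
            a, b, cv("SLC9A3R1"),
            phase={pair_key(a, b): Phase.TRANS_BY_READS},
        )
        d = assign_category(g, panel)
        assert d.category is Category.BIALLELIC_AD_AR
        assert {f.gene for f in d.gene_findings} == {"SLC7A9", "SLC9A3R1"}

    def test_vus_only_is_vus_carrier(self, panel):
        g = genotype_of(cv("ALPL", cls=AcmgClass.VUS))
        d = assign_category(g, panel)
        assert d.category is Category.VUS_CARRIER
        assert not d.monogenic_ksd

    def test_carrier_ar_not_monogenic(self, panel):
        d = assign_category(genotype_of(cv("SLC3A1")), panel)
        assert d.category is Category.CARRIER_AR
        assert not d.monogenic_ksd

    def test_precedence_lp_over_vus_over_benign(self, panel):
        g = genotype_of(
            cv("SLC34A3"), cv("ALPL", cls=AcmgClass.VUS),
            cv("AGXT", cls=AcmgClass.B),
        )
        assert (
            assign_category(g, panel).category is Category.MONOALLELIC_AD_AR
        )

    def test_no_variants_is_none(self, panel):
        d = assign_category(genotype_of(), panel)
        assert d.category is Category.NONE


class TestReclassification:
    def demote(self, d, panel):
        return reclassify_strong_risk(d, panel)

    def test_monoallelic_demoted_gene_loses_strong_risk(self, panel):
        d = assign_category(genotype_of(cv("CYP24A1")), panel)
        assert d.monogenic_ksd
        assert not self.demote(d, panel).strong_risk_factor

    def test_monoallelic_slc34a3_keeps_strong_risk(self, panel):
        d = assign_category(genotype_of(cv("SLC34A3")), panel)
        assert self.demote(d, panel).strong_risk_factor

    def test_biallelic_demoted_gene_keeps_strong_risk(self, panel):
        d = assign_category(
            genotype_of(cv("CYP24A1", Genotype.HOM_ALT)), panel
        )
        assert d.category is Category.BIALLELIC_AD_AR
        assert self.demote(d, panel).strong_risk_factor

    def test_recurrent_hypomorphic_allele_demoted_when_sole_support(
        self, panel
    ):
        d = assign_category(
            genotype_of(cv("SLC7A9", hgvs="p.(Ala182Thr)")), panel
        )
        assert not self.demote(d, panel).strong_risk_factor

    def test_other_slc7a9_alleles_keep_strong_risk(self, panel):
        d = assign_category(
            genotype_of(cv("SLC7A9", hgvs="p.(Gly105Arg)")), panel
        )
        assert self.demote(d, panel).strong_risk_factor

    def test_second_non_demoted_gene_preserves_strong_risk(self, panel):
        g = genotype_of(cv("CYP24A1"), cv("SLC34A3"))
        d = self.demote(assign_category(g, panel), panel)
        assert d.strong_risk_factor

    def test_category_itself_is_never_changed(self, panel):
        d = assign_category(genotype_of(cv("SLC9A3R1")), panel)
        assert self.demote(d, panel).category is d.category


class TestCohortSummaries:
    def test_round_pct_half_up(self):
        assert round_pct(11, 701) == 1.6
        assert round_pct(38, 701) == 5.4
        assert round_pct(1, 16) == 6.3  # 6.25 rounds up, not to even

    def test_counts_partition_and_duplicate_detection(self, panel):
        genotypes = [
            genotype_of(cv("SLC34A3")),
            genotype_of(cv("SLC3A1")),
            genotype_of(),
        ]
        for i, g in enumerate(genotypes):
            g.individual_id = f"I{i}"
        results = diagnose_cohort(genotypes, panel)
        table = cohort_counts(results, "KSF")
        assert table["count"].sum() == 3
        results[1] = DiagnosisResult(
            individual_id="I0", group="KSF", category=Category.NONE,
            monogenic_ksd=False, strong_risk_factor=False, presumed=False,
            supporting_variants=[],
        )
        with pytest.raises(ValueError, match="duplicate"):
            cohort_counts(results, "KSF")

    def test_empty_cohort_counts(self):
        assert cohort_counts([], "KSF").empty

    def test_solve_rate_modes(self, panel):
        genotypes = []
        for i, maker in enumerate(
            [lambda: genotype_of(cv("SLC34A3"))] * 2
            + [lambda: genotype_of(cv("CYP24A1"))] * 3
            + [lambda: genotype_of()] * 5
        ):
            g = maker()
            g.individual_id = f"I{i}"
            genotypes.append(g)
        results = diagnose_cohort(genotypes, panel)
        assert solve_rate(results, "pre_reclassification") == 50.0
        assert solve_rate(results, "post_reclassification") == 20.0

    def test_zero_lp_p_cohort_rate(self, panel):
        g = genotype_of(cv("ALPL", cls=AcmgClass.VUS))
        assert solve_rate(diagnose_cohort([g], panel),
                          "post_reclassification") == 0.0


class TestSerialization:
    def test_jsonl_round_trip_preserves_counts(self, panel, tmp_path):
        genotypes = []
        for i in range(4):
            g = genotype_of(cv("SLC34A3")) if i % 2 else genotype_of()
            g.individual_id = f"I{i}"
            genotypes.append(g)
        results = diagnose_cohort(genotypes, panel)
        path = tmp_path / "results.jsonl"
        write_results_jsonl(results, path)
        df = read_results_jsonl(path)
        assert df["category"].value_counts().to_dict() == {
            "monoallelic_AD_AR": 2,
            "none": 2,
        }


class TestCohortScalePartition:
    def test_every_individual_exactly_one_category(self, default_cohort):
        from ksdcohort.pipeline import diagnose_simulated

        results, _ = diagnose_simulated(default_cohort)
        assert len(results) == default_cohort.n_individuals
        for group, n in (("KSF", 701), ("NKSF", 200)):
            table = cohort_counts(results, group)
            assert table["count"].sum() == n

    def test_demotion_never_increases_strong_risk(self, default_cohort):
        from ksdcohort.pipeline import diagnose_simulated

        pre, _ = diagnose_simulated(default_cohort, reclassify=False)
        post, _ = diagnose_simulated(default_cohort, reclassify=True)
        n_pre = sum(r.strong_risk_factor for r in pre)
        n_post = sum(r.strong_risk_factor for r in post)
        assert n_post <= n_pre
        assert solve_rate(post, "post_reclassification") <= solve_rate(
            post, "pre_reclassification"
        )

    def test_bar_view_double_counts_multi_gene_individuals(
        self, default_cohort
    ):
        from ksdcohort.pipeline import diagnose_simulated

        results, _ = diagnose_simulated(default_cohort)
        bars = gene_bar_counts(results, "KSF")
        r1 = bars[(bars.gene == "SLC9A3R1")]["count"].sum()
        assert r1 == 6  # 5 monoallelic-category + 1 attached to biallelic
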