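# Methods

`ksdcohort` reimplements, as a tested pipeline, a cohort-scale workflow
for interpreting rare variants in adult kidney stone disease (KSD):
panel-restricted variant filtering, ACMG/AMP classification,
inheritance-mode-aware monogenic diagnosis with biochemistry-driven
reclassification, derived biochemical phenotyping, and stone-recurrence
survival analysis. Because individual-level sequencing and visit data
from such studies are not publicly distributable, the package ships a
synthetic cohort generator that emulates the structure of a two-group
study (701 stone formers, KSF; 200 CT-verified stone-free controls,
NKSF) so that every stage is exercised end to end.

## Variant filtering

Variant calls are restricted to a 39-gene KSD panel and filtered
site-wise in a fixed order: (1) quality — a site is dropped for all its
carriers when more than 60% of carriers show a variant allele fraction
below 0.3, or when site quality is below 25; (2) cohort frequency —
sites carried by more than 10% of cohort individuals are dropped as
artifacts or common polymorphisms; (3) population frequency — gnomAD
allele frequency above 1% excludes a variant; (4) consequence — only
nonsynonymous coding changes within 10 bp of the exon boundary,
canonical splice-site variants, and whitelisted known-pathogenic
intronic variants are retained. All frequency comparisons are strict
(`>`). Three conventions are deliberate design choices:

* "read frequency" is interpreted as the per-carrier variant allele
  fraction, and the 60% proportion is computed over the *carriers* of a
  site (carrier-based artifact removal is standard practice; the
  all-individuals reading would make the rule nearly vacuous for rare
  variants);
* a missing gnomAD frequency is treated as rare and retained — novel
  variants must survive to classification;
* `splice_region` consequences count as nonsynonymous coding inside the
  10 bp window (they lie in the region of interest and are not
  demonstrably silent).

Variant identity across individuals is the `(chrom, pos, ref, alt)`
tuple in 1-based VCF convention; multi-allelic records are decomposed
per alt allele. The cascade reports first-removing-stage attribution,
so `n_in = n_out + Σ removals` always holds.

## ACMG/AMP classification

Evidence codes (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7) are
curation *inputs*; the engine only combines them. The published
combining rules are implemented on strength-tier counts, with two
extensions used in current practice: `PVS1 + 1 moderate → LP` and `≥2
very-strong → P`. Caller-supplied strength overrides (e.g. calibrated
PP3/BP4 usage) are applied before rule matching. Evidence satisfying
both a pathogenic and a benign rule — a case the guidelines leave to
judgement — is conservatively VUS. Published functional support can
upgrade a VUS to LP only through an explicit override flag, never
silently. The engine is checked exhaustively against an independently
coded rule-table oracle over all evidence multisets with up to three
codes per strength tier (4096 combinations).

## Diagnosis and reclassification

Per gene, LP/P variants are resolved to a zygosity status: a homozygous
or hemizygous call is biallelic by itself; two heterozygotes are proven
biallelic by read-backed *trans* phase, refuted by *cis* phase, and
*presumed* biallelic when reads cannot phase them. Urinary dibasic
amino-acid corroboration of presumed *trans* is recorded as an
annotation but never changes the category — matching the study
convention that kept a biochemically discordant presumed compound
heterozygote in the presumed-biallelic group.

Each individual receives exactly one category by precedence:
biallelic in an AR gene > biallelic in an AD/AR gene > XLR hemizygous
(males) > monoallelic in an AD gene > monoallelic in an AD/AR gene >
AR-carrier > VUS carrier > LB/B carrier > none. The first five count as
monogenic KSD. Individuals with qualifying variants in several genes
take the highest category in this exclusive ("pie") view and are listed
once per gene in a separate non-exclusive ("bar") view.

Reclassification demotes monoallelic LP/P genotypes without a
biochemical phenotype: heterozygous variants in *SLC9A3R1*, *SLC34A1*
and *CYP24A1* (gene-level flags) and the recurrent hypomorphic
*SLC7A9* p.(Ala182Thr) allele (allele-level flag). Biallelic and
hemizygous genotypes are never demoted, and a second non-demoted
monoallelic finding preserves the flag. Only the strong-risk flag
moves; the category is unchanged. Printed percentages use half-up
rounding to one decimal.

## Derived biochemistry

* TRP = 1 − (U_P·P_cr)/(U_cr·P_P); TmP/GFR by the Payne/Barth algebraic
  approximation of the Walton–Bijvoet nomogram: linear (TRP·P_P) for
  TRP ≤ 0.86, else 0.3·TRP/(1 − 0.8·TRP)·P_P. The published
  approximation is discontinuous at the branch point (0.86·P_P vs
  ≈0.8269·P_P); the branch rule is applied exactly and tested at the
  boundary. Units: plasma phosphate mmol/L, plasma creatinine µmol/L
  (converted internally).
* Urinary ratios are analyte/creatinine on matching amount units, hence
  volume-invariant.
* The supersaturation index is a deliberately simplified surrogate for
  iterative ion-speciation programs: ion-activity product over a
  configurable solubility product, with Davies activity coefficients
  (A = 0.509), ionic strength from the measured divalent ions plus a
  configurable monovalent background (default 0.15 mol/L), and
  pH-dependent phosphate speciation through pKa₂ = 6.8 only (pKa₁ and
  pKa₃ are negligible at urine pH 4–9). Oxalate is treated as fully
  dissociated; an optional single 1:1 calcium–citrate binding
  correction (log K = 3.5, off by default) reduces free calcium.
  Default solubility products: calcium oxalate monohydrate 2.32·10⁻⁹,
  brushite 2.57·10⁻⁷ mol²/L². **This index is rank- and
  direction-comparable only; it makes no claim of numerical agreement
  with EQUIL2-style speciation outputs.**
* The cystinuria profile classifies cystine/ornithine/lysine/arginine
  ratios (mmol/mol creatinine) against editable adult reference upper
  limits (25/15/60/8), "marked" above five times the limit; the summary
  flag is marked when cystine is marked or at least two dibasic amino
  acids are elevated.

## Statistics

Pearson chi-square on 2×2 tables is computed *without* Yates continuity
correction: on the study's carrier table (107/594 vs 18/182) the
uncorrected statistic (χ² = 5.11) reproduces the reported p = 0.0238,
while the corrected one gives ≈0.032. Mann-Whitney U is two-sided, with
exact enumeration for small untied samples and the tie-corrected normal
approximation otherwise; Kruskal-Wallis is tie-corrected. A
Shapiro-Wilk gate (α = 0.05) selects median (IQR) versus mean ± SD
summaries. Survival uses lifelines: Kaplan-Meier product-limit curves,
the log-rank test, and Cox proportional hazards with Efron tie handling
(a robust default; the tie method is not otherwise constrained) and
Wald confidence intervals. No multiple-testing correction is applied by
default, matching the reporting convention of small-n genotype
subgroups; a Benjamini–Hochberg step is available via
`statsmodels.stats.multitest` where needed. Censoring is administrative
at the 3-year horizon, with time measured from enrollment.

## Synthetic cohort

The generator defines the study conditions; its defaults are fixed, not
tuned. Category counts per group mirror the internally consistent
published counts: among 701 KSFs — 11 (presumed) biallelic (5 *SLC3A1*:
3 homozygous, 1 read-proven, 1 presumed; 4 *SLC7A9*: 2 proven, 2
presumed, one of them the p.(Ala354Thr)/p.(Ala182Thr) compound with
discordant biochemistry; 2 homozygous *CYP24A1*), 1 hemizygous *OCRL*
male, 24 monoallelic in AD genes, 33 in AD/AR genes, 38 AR carriers,
256 VUS carriers, 143 LB/B carriers, and 195 without rare variants.
Demotion leaves 48 strong-risk individuals (6.8%) from the 69 (9.8%)
monogenic pre-reclassification. The 200 controls carry 11
monoallelic-category individuals (one with hets in two genes) and 7 AR
carriers, 90 VUS and 34 LB/B carriers. One source-table inconsistency
is knowingly not "fixed": the published VUS/LB-B/none percentages do
not sum with the LP/P counts to the group sizes (the implied total
exceeds 701); the generator keeps the LP/P, VUS and LB/B counts and
derives the no-variant remainder (195 KSF, 58 NKSF) so the partition is
exact.

Biochemistry is log-normal per analyte (total log-SD 0.25, 60% of the
variance between individuals), with visits V1–V7 for KSFs and V1 for
controls; urine pH and volume are bounded Gaussian. Genotype effects
are configured in units of the log-scale SD with directions anchored to
the reported genotype–phenotype correlations — monoallelic *SLC34A3*:
phosphate wasting (plasma phosphate ↓, urinary phosphate and calcium ↑,
hence TmP/GFR ↓ and brushite supersaturation ↑); biallelic
*SLC3A1*/*SLC7A9*: marked cystine and dibasic amino-aciduria;
monoallelic non-Ala182Thr *SLC7A9*: moderate cystine elevation;
demoted genotypes: null effects. Magnitudes are configuration values
chosen to give the qualitative separations described (marked vs
moderate vs none), not measurements. KSF and NKSF carriers of the same
genotype class are treated identically.

Recurrence is exponential with baseline hazard 2·10⁻⁴/day (≈20% 3-year
event probability in the no-risk group), multiplied by a true hazard
ratio of 2.4506 for strong-risk individuals, censored at 1095 days.
The follow-up set is all 48 strong-risk KSFs plus a seeded random
subset of 302 others (emulating complete-follow-up selection).
Individuals with more than one recurrence are planted deterministically
among those with an event (5 strong-risk, 7 others by default).

What the generator does *not* emulate: real within-gene allelic
heterogeneity, linkage between variants, covariate-dependent biochem
(age, sex, diet), informative censoring, medication effects, and
measured stone composition. Passing tests therefore demonstrate the
correctness of the pipeline's logic and the statistical machinery under
the planted structure — not the clinical effect sizes themselves.

## Numerical and testing choices

Problem sizes in the test suite are chosen to give stable Monte-Carlo
verdicts on one CPU: 200 replicates for Cox parameter recovery
(n = 2000 per replicate; mean log-HR within ±10% of the generating
value) and CI coverage at the study's 48 vs 302 group sizes; 2000
replicates per null-calibration check (type-I error in [0.035, 0.065]
at α = 0.05) for chi-square, Mann-Whitney, Kruskal-Wallis and log-rank;
a 1000-composition grid for supersaturation monotonicity and zero-ion
properties; the exhaustive 4096-case classifier oracle. All randomness
flows from explicit integer seeds; the fixture bundle is byte-identical
per (config, seed).

## Known limitations

* Evidence codes are never derived from sequence context; the package
  cannot classify a variant without curated evidence.
* The supersaturation surrogate ignores ion pairs other than the
  optional calcium–citrate correction and uses fixed-temperature
  constants.
* Family segregation, polygenic scores, eGFR trajectories and ancestry
  inference are out of scope.
* The diagnosis engine processes >2 LP/P variants per gene pairwise and
  flags them for manual review rather than attempting full haplotype
  reconstruction.
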