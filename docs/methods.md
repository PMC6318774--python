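# Methods

## Scope and model

`exome-triage` reproduces the computational core of a secondary-findings
workflow for exome cohorts of generally healthy adults: from annotated
per-participant variant calls, a deterministic filter cascade selects the
small set of variants worth expert curation; a rule-table engine combines
curator-assigned ACMG/AMP evidence codes into classifications; classified
variants are categorized (actionable, recessive-disease carrier,
nonactionable risk, APOE status, pharmacogenetic) and gated by each
participant's consent; and cohort-level yields are summarized with binomial
confidence intervals.

Two human activities are deliberately modeled as *inputs*, not computations:

* **Annotation.** Gene, consequence class, HGVS, population frequencies,
  ClinVar status and the HGMD disease-mutation match arrive inside the VCF
  through a documented INFO dialect (see `core_io`). The pipeline never
  recomputes a consequence against a transcript model and never queries a
  live database.
* **Curation.** Evidence codes, strength overrides (e.g. `PS4:moderate`),
  the risk-allele flag, and the read-artifact blacklist are curator-supplied
  tables. The engine combines evidence; it does not generate it (no
  automated PM2 frequency calls, no in-silico PP3 scores, no literature
  mining).

## Filter cascade

Stages run in a fixed order; each stage conserves counts (input = kept +
removed) and is logged in a stage-by-stage audit:

1. **Call quality** — keep Phred quality ≥ 20 and read depth ≥ 10 (both
   inclusive).
2. **Consequence** — keep coding or canonical-splice classes: missense,
   nonsense, frameshift insertion/deletion, in-frame indel, canonical
   splice. Synonymous changes are excluded by default because every curated
   category targets protein-altering or splice-disrupting variation; the
   inclusion set is configurable.
3. **Global MAF** — exclude when *either* the 1000 Genomes or the ExAC
   global MAF is strictly above 0.5% (a value exactly at 0.5% is kept).
   Absence from a database is treated as frequency 0 (unobserved = rare).
4. **ClinVar rescue** — common founder alleles are recovered from the MAF
   exclusions when ClinVar calls them pathogenic or likely pathogenic with
   ≥ 2 review stars. Rescued variants re-enter downstream of the MAF filter
   and are exempt from the subpopulation re-check (their global frequency
   already failed it by construction).
5. **Gene list** — keep variants in the Mendelian search space: OMIM
   Mendelian genes or the ACMG-59 secondary-findings genes. Genes whose
   only OMIM annotations are exception categories (bracketed non-disease,
   braced multifactorial, question-marked provisional) are outside the
   search space unless they sit on the ACMG-59 list.
6. **Subpopulation MAF re-check** — a globally rare variant is removed when
   a well-supported subpopulation frequency exceeds 0.5%. Subpopulations
   are walked in descending frequency; entries with an allele number below
   2 000 or an implied alternate-allele count below 5 are not trusted and
   the next-highest entry decides. The floors are configurable; they encode
   the principle that a frequency based on one allele out of a few hundred
   should not veto a variant.
7. **Phenotype consistency** — variants in serious, highly penetrant,
   young-onset disease genes are removed when the participant's genotype
   would be expected to cause disease (homozygous for a recessive gene,
   heterozygous for a dominant one) and none of the gene's phenotype terms
   appear in the participant's record. Genes with variable onset, or
   participants younger than the gene's recorded full-penetrance age, are
   exempt. Carrier genotypes are never removed here.
8. **Gene-level evidence** — variants in genes whose disease association is
   provisional (question-marked in OMIM: GWAS-only or single-report) are
   removed unless the gene is on the ACMG-59 list.
9. **Artifact blacklist** — an optional curator-supplied list of site keys
   flagged as alignment artifacts after read review; the pipeline consumes
   the list rather than re-inspecting reads.
10. **Curation queue** — a surviving variant is queued when any trigger
    fires: likely loss-of-function type (indels, nonsense, splice), exact
    HGMD disease-mutation match, ACMG-59 gene, ClinVar rescue, or an exact
    term match between the gene's phenotype terms and the participant's
    personal/family history. Term matching is exact by design; ontology
    expansion is out of scope.

Survivors that are never queued are reported as "reviewed and not
classified", as are queued variants without an evidence assignment.

## Evidence combination

The engine counts codes at their *effective* strengths (curator overrides
included) and applies the published combining rules: pathogenic requires a
very-strong code plus corroboration, two strong codes, or one strong code
with sufficient moderate/supporting weight; likely pathogenic covers the
intermediate combinations; BA1 or two strong-benign codes give benign; one
strong-benign plus one supporting, or two supporting-benign codes, give
likely benign. When a pathogenic-side and a benign-side rule both fire the
evidence is contradictory and the call is VUS, as is an empty or
insufficient code set. A curator risk-allele flag (used for
moderate-penetrance founder alleles with published management guidelines,
such as APC p.I1307K) overrides the rule-based output.

Numerical edge: the published table assumes at most one very-strong
criterion (PVS1 is the only code with that default weight). Code sets with
two very-strong criteria — reachable only through overrides — match no
clause and fall back to VUS; the pathogenic-side monotonicity property is
therefore stated over the natural domain of at most one very-strong code,
and the exhaustive oracle-equivalence test pins the behavior outside it.

## Findings and consent

A classified variant is **actionable** when the classification is
pathogenic, likely pathogenic or risk-allele; the gene has an actionable
disease association of at least moderate penetrance; and the genotype
supports risk — heterozygous for a dominant gene, homozygous or presumed
compound heterozygous (two heterozygous P/LP variants in one recessive
gene, unphased exomes cannot distinguish cis from trans) for a recessive
gene, or heterozygous in a gene whose heterozygotes carry guideline-managed
risk (the MUTYH pattern). A heterozygous P/LP variant in a recessive gene
that is not actionable makes the participant a **carrier**. Genes
conferring risk without an effective intervention (GBA heterozygotes and
Parkinson disease) additionally flag **nonactionable risk**; a variant may
be both carrier and nonactionable risk, while actionable and carrier are
mutually exclusive.

**APOE** diplotypes are called from rs429358/rs7412 (C/C → e4, T/C → e3,
T/T → e2). The unphased double-heterozygote is ambiguous between e2/e4 and
e1/e3 and is reported as e2/e4, the standard convention given the rarity of
e1; allele combinations that force an e1 haplotype raise rather than guess.
**Pharmacogenetic** findings are non-reference genotypes at panel rsIDs;
diplotype-to-phenotype translation (star-allele metabolizer calling) is out
of scope.

Return gating: opt-outs receive nothing; actionable-only consent returns
only actionable findings; full consent returns actionable, carrier,
nonactionable-risk and pharmacogenetic findings. APOE status is returned
only on specific request, and VUS are never returned under any consent.

## Cohort statistics

The actionable yield is a binomial proportion with a **Wald** interval,
p ± z·√(p(1−p)/n), z = 1.96, clamped to [0, 1], reported in whole percent
with half-up rounding. The method is configurable (Wilson and
Clopper–Pearson via statsmodels), but Wald is the default because it is the
only standard interval whose whole-percent rounding yields 8%–26% at 12/70
(Wilson gives 10%–28%, Clopper–Pearson 9%–28%); its simulated coverage at
p = 0.17, n = 70 sits near 94%, inside the 90–97% sanity band the tests
enforce. Per-participant classification means are count/n rounded half-up
to one decimal. The nonactionable union is counted directly and
cross-checked against inclusion–exclusion
(|carriers| + |APOE e4| − |both|); a mismatch is an error, not a warning.

## Synthetic cohort

The generator emulates the study conditions rather than real sequence data.
Defaults: 70 participants; 12 planted with the curated actionable set (11
distinct variants — one founder allele shared by two participants — with
their evidence codes, strength overrides and risk-allele flag); 150
heterozygous P/LP carrier variants in 60 participants drawn from a 30-gene
recessive pool, genes distinct within a participant so no spurious compound
heterozygote arises; 21 participants with one or two APOE e4 alleles, 18 of
them also carriers; one to six non-reference panel genotypes per
participant across a 28-rsID pharmacogenetic panel; and a Poisson(30)
benign background per participant, 80% common (MAF > 0.5%) and 20% rare,
with small planted fractions of low-quality calls, synonymous/non-coding
classes, high-subpopulation-MAF variants and provisional-gene variants so
every cascade stage removes something. Consent defaults: 5% opt-out, 25%
actionable-only, 70% all medically relevant, with exactly two participants
requesting APOE status. All draws flow from a single integer seed and a
fixed seed regenerates byte-identical files.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: linkage disequilibrium, relatedness and
population structure; realistic per-gene mutation spectra; annotation
errors and caller artifacts; the composition of real curation workloads
(the background's "reviewed and not classified" counts are a consequence of
the planted mixture, not a reproduction of any observed tally). Planted
coordinates are synthetic but stable, since the pipeline never derives
anything from position.

The bundled gene catalog and the 28-rsID panel are constructed stand-ins
(the panel file is named `pgx_panel_synthetic.tsv` accordingly): the
catalog carries the curated actionable genes with their inheritance,
penetrance and actionability metadata, the full ACMG-59 list, the carrier
pool, OMIM-exception examples and background genes; it is not a dump of any
proprietary resource (OMIM and HGMD content is not redistributable, which
is also why HGMD matching is consumed as a precomputed boolean flag).

## Design choices on open points

* The subpopulation re-check runs as a filter stage before queue
  construction, alongside the other frequency filters.
* "Coding" excludes synonymous variants (configurable).
* MAF exclusion uses either-database-exceeds with a strict boundary.
* Evidence is keyed by site (`chrom:pos:ref:alt`), so a variant shared by
  several participants is curated once.
* The reporter counts pharmacogenetic findings as panel sites with a
  non-reference genotype.
* Problem sizes in tests and the acceptance script (70 participants,
  ~2 000–4 000 variant records per cohort, five regeneration seeds) match
  the emulated study conditions; they are the package's chosen desk-scale
  defaults.

## Known limitations

* The Wald interval is used for fidelity of the reported bounds, not
  because it is the best interval at small n; Wilson or Clopper–Pearson can
  be selected where calibration matters more than reproduction.
* Phenotype/history matching is exact string equality on curated terms.
* X-linked inheritance is carried in the metadata but no sex-aware genotype
  logic is applied beyond the dominant/recessive rules.
* Compound heterozygosity is presumed from two heterozygous P/LP variants
  in one gene; phase is never inferred.
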