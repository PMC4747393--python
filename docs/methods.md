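# Methods

## Phenotype model

Each subject carries one familial MMR mutation (*MLH1*→chr3, *MSH2*/*MSH6*→chr2,
*PMS2*→chr7) and exactly one endometrial-cancer (EC) diagnosis. The phenotype
is **poor** if EC was diagnosed before the age cutoff (default 50, i.e. ≤49)
or the subject has at least one non-EC tumor; otherwise **neutral**. A
subject with unknown EC age and no other tumor cannot be classified and
raises `IndeterminatePhenotypeError` rather than defaulting. The label keeps
its reasons (`young_onset`, `multiple_cancers`) for auditing. Cohort moments
use the n−1 (sample) standard deviation.

## Variant ingestion and consequence calling

VCF positions are 1-based, panel BED intervals half-open 0-based; conversion
happens exactly once, at the ingestion boundary. Multi-allelic sites are
split into one record per alternate allele; sites with no carrier are
dropped; off-panel calls are retained but flagged `off_target`. A variant's
consequence on a (toy) transcript is determined mechanically:

- **SNV in the CDS** — rebuild the affected codon (strand-aware, using
  Biopython for translation/reverse complement) and compare residues:
  silent / missense / nonsense.
- **Indel** — anchor-base convention (change begins after the first REF
  base); frameshift when the length difference is not a multiple of 3,
  otherwise in-frame insertion/deletion.
- **Near-exon positions** — within 2 nt of an exon boundary:
  `splice_region`; 3–10 nt: `intronic_flank`. Beyond the 10 nt captured
  flank the caller refuses to annotate (`AnnotationError`) rather than
  guessing.

The caller is tested against an independent oracle: mutate the whole
chromosome sequence, re-splice, re-translate and diff the full proteins.

## Rare filter

Retain variants with MAF strictly below the threshold (default **0.001**,
matching the study's rare-variant definition) or with unknown MAF
(non-dbSNP variants are treated as rare). Frequent variants previously
reported pathogenic or disease-associated are *rescued* into the retained
set and flagged. The filter is monotone in the threshold by construction.

## Five-tier classification

Clinical-genetics tiers: 1/2 no effect, 3 unknown significance, 4 likely
pathogenic, 5 pathogenic. Rules (all that fire are recorded in an
audit trace; the highest tier wins):

| rule | condition | tier |
| --- | --- | --- |
| R1 | silent, splice-region or intronic-flank | 1 |
| R2 | conservative missense | 2 |
| R3 | conservative missense + disease-associated/predicted-damaging prior | 3 |
| R4 | non-conservative missense, nonsense, frameshift, in-frame indel | 3 |
| R5 | prior "likely pathogenic" report | 4 |
| R6 | prior pathogenic report for another disorder | 4 |
| R7 | prior pathogenic report for the study disease | 5 |

`replay_trace` re-derives the tier from the stored trace, so every call is
auditable. Conservativeness uses fixed physicochemical groups
({AVLIMFW}, {GPC}, {STNQY}, {DE}, {KRH}) by default — chosen because they
reproduce the curated calls behind the published risk-variant set
(Asp→Gly, Asp→Ser, Ala→Ser all non-conservative) — or
`grantham:<threshold>`, with the Grantham distance computed from the
composition/polarity/volume formula (α = 1.833, β = 0.1018, γ = 0.000399,
normalizer ρ = 50.723); the computed matrix matches the published integer
matrix on spot-checked entries. Stop-loss substitutions are treated as
non-conservative.

A **risk-variant** is class ≥ 4, or class 3 with a non-conservative
protein-altering change. Class-5 annotations on non-protein-altering
variants never qualify (selection requires a protein-level mechanism).

## Linkage and burden

Within a subject, an MMR-gene risk-variant on the familial mutation's
chromosome cannot be shown independent of it and is excluded from counts;
non-MMR risk-variant pairs sharing a chromosome are flagged and, under the
`collapse_same_chromosome` sensitivity mode, count once per chromosome
(putative haplotype). The headline burden is the number of independent
non-MMR risk-variants; MMR-gene extras are reported separately. The
dichotomy cut is **k = 2** (burden 0–1 vs ≥2), the cut used in the printed
distribution.

## Statistics

All statistics are assembled from first principles; scipy supplies only
distribution tails.

- **Fisher exact (two-sided)** — probability-mass ordering: sum
  hypergeometric probabilities of all tables with the observed margins
  whose probability does not exceed the observed one. Probabilities are
  computed in log space via `lgamma` (no overflow for any table size); the
  tie cutoff is `log(p_obs) + log1p(1e-7)` to absorb floating-point ties,
  matching exact rational enumeration to ≥10 significant digits on random
  tables.
- **Pearson chi-square** — no continuity correction; upper tail from the
  regularized incomplete gamma function; warns when any expected count is
  below 5 (the published 6×2 table is sparse, so its p = 0.0471 is
  asymptotic and flagged as such).
- **Two-sample t** — pooled variance by default, Welch optional.
- **Kaplan–Meier** — product-limit estimator on the age scale; at tied
  times events are processed before censorings (a subject censored at *t*
  remains in the risk set for events at *t*).
- **Log-rank (Mantel–Cox)** — statistic `(Σ(O₁ⱼ−E₁ⱼ))² / ΣVⱼ` over distinct
  event times with the hypergeometric variance; p from chi-square with
  1 df. Verified within 1e-8 of lifelines on random censored datasets.

Survival endpoints: `any_poor` (first poor-phenotype feature), `young_ec`,
`second_tumor`; censoring at last follow-up, falling back to the latest
known diagnosis age.

## Synthetic generator

`simulate_cohort(SimulationConfig(seed=...))` draws, with four independent
seeded RNG streams (panel / clinical / variants / frequencies):

- **Panel** — two-exon toy genes laid along chr1–22 (47 estrogen-pathway,
  35 oncogene, 63 tumor-suppressor, 9 other, matching the study panel's
  group sizes) plus the four MMR genes on their real chromosomes; captured
  intervals are the exons ±10 nt.
- **Cohort** — default 35 subjects in 29 families (6 two-member families);
  EC ages from N(53.1, 10.7²) truncated to [31, 81].
- **Burden and phenotype** — per-subject risk-variant count ~
  Poisson(1.5); `P(poor) = expit(β₀ + ln(OR)·1[burden ≥ 2])` with
  β₀ = logit(6/17) (the observed low-burden poor rate) and OR defaulting to
  14.7, the odds ratio the dichotomized published table implies. Poor
  subjects are realized as young EC and/or extra tumors; ages are sampled
  *stratified by phenotype* with the young-age mass chosen in closed form so
  the marginal EC-age distribution stays the truncated normal above.
- **Variants** — every planted variant is probed onto a transcript by
  running the real `annotate_consequence` and `conservativeness`, so the
  curation stage inverts the generator exactly: recovered burdens equal the
  planted truth with zero mismatches (tested on multiple seeds). Background
  class-1/2 variants, common variants (MAF ≥ 0.001, excluded by the
  filter), occasional rescued variants, family-shared variants, and extra
  MMR-gene variants (some on the familial chromosome, exercising the
  linkage exclusion) are layered on top. The MAF spectrum mixes dbSNP
  (log-uniform below 0.001) and never-deposited variants (47%).

**Fidelity and limits.** The generator reproduces the study's marginal
structure (cohort size, family structure, age distribution, panel
composition, rare-variant spectrum, burden–phenotype coupling) but not
linkage disequilibrium, sequencing error, variable capture depth, or
realistic gene lengths; transcripts are two-exon miniatures. Truth burdens
are capacity-corrected: if a subject's drawn burden cannot be planted
(gene pool exhausted), the truth records the planted count.

**Null calibration and power** use replicate studies of the
burden→phenotype layer only (`fisher_rejection_rate`), justified because
the variant layer is shown elsewhere to recover burdens exactly; degenerate
tables (empty margin) count as non-rejections. Measured: null (OR = 1,
n = 35, 2,000 replicates) rejection rate ≈ 0.03 at α = 0.05 — conservative,
as expected for an exact test on small discrete tables; power at OR = 8,
n = 200 over 500 replicates = 1.0.

## Numerical and I/O choices

- Seeds are mandatory (`SimulationConfig(seed=...)`); streams are
  `numpy.random.default_rng([seed, k])`. Fixture writing is byte-stable for
  a fixed seed.
- MAF values are serialized with `repr` (round-trip exact); unknown values
  are empty fields, never 0.
- The GFF3/FASTA transcript fixtures are read back with Biopython SeqIO
  plus a constrained GFF3 line parser (only `gene`/`CDS` rows with
  `ID=`/`Parent=` attributes, as written by the serializer).
- The pipeline writes a `manifest.json` with the package version, full
  configuration and SHA-256 hashes of every input.
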