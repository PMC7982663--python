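# Methods

This note documents the models and procedures `famgen` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Variant QC and clinical-grade gating

Per-sample metrics are computed in one pass over the parsed VCF: mean DP and
mean GQ over called sites, homozygous-alt / heterozygous call ratio, and
Ts/Tv over biallelic-SNV alt assessments (transitions A↔G and C↔T; a
multi-allelic site is split into per-alt assessments and counts once per alt
the sample carries). Zero-denominator ratios return an explicit NaN marker
that downstream grading treats as a failure with reason "undefined", never
an exception.

"Coverage" is approximated by mean per-site DP from the VCF because
alignment files are out of scope; the field is named `mean_depth` to say
what it actually is. Site filtering removes records with QUAL strictly
below the threshold (default 20; a record at exactly 20 is kept); records
with missing QUAL are removed by default (conservative) and retainable by
flag.

Clinical-grade thresholds are configuration, not claims: defaults are
depth ≥ 15, GQ ≥ 40, hom/het ∈ [0.3, 2.5], Ts/Tv ∈ [1.5, 3.5], all bounds
inclusive. The hom/het band is written for whole-genome callsets; on a
common-variant marker panel (the simulator's output) the expected ratio is
E[f²]/E[2f(1−f)] ≈ 0.25 for f ~ U(0.05, 0.5), so panel-level analyses
configure a wider band (0.1–2.5) rather than misread panel composition as
sample failure. A sample that fails the gate remains eligible for
pathogenicity screening only; the pipeline enforces the exclusion from risk
scoring, pharmacogenomics and traits and records it in the report.

## Pathogenicity screening

Three gates make a variant a candidate for an individual: the gene is on at
least one configured panel; the ClinVar consensus class is pathogenic or
likely pathogenic with a matching allele; and the maximum population AF does
not exceed the hard cutoff. The common-site threshold (AF > 0.01, the
gnomAD "common" convention) deprioritises rather than excludes, because
borderline-common variants can still deserve an explicit written assessment;
hard exclusion applies only above a configurable 0.05. When a per-population
AF table is supplied the maximum across populations is used (worst case).
Unannotated variants are skipped and counted, never raised.

Prioritisation is lexicographic: ClinVar strength, then effect severity
(LoF > missense > other), then ascending AF, then position; frequency-
flagged candidates sort after unflagged ones.

The frequency-vs-prevalence bound uses the simplest Hardy–Weinberg
arguments: for a fully penetrant dominant disorder of prevalence P the
pathogenic AF cannot exceed P/2; for a recessive one, √P; penetrance f
relaxes either bound by 1/f (default f = 1). An observed AF above the bound
is benign support. Unknown inheritance yields no flag with an explicit
reason. The bound is monotone increasing in prevalence and decreasing in
penetrance (property-tested).

The ACMG/AMP combiner implements the published rule algebra over evidence
categories (PVS/PS/PM/PP vs BA/BS/BP): the pathogenic combinations
(PVS1 with strong/moderate/supporting backup; ≥2 strong; strong with
moderate/supporting combinations), likely-pathogenic combinations, benign
(BA1 alone or ≥2 BS) and likely-benign (BS+BP or ≥2 BP). Any simultaneous
pathogenic-side and benign-side hit resolves to uncertain significance, as
does an empty set. Strict algebra is kept even where a looser reading is
common in practice: 1 BS + 1 BP is *likely* benign, not benign. The
implementation is verified by exhaustive comparison (all code sets of size
≤ 4, >20,000 sets) against an independently written rule-table oracle.

Computational evidence (PP3/BP4-style) is taken as an input flag, not
recomputed — no in-scope predictor.

## Genetic risk scores

For one phenotype, `GRS = Σᵢ wᵢ·dᵢ / N` where `wᵢ` is the reported effect
size (odds ratio or beta, summed as given; a `log_or` option converts ORs
to ln(OR) first and defaults off), `dᵢ ∈ {0,1,2}` is the risk-allele dosage
and `N` the harmonized panel size. The denominator interprets "alleles
reported for the phenotype" as one per marker; the alternative 2N rescales
every score by the same constant and cannot change SD-based flags — the
affine-invariance property test covers exactly this. Dosage weighting
(0/1/2) is used for homozygotes for the same reason: flags are invariant to
any common positive affine transform of all scores of a phenotype.

Markers enter a panel only with a risk allele, an effect size, and
association p < 1e-5; harmonization against the background callset drops
markers absent from the background, resolves strand flips by
complementation, and excludes strand-ambiguous A/T and C/G markers by
default. Missing genotypes contribute dosage 0 and are counted (HWE mean
imputation, 2f, is available behind a flag).

The background distribution uses the sample SD (n−1); flags are upper-tail
only: `over_2sd` iff score > mean + 2·SD (strict), `over_1sd` between
mean + 1·SD (exclusive) and mean + 2·SD (inclusive). One-sided mean + 2SD
is the ~97.7th percentile — slightly stricter than a literal "top 5%"
reading; the stricter literal threshold is implemented. A phenotype is
retained for reporting iff some member is over 2SD or ≥ 2 members are
flagged at all; no multiple-testing correction is applied because the
object is identifying members in the extreme tail, not hypothesis testing.
A zero-SD background yields no flags plus a warning.

Calibration: with members drawn from the same generator as the background
(100 markers, background n = 5,000, 400 replicate members), the measured
over-2SD rate must sit within 3 binomial SEs of the Gaussian upper-tail
mass 0.0228 — with 100 independent marker contributions the score is close
enough to Gaussian for this to hold. Recovery: a founder spiked to carry
each risk allele with probability 0.9 over a 100-marker phenotype lands
~16 background SDs above the mean and must be flagged in ≥ 95 of 100
seeded replicates (background n = 2,000 per replicate).

## Pharmacogenomics

Star-allele definitions are configuration TSVs (gene, allele, activity
value, function class, defining variants); *1 is the reference haplotype
with an empty defining set. The packaged CYP2C9/CYP2C19/CYP2D6 tables use
the well-known defining SNPs (e.g. the CYP2D6 1846G>A splice defect for
*4) with overlapping definitions where the real haplotypes overlap — this
is what makes ambiguity representable. Activity values (*1 = 1, CYP2D6
*2 = 1, *41 = 0.5, *10 = 0.25, *4 = 0, *20 = 0; CYP2C9 *2 = 0.5, *3 = 0;
CYP2C19 *2/*4/*4A = 0, *17 = 1) are data, not code.

Calling takes genotype copy counts at the defining positions, extracting
non-variant (homozygous-reference) positions when present in the input; a
defining position absent from the input is assumed homozygous reference and
marks the call low-confidence unless the input is declared all-sites. A ref
allele conflicting between input and definitions is a data-consistency
error.

Resolution enumerates all unordered allele pairs whose combined
defining-variant multiset reproduces the observed copy counts *exactly*
(unphased). Hence: no hits → *1/*1; a single het defining allele → paired
with *1 (wild-type presumption); an observation explained by several pairs
→ an unresolved candidate set (e.g. CYP2C19 with −806C>T and 1A>G each het
is *17/*4 or *4A/*1 — indistinguishable without phase). No
maximum-parsimony shortcut is taken; forcing one call would discard real
ambiguity. Exact-multiset semantics also imply that two candidate pairs
sharing one allele must have identical partner definitions, so some
multi-allele candidate lists quoted in clinical reports (which draw on
phase or copy-number knowledge) are not reproducible from unphased
genotypes alone; the activity interval machinery accepts such externally
supplied candidate sets regardless. Round-trip completeness — every pair in
every packaged table is recovered from its own fixture — is tested
exhaustively.

Activity of a diplotype is the sum of its allele values; an unresolved set
yields the [min, max] interval over candidate sums, which always contains
the true pair's point score. Status bins are per-gene configuration; the
CYP2D6 defaults are 0 → poor, (0,1] → intermediate, (1,2.25) → normal,
≥ 2.25 → ultrarapid. CYP2C9 bins place a summed activity ≤ 1 in poor and
(1, 1.75] in intermediate so that *2/*2 (1.0) is poor and *1/*2 (1.5)
intermediate, matching how those diplotypes are reported clinically.

Warfarin dosing is a pure lookup keyed on (CYP2C9 diplotype, VKORC1
rs9923231 genotype). Only the *2/*2+TT → 20% and *1/*2+TT/CT → 60% cells
are guidance-anchored; the rest of the packaged grid is filled with
monotone interpolations and labelled as such in the table's `source`
column. An uncovered key raises "no guidance" — never a silent default.
Copy-number variation is not detected; an optional per-gene CNV flag can be
ingested, and no packaged analysis asserts one.

## Trait evidence grading and interpretation

Each marker's evidence profile carries study quality (A–D), interaction
type, variant nature, plausibility, number of independent studies (a
"many" entry is encoded as the sentinel 20), a lower bound on total
subjects, and mechanistic-knowledge level. A curator label, when present,
is authoritative; the heuristic serves de-novo markers:

- convincing: ≥ 3 studies, ≥ 1,000 subjects, mechanism not low, quality
  better than D, and either ≥ 3,500 subjects or ≥ 20 studies;
- probable: ≥ 3 studies, ≥ 250 subjects, mechanism high or medium;
- possible: ≥ 2 studies with non-low mechanism;
- otherwise not demonstrated.

The convincing tier deliberately demands either a large aggregate cohort or
broad replication on top of the base requirements: a handful of
1–3k-subject studies reads as "probable" in curated practice even at
quality B. The 250-subject floor for probable is anchored by the
caffeine-response marker (7 studies totalling 250 subjects, graded
probable). On the 42 packaged curated rows the heuristic reproduces 34
labels (81%); the mismatches are rows where the printed label is not
derivable from the table columns at all (e.g. one C-quality marker with
huge cohorts graded only "possible" while a weaker-columned marker is
"convincing") — which is precisely why curator labels override. The
carry-forward filter keeps convincing + probable markers and reports
per-category grade counts.

Genotype interpretation is a deterministic per-marker lookup keyed by
effect-allele count, with the model (dominant / recessive / additive /
genotype-table) recorded and every packaged marker covering all three
genotype classes (schema-checked). Each marker declares its reporting
strand; incoming genotypes are complemented when they match the declared
alleles only on the opposite strand (the lactase-persistence marker is the
canonical case: G/A on one strand, C/T on the other), and a genotype
matching neither orientation is a strand-mismatch error.

The VO₂max trainability score counts panel SNPs at which the individual
carries ≥ 1 favorable allele, giving 0–21 on the canonical 21-SNP panel;
printed scores of the form "x/21" imply presence counting rather than 0–42
dosage counting, which remains available behind a flag. The packaged panel
is a synthetic stand-in (21 invented SNPs with one favorable allele each)
because the published panel membership is not reproduced here; the file and
loader say so.

## Synthetic data

The simulator emulates the study's input shapes: a marker database (default
AF law U(0.05, 0.5), weights |N(0, 0.2)| tagged beta, association p-values
well below 1e-5), an HWE background cohort standing in for a reference
panel, and a five-member pedigree in which the aunt is the mother's full
sibling via two hidden simulated grandparents. Children draw each allele
uniformly from the corresponding parent's pair, so Mendelian consistency
holds at 100% of markers (de-novo rate 0). Ref/alt pairs are sampled
transition-heavy (2:1) so simulated Ts/Tv lands near genome-like values,
and A/T–C/G pairs are never generated so harmonization keeps every marker.

Spiking replaces one founder's draw: each allele at the spiked phenotype's
markers is the risk allele with the spike probability. Spiking a child is a
configuration error — children inherit. The degradation transform drops a
fraction of one member's calls (default 70%) and deflates GQ/DP (and QUAL
where the member is the sole carrier), reproducing the failure mode of a
low-quality sample so the screen-only gating path is exercisable.

All randomness flows from one master seed through fixed named substreams
(markers / background / family / metadata), so modules re-run independently
and byte-identically. What the generator does *not* emulate: linkage
disequilibrium (the risk score is LD-blind, so independence changes
nothing the pipeline can measure), population structure beyond optional
per-population AF shifts, sequencing error, and genotype-calling artefacts
— passing tests therefore demonstrate the pipeline's arithmetic and
gating, not robustness to real-data noise.

Problem sizes in the test and acceptance suites (background 2,000–5,000,
100-marker panels, 400 null members, 100 spike replicates) were chosen so
every stochastic band is a 3·SE interval with meaningful width while the
whole suite stays desk-scale.

## Reporting

The report is assembled deterministically (member role order, then genomic
position / phenotype label): per-member QC verdicts, screening candidates
with classification and carrier/at-risk context, retained risk phenotypes,
pharmacogenomic calls, trait calls and VO₂max; family-level shared variants
(exact key match, ≥ 2 carriers), phenotypes flagged in ≥ 2 members, and
negative findings. The negative-finding watchlist defaults to the APOE ε4
haplotype and pathogenic hits in the secondary-findings panel: entries with
no positive hit are reported explicitly, because "looked and found nothing"
is informative when family history exists. APOE ε resolution from rs429358
and rs7412 is a two-SNP haplotype table with unphased semantics; the
double-heterozygote is genuinely ambiguous (ε2/ε4 vs the rare ε1/ε3) and is
reported as such. Reports validate against a structural schema, and reruns
on identical inputs are byte-identical (no timestamps in the payload).

## Known limitations

- Screening classifies with externally supplied evidence codes; it does not
  derive PVS/PS/PM/PP codes from annotations itself.
- Diplotype resolution is unphased and CNV-blind; gene deletions or
  duplications change metaboliser status in ways the caller cannot see.
- The GRS makes no attempt at LD pruning, ancestry correction beyond
  sub-population restriction, or imputation.
- The evidence-grading heuristic is a calibration to one curated corpus;
  curator labels remain authoritative where they exist.
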