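# famgen

Family-scale whole-genome interpretation as a tested, reusable pipeline.
`famgen` covers the analysis layers a preventative-genomics workup runs on a
small pedigree — here a family of five (father, mother, aunt, daughter, son):

- **Variant-file QC and clinical-grade gating** — site-quality filtering
  (QUAL < 20 removed), per-sample mean depth, mean genotype quality,
  homozygous/heterozygous ratio and Ts/Tv ratio, gated against configurable
  clinical-grade thresholds. A failing sample (e.g. degraded DNA) stays in
  pathogenicity screening but is excluded from all quantitative stages.
- **Panel-based pathogenicity screening** — gene panels (OMIM-morbid-style,
  ACMG secondary findings, hereditary cancer), ClinVar-consensus P/LP gating
  with allele match, a common-variant frequency rule (AF > 0.01
  deprioritised, AF > 0.05 excluded), frequency-vs-prevalence benign
  reasoning, the full ACMG/AMP five-tier evidence-combining algebra, and
  carrier/at-risk inheritance context.
- **Genetic risk scores** — per phenotype,
  `GRS = Σᵢ wᵢ·dᵢ / N` over GWAS markers (weight `wᵢ`, risk-allele dosage
  `dᵢ ∈ {0,1,2}`, panel size `N`), referenced to the score distribution of a
  background cohort; upper-tail flags at mean + 1·SD and mean + 2·SD with a
  family-sharing retention rule (an isolated 1SD signal is dropped).
- **Star-allele pharmacogenomics** — CYP2C9 / CYP2C19 / CYP2D6 diplotype
  calling by exact multiset explanation of the observed defining variants
  (wild-type *1 presumed for a lone heterozygous hit; ambiguous observations
  stay unresolved candidate sets), Gaedigk-style activity scores and
  metaboliser-status bins, genotype-keyed warfarin dosing
  (CYP2C9 × VKORC1 rs9923231) and single-SNP response lookups (IL28B).
- **Evidence-graded fitness/nutrition traits** — scientific-validity grading
  (convincing / probable / possible / not demonstrated) of gene×lifestyle
  markers from study counts, cohort sizes, quality ratings and mechanistic
  knowledge; only convincing/probable markers are carried forward to
  genotype interpretation; 21-SNP VO₂max-trainability favorable-allele score.
- **Synthetic data** — a Mendelian pedigree simulator (HWE founders, child
  alleles drawn uniformly from parental pairs, risk-allele spiking, a
  degradation transform for the failed-QC path) that generates every input
  the pipeline needs, since real family genomes of this kind are not
  publicly shareable.

## Worked example

Simulate a cohort and run the stages from the `famgen` CLI:

```bash
famgen simulate --seed 3 --n-background 200 --out demo
famgen qc --vcf demo/family.vcf --sample son
```

```json
{
  "sample_id": "son",
  "mean_depth": 29.845637583892618,
  "mean_gq": 89.91275167785236,
  "hom_het_ratio": 0.25806451612903225,
  "tstv_ratio": 2.7142857142857144,
  "n_variants": 149,
  "removed_low_qual": 1
}
```

One simulated site fell below QUAL 20 and was removed; the son's 149
remaining calls average ~30× depth and GQ ~90, with a Ts/Tv of 2.71
(the simulator draws transition-biased variants) and a hom/het ratio of
0.26 — the value expected for a common-variant marker panel, lower than the
~0.5 typical of whole-genome callsets.

Risk scoring against the simulated background:

```bash
famgen grs --vcf demo/family.vcf --background demo/background.vcf --markers demo/markers.tsv
```

```text
            father  mother  aunt  daughter  son
phenotype_00  none    none  none  over_1sd  none
phenotype_01  none    none  none  none      none
phenotype_02  none    none  none  none      none
retained: []
```

The daughter exceeds mean + 1·SD for one phenotype, but no other member
shares it and nobody crosses 2·SD, so nothing is retained for reporting —
exactly the family-sharing rule.

In the library, the pharmacogenomics path for a warfarin-relevant genotype:

```python
from famgen import pgx
from famgen.simulate import make_pgx_fixture

defs = pgx.default_definitions()
fx = make_pgx_fixture(defs["CYP2C9"], ("*2", "*2"))          # hom for the *2 SNP
hits = pgx.call_star_alleles(fx, defs["CYP2C9"], all_sites=True)
dip = pgx.resolve_diplotypes(hits, defs["CYP2C9"])           # -> *2/*2
dose = pgx.warfarin_dose("*2/*2", "TT")
print(dip, dose.fraction_of_standard)                        # *2/*2 0.2
```

A CYP2C9 \*2/\*2 poor metaboliser with VKORC1 rs9923231 TT is recommended
20% of the standard initial warfarin dose; \*1/\*2 with TT gets 60%.

## Layout

```
src/famgen/
  vcfio.py      VCF read/write (pysam-backed) and genotype containers
  qc.py         QC metrics, QUAL filter, clinical-grade gating
  acmg.py       ACMG/AMP evidence-combining algebra
  screen.py     gene panels, screening gates, frequency-vs-prevalence
  risk.py       GWAS marker DB, harmonization, GRS, background flags
  pgx.py        star alleles, diplotypes, activity/status, dosing
  traits.py     evidence grading, trait interpretation, VO2max score
  simulate.py   marker/background/pedigree simulators, fixtures
  report.py     report assembly, APOE epsilon haplotyping, orchestration
  cli.py        `famgen` command group
  data/         packaged evidence tables, star-allele definitions,
                dosing/response tables, trait markers, synthetic VO2max panel
```

See `docs/methods.md` for the models, parameter choices and limitations.
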