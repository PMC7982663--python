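"""Variant I/O, site-quality filtering, per-sample QC and clinical grading."""

import math
import random

import pytest

from famgen.qc import (
    ClinicalGradeThresholds,
    QCReport,
    apply_qual_filter,
    compute_sample_qc,
    grade_clinical,
    is_undefined,
)
from famgen.simulate import SimulationConfig, cohort_records, simulate_family, simulate_marker_db, write_cohort
from famgen.vcfio import RosterError, SampleGenotype, VariantRecord, read_vcf, write_vcf


def _record(chrom="1", pos=100, ref="A", alt="G", qual=50.0, **samples):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=(alt,), qual=qual,
        per_sample=dict(samples),
    )


class TestReadVcf:
    def test_reads_rows_and_roster(self, write_text_vcf):
        path = write_text_vcf([
            ("1", 100, "rs1", "A", "G", 50, "PASS", ".", "GT:GQ:DP", "0/1:99:30", "0/0:80:25"),
            ("1", 200, ".", "C", "T", 60, "PASS", ".", "GT:GQ:DP", "1/1:70:20", "0/1:90:31"),
            ("2", 300, ".", "G", "A", 40, "PASS", ".", "GT:GQ:DP", "0/0:88:28", "0/0:85:29"),
        ])
        records, roster = read_vcf(path)
        assert len(records) == 3
        assert roster == ["S1", "S2"]
        assert records[0].rsid == "rs1"
        assert records[0].per_sample["S1"].allele_indices == (0, 1)
        assert records[1].per_sample["S1"].is_hom_alt

    def test_missing_gq_is_absent_not_zero(self, write_text_vcf):
        path = write_text_vcf([
            ("1", 100, ".", "A", "G", 50, "PASS", ".", "GT", "0/1", "0/0"),
        ])
        records, _ = read_vcf(path)
        call = records[0].per_sample["S1"]
        assert call.gq is None
        assert call.dp is None

    def test_unknown_sample_subset_raises(self, write_text_vcf):
        path = write_text_vcf([
            ("1", 100, ".", "A", "G", 50, "PASS", ".", "GT", "0/1", "0/0"),
        ])
        with pytest.raises(RosterError):
            read_vcf(path, sample_subset=["NOPE"])

    def test_write_read_round_trip_preserves_genotypes(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_phenotypes=2, markers_per_phenotype=15)
        cohort = simulate_family(simulate_marker_db(cfg), cfg)
        path = str(tmp_path / "fam.vcf")
        members = write_cohort(cohort, path)
        records, roster = read_vcf(path)
        assert roster == members
        for rec in records:
            for m in members:
                assert rec.per_sample[m].alt_copies(1) == cohort.family[m][rec.rsid]

    def test_double_round_trip_is_idempotent(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_phenotypes=1, markers_per_phenotype=10)
        cohort = simulate_family(simulate_marker_db(cfg), cfg)
        p1, p2 = str(tmp_path / "a.vcf"), str(tmp_path / "b.vcf")
        write_cohort(cohort, p1)
        records, roster = read_vcf(p1)
        write_vcf(records, roster, p2)
        records2, roster2 = read_vcf(p2)
        assert roster2 == roster
        for r1, r2 in zip(records, records2):
            assert (r1.chrom, r1.pos, r1.ref, r1.alts, r1.rsid) == (
                r2.chrom, r2.pos, r2.ref, r2.alts, r2.rsid)
            assert r1.qual == pytest.approx(r2.qual, abs=1e-4)
            assert r1.per_sample == r2.per_sample

    def test_symbolic_alleles_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord(chrom="1", pos=5, ref="A", alts=("<DEL>",))


class TestQualFilter:
    def test_boundary_is_below_threshold(self):
        records = [_record(pos=p, qual=q) for p, q in zip((1, 2, 3, 4), (5, 19.9, 20, 35))]
        kept, removed = apply_qual_filter(records, 20)
        assert [r.qual for r in kept] == [20, 35]
        assert removed == 2

    def test_zero_threshold_keeps_all(self):
        records = [_record(pos=p, qual=q) for p, q in enumerate((0.0, 1.0, 99.0), 1)]
        kept, removed = apply_qual_filter(records, 0)
        assert len(kept) == 3 and removed == 0

    def test_missing_qual_policy(self):
        records = [_record(pos=1, qual=None), _record(pos=2, qual=30.0)]
        kept, removed = apply_qual_filter(records)
        assert len(kept) == 1 and removed == 1
        kept2, removed2 = apply_qual_filter(records, keep_missing=True)
        assert len(kept2) == 2 and removed2 == 0

    def test_matches_brute_force_scan(self):
        rng = random.Random(42)
        records = [_record(pos=i + 1, qual=rng.uniform(0, 40)) for i in range(1000)]
        kept, removed = apply_qual_filter(records, 20)
        brute = sum(1 for r in records if r.qual < 20)
        assert removed == brute
        assert len(kept) + removed == len(records)


class TestSampleQc:
    def test_all_het_gives_zero_hom_het_ratio(self):
        records = [
            _record(pos=p, S=SampleGenotype((0, 1), gq=90, dp=30)) for p in (1, 2, 3)
        ]
        rep = compute_sample_qc(records, "S")
        assert rep.hom_het_ratio == 0.0
        assert rep.n_variants == 3

    def test_tstv_hand_count(self):
        # three transitions (A>G, C>T, G>A) and one transversion (A>C)
        rows = [("A", "G"), ("C", "T"), ("G", "A"), ("A", "C")]
        records = [
            _record(pos=i + 1, ref=r, alt=a, S=SampleGenotype((0, 1)))
            for i, (r, a) in enumerate(rows)
        ]
        assert compute_sample_qc(records, "S").tstv_ratio == 3.0

    def test_zero_transversions_is_undefined_marker(self):
        records = [_record(pos=1, ref="A", alt="G", S=SampleGenotype((0, 1)))]
        rep = compute_sample_qc(records, "S")
        assert is_undefined(rep.tstv_ratio)

    def test_uncarried_alt_not_counted_in_tstv(self):
        records = [
            _record(pos=1, ref="A", alt="G", S=SampleGenotype((0, 0))),
            _record(pos=2, ref="A", alt="C", S=SampleGenotype((1, 1))),
        ]
        assert compute_sample_qc(records, "S").tstv_ratio == 0.0

    def test_matches_independent_counting_oracle(self):
        rng = random.Random(9)
        bases = "ACGT"
        records = []
        for i in range(300):
            ref = rng.choice(bases)
            alt = rng.choice([b for b in bases if b != ref])
            gt = rng.choice([(0, 0), (0, 1), (1, 1), (-1, -1)])
            records.append(_record(pos=i + 1, ref=ref, alt=alt,
                                   S=SampleGenotype(gt, gq=rng.randint(0, 99), dp=rng.randint(0, 60))))
        rep = compute_sample_qc(records, "S")
        ts = tv = hom = het = 0
        for r in records:
            a, b = r.per_sample["S"].allele_indices
            if a < 0:
                continue
            if a != b:
                het += 1
            elif a == 1:
                hom += 1
            if (a == 1 or b == 1) and len(r.ref) == 1 == len(r.alts[0]):
                if {r.ref, r.alts[0]} in ({"A", "G"}, {"C", "T"}):
                    ts += 1
                else:
                    tv += 1
        assert rep.tstv_ratio == pytest.approx(ts / tv)
        assert rep.hom_het_ratio == pytest.approx(hom / het)

    def test_unknown_sample_raises(self):
        records = [_record(pos=1, S=SampleGenotype((0, 1)))]
        with pytest.raises(RosterError):
            compute_sample_qc(records, "missing")


class TestClinicalGrade:
    def test_exact_threshold_values_pass(self):
        th = ClinicalGradeThresholds(15, 40, (0.3, 2.5), (1.5, 3.5))
        rep = QCReport("s", mean_depth=15, mean_gq=40, hom_het_ratio=0.3,
                       tstv_ratio=3.5, n_variants=10)
        assert grade_clinical(rep, th).passed

    def test_degraded_sample_fails_all_four_metrics(self):
        # depth 2.0, GQ 4.7, hom/het 0.11, Ts/Tv 1.06 under depth>=15, GQ>=40
        rep = QCReport("aunt", mean_depth=2.0, mean_gq=4.7, hom_het_ratio=0.11,
                       tstv_ratio=1.06, n_variants=970_018)
        res = grade_clinical(rep, ClinicalGradeThresholds(min_mean_depth=15, min_mean_gq=40))
        assert not res.passed
        assert res.failed_metrics() == ["mean_depth", "mean_gq", "hom_het_ratio", "tstv_ratio"]

    def test_undefined_metric_fails_with_reason(self):
        rep = QCReport("s", 30, 90, float("nan"), 2.0, 5)
        res = grade_clinical(rep)
        verdict = {v.metric: v for v in res.verdicts}["hom_het_ratio"]
        assert not verdict.passed and verdict.reason == "undefined"

    def test_matches_brute_force_comparison(self):
        rng = random.Random(1)
        for _ in range(100):
            rep = QCReport("s", rng.uniform(0, 50), rng.uniform(0, 100),
                           rng.uniform(0, 3), rng.uniform(0, 4), 10)
            lo_h, hi_h = sorted((rng.uniform(0, 3), rng.uniform(0, 3)))
            lo_t, hi_t = sorted((rng.uniform(0, 4), rng.uniform(0, 4)))
            th = ClinicalGradeThresholds(rng.uniform(0, 50), rng.uniform(0, 100),
                                         (lo_h, hi_h), (lo_t, hi_t))
            expected = (rep.mean_depth >= th.min_mean_depth
                        and rep.mean_gq >= th.min_mean_gq
                        and lo_h <= rep.hom_het_ratio <= hi_h
                        and lo_t <= rep.tstv_ratio <= hi_t)
            assert grade_clinical(rep, th).passed == expected

    def test_loosening_thresholds_is_monotone(self):
        rng = random.Random(5)
        for _ in range(50):
            rep = QCReport("s", rng.uniform(0, 50), rng.uniform(0, 100),
                           rng.uniform(0, 3), rng.uniform(0, 4), 10)
            th = ClinicalGradeThresholds(20, 50, (0.5, 2.0), (1.8, 3.0))
            loose = ClinicalGradeThresholds(10, 25, (0.1, 3.0), (0.9, 4.0))
            if grade_clinical(rep, th).passed:
                assert grade_clinical(rep, loose).passed
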