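"""Variant-file quality control and clinical-grade gating.

Per-sample QC summarises the metrics a clinical lab checks before trusting a
variant file for interpretation: mean depth, mean genotype quality, the
homozygous-alt/heterozygous call ratio and the transition/transversion (Ts/Tv)
ratio.  A configurable :class:`ClinicalGradeThresholds` gate decides whether a
sample takes part in downstream stages; samples that fail remain eligible for
pathogenicity screening only (the pipeline enforces that rule, not this
module).

Depth here is the mean per-site DP from the VCF — an approximation of
alignment-level coverage, which would need BAMs that are out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .vcfio import RosterError, VariantRecord

__all__ = [
    "UNDEFINED",
    "QCReport",
    "ClinicalGradeThresholds",
    "MetricVerdict",
    "ClinicalGradeResult",
    "apply_qual_filter",
    "compute_sample_qc",
    "grade_clinical",
]

#: Marker for a ratio with zero denominator; never an exception.
UNDEFINED = float("nan")

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_undefined(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class QCReport:
    """Clinical-grade quality metrics for one sample."""

    sample_id: str
    mean_depth: float
    mean_gq: float
    hom_het_ratio: float
    tstv_ratio: float
    n_variants: int
    n_coding: int | None = None

    def to_dict(self) -> dict:
        def _clean(x):
            return None if is_undefined(x) else x

        return {
            "sample_id": self.sample_id,
            "mean_depth": _clean(self.mean_depth),
            "mean_gq": _clean(self.mean_gq),
            "hom_het_ratio": _clean(self.hom_het_ratio),
            "tstv_ratio": _clean(self.tstv_ratio),
            "n_variants": self.n_variants,
            "n_coding": self.n_coding,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class ClinicalGradeThresholds:
    """Configurable pass bands, inclusive at both ends.

    Defaults are illustrative lab-style cutoffs, not literature claims:
    depth >= 15, GQ >= 40 (the minimum acceptable genotype quality used when
    triaging degraded samples), hom/het in [0.3, 2.5], Ts/Tv in [1.5, 3.5].
    """

    min_mean_depth: float = 15.0
    min_mean_gq: float = 40.0
    hom_het_range: tuple[float, float] = (0.3, 2.5)
    tstv_range: tuple[float, float] = (1.5, 3.5)

    def __post_init__(self) -> None:
        for low, high in (self.hom_het_range, self.tstv_range):
            if low > high:
                raise ValueError("range low must be <= high")


@dataclass(frozen=True)
class MetricVerdict:
    metric: str
    value: float
    passed: bool
    reason: str


@dataclass
class ClinicalGradeResult:
    sample_id: str
    verdicts: list[MetricVerdict]
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = all(v.passed for v in self.verdicts)

    def failed_metrics(self) -> list[str]:
        return [v.metric for v in self.verdicts if not v.passed]


def apply_qual_filter(
    records: list[VariantRecord],
    min_qual: float = 20.0,
    keep_missing: bool = False,
) -> tuple[list[VariantRecord], int]:
    """Drop records below the site-quality threshold (QUAL < min_qual).

    Records at exactly ``min_qual`` are kept.  Records with missing QUAL are
    removed by default (conservative); pass ``keep_missing=True`` to retain
    them.  Returns (retained records, number removed).
    """
    kept: list[VariantRecord] = []
    for rec in records:
        if rec.qual is None:
            if keep_missing:
                kept.append(rec)
        elif rec.qual >= min_qual:
            kept.append(rec)
    return kept, len(records) - len(kept)


def compute_sample_qc(records: list[VariantRecord], sample_id: str) -> QCReport:
    """Compute per-sample QC metrics in one pass over the records.

    Ts/Tv is counted over biallelic-SNV alt assessments: a site contributes
    once per alt allele the sample carries (multi-allelic sites are split into
    per-alt assessments).  Zero-denominator ratios come back as the explicit
    undefined marker (NaN), never an exception.
    """
    if records and sample_id not in records[0].per_sample:
        raise RosterError(f"unknown sample {sample_id!r}")

    depths: list[int] = []
    gqs: list[int] = []
    n_called = n_het = n_hom_alt = 0
    transitions = transversions = 0

    for rec in records:
        call = rec.per_sample.get(sample_id)
        if call is None or not call.is_called:
            continue
        n_called += 1
        if call.dp is not None:
            depths.append(call.dp)
        if call.gq is not None:
            gqs.append(call.gq)
        if call.is_het:
            n_het += 1
        elif call.is_hom_alt:
            n_hom_alt += 1
        for alt_index in range(1, len(rec.alts) + 1):
            if call.alt_copies(alt_index) == 0 or not rec.is_snv(alt_index):
                continue
            pair = (rec.ref, rec.alts[alt_index - 1])
            if pair in _TRANSITIONS:
                transitions += 1
            else:
                transversions += 1

    def _ratio(num: float, den: float) -> float:
        return num / den if den else UNDEFINED

    return QCReport(
        sample_id=sample_id,
        mean_depth=_ratio(sum(depths), len(depths)),
        mean_gq=_ratio(sum(gqs), len(gqs)),
        hom_het_ratio=_ratio(n_hom_alt, n_het),
        tstv_ratio=_ratio(transitions, transversions),
        n_variants=n_called,
    )


def grade_clinical(
    qc: QCReport, thresholds: ClinicalGradeThresholds | None = None
) -> ClinicalGradeResult:
    """Score a QC report against clinical-grade thresholds.

    One verdict per configured metric, bounds inclusive; an undefined metric
    fails with reason "undefined"; overall pass iff every metric passes.
    """
    thresholds = thresholds or ClinicalGradeThresholds()
    verdicts: list[MetricVerdict] = []

    def _check(metric: str, value: float, low: float, high: float | None) -> None:
        if is_undefined(value):
            verdicts.append(MetricVerdict(metric, value, False, "undefined"))
            return
        ok = value >= low and (high is None or value <= high)
        bound = f">= {low}" if high is None else f"in [{low}, {high}]"
        reason = "ok" if ok else f"{value:g} not {bound}"
        verdicts.append(MetricVerdict(metric, value, ok, reason))

    _check("mean_depth", qc.mean_depth, thresholds.min_mean_depth, None)
    _check("mean_gq", qc.mean_gq, thresholds.min_mean_gq, None)
    _check("hom_het_ratio", qc.hom_het_ratio, *thresholds.hom_het_range)
    _check("tstv_ratio", qc.tstv_ratio, *thresholds.tstv_range)
    return ClinicalGradeResult(sample_id=qc.sample_id, verdicts=verdicts)
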