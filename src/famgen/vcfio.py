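"""VCF reading and writing for small family/cohort callsets.

Variants are held in memory as :class:`VariantRecord` objects — one VCF row
with per-sample :class:`SampleGenotype` calls — which every downstream stage
(QC gating, pathogenicity screening, risk scoring, pharmacogenomics, traits)
consumes.  Parsing and serialisation go through :mod:`pysam`; this module only
adapts pysam records to the plain containers used by the rest of the package.

Coordinates are VCF-style: 1-based, inclusive.  The genome build is treated as
an opaque label that must match across all input tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pysam

__all__ = [
    "SampleGenotype",
    "VariantRecord",
    "VcfParseError",
    "RosterError",
    "read_vcf",
    "write_vcf",
]

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


class VcfParseError(ValueError):
    """Malformed VCF header or data row."""


class RosterError(KeyError):
    """A requested sample is not in the file's sample roster."""


@dataclass(frozen=True)
class SampleGenotype:
    """One sample's call at one site.

    ``allele_indices`` holds the two GT allele indices with -1 for missing
    alleles; ``gq`` and ``dp`` are ``None`` when the FORMAT field is absent,
    never silently zero.
    """

    allele_indices: tuple[int, int] = (-1, -1)
    phased: bool = False
    gq: int | None = None
    dp: int | None = None

    def __post_init__(self) -> None:
        for idx in self.allele_indices:
            if idx < -1:
                raise ValueError(f"allele index {idx} out of range")
        if self.gq is not None and self.gq < 0:
            raise ValueError("GQ must be >= 0")
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP must be >= 0")

    @property
    def is_called(self) -> bool:
        return all(i >= 0 for i in self.allele_indices)

    @property
    def is_het(self) -> bool:
        a, b = self.allele_indices
        return self.is_called and a != b

    @property
    def is_hom_alt(self) -> bool:
        a, b = self.allele_indices
        return self.is_called and a == b and a > 0

    @property
    def is_hom_ref(self) -> bool:
        a, b = self.allele_indices
        return self.is_called and a == b == 0

    def alt_copies(self, alt_index: int = 1) -> int:
        """Number of copies of the given ALT allele (1-based index) carried."""
        return sum(1 for i in self.allele_indices if i == alt_index)


@dataclass
class VariantRecord:
    """One VCF row: site fields plus per-sample genotype calls."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    filters: tuple[str, ...] = ()
    rsid: str | None = None
    per_sample: dict[str, SampleGenotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, *self.alts):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"unsupported (symbolic/empty) allele {allele!r}")
        if self.qual is not None and self.qual < 0:
            raise ValueError("QUAL must be >= 0 or missing")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, first alt) — the variant key used by annotation tables."""
        return (self.chrom, self.pos, self.ref, self.alts[0])

    def is_snv(self, alt_index: int = 1) -> bool:
        alt = self.alts[alt_index - 1]
        return len(self.ref) == 1 == len(alt) and self.ref != alt


def _convert_sample(sample) -> SampleGenotype:
    gt = sample.get("GT")
    if gt is None or all(a is None for a in gt):
        indices: tuple[int, int] = (-1, -1)
    else:
        pair = tuple(-1 if a is None else int(a) for a in gt)
        if len(pair) == 1:  # haploid call stored as a pair with missing mate
            pair = (pair[0], -1)
        indices = (pair[0], pair[1])
    gq = sample.get("GQ")
    dp = sample.get("DP")
    return SampleGenotype(
        allele_indices=indices,
        phased=bool(sample.phased),
        gq=None if gq is None else int(gq),
        dp=None if dp is None else int(dp),
    )


def read_vcf(
    path: str,
    sample_subset: list[str] | None = None,
) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF 4.x file (plain text or bgzip) into memory.

    Returns the records in file order and the sample roster.  Missing GQ/DP
    fields come back as ``None``.  Symbolic ALT alleles are rejected.
    """
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc

    roster = list(vf.header.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in roster]
        if missing:
            raise RosterError(f"samples not in {path}: {missing}")
        roster = list(sample_subset)

    records: list[VariantRecord] = []
    with vf:
        for line_no, rec in enumerate(vf, start=1):
            try:
                per_sample = {s: _convert_sample(rec.samples[s]) for s in roster}
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alts=tuple(rec.alts or ()),
                        qual=rec.qual,
                        filters=tuple(rec.filter.keys()),
                        rsid=None if rec.id in (None, ".") else rec.id,
                        per_sample=per_sample,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise VcfParseError(
                    f"{path}: bad record at data line {line_no} "
                    f"({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    return records, roster


def write_vcf(records: list[VariantRecord], roster: list[str], path: str) -> None:
    """Write records as VCF 4.2 with GT/GQ/DP FORMAT fields."""
    header = pysam.VariantHeader()
    seen: set[str] = set()
    for rec in records:
        if rec.chrom not in seen:
            header.contigs.add(rec.chrom)
            seen.add(rec.chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (phred)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for sample in roster:
        header.add_sample(sample)

    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
                id=rec.rsid,
                qual=rec.qual,
            )
            for flt in rec.filters:
                row.filter.add(flt)
            for sample in roster:
                call = rec.per_sample.get(sample, SampleGenotype())
                gt = tuple(None if i < 0 else i for i in call.allele_indices)
                row.samples[sample]["GT"] = gt
                row.samples[sample].phased = call.phased
                if call.gq is not None:
                    row.samples[sample]["GQ"] = call.gq
                if call.dp is not None:
                    row.samples[sample]["DP"] = call.dp
            out.write(row)
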