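"""Star-allele pharmacogenomics: diplotype calling, activity scores, dosing.

Pharmacogenes such as CYP2D6, CYP2C9 and CYP2C19 are reported as star-allele
diplotypes (e.g. *1/*2).  Each non-reference star allele is defined by a set
of variants; *1 is the reference haplotype with an empty defining set.  The
caller works from genotype copy counts at the defining positions — extracting
reference (non-variant) positions when required — and resolves the diplotype
by exact multiset explanation: a pair of alleles is a candidate iff the sum
of their defining-variant multisets reproduces the observed copy counts
exactly.  A single heterozygous defining allele therefore pairs with the wild
haplotype *1; an observation explainable by several pairs is returned as an
unresolved candidate set rather than forced into one call.

Activity scores (Gaedigk system) are per-allele values summed over a
diplotype and binned into metaboliser status (poor / intermediate /
normal-extensive / ultrarapid); an unresolved candidate set yields an
activity interval and possibly a range of adjacent statuses.  Dosing is a
pure table lookup keyed on the diplotype class and co-genotypes (warfarin:
CYP2C9 diplotype x VKORC1 rs9923231).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .vcfio import VariantRecord

__all__ = [
    "VariantKey",
    "StarAlleleDefinition",
    "GeneDefinitions",
    "Diplotype",
    "ActivityScore",
    "StatusBin",
    "DoseRecommendation",
    "load_star_definitions",
    "default_definitions",
    "default_status_bins",
    "load_dosing_table",
    "default_dosing_table",
    "genotypes_from_records",
    "call_star_alleles",
    "resolve_diplotypes",
    "activity_and_status",
    "warfarin_dose",
    "snp_response_lookup",
    "InconsistentDefinitionsError",
    "NoGuidanceError",
]

VariantKey = tuple[str, int, str, str]


class InconsistentDefinitionsError(ValueError):
    """Observed defining-variant hits cannot be explained by any allele pair."""


class NoGuidanceError(KeyError):
    """The dosing table does not cover the queried genotype key."""


@dataclass(frozen=True)
class StarAlleleDefinition:
    gene: str
    name: str  # e.g. "*4"
    defining_variants: tuple[VariantKey, ...]
    activity_value: float
    function: str = "unknown"  # normal|decreased|none|increased|unknown

    def __post_init__(self) -> None:
        if self.activity_value < 0:
            raise ValueError("activity value must be >= 0")
        if self.name == "*1" and self.defining_variants:
            raise ValueError("*1 is the reference allele; its defining set is empty")


@dataclass
class GeneDefinitions:
    gene: str
    alleles: dict[str, StarAlleleDefinition]

    def __post_init__(self) -> None:
        if "*1" not in self.alleles:
            self.alleles["*1"] = StarAlleleDefinition(self.gene, "*1", (), 1.0, "normal")

    @property
    def defining_positions(self) -> set[VariantKey]:
        return {v for d in self.alleles.values() for v in d.defining_variants}

    def activity(self, allele: str) -> float:
        d = self.alleles.get(allele)
        if d is None:
            raise KeyError(f"{self.gene}: no activity value for allele {allele}")
        return d.activity_value


@dataclass
class StarAlleleHits:
    """Observed copy counts at a gene's defining positions for one sample."""

    gene: str
    variant_copies: dict[VariantKey, int]
    #: per star allele: minimum copy count over its defining variants
    allele_support: dict[str, int]
    low_confidence: bool = False  # reference assumed at unasserted positions


@dataclass
class Diplotype:
    gene: str
    candidates: list[tuple[str, str]]  # unordered pairs, canonically sorted
    resolved: bool = field(init=False)
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("diplotype needs at least one candidate pair")
        self.resolved = len(self.candidates) == 1

    def __str__(self) -> str:
        return " | ".join("/".join(pair) for pair in self.candidates)


@dataclass(frozen=True)
class ActivityScore:
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (0 <= self.min <= self.max):
            raise ValueError("need 0 <= min <= max")


@dataclass(frozen=True)
class StatusBin:
    label: str
    lo: float
    hi: float
    lo_incl: bool = False
    hi_incl: bool = True

    def contains(self, x: float) -> bool:
        above = x > self.lo or (self.lo_incl and x == self.lo)
        below = x < self.hi or (self.hi_incl and x == self.hi)
        return above and below


@dataclass(frozen=True)
class DoseRecommendation:
    drug: str
    fraction_of_standard: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.fraction_of_standard <= 2:
            raise ValueError("dose fraction must be in (0, 2]")


# ---------------------------------------------------------------------------
# configuration loading

def _parse_variant_key(token: str) -> VariantKey:
    chrom, pos, ref, alt = token.split(":")
    return (chrom, int(pos), ref, alt)


def load_star_definitions(path_or_buf) -> dict[str, GeneDefinitions]:
    """Load star-allele definitions from TSV.

    Columns: gene, allele, activity, function, defining_variants — the last
    a semicolon-separated list of chrom:pos:ref:alt tokens, empty for *1.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    genes: dict[str, GeneDefinitions] = {}
    for row in df.itertuples(index=False):
        tokens = [] if pd.isna(row.defining_variants) or row.defining_variants == "" else row.defining_variants.split(";")
        d = StarAlleleDefinition(
            gene=row.gene,
            name=row.allele,
            defining_variants=tuple(_parse_variant_key(t) for t in tokens),
            activity_value=float(row.activity),
            function=row.function,
        )
        genes.setdefault(row.gene, GeneDefinitions(row.gene, {})).alleles[d.name] = d
    return genes


def _data(name: str):
    return resources.files("famgen.data").joinpath(name)


def default_definitions() -> dict[str, GeneDefinitions]:
    """Packaged CYP2C9 / CYP2C19 / CYP2D6 definition and activity tables."""
    with resources.as_file(_data("star_alleles.tsv")) as p:
        return load_star_definitions(p)


def default_status_bins() -> dict[str, list[StatusBin]]:
    """Metaboliser-status bins per gene (configuration, not hard constants)."""
    inf = math.inf
    return {
        "CYP2D6": [
            StatusBin("poor", 0.0, 0.0, lo_incl=True),
            StatusBin("intermediate", 0.0, 1.0),
            StatusBin("normal", 1.0, 2.25, hi_incl=False),
            StatusBin("ultrarapid", 2.25, inf, lo_incl=True),
        ],
        "CYP2C9": [
            StatusBin("poor", 0.0, 1.0, lo_incl=True),
            StatusBin("intermediate", 1.0, 1.75),
            StatusBin("normal", 1.75, 2.25, hi_incl=False),
            StatusBin("ultrarapid", 2.25, inf, lo_incl=True),
        ],
        "CYP2C19": [
            StatusBin("poor", 0.0, 0.0, lo_incl=True),
            StatusBin("intermediate", 0.0, 1.5),
            StatusBin("normal", 1.5, 2.25, hi_incl=False),
            StatusBin("ultrarapid", 2.25, inf, lo_incl=True),
        ],
    }


def load_dosing_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"fraction": float})
    needed = {"drug", "diplotype", "cogenotype", "fraction", "source"}
    if not needed.issubset(df.columns):
        raise ValueError(f"dosing table needs columns {sorted(needed)}")
    return df


def default_dosing_table() -> pd.DataFrame:
    with resources.as_file(_data("warfarin_dosing.tsv")) as p:
        return load_dosing_table(p)


def default_snp_responses() -> pd.DataFrame:
    with resources.as_file(_data("snp_responses.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# calling

def genotypes_from_records(
    records: Iterable[VariantRecord], sample: str
) -> dict[VariantKey, int]:
    """Alt-copy counts per (chrom,pos,ref,alt) for one sample.

    Sites with multiple ALTs contribute one key per alt.  Uncalled genotypes
    are omitted (treated as unasserted positions downstream).
    """
    out: dict[VariantKey, int] = {}
    for rec in records:
        call = rec.per_sample.get(sample)
        if call is None or not call.is_called:
            continue
        for i, alt in enumerate(rec.alts, start=1):
            out[(rec.chrom, rec.pos, rec.ref, alt)] = call.alt_copies(i)
    return out


def call_star_alleles(
    genotypes: Mapping[VariantKey, int],
    defs: GeneDefinitions,
    all_sites: bool = False,
) -> StarAlleleHits:
    """Count observed copies of each defining variant of a gene.

    Positions absent from the genotype source are taken as homozygous
    reference (the non-variant-extraction contract); unless the input is
    declared ``all_sites``, their use marks the call low-confidence.
    Conflicting ref alleles between input and definitions raise.
    """
    positions = defs.defining_positions
    by_locus = {(k[0], k[1]): k for k in positions}
    for (chrom, pos, ref, alt) in genotypes:
        want = by_locus.get((chrom, pos))
        if want is not None and want[2] != ref:
            raise ValueError(
                f"{defs.gene}: ref allele conflict at {chrom}:{pos} "
                f"(definitions say {want[2]}, input says {ref})"
            )
    observed: dict[VariantKey, int] = {}
    assumed_reference = False
    for key in positions:
        if key in genotypes:
            observed[key] = int(genotypes[key])
        else:
            observed[key] = 0
            assumed_reference = True
    support = {
        name: min((observed[v] for v in d.defining_variants), default=0)
        for name, d in defs.alleles.items()
        if d.defining_variants
    }
    return StarAlleleHits(
        gene=defs.gene,
        variant_copies=observed,
        allele_support={n: c for n, c in support.items() if c > 0},
        low_confidence=assumed_reference and not all_sites,
    )


def resolve_diplotypes(hits: StarAlleleHits, defs: GeneDefinitions) -> Diplotype:
    """Enumerate all allele pairs whose combined defining-variant multiset
    explains the observed copy counts exactly (unphased).

    No hits resolves to *1/*1; a single heterozygous defining allele pairs
    with *1 (wild-haplotype presumption); several consistent pairs come back
    unresolved.  Hits no pair can explain raise
    :class:`InconsistentDefinitionsError`.
    """
    observed = Counter({k: c for k, c in hits.variant_copies.items() if c > 0})
    names = sorted(defs.alleles)
    multisets = {n: Counter(defs.alleles[n].defining_variants) for n in names}
    candidates: list[tuple[str, str]] = []
    for i, a in enumerate(names):
        for b in names[i:]:
            if multisets[a] + multisets[b] == observed:
                candidates.append(tuple(sorted((a, b))))
    if not candidates:
        raise InconsistentDefinitionsError(
            f"{defs.gene}: observed defining variants {dict(observed)} "
            "are not explainable by any allele pair — inconsistent definitions"
        )
    # wild-type pairing and reference call first, then lexicographic
    candidates.sort()
    return Diplotype(
        gene=defs.gene, candidates=candidates, low_confidence=hits.low_confidence
    )


def activity_and_status(
    diplotype: Diplotype,
    defs: GeneDefinitions,
    bins: Mapping[str, list[StatusBin]] | None = None,
) -> tuple[ActivityScore, list[str]]:
    """Activity interval over candidate pairs plus the status bin(s) it spans.

    A resolved diplotype gives a point score; an unresolved one gives the
    [min, max] of the pairwise activity sums and every status bin attained by
    a candidate sum, in bin order.
    """
    bins = bins or default_status_bins()
    gene_bins = bins.get(diplotype.gene)
    if gene_bins is None:
        raise KeyError(f"no status bins configured for {diplotype.gene}")
    sums = [defs.activity(a) + defs.activity(b) for a, b in diplotype.candidates]
    score = ActivityScore(min=min(sums), max=max(sums))
    labels: list[str] = []
    for b in gene_bins:
        if any(b.contains(s) for s in sums) and b.label not in labels:
            labels.append(b.label)
    return score, labels


# ---------------------------------------------------------------------------
# dosing and single-SNP lookups

def _norm_diplotype(diplotype: str) -> str:
    return "/".join(sorted(diplotype.split("/")))


def warfarin_dose(
    cyp2c9_diplotype: str,
    vkorc1_genotype: str,
    table: pd.DataFrame | None = None,
) -> DoseRecommendation:
    """Initial warfarin dose as a fraction of standard, from the packaged
    CYP2C9 x VKORC1 rs9923231 guidance table.  Pure lookup: an uncovered key
    raises :class:`NoGuidanceError`, never a silent default.
    """
    table = table if table is not None else default_dosing_table()
    dip = _norm_diplotype(cyp2c9_diplotype)
    geno = "".join(sorted(vkorc1_genotype.upper()))
    rows = table[
        (table["drug"] == "warfarin")
        & (table["diplotype"].map(_norm_diplotype) == dip)
        & (table["cogenotype"].map(lambda g: "".join(sorted(g.upper()))) == geno)
    ]
    if rows.empty:
        raise NoGuidanceError(
            f"no guidance for warfarin with CYP2C9 {dip} and VKORC1 {geno}"
        )
    row = rows.iloc[0]
    return DoseRecommendation("warfarin", float(row["fraction"]), str(row["source"]))


@dataclass(frozen=True)
class SnpResponse:
    rsid: str
    genotype: str
    category: str
    annotation: str


def snp_response_lookup(
    rsid: str, genotype: str, table: pd.DataFrame | None = None
) -> SnpResponse:
    """Genotype-keyed drug-response annotation for single-SNP markers
    (e.g. IL28B rs12979860 and interferon response); unknown rsid or genotype
    yields an explicit no-annotation result.
    """
    table = table if table is not None else default_snp_responses()
    geno = "".join(sorted(genotype.upper()))
    rows = table[
        (table["rsid"] == rsid)
        & (table["genotype"].map(lambda g: "".join(sorted(g.upper()))) == geno)
    ]
    if rows.empty:
        return SnpResponse(rsid, geno, "no_annotation", "no annotation")
    row = rows.iloc[0]
    return SnpResponse(rsid, geno, str(row["category"]), str(row["annotation"]))
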