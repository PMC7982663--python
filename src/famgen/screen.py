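"""Panel-based pathogenicity screening.

Variants are screened against gene panels (e.g. OMIM morbid, the ACMG
secondary-findings list, a hereditary-cancer panel) with three gates: the gene
must be on a panel, the ClinVar consensus must be pathogenic / likely
pathogenic with a matching allele, and the population allele frequency must
not mark the site as common.  Candidates are then prioritised, classified with
the ACMG algebra (:mod:`famgen.acmg`), and placed in an inheritance context
(carrier vs at-risk).

The frequency gate follows gnomAD's definition of a common site (AF > 0.01)
but deprioritises rather than hard-excludes until a higher configurable cutoff
(default 0.05), because borderline-common variants can still deserve a written
assessment — the frequency-vs-prevalence bound of
:func:`frequency_vs_prevalence` then supplies the benign-support reasoning.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .vcfio import VariantRecord

__all__ = [
    "GenePanel",
    "EffectClass",
    "ClinvarClass",
    "AnnotationRecord",
    "PrevalenceModel",
    "Inheritance",
    "ScreenCandidate",
    "FrequencyVsPrevalence",
    "screen_panels",
    "frequency_vs_prevalence",
    "annotate_inheritance_context",
]

VariantKey = tuple[str, int, str, str]


class EffectClass(str, enum.Enum):
    LOSS_OF_FUNCTION = "loss_of_function"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class ClinvarClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    CONFLICTING = "conflicting"
    ABSENT = "absent"


class Inheritance(str, enum.Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    X_LINKED = "x_linked"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes) -> None:
        genes = frozenset(genes)
        if not name or not genes:
            raise ValueError("panel needs a name and at least one gene")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)

    @classmethod
    def from_file(cls, name: str, path: str) -> "GenePanel":
        """Load a one-symbol-per-line panel file (blank lines and # ignored)."""
        with open(path) as fh:
            genes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        return cls(name, genes)


@dataclass
class AnnotationRecord:
    """Locally snapshotted annotation for one variant allele."""

    key: VariantKey
    gene: str
    effect: EffectClass = EffectClass.OTHER
    clinvar_class: ClinvarClass = ClinvarClass.ABSENT
    clinvar_allele_match: bool = False
    pop_af: dict[str, float] | None = None  # population label -> AF
    constraint_missense_z: float | None = None
    computational_support: str = "inconclusive"  # benign_support|pathogenic_support|inconclusive

    def __post_init__(self) -> None:
        for pop, af in (self.pop_af or {}).items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"AF for {pop} out of [0,1]: {af}")

    @property
    def max_af(self) -> float | None:
        """Worst-case (maximum) AF over the population table, None if absent."""
        if not self.pop_af:
            return None
        return max(self.pop_af.values())


@dataclass
class PrevalenceModel:
    disorder: str
    prevalence: float
    inheritance: Inheritance = Inheritance.UNKNOWN
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0,1]")


_CLINVAR_STRENGTH = {ClinvarClass.PATHOGENIC: 0, ClinvarClass.LIKELY_PATHOGENIC: 1}
_EFFECT_SEVERITY = {
    EffectClass.LOSS_OF_FUNCTION: 0,
    EffectClass.MISSENSE: 1,
    EffectClass.SYNONYMOUS: 2,
    EffectClass.OTHER: 2,
}


@dataclass
class ScreenCandidate:
    record: VariantRecord
    annotation: AnnotationRecord
    panels: list[str]
    alt_copies: int
    common: bool = False  # AF above the common threshold but below the hard cutoff

    @property
    def sort_key(self):
        ann = self.annotation
        af = ann.max_af if ann.max_af is not None else 0.0
        return (
            _CLINVAR_STRENGTH.get(ann.clinvar_class, 9),
            _EFFECT_SEVERITY.get(ann.effect, 9),
            af,
            self.record.chrom,
            self.record.pos,
        )


@dataclass
class ScreenResult:
    candidates: dict[str, list[ScreenCandidate]]  # sample -> prioritised list
    n_unannotated: int = 0
    n_excluded_common: int = 0


def screen_panels(
    records: list[VariantRecord],
    annotations: dict[VariantKey, AnnotationRecord],
    panels: list[GenePanel],
    common_af: float = 0.01,
    hard_af: float = 0.05,
) -> ScreenResult:
    """Screen per-individual variants through the three candidate gates.

    A variant is a candidate for a sample iff the sample carries the alt
    allele, the gene sits on at least one panel, ClinVar consensus is P/LP
    with an allele match, and its maximum population AF does not exceed
    ``hard_af``.  Sites with AF strictly above ``common_af`` are retained but
    flagged ``common`` and deprioritised.  Unannotated variants are skipped
    and counted, never raised.
    """
    result = ScreenResult(candidates={})
    samples = list(records[0].per_sample) if records else []
    for s in samples:
        result.candidates[s] = []

    for rec in records:
        ann = annotations.get(rec.key)
        if ann is None:
            result.n_unannotated += 1
            continue
        admitting = [p.name for p in panels if ann.gene in p.genes]
        if not admitting:
            continue
        if ann.clinvar_class not in _CLINVAR_STRENGTH or not ann.clinvar_allele_match:
            continue
        af = ann.max_af
        if af is not None and af > hard_af:
            result.n_excluded_common += 1
            continue
        common = af is not None and af > common_af
        for s in samples:
            call = rec.per_sample.get(s)
            copies = call.alt_copies(1) if call is not None else 0
            if copies > 0:
                result.candidates[s].append(
                    ScreenCandidate(rec, ann, admitting, copies, common)
                )

    for s in samples:
        result.candidates[s].sort(key=lambda c: (c.common, c.sort_key))
    return result


def load_annotations(path: str) -> dict[VariantKey, AnnotationRecord]:
    """Load a local annotation snapshot TSV.

    Columns: chrom, pos, ref, alt, gene, effect, clinvar_class, allele_match
    (0/1), and zero or more ``af_<population>`` frequency columns (blank =
    absent).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    af_cols = [c for c in df.columns if c.startswith("af_")]
    out: dict[VariantKey, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        pop_af = {
            c[3:]: float(getattr(row, c))
            for c in af_cols
            if not pd.isna(getattr(row, c))
        }
        key = (str(row.chrom), int(row.pos), row.ref, row.alt)
        out[key] = AnnotationRecord(
            key=key,
            gene=row.gene,
            effect=EffectClass(row.effect),
            clinvar_class=ClinvarClass(row.clinvar_class),
            clinvar_allele_match=bool(int(row.allele_match)),
            pop_af=pop_af or None,
        )
    return out


@dataclass(frozen=True)
class FrequencyVsPrevalence:
    benign_support: bool
    max_credible_af: float | None
    reason: str


def frequency_vs_prevalence(af: float, model: PrevalenceModel) -> FrequencyVsPrevalence:
    """Compare an allele frequency against the maximum credible AF implied by
    disorder prevalence, inheritance mode, and penetrance.

    Under Hardy-Weinberg, a fully penetrant dominant disorder of prevalence P
    caps the pathogenic AF at P/2; a recessive one at sqrt(P).  Penetrance f
    relaxes each bound by 1/f.  An observed AF above the bound supports
    benignity.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError("af must be in [0,1]")
    if model.inheritance == Inheritance.AUTOSOMAL_DOMINANT:
        bound = model.prevalence / (2.0 * model.penetrance)
    elif model.inheritance == Inheritance.AUTOSOMAL_RECESSIVE:
        bound = math.sqrt(model.prevalence) / model.penetrance
    elif model.inheritance == Inheritance.X_LINKED:
        # conservative: treat as dominant-like on the hemizygous sex
        bound = model.prevalence / model.penetrance
    else:
        return FrequencyVsPrevalence(False, None, "inheritance unknown")
    support = af > bound
    reason = (
        f"AF {af:g} {'exceeds' if support else 'is within'} "
        f"max credible AF {bound:.3g} for {model.disorder}"
    )
    return FrequencyVsPrevalence(support, bound, reason)


@dataclass(frozen=True)
class InheritanceContext:
    label: str  # "carrier" | "at_risk"
    note: str


def annotate_inheritance_context(
    zygosity: str,
    inheritance: Inheritance,
    second_hit: bool = False,
) -> InheritanceContext:
    """Place a P/LP candidate in its inheritance context.

    ``zygosity`` is "heterozygous" or "homozygous".  A heterozygous hit in a
    recessive gene with no second hit is a carrier finding; two hits (or
    homozygosity), or any hit in a dominant gene, is an at-risk finding.
    """
    if zygosity not in ("heterozygous", "homozygous"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    if inheritance == Inheritance.AUTOSOMAL_RECESSIVE:
        if zygosity == "heterozygous" and not second_hit:
            return InheritanceContext(
                "carrier",
                "heterozygous in a recessive gene with no second hit: "
                "both alleles must be affected to cause the disorder",
            )
        return InheritanceContext(
            "at_risk", "both alleles affected in a recessive gene"
        )
    if inheritance in (Inheritance.AUTOSOMAL_DOMINANT, Inheritance.X_LINKED):
        return InheritanceContext("at_risk", f"{zygosity} in a {inheritance.value} gene")
    return InheritanceContext(
        "at_risk", "inheritance mode unknown; reported conservatively as at-risk"
    )
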