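"""Evidence-graded fitness and nutrition trait analysis.

Gene x lifestyle markers are first graded for scientific validity
(convincing / probable / possible / not demonstrated) from structured
evidence columns — study count, total subjects, study quality, knowledge of
the biological mechanism — in the style of consensus nutrigenomics guidance.
Only markers graded convincing or probable are carried forward to genotype
interpretation in the family.  Interpretation itself is a deterministic
lookup per marker model (dominant / recessive / additive / genotype table)
with declared-strand normalisation, plus a dedicated 21-SNP favorable-allele
count for VO2max trainability.

The printed validity labels of curated evidence tables are not perfectly
derivable from the table columns alone, so each profile may carry a
``curator_label`` that overrides the heuristic; the heuristic remains
available for de-novo markers.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ValidityScore",
    "EvidenceProfile",
    "TraitMarker",
    "TraitCall",
    "Vo2maxPanel",
    "Vo2maxScore",
    "grade_evidence",
    "carry_forward_filter",
    "interpret_trait_genotype",
    "vo2max_score",
    "load_evidence_table",
    "default_evidence_tables",
    "load_trait_markers",
    "default_trait_markers",
    "load_vo2max_panel",
    "default_vo2max_panel",
    "StrandMismatchError",
]

#: sentinel used when a table says "many" studies rather than a count
MANY_STUDIES = 20

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class StrandMismatchError(ValueError):
    """Genotype alleles match neither the marker's strand nor its complement."""


class ValidityScore(str, enum.Enum):
    CONVINCING = "convincing"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    NOT_DEMONSTRATED = "not_demonstrated"


_QUALITY = {"A", "B", "C", "D"}
_INTERACTION = {"direct", "intermediate", "indirect"}
_NATURE = {"causal", "LD", "associated_unknown"}
_PLAUSIBILITY = {"high", "medium", "low", "unknown"}
_MECHANISM = {"high", "medium", "low"}


@dataclass
class EvidenceProfile:
    """Structured evidence for one gene x lifestyle marker."""

    category: str  # fitness | nutrition
    trait: str
    rsid: str
    gene: str
    study_quality: str
    interaction_type: str
    variant_nature: str
    plausibility: str
    n_studies: int  # MANY_STUDIES encodes a "many" entry
    total_subjects: int  # lower bound
    mechanism_knowledge: str
    curator_label: ValidityScore | None = None

    def __post_init__(self) -> None:
        if self.study_quality not in _QUALITY:
            raise ValueError(f"study quality {self.study_quality!r} not in {_QUALITY}")
        if self.interaction_type not in _INTERACTION:
            raise ValueError(f"interaction type {self.interaction_type!r} invalid")
        if self.variant_nature not in _NATURE:
            raise ValueError(f"variant nature {self.variant_nature!r} invalid")
        if self.plausibility not in _PLAUSIBILITY:
            raise ValueError(f"plausibility {self.plausibility!r} invalid")
        if self.mechanism_knowledge not in _MECHANISM:
            raise ValueError(f"mechanism knowledge {self.mechanism_knowledge!r} invalid")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")


def grade_evidence(profile: EvidenceProfile) -> tuple[ValidityScore, str]:
    """Grade one marker's scientific validity.

    A curator label, when present, is returned verbatim.  Otherwise the
    heuristic requires, for *convincing*, at least 3 studies with at least
    1,000 subjects in total, non-low mechanistic knowledge, quality above D,
    and either a large aggregate cohort (>= 3,500 subjects) or broad
    replication (>= 20 studies); *probable* needs >= 3 studies, >= 250
    subjects and at least some mechanistic understanding; *possible* needs
    >= 2 studies with non-low mechanism; anything weaker is not demonstrated.
    """
    if profile.curator_label is not None:
        return profile.curator_label, "curator"
    n, subj = profile.n_studies, profile.total_subjects
    mech = profile.mechanism_knowledge
    if (
        n >= 3
        and subj >= 1000
        and mech != "low"
        and profile.study_quality != "D"
        and (subj >= 3500 or n >= MANY_STUDIES)
    ):
        return ValidityScore.CONVINCING, (
            f"{n} studies, >= {subj} subjects, mechanism {mech}"
        )
    if n >= 3 and subj >= 250 and mech in ("high", "medium"):
        return ValidityScore.PROBABLE, f"{n} studies, >= {subj} subjects"
    if n >= 2 and mech != "low":
        return ValidityScore.POSSIBLE, f"only {n} studies"
    return ValidityScore.NOT_DEMONSTRATED, "insufficient studies or mechanism"


def carry_forward_filter(
    profiles: Iterable[EvidenceProfile],
) -> tuple[list[EvidenceProfile], dict[str, Counter]]:
    """Keep markers graded convincing or probable.

    Returns the kept profiles and per-category grade counts (all four grades
    counted, kept or not).
    """
    kept: list[EvidenceProfile] = []
    counts: dict[str, Counter] = {}
    for p in profiles:
        grade, _ = grade_evidence(p)
        counts.setdefault(p.category, Counter())[grade.value] += 1
        if grade in (ValidityScore.CONVINCING, ValidityScore.PROBABLE):
            kept.append(p)
    return kept, counts


# ---------------------------------------------------------------------------
# genotype interpretation

@dataclass
class TraitMarker:
    trait: str
    rsid: str
    gene: str
    alleles: tuple[str, str]  # (other, effect) on the declared strand
    model: str  # dominant | recessive | additive | genotype-table
    #: effect-allele count (0,1,2) -> (interpretation text, direction tag)
    mapping: dict[int, tuple[str, str]]
    category: str = ""

    def __post_init__(self) -> None:
        if set(self.mapping) != {0, 1, 2}:
            raise ValueError(
                f"{self.rsid}: mapping must cover all 3 genotype classes"
            )


@dataclass(frozen=True)
class TraitCall:
    rsid: str
    trait: str
    genotype: str  # normalised to the marker's declared strand
    effect_count: int
    interpretation: str
    direction: str


def _normalise_genotype(marker: TraitMarker, genotype: str) -> str:
    """Map incoming genotype letters onto the marker's declared strand,
    complementing when the input was read off the opposite strand."""
    letters = [b.upper() for b in genotype if not b.isspace() and b != "/"]
    if len(letters) != 2:
        raise ValueError(f"{marker.rsid}: genotype {genotype!r} is not diploid")
    declared = set(marker.alleles)
    if set(letters) <= declared:
        return "".join(letters)
    flipped = [_COMPLEMENT.get(b, "?") for b in letters]
    if set(flipped) <= declared:
        return "".join(flipped)
    raise StrandMismatchError(
        f"{marker.rsid}: genotype {genotype!r} matches neither declared "
        f"alleles {marker.alleles} nor their complement"
    )


def interpret_trait_genotype(marker: TraitMarker, genotype: str) -> TraitCall:
    """Deterministic per-marker genotype interpretation.

    The genotype is normalised to the marker's declared strand first; an
    unmapped class yields an explicit no-interpretation call.
    """
    norm = _normalise_genotype(marker, genotype)
    effect = marker.alleles[1]
    count = sum(1 for b in norm if b == effect)
    text, direction = marker.mapping.get(count, ("no interpretation", "none"))
    return TraitCall(marker.rsid, marker.trait, norm, count, text, direction)


# ---------------------------------------------------------------------------
# VO2max trainability score

@dataclass
class Vo2maxPanel:
    """Favorable-allele panel for VO2max trainability (canonically 21 SNPs)."""

    markers: pd.DataFrame  # columns rsid, chrom, pos, ref, alt, favorable_allele

    def __post_init__(self) -> None:
        needed = {"rsid", "chrom", "pos", "ref", "alt", "favorable_allele"}
        if not needed.issubset(self.markers.columns):
            raise ValueError(f"panel needs columns {sorted(needed)}")

    def __len__(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class Vo2maxScore:
    individual: str
    score: int
    panel_size: int
    n_missing: int

    def __str__(self) -> str:
        return f"{self.score}/{self.panel_size}"


def vo2max_score(
    genotypes: Mapping[str, str],
    panel: Vo2maxPanel,
    individual: str = "",
    allow_any_size: bool = False,
    dosage_mode: bool = False,
) -> Vo2maxScore:
    """Count panel SNPs at which the individual carries >= 1 favorable allele.

    ``genotypes`` maps rsid -> genotype string (e.g. "AG").  Presence
    counting gives a 0..21 score; ``dosage_mode`` counts favorable-allele
    copies (0..42) instead.  A missing genotype counts 0 and is tallied.
    The panel must hold exactly 21 markers unless ``allow_any_size`` (toy
    panels).
    """
    if len(panel) != 21 and not allow_any_size:
        raise ValueError(f"VO2max panel must have 21 markers, got {len(panel)}")
    score = 0
    n_missing = 0
    for row in panel.markers.itertuples(index=False):
        geno = genotypes.get(row.rsid)
        if geno is None:
            n_missing += 1
            continue
        copies = sum(1 for b in geno.upper() if b == row.favorable_allele)
        score += copies if dosage_mode else int(copies >= 1)
    return Vo2maxScore(individual, score, len(panel), n_missing)


# ---------------------------------------------------------------------------
# table loading

def _parse_count(token, many: int = MANY_STUDIES) -> int:
    """Parse table counts like '24', '>1000', '~2000', 'many'."""
    s = str(token).strip().lower()
    if s in ("many",):
        return many
    m = re.match(r"^[>~]?\s*([\d,]+)\+?$", s)
    if not m:
        raise ValueError(f"cannot parse count {token!r}")
    return int(m.group(1).replace(",", ""))


def load_evidence_table(path_or_buf) -> list[EvidenceProfile]:
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    profiles: list[EvidenceProfile] = []
    for row in df.itertuples(index=False):
        label = None
        if hasattr(row, "curator_label") and not pd.isna(row.curator_label):
            label = ValidityScore(row.curator_label)
        profiles.append(
            EvidenceProfile(
                category=row.category,
                trait=row.trait,
                rsid=row.rsid,
                gene=row.gene,
                study_quality=row.study_quality,
                interaction_type=row.interaction_type,
                variant_nature=row.variant_nature,
                plausibility=row.plausibility,
                n_studies=_parse_count(row.n_studies),
                total_subjects=_parse_count(row.total_subjects, many=100_000),
                mechanism_knowledge=row.mechanism_knowledge,
                curator_label=label,
            )
        )
    return profiles


def _data(name: str):
    return resources.files("famgen.data").joinpath(name)


def default_evidence_tables() -> list[EvidenceProfile]:
    """Packaged fitness (10-row) and nutrition (32-row) evidence tables."""
    out: list[EvidenceProfile] = []
    for name in ("fitness_evidence.tsv", "nutrition_evidence.tsv"):
        with resources.as_file(_data(name)) as p:
            out.extend(load_evidence_table(p))
    return out


def load_trait_markers(path_or_buf) -> list[TraitMarker]:
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    markers: list[TraitMarker] = []
    for row in df.itertuples(index=False):
        other, effect = row.strand_alleles.split("/")
        if effect != row.effect_allele:
            other, effect = effect, other
        markers.append(
            TraitMarker(
                trait=row.trait,
                rsid=row.rsid,
                gene=row.gene,
                alleles=(other, effect),
                model=row.model,
                mapping={
                    0: (row.interp_0, row.dir_0),
                    1: (row.interp_1, row.dir_1),
                    2: (row.interp_2, row.dir_2),
                },
                category=row.category,
            )
        )
    return markers


def default_trait_markers() -> list[TraitMarker]:
    with resources.as_file(_data("trait_markers.tsv")) as p:
        return load_trait_markers(p)


def load_vo2max_panel(path_or_buf) -> Vo2maxPanel:
    return Vo2maxPanel(pd.read_csv(path_or_buf, sep="\t", dtype={"chrom": str}))


def default_vo2max_panel() -> Vo2maxPanel:
    """Packaged synthetic 21-SNP VO2max trainability panel.

    The panel membership is a synthetic stand-in with the published panel's
    shape (21 SNPs, one favorable allele each), not the published SNP list.
    """
    with resources.as_file(_data("vo2max_panel_synthetic.tsv")) as p:
        return load_vo2max_panel(p)
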