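"""Genetic risk scores referenced to a background population.

A phenotype's genetic risk score for one person is the sum of the marker
weights times the person's risk-allele dosage, divided by the number of risk
alleles reported for the phenotype (the harmonized panel size N):

    GRS = ( sum_i  w_i * d_i ) / N,      d_i in {0, 1, 2}

Scores are not interpreted on an absolute scale; each family member's score
is placed against the distribution of scores of a background cohort (the
stand-in for a reference panel such as 1000 Genomes Phase 3).  A member is
flagged ``over_2sd`` when the score exceeds mean + 2*SD of the background
(upper tail only), ``over_1sd`` between mean + 1*SD and mean + 2*SD.  A
phenotype is retained for reporting iff at least one member is over 2SD or
at least two members are flagged at 1SD or higher — an isolated mild signal
in a single member is dropped.  No multiple-testing correction is applied:
the object is to find members in the extreme tail, not to test hypotheses.

Markers enter the panel only if they carry a risk allele, an effect size and
a genome-wide-suggestive association p-value, and only if they are present in
the background callset; strand flips are resolved by complementation and
strand-ambiguous A/T and C/G markers are excluded by default.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GwasMarker",
    "PhenotypePanel",
    "RiskScore",
    "BackgroundDistribution",
    "RiskFlag",
    "GenotypeCallset",
    "load_marker_db",
    "harmonize_markers",
    "compute_grs",
    "background_stats",
    "flag_and_report_family",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

#: association p-value ceiling enforced on load (GWAS-suggestive threshold)
P_VALUE_CEILING = 1.0e-5


class RiskFlag(str, enum.Enum):
    NONE = "none"
    OVER_1SD = "over_1sd"
    OVER_2SD = "over_2sd"


@dataclass(frozen=True)
class GwasMarker:
    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    risk_allele: str
    weight: float
    phenotype: str
    weight_kind: str = "beta"  # "beta" | "odds_ratio"
    assoc_p: float = 1.0e-8
    study: str = ""
    #: set by harmonization: "direct" (risk allele as given) or "flipped"
    orientation: str = "direct"
    #: risk allele is the alt allele (True) or the ref allele (False)
    risk_is_alt: bool = True
    af: float | None = None  # background risk-allele frequency, when known


@dataclass
class PhenotypePanel:
    phenotype: str
    markers: list[GwasMarker]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError(f"panel {self.phenotype!r} has no markers")
        rsids = [m.rsid for m in self.markers]
        if len(set(rsids)) != len(rsids):
            raise ValueError(f"duplicate rsids in panel {self.phenotype!r}")

    def __len__(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class RiskScore:
    individual: str
    phenotype: str
    value: float
    n_markers_used: int
    n_markers_missing: int


@dataclass
class BackgroundDistribution:
    phenotype: str
    scores: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size < 2:
            raise ValueError("background needs at least 2 individuals")
        self.mean = float(self.scores.mean())
        self.sd = float(self.scores.std(ddof=1))

    @property
    def n(self) -> int:
        return int(self.scores.size)


@dataclass
class GenotypeCallset:
    """Alt-allele dosage matrix for a cohort: rows samples, columns markers.

    ``dosages`` holds alt-allele copy counts with -1 for missing calls.
    ``alleles`` maps rsid -> (ref, alt) so harmonization can match risk
    alleles; ``populations`` optionally labels each sample.
    """

    samples: list[str]
    rsids: list[str]
    dosages: np.ndarray
    alleles: dict[str, tuple[str, str]]
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.samples), len(self.rsids)):
            raise ValueError("dosage matrix shape mismatch")
        self._col = {r: i for i, r in enumerate(self.rsids)}

    def column(self, rsid: str) -> np.ndarray:
        return self.dosages[:, self._col[rsid]]

    def sample_genotypes(self, sample: str) -> dict[str, int]:
        row = self.dosages[self.samples.index(sample)]
        return dict(zip(self.rsids, (int(x) for x in row)))

    def subset(self, population: str) -> "GenotypeCallset":
        keep = [i for i, s in enumerate(self.samples) if self.populations.get(s) == population]
        if not keep:
            raise ValueError(f"no samples with population label {population!r}")
        samples = [self.samples[i] for i in keep]
        return GenotypeCallset(
            samples=samples,
            rsids=list(self.rsids),
            dosages=self.dosages[keep, :],
            alleles=dict(self.alleles),
            populations={s: self.populations[s] for s in samples},
        )


MARKER_DB_COLUMNS = [
    "rsid", "chrom", "pos", "ref", "alt", "risk_allele",
    "weight", "weight_kind", "p_value", "phenotype", "study",
]


def load_marker_db(path: str) -> tuple[list[PhenotypePanel], list[dict]]:
    """Load a GWAS marker TSV into per-phenotype panels.

    Rows missing the risk allele or the effect size, or with an association
    p-value at or above the suggestive ceiling, are rejected with a reason;
    the rejection log is returned alongside the panels.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing_cols = [c for c in MARKER_DB_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"marker DB missing columns: {missing_cols}")

    rejected: list[dict] = []
    by_phen: dict[str, list[GwasMarker]] = defaultdict(list)
    for row in df.itertuples(index=False):
        reason = None
        if pd.isna(row.risk_allele) or str(row.risk_allele) == "":
            reason = "no risk allele"
        elif pd.isna(row.weight):
            reason = "no effect size"
        elif pd.isna(row.p_value) or float(row.p_value) >= P_VALUE_CEILING:
            reason = f"association p >= {P_VALUE_CEILING:g}"
        if reason is not None:
            rejected.append({"rsid": row.rsid, "phenotype": row.phenotype, "reason": reason})
            continue
        by_phen[str(row.phenotype)].append(
            GwasMarker(
                rsid=str(row.rsid), chrom=str(row.chrom), pos=int(row.pos),
                ref=str(row.ref), alt=str(row.alt),
                risk_allele=str(row.risk_allele), weight=float(row.weight),
                phenotype=str(row.phenotype), weight_kind=str(row.weight_kind),
                assoc_p=float(row.p_value), study=str(row.study),
            )
        )
    panels = [PhenotypePanel(p, ms) for p, ms in by_phen.items()]
    return panels, rejected


def _is_ambiguous(ref: str, alt: str) -> bool:
    return frozenset({ref, alt}) in _AMBIGUOUS_PAIRS


def harmonize_markers(
    panel: PhenotypePanel,
    callset: GenotypeCallset,
    drop_ambiguous: bool = True,
) -> tuple[PhenotypePanel | None, list[dict]]:
    """Match panel markers to the background callset.

    Markers absent from the callset are excluded; the risk allele is matched
    against the callset's ref/alt either directly or via strand complement;
    A/T and C/G strand-ambiguous markers are excluded by default.  Returns
    the usable panel (None if no marker survives) and the exclusion log.
    """
    kept: list[GwasMarker] = []
    excluded: list[dict] = []
    for m in panel.markers:
        if m.rsid not in callset.alleles:
            excluded.append({"rsid": m.rsid, "reason": "absent from background"})
            continue
        ref, alt = callset.alleles[m.rsid]
        if drop_ambiguous and _is_ambiguous(ref, alt):
            excluded.append({"rsid": m.rsid, "reason": "strand-ambiguous"})
            continue
        if m.risk_allele == alt:
            orientation, risk_is_alt = "direct", True
        elif m.risk_allele == ref:
            orientation, risk_is_alt = "direct", False
        elif _COMPLEMENT.get(m.risk_allele) == alt:
            orientation, risk_is_alt = "flipped", True
        elif _COMPLEMENT.get(m.risk_allele) == ref:
            orientation, risk_is_alt = "flipped", False
        else:
            excluded.append({"rsid": m.rsid, "reason": "risk allele matches neither strand"})
            continue
        kept.append(
            GwasMarker(
                rsid=m.rsid, chrom=m.chrom, pos=m.pos, ref=ref, alt=alt,
                risk_allele=m.risk_allele, weight=m.weight, phenotype=m.phenotype,
                weight_kind=m.weight_kind, assoc_p=m.assoc_p, study=m.study,
                orientation=orientation, risk_is_alt=risk_is_alt, af=m.af,
            )
        )
    if not kept:
        return None, excluded
    return PhenotypePanel(panel.phenotype, kept), excluded


def _risk_dosage(alt_dosage: int, risk_is_alt: bool) -> int:
    if alt_dosage < 0:
        return -1
    return alt_dosage if risk_is_alt else 2 - alt_dosage


def compute_grs(
    genotypes: Mapping[str, int],
    panel: PhenotypePanel,
    individual: str = "",
    log_or: bool = False,
    impute_missing: bool = False,
) -> RiskScore:
    """Score one individual against a harmonized phenotype panel.

    ``genotypes`` maps rsid -> alt-allele dosage (-1 or absent = missing).
    Odds-ratio weights are summed as given unless ``log_or`` converts them to
    ln(OR) first.  Missing genotypes contribute dosage 0 (or the HWE mean
    dosage 2f when ``impute_missing`` and the marker AF is known) and are
    counted in ``n_markers_missing``.  The denominator is the panel marker
    count N.
    """
    if len(panel) == 0:
        raise ValueError("no markers")
    total = 0.0
    n_missing = 0
    for m in panel.markers:
        w = float(np.log(m.weight)) if (log_or and m.weight_kind == "odds_ratio") else m.weight
        alt_dos = genotypes.get(m.rsid, -1)
        dos = _risk_dosage(int(alt_dos), m.risk_is_alt)
        if dos < 0:
            n_missing += 1
            dosage = (2.0 * m.af) if (impute_missing and m.af is not None) else 0.0
        else:
            dosage = float(dos)
        total += w * dosage
    n = len(panel)
    return RiskScore(individual, panel.phenotype, total / n, n - n_missing, n_missing)


def background_stats(
    callset: GenotypeCallset,
    panel: PhenotypePanel,
    population: str | None = None,
    log_or: bool = False,
) -> BackgroundDistribution:
    """Score every background individual and summarise the distribution.

    SD uses the n-1 denominator.  ``population`` restricts to samples with
    that label (sub-population analysis).  Vectorised: equivalent to calling
    :func:`compute_grs` per individual.
    """
    if population is not None:
        callset = callset.subset(population)
    if len(callset.samples) < 2:
        raise ValueError("background needs at least 2 individuals")

    weights = np.array(
        [
            np.log(m.weight) if (log_or and m.weight_kind == "odds_ratio") else m.weight
            for m in panel.markers
        ],
        dtype=float,
    )
    cols = np.stack([callset.column(m.rsid) for m in panel.markers], axis=1).astype(float)
    risk = np.where(
        np.array([m.risk_is_alt for m in panel.markers])[None, :], cols, 2.0 - cols
    )
    risk[cols < 0] = 0.0  # missing -> dosage 0, matching compute_grs defaults
    scores = risk @ weights / len(panel)
    return BackgroundDistribution(panel.phenotype, scores)


def flag_score(score: float, dist: BackgroundDistribution) -> RiskFlag:
    """Upper-tail flag for one score against the background (strict bounds)."""
    if dist.sd == 0.0:
        return RiskFlag.NONE
    if score > dist.mean + 2.0 * dist.sd:
        return RiskFlag.OVER_2SD
    if score > dist.mean + dist.sd:
        return RiskFlag.OVER_1SD
    return RiskFlag.NONE


@dataclass
class FamilyRiskReport:
    #: phenotype -> member -> flag
    flags: dict[str, dict[str, RiskFlag]]
    #: phenotypes surviving the family-sharing retention rule
    retained: list[str]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {p: {m: f.value for m, f in row.items()} for p, row in self.flags.items()}
        ).T


def flag_and_report_family(
    family_scores: Mapping[str, Mapping[str, RiskScore]],
    distributions: Mapping[str, BackgroundDistribution],
    member_order: Iterable[str] | None = None,
) -> FamilyRiskReport:
    """Flag each member per phenotype and apply the retention rule.

    ``family_scores`` maps member -> phenotype -> RiskScore.  A phenotype is
    retained iff one member is over 2SD, or at least two members are flagged
    (1SD or higher).  Zero-SD backgrounds yield no flags and a warning.
    """
    members = list(member_order) if member_order is not None else list(family_scores)
    flags: dict[str, dict[str, RiskFlag]] = {}
    warnings: list[str] = []
    for phen, dist in distributions.items():
        if dist.sd == 0.0:
            warnings.append(f"{phen}: background SD is 0; no flags assigned")
        flags[phen] = {}
        for member in members:
            score = family_scores.get(member, {}).get(phen)
            flags[phen][member] = (
                RiskFlag.NONE if score is None else flag_score(score.value, dist)
            )
    retained = [
        phen
        for phen, row in flags.items()
        if any(f == RiskFlag.OVER_2SD for f in row.values())
        or sum(1 for f in row.values() if f != RiskFlag.NONE) >= 2
    ]
    return FamilyRiskReport(flags=flags, retained=retained, warnings=warnings)
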