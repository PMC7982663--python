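"""Synthetic inputs for the whole pipeline.

The family genomes the pipeline was designed around are not redistributable,
so every input is generated here instead: a GWAS-style marker database, a
Hardy-Weinberg background cohort standing in for a reference panel, and a
Mendelian-consistent five-member family (father, mother, aunt — the mother's
sister — daughter and son).  Founder haplotypes are drawn per marker from the
marker's allele frequency; the aunt and mother share a pair of simulated
grandparents; each child allele is drawn uniformly from the corresponding
parent's two alleles.  An optional "spike" replaces one founder's draw so
that each of their alleles is the risk allele with a chosen probability —
the handle used to plant a detectable extreme-risk member.  A "degrade"
transform emulates a poor-quality sample (dropped sites, deflated
QUAL/GQ/DP) so the clinical-grade gating path is exercisable.

Markers are simulated independent (no linkage disequilibrium): the risk
score is LD-blind, so LD structure would not change what the pipeline can
see.  All randomness flows from one master seed through fixed, named
substreams, giving byte-identical reruns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .pgx import GeneDefinitions, VariantKey
from .risk import GenotypeCallset
from .vcfio import SampleGenotype, VariantRecord, write_vcf

__all__ = [
    "SimulationConfig",
    "SpikeSpec",
    "Pedigree",
    "SimulatedCohort",
    "default_pedigree",
    "simulate_marker_db",
    "simulate_background",
    "simulate_family",
    "make_pgx_fixture",
    "cohort_records",
    "write_cohort",
    "degrade_records",
]

_SUBSTREAM = {"markers": 1, "background": 2, "family": 3, "meta": 4}

# ref/alt pairs that survive strand harmonization (no A/T or C/G, no identity),
# sampled transition-heavy (~2:1) to mimic genome-wide Ts/Tv
_TRANSITION_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
_TRANSVERSION_PAIRS = [("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_SUBSTREAM[stream],))
    )


@dataclass(frozen=True)
class SpikeSpec:
    member: str
    phenotype: str
    prob: float = 0.9  # probability each founder allele is the risk allele

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("spike probability must be in [0,1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_background: int = 1000
    populations: dict[str, float] = field(default_factory=lambda: {"EUR": 1.0})
    n_phenotypes: int = 3
    markers_per_phenotype: int = 50
    af_range: tuple[float, float] = (0.05, 0.5)
    weight_sigma: float = 0.2  # weights ~ |Normal(0, sigma)|, tagged beta
    spike: SpikeSpec | None = None

    def __post_init__(self) -> None:
        if self.n_background < 2:
            raise ValueError("n_background must be >= 2")
        lo, hi = self.af_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("allele-frequency range invalid")
        if abs(sum(self.populations.values()) - 1.0) > 1e-9:
            raise ValueError("population proportions must sum to 1")
        if self.weight_sigma <= 0:
            raise ValueError("weight sigma must be positive")


@dataclass
class Pedigree:
    """Member roles and parent links; founders have no in-pedigree parents."""

    members: list[str]
    parents: dict[str, tuple[str, str]]  # child -> (parent1, parent2)
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, pair in self.parents.items():
            if len(pair) != 2:
                raise ValueError(f"{child} needs exactly 2 parents")

    @property
    def founders(self) -> list[str]:
        return [m for m in self.members if m not in self.parents]


def default_pedigree() -> Pedigree:
    """The five reported members plus two hidden grandparents that make the
    aunt a full sibling of the mother."""
    return Pedigree(
        members=[
            "grandfather", "grandmother",
            "father", "mother", "aunt", "daughter", "son",
        ],
        parents={
            "mother": ("grandfather", "grandmother"),
            "aunt": ("grandfather", "grandmother"),
            "daughter": ("father", "mother"),
            "son": ("father", "mother"),
        },
        sex={
            "grandfather": "1", "grandmother": "2", "father": "1",
            "mother": "2", "aunt": "2", "daughter": "2", "son": "1",
        },
    )


#: members written to outputs (hidden grandparents stay internal)
REPORTED_MEMBERS = ["father", "mother", "aunt", "daughter", "son"]


@dataclass
class SimulatedCohort:
    markers: pd.DataFrame
    family: dict[str, dict[str, int]]  # member -> rsid -> alt dosage
    pedigree: Pedigree
    truth: dict


def simulate_marker_db(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a GWAS marker table: per-phenotype panels with risk allele,
    weight, allele frequency and association p-value.

    Reproducible under a fixed seed; AFs uniform on the configured range;
    the risk allele is always the alt allele.
    """
    rng = _rng(config.seed, "markers")
    rows = []
    idx = 0
    for p in range(config.n_phenotypes):
        phen = f"phenotype_{p:02d}"
        for _ in range(config.markers_per_phenotype):
            idx += 1
            pool = _TRANSITION_PAIRS if rng.random() < 2 / 3 else _TRANSVERSION_PAIRS
            ref, alt = pool[rng.integers(len(pool))]
            rows.append(
                {
                    "rsid": f"rs77{idx:06d}",
                    "chrom": str(1 + (idx % 22)),
                    "pos": 1_000_000 + idx * 1000,
                    "ref": ref,
                    "alt": alt,
                    "risk_allele": alt,
                    "weight": float(abs(rng.normal(0.0, config.weight_sigma))),
                    "weight_kind": "beta",
                    "p_value": float(10.0 ** rng.uniform(-30, -6)),
                    "phenotype": phen,
                    "study": "simulated",
                    "af": float(rng.uniform(*config.af_range)),
                }
            )
    return pd.DataFrame(rows)


def simulate_background(
    markers: pd.DataFrame,
    n: int,
    seed: int,
    populations: Mapping[str, float] | None = None,
    pop_af_shift: float = 0.0,
) -> GenotypeCallset:
    """Draw a background cohort under Hardy-Weinberg equilibrium.

    Genotypes are independent across markers; each marker's risk-allele
    frequency is its ``af`` column, optionally shifted per population by up
    to ``pop_af_shift`` (clipped to [0,1]).
    """
    rng = _rng(seed, "background")
    populations = dict(populations or {"EUR": 1.0})
    labels = list(populations)
    assign = rng.choice(len(labels), size=n, p=list(populations.values()))
    afs = markers["af"].to_numpy(dtype=float)
    shifts = {
        lab: (rng.uniform(-pop_af_shift, pop_af_shift, size=afs.size) if pop_af_shift else 0.0)
        for lab in labels
    }
    if not pop_af_shift:
        dosages = rng.binomial(2, afs, size=(n, afs.size)).astype(np.int8)
    else:
        dosages = np.empty((n, afs.size), dtype=np.int8)
        for i, lab_idx in enumerate(assign):
            f = np.clip(afs + shifts[labels[lab_idx]], 0.0, 1.0)
            dosages[i] = rng.binomial(2, f)
    samples = [f"BG{i:05d}" for i in range(n)]
    return GenotypeCallset(
        samples=samples,
        rsids=list(markers["rsid"]),
        dosages=dosages,
        alleles={r.rsid: (r.ref, r.alt) for r in markers.itertuples(index=False)},
        populations={s: labels[a] for s, a in zip(samples, assign)},
    )


def simulate_family(
    markers: pd.DataFrame,
    config: SimulationConfig,
    pedigree: Pedigree | None = None,
) -> SimulatedCohort:
    """Simulate Mendelian-consistent family genotypes.

    Founder haplotypes come from the background law (Bernoulli at each
    marker's AF); children draw each allele uniformly from the matching
    parent's pair.  A spike replaces the spiked founder's draw at the spiked
    phenotype's markers: each allele is the risk allele with the spike
    probability.  Spiking is only valid for founders — children inherit.
    """
    pedigree = pedigree or default_pedigree()
    rng = _rng(config.seed, "family")
    afs = markers["af"].to_numpy(dtype=float)
    rsids = list(markers["rsid"])
    phen = markers["phenotype"].to_numpy()
    n_mark = len(rsids)

    spike = config.spike
    if spike is not None and spike.member not in pedigree.founders:
        raise ValueError(
            f"spike member {spike.member!r} is not a founder; spiking applies "
            "to founders and children inherit"
        )

    haplos: dict[str, np.ndarray] = {}  # member -> (2, n_markers) 0/1 risk alleles
    for member in pedigree.members:
        if member in pedigree.parents:
            p1, p2 = pedigree.parents[member]
            h1 = haplos[p1][rng.integers(2, size=n_mark), np.arange(n_mark)]
            h2 = haplos[p2][rng.integers(2, size=n_mark), np.arange(n_mark)]
            haplos[member] = np.stack([h1, h2])
        else:
            draw = rng.binomial(1, afs, size=(2, n_mark)).astype(np.int8)
            if spike is not None and member == spike.member:
                mask = phen == spike.phenotype
                spiked = rng.binomial(1, spike.prob, size=(2, int(mask.sum())))
                draw[:, mask] = spiked
            haplos[member] = draw

    family = {
        m: dict(zip(rsids, (int(x) for x in haplos[m].sum(axis=0))))
        for m in pedigree.members
    }
    truth = {
        "haplotypes": {m: haplos[m].tolist() for m in pedigree.members},
        "spike": None
        if spike is None
        else {"member": spike.member, "phenotype": spike.phenotype, "prob": spike.prob},
        "seed": config.seed,
    }
    return SimulatedCohort(markers=markers, family=family, pedigree=pedigree, truth=truth)


def make_pgx_fixture(
    defs: GeneDefinitions,
    target: tuple[str, str],
    all_sites: bool = True,
) -> dict[VariantKey, int]:
    """Genotype copy counts realising a target star-allele pair.

    The fixture contains exactly the defining variants of the target pair
    (summed as a multiset); with ``all_sites`` every other defining position
    is asserted homozygous reference, mirroring an all-sites extraction.
    Resolution over the fixture is guaranteed to include the target pair.
    """
    a, b = target
    for name in target:
        if name not in defs.alleles:
            raise KeyError(f"unknown allele {name} for {defs.gene}")
    counts = Counter(defs.alleles[a].defining_variants)
    counts += Counter(defs.alleles[b].defining_variants)
    fixture = dict(counts)
    if all_sites:
        for key in defs.defining_positions:
            fixture.setdefault(key, 0)
    return fixture


# ---------------------------------------------------------------------------
# VCF materialisation

def cohort_records(
    cohort: SimulatedCohort,
    seed: int,
    members: list[str] | None = None,
) -> tuple[list[VariantRecord], list[str]]:
    """Materialise family genotypes as VariantRecords with simulated QUAL,
    GQ and DP drawn from fixed laws (QUAL ~ N(60,15) clipped at 0,
    GQ ~ N(90,8) clipped to [0,99], DP ~ Poisson(30))."""
    rng = _rng(seed, "meta")
    members = members or [m for m in REPORTED_MEMBERS if m in cohort.family]
    records: list[VariantRecord] = []
    for row in cohort.markers.itertuples(index=False):
        qual = float(max(0.0, rng.normal(60.0, 15.0)))
        per_sample = {}
        for m in members:
            dos = cohort.family[m][row.rsid]
            gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[dos]
            per_sample[m] = SampleGenotype(
                allele_indices=gt,
                gq=int(np.clip(rng.normal(90.0, 8.0), 0, 99)),
                dp=int(rng.poisson(30)),
            )
        records.append(
            VariantRecord(
                chrom=str(row.chrom), pos=int(row.pos), ref=row.ref,
                alts=(row.alt,), qual=round(qual, 2), filters=("PASS",),
                rsid=row.rsid, per_sample=per_sample,
            )
        )
    records.sort(key=lambda r: (int(r.chrom), r.pos))
    return records, members


def degrade_records(
    records: list[VariantRecord],
    member: str,
    seed: int,
    drop_fraction: float = 0.7,
    gq_scale: float = 0.05,
    dp_scale: float = 0.08,
    qual_scale: float = 0.4,
) -> list[VariantRecord]:
    """Emulate a degraded sample (e.g. DNA from hair rather than saliva).

    For the named member: a fraction of sites lose their call entirely and
    the rest have GQ/DP deflated; site QUAL is deflated wherever the member
    is the only carrier.  Returns new records; other members are untouched.
    """
    rng = _rng(seed, "meta")
    out: list[VariantRecord] = []
    for rec in records:
        per_sample = dict(rec.per_sample)
        call = per_sample.get(member)
        qual = rec.qual
        if call is not None and call.is_called:
            if rng.random() < drop_fraction:
                per_sample[member] = SampleGenotype()
            else:
                per_sample[member] = SampleGenotype(
                    allele_indices=call.allele_indices,
                    phased=call.phased,
                    gq=None if call.gq is None else max(0, int(call.gq * gq_scale)),
                    dp=None if call.dp is None else max(0, int(call.dp * dp_scale)),
                )
            others = [
                s for s, c in rec.per_sample.items() if s != member and c.alt_copies(1) > 0
            ]
            if not others and qual is not None:
                qual = round(qual * qual_scale, 2)
        out.append(
            VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=rec.alts,
                qual=qual, filters=rec.filters, rsid=rec.rsid,
                per_sample=per_sample,
            )
        )
    return out


def write_background_vcf(callset, markers: pd.DataFrame, path: str) -> None:
    """Write a background callset as a (QUAL-less metadata) multi-sample VCF."""
    gt = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (-1, -1)}
    records = []
    for j, row in enumerate(markers.itertuples(index=False)):
        per_sample = {
            s: SampleGenotype(allele_indices=gt[int(callset.dosages[i, j])])
            for i, s in enumerate(callset.samples)
        }
        records.append(VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alts=(row.alt,),
            qual=99.0, filters=("PASS",), rsid=row.rsid, per_sample=per_sample,
        ))
    records.sort(key=lambda r: (int(r.chrom), r.pos))
    write_vcf(records, callset.samples, path)


def write_cohort(
    cohort: SimulatedCohort,
    vcf_path: str,
    ped_path: str | None = None,
    seed: int | None = None,
) -> list[str]:
    """Write the reported family members as multi-sample VCF (+ PED)."""
    records, members = cohort_records(cohort, seed if seed is not None else cohort.truth["seed"])
    write_vcf(records, members, vcf_path)
    if ped_path is not None:
        ped = cohort.pedigree
        with open(ped_path, "w") as fh:
            for m in members:
                pa, ma = ped.parents.get(m, ("0", "0"))
                pa = pa if pa in members else "0"
                ma = ma if ma in members else "0"
                fh.write(f"FAM1\t{m}\t{pa}\t{ma}\t{ped.sex.get(m, '0')}\t0\n")
    return members
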