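"""Per-individual and family-level interpretation reports.

The report assembles every stage's output into one "genetic story": QC
verdicts, screened variants with their classification and inheritance
context, retained risk phenotypes with flags, pharmacogenomic calls with
dose recommendations, trait calls and the VO2max score — plus a family
section listing variants shared by two or more members, phenotypes flagged
in several members, and explicit negative findings (watchlist entries with
no positive hit, e.g. APOE epsilon-4 or pathogenic hits in the secondary-
findings panel when family history warrants saying "nothing found").

A sample that fails clinical-grade gating stays in pathogenicity screening
but is excluded from risk scoring, pharmacogenomics and trait analysis; the
report records each exclusion.  Output ordering is deterministic (member
role order, then genomic position / phenotype label) so reruns are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import pgx as _pgx
from . import traits as _traits
from .qc import ClinicalGradeResult, ClinicalGradeThresholds, apply_qual_filter, compute_sample_qc, grade_clinical
from .risk import FamilyRiskReport, RiskFlag
from .screen import ScreenResult
from .vcfio import read_vcf

__all__ = [
    "APOE_HAPLOTYPES",
    "apoe_epsilon",
    "FamilyReport",
    "build_report",
    "validate_report",
    "run_pipeline",
]

#: epsilon haplotype -> (rs429358 allele, rs7412 allele)
APOE_HAPLOTYPES = {
    "e1": ("C", "T"),
    "e2": ("T", "T"),
    "e3": ("T", "C"),
    "e4": ("C", "C"),
}


def apoe_epsilon(geno_rs429358: str, geno_rs7412: str) -> tuple[list[str], bool]:
    """Resolve the APOE epsilon diplotype from the two coding SNPs.

    Unphased resolution: every epsilon-haplotype pair whose combined allele
    counts reproduce both genotypes is a candidate.  The double-heterozygote
    is genuinely ambiguous (e2/e4 vs the rare e1/e3) and is returned as two
    candidates with ``resolved=False``.
    """
    g1 = sorted(geno_rs429358.upper())
    g2 = sorted(geno_rs7412.upper())
    names = sorted(APOE_HAPLOTYPES)
    candidates = []
    for i, a in enumerate(names):
        for b in names[i:]:
            ha, hb = APOE_HAPLOTYPES[a], APOE_HAPLOTYPES[b]
            if sorted((ha[0], hb[0])) == g1 and sorted((ha[1], hb[1])) == g2:
                candidates.append(f"{a}/{b}")
    return candidates, len(candidates) == 1


@dataclass
class FamilyReport:
    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"Family report ({len(self.data.get('members', {}))} members)"]
        for member, section in self.data.get("members", {}).items():
            lines.append(f"\n== {member} ==")
            qc = section.get("qc")
            if qc:
                lines.append(f"  clinical grade: {'PASS' if qc['passed'] else 'FAIL'}"
                             f" ({', '.join(qc['failed_metrics']) or 'all metrics ok'})")
            for hit in section.get("screen", []):
                lines.append(
                    f"  screen: {hit['variant']} {hit['gene']} "
                    f"{hit['classification']} ({hit['context']})"
                )
            for phen, flag in section.get("risk_flags", {}).items():
                lines.append(f"  risk: {phen} {flag}")
            for call in section.get("pgx", []):
                lines.append(
                    f"  pgx: {call['gene']} {call['diplotype']} "
                    f"activity {call['activity']} -> {call['status']}"
                )
            if "vo2max" in section:
                lines.append(f"  vo2max trainability: {section['vo2max']}")
            for t in section.get("traits", []):
                lines.append(f"  trait: {t['trait']} [{t['genotype']}] {t['direction']}")
            if section.get("excluded_from"):
                lines.append(f"  excluded from: {', '.join(section['excluded_from'])}")
        fam = self.data.get("family", {})
        for entry in fam.get("shared_variants", []):
            lines.append(f"shared variant {entry['variant']}: {', '.join(entry['members'])}")
        for entry in fam.get("shared_risk_phenotypes", []):
            lines.append(f"shared risk {entry['phenotype']}: {', '.join(entry['members'])}")
        for entry in fam.get("negative_findings", []):
            lines.append(f"negative finding: {entry['watch']}: {entry['note']}")
        return "\n".join(lines)


def build_report(
    members: list[str],
    qc: dict[str, ClinicalGradeResult] | None = None,
    screen: dict[str, list[dict]] | None = None,
    risk: FamilyRiskReport | None = None,
    pgx_calls: dict[str, list[dict]] | None = None,
    trait_calls: dict[str, list[dict]] | None = None,
    vo2max: dict[str, str] | None = None,
    watchlist: list[dict] | None = None,
    excluded: dict[str, list[str]] | None = None,
) -> FamilyReport:
    """Assemble stage outputs into the per-member + family report.

    ``watchlist`` entries are dicts with keys ``watch`` and ``hit`` (bool)
    and ``note``; entries with no positive hit become negative findings.
    Shared variants are computed by exact (chrom,pos,ref,alt) match over the
    screening candidates of carrying members.
    """
    if risk is not None:
        for row in risk.flags.values():
            for m in row:
                if m not in members:
                    raise KeyError(f"risk table member {m!r} not in pedigree roster")

    data: dict = {"members": {}, "family": {}}
    screen = screen or {}
    for member in members:
        section: dict = {}
        if qc and member in qc:
            res = qc[member]
            section["qc"] = {
                "passed": res.passed,
                "failed_metrics": res.failed_metrics(),
                "verdicts": [
                    {"metric": v.metric,
                     "value": None if v.value != v.value else v.value,  # NaN -> null
                     "passed": v.passed, "reason": v.reason}
                    for v in res.verdicts
                ],
            }
        if member in screen:
            section["screen"] = sorted(
                screen[member], key=lambda h: h["variant"]
            )
        if risk is not None:
            flags = {
                phen: risk.flags[phen][member].value
                for phen in sorted(risk.retained)
                if risk.flags[phen].get(member, RiskFlag.NONE) != RiskFlag.NONE
            }
            if flags:
                section["risk_flags"] = flags
        if pgx_calls and member in pgx_calls:
            section["pgx"] = pgx_calls[member]
        if trait_calls and member in trait_calls:
            section["traits"] = sorted(trait_calls[member], key=lambda t: t["trait"])
        if vo2max and member in vo2max:
            section["vo2max"] = vo2max[member]
        if excluded and excluded.get(member):
            section["excluded_from"] = sorted(excluded[member])
        data["members"][member] = section

    # family section: variants shared by >= 2 members
    carriers: dict[str, list[str]] = {}
    gene_of: dict[str, str] = {}
    for member in members:
        for hit in screen.get(member, []):
            carriers.setdefault(hit["variant"], []).append(member)
            gene_of[hit["variant"]] = hit.get("gene", "")
    data["family"]["shared_variants"] = [
        {"variant": v, "gene": gene_of[v], "members": sorted(set(ms))}
        for v, ms in sorted(carriers.items())
        if len(set(ms)) >= 2
    ]
    shared_risk = []
    if risk is not None:
        for phen in sorted(risk.retained):
            flagged = sorted(
                m for m, f in risk.flags[phen].items() if f != RiskFlag.NONE
            )
            if len(flagged) >= 2:
                shared_risk.append({"phenotype": phen, "members": flagged})
    data["family"]["shared_risk_phenotypes"] = shared_risk
    data["family"]["negative_findings"] = [
        {"watch": w["watch"], "note": w.get("note", "no positive finding")}
        for w in (watchlist or [])
        if not w.get("hit", False)
    ]
    report = FamilyReport(data)
    validate_report(report.data)
    return report


def validate_report(data: dict) -> None:
    """Structural validation of the report payload.

    Every shared-variant entry must list >= 2 members, members referenced in
    the family section must exist, and risk flags must use the flag
    vocabulary.
    """
    if "members" not in data or "family" not in data:
        raise ValueError("report must have members and family sections")
    roster = set(data["members"])
    for entry in data["family"].get("shared_variants", []):
        if len(entry["members"]) < 2:
            raise ValueError(f"shared variant {entry['variant']} lists < 2 members")
        if not set(entry["members"]) <= roster:
            raise ValueError("shared variant lists unknown member")
    flag_values = {f.value for f in RiskFlag}
    for member, section in data["members"].items():
        for phen, flag in section.get("risk_flags", {}).items():
            if flag not in flag_values:
                raise ValueError(f"{member}/{phen}: bad flag {flag!r}")


# ---------------------------------------------------------------------------
# orchestration

def run_pipeline(config: dict) -> FamilyReport:
    """Run qc -> screen -> grs -> pgx -> traits -> report from a config dict.

    Recognised keys (all paths; stages without inputs are skipped):
    ``family_vcf`` (required), ``min_qual``, ``thresholds`` (mapping),
    ``annotations_tsv`` + ``panels`` (name -> path), ``markers_tsv`` +
    ``background_vcf``, ``report_json`` output path.  Members failing
    clinical-grade gating keep their screening section but are excluded from
    grs/pgx/traits.
    """
    from . import risk as _risk
    from .acmg import AcmgEvidence, combine_acmg
    from .screen import GenePanel, Inheritance, annotate_inheritance_context, load_annotations, screen_panels

    records, roster = read_vcf(config["family_vcf"])
    records, n_removed = apply_qual_filter(records, float(config.get("min_qual", 20.0)))
    thresholds = ClinicalGradeThresholds(**config.get("thresholds", {}))

    qc_results = {s: grade_clinical(compute_sample_qc(records, s), thresholds) for s in roster}
    passing = [s for s in roster if qc_results[s].passed]
    excluded = {
        s: (["grs", "pgx", "traits"] if s not in passing else [])
        for s in roster
    }

    screen_section: dict[str, list[dict]] = {}
    if "annotations_tsv" in config:
        annotations = load_annotations(config["annotations_tsv"])
        panels = [GenePanel.from_file(name, path) for name, path in config.get("panels", {}).items()]
        result: ScreenResult = screen_panels(records, annotations, panels)
        modes = {g: Inheritance(m) for g, m in config.get("gene_inheritance", {}).items()}
        for sample, cands in result.candidates.items():
            rows = []
            for c in cands:
                zyg = "homozygous" if c.alt_copies == 2 else "heterozygous"
                mode = modes.get(c.annotation.gene, Inheritance.UNKNOWN)
                ctx = annotate_inheritance_context(zyg, mode)
                verdict = combine_acmg(AcmgEvidence(set(config.get(
                    "acmg_evidence", {}).get("|".join(map(str, c.record.key)), []))))
                rows.append({
                    "variant": "{}:{}:{}>{}".format(*c.record.key),
                    "gene": c.annotation.gene,
                    "panels": sorted(c.panels),
                    "zygosity": zyg,
                    "classification": verdict.value,
                    "context": ctx.label,
                })
            screen_section[sample] = rows

    risk_report = None
    if "markers_tsv" in config and "background_vcf" in config:
        panels_r, _rej = _risk.load_marker_db(config["markers_tsv"])
        bg_records, bg_roster = read_vcf(config["background_vcf"])
        callset = _callset_from_records(bg_records, bg_roster)
        fam_scores: dict[str, dict] = {m: {} for m in passing}
        dists = {}
        for panel in panels_r:
            hp, _ = _risk.harmonize_markers(panel, callset)
            if hp is None:
                continue
            dists[hp.phenotype] = _risk.background_stats(callset, hp)
            for m in passing:
                genos = _genotypes_by_rsid(records, m)
                fam_scores[m][hp.phenotype] = _risk.compute_grs(genos, hp, individual=m)
        risk_report = _risk.flag_and_report_family(fam_scores, dists, member_order=passing)

    pgx_section: dict[str, list[dict]] = {}
    defs = _pgx.default_definitions()
    for m in passing:
        genos = _pgx.genotypes_from_records(records, m)
        calls = []
        for gene, gd in sorted(defs.items()):
            if not (gd.defining_positions & set(genos)):
                continue  # gene not covered by this input
            hits = _pgx.call_star_alleles(genos, gd, all_sites=bool(config.get("all_sites", False)))
            dip = _pgx.resolve_diplotypes(hits, gd)
            score, status = _pgx.activity_and_status(dip, gd)
            calls.append({
                "gene": gene,
                "diplotype": str(dip),
                "resolved": dip.resolved,
                "activity": [score.min, score.max],
                "status": "/".join(status),
            })
        if calls:
            pgx_section[m] = calls

    trait_section: dict[str, list[dict]] = {}
    vo2 = {}
    markers = _traits.default_trait_markers()
    kept, _counts = _traits.carry_forward_filter(_traits.default_evidence_tables())
    kept_rsids = {p.rsid for p in kept}
    for m in passing:
        genos = _genotype_strings_by_rsid(records, m)
        rows = []
        for marker in markers:
            if marker.rsid not in kept_rsids or marker.rsid not in genos:
                continue
            call = _traits.interpret_trait_genotype(marker, genos[marker.rsid])
            rows.append({
                "trait": call.trait, "rsid": call.rsid,
                "genotype": call.genotype, "direction": call.direction,
                "interpretation": call.interpretation,
            })
        if rows:
            trait_section[m] = rows
        panel = _traits.default_vo2max_panel()
        if any(r in genos for r in panel.markers["rsid"]):
            vo2[m] = str(_traits.vo2max_score(genos, panel, individual=m))

    watchlist = _build_watchlist(records, roster, screen_section, config)

    report = build_report(
        members=roster,
        qc=qc_results,
        screen=screen_section,
        risk=risk_report,
        pgx_calls=pgx_section,
        trait_calls=trait_section,
        vo2max=vo2,
        watchlist=watchlist,
        excluded=excluded,
    )
    report.data["qc_removed_low_qual"] = n_removed
    if "report_json" in config:
        with open(config["report_json"], "w") as fh:
            fh.write(report.to_json())
    return report


def _build_watchlist(records, roster, screen_section, config) -> list[dict]:
    """Default negative-finding watchlist: APOE e4 and ACMG-panel P/LP."""
    watch: list[dict] = []
    genos_by_member = {m: _genotype_strings_by_rsid(records, m) for m in roster}
    apoe_hits = []
    for m in roster:
        g = genos_by_member[m]
        if "rs429358" in g and "rs7412" in g:
            calls, _resolved = apoe_epsilon(g["rs429358"], g["rs7412"])
            if any("e4" in c for c in calls):
                apoe_hits.append(m)
    if any("rs429358" in g for g in genos_by_member.values()):
        watch.append({
            "watch": "APOE e4",
            "hit": bool(apoe_hits),
            "note": "no member carries an epsilon-4 haplotype"
            if not apoe_hits else f"epsilon-4 candidate in {sorted(apoe_hits)}",
        })
    acmg_genes = set()
    for path in (config.get("watch_panels") or {}).values():
        from .screen import GenePanel

        acmg_genes |= set(GenePanel.from_file("watch", path).genes)
    if acmg_genes:
        hits = [
            h["gene"] for rows in screen_section.values() for h in rows
            if h["gene"] in acmg_genes and h["classification"] in ("pathogenic", "likely_pathogenic")
        ]
        watch.append({
            "watch": "secondary-findings panel P/LP",
            "hit": bool(hits),
            "note": "no pathogenic/likely pathogenic hit in the panel genes"
            if not hits else f"hits in {sorted(set(hits))}",
        })
    return watch


def _genotypes_by_rsid(records, sample) -> dict[str, int]:
    out = {}
    for rec in records:
        if rec.rsid is None:
            continue
        call = rec.per_sample.get(sample)
        if call is not None and call.is_called:
            out[rec.rsid] = call.alt_copies(1)
    return out


def _genotype_strings_by_rsid(records, sample) -> dict[str, str]:
    out = {}
    for rec in records:
        if rec.rsid is None:
            continue
        call = rec.per_sample.get(sample)
        if call is not None and call.is_called:
            alleles = [rec.ref if i == 0 else rec.alts[i - 1] for i in call.allele_indices]
            out[rec.rsid] = "".join(alleles)
    return out


def _callset_from_records(records, roster):
    import numpy as np

    from .risk import GenotypeCallset

    rsids, alleles, cols = [], {}, []
    for rec in records:
        if rec.rsid is None or len(rec.alts) != 1:
            continue
        rsids.append(rec.rsid)
        alleles[rec.rsid] = (rec.ref, rec.alts[0])
        cols.append([
            rec.per_sample[s].alt_copies(1) if rec.per_sample[s].is_called else -1
            for s in roster
        ])
    return GenotypeCallset(
        samples=list(roster),
        rsids=rsids,
        dosages=np.array(cols, dtype=np.int8).T if cols else np.empty((len(roster), 0), dtype=np.int8),
        alleles=alleles,
    )
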