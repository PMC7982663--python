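"""Marker DB loading, harmonization, risk scoring and background flags."""

import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famgen.risk import (
    BackgroundDistribution,
    GenotypeCallset,
    GwasMarker,
    PhenotypePanel,
    RiskFlag,
    background_stats,
    compute_grs,
    flag_and_report_family,
    flag_score,
    harmonize_markers,
    load_marker_db,
    RiskScore,
)
from famgen.simulate import SimulationConfig, simulate_background, simulate_marker_db


def _marker(rsid, weight, risk="G", ref="A", alt="G", phen="p", af=None, risk_is_alt=True):
    return GwasMarker(rsid=rsid, chrom="1", pos=1, ref=ref, alt=alt,
                      risk_allele=risk, weight=weight, phenotype=phen,
                      af=af, risk_is_alt=risk_is_alt)


def _db_frame(rows):
    return pd.DataFrame(rows, columns=[
        "rsid", "chrom", "pos", "ref", "alt", "risk_allele", "weight",
        "weight_kind", "p_value", "phenotype", "study"])


class TestLoadMarkerDb:
    def test_row_without_weight_rejected(self, tmp_path):
        df = _db_frame([
            ("rs1", "1", 10, "A", "G", "G", 0.2, "beta", 1e-8, "p1", "s"),
            ("rs2", "1", 20, "A", "G", "G", None, "beta", 1e-8, "p1", "s"),
        ])
        path = tmp_path / "db.tsv"
        df.to_csv(path, sep="\t", index=False)
        panels, rejected = load_marker_db(str(path))
        assert len(panels) == 1 and len(panels[0]) == 1
        assert rejected == [{"rsid": "rs2", "phenotype": "p1", "reason": "no effect size"}]

    def test_weak_association_rejected(self, tmp_path):
        df = _db_frame([("rs1", "1", 10, "A", "G", "G", 0.2, "beta", 1e-4, "p1", "s")])
        path = tmp_path / "db.tsv"
        df.to_csv(path, sep="\t", index=False)
        panels, rejected = load_marker_db(str(path))
        assert panels == [] and "p >=" in rejected[0]["reason"]

    def test_three_phenotypes_two_markers_each(self, tmp_path):
        rows = [(f"rs{p}{i}", "1", 10 * i + p, "A", "G", "G", 0.1, "beta", 1e-9, f"p{p}", "s")
                for p in range(3) for i in range(2)]
        path = tmp_path / "db.tsv"
        _db_frame(rows).to_csv(path, sep="\t", index=False)
        panels, rejected = load_marker_db(str(path))
        assert sorted((pl.phenotype, len(pl)) for pl in panels) == [
            ("p0", 2), ("p1", 2), ("p2", 2)]
        assert rejected == []

    def test_defective_fraction_matches_brute_force(self, tmp_path):
        rng = random.Random(3)
        rows = []
        for i in range(500):
            defect = rng.random() < 0.05
            kind = rng.choice(["weight", "risk", "pval"]) if defect else None
            rows.append((
                f"rs{i}", "1", i + 1, "A", "G",
                "" if kind == "risk" else "G",
                None if kind == "weight" else 0.1,
                "beta",
                1e-3 if kind == "pval" else 1e-9,
                f"p{i % 5}", "s",
            ))
        path = tmp_path / "db.tsv"
        _db_frame(rows).to_csv(path, sep="\t", index=False)
        panels, rejected = load_marker_db(str(path))
        expected_bad = sum(1 for r in rows if r[5] == "" or r[6] is None or r[8] >= 1e-5)
        assert len(rejected) == expected_bad
        assert sum(len(p) for p in panels) == 500 - expected_bad


def _callset(alleles, n=4, fill=1):
    rsids = list(alleles)
    return GenotypeCallset(
        samples=[f"s{i}" for i in range(n)],
        rsids=rsids,
        dosages=np.full((n, len(rsids)), fill, dtype=np.int8),
        alleles=alleles,
    )


class TestHarmonize:
    def test_direct_match_kept(self):
        panel = PhenotypePanel("p", [_marker("rs1", 0.1, risk="G")])
        hp, excl = harmonize_markers(panel, _callset({"rs1": ("A", "G")}))
        assert hp.markers[0].orientation == "direct"
        assert hp.markers[0].risk_is_alt and excl == []

    def test_complement_match_flipped(self):
        # risk reported as G, background stores the site as T>C: complement of G
        panel = PhenotypePanel("p", [_marker("rs1", 0.1, risk="G")])
        hp, excl = harmonize_markers(panel, _callset({"rs1": ("T", "C")}))
        assert hp.markers[0].orientation == "flipped"
        assert hp.markers[0].risk_is_alt

    def test_risk_allele_may_be_reference(self):
        panel = PhenotypePanel("p", [_marker("rs1", 0.1, risk="A")])
        hp, _ = harmonize_markers(panel, _callset({"rs1": ("A", "G")}))
        assert not hp.markers[0].risk_is_alt

    def test_ambiguous_and_absent_markers_excluded(self):
        panel = PhenotypePanel("p", [
            _marker("rs1", 0.1, risk="A"), _marker("rs2", 0.1, risk="G")])
        hp, excl = harmonize_markers(panel, _callset({"rs1": ("A", "T")}))
        assert hp is None
        reasons = {e["rsid"]: e["reason"] for e in excl}
        assert reasons == {"rs1": "strand-ambiguous", "rs2": "absent from background"}


class TestComputeGrs:
    def test_zero_dosages_give_zero(self):
        panel = PhenotypePanel("p", [_marker("rs1", 0.5), _marker("rs2", 0.7)])
        score = compute_grs({"rs1": 0, "rs2": 0}, panel)
        assert score.value == 0.0 and score.n_markers_used == 2

    def test_hand_arithmetic(self):
        panel = PhenotypePanel("p", [_marker("rs1", 0.2), _marker("rs2", 0.3)])
        score = compute_grs({"rs1": 1, "rs2": 2}, panel)
        assert score.value == pytest.approx((0.2 * 1 + 0.3 * 2) / 2) == pytest.approx(0.4)

    def test_missing_counts_and_denominator(self):
        panel = PhenotypePanel("p", [_marker("rs1", 0.4), _marker("rs2", 0.4)])
        score = compute_grs({"rs1": 2}, panel)
        assert score.n_markers_missing == 1
        assert score.n_markers_used + score.n_markers_missing == len(panel)
        assert score.value == pytest.approx(0.8 / 2)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="no markers"):
            PhenotypePanel("p", [])

    def test_matches_brute_force_accumulation(self):
        rng = random.Random(11)
        for _ in range(1000):
            n = rng.randint(1, 20)
            markers = [
                _marker(f"rs{i}", rng.uniform(0, 1), risk_is_alt=rng.random() < 0.5)
                for i in range(n)
            ]
            panel = PhenotypePanel("p", markers)
            genos = {f"rs{i}": rng.choice([-1, 0, 1, 2]) for i in range(n)}
            got = compute_grs(genos, panel).value
            total = 0.0
            for m in markers:
                d = genos[m.rsid]
                if d < 0:
                    d = 0
                elif not m.risk_is_alt:
                    d = 2 - d
                total += m.weight * d
            assert got == pytest.approx(total / n)


class TestBackgroundStats:
    def test_identical_individuals_give_zero_sd(self):
        cs = _callset({"rs1": ("A", "G")}, n=5, fill=1)
        panel = PhenotypePanel("p", [_marker("rs1", 0.3)])
        dist = background_stats(cs, panel)
        assert dist.sd == 0.0 and dist.mean == pytest.approx(0.3)

    def test_hwe_mean_matches_analytic_expectation(self):
        cfg = SimulationConfig(seed=21, n_background=1000, n_phenotypes=1,
                               markers_per_phenotype=30)
        markers = simulate_marker_db(cfg)
        bg = simulate_background(markers, cfg.n_background, cfg.seed)
        panels, _ = _load_panels_from_frame(markers)
        hp, _ = harmonize_markers(panels[0], bg)
        dist = background_stats(bg, hp)
        w = np.array([m.weight for m in hp.markers])
        f = markers.set_index("rsid").loc[[m.rsid for m in hp.markers], "af"].to_numpy()
        expect = float((w * 2 * f).sum() / len(hp))
        se = dist.sd / np.sqrt(dist.n)
        assert abs(dist.mean - expect) < 3 * se + 1e-12

    def test_subpopulation_equals_subset_recompute(self):
        cfg = SimulationConfig(seed=5, n_background=300, n_phenotypes=1,
                               markers_per_phenotype=10,
                               populations={"EUR": 0.6, "AFR": 0.4})
        markers = simulate_marker_db(cfg)
        bg = simulate_background(markers, cfg.n_background, cfg.seed,
                                 populations=cfg.populations)
        panels, _ = _load_panels_from_frame(markers)
        hp, _ = harmonize_markers(panels[0], bg)
        sub = background_stats(bg, hp, population="EUR")
        manual = background_stats(bg.subset("EUR"), hp)
        assert sub.mean == pytest.approx(manual.mean)
        assert sub.sd == pytest.approx(manual.sd)
        assert sub.n == manual.n

    def test_too_small_background_rejected(self):
        cs = _callset({"rs1": ("A", "G")}, n=1)
        with pytest.raises(ValueError):
            background_stats(cs, PhenotypePanel("p", [_marker("rs1", 0.3)]))


def _load_panels_from_frame(markers):
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        markers.to_csv(fh.name, sep="\t", index=False)
        return load_marker_db(fh.name)


def _score(member, phen, value):
    return RiskScore(member, phen, value, 1, 0)


class TestFlags:
    def _dist(self, scores):
        return BackgroundDistribution("p", np.asarray(scores, dtype=float))

    def test_exactly_two_sd_is_over_1sd_not_2sd(self):
        dist = self._dist([0, 1, 2, 3, 4])  # mean 2, sd ~1.58
        assert flag_score(dist.mean + 2 * dist.sd, dist) == RiskFlag.OVER_1SD
        assert flag_score(dist.mean + 2 * dist.sd + 1e-9, dist) == RiskFlag.OVER_2SD
        assert flag_score(dist.mean + dist.sd, dist) == RiskFlag.NONE

    def test_lower_tail_never_flagged(self):
        dist = self._dist([0, 1, 2, 3, 4])
        assert flag_score(dist.mean - 3 * dist.sd, dist) == RiskFlag.NONE

    def test_retention_rules(self):
        dist = self._dist(list(range(10)))
        hi = dist.mean + 2.5 * dist.sd
        mid = dist.mean + 1.5 * dist.sd
        scores = {
            "father": {"solo2sd": _score("father", "solo2sd", hi),
                       "solo1sd": _score("father", "solo1sd", mid),
                       "shared1sd": _score("father", "shared1sd", mid)},
            "mother": {"solo2sd": _score("mother", "solo2sd", 0.0),
                       "solo1sd": _score("mother", "solo1sd", 0.0),
                       "shared1sd": _score("mother", "shared1sd", mid)},
        }
        dists = {p: dist for p in ("solo2sd", "solo1sd", "shared1sd")}
        rep = flag_and_report_family(scores, dists)
        assert "solo2sd" in rep.retained          # one member beyond 2SD
        assert "solo1sd" not in rep.retained      # isolated mild signal dropped
        assert "shared1sd" in rep.retained        # shared by two members

    def test_zero_sd_background_warns_and_flags_nothing(self):
        dist = self._dist([1.0, 1.0, 1.0])
        rep = flag_and_report_family(
            {"m": {"p": _score("m", "p", 99.0)}}, {"p": dist})
        assert rep.flags["p"]["m"] == RiskFlag.NONE
        assert rep.warnings

    @settings(max_examples=60, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), shift=st.floats(-50.0, 50.0))
    def test_flags_invariant_under_positive_affine_transform(self, scale, shift):
        rng = np.random.default_rng(0)
        bg = rng.normal(0.3, 0.1, size=200)
        dist0 = BackgroundDistribution("p", bg)
        # family scores well inside each flag band, away from fp boundaries
        fam = {
            "m1": dist0.mean + 2.7 * dist0.sd,
            "m2": dist0.mean + 1.5 * dist0.sd,
            "m3": dist0.mean - 1.0 * dist0.sd,
        }
        base = {m: flag_score(v, dist0) for m, v in fam.items()}
        dist_t = BackgroundDistribution("p", bg * scale + shift)
        transformed = {
            m: flag_score(v * scale + shift, dist_t) for m, v in fam.items()
        }
        assert transformed == base
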