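"""Decision workflow, rescues, genotype overrides, and accountancy identities."""

from __future__ import annotations

import itertools

import pytest

from probeqc.feature_annotation import ProbeFlags
from probeqc.filter_engine import (
    FilterConfig,
    FilterDecision,
    accounting_summary,
    apply_filter,
    audit_category_table,
    export_annotations,
    genotype_override,
    read_annotations,
    region_removal_fractions,
    rescue_report,
    summarize_any_overlap,
    summarize_unique,
)
from probeqc.manifest_io import ProbeRecord

SEQ = "ACGT" * 12 + "AC"


def flags(pid="p1", design="I", **kw) -> ProbeFlags:
    return ProbeFlags(probe_id=pid, design_type=design, **kw)


class TestApplyFilter:
    def test_type_I_body_snp_discarded(self):
        f = flags(body_snps_total=1)
        dec = apply_filter({"p1": f})["p1"]
        assert dec.verdict == "discard" and dec.reasons == ["BODY_SNP_TYPE_I"]

    def test_type_II_body_snps_tolerated(self):
        f = flags(design="II", body_snps_total=3)
        dec = apply_filter({"p1": f})["p1"]
        assert dec.verdict == "keep" and dec.rescued_by == "TYPE_II_TOLERANT"

    def test_all_bisokay_rescued(self):
        f = flags(body_snps_total=2, body_snps_bisokay=2)
        dec = apply_filter({"p1": f})["p1"]
        assert dec.verdict == "keep" and dec.rescued_by == "BIS_OKAY"

    def test_reasons_accumulate_in_workflow_order(self):
        f = flags(multimap=True, repeat=True, snp_at_cpg_c=True, body_snps_total=1, unknown_factor=True)
        dec = apply_filter({"p1": f})["p1"]
        assert dec.reasons == ["MULTIMAP", "REPEAT", "SNP_AT_CPG", "BODY_SNP_TYPE_I", "UNKNOWN_FACTOR"]

    def test_indel_kept_by_default_dropped_for_population(self):
        f = flags(indel=True)
        assert apply_filter({"p1": f})["p1"].verdict == "keep"
        assert apply_filter({"p1": f})["p1"].rescued_by == "INDEL_TOLERANT"
        pop = FilterConfig.from_preset("population")
        assert apply_filter({"p1": f}, pop)["p1"].reasons == ["INDEL"]

    def test_cell_line_keeps_cpg_snp_probes(self):
        f = flags(snp_at_cpg_c=True)
        cfg = FilterConfig.from_preset("cell_line")
        dec = apply_filter({"p1": f}, cfg)["p1"]
        assert dec.verdict == "keep" and dec.rescued_by == "CONFIG_TOLERANT"

    def test_unevaluable_unknown_never_fires(self):
        f = flags(unknown_factor=None)
        assert apply_filter({"p1": f})["p1"].verdict == "keep"

    def test_missing_probe_listed(self):
        with pytest.raises(KeyError, match="p2"):
            apply_filter({"p1": flags()}, probe_ids=["p1", "p2"])

    def test_conservative_discards_superset(self, world):
        default = world.decisions
        conservative = apply_filter(world.flags, FilterConfig.from_preset("conservative"))
        d_default = {pid for pid, d in default.items() if d.verdict == "discard"}
        d_cons = {pid for pid, d in conservative.items() if d.verdict == "discard"}
        assert d_default <= d_cons

    def test_monotonicity_of_drop_flags(self, world):
        """Enabling any additional drop_* flag never increases the kept count."""
        base = FilterConfig()
        kept_base = sum(d.verdict == "keep" for d in apply_filter(world.flags, base).values())
        for change in (
            {"drop_indel": True},
            {"drop_typeII_body_snp": True},
            {"bisokay_rescue": False},
        ):
            cfg = FilterConfig(**{**base.__dict__, **change})
            kept = sum(d.verdict == "keep" for d in apply_filter(world.flags, cfg).values())
            assert kept <= kept_base

    def test_determinism_byte_identical_export(self, tmp_path, world):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        export_annotations(world.flags, world.decisions, p1)
        export_annotations(world.flags, world.decisions, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestGenotypeOverride:
    def _setup(self, call_c=None):
        probe = ProbeRecord("p1", "I", "chr1", 1001, "+", SEQ)
        f = flags(snp_at_cpg_c=True)
        decisions = apply_filter({"p1": f})
        genotypes = {("chr1", 1001): call_c} if call_c else {}
        return probe, f, decisions, genotypes

    def test_hom_ref_rescues(self):
        probe, f, decisions, genotypes = self._setup("hom_ref")
        out = genotype_override(decisions, {"p1": f}, [probe], genotypes)
        assert out["p1"].verdict == "keep" and out["p1"].rescued_by == "GENOTYPE"

    def test_hom_alt_forces_discard(self):
        probe, f, decisions, genotypes = self._setup("hom_alt")
        out = genotype_override(decisions, {"p1": f}, [probe], genotypes)
        assert out["p1"].verdict == "discard" and "GENOTYPE" in out["p1"].reasons

    def test_het_leaves_default(self):
        probe, f, decisions, genotypes = self._setup("het")
        out = genotype_override(decisions, {"p1": f}, [probe], genotypes)
        assert out["p1"] == decisions["p1"]

    def test_no_overlap_identity(self):
        probe, f, decisions, _ = self._setup()
        out = genotype_override(decisions, {"p1": f}, [probe], {("chr9", 5): "hom_alt"})
        assert out == decisions

    def test_invalid_call_rejected(self):
        probe, f, decisions, _ = self._setup()
        with pytest.raises(ValueError):
            genotype_override(decisions, {"p1": f}, [probe], {("chr1", 1001): "0/1"})


class TestSummaries:
    def test_any_overlap_counts_probe_in_every_category(self):
        f = flags(multimap=True, repeat=True)
        table = summarize_any_overlap({"p1": f})
        assert table.loc["multimap", "type_i"] == 1
        assert table.loc["repeat", "type_i"] == 1
        assert (table["total"] == table["type_i"] + table["type_ii"]).all()

    def test_unique_partition_identities(self, world):
        table = summarize_unique(world.flags, world.decisions)
        n = len(world.flags)
        assert table.loc["total", "total"] == n
        kept = sum(d.verdict == "keep" for d in world.decisions.values())
        assert table.loc["total", "kept_total"] == kept
        # rows (categories + high_quality) partition the probes
        rows = [r for r in table.index if r != "total"]
        assert table.loc[rows, "total"].sum() == n
        # kept = high-quality + rescued, overall and per chemistry
        resc = rescue_report(world.flags, world.decisions)
        for chem in ("type_i", "type_ii"):
            hq = table.loc["high_quality", f"kept_{chem}"]
            assert hq + resc.loc["total", chem] == table.loc["total", f"kept_{chem}"]

    def test_unique_counts_match_planted_categories(self, world):
        truth = world.fixture.truth
        table = summarize_unique(world.flags, world.decisions)
        # planted indel probes without a coincidental unknown flag are unique-indel
        planted = truth[(truth["category"] == "indel") & (truth["unknown_factor"] == False)]  # noqa: E712
        assert table.loc["indel", "total"] == len(planted)
        assert table.loc["indel", "kept_total"] == len(planted)

    def test_rescue_report_zero_factor_fixture(self):
        table = rescue_report({"p1": flags()}, apply_filter({"p1": flags()}))
        assert table.loc["total", "total"] == 0

    def test_rescue_report_bisokay_fixture(self):
        fl = {f"p{i}": flags(f"p{i}", body_snps_total=1, body_snps_bisokay=1) for i in range(12)}
        dec = apply_filter(fl)
        table = rescue_report(fl, dec)
        assert table.loc["BIS_OKAY", "total"] == 12
        assert table.loc["total", "total"] == 12


class TestRegionRemoval:
    def _world(self):
        probes = [ProbeRecord(f"p{i}", "I", "chr1", 1001 + 100 * i, "+", SEQ) for i in range(4)]
        fl = {
            "p0": flags("p0", repeat=True), "p1": flags("p1", repeat=True),
            "p2": flags("p2"), "p3": flags("p3"),
        }
        return probes, apply_filter(fl)

    def test_fractions(self):
        probes, decisions = self._world()
        regions = [
            ("chr1", 900, 1150, "island"),    # p0 (discard), p1 (discard)
            ("chr1", 1150, 1400, "shore"),    # p2, p3 (keep)
            ("chr1", 5000, 6000, "shelf"),    # empty
        ]
        table = region_removal_fractions(probes, decisions, regions)
        assert table.loc["island", "fraction_removed"] == 1.0
        assert table.loc["shore", "fraction_removed"] == 0.0
        assert table.loc["shelf", "n_total"] == 0
        assert table.loc["shelf", "fraction_removed"] != table.loc["shelf", "fraction_removed"]  # NaN

    def test_half_removed(self):
        probes, decisions = self._world()
        table = region_removal_fractions(probes, decisions, [("chr1", 900, 1350, "mixed")])
        assert table.loc["mixed", "fraction_removed"] == pytest.approx(0.5)


class TestAccounting:
    def test_toy_numbers(self):
        summary = accounting_summary(
            total={"type_i": 100, "type_ii": 300},
            high_quality={"type_i": 60, "type_ii": 200},
            rescued={"type_i": 10, "type_ii": 50},
        )
        assert summary["noisy"]["total"] == 140
        assert summary["kept"] == {"type_i": 70, "type_ii": 250, "total": 320}
        assert summary["removed"]["total"] == 80
        assert summary["removal_pct"] == 20

    def test_audit_flags_inconsistent_row(self):
        out = audit_category_table({"ok": (1, 2, 3), "bad": (10, 20, 31)})
        assert out["ok"]["consistent"] is True
        assert out["bad"]["consistent"] is False and out["bad"]["computed_total"] == 30


class TestExportRoundTrip:
    def test_lossless(self, tmp_path, world):
        path = tmp_path / "ann.csv"
        export_annotations(world.flags, world.decisions, path)
        flags2, decisions2 = read_annotations(path)
        assert flags2 == world.flags
        assert decisions2 == world.decisions

    def test_row_count_and_header(self, tmp_path, world):
        path = tmp_path / "ann.csv"
        export_annotations(world.flags, world.decisions, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == len(world.flags) + 1
        assert lines[0].startswith("probe_id,design_type,multimap")
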