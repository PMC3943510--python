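"""Shared fixtures: one seeded synthetic world, annotated once per session."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from probeqc.bisulfite_mapping import BisulfiteGenome, bisulfite_convert, flag_multimappers
from probeqc.feature_annotation import (
    ProbeFlags,
    annotate_probes,
    apply_unknown_flags,
    load_repeats_bed,
    load_variants_vcf,
)
from probeqc.filter_engine import FilterConfig, FilterDecision, apply_filter
from probeqc.synthetic_data import Fixture, FixtureConfig, generate_fixture
from probeqc.wgbs_stats import (
    PairedBeta,
    flag_unknown_factors,
    load_wgbs_sites,
    pair_probe_wgbs,
)

SMALL_CONFIG = FixtureConfig(
    seed=7,
    n_probes=800,
    n_multimap=30,
    n_repeat=40,
    n_indel=30,
    n_cpg_snp_c=30,
    n_cpg_snp_g=30,
    n_body_snp1=50,
    n_body_snp2=30,
    n_bisokay_only=30,
    n_unknown=25,
)


@dataclass
class AnnotatedWorld:
    """A generated fixture taken through the full annotation pipeline."""

    fixture: Fixture
    bsgenome: BisulfiteGenome
    multimapped: set[str]
    unmappable: set[str]
    flags: dict[str, ProbeFlags]
    pairs: list[PairedBeta]
    unmatched: list[str]
    decisions: dict[str, FilterDecision]


@pytest.fixture(scope="session")
def world(tmp_path_factory) -> AnnotatedWorld:
    fixture = generate_fixture(SMALL_CONFIG, tmp_path_factory.mktemp("fixture"))
    bsg = bisulfite_convert(fixture.genome)
    mm = flag_multimappers(fixture.probes, bsg)
    variants = load_variants_vcf(fixture.paths["variants"])
    repeats = load_repeats_bed(fixture.paths["repeats"])
    flags = annotate_probes(fixture.probes, fixture.genome, variants, repeats, mm.multimapped)
    sites = load_wgbs_sites(fixture.paths["wgbs"])
    pairs, unmatched = pair_probe_wgbs(
        fixture.probes, sites, fixture.beta_matrix["sample_01"].to_dict()
    )
    apply_unknown_flags(flags, flag_unknown_factors(pairs), [p.probe_id for p in pairs])
    decisions = apply_filter(flags, FilterConfig())
    return AnnotatedWorld(
        fixture=fixture,
        bsgenome=bsg,
        multimapped=mm.multimapped,
        unmappable=mm.unmappable,
        flags=flags,
        pairs=pairs,
        unmatched=unmatched,
        decisions=decisions,
    )
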