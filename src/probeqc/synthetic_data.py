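"""Seeded toy-scale fixture generation with known ground truth.

Generates a small random genome plus every input the pipeline consumes —
probe manifest, variant track (VCF), repeat track (BED), WGBS bedGraph,
array beta matrix, per-sample genotype calls — with per-probe ground-truth
category labels, expected annotation flags and expected default verdicts.

The stated world:

* probes are genuine 50-mers of the generated genome, so the bisulfite
  mapper verifies and uniquely maps them; multi-mapping probes come from
  genomic segments duplicated into a probe-free decoy zone;
* WGBS betas are digital: coverage ~ Poisson(mean 30), methylated reads ~
  Binomial(coverage, true beta), score = round(100 * m / cov);
* array betas are analog: clamp(center + Normal(0, sd)) with sd =
  background (0.05) plus a per-category extra (repeats +0.10, multimap
  +0.05), emulating the category-specific |delta beta| inflation of the
  array-vs-WGBS comparison;
* true betas come from a bimodal Beta(0.3, 0.3), concentrating density at
  (0,0) and (1,1) of the 2-D beta matrix;
* probes with a homozygous-alternate SNP genotype at the interrogated CpG
  collapse to a near-zero array beta (no methylation signal);
* "unknown factor" probes get a +-0.45 array offset so their |delta beta|
  robustly exceeds the 0.3 threshold.

One global integer seed; every track derives its own generator by labelled
hashing, so adding a track does not perturb the others. Identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .filter_engine import FilterConfig
from .manifest_io import ProbeRecord, probe_footprint, revcomp, write_manifest

__all__ = ["FixtureConfig", "Fixture", "generate_fixture", "expected_decisions", "simulate_paired_betas"]

_CATEGORIES = (
    "multimap", "repeat", "indel", "cpg_snp_c", "cpg_snp_g",
    "body_snp1", "body_snp2", "bisokay_only", "unknown",
)


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic world. Defaults are the tested conditions."""

    seed: int = 0
    n_chrom: int = 4
    chrom_len: int = 100_000
    n_probes: int = 2_000
    typeII_fraction: float = 0.72  # HM450K is ~72% Infinium II
    n_multimap: int = 60
    n_repeat: int = 80
    n_indel: int = 60
    n_cpg_snp_c: int = 50
    n_cpg_snp_g: int = 50
    n_body_snp1: int = 100
    n_body_snp2: int = 60
    n_bisokay_only: int = 60
    n_unknown: int = 50
    background_sd: float = 0.05
    extra_sd: Mapping[str, float] = field(default_factory=lambda: {"repeat": 0.10, "multimap": 0.05})
    cpg_snp_homalt_beta: float = 0.02
    unknown_offset: float = 0.45
    coverage_mean: float = 30.0
    n_samples: int = 8
    het_missing_fraction: float = 0.2

    def planted_counts(self) -> dict[str, int]:
        return {
            "multimap": self.n_multimap, "repeat": self.n_repeat, "indel": self.n_indel,
            "cpg_snp_c": self.n_cpg_snp_c, "cpg_snp_g": self.n_cpg_snp_g,
            "body_snp1": self.n_body_snp1, "body_snp2": self.n_body_snp2,
            "bisokay_only": self.n_bisokay_only, "unknown": self.n_unknown,
        }


@dataclass
class Fixture:
    """Generated files plus the in-memory objects and ground truth."""

    config: FixtureConfig
    paths: dict[str, Path]
    genome: dict[str, str]
    probes: list[ProbeRecord]
    truth: pd.DataFrame  # indexed by probe_id
    genotypes: dict[tuple[str, int], str]
    beta_matrix: pd.DataFrame


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


_SLOT = 110  # exclusive genomic slot per probe; footprint sits centrally

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> Fixture:
    """Generate the full fixture into ``out_dir`` (created if needed)."""
    planted = config.planted_counts()
    if sum(planted.values()) > config.n_probes:
        raise ValueError("planted category counts exceed n_probes")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    L = config.chrom_len
    probe_zone = (1_000, int(0.70 * L))
    decoy_zone = (int(0.72 * L), int(0.85 * L))
    background_zone = (int(0.87 * L), L - 200)

    n_slots_per_chrom = (probe_zone[1] - probe_zone[0]) // _SLOT
    if n_slots_per_chrom * config.n_chrom < config.n_probes:
        raise ValueError(
            f"genome too small: {n_slots_per_chrom * config.n_chrom} probe slots < {config.n_probes} probes"
        )

    rng_genome = _rng(config.seed, "genome")
    genome_arr = {c: _BASES[rng_genome.integers(0, 4, size=L)].copy() for c in chroms}

    # --- assign slots, chemistries, strands, categories -------------------
    rng_probe = _rng(config.seed, "probes")
    labels = []
    for cat, n in planted.items():
        labels.extend([cat] * n)
    labels.extend(["clean"] * (config.n_probes - len(labels)))
    labels = list(np.array(labels, dtype=object)[rng_probe.permutation(config.n_probes)])
    design = np.where(rng_probe.random(config.n_probes) < config.typeII_fraction, "II", "I")
    strands = np.where(rng_probe.random(config.n_probes) < 0.5, "+", "-")

    probe_meta = []  # (probe_id, chrom, c0, design, strand, category)
    for i in range(config.n_probes):
        chrom = chroms[i % config.n_chrom]
        slot = i // config.n_chrom
        c0 = probe_zone[0] + slot * _SLOT + 55  # 0-based forward C position
        pid = f"cg{i:08d}"
        probe_meta.append((pid, chrom, c0, str(design[i]), str(strands[i]), labels[i]))

    # --- genome surgery before sequence extraction ------------------------
    variants_rows = []  # (chrom, pos1, ref, alt, vtype, avg_het)
    repeat_rows = []  # (chrom, start, end, family)
    rng_var = _rng(config.seed, "variants")

    def _het() -> float | None:
        if rng_var.random() < config.het_missing_fraction:
            return None
        return float(np.round(rng_var.uniform(0.0, 0.5), 4))

    truth_rows = []
    for pid, chrom, c0, dt, strand, cat in probe_meta:
        arr = genome_arr[chrom]
        arr[c0] = ord("C")
        arr[c0 + 1] = ord("G")
        probe_stub = ProbeRecord(pid, dt, chrom, c0 + 1, strand, "A" * 50)
        fp = probe_footprint(probe_stub)
        body_anchor = fp.start + 20  # safely inside every footprint geometry, off the CpG
        t = {
            "probe_id": pid, "chrom": chrom, "cpg_pos": c0 + 1, "design_type": dt,
            "strand": strand, "category": cat, "multimap": cat == "multimap",
            "repeat": cat == "repeat", "indel": cat == "indel",
            "snp_at_cpg_c": cat == "cpg_snp_c", "snp_at_cpg_g": cat == "cpg_snp_g",
            "body_snps_total": 0, "body_snps_bisokay": 0, "genotype": "",
        }
        if cat == "bisokay_only":
            p = body_anchor
            arr[p] = ord("C")
            arr[p + 1] = ord("A")  # downstream non-G: the C/T SNP is bisulfite-okay
            variants_rows.append((chrom, p + 1, "C", "T", "SNP", _het()))
            t["body_snps_total"], t["body_snps_bisokay"] = 1, 1
        elif cat in ("body_snp1", "body_snp2"):
            offs = (15, 30) if cat == "body_snp2" else (20,)
            for off in offs:
                p = fp.start + off
                ref = chr(arr[p])
                alt = "A" if ref == "G" else "G"  # never a C<->T pair: not bisulfite-okay
                variants_rows.append((chrom, p + 1, ref, alt, "SNP", _het()))
            t["body_snps_total"] = len(offs)
        elif cat == "cpg_snp_c":
            variants_rows.append((chrom, c0 + 1, "C", "A", "SNP", _het()))
        elif cat == "cpg_snp_g":
            variants_rows.append((chrom, c0 + 2, "G", "A", "SNP", _het()))
        elif cat == "indel":
            p = body_anchor
            ref = "".join(chr(b) for b in arr[p : p + 4])
            variants_rows.append((chrom, p + 1, ref, ref[0], "INDEL", _het()))
        elif cat == "repeat":
            repeat_rows.append((chrom, fp.start + 10, fp.start + 35, "SYN_repeat"))
        truth_rows.append(t)

    # background clutter away from every footprint
    rng_bg = _rng(config.seed, "background")
    for chrom in chroms:
        arr = genome_arr[chrom]
        for _ in range(40):
            p = int(rng_bg.integers(background_zone[0], background_zone[1]))
            ref = chr(arr[p])
            alt = rng_bg.choice([b for b in "ACGT" if b != ref])
            variants_rows.append((chrom, p + 1, ref, str(alt), "SNP", _het()))
        for _ in range(10):
            p = int(rng_bg.integers(background_zone[0], background_zone[1]))
            ref = "".join(chr(b) for b in arr[p : p + 3])
            variants_rows.append((chrom, p + 1, ref, ref[0], "INDEL", None))
            s = int(rng_bg.integers(background_zone[0], background_zone[1] - 120))
            repeat_rows.append((chrom, s, s + 100, "SYN_background"))

    # --- extract probe sequences (after surgery), plant multimap decoys ----
    genome = {c: genome_arr[c].tobytes().decode("ascii") for c in chroms}
    probes: list[ProbeRecord] = []
    decoy_cursor = {c: decoy_zone[0] for c in chroms}
    for (pid, chrom, c0, dt, strand, cat), t in zip(probe_meta, truth_rows):
        stub = ProbeRecord(pid, dt, chrom, c0 + 1, strand, "A" * 50)
        fp = probe_footprint(stub)
        seq = genome[chrom][fp.start : fp.end]
        if cat == "multimap":
            dest_chrom = chrom
            dest = decoy_cursor[dest_chrom]
            if dest + 50 > decoy_zone[1]:
                raise ValueError("decoy zone exhausted; reduce n_multimap or grow chrom_len")
            genome_arr[dest_chrom][dest : dest + 50] = np.frombuffer(seq.encode(), dtype=np.uint8)
            decoy_cursor[dest_chrom] = dest + 60
        if strand == "-":
            seq = revcomp(seq)
        if dt == "II":
            # degenerate purine readout at the G of each internal CpG
            s = list(seq)
            for i in range(len(s) - 1):
                if s[i] == "C" and s[i + 1] == "G":
                    s[i + 1] = "R"
            seq = "".join(s)
        probes.append(ProbeRecord(pid, dt, chrom, c0 + 1, strand, seq, source_seq=None))
    # decoys were written after sequence extraction: rebuild the genome text
    genome = {c: genome_arr[c].tobytes().decode("ascii") for c in chroms}

    # --- genotypes at CpG-site SNPs ---------------------------------------
    rng_gt = _rng(config.seed, "genotypes")
    genotypes: dict[tuple[str, int], str] = {}
    for t in truth_rows:
        if t["category"] in ("cpg_snp_c", "cpg_snp_g"):
            call = str(rng_gt.choice(["hom_ref", "het", "hom_alt"], p=[0.25, 0.5, 0.25]))
            pos = t["cpg_pos"] if t["category"] == "cpg_snp_c" else t["cpg_pos"] + 1
            genotypes[(t["chrom"], pos)] = call
            t["genotype"] = call

    # --- methylation truth, WGBS and array betas ---------------------------
    rng_beta = _rng(config.seed, "betas")
    rng_wgbs = _rng(config.seed, "wgbs")
    rng_array = _rng(config.seed, "array")
    n = config.n_probes
    true_beta = rng_beta.beta(0.3, 0.3, size=n)
    coverage = rng_wgbs.poisson(config.coverage_mean, size=n)
    meth = rng_wgbs.binomial(coverage, true_beta)
    score = np.where(coverage > 0, np.rint(100.0 * meth / np.maximum(coverage, 1)), 0).astype(int)

    centers = np.empty(n)
    sds = np.empty(n)
    for i, t in enumerate(truth_rows):
        cat = t["category"]
        sds[i] = config.background_sd + float(config.extra_sd.get(cat, 0.0))
        tb = true_beta[i]
        if cat == "unknown":
            centers[i] = tb + config.unknown_offset if tb < 0.5 else tb - config.unknown_offset
        elif cat in ("cpg_snp_c", "cpg_snp_g"):
            call = t["genotype"]
            if call == "hom_alt":
                centers[i] = config.cpg_snp_homalt_beta
            elif call == "het":
                centers[i] = 0.5 * tb
            else:
                centers[i] = tb
        else:
            centers[i] = tb
    betas = np.clip(
        centers[:, None] + rng_array.normal(0.0, 1.0, size=(n, config.n_samples)) * sds[:, None],
        0.0, 1.0,
    )
    betas = np.round(betas, 6)  # written at 6 decimals; keep memory == file
    sample_ids = [f"sample_{j + 1:02d}" for j in range(config.n_samples)]
    beta_matrix = pd.DataFrame(betas, index=[t["probe_id"] for t in truth_rows], columns=sample_ids)
    beta_matrix.index.name = "probe_id"

    # expected unknown-factor flag, evaluated exactly as the pipeline does
    # (reference sample = sample_01, WGBS beta = score/100, coverage >= 5)
    wgbs_beta = score / 100.0
    evaluable = coverage >= 5
    abs_diff = np.abs(betas[:, 0] - wgbs_beta)
    for i, t in enumerate(truth_rows):
        t["true_beta"] = float(np.round(true_beta[i], 6))
        t["wgbs_coverage"] = int(coverage[i])
        t["wgbs_score"] = int(score[i])
        t["unknown_factor"] = bool(abs_diff[i] > 0.3) if evaluable[i] else None

    truth = pd.DataFrame(truth_rows).set_index("probe_id")
    truth["expected_verdict"] = [
        expected_verdict_from_labels(row) for _, row in truth.iterrows()
    ]

    # --- write everything --------------------------------------------------
    paths = {
        "genome": out_dir / "genome.fa",
        "manifest": out_dir / "manifest.csv",
        "variants": out_dir / "variants.vcf",
        "repeats": out_dir / "repeats.bed",
        "wgbs": out_dir / "wgbs.bedgraph",
        "betas": out_dir / "betas.csv",
        "truth": out_dir / "truth.tsv",
        "genotypes": out_dir / "genotypes.tsv",
    }
    _write_fasta(genome, paths["genome"])
    write_manifest(probes, paths["manifest"])
    _write_vcf(sorted(variants_rows, key=lambda r: (r[0], r[1], r[3])), chroms, L, paths["variants"])
    with paths["repeats"].open("w") as fh:
        for chrom, s, e, fam in sorted(repeat_rows):
            fh.write(f"{chrom}\t{s}\t{e}\t{fam}\t0\t+\n")
    with paths["wgbs"].open("w") as fh:
        rows = sorted(
            (t["chrom"], t["cpg_pos"] - 1, t["cpg_pos"], t["wgbs_score"], t["wgbs_coverage"])
            for t in truth_rows
        )
        for chrom, s, e, sc, cov in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{sc}\t{cov}\n")
    beta_matrix.to_csv(paths["betas"], float_format="%.6f")
    truth.to_csv(paths["truth"], sep="\t")
    with paths["genotypes"].open("w") as fh:
        fh.write("chrom\tpos\tcall\n")
        for (chrom, pos), call in sorted(genotypes.items()):
            fh.write(f"{chrom}\t{pos}\t{call}\n")

    return Fixture(
        config=config, paths=paths, genome=genome, probes=probes,
        truth=truth, genotypes=genotypes, beta_matrix=beta_matrix,
    )


def _truthy(value) -> bool:
    """Interpret a ground-truth flag whether in memory (bool/None) or re-read
    from truth.tsv (the strings "True"/"False"/"")."""
    if isinstance(value, str):
        return value == "True"
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return bool(value)


def expected_verdict_from_labels(row) -> str:
    """Default-config verdict restated directly from ground-truth labels.

    Independent of the filter engine: discard iff multimap, repeat, a SNP at
    either CpG position, a non-bis-okay body SNP on a type I probe, or the
    unknown-factor flag. INDELs and type II body SNPs are kept by default.
    """
    effective = int(row["body_snps_total"]) - int(row["body_snps_bisokay"])
    discard = (
        _truthy(row["multimap"])
        or _truthy(row["repeat"])
        or _truthy(row["snp_at_cpg_c"])
        or _truthy(row["snp_at_cpg_g"])
        or (row["design_type"] == "I" and effective > 0)
        or _truthy(row["unknown_factor"])
    )
    return "discard" if discard else "keep"


def expected_decisions(truth: pd.DataFrame, config: FilterConfig = FilterConfig()) -> dict[str, str]:
    """Verdict per probe computed from ground-truth labels alone.

    A deliberate restatement of the filtering rules with no shared code with
    the filter engine, used as its independent oracle.
    """
    out: dict[str, str] = {}
    for pid, row in truth.iterrows():
        total = int(row["body_snps_total"])
        bisokay = int(row["body_snps_bisokay"])
        effective = (total - bisokay) if config.bisokay_rescue else total
        unknown = _truthy(row["unknown_factor"])
        discard = (
            (config.drop_multimap and _truthy(row["multimap"]))
            or (config.drop_repeat and _truthy(row["repeat"]))
            or (config.drop_indel and _truthy(row["indel"]))
            or (config.drop_snp_at_cpg and (_truthy(row["snp_at_cpg_c"]) or _truthy(row["snp_at_cpg_g"])))
            or (row["design_type"] == "I" and config.drop_typeI_body_snp and effective > 0)
            or (row["design_type"] == "II" and config.drop_typeII_body_snp and effective > 0)
            or (config.drop_unknown and unknown)
        )
        out[str(pid)] = "discard" if discard else "keep"
    return out


def simulate_paired_betas(
    n: int,
    array_sd: float,
    seed: int,
    coverage_mean: float = 30.0,
    array_bias: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (beta_array, beta_wgbs) for n probes under the fixture noise model.

    Used for power/null studies without building file fixtures: true betas ~
    Beta(0.3, 0.3); WGBS is a binomial read draw at Poisson coverage; array is
    a clamped Gaussian around the true beta (plus an optional systematic bias).
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(b"simulate_paired_betas")])
    true = rng.beta(0.3, 0.3, size=n)
    cov = np.maximum(rng.poisson(coverage_mean, size=n), 1)
    wgbs = np.rint(100.0 * rng.binomial(cov, true) / cov) / 100.0
    arr = np.clip(true + array_bias + rng.normal(0.0, array_sd, size=n), 0.0, 1.0)
    return arr, wgbs


def _write_fasta(genome: Mapping[str, str], path: Path, width: int = 70) -> None:
    with path.open("w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_vcf(rows, chroms, chrom_len: int, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom},length={chrom_len}>\n")
        fh.write('##INFO=<ID=AVGHET,Number=1,Type=Float,Description="Average heterozygosity">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, (chrom, pos, ref, alt, _vtype, het) in enumerate(rows):
            info = f"AVGHET={het:.4f}" if het is not None else "."
            fh.write(f"{chrom}\t{pos}\trs{i:07d}\t{ref}\t{alt}\t.\tPASS\t{info}\n")
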