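"""Genomic-factor annotation of probe footprints.

Flags each probe for overlap with repeats and INDELs, assigns SNPs to
probe-relative offsets, classifies SNPs at the interrogated CpG dinucleotide,
applies the bisulfite-space rescue rule (a C<->T SNP whose downstream base is
not G is invisible after conversion), stratifies SNP-affected probes by
population average heterozygosity, and summarizes |array beta - WGBS beta|
by SNP offset.

Offsets are 0-based from the interrogated C, strand-oriented so positive
points into the probe body: offset 0 is the C itself (forward ``cpg_pos`` for
'+' probes, ``cpg_pos + 1`` for '-' probes), offset 1 the paired G. Body SNPs
are footprint SNPs away from the two CpG dinucleotide positions.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .manifest_io import GenomicInterval, ProbeRecord, fetch_sequence, probe_footprint

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "RepeatInterval",
    "ProbeFlags",
    "load_variants_vcf",
    "load_variants_tsv",
    "load_repeats_bed",
    "overlap_repeats",
    "overlap_indels",
    "assign_snps",
    "classify_cpg_snps",
    "is_bisulfite_okay",
    "effective_body_snp_count",
    "annotate_probes",
    "heterozygosity_strata",
    "snp_offset_profile",
    "DEFAULT_HET_BINS",
]

DEFAULT_HET_BINS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant; multi-allelic rows are split before construction."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str  # "SNP" or "INDEL"
    avg_het: float | None = None

    def __post_init__(self) -> None:
        if self.vtype == "SNP":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError(f"SNP at {self.chrom}:{self.pos} must have 1-bp alleles")
        elif self.vtype == "INDEL":
            if len(self.ref) == len(self.alt):
                raise ValueError(f"INDEL at {self.chrom}:{self.pos} must change length")
        else:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.avg_het is not None and not (0.0 <= self.avg_het <= 0.5):
            raise ValueError(f"avg_het must be in [0, 0.5], got {self.avg_het}")

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span [pos-1, pos-1+len(ref))."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


@dataclass(frozen=True)
class RepeatInterval:
    """RepeatMasker-style repeat, 0-based half-open."""

    chrom: str
    start: int
    end: int
    family: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty repeat interval [{self.start}, {self.end})")


@dataclass
class ProbeFlags:
    """Per-probe annotation of every genomic factor.

    ``unknown_factor`` is True/False once a WGBS pairing has been evaluated and
    None ("unevaluable") otherwise. ``design_type`` is denormalized here so the
    accounting layer does not need the manifest.
    """

    probe_id: str
    design_type: str = "II"
    multimap: bool = False
    repeat: bool = False
    indel: bool = False
    snp_at_cpg_c: bool = False
    snp_at_cpg_g: bool = False
    body_snps_total: int = 0
    body_snps_bisokay: int = 0
    max_avg_het: float | None = None
    unknown_factor: bool | None = None
    unevaluable: bool = False  # genome/track did not cover this probe's chromosome

    @property
    def body_snps_effective(self) -> int:
        return self.body_snps_total - self.body_snps_bisokay

    @property
    def any_snp(self) -> bool:
        return self.snp_at_cpg_c or self.snp_at_cpg_g or self.body_snps_total > 0

    def factor_flags(self) -> dict[str, bool]:
        """The genomic factors of the any-overlap summary (unknown excluded)."""
        return {
            "multimap": self.multimap,
            "repeat": self.repeat,
            "indel": self.indel,
            "snp_at_cpg": self.snp_at_cpg_c or self.snp_at_cpg_g,
            "body_snp": self.body_snps_total > 0,
        }

    @property
    def is_high_quality(self) -> bool:
        """No genomic factor and not unknown-flagged (unevaluable counts as clean)."""
        return not any(self.factor_flags().values()) and self.unknown_factor is not True


# ---------------------------------------------------------------------------
# track loading


def load_variants_vcf(path: str | Path, het_info_key: str = "AVGHET") -> list[VariantRecord]:
    """Read SNPs/INDELs from a VCF; multi-allelic rows are split biallelic."""
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            het = rec.info.get(het_info_key) if het_info_key in rec.info else None
            if isinstance(het, tuple):
                het = het[0]
            for alt in rec.alts or ():
                vtype = "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "INDEL"
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=str(alt).upper(),
                        vtype=vtype,
                        avg_het=float(het) if het is not None else None,
                    )
                )
    return out


def load_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a 6-column variant table: chrom, pos(1-based), ref, alt, type, avg_het."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "ref", "alt", "vtype", "avg_het"])
    out = []
    for row in df.itertuples(index=False):
        het = None if pd.isna(row.avg_het) or row.avg_het == "." else float(row.avg_het)
        out.append(VariantRecord(str(row.chrom), int(row.pos), str(row.ref).upper(),
                                 str(row.alt).upper(), str(row.vtype).upper(), het))
    return out


def load_repeats_bed(path: str | Path) -> list[RepeatInterval]:
    """Read a BED(6) repeat track; only chrom/start/end/name are used."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    out = []
    for row in df.itertuples(index=False):
        family = str(row[3]) if len(row) > 3 else "."
        out.append(RepeatInterval(str(row[0]), int(row[1]), int(row[2]), family))
    return out


# ---------------------------------------------------------------------------
# interval overlap (sorted-array bisection; adequate at annotation scale)


class _IntervalIndex:
    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            self._starts[chrom] = np.array([s for s, _ in ivs], dtype=np.int64)
            # running max of ends supports overlap queries on overlapping intervals
            self._ends[chrom] = np.maximum.accumulate(np.array([e for _, e in ivs], dtype=np.int64))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._starts:
            return False
        starts, ends = self._starts[chrom], self._ends[chrom]
        i = int(np.searchsorted(starts, end, side="left"))  # intervals with s < end
        if i == 0:
            return False
        return bool(ends[i - 1] > start)


def overlap_repeats(
    probes: Sequence[ProbeRecord],
    repeats: Sequence[RepeatInterval],
    convention: str = "illumina",
) -> dict[str, bool]:
    """True iff the probe footprint shares >= 1 base with any repeat interval."""
    idx = _IntervalIndex((r.chrom, r.start, r.end) for r in repeats)
    known_chroms = {r.chrom for r in repeats}
    flags: dict[str, bool] = {}
    missing: set[str] = set()
    for probe in probes:
        fp = probe_footprint(probe, convention)
        if probe.chrom not in known_chroms:
            missing.add(probe.chrom)
        flags[probe.probe_id] = idx.overlaps(fp.chrom, fp.start, fp.end)
    if missing:
        logger.info("repeat track has no intervals on chromosome(s): %s", sorted(missing))
    return flags


def overlap_indels(
    probes: Sequence[ProbeRecord],
    variants: Sequence[VariantRecord],
    convention: str = "illumina",
) -> dict[str, bool]:
    """True iff any INDEL's reference span intersects the probe footprint."""
    indels = [v for v in variants if v.vtype == "INDEL"]
    idx = _IntervalIndex((v.chrom, *v.span) for v in indels)
    return {
        p.probe_id: idx.overlaps(p.chrom, *(lambda fp: (fp.start, fp.end))(probe_footprint(p, convention)))
        for p in probes
    }


# ---------------------------------------------------------------------------
# SNP assignment and classification


def _cpg_positions(probe: ProbeRecord) -> tuple[int, int]:
    """0-based forward positions of the CpG (C, G)."""
    c = probe.cpg_pos - 1
    return c, c + 1


def _offset(probe: ProbeRecord, pos0: int) -> int:
    """Strand-oriented 0-based offset of a forward position from the interrogated C."""
    c, g = _cpg_positions(probe)
    return pos0 - c if probe.strand == "+" else g - pos0


def assign_snps(
    probe: ProbeRecord,
    variants: Sequence[VariantRecord],
    convention: str = "illumina",
) -> list[tuple[VariantRecord, int]]:
    """All SNPs inside the probe footprint with their strand-oriented offsets."""
    fp = probe_footprint(probe, convention)
    out = []
    for v in variants:
        if v.vtype != "SNP" or v.chrom != probe.chrom:
            continue
        pos0 = v.pos - 1
        if fp.start <= pos0 < fp.end:
            out.append((v, _offset(probe, pos0)))
    out.sort(key=lambda t: (t[1], t[0].pos, t[0].alt))
    return out


def classify_cpg_snps(
    probe: ProbeRecord,
    snps: Sequence[tuple[VariantRecord, int]],
) -> tuple[bool, bool]:
    """(snp_at_cpg_c, snp_at_cpg_g) from assigned SNPs.

    The flags refer to the two forward dinucleotide positions ``cpg_pos`` and
    ``cpg_pos + 1`` only; SNPs there may sit outside the footprint (type II),
    so classification is by genomic position, not offset.
    """
    c, g = _cpg_positions(probe)
    at_c = any(v.pos - 1 == c for v, _ in snps)
    at_g = any(v.pos - 1 == g for v, _ in snps)
    return at_c, at_g


def is_bisulfite_okay(variant: VariantRecord, genome) -> bool:
    """Is a SNP invisible in bisulfite space?

    True iff the allele set is exactly {C, T} (forward-normalized) and the
    genomic base immediately 3' of the site is not G: such a site reads as T
    after conversion whichever allele is present. At a chromosome end the
    downstream base is undefined and the SNP is conservatively not okay.
    """
    if variant.vtype != "SNP":
        raise ValueError("is_bisulfite_okay applies to SNPs only")
    if {variant.ref, variant.alt} != {"C", "T"}:
        return False
    pos0 = variant.pos - 1
    try:
        downstream = fetch_sequence(genome, variant.chrom, pos0 + 1, pos0 + 2)
    except (KeyError, IndexError):
        downstream = ""
    if len(downstream) != 1:
        logger.warning("variant %s:%d at chromosome end; downstream base undefined", variant.chrom, variant.pos)
        return False
    return downstream != "G"


def effective_body_snp_count(
    probe: ProbeRecord,
    snps: Sequence[tuple[VariantRecord, int]],
    genome,
) -> tuple[int, int, int]:
    """(total, bisokay, effective) over body SNPs.

    Body SNPs are footprint SNPs away from the two CpG dinucleotide positions;
    effective = total - bisokay.
    """
    c, g = _cpg_positions(probe)
    body = [v for v, _ in snps if v.pos - 1 not in (c, g)]
    total = len(body)
    bisokay = sum(1 for v in body if is_bisulfite_okay(v, genome))
    return total, bisokay, total - bisokay


# ---------------------------------------------------------------------------
# full annotation


def annotate_probes(
    probes: Sequence[ProbeRecord],
    genome,
    variants: Sequence[VariantRecord] = (),
    repeats: Sequence[RepeatInterval] = (),
    multimapped: Iterable[str] = (),
    convention: str = "illumina",
) -> dict[str, ProbeFlags]:
    """Combine every genomic-factor annotation into per-probe ProbeFlags.

    ``multimapped`` comes from :func:`probeqc.bisulfite_mapping.flag_multimappers`.
    Probes on chromosomes absent from the genome are carried through with
    genome-dependent fields unevaluable rather than dropped.
    """
    multimapped = set(multimapped)
    genome_chroms = set(genome.keys())
    repeat_flags = overlap_repeats(probes, repeats, convention)
    indel_flags = overlap_indels(probes, variants, convention)
    snps_by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.vtype == "SNP":
            snps_by_chrom.setdefault(v.chrom, []).append(v)
    for lst in snps_by_chrom.values():
        lst.sort(key=lambda v: v.pos)
    indels = [v for v in variants if v.vtype == "INDEL"]

    out: dict[str, ProbeFlags] = {}
    for probe in sorted(probes, key=lambda p: p.probe_id):
        flags = ProbeFlags(probe_id=probe.probe_id, design_type=probe.design_type)
        flags.multimap = probe.probe_id in multimapped
        flags.repeat = repeat_flags[probe.probe_id]
        flags.indel = indel_flags[probe.probe_id]
        if probe.chrom not in genome_chroms:
            flags.unevaluable = True
            out[probe.probe_id] = flags
            continue
        chrom_snps = snps_by_chrom.get(probe.chrom, [])
        fp = probe_footprint(probe, convention)
        pos_list = [v.pos for v in chrom_snps]
        lo = bisect_left(pos_list, fp.start + 1)  # 1-based positions inside [start, end)
        hi = bisect_right(pos_list, fp.end)
        window = chrom_snps[lo:hi]
        snps = assign_snps(probe, window, convention)
        c, g = _cpg_positions(probe)
        # CpG-site SNPs may fall outside a type II footprint; look them up directly.
        cpg_snps = [(v, _offset(probe, v.pos - 1)) for v in chrom_snps if v.pos - 1 in (c, g)]
        seen = {id(v) for v, _ in snps}
        snps = snps + [sv for sv in cpg_snps if id(sv[0]) not in seen]
        flags.snp_at_cpg_c, flags.snp_at_cpg_g = classify_cpg_snps(probe, snps)
        total, bisokay, _eff = effective_body_snp_count(probe, snps, genome)
        flags.body_snps_total = total
        flags.body_snps_bisokay = bisokay
        # An INDEL spanning the CpG dinucleotide disrupts the interrogated site too.
        for v in indels:
            if v.chrom != probe.chrom:
                continue
            s, e = v.span
            if s <= c < e:
                flags.snp_at_cpg_c = True
            if s <= g < e:
                flags.snp_at_cpg_g = True
        hets = [v.avg_het for v, _ in snps if v.avg_het is not None]
        flags.max_avg_het = max(hets) if hets else None
        out[probe.probe_id] = flags
    return out


def apply_unknown_flags(
    flags: Mapping[str, ProbeFlags],
    flagged_ids: Iterable[str],
    evaluable_ids: Iterable[str],
) -> None:
    """Fill the WGBS unknown-factor flag in place.

    ``evaluable_ids`` are probes with a surviving WGBS pairing; probes outside
    that set keep ``unknown_factor = None`` (unevaluable, never fires).
    """
    flagged = set(flagged_ids)
    for pid in evaluable_ids:
        if pid in flags:
            flags[pid].unknown_factor = pid in flagged


__all__.append("apply_unknown_flags")


_FLAGS_COLUMNS = (
    "probe_id", "design_type", "multimap", "repeat", "indel", "snp_at_cpg_c",
    "snp_at_cpg_g", "body_snps_total", "body_snps_bisokay", "max_avg_het",
    "unknown_factor", "unevaluable",
)


def write_flags(flags: Mapping[str, ProbeFlags], path: str | Path) -> None:
    """CSV export of per-probe flags (the annotate stage's artifact)."""
    import csv

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FLAGS_COLUMNS)
        for pid in sorted(flags):
            f = flags[pid]
            writer.writerow([
                pid, f.design_type, int(f.multimap), int(f.repeat), int(f.indel),
                int(f.snp_at_cpg_c), int(f.snp_at_cpg_g), f.body_snps_total,
                f.body_snps_bisokay,
                "" if f.max_avg_het is None else repr(f.max_avg_het),
                "" if f.unknown_factor is None else int(f.unknown_factor),
                int(f.unevaluable),
            ])


def read_flags(path: str | Path) -> dict[str, ProbeFlags]:
    """Inverse of :func:`write_flags`."""
    import csv

    out: dict[str, ProbeFlags] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != _FLAGS_COLUMNS:
            raise ValueError(f"{path}: unexpected flags header")
        for row in reader:
            out[row["probe_id"]] = ProbeFlags(
                probe_id=row["probe_id"],
                design_type=row["design_type"],
                multimap=bool(int(row["multimap"])),
                repeat=bool(int(row["repeat"])),
                indel=bool(int(row["indel"])),
                snp_at_cpg_c=bool(int(row["snp_at_cpg_c"])),
                snp_at_cpg_g=bool(int(row["snp_at_cpg_g"])),
                body_snps_total=int(row["body_snps_total"]),
                body_snps_bisokay=int(row["body_snps_bisokay"]),
                max_avg_het=float(row["max_avg_het"]) if row["max_avg_het"] else None,
                unknown_factor=bool(int(row["unknown_factor"])) if row["unknown_factor"] != "" else None,
                unevaluable=bool(int(row["unevaluable"])),
            )
    return out


__all__.extend(["write_flags", "read_flags"])


def heterozygosity_strata(
    flags: Mapping[str, ProbeFlags],
    bin_edges: Sequence[float] = DEFAULT_HET_BINS,
) -> dict[str, set[str]]:
    """Partition SNP-affected probes by their maximum average heterozygosity.

    Strata are [e_i, e_{i+1}) with the last bin closed; probes whose SNPs all
    lack avg_het go to the "unknown" stratum. Strata partition the input.
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(edges) < 2:
        raise ValueError("bin_edges must be sorted with at least two edges")
    labels = [f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])]
    labels[-1] = f"[{edges[-2]:g},{edges[-1]:g}]"
    strata: dict[str, set[str]] = {lab: set() for lab in labels}
    strata["unknown"] = set()
    for pid, f in flags.items():
        if not f.any_snp:
            continue
        if f.max_avg_het is None:
            strata["unknown"].add(pid)
            continue
        i = min(bisect_right(edges, f.max_avg_het) - 1, len(labels) - 1)
        i = max(i, 0)
        strata[labels[i]].add(pid)
    return strata


def snp_offset_profile(
    probes: Sequence[ProbeRecord],
    variants: Sequence[VariantRecord],
    paired_abs_diff: Mapping[str, float],
    bins: Sequence[int] | None = None,
    convention: str = "illumina",
) -> pd.DataFrame:
    """n and median |delta beta| of probes by nearest-body-SNP offset bin.

    Default bins are the singleton offsets 1..50. Only probes present in
    ``paired_abs_diff`` (i.e. with a WGBS pairing) contribute.
    """
    rows: dict[int, list[float]] = {}
    for probe in probes:
        if probe.probe_id not in paired_abs_diff:
            continue
        snps = assign_snps(probe, variants, convention)
        c, g = _cpg_positions(probe)
        offsets = [off for v, off in snps if v.pos - 1 not in (c, g)]
        if not offsets:
            continue
        nearest = min(offsets, key=abs)
        rows.setdefault(nearest, []).append(paired_abs_diff[probe.probe_id])
    if bins is None:
        bins = sorted(rows)
    records = [
        {"offset": b, "n": len(rows.get(b, [])),
         "median_abs_diff": float(np.median(rows[b])) if rows.get(b) else np.nan}
        for b in bins
    ]
    return pd.DataFrame.from_records(records, columns=["offset", "n", "median_abs_diff"])
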