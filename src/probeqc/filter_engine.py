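"""Keep/discard decision workflow, rescues, and filtering accountancy.

The decision workflow walks each probe's genomic-factor flags in a fixed
order (multimap, repeat, INDEL, SNP at the interrogated CpG, body SNPs,
unknown factor) and accumulates reason codes for every enabled factor the
probe carries; the verdict is discard iff any reason fired. Reason codes
accumulate rather than short-circuiting because the unique-category
accounting (Table-3 style, with its "multiple factors" row) needs the full
flag set.

Default rescues: bisulfite-okay body SNPs never count; type II probes
tolerate body SNPs; INDEL-bearing probes are kept. Presets adjust these for
population studies (drop INDELs), genetically homogeneous cell lines (keep
CpG-site SNP probes) and a conservative mode (drop everything, no bis-okay
rescue).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .feature_annotation import ProbeFlags
from .manifest_io import ProbeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterDecision",
    "REASON_ORDER",
    "RESCUE_CLASSES",
    "apply_filter",
    "genotype_override",
    "summarize_any_overlap",
    "summarize_unique",
    "rescue_report",
    "region_removal_fractions",
    "accounting_summary",
    "audit_category_table",
    "export_annotations",
    "read_annotations",
]

# workflow order
REASON_ORDER = (
    "MULTIMAP",
    "REPEAT",
    "INDEL",
    "SNP_AT_CPG",
    "BODY_SNP_TYPE_I",
    "BODY_SNP_TYPE_II",
    "UNKNOWN_FACTOR",
    "GENOTYPE",
)

# rescue classes in precedence order
RESCUE_CLASSES = ("GENOTYPE", "BIS_OKAY", "TYPE_II_TOLERANT", "INDEL_TOLERANT", "CONFIG_TOLERANT")

PRESETS = ("default", "population", "cell_line", "conservative")


@dataclass(frozen=True)
class FilterConfig:
    """Which factors discard a probe, and the thresholds behind the flags."""

    drop_multimap: bool = True
    drop_repeat: bool = True
    drop_indel: bool = False
    drop_snp_at_cpg: bool = True
    drop_typeI_body_snp: bool = True
    drop_typeII_body_snp: bool = False
    drop_unknown: bool = True
    bisokay_rescue: bool = True
    unknown_threshold: float = 0.3
    min_wgbs_coverage: int = 5
    min_sd_report: float = 0.10
    preset: str = "default"

    def __post_init__(self) -> None:
        if not (0.0 <= self.unknown_threshold <= 1.0):
            raise ValueError("unknown_threshold must be in [0, 1]")
        if not (0.0 <= self.min_sd_report <= 1.0):
            raise ValueError("min_sd_report must be in [0, 1]")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_preset(cls, preset: str) -> "FilterConfig":
        base = cls(preset=preset if preset in PRESETS else preset)
        if preset == "default":
            return base
        if preset == "population":
            return replace(base, drop_indel=True)
        if preset == "cell_line":
            return replace(base, drop_snp_at_cpg=False)
        if preset == "conservative":
            return replace(
                base,
                drop_indel=True,
                drop_typeII_body_snp=True,
                bisokay_rescue=False,
            )
        raise ValueError(f"unknown preset {preset!r}")


@dataclass
class FilterDecision:
    """Verdict for one probe with ordered reason codes and an optional rescue."""

    probe_id: str
    verdict: str  # "keep" or "discard"
    reasons: list[str] = field(default_factory=list)
    rescued_by: str | None = None

    def __post_init__(self) -> None:
        if (self.verdict == "discard") != bool(self.reasons):
            raise ValueError(f"{self.probe_id}: discard iff reasons nonempty")


def _effective_body(f: ProbeFlags, config: FilterConfig) -> int:
    return f.body_snps_effective if config.bisokay_rescue else f.body_snps_total


def _decide(f: ProbeFlags, config: FilterConfig) -> FilterDecision:
    reasons: list[str] = []
    if config.drop_multimap and f.multimap:
        reasons.append("MULTIMAP")
    if config.drop_repeat and f.repeat:
        reasons.append("REPEAT")
    if config.drop_indel and f.indel:
        reasons.append("INDEL")
    if config.drop_snp_at_cpg and (f.snp_at_cpg_c or f.snp_at_cpg_g):
        reasons.append("SNP_AT_CPG")
    eff = _effective_body(f, config)
    if eff > 0:
        if f.design_type == "I" and config.drop_typeI_body_snp:
            reasons.append("BODY_SNP_TYPE_I")
        if f.design_type == "II" and config.drop_typeII_body_snp:
            reasons.append("BODY_SNP_TYPE_II")
    if config.drop_unknown and f.unknown_factor is True:
        reasons.append("UNKNOWN_FACTOR")
    verdict = "discard" if reasons else "keep"
    rescued = None
    if verdict == "keep":
        rescued = _rescue_class(f, config)
    return FilterDecision(f.probe_id, verdict, reasons, rescued)


def _rescue_class(f: ProbeFlags, config: FilterConfig) -> str | None:
    """Why a factor-flagged probe was nevertheless kept (None if unflagged)."""
    if not any(f.factor_flags().values()) and f.unknown_factor is not True:
        return None
    if config.bisokay_rescue and f.body_snps_total > 0 and f.body_snps_effective == 0 \
            and not (f.snp_at_cpg_c or f.snp_at_cpg_g):
        return "BIS_OKAY"
    if f.design_type == "II" and _effective_body(f, config) > 0 and not config.drop_typeII_body_snp:
        return "TYPE_II_TOLERANT"
    if f.indel and not config.drop_indel:
        return "INDEL_TOLERANT"
    return "CONFIG_TOLERANT"


def apply_filter(
    flags: Mapping[str, ProbeFlags],
    config: FilterConfig = FilterConfig(),
    probe_ids: Iterable[str] | None = None,
) -> dict[str, FilterDecision]:
    """Apply the decision workflow to every probe.

    ``probe_ids`` restricts and validates coverage: ids missing from
    ``flags`` raise with the offending list.
    """
    if probe_ids is not None:
        probe_ids = list(probe_ids)
        missing = [pid for pid in probe_ids if pid not in flags]
        if missing:
            raise KeyError(f"probes missing from flags: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    else:
        probe_ids = sorted(flags)
    return {pid: _decide(flags[pid], config) for pid in probe_ids}


def genotype_override(
    decisions: Mapping[str, FilterDecision],
    flags: Mapping[str, ProbeFlags],
    probes: Sequence[ProbeRecord],
    genotypes: Mapping[tuple[str, int], str],
) -> dict[str, FilterDecision]:
    """Adjust CpG-site-SNP verdicts with per-sample genotype calls.

    ``genotypes`` maps (chrom, 1-based pos) to one of "hom_ref", "het",
    "hom_alt". A CpG-SNP probe that is homozygous reference at both
    dinucleotide positions loses its SNP_AT_CPG reason (rescued, GENOTYPE);
    homozygous alternate at either position forces discard with reason
    GENOTYPE; heterozygous (or missing) calls leave the verdict unchanged.
    Positions without an annotated SNP count as reference.
    """
    valid = {"hom_ref", "het", "hom_alt"}
    bad = [g for g in set(genotypes.values()) if g not in valid]
    if bad:
        raise ValueError(f"unknown genotype call(s) {bad}; expected {sorted(valid)}")
    by_id = {p.probe_id: p for p in probes}
    annotated = {pid for pid, f in flags.items() if f.snp_at_cpg_c or f.snp_at_cpg_g}
    used_positions: set[tuple[str, int]] = set()
    out = dict(decisions)
    for pid in sorted(annotated):
        if pid not in decisions or pid not in by_id:
            continue
        probe = by_id[pid]
        f = flags[pid]
        c_pos = (probe.chrom, probe.cpg_pos)
        g_pos = (probe.chrom, probe.cpg_pos + 1)
        calls = []
        for pos_key, has_snp in ((c_pos, f.snp_at_cpg_c), (g_pos, f.snp_at_cpg_g)):
            if not has_snp:
                calls.append("hom_ref")  # no annotated SNP: reference
                continue
            call = genotypes.get(pos_key)
            if call is not None:
                used_positions.add(pos_key)
            calls.append(call)
        dec = decisions[pid]
        if "hom_alt" in calls:
            reasons = [r for r in dec.reasons if r != "GENOTYPE"] + ["GENOTYPE"]
            out[pid] = FilterDecision(pid, "discard", reasons, None)
        elif all(c == "hom_ref" for c in calls):
            reasons = [r for r in dec.reasons if r != "SNP_AT_CPG"]
            if reasons:
                out[pid] = FilterDecision(pid, "discard", reasons, None)
            else:
                out[pid] = FilterDecision(pid, "keep", [], "GENOTYPE")
        # het or missing call: unchanged
    ignored = set(genotypes) - used_positions
    if ignored:
        logger.warning("%d genotype call(s) at positions without an annotated CpG SNP; ignored", len(ignored))
    return out


# ---------------------------------------------------------------------------
# accountancy

_ANY_CATEGORIES = ("multimap", "repeat", "indel", "snp_at_cpg", "snp", "unknown")
_UNIQUE_FACTORS = ("multimap", "repeat", "indel", "snp_at_cpg", "body_snp", "unknown")


def _chem(f: ProbeFlags) -> str:
    return "type_i" if f.design_type == "I" else "type_ii"


def summarize_any_overlap(flags: Mapping[str, ProbeFlags]) -> pd.DataFrame:
    """Table-1-style any-overlap counts: a probe counts in every category it carries.

    Rows: each factor category plus total / high_quality / noisy; columns
    type_i, type_ii, total (= type_i + type_ii).
    """
    zero = {c: {"type_i": 0, "type_ii": 0} for c in _ANY_CATEGORIES + ("total", "high_quality", "noisy")}
    for f in flags.values():
        chem = _chem(f)
        zero["total"][chem] += 1
        cats = f.factor_flags()
        if cats["multimap"]:
            zero["multimap"][chem] += 1
        if cats["repeat"]:
            zero["repeat"][chem] += 1
        if cats["indel"]:
            zero["indel"][chem] += 1
        if cats["snp_at_cpg"]:
            zero["snp_at_cpg"][chem] += 1
        if f.any_snp:
            zero["snp"][chem] += 1
        if f.unknown_factor is True:
            zero["unknown"][chem] += 1
        if f.is_high_quality:
            zero["high_quality"][chem] += 1
        else:
            zero["noisy"][chem] += 1
    df = pd.DataFrame(zero).T
    df["total"] = df["type_i"] + df["type_ii"]
    return df


def summarize_unique(
    flags: Mapping[str, ProbeFlags],
    decisions: Mapping[str, FilterDecision],
) -> pd.DataFrame:
    """Table-3-style unique-category accounting.

    Probes with exactly one flagged factor are counted under that factor
    (body SNPs split into body_snp_1 / body_snp_2plus); probes with two or
    more factors under "multiple_factors". Kept columns reflect rescues.
    Identities: kept + discarded = total; kept = high_quality + rescued.
    """
    rows = ["multimap", "repeat", "indel", "snp_at_cpg", "body_snp_1", "body_snp_2plus",
            "unknown", "multiple_factors", "high_quality", "total"]
    data = {r: {"type_i": 0, "type_ii": 0, "kept_type_i": 0, "kept_type_ii": 0} for r in rows}
    for pid, f in flags.items():
        chem = _chem(f)
        kept = decisions[pid].verdict == "keep"
        factors = dict(f.factor_flags())
        if f.unknown_factor is True:
            factors["unknown"] = True
        active = [k for k, v in factors.items() if v]
        if not active:
            row = "high_quality"
        elif len(active) == 1:
            row = active[0]
            if row == "body_snp":
                row = "body_snp_1" if f.body_snps_total == 1 else "body_snp_2plus"
        else:
            row = "multiple_factors"
        data[row][chem] += 1
        data["total"][chem] += 1
        if kept:
            data[row][f"kept_{chem}"] += 1
            data["total"][f"kept_{chem}"] += 1
    df = pd.DataFrame(data).T
    df["total"] = df["type_i"] + df["type_ii"]
    df["kept_total"] = df["kept_type_i"] + df["kept_type_ii"]
    return df[["type_i", "type_ii", "total", "kept_type_i", "kept_type_ii", "kept_total"]]


def rescue_report(
    flags: Mapping[str, ProbeFlags],
    decisions: Mapping[str, FilterDecision],
) -> pd.DataFrame:
    """Counts of rescued probes (factor-flagged yet kept) by rescue class and chemistry."""
    data = {r: {"type_i": 0, "type_ii": 0} for r in RESCUE_CLASSES + ("total",)}
    for pid, dec in decisions.items():
        if dec.verdict != "keep" or dec.rescued_by is None:
            continue
        chem = _chem(flags[pid])
        data[dec.rescued_by][chem] += 1
        data["total"][chem] += 1
    df = pd.DataFrame(data).T
    df["total"] = df["type_i"] + df["type_ii"]
    return df


def accounting_summary(
    total: Mapping[str, int],
    high_quality: Mapping[str, int],
    rescued: Mapping[str, int],
) -> dict:
    """Headline accounting arithmetic from per-chemistry counts.

    Inputs are {"type_i": n, "type_ii": n} mappings. Returns noisy (= total -
    high_quality), kept (= high_quality + rescued), removed (= total - kept),
    and removal percentages, each with a grand total.
    """

    def _tot(m: Mapping[str, int]) -> dict[str, int]:
        return {"type_i": int(m["type_i"]), "type_ii": int(m["type_ii"]),
                "total": int(m["type_i"]) + int(m["type_ii"])}

    total_, hq, resc = _tot(total), _tot(high_quality), _tot(rescued)
    noisy = {k: total_[k] - hq[k] for k in total_}
    kept = {k: hq[k] + resc[k] for k in total_}
    removed = {k: total_[k] - kept[k] for k in total_}
    return {
        "total": total_,
        "high_quality": hq,
        "rescued": resc,
        "noisy": noisy,
        "kept": kept,
        "removed": removed,
        "removal_pct": round(100.0 * removed["total"] / total_["total"]) if total_["total"] else float("nan"),
        "aggressive_removal_pct": round(100.0 * noisy["total"] / total_["total"]) if total_["total"] else float("nan"),
    }


def audit_category_table(rows: Mapping[str, tuple[int, int, int]]) -> dict[str, dict]:
    """Check per-category rows (type_i, type_ii, printed_total) for consistency.

    Returns per-category computed sums with a ``consistent`` flag; printed
    totals that disagree with type_i + type_ii are reported, not corrected.
    """
    out = {}
    for name, (ti, tii, printed) in rows.items():
        computed = ti + tii
        if computed != printed:
            logger.warning("category %s: printed total %d != computed %d", name, printed, computed)
        out[name] = {"type_i": ti, "type_ii": tii, "computed_total": computed,
                     "printed_total": printed, "consistent": computed == printed}
    return out


def region_removal_fractions(
    probes: Sequence[ProbeRecord],
    decisions: Mapping[str, FilterDecision],
    regions: Sequence[tuple[str, int, int, str]],
) -> pd.DataFrame:
    """Removed/total probe fraction per labelled region.

    ``regions`` rows are (chrom, start, end, label) with 0-based half-open
    coordinates; a probe belongs to a region iff its interrogated C falls in
    it. Labels with zero probes report NaN (undefined), not 0.
    """
    labels = sorted({r[3] for r in regions})
    counts = {lab: {"n_total": 0, "n_removed": 0} for lab in labels}
    by_label: dict[str, list[tuple[str, int, int]]] = {lab: [] for lab in labels}
    for chrom, start, end, lab in regions:
        by_label[lab].append((chrom, start, end))
    for probe in probes:
        pos0 = probe.cpg_pos - 1
        dec = decisions.get(probe.probe_id)
        if dec is None:
            continue
        for lab in labels:
            if any(chrom == probe.chrom and s <= pos0 < e for chrom, s, e in by_label[lab]):
                counts[lab]["n_total"] += 1
                if dec.verdict == "discard":
                    counts[lab]["n_removed"] += 1
    records = []
    for lab in labels:
        n, r = counts[lab]["n_total"], counts[lab]["n_removed"]
        records.append({"label": lab, "n_total": n, "n_removed": r,
                        "fraction_removed": (r / n) if n else float("nan")})
    return pd.DataFrame.from_records(records).set_index("label")


# ---------------------------------------------------------------------------
# annotation export

_EXPORT_COLUMNS = (
    "probe_id", "design_type", "multimap", "repeat", "indel",
    "snp_at_cpg_c", "snp_at_cpg_g", "body_snps_total", "body_snps_bisokay",
    "body_snps_effective", "max_avg_het", "unknown_factor", "unevaluable",
    "verdict", "reasons", "rescued_by",
)


def export_annotations(
    flags: Mapping[str, ProbeFlags],
    decisions: Mapping[str, FilterDecision],
    path: str | Path,
) -> None:
    """One CSV row per probe with all flags, verdict, reasons and rescue.

    Deterministic (sorted by probe id) and lossless through
    :func:`read_annotations`.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_EXPORT_COLUMNS)
        for pid in sorted(flags):
            f = flags[pid]
            d = decisions[pid]
            writer.writerow([
                pid, f.design_type, int(f.multimap), int(f.repeat), int(f.indel),
                int(f.snp_at_cpg_c), int(f.snp_at_cpg_g), f.body_snps_total,
                f.body_snps_bisokay, f.body_snps_effective,
                "" if f.max_avg_het is None else repr(f.max_avg_het),
                "" if f.unknown_factor is None else int(f.unknown_factor),
                int(f.unevaluable), d.verdict, ";".join(d.reasons), d.rescued_by or "",
            ])


def read_annotations(path: str | Path) -> tuple[dict[str, ProbeFlags], dict[str, FilterDecision]]:
    """Inverse of :func:`export_annotations`."""
    flags: dict[str, ProbeFlags] = {}
    decisions: dict[str, FilterDecision] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != _EXPORT_COLUMNS:
            raise ValueError(f"{path}: unexpected annotation header")
        for row in reader:
            pid = row["probe_id"]
            flags[pid] = ProbeFlags(
                probe_id=pid,
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
            decisions[pid] = FilterDecision(
                probe_id=pid,
                verdict=row["verdict"],
                reasons=[r for r in row["reasons"].split(";") if r],
                rescued_by=row["rescued_by"] or None,
            )
    return flags, decisions
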