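"""Bisulfite-genome construction and probe uniqueness mapping.

Bisulfite treatment converts unmethylated C to T, so a hybridization probe is
matched against a reduced-complexity "bisulfite genome" in which every C has
been converted to T, on both strands. A probe whose bisulfite-space sequence
occurs at more than one genomic location is ambiguous (a multi-mapper) and is
flagged for removal; a probe with zero occurrences is reported as unmappable.

Match semantics (methylation-blind, strand-symmetric):

* probe ``C`` followed by ``G`` (or ``R``): CpG context, may be methylated ->
  matches ``{C, T}`` in the converted text;
* any other probe ``C``: matches ``{T}``;
* probe ``R`` (type II degenerate base): matches ``{A, G}``;
* ``A``/``G``/``T`` match themselves; genome ``N`` matches nothing.

Default matching is exact (``max_mismatch=0``): uniqueness, not alignment
sensitivity, is the product. A mismatch-tolerant scan is available for
sensitivity analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .manifest_io import ProbeRecord, revcomp

__all__ = [
    "BisulfiteGenome",
    "BisulfiteQuery",
    "HitReport",
    "MultimapResult",
    "bisulfite_convert",
    "bisulfite_convert_text",
    "convert_probe_to_bisulfite_space",
    "count_genomic_hits",
    "flag_multimappers",
    "write_hit_reports",
]

_C_TO_T = str.maketrans("C", "T")


def bisulfite_convert_text(seq: str) -> str:
    """Convert every C to T; all other letters (including N) pass through."""
    return seq.upper().translate(_C_TO_T)


@dataclass
class BisulfiteGenome:
    """Both fully converted strand texts of a genome.

    ``forward`` is C->T applied to the forward text; ``reverse`` is C->T
    applied to the reverse complement of the forward text. Neither contains C.
    """

    forward: dict[str, str]
    reverse: dict[str, str]
    source_id: str = ""

    def chroms(self) -> list[str]:
        return sorted(self.forward)

    def __len__(self) -> int:
        return sum(len(s) for s in self.forward.values())


def bisulfite_convert(genome: Mapping[str, object], source_id: str = "") -> BisulfiteGenome:
    """Build the two converted strand texts for every chromosome."""
    fwd: dict[str, str] = {}
    rev: dict[str, str] = {}
    for chrom in genome.keys():
        text = str(genome[chrom]).upper()
        fwd[chrom] = bisulfite_convert_text(text)
        rev[chrom] = bisulfite_convert_text(revcomp(text))
    return BisulfiteGenome(forward=fwd, reverse=rev, source_id=source_id)


@dataclass(frozen=True)
class BisulfiteQuery:
    """A probe rendered as per-position allowed-letter sets plus a regex.

    ``anchor``/``anchor_offset`` describe the longest wildcard-free run of the
    query, used as a fast literal prefilter during scanning.
    """

    allowed: tuple[frozenset[str], ...]
    pattern: str  # regex with one alternative character class per position
    anchor: str = ""
    anchor_offset: int = 0

    def __len__(self) -> int:
        return len(self.allowed)


def convert_probe_to_bisulfite_space(probe: ProbeRecord | str) -> BisulfiteQuery:
    """Render a probe sequence as a bisulfite-space wildcard query.

    Cs outside CpG context are fixed to T; CpG-context Cs become the {C,T}
    wildcard; R becomes the {A,G} wildcard.
    """
    seq = probe.probe_seq if isinstance(probe, ProbeRecord) else str(probe).upper()
    bad = set(seq) - set("ACGTR")
    if bad:
        raise ValueError(f"probe sequence has non-alphabet characters {sorted(bad)}")
    allowed: list[frozenset[str]] = []
    for i, base in enumerate(seq):
        if base == "C":
            nxt = seq[i + 1] if i + 1 < len(seq) else ""
            allowed.append(frozenset("CT") if nxt in ("G", "R") else frozenset("T"))
        elif base == "R":
            allowed.append(frozenset("AG"))
        else:
            allowed.append(frozenset(base))
    parts = []
    for a in allowed:
        s = "".join(sorted(a))
        parts.append(s if len(s) == 1 else f"[{s}]")
    pattern = "".join(parts)
    # longest fixed (singleton) run doubles as a literal search anchor
    best_start = best_len = run_start = run_len = 0
    for i, a in enumerate(allowed):
        if len(a) == 1:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    anchor = "".join(next(iter(allowed[i])) for i in range(best_start, best_start + best_len))
    return BisulfiteQuery(allowed=tuple(allowed), pattern=pattern, anchor=anchor, anchor_offset=best_start)


def _scan_anchored(query: BisulfiteQuery, text: str) -> list[int]:
    """Exact scan using the literal anchor as a prefilter; counts overlaps."""
    k = len(query)
    out = []
    i = text.find(query.anchor)
    while i != -1:
        start = i - query.anchor_offset
        if 0 <= start <= len(text) - k:
            window = text[start : start + k]
            if all(base in allowed for base, allowed in zip(window, query.allowed)):
                out.append(start)
        i = text.find(query.anchor, i + 1)
    return out


@dataclass
class HitReport:
    """Occurrence count of one probe over both converted strand texts.

    ``hit_count`` is always exact; ``hit_locations`` (chrom, 0-based forward
    start, strand) is capped at ``max_locations`` entries for predictability.
    """

    probe_id: str
    hit_count: int
    hit_locations: list[tuple[str, int, str]] = field(default_factory=list)


def _scan_exact(pattern: str, text: str) -> list[int]:
    # Lookahead makes overlapping occurrences countable.
    return [m.start() for m in re.finditer(f"(?=(?:{pattern}))", text)]


def _scan_mismatch(allowed: Sequence[frozenset[str]], text: str, max_mismatch: int) -> list[int]:
    k = len(allowed)
    n = len(text) - k + 1
    if n <= 0:
        return []
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    mism = np.zeros(n, dtype=np.int16)
    for j, letters in enumerate(allowed):
        lut = np.zeros(256, dtype=bool)
        for ch in letters:
            lut[ord(ch)] = True
        mism += ~lut[arr[j : j + n]]
    return np.flatnonzero(mism <= max_mismatch).tolist()


def count_genomic_hits(
    query: BisulfiteQuery | ProbeRecord | str,
    genome: BisulfiteGenome,
    max_mismatch: int = 0,
    max_locations: int = 16,
    probe_id: str = "",
) -> HitReport:
    """Count occurrences of a bisulfite-space query over both strand texts.

    The result is independent of chromosome iteration order (chromosomes are
    scanned in sorted order; reverse-text match positions are reported as
    forward-strand starts).
    """
    if not genome.forward:
        raise ValueError("empty bisulfite genome")
    if isinstance(query, ProbeRecord):
        probe_id = probe_id or query.probe_id
        query = convert_probe_to_bisulfite_space(query)
    elif isinstance(query, str):
        query = convert_probe_to_bisulfite_space(query)
    k = len(query)
    locations: list[tuple[str, int, str]] = []
    count = 0
    for chrom in genome.chroms():
        for strand, text in (("+", genome.forward[chrom]), ("-", genome.reverse[chrom])):
            if max_mismatch == 0:
                # literal-anchor prefilter when the fixed run is long enough to
                # be selective; regex scan otherwise
                if len(query.anchor) >= 8:
                    starts = _scan_anchored(query, text)
                else:
                    starts = _scan_exact(query.pattern, text)
            else:
                starts = _scan_mismatch(query.allowed, text, max_mismatch)
            count += len(starts)
            for s in starts:
                if len(locations) < max_locations:
                    fwd_start = s if strand == "+" else len(text) - s - k
                    locations.append((chrom, fwd_start, strand))
    return HitReport(probe_id=probe_id, hit_count=count, hit_locations=locations)


@dataclass
class MultimapResult:
    """Probe ids partitioned by mappability."""

    multimapped: set[str]
    unmappable: set[str]
    reports: dict[str, HitReport]


def flag_multimappers(
    probes: Iterable[ProbeRecord],
    genome: BisulfiteGenome,
    max_mismatch: int = 0,
) -> MultimapResult:
    """Flag probes whose bisulfite-space sequence hits more than one locus."""
    multi: set[str] = set()
    unmapped: set[str] = set()
    reports: dict[str, HitReport] = {}
    for probe in probes:
        rep = count_genomic_hits(probe, genome, max_mismatch=max_mismatch)
        reports[probe.probe_id] = rep
        if rep.hit_count > 1:
            multi.add(probe.probe_id)
        elif rep.hit_count == 0:
            unmapped.add(probe.probe_id)
    return MultimapResult(multimapped=multi, unmappable=unmapped, reports=reports)


def write_hit_reports(reports: Mapping[str, HitReport], path: str | Path) -> None:
    """TSV export: probe_id, hit_count, first locations as chrom:start:strand."""
    with Path(path).open("w") as fh:
        fh.write("probe_id\thit_count\tlocations\n")
        for probe_id in sorted(reports):
            rep = reports[probe_id]
            locs = ";".join(f"{c}:{s}:{st}" for c, s, st in rep.hit_locations)
            fh.write(f"{probe_id}\t{rep.hit_count}\t{locs}\n")
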