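"""Probe manifest parsing and genomic-geometry resolution.

An HM450K-style manifest assigns each probe an id, an Infinium chemistry
(type I or II), a genomic anchor (chromosome, 1-based forward-strand position
of the C of the interrogated CpG, strand) and a 50-mer probe sequence.
This module validates manifests, derives the 50-bp hybridization footprint of
each probe, and verifies probe sequences against a reference genome in
bisulfite space.

Coordinate conventions
----------------------
Manifest positions are 1-based (the C of the CpG on the forward strand).
All internal intervals are 0-based half-open on the forward strand.
With ``c = cpg_pos - 1`` the default ("illumina") footprint is::

    type I,  '+':  [c,    c+50)   the probe 3' terminus pairs with the C
    type II, '+':  [c+1,  c+51)   single-base extension reads the C
    type I,  '-':  [c-48, c+2)    mirror image; reverse-strand C is at c+1
    type II, '-':  [c-49, c+1)

Every footprint has length 50 and contains or abuts the CpG dinucleotide
``[c, c+2)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ProbeRecord",
    "GenomicInterval",
    "ManifestDialect",
    "ManifestError",
    "ParseResult",
    "parse_manifest",
    "write_manifest",
    "probe_footprint",
    "verify_probe_against_reference",
    "fetch_sequence",
    "revcomp",
]

PROBE_LENGTH = 50
_COMPLEMENT = str.maketrans("ACGTRYN", "TGCAYRN")
_STRAND_ALIASES = {"+": "+", "-": "-", "F": "+", "R": "-"}


class ManifestError(ValueError):
    """A manifest is structurally unusable (e.g. missing a mandatory column)."""


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,R,Y,N}; R (A/G) complements to Y (C/T)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProbeRecord:
    """One manifest entry.

    ``probe_seq`` is the genomic source copy of the footprint on the declared
    strand; type II probes carry ``R`` at degenerate body-CpG positions.
    """

    probe_id: str
    design_type: str  # "I" or "II"
    chrom: str
    cpg_pos: int  # 1-based forward-strand position of the interrogated C
    strand: str  # "+" or "-"
    probe_seq: str
    source_seq: str | None = None

    def __post_init__(self) -> None:
        if self.design_type not in ("I", "II"):
            raise ValueError(f"{self.probe_id}: design_type must be I or II, got {self.design_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.probe_id}: strand must be + or -, got {self.strand!r}")
        if not self.chrom:
            raise ValueError(f"{self.probe_id}: chrom is empty")
        if self.cpg_pos < 1:
            raise ValueError(f"{self.probe_id}: cpg_pos must be >= 1, got {self.cpg_pos}")
        if len(self.probe_seq) != PROBE_LENGTH:
            raise ValueError(
                f"{self.probe_id}: probe_seq length must be {PROBE_LENGTH}, got {len(self.probe_seq)}"
            )
        bad = set(self.probe_seq) - set("ACGTR")
        if bad:
            raise ValueError(f"{self.probe_id}: probe_seq has invalid characters {sorted(bad)}")
        if "R" in self.probe_seq and self.design_type != "II":
            raise ValueError(f"{self.probe_id}: R bases are only allowed in type II probes")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open forward-strand interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class ManifestDialect:
    """Column-name mapping for manifest CSVs; defaults follow Illumina naming."""

    probe_id: str = "IlmnID"
    design_type: str = "Infinium_Design_Type"
    chrom: str = "CHR"
    cpg_pos: str = "MAPINFO"
    strand: str = "Strand"
    probe_seq: str = "AlleleA_ProbeSeq"
    source_seq: str | None = "SourceSeq"

    def mandatory(self) -> tuple[str, ...]:
        return (self.probe_id, self.design_type, self.chrom, self.cpg_pos, self.strand, self.probe_seq)


DEFAULT_DIALECT = ManifestDialect()


@dataclass
class ParseResult:
    """Outcome of a manifest parse: valid records plus row-level diagnostics."""

    records: list[ProbeRecord] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    n_rows: int = 0

    @property
    def n_parsed(self) -> int:
        return len(self.records)


def parse_manifest(
    path: str | Path,
    dialect: ManifestDialect = DEFAULT_DIALECT,
    strict: bool = False,
) -> ParseResult:
    """Read a probe manifest CSV.

    Rows violating :class:`ProbeRecord` invariants are collected as row-level
    diagnostics (``result.errors``) rather than aborting the parse, unless
    ``strict`` is set. A missing mandatory column raises :class:`ManifestError`.
    """
    path = Path(path)
    result = ParseResult()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ManifestError(f"{path}: empty manifest")
        missing = [c for c in dialect.mandatory() if c not in reader.fieldnames]
        if missing:
            raise ManifestError(f"{path}: missing mandatory column(s) {missing}")
        has_source = dialect.source_seq is not None and dialect.source_seq in reader.fieldnames
        for i, row in enumerate(reader, start=2):  # header is line 1
            result.n_rows += 1
            probe_id = (row.get(dialect.probe_id) or "").strip()
            try:
                design = (row[dialect.design_type] or "").strip().upper()
                strand_raw = (row[dialect.strand] or "").strip().upper()
                strand = _STRAND_ALIASES.get(strand_raw)
                if strand is None:
                    raise ValueError(f"{probe_id}: unrecognized strand {strand_raw!r}")
                rec = ProbeRecord(
                    probe_id=probe_id,
                    design_type=design,
                    chrom=(row[dialect.chrom] or "").strip(),
                    cpg_pos=int(row[dialect.cpg_pos]),
                    strand=strand,
                    probe_seq=(row[dialect.probe_seq] or "").strip().upper(),
                    source_seq=(row[dialect.source_seq].strip().upper() or None) if has_source and row.get(dialect.source_seq) else None,
                )
            except (ValueError, KeyError) as exc:
                msg = f"line {i}: {exc}"
                if strict:
                    raise ManifestError(msg) from exc
                result.errors.append(msg)
                continue
            result.records.append(rec)
    return result


def write_manifest(
    records: Iterable[ProbeRecord],
    path: str | Path,
    dialect: ManifestDialect = DEFAULT_DIALECT,
) -> None:
    """Write records back to a manifest CSV (inverse of :func:`parse_manifest`)."""
    path = Path(path)
    cols = list(dialect.mandatory())
    if dialect.source_seq:
        cols.append(dialect.source_seq)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            row = [rec.probe_id, rec.design_type, rec.chrom, rec.cpg_pos, rec.strand, rec.probe_seq]
            if dialect.source_seq:
                row.append(rec.source_seq or "")
            writer.writerow(row)


def probe_footprint(probe: ProbeRecord, convention: str = "illumina") -> GenomicInterval:
    """50-bp hybridization footprint of a probe on forward coordinates.

    Raises a coordinate error (ValueError) if the footprint would extend
    before position 1 of the chromosome.
    """
    if convention != "illumina":
        raise ValueError(f"unknown footprint convention {convention!r}")
    c = probe.cpg_pos - 1
    if probe.strand == "+":
        start = c if probe.design_type == "I" else c + 1
    else:
        start = c - 48 if probe.design_type == "I" else c - 49
    if start < 0:
        raise ValueError(f"{probe.probe_id}: footprint starts before position 1 (start={start})")
    return GenomicInterval(probe.chrom, start, start + PROBE_LENGTH, probe.strand)


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) as an uppercase string from a dict or pyfaidx.Fasta."""
    if isinstance(genome, Mapping):
        seq = genome[chrom][start:end]
    else:  # pyfaidx.Fasta or similar record store
        seq = str(genome[chrom][start:end])
    return str(seq).upper()


def _chrom_length(genome, chrom: str) -> int:
    if isinstance(genome, Mapping):
        return len(genome[chrom])
    return len(genome[chrom])


def _matches_bisulfite(probe_seq: str, genomic: str) -> bool:
    # Local import to avoid a cycle: bisulfite_mapping builds on ProbeRecord.
    from .bisulfite_mapping import convert_probe_to_bisulfite_space, bisulfite_convert_text

    query = convert_probe_to_bisulfite_space(probe_seq)
    converted = bisulfite_convert_text(genomic)
    if len(converted) != len(query.allowed):
        return False
    return all(base in allowed for base, allowed in zip(converted, query.allowed))


def verify_probe_against_reference(probe: ProbeRecord, genome, convention: str = "illumina") -> str:
    """Check a probe sequence against the reference genome in bisulfite space.

    Returns ``"consistent"`` if the probe matches the bisulfite-converted
    genomic footprint on its declared strand, ``"strand_flipped"`` if it only
    matches under the opposite strand annotation, else ``"mismatch"``.
    """
    if probe.chrom not in (genome.keys() if isinstance(genome, Mapping) else genome):
        raise KeyError(f"{probe.probe_id}: chromosome {probe.chrom!r} not in genome")
    verdicts = {}
    for strand in ("+", "-"):
        cand = probe if strand == probe.strand else replace(probe, strand=strand)
        try:
            fp = probe_footprint(cand, convention)
        except ValueError:
            verdicts[strand] = False
            continue
        if fp.end > _chrom_length(genome, probe.chrom):
            if strand == probe.strand:
                raise ValueError(f"{probe.probe_id}: footprint beyond chromosome end")
            verdicts[strand] = False
            continue
        genomic = fetch_sequence(genome, fp.chrom, fp.start, fp.end)
        if strand == "-":
            genomic = revcomp(genomic)
        verdicts[strand] = _matches_bisulfite(probe.probe_seq, genomic)
    if verdicts[probe.strand]:
        return "consistent"
    other = "-" if probe.strand == "+" else "+"
    if verdicts[other]:
        return "strand_flipped"
    return "mismatch"
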