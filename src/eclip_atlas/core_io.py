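"""Readers/writers for the formats every pipeline stage touches.

All internal coordinates are 0-based half-open on the forward genomic
strand; conversion to/from 1-based closed happens only at the GTF
boundary.  BED/narrowPeak coordinates are taken as-is (BED is native).

Alignments can come from SAM/BAM (via pysam, requires the MD tag) or
from the tab-delimited "alignment table" dialect defined here, which
carries mismatch offsets/qualities and gap lengths explicitly:

    read_id  mate  kind  target  start  end  strand  mismatches  gaps

``mismatches`` is ``off:Q`` entries joined by ``;`` (``.`` if none) and
``gaps`` is ``;``-joined gap lengths (``.`` if none).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger("eclip_atlas")

ALIGNMENT_TABLE_COLUMNS = [
    "read_id", "mate", "kind", "target", "start", "end", "strand",
    "mismatches", "gaps",
]


class ParseError(ValueError):
    """Malformed input file (message carries the line number)."""


class ValidationError(ValueError):
    """Input parsed but violates an invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 base on the same chromosome."""
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus an optional CDS span.

    UTR lists are derived (exonic sequence outside the CDS span); ``tpm``
    is filled from an abundance table when representatives are selected.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_span: tuple[int, int] | None = None
    tpm: float = 0.0

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})")
        if self.tpm < 0:
            raise ValidationError(f"{self.transcript_id}: tpm < 0")
        if self.cds_span is not None:
            s, e = self.cds_span
            if s < self.exons[0].start or e > self.exons[-1].end or s >= e:
                raise ValidationError(
                    f"{self.transcript_id}: CDS outside exon span")

    # -- derived structure -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start,
                                           self.strand))
        return out

    def _exonic_outside_cds(self, side: str) -> list[GenomicInterval]:
        if self.cds_span is None:
            return []
        cs, ce = self.cds_span
        out = []
        for x in self.exons:
            if side == "left" and x.start < cs:
                out.append(GenomicInterval(self.chrom, x.start,
                                           min(x.end, cs), self.strand))
            if side == "right" and x.end > ce:
                out.append(GenomicInterval(self.chrom, max(x.start, ce),
                                           x.end, self.strand))
        return out

    @property
    def utr5(self) -> list[GenomicInterval]:
        side = "left" if self.strand == "+" else "right"
        return self._exonic_outside_cds(side)

    @property
    def utr3(self) -> list[GenomicInterval]:
        side = "right" if self.strand == "+" else "left"
        return self._exonic_outside_cds(side)

    def spliced_length(self) -> int:
        return sum(len(x) for x in self.exons)

    def genomic_to_spliced(self, gpos: int) -> int | None:
        """Map a genomic position to 5'->3' spliced coordinates (None if intronic)."""
        off = 0
        for x in self.exons:
            if x.start <= gpos < x.end:
                spl = off + (gpos - x.start)
                if self.strand == "-":
                    spl = self.spliced_length() - 1 - spl
                return spl
            off += len(x)
        return None


@dataclass(slots=True)
class AlignmentRecord:
    """One mate's mapping to a family transcript or to the genome."""

    read_id: str
    mate: int
    target_id: str
    target_kind: str  # "family_transcript" | "genome"
    start: int
    end: int
    strand: str
    mismatches: list[tuple[int, int]] = field(default_factory=list)
    gaps: list[int] = field(default_factory=list)
    is_unique_genomic: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"{self.read_id}: start >= end ({self.start}, {self.end})")
        for _, q in self.mismatches:
            if not (0 <= q <= 41):
                raise ValidationError(f"{self.read_id}: quality {q} not in 0..41")
        for n in self.gaps:
            if n < 1:
                raise ValidationError(f"{self.read_id}: gap length {n} < 1")


@dataclass
class PeakSet:
    """Reproducible peaks of one eCLIP dataset, with per-peak statistics."""

    dataset_id: str
    peaks: list[GenomicInterval]
    fold_enrichment: list[float] = field(default_factory=list)
    p_value: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def significant_reproducible(self, min_fold: float = 8.0,
                                 max_p: float = 1e-3) -> "PeakSet":
        """Subset to peaks with fold >= 8 and p <= 1e-3 (the reproducible set)."""
        keep = [i for i in range(len(self.peaks))
                if self.fold_enrichment[i] >= min_fold
                and self.p_value[i] <= max_p]
        return PeakSet(self.dataset_id,
                       [self.peaks[i] for i in keep],
                       [self.fold_enrichment[i] for i in keep],
                       [self.p_value[i] for i in keep])


# ---------------------------------------------------------------------------
# GTF

def _gtf_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_annotation(path) -> list[TranscriptModel]:
    """Parse a GENCODE-style GTF into TranscriptModels.

    1-based closed GTF coordinates become 0-based half-open; UTRs are
    derived from exons minus the CDS span, not read from UTR features.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, "
                                 f"got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end0 <= start0:
                raise ValidationError(f"{path}:{lineno}: end < start")
            a = _gtf_attributes(attrs)
            tid = a.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}:{lineno}: missing transcript_id")
            meta.setdefault(tid, (a.get("gene_id", tid), chrom, strand))
            if feature == "exon":
                exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, start0, end0, strand))
            else:
                cds.setdefault(tid, []).append((start0, end0))
    models = []
    for tid, ex in exons.items():
        gene_id, chrom, strand = meta[tid]
        span = None
        if tid in cds:
            span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
            lo = min(x.start for x in ex)
            hi = max(x.end for x in ex)
            if span[0] < lo or span[1] > hi:
                raise ValidationError(f"{tid}: CDS outside exons")
        models.append(TranscriptModel(gene_id, tid, chrom, strand, ex, span))
    return models


def write_annotation(models: list[TranscriptModel], path) -> None:
    """Write models back to GTF (exon + CDS features, 1-based closed)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id)):
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for x in m.exons:
                fh.write("\t".join([m.chrom, "eclip_atlas", "exon",
                                    str(x.start + 1), str(x.end), ".",
                                    m.strand, ".", attrs]) + "\n")
            if m.cds_span is not None:
                cs, ce = m.cds_span
                for x in m.exons:
                    s, e = max(x.start, cs), min(x.end, ce)
                    if s < e:
                        fh.write("\t".join([m.chrom, "eclip_atlas", "CDS",
                                            str(s + 1), str(e), ".",
                                            m.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak

def read_intervals(path, default_strand: str = "+"):
    """Read BED3+/narrowPeak intervals (0-based half-open, BED-native).

    Returns (intervals, scores) where scores is a per-interval dict with
    narrowPeak signal/p-value columns when present (empty dicts for BED).
    Strand "." maps to ``default_strand`` with a warning.
    """
    intervals, scores = [], []
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            if strand == ".":
                if not warned:
                    warnings.warn(f"{path}: strand '.' treated as "
                                  f"'{default_strand}'", stacklevel=2)
                    warned = True
                strand = default_strand
            intervals.append(GenomicInterval(f[0], start, end, strand, name))
            sc = {}
            if len(f) >= 10:  # narrowPeak: signalValue, pValue, qValue, peak
                sc = {"signal": float(f[6]), "log10_p": float(f[7]),
                      "log10_q": float(f[8]), "summit": int(f[9])}
            scores.append(sc)
    return intervals, scores


def write_intervals(intervals, path, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end), iv.label or ".",
                   "0", iv.strand]
            if scores is not None:
                row[4] = str(scores[i])
            fh.write("\t".join(row) + "\n")


def read_peakset(path, dataset_id: str | None = None) -> PeakSet:
    """Read a narrowPeak file as a PeakSet (signal=fold, p from -log10)."""
    intervals, scores = read_intervals(path)
    folds = [s.get("signal", 0.0) for s in scores]
    pvals = [10 ** -s.get("log10_p", 0.0) for s in scores]
    return PeakSet(dataset_id or str(path), intervals, folds, pvals)


# ---------------------------------------------------------------------------
# Alignments

def _parse_mismatches(text: str) -> list[tuple[int, int]]:
    if text in (".", ""):
        return []
    out = []
    for item in text.split(";"):
        off, _, q = item.partition(":")
        out.append((int(off), int(q)))
    return out


def _parse_gaps(text: str) -> list[int]:
    if text in (".", ""):
        return []
    return [int(x) for x in text.split(";")]


def read_alignment_table(path):
    """Stream AlignmentRecords from the tabular alignment dialect."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ALIGNMENT_TABLE_COLUMNS:
            raise ParseError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(ALIGNMENT_TABLE_COLUMNS):
                raise ParseError(f"{path}:{lineno}: bad column count")
            yield AlignmentRecord(
                read_id=f[0], mate=int(f[1]), target_kind=f[2], target_id=f[3],
                start=int(f[4]), end=int(f[5]), strand=f[6],
                mismatches=_parse_mismatches(f[7]), gaps=_parse_gaps(f[8]),
                is_unique_genomic=(f[2] == "genome"))


def write_alignment_table(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_TABLE_COLUMNS) + "\n")
        for r in records:
            mm = ";".join(f"{o}:{q}" for o, q in r.mismatches) or "."
            gp = ";".join(str(n) for n in r.gaps) or "."
            fh.write("\t".join([r.read_id, str(r.mate), r.target_kind,
                                r.target_id, str(r.start), str(r.end),
                                r.strand, mm, gp]) + "\n")


def read_alignments(path):
    """Read alignments from SAM/BAM or the tabular dialect (by extension).

    SAM/BAM records must carry the MD tag plus base qualities so mismatch
    positions and qualities can be recovered; unmapped records are
    skipped (counted in the log).
    """
    path = str(path)
    if path.endswith((".sam", ".bam")):
        yield from _read_sam(path)
    else:
        yield from read_alignment_table(path)


def _read_sam(path):
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    skipped = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                skipped += 1
                continue
            if not rec.has_tag("MD"):
                raise ParseError(
                    f"{path}: record {rec.query_name} lacks an MD tag; "
                    "use the tabular alignment dialect instead")
            mismatches = _sam_mismatches(rec)
            gaps = [length for op, length in (rec.cigartuples or [])
                    if op in (1, 2)]  # I or D
            yield AlignmentRecord(
                read_id=rec.query_name,
                mate=2 if rec.is_read2 else 1,
                target_id=rec.reference_name,
                target_kind="genome",
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mismatches=mismatches,
                gaps=gaps,
                is_unique_genomic=rec.mapping_quality > 3)
    if skipped:
        log.info("%s: skipped %d unmapped records", path, skipped)


def _sam_mismatches(rec) -> list[tuple[int, int]]:
    quals = rec.query_qualities
    out = []
    for qpos, _, refbase in rec.get_aligned_pairs(with_seq=True):
        if qpos is None or refbase is None:
            continue
        if refbase.islower():  # pysam lowercases substituted reference bases
            q = quals[qpos] if quals is not None else 40
            out.append((qpos, int(q)))
    return out


# ---------------------------------------------------------------------------
# Generic tables

def write_table(rows: pd.DataFrame, path, schema: list[str],
                primary_key: str | None = None) -> None:
    """Write a tab-delimited table with header, rows sorted by primary key.

    ``schema`` is the exact expected column list; a mismatch or a
    duplicated primary key raises.
    """
    if list(rows.columns) != list(schema):
        raise ValidationError(
            f"schema mismatch: expected {schema}, got {list(rows.columns)}")
    key = primary_key or schema[0]
    if rows[key].duplicated().any():
        dup = rows[key][rows[key].duplicated()].iloc[0]
        raise ValidationError(f"duplicate primary key {dup!r}")
    rows.sort_values(key, kind="mergesort").to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
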