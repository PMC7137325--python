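"""Branch-point calling from read 5'-end truncation pileups.

Reverse transcription stops at the branch-point adenosine of the intron
lariat, so eCLIP read 5' ends pile up one base 3' of the branch point.
Windows of offsets -50..-15 from each annotated 3' splice site are
scanned; a window with >= 20 reads where a single position holds more
than half of them yields a call, placed one base 5' of the mode read
start.  An 11-mer around each call summarizes the motif.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import AlignmentRecord, TranscriptModel

WINDOW_LO, WINDOW_HI = -50, -15  # inclusive offsets from the 3'SS
WINDOW_LEN = WINDOW_HI - WINDOW_LO + 1  # 36


@dataclass
class BPWindow:
    """Read 5'-end counts at offsets -50..-15 from one 3' splice site."""

    intron_id: str
    chrom: str
    ss3_pos: int  # genomic position of the first exonic base (3'SS)
    strand: str
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros(WINDOW_LEN, dtype=int))

    def offset_to_genomic(self, offset: int) -> int:
        return self.ss3_pos + offset if self.strand == "+" \
            else self.ss3_pos - offset

    @property
    def n_region_reads(self) -> int:
        return int(self.counts.sum())


@dataclass
class BranchPointCall:
    intron_id: str
    chrom: str
    strand: str
    bp_genomic_position: int
    mode_offset: int  # offset of the mode read start (BP is one base 5')
    n_region_reads: int
    mode_fraction: float
    motif_window: str = ""


def extract_bp_windows(models: list[TranscriptModel],
                       reads, mate: int = 2) -> list[BPWindow]:
    """One window per annotated intron 3'SS, deduplicated by
    (chrom, 3'SS, strand); reads contribute where their strand-aware
    5' end lands at offsets -50..-15.
    """
    windows: dict[tuple, BPWindow] = {}
    order: list[tuple] = []
    for m in models:
        for k, iv in enumerate(m.introns()):
            ss3 = iv.end if m.strand == "+" else iv.start - 1
            key = (m.chrom, ss3, m.strand)
            if key in windows:
                continue
            if len(iv) < 50:
                import warnings
                warnings.warn(f"{m.transcript_id} intron {k}: shorter than "
                              "50 nt, window truncated", stacklevel=2)
            windows[key] = BPWindow(f"{m.transcript_id}.intron{k}",
                                    m.chrom, ss3, m.strand)
            order.append(key)
    by_loc: dict[tuple[str, str], list[BPWindow]] = {}
    for key in order:
        w = windows[key]
        by_loc.setdefault((w.chrom, w.strand), []).append(w)
    for rec in reads:
        if rec.mate != mate:
            continue
        five_prime = rec.start if rec.strand == "+" else rec.end - 1
        for w in by_loc.get((rec.target_id, rec.strand), ()):
            offset = five_prime - w.ss3_pos if w.strand == "+" \
                else w.ss3_pos - five_prime
            if WINDOW_LO <= offset <= WINDOW_HI:
                w.counts[offset - WINDOW_LO] += 1
    return [windows[key] for key in order]


def call_branchpoints(windows: list[BPWindow], min_reads: int = 20,
                      min_fraction: float = 0.5) -> list[BranchPointCall]:
    """A window calls a branch point iff it holds >= min_reads reads and
    one offset carries strictly more than min_fraction of them (such an
    offset is necessarily unique).  The BP is one base 5' of that mode
    read start."""
    calls = []
    for w in windows:
        n = w.n_region_reads
        if n < min_reads:
            continue
        mode_idx = int(np.argmax(w.counts))
        mode_count = int(w.counts[mode_idx])
        if mode_count <= min_fraction * n:
            continue
        mode_offset = WINDOW_LO + mode_idx
        start_pos = w.offset_to_genomic(mode_offset)
        bp_pos = start_pos - 1 if w.strand == "+" else start_pos + 1
        calls.append(BranchPointCall(
            w.intron_id, w.chrom, w.strand, bp_pos, mode_offset, n,
            mode_count / n))
    return calls


_COMP = str.maketrans("ACGT", "TGCA")


def _window_seq(genome: dict, chrom: str, center: int, strand: str,
                flank: int = 5) -> str | None:
    seq = genome[chrom]
    lo, hi = center - flank, center + flank + 1
    if lo < 0 or hi > len(seq):
        return None
    sub = seq[lo:hi]
    return sub if strand == "+" else sub.translate(_COMP)[::-1]


def branchpoint_motif(calls: list[BranchPointCall], genome: dict,
                      anchor: str = "branch_point"):
    """Position frequency matrix of 11-mers around the calls.

    ``anchor`` centers the 11-mer on the inferred branch-point base
    (default) or on the mode read start ("read_start"); the two differ
    by one position.  Returns (pfm DataFrame rows A/C/G/T x 11 columns,
    information vector 2 + sum_b f_b log2 f_b per column).  Calls too
    close to a sequence end are skipped with a warning.
    """
    if not calls:
        raise ValueError("no branch-point calls")
    if anchor not in ("branch_point", "read_start"):
        raise ValueError(anchor)
    counts = np.zeros((4, 11), dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    n_used = 0
    for c in calls:
        center = c.bp_genomic_position
        if anchor == "read_start":
            center = center + 1 if c.strand == "+" else center - 1
        sub = _window_seq(genome, c.chrom, center, c.strand)
        if sub is None:
            import warnings
            warnings.warn(f"{c.intron_id}: call too close to sequence end, "
                          "skipped", stacklevel=2)
            continue
        c.motif_window = sub
        for j, b in enumerate(sub):
            if b in base_idx:
                counts[base_idx[b], j] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("every call fell off the sequence ends")
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    information = 2.0 + plogp.sum(axis=0)
    return counts, freqs, information
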