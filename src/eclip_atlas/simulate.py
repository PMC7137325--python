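"""Synthetic eCLIP inputs with planted ground truth.

Every input the pipeline consumes can be generated here: a multicopy
family database (primary transcript plus diverged pseudogenes per
family), a small genome with multi-exon genes and embedded sense/
antisense element copies, paired-end IP/input alignment tables with
UMIs, PCR duplicates and configurable per-family enrichment,
branch-point truncation pileups, A3SS event tables with planted
enrichment bumps, and association fixtures (peak sets with planted
overlap, knockdown log2FC tables, annotation and interaction tables).

All generators are pure functions of (config, seed): the same seed
yields byte-identical outputs.  Truth tables record the source of every
simulated read/event/gene so recovery can be scored exactly.

Family reads are emitted with mappings to every member of their source
family only: families are independent random sequences, so a
cross-family alignment of a 50 nt read would carry ~37 mismatches and
can never compete with within-family scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import AlignmentRecord, GenomicInterval, PeakSet, TranscriptModel
from .family_quant import ANTISENSE_SUFFIX, FamilyDatabase

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_FAMILY_NAMES = ["RNA18S", "RNA28S", "L1", "Alu", "RN7SK", "YRNA",
                 "SNORD", "RNU1", "RNU2", "VTRNA1", "RN7SL", "tRNA"]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


@dataclass
class SimConfig:
    """Knobs for every generator; rates in [0,1], depth > 0."""

    seed: int = 0
    # family database
    n_families: int = 6
    pseudogenes_per_family: int = 3
    transcript_length: int = 400
    pseudogene_divergence: float = 0.05
    # genome / annotation
    n_genes: int = 5
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 1600
    utr5_length: int = 60
    utr3_length: int = 150
    intergenic_gap: int = 1000
    n_sense_insertions: int = 2
    n_antisense_insertions: int = 2
    element_divergence_multiplier: float = 2.0
    # eCLIP library
    read_length: int = 50
    umi_length: int = 10
    depth: int = 20_000
    per_base_error_rate: float = 0.01
    duplicate_rate: float = 0.0
    enrichment: dict = field(default_factory=dict)
    family_weight: float = 1.0
    genomic_weight: float = 0.25
    element_copy_weight: float = 0.5
    # branch points
    truncation_fraction: float = 0.7
    bp_reads_per_intron: int = 30
    bp_truth_fraction: float = 1.0
    bp_read_length: int = 30
    # A3SS events
    n_events: int = 60
    n_responsive: int = 20
    a3ss_bump_offset: int = -80
    a3ss_bump_height: float = 30.0
    a3ss_bump_width: float = 5.0
    a3ss_base_rate: float = 5.0
    a3ss_intron_length: int = 1000
    # association fixtures
    n_datasets: int = 4
    peaks_per_set: int = 150
    peak_width: int = 50
    planted_overlap: dict = field(default_factory=dict)
    assoc_n_genes: int = 600
    bound_gene_fraction: float = 0.25
    bound_log2fc_shift: float = -0.5

    def __post_init__(self):
        for name in ("pseudogene_divergence", "per_base_error_rate",
                     "duplicate_rate", "truncation_fraction",
                     "bp_truth_fraction", "bound_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for fold in self.enrichment.values():
            if fold <= 0:
                raise ValueError("enrichment folds must be > 0")


@dataclass
class SimTruth:
    """Planted ground truth for one simulation run."""

    read_provenance: dict = field(default_factory=dict)
    true_family_enrichment: dict = field(default_factory=dict)
    true_branchpoints: dict = field(default_factory=dict)
    true_a3ss_effect: dict = field(default_factory=dict)
    bound_gene_effect: float = 0.0


# ---------------------------------------------------------------------------
# Family database

@dataclass
class SimFamilyDatabase:
    db: FamilyDatabase
    sequences: dict  # transcript_id -> uint8 array
    family_names: list

    def fasta(self) -> dict:
        return {tid: _decode(seq) for tid, seq in sorted(self.sequences.items())}


def _mutate(seq: np.ndarray, rate: float, rng) -> np.ndarray:
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hit):
        # substitute uniformly among the 3 alternative bases
        out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return out


def build_family_database(cfg: SimConfig) -> SimFamilyDatabase:
    """One priority-1 primary plus diverged pseudogenes per family."""
    if cfg.n_families < 1:
        raise ValueError("n_families must be >= 1")
    if cfg.pseudogene_divergence >= 0.5:
        raise ValueError("divergence >= 0.5 makes families unassignable")
    rng = np.random.default_rng(cfg.seed)
    names = [(_FAMILY_NAMES[i] if i < len(_FAMILY_NAMES) else f"FAM{i:02d}")
             for i in range(cfg.n_families)]
    db = FamilyDatabase()
    seqs: dict[str, np.ndarray] = {}
    for fam in names:
        primary = rng.integers(0, 4, size=cfg.transcript_length,
                               dtype=np.uint8)
        tid = f"{fam}-tx1"
        db.add(fam, tid, 1)
        seqs[tid] = primary
        for j in range(cfg.pseudogenes_per_family):
            pid = f"{fam}-ps{j + 1}"
            db.add(fam, pid, j + 2)
            seqs[pid] = _mutate(primary, cfg.pseudogene_divergence, rng)
    return SimFamilyDatabase(db, seqs, names)


# ---------------------------------------------------------------------------
# Genome + annotation

@dataclass
class SimGenome:
    chrom: str
    sequence: np.ndarray  # uint8, mutable (branch-point A planting edits it)
    models: list
    rmsk: list  # GenomicInterval with label = family name
    element_sources: list  # (element interval, family, host gene strand)

    @property
    def chrom_sizes(self) -> dict:
        return {self.chrom: len(self.sequence)}

    def fasta(self) -> dict:
        return {self.chrom: _decode(self.sequence)}

    def base(self, pos: int) -> str:
        return "ACGT"[self.sequence[pos]]


def simulate_genome_annotation(cfg: SimConfig,
                               famdb: SimFamilyDatabase | None = None
                               ) -> SimGenome:
    """A single-chromosome genome of multi-exon genes with embedded,
    decayed family copies (sense and antisense) recorded in rmsk rows."""
    rng = np.random.default_rng(cfg.seed + 1)
    gene_span = (cfg.exons_per_gene * cfg.exon_length
                 + (cfg.exons_per_gene - 1) * cfg.intron_length)
    total = cfg.intergenic_gap + cfg.n_genes * (gene_span + cfg.intergenic_gap)
    seq = rng.integers(0, 4, size=total, dtype=np.uint8)
    models = []
    introns_by_gene: list[list[GenomicInterval]] = []
    pos = cfg.intergenic_gap
    for g in range(cfg.n_genes):
        strand = "+" if g % 2 == 0 else "-"
        exons = []
        p = pos
        for _ in range(cfg.exons_per_gene):
            exons.append(GenomicInterval("chrSim", p, p + cfg.exon_length,
                                         strand))
            p += cfg.exon_length + cfg.intron_length
        gstart, gend = exons[0].start, exons[-1].end
        if strand == "+":
            cds = (gstart + cfg.utr5_length, gend - cfg.utr3_length)
        else:
            cds = (gstart + cfg.utr3_length, gend - cfg.utr5_length)
        m = TranscriptModel(f"gene{g:02d}", f"gene{g:02d}-tx1", "chrSim",
                            strand, exons, cds, tpm=10.0)
        models.append(m)
        introns_by_gene.append(m.introns())
        pos += gene_span + cfg.intergenic_gap
    rmsk: list[GenomicInterval] = []
    element_sources = []
    if (cfg.n_sense_insertions or cfg.n_antisense_insertions) and famdb is None:
        raise ValueError("element insertions need a family database")
    n_ins = cfg.n_sense_insertions + cfg.n_antisense_insertions
    if n_ins:
        elen = cfg.transcript_length
        div = cfg.pseudogene_divergence * cfg.element_divergence_multiplier
        taken: list[tuple[int, int]] = []
        for k in range(n_ins):
            sense = k < cfg.n_sense_insertions
            fam = famdb.family_names[k % len(famdb.family_names)]
            primary = famdb.sequences[f"{fam}-tx1"]
            placed = False
            for _attempt in range(1000):
                gi = int(rng.integers(0, cfg.n_genes))
                host = models[gi]
                introns = introns_by_gene[gi]
                if not introns:
                    continue
                iv = introns[int(rng.integers(0, len(introns)))]
                if len(iv) < elen + 20:
                    continue
                s = int(rng.integers(iv.start + 10, iv.end - elen - 10))
                if any(s < e0 and t0 < s + elen for t0, e0 in taken):
                    continue
                copy = _mutate(primary, div, rng)
                estrand = host.strand if sense else ("-" if host.strand == "+"
                                                     else "+")
                # genome holds the + strand; flip the copy if element is on -
                seq[s:s + elen] = copy if estrand == "+" else _revcomp(copy)
                el = GenomicInterval("chrSim", s, s + elen, estrand, fam)
                rmsk.append(el)
                element_sources.append((el, fam, host.strand))
                taken.append((s, s + elen))
                placed = True
                break
            if not placed:
                raise RuntimeError("could not place element after 1000 attempts")
    return SimGenome("chrSim", seq, models, rmsk, element_sources)


# ---------------------------------------------------------------------------
# eCLIP library

@dataclass
class SimLibrary:
    samples: dict  # sample name -> list[AlignmentRecord]
    truth: SimTruth


def _diff_positions(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.flatnonzero(a != b)


class _UmiSource:
    """Deterministic UMI strings drawn from the run's rng."""

    def __init__(self, rng, length: int):
        self.rng = rng
        self.length = length

    def __call__(self) -> str:
        return _decode(self.rng.integers(0, 4, size=self.length,
                                         dtype=np.uint8))


def simulate_eclip_library(cfg: SimConfig, famdb: SimFamilyDatabase,
                           genome: SimGenome,
                           samples: tuple = ("ip1", "ip2", "input")
                           ) -> SimLibrary:
    """Paired-end IP/input libraries over family and genomic sources.

    Input reads are drawn proportional to source abundance; IP reads get
    per-source multipliers from ``cfg.enrichment`` (keys are family
    names, ``<family>_antisense`` labels, or region-class labels).  Each
    pair carries a UMI in its read id; PCR duplicates are injected at
    ``cfg.duplicate_rate``; sequencing errors substitute bases at
    ``cfg.per_base_error_rate`` with quality from a {40, 20} two-point
    mixture.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    umis = _UmiSource(rng, cfg.umi_length)
    L = cfg.read_length

    # --- source catalogue: (label, kind, payload, weight)
    sources = []
    for fam in famdb.family_names:
        sources.append((fam, "family", fam, cfg.family_weight))
    region_sources = _region_sources(cfg, genome)
    for label, interval, strand in region_sources:
        sources.append((label, "region", (interval, strand),
                        cfg.genomic_weight))
    for el, fam, host_strand in genome.element_sources:
        label = fam if el.strand == host_strand else fam + ANTISENSE_SUFFIX
        sources.append((label, "element", (el, fam, host_strand),
                        cfg.element_copy_weight))
    labels = [s[0] for s in sources]
    for key in cfg.enrichment:
        if key not in labels:
            raise ValueError(f"enrichment names unknown source {key!r}")

    # per-family member windows and pairwise diffs, precomputed once
    members: dict[str, list[str]] = {
        fam: [tid for tid, _ in famdb.db.families[fam]]
        for fam in famdb.family_names}
    diffs: dict[tuple[str, str], np.ndarray] = {}
    for fam in famdb.family_names:
        for a in members[fam]:
            for b in members[fam]:
                diffs[(a, b)] = _diff_positions(famdb.sequences[a],
                                                famdb.sequences[b])
    copy_vs_member: dict[tuple[int, str], np.ndarray] = {}
    for ei, (el, fam, _hs) in enumerate(genome.element_sources):
        copy = genome.sequence[el.start:el.end]
        if el.strand == "-":
            copy = _revcomp(copy)
        for m in members[fam]:
            copy_vs_member[(ei, m)] = _diff_positions(copy,
                                                      famdb.sequences[m])

    weights = np.array([s[3] for s in sources], dtype=float)
    base_p = weights / weights.sum()
    # IP shares: enriched sources get exactly fold * input share; the
    # remaining mass is spread over unspecified sources so the planted
    # fold survives normalization (p_i = fold_i * q_i by construction)
    spec_idx = [i for i, s in enumerate(sources) if s[0] in cfg.enrichment]
    ip_p = base_p.copy()
    for i in spec_idx:
        ip_p[i] = base_p[i] * cfg.enrichment[sources[i][0]]
    spec_mass = ip_p[spec_idx].sum()
    if spec_mass >= 1.0:
        raise ValueError("enrichment spec uses >= 100% of IP read mass; "
                         "lower the folds or the sources' base weights")
    rest = [i for i in range(len(sources)) if i not in spec_idx]
    ip_p[rest] = base_p[rest] * (1.0 - spec_mass) / base_p[rest].sum()
    truth = SimTruth(true_family_enrichment=dict(cfg.enrichment))
    out: dict[str, list[AlignmentRecord]] = {}
    for sample in samples:
        p = ip_p if sample != "input" else base_p
        out[sample] = _simulate_sample(cfg, sample, sources, p, famdb, genome,
                                       members, diffs, copy_vs_member, rng,
                                       umis, truth, L)
    return SimLibrary(out, truth)


def _region_sources(cfg: SimConfig, genome: SimGenome):
    """Representative genomic intervals per region class, avoiding rmsk."""
    rmsk_spans = [(e.start, e.end) for e in genome.rmsk]

    def clear(s, e):
        return not any(s < b and a < e for a, b in rmsk_spans)

    out = []
    for m in genome.models[:2]:
        cs, ce = m.cds_span
        mid = m.exons[len(m.exons) // 2]
        s = max(mid.start, cs)
        e = min(mid.end, ce)
        if e - s > 2 * cfg.read_length and clear(s, e):
            out.append(("CDS", GenomicInterval(m.chrom, s, e, m.strand),
                        m.strand))
        for iv in m.utr3:
            if len(iv) > 2 * cfg.read_length and clear(iv.start, iv.end):
                out.append(("3UTR", iv, m.strand))
                break
        for iv in m.introns():
            a, b = iv.start + 600, iv.end - 600
            if b - a > 2 * cfg.read_length and clear(a, b):
                out.append(("distal_intronic",
                            GenomicInterval(m.chrom, a, b, m.strand),
                            m.strand))
                break
    s = 10
    e = cfg.intergenic_gap - 10
    if e - s > 2 * cfg.read_length and clear(s, e):
        out.append(("intergenic", GenomicInterval("chrSim", s, e, "+"), "+"))
    return out


def _mk_qual(rng) -> int:
    return 40 if rng.random() < 0.5 else 20


def _window_mismatches(diff: np.ndarray, s: int, L: int,
                       err_off: np.ndarray, err_base: np.ndarray,
                       src: np.ndarray, tgt: np.ndarray, rng
                       ) -> list[tuple[int, int]]:
    """Mismatches of a read (from ``src`` at [s, s+L) with substitution
    errors) against target sequence ``tgt`` at the same window."""
    lo, hi = np.searchsorted(diff, (s, s + L))
    offs = set((diff[lo:hi] - s).tolist())
    for e, nb in zip(err_off, err_base):
        if tgt[s + e] == nb:
            offs.discard(int(e))
        else:
            offs.add(int(e))
    return [(int(o), _mk_qual(rng)) for o in sorted(offs)]


def _simulate_sample(cfg, sample, sources, p, famdb, genome, members, diffs,
                     copy_vs_member, rng, umis, truth, L):
    n = cfg.depth
    picks = rng.choice(len(sources), size=n, p=p)
    err_rate = cfg.per_base_error_rate
    records: list[AlignmentRecord] = []
    for i in range(n):
        label, kind, payload, _w = sources[picks[i]]
        umi = umis()
        rid = f"{sample}r{i:07d}_{umi}"
        truth.read_provenance[rid] = label
        pair_recs = _make_pair(cfg, rid, label, kind, payload, famdb, genome,
                               members, diffs, copy_vs_member, rng, err_rate, L)
        records.extend(pair_recs)
        if cfg.duplicate_rate and rng.random() < cfg.duplicate_rate:
            dup_id = f"{sample}r{i:07d}d_{umi}"
            truth.read_provenance[dup_id] = label
            for r in pair_recs:
                records.append(replace(r, read_id=dup_id))
    return records


def _make_pair(cfg, rid, label, kind, payload, famdb, genome, members, diffs,
               copy_vs_member, rng, err_rate, L):
    def errors():
        if err_rate == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=np.uint8)
        k = rng.binomial(L, err_rate)
        if k == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=np.uint8)
        off = np.unique(rng.integers(0, L, size=k))
        return off, None  # bases filled per-target below (need originals)

    if kind == "family":
        fam = payload
        mem = members[fam]
        src_tid = mem[int(rng.integers(0, len(mem)))]
        src = famdb.sequences[src_tid]
        tlen = len(src)
        frag = int(rng.integers(L, min(2 * L, tlen) + 1))
        s = int(rng.integers(0, tlen - frag + 1))
        starts = (s, s + frag - L)
        recs = []
        for mate, ms in enumerate(starts, start=1):
            off, _ = errors()
            newb = (src[ms + off] + rng.integers(1, 4, size=len(off))) % 4 \
                if len(off) else np.empty(0, dtype=np.uint8)
            for tid in mem:
                mm = _window_mismatches(diffs[(src_tid, tid)], ms, L, off,
                                        newb, src, famdb.sequences[tid], rng)
                recs.append(AlignmentRecord(
                    rid, mate, tid, "family_transcript", ms, ms + L, "+",
                    mismatches=mm))
        return recs

    if kind == "region":
        interval, strand = payload
        frag = int(rng.integers(L, 2 * L + 1))
        s = int(rng.integers(interval.start, interval.end - frag + 1))
        recs = []
        for mate, ms in enumerate((s, s + frag - L), start=1):
            # reads come from the genome itself: every error is a mismatch
            off, _ = errors()
            mm = [(int(o), _mk_qual(rng)) for o in off]
            recs.append(AlignmentRecord(
                rid, mate, genome.chrom, "genome", ms, ms + L, strand,
                mismatches=mm, is_unique_genomic=True))
        return recs

    # element copy: unique genomic mapping + family-transcript mappings
    el, fam, host_strand = payload
    ei = next(j for j, src in enumerate(genome.element_sources)
              if src[0] is el)
    elen = len(el)
    frag = int(rng.integers(L, min(2 * L, elen) + 1))
    es = int(rng.integers(0, elen - frag + 1))  # element coordinates, 5'->3'
    rel_strand = "+" if el.strand == host_strand else "-"
    recs = []
    for mate, ms in enumerate((es, es + frag - L), start=1):
        off, _ = errors()
        copy = genome.sequence[el.start:el.end]
        if el.strand == "-":
            copy = _revcomp(copy)
        newb = (copy[ms + off] + rng.integers(1, 4, size=len(off))) % 4 \
            if len(off) else np.empty(0, dtype=np.uint8)
        # genomic mapping: errors always mismatch the genome
        gmm = [(int(o), _mk_qual(rng)) for o in off]
        gs = el.start + ms if el.strand == "+" else el.end - ms - L
        recs.append(AlignmentRecord(
            rid, mate, genome.chrom, "genome", gs, gs + L, host_strand,
            mismatches=gmm, is_unique_genomic=True))
        for tid in members[fam]:
            mm = _window_mismatches(copy_vs_member[(ei, tid)], ms, L, off,
                                    newb, copy, famdb.sequences[tid], rng)
            recs.append(AlignmentRecord(
                rid, mate, tid, "family_transcript", ms, ms + L, rel_strand,
                mismatches=mm))
    return recs


# ---------------------------------------------------------------------------
# Branch-point truncation pileups

def simulate_branchpoint_reads(cfg: SimConfig, genome: SimGenome
                               ) -> tuple[list, dict]:
    """Single-end (mate-2) pileups around annotated 3' splice sites.

    For each truth intron a branch point is planted at an offset in
    [-50, -15] from the 3'SS, the genome base there is set to A, and
    ``truncation_fraction`` of the intron's reads start exactly one base
    3' of it; the rest start uniformly in the window.  Returns
    (records, {intron_id: bp genomic position}).
    """
    if not (0.0 <= cfg.truncation_fraction <= 1.0):
        raise ValueError("truncation_fraction outside [0, 1]")
    rng = np.random.default_rng(cfg.seed + 3)
    umis = _UmiSource(rng, cfg.umi_length)
    records: list[AlignmentRecord] = []
    truth: dict[str, int] = {}
    rl = cfg.bp_read_length
    for m in genome.models:
        for k, iv in enumerate(m.introns()):
            if len(iv) < 100:
                continue
            intron_id = f"{m.transcript_id}.intron{k}"
            ss3 = iv.end if m.strand == "+" else iv.start - 1
            # genomic position at transcript-strand offset o (< 0) from 3'SS
            def gpos(o):
                return ss3 + o if m.strand == "+" else ss3 - o
            planted = rng.random() < cfg.bp_truth_fraction
            if planted:
                bp_off = int(rng.integers(-50, -14))  # [-50, -15]
                bp_pos = gpos(bp_off)
                # plant an A at the branch point on the transcript strand
                # (stored + strand base is its complement for minus genes)
                genome.sequence[bp_pos] = 0 if m.strand == "+" else 3
                truth[intron_id] = bp_pos
            for j in range(cfg.bp_reads_per_intron):
                if planted and rng.random() < cfg.truncation_fraction:
                    off5 = bp_off + 1
                else:
                    off5 = int(rng.integers(-50, -14))
                g5 = gpos(off5)
                if m.strand == "+":
                    s, e = g5, g5 + rl
                else:
                    s, e = g5 - rl + 1, g5 + 1
                records.append(AlignmentRecord(
                    f"{intron_id}.r{j:04d}_{umis()}", 2, genome.chrom,
                    "genome", s, e, m.strand, is_unique_genomic=True))
    return records, truth


# ---------------------------------------------------------------------------
# A3SS events

@dataclass
class SimA3SS:
    events: pd.DataFrame
    densities: dict  # event_id -> dict(ip=..., input=..., ip_total, input_total)
    truth: dict  # event_id -> planted bump offset (None for native)
    region_length: int = 700


def simulate_a3ss_dataset(cfg: SimConfig) -> SimA3SS:
    """Alternative 3'SS events plus per-position IP/input read densities.

    The event region is two 350-position windows (300 intron + 50 exon,
    5'->3'), distal then proximal.  Responsive events carry a planted
    IP bump at ``a3ss_bump_offset`` from the proximal 3'SS; native
    events have 0.05 < inclusion < 0.95 and flat IP.
    """
    if cfg.n_events < 1:
        raise ValueError("n_events must be >= 1")
    if cfg.a3ss_intron_length < 300:
        raise ValueError("window (300 nt intron) longer than intron")
    rng = np.random.default_rng(cfg.seed + 4)
    region = 700
    # proximal window occupies region[350:700]; its intron offsets are
    # -300..-1 at indices 350..649, exon offsets 0..49 at 650..699
    bump_idx = 350 + 300 + cfg.a3ss_bump_offset
    if not (0 <= bump_idx < region):
        raise ValueError("bump offset outside the event region")
    rows, densities, truth = [], {}, {}
    x = np.arange(region)
    bump = cfg.a3ss_bump_height * np.exp(
        -0.5 * ((x - bump_idx) / cfg.a3ss_bump_width) ** 2)
    for i in range(cfg.n_events):
        responsive = i < cfg.n_responsive
        eid = f"ev{i:04d}"
        base = rng.poisson(cfg.a3ss_base_rate, size=region).astype(float)
        input_d = base + rng.poisson(cfg.a3ss_base_rate, size=region)
        ip_d = base + rng.poisson(cfg.a3ss_base_rate, size=region).astype(float)
        if responsive:
            ip_d += rng.poisson(bump).astype(float)
            incl = float(rng.uniform(0.0, 1.0))
            truth[eid] = cfg.a3ss_bump_offset
        else:
            incl = float(rng.uniform(0.051, 0.949))
            truth[eid] = None
        gene_start = 10_000 + i * 5_000
        prox = gene_start + cfg.a3ss_intron_length
        rows.append({
            "event_id": eid, "gene": f"gene{i:04d}", "strand": "+",
            "distal_3ss": prox - 120, "proximal_3ss": prox,
            "inclusion_level": incl,
            "set_label": "responsive" if responsive else "native"})
        densities[eid] = {"ip": ip_d, "input": input_d,
                          "ip_total": 1_000_000.0, "input_total": 1_000_000.0}
    return SimA3SS(pd.DataFrame(rows), densities, truth)


# ---------------------------------------------------------------------------
# Association fixtures

@dataclass
class SimAssociation:
    peak_sets: dict  # dataset_id -> PeakSet
    log2fc: pd.DataFrame  # gene, log2fc, n_elements, n_bound_elements
    annotation: pd.DataFrame  # dataset_id, function
    interactions: list  # (dataset_a, dataset_b)
    truth: SimTruth


def simulate_association_fixtures(cfg: SimConfig) -> SimAssociation:
    """Peak sets with planted pairwise overlap, a knockdown log2FC table
    with a planted shift for element-bound genes, and annotation and
    interaction tables."""
    if cfg.n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    for frac in cfg.planted_overlap.values():
        if not (0.0 <= frac <= 1.0):
            raise ValueError("requested overlap outside [0, 1]")
    rng = np.random.default_rng(cfg.seed + 5)
    ids = [f"RBP{i:02d}" for i in range(cfg.n_datasets)]
    w = cfg.peak_width
    slot = 10 * w
    peak_sets: dict[str, PeakSet] = {}
    starts: dict[str, np.ndarray] = {}
    lane = {d: i for i, d in enumerate(ids)}  # disjoint default lanes
    for d in ids:
        base = lane[d] * 4_000_000
        s = base + slot * rng.permutation(10 * cfg.peaks_per_set
                                          )[:cfg.peaks_per_set]
        starts[d] = np.sort(s)
    for (a, b), frac in cfg.planted_overlap.items():
        k = int(round(frac * cfg.peaks_per_set))
        jitter = rng.integers(-w // 2, w // 2, size=k)
        starts[b] = np.sort(np.concatenate(
            [starts[a][:k] + jitter, starts[b][k:]]))
    for d in ids:
        peaks = [GenomicInterval("chrSim", int(s), int(s) + w, "+",
                                 f"{d}.p{i}")
                 for i, s in enumerate(starts[d])]
        n = len(peaks)
        peak_sets[d] = PeakSet(d, peaks, [10.0] * n, [1e-5] * n)

    genes = [f"g{i:04d}" for i in range(cfg.assoc_n_genes)]
    has_el = rng.random(cfg.assoc_n_genes) < 0.5
    bound = has_el & (rng.random(cfg.assoc_n_genes) < cfg.bound_gene_fraction)
    lfc = rng.normal(0.0, 1.0, size=cfg.assoc_n_genes)
    lfc[bound] += cfg.bound_log2fc_shift
    log2fc = pd.DataFrame({
        "gene": genes, "log2fc": lfc, "tpm": 5.0,
        "n_elements": has_el.astype(int), "n_bound_elements": bound.astype(int)})
    annotation = pd.DataFrame({
        "dataset_id": ids,
        "function": ["splicing" if i % 2 == 0 else "ribosome"
                     for i in range(len(ids))]})
    interactions = [pair for pair in cfg.planted_overlap]
    truth = SimTruth(bound_gene_effect=cfg.bound_log2fc_shift)
    return SimAssociation(peak_sets, log2fc, annotation, interactions, truth)
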