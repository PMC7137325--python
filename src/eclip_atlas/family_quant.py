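"""Family-aware assignment of read pairs to multicopy RNA element families.

Multi-mapping read pairs are scored with bowtie2-style mismatch/gap
penalties, assigned to the single best-scoring repeat family (pairs tied
across families are discarded), integrated with unique genomic mappings,
PCR-deduplicated by (position, UMI), and tallied into per-element counts
with fold-enrichment, Fisher/chi-square significance and relative
information p*log2(p/q) against the size-matched input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core_io import AlignmentRecord, GenomicInterval, TranscriptModel

ANTISENSE_SUFFIX = "_antisense"

ENRICHMENT_COLUMNS = [
    "element", "ip_rep1_count", "ip_rep2_count", "input_count",
    "fold_rep1", "fold_rep2", "fold_merged", "p_value", "test_used",
    "relinfo_rep1", "relinfo_rep2", "relinfo_merged",
    "canonical_count", "divergent_count",
]


@dataclass(frozen=True)
class ScoringParams:
    """Alignment penalty parameters (bowtie2 defaults).

    A mismatch costs MN + floor((MX-MN) * min(Q,40)/40); a gap of length
    N costs GO + N*GE.  ``genomic_preference_margin`` is the pair-score
    margin by which a unique genomic mapping must beat the family
    mapping to win (24 = two full-quality mismatches per read).
    """

    MX: int = 6
    MN: int = 2
    GO: int = 5
    GE: int = 3
    genomic_preference_margin: int = 24

    def __post_init__(self):
        if not (self.MX >= self.MN >= 0):
            raise ValueError("require MX >= MN >= 0")
        if self.GO < 0 or self.GE < 0 or self.genomic_preference_margin < 0:
            raise ValueError("penalties must be non-negative")


class FamilyDatabase:
    """Families of homologous transcripts with priority ranks.

    Each transcript belongs to exactly one family; rank 1 is the primary
    transcript, pseudogenes carry larger ranks.  Reverse-strand mappings
    count toward a paired "antisense" family, except for families in
    ``merged_families`` (simple repeats), which are strand-insensitive.
    """

    def __init__(self, merged_families: set[str] | None = None):
        self.families: dict[str, list[tuple[str, int]]] = {}
        self._transcript_family: dict[str, str] = {}
        self._transcript_priority: dict[str, int] = {}
        self.merged_families = set(merged_families or ())

    def add(self, family_id: str, transcript_id: str, priority: int) -> None:
        if transcript_id in self._transcript_family:
            raise ValueError(f"{transcript_id} already in a family")
        members = self.families.setdefault(family_id, [])
        if any(p == priority for _, p in members):
            raise ValueError(f"duplicate priority {priority} in {family_id}")
        members.append((transcript_id, priority))
        members.sort(key=lambda tp: (tp[1], tp[0]))
        self._transcript_family[transcript_id] = family_id
        self._transcript_priority[transcript_id] = priority

    def family_of(self, transcript_id: str) -> str:
        return self._transcript_family[transcript_id]

    def priority_of(self, transcript_id: str) -> int:
        return self._transcript_priority[transcript_id]

    def antisense_name(self, family_id: str) -> str:
        return family_id + ANTISENSE_SUFFIX

    def effective_family(self, transcript_id: str, strand: str) -> str:
        fam = self.family_of(transcript_id)
        if strand == "-" and fam not in self.merged_families:
            return self.antisense_name(fam)
        return fam

    @classmethod
    def from_table(cls, rows: pd.DataFrame,
                   merged_families: set[str] | None = None) -> "FamilyDatabase":
        """Build from a (family_id, transcript_id, priority) table."""
        db = cls(merged_families)
        for row in rows.itertuples(index=False):
            db.add(str(row.family_id), str(row.transcript_id), int(row.priority))
        return db


@dataclass
class ReadPairAssignment:
    """Final disposition of one read pair."""

    read_id: str
    umi: str
    pair_score: int
    assigned_class: str | None  # family | element-via-genome | region class
    kind: str  # "family" | "genome" | "discarded"
    target: str = ""
    start: int = 0
    stop: int = 0
    strand: str = "+"
    discard_reason: str = "none"  # none | multi_family | pcr_duplicate

    def __post_init__(self):
        if (self.assigned_class is None) != (self.discard_reason != "none"):
            raise ValueError("assigned_class must be set iff not discarded")
        if self.pair_score < 0:
            raise ValueError("pair_score < 0")


def umi_from_read_id(read_id: str) -> str:
    """UMIs are appended to read ids after an underscore (eCLIP convention)."""
    if "_" not in read_id:
        raise ValueError(f"read id {read_id!r} carries no UMI suffix")
    return read_id.rsplit("_", 1)[1]


# ---------------------------------------------------------------------------
# Scoring

def score_alignment(rec: AlignmentRecord, params: ScoringParams) -> int:
    """Penalty of one mate: sum of mismatch and gap penalties."""
    total = 0
    for _, q in rec.mismatches:
        if q < 0:
            raise ValueError(f"negative base quality {q}")
        total += params.MN + math.floor(
            (params.MX - params.MN) * min(q, 40.0) / 40.0)
    for n in rec.gaps:
        total += params.GO + n * params.GE
    return total


def pair_score(records: list[AlignmentRecord], params: ScoringParams) -> int:
    """Pair penalty: sum over both mates' mappings to one target."""
    return sum(score_alignment(r, params) for r in records)


# ---------------------------------------------------------------------------
# Assignment

def resolve_family_assignment(mappings: list[AlignmentRecord],
                              db: FamilyDatabase,
                              params: ScoringParams) -> ReadPairAssignment:
    """Assign one pair's family-transcript mappings to a single family.

    Only minimum-score mappings are kept; equal-best hits to more than
    one family discard the pair; within a family, the highest-priority
    (lowest rank, then lexicographic) transcript is the primary match.
    Reverse-strand hits count toward the antisense family unless the
    family is strand-merged.
    """
    if not mappings:
        raise ValueError("empty mapping list")
    read_id = mappings[0].read_id
    by_target: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in mappings:
        by_target.setdefault((rec.target_id, rec.strand), []).append(rec)
    scored = {key: pair_score(recs, params) for key, recs in by_target.items()}
    best = min(scored.values())
    candidates = [key for key, s in scored.items() if s == best]
    families = {db.effective_family(t, s) for t, s in candidates}
    umi = umi_from_read_id(read_id)
    if len(families) > 1:
        return ReadPairAssignment(read_id, umi, best, None, "discarded",
                                  discard_reason="multi_family")
    tid, strand = min(candidates,
                      key=lambda ts: (db.priority_of(ts[0]), ts[0]))
    recs = by_target[(tid, strand)]
    return ReadPairAssignment(
        read_id, umi, best, families.pop(), "family", target=tid,
        start=min(r.start for r in recs), stop=max(r.end for r in recs),
        strand=strand)


def integrate_with_genomic(family_assignment: ReadPairAssignment | None,
                           genomic_mappings: list[AlignmentRecord] | None,
                           params: ScoringParams) -> ReadPairAssignment | None:
    """Arbitrate between a family assignment and a unique genomic mapping.

    The genomic mapping wins only when it beats the family pair score by
    strictly more than the preference margin (default 24); ties and
    smaller margins keep the family assignment.  Pairs with only one
    mapping kind keep it.
    """
    genomic = None
    if genomic_mappings:
        recs = [r for r in genomic_mappings if r.is_unique_genomic]
        if recs:
            g_score = pair_score(recs, params)
            genomic = ReadPairAssignment(
                recs[0].read_id, umi_from_read_id(recs[0].read_id), g_score,
                "unannotated_genomic", "genome", target=recs[0].target_id,
                start=min(r.start for r in recs),
                stop=max(r.end for r in recs), strand=recs[0].strand)
    fam = family_assignment
    if fam is not None and fam.discard_reason == "multi_family":
        # discarded at the family stage stays discarded
        return fam
    if fam is None:
        return genomic
    if genomic is None:
        return fam
    if fam.pair_score - genomic.pair_score > params.genomic_preference_margin:
        return genomic
    return fam


def deduplicate_pairs(assignments: list[ReadPairAssignment]
                      ) -> list[ReadPairAssignment]:
    """Remove PCR duplicates: one survivor per (target, start, stop, UMI).

    The survivor is the lexicographically smallest read_id in each key
    group; removed pairs are returned too, flagged pcr_duplicate.
    Idempotent.  Discarded assignments pass through untouched.
    """
    groups: dict[tuple, ReadPairAssignment] = {}
    out = []
    for a in assignments:
        if a.discard_reason != "none":
            out.append(a)
            continue
        if not a.umi:
            raise ValueError(f"{a.read_id}: missing UMI")
        key = (a.target, a.start, a.stop, a.umi)
        prev = groups.get(key)
        if prev is None or a.read_id < prev.read_id:
            groups[key] = a
    survivors = {id(a) for a in groups.values()}
    for a in assignments:
        if a.discard_reason != "none":
            continue
        if id(a) in survivors:
            out.append(a)
        else:
            out.append(ReadPairAssignment(
                a.read_id, a.umi, a.pair_score, None, "discarded",
                discard_reason="pcr_duplicate"))
    return out


# ---------------------------------------------------------------------------
# Genomic region annotation

_REGION_PRIORITY = [
    "CDS", "5UTR_and_3UTR", "3UTR", "5UTR", "proximal_intronic",
    "distal_intronic", "noncoding_exonic", "noncoding_proximal_intronic",
    "noncoding_distal_intronic", "antisense_to_transcript", "intergenic",
]


class GenomeAnnotator:
    """Classifies genomic fragments into RepBase families or region classes.

    A fragment overlapping a RepeatMasker element by >= 1 base takes the
    element's family (antisense variant when strands differ); otherwise
    the first matching class in the fixed priority order: CDS, 5'UTR and
    3'UTR, 3'UTR, 5'UTR, proximal intronic (within 500 nt of a splice
    site), distal intronic, their non-coding analogues, antisense to any
    transcript, intergenic.
    """

    PROXIMAL = 500

    def __init__(self, models: list[TranscriptModel],
                 rmsk: list[GenomicInterval],
                 chrom_sizes: dict[str, int] | None = None):
        self.chrom_sizes = chrom_sizes
        self._rmsk: dict[str, IntervalTree] = {}
        for el in rmsk:
            self._rmsk.setdefault(el.chrom, IntervalTree()).addi(
                el.start, el.end, el)
        self._trees: dict[tuple[str, str, str], IntervalTree] = {}
        self._span: dict[str, IntervalTree] = {}
        for m in models:
            self._span.setdefault(m.chrom, IntervalTree()).addi(
                m.start, m.end, m.strand)
            if m.is_coding:
                cs, ce = m.cds_span
                for x in m.exons:
                    s, e = max(x.start, cs), min(x.end, ce)
                    if s < e:
                        self._add(m.chrom, m.strand, "CDS", s, e)
                for iv in m.utr5:
                    self._add(m.chrom, m.strand, "5UTR", iv.start, iv.end)
                for iv in m.utr3:
                    self._add(m.chrom, m.strand, "3UTR", iv.start, iv.end)
                self._add_introns(m, "proximal_intronic", "distal_intronic")
            else:
                for x in m.exons:
                    self._add(m.chrom, m.strand, "noncoding_exonic",
                              x.start, x.end)
                self._add_introns(m, "noncoding_proximal_intronic",
                                  "noncoding_distal_intronic")

    def _add(self, chrom, strand, feature, start, end):
        if start < end:
            self._trees.setdefault((chrom, strand, feature),
                                   IntervalTree()).addi(start, end)

    def _add_introns(self, m: TranscriptModel, prox: str, dist: str):
        for iv in m.introns():
            p = self.PROXIMAL
            if len(iv) <= 2 * p:
                self._add(m.chrom, m.strand, prox, iv.start, iv.end)
            else:
                self._add(m.chrom, m.strand, prox, iv.start, iv.start + p)
                self._add(m.chrom, m.strand, prox, iv.end - p, iv.end)
                self._add(m.chrom, m.strand, dist, iv.start + p, iv.end - p)

    def _hits(self, chrom, strand, feature, start, end) -> bool:
        tree = self._trees.get((chrom, strand, feature))
        return bool(tree and tree.overlap(start, end))

    def classify(self, fragment: GenomicInterval) -> str:
        if self.chrom_sizes is not None:
            size = self.chrom_sizes.get(fragment.chrom)
            if size is None or fragment.end > size:
                raise ValueError(
                    f"fragment {fragment} outside declared chromosomes")
        tree = self._rmsk.get(fragment.chrom)
        if tree:
            hits = sorted(tree.overlap(fragment.start, fragment.end),
                          key=lambda h: (h.begin, h.data.label))
            if hits:
                el = hits[0].data
                fam = el.label
                if fragment.strand != el.strand:
                    fam += ANTISENSE_SUFFIX
                return fam
        c, s, a, b = fragment.chrom, fragment.strand, fragment.start, fragment.end
        if self._hits(c, s, "CDS", a, b):
            return "CDS"
        has5, has3 = self._hits(c, s, "5UTR", a, b), self._hits(c, s, "3UTR", a, b)
        if has5 and has3:
            return "5UTR_and_3UTR"
        if has3:
            return "3UTR"
        if has5:
            return "5UTR"
        for feature in ("proximal_intronic", "distal_intronic",
                        "noncoding_exonic", "noncoding_proximal_intronic",
                        "noncoding_distal_intronic"):
            if self._hits(c, s, feature, a, b):
                return feature
        span = self._span.get(c)
        if span:
            for h in span.overlap(a, b):
                if h.data != s:
                    return "antisense_to_transcript"
        return "intergenic"

    def annotate(self, assignment: ReadPairAssignment) -> ReadPairAssignment:
        """Fill in the region class of a unique-genomic assignment."""
        if assignment.kind != "genome" or assignment.discard_reason != "none":
            return assignment
        frag = GenomicInterval(assignment.target, assignment.start,
                               assignment.stop, assignment.strand)
        assignment.assigned_class = self.classify(frag)
        return assignment


def annotate_genomic_fragment(fragment: GenomicInterval,
                              models: list[TranscriptModel],
                              rmsk: list[GenomicInterval]) -> str:
    """One-shot wrapper around GenomeAnnotator for a single fragment."""
    return GenomeAnnotator(models, rmsk).classify(fragment)


# ---------------------------------------------------------------------------
# Tally + enrichment

@dataclass
class ElementCounts:
    """Per-element deduplicated pair counts for one sample."""

    counts: dict[str, int] = field(default_factory=dict)
    canonical: dict[str, int] = field(default_factory=dict)  # family-assigned
    divergent: dict[str, int] = field(default_factory=dict)  # rmsk-overlap
    total: int = 0


def tally_elements(assignments: list[ReadPairAssignment],
                   family_ids: set[str] | None = None) -> ElementCounts:
    """Count deduplicated pairs per element/region class.

    Family-assigned pairs are "canonical"; unique-genomic pairs whose
    fragment overlapped a RepeatMasker element of the family (already
    annotated with the family label) are "divergent".  The denominator
    is every surviving pair, family plus unique genomic.
    """
    out = ElementCounts()
    for a in assignments:
        if a.discard_reason != "none":
            continue
        cls = a.assigned_class
        out.counts[cls] = out.counts.get(cls, 0) + 1
        out.total += 1
        base = cls.removesuffix(ANTISENSE_SUFFIX)
        is_family_class = family_ids is None or base in family_ids
        if is_family_class and cls not in _REGION_PRIORITY \
                and cls != "unannotated_genomic":
            which = out.canonical if a.kind == "family" else out.divergent
            which[cls] = which.get(cls, 0) + 1
    return out


def relative_information(p: float, q: float) -> float:
    """p * log2(p/q): element i's contribution to KL(IP || input)."""
    if not (0 < p <= 1) or not (0 < q <= 1):
        raise ValueError("p and q must be in (0, 1] after pseudocounting")
    return p * math.log2(p / q)


def _frac(count: int, total: int) -> float:
    """Fraction with the zero-count pseudocount (add 1 read when 0)."""
    if count == 0:
        return 1.0 / (total + 1)
    return count / total


def _significance(k_ip: int, n_ip: int, k_in: int, n_in: int):
    """2x2 (element vs rest) x (IP vs input): chi-square when all observed
    and expected are >= 5, else two-sided Fisher."""
    table = np.array([[k_ip, n_ip - k_ip], [k_in, n_in - k_in]])
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    if (table >= 5).all() and (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        return p, "chi2"
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return p, "fisher"


def element_enrichment(ip_counts: list[ElementCounts],
                       input_counts: ElementCounts) -> pd.DataFrame:
    """Per-element fold enrichment, significance and relative information.

    ``ip_counts`` holds one ElementCounts per IP replicate (two in the
    standard design).  Folds and relative information are computed per
    replicate and replicate-merged (average IP RPM vs input RPM);
    significance uses pooled IP counts.
    """
    if input_counts.total == 0 or any(c.total == 0 for c in ip_counts):
        raise ValueError("zero total reads in a sample")
    universe = sorted(set(input_counts.counts)
                      | set().union(*(c.counts for c in ip_counts)))
    rows = []
    for el in universe:
        ip_k = [c.counts.get(el, 0) for c in ip_counts]
        in_k = input_counts.counts.get(el, 0)
        q = _frac(in_k, input_counts.total)
        ps = [_frac(k, c.total) for k, c in zip(ip_k, ip_counts)]
        folds = [p / q for p in ps]
        ris = [relative_information(p, q) for p in ps]
        p_merged = float(np.mean(ps))
        pval, test = _significance(sum(ip_k), sum(c.total for c in ip_counts),
                                   in_k, input_counts.total)
        canon = sum(c.canonical.get(el, 0) for c in ip_counts)
        diverg = sum(c.divergent.get(el, 0) for c in ip_counts)
        rows.append({
            "element": el,
            "ip_rep1_count": ip_k[0],
            "ip_rep2_count": ip_k[1] if len(ip_k) > 1 else 0,
            "input_count": in_k,
            "fold_rep1": folds[0],
            "fold_rep2": folds[1] if len(folds) > 1 else float("nan"),
            "fold_merged": p_merged / q,
            "p_value": pval,
            "test_used": test,
            "relinfo_rep1": ris[0],
            "relinfo_rep2": ris[1] if len(ris) > 1 else float("nan"),
            "relinfo_merged": relative_information(p_merged, q),
            "canonical_count": canon,
            "divergent_count": diverg,
        })
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Whole-sample driver

def assign_sample(records, db: FamilyDatabase, params: ScoringParams,
                  annotator: GenomeAnnotator | None = None
                  ) -> list[ReadPairAssignment]:
    """Run one sample end to end: group mappings by pair, resolve family
    vs genomic, deduplicate, and annotate unique-genomic fragments."""
    family_maps: dict[str, list[AlignmentRecord]] = {}
    genome_maps: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    seen: set[str] = set()
    for rec in records:
        if rec.read_id not in seen:
            seen.add(rec.read_id)
            order.append(rec.read_id)
        bucket = family_maps if rec.target_kind == "family_transcript" \
            else genome_maps
        bucket.setdefault(rec.read_id, []).append(rec)
    assignments = []
    for rid in order:
        fam = None
        if rid in family_maps:
            fam = resolve_family_assignment(family_maps[rid], db, params)
        final = integrate_with_genomic(fam, genome_maps.get(rid), params)
        if final is not None:
            assignments.append(final)
    assignments = deduplicate_pairs(assignments)
    if annotator is not None:
        assignments = [annotator.annotate(a) for a in assignments]
    return assignments
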