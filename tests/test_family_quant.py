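import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eclip_atlas import family_quant as fq
from eclip_atlas.core_io import AlignmentRecord, GenomicInterval
from conftest import random_alignment_record


def oracle_score(mismatch_quals, gap_lengths, p=fq.ScoringParams()):
    """Independent recomputation of the penalty from raw quality/gap lists."""
    s = 0.0
    for q in mismatch_quals:
        s += p.MN + math.floor((p.MX - p.MN) * min(q, 40.0) / 40.0)
    for n in gap_lengths:
        s += p.GO + n * p.GE
    return int(s)


def rec(read_id, target, mismatches=(), gaps=(), strand="+", mate=1,
        kind="family_transcript", start=0, end=50, unique=False):
    return AlignmentRecord(read_id, mate, target, kind, start, end, strand,
                           mismatches=list(mismatches), gaps=list(gaps),
                           is_unique_genomic=unique)


@pytest.fixture()
def db():
    d = fq.FamilyDatabase(merged_families={"SimpleRepeat"})
    d.add("famA", "famA-tx1", 1)
    d.add("famA", "famA-ps1", 2)
    d.add("famB", "famB-tx1", 1)
    d.add("SimpleRepeat", "SR-1", 1)
    return d


class TestScoring:
    @pytest.mark.parametrize("mismatches,gaps,expected", [
        ([(0, 40)], [], 6),            # full-quality mismatch costs MX
        ([(0, 20)], [], 4),            # 2 + floor(4 * 0.5)
        ([(0, 41)], [], 6),            # Q capped at 40
        ([], [2], 11),                 # 5 + 2*3
        ([(0, 40), (5, 20)], [1, 3], 32),  # 6+4 + (5+3)+(5+9)
        ([], [], 0),
    ])
    def test_penalty_examples(self, mismatches, gaps, expected,
                              scoring_params):
        r = rec("r_A", "t", mismatches, gaps)
        assert fq.score_alignment(r, scoring_params) == expected

    def test_negative_quality_rejected(self, scoring_params):
        r = rec("r_A", "t")
        r.mismatches = [(0, -1)]
        with pytest.raises(ValueError):
            fq.score_alignment(r, scoring_params)

    def test_matches_independent_oracle_on_random_records(self,
                                                          scoring_params):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            r = random_alignment_record(rng)
            assert fq.score_alignment(r, scoring_params) == oracle_score(
                [q for _, q in r.mismatches], r.gaps)


class TestResolveFamily:
    def test_strict_minimum_wins(self, db, scoring_params):
        maps = [rec("r_A", "famA-tx1", [(0, 40)]),        # score 6
                rec("r_A", "famB-tx1", [(0, 40), (1, 40)])]  # score 12
        a = fq.resolve_family_assignment(maps, db, scoring_params)
        assert a.assigned_class == "famA" and a.discard_reason == "none"

    def test_equal_best_across_families_discards(self, db, scoring_params):
        maps = [rec("r_A", "famA-tx1", [(0, 40)]),
                rec("r_A", "famB-tx1", [(0, 40)])]
        a = fq.resolve_family_assignment(maps, db, scoring_params)
        assert a.discard_reason == "multi_family"
        assert a.assigned_class is None

    def test_primary_prioritized_within_family(self, db, scoring_params):
        maps = [rec("r_A", "famA-ps1", [(0, 40)]),
                rec("r_A", "famA-tx1", [(0, 40)])]
        a = fq.resolve_family_assignment(maps, db, scoring_params)
        assert a.target == "famA-tx1" and a.assigned_class == "famA"

    def test_reverse_strand_maps_to_antisense_family(self, db,
                                                     scoring_params):
        a = fq.resolve_family_assignment(
            [rec("r_A", "famA-tx1", strand="-")], db, scoring_params)
        assert a.assigned_class == "famA_antisense"

    def test_merged_family_is_strand_insensitive(self, db, scoring_params):
        a = fq.resolve_family_assignment(
            [rec("r_A", "SR-1", strand="-")], db, scoring_params)
        assert a.assigned_class == "SimpleRepeat"

    def test_sense_antisense_tie_is_multi_family(self, db, scoring_params):
        maps = [rec("r_A", "famA-tx1", strand="+"),
                rec("r_A", "famA-tx1", strand="-")]
        a = fq.resolve_family_assignment(maps, db, scoring_params)
        assert a.discard_reason == "multi_family"

    def test_empty_mapping_list_rejected(self, db, scoring_params):
        with pytest.raises(ValueError):
            fq.resolve_family_assignment([], db, scoring_params)


class TestGenomicIntegration:
    def fam_assignment(self, score):
        return fq.ReadPairAssignment("r_A", "A", score, "famA", "family",
                                     target="famA-tx1", start=0, stop=50)

    def genomic(self, read_id="r_A", mismatches=()):
        return [rec(read_id, "chr1", mismatches, kind="genome", unique=True)]

    def test_margin_beyond_24_switches_to_genomic(self, scoring_params):
        out = fq.integrate_with_genomic(self.fam_assignment(30),
                                        self.genomic(), scoring_params)
        assert out.kind == "genome"

    def test_margin_exactly_24_keeps_family(self, scoring_params):
        out = fq.integrate_with_genomic(self.fam_assignment(24),
                                        self.genomic(), scoring_params)
        assert out.kind == "family" and out.assigned_class == "famA"

    def test_genomic_only_pair_kept(self, scoring_params):
        out = fq.integrate_with_genomic(None, self.genomic(), scoring_params)
        assert out.kind == "genome"

    def test_family_only_pair_kept(self, scoring_params):
        out = fq.integrate_with_genomic(self.fam_assignment(3), None,
                                        scoring_params)
        assert out.assigned_class == "famA"

    def test_non_unique_genomic_ignored(self, scoring_params):
        g = [rec("r_A", "chr1", kind="genome", unique=False)]
        out = fq.integrate_with_genomic(self.fam_assignment(100), g,
                                        scoring_params)
        assert out.kind == "family"


class TestDedup:
    def asn(self, read_id, umi, target="t", start=0, stop=50):
        return fq.ReadPairAssignment(read_id, umi, 0, "famA", "family",
                                     target=target, start=start, stop=stop)

    def test_identical_key_keeps_one(self):
        out = fq.deduplicate_pairs([self.asn(f"r{i}_AAAA", "AAAA")
                                    for i in range(3)])
        kept = [a for a in out if a.discard_reason == "none"]
        dups = [a for a in out if a.discard_reason == "pcr_duplicate"]
        assert len(kept) == 1 and len(dups) == 2
        assert kept[0].read_id == "r0_AAAA"  # lexicographic survivor

    def test_distinct_umis_both_kept(self):
        out = fq.deduplicate_pairs([self.asn("r1_AAAA", "AAAA"),
                                    self.asn("r2_CCCC", "CCCC")])
        assert all(a.discard_reason == "none" for a in out)

    def test_empty_input(self):
        assert fq.deduplicate_pairs([]) == []

    def test_missing_umi_rejected(self):
        a = self.asn("r1_AAAA", "AAAA")
        a.umi = ""
        with pytest.raises(ValueError):
            fq.deduplicate_pairs([a])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 2)),
                    min_size=0, max_size=20))
    def test_idempotent_and_key_unique(self, keys):
        assignments = [self.asn(f"r{i}_U{u}", f"U{u}", start=s)
                       for i, (s, u) in enumerate(keys)]
        once = fq.deduplicate_pairs(assignments)
        twice = fq.deduplicate_pairs(
            [a for a in once if a.discard_reason == "none"])
        kept_once = {(a.target, a.start, a.stop, a.umi)
                     for a in once if a.discard_reason == "none"}
        assert len(kept_once) == sum(
            1 for a in once if a.discard_reason == "none")
        assert all(a.discard_reason == "none" for a in twice)


class TestRegionAnnotation:
    @pytest.fixture()
    def annotator(self, coding_model):
        rmsk = [GenomicInterval("chr1", 150, 180, "+", "L1")]
        return fq.GenomeAnnotator([coding_model], rmsk, {"chr1": 1000})

    def test_rmsk_overlap_beats_everything(self, annotator):
        # one base of overlap with the element suffices
        assert annotator.classify(
            GenomicInterval("chr1", 179, 210, "+")) == "L1"

    def test_antisense_element(self, annotator):
        assert annotator.classify(
            GenomicInterval("chr1", 155, 170, "-")) == "L1_antisense"

    def test_cds_beats_utr(self, annotator):
        # spans the 5'UTR/CDS boundary at 20
        assert annotator.classify(
            GenomicInterval("chr1", 10, 30, "+")) == "CDS"

    def test_utr5_and_utr3_class(self):
        from eclip_atlas.core_io import TranscriptModel
        t1 = TranscriptModel("g1", "t1", "chr1", "+",
                             [GenomicInterval("chr1", 0, 100)],
                             cds_span=(5, 40))   # 3'UTR = [40,100)
        t2 = TranscriptModel("g2", "t2", "chr1", "+",
                             [GenomicInterval("chr1", 20, 200)],
                             cds_span=(120, 195))  # 5'UTR = [20,120)
        ann = fq.GenomeAnnotator([t1, t2], [])
        frag = GenomicInterval("chr1", 50, 60, "+")  # both UTRs, no CDS
        assert ann.classify(frag) == "5UTR_and_3UTR"

    def test_proximal_vs_distal_intron(self):
        from eclip_atlas.core_io import TranscriptModel
        m = TranscriptModel("g", "t", "chr1", "+",
                            [GenomicInterval("chr1", 0, 100),
                             GenomicInterval("chr1", 1400, 1500)],
                            cds_span=(10, 1490))
        ann = fq.GenomeAnnotator([m], [])
        # 400 nt from the 5' splice site -> proximal
        assert ann.classify(
            GenomicInterval("chr1", 480, 500, "+")) == "proximal_intronic"
        assert ann.classify(
            GenomicInterval("chr1", 640, 660, "+")) == "distal_intronic"

    def test_antisense_and_intergenic(self, annotator):
        assert annotator.classify(
            GenomicInterval("chr1", 40, 60, "-")) == "antisense_to_transcript"
        assert annotator.classify(
            GenomicInterval("chr1", 500, 520, "+")) == "intergenic"

    def test_out_of_bounds_rejected(self, annotator):
        with pytest.raises(ValueError):
            annotator.classify(GenomicInterval("chr1", 900, 1100, "+"))


class TestTally:
    def test_family_plus_divergent_additivity(self):
        asn = []
        for i in range(10):
            asn.append(fq.ReadPairAssignment(f"f{i}_A", "A", 0, "famA",
                                             "family"))
        for i in range(5):
            asn.append(fq.ReadPairAssignment(f"g{i}_A", "A", 0, "famA",
                                             "genome"))
        counts = fq.tally_elements(asn, {"famA"})
        assert counts.counts["famA"] == 15
        assert counts.canonical["famA"] == 10
        assert counts.divergent["famA"] == 5

    def test_classes_partition_total(self, library, famdb, genome,
                                     scoring_params):
        annot = fq.GenomeAnnotator(genome.models, genome.rmsk)
        asn = fq.assign_sample(library.samples["input"], famdb.db,
                               scoring_params, annot)
        counts = fq.tally_elements(asn, set(famdb.db.families))
        assert sum(counts.counts.values()) == counts.total
        assert counts.total == sum(1 for a in asn
                                   if a.discard_reason == "none")

    def test_zero_assignments(self):
        counts = fq.tally_elements([])
        assert counts.total == 0 and counts.counts == {}


class TestRelativeInformation:
    @pytest.mark.parametrize("p,q,expected", [
        (0.3, 0.3, 0.0),
        (0.5, 0.25, 0.5),
        (0.1, 0.2, -0.1),
    ])
    def test_examples(self, p, q, expected):
        assert fq.relative_information(p, q) == pytest.approx(expected)

    def test_domain_errors(self):
        for p, q in [(0.0, 0.5), (0.5, 0.0), (1.5, 0.5)]:
            with pytest.raises(ValueError):
                fq.relative_information(p, q)

    def test_kl_nonnegativity_over_random_tables(self):
        """Sum_i p_i log2(p_i/q_i) >= 0 for any pair of count tables."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 12))
            ip = rng.integers(1, 1000, size=k).astype(float)
            inp = rng.integers(1, 1000, size=k).astype(float)
            p, q = ip / ip.sum(), inp / inp.sum()
            kl = sum(fq.relative_information(pi, qi)
                     for pi, qi in zip(p, q))
            assert kl >= -1e-12


def fisher_oracle_two_sided(table):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)
                / math.comb(n, c1))

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-7))


def chi2_oracle(table):
    """Pearson chi-square (no correction) with df=1 p via erfc."""
    t = np.asarray(table, dtype=float)
    exp = t.sum(1, keepdims=True) * t.sum(0, keepdims=True) / t.sum()
    stat = ((t - exp) ** 2 / exp).sum()
    return math.erfc(math.sqrt(stat / 2.0))


class TestElementEnrichment:
    def counts(self, d, total=None):
        c = fq.ElementCounts(counts=dict(d))
        c.total = total if total is not None else sum(d.values())
        return c

    def test_fold_from_fractions(self):
        ip = self.counts({"famA": 90, "other": 10})
        inp = self.counts({"famA": 50, "other": 50})
        table = fq.element_enrichment([ip], inp)
        row = table.set_index("element").loc["famA"]
        assert row["fold_rep1"] == pytest.approx(1.8)

    def test_merged_fold_averages_rpm(self):
        # replicate fractions 0.2 and 0.4 vs input 0.1 -> merged fold 3.0
        ip1 = self.counts({"famA": 20, "other": 80})
        ip2 = self.counts({"famA": 40, "other": 60})
        inp = self.counts({"famA": 10, "other": 90})
        row = fq.element_enrichment([ip1, ip2], inp).set_index(
            "element").loc["famA"]
        assert row["fold_merged"] == pytest.approx(3.0)

    def test_significance_matches_enumeration_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = rng.integers(0, 15, size=2)
            c, d = rng.integers(0, 15, size=2)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p, test = fq._significance(a, a + b, c, c + d)
            t = np.array([[a, b], [c, d]])
            exp = t.sum(1, keepdims=True) * t.sum(0, keepdims=True) / t.sum()
            if (t >= 5).all() and (exp >= 5).all():
                assert test == "chi2"
                assert p == pytest.approx(chi2_oracle(t), rel=1e-9)
            else:
                assert test == "fisher"
                assert p == pytest.approx(fisher_oracle_two_sided(t),
                                          rel=1e-6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fq.element_enrichment([self.counts({})],
                                  self.counts({"famA": 5}))


class TestGroundTruthRecovery:
    def test_error_free_assignments_match_provenance(self, library, famdb,
                                                     genome, scoring_params):
        annot = fq.GenomeAnnotator(genome.models, genome.rmsk)
        for sample in ("ip1", "input"):
            asn = fq.assign_sample(library.samples[sample], famdb.db,
                                   scoring_params, annot)
            checked = 0
            for a in asn:
                if a.discard_reason != "none":
                    continue
                assert a.assigned_class == \
                    library.truth.read_provenance[a.read_id]
                checked += 1
            assert checked > 0
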