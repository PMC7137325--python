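# eclip-atlas

Analysis methods for interpreting eCLIP protein–RNA interaction maps:
family-aware quantification of multicopy RNA elements, meta-gene and
meta-exon peak-density profiles, branch-point identification from
reverse-transcription truncation, normalized splicing maps at
alternative 3′ splice sites, and cross-dataset RBP association
statistics. Every analysis can be exercised on synthetic data with
planted ground truth, so the full pipeline is testable without any
download.

## Who this is for

CLIP-seq pipelines that require unique genomic mapping discard the
large read fraction arising from rRNA, snRNA, snoRNA, Y RNA,
retrotransposons and other multicopy elements. This package is for
computational biologists who want those reads quantified: reads are
assigned to *families* of homologous transcripts by alignment penalty

    mismatch: MN + floor((MX − MN) · min(Q, 40)/40)   (MX=6, MN=2)
    gap:      GO + N·GE                               (GO=5, GE=3)

with pairs tied across families discarded, family hits reconciled
against unique genomic mappings (genomic wins only when better by > 24,
i.e. two full mismatches per read), PCR duplicates removed by
(position, UMI), and each element i scored against the size-matched
input by fold enrichment p_i/q_i and **relative information**

    RI_i = p_i · log2(p_i / q_i)

— element i's contribution to the Kullback–Leibler divergence between
the IP and input read-fraction distributions. Significance uses
Pearson's chi-square when all observed and expected counts are ≥ 5,
else Fisher's exact test.

Downstream modules build 162-bin meta-mRNA and splice-site-anchored
meta-exon profiles with bootstrap bands, call branch points as
positions where > 50% of ≥ 20 window reads share one 5′ end (reverse
transcriptase stops one base 3′ of the branch adenosine), compute
input-subtracted sum-one-normalized splicing maps with trimmed means
and native-event confidence bands, and quantify peak co-occurrence and
RBP-target enrichment across datasets.

## Worked example

Simulate a small eCLIP experiment (two IP replicates + size-matched
input) with a planted 5-fold enrichment of the 18S rRNA family, run the
family-aware pipeline, and inspect the enrichment table:

```python
from eclip_atlas import simulate, family_quant as fq

cfg = simulate.SimConfig(seed=1, n_families=6, pseudogenes_per_family=3,
                         depth=20_000, per_base_error_rate=0.0,
                         enrichment={"RNA18S": 5.0})
famdb  = simulate.build_family_database(cfg)
genome = simulate.simulate_genome_annotation(cfg, famdb)
lib    = simulate.simulate_eclip_library(cfg, famdb, genome)

params    = fq.ScoringParams()
annotator = fq.GenomeAnnotator(genome.models, genome.rmsk)
counts = {s: fq.tally_elements(
              fq.assign_sample(recs, famdb.db, params, annotator),
              set(famdb.db.families))
          for s, recs in lib.samples.items()}
table = fq.element_enrichment([counts["ip1"], counts["ip2"]],
                              counts["input"])
print(table.set_index("element")
           .loc["RNA18S", ["fold_merged", "relinfo_merged", "test_used"]])
```

Output:

```
fold_merged       5.130674
relinfo_merged    1.813183
test_used             chi2
```

The replicate-merged fold recovers the planted 5× enrichment (5.13,
binomial error at this depth), and the relative information of 1.81
bits reflects both the enrichment and the large IP read share the
family captures; the 2×2 test used chi-square because every cell was
well above 5. Checking assignments against the simulation's truth
table shows 100% of non-discarded pairs match their planted source at
zero sequencing error.

A thin CLI wraps the same entry points:

```bash
eclip-atlas simulate library --seed 5 --out-dir fixtures --depth 3000
eclip-atlas quantify --ip1 fixtures/ip1.aln.tsv --ip2 fixtures/ip2.aln.tsv \
    --input fixtures/input.aln.tsv --db families.tsv \
    --rmsk fixtures/rmsk.bed --gtf fixtures/annotation.gtf --out enrich.tsv
eclip-atlas branchpoint --alignments bp.aln.tsv --gtf annotation.gtf \
    --fasta genome.fa --out-prefix bp
```

## Layout

| module | contents |
| --- | --- |
| `eclip_atlas.core_io` | GTF/BED/narrowPeak/SAM/FASTA readers-writers, the tabular alignment dialect, domain types |
| `eclip_atlas.simulate` | synthetic families, genome, libraries, branch-point pileups, A3SS events, association fixtures — all with planted truth |
| `eclip_atlas.family_quant` | penalty scoring, family resolution, genomic integration, UMI dedup, region classes, enrichment statistics |
| `eclip_atlas.profiles` | representative transcripts, meta-gene/meta-exon profiles, position-wise relative information, paralog read attribution |
| `eclip_atlas.branchpoint` | 3′SS windows, branch-point calls, motif matrices |
| `eclip_atlas.splicing_map` | event-normalized densities, trimmed-mean maps, native control bands |
| `eclip_atlas.association` | peak overlap, running-sum enrichment, cutoff sweeps, contingency tests, expression shifts, RBP-target enrichment |

See `docs/methods.md` for the full model description, parameter
defaults, and known limitations.
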