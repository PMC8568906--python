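# recurvar

Recurrent-indel analysis in homopolymer runs, built around a genotype-first
search for a recurrent single-guanine duplication in *SHANK3* exon 21 that is
strongly associated with Autism Spectrum Disorder (ASD).

## The problem

Indels inside a homopolymer run (HR: six or more identical nucleotides) have
many equivalent coordinate spellings. An extra G in a run of 8 Gs can be
written as a left-aligned anchored record (`chr22-50721503-50721504-T-TG`,
the NGS/VCF convention), a most-3′ duplication (`chr22:g.50721512dup`, the
HGVS/Sanger convention), or anything in between — and the spelling also
changes with genome build (hg19 vs hg38) and transcript (`c.3679dup`,
`c.3676dup`, `c.3727dup`). A recurrence search that groups variants by
"exactly the same genomic location" silently undercounts unless all spellings
are first reduced to one identity. `recurvar` provides that reduction and the
downstream statistics:

* **`recurvar.normalize`** — homopolymer-run detection, VCF left alignment,
  the HGVS 3′-rule (strand-aware), a canonical `NormalizedVariantKey`
  (left-aligned parsimonious core), cross-build equivalence via an explicit
  anchor table, and genomic → cDNA projection on exon models.
* **`recurvar.recurrence`** — the rare (AF < 0.001) de novo damaging filter,
  cross-cohort individual deduplication, recurrence grouping by canonical
  key, carrier frequencies as exact rationals with half-even percentage
  rounding, a from-scratch exact conditional (Fisher) test in log-factorial
  space, and tri-state (yes / no / not assessed) phenotype matrices.
* **`recurvar.mosaic`** — variant allele fraction with Clopper–Pearson
  intervals, an absent / possible_mosaic / mosaic / heterozygous /
  ambiguous decision table built on two exact binomial tests (two-sided
  against the heterozygous 0.5, one-sided against the sequencing error
  rate), cross-platform pooling, and a simplified trio de novo posterior
  (ppDNM) from Hardy–Weinberg priors, Mendelian transmission with a
  per-gamete mutation rate, and binomial read likelihoods.
* **`recurvar.consequence`** — CDS editing (dup/del/ins/sub in cDNA
  coordinates), translation, HGVS protein names (`p.Ala1227Glyfs*69`), and
  per-domain intact / truncated / lost calls.
* **`recurvar.idr`** — disordered-region sequence features: sequence charge
  decoration SCD = (1/N) Σ_{m>n} q_m q_n √(m−n), overlapping RG/RR dipeptide
  counts, residue fractions, SH3 class I motif (`[RK]xxPxxP`) counts, and
  wild-type vs variant deltas.
* **`recurvar.synthetic`** — toy references with planted runs, simulated trio
  cohorts with mosaic parents and randomized variant spellings, and the
  packaged fixture tables (annotation rows, 19 + 6 carrier records,
  18 phenotype records, the exon-21 context window, build anchors).

Real controlled-access cohort data is never required: the carrier and
phenotype tables ship as transcribed TSV fixtures, and the transcript-scale
worked examples run on a deterministic synthetic stand-in CDS that
reproduces every documented property of the real exon-21 context.

## Worked example

```python
import recurvar as rv

ref = rv.context_contig("hg38")          # packaged exon-21 window
v_sanger = rv.GenomicVariant("chr22", 50721512, "G", "GG", "hg38", "hgvs_dup")
v_ngs    = rv.GenomicVariant("chr22", 51159932, "T", "TG", "hg19")

rv.variants_equivalent(v_ngs, v_sanger, rv.context_contig("hg19"),
                       rv.load_fixture("build_anchors"))
# True — both spellings are the same extra G in the 8-G run

cds = rv.make_shank3_like_cds()          # synthetic stand-in CDS
rv.frameshift_consequence(cds, rv.CdsEdit("dup", 3679)).hgvs_p
# 'p.Ala1227Glyfs*69'  (new reading frame ends at stop position 69)
rv.frameshift_consequence(cds, rv.CdsEdit("del", 3679)).hgvs_p
# 'p.Ala1227Profs*57'

rv.classify_parent(rv.ReadCounts(8, 50)).classification
# 'mosaic'  (VAF 0.16: heterozygous null and error null both rejected)
rv.combine_evidence([rv.ReadCounts(1, 32), rv.ReadCounts(2, 110)]).classification
# 'mosaic'  (pooled 3/142 across WGS + exome platforms)
```

Running the pipeline over the packaged carrier table restricted to the two
genome-sequenced cohorts gives one recurrence group of 6 individuals from 5
families; with the cohort denominators 7,521 affected individuals and 6,681
families this prints carrier frequencies `0.08%` and `0.07%`. The phenotype
table yields 17 carriers with a completed formal ASD assessment, all
positive.

A thin CLI mirrors the library (`recurvar simulate | normalize | equivalent |
project | recur | mosaic | consequence | features`), e.g.

```bash
recurvar mosaic --alt 1 --depth 32 --alt 2 --depth 110
# {"alt": 3, "depth": 142, ..., "classification": "mosaic"}
```

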