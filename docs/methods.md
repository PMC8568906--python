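# Methods

## Variant identity in homopolymer runs

A homopolymer run (HR) is a maximal stretch of ≥ `min_run_length` identical
nucleotides; the default of 6 follows the standard HR definition under which
indel mutation rates are strongly elevated. Detection is a linear scan over
the sequence and is checked against a brute-force regex oracle in the tests.

A single-base insertion inside a run of length L has L + 1 placements plus
anchored and unanchored renderings, all denoting one edit. The package
represents every spelling as a replacement of `ref` by `alt` at a 1-based,
fully closed plus-strand coordinate and derives:

* **left alignment** (VCF convention): trim the shared affix to a
  parsimonious core, then roll a pure-indel core leftward while the base
  entering from the left equals the base leaving on the right; re-anchor on
  the preceding base. Cross-checked against `bcftools norm` and against an
  exhaustive spelling-enumeration oracle in the tests; idempotent.
* **3′ shifting** (HGVS rule): the mirror-image roll, applied in transcript
  orientation for cDNA naming — on a minus-strand transcript the 3′-rule
  therefore moves toward *lower* genomic coordinates. Insertions that copy
  the immediately preceding reference segment render as duplications.
* **canonical key**: the left-aligned parsimonious core
  (contig, build, position, deleted core, inserted core). The left-aligned
  form was chosen as the identity because it is anchor-free and
  build-translatable; the 3′ rendering varies by annotation tool and is
  treated as presentation. `run_span` marks the containing HR when the core
  is a uniform-base indel inside one.

Cross-build comparison goes through an explicit anchor table (pairs of
equivalent positions, constant offset trusted within ±500 bp of an anchor).
This deliberately replaces chain-file liftover: the packaged analyses live
in an 81-bp window, and a comparison outside anchor coverage raises an
explicit "unmappable" error rather than returning false.

Genomic → cDNA projection maps the edit core through a two-sided exon model
(ordered exon intervals, transcript-relative CDS bounds), re-shifts on the
spliced sequence under the requested rule, and reports `c.Ndup` / `c.Ndel` /
`c.N_MinsX`, or an explicit non-coding result. Only the HGVS subset used in
annotation tables is parsed (`g.Ndup`, `g.Ndel`, `g.N_MinsSEQ`, anchored
pos-ref-alt); a full HGVS grammar is out of scope.

## Recurrence pipeline

Records qualify when they are de novo-like, rare, and damaging. Transmission
through a somatically mosaic parent is counted as de novo-like: it is a
fresh mutational event in the family, and the inheritance flag is retained
in the output. Missing population allele frequency is treated as 0 (absent
from controls) — conservative for a rarity filter. The defaults
(AF < 0.001; damaging = stop-gain, frameshift, canonical-splice,
predicted-damaging missense) are configuration, not annotation: consequence
class is an input.

Deduplication closes `same_individual_as` links with union–find, keeps the
first record of each component, retains merged source labels, and raises if
linked records carry non-equivalent variants. Grouping maps every record to
its canonical key; records reported only as coding changes (common in the
literature rows) are reconciled through a (transcript accession, c-spelling)
→ key map derived from the packaged annotation table. Unmappable records
raise rather than vanish. Carrier counting is per deduplicated individual;
families are distinct `family_id`s (siblings share one; a mosaic parent is
not a carrier case).

Frequencies are exact rationals; percentages are rendered with banker's
(half-even) rounding at 2 decimals by default (a 3-decimal rendering is one
flag away). The packaged carrier table reproduces 6/7,521 → 0.08% and
5/6,681 → 0.07%.

The association test is a from-scratch exact conditional test on a 2×2
table: hypergeometric probabilities accumulated in log-factorial
(`lgamma`) space, two-sided by summing all tables (fixed margins) with
probability ≤ the observed one, with a 1e-9 log-space tolerance for ties.
Exhaustive comparison against exact-rational enumeration over all 135,750
tables with total ≤ 40 shows max |Δp| ≈ 4e-14; `scipy.stats.fisher_exact`
serves as a second, independent cross-check. The published association
p-value for this variant cannot be reproduced exactly because the exact
contingency table behind it is not specified; the package computes the test
for any user-stated table, and the direction check on the printed carrier
counts (6 of 7,521 cases vs 16 of 160,994 control alleles) is significant
at 0.05 however the table is formed.

Phenotypes are strictly tri-state (`yes` / `no` / `not_assessed`) because
absence of a phenotype and absence of an assessment are different facts;
tallies conserve counts per category, and matrix rows keep family grouping.

## Mosaicism statistics

VAF is alt/depth with an exact Clopper–Pearson interval (beta-quantile
inversion of the binomial tails). Parent classification uses two exact
binomial tests: two-sided against p = 0.5 (heterozygous null) and one-sided
upper-tail against p = error_rate (absent null). Decision table: both
rejected → mosaic (only when VAF < 0.5 — mosaicism is sub-heterozygous by
definition; a significant excess above 0.5 is reported ambiguous); het only
→ absent (VAF ≤ error rate) or possible_mosaic; error only → heterozygous;
neither → ambiguous. Evidence from independent platforms is pooled by
summing counts before testing (no overdispersion term; an overdispersed
beta-binomial is a natural extension, not implemented).

Defaults: error_rate 0.005, alpha 0.05, 95% intervals, per-gamete mutation
rate 1e-8. These are stated, configurable values; the source read counts
come with no printed test statistics, so classification is validated against
this stated model and simulation, not against published p-values. Under the
defaults the documented counts behave as described qualitatively: 8/50 →
mosaic; 1/32 alone is not separable from sequencing error (p ≈ 0.15) but
pooled with 2/110 (3/142) it is (p ≈ 0.035).

The trio de novo posterior is an explicitly simplified stand-in for a full
trio caller: Hardy–Weinberg parental genotype priors at the supplied
population frequency, Mendelian transmission with symmetric per-gamete
mutation rate μ, binomial read likelihoods with genotype alt fractions
(error, 0.5, 1 − error), posterior normalized over the 27 trio genotype
configurations. ppDNM is the mass on configurations in which the child
carries an alt allele absent from both parental genotypes. The conventional
0.8 reporting threshold is a configuration value, not a model constant.

**Discreteness caveat.** The exact binomial test is conservative: at depth
50 and alpha 0.05 the attainable two-sided size is 0.0328, and the next
achievable size (mid-p) is 0.0649 — no deterministic exact-style test has
size 0.05 at that depth, only a randomized test does. Calibration tests
therefore assert that the empirical type-I rate equals the analytic size of
the discrete rejection region and never exceeds alpha, rather than that it
equals alpha. Detection is not fragile to this: simulated mosaic parents at
fraction 0.1 and depth 100 are called mosaic in ≈ 99.8% of replicates.

## Frameshift consequences

`apply_cds_edit` is a pure string edit (dup copies the base at the given
cDNA position after itself; del removes it); well-formedness of the
wild-type CDS (ATG start, length divisible by 3, terminal stop) is enforced
where a consequence is named, so intermediate sequences can be re-edited
(round-trip dup→del). Translation uses the standard genetic code. The first
changed residue is the first position where wild-type and variant
translations differ — for repeat-region edits this coincides with the HGVS
3′-most name, because repeat-encoded residues are unchanged up to the last
repeat codon. `fs*N` counts the new stop with the first changed residue as
1; a new frame that reaches the transcript end without a stop is reported
`no_stop` with its translated tail, not as an error. A ±1 frameshift can
never be synonymous (property-tested). Domain status is interval algebra on
the wild-type protein: entirely 5′ of the first changed residue → intact,
spanning it → truncated, entirely 3′ → lost; domain coordinates are an
editable fixture, not a prediction.

## Disordered-region features

SCD follows the Sawle–Ghosh definition, (1/N) Σ_{m>n} q_m q_n √(m−n), over
the full supplied sequence; callers wanting an IDR window pass the window
(disorder prediction is out of scope). The default charge assignment is
D,E → −1; K,R → +1; H → 0 (His titrates near physiological pH; the
assignment is configurable). Dipeptides and motifs use overlapping counts —
"instances" is ambiguous, so the inclusive convention is declared and
tested; the shipped motif table contains the SH3 class I consensus
[RK]xxPxxP and is extensible. Published per-isoform SCD magnitudes for this
variant depend on an unstated disorder-window choice and are documented as
non-targets; deltas are reported raw (no normalization is defined for
them).

## Synthetic data: what it does and does not show

`make_reference` plants homopolymer runs at known coordinates in a
background whose runs are capped below 6 and whose run flanks differ from
the run base, so a detector must recover the planting plan exactly — any
spurious or extended run is a test failure, not noise. `simulate_cohort`
draws Poisson depths around `mean_depth` (default 40, typical of WGS),
binomial alt counts at 0.5 for heterozygous probands, the error rate
(default 0.005) for non-carriers, and a uniform 0.02–0.20 fraction for
mosaic parents (the sub-heterozygous range in which parental mosaicism is
typically observed); each carrier's variant is rendered in a randomly chosen
spelling (left-aligned, 3′ duplication, or mid-run anchored) to force
reconciliation. All randomness flows from one explicit integer seed per
call; there is no global random state.

The packaged exon-21 context and the 5,193-nt stand-in CDS are synthetic:
they reproduce every documented constraint of the real locus (the 8-G run
ending at c.3679 with its anchored-T at the hg38/hg19 anchor positions,
Ala at codon 1227 preceded by two run-encoded glycines, a +1-frame stop at
new-frame position 69, a −1-frame stop at position 57, and the c.3676
numbering offset of the alternative transcript model), but their background
sequence is generated, not downloaded. Tests passing on them demonstrate
the correctness of the machinery — normalization, projection, naming — for
any transcript satisfying those constraints, including the real one; they
do not re-verify the real accession's sequence itself. Likewise the cohort
simulator emulates trio structure, spelling diversity, depth and mosaicism,
but not read-level artifacts, mapping bias in GC-rich exons, or
platform-specific error profiles; conclusions about such effects are outside
what a green suite shows.

Problem sizes used by the shipped checks — an 81-bp context window, 2-kb toy
contigs, cohorts of 10–1,200 families, 10,000-replicate calibration runs,
exhaustive 2×2 enumeration to total 40 — were chosen so each check is exact
or statistically decisive at desk scale.

## Known limitations

* Cross-build translation is anchor-window offsetting, not liftover; it is
  only valid near packaged anchors.
* The de novo posterior ignores mapping quality, allele bias, and linked
  sites; it is a reporting aid, not a caller.
* Pooled mosaic evidence assumes platform homogeneity (no overdispersion).
* Multi-allelic VCF records are out of scope (biallelic only), as are full
  HGVS parsing and NMD modeling.
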