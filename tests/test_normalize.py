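"""Indel normalization: run detection, shifting, canonical keys, projection."""

import re
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recurvar as rv
from recurvar.normalize import CdnaEdit, back_project_cds, parse_variant


def _random_contig(seed, length=60):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return rv.ReferenceContig("toy", seq)


def _apply(variant, contig):
    """Edited sequence — the ground truth identity of a spelling."""
    i = variant.pos - contig.start
    assert contig.sequence[i:i + len(variant.ref)] == variant.ref
    return (contig.sequence[:i] + variant.alt
            + contig.sequence[i + len(variant.ref):])


# ---------------------------------------------------------------------------
# Homopolymer run detection
# ---------------------------------------------------------------------------

def test_detect_single_run_trivial():
    runs = rv.detect_homopolymer_runs("AAAAAA", 6)
    assert [(r.start, r.end, r.base) for r in runs] == [(1, 6, "A")]


def test_detect_runs_matches_regex_oracle():
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
    for min_len in (2, 3, 6):
        expected = [(m.start() + 1, m.end(), m.group(0)[0])
                    for m in re.finditer(r"(.)\1*", seq)
                    if m.end() - m.start() >= min_len]
        got = [(r.start, r.end, r.base)
               for r in rv.detect_homopolymer_runs(seq, min_len)]
        assert got == expected


def test_detect_rejects_bad_input():
    with pytest.raises(ValueError):
        rv.detect_homopolymer_runs("ACGTN", 6)
    with pytest.raises(ValueError):
        rv.detect_homopolymer_runs("ACGT", 1)


def test_runs_to_bed_is_zero_based_half_open():
    runs = rv.detect_homopolymer_runs("TTAAAAAAGG", 6, contig="c1")
    assert rv.runs_to_bed(runs) == "c1\t2\t8\tAx6\n"


# ---------------------------------------------------------------------------
# Left alignment / 3' shifting
# ---------------------------------------------------------------------------

def test_insertion_in_run_left_aligns_to_anchor():
    contig = rv.make_reference(3, 120, [rv.PlantedRunSpec("G", 8, 50)])
    for p in range(50, 58):
        v = rv.GenomicVariant("toy1", p, "G", "GG")
        la = rv.left_align(v, contig)
        assert (la.pos, la.ref, la.alt) == (49, contig.base(49),
                                            contig.base(49) + "G")
        assert rv.left_align(la, contig) == la  # idempotent


def test_non_repeat_insertion_does_not_shift():
    contig = rv.ReferenceContig("toy", "ACT")
    v = rv.GenomicVariant("toy", 2, "C", "CG")
    la = rv.left_align(v, contig)
    assert (la.pos, la.ref, la.alt) == (2, "C", "CG")


@pytest.mark.parametrize("seed", range(12))
def test_left_align_matches_exhaustive_enumeration(seed):
    """Left alignment equals the left-most equivalent spelling by brute force."""
    contig = _random_contig(seed)
    rng = np.random.default_rng(seed + 100)
    for _ in range(20):
        pos = int(rng.integers(2, len(contig.sequence)))
        if rng.random() < 0.5:
            base = "ACGT"[rng.integers(4)]
            v = rv.GenomicVariant("toy", pos, contig.base(pos),
                                  contig.base(pos) + base)
        else:
            v = rv.GenomicVariant("toy", pos - 1,
                                  contig.base(pos - 1) + contig.base(pos),
                                  contig.base(pos - 1))
        edited = _apply(v, contig)
        candidates = []
        for p in range(2, len(contig.sequence) + 1):
            anchor = contig.base(p - 1)
            if len(edited) > len(contig.sequence):   # insertion
                for b in "ACGT":
                    cand = rv.GenomicVariant("toy", p - 1, anchor, anchor + b)
                    if _apply(cand, contig) == edited:
                        candidates.append(cand)
            else:                                    # single-base deletion
                if p <= len(contig.sequence):
                    cand = rv.GenomicVariant("toy", p - 1,
                                             anchor + contig.base(p), anchor)
                    if _apply(cand, contig) == edited:
                        candidates.append(cand)
        expected = min(candidates, key=lambda c: c.pos)
        la = rv.left_align(v, contig)
        assert (la.pos, la.ref, la.alt) == (expected.pos, expected.ref,
                                            expected.alt)
        assert _apply(la, contig) == edited


def test_shift_3prime_names_final_run_base_as_dup():
    contig = rv.make_reference(3, 120, [rv.PlantedRunSpec("G", 8, 50)])
    for p in range(50, 58):
        tp = rv.shift_3prime(rv.GenomicVariant("toy1", p, "G", "GG"), contig)
        assert (tp.pos, tp.ref, tp.alt, tp.style) == (57, "G", "GG",
                                                      "hgvs_dup")
        assert rv.shift_3prime(tp, contig) == tp  # idempotent


@pytest.mark.parametrize("seed", range(8))
def test_left_align_absorbs_3prime_shift(seed):
    contig = _random_contig(seed)
    rng = np.random.default_rng(seed + 500)
    for _ in range(15):
        pos = int(rng.integers(2, len(contig.sequence)))
        base = "ACGT"[rng.integers(4)]
        v = rv.GenomicVariant("toy", pos, contig.base(pos),
                              contig.base(pos) + base)
        tp = rv.shift_3prime(v, contig)
        assert rv.left_align(tp, contig) == rv.left_align(v, contig)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(seq=st.text(alphabet="ACGT", min_size=10, max_size=60),
       pos=st.integers(min_value=2, max_value=9),
       base=st.sampled_from("ACGT"))
def test_shifting_never_changes_the_edited_sequence(seq, pos, base):
    """Left/3' spellings of an insertion stay the same underlying edit."""
    contig = rv.ReferenceContig("h", seq)
    v = rv.GenomicVariant("h", pos, contig.base(pos), contig.base(pos) + base)
    edited = _apply(v, contig)
    for spelled in (rv.left_align(v, contig), rv.shift_3prime(v, contig)):
        assert _apply(spelled, contig) == edited
    assert rv.canonical_key(rv.left_align(v, contig), contig) == \
        rv.canonical_key(rv.shift_3prime(v, contig), contig)


def test_table1_two_spellings_of_the_duplication(ref38):
    """Anchored-at-run-start vs final-G dup: the documented tool divergence."""
    anchored = rv.GenomicVariant("chr22", 50721504, "T", "TG", "hg38")
    tp = rv.shift_3prime(anchored, ref38)
    assert (tp.pos, tp.style) == (50721512, "hgvs_dup")
    la = rv.left_align(rv.GenomicVariant("chr22", 50721512, "G", "GG",
                                         "hg38", "hgvs_dup"), ref38)
    assert (la.pos, la.ref, la.alt) == (50721504, "T", "TG")


def test_ref_mismatch_raises(ref38):
    with pytest.raises(rv.RefMismatchError):
        rv.left_align(rv.GenomicVariant("chr22", 50721504, "A", "AG",
                                        "hg38"), ref38)


def test_left_align_agrees_with_bcftools_norm(tmp_path):
    """Independent cross-check of VCF left alignment against bcftools."""
    if shutil.which("bcftools") is None:
        pytest.fail("bcftools expected on PATH for this cross-check")
    contig = rv.make_reference(5, 300, [rv.PlantedRunSpec("G", 8, 100),
                                        rv.PlantedRunSpec("A", 7, 200)])
    fa = tmp_path / "ref.fa"
    fa.write_text(f">{contig.name}\n{contig.sequence}\n")
    spellings = [(99, contig.base(99), contig.base(99) + "G"),
                 (107, "G", "GG"), (103, "G", "GG"),
                 (100, "GG", "G"), (105, "GG", "G"),
                 (199, contig.base(199), contig.base(199) + "A"),
                 (206, "A", "AA"), (201, "AA", "A")]
    vcf = tmp_path / "in.vcf"
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={contig.name},length={len(contig.sequence)}>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    lines += [f"{contig.name}\t{p}\t.\t{r}\t{a}\t.\t.\t." for p, r, a in
              spellings]
    vcf.write_text("\n".join(lines) + "\n")
    out = subprocess.run(["bcftools", "norm", "-f", str(fa), str(vcf)],
                         capture_output=True, text=True, check=True)
    bcf = [(int(f[1]), f[3], f[4]) for f in
           (l.split("\t") for l in out.stdout.splitlines()
            if not l.startswith("#"))]
    mine = []
    for p, r, a in spellings:
        la = rv.left_align(rv.GenomicVariant(contig.name, p, r, a), contig)
        mine.append((la.pos, la.ref, la.alt))
    assert mine == bcf


# ---------------------------------------------------------------------------
# Canonical keys
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("run_len", range(2, 13))
def test_all_insertion_placements_collapse_to_one_key(run_len):
    contig = rv.ReferenceContig("toy", "ACT" + "G" * run_len + "TCA")
    keys = set()
    # anchored insertion before every run position, plus the run-end dup
    for p in range(4, 4 + run_len):
        keys.add(rv.canonical_key(
            rv.GenomicVariant("toy", p - 1, contig.base(p - 1),
                              contig.base(p - 1) + "G"), contig))
    keys.add(rv.canonical_key(
        rv.GenomicVariant("toy", 3 + run_len, "G", "GG", style="hgvs_dup"),
        contig))
    assert len(keys) == 1
    key = keys.pop()
    assert (key.left_anchor, key.ref_core, key.alt_core) == (4, "", "G")
    if run_len >= 6:
        assert key.run_span == (4, 3 + run_len)
    else:
        assert key.run_span is None


def test_insertion_and_deletion_keys_differ(ref38):
    ins = rv.canonical_key(rv.GenomicVariant("chr22", 50721512, "G", "GG",
                                             "hg38", "hgvs_dup"), ref38)
    dele = rv.canonical_key(rv.GenomicVariant("chr22", 50721504, "TG", "T",
                                              "hg38"), ref38)
    assert ins != dele
    assert ins.run_span == dele.run_span == (50721505, 50721512)


def test_hg19_annotation_rows_share_one_key(ref19):
    dup = rv.GenomicVariant("chr22", 51159940, "G", "GG", "hg19", "hgvs_dup")
    anchored = rv.GenomicVariant("chr22", 51159932, "T", "TG", "hg19")
    mid = rv.GenomicVariant("chr22", 51159933, "G", "GG", "hg19")
    assert rv.canonical_key(dup, ref19) == rv.canonical_key(anchored, ref19) \
        == rv.canonical_key(mid, ref19)


# ---------------------------------------------------------------------------
# Cross-build equivalence
# ---------------------------------------------------------------------------

def test_cross_build_equivalence_through_anchors(ref19, anchors):
    v19 = rv.GenomicVariant("chr22", 51159932, "T", "TG", "hg19")
    v38 = rv.GenomicVariant("chr22", 50721512, "G", "GG", "hg38", "hgvs_dup")
    assert rv.variants_equivalent(v19, v38, ref19, anchors)
    assert rv.variants_equivalent(v38, v19, ref19, anchors)  # symmetric


def test_substitution_not_equivalent_to_insertion(ref38):
    sub = rv.GenomicVariant("chr22", 50721504, "T", "G", "hg38",
                            "substitution")
    ins = rv.GenomicVariant("chr22", 50721504, "T", "TG", "hg38")
    assert not rv.variants_equivalent(sub, ins, ref38)


def test_unmappable_cross_build_raises_not_false(ref19, anchors):
    far = rv.GenomicVariant("chr22", 40_000_000, "T", "TG", "hg38")
    near = rv.GenomicVariant("chr22", 51159932, "T", "TG", "hg19")
    with pytest.raises(rv.UnmappableVariantError):
        rv.variants_equivalent(near, far, ref19, anchors)


def test_equivalence_is_an_equivalence_relation_on_spelling_sets():
    contig = rv.make_reference(9, 200, [rv.PlantedRunSpec("C", 7, 80)])
    spellings = [rv.GenomicVariant("toy1", 79, contig.base(79),
                                   contig.base(79) + "C")]
    spellings += [rv.GenomicVariant("toy1", p, "C", "CC")
                  for p in range(80, 87)]
    spellings.append(rv.GenomicVariant("toy1", 86, "C", "CC",
                                       style="hgvs_dup"))
    for a in spellings:
        assert rv.variants_equivalent(a, a, contig)          # reflexive
        for b in spellings:
            assert rv.variants_equivalent(a, b, contig)      # pairwise


# ---------------------------------------------------------------------------
# HGVS-subset parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,expect", [
    ("chr22:g.50721512dup", (50721512, "G", "GG", "hgvs_dup")),
    ("Chr22:g.51159940dupG", (51159940, "G", "GG", "hgvs_dup")),
    ("22-50721503-50721504-T-TG", (50721504, "T", "TG", "vcf_anchored")),
    ("22:51159932:T:TG", (51159932, "T", "TG", "vcf_anchored")),
])
def test_parse_variant_table_spellings(text, expect, ref38, ref19, anchors):
    build = "hg38" if "5072" in text else "hg19"
    ref = ref38 if build == "hg38" else ref19
    v = parse_variant(text, build, ref)
    assert (v.pos, v.ref, v.alt, v.style) == expect


def test_parse_variant_rejects_junk():
    with pytest.raises(ValueError):
        parse_variant("not-a-variant")


# ---------------------------------------------------------------------------
# Genomic -> cDNA projection
# ---------------------------------------------------------------------------

def _single_exon_tx(contig, cds_start=1, cds_end=None, strand="+",
                    tx_id="tx"):
    cds_end = cds_end or len(contig.sequence)
    return rv.TranscriptModel.from_reference(
        tx_id, contig, strand, [(contig.start, contig.end)], cds_start,
        cds_end)


def test_projection_applies_3prime_rule_on_toy():
    # CDS with a 7-G run starting at c.3: insertion anywhere -> c.9dup
    contig = rv.ReferenceContig("toy", "AT" + "G" * 7 + "TCAGCATCG")
    tx = _single_exon_tx(contig)
    for gpos in range(3, 10):
        v = rv.GenomicVariant("toy", gpos, "G", "GG")
        assert str(rv.project_genomic_to_cds(v, tx, contig)) == "c.9dup"
    v = rv.GenomicVariant("toy", 2, "T", "TG")
    assert str(rv.project_genomic_to_cds(v, tx, contig, rule="left")) == \
        "c.2_3insG"  # left rule keeps the 5' spelling


def test_projection_on_standin_transcripts(transcript_models):
    contig, models = transcript_models
    v = rv.GenomicVariant("chr22", 50721512, "G", "GG", "hg38", "hgvs_dup")
    assert str(rv.project_genomic_to_cds(v, models["nm"], contig)) == \
        "c.3679dup"
    assert str(rv.project_genomic_to_cds(v, models["enst"], contig)) == \
        "c.3676dup"


def test_intronic_variant_reports_non_coding(transcript_models):
    contig, models = transcript_models
    v = rv.GenomicVariant("chr22", 50721000, contig.base(50721000),
                          contig.base(50721000) + "G", "hg38")
    assert rv.project_genomic_to_cds(v, models["nm"], contig).non_coding


def test_projection_round_trip_preserves_canonical_key(transcript_models):
    contig, models = transcript_models
    tx = models["nm"]
    rng = np.random.default_rng(12)
    done = 0
    while done < 25:
        gpos = int(rng.integers(50721455, 50721595))
        base = "ACGT"[rng.integers(4)]
        v = rv.GenomicVariant("chr22", gpos, contig.base(gpos),
                              contig.base(gpos) + base, "hg38")
        edit = rv.project_genomic_to_cds(v, tx, contig)
        if edit.non_coding:
            continue
        back = back_project_cds(edit, tx)
        back = rv.GenomicVariant(back.contig, back.pos, back.ref, back.alt,
                                 "hg38", back.style)
        assert rv.canonical_key(back, contig) == rv.canonical_key(v, contig)
        done += 1


def test_minus_strand_3prime_rule_shifts_to_lower_genomic_coordinates():
    # plus strand has a C-run; the minus-strand transcript reads it as a
    # G-run, so the transcript 3'-rule must land at the run's *lowest*
    # genomic coordinate
    contig = rv.ReferenceContig("toy", "ATA" + "C" * 6 + "GATCGA")
    tx = _single_exon_tx(contig, strand="-",
                         cds_end=len(contig.sequence) - (len(contig.sequence)
                                                         % 3))
    run = rv.contig_runs(contig, 6)[0]
    assert (run.start, run.end, run.base) == (4, 9, "C")
    for gpos in range(4, 10):
        v = rv.GenomicVariant("toy", gpos, "C", "CC")
        edit = rv.project_genomic_to_cds(v, tx, contig)
        assert edit.kind == "dup"
        g_of_dup = tx.transcript_to_genomic(edit.c_start + tx.cds_start - 1)
        assert g_of_dup == run.start  # most-3' on transcript = lowest genomic


def test_transcript_model_invariants():
    contig = rv.ReferenceContig("toy", "ATGAAACCCGGGTTTTAG")
    with pytest.raises(ValueError):
        rv.TranscriptModel("t", "toy", "+", [(1, 18)], 1, 17, contig.sequence)
    tx = _single_exon_tx(contig)
    assert tx.cds == contig.sequence
    assert tx.genomic_to_transcript(5) == 5
    assert tx.transcript_to_genomic(5) == 5
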