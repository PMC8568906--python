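"""Indel normalization inside and outside homopolymer runs.

An insertion or deletion that falls inside a homopolymer run (a stretch of
identical nucleotides) has many equivalent coordinate spellings: NGS pipelines
left-align it (VCF convention), Sanger-derived HGVS names shift it to the
most-3' position (the 3'-rule), and some annotators anchor it mid-run.  This
module parses the common spellings, shifts them in either direction, reduces
every spelling of the same underlying edit to one canonical, anchor-free key,
compares variants across genome builds through an explicit anchor table, and
projects genomic edits onto transcript (cDNA) coordinates.

Coordinates are 1-based and fully closed on the plus strand throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

DNA_ALPHABET = frozenset("ACGT")

#: Minimum length for a stretch of identical bases to count as a homopolymer
#: run.  Runs this long are strongly mutation-enriched and are where indel
#: spellings become ambiguous.
DEFAULT_MIN_RUN_LENGTH = 6

#: Half-width (bp) of the window around a build anchor inside which a constant
#: coordinate offset is trusted for cross-build translation.
DEFAULT_ANCHOR_WINDOW = 500

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> None:
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"{what} contains non-ACGT characters: {bad}")


class RefMismatchError(ValueError):
    """A variant's stated reference allele disagrees with the reference."""


class UnmappableVariantError(ValueError):
    """Cross-build comparison requested without a covering anchor."""


# ---------------------------------------------------------------------------
# Reference contigs
# ---------------------------------------------------------------------------

@dataclass
class ReferenceContig:
    """A (possibly windowed) reference sequence.

    ``start`` is the 1-based genomic coordinate of the first base, so a short
    window extracted from a chromosome keeps its native coordinates.
    """

    name: str
    sequence: str
    build_label: str = "toy1"
    start: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("contig sequence must be non-empty")
        _check_dna(self.sequence, f"contig {self.name}")
        if self.start < 1:
            raise ValueError("contig start must be >= 1")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def base(self, pos: int) -> str:
        if not self.start <= pos <= self.end:
            raise IndexError(f"position {pos} outside contig {self.name} "
                             f"[{self.start}, {self.end}]")
        return self.sequence[pos - self.start]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based slice."""
        if start > end:
            return ""
        if not (self.start <= start and end <= self.end):
            raise IndexError(f"[{start}, {end}] outside contig {self.name}")
        return self.sequence[start - self.start:end - self.start + 1]


# ---------------------------------------------------------------------------
# Homopolymer runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomopolymerRun:
    contig: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_homopolymer_runs(sequence: str,
                            min_len: int = DEFAULT_MIN_RUN_LENGTH,
                            contig: str = "",
                            offset: int = 1) -> list[HomopolymerRun]:
    """All maximal runs of identical bases with length >= ``min_len``.

    ``offset`` is the 1-based coordinate of ``sequence[0]`` so runs detected
    in a windowed contig carry genomic coordinates.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    _check_dna(sequence)
    runs: list[HomopolymerRun] = []
    i = 0
    n = len(sequence)
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_len:
            runs.append(HomopolymerRun(contig, offset + i, offset + j - 1,
                                       sequence[i]))
        i = j
    return runs


def contig_runs(ref: ReferenceContig,
                min_len: int = DEFAULT_MIN_RUN_LENGTH) -> list[HomopolymerRun]:
    return detect_homopolymer_runs(ref.sequence, min_len, ref.name, ref.start)


def runs_to_bed(runs: Iterable[HomopolymerRun]) -> str:
    """Render runs as BED (0-based, half-open) text."""
    lines = [f"{r.contig}\t{r.start - 1}\t{r.end}\t{r.base}x{r.length}"
             for r in runs]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

VARIANT_STYLES = ("vcf_anchored", "hgvs_dup", "hgvs_del", "hgvs_ins",
                  "substitution")


@dataclass(frozen=True)
class GenomicVariant:
    """One spelling of a sequence-level variant.

    ``style`` records how the spelling is rendered; ``pos``/``ref``/``alt``
    always describe the replacement of ``ref`` (starting at ``pos``) by
    ``alt`` on the plus strand, so every style shares one internal algebra.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    build_label: str = "toy1"
    style: str = "vcf_anchored"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        _check_dna(self.ref, "ref")
        _check_dna(self.alt, "alt")
        if self.style not in VARIANT_STYLES:
            raise ValueError(f"unknown style {self.style!r}")
        if self.style == "vcf_anchored":
            # VCF anchors on the base before the event, or — at the start of
            # a contig — on the base after it
            if not self.ref or not self.alt or \
                    (self.ref[0] != self.alt[0]
                     and self.ref[-1] != self.alt[-1]):
                raise ValueError("vcf_anchored spelling requires a shared "
                                 "leading or trailing anchor base")


_HGVS_G = re.compile(
    r"^(?:chr)?(?P<contig>[\w.]+):g\.(?P<start>[\d,]+)"
    r"(?:_(?P<end>[\d,]+))?(?P<op>dup|del|ins)(?P<seq>[ACGT]*)$",
    re.IGNORECASE)
_ANCHORED = re.compile(
    r"^(?:chr)?(?P<contig>[\w.]+)[-:](?:(?P<start>\d+)[-:])?(?P<pos>\d+)"
    r"[-:](?P<ref>[ACGT]+)[-:](?P<alt>[ACGT]+)$")


def parse_variant(text: str, build_label: str = "toy1",
                  reference: Optional[ReferenceContig] = None) -> GenomicVariant:
    """Parse the variant spellings used in annotation tables.

    Supports the anchored pos-ref-alt form (``chr22-51159932-T-TG``, with or
    without a redundant leading interval coordinate) and the genomic HGVS
    subset ``g.Ndup``, ``g.N_Mdup``, ``g.Ndel``, ``g.N_MinsSEQ``.  ``dup`` and
    ``del`` spellings need ``reference`` to recover the repeated bases.
    """
    text = text.strip().replace(" ", "").replace("–", "-")
    m = _HGVS_G.match(text)
    if m:
        start = int(m.group("start").replace(",", ""))
        end = int(m.group("end").replace(",", "")) if m.group("end") else start
        op = m.group("op").lower()
        seq = (m.group("seq") or "").upper()
        contig = m.group("contig")
        if op == "ins":
            if not seq:
                raise ValueError(f"insertion without sequence: {text!r}")
            return GenomicVariant(contig, start, "", seq, build_label,
                                  "hgvs_ins")
        if reference is None:
            if op == "dup" and seq:
                dup = seq
            else:
                raise ValueError(
                    f"{op} spelling {text!r} needs a reference sequence")
        else:
            dup = reference.slice(start, end)
            if seq and seq != dup:
                raise RefMismatchError(
                    f"{text!r}: stated bases {seq} != reference {dup}")
        if op == "dup":
            return GenomicVariant(contig, start, dup, dup + dup, build_label,
                                  "hgvs_dup")
        return GenomicVariant(contig, start, dup, "", build_label, "hgvs_del")
    m = _ANCHORED.match(text)
    if m:
        ref, alt = m.group("ref").upper(), m.group("alt").upper()
        style = ("substitution" if len(ref) == len(alt) == 1
                 else "vcf_anchored")
        return GenomicVariant(m.group("contig"), int(m.group("pos")), ref, alt,
                              build_label, style)
    raise ValueError(f"unrecognized variant spelling: {text!r}")


# --- internal edit algebra -------------------------------------------------

def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared leading/trailing bases; parsimonious core."""
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _validate_on_reference(v: GenomicVariant, ref: ReferenceContig) -> None:
    if v.ref:
        seen = ref.slice(v.pos, v.pos + len(v.ref) - 1)
        if seen != v.ref:
            raise RefMismatchError(
                f"{v.contig}:{v.pos} stated ref {v.ref!r} != reference "
                f"{seen!r}")


def _core(v: GenomicVariant,
          ref: ReferenceContig) -> tuple[int, str, str]:
    """(pos, deleted, inserted) parsimonious core, validated on reference."""
    _validate_on_reference(v, ref)
    pos, dele, ins = _trim(v.pos, v.ref, v.alt)
    return pos, dele, ins


def _shift_left(pos: int, dele: str, ins: str,
                ref: ReferenceContig) -> tuple[int, str, str]:
    # pure indel cores can roll left while the base entering from the left
    # equals the base leaving on the right
    if dele and ins:
        return pos, dele, ins
    seq = dele or ins
    while pos > ref.start:
        prev = ref.base(pos - 1)
        if prev != seq[-1]:
            break
        seq = prev + seq[:-1]
        pos -= 1
    return (pos, seq, "") if dele else (pos, "", seq)


def _shift_right(pos: int, dele: str, ins: str,
                 ref: ReferenceContig) -> tuple[int, str, str]:
    if dele and ins:
        return pos, dele, ins
    seq = dele or ins
    k = len(dele)
    while True:
        nxt_pos = pos + k  # first reference base to the right of the edit
        if nxt_pos > ref.end:
            break
        nxt = ref.base(nxt_pos)
        if nxt != seq[0]:
            break
        seq = seq[1:] + nxt
        pos += 1
    return (pos, seq, "") if dele else (pos, "", seq)


def _render_anchored(pos: int, dele: str, ins: str,
                     ref: ReferenceContig) -> GenomicVariant:
    """VCF-style spelling with a left anchor base."""
    if dele and ins:  # MNV/substitution needs no anchor
        style = "substitution" if len(dele) == len(ins) == 1 else "vcf_anchored"
        if style == "vcf_anchored":
            if pos > ref.start:
                anchor = ref.base(pos - 1)
                return GenomicVariant(ref.name, pos - 1, anchor + dele,
                                      anchor + ins, ref.build_label,
                                      "vcf_anchored")
        return GenomicVariant(ref.name, pos, dele, ins, ref.build_label, style)
    if pos > ref.start:
        anchor_pos = pos - 1
        anchor = ref.base(anchor_pos)
        return GenomicVariant(ref.name, anchor_pos, anchor + dele,
                              anchor + ins, ref.build_label, "vcf_anchored")
    # event at the very first base: VCF anchors on the following base
    anchor = ref.base(pos + len(dele))
    return GenomicVariant(ref.name, pos, dele + anchor, ins + anchor,
                          ref.build_label, "vcf_anchored")


def left_align(variant: GenomicVariant,
               reference: ReferenceContig) -> GenomicVariant:
    """Parsimonious, left-most (VCF convention) spelling.  Idempotent."""
    pos, dele, ins = _core(variant, reference)
    if not dele and not ins:
        raise ValueError("variant is a no-op after trimming")
    pos, dele, ins = _shift_left(pos, dele, ins, reference)
    return _render_anchored(pos, dele, ins, reference)


def shift_3prime(variant: GenomicVariant,
                 reference: ReferenceContig) -> GenomicVariant:
    """Most-3' (HGVS rule, plus strand) spelling.  Idempotent.

    Insertions that duplicate the immediately preceding reference segment are
    rendered ``hgvs_dup``; other insertions ``hgvs_ins``; deletions
    ``hgvs_del``.
    """
    pos, dele, ins = _core(variant, reference)
    if not dele and not ins:
        raise ValueError("variant is a no-op after trimming")
    pos, dele, ins = _shift_right(pos, dele, ins, reference)
    if dele and ins:
        style = "substitution" if len(dele) == len(ins) == 1 else "vcf_anchored"
        if style == "vcf_anchored":
            return _render_anchored(pos, dele, ins, reference)
        return GenomicVariant(reference.name, pos, dele, ins,
                              reference.build_label, style)
    if dele:
        return GenomicVariant(reference.name, pos, dele, "",
                              reference.build_label, "hgvs_del")
    # insertion: duplication if it copies the preceding reference bases
    k = len(ins)
    dup_start = pos - k
    if dup_start >= reference.start and \
            reference.slice(dup_start, pos - 1) == ins:
        return GenomicVariant(reference.name, dup_start, ins, ins + ins,
                              reference.build_label, "hgvs_dup")
    return GenomicVariant(reference.name, pos, "", ins,
                          reference.build_label, "hgvs_ins")


# ---------------------------------------------------------------------------
# Canonical keys and equivalence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedVariantKey:
    """Canonical, spelling-free identity of an edit.

    The identity is the left-aligned parsimonious core: ``left_anchor`` is the
    1-based position of the first core base (for a pure insertion, the
    position the inserted bases would occupy).  The 3'-aligned form is a
    rendering, not the identity, because it depends on the annotation tool.
    ``run_span`` is populated when the edit sits inside a homopolymer run of
    its own base.
    """

    contig: str
    build_label: str
    left_anchor: int
    ref_core: str
    alt_core: str
    run_span: Optional[tuple[int, int]] = None


def canonical_key(variant: GenomicVariant, reference: ReferenceContig,
                  min_run_length: int = DEFAULT_MIN_RUN_LENGTH
                  ) -> NormalizedVariantKey:
    """One key for every spelling of the same underlying edit."""
    pos, dele, ins = _core(variant, reference)
    if not dele and not ins:
        raise ValueError("variant is a no-op after trimming")
    pos, dele, ins = _shift_left(pos, dele, ins, reference)
    run_span = None
    core_seq = dele or ins
    if not (dele and ins) and len(set(core_seq)) == 1:
        # look up a containing run of the same base around the edit site
        base = core_seq[0]
        lo = pos
        while lo - 1 >= reference.start and reference.base(lo - 1) == base:
            lo -= 1
        # deletions include their own deleted bases in the run; insertions
        # sit between reference bases, so scan right from pos - 1
        hi = pos + len(dele) - 1
        while hi + 1 <= reference.end and reference.base(hi + 1) == base:
            hi += 1
        if hi - lo + 1 >= min_run_length:
            run_span = (lo, hi)
    return NormalizedVariantKey(reference.name, reference.build_label,
                                pos, dele, ins, run_span)


@dataclass
class AnchorTable:
    """Coordinate-equivalence anchors between two genome builds.

    Each anchor states that ``pos_a`` (in ``build_a``) and ``pos_b`` (in
    ``build_b``) are the same base; the constant offset is trusted only within
    ``window`` bp of the anchor.  This deliberately replaces chain-file
    liftover for the small windows the package ships.
    """

    anchors: list[tuple[str, int, str, int]]
    window: int = DEFAULT_ANCHOR_WINDOW

    def translate(self, pos: int, from_build: str, to_build: str) -> int:
        if from_build == to_build:
            return pos
        best: Optional[int] = None
        best_dist: Optional[int] = None
        for build_a, pos_a, build_b, pos_b in self.anchors:
            if (build_a, build_b) == (from_build, to_build):
                src, dst = pos_a, pos_b
            elif (build_b, build_a) == (from_build, to_build):
                src, dst = pos_b, pos_a
            else:
                continue
            dist = abs(pos - src)
            if dist <= self.window and (best_dist is None or dist < best_dist):
                best, best_dist = pos + (dst - src), dist
        if best is None:
            raise UnmappableVariantError(
                f"no anchor within {self.window} bp maps {from_build}:{pos} "
                f"to {to_build}")
        return best


def variants_equivalent(v1: GenomicVariant, v2: GenomicVariant,
                        reference: ReferenceContig,
                        anchors: Optional[AnchorTable] = None,
                        min_run_length: int = DEFAULT_MIN_RUN_LENGTH) -> bool:
    """True iff both spellings denote the same edit.

    ``reference`` must be in one of the two builds; a variant in the other
    build is translated through ``anchors`` first (raising
    :class:`UnmappableVariantError` when no anchor covers it, rather than
    returning False).
    """
    def to_ref_build(v: GenomicVariant) -> GenomicVariant:
        if v.build_label == reference.build_label:
            return v
        if anchors is None:
            raise UnmappableVariantError(
                f"variant in build {v.build_label} but no anchor table given")
        newpos = anchors.translate(v.pos, v.build_label,
                                   reference.build_label)
        return replace(v, pos=newpos, build_label=reference.build_label)

    k1 = canonical_key(to_ref_build(v1), reference, min_run_length)
    k2 = canonical_key(to_ref_build(v2), reference, min_run_length)
    return k1 == k2


# ---------------------------------------------------------------------------
# Transcript models and genomic <-> cDNA projection
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Exon structure + CDS bounds enabling genomic<->cDNA projection.

    ``exons`` are genomic (start, end) intervals ordered 5'->3' on the
    transcript (descending genomic coordinates on the minus strand);
    ``cds_start``/``cds_end`` are transcript-relative 1-based positions;
    ``sequence`` is the spliced transcript (transcript orientation).
    """

    id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        spliced = sum(e - s + 1 for s, e in self.exons)
        if spliced != len(self.sequence):
            raise ValueError("spliced exon length != sequence length")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        ordered = self.exons if self.strand == "+" else self.exons[::-1]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError("exons must be non-overlapping and ordered")

    @classmethod
    def from_reference(cls, tx_id: str, ref: ReferenceContig, strand: str,
                       exons: Sequence[tuple[int, int]], cds_start: int,
                       cds_end: int) -> "TranscriptModel":
        parts = [ref.slice(s, e) for s, e in
                 (exons if strand == "+" else reversed(list(exons)))]
        seq = "".join(parts)
        if strand == "-":
            seq = revcomp(seq)
        exon_list = sorted(exons, reverse=(strand == "-"))
        return cls(tx_id, ref.name, strand, list(exon_list), cds_start,
                   cds_end, seq)

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1:self.cds_end]

    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        offset = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                if self.strand == "+":
                    return offset + (gpos - s) + 1
                return offset + (e - gpos) + 1
            offset += e - s + 1
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        offset = 0
        for s, e in self.exons:
            n = e - s + 1
            if tpos <= offset + n:
                within = tpos - offset - 1
                return s + within if self.strand == "+" else e - within
            offset += n
        raise IndexError(f"transcript position {tpos} beyond {self.id}")


@dataclass(frozen=True)
class CdnaEdit:
    """A cDNA-coordinate edit description (``c.`` numbering within the CDS)."""

    kind: str            # dup | del | ins | sub | non_coding
    c_start: int = 0
    c_end: int = 0
    bases: str = ""

    @property
    def non_coding(self) -> bool:
        return self.kind == "non_coding"

    def __str__(self) -> str:
        if self.non_coding:
            return "non-coding"
        if self.kind in ("dup", "del"):
            span = (f"c.{self.c_start}" if self.c_start == self.c_end
                    else f"c.{self.c_start}_{self.c_end}")
            return f"{span}{self.kind}"
        if self.kind == "ins":
            return f"c.{self.c_start}_{self.c_end}ins{self.bases}"
        return f"c.{self.c_start}{self.kind}"


def project_genomic_to_cds(variant: GenomicVariant, tx: TranscriptModel,
                           reference: ReferenceContig,
                           rule: str = "three_prime") -> CdnaEdit:
    """Project a genomic edit onto CDS coordinates under a shifting rule.

    The edit is re-shifted *in transcript orientation* (the HGVS 3'-rule is
    defined on the coding strand), so on a minus-strand transcript the
    3'-rule moves the edit toward lower genomic coordinates.  Variants whose
    shifted core falls outside the CDS (or in an intron) yield a
    ``non_coding`` result.
    """
    if rule not in ("three_prime", "left"):
        raise ValueError("rule must be 'three_prime' or 'left'")
    pos, dele, ins = _core(variant, reference)
    if dele and ins:  # substitution / MNV: no shifting ambiguity
        t = tx.genomic_to_transcript(pos)
        if t is None:
            return CdnaEdit("non_coding")
        if tx.strand == "-":
            t = t - len(dele) + 1
            dele, ins = revcomp(dele), revcomp(ins)
        c = t - tx.cds_start + 1
        if not 1 <= c <= len(tx.cds):
            return CdnaEdit("non_coding")
        return CdnaEdit("sub", c, c + len(dele) - 1, ins)

    # map the pure-indel core into transcript coordinates
    if dele:
        tpositions = [tx.genomic_to_transcript(p)
                      for p in range(pos, pos + len(dele))]
        if any(t is None for t in tpositions):
            return CdnaEdit("non_coding")
        t_lo = min(tpositions)  # type: ignore[type-var]
        seq_t = dele if tx.strand == "+" else revcomp(dele)
        t_pos, t_del, t_ins = t_lo, seq_t, ""
    else:
        # an insertion lands between two reference bases; in transcript space
        # it must fall between consecutive exonic positions
        left_g, right_g = pos - 1, pos
        tl = tx.genomic_to_transcript(left_g)
        tr = tx.genomic_to_transcript(right_g)
        if tl is None or tr is None or abs(tl - tr) != 1:
            return CdnaEdit("non_coding")
        t_pos = min(tl, tr) + 1  # transcript position the insert would occupy
        seq_t = ins if tx.strand == "+" else revcomp(ins)
        t_pos, t_del, t_ins = t_pos, "", seq_t

    # shift on the spliced transcript sequence per the requested rule
    tx_ref = ReferenceContig(tx.id, tx.sequence, tx.contig, 1)
    if rule == "three_prime":
        t_pos, t_del, t_ins = _shift_right(t_pos, t_del, t_ins, tx_ref)
    else:
        t_pos, t_del, t_ins = _shift_left(t_pos, t_del, t_ins, tx_ref)

    c = t_pos - tx.cds_start + 1
    seq = t_del or t_ins
    if not (1 <= c and c + len(t_del) - 1 <= len(tx.cds)):
        return CdnaEdit("non_coding")
    if t_del:
        return CdnaEdit("del", c, c + len(t_del) - 1, t_del)
    k = len(t_ins)
    if t_pos - k >= 1 and tx.sequence[t_pos - k - 1:t_pos - 1] == t_ins:
        return CdnaEdit("dup", c - k, c - 1, t_ins)
    return CdnaEdit("ins", c - 1, c, t_ins)


def read_transcripts_tsv(path, ref: ReferenceContig) -> list[TranscriptModel]:
    """Transcript models from the package-defined TSV.

    Columns: ``transcript_id  contig  strand  exons  cds_start  cds_end``
    where ``exons`` is a comma-separated list of ``start-end`` genomic
    intervals in transcript order.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        exons = [tuple(int(x) for x in part.split("-"))
                 for part in str(row["exons"]).split(",")]
        out.append(TranscriptModel.from_reference(
            str(row["transcript_id"]), ref, str(row["strand"]),
            [(s, e) for s, e in exons], int(row["cds_start"]),
            int(row["cds_end"])))
    return out


def back_project_cds(edit: CdnaEdit, tx: TranscriptModel) -> GenomicVariant:
    """Map a CDS edit back to a genomic spelling (inverse of projection)."""
    if edit.non_coding:
        raise ValueError("cannot back-project a non-coding result")
    t_start = edit.c_start + tx.cds_start - 1
    t_end = edit.c_end + tx.cds_start - 1
    if edit.kind == "dup":
        ins = tx.sequence[t_start - 1:t_end]
        g_after = tx.transcript_to_genomic(t_end)
        ins_g = ins if tx.strand == "+" else revcomp(ins)
        gpos = g_after + 1 if tx.strand == "+" else g_after
        return GenomicVariant(tx.contig, gpos, "", ins_g,
                              build_label="", style="hgvs_ins")
    if edit.kind == "ins":
        g_left = tx.transcript_to_genomic(t_start)
        ins_g = edit.bases if tx.strand == "+" else revcomp(edit.bases)
        gpos = g_left + 1 if tx.strand == "+" else g_left - len(edit.bases) + 1
        return GenomicVariant(tx.contig, gpos, "", ins_g,
                              build_label="", style="hgvs_ins")
    if edit.kind == "del":
        g1 = tx.transcript_to_genomic(t_start)
        g2 = tx.transcript_to_genomic(t_end)
        lo, hi = min(g1, g2), max(g1, g2)
        dele = tx.sequence[t_start - 1:t_end]
        dele_g = dele if tx.strand == "+" else revcomp(dele)
        return GenomicVariant(tx.contig, lo, dele_g, "",
                              build_label="", style="hgvs_del")
    raise ValueError(f"cannot back-project edit kind {edit.kind!r}")
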