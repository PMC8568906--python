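"""Synthetic references, transcripts, trio cohorts, and packaged fixtures.

Everything downstream of controlled-access cohort data is exercised against
two kinds of inputs this module provides:

* toy references with homopolymer runs planted at known coordinates, and
  simulated trio cohorts in which carrier probands receive the same
  single-base insertion rendered in different annotation spellings, with
  optionally mosaic parents at low variant allele fraction;
* packaged transcriptions of published annotation/carrier/phenotype tables
  for the recurrent SHANK3 exon-21 guanine duplication, together with a
  deterministic *synthetic stand-in* coding sequence whose exon-21 context
  reproduces every documented property of the real transcript (8-G run
  ending at c.3679, Ala at codon 1227, duplication -> Glyfs*69,
  deletion -> Profs*57, and the c.3676 numbering of the alternative
  transcript).  Real accessions can be substituted by the caller when
  available; no download is performed here.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .consequence import DomainAnnotation
from .mosaic import ReadCounts
from .normalize import (AnchorTable, GenomicVariant, ReferenceContig,
                        TranscriptModel, contig_runs,
                        detect_homopolymer_runs)
from .normalize import NormalizedVariantKey, canonical_key
from .recurrence import CohortRecord, normalize_cdna_text

FIXTURE_NAMES = ("table1", "table2", "table3", "context", "build_anchors")

#: Constant coordinate offset between the two packaged build windows
#: (hg19 position = hg38 position + this), valid across the fixture window.
HG19_MINUS_HG38 = 438428

#: hg38 coordinates of the fixture context window and its variant site.
CONTEXT_START_HG38 = 50721472
VARIANT_SITE_HG38 = 50721512
#: cDNA coordinate (NM-style numbering) of the first context base.
CONTEXT_CDS_START = 3639


def _data_path(name: str):
    return resources.files("recurvar.data").joinpath(name)


# ---------------------------------------------------------------------------
# Toy reference generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRunSpec:
    base: str
    length: int
    position: int  # 1-based start within the contig

    def __post_init__(self) -> None:
        if self.base not in "ACGT":
            raise ValueError("base must be one of A/C/G/T")
        if self.length < 6:
            raise ValueError("planted runs must satisfy the homopolymer "
                             "definition (length >= 6)")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def end(self) -> int:
        return self.position + self.length - 1


def make_reference(seed: int, length: int,
                   runs: Sequence[PlantedRunSpec],
                   name: str = "toy1",
                   build_label: str = "toy1") -> ReferenceContig:
    """Random contig containing each planted run exactly as specified.

    Background bases never form a run of six or more, and the bases flanking
    each planted run differ from the run base, so a detector recovers the
    planting plan exactly.  Reproducible for a fixed seed.
    """
    occupied: list[tuple[int, int]] = []
    for spec in sorted(runs, key=lambda r: r.position):
        if spec.end > length:
            raise ValueError(f"run {spec} extends beyond contig length "
                             f"{length}")
        # reserve one flank base each side so maximality is enforceable
        lo, hi = max(1, spec.position - 1), min(length, spec.end + 1)
        for plo, phi in occupied:
            if lo <= phi and plo <= hi:
                raise ValueError(f"run {spec} overlaps another planted run "
                                 "(or abuts one without a gap)")
        occupied.append((lo, hi))

    rng = np.random.default_rng(seed)
    run_at: dict[int, str] = {}
    flank_exclude: dict[int, str] = {}
    for spec in runs:
        for p in range(spec.position, spec.end + 1):
            run_at[p] = spec.base
        for p in (spec.position - 1, spec.end + 1):
            if 1 <= p <= length:
                flank_exclude[p] = spec.base

    bases = "ACGT"
    seq: list[str] = []
    streak_base, streak_len = "", 0
    for pos in range(1, length + 1):
        if pos in run_at:
            b = run_at[pos]
        else:
            forbidden = set()
            if streak_len >= 5:
                forbidden.add(streak_base)  # cap background runs below 6
            if pos in flank_exclude:
                forbidden.add(flank_exclude[pos])
            allowed = [c for c in bases if c not in forbidden]
            b = allowed[rng.integers(len(allowed))]
        seq.append(b)
        if b == streak_base:
            streak_len += 1
        else:
            streak_base, streak_len = b, 1
    return ReferenceContig(name, "".join(seq), build_label)


# ---------------------------------------------------------------------------
# Trio cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortPlan:
    n_families: int
    carrier_families: frozenset
    mosaic_parent_fraction: float = 0.0
    mean_depth: float = 40.0
    error_rate: float = 0.005
    seed: int = 0
    mosaic_vaf_range: tuple[float, float] = (0.02, 0.20)

    def __post_init__(self) -> None:
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if not set(self.carrier_families) <= set(range(self.n_families)):
            raise ValueError("carrier_families must be family indices")
        if not 0 <= self.mosaic_parent_fraction <= 1:
            raise ValueError("mosaic_parent_fraction must be in [0,1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")


@dataclass
class TrioRecord:
    family_id: str
    proband_id: str
    carrier: bool
    variant: Optional[GenomicVariant]
    spelling: str                     # left | three_prime | mid_run | none
    inheritance: str                  # de_novo | maternal_mosaic | ...
    proband: ReadCounts
    mother: ReadCounts
    father: ReadCounts
    true_parent_vaf: Optional[float] = None   # simulator's own mosaic draw


def _spellings(run_start: int, run_end: int, base: str,
               contig: ReferenceContig) -> dict[str, GenomicVariant]:
    anchor_pos = run_start - 1
    anchor = contig.base(anchor_pos)
    return {
        "left": GenomicVariant(contig.name, anchor_pos, anchor,
                               anchor + base, contig.build_label,
                               "vcf_anchored"),
        "three_prime": GenomicVariant(contig.name, run_end, base,
                                      base + base, contig.build_label,
                                      "hgvs_dup"),
        # mid-run anchored: REF/ALT anchored on an interior run base
        "mid_run": None,  # filled per-draw (random interior position)
    }


def simulate_cohort(plan: CohortPlan, contig: ReferenceContig,
                    site: int) -> list[TrioRecord]:
    """Trio records for ``plan.n_families`` families around one run site.

    Carrier probands receive a single-base insertion of the run base rendered
    in one of three spellings (left-aligned, 3'-aligned duplication, or
    anchored mid-run) so downstream reconciliation is exercised; depths are
    Poisson around ``mean_depth``; alt reads are binomial with fraction 0.5
    (heterozygote), a uniform draw from ``mosaic_vaf_range`` (mosaic parent)
    or ``error_rate`` (non-carrier).
    """
    runs = [r for r in contig_runs(contig) if r.start <= site <= r.end]
    if not runs:
        raise ValueError(f"site {site} is not inside a homopolymer run")
    run = runs[0]
    rng = np.random.default_rng(plan.seed)
    out: list[TrioRecord] = []

    def depth() -> int:
        return int(max(1, rng.poisson(plan.mean_depth)))

    def reads(fraction: float) -> ReadCounts:
        d = depth()
        return ReadCounts(int(rng.binomial(d, fraction)), d)

    for fam in range(plan.n_families):
        fid = f"F{fam:04d}"
        carrier = fam in plan.carrier_families
        if not carrier:
            out.append(TrioRecord(fid, f"{fid}.p1", False, None, "none",
                                  "de_novo", reads(plan.error_rate),
                                  reads(plan.error_rate),
                                  reads(plan.error_rate)))
            continue
        style = ("left", "three_prime", "mid_run")[rng.integers(3)]
        if style == "mid_run":
            mid = int(rng.integers(run.start, run.end + 1))
            variant = GenomicVariant(contig.name, mid, run.base,
                                     run.base + run.base,
                                     contig.build_label, "vcf_anchored")
        else:
            variant = _spellings(run.start, run.end, run.base, contig)[style]
        mosaic = rng.random() < plan.mosaic_parent_fraction
        true_vaf: Optional[float] = None
        if mosaic:
            lo, hi = plan.mosaic_vaf_range
            true_vaf = float(rng.uniform(lo, hi))
            which = "mother" if rng.random() < 0.5 else "father"
            mother = reads(true_vaf if which == "mother"
                           else plan.error_rate)
            father = reads(true_vaf if which == "father"
                           else plan.error_rate)
            inheritance = ("maternal_mosaic" if which == "mother"
                           else "paternal_mosaic")
        else:
            mother = reads(plan.error_rate)
            father = reads(plan.error_rate)
            inheritance = "de_novo"
        out.append(TrioRecord(fid, f"{fid}.p1", True, variant, style,
                              inheritance, reads(0.5), mother, father,
                              true_vaf))
    return out


def cohort_records(trios: Iterable[TrioRecord],
                   cohort: str = "sim") -> list[CohortRecord]:
    """Proband-level pipeline records for the carriers of a simulated cohort."""
    out = []
    for t in trios:
        if not t.carrier or t.variant is None:
            continue
        out.append(CohortRecord(
            individual_id=t.proband_id, family_id=t.family_id, cohort=cohort,
            affected=True, variant=t.variant, inheritance=t.inheritance,
            population_af=None, consequence_class="frameshift"))
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _read_context() -> tuple[str, str]:
    from Bio import SeqIO

    with _data_path("context.fa").open() as fh:
        recs = {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}
    return recs["context_wt"], recs["context_variant"]


def load_anchor_table() -> AnchorTable:
    df = pd.read_csv(_data_path("build_anchors.tsv"), sep="\t")
    return AnchorTable([(r.build_a, int(r.pos_a), r.build_b, int(r.pos_b))
                        for r in df.itertuples()])


def context_contig(build: str = "hg38") -> ReferenceContig:
    """The packaged wild-type exon-21 context as a coordinate-true window."""
    wt, _ = _read_context()
    if build == "hg38":
        return ReferenceContig("chr22", wt, "hg38", CONTEXT_START_HG38)
    if build == "hg19":
        return ReferenceContig("chr22", wt, "hg19",
                               CONTEXT_START_HG38 + HG19_MINUS_HG38)
    raise ValueError(f"unknown build {build!r}")


def _table2_record(row: pd.Series) -> CohortRecord:
    if pd.notna(row.get("pos")) and str(row.get("pos")).strip():
        variant: object = GenomicVariant(
            "chr22", int(row["pos"]), str(row["ref"]), str(row["alt"]),
            str(row["build"]), str(row["style"]))
    else:
        variant = str(row["coding"]) if pd.notna(row.get("coding")) else None
    link = row.get("same_individual_as")
    return CohortRecord(
        individual_id=str(row["individual_id"]),
        family_id=str(row["family_id"]),
        cohort=str(row["cohort"]),
        affected=True,
        variant=variant,
        inheritance=str(row["inheritance"]),
        same_individual_as=str(link) if pd.notna(link) and str(link).strip()
        else None,
        population_af=None,
        consequence_class="frameshift",
        formally_tested_asd=str(row["formally_tested_asd"]),
        transcript=str(row["transcript"]) if pd.notna(row.get("transcript"))
        else "",
        sources=(str(row["cohort"]),),
    )


PHENOTYPE_CATEGORIES = ("asd", "dysmorphia", "id_dd", "other_medical",
                        "psychiatric", "neurological", "organ_anomalies",
                        "language_speech")


def load_fixture(name: str):
    """Packaged transcription of a published table (or context/anchors).

    ``table1`` -> annotation rows (DataFrame); ``table2`` -> carrier records
    (list of :class:`CohortRecord`, 19 individuals + 6 ClinVar-only);
    ``table3`` -> phenotype records (list of CohortRecord with tri-state
    phenotype maps); ``context`` -> (wild-type, variant) sequence pair;
    ``build_anchors`` -> :class:`AnchorTable`.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of "
                       f"{FIXTURE_NAMES}")
    if name == "table1":
        return pd.read_csv(_data_path("table1.tsv"), sep="\t")
    if name == "table2":
        df = pd.read_csv(_data_path("table2.tsv"), sep="\t")
        return [_table2_record(row) for _, row in df.iterrows()]
    if name == "table3":
        df = pd.read_csv(_data_path("table3.tsv"), sep="\t")
        out = []
        for _, row in df.iterrows():
            out.append(CohortRecord(
                individual_id=str(row["individual_id"]),
                family_id=str(row["family_id"]), cohort="table3",
                affected=True, variant=None,
                formally_tested_asd=str(row["asd"]),
                phenotypes={c: str(row[c]) for c in PHENOTYPE_CATEGORIES}))
        return out
    if name == "context":
        return _read_context()
    return load_anchor_table()


@dataclass
class FixtureBundle:
    table1_records: pd.DataFrame
    table2_records: list[CohortRecord]
    table3_records: list[CohortRecord]
    context_wt: str
    context_variant: str
    build_anchors: AnchorTable


def fixture_bundle() -> FixtureBundle:
    wt, var = _read_context()
    return FixtureBundle(load_fixture("table1"), load_fixture("table2"),
                         load_fixture("table3"), wt, var,
                         load_anchor_table())


def cdna_key_map(reference: Optional[ReferenceContig] = None,
                 anchors: Optional[AnchorTable] = None
                 ) -> dict[tuple[str, str], NormalizedVariantKey]:
    """(transcript, c. spelling) -> canonical key, from the annotation table.

    This is the reconciliation map that lets carrier records reported only as
    coding changes join the genomic recurrence grouping.
    """
    reference = reference or context_contig("hg38")
    anchors = anchors or load_anchor_table()
    table1 = load_fixture("table1")
    out: dict[tuple[str, str], NormalizedVariantKey] = {}
    for _, row in table1.iterrows():
        if not (pd.notna(row["pos"]) and pd.notna(row["coding"])):
            continue
        pos = int(row["pos"])
        if str(row["build"]) != reference.build_label:
            pos = anchors.translate(pos, str(row["build"]),
                                    reference.build_label)
        v = GenomicVariant("chr22", pos, str(row["ref"]), str(row["alt"]),
                           reference.build_label, str(row["style"]))
        key = canonical_key(v, reference)
        out[(str(row["transcript"]), normalize_cdna_text(str(row["coding"])))
            ] = key
    return out


def shank3_domains() -> list[DomainAnnotation]:
    df = pd.read_csv(_data_path("domains.tsv"), sep="\t")
    return [DomainAnnotation(str(r["name"]), int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# Synthetic stand-in CDS and transcript models
# ---------------------------------------------------------------------------

#: Coding length of the stand-in CDS: 1730 residues + stop.
CDS_LENGTH = 5193
#: cDNA coordinates (NM-style) of engineered stop codons in the shifted
#: frames: the -1 frame (G deletion) stops at new-residue 57, the +1 frame
#: (G duplication) at new-residue 69.
_DEL_FRAME_STOP = 3848   # TAA at c.3848-3850
_DUP_FRAME_STOP = 3882   # TGA at c.3882-3884


def _tfree_flank(rng: np.random.Generator, n: int,
                 prev: str = "") -> str:
    """T-free sequence (no stop codons in any frame), runs capped below 4."""
    out: list[str] = []
    tail = prev[-3:]
    while len(out) < n:
        b = "ACG"[rng.integers(3)]
        recent = (tail + "".join(out))[-3:]
        if len(recent) == 3 and recent == b * 3:
            continue
        out.append(b)
    return "".join(out)


def make_shank3_like_cds() -> str:
    """Deterministic synthetic stand-in for the SHANK3 coding sequence.

    Not the real accession (no download): a 5,193-nt CDS that embeds the
    packaged exon-21 context at c.3639-3719 and is engineered so that the
    documented consequences hold exactly — wild-type Ala at codon 1227
    preceded by Gly-Gly encoded over an 8-G run ending at c.3679, the +1
    frame after a G duplication reaching its first stop at new-frame
    position 69, and the -1 frame after a G deletion at position 57.
    """
    wt_context, _ = _read_context()
    rng = np.random.default_rng(20211104)
    parts: list[str] = ["ATG"]
    parts.append(_tfree_flank(rng, CONTEXT_CDS_START - 1 - 3, "ATG"))
    parts.append(wt_context)                       # c.3639-3719
    cur = "".join(parts)
    parts.append(_tfree_flank(rng, _DEL_FRAME_STOP - 1 - 3719, cur))
    parts.append("TAA")                            # c.3848-3850
    cur = "".join(parts)
    parts.append(_tfree_flank(rng, _DUP_FRAME_STOP - 1 - 3850, cur))
    parts.append("TGA")                            # c.3882-3884
    cur = "".join(parts)
    parts.append(_tfree_flank(rng, CDS_LENGTH - 3 - 3884, cur))
    parts.append("TGA")                            # c.5191-5193
    cds = "".join(parts)
    assert len(cds) == CDS_LENGTH
    assert cds[3670:3671] == "T" and cds[3671:3679] == "G" * 8
    assert cds[3678:3681] == "GCC"    # codon 1227 = Ala
    runs = detect_homopolymer_runs(cds, 6)
    assert [(r.start, r.end, r.base) for r in runs] == [(3672, 3679, "G")]
    return cds


def make_transcript_models() -> tuple[ReferenceContig,
                                      dict[str, TranscriptModel]]:
    """Mini hg38-like reference plus two-exon stand-in transcript models.

    The final coding exon carries the packaged context at its true hg38
    coordinates; a single synthetic upstream exon supplies the cumulative
    coding length that makes the duplication project to c.3679 on the
    NM-style model and c.3676 on the ENST-style model (whose CDS numbering
    starts three bases later).
    """
    cds = make_shank3_like_cds()
    g0 = 50717000
    exon_a = (50717101, 50720716)          # CDS c.1-3616
    exon_b = (50721450, 50721601)          # CDS c.3617-3768
    rng = np.random.default_rng(4)
    pieces = []
    pieces.append(_tfree_flank(rng, exon_a[0] - g0))
    pieces.append(cds[:3616])
    cur = "".join(pieces)
    pieces.append(_tfree_flank(rng, exon_b[0] - exon_a[1] - 1, cur))
    pieces.append(cds[3616:3768])
    cur = "".join(pieces)
    pieces.append(_tfree_flank(rng, 50721700 - exon_b[1], cur))
    seq = "".join(pieces)
    contig = ReferenceContig("chr22", seq, "hg38", g0)
    assert contig.slice(CONTEXT_START_HG38,
                        CONTEXT_START_HG38 + 80) == _read_context()[0]
    assert [(r.start, r.end) for r in contig_runs(contig)] == [(50721505,
                                                                50721512)]
    nm = TranscriptModel.from_reference(
        "NM_033517.1-like-synthetic", contig, "+", [exon_a, exon_b],
        cds_start=1, cds_end=3768)
    # the alternative-numbering model starts its CDS three bases later
    enst = TranscriptModel.from_reference(
        "ENST00000262795.5-like-synthetic", contig, "+",
        [(exon_a[0] + 3, exon_a[1]), exon_b], cds_start=1, cds_end=3765)
    return contig, {"nm": nm, "enst": enst}


# ---------------------------------------------------------------------------
# FASTA / VCF output
# ---------------------------------------------------------------------------

def write_fasta(contig: ReferenceContig, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(contig.sequence), id=contig.name,
                    description=f"build={contig.build_label} "
                                f"start={contig.start}")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def write_cohort_vcf(trios: Sequence[TrioRecord], contig: ReferenceContig,
                     path) -> None:
    """Minimal VCF v4.2 (GT:AD:DP) for a simulated cohort.

    Carrier probands keep the spelling they were simulated with; each family
    contributes one record carrying trio genotypes.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig.name},length={contig.end}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allele depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                    'Description="Depth">')
    samples: list[str] = []
    for t in trios:
        samples += [t.proband_id, f"{t.family_id}.mo", f"{t.family_id}.fa"]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for t in trios:
            if not t.carrier or t.variant is None:
                continue
            v = t.variant
            rec = vcf.new_record(contig=contig.name, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            members = {
                t.proband_id: (t.proband, (0, 1)),
                f"{t.family_id}.mo": (t.mother, (0, 0)),
                f"{t.family_id}.fa": (t.father, (0, 0)),
            }
            for sample, (rc, gt) in members.items():
                rec.samples[sample]["GT"] = gt
                rec.samples[sample]["AD"] = (rc.depth - rc.alt, rc.alt)
                rec.samples[sample]["DP"] = rc.depth
            vcf.write(rec)
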