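"""Recurrent rare de novo variant aggregation across families and cohorts.

A genotype-first search filters rare de novo damaging variants, collapses
every annotation spelling of the same edit onto one canonical key (see
:mod:`recurvar.normalize`), deduplicates individuals that appear in more than
one cohort or publication, counts carriers per individual and per family,
tests case/control carrier enrichment with an exact conditional test, and
tabulates tri-state phenotype data (yes / no / not assessed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .normalize import (AnchorTable, GenomicVariant, NormalizedVariantKey,
                        ReferenceContig, canonical_key)

INHERITANCE_VALUES = ("de_novo", "maternal_mosaic", "paternal_mosaic",
                      "unknown")
CONSEQUENCE_CLASSES = ("stop_gain", "frameshift", "canonical_splice",
                       "missense_damaging", "other")
TRISTATE = ("yes", "no", "not_assessed")

#: Inheritance modes that qualify as "de novo-like" for recurrence counting.
#: Transmission through a somatically mosaic parent is a fresh mutational
#: event in the family and is counted with the de novo carriers.
DE_NOVO_LIKE = ("de_novo", "maternal_mosaic", "paternal_mosaic")


@dataclass
class CohortRecord:
    """One individual's observation of a candidate variant."""

    individual_id: str
    family_id: str
    cohort: str
    affected: bool
    variant: Union[GenomicVariant, str, None]   # genomic spelling or cDNA text
    inheritance: str = "unknown"
    same_individual_as: Optional[str] = None
    population_af: Optional[float] = None
    consequence_class: str = "other"
    formally_tested_asd: str = "not_assessed"
    phenotypes: dict[str, str] = field(default_factory=dict)
    transcript: str = ""
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_VALUES:
            raise ValueError(f"bad inheritance {self.inheritance!r}")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(f"bad consequence_class "
                             f"{self.consequence_class!r}")
        if self.formally_tested_asd not in TRISTATE:
            raise ValueError("formally_tested_asd must be tri-state")
        for cat, val in self.phenotypes.items():
            if val not in TRISTATE:
                raise ValueError(f"phenotype {cat!r} must be tri-state, "
                                 f"got {val!r}")


@dataclass
class PipelineConfig:
    rare_af_threshold: float = 0.001
    damaging_classes: frozenset = frozenset(
        {"stop_gain", "frameshift", "canonical_splice", "missense_damaging"})
    min_families_for_recurrence: int = 2
    alpha: float = 0.05
    percentage_decimals: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.rare_af_threshold < 1:
            raise ValueError("rare_af_threshold must be in (0,1)")
        if self.min_families_for_recurrence < 2:
            raise ValueError("min_families_for_recurrence must be >= 2")


@dataclass
class RecurrenceGroup:
    key: NormalizedVariantKey
    members: list[CohortRecord]

    @property
    def n_individuals(self) -> int:
        return len(self.members)

    @property
    def n_families(self) -> int:
        return len({m.family_id for m in self.members})


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_rare_damaging_de_novo(records: Iterable[CohortRecord],
                                 cfg: Optional[PipelineConfig] = None
                                 ) -> list[CohortRecord]:
    """Keep de novo-like, rare, damaging-class records (order-stable).

    Missing population allele frequency is treated as 0 (absent from
    controls), which is conservative for a rarity filter.
    """
    cfg = cfg or PipelineConfig()
    kept = []
    for rec in records:
        af = rec.population_af if rec.population_af is not None else 0.0
        if rec.inheritance not in DE_NOVO_LIKE:
            continue
        if af >= cfg.rare_af_threshold:
            continue
        if rec.consequence_class not in cfg.damaging_classes:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# Deduplication across cohorts / publications
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def deduplicate(records: Sequence[CohortRecord],
                extra_links: Iterable[tuple[str, str]] = (),
                key_fn: Optional[Callable[[CohortRecord],
                                          NormalizedVariantKey]] = None
                ) -> list[CohortRecord]:
    """One representative per linked component of ``same_individual_as``.

    Links are closed symmetrically/transitively (union-find).  ``extra_links``
    adds explicit cross-study identities not encoded in the records.  When
    ``key_fn`` is supplied, linked records with non-equivalent variants raise
    ``ValueError``.  The representative is the first record of its component
    in input order; merged source labels are retained on ``sources``.
    """
    by_id = {r.individual_id: r for r in records}
    uf = _UnionFind()
    for r in records:
        uf.find(r.individual_id)
        if r.same_individual_as:
            if r.same_individual_as not in by_id:
                raise ValueError(f"{r.individual_id} linked to unknown "
                                 f"individual {r.same_individual_as!r}")
            uf.union(r.individual_id, r.same_individual_as)
    for a, b in extra_links:
        if a not in by_id or b not in by_id:
            raise ValueError(f"extra link ({a!r}, {b!r}) names unknown "
                             "individuals")
        uf.union(a, b)

    components: dict[str, list[CohortRecord]] = {}
    for r in records:
        components.setdefault(uf.find(r.individual_id), []).append(r)

    out: list[CohortRecord] = []
    for r in records:
        comp = components[uf.find(r.individual_id)]
        if comp[0] is not r:
            continue
        if key_fn is not None and len(comp) > 1:
            keys = {key_fn(m) for m in comp}
            if len(keys) > 1:
                ids = [m.individual_id for m in comp]
                raise ValueError(f"linked records {ids} carry non-equivalent "
                                 "variants")
        merged_sources = tuple(dict.fromkeys(
            s for m in comp for s in (m.sources or (m.cohort,))))
        rep = CohortRecord(**{**r.__dict__, "sources": merged_sources})
        out.append(rep)
    return out


# ---------------------------------------------------------------------------
# Grouping by canonical key
# ---------------------------------------------------------------------------

def resolve_key(record: CohortRecord, reference: ReferenceContig,
                anchors: Optional[AnchorTable] = None,
                cdna_key_map: Optional[Mapping[tuple[str, str],
                                               NormalizedVariantKey]] = None
                ) -> NormalizedVariantKey:
    """Canonical key for a record's variant, whatever its spelling.

    Genomic variants are normalized on ``reference`` (translating builds
    through ``anchors`` if needed); cDNA-only records are looked up in
    ``cdna_key_map`` keyed by (transcript accession, normalized c. spelling)
    — the reconciliation table derived from published annotation rows.
    """
    v = record.variant
    if isinstance(v, GenomicVariant):
        if v.build_label != reference.build_label:
            if anchors is None:
                raise ValueError(f"record {record.individual_id} is in build "
                                 f"{v.build_label}; no anchor table given")
            pos = anchors.translate(v.pos, v.build_label,
                                    reference.build_label)
            v = GenomicVariant(v.contig, pos, v.ref, v.alt,
                               reference.build_label, v.style)
        return canonical_key(v, reference)
    if isinstance(v, str) and v:
        if cdna_key_map is None:
            raise ValueError(f"record {record.individual_id} has a cDNA-only "
                             "variant but no cdna_key_map was supplied")
        key = (record.transcript, normalize_cdna_text(v))
        if key not in cdna_key_map:
            raise KeyError(f"no reconciliation entry for {key}")
        return cdna_key_map[key]
    raise ValueError(f"record {record.individual_id} has no variant")


def normalize_cdna_text(text: str) -> str:
    """Normalize a coding-change spelling for table lookup.

    Collapses whitespace and drops the redundant repeated base from ``dupG``
    style spellings (``c.3679dupG`` == ``c.3679dup``).
    """
    t = text.replace(" ", "")
    for op in ("dup", "del"):
        i = t.find(op)
        if i != -1 and t[i + len(op):].isalpha():
            t = t[:i + len(op)]
    return t


def group_recurrent(records: Sequence[CohortRecord],
                    reference: ReferenceContig,
                    anchors: Optional[AnchorTable] = None,
                    cfg: Optional[PipelineConfig] = None,
                    cdna_key_map: Optional[Mapping] = None,
                    extra_links: Iterable[tuple[str, str]] = ()
                    ) -> list[RecurrenceGroup]:
    """Groups of deduplicated individuals sharing one canonical key.

    Only keys seen in at least ``cfg.min_families_for_recurrence`` distinct
    families are reported; groups are sorted by family count, descending.
    Records whose variant cannot be resolved raise — unmappable records are
    never dropped silently.
    """
    cfg = cfg or PipelineConfig()

    def kf(rec: CohortRecord) -> NormalizedVariantKey:
        return resolve_key(rec, reference, anchors, cdna_key_map)

    deduped = deduplicate(records, extra_links=extra_links, key_fn=kf)
    buckets: dict[NormalizedVariantKey, list[CohortRecord]] = {}
    for rec in deduped:
        buckets.setdefault(kf(rec), []).append(rec)
    groups = [RecurrenceGroup(k, members) for k, members in buckets.items()
              if len({m.family_id for m in members})
              >= cfg.min_families_for_recurrence]
    groups.sort(key=lambda g: -g.n_families)
    return groups


# ---------------------------------------------------------------------------
# Carrier frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyReport:
    individual_fraction: Fraction
    family_fraction: Fraction
    individual_pct: str
    family_pct: str


def format_percentage(frac: Fraction, decimals: int = 2) -> str:
    """Round-half-even percentage string, e.g. Fraction(6, 7521) -> '0.08%'."""
    pct = Decimal(frac.numerator * 100) / Decimal(frac.denominator)
    q = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(q, rounding=ROUND_HALF_EVEN)}%"


def carrier_frequencies(n_carriers: int, n_carrier_families: int,
                        n_affected: int, n_families: int,
                        cfg: Optional[PipelineConfig] = None
                        ) -> FrequencyReport:
    cfg = cfg or PipelineConfig()
    if n_affected <= 0 or n_families <= 0:
        raise ValueError("denominators must be positive")
    fi = Fraction(n_carriers, n_affected)
    ff = Fraction(n_carrier_families, n_families)
    d = cfg.percentage_decimals
    return FrequencyReport(fi, ff, format_percentage(fi, d),
                           format_percentage(ff, d))


# ---------------------------------------------------------------------------
# Exact association test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


def fisher_exact(table: Sequence[Sequence[int]]) -> AssociationResult:
    """Two-sided exact conditional (hypergeometric) test on a 2x2 table.

    Sums the probabilities of every table with the same margins whose
    hypergeometric probability does not exceed the observed table's
    (Fisher's rule), accumulating in log-factorial space so the test stays
    exact for large totals.  The odds ratio is (a*d)/(b*c), reported as
    ``inf`` when b*c == 0 and a*d > 0, and ``nan`` for a degenerate table.
    """
    (a, b), (c, d) = ((int(table[0][0]), int(table[0][1])),
                      (int(table[1][0]), int(table[1][1])))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("at least one margin must be positive")
    row1, col1 = a + b, a + c

    lf = math.lgamma  # log-factorial via lgamma(k + 1)

    def log_p(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, col1, row1)
        return (lf(row1 + 1) - lf(x + 1) - lf(row1 - x + 1)
                + lf(n - row1 + 1) - lf(col1 - x + 1)
                - lf(n - row1 - col1 + x + 1)
                - (lf(n + 1) - lf(col1 + 1) - lf(n - col1 + 1)))

    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    lp_obs = log_p(a)
    # relative tolerance guards against ties broken by round-off
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    p = min(1.0, total)

    if b * c == 0:
        orat = math.nan if a * d == 0 else math.inf
    else:
        orat = (a * d) / (b * c)
    return AssociationResult(((a, b), (c, d)), orat, p)


# ---------------------------------------------------------------------------
# Phenotype matrix
# ---------------------------------------------------------------------------

def phenotype_matrix(records: Sequence[CohortRecord],
                     categories: Sequence[str]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tri-state phenotype matrix and per-category tallies.

    Rows follow the input order with individuals grouped by family (stable:
    families ordered by first appearance).  A record lacking a value for a
    requested category is counted ``not_assessed``; a requested category that
    no record knows raises (requesting a subset is fine).
    """
    if records:
        seen = set().union(*(set(r.phenotypes) for r in records))
        unknown = [c for c in categories if c not in seen]
        if unknown:
            raise KeyError(f"categories absent from every record: {unknown}")
    fam_order = list(dict.fromkeys(r.family_id for r in records))
    ordered = sorted(records,
                     key=lambda r: fam_order.index(r.family_id))
    matrix = pd.DataFrame(
        [[r.phenotypes.get(cat, "not_assessed") for cat in categories]
         for r in ordered],
        index=[r.individual_id for r in ordered], columns=list(categories))
    tallies = pd.DataFrame(
        {state: (matrix == state).sum(axis=0) for state in TRISTATE})
    return matrix, tallies


# ---------------------------------------------------------------------------
# I/O helpers (pedigree TSV, VCF, run summary)
# ---------------------------------------------------------------------------

def read_pedigree(path) -> pd.DataFrame:
    """Pedigree TSV: individual, family, father, mother, affected."""
    ped = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "family", "father", "mother", "affected"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree lacks columns {sorted(missing)}")
    return ped


def records_from_vcf(path, ped: pd.DataFrame,
                     build_label: str = "toy1") -> list[CohortRecord]:
    """Cohort records for affected individuals carrying an ALT allele.

    Reads a (biallelic) VCF with GT:AD:DP genotypes; inheritance is taken as
    de novo when both parents are genotyped 0/0, unknown otherwise.
    Consequence class and population AF are the caller's to refine — the
    package does not annotate.
    """
    import pysam

    ped_idx = ped.set_index("individual")
    out: list[CohortRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            for sample, call in site.samples.items():
                gt = call.get("GT")
                if not gt or not any(g == 1 for g in gt if g is not None):
                    continue
                if sample not in ped_idx.index:
                    continue
                row = ped_idx.loc[sample]
                if str(row["affected"]) not in ("1", "2", "yes", "True"):
                    continue
                father, mother = row["father"], row["mother"]

                def parent_has_alt(pid: str) -> Optional[bool]:
                    if pid in ("0", "", None) or pid not in site.samples:
                        return None
                    pgt = site.samples[pid].get("GT")
                    if pgt is None:
                        return None
                    return any(g == 1 for g in pgt if g is not None)

                pa, ma = parent_has_alt(father), parent_has_alt(mother)
                inheritance = ("de_novo" if pa is False and ma is False
                               else "unknown")
                var = GenomicVariant(site.chrom, site.pos, site.ref,
                                     site.alts[0], build_label,
                                     "vcf_anchored"
                                     if site.ref[0] == site.alts[0][0]
                                     else "substitution")
                out.append(CohortRecord(
                    individual_id=sample, family_id=str(row["family"]),
                    cohort="vcf", affected=True, variant=var,
                    inheritance=inheritance,
                    consequence_class="frameshift"
                    if len(site.ref) != len(site.alts[0]) else "other"))
    return out


def run_summary_json(groups: Sequence[RecurrenceGroup],
                     freq: Optional[FrequencyReport] = None,
                     association: Optional[AssociationResult] = None) -> str:
    payload: dict = {
        "groups": [{
            "contig": g.key.contig,
            "build": g.key.build_label,
            "left_anchor": g.key.left_anchor,
            "ref_core": g.key.ref_core,
            "alt_core": g.key.alt_core,
            "n_individuals": g.n_individuals,
            "n_families": g.n_families,
            "members": [m.individual_id for m in g.members],
        } for g in groups],
    }
    if freq is not None:
        payload["carrier_frequency"] = {
            "individuals": freq.individual_pct,
            "families": freq.family_pct,
        }
    if association is not None:
        payload["association"] = {
            "table": association.table,
            "odds_ratio": association.odds_ratio,
            "p_two_sided": association.p_two_sided,
        }
    return json.dumps(payload, indent=2)
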