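"""Frameshift consequence prediction and HGVS-style protein naming.

Applies a coding-sequence edit (dup / del / ins / sub in cDNA coordinates),
translates wild-type and edited sequences with the standard genetic code, and
names the outcome in HGVS protein notation — for a frameshift,
``p.(Wt)(Pos)(New)fs*(N)`` where N counts the new stop codon with the first
changed residue as 1.  Also reports which annotated protein domains a
truncation leaves intact, truncates, or removes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

_CODON = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)

EDIT_KINDS = ("dup", "del", "ins", "sub")
CONSEQUENCE_KINDS = ("frameshift", "nonsense", "missense", "synonymous",
                     "no_stop")


def aa3(residue: str) -> str:
    """One-letter to three-letter residue code ('A' -> 'Ala', '*' -> 'Ter')."""
    return "Ter" if residue == "*" else seq3(residue)


@dataclass(frozen=True)
class CdsEdit:
    kind: str
    position: int          # 1-based cDNA coordinate within the CDS
    bases: str = ""        # inserted (ins) or replacement (sub) bases

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.kind in ("ins", "sub") and not self.bases:
            raise ValueError(f"{self.kind} requires bases")


@dataclass(frozen=True)
class ProteinConsequence:
    kind: str
    first_changed_residue: int
    wt_residue: str
    new_residue: str
    stop_offset: Optional[int]     # N in fs*N; None when no new stop found
    variant_protein: str
    hgvs_p: str


@dataclass(frozen=True)
class DomainAnnotation:
    name: str
    start: int   # 1-based residue interval on the wild-type protein
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("need 1 <= start <= end")


def _check_cds(cds: str) -> None:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    if cds[-3:] not in _STOPS:
        raise ValueError("CDS must end with a stop codon")


def apply_cds_edit(cds: str, edit: CdsEdit) -> str:
    """Edited nucleotide string.

    ``dup`` inserts a copy of the base at ``position`` immediately after it;
    ``del`` removes it; ``ins`` inserts ``bases`` immediately after
    ``position``; ``sub`` replaces the base at ``position``.

    Only range/alphabet validity is enforced here, so intermediate edited
    sequences (which are generally no longer well-formed CDSs) can be edited
    again; :func:`frameshift_consequence` checks CDS well-formedness.
    """
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    i = edit.position - 1
    if i >= len(cds):
        raise IndexError(f"position {edit.position} beyond CDS "
                         f"length {len(cds)}")
    if edit.kind == "dup":
        return cds[:i + 1] + cds[i] + cds[i + 1:]
    if edit.kind == "del":
        return cds[:i] + cds[i + 1:]
    if edit.kind == "ins":
        return cds[:i + 1] + edit.bases + cds[i + 1:]
    return cds[:i] + edit.bases + cds[i + 1:]


def translate_cds(dna: str) -> str:
    """In-frame translation from position 1, stopping at the first stop.

    Returns the residues before the stop; if no stop codon is reached the
    full-length translation of complete codons is returned (the caller
    distinguishes the two via the CDS itself or uses
    :func:`frameshift_consequence`, which reports ``no_stop`` explicitly).
    """
    if len(dna) < 3:
        raise ValueError("need at least one codon")
    bad = set(dna) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    residues = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i:i + 3]
        if codon in _STOPS:
            return "".join(residues)
        residues.append(_CODON[codon])
    return "".join(residues)


def _translate_with_stop(dna: str) -> tuple[str, bool]:
    protein = translate_cds(dna)
    seen_stop = len(protein) < len(dna) // 3 or \
        dna[3 * len(protein):3 * len(protein) + 3] in _STOPS
    return protein, seen_stop


def frameshift_consequence(cds: str, edit: CdsEdit) -> ProteinConsequence:
    """Compare wild-type and edited translations and name the consequence.

    The first changed residue is the first position at which the proteins
    differ (for edits inside repeats this coincides with the HGVS 3'-rule
    name, because the repeat-encoded residues are unchanged up to the last
    repeat codon).  For a frameshift, ``stop_offset`` counts the new stop
    with the first changed residue as 1; when the new frame reaches the end
    of the transcript without a stop the consequence is ``no_stop`` and the
    translated tail is still reported.
    """
    _check_cds(cds)
    wt = translate_cds(cds)
    edited = apply_cds_edit(cds, edit)
    var, var_has_stop = _translate_with_stop(edited)

    frame_shifted = (len(edited) - len(cds)) % 3 != 0

    # first differing residue
    first = None
    for i, (a, b) in enumerate(zip(wt, var)):
        if a != b:
            first = i + 1
            break
    if first is None:
        if len(var) == len(wt) and not frame_shifted:
            return ProteinConsequence("synonymous", 0, "", "", None, var,
                                      "p.(=)")
        first = min(len(wt), len(var)) + 1

    wt_res = wt[first - 1] if first <= len(wt) else "*"
    new_res = var[first - 1] if first <= len(var) else "*"

    if frame_shifted:
        if not var_has_stop:
            name = (f"p.{aa3(wt_res)}{first}{aa3(new_res)}fs*?"
                    if first <= len(var) else "p.?")
            return ProteinConsequence("no_stop", first, wt_res, new_res,
                                      None, var, name)
        stop_offset = len(var) - first + 2  # stop position, first changed = 1
        name = f"p.{aa3(wt_res)}{first}{aa3(new_res)}fs*{stop_offset}"
        return ProteinConsequence("frameshift", first, wt_res, new_res,
                                  stop_offset, var, name)

    # in-frame edit
    if new_res == "*" or len(var) < len(wt):
        if first == len(var) + 1 and var_has_stop:
            name = f"p.{aa3(wt_res)}{first}Ter"
            return ProteinConsequence("nonsense", first, wt_res, "*", None,
                                      var, name)
    if not var_has_stop:
        return ProteinConsequence("no_stop", first, wt_res, new_res, None,
                                  var, f"p.{aa3(wt_res)}{first}{aa3(new_res)}")
    name = f"p.{aa3(wt_res)}{first}{aa3(new_res)}"
    return ProteinConsequence("missense", first, wt_res, new_res, None, var,
                              name)


DOMAIN_STATUSES = ("intact", "truncated", "lost")


def domains_lost(consequence: ProteinConsequence,
                 domains: Iterable[DomainAnnotation],
                 wt_length: Optional[int] = None) -> dict[str, str]:
    """Per-domain status given the truncation point.

    A domain entirely 5' of the first changed residue is ``intact``, one
    spanning it is ``truncated``, one entirely 3' of it is ``lost``.
    """
    cut = consequence.first_changed_residue
    out: dict[str, str] = {}
    for dom in domains:
        if wt_length is not None and dom.end > wt_length:
            raise ValueError(f"domain {dom.name} extends beyond the "
                             f"wild-type protein ({dom.end} > {wt_length})")
        if dom.end < cut:
            out[dom.name] = "intact"
        elif dom.start >= cut:
            out[dom.name] = "lost"
        else:
            out[dom.name] = "truncated"
    return out
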