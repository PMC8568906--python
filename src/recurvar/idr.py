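"""Sequence features of intrinsically disordered regions (IDRs).

Frameshift tails that replace a disordered region change its physical
character: charge patterning (sequence charge decoration, SCD), arginine
dipeptide content (RG / RR, associated with RNA binding and phase
separation), cysteine fraction, and short linear interaction motifs such as
the SH3 class I consensus [RK]xxPxxP.  This module computes those features
for wild-type and variant proteins and their differences.

SCD (Sawle & Ghosh) for charges :math:`q_1..q_N` is

.. math:: \\mathrm{SCD} = \\frac{1}{N} \\sum_{m>n} q_m q_n \\sqrt{m-n}

More negative values indicate well-mixed opposite charges; blocky
same-charge patterning drives it positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default residue charge model: Asp/Glu -1, Lys/Arg +1, His 0 (the common
#: SCD convention; configurable because His titrates near physiological pH).
DEFAULT_CHARGES: dict[str, int] = {"D": -1, "E": -1, "K": 1, "R": 1, "H": 0}

#: Registered positional motif classes; ``x`` means any residue.  Extensible
#: by passing a custom registry to :func:`motif_count`.
MOTIF_REGISTRY: dict[str, str] = {
    "SH3_class1": "[RK]..P..P",
}


@dataclass(frozen=True)
class IDRFeatureVector:
    scd: float
    rg_count: int
    rr_count: int
    cys_fraction: float
    sh3_class1_count: int
    length: int


@dataclass(frozen=True)
class FeatureDelta:
    """Per-feature variant minus wild-type differences."""

    scd: float
    rg_count: int
    rr_count: int
    cys_fraction: float
    sh3_class1_count: int
    length: int
    wild_type: IDRFeatureVector
    variant: IDRFeatureVector
    tail: Optional[IDRFeatureVector] = None


def _charges(protein: str, charges: Optional[Mapping[str, int]],
             strict: bool) -> np.ndarray:
    table = DEFAULT_CHARGES if charges is None else dict(charges)
    if any(c not in (-1, 0, 1) for c in table.values()):
        raise ValueError("charges must be in {-1, 0, +1}")
    unknown = set(protein) - AMINO_ACIDS - set(table)
    if strict and unknown:
        raise ValueError(f"unknown residue letters: {sorted(unknown)}")
    return np.array([table.get(res, 0) for res in protein], dtype=float)


def scd(protein: str, charges: Optional[Mapping[str, int]] = None,
        strict: bool = True) -> float:
    """Sequence charge decoration of the full supplied sequence.

    Callers wanting SCD of an IDR window pass the window itself; the package
    does not predict disorder.  In lenient mode unknown letters contribute
    charge 0.
    """
    if len(protein) < 2:
        raise ValueError("need at least two residues")
    q = _charges(protein, charges, strict)
    n = len(q)
    idx = np.nonzero(q)[0]
    if idx.size < 2:
        return 0.0
    qi = q[idx]
    total = 0.0
    # pair sum restricted to charged residues; sqrt of index separation
    for j in range(1, idx.size):
        total += float(np.sum(qi[:j] * qi[j]
                              * np.sqrt(idx[j] - idx[:j])))
    return total / n


def dipeptide_count(protein: str, pair: str) -> int:
    """Overlapping occurrences of a two-residue word, scanning left to right."""
    if len(pair) != 2:
        raise ValueError("pair must have length 2")
    return sum(1 for i in range(len(protein) - 1)
               if protein[i:i + 2] == pair)


def residue_fraction(protein: str, residue: str) -> float:
    if not protein:
        raise ValueError("empty sequence")
    return protein.count(residue) / len(protein)


def motif_count(protein: str, pattern: str = "SH3_class1",
                registry: Optional[Mapping[str, str]] = None) -> int:
    """Count all (possibly overlapping) matches of a registered motif class."""
    table = MOTIF_REGISTRY if registry is None else registry
    if pattern not in table:
        raise KeyError(f"unregistered motif pattern {pattern!r}")
    rx = re.compile(f"(?=({table[pattern]}))")
    return sum(1 for _ in rx.finditer(protein))


def feature_vector(protein: str,
                   charges: Optional[Mapping[str, int]] = None,
                   strict: bool = True) -> IDRFeatureVector:
    return IDRFeatureVector(
        scd=scd(protein, charges, strict),
        rg_count=dipeptide_count(protein, "RG"),
        rr_count=dipeptide_count(protein, "RR"),
        cys_fraction=residue_fraction(protein, "C"),
        sh3_class1_count=motif_count(protein, "SH3_class1"),
        length=len(protein),
    )


def feature_delta(wild_type: str, variant: str,
                  charges: Optional[Mapping[str, int]] = None,
                  first_changed_residue: Optional[int] = None,
                  strict: bool = True) -> FeatureDelta:
    """Variant minus wild-type feature differences.

    When ``first_changed_residue`` is given, features of the novel frameshift
    tail (variant residues from that index on) are additionally reported.
    """
    if not wild_type or not variant:
        raise ValueError("sequences must be non-empty")
    wt = feature_vector(wild_type, charges, strict)
    var = feature_vector(variant, charges, strict)
    tail = None
    if first_changed_residue is not None:
        tail_seq = variant[first_changed_residue - 1:]
        if len(tail_seq) >= 2:
            tail = feature_vector(tail_seq, charges, strict)
    return FeatureDelta(
        scd=var.scd - wt.scd,
        rg_count=var.rg_count - wt.rg_count,
        rr_count=var.rr_count - wt.rr_count,
        cys_fraction=var.cys_fraction - wt.cys_fraction,
        sh3_class1_count=var.sh3_class1_count - wt.sh3_class1_count,
        length=var.length - wt.length,
        wild_type=wt, variant=var, tail=tail,
    )
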