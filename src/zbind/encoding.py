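"""Peptide records and z-scale descriptor encoding.

A peptide of length L becomes a flat descriptor vector of 3L reals,
{z1(aa1), z2(aa1), z3(aa1), ..., z3(aaL)}, the standard QSAR encoding for
fixed-length peptide sets.  Binding affinities (ic50, nM) are modelled on the
natural-log scale throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aa_properties import AMINO_ACIDS, ZScaleTable

CLASS_I_LENGTH = 9
CLASS_II_LENGTH = 15

_STANDARD = set(AMINO_ACIDS)


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, aa in enumerate(sequence):
        if aa not in _STANDARD:
            raise ValueError(
                f"non-standard residue {aa!r} at position {i + 1} in {sequence!r}"
            )


@dataclass
class PeptideRecord:
    """One peptide with optional binding affinity.

    ``ln_ic50`` is derived from ``ic50_nM`` when absent; if both are given
    they must agree.
    """

    sequence: str
    allele: str = ""
    ic50_nM: float | None = None
    ln_ic50: float | None = None

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if self.ic50_nM is not None:
            if not (self.ic50_nM > 0):
                raise ValueError(f"ic50 must be positive (nM), got {self.ic50_nM}")
            ln = math.log(self.ic50_nM)
            if self.ln_ic50 is None:
                self.ln_ic50 = ln
            elif abs(self.ln_ic50 - ln) > 1e-9 * max(1.0, abs(ln)):
                raise ValueError(
                    f"inconsistent ln_ic50={self.ln_ic50} for ic50={self.ic50_nM} nM"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DescriptorVector:
    """Flat z-scale descriptor of one peptide (3 values per residue)."""

    values: np.ndarray  # length 3L
    position_labels: tuple[str, ...]  # length L

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (3 * len(self.position_labels),):
            raise ValueError("descriptor length must be 3 x number of positions")


def position_labels(length: int, mhc_class: str) -> list[str]:
    """Binding-groove position labels.

    Class I 9-mers occupy pockets P1..P9.  Class II 15-mers place a 9-residue
    core in the open groove with three peptide-flanking residues on each side:
    N-3, N-2, N-1, P1..P9, C+1, C+2, C+3.
    """
    cls = str(mhc_class).upper().removeprefix("MHC-")
    if cls == "I" and length == CLASS_I_LENGTH:
        return [f"P{i}" for i in range(1, 10)]
    if cls == "II" and length == CLASS_II_LENGTH:
        return (
            ["N-3", "N-2", "N-1"]
            + [f"P{i}" for i in range(1, 10)]
            + ["C+1", "C+2", "C+3"]
        )
    raise ValueError(
        f"unsupported (length={length}, class={mhc_class!r}): expected "
        f"(9, I) or (15, II)"
    )


def default_labels(length: int) -> list[str]:
    """Groove labels for the supported geometries, generic P1..PL otherwise."""
    if length == CLASS_I_LENGTH:
        return position_labels(length, "I")
    if length == CLASS_II_LENGTH:
        return position_labels(length, "II")
    return [f"P{i}" for i in range(1, length + 1)]


def encode_peptide(p: PeptideRecord | str, zt: ZScaleTable) -> DescriptorVector:
    """Encode one peptide: residue i contributes (z1, z2, z3) at slots 3i-2..3i."""
    seq = p.sequence if isinstance(p, PeptideRecord) else p
    _validate_sequence(seq)
    vals = np.concatenate([zt.triple(aa) for aa in seq])
    return DescriptorVector(values=vals, position_labels=tuple(default_labels(len(seq))))


def encode_dataset(
    records: Sequence[PeptideRecord], zt: ZScaleTable
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a uniform single-allele peptide set into (X, y).

    Returns the n x 3L descriptor matrix (row order preserved) and the
    response vector of ln(ic50).  Mixed lengths, mixed alleles or missing
    affinities are rejected with the offending records listed.
    """
    if not records:
        raise ValueError("no records to encode")
    length = len(records[0].sequence)
    allele = records[0].allele
    bad_len = [i for i, r in enumerate(records) if len(r.sequence) != length]
    if bad_len:
        raise ValueError(f"mixed peptide lengths; offending record indices {bad_len}")
    bad_allele = [i for i, r in enumerate(records) if r.allele != allele]
    if bad_allele:
        raise ValueError(f"mixed alleles; offending record indices {bad_allele}")
    no_y = [i for i, r in enumerate(records) if r.ln_ic50 is None]
    if no_y:
        raise ValueError(f"missing affinities; offending record indices {no_y}")
    X = np.vstack([encode_peptide(r, zt).values for r in records])
    y = np.array([r.ln_ic50 for r in records], dtype=float)
    return X, y
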