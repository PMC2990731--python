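"""File formats and proteome k-mer sampling.

Binding data travel as TSV with columns ``allele  peptide  ic50_nM``
('#' comment lines ignored, UTF-8).  Proteomes are standard FASTA (read via
Biopython).  ``sample_kmers`` draws random fixed-length windows from a
proteome to build test sets of peptides, the way a random 15-mer comparator
set is drawn from a bacterial proteome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aa_properties import AMINO_ACIDS
from .encoding import CLASS_I_LENGTH, CLASS_II_LENGTH, PeptideRecord

_STANDARD = set(AMINO_ACIDS)
_COLUMNS = ["allele", "peptide", "ic50_nM"]


def _class_for_length(length: int) -> str | None:
    if length == CLASS_I_LENGTH:
        return "I"
    if length == CLASS_II_LENGTH:
        return "II"
    return None


@dataclass
class BindingDataset:
    """A uniform-length peptide binding dataset, possibly multi-allele.

    ``subset_tags`` optionally labels each record (e.g. the generating subset
    of a synthetic dataset); ``ln_true`` is generator ground-truth metadata
    (uncensored ln ic50) and is never written by the standard TSV view.
    """

    records: list[PeptideRecord]
    mhc_class: str | None = None
    subset_tags: list[str] | None = None
    ln_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty dataset")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"mixed peptide lengths in dataset: {sorted(lengths)}")
        if self.mhc_class is None:
            self.mhc_class = _class_for_length(self.peptide_length)
        if self.subset_tags is not None and len(self.subset_tags) != len(self.records):
            raise ValueError("subset_tags length must match records")

    @property
    def peptide_length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def alleles(self) -> set[str]:
        return {r.allele for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def for_allele(self, allele: str) -> list[PeptideRecord]:
        return [r for r in self.records if r.allele == allele]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "allele": [r.allele for r in self.records],
                "peptide": [r.sequence for r in self.records],
                "ic50_nM": [r.ic50_nM for r in self.records],
            }
        )


def read_binding_table(path: str | Path) -> BindingDataset:
    """Read a binding TSV; malformed rows are rejected with line numbers.

    Duplicate (allele, peptide) pairs are retained with a warning (repeat
    measurements are common in assay compilations).
    """
    path = Path(path)
    records: list[PeptideRecord] = []
    errors: list[str] = []
    with path.open(encoding="utf-8") as fh:
        lines = fh.readlines()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            cols = line.split("\t")
            if cols != _COLUMNS:
                raise ValueError(
                    f"{path.name}:{lineno}: header must be {_COLUMNS}, got {cols}"
                )
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            errors.append(f"line {lineno}: expected 3 columns, got {len(parts)}")
            continue
        allele, peptide, ic50 = (p.strip() for p in parts)
        try:
            records.append(
                PeptideRecord(sequence=peptide, allele=allele, ic50_nM=float(ic50))
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if not header_seen:
        raise ValueError(f"{path.name}: empty file or missing header")
    if errors:
        raise ValueError(f"{path.name}: malformed rows:\n  " + "\n  ".join(errors))
    seen: dict[tuple[str, str], int] = {}
    for r in records:
        seen[(r.allele, r.sequence)] = seen.get((r.allele, r.sequence), 0) + 1
    dupes = [k for k, c in seen.items() if c > 1]
    if dupes:
        warnings.warn(
            f"{len(dupes)} duplicate (allele, peptide) pairs retained", stacklevel=2
        )
    return BindingDataset(records=records)


def write_binding_table(ds: BindingDataset | Sequence[PeptideRecord], path: str | Path) -> None:
    """Write a binding TSV (round-trips bit-identically through read_binding_table)."""
    records = ds.records if isinstance(ds, BindingDataset) else list(ds)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in records:
            ic50 = "" if r.ic50_nM is None else repr(float(r.ic50_nM))
            fh.write(f"{r.allele}\t{r.sequence}\t{ic50}\n")


def read_fasta(path: str | Path, strict: bool = True) -> list[tuple[str, str]]:
    """Read FASTA as (identifier, sequence) pairs, order preserved.

    Sequences are uppercased and terminal '*' stop symbols stripped.  In
    strict mode records with non-standard residues are skipped with a
    warning; in lenient mode they are kept as-is.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().strip("*")
        if strict and (set(seq) - _STANDARD):
            bad = sorted(set(seq) - _STANDARD)
            warnings.warn(
                f"skipping record {rec.id!r}: non-standard residues {bad}",
                stacklevel=2,
            )
            continue
        out.append((rec.id, seq))
    if not out:
        raise ValueError(f"{path.name}: no usable FASTA records")
    return out


def sample_kmers(
    proteome: Sequence[str] | Sequence[tuple[str, str]],
    k: int = 15,
    n: int = 1000,
    seed: int = 0,
) -> list[PeptideRecord]:
    """Draw n distinct k-mer windows uniformly at random from a proteome.

    Sampling is without replacement over distinct (sequence, offset) windows
    containing only standard residues; duplicate peptide strings from
    different windows may occur (proteomes repeat motifs).  If fewer than n
    eligible windows exist, all are returned with a warning.
    """
    seqs = [s[1] if isinstance(s, tuple) else s for s in proteome]
    windows: list[str] = []
    for seq in seqs:
        seq = seq.upper()
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if not set(kmer) - _STANDARD:
                windows.append(kmer)
    if not windows:
        raise ValueError(f"no sequence of length >= {k} with standard residues")
    rng = np.random.default_rng(seed)
    if len(windows) <= n:
        if len(windows) < n:
            warnings.warn(
                f"only {len(windows)} eligible windows (< {n}); returning all",
                stacklevel=2,
            )
        chosen = windows
    else:
        idx = rng.choice(len(windows), size=n, replace=False)
        chosen = [windows[i] for i in idx]
    return [PeptideRecord(sequence=s) for s in chosen]
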