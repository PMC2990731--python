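"""Amino-acid physicochemical property tables and principal-component z-scales.

Peptide QSAR encodes each residue by its scores on the leading principal
components of a panel of physicochemical property scales.  These scores are
the "z-scales": z1 tracks polarity/hydrophobicity, z2 molecular size and z3
electronic character.  This module loads raw property tables, derives
z-scales by PCA of the property correlation matrix, and ships the canonical
three-component table used by the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The 20 standard amino acids in canonical (alphabetical one-letter) order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Canonical z-scales: first three principal components of a 31-scale
# physicochemical property panel.  z1 = polarity/hydrophobicity,
# z2 = size, z3 = electronic character.
_CANONICAL_Z = {
    "A": (0.72, 2.48, 1.42),
    "C": (2.11, 2.74, -3.84),
    "D": (-6.04, 0.03, -0.18),
    "E": (-5.70, 0.34, -1.46),
    "F": (7.18, -1.53, 0.05),
    "G": (-0.76, 3.08, 1.21),
    "H": (-2.55, -1.00, -1.94),
    "I": (6.65, 0.29, 0.04),
    "K": (-6.68, -1.32, 1.16),
    "L": (6.59, -0.20, 1.17),
    "M": (4.14, -0.43, -1.46),
    "N": (-4.35, 0.21, 0.30),
    "P": (-0.03, -0.36, 1.87),
    "Q": (-3.97, -0.47, 0.15),
    "R": (-6.30, -2.93, -0.91),
    "S": (-2.65, 1.84, 1.30),
    "T": (-1.42, 0.80, 0.94),
    "V": (4.79, 1.98, -0.35),
    "W": (5.68, -3.50, 0.16),
    "Y": (2.58, -2.06, 0.37),
}

#: Approximate cumulative variance of the property panel captured by the
#: three canonical components (the individual proportions were not retained).
CANONICAL_CUMULATIVE_VARIANCE = 0.90


@dataclass(frozen=True)
class PropertyMatrix:
    """Raw physicochemical measurements: 20 amino acids x P property scales."""

    amino_acids: tuple[str, ...]
    property_names: tuple[str, ...]
    values: np.ndarray  # 20 x P, heterogeneous units

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if tuple(self.amino_acids) != tuple(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - set(self.amino_acids))
            extra = sorted(set(self.amino_acids) - set(AMINO_ACIDS))
            raise ValueError(
                f"amino acids must be exactly {AMINO_ACIDS!r} in order; "
                f"missing={missing} unexpected={extra}"
            )
        if len(self.property_names) < 3:
            raise ValueError("at least 3 property columns are required")
        if vals.shape != (20, len(self.property_names)):
            raise ValueError(
                f"values must be 20x{len(self.property_names)}, got {vals.shape}"
            )
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite cell at amino acid {self.amino_acids[bad[0]]!r}, "
                f"property {self.property_names[bad[1]]!r}"
            )

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.amino_acids), columns=list(self.property_names)
        )


@dataclass(frozen=True)
class ZScaleTable:
    """Per-amino-acid principal-component scores (z-scales).

    ``z[i, j]`` is the score of amino acid ``amino_acids[i]`` on component
    ``j+1``.  ``variance_explained`` holds eigenvalue proportions (NaN for the
    canonical table, where only the cumulative ~0.90 is known).
    """

    amino_acids: tuple[str, ...]
    z: np.ndarray  # 20 x n_components
    variance_explained: np.ndarray
    provenance: str = "derived"  # "canonical_table1" or "derived"

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        ve = np.asarray(self.variance_explained, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "variance_explained", ve)
        if tuple(self.amino_acids) != tuple(AMINO_ACIDS):
            raise ValueError("z-scale table must cover the 20 standard amino acids in order")
        if z.ndim != 2 or z.shape[0] != 20:
            raise ValueError(f"z must be 20 x n_components, got {z.shape}")
        if ve.shape != (z.shape[1],):
            raise ValueError("variance_explained length must equal n_components")
        finite = ve[np.isfinite(ve)]
        if finite.size and (np.any(np.diff(finite) > 1e-12) or finite.sum() > 1 + 1e-9):
            raise ValueError("variance_explained must be non-increasing and sum to <= 1")

    @property
    def n_components(self) -> int:
        return self.z.shape[1]

    def triple(self, aa: str) -> np.ndarray:
        """Scores of one amino acid, e.g. ``triple('K') -> (-6.68, -1.32, 1.16)``."""
        try:
            return self.z[_AA_INDEX[aa]]
        except KeyError:
            raise KeyError(f"not a standard amino acid: {aa!r}") from None

    __getitem__ = triple

    def to_frame(self) -> pd.DataFrame:
        cols = [f"z{j + 1}" for j in range(self.n_components)]
        return pd.DataFrame(self.z, index=list(self.amino_acids), columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        """Write ``aa<TAB>z1<TAB>z2<TAB>z3`` at 6 decimals (lossless round-trip)."""
        df = self.to_frame()
        df.index.name = "aa"
        df.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ZScaleTable":
        df = pd.read_csv(path, sep="\t", index_col="aa").loc[list(AMINO_ACIDS)]
        k = df.shape[1]
        return cls(
            amino_acids=tuple(AMINO_ACIDS),
            z=df.to_numpy(dtype=float),
            variance_explained=np.full(k, np.nan),
            provenance="derived",
        )


def load_property_table(path: str | Path) -> PropertyMatrix:
    """Load a property TSV (header of property names, first column = one-letter code).

    Rows are reordered to canonical ACDEFGHIKLMNPQRSTVWY order regardless of
    file order.  Missing/duplicate amino acids, non-numeric cells and tables
    with fewer than 3 properties are rejected with the offending row or column
    named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    codes = [str(c).strip().upper() for c in df.index]
    dupes = sorted({c for c in codes if codes.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicate amino-acid rows: {dupes}")
    missing = sorted(set(AMINO_ACIDS) - set(codes))
    if missing:
        raise ValueError(f"missing amino acids: {missing}")
    unknown = sorted(set(codes) - set(AMINO_ACIDS))
    if unknown:
        raise ValueError(f"unknown amino-acid rows: {unknown}")
    if df.shape[1] < 3:
        raise ValueError(f"need at least 3 property columns, found {df.shape[1]}")
    df.index = codes
    df = df.loc[list(AMINO_ACIDS)]
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"non-numeric cell in property {col!r} at amino acid {bad!r}"
            ) from None
    return PropertyMatrix(
        amino_acids=tuple(AMINO_ACIDS),
        property_names=tuple(str(c) for c in df.columns),
        values=df.to_numpy(dtype=float),
    )


# Score-sign anchors fixing the arbitrary PCA orientation: z1(F) > 0,
# z2(G) > 0, z3(P) > 0, matching the canonical table (hydrophobic F positive
# on the polarity axis, tiny G positive on the size axis).
_SIGN_ANCHORS = {0: "F", 1: "G", 2: "P"}


def compute_zscales(props: PropertyMatrix, n_components: int = 3) -> ZScaleTable:
    """Derive z-scales by PCA of the property correlation matrix.

    Each property column is standardized to mean 0 / variance 1 over the 20
    amino acids; the correlation matrix is eigendecomposed; scores are the
    projections of the standardized data onto unit eigenvectors (so they carry
    eigenvalue weighting -- components are numerically weighted by their
    contribution and need no further scaling downstream).
    """
    if not 1 <= n_components <= min(20, props.n_properties):
        raise ValueError(
            f"n_components must be in [1, {min(20, props.n_properties)}], got {n_components}"
        )
    X = props.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd < 1e-12)
    if zero.size:
        raise ValueError(
            f"constant property column (zero variance): {props.property_names[zero[0]]!r}"
        )
    Z = (X - mean) / sd
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    # descending eigenvalues; stable sort keeps a deterministic order on ties
    order = np.argsort(-eigvals, kind="stable")
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    scores = Z @ eigvecs[:, :n_components]
    for j in range(n_components):
        anchor = _SIGN_ANCHORS.get(j)
        if anchor is not None:
            ref = scores[_AA_INDEX[anchor], j]
        else:  # beyond the canonical three: largest-|loading| entry positive
            ref = eigvecs[np.argmax(np.abs(eigvecs[:, j])), j]
        if ref < 0:
            scores[:, j] = -scores[:, j]
            eigvecs[:, j] = -eigvecs[:, j]
    return ZScaleTable(
        amino_acids=tuple(AMINO_ACIDS),
        z=scores,
        variance_explained=eigvals[:n_components] / eigvals.sum(),
        provenance="derived",
    )


def canonical_zscales() -> ZScaleTable:
    """The canonical three-component z-scale table (provenance ``canonical_table1``).

    Individual variance proportions were not retained for this table; the
    three components jointly capture about 90% of the property-panel variance
    (:data:`CANONICAL_CUMULATIVE_VARIANCE`).
    """
    z = np.array([_CANONICAL_Z[aa] for aa in AMINO_ACIDS], dtype=float)
    return ZScaleTable(
        amino_acids=tuple(AMINO_ACIDS),
        z=z,
        variance_explained=np.full(3, np.nan),
        provenance="canonical_table1",
    )
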