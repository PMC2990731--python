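"""Per-allele PLS regression (NIPALS) and the Variable Importance in Projection.

The linear predictor of ln(ic50) is fitted by partial least squares on the
z-scale descriptor matrix.  With a single response, each NIPALS dimension has
weight vector w_a proportional to X'y of the deflated data (the alternating
update converges after one pass), scores t_a = X w_a, and the response is
deflated by its regression on t_a.  SSY_a records the residual sum of squares
of the (centered) response after a dimensions, so SSY_{a-1} - SSY_a is the
response sum of squares explained by dimension a.

The importance of descriptor k in a fitted A-dimension model is

    VIP_k = sqrt( K * sum_a [ w_ak^2 (SSY_{a-1} - SSY_a) ] / (SSY_0 - SSY_A) )

which is normalized so that sum_k VIP_k^2 = K (average VIP = 1); descriptors
with VIP > 1 are the ones most relevant to the binding response.

Descriptor columns are centered but deliberately not unit-scaled: z-scales
already carry the eigenvalue weighting of the underlying property PCA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import default_labels

_RANK_TOL = 1e-10
#: Training sets smaller than this are fitted but flagged.
SMALL_SAMPLE_N = 30


@dataclass
class PLSModel:
    """A fitted NIPALS PLS regression of ln(ic50) on z-scale descriptors."""

    n_factors: int
    weights: np.ndarray  # K x A, unit-norm columns
    x_loadings: np.ndarray  # K x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray  # n x A
    coefficients: np.ndarray  # K (regression form)
    x_center: np.ndarray  # K
    y_center: float
    ssy: np.ndarray  # A+1: SSY_0 .. SSY_A
    position_labels: tuple[str, ...] = ()
    x_min: np.ndarray | None = None  # observed training ranges (for surfaces)
    x_max: np.ndarray | None = None
    small_sample: bool = False

    @property
    def n_terms(self) -> int:
        return self.coefficients.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_pls(self, X)

    def to_dict(self) -> dict:
        d = {
            "format": "zbind-model",
            "version": 1,
            "kind": "pls",
            "n_factors": self.n_factors,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "coefficients": self.coefficients.tolist(),
            "x_center": self.x_center.tolist(),
            "y_center": float(self.y_center),
            "ssy": self.ssy.tolist(),
            "position_labels": list(self.position_labels),
            "x_min": None if self.x_min is None else self.x_min.tolist(),
            "x_max": None if self.x_max is None else self.x_max.tolist(),
            "small_sample": self.small_sample,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        if d.get("kind") != "pls":
            raise ValueError(f"not a PLS model file (kind={d.get('kind')!r})")
        arr = lambda k: np.asarray(d[k], dtype=float)
        return cls(
            n_factors=int(d["n_factors"]),
            weights=arr("weights"),
            x_loadings=arr("x_loadings"),
            y_loadings=arr("y_loadings"),
            scores=arr("scores"),
            coefficients=arr("coefficients"),
            x_center=arr("x_center"),
            y_center=float(d["y_center"]),
            ssy=arr("ssy"),
            position_labels=tuple(d.get("position_labels", ())),
            x_min=None if d.get("x_min") is None else arr("x_min"),
            x_max=None if d.get("x_max") is None else arr("x_max"),
            small_sample=bool(d.get("small_sample", False)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class VIPMatrix:
    """Position x principal-component VIP grid for one allele.

    ``vip_flat`` follows descriptor order; ``values`` is its L x 3 reshape
    (rows = groove positions, columns = PC1..PC3) when K is a multiple of 3.
    """

    allele: str
    vip_flat: np.ndarray  # K
    values: np.ndarray | None  # L x 3 or None for non-peptide geometries
    position_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        flat = np.asarray(self.vip_flat, dtype=float)
        object.__setattr__(self, "vip_flat", flat)
        if np.any(flat < 0):
            raise ValueError("VIP values must be non-negative")
        if self.values is not None:
            object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_factors: int, allow_fewer: bool = False):
    """Run NIPALS deflation on centered data; returns (W, P, q, T, ssy)."""
    n, K = Xc.shape
    Xd = Xc.copy()
    yd = yc.copy()
    W, P, T, q = [], [], [], []
    ssy = [float(yd @ yd)]
    for _ in range(n_factors):
        # single-response NIPALS: the w/t alternation converges in one pass
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < _RANK_TOL * max(1.0, np.linalg.norm(Xd)):
            if allow_fewer:
                break
            raise ValueError(
                f"cannot extract {n_factors} factors: data rank exhausted after {len(W)}"
            )
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < _RANK_TOL:
            if allow_fewer:
                break
            raise ValueError(
                f"cannot extract {n_factors} factors: degenerate score at {len(W) + 1}"
            )
        p = Xd.T @ t / tt
        qa = float(t @ yd) / tt
        Xd -= np.outer(t, p)
        yd = yd - qa * t
        W.append(w)
        P.append(p)
        T.append(t)
        q.append(qa)
        ssy.append(float(yd @ yd))
    W = np.column_stack(W) if W else np.zeros((K, 0))
    P = np.column_stack(P) if P else np.zeros((K, 0))
    T = np.column_stack(T) if T else np.zeros((n, 0))
    return W, P, np.asarray(q), T, np.asarray(ssy)


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """Regression coefficients of the first ``a`` dimensions: W_a (P_a'W_a)^-1 q_a."""
    if a == 0:
        return np.zeros(W.shape[0])
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    position_labels: Sequence[str] | None = None,
) -> PLSModel:
    """Fit a PLS regression with ``n_factors`` NIPALS dimensions.

    X columns are centered (not scaled); y is centered.  Raises if y has no
    variance, if ``n_factors`` is not in [1, rank(X)] or ``n >= n_factors``
    fails.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} are incompatible")
    n, K = X.shape
    if not 1 <= n_factors < n:
        raise ValueError(f"need n > n_factors >= 1, got n={n}, n_factors={n_factors}")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in X or y")
    if np.var(y) < 1e-15:
        raise ValueError("response has zero variance")
    if n_factors > np.linalg.matrix_rank(X - X.mean(axis=0)):
        raise ValueError(f"n_factors={n_factors} exceeds rank of centered X")
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    W, P, q, T, ssy = _nipals(X - x_center, y - y_center, n_factors)
    labels = tuple(position_labels) if position_labels is not None else (
        tuple(default_labels(K // 3)) if K % 3 == 0 else ()
    )
    if n < SMALL_SAMPLE_N:
        warnings.warn(
            f"only {n} training peptides (< {SMALL_SAMPLE_N}); model flagged",
            stacklevel=2,
        )
    return PLSModel(
        n_factors=n_factors,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coefficients=_coefficients(W, P, q, n_factors),
        x_center=x_center,
        y_center=y_center,
        ssy=ssy,
        position_labels=labels,
        x_min=X.min(axis=0),
        x_max=X.max(axis=0),
        small_sample=n < SMALL_SAMPLE_N,
    )


def predict_pls(m: PLSModel, X: np.ndarray) -> np.ndarray:
    """Deterministic linear prediction: y_center + (X - x_center) . coefficients."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.n_terms:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {m.n_terms}")
    return m.y_center + (X - m.x_center) @ m.coefficients


def press_by_factors(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    n_folds: int = 7,
    seed: int | None = None,
) -> np.ndarray:
    """Cross-validated PRESS for A = 1..max_factors (contiguous-block folds).

    When a seed is given, rows are permuted once before the contiguous blocks
    are cut (equivalent to a random equal partition); seed=None keeps the
    original row order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    n_folds = min(n_folds, n)
    idx = np.arange(n)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(n)
    blocks = np.array_split(idx, n_folds)
    press = np.zeros(max_factors)
    achieved = max_factors
    for val in blocks:
        train = np.setdiff1d(idx, val, assume_unique=False)
        Xtr, ytr = X[train], y[train]
        xc = Xtr.mean(axis=0)
        yc = float(ytr.mean())
        W, P, q, _, _ = _nipals(Xtr - xc, ytr - yc, max_factors, allow_fewer=True)
        achieved = min(achieved, W.shape[1])
        for a in range(1, max_factors + 1):
            b = _coefficients(W, P, q, min(a, W.shape[1]))
            pred = yc + (X[val] - xc) @ b
            press[a - 1] += float(np.sum((y[val] - pred) ** 2))
    return press[:achieved]


def select_factors(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    n_folds: int = 7,
    seed: int | None = None,
) -> int:
    """Choose the number of latent factors by cross-validated PRESS.

    Parsimony rule: the smallest A whose PRESS is within 2% of the global
    minimum over 1..max_factors.  Pure-noise responses therefore floor at 1.
    """
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    press = press_by_factors(X, y, max_factors, n_folds=n_folds, seed=seed)
    best = float(press.min())
    within = np.flatnonzero(press <= 1.02 * best)
    return int(within[0]) + 1


def compute_vip(m: PLSModel, allele: str = "") -> VIPMatrix:
    """Variable Importance in Projection of a fitted model.

    Normalized so sum_k VIP_k^2 = K.  Rejects models that explain no response
    variance (SSY_0 = SSY_A), where the ratio is undefined.
    """
    explained = -np.diff(m.ssy)  # per-dimension explained SS, length A
    total = float(m.ssy[0] - m.ssy[-1])
    if total <= 1e-12 * m.ssy[0]:
        raise ValueError("model explains no response variance; VIP undefined")
    K = m.n_terms
    vip = np.sqrt(K * (m.weights**2 @ explained) / total)
    values = vip.reshape(-1, 3) if K % 3 == 0 else None
    return VIPMatrix(
        allele=allele,
        vip_flat=vip,
        values=values,
        position_labels=m.position_labels,
    )


def vip_table(vips: Sequence[VIPMatrix]) -> "pd.DataFrame":
    """Assemble VIP matrices into a table: rows = alleles, columns = position x PC."""
    import pandas as pd

    rows = {}
    cols = None
    for v in vips:
        labels = v.position_labels or tuple(
            f"P{i + 1}" for i in range(v.vip_flat.size // 3)
        )
        these = [f"{pos}:PC{j + 1}" for pos in labels for j in range(3)]
        if cols is None:
            cols = these
        elif these != cols:
            raise ValueError("VIP matrices have mismatched geometries")
        rows[v.allele] = v.vip_flat
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
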