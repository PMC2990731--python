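"""Three-layer perceptron regression of ln(ic50) with two cross-validation schemes.

The network mirrors the geometry of the binding reaction: one input per
z-scale descriptor, a hidden layer with as many logistic nodes as residues in
the binding domain (9 for MHC-I 9-mers, 15 for MHC-II 15-mers) and a single
linear output, the natural log of the ic50.  Overfitting is controlled by an
L2 penalty on all weights; the penalty is tuned so the training r^2 lands
near 0.9, the share of property-panel variance the three z-scales capture.

Two schemes turn single fits into a prediction model:

* Method 1 -- several "tours" (random seeds) of a random-holdback split;
  the tour with the best holdback r^2 is kept.
* Method 2 -- an ensemble of networks, each trained on an independent random
  2/3 subset of the training peptides (nine subsets by default, so each
  peptide is used six times in expectation).  Per-peptide predictions carry
  the ensemble mean, SEM and coefficient of variation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

HIDDEN_CLASS_I = 9
HIDDEN_CLASS_II = 15


def default_hidden_nodes(peptide_length: int) -> int:
    """Hidden-layer width mirroring the binding domain: 9 for MHC-I 9-mers,
    15 for MHC-II 15-mers."""
    if peptide_length == 9:
        return HIDDEN_CLASS_I
    if peptide_length == 15:
        return HIDDEN_CLASS_II
    raise ValueError(f"no default architecture for peptide length {peptide_length}")

_MAX_ITER = 2000
_GTOL = 1e-8
_INIT_SCALE = 0.1


@dataclass
class PerceptronModel:
    """A trained perceptron: K inputs -> H logistic hidden nodes -> linear output.

    Inputs are standardized internally (and the response de-standardized on
    output); this is invisible at the interface.
    """

    n_inputs: int
    n_hidden: int
    input_weights: np.ndarray  # H x (K+1), last column = bias
    output_weights: np.ndarray  # H+1, last entry = bias
    penalty: float
    seed: int
    train_r2: float
    converged: bool = True
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None
    position_labels: tuple[str, ...] = ()
    holdback_r2: float | None = None
    tour: int | None = None

    @property
    def x_center(self) -> np.ndarray:
        """Training-mean input row (for response-surface rendering)."""
        return self.x_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"X has {X.shape[1]} columns, model expects {self.n_inputs}")
        Xs = (X - self.x_mean) / self.x_scale
        hidden = expit(Xs @ self.input_weights[:, :-1].T + self.input_weights[:, -1])
        ys = hidden @ self.output_weights[:-1] + self.output_weights[-1]
        return self.y_mean + self.y_scale * ys

    def to_dict(self) -> dict:
        return {
            "format": "zbind-model",
            "version": 1,
            "kind": "perceptron",
            "n_inputs": self.n_inputs,
            "n_hidden": self.n_hidden,
            "input_weights": self.input_weights.tolist(),
            "output_weights": self.output_weights.tolist(),
            "penalty": self.penalty,
            "seed": self.seed,
            "train_r2": self.train_r2,
            "converged": self.converged,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "x_min": None if self.x_min is None else self.x_min.tolist(),
            "x_max": None if self.x_max is None else self.x_max.tolist(),
            "position_labels": list(self.position_labels),
            "holdback_r2": self.holdback_r2,
            "tour": self.tour,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerceptronModel":
        if d.get("kind") != "perceptron":
            raise ValueError(f"not a perceptron model file (kind={d.get('kind')!r})")
        arr = lambda k: None if d.get(k) is None else np.asarray(d[k], dtype=float)
        return cls(
            n_inputs=int(d["n_inputs"]),
            n_hidden=int(d["n_hidden"]),
            input_weights=arr("input_weights"),
            output_weights=arr("output_weights"),
            penalty=float(d["penalty"]),
            seed=int(d["seed"]),
            train_r2=float(d["train_r2"]),
            converged=bool(d["converged"]),
            x_mean=arr("x_mean"),
            x_scale=arr("x_scale"),
            y_mean=float(d["y_mean"]),
            y_scale=float(d["y_scale"]),
            x_min=arr("x_min"),
            x_max=arr("x_max"),
            position_labels=tuple(d.get("position_labels", ())),
            holdback_r2=d.get("holdback_r2"),
            tour=d.get("tour"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PerceptronModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class EnsembleModel:
    """Method-2 ensemble: one perceptron per random training subset."""

    members: list[PerceptronModel]
    subset_fraction: float
    n_subsets: int
    membership: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")

    @property
    def position_labels(self) -> tuple[str, ...]:
        return self.members[0].position_labels

    @property
    def x_center(self) -> np.ndarray:
        return self.members[0].x_mean

    @property
    def x_min(self) -> np.ndarray:
        return self.members[0].x_min

    @property
    def x_max(self) -> np.ndarray:
        return self.members[0].x_max

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble-mean prediction (full per-row statistics: predict_ensemble)."""
        return np.mean([m.predict(X) for m in self.members], axis=0)

    def to_dict(self) -> dict:
        return {
            "format": "zbind-model",
            "version": 1,
            "kind": "ensemble",
            "subset_fraction": self.subset_fraction,
            "n_subsets": self.n_subsets,
            "membership": [m.tolist() for m in self.membership],
            "members": [m.to_dict() for m in self.members],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        if d.get("kind") != "ensemble":
            raise ValueError(f"not an ensemble model file (kind={d.get('kind')!r})")
        return cls(
            members=[PerceptronModel.from_dict(m) for m in d["members"]],
            subset_fraction=float(d["subset_fraction"]),
            n_subsets=int(d["n_subsets"]),
            membership=[np.asarray(m, dtype=int) for m in d["membership"]],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class EnsemblePrediction:
    """Per-peptide ensemble summary: mean ln(ic50), SEM and CV% over members."""

    mean_ln_ic50: float
    sem: float
    cv_pct: float  # NaN when |mean| ~ 0 (undefined)


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < 1e-15:
        return float("nan")
    return 1.0 - float(np.sum((y - pred) ** 2)) / sst


def _loss_grad(theta, Xs, ys, H, K, lam):
    W = theta[: H * (K + 1)].reshape(H, K + 1)
    v = theta[H * (K + 1) :]
    hidden = expit(Xs @ W[:, :-1].T + W[:, -1])
    pred = hidden @ v[:-1] + v[-1]
    r = pred - ys
    loss = float(r @ r) + lam * float(theta @ theta)
    # backprop
    g_out = np.empty(H + 1)
    g_out[:-1] = 2.0 * (hidden.T @ r)
    g_out[-1] = 2.0 * r.sum()
    d_hidden = np.outer(2.0 * r, v[:-1]) * hidden * (1.0 - hidden)
    gW = np.empty_like(W)
    gW[:, :-1] = d_hidden.T @ Xs
    gW[:, -1] = d_hidden.sum(axis=0)
    grad = np.concatenate([gW.ravel(), g_out]) + 2.0 * lam * theta
    return loss, grad


def train_perceptron(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    penalty: float = 0.0,
    seed: int = 0,
    max_iter: int = _MAX_ITER,
    position_labels: Sequence[str] | None = None,
) -> PerceptronModel:
    """Train one perceptron by penalized least squares.

    Minimizes sum (y - yhat)^2 + penalty * sum(all weights^2) with full-batch
    L-BFGS from small seed-determined uniform initial weights; deterministic
    given (X, y, n_hidden, penalty, seed).  If the iteration cap is hit the
    best iterate is returned with ``converged=False`` and a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in X or y")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    n, K = X.shape
    H = int(n_hidden)
    if n < 10 * H:
        warnings.warn(
            f"n={n} below the recommended 10 x n_hidden = {10 * H}", stacklevel=2
        )
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale < 1e-12] = 1.0
    y_mean = float(y.mean())
    y_scale = float(y.std()) or 1.0
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale

    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-_INIT_SCALE, _INIT_SCALE, size=H * (K + 1) + H + 1)
    res = minimize(
        _loss_grad,
        theta0,
        args=(Xs, ys, H, K, float(penalty)),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": _GTOL, "maxfun": 10 * max_iter},
    )
    theta = res.x
    model = PerceptronModel(
        n_inputs=K,
        n_hidden=H,
        input_weights=theta[: H * (K + 1)].reshape(H, K + 1),
        output_weights=theta[H * (K + 1) :],
        penalty=float(penalty),
        seed=int(seed),
        train_r2=0.0,
        converged=bool(res.success),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        x_min=X.min(axis=0),
        x_max=X.max(axis=0),
        position_labels=tuple(position_labels or ()),
    )
    model.train_r2 = _r2(y, model.predict(X))
    if not res.success:
        warnings.warn(
            f"perceptron optimizer stopped before convergence: {res.message}",
            stacklevel=2,
        )
    return model


def tune_penalty(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    target_r2: float = 0.9,
    seed: int = 0,
    tol: float = 0.02,
    max_bisect: int = 30,
) -> float:
    """Find the L2 penalty whose training r^2 lands within ``tol`` of the target.

    Log-space bisection, exploiting the (empirically monotone) decrease of
    training r^2 in the penalty.  If even the unpenalized fit cannot reach the
    target, a warning is emitted and 0.0 is returned.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    base = train_perceptron(X, y, n_hidden, penalty=0.0, seed=seed)
    if base.train_r2 < target_r2:
        warnings.warn(
            f"target r^2={target_r2} unattainable (max achievable "
            f"{base.train_r2:.3f}); returning penalty 0",
            stacklevel=2,
        )
        return 0.0
    lo, hi = -8.0, 6.0  # log10(lambda) bracket
    best_lam, best_gap = 0.0, abs(base.train_r2 - target_r2)
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        lam = 10.0**mid
        r2 = train_perceptron(X, y, n_hidden, penalty=lam, seed=seed).train_r2
        gap = abs(r2 - target_r2)
        if gap < best_gap:
            best_lam, best_gap = lam, gap
        if gap <= tol:
            return lam
        if r2 > target_r2:
            lo = mid
        else:
            hi = mid
    return best_lam


def train_method1(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    n_tours: int = 5,
    holdback_fraction: float = 1.0 / 3.0,
    seed: int = 0,
    penalty: float | None = None,
    target_r2: float = 0.9,
) -> PerceptronModel:
    """Method 1: multi-tour random holdback; keep the best-generalizing tour.

    Each tour holds back a random ``holdback_fraction`` of rows, tunes the
    overfitting penalty on its training portion (unless ``penalty`` is given)
    and trains from a tour-specific seed.  The tour with the highest holdback
    r^2 wins; ties go to the earlier tour.
    """
    if n_tours < 2:
        raise ValueError("n_tours must be >= 2")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    n_hold = max(1, int(round(holdback_fraction * n)))
    rng = np.random.default_rng(seed)
    best: PerceptronModel | None = None
    for tour in range(1, n_tours + 1):
        child = int(rng.integers(2**31))
        perm = np.random.default_rng(child).permutation(n)
        hold, train = perm[:n_hold], perm[n_hold:]
        lam = (
            penalty
            if penalty is not None
            else tune_penalty(X[train], y[train], n_hidden, target_r2, seed=child)
        )
        model = train_perceptron(X[train], y[train], n_hidden, penalty=lam, seed=child)
        model.holdback_r2 = _r2(y[hold], model.predict(X[hold]))
        model.tour = tour
        if best is None or model.holdback_r2 > best.holdback_r2:
            best = model
    return best


def draw_subsets(
    n: int, n_subsets: int, subset_fraction: float, seed: int
) -> list[np.ndarray]:
    """Independent uniform subsets of floor(subset_fraction * n) rows, no replacement.

    This is the Method-2 resampling plan: at the defaults (nine subsets of
    2/3) every peptide is included 9 * 2/3 = 6 times in expectation.
    """
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    if not 0 < subset_fraction < 1:
        raise ValueError("subset_fraction must be in (0, 1)")
    size = int(math.floor(subset_fraction * n))
    if size < 1:
        raise ValueError("subset_fraction too small for n")
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(n, size=size, replace=False)) for _ in range(n_subsets)]


def train_method2(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    n_subsets: int = 9,
    subset_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    penalty: float | None = None,
    target_r2: float = 0.9,
) -> EnsembleModel:
    """Method 2: ensemble of perceptrons over independent random subsets.

    The penalty is tuned once on the full training set (unless given) and
    shared by all members; each member trains on its own subset from its own
    derived seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    membership = draw_subsets(n, n_subsets, subset_fraction, seed)
    if len(membership[0]) < 10 * n_hidden:
        warnings.warn(
            f"subset size {len(membership[0])} below 10 x n_hidden = {10 * n_hidden}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lam = (
        penalty
        if penalty is not None
        else tune_penalty(X, y, n_hidden, target_r2, seed=int(rng.integers(2**31)))
    )
    members = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-member small-n warnings already issued
        for idx in membership:
            child = int(rng.integers(2**31))
            members.append(
                train_perceptron(X[idx], y[idx], n_hidden, penalty=lam, seed=child)
            )
    return EnsembleModel(
        members=members,
        subset_fraction=subset_fraction,
        n_subsets=n_subsets,
        membership=membership,
    )


def predict_ensemble(e: EnsembleModel, X: np.ndarray) -> list[EnsemblePrediction]:
    """Per-row ensemble statistics: mean, SEM (sd/sqrt(m)) and CV% (100*sd/|mean|)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    preds = np.vstack([m.predict(X) for m in e.members])  # m x n
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0, ddof=1)
    m = preds.shape[0]
    out = []
    for mu, s in zip(mean, sd):
        cv = float("nan") if abs(mu) < 1e-9 else 100.0 * s / abs(mu)
        out.append(EnsemblePrediction(float(mu), float(s / math.sqrt(m)), float(cv)))
    return out


def mean_cv_pct(predictions: Sequence[EnsemblePrediction]) -> float:
    """Allele-level summary: mean of per-peptide CV% (finite entries only)."""
    vals = np.array([p.cv_pct for p in predictions], dtype=float)
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")
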