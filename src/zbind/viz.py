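"""Heat-plot visualization of VIP matrices, affinity histograms and surfaces.

A VIP heat plot shows, for a panel of alleles, the importance of each groove
position x principal-component descriptor in predicting ln(ic50).  Cells
with VIP > 1 are the descriptors that matter.  Three coloring schemes expose
different comparisons: uniform scaling across the whole matrix, per-position
(column-relative) scaling, and per-allele scaling.  Rendering never alters
the numbers -- every plot writes a sidecar TSV holding the exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dataio import BindingDataset
from .pls_vip import VIPMatrix, vip_table

_SCALINGS = ("global_uniform", "column_relative", "within_allele")
#: A bin holding more than this fraction of all observations is a censor spike.
SPIKE_FRACTION = 0.20


@dataclass
class HeatPlotSpec:
    """What to draw: one VIP matrix per allele plus a coloring scheme."""

    matrices: list[VIPMatrix]
    scaling: str = "global_uniform"
    component: str = "all"  # "PC1" | "PC2" | "PC3" | "all"
    threshold_marker: float = 1.0

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("at least one VIP matrix is required")
        if self.scaling not in _SCALINGS:
            raise ValueError(f"scaling must be one of {_SCALINGS}")
        geoms = {m.values.shape for m in self.matrices if m.values is not None}
        if len(geoms) != 1:
            raise ValueError("all VIP matrices must share the same geometry")
        if self.component not in ("all", "PC1", "PC2", "PC3"):
            raise ValueError("component must be PC1, PC2, PC3 or 'all'")


def _sidecar_path(out_path: str | Path) -> Path:
    p = Path(out_path)
    return p.with_suffix(".tsv")


def _color_data(panel: np.ndarray, scaling: str) -> tuple[np.ndarray, float, float]:
    """Transform a (alleles x positions) panel for coloring; returns legend range."""
    if scaling == "global_uniform":
        return panel, float(panel.min()), float(panel.max())
    if scaling == "column_relative":
        lo, hi = panel.min(axis=0), panel.max(axis=0)
    else:  # within_allele
        lo, hi = panel.min(axis=1, keepdims=True), panel.max(axis=1, keepdims=True)
        lo, hi = lo, hi
    rng = hi - lo
    scaled = np.where(rng > 0, (panel - lo) / np.where(rng > 0, rng, 1.0), 0.5)
    return scaled, 0.0, 1.0


def render_vip_heatmap(spec: HeatPlotSpec, out_path: str | Path) -> tuple[Path, Path]:
    """Render the heat plot and write the untouched numeric sidecar TSV.

    Rows are alleles, columns groove positions, one panel per principal
    component.  Cells above ``threshold_marker`` (VIP > 1 by default) are
    marked with a dot.  Returns (image path, sidecar path).
    """
    out_path = Path(out_path)
    comps = [0, 1, 2] if spec.component == "all" else [int(spec.component[2]) - 1]
    alleles = [m.allele for m in spec.matrices]
    labels = spec.matrices[0].position_labels or tuple(
        f"P{i + 1}" for i in range(spec.matrices[0].values.shape[0])
    )
    # panels[c]: alleles x positions for component c
    panels = {
        c: np.vstack([m.values[:, c] for m in spec.matrices]) for c in comps
    }
    if spec.scaling == "global_uniform":
        # one shared legend across every cell of every requested panel
        allvals = np.concatenate([p.ravel() for p in panels.values()])
        vmin, vmax = float(allvals.min()), float(allvals.max())
        if vmax - vmin < 1e-12:
            vmax = vmin + 1e-12  # degenerate range: uniform color, no crash
    fig, axes = plt.subplots(
        1, len(comps), figsize=(1 + 0.65 * len(labels) * len(comps), 1 + 0.45 * len(alleles)),
        squeeze=False,
    )
    for ax, c in zip(axes[0], comps):
        panel = panels[c]
        if spec.scaling == "global_uniform":
            img, lo, hi = panel, vmin, vmax
        else:
            img, lo, hi = _color_data(panel, spec.scaling)
        im = ax.imshow(img, cmap="viridis", vmin=lo, vmax=hi, aspect="auto")
        ys, xs = np.nonzero(panel > spec.threshold_marker)
        ax.scatter(xs, ys, s=12, c="white", edgecolors="black", linewidths=0.4)
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(alleles)), alleles if c == comps[0] else [], fontsize=7)
        ax.set_title(f"PC{c + 1}", fontsize=9)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.suptitle(f"VIP ({spec.scaling}); dots mark VIP > {spec.threshold_marker:g}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    sidecar = _sidecar_path(out_path)
    vip_table(spec.matrices).to_csv(sidecar, sep="\t")
    return out_path, sidecar


def render_affinity_histogram(
    ds: BindingDataset, bins: int = 30, out_path: str | Path = "affinity_hist.png"
) -> list[tuple[float, float]]:
    """Histogram of ln(ic50) with a normal-fit overlay and spike highlighting.

    Bins containing more than 20% of all observations (assay-limit censoring
    spikes) are drawn dark.  Returns the highlighted bin intervals.
    """
    if len(ds) < 10:
        raise ValueError(f"need at least 10 records, got {len(ds)}")
    vals = np.array([r.ln_ic50 for r in ds.records], dtype=float)
    counts, edges = np.histogram(vals, bins=bins)
    spikes = [
        (float(edges[i]), float(edges[i + 1]))
        for i in np.flatnonzero(counts > SPIKE_FRACTION * vals.size)
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    widths = np.diff(edges)
    dark = counts > SPIKE_FRACTION * vals.size
    ax.bar(
        edges[:-1], counts, width=widths, align="edge",
        color=np.where(dark, "#30303a", "#9fb8d0"), edgecolor="white",
    )
    mu, sd = float(vals.mean()), float(vals.std(ddof=1))
    if sd > 0:
        xs = np.linspace(edges[0], edges[-1], 200)
        pdf = np.exp(-0.5 * ((xs - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        ax.plot(xs, pdf * vals.size * widths.mean(), color="crimson", lw=1.5)
    ax.set_xlabel("ln(ic50)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return spikes


def render_response_surface(
    model,
    position_a: str,
    component_a: str,
    position_b: str,
    component_b: str,
    grid: int = 25,
    out_path: str | Path = "surface.png",
) -> pd.DataFrame:
    """Predicted ln(ic50) over a grid of two descriptors, others at training means.

    ``model`` must expose ``predict``, ``position_labels``, ``x_center`` and
    the training ranges ``x_min``/``x_max`` (PLS and perceptron models do).
    Returns the grid as a DataFrame (index = axis-a values, columns = axis-b
    values) and writes it next to the rendered contour plot.
    """
    labels = list(model.position_labels)
    if not labels:
        raise ValueError("model carries no position labels")

    def col(pos: str, comp: str) -> int:
        if pos not in labels:
            raise ValueError(f"position {pos!r} not in model geometry {labels}")
        pc = int(str(comp).upper().removeprefix("PC"))
        if pc not in (1, 2, 3):
            raise ValueError(f"component must be PC1..PC3, got {comp!r}")
        return 3 * labels.index(pos) + (pc - 1)

    ia, ib = col(position_a, component_a), col(position_b, component_b)
    if ia == ib:
        raise ValueError("the two surface axes must be distinct descriptors")
    avals = np.linspace(model.x_min[ia], model.x_max[ia], grid)
    bvals = np.linspace(model.x_min[ib], model.x_max[ib], grid)
    X = np.tile(np.asarray(model.x_center, dtype=float), (grid * grid, 1))
    A, B = np.meshgrid(avals, bvals, indexing="ij")
    X[:, ia] = A.ravel()
    X[:, ib] = B.ravel()
    Z = np.asarray(model.predict(X)).reshape(grid, grid)
    df = pd.DataFrame(Z, index=avals, columns=bvals)
    out_path = Path(out_path)
    df.to_csv(_sidecar_path(out_path), sep="\t")
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    cs = ax.contourf(B, A, Z, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=ax, label="predicted ln(ic50)")
    ax.set_xlabel(f"{position_b} {component_b} (z-scale)")
    ax.set_ylabel(f"{position_a} {component_a} (z-scale)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return df
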