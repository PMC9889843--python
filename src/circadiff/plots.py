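"""Visualization: fitted-curve scatter, phase-ordered heatmap, phase radar,
and the phase-difference circos plot.

Every plot is split into a pure geometry function (point coordinates, row
orders, bin counts) and a thin matplotlib renderer, so the quantitative
content is testable without parsing images.  Renderers write PNG/PDF/SVG
depending on the output file extension.
"""

from __future__ import annotations

import logging
import math

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cosinor import fit_cosinor
from .dataset import RhythmDataset

logger = logging.getLogger(__name__)

__all__ = [
    "gene_scatter_geometry",
    "plot_gene_scatter",
    "phase_order_table",
    "plot_phase_heatmap",
    "phase_histogram",
    "plot_phase_radar",
    "circos_coords",
    "plot_phase_circos",
]

GROUP_COLORS = {"I": "#1f6fb4", "II": "#d95f02"}


# ---------------------------------------------------------------- scatter

def gene_scatter_geometry(
    dataset: RhythmDataset, gene: str, fits: dict | None = None, n_curve: int = 240
) -> dict:
    """Points, fitted curves and annotations for one gene's scatter plot.

    Returns ``{group: {"t", "y", "curve_t", "curve_y", "annotation"}}``;
    times are folded mod the period and the curve is sampled at ``n_curve``
    (>= 200) points across one period.
    """
    n_curve = max(n_curve, 200)
    P = dataset.period
    out = {}
    for group in ("I", "II"):
        y, t = dataset.gene_data(gene, group)
        fit = (fits or {}).get(group)
        if fit is None:
            fit = fit_cosinor(y, t, P)
        grid = np.linspace(0.0, P, n_curve)
        out[group] = {
            "t": np.mod(t, P),
            "y": y,
            "curve_t": grid,
            "curve_y": fit.predict(grid),
            "fit": fit,
            "annotation": (
                f"A={fit.amplitude:.2f}, φ={fit.phase:.2f} h, "
                f"M={fit.mesor:.2f}, R²={fit.r2:.2f}"
            ),
        }
    return out


def plot_gene_scatter(
    dataset: RhythmDataset, gene: str, out, fits: dict | None = None
) -> dict:
    """Scatter of one gene's expression over ZT with fitted cosinor curves.

    One panel per group with the points, the fitted curve and an annotation
    of (A, phi, M, R^2).  Returns the geometry dict.
    """
    geom = gene_scatter_geometry(dataset, gene, fits)
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), sharey=True)
    for ax, (group, g) in zip(axes, geom.items()):
        ax.scatter(g["t"], g["y"], s=18, color=GROUP_COLORS[group], zorder=3)
        ax.plot(g["curve_t"], g["curve_y"], color=GROUP_COLORS[group], lw=1.5)
        ax.set_title(f"{gene} — group {group}\n{g['annotation']}", fontsize=8)
        ax.set_xlabel("ZT (h)")
    axes[0].set_ylabel("expression")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return geom


# ---------------------------------------------------------------- heatmap

def phase_order_table(fits: pd.DataFrame, group: str, top_k: int) -> pd.DataFrame:
    """Top rhythmic genes in one group, ordered by fitted phase.

    Genes are ranked by rhythmicity p ascending (ties broken by R^2
    descending), the top ``top_k`` kept (clamped with a warning when fewer
    are available), then sorted by phase ascending.  This is the row order
    of the heatmap, exposed for testing.
    """
    sub = fits[fits["group"] == group].copy()
    if sub.empty:
        raise ValueError(f"no fits available for group {group!r}")
    if top_k > len(sub):
        logger.warning(
            "top_k=%d exceeds the %d available genes; clamping", top_k, len(sub)
        )
        top_k = len(sub)
    sub = sub.sort_values(["p_rhythm", "r2"], ascending=[True, False],
                          kind="mergesort").head(top_k)
    sub = sub.sort_values("phase", kind="mergesort")
    return sub[["gene", "phase", "p_rhythm", "r2"]].reset_index(drop=True)


def plot_phase_heatmap(
    dataset: RhythmDataset, fits: pd.DataFrame, group: str, top_k: int, out
) -> pd.DataFrame:
    """Phase-ordered heatmap of the top rhythmic genes in one group.

    Rows are the phase-ordered top genes (see :func:`phase_order_table`),
    columns the group's samples ordered by ZT, values z-scored per gene.
    Returns the row-order table.
    """
    order = phase_order_table(fits, group, top_k)
    mask = dataset.group_mask(group)
    t = dataset.time[mask]
    col_order = np.argsort(np.mod(t, dataset.period), kind="stable")
    idx = [dataset.gene_index(g) for g in order["gene"]]
    mat = dataset.values[np.ix_(idx, np.where(mask)[0])][:, col_order]
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd

    fig, ax = plt.subplots(figsize=(6, max(2.5, 0.04 * len(order))))
    im = ax.imshow(z, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_xlabel("samples (by ZT)")
    ax.set_ylabel(f"top {len(order)} rhythmic genes (phase-ordered)")
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return order


# ---------------------------------------------------------------- radar

def phase_histogram(
    phases: np.ndarray, period: float = 24.0, bins: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Circular histogram counts of phases folded into ``[0, P)``.

    Returns ``(counts, edges)`` with ``bins`` equal-width bins; counts sum
    to the number of phases.
    """
    if bins < 4:
        raise ValueError(f"at least 4 bins required, got {bins}")
    phases = np.mod(np.asarray(phases, dtype=float), period)
    edges = np.linspace(0.0, period, bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    return counts, edges


def plot_phase_radar(
    phases_by_group: dict, out, period: float = 24.0, bins: int = 12
) -> dict:
    """Radar (circular histogram) of acrophase distributions per group.

    ``phases_by_group`` maps group label -> array of fitted phases
    (typically the RhyBoth genes).  Returns ``{group: counts}``; counts per
    group sum to that group's gene count.
    """
    counts = {}
    fig = plt.figure(figsize=(4.5, 4.5))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    width = 2 * math.pi / bins
    for group, phases in phases_by_group.items():
        c, edges = phase_histogram(phases, period, bins)
        counts[group] = c
        theta = edges[:-1] * 2 * math.pi / period + width / 2
        ax.bar(theta, c, width=width, alpha=0.45,
               color=GROUP_COLORS.get(group), label=f"group {group}")
    ax.set_xticks(np.linspace(0, 2 * math.pi, 8, endpoint=False))
    ax.set_xticklabels([f"ZT{int(h)}" for h in np.arange(0, period, period / 8)])
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return counts


# ---------------------------------------------------------------- circos

#: radial band of the circos plot: delta_phi = 0 sits on the mid circle
CIRCOS_R_MID = 1.0
CIRCOS_R_HALFBAND = 0.5


def circos_coords(
    phi_ref: np.ndarray, delta_phi: np.ndarray, period: float = 24.0
) -> pd.DataFrame:
    """Polar coordinates of the phase-difference circos plot.

    Angle is the reference-group phase scaled to ``[0, 2 pi)``; radius maps
    the wrapped difference ``delta_phi in (-P/2, P/2]`` linearly onto a
    symmetric band around the zero-reference circle at radius 1 (antipodal
    ``+P/2`` touches the outer edge, never the inner).
    """
    phi_ref = np.mod(np.asarray(phi_ref, dtype=float), period)
    delta_phi = np.asarray(delta_phi, dtype=float)
    if phi_ref.size == 0:
        raise ValueError("no genes to plot")
    if np.any(delta_phi > period / 2) or np.any(delta_phi <= -period / 2):
        raise ValueError("delta_phi must be wrapped to (-P/2, P/2]")
    theta = phi_ref * 2 * math.pi / period
    radius = CIRCOS_R_MID + CIRCOS_R_HALFBAND * delta_phi / (period / 2)
    return pd.DataFrame({"theta": theta, "radius": radius,
                         "phi_ref": phi_ref, "delta_phi": delta_phi})


def plot_phase_circos(params: pd.DataFrame, reference_phases, out,
                      period: float = 24.0) -> pd.DataFrame:
    """Circos-style polar scatter of per-gene phase differences.

    ``params`` must carry ``delta_phi`` (one row per RhyBoth gene) and
    ``reference_phases`` the matching reference-group phases.  A dashed
    circle marks ``delta_phi = 0``.  Returns the coordinate table.
    """
    if len(params) == 0:
        raise ValueError("no genes with a computed phase difference")
    coords = circos_coords(np.asarray(reference_phases),
                           params["delta_phi"].to_numpy(), period)
    fig = plt.figure(figsize=(4.5, 4.5))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.scatter(coords["theta"], coords["radius"], s=12, alpha=0.7,
               color="#444444")
    circle = np.linspace(0, 2 * math.pi, 200)
    ax.plot(circle, np.full_like(circle, CIRCOS_R_MID), ls="--", lw=1,
            color="#888888", label="Δφ = 0")
    ax.set_ylim(CIRCOS_R_MID - CIRCOS_R_HALFBAND - 0.05,
                CIRCOS_R_MID + CIRCOS_R_HALFBAND + 0.05)
    ax.set_yticks([])
    ax.set_xticks(np.linspace(0, 2 * math.pi, 8, endpoint=False))
    ax.set_xticklabels([f"ZT{int(h)}" for h in np.arange(0, period, period / 8)])
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return coords
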