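"""Latent-space and biomarker-score plots.

The latent-space plot places each sample at its two hidden-neuron
activations inside (−1, 1)² and draws gray contours of the maximum
subtype probability computed by pushing a grid of latent points through
the model's output layer — so distance from the center visually encodes
call confidence. Glyphs are colored by a clinical annotation channel
(RECIST BOR by default) or by called subtype.

The score-distribution plot shows each sample's signed biomarker score
(2·P(B+) − 1) with the decision boundary at 0 and a light-gray density
silhouette; a well-separated classifier yields a bimodal cloud with a
thinned-out waist at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

# deterministic SVG output (element ids are otherwise salted per process)
plt.rcParams["svg.hashsalt"] = "stromatype"
import numpy as np
import pandas as pd

from .io import CohortClinical, SUBTYPES
from .model import TrainedModel, SubtypeCalls, output_layer_probabilities
from .biomarker import BiomarkerCalls

SUBTYPE_COLORS = {"A": "#c0392b", "IA": "#2e6da4", "ID": "#27ae60", "IS": "#8e44ad"}
BOR_COLORS = {"CR": "#1a9641", "PR": "#a6d96a", "SD": "#fdae61", "PD": "#d7191c",
              "NE": "#999999"}


@dataclass
class PlotSpec:
    """Output location and styling for a plot."""

    out_path: str | Path
    annotation: str = "bor"  # bor | subtype | msi | pdl1_cps
    grid_resolution: int = 200
    contour_levels: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)
    figsize: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self):
        if self.grid_resolution < 20:
            raise ValueError("grid_resolution must be ≥ 20")


def max_probability_grid(
    model: TrainedModel, resolution: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Max subtype probability over a latent grid covering (−1, 1)²."""
    ax = np.linspace(-1.0, 1.0, resolution)
    g1, g2 = np.meshgrid(ax, ax)
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    pmax = output_layer_probabilities(model, pts).max(axis=1).reshape(g1.shape)
    return g1, g2, pmax


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    meta = {"Date": None} if path.suffix.lower() == ".svg" else None
    fig.savefig(path, dpi=150, metadata=meta)
    plt.close(fig)
    return path


def latent_space_plot(
    model: TrainedModel,
    calls: SubtypeCalls,
    clinical: CohortClinical | None,
    spec: PlotSpec,
) -> Path:
    """Samples in the hidden-neuron plane over a probability-gradient
    background; deterministic for identical inputs."""
    fig, ax = plt.subplots(figsize=spec.figsize)
    g1, g2, pmax = max_probability_grid(model, spec.grid_resolution)
    levels = [lv for lv in sorted(spec.contour_levels) if pmax.min() < lv < pmax.max()]
    if levels:
        cs = ax.contour(g1, g2, pmax, levels=levels, colors="gray", linewidths=0.8)
        ax.clabel(cs, fmt="%.1f", fontsize=7)

    if spec.annotation == "subtype":
        colors = calls.subtype.map(SUBTYPE_COLORS)
        legend_items = SUBTYPE_COLORS
    else:
        if clinical is None or spec.annotation not in clinical.table.columns:
            raise ValueError(
                f"annotation channel {spec.annotation!r} absent from clinical table"
            )
        channel = clinical.table[spec.annotation].reindex(calls.table.index)
        if spec.annotation == "bor":
            colors = channel.map(BOR_COLORS).fillna("#999999")
            legend_items = BOR_COLORS
        else:
            cats = pd.unique(channel.astype(str))
            cmap = plt.get_cmap("tab10")
            palette = {c: cmap(i % 10) for i, c in enumerate(sorted(cats))}
            colors = channel.astype(str).map(palette)
            legend_items = palette
    ax.scatter(
        calls.table["neuron1"],
        calls.table["neuron2"],
        c=list(colors),
        s=30,
        edgecolor="black",
        linewidth=0.4,
        zorder=3,
    )
    for name, color in legend_items.items():
        ax.scatter([], [], c=[color], s=30, edgecolor="black", linewidth=0.4,
                   label=str(name))
    ax.legend(loc="upper left", fontsize=7, frameon=False)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.axhline(0, color="lightgray", lw=0.5)
    ax.axvline(0, color="lightgray", lw=0.5)
    ax.set_xlabel("hidden neuron 1")
    ax.set_ylabel("hidden neuron 2")
    ax.set_title("TME latent space")
    return _save(fig, spec.out_path)


def score_distribution_plot(biomarker: BiomarkerCalls, spec: PlotSpec) -> Path:
    """Signed biomarker scores with the B+/B− boundary at 0."""
    if len(biomarker) == 0:
        raise ValueError("no biomarker calls to plot")
    scores = biomarker.score.to_numpy()
    fig, ax = plt.subplots(figsize=spec.figsize)

    # density silhouette (20-bin histogram mirrored about x = 0)
    hist, edges = np.histogram(scores, bins=20, range=(-1, 1), density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    width = hist / max(hist.max(), 1e-9) * 0.35
    ax.fill_betweenx(centers, -width, width, color="0.85", zorder=1)

    rng = np.random.default_rng(0)  # fixed jitter seed: deterministic render
    x = rng.uniform(-0.3, 0.3, size=scores.size)
    colors = np.where(biomarker.positive_mask.to_numpy(), "#2e6da4", "#c0392b")
    ax.scatter(x, scores, c=colors, s=25, edgecolor="black", linewidth=0.3, zorder=3)
    ax.axhline(0.0, color="black", lw=1.0, ls="--")
    ax.set_ylim(-1.05, 1.05)
    ax.set_xticks([])
    ax.set_ylabel(f"biomarker score ({biomarker.rule.name}); y ≥ 0 ⇒ B+")
    ax.set_title("Biomarker score distribution")
    return _save(fig, spec.out_path)
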