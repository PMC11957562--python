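"""Circular and linear strand-profile figures.

The circular style renders the plus and minus tracks as opposing rings
on a polar axis with an annotation band and call markers; the linear
style mirrors the minus strand below the axis. Rendering is
deterministic for fixed inputs.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .genome import Annotation
from .screen import PeakCall
from .tracks import StrandedTrack

_LABEL_COLORS = {
    "occupancy_like": "tab:green",
    "artifact_like": "tab:red",
    "ambiguous": "tab:orange",
    "masked": "tab:gray",
}


def _norm(v: np.ndarray) -> np.ndarray:
    m = v.max()
    return v / m if m > 0 else v


def plot_strand_profiles(tracks: list[StrandedTrack], path: str,
                         calls: list[PeakCall] | None = None,
                         masks: list[Annotation] | None = None,
                         style: str = "circular",
                         predicted: StrandedTrack | None = None) -> str:
    if not tracks:
        raise ValueError("no tracks to plot")
    if style == "circular":
        fig = _plot_circular(tracks, calls or [], masks or [], predicted)
    elif style == "linear":
        fig = _plot_linear(tracks, calls or [], masks or [], predicted)
    else:
        raise ValueError(f"unknown style {style!r}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _plot_circular(tracks, calls, masks, predicted):
    n = tracks[0].length
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(figsize=(7, 7), subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    base = 1.0
    for i, track in enumerate(tracks):
        r_out = base + 0.35 * _norm(track.plus)
        r_in = base - 0.35 * _norm(track.minus)
        ax.plot(theta, r_out, color="black", lw=0.6,
                label="plus strand" if i == 0 else None)
        ax.plot(theta, r_in, color="goldenrod", lw=0.6,
                label="minus strand" if i == 0 else None)
        base += 0.9
    if predicted is not None:
        r_pred = base + 0.35 * _norm(predicted.total)
        ax.plot(theta, r_pred, color="tab:blue", lw=0.6, label="predicted")
        base += 0.9
    for m in masks:
        pos = m.positions(n)
        ax.plot(theta[pos], np.full(len(pos), 0.45), color="tab:gray", lw=4,
                solid_capstyle="butt")
    for call in calls:
        t = theta[call.region.site_estimate]
        ax.plot([t], [base], marker="v",
                color=_LABEL_COLORS.get(call.label, "black"), ms=6)
    ax.set_yticks([])
    ax.set_xticks(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    ax.set_xticklabels([f"{int(x)}" for x in np.linspace(0, n, 8, endpoint=False)],
                       fontsize=7)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=7)
    return fig


def _plot_linear(tracks, calls, masks, predicted):
    n = tracks[0].length
    x = np.arange(n)
    fig, ax = plt.subplots(figsize=(10, 3.2))
    for track in tracks:
        ax.fill_between(x, track.plus, 0, color="black", lw=0, alpha=0.8)
        ax.fill_between(x, -track.minus, 0, color="goldenrod", lw=0, alpha=0.8)
    if predicted is not None:
        scale = (max(t.total.max() for t in tracks) /
                 max(predicted.total.max(), 1e-12))
        ax.plot(x, predicted.total * scale, color="tab:blue", lw=0.8,
                label="predicted (scaled)")
    for m in masks:
        for s, e in m.segments(n):
            ax.axvspan(s, e, color="tab:gray", alpha=0.25, lw=0)
    for call in calls:
        ax.axvline(call.region.site_estimate, lw=0.8,
                   color=_LABEL_COLORS.get(call.label, "black"), ls="--")
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlim(0, n)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("coverage (+ up, − down)")
    handles = [plt.Line2D([], [], color=c, ls="--", label=l)
               for l, c in _LABEL_COLORS.items()]
    ax.legend(handles=handles, fontsize=7, ncol=4)
    fig.tight_layout()
    return fig


def plot_cluster_heatmap(profiles: np.ndarray, order: list[int],
                         labels: list[str], path: str) -> str:
    """Row-ordered heatmap of normalized per-dataset profiles."""
    profiles = np.asarray(profiles, dtype=float)
    norm = profiles / np.maximum(profiles.sum(axis=1, keepdims=True), 1e-12)
    fig, ax = plt.subplots(figsize=(8, 0.3 * len(order) + 1.5))
    ax.imshow(norm[order], aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([labels[i] for i in order], fontsize=7)
    ax.set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
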