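"""Figure helpers (headless Agg backend)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_mfa_track(track, path, calls=(), origin_annotation=None,
                   title=None) -> None:
    """Marker-frequency figure: per-window log2 ratios (points) with the
    smoothed average (line), optional origin calls and an annotated locus."""
    fig, ax = plt.subplots(figsize=(9, 3))
    x = track.midpoints / 1e3
    ax.plot(x, track.log2_ratio, ".", ms=1.5, color="#c44e52", alpha=0.5,
            label="per-window log2 ratio")
    if track.smoothed is not None:
        order = np.argsort(x)
        ax.plot(x[order], np.asarray(track.smoothed)[order], "-", lw=1.0,
                color="black", label="smoothed")
    for call in calls:
        ax.axvline(call.peak / 1e3, color="#4c72b0", lw=1, ls="--")
    if origin_annotation is not None:
        pos, text = origin_annotation
        ax.axvline(pos / 1e3, color="#55a868", lw=1)
        ax.annotate(text, (pos / 1e3, ax.get_ylim()[1]), fontsize=8,
                    ha="center", va="bottom")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("genome position (kb)")
    ax.set_ylabel("log2(exp/stat)")
    if title:
        ax.set_title(title, fontsize=10)
    ax.legend(frameon=False, fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cumulative_skew(skew_result, path) -> None:
    fig, ax = plt.subplots(figsize=(9, 3))
    x = skew_result.starts / 1e3
    ax.plot(x, skew_result.cumulative, lw=1, color="#4c72b0")
    ax.axvline(skew_result.origin_candidate / 1e3, color="#55a868", lw=1,
               label="cumulative-skew minimum (candidate origin)")
    ax.axvline(skew_result.terminus_candidate / 1e3, color="#c44e52", lw=1,
               label="maximum (candidate terminus)")
    ax.set_xlabel("genome position (kb)")
    ax.set_ylabel("cumulative (G-C)/(G+C)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
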