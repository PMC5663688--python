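"""GC-dependent coverage bias: estimation and removal.

Windows are binned by GC fraction (default bin width 0.01), the mean coverage
of each bin is smoothed with a Lowess regression against the bin centre, and
each window's coverage is multiplied by ``global_mean / fitted(GC)``.  The
correction is estimated and applied per sample, before any between-sample
ratio is formed.

Windows whose GC falls in a bin with no data use a fitted value linearly
interpolated between the neighbouring non-empty bins (flagged on the track,
with a logged warning); beyond the observed GC range the fit is clamped at
the boundary value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .coverage import CoverageTrack


class BiasModelError(ValueError):
    pass


@dataclass
class GCBiasModel:
    bin_width: float
    bin_centers: np.ndarray      # non-empty bins only
    bin_mean_coverage: np.ndarray
    fitted_values: np.ndarray    # Lowess fit evaluated at bin_centers
    lowess_fraction: float
    global_mean: float

    def fitted(self, gc: np.ndarray) -> np.ndarray:
        """Fitted mean coverage at arbitrary GC, clamped to the observed range."""
        return np.interp(np.asarray(gc, dtype=float),
                         self.bin_centers, self.fitted_values)

    def in_empty_bin(self, gc: np.ndarray) -> np.ndarray:
        """True where a window's own GC bin carried no data (nearest bin used)."""
        idx = np.floor(np.asarray(gc) / self.bin_width).astype(int)
        observed = set(np.floor(self.bin_centers / self.bin_width).astype(int))
        return np.array([i not in observed for i in idx])

    def to_json(self, path) -> None:
        payload = {
            "bin_width": self.bin_width,
            "lowess_fraction": self.lowess_fraction,
            "global_mean": self.global_mean,
            "bin_centers": self.bin_centers.tolist(),
            "bin_mean_coverage": self.bin_mean_coverage.tolist(),
            "fitted_values": self.fitted_values.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def from_json(path) -> "GCBiasModel":
        with open(path) as fh:
            d = json.load(fh)
        return GCBiasModel(
            bin_width=d["bin_width"],
            bin_centers=np.asarray(d["bin_centers"]),
            bin_mean_coverage=np.asarray(d["bin_mean_coverage"]),
            fitted_values=np.asarray(d["fitted_values"]),
            lowess_fraction=d["lowess_fraction"],
            global_mean=d["global_mean"],
        )


def fit_gc_bias(track: CoverageTrack, bin_width: float = 0.01,
                lowess_fraction: float = 0.3) -> GCBiasModel:
    """Fit the GC-bias model on one sample's coverage track.

    Requires >= 20 windows and >= 3 non-empty GC bins; with fewer bins the
    bias curve is not identifiable.
    """
    if track.gc is None or track.coverage is None:
        raise BiasModelError("track needs gc and coverage before bias fitting")
    if track.n_windows < 20:
        raise BiasModelError(f"need >= 20 windows, track has {track.n_windows}")
    gc = np.asarray(track.gc, dtype=float)
    cov = np.asarray(track.coverage, dtype=float)
    idx = np.floor(gc / bin_width).astype(int)
    uniq, inverse = np.unique(idx, return_inverse=True)
    if len(uniq) < 3:
        raise BiasModelError(
            f"only {len(uniq)} non-empty GC bin(s); bias is not identifiable"
        )
    sums = np.bincount(inverse, weights=cov)
    counts = np.bincount(inverse)
    centers = (uniq + 0.5) * bin_width
    means = sums / counts
    fit = lowess(means, centers, frac=lowess_fraction, return_sorted=True)
    fitted = np.interp(centers, fit[:, 0], fit[:, 1])
    return GCBiasModel(
        bin_width=bin_width,
        bin_centers=centers,
        bin_mean_coverage=means,
        fitted_values=fitted,
        lowess_fraction=lowess_fraction,
        global_mean=float(cov.mean()),
    )


def correct_coverage(track: CoverageTrack, model: GCBiasModel) -> CoverageTrack:
    """Set ``track.corrected = coverage * global_mean / fitted(gc)``."""
    if track.gc is None or track.coverage is None:
        raise BiasModelError("track needs gc and coverage before correction")
    fitted = model.fitted(track.gc)
    if np.any(fitted <= 0):
        bad_gc = np.asarray(track.gc)[fitted <= 0]
        raise BiasModelError(
            f"fitted mean coverage <= 0 for GC class(es) near {bad_gc[:3]}; "
            "cannot form a correction factor"
        )
    track.corrected = np.asarray(track.coverage, dtype=float) * (model.global_mean / fitted)
    track.nearest_bin_flag = model.in_empty_bin(track.gc)
    n_flagged = int(track.nearest_bin_flag.sum())
    if n_flagged:
        logging.getLogger("mfakit").warning(
            "%d window(s) fall in GC bins with no data; fitted value "
            "interpolated/clamped from neighbouring bins", n_flagged)
    return track


def plot_gc_fit(model: GCBiasModel, path) -> None:
    """Diagnostic scatter of bin means with the Lowess curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(model.bin_centers, model.bin_mean_coverage, "o", ms=3,
            label="bin mean coverage")
    ax.plot(model.bin_centers, model.fitted_values, "-", lw=1.5,
            label="Lowess fit")
    ax.axhline(model.global_mean, color="grey", ls=":", lw=1,
               label="global mean")
    ax.set_xlabel("window GC fraction")
    ax.set_ylabel("coverage (bases/window)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
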