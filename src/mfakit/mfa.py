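"""Marker-frequency analysis: log2 exponential/stationary ratio tracks,
smoothing, origin peak calling, and detection-power studies.

The MFA statistic is the per-window log2 ratio of GC-corrected coverage in an
exponentially growing culture over a stationary-phase control, after scaling
both samples to a common library size.  Origin-proximal regions of an
origin-replicating chromosome are over-represented in the growing sample, so
the track shows a peak at each active origin and a trough at the terminus; a
chromosome replicating from many dispersed (recombination-initiated) sites
gives a flat track.

Order of operations: per-sample GC correction -> library-size scaling ->
pseudocounted ratio -> log2 -> median re-centring -> circular sliding-mean
smoothing -> threshold/width peak calling.  The log2 is computed as
``log2(num) - log2(den)`` so that exchanging the two samples negates every
unmasked value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, WindowScheme, window_coverage, window_gc
from .gcbias import correct_coverage, fit_gc_bias
from .genome import circular_distance
from .synthetic import (GCBiasSpec, SimulationConfig, copy_number_profile,
                        generate_genome, simulate_fragments)

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_STAT_FRACTION = 0.1
DEFAULT_THRESHOLD_LOG2 = 0.15
DEFAULT_MIN_WIDTH_WINDOWS = 5
DEFAULT_SMOOTH_SPAN = 3
RECOVERY_SMOOTH_SPAN = 21  # wider span for origin localisation (see methods)


class TrackMismatchError(ValueError):
    pass


@dataclass
class MarkerFrequencyTrack:
    genome_id: str
    genome_length: int
    scheme: WindowScheme
    starts: np.ndarray
    log2_raw: np.ndarray        # before median re-centring; NaN where masked
    log2_ratio: np.ndarray      # re-centred so the unmasked median is 0
    mask: np.ndarray            # True where masked
    mask_reason: np.ndarray     # '' | 'low_stationary_coverage'
    median_shift: float
    scale_exp: float            # library-size factors applied to each sample
    scale_stat: float
    smoothed: Optional[np.ndarray] = None
    smoothing_span: Optional[int] = None

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.scheme.window_size // 2) % self.genome_length

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.genome_id,
            "start": self.starts,
            "end": self.starts + self.scheme.window_size,
            "log2_raw": self.log2_raw,
            "log2_ratio": self.log2_ratio,
            "mask": self.mask.astype(int),
            "mask_reason": self.mask_reason,
        })
        if self.smoothed is not None:
            df["smoothed"] = self.smoothed
        return df

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"#mfakit_mfa\tgenome_id={self.genome_id}\t"
                f"genome_length={self.genome_length}\t"
                f"window={self.scheme.window_size}\tstep={self.scheme.step}\t"
                f"circular={int(self.scheme.circular)}\t"
                f"median_shift={float(self.median_shift)!r}\t"
                f"scale_exp={float(self.scale_exp)!r}\t"
                f"scale_stat={float(self.scale_stat)!r}\t"
                f"span={self.smoothing_span or 0}\n"
            )
            self.to_dataframe().to_csv(fh, sep="\t", index=False,
                                       float_format="%.10g")

    @staticmethod
    def from_tsv(path) -> "MarkerFrequencyTrack":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#mfakit_mfa"):
                raise ValueError(f"{path} is not an mfakit MFA TSV")
            meta = dict(kv.split("=", 1) for kv in header.split("\t")[1:])
            df = pd.read_csv(fh, sep="\t")
        scheme = WindowScheme(int(meta["window"]), int(meta["step"]),
                              bool(int(meta["circular"])))
        span = int(meta["span"])
        return MarkerFrequencyTrack(
            genome_id=meta["genome_id"],
            genome_length=int(meta["genome_length"]),
            scheme=scheme,
            starts=df["start"].to_numpy(np.int64),
            log2_raw=df["log2_raw"].to_numpy(float),
            log2_ratio=df["log2_ratio"].to_numpy(float),
            mask=df["mask"].to_numpy(bool),
            mask_reason=df["mask_reason"].fillna("").to_numpy(object),
            median_shift=float(meta["median_shift"]),
            scale_exp=float(meta["scale_exp"]),
            scale_stat=float(meta["scale_stat"]),
            smoothed=df["smoothed"].to_numpy(float) if "smoothed" in df else None,
            smoothing_span=span if span > 0 else None,
        )

    def to_bedgraph(self, path, value: str = "smoothed") -> None:
        arr = getattr(self, value)
        if arr is None:
            raise ValueError(f"track has no {value!r} values")
        L = self.genome_length
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="mfa_{value}"\n')
            for s, v in zip(self.starts, arr):
                if np.isnan(v):
                    continue
                fh.write(f"{self.genome_id}\t{s}\t{min(s + self.scheme.window_size, L)}\t{v:.6g}\n")


def mfa_ratio(exp_track: CoverageTrack, stat_track: CoverageTrack,
              pseudocount: float = DEFAULT_PSEUDOCOUNT,
              min_stat_fraction: float = DEFAULT_MIN_STAT_FRACTION,
              ) -> MarkerFrequencyTrack:
    """Form the per-window log2(exponential/stationary) track.

    Both tracks must share the window scheme and genome and carry GC-corrected
    coverage.  Corrected coverages are scaled to the mean of the two library
    totals, a pseudocount (in bases) stabilises empty windows, and windows
    whose scaled stationary coverage falls below ``min_stat_fraction`` of the
    stationary mean are masked rather than allowed to explode.
    """
    if exp_track.scheme != stat_track.scheme \
            or exp_track.genome_length != stat_track.genome_length \
            or exp_track.n_windows != stat_track.n_windows:
        raise TrackMismatchError(
            "exponential and stationary tracks disagree on scheme or genome"
        )
    for t, name in ((exp_track, "exponential"), (stat_track, "stationary")):
        if t.corrected is None:
            raise TrackMismatchError(f"{name} track lacks corrected coverage")
    e = np.asarray(exp_track.corrected, dtype=float)
    s = np.asarray(stat_track.corrected, dtype=float)
    te, ts = e.sum(), s.sum()
    if te <= 0 or ts <= 0:
        raise TrackMismatchError("a track has zero total corrected coverage")
    target = 0.5 * (te + ts)
    fe, fs = target / te, target / ts
    e = e * fe
    s = s * fs
    mask = s < min_stat_fraction * s.mean()
    reasons = np.where(mask, "low_stationary_coverage", "")
    # log2(num) - log2(den): exact antisymmetry under sample exchange
    raw = np.log2(e + pseudocount) - np.log2(s + pseudocount)
    raw[mask] = np.nan
    med = float(np.nanmedian(raw)) if (~mask).any() else 0.0
    return MarkerFrequencyTrack(
        genome_id=exp_track.genome_id,
        genome_length=exp_track.genome_length,
        scheme=exp_track.scheme,
        starts=exp_track.starts,
        log2_raw=raw,
        log2_ratio=raw - med,
        mask=mask,
        mask_reason=reasons,
        median_shift=med,
        scale_exp=fe,
        scale_stat=fs,
    )


def smooth_track(track: MarkerFrequencyTrack,
                 span_windows: int = DEFAULT_SMOOTH_SPAN) -> MarkerFrequencyTrack:
    """Centred circular sliding mean over unmasked windows.

    ``span_windows`` must be odd.  A window's smoothed value is masked when
    more than half of its span is masked.
    """
    if span_windows < 1 or span_windows % 2 == 0:
        raise ValueError(f"span must be odd and >= 1, got {span_windows}")
    v = np.asarray(track.log2_ratio, dtype=float)
    n = len(v)
    h = span_windows // 2
    valid = ~np.isnan(v)
    filled = np.where(valid, v, 0.0)
    if track.scheme.circular and h > 0:
        filled_ext = np.concatenate([filled[-h:], filled, filled[:h]])
        valid_ext = np.concatenate([valid[-h:], valid, valid[:h]])
    else:
        filled_ext = np.pad(filled, h)
        valid_ext = np.pad(valid, h)
    kernel = np.ones(span_windows)
    sums = np.convolve(filled_ext, kernel, mode="valid")
    counts = np.convolve(valid_ext.astype(float), kernel, mode="valid")
    need = span_windows - h  # ceil(span/2): masked when > half the span is masked
    smoothed = np.where(counts >= need, sums / np.maximum(counts, 1), np.nan)
    track.smoothed = smoothed[:n]
    track.smoothing_span = span_windows
    return track


# ---------------------------------------------------------------------------
# Origin calls
# ---------------------------------------------------------------------------

@dataclass
class OriginCall:
    """A contiguous run of super-threshold smoothed windows."""

    peak: int               # bp; refined peak position
    peak_window: int        # bp midpoint of the maximal window
    interval_start: int     # bp, start of first window in the run
    interval_end: int       # bp, nominal end of last window (may exceed L: wrap)
    height: float           # max smoothed log2 ratio in the run
    width_bp: int
    n_windows: int


def _circular_runs(above: np.ndarray) -> list:
    """Maximal runs of True in a circular boolean array, as (start, length)."""
    n = len(above)
    if not above.any():
        return []
    if above.all():
        return [(0, n)]
    # rotate so position 0 is False, find linear runs, rotate back
    first_false = int(np.flatnonzero(~above)[0])
    rot = np.roll(above, -first_false)
    d = np.diff(rot.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    ends = np.append(ends, n) if len(ends) < len(starts) else ends
    return [((int(s) + first_false) % n, int(e) - int(s))
            for s, e in zip(starts, ends)]


def _merge_runs(runs: list, n: int, max_gap: int) -> list:
    """Merge circular runs separated by gaps shorter than ``max_gap`` windows."""
    if len(runs) <= 1:
        return runs
    runs = sorted(runs)
    merged = [list(runs[0])]
    for s, ln in runs[1:]:
        ps, pln = merged[-1]
        if s - (ps + pln) < max_gap:
            merged[-1][1] = s + ln - ps
        else:
            merged.append([s, ln])
    # wrap-around gap between last and first
    if len(merged) > 1:
        s0, l0 = merged[0]
        s1, l1 = merged[-1]
        if (s0 + n) - (s1 + l1) < max_gap:
            merged[0] = [s1, (s0 + l0 + n) - s1]
            merged.pop()
    return [tuple(m) for m in merged]


def _centroid_peak(idx: np.ndarray, excess: np.ndarray, n: int, ref: int) -> float:
    """Excess-weighted centroid of window indices, unwrapped around ``ref``."""
    rel = (idx - ref + n // 2) % n - n // 2
    w = np.clip(excess, 0.0, None)
    if w.sum() <= 0:
        return float(ref)
    return float(ref + (rel * w).sum() / w.sum()) % n


def call_origins(track: MarkerFrequencyTrack,
                 threshold_log2: float = DEFAULT_THRESHOLD_LOG2,
                 min_width_windows: int = DEFAULT_MIN_WIDTH_WINDOWS,
                 merge_gap_windows: Optional[int] = None) -> list:
    """Report maximal runs of smoothed windows at or above the threshold.

    Runs separated by sub-threshold gaps shorter than ``merge_gap_windows``
    (default: the smoothing span) are merged before the minimum-width filter,
    so that sampling noise cannot split one broad peak into several calls.
    Calls are sorted by height (ties: leftmost first).  Each call's peak is
    the excess-weighted centroid of its run, a lower-variance locator than
    the single maximal window (also reported as ``peak_window``).
    """
    if track.smoothed is None:
        raise ValueError("smooth_track must run before call_origins")
    if merge_gap_windows is None:
        merge_gap_windows = track.smoothing_span or DEFAULT_SMOOTH_SPAN
    sm = np.asarray(track.smoothed, dtype=float)
    n = len(sm)
    above = np.where(np.isnan(sm), False, sm >= threshold_log2)
    runs = _merge_runs(_circular_runs(above), n, merge_gap_windows)
    S = track.scheme.step
    W = track.scheme.window_size
    L = track.genome_length
    mids = track.midpoints
    calls = []
    for start, length in runs:
        if length < min_width_windows:
            continue
        idx = (start + np.arange(length)) % n
        vals = sm[idx]
        vals = np.where(np.isnan(vals), -np.inf, vals)
        imax = int(np.argmax(vals))
        height = float(vals[imax])
        excess = np.where(np.isfinite(vals), vals - threshold_log2, 0.0)
        cidx = _centroid_peak(idx, excess, n, int(idx[imax]))
        peak = int(round((cidx * S + W // 2))) % L
        calls.append(OriginCall(
            peak=peak,
            peak_window=int(mids[idx[imax]]),
            interval_start=int(track.starts[idx[0]]),
            interval_end=int(track.starts[idx[-1]] + W),
            height=height,
            width_bp=int(length * S),
            n_windows=int(length),
        ))
    calls.sort(key=lambda c: (-c.height, c.peak))
    return calls


@dataclass
class GradientFit:
    """Least-squares fit of a single-origin log2-linear gradient template."""

    origin: int          # bp, sub-window refined
    amplitude: float     # fitted log2 span per replichore (estimate of k)
    correlation: float   # Pearson r between track and best-shifted template


def fit_gradient_origin(track: MarkerFrequencyTrack) -> GradientFit:
    """Matched-filter localisation of a single replication origin.

    Cross-correlates the unmasked log2 track with the symmetric circular
    triangle expected for one origin and two equal replichores, over all
    window shifts (via FFT), and refines the best shift by parabolic
    interpolation.  This is the maximum-likelihood position estimate under
    Gaussian window noise and is considerably more precise than the argmax
    of the smoothed track.
    """
    y = np.asarray(track.log2_ratio, dtype=float).copy()
    n = len(y)
    y[np.isnan(y)] = 0.0
    y = y - y.mean()
    L = track.genome_length
    mids = track.midpoints.astype(float)
    d = np.minimum(mids, L - mids)  # distance of each window to position 0
    t = 1.0 - d / (L / 2.0)
    t = t - t.mean()
    # circular cross-correlation: corr[j] = sum_i y[i] * t[i - j]
    corr = np.real(np.fft.ifft(np.fft.fft(y) * np.conj(np.fft.fft(t))))
    # corr[j] as written correlates t shifted by -j; conjugate order gives +j
    j = int(np.argmax(corr))
    c0, c1, c2 = corr[(j - 1) % n], corr[j], corr[(j + 1) % n]
    denom = c0 - 2 * c1 + c2
    frac = 0.0 if denom == 0 else 0.5 * (c0 - c2) / denom
    frac = float(np.clip(frac, -0.5, 0.5))
    S = track.scheme.step
    W = track.scheme.window_size
    origin = int(round((j + frac) * S + W // 2)) % L
    tt = float((t * t).sum())
    amplitude = float(c1 / tt)
    r = float(c1 / np.sqrt(tt * (y * y).sum())) if y.any() else 0.0
    return GradientFit(origin=origin, amplitude=amplitude, correlation=r)


# ---------------------------------------------------------------------------
# Simulation-based detection power
# ---------------------------------------------------------------------------

def simulate_mfa_replicate(L: int, mode: str, origins: Sequence[int], k: float,
                            depth: float, seed: int,
                            scheme: WindowScheme = WindowScheme(),
                            fragment_length: int = 150,
                            span_windows: int = RECOVERY_SMOOTH_SPAN,
                            gc: float = 0.5) -> MarkerFrequencyTrack:
    """One full simulate -> coverage -> GC-correct -> ratio -> smooth pass."""
    cfg = SimulationConfig(genome_length=L, gc_blocks=((L, gc),), seed=seed)
    genome = generate_genome(cfg)
    n = int(round(depth * L / fragment_length))
    profile = copy_number_profile(L, mode, origins, k)
    flat = copy_number_profile(L, "random")
    seeds = cfg.child_seeds(4)
    bias = GCBiasSpec.identity()
    tracks = {}
    for label, prof, sd in (("exponential", profile, seeds[1]),
                            ("stationary", flat, seeds[2])):
        frags = simulate_fragments(genome, prof, bias, fragment_length, n, int(sd))
        tr = window_coverage(frags, L, scheme, label=label)
        window_gc(genome, tr)
        correct_coverage(tr, fit_gc_bias(tr))
        tracks[label] = tr
    mt = mfa_ratio(tracks["exponential"], tracks["stationary"])
    return smooth_track(mt, span_windows)


def detection_power(n_origins: int, k: float, depth: float, reps: int,
                    threshold: Optional[float] = None, seed: int = 0,
                    L: int = 1_000_000,
                    tolerance_bp: int = 1000,
                    span_windows: int = RECOVERY_SMOOTH_SPAN,
                    refine_single: bool = True) -> dict:
    """Fraction of simulated replicates in which all origins are recovered.

    A replicate counts as a success when at least ``n_origins`` calls are
    made and every true origin lies within ``tolerance_bp`` of some call
    peak.  For ``n_origins == 1`` the single-call peak is refined with the
    gradient matched filter.  With ``threshold=None`` an amplitude-scaled
    threshold ``0.3 * k / (2 * n_origins)`` is used — with ``m`` evenly
    spaced origins the max-of-gradients profile has log2 relief ``k/m``, so
    a fixed threshold calibrated for one origin can never fire for several.
    Falls back to the single-origin default when ``k = 0`` (null case).
    """
    if n_origins < 1 or reps < 1:
        raise ValueError("need n_origins >= 1 and reps >= 1")
    if threshold is None:
        threshold = (0.3 * k / (2 * n_origins)) if k > 0 else DEFAULT_THRESHOLD_LOG2
    rng = np.random.default_rng(seed)
    successes = 0
    n_calls_list = []
    for _ in range(reps):
        offset = int(rng.integers(L))
        if k > 0:
            origins = [(offset + i * L // n_origins) % L for i in range(n_origins)]
            mode = "single_origin" if n_origins == 1 else "multi_origin"
        else:
            origins, mode = [], "random"
        rep_seed = int(rng.integers(2**31))
        track = simulate_mfa_replicate(L, mode, origins, k, depth, rep_seed,
                                        span_windows=span_windows)
        calls = call_origins(track, threshold_log2=threshold)
        n_calls_list.append(len(calls))
        if k == 0:
            successes += len(calls) > 0  # false-positive tally in null mode
            continue
        if len(calls) < n_origins:
            continue
        peaks = [c.peak for c in calls]
        if refine_single and n_origins == 1:
            peaks = [fit_gradient_origin(track).origin]
        if all(any(circular_distance(o, p, L) <= tolerance_bp for p in peaks)
               for o in origins):
            successes += 1
    return {
        "n_origins": n_origins,
        "k": k,
        "depth": depth,
        "reps": reps,
        "threshold": threshold,
        "tolerance_bp": tolerance_bp,
        "sensitivity": successes / reps,
        "mean_calls": float(np.mean(n_calls_list)),
    }
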