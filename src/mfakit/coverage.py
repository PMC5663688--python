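"""Sliding-window base coverage and GC content.

The genome is binned into windows of ``W`` bp advancing by ``S`` bp (defaults
1 kb / 500 bp, i.e. half-overlapping).  On circular genomes the final windows
wrap past the coordinate end so every window has uniform width and the track
has exactly ``ceil(L / S)`` windows.  A window's coverage is the number of
aligned fragment bases overlapping it — chimeric fragments contribute each
block independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .genome import GenomeRecord


class WindowSchemeError(ValueError):
    pass


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window layout.  ``0 < step <= window_size``."""

    window_size: int = 1000
    step: int = 500
    circular: bool = True

    def __post_init__(self):
        if not 0 < self.step <= self.window_size:
            raise WindowSchemeError(
                f"need 0 < step <= window_size, got step={self.step}, "
                f"window={self.window_size}"
            )

    def n_windows(self, L: int) -> int:
        if self.window_size > L:
            raise WindowSchemeError(
                f"window size {self.window_size} exceeds genome length {L}"
            )
        if self.circular:
            return math.ceil(L / self.step)
        return (L - self.window_size) // self.step + 1


def make_windows(L: int, scheme: WindowScheme) -> np.ndarray:
    """Window start coordinates.  Ends are ``start + W`` (wrapping if circular)."""
    n = scheme.n_windows(L)
    return np.arange(n, dtype=np.int64) * scheme.step


@dataclass
class CoverageTrack:
    """Ordered sliding windows with GC fraction and (corrected) coverage."""

    genome_id: str
    genome_length: int
    scheme: WindowScheme
    starts: np.ndarray
    gc: Optional[np.ndarray] = None
    coverage: Optional[np.ndarray] = None
    corrected: Optional[np.ndarray] = None
    total_aligned_bases: int = 0
    label: str = ""
    nearest_bin_flag: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        """Nominal half-open ends; may exceed L for wrapping windows."""
        return self.starts + self.scheme.window_size

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.scheme.window_size // 2) % self.genome_length

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.genome_id,
            "start": self.starts,
            "end": self.ends,
        })
        for col, arr in (("gc", self.gc), ("coverage", self.coverage),
                         ("corrected", self.corrected)):
            if arr is not None:
                df[col] = arr
        return df

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"#mfakit_coverage\tgenome_id={self.genome_id}\t"
                f"genome_length={self.genome_length}\t"
                f"window={self.scheme.window_size}\tstep={self.scheme.step}\t"
                f"circular={int(self.scheme.circular)}\tlabel={self.label}\t"
                f"total_aligned_bases={self.total_aligned_bases}\n"
            )
            self.to_dataframe().to_csv(fh, sep="\t", index=False,
                                       float_format="%.10g")

    @staticmethod
    def from_tsv(path) -> "CoverageTrack":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#mfakit_coverage"):
                raise ValueError(f"{path} is not an mfakit coverage TSV")
            meta = dict(kv.split("=", 1) for kv in header.split("\t")[1:])
            df = pd.read_csv(fh, sep="\t")
        scheme = WindowScheme(int(meta["window"]), int(meta["step"]),
                              bool(int(meta["circular"])))
        return CoverageTrack(
            genome_id=meta["genome_id"],
            genome_length=int(meta["genome_length"]),
            scheme=scheme,
            starts=df["start"].to_numpy(np.int64),
            gc=df["gc"].to_numpy(float) if "gc" in df else None,
            coverage=df["coverage"].to_numpy(float) if "coverage" in df else None,
            corrected=df["corrected"].to_numpy(float) if "corrected" in df else None,
            total_aligned_bases=int(meta["total_aligned_bases"]),
            label=meta["label"].strip(),
        )

    def to_bedgraph(self, path, value: str = "coverage") -> None:
        """bedGraph export; wrapping windows are clipped at L for browsers."""
        arr = getattr(self, value)
        if arr is None:
            raise ValueError(f"track has no {value!r} values")
        L = self.genome_length
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{self.label or value}"\n')
            for s, e, v in zip(self.starts, self.ends, arr):
                fh.write(f"{self.genome_id}\t{s}\t{min(int(e), L)}\t{v:.6g}\n")


def _window_sums(per_base: np.ndarray, starts: np.ndarray, W: int,
                 circular: bool) -> np.ndarray:
    """Sum of a per-base array over each window, wrapping when circular."""
    if circular:
        ext = np.concatenate([per_base, per_base[:W]])
    else:
        ext = per_base
    cs = np.concatenate([[0], np.cumsum(ext)])
    return cs[starts + W] - cs[starts]


def window_coverage(fragments: FragmentSet, genome_length: int,
                    scheme: WindowScheme, genome_id: Optional[str] = None,
                    label: str = "") -> CoverageTrack:
    """Per-window aligned-base coverage via per-base accumulation.

    Equivalent to summing, for every fragment block, its overlap in bases
    with each window.
    """
    fragments.validate(genome_length)
    starts = make_windows(genome_length, scheme)
    bs, be = fragments.block_arrays()
    # difference array -> per-base depth
    diff = np.bincount(bs, minlength=genome_length + 1).astype(np.int64)
    diff -= np.bincount(be, minlength=genome_length + 1)
    per_base = np.cumsum(diff[:genome_length])
    cov = _window_sums(per_base, starts, scheme.window_size, scheme.circular)
    return CoverageTrack(
        genome_id=genome_id or fragments.chrom,
        genome_length=genome_length,
        scheme=scheme,
        starts=starts,
        coverage=cov.astype(float),
        total_aligned_bases=fragments.total_bases,
        label=label,
    )


def window_gc(genome: GenomeRecord, track: CoverageTrack) -> CoverageTrack:
    """Set each window's GC fraction (G+C count over window width).

    ``N`` counts as neither G nor C but remains in the denominator; characters
    outside {A,C,G,T,N} were already rejected when the genome was loaded.
    """
    if genome.length != track.genome_length:
        raise ValueError(
            f"genome length {genome.length} != track genome length "
            f"{track.genome_length}"
        )
    gc_counts = _window_sums(genome.gc_mask.astype(np.int64), track.starts,
                             track.scheme.window_size, track.scheme.circular)
    track.gc = gc_counts / track.scheme.window_size
    return track


@dataclass
class GcSkewResult:
    """Per-window (G-C)/(G+C) skew and its cumulative profile.

    The cumulative profile runs over non-overlapping windows; its global
    minimum is the classical candidate replication origin and the maximum the
    candidate terminus (for a genome whose leading strand is G-rich).
    """

    starts: np.ndarray
    skew: np.ndarray
    cumulative: np.ndarray
    origin_candidate: int
    terminus_candidate: int


def cumulative_gc_skew(genome: GenomeRecord, window_size: int = 1000) -> GcSkewResult:
    """GC skew over non-overlapping windows plus the cumulative-skew extrema."""
    L = genome.length
    if window_size > L:
        raise WindowSchemeError(f"window size {window_size} exceeds genome length {L}")
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    n = L // window_size
    starts = np.arange(n, dtype=np.int64) * window_size
    g = np.add.reduceat(is_g[: n * window_size], starts)
    c = np.add.reduceat(is_c[: n * window_size], starts)
    denom = g + c
    skew = np.zeros(n, dtype=float)
    nz = denom > 0
    skew[nz] = (g[nz] - c[nz]) / denom[nz]
    cum = np.cumsum(skew)
    mids = starts + window_size // 2
    return GcSkewResult(
        starts=starts,
        skew=skew,
        cumulative=cum,
        origin_candidate=int(mids[int(np.argmin(cum))]),
        terminus_candidate=int(mids[int(np.argmax(cum))]),
    )
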