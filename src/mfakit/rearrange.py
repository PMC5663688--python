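"""Subpopulation inversions and excisions from chimeric junction fragments.

A fragment whose two aligned blocks are non-collinear on the reference is
evidence for a structural rearrangement breakpoint carried by a fraction of
the genomes in the culture:

* blocks on opposite strands — an inversion junction.  With blocks in genomic
  order and canonical orientation, a ``(+,-)`` pair is the head-to-head
  junction (both blocks end at their breakpoints) and ``(-,+)`` the
  tail-to-tail junction (both blocks start at their breakpoints); both encode
  the same breakpoint pair (a, b).
* same-strand blocks separated by a gap — an excision junction whose deleted
  interval is (first block end, second block start).

Circular wrap-around splits (first block starting at 0 and second ending at
the genome length, same strand) are collinear on the circle and are not
junctions.

The subpopulation fraction is estimated per call as
``f_hat = J_joint / (J_joint + C_bp)`` where ``J_joint`` is the junction
count per novel joint (an inversion has two joints, an excision one) and
``C_bp`` the mean count of reference-collinear fragments spanning a
breakpoint.  The per-joint normalisation keeps the estimate unbiased for
excisions, which present one joint but two reference breakpoints.  For
excision calls a second, coverage-based estimate (the relative coverage dip
inside the deleted interval) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .fragments import FragmentSet


@dataclass
class JunctionTable:
    """Classified two-block junction fragments."""

    kind: np.ndarray        # 'inversion' | 'excision'
    a: np.ndarray           # lower breakpoint per junction fragment
    b: np.ndarray           # upper breakpoint
    n_collinear_wrap: int   # circular wrap splits (not junctions)
    n_unclassified: int

    def __len__(self) -> int:
        return len(self.kind)


@dataclass
class RearrangementCall:
    kind: str
    breakpoint_a: int
    breakpoint_b: int
    tolerance_bp: int
    support: int            # junction fragments in the cluster
    local_depth: int        # collinear fragments spanning either breakpoint
    f_hat: float            # junction-based subpopulation fraction
    dip_estimate: Optional[float] = None   # excision only; None = not estimable
    coverage_anomaly: bool = False


def find_junction_fragments(fragments: FragmentSet,
                            genome_length: int) -> JunctionTable:
    """Classify every two-block fragment by its breakpoint signature."""
    fragments.validate(genome_length)
    chim = fragments.is_chimeric
    b1s = fragments.b1_start[chim]
    b1e = fragments.b1_end[chim]
    st1 = fragments.b1_strand[chim]
    b2s = fragments.b2_start[chim]
    b2e = fragments.b2_end[chim]
    st2 = fragments.b2_strand[chim]

    same = st1 == st2
    wrap = same & (b1s == 0) & (b2e == genome_length)
    gap = same & ~wrap & (b2s > b1e)
    hh = (st1 == 1) & (st2 == -1)
    tt = (st1 == -1) & (st2 == 1)

    kinds, aa, bb = [], [], []
    for mask, kind, a_arr, b_arr in (
        (hh, "inversion", b1e, b2e),
        (tt, "inversion", b1s, b2s),
        (gap, "excision", b1e, b2s),
    ):
        m = int(mask.sum())
        if m:
            kinds.extend([kind] * m)
            aa.extend(a_arr[mask].tolist())
            bb.extend(b_arr[mask].tolist())
    unclassified = int(len(b1s) - wrap.sum() - gap.sum() - hh.sum() - tt.sum())
    return JunctionTable(
        kind=np.array(kinds, dtype=object),
        a=np.array(aa, dtype=np.int64),
        b=np.array(bb, dtype=np.int64),
        n_collinear_wrap=int(wrap.sum()),
        n_unclassified=unclassified,
    )


def _cluster(kind: str, a: np.ndarray, b: np.ndarray, tol: int) -> list:
    """Greedy clustering on breakpoint pairs: members join a cluster when both
    coordinates are within ``tol`` of the cluster's running medians."""
    order = np.lexsort((b, a))
    clusters = []
    for i in order:
        placed = False
        for cl in clusters:
            if abs(a[i] - np.median(cl[0])) <= tol and \
               abs(b[i] - np.median(cl[1])) <= tol:
                cl[0].append(int(a[i]))
                cl[1].append(int(b[i]))
                placed = True
                break
        if not placed:
            clusters.append(([int(a[i])], [int(b[i])]))
    return [(kind, cl[0], cl[1]) for cl in clusters]


def _crossing_count(fragments: FragmentSet, pos: int) -> int:
    """Collinear (single-block) fragments strictly spanning ``pos``."""
    single = ~fragments.is_chimeric
    s = fragments.b1_start[single]
    e = fragments.b1_end[single]
    return int(np.sum((s < pos) & (e > pos)))


def _local_start_density(fragments: FragmentSet, pos: int, halfwidth: int,
                         genome_length: int) -> float:
    s = fragments.b1_start
    lo, hi = pos - halfwidth, pos + halfwidth
    n = np.sum((s >= lo) & (s < hi))
    return float(n) / (2 * halfwidth)


def call_rearrangements(junctions: JunctionTable, fragments: FragmentSet,
                        genome_length: int,
                        cluster_tolerance_bp: int = 300,
                        min_support: int = 3) -> list:
    """Cluster junction fragments into rearrangement calls.

    Clusters with fewer than ``min_support`` members are dropped.  Inversion
    head-to-head and tail-to-tail junctions carry the same (a, b) pair and
    fall into one cluster whose support is their sum; ``f_hat`` divides the
    support by the number of novel joints (2 for inversions, 1 for excisions)
    before comparing with the mean collinear crossing depth per breakpoint.
    """
    calls = []
    for kind in ("inversion", "excision"):
        m = junctions.kind == kind
        if not m.any():
            continue
        for _, a_list, b_list in _cluster(kind, junctions.a[m], junctions.b[m],
                                          cluster_tolerance_bp):
            support = len(a_list)
            if support < min_support:
                continue
            a = int(np.median(a_list))
            b = int(np.median(b_list))
            cross_a = _crossing_count(fragments, a)
            cross_b = _crossing_count(fragments, b)
            n_joints = 2 if kind == "inversion" else 1
            j_per_joint = support / n_joints
            c_per_bp = (cross_a + cross_b) / 2.0
            f_hat = j_per_joint / (j_per_joint + c_per_bp) \
                if (j_per_joint + c_per_bp) > 0 else 0.0
            # qualitative spike/dip flag: junction-adjacent start density vs global
            frag_len = int(np.median(fragments.b1_end - fragments.b1_start))
            dens = np.mean([
                _local_start_density(fragments, p, 2 * frag_len, genome_length)
                for p in (a, b)
            ])
            global_dens = len(fragments) / genome_length
            anomaly = bool(abs(dens - global_dens) > 0.2 * global_dens)
            calls.append(RearrangementCall(
                kind=kind, breakpoint_a=a, breakpoint_b=b,
                tolerance_bp=cluster_tolerance_bp,
                support=support, local_depth=cross_a + cross_b,
                f_hat=float(np.clip(f_hat, 0.0, 1.0)),
                coverage_anomaly=anomaly,
            ))
    calls.sort(key=lambda c: (-c.support, c.breakpoint_a))
    return calls


def excision_dip_estimate(call: RearrangementCall,
                          exp_track: CoverageTrack) -> RearrangementCall:
    """Coverage-based excision fraction: relative dip inside the deleted interval.

    ``dip = 1 - mean(corrected coverage inside (a,b)) / mean(corrected
    coverage in equal-width flanks)``.  Requires a GC-corrected exponential
    track and at least two windows fully inside the interval; otherwise the
    call is returned with ``dip_estimate = None``.
    """
    if call.kind != "excision":
        raise ValueError("dip estimate applies to excision calls only")
    if exp_track.corrected is None:
        raise ValueError("corrected coverage required for the dip estimate")
    a, b = call.breakpoint_a, call.breakpoint_b
    width = b - a
    L = exp_track.genome_length
    starts = exp_track.starts
    ends = exp_track.ends
    inside = (starts >= a) & (ends <= b)
    if inside.sum() < 2:
        call.dip_estimate = None
        return call
    left = (starts >= max(a - width, 0)) & (ends <= a)
    right = (starts >= b) & (ends <= min(b + width, L))
    flank = left | right
    if flank.sum() < 2:
        call.dip_estimate = None
        return call
    mean_in = float(exp_track.corrected[inside].mean())
    mean_fl = float(exp_track.corrected[flank].mean())
    call.dip_estimate = float(1.0 - mean_in / mean_fl) if mean_fl > 0 else None
    return call


def calls_to_dataframe(calls) -> pd.DataFrame:
    return pd.DataFrame([{
        "kind": c.kind, "breakpoint_a": c.breakpoint_a,
        "breakpoint_b": c.breakpoint_b, "support": c.support,
        "local_depth": c.local_depth, "f_hat": c.f_hat,
        "dip_estimate": c.dip_estimate, "coverage_anomaly": c.coverage_anomaly,
    } for c in calls])


def junctions_to_bedpe(junctions: JunctionTable, chrom: str, path) -> None:
    """BEDPE export of individual junction fragments (1 bp intervals)."""
    with open(path, "w") as fh:
        for i in range(len(junctions)):
            a, b = int(junctions.a[i]), int(junctions.b[i])
            fh.write(f"{chrom}\t{a}\t{a + 1}\t{chrom}\t{b}\t{b + 1}\t"
                     f"junc{i}\t0\t.\t.\t{junctions.kind[i]}\n")
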