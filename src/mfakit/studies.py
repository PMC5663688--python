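"""Replicated simulation studies of pipeline performance.

Each study runs the full simulate -> coverage -> GC-correct -> ratio ->
smooth -> call chain (or the rearrangement chain) over seeded replicates at
stated conditions and reports per-replicate outcomes plus aggregate rates.
These back both the test suite's recovery/specificity checks and the
reproduction script.

Study conditions (genome size, fork amplitude k, depth, fragment length,
subpopulation fraction) are fixed by the caller; the functions add no hidden
rescaling.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.stats import spearmanr

from .coverage import WindowScheme, window_coverage, window_gc
from .gcbias import correct_coverage, fit_gc_bias
from .genome import circular_distance
from .mfa import (DEFAULT_THRESHOLD_LOG2, RECOVERY_SMOOTH_SPAN, call_origins,
                  fit_gradient_origin, simulate_mfa_replicate)
from .rearrange import (call_rearrangements, excision_dip_estimate,
                        find_junction_fragments)
from .synthetic import (GCBiasSpec, RearrangementSpec, SimulationConfig,
                        apply_rearrangements, copy_number_profile,
                        generate_genome, simulate_fragments)


def single_origin_recovery(reps: int = 20, seed: int = 0, L: int = 1_000_000,
                           k: float = 1.0, depth: float = 100.0,
                           tolerance_bp: int = 1000,
                           span_windows: int = RECOVERY_SMOOTH_SPAN,
                           threshold: float = DEFAULT_THRESHOLD_LOG2) -> dict:
    """Exact recovery of one origin against a uniform stationary control.

    A replicate succeeds when exactly one origin call is made and the
    gradient-refined peak lies within ``tolerance_bp`` of the true origin.
    The looser detection-only rate (>= 1 call, any position) and the peak
    localisation errors are reported alongside.
    """
    rng = np.random.default_rng(seed)
    n_success = n_exactly_one = n_detected = 0
    errors = []
    for _ in range(reps):
        origin = int(rng.integers(L))
        rep_seed = int(rng.integers(2**31))
        track = simulate_mfa_replicate(L, "single_origin", [origin], k, depth,
                                       rep_seed, span_windows=span_windows)
        calls = call_origins(track, threshold_log2=threshold)
        n_detected += len(calls) >= 1
        n_exactly_one += len(calls) == 1
        if not calls:
            continue
        peak = fit_gradient_origin(track).origin
        err = circular_distance(peak, origin, L)
        errors.append(err)
        if len(calls) == 1 and err <= tolerance_bp:
            n_success += 1
    return {
        "reps": reps, "k": k, "depth": depth, "tolerance_bp": tolerance_bp,
        "recovery_rate": n_success / reps,
        "detection_rate": n_detected / reps,
        "exactly_one_call_rate": n_exactly_one / reps,
        "median_peak_error_bp": float(np.median(errors)) if errors else None,
    }


def flat_specificity(reps: int = 20, seed: int = 0, L: int = 1_000_000,
                     depth: float = 100.0,
                     span_windows: int = RECOVERY_SMOOTH_SPAN,
                     threshold: float = DEFAULT_THRESHOLD_LOG2) -> dict:
    """False origin calls under random (dispersed) initiation.

    Both conditions are flat at the same depth; reports the fraction of
    replicates with zero calls at the default threshold.
    """
    rng = np.random.default_rng(seed)
    zero = 0
    n_calls = []
    for _ in range(reps):
        rep_seed = int(rng.integers(2**31))
        track = simulate_mfa_replicate(L, "random", [], 0.0, depth, rep_seed,
                                       span_windows=span_windows)
        calls = call_origins(track, threshold_log2=threshold)
        n_calls.append(len(calls))
        zero += len(calls) == 0
    return {
        "reps": reps, "depth": depth, "threshold": threshold,
        "zero_call_rate": zero / reps,
        "mean_calls": float(np.mean(n_calls)),
    }


def multi_origin_power(n_origins: int = 5, reps: int = 20, seed: int = 0,
                       L: int = 1_000_000, k: float = 1.0,
                       depth: float = 100.0, tolerance_bp: int = 1000,
                       span_windows: int = RECOVERY_SMOOTH_SPAN,
                       threshold: Optional[float] = None) -> dict:
    """Power to recover m evenly spaced origins.

    Success requires >= m calls with every true origin within
    ``tolerance_bp`` of some call peak.  The default threshold scales with
    the expected profile relief, 0.3 * k / (2m).  A detection-only rate at a
    tolerance of one origin spacing's quarter is reported alongside, to
    separate "the peaks are seen" from "the peaks are localised".
    """
    if threshold is None:
        threshold = 0.3 * k / (2 * n_origins)
    rng = np.random.default_rng(seed)
    n_strict = n_loose = 0
    loose_tol = L // n_origins // 4
    for _ in range(reps):
        offset = int(rng.integers(L))
        origins = [(offset + i * L // n_origins) % L for i in range(n_origins)]
        rep_seed = int(rng.integers(2**31))
        track = simulate_mfa_replicate(
            L, "multi_origin" if n_origins > 1 else "single_origin",
            origins, k, depth, rep_seed, span_windows=span_windows)
        calls = call_origins(track, threshold_log2=threshold)
        peaks = [c.peak for c in calls]
        if len(calls) >= n_origins:
            def all_within(tol):
                return all(any(circular_distance(o, p, L) <= tol for p in peaks)
                           for o in origins)
            n_strict += all_within(tolerance_bp)
            n_loose += all_within(loose_tol)
    return {
        "n_origins": n_origins, "reps": reps, "k": k, "depth": depth,
        "threshold": threshold, "tolerance_bp": tolerance_bp,
        "power": n_strict / reps,
        "loose_tolerance_bp": loose_tol,
        "detection_power_loose": n_loose / reps,
    }


def rearrangement_recovery(kind: str = "inversion", reps: int = 20,
                           seed: int = 0, L: int = 200_000,
                           breakpoints: Optional[tuple] = None,
                           fraction: float = 0.10, depth: float = 300.0,
                           fragment_length: int = 150,
                           breakpoint_tolerance_bp: int = 150,
                           f_hat_band: tuple = (0.05, 0.15),
                           with_dip: bool = False) -> dict:
    """Recovery of a subpopulation rearrangement at stated conditions.

    A replicate succeeds when exactly one call of the simulated kind is made,
    both breakpoints fall within ``breakpoint_tolerance_bp`` of truth, and
    f_hat lies inside ``f_hat_band``.
    """
    if breakpoints is None:
        breakpoints = (int(0.35 * L), int(0.65 * L)) if kind == "inversion" \
            else (int(0.40 * L), int(0.55 * L))
    a, b = breakpoints
    rng = np.random.default_rng(seed)
    n = int(round(depth * L / fragment_length))
    n_success = 0
    f_hats, bp_errors, dips = [], [], []
    for _ in range(reps):
        g_seed, f_seed = (int(x) for x in rng.integers(2**31, size=2))
        genome = generate_genome(SimulationConfig(
            genome_length=L, gc_blocks=((L, 0.5),), seed=g_seed))
        flat = copy_number_profile(L, "random")
        spec = RearrangementSpec(kind, a, b, fraction)
        frags = apply_rearrangements(genome, flat, GCBiasSpec.identity(),
                                     fragment_length, n, [spec], f_seed)
        junctions = find_junction_fragments(frags, L)
        calls = call_rearrangements(junctions, frags, L)
        matching = [c for c in calls if c.kind == kind]
        if len(matching) != 1 or len(calls) != 1:
            continue
        c = matching[0]
        err = max(abs(c.breakpoint_a - a), abs(c.breakpoint_b - b))
        bp_errors.append(err)
        f_hats.append(c.f_hat)
        if with_dip and kind == "excision":
            track = window_coverage(frags, L, WindowScheme())
            window_gc(genome, track)
            correct_coverage(track, fit_gc_bias(track))
            excision_dip_estimate(c, track)
            if c.dip_estimate is not None:
                dips.append(c.dip_estimate)
        if err <= breakpoint_tolerance_bp and \
                f_hat_band[0] <= c.f_hat <= f_hat_band[1]:
            n_success += 1
    out = {
        "kind": kind, "reps": reps, "fraction": fraction, "depth": depth,
        "recovery_rate": n_success / reps,
        "median_breakpoint_error_bp": float(np.median(bp_errors)) if bp_errors else None,
        "mean_f_hat": float(np.mean(f_hats)) if f_hats else None,
    }
    if with_dip and kind == "excision":
        out["mean_dip_estimate"] = float(np.mean(dips)) if dips else None
    return out


def rearrangement_control_specificity(reps: int = 20, seed: int = 0,
                                      L: int = 200_000, depth: float = 300.0,
                                      fragment_length: int = 150) -> dict:
    """False rearrangement calls on event-free simulations."""
    rng = np.random.default_rng(seed)
    n = int(round(depth * L / fragment_length))
    zero = 0
    for _ in range(reps):
        g_seed, f_seed = (int(x) for x in rng.integers(2**31, size=2))
        genome = generate_genome(SimulationConfig(
            genome_length=L, gc_blocks=((L, 0.5),), seed=g_seed))
        flat = copy_number_profile(L, "random")
        frags = simulate_fragments(genome, flat, GCBiasSpec.identity(),
                                   fragment_length, n, f_seed)
        junctions = find_junction_fragments(frags, L)
        zero += len(call_rearrangements(junctions, frags, L)) == 0
    return {"reps": reps, "zero_call_rate": zero / reps}


def gc_bias_removal(seed: int = 0, L: int = 100_000, depth: float = 100.0,
                    high_weight: float = 2.0) -> dict:
    """Injected two-fold GC step bias: Spearman before/after correction.

    The genome alternates 5 kb blocks at GC 0.3 / 0.7 and the sampler favours
    fragments with GC > 0.5 by ``high_weight``.  Reports the rank correlation
    between window GC and (corrected) coverage, the recovered plateau ratio,
    and the mean-preservation error of the correction.
    """
    rng = np.random.default_rng(seed)
    g_seed, f_seed = (int(x) for x in rng.integers(2**31, size=2))
    genome = generate_genome(SimulationConfig(
        genome_length=L, gc_blocks=((5000, 0.3), (5000, 0.7)), seed=g_seed))
    flat = copy_number_profile(L, "random")
    n = int(round(depth * L / 150))
    frags = simulate_fragments(genome, flat, GCBiasSpec.step(0.5, high_weight),
                               150, n, f_seed)
    track = window_coverage(frags, L, WindowScheme())
    window_gc(genome, track)
    rho_before = float(spearmanr(track.gc, track.coverage).statistic)
    model = fit_gc_bias(track)
    correct_coverage(track, model)
    rho_after = float(spearmanr(track.gc, track.corrected).statistic)
    return {
        "rho_before": rho_before,
        "rho_after": rho_after,
        "abs_rho_after": abs(rho_after),
        "fitted_plateau_ratio": float(model.fitted(0.70) / model.fitted(0.30)),
        "mean_preservation_ratio": float(track.corrected.mean() / model.global_mean),
    }
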