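"""End-to-end orchestration: coverage -> GC correction -> MFA -> origin and
rearrangement calls, with a machine-readable run summary.

The pipeline consumes a genome FASTA plus one aligned-fragment BED per
condition (exponential and stationary) — typically a fixture set written by
:func:`mfakit.synthetic.write_fixture_set` — and emits per-sample coverage
tracks, the fitted GC-bias models, the marker-frequency track, origin calls,
rearrangement calls and diagnostic figures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coverage import (WindowScheme, cumulative_gc_skew, window_coverage,
                       window_gc)
from .fragments import FragmentSet
from .gcbias import correct_coverage, fit_gc_bias, plot_gc_fit
from .genome import read_fasta
from .mfa import (DEFAULT_MIN_WIDTH_WINDOWS, DEFAULT_MIN_STAT_FRACTION,
                  DEFAULT_PSEUDOCOUNT, DEFAULT_SMOOTH_SPAN,
                  DEFAULT_THRESHOLD_LOG2, call_origins, detection_power,
                  fit_gradient_origin, mfa_ratio, smooth_track)
from .plotting import plot_cumulative_skew, plot_mfa_track
from .rearrange import (call_rearrangements, calls_to_dataframe,
                        excision_dip_estimate, find_junction_fragments,
                        junctions_to_bedpe)

log = logging.getLogger("mfakit")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    genome_fasta: str
    exponential_bed: str
    stationary_bed: str
    outdir: str
    window_size: int = 1000
    step: int = 500
    circular: bool = True
    gc_bin_width: float = 0.01
    lowess_fraction: float = 0.3
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    min_stat_fraction: float = DEFAULT_MIN_STAT_FRACTION
    smooth_span: int = DEFAULT_SMOOTH_SPAN
    threshold_log2: float = DEFAULT_THRESHOLD_LOG2
    min_width_windows: int = DEFAULT_MIN_WIDTH_WINDOWS
    cluster_tolerance_bp: int = 300
    min_support: int = 3
    seed: int = 0
    log_level: str = "INFO"
    make_plots: bool = True

    def validate(self) -> None:
        for attr in ("genome_fasta", "exponential_bed", "stationary_bed"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise PipelineConfigError(f"{attr}: no such file {p}")

    @staticmethod
    def from_json(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the run summary dict."""
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    scheme = WindowScheme(config.window_size, config.step, config.circular)

    genome = read_fasta(config.genome_fasta, circular=config.circular)
    log.info("genome %s: %d bp", genome.id, genome.length)

    tracks = {}
    frag_sets = {}
    for label, path in (("exponential", config.exponential_bed),
                        ("stationary", config.stationary_bed)):
        t = time.monotonic()
        frags = FragmentSet.from_bed(path)
        track = window_coverage(frags, genome.length, scheme,
                                genome_id=genome.id, label=label)
        window_gc(genome, track)
        model = fit_gc_bias(track, config.gc_bin_width, config.lowess_fraction)
        correct_coverage(track, model)
        track.to_tsv(outdir / f"coverage_{label}.tsv")
        model.to_json(outdir / f"gc_bias_{label}.json")
        if config.make_plots:
            plot_gc_fit(model, outdir / f"gc_bias_{label}.png")
        tracks[label] = track
        frag_sets[label] = frags
        log.info("%s: %d fragments, mean coverage %.1fx, GC model on %d bins "
                 "(%.1fs)", label, len(frags),
                 track.total_aligned_bases / genome.length,
                 len(model.bin_centers), time.monotonic() - t)

    mfa_track = mfa_ratio(tracks["exponential"], tracks["stationary"],
                          config.pseudocount, config.min_stat_fraction)
    smooth_track(mfa_track, config.smooth_span)
    mfa_track.to_tsv(outdir / "mfa_track.tsv")
    mfa_track.to_bedgraph(outdir / "mfa_smoothed.bedgraph")

    calls = call_origins(mfa_track, config.threshold_log2,
                         config.min_width_windows)
    grad = fit_gradient_origin(mfa_track)
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        outdir / "origin_calls.tsv", sep="\t", index=False)
    log.info("origin calls: %d (gradient fit: pos=%d amp=%.3f r=%.3f)",
             len(calls), grad.origin, grad.amplitude, grad.correlation)

    junctions = find_junction_fragments(frag_sets["exponential"], genome.length)
    re_calls = call_rearrangements(junctions, frag_sets["exponential"],
                                   genome.length, config.cluster_tolerance_bp,
                                   config.min_support)
    for c in re_calls:
        if c.kind == "excision":
            excision_dip_estimate(c, tracks["exponential"])
    calls_to_dataframe(re_calls).to_csv(outdir / "rearrangement_calls.tsv",
                                        sep="\t", index=False)
    junctions_to_bedpe(junctions, genome.id, outdir / "junctions.bedpe")

    skew = cumulative_gc_skew(genome, config.window_size)
    if config.make_plots:
        plot_mfa_track(mfa_track, outdir / "mfa_track.png", calls=calls)
        plot_cumulative_skew(skew, outdir / "gc_skew.png")

    summary = {
        "mfakit_version": __version__,
        "parameters": config.to_dict(),
        "inputs": {k: _sha256(getattr(config, k)) for k in
                   ("genome_fasta", "exponential_bed", "stationary_bed")},
        "genome": {"id": genome.id, "length": genome.length},
        "samples": {
            label: {
                "n_fragments": len(frag_sets[label]),
                "total_aligned_bases": tracks[label].total_aligned_bases,
                "mean_coverage": tracks[label].total_aligned_bases / genome.length,
            } for label in tracks
        },
        "origin_calls": [dataclasses.asdict(c) for c in calls],
        "gradient_fit": dataclasses.asdict(grad),
        "rearrangement_calls": [dataclasses.asdict(c) for c in re_calls],
        "junction_fragments": len(junctions),
        "gc_skew": {"origin_candidate": skew.origin_candidate,
                    "terminus_candidate": skew.terminus_candidate},
        "runtime_s": round(time.monotonic() - t0, 2),
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_simulation_study(scenarios=None, reps: int = 10, seed: int = 0,
                         out_csv=None) -> pd.DataFrame:
    """Sensitivity / specificity table over (n_origins, k, depth) scenarios.

    Default scenarios: single origin, five evenly spaced origins, and the
    random-initiation null, all at k=1 and 100x depth.
    """
    if reps < 1:
        raise PipelineConfigError("need reps >= 1")
    if scenarios is None:
        scenarios = [(1, 1.0, 100.0), (5, 1.0, 100.0), (1, 0.0, 100.0)]
    rows = []
    for i, (n_origins, k, depth) in enumerate(scenarios):
        res = detection_power(n_origins, k, depth, reps=reps,
                              seed=seed + 1000 * i)
        res["scenario"] = ("null_random" if k == 0
                           else f"{n_origins}_origin_k{k:g}")
        rows.append(res)
        log.info("study %s: sensitivity %.2f (mean calls %.1f)",
                 res["scenario"], res["sensitivity"], res["mean_calls"])
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
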