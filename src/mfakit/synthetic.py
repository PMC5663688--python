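"""Synthetic genomes, replication-mode copy-number profiles, and GC-biased
aligned fragments.

The simulator emulates the inputs to marker-frequency analysis (MFA) of a
circular microbial chromosome:

* exponential-phase cultures replicating from one or more defined origins
  produce a copy-number gradient — loci near an origin are over-represented,
  the terminus under-represented;
* random / recombination-driven initiation and stationary-phase cultures
  produce flat profiles;
* library preparation and sequencing sample fragments with a GC-dependent
  weight;
* a subpopulation of genomes may carry a large inversion or excision, which
  leaves chimeric junction fragments and coverage dips in the mix.

Fragments are emitted already aligned (the pipeline consumes mapped
fragments; trimming and alignment are upstream concerns), with circular
wrap-arounds split into two collinear blocks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .fragments import FragmentSet
from .genome import GenomeRecord, write_fasta

VALID_MODES = ("single_origin", "multi_origin", "random")


class ConfigurationError(ValueError):
    """Invalid simulation parameterisation."""


# ---------------------------------------------------------------------------
# GC sampling bias
# ---------------------------------------------------------------------------

@dataclass
class GCBiasSpec:
    """Relative sampling weight as a function of fragment GC fraction.

    ``bias_function`` must be vectorised over numpy arrays and strictly
    positive on [0, 1].
    """

    bias_function: Callable[[np.ndarray], np.ndarray]
    description: str = "custom"

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        w = np.asarray(self.bias_function(np.asarray(gc, dtype=float)), dtype=float)
        if np.any(w <= 0):
            raise ConfigurationError(
                f"GC bias {self.description!r} is non-positive somewhere on [0,1]"
            )
        return w

    @staticmethod
    def identity() -> "GCBiasSpec":
        return GCBiasSpec(lambda gc: np.ones_like(gc, dtype=float), "identity")

    @staticmethod
    def step(threshold: float = 0.5, high_weight: float = 2.0) -> "GCBiasSpec":
        """Fragments with GC > threshold sampled ``high_weight``-fold more."""
        return GCBiasSpec(
            lambda gc: np.where(gc > threshold, float(high_weight), 1.0),
            f"step(GC>{threshold}: x{high_weight})",
        )


# ---------------------------------------------------------------------------
# Replication copy-number profiles
# ---------------------------------------------------------------------------

@dataclass
class ReplicationProfile:
    """Per-position relative copy number for a replication mode.

    For origin-dependent theta replication the steady-state marker-frequency
    expectation is log2-linear in distance from the origin:
    ``log2 value(d) = k * (1 - d / (L/2))`` with ``d`` the circular distance
    to the owning origin, so the origin:terminus ratio is ``2**k``.
    Random (recombination-driven) initiation gives a flat profile.
    """

    mode: str
    origin_positions: list
    fork_amplitude: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ConfigurationError("profile values must be positive")


def copy_number_profile(L: int, mode: str, origins: Sequence[int] = (),
                        k: float = 1.0) -> ReplicationProfile:
    """Build the relative copy-number profile for a replication mode.

    Parameters
    ----------
    L : genome length (bp)
    mode : 'single_origin', 'multi_origin' or 'random'
    origins : origin positions in [0, L); ignored for 'random'
    k : log2 copy-number span per replichore (origin:terminus ratio 2**k)
    """
    if mode not in VALID_MODES:
        raise ConfigurationError(f"unknown replication mode {mode!r}")
    if k < 0:
        raise ConfigurationError(f"fork amplitude k must be >= 0, got {k}")
    if mode == "random":
        return ReplicationProfile("random", [], k, np.ones(L))
    origins = [int(o) for o in origins]
    if not origins:
        raise ConfigurationError(f"mode {mode!r} needs at least one origin")
    if mode == "single_origin" and len(origins) != 1:
        raise ConfigurationError("single_origin mode takes exactly one origin")
    for o in origins:
        if not 0 <= o < L:
            raise ConfigurationError(f"origin {o} outside [0, {L})")
    pos = np.arange(L)
    log2v = np.full(L, -np.inf)
    for o in origins:
        d = np.abs(pos - o)
        d = np.minimum(d, L - d)  # circular distance
        log2v = np.maximum(log2v, k * (1.0 - d / (L / 2.0)))
    return ReplicationProfile(mode, origins, k, np.exp2(log2v))


# ---------------------------------------------------------------------------
# Rearrangements
# ---------------------------------------------------------------------------

@dataclass
class RearrangementSpec:
    """A subpopulation structural event on the reference.

    kind : 'inversion' (segment [a, b) reversed) or 'excision'
        (segment [a, b) deleted).
    subpopulation_fraction : fraction of genomes carrying the event.
    """

    kind: str
    breakpoint_a: int
    breakpoint_b: int
    subpopulation_fraction: float

    def __post_init__(self):
        if self.kind not in ("inversion", "excision"):
            raise ConfigurationError(f"unknown rearrangement kind {self.kind!r}")
        if not self.breakpoint_a < self.breakpoint_b:
            raise ConfigurationError(
                f"breakpoints must satisfy a < b, got {self.breakpoint_a}, {self.breakpoint_b}"
            )
        if not 0.0 <= self.subpopulation_fraction <= 1.0:
            raise ConfigurationError(
                f"subpopulation fraction must be in [0,1], got {self.subpopulation_fraction}"
            )


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Complete recipe for a two-condition (exponential/stationary) fixture.

    ``gc_blocks`` is a list of ``(block_length, gc_target)`` pairs tiled over
    the genome; a single pair gives a homogeneous composition.
    """

    genome_length: int = 1_000_000
    gc_blocks: Sequence = ((1_000_000, 0.52),)
    mode: str = "single_origin"
    origins: Sequence[int] = (0,)
    fork_amplitude: float = 1.0
    bias: GCBiasSpec = field(default_factory=GCBiasSpec.identity)
    fragment_length: int = 150
    n_fragments: int = 100_000
    rearrangements: Sequence[RearrangementSpec] = ()
    seed: int = 0
    genome_id: str = "synthetic_chr"

    @property
    def mean_depth(self) -> float:
        return self.n_fragments * self.fragment_length / self.genome_length

    def child_seeds(self, n: int) -> list:
        """Deterministic per-stage child RNG seeds from the master seed."""
        return list(np.random.SeedSequence(self.seed).generate_state(n))


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> GenomeRecord:
    """Sample a circular genome with per-block GC targets (binomial sampling)."""
    L = int(config.genome_length)
    if L <= 0:
        raise ConfigurationError(f"genome length must be positive, got {L}")
    rng = np.random.default_rng(config.child_seeds(4)[0])
    pieces = []
    total = 0
    blocks = list(config.gc_blocks)
    bi = 0
    bases_at = np.frombuffer(b"AT", dtype=np.uint8)
    bases_gc = np.frombuffer(b"GC", dtype=np.uint8)
    while total < L:
        block_len, gc = blocks[bi % len(blocks)]
        bi += 1
        block_len = min(int(block_len), L - total)
        if not 0.0 < gc < 1.0:
            raise ConfigurationError(f"GC target must be in (0,1), got {gc}")
        is_gc = rng.random(block_len) < gc
        out = np.empty(block_len, dtype=np.uint8)
        out[~is_gc] = rng.choice(bases_at, size=int((~is_gc).sum()))
        out[is_gc] = rng.choice(bases_gc, size=int(is_gc.sum()))
        pieces.append(out)
        total += block_len
    seq = np.concatenate(pieces).tobytes().decode("ascii")
    return GenomeRecord(id=config.genome_id, sequence=seq, circular=True)


# ---------------------------------------------------------------------------
# Fragment sampling
# ---------------------------------------------------------------------------

def _sample_starts(weights: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    return np.searchsorted(cdf, rng.random(n), side="right")


def _fragment_gc(gc_mask: np.ndarray, fragment_length: int) -> np.ndarray:
    """GC fraction of the fragment starting at each position (circular)."""
    ext = np.concatenate([gc_mask, gc_mask[:fragment_length]])
    cs = np.concatenate([[0], np.cumsum(ext)])
    L = len(gc_mask)
    return (cs[fragment_length:L + fragment_length] - cs[:L]) / fragment_length


def _emit_wrapped(chrom: str, starts: np.ndarray, flen: int, L: int,
                  strands: np.ndarray) -> FragmentSet:
    """Fragments [s, s+flen) on a circular genome, splitting wrap-arounds."""
    ends = starts + flen
    wrap = ends > L
    b1s = np.where(wrap, 0, starts)
    b1e = np.where(wrap, ends - L, ends)
    b2s = np.where(wrap, starts, -1)
    b2e = np.where(wrap, L, -1)
    b2strand = np.where(wrap, strands, 0).astype(np.int8)
    return FragmentSet(chrom, b1s, b1e, strands, b2s, b2e, b2strand)


def simulate_fragments(genome: GenomeRecord, profile: ReplicationProfile,
                       bias: GCBiasSpec, fragment_length: int, n: int,
                       seed: int) -> FragmentSet:
    """Draw ``n`` aligned fragments of fixed length.

    Start positions are drawn with probability proportional to
    ``profile.value[start] * bias(GC of the fragment)``; read strand is an
    independent fair coin.  Wrap-around fragments are split into two
    collinear blocks.  Deterministic under ``seed``.
    """
    L = genome.length
    if fragment_length >= L:
        raise ConfigurationError(
            f"fragment_length {fragment_length} must be < genome length {L}"
        )
    if n < 0:
        raise ConfigurationError("fragment count must be non-negative")
    if n == 0:
        return FragmentSet.empty(genome.id)
    if len(profile.values) != L:
        raise ConfigurationError("profile length does not match genome length")
    rng = np.random.default_rng(seed)
    weights = profile.values
    if bias.description != "identity":
        weights = weights * bias(_fragment_gc(genome.gc_mask, fragment_length))
    starts = _sample_starts(weights, n, rng)
    strands = np.where(rng.random(n) < 0.5, 1, -1).astype(np.int8)
    return _emit_wrapped(genome.id, starts, fragment_length, L, strands)


# ---------------------------------------------------------------------------
# Rearranged subpopulations
# ---------------------------------------------------------------------------

def _map_inversion_fragments(chrom, starts, flen, L, a, b,
                             rng) -> FragmentSet:
    """Map fragments sampled on the inverted molecule back to the reference."""
    ends = starts + flen
    cross_a = (starts < a) & (ends > a)
    cross_b = (starts < b) & (ends > b) & (ends <= L)
    internal = (starts >= a) & (ends <= b)
    plain = ~(cross_a | cross_b | internal)

    parts = []
    # plain fragments (incl. wrap-around at the coordinate origin): identity map
    if plain.any():
        st = np.where(rng.random(int(plain.sum())) < 0.5, 1, -1).astype(np.int8)
        parts.append(_emit_wrapped(chrom, starts[plain], flen, L, st))
    # internal to the inverted segment: single collinear block on the - strand
    if internal.any():
        s, e = starts[internal], ends[internal]
        rs, re = a + b - e, a + b - s
        st = np.full(len(s), -1, dtype=np.int8)
        parts.append(FragmentSet(chrom, rs, re, st))
    # head-to-head junction at a: ref [s, a)+  +  ref [a+b-e, b)-
    if cross_a.any():
        s, e = starts[cross_a], ends[cross_a]
        b1s, b1e = s, np.full(len(s), a)
        b2s, b2e = a + b - e, np.full(len(s), b)
        parts.append(FragmentSet(chrom, b1s, b1e, np.ones(len(s), dtype=np.int8),
                                 b2s, b2e, np.full(len(s), -1, dtype=np.int8)))
    # tail-to-tail junction at b: ref [a, a+b-s)-  +  ref [b, e)+
    if cross_b.any():
        s, e = starts[cross_b], ends[cross_b]
        b1s, b1e = np.full(len(s), a), a + b - s
        b2s, b2e = np.full(len(s), b), e
        parts.append(FragmentSet(chrom, b1s, b1e, np.full(len(s), -1, dtype=np.int8),
                                 b2s, b2e, np.ones(len(s), dtype=np.int8)))
    return FragmentSet.concat(parts)


def _map_excision_fragments(chrom, starts, flen, L, a, b, rng) -> FragmentSet:
    """Map fragments sampled on the excised molecule back to the reference."""
    d = b - a
    LR = L - d
    ends = starts + flen
    cross = (starts < a) & (ends > a)
    plain = ~cross
    parts = []
    if plain.any():
        s = starts[plain]
        # positions at/after the joint shift up by the deleted length
        s = np.where(s >= a, s + d, s)
        st = np.where(rng.random(len(s)) < 0.5, 1, -1).astype(np.int8)
        parts.append(_emit_wrapped(chrom, s, flen, L, st))
    if cross.any():
        s, e = starts[cross], ends[cross]
        b1s, b1e = s, np.full(len(s), a)
        b2s, b2e = np.full(len(s), b), b + (e - a)
        ones = np.ones(len(s), dtype=np.int8)
        parts.append(FragmentSet(chrom, b1s, b1e, ones, b2s, b2e, ones))
    return FragmentSet.concat(parts)


def _rearranged_weights(genome: GenomeRecord, profile: ReplicationProfile,
                        bias: GCBiasSpec, spec: RearrangementSpec,
                        fragment_length: int) -> np.ndarray:
    """Per-start sampling weights on the rearranged molecule: the profile value
    of the reference locus each position derives from, times the GC bias of the
    rearranged fragment sequence."""
    L = genome.length
    a, b = spec.breakpoint_a, spec.breakpoint_b
    pos = np.arange(L)
    if spec.kind == "inversion":
        refpos = np.where((pos >= a) & (pos < b), a + b - 1 - pos, pos)
        gc_mask = genome.gc_mask.copy()
        gc_mask[a:b] = gc_mask[a:b][::-1]  # complement preserves G+C
    else:
        refpos = np.concatenate([pos[:a], pos[b:]])
        gc_mask = np.concatenate([genome.gc_mask[:a], genome.gc_mask[b:]])
    w = profile.values[refpos]
    if bias.description != "identity":
        w = w * bias(_fragment_gc(gc_mask, fragment_length))
    return w


def apply_rearrangements(genome: GenomeRecord, profile: ReplicationProfile,
                         bias: GCBiasSpec, fragment_length: int, n: int,
                         specs: Sequence[RearrangementSpec],
                         seed: int) -> FragmentSet:
    """Simulate a mixture in which each spec defines an independent subpopulation.

    A Binomial share of the ``n`` fragments is drawn from each rearranged
    molecule and mapped back to reference coordinates; fragments crossing a
    breakpoint become two-block chimeras encoding the junction, and excised
    intervals contribute no bases from the carrier subpopulation.  With an
    empty spec list (or all fractions zero) the output is exactly
    :func:`simulate_fragments` under the same seed.
    """
    specs = [s for s in specs if s.subpopulation_fraction > 0]
    if not specs:
        return simulate_fragments(genome, profile, bias, fragment_length, n, seed)
    L = genome.length
    fracs = [s.subpopulation_fraction for s in specs]
    if sum(fracs) > 1.0:
        raise ConfigurationError("subpopulation fractions sum to > 1")
    for s in specs:
        if s.breakpoint_b > L:
            raise ConfigurationError(f"breakpoint {s.breakpoint_b} beyond genome end {L}")
        if s.breakpoint_a < fragment_length or s.breakpoint_b > L - fragment_length:
            raise ConfigurationError(
                "breakpoints must be at least one fragment length away from the "
                "coordinate origin"
            )
        if s.breakpoint_b - s.breakpoint_a <= fragment_length:
            raise ConfigurationError("rearranged segment shorter than a fragment")
    rng = np.random.default_rng(seed)
    # f is a genome (cell) fraction; sequencing samples DNA mass, so each
    # subpopulation's share of fragments is weighted by its molecule length
    # (an excised molecule is shorter and yields proportionally fewer reads).
    lengths = [L if s.kind == "inversion" else L - (s.breakpoint_b - s.breakpoint_a)
               for s in specs]
    shares = np.array([f * lr for f, lr in zip(fracs, lengths)]
                      + [(1.0 - sum(fracs)) * L])
    counts = rng.multinomial(n, shares / shares.sum())
    parts = []
    if counts[-1] > 0:
        parts.append(simulate_fragments(genome, profile, bias, fragment_length,
                                        int(counts[-1]),
                                        int(rng.integers(2**31))))
    for spec, ni in zip(specs, counts[:-1]):
        if ni == 0:
            continue
        w = _rearranged_weights(genome, profile, bias, spec, fragment_length)
        starts = _sample_starts(w, int(ni), rng)
        a, b = spec.breakpoint_a, spec.breakpoint_b
        if spec.kind == "inversion":
            parts.append(_map_inversion_fragments(genome.id, starts,
                                                  fragment_length, L, a, b, rng))
        else:
            parts.append(_map_excision_fragments(genome.id, starts,
                                                 fragment_length, L, a, b, rng))
    return FragmentSet.concat(parts)


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------

def write_fixture_set(config: SimulationConfig, outdir) -> dict:
    """Materialise a complete two-condition fixture.

    Writes ``genome.fasta``, ``exponential.bed`` (replication profile plus any
    rearranged subpopulations), ``stationary.bed`` (flat profile, same bias
    and sampling depth), ``truth.json`` and ``config.json``.  Returns the
    path dict.  Byte-identical under a repeated seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    profile = copy_number_profile(config.genome_length, config.mode,
                                  config.origins, config.fork_amplitude)
    flat = copy_number_profile(config.genome_length, "random")
    seeds = config.child_seeds(4)
    exp_frags = apply_rearrangements(genome, profile, config.bias,
                                     config.fragment_length, config.n_fragments,
                                     config.rearrangements, int(seeds[1]))
    stat_frags = simulate_fragments(genome, flat, config.bias,
                                    config.fragment_length, config.n_fragments,
                                    int(seeds[2]))
    paths = {
        "genome": outdir / "genome.fasta",
        "exponential": outdir / "exponential.bed",
        "stationary": outdir / "stationary.bed",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    write_fasta(genome, paths["genome"])
    exp_frags.to_bed(paths["exponential"])
    stat_frags.to_bed(paths["stationary"])
    truth = {
        "mode": config.mode,
        "origins": list(config.origins) if config.mode != "random" else [],
        "fork_amplitude": config.fork_amplitude,
        "rearrangements": [
            {"kind": s.kind, "breakpoint_a": s.breakpoint_a,
             "breakpoint_b": s.breakpoint_b,
             "subpopulation_fraction": s.subpopulation_fraction}
            for s in config.rearrangements
        ],
        "mean_depth": config.mean_depth,
        "genome_length": config.genome_length,
        "seed": config.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    cfg = dataclasses.asdict(config)
    cfg["bias"] = config.bias.description
    cfg["gc_blocks"] = [list(map(float, blk)) for blk in config.gc_blocks]
    cfg["origins"] = [int(o) for o in config.origins]
    cfg["rearrangements"] = truth["rearrangements"]
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
    return paths
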