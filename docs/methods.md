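# Methods

`mfakit` implements marker-frequency analysis (MFA) for a single circular
replicon, together with a read-sampling simulator that generates every input
the analysis consumes. This note records the model, the parameter choices,
the numerical decisions, and the limits of what the simulations demonstrate.

## Marker-frequency model

In a steadily growing population replicating from a defined origin, the
expected relative copy number of a locus decays exponentially with its
distance from the origin: on each replichore

    log2 n(d) = k · (1 − d / (L/2)),

where `d` is the circular distance to the origin, `L` the genome length and
`k` the log2 copy-number span per replichore, so the origin:terminus ratio
is `2^k`. This log2-linear ("triangle") profile is the standard steady-state
expectation for bidirectional theta replication at constant fork speed. With
`m` origins the per-position expectation is the maximum over the per-origin
gradients (each origin supplies its nearest replichore), which gives a
sawtooth with log2 relief `k/m` — an important consequence: the more origins
are active, the *shallower* each peak becomes, so multi-origin detection
needs a threshold scaled to `k/m`, not a fixed one.

Replication initiated at many dispersed sites (recombination-driven
initiation) and stationary-phase DNA both yield a flat profile; the MFA
signal for "no defined origin" is the *absence* of structure in the
exponential/stationary ratio, and the pipeline's corresponding output is an
empty origin-call list plus a gradient-template fit with amplitude ≈ 0.

## Pipeline

1. **Windowed coverage.** The genome is binned into 1 kb windows advancing
   by 500 bp (half-overlapping). Window coverage is the number of aligned
   fragment bases overlapping the window, accumulated per base; chimeric
   fragments contribute each block. Windows wrap across the arbitrary
   coordinate origin of the circular chromosome so every window has uniform
   width (`ceil(L/S)` windows in total); this avoids edge artifacts at
   position 0. Coverage is exact integer arithmetic and is tested against an
   independent brute-force per-base oracle.
2. **GC-bias correction (per sample).** Windows are binned by GC fraction
   (bin width 0.01), bin mean coverages are smoothed by Lowess against bin
   centre (span 0.3), and each window's coverage is multiplied by
   `global_mean / fitted(GC)`. Bin width and span are conventional defaults
   exposed in the configuration; with ~0.01-wide bins a 2 Mb genome yields
   hundreds of windows per occupied bin, and span 0.3 keeps the fit smooth
   across sparsely occupied extreme-GC bins. Windows whose GC bin holds no
   data receive a value interpolated linearly between neighbouring bins
   (clamped at the observed range) and are flagged; interpolation was chosen
   over nearest-bin lookup because it is continuous in GC, in the same
   spirit as the Lowess smooth. The correction preserves the global mean by
   construction up to binning effects (observed ≤ 0.2% on simulations).
3. **Ratio track.** Corrected coverages of the exponential and stationary
   samples are scaled to the mean of the two library totals, a pseudocount
   of 1 base is added, and the per-window statistic is
   `log2(exp) − log2(stat)` — computed as a difference of logarithms so that
   exchanging the samples negates every value bitwise-exactly. Windows whose
   scaled stationary coverage falls below 0.1× the stationary mean are
   masked (a near-empty denominator carries no information and would
   otherwise explode). The track is re-centred so the unmasked median is 0.
4. **Smoothing.** Centred circular sliding mean; a window is masked when
   more than half its span is masked. The *display* default is a span of
   3 windows, mirroring the classical figure style of a 500 bp sliding
   average over 1 kb bins. Origin-*recovery* runs use a span of 21 windows
   (10.5 kb); see "Noise model" below for why.
5. **Origin calling.** Maximal runs of smoothed windows at or above a log2
   threshold (default 0.15), with sub-threshold gaps shorter than the
   smoothing span merged (so sampling noise cannot split one broad peak),
   and runs shorter than 5 windows discarded. Each call reports its
   interval, height, the maximal window, and a peak position refined as the
   excess-weighted centroid of the run. When a single origin is the
   hypothesis, `fit_gradient_origin` additionally cross-correlates the whole
   unmasked track with the circular triangle template over all shifts (via
   FFT, with parabolic sub-window interpolation); this matched filter is the
   least-squares position estimate and is used for localisation in the
   recovery studies. The default threshold 0.15 is 0.3× the recentred
   amplitude (k/2) of a k = 1 single-origin profile; detection-power studies
   scale it as `0.3 · k / (2m)` for `m` origins for the reason given above.
6. **Rearrangement detection.** Two-block fragments are classified by
   geometry: opposite-strand blocks are inversion junctions (head-to-head
   `(+,−)` pairs join both block *ends* at the breakpoints; tail-to-tail
   `(−,+)` pairs join both block *starts*), same-strand blocks separated by
   a gap are excision junctions, and same-strand pairs touching coordinates
   0 and L are circular wrap splits, not junctions. Junctions are clustered
   when both breakpoints agree within 300 bp (2× fragment length); clusters
   below 3 supporting fragments are dropped. The subpopulation fraction is
   estimated as

       f̂ = J_joint / (J_joint + C_bp),

   with `J_joint` the junction count per novel joint (2 joints for an
   inversion, 1 for an excision) and `C_bp` the mean count of collinear
   fragments spanning a breakpoint. The per-joint normalisation matters:
   an excision presents one joint against two reference breakpoints, and
   the naive pooled ratio would estimate `f/(2−f)` instead of `f`. For
   excisions an independent coverage-based estimate, the relative dip of
   corrected coverage inside the deleted interval versus equal-width
   flanks, is reported alongside; the two agree on simulations (both
   ≈ 0.097 at true f = 0.10, 300×).

## Synthetic data

The simulator emulates: (a) fragment start positions drawn with probability
proportional to the copy-number profile at the start times a GC-dependent
sampling weight of the fragment sequence; (b) genomes as independent draws
per position with per-block GC targets; (c) subpopulations carrying an
inversion or excision, whose fragments are sampled on the rearranged
molecule and mapped back to reference coordinates — fragments crossing a
breakpoint become two-block chimeras, excised intervals contribute nothing;
(d) circular wrap-around, emitted as split collinear blocks. Fragments are
fixed-length (150 bp, the common short-read length), single-end; one master
seed deterministically derives all per-stage seeds, and identical
configurations reproduce outputs byte-for-byte.

Subpopulation fractions are *genome* fractions: each subpopulation's share
of fragments is weighted by its molecule length, as DNA-mass sampling
dictates. This makes both f̂ and the dip estimate unbiased for f; mixing by
raw fragment fraction would inflate f̂ for excisions by the length ratio.

Not modelled: base-call errors and quality scores, adapter content,
paired-end insert geometry (junction evidence is carried by split blocks
rather than discordant pairs), mappability, duplicates, multi-replicon
cells. Consequently, passing tests demonstrate the *statistical* behaviour
of the estimators under sampling noise, not robustness to alignment
artifacts or library chemistry; on real data the upstream aligner's block
coordinates stand where the simulator's exact breakpoints stand here, so
real breakpoint uncertainty is larger than the simulated ~0 bp.

The simulator leaves `k` free: the growth-rate-dependent origin:terminus
ratio of the organism is not pinned by any measurement we rely on, and all
recovery studies state the `k` they assume (default 1, i.e. a 2-fold
gradient, typical of moderately fast-growing prokaryotes).

## Noise model and the limits of origin localisation

At depth `c` with fragment length `ℓ`, window coverage is a compound-Poisson
sum over ~`c·(W+ℓ)/ℓ` fragments, not `c·W` independent bases; for W = 1 kb,
ℓ = 150, c = 100× this gives a relative SD of ≈ 3.8% per window (measured
0.079 in log2-ratio units, matching the calculation) — roughly twelve times
the per-base-independent figure. Propagating this through the k = 1
triangle, the Fisher information of the fragment-start likelihood bounds any
unbiased origin-position estimate at SD ≳ 0.9 kb (exponential track alone;
≈ 1.2 kb through the ratio) for L = 1 Mb at 100×. The matched filter
attains essentially this bound (measured median |error| ≈ 1.2 kb), so
sub-kilobase origin localisation at these conditions is information-
theoretically out of reach — it requires deeper coverage (the bound scales
as `1/√c`), not a better estimator. With `m` origins the per-origin
information is `m`-fold smaller (SD ≈ 2 kb at m = 5), which is why the
five-origin study reports near-zero power at a ±1 kb tolerance while
detecting all five peaks reliably at a quarter-spacing tolerance. The wide
(21-window) smoothing span for recovery runs follows from the same numbers:
localising a gradient apex whose slope is 10⁻³ log2-units per window under
0.08-unit noise requires averaging over ≥ 10 kb before run/threshold logic
is meaningful.

These constraints cut the other way for the biological question the method
answers: at several-thousand-fold coverage, even a shallow single-origin
gradient would tower over sampling noise, so a flat observed track is strong
evidence against a defined origin rather than a power failure.

## Degenerate inputs and tie-breaking

Empty fragment sets give all-zero coverage; a window scheme wider than the
genome, non-positive steps, GC targets outside (0,1), origins outside
[0, L), negative `k`, and breakpoint pairs with `a ≥ b` are configuration
errors. Windows with G+C = 0 have skew 0 by convention. `N` bases count as
neither G nor C but stay in the GC denominator; characters outside
{A,C,G,T,N} are rejected at genome load. Origin calls are ordered by height
then leftmost position; a track entirely above threshold yields one
genome-spanning call. Fewer than 3 occupied GC bins make the bias model
unidentifiable and raise rather than silently fitting a line through noise.

## Reproducibility

Every stochastic operation takes an explicit seed; studies derive
per-replicate seeds from one master seed via `numpy.random.SeedSequence`.
`scripts/acceptance.py --seed N --out results/acceptance.json` re-runs the
whole battery (20 replicates per study) in about a minute and writes every
measured rate; the pipeline emits a machine-readable run summary with
package version, all parameters, and SHA-256 checksums of its inputs.
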