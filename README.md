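# mfakit

Marker-frequency analysis (MFA) of circular microbial genomes from
whole-genome sequencing coverage: windowed read-depth and GC profiles,
Lowess GC-bias correction, log2 exponential/stationary replication tracks
with origin peak calling, cumulative GC-skew origin prediction, and
detection of large inversions and excisions carried by subpopulations of
cells — plus a read-sampling simulator so the entire pipeline is testable
and benchmarkable without external sequencing data.

It is written for microbiologists and bioinformaticians asking *where does
this chromosome initiate replication, and does it initiate at a defined
origin at all?* — the question raised by archaea such as *Thermococcus
kodakarensis*, whose flat MFA profiles suggest recombination-driven
initiation at many dispersed sites rather than a single oriC, in contrast
to the clear origin peaks of organisms like *E. coli* or *Pyrococcus
furiosus*.

## The statistic

In a steadily growing culture replicating from an origin, loci near the
origin are present in more copies than loci near the terminus. For a
circular chromosome of length *L* with one origin and fork amplitude *k*,
the expected relative copy number at circular distance *d* from the origin
is

    log2 n(d) = k (1 − d / (L/2)),        ori:ter ratio = 2^k ,

and with *m* evenly spaced origins the profile is the maximum of the
per-origin gradients (log2 relief *k/m*). The pipeline measures this as the
per-window statistic

    MFA(w) = log2 [ ĉ_exp(w) / ĉ_stat(w) ] ,

where ĉ are GC-corrected, library-size-scaled coverages (bases overlapping
each 1 kb window, sliding by 500 bp) in exponential-phase versus
stationary-phase DNA, median-centred at 0. An origin appears as a peak, the
terminus as a trough, and dispersed (recombination-driven) initiation as a
flat line. Subpopulation rearrangements surface independently as chimeric
junction fragments whose two aligned blocks flank the breakpoints; the
affected cell fraction is estimated from junction versus breakpoint-spanning
read counts, cross-checked by the coverage dip for excisions.

## Worked example

Simulate a 1 Mb genome replicating from a single origin at 300 kb
(k = 1, 100× depth) with a matching flat stationary-phase control, then run
the full pipeline:

```
$ mfakit simulate -L 1000000 --depth 100 --origins 300000 -k 1 --seed 7 -o fx
$ mfakit all --genome fx/genome.fasta --exponential fx/exponential.bed \
             --stationary fx/stationary.bed --outdir out --span 21
mfakit INFO exponential: 666667 fragments, mean coverage 100.0x, GC model on 11 bins
mfakit INFO stationary: 666667 fragments, mean coverage 100.0x, GC model on 11 bins
mfakit INFO origin calls: 1 (gradient fit: pos=302778 amp=1.001 r=0.966)
```

`out/run_summary.json` then holds one origin call — peak 300,278 bp, height
+0.517 log2 units, width 369.5 kb — and the gradient-template fit localises
the origin at 302,778 bp with amplitude 1.001 (the true k was 1.0; the
~2.8 kb position error is at the scale sampling noise dictates for 100×
coverage). The call height ≈ +0.5 is exactly what a k = 1 gradient predicts
after median centring: the origin sits k/2 above the genome median.
Re-running the same simulation in `random` initiation mode yields zero
origin calls and a fitted amplitude ≈ 0 — the flat-profile signature.

`out/` also contains the per-sample coverage TSVs, the fitted GC-bias
models, the MFA track (TSV + bedGraph), rearrangement calls with junction
BEDPE, and figure-style plots of the track and cumulative GC skew.

The packaged transcription of the KOD1-vs-TS559 genome difference table is
summarised with:

```
$ mfakit variants-summary
{
  "total": 35,
  "substitutions": 24,
  "deletions": 5,
  "insertions": 6,
  "coding": 31,
  "intergenic": 4,
  "missense": 20,
  "frameshift": 8,
  "no_change": 3
}
```

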