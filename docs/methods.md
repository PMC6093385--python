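# Methods

## The measurement problem

In dry, quiescent seeds, stored mRNA cannot be repaired or turned over; it
slowly fragments over years to decades of storage, and the extent of
fragmentation is a candidate marker of sub-lethal aging.  Whole-molecule cDNA
sequencing makes fragmentation visible as a coverage asymmetry: with poly(A)
selection and oligo(dT)-primed strand-switching cDNA synthesis, only the
fragment of a broken molecule that retains the poly(A) tail is converted to a
read, so per-base read depth along a degraded transcript rises from the 5' to
the 3' end.  `seedrd` turns that asymmetry into per-transcript statistics and
provides a generative model to test the whole analysis chain.

## The fission model

Each of the L−1 backbone bonds of a transcript of length L breaks
independently with per-bond probability λ (dimensionless; realistic values
are 10⁻⁴–10⁻³ breaks·bond⁻¹).  Two cohorts share an early-degradation rate
`lambda_early` and the aged cohort adds `lambda_aging`, i.e. breaks
accumulate additively with storage.  Spike-in control transcripts are exempt
(λ = 0) by construction.

Under oligo(dT)/poly(A) chemistry the captured read is the 3'-terminal
fragment `[b_last+1, L]`, where `b_last` is the 3'-most broken bond.  The
probability that a captured molecule still covers position x is

    P(cover x) = (1 − λ)^(L − x),

which is the package's closed-form oracle: simulated coverage must match it
within binomial error, and a log-linear regression of depth on (L − x) over
the central window recovers λ (`seedrd.simulate.estimate_lambda`).  Sampling
exploits the same structure: the distance from the 3' end to the first broken
bond is geometric, so reads are drawn in O(1) per molecule, and the
molecule's total break count is reconstructed from the exact conditional
1 + Binomial(start − 2, λ).  Random-hexamer/total-RNA chemistry instead
captures one fragment per molecule with probability proportional to fragment
length, yielding near-uniform coverage.

Per-transcript molecule counts are log-uniform over two decades by default —
the real libraries' abundance distribution is unknown, and a heavy-tailed
choice exercises the depth filter realistically.  Optional depth noise is
Poisson resampling of the expected depth, with an optional homopolymer-dip
variant that multiplies a random fraction of positions (default 1%) by a
constant (default 0.3) before resampling, mimicking basecaller dropouts at
homopolymer stretches.  Noise is off by default so the closed-form oracles
hold exactly.

## Depth, normalization, smoothing

Depth is computed from primary alignments only (one molecule, one read) or
read from samtools-depth-style TSV, with missing positions zero-filled;
coordinates are 1-based and closed throughout.  Each sample's profile is
scaled so its maximum over the *full* transcript is 100, and replicate
profiles are averaged per cohort afterwards.  Normalize-then-average (rather
than averaging raw depths) equalizes library-size differences between
replicates; it is the package's default and the order is fixed, not
configurable per run, to keep outputs comparable.  The 100-bp centered moving
average (truncated at the ends; for even widths the window extends one
position further 3') is for display only and never feeds RD.

## RD statistics

With the cohort-mean normalized profiles d̄_ref and d̄_aged and the analysis
window W = [⌈0.25 L⌉, ⌊0.75 L⌋] (transcript ends excluded as unreliable):

    RD_ref   = Σ_{b∈W} (100 − d̄_ref(b))           / (L·100)
    RD_delta = Σ_{b∈W} (d̄_ref(b) − d̄_aged(b))     / (L·100)

The denominator uses the full length L although the sum spans roughly half
the positions, so the attainable maximum is ≈ 0.5 (exactly (|W|)/L ≤ 0.5 +
1/L).  This convention is what makes the region-C cut RD_ref > 0.4
reachable.  RD_delta is antisymmetric under swapping the cohorts and can be
slightly negative.  Both statistics are exactly invariant to scaling any
sample's raw depths by a positive constant.

## Region classification

Regions are rectangles in the (RD_delta, RD_ref) plane, all inequalities
strict:

| region | RD_delta | RD_ref | reading |
|---|---|---|---|
| A  | −0.028 < δ < 0.02 | 0.06 < r < 0.12 | intact in both cohorts (spike-in box) |
| A′ | δ < 0.1 | r < 0.2 | intact-ish superset of A |
| B  | δ > 0.15 | r < 0.2 | degraded only during storage |
| C  | δ > 0.15 | r > 0.4 | early and progressive degradation |
| D  | δ < 0.1 | r > 0.4 | early degradation, then stable |

A′/B/C/D are pairwise disjoint; A ⊂ A′ and takes precedence as the primary
label; the deliberate gaps between regions (e.g. 0.1 ≤ δ ≤ 0.15) are
"unclassified".  The A box may be re-derived from spike-in controls as the
min/max of their RD values.  Because the inequalities are strict, the literal
min/max box excludes its own defining extremes — and in a noise-free
simulation every spike-in sits exactly at (0, 0), collapsing the box to a
point.  `derive_spikein_bounds` therefore widens the box by a pad
(default 10⁻⁹, i.e. infinitesimal) so the controls satisfy their own box;
`pad=0` gives the literal min/max.

## Curation cascade

Three stages, in order, each emitting a per-transcript report: presence
(≥1 read in every sample), coverage (mean reference-cohort covered fraction
strictly > 0.75; configurable to require every replicate), depth (some base
with raw depth ≥ 20 in every sample; configurable to pooled depth).  The
">" at the coverage boundary and the per-sample reading of the depth rule
are the defaults; survivor sets are nested by construction.  No dedicated
length cutoff exists — very long, poorly covered transcripts fall to the
coverage stage naturally.

## qPCR ΔCt assay

ΔCt = Ct(3' amplicon) − Ct(5' amplicon); technical replicates are averaged
within a biological replicate first, then mean ± SD is taken across
biological replicates, with Welch's t-test comparing cohorts.  Primer
efficiency comes from a 2× dilution series: slope m of Ct on log₂(input)
gives E = 2^(−1/m), accepted in the 1.93–2.13 band.  Under the fission model
a cDNA amplifies an amplicon iff its span covers the amplicon entirely, so
3'-anchored libraries (poly(A) selection and/or oligo(dT) priming) obey

    ΔCt = (s₃ − s₅) · ln(1 − λ) / ln E ≤ 0,

while the random-hexamer/total library's template depends only on the
amplicon staying unbroken — equal-length end amplicons give a cohort
difference of zero.  The hexamer template model ignores where within a
fragment priming starts (downstream priming availability is absorbed into
the free Ct intercept); for end amplicons the residual position effects are
symmetric and cancel in ΔCt, which the Monte-Carlo consistency check
(closed form vs simulated molecules, within 0.1 cycles at 10⁵ molecules)
confirms.

## Problem sizes and numerical choices

The bundled studies use sizes chosen to make the statistical checks sharp on
one CPU: 10⁴ reads for closed-form coverage checks (3 break rates × 3
seeds, 10-point grids compared at 3 binomial SE; λ recovered within 10%);
a stratification study of 300 transcripts (log-uniform lengths 300–7000 bp,
λ_early = 2×10⁻⁴, λ_aging = 1.5×10⁻³, 2 cohorts × 5 replicates, 30 000
reads/sample, 8 spike-ins); 10⁵ molecules for qPCR contrasts.  Brute-force
RD oracles run on 200 random small matrices (L ∈ [8, 200]) and agree with
the pipeline to 10⁻¹².  All randomness flows from explicit seeds through
`numpy.random.default_rng`; repeated pipeline runs are byte-identical, and
output floats are formatted with fixed precision to keep files stable.

Degenerate inputs are errors, not silent defaults: all-zero profiles
(undefined normalization; excluded upstream by the presence filter),
transcripts shorter than the window supports (L = 1), empty transcript
sets, unsupported priming/selection combinations, out-of-range positions.

## What the simulator does and does not emulate

It reproduces: 3'-anchored coverage bias and its dependence on λ and L, the
additive young/aged rate structure, intact spike-ins, abundance-driven
presence/depth filtering, Poisson depth noise with homopolymer dips, and the
library-chemistry contrast in ΔCt.  It does not model: nucleotide-level
basecalling errors, adapters or chimeric reads, base oxidation, alternative
splicing (so region D — early-degraded or splice-like profiles in real data
— is reachable only via the unclassified gaps in simulations at realistic
rates), or transcript-to-transcript variation in the early degradation
rate.  That last omission matters for interpretation: with one shared
λ_early, RD_ref is an almost deterministic smooth function of length
(R² ≈ 0.98 in the stratification study), whereas in real seed data early
degradation is idiosyncratic and length predicts RD_delta far better than
RD_ref.  Passing tests therefore validate the statistics and the machinery,
not the biological variance structure of real libraries.

## Known limitations

- RD_delta compares independently normalized cohort means; no depth matching
  between cohorts is attempted, so extreme library-size imbalance shows up
  only through sampling noise.
- The through-origin regression reports the centered R² (spreadsheet
  convention; can be negative); an uncentered variant is available.
- GC is computed from the reference sequence, counting ambiguity codes in
  the denominator only.
- The qPCR intercept is a free per-amplicon constant; absolute Ct values are
  not meaningful, only differences.
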