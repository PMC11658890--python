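# Methods

## Depletion-assay model

The library fragment is modelled as a fixed 206-nt amplicon:
a 182-nt 5′ constant region (a 98-nt adapter-side segment, filler, a 22-nt
protospacer, and the fixed TTTT of the PAM cassette), the 4-nt randomized
window, and a 20-nt 3′ constant region. The randomized positions are
labelled −5, −6, −7, −8 in the 5′→3′ direction, so the consensus strings
produced here (CWAA, CNNN) are the variable half of the full 8-nt cassette
5′-TTTTNNNN-3′. The exact internal layout of the constant regions is a
package choice — published fragment designs constrain the total length and
the 3′ flank but not every internal coordinate — and extraction depends only
on the anchor sequences, which are validated for uniqueness (both strands)
when a design is loaded.

**Extraction.** Each read and its reverse complement are scanned for
`upstream_anchor + N{4} + downstream_anchor` with exact anchor matching
(anchor length 12 by default, configurable). A read is counted only if
exactly one site is found across both orientations and the tetramer is
unambiguous; everything else (no site, multiple sites, N in the window)
increments the total-read denominator only. Exact matching mirrors plain
pattern-matching extraction; with error-free synthetic reads it is lossless,
and with real reads it is conservative (mismatched anchors drop reads, never
miscount them).

**Frequencies and fold-change.** Frequencies are computed over matched reads
with an additive pseudocount a (default 1):
f(p) = (n_p + a) / (N + a·256). The pseudocount keeps fully depleted PAMs at
a finite frequency so log₂FC = log₂(f_sample/f_untreated) is defined; at the
read depths the assay uses (≥10⁴ matched reads, ~40+ reads per PAM) its
effect on non-depleted PAMs is negligible.

**Significance threshold.** The published rule — depletion beyond a
99.9999% confidence interval of the non-targeting controls — is realized as
a one-sided Gaussian quantile on the pooled control log₂FC values:
threshold = m − z·s with z = Φ⁻¹(0.999999) ≈ 4.7534, and threshold = m when
s = 0. Pooling all control values (rather than per-sample maxima) was chosen
because it uses every control observation and has a closed form; an
empirical alternative (threshold = minimum observed control log₂FC) is
available via `threshold_method="empirical_min"`. Significance is strict
(log₂FC < threshold), so a degenerate all-zero null yields no calls.

**Logo and consensus.** Over the significant set, each position's base
frequencies are unweighted shares (optionally weighted by −log₂FC via
`weight_by_depletion`), and the information content is 2 + Σ_b f_b log₂ f_b
bits (0·log 0 ≡ 0), uncorrected for small samples — the set summarized is a
motif list, not a sampled alignment. The IUPAC consensus takes, per
position, all bases with frequency ≥ 0.25 (the uniform background; a base at
or above background is evidence of inclusion) and maps the base set to its
ambiguity code. Both the inclusion fraction and the confidence are exposed
as parameters.

## Kinetic models

Cleavage: Y = Ymax·(1 − e^(−kt)), bounds 0 ≤ Ymax ≤ 1, k > 0, fitted by
bounded nonlinear least squares (`scipy.optimize.curve_fit`, trust-region
reflective). 2AP fluorescence: Y = Y₀ + Ymax·(1 − e^(−kt)) with Y₀ fixed to
the mean of the matching blank trace and Ymax ≥ 0. Initialization uses
Ymax₀ = max(Y) − Y₀ and k₀ = 1/t*, t* being the first time the trace crosses
half its amplitude; five additional log-spaced k₀ starts guard against local
minima, and an optimizer failure yields an nd-flagged result rather than an
exception.

**Fitting target.** Cleavage courses are fitted on pooled replicate points
(one fit per condition); for a balanced design this estimates the same curve
as fitting the replicate mean. 2AP traces are fitted per replicate and the
rates averaged (mean ± sample SD, n−1 denominator), matching how triplicate
fluorimetry is conventionally reported. Both modes are available for either
assay via `fit(per_replicate=...)`.

**nd rule.** k_obs is reported as "nd" when the fitted amplitude is at or
below the assay floor — Ymax ≤ 0.05 cleaved fraction, or Ymax ≤ 100 AU for
2AP — with the boundary inclusive. nd replicates are excluded from
aggregates (and annotated); a fold-change involving an nd rate is an error,
not a number. For display, rates are rounded to one significant figure;
full precision is kept in JSON artifacts.

**Units.** Rates carry the course's time unit (min⁻¹ for gels, s⁻¹ for
fluorimetry); converting a course between minutes and seconds rescales the
fitted k by exactly 60, and fold-changes refuse mixed units.

## Synthetic data

The read simulator draws each read's tetramer from a uniform prior over the
256 PAMs reweighted by survival: weight 1 − P(cleave) for targeting samples
(first-matching-rule IUPAC model), weight 1 for untreated and non-targeting
samples, then multinomial sampling of the per-sample read count and a seeded
permutation. Reads are the full 206-nt fragment with constant quality; an
optional uniform substitution rate and reverse-complement fraction (both
default 0) exercise robustness paths. PCR amplification of surviving
fragments is collapsed into the multinomial weights — the analysis consumes
frequencies, for which this is statistically equivalent — and no model of
cleavage kinetics during incubation, bead cleanup, adapters/indices, or
sequencing error is included. Passing tests on these data therefore
demonstrate correctness of the statistics, not robustness to real-library
artifacts such as synthesis bias, PCR jackpots or index hopping.

Curve generators evaluate their model equations exactly at the requested
times (the gel schedule 0, 0.5, 1, 2.5, 5, 10, 30, 60, 120 min; 2AP samples
every 20 s) and add i.i.d. Gaussian noise; cleaved fractions are clipped to
[0, 1]. All generators are deterministic given an integer seed, and FASTQ
output is byte-identical across runs.

## Problem sizes and numerical tolerances

Default study conditions: 10⁵ reads per sample and five samples (one
untreated, three non-targeting, one targeting) for planted-signal recovery;
the 20-seed false-positive control runs at 2×10⁴ reads per sample, a depth
(~78 expected reads per PAM) at which the control-derived null spread is
already well estimated. The repeated-seed recovery property is exercised at
10 seeds. Noiseless round-trip fits are checked to 10⁻⁴ relative error;
estimator quality uses 100 noisy draws (noise SD 0.02, 3 replicates) with a
10% median-relative-error criterion on k. Frequency normalization is checked
to 10⁻⁹.

## Known limitations

- Exact anchor matching discards reads with sequencing errors inside the
  anchors; a mismatch-tolerant extractor is out of scope.
- The Gaussian null is a modelling choice; heavy-tailed control noise would
  argue for the empirical rule instead.
- Single-exponential fits only; biphasic progress curves are not modelled,
  and gel densitometry itself (band quantification) is upstream of this
  package.
- The significance rule assumes non-targeting log₂FC values are exchangeable
  across PAMs; composition-dependent amplification bias would violate this
  and is not modelled.
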