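# casassay

Analysis of two families of in-vitro Cas9 assays, built for biochemists
characterizing engineered Cas9 variants (here, the thermostable GeoCas9 and
its evolved derivative iGeoCas9):

1. **Randomized-PAM depletion profiling.** A plasmid library carries a PAM
   cassette 5′-TTTTNNNN-3′ on the non-target strand, with the four randomized
   positions labelled −5…−8 in the 5′→3′ direction. Incubation with a Cas9
   ribonucleoprotein cleaves the library members whose PAM the enzyme
   recognizes, so those PAMs are depleted from the subsequently amplified and
   sequenced pool. The package extracts the tetramers from amplicon FASTQ,
   normalizes to sequencing depth, computes per-PAM log₂ fold-changes against
   the untreated library,

   log₂FC(p) = log₂ [ f_sample(p) / f_untreated(p) ],

   derives a significance threshold from non-targeting-guide controls
   (Gaussian rule: threshold = m − z·s over the pooled control log₂FC values,
   z ≈ 4.7534 at the default one-sided 99.9999% confidence), and summarizes
   the significantly depleted PAMs as a position frequency/information
   matrix and an IUPAC consensus (e.g. CWAA, CNNN).

2. **Single-exponential kinetics.** Cleavage time courses (gel densitometry,
   cleaved fraction Y ∈ [0,1]) are fitted to Y = Ymax·(1 − e^(−k·t)); 2-aminopurine
   (2AP) fluorescence traces reporting R-loop formation are fitted to
   Y = Y₀ + Ymax·(1 − e^(−k·t)) with Y₀ fixed to the mean of a blank trace.
   k is the observed first-order rate constant k_obs. A fit whose amplitude
   is at or below the assay floor (Ymax ≤ 0.05 cleaved fraction; Ymax ≤ 100 AU)
   is flagged **nd** (not determined). Replicates are averaged as mean ± sample
   SD, and rate ratios between conditions are reported as fold-changes.

A seeded synthetic-data module emulates both assays — multinomial read
sampling from a 206-nt library fragment under a configurable IUPAC
recognition model, and exponential curves with Gaussian noise — so the whole
pipeline is testable without any sequencing download.

## Worked example

Simulate a depletion experiment in which every CWAA-matching PAM (CAAA and
CTAA) is fully cleaved, then analyze it:

```bash
casassay simulate pam-library --rule CWAA:1.0 --reads-per-sample 100000 \
    --seed 7 --out sim
casassay pam run --samples sim/samples.tsv --out pamrun
```

prints

```json
{
  "targeting": {
    "consensus": "CWAA",
    "n_significant": 2,
    "significant": ["CAAA", "CTAA"]
  }
}
```

i.e. exactly the two planted PAMs fall below the control-derived log₂FC
threshold, and their IUPAC consensus is the planted pattern CWAA (read as
5′-N₄CWAA-3′ on the full 8-nt cassette). Fitting two noiseless cleavage
courses generated at 0.2 min⁻¹ and 0.04 min⁻¹ — the wild-type enzyme's rates
on a mismatched versus linear suboptimal-PAM substrate —

```bash
casassay kin run --timecourse both.tsv --fold mismatched/linear --out kinrun
```

recovers both rates and their ratio:

```json
{
  "fold_changes": {"mismatched/linear": 4.999999999999954},
  "linear":     {"mean_k_obs": 0.04000000000000099, "n": 1, ...},
  "mismatched": {"mean_k_obs": 0.20000000000000312, "n": 1, ...}
}
```

a 5-fold rate increase from destabilizing the duplex next to the PAM. The
same operations are available as library calls (`PamDepletionModel(...).fit()`,
`ExponentialKineticsModel(course).fit()`, `fold_change(a, b)`); see
`docs/methods.md` for the statistical details.

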