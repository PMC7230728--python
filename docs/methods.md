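# Methods

## Markov odds and the avoidance model

The central statistic is the maximal-order Markov odds ratio of a word
*w* of length *k*:

    odds(w) = obs(w) / E(w),
    E(w) = N_k · f(prefix_{k-1}) · f(suffix_{k-1}) / f(core_{k-2})

with frequencies taken from the genome's own overlapping window counts
at k−1 and k−2 and N_k the number of valid k-windows. This is the
standard null for oligonucleotide relative-abundance studies: it
conditions on all (k−1)-mer composition, so residual departures isolate
genuinely k-mer-specific selection rather than base or sub-word bias.
The equivalent relative-abundance form is
ρ\*(w) = f(w)·f(core)/(f(prefix)·f(suffix)). A zero-order null
(product of base frequencies) is provided for comparison; on real
genomes it conflates dinucleotide bias with avoidance and is not the
default.

Counting conventions:

* Overlapping windows, forward strand only. Every motif of interest is
  a reverse-complement palindrome, for which forward counting is
  strand-symmetric; `count_ambiguous_motif(..., both_strands=True)`
  symmetrizes non-palindromic motifs explicitly.
* Windows containing N are skipped, never imputed. IUPAC ambiguity
  codes on input are retained as N; a sequence N matches no motif
  position.
* Circular records contribute their k−1 wrap-around windows, so
  re-opened provirus circles and linear virions are both well defined.
* Linear virion genomes carry their terminal repeat twice and are
  counted as deposited, with no masking.

Classification: observed = 0 → **absent**; odds < 0.78 with a non-zero
count → **under-represented**; otherwise **normal**. The 0.78 cut is
the conventional significance boundary for tetramer relative abundance
and is configurable. Odds are reported to two decimals.

The model surface follows the fitted-model idiom: `MotifAvoidance`
holds the data (one or more genomes) and design (motif list or
palindrome census at even k, null model, exclusion sub-motifs);
`fit()` computes the count tables once per genome and returns
`AvoidanceResults` with the long-form table, an odds matrix,
`absent_in_all`, and `summary()`. In census mode, a candidate whose
core word is itself absent has an undefined maximal-order expectation;
the census records expected = NaN, odds = 0 and classification
"absent", which is the only well-defined statement in that case.

Sub-motif exclusion (census mode) drops every candidate containing a
listed shorter word, separating genuinely new absent words from trivial
super-motifs of cores that are already absent.

## Terminal direct repeats

`find_tdr` returns the largest L ≤ n/2 with Hamming distance between
`seq[:L]` and `seq[-L:]` at most `max_mismatch`; L below `min_len`
(default 50) is reported as length 0. The exact case uses the KMP
border decomposition (all prefix-suffix lengths in O(n)); the
mismatch-tolerant case computes per-shift match counts with one FFT
autocorrelation per base (O(n log n)), then verifies the selected L by
direct comparison so FFT rounding can never change a reported length.
Exact matching is the default: the deposited genomes carry identical
repeat copies; the tolerance exists for draft assemblies. The L ≤ n/2
cap prevents the two copies from overlapping. N never matches during
the mismatch-tolerant scan (it is absent from all four indicator
vectors).

## CxxC census

The census scans CDS translations for C-x-x-C (exactly two spacer
residues; `spacing` is configurable but non-default spacings are not
part of the census definition). Overlapping matches all count, but the
census counts *proteins* with at least one motif, not motif totals.
Micro-proteins are strictly shorter than 100 aa. The annotated
/translation is used when present; otherwise coordinates are translated
with NCBI table 11 (archaea/bacteria) and the trailing stop trimmed. A
CDS with neither a translation nor clean coordinates (length not a
multiple of 3, or internal stops) is skipped with a warning and
tallied.

## Pairwise identity

Seed-and-chain with defaults k = 14, min_extend_len = 30, X-drop = 20:

1. Exact shared k-mers (k-mers occurring > 50 times in the query are
   dropped as repeats) are merged along diagonals and extended
   ungapped under +1/−1 scoring with an X-drop stop.
2. Both strands of the subject are anchored; the strand with the larger
   total match weight is chained by weighted
   longest-increasing-subsequence (weight = anchor matches, small
   overlaps trimmed at walk time — trimming both coordinates equally
   keeps an ungapped anchor ungapped).
3. Inter-anchor and terminal gaps up to `gap_cap` (5,000 bp) are closed
   by edlib global alignment restricted to an edit-distance band of
   0.2 × gap + 50; larger or band-exceeding gaps contribute
   max(gap_a, gap_b) unaligned, non-identical columns. The band and cap
   bound worst-case work on ~75 kb genomes to desk scale.

Percent identity is identical columns over *all* columns, gap columns
included — the convention used when reading identities off a multiple
alignment. Published identities from external aligners are reproduced
to within a couple of points; the exact treatment of terminal gaps and
long indels differs between aligners, which is why the package never
claims sub-point agreement with them.

## Synthetic genomes

The generator's defaults are the study conditions of an HF1-group
isolate: 74,196 bp linear dsDNA at 57% G+C, order-1 Markov structure,
GATC and CTAG fully avoided, a 306 bp TDR, 126 CDS with 23 CxxC
proteins of which 14 are micro-proteins. Mechanics:

* **Composition.** An order-m transition matrix (m ∈ {0,1,2}) gets
  genuine context dependence from log-normal jitter (σ = 0.15 on log
  probabilities); a multiplicative reweighting loop then pins the
  stationary G+C back on target. Realized G+C at 100 kb is within
  ±0.01 of target.
* **Avoidance.** Sampling is left-to-right: any base that would
  complete an avoided word or its reverse complement is removed from
  the proposal and the transition renormalized. Whole-sequence
  rejection has vanishing acceptance at 75 kb; local constraint
  sampling is exact and linear-time. Segments that hit a dead end
  (possible only for dense forbidden sets) are re-emitted, with a
  bounded retry budget and a constructive-failure error beyond it.
* **CDS.** Protein lengths: micro CxxC 40–99 aa, other CxxC
  100–300 aa, remaining CDS 50–300 aa (deposited HF1-group genomes
  average ~500 nt per CDS at ~90% coding density); unlucky draws that
  overshoot the genome are rescaled proportionally rather than
  rejected. Translations use a 19-letter alphabet *without cysteine*;
  CxxC proteins then get exactly one planted C..C pair, so census
  ground truth is exact by construction. Coding sequence is emitted
  codon-by-codon among synonymous table-11 codons that respect the
  avoidance constraints, weighted by exp(λ·GC(codon)) with λ solved by
  bisection so the expected genome-wide G+C matches the target (a
  90%-coding genome would otherwise sit near 50% G+C regardless of the
  intergenic model). All planted CDS are on the plus strand;
  minus-strand parsing and scanning are exercised with hand-written
  fixtures instead.
* **TDR.** The leading `tdr_length` bases are copied over the trailing
  ones. Only windows straddling the copy junction can violate
  avoidance (the copied interior equals the already-clean prefix);
  those are repaired by resampling core-side bases, and a final
  whole-genome assertion guarantees soundness of every emitted genome.
* **Determinism.** One PRNG stream per genome seeded from the spec;
  byte-identical regeneration is tested. The seed and parameters are
  recorded in the record description.

`mutate` applies independent substitutions (uniform over the three
alternative bases) and drops features, since the annotation no longer
describes the sequence.

What the generator does **not** emulate: real codon usage and the
acidic haloarchaeal proteome, tRNA genes and intergenic repeat
elements, overlapping or minus-strand CDS, assembly artifacts, and the
gradual (rather than planted) divergence structure of related genomes.
Passing tests therefore demonstrate correctness of the statistics and
detectors under controlled truth, not robustness to annotation noise in
arbitrary user data.

## Numerical and design choices

* Internal coordinates are 0-based half-open; user-facing reports are
  1-based inclusive (GenBank convention).
* Odds comparisons against printed two-decimal values use ±0.005 after
  rounding, with a documented ±0.02 fallback because the published
  table's exact null order is not stated; both nulls are implemented
  and maximal-order is the default.
* The provirus re-opening offset is an explicit argument of
  `linearize_provirus`, never inferred: the choice of terminus on an
  integrated element is a judgment call the caller must make.
* `frameshift_motif_scan` looks for IUPAC TTTCGN within the final
  30 bp (configurable) of each coding sequence, stop codon excluded,
  on the coding strand only — the slippery-motif geometry of +1
  frameshift candidates.
* Problem sizes in the test-suite simulations (10–100 kb genomes,
  10–20 replicate seeds, 100 planted-TDR instances) were chosen so the
  full property battery completes in well under a minute while keeping
  Monte-Carlo standard errors an order of magnitude below the asserted
  tolerances.

## Known limitations

* The identity measure is anchor-based; for genome pairs below ~50%
  identity, anchors vanish before alignment does, and the reported
  identity degrades to coverage-limited values faster than a full
  aligner's would.
* The maximal-order expectation is undefined for words whose core is
  absent; censuses report such words as absent with NaN expectation
  rather than extrapolating a lower-order null.
* `read_genbank` takes the overall span of compound (join) locations;
  spliced CDS are not reconstructed (halovirus CDS are unspliced).
* The deposited-genome replay (`halomotif.replay`) requires a local
  copy of the seven GenBank records; the library performs no network
  access by design.
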