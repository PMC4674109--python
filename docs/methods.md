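# Methods

This note documents the models, parameter choices and numerical decisions
behind srnapipe, and what the synthetic-data generator does and does not
emulate.

## Read cleaning

A read survives cleaning when (i) the leading `min_adapter_overlap` = 6
bases of the 3' adapter occur in it (leftmost exact match; the insert is
everything upstream), (ii) the insert is 18–30 nt, (iii) it contains no
ambiguous base (`max_n` = 0), and (iv) its mean Phred quality is ≥ 20.
Reads with no adapter hit are dropped rather than kept untrimmed, because
without the adapter boundary the insert length is unknown. Adapter
matching is exact-substring with no mismatch tolerance: this is auditable
and sufficient at the substitution rates the generator produces; real
degraded adapters would need a fuzzy trimmer. All four thresholds are
configurable (`CleanParams`). The rejection tally partitions the rejected
reads by first failing rule, so clean + rejected always equals raw.

## Annotation hierarchy

Each unique tag receives exactly one category by priority:
miRNA > rRNA > tRNA > snRNA > snoRNA > mRNA > unannotated, with
membership defined as exact substring occurrence in the category's
reference sequences. miRNA sits first so that genuine mature miRNAs are
not absorbed by overlapping ncRNA annotations; the order is a parameter.
Conserved-miRNA identification is a separate, more tolerant pass: tags of
18–25 nt are matched to mature references of the same length by Hamming
distance (no indels), default budget 2 mismatches (0–3 configurable),
ties broken toward the lexicographically smallest reference id so
assignment is deterministic. Family names collapse the species prefix and
variant suffix: `cme-miR159a → miR159`.

Category percentages print with half-up rounding at 2 decimals, falling
back to 3 decimals when the 2-decimal form would be 0.00 % or 0.01 %, so
very small categories keep a significant digit.

## Normalization and differential expression

Normalized expression is reads per million of the library's clean-read
total. Two special rules govern low counts:

* a raw count of zero becomes exactly RPM 0.01, keeping log2 fold changes
  finite;
* a gene below RPM 1 in **both** libraries of a comparison is excluded
  from testing. The phrase "expression of the two samples less than 1"
  admits an either-sample reading; the both-samples reading is the
  default because the either-sample rule would discard genes that are
  silent in one library yet clearly expressed in the other — exactly the
  presence/absence changes such studies care about. `exclusion_mode=
  "either"` selects the stricter variant.

The test conditions on the count `x` in one library and asks how
surprising the count `y` in the other is under Poisson tag sampling with
library sizes `N₁`, `N₂`. The conditional law of `y` is negative binomial
with size `x + 1` and success probability `N₁/(N₁+N₂)`; it is evaluated
through log-gamma, lower tails by log-sum-exp over `0..y`, upper tails by
direct log-space summation upward from `y` until terms fall 40 nats below
the running total — never as `1 − CDF`, which would cancel
catastrophically for extreme counts. The implementation agrees with an
exact rational-arithmetic oracle to 10⁻¹⁰ relative error over the full
grid `0 ≤ x, y ≤ 60`.

Two-sidedness: the p-value is `min(1, 2·min(P(Y ≥ y | x), P(X ≥ x | y)))`
with roles and library sizes swapped in the second tail and the observed
point included in both. This symmetrized form makes the two libraries
exchangeable — swapping `(x, N₁)` with `(y, N₂)` leaves the p-value
unchanged — which the naive doubled lower/upper tail of `Y` does not
satisfy at discrete points. One-sided alternatives (`greater`, `less`)
use the plain single tail of `Y` given `x`. The doubled-tail construction
is conservative; under null simulation the empirical false-positive rate
at p < 0.05 stays below 0.05.

Significance needs p < α (default 0.05) **and** |log2FC| ≥ 1.0, computed
on the zero-adjusted normalized values; no multiple-testing correction is
applied by default, matching the raw-threshold convention of unreplicated
tag-count studies.

Three-way overlaps are reported as all seven Venn regions plus the union;
pairwise counts are intersection totals (they include the triple region),
which is how co-expression between two libraries is conventionally
quoted, and the inclusion–exclusion identities are exposed as properties
(`union`, `set_sizes`, `pairwise_only`).

## Target prediction and cleavage mapping

Duplexes are scored with penalties mismatch 1.0, G:U wobble 0.5
(G·T in either orientation on the DNA alphabet), gap 1.0, all doubled at
miRNA positions 2–13 from the 5' end; sites at or below 4.0 are reported.
The constants live in `ScoringScheme` and are deliberately parameters,
not hard-coded values. The scanner scores every miRNA-length window with
a vectorized ungapped pass, then refines near-threshold windows
(ungapped penalty ≤ cutoff + 4) with single-gap variants one base longer
or shorter; a bulged site far from any well-paired ungapped register
would be missed, which is acceptable for the ≤ 1-gap duplexes the scheme
is meant for. Overlapping placements collapse to the local best.

The canonical cleavage position is the transcript base paired with miRNA
position 10 (the standard 10/11 slicing rule), stored 1-based on the
transcript; RACE clone 5' ends are tallied over the duplex span and
reported as a `k/n` label and fraction.

## qPCR

ΔCT = CT_target − CT_reference per well; technical replicates are
averaged into their biological replicate before ΔCTs are averaged across
biological replicates — chosen so that unbalanced technical replication
cannot bias a condition. ΔΔCT subtracts control from treatment and the
relative expression is 2^-ΔΔCT. Concordance with sequencing is ordinary
least squares of qPCR log2 fold change on sequencing log2 fold change;
R² equals the squared Pearson correlation. In the end-to-end pipeline the
concordance set is restricted to miRNAs with at least one read in both
libraries: fold changes resting on the 0.01 zero-adjustment are sequencing
artifacts that a qPCR assay cannot reproduce.

## Synthetic data

The generator emulates the *statistical* shape of a three-library leaf
small-RNA study, not its biology:

* **References.** 60 mature miRNAs (20–22 nt, family-coded names) in 48
  families; 20 fragment-source sequences each for rRNA, tRNA, snRNA and
  snoRNA; 8 transcripts of 300–600 nt, two of which carry planted target
  sites — one perfect complement (score 0) and one built with a core
  mismatch, a core wobble and a 3' wobble (score 3.5 under the default
  scheme); a background pool of 3,000 unannotated siRNA-like tags whose
  length law peaks at 24 nt with a 21-nt shoulder, mimicking the
  heterochromatic-siRNA-dominated profile of plant leaves.
* **Counts.** Per-miRNA counts are Poisson with mean RPM·depth/10⁶; the
  intended RPMs are log-normal (σ = 1.6) scaled so miRNAs hold ~5 % of
  the library, echoing the observed category shares. An overdispersion
  knob (gamma-Poisson) exists but defaults to off, because the Poisson
  law is exactly the sampling model the test assumes. Twelve miRNAs are
  spiked at |log2FC| = 2 in A vs CK (half up, half down) and an
  overlapping set in M vs CK — the shared half mimics a wounding
  component common to real and mock treatment; ~15 % of low-abundance
  miRNAs are silenced in single libraries to create Venn structure.
* **Reads.** 49-nt reads: insert + 3' adapter + random fill, uniform
  Phred 38; 0.5 % junk reads (no adapter / short insert / N-containing /
  low quality), keeping the clean fraction above 99 %. The default
  simulated depth in the end-to-end study is 20,000–50,000 reads per
  library — deep enough that the modal length, category shares and
  spike recovery are stable, and small enough to iterate quickly.
* **RACE / qPCR.** Clones fall on the canonical position with a set
  probability (default 0.8) and otherwise uniformly over the duplex;
  CT tables place the control at a fixed ΔCT and offset the treatment by
  −log2FC, with Gaussian CT noise per well, so noise-free tables
  reproduce the intended fold change exactly.

What passing on these data does **not** show: robustness to sequencing
error profiles, adapter variants, overdispersed biological replicates,
hairpin-precursor validation of novel miRNAs, or genome-scale target
scanning — none of which the generator models.

Replication note: such studies sometimes pool time points into a single
library per condition while still describing replicated measurements; the
simulator supports both designs (one library per condition is the default
end-to-end layout; replicated count tables can be built directly from
`simulate_counts` with distinct seeds) without asserting either as the
only faithful one.

## Determinism

Every generator takes an explicit seed and draws through a single numpy
`Generator`; the pipeline derives per-stage seeds from the run seed via
`SeedSequence`. Two runs with the same configuration write byte-identical
artifacts, which the test suite asserts on checksums.
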