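# Methods

## Model overview

`mirevo` predicts miRNA recognition elements (MREs) with a two-stage
model. The first, ab-initio stage is generative and target-independent:
for one miRNA it searches sequence space for strings that would bind the
miRNA well, then looks for approximate copies of those strings in 3'UTRs.
The second stage is discriminative: an SVM over 25 site/context features
removes the false positives the permissive first stage lets through. The
stages are charged jointly at evaluation time, so a positive lost by the
first stage counts against the whole predictor.

Throughout, coordinates are 0-based half-open, sequences are RNA 5'→3'
(DNA `T` is normalized to `U`), the miRNA seed is positions 1–8 from the
5' end, and — because the duplex is antiparallel — the seed's complement
occupies the *last* eight positions of a site written 5'→3'.

## Duplex energetics

The miRNA:site duplex is scored with an intermolecular-only
nearest-neighbor model: non-crossing antiparallel base pairs
(Watson–Crick, optionally G·U), stacking free energies for adjacent
pairs, affine bulge penalties (one strand unpaired) and a linear
internal-loop penalty (both strands unpaired). Intramolecular structure,
ensemble/partition-function effects and temperature dependence are out of
scope; the `EnergyModel` is pluggable so a full thermodynamic backend can
be substituted while keeping the same `DuplexResult` contract, and the
absolute kcal/mol values are therefore backend-specific by design.

Defaults: the standard Watson–Crick RNA stacking table (−0.93 to
−3.42 kcal/mol); a flat −0.5 kcal/mol for any stack involving a G·U
wobble; `bulge_open` 3.0, `bulge_extend` 0.6, `internal_loop_penalty`
0.8 kcal/mol per base. The wobble value is deliberately weaker than every
Watson–Crick stack so that mutating a perfectly complementary site can
never *lower* the duplex energy — a monotonicity property the test suite
asserts. The minimum-energy pairing is found by an O(N·M) dynamic program
(running prefix minima handle the affine/linear loop transitions); ties
are broken deterministically by candidate order. If no pairing has
negative energy the duplex is reported open (energy 0, everything
unpaired). The DP is verified against exhaustive enumeration of all
non-crossing pairings on small instances.

Region decomposition: every stacking/loop term is attributed to the
region of its 5'-most miRNA base. The out-seed region is everything
outside the seed, so `E_seed + E_out-seed = E_duplex` exactly; the 13–16
block is contained in out-seed and reported separately (the quantities
feed `fitness_0` and two SVM features). Unpaired-base counts follow the
same region convention.

## Genetic algorithm

Individuals are plain length-N nucleotide strings (gaps and bulges arise
only inside the duplex DP, never as explicit characters, which keeps the
downstream positionwise mapping well defined). Defaults: population 10,
100 offspring per generation, per-position mutation probability 0.2,
single-point crossover fixed at position N−8 so the seed-binding 3' block
is inherited intact, truncation selection. The generational scheme is
elitist (μ+λ): the next parents are the truncation-best of parents plus
offspring, which makes the best fitness non-increasing and gives the
stall-based stop (no improvement for 2 consecutive generations,
configurable; hard cap 200 generations as a safety bound) a clean
meaning. Each offspring is produced by crossover of two distinct
uniformly drawn parents followed by mutation.

The candidate pool collects the best individual of each generation; the
returned set keeps those strictly better than a *reference* fitness — the
fitness of a site whose seed-binding block is the exact reverse
complement of the miRNA seed and whose out-seed block copies the miRNA's
own out-seed bases (reversed), a filler that cannot Watson–Crick pair
with itself. The reference is recomputed under whichever fitness variant
is active. All randomness flows from one seeded generator, so runs are
bit-reproducible.

## Weighted-Hamming mapping

Virtual sites are compared directly with every UTR window on the sense
strand (virtual sites model the mRNA-side element, so no complementation
happens at this stage). Out-seed positions contribute the plain mismatch
indicator; the eight seed-block positions contribute ±1, rewarding seed
matches instead of merely tolerating them, so HD ranges down to −8.

The acceptance threshold is stated in terms of a reference configuration
(perfect seed block, at least 4 additional out-seed matches). Two
readings coexist: the printed out-seed mismatch count `(N−8) − 4` (10 at
N = 22), and the weighted distance of that same configuration,
`(N−8−4) − 8` (2 at N = 22). They are mutually inconsistent; the default
honors the printed number and a `strict_threshold` switch selects the
self-consistent reading. Comparison is strict (`HD < T`). Windows hit by
several virtual sites are merged to one record keeping the minimum HD
(ties: lexicographically smallest source) unless `report_all_hits` is
set. The vectorized scanner is required to agree bit-exactly with a naive
rescan, which the suite enforces on random instances.

## Features

Per candidate site, 25 features: (1–3) unpaired miRNA bases in seed,
13–16, out-seed; (4–6) duplex, seed and out-seed energies; (7) AU
fraction of the flanks over the whole-UTR AU fraction; (8) AUUUA
pentamer presence anywhere in the mRNA (binary, not a count); (9, 10)
G/C motif downstream — operationalized as ≥ 4 identical bases in a 6-nt
window, thresholds configurable, since the motif's source definition is
not restated here; (11–13) folding free energy of flanks+site, upstream
flank, downstream flank; (14) ΔΔG = duplex energy − neighborhood folding
energy; (15–17) relative position, absolute start, UTR length (both
positional variants are kept deliberately even though one is a scaled
version of the other); (18–25) base fractions of the mRNA and of the
site. Flanks default to 70 nt per side (a typical accessibility-window
scale; configurable) and truncate at UTR boundaries, with empty windows
folding to 0 by convention.

Window folding uses a pluggable backend; the built-in default is a
deterministic Nussinov-style minimum-energy pairing (GC −3, AU −2,
GU −1 kcal/mol, minimum hairpin loop 3), JIT-compiled with numba when
available and memoized. The neighborhood energy (11) is taken literally
as the folding free energy of the site±flank window, not a
constrained-minus-unconstrained opening difference.

## Classifier

Features are scaled per dimension to [−1, 1] by the training min/max
(degenerate features map to 0; unseen values extrapolate unclipped) — the
standard companion of the underlying libsvm-style implementation, as the
original scaling is unstated. The SVM defaults to the optimized operating
point: RBF kernel, C = 4, γ = 0.2; linear and degree-2 polynomial kernels
are selectable. No class weighting is applied by default — negative
expansion is itself the balancing mechanism — but a weight flag exists.
Raw decision values are exposed alongside labels so the operating point
can be swept. Models persist as a versioned joblib archive carrying the
scaler, SVM and feature order; prediction refuses mismatched feature
orders.

Negative expansion runs the full ab-initio stage on UTRs with
non-regulation evidence for given miRNAs and labels every candidate a
negative record. The resulting negatives all bind with negative free
energy — hard examples, unlike random windows.

## Evaluation

Composite two-stage metrics: `Q = (TP_ML + TN_ML + TN_ab) / total`,
`SP = (TN_ML + TN_ab)/(FP_ML + TN_ML + TN_ab)`,
`SE = TP_ML/(TP_ML + FN_ML + FN_ab)`; a zero denominator yields an
explicit *undefined*, never a silent 0, and with `TN_ab = FN_ab = 0` the
formulas reduce to the single-stage metrics. Gene-level (indirect)
validation reports `|predicted ∩ SS|/|SS|` and `|predicted ∩ SS|/|predicted|`
against a selected set SS of expression-affected genes.

Feature ranking: the per-feature F-score is implemented exactly as
printed, `|μ_P − μ_N| / |σ_P − σ_N|` with population standard deviations.
The denominator is nonstandard (the usual Fisher-type score sums the
dispersions); a `standard=True` flag provides the conventional variant
for comparison. A zero numerator returns 0 (no separation); equal
dispersions with distinct means raise an undefined flag. The correlation
ranking uses absolute Pearson correlations (Spearman selectable), ranks
each column ascending — rank 1 = least correlated — with mean-rank ties
and zero-variance features ranked last, and sums ranks per feature. The
final ranking adds the F-score ranking (1 = most discriminative) to the
correlation ranking and ranks the total, tied totals sharing the minimum
rank, matching the shared-rank convention of the reference table.

Cross-validation partitions *miRNAs*, never records, into k folds
(default 20, repeated 10 runs), so train and test never share a miRNA;
the confidence interval is the t-interval over per-run means at
significance 0.05.

## Synthetic benchmark

The generator emulates the structure of a direct-validation dataset:
20 uniform random 22-nt miRNAs; 100 positive UTRs (250–400 nt, uniform
background), each carrying one implanted site — the reverse complement of
its miRNA with out-seed positions mutated at rate 0.15 and the seed block
kept perfect (a flag produces seed-degenerate, 3'-compensatory-style
implants) — with flanks rewritten to AU fraction 0.75; 100 non-regulated
UTRs rejected-and-resampled until free of any exact 8-mer seed
complement, paired round-robin with miRNAs as non-regulation couples.
Experimental-style decoy negatives (off-implant candidates on positive
UTRs) are kept scarce — one per positive UTR with probability 0.15 —
mirroring the real-world scarcity of validated negatives that motivates
expansion; expanded negatives are capped at the 5 best candidates per
couple. The labelled records split 70/30 by miRNA.

What the generator does *not* emulate: conservation, CDS/5'UTR context,
isoform-level UTR variation, expression-level noise, or the cross-species
heterogeneity of real training data. Passing the benchmark therefore
shows the machinery is correct and the negative-expansion design
effective under idealized conditions, not that real-data accuracies are
reproduced. Under perfect-seed implants the positives are uniformly more
stable than any candidate on a seed-free UTR, so the positive and
expanded-negative energy distributions overlap only in the
seed-degenerate generator mode; the suite probes the overlap there.

## Problem sizes and numerics

The default benchmark (20 miRNAs, 200 UTRs) was sized to keep a full
end-to-end run in the low seconds-to-minutes range on one CPU while still
exercising every stage at realistic per-miRNA scale. Brute-force oracles
run on sequences of length ≤ 10 (duplex) and UTRs ≤ 200 nt (scanner),
where exhaustive enumeration is exact and fast. Floating-point
comparisons in tests use absolute tolerances of 1e−9 or tighter; all
stochastic components (GA, generator, SVM seeding, CV shuffles) are
driven by explicit integer seeds.

## Known limitations

* Duplex energies are model-relative; do not compare kcal/mol values
  against thermodynamic tools without swapping in such a backend.
* The printed threshold rule is generous; at N = 22 a virtual site with a
  perfect seed block maps to every window sharing that block regardless
  of out-seed agreement, so downstream filtering carries most of the
  specificity burden (this mirrors the intended division of labor).
* The F-score's printed denominator can flag features as undefined that a
  conventional Fisher score would rank normally; use the standard variant
  for cross-tool comparisons.
* Only the sense strand of the given 3'UTR is scanned; UTR extraction,
  annotation and conservation are out of scope.
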