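# Methods

This note documents the models, numerical choices and limitations behind
motifspace, in the order a user meets them: library combinatorics,
selection count analysis, epistasis measures, the fitness model and beam
search, and the simulator that ties them together.

## Library design and exact combinatorics

A `MotifConstraintSpec` partitions positions into conserved (one fixed
base), variable unpaired (an allowed base set) and base pairs (a set of
allowed ordered dinucleotides, default the six pairing combinations AT,
TA, CG, GC, GT, TG; custom sets support noncanonical pairs). Coordinates
are 1-based; a pair is written (5′ position, 3′ position).

**Pair encodings.** `expand_pair_encodings` covers an allowed dinucleotide
set with products of IUPAC codes. Only "closed" products need to be
searched (a product can always be shrunk to the closure of the allowed
pairs it covers without losing coverage or adding off-target sequences),
which keeps the search exact and small. The cost function is
`(#off-target dinucleotides introduced) + (#code pairs − 1)`, ties broken
by fewer code pairs and then lexicographic symbol order. The two terms
reflect the real trade-off in library synthesis: off-target dinucleotides
waste library on pairing-broken variants, while every extra code pair is
an extra oligonucleotide synthesis. Under this cost the unconstrained pair
is encoded as {(R,Y), (Y,R)}, a fixed pair as itself, the set {AT, GC, GT}
as the single code (R,Y) (accepting AC as the one off-target), and
{AT, TA} as the two exact alternatives (A,T)/(T,A). A design with k
multi-alternative pairs therefore expands into the Cartesian product of
alternatives - 2^k sub-pools for k two-alternative pairs - mixed
equimolarly by default (arbitrary weights are supported).

**Counting.** All set sizes over the union of sub-pools use
inclusion-exclusion: the intersection of any sub-pool subset is again a
product set whose size factorises over positions. This covers unique
counts, two-library intersections (a double inclusion-exclusion over both
sub-pool lists), pair-satisfaction fractions (per-term counts factorise
over pairs and free positions) and distance distributions (a polynomial
product over positions, or over position groups when each base pair counts
as one unit). Exactness is tested against brute-force enumeration on
hundreds of random designs. The 2^m subset sum is capped at m = 20
sub-pools; beyond that the design should be enumerated explicitly
(`enumerate_design`, with a memory guard). Distances are plain
per-nucleotide Hamming by default; the grouped mode is opt-in because
different analyses legitimately want different conventions.

**Bundled reconstruction.** `motifspace.aurora` ships a synthetic 46-nt
Aurora-like library: 11 base pairs (three unconstrained and split over
R-Y/Y-R, three encoded by a single R-Y pair, five fixed), eight degenerate
unpaired positions, eight equimolar sub-pools, 28,311,552 unique
sequences, a (3/4)⁶ = 17.8% all-pairs-intact fraction, 35 encoded
substitutions, and a single-pool random-mutagenesis control (35
substitutions at 24 positions) that shares exactly 128 = 2⁷ sequences with
it. The module docstring marks it clearly as an invented stand-in: the
deposited oligonucleotide lists are not bundled, so per-position
coordinates and conserved bases are synthetic. One consequence of keeping
the count, satisfaction, sub-pool and substitution statistics
simultaneously exact under this encoding grammar is that the structured
library's 35 substitutions fall on 20 positions (the grammar admits no
nonnegative combination of encoding blocks realising all those statistics
on 24 positions); the control uses 24. Analyses that need the real
deposited library should load it from its own spec/design JSON.

## Selection analysis

CPM(s) = count(s)·10⁶ / total reads; values sum to 10⁶ by construction.
Enrichment(s) = observed frequency / designed frequency, with
design-absent sequences reported separately and never divided. No
pseudocounts anywhere: unobserved sequences are missing, and ratio-based
analyses skip missing members rather than impute. Read ingestion assumes
pre-merged, orientation-unified FASTA/FASTQ; flanks are clipped by exact
match and off-length inserts discarded (adaptor trimming and merging are
upstream tools' jobs).

**Calibration** between two datasets fits an ordinary least-squares line
to log₁₀ CPM over sequences observed in both, restricted to a reliable
CPM range (default 1-1000 CPM, configurable). Sequences observed in only
one dataset are excluded from the fit.

**Position slope analysis.** To find bases that modulate one kinetic
parameter specifically, shared sequences are partitioned by the base at a
position and a per-group OLS line of log₁₀ CPM(KM condition) against
log₁₀ CPM(kcat condition) is fitted, with bootstrap slope standard errors
(default 1000 resamples, seeded, vectorised). The divergence score of a
position is the largest pairwise slope difference in units of the
combined bootstrap SE. Two numerical choices matter here. First, each
group is fitted only over a CPM window common to all groups (intersection
of per-group 5-95% quantile ranges on the x axis, configurable or
disableable): the CPM-CPM relation is mildly curved wherever the reaction
leaves the linear regime, so groups occupying different activity ranges
would otherwise show spurious slope differences even without any
KM-specific effect; segment-matching removes that artefact while a base
that genuinely shifts KM still separates its groups onto different
curves. Second, OLS with bootstrap SEs was chosen over robust estimators
for simplicity and reproducibility at the group sizes involved. Groups
with fewer than `min_group` usable members are skipped with a warning.

## Epistasis and mutual information

A mutation is a substitution at one position group (a single position, or
a base pair treated as one ordered-dinucleotide unit). Its effect in
background b is CPM(b+m)/CPM(b); backgrounds are sequences carrying the
reference state at the mutated positions, so "the same mutation" means
the same substitution everywhere. Relative effects divide by the effect
in the reference background; `effect_vs_distance` averages each
mutation's log₁₀ relative effect per (grouped) distance bin and reports
the mean absolute value and the fraction of mutations within a fold
threshold (default 5×). Coverage (fraction of candidate backgrounds with
both members observed) is always reported; missing ratios are never 0,
∞ or imputed.

Stratified pairwise-distance histograms default to CPM tertiles
(configurable absolute cutoffs); all pairs are enumerated up to a
configurable stratum size, above which uniformly random pairs are
sampled with a stated seed.

Mutual information between two positions is the plug-in estimate on the
(optionally weighted) joint base distribution, in bits. The default
applies the Miller-Madow correction, ((Kᵢ−1)+(Kⱼ−1)−(Kᵢⱼ−1))/(2N ln 2)
with K the occupied category counts and N the (Kish-effective) sample
size, and clamps the result into [0, min(Hᵢ, Hⱼ)] so the standard MI
bounds hold for every input; a constant column gives exactly 0. The
matrix workflow defaults to unweighted MI over sequences above a CPM
cutoff (default 10), since activity filtering, not weighting, is what
isolates the covariation carried by functional sequences.

## Fitness models and beam search

Sequences are one-hot encoded position-major with A<C<G<T ordering. The
model contract is fit/predict; the provided implementation is a seeded
scikit-learn `MLPRegressor` whose default grid is 6 layer layouts ×
3 initial learning rates × 2 batch sizes = 36 combinations
(`hidden_layer_sizes` ∈ {(50,50), (50,50,50), (100,100), (100,100,100),
(200,200,200), (100,100,100,100)}, `learning_rate_init` ∈ {0.01, 0.001,
0.0001}, `batch_size` ∈ {100, 200}). `train_model` regresses on raw CPM
by default; the end-to-end workflows (grid search, benchmarks, examples)
use the exposed log₁₀-CPM option because simulated CPM spans roughly four
orders of magnitude and the network trains far more stably on the log
scale. Training metadata (hyperparameters, seed, training-set hash) is
recorded with the model.

Two splits are provided: a uniform random disjoint train/test split
(default 0.1/0.1), and the fitness split holding out the top `n_test`
CPM sequences for testing and the next `n_val` for validation, with the
remainder (optionally subsampled by a fraction) for training; CPM ties
break lexicographically so splits are exactly reproducible.

The beam search is level-synchronous: the frontier starts as the
`topN_start` best training sequences; at each depth every unvisited
single-mutation neighbour (per-position alphabet, by default the bases the
library design allows, so the search stays inside encoded space) is scored
by the model and becomes a tree node; the `beam_width` best scored mutants
form the next frontier, ties broken by sequence order. The tree therefore
contains every scored sequence, not just kept frontiers, and its size is
what `fraction_explored` divides by the number of encoded-but-absent
sequences. `mode="random"` replaces the frontier selection by a uniform
draw over the scored candidates (decisions about propagation direction are
random; the model still ranks the final `top_explored` output), which is
the matched control for how much the model's guidance contributes. After
grid search the validation set is merged into training and the model
retrained before the final search. Precision compares the search's top-k
against the true top-k and equals recall since both sets have size k.

## The simulator

`GroundTruthLandscape` assigns log kcat(s) = Σ additive effects of
non-reference bases + pairwise epistatic terms − pairing penalties for
broken base pairs, and log KM(s) = Σ KM modulators; the reference sequence
sits exactly at `base_kcat` (default 0.1 min⁻¹) and `base_km` (default
40 µM). Defaults: additive effects N(0, 1) in ln units per non-reference
base; pairing penalty 1.5 ln units per broken pair (this plants the
clustering of active sequences around pairing-compatible variants); one
pairwise epistatic term per variable position, N(0, ruggedness) with
ruggedness 0.5; KM-designated positions carry one base shifting log KM by
−2 (about 7.4-fold tighter substrate binding) and contribute nothing to
kcat, so the kcat/KM contrast is clean by construction. Selection follows
single-turnover Michaelis-Menten kinetics, p(s) = 1 − exp(−kcat·S/(KM+S)·t)
— the minimal kinetic model under which substrate-concentration/time
contrasts behave like kcat- and KM-biased selections. Reads are
multinomial draws: pre-selection with the designed frequencies,
post-selection proportional to frequency × p. Sequencing noise is purely
multinomial; there is no PCR-bias or sequencing-error model, which matches
the single-round workflow the package analyses but means tests say nothing
about amplification artefacts in multi-round data.

The default study conditions mirror the two-condition design the analyses
expect: kcat-biased selection at 100 µM substrate for 100 s and KM-biased
selection at 20 µM for 10 min.

**What the synthetic benchmarks use (and why these sizes).** The
benchmark/test design is a 4096-sequence single-sub-pool motif (one R-Y
pair, four N positions, one G/T and one A/T position) — large enough that
splits, searches and scans are non-trivial, small enough to enumerate
exhaustively for oracle comparisons. Benchmarks run at 10⁶ reads for CPM
fidelity and the beam workflow, 2×10⁵ reads per condition over 50 seeds
for the KM-position scan (200 bootstrap resamples in scan mode), and 20
seeds for the directed-vs-random comparison with the canonical beam
parameters (topN_start 5, beam_width 5, max_depth 5, top_explored 100).
These were fixed as the package's standard benchmark conditions.

## Known limitations

- CPM ratios estimate mutational effects faithfully only where the
  reaction is in its linear regime and counts are adequate; strongly
  saturated variants compress toward each other. The simulator makes this
  visible rather than hiding it.
- Inclusion-exclusion is exponential in the number of sub-pools (capped at
  20); designs beyond that need explicit enumeration.
- The bundled Aurora-like library is a synthetic reconstruction (see
  above), suitable for validating machinery and reproducing headline
  combinatorics, not for biological conclusions about the real motif.
- `fraction_explored` is only meaningful when the dataset is sparse in the
  encoded space; on near-complete toy datasets its denominator is tiny.
- No base-quality filtering, UMI handling or PCR-duplicate modelling; read
  preprocessing (merging, trimming, orientation) is delegated to standard
  external tools.
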