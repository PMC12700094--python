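# motifspace

Tools for exploring the sequence space of a functional DNA motif with
structured ("secondary structure") libraries, single-step selections, and
model-guided search. The package is written for nucleic-acid engineers who
work with catalytic DNA/RNA motifs (deoxyribozymes, ribozymes, aptamers)
and want to go from a motif's base-pairing constraints to a synthesizable
degenerate library, from selection sequencing counts to quantitative
activity estimates, and from those estimates to predictions about variants
never observed.

## What it computes

**Library design.** A motif is specified by conserved positions, variable
unpaired positions with allowed base sets, and base-pair constraints. Pair
patterns that a single degenerate oligonucleotide cannot encode (an
unconstrained pair may be AT, TA, CG, GC, GT or TG) are split over minimal
IUPAC code pairs - R-Y and Y-R - so a design expands into 2^k equimolar
sub-pools for k split pairs. All combinatorics are exact, via
inclusion-exclusion over sub-pool subsets: unique-sequence counts,
intersections between libraries, per-sequence designed frequencies,
pair-satisfaction fractions, mutation censuses, and full distance
distributions (optionally counting each base pair as one unit).

**Selection analysis.** For a sequence *s* with read count *c(s)* in a
dataset of *N* reads, CPM(s) = 10⁶ · c(s)/N; enrichment divides the
observed frequency by the designed starting frequency. Selections are
compared after calibrating log₁₀ CPM on shared sequences (least-squares
line over a configurable reliable range, default 1-1000 CPM). Comparing a
kcat-biased selection (saturating substrate, short incubation) with a
KM-biased one (sub-saturating substrate, longer incubation) and fitting
per-base log-log CPM lines at each position flags bases that modulate one
kinetic parameter specifically.

**Epistasis.** A mutation's effect in background *b* is
CPM(b + mutation)/CPM(b); its relative effect divides by the same
mutation's effect in a reference background. The package summarises
relative effects across backgrounds, their growth with mutational distance
(base pairs groupable as single units), CPM-stratified pairwise distance
histograms, and positionwise mutual information
MI(i, j) = Σ p(a,b) log₂ [p(a,b)/(p(a)p(b))] with optional weights and
Miller-Madow bias correction.

**Model-guided search.** One-hot encoded sequences train a fully connected
feed-forward network (scikit-learn `MLPRegressor`) to predict CPM, under a
random disjoint split or a fitness split (top-100 CPM held out as testing,
next 100 as validation). A level-synchronous beam search with parameters
`topN_start`, `beam_width`, `max_depth`, `top_explored` and `mode`
(directed/random) explores single-mutation neighbourhoods under the
model's guidance; precision is the fraction of the true top-100 recovered
among the search's top-100 predictions (equal to recall by construction).

**Simulator.** A ground-truth landscape assigns each sequence
log-additive, base-pairing-bonus and pairwise-epistatic contributions to
kcat, plus designated positions that shift KM only. Selections follow
single-turnover Michaelis-Menten kinetics, p = 1 − exp(−kcat·S/(KM+S)·t),
with multinomial read sampling - so every analysis in the package can be
validated against known ground truth.

The package also bundles a **synthetic reconstruction** of an Aurora-like
deoxyribozyme library (`motifspace.aurora`): a 46-nt motif with 11 base
pairs whose eight sub-pools encode 28,311,552 unique sequences, 17.8% of
them able to form every pair, plus a random-mutagenesis control sharing
exactly 128 sequences with it. It is an invented stand-in with the
published grammar and headline statistics, not the deposited oligo lists.

## Worked example

```
$ python examples/03_simulate_selection_and_rank.py
observed sequences after selection: 4096
Spearman(CPM, true k_obs) = 0.997
top sequence GCCCGAACT: CPM 1025, enrichment 4.2x
reference AAAAGAACT: CPM 109.0
```

One simulated round of selection (100 s at 100 µM substrate, 10⁶ reads)
ranks the 4096 library members almost perfectly by their true catalytic
rate constant: CPM is a quantitative activity readout. Continuing with the
model-guided search on the same kind of data:

```
$ python examples/06_model_guided_search.py
directed search: precision 0.87, tree size 268 of 4096 encoded sequences
  random search: precision 0.20, tree size 316 of 4096 encoded sequences
```

After hiding the 100 best sequences from training, the trained network
steered the beam search to recover 87 of them while scoring only 268
sequences; the random-propagation control managed 20. The other examples
cover library design combinatorics, the bundled Aurora-like
reconstruction, the two-condition slope scan, and the epistasis/mutual
information analyses.

A `motifspace` command-line tool exposes the same operations
(`motifspace design|select|epistasis|ml|simulate --help`).

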