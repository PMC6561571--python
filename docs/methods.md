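# Methods

## The problem

An RNA switch (a riboswitch being the canonical case) regulates gene
expression by toggling between two secondary-structure conformations.
Predicting the *stable* conformation is ordinary free-energy minimization;
the biologically interesting part is the *alternative* (metastable)
conformation, which ordinary minimization never returns. `rnaswitch`
implements two predictors for the alternative structure of a single
sequence — a conditional-probability (CP) method and a sampling–clustering
(SC) baseline — together with the evaluation metrics to compare them and a
synthetic-data generator that provides ground-truth two-state sequences.

## Thermodynamic model

All predictions live in the Boltzmann ensemble: a structure *S* has
probability proportional to exp(−E(S)/RT), with R = 1.98717×10⁻³
kcal/(mol·K) and T the folding temperature in kelvin.

The package's reference energy model is deliberately minimal and strictly
additive:

* pair energies by canonical class: GC/CG −3.0, AU/UA −2.0, GU/UG −1.0
  kcal/mol;
* a stacking bonus of −1.0 kcal/mol for every directly stacked adjacent
  pair ([i·j] together with [i+1·j−1]);
* a hard minimum of 3 unpaired bases in every hairpin loop; no loop-size,
  dangle, or multiloop terms.

All parameters are configuration-exposed (`--params`, a flat `key = value`
file). The choice is not an approximation of Turner nearest-neighbor
energies and is not meant to reproduce them: it preserves the GC > AU > GU
stability ordering and stacking cooperativity while keeping the dynamic
programming *exactly* consistent with an exhaustive enumeration oracle
that shares the same energy function, so every engine operation can be
verified to 10⁻⁹ rather than benchmarked approximately. The
`EnsembleModel` contract — `(sequence, structure, temperature) → kcal/mol`
with this additive decomposition — admits a full nearest-neighbor plug-in.

Temperature enters only through RT (no enthalpy/entropy split). The
"melting temperature" used by the SC sampling ladder is therefore an
ensemble notion, defined operationally: the smallest T in a 1 °C scan over
[37, 100] at which the expected number of base pairs falls to half its
37 °C value, with 100 °C returned when the criterion is never met (the
usual case for GC-rich sequences under this model) and 37 °C for
unpairable sequences.

## The dynamic-programming engine

A McCaskill-style interval recursion computes, under hard constraints
(excluded pairs that must not occur; forced pairs that must occur):

* the partition function Z (inside recursion, O(n³) time / O(n²) space);
* exact base-pair probabilities P_ij via an inside–outside recursion
  (O(n⁴) worst case with the vectorized outside step; n here is at most a
  few hundred);
* the constrained MFE structure by the min/+ analogue of the same
  decomposition;
* independent Boltzmann samples by stochastic traceback over the inside
  tables.

Because the model is additive over pairs and stacks, the closed-interval
weight obeys `Qb(i,j) = w_pair(i,j)·[Q(i+1,j−1) + (w_stack−1)·Qb(i+1,j−1)]`
— the correction term upgrades interior structures whose outermost pair is
[i+1·j−1] to stacked weight — and no multiloop recursion is needed.
Excluded pairs zero only their own `Qb`; a forced pair [a·b] zeroes every
decomposition in which *a* or *b* is unpaired or paired otherwise (forced
pairs must be canonical, non-crossing, position-disjoint, and loop-legal;
contradictions raise `ConstraintError`).

Numerical choices:

* Tables are ordinary doubles with a per-nucleotide rescaling factor
  engaged only when the estimated maximal table entry would overflow
  (roughly n > 90 for pure GC duplexes); the factor cancels in every
  probability and log Z is reconstructed exactly. Severely sub-dominant
  contributions may underflow to zero under rescaling, which is harmless
  at the 10⁻⁹ tolerances used throughout.
* MFE tie-breaking is deterministic: the traceback prefers pairing over
  not pairing, then the 5′-most pairing partner, with a 10⁻⁹ energy
  tolerance for tie detection.
* Computed probabilities are clipped to [0, 1] (floating-point dust only).
* Every stochastic operation takes an explicit seed (or Generator) and is
  bit-reproducible.

The exhaustive enumeration oracle (`enumerate_all_structures`, guarded at
n ≤ 22) lists every valid structure with its energy and is the ground
truth for all of the above in the test suite and the acceptance script.

## Conditional-probability (CP) prediction

1. S1\* = unconstrained MFE at 37 °C (always 37 °C, even when the
   probability temperature differs; under this model the MFE structure is
   temperature-independent anyway, since E(S) does not depend on T).
2. Exclusion set E(τ) = all index pairs within base-pair-to-structure
   distance δbs ≤ τ of S1\*, where δbs([i·j], S) = min over [i′·j′] ∈ S of
   max(|i−i′|, |j−j′|). E(0) is exactly the pair set of S1\*. Membership
   is positional — the sequence is not consulted — because excluding an
   impossible pair is a no-op. An empty S1\* yields an empty E for every τ
   (empty-minimum convention; δbs of an empty structure is +∞).
3. Conditional probabilities P̃_ij: base-pair probabilities in the
   ensemble restricted to structures containing no pair of E, at the
   configured temperature (default 37 °C).
4. Seed L\*: by default the longest bulge-tolerant stem whose every pair
   individually has P̃ > 0.5 (strict). A stem chain may step by (1,1)
   (stack), (2,1) (5′ bulge) or (1,2) (3′ bulge); 1×1 internal loops are
   not steps — only single *bulges* are tolerated. The chain search is a
   DP over qualifying pairs ordered by span; ties are broken by larger
   total conditional probability along the chain, then by the smaller
   first pair, then stack-before-bulge. Alternative seed kinds:
   `single-bp` (argmax pair) and `all-above-threshold`.
5. S2\* = minimum-energy structure forced to contain the seed. E
   constrains only the probability computation, never this final fold, so
   S2\* may incidentally re-use excluded pairs. Because every seed pair
   has positive conditional probability it lies outside E ⊇ pairs(S1\*),
   hence S2\* ≠ S1\* whenever the seed is non-empty, and
   E(S2\*) ≥ E(S1\*) by MFE minimality. An empty seed is a reported
   outcome, not an error.

Iteration i > 2 repeats steps 2–5 with E the union of the τ-neighborhoods
of *all* previously predicted structures (S1\*, S2\*, …), yielding S3\*,
S4\*, …. The recurrence in the source description is ambiguous about
whether bare pair sets or neighborhoods are unioned; this package unions
neighborhoods, which makes iteration 2 a special case of the same rule.

Defaults: τ = 5, T = 37 °C, stem seed, threshold 0.5, iteration 2.

The riboswitch classification score is the normalized seed length
\#L\*/log₁₀(n). Switch-like sequences retain a long high-probability stem
after the MFE neighborhood is excluded; single-structure sequences do not.

## Sampling–clustering (SC) baseline

* Sampling protocol: 300 samples at 37 °C plus 150 at each of six ladder
  temperatures T_k = 37 + k·(Tm − 37)/10, k = 1…6 (decile steps toward the
  melting temperature), 1200 samples total. All counts are configurable.
* Samples are encoded as binary base-pair indicator vectors over the pairs
  observed in the set (an equivalent metric with bounded memory: squared
  Euclidean distance on these vectors equals base-pair Hamming distance on
  the structures) and split by k-means, k = 2, with 10 seeded k-means++
  restarts, best inertia kept. Mean indicator vectors (not medoids) are
  the centroids. An all-identical sample set yields a flagged degenerate
  single-cluster result.
* The MFE structure's cluster is found by assigning S1\*'s own indicator
  vector to the nearest centroid; S1\* is *not* injected into the sample
  set. Ŝ2\* is the lowest-energy sample of the other cluster, ties broken
  by first occurrence.
* The mean silhouette over all samples (Hamming distance; members of
  singleton clusters score 0) is SC's classification score.

## Synthetic data

`generate_bistable` builds a sequence a·l1·b·l2·c: core *b* a guanosine
run, arms *a*, *c* cytosine runs (reverse complement of the core), linkers
adenosine runs. Helix A pairs arm a with the core; helix B pairs the core
with arm c; the helices share the core, so they are mutually exclusive.
Composition makes these the only pairing opportunities: no segment pairs
internally, pyrimidine arms cannot pair each other, and with no uridine in
the molecule the A-linkers are inert. Although the segments are
homopolymeric, the *full* helix register is unique — the only non-crossing
antiparallel matching using every core G and arm C — so each ground-truth
helix is one well-defined structure.

The bias mutation (on by default) inserts a single adenosine *bulge* into
arm c at a seeded interior position. Helix B keeps all m Watson–Crick
pairs but loses exactly one stacking interaction (1 kcal/mol): helix A is
the designed stable state, helix B the designed alternative, and helix B
is precisely a bulge-tolerant stem — the object the seed search targets.
A substitution-based bias was rejected: mutating the shared core breaks
helix A, and a one-sided arm substitution can only reach G·U, whose U
would pair the linker adenosines and contaminate the MFE structure.

Defaults: core 6 nt, linkers 6 nt. The linker length keeps every helix-B
pair at δbs ≥ linker + 1 = 7 from helix A, outside the default τ = 5
exclusion neighborhood; the sequences are 31 nt (30 unbiased), small
enough that a full CP run takes milliseconds and a 1200-sample SC run a
fraction of a second.

One modeling consequence of the flat energy model deserves note. A
"chimera" — k helix-A pairs plus m−k helix-B pairs split across the core —
always costs exactly one stack relative to the full stable helix, the same
as the bulge bias, so in *biased* designs the alternative state is
energy-degenerate with a combinatorial family of chimeras. CP is immune
(conditioning on E(τ) removes every chimera's A-side), and the biased
designs are the cohort for all CP properties. The SC pick (lowest-energy
member of the non-MFE cluster, ties by first occurrence) cannot
distinguish degenerate states, so SC basin-recovery is demonstrated on the
*unbiased* variant of the same designs, where the two full helices are the
unique ground states, chimeras sit strictly 1 kcal/mol above, and the MFE
tie between the helices is broken deterministically by the traceback
(which prefers pairing the 3′ end, making helix B the S1\* and helix A the
recovered alternative). Under a realistic nearest-neighbor model the
degeneracy would be broken by loop penalties instead.

`generate_monostable` emits a single G/C hairpin with an inert A loop —
the negative class for classification. After its MFE neighborhood is
excluded nothing pairable remains, so its seed is empty and its normalized
seed length 0.

What the generator does *not* emulate: multi-helix aptamer architecture,
ligand-binding energetics, kinetic traps, sequence heterogeneity, or
realistic loop entropies. Passing the synthetic cohorts shows the
pipeline's logic is correct under its own thermodynamic model, not that
published benchmark accuracies are reproduced.

## Evaluation

Base-pair accuracy is pooled over a dataset: total-SEN =
ΣTP/(ΣTP+ΣFN)·100, total-PPV = ΣTP/(ΣTP+ΣFP)·100, with exact-index pair
matching (no slippage tolerance). The combined score is the harmonic mean
of the two proportions and is labeled F1 throughout. A metric with a zero
pooled denominator is reported as undefined (None), never 0. ROC/AUC is
the rank-based Mann–Whitney formulation (ties counted half).
Classification feeds normalized seed length (CP) or mean silhouette (SC)
to the same AUC; no decision threshold is baked in. The
alternative-structure-referenced (ASR) landscape export writes one
(Hamming distance to reference, energy, cluster) row per sample plus the
reference itself at distance 0; passing S1\* as the reference gives the
standard landscape instead.

On the synthetic cohorts the silhouette score runs *counter* to its
direction on real riboswitch data: a monostable hairpin's samples split
into two extremely tight clusters (full stem vs. near-empty), scoring
higher than the broader bistable landscapes. The synthetic negative class
is "too clean"; silhouette-based classification is meaningful only on
real data, which is why the acceptance computation reports the CP
(normalized-seed-length) AUC.

## Problem sizes

The test suite and the acceptance script verify the engine against
exhaustive enumeration on 200 random sequences of length 5–18 (the
regime where enumeration is exact and fast), run the CP pipeline on 50
seeded bistable designs plus 20/20 classification cohorts, draw 10,000
Boltzmann samples for the chi-square check, and run full 1200-sample SC
on 8 designs. The whole acceptance computation takes a few seconds on one
CPU.

## Known limitations

* The reference energy model is not Turner-parameterized; absolute
  energies and melting behavior are not comparable to UNAFold/ViennaRNA
  outputs, and published benchmark numbers are out of reach by design.
* Pseudoknots and base triples are rejected (dropped with a warning when
  reading external reference structures).
* The exclusion set grows as O(|S1*|·τ²); very large τ approaches the
  all-pairs set and leaves nothing to condition on.
* The O(n⁴) outside recursion is the practical length bound (a few
  hundred nt); a dedicated O(n³) outside implementation would lift it.
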