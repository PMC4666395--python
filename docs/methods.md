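# Methods

This note records the model, the numerical choices and the synthetic study
conditions behind `rnadca`, including the points where the design was
genuinely open and what the tests do and do not demonstrate.

## Model and inference

Aligned sequences over the 5-state alphabet `(-, A, C, G, U)` (fixed order;
the gap is state 0) are modelled by a pairwise Potts model
`P(A) ∝ exp(Σ_{i<j} e_ij(A_i,A_j) + Σ_i h_i(A_i))`. Inference is naive
mean field:

1. **Reweighting.** Sequence weight = 1 / (number of rows, including self,
   with pairwise identity ≥ 0.9, gap-gap positions counting as matches);
   `Meff` is the weight sum. The threshold is the `reweight` parameter
   (fraction in (0,1], default 0.9).
2. **Frequencies.** Reweighted single/pair counts are divided by `Meff` and
   mixed with the uniform distribution: `f_i = (1-λ) f̂_i + λ/q`,
   `f_ij = (1-λ) f̂_ij + λ/q²` (λ = `pseudocount`, default 0.5, the
   established mean-field default for strongly reweighted alignments; the
   closed interval [0,1] is accepted, and λ=1 is the uniform limit). This
   mixing keeps marginalization of `f_ij` exactly consistent with `f_i`.
3. **Inversion.** The `(q−1)L`-dimensional connected-correlation matrix
   over the non-gap states (gap = reference state) is symmetrized and
   inverted by a dense solve; no regularization beyond the pseudocount.
   Couplings are the negated inverse blocks, zero-padded on the gap state
   and shifted to the zero-sum gauge (row/column sums of every `e_ij`
   vanish to < 1e-8). Fields follow from the mean-field self-consistency
   `h_i(A) = log f_i(A)/f_i(-) − Σ_j e_ij(A,·)·f_j`; they are reported but
   do not enter pair scoring.
4. **Scores.** `Fapc(i,j) = ‖e_ij‖_F − F(i,·)F(·,j)/F(·,·)` with
   off-diagonal arithmetic means (diagonal excluded). The Frobenius norm
   includes the gap state by default (`include_gap=False` drops it; the
   two variants are one flag apart and both are exercised in the tests).
   MI is Eq.-style plug-in mutual information in natural log (nats; the
   base only rescales rankings), optionally with the same average product
   correction (MIapc). With λ=0, `0·log 0` terms are 0.

**A pseudocount subtlety.** For independent columns the uniform-admixture
pseudocount creates an exact rank-one connected-correlation term
`λ(1−λ)(f_i − 1/q)(f_j − 1/q)ᵀ`, so inferred couplings vanish with sample
size only when column marginals are uniform; for non-uniform marginals a
small marginal-dependent background survives — precisely the product-form
background the average product correction removes. The independence-limit
test draws uniform 5-state columns for this reason. A related
conditioning point: when the gap state is (nearly) unobserved and λ is
tiny, the correlation matrix is nearly singular along the simplex
direction and noise is strongly amplified; the default λ=0.5 regularizes
this.

APC removes any constant (rank-one) off-diagonal score surface exactly.
For a general outer product `u_i u_j` with non-constant `u`, exact removal
is impossible from off-diagonal data alone (the diagonal is undefined on a
score matrix), and the standard correction leaves a residual of the order
of the variance of `u`; this is inherent to APC, not an implementation
choice.

## Secondary structure prediction

The pair-scoring matrix for a target sequence is prefilled with −1 for
nucleotide pairs that are not Watson-Crick (A·U, G·C) or wobble (G·U) and
0 for compatible ones. The `top_k` largest covariation scores (default:
the alignment length L, capping positive entries at L and thereby
preventing the overpairing a strictly positive MI surface would cause) are
mapped onto target positions; scores on gap columns of the target row or
on incompatible nucleotides leave the prefill unchanged. The Nussinov
dynamic program maximizes total pair score over nested structures with
`min_loop = 3` unpaired nucleotides strictly between paired ends. Only
strictly positive cells may pair: a zero-score compatible pair adds
nothing and would only overpair, and −1 cells can never improve the
optimum, so forbidding them outright is behaviourally identical to
allowing them. Traceback is deterministic with fixed precedence: pair
(i,j), then bifurcation at the smallest split point, then leaving i, then
j unpaired.

Evaluation restricts predicted and reference pair sets to pairs with both
ends in the assessable position set; sensitivity = TP/(TP+FN), precision =
TP/(TP+FP), and an empty prediction reports precision 1.0 with an explicit
`no_predictions` flag (avoiding 0/0). The `topk_sweep` helper (and the
`sweep` subcommand) traces quality as a function of the retained-score
cutoff, the method's main free parameter.

Consensus curation maps Stockholm `SS_cons` pairs onto a chosen target row,
drops pairs with unmappable ends or incompatible nucleotides, and can
optionally grow kept helices by adjacent compatible, conflict-free, nested,
loop-legal pairs (off by default; families differ in whether extension is
appropriate). Crossing pairs from extended WUSS annotation (including
pseudoknot letters) are parsed into a separate crossing list and never
enter the nested consensus.

## Tertiary contacts and enrichment

Candidate column pairs are mapped to target residues and excluded — with
exactly one recorded reason each, in the order unmappable/unresolved,
near-diagonal (|i−j| < 5), secondary-structure neighbourhood (within ±2 of
both ends of any secondary pair, the 5×5 neighbourhood rule) — then sorted
by descending score with deterministic index tie-breaks. Contact truth is
the minimal non-hydrogen inter-atom distance between standard RNA residues
of one chain (waters, ions, heteroatoms skipped; highest-occupancy
conformer for disordered atoms; chain reconciled to the target by exact
substring match), thresholded at 8 Å (or 4 Å).

The enrichment scan slides a window of `Y = round_half_up(0.10 × list)`
(floored at 1) along the ranking in steps of 1. At offset X the null
success rate `r0(X)` is the TP fraction among pairs of rank > X, and
`p(X) = P[Binomial(Y, r0) ≥ T(X,Y)]` is computed by exact summation of PMF
terms (list sizes are small; no normal approximation). `first_crossing` is
the smallest X with p > α (α = 0.01); sensitivity and precision of the
first X predictions are reported there, with precision 1.0 plus a
`no_predictions` flag at X = 0. Under a signal-free ranking the discrete
exact test is conservative, so the fraction of windows reaching p ≤ 0.01
stays at or below the nominal level.

Restraint export writes the top-n ranked pairs as TSV and Rosetta-style
`AtomPair` lines with a flat-bottom bound (`FLAT_HARMONIC 0.0 1.0 upper`,
default upper 8 Å — soft constraints, since native distances are unknown).
The default atom rule maps each nucleotide to its Watson-Crick edge
nitrogen (N1 for purines, N3 for pyrimidines); it is a deliberately simple
placeholder and fully configurable per nucleotide type.

## Synthetic study conditions

The generator emulates a curated riboswitch-like family; its defaults are
the package's study conditions and are fixed once:

| parameter | default | rationale |
|---|---|---|
| n (target length) | 70 | mid-sized riboswitch |
| M (sequences) | 1000 | well above the ~250-sequence stability regime |
| secondary coupling | 2.0 (wobble ×0.5) | strong WC covariation of helices |
| tertiary coupling | Gaussian, sd 0.5 | much weaker, non-WC-specific signal |
| fields | Gaussian, sd 0.2 | compositional bias between columns |
| redundancy rate | 0.30 | phylogenetic near-duplicates (duplicate rows mutated at 2%/site) |
| gap rate | 0.02 | alignment gaps (target row kept gap-free) |
| Gibbs burn-in / thinning | 1000 / 10 sweeps | recorded in the fixture manifest |

Sampling runs one independent Gibbs chain per sequence, vectorised across
chains, each for the burn-in; thinning applies only when fewer chains than
sequences are requested. Identical spec and seed give byte-identical
fixture bundles. The layout places three 4-pair hairpins inside a 4-pair
closing stem; tertiary pairs are drawn (seeded) among positions that pass
the near-diagonal and neighbourhood filters by construction, so every
pipeline stage sees a non-trivial input. The coordinate fixture puts one
pseudo-atom per residue 20 Å apart on a line and moves the second residue
of each requested contact pair to exactly the requested distance along a
per-pair axis; contact pairs must be residue-disjoint.

What the generator does *not* emulate: phylogenetic tree structure beyond
duplication-plus-noise, alignment errors, non-canonical base-pair
geometries, length variation, or realistic 3D geometry. Passing tests
therefore demonstrate correctness of the statistics and algorithms under
the stated model, not prediction accuracy on real families.

Benchmark problem sizes (chosen as the package's study sizes): the
dynamic-programming/enumeration cross-check uses 200 random matrices at
n ≤ 12; two-site coupling recovery uses M = 50,000 i.i.d. draws from the
exactly enumerated distribution with λ = 0.01 and compares the
gauge-invariant double difference `e(A,A)+e(C,C)−e(A,C)−e(C,A)` to the
true coupling; chain studies use L = 6, M = 2,000, 20 replicates; folding
and enrichment studies use 20 and 10 replicates of the default family with
a 300-sweep burn-in (the sparse coupling graph mixes quickly, and fixture
tests use shorter burn-ins still). On clean synthetic families the three
scores often tie on secondary-structure sensitivity — helices covary
strongly enough for any measure — while the chain margins and the
tertiary-contact enrichment show the disentangling advantage of the
global model clearly.

## Known limitations

- Mean-field inference is a small-coupling approximation; recovered
  couplings are biased at strong coupling regardless of sample size.
- No pseudolikelihood or Boltzmann-machine variants, no Direct Information
  score; ranking is by Fapc only.
- PDB coordinate section only (no mmCIF); standard residues A/C/G/U only.
- No pseudoknot prediction; crossing input pairs are carried but unused by
  the folding DP.
- The residue-to-atom restraint mapping is a single-atom-per-nucleotide
  placeholder, not a literature-calibrated atom-pair table.
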