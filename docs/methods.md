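# Methods

## The estimation problem

Given K homologous RNA sequences x_1 … x_K, the package estimates, for each
sequence, the posterior probability that nucleotides i and j form a base
pair in its secondary structure. The estimate combines two sources of
information:

* **intrinsic** — the sequence's own folding thermodynamics, via a
  nearest-neighbor partition function;
* **extrinsic** — the pairing tendencies of the other sequences, mapped
  onto this sequence through probabilistic pairwise alignment.

These are iterated: extrinsic priors sharpen each sequence's pairing
probabilities, the sharpened probabilities produce better priors for the
others, and so on — a message-passing scheme in the spirit of turbo
decoding.

## Alignment model and co-incidence

Each ordered pair of sequences is aligned with a three-state pair HMM
(ALN, INS1, INS2) with affine-gap semantics. A silent begin state enters
the emitting states with the stationary distribution of the transition
matrix and termination is allowed from any state; this is the simplest
complete-path semantics and is stated so results are reproducible.

Two positions i (in x_m) and k (in x_s) are *co-incident* when the
alignment path visits lattice cell (i, k) in any of the three states —
aligned, or inserted anchored at the partner position. The posterior
co-incidence matrix is computed by forward–backward in linear space with
per-row rescaling (no underflow for sequence pairs of several hundred
nucleotides). Pairwise sequence identity ψ is the fraction of
maximum-likelihood (Viterbi) path columns, counting insertion columns,
that align identical nucleotides. Viterbi ties are broken in the fixed
state order ALN < INS1 < INS2. Because co-incidence is symmetric, each
unordered pair is evaluated in a canonical orientation and transposed,
making the transpose-symmetry of the matrix (and of ψ) exact to the bit.

The shipped HMM parameters (`data/hmm_params.yaml`) are documented
defaults — match-biased joint emissions (0.16 same / 0.03 different), gap
open ≈ 0.03, gap extend ≈ 0.30 — not values trained on alignment
databases; any file with the same schema can be substituted. Constraint
sets keep, per position, the partner indices with co-incidence above a
significance threshold τ_c (default 1e-4, configurable): low enough to
discard only negligible mass, high enough to keep the induced-proclivity
sums sparse.

## Extrinsic information

A source pair (k, l) with probability p in x_s induces a proclivity
p · c(i,k) · c(j,l) on the target pair (i, j); proclivities are summed over
all source pairs with k, l restricted to the constraint sets. Orientation
is preserved (i→k, j→l with k < l): alignment paths are monotone, so the
reversed assignment cannot occur on any single path. Each other sequence's
proclivity matrix is weighted by (1 − ψ) — an identical homolog carries no
independent information — summed in a fixed order, and the aggregate is
divided by its maximum entry so the largest value is exactly 1. If the
aggregate is identically zero (all ψ = 1, or all source probabilities
zero) the neutral all-ones matrix is used instead, which reduces the next
step to the plain single-sequence partition function.

## Modified partition function

Structures are weighted by a modified Boltzmann distribution: structure S
has weight exp(−ΔG⁰(S)/RT) · Π_{(i,j)∈S} ext(i,j)^{γ/RT}, i.e. each pair
contributes a pseudo-free energy −γ·ln ext(i,j). γ is expressed in RT
units in all interfaces; the default γ = 0.3·RT trades sensitivity against
PPV well in practice, and η = 3 iterations captures nearly all of the
refinement gain. Extrinsic entries are floored at 1e-12 before the
logarithm so a zero prior leaves a pair negligibly probable rather than
forbidden (keeping the DP well-conditioned).

Pairing probabilities are computed by McCaskill-style inside–outside
recursions over the loop decomposition (hairpins, stacks, bulge/internal
loops, linear multibranch model, free exterior loop) in O(N³) time and
O(N²) memory. Numerical choices:

* Internal/bulge loops are capped at a combined unpaired length of 30 in
  the DP (standard practice); the loop tables extrapolate logarithmically
  (G(n) = G(L) + 1.75·RT·ln(n/L)) for the structure scorer, which has no
  cap. At the scales where the DP is cross-checked against enumeration
  (N ≤ 18) the cap cannot bind, so the two routes agree exactly.
* A per-nucleotide scale factor σ keeps the partition function inside
  double range; σ is chosen by a deterministic adaptive schedule (neutral
  below 300 nt, exp(−0.8) above, adjusted in exp(±0.6) steps on
  overflow/underflow) and cancels exactly in every probability ratio.
  `modified_partition` reports log Z; the `z` convenience property may
  overflow to inf for very long sequences.
* The brute-force oracle enumerates every pseudoknot-free set of canonical
  pairs (N ≤ 20 guard), scores each with the loop-decomposition energy
  function, and sums weights explicitly; it shares no code with the DP
  recursions beyond the energy tables.

## Energy model

The nearest-neighbor parameterisation is deliberately simplified and ships
as a versioned YAML file: Watson–Crick + GU stacking energies (6×6 table
with reverse-complement symmetry enforced at load), length-dependent
hairpin/bulge/internal penalties, a linear multibranch model
(a + b·branches + c·unpaired), and a terminal AU/GU penalty applied once
per non-stacked side of a weak pair. Dangling ends, coaxial stacking,
sequence-specific hairpin bonuses and loop-asymmetry terms are omitted:
the package's contribution is the iterative estimation framework, and the
energy model is pluggable — a fuller table with the same schema drops in.
RT defaults to 0.61633 kcal/mol (310.15 K); overriding the temperature
recomputes RT. The per-side terminal-penalty rule was chosen over the
per-helix-end bookkeeping of richer rule sets because it is expressible
identically in both the loop-decomposition scorer and the DP recursions,
which keeps the enumeration oracle and the DP on the same model by
construction.

## Iteration schedule

Co-incidence matrices, identities and constraint sets are computed once.
Iteration t = 0 folds every sequence with the neutral prior. Iterations
t = 1…η use a synchronous (Jacobi) update: every extrinsic matrix of
iteration t is computed from the complete iteration t−1 snapshot, never
from a mixture. This makes results independent of sequence processing
order and thread count — per-sequence partition computations within an
iteration are embarrassingly parallel and the thread pool only changes
wall time, bitwise-never results. Co-incidence probabilities are *not*
updated across iterations. A single-sequence input degenerates to the
plain partition function with a warning.

## Structure prediction

*Thresholding* keeps pairs with probability strictly above P_thresh. Above
0.5 the per-position probability mass constraint forces a valid
pseudoknot-free structure; at or below 0.5 crossing or conflicting pairs
are possible, the result is flagged `unchecked`, and the CLI writes a
plain pair list instead of dot-bracket. The CLI default in threshold mode
is 0.51, the smallest round value that preserves the guarantee.

*Maximum expected accuracy* maximises Σ w·p(i,j) + Σ q(i) (q = unpaired
probability, default pair weight w = 2, counting both nucleotides of a
pair) with a Nussinov-style O(N³) DP. Ties prefer leaving a position
unpaired, then the nearest partner — deterministic across platforms. No
minimum-hairpin constraint is imposed in the DP; pairs below the hairpin
minimum carry zero probability from the partition module, so the
constraint is inherited where it matters, and the brute-force MEA oracle
searches the identical structure space.

## Scoring

Sensitivity and PPV use single-position slippage: a predicted pair (i, j)
is correct if the known structure contains (i, j), (i±1, j) or (i, j±1).
Sensitivity counts known pairs matched by at least one predicted pair
under the mirrored rule; PPV counts predicted pairs matched by at least
one known pair; the at-least-one counting prevents double counting. Zero
denominators report 0 and are flagged.

## Synthetic families

The generator emulates a family of homologs sharing a conserved fold: a
designed 76-nt three-arm cloverleaf template (a shape typical of small
structured ncRNAs) diverges by compensatory pair resampling at paired
positions (uniform over the six canonical pairs), point substitutions at
loop positions, and loop-restricted indels with per-member structures
remapped through the indels. Deletions that would shrink a hairpin loop
below the three-nucleotide minimum are suppressed, so every emitted
(sequence, structure) pair satisfies the energy model's preconditions. A
designated helix can be dropped per member with probability
`variable_arm_prob` (default 0), emulating variable structural elements.

The per-position mutation rate is derived from the target mean pairwise
identity by inverting a closed-form expectation of the identity between
two independent mutants (loop match probability (1−r)² + r²/3; paired-
position terms use the frequency of each nucleotide among canonical-pair
ends). Defaults — K = 5, identity 0.5, indel rate 0.02 per loop
nucleotide — give families at the hard end of the comparative-folding
regime (40–70% identity). Realised Viterbi-based identity lands within a
few points of target (validated over seeds in the tests). What the
generator does *not* emulate: phylogenetic correlation (all members are
independent draws from the template), rate heterogeneity, non-loop indels
and structure rearrangements beyond the optional arm; pipeline accuracy on
these fixtures therefore shows that the estimator propagates and exploits
homolog information correctly, not how it performs on real, tree-
correlated families.

## Problem sizes used in the shipped checks

Oracle cross-checks run at the largest sizes where exhaustive enumeration
is exact and fast: N ≤ 18 (partition), N ≤ 5 per sequence (alignment
paths), N ≤ 14 (MEA). Pipeline-level checks use families of five 76-nt
members over 20 seeds; scaling checks run single 500-nt folds and one
500×500 alignment. These sizes exercise every recursion branch
(multibranch loops included) while keeping the default test run fast.

## Known limitations

* The simplified energy model is not Turner-complete; absolute free
  energies and probabilities differ from RNAstructure/ViennaRNA outputs.
* No structural alignment is produced — only per-sequence probabilities
  and structures.
* HMM parameters are sensible defaults, not trained values.
* Pseudoknots are outside the model everywhere except sub-0.5
  thresholding output, which is reported as a raw pair list.
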