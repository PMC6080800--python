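# Methods

## Model and scope

`phikit` analyzes discrete Markovian dynamical systems of `n` binary
elements. The system is fully specified by its transition probability
matrix; the analysis assumes (and, for state-by-state input, verifies) the
*conditional independence* of the elements' next states given the current
system state — each node's update depends only on the joint state at `t`,
with no instantaneous interaction. Only under this Markov factorization does
the compact state-by-node representation exist, and it is what licenses the
per-node factorization of repertoires used throughout.

All probability distributions over past states are interventional: the
analysis perturbs the system uniformly rather than weighting states by their
stationary frequency, so marginalization over perturbed nodes is always the
unweighted mean over their states. State indexing is little-endian
everywhere (first node = least-significant bit), including flattened
repertoires (column-major reshapes).

## Repertoires

The effect repertoire of mechanism M over a single purview node is obtained
from the node's own TPM by fixing the mechanism parents in their current
state and averaging over the remaining parents; multi-node purviews are the
tensor product of the single-node repertoires. The cause repertoire of a
single mechanism node is the backward likelihood of its current state over
purview states (non-purview parents averaged), normalized by Bayes' rule
under a uniform prior; multi-node mechanisms multiply likelihoods and
renormalize (the constant K). This per-node factorization realizes
*independent* virtual noise on every input: shared noised parents do not
induce correlations between their targets. The test suite checks the
factored computation against a literal state-enumeration oracle that applies
the fixing/noising semantics directly to the 2-D TPM.

Degenerate cases: a cause repertoire with K = 0 (the analyzed mechanism
state cannot be produced by any purview state — possible because any binary
state may be analyzed, reachable or not) is returned as an all-zero tensor
with a flag, and the MIP treats such a pair as trivially reducible (φ = 0).
A partition part with an empty purview contributes the multiplicative
identity; a part with an empty mechanism contributes the unconstrained
repertoire (uniform for causes, per-node mean activation for effects). If a
*partitioned* repertoire is all-zero (a part with K = 0), it is not a
probability distribution; that partition is scored as maximally distant so
it is never selected as the MIP.

## Distances

Repertoire distance is the earth mover's distance with the Hamming distance
between purview states as the ground metric. Cause-side comparisons solve
the transportation problem exactly: shared mass is cancelled (optimal for
any zero-diagonal metric ground cost), and the residual is solved by a
successive-shortest-augmenting-path min-cost-flow kernel (numba-compiled;
dense Bellman-Ford per augmentation, which at ≤ 16 bins a side is both fast
and robust to floating-point degeneracy; a scipy LP is the fallback for the
never-observed degenerate abort, and the LP is also the independent oracle
in the tests). Effect repertoires are always products of their single-node
marginals (by conditional independence), and for product distributions the
EMD reduces to the sum over nodes of |Δ Pr(node ON)| — used for every
effect-side comparison.

The distance between two cause-effect structures is an EMD in concept
space: each concept is a transport bin with mass φ; the ground distance
between two concepts is the repertoire EMD between their cause repertoires
expanded to the full subsystem plus the same for their effect repertoires;
each side has an additional *null concept* bin (the subsystem's
unconstrained cause and effect repertoires) that absorbs surplus mass, with
null-to-null transport free. Concepts identical in mechanism, φ and
repertoires are cancelled first (they transport at zero cost). A concept is
expanded with the unconstrained repertoires of *its own* subsystem, so
concepts of a cut system fill in non-purview nodes with the cut system's
marginal activations.

## Partitions, cuts, and search

Mechanism-purview partitions are unordered bipartitions
{(M1, P1), (M2, P2)} with M1 ⊔ M2 = M, P1 ⊔ P2 = P and neither part
(∅, ∅); each partition is enumerated once (swapped part orders are the same
factorization, so multiplicity cannot affect the minimum). Other
partitioning schemes and distance measures are configuration registry hooks
that raise if selected. φ and Φ are rounded to 6 decimal places before
comparison, which makes zero-detection and tie-breaking robust; the row-sum
and conditional-independence checks use an absolute tolerance of 1e-10.

Tie-breaks are fixed for reproducibility: among equally maximal purviews the
larger wins, then the lexicographically smallest; among equal partitions or
cuts, the first in the deterministic enumeration order; among equal-Φ
subsystems, the larger node set, then lexicographic.

System cuts are the 2^n − 2 unidirectional bipartitions (all ordered pairs
of nonempty complementary parts); the `cut_one` approximation restricts to
the cuts isolating a single node (2n, fewer when n = 2 where the orders
coincide), which can only raise the minimum and hence upper-bounds Φ. A cut
is applied by marginalizing each severed source out of its target's node
TPM and recomposing the subsystem TPM; the partitioned CES is recomputed
from scratch from the cut system unless `no_new_concepts` restricts
candidate mechanisms to those with unpartitioned concepts (no bound either
way). A cut that severs no edges present in the connectivity matrix leaves
the node TPMs bit-identical, so its CES distance is 0 without recomputation;
since distances are nonnegative, the cut search stops early when it reaches
0. This is also why a subsystem whose connectivity graph is not strongly
connected has Φ = 0 — some unidirectional bipartition crosses no edges —
and that short-circuit is applied before any computation (it can be disabled
per call to audit it, which the tests do).

Two connectivity optimizations prune mechanism-level work: if the bipartite
graph between mechanism and purview (edges per the connectivity matrix, in
the direction under analysis) is disconnected, the repertoire factors
exactly across the components and φ = 0 without a search. Both shortcuts
log when they fire so optimized and exhaustive runs can be compared.

Single-node subsystems have Φ = 0 by convention (no admissible bipartition).
State reachability is not checked: any binary state may be analyzed.
Complexes are found by greedy peeling: take the maximal-Φ subsystem, exclude
everything overlapping it, recurse on the remainder.

## Configuration and determinism

Defaults (EMD repertoire distance, extended-EMD CES distance, bipartitions,
exhaustive cuts, precision 6) reproduce the worked 3-node example end to
end: Φ = 1.916666 (printed as 1.92 at two decimals) with minimal cut
AB → C. All analysis code is deterministic; randomness exists only in the
fixture generator, which derives everything from an explicit integer seed.
Parallel cut evaluation (joblib) preserves the serial enumeration order and
reduction, so its output is identical to serial execution.

## Synthetic fixtures

The generator produces two families used by the tests:

* `random_boolean(n, density, noise, seed)` — each node samples its parent
  set (each candidate parent with probability `density`) and a uniform
  random Boolean truth table over those parents; the output is flipped with
  probability `noise`. With `noise = 0` these are classical random Boolean
  networks; `density` controls how often the connectivity graph is strongly
  connected.
* `noisy_majority_chain(n, noise, seed)` — a circular chain of bidirectional
  edges, each node the majority of its two neighbors (ties → 0.5) with flip
  probability `noise`.

Study conditions used by the verification suite, chosen a priori: the
strong-connectivity theorem is exercised on 50 seeded `random_boolean`
networks with n ∈ {3, 4} and density 0.5 (sparse enough that non-strongly-
connected graphs are common), noise 0; the cut-one bound on 20 seeded 4-node
networks with density 0.75 and noise 0.1 (dense and stochastic, so most
candidates are strongly connected and Φ > 0 is common); oracle equivalence
on 3-node networks with density 0.6 and noise 0.1; the analytic-EMD theorem
on 1000 uniformly random marginal pairs over 1–4 nodes. The 5- and 7-node
majority chains are generator smoke tests only.

What the fixtures do not emulate: real biological networks have structured
(non-uniform) wiring, multi-valued or continuous states, and TPMs estimated
from observed time series rather than perturbations. Passing tests show the
algorithmic pipeline is exact for binary interventional TPMs; they say
nothing about the validity of applying the analysis to observational data,
where conditional independence may fail.

## Known limitations

Runtime is exponential in system size (states, mechanisms, purviews,
partitions and cuts all grow combinatorially); exact analyses here are
practical to roughly 5–6 nodes, and the verification suite sizes its random
studies at n ≤ 4. Elements must be binary. The repertoire-distance and
CES-distance registries ship only the EMD variants; KLD/L1 measures and
wedge/tri-partition schemes are unimplemented hooks. Memoization is
per-subsystem and in-run only (keyed by direction, mechanism, purview);
there is no persistent cache.
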