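# Methods

## Scope and model class

`pkdesign` designs RNA sequences that fold, at thermodynamic
equilibrium, into a single target secondary structure that may contain
pseudoknots, by minimizing the normalized ensemble defect with an
adaptive defect-weighted stochastic local search.  The supported
structure class is the *two-page* class: pair sets whose crossing graph
(pairs (i,j), (k,l) cross iff i < k < j < l) is bipartite, i.e.
structures decomposable into two pseudoknot-free ("nested" and
"non-nested") pages.  Page assignment is canonical: within each
connected crossing component the 5'-most pair takes page 1 and the
2-coloring is propagated; input dot-bracket pages (round = page 1,
square = page 2) are trusted but re-validated.  The minimum hairpin
loop is two unpaired bases (a pair (i, j) requires j >= i + 3).

## Equilibrium quantities

For a sequence phi of length n over an ensemble Gamma of admissible
structures, the package computes

* the partition function Q = sum_tau exp(-dG(phi, tau)/kT),
* the equilibrium probability p(phi, tau) = exp(-dG/kT)/Q, reported as
  the *Boltzmann frequency* B_f when used to measure target dominance
  (the two expressions are identical and are computed once),
* the augmented base-pair probability matrix P (n x (n+1); the last
  column holds unpaired probabilities, rows sum to 1) and its page
  split P' (nested) + P'' (non-nested) = P,
* the ensemble defect n(phi, tau) = n - sum_{i,j} P_ij S_ij over the
  augmented matrices, with S the 0/1 structure matrix of the target,
  and its normalized form N = n(phi, tau)/n,
* the probability defect pi = 1 - p(phi, tau),
* the MFE defect mu: the per-position structure Hamming distance
  between the predicted MFE structure and the target (unpaired vs
  paired counts as disagreement; a wrong partner counts once per
  endpoint), so mu = 0 exactly when the MFE structure is the target,
* the sequence identity S_id of a designed set: the mean over
  unordered distinct sequence pairs of the fraction of identical
  positions (the raw sum in the usual formula is not normalized; this
  convention keeps S_id in [0, 1] and preserves its comparative use).

## Energy model

Full nearest-neighbor pseudoknot thermodynamics is deliberately out of
scope; the package uses a configurable additive model chosen to keep
an exact, exhaustively enumerable ensemble:

| parameter      | default | units    | meaning                                   |
|----------------|--------:|----------|-------------------------------------------|
| AU             |    -2.0 | kcal/mol | per A-U pair                               |
| GC             |    -3.0 | kcal/mol | per G-C pair                               |
| GU             |    -1.0 | kcal/mol | per G-U wobble pair                        |
| `pk_penalty`   |    +0.5 | kcal/mol | per page-2 pair                            |
| `pk_init`      |    +3.5 | kcal/mol | once per pseudoknot (crossing component)   |
| T              |  310.15 | K        | temperature; kT = 0.0019872 * T = 0.6163   |

The pseudoknot *initiation* term follows the functional form of
standard pseudoknot energy models (a one-time penalty per pseudoknot
plus a small per-pair term).  It is load-bearing: with a per-pair
penalty alone, a single spurious crossing pair costs at most
`pk_penalty` against a -2 or -3 pairing gain, so the two-page ensemble
of any sequence is irreducibly diffuse and low-defect design is
impossible in principle.  The default 3.5 exceeds the strongest pair
energy (|GC| = 3.0), making isolated crossing pairs always
net-destabilizing while multi-pair pseudoknot helices remain
favorable.

A known limitation of the whole model class (any per-pair additive
energy, with or without the initiation term): a pseudoknotted target
with h pairs, h2 of them on page 2, always competes against nested
rewirings of the same complementary letters, which pay no pseudoknot
cost.  Writing |e| for a pair energy, the two requirements "a stray
crossing pair is net-destabilizing" (pk_init + pk_penalty > |e|) and
"the target beats its (h-1)-pair nested rewiring"
(|e| > pk_init + pk_penalty * h2) sum to an impossibility for h2 >= 2,
and free (loop/tail) positions always leak because every RNA letter
has at least one pairing partner class.  Consequently the minimum
achievable normalized ensemble defect on short pseudoknotted targets
under this model is of order 0.1-0.4 (measured by independent greedy
search over compatible sequences), not the ~0.01 reachable with
nearest-neighbor loop-based energies.  Pseudoknot-free targets do not
suffer from this and design to N ~ 0.01 readily.  What passing tests
show, therefore, is that the machinery (ensemble, metrics, operators,
loop) is correct and that the search behaves as specified — not that
this energy model reproduces the design quality reachable with a full
thermodynamic parameter set.

Energies of fixed (sequence, structure) pairs use the structure's own
page labels; ensemble enumeration uses the canonical split.  The two
agree whenever the 5'-most helix of each pseudoknot is written in
round brackets, which holds for every bundled and generated target.

## Backends

All backends return the same containers (P, P', P'', plus partition
function, structure count and MFE structure); callers never branch on
backend identity.

* `exact` — exhaustive enumeration of the two-page ensemble by an
  iterative depth-first search over partial matchings with an
  incremental bipartiteness check (a parity union-find with rollback;
  a branch is pruned as soon as its crossing graph acquires an odd
  cycle).  Boltzmann weights are accumulated as exp((E_lb - E)/kT)
  against a precomputed lower bound E_lb, so no overflow is possible.
  The ensemble grows roughly like 2.4^n (about 2 x 10^4 structures at
  n = 16, 10^7 near n = 24), so the backend refuses n > 26 by default.
  The MFE structure is tracked in the same pass; energy ties break to
  the lexicographically smallest dot-bracket string.
* `nested` — inside/outside dynamic programming over the
  pseudoknot-free ensemble: O(n^3) inside, O(n^4) outside, with
  per-nucleotide rescaling anchored at the nested MFE so tables stay
  in double-precision range for sequences of hundreds of nucleotides.
  The MFE traceback composes, per segment, the lexicographically
  smallest optimal dot-bracket, reproducing the exact backend's
  tie-break.  P'' is identically zero.
* `nupack` — a feature-gated subprocess adapter around an external
  pseudoknot-capable `prob` program; active only when the binary is on
  PATH.

The exact backend doubles as the oracle: a second, independently coded
reference enumerator (plain recursion in the package; subset iteration
with networkx bipartiteness in the tests) validates it structure by
structure.

## The designer

One trial follows the published algorithm shape: draw a random seed
compatible with the target (template positions copied verbatim; paired
positions drawn jointly as pair types; unconstrained positions
approximate the requested GC content, or a GC fraction drawn uniformly
from [0.20, 0.80] when unset), then iterate: choose a mutation
operator uniformly at random from the applicable subset, mutate,
re-evaluate P, P', P'', N, pi.  The loop stops when N <= f_stop or
after max_it iterations, and the fittest (lowest-N) candidate observed
is returned.  There is no accept/reject on N: the walk's only guidance
is *where* it mutates.

* Operator 1 draws unpaired positions uniformly, skips template-locked
  ones, accepts position i with probability 1 - P[i, n+1], and
  replaces the base with one of the three alternatives uniformly.
* Operator 2 draws target pairs uniformly; both-ends-locked pairs are
  skipped; one-end-locked pairs mutate the free end to another allowed
  partner immediately (no probability gate); free nested pairs are
  accepted with probability 1 - P'[i, j] and reassigned from
  {A-U, G-C, G-U}; free non-nested pairs with 1 - P''[i, j] from all
  six orientations.  The asymmetric nested alphabet is kept as the
  algorithm defines it; a configuration switch
  (`nested_pair_all_orientations`) enables all six orientations.
* Operator 3 draws m = floor(|Normal(m', m'/5)|), clamped to >= 1,
  with m' = N * n / C (C = 5 by default), then applies single/pair
  mutations chosen by uniform random positions until the counted total
  reaches exactly m (a pair step counts 2 even if only one base
  changes; when one count remains, a single-nucleotide step is forced
  so the total lands on m; if the target offers only pairs, the final
  pair step caps the count at m).

Numerical/degenerate-case choices:

* Operator selection is uniform over the *applicable* subset: a target
  with no unpaired position excludes operator 1, one with no mutable
  pair excludes operator 2; a literal uniform 1..3 draw would deadlock
  on such targets.
* The acceptance loops of operators 1-2 are bounded by a retry cap
  (default 100 * n draws); past it, site selection falls back to an
  ungated uniform choice among mutable sites.  In non-degenerate
  regimes the cap is never reached; it only matters when every
  candidate site already has acceptance probability near 0.
* "Resample until different" steps draw uniformly from the
  alternatives excluding the current assignment — equivalent to
  rejection sampling but loop-free.
* Each trial k of a campaign uses `default_rng((base_seed, k))`;
  results are bit-reproducible from the configuration alone.
* Template safety is asserted on every iteration (O(n) against the
  O(ensemble) evaluation, so it is always on).

## Synthetic targets

The generator emulates the structural character of curated natural
pseudoknot collections (H-type dominant) at desk scale: a nested helix
whose loop hosts the 5' half of a second helix closing downstream, so
every page-2 pair genuinely crosses page-1 pairs; gap lengths are
drawn randomly subject to the minimum-loop constraints.  Named suites:

* `toy` — hand-built cases plus an 85-nt hammerhead-ribozyme target
  with its conserved-motif template (CCUGAUGAG / GCGAAA / UCG locked,
  67 free positions).  The hammerhead secondary structure is a
  *synthetic reconstruction*: the published dot-bracket is typeset
  with ellipses, so loop lengths were reconstructed to be consistent
  with the 85-character template and the printed stem/pseudoknot
  skeleton.
* `desk` — 20 two-page pseudoknotted targets of 15-16 nt.  The length
  cap keeps one exact-backend evaluation at a few milliseconds, which
  is what makes full 400-iteration design loops affordable inside a
  test run; the trade-off against the published benchmark (21-140 nt)
  is size only, not structure class.
* `bench` — 20 targets of 21-35 nt for structure-level and
  file-format work; full design loops on these would need the
  out-of-scope polynomial pseudoknot partition function, since their
  exact ensembles reach 10^7-10^13 structures.

What the generator does *not* emulate: natural base-composition bias,
loop-length distributions of real families, and any tertiary or
kissing-loop interactions.

## Trial statistics

Per-target campaign summaries report f^k (trials with N <= 0.01 by
default), the success count (mu = 0), medians of N, pi, dG, B_f and
iterations (numpy convention: even-length medians average the two
central values), and S_id.  Method comparisons count per-target wins
on a chosen metric (lower-better for defects and S_id, higher-better
for B_f and success counts), exclude ties, and report a two-sided
exact sign-test p-value (binomial, p = 1/2).

## Known limitations

* The model-class limitation above: pseudoknotted targets cannot be
  designed to N <= 0.05 under any parameterization of this additive
  model; the convergence statistics bundled with the package document
  this honestly rather than hiding it.
* The exact backend is exponential; n > 26 needs the nested backend
  (which ignores the non-nested page) or an external folder.
* The nested backend's pi for a pseudoknotted target is clamped into
  [0, 1]: the target lies outside that backend's ensemble, so the
  ratio is a bound, not a probability.
* Wall-clock fields are recorded but never asserted on
  (hardware-dependent).
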