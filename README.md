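# pkdesign

Inverse folding for pseudoknotted RNA: design sequences that fold, at
equilibrium, into a single target secondary structure that may contain
pseudoknots, by minimizing the *normalized ensemble defect* with an
adaptive defect-weighted stochastic local search.

The package is aimed at desk-scale methodological work: it carries an
**exact** equilibrium ensemble (exhaustive enumeration of all two-page
structures of a sequence, with a simplified additive energy model)
instead of an approximate polynomial folding engine, so every
probability, defect and design decision can be verified against brute
force.  Structures are restricted to the *two-page* class — pair sets
decomposable into two mutually non-crossing groups, written in
dot-bracket notation with `()` for page-1 and `[]` for page-2 pairs.

## The quantities

For a sequence φ of length *n*, a target structure τ, partition
function *Q* = Σ_τ' exp(−ΔG(φ, τ')/k_BT) and augmented pair-probability
matrix *P* (last column = unpaired probabilities):

* **ensemble defect** n(φ, τ) = *n* − Σ_{i,j} P_ij S_ij(τ), the
  expected number of incorrectly paired nucleotides at equilibrium,
  and its normalized form **N** = n(φ, τ)/*n* — the design objective;
* **probability defect** π = 1 − p(φ, τ), with p = exp(−ΔG/k_BT)/Q
  also reported as the **Boltzmann frequency** B_f;
* **MFE defect** μ: per-position distance between the minimum
  free-energy structure of φ and τ (μ = 0 defines design success);
* **sequence identity** S_id of a set of designs: mean pairwise
  fraction of identical positions.

One design trial seeds a random compatible sequence (honoring an
optional design template that locks conserved nucleotides) and then
repeatedly mutates it with one of three operators chosen uniformly at
random: a single unpaired position (accepted with probability
1 − P_{i,n+1}), a single target pair (gated by 1 − P′_ij for nested
and 1 − P″_ij for pseudoknot pairs), or an adaptive *m*-mutation that
applies m ≈ N·n/C positional mutations at once.  The loop stops when
N ≤ f_stop or after max_it iterations and returns the fittest
candidate observed.

## Worked example

```python
from pkdesign import DesignConfig, design, parse_dot_bracket

target = parse_dot_bracket("((((....))))")
res = design(target, config=DesignConfig(f_stop=0.05, max_it=400, rng_seed=7))
print(res.sequence, res.N, res.pi, res.dG, res.mfe_defect, res.iterations_used)
```

prints

```
AGGGCAAACCCU 0.03618... 0.11909... -11.0 0 86
```

i.e. after 86 iterations the designer found a 12-mer whose equilibrium
ensemble mispairs on average 3.6% of nucleotides relative to the
target hairpin (N = 0.036 ≤ f_stop), folds into the target as its MFE
structure (μ = 0), and spends 88% of its Boltzmann ensemble on the
exact target (B_f = 1 − π = 0.881) at ΔG = −11 kcal/mol.

The same call on a pseudoknotted target documents the limit of the
simplified energy model rather than hiding it: additive pair energies
cannot thermodynamically isolate a pseudoknot from nested rewirings of
the same complementary letters, so N plateaus near 0.3–0.5 there (see
`docs/methods.md` for the analysis).

The command line mirrors the library:

```sh
pkdesign synth --suite desk --out targets.tsv        # synthetic two-page targets
pkdesign design --target targets.tsv --trials 5 --seed 1 --out results/
pkdesign evaluate --sequence GGGAAACCC --target "(((...)))" --fmt json
pkdesign filter targets.tsv                          # two-page class report
pkdesign benchmark targets.tsv --trials 5 --out summary.tsv
```

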