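# mothra

Pareto multiobjective Monte Carlo tree search for *de novo* molecular
generation over SMILES strings.

Early-stage drug discovery needs molecules that are good at several things
at once — binding the target, looking drug-like, staying non-toxic — and
these goals trade off against each other. Collapsing them into one weighted
score hides the trade-off and forces arbitrary weights (a QED of 0.5 and a
docking reward of 0.5 are not the same kind of "0.5"). This package instead
searches the chemical space for the **Pareto front**: the set of molecules
no other generated molecule beats on every objective simultaneously. It is
written for computational chemists who want a self-contained, scriptable
multiobjective generator with deterministic, testable parts.

## Method

Molecules are built token by token in a search tree whose root is the start
sentinel `&`; a root-to-node path is a SMILES prefix. Each search iteration
runs the four MCTS steps:

1. **Selection.** For a child *s* with visit count *n_s* and running mean
   reward vector *r̄_s*, form the component-wise upper confidence bound

   *U_i(s) = r̄_{s,i} + c_i √(2 ln N / n_s)*,

   clip it into [0, 1]^d, and score it by the hypervolume (Lebesgue measure
   of the dominated region above a reference point *z*, the origin here) it
   would add to the current Pareto front *P*:

   *W(s) = HV(P ∪ {U(s)}, z)* if *U(s)* is nondominated, otherwise
   *W(s) = HV(P, z) − dist(U(s), P)*,

   where the penalty is the Euclidean distance from the dominated UCB point
   to the nearest front point. Descend by argmax *W*.
2. **Expansion.** Add one child: the most probable next token under the
   rollout policy not yet in the tree (probability floor 10⁻³).
3. **Simulation.** A frozen recurrent SMILES language model (embedding +
   two GRU layers + softmax; an n-gram count model is the deterministic
   stand-in) completes the prefix. The string is sanitized, filtered on
   synthetic accessibility (SAscore ≤ 3.5), and scored into a reward vector:
   docking score *DS* → max(0, (DS_baseline − DS)/(1 + DS_baseline − DS)),
   QED used as-is, toxicity probability *p* → 1 − *p*. The front is updated
   incrementally.
4. **Backpropagation.** The reward vector (zero for invalid or filtered
   strings) updates *n_s* and *r̄_s* along the path.

With one live objective plus a constant dummy the node value ranks children
exactly as scalar UCB1, so the search degrades gracefully to ordinary
single-objective MCTS. Hypervolume is computed exactly (sorted staircase in
2-D, dimension-sweep recursion in higher dimensions). Run quality is
reported with the standard generative-model metrics: validity, uniqueness,
duplication ratio, novelty and internal diversity (1 − mean pairwise
Tanimoto over Morgan fingerprints, radius 2, 2048 bits).

## Worked example

A fully offline run — synthetic 60-molecule corpus, n-gram rollout policy,
deterministic mock objectives:

```python
import numpy as np, mothra

corpus = mothra.generate_fixture_corpus(60, seed=1)
policy = mothra.train_policy(corpus, mothra.PolicyConfig(max_length=40), kind="ngram")
evaluator = mothra.ObjectiveEvaluator([
    mothra.ObjectiveSpec("docking", "mock"),
    mothra.ObjectiveSpec("qed", "qed"),
    mothra.ObjectiveSpec("toxicity", "toxicity"),
])
cfg = mothra.SearchConfig(max_iterations=500, max_length=40, seed=1)
result = mothra.run_search(cfg, policy, evaluator)
print(f"rollouts: {len(result.records)}  valid molecules: {result.n_valid}")
print(f"Pareto front size: {len(result.front)}")
print(f"front hypervolume (z = origin): {result.front.hypervolume(np.zeros(3)):.4f}")
print(mothra.compute_metrics(result.records, corpus))
```

prints

```
rollouts: 500  valid molecules: 32
Pareto front size: 10
front hypervolume (z = origin): 0.2687
generated 500  valid 32  unique 17
validity            0.0640
uniqueness          0.5312
duplication ratio   0.4688
novelty             0.8824
internal diversity  0.9357
```

The 500 tree iterations yielded 32 sanitizable, filter-passing molecules;
ten of them form the current Pareto front, whose dominated volume above the
origin is 0.2687 (out of a maximum of 1 for a single perfect molecule). The
low validity is characteristic of the order-3 n-gram stand-in policy, which
cannot balance rings and branches; the trained GRU policy reaches over 90%
valid rollouts on the same corpus. High novelty and internal diversity say
the valid molecules are mostly new (not corpus members) and structurally
varied.

The same pipeline is available from the shell:

```sh
mothra fixtures --n 60 --seed 1 --out corpus.smi
mothra train    --corpus corpus.smi --out policy.npz --epochs 20
mothra run      --config run.yaml --checkpoint policy.npz
mothra metrics  --log mothra_out/generation_log.csv --corpus corpus.smi
mothra front    --log mothra_out/generation_log.csv --at 100
```

For a structure-based campaign, point an objective of kind `docking` at a
prepared receptor PDBQT with a box (center + extents in Å, exhaustiveness 1)
in `run.yaml`; receptor preparation itself is outside this package's scope.

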