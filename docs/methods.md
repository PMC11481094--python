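# Methods

## Model and procedure

The generator couples a frozen autoregressive SMILES language model with a
multiobjective Monte Carlo tree search. The tree's nodes are single
vocabulary tokens; a path from the root (the start sentinel `&`) is a SMILES
prefix, and the terminator `\n` closes a molecule. The search maintains an
archive of mutually nondominated reward vectors (the Pareto front) over all
valid, filter-passing molecules seen so far, and steers selection by how
much a child's optimistic reward estimate would enlarge the front's
hypervolume.

Key assumptions:

* rewards are shaped into [0, 1] with the maximization convention, so the
  hypervolume reference point can be fixed at the origin and the front's
  dominated volume is bounded by 1;
* the rollout policy is pretrained once and never updated during search —
  all adaptation happens in the tree statistics;
* objectives are deterministic functions of the molecule (stochastic
  engines such as docking are treated as deterministic given their own
  fixed seeds).

### Node value

For child *s* under a parent with *N* visits, the component-wise UCB1
vector is *U_i(s) = r̄_{s,i} + c_i √(2 ln N / n_s)*; unvisited children have
infinite priority. The vector is clipped to [0, 1]^d before scoring —
early-search exploration bonuses would otherwise dominate the hypervolume.
If the clipped point is nondominated with respect to the front *P*, the node
value is HV(*P* ∪ {U}, z); if it is dominated, the value is HV(*P*, z) minus
the Euclidean distance from U to the nearest front point. The nearest-point
penalty is an O(|P|) surrogate for a projection onto the front's attainment
surface; it is zero exactly on nondominated points, strictly positive on
dominated ones, and preserves the scalar-UCB1 ranking in the degenerate
single-objective mode (verified in the test suite), which is the behavior
the penalty exists to provide.

### The running mean as cumulative reward

Backpropagation stores the arithmetic mean of all reward vectors routed
through a node, updated incrementally (`mean += (r - mean)/n`). A mean
rather than a sum keeps UCB values bounded and comparable across visit
counts. Invalid and filtered rollouts backpropagate the zero vector — the
reward-space infimum under the clipping convention — and do count as
visits, so selection pressure moves away from regions that mostly produce
unparsable strings.

### Expansion

One child per visit, candidates ordered by policy probability, with a
probability floor (default 10⁻³) that prevents a full vocabulary-width
branch explosion. A node whose prefix has reached `max_length - 1` tokens
can only expand the terminator, so no sequence ever exceeds `max_length`.
When a node's candidates are exhausted it is marked fully expanded and
later selections simulate from it directly.

## Objectives and filters

* **Docking**: reward = max(0, x/(1+x)) with x = baseline − score; baseline
  defaults to 0 kcal/mol, so a score of −9.4 maps to 9.4/10.4 ≈ 0.904. The
  transform is strictly monotone below the baseline (it re-scales but never
  re-orders docking scores) and is isolated behind the `ds_baseline`
  parameter. The subprocess adapter runs AutoDock Vina (exhaustiveness 1,
  single lowest-energy Open Babel conformer, box as center + extents in Å)
  and parses the best-mode affinity; when the binary is absent a
  deterministic surrogate — an additive model of heavy-atom and ring counts
  clipped to [−14, 0] kcal/mol — is substituted with a warning.
* **QED**: the desirability aggregate is already a [0, 1] drug-likeness
  score and is used unchanged.
* **Toxicity**: reward = 1 − p for a predicted toxicity probability p. The
  predictor is a pluggable interface; the shipped implementation is a
  deterministic logistic surrogate over logP, aromatic-ring count and
  molecular weight, standing in for an externally trained classifier.
* **SAscore filter**: synthetic accessibility on [1, 10], computed by the
  fragment-contribution method; molecules above 3.5 are rejected before any
  objective is evaluated. The boundary is inclusive (3.5 passes) — the
  threshold is a published convention, the inclusivity a package choice.

Duplicate molecules are detected on canonical SMILES and served from a
cache, so objectives run once per distinct molecule; duplicates still enter
the generation log, where the duplication-ratio metric counts them.

## Policies

The recurrent policy is an embedding (default 81 dimensions) feeding two
256-unit GRU layers (tanh candidate activation) and a linear-softmax head,
trained with Adam (learning rate 0.01, batch 256, 100 epochs) by next-token
cross-entropy on sentinel-wrapped sequences. Those defaults are the
full-scale training configuration; the test suite trains reduced models
(24/64 dimensions, 20 epochs) on the synthetic corpus, which already reach
>90% valid rollouts. Sampling is multinomial at temperature 1.0 — the
simplest choice consistent with using the model as a stochastic rollout
policy; temperature, gradient clipping and validation splits are
deliberately not modeled. The network and its backpropagation through time
are implemented directly on NumPy arrays and checked against central finite
differences.

The n-gram policy (order 3, add-one smoothing, uniform on unseen contexts)
is a fully deterministic count model with the same interface. It exists so
the search is testable without training: every distribution it returns can
be recomputed by hand from the corpus. Its `alpha` smoothing parameter is
exposed; `alpha = 0` gives unsmoothed conditional frequencies, under which
a single-sequence corpus forces a unique rollout.

The tokenizer matches greedily, longest token first, so two-character
elements ("Br") and bracket atoms ("[C@@H]") never split. The default
vocabulary ships the standard atom/bond/bracket-atom inventory plus ring
digits and parentheses, which any real corpus requires; in normal use the
vocabulary is rebuilt from the training corpus and persisted inside the
policy checkpoint, and a checkpoint whose vocabulary disagrees with the
caller's refuses to load.

## Synthetic data

`generate_fixture_corpus` emulates a drug-like training set at miniature
scale: alkyl chains with occasional ether/amine/alcohol/acid/amide groups
(~75%) and singly substituted aromatic or saturated six-membered rings
(~25%), all RDKit-sanitizable, deterministic under a seed. It reproduces
the token statistics and grammatical structures (branches, rings,
heteroatoms) a SMILES policy must learn, but not the size, scaffold
diversity, stereochemistry or charge states of a real 250k-molecule ZINC
corpus. Tests passing on it therefore demonstrate the machinery — lossless
tokenization, learnable grammar, front bookkeeping — not chemical coverage
at production scale.

The toy spaces strip chemistry out entirely: strings over a 3-letter
alphabet scored by deterministic anti-correlated objectives (fractions of
the first and last letter under a shared length budget), small enough to
enumerate exhaustively. They provide the exact Pareto front the search is
graded against.

## Numerical choices

* Dominance is weak inequality plus strict somewhere; equal vectors never
  dominate each other, and equal rewards from different molecules share one
  front point with merged provenance.
* Hypervolume is exact: sorted staircase in 2-D, recursive slicing on the
  last objective for d ≥ 3, nondominated-filtering each slab. Oracles in
  the tests (inclusion-exclusion, Monte-Carlo box sampling) are independent
  implementations.
* Selection ties are broken by a seeded uniform draw; expansion ties by
  vocabulary order under a stable sort. All randomness in a run flows from
  one seed through one generator, which is what makes two equal-seed runs
  byte-identical.
* Front snapshots are taken when the valid-molecule count first reaches
  each entry of the checkpoint schedule (default 100/500/1000).
* Degenerate inputs: an empty front scores a node by its own box volume;
  truncated (never-terminated) rollouts are flagged and scored as invalid
  strings; metrics on a log with no valid molecules report zero uniqueness
  and diversity rather than dividing by zero.

## Problem sizes

The shipped tests and the acceptance script run at desk scale as a matter
of design: 60-molecule corpora, 250-800 search iterations for end-to-end
checks, 2000 iterations for toy-front recovery, 10⁶ Monte-Carlo points for
the 3-D hypervolume oracle, 100 rollouts for policy validity. The
full-scale configuration (250k-molecule corpus, the full 81/256 GRU, real
docking against a prepared receptor, multi-day search budgets) is expressed
by the same code paths via the config file but is not exercised by the test
suite.

## Known limitations

* The n-gram stand-in produces mostly invalid SMILES (it cannot count ring
  bonds or parentheses); it is a mechanism double, not a chemistry model.
* The projection penalty measures distance to the front's point set, not to
  its continuous attainment surface; with very sparse fronts the penalty
  can overestimate the distance to the dominated boundary.
* Exact hypervolume by dimension sweep is exponential in the number of
  objectives; it is comfortable for d ≤ 4, which matches the "many-objective
  problems need a different tool" stance of the method.
* Single-threaded by design — determinism is preferred over parallel tree
  search.
* The docking adapter assumes a prepared receptor PDBQT; protonation and
  charge assignment are out of scope.
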