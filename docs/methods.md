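# Methods

This note documents the model, the numerical and design choices behind the
implementation, what the synthetic benchmark does and does not emulate, and
the known limitations. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The decision process

The knowledge graph is strictly layered: drug → target → pathway → gene →
ADR, with edges directed along that hierarchy only. An episode starts at a
drug with a designated target ADR a★ and ends on entering any ADR node, on
a dead end, or after four transitions. The state is (vₜ, k, a★) with hop
count k ∈ {0,1,2,3}; admissible actions are out-neighbors on the next
layer, so hop count equals layer depth by construction and every episode
terminates within four transitions.

Rewards form a three-letter alphabet: +5 for entering a★, +1 per
on-structure intermediate hop, −5 for a wrong ADR. A dead end one layer
short of the sink also scores −5 (this case is underdetermined in the
problem statement; the penalty is exposed in `RewardScheme` and can be set
to 0). Wrong-ADR arrival is terminal — ADR nodes are sinks, so there is
nothing to backtrack to.

With γ = 0.946 the optimal return of the canonical four-edge episode is
1 + γ(1 + γ(1 + 5γ)) ≈ 7.0739; the test suite checks the trained Q against
an independent tabular value-iteration oracle on toy MDPs.

## The Q-network

Q(s, a) is computed from the concatenation [e_a; e_k; e_{a★}] of three
32-dim embeddings — the *action* node, the hop index, and the target ADR —
through an MLP (default 96→128→64→1, ReLU, dropout 0.3 between hidden
layers, scalar output). The hidden architecture is not pinned down by the
problem statement; two hidden layers are the smallest shape that trains
stably at the scales used here, and the widths are configurable. Dropout
is active only in training mode; evaluation is deterministic.

Note that the current node does not enter the encoding, only the action
being evaluated. Two consequences matter later: the learned Q generalizes
perfectly to unseen drugs (the first-hop value depends only on the target
reached), and explanations are identifiable only up to chains with equal
per-step Q (see "Explanation identifiability").

Node-embedding rows are initialized from the attribute feature vectors
(scaled to unit norm; random-normal where no attribute exists), step
embeddings are random-normal. This reconciles "learnable embedding
matrices" with attribute enrichment: attributes seed the tables, training
refines them (gradients do flow into both tables — asserted in the tests).

The network, backpropagation and Adam are implemented directly in NumPy.
The model is small enough that a framework would add dependency weight
without measurable speedup at these problem sizes; gradient correctness is
verified against central finite differences in the test suite.

The TD target is the standard one-step form
R + γ·maxₐ′ Q_target(s′, a′)·(1 − done), with a target network
synchronized every `target_sync_interval` episodes (default 25; setting it
to 1 emulates training without a separate target network). As printed in
the source description the bootstrap term references the current state,
which does not define a consistent update; the prose ("one-step
temporal-difference error") is unambiguous and is what is implemented.

## Training loop

The replay buffer (uniform, FIFO, capacity 10⁶) is pre-filled by
decomposing demonstration paths into four reward-labelled transitions
each, conditioned on the path's own endpoint ADR. A configurable fraction
of paths is retained (default 0.8, the quantity found sufficient in the
source ablation). Only paths starting at training-split drugs are used, to
keep the drug-level split leak-free. Each episode samples a training
(drug, ADR) positive, rolls out ε-greedily, appends transitions, performs
one batched Adam update (batch 173 by default, sampled uniformly without
replacement), anneals ε by ε′ = max(0.066, 0.987·ε), decays the learning
rate (exponential, factor 0.999/episode — the scheduler family is not
specified upstream and is config-exposed), and periodically syncs the
target network. Checkpoints are a portable `.npz` tensor archive with a
JSON sidecar.

Default hyperparameters are the published configuration (η = 8·10⁻⁴,
γ = 0.946, B = 173, ε-decay 0.987, ε-min 0.066, dropout 0.3, 32-dim
embeddings). For the scaled-down instances used in tests and the
acceptance script, the schedule is scaled accordingly, as the package's
own choice for those problem sizes: the 200-node benchmark trains 3000
episodes at η = 5·10⁻³; the 5-node single-chain MDP trains 400 episodes at
η = 10⁻², batch 16, dropout 0 (on a deterministic tabular-size MDP dropout
is pure gradient noise with nothing to regularize).

## Node features (all 32-dim)

* **Drugs** — binary Morgan/ECFP fingerprint, radius 2, 32 bits (RDKit).
* **Targets** — 20 relative residue frequencies (fixed order A..Y) plus
  sequence means of 12 per-residue scales. The scales are not named
  upstream; the package uses twelve standard published ones
  (Kyte–Doolittle hydropathy, Zamyatnin volume, Grantham polarity,
  isoelectric point, Vihinen flexibility, Zimmerman bulkiness, aromaticity
  indicator, charge at pH 7, H-bond donor count, Tien max ASA, and the two
  Chou–Fasman helix/sheet propensities), embedded as a constant table in
  `_scales.py`.
* **Pathways** — TF-IDF over whitespace member tokens (natural tf ×
  smoothed log idf, L2-normalized rows — the most common convention),
  reduced by PCA to 32 scores.
* **Genes** — relative overlapping 3-mer frequencies (64-dim, lexicographic
  ACGT order) reduced by PCA.
* **ADRs** — node2vec over the undirected view of the full heterogeneous
  graph: second-order walks with return p = 2 and in-out q = 0.5
  (depth-first-favoring), walk length 20, 100 walks/node, window 5,
  skip-gram with 5 negative samples, seeded. Whether to embed the full
  graph or an ADR projection is an open choice; the full graph is the
  default because it uses all relational context. The skip-gram averages
  gradients over each minibatch so the update magnitude is independent of
  how often a node recurs within a batch — per-pair updates diverge on
  small vocabularies.

PCA retains `min(32, n_samples, n_features)` components and zero-pads the
scores, with a warning, when fewer than 33 samples are available;
explained-variance fractions are reported, not asserted, because their
values are properties of the data. Missing attributes yield zero vectors
with a warning so partially annotated graphs still train.

## Scoring and explanation

`score_pair` runs a level-wise beam search (default width 10) from the
drug, conditioned on the query ADR, pruning partial paths by the Q of
their latest transition. The association score is the logistic of the best
terminal-step Q over complete beam paths (falling back to the best
first-hop Q when the beam completes nothing, and to 0 for a drug with no
out-edges). The upstream method reports AUC without defining the pair
score; this definition uses exactly the quantity the model learns and
degrades gracefully when no path exists. The classification threshold is
0.5 on the logistic score.

Ranked explanations (`top_k_paths`) enumerate all chains from drug to ADR
exhaustively when at most 10⁵ candidates exist (counted by layer-wise
dynamic programming), otherwise fall back to a wide beam. Paths are ranked
by the **sum of per-transition Q-values** (the estimated return of the
chain). Terminal-step Q cannot rank paths to the same ADR — it is
identical for all of them because the encoding sees only (action, step,
target) — while the summed Q discriminates via the intermediate hops.
Exact ties break lexicographically.

### Explanation identifiability

Because Q never sees the drug or the walk history, any two chains composed
of well-supported edges that reach the same target ADR have nearly equal
value. Explanation recovery on the synthetic benchmark is therefore
measured at the edge level: an explanation counts as recovered when every
edge it uses is a planted mechanism edge (i.e. it never rides a noise
edge). Recovery of one specific planted chain among several equally valid
mechanism chains is not identifiable under this state encoding, and the
acceptance script reports both fractions.

## Interpretability analyses

* **Similarity concordance** — per ADR with ≥ 8 drugs (threshold
  config-exposed; the source alternates between "at least" and "more
  than" eight), pairwise drug–drug cosine similarities of fingerprint
  vectors are Spearman-correlated with pairwise path–path cosine
  similarities; p-values are Benjamini–Hochberg adjusted across ADRs.
  A path's vector is the mean of the 32-dim attribute vectors of its
  target, pathway and gene nodes — a representation choice the source
  leaves open; it is symmetric across layers and uses the model's own
  features. When a drug has several explanation paths for one ADR the
  rank-1 path is used. Zero-variance similarity vectors make ρ undefined;
  such ADRs are flagged and excluded from the BH family.
* **Masking fidelity** — for each pair, the node cited by the explanation
  at a given level (target/pathway/gene) is removed and the pair
  re-scored; fidelity is the score drop, averaged over pairs. Negative
  values are legal and expected: removing a cited node can reroute the
  beam through higher-Q alternatives. Pairs whose drug is disconnected
  entirely by the masking are skipped with a log entry; an empty mean is
  an explicit error.

## The synthetic generator

`SyntheticSpec` plants `planted_pairs` drug→ADR mechanisms (spread
round-robin over drugs; defaults emulate the benchmark: 40/60/30/50/20
nodes per layer, 80 planted pairs ≈ 2 per drug, noise fraction 0.2). With
probability `mechanism_overlap` (default 0.5) a new pair for an
already-planted ADR reuses an existing (target, pathway, gene) chain, so
drugs sharing an ADR tend to share mechanism — the signal the concordance
analysis needs. Noise respects the hierarchy: every candidate (u, v) pair
not on a mechanism becomes an edge independently with probability
`noise_edge_fraction · edges_per_node / n_destinations`, giving a mean
noise out-degree of `noise_edge_fraction · edges_per_node` per source
node. Attributes are valid approved-drug SMILES from a built-in list of
130, random 100–400-residue protein sequences, random 300–900-nt
transcripts, and pathway member strings drawn from each pathway's actual
neighbors. Everything is reproducible byte-for-byte from the spec seed.

What the generator does **not** emulate: realistic degree distributions
(real KGs are scale-free; the generator is near-homogeneous), correlation
between drug chemistry and mechanism (SMILES are assigned at random, so
chemical similarity does not predict shared pathways the way it does in
curated data), edge confidence scores, and incomplete annotation. Passing
tests therefore demonstrate that the machinery learns and explains planted
relational signal at realistic scale — not that the model attains any
particular performance on curated pharmacological databases.

## Numerical choices and degenerate inputs

Adjacency lists are sorted lexicographically, making enumeration, greedy
rollouts and argmax tie-breaking deterministic; all stochastic components
take explicit generators or seeds, and the pipeline fans a single global
seed out to stages by fixed offsets. AUC uses the Mann–Whitney rank
statistic with midrank tie credit; metrics with zero denominators raise an
explicit error rather than returning silent zeros. Pruning keeps
unconfident-scored edges, removes duplicates, and deletes every node not
on a complete drug→ADR chain (for intermediates, both an incoming chain
from a drug and an outgoing chain to an ADR); between two surviving nodes
every hierarchy edge lies on a complete chain, so edge filtering by
endpoint survival is exact. Pruning is idempotent and never adds anything.

## Known limitations

* Explanation identifiability is limited as described above; with richer
  state encodings (walk history, drug conditioning) this would change, at
  the cost of departing from the published formulation.
* Fold-level cross-validation dispersion is dominated by fold size at
  benchmark scale: a fold holding out ~8 drugs contributes only ~16
  positive and 16 negative pairs, so the sampling standard deviation of a
  fold AUC is of order 0.1 regardless of model quality, and the share of
  graph-reachable sampled negatives varies between folds. CV on the
  synthetic task measures this combination, not model instability.
* Target features are composition-level only; binding-site topology and
  conformation are out of scope.
* Prioritized replay, double/dueling variants, and GPU execution are
  deliberately not implemented.
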