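# Methods

## Overview

`gtam` couples two views of a molecule — the topological bond graph
(`Graph2D`: typed atoms, typed bonds stored in both directions) and the 3D
conformation (`Graph3D`: coordinates in Å with the fully connected pairwise
distance map, no cutoff) — through a pair of encoders built on a *geometric
triangle awareness* update, and trains them with cross-modal objectives:
edge-level supervision in both directions, noise-contrastive node
discrimination through two conditional diffusion score networks, denoising
score matching for both generation directions, and an optional InfoNCE term
on pooled molecule embeddings.

## Compute substrate

No tensor-autodiff framework is assumed: the package carries a small
reverse-mode automatic-differentiation engine over NumPy arrays
(`gtam.autodiff`) and a layer library on top of it (`gtam.nn`: Linear with
Glorot-uniform init, LayerNorm with learned affine, SiLU MLPs, Adam with
global-norm gradient clipping at 10).  Everything runs in float64 on CPU.
At the molecule sizes this package targets (3–12 heavy atoms) that choice
costs little and buys exact reproducibility and oracle comparisons at
1e-5–1e-6 tolerances.  All parameter initialization and every stochastic
operation is driven by an explicit integer seed; runs are bit-reproducible
single-threaded.

## Triangle awareness updates

Both encoders maintain per-node embeddings `h` (N × D_h) and per-ordered-pair
embeddings `z` (N × N × D_z) and iterate blocks of four residual updates:

1. **node-to-edge**: `z_uv += Linear(f(h_u) ⊙ f(h_v))`, `f = Linear∘LayerNorm`.
   The product is elementwise by default (commutative, so undirected bonds
   keep `z_uv = z_vu`); an outer-product variant is available behind
   `EncoderConfig.tensor_product="outer"`, with the node projection reduced
   to `outer_rank` so the flattened outer product stays tractable.
2. **triangle multiplicative**: for each pair `(u,v)`, the admissible third
   vertices `w` contribute `LN(z_uw) ⊙ LN(z_vw)`; the sum is LayerNormed,
   linearly projected, gated by `sigmoid(Linear(z_uv))`, and added.
3. **triangle attention**: per head, logits `q_uv·k_wv/√d_head + b_wu` over
   admissible `w` (the printed single-head form is recovered exactly with
   `n_heads=1`; multi-head splits D_z into slices).  The third-edge bias
   `b_wu` is how each edge sees the triangles it closes.  The gated
   attention sum is added residually.  The bias/key orientation follows the
   printed index pattern `(k_wv, b_wu)` as-is.
4. **edge-to-node**: `h_u += MLP(Σ_v LN(z)_vu) + MLP(Σ_v LN(z)_uv)` — two
   independent three-layer MLPs over the row and column aggregations.

**Admissible third vertices.** On the fully connected 3D pair set, `W(u,v)`
is every node other than `u` and `v`.  On the sparse 2D bond graph the
multiplicative product needs both `z_uw` and `z_vw`, so the default is the
intersection `N(u) ∩ N(v)`; `EncoderConfig.w_set="union"` realizes the union
reading, with non-bonded pair embeddings materialized as the learned
no-bond vector that initializes them.

**Empty sets are identities.** An edge that closes no triangle, and a node
with no incident pairs, pass through unchanged — this avoids LayerNorm of a
zero vector and makes the residual structure testable exactly.

## Encoders

*GTA-2D* initializes `h` from summed embeddings of element (11-way
vocabulary {H,C,N,O,F,P,S,Cl,Br,I,other}), formal charge (clipped to ±2)
and aromaticity, then applies two bond-aware GIN layers
(`h' = MLP((1+ε)h + Σ_v ReLU(h_v + bond_emb))`, sum aggregation), exposing
two-hop topology before the triangle blocks run on the bonded pair set.
Pair embeddings start from a 5-class bond-label embedding (single, double,
triple, aromatic, no-bond), so every ordered pair carries a defined vector.

*GTA-3D* initializes `h` with one continuous-filter convolution: a filter
MLP over a Gaussian radial basis (32 centers spanning 0–5 Å) of each
interatomic distance, multiplied into the neighbour embeddings and summed;
pair embeddings are a linear image of the same basis.  Every downstream
quantity therefore depends on coordinates only through distances, giving
exact invariance to rotations and translations (verified to float
round-off, tested at 1e-4 relative).

Both encoders mean-pool node embeddings and project linearly to a
256-dimensional molecule vector.  Defaults are `D_h = D_z = 128`, 3 triangle
blocks, 4 heads; the tests and the acceptance script run widths 16–32 with
1–2 blocks, which preserves every property under test at a fraction of the
cost (problem sizes are stated in each run's config).

The 3D encoder accepts coordinates as a differentiable leaf, so energies
predicted from its outputs can be differentiated back to atom positions.

## Forward SDEs and score networks

Coordinates diffuse under a variance-exploding SDE (kernel std
`σ_min (σ_max/σ_min)^t`, defaults σ_min = 0.01 Å, σ_max = 2.0 Å); the 2D
node/edge features are first relaxed to continuous one-hots and diffuse
under a variance-preserving SDE (`β(t)` linear between 0.1 and 9.5) with
independent Brownian drivers for the node and edge channels.  `t_eps = 1e-3`
bounds the sampled times away from zero.  These constants are conventional
diffusion-model defaults and are config-overridable; nothing downstream
depends on their exact values.  Coordinates are centered before
perturbation so the translation-invariant score is well defined.

Both kernels are Gaussian, so the target score at a noised sample has the
closed form `-(x_t - mean)/std²`, used directly as the regression label
(labels never receive gradients).

The 2D→3D score network predicts invariant scalar pair weights from the 2D
condition embeddings of both endpoints, a radial basis of the current
noised distances, and `t`, and contracts them against relative coordinate
directions: rotation equivariant and translation invariant by construction.
The 3D→2D score network is a per-node / per-pair MLP over noised features
and the (already rigid-motion-invariant) 3D condition embeddings.  Both
output heads are zero-initialized, so the initial score is exactly zero and
the zero-network loss identity below holds at initialization.

## Training objectives

* **Edge losses.** The distogram loss projects 2D pair embeddings to 32
  logits over distance bins spanning [1.0, 2.4] Å (left-closed bins,
  absorbing end bins so distances outside the range clamp in and the loss
  stays total over all pairs; a `bonded_only` pair set matches the
  bonds-only normalizer reading).  The bond loss projects 3D pair embeddings
  to the 5 bond classes.  Both default to mean-per-pair (scale-stable
  across molecule sizes) with a literal-sum option.  Uniform predictions
  give exactly ln 32 and ln 5 per pair — frozen closed-form tests.
* **Node contrastive (EBM-NCE).** Matched (noised sample, condition) pairs
  are positives; in-batch mismatched pairs, drawn by a seeded derangement,
  are negatives; a scalar discriminator head over each score network's
  pooled invariant representation supplies the logit, and each modality
  contributes `-½E[log σ(D_pos)] - ½E[log(1-σ(D_neg))]` (zero logits give
  ln 2 per modality).  Because mismatched molecules differ in atom count,
  the discriminator pathway conditions on the molecule-level mean of the
  condition embeddings tiled to the sample's atoms — a molecule-level
  contrast that is size-agnostic by design.
* **Score matching.** Monte-Carlo denoising score matching with one uniform
  `t` per molecule and the conventional `std(t)²` weighting, under which a
  zero network has expectation equal to the perturbed dimensionality
  (3·atoms for coordinates; atoms·11 + ordered-pairs·5 for relaxed 2D
  features) — verified within 5% over 10⁴ draws.  The unweighted form is a
  config option.
* **InfoNCE (off by default).** Symmetric cross-entropy over cosine
  similarities of the pooled 2D/3D batch at temperature 0.1.
* **Total.** `L = α1(η1 L_node + η2 L_edge) + α2 L_2D→3D + α3 L_3D→2D
  (+ α4 L_infomax)`, all weights defaulting to 1 (α4 = 0), validated
  non-negative, and exactly linear (finite-difference checked).

## Synthetic paired molecules

The generator emulates exactly the regularity the cross-modal losses need:
bond type determines bond length.  Topologies are valence-respecting chains,
branched chains and 5/6-rings (aromatic six-rings with probability 0.6)
over {C, N, O}, 3–12 heavy atoms.  Coordinates are grown with standard
internal geometry — tetrahedral/trigonal/linear angles by bond order,
near-trans dihedrals with 8° jitter, planar rings, radial substituents —
with per-bond lengths drawn as type mean + N(0, σ_len), σ_len = 0.01 Å
(3σ below the smallest inter-mean gap of 0.05 Å, so type classes stay
separable; the constructor rejects specs violating this).  A short
steric-relaxation loop pushes residual non-bonded clashes beyond ~2.45 Å
while harmonically restoring bonds; this is best-effort and only
bonded-pair geometry is guaranteed.  Ring closure is kept exact by sharing
one jittered side length per ring, which slightly narrows the realized
length variance of ring bonds; per-type means remain within 2%.

What the fixtures do *not* emulate: conformational ensembles, torsional
diversity, stereochemistry, non-bonded physics, heteroatom-specific bond
lengths (all types use the carbon-class means), or real label noise.
Passing tests therefore demonstrate the *mechanics* of the objectives and
the claimed symmetries — not chemical accuracy on real molecules.

Labels: ring presence (classification), sum of bonded 3D lengths
(regression), and a harmonic bond-energy toy `E = Σ k(d_uv - d⁰_type)²`
with analytic forces (forces task).

## Downstream protocols

Classification fits a linear head, regression a 2-layer MLP head, on the
pooled 256-vector (encoder frozen or not by flag), reporting test ROC-AUC /
MAE; ROC-AUC is cross-checked in tests against a brute-force
pairwise-concordance enumeration.  Scaffold splits group molecules by
Bemis–Murcko scaffold, sort groups by descending size (seed shuffles ties)
and assign each to the split with the largest remaining deficit, train
first — so 10 singleton scaffolds at 8:1:1 give sizes 8/1/1 and a
single-scaffold set lands entirely in train.  One consequence worth noting:
all acyclic molecules share the empty scaffold, so on a ring-presence label
the scaffold test split is single-class by construction and the
classification overfit checks use balanced index splits instead.

**Forces.** The energy model for the force task is a bond-aware pairwise
radial-basis potential: `E = Σ_{u≠v} w[y_uv] · rbf(d_uv)` with the channel
selected by the 5-class 2D bond label and a 48-Gaussian basis over 0–5 Å.
Because the model is linear in `w`, force matching is exact least squares
on finite-difference feature Jacobians (with energy rows anchoring the
constant), and predicted forces are the negative coordinate gradient via
autodiff — consistent with finite differences of the energy to < 1e-3
relative.  This head replaces a pooled-embedding energy head for this task:
the pooled vector is a linear image of the mean node embedding, and while
it supports excellent energy *value* fits, its coordinate *gradient* is not
pinned down by value supervision at desk scale (we measured force cosines
near zero at energy R² ≈ 0.99 across frozen, unfrozen, jitter-augmented and
difference-supervised variants).  A per-pair potential is the standard
physically-structured alternative, is itself cross-modal (2D labels gate 3D
geometry channels), and recovers the toy forces essentially exactly.  A
generic pooled energy head remains supported in `predict_forces` for
experimentation.

Retrieval ranks a corpus by cosine similarity of pooled embeddings
(descending, ties broken by corpus index, computed with per-row dot
products so duplicate molecules tie bit-exactly) and reports ECFP4/Tanimoto
(radius 2, 2048 bits) alongside.

## Orchestration, checkpoints, determinism

`pretrain` computes all enabled loss components on the full fixture batch
each step, applies one Adam update (lr default 1e-4 for the package;
sanity-run configs in the tests use 3e-3), logs every component per step as
JSONL, and aborts naming the component and step if any loss goes
non-finite.  Checkpoints are self-describing `.npz` archives (config JSON +
parameter arrays + step + generator state); save→load→forward is
bit-identical, and a resumed run reproduces the next step's loss exactly
(the optimizer moments are not checkpointed, so later steps may drift at
float precision — documented, not load-bearing).  Determinism claims hold
single-threaded.

## Numerical choices and edge cases

* Attention masking uses additive -1e9 logits; rows whose admissible set is
  empty are excluded from the residual update rather than softmaxed.
* Distance maps built from differentiable coordinates add 1e-12 (and the
  identity on the diagonal) under the square root to keep gradients finite.
* Discrete labels (bins, bond classes, kernel scores) are plain arrays —
  no gradient flows into supervision targets.
* `bin_distance` is total: distances below/above the range clamp into the
  end bins; boundary values go to the higher bin (left-closed convention).
* Batch size 1 is rejected wherever in-batch negatives are required
  (node contrastive, InfoNCE).

## Known limitations

* Desk scale only: dense N³ triangle tensors and a pure-NumPy substrate cap
  practical molecule sizes at a few dozen atoms.
* No reverse-SDE sampling or conformer generation; the diffusion machinery
  exists for the training objectives.
* The node-contrastive discriminator contrasts molecule-level conditions
  (see above), a deliberately coarse reading of the per-node form.
* Fixture realism limits are listed above; none of the reported accuracies
  transfer claims to real chemical datasets.
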