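# Methods

This note documents the model, the numerical choices, and the limits of
what the desk-scale test battery demonstrates.

## Problem and model

Inverse folding asks for a sequence whose secondary structure equals a
given target. We frame it as sequential decision making: decode the
sequence left to right, one nucleotide per step, and learn per-position
action values `Q_θ(s_t, a)` — the expected cumulative future reward of
placing base `a` at position `t` — with deep Q-learning. Rewards come from
an *environment*: a function folding the finished sequence (and optionally
predicting its SHAPE reactivity profile) that is compared per position
against the target. The reward at `t` is the product of two indicators —
pairing status correct, SHAPE constraint satisfied — so a position earns
credit only when its structure is right, and the SHAPE term can only
subtract. SHAPE compliance is evaluated against the target pairing status;
because the product gates on structure correctness, this coincides with
the predicted status wherever the reward is nonzero.

### Action masking

At a paired position whose 5′ partner is already decoded, only canonical
complements are legal (A–U, G–C, G–U; so a decoded G leaves {C, U}, a
decoded A leaves {U}). The mask guarantees stem complementarity by
construction; what remains to be *learned* is everything the mask cannot
see: choosing loop bases that do not form spurious pairs, and choosing
among the allowed complements so that the global maximum-pairing structure
is exactly the target.

## The environment

The reference environment is deterministic and self-contained:

- **Folder** — Nussinov dynamic programming maximizing the number of
  canonical pairs subject to nesting and a minimum hairpin loop of 3
  (`j − i − 1 ≥ 3`). Traceback ties are broken by preferring "j unpaired"
  and then the smallest bifurcation index, so folds are unique and
  reproducible. This folder knows nothing about stacking energies or
  pseudoknots; it exists to make the whole learning loop exercisable and
  exactly checkable (its output is verified against exhaustive enumeration
  of all nested pairings at n ≤ 12).
- **SHAPE oracle** — paired positions react at 0.1, unpaired at 0.9, plus
  optional seeded Gaussian noise clipped at 0. The noise stream is derived
  from the sequence so the oracle remains a pure function.
- **Pair extraction** — predictors may return an L×L pairing-probability
  matrix instead of a structure; pairs are then extracted by maximum-weight
  linear assignment (`scipy.optimize.linear_sum_assignment`) on the
  symmetrized matrix, keeping mutually assigned pairs with probability
  ≥ 0.5 after zeroing the `|j − i| ≤ 3` band (chemically impossible
  pairs). Threshold and band are config keys — reward thresholds being
  wrong is a known failure mode, so nothing is implicit.

Neural structure/SHAPE predictors attach through the same two-method
interface (`fold`, `shape`) without changes elsewhere; they are outside
the scope of this package.

## Network

A small encoder–decoder in float64 numpy, differentiated with autograd.
Encoder: learned dot-bracket token embedding → unidirectional LSTM
positional encoding (added) → kernel-5 1-D convolution → contact-graph
message passing (row-normalized adjacency with self-loops, one ReLU-linear
round per layer, residual) → pre-norm multi-head self-attention blocks.
Decoder: base-token embedding plus an embedded paired/unpaired flag —
aligned to the *output* position, so the flag of position `t` accompanies
the input predicting `t` — then LSTM positional encoding, a causal
convolution (left padding only), and pre-norm blocks of masked
self-attention, cross-attention over the encoder context, and a
feed-forward layer; a final projection yields 4 action values (the padding
token receives none).

Defaults are deliberately small (embed 64, 2+2 layers, 4 heads; the toy
curriculum uses embed 32, 1+1 layers, 2 heads): the object of study is the
training scheme, not capacity. Initialization is seeded (Glorot for linear
maps, σ = 0.02 normals for embeddings); there are no stochastic layers, so
evaluation is deterministic by construction.

Stepwise decoding caches per-layer self-attention keys/values, the LSTM
carry, the causal-convolution window, and the cross-attention projections
of the context. Cache-based decoding reproduces the full forward pass to
float round-off (~1e-15 observed; tests allow 1e-4), which is the module's
central correctness oracle.

## Training

Each outer round alternates:

1. **Play** — one episode per target: epsilon-greedy decoding under the
   action mask (a single epsilon per phase), fold, reward. The driver
   decays epsilon linearly across rounds (default 0.5 → 0.05); starting
   exploratory makes the first-round reward reflect an untrained policy
   rather than initialization luck, and ending near-greedy measures the
   learned policy.
2. **Train** — over the freshly played episodes (the replay store is the
   latest play phase, consumed once; a multi-round buffer is out of scope):
   rewards are reweighted by `exp(mean r)`, the decoder input is the action
   sequence shifted right with START, the frozen target network supplies
   `max_a′ Q⁻` shifted left (zero at the terminal position — the episodic
   convention for the unspecified last slot), and the squared error at the
   taken actions is minimized with Adam (lr 1e-3 default) under
   global-norm gradient clipping (1.0). The target network is a frozen
   parameter copy synchronized every `target_sync_epochs` rounds (default
   1, i.e. after each round's training passes).

Discount defaults `γ_start = 0.95`, `γ_end = 0.5` span "look far ahead
early, act locally late"; no principled external value exists for these,
so both are explicit config keys.

### Desk-scale study conditions

The learning battery uses 50 random hairpins of length 20 (stems 3–8,
loops ≥ 3), structure-only reward, the Nussinov environment, 30 rounds,
2 gradient passes per round, batch 50. This fits in ~25 s on one CPU and
is robust across seeds (checked over several network/play seed
combinations during development). Held-out evaluation decodes 20 unseen
hairpins greedily and counts exact folds (base-pair Jaccard 1.0).

## Inference

- **Beam search** ranks prefixes by the *sum* of selected Q-values, raw
  and unnormalized (cumulative Q has no probabilistic meaning), expanding
  only mask-valid actions, with lexicographic tie-breaking for
  determinism. Width 1 is exactly greedy. Note a property worth knowing:
  because Q-values are not additively consistent, a *larger* beam is not
  guaranteed to finish with a better best-of-beam — the greedy path can be
  pruned at an intermediate step. The exhaustive beam (k covering the
  whole space) is an upper bound on every finite beam, and that is the
  soundness property the tests assert.
- **Random search** samples per position from softmax(Q/T) over valid
  actions, or uniformly with probability `uniform_prob`.
- **Rescue** groups fold-vs-target mismatch positions into target pairs
  (plus target-unpaired singles), and when at most `max_mismatch_pairs`
  (default 2) pairs are affected, enumerates the 6 canonical assignments
  per pair × 4 bases per single, refolding each variant; the first exact
  refold wins, else the best Jaccard if it improves the input. Under the
  Nussinov environment a broken pair in a dense fold-derived target often
  triggers a global refolding cascade that exceeds any small cap; rescue
  is therefore effective on locally perturbed designs (for example solved
  hairpins with one stem pair mutated, repaired essentially always) and
  deliberately refuses global repairs.
- **Screening** folds and SHAPE-profiles each candidate, deduplicates by
  sequence, and ranks by (Jaccard, combined consistency score)
  lexicographically.

## Scoring conventions

- Jaccard of base pairs is |P∩T|/|P∪T|, defined as 1.0 for two empty sets.
- SHAPE profiles are normalized so the 90th percentile (linear
  interpolation between order statistics) equals 1.0; an all-zero profile
  cannot be normalized and is an error.
- Eterna Classic Score: 100 × fraction of residues consistent with their
  pairing status — paired residues are penalized for normalized
  reactivity strictly above 0.5, unpaired strictly below 0.125 (values at
  the threshold count as consistent, matching the strict inequalities of
  the penalty rules).
- Crossed Pair Quality Score: the same count restricted to residues of
  crossing pairs after removing singlets (pairs with no stacked neighbor);
  residues whose partner lies in a designated flanking interval contribute
  with weight `flank_weight` (default 0.5) to numerator and denominator.
  Flank intervals default to empty — they are a property of the design
  construct, supplied per run. A structure with no surviving crossing
  pairs scores 0: a design that forms no pseudoknot earns no crossed-pair
  credit. (A defensible alternative is to omit the term for such targets;
  the convention here is fixed and documented so scores are comparable.)
- The combined score is the arithmetic mean of the two components. Under
  this convention a perfect hairpin tops out at 50, which is visible in
  the worked example.

## What the synthetic battery does and does not show

The fixtures (hairpins, H-type pseudoknots, fold-derived targets) are
designable *by construction* under the reference environment, making the
toy curriculum well-posed: the learning test demonstrates that the
twice-shifted TD machinery, masking, reward transforms and decoding are
wired correctly and can drive a policy to solve unseen targets. It does
not demonstrate performance against a learned neural folding environment,
on 100–240mer pseudoknot targets, or against wet-lab chemical mapping —
those regimes require external predictor weights and GPU-scale training
that are explicitly out of scope. The Nussinov folder also differs
qualitatively from thermodynamic or learned folders (no stacking
cooperativity, no pseudoknot prediction), so learned policies here exploit
its maximum-pairing objective (e.g. wobble-rich stems) in ways a
free-energy environment would not reward.

## Known limitations

- Single-process training only; no prioritized or multi-round replay.
- Left-to-right decoding order only.
- Rescue is local by design (see above).
- The dot-bracket renderer supports four bracket tiers; structures needing
  deeper pseudoknot orders are rejected with the required tier count.
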