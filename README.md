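# rnaqdesign

RNA inverse folding with deep Q-learning: design RNA sequences that fold
into a prescribed secondary structure — pseudoknots included — and
optionally satisfy SHAPE reactivity constraints.

## Who this is for

RNA engineers and method developers who need a structure-conditioned
sequence generator that (a) treats the folding engine as a pluggable
*environment* rather than an energy model baked into the search, and
(b) runs end to end on a laptop against a deterministic reference folder,
so every component is testable without GPUs or external model weights.

## The method

Sequence design is cast as a Markov decision process. The state `s_t` is
the target structure (dot-bracket, contact matrix) plus the partial
sequence decoded so far; the action `a_t ∈ {A, C, G, U}` is the nucleotide
placed at position `t`, masked so that a position whose target partner is
already decoded may only receive a canonical complement (A–U, G–C, G–U).
After a full sequence is generated, the environment folds it and emits a
dense per-position reward

    r_t = 1[pairing status at t matches the target] · 1[SHAPE constraint holds at t],

where the SHAPE term (optional) requires unpaired positions to show
reactivity > 0.5 and paired positions < 0.25. A structure-conditioned
encoder–decoder network predicts action values `Q_θ(s_t, a)` and is trained
with a temporal-difference objective against a periodically synchronized
frozen copy `Q_θ⁻`:

    L = E[ ( Q_θ(s_t, a_t) − r̃_t − γ_t · max_a′ Q_θ⁻(s_{t+1}, a′) )² ],

with two scheme-specific transforms: rewards are reweighted by
`exp(mean_t r_t)` so nearly-perfect episodes dominate the gradient, and the
discount `γ_t` decays linearly along the sequence
(`γ_t = γ_start − t/(L−1)·(γ_start − γ_end)`) so early positions — which
dominate global structure formation — look further ahead. Both the decoder
input (sequence shifted right with a START token) and the TD target
(next-state maximum shifted left) are temporally offset, hence
*twice-shifted* action-value training.

At inference time sequences are decoded greedily, by beam search over
cumulative Q-values, or by softmax/uniform sampling; near-miss designs are
*rescued* by enumerating canonical-pair assignments at mismatched
positions and refolding. Candidates are screened by base-pair Jaccard and
by chemical-mapping consistency scores (Eterna Classic, Crossed Pair
Quality, and their mean).

The bundled environment is a deterministic Nussinov maximum-base-pairing
folder plus a structure-derived SHAPE oracle; any predictor mapping a
sequence to a structure (or an L×L pairing-probability matrix, reduced by
Hungarian assignment) and a reactivity profile plugs in through the same
interface.

## Worked example

Train on a toy curriculum of 50 random length-20 hairpins against the
Nussinov environment (about half a minute on one CPU), then design
sequences for held-out targets:

```bash
rnaqd fixtures --kind hairpin --n 3 --length 20 --seed 99 --out holdout.tsv
rnaqd train --config examples/toy.yaml --run-dir run
# finished round 29: mean_reward=0.9730 mean_loss=1.5905
rnaqd design --target holdout.tsv --checkpoint run/checkpoint_round029.npz \
             --strategy beam --beam-k 4 --out designs.tsv
```

`designs.tsv` (first rows):

```
target_id  sequence              provenance  cumulative_q  jaccard  eterna_classic  crossed_pair_quality  openknot
hairpin_0  UUUUUUUUUUUUGGGGAGGG  beam        159.3479      1.0000   100.00          0.00                  50.00
hairpin_0  UUUUUUUUUUUUGGGGGAGG  beam        159.2419      1.0000   100.00          0.00                  50.00
```

`jaccard = 1.0` means the designed sequence's fold reproduces the target
base-pair set exactly (here the policy learned U·G wobble stems, a valid
canonical choice under the environment). `eterna_classic = 100` says every
residue's oracle reactivity is consistent with its pairing status; the
crossed-pair score is 0 for hairpins because they contain no crossing
pairs, so the combined score is 50 — pseudoknotted targets are needed to
earn the second component.

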