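"""Sequence generation strategies and candidate screening.

Generation is guided by the trained network's action values:

* **greedy** — argmax action at each position (beam width 1);
* **beam search** — retain the top-k prefixes by cumulative (summed)
  Q-value; cumulative Q has no probabilistic interpretation, it simply
  ranks prefixes by expected structural fidelity;
* **random search** — per position, sample from a softmax-transformed
  Q-distribution at a given temperature, or uniformly over valid actions.

All strategies respect the valid-action mask: at a paired position whose
partner is already decoded, only canonical complements are considered.

Post-processing: **rescue** repairs near-miss sequences by enumerating
canonical-pair assignments at mismatched positions and refolding;
**screen** folds and scores every candidate (Jaccard + chemical-mapping
consistency) and ranks them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np

from .environment import (
    CANONICAL_PAIRS,
    DesignTarget,
    Predictor,
    predict_structure,
)
from .qnet import BASES, START_TOKEN, DecoderCache, QNetwork, decode_step
from .scoring import ScoreReport, jaccard_basepairs, normalize_shape, openknot_score
from .training import valid_actions

logger = logging.getLogger(__name__)

#: Ordered canonical assignments for one target pair, enumerated in rescue.
_PAIR_COMBOS: tuple[tuple[str, str], ...] = tuple(sorted(CANONICAL_PAIRS))


@dataclass(frozen=True)
class Candidate:
    """A generated sequence with its provenance and (optional) scores."""

    sequence: str
    cumulative_q: float
    provenance: str  # greedy | beam | random | rescued
    report: ScoreReport | None = None


def beam_search(network: QNetwork, target: DesignTarget, k: int = 16) -> list[Candidate]:
    """Top-k sequences by cumulative Q-value under the valid-action mask.

    Standard beam over positions: every retained prefix is expanded by all
    its valid actions, scored by the running sum of selected Q-values, and
    the k best expansions survive.  The result is sorted by cumulative Q
    descending with lexicographic sequence tie-break.  ``k=1`` is exactly
    greedy decoding.
    """
    if k < 1:
        raise ValueError("beam width must be at least 1")
    structure = target.structure
    ctx = network.encode_structure(structure)
    flags = structure.paired_flags()
    # beams: (sequence string, cumulative q, cache, next input token)
    beams: list[tuple[str, float, DecoderCache, int]] = [
        ("", 0.0, network.init_cache(ctx), START_TOKEN)
    ]
    for t in range(structure.length):
        expansions: list[tuple[str, float, DecoderCache, int]] = []
        for seq, cum, cache, token in beams:
            q = decode_step(cache, token, int(flags[t]))[0]
            mask = valid_actions(structure, t, seq)
            for action in np.flatnonzero(mask):
                expansions.append(
                    (seq + BASES[action], cum + float(q[action]), cache, int(action))
                )
        expansions.sort(key=lambda e: (-e[1], e[0]))
        survivors = expansions[:k]
        # caches are stateful: share only when a cache survives once
        beams = []
        used: set[int] = set()
        for seq, cum, cache, token in survivors:
            if id(cache) in used:
                cache = cache.copy()
            used.add(id(cache))
            beams.append((seq, cum, cache, token))
    provenance = "greedy" if k == 1 else "beam"
    return [
        Candidate(sequence=seq, cumulative_q=cum, provenance=provenance)
        for seq, cum, _, _ in beams
    ]


def greedy_decode(network: QNetwork, target: DesignTarget) -> Candidate:
    return beam_search(network, target, k=1)[0]


def random_search(
    network: QNetwork,
    target: DesignTarget,
    n: int = 16,
    temperature: float = 1.0,
    uniform_prob: float = 0.0,
    seed: int = 0,
) -> list[Candidate]:
    """Stochastic decoding: softmax(Q / temperature) over valid actions,
    with probability ``uniform_prob`` a uniform draw over valid actions."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not 0.0 <= uniform_prob <= 1.0:
        raise ValueError("uniform_prob must lie in [0, 1]")
    structure = target.structure
    ctx = network.encode_structure(structure)
    flags = structure.paired_flags()
    rng = np.random.default_rng(seed)
    out: list[Candidate] = []
    for _ in range(n):
        cache = network.init_cache(ctx)
        token = START_TOKEN
        seq: list[str] = []
        cum = 0.0
        for t in range(structure.length):
            q = decode_step(cache, token, int(flags[t]))[0]
            mask = valid_actions(structure, t, "".join(seq))
            idx = np.flatnonzero(mask)
            if rng.random() < uniform_prob:
                action = int(rng.choice(idx))
            else:
                logits = q[idx] / temperature
                logits = logits - logits.max()
                p = np.exp(logits)
                action = int(rng.choice(idx, p=p / p.sum()))
            seq.append(BASES[action])
            cum += float(q[action])
            token = action
        out.append(Candidate(sequence="".join(seq), cumulative_q=cum, provenance="random"))
    return out


def rescue(
    sequence: str,
    target: DesignTarget,
    predictor: Predictor,
    max_mismatch_pairs: int = 2,
    fold_threshold: float = 0.5,
) -> Candidate | None:
    """Repair a near-miss sequence by local enumeration and refolding.

    Positions whose pairing status under the environment's fold disagrees
    with the target are grouped into target pairs (plus target-unpaired
    singles).  When at most ``max_mismatch_pairs`` target pairs are
    affected, every canonical assignment of those pairs (6 each) crossed
    with every base at the single positions (4 each) is refolded; the first
    variant (in deterministic enumeration order) whose fold matches the
    target exactly is returned, else the variant with the highest base-pair
    Jaccard if it improves on the input, else ``None``.
    """
    if max_mismatch_pairs < 1:
        raise ValueError("max_mismatch_pairs must be at least 1")
    structure = target.structure
    if len(sequence) != structure.length:
        raise ValueError("sequence length does not match target")
    folded = predict_structure(predictor, sequence, threshold=fold_threshold)
    base_jaccard = jaccard_basepairs(folded, structure)
    if folded.pairs == structure.pairs:
        return Candidate(sequence=sequence, cumulative_q=0.0, provenance="rescued")

    pred_status = folded.pairing_status()
    targ_status = structure.pairing_status()
    mismatched = [t for t in range(structure.length) if pred_status[t] != targ_status[t]]
    partner = structure.partner
    pair_sites: list[tuple[int, int]] = []
    single_sites: list[int] = []
    seen: set[int] = set()
    for t in mismatched:
        if t in seen:
            continue
        j = partner.get(t)
        if j is None:
            single_sites.append(t)
            seen.add(t)
        else:
            pair_sites.append((min(t, j), max(t, j)))
            seen.update((t, j))
    if len(pair_sites) > max_mismatch_pairs:
        logger.info(
            "rescue skipped: %d mismatched target pairs exceed cap %d",
            len(pair_sites),
            max_mismatch_pairs,
        )
        return None

    best: tuple[float, str] | None = None
    chars = list(sequence)
    for pair_assign in itertools.product(_PAIR_COMBOS, repeat=len(pair_sites)):
        for single_assign in itertools.product(BASES, repeat=len(single_sites)):
            variant = chars[:]
            for (i, j), (bi, bj) in zip(pair_sites, pair_assign):
                variant[i], variant[j] = bi, bj
            for t, b in zip(single_sites, single_assign):
                variant[t] = b
            vseq = "".join(variant)
            vfold = predict_structure(predictor, vseq, threshold=fold_threshold)
            if vfold.pairs == structure.pairs:
                return Candidate(sequence=vseq, cumulative_q=0.0, provenance="rescued")
            jac = jaccard_basepairs(vfold, structure)
            if best is None or jac > best[0]:
                best = (jac, vseq)
    if best is not None and best[0] > base_jaccard:
        return Candidate(sequence=best[1], cumulative_q=0.0, provenance="rescued")
    return None


def screen(
    candidates: list[Candidate],
    target: DesignTarget,
    predictor: Predictor,
    shape_source=None,
    fold_threshold: float = 0.5,
) -> list[Candidate]:
    """Fold, score and rank candidates.

    Each candidate is folded with the environment and profiled with the
    environment's SHAPE predictor (or ``shape_source(sequence)`` when
    given); the report carries base-pair Jaccard against the target plus
    the chemical-mapping consistency scores.  Duplicates (by sequence) are
    collapsed, keeping the first occurrence; ranking is by (jaccard,
    openknot) lexicographically descending, ties broken by sequence.
    """
    seen: set[str] = set()
    scored: list[Candidate] = []
    for cand in candidates:
        if cand.sequence in seen:
            continue
        seen.add(cand.sequence)
        folded = predict_structure(predictor, cand.sequence, threshold=fold_threshold)
        raw = shape_source(cand.sequence) if shape_source else predictor.shape(cand.sequence)
        report = openknot_score(folded, normalize_shape(raw), target=target.structure)
        scored.append(replace(cand, report=report))
    scored.sort(key=lambda c: (-c.report.jaccard, -c.report.openknot, c.sequence))
    return scored
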