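"""Synthetic, seeded design targets.

Three families cover the behaviours the rest of the package needs to
exercise without any external data:

* hairpins — a single nested helix, the simplest designable motif;
* H-type pseudoknots — two mutually crossing helices, exercising tiered
  dot-bracket rendering and the crossed-pair metrics;
* fold-derived targets — Nussinov folds of random GC-biased sequences,
  which are designable *by construction* (the source sequence solves them)
  and therefore make toy training curricula well-posed.
"""

from __future__ import annotations

import numpy as np

from .environment import RNA_ALPHABET, nussinov_fold
from .structures import SecondaryStructure


def make_hairpin(stem: int, loop: int) -> SecondaryStructure:
    """A single helix of ``stem`` pairs closing a loop of ``loop`` bases."""
    if stem < 1:
        raise ValueError("stem must be at least 1 pair")
    if loop < 3:
        raise ValueError("loop must span at least 3 bases (folding loop rule)")
    length = 2 * stem + loop
    pairs = frozenset((i, length - 1 - i) for i in range(stem))
    return SecondaryStructure(length=length, pairs=pairs)


def make_htype_pseudoknot(
    stem1: int = 3,
    loop1: int = 3,
    stem2: int = 3,
    loop2: int = 3,
    tail: int = 0,
) -> SecondaryStructure:
    """An H-type pseudoknot: two helices whose pair sets mutually cross.

    Layout along the strand: stem1-5' | loop1 | stem2-5' | loop2 (closes
    stem1) | stem2-3' | tail.  Stem 1 pairs across loop1 and the 5' half of
    stem 2; stem 2 pairs across loop2 and the 3' half of stem 1's closing
    region, producing the crossing topology.
    """
    if stem1 < 1 or stem2 < 1:
        raise ValueError("both stems need at least 1 pair")
    if loop1 < 3 or loop2 < 3:
        raise ValueError("loops must span at least 3 bases (folding loop rule)")
    if tail < 0:
        raise ValueError("tail must be non-negative")
    # segment offsets
    a = 0                      # stem1 5' half: [a, a+stem1)
    b = a + stem1              # loop1: [b, b+loop1)
    c = b + loop1              # stem2 5' half: [c, c+stem2)
    d = c + stem2              # loop2 + stem1 3' half: [d, d+loop2+stem1)
    e = d + loop2 + stem1      # stem2 3' half: [e, e+stem2)
    length = e + stem2 + tail
    pairs = set()
    for i in range(stem1):
        pairs.add((a + i, d + loop2 + stem1 - 1 - i))
    for i in range(stem2):
        pairs.add((c + i, e + stem2 - 1 - i))
    structure = SecondaryStructure(length=length, pairs=frozenset(pairs))
    # geometric sanity: both helices must actually cross
    from .structures import crossing_pairs

    if len(crossing_pairs(structure)) != len(pairs):
        raise ValueError("infeasible pseudoknot geometry: helices do not cross")
    return structure


def random_sequence(length: int, rng: np.random.Generator, gc_bias: float = 0.6) -> str:
    """Random RNA sequence with the given total G+C probability."""
    p_gc = gc_bias / 2.0
    p_au = (1.0 - gc_bias) / 2.0
    probs = {"A": p_au, "C": p_gc, "G": p_gc, "U": p_au}
    bases = rng.choice(list(RNA_ALPHABET), size=length, p=[probs[b] for b in RNA_ALPHABET])
    return "".join(bases)


def make_fold_derived_targets(
    n: int,
    length: int,
    seed: int = 0,
    gc_bias: float = 0.6,
    min_loop: int = 3,
) -> list[tuple[str, SecondaryStructure]]:
    """Designable targets from Nussinov folds of random sequences.

    Draws GC-biased random sequences, folds each, and keeps folds with at
    least ``length / 6`` pairs (discarding near-trivial structures).  Every
    returned target is solvable by its own source sequence.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, SecondaryStructure]] = []
    min_pairs = length / 6.0
    while len(out) < n:
        seq = random_sequence(length, rng, gc_bias)
        structure = nussinov_fold(seq, min_loop=min_loop)
        if len(structure.pairs) >= min_pairs:
            out.append((seq, structure))
    return out


def random_hairpins(
    n: int, length: int, seed: int = 0, min_stem: int = 3
) -> list[SecondaryStructure]:
    """Seeded hairpins of fixed total length with varying stem/loop split."""
    rng = np.random.default_rng(seed)
    max_stem = (length - 3) // 2
    if max_stem < min_stem:
        raise ValueError(f"length {length} too short for a stem of {min_stem}")
    out = []
    for _ in range(n):
        stem = int(rng.integers(min_stem, max_stem + 1))
        out.append(make_hairpin(stem, length - 2 * stem))
    return out


def random_structure(length: int, rng: np.random.Generator, p_pair: float = 0.3) -> SecondaryStructure:
    """Arbitrary valid structure (possibly pseudoknotted) for property tests.

    Repeatedly draws index pairs with span > 1 and keeps those not clashing
    with already-placed pairs; pairs that would demand a fifth bracket tier
    (more than four mutually crossing families) are skipped, so the result
    is always renderable.  Makes no loop-rule or designability claim.
    """
    from .structures import render_dotbracket

    taken: set[int] = set()
    pairs: set[tuple[int, int]] = set()
    n_attempts = int(p_pair * length)
    for _ in range(n_attempts):
        i, j = sorted(rng.choice(length, size=2, replace=False).tolist())
        if j - i < 2 or i in taken or j in taken:
            continue
        candidate = SecondaryStructure(length=length, pairs=frozenset(pairs | {(i, j)}))
        try:
            render_dotbracket(candidate)
        except ValueError:  # would need a fifth bracket tier
            continue
        pairs.add((i, j))
        taken.update((i, j))
    return SecondaryStructure(length=length, pairs=frozenset(pairs))
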