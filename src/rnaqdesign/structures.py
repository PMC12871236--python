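"""Pseudoknotted RNA secondary structures as base-pair sets.

A secondary structure over ``L`` nucleotides is a set of pairs ``(i, j)`` with
``0 <= i < j < L`` in which every position participates in at most one pair.
Structures are rendered in dot-bracket notation; crossing (pseudoknotted)
pairs are assigned to additional bracket tiers ``[]``, ``{}``, ``<>``.

Indexing is 0-based and inclusive everywhere in this package, and pairs are
always stored with the smaller index first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

#: Bracket tiers in rendering priority order.
BRACKET_TIERS: tuple[tuple[str, str], ...] = (("(", ")"), ("[", "]"), ("{", "}"), ("<", ">"))

_OPEN = {o: t for t, (o, _) in enumerate(BRACKET_TIERS)}
_CLOSE = {c: t for t, (_, c) in enumerate(BRACKET_TIERS)}


class DotBracketError(ValueError):
    """Raised for malformed dot-bracket text (position-annotated)."""


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA secondary structure: a length and a set of base pairs.

    Parameters
    ----------
    length
        Number of nucleotides.
    pairs
        Base pairs ``(i, j)`` with ``i < j``; each index appears in at most
        one pair.  No minimum loop span is enforced here — structures read
        from external sources may violate the folding oracle's loop rule.
    """

    length: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"negative length {self.length}")
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i}, {j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"position in pair ({i}, {j}) participates in two pairs")
            seen.update((i, j))

    @property
    def partner(self) -> dict[int, int]:
        """Map each paired position to its partner (both directions)."""
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m

    def pairing_status(self) -> list[int | None]:
        """Per-position partner index, ``None`` when unpaired."""
        m = self.partner
        return [m.get(t) for t in range(self.length)]

    def paired_flags(self) -> np.ndarray:
        """Binary vector, 1 where the position is paired."""
        flags = np.zeros(self.length, dtype=np.int64)
        for i, j in self.pairs:
            flags[i] = flags[j] = 1
        return flags

    @property
    def dotbracket(self) -> str:
        return render_dotbracket(self)

    def __len__(self) -> int:
        return self.length


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse dot-bracket text (pseudoknot tiers allowed) into a structure.

    Each bracket tier is matched with its own stack, so crossing pairs in
    different tiers are legal.  Raises :class:`DotBracketError` naming the
    offending position for unbalanced brackets or unknown characters.
    """
    stacks: list[list[int]] = [[] for _ in BRACKET_TIERS]
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(pos)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE[ch]]
            if not stack:
                raise DotBracketError(f"unmatched '{ch}' at position {pos}")
            pairs.add((stack.pop(), pos))
        else:
            raise DotBracketError(f"unknown character {ch!r} at position {pos}")
    for tier, stack in enumerate(stacks):
        if stack:
            o = BRACKET_TIERS[tier][0]
            raise DotBracketError(f"unmatched '{o}' at position {stack[-1]}")
    return SecondaryStructure(length=len(text), pairs=frozenset(pairs))


def _pairs_cross(a: tuple[int, int], b: tuple[int, int]) -> bool:
    i, j = a
    k, l = b
    return i < k < j < l or k < i < l < j


def render_dotbracket(structure: SecondaryStructure) -> str:
    """Render a structure as dot-bracket text.

    Crossing pairs are assigned to distinct bracket tiers by greedy coloring
    of the crossing graph, visiting pairs in order of opening position and
    taking the first tier free of crossings.  More than four mutually
    crossing families cannot be rendered and raise ``ValueError`` reporting
    the tier count that would be required.
    """
    ordered = sorted(structure.pairs)
    tier_of: dict[tuple[int, int], int] = {}
    for p in ordered:
        used = {tier_of[q] for q in ordered if q in tier_of and _pairs_cross(p, q)}
        tier = next((t for t in range(len(BRACKET_TIERS)) if t not in used), None)
        if tier is None:
            raise ValueError(
                f"structure needs {len(used) + 1} bracket tiers; only "
                f"{len(BRACKET_TIERS)} are supported"
            )
        tier_of[p] = tier
    out = ["."] * structure.length
    for (i, j), t in tier_of.items():
        out[i], out[j] = BRACKET_TIERS[t]
    return "".join(out)


def crossing_pairs(structure: SecondaryStructure) -> frozenset[tuple[int, int]]:
    """All pairs that cross some other pair (the pseudoknotted pairs).

    Pairs ``(i, j)`` and ``(k, l)`` cross when ``i < k < j < l`` or
    ``k < i < l < j``.
    """
    ordered = sorted(structure.pairs)
    out: set[tuple[int, int]] = set()
    for idx, p in enumerate(ordered):
        for q in ordered[idx + 1 :]:
            if _pairs_cross(p, q):
                out.add(p)
                out.add(q)
    return frozenset(out)


def remove_singlets(structure: SecondaryStructure) -> SecondaryStructure:
    """Drop isolated pairs: ``(i, j)`` with neither ``(i-1, j+1)`` nor
    ``(i+1, j-1)`` present (no stacked neighbor on either side)."""
    pairs = structure.pairs
    kept = frozenset(
        (i, j) for i, j in pairs if (i - 1, j + 1) in pairs or (i + 1, j - 1) in pairs
    )
    return SecondaryStructure(length=structure.length, pairs=kept)


def contact_matrix(structure: SecondaryStructure) -> np.ndarray:
    """Symmetric binary ``L x L`` contact matrix with zero diagonal."""
    mat = np.zeros((structure.length, structure.length), dtype=np.int64)
    for i, j in structure.pairs:
        mat[i, j] = mat[j, i] = 1
    return mat


# ---------------------------------------------------------------------------
# File formats: "id<TAB>dotbracket" structure tables and FASTA sequences.

def read_structures(path: str) -> list[tuple[str, SecondaryStructure]]:
    """Read a structure table: one ``id<TAB>dotbracket`` record per line."""
    records: list[tuple[str, SecondaryStructure]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                name, db = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>dotbracket'") from exc
            records.append((name, parse_dotbracket(db)))
    return records


def write_structures(path: str, records: Iterable[tuple[str, SecondaryStructure]]) -> None:
    with open(path, "w") as fh:
        for name, structure in records:
            fh.write(f"{name}\t{render_dotbracket(structure)}\n")


def read_fasta(path: str) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` from FASTA; T is mapped to U on read."""
    from Bio import SeqIO

    for record in SeqIO.parse(path, "fasta"):
        yield record.id, str(record.seq).upper().replace("T", "U")


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path,
        "fasta",
    )
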