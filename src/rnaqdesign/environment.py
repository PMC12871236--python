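"""The reward-providing environment for sequence design.

A *predictor* maps an RNA sequence to structural feedback: either a
secondary structure directly, or an ``L x L`` pairing-probability matrix
(from which pairs are extracted by maximum-weight assignment), plus a SHAPE
reactivity profile.  The environment compares the predicted structure with
the design target and emits a dense per-position binary reward:

    r_t = 1[pairing status at t is correct] * 1[SHAPE constraint holds at t]

The default predictor is a deterministic Nussinov maximum-base-pairing
folder together with a structure-derived SHAPE oracle, so the whole design
loop runs at desk scale with no external model.  Neural predictors attach
through the same :class:`Predictor` contract without changes elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.optimize import linear_sum_assignment

from .structures import SecondaryStructure

RNA_ALPHABET = "ACGU"

#: The six canonical ordered pairs: Watson-Crick plus the G-U wobble.
CANONICAL_PAIRS: frozenset[tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: For a given base, the partners it can pair with.
COMPLEMENTS: dict[str, tuple[str, ...]] = {
    "A": ("U",),
    "U": ("A", "G"),
    "G": ("C", "U"),
    "C": ("G",),
}


@dataclass(frozen=True)
class ShapeProfile:
    """Per-position SHAPE reactivities (non-negative floats).

    High reactivity indicates a flexible, typically unpaired nucleotide; low
    reactivity indicates a paired one.  ``normalized`` records whether the
    profile has been scaled so its 90th percentile equals 1.0.
    """

    reactivities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.reactivities, dtype=float)
        if arr.ndim != 1:
            raise ValueError("reactivities must be a 1-D vector")
        if np.any(arr < 0):
            raise ValueError("reactivities must be non-negative")
        object.__setattr__(self, "reactivities", arr)

    def __len__(self) -> int:
        return self.reactivities.shape[0]


@dataclass(frozen=True)
class ShapeThresholds:
    """Binary SHAPE-compliance rule for the reward.

    Unpaired positions must show reactivity strictly above ``unpaired_min``;
    paired positions strictly below ``paired_max``.
    """

    unpaired_min: float = 0.5
    paired_max: float = 0.25

    def __post_init__(self) -> None:
        if not self.unpaired_min > self.paired_max:
            raise ValueError("unpaired_min must exceed paired_max")


@dataclass(frozen=True)
class DesignTarget:
    """A target structure plus optional SHAPE constraint thresholds."""

    structure: SecondaryStructure
    name: str = "target"
    shape_thresholds: ShapeThresholds | None = None

    def __len__(self) -> int:
        return self.structure.length


@runtime_checkable
class Predictor(Protocol):
    """Environment contract: pure functions of the sequence."""

    def fold(self, sequence: str) -> SecondaryStructure | np.ndarray:
        """Secondary structure, or a symmetric L x L pairing-probability matrix."""

    def shape(self, sequence: str) -> ShapeProfile:
        """Predicted SHAPE reactivity profile for the sequence."""


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"invalid characters in RNA sequence: {sorted(bad)}")
    return seq


def nussinov_fold(sequence: str, min_loop: int = 3) -> SecondaryStructure:
    """Maximum canonical base pairing by Nussinov dynamic programming.

    Maximizes the number of pairs from {AU, UA, GC, CG, GU, UG} subject to
    nesting and a hairpin loop constraint ``j - i - 1 >= min_loop``.
    Traceback is deterministic: at span ``(i, j)`` the "j unpaired" branch is
    taken whenever it attains the optimum, otherwise ``j`` is paired with
    the smallest admissible ``k``.
    """
    seq = _check_sequence(sequence)
    if min_loop < 0:
        raise ValueError("min_loop must be non-negative")
    n = len(seq)
    if n == 0:
        return SecondaryStructure(length=0)

    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            can[i, j] = (seq[i], seq[j]) in CANONICAL_PAIRS

    # N[i, j] = max pairs in seq[i..j]; padded so N[i, i-1] reads as 0.
    N = np.zeros((n + 1, n + 1), dtype=np.int64)

    def _get(i: int, j: int) -> int:
        return int(N[i, j]) if i <= j else 0

    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i, j - 1]  # j unpaired
            ks = np.flatnonzero(can[i : j - min_loop, j]) + i
            if ks.size:
                left = np.array([_get(i, k - 1) for k in ks])
                right = np.array([_get(k + 1, j - 1) for k in ks])
                best = max(best, int((left + right + 1).max()))
            N[i, j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        if N[i, j] == N[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if can[k, j] and _get(i, k - 1) + _get(k + 1, j - 1) + 1 == N[i, j]:
                pairs.add((k, j))
                stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    return SecondaryStructure(length=n, pairs=frozenset(pairs))


def oracle_shape(
    sequence: str,
    structure: SecondaryStructure,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ShapeProfile:
    """Deterministic structure-derived SHAPE oracle.

    Paired positions react at 0.1, unpaired at 0.9; optional zero-mean
    Gaussian noise of scale ``noise_sd`` is added and the result clipped at
    zero.  Seeded, hence reproducible.
    """
    seq = _check_sequence(sequence)
    if len(seq) != structure.length:
        raise ValueError(
            f"sequence length {len(seq)} != structure length {structure.length}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    vals = np.where(structure.paired_flags() == 1, 0.1, 0.9).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = np.clip(vals + rng.normal(0.0, noise_sd, size=vals.shape), 0.0, None)
    return ShapeProfile(reactivities=vals)


def extract_pairs_hungarian(
    prob: np.ndarray,
    threshold: float = 0.5,
    min_loop: int = 3,
    sym_tol: float = 1e-6,
) -> SecondaryStructure:
    """Extract base pairs from a pairing-probability matrix by assignment.

    Solves a maximum-weight one-to-one assignment on the symmetrized matrix
    and keeps only mutually assigned pairs ``i <-> j`` with probability at
    least ``threshold``.  Entries on or near the diagonal
    (``|j - i| <= min_loop``) are zeroed first, so chemically impossible
    pairs can never be selected.
    """
    prob = np.asarray(prob, dtype=float)
    if prob.ndim != 2 or prob.shape[0] != prob.shape[1]:
        raise ValueError("probability matrix must be square")
    if np.abs(prob - prob.T).max(initial=0.0) > sym_tol:
        raise ValueError("probability matrix is not symmetric within tolerance")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    n = prob.shape[0]
    w = (prob + prob.T) / 2.0
    offsets = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    w[offsets <= min_loop] = 0.0
    rows, cols = linear_sum_assignment(w, maximize=True)
    assigned = dict(zip(rows.tolist(), cols.tolist()))
    pairs = frozenset(
        (i, j)
        for i, j in assigned.items()
        if i < j and assigned.get(j) == i and w[i, j] >= threshold
    )
    return SecondaryStructure(length=n, pairs=pairs)


def shape_constraint_satisfied(
    position_paired: bool,
    reactivity: float,
    thresholds: ShapeThresholds = ShapeThresholds(),
) -> bool:
    """Binary SHAPE rule: unpaired positions must be reactive, paired quiet."""
    if position_paired:
        return reactivity < thresholds.paired_max
    return reactivity > thresholds.unpaired_min


def compute_rewards(
    predicted: SecondaryStructure,
    target: SecondaryStructure,
    shape: ShapeProfile | None = None,
    thresholds: ShapeThresholds = ShapeThresholds(),
) -> np.ndarray:
    """Per-position binary reward: structure correctness times SHAPE compliance.

    Position ``t`` earns reward 1 iff its pairing status (partner index, or
    unpaired) agrees between prediction and target AND, when a SHAPE profile
    is given, the reactivity at ``t`` satisfies the threshold rule for the
    target pairing status.  With ``shape=None`` the reward is structure-only.
    """
    if predicted.length != target.length:
        raise ValueError("predicted and target structures differ in length")
    if shape is not None and len(shape) != target.length:
        raise ValueError("SHAPE profile length does not match structure length")
    pred_status = predicted.pairing_status()
    targ_status = target.pairing_status()
    rewards = np.zeros(target.length, dtype=float)
    for t in range(target.length):
        if pred_status[t] != targ_status[t]:
            continue
        if shape is not None and not shape_constraint_satisfied(
            targ_status[t] is not None, float(shape.reactivities[t]), thresholds
        ):
            continue
        rewards[t] = 1.0
    return rewards


@dataclass(frozen=True)
class NussinovPredictor:
    """Deterministic reference environment: Nussinov fold + SHAPE oracle.

    The SHAPE profile is derived from the sequence's own fold, so the
    predictor remains a pure function of the sequence.
    """

    min_loop: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def fold(self, sequence: str) -> SecondaryStructure:
        return nussinov_fold(sequence, min_loop=self.min_loop)

    def shape(self, sequence: str) -> ShapeProfile:
        structure = self.fold(sequence)
        # derive the noise stream from the sequence so shape() is pure
        # (zlib.crc32 is stable across processes, unlike hash())
        import zlib

        sub = (self.seed * 1000003 + zlib.crc32(sequence.encode())) % (2**31)
        return ShapeProfile(
            oracle_shape(sequence, structure, self.noise_sd, sub).reactivities
        )


def predict_structure(
    predictor: Predictor,
    sequence: str,
    threshold: float = 0.5,
    min_loop: int = 3,
) -> SecondaryStructure:
    """Fold a sequence, extracting pairs when the predictor returns a matrix."""
    out = predictor.fold(sequence)
    if isinstance(out, SecondaryStructure):
        return out
    return extract_pairs_hungarian(np.asarray(out), threshold=threshold, min_loop=min_loop)


# ---------------------------------------------------------------------------
# SHAPE profile text format: two whitespace-separated columns,
# 0-based position and reactivity.

def read_shape_profile(path: str) -> ShapeProfile:
    entries: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                pos_s, val_s = line.split()
                entries[int(pos_s)] = float(val_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 'position reactivity'") from exc
    if sorted(entries) != list(range(len(entries))):
        raise ValueError(f"{path}: positions must cover 0..L-1 exactly once")
    return ShapeProfile(np.array([entries[i] for i in range(len(entries))]))


def write_shape_profile(path: str, profile: ShapeProfile) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(profile.reactivities):
            fh.write(f"{i}\t{v:.6f}\n")
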