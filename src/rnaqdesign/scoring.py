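"""Screening metrics for designed sequences.

Two families of metric are provided:

* **Jaccard of base pairs** — intersection over union of the predicted and
  target base-pair sets; the structural-fidelity yardstick.
* **Chemical-mapping consistency scores** (0-100), computed from a SHAPE
  profile normalized to a 90th-percentile of 1.0:

  - *Eterna Classic Score*: fraction of residues whose reactivity is
    consistent with their pairing status — a paired residue is penalized
    when its normalized reactivity exceeds 0.5, an unpaired residue when it
    falls below 0.125.
  - *Crossed Pair Quality Score*: the same consistency count restricted to
    residues in crossing (pseudoknotted) pairs, after removing singlet
    pairs; residues whose partner lies in a designated flanking region are
    downweighted.
  - *OpenKnot score*: the mean of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import ShapeProfile
from .structures import SecondaryStructure, crossing_pairs, remove_singlets

#: A paired residue is consistent iff normalized reactivity <= this value.
PAIRED_MAX_REACTIVITY = 0.5
#: An unpaired residue is consistent iff normalized reactivity >= this value.
UNPAIRED_MIN_REACTIVITY = 0.125


@dataclass(frozen=True)
class ScoreReport:
    jaccard: float
    eterna_classic: float
    crossed_pair_quality: float

    @property
    def openknot(self) -> float:
        return (self.eterna_classic + self.crossed_pair_quality) / 2.0


def jaccard_basepairs(predicted: SecondaryStructure, target: SecondaryStructure) -> float:
    """|P ∩ T| / |P ∪ T| over base-pair sets; 1.0 when both are empty."""
    if predicted.length != target.length:
        raise ValueError("structures differ in length")
    union = predicted.pairs | target.pairs
    if not union:
        return 1.0
    return len(predicted.pairs & target.pairs) / len(union)


def normalize_shape(profile: ShapeProfile) -> ShapeProfile:
    """Scale reactivities so the 90th percentile (linear interpolation) is 1.0.

    Idempotent; raises on an all-zero profile, for which normalization is
    undefined.
    """
    if profile.normalized:
        return profile
    p90 = float(np.percentile(profile.reactivities, 90, method="linear"))
    if p90 <= 0:
        raise ValueError("cannot normalize a profile whose 90th percentile is zero")
    return ShapeProfile(profile.reactivities / p90, normalized=True)


def _consistent(paired: bool, reactivity: float) -> bool:
    if paired:
        return reactivity <= PAIRED_MAX_REACTIVITY
    return reactivity >= UNPAIRED_MIN_REACTIVITY


def eterna_classic_score(structure: SecondaryStructure, shape: ShapeProfile) -> float:
    """0-100 consistency between pairing status and normalized reactivity."""
    if not shape.normalized:
        raise ValueError("profile must be normalized (90th percentile = 1.0) first")
    if len(shape) != structure.length:
        raise ValueError("profile and structure differ in length")
    if structure.length == 0:
        return 0.0
    flags = structure.paired_flags()
    good = sum(
        _consistent(bool(flags[t]), float(shape.reactivities[t]))
        for t in range(structure.length)
    )
    return 100.0 * good / structure.length


def crossed_pair_quality_score(
    structure: SecondaryStructure,
    shape: ShapeProfile,
    flank_regions: tuple[tuple[int, int], ...] = (),
    flank_weight: float = 0.5,
) -> float:
    """Consistency score over residues in crossing pairs (singlets removed).

    Every residue belonging to a crossing pair is scored with the paired
    rule; a residue whose partner lies in one of the half-open flanking
    intervals ``[a, b)`` contributes with ``flank_weight`` to both the
    numerator and the denominator.  Returns 0.0 when no crossing residues
    remain after singlet removal.
    """
    if not shape.normalized:
        raise ValueError("profile must be normalized (90th percentile = 1.0) first")
    if not 0.0 <= flank_weight <= 1.0:
        raise ValueError("flank_weight must lie in [0, 1]")
    crossing = crossing_pairs(remove_singlets(structure))
    if not crossing:
        return 0.0

    def in_flank(pos: int) -> bool:
        return any(a <= pos < b for a, b in flank_regions)

    num = den = 0.0
    for i, j in sorted(crossing):
        for pos, partner in ((i, j), (j, i)):
            w = flank_weight if in_flank(partner) else 1.0
            den += w
            if _consistent(True, float(shape.reactivities[pos])):
                num += w
    if den == 0:
        return 0.0
    return 100.0 * num / den


def openknot_score(
    structure: SecondaryStructure,
    shape: ShapeProfile,
    target: SecondaryStructure | None = None,
    flank_regions: tuple[tuple[int, int], ...] = (),
    flank_weight: float = 0.5,
) -> ScoreReport:
    """Combined report; ``jaccard`` compares against ``target`` when given,
    else is 1.0 by self-comparison convention."""
    shape = normalize_shape(shape)
    ecs = eterna_classic_score(structure, shape)
    cpq = crossed_pair_quality_score(structure, shape, flank_regions, flank_weight)
    jac = jaccard_basepairs(structure, target) if target is not None else 1.0
    return ScoreReport(jaccard=jac, eterna_classic=ecs, crossed_pair_quality=cpq)
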