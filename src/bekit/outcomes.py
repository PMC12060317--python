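"""Editing-outcome enumeration and the probability algebra shared by
quantification, simulation and the prediction model.

An outcome is a subset of the protospacer's adenines converted to G.  The
outcome space of a site with k editable adenines has 2^k members including the
unedited sequence; to bound combinatorics k is capped at ``max_positions``
with the editable set centred on the canonical peak of the editing window
(position 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NORM_TOL = 1e-9


@dataclass(frozen=True)
class Outcome:
    """One A→G editing outcome: which protospacer positions were converted."""

    positions: tuple[int, ...]   # 1-based protospacer positions edited (sorted)
    sequence: str                # 20-nt protospacer with edits applied

    @property
    def is_edited(self) -> bool:
        return len(self.positions) > 0

    def label(self) -> str:
        return "WT" if not self.positions else "-".join(map(str, self.positions))

    @classmethod
    def from_label(cls, label: str, protospacer: str) -> "Outcome":
        if label == "WT":
            return apply_edits(protospacer, ())
        return apply_edits(protospacer, tuple(int(x) for x in label.split("-")))


def apply_edits(protospacer: str, positions) -> Outcome:
    """Build an Outcome by substituting A→G at the given 1-based positions."""
    positions = tuple(sorted(int(p) for p in positions))
    seq = list(protospacer)
    for p in positions:
        if seq[p - 1] != "A":
            raise ValueError(f"position {p} of protospacer is {seq[p-1]!r}, not 'A'")
        seq[p - 1] = "G"
    return Outcome(positions, "".join(seq))


def editable_positions(protospacer: str, max_positions: int = 12) -> tuple[int, ...]:
    """Adenine positions eligible for outcome enumeration.

    If more than ``max_positions`` adenines are present, keep the ones closest
    to position 6 (the window peak), breaking distance ties toward the
    PAM-distal (lower-numbered) position.
    """
    a_pos = [i + 1 for i, c in enumerate(protospacer) if c == "A"]
    if len(a_pos) <= max_positions:
        return tuple(a_pos)
    ranked = sorted(a_pos, key=lambda p: (abs(p - 6), p))
    return tuple(sorted(ranked[:max_positions]))


def enumerate_outcomes(protospacer: str, max_positions: int = 12) -> list[Outcome]:
    """All 2^k outcomes over the editable adenines, unedited mask first.

    Ordering is deterministic: the subset mask read as a little-endian integer
    over the (ascending) editable positions.
    """
    pos = editable_positions(protospacer, max_positions)
    k = len(pos)
    out = []
    for m in range(2 ** k):
        chosen = tuple(pos[j] for j in range(k) if m >> j & 1)
        out.append(apply_edits(protospacer, chosen))
    return out


@dataclass
class OutcomeDistribution:
    """Probability distribution over the outcomes of one target site."""

    site_id: str
    outcomes: list[Outcome]
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.outcomes) != len(self.probs):
            raise ValueError("outcomes and probs length mismatch")
        if np.any(self.probs < -NORM_TOL):
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > NORM_TOL:
            raise ValueError(f"probabilities sum to {self.probs.sum()!r}, not 1")
        if not any(not o.is_edited for o in self.outcomes):
            raise ValueError("unedited outcome missing from distribution")

    @property
    def unedited_index(self) -> int:
        return next(i for i, o in enumerate(self.outcomes) if not o.is_edited)


def total_efficiency(dist: OutcomeDistribution) -> float:
    """Total editing efficiency: probability of carrying ≥1 A→G conversion."""
    return float(1.0 - dist.probs[dist.unedited_index])


def per_position_efficiency(dist: OutcomeDistribution, length: int = 20) -> np.ndarray:
    """Marginal A→G probability for each protospacer position (length-20 vector)."""
    eff = np.zeros(length)
    for o, p in zip(dist.outcomes, dist.probs):
        for pos in o.positions:
            eff[pos - 1] += p
    return eff


def conditional_proportions(dist: OutcomeDistribution) -> dict[Outcome, float]:
    """Distribution within the edited reads: edited probs / total efficiency."""
    tot = total_efficiency(dist)
    if tot <= 0:
        raise ValueError("total efficiency is 0; conditional distribution undefined")
    return {o: float(p / tot) for o, p in zip(dist.outcomes, dist.probs) if o.is_edited}


def combine(site_id: str, efficiency: float, proportions: dict[Outcome, float],
            protospacer: str) -> OutcomeDistribution:
    """Recombine an efficiency and a conditional distribution into a full one."""
    if not 0 <= efficiency <= 1:
        raise ValueError(f"efficiency {efficiency} outside [0, 1]")
    outcomes = [apply_edits(protospacer, ())]
    probs = [1.0 - efficiency]
    for o, q in proportions.items():
        outcomes.append(o)
        probs.append(efficiency * q)
    return OutcomeDistribution(site_id, outcomes, np.array(probs))


def window_efficiency(dist: OutcomeDistribution, window: tuple[int, int]) -> float:
    """Probability of ≥1 edit inside a positional window [lo, hi] (inclusive)."""
    lo, hi = window
    p = 0.0
    for o, q in zip(dist.outcomes, dist.probs):
        if any(lo <= pos <= hi for pos in o.positions):
            p += q
    return float(p)
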