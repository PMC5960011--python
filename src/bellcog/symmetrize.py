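"""Rotation symmetrization of windrose coincidence data.

The raw experiment breaks the isotropy of space: respondents do not treat
North and South (or the other antipodal pairs) symmetrically, which shows
up as marginal-law violations.  The symmetrized protocols restore isotropy
by mixing, uniformly at random, rotated replicas of the whole measurement
configuration:

* coin flip: rotations {0°, 180°};
* octahedral die: rotations {0°, 45°, ..., 315°}.

Under the consistency assumption - a respondent selects the same unordered
pair of compass directions whichever rotated configuration presents it -
the rotated-replica probabilities are a pure reindexing of the unrotated
ones, so the mixed table can be computed exactly by averaging reindexed
copies of the original table.  The mix forces every marginal to 1/2
(restoring the marginal law) while leaving the CHSH combination S exactly
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core_tables import (
    MEASUREMENTS,
    CompassDirection,
    JointProbabilityTable,
    MeasurementScheme,
)

Slot = Tuple[str, int, int]  # (measurement id, i, j), one-based outcome indices


class MappingError(ValueError):
    """No unrotated slot matches a rotated direction pair."""


@dataclass(frozen=True)
class Rotation:
    """Clockwise rotation by a multiple of 45 degrees; composition is
    addition of ``k`` mod 8."""

    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= 7:
            raise ValueError(f"rotation index k must be in [0, 7], got {self.k}")

    @property
    def degrees(self) -> int:
        return 45 * self.k

    def __add__(self, other: "Rotation") -> "Rotation":
        return Rotation((self.k + other.k) % 8)

    @property
    def inverse(self) -> "Rotation":
        return Rotation((8 - self.k) % 8)


@dataclass(frozen=True)
class SlotCorrespondence:
    """Bijection from rotated slots to the unrotated slots holding the
    same unordered direction pair."""

    rotation: Rotation
    map: Dict[Slot, Slot]

    def __getitem__(self, slot: Slot) -> Slot:
        return self.map[slot]

    def inverse_map(self) -> Dict[Slot, Slot]:
        return {v: k for k, v in self.map.items()}


def rotate_direction(d: CompassDirection, r: Rotation) -> CompassDirection:
    """Rotate a compass direction clockwise by 45 k degrees."""
    return CompassDirection.from_angle(d.angle + r.degrees)


def correspondence(scheme: MeasurementScheme, r: Rotation) -> SlotCorrespondence:
    """Build the consistency reindexing for rotation ``r``.

    A rotated slot whose outcome directions are (d1, d2) maps to the
    unique unrotated slot whose *unordered* pair of directions equals
    {d1, d2}: the respondent selects a pair of directions, not an ordered
    assignment of directions to sub-systems.
    """
    by_pair: Dict[frozenset, Slot] = {}
    for m in MEASUREMENTS:
        for i in (1, 2):
            for j in (1, 2):
                pair = frozenset(scheme.slot_directions(m, i, j))
                if pair in by_pair:
                    raise MappingError(
                        f"scheme is degenerate: pair {sorted(d.name for d in pair)} "
                        f"appears in more than one slot"
                    )
                by_pair[pair] = (m, i, j)
    mapping: Dict[Slot, Slot] = {}
    for m in MEASUREMENTS:
        for i in (1, 2):
            for j in (1, 2):
                d1, d2 = scheme.slot_directions(m, i, j)
                pair = frozenset((rotate_direction(d1, r), rotate_direction(d2, r)))
                try:
                    mapping[(m, i, j)] = by_pair[pair]
                except KeyError:
                    raise MappingError(
                        f"rotated slot ({m}, ({i},{j})) with directions "
                        f"{sorted(d.name for d in pair)} matches no unrotated slot"
                    ) from None
    return SlotCorrespondence(rotation=r, map=mapping)


def rotated_table(table: JointProbabilityTable, r: Rotation) -> JointProbabilityTable:
    """Probabilities of the rotated replica, read off the unrotated data
    via the consistency correspondence."""
    corr = correspondence(table.scheme, r)
    p = {m: np.empty((2, 2)) for m in MEASUREMENTS}
    for m in MEASUREMENTS:
        for i in (1, 2):
            for j in (1, 2):
                ms, si, sj = corr[(m, i, j)]
                p[m][i - 1, j - 1] = table.cell(ms, si, sj)
    return JointProbabilityTable(p=p, scheme=table.scheme, n_participants=table.n_participants)


def mix_uniform(tables: Sequence[JointProbabilityTable]) -> JointProbabilityTable:
    """Cellwise arithmetic mean of tables sharing a scheme."""
    if len(tables) == 0:
        raise ValueError("cannot mix an empty list of tables")
    first = tables[0]
    for t in tables[1:]:
        if t.scheme != first.scheme:
            raise ValueError("all mixed tables must share a measurement scheme")
    p = {
        m: np.mean([t.block(m) for t in tables], axis=0)
        for m in MEASUREMENTS
    }
    return JointProbabilityTable(p=p, scheme=first.scheme, n_participants=first.n_participants)


def _symmetrize(table: JointProbabilityTable, ks: List[int]) -> JointProbabilityTable:
    return mix_uniform([rotated_table(table, Rotation(k)) for k in ks])


def symmetrize_180(table: JointProbabilityTable) -> JointProbabilityTable:
    """Coin-flip protocol: uniform mix of the 0° and 180° replicas."""
    return _symmetrize(table, [0, 4])


def symmetrize_octahedral(table: JointProbabilityTable) -> JointProbabilityTable:
    """Eight-face-die protocol: uniform mix of all eight 45° replicas."""
    return _symmetrize(table, list(range(8)))
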