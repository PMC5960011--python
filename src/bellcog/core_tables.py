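"""Data model for bipartite coincidence-experiment probability tables.

A "table" here is the full record of a four-measurement coincidence
experiment: for each joint measurement AB, AB', A'B, A'B' (one measurement
per sub-system, two outcomes each) it stores the four joint outcome
probabilities p(X_i, Y_j).  On such tables the module computes the two
statistics the analysis revolves around:

* the CHSH combination  S = E(A,B) - E(A,B') + E(A',B) + E(A',B'),
  where E(X,Y) = p11 - p12 - p21 + p22, whose classical (experimentally
  separated) bound is |S| <= 2;
* the eight marginal-law (no-signaling) residuals: differences between a
  sub-system's outcome marginals under the two possible partner
  measurements, all zero for experimentally separated sub-systems.

The concrete experiment this models asks respondents to pick a pair of
compass directions as a good example of *Two Different Wind Directions*;
outcomes are the eight windrose directions, arranged as four antipodal
measurement axes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

#: Canonical joint-measurement identifiers, in fixed order.  ASCII "p"
#: stands for the prime: ABp == AB'.
MEASUREMENTS: Tuple[str, str, str, str] = ("AB", "ABp", "ApB", "ApBp")

#: Axis names of the first (left) and second (right) sub-system.
FIRST_AXES: Tuple[str, str] = ("A", "Ap")
SECOND_AXES: Tuple[str, str] = ("B", "Bp")

#: measurement id -> (left axis, right axis)
MEASUREMENT_AXES: Dict[str, Tuple[str, str]] = {
    "AB": ("A", "B"),
    "ABp": ("A", "Bp"),
    "ApB": ("Ap", "B"),
    "ApBp": ("Ap", "Bp"),
}

#: Default normalization tolerance for program-generated tables.
TAU_NORM = 1e-9
#: Normalization slack appropriate for hand-entered 2-decimal tables.
TAU_NORM_PRINTED = 0.011
#: Default marginal-law tolerance.
TAU_MARG = 1e-9


class TableError(ValueError):
    """Base class for table validation failures."""


class NormalizationError(TableError):
    """A measurement block does not sum to one within tolerance."""


class NegativeProbabilityError(TableError):
    """A cell holds a negative probability."""


class CompassDirection(enum.Enum):
    """One of the eight windrose directions.

    The enum value is the compass angle in degrees, measured clockwise
    from North.
    """

    N = 0
    NE = 45
    E = 90
    SE = 135
    S = 180
    SW = 225
    W = 270
    NW = 315

    @property
    def angle(self) -> int:
        """Compass angle in degrees clockwise from North."""
        return self.value

    @classmethod
    def from_angle(cls, angle: int) -> "CompassDirection":
        return cls(angle % 360)

    @property
    def antipode(self) -> "CompassDirection":
        return CompassDirection.from_angle(self.angle + 180)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CompassDirection.{self.name}"


@dataclass(frozen=True)
class MeasurementAxis:
    """A two-outcome measurement along one compass axis.

    ``outcome1`` and ``outcome2`` are the directions selected when the
    measurement yields outcome 1 or 2; they must be antipodal.
    """

    name: str
    outcome1: CompassDirection
    outcome2: CompassDirection

    def __post_init__(self) -> None:
        if self.outcome2 is not self.outcome1.antipode:
            raise ValueError(
                f"axis {self.name}: outcomes {self.outcome1.name}/"
                f"{self.outcome2.name} are not antipodal"
            )

    def outcome(self, i: int) -> CompassDirection:
        """Direction for outcome index i in {1, 2}."""
        if i == 1:
            return self.outcome1
        if i == 2:
            return self.outcome2
        raise ValueError(f"outcome index must be 1 or 2, got {i}")


@dataclass(frozen=True)
class MeasurementScheme:
    """The four measurement axes of the windrose experiment.

    The eight outcome directions must tile the eight compass directions
    exactly.  The default is the published layout: A = (N, S),
    A' = (E, W), B = (NE, SW), B' = (SE, NW).
    """

    axes: Mapping[str, MeasurementAxis]

    def __post_init__(self) -> None:
        expected = set(FIRST_AXES) | set(SECOND_AXES)
        if set(self.axes) != expected:
            raise ValueError(f"scheme must define axes {sorted(expected)}")
        used = [ax.outcome(i) for ax in self.axes.values() for i in (1, 2)]
        if len(set(used)) != 8:
            raise ValueError(
                "scheme outcomes must cover all 8 compass directions exactly once"
            )

    @classmethod
    def windrose(cls) -> "MeasurementScheme":
        """The default windrose scheme of the experiment."""
        D = CompassDirection
        return cls(
            axes={
                "A": MeasurementAxis("A", D.N, D.S),
                "Ap": MeasurementAxis("Ap", D.E, D.W),
                "B": MeasurementAxis("B", D.NE, D.SW),
                "Bp": MeasurementAxis("Bp", D.SE, D.NW),
            }
        )

    def slot_directions(
        self, m: str, i: int, j: int
    ) -> Tuple[CompassDirection, CompassDirection]:
        """Direction pair selected at slot (m, (i, j))."""
        left, right = MEASUREMENT_AXES[m]
        return self.axes[left].outcome(i), self.axes[right].outcome(j)


def _as_block(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (2, 2):
        raise ValueError(f"each measurement block must be 2x2, got shape {a.shape}")
    return a


@dataclass
class JointProbabilityTable:
    """Joint outcome probabilities for the four coincidence measurements.

    ``p[m]`` is a 2x2 array indexed by (outcome of the left measurement,
    outcome of the right measurement), zero-based; ``cell(m, i, j)`` uses
    the one-based indices of the experimental notation p(X_i, Y_j).
    """

    p: Dict[str, np.ndarray]
    scheme: MeasurementScheme = field(default_factory=MeasurementScheme.windrose)
    n_participants: Optional[int] = None

    def __post_init__(self) -> None:
        missing = [m for m in MEASUREMENTS if m not in self.p]
        if missing:
            raise ValueError(f"table missing measurement blocks: {missing}")
        self.p = {m: _as_block(self.p[m]) for m in MEASUREMENTS}

    def block(self, m: str) -> np.ndarray:
        if m not in self.p:
            raise KeyError(f"unknown measurement id {m!r}; expected one of {MEASUREMENTS}")
        return self.p[m]

    def cell(self, m: str, i: int, j: int) -> float:
        """p(X_i, Y_j) with one-based outcome indices."""
        return float(self.block(m)[i - 1, j - 1])

    def copy(self) -> "JointProbabilityTable":
        return JointProbabilityTable(
            p={m: self.p[m].copy() for m in MEASUREMENTS},
            scheme=self.scheme,
            n_participants=self.n_participants,
        )

    @classmethod
    def uniform(cls, scheme: Optional[MeasurementScheme] = None) -> "JointProbabilityTable":
        """All sixteen cells equal to 1/4."""
        return cls(
            p={m: np.full((2, 2), 0.25) for m in MEASUREMENTS},
            scheme=scheme or MeasurementScheme.windrose(),
        )


@dataclass
class CorrelationSummary:
    """Bundled CHSH and marginal-law statistics of one table."""

    E: Dict[str, float]
    S: float
    absS: float
    marginal_residuals: np.ndarray
    marginal_ok: bool
    minus_term: str


def validate_table(
    table: JointProbabilityTable, tol: float = TAU_NORM
) -> JointProbabilityTable:
    """Check nonnegativity and per-block normalization.

    Returns the table unchanged when valid; probabilities are never
    silently renormalized.
    """
    for m in MEASUREMENTS:
        block = table.block(m)
        for (r, c), v in np.ndenumerate(block):
            if v < 0:
                raise NegativeProbabilityError(
                    f"cell ({m}, ({r + 1},{c + 1})) is negative: {v}"
                )
        s = float(block.sum())
        if abs(s - 1.0) > tol:
            raise NormalizationError(
                f"block {m} sums to {s}, outside tolerance {tol} of 1"
            )
    return table


def expectation_value(table: JointProbabilityTable, m: str) -> float:
    """Correlation E(X,Y) = p11 - p12 - p21 + p22 for block ``m``."""
    b = table.block(m)
    return float(b[0, 0] - b[0, 1] - b[1, 0] + b[1, 1])


def chsh_from_expectations(E: Mapping[str, float], minus_term: str = "ABp") -> float:
    """CHSH combination with the minus sign on ``minus_term``."""
    if minus_term not in MEASUREMENTS:
        raise ValueError(f"minus_term must be one of {MEASUREMENTS}")
    return float(sum(E[m] if m != minus_term else -E[m] for m in MEASUREMENTS))


def marginal_residuals(table: JointProbabilityTable) -> np.ndarray:
    """The eight signed marginal-law residuals, in the fixed order
    of the published comparison:

    rows of A vs AB'; columns of B vs A'B; rows of A' vs A'B';
    columns of B' vs A'B'.  Each residual is (left-hand marginal sum)
    minus (right-hand marginal sum); all zero iff the marginal law holds.
    """
    ab, abp = table.block("AB"), table.block("ABp")
    apb, apbp = table.block("ApB"), table.block("ApBp")
    res = [
        ab[0].sum() - abp[0].sum(),        # p(A1,B.) vs p(A1,B'.)
        ab[1].sum() - abp[1].sum(),        # p(A2,B.) vs p(A2,B'.)
        ab[:, 0].sum() - apb[:, 0].sum(),  # p(.,B1) under A vs A'
        ab[:, 1].sum() - apb[:, 1].sum(),  # p(.,B2) under A vs A'
        apb[0].sum() - apbp[0].sum(),      # p(A'1,B.) vs p(A'1,B'.)
        apb[1].sum() - apbp[1].sum(),      # p(A'2,B.) vs p(A'2,B'.)
        abp[:, 0].sum() - apbp[:, 0].sum(),  # p(.,B'1) under A vs A'
        abp[:, 1].sum() - apbp[:, 1].sum(),  # p(.,B'2) under A vs A'
    ]
    return np.array(res, dtype=float)


def chsh(
    table: JointProbabilityTable,
    minus_term: str = "ABp",
    tau_marg: float = TAU_MARG,
) -> CorrelationSummary:
    """Full correlation summary: per-measurement E, S, |S|, marginal residuals."""
    E = {m: expectation_value(table, m) for m in MEASUREMENTS}
    S = chsh_from_expectations(E, minus_term)
    res = marginal_residuals(table)
    return CorrelationSummary(
        E=E,
        S=S,
        absS=abs(S),
        marginal_residuals=res,
        marginal_ok=bool(np.max(np.abs(res)) <= tau_marg),
        minus_term=minus_term,
    )


def summarize(
    table: JointProbabilityTable,
    minus_term: str = "ABp",
    tau_marg: float = TAU_MARG,
    tol: float = TAU_NORM,
) -> CorrelationSummary:
    """Validate then summarize a table."""
    validate_table(table, tol=tol)
    return chsh(table, minus_term=minus_term, tau_marg=tau_marg)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Report-time rounding matching hand arithmetic on printed tables."""
    q = 10.0 ** decimals
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)
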