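"""Generalized rigid-rod model: two elastic-band "quantum machines".

Each sub-system is a Bloch sphere whose measurement is an elastic band
stretched along a diameter: the point particle falls orthogonally onto the
band, the band breaks at a uniformly random point of its breakable
segment, and the particle is drawn to the end point on the far side of the
break.  An (epsilon, d)-band is uniformly breakable only on
[d - epsilon, d + epsilon] (coordinates on [-1, 1], +1 end = outcome 1);
epsilon = 1, d = 0 reproduces Born statistics exactly.

The two spheres are entangled mechanically: both particles start at their
sphere centers joined by a rigid rod through a pivot, so the first
measurement's outcome forces the second particle to the antipodal point of
its own sphere, from which it falls onto the second band at coordinate
-(first outcome sign) * cos(theta), theta the relative band angle.  The
model violates the CHSH inequality (up to |S| = 4) through the rod alone,
while the marginal law is violated only by band asymmetry (d != 0) - and
asymmetry *reduces* |S|.  The two violations therefore have independent
mechanisms.

Closed forms assume the second particle always lands on a breakable
segment: |cos theta| <= epsilon - |d| for both bands of a pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .core_tables import (
    MEASUREMENT_AXES,
    MEASUREMENTS,
    JointProbabilityTable,
    MeasurementScheme,
)

SQRT2 = math.sqrt(2.0)


class AssumptionError(ValueError):
    """A particle can land outside a breakable segment for these parameters."""


@dataclass(frozen=True)
class ElasticBand:
    """An (epsilon, d) measurement band.

    ``epsilon``: half-length of the breakable segment, in (0, 1];
    ``d``: its center offset, |d| <= 1 - epsilon.
    """

    epsilon: float
    d: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in (0, 1], got {self.epsilon}")
        if abs(self.d) > 1.0 - self.epsilon + 1e-12:
            raise ValueError(
                f"|d| must be <= 1 - epsilon = {1 - self.epsilon}, got d={self.d}"
            )

    @property
    def breakable_margin(self) -> float:
        """epsilon - |d|: largest |coordinate| guaranteed breakable."""
        return self.epsilon - abs(self.d)

    def outcome1_probability(self, coord: float) -> float:
        """P(outcome 1) for a particle sitting at ``coord`` on the band:
        the band breaks below the particle with probability
        (coord - (d - epsilon)) / (2 epsilon)."""
        return (coord - self.d + self.epsilon) / (2.0 * self.epsilon)


def _check_landing(band: ElasticBand, theta: float) -> None:
    if abs(math.cos(theta)) > band.breakable_margin + 1e-12:
        raise AssumptionError(
            f"|cos(theta)| = {abs(math.cos(theta)):.6g} exceeds the breakable "
            f"margin epsilon - |d| = {band.breakable_margin:.6g}"
        )


def sequential_probs(
    first: ElasticBand, second: ElasticBand, theta: float
) -> np.ndarray:
    """Joint outcome probabilities of the sequential measurement
    'first then second', as a 2x2 array indexed (first outcome, second
    outcome), zero-based.

    p(1,1) = (eps1 - d1)/(2 eps1) * (eps2 - d2 - cos theta)/(2 eps2), etc.
    """
    _check_landing(second, theta)
    e1, d1 = first.epsilon, first.d
    e2, d2 = second.epsilon, second.d
    c = math.cos(theta)
    p_first1 = (e1 - d1) / (2 * e1)
    p_first2 = (e1 + d1) / (2 * e1)
    # after outcome +-1 on the first band, the second particle sits at -+ cos theta
    p11 = p_first1 * (e2 - d2 - c) / (2 * e2)
    p12 = p_first1 * (e2 + d2 + c) / (2 * e2)
    p21 = p_first2 * (e2 - d2 + c) / (2 * e2)
    p22 = p_first2 * (e2 + d2 - c) / (2 * e2)
    return np.array([[p11, p12], [p21, p22]])


def mixed_probs(left: ElasticBand, right: ElasticBand, theta: float) -> np.ndarray:
    """Order-mixed joint probabilities: uniform average of 'left then
    right' and 'right then left', indexed (left outcome, right outcome)."""
    _check_landing(left, theta)
    _check_landing(right, theta)
    ab = sequential_probs(left, right, theta)
    ba = sequential_probs(right, left, theta)
    return 0.5 * (ab + ba.T)


def rod_marginals(left: ElasticBand, right: ElasticBand, theta: float) -> np.ndarray:
    """The four order-mixed marginal sums, closed form:

    [p(L1,.), p(L2,.), p(.,R1), p(.,R2)] where e.g.
    p(L1,.) = (epsL - dL)/(2 epsL) + dR cos(theta)/(4 epsL epsR).
    The second term is the marginal-law violation; it vanishes when the
    partner band is symmetric (dR = 0) or the bands are orthogonal.
    """
    eL, dL = left.epsilon, left.d
    eR, dR = right.epsilon, right.d
    c = math.cos(theta)
    cross = c / (4 * eL * eR)
    return np.array(
        [
            (eL - dL) / (2 * eL) + dR * cross,
            (eL + dL) / (2 * eL) - dR * cross,
            (eR - dR) / (2 * eR) + dL * cross,
            (eR + dR) / (2 * eR) - dL * cross,
        ]
    )


def rod_expectation(e: ElasticBand, theta: float) -> float:
    """Order-mixed correlation when both bands share (epsilon, d):

    E = -cos(theta)/epsilon + d^2/epsilon^2.

    At (epsilon, d) = (1, 0) this is the singlet value -cos(theta).
    """
    return -math.cos(theta) / e.epsilon + e.d**2 / e.epsilon**2


def rod_chsh(e: ElasticBand) -> float:
    """|S| at the maximal-violation coplanar angle set (cosines +-sqrt2/2):

    |S| = 2 |sqrt(2)/epsilon - d^2/epsilon^2|.

    Requires epsilon - |d| >= sqrt(2)/2 so the angle set satisfies the
    breakable-landing assumption.  (1, 0) gives the Tsirelson value
    2 sqrt(2); the minimal admissible (sqrt(2)/2, 0) gives the algebraic
    maximum 4.  Increasing |d| (the marginal-law-violating asymmetry)
    only ever reduces |S|.
    """
    if e.breakable_margin < SQRT2 / 2 - 1e-12:
        raise AssumptionError(
            f"maximal-violation angles need epsilon - |d| >= sqrt(2)/2, "
            f"got {e.breakable_margin:.6g}"
        )
    return 2.0 * abs(SQRT2 / e.epsilon - e.d**2 / e.epsilon**2)


@dataclass
class RodConfig:
    """Bands and in-plane orientations for the four measurements.

    ``orientations`` holds one angle per measurement name (radians,
    measured like compass angles); the relative angle of a joint pair is
    the difference of its two orientations.  ``order_policy`` selects
    which sub-system is measured first in the simulator.
    """

    elastics: Dict[str, ElasticBand]
    orientations: Dict[str, float]
    order_policy: str = "uniform-mix"

    _POLICIES = ("first-left", "first-right", "uniform-mix")

    def __post_init__(self) -> None:
        for name in ("A", "Ap", "B", "Bp"):
            if name not in self.elastics:
                raise ValueError(f"missing elastic for measurement {name}")
            if name not in self.orientations:
                raise ValueError(f"missing orientation for measurement {name}")
        if self.order_policy not in self._POLICIES:
            raise ValueError(f"order_policy must be one of {self._POLICIES}")

    @classmethod
    def uniform(
        cls,
        epsilon: float = 1.0,
        d: float = 0.0,
        orientations: Optional[Mapping[str, float]] = None,
        order_policy: str = "uniform-mix",
    ) -> "RodConfig":
        """All four bands share (epsilon, d)."""
        band = ElasticBand(epsilon, d)
        if orientations is None:
            orientations = maximal_violation_orientations()
        return cls(
            elastics={n: band for n in ("A", "Ap", "B", "Bp")},
            orientations=dict(orientations),
            order_policy=order_policy,
        )

    def relative_angle(self, m: str) -> float:
        left, right = MEASUREMENT_AXES[m]
        return self.orientations[left] - self.orientations[right]

    def validate(self) -> "RodConfig":
        """Check the breakable-landing assumption for every joint pair."""
        for m in MEASUREMENTS:
            left, right = MEASUREMENT_AXES[m]
            c = abs(math.cos(self.relative_angle(m)))
            margin = min(
                self.elastics[left].breakable_margin,
                self.elastics[right].breakable_margin,
            )
            if c > margin + 1e-12:
                raise AssumptionError(
                    f"pair {m}: |cos(theta)| = {c:.6g} exceeds the breakable "
                    f"margin {margin:.6g}"
                )
        return self


def maximal_violation_orientations() -> Dict[str, float]:
    """Coplanar orientations realizing cos(theta_AB) = cos(theta_A'B) =
    cos(theta_A'B') = +sqrt(2)/2 and cos(theta_AB') = -sqrt(2)/2, the
    angle set that maximizes |S|."""
    return {"A": 0.0, "B": math.pi / 4, "Ap": math.pi / 2, "Bp": 3 * math.pi / 4}


@dataclass
class RodTrialRecord:
    """Trace of a single simulated coincidence trial."""

    measurement: str
    order: str  # "left-first" | "right-first"
    break_first: float
    break_second: float
    outcomes: Tuple[int, int]  # (left sign, right sign)


@dataclass
class RodSimulationResult:
    """Empirical table plus provenance of a rod simulation."""

    table: JointProbabilityTable
    counts: Dict[str, np.ndarray]
    n_trials: int
    seed: int
    generator: str = "numpy.random.PCG64"
    records: List[RodTrialRecord] = field(default_factory=list)


def simulate_rod(
    config: RodConfig,
    n_trials: int,
    seed: int,
    keep_records: bool = False,
    scheme: Optional[MeasurementScheme] = None,
) -> RodSimulationResult:
    """Monte-Carlo mechanics of the rod model, ``n_trials`` per joint pair.

    Per trial: the first particle sits at band coordinate 0; the break
    point is uniform on [d - epsilon, d + epsilon]; the outcome is +1 iff
    the break point is at or below the particle.  The rod places the
    second particle antipodally, i.e. at coordinate
    -(first outcome sign) * cos(theta) on the second band, where the same
    break rule applies.
    """
    if n_trials <= 0:
        raise ValueError(f"n_trials must be positive, got {n_trials}")
    config.validate()
    rng = np.random.default_rng(seed)
    counts: Dict[str, np.ndarray] = {}
    records: List[RodTrialRecord] = []
    for m in MEASUREMENTS:
        left_name, right_name = MEASUREMENT_AXES[m]
        bL, bR = config.elastics[left_name], config.elastics[right_name]
        c = math.cos(config.relative_angle(m))
        if config.order_policy == "first-left":
            left_first = np.ones(n_trials, dtype=bool)
        elif config.order_policy == "first-right":
            left_first = np.zeros(n_trials, dtype=bool)
        else:
            left_first = rng.random(n_trials) < 0.5
        # draw a break point on each band for every trial; only the
        # ordering decides which one is "first"
        brL = rng.uniform(bL.d - bL.epsilon, bL.d + bL.epsilon, n_trials)
        brR = rng.uniform(bR.d - bR.epsilon, bR.d + bR.epsilon, n_trials)
        sL = np.empty(n_trials, dtype=np.int8)
        sR = np.empty(n_trials, dtype=np.int8)
        # left measured first: left particle at 0, right at -sL*cos(theta)
        lf = left_first
        sL[lf] = np.where(brL[lf] <= 0.0, 1, -1)
        sR[lf] = np.where(brR[lf] <= -sL[lf] * c, 1, -1)
        # right measured first
        rf = ~left_first
        sR[rf] = np.where(brR[rf] <= 0.0, 1, -1)
        sL[rf] = np.where(brL[rf] <= -sR[rf] * c, 1, -1)
        block = np.zeros((2, 2))
        for i, si in ((0, 1), (1, -1)):
            for j, sj in ((0, 1), (1, -1)):
                block[i, j] = np.count_nonzero((sL == si) & (sR == sj))
        counts[m] = block
        if keep_records:
            for t in range(n_trials):
                records.append(
                    RodTrialRecord(
                        measurement=m,
                        order="left-first" if left_first[t] else "right-first",
                        break_first=float(brL[t] if left_first[t] else brR[t]),
                        break_second=float(brR[t] if left_first[t] else brL[t]),
                        outcomes=(int(sL[t]), int(sR[t])),
                    )
                )
    table = JointProbabilityTable(
        p={m: counts[m] / n_trials for m in MEASUREMENTS},
        scheme=scheme or MeasurementScheme.windrose(),
        n_participants=n_trials,
    )
    return RodSimulationResult(
        table=table, counts=counts, n_trials=n_trials, seed=seed, records=records
    )


def closed_form_table(
    config: RodConfig, scheme: Optional[MeasurementScheme] = None
) -> JointProbabilityTable:
    """Order-mixed closed-form probabilities for every joint pair of a
    uniform-mix config."""
    p = {}
    for m in MEASUREMENTS:
        left, right = MEASUREMENT_AXES[m]
        p[m] = mixed_probs(
            config.elastics[left], config.elastics[right], config.relative_angle(m)
        )
    return JointProbabilityTable(p=p, scheme=scheme or MeasurementScheme.windrose())


def fit_elastic(
    table: JointProbabilityTable,
    orientations: Mapping[str, float],
    x0: Tuple[float, float] = (0.9, 0.0),
) -> ElasticBand:
    """Estimate a shared (epsilon, d) from an (empirical) order-mixed table
    by least squares on the sixteen closed-form cells."""
    from scipy.optimize import least_squares

    angles = {
        m: orientations[MEASUREMENT_AXES[m][0]] - orientations[MEASUREMENT_AXES[m][1]]
        for m in MEASUREMENTS
    }
    min_eps = max(abs(math.cos(t)) for t in angles.values())

    def cells(e: float, d: float, theta: float) -> np.ndarray:
        # unchecked order-mixed closed form, valid as algebra for any e > 0
        c = math.cos(theta)
        seq = np.array(
            [
                [(e - d) * (e - d - c), (e - d) * (e + d + c)],
                [(e + d) * (e - d + c), (e + d) * (e + d - c)],
            ]
        ) / (4 * e * e)
        return 0.5 * (seq + seq.T)

    # parametrize d = f * (1 - epsilon), f in [-1, 1], so the admissible
    # region |d| <= 1 - epsilon is the box itself
    def unpack(x: np.ndarray) -> Tuple[float, float]:
        return float(x[0]), float(x[1]) * (1.0 - float(x[0]))

    def resid(x: np.ndarray) -> np.ndarray:
        e, d = unpack(x)
        out = []
        for m in MEASUREMENTS:
            out.append((cells(e, d, angles[m]) - table.block(m)).ravel())
        return np.concatenate(out)

    lo = [max(min_eps, 1e-6), -1.0]
    hi = [1.0, 1.0]
    e0 = min(max(x0[0], lo[0]), 1.0)
    f0 = 0.0 if e0 >= 1.0 else min(max(x0[1] / (1.0 - e0), -1.0), 1.0)
    sol = least_squares(resid, (e0, f0), bounds=(lo, hi))
    return ElasticBand(*unpack(sol.x))
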