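"""Singlet-state quantum model for symmetric coincidence tables.

The Hilbert space is C^2 (x) C^2.  The bipartite entity is prepared in the
rotationally invariant singlet state |Psi> = (|12> - |21>)/sqrt(2), and
each joint measurement is the product spin observable
(sigma . dL) (x) (sigma . dR) for unit Bloch directions dL, dR.  The Born
rule then gives, for outcome signs sL, sR in {+1, -1},

    p(sL, sR) = 1/4 (1 - sL sR  dL . dR),

so every block of the predicted table satisfies p11 = p22, p12 = p21,
E = -dL . dR, the marginal law holds exactly, and |S| <= 2 sqrt(2)
(Tsirelson bound).  ``solve_directions`` inverts this map: given a
symmetric table it finds four directions a, a', b, b' whose predicted
table reproduces it, using the closed-form gauge theta_a = 0,
phi_a = phi_b = 0, phi_a' = phi_b', and falling back to seeded
multi-start least squares when that gauge is insufficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .core_tables import (
    MEASUREMENT_AXES,
    MEASUREMENTS,
    JointProbabilityTable,
    MeasurementScheme,
    expectation_value,
)

#: direction name per sub-system axis, in the measurement-pair layout
DIRECTION_NAMES: Tuple[str, str, str, str] = ("a", "ap", "b", "bp")

#: measurement id -> (left direction name, right direction name)
MEASUREMENT_DIRECTIONS: Dict[str, Tuple[str, str]] = {
    "AB": ("a", "b"),
    "ABp": ("a", "bp"),
    "ApB": ("ap", "b"),
    "ApBp": ("ap", "bp"),
}

PAULI_X = np.array([[0, 1], [1, 0]], dtype=complex)
PAULI_Y = np.array([[0, -1j], [1j, 0]], dtype=complex)
PAULI_Z = np.array([[1, 0], [0, -1]], dtype=complex)

_FALLBACK_SEED = 1729
_FALLBACK_STARTS = 8


class InfeasibleTargetError(ValueError):
    """No product-measurement direction set reproduces the target table."""


@dataclass(frozen=True)
class BlochDirection:
    """A unit direction on the Bloch sphere in spherical coordinates.

    ``theta`` is the polar angle from +z, ``phi`` the azimuth from +x,
    both in radians.  ``xyz`` is the derived Cartesian unit vector
    (sin theta cos phi, sin theta sin phi, cos theta).
    """

    theta: float
    phi: float

    @property
    def xyz(self) -> np.ndarray:
        st = math.sin(self.theta)
        return np.array(
            [st * math.cos(self.phi), st * math.sin(self.phi), math.cos(self.theta)]
        )

    @classmethod
    def from_xyz(cls, v: Sequence[float]) -> "BlochDirection":
        v = np.asarray(v, dtype=float)
        n = np.linalg.norm(v)
        if not math.isclose(n, 1.0, abs_tol=1e-9):
            raise ValueError(f"direction must be a unit vector, norm={n}")
        theta = math.acos(max(-1.0, min(1.0, v[2] / n)))
        phi = math.atan2(v[1], v[0])
        return cls(theta=theta, phi=phi)

    def dot(self, other: "BlochDirection") -> float:
        return float(self.xyz @ other.xyz)


def singlet_state() -> np.ndarray:
    """|Psi> = (|f1 f2> - |f2 f1>) / sqrt(2) in the canonical product basis."""
    return np.array([0, 1, -1, 0], dtype=complex) / math.sqrt(2)


@dataclass
class SingletState:
    """The rotationally invariant two-qubit singlet."""

    amplitudes: np.ndarray = field(default_factory=singlet_state)


def spin_observable(d: BlochDirection) -> np.ndarray:
    """The spin observable sigma . d; Hermitian, traceless, eigenvalues +-1."""
    x, y, z = d.xyz
    return x * PAULI_X + y * PAULI_Y + z * PAULI_Z


def _single_eigenvector(theta: float, phi: float, sign: int) -> np.ndarray:
    """Eigenvector of sigma.d for eigenvalue ``sign`` in {+1,-1}, with the
    half-angle phase convention e^{-+ i phi/2} on the components."""
    c, s = math.cos(theta / 2), math.sin(theta / 2)
    em = np.exp(-0.5j * phi)
    ep = np.exp(0.5j * phi)
    if sign == +1:
        return np.array([c * em, s * ep])
    if sign == -1:
        return np.array([-s * em, c * ep])
    raise ValueError(f"eigenvalue sign must be +1 or -1, got {sign}")


def joint_eigenvector(
    dL: BlochDirection, dR: BlochDirection, sL: int, sR: int
) -> np.ndarray:
    """Product eigenvector of (sigma.dL) (x) (sigma.dR) with eigenvalue sL*sR."""
    return np.kron(
        _single_eigenvector(dL.theta, dL.phi, sL),
        _single_eigenvector(dR.theta, dR.phi, sR),
    )


def singlet_probability(
    dL: BlochDirection, dR: BlochDirection, sL: int, sR: int, method: str = "closed"
) -> float:
    """Born probability of the outcome pair (sL, sR) on the singlet.

    ``method="closed"`` uses 1/4 (1 - sL sR dL.dR); ``method="hilbert"``
    computes |<eigenvector|Psi>|^2 explicitly in C^4.  The two agree to
    machine precision.
    """
    if sL not in (1, -1) or sR not in (1, -1):
        raise ValueError("outcome signs must be +1 or -1")
    if method == "closed":
        return 0.25 * (1.0 - sL * sR * dL.dot(dR))
    if method == "hilbert":
        amp = np.vdot(joint_eigenvector(dL, dR, sL, sR), singlet_state())
        return float(abs(amp) ** 2)
    raise ValueError(f"unknown method {method!r}")


def predicted_table(
    directions: Mapping[str, BlochDirection],
    scheme: Optional[MeasurementScheme] = None,
) -> JointProbabilityTable:
    """Singlet Born probabilities for all 16 slots.

    ``directions`` maps the four names a, ap, b, bp to Bloch directions.
    Each block has E = -(dL . dR); the marginal law holds exactly.
    """
    missing = [n for n in DIRECTION_NAMES if n not in directions]
    if missing:
        raise ValueError(f"missing directions: {missing}")
    p = {}
    for m in MEASUREMENTS:
        ln, rn = MEASUREMENT_DIRECTIONS[m]
        dL, dR = directions[ln], directions[rn]
        block = np.empty((2, 2))
        for i, sL in ((1, +1), (2, -1)):
            for j, sR in ((1, +1), (2, -1)):
                block[i - 1, j - 1] = singlet_probability(dL, dR, sL, sR)
        p[m] = block
    return JointProbabilityTable(p=p, scheme=scheme or MeasurementScheme.windrose())


@dataclass
class QuantumModelSolution:
    """Solved measurement directions and the table they predict.

    ``residual`` is the max absolute cell difference between ``predicted``
    and the target; ``method`` records whether the closed-form gauge or
    the least-squares fallback produced the directions; ``branch`` is the
    sign used in theta_a' = theta_b' -+ arccos(-E(A'B')), surfacing the
    |theta_b' - theta_a'| ambiguity of the closed form.
    """

    directions: Dict[str, BlochDirection]
    predicted: JointProbabilityTable
    residual: float
    method: str
    branch: int = -1
    state: SingletState = field(default_factory=SingletState)


def _target_dots(target: JointProbabilityTable) -> Dict[str, float]:
    # E = -(dL . dR) for singlet product measurements
    return {m: -expectation_value(target, m) for m in MEASUREMENTS}


def _closed_form(
    c: Dict[str, float],
) -> Iterable[Tuple[int, Dict[str, BlochDirection]]]:
    """Candidate gauge-fixed solutions: theta_a=0, phi_a=phi_b=0,
    phi_a'=phi_b'; yields one candidate per feasible theta_a' branch."""
    if any(abs(v) > 1 + 1e-12 for v in c.values()):
        return
    clip = lambda x: max(-1.0, min(1.0, x))
    theta_b = math.acos(clip(c["AB"]))
    theta_bp = math.acos(clip(c["ABp"]))
    delta = math.acos(clip(c["ApBp"]))
    for branch in (-1, +1):
        theta_ap = theta_bp + branch * delta
        st = math.sin(theta_ap) * math.sin(theta_b)
        num = c["ApB"] - math.cos(theta_ap) * math.cos(theta_b)
        if abs(st) < 1e-15:
            if abs(num) > 1e-12:
                continue
            phi_ap = 0.0
        else:
            x = num / st
            if abs(x) > 1 + 1e-9:
                continue
            phi_ap = math.acos(clip(x))
        yield branch, {
            "a": BlochDirection(0.0, 0.0),
            "b": BlochDirection(theta_b, 0.0),
            "ap": BlochDirection(theta_ap, phi_ap),
            "bp": BlochDirection(theta_bp, phi_ap),
        }


def _residual(pred: JointProbabilityTable, target: JointProbabilityTable) -> float:
    return max(
        float(np.max(np.abs(pred.block(m) - target.block(m)))) for m in MEASUREMENTS
    )


def _lsq_fallback(target: JointProbabilityTable) -> Dict[str, BlochDirection]:
    """Multi-start bounded least squares on the five free gauge parameters
    (theta_b, theta_a', theta_b', phi_a', phi_b')."""

    def cells(params: np.ndarray) -> np.ndarray:
        tb, tap, tbp, pap, pbp = params
        dirs = {
            "a": BlochDirection(0.0, 0.0),
            "b": BlochDirection(tb, 0.0),
            "ap": BlochDirection(tap, pap),
            "bp": BlochDirection(tbp, pbp),
        }
        pred = predicted_table(dirs, scheme=target.scheme)
        return np.concatenate(
            [(pred.block(m) - target.block(m)).ravel() for m in MEASUREMENTS]
        )

    rng = np.random.default_rng(_FALLBACK_SEED)
    lo = np.array([0.0, -math.pi, 0.0, -math.pi, -math.pi])
    hi = np.array([math.pi, 2 * math.pi, math.pi, math.pi, math.pi])
    best, best_cost = None, np.inf
    for _ in range(_FALLBACK_STARTS):
        x0 = lo + (hi - lo) * rng.random(5)
        sol = least_squares(
            cells, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    tb, tap, tbp, pap, pbp = best.x
    return {
        "a": BlochDirection(0.0, 0.0),
        "b": BlochDirection(tb, 0.0),
        "ap": BlochDirection(tap, pap),
        "bp": BlochDirection(tbp, pbp),
    }


def solve_directions(
    target: JointProbabilityTable, tol: float = 1e-9
) -> QuantumModelSolution:
    """Find measurement directions whose singlet predictions match ``target``.

    The target must (within ``tol``) obey the marginal law and the block
    symmetry p11 = p22, p12 = p21 of a singlet product model.  The closed
    form is tried first (both theta_a' branches, preferring the published
    theta_a' = theta_b' - arccos(-E(A'B')) branch); if neither reaches
    ``tol`` the seeded least-squares fallback is used.  Raises
    :class:`InfeasibleTargetError` when no direction set reproduces the
    table within ``tol`` (e.g. a target beyond the Tsirelson bound).
    """
    c = _target_dots(target)
    best: Optional[QuantumModelSolution] = None
    for branch, dirs in _closed_form(c):
        pred = predicted_table(dirs, scheme=target.scheme)
        r = _residual(pred, target)
        if best is None or r < best.residual:
            best = QuantumModelSolution(
                directions=dirs, predicted=pred, residual=r,
                method="closed-form", branch=branch,
            )
        if r <= tol:
            break
    if best is None or best.residual > tol:
        dirs = _lsq_fallback(target)
        pred = predicted_table(dirs, scheme=target.scheme)
        r = _residual(pred, target)
        if best is None or r < best.residual:
            best = QuantumModelSolution(
                directions=dirs, predicted=pred, residual=r,
                method="least-squares", branch=0,
            )
    if best.residual > tol:
        raise InfeasibleTargetError(
            f"no product-measurement direction set reproduces the target "
            f"within tolerance {tol} (best residual {best.residual:.3g}); "
            f"the target may violate the marginal law, the block symmetry "
            f"p11=p22, p12=p21, or the Tsirelson bound"
        )
    return best


def pairwise_angles(vectors: Mapping[str, Sequence[float]]) -> Dict[Tuple[str, str], float]:
    """Angles (degrees) between every pair of direction vectors.

    Accepts raw 3-vectors or :class:`BlochDirection` values; the angle is
    arccos of the raw dot product, so slightly non-unit printed vectors
    are handled as printed.
    """
    xyz = {
        k: (v.xyz if isinstance(v, BlochDirection) else np.asarray(v, dtype=float))
        for k, v in vectors.items()
    }
    names = list(xyz)
    out: Dict[Tuple[str, str], float] = {}
    for idx, n1 in enumerate(names):
        for n2 in names[idx + 1:]:
            d = float(np.clip(xyz[n1] @ xyz[n2], -1.0, 1.0))
            out[(n1, n2)] = math.degrees(math.acos(d))
    return out


def max_chsh(n_starts: int = 16, seed: int = _FALLBACK_SEED) -> float:
    """Numerically maximize |S| over the four measurement directions.

    Returns the attained maximum, which for singlet product measurements
    is the Tsirelson bound 2 sqrt(2).
    """
    from scipy.optimize import minimize

    def neg_abs_s(x: np.ndarray) -> float:
        dirs = {
            "a": BlochDirection(x[0], x[1]),
            "ap": BlochDirection(x[2], x[3]),
            "b": BlochDirection(x[4], x[5]),
            "bp": BlochDirection(x[6], x[7]),
        }
        E = {
            m: -dirs[l].dot(dirs[r]) for m, (l, r) in MEASUREMENT_DIRECTIONS.items()
        }
        S = E["AB"] - E["ABp"] + E["ApB"] + E["ApBp"]
        return -abs(S)

    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(n_starts):
        x0 = rng.uniform([0, -math.pi] * 4, [math.pi, math.pi] * 4)
        res = minimize(neg_abs_s, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = max(best, -res.fun)
    return best
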