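"""Synthetic respondent sampling for the windrose coincidence experiment.

Emulates the study design: each of ``n`` participants (85 in the original
study) answers all four joint measurements, selecting one outcome pair per
measurement from that measurement's categorical distribution.  Counts are
the primitive record; probability tables are derived views.

The rotated-protocol samplers realize the symmetrized experiments
stochastically: a rotation is actually drawn per participant (coin for
{0°, 180°}, octahedral die for the eight 45° multiples) and the
participant's choices are the deterministic consistency images of latent
unrotated draws - no new randomness enters beyond the rotation draw.
A percentile bootstrap over participants supplies resampling uncertainty
for any table statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .core_tables import (
    MEASUREMENTS,
    JointProbabilityTable,
    MeasurementScheme,
    validate_table,
)
from .symmetrize import Rotation, correspondence

PROTOCOLS = ("plain", "coin-180", "octahedral")

#: pair index encoding: (i, j) one-based -> 2*(i-1) + (j-1) in 0..3
def pair_index(i: int, j: int) -> int:
    return 2 * (i - 1) + (j - 1)


def pair_from_index(q: int) -> Tuple[int, int]:
    return q // 2 + 1, q % 2 + 1


@dataclass
class RespondentSample:
    """Per-participant outcome selections for the four joint measurements.

    ``choices[m]`` is an integer array of shape (n,) with values 0..3
    encoding the selected outcome pair of measurement ``m`` (row-major
    over (i, j)).  For rotated protocols, ``rotations`` records each
    participant's drawn rotation index k.
    """

    n: int
    choices: Dict[str, np.ndarray]
    protocol: str = "plain"
    seed: Optional[int] = None
    scheme: MeasurementScheme = field(default_factory=MeasurementScheme.windrose)
    rotations: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        for m in MEASUREMENTS:
            a = np.asarray(self.choices[m])
            if a.shape != (self.n,) or a.min(initial=0) < 0 or a.max(initial=0) > 3:
                raise ValueError(f"choices[{m}] must be (n,) ints in 0..3")

    def counts(self) -> Dict[str, np.ndarray]:
        """Per-measurement 2x2 outcome-pair counts."""
        return {
            m: np.bincount(self.choices[m], minlength=4).reshape(2, 2).astype(float)
            for m in MEASUREMENTS
        }

    def empirical_table(self) -> JointProbabilityTable:
        """Counts normalized per block."""
        return JointProbabilityTable(
            p={m: c / self.n for m, c in self.counts().items()},
            scheme=self.scheme,
            n_participants=self.n,
        )


def _categorical_draws(
    rng: np.random.Generator,
    table: JointProbabilityTable,
    n: int,
    coupling: float,
) -> Dict[str, np.ndarray]:
    choices: Dict[str, np.ndarray] = {}
    if coupling > 0.0:
        coupled = rng.random(n) < coupling
        shared_u = rng.random(n)
    for m in MEASUREMENTS:
        p = table.block(m).ravel()
        p = p / p.sum()
        draws = rng.choice(4, size=n, p=p)
        if coupling > 0.0:
            # comonotone coupling: coupled participants use one shared
            # uniform through each block's inverse CDF
            cum = np.cumsum(p)
            draws = np.where(coupled, np.searchsorted(cum, shared_u[: n]), draws)
        choices[m] = draws.astype(np.int64)
    return choices


def sample_plain(
    table: JointProbabilityTable,
    n: int = 85,
    seed: Optional[int] = None,
    coupling: float = 0.0,
) -> RespondentSample:
    """Independent categorical draws, one per participant per measurement.

    ``coupling`` (default 0, the study assumption) is an optional latent
    shared-pair-preference extension: with that probability a participant
    uses a single latent uniform across all four blocks.
    """
    if n <= 0:
        raise ValueError(f"participant count must be positive, got {n}")
    validate_table(table, tol=0.011)
    rng = np.random.default_rng(seed)
    return RespondentSample(
        n=n,
        choices=_categorical_draws(rng, table, n, coupling),
        protocol="plain",
        seed=seed,
        scheme=table.scheme,
    )


def _rotation_maps(
    scheme: MeasurementScheme, r: Rotation
) -> Dict[str, Tuple[str, np.ndarray]]:
    """For each rotated measurement m: the unrotated measurement m' its
    slots draw from, and the permutation taking an unrotated pair index
    of m' to the rotated pair index of m."""
    corr = correspondence(scheme, r)
    out: Dict[str, Tuple[str, np.ndarray]] = {}
    for m in MEASUREMENTS:
        perm = np.empty(4, dtype=np.int64)
        source = None
        for i in (1, 2):
            for j in (1, 2):
                ms, si, sj = corr[(m, i, j)]
                if source is None:
                    source = ms
                elif source != ms:  # pragma: no cover - impossible for tiling schemes
                    raise ValueError("correspondence mixes source measurements")
                perm[pair_index(si, sj)] = pair_index(i, j)
        out[m] = (source, perm)
    return out


def apply_consistency(sample: RespondentSample, r: Rotation) -> RespondentSample:
    """Choices each participant would make in the r-rotated configuration.

    Deterministic: the rotated choice is the unique slot presenting the
    same unordered direction pair the participant selected unrotated.
    The empirical table of the result equals ``rotated_table`` of the
    sample's empirical table, for any seed.
    """
    maps = _rotation_maps(sample.scheme, r)
    choices = {
        m: perm[sample.choices[source]] for m, (source, perm) in maps.items()
    }
    return RespondentSample(
        n=sample.n,
        choices=choices,
        protocol=sample.protocol,
        seed=sample.seed,
        scheme=sample.scheme,
        rotations=np.full(sample.n, r.k, dtype=np.int64),
    )


def sample_mixed_protocol(
    table: JointProbabilityTable,
    n: int = 85,
    protocol: str = "coin-180",
    seed: Optional[int] = None,
    coupling: float = 0.0,
) -> RespondentSample:
    """Stochastic symmetrized protocols: per participant, draw a rotation
    (coin: k in {0, 4}; octahedral: k in 0..7), then record the
    consistency images of latent plain-protocol draws.  The empirical
    table estimates the corresponding exactly symmetrized table.
    """
    if protocol not in ("coin-180", "octahedral"):
        raise ValueError("protocol must be 'coin-180' or 'octahedral'")
    if n <= 0:
        raise ValueError(f"participant count must be positive, got {n}")
    validate_table(table, tol=0.011)
    rng = np.random.default_rng(seed)
    ks = rng.choice([0, 4] if protocol == "coin-180" else np.arange(8), size=n)
    latent = _categorical_draws(rng, table, n, coupling)
    choices = {m: np.empty(n, dtype=np.int64) for m in MEASUREMENTS}
    for k in np.unique(ks):
        sel = ks == k
        maps = _rotation_maps(table.scheme, Rotation(int(k)))
        for m, (source, perm) in maps.items():
            choices[m][sel] = perm[latent[source][sel]]
    return RespondentSample(
        n=n,
        choices=choices,
        protocol=protocol,
        seed=seed,
        scheme=table.scheme,
        rotations=ks.astype(np.int64),
    )


@dataclass
class BootstrapResult:
    """Percentile bootstrap of a table statistic over participants."""

    point: float
    lower: float
    upper: float
    reps: int
    seed: Optional[int]
    values: np.ndarray


def bootstrap_statistic(
    sample: RespondentSample,
    statistic: Callable[[JointProbabilityTable], float],
    reps: int = 1000,
    seed: Optional[int] = None,
) -> BootstrapResult:
    """Resample participants with replacement; 2.5/97.5 percentile interval."""
    if reps <= 0:
        raise ValueError(f"reps must be positive, got {reps}")
    rng = np.random.default_rng(seed)
    point = float(statistic(sample.empirical_table()))
    values = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, sample.n, size=sample.n)
        boot = RespondentSample(
            n=sample.n,
            choices={m: sample.choices[m][idx] for m in MEASUREMENTS},
            protocol=sample.protocol,
            seed=sample.seed,
            scheme=sample.scheme,
        )
        values[r] = statistic(boot.empirical_table())
    lower, upper = np.percentile(values, [2.5, 97.5])
    return BootstrapResult(
        point=point, lower=float(lower), upper=float(upper),
        reps=reps, seed=seed, values=values,
    )
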