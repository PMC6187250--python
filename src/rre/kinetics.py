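"""Kinetic core: rate laws and trajectory simulation for a two-biomarker cascade.

The model treats two regional imaging biomarkers (SUVR- or binding-potential-like
concentration proxies, unitless; time in years) as species in a biochemical
reaction in which the *upstream* species BP1 drives production of the
*downstream* species BP2:

    a BP1 + sum_i b_i B_i  ->  m BP2 + sum_j n_j C_j

with unknown bath species ``B_i`` (reactants already abundant in healthy tissue)
and by-products ``C_j``.  The reaction speed follows a power rate law

    d[BP2]/dt = -(m/a) d[BP1]/dt = k [BP1]^x * prod_i [B_i]^{y_i}

When the bath species start in large excess over BP1 ([B_i]_0 >> [BP1]_0) their
concentrations are effectively constant and fold into a pseudo-first-order
effective constant k' = k * prod_i [B_i]_0^{y_i}, leaving the reduced law

    d[BP2]/dt = k' [BP1]^x

Only BP1 and BP2 are observable; the bath enters through k'.  This module
simulates both the full (bath-depleting) and reduced (closed two-species)
systems and provides the finite-difference rate estimates that the log-linear
estimators consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ReactionSpec",
    "SystemState",
    "Trajectory",
    "rate_reduced",
    "rate_full",
    "effective_kprime",
    "simulate_closed",
    "simulate_full",
    "trajectory_rates",
    "finite_difference_rates",
    "write_trajectory",
    "read_trajectory",
]

#: integrator tolerances: closed-form cross-checks demand ~1e-6 relative
#: agreement, so integrate well below that.
_RTOL = 1e-8
_ATOL = 1e-10


@dataclass(frozen=True)
class ReactionSpec:
    """The kinetic hypothesis for one ordered biomarker pair.

    Parameters
    ----------
    kprime
        Effective pseudo-first-order rate constant k' (per year) of the
        reduced law.  This is the constant the estimators recover.
    x
        Reaction order of the upstream species (dimensionless, > 0).  Need
        not equal the stoichiometric coefficient ``a``.
    k
        Rate constant of the full law (per year).  Defaults to ``kprime``,
        which is exactly consistent when the bath factor is 1 (empty bath or
        unit bath concentrations).
    y
        Reaction orders of the bath species, one per bath component.
    a, m
        Stoichiometric coefficients of the upstream and downstream species
        (>= 1).  One reaction event consumes ``a`` units of BP1 and produces
        ``m`` units of BP2.
    direction
        Which labeled biomarker plays the upstream role, as a
        ``(upstream_label, downstream_label)`` pair.
    """

    kprime: float = 0.05
    x: float = 1.0
    k: float | None = None
    y: tuple[float, ...] = ()
    a: float = 1.0
    m: float = 1.0
    direction: tuple[str, str] = ("BP1", "BP2")

    def __post_init__(self) -> None:
        if self.k is None:
            object.__setattr__(self, "k", float(self.kprime))
        object.__setattr__(self, "y", tuple(float(v) for v in self.y))
        if not (self.kprime > 0 or self.kprime == 0):
            raise ValueError(f"kprime must be >= 0, got {self.kprime}")
        if self.kprime < 0 or self.k < 0:
            raise ValueError("rate constants must be nonnegative")
        if not self.x > 0:
            raise ValueError(f"reaction order x must be > 0, got {self.x}")
        if self.a < 1 or self.m < 1:
            raise ValueError("stoichiometric coefficients a, m must be >= 1")
        if len(self.direction) != 2 or self.direction[0] == self.direction[1]:
            raise ValueError("direction must name two distinct biomarker labels")


@dataclass(frozen=True)
class SystemState:
    """Concentrations of the modeled species at one instant (all >= 0)."""

    bp1: float
    bp2: float
    bath: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "bath", tuple(float(v) for v in self.bath))
        if self.bp1 < 0 or self.bp2 < 0 or any(b < 0 for b in self.bath):
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed concentrations for one subject/region.

    ``times`` is strictly increasing (years); ``bp1``/``bp2`` are aligned 1-D
    arrays and ``bath`` is ``(n_times, n_bath)``.
    """

    times: np.ndarray
    bp1: np.ndarray
    bp2: np.ndarray
    bath: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        bp1 = np.asarray(self.bp1, dtype=float)
        bp2 = np.asarray(self.bp2, dtype=float)
        bath = np.asarray(self.bath, dtype=float)
        if bath.size == 0:
            bath = np.empty((len(times), 0))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "bp1", bp1)
        object.__setattr__(self, "bp2", bp2)
        object.__setattr__(self, "bath", bath)
        if not (len(times) == len(bp1) == len(bp2) == len(bath)):
            raise ValueError("times, bp1, bp2, bath must have equal length")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def states(self) -> list[SystemState]:
        return [
            SystemState(self.bp1[i], self.bp2[i], tuple(self.bath[i]))
            for i in range(len(self.times))
        ]

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "bp1": self.bp1, "bp2": self.bp2}
        for j in range(self.bath.shape[1]):
            data[f"bath_{j + 1}"] = self.bath[:, j]
        return pd.DataFrame(data)


def rate_reduced(bp1, spec: ReactionSpec):
    """Reduced (pseudo-first-order) rate law: k' * [BP1]^x.

    Accepts a scalar or array of nonnegative concentrations; returns the
    reaction rate (concentration per year).  Zero iff ``bp1`` is zero.
    """
    bp1 = np.asarray(bp1, dtype=float)
    if np.any(bp1 < 0):
        raise ValueError("bp1 must be nonnegative")
    out = spec.kprime * bp1**spec.x
    return float(out) if out.ndim == 0 else out


def rate_full(state: SystemState, spec: ReactionSpec) -> float:
    """Full rate law: k * [BP1]^x * prod_i [B_i]^{y_i}.

    Equals :func:`rate_reduced` whenever the bath is frozen at values with
    ``k * prod(bath**y) == kprime``.
    """
    if len(spec.y) != len(state.bath):
        raise ValueError(
            f"bath/order length mismatch: {len(state.bath)} bath species, "
            f"{len(spec.y)} orders"
        )
    bath = np.asarray(state.bath, dtype=float)
    return float(spec.k * state.bp1**spec.x * np.prod(bath ** np.asarray(spec.y)))


def effective_kprime(spec: ReactionSpec, bath0) -> float:
    """k' implied by freezing the bath at ``bath0``: k * prod(bath0**y)."""
    bath0 = np.asarray(bath0, dtype=float)
    if len(spec.y) != len(bath0):
        raise ValueError("bath/order length mismatch")
    return float(spec.k * np.prod(bath0 ** np.asarray(spec.y)))


def _check_grid(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("times must be a 1-D grid with at least 2 points")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return times


def _integrate(rhs, y0, times: np.ndarray) -> np.ndarray:
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    # the power law's domain is [0, inf); clip tiny negative excursions
    return np.maximum(sol.y, 0.0)


def simulate_closed(spec: ReactionSpec, init: SystemState, times) -> Trajectory:
    """Integrate the closed two-species system under the reduced rate law.

    d[BP1]/dt = -a * k'[BP1]^x,  d[BP2]/dt = +m * k'[BP1]^x.

    For a = m = 1 the total BP1 + BP2 is conserved and the two rates are exact
    negatives of each other.  Bath concentrations in ``init`` are carried
    through unchanged.
    """
    times = _check_grid(times)

    def rhs(_t, yv):
        r = spec.kprime * max(yv[0], 0.0) ** spec.x
        return (-spec.a * r, spec.m * r)

    y = _integrate(rhs, (init.bp1, init.bp2), times)
    bath = np.tile(np.asarray(init.bath, dtype=float), (len(times), 1))
    return Trajectory(times, y[0], y[1], bath)


def simulate_full(
    spec: ReactionSpec,
    init: SystemState,
    times,
    bath_stoichiometry: tuple[float, ...] | None = None,
) -> Trajectory:
    """Integrate the full rate law with bath depletion.

    Each reaction event consumes bath species with unit stoichiometry by
    default (``bath_stoichiometry`` overrides, one coefficient per bath
    component).  As ``init.bath`` grows large relative to ``init.bp1`` the
    result converges to :func:`simulate_closed` with
    ``kprime = effective_kprime(spec, init.bath)``.
    """
    times = _check_grid(times)
    nb = len(init.bath)
    if len(spec.y) != nb:
        raise ValueError("bath/order length mismatch between spec.y and init.bath")
    stoich = np.ones(nb) if bath_stoichiometry is None else np.asarray(
        bath_stoichiometry, dtype=float
    )
    if len(stoich) != nb:
        raise ValueError("bath_stoichiometry length must match bath size")
    yexp = np.asarray(spec.y)

    def rhs(_t, yv):
        bp1 = max(yv[0], 0.0)
        bath = np.maximum(yv[2:], 0.0)
        r = spec.k * bp1**spec.x * np.prod(bath**yexp)
        return np.concatenate(([-spec.a * r, spec.m * r], -stoich * r))

    y0 = np.concatenate(([init.bp1, init.bp2], init.bath))
    y = _integrate(rhs, y0, times)
    return Trajectory(times, y[0], y[1], y[2:].T)


def finite_difference_rates(times, values) -> np.ndarray:
    """Finite-difference d(value)/dt on a (possibly nonuniform) grid.

    Second-order central differences at interior points (exact for
    quadratics), first-order one-sided at the two endpoints.  Requires at
    least 3 grid points.  Downstream fitting may drop the two endpoint
    estimates, which carry O(h) bias.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 grid points for rate estimates")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return np.gradient(values, times, edge_order=1)


def trajectory_rates(traj: Trajectory) -> np.ndarray:
    """Per-grid-point estimates of d[BP2]/dt for a simulated trajectory."""
    return finite_difference_rates(traj.times, traj.bp2)


def write_trajectory(traj: Trajectory, path) -> None:
    """Serialize to delimited text at 17 significant digits (round-trips doubles)."""
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    bath_cols = [c for c in df.columns if c.startswith("bath_")]
    return Trajectory(
        df["time"].to_numpy(),
        df["bp1"].to_numpy(),
        df["bp2"].to_numpy(),
        df[bath_cols].to_numpy() if bath_cols else np.empty((len(df), 0)),
    )
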