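"""Stochastic half-cell model of microtubule-driven cell elongation.

A fixed pool of ``N_m`` microtubules nucleates at the cell centre and grows
toward the cell boundary at velocity ``v_g``.  Each microtubule undergoes
catastrophe stochastically — at rate ``c_I`` in the cell interior and at the
elevated rate ``c_B`` once its tip is inside the cortex zone (within ``w_c``
of the boundary).  A catastrophe instantly resets the microtubule to zero
length (no rescue, no shrinkage phase), so the number of growing microtubules
is conserved.  Microtubules whose tips contact the cortex jointly push the
boundary outward with velocity ``v_g * exp(-alpha / n)`` for ``n`` contacts,
against a constant retraction ``v_B``; with no contacts the boundary retracts
at ``v_B``.

Time integration is fixed-step Euler with a per-step Bernoulli catastrophe
trial of probability ``dt * c_m`` per microtubule.  One half-cell boundary is
simulated; reported cell length is twice the boundary position.  Units are
micrometres and minutes throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

logger = logging.getLogger("mtlength")

__all__ = [
    "SimulationParams",
    "MicrotubuleEnsemble",
    "CellTrajectory",
    "make_params",
    "catastrophe_rate_for",
    "boundary_velocity",
    "step",
    "simulate",
    "catastrophe_waiting_times",
]

#: Maximum allowed per-step catastrophe probability.  Beyond this the
#: Bernoulli trial is a poor approximation of the exponential hazard.
MAX_HAZARD_PER_STEP = 0.1


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Model rates, counts and numerical controls.

    Defaults are the published parameter set for HeLa-like cells on adhesive
    lines: growth velocity and catastrophe rates from live-imaging
    measurements, retraction rate from microtubule-free cells, and the two
    free parameters ``N_m`` and ``alpha`` at the values used for the
    reference simulations.

    Parameters
    ----------
    v_g : float
        Microtubule growth (polymerisation) velocity, µm/min.
    c_I : float
        Catastrophe rate in the cell interior, 1/min.
    c_B : float
        Catastrophe rate at the cell boundary (cortex zone), 1/min.
    v_B : float
        Boundary retraction rate with no microtubule contact, µm/min.
    N_m : int
        Number of microtubule nucleation sites (pool size).
    alpha : float
        Dimensionless cooperation constant of the boundary-advance factor
        ``exp(-alpha / n)``.
    dt : float
        Euler time step, min.
    w_c : float
        Cortex-zone width: tips within this distance of the boundary count
        as contacting, µm.
    L0 : float
        Initial half-cell boundary position, µm.
    seed : int
        Seed of the per-simulation random stream.
    """

    v_g: float = 15.0
    c_I: float = 0.3
    c_B: float = 4.8
    v_B: float = 0.4
    N_m: int = 11
    alpha: float = 8.0
    dt: float = 0.001
    w_c: float = 3.0
    L0: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.v_g > 0, "v_g", "must be > 0"),
            (self.v_B >= 0, "v_B", "must be >= 0"),
            (self.c_I >= 0, "c_I", "must be >= 0"),
            (self.c_B >= 0, "c_B", "must be >= 0"),
            (self.N_m >= 0 and self.N_m == int(self.N_m), "N_m",
             "must be a non-negative integer"),
            (self.alpha >= 0, "alpha", "must be >= 0"),
            (self.dt > 0, "dt", "must be > 0"),
            (self.w_c > 0, "w_c", "must be > 0"),
            (self.L0 >= self.w_c, "L0", "must be >= w_c"),
        ]
        for ok, name, msg in checks:
            if not ok:
                raise ValueError(f"SimulationParams.{name} {msg} "
                                 f"(got {getattr(self, name)!r})")
        hazard = self.dt * max(self.c_I, self.c_B)
        if hazard > MAX_HAZARD_PER_STEP:
            raise ValueError(
                f"SimulationParams.dt: dt*max(c_I, c_B) = {hazard:.3g} exceeds "
                f"{MAX_HAZARD_PER_STEP}; the per-step Bernoulli catastrophe "
                f"trial no longer approximates the exponential hazard "
                f"(reduce dt or the catastrophe rates)")

    def replace(self, **overrides) -> "SimulationParams":
        """Return a validated copy with the given fields replaced."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_params(**overrides) -> SimulationParams:
    """Build a :class:`SimulationParams` from defaults plus overrides.

    Raises
    ------
    ValueError
        If an override names an unknown field or violates an invariant
        (for example ``dt * c_B > 0.1``).
    """
    return SimulationParams().replace(**overrides)


# ---------------------------------------------------------------------------
# Ensemble and trajectory containers
# ---------------------------------------------------------------------------

@dataclass
class MicrotubuleEnsemble:
    """Lengths of the ``N_m`` microtubules, measured from the cell centre."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 1:
            raise ValueError("lengths must be a 1-D array")

    @classmethod
    def initial(cls, params: SimulationParams) -> "MicrotubuleEnsemble":
        """All microtubules start at the nucleation centre (length 0)."""
        return cls(np.zeros(params.N_m))

    def contact_mask(self, boundary: float, params: SimulationParams) -> np.ndarray:
        """Boolean mask of boundary microtubules (tip within w_c, inclusive)."""
        return boundary - self.lengths <= params.w_c

    def n_contact(self, boundary: float, params: SimulationParams) -> int:
        return int(np.count_nonzero(self.contact_mask(boundary, params)))

    def catastrophe_rates(self, boundary: float,
                          params: SimulationParams) -> np.ndarray:
        """Per-microtubule catastrophe rate c_m (1/min): c_B in the cortex
        zone, c_I in the interior."""
        return np.where(self.contact_mask(boundary, params),
                        params.c_B, params.c_I)

    def velocities(self, boundary: float, params: SimulationParams) -> np.ndarray:
        """Per-microtubule effective tip velocity v_m (µm/min): v_g for free
        tips, the boundary's own velocity for tips capped at the boundary."""
        capped = self.lengths >= boundary
        n = self.n_contact(boundary, params)
        return np.where(capped, boundary_velocity(n, params), params.v_g)


@dataclass
class CellTrajectory:
    """Recorded time series of one simulation.

    ``L_B_series`` is the half-cell boundary position; reported cell length
    is ``2 * L_B``.  ``n_B_series`` is the number of microtubules in contact
    with the cortex zone at each recorded time.
    """

    times: np.ndarray
    L_B_series: np.ndarray
    n_B_series: np.ndarray
    params: SimulationParams
    snapshots: np.ndarray | None = None   # (n_records, N_m) tip lengths
    final_lengths: np.ndarray | None = None
    final_boundary: float | None = None
    t_switch: float | None = None         # set by perturbation protocols

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.L_B_series) == len(self.n_B_series)):
            raise ValueError("trajectory series must have equal length")

    @property
    def cell_length_series(self) -> np.ndarray:
        """Full cell length (twice the half-cell boundary position), µm."""
        return 2.0 * self.L_B_series

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_min": self.times,
            "L_B_um": self.L_B_series,
            "n_B": self.n_B_series.astype(int),
            "cell_length_um": self.cell_length_series,
        })

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write the tidy trajectory CSV plus a JSON parameter sidecar."""
        from . import __version__

        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {
                "params": self.params.to_dict(),
                "seed": self.params.seed,
                "t_switch_min": self.t_switch,
                "package_version": __version__,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# Elementary rates
# ---------------------------------------------------------------------------

def catastrophe_rate_for(tip_position: float, boundary: float,
                         params: SimulationParams) -> float:
    """Catastrophe rate (1/min) for a tip at the given position.

    Returns ``c_B`` when the tip is within the cortex zone (distance to the
    boundary <= ``w_c``, inclusive), ``c_I`` otherwise.
    """
    if tip_position < 0 or tip_position > boundary:
        raise ValueError(
            f"tip position {tip_position} outside [0, boundary={boundary}]")
    return params.c_B if boundary - tip_position <= params.w_c else params.c_I


def boundary_velocity(n_contact: int, params: SimulationParams) -> float:
    """Boundary velocity (µm/min) for ``n_contact`` cortex contacts.

    ``v_g * exp(-alpha / n) - v_B``, with the convention ``exp(-alpha/0) := 0``
    so that zero contacts give pure retraction at ``-v_B``.
    """
    if n_contact < 0:
        raise ValueError(f"negative contact count: {n_contact}")
    if n_contact == 0:
        return -params.v_B
    return params.v_g * math.exp(-params.alpha / n_contact) - params.v_B


# ---------------------------------------------------------------------------
# One Euler step (reference implementation)
# ---------------------------------------------------------------------------

def step(params: SimulationParams, ensemble: MicrotubuleEnsemble,
         boundary: float, rng: np.random.Generator
         ) -> tuple[MicrotubuleEnsemble, float]:
    """Advance the system by one time step ``dt``.

    Per microtubule (in index order): draw ``r`` uniform on [0, 1); if
    ``r < dt * c_m`` the microtubule catastrophes and renucleates at length 0,
    otherwise it grows by ``dt * v_g``, capped at the current boundary.  The
    boundary then moves by ``dt * boundary_velocity(n)`` using the contact
    count of the updated tips against the pre-move boundary, floored at 0;
    finally tips are clipped to the new boundary.

    This is the reference NumPy implementation; :func:`simulate` runs the
    identical update (and consumes the identical random stream) in a compiled
    kernel.
    """
    L = ensemble.lengths
    c_m = np.where(boundary - L <= params.w_c, params.c_B, params.c_I)
    r = rng.random(params.N_m)
    catastrophe = r < params.dt * c_m
    L_new = np.where(catastrophe, 0.0,
                     np.minimum(L + params.dt * params.v_g, boundary))
    n = int(np.count_nonzero(boundary - L_new <= params.w_c))
    new_boundary = max(0.0, boundary + params.dt * boundary_velocity(n, params))
    L_new = np.minimum(L_new, new_boundary)
    return MicrotubuleEnsemble(L_new), new_boundary


@njit(cache=True)
def _simulate_kernel(L, boundary, n_steps, record_every,
                     dt, v_g, c_I, c_B, v_B, alpha, w_c,
                     rng, rec_LB, rec_nB, rec_L, save_snapshots):
    """Compiled inner loop; same update and random stream as :func:`step`.

    Draw order per step is microtubule 0..N_m-1, one uniform each; the
    boundary update consumes no randomness.  Records start at index 1
    (index 0 is the initial state, filled by the caller).
    """
    N_m = L.shape[0]
    k = 1
    for s in range(1, n_steps + 1):
        for j in range(N_m):
            c = c_B if boundary - L[j] <= w_c else c_I
            r = rng.random()
            if r < dt * c:
                L[j] = 0.0
            else:
                Lj = L[j] + dt * v_g
                if Lj > boundary:
                    Lj = boundary
                L[j] = Lj
        n = 0
        for j in range(N_m):
            if boundary - L[j] <= w_c:
                n += 1
        if n == 0:
            v = -v_B
        else:
            v = v_g * np.exp(-alpha / n) - v_B
        boundary = boundary + dt * v
        if boundary < 0.0:
            boundary = 0.0
        n_B = 0
        for j in range(N_m):
            if L[j] > boundary:
                L[j] = boundary
            if boundary - L[j] <= w_c:
                n_B += 1
        if s % record_every == 0:
            rec_LB[k] = boundary
            rec_nB[k] = n_B
            if save_snapshots:
                for j in range(N_m):
                    rec_L[k, j] = L[j]
            k += 1
    return boundary


@njit(cache=True)
def _waiting_times_kernel(n_steps, dt, v_g, c_I, c_B, w_c, boundary, rng, out):
    L = 0.0
    t_birth = 0
    k = 0
    for s in range(1, n_steps + 1):
        c = c_B if boundary - L <= w_c else c_I
        if rng.random() < dt * c:
            out[k] = (s - t_birth) * dt
            k += 1
            L = 0.0
            t_birth = s
            if k == out.shape[0]:
                break
        else:
            Lj = L + dt * v_g
            L = Lj if Lj < boundary else boundary
    return k


def catastrophe_waiting_times(params: SimulationParams, boundary: float,
                              max_events: int = 1000,
                              max_duration: float = 1e6) -> np.ndarray:
    """Waiting times between renucleation and catastrophe of a single
    microtubule growing against a fixed boundary.

    The boundary placement selects the hazard zone: a boundary far beyond
    the reach of a typical excursion keeps the tip in the interior (rate
    ``c_I``); a boundary at or below ``w_c`` keeps it in the cortex zone
    (rate ``c_B``).  Uses the same per-step Bernoulli trial as the full
    simulation, so the sampled times follow the discretised (geometric)
    version of the exponential law.  Censored final excursions are dropped.
    """
    if boundary <= 0:
        raise ValueError("boundary must be > 0")
    n_steps = int(max_duration / params.dt)
    out = np.empty(max_events)
    rng = np.random.default_rng(params.seed)
    k = _waiting_times_kernel(n_steps, params.dt, params.v_g, params.c_I,
                              params.c_B, params.w_c, boundary, rng, out)
    return out[:k]


def simulate(params: SimulationParams, duration: float,
             record_interval: float = 1.0, *,
             record_snapshots: bool = False,
             initial_lengths: np.ndarray | None = None,
             initial_boundary: float | None = None,
             rng: np.random.Generator | None = None) -> CellTrajectory:
    """Run the model for ``duration`` minutes and record the trajectory.

    The initial state has the boundary at ``L0`` and all microtubule lengths
    at 0 (unless an explicit state is supplied to continue a previous run).
    Times, boundary position and contact count are recorded every
    ``record_interval`` minutes, starting with the initial state at t=0.
    A fixed ``params.seed`` gives a bit-identical trajectory.

    Parameters
    ----------
    duration : float
        Simulated time, min.  Durations that are not a multiple of ``dt``
        are truncated down (with a logged warning).
    record_interval : float
        Recording cadence, min; must be >= ``dt``.
    record_snapshots : bool
        Also record the full set of tip lengths at each recorded time
        (needed for density profiles).
    initial_lengths, initial_boundary, rng
        Continue from an explicit state and random stream instead of the
        default cold start; used by perturbation protocols.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if record_interval < params.dt:
        raise ValueError("record_interval must be >= dt")

    n_steps = int(math.floor(duration / params.dt + 1e-9))
    if abs(n_steps * params.dt - duration) > 1e-9 * max(1.0, duration):
        logger.warning("duration %.6g min is not a multiple of dt=%.6g; "
                       "truncating to %d steps (%.6g min)",
                       duration, params.dt, n_steps, n_steps * params.dt)
    record_every = max(1, int(round(record_interval / params.dt)))
    n_records = n_steps // record_every + 1

    if initial_lengths is None:
        L = np.zeros(params.N_m)
    else:
        L = np.array(initial_lengths, dtype=float)
        if L.shape != (params.N_m,):
            raise ValueError("initial_lengths must have shape (N_m,)")
    boundary = params.L0 if initial_boundary is None else float(initial_boundary)
    if np.any(L > boundary) or np.any(L < 0):
        raise ValueError("initial lengths must lie in [0, boundary]")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    rec_LB = np.empty(n_records)
    rec_nB = np.empty(n_records, dtype=np.int64)
    rec_L = (np.empty((n_records, params.N_m))
             if record_snapshots else np.empty((1, max(params.N_m, 1))))

    rec_LB[0] = boundary
    rec_nB[0] = int(np.count_nonzero(boundary - L <= params.w_c))
    if record_snapshots:
        rec_L[0] = L

    boundary = _simulate_kernel(
        L, boundary, n_steps, record_every,
        params.dt, params.v_g, params.c_I, params.c_B, params.v_B,
        params.alpha, params.w_c, rng, rec_LB, rec_nB, rec_L,
        record_snapshots)

    times = np.arange(n_records) * (record_every * params.dt)
    return CellTrajectory(
        times=times, L_B_series=rec_LB, n_B_series=rec_nB, params=params,
        snapshots=rec_L if record_snapshots else None,
        final_lengths=L, final_boundary=boundary)
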