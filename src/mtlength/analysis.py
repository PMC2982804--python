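"""Steady-state statistics and in-silico experiments on simulated cells.

Summaries of post-burn-in trajectories, homeostasis maps over the two free
parameters (pool size ``N_m`` and cooperation ``alpha``), mid-run parameter
perturbations (e.g. halving the growth velocity to mimic a microtubule
drug), microtubule density profiles along the cell axis, and the regression
of steady-state cell length on growth velocity.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CellTrajectory, SimulationParams, simulate

logger = logging.getLogger("mtlength")

__all__ = [
    "SteadyStateSummary",
    "HomeostasisMap",
    "DensityProfile",
    "LengthVsVgFit",
    "summarize",
    "homeostasis_map",
    "perturb_parameter",
    "density_profile",
    "length_vs_vg_fit",
    "estimate_catastrophe_rate",
    "estimate_growth_velocity",
]

#: Default burn-in discarded before steady-state statistics, min.
DEFAULT_BURN_IN = 500.0


def _subseed(master: int, *coords: int) -> np.random.SeedSequence:
    """Deterministic per-task seed from a master seed and grid coordinates."""
    return np.random.SeedSequence((int(master),) + tuple(int(c) for c in coords))


def _seed_int(master: int, *coords: int) -> int:
    return int(_subseed(master, *coords).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Steady-state summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyStateSummary:
    """Post-burn-in statistics of a trajectory (lengths are full cell
    lengths, i.e. twice the half-cell boundary position)."""

    burn_in: float
    mean_length: float
    sd_length: float
    cv_length: float
    mean_n_B: float
    n_samples: int


def summarize(traj: CellTrajectory, burn_in: float = DEFAULT_BURN_IN,
              check_trend: bool = False) -> SteadyStateSummary:
    """Compute steady-state statistics over samples with time >= burn_in.

    With ``check_trend=True`` an ordinary least-squares line is fitted to the
    post-burn-in length series and a warning is logged if its slope is
    significantly non-zero (the window may not have equilibrated; note the
    series is autocorrelated, so this is a coarse screen).
    """
    mask = traj.times >= burn_in
    if not np.any(mask):
        raise ValueError(f"no samples at or after burn_in={burn_in} min "
                         f"(trajectory ends at {traj.times[-1]} min)")
    length = traj.cell_length_series[mask]
    n_B = traj.n_B_series[mask]
    mean = float(np.mean(length))
    sd = float(np.std(length, ddof=1)) if length.size > 1 else 0.0
    if check_trend and length.size > 2:
        res = stats.linregress(traj.times[mask], length)
        half_width = 1.96 * res.stderr
        if abs(res.slope) > half_width:
            logger.warning(
                "post-burn-in length series has a non-zero linear trend "
                "(%.3g ± %.3g µm/min): steady state may not be reached",
                res.slope, half_width)
    return SteadyStateSummary(
        burn_in=float(burn_in), mean_length=mean, sd_length=sd,
        cv_length=sd / mean if mean > 0 else float("nan"),
        mean_n_B=float(np.mean(n_B)), n_samples=int(length.size))


# ---------------------------------------------------------------------------
# Homeostasis map over (N_m, alpha)
# ---------------------------------------------------------------------------

@dataclass
class HomeostasisMap:
    """Grid of steady-state length variability over the two free parameters.

    ``sd_length[i, j]`` is the post-burn-in standard deviation of cell length
    for ``N_m_values[i]`` and ``alpha_values[j]``; low values mark the
    homeostatic regime.
    """

    N_m_values: np.ndarray
    alpha_values: np.ndarray
    sd_length: np.ndarray
    mean_length: np.ndarray
    mean_n_B: np.ndarray
    duration: float
    burn_in: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sd_length,
                            index=pd.Index(self.N_m_values, name="N_m"),
                            columns=pd.Index(self.alpha_values, name="alpha"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def homeostasis_map(N_m_values, alpha_values, params: SimulationParams,
                    duration: float = 10_000.0,
                    burn_in: float = DEFAULT_BURN_IN,
                    record_interval: float = 1.0) -> HomeostasisMap:
    """Sweep (N_m, alpha), one independent seeded simulation per grid cell.

    Seeds are derived deterministically from ``params.seed`` and the grid
    coordinates, so the map is reproducible and cells are independent.
    """
    N_m_values = np.atleast_1d(np.asarray(N_m_values, dtype=int))
    alpha_values = np.atleast_1d(np.asarray(alpha_values, dtype=float))
    if N_m_values.size == 0 or alpha_values.size == 0:
        raise ValueError("grid axes must be non-empty")
    if duration < 10 * burn_in:
        raise ValueError(f"duration {duration} must be >= 10x burn_in {burn_in}")

    shape = (N_m_values.size, alpha_values.size)
    sd = np.empty(shape)
    mean = np.empty(shape)
    n_B = np.empty(shape)
    for i, N_m in enumerate(N_m_values):
        for j, alpha in enumerate(alpha_values):
            try:
                p = params.replace(N_m=int(N_m), alpha=float(alpha),
                                   seed=_seed_int(params.seed, i, j))
                traj = simulate(p, duration, record_interval)
            except ValueError as err:
                raise ValueError(
                    f"grid cell (N_m={N_m}, alpha={alpha}): {err}") from err
            s = summarize(traj, burn_in)
            sd[i, j] = s.sd_length
            mean[i, j] = s.mean_length
            n_B[i, j] = s.mean_n_B
    return HomeostasisMap(N_m_values, alpha_values, sd, mean, n_B,
                          duration=float(duration), burn_in=float(burn_in))


# ---------------------------------------------------------------------------
# Parameter perturbation (drug-like protocols)
# ---------------------------------------------------------------------------

def perturb_parameter(params: SimulationParams, t_switch: float,
                      factors: dict[str, float], duration: float,
                      record_interval: float = 1.0) -> CellTrajectory:
    """Run with ``params`` until ``t_switch``, then scale fields and continue.

    The microtubule lengths, boundary position and random stream carry over
    the switch, so an empty ``factors`` map reproduces the unperturbed run
    exactly.  Scaled parameters are re-validated (a scaling that breaks an
    invariant is rejected).  The returned trajectory records ``t_switch``.
    """
    if not 0 < t_switch < duration:
        raise ValueError("need 0 < t_switch < duration")
    valid = {f.name for f in dataclasses.fields(SimulationParams)}
    for name, factor in factors.items():
        if name not in valid:
            raise ValueError(f"unknown parameter field: {name!r}")
        if factor <= 0:
            raise ValueError(f"factor for {name!r} must be > 0 (got {factor})")
    scaled = params.replace(**{name: getattr(params, name) * factor
                               for name, factor in factors.items()})

    rng = np.random.default_rng(params.seed)
    first = simulate(params, t_switch, record_interval, rng=rng)
    second = simulate(scaled, duration - t_switch, record_interval,
                      initial_lengths=first.final_lengths,
                      initial_boundary=first.final_boundary, rng=rng)
    return CellTrajectory(
        times=np.concatenate([first.times, t_switch + second.times[1:]]),
        L_B_series=np.concatenate([first.L_B_series, second.L_B_series[1:]]),
        n_B_series=np.concatenate([first.n_B_series, second.n_B_series[1:]]),
        params=params, t_switch=float(t_switch),
        final_lengths=second.final_lengths,
        final_boundary=second.final_boundary)


# ---------------------------------------------------------------------------
# Microtubule density along the cell axis
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Time-averaged microtubule occupancy along the cell axis.

    ``occupancy[k]`` is the expected number of microtubules overlapping the
    position ``positions[k]`` (percent of the instantaneous half-length from
    the centre).  All microtubules overlap the centre, so occupancy at 0% is
    exactly ``N_m``; occupancy at 100% is the boundary contact count up to
    the cortex-zone bin.
    """

    positions: np.ndarray   # % of half-length, 0..100
    occupancy: np.ndarray
    n_snapshots: int

    def linear_fit(self) -> tuple[float, float, float]:
        """OLS straight-line fit; returns (slope, intercept, R^2)."""
        res = stats.linregress(self.positions, self.occupancy)
        return float(res.slope), float(res.intercept), float(res.rvalue ** 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_pct": self.positions,
                             "occupancy": self.occupancy})


def density_profile(params: SimulationParams, duration: float = 3_000.0,
                    n_snapshots: int = 500,
                    burn_in: float = DEFAULT_BURN_IN,
                    n_bins: int = 51) -> DensityProfile:
    """Time-averaged occupancy profile from post-burn-in ensemble snapshots.

    ``occupancy(x)`` counts microtubules with length >= x% of the
    instantaneous half-length, averaged over snapshots taken after burn-in.
    """
    if duration <= burn_in:
        raise ValueError("duration must exceed burn_in")
    record_interval = max(params.dt, (duration - burn_in) / n_snapshots)
    traj = simulate(params, duration, record_interval, record_snapshots=True)
    mask = traj.times >= burn_in
    if int(np.count_nonzero(mask)) < n_snapshots:
        raise ValueError("insufficient post-burn-in snapshots")
    snaps = traj.snapshots[mask]            # (T, N_m)
    LB = traj.L_B_series[mask][:, None]
    positions = np.linspace(0.0, 100.0, n_bins)
    frac = snaps / LB                        # tip position as fraction of L_B
    occupancy = np.array([np.mean(np.sum(frac >= x / 100.0, axis=1))
                          for x in positions])
    return DensityProfile(positions=positions, occupancy=occupancy,
                          n_snapshots=int(np.count_nonzero(mask)))


# ---------------------------------------------------------------------------
# Steady-state length vs growth velocity
# ---------------------------------------------------------------------------

@dataclass
class LengthVsVgFit:
    """OLS fit of mean steady-state cell length against growth velocity.

    ``mean_lengths`` are full cell lengths (twice the half-cell boundary);
    ``mean_half_lengths`` are also kept so the regression can be read on
    either convention (the half-length slope is exactly half the full one).
    """

    vg_values: np.ndarray
    mean_lengths: np.ndarray
    sd_lengths: np.ndarray
    mean_half_lengths: np.ndarray
    slope: float            # min (µm per µm/min)
    intercept: float        # µm
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"v_g_um_per_min": self.vg_values,
                             "mean_length_um": self.mean_lengths,
                             "sd_length_um": self.sd_lengths,
                             "mean_half_length_um": self.mean_half_lengths})


def estimate_catastrophe_rate(waiting_times: np.ndarray
                              ) -> tuple[float, float, float]:
    """Estimate a catastrophe rate (1/min) from event waiting times.

    Maximum-likelihood rate for exponential data is the reciprocal mean;
    the 95% confidence interval follows from 2*n*rate_true/rate_hat being
    chi-squared with 2n degrees of freedom.  Returns (rate, lo, hi).
    """
    w = np.asarray(waiting_times, dtype=float)
    if w.size < 2 or np.any(w <= 0):
        raise ValueError("need >= 2 positive waiting times")
    n = w.size
    rate = 1.0 / w.mean()
    lo = rate * stats.chi2.ppf(0.025, 2 * n) / (2 * n)
    hi = rate * stats.chi2.ppf(0.975, 2 * n) / (2 * n)
    return float(rate), float(lo), float(hi)


def estimate_growth_velocity(traj: CellTrajectory) -> float:
    """Recover v_g (µm/min) from tip displacements between snapshots.

    Uses per-microtubule length increments over one recording interval,
    keeping only uninterrupted growth excursions (positive increments away
    from the boundary cap); the estimate is the median increment divided by
    the interval, robust to the catastrophe resets mixed into the series.
    """
    if traj.snapshots is None:
        raise ValueError("trajectory has no ensemble snapshots "
                         "(simulate with record_snapshots=True)")
    dt_rec = float(traj.times[1] - traj.times[0])
    inc = np.diff(traj.snapshots, axis=0)
    capped = traj.snapshots[1:] >= traj.L_B_series[1:, None]
    growth = inc[(inc > 0) & ~capped]
    if growth.size == 0:
        raise ValueError("no free-growth increments in the snapshots")
    return float(np.median(growth) / dt_rec)


def length_vs_vg_fit(vg_values, params: SimulationParams,
                     duration: float = 10_000.0,
                     burn_in: float = DEFAULT_BURN_IN,
                     record_interval: float = 1.0) -> LengthVsVgFit:
    """Mean steady-state cell length per growth velocity, with an OLS line.

    One independently seeded simulation per ``v_g``; velocities at or below
    the retraction rate are rejected (no equilibrium exists there).
    """
    vg_values = np.sort(np.unique(np.asarray(vg_values, dtype=float)))
    if vg_values.size < 3:
        raise ValueError("need >= 3 distinct v_g values for a fit")
    if np.any(vg_values <= params.v_B):
        bad = vg_values[vg_values <= params.v_B]
        raise ValueError(f"v_g values {bad.tolist()} <= v_B={params.v_B}: "
                         "no steady state exists (boundary always retracts)")

    means, sds, halves = [], [], []
    for k, v_g in enumerate(vg_values):
        p = params.replace(v_g=float(v_g), seed=_seed_int(params.seed, k))
        s = summarize(simulate(p, duration, record_interval), burn_in)
        means.append(s.mean_length)
        sds.append(s.sd_length)
        halves.append(s.mean_length / 2.0)
    means = np.array(means)
    res = stats.linregress(vg_values, means)
    return LengthVsVgFit(
        vg_values=vg_values, mean_lengths=means, sd_lengths=np.array(sds),
        mean_half_lengths=np.array(halves),
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2))
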