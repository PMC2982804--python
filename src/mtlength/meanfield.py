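"""Closed-form and renewal-theory approximations of the stochastic model.

These serve as independent oracles for the simulator: the equilibrium
contact count follows from flux balance of the boundary equation, and the
steady-state half-length from a renewal approximation of the
nucleate-grow-catastrophe cycle of a single microtubule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .model import SimulationParams

__all__ = [
    "MeanFieldPrediction",
    "equilibrium_contact_count",
    "predicted_steady_length",
]


@dataclass(frozen=True)
class MeanFieldPrediction:
    """Equilibrium contact count and predicted steady-state half-length."""

    n_star: float          # boundary-contact count at flux balance
    L_half_pred: float     # steady-state half-cell length, µm


def equilibrium_contact_count(alpha: float, v_g: float, v_B: float) -> float:
    """Contact count ``n*`` at which elongation balances retraction.

    Setting the boundary velocity ``v_g * exp(-alpha/n) - v_B`` to zero gives
    ``n* = alpha / ln(v_g / v_B)`` — independent of the microtubule pool size
    and of cell length.  With the default rates (v_g=15, v_B=0.4, alpha=8)
    this is 2.21, the "about two pioneer microtubules" that maintain length.

    Raises
    ------
    ValueError
        If ``v_g <= v_B`` (no equilibrium: the boundary cannot outrun
        retraction at any contact count).
    """
    if v_B <= 0:
        raise ValueError("v_B must be > 0 for a flux balance to exist")
    if v_g <= v_B:
        raise ValueError(
            f"no equilibrium: v_g={v_g} <= v_B={v_B} (boundary always retracts)")
    if alpha == 0:
        warnings.warn("alpha=0: no cooperation requirement, boundary advances "
                      "for any contact — runaway growth regime", stacklevel=2)
        return 0.0
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return alpha / math.log(v_g / v_B)


def _steady_contact_count(L_half: float, params: SimulationParams) -> float:
    """Expected boundary-contact count at a fixed half-length ``L_half``.

    Renewal approximation of one microtubule's cycle: it grows from the
    centre, survives the interior (length ``L_half - w_c``) with probability
    ``p = exp(-c_I * (L_half - w_c) / v_g)``, then resides in the cortex zone
    for a mean time ``1/c_B`` before catastrophe.  The mean cycle time is
    ``E[T] = (1 - p)/c_I + p/c_B`` (mean of the interior waiting time
    truncated at the traversal time, plus the cortical residence when it gets
    there).  The long-run fraction of time spent at the boundary is
    ``p / (c_B * E[T])``, so the expected contact count of the pool is
    ``N_m * p / (c_B * E[T])``.  Boundary motion during a microtubule's
    lifetime and tip capping are ignored.
    """
    p = math.exp(-params.c_I * (L_half - params.w_c) / params.v_g)
    tau_B = 1.0 / params.c_B
    if params.c_I == 0:
        # every microtubule reaches the cortex; cycle = traversal + residence
        travel = (L_half - params.w_c) / params.v_g
        return params.N_m * tau_B / (travel + tau_B)
    mean_cycle = (1.0 - p) / params.c_I + p * tau_B
    return params.N_m * p * tau_B / mean_cycle


def predicted_steady_length(params: SimulationParams) -> MeanFieldPrediction:
    """Predict the steady-state half-length from the renewal approximation.

    Solves ``N_m * p * tau_B / E[T] = n*`` for the half-length, where ``n*``
    is :func:`equilibrium_contact_count`.  The left side decreases from
    ``N_m`` (at ``L = w_c``) toward 0, so a root exists iff ``N_m > n*``;
    otherwise the pool cannot sustain the equilibrium contact count and the
    model runs away or collapses.

    The approximation ignores boundary motion (slow compared with ``v_g`` at
    steady state) and tip capping; simulated mean half-lengths agree with it
    to within roughly 25%.
    """
    n_star = equilibrium_contact_count(params.alpha, params.v_g, params.v_B)
    if n_star <= 0:
        raise ValueError("alpha=0 has no finite steady length (runaway)")
    if params.N_m <= n_star:
        raise ValueError(
            f"no steady state: pool N_m={params.N_m} cannot sustain the "
            f"equilibrium contact count n*={n_star:.3g}")

    f = lambda L: _steady_contact_count(L, params) - n_star
    lo, hi = params.w_c * (1 + 1e-12), 1e3
    if f(hi) > 0:
        raise ValueError(
            f"no root below {hi} µm: interior catastrophe too weak to bound "
            f"cell length in this parameter regime (c_I={params.c_I})")
    L_half = brentq(f, lo, hi, xtol=1e-9, rtol=8.9e-16)
    return MeanFieldPrediction(n_star=n_star, L_half_pred=float(L_half))
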