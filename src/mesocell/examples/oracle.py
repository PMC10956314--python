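"""Well-mixed kinetics oracles.

``ode_oracle`` integrates an arbitrary mass-action network by forward
Euler under the well-mixed assumption; it is the reference against which
all stochastic kinetics results are compared.  The calmodulin helpers
build the cooperative two-lobe binding network from a set of lobe rate
constants and solve its equilibrium algebraically (detailed balance),
independently of the time integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


@dataclass(frozen=True)
class MassActionReaction:
    """One elementary reaction: species names and a rate constant in
    concentration units (s^-1 for one reactant, M^-1 s^-1 for two)."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float


def ode_oracle(reactions: list[MassActionReaction],
               initial: dict[str, float], dt: float, t_end: float,
               record_every: int = 1,
               ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Forward-Euler integration of a well-mixed mass-action system.

    ``initial`` maps species to concentrations (mol/L).  Returns the
    recorded times and one concentration trajectory per species.  Raises
    on non-finite state (step size too large for the network stiffness).
    """
    names = list(initial)
    idx = {n: i for i, n in enumerate(names)}
    c = np.array([initial[n] for n in names], dtype=float)
    n_steps = int(round(t_end / dt))
    times = [0.0]
    traj = [c.copy()]
    for step in range(1, n_steps + 1):
        dc = np.zeros_like(c)
        for r in reactions:
            rate = r.k
            for sp in r.reactants:
                rate *= c[idx[sp]]
            for sp in r.reactants:
                dc[idx[sp]] -= rate
            for sp in r.products:
                dc[idx[sp]] += rate
        c = c + dc * dt
        if not np.all(np.isfinite(c)):
            raise FloatingPointError(
                f"non-finite concentration at step {step}; reduce dt")
        if step % record_every == 0:
            times.append(step * dt)
            traj.append(c.copy())
    arr = np.array(traj)
    return np.array(times), {n: arr[:, i] for i, n in enumerate(names)}


# ---------------------------------------------------------------------
# calmodulin cooperative binding network
# ---------------------------------------------------------------------

#: lobe state names: number of bound ions per lobe
_LOBE_STATES = (0, 1, 2)


def cam_state_name(n_bound_n: int, n_bound_c: int) -> str:
    return f"CaM_N{n_bound_n}C{n_bound_c}"


def calmodulin_network(n_lobe, c_lobe) -> list[MassActionReaction]:
    """Mass-action network over the 9 lobe-state combinations.

    ``n_lobe``/``c_lobe`` carry per-site T/R constants (attributes
    ``k_on_T``, ``k_off_T``, ``k_on_R``, ``k_off_R``); the statistical
    factors (2x first association, 2x dissociation from the full lobe)
    are applied here.
    """
    out: list[MassActionReaction] = []

    def lobe_steps(rates):
        return [(0, 1, 2.0 * rates.k_on_T, rates.k_off_T),
                (1, 2, rates.k_on_R, 2.0 * rates.k_off_R)]

    for lo, hi, k_on, k_off in lobe_steps(n_lobe):
        for j in _LOBE_STATES:
            out.append(MassActionReaction(
                ("Ca", cam_state_name(lo, j)),
                (cam_state_name(hi, j),), k_on))
            out.append(MassActionReaction(
                (cam_state_name(hi, j),),
                ("Ca", cam_state_name(lo, j)), k_off))
    for lo, hi, k_on, k_off in lobe_steps(c_lobe):
        for i in _LOBE_STATES:
            out.append(MassActionReaction(
                ("Ca", cam_state_name(i, lo)),
                (cam_state_name(i, hi),), k_on))
            out.append(MassActionReaction(
                (cam_state_name(i, hi),),
                ("Ca", cam_state_name(i, lo)), k_off))
    return out


def _lobe_weights(c: float, rates) -> np.ndarray:
    """Unnormalised equilibrium weights of lobe occupancies 0, 1, 2 at
    free-Ca concentration ``c`` (detailed balance)."""
    k_t = rates.k_off_T / rates.k_on_T
    k_r = rates.k_off_R / rates.k_on_R
    return np.array([1.0, 2.0 * c / k_t, c * c / (k_t * k_r)])


def cam_equilibrium(cam_total: float, ca_total: float, n_lobe, c_lobe,
                    ) -> tuple[float, np.ndarray]:
    """Algebraic equilibrium of the cooperative network.

    Solves the free-Ca conservation equation and returns
    ``(free_ca, fractions)`` where ``fractions[n]`` is the equilibrium
    fraction of calmodulin with ``n`` of its 4 sites occupied.
    """
    if ca_total <= 0 or cam_total <= 0:
        frac = np.zeros(5)
        frac[0] = 1.0
        return max(ca_total, 0.0), frac

    def bound_per_cam(c: float) -> float:
        tot = 0.0
        for rates in (n_lobe, c_lobe):
            w = _lobe_weights(c, rates)
            tot += (w[1] + 2.0 * w[2]) / w.sum()
        return tot

    def residual(c: float) -> float:
        return c + cam_total * bound_per_cam(c) - ca_total

    free = brentq(residual, 0.0, ca_total, xtol=1e-18, rtol=1e-14)
    w_n = _lobe_weights(free, n_lobe)
    w_c = _lobe_weights(free, c_lobe)
    p_n = w_n / w_n.sum()
    p_c = w_c / w_c.sum()
    frac = np.zeros(5)
    for i in _LOBE_STATES:
        for j in _LOBE_STATES:
            frac[i + j] += p_n[i] * p_c[j]
    return free, frac


def cam_ode_initial(cam_total: float, ca_total: float) -> dict[str, float]:
    """Initial concentrations for the calmodulin network: all calmodulin
    unloaded, all calcium free."""
    init = {"Ca": ca_total}
    for i in _LOBE_STATES:
        for j in _LOBE_STATES:
            init[cam_state_name(i, j)] = 0.0
    init[cam_state_name(0, 0)] = cam_total
    return init


def cam_fractions_from_traj(traj: dict[str, np.ndarray]) -> np.ndarray:
    """Per-time fractions of calmodulin with 0..4 sites bound, from an
    ODE trajectory."""
    totals = None
    frac = None
    for i in _LOBE_STATES:
        for j in _LOBE_STATES:
            c = traj[cam_state_name(i, j)]
            if frac is None:
                frac = np.zeros((5, len(c)))
                totals = np.zeros(len(c))
            frac[i + j] += c
            totals += c
    return (frac / totals).T  # shape (t, 5)
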