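"""Self-contained kinetics/diffusion benchmark drivers.

These drive the package's own primitives (binding-radius calibration,
greedy pair matching, Gaussian particle steps) in minimal periodic-box or
free-space geometries so that simulated kinetics can be compared against
closed-form mass-action solutions without the full lattice machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import N_AVOGADRO
from .reactions import binding_radius, match_pairs, smoluchowski_radius

__all__ = ["pair_reaction_trajectory", "second_order_equal_conc",
           "decay_model", "msd_per_step", "PairReactionResult"]


@dataclass
class PairReactionResult:
    times: np.ndarray
    n_a: np.ndarray
    n_c: np.ndarray
    box: float
    sigma: float

    @property
    def volume_litres(self) -> float:
        return self.box ** 3 * 1e-15

    def conc_a(self) -> np.ndarray:
        return self.n_a / (N_AVOGADRO * self.volume_litres)

    def conc_c(self) -> np.ndarray:
        return self.n_c / (N_AVOGADRO * self.volume_litres)


def pair_reaction_trajectory(n_a: int, n_b: int, box: float, k: float,
                             D_a: float, D_b: float, dt: float,
                             n_steps: int, seed: int,
                             radius_mode: str = "ab",
                             log_every: int = 1) -> PairReactionResult:
    """Irreversible A + B -> C in a periodic cube of edge ``box`` um.

    ``radius_mode`` selects the timestep-calibrated binding radius
    (``"ab"``) or the uncorrected Smoluchowski radius (``"naive"``, the
    control that fails at coarse timesteps).
    """
    d_sum = D_a + D_b
    if radius_mode == "ab":
        sigma = binding_radius(k, d_sum, dt).sigma_b
    elif radius_mode == "naive":
        sigma = smoluchowski_radius(k, d_sum)
    else:
        raise ValueError(f"unknown radius_mode '{radius_mode}'")
    rng = np.random.default_rng(seed)
    pos_a = rng.random((n_a, 3)) * box
    pos_b = rng.random((n_b, 3)) * box
    s_a = np.sqrt(2.0 * D_a * dt)
    s_b = np.sqrt(2.0 * D_b * dt)
    times = [0.0]
    na = [n_a]
    nc = [0]
    made = 0
    for step in range(1, n_steps + 1):
        pos_a = np.mod(pos_a + rng.normal(0.0, s_a, pos_a.shape), box)
        pos_b = np.mod(pos_b + rng.normal(0.0, s_b, pos_b.shape), box)
        pairs = match_pairs(pos_a, pos_b, sigma, box=box)
        if pairs:
            ia = np.array([p[0] for p in pairs])
            ib = np.array([p[1] for p in pairs])
            keep_a = np.ones(len(pos_a), bool)
            keep_a[ia] = False
            keep_b = np.ones(len(pos_b), bool)
            keep_b[ib] = False
            pos_a = pos_a[keep_a]
            pos_b = pos_b[keep_b]
            made += len(pairs)
        if step % log_every == 0:
            times.append(step * dt)
            na.append(len(pos_a))
            nc.append(made)
    return PairReactionResult(np.array(times), np.array(na),
                              np.array(nc), box, sigma)


def second_order_equal_conc(c0: float, k: float,
                            t: np.ndarray) -> np.ndarray:
    """Closed-form A(t) for A + B -> C with equal initial concentrations:
    ``1/A = 1/A0 + k t``."""
    return c0 / (1.0 + c0 * k * t)


def decay_model(n0: int, k: float, dt: float, n_steps: int,
                log_every: int = 1):
    """Minimal engine model for first-order particle decay A -> B."""
    from .model import (Box, CompartmentSpec, EnvironmentSpec,
                        InitialCondition, ModelSpec, OutputConfig,
                        ReactionRule, SpeciesDef, SpeciesPattern)
    env = EnvironmentSpec(2, 2, 2, 0.5, dt, n_steps)
    return ModelSpec(
        environment=env,
        compartments=[CompartmentSpec("box",
                                      boxes=[Box(0, 2, 0, 2, 0, 2)])],
        species=[SpeciesDef("A", "particle", 0.0,
                            allowed_compartments=["box"]),
                 SpeciesDef("B", "particle", 0.0,
                            allowed_compartments=["box"])],
        reactions=[ReactionRule("decay", [SpeciesPattern("A")],
                                [SpeciesPattern("B")], k=k)],
        initial_conditions=[InitialCondition("A", "count", n0)],
        output=OutputConfig(log_interval=log_every))


def msd_per_step(D: float, dt: float, n_samples: int, seed: int) -> float:
    """Mean squared 3-D displacement of one particle-diffusion step taken
    with the package's Brownian stepper, far from any boundary (expected
    ``6*D*dt``)."""
    from .diffusion import step_many
    from .geometry import Lattice
    s = np.sqrt(2.0 * D * dt)
    lat = Lattice((3, 3, 3), max(1000.0 * s, 1e-6))
    rng = np.random.default_rng(seed)
    access = np.ones(lat.dims, dtype=bool)
    start = np.tile(lat.extent / 2.0, (n_samples, 1))
    new = step_many(start.copy(), D, dt, rng, lat, access)
    disp = new - start
    return float(np.mean(np.sum(disp * disp, axis=1)))
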