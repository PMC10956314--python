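"""One-timestep movement operators.

Bulk species diffuse deterministically on the voxel grid by an explicit
forward-Euler discretisation of Fick's second law with a 6-point stencil;
flux across an interface into a voxel the species may not occupy is zero,
so restricted compartments act as reflecting boundaries and total amount is
conserved exactly.

Point particles take independent Gaussian steps of per-axis standard
deviation ``sqrt(2*D*dt)`` (Brownian motion); proposed positions are passed
through specular reflection at the domain boundary and at the boundary of
any voxel the species may not occupy.  Membrane-bound particles keep one
frozen (outward-normal) coordinate and diffuse in-plane only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Lattice, voxels_of
from .model import STABILITY_LIMIT, SpeciesDef

#: retry cap for repeated reflection of one proposed step
REFLECT_CAP = 10


@dataclass
class ConcentrationField:
    """Real-valued molecule amount of one bulk species per voxel."""

    species: str
    amounts: np.ndarray  # float array, shape = lattice dims

    def total(self) -> float:
        return float(self.amounts.sum())


@dataclass
class Particle:
    """One tracked point molecule (scalar API; the engine stores particles
    in per-species arrays and uses the vectorized kernels below)."""

    particle_id: int
    species: str
    pos: np.ndarray
    site_occupancy: dict[str, bool] = field(default_factory=dict)
    state_flags: dict[str, bool] = field(default_factory=dict)
    immobilized: bool = False
    frozen_axis: int = -1  # -1 = free 3-D diffusion


def bulk_diffusion_step(field_: ConcentrationField, D: float, dt: float,
                        lattice: Lattice,
                        species: SpeciesDef) -> ConcentrationField:
    """Advance one bulk field by one forward-Euler diffusion step.

    ``N_i' = N_i + (D*dt/h^2) * sum_j (N_j - N_i)`` over face neighbors j
    accessible to the species; pairs with an inaccessible end exchange no
    flux.  Raises on a stability violation (``D*dt/h^2 > 1/6``).
    """
    coef = D * dt / lattice.h ** 2
    if coef > STABILITY_LIMIT + 1e-12:
        raise ValueError(
            f"diffusion unstable for species '{species.name}': "
            f"D*dt/h^2 = {coef:.4g} > 1/6")
    if coef == 0.0:
        return ConcentrationField(field_.species, field_.amounts.copy())
    acc = lattice.accessibility_mask(species)
    N = field_.amounts
    out = N.copy()
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        lo_t, hi_t = tuple(lo), tuple(hi)
        open_face = acc[lo_t] & acc[hi_t]
        flux = np.where(open_face, coef * (N[hi_t] - N[lo_t]), 0.0)
        out[lo_t] += flux
        out[hi_t] -= flux
    return ConcentrationField(field_.species, out)


def displacement_sigma(D: float, dt: float) -> float:
    """Per-axis standard deviation of one Brownian step (um)."""
    return float(np.sqrt(2.0 * D * dt))


def _fold_bounds(pos: np.ndarray, extent: np.ndarray) -> np.ndarray:
    """Specular fold of positions into [0, extent) per axis (handles steps
    of any length via the triangle-wave identity)."""
    oob = (pos < 0.0) | (pos >= extent)
    rows = np.flatnonzero(oob.any(axis=1)) if pos.ndim == 2 else None
    if rows is None:
        if not oob.any():
            return pos
        sub = pos
    else:
        if rows.size == 0:
            return pos
        sub = pos[rows]
    y = np.mod(sub, 2.0 * extent)
    np.copyto(y, 2.0 * extent - y, where=y > extent)
    # keep strictly inside the half-open box
    np.copyto(y, 0.0, where=y < 0.0)
    hi = np.broadcast_to(np.nextafter(extent, 0.0), y.shape)
    np.copyto(y, hi, where=y >= extent)
    if rows is None:
        return y
    pos[rows] = y
    return pos


def reflect_many(pos_old: np.ndarray, pos_prop: np.ndarray,
                 access: np.ndarray, lattice: Lattice) -> np.ndarray:
    """Vectorized specular reflection of proposed positions.

    ``access`` is a boolean per-voxel mask of voxels the species may occupy.
    Positions are first folded at the domain boundary, then particles that
    landed in an inaccessible voxel are mirrored across the voxel-boundary
    plane(s) they crossed (relative to their old voxel) and re-checked;
    after ``REFLECT_CAP`` failures a particle stays at its old position.
    """
    pos = _fold_bounds(pos_prop, lattice.extent)
    idx = voxels_of(pos, lattice)
    bad = ~access[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not bad.any():
        return pos
    # iterate on the offending subset only
    rows = np.flatnonzero(bad)
    old_sub = pos_old[rows]
    old_idx = voxels_of(old_sub, lattice)
    p = pos[rows]
    for _ in range(REFLECT_CAP):
        sub_idx = voxels_of(p, lattice)
        still = ~access[sub_idx[:, 0], sub_idx[:, 1], sub_idx[:, 2]]
        if not still.any():
            break
        b = np.flatnonzero(still)
        q = p[b]
        for axis in range(3):
            crossed_up = sub_idx[b, axis] > old_idx[b, axis]
            crossed_dn = sub_idx[b, axis] < old_idx[b, axis]
            plane_up = (old_idx[b, axis] + 1) * lattice.h
            plane_dn = old_idx[b, axis] * lattice.h
            q[:, axis] = np.where(crossed_up, 2 * plane_up - q[:, axis],
                                  q[:, axis])
            q[:, axis] = np.where(crossed_dn, 2 * plane_dn - q[:, axis],
                                  q[:, axis])
        p[b] = _fold_bounds(q, lattice.extent)
    # unresolved after the cap: stay put
    sub_idx = voxels_of(p, lattice)
    still = ~access[sub_idx[:, 0], sub_idx[:, 1], sub_idx[:, 2]]
    p[still] = old_sub[still]
    pos[rows] = p
    return pos


def reflect(pos_old: np.ndarray, pos_proposed: np.ndarray,
            species: SpeciesDef, lattice: Lattice) -> np.ndarray:
    """Scalar reflection of one proposed position (see ``reflect_many``)."""
    access = lattice.accessibility_mask(species)
    out = reflect_many(np.asarray(pos_old, float)[None, :],
                       np.asarray(pos_proposed, float)[None, :],
                       access, lattice)
    return out[0]


def step_many(pos: np.ndarray, D: float, dt: float, rng: np.random.Generator,
              lattice: Lattice, access: np.ndarray,
              frozen_axis: np.ndarray | None = None,
              mobile: np.ndarray | None = None) -> np.ndarray:
    """Vectorized Brownian step + reflection for an (n, 3) position array.

    ``frozen_axis`` (int per particle, -1 = free) zeroes the displacement
    on the frozen axis of membrane-bound particles; ``mobile`` masks out
    immobilized particles entirely.
    """
    n = pos.shape[0]
    if n == 0:
        return pos
    disp = rng.normal(0.0, displacement_sigma(D, dt), size=(n, 3))
    if frozen_axis is not None:
        fa = frozen_axis
        has = fa >= 0
        if has.any():
            disp[np.where(has)[0], fa[has]] = 0.0
    if mobile is not None:
        disp[~mobile] = 0.0
    return reflect_many(pos, pos + disp, access, lattice)


def particle_step(p: Particle, D: float, dt: float,
                  rng: np.random.Generator, lattice: Lattice,
                  species: SpeciesDef | None = None) -> Particle:
    """Advance one particle by one Brownian step with reflection.

    Immobilized particles are returned unchanged.  If ``species`` is None,
    reflection only enforces the domain boundary.
    """
    if p.immobilized:
        return p
    if species is not None:
        access = lattice.accessibility_mask(species)
    else:
        access = np.ones(lattice.dims, dtype=bool)
    fa = np.array([p.frozen_axis], dtype=np.int8)
    new_pos = step_many(np.asarray(p.pos, float)[None, :], D, dt, rng,
                        lattice, access, frozen_axis=fa)
    return replace(p, pos=new_pos[0])
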