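"""Non-reaction events: sources/sinks, probabilistic inter-compartment
transport, microdomain partition biasing and reversible immobilization.

Transport abstracts vesicle-mediated trafficking (e.g. clathrin-mediated
internalization, export to the membrane) as a single probabilistic
relocation event per timestep.  Immobilization is the surrogate for
trans-binding of membrane receptors to an apposed cell: a matching mobile
particle becomes immobilized at rate ``k_on`` and is released at ``k_off``;
immobilized particles skip diffusion and transport.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .diffusion import ConcentrationField, Particle
from .geometry import Lattice, voxels_of
from .model import (N_AVOGADRO, ImmobilizationRule, MicrodomainSpec,
                    SourceSinkSpec, TransportRule, voxel_volume_litres)
from .reactions import fire_probability, pattern_matches


def apply_sources_sinks(field: ConcentrationField,
                        specs: list[SourceSinkSpec], dt: float,
                        lattice: Lattice) -> ConcentrationField:
    """Apply clamp / influx / absorb boundary conditions after diffusion.

    ``clamp`` sets the voxel to the target concentration (mol/L) exactly,
    ``influx`` adds ``value`` molecules, ``absorb`` zeroes the voxel.
    """
    v_litres = voxel_volume_litres(lattice.h)
    for spec in specs:
        if spec.species != field.species or not spec.voxels:
            continue
        idx = np.asarray(spec.voxels, dtype=np.intp)
        sel = (idx[:, 0], idx[:, 1], idx[:, 2])
        if spec.mode == "clamp":
            field.amounts[sel] = spec.value * N_AVOGADRO * v_litres
        elif spec.mode == "influx":
            field.amounts[sel] += spec.value
        elif spec.mode == "absorb":
            field.amounts[sel] = 0.0
    return field


def transport_step(particles: list[Particle], rule: TransportRule,
                   rng: np.random.Generator, lattice: Lattice,
                   dest_voxels: np.ndarray | None = None,
                   ) -> list[Particle]:
    """Relocate matching particles between compartments.

    Each mobile particle matching the rule's pattern, located in
    ``from_compartment`` and not carrying ``blocked_by_state``, relocates
    with probability ``prob_per_step`` to a uniformly random position in a
    uniformly random voxel of ``to_compartment`` (``dest_voxels`` may
    pre-restrict the destination set, e.g. to accessible voxels).
    """
    if dest_voxels is None:
        dest_voxels = lattice.compartment_voxels(rule.to_compartment)
    if len(dest_voxels) == 0:
        raise ValueError(
            f"transport '{rule.rule_id}': destination compartment "
            f"'{rule.to_compartment}' has no accessible voxel")
    from_id = lattice.compartment_names.index(rule.from_compartment)
    out = []
    for p in particles:
        if (p.immobilized or not pattern_matches(p, rule.pattern)
                or (rule.blocked_by_state is not None
                    and p.state_flags.get(rule.blocked_by_state, False))):
            out.append(p)
            continue
        vox = voxels_of(np.asarray(p.pos, float)[None, :], lattice)[0]
        if lattice.compartment_id[tuple(vox)] != from_id:
            out.append(p)
            continue
        if rng.random() >= rule.prob_per_step:
            out.append(p)
            continue
        out.append(replace(p, pos=random_position_in(
            dest_voxels, lattice, rng),
            frozen_axis=-1))
    return out


def random_position_in(voxel_list: np.ndarray, lattice: Lattice,
                       rng: np.random.Generator) -> np.ndarray:
    """Uniform random position inside a uniformly chosen voxel of the
    list."""
    vox = voxel_list[rng.integers(len(voxel_list))]
    return (np.asarray(vox, float) + rng.random(3)) * lattice.h


def partition_crossing(p: Particle, from_region: str | None,
                       to_region: str | None,
                       domains: list[MicrodomainSpec],
                       rng: np.random.Generator) -> bool:
    """Decide whether a particle's step across a microdomain boundary is
    allowed.

    Entry into a domain is accepted with that domain's ``entry_bias`` for
    the species, exit with its ``exit_bias``; species without a declared
    partition cross freely.  Returns True (allow) or False (deny; the
    caller reflects the particle at the domain boundary).
    """
    if from_region == to_region:
        return True
    by_name = {d.name: d for d in domains}
    if to_region is not None and to_region in by_name:
        bias = by_name[to_region].partition.get(p.species)
        if bias is not None and rng.random() >= bias.entry_bias:
            return False
    if from_region is not None and from_region in by_name:
        bias = by_name[from_region].partition.get(p.species)
        if bias is not None and rng.random() >= bias.exit_bias:
            return False
    return True


def immobilize_step(particles: list[Particle], rule: ImmobilizationRule,
                    dt: float, rng: np.random.Generator) -> list[Particle]:
    """Flip matching particles between mobile and immobilized states with
    first-order probabilities ``1 - exp(-k*dt)`` per step."""
    p_on = fire_probability(rule.k_on, dt) if rule.k_on > 0 else 0.0
    p_off = fire_probability(rule.k_off, dt) if rule.k_off > 0 else 0.0
    out = []
    for p in particles:
        if not pattern_matches(p, rule.pattern):
            out.append(p)
            continue
        if not p.immobilized and p_on > 0 and rng.random() < p_on:
            out.append(replace(p, immobilized=True))
        elif p.immobilized and p_off > 0 and rng.random() < p_off:
            out.append(replace(p, immobilized=False))
        else:
            out.append(p)
    return out
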