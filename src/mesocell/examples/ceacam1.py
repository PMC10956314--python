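"""Built-in CEACAM1 membrane-clustering models (raft and no-raft).

CEACAM1 is a transmembrane adhesion receptor: cis-homodimers are
signalling-inactive; activated calmodulin dissociates dimers into
monomers, Src-family kinase Lck phosphorylates monomer ITIM motifs
(blocking clathrin-mediated internalization), and monomers can become
transiently immobilized on the membrane, the surrogate for trans-binding
to receptors on an apposed cell ("clustered" CEACAM1 = currently
immobilized monomers).

Geometry: a 6 x 6 x 6 lattice of 0.2 um voxels with four compartments --
``membrane`` (outer voxel layer, 2-D diffusion), ``cytosolic_interface``
(next layer; activated calmodulin is confined here), ``cytosol`` and an
``organelle`` (excluded region) sharing the 2 x 2 x 2 core.  The raft
variant adds one 2 x 2-voxel lipid-raft patch per face (area fraction
~0.11) with monomer-favouring and dimer-excluding partition biases; Lck
starts inside rafts and cannot leave them.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..model import (Box, CompartmentSpec, EnvironmentSpec,
                     ImmobilizationRule, InitialCondition, MicrodomainSpec,
                     ModelSpec, OutputConfig, PartitionBias, ReactionRule,
                     SpeciesPattern, SpeciesDef, TransportRule)

#: Fig-level parameter grids explored by the published sweeps
LCK_COUNTS = (0, 10, 20)
CAM_COUNTS = (0, 2, 5, 10, 20)


@dataclass
class CeacamParams:
    """Parameters of the CEACAM1 localization model."""

    raft: bool = True
    n_lck: int = 20
    n_cam: int = 20
    n_dimer: int = 50
    k_dissoc: float = 4e7     # dimer + CaM_active, M^-1 s^-1
    k_dim: float = 1e6        # monomer + monomer -> dimer, M^-1 s^-1
    k_phos: float = 1e6       # Lck + monomer, M^-1 s^-1
    trans_k_on: float = 1.0   # immobilization (trans-binding), s^-1
    trans_k_off: float = 0.1  # release, s^-1
    p_export: float = 1e-3    # cytosol -> membrane, per step
    p_internalize: float = 1e-3  # membrane -> cytosol, per step
    d_membrane: float = 0.2   # um^2/s, membrane proteins
    d_cam: float = 25.0       # um^2/s, calmodulin
    raft_entry_monomer: float = 1.0
    raft_exit_monomer: float = 0.2
    raft_entry_dimer: float = 0.2
    raft_exit_dimer: float = 1.0
    dt: float = 50e-6
    n_steps: int = 200_000
    log_interval: int = 200
    seed: int = 0

    #: trans-binding rate-constant scan of the clustering sweep (s^-1)
    trans_k_on_scan: tuple[float, ...] = (0.1, 1.0, 10.0)
    #: dimerization rate-constant scan (M^-1 s^-1)
    k_dim_scan: tuple[float, ...] = (1e4, 1e5, 1e6, 1e7)


def _compartments() -> list[CompartmentSpec]:
    n = 6
    membrane = CompartmentSpec("membrane", membrane_2d=True, boxes=[
        Box(0, 1, 0, n, 0, n), Box(n - 1, n, 0, n, 0, n),
        Box(1, n - 1, 0, 1, 0, n), Box(1, n - 1, n - 1, n, 0, n),
        Box(1, n - 1, 1, n - 1, 0, 1), Box(1, n - 1, 1, n - 1, n - 1, n),
    ])
    interface = CompartmentSpec("cytosolic_interface", boxes=[
        Box(1, 2, 1, 5, 1, 5), Box(4, 5, 1, 5, 1, 5),
        Box(2, 4, 1, 2, 1, 5), Box(2, 4, 4, 5, 1, 5),
        Box(2, 4, 2, 4, 1, 2), Box(2, 4, 2, 4, 4, 5),
    ])
    # the 2x2x2 core splits into a 2x2x1 organelle slab and a 2x2x1
    # cytosol slab (the 6^3 geometry leaves no room for both a full
    # central organelle and a distinct cytosol)
    organelle = CompartmentSpec("organelle", boxes=[Box(2, 4, 2, 4, 2, 3)])
    cytosol = CompartmentSpec("cytosol", boxes=[Box(2, 4, 2, 4, 3, 4)])
    return [membrane, interface, cytosol, organelle]


def _raft_domain(p: CeacamParams) -> MicrodomainSpec:
    n = 6
    vox = []
    for a in (0, n - 1):
        vox += [(a, j, k) for j in (2, 3) for k in (2, 3)]        # x faces
        vox += [(i, a, k) for i in (2, 3) for k in (2, 3)]        # y faces
        vox += [(i, j, a) for i in (2, 3) for j in (2, 3)]        # z faces
    vox = sorted(set(vox))
    return MicrodomainSpec("rafts", voxels=vox, partition={
        "CEACAM1_monomer": PartitionBias(p.raft_entry_monomer,
                                         p.raft_exit_monomer),
        "CEACAM1_dimer": PartitionBias(p.raft_entry_dimer,
                                       p.raft_exit_dimer),
        "Lck": PartitionBias(1.0, 0.0),
    })


def build_ceacam1_model(p: CeacamParams | None = None) -> ModelSpec:
    """Build the raft or no-raft CEACAM1 model."""
    p = p or CeacamParams()
    env = EnvironmentSpec(6, 6, 6, 0.2, p.dt, p.n_steps)
    comps = _compartments()
    species = [
        SpeciesDef("CEACAM1_dimer", "particle", p.d_membrane,
                   allowed_compartments=["membrane", "cytosol"],
                   membrane_bound=True),
        SpeciesDef("CEACAM1_monomer", "particle", p.d_membrane,
                   states=["phosphorylated"],
                   allowed_compartments=["membrane", "cytosol"],
                   membrane_bound=True),
        SpeciesDef("Lck", "particle", p.d_membrane,
                   allowed_compartments=["membrane"],
                   membrane_bound=True),
        SpeciesDef("CaM_active", "particle", p.d_cam,
                   allowed_compartments=["cytosolic_interface"]),
    ]
    reactions = [
        # activated calmodulin dissociates cis-dimers (catalytic)
        ReactionRule("dimer_dissociation",
                     [SpeciesPattern("CEACAM1_dimer"),
                      SpeciesPattern("CaM_active")],
                     [SpeciesPattern("CEACAM1_monomer"),
                      SpeciesPattern("CEACAM1_monomer"),
                      SpeciesPattern("CaM_active")],
                     k=p.k_dissoc),
        ReactionRule("dimerization",
                     [SpeciesPattern("CEACAM1_monomer"),
                      SpeciesPattern("CEACAM1_monomer")],
                     [SpeciesPattern("CEACAM1_dimer")],
                     k=p.k_dim),
        ReactionRule("itim_phosphorylation",
                     [SpeciesPattern("Lck"),
                      SpeciesPattern("CEACAM1_monomer",
                                     states={"phosphorylated": False})],
                     [SpeciesPattern("Lck"),
                      SpeciesPattern("CEACAM1_monomer",
                                     states={"phosphorylated": True})],
                     k=p.k_phos, compartments=["membrane"]),
    ]
    transports = [
        TransportRule("export_dimer", SpeciesPattern("CEACAM1_dimer"),
                      "cytosol", "membrane", p.p_export),
        TransportRule("export_monomer", SpeciesPattern("CEACAM1_monomer"),
                      "cytosol", "membrane", p.p_export),
        TransportRule("internalize_dimer", SpeciesPattern("CEACAM1_dimer"),
                      "membrane", "cytosol", p.p_internalize),
        TransportRule("internalize_monomer",
                      SpeciesPattern("CEACAM1_monomer"),
                      "membrane", "cytosol", p.p_internalize,
                      blocked_by_state="phosphorylated"),
    ]
    immobilizations = [
        ImmobilizationRule("trans_binding",
                           SpeciesPattern("CEACAM1_monomer"),
                           k_on=p.trans_k_on, k_off=p.trans_k_off,
                           compartments=["membrane"]),
    ]
    initial = [
        InitialCondition("CEACAM1_dimer", "count", p.n_dimer, "cytosol"),
        InitialCondition("CaM_active", "count", p.n_cam,
                         "cytosolic_interface"),
    ]
    microdomains = []
    if p.raft:
        microdomains.append(_raft_domain(p))
        initial.append(InitialCondition("Lck", "count", p.n_lck,
                                        "membrane",
                                        microdomain="rafts"))
    else:
        initial.append(InitialCondition("Lck", "count", p.n_lck,
                                        "membrane"))
    return ModelSpec(
        environment=env, compartments=comps, species=species,
        reactions=reactions, transports=transports,
        immobilizations=immobilizations,
        microdomains=microdomains, initial_conditions=initial,
        output=OutputConfig(log_interval=p.log_interval),
        seed=p.seed)
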