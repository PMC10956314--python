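"""Built-in calmodulin activation models.

Calmodulin (CaM) carries four calcium-binding sites organised as two
lobes (N- and C-terminal) of two sites each; binding within a lobe is
sequential and positively cooperative (second-site affinity higher).  In
these models Ca2+ is a bulk species and calmodulin a point-particle
species with sites ``N1, N2, C1, C2``; the sequential scheme is expressed
as state-dependent bulk-particle binding rules (site 2 of a lobe can only
bind while site 1 is bound).

Two geometries are provided:

* a well-mixed box (4 x 4 x 4 voxels of 0.2 um; 0.8 um cube, volume
  5.12e-16 L) for comparison against the well-mixed oracle, and
* a calcium-microdomain model: 10 x 10 x 10 voxels of 0.08 um divided
  into five cross-sectional quintile slabs Q1..Q5, with four Ca2+
  channel (source) voxels on the Q1 face releasing calcium every step
  and an absorbing sink face at the far side of Q5, producing a
  standing Ca2+ gradient spanning the few-uM range.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import yaml

from ..model import (Box, CompartmentSpec, EnvironmentSpec,
                     InitialCondition, ModelSpec, OutputConfig,
                     ReactionRule, SourceSinkSpec, SpeciesDef,
                     SpeciesPattern)

#: diffusion coefficients (um^2/s): free Ca2+ in cytosol and calmodulin
D_CA = 220.0
D_CAM = 25.0

#: advisory range for calcium-calmodulin association constants
K_ON_RANGE = (1e7, 1e10)

SOURCE_LAYOUTS = ("center", "original", "split")


@dataclass(frozen=True)
class LobeRates:
    """Per-site sequential (T/R) rate constants of one lobe.  Statistical
    factors are applied by the rule builder, not stored here."""

    k_on_T: float   # M^-1 s^-1
    k_off_T: float  # s^-1
    k_on_R: float   # M^-1 s^-1
    k_off_R: float  # s^-1

    @property
    def k_on1(self) -> float:
        """Effective first-site association constant (2 x per-site)."""
        return 2.0 * self.k_on_T

    @property
    def k_off1(self) -> float:
        return self.k_off_T

    @property
    def k_on2(self) -> float:
        return self.k_on_R

    @property
    def k_off2(self) -> float:
        """Effective dissociation from the doubly-occupied lobe."""
        return 2.0 * self.k_off_R


def load_default_rates() -> dict[str, LobeRates]:
    """Load the versioned cooperative rate-constant file."""
    ref = importlib.resources.files("mesocell.examples") \
        / "data" / "calmodulin_rates.yaml"
    raw = yaml.safe_load(ref.read_text())
    return {lobe: LobeRates(**{k: float(v) for k, v in vals.items()})
            for lobe, vals in raw.items()}


def _default_n_lobe() -> LobeRates:
    return load_default_rates()["n_lobe"]


def _default_c_lobe() -> LobeRates:
    return load_default_rates()["c_lobe"]


@dataclass
class CalmodulinParams:
    """Parameters of the calmodulin models (concentrations mol/L)."""

    cam_total: float = 2e-6
    ca_total: float = 1e-5
    n_lobe: LobeRates = field(default_factory=_default_n_lobe)
    c_lobe: LobeRates = field(default_factory=_default_c_lobe)
    dims: tuple[int, int, int] = (4, 4, 4)
    voxel_len: float = 0.2
    dt: float = 1e-6
    n_steps: int = 50_000
    d_ca: float = D_CA
    d_cam: float = D_CAM
    log_interval: int = 500
    seed: int = 0

    def check(self) -> None:
        lo, hi = K_ON_RANGE
        for name, rates in (("n_lobe", self.n_lobe),
                            ("c_lobe", self.c_lobe)):
            for attr in ("k_on_T", "k_on_R"):
                k = getattr(rates, attr)
                if not lo <= k <= hi:
                    warnings.warn(
                        f"{name}.{attr} = {k:.3g} M^-1 s^-1 outside the "
                        f"typical association range {lo:g}-{hi:g}",
                        stacklevel=2)
            if any(getattr(rates, a) < 0 for a in
                   ("k_on_T", "k_off_T", "k_on_R", "k_off_R")):
                raise ValueError(f"{name}: negative rate constant")


CAM_SITES = ["N1", "N2", "C1", "C2"]


def _binding_rules(p: CalmodulinParams) -> list[ReactionRule]:
    """Sequential cooperative binding/release rules for both lobes."""
    rules = []
    for lobe, (s1, s2) in (("n_lobe", ("N1", "N2")),
                           ("c_lobe", ("C1", "C2"))):
        rates: LobeRates = getattr(p, lobe)
        rules += [
            ReactionRule(
                f"{lobe}_bind1",
                [SpeciesPattern("Ca"),
                 SpeciesPattern("CaM", sites={s1: False})],
                [SpeciesPattern("CaM", sites={s1: True})],
                k=rates.k_on1),
            ReactionRule(
                f"{lobe}_release1",
                [SpeciesPattern("CaM", sites={s1: True, s2: False})],
                [SpeciesPattern("CaM", sites={s1: False}),
                 SpeciesPattern("Ca")],
                k=rates.k_off1),
            ReactionRule(
                f"{lobe}_bind2",
                [SpeciesPattern("Ca"),
                 SpeciesPattern("CaM", sites={s1: True, s2: False})],
                [SpeciesPattern("CaM", sites={s2: True})],
                k=rates.k_on2),
            ReactionRule(
                f"{lobe}_release2",
                [SpeciesPattern("CaM", sites={s2: True})],
                [SpeciesPattern("CaM", sites={s2: False}),
                 SpeciesPattern("Ca")],
                k=rates.k_off2),
        ]
    return rules


def build_calmodulin_wellmixed(p: CalmodulinParams | None = None,
                               ) -> ModelSpec:
    """Well-mixed calmodulin activation model in a 0.8 um cube."""
    p = p or CalmodulinParams()
    p.check()
    nx, ny, nz = p.dims
    env = EnvironmentSpec(nx, ny, nz, p.voxel_len, p.dt, p.n_steps)
    comp = CompartmentSpec("cytosol", boxes=[Box(0, nx, 0, ny, 0, nz)])
    species = [
        SpeciesDef("Ca", "bulk", p.d_ca,
                   allowed_compartments=["cytosol"]),
        SpeciesDef("CaM", "particle", p.d_cam, sites=list(CAM_SITES),
                   allowed_compartments=["cytosol"]),
    ]
    return ModelSpec(
        environment=env, compartments=[comp], species=species,
        reactions=_binding_rules(p),
        initial_conditions=[
            InitialCondition("Ca", "concentration", p.ca_total),
            InitialCondition("CaM", "concentration", p.cam_total),
        ],
        output=OutputConfig(log_interval=p.log_interval),
        seed=p.seed)


#: quintile-model source layouts: (j, k) voxel coordinates on the Q1
#: face (x = 0); the exact placement is non-critical (verified by the
#: layout-insensitivity test)
_LAYOUT_JK = {
    "center": [(4, 4), (4, 5), (5, 4), (5, 5)],
    "original": [(5, 5), (5, 6), (6, 5), (6, 6)],
    "split": [(2, 2), (2, 7), (7, 2), (7, 7)],
}


#: default Ca2+ release per source voxel per step (molecules).  The
#: channel release rate is not published; this value is calibrated once
#: so that the standing quintile-average Ca2+ gradient spans the few-uM
#: range reported for the system (order 10 uM next to the source, order
#: 1 uM at the far sink; box average ~1-2 uM).  A literal 1 mM Dirichlet
#: clamp at the source voxels would pin the whole box at hundreds of uM
#: in steady state, far above that regime.
RELEASE_PER_STEP = 0.3


def build_microdomain_model(layout: str = "center",
                            p: CalmodulinParams | None = None,
                            release_per_step: float = RELEASE_PER_STEP,
                            source_mode: str = "influx",
                            clamp_M: float = 1e-3) -> ModelSpec:
    """Calcium-microdomain quintile model.

    10 x 10 x 10 lattice of 0.08 um voxels, five 2-voxel slabs Q1..Q5
    along x; four channel (source) voxels on the Q1 outer face release
    calcium every step (``influx`` mode, ``release_per_step`` molecules
    per voxel, or ``clamp`` mode pinning them at ``clamp_M`` mol/L); the
    Q5 outer face absorbs.  All other boundaries reflect.  Calmodulin
    diffuses freely through all quintiles.
    """
    if layout not in SOURCE_LAYOUTS:
        raise ValueError(f"unknown source layout '{layout}'; choose from "
                         f"{SOURCE_LAYOUTS}")
    if source_mode not in ("influx", "clamp"):
        raise ValueError(f"unknown source mode '{source_mode}'")
    p = p or CalmodulinParams(dims=(10, 10, 10), voxel_len=0.08,
                              n_steps=300_000, log_interval=2000)
    p.check()
    nx, ny, nz = p.dims
    env = EnvironmentSpec(nx, ny, nz, p.voxel_len, p.dt, p.n_steps)
    slab = nx // 5
    comps = [CompartmentSpec(f"Q{q + 1}",
                             boxes=[Box(q * slab, (q + 1) * slab,
                                        0, ny, 0, nz)])
             for q in range(5)]
    quintiles = [c.name for c in comps]
    species = [
        SpeciesDef("Ca", "bulk", p.d_ca, allowed_compartments=quintiles),
        SpeciesDef("CaM", "particle", p.d_cam, sites=list(CAM_SITES),
                   allowed_compartments=quintiles),
    ]
    src_voxels = [(0, j, k) for j, k in _LAYOUT_JK[layout]]
    if source_mode == "influx":
        sources = [SourceSinkSpec("Ca", voxels=src_voxels, mode="influx",
                                  value=release_per_step)]
    else:
        sources = [SourceSinkSpec("Ca", voxels=src_voxels, mode="clamp",
                                  value=clamp_M)]
    sinks = [SourceSinkSpec(
        "Ca", voxels=[(nx - 1, j, k) for j in range(ny)
                      for k in range(nz)],
        mode="absorb")]
    return ModelSpec(
        environment=env, compartments=comps, species=species,
        reactions=_binding_rules(p),
        sources_sinks=sources + sinks,
        initial_conditions=[
            InitialCondition("CaM", "concentration", p.cam_total),
        ],
        output=OutputConfig(log_interval=p.log_interval),
        seed=p.seed)
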