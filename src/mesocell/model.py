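"""In-memory model description and validation.

A :class:`ModelSpec` fully describes one simulation: the voxel lattice and
its compartments, the molecular species (bulk concentration fields vs point
particles), reaction and transport rules, sources/sinks, membrane
microdomains, initial conditions and output configuration.

Unit conventions, fixed at this interface:

* lengths in micrometres (um), times in seconds
* bulk concentrations in mol/L; bimolecular rate constants in M^-1 s^-1,
  unimolecular in s^-1
* a voxel of edge ``h`` um has volume ``h**3 * 1e-15`` litres
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Avogadro's number (mol^-1), 2019 SI exact value.
N_AVOGADRO = 6.02214076e23

#: Working range of voxel edge lengths (um); outside it validation records
#: an advisory warning (the discretisation is still legal, just unusual).
VOXEL_LEN_RANGE = (0.01, 1.0)

#: Forward-Euler stability bound for the 3-D 6-point diffusion stencil.
STABILITY_LIMIT = 1.0 / 6.0

#: Name of the implicit compartment covering voxels not claimed by any
#: declared compartment.
DEFAULT_COMPARTMENT = "environment"


def voxel_volume_litres(voxel_len: float) -> float:
    """Volume of one cubic voxel of edge ``voxel_len`` um, in litres."""
    return float(voxel_len) ** 3 * 1e-15


@dataclass(frozen=True)
class EnvironmentSpec:
    """Global lattice geometry and time discretisation."""

    nx: int
    ny: int
    nz: int
    voxel_len: float  # um
    timestep: float  # s
    n_steps: int

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def extent(self) -> tuple[float, float, float]:
        return (self.nx * self.voxel_len,
                self.ny * self.voxel_len,
                self.nz * self.voxel_len)


@dataclass(frozen=True)
class Box:
    """Axis-aligned voxel-index box, 0-based half-open on each axis."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def voxels(self) -> list[tuple[int, int, int]]:
        return [(i, j, k)
                for i in range(self.x0, self.x1)
                for j in range(self.y0, self.y1)
                for k in range(self.z0, self.z1)]


@dataclass
class CompartmentSpec:
    """A named set of voxels; may nest inside a parent compartment."""

    name: str
    boxes: list[Box] = field(default_factory=list)
    voxels: list[tuple[int, int, int]] = field(default_factory=list)
    parent: str | None = None
    membrane_2d: bool = False

    def voxel_set(self) -> set[tuple[int, int, int]]:
        out: set[tuple[int, int, int]] = set(map(tuple, self.voxels))
        for b in self.boxes:
            out.update(b.voxels())
        return out


@dataclass
class SpeciesDef:
    """One molecular species.

    ``kind`` is ``"bulk"`` (real-valued amount per voxel, deterministic
    grid diffusion) or ``"particle"`` (individually tracked point molecule
    with continuous coordinates and internal state).
    """

    name: str
    kind: str  # "bulk" | "particle"
    D: float  # um^2/s
    sites: list[str] = field(default_factory=list)
    states: list[str] = field(default_factory=list)
    allowed_compartments: list[str] = field(default_factory=list)
    membrane_bound: bool = False


@dataclass
class SpeciesPattern:
    """Species selector with optional site-occupancy / state constraints.

    As a *reactant* pattern, ``sites``/``states`` entries are match
    conditions (site name -> required bound/empty, state name -> required
    flag value); unnamed sites/states match anything.  As a *product*
    pattern they are assignments applied to the outgoing particle.
    """

    species: str
    sites: dict[str, bool] = field(default_factory=dict)
    states: dict[str, bool] = field(default_factory=dict)


@dataclass
class ReactionRule:
    """Unimolecular or bimolecular mass-action rule.

    ``k`` is in s^-1 for one reactant and M^-1 s^-1 for two.  An empty
    ``compartments`` list scopes the rule everywhere.
    """

    rule_id: str
    reactants: list[SpeciesPattern]
    products: list[SpeciesPattern]
    k: float
    compartments: list[str] = field(default_factory=list)
    reversible: bool = False
    k_rev: float = 0.0


@dataclass
class TransportRule:
    """Probabilistic relocation of matching particles between compartments."""

    rule_id: str
    pattern: SpeciesPattern
    from_compartment: str
    to_compartment: str
    prob_per_step: float
    blocked_by_state: str | None = None


@dataclass
class ImmobilizationRule:
    """Reversible immobilization of matching particles (trans-binding
    surrogate): mobile -> immobilized at rate ``k_on`` (s^-1), released at
    ``k_off`` (s^-1).  Immobilized particles skip diffusion and transport."""

    rule_id: str
    pattern: SpeciesPattern
    k_on: float
    k_off: float
    compartments: list[str] = field(default_factory=list)


@dataclass
class SourceSinkSpec:
    """Per-step boundary condition on a bulk species.

    ``mode``: ``clamp`` (Dirichlet; voxel concentration set to ``value``
    mol/L after diffusion), ``influx`` (``value`` molecules added per step)
    or ``absorb`` (voxel amount zeroed).
    """

    species: str
    voxels: list[tuple[int, int, int]]
    mode: str  # "clamp" | "influx" | "absorb"
    value: float = 0.0


@dataclass
class PartitionBias:
    """Entry/exit acceptance probabilities for one species at a
    microdomain boundary."""

    entry_bias: float = 1.0
    exit_bias: float = 1.0


@dataclass
class MicrodomainSpec:
    """Membrane sub-region (e.g. a lipid raft) with species-specific
    entry/exit biases; crossing attempts are accepted with the bias
    probability, otherwise the particle reflects at the domain boundary."""

    name: str
    voxels: list[tuple[int, int, int]] = field(default_factory=list)
    partition: dict[str, PartitionBias] = field(default_factory=dict)


@dataclass
class InitialCondition:
    """Initial placement of one species.

    ``amount`` is ``"count"`` (particles or molecules) or
    ``"concentration"`` (mol/L, converted via voxel volume).  ``compartment``
    of ``None`` places uniformly over all accessible voxels; an optional
    ``microdomain`` further restricts placement to that domain's voxels.
    """

    species: str
    amount: str  # "count" | "concentration"
    value: float
    compartment: str | None = None
    microdomain: str | None = None


@dataclass
class OutputConfig:
    log_interval: int = 1
    particle_log: bool = False


@dataclass
class ModelSpec:
    """Complete simulation model."""

    environment: EnvironmentSpec
    compartments: list[CompartmentSpec] = field(default_factory=list)
    species: list[SpeciesDef] = field(default_factory=list)
    reactions: list[ReactionRule] = field(default_factory=list)
    transports: list[TransportRule] = field(default_factory=list)
    immobilizations: list[ImmobilizationRule] = field(default_factory=list)
    sources_sinks: list[SourceSinkSpec] = field(default_factory=list)
    microdomains: list[MicrodomainSpec] = field(default_factory=list)
    initial_conditions: list[InitialCondition] = field(default_factory=list)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 0

    def species_by_name(self) -> dict[str, SpeciesDef]:
        return {s.name: s for s in self.species}

    def compartment_names(self) -> list[str]:
        names = [c.name for c in self.compartments]
        if DEFAULT_COMPARTMENT not in names:
            names.append(DEFAULT_COMPARTMENT)
        return names


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    element: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.element}: {self.message}"


class ValidationError(ValueError):
    """Raised when a model with error-level violations is used."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


def _in_bounds(v: tuple[int, int, int], dims: tuple[int, int, int]) -> bool:
    return all(0 <= v[a] < dims[a] for a in range(3))


def _outer_layer(dims: tuple[int, int, int]) -> set[tuple[int, int, int]]:
    nx, ny, nz = dims
    return {(i, j, k)
            for i in range(nx) for j in range(ny) for k in range(nz)
            if i in (0, nx - 1) or j in (0, ny - 1) or k in (0, nz - 1)}


def _check_pattern(pat: SpeciesPattern, species: dict[str, SpeciesDef],
                   where: str, out: list[Violation]) -> None:
    sp = species.get(pat.species)
    if sp is None:
        out.append(Violation(where, f"unknown species '{pat.species}'"))
        return
    for s in pat.sites:
        if s not in sp.sites:
            out.append(Violation(
                where, f"species '{sp.name}' has no site '{s}'"))
    for s in pat.states:
        if s not in sp.states:
            out.append(Violation(
                where, f"species '{sp.name}' has no state '{s}'"))
    if sp.kind == "bulk" and (pat.sites or pat.states):
        out.append(Violation(
            where, f"bulk species '{sp.name}' cannot carry sites/states"))


def validate_model(model: ModelSpec) -> list[Violation]:
    """Check every model invariant; returns an empty list iff all hold.

    Violations are data, not exceptions; error-severity entries make the
    model unusable, warning-severity entries are advisory.
    """
    out: list[Violation] = []
    env = model.environment
    dims = env.dims

    # --- environment -----------------------------------------------------
    if min(dims) < 1:
        out.append(Violation("environment", "voxel counts must be >= 1"))
    if env.voxel_len <= 0:
        out.append(Violation("environment", "voxel_len must be > 0"))
    if env.timestep <= 0:
        out.append(Violation("environment", "timestep must be > 0"))
    if env.n_steps < 0:
        out.append(Violation("environment", "n_steps must be >= 0"))
    lo, hi = VOXEL_LEN_RANGE
    if env.voxel_len > 0 and not (lo <= env.voxel_len <= hi):
        out.append(Violation(
            "environment",
            f"voxel_len {env.voxel_len} um outside working range "
            f"{lo}-{hi} um", severity="warning"))
    if min(dims) < 1 or env.voxel_len <= 0:
        return out  # geometry-dependent checks would be meaningless

    # --- compartments ----------------------------------------------------
    comp_names = [c.name for c in model.compartments]
    if len(set(comp_names)) != len(comp_names):
        out.append(Violation("compartments", "duplicate compartment name"))
    known_comps = set(comp_names) | {DEFAULT_COMPARTMENT}
    outer = _outer_layer(dims)
    claimed: dict[tuple[int, int, int], str] = {}
    comp_voxels: dict[str, set[tuple[int, int, int]]] = {}
    for comp in model.compartments:
        vs = comp.voxel_set()
        comp_voxels[comp.name] = vs
        for v in vs:
            if not _in_bounds(v, dims):
                out.append(Violation(
                    f"compartment '{comp.name}'",
                    f"voxel {v} outside lattice bounds {dims}"))
        if comp.parent is not None:
            if comp.parent not in known_comps:
                out.append(Violation(
                    f"compartment '{comp.name}'",
                    f"unknown parent '{comp.parent}'"))
            elif comp.parent in comp_voxels and \
                    not vs <= comp_voxels[comp.parent]:
                out.append(Violation(
                    f"compartment '{comp.name}'",
                    f"not contained in parent '{comp.parent}'"))
        for v in vs:
            owner = claimed.get(v)
            if owner is not None and owner != comp.parent:
                out.append(Violation(
                    f"compartment '{comp.name}'",
                    f"voxel {v} already belongs to '{owner}'"))
                break
        claimed.update({v: comp.name for v in vs})
        if comp.membrane_2d and not vs <= outer:
            out.append(Violation(
                f"compartment '{comp.name}'",
                "membrane_2d compartment must lie in the outer voxel layer"))

    # --- species ---------------------------------------------------------
    species = model.species_by_name()
    if len(species) != len(model.species):
        out.append(Violation("species", "duplicate species name"))
    h, dt = env.voxel_len, env.timestep
    for sp in model.species:
        el = f"species '{sp.name}'"
        if sp.kind not in ("bulk", "particle"):
            out.append(Violation(el, f"unknown kind '{sp.kind}'"))
        if sp.D < 0:
            out.append(Violation(el, "diffusion coefficient D must be >= 0"))
        if sp.kind == "bulk" and (sp.sites or sp.states):
            out.append(Violation(el, "bulk species cannot have sites/states"))
        if not sp.allowed_compartments:
            out.append(Violation(el, "allowed_compartments must be non-empty"))
        for c in sp.allowed_compartments:
            if c not in known_comps:
                out.append(Violation(el, f"unknown compartment '{c}'"))
        if sp.kind == "bulk" and dt > 0:
            ratio = sp.D * dt / h ** 2
            if ratio > STABILITY_LIMIT:
                out.append(Violation(
                    el,
                    f"forward-Euler stability violated: D*dt/h^2 = "
                    f"{ratio:.4g} > 1/6"))

    # --- reactions -------------------------------------------------------
    for rule in model.reactions:
        el = f"reaction '{rule.rule_id}'"
        if not 1 <= len(rule.reactants) <= 2:
            out.append(Violation(el, "must have 1 or 2 reactants"))
        if rule.k < 0 or (rule.reversible and rule.k_rev < 0):
            out.append(Violation(el, "rate constants must be >= 0"))
        for pat in rule.reactants + rule.products:
            _check_pattern(pat, species, el, out)
        for c in rule.compartments:
            if c not in known_comps:
                out.append(Violation(el, f"unknown compartment '{c}'"))
        r_kinds = [species[p.species].kind for p in rule.reactants
                   if p.species in species]
        if r_kinds and all(k == "bulk" for k in r_kinds):
            for p in rule.products:
                if p.species in species and \
                        species[p.species].kind == "particle":
                    out.append(Violation(
                        el, "bulk-only reactions cannot create particle "
                            "products"))
        _check_site_mass(rule, species, el, out)

    # --- transports ------------------------------------------------------
    for tr in model.transports:
        el = f"transport '{tr.rule_id}'"
        _check_pattern(tr.pattern, species, el, out)
        if not 0 <= tr.prob_per_step <= 1:
            out.append(Violation(el, "prob_per_step must be in [0, 1]"))
        if tr.from_compartment == tr.to_compartment:
            out.append(Violation(el, "from and to compartments must differ"))
        for c in (tr.from_compartment, tr.to_compartment):
            if c not in known_comps:
                out.append(Violation(el, f"unknown compartment '{c}'"))
        sp = species.get(tr.pattern.species)
        if sp is not None and tr.to_compartment in known_comps and \
                tr.to_compartment not in sp.allowed_compartments:
            out.append(Violation(
                el, f"destination '{tr.to_compartment}' not accessible to "
                    f"species '{sp.name}'"))
        if tr.blocked_by_state is not None and sp is not None and \
                tr.blocked_by_state not in sp.states:
            out.append(Violation(
                el, f"unknown blocking state '{tr.blocked_by_state}'"))

    # --- immobilizations -------------------------------------------------
    for im in model.immobilizations:
        el = f"immobilization '{im.rule_id}'"
        _check_pattern(im.pattern, species, el, out)
        if im.k_on < 0 or im.k_off < 0:
            out.append(Violation(el, "rates must be >= 0"))

    # --- sources/sinks ---------------------------------------------------
    for i, src in enumerate(model.sources_sinks):
        el = f"source/sink[{i}] ({src.species})"
        if src.species not in species:
            out.append(Violation(el, f"unknown species '{src.species}'"))
        elif species[src.species].kind != "bulk":
            out.append(Violation(el, "sources/sinks apply to bulk species"))
        if src.mode not in ("clamp", "influx", "absorb"):
            out.append(Violation(el, f"unknown mode '{src.mode}'"))
        if src.mode in ("clamp", "influx") and src.value < 0:
            out.append(Violation(el, "value must be >= 0"))
        for v in src.voxels:
            if not _in_bounds(v, dims):
                out.append(Violation(el, f"voxel {v} outside bounds"))

    # --- microdomains ----------------------------------------------------
    membrane_voxels: set[tuple[int, int, int]] = set()
    for comp in model.compartments:
        if comp.membrane_2d:
            membrane_voxels |= comp_voxels.get(comp.name, set())
    for dom in model.microdomains:
        el = f"microdomain '{dom.name}'"
        if not set(dom.voxels) <= membrane_voxels:
            out.append(Violation(
                el, "voxels must lie inside a membrane_2d compartment"))
        for sp_name, bias in dom.partition.items():
            if sp_name not in species:
                out.append(Violation(el, f"unknown species '{sp_name}'"))
            if not (0 <= bias.entry_bias <= 1 and 0 <= bias.exit_bias <= 1):
                out.append(Violation(
                    el, f"biases for '{sp_name}' must be in [0, 1]"))

    # --- initial conditions ---------------------------------------------
    for i, ic in enumerate(model.initial_conditions):
        el = f"initial[{i}] ({ic.species})"
        if ic.species not in species:
            out.append(Violation(el, f"unknown species '{ic.species}'"))
        if ic.amount not in ("count", "concentration"):
            out.append(Violation(el, f"unknown amount kind '{ic.amount}'"))
        if ic.value < 0:
            out.append(Violation(el, "initial amount must be >= 0"))
        if ic.compartment is not None and ic.compartment not in known_comps:
            out.append(Violation(el, f"unknown compartment '{ic.compartment}'"))
        if ic.microdomain is not None and ic.microdomain not in \
                {d.name for d in model.microdomains}:
            out.append(Violation(el, f"unknown microdomain '{ic.microdomain}'"))

    # --- output ----------------------------------------------------------
    if model.output.log_interval < 1:
        out.append(Violation("output", "log_interval must be >= 1"))

    return out


def _check_site_mass(rule: ReactionRule, species: dict[str, SpeciesDef],
                     el: str, out: list[Violation]) -> None:
    """For binding/unbinding rules (a particle species persisting from
    reactants to products plus a bulk co-reactant/product), the change in
    bound-site count must equal the number of bulk molecules consumed."""
    r_particles = [p for p in rule.reactants
                   if species.get(p.species, SpeciesDef("", "particle", 0)
                                  ).kind == "particle"]
    p_particles = [p for p in rule.products
                   if species.get(p.species, SpeciesDef("", "particle", 0)
                                  ).kind == "particle"]
    r_bulk = sum(1 for p in rule.reactants
                 if species.get(p.species) is not None
                 and species[p.species].kind == "bulk")
    p_bulk = sum(1 for p in rule.products
                 if species.get(p.species) is not None
                 and species[p.species].kind == "bulk")
    if len(r_particles) != 1 or len(p_particles) != 1:
        return
    if r_particles[0].species != p_particles[0].species:
        return
    if r_bulk == p_bulk == 0:
        return
    sdef = species.get(r_particles[0].species)
    if sdef is None or not sdef.sites:
        return  # catalytic consumption by a site-less species is legal
    # site delta implied by the product assignments relative to reactant
    # match constraints; only sites explicitly set in the product count
    delta = 0
    before = r_particles[0].sites
    for s, bound in p_particles[0].sites.items():
        was = before.get(s)
        if was is None or was == bound:
            continue
        delta += 1 if bound else -1
    if delta != r_bulk - p_bulk:
        out.append(Violation(
            el, f"site mass not conserved: bound-site change {delta:+d} vs "
                f"bulk molecule change {r_bulk - p_bulk:+d}"))


def require_valid(model: ModelSpec) -> None:
    """Raise :class:`ValidationError` if the model has error violations."""
    errors = [v for v in validate_model(model) if v.severity == "error"]
    if errors:
        raise ValidationError(errors)
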