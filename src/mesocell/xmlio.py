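"""Reader/writer for the XML model dialect.

The dialect is self-defined and documented here (no compatibility with any
external schema is claimed).  Root element ``<mesocell-model>`` with
children, in this fixed order (empty optional sections are omitted):

* ``<environment nx ny nz voxel_len timestep n_steps seed/>``
* ``<compartments><compartment name [parent] [membrane_2d]>`` containing
  ``<box x0 x1 y0 y1 z0 z1/>`` (0-based, half-open) and/or
  ``<voxel i j k/>`` elements
* ``<species name kind D [membrane_bound]>`` with ``<site name/>``,
  ``<state name/>`` and ``<allowed compartment=NAME/>`` children
* ``<reactions><reaction id k [k_rev] [reversible] [compartments]>`` with
  ``<reactant/>`` and ``<product/>`` pattern elements carrying
  ``species`` plus optional ``sites``/``states`` attributes written as
  comma-separated ``name=true|false`` assignments
* ``<transports><transport id species [sites] [states] from to prob
  [blocked_by]/>``
* ``<immobilizations><immobilization id species [sites] [states] k_on
  k_off/>``
* ``<sources><source species mode [value]>`` with ``<voxel/>`` children
* ``<microdomains><domain name>`` with ``<voxel/>``/``<box/>`` and
  ``<partition species entry exit/>`` children
* ``<initial species amount="count|concentration" value [compartment]/>``
* ``<output log_interval particle_log/>``

Numbers are serialized with ``repr`` so float values round-trip exactly.
"""

from __future__ import annotations

from lxml import etree

from .model import (Box, CompartmentSpec, EnvironmentSpec,
                    ImmobilizationRule, InitialCondition, MicrodomainSpec,
                    ModelSpec, OutputConfig, PartitionBias, ReactionRule,
                    SourceSinkSpec, SpeciesDef, SpeciesPattern,
                    TransportRule, require_valid)

ROOT_TAG = "mesocell-model"


class ModelParseError(ValueError):
    """Malformed XML or dialect violation, with source line when known."""


# ---------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, bool):
        return "true" if x else "false"
    return repr(x) if isinstance(x, float) else str(x)


def _get(el, name, conv=str, default=None, required=False):
    v = el.get(name)
    if v is None:
        if required:
            raise ModelParseError(
                f"line {el.sourceline}: <{el.tag}> missing attribute "
                f"'{name}'")
        return default
    try:
        if conv is bool:
            return v.lower() in ("1", "true", "yes")
        return conv(v)
    except ValueError as e:
        raise ModelParseError(
            f"line {el.sourceline}: bad value '{v}' for '{name}'") from e


def _fmt_assigns(d: dict[str, bool]) -> str:
    return ",".join(f"{k}={_fmt(v)}" for k, v in d.items())


def _parse_assigns(text: str | None) -> dict[str, bool]:
    out: dict[str, bool] = {}
    if not text:
        return out
    for part in text.split(","):
        name, _, val = part.partition("=")
        out[name.strip()] = val.strip().lower() in ("1", "true", "yes")
    return out


def _pattern_el(tag: str, pat: SpeciesPattern) -> etree._Element:
    el = etree.Element(tag, species=pat.species)
    if pat.sites:
        el.set("sites", _fmt_assigns(pat.sites))
    if pat.states:
        el.set("states", _fmt_assigns(pat.states))
    return el


def _parse_pattern(el) -> SpeciesPattern:
    return SpeciesPattern(
        species=_get(el, "species", required=True),
        sites=_parse_assigns(el.get("sites")),
        states=_parse_assigns(el.get("states")))


def _voxel_el(parent, v) -> None:
    etree.SubElement(parent, "voxel", i=str(v[0]), j=str(v[1]),
                     k=str(v[2]))


def _parse_voxel(el) -> tuple[int, int, int]:
    return (_get(el, "i", int, required=True),
            _get(el, "j", int, required=True),
            _get(el, "k", int, required=True))


# ---------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------

def write_model(model: ModelSpec) -> str:
    """Serialize a model to dialect XML (deterministic element order)."""
    root = etree.Element(ROOT_TAG)
    env = model.environment
    etree.SubElement(
        root, "environment", nx=str(env.nx), ny=str(env.ny),
        nz=str(env.nz), voxel_len=_fmt(float(env.voxel_len)),
        timestep=_fmt(float(env.timestep)), n_steps=str(env.n_steps),
        seed=str(model.seed))
    if model.compartments:
        comps = etree.SubElement(root, "compartments")
        for c in model.compartments:
            el = etree.SubElement(comps, "compartment", name=c.name)
            if c.parent is not None:
                el.set("parent", c.parent)
            if c.membrane_2d:
                el.set("membrane_2d", "true")
            for b in c.boxes:
                etree.SubElement(el, "box", x0=str(b.x0), x1=str(b.x1),
                                 y0=str(b.y0), y1=str(b.y1),
                                 z0=str(b.z0), z1=str(b.z1))
            for v in c.voxels:
                _voxel_el(el, v)
    for s in model.species:
        el = etree.SubElement(root, "species", name=s.name, kind=s.kind,
                              D=_fmt(float(s.D)))
        if s.membrane_bound:
            el.set("membrane_bound", "true")
        for site in s.sites:
            etree.SubElement(el, "site", name=site)
        for st in s.states:
            etree.SubElement(el, "state", name=st)
        for comp in s.allowed_compartments:
            etree.SubElement(el, "allowed", compartment=comp)
    if model.reactions:
        rxns = etree.SubElement(root, "reactions")
        for r in model.reactions:
            el = etree.SubElement(rxns, "reaction", id=r.rule_id,
                                  k=_fmt(float(r.k)))
            if r.reversible:
                el.set("reversible", "true")
                el.set("k_rev", _fmt(float(r.k_rev)))
            if r.compartments:
                el.set("compartments", ",".join(r.compartments))
            for pat in r.reactants:
                el.append(_pattern_el("reactant", pat))
            for pat in r.products:
                el.append(_pattern_el("product", pat))
    if model.transports:
        trs = etree.SubElement(root, "transports")
        for t in model.transports:
            el = _pattern_el("transport", t.pattern)
            el.set("id", t.rule_id)
            el.set("from", t.from_compartment)
            el.set("to", t.to_compartment)
            el.set("prob", _fmt(float(t.prob_per_step)))
            if t.blocked_by_state is not None:
                el.set("blocked_by", t.blocked_by_state)
            trs.append(el)
    if model.immobilizations:
        ims = etree.SubElement(root, "immobilizations")
        for im in model.immobilizations:
            el = _pattern_el("immobilization", im.pattern)
            el.set("id", im.rule_id)
            el.set("k_on", _fmt(float(im.k_on)))
            el.set("k_off", _fmt(float(im.k_off)))
            if im.compartments:
                el.set("compartments", ",".join(im.compartments))
            ims.append(el)
    if model.sources_sinks:
        srcs = etree.SubElement(root, "sources")
        for s2 in model.sources_sinks:
            el = etree.SubElement(srcs, "source", species=s2.species,
                                  mode=s2.mode, value=_fmt(float(s2.value)))
            for v in s2.voxels:
                _voxel_el(el, v)
    if model.microdomains:
        doms = etree.SubElement(root, "microdomains")
        for d in model.microdomains:
            el = etree.SubElement(doms, "domain", name=d.name)
            for v in d.voxels:
                _voxel_el(el, v)
            for sp, bias in d.partition.items():
                etree.SubElement(el, "partition", species=sp,
                                 entry=_fmt(float(bias.entry_bias)),
                                 exit=_fmt(float(bias.exit_bias)))
    for ic in model.initial_conditions:
        el = etree.SubElement(root, "initial", species=ic.species,
                              amount=ic.amount, value=_fmt(float(ic.value)))
        if ic.compartment is not None:
            el.set("compartment", ic.compartment)
        if ic.microdomain is not None:
            el.set("microdomain", ic.microdomain)
    out = model.output
    if out.log_interval != 1 or out.particle_log:
        etree.SubElement(root, "output",
                         log_interval=str(out.log_interval),
                         particle_log=_fmt(out.particle_log))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------

def parse_model(xml_text: str | bytes) -> ModelSpec:
    """Parse dialect XML into a fully validated :class:`ModelSpec`.

    Omitted optional sections receive defaults (no sources/microdomains,
    log interval 1, particle log off, seed 0).  Raises
    :class:`ModelParseError` for malformed XML (naming the line) and
    :class:`~mesocell.model.ValidationError` for semantic violations.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode()
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as e:
        raise ModelParseError(f"malformed XML: {e}") from e
    if root.tag != ROOT_TAG:
        raise ModelParseError(
            f"line {root.sourceline}: root element must be <{ROOT_TAG}>, "
            f"got <{root.tag}>")
    env_el = root.find("environment")
    if env_el is None:
        raise ModelParseError("missing <environment> element")
    env = EnvironmentSpec(
        nx=_get(env_el, "nx", int, required=True),
        ny=_get(env_el, "ny", int, required=True),
        nz=_get(env_el, "nz", int, required=True),
        voxel_len=_get(env_el, "voxel_len", float, required=True),
        timestep=_get(env_el, "timestep", float, required=True),
        n_steps=_get(env_el, "n_steps", int, required=True))
    model = ModelSpec(environment=env,
                      seed=_get(env_el, "seed", int, default=0))

    for c_el in root.iterfind("compartments/compartment"):
        comp = CompartmentSpec(
            name=_get(c_el, "name", required=True),
            parent=c_el.get("parent"),
            membrane_2d=_get(c_el, "membrane_2d", bool, default=False))
        for b in c_el.iterfind("box"):
            comp.boxes.append(Box(*[_get(b, a, int, required=True)
                                    for a in ("x0", "x1", "y0", "y1",
                                              "z0", "z1")]))
        for v in c_el.iterfind("voxel"):
            comp.voxels.append(_parse_voxel(v))
        model.compartments.append(comp)

    for s_el in root.iterfind("species"):
        model.species.append(SpeciesDef(
            name=_get(s_el, "name", required=True),
            kind=_get(s_el, "kind", required=True),
            D=_get(s_el, "D", float, required=True),
            sites=[_get(e, "name", required=True)
                   for e in s_el.iterfind("site")],
            states=[_get(e, "name", required=True)
                    for e in s_el.iterfind("state")],
            allowed_compartments=[_get(e, "compartment", required=True)
                                  for e in s_el.iterfind("allowed")],
            membrane_bound=_get(s_el, "membrane_bound", bool,
                                default=False)))

    for r_el in root.iterfind("reactions/reaction"):
        comps_attr = r_el.get("compartments")
        model.reactions.append(ReactionRule(
            rule_id=_get(r_el, "id", required=True),
            reactants=[_parse_pattern(e)
                       for e in r_el.iterfind("reactant")],
            products=[_parse_pattern(e) for e in r_el.iterfind("product")],
            k=_get(r_el, "k", float, required=True),
            compartments=comps_attr.split(",") if comps_attr else [],
            reversible=_get(r_el, "reversible", bool, default=False),
            k_rev=_get(r_el, "k_rev", float, default=0.0)))

    for t_el in root.iterfind("transports/transport"):
        model.transports.append(TransportRule(
            rule_id=_get(t_el, "id", required=True),
            pattern=_parse_pattern(t_el),
            from_compartment=_get(t_el, "from", required=True),
            to_compartment=_get(t_el, "to", required=True),
            prob_per_step=_get(t_el, "prob", float, required=True),
            blocked_by_state=t_el.get("blocked_by")))

    for i_el in root.iterfind("immobilizations/immobilization"):
        comps_attr = i_el.get("compartments")
        model.immobilizations.append(ImmobilizationRule(
            rule_id=_get(i_el, "id", required=True),
            pattern=_parse_pattern(i_el),
            k_on=_get(i_el, "k_on", float, required=True),
            k_off=_get(i_el, "k_off", float, required=True),
            compartments=comps_attr.split(",") if comps_attr else []))

    for s_el in root.iterfind("sources/source"):
        model.sources_sinks.append(SourceSinkSpec(
            species=_get(s_el, "species", required=True),
            voxels=[_parse_voxel(v) for v in s_el.iterfind("voxel")],
            mode=_get(s_el, "mode", required=True),
            value=_get(s_el, "value", float, default=0.0)))

    for d_el in root.iterfind("microdomains/domain"):
        dom = MicrodomainSpec(name=_get(d_el, "name", required=True))
        for v in d_el.iterfind("voxel"):
            dom.voxels.append(_parse_voxel(v))
        for b in d_el.iterfind("box"):
            dom.voxels.extend(Box(*[_get(b, a, int, required=True)
                                    for a in ("x0", "x1", "y0", "y1",
                                              "z0", "z1")]).voxels())
        for p_el in d_el.iterfind("partition"):
            dom.partition[_get(p_el, "species", required=True)] = \
                PartitionBias(
                    entry_bias=_get(p_el, "entry", float, default=1.0),
                    exit_bias=_get(p_el, "exit", float, default=1.0))
        model.microdomains.append(dom)

    for i_el in root.iterfind("initial"):
        model.initial_conditions.append(InitialCondition(
            species=_get(i_el, "species", required=True),
            amount=_get(i_el, "amount", required=True),
            value=_get(i_el, "value", float, required=True),
            compartment=i_el.get("compartment"),
            microdomain=i_el.get("microdomain")))

    o_el = root.find("output")
    if o_el is not None:
        model.output = OutputConfig(
            log_interval=_get(o_el, "log_interval", int, default=1),
            particle_log=_get(o_el, "particle_log", bool, default=False))

    require_valid(model)
    return model
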