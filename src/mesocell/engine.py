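"""Timestep loop orchestration, logging and results.

Each timestep executes, in fixed order: (1) bulk-field diffusion, (2)
particle Brownian steps with reflection and microdomain partition biasing,
(3) reactions in the sub-order unimolecular -> bulk-particle ->
particle-particle -> bulk-bulk, (4) probabilistic transport events, (5)
immobilization events, (6) sources/sinks, (7) logging at the configured
interval.  A single RNG stream consumed in this fixed phase order makes
runs fully reproducible given (model, seed).

Particles are stored per species in struct-of-arrays form so that the
per-step kernels are vectorized; the scalar :class:`~mesocell.diffusion.
Particle` API remains available for single-molecule use.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import xmlio
from .diffusion import ConcentrationField, step_many
from .geometry import Lattice, voxels_of
from .model import (N_AVOGADRO, ModelSpec, ReactionRule, SpeciesDef,
                    SpeciesPattern, require_valid, voxel_volume_litres)
from .reactions import (BindingRadius, binding_radius, fire_probability,
                        match_pairs)

__all__ = ["Simulation", "SimulationResult", "run", "write_counts_tsv",
           "write_particle_log", "read_counts_tsv"]


class ParticleStore:
    """Struct-of-arrays particle container for one species."""

    def __init__(self, sdef: SpeciesDef):
        self.sdef = sdef
        ns, nf = len(sdef.sites), len(sdef.states)
        self.pos = np.empty((0, 3), dtype=float)
        self.sites = np.empty((0, ns), dtype=bool)
        self.states = np.empty((0, nf), dtype=bool)
        self.immobilized = np.empty(0, dtype=bool)
        self.frozen = np.empty(0, dtype=np.int8)
        self.ids = np.empty(0, dtype=np.int64)
        self._vox: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def invalidate_vox(self) -> None:
        self._vox = None

    def get_vox(self, lattice) -> np.ndarray:
        """Cached voxel indices of all particles (recomputed after any
        position change)."""
        if self._vox is None or self._vox.shape[0] != self.n:
            self._vox = voxels_of(self.pos, lattice)
        return self._vox

    def append(self, pos: np.ndarray, ids: np.ndarray,
               sites: np.ndarray | None = None,
               states: np.ndarray | None = None,
               frozen: np.ndarray | None = None) -> None:
        m = pos.shape[0]
        ns, nf = len(self.sdef.sites), len(self.sdef.states)
        self.pos = np.vstack([self.pos, pos])
        self.ids = np.concatenate([self.ids, ids])
        self.sites = np.vstack([
            self.sites,
            sites if sites is not None else np.zeros((m, ns), bool)])
        self.states = np.vstack([
            self.states,
            states if states is not None else np.zeros((m, nf), bool)])
        self.immobilized = np.concatenate(
            [self.immobilized, np.zeros(m, bool)])
        self.frozen = np.concatenate(
            [self.frozen,
             frozen if frozen is not None else np.full(m, -1, np.int8)])

    def remove(self, idx: np.ndarray) -> None:
        keep = np.ones(self.n, dtype=bool)
        keep[idx] = False
        self.pos = self.pos[keep]
        self.sites = self.sites[keep]
        self.states = self.states[keep]
        self.immobilized = self.immobilized[keep]
        self.frozen = self.frozen[keep]
        self.ids = self.ids[keep]
        self._vox = None

    def match(self, pat: SpeciesPattern) -> np.ndarray:
        mask = None
        for s, want in pat.sites.items():
            c = self.sites[:, self.sdef.sites.index(s)] if want \
                else ~self.sites[:, self.sdef.sites.index(s)]
            mask = c if mask is None else mask & c
        for s, want in pat.states.items():
            c = self.states[:, self.sdef.states.index(s)] if want \
                else ~self.states[:, self.sdef.states.index(s)]
            mask = c if mask is None else mask & c
        if mask is None:
            return np.ones(self.n, dtype=bool)
        return mask

    def apply_pattern(self, rows: np.ndarray, pat: SpeciesPattern) -> None:
        for s, v in pat.sites.items():
            self.sites[rows, self.sdef.sites.index(s)] = v
        for s, v in pat.states.items():
            self.states[rows, self.sdef.states.index(s)] = v

    def bound_counts(self) -> np.ndarray:
        return self.sites.sum(axis=1)


@dataclass
class _CompiledReaction:
    rule: ReactionRule
    kind: str  # "uni_particle" | "uni_bulk" | "bulk_particle" |
    #            "particle_particle" | "bulk_bulk"
    comp_ids: np.ndarray | None  # None = everywhere
    radii: BindingRadius | None = None


@dataclass
class SimulationResult:
    """Counts table (and optional per-compartment counts / particle log)
    of one run, plus the final engine state."""

    counts: pd.DataFrame
    seed: int
    model_hash: str
    compartment_counts: pd.DataFrame | None = None
    particle_log: pd.DataFrame | None = None
    event_totals: dict[str, int] = field(default_factory=dict)
    final: "Simulation | None" = None


class Simulation:
    """Compiled, runnable state of one model."""

    def __init__(self, model: ModelSpec, seed: int | None = None,
                 sigma_u_factor: float = 1.0,
                 compartment_counts: bool = False,
                 phase_hook=None):
        require_valid(model)
        self.model = model
        self.lattice = Lattice.from_model(model)
        env = model.environment
        self.dt = env.timestep
        self.h = env.voxel_len
        self.v_litres = voxel_volume_litres(self.h)
        self.seed = model.seed if seed is None else int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.step_index = 0
        self.phase_hook = phase_hook
        self.compartment_counts = compartment_counts
        self._next_id = 0

        self.species = model.species_by_name()
        self.fields: dict[str, ConcentrationField] = {}
        self.parts: dict[str, ParticleStore] = {}
        self.access: dict[str, np.ndarray] = {}
        for sdef in model.species:
            self.access[sdef.name] = self.lattice.accessibility_mask(sdef)
            if sdef.kind == "bulk":
                self.fields[sdef.name] = ConcentrationField(
                    sdef.name, np.zeros(env.dims, dtype=float))
            else:
                self.parts[sdef.name] = ParticleStore(sdef)

        self._compile_reactions(sigma_u_factor)
        self._compile_partition()
        self._immob_columns = {im.pattern.species
                               for im in model.immobilizations}
        self._place_initial()
        self._columns = self._count_columns()

    # ------------------------------------------------------------------
    # setup
    # ------------------------------------------------------------------

    def _comp_ids(self, names: list[str]) -> np.ndarray | None:
        if not names:
            return None
        return np.array([self.lattice.compartment_names.index(n)
                         for n in names if n in
                         self.lattice.compartment_names])

    def _compile_reactions(self, sigma_u_factor: float) -> None:
        rules: list[ReactionRule] = []
        for r in self.model.reactions:
            rules.append(r)
            if r.reversible and r.k_rev > 0:
                rules.append(ReactionRule(
                    r.rule_id + "__rev", reactants=list(r.products),
                    products=list(r.reactants), k=r.k_rev,
                    compartments=list(r.compartments)))
        self.compiled: list[_CompiledReaction] = []
        fwd_radii: dict[str, BindingRadius] = {}
        for r in rules:
            if r.k <= 0:
                continue
            kinds = [self.species[p.species].kind for p in r.reactants]
            comp_ids = self._comp_ids(r.compartments)
            if len(kinds) == 1:
                kind = "uni_bulk" if kinds[0] == "bulk" else "uni_particle"
                # a reverse dissociation inherits the forward rule's
                # unbinding radius for product placement
                radii = fwd_radii.get(r.rule_id.removesuffix("__rev"))
                self.compiled.append(
                    _CompiledReaction(r, kind, comp_ids, radii))
                continue
            if kinds.count("particle") == 2:
                d_sum = sum(self.species[p.species].D for p in r.reactants)
                radii = binding_radius(r.k, d_sum, self.dt, r.rule_id,
                                       sigma_u_factor)
                fwd_radii[r.rule_id] = radii
                self.compiled.append(_CompiledReaction(
                    r, "particle_particle", comp_ids, radii))
            elif kinds.count("bulk") == 1:
                self.compiled.append(
                    _CompiledReaction(r, "bulk_particle", comp_ids))
            else:
                self.compiled.append(
                    _CompiledReaction(r, "bulk_bulk", comp_ids))
        order = {"uni_particle": 0, "uni_bulk": 0, "bulk_particle": 1,
                 "particle_particle": 2, "bulk_bulk": 3}
        self.compiled.sort(key=lambda c: order[c.kind])
        self.event_totals: dict[str, int] = {c.rule.rule_id: 0
                                             for c in self.compiled}

    def _compile_partition(self) -> None:
        """Per-species entry/exit bias lookup tables indexed by
        microdomain id (0 = outside any domain -> bias 1)."""
        nd = len(self.lattice.microdomain_names)
        self.part_entry: dict[str, np.ndarray] = {}
        self.part_exit: dict[str, np.ndarray] = {}
        for dom_i, dom in enumerate(self.model.microdomains):
            for sp, bias in dom.partition.items():
                e = self.part_entry.setdefault(sp, np.ones(nd + 1))
                x = self.part_exit.setdefault(sp, np.ones(nd + 1))
                did = self.lattice.microdomain_names.index(dom.name) + 1
                e[did] = bias.entry_bias
                x[did] = bias.exit_bias
        # species whose biases are all 1 cross freely: drop them so the
        # partition check consumes no randomness (all-unit biases must
        # leave trajectories identical to a domain-free run)
        trivial = [sp for sp in self.part_entry
                   if np.all(self.part_entry[sp] == 1.0)
                   and np.all(self.part_exit[sp] == 1.0)]
        for sp in trivial:
            del self.part_entry[sp]
            del self.part_exit[sp]

    def _accessible_voxels(self, species_name: str,
                           compartment: str | None) -> np.ndarray:
        cache = getattr(self, "_dest_cache", None)
        if cache is None:
            cache = self._dest_cache = {}
        key = (species_name, compartment)
        if key in cache:
            return cache[key]
        acc = self.access[species_name]
        if compartment is not None:
            cid = self.lattice.compartment_names.index(compartment)
            acc = acc & (self.lattice.compartment_id == cid)
        vox = np.argwhere(acc)
        if len(vox) == 0:
            raise ValueError(
                f"no accessible voxel for '{species_name}' in "
                f"'{compartment}'")
        cache[key] = vox
        return vox

    def _place_initial(self) -> None:
        for ic in self.model.initial_conditions:
            sdef = self.species[ic.species]
            vox = self._accessible_voxels(ic.species, ic.compartment)
            if ic.microdomain is not None:
                did = self.lattice.microdomain_names.index(
                    ic.microdomain) + 1
                keep = self.lattice.microdomain_id[
                    vox[:, 0], vox[:, 1], vox[:, 2]] == did
                vox = vox[keep]
                if len(vox) == 0:
                    raise ValueError(
                        f"initial placement: microdomain "
                        f"'{ic.microdomain}' has no accessible voxel for "
                        f"'{ic.species}'")
            if sdef.kind == "bulk":
                f = self.fields[ic.species]
                if ic.amount == "concentration":
                    per_vox = ic.value * N_AVOGADRO * self.v_litres
                else:
                    per_vox = ic.value / len(vox)
                f.amounts[vox[:, 0], vox[:, 1], vox[:, 2]] += per_vox
                continue
            if ic.amount == "concentration":
                n = int(round(ic.value * N_AVOGADRO
                              * self.v_litres * len(vox)))
            else:
                n = int(round(ic.value))
            if n == 0:
                continue
            choice = self.rng.integers(len(vox), size=n)
            pos = (vox[choice] + self.rng.random((n, 3))) * self.h
            ids = np.arange(self._next_id, self._next_id + n)
            self._next_id += n
            frozen = self._frozen_for(sdef, pos)
            pos = self._anchor_membrane(sdef, pos, frozen)
            self.parts[ic.species].append(pos, ids, frozen=frozen)

    def _frozen_for(self, sdef: SpeciesDef, pos: np.ndarray) -> np.ndarray:
        if not sdef.membrane_bound or pos.shape[0] == 0:
            return np.full(pos.shape[0], -1, np.int8)
        vox = voxels_of(pos, self.lattice)
        return self.lattice.frozen_axis[vox[:, 0], vox[:, 1], vox[:, 2]]

    #: membrane particles anchor this fraction of a voxel edge inward of
    #: the membrane layer's inner face (the cytosol-facing surface),
    #: matching the physical picture of receptors on the membrane surface
    #: and keeping them within reach of partners in the adjacent layer.
    MEMBRANE_ANCHOR_DEPTH = 0.005

    def _anchor_membrane(self, sdef: SpeciesDef, pos: np.ndarray,
                         frozen: np.ndarray) -> np.ndarray:
        """Pin the frozen-axis coordinate of membrane-bound particles to
        the inner face of their membrane voxel."""
        if not sdef.membrane_bound or pos.shape[0] == 0:
            return pos
        vox = voxels_of(pos, self.lattice)
        eps = self.MEMBRANE_ANCHOR_DEPTH * self.h
        for ax in range(3):
            sel = frozen == ax
            if not sel.any():
                continue
            on_min = vox[sel, ax] == 0
            lo = vox[sel, ax] * self.h
            pos[sel, ax] = np.where(on_min, lo + self.h - eps, lo + eps)
        return pos

    # ------------------------------------------------------------------
    # per-step phases
    # ------------------------------------------------------------------

    def _hook(self, phase: str) -> None:
        if self.phase_hook is not None:
            self.phase_hook(phase, self)

    def _bulk_stencil(self, sdef: SpeciesDef):
        """Cached per-axis open-face masks and slices for one species."""
        cached = getattr(self, "_bulk_cache", None)
        if cached is None:
            cached = self._bulk_cache = {}
        if sdef.name not in cached:
            acc = self.access[sdef.name]
            parts = []
            for axis in range(3):
                lo = [slice(None)] * 3
                hi = [slice(None)] * 3
                lo[axis] = slice(None, -1)
                hi[axis] = slice(1, None)
                lo_t, hi_t = tuple(lo), tuple(hi)
                parts.append((lo_t, hi_t,
                              (acc[lo_t] & acc[hi_t]).astype(float)))
            cached[sdef.name] = parts
        return cached[sdef.name]

    def _phase_bulk_diffusion(self) -> None:
        for sdef in self.model.species:
            if sdef.kind != "bulk" or sdef.D == 0:
                continue
            f = self.fields[sdef.name]
            coef = sdef.D * self.dt / self.h ** 2
            N = f.amounts
            out = N.copy()
            for lo_t, hi_t, open_face in self._bulk_stencil(sdef):
                flux = coef * (N[hi_t] - N[lo_t])
                flux *= open_face
                out[lo_t] += flux
                out[hi_t] -= flux
            f.amounts = out

    def _phase_particle_diffusion(self) -> None:
        for sdef in self.model.species:
            if sdef.kind != "particle":
                continue
            store = self.parts[sdef.name]
            if store.n == 0 or sdef.D == 0:
                continue
            old = store.pos.copy()
            old_vox = store.get_vox(self.lattice)
            new = step_many(store.pos, sdef.D, self.dt, self.rng,
                            self.lattice, self.access[sdef.name],
                            frozen_axis=store.frozen,
                            mobile=~store.immobilized)
            new = self._apply_partition(sdef.name, old, new,
                                        old_vox=old_vox)
            store.pos = new
            store.invalidate_vox()

    def _apply_partition(self, name: str, old: np.ndarray,
                         new: np.ndarray,
                         old_vox: np.ndarray | None = None) -> np.ndarray:
        entry = self.part_entry.get(name)
        if entry is None:
            return new
        exit_ = self.part_exit[name]
        mdid = self.lattice.microdomain_id
        vox_old = old_vox if old_vox is not None \
            else voxels_of(old, self.lattice)
        md_old = mdid[vox_old[:, 0], vox_old[:, 1], vox_old[:, 2]]
        vox_new = voxels_of(new, self.lattice)
        md_new = mdid[vox_new[:, 0], vox_new[:, 1], vox_new[:, 2]]
        changed = np.where(md_new != md_old)[0]
        if changed.size == 0:
            return new
        u = self.rng.random((changed.size, 2))
        ok = (u[:, 0] < entry[md_new[changed]]) \
            & (u[:, 1] < exit_[md_old[changed]])
        denied = changed[~ok]
        if denied.size == 0:
            return new
        # reflect denied crossings at the voxel boundary plane(s)
        p = new[denied].copy()
        for axis in range(3):
            up = vox_new[denied, axis] > vox_old[denied, axis]
            dn = vox_new[denied, axis] < vox_old[denied, axis]
            plane_up = (vox_old[denied, axis] + 1) * self.h
            plane_dn = vox_old[denied, axis] * self.h
            p[:, axis] = np.where(up, 2 * plane_up - p[:, axis],
                                  p[:, axis])
            p[:, axis] = np.where(dn, 2 * plane_dn - p[:, axis],
                                  p[:, axis])
        # accept the reflected position only if it restores the original
        # domain and remains accessible; otherwise stay at the old point
        vox_r = voxels_of(p, self.lattice)
        in_bounds = np.all((p >= 0) & (p < self.lattice.extent), axis=1)
        md_r = mdid[vox_r[:, 0], vox_r[:, 1], vox_r[:, 2]]
        acc = self.access[name][vox_r[:, 0], vox_r[:, 1], vox_r[:, 2]]
        good = in_bounds & (md_r == md_old[denied]) & acc
        new[denied[good]] = p[good]
        new[denied[~good]] = old[denied[~good]]
        return new

    # -- reactions ------------------------------------------------------

    def _scope_mask(self, comp_ids: np.ndarray | None,
                    vox: np.ndarray) -> np.ndarray:
        if comp_ids is None:
            return np.ones(vox.shape[0], dtype=bool)
        lut = np.zeros(len(self.lattice.compartment_names), dtype=bool)
        lut[comp_ids] = True
        cid = self.lattice.compartment_id[vox[:, 0], vox[:, 1], vox[:, 2]]
        return lut[cid]

    def _voxel_scope(self, comp_ids: np.ndarray | None) -> np.ndarray:
        if comp_ids is None:
            return np.ones(self.lattice.dims, dtype=bool)
        return np.isin(self.lattice.compartment_id, comp_ids)

    def _new_ids(self, n: int) -> np.ndarray:
        ids = np.arange(self._next_id, self._next_id + n)
        self._next_id += n
        return ids

    def _emit_products(self, rule: ReactionRule, anchors: np.ndarray,
                       consumed: dict[str, np.ndarray],
                       separation: float = 0.0) -> None:
        """Create product particles / bulk increments for ``len(anchors)``
        firings.  A product pattern whose species matches a consumed
        reactant species reuses those particles (catalyst / state-change
        semantics); other particle products are new particles at the
        anchor, additional ones offset by ``separation``; bulk products
        add one molecule per firing at the anchor voxel."""
        m = anchors.shape[0]
        pool = dict(consumed)  # species -> row indices, reused at most once
        n_new_at_anchor = 0
        for pat in rule.products:
            sdef = self.species[pat.species]
            if sdef.kind == "bulk":
                vox = voxels_of(anchors, self.lattice)
                np.add.at(self.fields[pat.species].amounts,
                          (vox[:, 0], vox[:, 1], vox[:, 2]), 1.0)
                continue
            rows = pool.pop(pat.species, None)
            if rows is not None:
                self.parts[pat.species].apply_pattern(rows, pat)
                continue
            pos = anchors.copy()
            if n_new_at_anchor > 0 and separation > 0:
                d = self.rng.normal(size=(m, 3))
                d /= np.linalg.norm(d, axis=1, keepdims=True)
                pos = anchors + separation * d
            n_new_at_anchor += 1
            store = self.parts[pat.species]
            ns, nf = len(sdef.sites), len(sdef.states)
            sites = np.zeros((m, ns), bool)
            states = np.zeros((m, nf), bool)
            for s, v in pat.sites.items():
                sites[:, sdef.sites.index(s)] = v
            for s, v in pat.states.items():
                states[:, sdef.states.index(s)] = v
            # keep products in accessible voxels (reflected off anchors)
            from .diffusion import reflect_many
            pos = reflect_many(anchors.copy(), pos,
                               self.access[pat.species], self.lattice)
            frozen = self._frozen_for(sdef, pos)
            pos = self._anchor_membrane(sdef, pos, frozen)
            store.append(pos, self._new_ids(m), sites, states, frozen)

    def _react_uni_particle(self, c: _CompiledReaction) -> None:
        rule = c.rule
        pat = rule.reactants[0]
        store = self.parts[pat.species]
        if store.n == 0:
            return
        mask = store.match(pat)
        if c.comp_ids is not None:
            mask &= self._scope_mask(c.comp_ids,
                                     store.get_vox(self.lattice))
        cand = np.where(mask)[0]
        if cand.size == 0:
            return
        p = fire_probability(rule.k, self.dt)
        fired = cand[self.rng.random(cand.size) < p]
        if fired.size == 0:
            return
        self.event_totals[rule.rule_id] += fired.size
        anchors = store.pos[fired].copy()
        keeps_self = any(q.species == pat.species for q in rule.products)
        consumed = {pat.species: fired} if keeps_self else {}
        sigma_u = c.radii.sigma_u if c.radii is not None else 0.0
        self._emit_products(rule, anchors, consumed, sigma_u)
        if not keeps_self:
            store.remove(fired)

    def _react_uni_bulk(self, c: _CompiledReaction) -> None:
        rule = c.rule
        f = self.fields[rule.reactants[0].species]
        scope = self._voxel_scope(c.comp_ids)
        frac = fire_probability(rule.k, self.dt)
        converted = np.where(scope, f.amounts * frac, 0.0)
        f.amounts -= converted
        self.event_totals[rule.rule_id] += int(round(converted.sum()))
        for pat in rule.products:
            sdef = self.species[pat.species]
            if sdef.kind == "bulk":
                self.fields[pat.species].amounts += converted
            # particle products of a bulk conversion are not supported;
            # validation rejects such rules upstream

    def _react_bulk_particle(self, c: _CompiledReaction) -> None:
        rule = c.rule
        bulk_pat = next(p for p in rule.reactants
                        if self.species[p.species].kind == "bulk")
        part_pat = next(p for p in rule.reactants
                        if self.species[p.species].kind == "particle")
        store = self.parts[part_pat.species]
        if store.n == 0:
            return
        f = self.fields[bulk_pat.species]
        mask = store.match(part_pat)
        vox = store.get_vox(self.lattice)
        if c.comp_ids is not None:
            mask &= self._scope_mask(c.comp_ids, vox)
        cand = np.where(mask)[0]
        if cand.size == 0:
            return
        vc = vox[cand]
        amounts = f.amounts[vc[:, 0], vc[:, 1], vc[:, 2]]
        conc = amounts / (N_AVOGADRO * self.v_litres)
        prob = -np.expm1(-rule.k * conc * self.dt)
        fired = cand[self.rng.random(cand.size) < prob]
        if fired.size == 0:
            return
        # consume one molecule per firing; cancel firings the voxel
        # cannot supply (conservation before rate fidelity)
        vf = vox[fired]
        flat = np.ravel_multi_index((vf[:, 0], vf[:, 1], vf[:, 2]),
                                    self.lattice.dims)
        order = np.argsort(flat, kind="stable")
        ok = np.ones(fired.size, dtype=bool)
        flat_sorted = flat[order]
        amounts_flat = f.amounts.reshape(-1)
        start = 0
        while start < len(order):
            end = start
            while end < len(order) and flat_sorted[end] == \
                    flat_sorted[start]:
                end += 1
            avail = int(amounts_flat[flat_sorted[start]])
            for j in range(start, end):
                if j - start >= avail:
                    ok[order[j]] = False
            start = end
        fired = fired[ok]
        if fired.size == 0:
            return
        vf = vox[fired]
        np.add.at(f.amounts, (vf[:, 0], vf[:, 1], vf[:, 2]), -1.0)
        self.event_totals[rule.rule_id] += fired.size
        anchors = store.pos[fired].copy()
        keeps_self = any(q.species == part_pat.species
                         for q in rule.products)
        consumed = {part_pat.species: fired} if keeps_self else {}
        self._emit_products(rule, anchors, consumed)
        if not keeps_self:
            store.remove(fired)

    def _react_particle_particle(self, c: _CompiledReaction) -> None:
        rule = c.rule
        pat_a, pat_b = rule.reactants
        same = pat_a.species == pat_b.species
        store_a = self.parts[pat_a.species]
        store_b = self.parts[pat_b.species]
        # immobilized (trans-engaged) particles do not collide
        mask_a = store_a.match(pat_a) & ~store_a.immobilized
        mask_b = store_b.match(pat_b) & ~store_b.immobilized
        if c.comp_ids is not None:
            mask_a &= self._scope_mask(c.comp_ids,
                                       store_a.get_vox(self.lattice))
            mask_b &= self._scope_mask(c.comp_ids,
                                       store_b.get_vox(self.lattice))
        idx_a = np.where(mask_a)[0]
        idx_b = np.where(mask_b)[0]
        if same:
            both = np.where(mask_a | mask_b)[0]
            # a particle may serve as either reactant; matching handles
            # uniqueness
            if both.size < 2:
                return
            pairs = match_pairs(store_a.pos[both], store_a.pos[both],
                                c.radii.sigma_b, same_species=True)
            pairs = [(both[i], both[j]) for i, j in pairs
                     if (mask_a[both[i]] and mask_b[both[j]])
                     or (mask_a[both[j]] and mask_b[both[i]])]
        else:
            if idx_a.size == 0 or idx_b.size == 0:
                return
            raw = match_pairs(store_a.pos[idx_a], store_b.pos[idx_b],
                              c.radii.sigma_b)
            pairs = [(idx_a[i], idx_b[j]) for i, j in raw]
        if not pairs:
            return
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        self.event_totals[rule.rule_id] += len(pairs)
        anchors = 0.5 * (store_a.pos[ia] + store_b.pos[ib])
        # catalysts (species on both sides) persist; consumed reactants
        # are removed after product emission
        consumed: dict[str, np.ndarray] = {}
        prod_species = [q.species for q in rule.products]
        a_survives = pat_a.species in prod_species
        b_survives = (not same) and pat_b.species in prod_species
        if same and a_survives:
            consumed[pat_a.species] = ia  # one of the pair persists
        elif a_survives:
            consumed[pat_a.species] = ia
        if b_survives:
            consumed[pat_b.species] = ib
        # anchor products at the surviving reactant when one persists
        if a_survives and not b_survives and not same:
            anchors = store_b.pos[ib].copy()
        elif b_survives and not a_survives:
            anchors = store_a.pos[ia].copy()
        self._emit_products(rule, anchors, consumed, c.radii.sigma_u)
        if not a_survives:
            if same:
                store_a.remove(np.concatenate([ia, ib]))
            else:
                store_a.remove(ia)
                if not b_survives:
                    store_b.remove(ib)
        elif same:
            store_a.remove(ib)
        elif not b_survives:
            store_b.remove(ib)

    def _react_bulk_bulk(self, c: _CompiledReaction) -> None:
        rule = c.rule
        f_a = self.fields[rule.reactants[0].species]
        f_b = self.fields[rule.reactants[1].species]
        conv = N_AVOGADRO * self.v_litres
        dN = rule.k * (f_a.amounts / conv) * (f_b.amounts / conv) \
            * conv * self.dt
        scope = self._voxel_scope(c.comp_ids)
        same = f_a is f_b
        cap = f_a.amounts if same else np.minimum(f_a.amounts, f_b.amounts)
        dN = np.where(scope, np.minimum(dN, cap), 0.0)
        f_a.amounts -= dN
        if not same:
            f_b.amounts -= dN
        self.event_totals[rule.rule_id] += int(round(dN.sum()))
        for pat in rule.products:
            if self.species[pat.species].kind == "bulk":
                self.fields[pat.species].amounts += dN

    def _phase_reactions(self) -> None:
        dispatch = {"uni_particle": self._react_uni_particle,
                    "uni_bulk": self._react_uni_bulk,
                    "bulk_particle": self._react_bulk_particle,
                    "particle_particle": self._react_particle_particle,
                    "bulk_bulk": self._react_bulk_bulk}
        for c in self.compiled:
            dispatch[c.kind](c)

    # -- transport / immobilization / sources ---------------------------

    def _phase_transport(self) -> None:
        for tr in self.model.transports:
            store = self.parts[tr.pattern.species]
            if store.n == 0 or tr.prob_per_step == 0:
                continue
            sdef = store.sdef
            mask = store.match(tr.pattern) & ~store.immobilized
            if tr.blocked_by_state is not None:
                col = sdef.states.index(tr.blocked_by_state)
                mask &= ~store.states[:, col]
            vox = store.get_vox(self.lattice)
            cid = self.lattice.compartment_names.index(tr.from_compartment)
            comp = self.lattice.compartment_id[vox[:, 0], vox[:, 1],
                                               vox[:, 2]]
            mask &= comp == cid
            cand = np.where(mask)[0]
            if cand.size == 0:
                continue
            moved = cand[self.rng.random(cand.size) < tr.prob_per_step]
            if moved.size == 0:
                continue
            dest = self._accessible_voxels(sdef.name, tr.to_compartment)
            choice = self.rng.integers(len(dest), size=moved.size)
            pos = (dest[choice] + self.rng.random((moved.size, 3))) \
                * self.h
            frozen = self._frozen_for(sdef, pos)
            pos = self._anchor_membrane(sdef, pos, frozen)
            store.pos[moved] = pos
            store.frozen[moved] = frozen
            store.invalidate_vox()

    def _phase_immobilization(self) -> None:
        for im in self.model.immobilizations:
            store = self.parts[im.pattern.species]
            if store.n == 0:
                continue
            mask = store.match(im.pattern)
            if im.compartments:
                mask &= self._scope_mask(self._comp_ids(im.compartments),
                                         store.get_vox(self.lattice))
            cand = np.where(mask)[0]
            if cand.size == 0:
                continue
            u = self.rng.random(cand.size)
            mob = ~store.immobilized[cand]
            p_on = fire_probability(im.k_on, self.dt)
            p_off = fire_probability(im.k_off, self.dt)
            flip_on = cand[mob & (u < p_on)]
            flip_off = cand[~mob & (u < p_off)]
            store.immobilized[flip_on] = True
            store.immobilized[flip_off] = False

    def _phase_sources_sinks(self) -> None:
        for spec in self.model.sources_sinks:
            f = self.fields[spec.species]
            if not spec.voxels:
                continue
            idx = np.asarray(spec.voxels, dtype=np.intp)
            sel = (idx[:, 0], idx[:, 1], idx[:, 2])
            if spec.mode == "clamp":
                f.amounts[sel] = spec.value * N_AVOGADRO * self.v_litres
            elif spec.mode == "influx":
                f.amounts[sel] += spec.value
            elif spec.mode == "absorb":
                f.amounts[sel] = 0.0

    # ------------------------------------------------------------------
    # stepping and logging
    # ------------------------------------------------------------------

    def step(self) -> None:
        self._hook("pre_step")
        self._phase_bulk_diffusion()
        self._phase_particle_diffusion()
        self._hook("post_diffusion")
        self._phase_reactions()
        self._hook("post_reactions")
        self._phase_transport()
        self._phase_immobilization()
        self._phase_sources_sinks()
        self.step_index += 1

    @property
    def time(self) -> float:
        return self.step_index * self.dt

    def _count_columns(self) -> list[str]:
        cols: list[str] = []
        for sdef in self.model.species:
            cols.append(sdef.name)
            if sdef.kind == "particle":
                for k in range(len(sdef.sites) + 1):
                    if sdef.sites:
                        cols.append(f"{sdef.name}:bound{k}")
                for st in sdef.states:
                    cols.append(f"{sdef.name}:{st}")
                if sdef.name in self._immob_columns:
                    cols.append(f"{sdef.name}:immobilized")
        return cols

    def _count_row(self) -> list[float]:
        row: list[float] = []
        for sdef in self.model.species:
            if sdef.kind == "bulk":
                row.append(self.fields[sdef.name].total())
                continue
            store = self.parts[sdef.name]
            row.append(store.n)
            if sdef.sites:
                bc = store.bound_counts()
                for k in range(len(sdef.sites) + 1):
                    row.append(int((bc == k).sum()))
            for j in range(len(sdef.states)):
                row.append(int(store.states[:, j].sum()))
            if sdef.name in self._immob_columns:
                row.append(int(store.immobilized.sum()))
        return row

    def _compartment_row(self) -> list[float]:
        row: list[float] = []
        for comp in self.lattice.compartment_names:
            cid = self.lattice.compartment_names.index(comp)
            cmask = self.lattice.compartment_id == cid
            for sdef in self.model.species:
                if sdef.kind == "bulk":
                    row.append(float(
                        self.fields[sdef.name].amounts[cmask].sum()))
                    continue
                store = self.parts[sdef.name]
                if store.n == 0:
                    row.extend([0] * (1 + (len(sdef.sites) + 1
                                           if sdef.sites else 0)))
                    continue
                vox = voxels_of(store.pos, self.lattice)
                inside = cmask[vox[:, 0], vox[:, 1], vox[:, 2]]
                row.append(int(inside.sum()))
                if sdef.sites:
                    bc = store.bound_counts()[inside]
                    for k in range(len(sdef.sites) + 1):
                        row.append(int((bc == k).sum()))
        return row

    def _compartment_columns(self) -> list[str]:
        cols = []
        for comp in self.lattice.compartment_names:
            for sdef in self.model.species:
                cols.append(f"{comp}/{sdef.name}")
                if sdef.kind == "particle" and sdef.sites:
                    for k in range(len(sdef.sites) + 1):
                        cols.append(f"{comp}/{sdef.name}:bound{k}")
        return cols

    def _particle_rows(self) -> list[tuple]:
        rows = []
        for sdef in self.model.species:
            if sdef.kind != "particle":
                continue
            store = self.parts[sdef.name]
            if store.n == 0:
                continue
            vox = voxels_of(store.pos, self.lattice)
            for i in range(store.n):
                tokens = [s for j, s in enumerate(sdef.sites)
                          if store.sites[i, j]]
                tokens += [s for j, s in enumerate(sdef.states)
                           if store.states[i, j]]
                rows.append((
                    self.step_index, int(store.ids[i]), sdef.name,
                    ",".join(tokens) if tokens else "-",
                    store.pos[i, 0], store.pos[i, 1], store.pos[i, 2],
                    self.lattice.compartment_names[
                        self.lattice.compartment_id[tuple(vox[i])]],
                    bool(store.immobilized[i])))
        return rows

    def _check_finite(self) -> None:
        for name, f in self.fields.items():
            if not np.all(np.isfinite(f.amounts)):
                raise RuntimeError(
                    f"non-finite bulk amount for '{name}' at step "
                    f"{self.step_index}")

    def run(self, n_steps: int | None = None,
            log_interval: int | None = None,
            particle_log: bool | None = None) -> SimulationResult:
        env = self.model.environment
        n_steps = env.n_steps if n_steps is None else int(n_steps)
        out = self.model.output
        interval = out.log_interval if log_interval is None \
            else int(log_interval)
        plog_on = out.particle_log if particle_log is None \
            else bool(particle_log)

        rows = [[0, 0.0] + self._count_row()]
        comp_rows = [[0, 0.0] + self._compartment_row()] \
            if self.compartment_counts else None
        plog: list[tuple] = self._particle_rows() if plog_on else []
        for i in range(1, n_steps + 1):
            self.step()
            if i % interval == 0:
                rows.append([self.step_index, self.time]
                            + self._count_row())
                if comp_rows is not None:
                    comp_rows.append([self.step_index, self.time]
                                     + self._compartment_row())
                if plog_on:
                    plog.extend(self._particle_rows())
                self._check_finite()
        counts = pd.DataFrame(rows, columns=["step", "time_s"]
                              + self._columns)
        counts["step"] = counts["step"].astype(int)
        comp_df = None
        if comp_rows is not None:
            comp_df = pd.DataFrame(
                comp_rows, columns=["step", "time_s"]
                + self._compartment_columns())
        plog_df = None
        if plog_on:
            plog_df = pd.DataFrame(
                plog, columns=["step", "particle_id", "species", "state",
                               "x_um", "y_um", "z_um", "compartment",
                               "immobilized"])
        return SimulationResult(
            counts=counts, seed=self.seed,
            model_hash=model_hash(self.model),
            compartment_counts=comp_df, particle_log=plog_df,
            event_totals=dict(self.event_totals), final=self)


def model_hash(model: ModelSpec) -> str:
    return hashlib.sha256(
        xmlio.write_model(model).encode()).hexdigest()[:16]


def run(model: ModelSpec, seed: int | None = None,
        n_steps: int | None = None, log_interval: int | None = None,
        particle_log: bool | None = None,
        compartment_counts: bool = False,
        phase_hook=None) -> SimulationResult:
    """Validate, compile and run a model; see :class:`Simulation`."""
    sim = Simulation(model, seed=seed,
                     compartment_counts=compartment_counts,
                     phase_hook=phase_hook)
    return sim.run(n_steps=n_steps, log_interval=log_interval,
                   particle_log=particle_log)


def write_counts_tsv(result: SimulationResult, path) -> None:
    """Write the counts table as TSV: ``step  time_s  <species[:state]>``
    columns, bulk amounts as reals, particle counts as integers."""
    df = result.counts.copy()
    for col in df.columns:
        if col != "time_s" and pd.api.types.is_integer_dtype(df[col]):
            df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_particle_log(result: SimulationResult, path) -> None:
    if result.particle_log is None:
        raise ValueError("particle logging was not enabled for this run")
    result.particle_log.to_csv(path, sep="\t", index=False)
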