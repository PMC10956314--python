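"""C-voxel lattice: compartment membership, neighbor topology,
accessibility and membrane-surface frames.

The simulation space is a box of ``dims * h`` um per axis, discretised into
cubic voxels of edge ``h``.  Continuous positions live in the half-open box
``[0, extent)`` per axis; ``voxel_of`` maps a position to its 0-based voxel
index by flooring.  Bulk diffusion and compartment geometry use the
6-neighborhood (face adjacency).
"""

from __future__ import annotations

import numpy as np

from .model import (DEFAULT_COMPARTMENT, ModelSpec, SpeciesDef,
                    require_valid)

_AXES = "xyz"


class Lattice:
    """Voxel grid with per-voxel compartment and microdomain membership.

    ``compartment_id`` and ``microdomain_id`` are int arrays of shape
    ``dims``; names are looked up through ``compartment_names`` /
    ``microdomain_names`` (index 0 of microdomains means "none").
    """

    def __init__(self, dims: tuple[int, int, int], voxel_len: float):
        self.dims = tuple(int(d) for d in dims)
        self.h = float(voxel_len)
        self.extent = np.array([d * self.h for d in self.dims])
        self._inv_h = 1.0 / self.h
        self._dims_minus1 = np.array(self.dims, dtype=np.intp) - 1
        self._extent_in = np.nextafter(self.extent, 0.0)
        self.compartment_names: list[str] = [DEFAULT_COMPARTMENT]
        self.compartment_id = np.zeros(self.dims, dtype=np.int32)
        self.microdomain_names: list[str] = []  # id 0 = none
        self.microdomain_id = np.zeros(self.dims, dtype=np.int32)
        self._membrane_comp_ids: set[int] = set()
        # frozen axis per voxel for membrane voxels (-1 elsewhere)
        self.frozen_axis = np.full(self.dims, -1, dtype=np.int8)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_model(cls, model: ModelSpec) -> "Lattice":
        require_valid(model)
        env = model.environment
        lat = cls(env.dims, env.voxel_len)
        for comp in model.compartments:
            cid = lat._add_compartment(comp.name)
            idx = np.array(sorted(comp.voxel_set()), dtype=np.intp)
            if idx.size:
                lat.compartment_id[idx[:, 0], idx[:, 1], idx[:, 2]] = cid
            if comp.membrane_2d:
                lat._membrane_comp_ids.add(cid)
        for dom in model.microdomains:
            lat.microdomain_names.append(dom.name)
            did = len(lat.microdomain_names)
            idx = np.array(sorted(set(dom.voxels)), dtype=np.intp)
            if idx.size:
                lat.microdomain_id[idx[:, 0], idx[:, 1], idx[:, 2]] = did
        lat._assign_frozen_axes()
        return lat

    def _add_compartment(self, name: str) -> int:
        if name in self.compartment_names:
            return self.compartment_names.index(name)
        self.compartment_names.append(name)
        return len(self.compartment_names) - 1

    def _assign_frozen_axes(self) -> None:
        """Outward-normal axis for membrane voxels, priority x -> y -> z
        for edge/corner voxels."""
        if not self._membrane_comp_ids:
            return
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny),
                                 np.arange(nz), indexing="ij")
        membrane = np.isin(self.compartment_id,
                           np.array(sorted(self._membrane_comp_ids)))
        on_x = (ii == 0) | (ii == nx - 1)
        on_y = (jj == 0) | (jj == ny - 1)
        on_z = (kk == 0) | (kk == nz - 1)
        self.frozen_axis[membrane & on_x] = 0
        self.frozen_axis[membrane & ~on_x & on_y] = 1
        self.frozen_axis[membrane & ~on_x & ~on_y & on_z] = 2

    # -- queries ----------------------------------------------------------

    def compartment_of(self, voxel: tuple[int, int, int]) -> str:
        return self.compartment_names[self.compartment_id[voxel]]

    def microdomain_of(self, voxel: tuple[int, int, int]) -> str | None:
        did = self.microdomain_id[voxel]
        return None if did == 0 else self.microdomain_names[did - 1]

    def is_membrane(self, voxel: tuple[int, int, int]) -> bool:
        return int(self.compartment_id[voxel]) in self._membrane_comp_ids

    def compartment_voxels(self, name: str) -> np.ndarray:
        """(n, 3) voxel indices belonging to compartment ``name``."""
        cid = self.compartment_names.index(name)
        return np.argwhere(self.compartment_id == cid)

    def accessibility_mask(self, species: SpeciesDef) -> np.ndarray:
        """Boolean array over voxels: True where ``species`` may reside."""
        allowed = np.zeros(len(self.compartment_names), dtype=bool)
        for name in species.allowed_compartments:
            if name in self.compartment_names:
                allowed[self.compartment_names.index(name)] = True
        return allowed[self.compartment_id]


def voxel_of(pos: np.ndarray, lattice: Lattice) -> tuple[int, int, int]:
    """Voxel index triple of a continuous position (floor convention).

    Raises ``ValueError`` for out-of-bounds positions.
    """
    pos = np.asarray(pos, dtype=float)
    if np.any(pos < 0) or np.any(pos >= lattice.extent):
        raise ValueError(f"position {pos} outside [0, {lattice.extent})")
    idx = np.floor(pos / lattice.h).astype(int)
    # guard against floating-point edge: pos just below a voxel boundary
    idx = np.minimum(idx, np.array(lattice.dims) - 1)
    return tuple(int(i) for i in idx)


def voxels_of(pos: np.ndarray, lattice: Lattice) -> np.ndarray:
    """Vectorized ``voxel_of`` for an (n, 3) position array (no bounds
    check; callers maintain the in-bounds invariant)."""
    idx = np.floor(pos * lattice._inv_h).astype(np.intp)
    np.minimum(idx, lattice._dims_minus1, out=idx)
    np.maximum(idx, 0, out=idx)
    return idx


def neighbors(voxel: tuple[int, int, int],
              lattice: Lattice) -> list[tuple[int, int, int]]:
    """The <= 6 face-adjacent in-bounds voxels."""
    if not all(0 <= voxel[a] < lattice.dims[a] for a in range(3)):
        raise ValueError(f"voxel {voxel} outside lattice {lattice.dims}")
    out = []
    for axis in range(3):
        for step in (-1, 1):
            nb = list(voxel)
            nb[axis] += step
            if 0 <= nb[axis] < lattice.dims[axis]:
                out.append(tuple(nb))
    return out


def is_accessible(species: SpeciesDef, voxel: tuple[int, int, int],
                  lattice: Lattice) -> bool:
    """True iff the voxel's compartment is allowed for the species."""
    return lattice.compartment_of(voxel) in species.allowed_compartments


def surface_frame(voxel: tuple[int, int, int], lattice: Lattice) -> int:
    """Frozen (outward-normal) axis index for a membrane voxel: 0=x, 1=y,
    2=z.  Edge/corner voxels resolve by priority x -> y -> z."""
    ax = int(lattice.frozen_axis[voxel])
    if ax < 0:
        raise ValueError(
            f"voxel {voxel} is not part of a membrane_2d compartment")
    return ax
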