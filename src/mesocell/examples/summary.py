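"""Post-run summary statistics for the built-in models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..model import N_AVOGADRO, ModelSpec, voxel_volume_litres
from ..engine import SimulationResult


@dataclass
class Summary:
    """Per-compartment time series and post-burn-in time averages.

    ``concentrations[(species, comp)]`` is the bulk concentration (mol/L)
    in that compartment over logged time; ``site_fractions[(species,
    comp)]`` the (t, n_sites+1) occupancy-level fractions of a
    site-carrying particle species; ``averages`` maps readable keys
    (e.g. ``"Ca[Q1]"``, ``"CaM:bound4[Q5]"``, ``"clustered"``) to window
    means.
    """

    time_s: np.ndarray
    concentrations: dict = field(default_factory=dict)
    site_fractions: dict = field(default_factory=dict)
    global_site_fractions: dict = field(default_factory=dict)
    clustered: np.ndarray | None = None
    surface: dict = field(default_factory=dict)
    averages: dict = field(default_factory=dict)


def summarize(result: SimulationResult, model: ModelSpec,
              burn_in_fraction: float = 0.5) -> Summary:
    """Compute per-compartment concentrations, site-occupancy fractions
    and clustered/surface counts, with time averages over the post
    burn-in window.

    Requires the run to have been made with ``compartment_counts=True``
    for the per-compartment series; raises if the averaging window is
    empty.
    """
    counts = result.counts
    t = counts["time_s"].to_numpy()
    window = t >= burn_in_fraction * t[-1]
    if not window.any():
        raise ValueError("empty averaging window")
    s = Summary(time_s=t)

    v_vox = voxel_volume_litres(model.environment.voxel_len)
    comp_sizes: dict[str, int] = {}
    for comp in model.compartments:
        comp_sizes[comp.name] = len(comp.voxel_set())

    # global site fractions per site-carrying particle species
    for sdef in model.species:
        if sdef.kind != "particle" or not sdef.sites:
            continue
        cols = [f"{sdef.name}:bound{k}"
                for k in range(len(sdef.sites) + 1)]
        raw = counts[cols].to_numpy(dtype=float)
        tot = raw.sum(axis=1)
        tot[tot == 0] = np.nan
        frac = raw / tot[:, None]
        s.global_site_fractions[sdef.name] = frac
        for k in range(len(sdef.sites) + 1):
            s.averages[f"{sdef.name}:bound{k}"] = float(
                np.nanmean(frac[window, k]))

    cc = result.compartment_counts
    if cc is not None:
        for comp_name, n_vox in comp_sizes.items():
            v_comp = n_vox * v_vox
            for sdef in model.species:
                if sdef.kind == "bulk":
                    col = f"{comp_name}/{sdef.name}"
                    conc = cc[col].to_numpy(dtype=float) \
                        / (N_AVOGADRO * v_comp)
                    s.concentrations[(sdef.name, comp_name)] = conc
                    s.averages[f"{sdef.name}[{comp_name}]"] = float(
                        conc[window].mean())
                elif sdef.sites:
                    cols = [f"{comp_name}/{sdef.name}:bound{k}"
                            for k in range(len(sdef.sites) + 1)]
                    raw = cc[cols].to_numpy(dtype=float)
                    tot = raw.sum(axis=1)
                    tot[tot == 0] = np.nan
                    frac = raw / tot[:, None]
                    s.site_fractions[(sdef.name, comp_name)] = frac
                    for k in range(len(sdef.sites) + 1):
                        s.averages[
                            f"{sdef.name}:bound{k}[{comp_name}]"] = \
                            float(np.nanmean(frac[window, k]))
                else:
                    col = f"{comp_name}/{sdef.name}"
                    series = cc[col].to_numpy(dtype=float)
                    s.surface[(sdef.name, comp_name)] = series
                    s.averages[f"{sdef.name}[{comp_name}]"] = float(
                        series[window].mean())

    immob_col = next((c for c in counts.columns
                      if c.endswith(":immobilized")), None)
    if immob_col is not None:
        s.clustered = counts[immob_col].to_numpy(dtype=float)
        s.averages["clustered"] = float(s.clustered[window].mean())
    return s
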