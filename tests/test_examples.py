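"""Built-in model systems: calmodulin cooperative binding, the quintile
microdomain geometry, CEACAM1 clustering, oracles and summaries."""

import numpy as np
import pytest

from mesocell import engine
from mesocell.model import N_AVOGADRO, validate_model
from mesocell.examples import (CalmodulinParams, CeacamParams,
                               MassActionReaction, SOURCE_LAYOUTS,
                               build_calmodulin_wellmixed,
                               build_ceacam1_model,
                               build_microdomain_model, cam_equilibrium,
                               cam_fractions_from_traj, cam_ode_initial,
                               calmodulin_network, load_default_rates,
                               ode_oracle, summarize)


@pytest.fixture(scope="module")
def rates():
    return load_default_rates()


class TestCalmodulinBuilder:
    def test_box_volume_is_half_femtolitre(self):
        p = CalmodulinParams()
        v = np.prod(p.dims) * p.voxel_len ** 3 * 1e-15
        assert v == pytest.approx(5.12e-16)
        assert float(f"{v:.0e}") == 5e-16  # one significant figure

    def test_particle_count_from_concentration(self):
        """2 uM calmodulin in 5.12e-16 L -> round(C*V*N_A) particles."""
        p = CalmodulinParams()
        sim = engine.Simulation(build_calmodulin_wellmixed(p), seed=1)
        v = np.prod(p.dims) * p.voxel_len ** 3 * 1e-15
        expected = round(p.cam_total * v * N_AVOGADRO)
        assert sim.parts["CaM"].n == expected == 617

    def test_zero_calcium_stays_fully_unloaded(self):
        p = CalmodulinParams(ca_total=0.0, n_steps=200, log_interval=200)
        res = engine.run(build_calmodulin_wellmixed(p), seed=1)
        assert (res.counts["CaM:bound0"] == 617).all()

    def test_negative_rate_constant_rejected(self):
        from mesocell.examples.calmodulin import LobeRates
        p = CalmodulinParams(
            n_lobe=LobeRates(-1.0, 1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            build_calmodulin_wellmixed(p)

    def test_association_constant_outside_range_warns(self):
        from mesocell.examples.calmodulin import LobeRates
        p = CalmodulinParams(
            c_lobe=LobeRates(1e5, 1.0, 1e8, 1.0))
        with pytest.warns(UserWarning, match="typical association"):
            build_calmodulin_wellmixed(p)

    def test_calcium_conservation_bulk_plus_bound(self):
        """Free bulk Ca + site-bound Ca is constant to 1e-9 relative at
        every logged step."""
        p = CalmodulinParams(ca_total=1e-5, n_steps=2000,
                             log_interval=100)
        res = engine.run(build_calmodulin_wellmixed(p), seed=2)
        free = res.counts["Ca"].to_numpy()
        bound = sum(k * res.counts[f"CaM:bound{k}"].to_numpy()
                    for k in range(5))
        total = free + bound
        np.testing.assert_allclose(total, total[0], rtol=1e-9)


class TestOdeOracle:
    def test_first_order_matches_closed_form(self):
        k = 5.0
        times, traj = ode_oracle(
            [MassActionReaction(("A",), ("B",), k)],
            {"A": 1e-6, "B": 0.0}, dt=1e-4, t_end=0.5, record_every=500)
        expected = 1e-6 * np.exp(-k * times)
        np.testing.assert_allclose(traj["A"], expected, rtol=1e-3)

    def test_second_order_unequal_matches_closed_form(self):
        k, a0, b0 = 1e8, 2e-6, 1e-6
        times, traj = ode_oracle(
            [MassActionReaction(("A", "B"), ("C",), k)],
            {"A": a0, "B": b0, "C": 0.0}, dt=1e-6, t_end=0.02,
            record_every=2000)
        # closed form for A0 != B0
        expo = np.exp((a0 - b0) * k * times)
        expected_a = a0 * (a0 - b0) * expo / (a0 * expo - b0)
        np.testing.assert_allclose(traj["A"], expected_a, rtol=5e-3)

    def test_nonfinite_state_raises(self):
        with pytest.raises(FloatingPointError):
            ode_oracle([MassActionReaction(("A", "A"), ("B",), 1e20)],
                       {"A": 1.0, "B": 0.0}, dt=1.0, t_end=10.0)

    def test_equilibrium_solver_agrees_with_long_ode(self):
        """Detailed-balance equilibrium fractions match the integrated
        network's long-time state within 0.5%.

        Uses synthetic moderate-stiffness lobe constants so the network
        equilibrates within an affordable number of Euler steps; the
        solver/integrator consistency being checked is
        constants-independent.
        """
        from mesocell.examples.calmodulin import LobeRates
        n_lobe = LobeRates(k_on_T=2e7, k_off_T=400.0,
                           k_on_R=5e7, k_off_R=50.0)
        c_lobe = LobeRates(k_on_T=5e7, k_off_T=150.0,
                           k_on_R=3e7, k_off_R=30.0)
        cam, ca = 2e-6, 1e-5
        free, frac_eq = cam_equilibrium(cam, ca, n_lobe, c_lobe)
        net = calmodulin_network(n_lobe, c_lobe)
        times, traj = ode_oracle(net, cam_ode_initial(cam, ca),
                                 dt=2e-6, t_end=0.4,
                                 record_every=200_000)
        frac_t = cam_fractions_from_traj(traj)
        np.testing.assert_allclose(frac_t[-1], frac_eq, atol=5e-3)

    def test_equilibrium_cam4_monotone_in_total_calcium(self, rates):
        scan = np.linspace(0, 16e-6, 17)
        cam4 = [cam_equilibrium(2e-6, ca, rates["n_lobe"],
                                rates["c_lobe"])[1][4] for ca in scan]
        assert all(b >= a - 1e-12 for a, b in zip(cam4, cam4[1:]))


class TestMicrodomainBuilder:
    def test_unknown_layout_rejected(self):
        with pytest.raises(ValueError, match="layout"):
            build_microdomain_model("diagonal")

    def test_layouts_have_four_source_voxels_in_q1_face(self):
        for layout in SOURCE_LAYOUTS:
            m = build_microdomain_model(layout)
            src = [s for s in m.sources_sinks if s.mode == "influx"][0]
            assert len(src.voxels) == 4
            assert all(v[0] == 0 for v in src.voxels)

    def test_clamp_source_mode_available(self):
        m = build_microdomain_model("center", source_mode="clamp")
        src = [s for s in m.sources_sinks if s.mode == "clamp"][0]
        assert src.value == 1e-3

    def test_quintiles_partition_the_lattice(self):
        m = build_microdomain_model("center")
        total = set()
        for comp in m.compartments:
            vs = comp.voxel_set()
            assert len(vs) == 200
            total |= vs
        assert len(total) == 1000

    def test_zero_source_gives_no_calcium_and_unloaded_cam(self):
        m = build_microdomain_model("center", release_per_step=0.0)
        res = engine.run(m, seed=1, n_steps=500, log_interval=500)
        assert res.counts["Ca"].to_numpy()[-1] == 0.0
        assert res.counts["CaM:bound0"].to_numpy()[-1] == \
            res.counts["CaM"].to_numpy()[-1]


class TestCeacamBuilder:
    def test_both_variants_validate(self):
        for raft in (True, False):
            m = build_ceacam1_model(CeacamParams(raft=raft))
            assert [v for v in validate_model(m)
                    if v.severity == "error"] == []

    def test_raft_area_fraction_in_stated_band(self):
        m = build_ceacam1_model(CeacamParams(raft=True))
        n_raft = len(set(m.microdomains[0].voxels))
        n_membrane = 152
        assert 0.1 <= n_raft / n_membrane <= 0.2

    def test_resting_cell_produces_no_monomers(self):
        """No calmodulin and no Lck: dimers have no dissociation
        pathway, so no monomers and no clustering ever appear."""
        m = build_ceacam1_model(CeacamParams(n_cam=0, n_lck=0))
        res = engine.run(m, seed=1, n_steps=2000, log_interval=200)
        assert (res.counts["CEACAM1_monomer"] == 0).all()
        assert (res.counts["CEACAM1_monomer:immobilized"] == 0).all()

    def test_ceacam_stoichiometry_conserved(self):
        """2 x dimers + monomers is invariant under dissociation,
        dimerization, transport and immobilization."""
        m = build_ceacam1_model(CeacamParams(n_cam=20, n_lck=20))
        res = engine.run(m, seed=3, n_steps=3000, log_interval=100)
        total = (2 * res.counts["CEACAM1_dimer"]
                 + res.counts["CEACAM1_monomer"]).to_numpy()
        assert (total == total[0]).all()

    def test_catalysts_never_consumed(self):
        m = build_ceacam1_model(CeacamParams(n_cam=20, n_lck=20))
        res = engine.run(m, seed=3, n_steps=3000, log_interval=500)
        assert (res.counts["CaM_active"] == 20).all()
        assert (res.counts["Lck"] == 20).all()

    def test_lck_confined_to_rafts_in_raft_model(self):
        m = build_ceacam1_model(CeacamParams(raft=True))
        res = engine.run(m, seed=4, n_steps=1000, log_interval=1000)
        sim = res.final
        store = sim.parts["Lck"]
        vox = store.get_vox(sim.lattice)
        mdid = sim.lattice.microdomain_id[vox[:, 0], vox[:, 1],
                                          vox[:, 2]]
        assert (mdid > 0).all()

    def test_phosphorylated_monomers_not_internalized(self):
        """ITIM phosphorylation blocks the internalization transport:
        phosphorylated monomers stay on the membrane."""
        p = CeacamParams(n_cam=20, n_lck=20, p_internalize=0.05,
                         trans_k_on=0.0)
        m = build_ceacam1_model(p)
        res = engine.run(m, seed=5, n_steps=5000, log_interval=5000)
        sim = res.final
        store = sim.parts["CEACAM1_monomer"]
        if store.n == 0:
            pytest.skip("no monomers produced in this short run")
        phos = store.states[:, store.sdef.states.index("phosphorylated")]
        vox = store.get_vox(sim.lattice)
        comp = sim.lattice.compartment_id[vox[:, 0], vox[:, 1],
                                          vox[:, 2]]
        mem_id = sim.lattice.compartment_names.index("membrane")
        assert (comp[phos] == mem_id).all()


class TestSummarize:
    def test_uniform_bulk_compartment_concentration_matches_global(self):
        m = build_microdomain_model("center", release_per_step=0.0)
        # preload uniform calcium instead of the clamped source
        from mesocell.model import InitialCondition
        m.sources_sinks = []
        m.initial_conditions.append(
            InitialCondition("Ca", "concentration", 2e-6))
        m.reactions = []
        res = engine.run(m, seed=1, n_steps=10, log_interval=10,
                         compartment_counts=True)
        s = summarize(res, m)
        for q in range(1, 6):
            assert s.averages[f"Ca[Q{q}]"] == pytest.approx(2e-6,
                                                            rel=1e-9)

    def test_site_fractions_sum_to_one(self):
        p = CalmodulinParams(ca_total=5e-6, n_steps=500, log_interval=50)
        res = engine.run(build_calmodulin_wellmixed(p), seed=1)
        m = build_calmodulin_wellmixed(p)
        s = summarize(res, m)
        frac = s.global_site_fractions["CaM"]
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, rtol=1e-12)

    def test_clustered_series_equals_immobilized_column(self):
        m = build_ceacam1_model(CeacamParams())
        res = engine.run(m, seed=1, n_steps=500, log_interval=100)
        s = summarize(res, m)
        np.testing.assert_array_equal(
            s.clustered, res.counts["CEACAM1_monomer:immobilized"])

    def test_clustered_matches_particle_log_immobilized(self):
        """The clustered count agrees with the number of immobilized
        monomers in the particle log (two independent output paths)."""
        m = build_ceacam1_model(CeacamParams(trans_k_on=5.0))
        res = engine.run(m, seed=6, n_steps=4000, log_interval=1000,
                         particle_log=True)
        log = res.particle_log
        for step, grp in log.groupby("step"):
            n_immob = int(((grp["species"] == "CEACAM1_monomer")
                           & grp["immobilized"]).sum())
            row = res.counts[res.counts["step"] == step]
            assert n_immob == int(
                row["CEACAM1_monomer:immobilized"].iloc[0])

    def test_empty_window_raises(self):
        m = build_ceacam1_model(CeacamParams())
        res = engine.run(m, seed=1, n_steps=10, log_interval=10)
        with pytest.raises(ValueError, match="window"):
            summarize(res, m, burn_in_fraction=2.0)
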