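"""Reaction kinetics: binding-radius calibration, one-step operators,
mass-action benchmarks and the coarse-timestep failure mode."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from mesocell import ConcentrationField
from mesocell.diffusion import Particle
from mesocell.model import (Box, CompartmentSpec, EnvironmentSpec,
                            InitialCondition, ModelSpec, OutputConfig,
                            ReactionRule, SpeciesDef, SpeciesPattern,
                            N_AVOGADRO)
from mesocell.reactions import (ActivationLimitedError, BindingRadius,
                                K_BIMOL_TO_UM3, apply_state_change,
                                bimolecular_particle_step,
                                binding_radius, bulk_bulk_step,
                                bulk_particle_step, discrete_pair_rate,
                                fire_probability, unimolecular_step)
from mesocell.benchmarks import (decay_model, pair_reaction_trajectory,
                                 second_order_equal_conc)
from mesocell import engine

from test_diffusion import make_lattice


class TestBindingRadius:
    def test_small_timestep_recovers_smoluchowski_radius(self):
        k, D = 1e9, 10.0
        sig_smol = k * K_BIMOL_TO_UM3 / (4 * math.pi * D)
        # rms step ~ sigma/100: deep in the diffusion-limited regime
        dt = (sig_smol / 100.0) ** 2 / (2 * D)
        br = binding_radius(k, D, dt)
        assert br.sigma_b == pytest.approx(sig_smol, rel=0.02)

    def test_large_timestep_recovers_well_mixed_radius(self):
        # rms step ~ 6x the radius: the per-step swept volume dominates
        k, D, dt = 1e9, 100.0, 1e-3
        sig_wm = (3 * k * K_BIMOL_TO_UM3 * dt / (4 * math.pi)) ** (1 / 3)
        br = binding_radius(k, D, dt)
        assert br.sigma_b == pytest.approx(sig_wm, rel=0.02)

    def test_zero_mutual_diffusion_uses_well_mixed_form(self):
        k, dt = 1e8, 1e-4
        br = binding_radius(k, 0.0, dt)
        expected = (3 * k * K_BIMOL_TO_UM3 * dt / (4 * math.pi)) ** (1 / 3)
        assert br.sigma_b == pytest.approx(expected, rel=1e-9)

    def test_activation_limited_regime_raises(self):
        # radius would exceed hundreds of rms steps: collision is no
        # longer rate-limiting at this resolution
        with pytest.raises(ActivationLimitedError):
            binding_radius(1e10, 10.0, 1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binding_radius(0.0, 1.0, 1e-6)

    def test_sigma_u_at_least_sigma_b(self):
        br = binding_radius(1e9, 10.0, 1e-6, sigma_u_factor=0.5)
        assert br.sigma_u >= br.sigma_b
        br2 = binding_radius(1e9, 10.0, 1e-6, sigma_u_factor=2.0)
        assert br2.sigma_u == pytest.approx(2.0 * br2.sigma_b)

    def test_discrete_rate_is_monotone_in_radius(self):
        D, dt = 20.0, 1e-6
        s = math.sqrt(2 * D * dt)
        rates = [discrete_pair_rate(x * s, D, dt)
                 for x in (0.25, 0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_intermediate_regime_against_calibration_simulation(self):
        """Brute-force pair simulation in the intermediate regime
        (radius comparable to the rms step) recovers the requested rate
        within 5%.

        The measurement window starts late because the encounter rate of
        an initially well-mixed system approaches its steady state
        algebraically (the time-dependent Smoluchowski transient).
        """
        k, D_sum, dt = 3.3e7, 20.0, 2e-7
        br = binding_radius(k, D_sum, dt)
        sigma = br.sigma_b
        s = math.sqrt(2 * D_sum * dt)
        assert 0.2 < sigma / s < 1.5  # genuinely between the two limits
        k_vol = k * K_BIMOL_TO_UM3
        # independent oracle: direct pair simulation with its own
        # collision bookkeeping (first-come removal)
        n = 10_000
        events_per_step = 10.0
        V = k_vol * dt * n * n / events_per_step
        box = V ** (1 / 3)
        rng = np.random.default_rng(2024)
        pos_a = rng.random((n, 3)) * box
        pos_b = rng.random((n, 3)) * box
        s_half = math.sqrt(D_sum * dt)  # split diffusivity equally
        events = 0
        weight = 0.0
        burn, total = 300, 600
        for step in range(total):
            pos_a = np.mod(pos_a + rng.normal(0, s_half, pos_a.shape),
                           box)
            pos_b = np.mod(pos_b + rng.normal(0, s_half, pos_b.shape),
                           box)
            pairs = cKDTree(pos_a, boxsize=box).query_ball_tree(
                cKDTree(pos_b, boxsize=box), sigma)
            used_b = set()
            hit_a = []
            for ia, cand in enumerate(pairs):
                for ib in cand:
                    if ib not in used_b:
                        used_b.add(ib)
                        hit_a.append(ia)
                        break
            if step >= burn:
                events += len(hit_a)
                weight += len(pos_a) * len(pos_b) * dt / V
            if hit_a:
                keep_a = np.ones(len(pos_a), bool)
                keep_a[hit_a] = False
                keep_b = np.ones(len(pos_b), bool)
                keep_b[sorted(used_b)] = False
                pos_a, pos_b = pos_a[keep_a], pos_b[keep_b]
        k_meas = events / weight
        assert k_meas == pytest.approx(k_vol, rel=0.05)


class TestUnimolecular:
    def rule(self, k):
        return ReactionRule("decay", [SpeciesPattern("A")],
                            [SpeciesPattern("B")], k=k)

    def test_zero_rate_no_conversion(self, rng):
        parts = [Particle(i, "A", np.zeros(3)) for i in range(100)]
        out, log = unimolecular_step(parts, self.rule(0.0), 1e-3, rng)
        assert all(p.species == "A" for p in out)
        assert log.counts == {}

    def test_bulk_fractional_conversion_exact(self, rng):
        f = ConcentrationField("A", np.full((2, 2, 2), 12.5))
        k = -math.log(0.9) / 1e-3  # 1 - exp(-k dt) = 0.1
        out, log = unimolecular_step(f, self.rule(k), 1e-3, rng)
        assert out.total() == pytest.approx(0.9 * 100.0, rel=1e-12)

    def test_survival_matches_exponential_decay(self):
        """10^4 particles at k*dt = 0.01: surviving fraction within 3
        s.e. of exp(-k t) at every logged time."""
        n0, k, dt = 10_000, 20.0, 5e-4
        m = decay_model(n0, k, dt, n_steps=500, log_every=50)
        res = engine.run(m, seed=7)
        t = res.counts["time_s"].to_numpy()
        surv = res.counts["A"].to_numpy()
        expected = n0 * np.exp(-k * t)
        se = np.sqrt(n0 * np.exp(-k * t) * (1 - np.exp(-k * t)))
        assert np.all(np.abs(surv - expected) <= 3 * np.maximum(se, 1.0))

    def test_products_conserve_total(self):
        n0, k, dt = 10_000, 20.0, 5e-4
        m = decay_model(n0, k, dt, n_steps=200, log_every=50)
        res = engine.run(m, seed=8)
        total = res.counts["A"] + res.counts["B"]
        assert (total == n0).all()


class TestBimolecularParticle:
    def rule(self):
        return ReactionRule("bind", [SpeciesPattern("A"),
                                     SpeciesPattern("B")],
                            [SpeciesPattern("C")], k=1e9)

    def test_no_pair_within_radius_no_reaction(self, rng):
        radii = BindingRadius("bind", 0.01, 0.01)
        parts = [Particle(0, "A", np.array([0.1, 0.1, 0.1])),
                 Particle(1, "B", np.array([0.5, 0.5, 0.5]))]
        out, log = bimolecular_particle_step(parts, self.rule(), radii,
                                             rng)
        assert {p.species for p in out} == {"A", "B"}
        assert log.counts == {}

    def test_pair_within_radius_products_at_midpoint(self, rng):
        sigma = 0.01
        radii = BindingRadius("bind", sigma, sigma)
        parts = [Particle(0, "A", np.array([0.0, 0.0, 0.0])),
                 Particle(1, "B", np.array([0.0, 0.0, 0.9 * sigma]))]
        out, log = bimolecular_particle_step(parts, self.rule(), radii,
                                             rng)
        assert len(out) == 1 and out[0].species == "C"
        np.testing.assert_allclose(out[0].pos,
                                   [0.0, 0.0, 0.45 * sigma])
        assert log.counts["bind"] == 1

    def test_each_particle_reacts_at_most_once(self, rng):
        sigma = 0.1
        radii = BindingRadius("bind", sigma, sigma)
        # one A surrounded by three B: only one C forms
        parts = [Particle(0, "A", np.array([0.5, 0.5, 0.5]))] + [
            Particle(i + 1, "B", np.array([0.5 + 0.02 * (i + 1), 0.5,
                                           0.5])) for i in range(3)]
        out, log = bimolecular_particle_step(parts, self.rule(), radii,
                                             rng)
        assert log.counts["bind"] == 1
        assert sum(p.species == "C" for p in out) == 1
        assert sum(p.species == "B" for p in out) == 2

    def test_nearest_pair_matched_first(self, rng):
        sigma = 0.1
        radii = BindingRadius("bind", sigma, sigma)
        parts = [Particle(0, "A", np.array([0.5, 0.5, 0.5])),
                 Particle(1, "B", np.array([0.58, 0.5, 0.5])),
                 Particle(2, "A", np.array([0.61, 0.5, 0.5]))]
        out, log = bimolecular_particle_step(parts, self.rule(), radii,
                                             rng)
        # B reacts with the nearer A (id 2, distance 0.03)
        survivors = {p.particle_id for p in out if p.species == "A"}
        assert survivors == {0}

    @pytest.mark.parametrize("dt,n_steps", [(1e-6, 2000), (2e-7, 10_000)])
    def test_mass_action_trajectory_with_calibrated_radii(self, dt,
                                                          n_steps):
        """A + B -> C particle kinetics track the second-order closed
        form within 5% at matched times, independent of dt (averaged
        over replicate trajectories)."""
        n, c0 = 1000, 0.83e-6
        box = (n / (c0 * N_AVOGADRO) * 1e15) ** (1 / 3)
        concs = []
        for seed in (0, 1, 2):
            res = pair_reaction_trajectory(
                n, n, box, k=1e9, D_a=10.0, D_b=10.0, dt=dt,
                n_steps=n_steps, seed=seed, log_every=n_steps // 10)
            concs.append(res.conc_a())
        conc = np.mean(concs, axis=0)
        theory = second_order_equal_conc(conc[0], 1e9, res.times)
        assert np.all(np.abs(conc / theory - 1.0) <= 0.05)

    def test_naive_radius_fails_at_coarse_timestep(self):
        """The uncorrected Smoluchowski radius misses encounters at the
        coarser timestep (the motivating failure mode for the
        timestep-calibrated radius)."""
        n, c0 = 1000, 0.83e-6
        box = (n / (c0 * N_AVOGADRO) * 1e15) ** (1 / 3)
        res = pair_reaction_trajectory(n, n, box, k=1e9, D_a=10.0,
                                       D_b=10.0, dt=1e-6, n_steps=2000,
                                       seed=31, radius_mode="naive",
                                       log_every=200)
        conc = res.conc_a()
        theory = second_order_equal_conc(conc[0], 1e9, res.times)
        assert np.abs(conc[-1] / theory[-1] - 1.0) > 0.05

    def test_dt_robustness_with_and_without_adjustment(self):
        """Final product counts at dt and 5 dt agree within 5% with
        calibrated radii and disagree by more with the naive radius."""
        n, c0 = 1000, 0.83e-6
        box = (n / (c0 * N_AVOGADRO) * 1e15) ** (1 / 3)
        t_end_steps = {1e-6: 1500, 2e-7: 7500}

        def final_product(mode, dt, seed):
            r = pair_reaction_trajectory(
                n, n, box, 1e9, 10.0, 10.0, dt, t_end_steps[dt], seed,
                radius_mode=mode, log_every=t_end_steps[dt])
            return r.n_c[-1]

        ab_fine = np.mean([final_product("ab", 2e-7, s) for s in (1, 2)])
        ab_coarse = np.mean([final_product("ab", 1e-6, s)
                             for s in (1, 2)])
        nv_fine = np.mean([final_product("naive", 2e-7, s)
                           for s in (1, 2)])
        nv_coarse = np.mean([final_product("naive", 1e-6, s)
                             for s in (1, 2)])
        assert abs(ab_coarse / ab_fine - 1.0) <= 0.05
        assert abs(nv_coarse / nv_fine - 1.0) > 0.05


class TestBulkParticle:
    def setup_rule(self, k=1e9):
        return ReactionRule("cap", [SpeciesPattern("B"),
                                    SpeciesPattern("P")],
                            [SpeciesPattern("Q")], k=k)

    def test_zero_concentration_no_firing(self, rng):
        lat, _, _ = make_lattice()
        f = ConcentrationField("B", np.zeros(lat.dims))
        parts = [Particle(i, "P", np.full(3, 0.5)) for i in range(50)]
        f2, out, log = bulk_particle_step(f, parts, self.setup_rule(),
                                          1e-6, rng, lat)
        assert log.counts == {} and len(out) == 50

    def test_firing_fraction_matches_bernoulli(self, rng):
        """Firing fraction of many replicate particles in uniform bulk
        within 3 s.e. of 1 - exp(-k C dt)."""
        lat, _, _ = make_lattice()
        from mesocell.model import voxel_volume_litres
        v = voxel_volume_litres(lat.h)
        amount = 1e6  # effectively undepletable
        conc = amount / (N_AVOGADRO * v)
        f = ConcentrationField("B", np.full(lat.dims, amount))
        n = 10_000
        k, dt = 3e4, 1e-6
        p_expect = fire_probability(k * conc, dt)
        assert 0.005 < p_expect < 0.2
        parts = [Particle(i, "P", np.full(3, 0.5)) for i in range(n)]
        f2, out, log = bulk_particle_step(f, parts, self.setup_rule(k),
                                          dt, rng, lat)
        fired = log.counts.get("cap", 0)
        se = math.sqrt(n * p_expect * (1 - p_expect))
        assert abs(fired - n * p_expect) <= 3 * se
        # one molecule consumed per firing
        assert f2.total() == pytest.approx(
            amount * np.prod(lat.dims) - fired, rel=1e-12)

    def test_accuracy_improves_with_bulk_diffusivity(self):
        """Local depletion biases the hybrid scheme at low bulk D; the
        error against the well-mixed ODE shrinks as D grows over two
        decades."""
        errors = []
        for D_bulk in (0.2, 2.0, 20.0):
            errs = []
            for seed in (0, 1, 2):
                errs.append(self._depletion_error(D_bulk, seed))
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]

    @staticmethod
    def _depletion_error(D_bulk, seed):
        env = EnvironmentSpec(4, 4, 4, 0.2, 1e-6, 4000)
        c0 = 5e-6
        model = ModelSpec(
            environment=env,
            compartments=[CompartmentSpec(
                "box", boxes=[Box(0, 4, 0, 4, 0, 4)])],
            species=[
                SpeciesDef("B", "bulk", D_bulk,
                           allowed_compartments=["box"]),
                SpeciesDef("P", "particle", 0.5,
                           allowed_compartments=["box"]),
            ],
            reactions=[ReactionRule(
                "consume", [SpeciesPattern("B"), SpeciesPattern("P")],
                [SpeciesPattern("P")], k=1.2e9)],
            initial_conditions=[
                InitialCondition("B", "concentration", c0),
                InitialCondition("P", "count", 50)],
            output=OutputConfig(log_interval=4000))
        res = engine.run(model, seed=seed)
        b_final = res.counts["B"].to_numpy()[-1]
        v_litres = 64 * (0.2 ** 3) * 1e-15
        c_p = 50 / (N_AVOGADRO * v_litres)
        b0 = res.counts["B"].to_numpy()[0]
        b_ode = b0 * math.exp(-1.2e9 * c_p * 4000 * 1e-6)
        return abs(b_final - b_ode) / b_ode


class TestBulkBulk:
    def rule(self, k=1e8):
        return ReactionRule("bb", [SpeciesPattern("X"),
                                   SpeciesPattern("Y")],
                            [SpeciesPattern("Z")], k=k)

    def test_zero_field_no_change(self):
        lat, _, _ = make_lattice()
        fx = ConcentrationField("X", np.zeros(lat.dims))
        fy = ConcentrationField("Y", np.full(lat.dims, 5.0))
        bulk_bulk_step(fx, fy, self.rule(), 1e-6, lat)
        assert fy.total() == 5.0 * 125

    def test_uniform_fields_match_ode_oracle(self):
        """Deterministic per-voxel mass action tracks the well-mixed
        forward-Euler oracle within 1% over 10^3 steps."""
        from mesocell.examples import MassActionReaction, ode_oracle
        lat, _, _ = make_lattice()
        from mesocell.model import voxel_volume_litres
        v = voxel_volume_litres(lat.h)
        c0x, c0y = 8e-6, 5e-6
        fx = ConcentrationField("X", np.full(lat.dims,
                                             c0x * N_AVOGADRO * v))
        fy = ConcentrationField("Y", np.full(lat.dims,
                                             c0y * N_AVOGADRO * v))
        k, dt, n = 1e8, 1e-6, 1000
        for _ in range(n):
            bulk_bulk_step(fx, fy, self.rule(k), dt, lat)
        times, traj = ode_oracle(
            [MassActionReaction(("X", "Y"), ("Z",), k)],
            {"X": c0x, "Y": c0y, "Z": 0.0}, dt, n * dt,
            record_every=n)
        cx = fx.total() / (125 * N_AVOGADRO * v)
        assert cx == pytest.approx(traj["X"][-1], rel=0.01)

    def test_cap_prevents_negative_amounts(self):
        lat, _, _ = make_lattice()
        fx = ConcentrationField("X", np.full(lat.dims, 0.5))
        fy = ConcentrationField("Y", np.full(lat.dims, 1e9))
        bulk_bulk_step(fx, fy, self.rule(k=1e12), 1.0, lat)
        assert (fx.amounts >= 0).all() and (fy.amounts >= 0).all()


class TestStateChange:
    def test_identity_rule_leaves_particle_unchanged(self):
        p = Particle(3, "M", np.array([0.1, 0.2, 0.3]),
                     state_flags={"on": False})
        rule = ReactionRule("id", [SpeciesPattern("M")],
                            [SpeciesPattern("M")], k=1.0)
        q = apply_state_change(p, rule)
        assert q.particle_id == 3 and q.state_flags == p.state_flags
        np.testing.assert_array_equal(q.pos, p.pos)

    def test_flag_set_preserves_position_and_id(self):
        p = Particle(9, "M", np.array([0.4, 0.4, 0.4]),
                     state_flags={"phos": False})
        rule = ReactionRule(
            "ph", [SpeciesPattern("M", states={"phos": False})],
            [SpeciesPattern("M", states={"phos": True})], k=1.0)
        q = apply_state_change(p, rule)
        assert q.state_flags["phos"] is True
        assert q.particle_id == 9
        np.testing.assert_array_equal(q.pos, p.pos)

    def test_undeclared_site_rejected(self):
        p = Particle(0, "M", np.zeros(3), site_occupancy={"a": False})
        rule = ReactionRule("bad", [SpeciesPattern("M")],
                            [SpeciesPattern("M", sites={"zz": True})],
                            k=1.0)
        with pytest.raises(ValueError, match="zz"):
            apply_state_change(p, rule)
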