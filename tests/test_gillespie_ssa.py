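"""Reaction-system assembly and exactness of the stochastic simulator."""

import numpy as np
import pytest
from scipy import stats as sps

import cole2sim as c
from cole2sim.gillespie_ssa import (
    Reaction,
    ReactionSystem,
    build_reaction_system,
    default_detailed_rates,
    ensemble,
    integrate_system_ode,
    simulate_ssa,
)


class TestBuildReactionSystem:
    def test_reduced_scheme_has_exactly_eight_reactions_for_certain_coremoval(self):
        system = build_reaction_system(c.RegulationParameters(), "reduced")
        assert len(system.reactions) == 8
        assert system.species == ["M", "A", "S"]

    def test_partial_survival_splits_coupled_degradation(self):
        p = c.RegulationParameters(p_M=0.5)
        system = build_reaction_system(p, "reduced")
        assert len(system.reactions) == 9
        x = np.array([3, 4, 5])
        a = system.propensities(x)
        names = [r.name for r in system.reactions]
        joint = a[names.index("coupled degradation M+A (CsrA removed)")]
        solo = a[names.index("coupled degradation M+A (CsrA survives)")]
        assert joint == pytest.approx(p.k_M * 0.5 * 3 * 4)
        assert solo == pytest.approx(p.k_M * 0.5 * 3 * 4)

    def test_split_reactions_reproduce_mean_field_coremoval_term(self):
        """SSA mean of the split scheme matches the ODE with the p-weighted term."""
        p = c.RegulationParameters(
            alpha_M=8.0, alpha_A=10.0, alpha_S=6.0, N=1.0, p_M=0.5, p_S=0.5,
            k_M=0.2, k_S=0.2, delta_A=0.2,
        )
        system = build_reaction_system(p, "reduced")
        ens = ensemble(system, [0, 0, 0], 3000.0, 24, base_seed=9)
        keep = ens.t >= 300
        ssa_A = ens.series("A")[:, keep].mean()
        ode = c.integrate_deterministic(p, c.SystemState(0, 0, 0),
                                        np.linspace(0, 3000, 60))
        # mean-field fixed point of Eqs with k p M A; small fluctuation
        # corrections are absorbed by a 10% band
        assert ssa_A == pytest.approx(ode["A"][-1], rel=0.10)

    def test_detailed_binding_uses_free_site_combinatorics(self):
        p = c.RegulationParameters(N=2.0, alpha_S=1.0)
        rates = default_detailed_rates(p)
        system = build_reaction_system(p, "detailed", detailed_rates=rates)
        x = np.zeros(system.n_species)
        x[system.species_index("A")] = 3
        x[system.species_index("C_0")] = 4
        x[system.species_index("C_1")] = 5
        a = system.propensities(x)
        names = [r.name for r in system.reactions]
        assert a[names.index("CsrA binding (n=0->1)")] == pytest.approx(
            2 * rates["k_plus"] * 3 * 4)
        assert a[names.index("CsrA binding (n=1->2)")] == pytest.approx(
            1 * rates["k_plus"] * 3 * 5)
        assert a[names.index("CsrA unbinding (n=1->0)")] == pytest.approx(
            1 * rates["k_minus"] * 5)

    def test_unknown_variant_and_missing_rates_reported(self):
        with pytest.raises(ValueError, match="unknown variant"):
            build_reaction_system(c.RegulationParameters(), "hybrid")
        with pytest.raises(ValueError, match="k_minus"):
            build_reaction_system(c.RegulationParameters(N=2.0), "detailed",
                                  detailed_rates={"k_plus": 1.0})

    def test_reaction_list_serializes_human_readably(self):
        system = build_reaction_system(c.RegulationParameters(), "reduced")
        text = system.to_text()
        assert "M, A, S" in text
        assert "coupled degradation" in text
        assert "58.52" in text


class TestSimulateSSA:
    def test_pure_birth_event_count_is_poissonian(self):
        lam, T, n = 7.0, 30.0, 300
        system = ReactionSystem(["X"], [Reaction("birth", (), (("X", 1),), lam)])
        ens = ensemble(system, [0], T, n, base_seed=21)
        counts = ens.series("X")[:, -1]
        mean_se = np.sqrt(lam * T / n)
        assert abs(counts.mean() - lam * T) < 3.0 * mean_se
        assert counts.var(ddof=1) == pytest.approx(lam * T, rel=0.25)

    def test_birth_death_stationary_distribution_is_poisson(self):
        """Goodness of fit on ~1e4 decorrelated samples."""
        lam, delta = 12.0, 1.0
        system = c.fixture_generator("birth_death", lam=lam, delta=delta)
        t_grid = np.arange(0.0, 50050.0, 5.0)  # 5 lifetimes apart
        traj = simulate_ssa(system, [0], 50050.0, seed=13, t_grid=t_grid)
        samples = traj["X"][10:]
        assert samples.size >= 10000 - 10
        kmax = int(samples.max())
        observed = np.bincount(samples, minlength=kmax + 1).astype(float)
        expected = sps.poisson.pmf(np.arange(kmax + 1), lam) * samples.size
        # pool sparse tails so the chi-square approximation is valid
        lo, hi = int(lam - 3 * np.sqrt(lam)), int(lam + 3 * np.sqrt(lam))
        obs = np.concatenate([[observed[:lo].sum()], observed[lo:hi],
                              [observed[hi:].sum()]])
        exp = np.concatenate([[expected[:lo].sum()], expected[lo:hi],
                              [expected[hi:].sum() + samples.size - expected.sum()]])
        chi2 = sps.chisquare(obs, exp * obs.sum() / exp.sum())
        assert chi2.pvalue > 1e-3

    def test_seed_determinism_is_bitwise(self):
        system = build_reaction_system(c.RegulationParameters(), "reduced")
        a = simulate_ssa(system, [0, 0, 0], 300.0, seed=99)
        b = simulate_ssa(system, [0, 0, 0], 300.0, seed=99)
        for sp in "MAS":
            assert np.array_equal(a[sp], b[sp])
        assert a.metadata["n_events"] == b.metadata["n_events"]
        ev1 = simulate_ssa(system, [0, 0, 0], 50.0, seed=7, record="events")
        ev2 = simulate_ssa(system, [0, 0, 0], 50.0, seed=7, record="events")
        assert np.array_equal(ev1.times, ev2.times)
        assert np.array_equal(ev1.reaction_indices, ev2.reaction_indices)

    def test_event_log_is_increasing_and_nonnegative(self):
        system = build_reaction_system(c.RegulationParameters(), "reduced")
        ev = simulate_ssa(system, [0, 0, 0], 30.0, seed=3, record="events")
        assert np.all(np.diff(ev.times) > 0)
        assert ev.states.min() >= 0

    def test_deep_sub_threshold_mrna_stays_silent(self):
        p = c.RegulationParameters(alpha_M=0.5)  # far below the titration balance
        system = build_reaction_system(p, "reduced")
        x0 = {"M": 0, "A": int(c.steady_state_exact(p).A_star), "S": 0}
        traj = simulate_ssa(system, x0, 2000.0, seed=17)
        assert traj["M"][200:].mean() < 0.1

    @pytest.mark.parametrize("s_eff,alpha_M", [(20.0, 50.0), (40.0, 30.0)])
    def test_time_average_matches_exact_steady_state(self, s_eff, alpha_M):
        p = c.RegulationParameters(alpha_M=alpha_M).with_srna_production(s_eff)
        system = build_reaction_system(p, "reduced")
        ens = ensemble(system, [0, 0, 0], 4000.0, 6, base_seed=3)
        keep = ens.t >= 1000
        per_run = ens.series("M")[:, keep].mean(axis=1)
        se = per_run.std(ddof=1) / np.sqrt(per_run.size)
        assert abs(per_run.mean() - c.steady_state_exact(p).M_star) < 4.0 * max(se, 0.05)

    def test_schedule_breakpoints_are_exact(self):
        """Scheduled zero rate produces nothing until the step, Poisson after."""
        system = ReactionSystem(
            ["X"], [Reaction("birth", (), (("X", 1),), 5.0, scheduled=True)]
        )
        ens = ensemble(system, [0], 100.0, 200, base_seed=5,
                       schedule=[(0.0, 0.0), (60.0, 1.0)])
        X = ens.series("X")
        assert X[:, 60].max() == 0
        final = X[:, -1]
        assert abs(final.mean() - 5.0 * 40.0) < 3.0 * np.sqrt(200.0 / 200)


class TestEnsemble:
    def test_single_realization_ensemble_equals_its_trajectory(self):
        system = build_reaction_system(c.RegulationParameters(), "reduced")
        ens = ensemble(system, [0, 0, 0], 100.0, 1, base_seed=42)
        traj = simulate_ssa(system, [0, 0, 0], 100.0, seed=int(ens.seeds[0]))
        assert np.array_equal(ens.data[0], np.stack([traj[sp] for sp in "MAS"]))

    def test_linear_birth_death_mean_matches_ode(self):
        lam, delta = 20.0, 0.3
        system = ReactionSystem(
            ["X"],
            [
                Reaction("birth", (), (("X", 1),), lam),
                Reaction("death", (("X", 1),), (("X", -1),), delta),
            ],
        )
        n = 150
        ens = ensemble(system, [0], 30.0, n, base_seed=6)
        expected = (lam / delta) * (1.0 - np.exp(-delta * ens.t))
        se = np.sqrt(np.maximum(expected, 1e-9) / n)  # ~Poisson transient variance
        assert np.all(np.abs(ens.mean("X") - expected) < 4.0 * se + 0.5)

    def test_child_seeds_are_distinct_and_bounded(self):
        seeds = c.spawn_seeds(123, 1000)
        assert len(set(seeds.tolist())) == 1000
        assert seeds.max() < 2**31

    def test_ode_of_reaction_system_matches_reduced_integrator(self):
        p = c.RegulationParameters(alpha_M=30.0)
        system = build_reaction_system(p, "reduced")
        t = np.linspace(0.0, 400.0, 81)
        a = integrate_system_ode(system, [0, 0, 0], t)
        b = c.integrate_deterministic(p, c.SystemState(0, 0, 0), t)
        for sp in "MAS":
            assert np.allclose(a[sp], b[sp], rtol=1e-5, atol=1e-5)


class TestDetailedScheme:
    def test_bookkeeping_conservation_laws(self):
        """sRNA total changes only by production/decay; binding conserves CsrA."""
        p = c.RegulationParameters(alpha_M=2.0, alpha_A=4.0, alpha_S=1.0, N=3.0,
                                   k_M=0.5, k_S=0.5, delta_A=0.1)
        system = build_reaction_system(p, "detailed")
        ev = simulate_ssa(system, np.zeros(system.n_species), 40.0, seed=2,
                          record="events")
        idx = {name: i for i, name in enumerate(ev.species)}
        names = [r.name for r in system.reactions]
        srna_cols = [idx[f"C_{n}"] for n in range(4)]
        total_srna = ev.states[:, srna_cols].sum(axis=1)
        bound = sum(n * ev.states[:, idx[f"C_{n}"]] for n in range(4))
        free_plus_bound = (ev.states[:, idx["A"]] + bound + ev.states[:, idx["C_ma"]])
        for k, r in enumerate(ev.reaction_indices):
            name = names[r]
            d_srna = total_srna[k + 1] - total_srna[k]
            if name == "sRNA production" or name.startswith("sRNA decay"):
                assert d_srna in (-1, 1)
            else:
                assert d_srna == 0
            d_csra = free_plus_bound[k + 1] - free_plus_bound[k]
            if ("binding" in name or "unbinding" in name or "formation" in name
                    or "dissociation" in name):
                assert d_csra == 0  # complex moves conserve CsrA

    def test_single_site_no_unbinding_matches_reduced_construction(self):
        """N = 1 with committed binding is the reduced scheme by construction."""
        p = c.RegulationParameters(alpha_M=5.0, alpha_A=8.0, alpha_S=6.0, N=1.0,
                                   k_M=0.4, k_S=0.4, delta_A=0.1)
        rates = {"k_plus": 0.4, "k_minus": 0.0, "v_plus": 0.4, "v_minus": 0.0,
                 "delta_cma": 1e9}
        # with instant complex decay and no unbinding, binding == joint removal;
        # compare stationary free-CsrA means
        detailed = build_reaction_system(p, "detailed", detailed_rates=rates)
        reduced = build_reaction_system(p, "reduced")
        ens_d = ensemble(detailed, np.zeros(detailed.n_species), 2500.0, 8, base_seed=1)
        ens_r = ensemble(reduced, [0, 0, 0], 2500.0, 8, base_seed=2)
        keep = ens_d.t >= 300
        a_d = ens_d.series("A")[:, keep].mean(axis=1)
        a_r = ens_r.series("A")[:, keep].mean(axis=1)
        se = np.hypot(a_d.std(ddof=1), a_r.std(ddof=1)) / np.sqrt(8)
        assert abs(a_d.mean() - a_r.mean()) < 4.0 * max(se, 0.05)

    def test_discrepancy_shrinks_as_complex_dynamics_speed_up(self):
        p = c.RegulationParameters(alpha_M=3.0, alpha_A=6.0, alpha_S=4.0 / 3.0,
                                   N=3.0, k_M=0.5, k_S=0.5, delta_A=0.1)
        report = c.reduced_vs_detailed_equivalence(
            p, speedup_factors=(1.0, 10.0, 100.0), t_max=4000.0, burn_in=500.0,
            seed=4, n_reps=4,
        )
        d = [row["discrepancy_A"] for row in report["rows"]]
        assert d[2] < d[1] < d[0]
        row = report["rows"][2]
        assert row["detailed_free_sites"] == pytest.approx(row["reduced_S"], rel=0.15)
        assert row["detailed_M"] == pytest.approx(row["reduced_M"], rel=0.15)

    def test_partial_survival_not_supported_in_detailed_scheme(self):
        with pytest.raises(NotImplementedError):
            build_reaction_system(c.RegulationParameters(p_S=0.5), "detailed")
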