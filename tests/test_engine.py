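"""Kinetic engine: waiting times, clock competition, diffusion, pairing,
single-cell and ensemble trajectories against closed-form oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from dsbrepair.damage import DamageSet, NucleusGeometry
from dsbrepair.engine import (
    EndState,
    SimulationConfig,
    attempt_synapsis,
    diffuse,
    next_event,
    run_cell,
    run_ensemble,
    sample_waiting_time,
)
from dsbrepair.states import (
    Pathway,
    Phase,
    Protein,
    ScenarioConfig,
    StateGraph,
    TransitionRule,
    build_scenario,
)
from conftest import chain_graph, damage_with_n, hypoexponential_cdf


class TestSampleWaitingTime:
    def test_rejects_nonpositive_tau(self):
        rng = np.random.default_rng(0)
        for tau in (0.0, -1.0):
            with pytest.raises(ValueError):
                sample_waiting_time(tau, rng)

    def test_mean_and_variance_match_exponential_law(self):
        # 1e5 draws at tau = 120 s: mean within 3 sigma/sqrt(n), var ~ tau^2
        rng = np.random.default_rng(1)
        draws = np.array([sample_waiting_time(120.0, rng) for _ in range(100_000)])
        assert abs(draws.mean() - 120.0) < 3 * 120.0 / np.sqrt(len(draws))
        assert abs(draws.var(ddof=1) - 120.0**2) < 0.05 * 120.0**2
        # median of Exponential(tau) is tau * ln 2
        assert abs(np.median(draws) - 120.0 * np.log(2)) < 2.0

    def test_deterministic_under_fixed_rng_state(self):
        a = sample_waiting_time(50.0, np.random.default_rng(7))
        b = sample_waiting_time(50.0, np.random.default_rng(7))
        assert a == b


def _two_rule_graph(tau_a: float, tau_b: float) -> StateGraph:
    rules = (
        TransitionRule(
            name="A",
            tau=tau_a,
            from_phase=frozenset({Phase.FREE}),
            gains=frozenset({Protein.KU}),
        ),
        TransitionRule(
            name="B",
            tau=tau_b,
            from_phase=frozenset({Phase.FREE}),
            gains=frozenset({Protein.RESECTED}),
            set_lock=Pathway.HR,
        ),
    )
    return StateGraph(rules=rules, config=ScenarioConfig.default("C", end_cleaning=False))


def _free_end() -> EndState:
    return EndState(end_id=0, dsb_id=0, index=0, partner_index=1, phase=Phase.FREE)


class TestNextEvent:
    def test_single_eligible_rule_always_selected(self):
        graph = chain_graph(100.0, 200.0)
        rng = np.random.default_rng(3)
        for _ in range(50):
            rule, wt = next_event(_free_end(), graph, rng)
            assert rule.name == "load" and wt > 0

    def test_equal_rates_split_evenly(self):
        graph = _two_rule_graph(50.0, 50.0)
        rng = np.random.default_rng(4)
        wins = sum(
            next_event(_free_end(), graph, rng)[0].name == "A" for _ in range(20_000)
        )
        p = wins / 20_000
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / 20_000)

    def test_min_of_exponentials_selection_probability(self):
        # tau_A = 1, tau_B = 3: P(A wins) = (1/1) / (1/1 + 1/3) = 0.75
        graph = _two_rule_graph(1.0, 3.0)
        rng = np.random.default_rng(5)
        wins = sum(
            next_event(_free_end(), graph, rng)[0].name == "A" for _ in range(20_000)
        )
        assert abs(wins / 20_000 - 0.75) < 3 * np.sqrt(0.75 * 0.25 / 20_000)

    def test_no_eligible_rule_returns_none(self):
        graph = chain_graph(100.0, 200.0)
        end = _free_end()
        end.locked = Pathway.HR  # chain rules require unlocked FREE... still allowed
        end.phase = Phase.INHIBITED  # no rule from inhibited in the chain graph
        assert next_event(end, graph, np.random.default_rng(0)) is None


class TestDiffuse:
    def test_zero_diffusion_leaves_positions_unchanged(self):
        pts = np.random.default_rng(0).normal(size=(100, 3))
        out = diffuse(pts, 30.0, 0.0, None, np.random.default_rng(1))
        np.testing.assert_array_equal(out, pts)

    def test_msd_matches_brownian_closed_form(self):
        # unbounded medium: <r^2> after time t is 6 D t
        D, t = 0.01, 250.0
        pts = np.zeros((10_000, 3))
        rng = np.random.default_rng(2)
        for _ in range(5):  # five steps of t/5 each
            pts = diffuse(pts, t / 5, D, None, rng)
        msd = (pts**2).sum(axis=1).mean()
        expect = 6 * D * t
        sem = (pts**2).sum(axis=1).std(ddof=1) / np.sqrt(len(pts))
        assert abs(msd - expect) < 4 * sem

    def test_reflecting_boundary_keeps_walkers_inside(self):
        geom = NucleusGeometry("sphere", (1.0, 1.0, 1.0))
        pts = geom.sample_uniform(500, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        for _ in range(200):
            pts = diffuse(pts, 30.0, 1e-3, geom, rng)
            assert geom.contains(pts).all()

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            diffuse(np.zeros((1, 3)), 0.0, 1.0, None, np.random.default_rng(0))


def _eligible_ends(positions) -> list[EndState]:
    ends = []
    for i in range(len(positions)):
        e = EndState(
            end_id=i,
            dsb_id=i // 2,
            index=i,
            partner_index=i ^ 1,
            phase=Phase.FREE,
            occupancy={Protein.KU, Protein.PKCS},
        )
        ends.append(e)
    return ends


class TestAttemptSynapsis:
    def test_far_apart_ends_do_not_pair(self):
        pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        assert attempt_synapsis(_eligible_ends(pos), pos, 0.25) == []

    def test_cognate_ends_at_zero_distance_form_one_pair(self):
        pos = np.zeros((2, 3))
        ends = _eligible_ends(pos)
        assert attempt_synapsis(ends, pos, 0.25) == [(0, 1)]
        assert attempt_synapsis(ends, pos, 0.25, "original_partner_only") == [(0, 1)]

    def test_ineligible_ends_are_ignored(self):
        pos = np.zeros((2, 3))
        ends = _eligible_ends(pos)
        ends[0].occupancy = {Protein.KU}  # DNA-PKcs not loaded
        assert attempt_synapsis(ends, pos, 0.25) == []
        ends[0].occupancy = {Protein.KU, Protein.PKCS}
        ends[0].synapsis_id = 3  # already in a complex
        assert attempt_synapsis(ends, pos, 0.25) == []

    def test_line_of_four_matches_greedy_minimum_distance_oracle(self):
        # spacing 0.1 < radius: greedy picks the closest disjoint pairs
        pos = np.array([[0.0, 0, 0], [0.10, 0, 0], [0.21, 0, 0], [0.33, 0, 0]])
        got = attempt_synapsis(_eligible_ends(pos), pos, 0.25)
        assert got == [(0, 1), (2, 3)]

    def test_original_partner_mode_skips_non_cognate_neighbours(self):
        # ends 1 and 2 are nearest neighbours but belong to different DSBs
        pos = np.array([[0.0, 0, 0], [0.2, 0, 0], [0.21, 0, 0], [0.4, 0, 0]])
        got = attempt_synapsis(
            _eligible_ends(pos), pos, 0.25, "original_partner_only"
        )
        assert sorted(got) == [(0, 1), (2, 3)]

    def test_matches_exhaustive_greedy_oracle_on_random_configs(self):
        rng = np.random.default_rng(6)
        for trial in range(30):
            n = int(rng.integers(2, 7))
            pos = rng.uniform(-0.3, 0.3, size=(n, 3))
            ends = _eligible_ends(pos)
            got = attempt_synapsis(ends, pos, 0.25)
            # oracle: sort all admissible pairs by (distance, ids), greedily
            # accept disjoint ones -- built independently with plain loops
            admissible = []
            for i in range(n):
                for j in range(i + 1, n):
                    dist = float(np.sqrt(((pos[i] - pos[j]) ** 2).sum()))
                    if dist <= 0.25:
                        admissible.append((dist, i, j))
            admissible.sort()
            used: set[int] = set()
            expected = []
            for _, i, j in admissible:
                if i not in used and j not in used:
                    used.update((i, j))
                    expected.append((i, j))
            assert got == expected


class TestRunCell:
    def test_zero_damage_gives_flat_zero_trajectory(self, geometry):
        damage = DamageSet([], dose=0.0, geometry=geometry)
        graph = build_scenario(ScenarioConfig.default("D"))
        tr = run_cell(damage, graph, SimulationConfig(), seed=0)
        assert tr.n_dsb == 0 and tr.n_ends == 0
        for arr in tr.phase_counts.values():
            assert (arr == 0).all()
        assert (tr.dsb_unrepaired == 0).all()

    def test_end_conservation_and_repair_monotonicity(self, small_ensembles):
        for (scenario, deficiency), ens in small_ensembles.items():
            for tr in ens.trajectories:
                total = sum(arr for arr in tr.phase_counts.values())
                assert (total == tr.n_ends).all(), (scenario, deficiency)
                assert (np.diff(tr.dsb_nhej) >= 0).all()
                assert (np.diff(tr.dsb_hr) >= 0).all()
                assert (np.diff(tr.dsb_unrepaired) <= 0).all()

    def test_chain_repair_matches_hypoexponential_cdf(self, geometry):
        # free -> Ku -> repaired with tau1=300, tau2=900: per-end repair time
        # is hypoexponential; compare the empirical fraction on the grid
        tau1, tau2 = 300.0, 900.0
        graph = chain_graph(tau1, tau2)
        sim = SimulationConfig(
            t_end=7200.0, record_dt=30.0, diffusion_coefficient=0.0
        )
        damage = damage_with_n(1000, geometry, seed=8)
        tr = run_cell(damage, graph, sim, seed=9)
        frac = tr.phase_counts[Phase.REPAIRED_NHEJ.value] / tr.n_ends
        expect = hypoexponential_cdf(tr.times, tau1, tau2)
        sem = np.sqrt(expect * (1 - expect) / tr.n_ends)
        assert (np.abs(frac - expect) <= 3 * sem + 1.0 / tr.n_ends).all()

    def test_chain_first_step_waiting_times_are_exponential(self, geometry):
        # Markov check: the per-end first event times follow Exp(tau1)
        graph = chain_graph(120.0, 2000.0)
        sim = SimulationConfig(
            t_end=28_800.0, record_dt=1800.0, diffusion_coefficient=0.0
        )
        damage = damage_with_n(5000, geometry, seed=10)
        tr = run_cell(damage, graph, sim, seed=11)
        waits = np.array([t for t, _, name in tr.event_log if name == "load"])
        res = stats.kstest(waits, stats.expon(scale=120.0).cdf)
        assert len(waits) == tr.n_ends
        assert res.pvalue > 0.01

    def test_scenario_b_lig4_branching_plateau(self, geometry):
        # per-end capture: P(Ku first) = (1/10)/(1/10 + 1/1000); a DSB is
        # repaired (through whole-break HR) iff at least one end resects
        cfg = ScenarioConfig.default(
            "B",
            "Lig4",
            tau_overrides={
                "ku_attach": 10.0,
                "ctip_resect": 1000.0,
                "hr_repair": 600.0,
            },
        )
        graph = build_scenario(cfg)
        sim = SimulationConfig(n_repeats=1, rng_seed=0)
        repaired = 0
        n_cells = 300
        for i in range(n_cells):
            tr = run_cell(damage_with_n(1, geometry, seed=i), graph, sim, seed=5000 + i)
            repaired += int(tr.dsb_nhej[-1] + tr.dsb_hr[-1])
        p_ku = (1 / 10) / (1 / 10 + 1 / 1000)
        expect = 1 - p_ku**2
        tol = 3 * np.sqrt(expect * (1 - expect) / n_cells)
        assert abs(repaired / n_cells - expect) < tol

    def test_event_log_reproducible_for_fixed_seed(self, geometry):
        graph = build_scenario(ScenarioConfig.default("D"))
        damage = damage_with_n(20, geometry, seed=12)
        sim = SimulationConfig()
        a = run_cell(damage, graph, sim, seed=13)
        b = run_cell(damage, graph, sim, seed=13)
        assert a.event_log == b.event_log
        for key in a.phase_counts:
            np.testing.assert_array_equal(a.phase_counts[key], b.phase_counts[key])

    def test_synapsis_search_timeout_releases_isolated_ends(self, geometry):
        # one lone DSB whose partner end is resected away: under Scenario A
        # the timeout strips NHEJ proteins and enforces the HR route
        graph = build_scenario(ScenarioConfig.default("A"))
        sim = SimulationConfig(synapsis_search_timeout=600.0)
        tr = run_cell(damage_with_n(3, geometry, seed=3), graph, sim, seed=20)
        # with a timeout configured no end can stay DNA-PK-loaded forever
        assert (
            tr.phase_counts[Phase.REPAIRED_NHEJ.value][-1]
            + tr.phase_counts[Phase.REPAIRED_HR.value][-1]
            + tr.phase_counts[Phase.SYNAPSIS_STABLE.value][-1]
            + tr.phase_counts[Phase.FREE.value][-1]
            == tr.n_ends
        )


class TestRunEnsemble:
    def test_forced_identical_repeats_have_zero_sem(self, geometry):
        graph = build_scenario(ScenarioConfig.default("C"))
        sim = SimulationConfig(n_repeats=2, rng_seed=1)
        damage = damage_with_n(10, geometry, seed=14)
        ens = run_ensemble(damage, graph, sim, repeat_seeds=[7, 7])
        stacked = ens.stack("dsb_unrepaired")
        np.testing.assert_array_equal(stacked[0], stacked[1])

    def test_master_seed_makes_ensemble_bit_identical(self, geometry):
        graph = build_scenario(ScenarioConfig.default("D"))
        sim = SimulationConfig(n_repeats=3, rng_seed=21)
        src = lambda s: damage_with_n(12, geometry, s)
        a = run_ensemble(src, graph, sim)
        b = run_ensemble(src, graph, sim)
        for series in ("dsb_unrepaired", Protein.KU.value, Phase.FREE.value):
            np.testing.assert_array_equal(a.stack(series), b.stack(series))

    def test_repeats_see_independent_exposures(self, geometry):
        graph = build_scenario(ScenarioConfig.default("C"))
        sim = SimulationConfig(n_repeats=4, rng_seed=2)
        seen = []
        src = lambda s: (seen.append(s), damage_with_n(5, geometry, s))[1]
        run_ensemble(src, graph, sim)
        assert len(set(seen)) == 4

    def test_ensemble_mean_agrees_with_pooled_single_run(self, geometry):
        # toy chain: final unrepaired fraction of a 10x100-DSB ensemble agrees
        # with one pooled 1000-DSB cell within 3 SEM
        graph = chain_graph(600.0, 1200.0)
        sim = SimulationConfig(
            t_end=3600.0, record_dt=30.0, n_repeats=10, rng_seed=3,
            diffusion_coefficient=0.0,
        )
        ens = run_ensemble(lambda s: damage_with_n(100, geometry, s), graph, sim)
        fractions = ens.stack("dsb_unrepaired")[:, -1] / 100.0
        sem_ens = fractions.std(ddof=1) / np.sqrt(len(fractions))
        pooled = run_cell(
            damage_with_n(1000, geometry, seed=15), graph, sim, seed=16
        )
        pooled_frac = pooled.dsb_unrepaired[-1] / 1000.0
        # both estimates are stochastic: combine their standard errors
        sem_pool = np.sqrt(pooled_frac * (1 - pooled_frac) / 1000.0)
        tol = 3 * np.sqrt(sem_ens**2 + sem_pool**2)
        assert abs(fractions.mean() - pooled_frac) <= tol

    def test_scenario_orderings_hold(self, geometry):
        # deficient no-way-back cells barely repair; the entwined scenario
        # accelerates HR entry relative to pure re-competition
        sim = SimulationConfig(n_repeats=10, rng_seed=4)
        src = lambda s: damage_with_n(20, geometry, s)

        def final_shares(scenario, deficiency):
            graph = build_scenario(ScenarioConfig.default(scenario, deficiency))
            ens = run_ensemble(src, graph, sim)
            tot = 20 * sim.n_repeats
            stacked = ens.stack("dsb_unrepaired")
            repaired = 1 - stacked[:, -1].sum() / tot
            hr = ens.stack("dsb_hr")[:, -1].sum() / tot
            return repaired, hr

        b_wt, _ = final_shares("B", "WT")
        b_lig4, _ = final_shares("B", "Lig4")
        _, c_hr = final_shares("C", "WT")
        _, d_hr = final_shares("D", "WT")
        assert b_lig4 < 0.2 * b_wt  # deficient no-way-back: almost no repair
        assert d_hr > c_hr

    def test_invalid_repeat_seed_length_rejected(self, geometry):
        graph = build_scenario(ScenarioConfig.default("C"))
        sim = SimulationConfig(n_repeats=3, rng_seed=1)
        with pytest.raises(ValueError):
            run_ensemble(damage_with_n(2, geometry, 0), graph, sim, repeat_seeds=[1])


class TestSimulationConfig:
    def test_grid_must_divide_evenly(self):
        with pytest.raises(ValueError):
            SimulationConfig(t_end=100.0, record_dt=30.0)
        with pytest.raises(ValueError):
            SimulationConfig(record_dt=30.0, pairing_dt=20.0)

    def test_default_grid_has_8h_of_30s_points(self):
        sim = SimulationConfig()
        assert sim.t_end == 28_800.0 and sim.record_dt == 30.0
        assert sim.n_record == 961  # includes t = 0

    def test_unknown_pairing_mode_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(pairing_mode="closest_enemy")
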