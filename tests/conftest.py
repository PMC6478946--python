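"""Shared fixtures: geometries, toy graphs and reusable small ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from dsbrepair.damage import DamageRecord, DamageSet, NucleusGeometry
from dsbrepair.engine import SimulationConfig, run_ensemble
from dsbrepair.states import (
    Phase,
    Protein,
    ScenarioConfig,
    StateGraph,
    TransitionRule,
    build_scenario,
)

ALL_SCENARIOS = ("A", "B", "C", "D")
ALL_DEFICIENCIES = ("WT", "XLF", "Lig4")


@pytest.fixture(scope="session")
def geometry() -> NucleusGeometry:
    return NucleusGeometry("sphere", (5.0, 5.0, 5.0))


def damage_with_n(n: int, geometry: NucleusGeometry, seed: int) -> DamageSet:
    """A DamageSet with exactly n DSBs at uniform positions."""
    rng = np.random.default_rng(seed)
    pos = geometry.sample_uniform(n, rng)
    records = [
        DamageRecord(dsb_id=i, position=pos[i], end_ids=(2 * i, 2 * i + 1))
        for i in range(n)
    ]
    return DamageSet(records=records, dose=2.0, geometry=geometry)


def chain_graph(tau1: float, tau2: float) -> StateGraph:
    """Two-step linear toy graph: free -> Ku-loaded -> repaired.

    Per-end repair time is the sum of two independent exponential delays
    (hypoexponential); no pairing, no diffusion dependence.
    """
    rules = (
        TransitionRule(
            name="load",
            tau=tau1,
            from_phase=frozenset({Phase.FREE}),
            forbids=frozenset({Protein.KU}),
            gains=frozenset({Protein.KU}),
        ),
        TransitionRule(
            name="finish",
            tau=tau2,
            from_phase=frozenset({Phase.FREE}),
            requires=frozenset({Protein.KU}),
            to_phase=Phase.REPAIRED_NHEJ,
        ),
    )
    cfg = ScenarioConfig.default("C", end_cleaning=False)
    return StateGraph(rules=rules, config=cfg)


def hypoexponential_cdf(t: np.ndarray, tau1: float, tau2: float) -> np.ndarray:
    """CDF of the sum of Exp(tau1) and Exp(tau2), tau1 != tau2."""
    l1, l2 = 1.0 / tau1, 1.0 / tau2
    t = np.asarray(t, dtype=float)
    return 1.0 - (l2 * np.exp(-l1 * t) - l1 * np.exp(-l2 * t)) / (l2 - l1)


@pytest.fixture(scope="session")
def small_ensembles(geometry):
    """One small ensemble per (scenario, deficiency): 15 DSB, 5 repeats."""
    sim = SimulationConfig(n_repeats=5, rng_seed=7)
    out = {}
    for scenario in ALL_SCENARIOS:
        for deficiency in ALL_DEFICIENCIES:
            graph = build_scenario(ScenarioConfig.default(scenario, deficiency))
            out[(scenario, deficiency)] = run_ensemble(
                lambda s: damage_with_n(15, geometry, s), graph, sim
            )
    return out
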