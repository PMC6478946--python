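"""Per-end repair states and scenario transition graphs.

Each DSB end carries a *phase* (free, inhibited, in an unstable or stable
synaptic complex, or repaired by NHEJ/HR), a set of protein *occupancy* flags
(Ku70/80, DNA-PKcs, MRN, RNF138, CtIP-resected) and a *locked pathway* label.
Progression between states is governed by :class:`TransitionRule` objects,
each with a mean waiting time ``tau``; the kinetic engine races exponential
clocks over the eligible rules (the waiting-time law is pluggable at the
engine level, exponential by default).

Four repair-choice scenarios are expressed as different rule sets over the
same state vocabulary:

A. *NHEJ first* -- every end starts down NHEJ; only dissociation of an
   unstable synaptic complex releases it, and then resection-mediated repair
   (HR) is enforced, with no second NHEJ attempt.
B. *No way back* -- the first protein to attach (Ku, or CtIP via resection)
   locks the end into the corresponding pathway; no cross-over ever.
C. *Continuous competition* -- every dissociation returns the end to a naked
   free state where Ku attachment and resection entry compete again.
D. *Entwined pathway* -- Scenario C plus three literature mechanisms:
   MRN co-localisation with Ku/DNA-PK/synaptic states, RNF138 recruitment in
   an MRN-dependent manner with RNF138-mediated stripping of Ku and DNA-PKcs
   back to an MRN-attached end, and MRN-independent resection of naked ends.
   NHEJ-protein dissociation from a co-localised end falls back to an end
   with MRN still attached (MRN is modelled as persistent once loaded).

Lock-in points: HR locks at CtIP resection (canonical NHEJ cannot act on a
resected end); NHEJ locks at synaptic-complex stabilisation, the last
reversible NHEJ step (in Scenario B the initial Ku attachment already locks).

Protein deficiencies delete single progression rules: XLF-deficient cells
lose synaptic stabilisation, Lig4-deficient cells lose final ligation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

__all__ = [
    "Phase",
    "Protein",
    "Pathway",
    "ABSORBING_PHASES",
    "TransitionRule",
    "Mechanisms",
    "ScenarioConfig",
    "StateGraph",
    "DEFAULT_TAU_TABLE",
    "build_scenario",
    "apply_deficiency",
    "validate_graph",
    "reachable_states",
    "to_dot",
    "rule_eligible",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Scenario configuration is incomplete or inconsistent."""


class Phase(str, Enum):
    INHIBITED = "inhibited"
    FREE = "free"
    SYNAPSIS_UNSTABLE = "in_synapsis_unstable"
    SYNAPSIS_STABLE = "in_synapsis_stable"
    REPAIRED_NHEJ = "repaired_nhej"
    REPAIRED_HR = "repaired_hr"


class Protein(str, Enum):
    KU = "Ku"
    PKCS = "DNA-PKcs"
    MRN = "MRN"
    RNF138 = "RNF138"
    RESECTED = "CtIP"  # resected(CtIP) flag; commits the end to HR


class Pathway(str, Enum):
    NONE = "none"
    NHEJ = "NHEJ"
    HR = "HR"


ABSORBING_PHASES = frozenset({Phase.REPAIRED_NHEJ, Phase.REPAIRED_HR})

_ALL_PATHWAYS = frozenset(Pathway)


@dataclass(frozen=True)
class TransitionRule:
    """One allowed state transition with its mean waiting time.

    ``kind`` is ``"unimolecular"`` (acts on a single end) or ``"pairing"``
    (acts on a formed synaptic complex, i.e. on both member ends at the same
    event time).  The *from* side is a guard (phase set, required/forbidden
    occupancy, allowed lock labels); the *to* side is a mutation (new phase,
    gained/lost flags, optional new lock).  ``set_lock=None`` keeps the
    current lock.  ``lock_in`` marks the irreversible pathway-commitment
    rules.  ``repairs_partner`` gives whole-break semantics to the terminal
    HR step: completing resection-mediated repair resolves the cognate DSB,
    so the partner end is marked repaired at the same event time.
    """

    name: str
    tau: float
    kind: str = "unimolecular"
    from_phase: frozenset = frozenset({Phase.FREE})
    requires: frozenset = frozenset()
    forbids: frozenset = frozenset()
    locked_allowed: frozenset = _ALL_PATHWAYS
    to_phase: Phase | None = None
    gains: frozenset = frozenset()
    loses: frozenset = frozenset()
    set_lock: Pathway | None = None
    lock_in: bool = False
    repairs_partner: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("unimolecular", "pairing"):
            raise ValueError(f"unknown rule kind {self.kind!r}")


def rule_eligible(rule: TransitionRule, phase: Phase, occupancy, locked: Pathway) -> bool:
    """Guard check for a unimolecular rule against an end's state."""
    return (
        phase in rule.from_phase
        and rule.requires <= occupancy
        and not (rule.forbids & occupancy)
        and locked in rule.locked_allowed
    )


@dataclass(frozen=True)
class Mechanisms:
    """Scenario-D mechanism toggles (all off reduces D to C)."""

    mrn_colocalisation: bool = False
    rnf138_removal: bool = False
    mrn_independent_resection: bool = False


#: Default mean waiting times (seconds) per rule name.  The ordinal structure
#: follows the reported recruitment hierarchy: Ku and DNA-PKcs fast, MRN
#: slower, RNF138 slowest with tau_RNF138 = 80 x tau_Ku = 3 x tau_MRN.  The
#: absolute values are package defaults meant to be refined by calibration
#: against recruitment data (see calibration module and docs/methods.md).
DEFAULT_TAU_TABLE: dict[str, float] = {
    "end_cleaning": 10.0,
    "ku_attach": 15.0,
    "pkcs_attach": 15.0,
    "synapsis_stabilise": 1800.0,
    "synapsis_ligate": 3600.0,
    "synapsis_dissociate": 3600.0,
    "ctip_resect": 2000.0,
    "hr_repair": 14_400.0,  # tau_RR: lumped post-resection HR completion (free parameter)
    "mrn_attach": 1200.0 / 3.0,
    "rnf138_attach": 1200.0,
    "rnf138_strip": 120.0,
    "ku_release": 2400.0,
    "pkcs_release": 2400.0,
}

_SCENARIOS = ("A", "B", "C", "D")
_DEFICIENCIES = ("WT", "XLF", "Lig4")
_DEFICIENCY_DELETIONS = {
    "WT": (),
    "XLF": ("synapsis_stabilise",),
    "Lig4": ("synapsis_ligate",),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario id, deficiency, mechanism toggles and time-constant table.

    ``tau_table`` must cover every rule the scenario uses;
    :meth:`default` merges user overrides onto :data:`DEFAULT_TAU_TABLE`.
    ``tau_RR`` (the free post-resection HR time constant) is the
    ``"hr_repair"`` entry.
    """

    scenario: str = "D"
    deficiency: str = "WT"
    mechanisms: Mechanisms | None = None
    tau_table: dict = field(default_factory=lambda: dict(DEFAULT_TAU_TABLE))
    end_cleaning: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.deficiency not in _DEFICIENCIES:
            raise ConfigurationError(f"unknown deficiency {self.deficiency!r}")
        if self.mechanisms is None:
            default_on = self.scenario == "D"
            object.__setattr__(
                self,
                "mechanisms",
                Mechanisms(default_on, default_on, default_on),
            )

    @classmethod
    def default(
        cls,
        scenario: str,
        deficiency: str = "WT",
        tau_overrides: dict | None = None,
        mechanisms: Mechanisms | None = None,
        end_cleaning: bool = True,
    ) -> "ScenarioConfig":
        tau = dict(DEFAULT_TAU_TABLE)
        if tau_overrides:
            unknown = set(tau_overrides) - set(DEFAULT_TAU_TABLE)
            if unknown:
                raise ConfigurationError(
                    f"unknown rule names in tau overrides: {sorted(unknown)}"
                )
            tau.update(tau_overrides)
        return cls(
            scenario=scenario,
            deficiency=deficiency,
            mechanisms=mechanisms,
            tau_table=tau,
            end_cleaning=end_cleaning,
        )

    @property
    def tau_RR(self) -> float:
        return self.tau_table["hr_repair"]


@dataclass(frozen=True)
class StateGraph:
    """A scenario's full transition-rule set plus bookkeeping the engine needs.

    ``dissociation_lock`` records what happens to the pathway label of an end
    forcibly extracted from a synaptic complex (used when whole-break HR
    repair dissolves the partner's synapsis): ``None`` keeps the current
    lock (Scenario B), otherwise the label is set to the given value
    (Scenario A enforces HR, C/D reset to none).
    """

    rules: tuple
    config: ScenarioConfig
    dissociation_lock: Pathway | None = Pathway.NONE

    @property
    def unimolecular(self) -> tuple:
        return tuple(r for r in self.rules if r.kind == "unimolecular")

    @property
    def pairing(self) -> tuple:
        return tuple(r for r in self.rules if r.kind == "pairing")

    @property
    def has_pairing(self) -> bool:
        return any(r.kind == "pairing" for r in self.rules)

    @property
    def initial_phase(self) -> Phase:
        return Phase.INHIBITED if any(r.name == "end_cleaning" for r in self.rules) else Phase.FREE

    def rule(self, name: str) -> TransitionRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)


def _scenario_rules(cfg: ScenarioConfig, tau: dict[str, float]) -> list[TransitionRule]:
    s = cfg.scenario
    m = cfg.mechanisms
    rules: list[TransitionRule] = []
    FREE = frozenset({Phase.FREE})
    UNSTABLE = frozenset({Phase.SYNAPSIS_UNSTABLE})
    STABLE = frozenset({Phase.SYNAPSIS_STABLE})
    KU, PKCS, MRN, RNF, RES = (
        Protein.KU,
        Protein.PKCS,
        Protein.MRN,
        Protein.RNF138,
        Protein.RESECTED,
    )

    if cfg.end_cleaning:
        rules.append(
            TransitionRule(
                name="end_cleaning",
                tau=tau["end_cleaning"],
                from_phase=frozenset({Phase.INHIBITED}),
                to_phase=Phase.FREE,
            )
        )

    # --- NHEJ entry: Ku attachment -------------------------------------
    if s == "B":
        ku_locked = frozenset({Pathway.NONE, Pathway.NHEJ})
        ku_set_lock, ku_lock_in = Pathway.NHEJ, True
    else:
        ku_locked = frozenset({Pathway.NONE})
        ku_set_lock, ku_lock_in = None, False
    rules.append(
        TransitionRule(
            name="ku_attach",
            tau=tau["ku_attach"],
            from_phase=FREE,
            forbids=frozenset({KU, RES, RNF}),
            locked_allowed=ku_locked,
            gains=frozenset({KU}),
            set_lock=ku_set_lock,
            lock_in=ku_lock_in,
        )
    )
    rules.append(
        TransitionRule(
            name="pkcs_attach",
            tau=tau["pkcs_attach"],
            from_phase=FREE,
            requires=frozenset({KU}),
            forbids=frozenset({PKCS}),
            locked_allowed=frozenset({Pathway.NONE, Pathway.NHEJ}),
            gains=frozenset({PKCS}),
        )
    )

    # --- synaptic complex (pairing rules; formation itself is spatial) --
    rules.append(
        TransitionRule(
            name="synapsis_stabilise",
            tau=tau["synapsis_stabilise"],
            kind="pairing",
            from_phase=UNSTABLE,
            to_phase=Phase.SYNAPSIS_STABLE,
            loses=frozenset({KU, PKCS}),  # NHEJ proteins persist until stabilisation
            set_lock=Pathway.NHEJ,
            lock_in=True,
        )
    )
    rules.append(
        TransitionRule(
            name="synapsis_ligate",
            tau=tau["synapsis_ligate"],
            kind="pairing",
            from_phase=STABLE,
            to_phase=Phase.REPAIRED_NHEJ,
        )
    )
    if s == "A":
        dissoc_lock: Pathway | None = Pathway.HR  # HR enforced after NHEJ failure
        dissoc_lock_in = True
    elif s == "B":
        dissoc_lock = None  # end stays locked into NHEJ
        dissoc_lock_in = False
    else:
        dissoc_lock = Pathway.NONE  # re-competition
        dissoc_lock_in = False
    rules.append(
        TransitionRule(
            name="synapsis_dissociate",
            tau=tau["synapsis_dissociate"],
            kind="pairing",
            from_phase=UNSTABLE,
            to_phase=Phase.FREE,
            loses=frozenset({KU, PKCS}),  # MRN, if co-localised, stays attached
            set_lock=dissoc_lock,
            lock_in=dissoc_lock_in,
        )
    )

    # --- resection entry (HR lock-in) ----------------------------------
    if s == "A":
        resect_locked = frozenset({Pathway.HR})  # reachable only after synapsis failure
    else:
        resect_locked = frozenset({Pathway.NONE})
    resect_requires = frozenset()
    if s == "D" and m.mrn_colocalisation and not m.mrn_independent_resection:
        resect_requires = frozenset({MRN})
    rules.append(
        TransitionRule(
            name="ctip_resect",
            tau=tau["ctip_resect"],
            from_phase=FREE,
            requires=resect_requires,
            forbids=frozenset({KU, PKCS, RES}),
            locked_allowed=resect_locked,
            gains=frozenset({RES}),
            set_lock=Pathway.HR,
            lock_in=True,
        )
    )
    rules.append(
        TransitionRule(
            name="hr_repair",
            tau=tau["hr_repair"],
            from_phase=FREE,
            requires=frozenset({RES}),
            locked_allowed=frozenset({Pathway.HR}),
            to_phase=Phase.REPAIRED_HR,
            repairs_partner=True,
        )
    )

    # --- Scenario D mechanisms ------------------------------------------
    if s == "D" and m.mrn_colocalisation:
        rules.append(
            TransitionRule(
                name="mrn_attach",
                tau=tau["mrn_attach"],
                from_phase=frozenset(
                    {Phase.FREE, Phase.SYNAPSIS_UNSTABLE, Phase.SYNAPSIS_STABLE}
                ),
                forbids=frozenset({MRN, RES}),
                gains=frozenset({MRN}),
            )
        )
        # NHEJ-protein dissociation from co-localised states: the end falls
        # back to an MRN-attached end.
        rules.append(
            TransitionRule(
                name="pkcs_release",
                tau=tau["pkcs_release"],
                from_phase=FREE,
                requires=frozenset({PKCS, MRN}),
                loses=frozenset({PKCS}),
            )
        )
        rules.append(
            TransitionRule(
                name="ku_release",
                tau=tau["ku_release"],
                from_phase=FREE,
                requires=frozenset({KU, MRN}),
                forbids=frozenset({PKCS}),
                loses=frozenset({KU}),
            )
        )
    if s == "D" and m.rnf138_removal:
        # RNF138 is recruited MRN-dependently wherever MRN sits, including
        # alongside an ongoing NHEJ attempt; once attached it prohibits Ku
        # (re-)attachment, and it strips Ku/DNA-PKcs from free ends, leaving
        # an MRN/RNF138-marked end open for resection.
        rules.append(
            TransitionRule(
                name="rnf138_attach",
                tau=tau["rnf138_attach"],
                from_phase=frozenset(
                    {Phase.FREE, Phase.SYNAPSIS_UNSTABLE, Phase.SYNAPSIS_STABLE}
                ),
                requires=frozenset({MRN}),
                forbids=frozenset({RNF, RES}),
                gains=frozenset({RNF}),
            )
        )
        rules.append(
            TransitionRule(
                name="rnf138_strip",
                tau=tau["rnf138_strip"],
                from_phase=FREE,
                requires=frozenset({RNF, KU}),
                loses=frozenset({KU, PKCS}),
            )
        )
    return rules


def build_scenario(config: ScenarioConfig) -> StateGraph:
    """Build the transition graph for a scenario/deficiency configuration.

    Raises :class:`ConfigurationError` listing missing rule names if the
    time-constant table does not cover the scenario's rules.
    """
    # Determine required rule names first so an incomplete table fails fast.
    probe = dict.fromkeys(DEFAULT_TAU_TABLE, 1.0)
    required = [r.name for r in _scenario_rules(config, probe)]
    missing = [name for name in required if name not in config.tau_table]
    if missing:
        raise ConfigurationError(
            f"tau_table incomplete for scenario {config.scenario}: missing {missing}"
        )
    bad = [name for name in required if config.tau_table[name] <= 0]
    if bad:
        raise ConfigurationError(f"tau must be > 0 for rules {bad}")

    rules = _scenario_rules(config, config.tau_table)
    if config.scenario == "A":
        dissociation_lock: Pathway | None = Pathway.HR
    elif config.scenario == "B":
        dissociation_lock = None
    else:
        dissociation_lock = Pathway.NONE
    graph = StateGraph(
        rules=tuple(rules), config=config, dissociation_lock=dissociation_lock
    )
    if config.deficiency != "WT":
        graph = apply_deficiency(graph, config.deficiency)
    return graph


def apply_deficiency(graph: StateGraph, deficiency: str) -> StateGraph:
    """Delete the progression rules a protein deficiency removes.

    XLF-deficient cells lose synaptic-complex stabilisation; Lig4-deficient
    cells lose final ligation of the stable synaptic complex.  ``"WT"``
    returns the graph unchanged.
    """
    if deficiency not in _DEFICIENCY_DELETIONS:
        raise ConfigurationError(f"unknown deficiency {deficiency!r}")
    deleted = _DEFICIENCY_DELETIONS[deficiency]
    if not deleted:
        return graph
    rules = tuple(r for r in graph.rules if r.name not in deleted)
    cfg = replace(graph.config, deficiency=deficiency)
    return StateGraph(rules=rules, config=cfg, dissociation_lock=graph.dissociation_lock)


# --------------------------------------------------------------------------
# Abstract reachability and diagnostics

_AbstractState = tuple  # (Phase, frozenset[Protein], Pathway)


def _apply_abstract(rule: TransitionRule, state: _AbstractState) -> _AbstractState:
    phase, occ, locked = state
    new_phase = rule.to_phase if rule.to_phase is not None else phase
    new_occ = frozenset((occ | rule.gains) - rule.loses)
    if new_phase in ABSORBING_PHASES:
        new_occ = frozenset()
    new_lock = rule.set_lock if rule.set_lock is not None else locked
    return (new_phase, new_occ, new_lock)


def reachable_states(
    graph: StateGraph, initial: Iterable[_AbstractState] | None = None
) -> dict[_AbstractState, list[tuple[_AbstractState, str, _AbstractState]]]:
    """Breadth-first closure over the abstract per-end state space.

    States are (phase, occupancy, locked_pathway) triples.  Synaptic-complex
    formation is abstracted as a pseudo-transition available to any free end
    carrying both Ku and DNA-PKcs (spatial pairing is the engine's job).
    Returns the set of reachable states mapped to their outgoing edges
    ``(from, rule_name, to)``.
    """
    if initial is None:
        initial = [(graph.initial_phase, frozenset(), Pathway.NONE)]
    frontier = list(initial)
    seen: dict[_AbstractState, list] = {s: [] for s in frontier}
    while frontier:
        state = frontier.pop()
        phase, occ, locked = state
        edges = seen[state]
        candidates: list[tuple[str, _AbstractState]] = []
        for rule in graph.rules:
            if rule.kind == "unimolecular":
                if rule_eligible(rule, phase, occ, locked):
                    candidates.append((rule.name, _apply_abstract(rule, state)))
            else:  # pairing rule: guard on the synapsis phase only
                if phase in rule.from_phase:
                    candidates.append((rule.name, _apply_abstract(rule, state)))
        if (
            phase is Phase.FREE
            and Protein.KU in occ
            and Protein.PKCS in occ
        ):
            candidates.append(
                ("synapsis_formation", (Phase.SYNAPSIS_UNSTABLE, occ, locked))
            )
        for name, target in candidates:
            edges.append((state, name, target))
            if target not in seen:
                seen[target] = []
                frontier.append(target)
    return seen


def validate_graph(graph: StateGraph) -> list[str]:
    """Structural diagnostics for a scenario graph (never raises).

    Reports empty rule lists, non-positive time constants, rules departing
    from absorbing phases, and repaired phases that are unreachable from the
    initial naked-end state (expected for some deficient graphs, e.g.
    ``repaired_nhej`` without the ligation rule).
    """
    diagnostics: list[str] = []
    if not graph.rules:
        diagnostics.append("no rules")
        return diagnostics
    for rule in graph.rules:
        if not rule.tau > 0:
            diagnostics.append(f"rule {rule.name}: tau must be > 0 (got {rule.tau})")
        if rule.from_phase & ABSORBING_PHASES:
            diagnostics.append(f"rule {rule.name}: originates from an absorbing phase")
        if rule.to_phase in ABSORBING_PHASES and rule.from_phase & ABSORBING_PHASES:
            diagnostics.append(f"rule {rule.name}: absorbing-to-absorbing")
    reached = reachable_states(graph)
    phases = {s[0] for s in reached}
    for phase in (Phase.REPAIRED_NHEJ, Phase.REPAIRED_HR):
        if phase not in phases:
            diagnostics.append(f"unreachable: {phase.value}")
    return diagnostics


def to_dot(graph: StateGraph) -> str:
    """Export the reachable abstract state graph as GraphViz DOT for audit."""

    def label(state: _AbstractState) -> str:
        phase, occ, locked = state
        flags = ",".join(sorted(p.value for p in occ)) or "-"
        return f"{phase.value}\\n[{flags}] lock={locked.value}"

    reached = reachable_states(graph)
    ids = {state: f"s{i}" for i, state in enumerate(sorted(reached, key=repr))}
    lines = [
        "digraph scenario {",
        "  rankdir=LR;",
        f'  label="scenario {graph.config.scenario} ({graph.config.deficiency})";',
    ]
    for state, sid in ids.items():
        shape = "doublecircle" if state[0] in ABSORBING_PHASES else "box"
        lines.append(f'  {sid} [label="{label(state)}", shape={shape}];')
    for state, edges in reached.items():
        for src, name, dst in edges:
            lines.append(f'  {ids[src]} -> {ids[dst]} [label="{name}"];')
    lines.append("}")
    return "\n".join(lines)
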