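"""Continuous-time kinetic Monte Carlo engine for DSB-end populations.

The engine advances every DSB end of a damaged nucleus through a scenario
:class:`~dsbrepair.states.StateGraph`.  Protein-state progression is
event-driven: each eligible transition rule carries an independent
exponential clock with mean ``tau`` and the earliest clock fires (so the
selection probability of rule *i* among eligible rules is
``(1/tau_i) / sum_j (1/tau_j)``, the min-of-exponentials law).  Spatial
behaviour -- Brownian diffusion of free ends and synaptic-complex formation
between DNA-PKcs-loaded ends within a capture radius -- is evaluated on a
fixed sub-step (default: the 30 s recording interval), giving a hybrid
event-driven/discrete-space-update scheme.  The coupling error is bounded by
the sub-step: a pair that drifts into capture range can join at most one
sub-step late.

State counts are recorded on a fixed grid (defaults: 8 h horizon, 30 s
interval) and every run is bit-reproducible for a fixed seed.  Ends with no
eligible rule (for example NHEJ-locked ends in a ligation-deficient cell)
are flagged stalled and persist as unrepaired.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .damage import DamageSet, NucleusGeometry
from .states import (
    ABSORBING_PHASES,
    Pathway,
    Phase,
    Protein,
    StateGraph,
    TransitionRule,
    rule_eligible,
)

__all__ = [
    "SimulationConfig",
    "EndState",
    "CellTrajectory",
    "EnsembleResult",
    "sample_waiting_time",
    "next_event",
    "diffuse",
    "attempt_synapsis",
    "run_cell",
    "run_ensemble",
]


def sample_waiting_time(tau: float, rng: np.random.Generator) -> float:
    """Draw one waiting time from Exponential(mean = tau)."""
    if not tau > 0:
        raise ValueError("tau must be > 0")
    return float(rng.exponential(tau))


@dataclass
class SimulationConfig:
    """Run-length, recording, spatial and ensemble parameters.

    Defaults follow the benchmark protocol: an 8 h (28 800 s) horizon with
    the simulation state recorded every 30 s, repair ensembles of 50 repeats
    (recruitment ensembles use 250).  The diffusion coefficient and capture
    radius are free spatial parameters of this implementation (chromatin-end
    mobility scale); see docs/methods.md.
    """

    t_end: float = 28_800.0
    record_dt: float = 30.0
    n_repeats: int = 50
    rng_seed: int = 0
    diffusion_coefficient: float = 1e-5  # um^2/s (chromatin-locus mobility scale)
    capture_radius: float = 0.25  # um
    pairing_mode: str = "any_eligible"  # or "original_partner_only"
    pairing_dt: float | None = None  # spatial sub-step; default = record_dt
    synapsis_search_timeout: float | None = None  # optional per-end NHEJ failure route
    waiting_time_sampler: Callable[[float, np.random.Generator], float] = field(
        default=sample_waiting_time, repr=False
    )

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.record_dt <= 0:
            raise ValueError("t_end and record_dt must be > 0")
        n = self.t_end / self.record_dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_end must be an integer multiple of record_dt")
        if self.pairing_dt is None:
            self.pairing_dt = self.record_dt
        k = self.record_dt / self.pairing_dt
        if abs(k - round(k)) > 1e-9 or self.pairing_dt <= 0:
            raise ValueError("record_dt must be an integer multiple of pairing_dt")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.pairing_mode not in ("any_eligible", "original_partner_only"):
            raise ValueError(f"unknown pairing_mode {self.pairing_mode!r}")
        if self.diffusion_coefficient < 0 or self.capture_radius <= 0:
            raise ValueError("diffusion_coefficient >= 0 and capture_radius > 0 required")

    @property
    def n_record(self) -> int:
        return int(round(self.t_end / self.record_dt)) + 1  # grid includes t = 0


@dataclass
class EndState:
    """Mutable per-end simulation state."""

    end_id: int
    dsb_id: int
    index: int
    partner_index: int
    phase: Phase
    occupancy: set = field(default_factory=set)
    locked: Pathway = Pathway.NONE
    synapsis_id: int | None = None
    version: int = 0
    stalled: bool = False


@dataclass
class _Synapsis:
    id: int
    end_indices: tuple[int, int]
    phase: Phase
    version: int = 0


def next_event(
    end: EndState,
    graph: StateGraph,
    rng: np.random.Generator,
    sampler: Callable[[float, np.random.Generator], float] = sample_waiting_time,
) -> tuple[TransitionRule, float] | None:
    """Race exponential clocks over the eligible unimolecular rules.

    Returns ``(rule, waiting_time)`` for the earliest clock, or ``None`` if
    no rule is eligible (the end is stalled and counts as unrepaired).
    """
    if end.phase in ABSORBING_PHASES:
        return None
    best: tuple[TransitionRule, float] | None = None
    for rule in graph.unimolecular:
        if rule_eligible(rule, end.phase, end.occupancy, end.locked):
            wt = sampler(rule.tau, rng)
            if best is None or wt < best[1]:
                best = (rule, wt)
    return best


def diffuse(
    positions: np.ndarray,
    dt: float,
    diffusion_coefficient: float,
    geometry: NucleusGeometry | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Brownian step: Gaussian displacement of variance 2*D*dt per axis.

    With a geometry, steps are reflected back inside the nucleus; with
    ``geometry=None`` the medium is unbounded.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    pts = np.asarray(positions, dtype=float)
    if diffusion_coefficient == 0 or pts.size == 0:
        return pts.copy()
    sigma = math.sqrt(2.0 * diffusion_coefficient * dt)
    moved = pts + rng.normal(0.0, sigma, size=pts.shape)
    if geometry is not None:
        moved = geometry.reflect_inside(moved)
    return moved


def _pairing_eligible(end: EndState) -> bool:
    return (
        end.phase is Phase.FREE
        and Protein.KU in end.occupancy
        and Protein.PKCS in end.occupancy
        and end.synapsis_id is None
    )


def attempt_synapsis(
    ends: Sequence[EndState],
    positions: np.ndarray,
    capture_radius: float,
    pairing_mode: str = "any_eligible",
    candidates: Sequence[int] | None = None,
) -> list[tuple[int, int]]:
    """Propose synaptic pairs among DNA-PKcs-loaded, unsynapsed free ends.

    ``any_eligible`` performs greedy nearest-neighbour matching over all
    candidate pairs within ``capture_radius`` (ties broken by lower end id),
    which permits mispaired geometry and isolated ends;
    ``original_partner_only`` joins only cognate end pairs.  Returns index
    pairs into ``ends``.
    """
    if candidates is None:
        candidates = [e.index for e in ends if _pairing_eligible(e)]
    else:
        candidates = [i for i in candidates if _pairing_eligible(ends[i])]
    if len(candidates) < 2:
        return []
    pairs: list[tuple[float, int, int, int, int]] = []
    if pairing_mode == "original_partner_only":
        seen = set(candidates)
        for i in candidates:
            j = ends[i].partner_index
            if j in seen and i < j:
                d = float(np.linalg.norm(positions[i] - positions[j]))
                if d <= capture_radius:
                    pairs.append((d, ends[i].end_id, ends[j].end_id, i, j))
    else:
        pos = positions[candidates]
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((delta * delta).sum(axis=-1))
        m = len(candidates)
        for a in range(m):
            for b in range(a + 1, m):
                if dist[a, b] <= capture_radius:
                    i, j = candidates[a], candidates[b]
                    ida, idb = ends[i].end_id, ends[j].end_id
                    if ida > idb:
                        i, j, ida, idb = j, i, idb, ida
                    pairs.append((float(dist[a, b]), ida, idb, i, j))
    pairs.sort()
    taken: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, _, _, i, j in pairs:
        if i in taken or j in taken:
            continue
        taken.add(i)
        taken.add(j)
        matched.append((i, j))
    return matched


@dataclass
class CellTrajectory:
    """State counts of one simulated cell on the recording grid.

    ``phase_counts``/``protein_counts`` map series names to integer count
    arrays over ``times``; the three ``dsb_*`` arrays partition the DSBs into
    not-yet-repaired, NHEJ-repaired and HR-repaired (a DSB counts repaired
    once both of its ends sit in an absorbing repaired phase).
    """

    times: np.ndarray
    phase_counts: dict[str, np.ndarray]
    protein_counts: dict[str, np.ndarray]
    dsb_unrepaired: np.ndarray
    dsb_nhej: np.ndarray
    dsb_hr: np.ndarray
    n_dsb: int
    n_ends: int
    event_log: list[tuple[float, int, str]]
    final_phases: list[Phase]


_TIMEOUT_RULE = "synapsis_search_timeout"


class _CellSim:
    """One cell's event loop (internal)."""

    def __init__(
        self,
        damage: DamageSet,
        graph: StateGraph,
        sim: SimulationConfig,
        rng: np.random.Generator,
    ) -> None:
        self.graph = graph
        self.sim = sim
        self.rng = rng
        self.sampler = sim.waiting_time_sampler
        self.geometry = damage.geometry
        self.n_dsb = damage.n_dsb

        self.ends: list[EndState] = []
        pos = []
        initial_phase = graph.initial_phase
        for k, rec in enumerate(damage.records):
            i, j = 2 * k, 2 * k + 1
            self.ends.append(
                EndState(rec.end_ids[0], rec.dsb_id, i, j, initial_phase)
            )
            self.ends.append(
                EndState(rec.end_ids[1], rec.dsb_id, j, i, initial_phase)
            )
            pos.append(rec.position)
            pos.append(rec.position)
        self.positions = (
            np.array(pos, dtype=float) if pos else np.empty((0, 3))
        )

        self.phase_counter = {p: 0 for p in Phase}
        self.phase_counter[initial_phase] = len(self.ends)
        self.protein_counter = {p: 0 for p in Protein}
        self.dsb_absorbed = [0] * self.n_dsb
        self.n_unrepaired = self.n_dsb
        self.n_nhej = 0
        self.n_hr = 0

        self.heap: list = []
        self.seq = 0
        self.synapses: dict[int, _Synapsis] = {}
        self.next_syn_id = 0
        self.log: list[tuple[float, int, str]] = []

        nrec = sim.n_record
        self.rec_phase = {p.value: np.zeros(nrec, dtype=np.int64) for p in Phase}
        self.rec_protein = {p.value: np.zeros(nrec, dtype=np.int64) for p in Protein}
        self.rec_unrep = np.zeros(nrec, dtype=np.int64)
        self.rec_nhej = np.zeros(nrec, dtype=np.int64)
        self.rec_hr = np.zeros(nrec, dtype=np.int64)

    # -- scheduling -----------------------------------------------------

    def _push(self, t: float, kind: int, idx: int, version: int, rule) -> None:
        self.seq += 1
        heapq.heappush(self.heap, (t, self.seq, kind, idx, version, rule))

    def _schedule_end(self, e: EndState, t: float) -> None:
        if e.phase in ABSORBING_PHASES:
            return
        ev = next_event(e, self.graph, self.rng, self.sampler)
        timeout = self.sim.synapsis_search_timeout
        if (
            timeout is not None
            and _pairing_eligible(e)
            and (ev is None or ev[1] > timeout)
        ):
            # optional failure route for ends that never find a partner
            self._push(t + timeout, 0, e.index, e.version, _TIMEOUT_RULE)
            e.stalled = False
            return
        if ev is None:
            e.stalled = True
            return
        e.stalled = False
        rule, wt = ev
        self._push(t + wt, 0, e.index, e.version, rule)

    def _schedule_syn(self, syn: _Synapsis, t: float) -> None:
        best = None
        for rule in self.graph.pairing:
            if syn.phase in rule.from_phase:
                wt = self.sampler(rule.tau, self.rng)
                if best is None or wt < best[1]:
                    best = (rule, wt)
        if best is not None:
            self._push(t + best[1], 1, syn.id, syn.version, best[0])

    # -- mutations ------------------------------------------------------

    def _set_phase(self, e: EndState, new: Phase) -> None:
        if new is not e.phase:
            self.phase_counter[e.phase] -= 1
            self.phase_counter[new] += 1
            e.phase = new

    def _occ_update(self, e: EndState, gains, loses) -> None:
        for p in loses:
            if p in e.occupancy:
                e.occupancy.discard(p)
                self.protein_counter[p] -= 1
        for p in gains:
            if p not in e.occupancy:
                e.occupancy.add(p)
                self.protein_counter[p] += 1

    def _on_absorbed(self, e: EndState) -> None:
        d = self._dsb_index(e)
        self.dsb_absorbed[d] += 1
        if self.dsb_absorbed[d] == 2:
            self.n_unrepaired -= 1
            partner = self.ends[e.partner_index]
            if e.phase is Phase.REPAIRED_HR or partner.phase is Phase.REPAIRED_HR:
                self.n_hr += 1
            else:
                self.n_nhej += 1

    def _dsb_index(self, e: EndState) -> int:
        return e.index // 2

    def _apply_uni(self, e: EndState, rule, t: float) -> None:
        if rule == _TIMEOUT_RULE:
            # unpaired DNA-PK-loaded end gives up: same fallback as synapsis
            # dissociation (strip NHEJ proteins; lock per scenario semantics)
            self._occ_update(e, (), (Protein.KU, Protein.PKCS))
            if self.graph.dissociation_lock is not None:
                e.locked = self.graph.dissociation_lock
            self.log.append((t, e.end_id, _TIMEOUT_RULE))
            e.version += 1
            self._schedule_end(e, t)
            return
        self._occ_update(e, rule.gains, rule.loses)
        if rule.set_lock is not None:
            e.locked = rule.set_lock
        if rule.to_phase is not None:
            self._set_phase(e, rule.to_phase)
        if e.phase in ABSORBING_PHASES:
            self._occ_update(e, (), tuple(e.occupancy))
        self.log.append((t, e.end_id, rule.name))
        e.version += 1
        if e.phase in ABSORBING_PHASES:
            self._on_absorbed(e)
            if rule.repairs_partner:
                self._repair_partner(e, t)
        else:
            self._schedule_end(e, t)

    def _repair_partner(self, e: EndState, t: float) -> None:
        # Whole-break HR: completing resection-mediated repair resolves the
        # cognate DSB, so the partner end is repaired at the same event time.
        p = self.ends[e.partner_index]
        if p.phase in ABSORBING_PHASES:
            return
        if p.synapsis_id is not None:
            syn = self.synapses.pop(p.synapsis_id)
            oi = syn.end_indices[0] if syn.end_indices[1] == p.index else syn.end_indices[1]
            o = self.ends[oi]
            o.synapsis_id = None
            p.synapsis_id = None
            self._occ_update(o, (), (Protein.KU, Protein.PKCS))
            if self.graph.dissociation_lock is not None:
                o.locked = self.graph.dissociation_lock
            self._set_phase(o, Phase.FREE)
            o.version += 1
            self.log.append((t, o.end_id, "synapsis_disrupted"))
            self._schedule_end(o, t)
        self._occ_update(p, (), tuple(p.occupancy))
        self._set_phase(p, Phase.REPAIRED_HR)
        p.version += 1
        self.log.append((t, p.end_id, "hr_repair_partner"))
        self._on_absorbed(p)

    def _apply_pair(self, syn: _Synapsis, rule, t: float) -> None:
        members = [self.ends[i] for i in syn.end_indices]
        for e in members:
            self._occ_update(e, rule.gains, rule.loses)
            if rule.set_lock is not None:
                e.locked = rule.set_lock
            if rule.to_phase is not None:
                self._set_phase(e, rule.to_phase)
            if e.phase in ABSORBING_PHASES:
                self._occ_update(e, (), tuple(e.occupancy))
            self.log.append((t, e.end_id, rule.name))
            e.version += 1
        if members[0].phase is Phase.SYNAPSIS_STABLE:
            syn.phase = Phase.SYNAPSIS_STABLE
            syn.version += 1
            self._schedule_syn(syn, t)
            for e in members:
                self._schedule_end(e, t)
        else:  # dissociation or ligation dissolves the complex
            del self.synapses[syn.id]
            for e in members:
                e.synapsis_id = None
                if e.phase in ABSORBING_PHASES:
                    self._on_absorbed(e)
                else:
                    self._schedule_end(e, t)

    def _form_synapsis(self, i: int, j: int, t: float) -> None:
        sid = self.next_syn_id
        self.next_syn_id += 1
        syn = _Synapsis(id=sid, end_indices=(i, j), phase=Phase.SYNAPSIS_UNSTABLE)
        self.synapses[sid] = syn
        mid = 0.5 * (self.positions[i] + self.positions[j])
        self.positions[i] = mid
        self.positions[j] = mid
        for e in (self.ends[i], self.ends[j]):
            e.synapsis_id = sid
            self._set_phase(e, Phase.SYNAPSIS_UNSTABLE)
            e.version += 1
            self.log.append((t, e.end_id, "synapsis_formation"))
            self._schedule_end(e, t)  # co-localisation rules may still apply
        self._schedule_syn(syn, t)

    # -- main loop ------------------------------------------------------

    def _record(self, ri: int) -> None:
        for p in Phase:
            self.rec_phase[p.value][ri] = self.phase_counter[p]
        for p in Protein:
            self.rec_protein[p.value][ri] = self.protein_counter[p]
        self.rec_unrep[ri] = self.n_unrepaired
        self.rec_nhej[ri] = self.n_nhej
        self.rec_hr[ri] = self.n_hr

    def run(self) -> CellTrajectory:
        sim = self.sim
        for e in self.ends:
            self._schedule_end(e, 0.0)
        self._record(0)
        k_sub = int(round(sim.record_dt / sim.pairing_dt))
        heap = self.heap
        mobile_diffusion = sim.diffusion_coefficient > 0
        do_pairing = self.graph.has_pairing
        for ri in range(1, sim.n_record):
            for si in range(1, k_sub + 1):
                T = ((ri - 1) * k_sub + si) * sim.pairing_dt
                while heap and heap[0][0] <= T:
                    t_ev, _, kind, idx, version, rule = heapq.heappop(heap)
                    if kind == 0:
                        e = self.ends[idx]
                        if e.version != version:
                            continue
                        self._apply_uni(e, rule, t_ev)
                    else:
                        syn = self.synapses.get(idx)
                        if syn is None or syn.version != version:
                            continue
                        self._apply_pair(syn, rule, t_ev)
                if mobile_diffusion:
                    mask = [
                        e.index
                        for e in self.ends
                        if e.phase not in ABSORBING_PHASES and e.synapsis_id is None
                    ]
                    if mask:
                        self.positions[mask] = diffuse(
                            self.positions[mask],
                            sim.pairing_dt,
                            sim.diffusion_coefficient,
                            self.geometry,
                            self.rng,
                        )
                if do_pairing:
                    for i, j in attempt_synapsis(
                        self.ends, self.positions, sim.capture_radius, sim.pairing_mode
                    ):
                        self._form_synapsis(i, j, T)
            self._record(ri)
        times = np.arange(sim.n_record) * sim.record_dt
        return CellTrajectory(
            times=times,
            phase_counts=self.rec_phase,
            protein_counts=self.rec_protein,
            dsb_unrepaired=self.rec_unrep,
            dsb_nhej=self.rec_nhej,
            dsb_hr=self.rec_hr,
            n_dsb=self.n_dsb,
            n_ends=len(self.ends),
            event_log=self.log,
            final_phases=[e.phase for e in self.ends],
        )


def run_cell(
    damage: DamageSet,
    graph: StateGraph,
    sim: SimulationConfig,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> CellTrajectory:
    """Simulate one cell's DSB ends through a scenario graph.

    The event-driven loop interleaves exponential-clock transitions with
    diffusion/pairing sub-steps and records state counts on the fixed grid.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    return _CellSim(damage, graph, sim, rng).run()


@dataclass
class EnsembleResult:
    """Per-repeat trajectories of an ensemble of independently damaged cells."""

    trajectories: list[CellTrajectory]
    graph: StateGraph
    sim: SimulationConfig

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    @property
    def n_repeats(self) -> int:
        return len(self.trajectories)

    def stack(self, series: str) -> np.ndarray:
        """(n_repeats, n_times) array for a named series.

        ``series`` is a phase name, a protein name, or one of
        ``dsb_unrepaired``, ``dsb_nhej``, ``dsb_hr``.
        """
        rows = []
        for tr in self.trajectories:
            if series in tr.phase_counts:
                rows.append(tr.phase_counts[series])
            elif series in tr.protein_counts:
                rows.append(tr.protein_counts[series])
            elif hasattr(tr, series):
                rows.append(getattr(tr, series))
            else:
                raise KeyError(series)
        return np.stack(rows).astype(float)


def run_ensemble(
    damage_source,
    graph: StateGraph,
    sim: SimulationConfig,
    repeat_seeds: Sequence[int] | None = None,
) -> EnsembleResult:
    """Run ``sim.n_repeats`` independent cells and collect their trajectories.

    ``damage_source`` is either a fixed :class:`DamageSet` (every repeat sees
    the same exposure) or a callable ``seed -> DamageSet`` giving each repeat
    its own independent exposure.  Repeat seeds are derived deterministically
    from ``sim.rng_seed``; passing ``repeat_seeds`` explicitly overrides the
    derivation (useful for forcing identical repeats in tests).
    """
    if sim.n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    trajectories = []
    if repeat_seeds is not None:
        if len(repeat_seeds) != sim.n_repeats:
            raise ValueError("repeat_seeds must have length n_repeats")
        for s in repeat_seeds:
            damage = damage_source(int(s)) if callable(damage_source) else damage_source
            trajectories.append(run_cell(damage, graph, sim, int(s)))
    else:
        base = np.random.SeedSequence(sim.rng_seed)
        for child in base.spawn(sim.n_repeats):
            dmg_ss, dyn_ss = child.spawn(2)
            if callable(damage_source):
                dmg_seed = int(dmg_ss.generate_state(1)[0] & 0x7FFFFFFF)
                damage = damage_source(dmg_seed)
            else:
                damage = damage_source
            trajectories.append(run_cell(damage, graph, sim, dyn_ss))
    return EnsembleResult(trajectories=trajectories, graph=graph, sim=sim)
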