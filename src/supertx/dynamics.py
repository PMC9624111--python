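"""Hybrid continuous/stochastic integrator.

All loaded polymerases evolve as one coupled ODE system (position, nascent
RNA length, local excess twist, rotation), advanced with an explicit
adaptive Dormand-Prince 4(5) stepper (compiled in :mod:`supertx._kernel`).
Stochastic channels ride along:

* per-promoter initiation, whose rate follows the instantaneous
  supercoiling density at the TSS, is simulated by the integrated-hazard
  method -- the cumulative intensity of each channel is carried as an extra
  ODE state and an event fires when it crosses an Exp(1) draw, located by
  root-finding inside the accepted step;
* discrete reactions have piecewise-constant propensities (they change
  only when counts change), so their hazards advance analytically between
  events;
* first-order decay of species that feed back on nothing is realized by
  per-molecule exponential lifetimes, which is distributionally identical
  to a propensity channel but never interrupts the ODE;
* polymerase termination fires when a position crosses its gene's TES
  (root-found), and optional topoisomerase relaxation fires at a constant
  rate;
* while a polymerase occupies the TSS footprint the promoter is gated shut
  (no binding site exists); the gate re-opens through a root-found
  footprint-clearance event.

With no polymerases loaded every rate is constant and the simulation jumps
analytically from event to event.  A fixed seed yields a bit-identical
event log.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from supertx import _kernel as ker
from supertx import physics as phys
from supertx.circuits import (
    CircuitPreset,
    Reaction,
    promoter_base_rate,
)
from supertx.state import (
    BoundaryKind,
    DegenerateSegmentError,
    GenomeLayout,
    InitiationRejected,
    SupercoilingProfile,
    SystemState,
    insert_polymerase,
    supercoiling_profile,
    terminate_polymerase,
    topo_relax_intergenic,
    topo_relax_intragenic,
)

_EPS_T = 1.0e-9
_TSS_PROBE_NM = 1.0e-6  # promoter sigma is read just upstream of the TSS


@dataclass
class EventLog:
    """Timestamped initiation/termination/reaction/topoisomerase records."""

    rows: List[Tuple[float, str, str, str]] = field(default_factory=list)

    def append(self, time: float, kind: str, target: str, detail: str = "") -> None:
        self.rows.append((time, kind, target, detail))

    def finalize(self) -> None:
        self.rows.sort(key=lambda r: r[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["time", "kind", "target", "detail"])

    def times(self, kind: str, target: Optional[str] = None,
              include_rejected: bool = False) -> np.ndarray:
        out = [
            r[0] for r in self.rows
            if r[1] == kind
            and (target is None or r[2] == target)
            and (include_rejected or r[3] != "rejected")
        ]
        return np.array(out, dtype=float)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class Derivatives:
    """Per-polymerase time derivatives plus per-gene initiation rates.

    Satisfies omega0 * dz = dtheta + dphi identically: the rotation/twist
    partition is the closed-form solution of the torque balance."""

    dz: np.ndarray
    dx: np.ndarray
    dphi: np.ndarray
    dtheta: np.ndarray
    initiation_rates: np.ndarray


def _params_vector(p: phys.PhysicalParams) -> np.ndarray:
    return np.array([
        p.omega0, p.kBT, p.v0, p.tau_s, p.tau_w, p.chi, p.eta, p.n_drag,
        p.c_s, p.sigma_s, p.sigma_p, p.tau0, p.marko.plectoneme_stiffness,
        p.alpha, p.sigma_hyper_neg, p.sigma_hyper_pos,
        p.nuc_plateau[0], p.nuc_plateau[1], p.penalty_energy_kbt,
        math.log(p.max_enhancement),
    ])


_TK_CODE = {phys.TorqueModelKind.BASE_MARKO: 0,
            phys.TorqueModelKind.NUCLEOSOME_BUFFERED: 1}
_IK_CODE = {phys.InitiationModelKind.SUPERCOILING_INDEPENDENT: 0,
            phys.InitiationModelKind.FIRST_ORDER: 1,
            phys.InitiationModelKind.SECOND_ORDER: 2,
            phys.InitiationModelKind.SECOND_ORDER_WITH_HYPER_PENALTY: 3}


class _Compiled:
    """Flat arrays for the current polymerase set and per-gene constants."""

    __slots__ = ("n", "y0", "direction", "tes_pol", "base", "gate", "blocker")


class Simulation:
    """One stochastic replicate of a :class:`~supertx.circuits.CircuitPreset`.

    Parameters
    ----------
    preset : CircuitPreset
    seed : int or numpy Generator
    rtol, atol : float
        Local error tolerances of the adaptive stepper.
    max_step : float
        Upper bound on the ODE step, s.
    method : {"adaptive", "rk4_fixed"}
        ``rk4_fixed`` replaces the embedded 4(5) pair with a classical RK4
        at the constant step ``fixed_dt`` -- the slow reference integrator
        used to validate the adaptive path.
    collect_sigma : bool
        Record supercoiling-profile snapshots on the output grid.
    """

    def __init__(
        self,
        preset: CircuitPreset,
        seed=0,
        *,
        rtol: float = 1.0e-6,
        atol: float = 1.0e-8,
        max_step: float = 30.0,
        method: str = "adaptive",
        fixed_dt: float = 0.02,
        collect_sigma: bool = False,
    ):
        self.preset = preset
        self.layout: GenomeLayout = preset.layout
        self.params: phys.PhysicalParams = preset.params
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.rtol, self.atol, self.max_step = rtol, atol, max_step
        if method not in ("adaptive", "rk4_fixed"):
            raise ValueError("method must be 'adaptive' or 'rk4_fixed'")
        self.method = method
        self.fixed_dt = fixed_dt
        self.collect_sigma = collect_sigma

        self.genes = list(self.layout.genes)
        self.gene_names = [g.name for g in self.genes]
        self._gene_index = {n: i for i, n in enumerate(self.gene_names)}
        self.G = len(self.genes)
        self._pc = _params_vector(self.params)
        self._tk = _TK_CODE[preset.torque_kind]
        self._ik = _IK_CODE[preset.initiation_kind]
        self._circular = 1 if self.layout.boundary_kind == BoundaryKind.CIRCULAR else 0
        self._wall_lo, self._wall_hi = self.layout.wall_nm
        self._circ = self.layout.circumference_nm
        self._fp = self.layout.footprint_nm
        self._tss = np.array([self.layout.tss_nm(g) for g in self.genes])
        self._tes = np.array([self.layout.tes_nm(g) for g in self.genes])
        self._gdir = np.array([float(g.direction) for g in self.genes])
        self._probe = self._tss - _TSS_PROBE_NM * self._gdir

        self.state = SystemState(time=0.0)
        for s in preset.network.species:
            self.state.species[s] = int(preset.initial_species.get(s, 0))
        for g in self.genes:
            self.state.species.setdefault(g.mrna_species, 0)
        self.state.promoter_state = {
            g.name: {"induction": preset.rules[g.name].induction} for g in self.genes
        }

        # species that feed back on nothing decay via per-molecule lifetimes
        referenced = set()
        for r in preset.network.reactions:
            if self._is_unary_decay(r):
                continue
            referenced |= set(r.reactants) | set(r.catalysts)
        for rule in preset.rules.values():
            if rule.repressor:
                referenced.add(rule.repressor)
            if rule.occupancy_species:
                referenced.add(rule.occupancy_species)
        self._lifetime_rate: Dict[str, float] = {}
        self._channels: List[Reaction] = []
        for r in preset.network.reactions:
            if self._is_unary_decay(r):
                (s,) = r.reactants
                if s not in referenced:
                    self._lifetime_rate[s] = r.rate
                    continue
            self._channels.append(r)
        self._rxn_by_name = {r.name: r for r in preset.network.reactions}

        self.log = EventLog()
        self._death_heap: List[Tuple[float, str]] = []
        self._sigma_snapshots: List[Tuple[float, SupercoilingProfile]] = []

        self._rem_init = self.rng.standard_exponential(self.G)
        self._rem_rxn = self.rng.standard_exponential(len(self._channels))
        self._rem_topo = float(self.rng.standard_exponential())
        self._interventions = sorted(preset.protocol.interventions)
        self._iv_ptr = 0
        self._sample_times: List[float] = []
        self._sample_ptr = 0
        if collect_sigma:
            dt = preset.protocol.sample_dt
            n = int(math.floor(preset.protocol.duration / dt + 1.0e-9))
            self._sample_times = [k * dt for k in range(n + 1)]
        self._h_guess = 0.1
        self._n_steps = 0
        self._n_rejected = 0

    # -- helpers ------------------------------------------------------------
    @staticmethod
    def _is_unary_decay(r: Reaction) -> bool:
        return (
            len(r.reactants) == 1
            and next(iter(r.reactants.values())) == 1
            and not r.products
            and not r.catalysts
        )

    def _base_rate(self, gene_name: str) -> float:
        rule = self.preset.rules[gene_name]
        ind = self.state.promoter_state[gene_name]["induction"]
        return promoter_base_rate(rule, self.state.species, induction=ind)

    def _gate_and_blocker(self, g: int) -> Tuple[int, int]:
        """(1, -1) if the TSS is free, else (0, blocking polymerase index)."""
        tss = self._tss[g]
        best, best_d = -1, math.inf
        for i, p in enumerate(self.state.polymerases):
            d = abs(p.z - tss)
            if self._circular:
                d = min(d, self._circ - d)
            if d < self._fp - 1.0e-6 and d < best_d:
                best, best_d = i, d
        return (1, -1) if best < 0 else (0, best)

    def _compile(self) -> _Compiled:
        st = self.state
        st.sort_polymerases()
        c = _Compiled()
        n = len(st.polymerases)
        c.n = n
        c.direction = np.array([float(p.direction) for p in st.polymerases])
        c.tes_pol = np.array([self._tes[self._gene_index[p.gene]]
                              for p in st.polymerases])
        c.y0 = np.concatenate([
            [p.z for p in st.polymerases],
            [p.x for p in st.polymerases],
            [p.phi for p in st.polymerases],
            [p.theta for p in st.polymerases],
            np.zeros(self.G),
        ]).astype(float)
        c.base = np.array([self._base_rate(nm) for nm in self.gene_names])
        gate = np.empty(self.G, dtype=np.int8)
        blocker = np.empty(self.G, dtype=np.int64)
        for g in range(self.G):
            gate[g], blocker[g] = self._gate_and_blocker(g)
        c.gate = gate
        c.blocker = blocker
        return c

    def _rhs(self, c: _Compiled, y: np.ndarray) -> np.ndarray:
        out = np.empty_like(y)
        ker.rhs(y, out, c.n, self.G, c.direction, self._probe, c.base, c.gate,
                self._circular, self._wall_lo, self._wall_hi, self._circ,
                self._pc, self._ik, self._tk, self._fp)
        return out

    # -- scheduled (piecewise-constant) events ------------------------------
    def _propensities(self) -> np.ndarray:
        return np.array([r.propensity(self.state.species) for r in self._channels])

    def _scheduled_stop(self, t_end: float, props: np.ndarray):
        cands: List[Tuple[float, str, int]] = [(t_end, "end", -1)]
        t = self.state.time
        for j, a in enumerate(props):
            if a > 0.0:
                cands.append((t + self._rem_rxn[j] / a, "reaction", j))
        if self.preset.topo.mode != "none" and self.preset.topo.rate > 0.0:
            cands.append((t + self._rem_topo / self.preset.topo.rate, "topo", -1))
        if self._iv_ptr < len(self._interventions):
            cands.append((self._interventions[self._iv_ptr][0], "intervention",
                          self._iv_ptr))
        if self._sample_ptr < len(self._sample_times):
            cands.append((self._sample_times[self._sample_ptr], "sample",
                          self._sample_ptr))
        # ties: samples/interventions fire before the run-end stop
        prio = {"sample": 0, "intervention": 1, "reaction": 2, "topo": 3, "end": 4}
        return min(cands, key=lambda r: (r[0], prio[r[1]]))

    def _consume_constant(self, dt: float, props: np.ndarray) -> None:
        if len(props):
            self._rem_rxn = np.maximum(self._rem_rxn - props * dt, 0.0)
        if self.preset.topo.mode != "none":
            self._rem_topo = max(self._rem_topo - self.preset.topo.rate * dt, 0.0)

    # -- event application ---------------------------------------------------
    def _apply_initiation(self, g: int) -> None:
        gene = self.genes[g]
        try:
            insert_polymerase(self.state, gene, self.layout)
        except InitiationRejected:
            self.log.append(self.state.time, "initiation", gene.name, "rejected")
        else:
            self.log.append(self.state.time, "initiation", gene.name, "")
        self._rem_init[g] = float(self.rng.standard_exponential())

    def _apply_termination(self, i: int) -> None:
        pol = terminate_polymerase(self.state, i)
        self.log.append(self.state.time, "termination", pol.gene, "")
        key = f"{pol.gene}_mRNA"
        rate = self._lifetime_rate.get(key)
        if rate is not None:
            life = float(self.rng.standard_exponential()) / rate
            heapq.heappush(self._death_heap, (self.state.time + life, key))

    def _apply_reaction(self, j: int) -> None:
        r = self._channels[j]
        r.apply(self.state.species)
        self.log.append(self.state.time, "reaction", r.name, "")
        self._rem_rxn[j] = float(self.rng.standard_exponential())

    def _apply_topo(self) -> None:
        mode = self.preset.topo.mode
        if mode == "intergenic":
            topo_relax_intergenic(self.state, self.layout)
        elif mode == "intragenic":
            for g in self.genes:
                topo_relax_intragenic(self.state, self.layout, g)
        self.log.append(self.state.time, "topoisomerase", mode, "")
        self._rem_topo = float(self.rng.standard_exponential())

    def _apply_intervention(self, idx: int) -> None:
        _, gene, ind = self._interventions[idx]
        self.state.promoter_state[gene]["induction"] = ind
        self._iv_ptr += 1

    def _apply_sample(self) -> None:
        if self.collect_sigma:
            self._sigma_snapshots.append(
                (self.state.time, supercoiling_profile(self.state, self.layout))
            )
        self._sample_ptr += 1

    # -- main loop -----------------------------------------------------------
    def advance(self, t_end: float) -> None:
        while self.state.time < t_end - _EPS_T:
            if not self.state.polymerases:
                self._advance_analytic(t_end)
            else:
                self._advance_leg(t_end)
        self._flush_deaths(t_end)

    def _advance_analytic(self, t_end: float) -> None:
        """No polymerases: every rate is constant; jump to the next event."""
        t = self.state.time
        props = self._propensities()
        best = self._scheduled_stop(t_end, props)
        init_rates = np.array([self._base_rate(nm) for nm in self.gene_names])
        for g in range(self.G):
            if init_rates[g] > 0.0:
                cand = t + self._rem_init[g] / init_rates[g]
                if cand < best[0]:
                    best = (cand, "initiation", g)
        t1, kind, idx = best
        dt = t1 - t
        self._consume_constant(dt, props)
        self._rem_init = np.maximum(self._rem_init - init_rates * dt, 0.0)
        self.state.time = t1
        if kind == "initiation":
            self._apply_initiation(idx)
        elif kind == "reaction":
            self._apply_reaction(idx)
        elif kind == "topo":
            self._apply_topo()
        elif kind == "intervention":
            self._apply_intervention(idx)
        elif kind == "sample":
            self._apply_sample()

    def _advance_leg(self, t_end: float) -> None:
        """Integrate the ODE until the next event of any kind."""
        c = self._compile()
        t0 = self.state.time
        props = self._propensities()
        stop_t, stop_kind, stop_idx = self._scheduled_stop(t_end, props)
        y = c.y0
        h0 = self._h_guess if self.method == "adaptive" else self.fixed_dt
        code, idx, te, h_next, nsteps, nrej = ker.integrate_leg(
            t0, y, h0, stop_t, self.max_step, self.rtol, self.atol,
            c.n, self.G, c.direction, c.tes_pol, self._probe, c.base, c.gate,
            c.blocker, self._tss, self._fp,
            self._rem_init,
            self._circular, self._wall_lo, self._wall_hi, self._circ,
            self._pc, self._ik, self._tk,
            0 if self.method == "adaptive" else 1,
            self.fixed_dt,
        )
        self._n_steps += nsteps
        self._n_rejected += nrej
        if code == -1:
            raise DegenerateSegmentError(
                f"polymerase order inversion at t~{te:.6g}s "
                f"(gene loads: { {g: len(self.state.polymerases_of(g)) for g in self.gene_names} })"
            )
        self._h_guess = min(max(h_next, 1.0e-6), self.max_step)
        self._decode(y, te, c)
        self._consume_constant(te - t0, props)
        lam = np.maximum(y[4 * c.n:], 0.0)
        self._rem_init = np.maximum(self._rem_init - lam, 0.0)
        if code == 1:
            self._apply_initiation(idx)
        elif code == 2:
            self._apply_termination(idx)
        elif code == 3:
            pass  # footprint cleared; gates are recomputed on the next compile
        else:  # scheduled stop
            if stop_kind == "reaction":
                self._apply_reaction(stop_idx)
            elif stop_kind == "topo":
                self._apply_topo()
            elif stop_kind == "intervention":
                self._apply_intervention(stop_idx)
            elif stop_kind == "sample":
                self._apply_sample()
            elif stop_kind == "end":
                self.state.time = stop_t

    def _decode(self, y: np.ndarray, t: float, c: _Compiled) -> None:
        n = c.n
        for i, p in enumerate(self.state.polymerases):
            p.z = float(y[i])
            p.x = float(y[n + i])
            p.phi = float(y[2 * n + i])
            p.theta = float(y[3 * n + i])
        self.state.time = t

    def _flush_deaths(self, t_end: float) -> None:
        while self._death_heap and self._death_heap[0][0] <= t_end:
            t, key = heapq.heappop(self._death_heap)
            self.state.species[key] -= 1
            self.log.append(t, "reaction", key, "decay")
        self.log.finalize()

    # -- public convenience ---------------------------------------------------
    def derivatives(self) -> Derivatives:
        c = self._compile()
        f = self._rhs(c, c.y0)
        n = c.n
        return Derivatives(
            dz=f[:n], dx=f[n:2 * n], dphi=f[2 * n:3 * n],
            dtheta=f[3 * n:4 * n], initiation_rates=f[4 * n:],
        )

    def run(self, t_end: Optional[float] = None) -> "ReplicateResult":
        t_end = self.preset.protocol.duration if t_end is None else t_end
        self.advance(t_end)
        traj = trajectory_from_events(
            self.log,
            t_end=t_end,
            sample_dt=self.preset.protocol.sample_dt,
            initial_species={s: int(self.preset.initial_species.get(s, 0))
                             for s in self.state.species},
            gene_names=self.gene_names,
            reactions=self._rxn_by_name,
        )
        return ReplicateResult(
            seed=None,
            trajectory=traj,
            events=self.log,
            sigma_snapshots=self._sigma_snapshots if self.collect_sigma else None,
            final_state=self.state,
            n_steps=self._n_steps,
            n_rejected=self._n_rejected,
        )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def derivatives(state: SystemState, preset: CircuitPreset) -> Derivatives:
    """Instantaneous derivatives of every polymerase in ``state``.

    The returned quantities satisfy omega0 * dz/dt = dtheta/dt + dphi/dt
    identically (the rotation/twist partition is solved in closed form
    from the torque balance)."""
    sim = Simulation(preset, seed=0)
    sim.state.polymerases = state.polymerases
    sim.state.species.update(state.species)
    sim.state.time = state.time
    return sim.derivatives()


def advance(
    preset: CircuitPreset,
    t_end: Optional[float] = None,
    seed: int = 0,
    state: Optional[SystemState] = None,
    **kwargs,
) -> Tuple[SystemState, EventLog]:
    """Run one replicate to ``t_end``; returns the final state and event log."""
    sim = Simulation(preset, seed=seed, **kwargs)
    if state is not None:
        sim.state.polymerases = state.polymerases
        sim.state.species.update(state.species)
        sim.state.time = state.time
    sim.advance(preset.protocol.duration if t_end is None else t_end)
    sim.log.finalize()
    return sim.state, sim.log


@dataclass
class ReplicateResult:
    seed: Optional[int]
    trajectory: pd.DataFrame
    events: EventLog
    sigma_snapshots: Optional[List[Tuple[float, SupercoilingProfile]]]
    final_state: SystemState
    n_steps: int = 0
    n_rejected: int = 0


def replicate_seed(base_seed: int, k: int = 0) -> np.random.SeedSequence:
    """Deterministic per-replicate seed stream."""
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(k,))


def run_ensemble(
    preset: CircuitPreset,
    n_replicates: int,
    base_seed: int = 0,
    *,
    t_end: Optional[float] = None,
    collect_sigma: bool = False,
    **sim_kwargs,
) -> List[ReplicateResult]:
    """Run ``n_replicates`` independent replicates of a preset.

    Replicate k's generator is seeded from (base_seed, k), so ensembles are
    reproducible and extendable without re-running earlier replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for k in range(n_replicates):
        rng = np.random.default_rng(replicate_seed(base_seed, k))
        sim = Simulation(preset, seed=rng, collect_sigma=collect_sigma, **sim_kwargs)
        res = sim.run(t_end)
        res.seed = k
        out.append(res)
    return out


def trajectory_from_events(
    log: EventLog,
    t_end: float,
    sample_dt: float,
    initial_species: Dict[str, int],
    gene_names: List[str],
    reactions: Dict[str, Reaction],
) -> pd.DataFrame:
    """Species counts and per-gene polymerase loads on a uniform grid.

    Counts change only at logged events, so the trajectory is exactly
    reconstructible from the event log (samples are taken just before any
    event coinciding with a grid point).
    """
    grid = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    species = dict(initial_species)
    load = {g: 0 for g in gene_names}
    cols: Dict[str, np.ndarray] = {s: np.zeros(len(grid)) for s in species}
    for g in gene_names:
        cols[f"{g}_polymerases"] = np.zeros(len(grid))
    gi = 0

    def snapshot(upto):
        nonlocal gi
        while gi < len(grid) and grid[gi] < upto - 1.0e-12:
            for s, v in species.items():
                cols[s][gi] = v
            for g, v in load.items():
                cols[f"{g}_polymerases"][gi] = v
            gi += 1

    for time, kind, target, detail in log.rows:
        snapshot(time)
        if kind == "initiation" and detail != "rejected":
            load[target] += 1
        elif kind == "termination":
            load[target] -= 1
            key = f"{target}_mRNA"
            species[key] = species.get(key, 0) + 1
        elif kind == "reaction":
            if detail == "decay":
                species[target] = species.get(target, 0) - 1
            else:
                r = reactions[target]
                for s, nu in r.reactants.items():
                    species[s] = species.get(s, 0) - nu
                for s, nu in r.products.items():
                    species[s] = species.get(s, 0) + nu
    snapshot(math.inf)
    df = pd.DataFrame(cols)
    df.insert(0, "time", grid)
    return df
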