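"""Hybrid integrator: derivative identities, determinism, oracle
equivalence against a fixed-small-step reference, and the feedback-free
birth-death limit."""

import numpy as np
import pytest

from supertx.circuits import build_two_gene
from supertx.dynamics import (
    Simulation,
    derivatives,
    run_ensemble,
)
from supertx.physics import InitiationModelKind, PhysicalParams
from supertx.state import PolymeraseState, SystemState, supercoiling_profile


def small_preset(**kw):
    kw.setdefault("duration", 2000.0)
    return build_two_gene("convergent", induction=1.0, **kw)


def loaded_state(preset, zx):
    """State with polymerases placed by hand on the two genes."""
    st = SystemState()
    lay = preset.layout
    for gene_name, frac, x, phi in zx:
        g = lay.gene(gene_name)
        z = lay.tss_nm(g) + g.direction * frac * lay.to_nm(g.length_bp)
        st.polymerases.append(PolymeraseState(
            z=z, x=x, phi=phi, theta=0.0, gene=gene_name, direction=g.direction))
    st.sort_polymerases()
    return st


class TestDerivatives:
    def test_rotation_twist_partition_identity(self):
        """omega0 dz = dtheta + dphi holds exactly by construction."""
        preset = small_preset()
        st = loaded_state(preset, [
            ("reporter", 0.3, 100.0, 40.0),
            ("reporter", 0.7, 230.0, 90.0),
            ("adjacent", 0.5, 170.0, -60.0),
        ])
        d = derivatives(st, preset)
        w0 = preset.params.omega0
        assert np.allclose(w0 * d.dz, d.dtheta + d.dphi, rtol=0, atol=1e-12)

    def test_fresh_polymerase_rotates_freely(self):
        """x = 0 on relaxed DNA: all motion goes into rotation, none into
        twist (no supercoiling is injected yet)."""
        preset = small_preset()
        st = loaded_state(preset, [("reporter", 0.0, 0.0, 0.0)])
        d = derivatives(st, preset)
        p = preset.params
        assert d.dtheta[0] == pytest.approx(p.omega0 * d.dz[0], rel=1e-12)
        assert d.dphi[0] == pytest.approx(0.0, abs=1e-12)

    def test_drag_dominated_limit_deposits_all_twist(self):
        """Enormous nascent RNA: rotation freezes, dphi -> omega0 v."""
        preset = small_preset()
        st = loaded_state(preset, [("reporter", 0.5, 1.0e12, 0.0)])
        d = derivatives(st, preset)
        p = preset.params
        assert abs(d.dtheta[0]) < 1e-6 * abs(d.dphi[0])
        assert d.dphi[0] == pytest.approx(p.omega0 * d.dz[0], rel=1e-4)

    def test_reverse_gene_moves_left_and_underwinds(self):
        preset = small_preset()
        st = loaded_state(preset, [("adjacent", 0.4, 200.0, 0.0)])
        d = derivatives(st, preset)
        assert d.dz[0] < 0 < d.dx[0]
        assert d.dphi[0] < 0  # reverse polymerase injects negative twist

    def test_initiation_rate_reflects_promoter_sigma(self):
        preset = small_preset()
        # reporter polymerase mid-gene: negative sigma behind covers its own
        # promoter (enhanced), positive sigma ahead covers the adjacent
        # promoter (suppressed)
        st = loaded_state(preset, [("reporter", 0.5, 170.0, 80.0)])
        st.promoter_state = {"reporter": {"induction": 1.0},
                             "adjacent": {"induction": 1.0}}
        d = derivatives(st, preset)
        r0 = preset.rules["reporter"].r0
        assert d.initiation_rates[0] > r0      # reporter self-enhances
        assert d.initiation_rates[1] < r0      # adjacent suppressed


class TestDeterminism:
    def test_same_seed_identical_event_logs(self):
        preset = small_preset()
        logs = []
        for _ in range(2):
            sim = Simulation(preset, seed=42)
            sim.advance(1500.0)
            logs.append(sim.log.rows)
        assert logs[0] == logs[1]

    def test_different_replicate_seeds_differ(self):
        preset = small_preset()
        runs = run_ensemble(preset, 2, base_seed=7, t_end=1500.0)
        assert runs[0].events.rows != runs[1].events.rows

    def test_ensemble_reproducible(self):
        preset = small_preset()
        a = run_ensemble(preset, 2, base_seed=5, t_end=1000.0)
        b = run_ensemble(preset, 2, base_seed=5, t_end=1000.0)
        for ra, rb in zip(a, b):
            assert ra.events.rows == rb.events.rows


class TestConservation:
    def test_zero_sum_twist_along_trajectory(self):
        """The length-weighted sigma integral stays zero through initiation,
        elongation, and termination events."""
        preset = small_preset()
        sim = Simulation(preset, seed=3)
        for t_stop in np.linspace(100.0, 2000.0, 20):
            sim.advance(float(t_stop))
            prof = supercoiling_profile(sim.state, preset.layout)
            scale = max(1.0, max((abs(p.phi) for p in sim.state.polymerases),
                                 default=1.0))
            assert prof.twist_integral() * preset.params.omega0 == \
                pytest.approx(0.0, abs=1e-8 * scale)

    def test_event_log_bookkeeping(self):
        """Each termination is preceded by a matching initiation and the
        final mRNA count equals terminations minus decays."""
        preset = small_preset(duration=4000.0)
        sim = Simulation(preset, seed=9)
        sim.advance(4000.0)
        for gene in ("reporter", "adjacent"):
            ini = sim.log.times("initiation", gene)
            term = sim.log.times("termination", gene)
            assert len(term) <= len(ini)
            # k-th termination follows k-th initiation (FIFO transit)
            assert np.all(term >= ini[: len(term)])
            decays = sum(1 for r in sim.log.rows
                         if r[1] == "reaction" and r[2] == f"{gene}_mRNA")
            assert sim.state.species[f"{gene}_mRNA"] == len(term) - decays


class TestOracleEquivalence:
    """The adaptive integrator against a fixed-small-step classical RK4."""

    def test_trajectories_and_events_match_reference(self):
        preset = small_preset(duration=400.0)
        # force an interesting 2-3 polymerase instance deterministically
        adaptive = Simulation(preset, seed=17, method="adaptive")
        reference = Simulation(preset, seed=17, method="rk4_fixed", fixed_dt=0.01)
        adaptive.advance(400.0)
        reference.advance(400.0)
        ka = [(r[1], r[2], r[3]) for r in adaptive.log.rows]
        kr = [(r[1], r[2], r[3]) for r in reference.log.rows]
        assert ka == kr  # identical event sequence under shared hazard draws
        ta = np.array([r[0] for r in adaptive.log.rows])
        tr = np.array([r[0] for r in reference.log.rows])
        assert np.allclose(ta, tr, rtol=1e-4, atol=5e-3)
        # event times agree to ~5 ms; that jitter propagates into positions
        # at ~v0 * dt ~ 0.1 nm, so the end-state comparison is bounded by
        # event localization, not by integrator accuracy
        za = sorted((p.z, p.x, p.phi) for p in adaptive.state.polymerases)
        zr = sorted((p.z, p.x, p.phi) for p in reference.state.polymerases)
        assert np.allclose(np.array(za), np.array(zr), rtol=1e-4, atol=0.1)

    def test_reference_agreement_with_polymerases_loaded(self):
        """Start from a hand-built 2-polymerase state and integrate with no
        stochastic events: pure ODE agreement."""
        preset = small_preset(duration=200.0)
        for name in ("reporter", "adjacent"):
            preset.rules[name].induction = 0.0
        preset.protocol.interventions = []
        init = loaded_state(preset, [
            ("reporter", 0.2, 70.0, 25.0),
            ("reporter", 0.6, 200.0, 80.0),
        ])
        finals = []
        for method, dt in (("adaptive", None), ("rk4_fixed", 0.005)):
            sim = Simulation(preset, seed=0, method=method,
                             fixed_dt=dt or 0.02)
            sim.state.polymerases = [p.copy() for p in init.polymerases]
            sim.advance(150.0)
            finals.append(np.array(sorted(
                (p.z, p.x, p.phi, p.theta) for p in sim.state.polymerases)))
        assert np.allclose(finals[0], finals[1], rtol=1e-6, atol=1e-5)


class TestBirthDeathLimit:
    def test_steady_state_mean_is_r_over_d(self):
        """Supercoiling feedback off (independent initiation, stall disabled):
        mRNA is a birth-death process with mean r/d."""
        r0 = 1.0 / 40.0
        halflife = 300.0
        d = np.log(2.0) / halflife
        preset = build_two_gene(
            "convergent", induction=1.0, duration=6000.0,
            r0=r0, mrna_halflife=halflife,
            params=PhysicalParams().with_stall_disabled(),
            initiation_kind=InitiationModelKind.SUPERCOILING_INDEPENDENT,
        )
        preset.rules["adjacent"].induction = 1.0
        preset.protocol.interventions = []
        runs = run_ensemble(preset, 24, base_seed=11)
        t = runs[0].trajectory["time"].to_numpy()
        sel = t > 2500.0  # ~8 half-lives of burn-in
        vals = np.array([
            r.trajectory["reporter_mRNA"].to_numpy()[sel].mean() for r in runs
        ])
        expect = r0 / d
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expect) < 3.0 * se + 0.02 * expect

    def test_poisson_event_counts_in_feedback_free_limit(self):
        r0 = 1.0 / 20.0
        preset = build_two_gene(
            "divergent", induction=0.0, duration=4000.0, r0=r0,
            params=PhysicalParams().with_stall_disabled(),
            initiation_kind=InitiationModelKind.SUPERCOILING_INDEPENDENT,
        )
        preset.protocol.interventions = []
        runs = run_ensemble(preset, 20, base_seed=23)
        counts = np.array([len(r.events.times("initiation", "reporter"))
                           for r in runs])
        lam = r0 * 4000.0
        # mean and variance both ~ lambda for a Poisson count
        assert abs(counts.mean() - lam) < 4.0 * np.sqrt(lam / len(counts))
        assert 0.5 < counts.var(ddof=1) / lam < 2.0


class TestRunMachinery:
    def test_trajectory_matches_final_state(self):
        preset = small_preset(duration=3000.0)
        sim = Simulation(preset, seed=31)
        res = sim.run()
        last = res.trajectory.iloc[-1]
        for sp, cnt in sim.state.species.items():
            assert last[sp] == cnt
        assert last["time"] == pytest.approx(3000.0)

    def test_no_activity_when_all_rates_zero(self):
        preset = small_preset()
        preset.rules["reporter"].induction = 0.0
        preset.rules["adjacent"].induction = 0.0
        preset.protocol.interventions = []
        state, log = __import__("supertx.dynamics", fromlist=["advance"]).advance(
            preset, t_end=500.0, seed=1)
        assert state.time == pytest.approx(500.0)
        assert len(log) == 0

    def test_intervention_changes_induction(self):
        preset = small_preset(duration=2000.0)
        sim = Simulation(preset, seed=2)
        sim.advance(9.0)
        # induction switch is scheduled at t = 10000 s by default; use a
        # custom early intervention instead
        preset2 = small_preset(duration=2000.0)
        preset2.protocol.interventions = [(50.0, "adjacent", 2.5)]
        sim2 = Simulation(preset2, seed=2)
        sim2.advance(60.0)
        assert sim2.state.promoter_state["adjacent"]["induction"] == 2.5

    def test_sigma_snapshots_on_grid(self):
        preset = small_preset(duration=200.0)
        preset.protocol.sample_dt = 50.0
        sim = Simulation(preset, seed=4, collect_sigma=True)
        res = sim.run(200.0)
        times = [t for t, _ in res.sigma_snapshots]
        assert times == [0.0, 50.0, 100.0, 150.0, 200.0]
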