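import numpy as np
import pytest

from kvgating import (
    CurrentTrace,
    build_state_space,
    equilibrium_distribution,
    gating_current_trace,
    generator_at_voltage,
    gillespie_simulate,
    ionic_current_trace,
    make_cole_moore_protocol,
    make_gating_protocol,
    propagate_occupancy,
)
from kvgating.protocol import VoltageProtocol

from oracles import aggregate, explicit_propagate, ode_propagate


class TestProtocolBuilders:
    def test_default_gating_protocol_19_episodes(self):
        prot = make_gating_protocol()
        assert prot.n_episodes == 19
        assert prot.episode_labels[0] == -140.0
        assert prot.episode_labels[-1] == 40.0

    def test_single_episode_when_start_equals_stop(self):
        prot = make_gating_protocol(start=-20.0, stop=-20.0)
        assert prot.n_episodes == 1

    def test_step_sample_count(self):
        prot = make_gating_protocol(sample_interval_ms=0.1)
        t0, t1 = prot.segment_window(0, -1)
        t = prot.time_grid(0)
        n = ((t >= t0 - 1e-9) & (t <= t1 + 1e-9)).sum()
        assert n == 601  # 60 ms step at 0.1 ms, both endpoints

    def test_episode_structure(self):
        prot = make_gating_protocol()
        segs = prot.segments(5)
        assert len(segs) == 3
        assert segs[0][1] == -100.0     # holding
        assert segs[1] == (20.0, -140.0)  # prepulse
        assert segs[2][0] == 60.0

    def test_degenerate_ranges_rejected(self):
        with pytest.raises(ValueError):
            make_gating_protocol(increment=-10.0)
        with pytest.raises(ValueError):
            make_gating_protocol(start=40.0, stop=-140.0)

    def test_cole_moore_two_prepulses(self):
        prot = make_cole_moore_protocol([-140.0, -60.0], test_mV=40.0)
        assert prot.n_episodes == 2
        assert prot.episode_labels == (-140.0, -60.0)
        assert prot.segments(0)[2] == prot.segments(1)[2]

    def test_cole_moore_single_prepulse(self):
        prot = make_cole_moore_protocol([-120.0])
        assert prot.n_episodes == 1

    def test_cole_moore_empty_rejected(self):
        with pytest.raises(ValueError):
            make_cole_moore_protocol([])

    def test_sample_interval_must_fit_segments(self):
        with pytest.raises(ValueError):
            VoltageProtocol(episodes=(((1.0, -100.0),),), episode_labels=(0.0,),
                            holding_potential=-100.0, sample_interval=2.0)


class TestPropagation:
    def test_constant_protocol_is_stationary(self, hetero, pc):
        prot = VoltageProtocol(
            episodes=(((50.0, -100.0),),), episode_labels=(-100.0,),
            holding_potential=-100.0, sample_interval=0.5)
        traj = propagate_occupancy(hetero, prot, 0, pc)
        p0 = traj.probabilities[0]
        assert np.abs(traj.probabilities - p0).max() < 1e-10

    def test_converges_to_step_equilibrium(self, hetero, pc):
        prot = make_gating_protocol(start=40.0, stop=40.0, step_ms=60.0,
                                    sample_interval_ms=0.1)
        traj = propagate_occupancy(hetero, prot, 0, pc)
        peq = equilibrium_distribution(hetero, 40.0, pc)
        assert np.abs(traj.probabilities[-1] - peq).max() < 1e-6

    def test_simplex_preserved(self, hetero, pc):
        prot = make_gating_protocol(sample_interval_ms=0.2)
        for ep in (0, 9, 18):
            traj = propagate_occupancy(hetero, prot, ep, pc)
            assert traj.probabilities.min() >= -1e-12
            assert np.abs(traj.probabilities.sum(axis=1) - 1).max() < 1e-8

    def test_against_explicit_subunit_oracle(self, hetero, pc):
        """9-state aggregated chain == brute-force 17-state chain."""
        prot = make_gating_protocol(start=-60.0, stop=-60.0,
                                    sample_interval_ms=2.0)
        traj = propagate_occupancy(hetero, prot, 0, pc)
        ref = explicit_propagate(hetero, prot.segments(0),
                                 prot.holding_potential, traj.time, pc)
        assert np.abs(aggregate(ref) - traj.probabilities).max() < 1e-9

    def test_against_stiff_ode_oracle(self, hetero, pc):
        prot = make_gating_protocol(start=-20.0, stop=-20.0,
                                    sample_interval_ms=1.0)
        traj = propagate_occupancy(hetero, prot, 0, pc)
        p0 = equilibrium_distribution(hetero, prot.holding_potential, pc)
        ref = ode_propagate(
            lambda V: generator_at_voltage(hetero, V, pc).entries,
            prot.segments(0), p0, traj.time)
        assert np.abs(ref - traj.probabilities).max() < 1e-7

    def test_bad_episode_index(self, hetero, pc):
        prot = make_gating_protocol()
        with pytest.raises(IndexError):
            propagate_occupancy(hetero, prot, 99, pc)


class TestGatingCurrent:
    def test_zero_at_equilibrium(self, hetero, pc):
        prot = VoltageProtocol(
            episodes=(((50.0, -100.0),),), episode_labels=(-100.0,),
            holding_potential=-100.0, sample_interval=0.5)
        space = build_state_space(hetero)
        traj = propagate_occupancy(hetero, prot, 0, pc, space)
        tr = gating_current_trace(traj, space, hetero, pc)
        assert np.abs(tr.current).max() < 1e-10

    def test_charge_conservation_saturating_step(self, hetero, pc):
        """Integral of I_Q over a saturating step equals the equilibrium
        charge displacement (and the assembly's total charge)."""
        space = build_state_space(hetero)
        prot = make_gating_protocol(start=20.0, stop=20.0, step_ms=100.0,
                                    sample_interval_ms=0.02)
        traj = propagate_occupancy(hetero, prot, 0, pc, space)
        tr = gating_current_trace(traj, space, hetero, pc)
        t0, t1 = prot.segment_window(0, -1)
        sl = tr.window_slice((t0, t1))
        integral = np.trapezoid(tr.current[sl], tr.time[sl])
        q = space.charge_vector()
        i0 = int(np.searchsorted(traj.time, t0))
        expected = q @ (traj.probabilities[-1] - traj.probabilities[i0])
        assert integral == pytest.approx(expected, rel=5e-3)
        assert integral == pytest.approx(hetero.total_gating_charge, rel=5e-3)

    def test_integrated_charge_resolution_stable(self, homo, pc):
        """Halving dt changes the integrated ON charge by < 0.1%."""
        space = build_state_space(homo)
        vals = []
        for dt in (0.02, 0.01):
            prot = make_gating_protocol(start=-20.0, stop=-20.0,
                                        sample_interval_ms=dt)
            traj = propagate_occupancy(homo, prot, 0, pc, space)
            tr = gating_current_trace(traj, space, homo, pc)
            t0, t1 = prot.segment_window(0, -1)
            sl = tr.window_slice((t0, t1))
            vals.append(np.trapezoid(tr.current[sl], tr.time[sl]))
        assert abs(vals[1] - vals[0]) / abs(vals[1]) < 1e-3

    def test_qv_nondecreasing_in_voltage(self, hetero, pc):
        space = build_state_space(hetero)
        prot = make_gating_protocol(sample_interval_ms=0.05)
        charges = []
        for ep in range(prot.n_episodes):
            traj = propagate_occupancy(hetero, prot, ep, pc, space)
            tr = gating_current_trace(traj, space, hetero, pc)
            t0, t1 = prot.segment_window(ep, -1)
            sl = tr.window_slice((t0, t1))
            charges.append(np.trapezoid(tr.current[sl], tr.time[sl]))
        assert np.all(np.diff(charges) >= -1e-9)

    def test_population_scaling(self, hetero, pc):
        space = build_state_space(hetero)
        prot = make_gating_protocol(start=0.0, stop=0.0, sample_interval_ms=0.5)
        big = hetero.with_(n_channels=1000)
        traj = propagate_occupancy(big, prot, 0, pc, space)
        per = gating_current_trace(traj, space, big, pc, per_channel=True)
        pop = gating_current_trace(traj, space, big, pc, per_channel=False)
        assert np.allclose(pop.current, 1000 * per.current)


class TestIonicCurrent:
    def test_zero_when_closed(self, hetero, pc):
        prot = VoltageProtocol(
            episodes=(((50.0, -140.0),),), episode_labels=(-140.0,),
            holding_potential=-140.0, sample_interval=0.5)
        space = build_state_space(hetero)
        traj = propagate_occupancy(hetero, prot, 0, pc, space)
        tr = ionic_current_trace(traj, hetero, space)
        assert np.abs(tr.current).max() < 1e-6

    def test_zero_at_reversal(self, hetero, pc):
        asm = hetero.with_(reversal_potential=40.0)
        prot = make_gating_protocol(start=40.0, stop=40.0, sample_interval_ms=0.5)
        space = build_state_space(asm)
        traj = propagate_occupancy(asm, prot, 0, pc, space)
        tr = ionic_current_trace(traj, asm, space)
        step = tr.window_slice(prot.segment_window(0, -1))
        assert np.abs(tr.current[step]).max() < 1e-12

    def test_hetero_activates_earlier(self, pc):
        """Matched pair: the heterotetramer reaches half of its final
        current sooner than the homotetramer at the same test step."""
        from kvgating.presets import matched_pair
        homo, het = matched_pair(pc)
        prot = make_gating_protocol(start=0.0, stop=0.0, sample_interval_ms=0.02)
        t_half = {}
        for name, asm in (("homo", homo), ("het", het)):
            space = build_state_space(asm)
            traj = propagate_occupancy(asm, prot, 0, pc, space)
            tr = ionic_current_trace(traj, asm, space)
            sl = tr.window_slice(prot.segment_window(0, -1))
            y = tr.current[sl]
            t = tr.time[sl] - tr.time[sl][0]
            t_half[name] = t[np.argmax(y >= 0.5 * y[-1])]
        assert t_half["het"] < t_half["homo"]


class TestGillespie:
    def test_determinism(self, hetero, pc):
        prot = make_gating_protocol(start=-60.0, stop=-60.0, step_ms=10.0,
                                    prepulse_ms=5.0, holding_ms=1.0,
                                    sample_interval_ms=0.5)
        t1, c1 = gillespie_simulate(hetero, prot, 0, 50, seed=42, pc=pc)
        t2, c2 = gillespie_simulate(hetero, prot, 0, 50, seed=42, pc=pc)
        assert np.array_equal(c1, c2)

    def test_counts_conserved(self, hetero, pc):
        prot = make_gating_protocol(start=-60.0, stop=-60.0, step_ms=10.0,
                                    prepulse_ms=5.0, holding_ms=1.0,
                                    sample_interval_ms=0.5)
        _, c = gillespie_simulate(hetero, prot, 0, 37, seed=7, pc=pc)
        assert np.all(c.sum(axis=1) == 37)

    def test_mean_matches_master_equation(self, hetero, pc):
        """Mean over 2000 channels within 3 SE of the deterministic
        occupancies at 10 checkpoints (fixed seed)."""
        n = 2000
        prot = make_gating_protocol(start=-60.0, stop=-60.0, step_ms=30.0,
                                    prepulse_ms=10.0, holding_ms=2.0,
                                    sample_interval_ms=0.5)
        t, c = gillespie_simulate(hetero, prot, 0, n, seed=123, pc=pc)
        traj = propagate_occupancy(hetero, prot, 0, pc)
        checkpoints = np.linspace(0, len(t) - 1, 10).astype(int)
        for k in checkpoints:
            p = traj.probabilities[k]
            se = np.sqrt(np.clip(p * (1 - p), 1e-12, None) / n)
            diff = np.abs(c[k] / n - p)
            # 2/n slack: binomial counts are integers, so states with
            # expected counts below ~1 otherwise trip the normal bound
            assert np.all(diff <= 3 * se + 2.0 / n), f"checkpoint {k}: {diff / se}"

    def test_no_transitions_when_rates_vanish(self, pc):
        from kvgating import ChannelAssembly, SubunitKinetics
        kin = SubunitKinetics(1e-12, 1e-12, 1.0, 1.0)
        asm = ChannelAssembly.homotetramer(kin, opening_rate=1e-12,
                                           closing_rate=1e-12)
        prot = make_gating_protocol(start=0.0, stop=0.0, step_ms=10.0,
                                    prepulse_ms=5.0, holding_ms=1.0,
                                    sample_interval_ms=0.5)
        _, c = gillespie_simulate(asm, prot, 0, 1, seed=0, pc=pc)
        occupied = np.nonzero(c.sum(axis=0))[0]
        assert len(occupied) == 1
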