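"""Gillespie engine: exactness, replication dilution, determinism, protocols."""

import numpy as np
import pytest

import h3k27sim as h
from h3k27sim.engine import NEW, OLD, ensemble_seeds
from h3k27sim.kinetics import AC, ME1, ME2, ME3, U


def uniform_profile(lattice, psi_s=0.0, psi_p=0.0, psi_u=0.0):
    n = lattice.n_sites
    return h.HMEProfile(lattice, np.full(n, psi_s), np.full(n, psi_p), np.full(n, psi_u))


def frozen_params(**overrides):
    """All reaction rates zero unless overridden; replication pushed far away."""
    base = dict(k_me3=0.0, R=0.0, gamma_me=0.0, k_ac=0.0, gamma_ac=0.0,
                gamma_turn=0.0, T=1e6)
    base.update(overrides)
    return h.ModelParams(**base)


class TestSimulate:
    def test_all_rates_zero_configuration_constant(self):
        lattice = h.Lattice(n_sites=20)
        profile = uniform_profile(lattice, 0.5, 0.5, 0.5)
        protocol = h.SimulationProtocol(duration=40.0, burn_in_cycles=0, replication_phase=0.0)
        init = np.tile([U, AC, ME1, ME2, ME3], 4).astype(np.int8)
        tr = h.simulate(profile, frozen_params(), protocol, seed=1, initial_config=init)
        assert np.all(tr.states == init)

    def test_turnover_only_exponential_decay(self):
        """All-me3 start decays to u at rate gamma_turn; half-life ~23.1 h."""
        lattice = h.Lattice(n_sites=200)
        profile = uniform_profile(lattice)
        params = frozen_params(gamma_turn=0.03)
        protocol = h.SimulationProtocol(
            duration=25.0, burn_in_cycles=0, replication_phase=0.0, record_interval=0.1
        )
        init = np.full(200, ME3, dtype=np.int8)
        fractions = []
        for seed in range(10):
            tr = h.simulate(profile, params, protocol, seed=seed, initial_config=init)
            k = np.argmin(np.abs(tr.times - 23.1))
            fractions.append(tr.mark_fraction(ME3)[k])
        n = 10 * 200
        se = np.sqrt(0.25 / n)
        assert np.mean(fractions) == pytest.approx(0.5, abs=3 * se + 0.01)

    def test_acetylation_only_matches_periodic_oracle(self):
        """Site-wise time-averaged P(ac) vs the exact decoupled solution."""
        lattice = h.Lattice(n_sites=20)
        psi_p = np.linspace(0.05, 0.8, 20)
        profile = h.HMEProfile(lattice, np.zeros(20), psi_p, np.zeros(20))
        params = h.ModelParams(k_me3=0.0, gamma_me=0.0)
        protocol = h.SimulationProtocol(duration=4 * params.T, burn_in_cycles=6)
        ens = h.run_ensemble(profile, params, protocol, n_traj=40, seed=3)
        p_ac = ens.steady_profiles()["ac"]
        for i in [0, 7, 13, 19]:
            _, p_avg = h.single_site_periodic_steady_state(0.0, psi_p[i], 0.0, params)
            # autocorrelated sampling: allow ~3 SE with a conservative n_eff
            se = np.sqrt(p_avg[AC] * (1 - p_avg[AC]) / (40 * 8))
            assert p_ac[i] == pytest.approx(p_avg[AC], abs=3 * se + 0.01)
            # and the effective-rate formula stays within its documented bound
            assert p_ac[i] == pytest.approx(
                h.closed_form_ac(psi_p[i], params), abs=0.02 + 3 * se
            )

    def test_two_site_master_equation_exactness(self):
        """Empirical joint-state occupancy matches the dense stationary solution.

        Two coupled sites with spreading: brute-force 25-state generator,
        stationary distribution from its null space, compared to a long
        time-averaged trajectory without replication.
        """
        lattice = h.Lattice(n_sites=2, tss_index=1)
        psi_s, psi_p, psi_u = np.array([0.6, 0.3]), np.array([0.4, 0.2]), np.array([0.3, 0.5])
        profile = h.HMEProfile(lattice, psi_s, psi_p, psi_u)
        params = h.ModelParams(T=1e6, gamma_turn=0.05)

        # independent oracle: enumerate all 25 joint states and reactions
        k_me, eps = params.k_me, params.eps_me
        P01 = 1.0  # |0-1|^-1
        idx = lambda a, b: 5 * a + b
        Q = np.zeros((25, 25))

        def add(frm, to, rate):
            Q[to, frm] += rate
            Q[frm, frm] -= rate

        for a in range(5):
            for b in range(5):
                s = (a, b)
                for site in (0, 1):
                    other = 1 - site
                    spread = P01 * psi_s[other] * (s[other] == ME3)
                    cur = s[site]

                    def to_state(new):
                        t = list(s)
                        t[site] = new
                        return idx(*t)

                    if cur in (U, ME1, ME2):
                        x = {U: 0, ME1: 1, ME2: 2}[cur]
                        add(idx(a, b), to_state(cur + 2 if cur == U else cur + 1),
                            k_me[x] * psi_s[site] + eps[x] * spread)
                    if cur == U:
                        add(idx(a, b), to_state(AC), params.k_ac * psi_p[site])
                    if cur == AC:
                        add(idx(a, b), to_state(U), params.gamma_ac)
                    if cur in (ME1, ME2, ME3):
                        add(idx(a, b), to_state(U if cur == ME1 else cur - 1),
                            params.gamma_me * psi_u[site])
                    if cur != U:
                        add(idx(a, b), to_state(U), params.gamma_turn)

        w, v = np.linalg.eig(Q)
        stat = np.real(v[:, np.argmin(np.abs(w))])
        stat = stat / stat.sum()

        protocol = h.SimulationProtocol(
            duration=6000.0, burn_in_cycles=0, replication_phase=0.0, record_interval=0.5
        )
        counts = np.zeros(25)
        n_traj = 4
        for seed in range(n_traj):
            tr = h.simulate(profile, params, protocol, seed=100 + seed)
            keep = tr.times > 300.0  # discard transient
            joint = 5 * tr.states[keep, 0].astype(int) + tr.states[keep, 1].astype(int)
            counts += np.bincount(joint, minlength=25)
        emp = counts / counts.sum()
        # ~0.5 h correlation-limited samples: n_eff >> 1000 per trajectory
        n_eff = 1500.0 * n_traj
        for s in range(25):
            se = np.sqrt(max(stat[s] * (1 - stat[s]), 1e-6) / n_eff)
            assert emp[s] == pytest.approx(stat[s], abs=3 * se + 0.004), f"joint state {s}"

    def test_state_u_transition_encoding(self):
        # methylation from u goes to me1, not ac (encoding guard for the kernel)
        lattice = h.Lattice(n_sites=10)
        profile = uniform_profile(lattice, psi_s=5.0)
        params = frozen_params(k_me3=1.0, r13=1.0, r23=1.0)
        protocol = h.SimulationProtocol(duration=2.0, burn_in_cycles=0, replication_phase=0.0)
        tr = h.simulate(profile, params, protocol, seed=2)
        final = tr.states[-1]
        assert set(np.unique(final)).issubset({U, ME1, ME2, ME3})


class TestReplicate:
    def test_half_erased_on_average(self):
        rng = np.random.default_rng(0)
        erased = 0
        n_events = 100
        for _ in range(n_events):
            config = np.full(200, ME3, dtype=np.int8)
            pools = np.zeros(200, dtype=np.int8)
            h.replicate(config, pools, rng)
            erased += np.sum(config == U)
        mean = erased / (200 * n_events)
        se = np.sqrt(0.25 / (200 * n_events))
        assert mean == pytest.approx(0.5, abs=3 * se)

    def test_fixed_seed_reproduces_mask(self):
        config1 = np.full(50, ME2, dtype=np.int8)
        config2 = config1.copy()
        pools = np.zeros(50, dtype=np.int8)
        _, _, m1 = h.replicate(config1, pools.copy(), np.random.default_rng(42))
        _, _, m2 = h.replicate(config2, pools.copy(), np.random.default_rng(42))
        assert np.array_equal(m1, m2)
        assert np.array_equal(config1, config2)

    def test_all_u_lattice_unchanged_but_labels_flip(self):
        config = np.full(100, U, dtype=np.int8)
        pools = np.full(100, OLD, dtype=np.int8)
        _, _, lost = h.replicate(config, pools, np.random.default_rng(7))
        assert np.all(config == U)
        assert np.all(pools[lost] == NEW)
        assert np.all(pools[~lost] == OLD)


class TestEnsemble:
    def test_same_master_seed_identical_summaries(self, pcg_profile, params):
        protocol = h.SimulationProtocol(duration=10.0, burn_in_cycles=2)
        e1 = h.run_ensemble(pcg_profile, params, protocol, 4, seed=9)
        e2 = h.run_ensemble(pcg_profile, params, protocol, 4, seed=9)
        assert np.array_equal(e1.occupancy(), e2.occupancy())

    def test_single_trajectory_matches_derived_subseed(self, pcg_profile, params):
        protocol = h.SimulationProtocol(duration=10.0, burn_in_cycles=2)
        ens = h.run_ensemble(pcg_profile, params, protocol, 1, seed=5)
        sub = int(ensemble_seeds(5, 1)[0])
        tr = h.simulate(pcg_profile, params, protocol, sub)
        assert np.array_equal(ens.trajectories[0].states, tr.states)

    def test_state_conservation(self, wt_steady_ensemble):
        occ = wt_steady_ensemble.occupancy()
        assert np.allclose(occ.sum(axis=0), 1.0)

    def test_zero_trajectories_rejected(self, pcg_profile, params):
        protocol = h.SimulationProtocol(duration=1.0, burn_in_cycles=0)
        with pytest.raises(ValueError):
            h.run_ensemble(pcg_profile, params, protocol, 0, seed=1)


class TestProtocols:
    def test_washout_no_change_means_no_events(self, params):
        protocol = h.washout_protocol(10.0, params, params, duration=20.0)
        assert protocol.events == ()

    def test_washout_default_is_no_spreading_before(self, params):
        protocol = h.washout_protocol(0.0, None, params, duration=20.0)
        assert protocol.initial_params.R == 0.0
        assert protocol.events[0][1]["params"].R == params.R

    def test_negative_t0_rejected(self, params):
        with pytest.raises(ValueError):
            h.washout_protocol(-1.0, None, params, duration=10.0)

    def test_switch_identical_profiles_no_transient(self, pcg_profile):
        protocol = h.switch_protocol(5.0, pcg_profile, pcg_profile, duration=10.0)
        assert protocol.events == ()

    def test_event_times_strictly_increasing_enforced(self, params):
        with pytest.raises(ValueError):
            h.SimulationProtocol(
                duration=10.0,
                events=((2.0, {"params": params}), (2.0, {"params": params})),
            )

    def test_no_spreading_has_less_me3_than_wild_type(self, pcg_profile, params):
        from h3k27sim.observables import steady_state_ensemble

        ko = steady_state_ensemble(
            pcg_profile, params.with_(R=0.0), n_traj=12, burn_in_cycles=8,
            sample_cycles=3, seed=21,
        )
        wt = steady_state_ensemble(
            pcg_profile, params, n_traj=12, burn_in_cycles=8, sample_cycles=3, seed=22
        )
        assert wt.steady_profiles()["me3"].mean() > ko.steady_profiles()["me3"].mean() + 0.1
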