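import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from ngvu.synapse import pools as pools_mod
from ngvu.synapse.params import load_params
from ngvu.synapse.pools import (TransmitterPools, cleft_transmitter_rhs,
                                spontaneous_rate, tm_pool_step)
from ngvu.synapse.sensor import (READY_STATE, VesicleSensorState,
                                 propensities, sensor_step)


@pytest.fixture(scope="module")
def p():
    return load_params()


def oracle_generator(c_i, p):
    """Independent master-equation generator built from the printed scheme
    (5 sequential binding sites + isomerization), not via the package's
    propensity helper."""
    alpha, beta = p.sensor_alpha, p.sensor_beta
    gamma, delta = p.sensor_gamma, p.sensor_delta
    q = np.zeros((7, 7))
    for k in range(5):                    # k -> k+1 with rate (5-k) a c
        q[k, k + 1] = (5 - k) * alpha * c_i
    for k in range(1, 6):                 # k -> k-1 with rate k b
        q[k, k - 1] = k * beta
    q[5, 6] = gamma
    q[6, 5] = delta
    for k in range(7):
        q[k, k] = -q[k].sum() + q[k, k]
    return q


class TestPropensities:
    def test_zero_calcium_no_binding(self, p):
        props = propensities(0, 0.0, p)
        assert props == [(0.0, 1)]

    def test_mass_action_doubling(self, p):
        r1 = dict((nxt, r) for r, nxt in propensities(2, 1.0, p))
        r2 = dict((nxt, r) for r, nxt in propensities(2, 2.0, p))
        assert r2[3] == pytest.approx(2.0 * r1[3])     # forward doubles
        assert r2[1] == pytest.approx(r1[1])           # backward unchanged

    def test_isomerization_rates(self, p):
        assert dict((n, r) for r, n in propensities(5, 1.0, p))[READY_STATE] \
            == pytest.approx(p.sensor_gamma)
        assert propensities(READY_STATE, 1.0, p) == [(p.sensor_delta, 5)]


class TestSensorSSA:
    def test_drift_to_unbound_at_zero_calcium(self, p):
        rng = np.random.default_rng(0)
        s = VesicleSensorState(np.array([4, 5]))
        for _ in range(200):
            s, _ = sensor_step(s, 0.0, 0.1, rng, p)
        assert np.all(s.occupancy == 0)

    def test_stationary_distribution_matches_master_equation(self, p):
        """Long-run occupancy histogram vs the matrix-exponential
        stationary distribution of the independent oracle generator."""
        c_i = 5.0
        q = oracle_generator(c_i, p)
        pi = expm(q.T * 1e6)[:, 0]
        pi = pi / pi.sum()

        rng = np.random.default_rng(42)
        s = VesicleSensorState(np.zeros(1, dtype=int))
        counts = np.zeros(7)
        n_samples = 30000
        for _ in range(n_samples):
            s, _ = sensor_step(s, c_i, 0.05, rng, p)
            counts[s.occupancy[0]] += 1
        freq = counts / counts.sum()
        # MC error ~ 1/sqrt(n_eff); allow generous band
        assert np.abs(freq - pi).max() < 0.02

    def test_mean_trajectory_matches_ode(self, p):
        """Ensemble-mean occupancy vs the master-equation ODE within 3 SE
        at checkpoints."""
        c_i = 8.0
        q = oracle_generator(c_i, p)
        dt = 0.02       # ms
        n_rep = 3000
        n_steps = 25
        checks = [5, 10, 15, 20, 25]
        rng = np.random.default_rng(7)
        occ = np.zeros((n_rep,), dtype=int)
        states = [VesicleSensorState(np.zeros(1, dtype=int))
                  for _ in range(n_rep)]
        mean_traj = {}
        for step in range(1, n_steps + 1):
            for i in range(n_rep):
                states[i], _ = sensor_step(states[i], c_i, dt, rng, p)
            if step in checks:
                occ = np.array([s.occupancy[0] for s in states])
                mean_traj[step] = (occ.mean(), occ.std() / np.sqrt(n_rep))
        # ODE oracle
        def rhs(t, prob):
            return q.T @ prob
        prob0 = np.zeros(7)
        prob0[0] = 1.0
        sol = solve_ivp(rhs, (0.0, n_steps * dt), prob0, rtol=1e-10,
                        atol=1e-12, dense_output=True)
        lev = np.arange(7)
        for step, (mean, se) in mean_traj.items():
            expected = float(lev @ sol.sol(step * dt))
            assert abs(mean - expected) < 3.0 * max(se, 1e-6), \
                f"checkpoint {step}: {mean} vs {expected}"

    def test_ready_fraction_values(self, p):
        s = VesicleSensorState(np.array([READY_STATE, READY_STATE]))
        assert s.n_ready == 2
        rng = np.random.default_rng(0)
        _, f_r = sensor_step(VesicleSensorState(np.array([0, 0])), 0.0,
                             1e-9, rng, p)
        assert f_r == 0.0

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError):
            VesicleSensorState(np.array([9]))


class TestSpontaneousRate:
    def test_midpoint(self):
        assert spontaneous_rate(5.0, 5.0, 1.0, 3.0) == pytest.approx(1.5)

    def test_saturation(self):
        assert spontaneous_rate(1e9, 5.0, 1.0, 3.0) == pytest.approx(3.0)

    def test_monotone(self):
        c = np.linspace(0.0, 20.0, 100)
        lam = np.array([spontaneous_rate(x, 5.0, 1.0, 3.0) for x in c])
        assert np.all(np.diff(lam) > 0)

    def test_zero_a2_rejected(self):
        with pytest.raises(ValueError):
            spontaneous_rate(1.0, 5.0, 0.0, 3.0)


class TestTMPools:
    def test_partition_preserved(self, p):
        pool = TransmitterPools("glu", r=0.6, e=0.3)
        for k in range(2000):
            pool = tm_pool_step(pool, 1.0 if k % 200 == 0 else 0.0,
                                1e-4, p)
            assert pool.r + pool.e + pool.i == pytest.approx(1.0, abs=1e-10)
            assert 0.0 <= pool.r <= 1.0 and 0.0 <= pool.e <= 1.0

    def test_decay_closed_form(self, p):
        """f_r = 0: E(t) = E0 exp(-t/tau_inact) and R -> 1."""
        pool = TransmitterPools("glu", r=0.5, e=0.4)
        t = 0.01
        n = 100
        for _ in range(n):
            pool = tm_pool_step(pool, 0.0, t / n, p)
        assert pool.e == pytest.approx(0.4 * np.exp(-t / p.tau_inact),
                                       rel=1e-6)
        # long horizon: everything recovers to R = 1
        for _ in range(4000):
            pool = tm_pool_step(pool, 0.0, 2e-3, p)
        assert pool.r == pytest.approx(1.0, abs=1e-3)

    def test_refractory_lockout_glu(self, p):
        pool = TransmitterPools("glu")
        pool = tm_pool_step(pool, 1.0, 1e-4, p)
        e_after_first = pool.e
        assert e_after_first > 0.0
        # further release attempts within 6.34 ms are ignored
        for _ in range(60):   # 6.0 ms
            pool = tm_pool_step(pool, 1.0, 1e-4, p)
            assert pool.e <= e_after_first + 1e-12
        # after the window a new release succeeds
        for _ in range(10):   # +1.0 ms -> beyond 6.34 ms
            pool = tm_pool_step(pool, 0.0, 1e-4, p)
        e_before = pool.e
        pool = tm_pool_step(pool, 1.0, 1e-4, p)
        assert pool.e > e_before

    def test_gaba_refractory_longer(self, p):
        assert pools_mod.refractory_window("gaba", p) \
            == pytest.approx(0.0072)
        assert pools_mod.refractory_window("glu", p) \
            == pytest.approx(0.00634)


class TestCleftTransmitter:
    def test_decay_only(self, p):
        pool = TransmitterPools("glu", cleft=3.0, e=0.0)
        dg, _ = cleft_transmitter_rhs(pool, p)
        assert dg == pytest.approx(-p.g_c * 3.0)

    def test_steady_state(self, p):
        e = 0.01
        pool = TransmitterPools("glu", e=e)
        g_star = p.n_v * p.g_v_glu * e / p.g_c
        pool.cleft = g_star
        dg, _ = cleft_transmitter_rhs(pool, p)
        assert dg == pytest.approx(0.0, abs=1e-9)

    def test_vesicular_concentration_defaults(self, p):
        assert p.g_v_glu == 60000.0   # 60 mM
        assert p.g_v_gaba == 20000.0  # 20 mM
        assert p.record("g_v_glu")["source"] == "paper"
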