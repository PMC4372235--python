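import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtirf.sim import (
    CellGeometry,
    ConfigError,
    SimConfig,
    Trajectory,
    _reflect,
    ensemble_msd,
    simulate_membrane_dynamics,
)

TWO_PI = 2 * np.pi


def cfg(geometry, **kw):
    base = dict(D_free=0.02, dt=0.05, n_steps=30, n_particles=40, geometry=geometry, seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_negative_rate_rejected(self, geometry):
        with pytest.raises(ConfigError):
            cfg(geometry, k_on=-1.0)

    def test_nonfinite_diffusion_rejected(self, geometry):
        with pytest.raises(ConfigError):
            cfg(geometry, D_free=np.nan)

    def test_nonpositive_dt_rejected(self, geometry):
        with pytest.raises(ConfigError):
            cfg(geometry, dt=0.0)
        with pytest.raises(ConfigError):
            cfg(geometry, dt=-0.1)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ConfigError):
            CellGeometry(length=-1.0, radius=0.4)
        with pytest.raises(ConfigError):
            CellGeometry(length=3.0, radius=0.0)

    def test_step_size_warning(self, geometry):
        with pytest.warns(UserWarning, match="capture_radius"):
            cfg(geometry, D_free=1.0, dt=0.5, n_sites=5, k_on=1.0, capture_radius=0.05)

    def test_no_warning_without_sites(self, geometry):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            cfg(geometry, D_free=1.0, dt=0.5)


class TestFrozenDynamics:
    def test_zero_diffusion_freezes_everything(self, geometry):
        traj = simulate_membrane_dynamics(
            cfg(geometry, D_free=0.0, D_bound=0.0, k_on=0.0, n_particles=10)
        )
        for f in range(1, traj.n_frames):
            np.testing.assert_array_equal(traj.s_raw[f], traj.s_raw[0])
            np.testing.assert_array_equal(traj.arc_raw[f], traj.arc_raw[0])

    def test_no_sites_means_no_binding(self, geometry):
        traj = simulate_membrane_dynamics(cfg(geometry, n_sites=0, k_on=5.0, k_off=1.0))
        assert np.all(traj.bound_fraction() == 0.0)


class TestInvariants:
    def test_coordinates_stay_wrapped(self, small_traj, geometry):
        assert small_traj.s.min() >= 0
        assert small_traj.s.max() <= geometry.length
        assert small_traj.theta.min() >= 0
        assert small_traj.theta.max() < TWO_PI

    def test_particle_count_constant(self, small_traj):
        assert small_traj.s_raw.shape[1] == small_traj.config.n_particles

    def test_occupancy_within_capacity_and_conserved(self, geometry):
        traj = simulate_membrane_dynamics(
            cfg(
                geometry,
                n_sites=8,
                site_capacity=3,
                capture_radius=0.2,
                k_on=20.0,
                k_off=0.5,
                n_steps=100,
                n_particles=100,
            )
        )
        for f in range(traj.n_frames):
            occ = traj.occupancy(f)
            assert occ.max() <= 3
            assert occ.sum() == int(np.sum(traj.bound_site[f] >= 0))

    def test_seed_reproducibility_byte_identical(self, geometry):
        c = cfg(geometry, n_sites=5, k_on=10.0, k_off=1.0, capture_radius=0.3)
        t1 = simulate_membrane_dynamics(c)
        t2 = simulate_membrane_dynamics(c)
        assert t1.s_raw.tobytes() == t2.s_raw.tobytes()
        assert t1.arc_raw.tobytes() == t2.arc_raw.tobytes()
        assert t1.bound_site.tobytes() == t2.bound_site.tobytes()

    def test_particle_substreams_stable_under_count_change(self, geometry):
        t_small = simulate_membrane_dynamics(cfg(geometry, n_particles=5))
        t_big = simulate_membrane_dynamics(cfg(geometry, n_particles=9))
        np.testing.assert_array_equal(t_small.s_raw, t_big.s_raw[:, :5])
        np.testing.assert_array_equal(t_small.arc_raw, t_big.arc_raw[:, :5])


class TestMSD:
    def test_msd_matches_2d_brownian(self, ):
        # scaled-down version of the full acceptance oracle
        g = CellGeometry(length=40.0, radius=2.0)
        c = SimConfig(D_free=0.05, dt=0.01, n_steps=200, n_particles=2000, geometry=g, seed=5)
        t, msd = ensemble_msd(simulate_membrane_dynamics(c))
        slope = np.sum(t * msd) / np.sum(t * t)
        assert slope == pytest.approx(4 * 0.05, rel=0.08)

    def test_msd_zero_at_t0(self, small_traj):
        _, msd = ensemble_msd(small_traj)
        assert msd[0] == 0.0


def _gillespie_bound_fraction(n, k_on, k_off, t_total, rng):
    """Independent CTMC oracle for the all-particles-capturable two-state system."""
    b = 0
    t = 0.0
    acc = 0.0
    while t < t_total:
        rate = (n - b) * k_on + b * k_off
        wait = rng.exponential(1.0 / rate)
        wait = min(wait, t_total - t)
        acc += b * wait
        t += wait
        if t >= t_total:
            break
        if rng.random() < (n - b) * k_on / rate:
            b += 1
        else:
            b -= 1
    return acc / (t_total * n)


class TestBindingKinetics:
    def test_steady_state_matches_gillespie_oracle(self, geometry):
        k_on, k_off, n = 1.0, 1.5, 200
        c = cfg(
            geometry,
            n_particles=n,
            n_sites=1,
            site_capacity=n,
            capture_radius=100.0,  # capture everywhere
            k_on=k_on,
            k_off=k_off,
            dt=0.01,
            n_steps=3000,
        )
        traj = simulate_membrane_dynamics(c)
        sim_frac = traj.bound_fraction()[1000:].mean()
        oracle = _gillespie_bound_fraction(n, k_on, k_off, 400.0, np.random.default_rng(42))
        p = k_on / (k_on + k_off)
        # ~3 SE for the correlated mean (tau_corr = 1/(k_on+k_off) = 40 ticks)
        n_eff = 2000 / 40 * n
        se = np.sqrt(p * (1 - p) / n_eff) * 3
        assert abs(sim_frac - oracle) < 3 * se + 0.02

    def test_detailed_balance_equal_diffusion(self, geometry):
        k_on, k_off = 2.0, 2.0
        c = cfg(
            geometry,
            D_bound=0.02,
            n_particles=300,
            n_sites=1,
            site_capacity=300,
            capture_radius=100.0,
            k_on=k_on,
            k_off=k_off,
            dt=0.01,
            n_steps=2000,
        )
        traj = simulate_membrane_dynamics(c)
        frac = traj.bound_fraction()[500:].mean()
        assert frac == pytest.approx(k_on / (k_on + k_off), abs=0.03)


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path, geometry):
        traj = simulate_membrane_dynamics(
            cfg(geometry, n_sites=4, k_on=10.0, k_off=1.0, capture_radius=0.3, n_steps=10)
        )
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path)
        back = Trajectory.from_tsv(path)
        np.testing.assert_allclose(back.s, traj.s, rtol=1e-6, atol=1e-6)
        np.testing.assert_allclose(back.theta, traj.theta, rtol=1e-6, atol=1e-6)
        np.testing.assert_array_equal(back.bound_site, traj.bound_site)
        assert back.config.n_particles == traj.config.n_particles
        assert back.site_positions.shape == traj.site_positions.shape


@given(
    x=st.floats(-50, 50, allow_nan=False),
    length=st.floats(0.5, 10, allow_nan=False),
)
@settings(max_examples=200, deadline=None)
def test_reflect_stays_in_range(x, length):
    y = _reflect(np.array([x]), length)[0]
    assert 0.0 <= y <= length


def test_reflect_identity_inside():
    x = np.linspace(0, 3, 7)
    np.testing.assert_allclose(_reflect(x, 3.0), x)
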