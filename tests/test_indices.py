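"""TAWSS / OSI / RRT post-processing chain."""

import numpy as np
import pytest

from stenoflow.indices import (
    IndexProfile,
    WallTractionSeries,
    index_profile,
    osi,
    rrt,
    tawss,
)
from stenoflow.waveforms import synthetic_wall_traction


def _series(tau, period=1.0):
    tau = np.asarray(tau, dtype=float)
    n_pos, n_t = tau.shape[:2]
    return WallTractionSeries(
        positions=np.arange(n_pos, dtype=float),
        times=np.arange(n_t) * (period / n_t),
        period=period,
        tau=tau,
    )


class TestTawss:
    def test_constant_magnitude_exact(self):
        s = synthetic_wall_traction("constant", amplitude=3.25, n_points=5, n_time=64)
        assert np.allclose(tawss(s), 3.25, rtol=1e-13)

    def test_reversing_sinusoid_mean(self):
        # analytic mean of |A sin| is 2A/pi
        A = 1.7
        s = synthetic_wall_traction("reversing", amplitude=A, n_points=3, n_time=400)
        assert np.allclose(tawss(s), 2.0 * A / np.pi, rtol=5e-3)

    def test_all_zero_series(self):
        s = _series(np.zeros((4, 16, 2)))
        assert np.allclose(tawss(s), 0.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 time samples"):
            _series(np.zeros((2, 3, 2)))


class TestOsi:
    def test_constant_is_zero(self):
        s = synthetic_wall_traction("constant", amplitude=1.1, n_time=100)
        assert np.allclose(osi(s), 0.0, atol=1e-14)

    def test_reversing_is_half(self):
        s = synthetic_wall_traction("reversing", amplitude=0.8, n_time=100)
        assert np.allclose(osi(s), 0.5, atol=1e-12)

    def test_rotating_is_half(self):
        s = synthetic_wall_traction("rotating", amplitude=2.0, n_time=100)
        assert np.allclose(osi(s), 0.5, atol=1e-12)

    def test_zero_traction_convention(self):
        s = _series(np.zeros((3, 8, 2)))
        assert np.allclose(osi(s), 0.0)

    def test_range_invariant_random_series(self):
        rng = np.random.default_rng(42)
        s = _series(rng.normal(size=(20, 32, 3)))
        o = osi(s)
        assert np.all((o >= 0.0) & (o <= 0.5))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        tau = rng.normal(size=(10, 24, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert np.allclose(osi(_series(tau @ q.T)), osi(_series(tau)), atol=1e-12)


class TestRrt:
    def test_direct_substitutions(self):
        vals, flags = rrt(np.array([0.0, 0.25]), np.array([2.0, 1.0]))
        assert vals == pytest.approx([0.5, 2.0])
        assert not flags.any()

    def test_osi_half_flagged_singular(self):
        vals, flags = rrt(np.array([0.5]), np.array([3.0]), epsilon=1e-3)
        assert flags[0]
        assert vals[0] == pytest.approx(1.0 / (1e-3 * 3.0))

    def test_zero_tawss_flagged_infinite(self):
        vals, flags = rrt(np.array([0.1]), np.array([0.0]))
        assert flags[0] and np.isinf(vals[0])

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            rrt(np.array([0.0]), np.array([1.0]), epsilon=0.0)


class TestIndexProfile:
    def test_constant_composition(self):
        c = 2.5
        s = synthetic_wall_traction("constant", amplitude=c, n_points=4, n_time=100)
        prof = index_profile(s)
        assert np.allclose(prof.tawss, c)
        assert np.allclose(prof.osi, 0.0, atol=1e-14)
        assert np.allclose(prof.rrt, 1.0 / c)
        assert not prof.rrt_flag.any()

    def test_reversing_flags_everywhere(self):
        s = synthetic_wall_traction("reversing", amplitude=1.0, n_points=6, n_time=100)
        prof = index_profile(s)
        assert prof.rrt_flag.all()

    def test_mixed_fixture_flags_only_reversing_half(self):
        const = synthetic_wall_traction("constant", amplitude=1.0, n_points=4, n_time=100)
        rev = synthetic_wall_traction("reversing", amplitude=1.0, n_points=4, n_time=100)
        tau = np.concatenate([const.tau, rev.tau], axis=0)
        prof = index_profile(_series(tau, period=const.period))
        assert not prof.rrt_flag[:4].any()
        assert prof.rrt_flag[4:].all()

    def test_csv_round_trip(self, tmp_path):
        s = synthetic_wall_traction("offset_sine", amplitude=0.5, n_points=5, n_time=20)
        path = tmp_path / "traction.csv"
        s.to_csv(path)
        back = WallTractionSeries.from_csv(path, period=s.period)
        assert np.allclose(back.tau, s.tau)
        assert np.allclose(back.positions, s.positions)


class TestProperties:
    def test_quadrature_stability_under_time_doubling(self):
        # smooth mixed pattern: same analytic signal at 100 vs 200 samples
        out = {}
        for n in (100, 200):
            s = synthetic_wall_traction("offset_sine", amplitude=0.8, n_points=3,
                                        n_time=n, offset=1.0)
            out[n] = (tawss(s), osi(s))
        assert np.allclose(out[100][0], out[200][0], rtol=5e-3)
        assert np.allclose(out[100][1], out[200][1], atol=5e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        tau = rng.normal(size=(12, 40, 2)) + 1.5   # mostly one-signed
        s = _series(tau)
        k = 3.7
        sk = s.scaled(k)
        assert np.allclose(tawss(sk), k * tawss(s), rtol=1e-12)
        assert np.allclose(osi(sk), osi(s), atol=1e-13)
        p, pk = index_profile(s), index_profile(sk)
        ok = ~p.rrt_flag
        assert np.allclose(pk.rrt[ok], p.rrt[ok] / k, rtol=1e-12)
        assert np.array_equal(p.rrt_flag, pk.rrt_flag)
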