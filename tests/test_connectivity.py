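"""wPLI estimator, Hilbert phase, baseline normalization, window averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wmconn as w
from wmconn.connectivity import window_average

from conftest import ALPHA, make_analytic, make_epochs


def wpli_reference(z):
    """Naive triple-loop wPLI oracle, straight from the definition."""
    n_tr, n_reg, n_s = z.shape
    out = np.zeros((n_s, n_reg, n_reg))
    for t in range(n_s):
        for i in range(n_reg):
            for j in range(n_reg):
                if i == j:
                    continue
                num = den = 0.0
                for k in range(n_tr):
                    im = (z[k, i, t] * np.conj(z[k, j, t])).imag
                    num += im
                    den += abs(im)
                out[t, i, j] = abs(num) / den if den > 0 else 0.0
    return out


class TestAnalyticSignal:
    def test_cosine_phase_and_amplitude(self):
        fs, f = 600.0, 10.0
        t = np.arange(int(2 * fs)) / fs
        x = np.cos(2 * np.pi * f * t)[None, None, :]
        z = w.analytic_signal(make_epochs(x, fs=fs, t0=0.0)).data[0, 0]
        mid = len(t) // 2
        expected = 2 * np.pi * f * t[mid]
        got = np.angle(z[mid])
        circ = (got - expected + np.pi) % (2 * np.pi) - np.pi
        assert abs(circ) < 0.05
        interior = slice(int(0.2 * fs), -int(0.2 * fs))
        assert np.allclose(np.abs(z[interior]), 1.0, atol=0.02)

    def test_sine_lags_cosine_by_half_pi(self):
        fs, f = 600.0, 10.0
        t = np.arange(int(2 * fs)) / fs
        xc = np.cos(2 * np.pi * f * t)[None, None, :]
        xs = np.sin(2 * np.pi * f * t)[None, None, :]
        zc = w.analytic_signal(make_epochs(xc, fs=fs, t0=0.0)).data[0, 0]
        zs = w.analytic_signal(make_epochs(xs, fs=fs, t0=0.0)).data[0, 0]
        mid = len(t) // 2
        dphi = (np.angle(zc[mid]) - np.angle(zs[mid])) % (2 * np.pi)
        assert abs(dphi - np.pi / 2) < 0.05

    def test_am_envelope_recovered(self):
        fs, f = 600.0, 10.0
        t = np.arange(int(4 * fs)) / fs
        a = 1.0 + 0.3 * np.sin(2 * np.pi * 0.5 * t)
        x = (a * np.cos(2 * np.pi * f * t))[None, None, :]
        z = w.analytic_signal(make_epochs(x, fs=fs, t0=0.0)).data[0, 0]
        interior = slice(int(0.3 * fs), -int(0.3 * fs))
        assert np.allclose(np.abs(z[interior]), a[interior], rtol=0.03)

    def test_nonfinite_rejected(self):
        x = np.ones((2, 2, 100))
        ep = make_epochs(x)
        ep.data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            w.analytic_signal(ep)


class TestWpli:
    def test_constant_phase_lag_is_exactly_one(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 2 * np.pi, (20, 1, 5))
        z = np.concatenate([np.exp(1j * theta), np.exp(1j * (theta - 0.5))], axis=1)
        conn = w.wpli_timeseries(make_analytic(z))
        assert np.all(conn.values[:, 0, 1] == 1.0)

    def test_sign_balanced_imaginaries_are_exactly_zero(self):
        # trials with Im(X) = {+a, -a} cancel exactly
        z_i = np.ones((2, 1, 3), dtype=complex)
        z_j = np.stack([
            np.full((1, 3), np.exp(-0.5j)), np.full((1, 3), np.exp(0.5j)),
        ])
        conn = w.wpli_timeseries(make_analytic(np.concatenate([z_i, z_j], axis=1)))
        assert np.all(conn.values[:, 0, 1] == 0.0)

    def test_one_third_from_mixed_signs(self):
        # Im(X) across trials = {1, 1, -1}  ->  |1| / 3
        z_i = np.ones((3, 1, 2), dtype=complex)
        phases = np.array([-np.pi / 2, -np.pi / 2, np.pi / 2])
        z_j = np.exp(1j * phases)[:, None, None] * np.ones((3, 1, 2))
        conn = w.wpli_timeseries(make_analytic(np.concatenate([z_i, z_j], axis=1)))
        assert np.allclose(conn.values[:, 0, 1], 1.0 / 3.0)

    def test_random_phases_near_zero(self):
        rng = np.random.default_rng(42)
        z = np.exp(1j * rng.uniform(0, 2 * np.pi, (1000, 2, 4)))
        conn = w.wpli_timeseries(make_analytic(z))
        assert np.all(conn.values[:, 0, 1] < 0.1)

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((10, 5, 20)) + 1j * rng.standard_normal((10, 5, 20))
        conn = w.wpli_timeseries(make_analytic(z))
        assert np.max(np.abs(conn.values - wpli_reference(z))) <= 1e-12

    def test_global_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal((6, 3, 10)) + 1j * rng.standard_normal((6, 3, 10))
        base = w.wpli_timeseries(make_analytic(z)).values
        z2 = z.copy()
        z2[:, 0, :] *= 2.7
        z2[:, 1, :] *= 0.3
        scaled = w.wpli_timeseries(make_analytic(z2)).values
        assert np.allclose(base, scaled, atol=1e-12)

    def test_needs_two_trials(self):
        z = np.ones((1, 2, 5), dtype=complex)
        with pytest.raises(ValueError, match="at least 2 trials"):
            w.wpli_timeseries(make_analytic(z))

    def test_debiased_variant_below_standard(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal((20, 3, 8)) + 1j * rng.standard_normal((20, 3, 8))
        std = w.wpli_timeseries(make_analytic(z)).values
        db = w.wpli_timeseries(make_analytic(z), debiased=True).values
        iu = np.triu_indices(3, 1)
        assert np.all(db[:, iu[0], iu[1]] <= std[:, iu[0], iu[1]] ** 2 + 1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariants_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((5, 4, 6)) + 1j * rng.standard_normal((5, 4, 6))
        conn = w.wpli_timeseries(make_analytic(z))
        conn.validate()  # [0,1], symmetric, zero diagonal, finite


class TestZscore:
    def _conn(self, values_01):
        # edge (0,1) timeseries at t = -0.4, -0.2, 0.5 s
        vals = np.zeros((3, 2, 2))
        vals[:, 0, 1] = vals[:, 1, 0] = values_01
        return w.ConnectivityTimeseries(
            values=vals, time=np.array([-0.4, -0.2, 0.5])
        )

    def test_population_sd_default(self):
        z = w.zscore_to_baseline(self._conn([1.0, 3.0, 5.0]))
        # baseline {1, 3}: mean 2, population SD 1  ->  (5 - 2) / 1
        assert np.isclose(z.values[2, 0, 1], 3.0)
        assert z.normalized and z.baseline_window == (-500.0, 0.0)

    def test_sample_sd_convention(self):
        z = w.zscore_to_baseline(self._conn([1.0, 3.0, 5.0]), ddof=1)
        assert np.isclose(z.values[2, 0, 1], 3.0 / np.sqrt(2.0), atol=1e-4)
        assert np.isclose(z.values[2, 0, 1], 2.1213, atol=1e-4)

    def test_constant_baseline_rejected(self):
        with pytest.raises(ValueError, match=r"edge \(0, 1\)"):
            w.zscore_to_baseline(self._conn([2.0, 2.0, 5.0]))

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(3)
        vals = rng.random((50, 3, 3))
        vals = (vals + vals.swapaxes(1, 2)) / 2
        idx = np.arange(3)
        vals[:, idx, idx] = 0
        conn = w.ConnectivityTimeseries(
            values=vals, time=np.linspace(-0.5, 1.0, 50)
        )
        z = w.zscore_to_baseline(conn)
        mask = (conn.time * 1000 >= -500) & (conn.time * 1000 < 0)
        base = z.values[mask][:, 0, 1]
        assert abs(base.mean()) < 1e-12

    def test_double_normalization_rejected(self):
        z = w.zscore_to_baseline(self._conn([1.0, 3.0, 5.0]))
        with pytest.raises(ValueError, match="already"):
            w.zscore_to_baseline(z)


class TestWholeBrainAndWindows:
    def _conn3(self, e01, e02, e12, n_samples=4):
        vals = np.zeros((n_samples, 3, 3))
        vals[:, 0, 1] = vals[:, 1, 0] = e01
        vals[:, 0, 2] = vals[:, 2, 0] = e02
        vals[:, 1, 2] = vals[:, 2, 1] = e12
        return w.ConnectivityTimeseries(
            values=vals, time=np.linspace(0, 1, n_samples, endpoint=False)
        )

    def test_mean_of_three_edges(self):
        wb = w.mean_whole_brain(self._conn3(0.2, 0.4, 0.6))
        assert np.allclose(wb.values, 0.4)

    def test_region_permutation_invariance(self):
        conn = self._conn3(0.2, 0.4, 0.6)
        perm = [2, 0, 1]
        permuted = w.ConnectivityTimeseries(
            values=conn.values[:, perm][:, :, perm], time=conn.time
        )
        assert np.allclose(
            w.mean_whole_brain(conn).values, w.mean_whole_brain(permuted).values
        )

    def test_window_average_two_samples(self):
        conn = w.ConnectivityTimeseries(
            values=np.array([[[0, 1], [1, 0]], [[0, 3], [3, 0]]], dtype=float),
            time=np.array([0.3, 0.4]),
        )
        assert np.isclose(window_average(conn, (250.0, 450.0))[0, 1], 2.0)

    def test_retention_window_covers_600_samples_at_600hz(self):
        time = -1.0 + np.arange(1801) / 600.0
        from wmconn.containers import window_mask

        assert window_mask(time, (250.0, 1250.0)).sum() == 600

    def test_window_outside_axis_rejected(self):
        conn = self._conn3(0.1, 0.1, 0.1)
        with pytest.raises(ValueError, match="selects no samples"):
            window_average(conn, (5000.0, 6000.0))

    def test_scalar_for_wholebrain_series(self):
        wb = w.mean_whole_brain(self._conn3(0.2, 0.4, 0.6))
        assert window_average(wb, (0.0, 1000.0)) == pytest.approx(0.4)


class TestParameterRecovery:
    def test_planted_edge_recovered_from_cohort(self, tiny_cohort):
        """Generator + full connectivity chain: kappa=1 edge (0,1) shows
        near-ceiling retention wPLI and a baseline near the null floor."""
        cfg, cohort = tiny_cohort
        ep = cohort.epochs[0]  # FT subject
        conn = w.subject_connectivity(ep, ALPHA, condition="correct", zscore=False)
        ret = window_average(conn, (250.0, 1250.0))
        base = window_average(conn, (-500.0, 0.0))
        assert ret[0, 1] > 0.9
        assert base[0, 1] < 0.45
        # VPT subject has no planted coupling
        conn_v = w.subject_connectivity(
            cohort.epochs[-1], ALPHA, condition="correct", zscore=False
        )
        assert window_average(conn_v, (250.0, 1250.0))[0, 1] < 0.45

    def test_wpli_monotone_in_kappa(self):
        """Retention wPLI on a planted edge is non-decreasing in kappa."""
        values = []
        for kappa in (0.0, 0.3, 0.6, 1.0):
            cfg = w.SimulationConfig(
                n_regions=8,
                n_trials_per_condition=50,
                groups=(w.GroupSpec("FT", 2),),
                bands=(ALPHA,),
                planted_networks=(
                    w.PlantedNetwork("alpha", ((3, 7),), kappa=kappa),
                ),
                master_seed=11,
            )
            conn = w.subject_connectivity(
                w.make_cohort(cfg).epochs[0], ALPHA, condition="correct", zscore=False
            )
            values.append(window_average(conn, (250.0, 1250.0))[3, 7])
        assert np.all(np.diff(values) >= 0), values
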