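import numpy as np
import pytest

from sbpsnn.connectivity import (GCMatrix, coherence_summary, directed_network,
                                 fit_var, spectral_granger)
from sbpsnn.synth import generate_var_pair


class TestVarFit:
    def test_recovers_known_coefficients(self):
        xy = generate_var_pair(0.5, order=1, n=20000, seed=0, phi_x=0.6)
        A, Sigma, _ = fit_var(xy, order=1)
        assert A[0, 0, 0] == pytest.approx(0.6, abs=0.03)
        assert A[0, 1, 0] == pytest.approx(0.5, abs=0.03)
        assert abs(A[0, 0, 1]) < 0.03
        assert Sigma[0, 0] == pytest.approx(1.0, rel=0.1)

    def test_matches_statsmodels_var(self):
        """Independent cross-check of the OLS fit against statsmodels."""
        from statsmodels.tsa.api import VAR

        xy = generate_var_pair(0.4, order=2, n=5000, seed=1)
        A, _, _ = fit_var(xy, order=2)
        ref = VAR(xy.T).fit(maxlags=2, trend="n")
        assert np.allclose(A, ref.coefs, atol=0.02)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            fit_var(np.random.default_rng(0).standard_normal((2, 100)),
                    order=20)


class TestSpectralGC:
    def test_nonnegative_everywhere(self):
        xy = generate_var_pair(0.5, order=1, n=8000, seed=2)
        gc = spectral_granger(xy, fs=100.0, order=10)
        off_diag = gc.values[~np.eye(2, dtype=bool)]
        assert np.all(off_diag >= 0)

    def test_null_pair_near_zero(self):
        xy = generate_var_pair(0.0, order=1, n=20000, seed=3)
        gc = spectral_granger(xy, fs=100.0, order=20)
        assert gc.pair("ch0", "ch1").mean() < 0.02
        assert gc.pair("ch1", "ch0").mean() < 0.02

    def test_directed_pair_strongly_asymmetric(self):
        xy = generate_var_pair(0.5, order=1, n=20000, seed=4)
        gc = spectral_granger(xy, fs=100.0, order=20)
        fwd = gc.pair("ch0", "ch1").mean()
        rev = gc.pair("ch1", "ch0").mean()
        assert fwd / max(rev, 1e-12) >= 5.0

    def test_band_average_consistent_with_time_domain_gc(self):
        """Cross-check: spectral GC magnitude vs the OLS variance-ratio GC."""
        xy = generate_var_pair(0.5, order=1, n=20000, seed=5)
        # time-domain Geweke GC x->y: ln(reduced var / full var)
        x, y = xy
        Yf = y[1:]
        full = np.column_stack([y[:-1], x[:-1]])
        red = y[:-1][:, None]
        rf = Yf - full @ np.linalg.lstsq(full, Yf, rcond=None)[0]
        rr = Yf - red @ np.linalg.lstsq(red, Yf, rcond=None)[0]
        td_gc = np.log(rr.var() / rf.var())
        gc = spectral_granger(xy, fs=100.0, order=20,
                              freqs=np.linspace(0.5, 49.5, 99))
        # Geweke: the spectral measure averages to the time-domain measure
        assert gc.pair("ch0", "ch1").mean() == pytest.approx(td_gc, rel=0.25)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        a = generate_var_pair(0.4, order=1, n=6000, seed=6)
        z = rng.standard_normal((1, 6000))
        data = np.vstack([a, z])
        gc = spectral_granger(data, fs=100.0, order=5,
                              electrodes=("x", "y", "z"))
        perm = [2, 0, 1]
        gc_p = spectral_granger(data[perm], fs=100.0, order=5,
                                electrodes=("z", "x", "y"))
        assert np.allclose(gc.pair("x", "y"), gc_p.pair("x", "y"), atol=1e-9)

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            GCMatrix(-np.ones((2, 2, 3)), ("a", "b"), np.arange(3.0))


class TestDirectedNetwork:
    def _chain_trials(self, n_trials=6, n=3000, seed=0):
        """x -> y -> z chain of AR-driven channels, per-trial."""
        rng = np.random.default_rng(seed)
        trials = []
        for _ in range(n_trials):
            e = rng.standard_normal((3, n))
            x = np.zeros(n)
            y = np.zeros(n)
            z = np.zeros(n)
            for t in range(1, n):
                x[t] = 0.5 * x[t - 1] + e[0, t]
                y[t] = 0.5 * x[t - 1] + e[1, t]
                z[t] = 0.5 * y[t - 1] + e[2, t]
            trials.append(np.vstack([x, y, z]))
        return trials

    def test_chain_recovered_without_false_reverse_edge(self):
        trials = self._chain_trials()
        net = directed_network(trials, fs=100.0, electrodes=("x", "y", "z"),
                               band=(1.0, 48.0), band_name="broad",
                               order=5, n_surrogates=10, seed=0)
        found = {(s, d) for s, d, _b, _v in net.edges}
        assert ("x", "y") in found
        assert ("y", "z") in found
        assert ("z", "x") not in found

    def test_threshold_above_max_gives_empty_network(self):
        trials = self._chain_trials(n_trials=4, n=2000, seed=1)
        net = directed_network(trials, fs=100.0, electrodes=("x", "y", "z"),
                               band=(1.0, 48.0), order=5, threshold=np.inf)
        assert net.edges == []

    def test_zero_surrogates_rejected(self):
        x = np.random.default_rng(0).standard_normal((2, 1000))
        with pytest.raises(ValueError, match="surrogate"):
            directed_network([x], 100.0, ("a", "b"), (1, 10), order=2,
                             n_surrogates=0)


class TestCoherence:
    def test_identical_channels_full_coherence(self, rng):
        x = rng.standard_normal(4000)
        out = coherence_summary(np.vstack([x, x]), 250.0, ("a", "b"))
        for band, val in out[("a", "b")].items():
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_near_bias_floor(self, rng):
        x = rng.standard_normal((2, 50000))
        nper = 1000
        K = 2 * 50000 // nper - 1   # Welch segment count (50% overlap)
        out = coherence_summary(x, 250.0, ("a", "b"), nperseg=nper)
        for val in out[("a", "b")].values():
            assert val < 5.0 / K

    def test_values_bounded(self, rng):
        x = rng.standard_normal((3, 3000))
        out = coherence_summary(x, 250.0, ("a", "b", "c"))
        for row in out.values():
            for v in row.values():
                assert 0.0 <= v <= 1.0

    def test_symmetry_in_pair_order(self, rng):
        x = rng.standard_normal((2, 3000))
        from scipy.signal import coherence
        f1, c1 = coherence(x[0], x[1], fs=250.0, nperseg=1000)
        f2, c2 = coherence(x[1], x[0], fs=250.0, nperseg=1000)
        assert np.allclose(c1, c2)

    def test_segment_too_long_rejected(self, rng):
        with pytest.raises(ValueError, match="segment"):
            coherence_summary(rng.standard_normal((2, 100)), 100.0,
                              ("a", "b"), nperseg=1000)

    def test_single_channel_rejected(self, rng):
        with pytest.raises(ValueError, match="two electrodes"):
            coherence_summary(rng.standard_normal((1, 100)), 100.0, ("a",))
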