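import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.distance import pdist
from scipy.stats import norm

from nanoclust import (
    LabelingModel,
    RGrid,
    ThomasParams,
    Window,
    apply_labeling,
    k_function,
    simulate_csr,
    simulate_flim_frame,
    simulate_fret_experiment,
    simulate_matern,
    simulate_thomas,
    fret_efficiency,
)


class TestSimulateCsr:
    def test_empty_pattern(self, window):
        assert simulate_csr(0, window, seed=0).n == 0

    def test_exact_count_inside_window(self, window):
        pat = simulate_csr(250, window, seed=1)
        assert pat.n == 250
        assert window.contains(pat.coords).all()

    def test_deterministic_and_seed_sensitive(self, window):
        a = simulate_csr(50, window, seed=5)
        b = simulate_csr(50, window, seed=5)
        c = simulate_csr(50, window, seed=6)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)

    def test_subrectangle_count_is_binomial(self, window, rng):
        # expected count in a subrectangle of area a is n*a/A
        n, reps = 100, 1000
        counts = np.empty(reps)
        for i in range(reps):
            pat = simulate_csr(n, window, rng=rng)
            counts[i] = np.sum((pat.coords[:, 0] < 250) & (pat.coords[:, 1] < 400))
        p = 250 * 400 / window.area
        se = np.sqrt(n * p * (1 - p) / reps)
        assert abs(counts.mean() - n * p) < 3 * se


def _dim_retention(length, sigma):
    # fraction of Gaussian-displaced offspring staying inside [0, length]
    # when the parent coordinate is uniform on [0, length]
    f = lambda x: norm.cdf((length - x) / sigma) - norm.cdf(-x / sigma)
    return quad(f, 0, length)[0] / length


class TestSimulateThomas:
    PARAMS = ThomasParams.from_parent_count(20, 15, 10, Window())

    def test_expected_count_with_boundary_loss(self, window, rng):
        reps = 500
        counts = [simulate_thomas(self.PARAMS, window, rng=rng).n for _ in range(reps)]
        retention = _dim_retention(window.width, 10.0) * _dim_retention(window.height, 10.0)
        expected = 20 * 15 * retention
        # var of a Thomas count: kappa*A*(mu + mu^2), before boundary loss
        se = np.sqrt(20 * (15 + 15**2) / reps)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_clustering_signature_peaks_at_small_r(self, window, rng):
        grid = RGrid(np.arange(5.0, 241.0, 5.0))
        curves = []
        for _ in range(100):
            pat = simulate_thomas(self.PARAMS, window, rng=rng)
            if pat.n >= 2:
                curves.append(k_function(pat, grid).l_values)
        mean_l = np.mean(curves, axis=0)
        peak_r = grid.radii[np.argmax(mean_l)]
        assert mean_l.max() > 0
        assert peak_r < 50.0

    def test_large_sigma_degrades_to_csr(self, window, rng):
        # sigma far above nanocluster scale spreads offspring across the
        # whole window; residual L(50) drops from ~+25 nm to ~+1 nm
        diffuse = ThomasParams.from_parent_count(20, 15, 300.0, window)
        grid = RGrid(np.array([50.0]))
        l50 = []
        for _ in range(60):
            pat = simulate_thomas(diffuse, window, rng=rng)
            if pat.n >= 10:
                l50.append(k_function(pat, grid).l_values[0])
        # near-CSR: mean L(50) small compared with the clustered signature (~+25 nm)
        assert abs(np.mean(l50)) < 5.0

    def test_deterministic(self, window):
        a = simulate_thomas(self.PARAMS, window, seed=2)
        b = simulate_thomas(self.PARAMS, window, seed=2)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_matern_variant(self, window, rng):
        pat = simulate_matern(self.PARAMS, window, rng=rng)
        assert window.contains(pat.coords).all()

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ThomasParams(0.0, 15, 10)


class TestApplyLabeling:
    def test_identity_model(self, window, rng):
        pat = simulate_csr(50, window, rng=rng)
        out = apply_labeling(pat, LabelingModel(1.0, 0.0, 0.0), seed=0)
        np.testing.assert_array_equal(out.coords, pat.coords)

    def test_binomial_retention(self, window, rng):
        n, reps = 200, 300
        pat = simulate_csr(n, window, seed=0)
        model = LabelingModel(efficiency=0.5, linker_jitter_sd=0.0, hardcore_distance=0.0)
        kept = [apply_labeling(pat, model, rng=rng).n for _ in range(reps)]
        se = np.sqrt(n * 0.25 / reps)
        assert abs(np.mean(kept) - n / 2) < 3 * se

    def test_hardcore_postcondition(self, window, rng):
        pat = simulate_csr(400, window, rng=rng)
        out = apply_labeling(pat, LabelingModel(1.0, 0.0, 4.5), seed=3)
        assert out.n < pat.n or pdist(out.coords).min() >= 4.5
        if out.n >= 2:
            assert pdist(out.coords).min() >= 4.5

    def test_jitter_stays_in_window(self, window, rng):
        pat = simulate_csr(100, window, rng=rng)
        out = apply_labeling(pat, LabelingModel(1.0, 50.0, 0.0), seed=4)
        assert window.contains(out.coords).all()

    def test_deterministic(self, window):
        pat = simulate_csr(100, window, seed=9)
        model = LabelingModel(0.7, 2.0, 4.5)
        a = apply_labeling(pat, model, seed=5)
        b = apply_labeling(pat, model, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestSimulateFlimFrame:
    def test_zero_lifetime(self):
        frame = simulate_flim_frame(np.zeros((2, 2)))
        assert np.all(frame.phase == 0.0) and np.all(frame.modulation == 1.0)

    def test_forward_values_at_4ns_40mhz(self):
        frame = simulate_flim_frame(np.array([[4.0]]))
        assert frame.phase[0, 0] == pytest.approx(0.7880, abs=5e-4)
        assert frame.modulation[0, 0] == pytest.approx(0.7052, abs=5e-4)

    def test_noise_reproducible_per_seed(self):
        tau = np.full((4, 4), 2.5)
        a = simulate_flim_frame(tau, phase_noise_sd=0.01, mod_noise_sd=0.01, seed=1)
        b = simulate_flim_frame(tau, phase_noise_sd=0.01, mod_noise_sd=0.01, seed=1)
        np.testing.assert_array_equal(a.phase, b.phase)
        np.testing.assert_array_equal(a.modulation, b.modulation)

    def test_modulation_clipped_to_unit_interval(self):
        frame = simulate_flim_frame(np.full((20, 20), 0.1),
                                    mod_noise_sd=0.5, seed=2)
        assert frame.modulation.min() >= 0.0 and frame.modulation.max() <= 1.0

    def test_negative_lifetime_rejected(self):
        with pytest.raises(ValueError):
            simulate_flim_frame(np.array([[-1.0]]))


class TestSimulateFretExperiment:
    def test_exact_recovery_without_cell_noise(self):
        df = simulate_fret_experiment(2.5, 20.0, n_cells=10, cell_sd=0.0, seed=0)
        donor = df.loc[df["sample"] == "donor", "tau_ns"]
        da = df.loc[df["sample"] == "donor_acceptor", "tau_ns"]
        m = fret_efficiency(da.to_numpy(), float(donor.mean()))
        assert m.mean == pytest.approx(20.0)

    @pytest.mark.parametrize("true_e", [0.0, 20.0])
    def test_recovery_within_three_se(self, true_e):
        df = simulate_fret_experiment(2.5, true_e, n_cells=30, cell_sd=0.1, seed=7)
        donor = df.loc[df["sample"] == "donor", "tau_ns"]
        da = df.loc[df["sample"] == "donor_acceptor", "tau_ns"]
        m = fret_efficiency(da.to_numpy(), float(donor.mean()))
        assert abs(m.mean - true_e) < 3 * m.sem + 1e-9

    def test_lifetimes_positive(self):
        df = simulate_fret_experiment(0.5, 90.0, n_cells=200, cell_sd=0.3, seed=1)
        assert (df["tau_ns"] > 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_fret_experiment(2.5, 100.0)
        with pytest.raises(ValueError):
            simulate_fret_experiment(-1.0, 10.0)
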