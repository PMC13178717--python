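"""Perturbation spectra, radial profiles, band statistics, correlations."""

import numpy as np
import pytest
from scipy import stats

from sfprobe.frequency import OctaveBands, build_frequency_grid
from sfprobe.reliance import (
    SFProfile,
    band_delta_auc,
    correlate_band_with_robustness,
    mean_profile_with_ci,
    perturbation_power_spectrum,
    radial_profile,
)


def make_profile(props, centers=None):
    props = np.asarray(props, dtype=float)
    centers = (
        np.arange(1, len(props) + 1, dtype=float) if centers is None else np.asarray(centers)
    )
    return SFProfile(bin_centers_cpi=centers, proportions=props / props.sum())


class TestPowerSpectrum:
    def test_zero_delta_gives_zero_map(self):
        assert np.all(perturbation_power_spectrum(np.zeros((16, 16, 3))) == 0.0)

    def test_pure_cosine_concentrates_at_its_frequency(self):
        x = np.arange(32)
        delta = np.zeros((32, 32, 3))
        delta[:, :, 0] = np.cos(2 * np.pi * 5 * x[None, :] / 32)
        p = perturbation_power_spectrum(delta)
        mask = np.zeros_like(p, dtype=bool)
        mask[0, 5] = mask[0, -5] = True
        assert p[mask].sum() / p.sum() > 0.999

    def test_total_power_matches_parseval_oracle(self):
        rng = np.random.default_rng(0)
        delta = rng.standard_normal((16, 16, 3))
        p = perturbation_power_spectrum(delta)
        # Parseval: sum |F|^2 = N * sum x^2, averaged over 3 channels
        expected = 16 * 16 * np.sum(delta**2) / 3
        assert p.sum() == pytest.approx(expected, rel=1e-12)


class TestRadialProfile:
    def test_matches_bruteforce_binning_oracle(self, grid32):
        rng = np.random.default_rng(1)
        pmap = rng.random((32, 32))
        prof = radial_profile(pmap, grid32)
        # oracle: loop every coefficient, round radius to nearest integer bin
        sums = np.zeros(17)
        for i in range(32):
            for j in range(32):
                u = i if i <= 16 else i - 32
                v = j if j <= 16 else j - 32
                r = np.hypot(u, v)
                k = int(np.rint(r))
                if r > 0 and 1 <= k <= 16:
                    sums[k] += pmap[i, j]
        expected = sums[1:] / sums[1:].sum()
        assert np.allclose(prof.proportions, expected, atol=1e-8)

    def test_pure_cosine_lands_in_its_radial_bin(self, grid64):
        x = np.arange(64)
        delta = np.zeros((64, 64, 3))
        delta[:, :, :] = np.cos(2 * np.pi * 10 * x[None, :, None] / 64)
        prof = radial_profile(perturbation_power_spectrum(delta), grid64)
        assert prof.proportions[prof.bin_centers_cpi == 10.0][0] >= 0.99

    def test_white_noise_mean_proportions_track_coefficient_counts(self, grid32):
        rng = np.random.default_rng(2)
        acc = np.zeros(16)
        n_draws = 200
        for _ in range(n_draws):
            pmap = np.abs(np.fft.fft2(rng.standard_normal((32, 32)))) ** 2
            acc += radial_profile(pmap, grid32).proportions
        mean_props = acc / n_draws
        # counting oracle: expected proportion = bin coefficient count / total
        r = grid32.radial_freq
        k = np.rint(r).astype(int)
        keep = (r > 0) & (k >= 1) & (k <= 16)
        counts = np.bincount(k[keep], minlength=17)[1:]
        expected = counts / counts.sum()
        assert np.allclose(mean_props, expected, atol=0.01)

    def test_proportions_sum_to_one(self, grid64):
        rng = np.random.default_rng(3)
        prof = radial_profile(rng.random((64, 64)), grid64)
        assert prof.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_corner_frequencies_excluded(self, grid32):
        # power only beyond the nyquist radius -> nothing retained
        pmap = np.zeros((32, 32))
        pmap[16, 16] = 1.0  # r = sqrt(16^2+16^2) ~ 22.6 > 16
        with pytest.raises(ValueError):
            radial_profile(pmap, grid32)

    def test_all_zero_spectrum_flagged(self, grid32):
        with pytest.raises(ValueError):
            radial_profile(np.zeros((32, 32)), grid32)


class TestMeanProfileWithCI:
    def test_identical_profiles_give_zero_width_ci(self):
        p = make_profile([1, 2, 3, 4])
        agg = mean_profile_with_ci([p, p, p], n_boot=500, seed=0)
        assert np.allclose(agg.ci_low, agg.ci_high)
        assert np.allclose(agg.proportions, p.proportions)

    def test_default_bootstrap_resamples(self):
        import inspect

        sig = inspect.signature(mean_profile_with_ci)
        assert sig.parameters["n_boot"].default == 10_000

    def test_two_profile_bootstrap_matches_exhaustive_enumeration(self):
        a = make_profile([1, 0, 0])
        b = make_profile([0, 0, 1])
        agg = mean_profile_with_ci([a, b], n_boot=20_000, seed=1)
        # oracle: resamples of size 2 from {a,b} -> means {a, (a+b)/2, b}
        # with probabilities {1/4, 1/2, 1/4}; the 2.5% quantile of the first
        # bin is 0 (P[mean_bin1 = 0] = 1/4 > 0.025), the 97.5% quantile is 1
        assert agg.ci_low[0] == 0.0
        assert agg.ci_high[0] == 1.0
        assert agg.proportions[0] == pytest.approx(0.5)

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(ValueError):
            mean_profile_with_ci([make_profile([1, 1])], n_boot=10)

    def test_deterministic_under_seed(self):
        profs = [make_profile(np.random.default_rng(i).random(5)) for i in range(4)]
        a = mean_profile_with_ci(profs, n_boot=200, seed=7)
        b = mean_profile_with_ci(profs, n_boot=200, seed=7)
        assert np.array_equal(a.ci_low, b.ci_low)


class TestBandDeltaAUC:
    def bands(self):
        return OctaveBands.default(16.0)

    def test_model_equal_baseline_gives_all_zero(self):
        p = make_profile(np.arange(1, 17))
        stats_ = band_delta_auc(p, p, self.bands())
        assert np.allclose(stats_.delta_auc_pct_power, 0.0)

    def test_concentrated_vs_uniform_matches_hand_computation(self):
        bands = self.bands()  # edges 0,.5,1,2,4,8,16 at nyquist 16
        model = make_profile([0, 0, 0, 0, 1e-12, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0])
        baseline = make_profile(np.ones(16))
        st_ = band_delta_auc(model, baseline, bands)
        # band [8,16) holds bins 8..15: model share ~1 (bins 9-12 wait)
        # hand computation: model power in bins 9,10,11,12 -> centers 9..12
        # all inside [8,16); baseline share there = 8/16
        i = 5
        assert bands.edges_cpi[i] == 8.0
        assert st_.delta_auc_pct_power[i] == pytest.approx(1.0 - 8 / 16, abs=1e-9)

    def test_deltas_sum_to_zero_when_bands_tile_retained_power(self):
        # the top bin's center equals the nyquist edge and falls outside the
        # half-open bands, so the zero-sum identity holds when no power sits
        # there (all retained power strictly below the nyquist edge)
        rng = np.random.default_rng(4)
        props = rng.random(16)
        props[-1] = 0.0
        model = make_profile(props)
        props2 = rng.random(16)
        props2[-1] = 0.0
        baseline = make_profile(props2)
        st_ = band_delta_auc(model, baseline, self.bands())
        assert st_.delta_auc_pct_power.sum() == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_bins_rejected(self):
        a = make_profile(np.ones(16))
        b = make_profile(np.ones(8))
        with pytest.raises(ValueError):
            band_delta_auc(a, b, self.bands())


class TestCorrelation:
    def test_increasing_pairs_give_rho_one(self):
        res = correlate_band_with_robustness([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == pytest.approx(1.0)

    def test_reversed_pairs_give_rho_minus_one(self):
        res = correlate_band_with_robustness([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.random(10)
        y = rng.random(10)
        res = correlate_band_with_robustness(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_ties_use_average_ranks(self):
        x = [1.0, 1.0, 2.0, 3.0]
        y = [5.0, 6.0, 7.0, 8.0]
        res = correlate_band_with_robustness(x, y)
        rx = stats.rankdata(x)  # [1.5, 1.5, 3, 4]
        oracle = np.corrcoef(rx, stats.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(oracle)

    def test_exact_permutation_p_value_small_n(self):
        x = [0.1, 0.4, 0.2, 0.9, 0.7]
        y = [1.0, 2.0, 1.5, 3.0, 2.5]
        res = correlate_band_with_robustness(x, y, exact_p=True)
        # perfect monotone agreement on n=5: two-sided exact p = 2/5! = 1/60
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / 120)

    def test_too_few_models_rejected(self):
        with pytest.raises(ValueError):
            correlate_band_with_robustness([1, 2], [1, 2])


class TestProfileStability:
    def test_profiles_consistent_across_attack_magnitudes(
        self, trained_model, band_split, grid64
    ):
        # reliance profiles from eps in {3,4,5}/255 on the same model agree
        # (pairwise Spearman rho >= 0.9): the probe reads out a property of
        # the model, not of the attack budget
        from scipy import stats as sps

        from sfprobe.attacks import AttackConfig, filter_successful, pgd_attack
        from sfprobe.reliance import profiles_from_perturbations

        _, _, te_x, te_y = band_split
        x, y = te_x[:80], te_y[:80]
        profs = []
        for k in (3, 4, 5):
            perts = filter_successful(
                pgd_attack(trained_model, x, y, AttackConfig(epsilon=k / 255, seed=11))
            )
            mat = np.stack(
                [p.proportions for p in profiles_from_perturbations(perts, grid64)]
            )
            profs.append(mat.mean(axis=0))
        for i in range(3):
            for j in range(i + 1, 3):
                rho = sps.spearmanr(profs[i], profs[j]).statistic
                assert rho >= 0.9


class TestExports:
    def test_csv_exports_write_expected_columns(self, tmp_path):
        import pandas as pd

        from sfprobe.reliance import (
            CorrelationResult,
            export_band_stats_csv,
            export_correlations_csv,
            export_profiles_csv,
        )

        prof = make_profile([1, 2, 3, 4])
        export_profiles_csv({"m0": prof}, tmp_path / "profiles.csv")
        df = pd.read_csv(tmp_path / "profiles.csv")
        assert list(df.columns) == [
            "model_id", "bin_center_cpi", "proportion", "ci_low", "ci_high",
        ]
        assert df["proportion"].sum() == pytest.approx(1.0)

        bands = OctaveBands.default(16.0)
        bs = band_delta_auc(prof := make_profile(np.ones(16)), prof, bands, model_id="m0")
        export_band_stats_csv([bs], tmp_path / "bands.csv")
        assert len(pd.read_csv(tmp_path / "bands.csv")) == 6

        export_correlations_csv(
            {"[28,56)": CorrelationResult(rho=0.98, p_value=0.001, n=10)},
            tmp_path / "corr.csv",
        )
        row = pd.read_csv(tmp_path / "corr.csv").iloc[0]
        assert row["rho"] == 0.98 and row["n"] == 10
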