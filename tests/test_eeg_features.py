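"""Spectral feature estimators: band power, TBR, asymmetry, MSC, artifacts."""

import numpy as np
import pytest

from neuroadapt.eeg_features import (
    BandDefinition, BandPowerSet, alpha_asymmetry, band_power, band_powers,
    coherence_msc, coherence_permutation_test, reject_artifacts,
    theta_beta_ratio,
)
from neuroadapt.signals import ChannelTimeSeries
from tests.conftest import make_sinusoid_ts

THETA = BandDefinition("theta", 4.0, 8.0)
BETA = BandDefinition("beta", 13.0, 30.0)


def bp_from_values(values: dict) -> BandPowerSet:
    return BandPowerSet(powers=dict(values))


class TestBandPower:
    def test_tone_recovers_parseval_power(self):
        ts = make_sinusoid_ts(6.0, amp=10.0)
        power = band_power(ts, THETA).get("Fz", "theta")
        assert power == pytest.approx(50.0, rel=0.05)  # A^2/2

    def test_out_of_band_leakage_negligible(self):
        ts = make_sinusoid_ts(6.0, amp=10.0)
        assert band_power(ts, BETA).get("Fz", "beta") < 0.01 * 50.0

    def test_white_noise_band_partition_sums_to_variance(self, rng):
        fs = 256.0
        x = rng.standard_normal(int(60 * fs))
        ts = ChannelTimeSeries(["Cz"], fs, x[None, :])
        edges = np.linspace(0.5, fs / 2, 9)
        total = sum(
            band_power(ts, BandDefinition(f"b{i}", lo, hi)).get("Cz", f"b{i}")
            for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])))
        assert total == pytest.approx(np.var(x), rel=0.1)

    def test_band_above_nyquist_rejected(self):
        ts = make_sinusoid_ts(6.0, 1.0, fs=64.0)
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(ts, BandDefinition("gamma", 30, 45))

    def test_scale_equivariance_c_squared(self):
        ts = make_sinusoid_ts(6.0, amp=2.0)
        scaled = ChannelTimeSeries(ts.labels, ts.fs, 3.0 * ts.data)
        p1 = band_power(ts, THETA).get("Fz", "theta")
        p2 = band_power(scaled, THETA).get("Fz", "theta")
        assert p2 == pytest.approx(9.0 * p1, rel=1e-6)


class TestThetaBetaRatio:
    def test_equal_powers_give_unity(self):
        bp = bp_from_values({(s, b): 5.0 for s in ("Fz", "FCz", "Cz")
                             for b in ("theta", "beta")})
        assert theta_beta_ratio(bp) == pytest.approx(1.0)

    def test_mean_of_per_site_ratios(self):
        bp = bp_from_values({
            ("Fz", "theta"): 3.0, ("Fz", "beta"): 1.0,
            ("FCz", "theta"): 3.2, ("FCz", "beta"): 1.0,
            ("Cz", "theta"): 3.34, ("Cz", "beta"): 1.0,
        })
        assert theta_beta_ratio(bp) == pytest.approx(3.18)

    def test_missing_site_and_zero_beta_are_errors(self):
        bp = bp_from_values({("Fz", "theta"): 1.0, ("Fz", "beta"): 1.0})
        with pytest.raises(KeyError, match="FCz"):
            theta_beta_ratio(bp)
        bp = bp_from_values({(s, b): (0.0 if b == "beta" else 1.0)
                             for s in ("Fz", "FCz", "Cz")
                             for b in ("theta", "beta")})
        with pytest.raises(ValueError, match="zero beta"):
            theta_beta_ratio(bp)


class TestAlphaAsymmetry:
    @pytest.mark.parametrize("left_scale, expected",
                             [(0.72, -0.28), (1.0, 0.0), (2.0, 1.0)])
    def test_index_from_left_right_ratio(self, left_scale, expected):
        bp = bp_from_values({("F3", "alpha"): 10.0 * left_scale,
                             ("F4", "alpha"): 10.0})
        got = alpha_asymmetry(bp, ["F3"], ["F4"])
        assert got == pytest.approx(expected)

    def test_log_ratio_variant(self):
        bp = bp_from_values({("F3", "alpha"): 20.0, ("F4", "alpha"): 10.0})
        assert alpha_asymmetry(bp, ["F3"], ["F4"],
                               log_ratio=True) == pytest.approx(np.log(2))

    def test_empty_sites_rejected(self):
        bp = bp_from_values({("F3", "alpha"): 1.0})
        with pytest.raises(ValueError, match="non-empty"):
            alpha_asymmetry(bp, [], ["F3"])


class TestCoherence:
    def _two_channel(self, a, b, fs=128.0):
        return ChannelTimeSeries(["A", "B"], fs, np.vstack([a, b]))

    def test_identical_signals_give_unity(self, rng):
        x = rng.standard_normal(int(60 * 128))
        msc = coherence_msc(self._two_channel(x, x), ["A"], ["B"],
                            BandDefinition("theta", 4, 8))
        assert msc == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_near_one_over_k(self, rng):
        n = int(64 * 128)  # 63 epochs at 2 s / 50%
        vals = [coherence_msc(
            self._two_channel(rng.standard_normal(n), rng.standard_normal(n)),
            ["A"], ["B"], BandDefinition("theta", 4, 8)) for _ in range(10)]
        assert np.mean(vals) == pytest.approx(1 / 63, rel=0.5)

    def test_symmetry_and_bounds(self, rng):
        x = rng.standard_normal(int(30 * 128))
        y = 0.5 * x + rng.standard_normal(x.size)
        band = BandDefinition("alpha", 8, 12)
        ab = coherence_msc(self._two_channel(x, y), ["A"], ["B"], band)
        ba = coherence_msc(self._two_channel(y, x), ["A"], ["B"], band)
        assert ab == pytest.approx(ba, abs=1e-12)
        assert 0.0 <= ab <= 1.0

    def test_too_few_epochs_rejected(self, rng):
        x = rng.standard_normal(int(6 * 128))
        with pytest.raises(ValueError, match="epochs"):
            coherence_msc(self._two_channel(x, x), ["A"], ["B"],
                          BandDefinition("theta", 4, 8))

    def test_permutation_p_for_identical_signals_is_floor(self, rng):
        x = rng.standard_normal(int(30 * 128))
        res = coherence_permutation_test(
            self._two_channel(x, x), [(["A"], ["B"], "self")],
            BandDefinition("theta", 4, 8), n_perm=100, seed=0)
        assert res[0].p_value == pytest.approx(1 / 101)

    def test_bh_correction_across_pairs(self, rng):
        n = int(30 * 128)
        x = rng.standard_normal(n)
        data = np.vstack([x, x, rng.standard_normal(n)])
        ts = ChannelTimeSeries(["A", "B", "C"], 128.0, data)
        res = coherence_permutation_test(
            ts, [(["A"], ["B"], "coupled"), (["A"], ["C"], "independent")],
            BandDefinition("theta", 4, 8), n_perm=100, seed=1)
        ps = sorted(r.p_value for r in res)
        qs = sorted(r.q_value for r in res)
        # BH on two tests: q1 = min(2*p1, p2), q2 = p2
        assert qs[0] == pytest.approx(min(2 * ps[0], ps[1]))
        assert qs[1] == pytest.approx(ps[1])


class TestArtifacts:
    def _ts(self, data):
        return ChannelTimeSeries(["Fz"], 100.0, np.asarray(data)[None, :])

    def test_clean_record_keeps_everything(self):
        ts = self._ts(np.ones(1000) * 10)
        cleaned, rep = reject_artifacts(ts, epoch_s=1.0, amp_thresh_uv=150)
        assert rep.fraction_rejected == 0.0
        assert cleaned.n_samples == ts.n_samples

    def test_spiked_epochs_dropped_with_fraction(self):
        x = np.ones(1000) * 10
        x[150] = 500.0
        x[820] = -400.0
        _, rep = reject_artifacts(self._ts(x), epoch_s=1.0,
                                  amp_thresh_uv=150)
        assert rep.fraction_rejected == pytest.approx(0.2)
        assert rep.keep_mask.sum() == 8

    def test_infinite_threshold_is_identity(self):
        x = np.ones(500) * 1e5
        cleaned, rep = reject_artifacts(self._ts(x), epoch_s=1.0,
                                        amp_thresh_uv=np.inf)
        assert rep.fraction_rejected == 0.0
        assert cleaned.n_samples == 500

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            reject_artifacts(self._ts(np.ones(100)), 1.0, 0.0)


def test_tbr_and_msc_scale_invariant(flat_profiles):
    from neuroadapt.synth import synth_eeg
    from neuroadapt.synth.eeg import BANDS
    eeg = synth_eeg(flat_profiles["ADHD"], "AR", duration_s=20, fs=256)
    scaled = ChannelTimeSeries(eeg.labels, eeg.fs, 7.0 * eeg.data)
    band = BandDefinition("gamma", 30, 45)
    assert theta_beta_ratio(band_powers(eeg, BANDS)) == pytest.approx(
        theta_beta_ratio(band_powers(scaled, BANDS)), rel=1e-9)
    assert coherence_msc(eeg, ["Fz"], ["T7"], band) == pytest.approx(
        coherence_msc(scaled, ["Fz"], ["T7"], band), rel=1e-9)
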