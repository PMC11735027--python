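"""Unit selection, clustering, tagging, PETH, PCA, and GLM slopes."""

import numpy as np
import pytest

import timeddm as tdm
from timeddm.ephys import PETHConfig


def _unit(uid="u", rate=None, ptr=1.5, width=0.3, spikes=None):
    return tdm.UnitRecording(unit_id=uid,
                             spike_times_s=spikes if spikes is not None
                             else np.array([]),
                             mean_rate_hz=rate, peak_trough_ratio=ptr,
                             half_peak_width_ms=width)


class TestSelectUnits:
    def test_inclusive_bounds(self):
        units = [_unit("lo", 0.5), _unit("in", 7.0), _unit("hi", 20.0),
                 _unit("below", 0.4), _unit("above", 25.0)]
        kept = {u.unit_id for u in tdm.select_units(units)}
        assert kept == {"lo", "in", "hi"}

    def test_population_survivor_count(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0.0, 30.0, 500)
        units = [_unit(str(i), r) for i, r in enumerate(rates)]
        expected = int(np.sum((rates >= 0.5) & (rates <= 20.0)))
        assert len(tdm.select_units(units)) == expected


class TestClassifyMsnFsi:
    def test_separated_clusters_labelled_by_width(self):
        rng = np.random.default_rng(1)
        msn = [_unit(f"m{i}", ptr=rng.normal(1.6, 0.05),
                     width=rng.normal(0.32, 0.01)) for i in range(10)]
        fsi = [_unit(f"f{i}", ptr=rng.normal(0.9, 0.05),
                     width=rng.normal(0.12, 0.01)) for i in range(6)]
        labels = tdm.classify_msn_fsi(msn + fsi)
        assert all(labels[u.unit_id] == "MSN" for u in msn)
        assert all(labels[u.unit_id] == "FSI" for u in fsi)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        units = [_unit(str(i), ptr=rng.normal(1.2, 0.4),
                       width=rng.uniform(0.1, 0.4)) for i in range(12)]
        a = tdm.classify_msn_fsi(units)
        b = tdm.classify_msn_fsi(units[::-1])
        assert a == b

    def test_two_units_split_by_width(self):
        labels = tdm.classify_msn_fsi([_unit("wide", width=0.35),
                                       _unit("narrow", width=0.10)])
        assert labels == {"wide": "MSN", "narrow": "FSI"}

    def test_identical_features_rejected(self):
        with pytest.raises(ValueError):
            tdm.classify_msn_fsi([_unit("a"), _unit("b")])


class TestTagUnits:
    @pytest.mark.parametrize("latency_ms, tagged", [
        (2.0, True), (5.0, True), (8.0, False)])
    def test_latency_criterion_inclusive(self, latency_ms, tagged):
        pulses = np.arange(20) * 1.0
        spikes = pulses + latency_ms / 1000.0
        res = tdm.tag_units([_unit("u", spikes=spikes)], pulses)[0]
        assert res.tagged is tagged
        assert res.mean_latency_ms == pytest.approx(latency_ms, abs=1e-6)

    def test_waveform_correlation_criterion(self):
        pulses = np.arange(10) * 1.0
        u = _unit("u", spikes=pulses + 0.002)
        u.waveform = np.sin(np.linspace(0, 3, 40))
        u.evoked_waveform = -u.waveform          # anti-correlated
        assert not tdm.tag_units([u], pulses)[0].tagged

    def test_no_evoked_spikes_flagged_untagged(self):
        res = tdm.tag_units([_unit("u", spikes=np.array([100.0]))],
                            np.arange(5) * 1.0)[0]
        assert not res.tagged and np.isnan(res.mean_latency_ms)
        assert res.n_responses == 0


class TestPETH:
    def test_bin_count_is_130(self):
        assert PETHConfig().bin_centers.size == 130

    def test_raw_counts_conserve_spikes(self):
        rng = np.random.default_rng(3)
        starts = np.arange(10) * 40.0
        spikes = np.sort(rng.uniform(-4, 22, 200)) + starts[3]
        peth = tdm.compute_peth(spikes, starts, PETHConfig())
        assert peth.raw_counts.sum() == 200

    def test_ramp_yields_monotone_segment(self):
        spec = tdm.SynthUnitSpec(baseline_rate=5.0, ramp_slope=0.5,
                                 trial_gain_noise=0.0, seed=4)
        starts = np.arange(120) * 30.0
        st = tdm.gen_ramping_unit(spec, starts, 3600.0)
        peth = tdm.compute_peth(st, starts, PETHConfig())
        seg = peth.rate[(peth.bin_centers_s >= 1.0)
                        & (peth.bin_centers_s < 5.0)]
        slope = np.polyfit(np.arange(seg.size), seg, 1)[0]
        assert slope > 0

    def test_flat_unit_zscore_has_no_trend(self):
        spec = tdm.SynthUnitSpec(baseline_rate=8.0, ramp_slope=0.0,
                                 trial_gain_noise=0.0, seed=5)
        starts = np.arange(150) * 30.0
        st = tdm.gen_ramping_unit(spec, starts, 4500.0)
        peth = tdm.compute_peth(st, starts, PETHConfig())
        assert abs(peth.rate.mean()) < 1e-9 and peth.rate.std() == (
            pytest.approx(1.0))
        # smoothing correlates adjacent bins, so allow ~4 SE of slope
        slope = np.polyfit(peth.bin_centers_s, peth.rate, 1)[0]
        assert abs(slope) < 0.1

    def test_empty_spike_train_flagged(self):
        peth = tdm.compute_peth(np.array([]), np.array([0.0]), PETHConfig())
        assert peth.flat and np.all(peth.raw_counts == 0)


def _ramp_peths(slopes, seed=0, n_trials=100):
    starts = np.arange(n_trials) * 30.0
    peths = []
    rng = np.random.default_rng(seed)
    for i, s in enumerate(slopes):
        spec = tdm.SynthUnitSpec(unit_id=f"u{i}", baseline_rate=6.0,
                                 ramp_slope=s, trial_gain_noise=0.05,
                                 seed=int(rng.integers(2 ** 31)))
        st = tdm.gen_ramping_unit(spec, starts, n_trials * 30.0)
        peths.append(tdm.compute_peth(st, starts, PETHConfig(),
                                      unit_id=spec.unit_id))
    return peths


class TestPCA:
    def test_mixed_ramps_dominate_pc1_with_signed_scores(self):
        """Up- and down-ramping units load PC1 heavily; with the
        down-trending loading convention up-rampers score negative."""
        slopes = [0.5] * 8 + [-0.4] * 8
        res = tdm.pca_ensemble(_ramp_peths(slopes, seed=6))
        assert res.explained_fraction[0] > 0.5
        tt = res.bin_centers_s - res.bin_centers_s.mean()
        assert tt @ res.components[0] < 0          # sign convention
        assert np.all(res.scores[:8, 0] < 0)       # up-ramping units
        assert np.all(res.scores[8:, 0] > 0)       # down-ramping units

    def test_explained_fractions_valid(self):
        res = tdm.pca_ensemble(_ramp_peths([0.4, -0.3, 0.2, 0.0], seed=7))
        ef = res.explained_fraction
        assert np.all(ef >= 0) and np.all(np.diff(ef) <= 1e-12)
        assert ef.sum() <= 1.0 + 1e-9

    def test_identical_peths_rejected(self):
        p = _ramp_peths([0.3], seed=8)[0]
        with pytest.raises(ValueError):
            tdm.pca_ensemble([p, p])

    def test_pc1_scores_anticorrelate_with_glm_slopes(self):
        """Ramping direction drives both measures with opposite sign."""
        rng = np.random.default_rng(9)
        slopes = rng.uniform(-0.5, 0.5, 14)
        starts = np.arange(80) * 30.0
        peths, glm = [], []
        for i, s in enumerate(slopes):
            spec = tdm.SynthUnitSpec(unit_id=f"u{i}", baseline_rate=6.0,
                                     ramp_slope=s, seed=i)
            st = tdm.gen_ramping_unit(spec, starts, 2400.0)
            peths.append(tdm.compute_peth(st, starts, PETHConfig()))
            glm.append(tdm.glm_ramp_slope(st, starts).slope)
        res = tdm.pca_ensemble(peths)
        r = np.corrcoef(res.scores[:, 0], glm)[0, 1]
        assert r < -0.6


class TestPC1RandomBaseline:
    def test_structured_ensemble_beats_null(self):
        starts = np.arange(40) * 30.0
        span = 1200.0
        spikes = [tdm.gen_ramping_unit(
            tdm.SynthUnitSpec(baseline_rate=6.0,
                              ramp_slope=0.5 * (1 if i % 2 else -1),
                              seed=i), starts, span)
            for i in range(12)]
        res = tdm.pc1_random_baseline(spikes, starts, span,
                                      n_iter=100, seed=0)
        assert res.p_empirical <= 0.05
        assert res.baseline.size == 100

    def test_null_is_calibrated(self):
        """Random observed data produces unremarkable empirical p."""
        starts = np.arange(30) * 30.0
        span = 900.0
        ps = []
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            spikes = [rng.uniform(0, span, 300) for _ in range(8)]
            res = tdm.pc1_random_baseline(spikes, starts, span,
                                          n_iter=40, seed=rep)
            ps.append(res.p_empirical)
        assert 0.1 <= np.median(ps) <= 0.9

    def test_single_iteration_p_is_binary(self):
        starts = np.arange(20) * 30.0
        spikes = [np.random.default_rng(i).uniform(0, 600, 200)
                  for i in range(6)]
        res = tdm.pc1_random_baseline(spikes, starts, 600.0, n_iter=1,
                                      seed=0)
        assert res.p_empirical in (0.0, 1.0)


class TestGLMRampSlope:
    def test_recovers_generating_slope(self):
        spec = tdm.SynthUnitSpec(baseline_rate=6.0, ramp_slope=0.5,
                                 trial_gain_noise=0.0, seed=10)
        starts = np.arange(200) * 30.0
        st = tdm.gen_ramping_unit(spec, starts, 6000.0)
        fit = tdm.glm_ramp_slope(st, starts)
        assert fit.slope == pytest.approx(0.5, abs=0.1)

    def test_unbiased_across_many_units(self):
        """Mean recovered slope over 100 seeded units within 5% of truth."""
        true_slope = 0.4
        starts = np.arange(40) * 30.0
        recovered = []
        for seed in range(100):
            spec = tdm.SynthUnitSpec(baseline_rate=6.0,
                                     ramp_slope=true_slope,
                                     trial_gain_noise=0.0, seed=seed)
            st = tdm.gen_ramping_unit(spec, starts, 1200.0)
            recovered.append(tdm.glm_ramp_slope(st, starts).slope)
        assert np.mean(recovered) == pytest.approx(true_slope, rel=0.05)

    def test_constant_rate_gives_zero_slope(self):
        spec = tdm.SynthUnitSpec(baseline_rate=8.0, ramp_slope=0.0,
                                 trial_gain_noise=0.0, seed=11)
        starts = np.arange(150) * 30.0
        st = tdm.gen_ramping_unit(spec, starts, 4500.0)
        assert tdm.glm_ramp_slope(st, starts).slope == pytest.approx(
            0.0, abs=0.1)

    def test_down_ramp_recovers_negative_slope(self):
        spec = tdm.SynthUnitSpec(baseline_rate=6.0, ramp_slope=-0.2,
                                 trial_gain_noise=0.0, seed=12)
        starts = np.arange(200) * 30.0
        st = tdm.gen_ramping_unit(spec, starts, 6000.0)
        assert tdm.glm_ramp_slope(st, starts).slope < 0

    def test_nosepoke_regressor_used_and_dropped(self):
        spec = tdm.SynthUnitSpec(baseline_rate=6.0, ramp_slope=0.3, seed=13)
        starts = np.arange(50) * 30.0
        st = tdm.gen_ramping_unit(spec, starts, 1500.0)
        pokes = starts + 4.0
        with_pokes = tdm.glm_ramp_slope(st, starts, nosepoke_times_s=pokes)
        assert with_pokes.nosepoke_beta is not None
        outside = tdm.glm_ramp_slope(st, starts,
                                     nosepoke_times_s=starts + 10.0)
        assert outside.nosepoke_beta is None  # no pokes inside 0-6 s

    def test_to_switch_variant_truncates(self):
        spec = tdm.SynthUnitSpec(baseline_rate=6.0, ramp_slope=0.4, seed=14)
        starts = np.arange(60) * 30.0
        st = tdm.gen_ramping_unit(spec, starts, 1800.0)
        full = tdm.glm_ramp_slope(st, starts)
        trunc = tdm.glm_ramp_slope(st, starts,
                                   switch_times_s=np.full(60, 3.0),
                                   variant="to_switch")
        assert trunc.n_obs < full.n_obs
        assert trunc.slope == pytest.approx(0.4, abs=0.25)

    def test_outlier_variant_drops_observations(self):
        spec = tdm.SynthUnitSpec(baseline_rate=6.0, ramp_slope=0.3, seed=15)
        starts = np.arange(60) * 30.0
        st = tdm.gen_ramping_unit(spec, starts, 1800.0)
        fit = tdm.glm_ramp_slope(st, starts, variant="outlier_excluded")
        assert fit.n_obs < 60 * 30
        assert fit.variant == "outlier_excluded"


class TestEpochCompare:
    def test_up_down_groups_differ_early(self):
        peths = _ramp_peths([0.5] * 5 + [-0.4] * 5, seed=16, n_trials=60)
        groups = ["up"] * 5 + ["down"] * 5
        out = tdm.epoch_activity_compare(peths, groups).set_index("epoch")
        early = out.loc["early"]
        assert (early["mean_down"] - early["mean_up"]) != 0
        assert early["p_value"] < 0.05

    def test_whole_window_mean_of_zscore_is_zero(self):
        peths = _ramp_peths([0.3, -0.3, 0.2, -0.2], seed=17, n_trials=60)
        out = tdm.epoch_activity_compare(
            peths, ["a", "a", "b", "b"], early=(-4.0, 22.0),
            late=(0.0, 6.0)).set_index("epoch")
        assert abs(out.loc["early", "mean_a"]) < 1e-9
        assert abs(out.loc["early", "mean_b"]) < 1e-9
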