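import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aerodiv.catchment import initial_bearing_deg
from aerodiv.synthetic import (
    SyntheticConfig,
    make_community,
    make_survey,
    make_trajectories,
    sample_reads,
    spike_false_positives,
)


class TestMakeCommunity:
    def test_zero_noise_within_cluster_identical_up_to_offset(self):
        cfg = SyntheticConfig(
            n_genera=12, n_weeks=60, n_clusters=3, noise_sd=0.0, surge=False, seed=1
        )
        truth = make_community(cfg)
        for cid in range(1, 4):
            members = truth.cluster_of.index[truth.cluster_of == cid]
            base = truth.latent.loc[members[0]].to_numpy()
            for g in members[1:]:
                diff = truth.latent.loc[g].to_numpy() - base
                assert np.ptp(diff) < 1e-10  # constant offset

    def test_seed_determinism(self):
        cfg = SyntheticConfig(n_genera=20, n_weeks=40, n_clusters=2, seed=7)
        t1, t2 = make_community(cfg), make_community(cfg)
        pd.testing.assert_frame_equal(t1.latent, t2.latent)
        pd.testing.assert_series_equal(t1.cluster_of, t2.cluster_of)

    def test_invalid_cluster_count(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_genera=3, n_clusters=5)

    def test_surge_genus_share_path(self):
        cfg = SyntheticConfig(n_genera=50, n_weeks=200, n_clusters=5, seed=2)
        truth = make_community(cfg)
        shares = truth.softmax_shares().loc[truth.surge_genus]
        s0, s1, s2 = cfg.surge_shares
        assert shares.iloc[:10].mean() == pytest.approx(s0, abs=0.03)
        assert shares.max() == pytest.approx(s1, abs=0.03)
        assert shares.iloc[-5:].mean() == pytest.approx(s2, abs=0.05)


class TestSampleReads:
    def test_closure_to_library_size(self, small_truth, small_config, small_counts):
        totals = small_counts.counts.sum(axis=0)
        np.testing.assert_array_equal(
            totals.to_numpy(), small_counts.metadata["total_reads"].to_numpy()
        )

    def test_no_bias_proportions_match_softmax(self):
        cfg = SyntheticConfig(
            n_genera=5,
            n_weeks=4,
            n_clusters=2,
            noise_sd=0.0,
            read_length_bias_sd=0.0,
            batch_effect_sd=0.0,
            surge=False,
            library_size_mean=2_000_000,
            library_size_dispersion=0.0,
            seed=3,
        )
        truth = make_community(cfg)
        cm = sample_reads(truth, cfg)
        props = cm.counts / cm.counts.sum(axis=0)
        expected = truth.softmax_shares()
        np.testing.assert_allclose(
            props.to_numpy(), expected.to_numpy(), atol=3e-3
        )

    def test_empirical_proportions_within_monte_carlo_se(self):
        # 1000 replicate weeks of a constant composition: empirical mean
        # proportion within 3 multinomial SEs of truth
        cfg = SyntheticConfig(
            n_genera=6,
            n_weeks=1000,
            weeks_per_year=1000,
            n_clusters=1,
            noise_sd=0.0,
            seasonal_amplitude=0.0,
            read_length_bias_sd=0.0,
            batch_effect_sd=0.0,
            surge=False,
            library_size_mean=5000,
            library_size_dispersion=0.0,
            seed=4,
        )
        truth = make_community(cfg)
        cm = sample_reads(truth, cfg)
        p_true = truth.softmax_shares().iloc[:, 0].to_numpy()
        lib = cm.metadata["total_reads"].to_numpy()
        props = (cm.counts / lib).mean(axis=1).to_numpy()
        se = np.sqrt(p_true * (1 - p_true) / lib.mean() / cfg.n_weeks)
        assert (np.abs(props - p_true) < 3 * se + 1e-12).all()

    def test_metadata_batch_switch(self, small_counts, small_config):
        ft = small_counts.metadata["filter_type"].to_numpy()
        b = small_config.batch_change_week
        assert (ft[:b] == "CS5.0").all() and (ft[b:] == "HB5773").all()


class TestSpikeFalsePositives:
    def test_zero_spurious_identity(self, small_truth, small_counts):
        cfg = SyntheticConfig(
            n_genera=40, n_weeks=120, n_clusters=4, n_spurious_genera=0, seed=123
        )
        spiked, res = spike_false_positives(small_counts, small_truth, cfg)
        pd.testing.assert_frame_equal(spiked.counts, small_counts.counts)
        assert (res.labels == "positive").all()

    def test_labels_bookkeeping(self, small_truth, small_counts, small_config):
        spiked, res = spike_false_positives(small_counts, small_truth, small_config)
        planted = set(small_counts.genera)
        for g, lab in res.labels.items():
            assert lab == ("positive" if g in planted else "negative")

    def test_spurious_minimizer_profiles_degraded(self, small_truth, small_counts, small_config):
        _, res = spike_false_positives(small_counts, small_truth, small_config)
        s = res.summaries
        ratio = s["distinct_minimizers"] / s["total_minimizers"]
        spur = res.labels == "negative"
        assert ratio[spur].mean() < ratio[~spur].mean()

    def test_occurrences_far_for_spurious(self, small_truth, small_counts, small_config):
        from aerodiv.catchment import haversine_km
        from aerodiv.synthetic import STATION

        _, res = spike_false_positives(small_counts, small_truth, small_config)
        occ = res.occurrences
        spur_names = set(res.labels.index[res.labels == "negative"])
        spur_occ = occ[occ["taxon"].isin(spur_names)]
        d = haversine_km(
            STATION[0],
            STATION[1],
            spur_occ["decimalLatitude"].to_numpy(),
            spur_occ["decimalLongitude"].to_numpy(),
        )
        assert (d > 5000).all()


class TestMakeTrajectories:
    def test_isotropic_mean_bearing_uniform(self):
        cfg = SyntheticConfig(
            n_weeks=36, trajectories_per_week=30, trajectory_bias_concentration=0.0, seed=5
        )
        eps = make_trajectories(cfg)
        term = eps.endpoints.groupby(["week", "traj"]).last()
        bear = np.radians(
            initial_bearing_deg(
                eps.station[0], eps.station[1], term["lat"].to_numpy(), term["lon"].to_numpy()
            )
        )
        # Rayleigh test of circular uniformity
        n = len(bear)
        r = np.hypot(np.cos(bear).mean(), np.sin(bear).mean())
        p = np.exp(-n * r**2)
        assert p > 0.01

    def test_strong_south_bias_sectors(self):
        cfg = SyntheticConfig(
            n_weeks=20,
            trajectories_per_week=30,
            trajectory_bias_bearing=180.0,
            trajectory_bias_concentration=8.0,
            seed=6,
        )
        eps = make_trajectories(cfg)
        bear = initial_bearing_deg(
            eps.station[0],
            eps.station[1],
            eps.endpoints["lat"].to_numpy(),
            eps.endpoints["lon"].to_numpy(),
        )
        south = ((bear > 112.5) & (bear < 247.5)).mean()  # SE, S, SW sectors
        assert south > 0.8

    def test_heights_and_durations_from_design(self):
        cfg = SyntheticConfig(n_weeks=6, trajectories_per_week=10, seed=7)
        eps = make_trajectories(cfg)
        assert set(eps.endpoints["start_height"].unique()) <= {10.0, 100.0, 300.0, 500.0}
        durations = eps.endpoints.groupby(["week", "traj"])["hours_back"].max()
        assert set(durations.unique()) <= {24, 48, 72}

    def test_seed_determinism(self):
        cfg = SyntheticConfig(n_weeks=4, trajectories_per_week=5, seed=8)
        e1, e2 = make_trajectories(cfg), make_trajectories(cfg)
        pd.testing.assert_frame_equal(e1.endpoints, e2.endpoints)


class TestMakeSurvey:
    def test_zero_noise_monotone_with_latent(self):
        cfg = SyntheticConfig(
            n_genera=10,
            n_weeks=52 * 8,
            n_clusters=2,
            n_survey_routes=1,
            survey_noise_sd=0.0,
            surge=False,
            seed=9,
        )
        truth = make_community(cfg)
        survey = make_survey(truth, cfg)
        g = survey.counts["genus"].iloc[0]
        sub = survey.counts[survey.counts["genus"] == g].sort_values("year")
        latent = survey.latent_annual.loc[g]
        # with zero noise and the first route's zero offset, counts are the
        # rounded exponential of the latent annual mean exactly
        np.testing.assert_array_equal(
            sub["count"].to_numpy(), np.round(np.exp(latent.to_numpy())).astype(int)
        )

    def test_route_offsets_shift_level_not_shape(self):
        cfg = SyntheticConfig(
            n_genera=8,
            n_weeks=52 * 6,
            n_clusters=2,
            n_survey_routes=3,
            survey_noise_sd=0.0,
            surge=False,
            seed=10,
        )
        truth = make_community(cfg)
        survey = make_survey(truth, cfg)
        g = survey.counts["genus"].iloc[0]
        wide = survey.counts[survey.counts["genus"] == g].pivot(
            index="year", columns="route", values="count"
        )
        logw = np.log(wide + 0.5)
        diffs = logw.sub(logw["route1"], axis=0)
        # log-scale differences between routes are constant over years
        # (up to integer rounding of counts)
        assert diffs.std(axis=0).max() < 0.1

    def test_ar_coefficient_recovered_from_residuals(self):
        cfg = SyntheticConfig(
            n_genera=4,
            n_weeks=52 * 200,
            n_clusters=2,
            n_survey_routes=1,
            survey_ar=0.5,
            survey_noise_sd=0.3,
            noise_sd=0.0,
            seasonal_amplitude=0.0,
            surge=False,
            seed=11,
        )
        truth = make_community(cfg)
        survey = make_survey(truth, cfg)
        g = survey.counts["genus"].iloc[0]
        sub = survey.counts[survey.counts["genus"] == g].sort_values("year")
        resid = np.log(sub["count"].to_numpy() + 0.5) - (
            survey.latent_annual.loc[g].to_numpy() + survey.route_offsets.iloc[0]
        )
        phi_hat = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert phi_hat == pytest.approx(cfg.survey_ar, abs=0.1)
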