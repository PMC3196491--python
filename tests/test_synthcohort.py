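"""Ground-truth generator: geometry, rest/task runs, schedules, cohort."""

import numpy as np
import pytest

from restgraph import GroundTruth, make_geometry
from restgraph import synthcohort as sc
from restgraph import preprocess, voxelnet, graphmetrics, taskglm


class TestMakeGeometry:
    def test_counts_forced_by_inputs(self):
        g = make_geometry((4, 4, 4), 8, seed=1)
        assert g.n_total == 64
        assert len(np.unique(g.node_regions)) == 8
        assert np.all(np.bincount(g.node_regions) >= 1)

    def test_masks_mutually_exclusive_and_exhaustive(self):
        g = make_geometry((5, 5, 4), 6, seed=0)
        stacked = (g.gray_mask.astype(int) + g.wm_mask.astype(int)
                   + g.vent_mask.astype(int))
        assert np.all(stacked == 1)
        assert np.all(g.region_labels[g.gray_mask] >= 0)
        assert np.all(g.region_labels[~g.gray_mask] == -1)

    def test_deterministic_for_fixed_seed(self):
        a = make_geometry((4, 4, 4), 8, seed=7)
        b = make_geometry((4, 4, 4), 8, seed=7)
        np.testing.assert_array_equal(a.region_labels, b.region_labels)
        np.testing.assert_array_equal(a.gray_mask, b.gray_mask)

    def test_pigeonhole_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_geometry((2, 2, 2), 9)

    def test_unique_coordinates(self):
        g = make_geometry((3, 4, 5), 5, seed=0)
        assert len(np.unique(g.coords_vox, axis=0)) == g.n_total


class TestSimulateRestRun:
    def test_same_region_voxels_identical_without_noise(self, geom_small):
        truth = GroundTruth(noise_sd=0.0)
        run = sc.simulate_rest_run(geom_small, truth, {"group": "NDU"},
                                   n_vols=60, seed=4)
        nodes = run.data[geom_small.gray_mask]
        regions = geom_small.node_regions
        same = np.nonzero(regions == regions[0])[0]
        r = np.corrcoef(nodes[same[0]], nodes[same[1]])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_non_positive_definite_coupling_names_block(self, geom_small):
        truth = GroundTruth(hub_coupling=1.2)
        with pytest.raises(ValueError, match="region block"):
            sc.simulate_rest_run(geom_small, truth,
                                 {"group": "CHU", "duration_months": 50.0},
                                 n_vols=40, seed=0)

    def test_too_short_run_rejected(self, geom_small):
        with pytest.raises(ValueError, match="n_vols"):
            sc.simulate_rest_run(geom_small, GroundTruth(), {"group": "NDU"},
                                 n_vols=10, seed=0)

    def test_deterministic(self, geom_small):
        kw = dict(n_vols=40, seed=9)
        a = sc.simulate_rest_run(geom_small, GroundTruth(),
                                 {"group": "NDU"}, **kw)
        b = sc.simulate_rest_run(geom_small, GroundTruth(),
                                 {"group": "NDU"}, **kw)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.motion_params, b.motion_params)

    def test_equal_hub_coupling_gives_no_group_degree_difference(
            self, geom_small):
        """With identical hub sets the group mean degree difference sits
        within 2 SE of zero over many seeds."""
        truth = GroundTruth(
            hub_regions_per_group={"CHU": [1], "NDU": [1]},
            duration_efficiency_slope=0.0)
        diffs = []
        for seed in range(50):
            deg = {}
            for grp, off in (("CHU", 0), ("NDU", 1)):
                run = sc.simulate_rest_run(
                    geom_small, truth,
                    {"group": grp, "duration_months": 100.0},
                    n_vols=60, seed=2 * seed + off)
                nodes = preprocess.bandpass(run.data[geom_small.gray_mask], 2.0)
                adj = voxelnet.binarize(
                    voxelnet.correlation_matrix(nodes), 0.42)
                deg[grp] = graphmetrics.degree(adj).mean()
            diffs.append(deg["CHU"] - deg["NDU"])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 2 * se


class TestEventSchedule:
    def test_expected_duration_480s(self):
        """48 trials of 2 s with ISI ~ U(4, 12) average out to 480 s."""
        totals = []
        for seed in range(300):
            ev = sc.make_event_schedule(48, 2.0, 4.0, 12.0, seed=seed)
            last = ev.iloc[-1]
            # full schedule duration includes a final mean ISI
            totals.append(last["onset_s"] + last["duration_s"] + 8.0)
        assert np.mean(totals) == pytest.approx(480.0, abs=3.0)

    def test_fitted_schedule_fills_the_window_exactly(self):
        ev = sc.make_event_schedule(48, 2.0, 4.0, 12.0, seed=1,
                                    fit_total_s=480.0)
        assert ev["onset_s"].iloc[-1] + 2.0 <= 480.0
        assert len(ev) == 48
        assert sorted(ev["condition"].value_counts()) == [24, 24]

    def test_single_trial(self):
        ev = sc.make_event_schedule(1, 2.0, 4.0, 12.0, seed=0)
        assert len(ev) == 1 and ev["onset_s"].iloc[0] == 0.0

    def test_deterministic_and_increasing(self):
        a = sc.make_event_schedule(20, seed=5)
        b = sc.make_event_schedule(20, seed=5)
        assert a.equals(b)
        assert np.all(np.diff(a["onset_s"]) > 0)


class TestSimulateTaskRun:
    def test_noiseless_single_event_proportional_to_hrf(self, geom_small):
        truth = GroundTruth(task_noise_sd=0.0, drift_amp=0.0,
                            degree_activation_slope=0.0)
        ev = sc.make_event_schedule(1, 2.0, 4.0, 12.0, seed=0)
        run = sc.simulate_task_run(
            geom_small, truth, np.full(geom_small.n_regions, 90.0), ev,
            n_vols=40, seed=0)
        node = run.data[geom_small.gray_mask][0]
        reg = taskglm.convolve_events(ev, 40, 2.0)["heroin"].to_numpy()
        assert np.corrcoef(node, reg)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_overlapping_events_rejected(self, geom_small):
        import pandas as pd
        ev = pd.DataFrame({"onset_s": [0.0, 1.0], "duration_s": [2.0, 2.0],
                           "condition": ["heroin", "neutral"]})
        with pytest.raises(ValueError, match="overlap"):
            sc.simulate_task_run(geom_small, GroundTruth(),
                                 np.full(geom_small.n_regions, 90.0), ev,
                                 n_vols=40, seed=0)

    def test_zero_slope_decouples_contrast_from_degree(self, geom_small):
        """With degree_activation_slope = 0 the fitted contrast does not
        track resting degree across subjects."""
        truth = GroundTruth(degree_activation_slope=0.0)
        coupling = truth.hub_regions_per_group["CHU"]
        rs = []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            degs, cons = [], []
            ev = sc.make_event_schedule(12, 2.0, 4.0, 8.0, seed=rep,
                                        fit_total_s=120.0)
            design = taskglm.build_design(ev, 60, 2.0)
            for subj in range(8):
                region_deg = rng.uniform(40, 160, geom_small.n_regions)
                run = sc.simulate_task_run(geom_small, truth, region_deg, ev,
                                           n_vols=60,
                                           seed=1000 * rep + subj)
                cmap = taskglm.fit_contrast(
                    run.data[geom_small.gray_mask], design)
                m = np.isin(geom_small.node_regions, coupling)
                degs.append(region_deg[coupling].mean())
                cons.append(cmap.estimate[m].mean())
            rs.append(np.corrcoef(degs, cons)[0, 1])
        assert abs(np.mean(rs)) < 0.15


@pytest.fixture(scope="module")
def cohort(geom_small):
    return sc.simulate_cohort(geom_small, GroundTruth(), n_per_group=4,
                              n_rest_vols=60, n_task_vols=80, seed=3)


class TestSimulateCohort:
    def test_group_sizes_and_run_shapes(self, cohort, geom_small):
        assert len(cohort.group("CHU")) == len(cohort.group("NDU")) == 4
        s = cohort.subjects[0]
        assert s.rest_run.data.shape == (geom_small.n_total, 60)
        assert s.task_run.data.shape == (geom_small.n_total, 80)
        assert s.motion_params.shape == (60, 6)

    def test_covariates_follow_study_ranges(self, cohort):
        for s in cohort.group("CHU"):
            assert 19 <= s.duration_months <= 182
            assert 25 <= s.age_years <= 49
            assert 0 <= s.craving_pre <= 10 and 0 <= s.craving_post <= 10
        for s in cohort.group("NDU"):
            assert s.duration_months is None and s.task_run is None

    def test_phenotype_table_schema(self, cohort):
        table = cohort.phenotype()
        assert list(table.columns) == [
            "subject", "group", "age", "duration_months", "dosage",
            "craving_pre", "craving_post"]
        assert len(table) == 8

    def test_byte_identical_replay(self, geom_small):
        a = sc.simulate_cohort(geom_small, GroundTruth(), n_per_group=2,
                               n_rest_vols=40, n_task_vols=60, seed=11)
        b = sc.simulate_cohort(geom_small, GroundTruth(), n_per_group=2,
                               n_rest_vols=40, n_task_vols=60, seed=11)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.rest_run.data, sb.rest_run.data)
            if sa.task_run is not None:
                np.testing.assert_array_equal(sa.task_run.data,
                                              sb.task_run.data)
            assert sa.craving_pre == sb.craving_pre

    def test_craving_rises_after_cue_exposure(self, geom_study):
        cohort = sc.simulate_cohort(geom_study, GroundTruth(),
                                    n_per_group=16, n_rest_vols=60,
                                    n_task_vols=80, seed=21)
        from restgraph.inference import paired_t
        chu = cohort.group("CHU")
        res = paired_t([s.craving_pre for s in chu],
                       [s.craving_post for s in chu])
        assert res.direction == "A>B"  # post > pre
        assert res.p < 0.001
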