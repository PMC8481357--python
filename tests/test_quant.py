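"""Image quantification: segmentation, tracking, counting, fitting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skimage import measure

from conftest import disk_fixture

from zorbkit.errors import ArgumentError, ConfigurationError, FormatError
from zorbkit.quant import (
    ColonyRecord,
    SegmentationParams,
    cccp_table,
    count_base_cells,
    equivalent_diameter_um,
    fit_power_law,
    link_tracks,
    morphometrics,
    orientation_stats,
    segment_frame,
    sphere_volume_um3,
    weighted_timeseries,
)


def make_record(frame, cid, x, y, area):
    D = equivalent_diameter_um(area)
    return ColonyRecord(frame_index=frame, colony_id=cid,
                        centroid_um=(x, y), area_um2=area,
                        diameter_um=D, volume_um3=sphere_volume_um3(D))


class TestSegmentation:
    def test_blank_image_empty_mask(self):
        mask = segment_frame(np.full((64, 64), 128, dtype=np.uint8))
        assert mask.max() == 0

    def test_non_2d_rejected(self):
        with pytest.raises(FormatError):
            segment_frame(np.zeros((4, 4, 3)))

    def test_three_disks_recovered_with_accurate_areas(self):
        img, truth = disk_fixture()
        mask = segment_frame(img)
        props = measure.regionprops(mask)
        assert len(props) == 3
        areas = sorted(p.area for p in props)
        expected = sorted(t["area"] for t in truth)
        for a, e in zip(areas, expected):
            assert abs(a / e - 1) < 0.05

    def test_polarity_invariance_of_component_count(self):
        img, _ = disk_fixture()
        inv, _ = disk_fixture(inverted=True)
        n = len(measure.regionprops(segment_frame(img)))
        n_inv = len(measure.regionprops(segment_frame(inv)))
        assert n == n_inv == 3


class TestMorphometrics:
    def test_identities_hold_on_every_record(self):
        img, _ = disk_fixture()
        mask = segment_frame(img)
        recs = morphometrics(mask, pixel_size_um=1.5, roi_diameter_um=None)
        assert recs
        for r in recs:
            assert r.diameter_um == pytest.approx(
                2 * math.sqrt(r.area_um2 / math.pi), abs=1e-9)
            assert r.volume_um3 == pytest.approx(
                (4 / 3) * math.pi * (r.diameter_um / 2) ** 3, abs=1e-9)

    def test_small_component_filtered(self):
        # one component of area pi um^2 -> D = 2 um, below the 10 um floor
        mask = np.zeros((50, 50), dtype=int)
        mask[10:12, 10:12] = 1  # 4 px
        recs = morphometrics(mask, pixel_size_um=math.sqrt(math.pi) / 2,
                             roi_diameter_um=None)
        assert recs == []

    def test_closed_form_volume_at_50_um(self):
        assert sphere_volume_um3(50.0) == pytest.approx(65449.8, abs=0.1)
        assert equivalent_diameter_um(625 * math.pi) == pytest.approx(50.0)

    def test_roi_exclusion(self):
        mask = np.zeros((100, 100), dtype=int)
        mask[5:25, 5:25] = 1      # near the corner
        mask[45:65, 45:65] = 2    # near the center
        recs = morphometrics(mask, pixel_size_um=1.0,
                             roi_diameter_um=40.0)
        assert [r.colony_id for r in recs] == [2]

    def test_missing_pixel_size_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            morphometrics(np.zeros((4, 4), dtype=int), pixel_size_um=None)


class TestTracking:
    def test_stationary_disks_zero_velocity_no_events(self):
        frames = [
            [make_record(f, 1, 30.0, 40.0, 400.0),
             make_record(f, 2, 120.0, 60.0, 900.0)]
            for f in range(5)
        ]
        tracks, events = link_tracks(frames)
        assert len(tracks.tracks) == 2
        assert events.events == []
        for tr in tracks.tracks:
            assert len(tr.records) == 5
            assert all(v == 0.0 for v in tr.velocities_um_s)

    def test_requires_two_frames(self):
        with pytest.raises(ArgumentError):
            link_tracks([[make_record(0, 1, 0, 0, 400.0)]])

    def test_assignments_match_exhaustive_permutation_minimum(self):
        """Small jitter: the LAP linker finds the same assignment as a
        brute-force search over all permutations."""
        rng = np.random.default_rng(9)
        n = 6
        base = rng.uniform(50, 450, size=(n, 2))
        for trial in range(5):
            jitter = rng.uniform(-4, 4, size=(n, 2))
            perm = rng.permutation(n)
            prev = [make_record(0, i, *base[i], 500.0) for i in range(n)]
            curr = [make_record(1, 100 + i, *(base[p] + jitter[p]), 500.0)
                    for i, p in enumerate(perm)]
            tracks, _ = link_tracks([prev, curr], max_link_um=30.0)
            got = {}
            for tr in tracks.tracks:
                if len(tr.records) == 2:
                    got[tr.records[0].colony_id] = tr.records[1].colony_id

            def cost_of(assignment):
                return sum(
                    math.dist(prev[i].centroid_um,
                              curr[assignment[i]].centroid_um)
                    for i in range(n)
                )
            best = min(itertools.permutations(range(n)), key=cost_of)
            expected = {prev[i].colony_id: curr[best[i]].colony_id
                        for i in range(n)}
            assert got == expected

    def test_merge_event_excludes_velocity_spike(self):
        """Two colonies converge then merge: one merge event at the merge
        frame, and the surviving track has no displacement spike there."""
        frames = []
        for f in range(4):
            a = make_record(f, 1, 100.0 - 4 * f, 100.0, 900.0)
            b = make_record(f, 2, 140.0 + 4 * f * 0, 100.0, 400.0)
            frames.append([a, b])
        merged = make_record(4, 3, 112.0, 100.0, 1300.0)
        frames.append([merged])
        far = make_record(4, 4, 400.0, 400.0, 500.0)  # unrelated newcomer
        frames[-1].append(far)
        tracks, events = link_tracks(frames, max_link_um=40.0)
        merges = events.of_type("merge")
        assert len(merges) == 1
        assert merges[0]["frame_index"] == 4
        assert len(merges[0]["parent_ids"]) == 2
        # area bookkeeping lets the caller audit conservation
        assert merges[0]["area_before"] == pytest.approx(1300.0)
        surviving = [t for t in tracks.tracks if len(t.records) == 5]
        assert surviving
        assert math.isnan(surviving[0].velocities_um_s[-1])


class TestWeightedTimeseries:
    def test_equal_sizes_reduce_to_arithmetic_mean(self):
        frames = [
            [make_record(0, 1, 0, 0, 900.0), make_record(0, 2, 99, 0, 900.0)],
            [make_record(1, 1, 3, 0, 900.0), make_record(1, 2, 105, 0, 900.0)],
        ]
        tracks, _ = link_tracks(frames, frame_interval_s=1.0)
        ts = weighted_timeseries(tracks)
        row = ts[ts.frame == 1].iloc[0]
        assert row.weighted_mean_velocity_um_s == pytest.approx((3 + 6) / 2)

    def test_volume_weighting_formula(self):
        # V1 = 2 V2, velocities 1 and 4 -> weighted mean 2
        v1 = 2000.0
        d1 = 2 * (v1 * 3 / (4 * math.pi)) ** (1 / 3)
        a1 = math.pi * (d1 / 2) ** 2
        v2 = 1000.0
        d2 = 2 * (v2 * 3 / (4 * math.pi)) ** (1 / 3)
        a2 = math.pi * (d2 / 2) ** 2
        frames = [
            [make_record(0, 1, 0, 0, a1), make_record(0, 2, 200, 0, a2)],
            [make_record(1, 1, 1, 0, a1), make_record(1, 2, 204, 0, a2)],
        ]
        tracks, _ = link_tracks(frames, frame_interval_s=1.0,
                                max_link_um=20.0)
        ts = weighted_timeseries(tracks)
        row = ts[ts.frame == 1].iloc[0]
        assert row.weighted_mean_velocity_um_s == pytest.approx(
            (2 * 1 + 1 * 4) / 3, rel=1e-9)

    def test_empty_frames_report_missing_not_zero(self):
        frames = [[make_record(0, 1, 0, 0, 900.0)],
                  [make_record(1, 1, 0, 0, 900.0)]]
        tracks, _ = link_tracks(frames)
        ts = weighted_timeseries(tracks)
        assert math.isnan(ts[ts.frame == 0].iloc[0]
                          .weighted_mean_velocity_um_s)


class TestCCCPTable:
    def test_threshold_is_strict(self):
        mask = np.zeros((80, 80), dtype=int)
        mask[:25, :40] = 1   # exactly 1000 px^2
        mask[40:75, 40:75] = 2  # 1225 px^2
        df = cccp_table([mask], pixel_size_um=1.0)
        assert list(df.component) == [2]

    def test_1000_px2_maps_to_37_um_baseline(self):
        """With ~1.04 um/px the pixel-area cutoff equals the mature-colony
        diameter baseline."""
        px = 1.037
        D = equivalent_diameter_um(1000 * px**2)
        assert D == pytest.approx(37.0, abs=0.1)

    def test_merging_timepoints_fewer_but_larger(self):
        m1 = np.zeros((200, 200), dtype=int)
        m1[20:60, 20:60] = 1
        m1[80:120, 80:120] = 2
        m1[140:180, 20:60] = 3
        m2 = np.zeros((200, 200), dtype=int)
        m2[40:100, 40:100] = 1  # merged pair
        m2[140:180, 20:60] = 2
        df = cccp_table([m1, m2], pixel_size_um=1.5)
        g = df.groupby("timepoint")["diameter_um"]
        assert g.count()[0] > g.count()[1]
        assert g.median()[1] > g.median()[0]


class TestBaseCellCounting:
    def _spot_image(self, n_spots=20, seed=4, size=160, min_sep=12.0):
        rng = np.random.default_rng(seed)
        pts = []
        while len(pts) < n_spots:
            p = rng.uniform(20, size - 20, 2)
            if all(np.hypot(*(p - q)) >= min_sep for q in pts):
                pts.append(p)
        yy, xx = np.mgrid[0:size, 0:size]
        img = np.full((size, size), 25.0)
        for px, py in pts:
            img += 170 * np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * 2.2**2))
        img += rng.normal(0, 4, img.shape)
        return np.clip(img, 0, 255).astype(np.uint8), np.array(pts)

    def test_blank_image_counts_zero(self):
        n, coords = count_base_cells(np.full((64, 64), 7, dtype=np.uint8),
                                     prominence=50)
        assert n == 0 and coords.shape == (0, 2)

    def test_known_spots_recovered_within_one_pixel(self):
        img, pts = self._spot_image()
        n, coords = count_base_cells(img, prominence=60)
        assert n == len(pts)
        for p in pts:
            d = np.min(np.hypot(coords[:, 0] - p[0], coords[:, 1] - p[1]))
            assert d <= 1.0

    def test_close_pair_suppressed_to_single_maximum(self):
        """Two spots closer than the suppression scale count once."""
        size = 96
        yy, xx = np.mgrid[0:size, 0:size]
        img = np.full((size, size), 25.0)
        for px in (46.0, 48.5):
            img += 170 * np.exp(-((xx - px) ** 2 + (yy - 48.0) ** 2)
                                / (2 * 2.2**2))
        img = np.clip(img, 0, 255).astype(np.uint8)
        n, _ = count_base_cells(img, prominence=60, min_distance_px=4)
        assert n == 1

    def test_missing_prominence_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            count_base_cells(np.zeros((32, 32), dtype=np.uint8),
                             prominence=None)


class TestPowerLawFit:
    def test_noiseless_identity(self):
        D = np.arange(10.0, 101.0, 10.0)
        N = 0.2 * D**1.36
        res = fit_power_law(D, N)
        assert res["a"] == pytest.approx(0.2, abs=1e-10)
        assert res["b"] == pytest.approx(1.36, abs=1e-10)

    def test_constant_counts_give_zero_exponent(self):
        D = np.arange(10.0, 101.0, 10.0)
        res = fit_power_law(D, np.full_like(D, 7.0))
        assert res["b"] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_noise_recovery(self):
        rng = np.random.default_rng(0)
        D = rng.uniform(10, 100, 100)
        N = rng.poisson(0.2 * D**1.36)
        m = N > 0
        res = fit_power_law(D[m], N[m])
        assert abs(res["b"] - 1.36) < 0.1
        assert res["b_stderr"] < 0.1

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        D = rng.uniform(10, 100, 40)
        N = 0.3 * D**1.2 * np.exp(rng.normal(0, 0.1, 40))
        res = fit_power_law(D, N)
        k = 3.7
        res_k = fit_power_law(k * D, N)
        assert res_k["b"] == pytest.approx(res["b"], rel=1e-10)
        assert res_k["a"] == pytest.approx(res["a"] * k**(-res["b"]),
                                           rel=1e-9)

    def test_nls_close_to_loglog_on_clean_data(self):
        D = np.arange(10.0, 101.0, 5.0)
        N = 0.2 * D**1.36
        assert fit_power_law(D, N, method="nls")["b"] == pytest.approx(
            1.36, abs=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ArgumentError):
            fit_power_law([1, 2, 3], [1, 0, 2])


class TestOrientation:
    def test_parallel_cells_have_zero_relative_angle(self):
        df = pd.DataFrame({"x_um": [0, 3, 6, 9], "y_um": [0, 0, 0, 0],
                           "angle_deg": [40.0] * 4})
        res = orientation_stats(df)
        assert np.allclose(res.weighted_mean_relative_angle_deg, 0.0)

    def test_orthogonal_pair_at_half_radius(self):
        df = pd.DataFrame({"x_um": [0.0, 4.9], "y_um": [0.0, 0.0],
                           "angle_deg": [0.0, 90.0]})
        res = orientation_stats(df, search_radius_um=9.8)
        assert np.allclose(res.weighted_mean_relative_angle_deg, 90.0)
        assert list(res.n_neighbors) == [1, 1]

    def test_isolated_cells_omitted(self):
        df = pd.DataFrame({"x_um": [0.0, 100.0], "y_um": [0.0, 0.0],
                           "angle_deg": [10.0, 30.0]})
        res = orientation_stats(df)
        assert len(res) == 0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        n = 50
        df = pd.DataFrame({
            "x_um": rng.uniform(0, 40, n),
            "y_um": rng.uniform(0, 40, n),
            "angle_deg": rng.uniform(0, 180, n),
        })
        R = 9.8
        res = orientation_stats(df, search_radius_um=R).set_index(
            "cell_index")
        pts = df[["x_um", "y_um"]].to_numpy()
        ang = df["angle_deg"].to_numpy()
        for i in range(n):
            num = den = 0.0
            cnt = 0
            for j in range(n):
                if i == j:
                    continue
                d = math.dist(pts[i], pts[j])
                if d > R:
                    continue
                rel = abs(ang[i] - ang[j])
                rel = min(rel, 180 - rel)
                w = 1 - d / R
                num += w * rel
                den += w
                cnt += 1
            if cnt == 0:
                assert i not in res.index
            else:
                assert res.loc[i, "weighted_mean_relative_angle_deg"] == \
                    pytest.approx(num / den, abs=1e-12)
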