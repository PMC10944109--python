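"""Patch detection, linking, curation, pairing, alignment, and metrics."""

import numpy as np
import pytest

from arpquant import synth
from arpquant.io import ImageStack, SpotDetection, Trajectory
from arpquant.patches import (CalibrationConstants, DetectionParams, LinkParams,
                              PatchEvent, align_events, average_aligned,
                              compute_metrics, curate_tracks, detect_spots,
                              kymograph, link_spots, pair_channels,
                              strain_summary, to_molecules)

PX = 0.065


def _spot(t, x, y, quality=10.0, intensity=100.0):
    return SpotDetection(t=t, x=x, y=y, quality=quality,
                         raw_intensity=intensity, corrected_intensity=intensity)


def _render_movie(centres_per_frame, amp=400.0, shape=(64, 64), sigma_um=0.1,
                  offset=0.0, noise=0.0, seed=0):
    """Little renderer: a Gaussian spot of peak amplitude ``amp`` per centre."""
    rng = np.random.default_rng(seed)
    T = len(centres_per_frame)
    data = np.zeros((T, 1, *shape))
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    sig = sigma_um / PX
    for t, centres in enumerate(centres_per_frame):
        frame = np.zeros(shape)
        for (x, y) in centres:
            cx, cy = x / PX, y / PX
            frame += amp * np.exp(-((rows - cy) ** 2 + (cols - cx) ** 2)
                                  / (2 * sig**2))
        frame += offset
        if noise:
            frame = np.clip(frame + rng.normal(0, noise, shape), 0, None)
        data[t, 0] = frame
    return ImageStack(data=data, pixel_size=PX, frame_interval=1.0,
                      channel_names=["Abp1"])


class TestDetection:
    def test_single_spot_located_within_half_pixel(self):
        stack = _render_movie([[(2.0, 1.5)]], amp=80.0, offset=0.0, noise=8.0)
        dets = detect_spots(stack, "Abp1", DetectionParams())
        assert len(dets) == 1
        assert abs(dets[0].x - 2.0) < 0.5 * PX
        assert abs(dets[0].y - 1.5) < 0.5 * PX

    def test_blank_noise_frames_give_no_detections(self):
        rng = np.random.default_rng(0)
        data = np.clip(rng.normal(100, 8, (5, 1, 64, 64)), 0, None)
        stack = ImageStack(data=data, pixel_size=PX, frame_interval=1.0,
                           channel_names=["Abp1"])
        assert detect_spots(stack, "Abp1", DetectionParams()) == []

    def test_two_spots_one_micron_apart_resolved(self):
        stack = _render_movie([[(1.5, 2.0), (2.5, 2.0)]], amp=300.0, noise=5.0)
        dets = detect_spots(stack, "Abp1", DetectionParams())
        assert len(dets) == 2
        xs = sorted(d.x for d in dets)
        assert xs[0] == pytest.approx(1.5, abs=0.05)
        assert xs[1] == pytest.approx(2.5, abs=0.05)

    def test_raising_threshold_never_adds_detections(self):
        stack = _render_movie([[(1.0, 1.0), (2.5, 2.5), (1.0, 3.0)]],
                              amp=60.0, noise=10.0)
        counts = [len(detect_spots(stack, "Abp1",
                                   DetectionParams(quality_threshold=q)))
                  for q in (2.0, 5.0, 8.0, 12.0, 20.0)]
        assert counts == sorted(counts, reverse=True)

    def test_unknown_channel_rejected(self):
        stack = _render_movie([[(1.0, 1.0)]])
        with pytest.raises(KeyError):
            detect_spots(stack, "Arp2", DetectionParams())


class TestLinking:
    def test_slow_spot_yields_single_track(self):
        dets = [_spot(t, 0.5 + 0.1 * t, 1.0) for t in range(6)]
        tracks = link_spots(dets, LinkParams())
        assert len(tracks) == 1
        assert len(tracks[0]) == 6

    def test_large_jump_splits_track(self):
        dets = [_spot(0, 0.5, 1.0), _spot(1, 0.55, 1.0),
                _spot(2, 1.55, 1.0), _spot(3, 1.6, 1.0)]  # 1.0 um jump
        tracks = link_spots(dets, LinkParams())
        assert len(tracks) == 2

    def test_two_frame_gap_bridged_within_distance(self):
        dets = ([_spot(t, 1.0 + 0.02 * t, 1.0) for t in range(3)]
                + [_spot(t, 1.3, 1.0) for t in range(5, 8)])
        tracks = link_spots(dets, LinkParams())
        assert len(tracks) == 1
        assert list(tracks[0].frames) == [0, 1, 2, 5, 6, 7]

    def test_gap_beyond_max_frame_gap_not_bridged(self):
        dets = [_spot(0, 1.0, 1.0), _spot(4, 1.1, 1.0)]  # 3 missing frames
        tracks = link_spots(dets, LinkParams())
        assert len(tracks) == 2


class TestExternalImport:
    def test_trackmate_style_export_round_trips(self):
        import pandas as pd
        from arpquant.patches import trajectories_from_csv
        df = pd.DataFrame({
            "TRACK_ID": [0, 0, 0, 1, 1],
            "FRAME": [2, 3, 4, 1, 2],
            "POSITION_X": [1.0, 1.05, 1.1, 3.0, 3.0],
            "POSITION_Y": [2.0, 2.0, 2.0, 0.5, 0.5],
            "TOTAL_INTENSITY": [10.0, 20.0, 15.0, 5.0, 6.0],
        })
        tracks = trajectories_from_csv(df, channel="Abp1")
        assert [len(t) for t in tracks] == [3, 2]
        assert list(tracks[0].frames) == [2, 3, 4]
        np.testing.assert_allclose(tracks[0].intensities, [10.0, 20.0, 15.0])

    def test_missing_columns_named(self):
        import pandas as pd
        from arpquant.patches import trajectories_from_csv
        with pytest.raises(ValueError, match="POSITION_Y"):
            trajectories_from_csv(pd.DataFrame({"TRACK_ID": [], "FRAME": [],
                                                "POSITION_X": []}))


class TestCuration:
    def _stack(self, t=50):
        return ImageStack(data=np.zeros((t, 1, 64, 64)) + 1.0, pixel_size=PX,
                          frame_interval=1.0, channel_names=["Abp1"])

    def _track(self, frames, x=1.0, y=1.0, dx=0.0):
        return Trajectory(channel="Abp1",
                          spots=[_spot(t, x + dx * i, y)
                                 for i, t in enumerate(frames)])

    def test_track_touching_movie_start_dropped(self):
        tracks = [self._track(range(0, 11))]
        assert curate_tracks(tracks, self._stack()) == []

    def test_track_touching_movie_end_dropped(self):
        tracks = [self._track(range(40, 50))]
        assert curate_tracks(tracks, self._stack()) == []

    def test_concurrent_close_tracks_both_dropped(self):
        a = self._track(range(5, 15), x=1.0)
        b = self._track(range(8, 18), x=1.3)  # 0.3 um away
        assert curate_tracks([a, b], self._stack()) == []

    def test_isolated_interior_track_kept(self):
        tr = self._track(range(10, 25))
        assert curate_tracks([tr], self._stack()) == [tr]

    def test_roi_keeps_only_tracks_starting_inside(self):
        roi = np.zeros((64, 64), dtype=bool)
        roi[:, :16] = True  # x < ~1.04 um
        inside = self._track(range(5, 15), x=0.5, y=1.0)
        outside = self._track(range(5, 15), x=3.0, y=1.0)
        kept = curate_tracks([inside, outside], self._stack(), roi=roi)
        assert kept == [inside]


class TestPairingAlignment:
    def _traj(self, channel, frames, x, intensities=None):
        ints = intensities if intensities is not None else [100.0] * len(frames)
        spots = [SpotDetection(t=t, x=x, y=1.0, quality=10.0,
                               raw_intensity=v, corrected_intensity=v)
                 for t, v in zip(frames, ints)]
        return Trajectory(channel=channel, spots=spots)

    def test_colocated_overlapping_tracks_pair(self):
        las = self._traj("Las17", range(5, 15), 1.0)
        abp = self._traj("Abp1", range(10, 20), 1.1)
        events, ul, ua = pair_channels([las], [abp], frame_interval=1.0)
        assert len(events) == 1 and not ul and not ua

    def test_distant_tracks_do_not_pair(self):
        las = self._traj("Las17", range(5, 15), 1.0)
        abp = self._traj("Abp1", range(5, 15), 3.0)  # 2 um away
        events, ul, ua = pair_channels([las], [abp], frame_interval=1.0)
        assert events == [] and len(ul) == 1 and len(ua) == 1

    def test_one_to_one_pairing_prefers_nearer(self):
        las = self._traj("Las17", range(5, 15), 1.0)
        near = self._traj("Abp1", range(5, 15), 1.1)
        far = self._traj("Abp1", range(5, 15), 1.4)
        events, _ul, ua = pair_channels([las], [near, far], frame_interval=1.0)
        assert len(events) == 1
        assert events[0].abp1 is near
        assert ua == [far]

    def test_alignment_zeroes_time_at_abp1_maximum(self):
        intensities = [10, 20, 50, 200, 80, 30]
        abp = self._traj("Abp1", range(4, 10), 1.0, intensities)  # max frame 7
        las = self._traj("Las17", range(2, 8), 1.0)
        (event,) = align_events([PatchEvent(las17=las, abp1=abp,
                                            frame_interval=1.0)])
        assert event.t0_frame == 7
        assert event.times("Abp1")[int(np.argmax(intensities))] == 0.0

    def test_alignment_tie_resolves_to_earliest_frame(self):
        abp = self._traj("Abp1", range(0, 5), 1.0, [10, 90, 90, 20, 5])
        las = self._traj("Las17", range(0, 5), 1.0)
        (event,) = align_events([PatchEvent(las17=las, abp1=abp,
                                            frame_interval=1.0)])
        assert event.t0_frame == 1

    def test_average_of_identical_events_reproduces_event(self):
        abp = self._traj("Abp1", range(4, 10), 1.0, [10, 20, 50, 200, 80, 30])
        las = self._traj("Las17", range(2, 8), 1.0, [5, 15, 40, 30, 20, 10])
        events = align_events([PatchEvent(las17=las, abp1=abp, frame_interval=1.0)
                               for _ in range(5)])
        times, mean = average_aligned(events, "Abp1", use_molecules=False)
        np.testing.assert_allclose(mean, [10, 20, 50, 200, 80, 30])
        np.testing.assert_allclose(times, np.arange(4, 10) - 7.0)

    def test_all_zero_abp1_trace_cannot_align(self):
        abp = self._traj("Abp1", range(3), 1.0, [0.0, 0.0, 0.0])
        las = self._traj("Las17", range(3), 1.0)
        with pytest.raises(ValueError, match="zero"):
            align_events([PatchEvent(las17=las, abp1=abp, frame_interval=1.0)])


def _make_event(abp_frames, abp_intensities, las_frames, las_intensities,
                abp_positions=None, frame_interval=1.0):
    def traj(channel, frames, ints, positions):
        spots = []
        for i, (t, v) in enumerate(zip(frames, ints)):
            x, y = positions[i] if positions is not None else (1.0, 1.0)
            spots.append(SpotDetection(t=t, x=x, y=y, quality=10.0,
                                       raw_intensity=v, corrected_intensity=v))
        return Trajectory(channel=channel, spots=spots)

    ev = PatchEvent(
        las17=traj("Las17", las_frames, las_intensities, None),
        abp1=traj("Abp1", abp_frames, abp_intensities, abp_positions),
        frame_interval=frame_interval,
    )
    (ev,) = align_events([ev])
    unit = CalibrationConstants(reference_counts={"Las17": 1.0, "Abp1": 1.0},
                                control_max_intensity={"Las17": 1.0, "Abp1": 1.0})
    return to_molecules(ev, unit)


class TestCalibration:
    def test_control_mean_maximum_maps_to_reference_count(self):
        ev = _make_event([0, 1, 2, 3], [10, 50, 90, 40], [0, 1, 2, 3],
                         [5, 25, 15, 10])
        calib = CalibrationConstants.from_control_events(
            [ev], {"Abp1": 783.0, "Las17": 140.0})
        cal_ev = to_molecules(ev, calib)
        assert cal_ev.molecules["Abp1"].max() == pytest.approx(783.0)
        assert cal_ev.molecules["Las17"].max() == pytest.approx(140.0)

    def test_gain_change_cancels_when_calibration_recomputed(self):
        ints = [10.0, 50.0, 90.0, 40.0]
        ev1 = _make_event([0, 1, 2, 3], ints, [0, 1, 2, 3], ints)
        ev2 = _make_event([0, 1, 2, 3], [2 * v for v in ints], [0, 1, 2, 3],
                          [2 * v for v in ints])
        refs = {"Abp1": 500.0, "Las17": 100.0}
        m1 = to_molecules(ev1, CalibrationConstants.from_control_events([ev1], refs))
        m2 = to_molecules(ev2, CalibrationConstants.from_control_events([ev2], refs))
        np.testing.assert_allclose(m1.molecules["Abp1"], m2.molecules["Abp1"])

    def test_zero_intensity_gives_zero_molecules(self):
        ev = _make_event([0, 1, 2], [0.0, 10.0, 5.0], [0, 1, 2], [1.0, 2.0, 1.0])
        assert ev.molecules["Abp1"][0] == 0.0

    def test_missing_channel_calibration_rejected(self):
        ev = _make_event([0, 1, 2], [1, 2, 1], [0, 1, 2], [1, 2, 1])
        calib = CalibrationConstants(reference_counts={"Abp1": 1.0},
                                     control_max_intensity={"Abp1": 1.0})
        with pytest.raises(KeyError, match="Las17"):
            to_molecules(ev, calib)


class TestMetrics:
    def test_linear_rise_gives_exact_accumulation_rate(self):
        # 10 molecules per 1 s frame -> 10 molecules/s
        rise = [10.0 * (i + 1) for i in range(10)]
        ev = _make_event(range(10), rise, range(8), [1.0] * 8)
        m = compute_metrics(ev)
        assert m.accumulation_rate_abp1 == pytest.approx(10.0)
        assert m.assembly_time == pytest.approx(9.0)

    @pytest.mark.parametrize("displacement,expected", [
        (0.30, True), (0.10, False), (0.25, False),  # strictly greater-than
    ])
    def test_internalization_threshold_is_strict(self, displacement, expected):
        positions = [(1.0, 1.0)] * 5 + [(1.0 + displacement, 1.0)] * 5
        ev = _make_event(range(10), [10 * (i + 1) for i in range(10)],
                         range(8), [1.0] * 8, abp_positions=positions)
        m = compute_metrics(ev, internalization_threshold=0.25)
        assert m.max_displacement == pytest.approx(displacement)
        assert m.internalized is expected

    def test_las17_early_when_peak_precedes_abp1_start(self):
        # Las17 peaks at aligned t=-2 s; Abp1 first detected at t=-1 s
        ev = _make_event(
            abp_frames=[9, 10, 11, 12], abp_intensities=[10, 40, 100, 30],
            las_frames=[5, 6, 7, 8, 9], las_intensities=[10, 30, 60, 40, 20])
        m = compute_metrics(ev)
        assert m.las17_early is True
        ev2 = _make_event(
            abp_frames=[5, 6, 7, 8], abp_intensities=[10, 40, 100, 30],
            las_frames=[5, 6, 7, 8, 9], las_intensities=[10, 30, 60, 40, 20])
        assert compute_metrics(ev2).las17_early is False

    def test_short_phase_flagged_with_undefined_rate(self):
        ev = _make_event([0, 1, 2, 3], [10, 100, 50, 20], [0, 1, 2, 3],
                         [1, 2, 1, 1])
        m = compute_metrics(ev)
        assert m.accumulation_rate_abp1 is None
        assert "Abp1:accumulation_undefined" in m.flags


class TestStrainSummary:
    @staticmethod
    def _metric(i, las17_early=False, internalized=True):
        from arpquant.patches import PatchMetrics
        return PatchMetrics(
            event_id=i, max_molecules_las17=140.0, max_molecules_abp1=783.0,
            accumulation_rate_las17=2.0, accumulation_rate_abp1=70.0,
            deaccumulation_rate_las17=-2.0, deaccumulation_rate_abp1=-70.0,
            assembly_time=10.0, max_displacement=0.4 if internalized else 0.1,
            internalized=internalized, las17_early=las17_early)

    def test_las17_early_percentage_from_counts(self):
        metrics = [self._metric(i, las17_early=i < 70) for i in range(195)]
        summary = strain_summary(metrics)
        assert summary["percent_las17_early"] == pytest.approx(35.9, abs=0.05)

    def test_all_internalized_is_100_percent(self):
        positions = [(1.0, 1.0)] * 2 + [(1.5, 1.0)] * 2
        evs = [_make_event(range(4), [10, 100, 50, 20], range(4), [1, 2, 1, 1],
                           abp_positions=positions) for _ in range(5)]
        metrics = [compute_metrics(ev) for ev in evs]
        assert strain_summary(metrics)["percent_internalized"] == 100.0

    def test_single_event_reports_zero_sd_and_n_flag(self):
        ev = _make_event(range(4), [10, 100, 50, 20], range(4), [1, 2, 1, 1])
        summary = strain_summary([compute_metrics(ev)])
        assert summary["n"] == 1
        assert summary["sd_max_molecules_abp1"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            strain_summary([])


class TestKymograph:
    def _event(self, positions):
        spots = [SpotDetection(t=t, x=x, y=y, quality=1.0, raw_intensity=10.0,
                               corrected_intensity=10.0)
                 for t, (x, y) in enumerate(positions)]
        ev = PatchEvent(las17=Trajectory("Las17", list(spots)),
                        abp1=Trajectory("Abp1", list(spots)),
                        frame_interval=1.0)
        return align_events([ev])[0]

    def test_stationary_spot_gives_vertical_band(self):
        stack = _render_movie([[(2.0, 2.0)]] * 8, amp=100.0)
        ev = self._event([(2.0, 2.0)] * 8)
        s, img = kymograph(ev, stack, channel="Abp1", length_um=1.0)
        argmax = s[np.argmax(img, axis=0)]
        np.testing.assert_allclose(argmax, 0.0, atol=PX)

    def test_inward_moving_spot_band_slope(self):
        step = 0.1
        centres = [[(2.0 + step * t, 2.0)] for t in range(8)]
        stack = _render_movie(centres, amp=100.0)
        ev = self._event([c[0] for c in centres])
        s, img = kymograph(ev, stack, channel="Abp1", length_um=1.5)
        argmax = s[np.argmax(img, axis=0)]
        slope = np.polyfit(np.arange(8), argmax, 1)[0]
        assert slope == pytest.approx(step, abs=0.02)

    def test_blank_movie_gives_zero_image(self):
        stack = _render_movie([[]] * 5)
        ev = self._event([(2.0, 2.0)] * 5)
        _s, img = kymograph(ev, stack, channel="Abp1", length_um=1.0)
        assert img.max() == 0.0
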