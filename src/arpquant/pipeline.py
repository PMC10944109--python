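"""End-to-end patch analysis: preprocess, detect, link, curate, pair, align,
calibrate, score. Thin orchestration over the stage modules, driven by a
:class:`~arpquant.config.RunConfig`."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import patches as P
from .config import RunConfig
from .io import ImageStack, Trajectory
from .preprocess import preprocess_stack

__all__ = ["PatchRunResult", "analyze_patch_movie"]


@dataclass
class PatchRunResult:
    """Everything the patch pipeline produces for one movie."""

    corrected: ImageStack
    tracks: dict[str, list[Trajectory]]  # curated, per channel
    events: list[P.PatchEvent]  # aligned (and calibrated when possible)
    unpaired: dict[str, list[Trajectory]]
    metrics: list[P.PatchMetrics]
    summary: dict[str, float] | None

    def metrics_frame(self) -> pd.DataFrame:
        return P.metrics_frame(self.metrics)


def analyze_patch_movie(
    stack: ImageStack,
    config: RunConfig | None = None,
    calibration: P.CalibrationConstants | None = None,
    preprocess: bool = True,
) -> PatchRunResult:
    """Run the full two-channel patch pipeline on one movie.

    When no calibration is given but reference counts are configured, the
    movie is treated as its own control strain: the calibration is computed
    from this movie's events, so the control average maximum intensity maps
    exactly onto the configured reference count.
    """
    cfg = config or RunConfig()
    corrected = stack
    if preprocess:
        corrected, _ = preprocess_stack(
            stack,
            illumination_sigma=cfg.preprocess.illumination_sigma,
            background_radius=cfg.preprocess.background_radius,
            min_bleach_frames=cfg.preprocess.min_bleach_frames,
        )
    link = P.LinkParams(
        max_link_distance=cfg.linking.max_link_distance,
        gap_closing_distance=cfg.linking.gap_closing_distance,
        max_frame_gap=cfg.linking.max_frame_gap,
    )
    tracks: dict[str, list[Trajectory]] = {}
    for ch in corrected.channel_names:
        det_params = P.DetectionParams(
            diameter=cfg.detection.diameter,
            quality_threshold=cfg.detection.quality_threshold,
            median_filter=ch in cfg.detection.median_filter_channels,
        )
        detections = P.detect_spots(corrected, ch, det_params)
        linked = P.link_spots(detections, link, channel=ch)
        tracks[ch] = P.curate_tracks(
            linked, corrected,
            separation_distance=cfg.curation.separation_distance,
            min_length=cfg.curation.min_track_length,
        )
    events, unpaired_l, unpaired_a = P.pair_channels(
        tracks.get("Las17", []), tracks.get("Abp1", []),
        frame_interval=corrected.frame_interval,
        max_distance=cfg.pairing.max_distance,
        max_time_gap=cfg.pairing.max_time_gap,
    )
    events = P.align_events(events)
    if calibration is None and cfg.calibration.reference_counts and events:
        calibration = P.CalibrationConstants.from_control_events(
            events, cfg.calibration.reference_counts)
    metrics: list[P.PatchMetrics] = []
    if calibration is not None:
        events = [P.to_molecules(ev, calibration) for ev in events]
        metrics = [
            P.compute_metrics(
                ev, event_id=i,
                internalization_threshold=cfg.metrics.internalization_threshold)
            for i, ev in enumerate(events)
        ]
    summary = P.strain_summary(metrics) if metrics else None
    return PatchRunResult(
        corrected=corrected,
        tracks=tracks,
        events=events,
        unpaired={"Las17": unpaired_l, "Abp1": unpaired_a},
        metrics=metrics,
        summary=summary,
    )
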