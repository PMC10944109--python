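"""Shared fixtures: synthetic movies and pipeline runs reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from arpquant import beads as B
from arpquant import pipeline, synth
from arpquant.config import RunConfig

PATCH_SEED = 3
BEAD_SEED = 1


@pytest.fixture(scope="session")
def patch_sim():
    """Default-condition two-channel patch movie with its ground truth."""
    params = synth.PatchSimParams(seed=PATCH_SEED)
    stack, truth = synth.generate_patch_movie(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def patch_run(patch_sim):
    """Full pipeline run on the fixture movie, self-calibrated against the
    truth table's mean peak molecule counts (the control-strain role)."""
    params, stack, truth = patch_sim
    cfg = RunConfig()
    cfg.calibration.reference_counts = {
        "Las17": float(truth.las17_peak_molecules.mean()),
        "Abp1": float(truth.peak_molecules.mean()),
    }
    return pipeline.analyze_patch_movie(stack, cfg)


@pytest.fixture(scope="session")
def bead_sim():
    """Default-condition bead movie (two bundle streaks) with ground truth."""
    params = synth.BeadSimParams(seed=BEAD_SEED, bundle_count=2)
    stack, truth = synth.generate_bead_movie(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def bead_track(bead_sim):
    _params, stack, _truth = bead_sim
    return B.track_beads(stack)[0]


def truth_position(spec: synth.PatchSpec, params: synth.PatchSimParams,
                   t: float) -> np.ndarray:
    """Ground-truth Abp1 position of a patch at time ``t`` (matches the
    renderer's inward-motion convention)."""
    h_um = params.shape[0] * params.pixel_size
    w_um = params.shape[1] * params.pixel_size
    inward = np.array([w_um / 2 - spec.x, h_um / 2 - spec.y])
    n = np.linalg.norm(inward)
    inward = inward / n if n > 0 else np.array([0.0, 0.0])
    return spec.position(np.array([t]), inward)[0]


def detection_scores(stack, params: synth.PatchSimParams, channel: str,
                     median_filter: bool, match_radius: float = 0.25,
                     visible_snr: float = 5.0) -> tuple[float, float]:
    """(precision, recall) of spot detection against generator truth.

    Precision counts a detection as true when it lies within
    ``match_radius`` um of any patch that carries signal in that frame.
    Recall is scored over truth spots whose peak-pixel amplitude reaches
    ``visible_snr`` times the read noise (the stated SNR regime); recall is
    NaN when no truth spot qualifies.
    """
    from arpquant.patches import DetectionParams, detect_spots

    specs = synth.sample_patch_specs(params)
    dets = detect_spots(stack, channel, DetectionParams(median_filter=median_filter))
    by_frame: dict[int, list] = {}
    for d in dets:
        by_frame.setdefault(d.t, []).append(d)
    sig_px = params.psf_sigma / params.pixel_size
    tp = fp = visible = found = 0
    for t in range(params.n_frames):
        tt = t * params.frame_interval
        points = []
        for s in specs:
            m = float(s.molecules(np.array([tt]), channel)[0])
            if m <= 0:
                continue
            pos = (truth_position(s, params, tt) if channel == "Abp1"
                   else np.array([s.x, s.y]))
            amp = params.gain * m / (2 * np.pi * sig_px**2)
            points.append((pos, amp))
        for d in by_frame.get(t, []):
            if any(np.linalg.norm(d.position - p) < match_radius
                   for p, _a in points):
                tp += 1
            else:
                fp += 1
        for p, amp in points:
            if amp >= visible_snr * params.read_noise_sd:
                visible += 1
                found += any(np.linalg.norm(d.position - p) < match_radius
                             for d in by_frame.get(t, []))
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = found / visible if visible else float("nan")
    return precision, recall


def match_events_to_truth(result, truth: pd.DataFrame,
                          max_distance: float = 0.3) -> pd.DataFrame:
    """Per-event recovery errors against the generator truth table.

    Events match the nearest truth patch by the first Abp1 position; the
    frame holds relative errors of peak molecules and both rates per
    channel, plus measured/true internalization flags.
    """
    rows = []
    for ev, m in zip(result.events, result.metrics):
        p = ev.abp1.positions[0]
        d = np.hypot(truth.x_um - p[0], truth.y_um - p[1])
        k = int(d.idxmin())
        if d[k] > max_distance:
            continue
        tr = truth.loc[k]
        rows.append({
            "patch_id": int(tr.patch_id),
            "peak_err_abp1": m.max_molecules_abp1 / tr.peak_molecules - 1,
            "peak_err_las17": m.max_molecules_las17 / tr.las17_peak_molecules - 1,
            "acc_err": (np.nan if m.accumulation_rate_abp1 is None
                        else m.accumulation_rate_abp1 / tr.accumulation_rate - 1),
            "deacc_err": (np.nan if m.deaccumulation_rate_abp1 is None
                          else m.deaccumulation_rate_abp1 / tr.deaccumulation_rate - 1),
            "internalized_measured": bool(m.internalized),
            "internalized_true": bool(tr.internalized),
        })
    return pd.DataFrame(rows)
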