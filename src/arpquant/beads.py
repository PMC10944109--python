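"""Bead-motility quantification.

Nucleation-promoting-factor-coated beads propelled by branched actin comet
tails are tracked frame to frame; the metrics mirror the motility-assay
analysis: bead velocity (um/min), the relative surface polymerization rate
(velocity times the actin intensity at the rear bead surface), polar
angular-intensity distributions in an annulus around the bead, and bundle
quantification by peak finding along hand-drawn or synthetic line profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .io import ImageStack

__all__ = [
    "BeadTrack",
    "LineProfileRecord",
    "AngularProfile",
    "BundlePeak",
    "track_beads",
    "tracks_from_csv",
    "filter_beads",
    "bead_velocity",
    "motion_directions",
    "line_profile_analysis",
    "relative_polymerization_rate",
    "angular_intensity",
    "bundle_quantification",
]


@dataclass
class BeadTrack:
    """A bead's positions over contiguous frames, with inclusion status."""

    frames: np.ndarray  # contiguous frame indices
    positions: np.ndarray  # (N, 2) (x, y) um
    diameter_um: float
    frame_interval: float  # s
    included: bool = True
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("bead track frames must be contiguous")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be > 0")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class LineProfileRecord:
    """Leading/trailing edge peaks and central valley of one frame's profile.

    ``None`` fields mean the profile had fewer than two maxima (flagged).
    Distances in um, intensities in a.u.
    """

    frame: int
    leading_intensity: float | None
    trailing_intensity: float | None
    valley_intensity: float | None
    peak_to_peak: float | None
    peak_to_valley: float | None
    flagged: bool = False


@dataclass
class AngularProfile:
    """Polar intensity distribution around the bead, 0 deg = motion direction."""

    bin_edges_deg: np.ndarray  # length n_bins + 1, tiles 360 exactly
    mean: np.ndarray
    sd: np.ndarray
    counts: np.ndarray  # pixels aggregated per bin
    r_in_px: float
    r_out_px: float
    pixel_size: float

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])

    @property
    def r_in_um(self) -> float:
        return self.r_in_px * self.pixel_size

    @property
    def r_out_um(self) -> float:
        return self.r_out_px * self.pixel_size


@dataclass
class BundlePeak:
    """A filament-bundle peak along a 1-D intensity profile."""

    position_um: float
    intensity: float
    prominence: float
    width_um: float

    def __post_init__(self) -> None:
        if self.intensity < self.prominence:
            raise ValueError("peak intensity must be >= its prominence")


# ---------------------------------------------------------------------------
# tracking


def track_beads(
    stack: ImageStack,
    channel: int | str = 0,
    threshold_fraction: float = 0.5,
    min_area_px: int = 9,
) -> list[BeadTrack]:
    """Locate beads per frame and assemble nearest-neighbour tracks.

    Beads are segmented by thresholding each frame at ``threshold_fraction``
    of its above-background dynamic range. The actin shell renders each bead
    as a bright ring whose rear is contaminated by the comet tail, so the
    unweighted centroid of each component is refined iteratively using only
    pixels near the ring radius, which removes the tail bias. The median
    ring-pixel distance gives the bead radius estimate.
    """
    ci = stack.channel_index(channel)
    px = stack.pixel_size
    per_frame: list[list[tuple[np.ndarray, float]]] = []
    for t in range(stack.n_frames):
        img = stack.data[t, ci]
        bg = float(np.median(img))
        thr = bg + threshold_fraction * (float(img.max()) - bg)
        labels, n = ndimage.label(img > thr)
        found = []
        for lab in range(1, n + 1):
            mask = labels == lab
            if int(mask.sum()) < min_area_px:
                continue
            rows, cols = np.nonzero(mask)
            rc, cc = rows.mean(), cols.mean()
            # the shell's dark interior is unaffected by the comet tail, so
            # its centroid locates the bead centre without rearward bias
            hole = ndimage.binary_fill_holes(mask) & ~mask
            if hole.sum() >= 4:
                hr, hc = np.nonzero(hole)
                rc, cc = hr.mean(), hc.mean()
            d = np.hypot(rows - rc, cols - cc)
            r_est = float(np.median(d))
            centre = np.array([cc * px, rc * px])
            found.append((centre, 2.0 * r_est * px))
        per_frame.append(found)
    if not any(per_frame):
        raise ValueError("no beads found in any frame")

    tracks: list[dict] = []
    for t, found in enumerate(per_frame):
        active = [tr for tr in tracks if tr["frames"][-1] == t - 1]
        pairs = []
        for i, tr in enumerate(active):
            for j, (centre, _) in enumerate(found):
                pairs.append((float(np.linalg.norm(tr["pos"][-1] - centre)), i, j))
        used_i: set[int] = set()
        used_j: set[int] = set()
        for dist, i, j in sorted(pairs):
            if i in used_i or j in used_j:
                continue
            centre, diam = found[j]
            active[i]["frames"].append(t)
            active[i]["pos"].append(centre)
            active[i]["diam"].append(diam)
            used_i.add(i)
            used_j.add(j)
        for j, (centre, diam) in enumerate(found):
            if j not in used_j:
                tracks.append({"frames": [t], "pos": [centre], "diam": [diam]})

    return [BeadTrack(
        frames=np.array(tr["frames"]),
        positions=np.array(tr["pos"]),
        diameter_um=float(np.median(tr["diam"])),
        frame_interval=stack.frame_interval,
    ) for tr in tracks]


def tracks_from_csv(
    df: pd.DataFrame,
    frame_interval: float,
    diameter_um: float = 3.0,
) -> list[BeadTrack]:
    """Build bead tracks from an Imaris-style position table.

    Expects columns ``frame``, ``x``, ``y`` (um) and optionally ``track_id``
    and ``diameter``.
    """
    for col in ("frame", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"position table missing column {col!r}")
    out = []
    groups = df.groupby("track_id") if "track_id" in df.columns else [(0, df)]
    for _tid, g in groups:
        g = g.sort_values("frame")
        diam = float(g["diameter"].median()) if "diameter" in g.columns else diameter_um
        out.append(BeadTrack(
            frames=g["frame"].to_numpy(dtype=int),
            positions=g[["x", "y"]].to_numpy(dtype=float),
            diameter_um=diam,
            frame_interval=frame_interval,
        ))
    return out


def filter_beads(
    tracks: list[BeadTrack],
    field_size_um: tuple[float, float],
    max_diameter: float = 3.8,
) -> list[BeadTrack]:
    """Flag beads excluded from analysis.

    Exclusion rules: (a) the track crossed another bead (minimum inter-track
    distance below the sum of the two radii at any common frame), (b) the
    bead diameter exceeds ``max_diameter`` um, (c) the complete trajectory is
    not within the field of view (the bead edge leaves the bounds). Tracks
    are returned with ``included`` flags and reasons, not removed.
    """
    h_um, w_um = field_size_um
    reasons = ["" for _ in tracks]
    for i, a in enumerate(tracks):
        for j in range(i + 1, len(tracks)):
            b = tracks[j]
            common = set(a.frames.tolist()) & set(b.frames.tolist())
            if not common:
                continue
            pa = {f: p for f, p in zip(a.frames, a.positions)}
            pb = {f: p for f, p in zip(b.frames, b.positions)}
            dmin = min(float(np.linalg.norm(pa[f] - pb[f])) for f in common)
            if dmin < (a.diameter_um + b.diameter_um) / 2.0:
                reasons[i] = reasons[i] or "crossed"
                reasons[j] = reasons[j] or "crossed"
    out = []
    for tr, reason in zip(tracks, reasons):
        if not reason and tr.diameter_um > max_diameter:
            reason = "diameter"
        if not reason:
            r = tr.diameter_um / 2.0
            x, y = tr.positions[:, 0], tr.positions[:, 1]
            if (np.any(x < r) or np.any(x > w_um - r)
                    or np.any(y < r) or np.any(y > h_um - r)):
                reason = "field"
        out.append(BeadTrack(
            frames=tr.frames, positions=tr.positions,
            diameter_um=tr.diameter_um, frame_interval=tr.frame_interval,
            included=not reason, exclusion_reason=reason,
        ))
    return out


# ---------------------------------------------------------------------------
# velocity and direction


def bead_velocity(track: BeadTrack, smoothing_window: int = 1) -> np.ndarray:
    """Per-frame speed in um/min by central differences.

    Endpoints use one-sided differences; an optional boxcar of
    ``smoothing_window`` frames smooths the series. Exact on noiseless
    constant-velocity tracks.
    """
    if len(track) < 2:
        raise ValueError("need >= 2 frames for a velocity")
    p = track.positions
    dt = track.frame_interval
    n = len(track)
    v = np.empty(n)
    v[0] = np.linalg.norm(p[1] - p[0]) / dt
    v[-1] = np.linalg.norm(p[-1] - p[-2]) / dt
    if n > 2:
        v[1:-1] = np.linalg.norm(p[2:] - p[:-2], axis=1) / (2 * dt)
    v *= 60.0  # um/s -> um/min
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        v = np.convolve(np.pad(v, smoothing_window // 2, mode="edge"),
                        kernel, mode="valid")[:n]
    return v


def motion_directions(track: BeadTrack, min_speed: float = 0.05) -> np.ndarray:
    """(N, 2) unit motion direction per frame from 3-frame displacements.

    Frames where the local speed falls below ``min_speed`` um/min (or the
    local displacement is degenerate) fall back to the direction of the net
    track displacement.
    """
    p = track.positions
    n = len(track)
    net = p[-1] - p[0]
    net_norm = float(np.linalg.norm(net))
    fallback = net / net_norm if net_norm > 1e-12 else np.array([1.0, 0.0])
    speeds = bead_velocity(track) if n >= 2 else np.zeros(n)
    out = np.empty((n, 2))
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        d = p[hi] - p[lo]
        norm = float(np.linalg.norm(d))
        if norm < 1e-12 or speeds[i] < min_speed:
            out[i] = fallback
        else:
            out[i] = d / norm
    return out


# ---------------------------------------------------------------------------
# line profiles


def _profile_through(
    img: np.ndarray, centre_um: np.ndarray, direction: np.ndarray,
    pixel_size: float, half_length_um: float, step_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    s = np.arange(-half_length_um, half_length_um + step_um / 2, step_um)
    pts = centre_um[None, :] + s[:, None] * direction[None, :]
    rows = pts[:, 1] / pixel_size
    cols = pts[:, 0] / pixel_size
    vals = ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")
    return s, vals


def line_profile_analysis(
    stack: ImageStack,
    track: BeadTrack,
    channel: int | str = 0,
    half_length_factor: float = 2.0,
    min_speed: float = 0.05,
) -> list[LineProfileRecord]:
    """Leading/trailing peak and central-valley analysis of per-frame line
    profiles along the motion axis through the bead centre.

    Positive profile coordinates point in the direction of motion; the
    leading (front) and trailing (rear) local maxima bracketing the central
    local minimum are recorded with their separations. Frames whose profile
    shows fewer than two maxima are flagged.
    """
    ci = stack.channel_index(channel)
    dirs = motion_directions(track, min_speed=min_speed)
    half = half_length_factor * track.diameter_um
    step = stack.pixel_size / 2.0
    records = []
    for k, (frame, centre) in enumerate(zip(track.frames, track.positions)):
        s, vals = _profile_through(stack.data[frame, ci], centre, dirs[k],
                                   stack.pixel_size, half, step)
        peaks, _ = signal.find_peaks(vals)
        front = peaks[s[peaks] > 0]
        rear = peaks[s[peaks] < 0]
        if front.size == 0 or rear.size == 0:
            records.append(LineProfileRecord(
                frame=int(frame), leading_intensity=None, trailing_intensity=None,
                valley_intensity=None, peak_to_peak=None, peak_to_valley=None,
                flagged=True))
            continue
        lead = int(front[np.argmax(vals[front])])
        trail = int(rear[np.argmax(vals[rear])])
        between = vals[trail:lead + 1]
        v_idx = trail + int(np.argmin(between))
        records.append(LineProfileRecord(
            frame=int(frame),
            leading_intensity=float(vals[lead]),
            trailing_intensity=float(vals[trail]),
            valley_intensity=float(vals[v_idx]),
            peak_to_peak=float(s[lead] - s[trail]),
            peak_to_valley=float(s[v_idx] - s[trail]),
        ))
    return records


def relative_polymerization_rate(
    velocities: np.ndarray, profiles: list[LineProfileRecord]
) -> np.ndarray:
    """Velocity times the rear-surface actin intensity, per frame.

    The actin intensity at the bead surface is the trailing-peak local
    maximum, which sits at the rear of the bead. Flagged frames yield NaN.
    """
    velocities = np.asarray(velocities, dtype=float)
    if velocities.size != len(profiles):
        raise ValueError("velocity series and profiles cover different frames")
    trailing = np.array([
        rec.trailing_intensity if rec.trailing_intensity is not None else np.nan
        for rec in profiles])
    return velocities * trailing


# ---------------------------------------------------------------------------
# angular intensity


def angular_intensity(
    stack: ImageStack,
    track: BeadTrack,
    channel: int | str = 0,
    r_in: float = 4.0,
    r_out: float = 15.0,
    bin_deg: float = 30.0,
    frame_range: tuple[int, int] | None = None,
    min_speed: float = 0.05,
) -> AngularProfile:
    """Polar intensity distribution in an annulus around the moving bead.

    Pixels whose centre lies at a distance in [``r_in``, ``r_out``] pixels
    from the bead position are binned by their angle relative to the motion
    direction at that frame (0 deg ahead of the bead, 180 deg behind); bins
    of ``bin_deg`` degrees tile 360 exactly and are centred on 0, 30, ...
    degrees, so the bin at 180 deg straddles the comet tail symmetrically.
    The mean and SD are over all pixels and all frames in ``frame_range``.
    """
    if 360.0 % bin_deg:
        raise ValueError("bin width must divide 360 degrees")
    n_bins = int(round(360.0 / bin_deg))
    edges = np.arange(n_bins + 1) * bin_deg - bin_deg / 2.0
    ci = stack.channel_index(channel)
    px = stack.pixel_size
    H, W = stack.data.shape[2:]
    dirs = motion_directions(track, min_speed=min_speed)
    lo, hi = frame_range if frame_range is not None else (0, len(track))
    values: list[list[float]] = [[] for _ in range(n_bins)]
    for k in range(lo, hi):
        frame = int(track.frames[k])
        cx, cy = track.positions[k] / px  # pixel units
        if (cx - r_out < -0.5 or cx + r_out > W - 0.5
                or cy - r_out < -0.5 or cy + r_out > H - 0.5):
            raise ValueError("annulus extends outside the field")
        r0 = int(np.floor(cy - r_out))
        r1 = int(np.ceil(cy + r_out)) + 1
        c0 = int(np.floor(cx - r_out))
        c1 = int(np.ceil(cx + r_out)) + 1
        rows, cols = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(rows - cy, cols - cx)
        mask = (d >= r_in) & (d <= r_out)
        ux, uy = dirs[k]
        ang = np.degrees(np.arctan2(
            (rows - cy) * ux - (cols - cx) * uy,  # signed transverse
            (cols - cx) * ux + (rows - cy) * uy,  # along motion
        )) % 360.0
        img = stack.data[frame, ci, r0:r1, c0:c1]
        idx = np.round(ang[mask] / bin_deg).astype(int) % n_bins
        for b, v in zip(idx, img[mask]):
            values[b].append(float(v))
    mean = np.array([np.mean(v) if v else np.nan for v in values])
    sd = np.array([np.std(v, ddof=1) if len(v) > 1 else 0.0 for v in values])
    counts = np.array([len(v) for v in values])
    return AngularProfile(bin_edges_deg=edges, mean=mean, sd=sd, counts=counts,
                          r_in_px=r_in, r_out_px=r_out, pixel_size=px)


# ---------------------------------------------------------------------------
# bundle quantification


def bundle_quantification(
    positions_um: np.ndarray,
    intensities: np.ndarray,
    prominence: float | None = None,
    min_distance_um: float = 1.0,
    min_width_px: float | None = None,
    wlen: int | None = None,
) -> tuple[list[BundlePeak], float | None]:
    """Find filament-bundle peaks along a 1-D intensity profile.

    Local maxima must satisfy a prominence criterion (default 3x the
    profile's median absolute deviation), a minimum mutual distance
    (``min_distance_um``) and optionally a minimum width in samples;
    ``wlen`` restricts the window used to evaluate prominence. Returns the
    peaks and the maximum peak intensity (None when no peak passes).
    """
    pos = np.asarray(positions_um, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if pos.size == 0:
        raise ValueError("empty profile")
    if pos.size != y.size:
        raise ValueError("positions and intensities differ in length")
    step = float(np.median(np.diff(pos))) if pos.size > 1 else 1.0
    if prominence is None:
        mad = float(np.median(np.abs(y - np.median(y))))
        prominence = 3.0 * 1.4826 * mad
        if prominence <= 0:
            prominence = 3.0 * (y.std() + 1e-12)
    distance = max(int(round(min_distance_um / step)), 1)
    kwargs: dict = {"prominence": prominence, "distance": distance}
    if min_width_px is not None:
        kwargs["width"] = min_width_px
    if wlen is not None:
        kwargs["wlen"] = wlen
    idx, props = signal.find_peaks(y, **kwargs)
    widths_samples = props.get("widths")
    if widths_samples is None and idx.size:
        widths_samples = signal.peak_widths(y, idx, rel_height=0.5)[0]
    peaks = [BundlePeak(
        position_um=float(pos[i]),
        intensity=float(y[i]),
        prominence=float(p),
        width_um=float(w * step),
    ) for i, p, w in zip(idx, props["prominences"],
                         widths_samples if idx.size else [])]
    max_intensity = max((p.intensity for p in peaks), default=None)
    return peaks, max_intensity
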