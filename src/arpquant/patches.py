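"""Endocytic patch quantification.

The stage order mirrors the live-cell analysis workflow: Laplacian-of-
Gaussian spot detection per channel, greedy nearest-neighbour linking with
gap closing, curation (complete lifetime, well-separated, optional cortex
ROI), Las17/Abp1 channel pairing, alignment of every event to the Abp1
intensity maximum (t = 0), conversion of corrected fluorescence to molecule
counts against a control-strain calibration, and per-event metrics:
maximum molecules, accumulation/deaccumulation rates (straight-line slopes),
Abp1 assembly time, maximum displacement from origin, internalization
(strictly more than 0.25 um travelled) and whether Las17 began to
deaccumulate before actin assembly was detected ("Las17-early").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ImageStack, SpotDetection, Trajectory
from .preprocess import robust_noise_sd

__all__ = [
    "DetectionParams",
    "LinkParams",
    "CalibrationConstants",
    "PatchEvent",
    "PatchMetrics",
    "detect_spots",
    "link_spots",
    "trajectories_from_csv",
    "curate_tracks",
    "pair_channels",
    "align_events",
    "average_aligned",
    "to_molecules",
    "compute_metrics",
    "metrics_frame",
    "strain_summary",
    "kymograph",
]


@dataclass
class DetectionParams:
    """Spot-detector settings (blob diameter in um; detector-normalised
    quality threshold; optional 3x3 median prefilter)."""

    diameter: float = 0.5
    quality_threshold: float = 5.0
    median_filter: bool = False

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")


@dataclass
class LinkParams:
    """Frame-to-frame linking and gap-closing settings."""

    max_link_distance: float = 0.5  # um
    gap_closing_distance: float = 0.5  # um
    max_frame_gap: int = 2

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0 or self.gap_closing_distance <= 0:
            raise ValueError("link distances must be > 0")
        if self.max_frame_gap < 0:
            raise ValueError("max_frame_gap must be >= 0")


@dataclass
class CalibrationConstants:
    """Fluorescence-to-molecules calibration.

    ``reference_counts`` are literature average maximum molecule numbers per
    channel; ``control_max_intensity`` is the average maximum corrected
    fluorescence of the control strain measured with the same pipeline
    settings. The conversion factor per channel is their ratio.
    """

    reference_counts: dict[str, float]
    control_max_intensity: dict[str, float]

    def __post_init__(self) -> None:
        for d in (self.reference_counts, self.control_max_intensity):
            if any(v <= 0 for v in d.values()):
                raise ValueError("calibration constants must be > 0")

    def factor(self, channel: str) -> float:
        try:
            return (self.reference_counts[channel]
                    / self.control_max_intensity[channel])
        except KeyError:
            raise KeyError(f"no calibration for channel {channel!r}") from None

    @classmethod
    def from_control_events(
        cls, events: list["PatchEvent"], reference_counts: dict[str, float]
    ) -> "CalibrationConstants":
        """Average maximum corrected intensity per channel over control events."""
        if not events:
            raise ValueError("need at least one control event")
        maxima: dict[str, list[float]] = {ch: [] for ch in reference_counts}
        for ev in events:
            for ch in reference_counts:
                maxima[ch].append(float(ev.trajectory(ch).intensities.max()))
        return cls(
            reference_counts=dict(reference_counts),
            control_max_intensity={ch: float(np.mean(v)) for ch, v in maxima.items()},
        )


@dataclass
class PatchEvent:
    """A paired Las17/Abp1 endocytic event.

    After :func:`align_events`, ``t0_frame`` holds the frame of the Abp1
    corrected-intensity maximum and aligned times are
    (frame - t0_frame) * frame_interval. ``molecules`` holds per-channel
    molecule counts once calibrated.
    """

    las17: Trajectory
    abp1: Trajectory
    frame_interval: float
    t0_frame: int | None = None
    molecules: dict[str, np.ndarray] = field(default_factory=dict)

    def trajectory(self, channel: str) -> Trajectory:
        if channel == "Las17":
            return self.las17
        if channel == "Abp1":
            return self.abp1
        raise KeyError(f"unknown channel {channel!r}")

    def times(self, channel: str) -> np.ndarray:
        """Aligned times (s) of the channel's detections; t=0 at Abp1 max."""
        if self.t0_frame is None:
            raise RuntimeError("event is not aligned; run align_events first")
        return (self.trajectory(channel).frames - self.t0_frame) * self.frame_interval


@dataclass
class PatchMetrics:
    """Per-event scalar metrics (molecule counts, rates, displacement, flags)."""

    event_id: int
    max_molecules_las17: float
    max_molecules_abp1: float
    accumulation_rate_las17: float | None
    accumulation_rate_abp1: float | None
    deaccumulation_rate_las17: float | None
    deaccumulation_rate_abp1: float | None
    assembly_time: float
    max_displacement: float
    internalized: bool
    las17_early: bool
    flags: str = ""

    def __post_init__(self) -> None:
        if self.assembly_time < 0:
            raise ValueError("assembly_time must be >= 0")
        if self.max_displacement < 0:
            raise ValueError("max_displacement must be >= 0")


# ---------------------------------------------------------------------------
# detection


def _log_kernel_norm(sigma_px: float) -> float:
    """L2 norm of the scale-normalised LoG filter (impulse response)."""
    half = int(np.ceil(6 * sigma_px)) + 1
    impulse = np.zeros((2 * half + 1, 2 * half + 1))
    impulse[half, half] = 1.0
    kernel = -(sigma_px**2) * ndimage.gaussian_laplace(impulse, sigma_px)
    return float(np.sqrt((kernel**2).sum()))


def _spot_intensities(
    img: np.ndarray, row: float, col: float, radius_px: float
) -> tuple[float, float]:
    """(raw, background-corrected) pixel sums within ``radius_px``.

    The local background is the median of an annulus between 1x and 2x the
    spot radius, subtracted per pixel.
    """
    r0 = max(int(np.floor(row - 2 * radius_px)), 0)
    r1 = min(int(np.ceil(row + 2 * radius_px)) + 1, img.shape[0])
    c0 = max(int(np.floor(col - 2 * radius_px)), 0)
    c1 = min(int(np.ceil(col + 2 * radius_px)) + 1, img.shape[1])
    sub = img[r0:r1, c0:c1]
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - row, cc - col)
    disk = d <= radius_px
    annulus = (d > radius_px) & (d <= 2 * radius_px)
    raw = float(sub[disk].sum())
    bg = float(np.median(sub[annulus])) if annulus.any() else 0.0
    corrected = float((sub[disk] - bg).sum())
    return raw, corrected


def detect_spots(
    stack: ImageStack,
    channel: int | str,
    params: DetectionParams | None = None,
) -> list[SpotDetection]:
    """Laplacian-of-Gaussian blob detection in one channel of a preprocessed
    stack.

    The LoG scale is sigma = diameter / (2*sqrt(2)). The quality score of a
    candidate is its scale-normalised LoG response divided by the expected
    response noise -- the robust pixel noise sd of the (unfiltered) image
    times the L2 norm of the LoG kernel -- so quality 5 means five noise
    standard deviations regardless of any prefilter; candidates below
    ``quality_threshold`` are discarded, as are maxima within one spot
    radius of the image border (boundary artifacts of the filter). Positions
    are refined to sub-pixel precision by an intensity-weighted centroid
    within the spot radius and reported in micrometres.
    ``corrected_intensity`` is the background-subtracted pixel sum within
    the radius.
    """
    params = params or DetectionParams()
    ci = stack.channel_index(channel)
    px = stack.pixel_size
    sigma_px = params.diameter / (2.0 * np.sqrt(2.0)) / px
    radius_px = (params.diameter / 2.0) / px
    kernel_norm = _log_kernel_norm(sigma_px)
    detections: list[SpotDetection] = []
    for t in range(stack.n_frames):
        raw = stack.data[t, ci]
        img = ndimage.median_filter(raw, size=3, mode="nearest") \
            if params.median_filter else raw
        # scale-normalised negative LoG: bright blobs become positive peaks
        response = -(sigma_px**2) * ndimage.gaussian_laplace(img, sigma_px,
                                                             mode="nearest")
        noise = max(robust_noise_sd(raw) * kernel_norm, 1e-12)
        # local maxima of the response
        footprint = np.ones((3, 3), dtype=bool)
        maxima = (response == ndimage.maximum_filter(
            response, footprint=footprint, mode="nearest")) & (response > 0)
        rows, cols = np.nonzero(maxima)
        border = int(np.ceil(radius_px))
        inside = ((rows >= border) & (rows < img.shape[0] - border)
                  & (cols >= border) & (cols < img.shape[1] - border))
        rows, cols = rows[inside], cols[inside]
        qualities = response[rows, cols] / noise
        keep = qualities >= params.quality_threshold
        for r, c, q in zip(rows[keep], cols[keep], qualities[keep]):
            # sub-pixel refinement: weighted centroid of above-background
            # pixels within the spot radius
            r0 = max(int(r - np.ceil(radius_px)), 0)
            r1 = min(int(r + np.ceil(radius_px)) + 1, img.shape[0])
            c0 = max(int(c - np.ceil(radius_px)), 0)
            c1 = min(int(c + np.ceil(radius_px)) + 1, img.shape[1])
            sub = img[r0:r1, c0:c1]
            w = np.clip(sub - sub.min(), 0.0, None)
            if w.sum() > 0:
                rr, cc = np.mgrid[r0:r1, c0:c1]
                row_c = float((w * rr).sum() / w.sum())
                col_c = float((w * cc).sum() / w.sum())
            else:
                row_c, col_c = float(r), float(c)
            raw, corrected = _spot_intensities(img, row_c, col_c, radius_px)
            detections.append(SpotDetection(
                t=t, x=col_c * px, y=row_c * px, quality=float(q),
                raw_intensity=raw, corrected_intensity=corrected,
            ))
    return detections


# ---------------------------------------------------------------------------
# linking


def link_spots(
    detections: list[SpotDetection],
    params: LinkParams | None = None,
    channel: str = "",
) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking with gap closing.

    Candidate links within ``max_link_distance`` are assigned in order of
    increasing distance; leftover detections start new tracks. Track ends
    are then joined to later track starts across at most ``max_frame_gap``
    missing frames when within ``gap_closing_distance``, again greedily by
    distance.
    """
    params = params or LinkParams()
    by_frame: dict[int, list[SpotDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.t, []).append(d)

    tracks: list[list[SpotDetection]] = []
    for f in sorted(by_frame):
        spots = by_frame[f]
        active = [tr for tr in tracks if tr[-1].t == f - 1]
        pairs = []
        for i, tr in enumerate(active):
            p = tr[-1].position
            for j, s in enumerate(spots):
                dist = float(np.linalg.norm(p - s.position))
                if dist <= params.max_link_distance:
                    pairs.append((dist, i, j))
        used_tr: set[int] = set()
        used_sp: set[int] = set()
        for dist, i, j in sorted(pairs):
            if i in used_tr or j in used_sp:
                continue
            active[i].append(spots[j])
            used_tr.add(i)
            used_sp.add(j)
        for j, s in enumerate(spots):
            if j not in used_sp:
                tracks.append([s])

    # gap closing: one forward join per track end, one backward per start
    if params.max_frame_gap > 0:
        joins = []
        for a, ta in enumerate(tracks):
            for b, tb in enumerate(tracks):
                if a == b:
                    continue
                dframe = tb[0].t - ta[-1].t
                if 2 <= dframe <= params.max_frame_gap + 1:
                    dist = float(np.linalg.norm(ta[-1].position - tb[0].position))
                    if dist <= params.gap_closing_distance:
                        joins.append((dist, a, b))
        next_of: dict[int, int] = {}
        has_prev: set[int] = set()
        for dist, a, b in sorted(joins):
            if a in next_of or b in has_prev:
                continue
            next_of[a] = b
            has_prev.add(b)
        merged: list[list[SpotDetection]] = []
        heads = [i for i in range(len(tracks)) if i not in has_prev]
        for h in heads:
            chain = list(tracks[h])
            i = h
            while i in next_of:
                i = next_of[i]
                chain.extend(tracks[i])
            merged.append(chain)
        tracks = merged

    return [Trajectory(channel=channel, spots=tr, id=i)
            for i, tr in enumerate(sorted(tracks, key=lambda tr: (tr[0].t, tr[0].x)))]


def trajectories_from_csv(df: pd.DataFrame, channel: str = "") -> list[Trajectory]:
    """Build trajectories from a TrackMate-style spot export.

    Expects the standard columns ``TRACK_ID``, ``FRAME``, ``POSITION_X``,
    ``POSITION_Y`` (positions in um) and uses ``TOTAL_INTENSITY`` /
    ``QUALITY`` when present, so curated exports from external trackers can
    feed the same pairing/alignment/metrics stages as in-package tracking.
    """
    required = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing column(s) {missing}")
    out = []
    for tid, g in df.groupby("TRACK_ID"):
        g = g.sort_values("FRAME")
        spots = [SpotDetection(
            t=int(row.FRAME), x=float(row.POSITION_X), y=float(row.POSITION_Y),
            quality=float(getattr(row, "QUALITY", 0.0) or 0.0),
            raw_intensity=float(getattr(row, "TOTAL_INTENSITY", 0.0) or 0.0),
            corrected_intensity=float(getattr(row, "TOTAL_INTENSITY", 0.0) or 0.0),
        ) for row in g.itertuples()]
        out.append(Trajectory(channel=channel, spots=spots, id=int(tid)))
    return out


# ---------------------------------------------------------------------------
# curation


def curate_tracks(
    tracks: list[Trajectory],
    stack: ImageStack,
    roi: np.ndarray | None = None,
    separation_distance: float = 0.5,
    min_length: int = 3,
) -> list[Trajectory]:
    """Apply the three curation criteria to linked tracks.

    1. The entire lifetime must be recorded: tracks touching the first or
       last frame of the movie are dropped.
    2. The patch must be well separated: any two tracks that come within
       ``separation_distance`` (um) of each other while concurrent are both
       dropped.
    3. If a cortex ROI mask (Y, X boolean, pixel grid) is given, only tracks
       whose first position lies inside it are kept.
    """
    last_frame = stack.n_frames - 1
    candidates = [tr for tr in tracks
                  if tr.start > 0 and tr.end < last_frame and len(tr) >= min_length]

    crowded: set[int] = set()
    for i, a in enumerate(candidates):
        pa = {s.t: s.position for s in a.spots}
        for j in range(i + 1, len(candidates)):
            b = candidates[j]
            common = pa.keys() & {s.t for s in b.spots}
            if not common:
                continue
            pb = {s.t: s.position for s in b.spots}
            dmin = min(float(np.linalg.norm(pa[f] - pb[f])) for f in common)
            if dmin < separation_distance:
                crowded.add(i)
                crowded.add(j)
    candidates = [tr for k, tr in enumerate(candidates) if k not in crowded]

    if roi is not None:
        kept = []
        for tr in candidates:
            col = int(round(tr.spots[0].x / stack.pixel_size))
            row = int(round(tr.spots[0].y / stack.pixel_size))
            if (0 <= row < roi.shape[0] and 0 <= col < roi.shape[1]
                    and bool(roi[row, col])):
                kept.append(tr)
        candidates = kept
    return candidates


# ---------------------------------------------------------------------------
# pairing and alignment


def pair_channels(
    las17_tracks: list[Trajectory],
    abp1_tracks: list[Trajectory],
    frame_interval: float,
    max_distance: float = 0.5,
    max_time_gap: float = 10.0,
) -> tuple[list[PatchEvent], list[Trajectory], list[Trajectory]]:
    """One-to-one pairing of Las17 and Abp1 tracks into events.

    Tracks pair when their time-averaged positions are within
    ``max_distance`` (um) and their lifetimes overlap or abut within
    ``max_time_gap`` (s); assignment is greedy by increasing distance.
    Returns (events, unpaired Las17, unpaired Abp1).
    """
    pairs = []
    for i, la in enumerate(las17_tracks):
        pa = la.mean_position()
        for j, ab in enumerate(abp1_tracks):
            dist = float(np.linalg.norm(pa - ab.mean_position()))
            if dist > max_distance:
                continue
            gap_frames = max(la.start, ab.start) - min(la.end, ab.end)
            if gap_frames * frame_interval > max_time_gap:
                continue
            pairs.append((dist, i, j))
    used_l: set[int] = set()
    used_a: set[int] = set()
    events = []
    for dist, i, j in sorted(pairs):
        if i in used_l or j in used_a:
            continue
        events.append(PatchEvent(las17=las17_tracks[i], abp1=abp1_tracks[j],
                                 frame_interval=frame_interval))
        used_l.add(i)
        used_a.add(j)
    unpaired_l = [tr for i, tr in enumerate(las17_tracks) if i not in used_l]
    unpaired_a = [tr for j, tr in enumerate(abp1_tracks) if j not in used_a]
    return events, unpaired_l, unpaired_a


def align_events(events: list[PatchEvent]) -> list[PatchEvent]:
    """Set t = 0 at the Abp1 corrected-intensity maximum of every event.

    Ties resolve to the earliest maximal frame. An all-zero Abp1 trace is an
    error.
    """
    out = []
    for ev in events:
        intens = ev.abp1.intensities
        if np.all(intens <= 0):
            raise ValueError("Abp1 intensity trace is all zero; cannot align")
        t0 = int(ev.abp1.frames[int(np.argmax(intens))])
        out.append(dataclasses.replace(ev, t0_frame=t0))
    return out


def average_aligned(
    events: list[PatchEvent], channel: str, use_molecules: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Average molecule (or intensity) traces over events on the aligned axis.

    Returns (times, mean) where times are aligned seconds and the mean at
    each time is over the events detected at that offset.
    """
    if not events:
        raise ValueError("no events to average")
    acc: dict[float, list[float]] = {}
    for ev in events:
        tr = ev.trajectory(channel)
        values = (ev.molecules[channel] if use_molecules and channel in ev.molecules
                  else tr.intensities)
        for t, v in zip(ev.times(channel), values):
            acc.setdefault(round(float(t), 9), []).append(float(v))
    times = np.array(sorted(acc))
    means = np.array([np.mean(acc[t]) for t in times])
    return times, means


# ---------------------------------------------------------------------------
# calibration and metrics


def to_molecules(event: PatchEvent, calib: CalibrationConstants) -> PatchEvent:
    """Convert corrected intensities to molecule counts per channel.

    molecules(t) = corrected intensity(t) * reference count / control-strain
    average maximum corrected intensity, per channel.
    """
    molecules = {}
    for ch in ("Las17", "Abp1"):
        molecules[ch] = event.trajectory(ch).intensities * calib.factor(ch)
    return dataclasses.replace(event, molecules=molecules)


def _phase_slope(t: np.ndarray, y: np.ndarray) -> float | None:
    """Least-squares slope, or None when the phase has fewer than 3 points."""
    if t.size < 3:
        return None
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0:
        return None
    return float(tc @ (y - y.mean()) / denom)


def compute_metrics(
    event: PatchEvent,
    event_id: int = 0,
    internalization_threshold: float = 0.25,
) -> PatchMetrics:
    """Score one aligned, calibrated event.

    Accumulation rate is the least-squares slope of molecules versus time
    from first appearance through the maximum; deaccumulation rate from the
    maximum through the last measurable frame (ties at the maximum resolve
    to the earliest frame; a phase with fewer than 3 points leaves the rate
    undefined and flagged). Assembly time is t(Abp1 max) - t(Abp1 first).
    Maximum displacement is measured on the Abp1 track from its first
    detected position; an event internalizes when it exceeds the threshold
    strictly. Las17-early means the Las17 molecule maximum precedes the
    first detectable Abp1 frame.
    """
    if event.t0_frame is None:
        raise RuntimeError("event must be aligned before computing metrics")
    if not event.molecules:
        raise RuntimeError("event must be calibrated before computing metrics")
    flags: list[str] = []
    rates: dict[str, tuple[float | None, float | None, float]] = {}
    peak_times: dict[str, float] = {}
    for ch in ("Las17", "Abp1"):
        t = event.times(ch)
        m = event.molecules[ch]
        imax = int(np.argmax(m))  # earliest tie
        acc = _phase_slope(t[: imax + 1], m[: imax + 1])
        deacc = _phase_slope(t[imax:], m[imax:])
        if acc is None:
            flags.append(f"{ch}:accumulation_undefined")
        if deacc is None:
            flags.append(f"{ch}:deaccumulation_undefined")
        rates[ch] = (acc, deacc, float(m[imax]))
        peak_times[ch] = float(t[imax])

    t_abp1 = event.times("Abp1")
    assembly_time = peak_times["Abp1"] - float(t_abp1[0])
    pos = event.abp1.positions
    max_disp = float(np.max(np.linalg.norm(pos - pos[0], axis=1)))
    las17_early = peak_times["Las17"] < float(t_abp1[0])

    return PatchMetrics(
        event_id=event_id,
        max_molecules_las17=rates["Las17"][2],
        max_molecules_abp1=rates["Abp1"][2],
        accumulation_rate_las17=rates["Las17"][0],
        accumulation_rate_abp1=rates["Abp1"][0],
        deaccumulation_rate_las17=rates["Las17"][1],
        deaccumulation_rate_abp1=rates["Abp1"][1],
        assembly_time=assembly_time,
        max_displacement=max_disp,
        internalized=max_disp > internalization_threshold,
        las17_early=las17_early,
        flags=";".join(flags),
    )


def metrics_frame(metrics: list[PatchMetrics]) -> pd.DataFrame:
    """Flatten a list of :class:`PatchMetrics` into a DataFrame."""
    return pd.DataFrame([dataclasses.asdict(m) for m in metrics])


_SUMMARY_COLUMNS = [
    "max_molecules_las17", "max_molecules_abp1",
    "accumulation_rate_las17", "accumulation_rate_abp1",
    "deaccumulation_rate_las17", "deaccumulation_rate_abp1",
    "assembly_time", "max_displacement",
]


def strain_summary(metrics: list[PatchMetrics] | pd.DataFrame) -> dict[str, float]:
    """Per-strain aggregation: means and SDs of every scalar metric, percent
    internalized and percent Las17-early over scored events.

    SDs are sample standard deviations; with a single event the SD is
    reported as 0 and flagged via ``n = 1``.
    """
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    if df.empty:
        raise ValueError("no events to summarise")
    out: dict[str, float] = {"n": int(len(df))}
    for col in _SUMMARY_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        out[f"mean_{col}"] = float(vals.mean()) if len(vals) else float("nan")
        out[f"sd_{col}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    out["percent_internalized"] = float(100.0 * df["internalized"].mean())
    out["percent_las17_early"] = float(100.0 * df["las17_early"].mean())
    return out


# ---------------------------------------------------------------------------
# kymograph


def kymograph(
    event: PatchEvent,
    stack: ImageStack,
    channel: str = "Abp1",
    length_um: float = 2.0,
    back_um: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance x time intensity image along the inward axis of an event.

    The axis runs through the event origin along the direction of net Abp1
    displacement (toward the field centre when the event is stationary),
    sampled from ``-back_um`` to ``+length_um`` at pixel resolution every
    frame. Returns (distances_um, image) with image shaped
    (n_samples, n_frames).
    """
    pos = event.abp1.positions
    origin = pos[0]
    disp = pos[-1] - pos[0]
    norm = float(np.linalg.norm(disp))
    if norm > 1e-9:
        direction = disp / norm
    else:
        h_um, w_um = stack.field_size_um
        to_centre = np.array([w_um / 2, h_um / 2]) - origin
        n = float(np.linalg.norm(to_centre))
        direction = to_centre / n if n > 0 else np.array([1.0, 0.0])
    px = stack.pixel_size
    s = np.arange(-back_um, length_um + px / 2, px)
    points = origin[None, :] + s[:, None] * direction[None, :]
    cols = points[:, 0] / px
    rows = points[:, 1] / px
    H, W = stack.data.shape[2:]
    if (rows.min() < -0.5 or rows.max() > H - 0.5
            or cols.min() < -0.5 or cols.max() > W - 0.5):
        raise ValueError("kymograph axis extends outside the field")
    ci = stack.channel_index(channel)
    img = np.empty((s.size, stack.n_frames))
    for t in range(stack.n_frames):
        img[:, t] = ndimage.map_coordinates(
            stack.data[t, ci], [rows, cols], order=1, mode="nearest")
    return s, img
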