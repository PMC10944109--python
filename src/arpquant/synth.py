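"""Ground-truth generators for every data class the pipeline consumes.

Four generators emulate the four experimental readouts:

* :func:`generate_patch_movie` -- two-channel live-cell movies of cortical
  endocytic patches. Each patch is a Gaussian spot whose integrated
  intensity follows piecewise-linear accumulate -> peak -> deaccumulate
  kinetics (molecule counts times a camera gain); the Las17 channel leads
  the Abp1 (actin) channel, internalized patches translate inward during
  deaccumulation, and global photobleaching, a static illumination gradient,
  camera offset and Gaussian read noise are applied on top.
* :func:`generate_bead_movie` -- a nucleation-promoting-factor-coated bead
  translating at constant speed, rendered as a bright surface ring (the
  actin shell) with an exponentially decaying comet tail behind it and
  optional discrete bundle streaks running parallel to the trajectory.
* :func:`generate_pyrene_trace` -- logistic polymer growth
  P(t) = P_total / (1 + exp(-r (t - t_half))) mapped to fluorescence between
  a baseline and a plateau. The analytic maximum slope r * P_total / 4 makes
  the trace an exact oracle for maximum-polymerization-rate extraction.
* :func:`generate_depletion_data` -- fraction-bound titrations drawn from
  the tight-binding quadratic with multiplicative Gaussian noise.

Piecewise-linear patch kinetics are chosen deliberately: the analysis
measures accumulation and deaccumulation rates as straight-line slopes, so
generator and analyzer share an exact expectation and every stage becomes a
recovery test. All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .biochem import BindingMeasurement, PolymerizationTrace, quadratic_fraction
from .io import ImageStack

__all__ = [
    "PatchSpec",
    "PatchSimParams",
    "BeadSimParams",
    "BeadTruth",
    "PyreneSimParams",
    "DepletionSimParams",
    "sample_patch_specs",
    "generate_patch_movie",
    "generate_bead_movie",
    "generate_pyrene_trace",
    "generate_depletion_data",
]


# ---------------------------------------------------------------------------
# patches


@dataclass
class PatchSpec:
    """Ground-truth parameters of a single endocytic patch."""

    x: float  # origin, um
    y: float
    t_appear: float  # Abp1 first appearance, s
    acc_duration: float  # s
    deacc_duration: float  # s
    peak_molecules: float  # Abp1
    las17_peak_molecules: float
    las17_lead: float  # s by which Las17 appearance precedes Abp1
    las17_acc_duration: float
    las17_deacc_duration: float
    internalized: bool
    inward_displacement: float  # um, applied to Abp1 during deaccumulation

    def __post_init__(self) -> None:
        for name in ("acc_duration", "deacc_duration", "las17_acc_duration",
                     "las17_deacc_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.peak_molecules <= 0 or self.las17_peak_molecules <= 0:
            raise ValueError("peak molecule counts must be > 0")

    @property
    def las17_early(self) -> bool:
        """Las17 peaks (starts deaccumulating) before Abp1 appears."""
        las17_peak_time = self.t_appear - self.las17_lead + self.las17_acc_duration
        return las17_peak_time < self.t_appear

    def molecules(self, t: np.ndarray, channel: str) -> np.ndarray:
        """Piecewise-linear molecule count of this patch at times ``t`` (s)."""
        if channel == "Abp1":
            t0, acc, deacc, peak = (self.t_appear, self.acc_duration,
                                    self.deacc_duration, self.peak_molecules)
        elif channel == "Las17":
            t0 = self.t_appear - self.las17_lead
            acc, deacc, peak = (self.las17_acc_duration,
                                self.las17_deacc_duration,
                                self.las17_peak_molecules)
        else:
            raise KeyError(f"unknown channel {channel!r}")
        t = np.asarray(t, dtype=float)
        up = peak * (t - t0) / acc
        down = peak * (1.0 - (t - t0 - acc) / deacc)
        m = np.where(t < t0 + acc, up, down)
        return np.clip(m, 0.0, peak)

    def position(self, t: np.ndarray, inward: np.ndarray) -> np.ndarray:
        """(N, 2) Abp1 position at times ``t``: the origin, translating along
        ``inward`` by ``inward_displacement`` during deaccumulation.

        The motion completes within the first half of the deaccumulation
        phase (scission and vesicle departure precede full disassembly), so
        the displacement is attained while the patch is still bright.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        t_peak = self.t_appear + self.acc_duration
        frac = np.clip((t - t_peak) / (0.5 * self.deacc_duration), 0.0, 1.0)
        base = np.array([self.x, self.y])
        return base[None, :] + frac[:, None] * self.inward_displacement * inward[None, :]


@dataclass
class PatchSimParams:
    """Study conditions for synthetic two-channel patch movies.

    Defaults emulate a 75 s widefield acquisition at 1 s intervals with
    0.065 um pixels: ~800 peak Abp1 molecules (as in control strains),
    ~10 s accumulation and deaccumulation phases, Las17 leading Abp1 by
    8-15 s, and 97% of events internalizing by 0.3-0.5 um.
    """

    n_patches: int = 20
    n_frames: int = 75
    shape: tuple[int, int] = (160, 160)  # rows, cols (pixels)
    pixel_size: float = 0.065
    frame_interval: float = 1.0
    # per-patch sampling ranges (uniform)
    acc_duration: tuple[float, float] = (8.0, 12.0)
    deacc_duration: tuple[float, float] = (8.0, 12.0)
    peak_molecules: tuple[float, float] = (600.0, 1000.0)
    las17_peak_molecules: tuple[float, float] = (100.0, 200.0)
    las17_lead: tuple[float, float] = (8.0, 15.0)
    internalized_fraction: float = 0.97
    internalized_displacement: tuple[float, float] = (0.3, 0.5)
    failed_displacement: tuple[float, float] = (0.0, 0.1)
    # rendering
    psf_sigma: float = 0.1  # um
    camera_offset: float = 100.0
    # gain puts the dimmer Las17 channel at peak-pixel SNR ~ 5, matching
    # acquisitions where both channels are trackable
    gain: float = 4.0  # a.u. per molecule
    read_noise_sd: float = 8.0
    bleach_rate: float = 0.002  # 1/s, mild global photobleaching
    illumination_amplitude: float = 0.1  # fractional linear gradient along x
    cytosol_background: float = 30.0  # a.u., bleached and shaded like signal
    min_separation: float = 1.5  # um between patch origins
    margin: float = 1.0  # um from field edges
    patches: list[PatchSpec] | None = None  # explicit override
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma < self.pixel_size:
            raise ValueError("psf_sigma must be >= one pixel")
        if not 0 <= self.internalized_fraction <= 1:
            raise ValueError("internalized_fraction must lie in [0, 1]")


def sample_patch_specs(
    params: PatchSimParams, rng: np.random.Generator | None = None
) -> list[PatchSpec]:
    """Draw the per-patch ground-truth specs for ``params`` (seed-determined).

    Returns ``params.patches`` unchanged when given explicitly.
    """
    if params.patches is not None:
        return list(params.patches)
    p = params
    if rng is None:
        rng = np.random.default_rng(p.seed)
    h_um = p.shape[0] * p.pixel_size
    w_um = p.shape[1] * p.pixel_size
    total_t = p.n_frames * p.frame_interval
    specs: list[PatchSpec] = []
    positions: list[np.ndarray] = []
    attempts = 0
    while len(specs) < p.n_patches:
        attempts += 1
        if attempts > 2000 * max(p.n_patches, 1):
            raise RuntimeError(
                "could not place patches with the requested separation/margin"
            )
        pos = np.array([
            rng.uniform(p.margin, w_um - p.margin),
            rng.uniform(p.margin, h_um - p.margin),
        ])
        if any(np.linalg.norm(pos - q) < p.min_separation for q in positions):
            continue
        acc = rng.uniform(*p.acc_duration)
        deacc = rng.uniform(*p.deacc_duration)
        lead = rng.uniform(*p.las17_lead)
        lifetime = lead + acc + deacc + 2.0
        if total_t <= lifetime + 4.0:
            raise ValueError("movie too short for the requested patch lifetimes")
        t_appear = rng.uniform(lead + 2.0, total_t - acc - deacc - 2.0)
        internal = bool(rng.uniform() < p.internalized_fraction)
        disp = rng.uniform(*(p.internalized_displacement if internal
                             else p.failed_displacement))
        specs.append(PatchSpec(
            x=float(pos[0]), y=float(pos[1]), t_appear=float(t_appear),
            acc_duration=float(acc), deacc_duration=float(deacc),
            peak_molecules=float(rng.uniform(*p.peak_molecules)),
            las17_peak_molecules=float(rng.uniform(*p.las17_peak_molecules)),
            las17_lead=float(lead),
            las17_acc_duration=float(rng.uniform(*p.acc_duration)),
            las17_deacc_duration=float(rng.uniform(*p.deacc_duration)),
            internalized=internal, inward_displacement=float(disp),
        ))
        positions.append(pos)
    return specs


def _render_gaussian(frame: np.ndarray, x_um: float, y_um: float,
                     integral: float, sigma_um: float, pixel_size: float) -> None:
    """Add a 2-D Gaussian of given integrated intensity to ``frame`` in place."""
    if integral <= 0:
        return
    sig = sigma_um / pixel_size
    cx = x_um / pixel_size
    cy = y_um / pixel_size
    half = int(np.ceil(4 * sig))
    r0 = max(int(np.floor(cy)) - half, 0)
    r1 = min(int(np.floor(cy)) + half + 1, frame.shape[0])
    c0 = max(int(np.floor(cx)) - half, 0)
    c1 = min(int(np.floor(cx)) + half + 1, frame.shape[1])
    if r0 >= r1 or c0 >= c1:
        raise ValueError("patch placed outside the field")
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    gy = np.exp(-((rows - cy) ** 2) / (2 * sig**2))
    gx = np.exp(-((cols - cx) ** 2) / (2 * sig**2))
    amp = integral / (2 * np.pi * sig**2)
    frame[r0:r1, c0:c1] += amp * np.outer(gy, gx)


def generate_patch_movie(
    params: PatchSimParams,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a two-channel (Las17, Abp1) patch movie plus its truth table.

    The truth table lists every per-patch parameter along with the derived
    quantities each analysis stage should recover (accumulation and
    deaccumulation rates, internalized and Las17-early flags).
    """
    rng = np.random.default_rng(params.seed)
    specs = params.patches if params.patches is not None else sample_patch_specs(params, rng)
    T = params.n_frames
    H, W = params.shape
    h_um = H * params.pixel_size
    w_um = W * params.pixel_size
    for s in specs:
        if not (0 <= s.x < w_um and 0 <= s.y < h_um):
            raise ValueError(f"patch at ({s.x}, {s.y}) outside the field")
    center = np.array([w_um / 2.0, h_um / 2.0])
    times = np.arange(T) * params.frame_interval

    # static illumination field, mean ~ 1, linear gradient along x
    cols = np.arange(W)
    illum_1d = 1.0 + params.illumination_amplitude * (cols - (W - 1) / 2.0) / W
    illum = np.broadcast_to(illum_1d, (H, W))

    data = np.zeros((T, 2, H, W))
    channel_names = ["Las17", "Abp1"]
    for ti, t in enumerate(times):
        bleach = np.exp(-params.bleach_rate * t)
        for ci, ch in enumerate(channel_names):
            frame = np.zeros((H, W))
            for s in specs:
                m = float(s.molecules(np.array([t]), ch)[0])
                if m <= 0:
                    continue
                if ch == "Abp1":
                    inward = center - np.array([s.x, s.y])
                    n = np.linalg.norm(inward)
                    inward = inward / n if n > 0 else np.array([0.0, 0.0])
                    px, py = s.position(np.array([t]), inward)[0]
                else:
                    px, py = s.x, s.y
                _render_gaussian(frame, px, py, params.gain * m,
                                 params.psf_sigma, params.pixel_size)
            frame = (frame + params.cytosol_background) * bleach * illum
            frame += params.camera_offset
            if params.read_noise_sd > 0:
                frame = frame + rng.normal(0.0, params.read_noise_sd, size=frame.shape)
            data[ti, ci] = np.clip(frame, 0.0, None)

    stack = ImageStack(
        data=data,
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
        channel_names=channel_names,
    )
    rows = []
    for i, s in enumerate(specs):
        rows.append({
            "patch_id": i,
            "x_um": s.x,
            "y_um": s.y,
            "t_appear_s": s.t_appear,
            "acc_duration_s": s.acc_duration,
            "deacc_duration_s": s.deacc_duration,
            "peak_molecules": s.peak_molecules,
            "las17_peak_molecules": s.las17_peak_molecules,
            "las17_lead_s": s.las17_lead,
            "las17_acc_duration_s": s.las17_acc_duration,
            "las17_deacc_duration_s": s.las17_deacc_duration,
            "accumulation_rate": s.peak_molecules / s.acc_duration,
            "deaccumulation_rate": -s.peak_molecules / s.deacc_duration,
            "internalized": s.internalized,
            "inward_displacement_um": s.inward_displacement,
            "las17_early": s.las17_early,
        })
    truth = pd.DataFrame(
        rows,
        columns=[
            "patch_id", "x_um", "y_um", "t_appear_s", "acc_duration_s",
            "deacc_duration_s", "peak_molecules", "las17_peak_molecules",
            "las17_lead_s", "las17_acc_duration_s", "las17_deacc_duration_s",
            "accumulation_rate", "deaccumulation_rate", "internalized",
            "inward_displacement_um", "las17_early",
        ],
    )
    return stack, truth


# ---------------------------------------------------------------------------
# beads


@dataclass
class BeadSimParams:
    """Study conditions for synthetic bead-motility movies.

    Defaults emulate a 20x acquisition (0.325 um pixels) at 70 s frame
    intervals: a 3 um bead translating at ~1 um/min with an actin shell at
    its surface and a comet tail decaying over ~5 um behind it.
    """

    n_frames: int = 20
    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.325
    frame_interval: float = 70.0
    radius_um: float = 1.5
    speed: float = 1.0  # um/min
    heading_deg: float = 0.0  # 0 = +x
    start_xy: tuple[float, float] | None = None  # um; default = margin
    ring_amplitude: float = 300.0  # actin shell at the bead surface
    ring_width_um: float = 0.5
    tail_amplitude: float = 150.0  # at the rear surface
    tail_decay_um: float = 5.0
    tail_width_um: float = 1.5
    bundle_count: int = 0
    bundle_spacing_um: float = 3.0  # perpendicular offset step from the axis
    bundle_intensities: list[float] | None = None
    bundle_width_um: float = 0.5
    noise_sd: float = 5.0
    camera_offset: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")


@dataclass
class BeadTruth:
    """Ground truth for a synthetic bead movie."""

    positions: pd.DataFrame  # frame, t_s, x_um, y_um
    diameter_um: float
    speed: float  # um/min
    heading_deg: float
    bundles: pd.DataFrame  # offset_um (perpendicular), intensity


def generate_bead_movie(params: BeadSimParams) -> tuple[ImageStack, BeadTruth]:
    """Render a single-bead comet-tail movie plus its ground-truth track."""
    p = params
    rng = np.random.default_rng(p.seed)
    H, W = p.shape
    h_um, w_um = H * p.pixel_size, W * p.pixel_size
    theta = np.deg2rad(p.heading_deg)
    u = np.array([np.cos(theta), np.sin(theta)])  # motion direction (x, y)
    total_path = p.speed / 60.0 * p.frame_interval * (p.n_frames - 1)
    if p.start_xy is None:
        # clear of the border by the annulus outer radius used downstream
        margin = p.radius_um + 16.0 * p.pixel_size
        start = np.array([margin, h_um / 2.0]) if abs(u[0]) >= abs(u[1]) else np.array(
            [w_um / 2.0, margin])
        if u[0] < 0 or (abs(u[1]) > abs(u[0]) and u[1] < 0):
            start = np.array([w_um, h_um]) - start
    else:
        start = np.array(p.start_xy, dtype=float)
    end = start + total_path * u
    lim = np.array([w_um, h_um])
    if np.any(end < p.radius_um) or np.any(end > lim - p.radius_um) or \
       np.any(start < p.radius_um) or np.any(start > lim - p.radius_um):
        raise ValueError("bead trajectory leaves the field of view")

    # pixel-centre coordinate grids, um
    ys, xs = np.mgrid[0:H, 0:W]
    xs_um = xs * p.pixel_size
    ys_um = ys * p.pixel_size
    n_bundles = p.bundle_count
    intensities = list(p.bundle_intensities or [])
    if n_bundles and not intensities:
        intensities = [0.6 * p.ring_amplitude] * n_bundles
    if len(intensities) < n_bundles:
        raise ValueError("bundle_intensities shorter than bundle_count")
    offsets = [p.radius_um + p.bundle_spacing_um * (i + 1) for i in range(n_bundles)]

    data = np.zeros((p.n_frames, 1, H, W))
    rows = []
    v = np.array([-u[1], u[0]])  # perpendicular direction
    for ti in range(p.n_frames):
        t = ti * p.frame_interval
        c = start + (p.speed / 60.0) * t * u
        dx = xs_um - c[0]
        dy = ys_um - c[1]
        d = np.hypot(dx, dy)
        s = dx * u[0] + dy * u[1]  # along-motion coordinate
        q = dx * v[0] + dy * v[1]  # transverse coordinate
        frame = p.ring_amplitude * np.exp(
            -((d - p.radius_um) ** 2) / (2 * p.ring_width_um**2))
        behind = s < -p.radius_um
        tail = np.zeros_like(frame)
        tail[behind] = p.tail_amplitude * np.exp(
            (s[behind] + p.radius_um) / p.tail_decay_um) * np.exp(
            -(q[behind] ** 2) / (2 * p.tail_width_um**2))
        frame += tail
        # bundles: static streaks parallel to the trajectory axis, offset
        # transversely, spanning the region already passed by the bead
        q0 = (xs_um - start[0]) * v[0] + (ys_um - start[1]) * v[1]
        s0 = (xs_um - start[0]) * u[0] + (ys_um - start[1]) * u[1]
        s_c = (c - start) @ u
        for off, amp in zip(offsets, intensities[:n_bundles]):
            seg = (s0 > 0) & (s0 < s_c - p.radius_um)
            streak = np.zeros_like(frame)
            streak[seg] = amp * np.exp(-((q0[seg] - off) ** 2)
                                       / (2 * p.bundle_width_um**2))
            frame += streak
        frame += p.camera_offset
        if p.noise_sd > 0:
            frame = frame + rng.normal(0.0, p.noise_sd, size=frame.shape)
        data[ti, 0] = np.clip(frame, 0.0, None)
        rows.append({"frame": ti, "t_s": t, "x_um": float(c[0]), "y_um": float(c[1])})

    stack = ImageStack(data=data, pixel_size=p.pixel_size,
                       frame_interval=p.frame_interval, channel_names=["actin"])
    truth = BeadTruth(
        positions=pd.DataFrame(rows),
        diameter_um=2 * p.radius_um,
        speed=p.speed,
        heading_deg=p.heading_deg,
        bundles=pd.DataFrame({
            "offset_um": offsets,
            "intensity": intensities[:n_bundles],
        }),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# pyrene traces


@dataclass
class PyreneSimParams:
    """Logistic stand-in for a pyrene actin polymerization time course.

    The analytic maximum of dP/dt is r * P_total / 4 (attained at t_half),
    which serves as the oracle for maximum-polymerization-rate extraction.
    """

    p_total: float = 3000.0  # nM polymerizable actin
    rate: float = 0.005  # logistic r, 1/s
    t_half: float = 600.0  # s
    baseline: float = 100.0  # RFU
    plateau: float = 1100.0  # RFU
    noise_sd: float = 0.0  # RFU
    dt: float = 5.0  # s
    duration: float = 2400.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.p_total <= 0:
            raise ValueError("rate and p_total must be > 0")

    @property
    def max_rate(self) -> float:
        """Analytic maximum polymerization rate, nM/s."""
        return self.rate * self.p_total / 4.0


def generate_pyrene_trace(params: PyreneSimParams) -> PolymerizationTrace:
    """Noisy logistic fluorescence trace; see :class:`PyreneSimParams`."""
    p = params
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.duration + p.dt / 2, p.dt)
    polymer = p.p_total / (1.0 + np.exp(-p.rate * (t - p.t_half)))
    f = p.baseline + (p.plateau - p.baseline) * polymer / p.p_total
    if p.noise_sd > 0:
        f = f + rng.normal(0.0, p.noise_sd, size=f.shape)
    return PolymerizationTrace(time=t, fluorescence=f)


# ---------------------------------------------------------------------------
# depletion titrations


# reported dissociation constants of the dimeric activator constructs (uM),
# used as generator defaults for the two titration designs
WT_LAS17_KD_UM = 0.16
MYO5_KD_UM = 0.13


@dataclass
class DepletionSimParams:
    """Forward model of a supernatant-depletion titration.

    ``ligand_concentrations`` are total dimer concentrations (uM) on the
    beads; the receptor (Arp2/3 complex) is fixed at 0.05 uM as in the
    assay design.
    """

    kd: float = WT_LAS17_KD_UM
    receptor_total: float = 0.05
    ligand_concentrations: Sequence[float] = field(
        default_factory=lambda: tuple(np.geomspace(0.016, 2.06, 8)))
    noise_sd: float = 0.0  # fractional, multiplicative
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd < 0 or self.receptor_total < 0:
            raise ValueError("concentrations must be >= 0")
        if any(c < 0 for c in self.ligand_concentrations):
            raise ValueError("ligand concentrations must be >= 0")

    @classmethod
    def wt_las17(cls, noise_sd: float = 0.0, seed: int = 0) -> "DepletionSimParams":
        """The wild-type LZ-Las17 titration design: 8 dimer concentrations
        log-spaced over 16 nM - 2.06 uM against 50 nM complex."""
        return cls(kd=WT_LAS17_KD_UM, receptor_total=0.05,
                   ligand_concentrations=tuple(np.geomspace(0.016, 2.06, 8)),
                   noise_sd=noise_sd, seed=seed)

    @classmethod
    def myo5(cls, noise_sd: float = 0.0, seed: int = 0) -> "DepletionSimParams":
        """The LZ-Myo5-CA titration design: 25 nM - 1.6 uM dimer against
        50 nM complex."""
        return cls(kd=MYO5_KD_UM, receptor_total=0.05,
                   ligand_concentrations=tuple(np.geomspace(0.025, 1.6, 8)),
                   noise_sd=noise_sd, seed=seed)


def generate_depletion_data(params: DepletionSimParams) -> list[BindingMeasurement]:
    """Fraction-bound points from the tight-binding quadratic, with
    multiplicative Gaussian noise, clipped to [0, 1]."""
    p = params
    rng = np.random.default_rng(p.seed)
    out = []
    for L in p.ligand_concentrations:
        fb = quadratic_fraction(float(L), p.receptor_total, p.kd) if L > 0 else 0.0
        if p.noise_sd > 0:
            fb = fb * (1.0 + rng.normal(0.0, p.noise_sd))
        fb = float(np.clip(fb, 0.0, 1.0))
        out.append(BindingMeasurement(
            ligand_total=float(L),
            receptor_total=p.receptor_total,
            supernatant=p.receptor_total * (1.0 - fb),
            fraction_bound=fb,
        ))
    return out
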