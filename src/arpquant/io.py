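"""Shared domain types and file I/O.

Images are held as :class:`ImageStack` arrays ordered time x channel x row x
column, with physical metadata (pixel size in micrometres, frame interval in
seconds) attached. Positions are stored in micrometres everywhere in the
package; pixel coordinates appear only inside detection internals. The
coordinate convention is: frame indices are 0-based, and a spot at pixel
index (row, col) has position y = row * pixel_size, x = col * pixel_size
(origin at the centre of pixel (0, 0), x running along columns).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "SpotDetection",
    "Trajectory",
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
]

_META_KEY = "arpquant_meta"


@dataclass
class ImageStack:
    """A time-lapse fluorescence stack with physical metadata.

    Parameters
    ----------
    data:
        Intensity array ordered (T, C, Y, X), arbitrary fluorescence units.
    pixel_size:
        Lateral pixel pitch in micrometres per pixel.
    frame_interval:
        Time between consecutive frames in seconds.
    channel_names:
        One label per channel, e.g. ``["Las17", "Abp1"]``.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:  # single channel: insert C axis
            self.data = self.data[:, None, :, :]
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be (T, C, Y, X); got shape {self.data.shape}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(height, width) of the field in micrometres."""
        return (
            self.data.shape[2] * self.pixel_size,
            self.data.shape[3] * self.pixel_size,
        )

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        if not 0 <= channel < self.n_channels:
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """(T, Y, X) view of one channel."""
        return self.data[:, self.channel_index(channel)]

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """Copy of this stack with new pixel data, same metadata."""
        return ImageStack(
            data=np.asarray(data),
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            channel_names=list(self.channel_names),
        )


@dataclass
class SpotDetection:
    """A single detected diffraction-limited spot.

    Positions are in micrometres in image coordinates. ``raw_intensity`` is
    the plain pixel sum within the spot radius; ``corrected_intensity`` has
    the local (annulus-median) background removed.
    """

    t: int
    x: float
    y: float
    quality: float
    raw_intensity: float
    corrected_intensity: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("frame index must be >= 0")
        if self.quality < 0:
            raise ValueError("quality must be >= 0")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Trajectory:
    """Time-ordered spot detections for one patch in one channel.

    Frame gaps up to the linker's maximum are permitted; frame indices are
    strictly increasing.
    """

    channel: str
    spots: list[SpotDetection]
    id: int = 0

    def __post_init__(self) -> None:
        frames = [s.t for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("trajectory frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.t for s in self.spots], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) in micrometres."""
        return np.array([[s.x, s.y] for s in self.spots], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([s.corrected_intensity for s in self.spots], dtype=float)

    @property
    def start(self) -> int:
        return self.spots[0].t

    @property
    def end(self) -> int:
        return self.spots[-1].t

    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def __len__(self) -> int:
        return len(self.spots)


# ---------------------------------------------------------------------------
# image stack I/O


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as TIFF with metadata in the description."""
    meta = {
        _META_KEY: {
            "pixel_size": stack.pixel_size,
            "frame_interval": stack.frame_interval,
            "channel_names": stack.channel_names,
        }
    }
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF time series into an :class:`ImageStack`.

    Axes are normalised to (T, C, Y, X); a missing channel axis is inserted
    with length one. Metadata is taken from the file where present, with the
    keyword arguments acting as config fallback; a stack with no resolvable
    pixel size or frame interval is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict[str, Any] = {}
    if _META_KEY in desc:
        try:
            meta = json.loads(desc)[_META_KEY]
        except (json.JSONDecodeError, KeyError, TypeError):
            meta = {}
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]
    elif data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {data.shape} as T(C)YX")
    px = meta.get("pixel_size", pixel_size)
    dt = meta.get("frame_interval", frame_interval)
    names = meta.get("channel_names") or (
        list(channel_names) if channel_names is not None else None
    )
    if px is None:
        raise ValueError(f"{path}: pixel size not in file and no config override")
    if dt is None:
        raise ValueError(f"{path}: frame interval not in file and no config override")
    if names is not None and len(names) != data.shape[1]:
        raise ValueError(
            f"{len(names)} channel names for {data.shape[1]} channels in {path}"
        )
    return ImageStack(
        data=data,
        pixel_size=float(px),
        frame_interval=float(dt),
        channel_names=list(names) if names else [],
    )


# ---------------------------------------------------------------------------
# tabular I/O


def write_table(records: Sequence[Any], path: str | Path,
                fieldnames: Sequence[str] | None = None) -> pd.DataFrame:
    """Write homogeneous dataclass records (or dicts) to a one-header CSV.

    An empty list with explicit ``fieldnames`` yields a header-only CSV.
    Returns the frame written.
    """
    rows: list[dict[str, Any]] = []
    kinds = set()
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            kinds.add(type(rec))
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, dict):
            kinds.add(dict)
            rows.append(dict(rec))
        else:
            raise TypeError(f"cannot serialise record of type {type(rec)!r}")
    if len(kinds) > 1:
        raise TypeError(f"heterogeneous records: {sorted(k.__name__ for k in kinds)}")
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=list(fieldnames or []))
    df.to_csv(path, index=False)
    return df


def read_table(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, checking required columns."""
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df
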