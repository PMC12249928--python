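"""Tabular and image I/O plus the validated in-memory containers.

Conventions used throughout the package:

* frames are 0-based integers; time is carried in **minutes** internally
  (readers convert declared units on ingest);
* positions are in μm with the image origin at the top-left corner,
  x increasing rightward and y increasing downward (pixel convention);
* delimited text is comma-separated, "." decimal, UTF-8, LF line ends,
  one header row.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger("pbmquant")

#: tolerance (minutes) for the uniform-sampling check within a track
UNIFORM_DT_TOL = 1e-6

_TIME_FACTORS = {"min": 1.0, "s": 1.0 / 60.0, "sec": 1.0 / 60.0, "h": 60.0, "hr": 60.0}

#: column maps per input dialect -> canonical (track_id, frame, t, x, y)
DIALECTS = {
    "generic": {
        "track_id": "track_id",
        "frame": "frame",
        "t": "t",
        "x": "x",
        "y": "y",
    },
    # the flavour of CSV exported by common spot trackers (TrackMate-style
    # spot tables); time arrives in seconds unless told otherwise
    "tracker_export": {
        "track_id": "TRACK_ID",
        "frame": "FRAME",
        "t": "POSITION_T",
        "x": "POSITION_X",
        "y": "POSITION_Y",
    },
}


def configure_logging(level: str = "INFO") -> None:
    """Send package logs to stderr at the given level (idempotent)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers = [handler]
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# TrajectoryTable


@dataclass(frozen=True)
class TrajectoryTable:
    """Uniformly sampled 2-D cell tracks.

    Wraps a DataFrame with columns ``track_id, frame, t, x, y`` (t in
    minutes, x/y in μm), sorted by (track_id, frame). Within each track
    frames and times are strictly increasing and the time spacing is
    uniform to within :data:`UNIFORM_DT_TOL`.
    """

    df: pd.DataFrame

    REQUIRED = ("track_id", "frame", "t", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing column {missing[0]}")
        if self.df.empty:
            raise ValidationError("empty trajectory table")
        object.__setattr__(
            self,
            "df",
            self.df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(
                drop=True
            ),
        )
        for tid, g in self.df.groupby("track_id", sort=False):
            f = g["frame"].to_numpy()
            t = g["t"].to_numpy(dtype=float)
            if (np.diff(f) <= 0).any() or (np.diff(t) <= 0).any():
                raise ValidationError(f"non-monotone frames/times in track {tid!r}")
            dt = np.diff(t)
            if len(dt) and np.ptp(dt) > UNIFORM_DT_TOL:
                raise ValidationError(f"non-uniform time spacing in track {tid!r}")

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    @property
    def track_ids(self) -> list:
        return list(dict.fromkeys(self.df["track_id"]))

    def track(self, track_id) -> pd.DataFrame:
        g = self.df[self.df["track_id"] == track_id]
        if g.empty:
            raise KeyError(track_id)
        return g.reset_index(drop=True)

    def iter_tracks(self) -> Iterator[tuple[object, pd.DataFrame]]:
        for tid, g in self.df.groupby("track_id", sort=False):
            yield tid, g.reset_index(drop=True)

    def delta_t(self, track_id) -> float:
        """Sampling interval δt (min) of one track."""
        t = self.track(track_id)["t"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValidationError(f"track {track_id!r} has fewer than 2 points")
        return float(t[1] - t[0])


def _apply_spacing_policy(
    df: pd.DataFrame, policy: Literal["drop", "split", "error"]
) -> pd.DataFrame:
    """Enforce the uniform-δt invariant track by track."""
    keep: list[pd.DataFrame] = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame", kind="mergesort")
        t = g["t"].to_numpy(dtype=float)
        if (np.diff(t) <= 0).any():
            raise ValidationError(f"non-monotone time within track {tid!r}")
        dt = np.diff(t)
        if len(dt) == 0 or np.ptp(dt) <= UNIFORM_DT_TOL:
            keep.append(g)
            continue
        if policy == "error":
            raise ValidationError(f"non-uniform time spacing in track {tid!r}")
        if policy == "drop":
            logger.warning("dropping track %r: non-uniform time spacing", tid)
            continue
        # split at every spacing change into maximal uniform runs (>=2 points)
        breaks = np.where(np.abs(np.diff(dt)) > UNIFORM_DT_TOL)[0] + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [len(dt)]))
        part = 0
        for s, e in zip(starts, ends):
            seg = g.iloc[s : e + 1].copy()
            if len(seg) < 2:
                continue
            seg["track_id"] = f"{tid}/seg{part}"
            part += 1
            keep.append(seg)
        logger.warning("split track %r into %d uniform segments", tid, part)
    if not keep:
        raise ValidationError("no valid tracks after applying spacing policy")
    return pd.concat(keep, ignore_index=True)


def read_trajectories(
    path: str | Path,
    dialect: str = "generic",
    time_unit: str = "min",
    spacing_policy: Literal["drop", "split", "error"] = "drop",
) -> TrajectoryTable:
    """Read a trajectory CSV in the named dialect.

    Parameters
    ----------
    path
        Delimited-text file, one row per cell per frame.
    dialect
        ``generic`` (columns ``track_id,frame,t,x,y``) or ``tracker_export``
        (TrackMate-style spot-table column names).
    time_unit
        Unit of the time column in the file; converted to minutes.
    spacing_policy
        What to do with tracks whose sampling is not uniform:
        drop (default, logged), split into uniform segments, or error.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}")
    if time_unit not in _TIME_FACTORS:
        raise ParameterError(f"unknown time unit {time_unit!r}")
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty input file {path}") from None
    if raw.empty:
        raise ValidationError(f"empty input file {path}")
    colmap = DIALECTS[dialect]
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise FormatError(f"missing column {missing[0]}")
    df = pd.DataFrame(
        {canon: raw[src] for canon, src in colmap.items()}
    )
    df["frame"] = df["frame"].astype(int)
    if (df["frame"] < 0).any():
        raise ValidationError("negative frame index")
    df["t"] = df["t"].astype(float) * _TIME_FACTORS[time_unit]
    df = _apply_spacing_policy(df, spacing_policy)
    return TrajectoryTable(df)


# ---------------------------------------------------------------------------
# ImageStack


@dataclass
class ImageStack:
    """Pixel data normalised to axes (frame, y, x, channel).

    ``pixel_size`` is μm per pixel (None when uncalibrated); ``timestamps``
    are per-frame times in minutes when known.
    """

    data: np.ndarray
    pixel_size: float | None = None
    channel_names: list[str] = field(default_factory=list)
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.data)
        if a.ndim != 4:
            raise ValidationError(f"ImageStack data must be 4-D, got {a.ndim}-D")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.channel_names and len(self.channel_names) != a.shape[3]:
            raise ValidationError("channel_names length must equal channel count")
        if np.issubdtype(a.dtype, np.floating) and np.nanmin(a) < 0:
            raise ValidationError("intensities must be non-negative")
        self.data = a

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    def frame(self, i: int, channel: int = 0) -> np.ndarray:
        return self.data[i, :, :, channel]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """All frames of one channel, shape (frames, y, x)."""
        if isinstance(name_or_index, str):
            idx = self.channel_names.index(name_or_index)
        else:
            idx = name_or_index
        return self.data[:, :, :, idx]


_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64")


def read_image(path: str | Path, pixel_size: float | None = None) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    A single grayscale page becomes a 1-frame, 1-channel stack; a page
    with a trailing small axis (≤4) is treated as multi-channel; multiple
    pages become frames.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            n_pages = len(tif.pages)
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.dtype.name not in _SUPPORTED_DTYPES:
        raise FormatError(f"unsupported bit depth/dtype {arr.dtype}")
    if arr.ndim == 2:
        arr = arr[None, :, :, None]
    elif arr.ndim == 3:
        if n_pages > 1:
            arr = arr[:, :, :, None]  # pages are frames
        elif arr.shape[-1] <= 4:
            arr = arr[None, :, :, :]  # single page, interleaved channels
        else:
            arr = arr[:, :, :, None]
    elif arr.ndim == 4:
        pass
    else:
        raise FormatError(f"unsupported TIFF dimensionality {arr.ndim}")
    return ImageStack(arr, pixel_size=pixel_size)


def write_image(stack: ImageStack | np.ndarray, path: str | Path) -> None:
    """Write an ImageStack (or raw array) as a multi-page TIFF."""
    arr = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    arr = np.squeeze(arr)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


# ---------------------------------------------------------------------------
# CtTable


@dataclass(frozen=True)
class CtTable:
    """qPCR cycle-threshold measurements.

    One row per technical replicate: ``sample, condition, gene, ct``.
    Ct values must be finite; replicate structure is free-form (rows with
    identical sample+gene are replicates of each other).
    """

    df: pd.DataFrame

    REQUIRED = ("sample", "condition", "gene", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing column {missing[0]}")
        if self.df.empty:
            raise ValidationError("empty Ct table")
        ct = self.df["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all():
            raise ValidationError("non-finite Ct value")
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def require_reference(self, reference_gene: str) -> None:
        """Raise unless the reference gene was measured in every sample."""
        for sample, g in self.df.groupby("sample"):
            if reference_gene not in set(g["gene"]):
                raise ValidationError(
                    f"reference gene {reference_gene!r} missing in sample {sample!r}"
                )


def read_ct_table(path: str | Path) -> CtTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty input file {path}") from None
    return CtTable(df)


# ---------------------------------------------------------------------------
# generic table output


def write_table(
    records, path: str | Path, create_dirs: bool = True
) -> None:
    """Write any result table as delimited text (CSV, one header row).

    ``records`` may be a DataFrame, a container exposing ``to_frame()``,
    or a sequence of dataclass-like records. Round-tripping through
    :func:`read_table` preserves numeric fields to 1e-9 and identifiers
    exactly.
    """
    if records is None:
        raise ValidationError("records must not be None")
    if isinstance(records, pd.DataFrame):
        df = records
    elif hasattr(records, "to_frame"):
        df = records.to_frame()
    elif isinstance(records, Sequence):
        df = pd.DataFrame([vars(r) if hasattr(r, "__dict__") else r for r in records])
    else:
        raise ValidationError(f"cannot tabulate {type(records).__name__}")
    path = Path(path)
    if create_dirs:
        path.parent.mkdir(parents=True, exist_ok=True)
    elif not path.parent.is_dir():
        raise IOError(f"directory does not exist: {path.parent}")
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty input file {path}") from None
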