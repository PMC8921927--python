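"""Core domain types, angle conventions, the forearm channel map, and file I/O.

The pipeline works on two sensor streams recorded at their native rates:
multichannel surface EMG (volts, nominally 1,000 Hz) and a reference joint
angle (degrees, nominally 100 Hz).  All angles are kept in degrees; radians
appear only inside trigonometric internals elsewhere in the package.

Two angle conventions coexist in forearm rotation work:

``palm_up_zero``
    Trial convention: 0 deg at the supinated start (palm up), 180 deg at the
    pronated end (palm down).
``neutral_zero``
    Ergonomic convention: the neutral forearm position is 0 deg, giving a
    -90..+90 deg range.

The two are related by a fixed +90 deg offset
(``palm_up_zero = neutral_zero + 90``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MUSCLE_CHANNELS",
    "AngleConvention",
    "CONVENTION_RANGES",
    "CONVENTION_OFFSET_DEG",
    "EmgRecording",
    "AngleTrajectory",
    "convert_convention",
    "clamp_to_convention",
    "read_recording",
    "write_recording",
    "read_trajectory",
    "write_trajectory",
]

#: Electrode sites for the single pronation-supination degree of freedom:
#: the five main forearm muscles driving (or opposing) the rotation.
DEFAULT_MUSCLE_CHANNELS: tuple[str, ...] = (
    "pronator_teres",
    "flexor_carpi_radialis",
    "extensor_carpi_radialis_longus",
    "supinator",
    "brachioradialis",
)


class AngleConvention(str, enum.Enum):
    """Zero-reference convention for the forearm rotation angle."""

    PALM_UP_ZERO = "palm_up_zero"
    NEUTRAL_ZERO = "neutral_zero"


#: Valid angle range (degrees) under each convention, after clamping.
CONVENTION_RANGES: dict[AngleConvention, tuple[float, float]] = {
    AngleConvention.PALM_UP_ZERO: (0.0, 180.0),
    AngleConvention.NEUTRAL_ZERO: (-90.0, 90.0),
}

#: palm_up_zero angle = neutral_zero angle + this offset.
CONVENTION_OFFSET_DEG: float = 90.0


@dataclass(frozen=True)
class EmgRecording:
    """Multichannel sEMG samples with a fixed sample rate.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz; must be positive.
    channel_names : tuple of str
        Ordered, unique muscle labels, one per column of ``samples``.
    samples : ndarray, shape (n_samples, n_channels)
        Voltages in volts.  All values must be finite.
    start_time : float
        Time of the first sample in seconds from trial start.
    """

    sample_rate: float
    channel_names: tuple[str, ...]
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time x channel) array")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"samples has {samples.shape[1]} columns but "
                f"{len(self.channel_names)} channel names were given"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Trial span covered by the samples, in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        """Return a copy with the sample matrix replaced (same metadata)."""
        return replace(self, samples=samples)


@dataclass(frozen=True)
class AngleTrajectory:
    """Timestamped joint angles in degrees under a declared convention."""

    timestamps: np.ndarray
    angles: np.ndarray
    convention: AngleConvention = AngleConvention.PALM_UP_ZERO

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        ang = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "convention", AngleConvention(self.convention))
        if ts.ndim != 1 or ang.ndim != 1:
            raise ValueError("timestamps and angles must be 1-D")
        if ts.shape != ang.shape:
            raise ValueError("timestamps and angles must have equal length")
        if ts.size == 0:
            raise ValueError("trajectory must contain at least one sample")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(ts)) and np.all(np.isfinite(ang))):
            raise ValueError("trajectory contains NaN or Inf")

    def __len__(self) -> int:
        return self.timestamps.size

    def clamped(self) -> "AngleTrajectory":
        """Return a copy with angles clamped to the convention's range."""
        lo, hi = CONVENTION_RANGES[self.convention]
        return replace(self, angles=np.clip(self.angles, lo, hi))


def clamp_to_convention(angles: np.ndarray, convention: AngleConvention) -> np.ndarray:
    """Clamp angles (degrees) to the valid range of *convention*."""
    lo, hi = CONVENTION_RANGES[AngleConvention(convention)]
    return np.clip(np.asarray(angles, dtype=float), lo, hi)


def convert_convention(
    traj: AngleTrajectory, target: AngleConvention
) -> AngleTrajectory:
    """Re-express a trajectory under *target* convention.

    The mapping is the fixed +/-90 deg offset; converting to the current
    convention is the identity, and a there-and-back conversion reproduces
    the original angles exactly.
    """
    target = AngleConvention(target)
    if target == traj.convention:
        return traj
    if traj.convention == AngleConvention.PALM_UP_ZERO:
        shifted = traj.angles - CONVENTION_OFFSET_DEG
    else:
        shifted = traj.angles + CONVENTION_OFFSET_DEG
    return AngleTrajectory(traj.timestamps, shifted, target)


# ---------------------------------------------------------------------------
# File I/O
#
# CSV dialect: leading '#'-prefixed metadata lines, then a header row, then
# numeric rows.  Recordings carry '# sample_rate_hz=...', trajectories carry
# '# convention=...'.  The 'npz' format is a lossless binary container for
# run-time artifacts.
# ---------------------------------------------------------------------------

_CSV_FLOAT_FMT = "%.9g"


def _read_metadata(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, n_meta


def _locate_bad_cell(path: Path, n_meta: int) -> None:
    """Scan a CSV for the first non-numeric cell and raise naming row/column."""
    with open(path) as fh:
        lines = fh.readlines()
    header = lines[n_meta].rstrip("\n").split(",")
    for i, line in enumerate(lines[n_meta + 1 :], start=n_meta + 2):
        for j, cell in enumerate(line.rstrip("\n").split(",")):
            try:
                float(cell)
            except ValueError:
                col = header[j] if j < len(header) else f"column {j + 1}"
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {i}, column {col!r}"
                ) from None


def _read_csv_table(path: Path, n_meta: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, skiprows=n_meta)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no samples")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        _locate_bad_cell(path, n_meta)
        raise ValueError(f"{path}: non-numeric data")
    return df


def read_recording(
    path: str | Path,
    format: str = "csv",
    channel_map: Sequence[str] | None = None,
) -> EmgRecording:
    """Read an :class:`EmgRecording` from disk.

    ``format='csv'`` expects a ``# sample_rate_hz=...`` metadata line, a
    ``time_s,<ch1>,...`` header, and numeric rows.  ``format='npz'`` reads the
    lossless container written by :func:`write_recording`.  If *channel_map*
    is given, the file's channels must match it exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "npz":
        with np.load(path, allow_pickle=False) as data:
            rec = EmgRecording(
                sample_rate=float(data["sample_rate"]),
                channel_names=tuple(str(c) for c in data["channel_names"]),
                samples=data["samples"],
                start_time=float(data["start_time"]),
            )
    elif format == "csv":
        meta, n_meta = _read_metadata(path)
        if "sample_rate_hz" not in meta:
            raise ValueError(f"{path}: missing '# sample_rate_hz=' metadata line")
        df = _read_csv_table(path, n_meta)
        if df.shape[1] < 2 or df.columns[0] != "time_s":
            raise ValueError(f"{path}: header must be 'time_s,<channel>,...'")
        rec = EmgRecording(
            sample_rate=float(meta["sample_rate_hz"]),
            channel_names=tuple(df.columns[1:]),
            samples=df.iloc[:, 1:].to_numpy(dtype=float),
            start_time=float(df.iloc[0, 0]),
        )
    else:
        raise ValueError(f"unknown recording format {format!r}")
    if channel_map is not None and tuple(channel_map) != rec.channel_names:
        raise ValueError(
            f"{path}: channels {rec.channel_names} do not match the supplied "
            f"channel map {tuple(channel_map)}"
        )
    return rec


def write_recording(rec: EmgRecording, path: str | Path, format: str = "csv") -> None:
    """Write a recording; ``read_recording`` round-trips within format precision.

    CSV stores 9 significant digits (round-trip error below 1e-5 V for
    signals of order 1 V); npz is lossless.
    """
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"{path} is a directory")
    if format == "npz":
        np.savez_compressed(
            path,
            sample_rate=rec.sample_rate,
            channel_names=np.array(rec.channel_names),
            samples=rec.samples,
            start_time=rec.start_time,
        )
    elif format == "csv":
        df = pd.DataFrame(rec.samples, columns=list(rec.channel_names))
        df.insert(0, "time_s", rec.times)
        with open(path, "w") as fh:
            fh.write(f"# sample_rate_hz={rec.sample_rate:g}\n")
            df.to_csv(fh, index=False, float_format=_CSV_FLOAT_FMT)
    else:
        raise ValueError(f"unknown recording format {format!r}")


def read_trajectory(path: str | Path) -> AngleTrajectory:
    """Read an angle trajectory CSV (``# convention=...`` + ``time_s,angle_deg``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, n_meta = _read_metadata(path)
    df = _read_csv_table(path, n_meta)
    if list(df.columns[:2]) != ["time_s", "angle_deg"]:
        raise ValueError(f"{path}: header must be 'time_s,angle_deg'")
    convention = AngleConvention(meta.get("convention", "palm_up_zero"))
    return AngleTrajectory(
        df["time_s"].to_numpy(float), df["angle_deg"].to_numpy(float), convention
    )


def write_trajectory(traj: AngleTrajectory, path: str | Path) -> None:
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"{path} is a directory")
    df = pd.DataFrame({"time_s": traj.timestamps, "angle_deg": traj.angles})
    with open(path, "w") as fh:
        fh.write(f"# convention={traj.convention.value}\n")
        df.to_csv(fh, index=False, float_format=_CSV_FLOAT_FMT)
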