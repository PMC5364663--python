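"""Readers and writers for single-channel ASCII EEG segments, multichannel CSV
recordings, 10-20 montages and TSV result tables.

Single-channel segments follow the Bonn corpus layout: plain text, one
amplitude sample (µV) per line, conventionally 4097 samples at 173.61 Hz.
Multichannel resting-state recordings are CSV matrices whose header row names
the electrodes and whose rows are time points.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Segment",
    "Recording",
    "Montage",
    "BONN_FS",
    "MULTICHANNEL_FS",
    "STANDARD_1020_19",
    "read_bonn_segment",
    "read_multichannel_csv",
    "load_montage",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Malformed input file (bad line, ragged columns, duplicate header...)."""


#: Sampling rate of the Bonn corpus segments (Hz).
BONN_FS = 173.61
#: Default sampling rate assumed for multichannel CSV recordings (Hz).
MULTICHANNEL_FS = 500.0


@dataclass(frozen=True)
class Segment:
    """One channel's amplitude series.

    Parameters
    ----------
    samples : array-like of float
        Amplitude samples in µV, at least two, all finite.
    fs : float
        Sampling rate in Hz (> 0). Metadata only — no operation in this
        package filters by frequency.
    label : str
        Condition tag, e.g. ``"Z"``, ``"O"``, ``"N"``, ``"F"``, ``"S"``,
        ``"EC"``, ``"EO"``; free-form, may be empty.
    electrode : str, optional
        Electrode name for multichannel data.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    electrode: Optional[str] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("Segment needs a 1-D series of length >= 2")
        if not np.all(np.isfinite(x)):
            raise ValueError("Segment samples must all be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be > 0")
        object.__setattr__(self, "samples", x)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs


@dataclass(frozen=True)
class Recording:
    """A multichannel recording: an ordered electrode → :class:`Segment` map.

    All channels must share length and sampling rate; names are unique by
    construction (dict keys).
    """

    channels: Mapping[str, Segment]
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("Recording needs at least one channel")
        lengths = {len(seg) for seg in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels differ in length: {sorted(lengths)}")
        rates = {seg.fs for seg in self.channels.values()}
        if len(rates) != 1:
            raise ValueError(f"channels differ in sampling rate: {sorted(rates)}")
        object.__setattr__(self, "channels", dict(self.channels))

    @property
    def electrodes(self) -> list[str]:
        return list(self.channels)

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


# 19 electrodes of the study's 10-20 layout, planar azimuthal-equidistant
# coordinates on the unit disc (x: left→right, y: back→front, Cz at origin).
# Exact values are a plotting convention, not a measured quantity.
_S18, _C18 = math.sin(math.pi / 10), math.cos(math.pi / 10)  # 18°
_S54, _C54 = math.sin(3 * math.pi / 10), math.cos(3 * math.pi / 10)  # 54°
STANDARD_1020_19: dict[str, tuple[float, float]] = {
    "Fp1": (-_S18, _C18),
    "Fp2": (_S18, _C18),
    "F7": (-_S54, _C54),
    "F3": (-0.40, 0.45),
    "Fz": (0.0, 0.5),
    "F4": (0.40, 0.45),
    "F8": (_S54, _C54),
    "T7": (-1.0, 0.0),
    "C3": (-0.5, 0.0),
    "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0),
    "T8": (1.0, 0.0),
    "P7": (-_S54, -_C54),
    "P3": (-0.40, -0.45),
    "Pz": (0.0, -0.5),
    "P4": (0.40, -0.45),
    "P8": (_S54, -_C54),
    "O1": (-_S18, -_C18),
    "O2": (_S18, -_C18),
}


@dataclass(frozen=True)
class Montage:
    """Electrode names with 2-D head-plane coordinates inside the unit disc."""

    electrodes: Sequence[str]
    coords: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.electrodes)
        if len(set(names)) != len(names):
            raise ValueError("electrode names must be unique")
        coords = {n: (float(x), float(y)) for n, (x, y) in self.coords.items()}
        for name, (x, y) in coords.items():
            if x * x + y * y > 1.0 + 1e-9:
                raise ValueError(f"electrode {name!r} at ({x}, {y}) lies outside the unit disc")
        object.__setattr__(self, "electrodes", names)
        object.__setattr__(self, "coords", coords)

    def position(self, name: str) -> tuple[float, float]:
        try:
            return self.coords[name]
        except KeyError:
            raise KeyError(f"electrode {name!r} not in montage") from None


_LABEL_RE = re.compile(r"^([ZONFSzonfs])\d")


def read_bonn_segment(path: Union[str, Path], fs: float = BONN_FS) -> Segment:
    """Read a Bonn-style ASCII segment: one real amplitude (µV) per line.

    Blank lines and surrounding whitespace are tolerated; the decimal
    separator is the point. The condition label is inferred from a filename
    of the form ``Z001.txt`` (leading set letter Z/O/N/F/S followed by a
    digit), otherwise left empty.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: cannot parse {line!r} as a number"
                ) from None
    if not values:
        raise FormatError(f"{path}: file contains no samples")
    m = _LABEL_RE.match(path.stem)
    label = m.group(1).upper() if m else ""
    return Segment(np.array(values), fs=fs, label=label)


def read_multichannel_csv(
    path: Union[str, Path],
    fs: float = MULTICHANNEL_FS,
    condition: str = "",
    subject_id: str = "",
) -> Recording:
    """Read a multichannel CSV recording (header = electrode names, rows = time).

    Raises :class:`FormatError` on duplicate electrode names, non-numeric
    cells or ragged columns.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    names = [h.strip() for h in header_line.strip().split(",")]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"{path}: duplicate electrode names in header: {dupes}")
    try:
        df = pd.read_csv(path, header=0, names=names, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or non-numeric columns")
    channels = {
        name: Segment(df[name].to_numpy(), fs=fs, label=condition, electrode=name)
        for name in names
    }
    return Recording(channels, condition=condition, subject_id=subject_id)


def load_montage(path: Optional[Union[str, Path]] = None) -> Montage:
    """Load a montage from a ``name,x,y`` CSV, or the built-in 19-electrode
    10-20 layout when *path* is None."""
    if path is None:
        return Montage(list(STANDARD_1020_19), dict(STANDARD_1020_19))
    coords: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith("name,"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 'name,x,y'")
            try:
                coords[parts[0]] = (float(parts[1]), float(parts[2]))
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: bad coordinates") from None
    return Montage(list(coords), coords)


def write_table(rows, path: Union[str, Path], float_format: str = "%.6f") -> None:
    """Write tabular results as TSV with a header row.

    *rows* may be a DataFrame or a sequence of dicts sharing a schema. Values
    round-trip through :func:`read_table` to 6 decimal places.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a TSV table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
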