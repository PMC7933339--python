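"""Reading and writing of chromatograms and study manifests.

Chromatograms are stored as two-column delimited text (time in minutes,
detector response in arbitrary units), one file per (sample, wavelength).
A study manifest is a tabular file with one row per sample holding the
sample id, the origin label, and one chromatogram path per detection
channel (columns ``path_<channel>``).

The time grid of a chromatogram must be strictly increasing and uniform;
non-uniform input is rejected rather than silently resampled.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ChromatogramParseError,
    ChromatogramStructureError,
    StudyError,
)

#: Relative tolerance on the constancy of the sampling step.
GRID_RTOL = 1e-6

#: Default detection channels (nm) of the three-wavelength setup.
DEFAULT_CHANNELS = ("203", "270", "325")

#: Channel tag of a fused (wavelength-summed) trace.
FUSED = "fused"


def _validate_grid(times: np.ndarray) -> None:
    if times.ndim != 1 or times.size < 2:
        raise ChromatogramStructureError(
            f"a chromatogram needs at least 2 points, got {times.size}"
        )
    diffs = np.diff(times)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        row = int(bad[0]) + 2  # 1-based row of the offending time stamp
        raise ChromatogramStructureError(
            f"time grid not strictly increasing at data row {row} "
            f"(t={times[bad[0] + 1]!r} after t={times[bad[0]]!r})"
        )
    step = diffs[0]
    off = np.nonzero(np.abs(diffs - step) > GRID_RTOL * abs(step))[0]
    if off.size:
        row = int(off[0]) + 2
        raise ChromatogramStructureError(
            f"time grid not uniform at data row {row}: step {diffs[off[0]]!r} "
            f"differs from first step {step!r}"
        )


@dataclass(frozen=True)
class Chromatogram:
    """One detector trace of one sample at one detection channel.

    Parameters
    ----------
    sample_id : str
        Sample identifier, e.g. ``"S1"``.
    wavelength : str
        Detection channel tag: a wavelength in nm (``"203"``) or
        ``"fused"`` for a wavelength-summed trace.
    times : ndarray
        Retention times in minutes on a strictly increasing uniform grid.
    intensities : ndarray
        Detector response (arbitrary units), same length as ``times``.
    sources : tuple of str
        For fused traces, the tags of the summed source channels.
    """

    sample_id: str
    wavelength: str
    times: np.ndarray
    intensities: np.ndarray
    sources: tuple = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        _validate_grid(times)
        if intens.shape != times.shape:
            raise ChromatogramStructureError(
                f"times and intensities differ in length "
                f"({times.size} vs {intens.size})"
            )
        if not np.all(np.isfinite(intens)):
            raise ChromatogramStructureError("intensities contain non-finite values")
        object.__setattr__(self, "wavelength", str(self.wavelength))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)
        object.__setattr__(self, "sources", tuple(self.sources))

    @property
    def step(self) -> float:
        """Sampling step in minutes."""
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)

    def with_intensities(self, intensities: np.ndarray) -> "Chromatogram":
        """Return a copy with replaced intensities (same grid and identity)."""
        return dataclasses.replace(self, intensities=intensities)


_NUMBER = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_row(line: str) -> list[str]:
    for sep in (",", "\t", ";"):
        if sep in line:
            return [c.strip() for c in line.split(sep)]
    return line.split()


def read_chromatogram(path, sample_id: str, wavelength: str) -> Chromatogram:
    """Read a two-column delimited text chromatogram.

    The delimiter (comma, tab, semicolon or whitespace) is auto-detected
    and a single header row is tolerated.  Structural problems raise
    :class:`ChromatogramStructureError` naming the first offending row;
    non-numeric cells raise :class:`ChromatogramParseError` with the line
    number.
    """
    path = Path(path)
    times: list[float] = []
    intens: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = _split_row(line)
            if len(cells) < 2:
                raise ChromatogramParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(cells)}"
                )
            if not (_NUMBER.match(cells[0]) and _NUMBER.match(cells[1])):
                if not times and lineno <= 2:
                    continue  # header row
                raise ChromatogramParseError(
                    f"{path}: line {lineno}: non-numeric cell in {cells[:2]!r}"
                )
            times.append(float(cells[0]))
            intens.append(float(cells[1]))
    return Chromatogram(sample_id, wavelength, np.array(times), np.array(intens))


def write_chromatogram(chrom: Chromatogram, path) -> Path:
    """Write ``chrom`` as comma-delimited text at full float precision.

    The written file round-trips losslessly through
    :func:`read_chromatogram`.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time_min,intensity\n")
        for t, v in zip(chrom.times, chrom.intensities):
            fh.write(f"{float(t)!r},{float(v)!r}\n")
    return path


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    origin: str
    paths: Mapping[str, Path] = field(default_factory=dict)


@dataclass(frozen=True)
class StudyManifest:
    """Sample records plus the list of detection channels of a study."""

    samples: tuple
    channels: tuple

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def origins(self) -> dict[str, str]:
        return {s.sample_id: s.origin for s in self.samples}


@dataclass
class Study:
    """A loaded (or simulated) study: manifest plus all chromatograms.

    ``chromatograms`` maps ``(sample_id, channel)`` to a
    :class:`Chromatogram`; completeness over samples x channels is
    guaranteed at construction.
    """

    manifest: StudyManifest
    chromatograms: dict

    def __post_init__(self) -> None:
        missing = [
            (s.sample_id, ch)
            for s in self.manifest.samples
            for ch in self.manifest.channels
            if (s.sample_id, ch) not in self.chromatograms
        ]
        if missing:
            raise StudyError(f"missing chromatograms for {missing}")

    def channel_traces(self, channel: str) -> dict[str, Chromatogram]:
        """All traces of one channel keyed by sample id, in manifest order."""
        return {
            sid: self.chromatograms[(sid, channel)]
            for sid in self.manifest.sample_ids
        }


def read_manifest(manifest_path) -> StudyManifest:
    """Parse a manifest table (sample_id, origin, path_<channel>...)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep=None, engine="python")
    table.columns = [c.strip() for c in table.columns]
    if "sample_id" not in table.columns or "origin" not in table.columns:
        raise StudyError(
            f"{manifest_path}: manifest needs 'sample_id' and 'origin' columns, "
            f"got {list(table.columns)}"
        )
    channels = tuple(
        c[len("path_"):] for c in table.columns if c.startswith("path_")
    )
    if not channels:
        raise StudyError(f"{manifest_path}: no path_<channel> columns found")
    ids = table["sample_id"].astype(str)
    dupes = ids[ids.duplicated()].tolist()
    if dupes:
        raise StudyError(f"{manifest_path}: duplicate sample ids {sorted(set(dupes))}")
    root = manifest_path.parent
    samples = []
    for _, row in table.iterrows():
        paths = {}
        for ch in channels:
            cell = row[f"path_{ch}"]
            if pd.isna(cell) or not str(cell).strip():
                raise StudyError(
                    f"sample {row['sample_id']} has no file for channel {ch} nm"
                )
            p = Path(str(cell).strip())
            paths[ch] = p if p.is_absolute() else root / p
        samples.append(SampleRecord(str(row["sample_id"]), str(row["origin"]), paths))
    return StudyManifest(tuple(samples), channels)


def load_study(manifest_path) -> Study:
    """Load and validate every chromatogram referenced by a manifest.

    Every sample must provide a readable trace for every channel; a
    missing file raises :class:`StudyError` naming the sample and
    wavelength.
    """
    manifest = read_manifest(manifest_path)
    chroms = {}
    for rec in manifest.samples:
        for ch in manifest.channels:
            path = rec.paths[ch]
            if not path.exists():
                raise StudyError(
                    f"sample {rec.sample_id}, channel {ch} nm: file not found: {path}"
                )
            chroms[(rec.sample_id, ch)] = read_chromatogram(path, rec.sample_id, ch)
    return Study(manifest, chroms)


def two_group_labels(manifest: StudyManifest) -> tuple:
    """Return the two origin labels of a discrimination study.

    Raises :class:`StudyError` unless exactly two distinct origin labels
    are present.
    """
    groups = sorted({s.origin for s in manifest.samples})
    if len(groups) != 2:
        raise StudyError(
            f"discrimination analyses need exactly two origin groups, got {groups}"
        )
    return tuple(groups)
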