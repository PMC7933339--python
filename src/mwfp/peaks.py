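"""Peak detection, integration, and cross-sample peak matching.

The processing chain is deliberately the simplest auditable one:

* baseline: a rolling-minimum envelope smoothed by a moving average of
  the same window, subtracted from the trace;
* detection: local maxima above a height threshold with topographic
  prominence above a prominence threshold;
* integration: valley-to-valley trapezoids, with the valley between two
  adjacent apexes placed at the intensity minimum of the interval
  between them; the search interval is capped at ``max_halfwidth``
  minutes on either side of the apex (trace ends bound the outermost
  peaks), so isolated peaks are not integrated across long stretches of
  residual baseline;
* matching: peaks pooled over samples, sorted by retention time, and
  grouped greedily — an apex joins the current group while it stays
  within the tolerance of the group's running mean or of the most
  recently added apex (chaining, which tolerates gradual retention
  drift); otherwise a new group starts.

Groups present in at least ``presence_fraction`` of the samples are kept
(1.0 keeps only peaks shared by every sample).  If one sample contributes
several peaks to a group their areas are summed, so matching never
creates or destroys area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .exceptions import EmptyMatrixError, MWFPError
from .io import Chromatogram


@dataclass(frozen=True)
class Peak:
    """One integrated chromatographic peak."""

    apex_rt: float
    start_rt: float
    end_rt: float
    area: float
    height: float

    def __post_init__(self) -> None:
        if not (self.start_rt < self.apex_rt < self.end_rt):
            raise MWFPError(
                f"peak boundaries must bracket the apex: "
                f"{self.start_rt} < {self.apex_rt} < {self.end_rt} fails"
            )
        if self.area <= 0 or self.height <= 0:
            raise MWFPError("peak area and height must be positive")


@dataclass
class FingerprintMatrix:
    """Samples x matched-peak-groups table of areas for one channel.

    ``peak_rts`` holds the strictly increasing mean apex retention times
    of the matched groups; ``areas`` is the n_samples x n_peaks matrix.
    With ``presence_fraction=1`` (co-possessing peaks) every entry is
    strictly positive.
    """

    sample_ids: list
    peak_rts: np.ndarray
    areas: np.ndarray
    channel: str = "unknown"

    def __post_init__(self) -> None:
        self.peak_rts = np.asarray(self.peak_rts, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.sample_ids), self.peak_rts.size):
            raise MWFPError(
                f"areas shape {self.areas.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {self.peak_rts.size} peaks"
            )
        if self.peak_rts.size and np.any(np.diff(self.peak_rts) <= 0):
            raise MWFPError("peak retention times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_rts.size)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{rt:.3f}" for rt in self.peak_rts]
        return pd.DataFrame(self.areas, index=list(self.sample_ids), columns=cols)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            i = list(self.sample_ids).index(sample_id)
        except ValueError:
            raise MWFPError(f"unknown sample id {sample_id!r}") from None
        return self.areas[i]

    def write(self, path) -> Path:
        path = Path(path)
        frame = self.to_frame()
        frame.index.name = "sample_id"
        frame.to_csv(path)
        return path

    @classmethod
    def read(cls, path, channel: str = "unknown") -> "FingerprintMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            sample_ids=[str(i) for i in frame.index],
            peak_rts=np.array([float(c) for c in frame.columns]),
            areas=frame.to_numpy(dtype=float),
            channel=channel,
        )


def subtract_baseline(chrom: Chromatogram, window: float = 1.5) -> Chromatogram:
    """Subtract a rolling-minimum baseline smoothed over ``window`` minutes.

    The baseline is the rolling minimum over the window, smoothed by a
    moving average of the same width; output intensities may dip slightly
    below zero at noise level.  ``window`` must span at least 3 grid steps.
    """
    if window <= 0:
        raise MWFPError(f"baseline window must be positive, got {window}")
    size = int(round(window / chrom.step))
    if size < 3:
        raise MWFPError(
            f"baseline window {window} min spans {size} grid steps; need >= 3"
        )
    floor = minimum_filter1d(chrom.intensities, size=size, mode="nearest")
    baseline = uniform_filter1d(floor, size=size, mode="nearest")
    return chrom.with_intensities(chrom.intensities - baseline)


def detect_peaks(
    chrom: Chromatogram,
    min_height: float = 0.5,
    min_prominence: float = 0.3,
    max_halfwidth: float = 0.6,
) -> list:
    """Detect and integrate peaks; returns them in retention-time order.

    Local maxima exceeding ``min_height`` with topographic prominence of
    at least ``min_prominence`` become apexes.  The boundary on each
    side of an apex sits at the intensity minimum of the interval
    towards the neighbouring apex (or trace end), with the search capped
    at ``max_halfwidth`` minutes from the apex.  Areas are trapezoidal
    integrals over those valley-to-valley windows.  An empty list is a
    valid result.
    """
    if min_height < 0 or min_prominence < 0:
        raise MWFPError("detection thresholds must be non-negative")
    if max_halfwidth <= 0:
        raise MWFPError("max_halfwidth must be positive")
    x = chrom.intensities
    t = chrom.times
    hw = max(2, int(round(max_halfwidth / chrom.step)))
    apexes, _ = find_peaks(x, height=min_height, prominence=min_prominence)
    if apexes.size == 0:
        return []
    peaks = []
    for k, apex in enumerate(apexes):
        left_stop = apexes[k - 1] if k > 0 else 0
        left_stop = max(left_stop, apex - hw)
        right_stop = apexes[k + 1] if k + 1 < apexes.size else x.size - 1
        right_stop = min(right_stop, apex + hw)
        lo = left_stop + int(np.argmin(x[left_stop : apex + 1]))
        hi = apex + int(np.argmin(x[apex : right_stop + 1]))
        if hi - lo < 2:
            continue
        area = float(np.trapezoid(x[lo : hi + 1], t[lo : hi + 1]))
        if area <= 0:
            continue
        peaks.append(
            Peak(
                apex_rt=float(t[apex]),
                start_rt=float(t[lo]),
                end_rt=float(t[hi]),
                area=area,
                height=float(x[apex]),
            )
        )
    return peaks


@dataclass
class _Group:
    rts: list = field(default_factory=list)
    members: list = field(default_factory=list)  # (sample_id, Peak)

    @property
    def mean_rt(self) -> float:
        return float(np.mean(self.rts))


def match_peaks(
    peak_lists: Mapping[str, Sequence[Peak]],
    rt_tolerance: float = 0.2,
    presence_fraction: float = 1.0,
    channel: str = "unknown",
) -> FingerprintMatrix:
    """Cluster peaks across samples on apex retention time.

    Parameters
    ----------
    peak_lists : mapping of sample_id -> peaks
        Per-sample detected peaks (at least 2 samples).
    rt_tolerance : float
        An apex joins the current group while it lies within this many
        minutes of the group's running mean or of the last apex added to
        it; otherwise a new group starts.
    presence_fraction : float in (0, 1]
        Keep groups detected in at least this fraction of the samples;
        1.0 keeps only peaks common to every sample.
    """
    if len(peak_lists) < 2:
        raise MWFPError("peak matching needs at least 2 samples")
    if rt_tolerance <= 0:
        raise MWFPError("rt_tolerance must be positive")
    if not (0 < presence_fraction <= 1):
        raise MWFPError("presence_fraction must lie in (0, 1]")
    sample_ids = list(peak_lists)
    pool = sorted(
        ((p.apex_rt, sid, p) for sid, plist in peak_lists.items() for p in plist),
        key=lambda item: (item[0], sample_ids.index(item[1])),
    )
    groups: list[_Group] = []
    for rt, sid, peak in pool:
        if groups and (
            rt - groups[-1].mean_rt <= rt_tolerance
            or rt - groups[-1].rts[-1] <= rt_tolerance
        ):
            groups[-1].rts.append(rt)
            groups[-1].members.append((sid, peak))
        else:
            groups.append(_Group(rts=[rt], members=[(sid, peak)]))
    n = len(sample_ids)
    kept = [
        g
        for g in groups
        if len({sid for sid, _ in g.members}) >= presence_fraction * n - 1e-12
    ]
    if not kept:
        raise EmptyMatrixError(
            "no peak group satisfies the presence requirement; "
            "consider increasing rt_tolerance or lowering presence_fraction"
        )
    kept.sort(key=lambda g: g.mean_rt)
    areas = np.zeros((n, len(kept)))
    for j, g in enumerate(kept):
        for sid, peak in g.members:
            areas[sample_ids.index(sid), j] += peak.area
    return FingerprintMatrix(
        sample_ids=sample_ids,
        peak_rts=np.array([g.mean_rt for g in kept]),
        areas=areas,
        channel=channel,
    )


def write_peak_table(peak_lists: Mapping[str, Sequence[Peak]], path) -> Path:
    """Write per-sample peak tables as one delimited text file."""
    rows = [
        {
            "sample_id": sid,
            "apex_rt": p.apex_rt,
            "start_rt": p.start_rt,
            "end_rt": p.end_rt,
            "area": p.area,
            "height": p.height,
        }
        for sid, plist in peak_lists.items()
        for p in plist
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
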