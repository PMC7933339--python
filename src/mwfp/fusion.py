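"""Multi-wavelength fusion profiling (MWFP).

A fused chromatogram is the projection of a sample's detector traces
along the wavelength axis: the point-wise (optionally weighted) sum of
the single-wavelength traces on their common time grid.  Fusion happens
at the signal level, before peak detection, so a compound invisible at
one wavelength but strong at another still contributes one coherent
fused peak.

Fusion is linear: additive and homogeneous in every channel, and
invariant to channel order.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import GridMismatchError, MWFPError
from .io import FUSED, Chromatogram, Study
from .peaks import (
    FingerprintMatrix,
    detect_peaks,
    match_peaks,
    subtract_baseline,
)

GRID_RTOL = 1e-6


def fuse(
    channels: Iterable[Chromatogram],
    weights: Sequence[float] | None = None,
) -> Chromatogram:
    """Sum the traces of one sample recorded at several wavelengths.

    All traces must share the sample id and (to 1e-6 relative) the time
    grid; no resampling is performed.  ``weights`` (default all ones)
    allows per-channel weighting.
    """
    traces = list(channels)
    if len(traces) < 2:
        raise MWFPError(f"fusion needs at least 2 channels, got {len(traces)}")
    ids = {c.sample_id for c in traces}
    if len(ids) != 1:
        raise MWFPError(f"cannot fuse traces of different samples: {sorted(ids)}")
    ref = traces[0]
    scale = max(abs(float(ref.times[0])), abs(float(ref.times[-1])), 1e-30)
    for c in traces[1:]:
        if len(c) != len(ref) or not np.allclose(
            c.times, ref.times, rtol=GRID_RTOL, atol=GRID_RTOL * scale
        ):
            raise GridMismatchError(
                f"sample {ref.sample_id}: channel {c.wavelength} grid differs "
                f"from channel {ref.wavelength}; fusion does not resample"
            )
    if weights is None:
        weights = np.ones(len(traces))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(traces),):
        raise MWFPError(
            f"need one weight per channel ({len(traces)}), got {weights.shape}"
        )
    summed = np.zeros(len(ref))
    for w, c in zip(weights, traces):
        summed = summed + w * c.intensities
    return Chromatogram(
        sample_id=ref.sample_id,
        wavelength=FUSED,
        times=ref.times,
        intensities=summed,
        sources=tuple(sorted(str(c.wavelength) for c in traces)),
    )


class PeakParams:
    """Thresholds of the baseline/detection/matching chain.

    Defaults suit the synthetic study: baseline window 1.5 min (much
    wider than a peak, much shorter than the drift period), detection
    thresholds well above the noise floor, matching tolerance about four
    times the peak sigma.
    """

    def __init__(
        self,
        baseline_window: float = 1.5,
        min_height: float = 0.5,
        min_prominence: float = 0.3,
        max_halfwidth: float = 0.6,
        rt_tolerance: float = 0.2,
        presence_fraction: float = 1.0,
    ) -> None:
        self.baseline_window = baseline_window
        self.min_height = min_height
        self.min_prominence = min_prominence
        self.max_halfwidth = max_halfwidth
        self.rt_tolerance = rt_tolerance
        self.presence_fraction = presence_fraction

    def asdict(self) -> dict:
        return dict(vars(self))

    def __repr__(self) -> str:  # pragma: no cover - convenience
        args = ", ".join(f"{k}={v!r}" for k, v in vars(self).items())
        return f"PeakParams({args})"


def fingerprint_channel(
    traces: Mapping[str, Chromatogram],
    params: PeakParams | None = None,
    channel: str = "unknown",
) -> FingerprintMatrix:
    """Baseline-correct, detect and match the peaks of one channel."""
    params = params or PeakParams()
    peak_lists = {
        sid: detect_peaks(
            subtract_baseline(tr, params.baseline_window),
            min_height=params.min_height,
            min_prominence=params.min_prominence,
            max_halfwidth=params.max_halfwidth,
        )
        for sid, tr in traces.items()
    }
    return match_peaks(
        peak_lists,
        rt_tolerance=params.rt_tolerance,
        presence_fraction=params.presence_fraction,
        channel=channel,
    )


def fuse_study(study: Study, weights: Sequence[float] | None = None) -> dict:
    """Fused trace for every sample of a study, keyed by sample id."""
    return {
        sid: fuse(
            [study.chromatograms[(sid, ch)] for ch in study.manifest.channels],
            weights=weights,
        )
        for sid in study.manifest.sample_ids
    }


def build_fingerprints(
    study: Study,
    params: PeakParams | None = None,
    weights: Sequence[float] | None = None,
    include_fused: bool = True,
) -> dict:
    """Fingerprint matrices for every single channel plus the fused one.

    Returns a dict mapping channel tag (``"203"``, ..., ``"fused"``) to
    :class:`FingerprintMatrix`.  With the default three-wavelength setup
    this yields four matrices.  If the study has a single channel the
    fused matrix is omitted.
    """
    params = params or PeakParams()
    matrices = {
        ch: fingerprint_channel(study.channel_traces(ch), params, channel=ch)
        for ch in study.manifest.channels
    }
    if include_fused and len(study.manifest.channels) >= 2:
        fused_traces = fuse_study(study, weights=weights)
        matrices[FUSED] = fingerprint_channel(fused_traces, params, channel=FUSED)
    return matrices
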