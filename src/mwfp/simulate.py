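"""Synthetic two-origin HPLC-DAD studies with known ground truth.

The generator emulates a 32-batch *P. notoginseng* origin study
(15 Sichuan + 17 Yunnan samples by default) recorded at 203, 270 and
325 nm.  Each of the 33 library compounds contributes a Gaussian peak at
its retention time whose area equals content (mg/g) times a per-
wavelength response factor; white detector noise and a slow sinusoidal
baseline drift are added on top.

Compound classes carry distinct spectral signatures: saponin-like
compounds respond at 203 nm only, flavonoid-like ones at 270 and
325 nm, amino-acid-like ones at 270 nm.  Origin effects are spread over
all three classes, so every single-wavelength fingerprint is blind to
part of the discriminating signal while the fused fingerprint sees all
of it — the property the fusion analysis is meant to demonstrate.

Contents are drawn log-normally: a per-sample global factor (overall
batch strength, shared by all compounds) times a per-compound
idiosyncratic factor, around origin-specific means.  For the five named
saponins the origin means are taken from the bundled content panel of
the real study; dispersions are calibrated so pooled per-compound RSDs
land in the panel's 19-28% range.  Origin effect sizes of the unnamed
compounds are declared generator configuration, not literature values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .exceptions import MWFPError
from .io import (
    Chromatogram,
    SampleRecord,
    Study,
    StudyManifest,
    write_chromatogram,
)
from .peaks import FingerprintMatrix

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class CompoundSpec:
    """One library compound of the synthetic study.

    ``response`` maps channel tag to area units per mg/g (zero = no
    absorbance at that wavelength); ``mean_content`` and ``rsd_percent``
    map origin label to the mean content (mg/g) and the idiosyncratic
    (per-compound) RSD of that origin.
    """

    name: str
    rt: float
    response: Mapping[str, float]
    mean_content: Mapping[str, float]
    rsd_percent: Mapping[str, float]
    sigma: float = 0.05
    discriminating: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise MWFPError(f"{self.name}: peak sigma must be positive")
        resp = dict(self.response)
        if any(v < 0 for v in resp.values()) or not any(v > 0 for v in resp.values()):
            raise MWFPError(
                f"{self.name}: response factors must be >= 0 with one positive"
            )
        if any(v <= 0 for v in self.mean_content.values()):
            raise MWFPError(f"{self.name}: mean contents must be positive")
        object.__setattr__(self, "response", resp)
        object.__setattr__(self, "mean_content", dict(self.mean_content))
        object.__setattr__(self, "rsd_percent", dict(self.rsd_percent))


_S = datasets.SICHUAN
_Y = datasets.YUNNAN

#: Sichuan-to-Yunnan content factor of unnamed discriminating saponin-like
#: compounds, and Yunnan up-shifts of the flavonoid/amino-acid classes.
SAPONIN_FILLER_FACTOR = 0.72
FLAVONOID_FACTOR = 1.67
AMINO_FACTOR = 1.45

#: Idiosyncratic per-compound RSD (percent) within an origin.
IDIO_RSD = 8.0


def _spec(name, rt, channel_resp, mean_s, mean_y, disc):
    return CompoundSpec(
        name=name,
        rt=rt,
        response=channel_resp,
        mean_content={_S: mean_s, _Y: mean_y},
        rsd_percent={_S: IDIO_RSD, _Y: IDIO_RSD},
        discriminating=disc,
    )


def default_library() -> tuple:
    """The default 33-compound library.

    Five compounds carry the names of the investigated saponins with
    origin means computed from the bundled content panel (retention
    times of NG-R1/NG-R2 are plausible synthetic placements; the others
    follow the qualitative peak assignment of the real study).  Fifteen
    compounds are flagged as origin-discriminating: the four saponins
    whose panel contents differ between origins plus declared effects on
    seven unnamed saponin-like, two flavonoid-like and two
    amino-acid-like compounds.
    """
    panel = datasets.load_saponin_contents()
    by_origin = panel.groupby("origin")[list(datasets.SAPONINS)].mean()
    m_s, m_y = by_origin.loc[_S], by_origin.loc[_Y]

    def saponin(name, rt, rf, disc):
        return _spec(name, rt, {"203": rf}, m_s[name], m_y[name], disc)

    lib = [
        # investigated saponins (respond at 203 nm only)
        saponin("NG-R1", 17.2, 1.2, False),  # panel origins do not differ
        saponin("G-Rg1", 18.3, 0.35, True),
        saponin("G-Rb1", 20.4, 0.40, True),
        saponin("NG-R2", 23.2, 6.0, True),
        saponin("G-Rd", 24.0, 1.2, True),
        # further known saponins, no origin effect
        _spec("G-Rf", 21.0, {"203": 1.5}, 4.0, 4.0, False),
        _spec("G-Rc", 22.5, {"203": 1.5}, 6.0, 6.0, False),
        # flavonoids (270 + 325 nm), higher in Yunnan
        _spec("quercetin-diglucoside", 13.9, {"270": 4.0, "325": 3.0},
              1.2, 1.2 * FLAVONOID_FACTOR, True),
        _spec("rutin", 16.7, {"270": 4.0, "325": 3.0},
              1.2, 1.2 * FLAVONOID_FACTOR, True),
        # amino acids (270 nm), higher in Yunnan
        _spec("proline", 3.4, {"270": 3.0}, 2.0, 2.0 * AMINO_FACTOR, True),
        _spec("tryptophan", 8.2, {"270": 3.0}, 2.0, 2.0 * AMINO_FACTOR, True),
    ]
    # unnamed saponin-like compounds with an origin effect
    for rt, mean in zip(
        (5.1, 9.7, 12.4, 19.4, 27.1, 30.5, 36.1),
        (5.0, 8.0, 3.0, 12.0, 6.0, 4.5, 7.0),
    ):
        lib.append(
            _spec(f"saponin-{rt:g}", rt, {"203": 1.5},
                  mean, mean * SAPONIN_FILLER_FACTOR, True)
        )
    # unnamed saponin-like compounds without an origin effect
    for rt, mean in zip(
        (6.3, 11.2, 15.3, 25.6, 28.8, 32.2, 34.0, 38.4, 40.7),
        (3.0, 7.0, 4.0, 9.0, 5.0, 3.5, 6.0, 4.5, 8.0),
    ):
        lib.append(_spec(f"saponin-{rt:g}", rt, {"203": 1.5}, mean, mean, False))
    # unnamed flavonoid-like and amino-acid-like compounds, no effect
    for rt in (14.8, 26.4, 42.9):
        lib.append(
            _spec(f"flavonoid-{rt:g}", rt, {"270": 3.5, "325": 2.5},
                  1.5, 1.5, False)
        )
    for rt in (4.3, 7.1, 10.4):
        lib.append(_spec(f"amino-{rt:g}", rt, {"270": 2.5}, 2.5, 2.5, False))
    lib.sort(key=lambda c: c.rt)
    return tuple(lib)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Declared conditions of a synthetic study.

    ``seed`` is mandatory: every artifact the generator produces is a
    deterministic function of the configuration.  ``dispersion_scale``
    multiplies both content dispersion components (0 freezes contents at
    their origin means); ``global_content_cv`` is the CV (percent) of
    the per-sample overall-strength factor shared by all compounds.
    """

    seed: int
    group_sizes: tuple = (15, 17)
    group_names: tuple = (datasets.SICHUAN, datasets.YUNNAN)
    library: tuple = field(default_factory=default_library)
    channels: tuple = ("203", "270", "325")
    grid_step: float = 0.01
    t_min: float = 0.0
    t_max: float = 55.0
    noise_sd: float = 0.02
    drift_amplitude: float = 0.5
    drift_period: float = 18.0
    rt_jitter_sd: float = 0.02
    global_content_cv: float = 10.0
    dispersion_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 2:
            raise MWFPError("each origin group needs at least 2 samples")
        if len(self.group_sizes) != 2 or len(self.group_names) != 2:
            raise MWFPError("the study design has exactly two origin groups")
        if self.grid_step <= 0 or self.t_max <= self.t_min:
            raise MWFPError("invalid time grid configuration")
        object.__setattr__(self, "library", tuple(self.library))
        missing = {
            origin
            for c in self.library
            for origin in self.group_names
            if origin not in c.mean_content
        }
        if missing:
            raise MWFPError(f"library lacks mean contents for origins {missing}")

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def sample_ids(self) -> list:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    @property
    def origins(self) -> list:
        out = []
        for name, size in zip(self.group_names, self.group_sizes):
            out.extend([name] * size)
        return out

    def noise_free(self) -> "SyntheticStudyConfig":
        """Copy with all noise sources off (contents frozen at means)."""
        return dataclasses.replace(
            self,
            noise_sd=0.0,
            drift_amplitude=0.0,
            rt_jitter_sd=0.0,
            dispersion_scale=0.0,
        )

    def grid(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.grid_step)) + 1
        return self.t_min + self.grid_step * np.arange(n)


@dataclass
class GroundTruth:
    """True contents, origin labels, and the discriminating set."""

    contents: pd.DataFrame  # samples x compounds, mg/g
    origins: pd.Series  # sample -> origin label
    discriminating: list  # compound names with an injected origin effect
    rt_jitter: pd.DataFrame  # samples x compounds, minutes

    def __post_init__(self) -> None:
        if (self.contents <= 0).any().any():
            raise MWFPError("ground-truth contents must be positive")


def _lognormal_factor(rng, cv_percent: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal factor with the given CV."""
    if cv_percent <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p((cv_percent / 100.0) ** 2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def sample_contents(
    config: SyntheticStudyConfig, rng: np.random.Generator
) -> GroundTruth:
    """Draw true contents and retention jitter for every sample.

    content = origin mean x global batch factor x idiosyncratic factor,
    both factors unit-mean log-normal.  Deterministic given the rng
    state.
    """
    lib = config.library
    names = [c.name for c in lib]
    n, p = config.n_samples, len(lib)
    scale = config.dispersion_scale
    global_factor = _lognormal_factor(
        rng, scale * config.global_content_cv, n
    )
    contents = np.empty((n, p))
    jitter = rng.normal(0.0, config.rt_jitter_sd, size=(n, p)) if (
        config.rt_jitter_sd > 0
    ) else np.zeros((n, p))
    origins = config.origins
    for j, comp in enumerate(lib):
        idio = np.column_stack(
            [
                _lognormal_factor(rng, scale * comp.rsd_percent[origin], 1)
                for origin in origins
            ]
        ).ravel()
        means = np.array([comp.mean_content[o] for o in origins])
        contents[:, j] = means * global_factor * idio
    ids = config.sample_ids
    return GroundTruth(
        contents=pd.DataFrame(contents, index=ids, columns=names),
        origins=pd.Series(origins, index=ids, name="origin"),
        discriminating=[c.name for c in lib if c.discriminating],
        rt_jitter=pd.DataFrame(jitter, index=ids, columns=names),
    )


def render_chromatograms(
    truth: GroundTruth,
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
) -> dict:
    """Render every (sample, channel) trace from the ground truth.

    Each compound contributes a Gaussian of area content x response
    factor at its (jittered) retention time; a slow positive sinusoidal
    drift and white Gaussian noise are added.  Returns a dict keyed by
    ``(sample_id, channel)``.
    """
    grid = config.grid()
    lib = config.library
    chroms = {}
    for sid in truth.contents.index:
        row = truth.contents.loc[sid]
        jit = truth.rt_jitter.loc[sid]
        signals = {ch: np.zeros(grid.size) for ch in config.channels}
        for comp in lib:
            rt = comp.rt + jit[comp.name]
            lo = np.searchsorted(grid, rt - 6 * comp.sigma)
            hi = np.searchsorted(grid, rt + 6 * comp.sigma)
            if hi <= lo:
                continue
            shape = np.exp(
                -0.5 * ((grid[lo:hi] - rt) / comp.sigma) ** 2
            ) / (comp.sigma * SQRT_2PI)
            for ch in config.channels:
                rf = comp.response.get(ch, 0.0)
                if rf > 0:
                    signals[ch][lo:hi] += row[comp.name] * rf * shape
        for ch in config.channels:
            trace = signals[ch]
            if config.drift_amplitude > 0:
                phase = rng.uniform(0.0, 2.0 * np.pi)
                trace = trace + config.drift_amplitude * 0.5 * (
                    1.0 + np.sin(2.0 * np.pi * grid / config.drift_period + phase)
                )
            if config.noise_sd > 0:
                trace = trace + rng.normal(0.0, config.noise_sd, grid.size)
            chroms[(sid, ch)] = Chromatogram(
                sample_id=sid, wavelength=ch, times=grid, intensities=trace
            )
    return chroms


def simulate_study(config: SyntheticStudyConfig):
    """Generate a complete in-memory study.

    Returns ``(study, truth)`` where ``study`` is an :class:`mwfp.io.Study`
    ready for the fingerprint pipeline.
    """
    rng = np.random.default_rng(config.seed)
    truth = sample_contents(config, rng)
    chroms = render_chromatograms(truth, config, rng)
    samples = tuple(
        SampleRecord(sid, origin, {})
        for sid, origin in zip(config.sample_ids, config.origins)
    )
    manifest = StudyManifest(samples, tuple(config.channels))
    return Study(manifest, chroms), truth


def generate_study(config: SyntheticStudyConfig, outdir):
    """Generate a study and write it to disk in the text formats of
    :mod:`mwfp.io` (chromatogram files, ``manifest.csv``,
    ``ground_truth.csv``).  Returns ``(study, truth)``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study, truth = simulate_study(config)
    rows = []
    for rec in study.manifest.samples:
        row = {"sample_id": rec.sample_id, "origin": rec.origin}
        for ch in study.manifest.channels:
            fname = f"{rec.sample_id}_{ch}.csv"
            write_chromatogram(
                study.chromatograms[(rec.sample_id, ch)], outdir / fname
            )
            row[f"path_{ch}"] = fname
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    gt = truth.contents.copy()
    gt.insert(0, "origin", truth.origins)
    gt.index.name = "sample_id"
    gt.to_csv(outdir / "ground_truth.csv")
    (outdir / "discriminating.txt").write_text(
        "\n".join(truth.discriminating) + "\n"
    )
    return study, truth


def discriminating_rts(config: SyntheticStudyConfig) -> np.ndarray:
    """Retention times of the injected discriminating compounds."""
    return np.array(
        sorted(c.rt for c in config.library if c.discriminating)
    )


def estimate_contents(
    matrix: FingerprintMatrix,
    library: Sequence[CompoundSpec],
    compounds: Sequence[str] | None = None,
    rt_tolerance: float = 0.2,
) -> pd.DataFrame:
    """Estimate contents (mg/g) from matched peak areas.

    For every requested compound with a positive response factor at the
    matrix's channel, the matched peak group nearest the compound's
    retention time (within ``rt_tolerance``) is divided by the response
    factor.  Compounds without a matched peak are skipped.
    """
    by_name = {c.name: c for c in library}
    if compounds is None:
        compounds = [c.name for c in library]
    out = {}
    for name in compounds:
        comp = by_name[name]
        rf = comp.response.get(matrix.channel, 0.0)
        if rf <= 0 or matrix.n_peaks == 0:
            continue
        j = int(np.argmin(np.abs(matrix.peak_rts - comp.rt)))
        if abs(matrix.peak_rts[j] - comp.rt) > rt_tolerance:
            continue
        out[name] = matrix.areas[:, j] / rf
    return pd.DataFrame(out, index=list(matrix.sample_ids))
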