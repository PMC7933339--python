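"""Calibration, concentration computation and content statistics.

Covers the quantitative stage of the workflow: ordinary-least-squares
calibration lines (with R2 and a 3.3*sigma/slope detection limit),
conversion of solution concentration (mg/mL) to content of the raw
material (mg/g) via the extraction ratio, per-compound mean and RSD%
summaries, and Welch two-sample t-tests for origin differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MWFPError

#: Default extraction: 0.500 g of powdered root in 20 mL of solvent, so
#: 1 mg/mL in solution corresponds to 40 mg/g of raw material.
SAMPLE_MASS_G = 0.5
EXTRACT_VOLUME_ML = 20.0


@dataclass(frozen=True)
class CalibrationCurve:
    """A linear response curve of one reference standard."""

    compound: str
    slope: float
    intercept: float
    r2: float
    lod: float  # mg/mL, 3.3 * residual sd / slope

    def concentration(self, response) -> np.ndarray:
        """Invert the curve: response -> solution concentration (mg/mL)."""
        return (np.asarray(response, dtype=float) - self.intercept) / self.slope


def fit_calibration(conc, response, compound: str = "") -> CalibrationCurve:
    """Ordinary least squares line through >= 3 calibration points.

    Rejects degenerate designs (fewer than 3 points, no concentration
    spread) and non-positive slopes.  LOD uses the 3.3*sigma/slope
    convention with the residual standard deviation (ddof=2).
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.size < 3 or conc.shape != response.shape:
        raise MWFPError("calibration needs >= 3 (concentration, response) pairs")
    if np.ptp(conc) <= 0:
        raise MWFPError("calibration concentrations must span a range")
    dc = conc - conc.mean()
    slope = float(dc @ (response - response.mean()) / (dc @ dc))
    intercept = float(response.mean() - slope * conc.mean())
    if slope <= 0:
        raise MWFPError(f"calibration slope must be positive, got {slope}")
    fitted = slope * conc + intercept
    ss_res = float(((response - fitted) ** 2).sum())
    ss_tot = float(((response - response.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    sd_res = np.sqrt(ss_res / (conc.size - 2))
    return CalibrationCurve(
        compound=compound,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        lod=float(3.3 * sd_res / slope),
    )


def to_content(
    solution_conc,
    sample_mass: float = SAMPLE_MASS_G,
    extract_volume: float = EXTRACT_VOLUME_ML,
):
    """Convert solution concentration (mg/mL) to content (mg/g).

    content = concentration * extract_volume / sample_mass; with the
    default 0.500 g / 20 mL extraction the factor is 40.
    """
    if sample_mass <= 0 or extract_volume <= 0:
        raise MWFPError("sample mass and extract volume must be positive")
    return np.asarray(solution_conc, dtype=float) * extract_volume / sample_mass


def summary_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-compound mean and RSD% (sd with n-1 over mean, in percent).

    ``table`` holds one row per sample and one numeric column per
    compound.  Returns a 2-row frame indexed ``mean`` / ``rsd_percent``.
    """
    values = table.select_dtypes("number")
    if len(values) < 2:
        raise MWFPError("summary statistics need at least 2 samples")
    mean = values.mean()
    if np.any(mean == 0):
        raise MWFPError("RSD undefined for zero-mean compound(s)")
    rsd = 100.0 * values.std(ddof=1) / mean
    return pd.DataFrame({"mean": mean, "rsd_percent": rsd}).T


def group_difference(table: pd.DataFrame, labels) -> pd.Series:
    """Welch two-sample t-test p-value per compound.

    ``labels`` maps sample (table index) to one of exactly two groups,
    each with at least 2 samples.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    labels = labels.loc[table.index]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise MWFPError(f"need exactly two groups, got {groups}")
    a = table.loc[labels == groups[0]].select_dtypes("number")
    b = table.loc[labels == groups[1]].select_dtypes("number")
    if len(a) < 2 or len(b) < 2:
        raise MWFPError("each group needs at least 2 samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return pd.Series(np.atleast_1d(res.pvalue), index=a.columns, name="p_value")
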