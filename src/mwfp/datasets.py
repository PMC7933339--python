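"""Bundled reference tables of the 32-batch two-origin study.

Two small published tables of a 32-sample *Panax notoginseng*
origin-discrimination study (15 Sichuan + 17 Yunnan batches) ship with
the package:

* the contents of five saponins (G-Rb1, G-Rg1, G-Rd, NG-R1, NG-R2) in
  mg/g of raw material for every batch, and
* the per-batch ALQFM similarity report (Sm, Pm%, alpha, grade) at the
  three single wavelengths and for the fused fingerprint.

They serve as ground truth for the statistics and grading code and as
calibration anchors of the synthetic study generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SICHUAN = "Sichuan"
YUNNAN = "Yunnan"

SAPONINS = ("G-Rb1", "G-Rg1", "G-Rd", "NG-R1", "NG-R2")


def _read(name: str) -> pd.DataFrame:
    with resources.files("mwfp").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_saponin_contents() -> pd.DataFrame:
    """32 batches x 5 saponin contents (mg/g) with origin labels.

    Indexed by sample id; ``origin`` column plus one numeric column per
    compound.
    """
    return _read("notoginseng_saponin_contents.csv").set_index("sample_id")


def load_similarity_report() -> pd.DataFrame:
    """Published ALQFM report: per batch, (Sm, Pm, alpha, grade) x 4 channels.

    Columns are ``{sm,pm,alpha,grade}_{203,270,325,fused}`` plus
    ``origin``; indexed by sample id.
    """
    return _read("notoginseng_alqfm_report.csv").set_index("sample_id")
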