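"""End-to-end orchestration: simulate/load -> fingerprints -> ALQFM ->
chemometrics -> quantitation, with all tables written as delimited text.

The stages and their parameters mirror the library modules; the pipeline
only wires them together and collects a :class:`PipelineReport`.  Two
references are used on purpose:

* the ALQFM *report* scores every sample against the column-mean
  reference of its channel (the similarity-software convention), while
* the *origin-discrimination* scoring uses a designated benchmark
  sample as reference (by default the batch of median total fused area,
  i.e. a typical batch).  Scoring against the grand mean of a two-group
  study is structurally symmetric and cannot separate the groups by
  grade; scoring against a benchmark batch of one origin can, chiefly
  through the ratio-dispersion parameter alpha.

Before hierarchical clustering the fingerprint rows are normalised to
relative areas (unit total), the standard way to remove overall batch
strength before comparing compositional profiles; columns are then
autoscaled.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .alqfm import (
    DEFAULT_CRITERIA,
    DiscriminationCounts,
    GradeCriteria,
    evaluate_study,
    grade_discrimination,
    results_report,
)
from .chemometrics import (
    cut_clusters,
    hca,
    misassignment_count,
    oplsda,
    pca,
    _scale,
)
from .exceptions import MWFPError
from .fusion import PeakParams, build_fingerprints
from .io import FUSED, Study, load_study, two_group_labels
from .quantitation import group_difference, summary_stats
from .simulate import (
    SyntheticStudyConfig,
    estimate_contents,
    simulate_study,
)

log = logging.getLogger("mwfp")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Exactly one of ``synthetic`` (a :class:`SyntheticStudyConfig`) or
    ``manifest`` (path to a study manifest) must be set.
    """

    synthetic: SyntheticStudyConfig | None = None
    manifest: str | None = None
    peak_params: PeakParams = field(default_factory=PeakParams)
    criteria: GradeCriteria = DEFAULT_CRITERIA
    reference_mode: str = "mean"  # reference of the ALQFM report
    discrimination_reference: str = "median_total"  # or "sample:<id>" / "mean"
    grade_cutoff: int = 4
    n_orthogonal: int = 1
    scaling: str = "uv"
    n_pca_components: int = 2
    vip_threshold: float = 1.0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticStudyConfig(**raw["synthetic"])
        if "manifest" in raw:
            kwargs["manifest"] = raw["manifest"]
        if "peak_params" in raw:
            kwargs["peak_params"] = PeakParams(**raw["peak_params"])
        if "criteria" in raw:
            kwargs["criteria"] = GradeCriteria(
                **{k: tuple(v) for k, v in raw["criteria"].items()}
            )
        for key in (
            "reference_mode",
            "discrimination_reference",
            "grade_cutoff",
            "n_orthogonal",
            "scaling",
            "n_pca_components",
            "vip_threshold",
            "outdir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class PipelineReport:
    """All stage outputs of one pipeline run."""

    alqfm: pd.DataFrame  # long-format (sample, channel) similarity results
    alqfm_wide: pd.DataFrame  # report layout, one row per sample
    discrimination: dict  # channel -> DiscriminationCounts
    discrimination_reference: str | None
    hca_labels: pd.Series | None
    hca_misassignments: int | None
    pca_explained: np.ndarray
    oplsda_r2y: float | None
    vip: pd.DataFrame | None  # peak_rt, vip, flagged
    quant_contents: pd.DataFrame | None
    quant_summary: pd.DataFrame | None
    quant_pvalues: pd.Series | None
    matrices: dict
    channels: tuple


def _benchmark_sample(matrix) -> str:
    """A typical batch: the one of median total matched area.

    An extreme batch would shift every other sample's Pm far from 100
    and drown the grade in the quantitative band; the median batch keeps
    Pm centred so the discrimination is carried by profile dispersion.
    """
    totals = matrix.areas.sum(axis=1)
    rank = np.argsort(totals, kind="stable")
    return matrix.sample_ids[int(rank[len(rank) // 2])]


def run(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and (optionally) write every table."""
    if (config.synthetic is None) == (config.manifest is None):
        raise MWFPError("configure exactly one of 'synthetic' or 'manifest'")
    truth = None
    if config.synthetic is not None:
        log.info("simulating study (seed=%d)", config.synthetic.seed)
        study, truth = simulate_study(config.synthetic)
    else:
        study = load_study(config.manifest)
    return analyse(study, config, truth=truth)


def analyse(study: Study, config: PipelineConfig, truth=None) -> PipelineReport:
    log.info("peak parameters: %s", config.peak_params.asdict())
    log.info("grade criteria: %s", dataclasses.asdict(config.criteria))
    if len(study.manifest.channels) < 2:
        log.warning(
            "single-channel study: fusion skipped, single-channel analysis only"
        )
    matrices = build_fingerprints(study, config.peak_params)
    analysis_channel = FUSED if FUSED in matrices else study.manifest.channels[0]
    analysis_matrix = matrices[analysis_channel]

    # --- ALQFM similarity report (mean-of-samples reference) -------------
    results = evaluate_study(
        matrices, criteria=config.criteria, reference_mode=config.reference_mode
    )
    wide = results_report(results)

    # --- grade-based origin discrimination (benchmark reference) ---------
    origins = pd.Series(study.manifest.origins)
    discrimination: dict = {}
    ref_mode = None
    try:
        two_group_labels(study.manifest)
        has_two_groups = True
    except MWFPError:
        has_two_groups = False
        log.warning("origin labels are not two-group; discrimination skipped")
    if has_two_groups:
        if config.discrimination_reference == "median_total":
            ref_id = _benchmark_sample(analysis_matrix)
            ref_mode = f"sample:{ref_id}"
        elif config.discrimination_reference == "mean":
            ref_mode = "mean"
        else:
            ref_mode = config.discrimination_reference
        log.info("discrimination reference: %s", ref_mode)
        disc_results = evaluate_study(
            matrices, criteria=config.criteria, reference_mode=ref_mode
        )
        similar_group = (
            origins[ref_mode.split(":", 1)[1]]
            if ref_mode.startswith("sample:")
            else None
        )
        for ch in matrices:
            sub = disc_results[disc_results["channel"] == ch]
            grades = pd.Series(
                sub["grade"].to_numpy(), index=sub["sample_id"].to_numpy()
            )
            discrimination[ch] = grade_discrimination(
                grades,
                origins,
                cutoff=config.grade_cutoff,
                similar_group=similar_group,
            )

    # --- chemometrics on the analysis matrix -----------------------------
    hca_labels = hca_errors = None
    rel = analysis_matrix.areas / analysis_matrix.areas.sum(axis=1, keepdims=True)
    Z, _, _ = _scale(rel, "uv")
    if has_two_groups:
        dendro = hca(Z)
        labels = cut_clusters(dendro, 2)
        hca_labels = pd.Series(labels, index=list(analysis_matrix.sample_ids))
        hca_errors = misassignment_count(
            labels, origins.loc[list(analysis_matrix.sample_ids)]
        )
    n_comp = min(
        config.n_pca_components,
        analysis_matrix.n_samples - 1,
        analysis_matrix.n_peaks,
    )
    pca_model = pca(analysis_matrix.areas, n_components=n_comp, scaling=config.scaling)
    r2y = None
    vip_table = None
    if has_two_groups:
        model = oplsda(
            analysis_matrix.areas,
            origins.loc[list(analysis_matrix.sample_ids)].to_numpy(),
            n_orthogonal=config.n_orthogonal,
            scaling=config.scaling,
        )
        r2y = float(model.r2y_)
        vip_table = pd.DataFrame(
            {
                "peak_rt": analysis_matrix.peak_rts,
                "vip": model.vip_,
                "flagged": model.vip_ > config.vip_threshold,
            }
        )

    # --- quantitation of the named saponins -------------------------------
    quant = quant_summary = quant_p = None
    if truth is not None and "203" in matrices:
        library = config.synthetic.library
        named = [n for n in datasets.SAPONINS if n in truth.contents.columns]
        quant = estimate_contents(
            matrices["203"],
            library,
            compounds=named,
            rt_tolerance=config.peak_params.rt_tolerance,
        )
        if quant.shape[1]:
            quant_summary = summary_stats(quant)
            if has_two_groups:
                quant_p = group_difference(
                    quant, origins.loc[quant.index]
                )

    report = PipelineReport(
        alqfm=results,
        alqfm_wide=wide,
        discrimination=discrimination,
        discrimination_reference=ref_mode,
        hca_labels=hca_labels,
        hca_misassignments=hca_errors,
        pca_explained=pca_model.explained_variance_ratio_,
        oplsda_r2y=r2y,
        vip=vip_table,
        quant_contents=quant,
        quant_summary=quant_summary,
        quant_pvalues=quant_p,
        matrices=matrices,
        channels=tuple(matrices),
    )
    if config.outdir:
        write_report(report, config)
    return report


def write_report(report: PipelineReport, config: PipelineConfig) -> Path:
    """Write every stage table of a report as delimited text."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch, matrix in report.matrices.items():
        matrix.write(outdir / f"fingerprint_{ch}.csv")
    report.alqfm_wide.to_csv(outdir / "alqfm_report.csv")
    if report.discrimination:
        pd.DataFrame(
            [
                {"channel": ch, **dataclasses.asdict(c), "errors": c.errors}
                for ch, c in report.discrimination.items()
            ]
        ).to_csv(outdir / "grade_discrimination.csv", index=False)
    if report.vip is not None:
        report.vip.to_csv(outdir / "vip.csv", index=False)
    if report.hca_labels is not None:
        report.hca_labels.rename("cluster").to_csv(outdir / "hca_clusters.csv")
    if report.quant_contents is not None:
        report.quant_contents.to_csv(outdir / "contents.csv")
        if report.quant_summary is not None:
            report.quant_summary.to_csv(outdir / "contents_summary.csv")
        if report.quant_pvalues is not None:
            report.quant_pvalues.to_csv(outdir / "contents_pvalues.csv")
    params = {
        "peak_params": config.peak_params.asdict(),
        "criteria": dataclasses.asdict(config.criteria),
        "reference_mode": config.reference_mode,
        "discrimination_reference": report.discrimination_reference,
        "grade_cutoff": config.grade_cutoff,
        "n_orthogonal": config.n_orthogonal,
        "scaling": config.scaling,
        "seed": config.synthetic.seed if config.synthetic else None,
    }
    (outdir / "run_params.yaml").write_text(yaml.safe_dump(params))
    return outdir
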