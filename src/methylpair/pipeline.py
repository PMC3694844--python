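"""End-to-end orchestration of the two analysis tracks.

The paired per-CpG track runs the full preprocessing chain (detection filter,
beta, M, background correction, quantile normalization, batch adjustment)
followed by per-probe signed-rank tests, q-values, the effect-size filter,
distribution enrichment and — when an expression matrix and candidate panels
are supplied — expression integration and candidate-gene summaries.

The global track omits quantile normalization, applies the cross-reactive /
SNP blacklist, and tests category-level average methylation.

Everything is deterministic given the inputs; the JSON run report is derived
from the emitted tables, never the other way around.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .array_model import (
    ValueMatrix,
    paired_subjects,
    read_manifest,
    read_matrix,
    read_sample_table,
    timepoint_samples,
    write_bed,
)
from .diffmeth import QValueConfig, call_dms, differential_table
from .global_meth import GROUPINGS, category_means, paired_category_test
from .integration import (
    candidate_summary,
    distribution_enrichment,
    expression_differential,
    integrate,
)
from .preprocess import (
    PreprocessConfig,
    adjust_batches,
    background_correct_m,
    compute_beta,
    control_m_values,
    detection_pvalues,
    filter_detected,
    filter_probes,
    matrix_beta_to_m,
    matrix_m_to_beta,
    quantile_normalize,
)
from .synthetic import SimulatedStudy, read_controls

logger = logging.getLogger("methylpair")


@dataclass
class PipelineConfig:
    """File-level configuration for a full run."""

    manifest: str
    meth: str
    unmeth: str
    controls: str
    samples: str
    expression: str | None = None
    candidates: dict[str, str] = field(default_factory=dict)  # panel name -> path
    outdir: str = "methylpair_out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    qvalue: QValueConfig = field(default_factory=QValueConfig)
    q_threshold: float = 0.05
    delta_threshold: float = 0.05
    age_p_threshold: float = 1e-5
    tracks: tuple[str, ...] = ("paired", "global")
    seed: int = 0

    def __post_init__(self) -> None:
        for value in (self.q_threshold, self.delta_threshold, self.age_p_threshold):
            if not 0 < value < 1:
                raise ValueError("thresholds must lie in (0, 1)")


def _preprocess_common(
    meth: ValueMatrix,
    unmeth: ValueMatrix,
    controls: np.ndarray,
    config: PreprocessConfig,
) -> ValueMatrix:
    """Shared head of both tracks: detection filter, beta, M, background."""
    beta = compute_beta(meth, unmeth, config.beta_offset)
    total = meth.with_values(meth.values + unmeth.values, "meth_intensity")
    detp = detection_pvalues(total, controls)
    beta = filter_detected(beta, detp, config.detection_mean_p_threshold)
    logger.info("detection filter: %d of %d probes retained", len(beta.probe_ids), len(meth.probe_ids))
    m = matrix_beta_to_m(beta)
    m = background_correct_m(m, control_m_values(controls, config.beta_offset))
    return m


def paired_track(
    meth: ValueMatrix,
    unmeth: ValueMatrix,
    controls: np.ndarray,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    preprocess_config: PreprocessConfig | None = None,
    qvalue_config: QValueConfig | None = None,
    q_threshold: float = 0.05,
    delta_threshold: float = 0.05,
) -> dict:
    """Per-CpG paired analysis on in-memory matrices.

    Returns the differential table, the DMS call sets and tallies, and the
    enrichment results for both groupings.
    """
    pre = preprocess_config or PreprocessConfig()
    m = _preprocess_common(meth, unmeth, controls, pre)
    if pre.apply_quantile_norm:
        m = quantile_normalize(m)
    if pre.apply_batch_adjust and samples["batch"].nunique() > 1:
        m = adjust_batches(m, samples["batch"], samples["timepoint"])
    logger.info("paired track: %d probes after preprocessing", len(m.probe_ids))

    subjects = paired_subjects(samples)
    before_ids = timepoint_samples(samples, subjects, "before")
    after_ids = timepoint_samples(samples, subjects, "after")
    m_before = m.select_samples(before_ids)
    m_after = m.select_samples(after_ids)
    beta_before = matrix_m_to_beta(m_before)
    beta_after = matrix_m_to_beta(m_after)

    results = differential_table(
        beta_before.values,
        beta_after.values,
        m_before.values,
        m_after.values,
        m.probe_ids,
        qvalue_config,
        q_threshold=q_threshold,
        delta_threshold=delta_threshold,
    )
    calls = call_dms(results, annotation, q_threshold, delta_threshold)

    enrichment = {}
    dms_probes = calls["set_q_delta"]["probe_id"].tolist()
    if dms_probes:
        for grouping in GROUPINGS:
            enrichment[grouping] = distribution_enrichment(
                dms_probes, m.probe_ids, annotation, grouping
            )
    return {
        "m": m,
        "results": results,
        "calls": calls,
        "enrichment": enrichment,
        "subjects": subjects,
    }


def global_track(
    meth: ValueMatrix,
    unmeth: ValueMatrix,
    controls: np.ndarray,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    preprocess_config: PreprocessConfig | None = None,
    qvalue_config: QValueConfig | None = None,
) -> dict:
    """Global-methylation analysis: blacklist-filtered category averages and
    paired category tests, per probe chemistry; no quantile normalization."""
    pre = preprocess_config or PreprocessConfig()
    m = _preprocess_common(meth, unmeth, controls, pre)
    if pre.apply_batch_adjust and samples["batch"].nunique() > 1:
        m = adjust_batches(m, samples["batch"], samples["timepoint"])
    ann = annotation.set_index("probe_id").loc[m.probe_ids].reset_index()
    keep = filter_probes(ann, pre)
    m = m.select_probes(keep)
    logger.info("global track: %d probes after blacklist filter", len(m.probe_ids))
    beta = matrix_m_to_beta(m)
    summaries = pd.concat(
        [category_means(beta, annotation, grouping) for grouping in GROUPINGS],
        ignore_index=True,
    )
    tests = paired_category_test(summaries, samples, qvalue_config)
    return {"summaries": summaries, "tests": tests}


def run_study(
    study: SimulatedStudy,
    preprocess_config: PreprocessConfig | None = None,
    qvalue_config: QValueConfig | None = None,
    q_threshold: float = 0.05,
    delta_threshold: float = 0.05,
    with_expression: bool = False,
) -> dict:
    """Run the paired track (and optional expression integration) on an
    in-memory simulated study; used by recovery and calibration checks."""
    out = paired_track(
        study.meth,
        study.unmeth,
        study.negative_controls,
        study.samples,
        study.annotation,
        preprocess_config,
        qvalue_config,
        q_threshold,
        delta_threshold,
    )
    if with_expression:
        expr_results = expression_differential(study.expression, study.samples, qvalue_config)
        out["expression_results"] = expr_results
        out["integration"] = integrate(
            out["calls"]["set_q_delta"], expr_results, study.annotation, q_threshold
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured tracks from files and emit all outputs.

    Writes result TSVs, a BED of the filtered DMS set, and a JSON run report
    with every tally; raises with the failing stage named on error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "q_threshold": config.q_threshold,
            "delta_threshold": config.delta_threshold,
            "age_p_threshold": config.age_p_threshold,
            "tracks": list(config.tracks),
            "preprocess": asdict(config.preprocess),
            "qvalue": {
                "pi0_mode": config.qvalue.pi0_mode,
                "lambda_grid": list(map(float, config.qvalue.lambda_grid)),
                "smoother_df": config.qvalue.smoother_df,
            },
        },
    }

    stage = "read inputs"
    try:
        annotation = read_manifest(config.manifest)
        meth = read_matrix(config.meth, "meth_intensity")
        unmeth = read_matrix(config.unmeth, "unmeth_intensity")
        controls = read_controls(config.controls)
        samples = read_sample_table(config.samples)
        expression = (
            read_matrix(config.expression, "expression") if config.expression else None
        )
        candidates = {
            name: [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
            for name, path in config.candidates.items()
        }

        if "paired" in config.tracks:
            stage = "paired track"
            paired = paired_track(
                meth,
                unmeth,
                controls,
                samples,
                annotation,
                config.preprocess,
                config.qvalue,
                config.q_threshold,
                config.delta_threshold,
            )
            results_path = outdir / "differential_methylation.tsv"
            paired["results"].to_csv(results_path, sep="\t", index=False)
            written.append(results_path)
            bed_path = outdir / "dms.bed"
            write_bed(paired["calls"]["set_q_delta"], annotation, bed_path)
            written.append(bed_path)
            report["paired"] = dict(paired["calls"]["tallies"])
            report["paired"]["n_paired_subjects"] = len(paired["subjects"])
            report["paired"]["enrichment"] = {
                grouping: {
                    "chi2": res.chi2_statistic,
                    "df": res.degrees_of_freedom,
                    "p_value": res.p_value,
                }
                for grouping, res in paired["enrichment"].items()
            }

            if expression is not None:
                stage = "expression integration"
                expr_results = expression_differential(expression, samples, config.qvalue)
                expr_path = outdir / "differential_expression.tsv"
                expr_results.to_csv(expr_path, sep="\t", index=False)
                written.append(expr_path)
                joined = integrate(
                    paired["calls"]["set_q_delta"], expr_results, annotation,
                    config.q_threshold,
                )
                join_path = outdir / "integration.tsv"
                joined["records"].to_csv(join_path, sep="\t", index=False)
                written.append(join_path)
                report["integration"] = joined["tallies"]

                if candidates:
                    stage = "candidate genes"
                    meth_results = paired["results"].merge(
                        annotation[["probe_id", "genes"]], on="probe_id"
                    )
                    report["candidates"] = {}
                    for name, panel in candidates.items():
                        records = candidate_summary(
                            meth_results, expr_results, panel, config.q_threshold
                        )
                        panel_path = outdir / f"candidates_{name}.tsv"
                        pd.DataFrame(
                            [
                                {
                                    "gene": r.gene,
                                    "n_sites": r.n_sites,
                                    "site_ids": ";".join(r.site_ids),
                                    "expression_q": r.expression_q,
                                    "expression_direction": r.expression_direction,
                                    "inverse_coupling": r.inverse_coupling,
                                }
                                for r in records
                            ]
                        ).to_csv(panel_path, sep="\t", index=False)
                        written.append(panel_path)
                        report["candidates"][name] = {
                            "n_genes": len(records),
                            "n_sites": int(sum(r.n_sites for r in records)),
                            "n_inverse_coupled": int(
                                sum(r.inverse_coupling for r in records)
                            ),
                        }

        if "global" in config.tracks:
            stage = "global track"
            glob = global_track(
                meth, unmeth, controls, samples, annotation,
                config.preprocess, config.qvalue,
            )
            glob_path = outdir / "global_methylation.tsv"
            glob["tests"].to_csv(glob_path, sep="\t", index=False)
            written.append(glob_path)
            report["global"] = {
                "n_categories": int(len(glob["tests"])),
                "n_significant": int(glob["tests"]["significant"].sum()),
            }
    except Exception as error:
        # partial outputs are removed so a failed run leaves no stale tables
        for path in written:
            path.unlink(missing_ok=True)
        logger.error("pipeline failed at stage: %s", stage)
        raise RuntimeError(f"pipeline stage failed: {stage}: {error}") from error

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


REQUIRED_REPORT_KEYS = ("version", "seed", "config")


def summarize_run(report: dict) -> str:
    """Human-readable run summary mirroring the headline count structure."""
    for key in REQUIRED_REPORT_KEYS:
        if key not in report:
            raise KeyError(f"malformed report: missing key {key!r}")
    lines = [f"methylpair {report['version']} (seed {report['seed']})"]
    paired = report.get("paired")
    if paired:
        lines += [
            f"probes tested: {paired['n_tested']}",
            f"q < threshold: {paired['n_q']} "
            f"({paired['n_q_increase']} increase / {paired['n_q_decrease']} decrease)",
            f"q + delta filter: {paired['n_q_delta']} "
            f"({paired['n_q_delta_increase']} increase / {paired['n_q_delta_decrease']} decrease)",
        ]
        if "n_unique_genes" in paired:
            lines.append(f"unique genes (filtered set): {paired['n_unique_genes']}")
    integration = report.get("integration")
    if integration:
        lines.append(
            f"integration: {integration['n_records']} records, "
            f"{integration['n_unique_genes']} genes, "
            f"{integration['n_inverse']} inverse "
            f"({integration['percent_inverse']:.1f}%)"
        )
    for name, panel in (report.get("candidates") or {}).items():
        lines.append(
            f"candidates [{name}]: {panel['n_sites']} sites in {panel['n_genes']} genes, "
            f"{panel['n_inverse_coupled']} inverse-coupled"
        )
    glob = report.get("global")
    if glob:
        lines.append(
            f"global categories: {glob['n_categories']} tested, "
            f"{glob['n_significant']} significant"
        )
    return "\n".join(lines)
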