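"""Methylation-expression integration, candidate genes, enrichment, concordance.

Promoter methylation canonically represses transcription, so the headline
integration question for an intervention study is: of the CpG sites whose
methylation changed, how many sit in genes whose mRNA changed in the opposite
direction?  Expression is compared with a paired t-test per gene; a
(DMS probe, gene) pair enters the join when the gene's expression q-value is
below threshold, and is classified by the sign pair of the two differences.

Candidate-gene summaries intersect the DMS list (q < 0.05, no effect-size
filter) with disease gene panels, and mark a gene as inverse-coupled when its
expression changed significantly and at least one of its sites moved opposite
in sign to the expression change.

Distribution enrichment asks whether DMS fall into annotation categories in
the same proportions as the analyzed background (chi-square goodness of fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .array_model import ValueMatrix, paired_subjects, timepoint_samples
from .diffmeth import QValueConfig, qvalues
from .global_meth import _category_members


def paired_ttest(before: np.ndarray, after: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired t-test on per-subject differences."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be equal-length 1-D vectors")
    n = len(before)
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")
    d = after - before
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences: t undefined")
    t, p = stats.ttest_rel(after, before)
    return float(t), float(p)


def expression_differential(
    expression: ValueMatrix,
    samples: pd.DataFrame,
    qvalue_config: QValueConfig | None = None,
) -> pd.DataFrame:
    """Per-gene paired t-test table over paired subjects with q-values."""
    subjects = paired_subjects(samples)
    before = expression.select_samples(timepoint_samples(samples, subjects, "before")).values
    after = expression.select_samples(timepoint_samples(samples, subjects, "after")).values
    t_stats = np.empty(len(expression.probe_ids))
    p_vals = np.empty(len(expression.probe_ids))
    for i in range(len(expression.probe_ids)):
        d = after[i] - before[i]
        if np.var(d, ddof=1) == 0:
            t_stats[i], p_vals[i] = 0.0, 1.0
        else:
            t_stats[i], p_vals[i] = stats.ttest_rel(after[i], before[i])
    q = qvalues(p_vals, qvalue_config)
    return pd.DataFrame(
        {
            "gene": expression.probe_ids,
            "mean_before": before.mean(axis=1),
            "mean_after": after.mean(axis=1),
            "difference": after.mean(axis=1) - before.mean(axis=1),
            "t": t_stats,
            "p_value": p_vals,
            "q_value": q,
        }
    )


def _relation(meth_difference: float, expr_difference: float) -> str:
    if meth_difference > 0 and expr_difference < 0:
        return "inverse_meth_up_expr_down"
    if meth_difference < 0 and expr_difference > 0:
        return "inverse_meth_down_expr_up"
    return "concordant"


def integrate(
    dms: pd.DataFrame,
    expression_results: pd.DataFrame,
    probe_gene_map: pd.DataFrame,
    expr_q_threshold: float = 0.05,
) -> dict:
    """Join DMS with per-gene expression results; classify the sign pairs.

    One record per (DMS probe, annotated gene) whose gene shows significant
    expression change.  Returns the record table plus tallies: record count,
    unique genes, inverse count and percent inverse.
    """
    gene_map = dict(zip(probe_gene_map["probe_id"], probe_gene_map["genes"]))
    expr = expression_results.set_index("gene")
    records = []
    for row in dms.itertuples(index=False):
        for gene in dict.fromkeys(gene_map.get(row.probe_id, [])):
            if gene not in expr.index:
                continue
            erow = expr.loc[gene]
            if not erow["q_value"] < expr_q_threshold:
                continue
            records.append(
                {
                    "probe_id": row.probe_id,
                    "gene": gene,
                    "meth_difference": row.difference,
                    "meth_q": row.q_value,
                    "expr_difference": erow["difference"],
                    "expr_q": erow["q_value"],
                    "relation": _relation(row.difference, erow["difference"]),
                }
            )
    table = pd.DataFrame(
        records,
        columns=[
            "probe_id",
            "gene",
            "meth_difference",
            "meth_q",
            "expr_difference",
            "expr_q",
            "relation",
        ],
    )
    n_records = len(table)
    n_inverse = int(table["relation"].str.startswith("inverse").sum()) if n_records else 0
    tallies = {
        "n_records": n_records,
        "n_unique_genes": int(table["gene"].nunique()) if n_records else 0,
        "n_inverse": n_inverse,
        "n_concordant": n_records - n_inverse,
        "percent_inverse": 100.0 * n_inverse / n_records if n_records else 0.0,
    }
    return {"records": table, "tallies": tallies}


@dataclass(frozen=True)
class CandidateGeneRecord:
    gene: str
    n_sites: int
    site_ids: tuple[str, ...]
    expression_q: float  # NaN when not measured / not reported
    expression_direction: str  # up / down / none
    inverse_coupling: bool

    def __post_init__(self) -> None:
        if self.n_sites != len(self.site_ids) or self.n_sites < 1:
            raise ValueError(f"gene {self.gene}: n_sites must equal |site_ids| >= 1")


def candidate_summary(
    meth_results: pd.DataFrame,
    expression_results: pd.DataFrame,
    candidate_genes: list[str],
    q_threshold: float = 0.05,
) -> list[CandidateGeneRecord]:
    """Summarize DMS hits within a candidate-gene panel.

    ``meth_results`` needs probe_id, genes (list), difference and q_value per
    probe; only q < threshold sites count (no effect-size filter — panels are
    screened for any significant change).  ``expression_results`` maps gene ->
    difference and q_value.  A gene is inverse-coupled when its expression q
    is significant and at least one site changed opposite in sign to the
    expression change.
    """
    if not candidate_genes:
        return []
    expr = expression_results.set_index("gene") if len(expression_results) else None
    significant = meth_results[meth_results["q_value"] < q_threshold]
    per_gene: dict[str, list[tuple[str, float]]] = {}
    for row in significant.itertuples(index=False):
        for gene in dict.fromkeys(row.genes):
            per_gene.setdefault(gene, []).append((row.probe_id, row.difference))
    records = []
    for gene in candidate_genes:
        sites = per_gene.get(gene)
        if not sites:
            continue
        expr_q = np.nan
        expr_diff = np.nan
        if expr is not None and gene in expr.index:
            expr_q = float(expr.loc[gene, "q_value"])
            expr_diff = float(expr.loc[gene, "difference"])
        significant_expr = np.isfinite(expr_q) and expr_q < q_threshold
        if significant_expr and expr_diff > 0:
            direction = "up"
        elif significant_expr and expr_diff < 0:
            direction = "down"
        else:
            direction = "none"
        inverse = significant_expr and any(
            delta * expr_diff < 0 for _, delta in sites
        )
        records.append(
            CandidateGeneRecord(
                gene=gene,
                n_sites=len(sites),
                site_ids=tuple(pid for pid, _ in sites),
                expression_q=expr_q,
                expression_direction=direction,
                inverse_coupling=inverse,
            )
        )
    return records


@dataclass(frozen=True)
class EnrichmentResult:
    grouping: str
    categories: tuple[str, ...]
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    chi2_statistic: float
    degrees_of_freedom: int
    p_value: float


def distribution_enrichment(
    dms_probes: list[str],
    background_probes: list[str],
    annotation: pd.DataFrame,
    grouping: str,
) -> EnrichmentResult:
    """Chi-square goodness of fit of DMS category counts vs the array background.

    Counts are over (probe, category) incidences so multi-region probes count
    once per listed category; expected counts scale the background incidence
    proportions to the DMS incidence total.  Categories with expected count
    below 5 are pooled into "other" with a warning.
    """
    dms_set = set(dms_probes)
    bg_set = set(background_probes)
    if not dms_set <= bg_set:
        raise ValueError("DMS probes must be a subset of the background")
    ann = annotation.set_index("probe_id")
    bg_ann = ann.loc[list(background_probes)].reset_index()
    dms_ann = ann.loc[list(dms_probes)].reset_index()
    bg_members = _category_members(bg_ann, grouping)
    dms_members = _category_members(dms_ann, grouping)
    categories = [c for c, mask in bg_members.items() if mask.sum() > 0]
    bg_counts = np.array([bg_members[c].sum() for c in categories], dtype=float)
    observed = np.array([dms_members[c].sum() for c in categories], dtype=float)
    total = observed.sum()
    expected = total * bg_counts / bg_counts.sum()

    small = expected < 5
    if small.any():
        warnings.warn(
            f"pooling categories with expected < 5 into 'other': "
            f"{[c for c, s in zip(categories, small) if s]}",
            stacklevel=2,
        )
        keep = [c for c, s in zip(categories, small) if not s]
        observed = np.append(observed[~small], observed[small].sum())
        expected = np.append(expected[~small], expected[small].sum())
        categories = keep + ["other"]
    if len(categories) < 2:
        raise ValueError("need >= 2 categories with adequate expected counts")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(categories) - 1
    p = float(stats.chi2.sf(chi2, df))
    return EnrichmentResult(
        grouping=grouping,
        categories=tuple(categories),
        observed=tuple(observed),
        expected=tuple(expected),
        chi2_statistic=chi2,
        degrees_of_freedom=df,
        p_value=p,
    )


def platform_concordance(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-tailed p between paired measurements
    (e.g. array vs pyrosequencing betas, or technical replicates)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
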