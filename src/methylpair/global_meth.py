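"""Category-level average methylation and paired before/after category tests.

Global methylation is summarized as the unweighted mean beta over all CpG
sites in a category, per sample, computed separately for the two probe
chemistries (Infinium I / II) because their beta distributions differ.
Categories come from either the gene-region annotation (TSS1500 ... 3'UTR,
plus Intergenic for unannotated probes) or the CpG-island relation.  A probe
annotated to several regions contributes to each listed category.

The before/after contrast per category uses the same paired signed-rank
engine as the per-CpG track, applied to the per-sample category means across
paired subjects, with q-values computed within each grouping family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .array_model import INTERGENIC, ISLAND_LABELS, REGION_LABELS, ValueMatrix, paired_subjects, timepoint_samples
from .diffmeth import QValueConfig, paired_signed_rank, qvalues

GROUPINGS = ("gene_region", "island_relation")


def _category_members(annotation: pd.DataFrame, grouping: str) -> dict[str, np.ndarray]:
    """Map category label -> boolean probe mask (multi-membership allowed)."""
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    n = len(annotation)
    members: dict[str, np.ndarray] = {}
    if grouping == "island_relation":
        labels = annotation["island_relation"].to_numpy()
        for category in ISLAND_LABELS:
            members[category] = labels == category
    else:
        for category in REGION_LABELS:
            members[category] = np.fromiter(
                (category in regions for regions in annotation["gene_regions"]),
                dtype=bool,
                count=n,
            )
        members[INTERGENIC] = np.fromiter(
            (len(genes) == 0 for genes in annotation["genes"]), dtype=bool, count=n
        )
    return members


def category_means(
    beta: ValueMatrix, annotation: pd.DataFrame, grouping: str
) -> pd.DataFrame:
    """Per (category, assay type, sample) unweighted mean beta.

    Returns a long table [grouping, category, assay_type, sample_id,
    mean_beta, n_probes].  Empty categories are omitted with a warning.
    """
    ann = annotation.set_index("probe_id").loc[beta.probe_ids].reset_index()
    members = _category_members(ann, grouping)
    assay = ann["assay_type"].to_numpy()
    rows = []
    for category, mask in members.items():
        for assay_type in ("I", "II"):
            sel = mask & (assay == assay_type)
            if not sel.any():
                warnings.warn(
                    f"empty category {category!r} (assay {assay_type}): omitted",
                    stacklevel=2,
                )
                continue
            means = beta.values[sel].mean(axis=0)
            for sample_id, value in zip(beta.sample_ids, means):
                rows.append(
                    {
                        "grouping": grouping,
                        "category": category,
                        "assay_type": assay_type,
                        "sample_id": sample_id,
                        "mean_beta": value,
                        "n_probes": int(sel.sum()),
                    }
                )
    return pd.DataFrame(rows)


def paired_category_test(
    summaries: pd.DataFrame,
    samples: pd.DataFrame,
    qvalue_config: QValueConfig | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Paired signed-rank test per (category, assay type) on per-sample means.

    Subjects must be paired (one before, one after sample); fewer than 3
    pairs is a hard error.  q-values are computed over the category family of
    each grouping separately.
    """
    subjects = paired_subjects(samples)
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 paired subjects, got {len(subjects)}")
    before_ids = timepoint_samples(samples, subjects, "before")
    after_ids = timepoint_samples(samples, subjects, "after")

    results = []
    for (grouping, category, assay_type), group in summaries.groupby(
        ["grouping", "category", "assay_type"], sort=False
    ):
        by_sample = group.set_index("sample_id")["mean_beta"]
        before = by_sample.loc[before_ids].to_numpy()
        after = by_sample.loc[after_ids].to_numpy()
        test = paired_signed_rank(before, after)
        results.append(
            {
                "grouping": grouping,
                "category": category,
                "assay_type": assay_type,
                "n_probes": int(group["n_probes"].iloc[0]),
                "mean_before": before.mean(),
                "sd_before": before.std(ddof=1),
                "mean_after": after.mean(),
                "sd_after": after.std(ddof=1),
                "p_value": test.p_value,
            }
        )
    table = pd.DataFrame(results)
    table["q_value"] = np.nan
    for grouping, idx in table.groupby("grouping").groups.items():
        table.loc[idx, "q_value"] = qvalues(
            table.loc[idx, "p_value"].to_numpy(), qvalue_config
        )
    table["significant"] = table["q_value"] < q_threshold
    return table
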