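"""Packaged result-table fixtures.

Four published-style result tables ship with the package as TSV:

* ``top_significant`` — the most significant CpG sites (q < 0.005) with a
  methylation difference of at least 5 percentage points;
* ``largest_changes`` — significant sites with the largest absolute change
  (> 8 percentage points), both directions;
* ``obesity_candidates`` / ``t2d_candidates`` — significant sites inside
  obesity and type 2 diabetes candidate genes, with the matching per-gene
  mRNA expression results.

Methylation levels are percent beta.  Expression p/q cells printed as bounds
("<0.001") are stored at the bound value; cells printed only as ">0.05" (and
their empty q companions) are stored as NaN — downstream logic only ever
thresholds them at 0.05.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_FILES = {
    "top_significant": "table_top_significant.tsv",
    "largest_changes": "table_largest_changes.tsv",
    "obesity_candidates": "table_obesity_candidates.tsv",
    "t2d_candidates": "table_t2d_candidates.tsv",
}


def load_table(name: str) -> pd.DataFrame:
    """Load one packaged fixture table by short name."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FILES)}")
    ref = resources.files("methylpair.data").joinpath(_FILES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def candidate_meth_results(table: pd.DataFrame) -> pd.DataFrame:
    """Reshape a candidate fixture into the per-probe result layout that
    :func:`methylpair.integration.candidate_summary` consumes."""
    return pd.DataFrame(
        {
            "probe_id": table["probe_id"],
            "genes": [[g] for g in table["gene"]],
            "difference": table["meth_difference"] / 100.0,
            "q_value": table["meth_q"],
        }
    )


def candidate_expression_results(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression results from a candidate fixture (one row per
    gene; the per-gene expression columns repeat across that gene's sites)."""
    per_gene = table.drop_duplicates("gene")
    return pd.DataFrame(
        {
            "gene": per_gene["gene"],
            "difference": per_gene["expr_difference"].astype(float),
            "q_value": per_gene["expr_q"].astype(float).fillna(np.nan),
        }
    ).reset_index(drop=True)
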