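"""Per-CpG paired testing, FDR estimation and effect filtering.

The before/after contrast at every CpG is a two-tailed Wilcoxon signed-rank
test on the per-subject paired M-values.  Small samples (n <= 12 after zero
removal) use the exact conditional null distribution by full enumeration of
the 2^n sign assignments (midranks for ties); larger samples use the normal
approximation with tie and continuity corrections — the study size of 23
pairs always takes the approximate path.

Multiple testing is handled with q-values: with the null proportion pi0 fixed
at 1 the procedure reduces to Benjamini-Hochberg step-up; the "smoother" mode
estimates pi0 from the tail of the p-value distribution over a lambda grid.

Effect filtering follows the two nested call sets used for a paired
intervention design: (i) q below threshold, (ii) additionally an absolute
difference of group-mean betas of at least 5 percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs remaining after zero removal
    method: str  # "exact" or "approx"
    all_zero: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-tailed exact p by enumerating all 2^n sign assignments."""
    n = len(ranks)
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_dist = signs @ ranks
    cdf = np.mean(w_dist <= w_plus + 1e-12)
    sf = np.mean(w_dist >= w_plus - 1e-12)
    return min(1.0, 2.0 * min(cdf, sf))


def _approx_signed_rank(
    w_plus: np.ndarray, n: np.ndarray, tie_term: np.ndarray
) -> np.ndarray:
    """Normal approximation with tie and continuity corrections (two-tailed)."""
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = w_plus - mu
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.minimum(p, 1.0)


def paired_signed_rank(
    before: np.ndarray, after: np.ndarray, exact_max_n: int = 12
) -> SignedRankResult:
    """Two-tailed Wilcoxon signed-rank test on one pair of vectors.

    Zero differences are dropped (the classical convention).  If every
    difference is zero the test is degenerate and p = 1 is returned flagged.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be equal-length 1-D vectors")
    d = after - before
    d = d[d != 0.0]
    n = len(d)
    if np.all(np.asarray(after) == np.asarray(before)):
        return SignedRankResult(0.0, 1.0, 0, "degenerate", all_zero=True)
    if n < 3:
        raise ValueError(f"need >= 3 non-zero paired differences, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # exact conditional null by enumeration; midranks make this valid
        # in the presence of ties among |differences|
        return SignedRankResult(w_plus, _exact_signed_rank_p(ranks, w_plus), n, "exact")
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    p = float(_approx_signed_rank(np.array(w_plus), np.array(n), np.array(tie_term)))
    return SignedRankResult(w_plus, p, n, "approx")


def signed_rank_matrix(before: np.ndarray, after: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise signed-rank tests (normal approximation) for probe matrices.

    ``before`` and ``after`` are probes x subjects arrays with columns paired
    by subject.  Returns (W+ statistics, two-tailed p-values).  Rows whose
    differences are all zero get p = 1.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after shapes differ")
    d = after - before
    absd = np.abs(d).astype(float)
    zero = d == 0.0
    absd_masked = np.where(zero, np.nan, absd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN rows handled below
        ranks = stats.rankdata(absd_masked, axis=1, nan_policy="omit")
    ranks = np.where(zero, 0.0, ranks)
    n = (~zero).sum(axis=1).astype(float)
    w_plus = np.where(d > 0, ranks, 0.0).sum(axis=1)

    tie_term = np.zeros(len(d))
    for i in range(len(d)):
        if n[i] == 0:
            continue
        _, counts = np.unique(ranks[i][~zero[i]], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)

    p = np.ones(len(d))
    ok = n >= 1
    p[ok] = _approx_signed_rank(w_plus[ok], n[ok], tie_term[ok])
    p[n == 0] = 1.0
    return w_plus, p


@dataclass
class QValueConfig:
    """Configuration of the q-value (FDR) procedure."""

    pi0_mode: str = "smoother"  # "fixed_one" or "smoother"
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 0.90 + 1e-9, 0.05), 2)
    )
    smoother_df: int = 3

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("lambda_grid must be strictly increasing")
        if grid.min() < 0 or grid.max() >= 1:
            raise ValueError("lambda_grid values must lie in [0, 1)")
        self.lambda_grid = grid
        if self.pi0_mode not in ("fixed_one", "smoother"):
            raise ValueError(f"unknown pi0_mode {self.pi0_mode!r}")


def estimate_pi0(pvals: np.ndarray, config: QValueConfig) -> float:
    """Estimate the null proportion pi0 from the p-value tail.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid is smoothed
    with a degree-``smoother_df`` polynomial trend and evaluated at the
    largest lambda, then clipped to [0.05, 1].
    """
    m = len(pvals)
    grid = config.lambda_grid
    pi0_lambda = np.array([(pvals > lam).mean() / (1.0 - lam) for lam in grid])
    coeffs = np.polyfit(grid, pi0_lambda, deg=config.smoother_df)
    pi0 = float(np.polyval(coeffs, grid.max()))
    return float(np.clip(pi0, 0.05, 1.0))


def qvalues(pvals: np.ndarray, config: QValueConfig | None = None) -> np.ndarray:
    """q-values by the pi0-scaled step-up procedure; monotone in p."""
    config = config or QValueConfig()
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if config.pi0_mode == "smoother" and m < 10:
        warnings.warn("fewer than 10 p-values: falling back to pi0 = 1", stacklevel=2)
        pi0 = 1.0
    elif config.pi0_mode == "smoother":
        pi0 = estimate_pi0(p, config)
    else:
        pi0 = 1.0
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_table(
    beta_before: np.ndarray,
    beta_after: np.ndarray,
    m_before: np.ndarray,
    m_after: np.ndarray,
    probe_ids: list[str],
    qvalue_config: QValueConfig | None = None,
    q_threshold: float = 0.05,
    delta_threshold: float = 0.05,
) -> pd.DataFrame:
    """Build the per-probe differential result table.

    Testing happens on the M scale; reported means, differences and fold
    changes are on the beta scale (mean over paired subjects per timepoint).
    """
    stat, p = signed_rank_matrix(m_before, m_after)
    q = qvalues(p, qvalue_config)
    mean_before = beta_before.mean(axis=1)
    mean_after = beta_after.mean(axis=1)
    difference = mean_after - mean_before
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_before > 0, difference / mean_before, np.nan)
    table = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "mean_before": mean_before,
            "mean_after": mean_after,
            "difference": difference,
            "fold_change": fold,
            "statistic": stat,
            "p_value": p,
            "q_value": q,
            "direction": np.where(difference > 0, "increase", "decrease"),
            "passes_q": q < q_threshold,
            "passes_delta": np.abs(difference) >= delta_threshold,
        }
    )
    return table


def fold_changes(results: pd.DataFrame) -> pd.Series:
    """Signed fold change (after - before) / before as percent; undefined
    (NaN) where the before mean is zero."""
    before = results["mean_before"].to_numpy(dtype=float)
    after = results["mean_after"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(before > 0, (after - before) / before * 100.0, np.nan)
    return pd.Series(fc, index=results.index, name="fold_change_percent")


def call_dms(
    results: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    q_threshold: float = 0.05,
    delta_threshold: float = 0.05,
) -> dict:
    """Call differentially methylated sites and tally directions.

    Returns the two nested call sets — q < threshold, and additionally
    |difference| >= delta threshold — with increase/decrease tallies, and,
    when annotation is supplied, the deduplicated gene list of the filtered
    set (a multi-gene probe contributes each symbol once).
    """
    set_q = results[results["q_value"] < q_threshold].copy()
    set_delta = set_q[np.abs(set_q["difference"]) >= delta_threshold].copy()
    tallies = {
        "n_tested": int(len(results)),
        "n_q": int(len(set_q)),
        "n_q_increase": int((set_q["difference"] > 0).sum()),
        "n_q_decrease": int((set_q["difference"] <= 0).sum()),
        "n_q_delta": int(len(set_delta)),
        "n_q_delta_increase": int((set_delta["difference"] > 0).sum()),
        "n_q_delta_decrease": int((set_delta["difference"] <= 0).sum()),
    }
    genes: list[str] = []
    if annotation is not None:
        gene_map = dict(zip(annotation["probe_id"], annotation["genes"]))
        seen: set[str] = set()
        for probe in set_delta["probe_id"]:
            for gene in dict.fromkeys(gene_map.get(probe, [])):
                if gene not in seen:
                    seen.add(gene)
                    genes.append(gene)
        tallies["n_unique_genes"] = len(genes)
    return {"set_q": set_q, "set_q_delta": set_delta, "tallies": tallies, "genes": genes}


def age_association(
    baseline_m: np.ndarray,
    ages: np.ndarray,
    probe_ids: list[str],
    p_threshold: float = 1e-5,
) -> pd.DataFrame:
    """OLS slope of M on age per probe with two-tailed t-test.

    Used as a drift control: CpGs whose baseline methylation tracks age
    (p below 1e-5) are candidates for age-related rather than
    intervention-related change.
    """
    y = np.asarray(baseline_m, dtype=float)
    x = np.asarray(ages, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError(f"need >= 5 baseline samples, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant age vector: slope undefined")
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    slope = y @ xc / sxx
    fitted = y.mean(axis=1, keepdims=True) + np.outer(slope, xc)
    rss = ((y - fitted) ** 2).sum(axis=1)
    df = n - 2
    se = np.sqrt(rss / df / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "slope": slope,
            "t": t,
            "p_value": p,
            "significant": p < p_threshold,
        }
    )


def overlap_positions(dms: pd.DataFrame, reference: pd.DataFrame) -> int:
    """Count DMS whose (chromosome, position) exactly matches a reference
    position list (both tables need chromosome and position columns)."""
    dms_keys = set(zip(dms["chromosome"].astype(str), dms["position"].astype(int)))
    ref_keys = set(zip(reference["chromosome"].astype(str), reference["position"].astype(int)))
    return len(dms_keys & ref_keys)
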