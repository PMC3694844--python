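"""Raw intensities to analysis-ready beta / M matrices.

The chain mirrors the standard 450K workflow for a paired intervention study:

1. beta = M / (U + M + offset) with offset 100 intensity units; the offset
   regularizes low-intensity probes and keeps beta strictly below 1.
2. Detection p-values from the negative-control background; probes with mean
   p >= 0.01 across samples are discarded.
3. M = log2(beta / (1 - beta)), the variance-stabilized scale used for all
   testing; betas are reported back to the user because they are the
   interpretable scale.
4. Background correction: subtract each sample's median negative-control
   M-value from every probe.
5. Quantile normalization across samples (paired per-CpG track only).
6. Parametric empirical-Bayes batch adjustment (ComBat-style location/scale
   model) with timepoint protected as a covariate.

Two tracks share this module: the per-CpG paired track applies the full chain
and keeps SNP-overlapping probes (subjects are their own controls); the
global-methylation track omits quantile normalization and removes
cross-reactive (>= 49 bases) and SNP (MAF > 5%) probes before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .array_model import ValueMatrix

#: beta values are clamped into [BETA_EPS, 1 - BETA_EPS] before the logit
BETA_EPS = 1e-6


@dataclass
class PreprocessConfig:
    """Tunable thresholds of the preprocessing chain."""

    beta_offset: float = 100.0
    detection_mean_p_threshold: float = 0.01
    cross_reactive_min_bases: int = 49
    snp_maf_threshold: float = 0.05
    apply_quantile_norm: bool = True
    apply_batch_adjust: bool = True

    def __post_init__(self) -> None:
        if self.beta_offset < 0:
            raise ValueError("beta_offset must be >= 0")
        if not 0 < self.detection_mean_p_threshold <= 1:
            raise ValueError("detection_mean_p_threshold must be in (0, 1]")
        if not 0 <= self.snp_maf_threshold <= 1:
            raise ValueError("snp_maf_threshold must be in [0, 1]")


def compute_beta(
    meth: ValueMatrix, unmeth: ValueMatrix, offset: float = 100.0
) -> ValueMatrix:
    """beta = M / (U + M + offset); strictly < 1 for offset > 0."""
    if meth.probe_ids != unmeth.probe_ids or meth.sample_ids != unmeth.sample_ids:
        raise ValueError("methylated and unmethylated matrices are not aligned")
    beta = meth.values / (unmeth.values + meth.values + offset)
    return ValueMatrix(meth.probe_ids, meth.sample_ids, beta, "beta")


def detection_pvalues(
    total_intensity: ValueMatrix, negative_controls: np.ndarray
) -> ValueMatrix:
    """Detection p per probe/sample from the negative-control background.

    ``negative_controls`` is a controls x samples array.  The background is
    modelled as normal with the sample's control mean and sd; the detection p
    is the upper-tail probability of the probe's total intensity, so strong
    probes get p near 0 and background-level probes get p near 0.5.
    """
    controls = np.asarray(negative_controls, dtype=float)
    if controls.ndim != 2 or controls.shape[0] < 2:
        raise ValueError("need at least 2 negative controls per sample")
    if controls.shape[1] != len(total_intensity.sample_ids):
        raise ValueError("control columns do not match sample count")
    mean = controls.mean(axis=0)
    sd = controls.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = total_intensity.sample_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"degenerate background: zero control variance in sample {bad!r}")
    p = stats.norm.sf(total_intensity.values, loc=mean, scale=sd)
    return total_intensity.with_values(p, "detection_p")


def filter_detected(
    values: ValueMatrix, detection_p: ValueMatrix, threshold: float = 0.01
) -> ValueMatrix:
    """Keep probes whose mean detection p across samples is strictly < threshold."""
    if values.probe_ids != detection_p.probe_ids:
        raise ValueError("value and detection matrices are not aligned")
    keep = detection_p.values.mean(axis=1) < threshold
    return values.select_probes(keep)


def beta_to_m(beta: np.ndarray) -> np.ndarray:
    """M = log2(beta / (1 - beta)); betas at 0/1 are clamped with a warning."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0.0) | (beta >= 1.0)):
        warnings.warn(
            f"beta values at or beyond [0, 1] clamped to [{BETA_EPS}, 1 - {BETA_EPS}]",
            stacklevel=2,
        )
        beta = np.clip(beta, BETA_EPS, 1.0 - BETA_EPS)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """Inverse logit2: beta = 2^M / (1 + 2^M), computed stably for large |M|."""
    m = np.asarray(m, dtype=float)
    # equivalent to expit(m * ln 2) without overflow
    out = np.empty_like(m, dtype=float)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    e = np.exp2(m[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def matrix_beta_to_m(beta: ValueMatrix) -> ValueMatrix:
    return beta.with_values(beta_to_m(beta.values), "m_value")


def matrix_m_to_beta(m: ValueMatrix) -> ValueMatrix:
    return m.with_values(m_to_beta(m.values), "beta")


def control_m_values(control_intensity: np.ndarray, offset: float = 100.0) -> np.ndarray:
    """Per-control M-like values: the control signal carried through the beta
    chain as a pure methylated channel (beta = I / (I + offset))."""
    intensity = np.asarray(control_intensity, dtype=float)
    beta = intensity / (intensity + offset)
    return beta_to_m(beta)


def background_correct_m(m: ValueMatrix, control_m: np.ndarray) -> ValueMatrix:
    """Subtract each sample's median control M-value from its column."""
    control_m = np.asarray(control_m, dtype=float)
    if control_m.ndim != 2 or control_m.shape[1] != len(m.sample_ids):
        raise ValueError("control M-values missing for one or more samples")
    medians = np.median(control_m, axis=0)
    return m.with_values(m.values - medians)


def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    n, k = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.take_along_axis(values, order, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(k):
        col_sorted = values[order[:, j], j]
        assigned = reference.copy()
        # ties receive the mean of the reference values over the tied rank span
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        sums = np.add.reduceat(reference, starts)
        counts = np.diff(np.concatenate((starts, [n])))
        group_means = sums / counts
        assigned = np.repeat(group_means, counts)
        out[order[:, j], j] = assigned
    return out


def quantile_normalize(m: ValueMatrix) -> ValueMatrix:
    """Force every sample column onto the mean of the column order statistics.

    After normalization all columns share an identical sorted value vector and
    each column's rank order is preserved.  Applying the transform twice gives
    the same result as applying it once.
    """
    if len(m.sample_ids) < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 samples", stacklevel=2)
        return m.with_values(m.values.copy())
    return m.with_values(_quantile_normalize_values(m.values))


def _moments_inverse_gamma(delta_hat: np.ndarray) -> tuple[float, float]:
    # moment-matched inverse-gamma hyperparameters for the scale prior
    mean = delta_hat.mean()
    var = delta_hat.var(ddof=1)
    a = (2.0 * var + mean**2) / var
    b = (mean * var + mean**3) / var
    return a, b


def _eb_iterate(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a_prior: float,
    b_prior: float,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    n = z_batch.shape[1]
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    change = 1.0
    while change > tol:
        gamma_new = (n * tau2 * gamma_hat + delta * gamma_bar) / (n * tau2 + delta)
        ssq = ((z_batch - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * ssq + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma) / np.maximum(np.abs(gamma), 1e-12)),
            np.max(np.abs(delta_new - delta) / np.maximum(np.abs(delta), 1e-12)),
        )
        gamma, delta = gamma_new, delta_new
    return gamma, delta


def adjust_batches(
    m: ValueMatrix,
    batches: pd.Series | np.ndarray | list,
    covariates: pd.Series | np.ndarray | list | None = None,
) -> ValueMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per probe, batch location (gamma) and scale (delta^2) are estimated on
    data standardized conditional on the protected covariate (timepoint),
    shrunk toward pooled batch priors (normal for gamma, inverse-gamma for
    delta^2, moment matched), then removed.  A batch confounded 1:1 with the
    covariate makes the batch effect unidentifiable and is a hard error.
    """
    batch_labels = pd.Series(list(batches), dtype=str)
    if len(batch_labels) != len(m.sample_ids):
        raise ValueError("batch labels do not match sample count")
    levels = batch_labels.unique().tolist()
    if len(levels) < 2:
        warnings.warn("single batch: nothing to adjust", stacklevel=2)
        return m.with_values(m.values.copy())
    counts = batch_labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with fewer than 2 samples: {small}")

    batch_design = pd.get_dummies(batch_labels).astype(float)
    batch_design = batch_design[levels]  # stable order
    design_parts = [batch_design.to_numpy()]
    n_cov = 0
    if covariates is not None:
        cov = pd.Series(list(covariates), dtype=str)
        cov_design = pd.get_dummies(cov, drop_first=True).astype(float).to_numpy()
        n_cov = cov_design.shape[1]
        design_parts.append(cov_design)
    design = np.hstack(design_parts)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "batch is confounded with the protected covariate; "
            "batch effect is unidentifiable"
        )

    y = m.values
    n_samples = y.shape[1]
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    batch_coef = coef[: len(levels)]
    sizes = counts.loc[levels].to_numpy(dtype=float)
    grand_mean = (sizes / n_samples) @ batch_coef
    fitted = design @ coef
    var_pooled = ((y.T - fitted) ** 2).mean(axis=0)
    if np.any(var_pooled == 0):
        raise ValueError("probe with zero pooled variance; cannot standardize")

    stand_mean = np.tile(grand_mean[:, None], (1, n_samples))
    if n_cov:
        cov_part = design[:, len(levels):] @ coef[len(levels):]
        stand_mean = stand_mean + cov_part.T
    z = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    adjusted = np.empty_like(z)
    for level in levels:
        cols = (batch_labels == level).to_numpy()
        z_b = z[:, cols]
        gamma_hat = z_b.mean(axis=1)
        delta_hat = z_b.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        a_prior, b_prior = _moments_inverse_gamma(delta_hat)
        gamma_star, delta_star = _eb_iterate(
            z_b, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior
        )
        adjusted[:, cols] = (z_b - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    return m.with_values(out)


def filter_probes(annotation: pd.DataFrame, config: PreprocessConfig | None = None) -> np.ndarray:
    """Blacklist mask for the global track: True = keep.

    Excludes probes cross-reacting over >= 49 bases or directly affected by a
    SNP with MAF > 5%.  The paired per-CpG track does not apply this mask:
    subjects are their own controls, so within-pair genetic variation cancels.
    """
    config = config or PreprocessConfig()
    cross = annotation["cross_reactive_bases"].to_numpy() >= config.cross_reactive_min_bases
    snp = annotation["snp_maf"].to_numpy() > config.snp_maf_threshold
    return ~(cross | snp)
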