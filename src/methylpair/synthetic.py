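"""Synthetic paired intervention methylome datasets with ground truth.

The generator emulates the statistical structure a 450K-style paired
before/after study presents to the analysis pipeline:

* bimodal beta baselines stratified by CpG-island context — islands low
  (9-21%), shores intermediate (31-44%), shelves and open sea high (67-76%);
* a mixture of the two probe chemistries (72% type II);
* paired subject effects (a subject-by-probe random effect shared across the
  two timepoints) plus independent measurement noise, both additive on the
  M (logit) scale;
* spiked differential sites with beta-scale differences in a configurable
  range and a strong (default 92%) bias toward increased methylation;
* additive per-probe batch shifts, with whole subjects assigned to batches so
  batch is never confounded with timepoint;
* negative-control probes whose intensities sit at the scale of the beta
  offset, giving the detection-p and background-correction stages a real
  background to estimate;
* an expression matrix in which a subset of genes carrying spiked probes
  moves opposite in sign to the methylation change.

Intensities are produced with a fixed total per probe (default 10,000), so
beta recomputed with the +100 offset recovers the latent beta up to a known
~1% multiplicative shrinkage — deliberately retained so downstream code is
exercised against it.

Effects are defined on the beta scale at the population mean (the truth table
stores the realized beta difference) and applied additively on the M scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .array_model import (
    ISLAND_LABELS,
    REGION_LABELS,
    ProbeAnnotation,
    ValueMatrix,
    annotation_frame,
    validate_sample_table,
    write_manifest,
    write_matrix,
    write_sample_table,
)
from .preprocess import beta_to_m, m_to_beta

#: Infinium II fraction of the array: 326,640 of 453,444 context-annotated assays
DEFAULT_FRACTION_TYPE_II = 326_640 / (126_804 + 326_640)

DEFAULT_CONTEXT_PROPORTIONS = {
    "Island": 0.31,
    "N_Shore": 0.12,
    "S_Shore": 0.11,
    "N_Shelf": 0.05,
    "S_Shelf": 0.05,
    "OpenSea": 0.36,
}

DEFAULT_BASELINE_RANGES = {
    "Island": (0.09, 0.21),
    "N_Shore": (0.31, 0.44),
    "S_Shore": (0.31, 0.44),
    "N_Shelf": (0.67, 0.76),
    "S_Shelf": (0.67, 0.76),
    "OpenSea": (0.67, 0.76),
}


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults follow the paired
    23-subject intervention design the pipeline targets."""

    n_subjects: int = 23
    n_probes: int = 20_000
    fraction_type_II: float = DEFAULT_FRACTION_TYPE_II
    island_context_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_PROPORTIONS)
    )
    baseline_beta_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RANGES)
    )
    n_true_dms: int = 2_000
    delta_range: tuple[float, float] = (0.002, 0.109)
    p_increase: float = 0.92
    subject_sd: float = 0.25  # M units
    noise_sd: float = 0.12  # M units
    n_batches: int = 2
    batch_shift_sd: float = 0.10  # M units
    n_negative_controls: int = 600
    total_intensity: float = 10_000.0
    n_genes: int = 2_000
    gene_fraction: float = 0.70  # fraction of probes annotated to a gene
    multi_region_fraction: float = 0.05
    expression_coupling_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        total = sum(self.island_context_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"context proportions must sum to 1, got {total}")
        low, high = self.delta_range
        if not (0 < low < high < 1):
            raise ValueError("delta_range must lie within (0, 1)")
        for sd in (self.subject_sd, self.noise_sd, self.batch_shift_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.n_true_dms > self.n_probes:
            raise ValueError("n_true_dms cannot exceed n_probes")


@dataclass
class SimulatedStudy:
    annotation: pd.DataFrame
    meth: ValueMatrix
    unmeth: ValueMatrix
    negative_controls: np.ndarray  # controls x samples intensities
    samples: pd.DataFrame
    expression: ValueMatrix
    truth: pd.DataFrame
    config: SimulationConfig


def _simulate_annotation(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_probes
    contexts = list(config.island_context_proportions)
    probs = np.array([config.island_context_proportions[c] for c in contexts])
    context = rng.choice(contexts, size=n, p=probs)
    assay = np.where(rng.random(n) < config.fraction_type_II, "II", "I")
    chromosomes = rng.choice([str(c) for c in range(1, 23)] + ["X"], size=n)
    positions = rng.integers(1, 200_000_000, size=n)

    has_gene = rng.random(n) < config.gene_fraction
    gene_idx = rng.integers(0, config.n_genes, size=n)
    gene_names = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    multi = has_gene & (rng.random(n) < config.multi_region_fraction)
    region_choices = rng.choice(REGION_LABELS, size=(n, 2))

    cross_reactive = np.where(rng.random(n) < 0.01, rng.integers(47, 51, size=n), 0)
    snp_maf = np.where(rng.random(n) < 0.02, rng.uniform(0.0, 0.5, size=n), 0.0)

    records = []
    for i in range(n):
        if has_gene[i]:
            gene = gene_names[gene_idx[i]]
            if multi[i]:
                first, second = region_choices[i]
                if first == second:
                    second = REGION_LABELS[(REGION_LABELS.index(first) + 1) % len(REGION_LABELS)]
                genes = (gene, gene)
                regions = (first, second)
            else:
                genes = (gene,)
                regions = (region_choices[i, 0],)
        else:
            genes = ()
            regions = ()
        records.append(
            ProbeAnnotation(
                probe_id=f"cg{i:08d}",
                chromosome=str(chromosomes[i]),
                position=int(positions[i]),
                assay_type=str(assay[i]),
                genes=genes,
                gene_regions=regions,
                island_relation=str(context[i]),
                cross_reactive_bases=int(cross_reactive[i]),
                snp_maf=float(snp_maf[i]),
            )
        )
    return annotation_frame(records), context


def _spike_deltas(
    config: SimulationConfig, baseline: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Signed beta-scale effects for the spiked probes, clamped so the shifted
    mean beta stays inside (0.01, 0.99)."""
    n = config.n_probes
    delta = np.zeros(n)
    spiked = rng.choice(n, size=config.n_true_dms, replace=False)
    low, high = config.delta_range
    magnitude = rng.uniform(low, high, size=config.n_true_dms)
    sign = np.where(rng.random(config.n_true_dms) < config.p_increase, 1.0, -1.0)
    headroom = np.where(sign > 0, 0.99 - baseline[spiked], baseline[spiked] - 0.01)
    magnitude = np.minimum(magnitude, headroom)
    delta[spiked] = sign * magnitude
    return delta


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full paired study; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    annotation, context = _simulate_annotation(config, rng)
    n = config.n_probes
    n_subj = config.n_subjects

    ranges = config.baseline_beta_ranges
    low = np.array([ranges[c][0] for c in context])
    high = np.array([ranges[c][1] for c in context])
    baseline_beta = rng.uniform(low, high)
    true_delta = _spike_deltas(config, baseline_beta, rng)

    m0 = beta_to_m(baseline_beta)
    m_shift = beta_to_m(baseline_beta + true_delta) - m0  # M-scale timepoint effect

    subjects = [f"P{i + 1:02d}" for i in range(n_subj)]
    sample_ids = [f"{s}_{tp}" for s in subjects for tp in ("before", "after")]
    timepoints = np.array([tp for _ in subjects for tp in ("before", "after")])
    subject_of_sample = np.repeat(np.arange(n_subj), 2)
    batch_of_subject = np.arange(n_subj) % config.n_batches
    batch_labels = np.array(
        [f"B{batch_of_subject[j] + 1}" for j in subject_of_sample]
    )

    subject_effect = rng.normal(0.0, config.subject_sd, size=(n, n_subj))
    noise = rng.normal(0.0, config.noise_sd, size=(n, 2 * n_subj))
    batch_effect = rng.normal(0.0, config.batch_shift_sd, size=(n, config.n_batches))

    m_latent = (
        m0[:, None]
        + subject_effect[:, subject_of_sample]
        + np.where(timepoints == "after", m_shift[:, None], 0.0)
        + batch_effect[:, batch_of_subject[subject_of_sample]]
        + noise
    )
    beta_latent = m_to_beta(m_latent)
    meth_values = beta_latent * config.total_intensity
    unmeth_values = config.total_intensity - meth_values

    probe_ids = annotation["probe_id"].tolist()
    meth = ValueMatrix(probe_ids, sample_ids, meth_values, "meth_intensity")
    unmeth = ValueMatrix(probe_ids, sample_ids, unmeth_values, "unmeth_intensity")

    controls = np.clip(
        rng.normal(100.0, 20.0, size=(config.n_negative_controls, 2 * n_subj)),
        10.0,
        None,
    )

    ages = rng.integers(30, 46, size=n_subj)
    samples = validate_sample_table(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": [subjects[j] for j in subject_of_sample],
                "timepoint": timepoints,
                "batch": batch_labels,
                "age": [float(ages[j]) for j in subject_of_sample],
            }
        )
    )

    expression, truth = _simulate_expression(
        config, annotation, true_delta, sample_ids, timepoints, rng
    )
    return SimulatedStudy(
        annotation=annotation,
        meth=meth,
        unmeth=unmeth,
        negative_controls=controls,
        samples=samples,
        expression=expression,
        truth=truth,
        config=config,
    )


def _simulate_expression(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    true_delta: np.ndarray,
    sample_ids: list[str],
    timepoints: np.ndarray,
    rng: np.random.Generator,
):
    gene_names = [f"G{i:05d}" for i in range(config.n_genes)]
    # net methylation effect per gene: sum of spiked deltas over its probes,
    # so genes with mixed-direction sites couple to the dominant direction
    spiked_gene_delta: dict[str, float] = {}
    for genes, delta in zip(annotation["genes"], true_delta):
        if delta != 0 and genes:
            gene = genes[0]
            spiked_gene_delta[gene] = spiked_gene_delta.get(gene, 0.0) + delta
    spiked_gene_delta = {g: d for g, d in spiked_gene_delta.items() if d != 0}
    spiked_genes = sorted(spiked_gene_delta)
    n_coupled = int(round(config.expression_coupling_fraction * len(spiked_genes)))
    coupled = set(
        rng.choice(spiked_genes, size=n_coupled, replace=False)
    ) if n_coupled else set()

    baseline = np.exp2(rng.uniform(4.0, 9.0, size=config.n_genes))
    n_samples = len(sample_ids)
    values = baseline[:, None] * (
        1.0 + rng.normal(0.0, 0.08, size=(config.n_genes, n_samples))
    )
    effects = np.zeros(config.n_genes)
    after = timepoints == "after"
    for g, gene in enumerate(gene_names):
        if gene in coupled:
            effect = -np.sign(spiked_gene_delta[gene]) * rng.uniform(0.10, 0.30) * baseline[g]
            values[g, after] += effect
            effects[g] = effect
    values = np.maximum(values, 0.1)
    expression = ValueMatrix(gene_names, sample_ids, values, "expression")

    gene_effect = dict(zip(gene_names, effects))

    def _coupled_to(genes: tuple, delta: float) -> str:
        # a probe is coupled when its gene is coupled and its own direction
        # matches the gene's net direction (the one expression responds to)
        if delta == 0 or not genes or genes[0] not in coupled:
            return ""
        if np.sign(delta) != np.sign(spiked_gene_delta[genes[0]]):
            return ""
        return genes[0]

    coupled_of = [
        _coupled_to(genes, delta)
        for genes, delta in zip(annotation["genes"], true_delta)
    ]
    truth = pd.DataFrame(
        {
            "probe_id": annotation["probe_id"],
            "true_delta": true_delta,
            "coupled_gene": coupled_of,
            "expression_effect": [
                gene_effect[g] if g else np.nan for g in coupled_of
            ],
        }
    )
    return expression, truth


def write_study(study: SimulatedStudy, directory: str | Path) -> dict[str, Path]:
    """Write all study components in the package's external formats."""
    directory = Path(directory)
    if not directory.exists():
        directory.mkdir(parents=True)
    paths = {
        "manifest": directory / "manifest.tsv",
        "meth": directory / "meth_intensity.tsv",
        "unmeth": directory / "unmeth_intensity.tsv",
        "controls": directory / "negative_controls.tsv",
        "samples": directory / "samples.tsv",
        "expression": directory / "expression.tsv",
        "truth": directory / "truth.tsv",
    }
    write_manifest(study.annotation, paths["manifest"])
    write_matrix(study.meth, paths["meth"])
    write_matrix(study.unmeth, paths["unmeth"])
    controls = pd.DataFrame(
        study.negative_controls,
        index=[f"ctrl{i:04d}" for i in range(study.negative_controls.shape[0])],
        columns=study.meth.sample_ids,
    )
    controls.index.name = "control_id"
    controls.to_csv(paths["controls"], sep="\t")
    write_sample_table(study.samples, paths["samples"])
    write_matrix(study.expression, paths["expression"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_controls(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)
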