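# methylpair

Paired-design analysis of Infinium HumanMethylation450-style DNA methylation
data, built for intervention studies in which the same subjects are measured
before and after a treatment (the motivating design: subcutaneous adipose
tissue from 23 men sampled before and after a six-month exercise program).

The package covers the whole chain from raw allele intensities to biology:

* **Preprocessing** — β = M/(U+M+100), detection p-values against the
  negative-control background, the logit transform M = log₂(β/(1−β)),
  per-sample background correction by the control median, quantile
  normalization, and parametric empirical-Bayes batch adjustment
  (location/scale model with the timepoint protected as a covariate).
* **Per-CpG differential methylation** — two-tailed Wilcoxon signed-rank
  tests on paired M-values (exact by enumeration for n ≤ 12, normal
  approximation with tie and continuity corrections above), q-value FDR
  estimation (Benjamini–Hochberg step-up with π₀ = 1, or a Storey-style
  π₀ smoother), and nested call sets: q < 0.05, then additionally
  |Δβ| ≥ 5 percentage points.
* **Global methylation** — unweighted category means per sample by gene
  region (TSS1500 … 3′UTR, intergenic) and CpG-island context (island,
  shores, shelves, open sea), split by Infinium I/II chemistry, with paired
  category tests.
* **Integration** — paired t-tests on a gene × sample expression matrix,
  methylation–expression joins classified by sign pair (inverse vs
  concordant), candidate-gene panel summaries, chi-square enrichment of DMS
  over annotation categories, and Pearson platform concordance.
* **Synthetic studies** — a generator that emulates the array's statistical
  structure (context-stratified bimodal β baselines, probe-type mixture,
  paired subject effects, spiked differences with a 92% increase bias,
  batches, negative controls, inversely coupled expression) with a ground
  truth table for recovery testing.

## Worked example

```python
from methylpair.synthetic import SimulationConfig, simulate_study
from methylpair.pipeline import run_study

study = simulate_study(SimulationConfig(
    n_subjects=23, n_probes=20_000, n_true_dms=2_000,
    delta_range=(0.02, 0.11), seed=1,
))
out = run_study(study)
print(out["calls"]["tallies"])
```

prints

```
{'n_tested': 20000, 'n_q': 4443, 'n_q_increase': 1824, 'n_q_decrease': 2619,
 'n_q_delta': 1220, 'n_q_delta_increase': 1111, 'n_q_delta_decrease': 109,
 'n_unique_genes': 691}
```

All 20,000 probes pass the detection filter; 1,220 sites survive both the
q < 0.05 and ≥5-percentage-point filters, 1,111 of them increases — the
direction asymmetry reflects the generator's 92% increase bias.  Joining
against `study.truth` shows none of the 1,220 calls is a false positive and
the mean error of the estimated β difference over all spiked sites is
−0.008 (a small attenuation, mostly from quantile normalization acting on
strongly asymmetric changes).

The same analyses run from the shell on TSV inputs:

```sh
methylpair simulate --config sim.yaml --out study/ --seed 1
methylpair diff --manifest study/manifest.tsv --meth study/meth_intensity.tsv \
    --unmeth study/unmeth_intensity.tsv --controls study/negative_controls.tsv \
    --samples study/samples.tsv --out results.tsv
methylpair run --config pipeline.yaml   # both tracks + JSON report
```

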