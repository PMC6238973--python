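# mirhinge

Threshold-aware inference of miRNA → target-gene repression from matched
expression profiles.

MicroRNA repression is often threshold-dependent: only sufficiently
abundant miRNAs measurably repress their targets.  A straight regression
line through miRNA and target expression misses such relationships.
`mirhinge` fits, per gene, two least-absolute-deviation (LAD) models on
z-scored expression over the same samples —

* a **linear model** `y = α + Σᵢ βᵢ xᵢ + ε` with repression-only slopes
  βᵢ ≤ 0, solved exactly as a linear program, and
* a **piecewise (hinge) model** `y = α + Σᵢ min(0, βᵢ xᵢ + γᵢ) + ε`,
  flat below the implied breakpoint bᵢ = −γᵢ/βᵢ and linearly repressive
  above it, solved to proven global optimality as a mixed-integer linear
  program (HiGHS via SciPy)

— and predicts the union of the (miRNA, gene) pairs supported by either
model.  Around the core sit the full analysis pipeline: candidate-pair
filtering (negative correlation), validation against miRNA-transfection
down-regulation lists (exact hypergeometric enrichment), molecular-subgroup
differential expression with opposed-direction pair selection, directional
mean-statistic permutation GSEA, tumor/stroma cell-type refinement with
binding-site integration, and a fully deterministic synthetic-data
generator with known ground truth.

It is written for computational biologists analysing paired miRNA/mRNA
cohorts (TCGA-style flat files) who want exactly solvable, auditable
models rather than heuristics.

## Worked example

Simulate a small cohort with known threshold regulations, run the
pipeline, and score recovery:

```python
import mirhinge as mh

cfg = mh.SimulationConfig(n_samples=60, n_mirnas=5, n_genes=12,
                          hinge_fraction=1.0, noise_sd=0.2,
                          regulation_density=0.4, seed=3)
genes, mirnas, pairs, truth = mh.generate_dataset(cfg)
gz, mz = mh.znormalize(genes), mh.znormalize(mirnas)
kept, audit = mh.correlation_filter(pairs, gz, mz)
preds = mh.run_target_prediction(gz, mz, kept, model="combined", tau=0.1)
print(preds[["mirna", "gene", "models", "beta_piecewise", "breakpoint"]]
      .head(4).to_string(index=False))
print(mh.score_recovery(preds, truth))
```

prints

```
  mirna     gene           models  beta_piecewise  breakpoint
mir-000 gene-000 linear+piecewise       -0.024192    2.018806
mir-003 gene-000 linear+piecewise       -1.631795   -0.085698
mir-003 gene-001 linear+piecewise       -2.064755    0.183610
mir-003 gene-002 linear+piecewise       -1.796878    0.005011
{'precision': 0.769..., 'recall': 1.0, 'n_predicted': 13, 'n_true': 10,
 'breakpoint_abs_errors': [0.0478, 0.1506, 0.2222, ...]}
```

All 10 true regulations are recovered (recall 1.0) and 3 decoy pairs slip
through (precision 0.77); the fitted breakpoints sit within ~0.05–0.22 of
the true thresholds on the z-score scale.  `beta_piecewise` is the
repressive slope above the fitted breakpoint; `models` records which of
the two regressions support each pair.

The same pipeline is scriptable from the shell:

```sh
printf 'n_samples: 60\nn_mirnas: 5\nn_genes: 12\nnoise_sd: 0.2\n' > sim.yaml
mirhinge simulate --config sim.yaml --seed 3 --out-dir run/sim
mirhinge preprocess --genes run/sim/genes.tsv --mirnas run/sim/mirnas.tsv \
         --pairs run/sim/pairs.tsv --no-raw --out-dir run/pre
mirhinge fit --genes run/pre/genes.z.tsv --mirnas run/pre/mirnas.z.tsv \
         --pairs run/pre/pairs.filtered.tsv --model combined \
         --out run/predictions.tsv
mirhinge evaluate --predictions run/predictions.tsv \
         --transfections run/sim/transfections --out run/eval.tsv
```

`docs/methods.md` describes the models, the MILP formulation, the
independent enumeration oracle, the statistics and the generator in
detail.

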