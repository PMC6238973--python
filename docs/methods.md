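# Methods

## Problem and model

MicroRNAs repress their target mRNAs, but repression is often not linear
in miRNA abundance: below some abundance threshold a miRNA competes poorly
for the silencing machinery and has little measurable effect, while above
it repression grows roughly linearly.  `mirhinge` infers miRNA → target
relationships from matched miRNA and gene expression matrices over the
same samples by fitting, per gene, two regression models on z-scored data
and taking the union of their supported pairs.

**Linear model (LAD).**  For gene *y* with candidate regulators
*x₁ … x_K*:

    y_s = α + Σ_i β_i x_{i,s} + ε_s,      β_i ≤ 0

fitted by minimising the sum of absolute residuals Σ|ε_s| (least absolute
deviations).  The L1 loss makes the problem an exact linear program and is
robust to the heavy tails typical of expression data.  Slopes are
constrained non-positive because only repression is modelled and the
candidate pairs are pre-filtered to negative correlation.

**Piecewise (hinge) model.**  Each regulator contributes

    u_i(x) = min(0, β_i x + γ_i),      β_i ≤ 0

i.e. no effect below the implied breakpoint *b_i = −γ_i / β_i* and a
linear decrease above it, continuous at the breakpoint.  Parameterising
the hinge in (β, γ) rather than (β, b) keeps the model free of bilinear
terms.  The LAD fit of

    y_s = α + Σ_i u_i(x_{i,s}) + ε_s

is a mixed-integer linear program: one binary z_{i,s} per (regulator,
sample) encodes which side of the breakpoint the sample lies on, and a
big-M construction ties u to min(0, βx + γ).  We solve to proven global
optimality with HiGHS (via `scipy.optimize.milp`), relative gap 1e-6.
Fits that are not proven optimal within the time limit are flagged and
excluded from predictions, never used silently.

Two implementation details make the MILP practical without changing its
optimum:

* **Threshold cuts.** With β ≤ 0 the hinge argument is monotonically
  non-increasing in x, so the inert segment is a lower set of the sorted x
  values.  Ordering constraints z_{(j)} ≥ z_{(j+1)} (ascending x) restrict
  the binaries to the S+1 threshold patterns; this cut is implied by the
  continuous constraints at integer feasibility and reduces solve times
  from ~50 s to ~1–2 s at S = 120.
* **Per-cell big-M.** The per-regulator constant M_i = B(1 + 2·max|x_i|) + B
  is tightened per sample to min(M_i, B|x_{i,s}| + γ-bound), which
  dominates |β x + γ| everywhere and strengthens the LP relaxation.

Bounds: |α| ≤ B, −B ≤ β ≤ 0, |γ_i| ≤ B(1 + max_s|x_{i,s}|) with B = 10,
generous for z-scored data (a slope of 10 sd/sd is far outside anything
biologically plausible).

**Fit score and prediction rule.**  A fit is scored against the best
constant predictor: score = 1 − SAE / SAE₀ with SAE₀ = Σ|y_s − median(y)|.
Score 1 means exact interpolation, 0 no better than a constant.  A fit
passes at score ≥ τ (default 0.1); within a passing fit every regulator
with slope < −1e-6 yields a predicted (miRNA, gene) pair.  The combined
model is the union of the pairs from the two single models — the
recall-increasing combination.  An optional 5-fold cross-validated score
(`cross_validated_score`, strided folds, training-median baseline) is
available for a more conservative out-of-sample assessment.  Per-gene
problems can be fitted jointly
over all candidates (default, capped at K = 10 regulators ranked by most
negative Pearson correlation, ties broken by miRNA id) or per pair
(`per_pair=True`), one single-regulator model per candidate; which the
original analysis used is not determinable, so both are provided.

## Independent oracle

`fit_hinge_grid` cross-checks the MILP for single-regulator problems.  It
enumerates the m+1 threshold segment patterns over the m unique x values;
for each pattern the fit is an LP in (α, β, γ) — inert samples regress on
the constant α, active samples on α + βx + γ, with boundary sign
constraints keeping the implied breakpoint inside the pattern's x-gap.
This searches exactly the segment patterns available to the MILP, so the
optimal SAE values agree to 1e-6; the test suite verifies this on hundreds
of random problems.  (A simpler oracle that fixes the breakpoint at
midpoints between consecutive x values is *not* equivalent: within a
pattern the optimal breakpoint is continuous, and on noise-free hinge data
the midpoint version misses exact interpolation.)

## Pipeline around the core

* **Pre-processing** — features that are exactly zero in every sample are
  removed from raw matrices; candidate pairs must show strictly negative
  Pearson correlation over the shared samples (r = 0 carries no repression
  signal and is excluded); each surviving feature is z-normalised across
  samples (sample sd, n−1).  Correlation is computed on values as provided,
  with an optional log2(x+1) transform.
* **Identifier collapse** — target sets of sibling mature miRNAs
  (-3p/-5p) are unioned per precursor; a mature id mapping to several
  precursors contributes to each of them, and unmapped mature ids are
  reported and excluded rather than passed through.
* **Transfection validation** — predictions for a transfected miRNA are
  tested for over-representation in that experiment's down-regulated gene
  list by an exact upper-tail hypergeometric test on the experiment's own
  measured universe; precision is reported alongside.  Models are compared
  per experiment by smaller enrichment p, ties credited to both.
* **Subgroup analysis** — one-vs-rest two-sided equal-variance t-tests per
  feature with BH correction; predicted pairs where the miRNA and the gene
  are both significant with opposite directions are kept.  Gene set
  enrichment uses the mean of member signed t statistics against a
  gene-randomisation null (random same-size subsets of the universe) with
  separate upper/lower "distinct directional" p-values, each BH-adjusted
  across sets; the default universe is all measured genes, with a
  predicted-targets-only restriction available.  When
  C(|universe|, set size) ≤ 10,000 the null is enumerated exhaustively and
  p-values are exact; otherwise Monte-Carlo with a +1 pseudocount
  (default 50,000 permutations).
* **Cell-type refinement** — stroma-vs-tumor differential expression per
  dataset (paired t-test when patient pairing exists, unpaired otherwise);
  candidate genes survive when significantly stroma-up (q ≤ 0.05) in at
  least one gene-level dataset; candidate miRNAs when significantly
  stroma-down in every miRNA-level dataset where measured, or among the
  top-5 strongest stroma-down in any single dataset.  Combinations of
  surviving miRNAs × genes absent from the model predictions are rescued
  as `binding_site` candidates when at least one prediction tool reports a
  site; model-predicted combinations are labelled `combined_model`.

## Synthetic data generator

The generator is the package's test bed and defines its study conditions.
MiRNA values are standard normal per sample — simulated data live on the
z-score scale and enter the pipeline post-normalisation (a raw mode wraps
values through a lognormal map and appends all-zero features to exercise
the raw-input filters).  Regulated genes receive
`slope · max(0, x − b)` from hinge regulators (slope ∈ [−2.5, −0.8],
breakpoint at a quantile of the regulator drawn from 0.3–0.7 by default,
redrawn until ≥ 3 samples sit on each side) or `slope · x` from linear
regulators, plus Gaussian noise (sd 0.3 by default).  The candidate table
is the true pairs topped up with inert decoy pairs to the requested
density.  Subgroup structure shifts selected miRNAs in their subgroup's
samples *before* gene generation, so opposed target shifts emerge through
the regulation itself rather than being painted on.  Cell-type datasets
add ± effect (default 3 noise-sd) to designated stroma-up genes /
stroma-down miRNAs.  Transfection readouts keep true targets with
probability 1−FN and admit non-targets with probability FP.  Every
artifact is a pure function of the configuration, with one global seed
deterministically split into per-component substreams.

What the generator does **not** emulate: count noise (negative binomial),
library-size or batch effects, correlated co-regulation, realistic TCGA
marginals, or annotation errors in the interaction table.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not performance on real tumor data.

## Benchmark protocols and problem sizes

The replication experiments are sized for a single CPU:

* Oracle equivalence: 200 random single-regulator problems, S ∈ [8, 40],
  mixed hinge / linear / unrelated responses with noise sd up to 0.4.
* Parameter recovery: 10 noise-free problems (S = 20) for exactness;
  50 noisy problems (S = 100, noise sd 0.1) for the median breakpoint
  error.
* Model comparison: 20 replicate studies, each S = 120 samples, 4 miRNAs,
  8 genes, one hinge regulator per gene, noise sd 0.3, transfection
  FN = 0.1 / FP = 0.05, per-pair fits at τ = 0.1.  Breakpoints are drawn
  in the 0.55–0.85 quantile range of the regulator: repression engaging
  only at high miRNA abundance is the regime the piecewise model exists
  for, and the regime where a straight line genuinely misses targets;
  with mid-range breakpoints both models recover essentially the same
  pairs and the comparison is uninformative.

## Numerical choices and degenerate inputs

* Solver tolerances: LP solved exactly by HiGHS; MILP relative gap 1e-6,
  per-fit time limit 60 s (30 s in the benchmark protocols).
* A slope is "active" when < −1e-6; breakpoints are undefined (NaN) for
  inactive slopes.
* Constant features are removed at z-normalisation (zero variance carries
  no signal); a constant response is an error at scoring time.
* Pearson correlation of a constant vector is undefined and treated as 0
  (pair excluded by the strict r < 0 rule); in the protein screen such
  pairs are flagged instead.
* Identical group distributions give t = 0/0; these are reported as
  t = 0, p = 1 (no evidence) rather than NaN.
* Writers emit floats at 17 significant digits and readers parse with
  round-trip precision, so write → read restores exact float64 bit
  patterns and reruns are byte-identical.

## Known limitations

* One breakpoint per regulator, lower segment identically zero; no
  multi-segment splines and no quadratic-loss variant.
* Joint fits with many regulators at large S can hit the MILP time limit;
  such fits are excluded from predictions rather than approximated.
* The score threshold τ = 0.1 is a pragmatic default; the package exposes
  it (and B, K, the time limit) rather than claiming an optimal value.
* Gene identifiers are opaque strings: no symbol-alias resolution, no
  network downloads.
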