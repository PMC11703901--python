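# Methods

`swarmnet` reconstructs, as a tested and reusable pipeline, a swarm-based
neural-network procedure for (1) augmenting a seed pathway gene set from
transcriptomic data, (2) inferring a directed, signed gene–gene interaction
matrix over the augmented set, and (3) ranking driver genes within and
between patient cohorts.  Because the original analysis ran on large AML
patient transcriptomes that this package does not ship, every guarantee is
established on synthetic cohorts with known ground truth.

## The neural engine

All stages share one model family: a feed-forward sigmoid perceptron with a
single two-unit hidden layer (N-2-1), trained by per-sample (online)
backpropagation with momentum on inputs and targets scaled to [0, 1].

Parameters, defaults and units:

| parameter | default | meaning |
|---|---|---|
| `learning_rate` | 0.1 | gradient step per sample |
| `momentum` | 0.5 | fraction of the previous update retained |
| `init_weight_range` | [−1, 1] | uniform weight/bias initialisation |
| `max_epochs` | 3000 | hard cap on training epochs |
| `patience_epochs` | 1000 (screening) / 100 (swarm) | early-stopping window |
| `mse_improvement_threshold` | 0.01 | validation-MSE gain that counts as improvement |
| `mse_target` | off | optional absolute validation-MSE convergence stop |
| splits | 60:20:20 | train : validation : test fractions |
| `mccv_iterations` | 50 | Monte Carlo cross-validation repeats |

Early stopping watches the validation MSE: training halts when the best
validation MSE has not improved by more than the threshold within the last
`patience_epochs` epochs (or at `max_epochs`).  The returned weights are
those of the best-validation epoch, not the last one — the stopping rule
would otherwise return weights from a degraded tail.  Design choices the
method description leaves open, fixed here and exposed in config: updates
are per-sample in a fixed seed-derived order (the classic formulation for
this architecture); early stopping watches validation rather than training
error; an absolute convergence stop exists but is off by default, because
halting as soon as a strongly driven target is "good enough" systematically
under-trains the weaker inputs whose weights the interaction scores read
out.  Weight initialisation, sample partitioning and presentation order are
driven by two independent seed streams (`init_seed`, `split_seed`), so
changing one provably leaves the other untouched.  Analytic gradients are
verified against central finite differences as a standing property test.

## Stage 1 — stepwise screening and concordance enrichment

For each pathway gene as target, every other transcriptome gene is scored
as a *single* input to a 1-2-1 net by its mean held-out-test MSE over
`mccv_iterations` random 60:20:20 partitions (lower = stronger predictor).
Candidates are ranked ascending; the whole ranking is repeated
`n_repetitions` = 10 times, and only candidates inside the top-`top_k`
prefix of every repetition are accepted.  The union of accepted candidates
across pathway genes, minus the seed set, is the enrichment; provenance
records which pathway gene(s) each added gene predicted.

Two reconstruction decisions deserve emphasis:

- **Direction.** Each pathway gene is the model *output* and each candidate
  the sole *input*, yielding one transcriptome ranking per pathway gene —
  the shape the concordance step consumes.  The reverse direction is
  available (`direction="candidate_as_output"`).
- **Independent MCCV draws per candidate.** Every (candidate, repetition,
  iteration) triple receives its own partition and weight draw.  We first
  implemented shared draws (common random numbers) and found they defeat
  the concordance filter: with shared partitions the split noise cancels
  between candidates, so a candidate that is spuriously correlated in the
  *sample* ranks identically in every repetition and survives all ten
  intersections.  With independent draws, repetition-to-repetition noise is
  large relative to spurious-correlation effects but small relative to real
  ones, which is precisely the false-discovery control the repetition ×
  intersection design is meant to buy.  Under the null (no planted
  regulators) the enrichment is empty in ≥ 9/10 seeds; planted regulators
  (effect size 2, 200 samples) are recovered through ten-fold concordance
  against 500 competing candidates.

`top_k` (how deep "consistent" reaches) is not stated by the method's
description; the default is 10 and it is reported in all output headers.
Concordance is evaluated per pathway gene and is a strict intersection
across all repetitions.  A classic iterative forward-selection loop
(`stepwise_forward_select`) is implemented but off the default path:
ranking + concordance, not model growth, is the selection mechanism.

## Stage 2 — swarm inference of the interaction matrix

For every gene of the enriched set as output, a swarm of 10 replicate
N-2-1 nets is trained on all remaining genes as inputs (the output gene is
excluded from its own input layer).  A replicate is accepted only if the
Pearson correlation between predicted and observed values on its validation
partition reaches the cut-off (default 0.7); rejected replicates are
excluded from the average, never retrained, and acceptance counts are
reported.  Entry (s, t) of the resulting matrix is the mean signed score of
source s over the accepted replicates for target t; the diagonal is
undefined, so N genes expose exactly N(N−1) entries.  Targets with zero
accepted replicates are recorded as *missing*, never as zero — a zero would
fabricate a "no interaction" claim.

**Score readout.** How a trained net's weights become a signed interaction
score is the largest single reconstruction in this package.  The default is
the connection-weight product

    score(i) = Σ_h  W_in_hidden[i, h] · W_hidden_out[h]

(the classic Olden-style signed importance: data-free, sign = stimulatory
vs inhibitory).  An analytic mean-gradient readout (mean over samples of
∂ŷ/∂x_i) is built in as a cross-check; in a near-linear regime the two
agree in sign on ≥ 95 % of inputs of well-fit nets (measured ≈ 99.7 %), and
a finite-difference oracle (`gradient_oracle_check`) is provided for ad-hoc
verification.  Replicate and per-target seeds are keyed on gene *symbols*,
not row positions, so the matrix is invariant to input row order.  The
swarm uses an internal 80:20 train/validation split only; the MCCV test
partition belongs to stage 1.

## Stage 3 — edge analysis

The matrix flattens to an edge list with two orderings — signed (largest to
smallest raw score, separating stimulatory from inhibitory) and absolute
(interaction strength) — with all rank ties broken lexicographically by
(source, target).  Top-K selection (default 500), per-gene neighbourhood
filters, a five-number score summary with the negative fraction (quartiles
by linear interpolation), and SIF/GraphML/TSV exports are provided.
GraphML carries score, absolute score and sign per edge and summed outgoing
influence per node (for node sizing); dense-module detection (MCODE) is a
published third-party algorithm consumed downstream via these exports
(parameters commonly used with it: degree cut-off 4, node score cut-off
0.2, K-core 2, max depth 1000) and is deliberately not re-implemented.

## Stage 4 — driver ranking and differential drivers

Driver score = row sum of outgoing weights; receiver score = column sum of
incoming weights; both conserve the grand sum of defined entries.
"Influence" ranks by |summed weight| with the sign reported alongside: in a
predominantly inhibitory network all the top drivers are negative, and a
signed descending order would invert "most influential" (a signed mode is
one flag away).  Two behaviours of this statistic are worth knowing.
First, the signed sum cancels under mixed edge signs: a regulator whose
outgoing edges are half stimulatory and half inhibitory can score near
zero however strong each edge is — the statistic is designed for the
predominantly one-signed matrices this method produces, and the synthetic
driver benchmarks plant predominantly negative edges accordingly.  Second,
per-gene min–max normalization removes amplitude, so scaling a cohort's
edge weights down (while they stay well above noise) shrinks the inferred
driver strength only through the degraded fit quality, not proportionally;
a cohort where the signal approaches the noise floor loses the driver
outright (replicates fail the r gate).  Differential analysis compares per-gene mean driver scores
between exactly two cohort groups; group means are unweighted across
cohorts by default (per-cohort weights, e.g. sample sizes, are accepted),
and gene universes are outer-joined with explicit missingness flags — never
silently intersected or imputed.

## The synthetic-data generator

Ground truth networks are sampled as DAGs: edges are drawn forward along a
random gene ordering (count = round(density·n(n−1)); signs negative with a
configurable probability, reflecting the predominantly inhibitory matrices
this method produces on real cohorts).  Expression propagates in
topological order: exogenous genes ~ Uniform(0, 1); each regulated gene is

    x_child = σ( 4 · Σ_j w_j (x_parent_j − 0.5) ) + ε,   ε ~ N(0, noise_sd²)

The gain 4 = 1/σ′(0) makes an edge of weight w contribute slope ≈ w at the
operating point, so the benchmark weights (|w| ∈ [0.5, 1]) plant monotone,
signed, *recoverable* effects without copying the inference model's exact
functional form.  Scenario builders plant hidden regulators behind a
pathway (`make_pathway_scenario`) and cohort pairs sharing topology with
scaled edge strengths (`make_cohort_pair`), recording ground-truth
identities for recovery scoring.

What the generator does *not* emulate: RNA-seq count distributions
(negative binomial, library size), batch effects, feedback loops (cycles
are excluded from generation, not from inference, which never assumes
acyclicity), and any cohort-specific biology.  Passing tests therefore show
that the pipeline recovers planted monotone signed effects at realistic
noise levels and sample sizes (150–400 samples), not that it reproduces any
particular cohort's interaction values.

## Problem sizes used by the test suite and acceptance script

Benchmarks are sized so the full suite replays in minutes on one CPU, as
the package's own reproducibility standard: edge recovery uses 20-gene
networks (density 0.1, 400 samples, noise 0.1, 3 seeds); stepwise recovery
uses 3 regulators of a 3-gene pathway among 500 candidates (200 samples,
MCCV 20, 10 repetitions, top_k 10); the null calibration keeps the same 2 %
top-k selectivity at one-third scale (150 candidates, top_k 3, 10 seeds);
the pair-enumeration check runs the swarm at the real analysis width (83
genes, 6,806 directed pairs) with a minimal training budget, since it
verifies accounting, not fit quality.  Full-scale defaults (MCCV 50,
patience 1000, 3000 epochs) remain the config defaults.

## Numerical notes and limitations

- Determinism is bit-level: all seeds derive from one root via
  `SeedSequence`, gene-keyed by CRC32 of the symbol; the training kernel
  contains no randomness.  Two runs with the same config and seed produce
  identical files.
- Constant genes are dropped at normalization (no trainable signal; the
  min–max formula is undefined for them); `midpoint` pins them to 0.5
  instead.  Normalize-then-subset equals subset-then-normalize for
  per-gene min–max, so the pipeline normalizes the full matrix first.
- Rank ties anywhere are broken lexicographically — reproducibility over
  unspecified behaviour.
- The Pearson-r acceptance gate interprets the training-parameter cut-off
  as per-replicate model quality on validation predictions; on pure-noise
  targets it rejects nearly all replicates, which is the intended guard
  against reading scores out of unfit models.
- Interaction scores carry no confidence intervals; replicate spread is
  available from the per-replicate archive but is not modelled.
- The stepwise stage's compute grows as (pathway genes × repetitions ×
  candidates × MCCV iterations) model fits; the compiled training kernel
  keeps a ~300,000-fit screening run in the minutes range, but genuinely
  transcriptome-wide screens (tens of thousands of candidates) need hours,
  not minutes, at full MCCV depth.
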