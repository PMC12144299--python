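# seqtlboga

Wrapper feature selection for tabular binary classification with a
quantum-encoded, self-adaptive teaching-learning-based optimizer hybridized
with a self-adaptive genetic algorithm. The engine simultaneously searches
the feature-mask space and the SVM hyperparameters (penalty C, RBF width
sigma), and ships five baseline wrappers (GA, PSO, cuckoo search,
differential evolution, grasshopper) behind the same interface plus the
nonparametric benchmark-comparison statistics (Friedman test with
Holm/Hochberg/Li post-hoc procedures).

## How it works

Each candidate solution ("learner") carries one qubit per feature — an
amplitude pair `(alpha, beta)` with `alpha^2 + beta^2 = 1`, where `beta^2`
is the probability that the feature is selected when the qubit string is
observed — plus a real-coded `(C, sigma)` tail. Per iteration:

1. every learner's qubits are rotated toward the current teacher (the best
   learner) by a lookup-table-guided rotation gate (step `0.01*pi`), with
   XOR disagreement indicating which positions move;
2. the real dimensions follow the weighted teacher phase (rank-dependent
   inertia weight, cosine-decaying teaching factor) and the peer-learning
   phase;
3. the observed masks and tails pass through self-adaptive crossover and
   mutation whose probabilities track the population's fitness spread and
   the quantum genotype (amplitude-derived crossover gates, overlap-derived
   mutation rates);
4. each candidate is scored by stratified K-fold cross-validated SVM
   accuracy and kept only if not worse (greedy acceptance + elitism, so the
   best-fitness trace is monotone).

All algorithms issue exactly `population_size * (max_iterations + 1)`
fitness evaluations, so benchmark comparisons are budget-fair by
construction.

## CLI

```sh
# generate a synthetic fixture with a known informative-feature subset
seqtlboga synth --samples 400 --features 20 --informative 5 --seed 1 --out data.csv

# one optimizer run (writes run_record.json + manifest.json)
seqtlboga select data.csv --algorithm seqtlboga --pop 30 --iters 100 --seed 7 --out run/

# benchmark several algorithms with the rank/Friedman/post-hoc report
seqtlboga bench data.csv --algorithms seqtlboga,ga,pso --runs 10 --out bench/
```

`select` and `bench` read the two UCI CSV dialects (9-feature integer
layout with `?` missing values and 2/4 class labels; 30-feature real-valued
layout with M/B diagnoses) as well as the generic `id,M/B,features...`
layout written by `synth`. No downloads are performed — loaders accept
local paths only. A flat YAML config file (`--config`) can hold any run
constant; CLI flags take precedence.

## Package layout

| module | contents |
| --- | --- |
| `seqtlboga.qpop` | qubit population: init, observation/collapse, rotation gate, guided angles, binary-learner distance, overlap, XOR |
| `seqtlboga.tlbo` | weighted/self-adaptive teaching and learning phases, rank-based inertia weight, teaching factors |
| `seqtlboga.saga` | self-adaptive crossover/mutation probabilities, quantum-derived operator rates, crossover/mutation/selection |
| `seqtlboga.wrapper_fitness` | learner decoding, stratified K-fold SVM fitness, confusion-derived metric suite |
| `seqtlboga.optimizer` | the hybrid orchestrator, the five baselines, Levy-flight sampling, budget-parity evaluation accounting |
| `seqtlboga.benchstats` | rank tables, Friedman statistic, post-hoc z comparisons, benchmark harness with FP/FN-rate histograms |
| `seqtlboga.datasets` | CSV dialect loaders, synthetic Gaussian-mixture generator with ground-truth informative subset |
| `seqtlboga.cli` | `select` / `bench` / `synth` commands, manifests, config handling |

## Notes

- The published AUC-style figure is the mean of sensitivity and
  specificity; it is exposed as `auc_balanced` to avoid confusion with
  ROC-curve AUC.
- The nonstandard printed false-positive-rate denominator was replaced by
  the standard `FP / (FP + TN)` so that `specificity + FPR = 1` holds.
- The block count N=4 used by the post-hoc worked example is the unique
  integer consistent with both the published chi-square statistic and the
  published z values.
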