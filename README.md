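# ppisem

Semantic-kernel classification of protein–protein-interaction (PPI)
sentences. The package builds word co-occurrence models (HAL and
BEAGLE) from unlabelled text, uses them to smooth bag-of-words sentence
vectors, and classifies with a probabilistic multiple-kernel learner — a
multinomial-probit GLM over a convex combination of Gram matrices,
fitted by variational Bayes, which returns calibrated class
probabilities and inferred per-kernel weights. A repeated
cross-validation harness (10×10 CV, per-fold Gaussian-parameter tuning,
variance-corrected paired t-test) evaluates pipelines, and a synthetic
corpus generator with controllable synonym clusters makes the whole
chain testable without external corpora.

## Layout

| module | contents |
| --- | --- |
| `ppisem.corpus` | corpus dialects, protein-mention anonymisation, tokenisation, vocabulary, count matrices |
| `ppisem.semantic` | HAL sliding-window co-occurrence (with per-distance components), BEAGLE environmental/context vectors, random projection |
| `ppisem.kernels` | `(X + ε)S` smoothing, cosine/Gaussian/polynomial kernels, convex combination, PSD validation |
| `ppisem.pmkl` | variational-Bayes multinomial-probit multiple kernel learning (fixed or inferred simplex weights) |
| `ppisem.evaluation` | CV fold plans (sentence/abstract schemes), metrics, θ tuning, corrected resampled t-test, experiment driver |
| `ppisem.synthetic` | labelled + unlabelled corpus generator with synonym clusters and a TEST-synonym holdout block |
| `ppisem.benchmark` | end-to-end smoothing-benefit benchmark on the synthetic holdout design |
| `ppisem.serialize` | triplet-text matrix files and JSON model bundles |

## CLI

```sh
# generate a synthetic labelled corpus (both dialects) + unlabelled corpus
ppisem synth --config gen.yaml --out-dir corpus/

# run a cross-validation experiment described by a YAML config
ppisem experiment run --config experiment.yaml --out results/exp1

# corrected paired t-test between two fold-record tables
ppisem experiment compare --a results/exp1_folds.tsv --b results/exp2_folds.tsv \
    --pipeline-a plain --pipeline-b smoothed --metric auc --k 10 --r 10
```

An experiment config names the corpora, the smoothing matrices and the
kernel pipelines:

```yaml
seed: 1
labeled: {path: corpus/labeled_inline.tsv, dialect: inline-tag}
unlabeled: {path: corpus/unlabeled.txt}
cv: {k: 10, r: 10, scheme: sentence}          # or scheme: abstract
tuning: {mode: per-fold, criterion: auc}      # per-fold | global | none
smoothers:
  hal3: {model: hal, L: 3}
  beagle: {model: beagle, D: 4096, max_basis: 30000}
pipelines:
  - name: plain
    kernels: [{kind: gaussian, theta: tune}]
  - name: smoothed
    kernels: [{kind: gaussian, theta: tune, smoother: hal3}]
  - name: composite
    kernels:
      - {kind: cosine}
      - {kind: gaussian, theta: tune, smoother: hal3}
      - {kind: gaussian, theta: tune, smoother: beagle}
```

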