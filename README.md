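# semrdm

Voxelwise encoding models of movie-evoked brain responses built from word-vector
semantic features, brain-derived word dissimilarity matrices, and an adaptive
multi-arrangement engine for behaviorally measured word dissimilarity — with a
synthetic-data generator that plants ground truth so the whole chain is testable
by parameter recovery.

## The scientific problem

Semantic content of natural movies can be summarized by averaging word
embeddings over human scene descriptions, and linear "encoding models" fit from
such features predict fMRI responses voxel by voxel. A separate question is
whether the *representational geometry* of the fitted models — how similar any
two words look in modeled brain space — matches the semantic dissimilarities
people report behaviorally. This package implements that full analysis:

1. **Scene vectors.** Each 1-s scene has one or more annotator descriptions.
   Word vectors are averaged within each description and the per-description
   means averaged across descriptions (a two-level average, not a pooled token
   mean), giving an S×K feature matrix **V**.
2. **Encoding model.** Responses are modeled as **R = VW + ε** after
   concatenating copies of **V** delayed by 3, 4, 5, 6 s (so the S×4K design
   absorbs hemodynamic latency). **W** (4K×N) is fit by L2-regularized least
   squares; the penalty is selected by 10 random 80/20 resamples of the
   training data, scoring each candidate by the voxel-mean Pearson r on the
   held-out 20%. Test-set accuracy is the per-voxel Pearson r, with
   Benjamini–Hochberg FDR significance (q = 0.05) and per-region summaries.
3. **Brain-derived RDM.** Weights are averaged across the four delay blocks
   (K×N), a voxel set is chosen (all, top-M by accuracy, or one region), task
   words are projected through the weights, and the P×P matrix of correlation
   distances (1 − Pearson r) between projected words forms the
   representational dissimilarity matrix (RDM).
4. **Behavioral RDM.** Participants (here, simulated subjects) arrange ≤60
   words in a circular arena; screen distances encode judged dissimilarity.
   Sessions are adaptive: after each trial an inverse-MDS estimator aligns
   trials by least-squares scale factors and combines them by evidence-weighted
   averaging (evidence = squared normalized screen distance, accumulated as
   E = 1 − ∏(1 − w)); the next trial arranges the words with the weakest
   evidence, until all pairs exceed 0.75 or the trial budget is spent.
5. **Statistics.** RDMs are compared by Spearman correlation of upper
   triangles; significance by permutation of item labels (10,000 draws,
   exhaustive for tiny P), differences of correlations by independent
   permutations per pair; Wilcoxon signed-rank and FDR for region-level
   comparisons.

Control feature spaces isolate what the embedding geometry contributes:
**untrained** random vectors (word identity, no structure),
**dimension-shuffled** vectors (each word's entries permuted — the chance
model), and **binary word-occurrence labels**.

## Worked example

```python
import semrdm as sm

cfg = sm.ExperimentConfig(
    master_seed=7, n_dims=20, vocab_per_category=50,
    n_train=1500, n_test=400, n_voxels=300, n_regions=30,
    feature_kinds=("trained", "dimension_shuffled"), n_control_instances=2,
    n_sessions=1, n_perm=2000,
)
bundle = sm.run_experiment(cfg)
report = sm.make_report(bundle)
print(report["performance"][["feature_kind", "mean_r", "significant_fraction"]])
```

prints

```
      feature_kind   mean_r  significant_fraction
           trained 0.076790              0.383333
dimension_shuffled 0.012780              0.006667
dimension_shuffled 0.015377              0.000000
```

and the brain–behavior comparison (`bundle.stats`) gives

```
brain_behavior_trained: rho=0.913  p=0.0005
brain_behavior_dimension_shuffled: rho=0.072  p=0.0095
```

Reading: the model fit on the true (structured) embedding predicts held-out
responses (mean r ≈ 0.08 across all voxels, ~38% individually significant),
while dimension-shuffled controls barely predict; the trained model's brain
RDM strongly tracks the simulated behavioral RDM (ρ = 0.91). The shuffled
control retains a small residual correlation through word occurrence
(scenes containing a word evoke that word's true response) — see
`docs/methods.md` for why that channel exists. The analytic accuracy
threshold `sm.r_threshold(1200, 1e-4)` rounds to 0.11.

A command-line interface mirrors the stages:

```bash
semrdm simulate --config cfg.json --out data/
semrdm fit --features data/features.csv --responses data/responses.csv --out model/
semrdm rdm --model model/ --embeddings data/embedding.txt --words data/task_words.txt --out brain_rdm.csv
semrdm arrange --truth data/true_word_rdm.csv --noise 0.05 --seed 7 --out session/
semrdm compare --rdm-a session/estimate.csv --rdm-b brain_rdm.csv --nperm 10000 --seed 1
semrdm run --config cfg.json --out bundle/
```

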