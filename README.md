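# fmribucket

Ensemble ("bucket of models") classification of two clinical groups from
task-fMRI activation maps, with atlas-region voxel-count features, an
agreement-threshold consensus statistic, and a full-pipeline permutation
test.

## The problem

Gulf War illness (GWI) and chronic fatigue syndrome (CFS) share a nearly
identical clinical picture — chronic pain, fatigue, post-exertional
malaise — and no accepted objective marker separates them.  One line of
evidence is working-memory fMRI: subjects perform an n-back task in the
scanner before and after an exercise stress test, and each subject's
2-back > 0-back contrast yields a 3-D t-statistic map of working-memory
activation.  The question this package operationalizes: does the
*spatial pattern* of suprathreshold activation, summarized per anatomical
region, discriminate the two diagnoses?

The pipeline:

1. **Feature extraction** — threshold each subject's t-map at t > 3.17
   (p < 0.001 uncorrected, strict inequality) and count surviving voxels
   within each of the 117 AAL-style atlas regions, giving a subjects x
   regions count matrix X.
2. **Collinearity screen** — Pearson correlations among regions computed
   three times (training half, testing half, combined); any pair with
   |r| >= 0.9 in any of the three is merged (counts summed) and
   re-screened to a fixed point.
3. **Model build** — stratified 50:50 train/test split; age, sex and BMI
   controlled by ANCOVA-style residualization; recursive feature
   elimination (backward, ranked by logistic coefficients, subset chosen
   by stratified 5-fold CV); then nine classifiers (k-NN, linear SVM,
   decision tree, random forest, AdaBoost, Gaussian naive Bayes, QDA,
   logistic regression, multilayer perceptron) are fit on identical
   features and iteratively re-built: features with random-forest
   importance 0, or with importance standard error above the importance,
   are pruned each round until every model clears a 69% accuracy floor.
4. **Consensus** — with M models voting, the segment at agreement
   threshold k is S_k = {subjects predicted CFS by >= k models}.  Per
   segment: n selected, precision |S_k ∩ CFS| / |S_k| (= 1 − FDR),
   sensitivity, specificity.  Precision rises with k at the cost of
   sensitivity.
5. **Significance** — group labels are permuted and the *entire* build is
   re-run per replicate; p = (1 + #{null >= observed}) / (R + 1) for the
   minimum per-model accuracy, with per-model p-values and a Bonferroni
   threshold alongside.

Because the original subject-level scans are not publicly deposited, the
package ships a synthetic cohort generator (`fmribucket.synthetic`) that
reproduces the data's statistical shape — negative-binomial region
counts, planted standardized group effects, demographics matched to the
study cohort, symptom scores coupled to region counts — so every stage
is testable end to end, including an *exact* round trip from generated
t-map volumes back to the latent counts.

## Worked example

```sh
python analysis/03_model_build.py --seed 0
```

```
terminated by 'floor' after 1 iteration(s); 40 features remain
planted regions retained: 5/5 ['Region_010', 'Region_033', 'Region_056', 'Region_079', 'Region_102']
  k_nearest_neighbors      0.76
  linear_svm               0.78
  decision_tree            0.81
  random_forest            0.86
  adaboost                 0.86
  naive_bayes              0.88
  quadratic_discriminant   0.85
  logistic_regression      0.83
  neural_net               0.76
```

All five planted effect regions survive to the final feature set and
every model beats the 69% floor on the held-out half.  The consensus
curve (`analysis/04_consensus_curve.py --seed 0`) then shows the
precision/sensitivity trade-off as more models must agree:

```
 k  n_selected  precision  sensitivity
 1          30      0.600        0.947
 5          13      0.923        0.632
 9           6      1.000        0.316
```

Subjects selected by all nine models are all truly CFS (precision 1.0),
but only 32% of the CFS group is captured at that stringency — the same
accuracy-versus-sensitivity trade-off the consensus statistic is designed
to expose.  `analysis/05_shuffle_test.py` checks that shuffled labels
cannot reproduce these scores, and `analysis/06_symptom_correlations.py`
relates the selected regions back to the nine symptom-severity scores.

The numbered scripts under `analysis/` run the stages in pipeline order
(simulate → screen → build → consensus → shuffle → symptoms), each a thin
driver over the library; `fmribucket.run_pipeline` executes the whole
sequence from one YAML/dict config and writes a reproducible report
bundle.

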