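# cpgc — correlation-purged Granger causality with RCE-SVM classification

`cpgc` estimates directed (effective) and instantaneous (functional)
connectivity from multivariate region time series — for example averaged
BOLD series of brain regions of interest — and classifies subjects into two
groups from those connectivity features using a recursive-cluster-elimination
support vector machine (RCE-SVM). It is aimed at researchers who want to ask
whether the *pattern of interactions* between regions, rather than activity
within regions, discriminates two cohorts (patients vs. controls, exposed
vs. unexposed), and which specific directed paths carry that information.

## The model

For a k-region series X(t) the usual vector autoregression (VAR) of order p,

    X(t) = Σₙ₌₁..ₚ A(n) X(t−n) + E(t),

yields multivariate Granger causality from the lagged coefficients: the
influence of region j on region i is Σₙ aᵢⱼ(n). When two series also share
*instantaneous* (zero-lag) variance — ubiquitous in slowly sampled data —
that shared variance leaks into the lagged coefficients and produces
spurious "causal" edges. `cpgc` therefore fits a modified VAR with an
explicit zero-lag term,

    X(t) = A′(0) X(t) + Σₙ₌₁..ₚ A′(n) X(t−n) + E(t),   diag A′(0) = 0,

in which each region is additionally regressed on the *other* regions at lag
zero (never on itself, so autocorrelation is untouched). The zero-lag
cross-correlation is then read off A′(0), and Granger causality computed
from A′(1..p) is *correlation-purged* (CPGC): free of the instantaneous
contamination. Each target's equation is an independent ordinary
least-squares fit; the order p is chosen by BIC.

The classifier half implements recursive cluster elimination with a linear
SVM: split the cohort into a training and a held-out test half; K-means the
training features into n clusters; score every cluster by the
cross-validated accuracy of a linear SVM on that cluster's features alone
(default 10 folds × 500 random re-partitions); eliminate the worst 10% of
clusters; shrink n by 10% and repeat down to one cluster. After each pass
the *evolving accuracy* — one SVM on all surviving features, evaluated on
the untouched test half — is recorded; the iteration with maximal test
accuracy (ties → fewer features) yields the final feature ranking.

## Worked example

Simulate a two-group cohort at realistic scale (9 regions, 210 time points
at TR = 2 s, 30 + 26 subjects) with three directed lag-1 path weights
shifted by 0.15 in group B, then estimate connectivity and classify:

```
cpgc simulate --k 9 --t 210 --n-a 30 --n-b 26 --n-planted 3 \
              --effect-size 0.15 --seed 42 --out cohort
cpgc estimate cohort/manifest.csv --feature-set instantaneous_plus_causal \
              --order 1 --no-bandpass --out conn
cpgc classify conn/features.csv --reps 50 --seed 42 --out rce
cpgc ttest conn/features.csv --out ttest.csv
```

which prints

```
wrote 56 subjects and cohort/manifest.csv
wrote connectivity matrices and conn/features.csv (56 subjects x 108 features)
best iteration 25: 4 features, test accuracy 0.964 (all-feature baseline 0.821)
wrote ttest.csv (9 of 108 features at p < 0.05)
```

The 108 features are the 36 undirected zero-lag couplings plus the 72
directed CPGC paths. An SVM using all of them classifies the held-out half
at 0.821; after recursive elimination four features remain and accuracy
rises to 0.964. The ranking (`rce/ranking.csv`, scores shown to three
decimals) puts the three planted paths first:

```
feature,score,rank
ACC->L_Amygdala,0.922,1
R_Amygdala->L_Parietal,0.853,2
ACC->R_Amygdala,0.847,3
L_PFC->MPFC,0.765,4
```

— exactly the paths named in the simulator's `cohort/ground_truth.json`.
`rce/accuracy_curve.csv` traces the evolving accuracy across iterations.

The same stages are available as a library: `TimeSeriesPreprocessor`
(nuisance regression, 0.009–0.08 Hz zero-phase band-pass, z-scoring),
`MVAR` (fit + `causality_matrix()` / `instantaneous_matrix()`),
`ConnectivityFeatureExtractor` (panel → feature table) and `RCESVC`, an
sklearn-style classifier with `fit`/`predict` and a full audit trail in
`result_`.

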