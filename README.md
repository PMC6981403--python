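# prednet — predictive-network confounder screening for categorical surveys

`prednet` screens high-dimensional categorical survey data (e.g. school
health questionnaires) for *potential confounders*: variables that carry
predictive information about many of the other variables and should
therefore be considered as covariates in any downstream association
analysis.

## The method

Given a table of subjects × categorical variables:

1. **One-hot encoding.** Every k-level variable becomes k binary dummy
   columns `var=level` (full one-hot, no reference level dropped).
2. **Per-target boosted models.** For each dummy `j`, a gradient
   boosting machine (100 trees of depth 4, Bernoulli deviance, Newton
   leaf steps, shrinkage 0.1) is trained on 70% of the subjects to
   predict `j` from all dummies of *other* source variables — sibling
   dummies are excluded from the predictor set, since under full one-hot
   coding they determine the target trivially (data leakage). The test
   AUC on the held-out 30% measures each model's accuracy.
3. **Predictive network.** Gain importances (summed squared-error
   reduction of all splits on a feature) populate a directed weighted
   adjacency matrix A with `A[i, j]` = importance of predictor `i` in
   the model for target `j` (rows = outgoing links, columns = incoming).
   No edge thresholding is applied.
4. **Hub centrality.** Variables are ranked by the HITS hub score: the
   principal eigenvector of `A·Aᵀ`, computed by power iteration and
   max-normalized. A high hub score marks a variable that is an
   important predictor in many models — a candidate confounder.
5. **Stratified replication.** The whole procedure is repeated
   independently per stratum (e.g. geographic region); per-node mean/SD
   of hub scores and the pairwise Pearson correlation of the stratum hub
   vectors quantify how replicable the ranking is.

A synthetic-survey generator with planted confounders
(`prednet.synthetic`) makes every stage testable end to end.

## Worked example

```python
import prednet as pn

# 3 strata x 2,000 subjects; one binary confounder drives 12 dependent
# binary variables at log-odds effect 2; 12 more variables are pure noise
table = pn.simulate_survey(pn.SimConfig(seed=1))

model = pn.ConfounderNetwork(table.data, stratum=table.stratum)
results = model.fit(seed=1)
print(results.summary())
```

```
Predictive-network confounder screen
==========================================================
subjects:     6000    variables: 25    dummies: 50
strata:   S1, S2, S3
boosting: 100 trees, depth 4, shrinkage 0.1, train fraction 0.7, seed 1

Top hub variables (mean across strata, SD in parentheses)
----------------------------------------------------------
  1. conf_1=0                     1.0000 (0.0000)
  2. conf_1=1                     0.8268 (0.1046)
  3. dep_11=0                     0.1280 (0.0172)
  4. noise_2=0                    0.1189 (0.0226)
  5. noise_3=0                    0.1181 (0.0167)

Test AUC per stratum
----------------------------------------------------------
  S1         n=  50  median=0.674  IQR=[0.503, 0.722]
  S2         n=  50  median=0.682  IQR=[0.496, 0.714]
  S3         n=  50  median=0.653  IQR=[0.498, 0.696]

Cross-stratum hub-score Pearson r: min=0.988, mean=0.993
```

The planted confounder's two dummies take ranks 1–2 with a wide margin
over everything else; hub scores correlate at r ≈ 0.99 across the three
strata, i.e. the ranking replicates; and the overall AUC median mixes
the predictable dependent targets (median ≈ 0.71) with the noise
targets (median ≈ 0.5, chance level).

The same pipeline is available from the shell:

```sh
prednet simulate --out survey.csv --truth truth.json --seed 1
prednet run --input survey.csv --stratum stratum --seed 1 --outdir report/
prednet report --rundir report/
```

`report/` then contains per-stratum hub scores, AUC tables and edge
lists, the cross-stratum mean/SD and correlation tables, the top-k
ranking, a run log and a config echo.

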