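# targetindex

Target-based gene expression indices for predicting tumor response to
chemotherapy.

## The problem

Neoadjuvant chemotherapy regimens for breast cancer are built around drugs
with known molecular targets — anthracyclines inhibit topoisomerase
II-alpha (TOP2A), taxanes bind beta-tubulin (TUBB) — yet the expression of
the target transcript alone is a weak clinical predictor of pathological
complete response (pCR). The idea implemented here is that the transcripts
*co-expressed* with the target are a better readout of target activity
than the target probe itself: averaging them cancels probe-level
measurement noise around the shared biological signal.

`targetindex` provides the full pipeline for building and validating such
indices:

1. **Discovery** — in each of several expression cohorts (which need no
   outcome annotation), Pearson-correlate every probe against the target
   probe and keep the most- and least-correlated 1%. Probes falling in the
   same tail in *every* cohort form a consensus signed index: a positive
   set P and a negative set N.
2. **Scoring** — after z-scoring every probe within a dataset
   (mean 0, sd 1), each patient's index is

   ```
   score = (1/n_P) Σ_{i∈P} x_i  −  (1/n_N) Σ_{j∈N} x_j
   ```

   the mean z-score over P minus the mean over N. Indices for different
   drug targets are summed into a combination index for multi-agent
   regimens. No responder threshold is attached.
3. **Validation** — AUC (Mann–Whitney, ties ½) with a two-sided p-value,
   t-tests of group means (Welch's correction when variances differ),
   univariate/multivariate logistic regression with Wald odds-ratio CIs
   (age per decade, grade ordinal, ER/node as indicators), and
   ANOVA + Tukey HSD for comparing predictors.

A synthetic-cohort generator (`targetindex.simulate`) reproduces the
statistical structure the method assumes — a latent per-patient target
activity driving a signed co-expression module and a logistic pCR outcome
at ~20% prevalence — so that every stage is testable end to end with known
ground truth and no downloads.

## Worked example

`examples/score_and_validate.py` discovers an index on three synthetic
cohorts (200 patients × 2000 probes, a 50/25-gene signed module) and
validates it on an independent 300-patient cohort with a strong latent
effect:

```
validation cohort: 77 pCR vs 223 RD
AUC = 0.787 (p = 5.56e-14)
mean score RD = -0.33, pCR = 0.96 (t = 9.23, p = 1.36e-16, Welch = True)
odds ratio per unit score = 2.74 [2.04, 3.69]
```

The AUC is the probability that a randomly chosen responder outscores a
randomly chosen non-responder; the odds ratio says each unit increase in
the index multiplies the odds of pCR by 2.74. The other examples cover
cohort simulation, discovery precision/recall against ground truth, and
index combination with ANOVA/Tukey predictor comparison.

The same stages are available from the shell:

```
targetindex simulate --config sim.yaml --seed 1 --out cohorts/
targetindex discover --expr A.tsv --expr B.tsv --expr C.tsv \
    --target 201292_at --fraction 0.01 --out idx.json
targetindex score    --expr V.tsv --index idx.json --out scores.tsv
targetindex validate --expr V.tsv --clinical C.csv --index idx.json \
    --index idx2.json --combine --out report.json
```

Expression input is tab-delimited log2 intensity (probes × samples; the
GEO series-matrix dialect is also accepted), clinical input is CSV with
`sample_id,response,age,er_status,grade,node`.

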