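# moodnpi

Predicting the severity of neuropsychiatric symptoms in dementia from
video-derived facial-expression time series.

Behavioral and psychological symptoms of dementia (BPSD) are usually scored
with the informant-based Neuropsychiatric Inventory (NPI) — slow, rater-
dependent, and retrospective over a month.  A camera-based facial-expression
recognition system instead emits a stream of mood labels (anger, sadness,
neutrality, happiness) during daily activities.  `moodnpi` implements the
analysis pipeline that turns such streams into NPI-score predictions, for
biostatisticians and dementia-care researchers who want to study or extend
that pipeline.  Because the original day-care observations were never
deposited, the package ships a synthetic cohort generator with the documented
scale and structure of that cohort, so every stage is runnable and testable
end to end.

## The model

Mood labels are encoded ordinally (anger = 1, sadness = 2, neutrality = 3,
happiness = 4).  For each NPI assessment, the codes `E1..EN` observed in the
7 days before the assessment are summarised by ten statistics: the five
mood-frequency counts (negative = sadness + anger, and each mood separately),
the happiness−sadness count difference, the mean amplitude `Ē = ΣEi/N`, the
switch frequency `Σ|Ei − Ei−1|`, the switch range
`max|Ei − Ei−1| − min|Ei − Ei−1|`, and the sample standard deviation of the
codes.

Three predictors of the NPI total `y ∈ [0, 144]` are fitted on these
features:

* **LR** — bidirectional p-value stepwise linear regression;
* **RF** — a random-forest regressor with an importance ranking;
* **EM** — the equal-weight ensemble `EM = (LR + RF) / 2`.

Model development is two-staged: LR and RF are fitted per recruitment wave
(7 then 16 participants, each split 50/50 into train and test), and the
features ranked in the RF top 6 of *both* stages become the final feature
set.  The final models are evaluated under patientwise 6-fold
cross-validation (folds partition participants, never assessments) and under
a Pocock–Simon minimization train/test allocation stratified by sex, age
band and NPI level.  Accuracy is MAE, RMSE and the Pearson correlation
between predicted and observed totals; predictions are clamped to the NPI
instrument range.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_two_stage_models.py
python analysis/04_final_models.py
python analysis/05_allocation_balance.py
```

`01` prints the cohort scale — 23 participants, 13,800 emotion records,
38 NPI assessments with 45 % zeros and a maximum of 45.  `02` shows the
univariate structure the models exploit, e.g.

```
freq_negative      r = +0.97
freq_sadness       r = +0.95
switch_frequency   r = +0.91
diff_happy_sad     r = -0.89
mean_amplitude     r = -0.94
```

— negative moods and mood lability up with symptom burden, happiness and
mean amplitude down.  `03` reports the stage fits and the cross-stage
selection (here `freq_negative, freq_sadness, freq_anger, mean_amplitude,
switch_frequency`), and `04` the final held-out accuracy:

```
    protocol model      mae     rmse        r
 patientwise    EM 2.069253 3.309808 0.972838
 patientwise    LR 2.147767 3.097750 0.975966
 patientwise    RF 2.286421 3.929119 0.961109
minimization    EM 1.045167 1.250866 0.996560
```

The ensemble's MAE never exceeds the LR/RF average (a triangle-inequality
guarantee) and its held-out correlation with the true scores is strong under
both sampling protocols.  `05` quantifies the design choice behind the
minimization split: over 200 simulated cohorts its worst per-factor arm
imbalance averages 5.5 against 9.8 for seeded random splits.

The same pipeline is scriptable on external data via the CLI
(`moodnpi simulate | featurize | fit | evaluate | report`); input formats
are plain CSVs documented in `moodnpi/io.py`.

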