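# strokesofa

Sepsis screening scores for stroke patients: scoring engines, score
derivation, paired-AUC non-inferiority inference, and synthetic cohorts.

## The problem

Infections after ischemic stroke (mostly pneumonia and urinary tract
infections) can progress to sepsis. Under the Sepsis-3 convention, sepsis is
operationalized as an acute rise of the Sequential Organ Failure Assessment
(SOFA) score of **ΔSOFA ≥ 2** over the admission baseline. The SOFA score,
however, was built for ICU patients: it needs arterial blood gases,
vasopressor doses and bilirubin — data rarely available on a stroke unit.

This package implements a stroke-adapted alternative, the **Stroke-SOFA
(S-SOFA)** score: five binary bedside items,

| Organ system   | S-SOFA item (1 point each)      | SOFA counterpart (0–4 points)  |
|----------------|---------------------------------|--------------------------------|
| CNS            | NIHSS ≥ 14                      | GCS bands 13–14 … < 6          |
| Respiration    | SpO₂ < 90 %                     | PaO₂/FiO₂ bands < 400 … < 100  |
| Cardiovascular | MAP < 70 mmHg                   | MAP < 70 / vasopressor tiers   |
| Coagulation    | platelets < 150 ×10⁹/l          | bands < 150 … < 20             |
| Renal          | creatinine ≥ 1.2 mg/dl          | bands 1.2–1.9 … ≥ 5.0 / urine  |

scored 0–5, with the same Δ ≥ 2 positivity rule. The package covers the full
workflow around such a score:

* **`strokesofa.scoring`** — SOFA (0–24) and S-SOFA (0–5) engines with the
  field's conventions: worst-value-of-day aggregation, SpO₂/FiO₂ substitution
  when PaO₂ is missing, missing components scored 0 and reported, the Δ ≥ 2
  rule.
* **`strokesofa.derivation`** — the three-step derivation procedure that
  produces such a score from a training cohort: univariable odds-ratio
  screen (Wald 95 % CI excluding 1), Youden-index dichotomization with
  rounding and normal-range overrides, and exhaustive model ranking by
  Nagelkerke's R² with explicit near-tie preference rules.
* **`strokesofa.auc`** — empirical (Mann–Whitney) AUC with DeLong
  variance/covariance for paired scores, the one-sided non-inferiority test
  (reject "AUC_a − AUC_b < −0.06" when the 95 % CI lower bound exceeds
  −0.06, equivalently p < 0.025), and an analytic + Monte-Carlo power and
  sample-size planner.
* **`strokesofa.cohort`** — synthetic stroke-infection cohorts with known
  ground truth (three timepoints per patient, latent septic deterioration,
  mRS outcomes, care-setting flags and missingness), so every pipeline is
  testable end to end without patient data.
* **`strokesofa.io` / CLI** — CSV cohort I/O with a column dictionary and
  range checks, score-definition files, and the `simulate`, `score`,
  `derive`, `validate`, `power` subcommands.

## Worked example

Simulate a 400-patient cohort, apply the Δ ≥ 2 rule, and compare both scores:

```bash
strokesofa simulate --n 400 --seed 7 --out cohort.csv
strokesofa score --input cohort.csv --score s-sofa --out scored.csv
strokesofa validate --input cohort.csv --out validation.csv
```

`scored.csv` starts

```
patient_id,score,admission_total,onset_total,day_after_total,baseline_total,window_max,delta,positive
P00000,s-sofa,1,5,5,1,5,4,True
P00001,s-sofa,2,2,2,2,2,0,False
```

patient `P00000` rose from 1 point at admission to 5 in the infection
window (Δ = 4 ≥ 2: screen positive), `P00001` did not change. The
full-cohort rows of `validation.csv` read (rounded):

```
       outcome  auc_a  auc_b  difference  diff_lo  p_one_sided  non_inferior
          poor  0.840  0.850      -0.010   -0.031          0.0          True
death_hospital  0.837  0.836       0.001   -0.025          0.0          True
     death_3mo  0.945  0.940       0.005   -0.011          0.0          True
```

`auc_a` is the S-SOFA AUC at infection onset, `auc_b` the SOFA AUC on the
same patients, and `non_inferior` applies the −0.06-margin rule to the
DeLong CI of the difference (`diff_lo` > −0.06 here, so non-inferiority is
declared on this synthetic cohort; AUCs on synthetic data are higher than
on real patients because the generator's outcome is driven directly by the
latent dysfunction burden).

The sample-size planner reproduces the validation design of the score —
margin −0.06, assumed true difference +0.06, 80 % power at one-sided 2.5 %,
30 % outcome prevalence:

```
$ strokesofa power
required n = 354 (achieved power 0.8003)
  n =   177  power = 0.5088
  n =   266  power = 0.6807
  n =   354  power = 0.8003
  n =   442  power = 0.8794
  n =   531  power = 0.9296
```

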