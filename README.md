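# swvquant

Calibration-curve-free caffeine quantification from square-wave voltammetry
(SWV) of untreated beverages.

Commercial coffee is a hostile matrix for electrochemistry: besides the
caffeine oxidation peak at ~1.6 V (on a boron-doped diamond electrode), the
voltammogram carries a broad 0–1 V band from hydroxyl-bearing organics, and
no electrolyte is added, so a conventional standard-addition calibration
curve cannot be built.  `swvquant` implements a machine-learning alternative:
train on beverages whose caffeine content the manufacturer publishes, and
predict an unknown beverage directly from its raw triplicate voltammograms.

## Method

Each sample is measured in triplicate.  Two feature representations feed a
principal-component regression (PCR) each:

* **analytic branch** — the full resampled spectrum, mean-centered, reduced
  to its leading principal-component scores; predictions X₁…X₃;
* **logical branch** — the caffeine oxidation window 1.55–1.65 V resampled
  to 51 points and integrated into 17 contiguous trapezoidal segment areas,
  z-scored; predictions Y₁…Y₃.

The component count of each PCR is chosen by leave-one-sample-out grid
search on the training set (replicates of a sample always move together).
The two branches are then combined by the **graded evaluation**:

```
α = X₁ + Y₁,  β = X₂ + Y₂,  γ = X₃ + Y₃        (pair sums)
Aveᵢ = (Xᵢ + Yᵢ) / 2                            (graded values)
ε = median(α, β, γ),   μ = ε ÷ 2                (final prediction)
```

so the final concentration μ is the median over replicates of the
branch-averaged prediction.  Accuracy bookkeeping uses
recovery = 100·predicted/published and accuracy = 100 − |recovery − 100|.

The package also ships a phenomenological SWV/CV simulator (Gaussian peaks,
interferent band, per-sample electrode gain, replicate noise) so the whole
pipeline is testable end to end, and an electrode-QC module that estimates
double-layer capacitance as the slope of |j_a − j_c|/2 at the non-faradaic
point (0.05 V) against scan rate.

## Worked example

The bundled *beverage panel* dataset holds the per-replicate branch
predictions for ten commercial coffees (40–82 mg caffeine/100 g, five
brands, one decaffeinated sample spiked with 60 mg/100 g).  Aggregating and
evaluating it:

```python
from swvquant.datasets import panel_records, panel_published
from swvquant.evaluation import evaluate_sample, summarize, sample_table

records = panel_records()
published = panel_published()
print(sample_table(records, published))
rows = [evaluate_sample(published[r.sample_id], r.final, r.sample_id)
        for r in records]
s = summarize(rows)
print(f"mean accuracy {s.mean_accuracy}%  median accuracy {s.median_accuracy}%")
```

prints

```
             published  predicted  recovery_pct  accuracy_pct  error
sample_id
Suntory A         40.0      47.58         119.0          81.0  -7.58
Suntory B         40.0      42.25         105.6          94.4  -2.25
Coca-Cola A       60.0      62.71         104.5          95.5  -2.71
UCC A             60.0      51.64          86.1          86.1   8.36
Asahi A           62.0      60.54          97.6          97.6   1.46
KIRIN A           70.0      67.47          96.4          96.4   2.53
Asahi B           70.0      68.69          98.1          98.1   1.31
KIRIN B           78.0      73.24          93.9          93.9   4.76
Asahi C           80.0      81.72         102.2          97.8  -1.72
Suntory C         82.0      80.37          98.0          98.0   1.63

mean accuracy 93.88%  median accuracy 95.95%
```

Each row compares the final graded prediction with the manufacturer's
published content: e.g. Suntory A is over-predicted by 7.58 mg/100 g
(recovery 119 %), while most samples sit within a few percent; the panel
averages 93.88 % accuracy with median 95.95 %.

The same pipeline runs end to end from the shell on simulated spectra:

```sh
swvquant simulate -c 40,40,60,60,62,70,70,78,80,82 --seed 7 --out panel_sim
# wrote 10 samples (30 spectra) -> panel_sim/manifest.csv
printf 'data: panel_sim/manifest.csv\noutput_dir: out\n' > run.yaml
swvquant quantify --config run.yaml
# 10 samples: mean accuracy 96.60%, median 97.15%
```

`out/` then contains `replicate_predictions.csv`, `sample_predictions.csv`,
`branch_errors.csv`, `summary.csv`, and `run_metadata.json` (config hash,
seed, per-fold selected component counts).

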