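# irpnn — infrared tissue-spectrum classification

`irpnn` classifies ATR-FT-IR absorbance spectra of tissue into three
stages of carcinogenesis — normal, early carcinoma, advanced carcinoma —
using discrete-wavelet energy features and a Parzen-window probabilistic
neural network (PNN). It is aimed at chemometrics users who want a small,
fully reproducible reference implementation of the FT-IR → DWT → PNN
chain, including a synthetic spectrum generator so every stage can be run
and tested without instrument data.

## Method

1. **Spectra.** Absorbance on the uniform grid 4000–650 cm⁻¹ at 2 cm⁻¹
   spacing (1676 points, stored descending). Analysis is restricted to
   the fingerprint region 2000–650 cm⁻¹ (676 points).
2. **Wavelet features.** The restricted spectrum is decomposed to five
   dyadic levels with the Daubechies db4 filter bank (Mallat pyramid,
   half-point symmetric extension). The detail sequences d₃ and d₄ are
   each split into two contiguous halves, and the energy
   Eᵣ = Σᵢ cᵢ² of each half forms one feature; the 4-vector is scaled to
   unit Euclidean norm.
3. **PNN.** The pattern layer stores one Gaussian kernel per training
   exemplar; the summation layer forms per class k

       H_k(x) = Σᵢ exp(−‖x − c_ki‖² / 2σ²),   Y_j = Σ_k w_jk H_k(x),

   with default weights w_jk = δ_jk / n_k, so Y_j is a Parzen
   kernel-density estimate of class j and the argmax decision is the
   Bayes rule under equal priors. The width σ is chosen by an ascending
   grid search on the leave-one-out error (goal ≤ 0.01).
4. **Evaluation.** A stratified 230/210 train/test split of the
   440-sample cohort (220/120/100 per class); the report gives the
   per-class recognition rate (confusion-matrix diagonal over row sum)
   for both partitions.

The synthetic generator renders each class as a sum of Gaussian bands at
the assigned tissue wavenumbers (3327, 2956, 2924, 2852, 1743, 1650,
1555, 1242, 1084 cm⁻¹) whose class-dependent amplitudes encode the
biochemistry of progression — e.g. the ester-carbonyl band at 1743 cm⁻¹
weakens in early carcinoma and is absent in advanced carcinoma — plus
per-band amplitude jitter, a random linear baseline, and white noise.

## Worked example

```python
import dataclasses
from irpnn import PipelineConfig, run_pipeline

report = run_pipeline(dataclasses.replace(PipelineConfig(), seed=1))
print(report.summary())
```

prints

```
Recognition rates (%)

          normal   early  advanced
training   100.0  100.00     100.0
testing    100.0   98.25     100.0

Confusion matrix — training (rows: true, cols: predicted)
          normal  early  advanced
normal       115      0         0
early          0     63         0
advanced       0      0        52
overall accuracy: 100.00%

Confusion matrix — testing (rows: true, cols: predicted)
          normal  early  advanced
normal       105      0         0
early          1     56         0
advanced       0      0        48
overall accuracy: 99.52%
```

Training recognition is perfect for all three classes; on the held-out
partition the only confusion is an early-carcinoma sample predicted as
normal — those two classes overlap by construction — while the advanced
class, whose band structure is strongly distinct, is recognized at 100%.

The same run from the shell:

```
irpnn run --seed 1 --out results/run1
```

writes `report.csv`, `summary.txt`, `model.json`, the two feature tables
and a parameter log. The other subcommands (`simulate`, `decompose`,
`extract`, `train`, `predict`, `evaluate`) expose the individual stages;
see `irpnn --help`.

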