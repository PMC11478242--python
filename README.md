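# cannclass

Hierarchical GA-PLS-DA classification of low-resolution EI mass spectra for
structural annotation of novel synthetic cannabinoids (NSCs).

## The problem

New synthetic cannabinoids reach the illicit market faster than reference
standards and library spectra can follow, so a routine GC-EI-MS library
search cannot identify them. Their mass spectra are nonetheless informative:
the core (indole, indazole, azaindole, naphthoylpyrrole), head (e.g.
naphthyl), and tail (e.g. pentyl, 5-fluoropentyl, 4-fluorobenzyl/FUB)
moieties each leave characteristic fragment ions — m/z 144 for an indole
core, 145 for indazole/azaindole, 127/155 for a naphthyl group, 109/252 for
a FUB tail, 232/233 for 5-fluoropentyl-bearing cores, and so on. `cannclass`
turns that chemistry into a decision cascade of seven binary PLS-DA
classifiers that flags whether an unknown is cannabinoid-related at all,
separates classical (THC-type) from synthetic cannabinoids, and then calls
the core, head, and tail groups of a synthetic — structural intelligence for
forensic triage, not a replacement for confirmatory NMR/HRMS.

## The model

Spectra are base-peak-normalized, cropped to m/z 40–300 and binned to unit
mass (261 variables), then autoscaled. Each node is a PLS1 regression
(NIPALS) of the autoscaled matrix **X** onto a coded class variable
y ∈ {+1, −1}: **X** = **T P**ᵀ + **E**, y = **T q** + f, with the
discrimination score ŷ = **x**ᵀ**b** thresholded at the equal-priors Bayes
crossing of class-wise Gaussians. A genetic algorithm (population 64,
window width 1, mutation rate 0.005, ≤ 50 generations) selects m/z
variables by minimizing the 10-fold venetian-blinds RMSECV; the
classical-vs-synthetic node skips the GA, where selection is known to
overfit. Models are scored with accuracy, sensitivity (TPR), specificity
(TNR), F1 and Matthews correlation coefficient (MCC), for calibration,
cross-validation and external validation. The per-LV weights map back to
m/z so each separation can be read in terms of fragment ions.

Because the real training/test libraries (SWGDRUG, Cayman) cannot be
redistributed, the package ships a synthetic spectrum generator encoding the
diagnostic fragment tables above, with configurable intensity jitter, noise
peaks, and peak dropout. See `docs/methods.md` for the full model and
generator description.

## Worked example

```sh
cat > run.yaml <<'YAML'
cv_folds: 10
sim: {n_train_per_class: 8, n_test_per_class: 4,
      intensity_jitter: 0.0, n_noise_peaks: 0, peak_dropout: 0.0}
ga: {population_size: 16, max_generations: 8}
YAML

cannclass simulate --config run.yaml --seed 7 --out data
cannclass train    --config run.yaml --seed 7 \
    --spectra data/train.msp --labels data/labels_train.csv --out bundle
cannclass evaluate --config run.yaml --bundle bundle \
    --cal-spectra data/train.msp --cal-labels data/labels_train.csv \
    --test data/test.msp --test-labels data/labels_test.csv --out table1.csv
cannclass predict  --bundle bundle --spectra data/test.msp --report report.json
```

`simulate` writes 96 training and 48 test spectra (8 + 4 per class, 12
classes, noiseless here so the example is exact). `evaluate` produces a
21-row figures-of-merit table (7 nodes × calibration / cross-validation /
external validation):

```
model,set,accuracy,tpr,tnr,f1,mcc,misclassified
cannabinoid_vs_other,calibration,1.0,1.0,1.0,1.0,1.0,
cannabinoid_vs_other,cross-validation,1.0,1.0,1.0,1.0,1.0,
cannabinoid_vs_other,external validation,1.0,1.0,1.0,1.0,1.0,
...
```

On noiseless data every metric is 1.0 — the classes are separable by
construction; under the generator's default noise the held-out MCC stays
≥ 0.9 at every node. The prediction report gives, for a JWH-018-like test
spectrum (indole core, naphthyl head, pentyl tail), the full route through
all seven nodes and the annotation:

```json
{
 "category": "synthetic cannabinoid",
 "core_group": "indole",
 "head_is_naphthyl": true,
 "tail_is_fub": false,
 "tail_is_5f_pentyl": false
}
```

with per-node scores and thresholds (node 1 score 1.007 against threshold
0.151 here: comfortably cannabinoid). A fentanyl-like spectrum instead stops
after node 1 with `"category": "other drug"`.

The same pipeline is available as a library:

```python
from cannclass import SimConfig, generate_dataset, train_cascade, classify_unknown

train, test = generate_dataset(SimConfig(seed=7))
model = train_cascade(train, seed=7)
```

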