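# Methods

`cannclass` implements a hierarchical system of binary PLS-DA classifiers
that annotates the structure of a suspected novel synthetic cannabinoid
(NSC) from its low-resolution electron-ionization (EI) mass spectrum. This
note documents the model, its assumptions, the tunable parameters, the
synthetic data generator, and the numerical choices that were genuinely open.

## Data model

A spectrum is a list of (m/z, intensity) peaks. The working representation
is a samples × m/z matrix: each spectrum is base-peak-normalized (most
intense peak = 100), cropped to nominal mass 40–300 (261 integer bins, both
bounds configurable), and binned to unit mass by round-half-up of m/z, with
coinciding peaks summed. Normalization precedes cropping so the base peak is
defined on the full spectrum — the order is a package choice; it matters only
for spectra whose base peak lies outside the crop window. Unit-mass binning
reflects the nominal-mass resolution of routine GC-EI-MS instruments.

Class structure follows the chemistry of synthetic cannabinoids, which
combine four moieties: a core (indole, indazole, azaindole,
naphthoylpyrrole), a head group (e.g. naphthyl), a linker, and a tail group
(e.g. pentyl, 5-fluoropentyl, 4-fluorobenzyl/FUB). Each compound carries an
explicit annotation record; "unknown / not applicable" is encoded as a
missing value, never as a default class.

## Preprocessing

All modeling is done on autoscaled data: per-variable mean-centering and
scaling to unit sample standard deviation (n−1 denominator, the chemometrics
convention). Scaling parameters are estimated on the training subpopulation
of each cascade node and applied unchanged to prediction data. Zero-variance
columns (std < 1e−12) are dropped, and the kept-column mask is stored so
prediction data are reduced identically.

Cross-validation uses venetian blinds: sample i (in dataset order) goes to
fold i mod k, k = 10 by default. Whether the original work reordered samples
before splitting is unknown; the splitter uses as-loaded order, and the
trainer offers an optional class-interleaved ordering so both classes land
in every fold even for block-ordered data. For node populations smaller than
k, the fold count is clipped to n.

## PLS-DA

Each node is a PLS1 regression of the autoscaled spectra onto a coded class
variable, +1 for the node's positive class and −1 for the negative, centered
internally. The decomposition is NIPALS with per-component deflation;
training scores are mutually orthogonal, and with as many latent variables
(LVs) as the rank of X the fit coincides with ordinary least squares (both
properties are tested against independent oracles). For a single response
NIPALS and SIMPLS give identical predictions, so the algorithm choice is
immaterial; the model bundle records `nipals` as provenance. Latent-vector
sign indeterminacy is fixed by forcing the largest-|loading| element of each
x-loading positive, making score plots and weight reports reproducible.

LV counts per node: 3 (cannabinoid vs other drugs), 2 (classical vs
synthetic), 3 (naphthoylpyrrole vs other cores), 2 (indole vs
indazole/azaindole), 2 (naphthyl head), 1 (FUB tail), 2 (5F-pentyl tail; no
stated value exists for this node, so it defaults to the most common
setting, configurable).

The decision threshold on the predicted score is the equal-priors Bayes
boundary of two Gaussians fitted to the class-wise training scores (the
equal-density crossing between the class means), falling back to the
midpoint of the means when either class variance is numerically zero or no
crossing lies between the means. A score exactly at the threshold is
assigned to the positive class (documented tie rule). The Gaussian-crossing
rule is a package choice — common chemometrics practice; the source material
shows a threshold without defining one.

`lv_weight_report` maps a latent variable's weights back to m/z values,
sorted by |weight| with sign retained, so an analyst can read which fragment
ions (e.g. 144 vs 145 for indole vs indazole cores) drive a separation and
in which direction.

Exploratory operations: PCA via SVD of the centered matrix (deterministic
sign convention as above) and Ward hierarchical clustering via SciPy's
Lance–Williams implementation, verified in tests against an exhaustive
brute-force Ward oracle.

## Genetic-algorithm variable selection

The GA searches binary inclusion masks over the 261 m/z variables. The
fitness of a mask is the venetian-blinds RMSECV of the PLS-DA score on the
masked columns, with scaling and the PLS model refit inside every fold; an
empty mask is +∞. The objective is a package choice (the toolbox convention
for GA variable selection); the source settings fix population 64, window
width 1, mutation rate 0.005, and 20–50 generations (hard cap 50 here).
Remaining operator choices are unstated anywhere and fixed for
reproducibility: inclusion probability 0.3 at initialization, tournament
selection of size 2, double-point crossover, elitism of one, per-gene bit
mutation. Runs are fully determined by (data, config, seed).

The original generation counts were chosen by human monitoring to avoid
overfitting. The package substitutes two safeguards: an optional stall-based
early stop (halt when the best fitness has not improved for a set number of
generations; off by default, exposed through the CLI config), and an
unconditional fallback — after the run, the selected mask's RMSECV is
compared with the all-variables RMSECV and the node falls back to all
variables with a logged warning if selection would hurt cross-validated
prediction. This mirrors the observed failure mode of GA selection on the
classical-vs-synthetic node, which therefore defaults to `use_ga = false`.

## The decision cascade

Seven binary nodes in a fixed routing order:

1. cannabinoid vs other drugs — all compounds;
2. classical vs synthetic cannabinoids — cannabinoids only;
3. naphthoylpyrrole vs other cores — synthetic cannabinoids only;
4. indole vs indazole/azaindole — synthetics excluding naphthoylpyrrole;
5. naphthyl vs other head groups — same population as node 4;
6. FUB tail present/absent — same population;
7. 5F-pentyl tail present/absent — same population.

Routing is a function of node decisions only. A spectrum rejected at node 1
is reported as "other drug" with exactly one executed node; a classical
cannabinoid stops after node 2; a naphthoylpyrrole-core compound skips nodes
4–7 (those models were trained without naphthoylpyrrole compounds); all
other synthetics run nodes 4–7, the two tail nodes independently, since a
compound can be negative for both. Training the head/tail nodes on
synthetics minus naphthoylpyrrole compounds is a design decision (the
subgroup discussion treats them against indole/indazole backbones) and is
configurable.

Node 4's positive class is indole, keeping the package-wide convention that
the first-named class of a node is positive. The published table reports the
same node with indazole/azaindole as positive; accuracy, F1 as defined here,
and MCC are unaffected, but TPR/TNR are swapped relative to that table.

A node with fewer than 4 compounds in either class is skipped with a
warning; predictions whose route crosses a missing node are flagged
`partial`. Trained bundles serialize to JSON (scaling, mask, PLS arrays,
threshold, labels, seed, config hash) and are byte-identical given identical
data, configuration, and seed.

## Figures of merit

Accuracy, TPR (sensitivity), TNR (specificity), F1 = 2TP/(2TP+FP+FN), and
Matthews correlation coefficient, computed from the binary confusion matrix.
MCC returns 0 when any denominator factor vanishes; TPR/TNR raise an
explicit error when their class is absent (reported as n/a in tables).
Evaluation tables report calibration, cross-validation (scaling, PLS and
threshold refit per fold, variable mask fixed — the mask is selected once on
the full training set, so CV rows carry the usual selection-bias optimism),
and external validation per node, with misclassified compound ids listed.
Exported tables round half-up to 4 decimals.

## Synthetic data generator

Real spectral libraries cannot be redistributed, so the generator emulates a
screening library: 12 compound classes — classical cannabinoids, 7 synthetic
core/head/tail combinations covering both labels at every node, and
fentanyl-, cathinone-, tryptamine- and phenethylamine-like "other drug"
classes (an opioid-like profile is also available). Characteristic fragment
m/z values follow the diagnostic ions documented for these classes (144/145
core ions, 214/215 and 232/233 core+tail ions tied to tail fluorination,
127/155/284/285 naphthyl ions, 109/252 FUB ions, 41/69/73/91/175/231/260 for
classical cannabinoids, etc.). Mean intensities, the naphthoylpyrrole
profile's non-naphthyl peaks, and the generic head-group peak are synthetic
design values, not measurements.

Noise model and defaults: per-peak dropout 0.05 (≈95% effective presence),
15 uniform-random noise peaks per spectrum at unoccupied m/z positions with
intensity ≤ 20, and multiplicative lognormal intensity jitter σ = 0.15.
Default sizes are 32 training and 8 test compounds per class (384/96
spectra), matching the scale of the real training library (~434 spectra);
node populations much smaller than that let the GA memorize chance
noise-peak alignments and degrade held-out accuracy, so the library scale is
treated as part of the study conditions. With jitter 0, dropout 0 and no
noise peaks the classes are linearly separable and the trained cascade is
exact at every node.

What passing tests on this generator do **not** show: robustness to real EI
intensity distributions, isotope patterns, co-eluting impurities, matrix
background, inter-instrument variation, or structural analogs outside the
encoded fragment tables. The generator's fidelity claim is limited to
providing enough statistical structure to exercise the pipeline.

## Numerical choices and degenerate inputs

- Variance floor 1e−12 for dropping constant columns and detecting
  degenerate Gaussians.
- NIPALS stops early if the residual collapses (fewer LVs than requested,
  with a warning); requesting more LVs than min(n−1, p) is an error.
- Round-half-up (not banker's rounding) both for nominal-mass binning and
  for 4-decimal metric reporting.
- MSP records whose declared peak count disagrees with the listed pairs are
  rejected individually with a warning; an entirely invalid file is an
  error.
- GA masks that would select zero variables are repaired at initialization
  and mutation by switching one random gene on; fitness of an empty mask
  is +∞.

## Known limitations

- Linker groups are not classified (no such model exists in the system).
- Binary nodes only; no multiclass PLS-DA, kernel PLS, ROC analysis,
  isotope modeling, or retention information.
- CV figures for GA-selected nodes inherit variable-selection bias (see
  above); external validation is the honest generalization estimate.
- The acceptance checks run on synthetic data; reproducing the published
  external-validation numbers exactly would require the original
  license-restricted spectral libraries.
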