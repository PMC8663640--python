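# ldptab — local differential privacy for mixed-type clinical tables

Clinical tabular data (vitals, labs, severity scores) cannot usually be
shared across institutions, yet most of its analytic value survives a
carefully randomized release. `ldptab` implements a **local** differential
privacy pipeline for mixed continuous + categorical tables: every cell is
perturbed by the data owner before release, so no central curator has to
be trusted, and — unlike a textbook Laplace mechanism — no released value
is ever impossible (no negative respiratory rates, no Glasgow coma "motor"
score of 2.37).

## The method

Every column is first normalized into `[-1, 1]` (min–max for continuous
columns; categorical columns are placed on an equally spaced grid of their
`m` labels). Each normalized value `q` is then released through the
**bounded Laplace mechanism**: noise with density

```
f_q(x) = (1 / C_q) · (1 / 2b) · exp(−|x − q| / b),     x ∈ [l, u] = [−1, 1],
C_q    = 1 − ( exp(−(q−l)/b) + exp(−(u−q)/b) ) / 2,
```

i.e. a Laplace distribution restricted to the legal domain and
renormalized. Sampling is by closed-form inverse CDF (one uniform variate
per cell, reproducible from a seed). The scale is `b = ΔQ/ε` with
sensitivity `ΔQ = 2` and privacy budget `ε` per attribute (`δ = 0`); a
`calibrated` mode solving `b = ΔQ / (ε − ln ΔC(b))` is provided for
geometries where the sensitivity is smaller than the domain width and the
renormalization genuinely costs privacy. On the default geometry the
worst-case privacy-loss ratio of the naive scale is exactly `e^ε`
(`privacy_loss_ratio` lets you audit this yourself).

A perturbed categorical value `y ∈ [−C, C]` is post-processed by
**randomized rounding**: map into index space `t = (y + C)(m − 1)/(2C)`,
split `t = k + p`, and release category `k + 1` with probability `p`,
else `k`. The release is always one of the original `m` labels, is
unbiased (`E[index] = t`), and is the identity when the noise vanishes —
so the misclassification rate falls to zero as `ε → ∞`.

Fidelity is measured per column (mean squared error for continuous,
misclassification rate for categorical) and downstream utility by six
classifier families (decision tree, KNN, SVM, logistic regression, naive
Bayes, random forest) predicting ICU mortality from original vs perturbed
features, with a stratified 80:20 split and 5-fold cross-validation.

Because real ICU databases are credentialed, the package ships a
synthetic APACHE-style generator: 4 binary treatment flags, the three
Glasgow coma components (cardinalities 4, 5, 6), 16 bounded continuous
vitals/labs, and a mortality label with ≈24 % prevalence driven by a
documented logistic severity model.

## Worked example

```bash
ldptab generate --n 2000 --seed 42 -o table.csv
ldptab perturb  --input table.csv --schema table.csv.schema.json \
                --epsilon 1.0 --seed 7 -o perturbed.csv
ldptab fidelity --input table.csv --schema table.csv.schema.json \
                --epsilons 0.1,1,10,100,1000 --seed 7 -o fidelity.csv
```

The perturb step logs the composition arithmetic —
`perturbed 2000 records x 23 columns at epsilon=1 (record-level budget
under basic composition: 23)` — and every command writes a JSON manifest
sufficient to reproduce it. Pivoting `fidelity.csv` for four columns:

```
epsilon        0.1        1.0       10.0    100.0   1000.0
heart_rate  3342.6950  2797.0184  465.2063  6.0601  0.0599
intubated      0.4750     0.4110    0.1015  0.0135  0.0015
ph             0.0936     0.0853    0.0174  0.0002  0.0000
verbal         0.8410     0.8165    0.4190  0.0575  0.0035
```

Reading this: at `ε = 0.1` the binary `intubated` flag is flipped in 47.5 %
of records (near the coin-flip ceiling of ≈0.49) and the six-level
`verbal` score is changed in 84 % (near its `(m−1)/m ≈ 0.83` ceiling),
while MSE scales with each variable's natural range — heart rate
(30–200 bpm) suffers thousands of squared bpm, pH (6.8–7.8) well under
0.1. By `ε = 1000` every metric has collapsed toward zero: privacy traded
for fidelity along the whole curve. `ldptab utility` runs the classifier
experiment over the same sweep; accuracies rise from the majority-class
rate at `ε = 0.1` back to each model's original-data baseline by
`ε = 10⁴`.

The same functionality is available as a library (`import ldptab`):
`infer_schema`, `perturb_table`, `fidelity_sweep`, `utility_curve`,
`gen_clinical_table`, and the low-level mechanism primitives.

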