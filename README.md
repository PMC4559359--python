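# netcure

Data curation for network inference: latent-structure imputation of missing
values, multivariate outlier detection and correction, and a minimal
information-theoretic inference engine to evaluate the curation end to end.

## The problem

Network inference — reconstructing interaction networks between species,
genes, metabolites or any other measured variables — starts from a data matrix
**X** (time points × variables). Real matrices have holes (failed
measurements, sensor dropouts) and faulty entries (acquisition or compilation
errors). Most inference methods silently assume complete, clean data; naive
fixes such as dropping incomplete rows or filling column means destroy exactly
the correlation structure the inference relies on.

`netcure` curates the matrix *coherently with its latent structure*, using the
principal component decomposition **X** = **T**·**P**ᵀ + **E**:

* **Missing data** — trimmed scores regression (**TSR**): iteratively fit a
  PCA model, regress each row's missing part on the scores of a model built
  from its observed columns, and impute the predictions until convergence.
  Five comparison methods ship alongside: the iterative algorithm (IA,
  reconstruction-based), complete-case analysis (CC), unconditional mean
  imputation (MI), linear interpolation in time (LI) and nearest-neighbor
  imputation (NN).
* **Outliers** — monitor each row's square prediction error
  SPE = **e**ᵀ**e** (distance to the PCA subspace) against a 95 % control
  limit resampled from a thousand random subsets; classify extreme points
  (above 2× the limit, or 10× farther from it than the lowest false alarm);
  isolate the faulty variable as the largest squared-residual contribution
  e²ᵢₖ; replace that cell by a missing value and reconstruct it with TSR.
  Hotelling's T² = Σₐ t²ₐ/λₐ is reported but not corrected: those outliers
  remain coherent with the correlation structure.
* **Inference** — links from lag-maximized mutual information
  I(X,Y) = H(X) + H(Y) − H(X,Y) against a permutation null, indirect links
  pruned when conditioning on mediating variables removes the entropy
  reduction, strength scored as (H(Y) − H(Y|X))/H(Y), direction assigned by
  transfer entropy T(X→Y) = H(Yᵗ|Yᵗ⁻τ) − H(Yᵗ|Yᵗ⁻τ, Xᵗ⁻τ).
* **Benchmarks** — generators with known ground truth (a lagged stochastic
  reaction chain W→Y→X→Z, low-rank Gaussian data), MCAR hole injection,
  univariate (beyond the 3·IQR fences) and multivariate (reflection across
  the mean) outlier injection, and precision/recall scoring
  P = TP/(TP+FP), R = TP/(TP+FN) of re-inferred networks against the
  clean-data network.

## A worked example

```sh
python examples/impute_missing_data.py
```

```
data: 50 x 10, 50 cells missing

tsr: imputed-cell RMSE = 0.154 (A=3, 23 iterations)
ia : imputed-cell RMSE = 0.154 (A=3, 185 iterations)
li : imputed-cell RMSE = 0.595
nn : imputed-cell RMSE = 0.386
mi : imputed-cell RMSE = 0.483
cc : dropped 32 incomplete rows, kept 18
```

A rank-3 correlated matrix loses 10 % of its cells completely at random; each
method fills them back in. The RMSE compares imputed cells to the hidden
truth: the latent-structure methods (TSR, IA — here with A = 3 components,
chosen automatically to explain 90 % of the variance) are three to four times
more accurate than mean imputation, and complete-case analysis discards 64 %
of the rows outright. The other example scripts demonstrate outlier curation
(`detect_and_correct_outliers.py`), network reconstruction of the simulated
chain (`infer_chain_network.py`) and the full corrupt–cure–re-infer benchmark
(`benchmark_curation_methods.py`).

## Command line

The same pipelines are exposed as a thin CLI over CSV/TSV matrices:

```sh
netcure impute --method tsr --in data.csv --out imputed.csv
netcure cure   --in data.csv --out cured.csv --report report.json --seed 1
netcure infer  --in cured.csv --edges edges.tsv --sif edges.sif
netcure benchmark --config study.yaml --out results.tsv
```

Missing cells are read from empty fields, `NA` or `NaN` (case-insensitive).

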