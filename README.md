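# bcrpqsar

Interpretable QSAR regression of **BCRP (ABCG2) transport inhibition**
from 2D structure.

BCRP is an ATP-binding-cassette efflux transporter expressed at the
blood–brain barrier, intestine, placenta and liver; inhibiting it is a
drug–drug-interaction liability that regulators ask to be evaluated
early.  Binary inhibitor/non-inhibitor classifiers exist, but a
*regression* model that predicts pIC50 = −log10(IC50 [M]) lets users
set their own activity threshold and rank compounds.  This package
implements such a workflow end to end, for computational chemists who
want every modelling step inspectable and every selected feature
resolvable to a chemical substructure:

* **curation** of heterogeneous IC50/EC50 records — assay-tag
  filtering, unit standardization to μM, structure standardization
  (largest organic fragment, neutralized, canonical), replicate
  averaging with a 3-fold consistency flag, merging by standardized
  SMILES;
* **featurization** with dictionary-defined substructure fingerprints
  (MACCS keys, count sections, curated functional groups, a
  systematic ring×substituent enumeration — ~1050 bits, every bit a
  SMARTS pattern or count rule in a TSV data file);
* **staged feature reduction** — variance < 0.01 filter, |r| > 0.8
  de-correlation, train-set z-normalization, Boruta-style
  shadow-feature selection at the 80th-percentile importance
  threshold, and recursive feature elimination (700→20, step 10) with
  knee-point detection on the RMSE curve;
* **repeated-split modelling** — ten 9:1 train/test splits, seeded
  hyperparameter search with inner 5-fold CV over a pluggable
  regressor registry (RF, LightGBM, Ridge/Lasso, …), finalization on
  the full set with the best split's settings;
* **evaluation** — RMSE, R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², and
  threshold-shifted classification views (balanced accuracy, Matthews
  correlation, rank-based AUC at pIC50 5–7, fraction within 3-fold
  error, |ΔpIC50| ≤ log10 3);
* **attribution** — exact path-dependent tree-Shapley values
  (implemented in-package, numba-accelerated, oracle-verified), bit →
  SMARTS resolution, and presence/absence t-/KS-tests per
  substructure;
* **applicability domain** — per-split max-Tanimoto cutoff sweeps
  (0.4→0.8, step 0.01) until the retained-set false-positive rate at
  pIC50 5 falls below 0.3, averaged into a final cutoff used to gate
  external screening.

Because the real curated datasets cannot be redistributed, the package
ships a first-class **synthetic generator**: fragment-assembled
molecules whose activity is additive over three planted causal
substructures (nitro-substituted benzene +0.6, N-heteroaromatic ring
+0.5, saturated N/O-heterocycle +0.4) plus Gaussian noise, matching
the emulated set's shape (n = 870, pIC50 ∈ [4, 8], ~10–14% below 5).
Every stage is validated against this ground truth; see
`docs/methods.md` for what that does and does not establish about real
data.

## Worked example

The analysis is a sequence of numbered drivers that write their tables
under `results/`:

```bash
python analysis/01_simulate.py       # data + truth + external set
python analysis/02_curate.py         # raw records -> curated pIC50
python analysis/03_featurize.py      # 870 x 1054 fingerprint matrix
python analysis/04_train_evaluate.py # cascade + 10 splits + finalize
python analysis/05_explain.py        # Shapley attribution + SMARTS
python analysis/06_screen.py         # applicability-domain screening
```

A run with the default seed prints, among other things:

```
generated 870 unique compounds (seed 1)
  pIC50 mean 5.448, range [4.00, 7.01], 13.7% below 5
cascade kept 30 of 1054 features
  test R2 0.335 ± 0.136, RMSE 0.345 ± 0.027 over 10 splits
  82.1% of test compounds within 3-fold error
  AD calibration: final cutoff 0.400, mean FPR 0.121
planted-motif recovery in top 10:
  'O=[N+]([O-])c1ccccc1': recovered
  '[nR]': recovered
  '[N,O;R]': recovered
screened 238 external compounds (62 excluded as overlaps/parse failures)
  cutoff 0.400: 91 in-domain, 147 out-of-domain
```

Reading this: the cascade reduced ~1050 bits to 30; the model explains
about a third of the held-out pIC50 variance — close to the ceiling
set by the generator's noise (σ = 0.35 against a signal spread of a
few tenths of a unit) — and 82% of predictions land within 3-fold of
the true concentration.  All three planted causal substructures are
recovered among the top-10 features by mean |Shapley attribution|,
and the similarity cutoff keeps the retained false-positive rate well
under the 0.3 target.  On this synthetic study the cutoff settles at
the low end of the sweep grid because false positives are rare to
begin with; on real, broader chemistry it lands higher.

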