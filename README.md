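# specsplit

Train/test data splitting for spectral classification, with a full
evaluation stack. The package implements three sample-selection strategies
over spectral datasets —

* **rs** — uniformly random per-class assignment;
* **ks** — Kennard–Stone max–min selection: the first two training picks are
  the most distant pair (Euclidean), each further pick maximizes the minimum
  distance to the already-selected set;
* **mlm** — Kennard–Stone followed by a *random mutation* step in which 10%
  (configurable) of train/test sample pairs are exchanged at random,
  keeping set sizes and class proportions fixed —

plus the pipeline needed to compare them: spectral preprocessing (region
excision, Savitzky–Golay smoothing, rubberband and asymmetric-least-squares
baselines, peak/vector normalization), a PCA-LDA classifier whose class
score is the pooled-covariance Mahalanobis distance in PC-score space,
venetian-blinds cross-validation for selecting the number of components,
accuracy/sensitivity/specificity reporting, and a Monte-Carlo benchmark on
a synthetic two-class product-normal generator.

## CLI

All data files are plain CSV/TSV: header row = wavenumber axis, optional
first `sample_id` column, labels either in a last `label` column or a
separate single-column file.

```sh
# preprocess with an ordered recipe (see examples/recipes/)
specsplit preprocess raw.csv clean.csv --config examples/recipes/atr_ftir.yaml

# compute a split and archive it
specsplit split clean.csv --method mlm --train-fraction 0.7 --mutation 0.10 \
    --seed 17 --out split.json

# train PCA-LDA on the training part (venetian-blinds CV picks the PC count)
specsplit train clean.csv --split split.json --max-pcs 20 --model model.json

# score the held-out test part
specsplit evaluate clean.csv --model model.json --split split.json \
    --report report.json

# Monte-Carlo benchmark of the three splitters on synthetic data
specsplit simulate --n-sims 1000 --master-seed 1 --out bench.json --plot bench.png
```

## Benchmark / acceptance report

`scripts/acceptance.py` recomputes the headline numbers of the synthetic
benchmark (mean test-set accuracy of each splitter over repeated
simulations of two 100×1000 product-normal classes, 70/30 split, 10%
mutation, venetian-blinds PC selection):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Defaults: 500 repetitions, CV grid up to 15 PCs (≈10 min on one CPU).
`--n-sims 1000` reproduces the full-size protocol offline.

## Notes

* The generator draws class 1 as an elementwise product of two independent
  standard-normal matrices and class 2 as (normal + 5) × normal — the shift
  is applied **before** the multiplication, so the classes differ in
  variance (1 vs 26), not in mean. No clipping is applied.
* The `awls` step is an asymmetric penalized weighted least squares
  (Whittaker) baseline, a stand-in for the proprietary toolbox step of the
  same name; behaviour is analogous, not bit-identical.
* PCA is refit inside every cross-validation fold (no information leakage).
* Splitting runs independently within each class pool by default so that
  class proportions survive the split; `--pooled` disables this.
* Real-dataset recipes under `examples/` are provided for manual use; the
  published spectra archives must be downloaded separately.
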