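#!/usr/bin/env python
"""Example end-to-end run on a real spectral dataset (manual download).

The published benchmark archives are MATLAB workspaces; export them to the
CSV layout this package reads (header row = wavenumbers, last column =
label) and point this script at the file. Not part of the test suite.

Usage:
    python examples/run_real_dataset.py spectra.csv --recipe examples/recipes/atr_ftir.yaml
"""

import argparse
import json

from specsplit.data import read_dataset, subset
from specsplit.metrics import report
from specsplit.pca_lda import fit_pca_lda, predict
from specsplit.preprocess import apply_recipe, load_recipe
from specsplit.splitters import (SplitConfig, kennard_stone_split, mlm_split,
                                 random_split)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("spectra")
    ap.add_argument("--labels", default=None)
    ap.add_argument("--recipe", default=None)
    ap.add_argument("--max-pcs", type=int, default=20)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    ds = read_dataset(args.spectra, args.labels)
    if args.recipe:
        ds = apply_recipe(ds, load_recipe(args.recipe))

    for name, splitter in [("rs", random_split), ("ks", kennard_stone_split),
                           ("mlm", mlm_split)]:
        sr = splitter(ds, SplitConfig(seed=args.seed))
        model = fit_pca_lda(subset(ds, sr.train_idx), max_pcs=args.max_pcs)
        test = subset(ds, sr.test_idx)
        rep = report(test.labels, predict(model, test), model.lda.class_order)
        print(f"== {name}: {model.n_pcs} PCs, training accuracy "
              f"{model.training_accuracy:.0f}%, CV accuracy "
              f"{model.cv_accuracy:.0f}%")
        print(rep.to_text())
        print(json.dumps(rep.to_dict()["confusion_matrix"]))


if __name__ == "__main__":
    main()
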