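"""Synthetic two-class benchmark and test-fixture generators.

The benchmark generator draws, per class, the elementwise product of two
independent standard-normal matrices; class 2's first factor is shifted by a
constant *before* the multiplication:

    class 1:  A .* B            A, B ~ N(0, 1) iid
    class 2:  (A + shift) .* B

Both classes therefore have zero mean entries, but class 2's entries have
variance 1 + shift^2 (26 at the default shift of 5). No clipping is applied.

:func:`run_benchmark` repeats the full protocol — generate, split 70/30 with
each configured method, fit PCA-LDA with venetian-blinds component selection
on the training set, score the test set — over many independent repetitions
and aggregates per-method accuracy distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import SpectralDataset, subset
from .metrics import report
from .pca_lda import fit_pca_lda, predict
from .splitters import (SplitConfig, kennard_stone_split, mlm_split,
                        random_split, validate_split)

logger = logging.getLogger("specsplit")

__all__ = ["SimConfig", "BenchmarkResult", "generate_two_classes",
           "run_benchmark", "make_fixture"]

_SPLITTERS = {"rs": random_split, "ks": kennard_stone_split, "mlm": mlm_split}


@dataclass(frozen=True)
class SimConfig:
    """Benchmark protocol parameters (defaults = the published protocol)."""

    n_obs_per_class: int = 100
    n_vars: int = 1000
    shift: float = 5.0
    n_sims: int = 1000
    train_fraction: float = 0.7
    mutation_factor: float = 0.10
    max_pcs: int = 20
    methods: tuple = ("rs", "ks", "mlm")
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obs_per_class < 2 or self.n_vars < 1:
            raise ValueError("need >= 2 observations per class and >= 1 variable")
        unknown = set(self.methods) - set(_SPLITTERS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class BenchmarkResult:
    """Per-method accuracy distribution over the repetitions."""

    methods: tuple
    accuracies: dict         # method -> list of test accuracies (percent)
    sens_spec_gap: dict      # method -> list of mean |sensitivity - specificity|
    histogram_edges: np.ndarray
    histograms: dict         # method -> counts per bin
    n_sims: int
    master_seed: int
    failures: list = field(default_factory=list)

    def mean(self, method: str) -> float:
        return float(np.mean(self.accuracies[method]))

    def min(self, method: str) -> float:
        return float(np.min(self.accuracies[method]))

    def max(self, method: str) -> float:
        return float(np.max(self.accuracies[method]))

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean(m), "min": self.min(m), "max": self.max(m),
                "mean_sens_spec_gap": float(np.mean(self.sens_spec_gap[m]))}
            for m in self.methods
        }

    def to_dict(self) -> dict:
        return {
            "n_sims": self.n_sims,
            "master_seed": self.master_seed,
            "summary": self.summary(),
            "accuracies": {m: list(map(float, v)) for m, v in self.accuracies.items()},
            "sens_spec_gap": {m: list(map(float, v)) for m, v in self.sens_spec_gap.items()},
            "histogram_edges": self.histogram_edges.tolist(),
            "histograms": {m: v.tolist() for m, v in self.histograms.items()},
            "failures": self.failures,
        }


def generate_two_classes(cfg: SimConfig, seed: int | None = None) -> SpectralDataset:
    """Draw one benchmark dataset: 2 * n_obs_per_class product-normal spectra.

    Deterministic given *seed*; the variable axis is simply 1..n_vars.
    """
    rng = np.random.default_rng(seed)
    n, p, s = cfg.n_obs_per_class, cfg.n_vars, cfg.shift
    class1 = rng.standard_normal((n, p)) * rng.standard_normal((n, p))
    class2 = (rng.standard_normal((n, p)) + s) * rng.standard_normal((n, p))
    return SpectralDataset(
        intensities=np.vstack([class1, class2]),
        wavenumbers=np.arange(1, p + 1, dtype=float),
        labels=np.asarray(["class_1"] * n + ["class_2"] * n, dtype=object),
        sample_ids=np.asarray([f"c1_{i}" for i in range(n)]
                              + [f"c2_{i}" for i in range(n)], dtype=object),
    )


def _run_one(ds: SpectralDataset, method: str, cfg: SimConfig,
             split_seed: int) -> tuple[float, float]:
    """Split, train, score; returns (test accuracy %, mean |sens - spec|)."""
    scfg = SplitConfig(train_fraction=cfg.train_fraction,
                       mutation_factor=cfg.mutation_factor,
                       seed=split_seed)
    sr = _SPLITTERS[method](ds, scfg)
    assert validate_split(ds, sr), "splitter produced an invalid partition"
    train, test = subset(ds, sr.train_idx), subset(ds, sr.test_idx)
    model = fit_pca_lda(train, max_pcs=cfg.max_pcs)
    rep = report(test.labels, predict(model, test), model.lda.class_order)
    gaps = [abs(rep.sensitivity[c] - rep.specificity[c])
            for c in rep.class_order
            if rep.sensitivity[c] is not None and rep.specificity[c] is not None]
    return rep.accuracy, float(np.mean(gaps)) if gaps else float("nan")


def run_benchmark(cfg: SimConfig, progress: bool = False) -> BenchmarkResult:
    """Monte-Carlo comparison of the configured splitting methods.

    Each repetition draws a fresh dataset from a seed derived from
    ``(master_seed, repetition)``, applies every method to the *same* dataset
    and records the test-set accuracy. Single-repetition failures are logged
    and skipped; more than 1% failures aborts the run.
    """
    accs: dict = {m: [] for m in cfg.methods}
    gaps: dict = {m: [] for m in cfg.methods}
    failures: list = []
    for s in range(cfg.n_sims):
        ss = np.random.SeedSequence(entropy=(cfg.master_seed, s))
        data_seed, rs_seed, mlm_seed = (int(c.generate_state(1)[0])
                                        for c in ss.spawn(3))
        ds = generate_two_classes(cfg, seed=data_seed)
        for m in cfg.methods:
            split_seed = {"rs": rs_seed, "mlm": mlm_seed}.get(m, 0)
            try:
                a, g = _run_one(ds, m, cfg, split_seed)
            except Exception as exc:  # noqa: BLE001 - recorded, bounded below
                failures.append({"sim": s, "method": m, "error": str(exc)})
                warnings.warn(f"simulation {s} / {m} failed: {exc}")
                continue
            accs[m].append(a)
            gaps[m].append(g)
        if progress and (s + 1) % 25 == 0:
            logger.info("benchmark: %d/%d repetitions done", s + 1, cfg.n_sims)
    if len(failures) > 0.01 * cfg.n_sims * len(cfg.methods):
        raise RuntimeError(f"{len(failures)} simulation failures (> 1%); aborting")

    edges = np.arange(50.0, 87.0, 2.0)  # integer-percent bins, width 2
    hists = {m: np.histogram(accs[m], bins=edges)[0] for m in cfg.methods}
    return BenchmarkResult(
        methods=cfg.methods, accuracies=accs, sens_spec_gap=gaps,
        histogram_edges=edges, histograms=hists,
        n_sims=cfg.n_sims, master_seed=cfg.master_seed, failures=failures,
    )


def make_fixture(n_per_class: int = 10, n_vars: int = 10, *,
                 kind: str = "blobs", separation: float = 10.0,
                 n_classes: int = 2, seed: int | None = None) -> SpectralDataset:
    """Small deterministic datasets for unit tests.

    ``kind="blobs"`` draws unit-variance Gaussian clusters whose means are
    *separation* apart along successive axes; ``kind="product"`` is a scaled-
    down version of the benchmark generator.
    """
    if n_per_class < 2:
        raise ValueError("need >= 2 samples per class")
    if kind == "product":
        cfg = SimConfig(n_obs_per_class=n_per_class, n_vars=n_vars)
        return generate_two_classes(cfg, seed=seed)
    if kind != "blobs":
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(seed)
    blocks, labels, ids = [], [], []
    for c in range(n_classes):
        mean = np.zeros(n_vars)
        mean[c % n_vars] = separation * c
        blocks.append(rng.standard_normal((n_per_class, n_vars)) + mean)
        labels += [f"class_{c + 1}"] * n_per_class
        ids += [f"c{c + 1}_{i}" for i in range(n_per_class)]
    return SpectralDataset(
        intensities=np.vstack(blocks),
        wavenumbers=np.arange(1, n_vars + 1, dtype=float),
        labels=np.asarray(labels, dtype=object),
        sample_ids=np.asarray(ids, dtype=object),
    )
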