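"""Train/test splitting: random, Kennard-Stone, and random-mutation KS.

Three selection strategies over a :class:`~specsplit.data.SpectralDataset`:

``random_split``
    Uniformly random per-class partition.
``kennard_stone_split``
    Deterministic max-min selection: within each pool the first two training
    picks are the most distant pair; each further pick maximizes the minimum
    Euclidean distance to the already-selected set.
``mlm_split``
    Kennard-Stone followed by a random mutation step: a fixed fraction of
    train/test sample pairs is exchanged at random, keeping set sizes fixed.

By default every strategy runs independently inside each class pool so that
the class proportions of the full dataset survive the split (70/30 by
default). Ties in distance are always broken by lowest sample index so the
deterministic splitters are reproducible bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import SpectralDataset, SplitResult, default_rng

logger = logging.getLogger("specsplit")

__all__ = [
    "SplitConfig",
    "random_split",
    "kennard_stone_split",
    "mlm_split",
    "validate_split",
]


@dataclass(frozen=True)
class SplitConfig:
    """Parameters shared by all splitters.

    ``mutation_base`` selects the pool whose size the mutation count is 10%
    of ("test", "train" or "total"); ``first_pick`` selects the Kennard-Stone
    initialization ("pair" = classic most-distant pair, "max_sum_distance" =
    single sample with largest summed distance to all others).
    """

    train_fraction: float = 0.7
    mutation_factor: float = 0.10
    per_class: bool = True
    seed: int | None = None
    mutation_base: str = "test"       # "test" | "train" | "total"
    first_pick: str = "pair"          # "pair" | "max_sum_distance"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0.0 <= self.mutation_factor < 1.0:
            raise ValueError("mutation_factor must lie in [0, 1)")
        if self.mutation_base not in ("test", "train", "total"):
            raise ValueError(f"unknown mutation_base {self.mutation_base!r}")
        if self.first_pick not in ("pair", "max_sum_distance"):
            raise ValueError(f"unknown first_pick {self.first_pick!r}")


def _round_half_away(x: float) -> int:
    """round() with halves away from zero (MATLAB-style), x >= 0."""
    return int(math.floor(x + 0.5))


def _train_count(n: int, fraction: float) -> int:
    """Training count for a pool of *n*: rounded, but >= 1 train and >= 1 test."""
    t = _round_half_away(fraction * n)
    return min(max(t, 1), n - 1)


def _pools(ds: SpectralDataset, per_class: bool) -> list[np.ndarray]:
    if per_class:
        return list(ds.class_indices().values())
    return [np.arange(ds.n_samples)]


def _check_pools(pools: list[np.ndarray]) -> None:
    for pool in pools:
        if pool.size < 2:
            raise ValueError(
                f"every selection pool needs >= 2 samples, got {pool.size}"
            )


def random_split(ds: SpectralDataset, cfg: SplitConfig = SplitConfig()) -> SplitResult:
    """Uniformly random partition honouring per-class train counts.

    Deterministic given ``cfg.seed``. Train and test indices are returned in
    ascending (file) order.
    """
    pools = _pools(ds, cfg.per_class)
    _check_pools(pools)
    rng = default_rng(cfg.seed)
    train: list[int] = []
    test: list[int] = []
    for pool in pools:
        t = _train_count(pool.size, cfg.train_fraction)
        chosen = rng.choice(pool.size, size=t, replace=False)
        mask = np.zeros(pool.size, dtype=bool)
        mask[chosen] = True
        train.extend(pool[mask])
        test.extend(pool[~mask])
    sr = SplitResult(
        train_idx=np.sort(train), test_idx=np.sort(test), method="rs",
        train_fraction=cfg.train_fraction, mutation_factor=0.0, seed=cfg.seed,
    )
    logger.info("random_split: n=%d -> %d train / %d test (seed=%s)",
                ds.n_samples, sr.train_idx.size, sr.test_idx.size, cfg.seed)
    return sr


def _ks_select(X: np.ndarray, n_train: int, first_pick: str) -> np.ndarray:
    """Kennard-Stone max-min selection of *n_train* rows of X.

    Returns local row indices in selection order. Ties broken by lowest
    index (np.argmax / argmin return the first maximizer).
    """
    n = X.shape[0]
    d = cdist(X, X)
    if first_pick == "pair":
        flat = int(np.argmax(d))  # first occurrence -> lexicographically lowest (i, j)
        i, j = divmod(flat, n)
        selected = [min(i, j), max(i, j)] if i != j else [0, 1]
    else:  # max_sum_distance
        selected = [int(np.argmax(d.sum(axis=1)))]
    min_d = d[selected].min(axis=0)
    min_d[selected] = -np.inf
    while len(selected) < n_train:
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        min_d = np.minimum(min_d, d[nxt])
        min_d[nxt] = -np.inf
    return np.asarray(selected[:n_train], dtype=int)


def kennard_stone_split(ds: SpectralDataset, cfg: SplitConfig = SplitConfig()) -> SplitResult:
    """Deterministic Kennard-Stone max-min split (no randomness involved).

    Training indices are returned in selection order (pools concatenated in
    class first-appearance order); test indices in ascending order.
    """
    pools = _pools(ds, cfg.per_class)
    _check_pools(pools)
    train: list[int] = []
    test: list[int] = []
    for pool in pools:
        t = _train_count(pool.size, cfg.train_fraction)
        local = _ks_select(ds.intensities[pool], t, cfg.first_pick)
        picked = pool[local]
        train.extend(picked)
        test.extend(np.setdiff1d(pool, picked))
    sr = SplitResult(
        train_idx=np.asarray(train), test_idx=np.sort(test), method="ks",
        train_fraction=cfg.train_fraction, mutation_factor=0.0, seed=None,
    )
    logger.info("kennard_stone_split: n=%d -> %d train / %d test",
                ds.n_samples, sr.train_idx.size, sr.test_idx.size)
    return sr


def mlm_split(ds: SpectralDataset, cfg: SplitConfig = SplitConfig()) -> SplitResult:
    """Kennard-Stone split followed by random paired train/test swaps.

    Per selection pool, ``m = round(mutation_factor * base)`` distinct
    train/test pairs are exchanged, where ``base`` is the pool's test size by
    default (configurable). Set sizes are unchanged; deterministic given
    ``cfg.seed``. With ``mutation_factor == 0`` the result is exactly the
    Kennard-Stone split.
    """
    ks = kennard_stone_split(ds, cfg)
    if cfg.mutation_factor == 0.0:
        return replace_method(ks, cfg)
    rng = default_rng(cfg.seed)
    pools = _pools(ds, cfg.per_class)
    train = list(ks.train_idx)
    test = list(ks.test_idx)
    any_swap = False
    for pool in pools:
        pool_set = set(pool.tolist())
        pool_train = [i for i in train if i in pool_set]
        pool_test = [i for i in test if i in pool_set]
        base = {"test": len(pool_test), "train": len(pool_train),
                "total": len(pool)}[cfg.mutation_base]
        m = _round_half_away(cfg.mutation_factor * base)
        m = min(m, len(pool_train), len(pool_test))
        if m == 0:
            logger.warning(
                "mlm_split: mutation_factor %.3g yields 0 swaps for pool of "
                "%d (train %d / test %d); Kennard-Stone result kept",
                cfg.mutation_factor, len(pool), len(pool_train), len(pool_test))
            continue
        any_swap = True
        out = rng.choice(len(pool_train), size=m, replace=False)
        inn = rng.choice(len(pool_test), size=m, replace=False)
        out_idx = {pool_train[i] for i in out}
        in_idx = [pool_test[i] for i in sorted(inn)]
        # preserve KS selection order for the retained training samples,
        # append the swapped-in ones at the end of this pool's block
        new_pool_train = [i for i in pool_train if i not in out_idx] + in_idx
        train = _replace_pool(train, pool, new_pool_train)
        test = sorted(set(test) - set(in_idx) | out_idx)
    sr = SplitResult(
        train_idx=np.asarray(train), test_idx=np.asarray(test, dtype=int),
        method="mlm", train_fraction=cfg.train_fraction,
        mutation_factor=cfg.mutation_factor if any_swap else 0.0, seed=cfg.seed,
    )
    logger.info("mlm_split: n=%d -> %d train / %d test (seed=%s, mutation=%.2f)",
                ds.n_samples, sr.train_idx.size, sr.test_idx.size,
                cfg.seed, cfg.mutation_factor)
    return sr


def _replace_pool(train: list[int], pool: np.ndarray, new_pool_train: list[int]) -> list[int]:
    """Replace this pool's contiguous block of train entries, keeping order."""
    pool_set = set(pool.tolist())
    out: list[int] = []
    inserted = False
    for i in train:
        if i in pool_set:
            if not inserted:
                out.extend(new_pool_train)
                inserted = True
        else:
            out.append(i)
    if not inserted:
        out.extend(new_pool_train)
    return out


def replace_method(sr: SplitResult, cfg: SplitConfig) -> SplitResult:
    """Relabel a KS result as an MLM result that performed zero swaps."""
    return SplitResult(
        train_idx=sr.train_idx, test_idx=sr.test_idx, method="mlm",
        train_fraction=sr.train_fraction, mutation_factor=cfg.mutation_factor,
        seed=cfg.seed,
    )


def validate_split(ds: SpectralDataset, sr: SplitResult,
                   per_class: bool = True) -> bool:
    """True iff *sr* is a partition of the dataset honouring per-class counts.

    Never raises; failed checks are logged at warning level.
    """
    train, test = set(sr.train_idx.tolist()), set(sr.test_idx.tolist())
    ok = True
    if len(train) != sr.train_idx.size or len(test) != sr.test_idx.size:
        logger.warning("validate_split: duplicate indices within a set")
        ok = False
    if train & test:
        logger.warning("validate_split: train and test overlap: %s",
                       sorted(train & test)[:5])
        ok = False
    if train | test != set(range(ds.n_samples)):
        logger.warning("validate_split: union does not cover 0..%d",
                       ds.n_samples - 1)
        ok = False
    if ok and per_class:
        for c, pool in ds.class_indices().items():
            expect = _train_count(pool.size, sr.train_fraction)
            got = len(train & set(pool.tolist()))
            if got != expect:
                logger.warning(
                    "validate_split: class %r has %d train samples, expected %d",
                    c, got, expect)
                ok = False
    return ok
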