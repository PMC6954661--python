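"""Core domain types and delimited-text I/O.

A :class:`SpectralDataset` bundles an intensity matrix (samples x variables)
with its wavenumber axis, per-sample class labels and sample identifiers.
Datasets are read from and written to plain CSV/TSV files: the header row
carries the wavenumber axis, an optional first ``sample_id`` column carries
identifiers and an optional last ``label`` column carries class labels
(labels may alternatively live in a separate single-column file).

:class:`SplitResult` records a train/test partition together with its
provenance (method, seed, mutation factor) and serializes to JSON so splits
can be archived and re-applied.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger("specsplit")

__all__ = [
    "SpectralDataset",
    "SplitResult",
    "FormatError",
    "ParseError",
    "ConsistencyError",
    "read_dataset",
    "write_dataset",
    "read_labels",
    "subset",
    "default_rng",
]


class FormatError(ValueError):
    """Structurally malformed input file (ragged rows, bad header...)."""


class ParseError(FormatError):
    """A cell that should be numeric is not; names row and column."""


class ConsistencyError(ValueError):
    """Components of a dataset disagree (e.g. label count mismatch)."""


_GLOBAL_RNG: np.random.Generator | None = None


def default_rng(seed: int | None) -> np.random.Generator:
    """Return a generator for *seed*, or the package-level generator if None.

    The package-level generator is created once per process from OS entropy
    and its seed sequence is logged, so unseeded runs remain traceable.
    """
    if seed is not None:
        return np.random.default_rng(seed)
    global _GLOBAL_RNG
    if _GLOBAL_RNG is None:
        ss = np.random.SeedSequence()
        logger.info("initialized package RNG with entropy=%s", ss.entropy)
        _GLOBAL_RNG = np.random.default_rng(ss)
    return _GLOBAL_RNG


@dataclass
class SpectralDataset:
    """Intensity matrix plus wavenumber axis, labels and sample ids.

    Invariants (checked on construction):

    * ``intensities`` is 2-D with one row per label / sample id;
    * ``wavenumbers`` is strictly monotonic (ascending or descending);
    * all intensities are finite.
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = np.asarray(
            [str(s) for s in np.asarray(self.sample_ids).ravel()], dtype=object
        )
        if self.intensities.ndim != 2:
            raise ConsistencyError("intensities must be a 2-D matrix")
        n, p = self.intensities.shape
        if n == 0 or p == 0:
            raise ConsistencyError("dataset must have at least one sample and one variable")
        if self.wavenumbers.shape != (p,):
            raise ConsistencyError(
                f"wavenumber axis length {self.wavenumbers.shape} does not match "
                f"{p} intensity columns"
            )
        if self.labels.shape != (n,):
            raise ConsistencyError(
                f"{self.labels.size} labels for {n} spectra"
            )
        if self.sample_ids.shape != (n,):
            raise ConsistencyError(
                f"{self.sample_ids.size} sample ids for {n} spectra"
            )
        d = np.diff(self.wavenumbers)
        if p > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ConsistencyError("wavenumbers must be strictly monotonic")
        if not np.all(np.isfinite(self.intensities)):
            bad = np.argwhere(~np.isfinite(self.intensities))[0]
            raise ConsistencyError(
                f"non-finite intensity at sample {bad[0]}, variable {bad[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_variables(self) -> int:
        return self.intensities.shape[1]

    @property
    def ascending(self) -> bool:
        """Whether the wavenumber axis increases left to right."""
        w = self.wavenumbers
        return bool(w.size < 2 or w[1] > w[0])

    @property
    def classes(self) -> list:
        """Distinct labels in first-appearance order."""
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def class_indices(self) -> dict:
        """Map class label -> array of row indices, first-appearance order."""
        out: dict = {c: [] for c in self.classes}
        for i, lab in enumerate(self.labels):
            out[lab].append(i)
        return {c: np.asarray(v, dtype=int) for c, v in out.items()}

    def replace_intensities(self, X: np.ndarray, wavenumbers: np.ndarray | None = None
                            ) -> "SpectralDataset":
        """New dataset with the same samples but different intensities/axis."""
        return SpectralDataset(
            intensities=np.asarray(X, dtype=float),
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            labels=self.labels.copy(),
            sample_ids=self.sample_ids.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (
            self.intensities.shape == other.intensities.shape
            and np.array_equal(self.intensities, other.intensities)
            and np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.sample_ids, other.sample_ids)
        )


def subset(ds: SpectralDataset, idx: Sequence[int] | np.ndarray) -> SpectralDataset:
    """Select rows of *ds* in the order given by *idx*.

    The wavenumber axis is carried over unchanged (same array values).
    Raises ``IndexError`` on out-of-range or duplicate indices and on an
    empty selection.
    """
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise IndexError("empty index set")
    if idx.min() < 0 or idx.max() >= ds.n_samples:
        raise IndexError(
            f"index out of range 0..{ds.n_samples - 1}: {idx[(idx < 0) | (idx >= ds.n_samples)][0]}"
        )
    if np.unique(idx).size != idx.size:
        raise IndexError("duplicate indices in subset selection")
    return SpectralDataset(
        intensities=ds.intensities[idx],
        wavenumbers=ds.wavenumbers,
        labels=ds.labels[idx],
        sample_ids=ds.sample_ids[idx],
    )


# ---------------------------------------------------------------------------
# delimited-file reading / writing

def _parse_float(cell: str, row: int, col: int, path: Path) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric value {cell!r} at row {row}, column {col}"
        ) from None


def read_dataset(
    spectra_path: str | Path,
    labels_path: str | Path | None = None,
    *,
    delimiter: str = ",",
) -> SpectralDataset:
    """Read a dataset from a delimited text file.

    Layout: header row = wavenumbers; optional first column named
    ``sample_id``; optional last column named ``label``. If *labels_path* is
    given it must be a single-column text file with one label per spectrum
    (a ``label`` header line is permitted and skipped).
    """
    spectra_path = Path(spectra_path)
    with open(spectra_path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    rows = [r for r in rows if r]  # drop blank lines
    if len(rows) < 2:
        raise FormatError(f"{spectra_path}: need a header row and at least one spectrum")
    header = [c.strip() for c in rows[0]]
    has_ids = header and header[0] == "sample_id"
    has_labels = header and header[-1] == "label"
    lo = 1 if has_ids else 0
    hi = len(header) - 1 if has_labels else len(header)
    if hi <= lo:
        raise FormatError(f"{spectra_path}: no wavenumber columns in header")
    wavenumbers = np.array(
        [_parse_float(header[j], 0, j, spectra_path) for j in range(lo, hi)]
    )

    intensities, labels, ids = [], [], []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            raise FormatError(
                f"{spectra_path}: row {i} has {len(row)} fields, header has {len(header)}"
            )
        ids.append(row[0].strip() if has_ids else f"sample_{i - 1}")
        if has_labels:
            labels.append(row[-1].strip())
        intensities.append(
            [_parse_float(row[j], i, j, spectra_path) for j in range(lo, hi)]
        )

    if labels_path is not None:
        file_labels = read_labels(labels_path)
        if has_labels and list(file_labels) != labels:
            raise ConsistencyError(
                f"{labels_path}: labels disagree with label column in {spectra_path}"
            )
        labels = list(file_labels)
    if not labels:
        raise ConsistencyError(
            f"{spectra_path}: no labels found (no 'label' column and no labels file)"
        )
    if len(labels) != len(intensities):
        raise ConsistencyError(
            f"{len(labels)} labels for {len(intensities)} spectra"
        )
    ds = SpectralDataset(
        intensities=np.asarray(intensities, dtype=float),
        wavenumbers=wavenumbers,
        labels=np.asarray(labels, dtype=object),
        sample_ids=np.asarray(ids, dtype=object),
    )
    logger.info("read_dataset: %d samples x %d variables from %s",
                ds.n_samples, ds.n_variables, spectra_path)
    return ds


def read_labels(path: str | Path) -> np.ndarray:
    """Read a single-column label file (optional ``label`` header)."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if lines and lines[0] == "label":
        lines = lines[1:]
    if not lines:
        raise FormatError(f"{path}: empty label file")
    return np.asarray(lines, dtype=object)


def write_dataset(ds: SpectralDataset, path: str | Path, *, delimiter: str = ",") -> None:
    """Write *ds* so that :func:`read_dataset` round-trips it.

    Floats are written with ``repr`` precision, so the round trip is exact
    well within the 1e-12 contract.
    """
    if ds.n_samples == 0:
        raise ConsistencyError("refusing to write an empty dataset")
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=delimiter)
            w.writerow(["sample_id", *(repr(float(x)) for x in ds.wavenumbers),
                        "label"])
            for sid, row, lab in zip(ds.sample_ids, ds.intensities, ds.labels):
                w.writerow([sid, *(repr(float(x)) for x in row), lab])
    except OSError as exc:
        raise OSError(f"failed writing dataset to {path}: {exc}") from exc
    logger.info("write_dataset: %d samples -> %s", ds.n_samples, path)


# ---------------------------------------------------------------------------
# split results

@dataclass
class SplitResult:
    """A train/test partition with provenance."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    method: str  # "rs" | "ks" | "mlm"
    train_fraction: float = 0.7
    mutation_factor: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.train_idx.size + self.test_idx.size

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "train_fraction": self.train_fraction,
            "mutation_factor": self.mutation_factor,
            "seed": self.seed,
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SplitResult":
        return cls(
            train_idx=np.asarray(d["train_idx"], dtype=int),
            test_idx=np.asarray(d["test_idx"], dtype=int),
            method=d["method"],
            train_fraction=float(d["train_fraction"]),
            mutation_factor=float(d.get("mutation_factor", 0.0)),
            seed=d.get("seed"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SplitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))
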