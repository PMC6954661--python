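"""Spectral preprocessing: region excision, smoothing, baselines, normalization.

Steps operate on a whole :class:`~specsplit.data.SpectralDataset` and return
a new dataset; samples are never permuted. Recipes are ordered lists of
steps loaded from YAML/JSON, e.g.::

    - kind: cut_region
      lo: 900
      hi: 1800
    - kind: savgol
      window: 7
      polyorder: 2
    - kind: awls
    - kind: peak_norm
      peak: 1650

The ``awls`` step is an asymmetric penalized weighted least squares baseline
(a Whittaker smoother with asymmetric weights); the toolbox algorithm it
stands in for is not publicly specified, so behaviour is analogous rather
than identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .data import SpectralDataset

__all__ = [
    "cut_region", "savgol_smooth", "rubberband_baseline", "awls_baseline",
    "peak_normalize", "vector_normalize", "load_recipe", "apply_recipe",
]


def cut_region(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep exactly the variables with lo <= wavenumber <= hi (order kept)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    mask = (ds.wavenumbers >= lo) & (ds.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(
            f"region [{lo}, {hi}] does not overlap the axis "
            f"[{ds.wavenumbers.min()}, {ds.wavenumbers.max()}]")
    return ds.replace_intensities(ds.intensities[:, mask], ds.wavenumbers[mask])


def savgol_smooth(ds: SpectralDataset, window: int, polyorder: int = 2) -> SpectralDataset:
    """Savitzky-Golay smoothing of each spectrum."""
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window {window} must exceed polyorder {polyorder}")
    if window > ds.n_variables:
        raise ValueError(f"window {window} exceeds {ds.n_variables} variables")
    return ds.replace_intensities(
        savgol_filter(ds.intensities, window, polyorder, axis=1))


def _lower_hull_baseline(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of (w, y) evaluated at every w (monotone chain)."""
    hull: list[int] = []
    for i in range(len(w)):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # pop i1 if it lies on or above the chord i0 -> i
            if (y[i1] - y[i0]) * (w[i] - w[i0]) >= (y[i] - y[i0]) * (w[i1] - w[i0]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(w, w[hull], y[hull])


def rubberband_baseline(ds: SpectralDataset) -> SpectralDataset:
    """Subtract the lower convex hull of each spectrum.

    Hull contact points map to exactly zero; a constant spectrum becomes all
    zeros. Works for ascending or descending axes (the hull is computed on
    the ascending ordering and mapped back).
    """
    if ds.n_variables < 3:
        raise ValueError("rubberband baseline needs >= 3 variables")
    order = np.argsort(ds.wavenumbers)
    w = ds.wavenumbers[order]
    X = ds.intensities.copy()
    for i in range(ds.n_samples):
        y = ds.intensities[i, order]
        corrected = y - _lower_hull_baseline(w, y)
        X[i, order] = corrected
    return ds.replace_intensities(X)


def _whittaker_system(n: int, lam: float) -> sparse.csc_matrix:
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    return (lam * (d.T @ d)).tocsc()


def awls_baseline(ds: SpectralDataset, smoothness: float = 1e5,
                  asymmetry: float = 0.01, max_iter: int = 10) -> SpectralDataset:
    """Asymmetric penalized weighted least squares baseline correction.

    Iteratively solves ``(W + smoothness * D2'D2) z = W y`` with weights
    ``asymmetry`` above the baseline and ``1 - asymmetry`` below it, until
    the weights change by less than 1e-6 or *max_iter* is reached, then
    subtracts the baseline z.
    """
    if smoothness <= 0 or not 0 < asymmetry < 1:
        raise ValueError("need smoothness > 0 and asymmetry in (0, 1)")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    n = ds.n_variables
    penalty = _whittaker_system(n, smoothness)
    X = np.empty_like(ds.intensities)
    for i, y in enumerate(ds.intensities):
        w = np.ones(n)
        z = y
        for _ in range(max_iter):
            A = sparse.diags(w).tocsc() + penalty
            z = spsolve(A, w * y)
            w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
            if np.max(np.abs(w_new - w)) < 1e-6:
                w = w_new
                break
            w = w_new
        X[i] = y - z
    return ds.replace_intensities(X)


def peak_normalize(ds: SpectralDataset, peak: float = 1650.0) -> SpectralDataset:
    """Divide each spectrum by its intensity at the axis point nearest *peak*."""
    wmin, wmax = ds.wavenumbers.min(), ds.wavenumbers.max()
    if not wmin <= peak <= wmax:
        raise ValueError(f"peak {peak} outside axis range [{wmin}, {wmax}]")
    j = int(np.argmin(np.abs(ds.wavenumbers - peak)))
    ref = ds.intensities[:, j]
    zero = np.flatnonzero(ref == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"zero intensity at normalization peak for sample "
            f"{ds.sample_ids[zero[0]]!r}")
    return ds.replace_intensities(ds.intensities / ref[:, None])


def vector_normalize(ds: SpectralDataset) -> SpectralDataset:
    """Scale each spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(ds.intensities, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"all-zero spectrum cannot be vector-normalized: sample "
            f"{ds.sample_ids[zero[0]]!r}")
    return ds.replace_intensities(ds.intensities / norms[:, None])


_STEPS: dict[str, Callable] = {
    "cut_region": cut_region,
    "savgol": savgol_smooth,
    "rubberband": rubberband_baseline,
    "awls": awls_baseline,
    "peak_norm": peak_normalize,
    "vector_norm": vector_normalize,
}


def load_recipe(path: str | Path) -> list[dict]:
    """Load an ordered step list from a YAML (or JSON) file."""
    steps = yaml.safe_load(Path(path).read_text())
    if not isinstance(steps, list):
        raise ValueError(f"{path}: recipe must be a list of steps")
    for step in steps:
        if not isinstance(step, dict) or "kind" not in step:
            raise ValueError(f"{path}: each step needs a 'kind' key")
        if step["kind"] not in _STEPS:
            raise ValueError(f"{path}: unknown step kind {step['kind']!r}")
    return steps


def apply_recipe(ds: SpectralDataset, steps: Sequence[dict]) -> SpectralDataset:
    """Apply an ordered list of steps ({'kind': ..., **params})."""
    for step in steps:
        params = {k: v for k, v in step.items() if k != "kind"}
        ds = _STEPS[step["kind"]](ds, **params)
    return ds
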