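"""Monte-Carlo calibration of outlier-detection cut-off points.

The detector flags observation ``i`` when the circular distance between
its absolute residual ``e_i`` and the residuals' circular median exceeds
a cut-off.  Cut-offs are calibrated under the null (outlier-free) model:

1. simulate a clean dataset from the reference model,
2. fit the chosen estimator with a CV-selected bandwidth,
3. take empirical quantiles of the median-distances ``dist_i``,
4. average the quantiles over many replicates.

The reference model draws ``x ~ N(3, 0.25)`` and sets

    y = [sin(1.5*x - pi/2) + (4/3)*cos(x/3) + eps] mod 2*pi,
    eps ~ WC(0, rho),

so one cut-off exists per (estimator, quantile level q, sample size n,
concentration rho).  A pre-computed table over n in {20, 30, 40, 50, 100,
200} and rho in {0.10, ..., 0.99} ships with the package and can be
regenerated (or extended) with :func:`generate_cutoffs`.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import circ_distance, circular_median, wrap
from .exceptions import InvalidQuantileError
from .regression import RegressionData, fit_regression
from .wrapped_cauchy import WCParams, sample_wc

__all__ = [
    "default_mean_function",
    "generate_model_data",
    "single_rep_quantiles",
    "generate_cutoffs",
    "CutoffTable",
    "lookup_cutoff",
]

X_MEAN = 3.0
X_SD = 0.5  # variance 0.25
DEFAULT_REPS = 2000
DEFAULT_QUANTILES = (0.90, 0.95, 0.99)


def default_mean_function(x):
    """Reference regression curve ``m(x) = sin(1.5x - pi/2) + (4/3) cos(x/3)``."""
    x = np.asarray(x, dtype=float)
    return np.sin(1.5 * x - np.pi / 2.0) + (4.0 / 3.0) * np.cos(x / 3.0)


def generate_model_data(n: int, rho: float, seed=None,
                        mean_function=None) -> RegressionData:
    """Simulate one clean dataset from the reference linear-circular model.

    ``seed`` may be an integer or a ``numpy.random.Generator``; the same
    seed always yields the same dataset.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = default_mean_function if mean_function is None else mean_function
    x = rng.normal(X_MEAN, X_SD, size=n)
    eps = sample_wc(n, WCParams(0.0, rho), rng)
    y = wrap(m(x) + eps)
    return RegressionData(x, y)


def median_distances(residuals) -> np.ndarray:
    """Distances of absolute residuals from their circular median."""
    e = np.atleast_1d(residuals)
    return circ_distance(e, circular_median(e))


def single_rep_quantiles(n: int, rho: float, method: str = "NW",
                         q_list=DEFAULT_QUANTILES, seed=None,
                         grid=None, fixed_h: float | None = None,
                         mean_function=None) -> np.ndarray:
    """One null-model replicate: simulate, fit, and return quantiles of the median-distances."""
    data = generate_model_data(n, rho, seed, mean_function)
    fit = fit_regression(data, method, h=fixed_h, grid=grid)
    dist = median_distances(fit.residuals)
    return np.quantile(dist, np.atleast_1d(q_list))  # linear interpolation of order stats


def generate_cutoffs(n: int, rho: float, method: str = "NW",
                     q_list=DEFAULT_QUANTILES, reps: int = DEFAULT_REPS,
                     seed: int = 0, grid=None, fixed_h: float | None = None,
                     mean_function=None) -> pd.DataFrame:
    """Mean of per-replicate quantiles over ``reps`` null replicates.

    Each replicate draws from an independent substream spawned from the
    master seed, so results do not depend on execution order.  Returns a
    tidy frame with one row per quantile level and the Monte-Carlo
    standard error of each cut-off.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    q = np.atleast_1d(q_list).astype(float)
    streams = np.random.SeedSequence(seed).spawn(reps)
    vals = np.empty((reps, q.size))
    for r, ss in enumerate(streams):
        vals[r] = single_rep_quantiles(n, rho, method, q, np.random.default_rng(ss),
                                       grid=grid, fixed_h=fixed_h,
                                       mean_function=mean_function)
    se = vals.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.full(q.size, np.nan)
    return pd.DataFrame({
        "method": method, "q": q, "n": n, "rho": rho,
        "cutoff": vals.mean(axis=0), "se": se, "reps": reps,
    })


@dataclass
class CutoffTable:
    """A grid of calibrated cut-offs with bilinear (n, rho) interpolation lookup.

    Backed by a tidy frame with columns ``method, q, n, rho, cutoff``.
    """

    frame: pd.DataFrame

    REQUIRED = ("method", "q", "n", "rho", "cutoff")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValueError(f"cut-off table is missing columns: {sorted(missing)}")

    @classmethod
    def packaged(cls) -> "CutoffTable":
        """The table shipped with the package (reference-model calibration)."""
        ref = importlib.resources.files("circoutlier.data") / "cutoff_tables.csv"
        with importlib.resources.as_file(ref) as path:
            return cls(pd.read_csv(path))

    @classmethod
    def from_csv(cls, path) -> "CutoffTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        out = self.frame.copy()
        out["cutoff"] = out["cutoff"].round(4)
        out.to_csv(path, index=False)

    def lookup(self, n: int, rho: float, q: float, method: str = "NW",
               extrapolate: bool = False) -> float:
        """Cut-off at (n, rho): exact at grid knots, bilinear between them.

        ``rho`` outside the tabulated range clamps to the nearest knot with
        a warning; ``n`` below the smallest tabulated size is an error
        unless ``extrapolate`` is set (which also clamps).
        """
        sub = self.frame[(self.frame["method"] == method)
                         & np.isclose(self.frame["q"], q)]
        if sub.empty:
            raise InvalidQuantileError(
                f"no cut-offs tabulated for method={method!r}, q={q}")
        pivot = sub.pivot_table(index="n", columns="rho", values="cutoff").sort_index()
        ns = pivot.index.to_numpy(dtype=float)
        rhos = pivot.columns.to_numpy(dtype=float)
        mat = pivot.to_numpy()
        if rho < rhos[0] or rho > rhos[-1]:
            warnings.warn(f"rho={rho:.4g} outside tabulated range "
                          f"[{rhos[0]}, {rhos[-1]}]; clamping", stacklevel=2)
        if n < ns[0] and not extrapolate:
            raise ValueError(f"n={n} below smallest tabulated size {int(ns[0])}; "
                             "pass extrapolate=True to clamp")
        if n > ns[-1]:
            warnings.warn(f"n={n} above largest tabulated size {int(ns[-1])}; "
                          "clamping", stacklevel=2)
        at_rho = np.array([np.interp(rho, rhos, row) for row in mat])
        return float(np.interp(n, ns, at_rho))


def lookup_cutoff(table: CutoffTable, n: int, rho: float, q: float,
                  method: str = "NW", **kw) -> float:
    """Functional alias for :meth:`CutoffTable.lookup`."""
    return table.lookup(n, rho, q, method, **kw)
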