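"""Simulation study of detection performance under controlled contamination.

Outliers are injected by rotating selected responses through an angle
``gamma * pi`` (``gamma`` is the contamination degree; ``gamma = 1`` is the
antipodal shift).  Performance per design cell is summarized by

* TDR — true detection rate, fraction of injected outliers flagged;
* masking (M) — fraction of injected outliers missed, ``M = 1 - TDR``;
* swamping (S) — fraction of clean observations wrongly flagged;
* MCE — mean circular error of the fit on the contaminated data.

``run_design`` crosses sample size, concentration, contamination degree,
contaminated fraction and estimator, detecting with table cut-offs looked
up at the true simulation concentration (the calibration grid is indexed
by the known rho; an option switches to the estimated concentration to
quantify the practical gap).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .angles import circ_distance, circular_median, wrap
from .cutoffs import CutoffTable, generate_model_data
from .detect import estimate_rho_for_lookup
from .regression import fit_regression, mce

__all__ = ["ContaminationSpec", "PerformanceSummary", "contaminate",
           "performance", "run_design"]


@dataclass(frozen=True)
class ContaminationSpec:
    """How to contaminate a sample: shift size ``gamma*pi`` and which points."""

    gamma: float
    fraction: float | None = None
    indices: tuple | None = None

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.fraction is None and self.indices is None:
            raise ValueError("give either a contaminated fraction or explicit indices")

    def n_outliers(self, n: int) -> int:
        if self.indices is not None:
            return len(self.indices)
        k = int(round(self.fraction * n))
        k = max(1, k)  # fractions below 1/n still inject a single outlier
        if k > n:
            raise ValueError("contaminated fraction exceeds the sample size")
        return k


def contaminate(y, spec: ContaminationSpec, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Shift selected responses by ``gamma*pi`` mod ``2*pi``.

    Returns ``(y_contaminated, true_outlier_indices)``.  When indices are
    not given they are drawn uniformly without replacement.
    """
    y = wrap(np.atleast_1d(y))
    n = y.size
    k = spec.n_outliers(n)
    if spec.indices is not None:
        idx = np.asarray(spec.indices, dtype=int)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.choice(n, size=k, replace=False)
    out = y.copy()
    out[idx] = wrap(out[idx] + spec.gamma * np.pi)
    return out, np.sort(idx)


@dataclass
class PerformanceSummary:
    """Detection rates for one evaluation: TDR + masking = 1 by construction."""

    tdr: float
    masking: float
    swamping: float


def performance(flagged, truth, n: int) -> PerformanceSummary:
    """Score a flagged index set against the true outlier set of a sample of size ``n``."""
    flagged = set(np.atleast_1d(np.asarray(flagged, dtype=int)).tolist())
    truth = set(np.atleast_1d(np.asarray(truth, dtype=int)).tolist())
    if not truth:
        raise ValueError("masking/TDR undefined for an empty truth set")
    if n <= len(truth):
        raise ValueError("swamping undefined when every observation is an outlier")
    tdr = len(flagged & truth) / len(truth)
    masking = len(truth - flagged) / len(truth)
    swamping = len(flagged - truth) / (n - len(truth))
    return PerformanceSummary(tdr=tdr, masking=masking, swamping=swamping)


def _run_cell(n, rho, gamma, fraction, method, q, reps, seed_seq, table,
              use_estimated_rho, grid):
    rows = np.empty((reps, 4))  # tdr, masking, swamping, mce
    spec = ContaminationSpec(gamma=gamma, fraction=fraction)
    for r, ss in enumerate(seed_seq.spawn(reps)):
        rng = np.random.default_rng(ss)
        data = generate_model_data(n, rho, rng)
        y_c, truth = contaminate(data.y, spec, rng)
        from .regression import RegressionData
        cdata = RegressionData(data.x, y_c)
        fit = fit_regression(cdata, method, grid=grid)
        dist = circ_distance(fit.residuals, circular_median(fit.residuals))
        rho_lookup = (estimate_rho_for_lookup(cdata, method, fit=fit)
                      if use_estimated_rho else rho)
        cutoff = table.lookup(n, rho_lookup, q, method, extrapolate=True)
        flagged = np.nonzero(dist > cutoff)[0]
        perf = performance(flagged, truth, n)
        rows[r] = (perf.tdr, perf.masking, perf.swamping, mce(cdata.y, fit.fitted))
    mean = rows.mean(axis=0)
    se = rows.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.full(4, np.nan)
    return mean, se


def run_design(ns, rhos, gammas, fractions, methods=("NW", "LL"), q: float = 0.95,
               reps: int = 500, seed: int = 0, table: CutoffTable | None = None,
               use_estimated_rho: bool = False, grid=None) -> pd.DataFrame:
    """Full crossover over the design factors; one row of mean rates per cell.

    Deterministic given ``seed``: every cell gets its own substream, so
    adding or reordering cells does not change any cell's result.
    """
    tab = table if table is not None else CutoffTable.packaged()
    cells = list(product(np.atleast_1d(methods), np.atleast_1d(ns).astype(int),
                         np.atleast_1d(rhos).astype(float),
                         np.atleast_1d(gammas).astype(float),
                         np.atleast_1d(fractions).astype(float)))
    streams = np.random.SeedSequence(seed).spawn(len(cells))
    out = []
    for (method, n, rho, gamma, fraction), ss in zip(cells, streams):
        mean, se = _run_cell(n, rho, gamma, fraction, method, q, reps, ss, tab,
                             use_estimated_rho, grid)
        out.append({"method": method, "q": q, "n": n, "rho": rho, "gamma": gamma,
                    "fraction": fraction, "reps": reps,
                    "tdr": mean[0], "masking": mean[1], "swamping": mean[2],
                    "mce": mean[3], "se_tdr": se[0], "se_swamping": se[2]})
    return pd.DataFrame(out)
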