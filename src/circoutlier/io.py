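"""Dataset ingest, serialization and synthetic fixtures."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import to_degrees, to_radians, wrap
from .cutoffs import generate_model_data
from .regression import RegressionData
from .simstudy import ContaminationSpec, contaminate
from .wrapped_cauchy import WCParams, sample_wc

__all__ = ["DatasetSpec", "read_dataset", "write_dataset", "make_fixture"]

log = logging.getLogger(__name__)


@dataclass
class DatasetSpec:
    """Where and how to read a delimited (x, angle) dataset."""

    path: str
    x_col: str
    y_col: str
    units: str = "radians"   # 'degrees' or 'radians'
    delimiter: str = ","


def read_dataset(spec: DatasetSpec) -> RegressionData:
    """Read paired observations; angles are reduced to [0, 2*pi) radians.

    Rows with missing values in either column are dropped (the count is
    logged at INFO).
    """
    df = pd.read_csv(spec.path, sep=spec.delimiter)
    for col in (spec.x_col, spec.y_col):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {spec.path}")
    sub = df[[spec.x_col, spec.y_col]].apply(pd.to_numeric, errors="coerce")
    kept = sub.dropna()
    dropped = len(sub) - len(kept)
    if dropped:
        log.info("dropped %d row(s) with missing values from %s", dropped, spec.path)
    if kept.empty:
        raise ValueError(f"no usable rows in {spec.path}")
    y = to_radians(kept[spec.y_col].to_numpy(), spec.units)
    return RegressionData(kept[spec.x_col].to_numpy(), y)


def write_dataset(data: RegressionData, path, x_col: str = "x", y_col: str = "y",
                  units: str = "radians", delimiter: str = ","):
    """Write a dataset back to delimited text, converting units on the way out."""
    y = to_degrees(data.y) if units == "degrees" else data.y
    pd.DataFrame({x_col: data.x, y_col: y}).to_csv(path, sep=delimiter, index=False)


# wind-speed/direction fixture defaults: a diffuse directional response
# (concentration ~0.18) around a gently varying curve, in degrees
_SCADA_N = 55
_SCADA_RHO = 0.1831
_SCADA_MU = 1.074


def make_fixture(kind: str, n: int | None = None, seed: int = 0, *,
                 rho: float | None = None, gamma: float = 0.85,
                 fraction: float = 0.0):
    """Build a synthetic dataset with known ground truth.

    ``kind='eq-model'`` (alias ``'model'``): the reference simulation model,
    optionally contaminated; returns ``(RegressionData, truth)`` where
    ``truth`` holds the clean responses, the mean-curve values and the
    injected outlier indices.

    ``kind='scada_like'``: a synthetic stand-in for a wind-turbine
    SCADA-style sample — 55 pairs of wind speed (m/s) against wind
    direction (degrees), a smooth speed-direction relation, diffuse
    wrapped-Cauchy noise (rho ~ 0.18) and a few injected antipodal
    shifts.  ``truth['frame']`` carries the natural-unit columns.
    """
    rng = np.random.default_rng(seed)
    if kind in ("eq-model", "model"):
        n = 100 if n is None else n
        rho = 0.9 if rho is None else rho
        data = generate_model_data(n, rho, rng)
        truth = {"clean_y": data.y.copy(),
                 "mean_curve": wrap(np.sin(1.5 * data.x - np.pi / 2)
                                    + (4.0 / 3.0) * np.cos(data.x / 3.0)),
                 "outlier_indices": np.array([], dtype=int)}
        if fraction > 0:
            y_c, idx = contaminate(data.y, ContaminationSpec(gamma, fraction), rng)
            data = RegressionData(data.x, y_c)
            truth["outlier_indices"] = idx
        return data, truth

    if kind == "scada_like":
        n = _SCADA_N if n is None else n
        rho = _SCADA_RHO if rho is None else rho
        speed = np.clip(rng.normal(6.5, 2.0, size=n), 0.5, None)  # m/s
        base = _SCADA_MU + 0.4 * np.sin((speed - 6.5) / 2.5)      # radians
        noise = sample_wc(n, WCParams(0.0, rho), rng)
        y = wrap(base + noise)
        n_out = max(1, int(round(0.05 * n)))
        idx = np.sort(rng.choice(n, size=n_out, replace=False))
        y[idx] = wrap(y[idx] + gamma * np.pi)
        data = RegressionData(speed, y)
        frame = pd.DataFrame({"wind_speed": speed,
                              "wind_direction": to_degrees(y)})
        truth = {"outlier_indices": idx, "frame": frame,
                 "units": "degrees", "rho": rho}
        return data, truth

    raise ValueError(f"unknown fixture kind: {kind!r}")
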