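"""Surface and tumor-localization accuracy metrics: RMSE, HD95, COME.

RMSE uses node correspondence (the clouds share mesh topology); HD95 is the
symmetric 95th-percentile directed nearest-neighbor distance and needs no
correspondence; COME is the distance between unweighted tumor centroids.
All values are in millimetres.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import SurfacePointCloud

__all__ = ["rmse", "hd95", "come", "MetricReport"]


def _coords(x) -> np.ndarray:
    if isinstance(x, SurfacePointCloud):
        return x.coords
    return np.atleast_2d(np.asarray(x, dtype=np.float64))


def rmse(pred, tar) -> float:
    """sqrt(mean_p ||x_pred_p - x_tar_p||^2) over corresponding nodes."""
    p, t = _coords(pred), _coords(tar)
    if p.shape != t.shape:
        raise ValueError("rmse requires node-aligned clouds")
    return float(np.sqrt(np.mean(np.sum((p - t) ** 2, axis=1))))


def hd95(pred, tar, percentile_method: str = "linear") -> float:
    """max of the two directed 95th-percentile nearest-neighbor distances.

    ``percentile_method='linear'`` interpolates between order statistics
    (default); 'nearest' gives the nearest-rank convention for sensitivity
    checks.
    """
    p, t = _coords(pred), _coords(tar)
    if p.size == 0 or t.size == 0:
        raise ValueError("hd95 requires nonempty clouds")
    d_pt = cKDTree(t).query(p)[0]
    d_tp = cKDTree(p).query(t)[0]
    method = {"linear": "linear", "nearest": "nearest"}[percentile_method]
    return float(max(np.percentile(d_pt, 95, method=method),
                     np.percentile(d_tp, 95, method=method)))


def come(pred_tumor, tar_tumor) -> float:
    """Center-of-mass error: distance between unweighted coordinate means."""
    p, t = _coords(pred_tumor), _coords(tar_tumor)
    if p.size == 0 or t.size == 0:
        raise ValueError("come requires nonempty point sets")
    return float(np.linalg.norm(p.mean(axis=0) - t.mean(axis=0)))


class MetricReport:
    """Per-case metric table with mean +- s.d. summary rows."""

    def __init__(self):
        self._rows: list[dict] = []

    def add(self, case_id, metric: str, value: float, **extra) -> None:
        value = float(value)
        if not np.isfinite(value) or value < 0:
            raise ValueError("metric values must be finite and nonnegative")
        self._rows.append({"case": case_id, "metric": metric,
                           "value_mm": value, **extra})

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows)

    def summary(self) -> pd.DataFrame:
        df = self.frame()
        if df.empty:
            return pd.DataFrame(columns=["metric", "mean_mm", "sd_mm", "n"])
        g = df.groupby("metric")["value_mm"]
        return pd.DataFrame({"mean_mm": g.mean(), "sd_mm": g.std(ddof=1),
                             "n": g.size()}).reset_index()

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)

    def summary_json(self) -> dict:
        return {row["metric"]: {"mean_mm": row["mean_mm"],
                                "sd_mm": (None if pd.isna(row["sd_mm"])
                                          else row["sd_mm"]),
                                "n": int(row["n"])}
                for _, row in self.summary().iterrows()}
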