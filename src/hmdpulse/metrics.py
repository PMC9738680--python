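"""Prediction-vs-ground-truth evaluation metrics.

All statistics are computed from the signed error ``E = P - GT``:
mean error (ME), population standard deviation of the error (SD),
root-mean-square error (RMSE), mean absolute percentage error (MAPE,
reported in percent) and Pearson's correlation (rho).

The population (1/n) form is used throughout, which gives the exact
identity ``RMSE**2 == ME**2 + SD**2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import MetricsError

__all__ = ["MetricsReport", "compute_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    me: float
    sd: float
    rmse: float
    mape: float  # percent
    rho: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        header = f"{'ME':>10} {'Standard Dev.':>15} {'RMSE':>10} {'MAPE':>10} {'rho':>8}"
        row = f"{self.me:>10.4f} {self.sd:>15.4f} {self.rmse:>10.4f} {self.mape:>10.4f} {self.rho:>8.4f}"
        return header + "\n" + row


def compute_metrics(predicted, ground_truth) -> MetricsReport:
    """Compute the full metrics report for two equal-length series.

    Parameters
    ----------
    predicted, ground_truth : array-like
        Equal-length 1-D series of at least two values. Ground-truth values
        must be nonzero (MAPE) and both series non-constant (rho).
    """
    p = np.asarray(predicted, dtype=float).ravel()
    gt = np.asarray(ground_truth, dtype=float).ravel()
    if p.shape != gt.shape:
        raise MetricsError(f"length mismatch: {p.shape} vs {gt.shape}")
    n = p.size
    if n < 2:
        raise MetricsError("need at least two pairs")
    if np.any(gt == 0):
        raise MetricsError("ground truth contains zeros; MAPE undefined")
    if np.ptp(p) == 0 or np.ptp(gt) == 0:
        raise MetricsError("constant series; correlation undefined")

    err = p - gt
    me = float(err.mean())
    sd = float(np.sqrt(np.mean((err - me) ** 2)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mape = float(100.0 * np.mean(np.abs(err) / gt))
    gt_c = gt - gt.mean()
    p_c = p - p.mean()
    rho = float((gt_c * p_c).sum() / np.sqrt((gt_c ** 2).sum() * (p_c ** 2).sum()))
    return MetricsReport(me=me, sd=sd, rmse=rmse, mape=mape, rho=rho, n=n)


def mean_absolute_error(predicted, ground_truth) -> float:
    """Optional extra metric; not part of the core report."""
    p = np.asarray(predicted, dtype=float).ravel()
    gt = np.asarray(ground_truth, dtype=float).ravel()
    if p.shape != gt.shape:
        raise MetricsError(f"length mismatch: {p.shape} vs {gt.shape}")
    return float(np.mean(np.abs(p - gt)))
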