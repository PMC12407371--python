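"""Voltage-to-RWC transfer functions and end-to-end evaluation.

A generated 10-point characteristic curve is turned into a continuous
mapping RWC = f(V_TRx) by least-squares polynomial fitting (degree 3 by
default).  The fit is used to translate instantaneous device voltages
(one-shot readings) and whole voltage traces into hydration values, and
the hold-out evaluation mirrors the study design: predict curves for
unseen leaves, score each by RMSE against its measured curve, and
report the best (minimum) alongside the mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CharacteristicCurve, TrainingLibrary
from .cvae import CurveGenerator, predict_curve
from .errors import (
    InvalidArgumentError,
    LeakageError,
    UnderdeterminedFitError,
)
from .morphometrics import LeafFeatures

logger = logging.getLogger(__name__)

__all__ = [
    "TransferFunction",
    "VoltageTrace",
    "EvaluationReport",
    "OneShotResult",
    "fit_transfer",
    "voltage_to_rwc",
    "translate_trace",
    "one_shot_rwc",
    "rmse",
    "evaluate_holdout",
]


@dataclass
class TransferFunction:
    """Polynomial RWC = f(V_TRx) valid on the source curve's V range.

    Outside ``v_range`` the polynomial is *not* extrapolated: the input
    clamps to the nearest range endpoint (cubic extrapolation is
    unbounded and physically meaningless), and the output clamps to
    [0, 100].
    """

    poly: np.polynomial.Polynomial
    degree: int
    v_range: tuple  # (v_lo, v_hi), mV
    source: Optional[str] = None
    fit_residual: float = 0.0  # max |f(v_i) - rwc_i| over the fitted points

    def __post_init__(self):
        if self.degree < 1:
            raise InvalidArgumentError("degree must be >= 1")
        if not self.v_range[0] < self.v_range[1]:
            raise InvalidArgumentError("v_range must satisfy v_lo < v_hi")

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients in the unscaled V domain, ascending powers."""
        return self.poly.convert().coef

    def __call__(self, v):
        return voltage_to_rwc(self, v)

    def is_monotone(self, n_grid: int = 256) -> bool:
        grid = np.linspace(*self.v_range, n_grid)
        dy = np.diff(self.poly(grid))
        return bool(np.all(dy <= 1e-12) or np.all(dy >= -1e-12))


@dataclass
class VoltageTrace:
    """Time-ordered PLP voltage samples: (time in h, V_TRx in mV)."""

    time_h: np.ndarray
    v_trx: np.ndarray

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.v_trx = np.asarray(self.v_trx, dtype=float)
        if self.time_h.shape != self.v_trx.shape or self.time_h.ndim != 1:
            raise InvalidArgumentError("time and voltage must be equal-length 1-D")
        if len(self.time_h) and np.any(np.diff(self.time_h) <= 0):
            raise InvalidArgumentError("time must be strictly increasing")
        if np.any(self.v_trx <= 0):
            raise InvalidArgumentError("all voltages must be positive")

    def __len__(self):
        return len(self.time_h)


def fit_transfer(curve: CharacteristicCurve, degree: int = 3) -> TransferFunction:
    """Least-squares polynomial fit of RWC against V_TRx.

    Requires more curve points than the degree.  Duplicate voltages
    with conflicting RWC make the fit ill-conditioned and are flagged.
    """
    if degree < 1:
        raise InvalidArgumentError("degree must be >= 1")
    if len(curve) <= degree:
        raise UnderdeterminedFitError(
            f"degree {degree} needs more than {degree} points, got {len(curve)}"
        )
    v, r = curve.v_trx, curve.rwc
    uniq, inv = np.unique(v, return_inverse=True)
    if len(uniq) < len(v):
        spread = max(np.ptp(r[inv == i]) for i in range(len(uniq)))
        if spread > 1e-9:
            logger.warning(
                "duplicate V_TRx values with conflicting RWC (spread %.3g); "
                "fit may be ill-conditioned",
                spread,
            )
    poly = np.polynomial.Polynomial.fit(v, r, degree)
    residual = float(np.max(np.abs(poly(v) - r)))
    tf = TransferFunction(
        poly=poly,
        degree=degree,
        v_range=(float(v.min()), float(v.max())),
        source=curve.leaf_id or curve.cultivar,
        fit_residual=residual,
    )
    if not tf.is_monotone():
        logger.warning(
            "fitted transfer function is non-monotone on its V range (source=%s)",
            tf.source,
        )
    return tf


def voltage_to_rwc(tf: TransferFunction, v) -> np.ndarray | float:
    """Evaluate the transfer function with range and output clamping."""
    v_arr = np.asarray(v, dtype=float)
    n_out = int(np.sum((v_arr < tf.v_range[0]) | (v_arr > tf.v_range[1])))
    if n_out:
        logger.info("%d voltage value(s) outside fit range %s; clamped", n_out, tf.v_range)
    v_clamped = np.clip(v_arr, *tf.v_range)
    out = np.clip(tf.poly(v_clamped), 0.0, 100.0)
    return float(out) if np.isscalar(v) or v_arr.ndim == 0 else out


def translate_trace(tf: TransferFunction, trace: VoltageTrace) -> pd.DataFrame:
    """Convert a voltage trace to an RWC time series, sample for sample."""
    if len(trace) == 0:
        return pd.DataFrame({"time_h": [], "rwc_pct": []})
    rwc = voltage_to_rwc(tf, trace.v_trx)
    return pd.DataFrame({"time_h": trace.time_h, "rwc_pct": np.atleast_1d(rwc)})


@dataclass
class OneShotResult:
    """A single translated RWC reading plus its audit trail."""

    rwc: float
    curve: CharacteristicCurve
    transfer: TransferFunction


def one_shot_rwc(
    gen: CurveGenerator, features: LeafFeatures, v: float, degree: int = 3
) -> OneShotResult:
    """One-touch RWC: predict the leaf's curve, fit, translate one voltage."""
    curve = predict_curve(gen, features, mode="deterministic")
    tf = fit_transfer(curve, degree=degree)
    return OneShotResult(rwc=float(voltage_to_rwc(tf, v)), curve=curve, transfer=tf)


def rmse(predicted: Sequence[float], truth: Sequence[float]) -> float:
    """Root mean squared error between two equal-length series."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size < 1:
        raise InvalidArgumentError("series must be equal-length and non-empty")
    return float(np.sqrt(np.mean((p - t) ** 2)))


@dataclass
class EvaluationReport:
    """Hold-out evaluation: per-leaf RMSEs with best-of-k summaries."""

    cultivar: str
    per_leaf: pd.DataFrame  # leaf_id, v_rmse_mv, rwc_rmse_pct
    best_v_rmse: float
    best_rwc_rmse: float
    mean_v_rmse: float
    mean_rwc_rmse: float
    best_v_leaf: str
    best_rwc_leaf: str
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cultivar": self.cultivar,
            "n_leaves": int(len(self.per_leaf)),
            "best_v_rmse_mv": self.best_v_rmse,
            "best_rwc_rmse_pct": self.best_rwc_rmse,
            "mean_v_rmse_mv": self.mean_v_rmse,
            "mean_rwc_rmse_pct": self.mean_rwc_rmse,
            "best_v_leaf": self.best_v_leaf,
            "best_rwc_leaf": self.best_rwc_leaf,
            "config": self.config,
        }

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_holdout(
    gen: CurveGenerator, test: TrainingLibrary, best_of: Optional[int] = None
) -> EvaluationReport:
    """Score deterministic curve predictions against held-out leaves.

    The test library must be disjoint (by leaf id) from the training
    library; overlap raises.  ``best_of`` limits evaluation to the
    first k test leaves, mirroring a best-of-k reporting design.  The
    "best" values are minima over the evaluated leaves and are labeled
    as such -- they are optimistic, not representative.
    """
    overlap = set(gen.train_leaf_ids) & set(test.leaf_ids)
    if overlap:
        raise LeakageError(f"test library shares {len(overlap)} leaf id(s) with training")
    k = test.n_leaves if best_of is None else min(best_of, test.n_leaves)
    if k < 1:
        raise InvalidArgumentError("need at least one test leaf")
    rows = []
    for i in range(k):
        feats = LeafFeatures(*test.features[i])
        pred = predict_curve(gen, feats, mode="deterministic")
        rows.append(
            {
                "leaf_id": test.leaf_ids[i],
                "v_rmse_mv": rmse(pred.v_trx, test.v_matrix[i]),
                "rwc_rmse_pct": rmse(pred.rwc, test.rwc_matrix[i]),
            }
        )
    df = pd.DataFrame(rows)
    i_v = int(df["v_rmse_mv"].idxmin())
    i_r = int(df["rwc_rmse_pct"].idxmin())
    return EvaluationReport(
        cultivar=gen.cultivar,
        per_leaf=df,
        best_v_rmse=float(df["v_rmse_mv"].min()),
        best_rwc_rmse=float(df["rwc_rmse_pct"].min()),
        mean_v_rmse=float(df["v_rmse_mv"].mean()),
        mean_rwc_rmse=float(df["rwc_rmse_pct"].mean()),
        best_v_leaf=str(df.loc[i_v, "leaf_id"]),
        best_rwc_leaf=str(df.loc[i_r, "leaf_id"]),
        config={"best_of": k, **gen.manifest},
    )
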