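"""Relative-water-content calibration and training-library assembly.

The stepwise drying protocol produces, per leaf, a sequence of
(fresh mass, V_TRx) readings; together with the turgid and 24-h dry
reference masses these become a 10-point "characteristic curve" of
transmit-receive voltage against relative water content

    RWC = 100 * (fresh - dry) / (turgid - dry)   [%].

Curves plus the per-leaf feature vectors form the training library
consumed by the generative model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import trunc
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCalibrationError,
    InconsistentLibraryError,
    InvalidArgumentError,
    UndefinedBaselineError,
)
from .morphometrics import LeafFeatures

__all__ = [
    "DryingRecord",
    "CharacteristicCurve",
    "TrainingLibrary",
    "compute_rwc",
    "assemble_curve",
    "build_library",
    "percent_change",
    "absolute_change",
    "write_library",
    "read_library",
]

CURVE_POINTS = 10  # drying loops per leaf in the acquisition protocol


@dataclass(frozen=True)
class DryingRecord:
    """One loop iteration: oven step index, leaf mass, and PLP voltage."""

    iteration: int
    fresh_mass: float  # g
    v_trx: float  # mV

    def __post_init__(self):
        if self.iteration < 0:
            raise InvalidArgumentError("iteration index must be >= 0")
        if not self.fresh_mass > 0:
            raise InvalidArgumentError("fresh_mass must be positive")
        if not self.v_trx > 0:
            raise InvalidArgumentError("v_trx must be positive")


@dataclass
class CharacteristicCurve:
    """Ordered (V_TRx, RWC) pairs for one leaf, in acquisition order.

    Acquisition runs turgid -> dry, so RWC is monotone non-increasing
    up to measurement noise; strong inversions are flagged, not fixed.
    """

    v_trx: np.ndarray  # mV
    rwc: np.ndarray  # %
    cultivar: Optional[str] = None
    leaf_id: Optional[str] = None

    def __post_init__(self):
        self.v_trx = np.asarray(self.v_trx, dtype=float)
        self.rwc = np.asarray(self.rwc, dtype=float)
        if self.v_trx.shape != self.rwc.shape or self.v_trx.ndim != 1:
            raise InvalidArgumentError("v_trx and rwc must be equal-length 1-D arrays")
        if len(self.v_trx) < 1:
            raise InvalidArgumentError("a curve needs at least one point")
        if not np.all(self.v_trx > 0):
            raise InvalidArgumentError("all v_trx must be positive")
        if np.any(self.rwc < 0) or np.any(self.rwc > 100):
            raise InvalidArgumentError("all rwc must lie in [0, 100]")
        if np.any(np.diff(self.rwc) > 5.0):
            warnings.warn(
                "curve RWC increases by >5 points between loops; "
                "check acquisition order",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.v_trx)

    @property
    def points(self):
        return list(zip(self.v_trx.tolist(), self.rwc.tolist()))


@dataclass
class TrainingLibrary:
    """Stacked per-cultivar training data: N curves + N feature rows."""

    v_matrix: np.ndarray  # N x 10, mV
    rwc_matrix: np.ndarray  # N x 10, %
    features: np.ndarray  # N x 5
    cultivar: str
    leaf_ids: Sequence[str]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        self.v_matrix = np.asarray(self.v_matrix, dtype=float)
        self.rwc_matrix = np.asarray(self.rwc_matrix, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        n = self.v_matrix.shape[0]
        if not (self.rwc_matrix.shape[0] == n and self.features.shape[0] == n == len(self.leaf_ids)):
            raise InconsistentLibraryError("row counts of curves, features and ids differ")
        if self.v_matrix.shape[1] != self.rwc_matrix.shape[1]:
            raise InconsistentLibraryError("V and RWC matrices differ in column count")
        if self.features.shape[1] != 5:
            raise InconsistentLibraryError("feature matrix must have 5 columns")

    @property
    def n_leaves(self) -> int:
        return self.v_matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.v_matrix.shape[1]


def compute_rwc(fresh_mass: float, turgid_mass: float, dry_mass: float) -> float:
    """Relative water content in percent from the three reference masses.

    Readings slightly outside [dry, turgid] (balance noise) clamp to the
    nearest bound with a warning; a turgid mass not exceeding the dry
    mass leaves no water range to normalise by and is an error.
    """
    if not dry_mass > 0:
        raise InvalidArgumentError("dry_mass must be positive")
    if turgid_mass <= dry_mass:
        raise DegenerateCalibrationError(
            f"turgid mass ({turgid_mass} g) must exceed dry mass ({dry_mass} g)"
        )
    tol = 1e-9 * (turgid_mass - dry_mass)
    if fresh_mass < dry_mass - tol or fresh_mass > turgid_mass + tol:
        warnings.warn(
            f"fresh mass {fresh_mass} g outside [dry, turgid]=[{dry_mass}, {turgid_mass}] g; "
            "RWC clamped",
            stacklevel=2,
        )
    rwc = 100.0 * (fresh_mass - dry_mass) / (turgid_mass - dry_mass)
    return float(min(100.0, max(0.0, rwc)))


def assemble_curve(
    records: Sequence[DryingRecord],
    turgid_mass: float,
    dry_mass: float,
    cultivar: Optional[str] = None,
    leaf_id: Optional[str] = None,
) -> CharacteristicCurve:
    """Turn a drying-loop record sequence into a characteristic curve."""
    if len(records) < 2:
        raise InvalidArgumentError("need at least 2 drying records")
    v = np.array([r.v_trx for r in records], dtype=float)
    rwc = np.array(
        [compute_rwc(r.fresh_mass, turgid_mass, dry_mass) for r in records], dtype=float
    )
    return CharacteristicCurve(v, rwc, cultivar=cultivar, leaf_id=leaf_id)


def build_library(
    curves: Sequence[CharacteristicCurve],
    features: Sequence[LeafFeatures],
    cultivar: str,
    manifest: Optional[dict] = None,
) -> TrainingLibrary:
    """Stack equal-length curves and feature vectors into matrices."""
    if len(curves) != len(features):
        raise InconsistentLibraryError(
            f"{len(curves)} curves but {len(features)} feature sets"
        )
    if len(curves) == 0:
        raise InvalidArgumentError("library cannot be empty")
    lengths = {len(c) for c in curves}
    if len(lengths) != 1:
        raise InconsistentLibraryError(f"mixed curve lengths: {sorted(lengths)}")
    v = np.vstack([c.v_trx for c in curves])
    rwc = np.vstack([c.rwc for c in curves])
    feats = np.vstack([f.as_array() for f in features])
    ids = [c.leaf_id if c.leaf_id is not None else f"{cultivar}-{i:04d}" for i, c in enumerate(curves)]
    man = dict(manifest or {})
    man.setdefault("cultivar", cultivar)
    man.setdefault("shapes", {"v": list(v.shape), "rwc": list(rwc.shape), "features": list(feats.shape)})
    return TrainingLibrary(v, rwc, feats, cultivar, ids, man)


def percent_change(initial: float, final: float, integer: bool = False) -> float:
    """Relative change 100*(final-initial)/initial in percent.

    With ``integer=True`` the value is truncated toward zero, matching
    how endpoint summaries are conventionally reported (238 -> 932 mV is
    a 291% rise).
    """
    if initial == 0:
        raise UndefinedBaselineError("percent change from a zero baseline is undefined")
    pc = 100.0 * (final - initial) / initial
    return float(trunc(pc)) if integer else float(pc)


def absolute_change(initial: float, final: float, integer: bool = False) -> float:
    """Difference final - initial, for quantities already in points (RWC %)."""
    d = float(final) - float(initial)
    return float(trunc(d)) if integer else d


# ---------------------------------------------------------------------------
# CSV / JSON persistence (long-format curves + wide features + manifest)

_FMT = "%.9g"  # 9 significant digits: round-trips through decimal text


def write_library(lib: TrainingLibrary, directory) -> None:
    """Write curves CSV (long), features CSV and a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n, k = lib.v_matrix.shape
    rows = {
        "leaf_id": np.repeat(lib.leaf_ids, k),
        "point_index": np.tile(np.arange(k), n),
        "v_trx_mv": lib.v_matrix.ravel(),
        "rwc_pct": lib.rwc_matrix.ravel(),
    }
    pd.DataFrame(rows).to_csv(directory / "curves.csv", index=False, float_format=_FMT)
    feat = pd.DataFrame(
        lib.features,
        columns=["area_cm2", "perimeter_cm", "ap_ratio_cm", "thickness_um", "skewness"],
    )
    feat.insert(0, "leaf_id", list(lib.leaf_ids))
    feat.to_csv(directory / "features.csv", index=False, float_format=_FMT)
    manifest = dict(lib.manifest)
    manifest["cultivar"] = lib.cultivar
    manifest["n_leaves"] = int(n)
    manifest["n_points"] = int(k)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_library(directory) -> TrainingLibrary:
    """Inverse of :func:`write_library`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    curves = pd.read_csv(directory / "curves.csv")
    feat = pd.read_csv(directory / "features.csv")
    ids = feat["leaf_id"].astype(str).tolist()
    k = int(manifest["n_points"])
    curves = curves.sort_values(["leaf_id", "point_index"], kind="stable")
    order = {lid: i for i, lid in enumerate(ids)}
    curves["_row"] = curves["leaf_id"].astype(str).map(order)
    curves = curves.sort_values(["_row", "point_index"], kind="stable")
    v = curves["v_trx_mv"].to_numpy().reshape(len(ids), k)
    rwc = curves["rwc_pct"].to_numpy().reshape(len(ids), k)
    feats = feat[["area_cm2", "perimeter_cm", "ap_ratio_cm", "thickness_um", "skewness"]].to_numpy()
    return TrainingLibrary(v, rwc, feats, manifest["cultivar"], ids, manifest)
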