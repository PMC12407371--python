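"""Synthetic leaf library generator.

Emulates the statistical structure of the three-cultivar sweet-potato
study design this pipeline is built for: 100 Honey (Cilembu) leaves plus
50 Japanese (Beniazuma) and 50 Orange (OFSP) leaves, each contributing a
10-point V_TRx-RWC characteristic curve acquired through a stepwise
oven-drying loop, together with the five-element morphometric feature
vector (A, P, A/P, T, S).

Ground truth per leaf is a two-endpoint power law

    V(rwc) = v_max - (v_max - v_min) * (rwc/100)**gamma,

the simplest family with the observed qualitative behaviour: voltage
rises monotonically and non-linearly as the blade dries (dry tissue
attenuates ultrasound less than water-filled tissue).  The endpoints and
shape exponent are smooth deterministic functions of the normalized leaf
features, so recovering curves from features alone is a well-posed task
for the generative model.  The Honey cultivar additionally carries two
amplitude groups (maximum voltage near 300 vs 600 mV) drawn
independently of the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .calibration import (
    CharacteristicCurve,
    DryingRecord,
    TrainingLibrary,
    assemble_curve,
    build_library,
)
from .errors import CanvasOverflowError, InvalidArgumentError, UnknownSpecError
from .morphometrics import LeafFeatures, LeafImage

__all__ = [
    "CultivarSpec",
    "GroundTruthCurveModel",
    "SyntheticLeaf",
    "CULTIVARS",
    "get_spec",
    "sample_features",
    "ground_truth_curve",
    "make_leaf",
    "simulate_drying_loop",
    "render_leaf_image",
    "generate_library",
    "save_leaf_image",
]


@dataclass(frozen=True)
class CultivarSpec:
    """Statistical description of one cultivar's leaves and curves.

    ``feature_ranges`` holds uniform (low, high) sampling bounds for
    area (cm^2), perimeter (cm), thickness (um) and skewness; the A/P
    ratio is never sampled -- it is recomputed from area and perimeter,
    and its implied range is derived from theirs.  ``amplitude_groups``
    lists (weight, v_max_scale) mixture components for cultivars whose
    curve amplitudes are bimodal.
    """

    name: str
    n_default: int
    feature_ranges: Dict[str, Tuple[float, float]]
    v_min_base: float  # mV
    v_max_base: float  # mV
    amplitude_groups: Tuple[Tuple[float, float], ...] = ((1.0, 1.0),)
    noise_v_sd: float = 3.0  # mV
    noise_rwc_sd: float = 1.0  # RWC points
    # exponent span covers convex through concave curve shapes while the
    # inverse map stays within reach of a 10-point cubic transfer fit
    curve_shape_gamma_range: Tuple[float, float] = (0.5, 1.5)
    final_rwc_range: Tuple[float, float] = (0.02, 0.10)

    def __post_init__(self):
        for key in ("area", "perimeter", "thickness", "skewness"):
            lo, hi = self.feature_ranges[key]
            if not lo < hi:
                raise InvalidArgumentError(f"{key} range must have low < high")
        if abs(sum(w for w, _ in self.amplitude_groups) - 1.0) > 1e-9:
            raise InvalidArgumentError("amplitude group weights must sum to 1")
        if self.noise_v_sd < 0 or self.noise_rwc_sd < 0:
            raise InvalidArgumentError("noise sds must be non-negative")
        if not 0 < self.v_min_base < self.v_max_base:
            raise InvalidArgumentError("need 0 < v_min_base < v_max_base")
        g_lo, g_hi = self.curve_shape_gamma_range
        if not 0 < g_lo < g_hi:
            raise InvalidArgumentError("gamma range must be positive and ordered")

    @property
    def ap_ratio_range(self) -> Tuple[float, float]:
        """Derived bounds on A/P given the area and perimeter bounds."""
        (a_lo, a_hi) = self.feature_ranges["area"]
        (p_lo, p_hi) = self.feature_ranges["perimeter"]
        return (a_lo / p_hi, a_hi / p_lo)

    def normalize_features(self, features: LeafFeatures) -> np.ndarray:
        """Map the 5 features to [0, 1] by their spec ranges."""
        ranges = [
            self.feature_ranges["area"],
            self.feature_ranges["perimeter"],
            self.ap_ratio_range,
            self.feature_ranges["thickness"],
            self.feature_ranges["skewness"],
        ]
        x = features.as_array()
        return np.array([(v - lo) / (hi - lo) for v, (lo, hi) in zip(x, ranges)])


@dataclass(frozen=True)
class GroundTruthCurveModel:
    """V(rwc) = v_max - (v_max - v_min) * (rwc/100)**gamma, rwc in %."""

    v_min: float  # mV, voltage of the fully turgid blade (rwc = 100)
    v_max: float  # mV, voltage of the fully dry blade (rwc = 0)
    gamma: float  # shape exponent

    def __post_init__(self):
        if not 0 < self.v_min < self.v_max:
            raise InvalidArgumentError("need v_max > v_min > 0")
        if not self.gamma > 0:
            raise InvalidArgumentError("gamma must be positive")

    def __call__(self, rwc) -> np.ndarray:
        rwc = np.asarray(rwc, dtype=float)
        return self.v_max - (self.v_max - self.v_min) * (rwc / 100.0) ** self.gamma


@dataclass(frozen=True)
class SyntheticLeaf:
    """A fully specified virtual leaf: features, truth curve and masses."""

    cultivar: str
    features: LeafFeatures
    truth: GroundTruthCurveModel
    turgid_mass: float  # g
    dry_mass: float  # g
    final_rwc: float = 0.05  # RWC fraction reached after the last loop

    def __post_init__(self):
        if not self.turgid_mass > self.dry_mass > 0:
            raise InvalidArgumentError("need turgid_mass > dry_mass > 0")
        if not 0 < self.final_rwc < 1:
            raise InvalidArgumentError("final_rwc must be in (0, 1)")


def _ranges_from_spread(pairs):
    return {k: tuple(v) for k, v in pairs.items()}


# Built-in cultivar specs.  Feature sampling bounds are set so the
# relative spread (max-min)/min of each feature matches the study
# design's per-cultivar percentages (e.g. Honey area ~155%, thickness
# ~173%); skewness bounds are capped at 0.36, the renderer's realizable
# taper limit.  Honey mixes two equally weighted amplitude groups whose
# maximum voltages sit near 300 and 600 mV.
CULTIVARS: Dict[str, CultivarSpec] = {
    "honey": CultivarSpec(
        name="honey",
        n_default=100,
        feature_ranges=_ranges_from_spread(
            {
                "area": (20.0, 51.0),  # 155% spread
                "perimeter": (11.0, 21.0),  # 91%
                "thickness": (150.0, 409.5),  # 173%
                "skewness": (0.16, 0.36),  # 125%
            }
        ),
        v_min_base=80.0,
        v_max_base=300.0,
        amplitude_groups=((0.5, 1.0), (0.5, 2.0)),
    ),
    "japanese": CultivarSpec(
        name="japanese",
        n_default=50,
        feature_ranges=_ranges_from_spread(
            {
                "area": (12.0, 48.24),  # 302%
                "perimeter": (12.0, 24.24),  # 102%
                "thickness": (210.0, 323.4),  # 54%
                "skewness": (0.08, 0.3408),  # 326%
            }
        ),
        v_min_base=110.0,
        v_max_base=450.0,
    ),
    "orange": CultivarSpec(
        name="orange",
        n_default=50,
        feature_ranges=_ranges_from_spread(
            {
                "area": (17.0, 40.97),  # 141%
                "perimeter": (14.0, 24.22),  # 73%
                "thickness": (240.0, 412.8),  # 72%
                "skewness": (0.05, 0.36),  # 620%
            }
        ),
        v_min_base=95.0,
        v_max_base=380.0,
    ),
}


def get_spec(cultivar: str) -> CultivarSpec:
    try:
        return CULTIVARS[cultivar]
    except KeyError:
        raise UnknownSpecError(
            f"unknown cultivar {cultivar!r}; known: {sorted(CULTIVARS)}"
        ) from None


def sample_features(spec: CultivarSpec, n: int, seed: int) -> List[LeafFeatures]:
    """Draw n feature vectors uniformly within the spec's ranges.

    A/P is recomputed from the sampled area and perimeter, never drawn
    independently.  Output is a pure function of (spec, n, seed).
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = np.random.default_rng(seed)
    area = rng.uniform(*spec.feature_ranges["area"], size=n)
    perim = rng.uniform(*spec.feature_ranges["perimeter"], size=n)
    thick = rng.uniform(*spec.feature_ranges["thickness"], size=n)
    skew = rng.uniform(*spec.feature_ranges["skewness"], size=n)
    return [
        LeafFeatures.from_measurements(a, p, t, s)
        for a, p, t, s in zip(area, perim, thick, skew)
    ]


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


# Fixed coefficients of the feature -> curve-parameter maps.  They are
# part of the generator's definition (documented constants), which is
# what makes parameter recovery from features a well-defined test.
_VMIN_COEF = {"t": 3.0, "a": 1.0, "lo": 0.75, "span": 0.5}
_VMAX_COEF = {"a": 2.4, "ap": 1.6, "s": -0.8, "lo": 0.85, "span": 0.3}
_GAMMA_COEF = {"p": 2.0, "t": 1.2}
_FINAL_RWC_COEF = {"t": 2.0, "a": -1.0}


def ground_truth_curve(
    features: LeafFeatures, spec: CultivarSpec, seed: int
) -> GroundTruthCurveModel:
    """Deterministic feature -> (v_min, v_max, gamma) map plus group draw.

    The endpoints and exponent are affine+logistic functions of the
    normalized features; for bimodal cultivars a seeded draw assigns the
    amplitude group scaling v_max.  Identical (features, spec, seed)
    always yield the identical model.
    """
    nA, nP, nAP, nT, nS = spec.normalize_features(features)
    v_min = spec.v_min_base * (
        _VMIN_COEF["lo"]
        + _VMIN_COEF["span"]
        * _logistic(_VMIN_COEF["t"] * (nT - 0.5) + _VMIN_COEF["a"] * (nA - 0.5))
    )
    v_max = spec.v_max_base * (
        _VMAX_COEF["lo"]
        + _VMAX_COEF["span"]
        * _logistic(
            _VMAX_COEF["a"] * (nA - 0.5)
            + _VMAX_COEF["ap"] * (nAP - 0.5)
            + _VMAX_COEF["s"] * (nS - 0.5)
        )
    )
    g_lo, g_hi = spec.curve_shape_gamma_range
    gamma = g_lo + (g_hi - g_lo) * _logistic(
        _GAMMA_COEF["p"] * (nP - 0.5) + _GAMMA_COEF["t"] * (nT - 0.5)
    )
    weights = [w for w, _ in spec.amplitude_groups]
    scales = [s for _, s in spec.amplitude_groups]
    rng = np.random.default_rng(seed)
    scale = scales[rng.choice(len(scales), p=weights)]
    return GroundTruthCurveModel(float(v_min), float(v_max * scale), float(gamma))


_DRY_TISSUE_DENSITY = 0.35  # g/cm^3 of blade volume occupied by dry matter
_TURGID_WATER_FRACTION = 0.8  # water mass fraction of a fully turgid blade


def make_leaf(
    spec: CultivarSpec, features: LeafFeatures, seed: int
) -> SyntheticLeaf:
    """Complete a feature vector into a SyntheticLeaf with masses and truth."""
    truth = ground_truth_curve(features, spec, seed)
    volume_cm3 = features.area * features.thickness * 1e-4
    dry = volume_cm3 * _DRY_TISSUE_DENSITY
    turgid = dry / (1.0 - _TURGID_WATER_FRACTION)
    nA, _, _, nT, _ = spec.normalize_features(features)
    f_lo, f_hi = spec.final_rwc_range
    final_rwc = f_lo + (f_hi - f_lo) * _logistic(
        _FINAL_RWC_COEF["t"] * (nT - 0.5) + _FINAL_RWC_COEF["a"] * (nA - 0.5)
    )
    return SyntheticLeaf(spec.name, features, truth, turgid, dry, float(final_rwc))


def simulate_drying_loop(
    leaf: SyntheticLeaf,
    n_iter: int = 10,
    rng: Optional[np.random.Generator] = None,
    noise_v_sd: float = 0.0,
) -> List[DryingRecord]:
    """Simulate the stepwise oven-drying acquisition loop.

    Water mass decays geometrically from the turgid amount toward
    ``leaf.final_rwc`` of it at the last iteration, so fresh masses fall
    strictly from the turgid mass toward the dry mass; the voltage at
    each step is the truth curve plus optional Gaussian noise.
    """
    if n_iter < 2:
        raise InvalidArgumentError("need at least 2 loop iterations")
    if rng is None:
        rng = np.random.default_rng(0)
    water0 = leaf.turgid_mass - leaf.dry_mass
    ratio = leaf.final_rwc ** (1.0 / (n_iter - 1))
    records = []
    for t in range(n_iter):
        water = water0 * ratio**t
        rwc = 100.0 * water / water0
        v = float(leaf.truth(rwc))
        if noise_v_sd > 0:
            v += rng.normal(0.0, noise_v_sd)
        # t = 0 reproduces the turgid mass exactly (no rounding residue)
        fresh = leaf.turgid_mass if t == 0 else leaf.dry_mass + water
        records.append(DryingRecord(t, fresh, max(v, 1e-6)))
    return records


# ---------------------------------------------------------------------------
# Leaf renderer: a tapered ellipse whose projected pixel density has a
# closed-form skewness, so requested shape statistics are honored
# analytically rather than by trial rendering.


def _taper_skewness(s: float) -> float:
    """Skewness of density f(u) ~ sqrt(1-u^2)(1-s u) on [-1, 1]."""
    var = 0.25 - s**2 / 16.0
    m3 = s / 16.0 - s**3 / 32.0
    return m3 / var**1.5


MAX_RENDER_SKEWNESS = abs(_taper_skewness(0.999))  # ~0.385


def _solve_taper(target_skew: float) -> float:
    """Invert the closed-form taper->skewness map."""
    if abs(target_skew) < 1e-12:
        return 0.0
    if abs(target_skew) > MAX_RENDER_SKEWNESS:
        raise InvalidArgumentError(
            f"|skewness| {abs(target_skew):.3f} exceeds renderable maximum "
            f"{MAX_RENDER_SKEWNESS:.3f}"
        )
    # density tail sits toward +u for s > 0, matching positive skew
    return brentq(lambda s: _taper_skewness(s) - target_skew, -0.999, 0.999)


def _blade_half_width(u: np.ndarray, b: float, s: float) -> np.ndarray:
    return b * np.sqrt(np.clip(1.0 - u**2, 0.0, None)) * (1.0 - s * u)


def _analytic_perimeter(a: float, b: float, s: float, n: int = 20001) -> float:
    """Arc length of the blade outline by dense quadrature (cm)."""
    u = np.linspace(-1.0, 1.0, n)
    w = _blade_half_width(u, b, s)
    top = np.hypot(np.diff(u) * a, np.diff(w)).sum()
    return float(2.0 * top)


def render_leaf_image(
    features: LeafFeatures,
    px_per_cm: float = 20.0,
    seed: int = 0,
    aspect: float = 0.6,
    margin_cm: float = 1.0,
    canvas_cm: Optional[Tuple[float, float]] = None,
) -> LeafImage:
    """Render a dark blade on a white background at the given scale.

    The blade is a tapered ellipse: half-width
    ``w(u) = b*sqrt(1-u^2)*(1-s*u)`` along the major axis ``u = x/a``,
    with the taper ``s`` solved in closed form from the requested
    skewness; its area is pi*a*b independent of s, so the requested
    area is honored exactly in the continuum.  The returned image
    carries ground truth (true mask, pixel-count area, analytic
    perimeter, direct-moment skewness) for downstream validation.
    """
    if px_per_cm < 10:
        raise InvalidArgumentError("px_per_cm must be >= 10 for a usable raster")
    s = _solve_taper(features.skewness)
    a = float(np.sqrt(features.area / (np.pi * aspect)))
    b = aspect * a
    u_grid = np.linspace(-1, 1, 2001)
    half_height = float(_blade_half_width(u_grid, b, s).max())

    width_cm = 2 * a + 2 * margin_cm
    height_cm = 2 * half_height + 2 * margin_cm
    if canvas_cm is not None:
        want_w, want_h = canvas_cm
        if 2 * a > want_w or 2 * half_height > want_h:
            raise CanvasOverflowError(
                f"blade {2*a:.1f} x {2*half_height:.1f} cm exceeds canvas "
                f"{want_w:.1f} x {want_h:.1f} cm"
            )
        width_cm, height_cm = want_w, want_h

    n_cols = int(round(width_cm * px_per_cm))
    n_rows = int(round(height_cm * px_per_cm))
    cols = (np.arange(n_cols) + 0.5) / px_per_cm - width_cm / 2.0
    rows = (np.arange(n_rows) + 0.5) / px_per_cm - height_cm / 2.0
    u = cols / a
    w_u = _blade_half_width(u, b, s)
    w_u[np.abs(u) > 1] = -1.0
    mask = np.abs(rows)[:, None] <= w_u[None, :]

    rng = np.random.default_rng(seed)
    img = np.full(mask.shape, 250, dtype=np.int16)
    texture = rng.integers(0, 25, size=mask.shape, dtype=np.int16)
    img[mask] = 30 + texture[mask]
    pixels = img.astype(np.uint8)

    n_fg = int(mask.sum())
    coords = np.argwhere(mask).astype(float)
    t = coords[:, 1] - coords[:, 1].mean()
    var = float(np.mean(t**2))
    true_skew = float(np.mean(t**3) / var**1.5) if var > 0 else 0.0
    ground_truth = {
        "mask": mask,
        "area_cm2": n_fg / px_per_cm**2,
        "perimeter_cm": _analytic_perimeter(a, b, s),
        "skewness": true_skew,
        "taper": s,
        "semi_axes_cm": (a, b),
        "requested": {
            "area_cm2": features.area,
            "skewness": features.skewness,
        },
    }
    return LeafImage(pixels, px_per_cm, ground_truth=ground_truth)


def save_leaf_image(image: LeafImage, path) -> None:
    """Write the raster as 8-bit PNG plus a side-car ground-truth JSON."""
    import json
    from pathlib import Path

    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, image.pixels)
    if image.ground_truth is not None:
        gt = {k: v for k, v in image.ground_truth.items() if k != "mask"}
        gt["px_per_cm"] = image.px_per_cm
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(gt, indent=2, default=float))


def generate_library(
    spec: CultivarSpec,
    n: Optional[int] = None,
    seed: int = 0,
    n_points: int = 10,
) -> TrainingLibrary:
    """Generate a full synthetic training library for one cultivar.

    Chains feature sampling, truth-curve assignment, the drying-loop
    simulation and curve assembly; measured RWC carries additive
    Gaussian noise (sd = spec.noise_rwc_sd) clamped to [0, 100], and
    V_TRx carries noise of sd = spec.noise_v_sd.  Leaf ids embed the
    seed so libraries from different seeds never collide.
    """
    if n is None:
        n = spec.n_default
    if n < 2:
        raise InvalidArgumentError("a library needs at least 2 leaves")
    feats = sample_features(spec, n, seed)
    master = np.random.default_rng(seed)
    leaf_seeds = master.integers(0, 2**31 - 1, size=n)
    noise_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
    curves: List[CharacteristicCurve] = []
    for i, f in enumerate(feats):
        leaf = make_leaf(spec, f, int(leaf_seeds[i]))
        records = simulate_drying_loop(
            leaf, n_points, rng=noise_rng, noise_v_sd=spec.noise_v_sd
        )
        curve = assemble_curve(
            records,
            leaf.turgid_mass,
            leaf.dry_mass,
            cultivar=spec.name,
            leaf_id=f"{spec.name}-s{seed}-{i:04d}",
        )
        if spec.noise_rwc_sd > 0:
            noisy = np.clip(
                curve.rwc + noise_rng.normal(0.0, spec.noise_rwc_sd, size=len(curve)),
                0.0,
                100.0,
            )
            curve = replace(curve, rwc=noisy)
        curves.append(curve)
    manifest = {
        "cultivar": spec.name,
        "seed": int(seed),
        "n_leaves": int(n),
        "n_points": int(n_points),
        "noise_v_sd": spec.noise_v_sd,
        "noise_rwc_sd": spec.noise_rwc_sd,
    }
    return build_library(curves, feats, spec.name, manifest)
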