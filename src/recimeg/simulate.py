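"""Simulation protocols and localization metrics.

Synthetic sensor signals are generated with the direct (column-wise)
forward path, noise is built from the forward fields of randomly placed
cortical dipoles with Gaussian strengths, signal and noise are mixed to a
target power-ratio SNR, and the localization quality of the inverse
solutions is scored by peak/centroid distances and classifier-style
ROC/AUC against a tagged target region.

Note on symbols: the signal/noise mixing parameter (the convex-combination
weight) is called ``eta`` here; the regularization parameter of the inverse
operator keeps the conventional name lambda^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bem import ChargeOperator, SolverConfig
from .geometry import HeadModel, SourceSpace, TriangleMesh, face_mean_curvature
from .leadfield import direct_column
from .sensors import SensorArray

__all__ = [
    "NoiseModel",
    "MixedSignal",
    "LocalizationResult",
    "ROCResult",
    "simulate_dipole_signal",
    "build_noise_model",
    "sample_noise",
    "mix_to_snr",
    "localize",
    "tag_target_region",
    "roc_auc",
    "error_map",
]


@dataclass
class NoiseModel:
    """Forward fields of K random normally-oriented cortical dipoles."""

    noise_leadfield: np.ndarray     # (M, K)
    dipole_positions: np.ndarray    # (K, 3)
    source_indices: np.ndarray      # (K,) indices into the source space
    seed: int

    @property
    def n_dipoles(self) -> int:
        return self.noise_leadfield.shape[1]


@dataclass
class MixedSignal:
    signal: np.ndarray
    eta: float                      # mixing weight in [0, 1)
    achieved_snr: float


@dataclass
class LocalizationResult:
    peak_position: np.ndarray
    centroid_position: np.ndarray
    threshold: float
    peak_distance: float
    centroid_distance: float
    region: np.ndarray = field(default=None, repr=False)  # above-threshold indices


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def simulate_dipole_signal(
    head: HeadModel,
    sensors: SensorArray,
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    config: SolverConfig | None = None,
    operator: ChargeOperator | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Sensor vector of a single dipole via the direct forward path."""
    b = direct_column(head, dipole_position, dipole_moment, sensors,
                      config=config, operator=operator)
    if normalize:
        nb = np.linalg.norm(b)
        if nb == 0:
            raise ValueError("zero forward field cannot be normalized")
        b = b / nb
    return b


def build_noise_model(
    head: HeadModel,
    sensors: SensorArray,
    source_space: SourceSpace,
    K: int = 2000,
    seed: int = 0,
    dipole_moment: float = 1e-8,
    config: SolverConfig | None = None,
    operator: ChargeOperator | None = None,
) -> NoiseModel:
    """Direct forward fields of K area-weighted random cortical dipoles.

    Dipoles sit at source-space positions (mid-surface convention is the
    caller's choice of source space) oriented along the source normals; the
    columns are direct forward solutions, reproducible for a fixed seed.
    """
    if K < 2:
        raise ValueError("need at least 2 noise dipoles")
    if K > source_space.n_sources:
        raise ValueError("K exceeds the number of candidate faces")
    rng = np.random.default_rng(seed)
    p = source_space.areas / source_space.areas.sum()
    idx = rng.choice(source_space.n_sources, size=K, replace=False, p=p)
    op = operator or ChargeOperator(head, config)
    cols = np.empty((len(sensors), K))
    for k, j in enumerate(idx):
        cols[:, k] = direct_column(
            head, source_space.positions[j],
            dipole_moment * source_space.normals[j], sensors, operator=op)
    return NoiseModel(cols, source_space.positions[idx], idx, seed)


def sample_noise(model: NoiseModel, seed: int, forbid: int | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Unit-norm noise vector eps = L X / ||L X||, X ~ N(0, 1) per dipole.

    ``forbid`` zeroes the strength of one noise dipole (used by error maps
    so the noise never feeds the probed source itself).
    """
    if model.n_dipoles == 0:
        raise ValueError("empty noise model")
    rng = rng or np.random.default_rng(seed)
    for _ in range(100):
        x = rng.standard_normal(model.n_dipoles)
        if forbid is not None:
            x[forbid] = 0.0
        eps = model.noise_leadfield @ x
        n = np.linalg.norm(eps)
        if n > 0:
            return eps / n
    raise RuntimeError("degenerate noise model: all draws map to zero")


def _snr_of(eta: float, b: np.ndarray, eps: np.ndarray) -> float:
    noise = (1.0 - eta) * eps
    return float(np.std(noise + eta * b) / np.std(noise))


def mix_to_snr(b: np.ndarray, eps: np.ndarray, snr_target: float,
               tol: float = 1e-3) -> MixedSignal:
    """Mix unit signal and unit noise, (1-eta) eps + eta b, to a target SNR.

    The power-ratio SNR equals 1 at eta = 0 and diverges as eta -> 1; the
    mixing weight is found by bisection to a 0.1% relative tolerance.
    Targets below 1 are unreachable in this parameterization.
    """
    if snr_target < 1:
        raise ValueError("snr_target below 1 is unreachable (SNR(0) = 1)")
    if snr_target == 1.0:
        return MixedSignal(eps.copy(), 0.0, 1.0)
    lo, hi = 0.0, 1.0 - 1e-12
    # expand: SNR is monotone increasing in eta for unit b, eps
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        s = _snr_of(mid, b, eps)
        if abs(s - snr_target) / snr_target <= tol:
            return MixedSignal((1 - mid) * eps + mid * b, mid, s)
        if s < snr_target:
            lo = mid
        else:
            hi = mid
    return MixedSignal((1 - mid) * eps + mid * b, mid, s)


def localize(strengths: np.ndarray, source_space: SourceSpace,
             true_position: np.ndarray, threshold: float = 0.75,
             area_weighted: bool = False) -> LocalizationResult:
    """Peak and thresholded-region centroid distances to the true source.

    The region is every source with |x| >= threshold * max|x|; the centroid
    is the unweighted arithmetic mean of region positions (area weighting by
    flag).  Strength magnitudes are used, since fixed-orientation estimates
    are signed.
    """
    s = np.abs(np.asarray(strengths, dtype=float))
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if np.all(s == 0):
        raise ValueError("cannot localize an identically zero estimate")
    peak = int(np.argmax(s))
    region = np.nonzero(s >= threshold * s[peak])[0]
    pos = source_space.positions[region]
    if area_weighted:
        w = source_space.areas[region]
        centroid = (pos * w[:, None]).sum(axis=0) / w.sum()
    else:
        centroid = pos.mean(axis=0)
    true_position = np.asarray(true_position, dtype=float)
    return LocalizationResult(
        peak_position=source_space.positions[peak],
        centroid_position=centroid,
        threshold=threshold,
        peak_distance=float(np.linalg.norm(source_space.positions[peak] - true_position)),
        centroid_distance=float(np.linalg.norm(centroid - true_position)),
        region=region,
    )


def tag_target_region(mesh: TriangleMesh, seed_point: np.ndarray,
                      curvature_threshold: float = 0.0,
                      area_fraction: float = 0.4) -> np.ndarray:
    """Boolean face mask of a sulcal target region around a seed point.

    Candidate faces are those with discrete mean curvature below the
    threshold (valleys); the mask keeps candidates within the smallest
    radius of the seed point whose cumulative area reaches
    ``area_fraction`` of the total candidate area.
    """
    if not (0 < area_fraction <= 1):
        raise ValueError("area_fraction must lie in (0, 1]")
    H = face_mean_curvature(mesh)
    candidates = H < curvature_threshold
    if not np.any(candidates):
        raise ValueError("no faces below the curvature threshold")
    idx = np.nonzero(candidates)[0]
    d = np.linalg.norm(mesh.face_centers[idx] - np.asarray(seed_point, float), axis=1)
    order = np.argsort(d)
    areas = mesh.face_areas[idx][order]
    target_area = area_fraction * areas.sum()
    cum = np.cumsum(areas)
    n_keep = int(np.searchsorted(cum, target_area) + 1)
    mask = np.zeros(mesh.n_faces, dtype=bool)
    mask[idx[order[:n_keep]]] = True
    return mask


def roc_auc(strengths: np.ndarray, target_mask: np.ndarray) -> ROCResult:
    """ROC curve and AUC of a source map against a target region.

    Sources with normalized strength strictly above a threshold are
    positives; the threshold sweeps 0..100% of the maximum strength (all
    distinct strength values are visited, so the curve is exact).
    """
    s = np.abs(np.asarray(strengths, dtype=float))
    mask = np.asarray(target_mask, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("target mask must contain both positives and negatives")
    smax = s.max()
    if smax == 0:
        raise ValueError("all-zero strengths")
    s = s / smax
    thr = np.concatenate([[ -np.inf ], np.unique(s), [np.inf]])
    P, Nn = mask.sum(), (~mask).sum()
    tpr = np.array([(s[mask] > t).sum() / P for t in thr])
    fpr = np.array([(s[~mask] > t).sum() / Nn for t in thr])
    order = np.lexsort((tpr, fpr))
    fpr_s, tpr_s = fpr[order], tpr[order]
    auc = float(np.trapezoid(tpr_s, fpr_s))
    return ROCResult(thr, fpr, tpr, auc)


def error_map(
    noise_model: NoiseModel,
    inverse_apply,
    source_space: SourceSpace,
    noise_level: float,
    n_samples: int = 100,
    seed: int = 0,
    dipole_subset: np.ndarray | None = None,
    threshold: float = 0.75,
) -> dict:
    """Per-dipole localization-error statistics at a fixed noise level.

    For each probed dipole j the signal is mixed as
    (1 - eta0) b_j + eta0 eps with b_j the unit-normalized forward field of
    dipole j (a column of the noise model) and eps a unit noise draw with
    the j-th strength forced to zero.  ``inverse_apply`` maps a sensor
    vector to per-source strengths.  Returns per-dipole mean/std of
    centroid and peak distances, reproducible for a fixed seed.
    """
    if not (0 <= noise_level < 1):
        raise ValueError("noise level must lie in [0, 1)")
    subset = np.arange(noise_model.n_dipoles) if dipole_subset is None else np.asarray(dipole_subset)
    rng = np.random.default_rng(seed)
    stats = {k: np.empty(len(subset)) for k in
             ("centroid_mean", "centroid_std", "peak_mean", "peak_std")}
    for row, k in enumerate(subset):
        b = noise_model.noise_leadfield[:, k]
        b = b / np.linalg.norm(b)
        true_pos = noise_model.dipole_positions[k]
        cd, pd = [], []
        n_draw = 1 if noise_level == 0 else n_samples
        for _ in range(n_draw):
            if noise_level == 0:
                sig = b
            else:
                eps = sample_noise(noise_model, 0, forbid=int(k), rng=rng)
                sig = (1 - noise_level) * b + noise_level * eps
            x = inverse_apply(sig)
            loc = localize(x, source_space, true_pos, threshold=threshold)
            cd.append(loc.centroid_distance)
            pd.append(loc.peak_distance)
        stats["centroid_mean"][row] = np.mean(cd)
        stats["centroid_std"][row] = np.std(cd)
        stats["peak_mean"][row] = np.mean(pd)
        stats["peak_std"][row] = np.std(pd)
    stats["dipole_indices"] = subset
    stats["noise_level"] = noise_level
    stats["seed"] = seed
    return stats
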