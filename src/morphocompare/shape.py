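"""Generalized Procrustes superimposition and size correction for landmarks.

The geometric methods remove position, scale and orientation by an iterative
generalized Procrustes analysis (GPA): every configuration is centred, scaled
to unit centroid size and rotated to the current consensus by orthogonal
least squares; the consensus is re-estimated until it stabilizes.  Aligned
shapes are then orthogonally projected onto the tangent plane at the
consensus so that subsequent statistics can be linear.

Centroid size CS is computed on the raw input coordinates; the remaining
allometric signal (shape change with size) is removed by ordinary least
squares regression of every aligned coordinate on log CS within pooling
groups (per species by default), and all downstream analyses run on the
residuals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import LandmarkDataset


class DegenerateSpecimenError(ValueError):
    """All landmarks of a specimen coincide (zero centroid size)."""


class ConvergenceError(RuntimeError):
    """GPA failed to converge within the iteration budget."""


@dataclass
class ProcrustesResult:
    """Output of a generalized Procrustes fit.

    ``aligned`` holds tangent-projected shape coordinates (n x 2K, flattened
    x1,y1..xK,yK); ``rotated`` the pre-projection unit-centroid-size aligned
    configurations (n x K x 2); ``mean_shape`` the consensus (K x 2, unit
    centroid size).
    """

    labels: pd.DataFrame
    aligned: np.ndarray
    rotated: np.ndarray
    centroid_size: np.ndarray
    mean_shape: np.ndarray
    landmark_names: list[str]
    n_iterations: int
    objective_history: list[float] = field(default_factory=list)

    @property
    def logCS(self) -> np.ndarray:
        return np.log(self.centroid_size)

    def aligned_frame(self) -> pd.DataFrame:
        cols = []
        for name in self.landmark_names:
            cols += [f"{name}_x", f"{name}_y"]
        return pd.concat(
            [self.labels, pd.DataFrame(self.aligned, columns=cols)], axis=1)


def _best_rotations(X: np.ndarray, mean: np.ndarray,
                    allow_reflection: bool) -> np.ndarray:
    """Optimal 2-D orthogonal alignment of each configuration to the mean.

    For planar data the rotation maximizing tr(R'S), S = X_i' M, has the
    closed form theta = atan2(S10 - S01, S00 + S11); the best reflection is
    compared only when reflections are allowed.
    """
    S = np.einsum("nki,kj->nij", X, mean)  # (n, 2, 2)
    a = S[:, 0, 0] + S[:, 1, 1]
    b = S[:, 1, 0] - S[:, 0, 1]
    rot_gain = np.hypot(a, b)
    theta = np.arctan2(b, a)
    c, s = np.cos(theta), np.sin(theta)
    R = np.empty((X.shape[0], 2, 2))
    R[:, 0, 0], R[:, 0, 1] = c, -s
    R[:, 1, 0], R[:, 1, 1] = s, c
    if allow_reflection:
        ar = S[:, 0, 0] - S[:, 1, 1]
        br = S[:, 0, 1] + S[:, 1, 0]
        ref_gain = np.hypot(ar, br)
        phi = np.arctan2(br, ar)
        use_ref = ref_gain > rot_gain
        cr, sr = np.cos(phi), np.sin(phi)
        R[use_ref, 0, 0], R[use_ref, 0, 1] = cr[use_ref], sr[use_ref]
        R[use_ref, 1, 0], R[use_ref, 1, 1] = sr[use_ref], -cr[use_ref]
    return R


def _canonical_rotation(mean: np.ndarray) -> np.ndarray:
    """Proper rotation putting the consensus into a canonical orientation.

    Aligns the consensus' major principal axis with x (making the overall
    fit invariant to a common rotation of the input) and resolves the
    remaining 180-degree ambiguity by requiring the first landmark to have
    non-negative x.
    """
    cov = mean.T @ mean
    evals, evecs = np.linalg.eigh(cov)
    R = evecs[:, ::-1]  # columns: major, minor axis
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    m = mean @ R
    if m[0, 0] < 0:
        R = -R  # 180-degree rotation (proper in 2-D)
    return R


def procrustes_fit(data: LandmarkDataset, allow_reflection: bool = False,
                   tol: float = 1e-8, max_iter: int = 100) -> ProcrustesResult:
    """Iterative GPA with unit-centroid-size scaling and tangent projection.

    Raises :class:`DegenerateSpecimenError` naming the specimen if any
    configuration has zero centroid size, and :class:`ConvergenceError` with
    the final consensus change if ``max_iter`` is exhausted.
    """
    if data.n_records < 2:
        raise ValueError("GPA needs at least two specimens")
    if data.n_landmarks < 3:
        raise ValueError("GPA needs at least three landmarks")
    X = data.coords.astype(float).copy()
    X -= X.mean(axis=1, keepdims=True)
    cs = np.sqrt((X ** 2).sum(axis=(1, 2)))
    if (cs < 1e-12).any():
        bad = data.labels.iloc[int(np.argmin(cs))]
        raise DegenerateSpecimenError(
            "zero centroid size (all landmarks coincident) for specimen "
            f"{bad['individual']} (measurer {bad['measurer']}, repeat {bad['repeat']})")
    X /= cs[:, None, None]

    mean = X[0] / np.sqrt((X[0] ** 2).sum())
    history: list[float] = []
    n_iter = 0
    converged = False
    change = np.inf
    for n_iter in range(1, max_iter + 1):
        R = _best_rotations(X, mean, allow_reflection)
        X = np.einsum("nki,nij->nkj", X, R)
        history.append(float(((X - mean) ** 2).sum()))
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean ** 2).sum())
        change = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if change < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(final consensus change {change:.3e})")

    # final alignment to the converged consensus, then canonical orientation
    R = _best_rotations(X, mean, allow_reflection)
    X = np.einsum("nki,nij->nkj", X, R)
    C = _canonical_rotation(mean)
    X = X @ C
    mean = mean @ C

    # orthogonal projection onto the tangent plane at the consensus
    m = mean.reshape(-1)
    flat = X.reshape(X.shape[0], -1)
    aligned = m + (flat - (flat @ m)[:, None] * m)

    return ProcrustesResult(
        labels=data.labels.copy(), aligned=aligned, rotated=X,
        centroid_size=cs, mean_shape=mean,
        landmark_names=list(data.landmark_names),
        n_iterations=n_iter, objective_history=history)


@dataclass
class ShapeResiduals:
    """Residual shape variables from the shape ~ logCS regression.

    ``variables`` has one row per specimen record and 2K residual columns;
    ``slopes``/``intercepts`` map each pooling group to its 2K regression
    coefficients.
    """

    labels: pd.DataFrame
    variables: pd.DataFrame
    slopes: dict[tuple, np.ndarray]
    intercepts: dict[tuple, np.ndarray]
    pooling: tuple[str, ...]

    @property
    def values(self) -> np.ndarray:
        return self.variables.to_numpy(float)


def regress_out_size(fit: ProcrustesResult,
                     pooling: tuple[str, ...] | str = ("species",),
                     strict: bool = False) -> ShapeResiduals:
    """OLS of each tangent coordinate on logCS within pooling groups.

    Within a group with (numerically) constant logCS the slope is set to
    zero and a warning is emitted (an error in ``strict`` mode); residuals
    are then simply the centred aligned shapes.
    """
    if isinstance(pooling, str):
        pooling = (pooling,)
    pooling = tuple(pooling)
    labels = fit.labels
    z = fit.logCS
    Y = fit.aligned
    resid = np.empty_like(Y)
    slopes: dict[tuple, np.ndarray] = {}
    intercepts: dict[tuple, np.ndarray] = {}
    if pooling:
        grouped = labels.groupby(list(pooling), sort=True).indices.items()
    else:
        grouped = [((), np.arange(len(labels)))]
    for key, idx in grouped:
        key = key if isinstance(key, tuple) else (key,)
        idx = np.asarray(idx)
        if len(idx) < 3:
            raise ValueError(f"pooling group {key} has fewer than 3 specimens")
        zg = z[idx]
        Yg = Y[idx]
        zc = zg - zg.mean()
        denom = (zc ** 2).sum()
        if denom < 1e-12 * max(1.0, zg.mean() ** 2):
            msg = f"logCS is constant within pooling group {key}; slope set to 0"
            if strict:
                raise np.linalg.LinAlgError(msg)
            warnings.warn(msg, stacklevel=2)
            slope = np.zeros(Y.shape[1])
        else:
            slope = zc @ (Yg - Yg.mean(axis=0)) / denom
        intercept = Yg.mean(axis=0) - slope * zg.mean()
        slopes[key] = slope
        intercepts[key] = intercept
        resid[idx] = Yg - (intercept + np.outer(zg, slope))
    cols = []
    for name in fit.landmark_names:
        cols += [f"{name}_x", f"{name}_y"]
    return ShapeResiduals(labels=labels.copy(),
                          variables=pd.DataFrame(resid, columns=cols),
                          slopes=slopes, intercepts=intercepts, pooling=pooling)
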