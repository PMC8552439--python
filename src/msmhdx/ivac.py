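"""Integrated VAC (IVAC): slow collective modes from a lag-time range.

Plain VAC/tICA solves C(tau) v = lambda C(0) v at one lag. IVAC instead sums
the symmetrized time-lagged covariance matrices over a range of lags,
C_int = sum_{tau=lag_min}^{lag_max} C(tau), and solves the generalized
symmetric eigenproblem C_int v = lambda C(0) v, which is far less sensitive
to the choice of lag. Time-lagged pairs never straddle trajectory boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.stats

from .trajectory import FeatureMatrix

__all__ = [
    "TICModel",
    "fit_ivac",
    "project",
    "select_seeds",
    "spectral_gap",
    "leading_subspace_angles",
]

_COND_LIMIT = 1e12
_RIDGE_SCALE = 1e-10


@dataclass
class TICModel:
    """Fitted IVAC model.

    Eigenvalues are the integrated generalized eigenvalues, sorted
    descending; eigenvector columns are normalized under the covariance
    metric (v^T C(0) v = 1).
    """

    lag_min: int
    lag_max: int
    stride: int
    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_frames_used: int

    @property
    def n_features(self) -> int:
        return len(self.mean)

    def lags(self) -> np.ndarray:
        return np.arange(self.lag_min, self.lag_max + 1, self.stride)


def _as_blocks(features) -> list[np.ndarray]:
    if isinstance(features, FeatureMatrix):
        return features.split()
    if isinstance(features, np.ndarray):
        return [np.asarray(features, dtype=float)]
    blocks = []
    for f in features:
        if isinstance(f, FeatureMatrix):
            blocks.extend(f.split())
        else:
            blocks.append(np.asarray(f, dtype=float))
    return blocks


def fit_ivac(features, lag_min: int, lag_max: int, stride: int = 1) -> TICModel:
    """Fit IVAC on one or more feature matrices.

    ``features`` may be a FeatureMatrix, a 2-D array, or a list of either;
    each block is treated as one contiguous trajectory. Lags are in frames.
    ``stride`` thins the lag schedule inside [lag_min, lag_max].
    """
    if lag_min < 1 or lag_min > lag_max:
        raise ValueError("require 1 <= lag_min <= lag_max")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    blocks = _as_blocks(features)
    d = blocks[0].shape[1]
    for t, b in enumerate(blocks):
        if b.shape[1] != d:
            raise ValueError("all trajectories must share one feature dimension")
        if len(b) <= lag_max:
            raise ValueError(
                f"trajectory {t} has {len(b)} frames, shorter than "
                f"lag_max={lag_max}"
            )

    n_total = sum(len(b) for b in blocks)
    mean = sum(b.sum(axis=0) for b in blocks) / n_total
    centered = [b - mean for b in blocks]

    c0 = np.zeros((d, d))
    for x in centered:
        c0 += x.T @ x
    c0 /= n_total

    lags = np.arange(lag_min, lag_max + 1, stride)
    c_int = np.zeros((d, d))
    for tau in lags:
        ct = np.zeros((d, d))
        n_pairs = 0
        for x in centered:
            ct += x[:-tau].T @ x[tau:]
            n_pairs += len(x) - tau
        ct /= n_pairs
        c_int += 0.5 * (ct + ct.T)

    cond = np.linalg.cond(c0)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        c0 = c0 + (_RIDGE_SCALE * np.trace(c0) / d) * np.eye(d)
    try:
        evals, evecs = scipy.linalg.eigh(c_int, c0)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "instantaneous covariance C(0) is singular; remove "
            "constant/duplicate features or increase the ridge regularization"
        ) from exc
    order = np.argsort(evals)[::-1]
    return TICModel(
        lag_min=int(lag_min),
        lag_max=int(lag_max),
        stride=int(stride),
        mean=mean,
        eigenvalues=evals[order],
        eigenvectors=evecs[:, order],
        n_frames_used=n_total,
    )


def project(model: TICModel, features, n_components: int | None = None) -> np.ndarray:
    """Project (frames x d) features onto the leading tICs: (x - mean) . v_i."""
    if isinstance(features, FeatureMatrix):
        x = features.values
    else:
        x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model "
            f"({model.n_features})"
        )
    if n_components is None:
        n_components = model.n_features
    y = (x - model.mean) @ model.eigenvectors[:, :n_components]
    return y[0] if single else y


def select_seeds(
    projected: np.ndarray,
    n_seeds: int = 14,
    bandwidth: float = 0.0,
    seed: int = 0,
    max_kde_samples: int = 20000,
) -> np.ndarray:
    """Frames of lowest estimated density in tIC space, for re-seeding sampling.

    Density is a Gaussian kernel estimate (Scott's rule) fitted on at most
    ``max_kde_samples`` frames (subsampled deterministically from ``seed``)
    and evaluated at every frame. Seeds are chosen greedily from the lowest
    density upward, each at least ``bandwidth`` (Euclidean, tIC units) from
    the ones already chosen; ties are broken by the lowest frame index.
    """
    x = np.atleast_2d(np.asarray(projected, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and projected.ndim == 1:
        x = x.T
    n = len(x)
    if n_seeds < 1:
        raise ValueError("n_seeds must be positive")
    if n_seeds > n:
        raise ValueError(f"n_seeds={n_seeds} exceeds {n} frames")

    rng = np.random.default_rng(seed)
    if n > max_kde_samples:
        fit_idx = np.sort(rng.choice(n, size=max_kde_samples, replace=False))
    else:
        fit_idx = np.arange(n)
    kde = scipy.stats.gaussian_kde(x[fit_idx].T)
    density = np.empty(n)
    chunk = 100000
    for start in range(0, n, chunk):
        density[start : start + chunk] = kde(x[start : start + chunk].T)

    order = np.lexsort((np.arange(n), density))  # density asc, index breaks ties
    chosen: list[int] = []
    for i in order:
        if len(chosen) == n_seeds:
            break
        if bandwidth > 0 and chosen:
            dmin = np.min(np.linalg.norm(x[chosen] - x[i], axis=1))
            if dmin < bandwidth:
                continue
        chosen.append(int(i))
    if len(chosen) < n_seeds:
        raise ValueError(
            f"only {len(chosen)} frames satisfy the {bandwidth} separation "
            f"constraint; requested {n_seeds}"
        )
    return np.array(chosen, dtype=int)


def spectral_gap(eigenvalues: np.ndarray) -> int:
    """Index g of the largest drop in a descending spectrum (retain first g).

    For eigenvalues (l_1 >= l_2 >= ...), returns argmax_i (l_i - l_{i+1}),
    one-based, i.e. the number of components before the largest gap.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.ndim != 1 or len(ev) < 3:
        raise ValueError("need at least 3 eigenvalues")
    diffs = ev[:-1] - ev[1:]
    if np.all(np.abs(diffs) < 1e-15):
        raise ValueError("no gap: constant spectrum")
    return int(np.argmax(diffs)) + 1


def leading_subspace_angles(
    model_a: TICModel, model_b: TICModel, n_components: int
) -> np.ndarray:
    """Principal angles (radians) between the leading tIC subspaces of two fits.

    Used for the lag-range robustness check: models fitted on the same data
    with different lag ranges should span nearly the same slow subspace.
    """
    va = model_a.eigenvectors[:, :n_components]
    vb = model_b.eigenvectors[:, :n_components]
    return scipy.linalg.subspace_angles(va, vb)
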