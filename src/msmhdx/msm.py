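"""Microstate clustering, Markov-state-model estimation and validation.

Frames are clustered in tIC space with k-means, a transition matrix is
estimated at a fixed lag by sliding-window counting inside each trajectory,
and frames are given equilibrium weights pi_s / n_s so that averages over
frames reproduce the stationary ensemble ("physically weighted" statistics).
The default count estimator symmetrizes the count matrix, which guarantees a
real spectrum and detailed balance — the assumptions PCCA rests on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

logger = logging.getLogger(__name__)

__all__ = [
    "MicrostateModel",
    "MarkovModel",
    "kmeans_cluster",
    "estimate_msm",
    "implied_timescales",
    "ck_test",
    "frame_weights",
]


def _as_blocks(data) -> list[np.ndarray]:
    if isinstance(data, np.ndarray) and data.ndim <= 2:
        return [np.asarray(data)]
    return [np.asarray(b) for b in data]


@dataclass
class MicrostateModel:
    """k-means discretization of projected data."""

    centers: np.ndarray
    assignments: list[np.ndarray]  # per trajectory, microstate index per frame
    k: int
    seed: int
    inertia: float

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.assignments)


def kmeans_cluster(
    projected,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    n_init: int = 1,
) -> MicrostateModel:
    """Cluster projected frames into k microstates (Lloyd + k-means++ init).

    ``projected`` is a (frames x g) array or a list of per-trajectory arrays.
    Deterministic for a fixed seed. Final assignments are recomputed as the
    nearest center so the nearest-center invariant holds exactly.
    """
    blocks = [np.atleast_2d(b.T).T if b.ndim == 1 else b for b in _as_blocks(projected)]
    x = np.concatenate(blocks, axis=0)
    if k > len(x):
        raise ValueError(f"k={k} exceeds the number of frames ({len(x)})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed,
    ).fit(x)
    labels = pairwise_distances_argmin(x, km.cluster_centers_)
    assignments, start = [], 0
    for b in blocks:
        assignments.append(labels[start : start + len(b)].astype(np.int64))
        start += len(b)
    return MicrostateModel(
        centers=km.cluster_centers_,
        assignments=assignments,
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


@dataclass
class MarkovModel:
    """Estimated MSM on the largest strongly connected microstate set.

    ``transition_matrix``, ``stationary`` and the spectrum live on the
    connected set; ``connected_set`` maps its rows back to original
    microstate indices.
    """

    lag: int
    count_matrix: np.ndarray
    transition_matrix: np.ndarray
    stationary: np.ndarray
    eigenvalues: np.ndarray
    left_eigenvectors: np.ndarray
    right_eigenvectors: np.ndarray
    connected_set: np.ndarray
    mode: str = "symmetrized"

    @property
    def n_states(self) -> int:
        return len(self.transition_matrix)

    def state_map(self, n_total: int | None = None) -> np.ndarray:
        """original microstate index -> row in the connected model (-1 if dropped)."""
        n_total = n_total if n_total is not None else len(self.count_matrix)
        m = np.full(n_total, -1, dtype=np.int64)
        m[self.connected_set] = np.arange(len(self.connected_set))
        return m

    @classmethod
    def from_transition_matrix(cls, T: np.ndarray, lag: int = 1) -> "MarkovModel":
        """Wrap an explicit row-stochastic matrix (useful for analytic tests).

        The stationary vector comes from the left eigenvector of eigenvalue
        1 (absolute value taken, so it stays nonnegative even when the
        eigenvalue is degenerate for reducible chains), polished by a few
        fixed-point sweeps.
        """
        T = np.asarray(T, dtype=float)
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows must sum to 1")
        n = len(T)
        evals_l, evecs_l = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(evals_l - 1.0)))
        pi = np.abs(np.real(evecs_l[:, i]))
        pi /= pi.sum()
        for _ in range(50):
            nxt = pi @ T
            nxt /= nxt.sum()
            if np.max(np.abs(nxt - pi)) < 1e-16:
                pi = nxt
                break
            pi = nxt
        evals, levec, revec = _sorted_spectrum(T, pi)
        return cls(
            lag=lag,
            count_matrix=T.copy(),
            transition_matrix=T,
            stationary=pi,
            eigenvalues=evals,
            left_eigenvectors=levec,
            right_eigenvectors=revec,
            connected_set=np.arange(n),
            mode="explicit",
        )


def _sorted_spectrum(T: np.ndarray, pi: np.ndarray | None):
    """Eigen-decomposition of T, sorted by descending real part / magnitude.

    If ``pi`` satisfies detailed balance the symmetric similarity transform
    is used, giving an exactly real spectrum.
    """
    if pi is not None and np.all(pi > 0):
        flux = pi[:, None] * T
        if np.allclose(flux, flux.T, atol=1e-10):
            sq = np.sqrt(pi)
            s = (T * sq[:, None]) / sq[None, :]
            s = 0.5 * (s + s.T)
            evals, v = np.linalg.eigh(s)
            order = np.argsort(evals)[::-1]
            evals, v = evals[order], v[:, order]
            right = v / sq[:, None]
            left = v * sq[:, None]
            # normalize: right eigvec for lambda=1 constant 1, left sums to pi
            return evals, left, right
    evals, levec, revec = scipy.linalg.eig(T, left=True, right=True)
    order = np.argsort(-np.abs(evals))
    evals = evals[order]
    levec, revec = levec[:, order], revec[:, order]
    if np.max(np.abs(evals.imag)) < 1e-10:
        evals = evals.real
        levec, revec = levec.real, revec.real
    return evals, levec, revec


def count_transitions(assignments, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag, per trajectory."""
    blocks = _as_blocks(assignments)
    if n_states is None:
        n_states = int(max(b.max() for b in blocks if len(b))) + 1
    C = np.zeros((n_states, n_states))
    counted = False
    for b in blocks:
        if len(b) > lag:
            np.add.at(C, (b[:-lag], b[lag:]), 1.0)
            counted = True
    if not counted:
        raise ValueError(f"no trajectory is longer than lag={lag}")
    return C


def estimate_msm(
    assignments,
    lag: int,
    mode: str = "symmetrized",
    n_states: int | None = None,
) -> MarkovModel:
    """Estimate a Markov state model at the given lag (frames).

    mode="symmetrized" replaces the counts with (C + C^T)/2 before row
    normalization, enforcing detailed balance; mode="naive" row-normalizes
    the raw counts. The model is restricted to the largest strongly
    connected set (weighted by counts); dropped states are logged.
    """
    if mode not in ("symmetrized", "naive"):
        raise ValueError(f"unknown count mode {mode!r}")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    C = count_transitions(assignments, lag, n_states)
    C_eff = 0.5 * (C + C.T) if mode == "symmetrized" else C

    n_comp, labels = connected_components(
        csr_matrix(C_eff > 0), connection="strong"
    )
    best, best_weight = -1, -1.0
    for c in range(n_comp):
        members = labels == c
        w = C_eff[members].sum()
        if w > best_weight:
            best, best_weight = c, w
    cs = np.flatnonzero(labels == best)
    if best_weight <= 0 or len(cs) == 0:
        raise ValueError("empty connected set: no transitions observed")
    dropped = np.flatnonzero(labels != best)
    if len(dropped):
        logger.info(
            "MSM: dropped %d microstates outside the largest connected set",
            len(dropped),
        )

    Ccs = C_eff[np.ix_(cs, cs)]
    rows = Ccs.sum(axis=1)
    if np.any(rows <= 0):
        raise ValueError("empty connected set: a retained state has no counts")
    T = Ccs / rows[:, None]

    if mode == "symmetrized":
        pi = rows / rows.sum()  # exact stationary vector of the reversible T
    else:
        evals, evecs = scipy.linalg.eig(T.T, right=True)
        i = int(np.argmin(np.abs(evals - 1.0)))
        pi = np.abs(np.real(evecs[:, i]))
        pi /= pi.sum()
    evals, levec, revec = _sorted_spectrum(T, pi if mode == "symmetrized" else None)
    return MarkovModel(
        lag=int(lag),
        count_matrix=C,
        transition_matrix=T,
        stationary=pi,
        eigenvalues=evals,
        left_eigenvectors=levec,
        right_eigenvectors=revec,
        connected_set=cs,
        mode=mode,
    )


def implied_timescales(model: MarkovModel, n: int | None = None) -> np.ndarray:
    """t_i = -lag / ln(lambda_{i+1}) for the nontrivial eigenvalues, descending.

    Eigenvalues >= 1 give infinite timescales; eigenvalues <= 0 have no
    defined relaxation time and are reported as NaN.
    """
    evals = np.real(model.eigenvalues)
    nontrivial = evals[1:]
    if n is not None:
        if n > len(nontrivial):
            raise ValueError(f"model has only {len(nontrivial)} nontrivial eigenvalues")
        nontrivial = nontrivial[:n]
    out = np.empty(len(nontrivial))
    for i, lam in enumerate(nontrivial):
        if lam >= 1.0:
            out[i] = np.inf
        elif lam <= 0.0:
            out[i] = np.nan
        else:
            out[i] = -model.lag / np.log(lam)
    return out


def frame_weights(model: MarkovModel, assignments) -> np.ndarray:
    """Equilibrium weight per frame: pi_s / (frames assigned to s).

    Frames in microstates outside the connected set get weight 0 (their
    count is logged); retained weights sum to 1. Returns one flat array over
    all frames, in trajectory order.
    """
    labels = np.concatenate(_as_blocks(assignments))
    n_total = len(model.count_matrix)
    smap = model.state_map(max(n_total, int(labels.max()) + 1))
    mapped = smap[labels]
    w = np.zeros(len(labels))
    counts = np.bincount(mapped[mapped >= 0], minlength=model.n_states)
    inside = mapped >= 0
    n_out = int((~inside).sum())
    if n_out:
        logger.info("frame_weights: %d frames outside the connected set get 0", n_out)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_state = np.where(counts > 0, model.stationary / np.maximum(counts, 1), 0.0)
    w[inside] = per_state[mapped[inside]]
    total = w.sum()
    if total > 0:
        w /= total  # exact unit mass even when some states have no frames
    return w


def ck_test(
    assignments,
    macro_sets: list[np.ndarray],
    lag: int,
    factors: list[int],
    mode: str = "symmetrized",
) -> pd.DataFrame:
    """Chapman–Kolmogorov test on lumped sets.

    For each factor f, compares the set-to-set transition probabilities of
    the lag-``lag`` model propagated f steps (T(lag)^f) with a model
    re-estimated directly at lag f*lag. The standard error uses the number
    of non-overlapping windows at the long lag, a conservative binomial
    estimate for the sliding-window estimator.
    """
    if min(factors) < 1:
        raise ValueError("factors must be >= 1")
    blocks = _as_blocks(assignments)
    base = estimate_msm(blocks, lag, mode=mode)
    n_total = len(base.count_matrix)
    sets = [np.asarray(s, dtype=int) for s in macro_sets]

    base_map = base.state_map(n_total)

    def lumped(model: MarkovModel, Tpow: np.ndarray) -> np.ndarray:
        """Set-to-set probabilities, start states weighted by the base pi."""
        smap = model.state_map(n_total)
        m = len(sets)
        P = np.full((m, m), np.nan)
        for a, A in enumerate(sets):
            keep = smap[A] >= 0
            rows = smap[A][keep]
            if len(rows) == 0:
                continue
            w = np.array(
                [
                    base.stationary[base_map[o]] if base_map[o] >= 0 else 0.0
                    for o in A[keep]
                ]
            )
            if w.sum() == 0:
                w[:] = 1.0
            w /= w.sum()
            for bset, B in enumerate(sets):
                cols = smap[B][smap[B] >= 0]
                if len(cols) == 0:
                    continue
                P[a, bset] = float(w @ Tpow[np.ix_(rows, cols)].sum(axis=1))
        return P

    records = []
    for f in factors:
        long_lag = f * lag
        try:
            refit = estimate_msm(blocks, long_lag, mode=mode, n_states=n_total)
        except ValueError as exc:
            raise ValueError(
                f"insufficient data to re-estimate at lag {long_lag}: {exc}"
            ) from exc
        Tpow = np.linalg.matrix_power(base.transition_matrix, f)
        P_pred = lumped(base, Tpow)
        P_est = lumped(refit, refit.transition_matrix)

        # counts of non-overlapping windows starting in each set
        starts = np.zeros(len(sets))
        for b in blocks:
            if len(b) <= long_lag:
                continue
            strided = b[:-long_lag:long_lag]
            for a, A in enumerate(sets):
                starts[a] += np.isin(strided, A).sum()
        for a in range(len(sets)):
            for bset in range(len(sets)):
                p = P_est[a, bset]
                se = (
                    np.sqrt(max(p * (1 - p), 0.0) / starts[a])
                    if starts[a] > 0 and np.isfinite(p)
                    else np.nan
                )
                records.append(
                    {
                        "factor": f,
                        "set_from": a,
                        "set_to": bset,
                        "predicted": P_pred[a, bset],
                        "estimated": P_est[a, bset],
                        "deviation": abs(P_pred[a, bset] - P_est[a, bset]),
                        "std_error": se,
                    }
                )
    return pd.DataFrame.from_records(records)
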