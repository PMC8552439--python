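"""Perron cluster analysis: metastable macro-clusters, populations and fluxes.

The m leading right eigenvectors of a reversible transition matrix map the
microstates into an (m-1)-simplex whose vertices correspond to the
metastable sets. The robust inner-simplex construction locates those
vertices and expresses every microstate as a fuzzy membership vector; crisp
labels are the argmax. Clusters are relabeled 0..m-1 by decreasing
population (ties broken by the original label), and equilibrium fluxes
F_AB = sum_{i in A, j in B} pi_i T_ij quantify exchange between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msm import MarkovModel

__all__ = ["MacroClustering", "pcca", "macro_populations", "macro_fluxes",
           "flux_edge_list"]

_HIGHLIGHT_FRACTION = 0.25  # fluxes above this fraction of the max are flagged


@dataclass
class MacroClustering:
    """Micro-to-macro coarse graining.

    membership rows (one per microstate of the model's connected set) sum
    to 1; macro labels are ordered by decreasing population. The flux matrix
    is probability mass transported per lag step (symmetric for reversible
    models); multiply by 1/lag (in time units) to convert to rates.
    """

    m: int
    membership: np.ndarray
    crisp_labels: np.ndarray
    populations: np.ndarray
    flux_matrix: np.ndarray
    normalized_flux: np.ndarray
    highlighted: np.ndarray
    connected_set: np.ndarray

    def macro_set(self, label: int) -> np.ndarray:
        """Original microstate indices belonging to one macro-cluster."""
        return self.connected_set[self.crisp_labels == label]

    def macro_sets(self) -> list[np.ndarray]:
        return [self.macro_set(a) for a in range(self.m)]


def _inner_simplex_memberships(psi: np.ndarray) -> np.ndarray:
    """Fuzzy memberships from eigenvector rows via the inner-simplex algorithm."""
    n, m = psi.shape
    ortho = psi.copy()
    idx = np.zeros(m, dtype=int)
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - ortho[idx[0]]
    for j in range(1, m):
        v = ortho[idx[j - 1]].copy()
        nv = np.linalg.norm(v)
        if nv > 0:
            v /= nv
            ortho = ortho - np.outer(ortho @ v, v)
        idx[j] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    vertices = psi[idx]
    try:
        chi = psi @ np.linalg.inv(vertices)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "degenerate simplex vertices; too many macro-clusters requested"
        ) from exc
    chi = np.clip(chi, 0.0, None)
    rowsum = chi.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return chi / rowsum


def pcca(model: MarkovModel, m: int) -> MacroClustering:
    """Group the model's microstates into m metastable macro-clusters.

    Requires a real spectrum (use the symmetrized/reversible estimator).
    Deterministic. The returned clustering carries populations (descending)
    and the equilibrium flux matrix between clusters.
    """
    if m < 2:
        raise ValueError("need at least 2 macro-clusters")
    if m > model.n_states:
        raise ValueError(f"m={m} exceeds the {model.n_states} microstates")
    evals = model.eigenvalues[:m]
    if np.max(np.abs(np.imag(evals))) > 1e-8:
        raise ValueError(
            "complex leading eigenvalues; re-estimate the MSM with the "
            "symmetrized (reversible) estimator before PCCA"
        )
    psi = np.real(model.right_eigenvectors[:, :m]).copy()
    # fix the trivial eigenvector to a clean constant
    psi[:, 0] = 1.0

    chi = _inner_simplex_memberships(psi)
    crisp = np.argmax(chi, axis=1)

    ordered_pops, order = macro_populations(crisp, model.stationary, m=m)
    relabel = np.empty(m, dtype=int)
    relabel[order] = np.arange(m)
    crisp = relabel[crisp]
    chi = chi[:, order]

    flux, norm_flux, highlighted = _flux_matrices(crisp, model, m)
    return MacroClustering(
        m=m,
        membership=chi,
        crisp_labels=crisp,
        populations=ordered_pops,
        flux_matrix=flux,
        normalized_flux=norm_flux,
        highlighted=highlighted,
        connected_set=model.connected_set,
    )


def macro_populations(
    crisp_labels: np.ndarray, pi: np.ndarray, m: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Macro populations sorted descending, with the ordering of old labels.

    population(A) = sum_{i in A} pi_i over crisp labels. Ties are broken by
    ascending original label. Returns (populations, order) where order[k] is
    the original label ranked k-th.
    """
    crisp_labels = np.asarray(crisp_labels, dtype=int)
    pi = np.asarray(pi, dtype=float)
    if len(crisp_labels) != len(pi):
        raise ValueError("crisp labels and stationary vector length mismatch")
    if m is None:
        m = int(crisp_labels.max()) + 1
    pops = np.bincount(crisp_labels, weights=pi, minlength=m)
    order = np.lexsort((np.arange(m), -pops))
    return pops[order], order


def _flux_matrices(crisp: np.ndarray, model: MarkovModel, m: int):
    pi = model.stationary
    T = np.real(model.transition_matrix)
    F = np.zeros((m, m))
    for a in range(m):
        ia = crisp == a
        if not ia.any():
            continue
        contrib = (pi[ia, None] * T[ia]).sum(axis=0)  # mass a -> each microstate
        for b in range(m):
            if b == a:
                continue
            F[a, b] = contrib[crisp == b].sum()
    fmax = F.max()
    norm = F / fmax if fmax > 0 else np.zeros_like(F)
    highlighted = norm >= _HIGHLIGHT_FRACTION
    np.fill_diagonal(highlighted, False)
    return F, norm, highlighted


def macro_fluxes(clustering: MacroClustering, model: MarkovModel) -> np.ndarray:
    """Equilibrium probability mass per lag step between macro-clusters.

    F_AB = sum_{i in A, j in B} pi_i T_ij with zero diagonal; also refreshes
    the clustering's normalized-flux and >=25%-of-max highlight fields.
    """
    F, norm, highlighted = _flux_matrices(clustering.crisp_labels, model, clustering.m)
    clustering.flux_matrix = F
    clustering.normalized_flux = norm
    clustering.highlighted = highlighted
    return F


def flux_edge_list(clustering: MacroClustering) -> pd.DataFrame:
    """Edge list (source, target, flux, normalized flux, highlighted)."""
    rows = []
    for a in range(clustering.m):
        for b in range(clustering.m):
            if a == b:
                continue
            rows.append(
                {
                    "source": a,
                    "target": b,
                    "flux": clustering.flux_matrix[a, b],
                    "normalized_flux": clustering.normalized_flux[a, b],
                    "highlighted": bool(clustering.highlighted[a, b]),
                }
            )
    return pd.DataFrame(rows)
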