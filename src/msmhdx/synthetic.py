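"""Synthetic trajectory ensembles emitted from a hidden discrete-state Markov chain.

Each hidden state has a coordinate template for a toy peptide chain (backbone
N, H, Cα, C, O plus a side-chain oxygen per residue, and water-oxygen
pseudo-atoms). Frames are the template of the current hidden state plus iid
isotropic Gaussian noise, so slow modes, metastable populations and per-site
hydrogen-bond patterns are all known a priori. Initial states are drawn from
the stationary distribution so empirical populations are unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .trajectory import Atom, Topology, TrajectoryEnsemble

__all__ = [
    "HiddenStateSpec",
    "GroundTruth",
    "stationary_distribution",
    "generate_ensemble",
    "make_hb_templates",
    "toy_chain_spec",
    "benchmark_three_state",
    "benchmark_protection",
]


def _validate_stochastic(T: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0):
        raise ValueError("transition matrix has negative entries")
    rowsum = T.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=atol, rtol=0):
        bad = np.flatnonzero(np.abs(rowsum - 1.0) > atol)
        raise ValueError(f"transition-matrix rows {bad.tolist()} do not sum to 1")
    return T


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary (left-eigenvalue-1) distribution of an irreducible chain.

    Raises a ValueError naming the disconnected blocks if the chain is
    reducible.
    """
    T = _validate_stochastic(transition_matrix)
    n = len(T)
    n_comp, labels = connected_components(csr_matrix(T > 0), connection="strong")
    if n_comp > 1:
        blocks = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(
            f"chain is reducible; strongly connected blocks: {blocks}"
        )
    evals, evecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    pi /= pi.sum()
    # polish with one fixed-point sweep to reduce round-off
    for _ in range(5):
        pi = pi @ T
        pi /= pi.sum()
    return pi


def _hidden_timescales(T: np.ndarray) -> np.ndarray:
    """-1/ln|λ| for the nontrivial eigenvalues, descending, in frame units."""
    evals = np.linalg.eigvals(T)
    mags = np.sort(np.abs(evals))[::-1][1:]  # drop the Perron eigenvalue
    out = np.full(mags.shape, np.inf)
    pos = (mags > 0) & (mags < 1)
    out[pos] = -1.0 / np.log(mags[pos])
    out[mags <= 0] = np.nan
    return out


@dataclass
class HiddenStateSpec:
    """Hidden-chain specification: transition matrix, per-state templates, noise.

    templates: (n_states, n_atoms, 3) array in nm, sharing ``topology``.
    hb_pattern: optional designed (n_states, n_sites, 2) integer array of
    expected (HB_p, HB_w) pairs per state and amide site.
    """

    transition_matrix: np.ndarray
    topology: Topology
    templates: np.ndarray
    noise_sigma: float = 0.0
    frame_interval: float = 10.0
    hb_pattern: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transition_matrix = _validate_stochastic(self.transition_matrix)
        self.templates = np.asarray(self.templates, dtype=float)
        n_states = len(self.transition_matrix)
        expected = (n_states, self.topology.n_atoms, 3)
        if self.templates.shape != expected:
            raise ValueError(
                f"templates shape {self.templates.shape} does not match "
                f"{expected} (all states must share one topology)"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.transition_matrix)


@dataclass
class GroundTruth:
    """Per-frame hidden states plus the analytic properties of the chain."""

    state_sequences: list[np.ndarray]
    true_populations: np.ndarray
    true_timescales: np.ndarray
    true_hb_pattern: np.ndarray | None = None

    def concatenated_states(self) -> np.ndarray:
        return np.concatenate(self.state_sequences)


def _simulate_chain(
    T: np.ndarray,
    pi: np.ndarray,
    n_frames: int,
    rng: np.random.Generator,
    start: int | None = None,
) -> np.ndarray:
    cum = np.cumsum(T, axis=1)
    u = rng.random(n_frames)
    seq = np.empty(n_frames, dtype=np.int64)
    if start is None:
        s = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
        seq[0] = min(s, len(pi) - 1)
    else:
        seq[0] = start
    for t in range(1, n_frames):
        row = cum[seq[t - 1]]
        seq[t] = min(int(np.searchsorted(row, u[t], side="right")), len(pi) - 1)
    return seq


def generate_ensemble(
    spec: HiddenStateSpec,
    n_traj: int,
    n_frames: int,
    seed: int,
    initial_states: np.ndarray | None = None,
) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Sample n_traj trajectories of n_frames frames from the hidden chain.

    Frame t is the template of the hidden state at t plus iid Gaussian noise
    of width ``spec.noise_sigma``. By default each trajectory starts from the
    stationary distribution (unbiased populations); ``initial_states`` pins
    the per-trajectory starting hidden state instead (used when re-seeding
    sampling from selected structures). Identical seeds give bit-identical
    output.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    if initial_states is not None and len(initial_states) != n_traj:
        raise ValueError("need one initial state per trajectory")
    if initial_states is None:
        pi = stationary_distribution(spec.transition_matrix)
    else:
        # starts are pinned, so the stationary distribution is informational
        # only; a reducible chain has none, and then we report NaN populations
        try:
            pi = stationary_distribution(spec.transition_matrix)
        except ValueError:
            pi = np.full(spec.n_states, np.nan)
    rng = np.random.default_rng(seed)

    sequences, trajectories = [], []
    for t in range(n_traj):
        start = None if initial_states is None else int(initial_states[t])
        seq = _simulate_chain(
            spec.transition_matrix, pi, n_frames, rng, start=start
        )
        xyz = spec.templates[seq].copy()
        if spec.noise_sigma > 0:
            xyz += rng.normal(0.0, spec.noise_sigma, size=xyz.shape)
        sequences.append(seq)
        trajectories.append(xyz)

    ensemble = TrajectoryEnsemble(
        spec.topology, trajectories, frame_interval=spec.frame_interval
    )
    truth = GroundTruth(
        state_sequences=sequences,
        true_populations=pi,
        true_timescales=_hidden_timescales(spec.transition_matrix),
        true_hb_pattern=None if spec.hb_pattern is None else spec.hb_pattern.copy(),
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

_RES_SPACING = 1.5  # nm between residue origins; keeps sites H-bond independent
_BOND_LEN = 0.30  # nm, designed donor-acceptor distance (inside every cutoff)


def make_hb_templates(
    patterns: np.ndarray,
    ca_displacement: float = 0.4,
    seed: int = 0,
) -> tuple[Topology, np.ndarray]:
    """Build per-state templates realising designed hydrogen-bond patterns.

    ``patterns`` is (n_states, n_residues, 2) with integer (HB_p, HB_w) in
    {0, 1, 2}. Designed acceptors sit 0.30 nm from the donor N at small
    N–H/N–acceptor angles, so they are counted under every cutoff of the
    distance grid (0.35–0.60 nm) and angle grid (40–90°); unused acceptors
    are parked several nm away (never counted). Cα atoms get a per-state
    pseudo-random displacement (up to ``ca_displacement`` nm, seeded) so that
    pairwise Cα distances distinguish the hidden states.
    """
    patterns = np.asarray(patterns, dtype=int)
    if patterns.ndim != 3 or patterns.shape[2] != 2:
        raise ValueError("patterns must be (n_states, n_residues, 2)")
    if patterns.min() < 0 or patterns.max() > 2:
        raise ValueError("designed HB counts must be in {0, 1, 2}")
    n_states, n_res, _ = patterns.shape

    atoms: list[Atom] = []
    for i in range(n_res):
        resid = i + 1
        for name, elem in (
            ("N", "N"),
            ("H", "H"),
            ("CA", "C"),
            ("C", "C"),
            ("O", "O"),
            ("OG", "O"),
        ):
            atoms.append(Atom("A", resid, "GLY", name, elem))
    n_protein = len(atoms)
    for i in range(n_res):
        for k in range(2):
            atoms.append(Atom("W", 1000 + 2 * i + k, "HOH", "O", "O"))
    top = Topology(atoms)

    rng = np.random.default_rng(seed)
    ca_disp = rng.uniform(-ca_displacement, ca_displacement, size=(n_states, n_res, 2))

    sin20, cos20 = np.sin(np.deg2rad(20)), np.cos(np.deg2rad(20))
    sin15, cos15 = np.sin(np.deg2rad(15)), np.cos(np.deg2rad(15))

    templates = np.zeros((n_states, top.n_atoms, 3))
    for s in range(n_states):
        for i in range(n_res):
            x = _RES_SPACING * i
            p, w = patterns[s, i]
            base = 6 * i
            templates[s, base + 0] = (x, 0.0, 0.0)  # N
            templates[s, base + 1] = (x, 0.10, 0.0)  # H along +y
            templates[s, base + 2] = (  # CA, state-dependent
                x + 0.0,
                -0.15 + ca_disp[s, i, 0],
                ca_disp[s, i, 1],
            )
            templates[s, base + 3] = (x, -0.30, 0.0)  # C (not an acceptor)
            if p >= 1:  # backbone O collinear with N->H: bonded
                templates[s, base + 4] = (x, _BOND_LEN, 0.0)
            else:  # behind the donor: angle 180 deg, never counted
                templates[s, base + 4] = (x, -0.50, 0.0)
            if p >= 2:  # side-chain O at 20 deg from N->H
                templates[s, base + 5] = (
                    x + _BOND_LEN * sin20,
                    _BOND_LEN * cos20,
                    0.0,
                )
            else:
                templates[s, base + 5] = (x, 0.0, 5.0)  # parked
            for k, sign in enumerate((+1.0, -1.0)):
                widx = n_protein + 2 * i + k
                if w > k:  # water O at +/-15 deg from N->H
                    templates[s, widx] = (
                        x + sign * _BOND_LEN * sin15,
                        _BOND_LEN * cos15,
                        0.0,
                    )
                else:
                    templates[s, widx] = (x, 0.0, 8.0 + k)
    return top, templates


def toy_chain_spec(
    transition_matrix: np.ndarray,
    patterns: np.ndarray | None = None,
    n_residues: int = 6,
    noise_sigma: float = 0.02,
    frame_interval: float = 10.0,
    seed: int = 0,
) -> HiddenStateSpec:
    """Convenience constructor: toy chain templates for a given hidden chain.

    Without ``patterns``, every state gets a neutral hydrogen-bond pattern
    (HB_p=1, HB_w=0 at every site) and states differ only in Cα geometry.
    """
    T = _validate_stochastic(transition_matrix)
    n_states = len(T)
    if patterns is None:
        patterns = np.zeros((n_states, n_residues, 2), dtype=int)
        patterns[:, :, 0] = 1
    top, templates = make_hb_templates(patterns, seed=seed)
    return HiddenStateSpec(
        transition_matrix=T,
        topology=top,
        templates=templates,
        noise_sigma=noise_sigma,
        frame_interval=frame_interval,
        hb_pattern=np.asarray(patterns, dtype=int),
    )


def benchmark_three_state(noise_sigma: float = 0.05) -> HiddenStateSpec:
    """Three-metastable-state benchmark chain used for pipeline validation.

    Dwell probabilities ~0.99 per frame give a slowest relaxation of roughly
    a hundred frames; the analytic populations and timescales come from the
    transition matrix itself.
    """
    T = np.array(
        [
            [0.990, 0.006, 0.004],
            [0.012, 0.985, 0.003],
            [0.012, 0.004, 0.984],
        ]
    )
    return toy_chain_spec(T, n_residues=6, noise_sigma=noise_sigma, seed=7)


def benchmark_protection(
    populations: tuple[float, float] = (0.7, 0.3),
    switch_scale: float = 0.01,
    n_residues: int = 8,
    noise_sigma: float = 0.01,
) -> HiddenStateSpec:
    """Two-state protection benchmark with designed protected/exposed sites.

    In state 0 the even-indexed sites are protected (HB_p=2, HB_w=0) and the
    odd-indexed sites exposed (HB_p=0, HB_w=2); state 1 swaps even sites to
    exposed while odd sites stay exposed, so even sites are the designed
    protected class under the stationary mix. Transition probabilities are
    chosen so the stationary distribution equals ``populations``.
    """
    p0, p1 = populations
    if not np.isclose(p0 + p1, 1.0) or min(p0, p1) <= 0:
        raise ValueError("populations must be positive and sum to 1")
    # detailed balance: p0 * T01 = p1 * T10
    t01 = switch_scale * p1
    t10 = switch_scale * p0
    T = np.array([[1 - t01, t01], [t10, 1 - t10]])
    patterns = np.zeros((2, n_residues, 2), dtype=int)
    for i in range(n_residues):
        if i % 2 == 0:
            patterns[0, i] = (2, 0)  # protected in the dominant state
            patterns[1, i] = (0, 2)
        else:
            patterns[0, i] = (0, 2)  # always exposed
            patterns[1, i] = (0, 2)
    return toy_chain_spec(
        T, patterns=patterns, n_residues=n_residues, noise_sigma=noise_sigma, seed=11
    )
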