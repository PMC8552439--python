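"""Geometric hydrogen-bond counting for backbone amide sites.

For every frame and every amide N-H donor, counts the hydrogen bonds to
protein acceptors (HB_p: any protein O or N atom, excluding the donor's own
N and its hydrogen) and to water oxygens (HB_w). A bond is counted when the
donor-acceptor distance is <= distance_cutoff and the angle at the donor N
between the N->H and N->acceptor directions is <= angle_cutoff. Comparisons
are inclusive so behavior at cutoff boundaries is deterministic; multiple
simultaneous acceptors each count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import TrajectoryEnsemble

__all__ = ["HBondCriteria", "HBondCounts", "count_hbonds", "GRID_DISTANCES",
           "GRID_ANGLES"]

#: the distance (nm) and angle (degrees) cutoff grids explored for robustness
GRID_DISTANCES = (0.35, 0.40, 0.50, 0.60)
GRID_ANGLES = (40.0, 50.0, 70.0, 90.0)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria for counting a hydrogen bond.

    distance_cutoff: donor(N)-acceptor distance, nm.
    angle_cutoff: hydrogen-donor-acceptor angle, degrees. By default the
        vertex is the donor N (angle between N->H and N->acceptor); set
        angle_vertex="hydrogen" for the H-vertex convention instead.
    include_self_residue: whether acceptors in the donor's own residue
        (backbone O, side-chain O) are eligible; the donor's N and H never are.
    """

    distance_cutoff: float = 0.50
    angle_cutoff: float = 70.0
    include_self_residue: bool = True
    angle_vertex: str = "donor"

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if not (0 < self.angle_cutoff <= 180):
            raise ValueError("angle_cutoff must be in (0, 180] degrees")
        if self.angle_vertex not in ("donor", "hydrogen"):
            raise ValueError("angle_vertex must be 'donor' or 'hydrogen'")


@dataclass
class HBondCounts:
    """Per-frame, per-site integer bond counts (frames x sites)."""

    sites: list[str]
    hb_p: np.ndarray
    hb_w: np.ndarray
    criteria: HBondCriteria

    @property
    def n_frames(self) -> int:
        return len(self.hb_p)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: frame, site, HB_p, HB_w."""
        n_frames, n_sites = self.hb_p.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_frames), n_sites),
                "site": np.tile(np.array(self.sites), n_frames),
                "HB_p": self.hb_p.ravel(),
                "HB_w": self.hb_w.ravel(),
            }
        )


def _count_site(
    xyz: np.ndarray,
    n_idx: int,
    h_idx: int,
    acceptors: np.ndarray,
    criteria: HBondCriteria,
) -> np.ndarray:
    """Bond count per frame for one donor against one acceptor set."""
    if len(acceptors) == 0:
        return np.zeros(len(xyz), dtype=np.int64)
    n = xyz[:, n_idx, :]
    h = xyz[:, h_idx, :]
    acc = xyz[:, acceptors, :]  # (F, A, 3)
    d_na = np.linalg.norm(acc - n[:, None, :], axis=2)
    within = d_na <= criteria.distance_cutoff

    if criteria.angle_vertex == "donor":
        v1 = h - n  # N->H
        v2 = acc - n[:, None, :]  # N->acceptor
        norm2 = d_na
    else:
        # hydrogen-vertex convention: deviation from linearity at H, i.e.
        # the angle between the N->H direction and H->acceptor (0 for a
        # perfectly linear N-H...A bond)
        v1 = h - n
        v2 = acc - h[:, None, :]
        norm2 = np.linalg.norm(v2, axis=2)

    norm1 = np.linalg.norm(v1, axis=1)
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.einsum("fj,faj->fa", v1, v2) / (
            norm1[:, None] * norm2
        )
    # degenerate geometry (coincident atoms): treat as perfectly aligned
    cosang = np.where(np.isfinite(cosang), cosang, 1.0)
    ok_angle = cosang >= cos_cut - 1e-12
    return (within & ok_angle).sum(axis=1).astype(np.int64)


def count_hbonds(
    ensemble: TrajectoryEnsemble,
    criteria: HBondCriteria | None = None,
    sites: list[tuple[str, int]] | None = None,
) -> HBondCounts:
    """Count HB_p and HB_w for every amide site over all frames.

    ``sites`` restricts the computation to a subset of (chain, resid) amide
    sites; the default is all of them.
    """
    criteria = criteria or HBondCriteria()
    top = ensemble.topology
    if sites is None:
        sites = list(top.amide_sites)
    else:
        for s in sites:
            top.site_donor(tuple(s))  # raises naming the site if invalid

    waters = np.array(top.water_oxygens, dtype=int)
    site_acceptors = []
    for site in sites:
        n_idx, h_idx = top.site_donor(tuple(site))
        acc = []
        for i in top.acceptor_atoms:
            if i == n_idx or i == h_idx:
                continue
            if (
                not criteria.include_self_residue
                and top.atoms[i].residue_key == tuple(site)
            ):
                continue
            acc.append(i)
        site_acceptors.append((n_idx, h_idx, np.array(acc, dtype=int)))

    hb_p_blocks, hb_w_blocks = [], []
    for xyz in ensemble.trajectories:
        hp = np.empty((len(xyz), len(sites)), dtype=np.int64)
        hw = np.empty_like(hp)
        for si, (n_idx, h_idx, acc) in enumerate(site_acceptors):
            hp[:, si] = _count_site(xyz, n_idx, h_idx, acc, criteria)
            hw[:, si] = _count_site(xyz, n_idx, h_idx, waters, criteria)
        hb_p_blocks.append(hp)
        hb_w_blocks.append(hw)

    labels = [f"{c}{r}" for c, r in sites]
    return HBondCounts(
        sites=labels,
        hb_p=np.concatenate(hb_p_blocks, axis=0),
        hb_w=np.concatenate(hb_w_blocks, axis=0),
        criteria=criteria,
    )
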