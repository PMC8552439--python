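"""Trajectory containers, I/O and pairwise-distance featurization.

Coordinates are stored in nanometres throughout; PDB input (Å) is converted
on read. All trajectories of an ensemble share a single topology and a
uniform frame interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "T3P", "TIP4", "SPC"}
#: atom names recognised as the backbone amide hydrogen
AMIDE_H_NAMES = ("H", "HN")


@dataclass(frozen=True)
class Atom:
    chain: str
    resid: int
    resname: str
    name: str
    element: str

    @property
    def is_water(self) -> bool:
        return self.resname.upper() in WATER_RESNAMES

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.resid)


class Topology:
    """Static description of the system: atoms, amide sites, acceptors, waters.

    An amide site is a protein residue carrying a backbone N with exactly one
    attached amide hydrogen (named ``H`` or ``HN``); proline-like residues
    without the hydrogen are simply not sites. Hydrogen-bond acceptors are all
    protein O and N atoms; water oxygens are O atoms of water residues.
    """

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms = list(atoms)
        self._index_residues()

    def _index_residues(self) -> None:
        residues: dict[tuple[str, int], dict[str, int]] = {}
        for i, a in enumerate(self.atoms):
            res = residues.setdefault(a.residue_key, {})
            if a.name in res:
                raise ValueError(
                    f"duplicate atom {a.name!r} in residue {a.chain}{a.resid}"
                )
            res[a.name] = i
        self._residues = residues

        self.water_oxygens = [
            i
            for i, a in enumerate(self.atoms)
            if a.is_water and a.element.upper() == "O"
        ]
        self.acceptor_atoms = [
            i
            for i, a in enumerate(self.atoms)
            if not a.is_water and a.element.upper() in ("O", "N")
        ]

        self.amide_sites: list[tuple[str, int]] = []
        self._site_atoms: dict[tuple[str, int], tuple[int, int]] = {}
        for key, names in residues.items():
            chain, resid = key
            if self.atoms[next(iter(names.values()))].is_water:
                continue
            if "N" not in names:
                continue
            h_names = [n for n in AMIDE_H_NAMES if n in names]
            if not h_names:
                continue
            if len(h_names) > 1:
                raise ValueError(
                    f"residue {chain}{resid} has more than one amide hydrogen"
                )
            self.amide_sites.append(key)
            self._site_atoms[key] = (names["N"], names[h_names[0]])
        self.amide_sites.sort()

    # -- lookups ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_atoms(self, chain: str, resid: int) -> dict[str, int]:
        try:
            return self._residues[(chain, resid)]
        except KeyError:
            raise KeyError(f"residue {chain}{resid} not in topology") from None

    def has_residue(self, chain: str, resid: int) -> bool:
        return (chain, resid) in self._residues

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        res = self.residue_atoms(chain, resid)
        try:
            return res[name]
        except KeyError:
            raise KeyError(f"atom {name!r} not in residue {chain}{resid}") from None

    def site_label(self, site: tuple[str, int]) -> str:
        return f"{site[0]}{site[1]}"

    @property
    def site_labels(self) -> list[str]:
        return [self.site_label(s) for s in self.amide_sites]

    def site_donor(self, site: tuple[str, int]) -> tuple[int, int]:
        """(N index, H index) of an amide site."""
        try:
            return self._site_atoms[site]
        except KeyError:
            raise KeyError(f"{site[0]}{site[1]} is not an amide site") from None

    def residues(self, chain: str | None = None) -> list[tuple[str, int]]:
        keys = sorted(self._residues)
        if chain is None:
            return keys
        return [k for k in keys if k[0] == chain]


@dataclass
class TrajectoryEnsemble:
    """Multi-trajectory coordinate set over one shared topology.

    trajectories: list of (n_frames, n_atoms, 3) arrays in nm.
    frame_interval: time between saved frames, ps.
    """

    topology: Topology
    trajectories: list[np.ndarray]
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for t, xyz in enumerate(self.trajectories):
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 3 or xyz.shape[1] != n or xyz.shape[2] != 3:
                raise ValueError(
                    f"trajectory {t}: shape {xyz.shape} does not match the "
                    f"topology ({n} atoms)"
                )
            self.trajectories[t] = xyz
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    @property
    def n_frames(self) -> int:
        return sum(len(x) for x in self.trajectories)

    @property
    def traj_lengths(self) -> list[int]:
        return [len(x) for x in self.trajectories]

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.trajectories, axis=0)


@dataclass
class FeatureMatrix:
    """Frames x d feature values with per-column labels.

    ``traj_lengths`` records the trajectory boundaries so that time-lagged
    statistics never straddle trajectories.
    """

    values: np.ndarray
    feature_labels: list[str]
    traj_lengths: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (frames x features)")
        if sum(self.traj_lengths) != len(self.values):
            raise ValueError("traj_lengths inconsistent with number of frames")
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError("one label per feature column required")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def split(self) -> list[np.ndarray]:
        """Per-trajectory blocks of the feature matrix."""
        out, start = [], 0
        for n in self.traj_lengths:
            out.append(self.values[start : start + n])
            start += n
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.feature_labels)


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def pairwise_ca_distances(
    ensemble: TrajectoryEnsemble,
    residue_selection: Sequence[tuple[str, int]] | None = None,
) -> FeatureMatrix:
    """Pairwise Cα–Cα Euclidean distances (nm) for the selected residues.

    Columns are ordered lexicographically by (chain, resid) residue pair,
    giving n(n-1)/2 features for n residues. No periodic minimum-image
    correction is applied (single solvated monomer).
    """
    top = ensemble.topology
    if residue_selection is None:
        residue_selection = [
            r for r in top.residues() if "CA" in top.residue_atoms(*r)
        ]
    selection = sorted(residue_selection)
    if len(selection) < 2:
        raise ValueError("need at least two residues for pairwise distances")
    ca_idx = []
    for chain, resid in selection:
        res = top.residue_atoms(chain, resid)  # raises naming the residue
        if "CA" not in res:
            raise KeyError(f"residue {chain}{resid} has no CA atom")
        ca_idx.append(res["CA"])

    pairs = list(itertools.combinations(range(len(selection)), 2))
    labels = [
        f"{selection[i][0]}{selection[i][1]}-{selection[j][0]}{selection[j][1]}"
        for i, j in pairs
    ]
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])

    blocks = []
    for xyz in ensemble.trajectories:
        ca = xyz[:, ca_idx, :]  # (F, n, 3)
        diff = ca[:, ii, :] - ca[:, jj, :]
        blocks.append(np.linalg.norm(diff, axis=2))
    values = np.concatenate(blocks, axis=0)
    return FeatureMatrix(values, labels, ensemble.traj_lengths)


# ---------------------------------------------------------------------------
# I/O (PDB topology, XTC/DCD/CSV coordinates) via mdtraj
# ---------------------------------------------------------------------------

def _topology_from_mdtraj(mtop) -> Topology:
    atoms = []
    for atom in mtop.atoms:
        chain_id = atom.residue.chain.chain_id
        if not chain_id or not str(chain_id).strip():
            chain_id = chr(ord("A") + atom.residue.chain.index)
        element = atom.element.symbol if atom.element is not None else ""
        atoms.append(
            Atom(
                chain=str(chain_id),
                resid=int(atom.residue.resSeq),
                resname=atom.residue.name,
                name=atom.name,
                element=element,
            )
        )
    return Topology(atoms)


def _topology_to_mdtraj(top: Topology):
    import mdtraj as md
    from mdtraj.core import element as md_element

    mtop = md.Topology()
    chains: dict[str, object] = {}
    residues: dict[tuple[str, int], object] = {}
    for a in top.atoms:
        if a.chain not in chains:
            chains[a.chain] = mtop.add_chain(chain_id=a.chain)
        key = a.residue_key
        if key not in residues:
            residues[key] = mtop.add_residue(
                a.resname, chains[a.chain], resSeq=a.resid
            )
        try:
            elem = md_element.get_by_symbol(a.element) if a.element else None
        except KeyError:
            elem = None
        mtop.add_atom(a.name, elem, residues[key])
    return mtop


def _load_csv_coordinates(path: Path, n_atoms: int) -> np.ndarray:
    """Plain columnar format: header frame,atom,x,y,z ; coordinates in nm."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"frame", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    frames = sorted(df["frame"].unique())
    xyz = np.empty((len(frames), n_atoms, 3))
    for fi, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("atom")
        if len(sub) != n_atoms or not np.array_equal(
            sub["atom"].to_numpy(), np.arange(n_atoms)
        ):
            raise ValueError(
                f"{path}: frame {f} has {len(sub)} atoms, expected {n_atoms}"
            )
        xyz[fi] = sub[["x", "y", "z"]].to_numpy()
    return xyz


def read_ensemble(
    topology_path: str | Path,
    trajectory_paths: Iterable[str | Path] | None = None,
    frame_interval: float = 10.0,
) -> TrajectoryEnsemble:
    """Read a PDB topology and XTC/DCD/CSV/PDB coordinate files.

    With no trajectory files, the PDB's own frames form a single trajectory.
    mdtraj handles unit conversion, so coordinates come back in nm.
    """
    import mdtraj as md

    topology_path = Path(topology_path)
    ref = md.load(str(topology_path))
    top = _topology_from_mdtraj(ref.topology)

    trajectories: list[np.ndarray] = []
    if trajectory_paths is None:
        trajectories.append(np.asarray(ref.xyz, dtype=float))
    else:
        for p in trajectory_paths:
            p = Path(p)
            suffix = p.suffix.lower()
            if suffix == ".csv":
                xyz = _load_csv_coordinates(p, top.n_atoms)
            elif suffix in (".xtc", ".dcd", ".pdb"):
                try:
                    traj = md.load(str(p), top=ref.topology)
                except Exception as exc:  # mdtraj raises assorted types
                    raise ValueError(f"cannot read trajectory {p}: {exc}") from exc
                if traj.xyz.shape[1] != top.n_atoms:
                    raise ValueError(
                        f"{p}: atom count {traj.xyz.shape[1]} does not match "
                        f"topology ({top.n_atoms})"
                    )
                xyz = np.asarray(traj.xyz, dtype=float)
            else:
                raise ValueError(f"unsupported trajectory format: {p}")
            trajectories.append(xyz)
    return TrajectoryEnsemble(top, trajectories, frame_interval=frame_interval)


def write_ensemble(
    ensemble: TrajectoryEnsemble,
    out_dir: str | Path,
    traj_format: str = "xtc",
    stem: str = "traj",
) -> tuple[Path, list[Path]]:
    """Write topology.pdb plus one coordinate file per trajectory.

    ``traj_format`` is one of xtc, dcd, csv. Returns the written paths.
    """
    import mdtraj as md

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtop = _topology_to_mdtraj(ensemble.topology)

    top_path = out_dir / "topology.pdb"
    first = md.Trajectory(ensemble.trajectories[0][:1], mtop)
    first.save_pdb(str(top_path))

    paths = []
    for t, xyz in enumerate(ensemble.trajectories):
        if traj_format == "csv":
            import pandas as pd

            path = out_dir / f"{stem}_{t:03d}.csv"
            n_frames, n_atoms, _ = xyz.shape
            df = pd.DataFrame(
                {
                    "frame": np.repeat(np.arange(n_frames), n_atoms),
                    "atom": np.tile(np.arange(n_atoms), n_frames),
                    "x": xyz[:, :, 0].ravel(),
                    "y": xyz[:, :, 1].ravel(),
                    "z": xyz[:, :, 2].ravel(),
                }
            )
            df.to_csv(path, index=False)
        elif traj_format in ("xtc", "dcd"):
            path = out_dir / f"{stem}_{t:03d}.{traj_format}"
            md.Trajectory(xyz, mtop).save(str(path))
        else:
            raise ValueError(f"unsupported trajectory format: {traj_format}")
        paths.append(path)
    return top_path, paths
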