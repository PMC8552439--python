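"""Internal-coordinate construction of toy polypeptide backbones.

Builds backbone-only chains (N, H, Ca, C, O per residue) from phi/psi
dihedrals with standard bond lengths and angles, in nm. Used to construct
geometric fixtures such as ideal alpha-helices and extended strands for the
structure-annotation rules.
"""

from __future__ import annotations

import numpy as np

from .trajectory import Atom, Topology

__all__ = ["place_atom", "build_chain", "ALPHA_HELIX", "EXTENDED"]

# canonical alpha-helix and extended-strand (phi, psi) in degrees
ALPHA_HELIX = (-57.0, -47.0)
EXTENDED = (180.0, 180.0)

# backbone internal coordinates (nm / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 0.1458, 0.1525, 0.1329
_B_C_O, _B_N_H = 0.1231, 0.0997
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 117.2, 121.7
_OMEGA = 180.0


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, dihedral: float,
) -> np.ndarray:
    """Position of atom d with given bond c-d, angle b-c-d and dihedral a-b-c-d.

    Standard natural-extension-of-reference-frame construction; angles in
    degrees, IUPAC dihedral sign convention.
    """
    angle = np.deg2rad(angle)
    dihedral = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("collinear reference atoms for dihedral placement")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _bisector_direction(center: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    v1 = x1 - center
    v2 = x2 - center
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    d = -(v1 + v2)
    return d / np.linalg.norm(d)


def build_chain(
    dihedrals: list[tuple[float, float]],
    chain: str = "A",
    resname: str = "GLY",
) -> tuple[Topology, np.ndarray]:
    """Build a backbone-only chain with the given per-residue (phi, psi).

    phi of the first residue is ignored (no preceding carbonyl); the first
    residue carries no amide hydrogen. Returns the topology and one frame of
    coordinates (n_atoms, 3) in nm.
    """
    n_res = len(dihedrals)
    if n_res < 2:
        raise ValueError("need at least two residues")

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))

    # seed the first residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_res):
        psi_prev = dihedrals[i - 1][1]
        phi = dihedrals[i][0]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for i in range(n_res):
        resid = i + 1
        atoms.append(Atom(chain, resid, resname, "N", "N"))
        coords.append(N[i])
        if i > 0:  # amide hydrogen, in the peptide plane
            atoms.append(Atom(chain, resid, resname, "H", "H"))
            coords.append(N[i] + _B_N_H * _bisector_direction(N[i], CA[i], C[i - 1]))
        atoms.append(Atom(chain, resid, resname, "CA", "C"))
        coords.append(CA[i])
        atoms.append(Atom(chain, resid, resname, "C", "C"))
        coords.append(C[i])
        # carbonyl O: trigonal in-plane, opposite the next amide N
        if i < n_res - 1:
            o = C[i] + _B_C_O * _bisector_direction(C[i], CA[i], N[i + 1])
        else:
            o = place_atom(N[i], CA[i], C[i], _B_C_O, 121.0, dihedrals[i][1] + 180.0)
        atoms.append(Atom(chain, resid, resname, "O", "O"))
        coords.append(o)

    return Topology(atoms), np.array(coords)
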