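"""Geometric annotation of conformational disorder elements.

Frames are classified against configurable rules built from a small set of
collective variables: backbone dihedrals, helix hydrogen-bond content,
minimum inter-segment distances, signed distances from an anchor plane, and
the presence of specific backbone hydrogen bonds. Rules are data (a YAML
config), not code, so definitions can be swapped without touching the
package. Per-cluster "physically weighted" percentages use the MSM
equilibrium frame weights rather than uniform frame counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .hbonds import HBondCriteria
from .trajectory import TrajectoryEnsemble

__all__ = [
    "APlane",
    "backbone_dihedral",
    "plane_side",
    "helix_content",
    "hbond_present",
    "classify_elements",
    "element_percentages",
    "ElementSummary",
    "load_rules",
    "default_insulin_rules",
]

#: Table-style occupancy bands: >=80% and the 20-80% intermediate band
BAND_HIGH, BAND_MID = 80.0, 20.0

#: default geometry for backbone i -> i+4 helix hydrogen bonds
HELIX_HBOND = HBondCriteria(distance_cutoff=0.35, angle_cutoff=40.0)


# ---------------------------------------------------------------------------
# collective variables
# ---------------------------------------------------------------------------

def _coords(ensemble: TrajectoryEnsemble) -> np.ndarray:
    return ensemble.concatenated()


def _dihedral(p0, p1, p2, p3) -> np.ndarray:
    """IUPAC-signed dihedral in degrees, vectorized over frames, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.einsum("...i,...i", n1, n2)
    y = np.einsum("...i,...i", m1, n2)
    deg = np.degrees(np.arctan2(-y, x))
    deg = np.where(deg <= -180.0, deg + 360.0, deg)
    return deg


def backbone_dihedral(
    ensemble: TrajectoryEnsemble, residue: tuple[str, int], which: str
) -> np.ndarray:
    """Backbone phi or psi of one residue, per frame, degrees in (-180, 180].

    phi = C(i-1), N(i), Ca(i), C(i); psi = N(i), Ca(i), C(i), N(i+1).
    Chain-terminal residues lacking the flanking atom raise an error.
    """
    top = ensemble.topology
    chain, resid = residue
    if which == "phi":
        quad = [(chain, resid - 1, "C"), (chain, resid, "N"),
                (chain, resid, "CA"), (chain, resid, "C")]
    elif which == "psi":
        quad = [(chain, resid, "N"), (chain, resid, "CA"),
                (chain, resid, "C"), (chain, resid + 1, "N")]
    else:
        raise ValueError("which must be 'phi' or 'psi'")
    try:
        idx = [top.atom_index(*q) for q in quad]
    except KeyError as exc:
        raise ValueError(
            f"cannot compute {which} of {chain}{resid}: {exc}"
        ) from exc
    xyz = _coords(ensemble)
    p = [xyz[:, i, :] for i in idx]
    return _dihedral(*p)


@dataclass(frozen=True)
class APlane:
    """Plane through three anchor atoms, with a recorded reference side.

    The sign of plane_side is fixed so the reference atom is on the positive
    side, keeping the convention stable across frames.
    """

    anchors: tuple[tuple[str, int], ...] = (("A", 9), ("A", 13), ("A", 20))
    atom_name: str = "CA"
    reference: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if len(self.anchors) != 3:
            raise ValueError("a plane needs exactly 3 anchor residues")


def plane_side(
    ensemble: TrajectoryEnsemble, plane: APlane, atom: tuple[str, int, str]
) -> np.ndarray:
    """Signed distance (nm) of an atom from the anchor plane, per frame."""
    top = ensemble.topology
    anchor_idx = [
        top.atom_index(c, r, plane.atom_name) for c, r in plane.anchors
    ]
    atom_idx = top.atom_index(*atom)
    xyz = _coords(ensemble)
    p1, p2, p3 = (xyz[:, i, :] for i in anchor_idx)
    normal = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(normal, axis=1)
    if np.any(area <= 1e-6):
        raise ValueError("collinear plane anchors (area <= 1e-6 nm^2)")
    nhat = normal / np.linalg.norm(normal, axis=1, keepdims=True)
    d = np.einsum("fi,fi->f", xyz[:, atom_idx, :] - p1, nhat)
    if plane.reference is not None:
        ref_idx = top.atom_index(*plane.reference)
        s = np.einsum("fi,fi->f", xyz[:, ref_idx, :] - p1, nhat)
        flip = np.sign(s)
        flip[flip == 0] = 1.0
        d = d * flip
    return d


def _bond_geometry(
    xyz: np.ndarray, n_idx: int, h_idx: int, o_idx: int, criteria: HBondCriteria
) -> np.ndarray:
    """Boolean per frame: donor N-H bonded to acceptor O under the criteria."""
    n = xyz[:, n_idx, :]
    h = xyz[:, h_idx, :]
    o = xyz[:, o_idx, :]
    d = np.linalg.norm(o - n, axis=1)
    v1 = h - n
    v2 = o - n
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.einsum("fi,fi->f", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
    cosang = np.where(np.isfinite(cosang), cosang, 1.0)
    return (d <= criteria.distance_cutoff) & (
        cosang >= np.cos(np.deg2rad(criteria.angle_cutoff)) - 1e-12
    )


def hbond_present(
    ensemble: TrajectoryEnsemble,
    donor: tuple[str, int],
    acceptor: tuple[str, int],
    criteria: HBondCriteria = HELIX_HBOND,
) -> np.ndarray:
    """Per-frame presence of the donor-amide -> acceptor-carbonyl-O bond."""
    top = ensemble.topology
    n_idx, h_idx = top.site_donor(tuple(donor))
    o_idx = top.atom_index(acceptor[0], acceptor[1], "O")
    return _bond_geometry(_coords(ensemble), n_idx, h_idx, o_idx, criteria)


def helix_content(
    ensemble: TrajectoryEnsemble,
    chain: str,
    start: int,
    end: int,
    criteria: HBondCriteria = HELIX_HBOND,
) -> np.ndarray:
    """Fraction of residues in [start, end] that are alpha-helical, per frame.

    Residue i counts as helical when its backbone O accepts a hydrogen bond
    from the amide N-H of residue i+4. Residues whose i+4 partner does not
    exist (or is not an amide site) are excluded from the denominator, which
    is therefore constant across frames.
    """
    if end - start + 1 < 5:
        raise ValueError("helix range must span at least 5 residues")
    top = ensemble.topology
    xyz = _coords(ensemble)
    evaluable = []
    for i in range(start, end + 1):
        if not top.has_residue(chain, i) or not top.has_residue(chain, i + 4):
            continue
        if (chain, i + 4) not in top._site_atoms:
            continue
        if "O" not in top.residue_atoms(chain, i):
            continue
        evaluable.append(i)
    if not evaluable:
        raise ValueError(
            f"no evaluable i -> i+4 pairs in {chain}{start}-{chain}{end}"
        )
    helical = np.zeros((len(xyz), len(evaluable)), dtype=bool)
    for k, i in enumerate(evaluable):
        n_idx, h_idx = top.site_donor((chain, i + 4))
        o_idx = top.atom_index(chain, i, "O")
        helical[:, k] = _bond_geometry(xyz, n_idx, h_idx, o_idx, criteria)
    return helical.mean(axis=1)


def _selection_atoms(top, sel: dict) -> list[int]:
    """Atom indices for a residue-range selection.

    sel: {chain, start, end, atoms: "heavy"|"CA"|[names...]}
    """
    chain = sel["chain"]
    start, end = int(sel["start"]), int(sel["end"])
    atoms_spec = sel.get("atoms", "heavy")
    idx = []
    found_res = False
    for resid in range(start, end + 1):
        if not top.has_residue(chain, resid):
            continue
        found_res = True
        for name, ai in top.residue_atoms(chain, resid).items():
            elem = top.atoms[ai].element.upper()
            if atoms_spec == "heavy":
                if elem != "H":
                    idx.append(ai)
            elif atoms_spec == "CA":
                if name == "CA":
                    idx.append(ai)
            elif name in atoms_spec:
                idx.append(ai)
    if not found_res:
        raise ValueError(f"selection {chain}{start}-{chain}{end} matches no residue")
    if not idx:
        raise ValueError(f"selection {chain}{start}-{chain}{end} matches no atom")
    return idx


def min_distance(
    ensemble: TrajectoryEnsemble, selection_a: dict, selection_b: dict
) -> np.ndarray:
    """Per-frame minimum distance (nm) between two atom selections."""
    top = ensemble.topology
    ia = _selection_atoms(top, selection_a)
    ib = _selection_atoms(top, selection_b)
    xyz = _coords(ensemble)
    a = xyz[:, ia, :]
    b = xyz[:, ib, :]
    diff = a[:, :, None, :] - b[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=3)).min(axis=(1, 2))


# ---------------------------------------------------------------------------
# rule evaluation
# ---------------------------------------------------------------------------

def _criteria_from_rule(rule: dict) -> HBondCriteria:
    c = rule.get("criteria")
    if c is None:
        return HELIX_HBOND
    return HBondCriteria(
        distance_cutoff=float(c.get("distance_cutoff", HELIX_HBOND.distance_cutoff)),
        angle_cutoff=float(c.get("angle_cutoff", HELIX_HBOND.angle_cutoff)),
    )


def _apply_op(values: np.ndarray, rule: dict) -> np.ndarray:
    op = rule.get("op", ">")
    if op == "between":
        return (values > float(rule["lo"])) & (values <= float(rule["hi"]))
    thr = float(rule["threshold"])
    if op == ">":
        return values > thr
    if op == ">=":
        return values >= thr
    if op == "<":
        return values < thr
    if op == "<=":
        return values <= thr
    raise ValueError(f"unknown comparison op {op!r}")


def evaluate_rule(ensemble: TrajectoryEnsemble, rule: dict) -> np.ndarray:
    """Evaluate one rule dict to a per-frame boolean array."""
    cv = rule.get("cv")
    if cv == "helix_fraction":
        vals = helix_content(
            ensemble, rule["chain"], int(rule["start"]), int(rule["end"]),
            criteria=_criteria_from_rule(rule),
        )
        return _apply_op(vals, rule)
    if cv == "min_distance":
        vals = min_distance(ensemble, rule["selection_a"], rule["selection_b"])
        return _apply_op(vals, rule)
    if cv == "plane_side":
        pspec = rule["plane"]
        plane = APlane(
            anchors=tuple((a[0], int(a[1])) for a in pspec["anchors"]),
            atom_name=pspec.get("atom_name", "CA"),
            reference=(
                tuple(pspec["reference"]) if pspec.get("reference") else None
            ),
        )
        atom = tuple(rule["atom"])
        vals = plane_side(ensemble, plane, (atom[0], int(atom[1]), atom[2]))
        return _apply_op(vals, rule)
    if cv == "dihedral":
        res = rule["residue"]
        vals = backbone_dihedral(ensemble, (res[0], int(res[1])), rule["which"])
        return (vals >= float(rule["lo"])) & (vals <= float(rule["hi"]))
    if cv == "hbond":
        d, a = rule["donor"], rule["acceptor"]
        return hbond_present(
            ensemble,
            (d["chain"], int(d["resid"])),
            (a["chain"], int(a["resid"])),
            criteria=_criteria_from_rule(rule),
        )
    if cv == "all_of":
        out = np.ones(ensemble.n_frames, dtype=bool)
        for sub in rule["rules"]:
            out &= evaluate_rule(ensemble, sub)
        return out
    if cv == "any_of":
        out = np.zeros(ensemble.n_frames, dtype=bool)
        for sub in rule["rules"]:
            out |= evaluate_rule(ensemble, sub)
        return out
    if cv == "not":
        return ~evaluate_rule(ensemble, rule["rule"])
    raise ValueError(f"unknown collective variable {cv!r}")


def classify_elements(
    ensemble: TrajectoryEnsemble, rules: dict[str, dict]
) -> pd.DataFrame:
    """Per-frame boolean flags for every configured element of disorder."""
    if "elements" in rules:
        rules = rules["elements"]
    flags = {}
    for name, rule in rules.items():
        flags[name] = evaluate_rule(ensemble, rule)
    return pd.DataFrame(flags)


def load_rules(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_insulin_rules() -> dict:
    """The shipped stand-in rule set for the insulin monomer (see data/)."""
    text = (
        resources.files("msmhdx").joinpath("data/insulin_rules.yaml").read_text()
    )
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# weighted aggregation
# ---------------------------------------------------------------------------

@dataclass
class ElementSummary:
    """Element x cluster weighted percentages, occupancy bands and totals."""

    percentages: pd.DataFrame
    bands: pd.DataFrame
    headline_fraction: float


def _band(p: float) -> str:
    if np.isnan(p):
        return "missing"
    if p >= BAND_HIGH:
        return "green"
    if p >= BAND_MID:
        return "orange"
    return "low"


def element_percentages(
    flags: pd.DataFrame,
    weights: np.ndarray,
    cluster_labels: np.ndarray,
    headline_elements: list[str] | None = None,
) -> ElementSummary:
    """Physically weighted percentage of frames showing each element.

    percentage(e, c) = 100 * (weight of flagged frames in c)/(weight of c);
    the "ensemble" column aggregates all frames. ``headline_fraction`` is the
    weighted fraction of the whole ensemble showing at least one of the
    headline elements (default: the first three columns).
    """
    weights = np.asarray(weights, dtype=float)
    labels = np.asarray(cluster_labels)
    if len(weights) != len(flags) or len(labels) != len(flags):
        raise ValueError("flags, weights and labels must align per frame")
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise ValueError("frame weights must sum to 1")

    clusters = sorted(int(c) for c in np.unique(labels))
    pct = pd.DataFrame(index=flags.columns, dtype=float)
    for c in clusters:
        mask = labels == c
        wc = weights[mask].sum()
        if wc <= 0:
            pct[c] = np.nan
            continue
        pct[c] = [
            100.0 * weights[mask & flags[e].to_numpy()].sum() / wc
            for e in flags.columns
        ]
    pct["ensemble"] = [
        100.0 * weights[flags[e].to_numpy()].sum() for e in flags.columns
    ]
    bands = pct.map(_band)

    if headline_elements is None:
        headline_elements = list(flags.columns[:3])
    any_headline = np.zeros(len(flags), dtype=bool)
    for e in headline_elements:
        any_headline |= flags[e].to_numpy()
    return ElementSummary(
        percentages=pct,
        bands=bands,
        headline_fraction=float(weights[any_headline].sum()),
    )
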