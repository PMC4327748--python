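"""Per-residue backbone geometry: phi, psi, kappa, alpha, TCO and accessibility.

All angle routines operate on the assignment :class:`~ssassign.pdbio.Layout`
and return ``None`` where the defining atoms do not exist (chain termini,
breaks), never NaN.  Angles are in degrees; solvent accessibility in A^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pdbio import Layout, Structure

__all__ = [
    "GeometryRow",
    "dihedral",
    "phi_psi",
    "kappa",
    "alpha_chirality",
    "tco",
    "accessibility",
    "compute_geometry",
]

#: van der Waals radii (A) used for accessible-surface integration
SASA_RADII = {"C": 1.80, "N": 1.65, "O": 1.40, "S": 1.85}
SASA_DEFAULT_RADIUS = 1.80
SASA_PROBE = 1.4
SASA_POINTS = 960

_EPS = 1e-10


@dataclass
class GeometryRow:
    """Geometric descriptors of one residue; ``None`` marks undefined values."""

    phi: float | None = None
    psi: float | None = None
    kappa: float | None = None
    alpha: float | None = None
    chirality: str = " "       # '+', '-', or ' '
    tco: float | None = None
    acc: float = 0.0


def dihedral(p1, p2, p3, p4) -> float | None:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in [-180, 180].

    IUPAC convention: positive for a clockwise rotation of p4 relative to p1
    when viewed from p2 towards p3.  Returns ``None`` when consecutive points
    coincide or the four points are collinear (the torsion is undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < _EPS:
        return None
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        return None
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return float(np.degrees(np.arctan2(y, x)))


def _angle(u: np.ndarray, v: np.ndarray) -> float | None:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        return None
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def phi_psi(lay: Layout) -> list[tuple[float | None, float | None]]:
    """Backbone torsions: phi(i) = C(i-1)-N-CA-C, psi(i) = N-CA-C-N(i+1)."""
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(lay.residues):
        phi = psi = None
        if lay.contiguous(i - 1, i):
            prev = lay.residues[i - 1]
            phi = dihedral(prev.coord("C"), res.coord("N"), res.coord("CA"), res.coord("C"))
        if lay.contiguous(i, i + 1):
            nxt = lay.residues[i + 1]
            psi = dihedral(res.coord("N"), res.coord("CA"), res.coord("C"), nxt.coord("N"))
        out.append((phi, psi))
    return out


def kappa(lay: Layout) -> list[float | None]:
    """Virtual bend angle at CA(i): between CA(i)-CA(i-2) and CA(i+2)-CA(i).

    0 for a straight CA trace; a bend (S) requires kappa > 70 degrees.
    """
    out: list[float | None] = []
    for i in range(len(lay)):
        if lay.contiguous(i - 2, i + 2):
            u = lay.residues[i].coord("CA") - lay.residues[i - 2].coord("CA")
            v = lay.residues[i + 2].coord("CA") - lay.residues[i].coord("CA")
            out.append(_angle(u, v))
        else:
            out.append(None)
    return out


def alpha_chirality(lay: Layout) -> list[tuple[float | None, str]]:
    """Virtual CA torsion CA(i-1)-CA(i)-CA(i+1)-CA(i+2) and its handedness."""
    out: list[tuple[float | None, str]] = []
    for i in range(len(lay)):
        if lay.contiguous(i - 1, i + 2):
            a = dihedral(*(lay.residues[i + k].coord("CA") for k in (-1, 0, 1, 2)))
        else:
            a = None
        if a is None:
            out.append((None, " "))
        else:
            out.append((a, "+" if a > 0 else "-"))
    return out


def tco(lay: Layout) -> list[float | None]:
    """Cosine of the angle between consecutive carbonyl C=O vectors."""
    out: list[float | None] = []
    for i in range(len(lay)):
        if lay.contiguous(i - 1, i):
            u = lay.residues[i].coord("O") - lay.residues[i].coord("C")
            v = lay.residues[i - 1].coord("O") - lay.residues[i - 1].coord("C")
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu < _EPS or nv < _EPS:
                out.append(None)
            else:
                out.append(float(np.dot(u, v) / (nu * nv)))
        else:
            out.append(None)
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def accessibility(
    structure: Structure,
    probe: float = SASA_PROBE,
    n_points: int = SASA_POINTS,
) -> dict[int, float]:
    """Solvent-accessible surface per residue by numerical sphere integration.

    Each heavy atom is inflated by the probe radius and sampled with a fixed
    quasi-uniform point set; a point is accessible when outside every
    neighbouring inflated sphere.  Hydrogens are ignored both as centres and
    as occluders.  Returns ``id(residue) -> area`` so callers can attach the
    values back to their residues.
    """
    centres: list[np.ndarray] = []
    radii: list[float] = []
    owner: list[int] = []
    residues = list(structure.residues())
    for res in residues:
        for atom in res.atoms.values():
            if atom.element == "H":
                continue
            centres.append(atom.coord)
            radii.append(SASA_RADII.get(atom.element, SASA_DEFAULT_RADIUS) + probe)
            owner.append(id(res))
    per_res: dict[int, float] = {id(r): 0.0 for r in residues}
    if not centres:
        return per_res
    xyz = np.array(centres)
    rad = np.array(radii)
    tree = cKDTree(xyz)
    unit = _sphere_points(n_points)
    max_rad = float(rad.max())
    for a in range(len(xyz)):
        pts = xyz[a] + rad[a] * unit
        neighbours = [b for b in tree.query_ball_point(xyz[a], rad[a] + max_rad) if b != a]
        free = np.ones(n_points, dtype=bool)
        for b in neighbours:
            d2 = np.sum((pts - xyz[b]) ** 2, axis=1)
            free &= d2 > rad[b] ** 2
            if not free.any():
                break
        area = 4.0 * np.pi * rad[a] ** 2 * free.sum() / n_points
        per_res[owner[a]] += area
    return per_res


def compute_geometry(lay: Layout, with_acc: bool = True) -> list[GeometryRow]:
    """All geometric descriptors for every residue in the layout."""
    pp = phi_psi(lay)
    kk = kappa(lay)
    ac = alpha_chirality(lay)
    tt = tco(lay)
    acc = accessibility(lay.structure) if with_acc else {}
    rows = []
    for i, res in enumerate(lay.residues):
        rows.append(
            GeometryRow(
                phi=pp[i][0],
                psi=pp[i][1],
                kappa=kk[i],
                alpha=ac[i][0],
                chirality=ac[i][1],
                tco=tt[i],
                acc=acc.get(id(res), 0.0),
            )
        )
    return rows
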