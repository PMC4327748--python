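"""Programmatic construction of test structures with known secondary structure.

Backbones are generated from internal coordinates (ideal peptide bond lengths
and angles, user-supplied phi/psi/omega torsions) by sequential torsion
placement, so every builder is deterministic and its true geometry is known by
construction.  These replace any need for downloaded coordinate files in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pdbio import Atom, Chain, Residue, Structure, write_pdb

__all__ = [
    "BackboneSpec",
    "build_backbone",
    "make_alpha_helix",
    "make_extended_strand",
    "make_antiparallel_hairpin",
    "write_pdb",
]

# ideal peptide geometry (Engh-Huber-like)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class BackboneSpec:
    n_residues: int
    phi: list[float] = field(default_factory=list)     # per residue, deg
    psi: list[float] = field(default_factory=list)
    omega: list[float] = field(default_factory=list)   # default 180 (trans)
    sequence: str = ""

    def __post_init__(self) -> None:
        n = self.n_residues
        if not self.phi:
            self.phi = [180.0] * n
        if not self.psi:
            self.psi = [180.0] * n
        if not self.omega:
            self.omega = [180.0] * n
        if not self.sequence:
            self.sequence = "A" * n
        if not (len(self.phi) == len(self.psi) == len(self.omega) == len(self.sequence) == n):
            raise ValueError("phi/psi/omega/sequence lengths must equal n_residues")


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: new atom D with |CD| = bond, angle BCD, torsion ABCD."""
    a, b, c = np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _carbonyl_oxygen(ca: np.ndarray, c: np.ndarray, n_next: np.ndarray) -> np.ndarray:
    """O in the CA-C-N(next) plane, opposite the external bisector of the two bonds."""
    u = ca - c
    u /= np.linalg.norm(u)
    v = n_next - c
    v /= np.linalg.norm(v)
    d = -(u + v)
    d /= np.linalg.norm(d)
    return c + B_C_O * d


def build_backbone(spec: BackboneSpec, chain_id: str = "A", start_seq: int = 1) -> Structure:
    """Generate an N/CA/C/O backbone from the torsion specification.

    phi(i) fixes the C(i-1)-N(i)-CA(i)-C(i) torsion (so phi of the first
    residue is unused), psi(i) fixes N-CA-C-N(i+1) (psi of the last residue
    only orients its carbonyl oxygen via a virtual next nitrogen).
    """
    n = spec.n_residues
    coords: list[dict[str, np.ndarray]] = [{} for _ in range(n)]
    # first residue: N at origin, CA on x, C in the xy-plane
    coords[0]["N"] = np.zeros(3)
    coords[0]["CA"] = np.array([B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - A_N_CA_C)
    coords[0]["C"] = coords[0]["CA"] + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        prev = coords[i - 1]
        coords[i]["N"] = place_atom(
            prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, spec.psi[i - 1]
        )
        coords[i]["CA"] = place_atom(
            prev["CA"], prev["C"], coords[i]["N"], B_N_CA, A_C_N_CA, spec.omega[i - 1]
        )
        coords[i]["C"] = place_atom(
            prev["C"], coords[i]["N"], coords[i]["CA"], B_CA_C, A_N_CA_C, spec.phi[i]
        )
        prev["O"] = _carbonyl_oxygen(prev["CA"], prev["C"], coords[i]["N"])
    # last residue's O from a virtual next N at its stated psi
    last = coords[n - 1]
    virtual_n = place_atom(last["N"], last["CA"], last["C"], B_C_N, A_CA_C_N, spec.psi[n - 1])
    last["O"] = _carbonyl_oxygen(last["CA"], last["C"], virtual_n)

    chain = Chain(chain_id)
    serial = 0
    for i in range(n):
        res = Residue(
            chain_id=chain_id,
            res_seq=start_seq + i,
            i_code=" ",
            res_name=ONE_TO_THREE.get(spec.sequence[i], "ALA"),
        )
        for name in ("N", "CA", "C", "O"):
            serial += 1
            res.atoms[name] = Atom(serial, name, " ", name[0], coords[i][name])
        chain.residues.append(res)
    return Structure(chains=[chain])


def make_alpha_helix(n: int) -> Structure:
    """Ideal right-handed alpha helix (phi = -57, psi = -47)."""
    return build_backbone(BackboneSpec(n, phi=[-57.0] * n, psi=[-47.0] * n))


def make_extended_strand(n: int) -> Structure:
    """Single extended strand (phi = -139, psi = 135); forms no H-bonds."""
    return build_backbone(BackboneSpec(n, phi=[-139.0] * n, psi=[135.0] * n))


# Exactly periodic extended strand: phi/psi solved (with the bond geometry
# above) so that residue i+2 is a pure translation of residue i.  This lets a
# single rigid transform tile an ideal antiparallel pairing for any length.
PHI_SHEET = -138.70509027
PSI_SHEET = 136.15531708

# Rigid placement of the hairpin's partner strand: a 180-degree rotation about
# an axis perpendicular to the strand direction, solved once by minimising the
# Kabsch-Sander energies of the facing CO/NH pairs (each bond comes out near
# -3.8 kcal/mol with N-O distances of 2.9 A) while keeping all other
# inter-strand atom contacts above 2.7 A.  See docs/methods.md.
_HAIRPIN_ROT = np.array(
    [
        [-0.765773778656, -0.328823649320, -0.552689359016],
        [-0.328823649320, -0.538373664007, 0.775905152420],
        [-0.552689359016, 0.775905152420, 0.304147442663],
    ]
)
_HAIRPIN_CENTRE6 = np.array([10.372594142484, 5.136472680790, 3.227453209691])


def _periodic_strand(n: int) -> list[dict[str, np.ndarray]]:
    s = build_backbone(BackboneSpec(n, phi=[PHI_SHEET] * n, psi=[PSI_SHEET] * n))
    return [
        {name: res.atoms[name].coord.copy() for name in ("N", "CA", "C", "O")}
        for res in s.chains[0].residues
    ]


def make_antiparallel_hairpin(strand_len: int) -> Structure:
    """Two-stranded antiparallel beta hairpin with a short two-residue linker.

    Both strands use the exactly periodic extended torsions; the second strand
    is the image of the first under a frozen two-fold rotation placed so that
    facing residues form the reciprocal CO(i)->NH(j) / CO(j)->NH(i) bond
    pattern at roughly 2.9 A N-O separation.  The linker residues bridge the
    strand ends geometrically; their own assignment is unconstrained.
    """
    if strand_len < 3:
        raise ValueError("strand_len must be >= 3")
    n = strand_len
    strand1 = _periodic_strand(n)
    period = strand1[2]["CA"] - strand1[0]["CA"]
    # slide the two-fold axis along the strand so the bonded pairs centre on
    # the strands: pairing (i, n-i) needs the axis at lattice position
    # (m - 6) / 4 periods from the length-6 reference, m = n rounded down even
    m = n if n % 2 == 0 else n - 1
    centre = _HAIRPIN_CENTRE6 + ((m - 6) / 4.0) * period
    strand2 = [
        {k: centre + _HAIRPIN_ROT @ (p[k] - centre) for k in p} for p in strand1
    ]

    # linker: six backbone atoms spaced evenly along an arc over the turn
    p_start = strand1[-1]["C"]
    p_end = strand2[0]["N"]
    gap = p_end - p_start
    normal = np.cross(gap, period)
    nn = np.linalg.norm(normal)
    normal = normal / nn if nn > 1e-9 else np.array([0.0, 0.0, 1.0])
    names = ("N", "CA", "C")
    linker: list[dict[str, np.ndarray]] = [{}, {}]
    for k in range(6):
        t = (k + 1) / 7.0
        arch = 1.6 * np.sin(np.pi * t)
        pos = p_start + t * gap + arch * normal
        linker[k // 3][names[k % 3]] = pos
    for r in linker:
        r["O"] = r["C"] + 1.23 * normal

    chain = Chain("A")
    serial = 0
    seq = 0
    for block in (strand1, linker, strand2):
        for coords in block:
            seq += 1
            res = Residue(chain_id="A", res_seq=seq, i_code=" ", res_name="ALA")
            for name in ("N", "CA", "C", "O"):
                serial += 1
                res.atoms[name] = Atom(serial, name, " ", name[0], coords[name].copy())
            chain.residues.append(res)
    return Structure(chains=[chain])
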