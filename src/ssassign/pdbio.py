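"""Reading and writing protein coordinates in PDB format.

The parser builds a light coordinate hierarchy (Structure -> chains ->
residues -> atoms) from the fixed-column wwPDB v3.3 record layout, keeps
HELIX/SHEET header annotations, and offers the pre-processing steps the
assignment pipeline needs: amide-hydrogen detection and modelling, chain-break
detection, chain selection and renumbering.

Only the first MODEL of a multi-model file is read.  For alternate locations
the first conformer (alt_loc ' ' or 'A') is kept, so every residue has a single
deterministic set of coordinates.  Waters are dropped; other HETATM residues
inside a polymer (e.g. selenomethionine) are retained and mapped to a
one-letter code where a standard mapping exists, 'X' otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1_extended as _3TO1

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SSRecordSet",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
    "detect_hydrogens",
    "place_amide_hydrogens",
    "detect_chain_breaks",
    "select_chain",
    "renumber_residues",
]

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: maximum peptide-bond C(i)-N(i+1) distance before a chain break is flagged
CHAIN_BREAK_CN = 2.5


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be interpreted as a coordinate file."""


@dataclass
class Atom:
    serial: int
    name: str
    alt_loc: str
    element: str
    coord: np.ndarray          # (3,) float, Angstrom
    occupancy: float = 1.0

    @property
    def x(self) -> float:
        return float(self.coord[0])

    @property
    def y(self) -> float:
        return float(self.coord[1])

    @property
    def z(self) -> float:
        return float(self.coord[2])


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    i_code: str                # ' ' when absent
    res_name: str              # 3-letter code
    atoms: dict[str, Atom] = field(default_factory=dict)
    is_het: bool = False
    # original identifiers survive renumbering for "absolute" reporting
    orig_res_seq: int | None = None
    orig_i_code: str | None = None
    no_donor: bool = False     # amide H could not be modelled

    def __post_init__(self) -> None:
        if self.orig_res_seq is None:
            self.orig_res_seq = self.res_seq
        if self.orig_i_code is None:
            self.orig_i_code = self.i_code

    @property
    def is_standard_aa(self) -> bool:
        return self.res_name in STANDARD_AA3

    @property
    def one_letter(self) -> str:
        if self.res_name in STANDARD_AA3:
            return _3TO1[self.res_name]
        return _3TO1.get(self.res_name, "X") if self.res_name in _3TO1 else "X"

    @property
    def has_backbone(self) -> bool:
        return all(n in self.atoms for n in ("N", "CA", "C", "O"))

    @property
    def has_amide_h(self) -> bool:
        return "H" in self.atoms

    def coord(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name].coord

    @property
    def label(self) -> str:
        """Absolute residue reference: chain id + original number + icode."""
        icode = (self.orig_i_code or " ").strip()
        return f"{self.chain_id}{self.orig_res_seq}{icode}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class SSRecordSet:
    """HELIX/SHEET ranges from a PDB header; ends are inclusive."""

    helices: list[tuple[str, tuple[int, str], tuple[int, str]]] = field(default_factory=list)
    strands: list[tuple[str, tuple[int, str], tuple[int, str]]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.helices or self.strands)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    #: (chain_id, residue position i) meaning "break between residue i and i+1"
    chain_breaks: set[tuple[str, int]] = field(default_factory=set)
    breaks_detected: bool = False

    @property
    def has_hydrogens(self) -> bool:
        return detect_hydrogens(self)

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(
            f"chain {chain_id!r} not present; available chains: "
            + ", ".join(repr(c) for c in self.chain_ids())
        )


def _infer_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # PDB atom names start with the element, possibly prefixed by a digit (1HB)
    first = stripped.lstrip("0123456789")
    if first[:1] in "HDQ":
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ("FE", "ZN", "MG", "SE", "CL", "BR", "NA"):
        return stripped[:2].capitalize()
    return first[:1].upper()


def parse_pdb(text: str) -> tuple[Structure, SSRecordSet]:
    """Parse PDB-format text into a Structure plus HELIX/SHEET records.

    Raises :class:`PDBParseError` when no ATOM record is present or a
    coordinate field cannot be read (the error names the offending line).
    """
    structure = Structure()
    records = SSRecordSet()
    current: Residue | None = None
    chain: Chain | None = None
    model_seen = False
    in_first_model = True
    n_atoms = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if model_seen:
                in_first_model = False
            model_seen = True
            continue
        if rec == "ENDMDL":
            in_first_model = False
            continue
        if rec == "HELIX ":
            try:
                records.helices.append((
                    line[19],
                    (int(line[21:25]), line[25] if len(line) > 25 else " "),
                    (int(line[33:37]), line[37] if len(line) > 37 else " "),
                ))
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"malformed HELIX record at line {lineno}") from exc
            continue
        if rec == "SHEET ":
            try:
                records.strands.append((
                    line[21],
                    (int(line[22:26]), line[26] if len(line) > 26 else " "),
                    (int(line[33:37]), line[37] if len(line) > 37 else " "),
                ))
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"malformed SHEET record at line {lineno}") from exc
            continue
        if rec == "TER   " or rec.strip() == "TER":
            chain = None
            current = None
            continue
        if rec not in ("ATOM  ", "HETATM") or not in_first_model:
            continue

        line = line.ljust(80)
        res_name = line[17:20].strip()
        if res_name in WATER_NAMES:
            continue
        alt_loc = line[16]
        if alt_loc not in (" ", "A"):
            continue
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = n_atoms + 1
        name = line[12:16].strip()
        chain_id = line[21]
        try:
            res_seq = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"malformed residue number at line {lineno}") from exc
        i_code = line[26]
        try:
            coord = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])], dtype=float
            )
        except ValueError as exc:
            raise PDBParseError(f"malformed coordinate field at line {lineno}") from exc
        if not np.all(np.isfinite(coord)):
            raise PDBParseError(f"non-finite coordinate at line {lineno}")
        try:
            occupancy = float(line[54:60])
        except ValueError:
            occupancy = 1.0
        element = line[76:78].strip() or _infer_element(name)

        if chain is None or chain.chain_id != chain_id:
            chain = None
            for existing in structure.chains:
                if existing.chain_id == chain_id:
                    chain = existing
                    break
            if chain is None:
                chain = Chain(chain_id)
                structure.chains.append(chain)
            current = chain.residues[-1] if chain.residues else None
        key = (res_seq, i_code, res_name)
        if (
            current is None
            or (current.res_seq, current.i_code, current.res_name) != key
        ):
            current = Residue(
                chain_id=chain_id,
                res_seq=res_seq,
                i_code=i_code,
                res_name=res_name,
                is_het=(rec == "HETATM"),
            )
            chain.residues.append(current)
        if name not in current.atoms:
            current.atoms[name] = Atom(serial, name, alt_loc, element, coord, occupancy)
        n_atoms += 1

    if n_atoms == 0:
        raise PDBParseError("no ATOM records found in input")
    return structure, records


def write_pdb(structure: Structure) -> str:
    """Serialise a Structure to PDB-format text (ATOM records, %8.3f coords)."""
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms.values():
                serial += 1
                name = atom.name
                # standard PDB justification: element starts in column 14
                padded = f" {name:<3s}" if len(name) < 4 else name
                rec = "HETATM" if res.is_het else "ATOM  "
                lines.append(
                    f"{rec}{serial:5d} {padded}{atom.alt_loc}{res.res_name:>3s} "
                    f"{res.chain_id}{res.res_seq:4d}{res.i_code}   "
                    f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}"
                )
        if chain.residues:
            serial += 1
            last = chain.residues[-1]
            lines.append(
                f"TER   {serial:5d}      {last.res_name:>3s} "
                f"{last.chain_id}{last.res_seq:4d}{last.i_code}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def detect_hydrogens(structure: Structure) -> bool:
    """True iff at least one residue that could carry a backbone amide H has one.

    Chain-first residues and prolines never carry the amide hydrogen used by
    the energy model, so they do not count as evidence.
    """
    for chain in structure.chains:
        for pos, res in enumerate(chain.residues):
            if pos == 0 or res.res_name == "PRO":
                continue
            if res.is_standard_aa and res.has_amide_h:
                return True
    return False


def detect_chain_breaks(structure: Structure) -> Structure:
    """Flag breaks between consecutive residues of a chain.

    A break is recorded when the peptide C(i)-N(i+1) distance exceeds
    ``CHAIN_BREAK_CN`` (2.5 A) or either atom is missing.  Turn, bridge and
    H-bond logic downstream never spans a break.
    """
    structure.chain_breaks = set()
    for chain in structure.chains:
        for pos in range(len(chain.residues) - 1):
            a, b = chain.residues[pos], chain.residues[pos + 1]
            if "C" not in a.atoms or "N" not in b.atoms:
                structure.chain_breaks.add((chain.chain_id, pos))
                continue
            dist = float(np.linalg.norm(a.coord("C") - b.coord("N")))
            if dist > CHAIN_BREAK_CN:
                structure.chain_breaks.add((chain.chain_id, pos))
    structure.breaks_detected = True
    return structure


def place_amide_hydrogens(structure: Structure) -> Structure:
    """Model missing backbone amide hydrogens.

    H is placed 1.0 A from N along the direction of the previous residue's
    C->O vector reversed: ``H = N(i) + 1.0 * unit(C(i-1) - O(i-1))``, i.e. the
    N-H bond is antiparallel to the preceding carbonyl C=O.  Chain-first
    residues, residues following a chain break, and prolines are skipped;
    residues whose predecessor lacks C or O are flagged ``no_donor``.
    Idempotent: residues already carrying an "H" atom are untouched.
    """
    if not structure.breaks_detected:
        detect_chain_breaks(structure)
    for chain in structure.chains:
        for pos, res in enumerate(chain.residues):
            if pos == 0 or res.res_name == "PRO" or res.has_amide_h:
                continue
            if (chain.chain_id, pos - 1) in structure.chain_breaks:
                continue
            if "N" not in res.atoms:
                res.no_donor = True
                continue
            prev = chain.residues[pos - 1]
            if "C" not in prev.atoms or "O" not in prev.atoms:
                res.no_donor = True
                continue
            direction = prev.coord("C") - prev.coord("O")
            norm = float(np.linalg.norm(direction))
            if norm < 1e-9:
                res.no_donor = True
                continue
            h = res.coord("N") + direction / norm
            res.atoms["H"] = Atom(0, "H", " ", "H", h)
    return structure


def select_chain(structure: Structure, chain_id: str) -> Structure:
    """Return a single-chain Structure preserving residue identity."""
    chain = structure.get_chain(chain_id)
    out = Structure(chains=[chain])
    if structure.breaks_detected:
        out.chain_breaks = {b for b in structure.chain_breaks if b[0] == chain_id}
        out.breaks_detected = True
    return out


def renumber_residues(structure: Structure, start: int = 1) -> Structure:
    """Renumber a single chain sequentially from ``start``.

    Insertion codes are cleared in the working numbering; the original
    identifiers remain available on each residue for absolute reporting.
    """
    if len(structure.chains) != 1:
        raise ValueError("renumbering requires a single-chain structure")
    for offset, res in enumerate(structure.chains[0].residues):
        res.res_seq = start + offset
        res.i_code = " "
    return structure


@dataclass
class Layout:
    """Flat, assignment-ready view of a structure.

    Holds the residues that can participate in assignment (complete N, CA, C,
    O backbone) in file order, with a segment id per residue: two residues
    share a segment iff they are consecutive in the same chain with no break
    and no excluded residue between them.  Sequential indices are 1-based.
    """

    structure: Structure
    residues: list[Residue] = field(default_factory=list)
    chain_ids: list[str] = field(default_factory=list)
    seg: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def contiguous(self, i: int, j: int) -> bool:
        """True iff residues i..j (inclusive, 0-based) are one unbroken run."""
        if i < 0 or j >= len(self.residues):
            return False
        return self.seg[i] == self.seg[j]

    def ca_array(self) -> np.ndarray:
        return np.array([r.coord("CA") for r in self.residues])


def layout(structure: Structure) -> Layout:
    """Build the assignment layout (detecting chain breaks if needed)."""
    if not structure.breaks_detected:
        detect_chain_breaks(structure)
    lay = Layout(structure)
    seg_counter = -1
    for chain in structure.chains:
        prev_pos: int | None = None
        for pos, res in enumerate(chain.residues):
            if not res.has_backbone:
                prev_pos = None
                continue
            broken = (
                prev_pos is None
                or pos != prev_pos + 1
                or (chain.chain_id, pos - 1) in structure.chain_breaks
            )
            if broken:
                seg_counter += 1
            lay.residues.append(res)
            lay.chain_ids.append(chain.chain_id)
            lay.seg.append(seg_counter)
            prev_pos = pos
        seg_counter += 1  # never merge segments across chains
    return lay
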