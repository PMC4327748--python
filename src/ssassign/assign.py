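"""Kabsch-Sander secondary structure assignment.

The pipeline follows the classic hydrogen-bond formalism: an electrostatic
bond energy between backbone C=O acceptors and N-H donors defines bonds
(E < -0.5 kcal/mol), bonds define n-turns and beta bridges, overlapping turns
nucleate helices, consecutive bridges form ladders and connected ladders form
sheets.  One deliberate departure from the classic dictionary: helical states
(H, G, I alike) are only assigned for runs of at least four consecutive
residues; shorter candidate runs fall back to H-bonded turns (T).

Summary states: H (alpha helix), G (3_10 helix), I (pi helix), E (extended
strand in a ladder), B (isolated beta bridge), T (H-bonded turn), S (bend),
' ' (none), with priority H > B > E > G > I > T > S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GeometryRow, compute_geometry
from .pdbio import Chain, Layout, Residue, SSRecordSet, Structure, layout, place_amide_hydrogens

__all__ = [
    "HBondTable",
    "SSAssignment",
    "hbond_energy",
    "build_hbond_table",
    "assign_turns",
    "assign_helices",
    "find_bridges",
    "build_ladders_sheets",
    "assign_bends",
    "assign_summary",
    "assign_secondary_structure",
    "simplify",
    "map_from_header_records",
    "HELICAL",
    "EXTENDED",
    "UNSTRUCTURED",
]

#: q1 * q2 * f = 0.42 e * 0.20 e * 332, giving E in kcal/mol
KS_COUPLING = 27.888
#: bonds must be at least this strong (kcal/mol) to count
HB_CUTOFF = -0.5
#: energies are clamped below at this value
ENERGY_FLOOR = -9.9
#: any defining distance below this (A) marks a clash, not a bond
CLASH_DISTANCE = 0.5
#: CA-CA prefilter beyond which the energy cannot reach the cutoff
CA_PREFILTER = 9.0
#: minimum length of a helical run (applies to G, H and I alike)
MIN_HELIX_RUN = 4
#: bend threshold on the virtual CA angle, strict inequality
BEND_KAPPA = 70.0
#: minimum sequence separation of bridge partners
MIN_BRIDGE_SEP = 3

# simplified 3-state codes used when painting structure onto alignments
HELICAL = "H"
EXTENDED = "E"
UNSTRUCTURED = "-"

_SIMPLIFY = {
    "H": HELICAL, "G": HELICAL, "I": HELICAL,
    "E": EXTENDED,
    "B": UNSTRUCTURED, "T": UNSTRUCTURED, "S": UNSTRUCTURED, " ": UNSTRUCTURED,
}


def hbond_energy(acceptor: Residue, donor: Residue) -> float | None:
    """Electrostatic H-bond energy (kcal/mol) of CO(acceptor) <- NH(donor).

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN), clamped below at
    -9.9 kcal/mol.  Returns ``None`` when no bond is possible: the donor is a
    proline or lacks an amide H, an atom is missing, or any defining distance
    is below the 0.5 A clash guard.
    """
    if donor.res_name == "PRO" or "H" not in donor.atoms or "N" not in donor.atoms:
        return None
    if "C" not in acceptor.atoms or "O" not in acceptor.atoms:
        return None
    c, o = acceptor.coord("C"), acceptor.coord("O")
    n, h = donor.coord("N"), donor.coord("H")
    r_on = float(np.linalg.norm(o - n))
    r_ch = float(np.linalg.norm(c - h))
    r_oh = float(np.linalg.norm(o - h))
    r_cn = float(np.linalg.norm(c - n))
    if min(r_on, r_ch, r_oh, r_cn) < CLASH_DISTANCE:
        return None
    e = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, ENERGY_FLOOR)


class HBondTable:
    """Per-residue best hydrogen-bond partners.

    For residue i, ``acceptors[i]`` holds up to two (j, E) pairs meaning
    "NH(i) donates to CO(j)" and ``donors[i]`` up to two (j, E) pairs meaning
    "CO(i) accepts from NH(j)", each sorted by ascending energy (ties broken
    towards the earlier-sequence partner).  The bond predicate additionally
    requires E < -0.5 kcal/mol and a sequence separation of at least 2.
    """

    def __init__(self, n: int):
        self.n = n
        self.acceptors: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        self.donors: list[list[tuple[int, float]]] = [[] for _ in range(n)]

    @staticmethod
    def _insert(slots: list[tuple[int, float]], j: int, e: float) -> None:
        slots.append((j, e))
        slots.sort(key=lambda item: (item[1], item[0]))
        del slots[2:]

    def add(self, acceptor: int, donor: int, e: float) -> None:
        self._insert(self.donors[acceptor], donor, e)
        self._insert(self.acceptors[donor], acceptor, e)

    def hb(self, i: int, j: int) -> bool:
        """True iff CO(i) accepts from NH(j) with a qualifying bond."""
        if abs(i - j) < 2:
            return False
        return any(p == j and e < HB_CUTOFF for p, e in self.donors[i])

    def n_bonds(self) -> int:
        return sum(1 for row in self.donors for _, e in row if e < HB_CUTOFF)


def build_hbond_table(lay: Layout) -> HBondTable:
    """Compute directed bond energies for all residue pairs within 9 A CA-CA."""
    table = HBondTable(len(lay))
    if len(lay) < 2:
        return table
    cas = lay.ca_array()
    tree = cKDTree(cas)
    for i, j in tree.query_pairs(CA_PREFILTER):
        for a, d in ((i, j), (j, i)):
            # the donor's modelled H is constructed from the preceding
            # residue's carbonyl, so the bond back onto that same carbonyl
            # (donor = acceptor + 1) is geometrically meaningless and skipped
            if d == a + 1:
                continue
            e = hbond_energy(lay.residues[a], lay.residues[d])
            if e is not None:
                table.add(a, d, e)
    return table


@dataclass
class SSAssignment:
    """Full per-residue assignment: summary states plus all report columns."""

    layout: Layout
    summary: list[str]
    turns: dict[int, list[str]]            # n -> per-residue mark
    bp1: list[int]                         # sequential partner indices, 0 = none
    bp2: list[int]
    ladder1: list[str]
    ladder2: list[str]
    sheet: list[str]
    geometry: list[GeometryRow]
    hbonds: HBondTable

    def __len__(self) -> int:
        return len(self.summary)

    @property
    def residues(self) -> list[Residue]:
        return self.layout.residues

    def summary_by_key(self) -> dict[tuple[str, int, str], str]:
        """Summaries keyed by (chain id, residue number, insertion code)."""
        return {
            (r.chain_id, r.res_seq, r.i_code): s
            for r, s in zip(self.layout.residues, self.summary)
        }


def assign_turns(table: HBondTable, lay: Layout) -> tuple[dict[int, list[bool]], dict[int, list[str]], list[bool]]:
    """n-turn flags (n = 3, 4, 5) from the bond predicate HB(i, i+n).

    Returns (turn_start flags per n, display marks per n, per-residue
    turn-interior flag used as the T candidate).  A turn requires the whole
    i..i+n span to lie in one unbroken segment.
    """
    n_res = len(lay)
    starts: dict[int, list[bool]] = {}
    marks: dict[int, list[str]] = {}
    t_flag = [False] * n_res
    for n in (3, 4, 5):
        st = [False] * n_res
        for i in range(n_res - n):
            if lay.contiguous(i, i + n) and table.hb(i, i + n):
                st[i] = True
        starts[n] = st
        mk = [" "] * n_res
        for i in range(n_res):
            is_start = st[i]
            is_end = i - n >= 0 and st[i - n]
            if is_start and is_end:
                mk[i] = "X"
            elif is_start:
                mk[i] = ">"
            elif is_end:
                mk[i] = "<"
            else:
                for k in range(max(0, i - n + 1), i):
                    if st[k]:
                        mk[i] = str(n)
                        break
        marks[n] = mk
        for i in range(n_res):
            if st[i]:
                for k in range(i + 1, i + n):
                    t_flag[k] = True
    return starts, marks, t_flag


def assign_helices(turn_starts: dict[int, list[bool]], n_res: int) -> list[str]:
    """Helix candidates from overlapping turns, with the minimum-run rule.

    A residue i begins an n-helix when n-turn(i-1) and n-turn(i) hold; the
    helix covers i..i+n-1.  Candidate runs shorter than four residues are
    dropped (they surface as turns instead), and when a residue qualifies for
    several helix types the priority is H > G > I.
    """
    result = [" "] * n_res
    for code, n in (("I", 5), ("G", 3), ("H", 4)):  # later types overwrite
        st = turn_starts[n]
        member = [False] * n_res
        for i in range(1, n_res):
            if st[i] and st[i - 1]:
                for k in range(i, min(i + n, n_res)):
                    member[k] = True
        i = 0
        while i < n_res:
            if member[i]:
                j = i
                while j < n_res and member[j]:
                    j += 1
                if j - i >= MIN_HELIX_RUN:
                    for k in range(i, j):
                        result[k] = code
                i = j
            else:
                i += 1
    # re-impose priority where an H run overwrote part of a G/I run and vice
    # versa: H was written last, so H already wins; G beat I by write order
    return result


def find_bridges(table: HBondTable, lay: Layout) -> list[tuple[int, int, str]]:
    """Beta bridges: (i, j, 'parallel'|'antiparallel') with i < j.

    Parallel:      HB(i-1, j) and HB(j, i+1), or HB(j-1, i) and HB(i, j+1)
    Antiparallel:  HB(i, j) and HB(j, i),     or HB(i-1, j+1) and HB(j-1, i+1)
    Partners must be at least MIN_BRIDGE_SEP apart in sequence and each must
    sit strictly inside an unbroken segment (i-1..i+1 and j-1..j+1).
    """
    n_res = len(lay)
    candidates: set[tuple[int, int]] = set()
    for i in range(n_res):
        for j, e in table.donors[i] + table.acceptors[i]:
            if e < HB_CUTOFF:
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        a, b = i + di, j + dj
                        if 0 <= a < n_res and 0 <= b < n_res and b - a >= MIN_BRIDGE_SEP:
                            candidates.add((a, b))
    bridges = []
    for i, j in sorted(candidates):
        if not (lay.contiguous(i - 1, i + 1) and lay.contiguous(j - 1, j + 1)):
            continue
        parallel = (table.hb(i - 1, j) and table.hb(j, i + 1)) or (
            table.hb(j - 1, i) and table.hb(i, j + 1)
        )
        antiparallel = (table.hb(i, j) and table.hb(j, i)) or (
            table.hb(i - 1, j + 1) and table.hb(j - 1, i + 1)
        )
        if parallel:
            bridges.append((i, j, "parallel"))
        elif antiparallel:
            bridges.append((i, j, "antiparallel"))
    return bridges


def build_ladders_sheets(
    bridges: list[tuple[int, int, str]], n_res: int
) -> tuple[list[str], list[int], list[int], list[str], list[str], list[str]]:
    """Group bridges into ladders and ladders into sheets.

    Consecutive bridges of one type extend a ladder: (i+1, j+1) for parallel,
    (i+1, j-1) for antiparallel.  Residues of ladders with >= 2 bridges are
    'E'; an isolated bridge leaves both partners 'B'.  Ladder letters cycle
    a-z (lower case parallel, upper case antiparallel); sheets are connected
    components of ladders sharing a residue, labelled A-Z.

    Returns (bridge_state, bp1, bp2, ladder1, ladder2, sheet_label) arrays.
    """
    ladder_of: dict[tuple[int, int], int] = {}
    ladders: list[dict] = []
    for i, j, kind in sorted(bridges):
        prev = (i - 1, j + 1) if kind == "antiparallel" else (i - 1, j - 1)
        lad = None
        if prev in ladder_of and ladders[ladder_of[prev]]["kind"] == kind:
            lad = ladder_of[prev]
        if lad is None:
            lad = len(ladders)
            ladders.append({"kind": kind, "bridges": []})
        ladders[lad]["bridges"].append((i, j))
        ladder_of[(i, j)] = lad

    # sheets: union-find over ladders sharing any residue
    parent = list(range(len(ladders)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    res_ladders: dict[int, list[int]] = {}
    for idx, lad in enumerate(ladders):
        for i, j in lad["bridges"]:
            for r in (i, j):
                for other in res_ladders.setdefault(r, []):
                    ra, rb = find(other), find(idx)
                    if ra != rb:
                        parent[rb] = ra
                if idx not in res_ladders[r]:
                    res_ladders[r].append(idx)

    sheet_ids: dict[int, int] = {}
    for idx in range(len(ladders)):
        root = find(idx)
        if root not in sheet_ids:
            sheet_ids[root] = len(sheet_ids)

    state = [" "] * n_res
    bp1 = [0] * n_res
    bp2 = [0] * n_res
    lad1 = [" "] * n_res
    lad2 = [" "] * n_res
    sheet = [" "] * n_res
    for idx, lad in enumerate(ladders):
        letter = chr(ord("a") + idx % 26)
        if lad["kind"] == "antiparallel":
            letter = letter.upper()
        code = "E" if len(lad["bridges"]) >= 2 else "B"
        sheet_letter = chr(ord("A") + sheet_ids[find(idx)] % 26)
        for i, j in lad["bridges"]:
            for r, partner in ((i, j), (j, i)):
                if state[r] == " " or code == "E":
                    state[r] = code
                if bp1[r] == 0:
                    bp1[r] = partner + 1
                    lad1[r] = letter
                elif bp2[r] == 0 and bp1[r] != partner + 1:
                    bp2[r] = partner + 1
                    lad2[r] = letter
                sheet[r] = sheet_letter
    return state, bp1, bp2, lad1, lad2, sheet


def assign_bends(geometry: list[GeometryRow]) -> list[bool]:
    """Bend candidates: kappa strictly greater than 70 degrees."""
    return [g.kappa is not None and g.kappa > BEND_KAPPA for g in geometry]


def assign_summary(
    helix: list[str],
    bridge_state: list[str],
    t_flag: list[bool],
    bend: list[bool],
) -> list[str]:
    """Final per-residue summary by priority H > B > E > G > I > T > S > ' '."""
    out = []
    for h, b, t, s in zip(helix, bridge_state, t_flag, bend):
        if h == "H":
            out.append("H")
        elif b in ("B", "E"):
            out.append(b)
        elif h in ("G", "I"):
            out.append(h)
        elif t:
            out.append("T")
        elif s:
            out.append("S")
        else:
            out.append(" ")
    return out


def assign_secondary_structure(
    structure: Structure, with_acc: bool = True
) -> SSAssignment:
    """Run the full pipeline on a structure (hydrogens are placed if absent)."""
    place_amide_hydrogens(structure)
    lay = layout(structure)
    table = build_hbond_table(lay)
    turn_starts, turn_marks, t_flag = assign_turns(table, lay)
    helix = assign_helices(turn_starts, len(lay))
    bridges = find_bridges(table, lay)
    bridge_state, bp1, bp2, lad1, lad2, sheet = build_ladders_sheets(bridges, len(lay))
    geometry = compute_geometry(lay, with_acc=with_acc)
    bend = assign_bends(geometry)
    summary = assign_summary(helix, bridge_state, t_flag, bend)
    return SSAssignment(
        layout=lay,
        summary=summary,
        turns=turn_marks,
        bp1=bp1,
        bp2=bp2,
        ladder1=lad1,
        ladder2=lad2,
        sheet=sheet,
        geometry=geometry,
        hbonds=table,
    )


def simplify(summary: list[str] | SSAssignment) -> list[str]:
    """Collapse 8-state summaries to helical / extended / unstructured.

    H, G and I map to helical ('H'), E maps to extended ('E'), everything
    else (B, T, S, none) to unstructured ('-').
    """
    if isinstance(summary, SSAssignment):
        summary = summary.summary
    return [_SIMPLIFY[s] for s in summary]


def map_from_header_records(records: SSRecordSet, chain: Chain) -> list[str]:
    """3-state labels from HELIX/SHEET header ranges (helical-first overlap).

    Ranges are resolved against the chain's residue numbering (residue number
    plus insertion code, inclusive ends); a range referencing an absent
    residue is clipped with a warning.
    """
    labels = [UNSTRUCTURED] * len(chain.residues)
    index = {
        (r.res_seq, r.i_code if r.i_code.strip() else " "): pos
        for pos, r in enumerate(chain.residues)
    }

    def positions(start: tuple[int, str], end: tuple[int, str], what: str):
        skey = (start[0], start[1] if start[1].strip() else " ")
        ekey = (end[0], end[1] if end[1].strip() else " ")
        if skey not in index or ekey not in index:
            present = [k for k in (skey, ekey) if k in index]
            warnings.warn(
                f"{what} record {start}-{end} references residues absent from "
                f"chain {chain.chain_id}; range clipped"
            )
            if not present:
                return range(0)
            pos = index[present[0]]
            return range(pos, pos + 1)
        return range(index[skey], index[ekey] + 1)

    # strands first so that overlapping helix ranges take precedence
    for chain_id, start, end in records.strands:
        if chain_id != chain.chain_id:
            continue
        for pos in positions(start, end, "SHEET"):
            labels[pos] = EXTENDED
    for chain_id, start, end in records.helices:
        if chain_id != chain.chain_id:
            continue
        for pos in positions(start, end, "HELIX"):
            labels[pos] = HELICAL
    return labels
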