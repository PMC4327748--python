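"""Serialisation of assignments to text reports, and parsing them back.

Two layouts are supported:

* the classic fixed-column DSSP per-residue record (summary state at column
  17, relative H-bond partner offsets, sequential residue indices, '!' rows
  at chain breaks), readable by third-party DSSP parsers;
* a "wide" whitespace-delimited layout carrying the same information but
  referencing residues by their absolute names (chain id + residue number +
  insertion code, e.g. ``A52`` or ``A52A``), which is easier to inspect and
  to post-process with standard column tools.

Undefined angles are rendered as 360.0 (the DSSP convention); missing H-bond
partners as offset 0 with energy 0.0.
"""

from __future__ import annotations

from .assign import SSAssignment

__all__ = [
    "write_dssp_format",
    "write_wide_format",
    "parse_dssp_format",
    "parse_wide_format",
    "ReportFormatError",
]

DSSP_HEADER_COLS = (
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA"
)

WIDE_HEADER_COLS = (
    "RES AA SS T3 T4 T5 BEND CHIR LAD1 LAD2 BP1 BP2 SHEET ACC "
    "NHO1 OHN1 NHO2 OHN2 TCO KAPPA ALPHA PHI PSI X-CA Y-CA Z-CA"
)


class ReportFormatError(ValueError):
    """Raised when report text cannot be parsed."""


def _angle(value: float | None) -> float:
    return 360.0 if value is None else value


def _report_indices(a: SSAssignment) -> list[int]:
    """Sequential report index per residue; break rows consume an index."""
    indices = []
    idx = 0
    for pos in range(len(a)):
        if pos > 0 and a.layout.seg[pos] != a.layout.seg[pos - 1]:
            idx += 1  # the '!' break row
        idx += 1
        indices.append(idx)
    return indices


def _hbond_slots(a: SSAssignment, pos: int, indices: list[int]):
    """Four (offset, energy) report fields: N-H->O x2 and O->H-N x2 interleaved."""
    acc = list(a.hbonds.acceptors[pos])  # NH(pos) donates to CO(j)
    don = list(a.hbonds.donors[pos])     # CO(pos) accepts from NH(j)
    acc += [(None, 0.0)] * (2 - len(acc))
    don += [(None, 0.0)] * (2 - len(don))
    slots = []
    for j, e in (acc[0], don[0], acc[1], don[1]):
        if j is None:
            slots.append((0, 0.0, None))
        else:
            slots.append((indices[j] - indices[pos], e, j))
    return slots


def write_dssp_format(a: SSAssignment) -> str:
    """Classic fixed-column DSSP-style report for an assignment."""
    lay = a.layout
    n_chains = len({c for c in lay.chain_ids})
    indices = _report_indices(a)
    lines = [
        "==== SECONDARY STRUCTURE ASSIGNMENT BY HYDROGEN BOND AND GEOMETRICAL ANALYSIS ====",
        f"{len(lay):5d}{n_chains:5d}{a.hbonds.n_bonds():5d}    "
        "TOTAL NUMBER OF RESIDUES, NUMBER OF CHAINS, TOTAL NUMBER OF H-BONDS",
        "    0    0    0    0    0    0    0    0    0    0    0    "
        "HISTOGRAMS NOT COMPUTED (PLACEHOLDER)",
        DSSP_HEADER_COLS,
    ]
    for pos, res in enumerate(lay.residues):
        if pos > 0 and lay.seg[pos] != lay.seg[pos - 1]:
            star = "*" if lay.chain_ids[pos] != lay.chain_ids[pos - 1] else " "
            lines.append(f"{indices[pos] - 1:5d}        !{star}".ljust(40))
        g = a.geometry[pos]
        aa = res.one_letter
        hb = _hbond_slots(a, pos, indices)
        hb_text = "".join(f"{off:6d},{e:4.1f}" for off, e, _ in hb)
        ca = res.coord("CA")
        lines.append(
            f"{indices[pos]:5d}{res.res_seq:5d}{res.i_code:1s}{res.chain_id:1s} {aa:1s}  "
            f"{a.summary[pos]:1s} {a.turns[3][pos]}{a.turns[4][pos]}{a.turns[5][pos]}"
            f"{'S' if (g.kappa is not None and g.kappa > 70.0) else ' '}"
            f"{g.chirality}{a.ladder1[pos]}{a.ladder2[pos]}"
            f"{a.bp1[pos]:4d}{a.bp2[pos]:4d}{a.sheet[pos]:1s}{round(g.acc):4d}"
            f"{hb_text}"
            f"{(0.0 if g.tco is None else g.tco):8.3f}{_angle(g.kappa):6.1f}"
            f"{_angle(g.alpha):6.1f}{_angle(g.phi):6.1f}{_angle(g.psi):6.1f}"
            f" {ca[0]:6.1f} {ca[1]:6.1f} {ca[2]:6.1f}"
        )
    return "\n".join(lines) + "\n"


def write_wide_format(a: SSAssignment) -> str:
    """Whitespace-delimited report with absolute residue references.

    Residues and H-bond partners are named chain id + residue number +
    insertion code ("A52", "A52A"); empty fields are a single '.'.
    """
    lay = a.layout
    indices = _report_indices(a)
    lines = [WIDE_HEADER_COLS]

    def dot(value: str) -> str:
        v = value.strip()
        return v if v else "."

    for pos, res in enumerate(lay.residues):
        g = a.geometry[pos]
        hb = _hbond_slots(a, pos, indices)
        hb_text = " ".join(
            "." if j is None else f"{lay.residues[j].label},{e:.1f}" for _, e, j in hb
        )
        fields = [
            res.label,
            res.one_letter,
            dot(a.summary[pos]),
            dot(a.turns[3][pos]),
            dot(a.turns[4][pos]),
            dot(a.turns[5][pos]),
            "S" if (g.kappa is not None and g.kappa > 70.0) else ".",
            dot(g.chirality),
            dot(a.ladder1[pos]),
            dot(a.ladder2[pos]),
            lay.residues[a.bp1[pos] - 1].label if a.bp1[pos] else ".",
            lay.residues[a.bp2[pos] - 1].label if a.bp2[pos] else ".",
            dot(a.sheet[pos]),
            str(round(g.acc)),
            hb_text,
            f"{(0.0 if g.tco is None else g.tco):.3f}",
            f"{_angle(g.kappa):.1f}",
            f"{_angle(g.alpha):.1f}",
            f"{_angle(g.phi):.1f}",
            f"{_angle(g.psi):.1f}",
            f"{res.coord('CA')[0]:.1f}",
            f"{res.coord('CA')[1]:.1f}",
            f"{res.coord('CA')[2]:.1f}",
        ]
        lines.append(" ".join(fields))
    return "\n".join(lines) + "\n"


def parse_dssp_format(text: str) -> list[tuple[str, int, str, str, str]]:
    """Read a fixed-column DSSP-style report.

    Returns (chain id, residue number, insertion code, one-letter AA, summary)
    per data row.  Break rows ('!') are skipped; lower-case amino acid letters
    (disulphide-bonded cysteines in the DSSP convention) are mapped to 'C'.
    """
    lines = text.splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.startswith("  #  RESIDUE AA"):
            start = k + 1
            break
    if start is None:
        raise ReportFormatError("missing '  #  RESIDUE AA' header line")
    rows = []
    for k, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if len(line) > 13 and line[13] == "!":
            continue
        if len(line) < 17:
            raise ReportFormatError(f"short data row at line {k}")
        aa = line[13]
        try:
            res_seq = int(line[5:10])
        except ValueError as exc:
            raise ReportFormatError(f"bad residue number at line {k}") from exc
        i_code = line[10]
        chain = line[11]
        if aa.islower():
            aa = "C"
        rows.append((chain, res_seq, i_code, aa, line[16]))
    return rows


def _split_label(label: str) -> tuple[str, int, str]:
    """Split an absolute residue reference like 'A52A' or 'B-3'."""
    chain = label[0]
    rest = label[1:]
    icode = " "
    if rest and rest[-1].isalpha():
        icode = rest[-1]
        rest = rest[:-1]
    return chain, int(rest), icode


def parse_wide_format(text: str) -> list[tuple[str, int, str, str, str]]:
    """Read the wide whitespace-delimited report; same row tuples as DSSP."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("RES AA SS"):
        raise ReportFormatError("missing wide-format header line")
    rows = []
    for k, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if len(fields) < 3:
            raise ReportFormatError(f"short data row at line {k}")
        chain, res_seq, i_code = _split_label(fields[0])
        ss = " " if fields[2] == "." else fields[2]
        rows.append((chain, res_seq, i_code, fields[1], ss))
    return rows
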