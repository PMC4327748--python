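"""Alignment-side utilities: annotated sequences, distance matrices, peptide
properties.

Sequences live in :class:`AnnotatedSequence` objects: a gapped one-letter
string plus an optional per-position 3-state secondary structure line using
the codes from :mod:`ssassign.assign` ('H' helical, 'E' extended, '-'
unstructured; gaps are unlabelled, shown as ' ').

Distances use pairwise deletion: alignment columns where either sequence has
a gap are excluded, p = differing / compared sites.  The "identity" method
reports percent identity 100*(1-p); the EMBOSS-style variant reports 100*p
and the MEGA-style variant the fraction p (the two differ only in scale
here).

Peptide properties follow common EMBOSS-style conventions: average residue
masses plus one water; extinction at 280 nm from Trp/Tyr/cystine counts
(Pace coefficients); net charge by Henderson-Hasselbalch sums over the
termini and D, E, C, Y, H, K, R side chains; pI as the root of the charge
curve found by bisection.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from Bio import AlignIO, SeqIO
from Bio.SeqUtils import molecular_weight

from .assign import EXTENDED, HELICAL, UNSTRUCTURED

__all__ = [
    "AnnotatedSequence",
    "DistanceMatrix",
    "PeptideProperties",
    "read_fasta",
    "read_clustal",
    "write_fasta",
    "annotate_from_structure",
    "pairwise_distance",
    "distance_matrix",
    "peptide_properties",
    "charge_at_pH",
]

GAP_CHARS = ".-"

#: side-chain and terminal pKa values (EMBOSS defaults)
PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.65, "E": 4.25, "H": 6.5,
    "K": 10.53, "R": 12.5, "Y": 10.07,
}
_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "C", "D", "E", "Y")

E280_TRP = 5500.0
E280_TYR = 1490.0
E280_CYSTINE = 125.0

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AnnotatedSequence:
    id: str
    residues: str                 # gapped, '-' for gaps
    ss: str | None = None         # same length; ' ' on gap positions

    def __post_init__(self) -> None:
        self.residues = "".join(
            "-" if c in GAP_CHARS else c for c in self.residues
        )
        if self.ss is not None and len(self.ss) != len(self.residues):
            raise ValueError(
                f"sequence {self.id!r}: annotation length {len(self.ss)} "
                f"differs from sequence length {len(self.residues)}"
            )

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: list[list[float]]
    method: str

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.ids)]
        for name, row in zip(self.ids, self.values):
            lines.append(name + "\t" + "\t".join(f"{v:.4f}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class PeptideProperties:
    n_residues: int
    mass: float            # Da, average masses
    e280: float            # 1/(M cm)
    pI: float
    charge_pH7: float


def read_fasta(text: str) -> list[AnnotatedSequence]:
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    seqs = [AnnotatedSequence(r.id, str(r.seq)) for r in records]
    _check_rectangular(seqs)
    return seqs


def read_clustal(text: str) -> list[AnnotatedSequence]:
    try:
        alignment = AlignIO.read(io.StringIO(text), "clustal")
    except ValueError as exc:
        raise ValueError(f"cannot read ClustalW alignment: {exc}") from exc
    return [AnnotatedSequence(r.id, str(r.seq)) for r in alignment]


def _check_rectangular(seqs: list[AnnotatedSequence]) -> None:
    lengths = {len(s.residues) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")


def write_fasta(seqs: list[AnnotatedSequence], width: int = 60) -> str:
    out = []
    for s in seqs:
        out.append(f">{s.id}")
        for k in range(0, len(s.residues), width):
            out.append(s.residues[k:k + width])
    return "\n".join(out) + "\n"


def annotate_from_structure(
    seq: AnnotatedSequence, simplified: list[str], residue_letters: str
) -> AnnotatedSequence:
    """Attach per-position 3-state labels from a structure assignment.

    ``simplified`` and ``residue_letters`` run over the structure's residues
    in order; the sequence's ungapped letters must match them exactly.  Labels
    land on non-gap columns only.
    """
    ungapped = seq.ungapped()
    if len(ungapped) != len(residue_letters):
        raise ValueError(
            f"sequence {seq.id!r} has {len(ungapped)} residues but the "
            f"structure provides {len(residue_letters)}"
        )
    for pos, (a, b) in enumerate(zip(ungapped, residue_letters), start=1):
        if a != b:
            raise ValueError(
                f"sequence/structure mismatch at position {pos}: {a!r} != {b!r}"
            )
    ss = []
    cursor = 0
    for c in seq.residues:
        if c == "-":
            ss.append(" ")
        else:
            ss.append(simplified[cursor])
            cursor += 1
    return AnnotatedSequence(seq.id, seq.residues, "".join(ss))


def pairwise_distance(a: AnnotatedSequence, b: AnnotatedSequence, method: str = "p_mega") -> float:
    """Pairwise distance with pairwise deletion of gapped columns.

    method: 'identity' -> percent identity 100*(1-p); 'p_emboss' -> 100*p;
    'p_mega' -> p as a fraction.
    """
    if len(a.residues) != len(b.residues):
        raise ValueError(f"aligned lengths differ for {a.id!r} and {b.id!r}")
    compared = differing = 0
    for x, y in zip(a.residues, b.residues):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            differing += 1
    if compared == 0:
        raise ValueError(f"no comparable sites between {a.id!r} and {b.id!r}")
    p = differing / compared
    if method == "identity":
        return 100.0 * (1.0 - p)
    if method == "p_emboss":
        return 100.0 * p
    if method == "p_mega":
        return p
    raise ValueError(f"unknown distance method {method!r}")


def distance_matrix(seqs: list[AnnotatedSequence], method: str = "p_mega") -> DistanceMatrix:
    if len(seqs) < 2:
        raise ValueError("distance matrix needs at least two sequences")
    _check_rectangular(seqs)
    n = len(seqs)
    zero = 100.0 if method == "identity" else 0.0
    values = [[zero] * n for _ in range(n)]
    for i in range(n):
        values[i][i] = 100.0 if method == "identity" else 0.0
        for j in range(i + 1, n):
            try:
                d = pairwise_distance(seqs[i], seqs[j], method)
            except ValueError as exc:
                raise ValueError(f"pair ({seqs[i].id!r}, {seqs[j].id!r}): {exc}") from exc
            values[i][j] = values[j][i] = d
    return DistanceMatrix([s.id for s in seqs], values, method)


def charge_at_pH(sequence: str, pH: float, pka: dict[str, float] | None = None) -> float:
    """Net charge (elementary charges) of an ungapped peptide at a given pH."""
    pka = pka or PKA
    counts = {aa: sequence.count(aa) for aa in "CDEHKRY"}
    charge = 0.0
    for group in _POSITIVE:
        n = 1 if group == "Nterm" else counts.get(group, 0)
        charge += n / (1.0 + 10.0 ** (pH - pka[group]))
    for group in _NEGATIVE:
        n = 1 if group == "Cterm" else counts.get(group, 0)
        charge -= n / (1.0 + 10.0 ** (pka[group] - pH))
    return charge


def peptide_properties(
    sequence: str,
    pka: dict[str, float] | None = None,
    reduced_cys: bool = False,
) -> PeptideProperties:
    """Physical properties of an ungapped peptide sequence.

    Mass is the sum of average residue masses plus one water; extinction at
    280 nm counts tryptophans, tyrosines and (unless ``reduced_cys``)
    cystines, i.e. oxidised cysteine pairs; pI is found by bisecting the
    strictly decreasing charge curve on pH 0..14 to 0.01 pH units.
    """
    sequence = sequence.upper()
    for c in sequence:
        if c not in AA20:
            raise ValueError(f"unknown amino acid letter {c!r}")
    if not sequence:
        raise ValueError("empty sequence")
    mass = molecular_weight(sequence, seq_type="protein")
    n_cystine = 0 if reduced_cys else sequence.count("C") // 2
    e280 = (
        E280_TRP * sequence.count("W")
        + E280_TYR * sequence.count("Y")
        + E280_CYSTINE * n_cystine
    )
    lo, hi = 0.0, 14.0
    while hi - lo > 0.005:
        mid = 0.5 * (lo + hi)
        if charge_at_pH(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    pi = round(0.5 * (lo + hi), 2)
    return PeptideProperties(
        n_residues=len(sequence),
        mass=mass,
        e280=e280,
        pI=pi,
        charge_pH7=charge_at_pH(sequence, 7.0, pka),
    )
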