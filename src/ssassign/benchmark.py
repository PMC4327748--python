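"""Residue-level comparison of two secondary structure assignments.

Builds the 8-state cross-tabulation of a reference assignment (rows) against
a query assignment (columns), collapses it to the 3-state scheme used for
alignment painting, and reports per-class agreement as the diagonal count
over the reference row total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EIGHT_STATE",
    "THREE_STATE",
    "ConfusionMatrix",
    "compare_assignments",
    "collapse_to_3state",
    "per_class_agreement",
    "class_totals",
]

#: fixed class order; ' ' is the "no assignment" state, rendered as "None"
EIGHT_STATE = (" ", "B", "E", "G", "H", "I", "S", "T")
THREE_STATE = ("unstructured", "helical", "extended")

_COLLAPSE = {
    " ": "unstructured", "B": "unstructured", "S": "unstructured", "T": "unstructured",
    "G": "helical", "H": "helical", "I": "helical",
    "E": "extended",
}


@dataclass
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray                       # rows = reference, cols = query
    unmatched_ref: int = 0
    unmatched_query: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> dict[str, int]:
        return {lab: int(s) for lab, s in zip(self.labels, self.counts.sum(axis=1))}

    def display_label(self, label: str) -> str:
        return "None" if label == " " else label

    def to_tsv(self) -> str:
        header = "ref\\query\t" + "\t".join(self.display_label(c) for c in self.labels)
        lines = [header]
        for lab, row in zip(self.labels, self.counts):
            lines.append(self.display_label(lab) + "\t" + "\t".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        agreements = {}
        for lab in self.labels:
            try:
                agreements[self.display_label(lab)] = per_class_agreement(self, lab)
            except ValueError:
                agreements[self.display_label(lab)] = None
        return json.dumps(
            {
                "labels": [self.display_label(c) for c in self.labels],
                "counts": self.counts.tolist(),
                "total": self.total,
                "unmatched_ref": self.unmatched_ref,
                "unmatched_query": self.unmatched_query,
                "agreement": agreements,
            },
            indent=2,
        )


ResidueKey = tuple[str, int, str]


def compare_assignments(
    ref: dict[ResidueKey, str], query: dict[ResidueKey, str]
) -> ConfusionMatrix:
    """Cross-tabulate two assignments keyed by (chain, residue number, icode).

    Residues present in both inputs contribute one cell; residues present in
    only one are tallied as unmatched and excluded from the matrix.
    """
    index = {lab: k for k, lab in enumerate(EIGHT_STATE)}
    counts = np.zeros((8, 8), dtype=int)
    unmatched_ref = unmatched_query = 0
    for key, r in ref.items():
        q = query.get(key)
        if q is None:
            unmatched_ref += 1
            continue
        try:
            counts[index[r], index[q]] += 1
        except KeyError as exc:
            raise ValueError(f"unknown summary state {exc} for residue {key}") from exc
    unmatched_query = sum(1 for key in query if key not in ref)
    return ConfusionMatrix(EIGHT_STATE, counts, unmatched_ref, unmatched_query)


def collapse_to_3state(m: ConfusionMatrix) -> ConfusionMatrix:
    """Merge the 8-state matrix by the helical/extended/unstructured mapping."""
    if m.labels != EIGHT_STATE:
        raise ValueError("expected an 8-state matrix")
    index = {lab: k for k, lab in enumerate(THREE_STATE)}
    counts = np.zeros((3, 3), dtype=int)
    for i, ri in enumerate(m.labels):
        for j, cj in enumerate(m.labels):
            counts[index[_COLLAPSE[ri]], index[_COLLAPSE[cj]]] += m.counts[i, j]
    return ConfusionMatrix(THREE_STATE, counts, m.unmatched_ref, m.unmatched_query)


def per_class_agreement(m: ConfusionMatrix, label: str) -> float:
    """diagonal(c, c) / reference row total of c, rounded to 3 decimals."""
    k = m.labels.index(label)
    row_total = int(m.counts[k].sum())
    if row_total == 0:
        raise ValueError(f"class {label!r} has an empty reference row")
    return round(float(m.counts[k, k]) / row_total, 3)


def class_totals(m: ConfusionMatrix) -> tuple[dict[str, int], int]:
    """Reference (row) totals per class and their grand total."""
    totals = m.row_totals()
    return totals, sum(totals.values())
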