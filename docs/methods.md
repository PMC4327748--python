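# Methods

## Scope and pipeline

`ssassign` assigns per-residue secondary structure to protein coordinates by
the Kabsch–Sander hydrogen-bond dictionary. The pipeline is
parse → hydrogen check/placement → chain-break detection → H-bond table →
turns/helices/bridges/ladders/sheets/bends → summary, with two report
serialisations and a comparison (benchmark) layer on top. All stages are
pure functions over an explicit `Layout` (the file-ordered list of residues
that have a complete N/CA/C/O backbone, segmented at chain breaks), so the
assignment is deterministic and invariant under rigid-body motion of the
input (verified by property tests).

## Input handling

* **PDB parsing.** Fixed-column wwPDB v3.3 records. Only the first `MODEL`
  of a multi-model file is read; alternate locations keep the first
  conformer (`alt_loc` blank or `A`). Waters are dropped; other HETATM
  residues inside a polymer (e.g. MSE) are retained, with one-letter codes
  from Biopython's extended 3→1 map and `X` for unknowns. `HELIX`/`SHEET`
  header records are captured verbatim as inclusive residue ranges.
* **Amide hydrogens.** If the file provides backbone `H` atoms they are
  kept. Otherwise H is modelled at `N(i) + 1.0 Å · unit(C(i−1) − O(i−1))`,
  i.e. the N–H bond antiparallel to the preceding carbonyl. Chain-first
  residues, residues following a chain break and prolines get no H (they
  are never donors); the placement is idempotent.
* **Chain breaks.** A break is flagged between consecutive residues when
  the peptide C(i)–N(i+1) distance exceeds 2.5 Å or either atom is missing.
  Turns require their whole i..i+n span unbroken; bridges require local
  continuity at i−1..i+1 and j−1..j+1. Raw H-bonds are *not* restricted to
  one segment — an inter-segment bond is physically meaningful (sheets
  between chains) and required for inter-strand pairing.

## Energy model and bond bookkeeping

E = 0.42 · 0.20 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,
clamped below at −9.9; any defining distance under 0.5 Å is treated as a
clash, not a bond. Pairs are pre-filtered at CA–CA ≤ 9.0 Å (beyond that the
energy cannot reach the −0.5 kcal/mol bond threshold with these charges).
Each residue keeps its two lowest-energy acceptors and donors, ties broken
towards the earlier-sequence partner. The energy for donor = acceptor+1 is
never computed: that donor's modelled H is constructed from the acceptor's
own carbonyl, so the pairing is degenerate by construction (and would
otherwise produce meaningless strongly negative values that evict real
partners from the best-two lists). The bond predicate used by turns and
bridges additionally requires a sequence separation of at least 2.

## Secondary structure rules

* n-turn at i ⇔ bond CO(i)→NH(i+n), n ∈ {3, 4, 5}.
* n-helix starts at i when n-turns start at both i−1 and i; the helix body
  is i..i+n−1. Candidate runs shorter than **four** residues are dropped
  for all three helix types — this is the package's minimum-run rule; the
  dropped residues surface as turns (T). Where a residue qualifies for
  several helix types the priority is H > G > I.
* β-bridge (i, j), |i−j| ≥ 3: parallel ⇔ [HB(i−1,j) ∧ HB(j,i+1)] ∨
  [HB(j−1,i) ∧ HB(i,j+1)]; antiparallel ⇔ [HB(i,j) ∧ HB(j,i)] ∨
  [HB(i−1,j+1) ∧ HB(j−1,i+1)]. Consecutive bridges of one type form a
  ladder; ladders with ≥ 2 bridges give their residues E, an isolated
  bridge gives both partners B; ladders sharing a residue join into one
  sheet (union-find). Ladder letters cycle a–z, upper case for
  antiparallel; sheets are labelled A–Z. β-bulges are not special-cased: a
  one-residue irregularity starts a new ladder (they still share a sheet
  when they share residues).
* Bend: κ(i) > 70° (strict), κ being the angle between CA(i)−CA(i−2) and
  CA(i+2)−CA(i).
* Summary priority: H > B > E > G > I > T > S > blank. A residue belonging
  to both an isolated bridge and a real ladder reports the ladder's E (the
  B state is reserved for bridges not promoted into any ladder).
* 3-state collapse: {H, G, I} → helical, {E} → extended, rest →
  unstructured. When structure is taken from header records instead,
  HELIX ranges map to helical, SHEET to extended; on overlap helical wins.

## Geometry conventions

Torsions use the IUPAC sign convention via the atan2 normal-vector form;
degenerate (coincident/collinear) constructions return "undefined", never
NaN. Undefined angles print as 360.0 (DSSP convention), angles to 1
decimal, TCO to 3. Solvent accessibility is Shrake–Rupley: probe 1.4 Å,
960-point deterministic Fibonacci sphere per heavy atom, radii C 1.80,
N 1.65, O 1.40, S 1.85 Å (1.80 for other elements), hydrogens ignored;
per-residue ACC is the sum over the residue's heavy atoms, reported as an
integer. ACC is informational: tests check stability under point-set
refinement (960 vs 10,000 points, within 2 %) and agreement with an
independent implementation, not a canonical value.

## Report formats

The fixed-column writer follows the classic per-residue record (summary at
column 17, turn marks, bend, chirality, ladder letters, BP1/BP2, sheet,
ACC, four H-bond (offset, energy) fields, TCO/κ/α/φ/ψ, CA coordinates),
with `!` rows at breaks (`!*` at chain changes) that consume a sequential
index, so third-party DSSP readers can consume it. The wide format carries
the same content whitespace-delimited with absolute residue references
(`A52`, insertion codes appended: `A52A`) and `.` for empty fields; its
column order is fixed by its header line. Content, not byte layout, is the
wide format's contract.

## Benchmark arithmetic

`compare_assignments` cross-tabulates two assignments keyed by (chain,
residue number, insertion code); rows are the reference, columns the query,
class order (None, B, E, G, H, I, S, T). Residues present in only one input
are tallied separately and excluded. Per-class agreement is
diagonal / reference row total, reported to 3 decimals — with the published
8-state reference counts (5,626 / 321 / 5,730 / 1,305 / 9,822 / 24 / 2,258
/ 2,988) and matched 3-state counts (10,204 / 9,949 / 5,342) this
reproduces the published totals 11,193 / 11,151 / 5,730 (grand total
28,074) and agreements 0.912 / 0.892 / 0.932. The original 100-structure
benchmark set itself is not regenerated: its selection depended on a
historical database snapshot, so the arithmetic layer accepts any
user-supplied pair of reports.

## Sequence tools

Distances use pairwise deletion; p = differing/compared sites; the
identity method reports 100(1−p), the EMBOSS-style variant 100p, the
MEGA-style variant p (they differ only in scale under pairwise deletion,
and tests assert the identity relation). Peptide properties: average
residue masses + one water (via Biopython); E280 = 5500·nTrp + 1490·nTyr +
125·⌊nCys/2⌋ (Pace convention; a flag switches to fully reduced cysteines);
net charge is a Henderson–Hasselbalch sum over the termini and D, E, C, Y,
H, K, R with EMBOSS default pKa values (N-term 8.6, C-term 3.6, C 8.5,
D 3.65, E 4.25, H 6.5, K 10.53, R 12.5, Y 10.07; configurable); the charge
curve is strictly decreasing in pH, so pI is found by bisection on
pH 0–14 to 0.01.

## Synthetic fixtures

Test structures are generated from internal coordinates (bond lengths
N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; angles N–CA–C 111.2°,
CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°) by sequential torsion placement;
the builder/measurer pair closes to well under 0.5°. Presets: ideal
α-helix (−57, −47), extended strand (−139, 135), and an antiparallel
hairpin built from an *exactly periodic* extended strand — (φ, ψ) solved to
(−138.705, 136.155) so residue i+2 is a pure translation of residue i under
the builder's bond geometry — whose partner strand is the image under a
frozen two-fold rotation. That rotation was solved once by minimising the
Kabsch–Sander energies of the facing CO/NH pairs subject to a clash
penalty, then hard-coded; sliding the two-fold axis along the lattice in
half-period steps registers the pairing for any strand length. Facing
N–O distances come out at 2.95 Å (even strand lengths) or 2.68 Å (odd),
each bond near −3.8 kcal/mol, minimum inter-strand heavy-atom contact
2.68 Å. A two-residue linker arcs over the turn; its own assignment is
deliberately unconstrained.

What the fixtures do *not* emulate: side chains beyond the backbone,
crystallographic disorder, real loop geometry, β-sheet twist across many
strands, and realistic B-factor/occupancy variation. Passing the fixture
suite therefore demonstrates the correctness of the dictionary's logic and
geometry handling, not parity with any particular program on crystal
structures; the one external cross-check (an independent C implementation
of the same dictionary, via mdtraj) is run on the fixtures only.

## Problem sizes and design choices

Tests and the acceptance script run on small fixtures (≤ 14 residues) plus
a 28,074-residue label-vector benchmark; the whole suite completes in a few
seconds. Open choices made here, besides the minimum-run rule above: the
summary hierarchy and helix-type priority follow the DSSP convention (the
alternatives are not distinguishable from the published aggregate tables);
isolated bridges adjacent to ladders are *not* promoted to E; EMBOSS pKa
and Pace E280 constants are conventions, stated rather than fitted. Known
limitations: no mmCIF input, no NMR-ensemble handling beyond the first
model, no polyproline-II state, relative (normalised) accessibility is not
computed, and the header histogram block of the classic report is emitted
as zero-filled placeholders.
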