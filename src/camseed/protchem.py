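"""Physicochemical characterization of seed storage protein sequences.

Computes, for a one-letter protein sequence, the summary a protein-chemistry
table reports for one cruciferin protomer: elemental formula (CHNOS), average
molecular mass, charged-residue counts and percentages, grand average of
hydropathy (GRAVY, Kyte-Doolittle), net charge as a function of pH
(Henderson-Hasselbalch) and the isoelectric point found by bisection.

All quantities are composition-level: no structure, no post-translational
modification, no signal-peptide handling. Sequences are taken exactly as
supplied (for cruciferin protomers the mature-chain boundaries must already
have been applied by the caller).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

from Bio import SeqIO

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Free amino acid elemental composition (C, H, N, O, S).
_RESIDUE_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 7, 1, 2, 0),
    "R": (6, 14, 4, 2, 0),
    "N": (4, 8, 2, 3, 0),
    "D": (4, 7, 1, 4, 0),
    "C": (3, 7, 1, 2, 1),
    "E": (5, 9, 1, 4, 0),
    "Q": (5, 10, 2, 3, 0),
    "G": (2, 5, 1, 2, 0),
    "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0),
    "L": (6, 13, 1, 2, 0),
    "K": (6, 14, 2, 2, 0),
    "M": (5, 11, 1, 2, 1),
    "F": (9, 11, 1, 2, 0),
    "P": (5, 9, 1, 2, 0),
    "S": (3, 7, 1, 3, 0),
    "T": (4, 9, 1, 3, 0),
    "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0),
    "V": (5, 11, 1, 2, 0),
}

# Conventional atomic weights (IUPAC 2021 abridged values).
ATOMIC_WEIGHT = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclasses.dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence over the 20 standard one-letter residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty protein sequence")
        for i, aa in enumerate(self.residues):
            if aa not in _RESIDUE_FORMULA:
                raise ValueError(
                    f"nonstandard residue {aa!r} at position {i + 1} "
                    f"in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class ElementalFormula:
    """Counts of C, H, N, O and S atoms in a molecule."""

    C: int
    H: int
    N: int
    O: int
    S: int

    def __post_init__(self) -> None:
        for el in ("C", "H", "N", "O", "S"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            self.C + other.C, self.H + other.H, self.N + other.N,
            self.O + other.O, self.S + other.S,
        )

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            self.C - other.C, self.H - other.H, self.N - other.N,
            self.O - other.O, self.S - other.S,
        )

    def __str__(self) -> str:
        parts = []
        for el in ("C", "H", "N", "O", "S"):
            n = getattr(self, el)
            if n:
                parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts) or "(empty)"


WATER = ElementalFormula(0, 2, 0, 1, 0)


@dataclasses.dataclass(frozen=True)
class PkaSet:
    """Ionisable-group pKa values used for net charge and pI.

    Defaults are the EMBOSS set, a common choice for sequence-level pI
    reporting; the published table this package reproduces does not state
    which scale was used, so pI comparisons carry a +/-0.1 pH tolerance.
    """

    asp: float = 3.9
    glu: float = 4.1
    cys: float = 8.5
    tyr: float = 10.1
    his: float = 6.5
    lys: float = 10.8
    arg: float = 12.5
    n_term: float = 8.6
    c_term: float = 3.6

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {f.name}={v} outside (0, 14)")


DEFAULT_PKA = PkaSet()


@dataclasses.dataclass(frozen=True)
class PropertyRecord:
    """One column of a protomer property table."""

    id: str
    length: int
    formula: ElementalFormula
    mass_kda: float
    pI: float
    neg_count: int
    neg_pct: float
    pos_count: int
    pos_pct: float
    gravy: float
    total_charge: int
    net_charge_pH7: float


def elemental_formula(seq: ProteinSeq) -> ElementalFormula:
    """CHNOS formula of the peptide: free residues minus (n-1) waters."""
    c = h = n = o = s = 0
    for aa in seq.residues:
        fc, fh, fn, fo, fs = _RESIDUE_FORMULA[aa]
        c += fc
        h += fh
        n += fn
        o += fo
        s += fs
    k = len(seq) - 1
    return ElementalFormula(c, h - 2 * k, n, o - k, s)


def average_mass(formula: ElementalFormula, unit: str = "kda") -> float:
    """Average molecular mass from conventional atomic weights.

    ``unit`` is ``"kda"`` or ``"da"``. Rounding to one decimal kDa happens
    only in the reporting layer, not here.
    """
    da = sum(
        getattr(formula, el) * w for el, w in ATOMIC_WEIGHT.items()
    )
    if unit == "da":
        return da
    if unit == "kda":
        return da / 1000.0
    raise ValueError(f"unknown unit {unit!r}")


def residue_pct(count: int, length: int) -> float:
    """Percentage of residues, rounded to one decimal as tables print it."""
    if length <= 0:
        raise ValueError("length must be positive")
    return round(100.0 * count / length, 1)


def charged_counts(seq: ProteinSeq) -> tuple[int, float, int, float]:
    """(neg_count, neg_pct, pos_count, pos_pct).

    Negative = Asp + Glu, positive = Arg + Lys, following the usual
    residue-count convention of protomer property tables (His excluded).
    """
    neg = seq.residues.count("D") + seq.residues.count("E")
    pos = seq.residues.count("R") + seq.residues.count("K")
    n = len(seq)
    return neg, residue_pct(neg, n), pos, residue_pct(pos, n)


def gravy(seq: ProteinSeq) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    return sum(KYTE_DOOLITTLE[aa] for aa in seq.residues) / len(seq)


def net_charge(seq: ProteinSeq, pH: float, pka: PkaSet = DEFAULT_PKA) -> float:
    """Henderson-Hasselbalch net charge at the given pH.

    Basic groups (N-terminus, His, Lys, Arg) contribute
    ``+1 / (1 + 10**(pH - pKa))``; acidic groups (C-terminus, Asp, Glu,
    Cys, Tyr) contribute ``-1 / (1 + 10**(pKa - pH))``. Strictly
    decreasing in pH, which makes the isoelectric point a unique root.
    """
    if not 0.0 < pH < 14.0:
        raise ValueError("pH must be in (0, 14)")
    counts = {aa: seq.residues.count(aa) for aa in "DECYHKR"}
    basic = [(1, pka.n_term), (counts["H"], pka.his),
             (counts["K"], pka.lys), (counts["R"], pka.arg)]
    acidic = [(1, pka.c_term), (counts["D"], pka.asp),
              (counts["E"], pka.glu), (counts["C"], pka.cys),
              (counts["Y"], pka.tyr)]
    q = 0.0
    for n, pk in basic:
        if n:
            q += n / (1.0 + 10.0 ** (pH - pk))
    for n, pk in acidic:
        if n:
            q -= n / (1.0 + 10.0 ** (pk - pH))
    return q


def isoelectric_point(
    seq: ProteinSeq, pka: PkaSet = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """pH at which net charge is zero, by bisection on [0.1, 13.9]."""
    lo, hi = 0.1, 13.9
    qlo = net_charge(seq, lo, pka)
    qhi = net_charge(seq, hi, pka)
    if qlo <= 0.0:
        return lo
    if qhi >= 0.0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def property_record(seq: ProteinSeq, pka: PkaSet = DEFAULT_PKA) -> PropertyRecord:
    """Aggregate all protomer-level properties for one sequence.

    ``total_charge`` is the residue-count arithmetic pos - neg (the
    convention used by the table this reproduces); the pH-dependent
    value is exposed separately as ``net_charge_pH7``.
    """
    formula = elemental_formula(seq)
    neg, neg_pct, pos, pos_pct = charged_counts(seq)
    return PropertyRecord(
        id=seq.id,
        length=len(seq),
        formula=formula,
        mass_kda=average_mass(formula),
        pI=isoelectric_point(seq, pka),
        neg_count=neg,
        neg_pct=neg_pct,
        pos_count=pos,
        pos_pct=pos_pct,
        gravy=gravy(seq),
        total_charge=pos - neg,
        net_charge_pH7=net_charge(seq, 7.0, pka),
    )


def read_fasta(path) -> list[ProteinSeq]:
    """Load protein sequences from a FASTA file."""
    return [
        ProteinSeq(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


_TABLE_ROWS = (
    ("Formula", lambda r: str(r.formula)),
    ("Amino acids", lambda r: str(r.length)),
    ("Mr (kDa)", lambda r: f"{r.mass_kda:.1f}"),
    ("pI", lambda r: f"{r.pI:.2f}"),
    ("Negative residues", lambda r: f"{r.neg_count} ({r.neg_pct:.1f}%)"),
    ("Positive residues", lambda r: f"{r.pos_count} ({r.pos_pct:.1f}%)"),
    ("GRAVY", lambda r: f"{r.gravy:.3f}"),
    ("Total charge", lambda r: str(r.total_charge)),
)


def write_property_table(records: Iterable[PropertyRecord], path) -> None:
    """Write a property table TSV: one row per property, one column per sequence."""
    records = list(records)
    with open(path, "w") as fh:
        fh.write("Property\t" + "\t".join(r.id for r in records) + "\n")
        for name, fmt in _TABLE_ROWS:
            fh.write(name + "\t" + "\t".join(fmt(r) for r in records) + "\n")
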