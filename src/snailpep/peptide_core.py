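"""Peptide sequences, theoretical masses, and reconciliation of reported masses.

MS search engines report a "theoretical precursor molecular weight" for each
identified peptide which may include the mass shift of a post-translational or
process-induced modification without saying which one.  This module computes
plain monoisotopic (and average) masses from one-letter sequences and, given a
small catalogue of common modification deltas, infers the most parsimonious
modification assignment that explains a reported mass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from pyteomics import mass as _pt_mass

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass of H2O (Da), the terminal group completion of a peptide.
WATER_MONO = 18.0105646863
#: Average mass of H2O (Da).
WATER_AVG = 18.01528
#: Monoisotopic proton mass (Da); reserved for m/z extensions.
PROTON = 1.00727646688


class SequenceError(ValueError):
    """Raised for empty sequences or residues outside the canonical 20."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence with optional MS provenance.

    Parameters
    ----------
    sequence : str
        Uppercase one-letter residue codes, canonical 20 only.
    accession : str, optional
        Parent-protein accession, e.g. ``sp|P54334|XKDO_BACSU``.
    reported_mass : float, optional
        Molecular weight reported by the identification pipeline, in Da.
    """

    sequence: str
    accession: Optional[str] = None
    reported_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError("sequence: must be non-empty")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise SequenceError(
                f"sequence: non-canonical residue(s) {sorted(bad)} in {self.sequence!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def parse_sequence(
    raw: str,
    accession: Optional[str] = None,
    reported_mass: Optional[float] = None,
) -> Peptide:
    """Validate and normalize a raw sequence string into a :class:`Peptide`.

    Uppercases the input and rejects anything outside the canonical 20
    residues (including the ambiguity codes B, J, O, U, X, Z), naming the
    offending character and its 1-based position.
    """
    if raw is None or not raw.strip():
        raise SequenceError("sequence: empty input")
    seq = raw.strip().upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in CANONICAL_RESIDUES:
            raise SequenceError(
                f"sequence: illegal residue {ch!r} at position {pos}"
            )
    return Peptide(sequence=seq, accession=accession, reported_mass=reported_mass)


@dataclass(frozen=True)
class MassTable:
    """Residue mass lookup used by all mass computations.

    ``residue_mono`` / ``residue_avg`` hold residue (water-loss) masses in Da;
    a peptide's neutral mass is the residue sum plus one water.
    """

    residue_mono: dict
    residue_avg: dict
    water_mono: float = WATER_MONO
    water_avg: float = WATER_AVG
    proton: float = PROTON


def _build_default_table() -> MassTable:
    mono = {r: _pt_mass.std_aa_mass[r] for r in CANONICAL_RESIDUES}
    avg = {
        r: _pt_mass.calculate_mass(sequence=r, average=True) - WATER_AVG
        for r in CANONICAL_RESIDUES
    }
    return MassTable(residue_mono=mono, residue_avg=avg)


_DEFAULT_TABLE: Optional[MassTable] = None


def default_mass_table() -> MassTable:
    """The standard monoisotopic/average residue mass table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = _build_default_table()
    return _DEFAULT_TABLE


def monoisotopic_mass(p: Peptide, table: Optional[MassTable] = None) -> float:
    """Neutral monoisotopic mass in Da: sum of residue masses plus water."""
    table = table or default_mass_table()
    return sum(table.residue_mono[r] for r in p.sequence) + table.water_mono


def average_mass(p: Peptide, table: Optional[MassTable] = None) -> float:
    """Neutral average molecular weight in Da."""
    table = table or default_mass_table()
    return sum(table.residue_avg[r] for r in p.sequence) + table.water_avg


def round_mass(x: float, ndigits: int = 2) -> float:
    """Round-half-up to ``ndigits`` decimals, as printed mass tables do.

    Python's builtin ``round`` is banker's rounding; printed MS tables use
    half-up, so 628.345 displays as 628.35 rather than 628.34.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ModificationDelta:
    """A named mass shift with a residue-applicability constraint.

    ``applicability`` is a frozenset of residues at least one of which must
    be present in the peptide, or ``None`` for modifications applicable to
    any peptide (e.g. N-terminal acetylation).
    """

    name: str
    delta: float
    applicability: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if not (abs(self.delta) < 200.0):
            raise ValueError(f"modification {self.name}: |delta| must be < 200 Da")

    def applies_to(self, sequence: str) -> bool:
        if self.applicability is None:
            return True
        return bool(self.applicability & set(sequence))


#: Catalogue of common search-engine mass shifts, the packaged default.
DEFAULT_MODIFICATIONS = (
    ModificationDelta("deamidation", 0.98402, frozenset("NQ")),
    ModificationDelta("oxidation", 15.99491, frozenset("MW")),
    ModificationDelta("acetylation", 42.01057, None),
    ModificationDelta("carbamidomethylation", 57.02146, frozenset("C")),
    ModificationDelta("dehydration", -18.01056, frozenset("STED")),
)

#: Tolerance (Da) for comparing full-precision masses with 2-dp printed
#: values; covers either rounding convention of a value printed to 0.01 Da.
DEFAULT_TOLERANCE = 0.011


@dataclass(frozen=True)
class MassReconciliation:
    """Outcome of comparing a reported mass with the computed one.

    status is ``match`` (plain mass within tolerance), ``modified_match``
    (explained by a modification subset), or ``unexplained``.
    """

    peptide: Peptide
    computed_mono: float
    residual: float
    inferred_modifications: tuple = ()
    status: str = "unexplained"


def reconcile_mass(
    p: Peptide,
    table: Optional[MassTable] = None,
    mods: Optional[Sequence[ModificationDelta]] = None,
    tol: float = DEFAULT_TOLERANCE,
    max_mods: int = 1,
) -> MassReconciliation:
    """Explain a reported mass as plain mass plus at most ``max_mods`` deltas.

    The residual (reported minus computed) is first compared to ``tol``
    directly; failing that, subsets of the modification catalogue of size
    1..``max_mods`` whose applicability the sequence satisfies are searched
    for a delta sum matching the residual.  The smallest subset wins, ties
    broken by smallest absolute mismatch, then lexicographic names.
    """
    if p.reported_mass is None:
        raise ValueError("reconcile_mass requires a peptide with reported_mass")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_mods < 0:
        raise ValueError("max_mods must be >= 0")
    if mods is None:
        mods = DEFAULT_MODIFICATIONS

    computed = monoisotopic_mass(p, table)
    residual = p.reported_mass - computed
    if abs(residual) <= tol:
        return MassReconciliation(p, computed, residual, (), "match")

    applicable = [m for m in mods if m.applies_to(p.sequence)]
    best = None  # (size, mismatch, names, subset)
    for size in range(1, max_mods + 1):
        for subset in itertools.combinations(applicable, size):
            mismatch = abs(residual - sum(m.delta for m in subset))
            if mismatch <= tol:
                key = (size, mismatch, tuple(m.name for m in subset))
                if best is None or key < best[0]:
                    best = (key, subset)
        if best is not None:
            break  # smaller subsets always win; stop at first size with a hit
    if best is not None:
        return MassReconciliation(p, computed, residual, best[1], "modified_match")
    return MassReconciliation(p, computed, residual, (), "unexplained")
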