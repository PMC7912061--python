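"""Fragmentomic scanning and novelty assessment.

Short peptides with confirmed bioactivity (here, antihypertensive dipeptides)
encrypted inside a longer hydrolysate peptide may confer activity on the
parent.  This module locates every occurrence of each reference sequence as a
contiguous substring of each hydrolysate peptide (overlaps counted) and,
separately, flags a peptide as *known* only when its full sequence exactly
matches a reference entry — substring containment never makes a peptide known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

from .tableio import BioactiveReference, PeptideTable


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a reference motif inside a peptide.

    Positions are 1-based and inclusive; ``peptide_index`` is the 1-based
    position of the peptide in its table.
    """

    peptide_index: int
    motif: str
    start: int
    end: int


@dataclass
class ScanSummary:
    per_motif_peptide_count: Dict[str, int]
    per_motif_occurrence_count: Dict[str, int]
    novel_count: int
    known_count: int


def scan_motifs(table: PeptideTable, reference: BioactiveReference) -> List[MotifHit]:
    """All occurrences of every reference sequence in every peptide.

    Overlapping occurrences are counted (GG occurs three times in GGGG).
    Output is sorted by (peptide_index, start, motif).
    """
    motifs = sorted({e.sequence for e in reference})
    for m in motifs:
        if not m:
            raise ValueError("reference contains an empty motif")
    hits: List[MotifHit] = []
    for idx, pep in enumerate(table, start=1):
        seq = pep.sequence
        for motif in motifs:
            pos = seq.find(motif)
            while pos != -1:
                hits.append(MotifHit(idx, motif, pos + 1, pos + len(motif)))
                pos = seq.find(motif, pos + 1)
    hits.sort(key=lambda h: (h.peptide_index, h.start, h.motif))
    return hits


def novelty_check(table: PeptideTable, reference: BioactiveReference) -> List[str]:
    """Per-peptide novelty flag: ``known`` iff the full sequence exactly
    equals a reference entry (case-insensitive), else ``novel``."""
    known = {e.sequence.upper() for e in reference}
    return ["known" if p.sequence in known else "novel" for p in table]


def summarize_scan(hits: Sequence[MotifHit], flags: Sequence[str]) -> ScanSummary:
    """Aggregate hits and novelty flags into cohort-level counts.

    ``per_motif_peptide_count`` counts distinct peptides containing at least
    one occurrence (the sense in which a motif is "found in N peptides");
    ``per_motif_occurrence_count`` counts all occurrences.  Keys are sorted
    lexicographically for deterministic serialization.
    """
    n = len(flags)
    if any(h.peptide_index < 1 or h.peptide_index > n for h in hits):
        raise ValueError("hits refer to peptides outside the flagged table")
    peptides_by_motif: Dict[str, set] = {}
    occurrences: Dict[str, int] = {}
    for h in hits:
        peptides_by_motif.setdefault(h.motif, set()).add(h.peptide_index)
        occurrences[h.motif] = occurrences.get(h.motif, 0) + 1
    motifs = sorted(occurrences)
    known = sum(1 for f in flags if f == "known")
    return ScanSummary(
        per_motif_peptide_count={m: len(peptides_by_motif[m]) for m in motifs},
        per_motif_occurrence_count={m: occurrences[m] for m in motifs},
        novel_count=n - known,
        known_count=known,
    )
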