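"""Generators for every input the pipeline consumes.

Emulates (i) an in-silico protease digest of parent proteins under a broad
subtilisin-like cleavage preference, producing a hydrolysate peptide table
with self-consistent reported masses; (ii) four-parameter-logistic
dose-response data with known IC50 and additive plate-reader noise; and
(iii) monotone pH-stat titration traces whose endpoint encodes a known degree
of hydrolysis.  All generators are deterministic for a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bioassay import DoseResponseCurve, TitrationRecord, degree_of_hydrolysis
from .peptide_core import CANONICAL_RESIDUES, Peptide, monoisotopic_mass
from .tableio import PeptideTable

#: Broad subtilisin-like P1 preference: cleave C-terminal to large
#: hydrophobic and small aliphatic residues.
DEFAULT_SPECIFICITY = frozenset("AFILMVWY")


@dataclass(frozen=True)
class DigestSpec:
    """Stochastic cleavage model for an in-silico protease digest.

    Each position whose residue is in ``specificity_set`` (except the
    C-terminal residue) is cut independently with ``cleavage_prob``;
    missed cleavages arise from ``cleavage_prob`` < 1.  Fragments outside
    [min_length, max_length] are recorded but flagged as excluded.
    """

    specificity_set: frozenset = DEFAULT_SPECIFICITY
    cleavage_prob: float = 0.5
    min_length: int = 6
    max_length: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cleavage_prob <= 1.0):
            raise ValueError("cleavage_prob must be in [0, 1]")
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")


@dataclass(frozen=True)
class Fragment:
    parent_id: str
    sequence: str
    start: int  # 1-based position in parent
    end: int    # inclusive
    retained: bool


@dataclass
class SimulatedHydrolysate:
    """Digest output: the retained-peptide table plus full provenance.

    ``fragments`` lists every fragment including those excluded by the
    length filter, so concatenating a parent's fragments in order
    reconstructs the parent exactly.
    """

    peptides: PeptideTable
    parents: List[Tuple[str, str]]
    cut_sites: Dict[str, List[int]]
    fragments: List[Fragment]


def simulate_digest(
    parents: Sequence[Tuple[str, str]],
    spec: DigestSpec,
    mass_noise_sd: float = 0.0,
) -> SimulatedHydrolysate:
    """Digest parent proteins under the stochastic cleavage model.

    Retained fragments become a :class:`PeptideTable` whose ``reported_mass``
    is the computed monoisotopic mass, optionally perturbed by Gaussian noise
    of ``mass_noise_sd`` Da (default exact, so the downstream reconciliation
    closes with zero unexplained masses).
    """
    if not parents:
        raise ValueError("parent set must be non-empty")
    rng = np.random.default_rng(spec.seed)
    fragments: List[Fragment] = []
    cut_sites: Dict[str, List[int]] = {}
    records: List[Peptide] = []
    for pid, seq in parents:
        seq = seq.upper()
        bad = set(seq) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"parent {pid!r}: non-canonical residue(s) {sorted(bad)}")
        eligible = [i for i in range(1, len(seq)) if seq[i - 1] in spec.specificity_set]
        cuts = [i for i in eligible if rng.random() < spec.cleavage_prob]
        cut_sites[pid] = cuts
        bounds = [0] + cuts + [len(seq)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            frag = seq[a:b]
            retained = spec.min_length <= len(frag) <= spec.max_length
            fragments.append(Fragment(pid, frag, a + 1, b, retained))
            if retained:
                mass = monoisotopic_mass(Peptide(frag))
                if mass_noise_sd > 0:
                    mass += rng.normal(0.0, mass_noise_sd)
                records.append(
                    Peptide(frag, accession=f"{pid}|{a + 1}-{b}", reported_mass=mass)
                )
    table = PeptideTable(records=records, source=f"<simulated digest seed={spec.seed}>")
    return SimulatedHydrolysate(table, [(p, s.upper()) for p, s in parents],
                                cut_sites, fragments)


def random_parents(
    n_parents: int, length: int, seed: int
) -> List[Tuple[str, str]]:
    """Uniform-random parent proteins for property checks."""
    rng = np.random.default_rng(seed)
    alphabet = sorted(CANONICAL_RESIDUES)
    return [
        (f"parent{i + 1}", "".join(rng.choice(alphabet, size=length)))
        for i in range(n_parents)
    ]


def simulate_dose_response(
    ic50: float,
    hill: float,
    doses: Sequence[float],
    noise_sd: float,
    seed: int,
) -> DoseResponseCurve:
    """4PL inhibition data with known parameters and additive Gaussian noise.

    y_i = 100 / (1 + (ic50/x_i)^hill) + eps_i, eps_i ~ N(0, noise_sd^2),
    clipped to [-5, 105] to emulate plate-reader replicate behaviour.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose list must be non-empty")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    rng = np.random.default_rng(seed)
    y = 100.0 / (1.0 + (ic50 / doses) ** hill)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=doses.shape)
    y = np.clip(y, -5.0, 105.0)
    return DoseResponseCurve(points=list(zip(doses.tolist(), y.tolist())))


@dataclass
class TitrationTrace:
    """Cumulative base consumption over the hydrolysis run."""

    time_min: np.ndarray
    B_ml: np.ndarray
    final_record: TitrationRecord


def simulate_titration(
    target_dh: float,
    template: TitrationRecord,
    n_steps: int = 60,
    seed: int = 0,
    duration_min: float = 180.0,
    jitter_frac: float = 0.02,
) -> TitrationTrace:
    """A monotone pH-stat trace whose endpoint encodes ``target_dh`` exactly.

    The final cumulative volume solves the DH relation for the target;
    intermediate points follow an exponential approach to that plateau with
    small positive jitter, kept non-decreasing and capped at the endpoint.
    """
    if target_dh <= 0:
        raise ValueError("target_dh must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    b_final = target_dh * template.M_P * template.h_tot / (
        100.0 * template.N_B * template.alpha_inv
    )
    t = np.linspace(0.0, 1.0, n_steps + 1)[1:]  # exclude t=0
    rate = 3.0
    base = b_final * (1.0 - np.exp(-rate * t)) / (1.0 - np.exp(-rate))
    rng = np.random.default_rng(seed)
    if n_steps > 1 and jitter_frac > 0:
        base = base + rng.uniform(0.0, jitter_frac * b_final / n_steps, size=n_steps)
    series = np.minimum(np.maximum.accumulate(base), b_final)
    series[-1] = b_final
    record = TitrationRecord(
        B=float(b_final),
        N_B=template.N_B,
        alpha_inv=template.alpha_inv,
        M_P=template.M_P,
        h_tot=template.h_tot,
    )
    assert abs(degree_of_hydrolysis(record) - target_dh) < 1e-9
    return TitrationTrace(time_min=t * duration_min, B_ml=series, final_record=record)
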