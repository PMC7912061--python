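"""Assay arithmetic: ACE-1 inhibition, IC50 fitting, pH-stat degree of
hydrolysis, and yield/proximate calculations.

The colorimetric ACE-1 kit reports inhibition as the relative drop in
absorbance against an uninhibited control.  IC50 is estimated from a
dose-response curve by a two-parameter log-logistic (Hill) fit with the
asymptotes fixed at 0% and 100% by default, with log-linear interpolation
between the points straddling 50% as a labelled fallback.  The degree of
hydrolysis follows the standard pH-stat relation

    DH = B * N_B * (1/alpha) / (M_P * h_tot) * 100

with B the volume of base consumed (mL), N_B its normality (eq/L), 1/alpha
the average dissociation factor of the liberated alpha-amino groups, M_P the
protein mass in the reactor (g) and h_tot the total peptide-bond content of
the substrate protein (meq/g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

#: Nitrogen-to-protein conversion factor for crude protein from total N.
NITROGEN_TO_PROTEIN = 6.25


@dataclass(frozen=True)
class AssayMeasurement:
    """One ACE-1 assay well pair: uninhibited control vs sample absorbance
    (450 nm)."""

    activity_control: float
    activity_sample: float
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.activity_control <= 0:
            raise ValueError("activity_control must be positive")
        if self.activity_sample < 0:
            raise ValueError("activity_sample must be non-negative")


def percent_inhibition(m: AssayMeasurement) -> float:
    """Percent ACE-1 inhibition, (control - sample) / control * 100.

    May be negative if the sample absorbs more than the control; such values
    are returned as-is for the caller to flag.
    """
    return (m.activity_control - m.activity_sample) / m.activity_control * 100.0


@dataclass
class DoseResponseCurve:
    """Concentration (mg/mL) vs percent-inhibition observations."""

    points: List[Tuple[float, float]]

    def __post_init__(self) -> None:
        if any(c <= 0 for c, _ in self.points):
            raise ValueError("concentrations must be strictly positive")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def inhibitions(self) -> np.ndarray:
        return np.array([y for _, y in self.points], dtype=float)


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float
    hill_slope: float
    bottom: float
    top: float
    method: str  # "loglogistic" or "interpolation"
    residual_sse: float


def _hill(logx: np.ndarray, log_ic50: float, h: float, bottom: float, top: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (h * (log_ic50 - logx)))


def fit_ic50(
    curve: DoseResponseCurve,
    bottom: float = 0.0,
    top: float = 100.0,
    free_asymptotes: bool = False,
) -> DoseResponseFit:
    """Estimate IC50 from a dose-response curve.

    Primary method: least-squares fit of the log-logistic model
    y = bottom + (top - bottom) / (1 + (ic50/x)^h) on log10 concentration,
    with the asymptotes fixed (default) because bounded percent-inhibition
    data rarely constrain four parameters.  When fewer than three points are
    available or the fit fails to converge, falls back to log-linear
    interpolation between the two points straddling 50%; the method used is
    recorded on the result.

    Raises ``ValueError`` when the observations do not cross 50% inhibition:
    the IC50 is then not identifiable from the data.
    """
    x = curve.concentrations
    y = curve.inhibitions
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    mid = (top + bottom) / 2.0
    if y.min() > mid or y.max() < mid:
        raise ValueError("IC50 not identifiable from data: inhibition never crosses 50%")

    logx = np.log10(x)
    order = np.argsort(logx)
    logx_s, y_s = logx[order], y[order]

    if len(x) >= 3:
        # start at the dose whose response is nearest the midpoint
        log_ic50_0 = logx_s[int(np.argmin(np.abs(y_s - mid)))]
        try:
            if free_asymptotes:
                popt, _ = curve_fit(
                    _hill, logx_s, y_s, p0=[log_ic50_0, 1.0, bottom, top], maxfev=20000
                )
                log_ic50, h, bot, tp = popt
            else:
                popt, _ = curve_fit(
                    lambda lx, li, h: _hill(lx, li, h, bottom, top),
                    logx_s, y_s, p0=[log_ic50_0, 1.0], maxfev=20000,
                )
                log_ic50, h = popt
                bot, tp = bottom, top
            pred = _hill(logx_s, log_ic50, h, bot, tp)
            sse = float(np.sum((y_s - pred) ** 2))
            return DoseResponseFit(10.0 ** log_ic50, float(h), float(bot),
                                   float(tp), "loglogistic", sse)
        except RuntimeError:
            pass  # no convergence: fall through to interpolation

    return _interpolate_ic50(logx_s, y_s, bottom, top, mid)


def _interpolate_ic50(logx_s, y_s, bottom, top, mid) -> DoseResponseFit:
    for i in range(len(y_s) - 1):
        y1, y2 = y_s[i], y_s[i + 1]
        if (y1 - mid) * (y2 - mid) <= 0 and y1 != y2:
            frac = (mid - y1) / (y2 - y1)
            log_ic50 = logx_s[i] + frac * (logx_s[i + 1] - logx_s[i])
            return DoseResponseFit(10.0 ** log_ic50, math.nan, bottom, top,
                                   "interpolation", math.nan)
    raise ValueError("IC50 not identifiable from data: no adjacent points straddle 50%")


@dataclass(frozen=True)
class TitrationRecord:
    """pH-stat quantities for the degree-of-hydrolysis calculation."""

    B: float          # mL NaOH consumed
    N_B: float        # normality of NaOH, eq/L
    alpha_inv: float  # 1/alpha, average dissociation factor
    M_P: float        # g protein in the reaction
    h_tot: float      # meq peptide bonds per g protein

    def __post_init__(self) -> None:
        if self.B < 0:
            raise ValueError("B must be >= 0")
        for name in ("N_B", "alpha_inv", "M_P", "h_tot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def degree_of_hydrolysis(t: TitrationRecord) -> float:
    """Percent of peptide bonds cleaved, from base consumption at constant pH.

    B (mL) times N_B (eq/L) gives milliequivalents of base, so the result is
    dimensionless and expressed in percent.
    """
    return t.B * t.N_B * t.alpha_inv / (t.M_P * t.h_tot) * 100.0


def percent_yield(recovered_mass: float, input_mass: float) -> float:
    """Mass recovered as a percentage of input (e.g. freeze-dried supernatant
    from ground starting material)."""
    if input_mass <= 0:
        raise ValueError("input_mass must be positive")
    if recovered_mass < 0:
        raise ValueError("recovered_mass must be non-negative")
    return recovered_mass / input_mass * 100.0


def enzyme_substrate_ratio(enzyme_volume: float, substrate_mass: float) -> float:
    """Enzyme dose as volume-per-weight percent (mL enzyme per g substrate)."""
    if substrate_mass <= 0:
        raise ValueError("substrate_mass must be positive")
    if enzyme_volume < 0:
        raise ValueError("enzyme_volume must be non-negative")
    return enzyme_volume / substrate_mass * 100.0


def protein_from_nitrogen(nitrogen_pct: float) -> float:
    """Crude protein percent from total nitrogen percent (Dumas/Kjeldahl
    convention, factor 6.25).  Nitrogen above 16% would imply >100% protein
    and is rejected."""
    if not (0.0 <= nitrogen_pct <= 100.0 / NITROGEN_TO_PROTEIN):
        raise ValueError("nitrogen_pct must be between 0 and 16")
    return nitrogen_pct * NITROGEN_TO_PROTEIN
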