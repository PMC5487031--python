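"""Quantification standards and the log-linear Ct calibration curve.

qPCR calibration rests on the log-linear response

    Ct = intercept + slope * log10(copies per reaction)

fitted by ordinary least squares over a dilution series of standards with
known copy numbers.  The amplification efficiency follows from the slope as
``E = 10^(-1/slope) - 1`` (a slope of -3.3219 is perfect per-cycle doubling,
100%).  Standards themselves are built from purified double-stranded DNA:
the copy concentration of a stock is computed from its mass concentration
and the molecular weight of the amplicon sequence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_plate import StandardPoint, reverse_complement

__all__ = [
    "StandardCurve",
    "DilutionSeries",
    "CurveFitError",
    "oligo_molecular_weight",
    "copies_per_ul_from_mass",
    "fit_standard_curve",
    "efficiency_from_slope",
    "copies_from_ct",
]

AVOGADRO = 6.02214076e23

# Monophosphate nucleotide weights minus water, g/mol, with the 5'-phosphate
# correction of -61.96 applied once per strand (Oligo-Calc convention).
_NT_WEIGHT = {"A": 313.21, "T": 304.2, "C": 289.18, "G": 329.21}
_PHOSPHATE_CORRECTION = 61.96


class CurveFitError(ValueError):
    """Standard-curve regression cannot be performed on the given points."""


@dataclass(frozen=True)
class StandardCurve:
    """Fitted calibration curve for one assay.

    ``slope`` is in cycles per log10(copies) and is negative; ``intercept``
    is the Ct expected at a single copy per reaction.  ``dynamic_range``
    spans the fitted nominal concentrations (copies/reaction).
    """

    assay_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    dynamic_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    @property
    def efficiency_pct(self) -> float:
        return efficiency_from_slope(self.slope)


@dataclass(frozen=True)
class DilutionSeries:
    """Serial dilution of a standard stock.

    ``fold`` is the dilution factor between consecutive steps (10 for a
    tenfold series, 4 for a four-fold series); step 0 is the undiluted stock.
    """

    stock_copies_per_ul: float
    fold: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.stock_copies_per_ul <= 0:
            raise ValueError("stock_copies_per_ul must be > 0")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def concentrations(self) -> list[float]:
        """Copies/µL at each step, strictly decreasing by ``fold``."""
        return [self.stock_copies_per_ul / self.fold**i for i in range(self.n_steps)]

    def copies_per_reaction(self, template_volume_ul: float) -> list[float]:
        """Nominal copies loaded per reaction at each step."""
        if template_volume_ul <= 0:
            raise ValueError("template_volume_ul must be > 0")
        return [c * template_volume_ul for c in self.concentrations()]


def oligo_molecular_weight(sequence: str, strands: int = 1) -> float:
    """Molecular weight (g/mol) of a DNA oligo or duplex.

    Single strand: sum of per-nucleotide monophosphate weights minus 61.96
    for the missing 5'-phosphate.  ``strands=2`` adds the weight of the
    reverse complement, giving the duplex weight used for dsDNA standards.
    Ambiguity codes are rejected — quantification standards are exact
    sequences.
    """
    seq = sequence.upper()
    if len(seq) == 0:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    if strands not in (1, 2):
        raise ValueError(f"strands must be 1 or 2, got {strands}")
    bad = set(seq) - set(_NT_WEIGHT)
    if bad:
        raise ValueError(
            f"sequence contains non-ACGT characters {sorted(bad)}; "
            "standards must be unambiguous"
        )
    weight = sum(_NT_WEIGHT[b] for b in seq) - _PHOSPHATE_CORRECTION
    if strands == 2:
        weight += oligo_molecular_weight(reverse_complement(seq), strands=1)
    return weight


def copies_per_ul_from_mass(conc_ng_per_ul: float, mw_g_per_mol: float) -> float:
    """Convert a mass concentration of a template to copies/µL.

    copies/µL = conc[ng/µL] · 1e-9 [g/ng] · N_A / MW[g/mol].
    """
    if mw_g_per_mol <= 0:
        raise ValueError(f"molecular weight must be > 0, got {mw_g_per_mol}")
    if conc_ng_per_ul < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_ng_per_ul}")
    return conc_ng_per_ul * 1e-9 * AVOGADRO / mw_g_per_mol


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from the standard-curve slope.

    ``(10^(-1/slope) - 1) * 100``; -3.3219 cycles/log10 gives 100%.
    """
    if slope >= 0:
        raise ValueError(f"slope must be negative, got {slope}")
    return (10 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(points: list[StandardPoint],
                       assay_id: str | None = None) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies/reaction).

    Only detected replicates enter the regression; a concentration whose
    replicates are all non-detect is dropped with a warning.  At least two
    distinct usable concentrations are required.
    """
    if assay_id is None:
        assay_id = points[0].assay_id if points else "unknown"
    xs: list[float] = []
    ys: list[float] = []
    used: list[float] = []
    for p in points:
        cts = [ct for ct in p.replicate_cts if ct is not None]
        if not cts:
            warnings.warn(
                f"standard at {p.nominal_copies_per_reaction:g} copies/reaction has "
                "no detected replicates; excluded from the curve fit",
                stacklevel=2,
            )
            continue
        used.append(p.nominal_copies_per_reaction)
        xs.extend([math.log10(p.nominal_copies_per_reaction)] * len(cts))
        ys.extend(cts)
    if len(set(used)) < 2:
        raise CurveFitError(
            "standard-curve fit needs >= 2 distinct concentrations with detected "
            f"replicates; got {len(set(used))}"
        )
    fit = stats.linregress(np.asarray(xs), np.asarray(ys))
    return StandardCurve(
        assay_id=assay_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(xs),
        dynamic_range=(min(used), max(used)),
    )


def copies_from_ct(ct: float, curve: StandardCurve) -> float:
    """Invert the calibration: copies/reaction = 10^((ct - intercept)/slope).

    Monotone decreasing in ct.  Non-detects carry no Ct, so callers must
    branch on detection before inverting.
    """
    if ct is None:
        raise ValueError("cannot convert a non-detect to copies; branch on detection first")
    if not math.isfinite(ct):
        raise ValueError(f"ct must be finite, got {ct}")
    return 10 ** ((ct - curve.intercept) / curve.slope)
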