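"""qPCR standard curves and per-milligram concentration normalization.

Quantities are calibrated against a standard dilution series (six decades,
10¹–10⁶ copies/µL, run in duplicate per plate): ordinary least squares of
Cq on log10(copies/µL) gives the curve, whose slope determines the
amplification efficiency 10^(−1/slope) − 1. Measured Cq values are inverted
through the curve, multiplied by the ×50 dilution and the 50 µL extraction
volume, and divided by the dust mass of the sample to obtain spore
equivalents (fungi) or cells (bacteria) per mg dust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _spstats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "StandardCurve",
    "QpcrMeasurement",
    "ConcentrationRecord",
    "fit_standard_curve",
    "quantify",
    "to_per_mg",
    "aggregate_replicates",
    "process_measurement",
]

LOWEST_STANDARD_COPIES_PER_UL = 10.0


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Cq = intercept + slope·log10(copies/µL) calibration line."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    n_points: int
    min_copies_per_ul: float = LOWEST_STANDARD_COPIES_PER_UL
    max_copies_per_ul: float = 1e6

    @property
    def valid(self) -> bool:
        """Slope must be negative: more template amplifies earlier."""
        return self.slope < 0 and self.efficiency > 0


@dataclass(frozen=True)
class QpcrMeasurement:
    """Triplicate Cq readings for one dust sample and one target assay."""

    sample_id: str
    target: str  # "fungal_18S" | "bacterial_16S"
    cq_values: tuple[float, ...]
    dust_mass_mg: float
    dilution_factor: float = 50.0
    extract_volume_ul: float = 50.0

    def __post_init__(self):
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")
        if self.extract_volume_ul <= 0:
            raise ValidationError("extract_volume_ul must be positive")


@dataclass(frozen=True)
class ConcentrationRecord:
    """Per-sample concentration (SE/mg or cells/mg) after replicate pooling."""

    sample_id: str
    target: str
    concentration: float
    replicate_cv: float
    flags: tuple[str, ...] = field(default=())


def fit_standard_curve(standards) -> StandardCurve:
    """OLS fit of Cq against log10(copies/µL) over the dilution series."""
    copies = np.asarray([c for c, _ in standards], dtype=float)
    cq = np.asarray([q for _, q in standards], dtype=float)
    if np.any(copies <= 0):
        raise ValidationError("standard concentrations must be positive")
    if not np.all(np.isfinite(cq)):
        raise ValidationError("standard Cq values must be finite")
    if np.unique(copies).size < 3:
        raise InsufficientDataError("need >= 3 distinct standard concentrations")
    res = _spstats.linregress(np.log10(copies), cq)
    slope = float(res.slope)
    efficiency = 10.0 ** (-1.0 / slope) - 1.0 if slope != 0 else float("nan")
    return StandardCurve(
        slope=slope,
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r_squared=float(res.rvalue**2),
        n_points=int(copies.size),
        min_copies_per_ul=float(copies.min()),
        max_copies_per_ul=float(copies.max()),
    )


def quantify(cq: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies/µL = 10^((Cq − intercept)/slope)."""
    if not curve.valid:
        raise ValidationError("standard curve is invalid (non-negative slope)")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def to_per_mg(copies_per_ul: float, measurement: QpcrMeasurement) -> float:
    """Apply the ×dilution and extraction-volume normalization per mg dust."""
    if measurement.dust_mass_mg <= 0:
        raise ValidationError("dust_mass_mg must be positive")
    return (
        copies_per_ul
        * measurement.dilution_factor
        * measurement.extract_volume_ul
        / measurement.dust_mass_mg
    )


def aggregate_replicates(
    concentrations, sample_id: str = "", target: str = ""
) -> ConcentrationRecord:
    """Pool replicate per-mg concentrations into one record.

    The point estimate is the geometric mean of the positive replicates
    (qPCR concentrations are lognormal-like); ``replicate_cv`` is the
    geometric coefficient of variation sqrt(exp(s²) − 1) with s the sample
    standard deviation of the log replicates.
    """
    vals = np.asarray(list(concentrations), dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise InsufficientDataError("no finite replicate values")
    positive = finite[finite > 0]
    flags: list[str] = []
    if positive.size == 0:
        return ConcentrationRecord(sample_id, target, 0.0, float("nan"),
                                   flags=("all-zero",))
    if positive.size < finite.size:
        flags.append("zero-replicates-dropped")
    logs = np.log(positive)
    conc = float(math.exp(logs.mean()))
    cv = float(math.sqrt(math.expm1(logs.var(ddof=1)))) if positive.size > 1 else 0.0
    return ConcentrationRecord(sample_id, target, conc, cv, flags=tuple(flags))


def process_measurement(
    measurement: QpcrMeasurement, curve: StandardCurve
) -> ConcentrationRecord:
    """Full path Cq → copies/µL → per-mg → replicate-pooled record."""
    per_mg = []
    below_range = False
    for cq in measurement.cq_values:
        copies = quantify(cq, curve)
        if copies < curve.min_copies_per_ul:
            below_range = True
        per_mg.append(to_per_mg(copies, measurement))
    rec = aggregate_replicates(per_mg, measurement.sample_id, measurement.target)
    if below_range:
        rec = ConcentrationRecord(
            rec.sample_id, rec.target, rec.concentration, rec.replicate_cv,
            flags=rec.flags + ("below-standard-range",),
        )
    return rec
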