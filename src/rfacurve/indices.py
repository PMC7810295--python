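"""Performance indices of an RFA impedance curve: delta, DR and AR.

All three are dimensionless percentages built from landmark ratios:

* ``delta = (t_minimum / t_half - 1) * 100`` — asymmetry of the curve:
  zero when the impedance minimum sits exactly at mid-procedure, positive
  when the minimum occurs after the midpoint.
* ``DR = -(Z_minimum / Z_initial - 1) * 100`` — Drop Ratio, the percentage
  decrease from initial to minimum impedance.  The literal ratio formula
  yields a negative number for any drop; the study reports the positive
  drop magnitude, so both are exposed (``dr`` and ``dr_signed``).
* ``AR = (Z_end / Z_minimum - 1) * 100`` — Ascent Ratio, the percentage
  rise from minimum impedance to the impedance at roll-off.

Under the 1.5x threshold roll-off convention Z_end = 1.5 * Z_initial, so
AR is algebraically pinned to DR: ``AR = 100 * (1.5 / (1 - DR/100) - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataError
from .params import CurveParameters

__all__ = [
    "PerformanceIndices",
    "delta_index",
    "drop_ratio",
    "ascent_ratio",
    "compute_indices",
]


@dataclass
class PerformanceIndices:
    sample_id: str
    delta: float
    dr: float
    dr_signed: float
    ar: float
    rolloff_mode: str


def delta_index(params: CurveParameters) -> float:
    """Percent displacement of the impedance minimum from mid-procedure."""
    if params.t_half <= 0:
        raise DataError("degenerate curve: t_half must be positive")
    return (params.t_minimum / params.t_half - 1.0) * 100.0


def drop_ratio(params: CurveParameters) -> tuple[float, float]:
    """Drop Ratio as ``(dr, dr_signed)`` percent.

    ``dr_signed`` is the literal ratio value (negative for a drop);
    ``dr`` is the positive drop magnitude used in reporting.
    """
    if params.Z_initial <= 0:
        raise DataError("Z_initial must be positive")
    dr_signed = (params.Z_minimum / params.Z_initial - 1.0) * 100.0
    return -dr_signed, dr_signed


def ascent_ratio(params: CurveParameters) -> float:
    """Percent rise from the impedance minimum to the roll-off impedance."""
    if params.Z_minimum <= 0:
        raise DataError("Z_minimum must be positive")
    return (params.Z_end / params.Z_minimum - 1.0) * 100.0


def compute_indices(params: CurveParameters) -> PerformanceIndices:
    """Bundle delta, DR and AR for one curve's landmarks."""
    dr, dr_signed = drop_ratio(params)
    return PerformanceIndices(
        sample_id=params.sample_id,
        delta=delta_index(params),
        dr=dr,
        dr_signed=dr_signed,
        ar=ascent_ratio(params),
        rolloff_mode=params.rolloff_mode,
    )
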