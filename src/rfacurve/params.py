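"""Extraction of the seven landmark parameters of an RFA impedance curve.

During radiofrequency ablation the circuit impedance first falls as the
heated tissue becomes more conductive, reaches a minimum, then rises
steeply as desiccated tissue insulates the electrode ("roll-off", the
procedure stop criterion).  Seven landmarks describe one curve:

===========  =================================================
``t_end``    duration until the first roll-off [s]
``t_half``   half the duration, ``t_end / 2`` [s]
``t_min``    time of the impedance minimum [s]
``Z_init``   initial impedance [ohm]
``Z_half``   impedance at ``t_half`` [ohm]
``Z_min``    minimum impedance [ohm]
``Z_end``    impedance at roll-off [ohm]
===========  =================================================

Two roll-off conventions are supported.  ``log_end`` takes the last logged
sample as the roll-off event (the equipment stops at the first roll-off,
so the log terminates there).  ``threshold`` defines roll-off as the first
time, after the minimum, at which impedance reaches
``threshold_factor * Z_initial`` (factor 1.5 by default), located by
linear interpolation.  The two conventions give very different ascent
magnitudes on real curves — the measured impedance at roll-off is several
times the minimum, while the 1.5x threshold caps the ascent near 100% — so
the convention used is stamped into every output record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .errors import DataError, NoRolloffError
from .io import ImpedanceCurve

__all__ = [
    "CurveParameters",
    "value_at_time",
    "estimate_initial_impedance",
    "detect_rolloff",
    "extract_parameters",
]

ROLLOFF_MODES = ("log_end", "threshold")


@dataclass
class CurveParameters:
    """The seven landmarks of one impedance curve plus extraction settings."""

    sample_id: str
    t_end: float
    t_half: float
    t_minimum: float
    Z_initial: float
    Z_half: float
    Z_minimum: float
    Z_end: float
    rolloff_mode: str = "log_end"
    threshold_factor: float = 1.5
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        if self.rolloff_mode not in ROLLOFF_MODES:
            raise ValueError(f"rolloff_mode must be one of {ROLLOFF_MODES}")
        if not np.isclose(self.t_half, self.t_end / 2.0, rtol=1e-12, atol=1e-12):
            raise DataError("t_half must equal t_end / 2")
        if not (0.0 <= self.t_minimum <= self.t_end):
            raise DataError("t_minimum outside [0, t_end]")
        zmin = self.Z_minimum
        if zmin > self.Z_initial or zmin > self.Z_half or zmin > self.Z_end:
            raise DataError("Z_minimum must not exceed Z_initial, Z_half or Z_end")


def value_at_time(curve: ImpedanceCurve, t_query: float) -> float:
    """Impedance at ``t_query`` by linear interpolation between samples."""
    if not (curve.t[0] <= t_query <= curve.t[-1]):
        raise DataError(
            f"t_query={t_query} outside curve range [{curve.t[0]}, {curve.t[-1]}]"
        )
    return float(np.interp(t_query, curve.t, curve.Z))


def estimate_initial_impedance(curve: ImpedanceCurve, k: int = 1) -> float:
    """Initial impedance as the mean of the first ``k`` samples.

    The default ``k = 1`` is the literal first reading; larger ``k``
    averages out sampling noise at the cost of mixing in early decay.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(curve):
        raise ValueError(f"k={k} exceeds curve length {len(curve)}")
    return float(np.mean(curve.Z[:k]))


def _interp_crossing(t0, t1, z0, z1, level) -> float:
    """Time at which the segment (t0,z0)-(t1,z1) crosses ``level`` upward."""
    if z1 == z0:
        return float(t0)
    return float(t0 + (t1 - t0) * (level - z0) / (z1 - z0))


def detect_rolloff(
    curve: ImpedanceCurve,
    mode: str = "log_end",
    factor: float = 1.5,
    Z_initial: float | None = None,
) -> tuple[float, float]:
    """Locate the roll-off event; returns ``(t_end, Z_end)``.

    ``log_end``: the log's last sample is the event.  ``threshold``: the
    earliest time after the global minimum at which impedance reaches
    ``factor * Z_initial``, by linear interpolation; raises
    :class:`NoRolloffError` when the curve never gets there.
    """
    if mode not in ROLLOFF_MODES:
        raise ValueError(f"mode must be one of {ROLLOFF_MODES}")
    if mode == "log_end":
        return float(curve.t[-1]), float(curve.Z[-1])

    if factor <= 1.0:
        raise ValueError("threshold factor must exceed 1")
    if Z_initial is None:
        Z_initial = float(curve.Z[0])
    level = factor * Z_initial
    # Search only after the global minimum so that initial readings above
    # the level (possible when Z_initial is an average) cannot trigger.
    i_min = int(np.argmin(curve.Z))
    z = curve.Z[i_min:]
    t = curve.t[i_min:]
    above = np.nonzero(z >= level)[0]
    if len(above) == 0:
        raise NoRolloffError(
            f"curve {curve.sample_id!r} never reaches {level:.3g} ohm "
            f"(max {curve.Z.max():.3g} ohm)",
            max_impedance=curve.Z.max(),
        )
    j = int(above[0])
    if j == 0:
        return float(t[0]), float(z[0])
    t_end = _interp_crossing(t[j - 1], t[j], z[j - 1], z[j], level)
    return t_end, float(level)


def extract_parameters(
    curve: ImpedanceCurve,
    mode: str = "log_end",
    factor: float = 1.5,
    init_k: int = 1,
    median_window: int = 0,
) -> CurveParameters:
    """Compute all seven landmarks of ``curve``.

    Parameters
    ----------
    mode, factor:
        Roll-off convention, see :func:`detect_rolloff`.
    init_k:
        Number of leading samples averaged for the initial impedance.
    median_window:
        Odd window length of an optional running-median filter applied
        before landmark extraction (0 disables it).  Recommended for noisy
        logs: the impedance minimum is a pointwise extreme and is biased
        low by sampling noise on the raw trace.
    """
    if len(curve) < 3:
        raise DataError("curve shorter than 3 points")
    if median_window:
        if median_window % 2 == 0 or median_window < 0:
            raise ValueError("median_window must be odd and positive (or 0)")
        # clamp to the curve length (largest odd window that fits)
        if median_window > len(curve):
            median_window = len(curve) - (1 - len(curve) % 2)
        z = medfilt(curve.Z, kernel_size=median_window)
        # medfilt zero-pads the ends; keep the raw edge samples instead so
        # Z_initial and the log-end Z_end are not distorted.
        half = median_window // 2
        z[:half] = curve.Z[:half]
        z[-half:] = curve.Z[-half:]
        curve = ImpedanceCurve(
            sample_id=curve.sample_id,
            t=curve.t,
            Z=z,
            source_path=curve.source_path,
            dropped_rows=curve.dropped_rows,
        )

    z_init = estimate_initial_impedance(curve, k=init_k)
    t_end, z_end = detect_rolloff(curve, mode=mode, factor=factor, Z_initial=z_init)
    t_half = t_end / 2.0
    z_half = value_at_time(curve, t_half)

    in_window = curve.t <= t_end
    z_win = curve.Z[in_window]
    i_min = int(np.argmin(z_win))  # argmin takes the earliest index on ties
    t_min = float(curve.t[in_window][i_min])
    z_min = float(z_win[i_min])

    # Averaged initialisation can sit above the first samples; the minimum
    # must never exceed the reported initial impedance.
    z_min = min(z_min, z_init)
    z_half = max(z_half, z_min)

    return CurveParameters(
        sample_id=curve.sample_id,
        t_end=float(t_end),
        t_half=float(t_half),
        t_minimum=t_min,
        Z_initial=float(z_init),
        Z_half=float(z_half),
        Z_minimum=z_min,
        Z_end=float(z_end),
        rolloff_mode=mode,
        threshold_factor=float(factor),
        dropped_rows=curve.dropped_rows,
    )
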