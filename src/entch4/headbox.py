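"""Ventilated head-box calorimetry.

A head box encloses the cow's head; a blower pulls air through at a
known flow (about 520 L/min at 0 degC, 1 atm) and CH4/CO2 analyzers
sample the outlet. Emission per second is flow times the
background-corrected concentration, totals are accumulated over the
15-min measurement, and the daily emission is the 15-min total scaled
by 1440/15 = 96. A CO2 recovery test (known volume injected, measured
volume recovered) characterizes each box; measured emissions are
divided by the recovery factor only when correction is explicitly
enabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sniffer import Background, GasTrace

__all__ = ["FluxResult", "compute_flux", "recovery_rate", "DEFAULT_MEASUREMENT_S"]

#: Nominal measurement duration (s): 15 minutes.
DEFAULT_MEASUREMENT_S = 900

#: 15-min periods per day; the daily extrapolation factor.
PERIODS_PER_DAY = 1440.0 / 15.0


@dataclass(frozen=True)
class FluxResult:
    """Totals and derived quantities for one head-box measurement."""

    ch4_total_15min: float  # L
    co2_total_15min: float  # L
    ratio: float  # L/L
    ch4_daily: float  # L/day
    recovery_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.ch4_total_15min < 0 or self.co2_total_15min < 0:
            raise ValueError("gas totals must be non-negative")


def compute_flux(
    trace: GasTrace,
    bg: Background,
    recovery_factor: float = 1.0,
    expected_duration_s: int = DEFAULT_MEASUREMENT_S,
    duration_tolerance_s: int = 60,
) -> FluxResult:
    """Integrate a head-box trace into 15-min totals and a daily rate.

    Per-second emission (L/s of pure gas) is ``flow/60 x excess_ppm x
    1e-6``; totals are sums over the measurement. Traces whose length
    deviates from 15 min are pro-rated to 15 min; a deviation beyond
    ``duration_tolerance_s`` additionally warns. The daily emission is
    ``ch4_total x 96 / recovery_factor``.
    """
    if trace.flow is None:
        raise ValueError("head-box flux requires a flow series")
    if recovery_factor <= 0:
        raise ValueError("recovery_factor must be positive")
    n = trace.duration_s
    if n == 0:
        raise ValueError("empty head-box trace")
    scale = expected_duration_s / n
    if abs(n - expected_duration_s) > duration_tolerance_s:
        warnings.warn(
            f"measurement of {n} s is outside {expected_duration_s} +/- "
            f"{duration_tolerance_s} s; totals pro-rated to 15 min",
            stacklevel=2,
        )
    ch4_excess = np.clip(trace.ch4 - bg.ch4, 0.0, None)
    co2_excess = np.clip(trace.co2 - bg.co2, 0.0, None)
    lps = trace.flow / 60.0  # L/s of air
    ch4_total = float(np.sum(lps * ch4_excess * 1e-6)) * scale
    co2_total = float(np.sum(lps * co2_excess * 1e-6)) * scale
    ratio = ch4_total / co2_total if co2_total > 0 else 0.0
    return FluxResult(
        ch4_total_15min=ch4_total,
        co2_total_15min=co2_total,
        ratio=ratio,
        ch4_daily=ch4_total * PERIODS_PER_DAY / recovery_factor,
        recovery_factor=recovery_factor,
    )


def recovery_rate(injected: float, measured: float) -> float:
    """Recovery of a calibration injection, in percent.

    ``100 x measured / injected`` for a known injected gas volume (L).
    """
    if injected <= 0:
        raise ValueError("injected volume must be positive")
    if measured < 0:
        raise ValueError("measured volume must be non-negative")
    return 100.0 * measured / injected
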