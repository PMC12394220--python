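"""Extraction of hemodynamic summaries from converged waveforms.

MAP and mean flow are period time-averages (trapezoidal rule on the uniform
sample grid, closing the period with the first sample); SP/DP are the
pressure extrema; the area-pulsation amplitude is max - min of the
cross-sectional area over the cycle.  Relative changes are percentages with
respect to the no-cuff baseline of the same probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class WaveformRecord:
    """Per-probe time series over one converged cardiac cycle.

    Units at this boundary are the conventional clinical ones: time s,
    pressure mmHg, flow ml/s, area mm^2.  The time grid spans [0, T) with
    uniform spacing.
    """

    probe: str
    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.pressure) == len(self.flow) == len(self.area) == n):
            raise ValueError("waveform channels must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("waveform time grid must be uniform")

    @property
    def period(self) -> float:
        return float(self.time[-1] + (self.time[1] - self.time[0]))


def _cycle_mean(t: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal time-average of a periodic signal sampled on [0, T)."""
    dt = t[1] - t[0]
    tc = np.append(t, t[-1] + dt)
    yc = np.append(y, y[0])
    return float(np.trapezoid(yc, tc) / (tc[-1] - tc[0]))


@dataclass
class HemodynamicSummary:
    """MAP/SP/DP (mmHg), mean flow (ml/s), area-pulsation amplitude (mm^2)."""

    MAP: float
    SP: float
    DP: float
    Qbar: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.DP <= self.MAP <= self.SP):
            raise ValueError("require DP <= MAP <= SP")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def summarize(record: WaveformRecord) -> HemodynamicSummary:
    """Compute the per-cycle summary of one probe record."""
    if len(record.time) < 2:
        raise ValueError("record must cover a full period with >= 2 samples")
    return HemodynamicSummary(
        MAP=_cycle_mean(record.time, record.pressure),
        SP=float(np.max(record.pressure)),
        DP=float(np.min(record.pressure)),
        Qbar=_cycle_mean(record.time, record.flow),
        amplitude=float(np.max(record.area) - np.min(record.area)),
    )


def relative_change(
    cuffed: HemodynamicSummary, baseline: HemodynamicSummary,
) -> dict[str, float]:
    """Per-metric percentage change 100 (x - x0)/x0 versus baseline.

    Metrics with a zero baseline are flagged as NaN rather than raising.
    """
    out: dict[str, float] = {}
    for name in ("MAP", "SP", "DP", "Qbar", "amplitude"):
        x = getattr(cuffed, name)
        x0 = getattr(baseline, name)
        out[name] = float("nan") if x0 == 0 else 100.0 * (x - x0) / x0
    return out


def occlusion_fraction(cuffed: WaveformRecord, baseline: WaveformRecord) -> float:
    """Percentage reduction of mean flow at an under-cuff probe."""
    q0 = _cycle_mean(baseline.time, baseline.flow)
    if q0 == 0:
        raise ValueError("baseline mean flow is zero")
    q = _cycle_mean(cuffed.time, cuffed.flow)
    return 100.0 * (1.0 - q / q0)


def amplitude_vs_pressure(
    sweep: dict[float, WaveformRecord],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Area-pulsation amplitude across a cuff-pressure sweep at one probe.

    ``sweep`` maps cuff pressure (mmHg) to the under-cuff probe record.
    Returns (pressures, amplitudes, argmax pressure).
    """
    p = np.array(sorted(sweep))
    amp = np.array([
        np.max(sweep[pc].area) - np.min(sweep[pc].area) for pc in p
    ])
    return p, amp, float(p[int(np.argmax(amp))])
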