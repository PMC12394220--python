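"""0-D inflow boundary: time-varying elastance left ventricle.

The ventricle generates p_lv = E(t) (V - V0).  E(t) is a raised-cosine
systolic activation: it rises from Emin to Emax and returns to Emin over the
systolic interval [0, tm), and stays at Emin on the diastolic plateau
[tm, T).  Filling comes from a constant-pressure left atrium through a
resistive-inertial mitral path; ejection goes into the ascending aorta
through a resistive-inertial aortic path.  Valves are pressure-gated
switches; the aortic valve tolerates a cumulative retrograde volume Vb per
beat before closing (Vb = 0 gives an ideal diode).

The same update is implemented inside the compiled solver kernel; this
module is the reference implementation used directly by tests and by the
standalone lumped-circuit checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .vascular import HeartParameters


def elastance(t: float, params: HeartParameters) -> float:
    """Ventricular elastance E(t) (Pa/m^3), periodic with period T.

    Raised cosine on [0, tm): Emin + (Emax-Emin) * (1 - cos(2 pi t/tm))/2,
    peaking at tm/2; constant Emin on [tm, T).
    """
    tau = t % params.T
    if tau < params.tm:
        phase = 2.0 * math.pi * tau / params.tm
        return params.Emin + (params.Emax - params.Emin) * 0.5 * (1.0 - math.cos(phase))
    return params.Emin


@dataclass
class HeartState:
    """Instantaneous state of the 0-D heart model."""

    volume: float  # LV volume, m^3
    q_mitral: float = 0.0  # mitral inflow, m^3/s
    q_aortic: float = 0.0  # aortic outflow (into the 1-D root), m^3/s
    retro_volume: float = 0.0  # cumulative retrograde aortic volume this beat, m^3
    mitral_open: bool = False
    aortic_open: bool = False

    @classmethod
    def end_diastolic(cls, params: HeartParameters) -> "HeartState":
        return cls(volume=params.Vlv)


def heart_step(
    state: HeartState, p_root: float, t: float, dt: float, params: HeartParameters,
) -> HeartState:
    """Advance the heart ODEs one step (explicit Euler on the valve paths).

    p_root is the luminal pressure at the ascending-aorta inlet.  Returns the
    new state; ``state.q_aortic`` of the result is the inflow handed to the
    1-D root.
    """

    E = elastance(t, params)
    p_lv = E * (state.volume - params.V0)

    new = HeartState(
        volume=state.volume,
        q_mitral=state.q_mitral,
        q_aortic=state.q_aortic,
        retro_volume=state.retro_volume,
        mitral_open=state.mitral_open,
        aortic_open=state.aortic_open,
    )

    # mitral path: pla - p_lv = Rla q + Lla dq/dt while open
    if not new.mitral_open and params.pla > p_lv:
        new.mitral_open = True
        new.q_mitral = 0.0
    if new.mitral_open:
        dq = (params.pla - p_lv - params.Rla * new.q_mitral) / params.Lla
        new.q_mitral += dt * dq
        if new.q_mitral < 0.0:  # ideal closure on reverse flow
            new.q_mitral = 0.0
            new.mitral_open = False
    else:
        new.q_mitral = 0.0

    # aortic path: p_lv - p_root = Rlv q + Llv dq/dt while open
    if not new.aortic_open and p_lv > p_root:
        new.aortic_open = True
        new.q_aortic = 0.0
        new.retro_volume = 0.0
    if new.aortic_open:
        dq = (p_lv - p_root - params.Rlv * new.q_aortic) / params.Llv
        new.q_aortic += dt * dq
        if new.q_aortic < 0.0:
            new.retro_volume += -new.q_aortic * dt
            if new.retro_volume >= params.Vb:
                new.q_aortic = 0.0
                new.aortic_open = False
    else:
        new.q_aortic = 0.0

    new.volume += dt * (new.q_mitral - new.q_aortic)
    if not math.isfinite(new.volume) or new.volume <= 0.0:
        raise FloatingPointError("heart state diverged (non-positive LV volume)")
    return new
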