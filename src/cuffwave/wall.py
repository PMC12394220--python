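"""Pressure-area constitutive laws of the arterial wall.

Two laws are used:

* an elastic distension law for every segment of the tree,

      PT(A; x) = beta(x) * (sqrt(A / A0(x)) - 1),      beta = (4/3) Eh/r0,

  with Eh/r0 from the k1,k2,k3 stiffness-radius relation.  It is strictly
  increasing in A, zero at the reference area A0, reaches zero area at the
  finite buckling pressure PT = -beta, and linearizes at A0 to the same
  stiffness (and wave speed c0^2 = (2/3)(Eh/r0)/rho) as the other standard
  square-root tube laws;

* the empirical collapsible-tube law (Drzewiecki-type),

      A(PT) = d * ln(a*PT + b) / (1 + exp(-c*PT)),

  valid from deep collapse (A -> 0 as PT -> -inf through the sigmoid
  denominator) to logarithmic distension at large positive PT, with its
  compliance dA/dPT peaking near PT = 0 (the basis of the oscillometric
  maximum).

The solver keeps the elastic law everywhere.  For a segment lying under an
inflated cuff, the elastic law is locally rescaled -- new reference area and
stiffness -- so that at the expected operating point PT* = (baseline mean
transmural pressure) - Pcuff it matches the collapsible law in both value and
slope.  The match has a closed form: for the elastic family,
A / (dA/dPT) = (beta + PT)/2 identically, so

      beta' = 2 A* / C* - PT*,        A0' = A* / (1 + PT*/beta')^2,

where A* and C* are the collapsible law's area and compliance at PT*.
beta' > 0 whenever A*, C* > 0, so the match is always solvable; at strongly
negative PT* the rescaled segment is very soft and fully collapses (A -> 0)
once the luminal pressure falls below P_ext - beta'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .units import MMHG_TO_PA
from .vascular import VesselSegment


class TubeLawError(ValueError):
    """Constitutive-law evaluation outside its admissible range."""


# ---------------------------------------------------------------------------
# elastic law
# ---------------------------------------------------------------------------

def segment_beta(segment: VesselSegment, x: float) -> float:
    """Elastic coefficient beta(x) = beta_scale * (4/3) Eh/r0 at position x (Pa)."""
    r0 = segment.radius(x)
    return segment.beta_scale * (4.0 / 3.0) * segment.stiffness.eh_over_r0(r0)


def segment_area0(segment: VesselSegment, x: float) -> float:
    """Effective reference area a0_scale * A0(x) at position x (m^2)."""
    return segment.a0_scale * segment.area0(x)


def elastic_pressure(A: float, segment: VesselSegment, x: float) -> float:
    """Transmural pressure PT (Pa) of the elastic law at area A (m^2)."""
    if A <= 0:
        raise TubeLawError("elastic law requires A > 0 (apply the area floor first)")
    beta = segment_beta(segment, x)
    a0 = segment_area0(segment, x)
    return beta * (math.sqrt(A / a0) - 1.0)


def elastic_area(PT: float, segment: VesselSegment, x: float) -> float:
    """Inverse of :func:`elastic_pressure`; requires PT > -beta (buckling)."""
    beta = segment_beta(segment, x)
    a0 = segment_area0(segment, x)
    u = 1.0 + PT / beta
    if u <= 0:
        raise TubeLawError("elastic law has no area for PT <= -beta")
    return a0 * u * u


def elastic_compliance(PT: float, segment: VesselSegment, x: float) -> float:
    """dA/dPT (m^2/Pa) of the elastic law at transmural pressure PT."""
    beta = segment_beta(segment, x)
    A = elastic_area(PT, segment, x)
    # identity A / (dA/dPT) = (beta + PT) / 2 for this family
    return 2.0 * A / (beta + PT)


def wave_speed(A: float, segment: VesselSegment, x: float, rho: float) -> float:
    """Local pulse wave speed (m/s).

    c^2 = (A/rho) dPT/dA = beta/(2 rho) sqrt(A/A0); at A = A0 this is the
    Moens-Korteweg-type speed c0 = sqrt((2/3) (Eh/r0) beta_scale / rho).
    """
    return wave_speed_from(segment_beta(segment, x), segment_area0(segment, x), A, rho)


def wave_speed_from(beta: float, a0: float, A: float, rho: float) -> float:
    return math.sqrt(beta / (2.0 * rho) * math.sqrt(A / a0))


# ---------------------------------------------------------------------------
# collapsible (Drzewiecki-type) law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrzewieckiLaw:
    """Empirical collapsible-tube law A(PT) = d ln(a PT + b)/(1 + exp(-c PT)).

    a (1/Pa) and b (dimensionless) set the logarithmic distension branch,
    c (1/Pa) the sharpness of the collapse sigmoid, d (m^2) the area scale.
    Defaults are a generic muscular-artery shape (pressures of order
    100 mmHg, compliance peak within a few mmHg of PT = 0); b and d are
    re-calibrated per segment against the elastic law before use.
    """

    a: float = 0.02 / MMHG_TO_PA  # per Pa
    b: float = 7.0
    c: float = 0.04 / MMHG_TO_PA
    d: float = 1.0e-5

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0 or self.d <= 0:
            raise TubeLawError("DrzewieckiLaw requires a, c, d > 0")

    @property
    def pt_min(self) -> float:
        """Lower admissible transmural pressure: log argument > 1 (A >= 0)."""
        return (1.0 - self.b) / self.a

    def _check(self, PT: float) -> None:
        if self.a * PT + self.b <= 1.0:
            raise TubeLawError(
                f"PT = {PT / MMHG_TO_PA:.1f} mmHg below the law's admissible "
                f"range (pt_min = {self.pt_min / MMHG_TO_PA:.1f} mmHg)"
            )

    def area(self, PT: float) -> float:
        """Cross-sectional area (m^2) at transmural pressure PT (Pa)."""
        self._check(PT)
        return self.d * math.log(self.a * PT + self.b) / (1.0 + math.exp(-self.c * PT))

    def compliance(self, PT: float) -> float:
        """dA/dPT (m^2/Pa) at transmural pressure PT (Pa)."""
        self._check(PT)
        x = self.a * PT + self.b
        s = math.exp(-self.c * PT)
        denom = 1.0 + s
        log_term = self.d * self.a / (x * denom)
        sig_term = self.d * math.log(x) * self.c * s / (denom * denom)
        return log_term + sig_term


def drzewiecki_area(PT: float, law: DrzewieckiLaw) -> float:
    """Functional alias for :meth:`DrzewieckiLaw.area`."""
    return law.area(PT)


MAX_SWEEP_PCUFF = 150.0 * MMHG_TO_PA
"""Documented cap of the cuff-pressure sweep; calibration keeps the
collapsible law admissible down to PT0 - this pressure."""


def calibrate_law_to_elastic(
    segment: VesselSegment,
    x: float,
    PT0: float,
    law: DrzewieckiLaw | None = None,
    pt_min_required: float | None = None,
) -> DrzewieckiLaw:
    """Fit the collapsible law to the segment's elastic law at PT0.

    Keeps a; solves for b so that the two laws share the same relative
    compliance C/A at PT0 (identically 2/(beta + PT0) for the elastic
    family), then sets d so the areas match.  With value and slope both
    matched at the baseline operating point, the under-cuff rescale at
    Pcuff = 0 reproduces the original elastic law exactly.  For stiff small
    arteries whose relative elastic compliance falls below the default
    sigmoid tail at PT0, the sharpness c is raised (a more abrupt buckling
    transition) until the slope can be matched; b stays at its default and
    only the value is matched in the rare case where even that fails.
    ``pt_min_required`` (default PT0 minus the 150 mmHg sweep cap) sets the
    transmural-pressure range over which the log argument must stay > 1.
    """

    base = law or DrzewieckiLaw()
    A_el = elastic_area(PT0, segment, x)
    C_el = elastic_compliance(PT0, segment, x)
    target = C_el / A_el  # 1/Pa

    if pt_min_required is None:
        pt_min_required = PT0 - MAX_SWEEP_PCUFF
    # admissibility down to pt_min_required: a PT + b > 1 there
    lo = 1.05 - base.a * min(pt_min_required, 0.0)
    hi = 1e4

    def solve_b(cc: float) -> float | None:
        # C/A = a/(x ln x) + c s/S, x = a PT0 + b, s = exp(-c PT0), S = 1+s;
        # decreasing in b; root matches the elastic relative compliance at PT0
        s = math.exp(-cc * PT0)
        S = 1.0 + s

        def resid(b: float) -> float:
            xx = base.a * PT0 + b
            return base.a / (xx * math.log(xx)) + cc * s / S - target

        if resid(lo) > 0 > resid(hi):
            return brentq(resid, lo, hi, xtol=1e-12, rtol=1e-14)
        return None

    c = base.c
    b = solve_b(c)
    while b is None and c < 60.0 * base.c:
        c *= 1.3
        b = solve_b(c)
    if b is None:
        c = base.c
        b = max(base.b, lo)  # value-only fallback (slope left approximate)
    interim = replace(base, b=b, c=c)
    d = base.d * A_el / interim.area(PT0)
    return replace(interim, d=d)


# ---------------------------------------------------------------------------
# under-cuff rescaling
# ---------------------------------------------------------------------------

def rescale_under_cuff(
    segment: VesselSegment,
    p_cuff: float,
    baseline_mean_PT: float,
    law: DrzewieckiLaw,
) -> VesselSegment:
    """Rescale a segment's elastic law for operation under an inflated cuff.

    The operating transmural pressure is PT* = baseline_mean_PT - p_cuff.
    The returned segment's elastic law matches ``law`` in both area and
    compliance at PT* (closed form, see module docstring).  Scales are
    defined at the segment midpoint and applied multiplicatively along the
    taper.  Segments not flagged under_cuff are returned unchanged.
    """

    if not segment.under_cuff:
        return segment
    pt_star = baseline_mean_PT - p_cuff
    a_star = law.area(pt_star)
    c_star = law.compliance(pt_star)
    if a_star <= 0 or c_star <= 0:
        raise TubeLawError("collapsible law must have A, dA/dPT > 0 at PT*")
    beta_new = 2.0 * a_star / c_star - pt_star
    if beta_new <= 0:
        raise TubeLawError(
            f"matching unsolvable at PT* = {pt_star / MMHG_TO_PA:.1f} mmHg"
        )
    u = 1.0 + pt_star / beta_new
    a0_new = a_star / (u * u)

    x_mid = segment.length / 2.0
    beta_ref = (4.0 / 3.0) * segment.stiffness.eh_over_r0(segment.radius(x_mid))
    a0_ref = segment.area0(x_mid)
    out = replace(segment)
    out.beta_scale = beta_new / beta_ref
    out.a0_scale = a0_new / a0_ref
    return out
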