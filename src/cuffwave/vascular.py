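"""Domain types for the arterial network and its boundary models.

The arterial tree is a rooted tree of tapered elastic vessel segments.  Each
leaf carries a three-element Windkessel terminal standing in for the distal
microvasculature; the root (ascending aorta) is fed by a time-varying
elastance ventricle (see :mod:`cuffwave.heart`).  All quantities are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .units import MMHG_TO_PA


class TreeValidationError(ValueError):
    """Raised when a parameter table or tree violates a structural invariant."""


@dataclass(frozen=True)
class BloodProperties:
    """Incompressible Newtonian blood: density (kg/m^3), viscosity (Pa s)."""

    density: float = 1050.0
    viscosity: float = 3.5e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise TreeValidationError("blood density and viscosity must be > 0")


@dataclass(frozen=True)
class WallStiffness:
    """Coefficients of the stiffness-radius relation Eh/r0 = k1*exp(k2*r0) + k3.

    With k2 < 0 the k1 term dominates for small radii and k3 for large ones,
    so the triple spans small, medium and large arteries.  Units: k1, k3 in
    Pa; k2 in 1/m.
    """

    k1: float = 2.0e6
    k2: float = -2253.0
    k3: float = 8.65e4

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k3 <= 0:
            raise TreeValidationError("require k1 >= 0 and k3 > 0")

    def eh_over_r0(self, r0: float) -> float:
        """Effective stiffness Eh/r0 (Pa) at reference radius r0 (m)."""
        val = self.k1 * math.exp(self.k2 * r0) + self.k3
        if val <= 0:
            raise TreeValidationError(f"non-positive Eh/r0 at r0={r0}")
        return val


@dataclass(frozen=True)
class WindkesselTerminal:
    """Three-element (R1-C-R2) Windkessel outflow model.

    R1, R2 in Pa s/m^3; C in m^3/Pa; p_out (venous back-pressure) in Pa.
    """

    R1: float
    R2: float
    C: float
    p_out: float = 0.0

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0 or self.C <= 0:
            raise TreeValidationError("Windkessel R1, R2, C must be > 0")


@dataclass(frozen=True)
class TerminalScaling:
    """Global multipliers on terminal resistances (SR) and compliances (SC)."""

    SR: float = 1.0
    SC: float = 1.0

    def __post_init__(self) -> None:
        if self.SR <= 0 or self.SC <= 0:
            raise TreeValidationError("SR and SC must be > 0")


@dataclass(frozen=True)
class HeartParameters:
    """Constants of the 0-D inflow model (time-varying elastance ventricle).

    The left ventricle with volume V and unstressed volume V0 generates
    pressure p_lv = E(t) (V - V0); it fills from a constant-pressure left
    atrium through a resistive-inertial mitral path (Rla, Lla) and ejects into
    the ascending aorta through an aortic path (Rlv, Llv).  The aortic valve
    tolerates at most a backflow volume Vb per beat before closing.
    """

    T: float = 0.8  # heart period, s
    Emin: float = 1.067e7  # minimal elastance, Pa/m^3  (~0.08 mmHg/ml)
    Emax: float = 5.33e8  # maximal elastance, Pa/m^3  (~4.0 mmHg/ml)
    tm: float = 0.30  # time to onset of the constant (diastolic) elastance, s
    V0: float = 1.0e-5  # unstressed LV volume, m^3 (10 ml)
    Vlv: float = 1.25e-4  # end-diastolic LV volume, m^3 (125 ml)
    pla: float = 1066.6  # left atrial pressure, Pa (~8 mmHg)
    Rlv: float = 4.0e5  # aortic-path resistance, Pa s/m^3
    Llv: float = 6.67e3  # aortic-path inertance, Pa s^2/m^3
    Rla: float = 6.0e5  # mitral-path resistance, Pa s/m^3
    Lla: float = 6.67e3  # mitral-path inertance, Pa s^2/m^3
    Vb: float = 2.0e-6  # permitted retrograde aortic volume per beat, m^3

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise TreeValidationError("heart period T must be > 0")
        if not (0 < self.Emin < self.Emax):
            raise TreeValidationError("require 0 < Emin < Emax")
        if not (0 < self.tm < self.T):
            raise TreeValidationError("require 0 < tm < T")
        if not (self.Vlv > self.V0 >= 0):
            raise TreeValidationError("require Vlv > V0 >= 0")
        for name in ("Rlv", "Llv", "Rla", "Lla"):
            if getattr(self, name) <= 0:
                raise TreeValidationError(f"{name} must be > 0")
        if self.Vb < 0:
            raise TreeValidationError("Vb must be >= 0")


#: canonical cuff placement codes: left/right wrist, left/right ankle
CUFF_SITES = ("LW", "RW", "LA", "RA")


@dataclass(frozen=True)
class CuffSpec:
    """Oscillometric cuff configuration.

    placements is a subset of {LW, RW, LA, RA}; width in m (0.15 m, the
    medium cuff of multi-limb devices); pressure in Pa, uniform across the
    cuff width and equal on all placed cuffs.
    """

    placements: tuple[str, ...]
    pressure: float = 0.0
    width: float = 0.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "placements", tuple(self.placements))
        for p in self.placements:
            if p not in CUFF_SITES:
                raise TreeValidationError(f"unknown cuff site {p!r}")
        if self.width <= 0:
            raise TreeValidationError("cuff width must be > 0")
        if self.pressure < 0:
            raise TreeValidationError("cuff pressure must be >= 0")

    @property
    def pressure_mmhg(self) -> float:
        return self.pressure / MMHG_TO_PA


@dataclass
class VesselSegment:
    """One tapered axisymmetric elastic vessel segment.

    The lumen radius tapers linearly from r_prox at x=0 to r_dist at x=length
    (x increases distally).  p_ext is the uniform external pressure (Pa);
    non-zero only under an inflated cuff.  beta_scale and a0_scale are the
    under-cuff tube-law rescaling factors (1 outside cuffs): the local elastic
    law is PT = beta_scale*beta0(x) * (1 - sqrt(a0_scale*A0(x)/A)).
    """

    id: str
    name: str
    length: float
    r_prox: float
    r_dist: float
    stiffness: WallStiffness = field(default_factory=WallStiffness)
    parent: str | None = None
    children: tuple[str, ...] = ()
    p_ext: float = 0.0
    under_cuff: bool = False
    beta_scale: float = 1.0
    a0_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise TreeValidationError(f"segment {self.id}: length must be > 0")
        if self.r_prox <= 0 or self.r_dist <= 0:
            raise TreeValidationError(f"segment {self.id}: radii must be > 0")
        if self.p_ext < 0:
            raise TreeValidationError(f"segment {self.id}: p_ext must be >= 0")

    def radius(self, x: float) -> float:
        """Reference radius r0(x) of the linear taper, x in [0, length]."""
        t = min(max(x / self.length, 0.0), 1.0)
        return self.r_prox + (self.r_dist - self.r_prox) * t

    def area0(self, x: float) -> float:
        """Reference cross-sectional area A0(x) = pi r0(x)^2 (before rescale)."""
        r = self.radius(x)
        return math.pi * r * r


@dataclass
class ArterialTree:
    """The vessel network: segments, terminal map, scaling and blood."""

    segments: dict[str, VesselSegment]
    terminals: dict[str, WindkesselTerminal]
    scaling: TerminalScaling = field(default_factory=TerminalScaling)
    blood: BloodProperties = field(default_factory=BloodProperties)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def root_id(self) -> str:
        roots = [s.id for s in self.segments.values() if s.parent is None]
        return roots[0]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def leaves(self) -> list[str]:
        return [s.id for s in self.segments.values() if not s.children]

    def validate(self) -> None:
        roots = [s for s in self.segments.values() if s.parent is None]
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        for seg in self.segments.values():
            if seg.parent is not None and seg.parent not in self.segments:
                raise TreeValidationError(
                    f"segment {seg.id}: parent {seg.parent!r} does not exist"
                )
            for c in seg.children:
                if c not in self.segments:
                    raise TreeValidationError(
                        f"segment {seg.id}: child {c!r} does not exist"
                    )
                if self.segments[c].parent != seg.id:
                    raise TreeValidationError(
                        f"segment {c}: parent link inconsistent with {seg.id}"
                    )
            if len(seg.children) > 2:
                raise TreeValidationError(f"segment {seg.id}: more than 2 children")
            if seg.children and seg.id in self.terminals:
                raise TreeValidationError(
                    f"segment {seg.id}: has both children and a terminal"
                )
            if not seg.children and seg.id not in self.terminals:
                raise TreeValidationError(f"leaf {seg.id}: missing terminal")
        # reachability: every segment reachable from the root exactly once
        seen: set[str] = set()
        stack = [roots[0].id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise TreeValidationError(f"segment {sid} visited twice")
            seen.add(sid)
            stack.extend(self.segments[sid].children)
        if seen != set(self.segments):
            orphans = set(self.segments) - seen
            raise TreeValidationError(f"orphan segments: {sorted(orphans)}")
        for sid in self.terminals:
            if sid not in self.segments:
                raise TreeValidationError(f"terminal attached to unknown segment {sid}")

    def copy(self) -> "ArterialTree":
        return ArterialTree(
            segments={k: replace(v) for k, v in self.segments.items()},
            terminals=dict(self.terminals),
            scaling=self.scaling,
            blood=self.blood,
        )

    def scaled_terminal(self, sid: str) -> WindkesselTerminal:
        """Terminal with the tree-level (SR, SC) scaling applied."""
        t = self.terminals[sid]
        return WindkesselTerminal(
            R1=t.R1 * self.scaling.SR,
            R2=t.R2 * self.scaling.SR,
            C=t.C * self.scaling.SC,
            p_out=t.p_out,
        )


def apply_scaling(tree: ArterialTree, scaling: TerminalScaling) -> ArterialTree:
    """Multiply every terminal's resistances by SR and compliance by SC.

    Returns a new tree; geometry untouched.  The scaling is folded into the
    terminal values (the tree-level scaling of the result stays (1, 1)) so
    successive applications compose multiplicatively.
    """

    new_terms = {
        sid: WindkesselTerminal(
            R1=t.R1 * scaling.SR, R2=t.R2 * scaling.SR, C=t.C * scaling.SC,
            p_out=t.p_out,
        )
        for sid, t in tree.terminals.items()
    }
    return ArterialTree(
        segments={k: replace(v) for k, v in tree.segments.items()},
        terminals=new_terms,
        scaling=tree.scaling,
        blood=tree.blood,
    )


# ---------------------------------------------------------------------------
# parameter-table I/O
# ---------------------------------------------------------------------------

TREE_COLUMNS = [
    "id", "name", "length_m", "r_prox_m", "r_dist_m", "k_class", "parent",
    "R1", "R2", "C", "P_out",
]

#: named stiffness classes; a table's k_class column selects one per segment
DEFAULT_STIFFNESS_SETS: dict[str, WallStiffness] = {
    "default": WallStiffness(),
}


def load_tree(
    path: str | Path,
    stiffness_sets: dict[str, WallStiffness] | None = None,
    blood: BloodProperties | None = None,
    scaling: TerminalScaling | None = None,
) -> ArterialTree:
    """Read an arterial tree from a CSV parameter table.

    Expected columns: id,name,length_m,r_prox_m,r_dist_m,k_class,parent,
    R1,R2,C,P_out.  Rows with empty parent are the root; rows with all of
    R1,R2,C present are leaves carrying a Windkessel terminal.  Lines
    starting with '#' are header/provenance comments.
    """

    df = pd.read_csv(path, comment="#", dtype={"id": str, "parent": str},
                     float_precision="round_trip")
    missing = [c for c in TREE_COLUMNS if c not in df.columns]
    if missing:
        raise TreeValidationError(f"parameter table missing columns: {missing}")
    sets = stiffness_sets or DEFAULT_STIFFNESS_SETS

    segments: dict[str, VesselSegment] = {}
    terminals: dict[str, WindkesselTerminal] = {}
    children: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        sid = str(row.id)
        parent = None if pd.isna(row.parent) or row.parent == "" else str(row.parent)
        kc = str(row.k_class)
        if kc in sets:
            ws_row = sets[kc]
        elif kc.startswith("k_"):
            # explicit triple encoded as k_<k1>_<k2>_<k3>
            try:
                k1, k2, k3 = (float(v) for v in kc[2:].split("_"))
            except ValueError as err:
                raise TreeValidationError(
                    f"segment {sid}: malformed stiffness triple {kc!r}"
                ) from err
            ws_row = WallStiffness(k1=k1, k2=k2, k3=k3)
        else:
            raise TreeValidationError(f"segment {sid}: unknown stiffness class {kc!r}")
        segments[sid] = VesselSegment(
            id=sid, name=str(row.name), length=float(row.length_m),
            r_prox=float(row.r_prox_m), r_dist=float(row.r_dist_m),
            stiffness=ws_row, parent=parent,
        )
        if parent is not None:
            children.setdefault(parent, []).append(sid)
        has_term = not (pd.isna(row.R1) or pd.isna(row.R2) or pd.isna(row.C))
        if has_term:
            p_out = 0.0 if pd.isna(row.P_out) else float(row.P_out)
            terminals[sid] = WindkesselTerminal(
                R1=float(row.R1), R2=float(row.R2), C=float(row.C), p_out=p_out,
            )
    for sid, kids in children.items():
        if sid not in segments:
            raise TreeValidationError(f"parent id {sid!r} referenced but absent")
        segments[sid].children = tuple(kids)
    return ArterialTree(
        segments=segments,
        terminals=terminals,
        scaling=scaling or TerminalScaling(),
        blood=blood or BloodProperties(),
    )


def save_tree(tree: ArterialTree, path: str | Path, header: str | None = None) -> None:
    """Write a tree back to the CSV parameter-table format (round-trip safe)."""

    # invert the stiffness sets so k_class survives a round trip
    inv: dict[WallStiffness, str] = {}
    for name, ws in DEFAULT_STIFFNESS_SETS.items():
        inv.setdefault(ws, name)
    rows = []
    for seg in tree.segments.values():
        kc = inv.get(seg.stiffness)
        if kc is None:
            kc = f"k_{seg.stiffness.k1:.6g}_{seg.stiffness.k2:.6g}_{seg.stiffness.k3:.6g}"
        term = tree.terminals.get(seg.id)
        rows.append({
            "id": seg.id, "name": seg.name, "length_m": repr(seg.length),
            "r_prox_m": repr(seg.r_prox), "r_dist_m": repr(seg.r_dist),
            "k_class": kc, "parent": seg.parent or "",
            "R1": repr(term.R1) if term else "",
            "R2": repr(term.R2) if term else "",
            "C": repr(term.C) if term else "",
            "P_out": repr(term.p_out) if term else "",
        })
    df = pd.DataFrame(rows, columns=TREE_COLUMNS)
    with open(path, "w") as fh:
        if header:
            for line in header.strip().splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
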