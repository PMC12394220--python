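"""Virtual patients: packaged baseline, cohort sampler, toy fixtures.

The packaged baseline emulates the arterial tree of a healthy young adult
male (~25 years, 175 cm): 71 tapered segments from the aortic root to the
wrist and ankle arteries, with three-element Windkessel terminals whose
resistances partition the cardiac output into physiologically plausible
regional fractions.  The geometry is SYNTHETIC: anatomically representative
lengths/radii assembled for this package (not transcribed from any specific
published subject), with terminal parameters tuned by
``scripts/build_baseline.py`` so that the simulated ascending-aorta pressure
is close to 125/95/80 mmHg (SP/MAP/DP).  Leg arteries are exactly
left-right symmetric; the arms are symmetric in their own geometry but fed
asymmetrically (the right side via the brachiocephalic trunk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .units import MMHG_TO_PA
from .vascular import (
    ArterialTree,
    BloodProperties,
    HeartParameters,
    TerminalScaling,
    TreeValidationError,
    VesselSegment,
    WallStiffness,
    WindkesselTerminal,
    load_tree,
)

# ---------------------------------------------------------------------------
# anatomy table: id, L (cm), r_prox (cm), r_dist (cm), parent, CO fraction
# (None for internal segments).  Synthetic representative anatomy.
# ---------------------------------------------------------------------------
_ANATOMY: list[tuple[str, float, float, float, str | None, float | None]] = [
    ("aortic_root",        2.0, 1.46, 1.45, None, None),
    ("l_coronary",        10.0, 0.22, 0.18, "aortic_root", 0.020),
    ("ascending_aorta",    3.0, 1.45, 1.36, "aortic_root", None),
    ("r_coronary",        10.0, 0.22, 0.18, "ascending_aorta", 0.020),
    ("aortic_arch_a",      2.0, 1.36, 1.30, "ascending_aorta", None),
    ("brachiocephalic",    3.4, 0.62, 0.60, "aortic_arch_a", None),
    ("aortic_arch_b",      2.0, 1.30, 1.24, "aortic_arch_a", None),
    ("l_common_carotid_a", 8.9, 0.39, 0.37, "aortic_arch_b", None),
    ("aortic_arch_c",      3.0, 1.24, 1.12, "aortic_arch_b", None),
    ("l_subclavian",       3.4, 0.42, 0.40, "aortic_arch_c", None),
    ("thoracic_aorta_a",   5.0, 1.12, 1.05, "aortic_arch_c", None),
    ("intercostals",       7.3, 0.30, 0.25, "thoracic_aorta_a", 0.025),
    ("thoracic_aorta_b",   8.0, 1.05, 0.95, "thoracic_aorta_a", None),
    ("thoracic_aorta_c",   8.0, 0.95, 0.87, "thoracic_aorta_b", None),
    ("abdominal_aorta_a",  4.0, 0.87, 0.80, "thoracic_aorta_c", None),
    ("celiac",             2.0, 0.39, 0.36, "abdominal_aorta_a", None),
    ("hepatic",            6.6, 0.27, 0.22, "celiac", 0.055),
    ("splenic",            6.3, 0.28, 0.22, "celiac", 0.050),
    ("abdominal_aorta_b",  2.0, 0.80, 0.77, "abdominal_aorta_a", None),
    ("sup_mesenteric",     5.9, 0.43, 0.35, "abdominal_aorta_b", 0.090),
    ("abdominal_aorta_c",  2.0, 0.77, 0.74, "abdominal_aorta_b", None),
    ("r_renal",            3.2, 0.28, 0.25, "abdominal_aorta_c", 0.075),
    ("abdominal_aorta_d",  2.0, 0.74, 0.71, "abdominal_aorta_c", None),
    ("l_renal",            3.2, 0.28, 0.25, "abdominal_aorta_d", 0.075),
    ("abdominal_aorta_e",  4.0, 0.71, 0.65, "abdominal_aorta_d", None),
    ("gonadal",            7.0, 0.16, 0.13, "abdominal_aorta_e", 0.005),
    ("abdominal_aorta_f",  4.0, 0.65, 0.61, "abdominal_aorta_e", None),
    ("inf_mesenteric",     5.0, 0.20, 0.16, "abdominal_aorta_f", 0.020),
    ("abdominal_aorta_g",  4.0, 0.61, 0.58, "abdominal_aorta_f", None),
    ("r_common_iliac",     5.9, 0.52, 0.50, "abdominal_aorta_g", None),
    ("l_common_iliac",     5.9, 0.52, 0.50, "abdominal_aorta_g", None),
    # head and neck
    ("r_common_carotid_a", 8.9, 0.39, 0.37, "brachiocephalic", None),
    ("r_common_carotid_b", 8.9, 0.37, 0.35, "r_common_carotid_a", None),
    ("r_int_carotid",     17.0, 0.25, 0.20, "r_common_carotid_b", 0.055),
    ("r_ext_carotid",     17.0, 0.20, 0.15, "r_common_carotid_b", 0.020),
    ("l_common_carotid_b", 8.9, 0.37, 0.35, "l_common_carotid_a", None),
    ("l_int_carotid",     17.0, 0.25, 0.20, "l_common_carotid_b", 0.055),
    ("l_ext_carotid",     17.0, 0.20, 0.15, "l_common_carotid_b", 0.020),
    # right arm (fed via the brachiocephalic trunk)
    ("r_subclavian",       3.4, 0.42, 0.40, "brachiocephalic", None),
    ("r_vertebral",       14.8, 0.19, 0.13, "r_subclavian", 0.018),
    ("r_axillary",        12.0, 0.40, 0.36, "r_subclavian", None),
    ("r_brachial",        22.0, 0.36, 0.28, "r_axillary", None),
    ("r_radial",          25.0, 0.19, 0.16, "r_brachial", 0.020),
    ("r_ulnar_a",          6.7, 0.21, 0.19, "r_brachial", None),
    ("r_interosseous",    21.0, 0.12, 0.09, "r_ulnar_a", 0.007),
    ("r_ulnar",           23.3, 0.19, 0.15, "r_ulnar_a", 0.018),
    # left arm
    ("l_vertebral",       14.8, 0.19, 0.13, "l_subclavian", 0.018),
    ("l_axillary",        12.0, 0.40, 0.36, "l_subclavian", None),
    ("l_brachial",        22.0, 0.36, 0.28, "l_axillary", None),
    ("l_radial",          25.0, 0.19, 0.16, "l_brachial", 0.020),
    ("l_ulnar_a",          6.7, 0.21, 0.19, "l_brachial", None),
    ("l_interosseous",    21.0, 0.12, 0.09, "l_ulnar_a", 0.007),
    ("l_ulnar",           23.3, 0.19, 0.15, "l_ulnar_a", 0.018),
    # right leg (legs exactly symmetric)
    ("r_int_iliac",        5.0, 0.28, 0.25, "r_common_iliac", 0.035),
    ("r_ext_iliac",       14.4, 0.45, 0.41, "r_common_iliac", None),
    ("r_femoral",         12.7, 0.40, 0.36, "r_ext_iliac", None),
    ("r_deep_femoral",    12.6, 0.28, 0.24, "r_femoral", 0.035),
    ("r_popliteal",       18.9, 0.34, 0.30, "r_femoral", None),
    ("r_anterior_tibial", 33.3, 0.15, 0.12, "r_popliteal", 0.017),
    ("r_tibiofibular",     3.5, 0.24, 0.23, "r_popliteal", None),
    ("r_peroneal",        32.0, 0.13, 0.10, "r_tibiofibular", 0.008),
    ("r_posterior_tibial", 30.8, 0.18, 0.14, "r_tibiofibular", 0.031),
    # left leg
    ("l_int_iliac",        5.0, 0.28, 0.25, "l_common_iliac", 0.035),
    ("l_ext_iliac",       14.4, 0.45, 0.41, "l_common_iliac", None),
    ("l_femoral",         12.7, 0.40, 0.36, "l_ext_iliac", None),
    ("l_deep_femoral",    12.6, 0.28, 0.24, "l_femoral", 0.035),
    ("l_popliteal",       18.9, 0.34, 0.30, "l_femoral", None),
    ("l_anterior_tibial", 33.3, 0.15, 0.12, "l_popliteal", 0.017),
    ("l_tibiofibular",     3.5, 0.24, 0.23, "l_popliteal", None),
    ("l_peroneal",        32.0, 0.13, 0.10, "l_tibiofibular", 0.008),
    ("l_posterior_tibial", 30.8, 0.18, 0.14, "l_tibiofibular", 0.031),
]


@dataclass
class VirtualPatient:
    """A complete parameterization of one simulated subject."""

    tree: ArterialTree
    heart: HeartParameters
    provenance: str  # packaged-baseline | sampled | toy

    @property
    def blood(self) -> BloodProperties:
        return self.tree.blood


def build_raw_tree(
    co: float = 9.0e-5,
    map_target: float = 95.0 * MMHG_TO_PA,
    p_out: float = 4.0 * MMHG_TO_PA,
    rc_time: float = 1.4,
    r1_fraction: float = 0.12,
    r1_impedance: bool = True,
    stiffness: WallStiffness | None = None,
    blood: BloodProperties | None = None,
) -> ArterialTree:
    """Assemble the synthetic 71-segment tree with untuned terminals.

    Terminal total resistances split the target cardiac output ``co`` (m^3/s)
    at the target mean pressure according to the anatomy table's regional
    fractions; compliances give every terminal the same RC time ``rc_time``
    (s).  ``scripts/build_baseline.py`` rescales these against the simulated
    pressures and freezes the result into the packaged table.
    """

    ws = stiffness or WallStiffness()
    fracs = {r[0]: r[5] for r in _ANATOMY if r[5] is not None}
    total = sum(fracs.values())
    segments: dict[str, VesselSegment] = {}
    terminals: dict[str, WindkesselTerminal] = {}
    children: dict[str, list[str]] = {}
    for sid, L, rp, rd, parent, frac in _ANATOMY:
        segments[sid] = VesselSegment(
            id=sid, name=sid.replace("_", " "), length=L / 100.0,
            r_prox=rp / 100.0, r_dist=rd / 100.0, stiffness=ws, parent=parent,
        )
        if parent is not None:
            children.setdefault(parent, []).append(sid)
        if frac is not None:
            q_i = co * frac / total
            r_tot = (map_target - p_out) / q_i
            if r1_impedance:
                # match R1 to the leaf's characteristic impedance rho c0 / A0
                # (minimizes terminal wave reflection), capped at 0.4 R_tot
                rho = (blood or BloodProperties()).density
                a_d = math.pi * (rd / 100.0) ** 2
                c0 = math.sqrt((2.0 / 3.0) * ws.eh_over_r0(rd / 100.0) / rho)
                r1 = min(rho * c0 / a_d, 0.4 * r_tot)
            else:
                r1 = r1_fraction * r_tot
            r2 = r_tot - r1
            terminals[sid] = WindkesselTerminal(
                R1=r1, R2=r2, C=rc_time / r2, p_out=p_out,
            )
    for sid, kids in children.items():
        segments[sid].children = tuple(kids)
    return ArterialTree(
        segments=segments, terminals=terminals,
        blood=blood or BloodProperties(),
    )


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cuffwave").joinpath("data").joinpath(name)))


def baseline_patient() -> VirtualPatient:
    """The packaged baseline virtual patient (deterministic).

    Loads the tuned parameter table and heart configuration shipped with the
    package (built once by ``scripts/build_baseline.py``).
    """
    tree = load_tree(_data_path("baseline_tree.csv"))
    if tree.n_segments != 71:
        raise TreeValidationError(
            f"packaged baseline must have 71 segments, found {tree.n_segments}"
        )
    with open(_data_path("baseline_config.yaml")) as fh:
        cfg = yaml.safe_load(fh)
    heart = HeartParameters(**cfg["heart"])
    blood = BloodProperties(**cfg.get("blood", {}))
    tree.blood = blood
    return VirtualPatient(tree=tree, heart=heart, provenance="packaged-baseline")


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

#: sampleable parameters: heart constants plus terminal/stiffness scalings
HEART_PARAM_NAMES = (
    "T", "Emin", "Emax", "tm", "V0", "Vlv", "pla",
    "Rlv", "Llv", "Rla", "Lla", "Vb",
)
SCALING_PARAM_NAMES = ("SR", "SC")
STIFFNESS_PARAM_NAMES = ("k1", "k2", "k3")
ALL_PARAM_NAMES = HEART_PARAM_NAMES + SCALING_PARAM_NAMES + STIFFNESS_PARAM_NAMES


def perturb_patient(
    base: VirtualPatient, multipliers: dict[str, float], provenance: str = "sampled",
) -> VirtualPatient:
    """Return a patient with named parameters multiplied by given factors.

    Multipliers apply to heart constants, SR/SC terminal scalings, and the
    k1/k2/k3 stiffness constants (k2, being negative, is scaled in
    magnitude).  Unknown names raise.
    """

    for name in multipliers:
        if name not in ALL_PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
    hkw = {n: getattr(base.heart, n) * multipliers.get(n, 1.0)
           for n in HEART_PARAM_NAMES}
    # keep tm a fixed fraction of T unless tm itself is perturbed
    heart = HeartParameters(**hkw)
    tree = base.tree.copy()
    sr = multipliers.get("SR", 1.0)
    sc = multipliers.get("SC", 1.0)
    tree.scaling = TerminalScaling(SR=tree.scaling.SR * sr, SC=tree.scaling.SC * sc)
    if any(n in multipliers for n in STIFFNESS_PARAM_NAMES):
        for seg in tree.segments.values():
            ws = seg.stiffness
            seg.stiffness = WallStiffness(
                k1=ws.k1 * multipliers.get("k1", 1.0),
                k2=ws.k2 * multipliers.get("k2", 1.0),
                k3=ws.k3 * multipliers.get("k3", 1.0),
            )
    return VirtualPatient(tree=tree, heart=heart, provenance=provenance)


def sample_cohort(
    n: int,
    fraction: float = 0.10,
    parameters: tuple[str, ...] = ALL_PARAM_NAMES,
    seed: int = 0,
    base: VirtualPatient | None = None,
) -> list[VirtualPatient]:
    """Draw ``n`` patients with parameters uniform in +/- fraction of default.

    Independent uniform multipliers in [1-fraction, 1+fraction] per parameter
    per patient; reproducible for a fixed seed.
    """

    if n < 1:
        raise ValueError("n must be >= 1")
    for p in parameters:
        if p not in ALL_PARAM_NAMES:
            raise KeyError(f"unknown parameter {p!r}")
    base = base or baseline_patient()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        mult = {
            p: 1.0 + fraction * (2.0 * rng.random() - 1.0) for p in parameters
        }
        out.append(perturb_patient(base, mult))
    return out


# ---------------------------------------------------------------------------
# toy fixtures
# ---------------------------------------------------------------------------

def toy_tree(n_segments: int = 1, seed: int = 0) -> VirtualPatient:
    """A small validated tree for fast tests (1 <= n_segments <= 15).

    n_segments in {1, 3, 7, 15} gives a symmetric binary tree of uniform
    depth; other values give a serial chain.  Physiologic magnitudes
    (centimetre radii, decimetre lengths, arterial stiffness defaults).
    """

    if not (1 <= n_segments <= 15):
        raise ValueError("n_segments must be in [1, 15]")
    ws = WallStiffness()
    segments: dict[str, VesselSegment] = {}
    terminals: dict[str, WindkesselTerminal] = {}
    # sized for the default heart's full output: ~90 ml/s at ~95 mmHg
    term = WindkesselTerminal(R1=1.6e7, R2=1.2e8, C=1.1e-8, p_out=4.0 * MMHG_TO_PA)

    def mk(sid: str, parent: str | None, L: float, rp: float, rd: float) -> None:
        segments[sid] = VesselSegment(
            id=sid, name=sid, length=L, r_prox=rp, r_dist=rd,
            stiffness=ws, parent=parent,
        )

    if n_segments in (3, 7, 15):
        depth = {3: 2, 7: 3, 15: 4}[n_segments]
        # complete binary tree; radii shrink by Murray-like factor per level
        def build(sid: str, parent: str | None, level: int, r: float) -> None:
            mk(sid, parent, 0.15, r, 0.92 * r)
            if level + 1 < depth:
                kids = (sid + "0", sid + "1")
                for k in kids:
                    build(k, sid, level + 1, 0.92 * r * 0.79)
                segments[sid].children = kids
            else:
                terminals[sid] = term
        build("s", None, 0, 0.01)
    else:
        prev = None
        r = 0.01
        for i in range(n_segments):
            sid = f"s{i}"
            mk(sid, prev, 0.15, r, 0.95 * r)
            if prev is not None:
                segments[prev].children = (sid,)
            prev = sid
            r *= 0.95
        terminals[prev] = term
    n_term = len(terminals)
    if n_term > 1:
        # split the single-vessel terminal conductance across the leaves
        for sid in terminals:
            terminals[sid] = WindkesselTerminal(
                R1=term.R1 * n_term, R2=term.R2 * n_term,
                C=term.C / n_term, p_out=term.p_out,
            )
    tree = ArterialTree(segments=segments, terminals=terminals)
    heart = HeartParameters()
    return VirtualPatient(tree=tree, heart=heart, provenance="toy")
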