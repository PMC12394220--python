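"""Cuff placement, segment splitting, external pressure and sweeps.

A wrist cuff compresses the distal radial, interosseous and ulnar arteries;
an ankle cuff the distal anterior and posterior tibial arteries.  Cuffs are
aligned so that each cuff ends at the distal end of the longest covered
artery: an artery shorter than the longest by delta is covered over
(width - delta) of its distal end (floored at zero, clipped to the artery
length).  Each covered artery is split into a pre-cuff segment (keeps the
original id) and an under-cuff segment (suffix ``__cuff``) that carries the
terminal and the external pressure.

Applying a cuff pressure sets P_ext = Pcuff uniformly on under-cuff
segments (zero everywhere else) and rescales their elastic tube law to the
collapsible law at the expected operating point (baseline mean transmural
pressure minus Pcuff); see :mod:`cuffwave.wall`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .solver import Probe, SimulationResult, SolverSettings, run_to_steady_state
from .units import MMHG_TO_PA
from .vascular import ArterialTree, CuffSpec, HeartParameters, TreeValidationError
from .wall import calibrate_law_to_elastic, rescale_under_cuff

CUFF_SUFFIX = "__cuff"

#: arteries covered per cuff site (terminal arteries of the limb)
SITE_ARTERIES: dict[str, tuple[str, ...]] = {
    "LW": ("l_radial", "l_interosseous", "l_ulnar"),
    "RW": ("r_radial", "r_interosseous", "r_ulnar"),
    "LA": ("l_anterior_tibial", "l_posterior_tibial"),
    "RA": ("r_anterior_tibial", "r_posterior_tibial"),
}


@dataclass
class CuffCoverage:
    """One covered artery: split position and resulting under-cuff segment."""

    artery: str
    covered_length: float
    split_x: float  # distance of the split from the artery's proximal end
    under_id: str


@dataclass
class CuffPlacementPlan:
    """Per-site coverage produced by :func:`place_cuffs`."""

    spec: CuffSpec
    coverage: dict[str, list[CuffCoverage]] = field(default_factory=dict)

    @property
    def under_cuff_ids(self) -> list[str]:
        return [c.under_id for cov in self.coverage.values() for c in cov]


def covered_lengths(
    tree: ArterialTree, arteries: tuple[str, ...], width: float,
) -> dict[str, float]:
    """Distal covered length per artery under the longest-artery alignment rule."""
    lengths = {a: tree.segments[a].length for a in arteries}
    lmax = max(lengths.values())
    out = {}
    for a, L in lengths.items():
        cov = width - (lmax - L)
        if cov > L:
            warnings.warn(
                f"cuff wider than artery {a}; covering its full length",
                stacklevel=2,
            )
            cov = L
        out[a] = max(cov, 0.0)
    return out


def place_cuffs(
    tree: ArterialTree, spec: CuffSpec,
) -> tuple[ArterialTree, CuffPlacementPlan]:
    """Split covered arteries into pre-cuff and under-cuff segments.

    Returns a new tree plus the placement plan.  Total length, taper and
    connectivity are preserved; the under-cuff child inherits the terminal.
    Idempotent: re-placing the same spec on an already-split tree is a no-op.
    """

    plan = CuffPlacementPlan(spec=spec)
    new = tree.copy()
    for site in spec.placements:
        arteries = SITE_ARTERIES[site]
        for a in arteries:
            if a not in tree.segments and a + CUFF_SUFFIX not in tree.segments:
                raise TreeValidationError(f"cuff site {site}: no artery {a!r} in tree")
        if all(a + CUFF_SUFFIX in new.segments for a in arteries):
            plan.coverage[site] = [
                CuffCoverage(
                    artery=a,
                    covered_length=new.segments[a + CUFF_SUFFIX].length,
                    split_x=new.segments[a].length,
                    under_id=a + CUFF_SUFFIX,
                )
                for a in arteries
            ]
            continue
        cov = covered_lengths(tree, arteries, spec.width)
        plan.coverage[site] = []
        for a in arteries:
            seg = new.segments[a]
            c = cov[a]
            if c <= 0:
                continue
            split_x = seg.length - c
            under_id = a + CUFF_SUFFIX
            if split_x <= 0:
                # fully covered: flag in place, no split
                seg.under_cuff = True
                plan.coverage[site].append(
                    CuffCoverage(artery=a, covered_length=seg.length,
                                 split_x=0.0, under_id=a)
                )
                continue
            r_split = seg.radius(split_x)
            under = replace(
                seg, id=under_id, name=seg.name + " (under cuff)",
                length=c, r_prox=r_split, r_dist=seg.r_dist,
                parent=a, children=(), under_cuff=True,
            )
            seg.length = split_x
            seg.r_dist = r_split
            seg.children = (under_id,)
            new.segments[under_id] = under
            if a in new.terminals:
                new.terminals[under_id] = new.terminals.pop(a)
            plan.coverage[site].append(
                CuffCoverage(artery=a, covered_length=c, split_x=split_x,
                             under_id=under_id)
            )
    new.validate()
    return new, plan


def apply_cuff_pressure(
    tree: ArterialTree,
    plan: CuffPlacementPlan,
    p_cuff: float,
    baseline: SimulationResult | None,
) -> ArterialTree:
    """Apply P_ext = p_cuff (Pa) to under-cuff segments and rescale their laws.

    ``baseline`` must be a converged run of the SAME split tree at zero cuff
    pressure; it supplies the per-segment baseline mean transmural pressures
    at which the collapsible law is calibrated.  p_cuff = 0 resets external
    pressure and tube-law scales (hemodynamically identical to baseline).
    """

    if p_cuff < 0:
        raise ValueError("cuff pressure must be >= 0")
    new = tree.copy()
    for uid in plan.under_cuff_ids:
        seg = new.segments[uid]
        seg.p_ext = p_cuff
        seg.beta_scale = 1.0
        seg.a0_scale = 1.0
        if p_cuff == 0.0:
            continue
        if baseline is None:
            raise ValueError("a converged baseline run is required for p_cuff > 0")
        pt0 = baseline.segment_mean_pressure[uid]  # zero P_ext at baseline
        law = calibrate_law_to_elastic(
            seg, seg.length / 2.0, pt0, pt_min_required=pt0 - p_cuff,
        )
        new.segments[uid] = rescale_under_cuff(seg, p_cuff, pt0, law)
        new.segments[uid].p_ext = p_cuff
    return new


# ---------------------------------------------------------------------------
# probes and sweeps
# ---------------------------------------------------------------------------

def central_probes(tree: ArterialTree) -> list[Probe]:
    """Midpoint probes in the ascending aorta, left CCA and abdominal aorta."""
    out = []
    for sid, label in (
        ("ascending_aorta", "ascending_aorta"),
        ("l_common_carotid_b", "left_cca"),
        ("abdominal_aorta_a", "abdominal_aorta"),
    ):
        out.append(Probe(segment=sid, x=tree.segments[sid].length / 2.0, label=label))
    return out


def radial_probes(tree: ArterialTree, plan: CuffPlacementPlan) -> list[Probe]:
    """The local-effect probes: 2 cm before, middle of, and end of the cuff.

    Defined on the left radial artery (pre-cuff and under-cuff segments).
    """
    pre = tree.segments["l_radial"]
    under_id = "l_radial" + CUFF_SUFFIX
    under = tree.segments[under_id]
    return [
        Probe("l_radial", max(pre.length - 0.02, 0.0), "radial_before_cuff"),
        Probe(under_id, under.length / 2.0, "radial_mid_cuff"),
        Probe(under_id, under.length, "radial_end_cuff"),
    ]


def baseline_run(
    tree: ArterialTree,
    heart: HeartParameters,
    settings: SolverSettings,
    probes: list[Probe],
) -> SimulationResult:
    return run_to_steady_state(tree, heart, settings, probes)


def pressure_sweep(
    tree: ArterialTree,
    heart: HeartParameters,
    spec: CuffSpec,
    pressures_mmhg: list[float],
    settings: SolverSettings,
    extra_probes: bool = False,
) -> dict[float, SimulationResult | Exception]:
    """Independent steady-state runs over a list of cuff pressures (mmHg).

    The tree is split once; a zero-pressure baseline on the split tree
    anchors the under-cuff law calibration and is reused for the 0 mmHg
    entry.  Each run restarts from the same quiescent initialization.
    Individual failures are recorded per pressure without aborting.
    """

    if list(pressures_mmhg) != sorted(pressures_mmhg):
        raise ValueError("pressures must be sorted ascending")
    split, plan = place_cuffs(tree, spec)
    probes = central_probes(split)
    if extra_probes and "LW" in spec.placements:
        probes = probes + radial_probes(split, plan)
    base = run_to_steady_state(split, heart, settings, probes)
    results: dict[float, SimulationResult | Exception] = {}
    for p in pressures_mmhg:
        if p == 0.0:
            results[0.0] = base
            continue
        try:
            cuffed = apply_cuff_pressure(split, plan, p * MMHG_TO_PA, base)
            results[p] = run_to_steady_state(cuffed, heart, settings, probes)
        except Exception as err:  # noqa: BLE001 - recorded per pressure
            results[p] = err
    return results
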