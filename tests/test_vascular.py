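"""Domain types, validation, parameter-table I/O and terminal scaling."""

from __future__ import annotations

import math

import pytest

from cuffwave import (
    MMHG_TO_PA,
    ArterialTree,
    BloodProperties,
    HeartParameters,
    TerminalScaling,
    TreeValidationError,
    VesselSegment,
    WallStiffness,
    WindkesselTerminal,
    apply_scaling,
    load_tree,
    save_tree,
)


def make_single_vessel(**kw) -> ArterialTree:
    seg = VesselSegment(id="v", name="vessel", length=0.1, r_prox=0.005,
                        r_dist=0.004, **kw)
    term = WindkesselTerminal(R1=1e8, R2=1e9, C=1e-9)
    return ArterialTree(segments={"v": seg}, terminals={"v": term})


class TestValidation:
    def test_single_vessel_tree_is_valid(self):
        tree = make_single_vessel()
        assert tree.n_segments == 1
        assert tree.root_id == "v"
        assert tree.leaves() == ["v"]

    def test_orphan_parent_reference_rejected(self):
        root = VesselSegment(id="v", name="v", length=0.1, r_prox=0.005,
                             r_dist=0.004)
        stray = VesselSegment(id="w", name="w", length=0.1, r_prox=0.004,
                              r_dist=0.003, parent="ghost")
        term = WindkesselTerminal(1e8, 1e9, 1e-9)
        with pytest.raises(TreeValidationError, match="ghost"):
            ArterialTree(segments={"v": root, "w": stray},
                         terminals={"v": term, "w": term})

    def test_leaf_without_terminal_rejected(self):
        seg = VesselSegment(id="v", name="v", length=0.1, r_prox=0.005,
                            r_dist=0.004)
        with pytest.raises(TreeValidationError, match="missing terminal"):
            ArterialTree(segments={"v": seg}, terminals={})

    @pytest.mark.parametrize("field,value", [
        ("length", -0.1), ("r_prox", 0.0), ("r_dist", -1e-3),
    ])
    def test_non_positive_geometry_rejected(self, field, value):
        kw = dict(id="v", name="v", length=0.1, r_prox=0.005, r_dist=0.004)
        kw[field] = value
        with pytest.raises(TreeValidationError):
            VesselSegment(**kw)

    def test_heart_parameter_invariants(self):
        with pytest.raises(TreeValidationError):
            HeartParameters(Emin=2.0, Emax=1.0)
        with pytest.raises(TreeValidationError):
            HeartParameters(tm=1.5, T=1.0)
        with pytest.raises(TreeValidationError):
            HeartParameters(Vlv=1e-5, V0=2e-5)

    def test_blood_and_windkessel_invariants(self):
        with pytest.raises(TreeValidationError):
            BloodProperties(density=-1.0)
        with pytest.raises(TreeValidationError):
            WindkesselTerminal(R1=0.0, R2=1e9, C=1e-9)


class TestUnits:
    def test_single_shared_mmhg_constant(self):
        assert MMHG_TO_PA == pytest.approx(133.322)
        # the same constant is used by every module that converts
        from cuffwave import units

        assert units.mmhg_to_pa(1.0) == MMHG_TO_PA
        assert units.pa_to_mmhg(MMHG_TO_PA) == pytest.approx(1.0)


class TestStiffness:
    def test_radius_relation_spans_size_classes(self):
        ws = WallStiffness()
        # k1 term dominates for small radii, k3 for large (k2 < 0)
        small = ws.eh_over_r0(0.001)
        large = ws.eh_over_r0(0.012)
        assert small > large
        assert large == pytest.approx(ws.k3, rel=1e-6)

    def test_taper_interpolates_linearly(self):
        seg = VesselSegment(id="v", name="v", length=0.2, r_prox=0.005,
                            r_dist=0.003)
        assert seg.radius(0.0) == 0.005
        assert seg.radius(0.2) == 0.003
        assert seg.radius(0.1) == pytest.approx(0.004)
        assert seg.area0(0.1) == pytest.approx(math.pi * 0.004**2)


class TestScaling:
    def test_identity_scaling_is_noop(self):
        tree = make_single_vessel()
        out = apply_scaling(tree, TerminalScaling(1.0, 1.0))
        assert out.terminals["v"] == tree.terminals["v"]

    def test_resistances_scale_exactly(self):
        tree = make_single_vessel()
        out = apply_scaling(tree, TerminalScaling(SR=1.1, SC=1.0))
        assert out.terminals["v"].R1 == pytest.approx(1.1e8, rel=1e-15)
        assert out.terminals["v"].R2 == pytest.approx(1.1e9, rel=1e-15)
        assert out.terminals["v"].C == tree.terminals["v"].C

    def test_scaling_round_trip_recovers_original(self):
        tree = make_single_vessel()
        fwd = apply_scaling(tree, TerminalScaling(SR=0.9, SC=0.9))
        back = apply_scaling(fwd, TerminalScaling(SR=1 / 0.9, SC=1 / 0.9))
        for name in ("R1", "R2", "C"):
            assert getattr(back.terminals["v"], name) == pytest.approx(
                getattr(tree.terminals["v"], name), rel=1e-12)

    def test_non_positive_scaling_rejected(self):
        with pytest.raises(TreeValidationError):
            TerminalScaling(SR=0.0, SC=1.0)


class TestTableIO:
    def test_round_trip_preserves_values(self, baseline, tmp_path):
        path = tmp_path / "tree.csv"
        save_tree(baseline.tree, path, header="round-trip test")
        back = load_tree(path)
        assert back.n_segments == baseline.tree.n_segments
        for sid, seg in baseline.tree.segments.items():
            b = back.segments[sid]
            assert b.length == seg.length
            assert b.r_prox == seg.r_prox
            assert b.r_dist == seg.r_dist
            assert b.parent == seg.parent
            assert set(b.children) == set(seg.children)
            assert b.stiffness == seg.stiffness
        for sid, term in baseline.tree.terminals.items():
            assert back.terminals[sid] == term

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,name,length_m\nv,v,0.1\n")
        with pytest.raises(TreeValidationError, match="missing columns"):
            load_tree(path)

    def test_leaf_count_equals_terminal_count(self, baseline):
        tree = baseline.tree
        assert len(tree.leaves()) == len(tree.terminals) == 32
        # traversal from the root reaches every segment exactly once
        seen = []
        stack = [tree.root_id]
        while stack:
            sid = stack.pop()
            seen.append(sid)
            stack.extend(tree.segments[sid].children)
        assert sorted(seen) == sorted(tree.segments)
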