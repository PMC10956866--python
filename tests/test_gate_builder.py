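"""Gate template construction, capture measurement, fitting and export."""

import numpy as np
import pytest

import facsort as fs
from facsort.errors import (
    GeometryError,
    InsufficientEventsError,
    TransformMismatchError,
    ValidationError,
)
from facsort.gate_builder import resample_ring, rightmost_arc

from .conftest import fit_pipeline, winding_number_contains


def _rect_contour(x0, x1, y0, y1, level=0.25, mass=0.25):
    ring = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)
    return fs.ContourPolygon(level, ring, enclosed_mass=mass)


class TestTemplateConstruction:
    def test_rectangular_contours_give_rectangle(self, axis):
        c80 = _rect_contour(-1, 1, 0.0, 10.0, level=0.8, mass=0.8)
        c25 = _rect_contour(-0.5, 0.5, 4.0, 6.0)
        gate = fs.build_template_gate(c80, c25, axis=axis)
        # left edge at the 25%-contour's right side, width = its fluorescence span
        assert set(np.round(gate.vertices[:, 0], 12)) == {0.5, 1.5}
        assert gate.bsc_extent() == (0.0, 10.0)

    def test_vertex_budget(self, axis):
        c80 = _rect_contour(-1, 1, 0, 10, level=0.8, mass=0.8)
        c25 = _rect_contour(-0.5, 0.5, 4, 6)
        for max_vertices in (3, 8, 60):
            cfg = fs.GateConfig(max_vertices=max_vertices)
            gate = fs.build_template_gate(c80, c25, cfg, axis=axis)
            assert gate.n_vertices <= max_vertices

    def test_vertical_extent_matches_height_contour(self, panel_tables, panel_fits, axis):
        """On a fitted synthetic sample the gate's back-scatter extent equals
        the 80% contour's within one grid cell."""
        table = panel_tables["sample_06"]
        grid = fs.estimate_density(table, axis)
        c80 = fs.main_component(fs.contour_at_mass(grid, 0.80))
        gate = panel_fits["sample_06"].gate
        dy = grid.cell_size[1]
        assert gate.bsc_extent()[0] == pytest.approx(c80.bsc_extent()[0], abs=dy)
        assert gate.bsc_extent()[1] == pytest.approx(c80.bsc_extent()[1], abs=dy)

    def test_disjoint_extents_rejected(self, axis):
        c80 = _rect_contour(-1, 1, 0, 1, level=0.8, mass=0.8)
        c25 = _rect_contour(-0.5, 0.5, 5, 6)
        with pytest.raises(GeometryError):
            fs.build_template_gate(c80, c25, axis=axis)

    def test_rightmost_arc_of_circle(self):
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        ring = np.column_stack([np.cos(theta), np.sin(theta)])
        arc = rightmost_arc(ring, np.array([0.0, 0.5, -0.5]))
        expected = np.sqrt(1 - np.array([0.0, 0.5, -0.5]) ** 2)
        np.testing.assert_allclose(arc[:, 0], expected, atol=1e-3)

    def test_resample_ring_preserves_perimeter(self):
        square = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], dtype=float)
        out = resample_ring(square, 16)
        assert len(out) == 16
        closed = np.vstack([out, out[:1]])
        perimeter = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        assert perimeter == pytest.approx(16.0, rel=1e-6)


class TestCapturedFraction:
    def test_bounding_box_captures_all(self, panel_tables, axis):
        table = panel_tables["sample_01"]
        x, y = table.values[:, 0], table.values[:, 1]
        box = np.array(
            [[x.min(), y.min()], [x.max(), y.min()], [x.max(), y.max()], [x.min(), y.max()]]
        )
        gate = fs.GatePolygon(box, axis, dict(table.transform_tags))
        assert fs.captured_fraction(gate, table, axis) == 1.0

    def test_distant_gate_captures_none(self, panel_tables, axis):
        table = panel_tables["sample_01"]
        box = np.array([[1e6, 1e6], [1e6 + 1, 1e6], [1e6 + 1, 1e6 + 1], [1e6, 1e6 + 1]])
        gate = fs.GatePolygon(box, axis, dict(table.transform_tags))
        assert fs.captured_fraction(gate, table, axis) == 0.0

    def test_matches_winding_number_oracle(self, axis):
        """500 random events against a random simple 12-gon: identical count
        to the brute-force winding-number implementation."""
        rng = np.random.default_rng(21)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 12))
        radii = rng.uniform(0.5, 2.0, 12)
        ring = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        pts = rng.uniform(-2.5, 2.5, size=(500, 2))
        table = fs.EventTable(
            "rnd", [axis.fluorescence_channel, axis.backscatter_channel], pts
        )
        gate = fs.GatePolygon(ring, axis)
        got = round(fs.captured_fraction(gate, table, axis) * 500)
        expected = sum(winding_number_contains(ring, px, py) for px, py in pts)
        assert got == expected

    def test_transform_mismatch_rejected(self, axis):
        ring = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        gate = fs.GatePolygon(
            ring, axis, {axis.fluorescence_channel: "asinh", axis.backscatter_channel: "linear"}
        )
        table = fs.EventTable(
            "lin", [axis.fluorescence_channel, axis.backscatter_channel],
            np.array([[0.5, 0.5]]),
            transform_tags={axis.fluorescence_channel: "linear",
                            axis.backscatter_channel: "linear"},
        )
        with pytest.raises(TransformMismatchError):
            fs.captured_fraction(gate, table, axis)


class TestFitGate:
    def test_default_target_on_panel_sample(self, panel_fits):
        fit = panel_fits["sample_03"]
        assert fit.converged
        assert fit.achieved_fraction == pytest.approx(0.01, abs=0.001)

    def test_panel_convergence_all_samples(self, panel_fits):
        for name, fit in panel_fits.items():
            assert fit.converged, name
            assert abs(fit.achieved_fraction - 0.01) <= 0.001, name

    def test_near_total_target_converges(self, panel_tables, axis):
        table = panel_tables["sample_02"]
        x, y = table.values[:, 0], table.values[:, 1]
        pad = 1.0
        box = np.array(
            [
                [x.min() - pad, y.min() - pad],
                [x.max() + pad, y.min() - pad],
                [x.max() + pad, y.max() + pad],
                [x.min() - pad, y.max() + pad],
            ]
        )
        template = fs.GatePolygon(box, axis, dict(table.transform_tags))
        cfg = fs.GateConfig(target_fraction=0.995, fraction_tolerance=0.004)
        fit = fs.fit_gate(template, table, axis, cfg)
        assert fit.converged

    def test_exponential_tail_five_percent_quantile(self, axis):
        """A tall rectangle fitted at 5% on an exponential bright tail puts its
        left edge inside the 94.5-95.5th empirical percentile band."""
        rng = np.random.default_rng(31)
        n = 60_000
        values = np.column_stack([rng.exponential(1.0, n), rng.uniform(0, 4, n)])
        table = fs.EventTable(
            "expo", [axis.fluorescence_channel, axis.backscatter_channel], values
        )
        box = np.array([[0.0, -1.0], [30.0, -1.0], [30.0, 5.0], [0.0, 5.0]])
        template = fs.GatePolygon(box, axis, dict(table.transform_tags))
        cfg = fs.GateConfig(target_fraction=0.05, max_rotation=0.0)
        fit = fs.fit_gate(template, table, axis, cfg)
        assert fit.converged
        left_edge = fit.gate.vertices[:, 0].min()
        lo, hi = np.percentile(values[:, 0], [94.5, 95.5])
        assert lo <= left_edge <= hi

    def test_capture_monotone_under_rightward_translation(self, panel_fits, panel_tables, axis):
        """Past the fitted position, shifting the gate brighter only loses events."""
        fit = panel_fits["sample_08"]
        table = panel_tables["sample_08"]
        fracs = [
            fs.captured_fraction(fit.gate.transformed(dx=dx), table, axis)
            for dx in np.linspace(0.0, 2.0, 9)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_unreachable_target_flagged_not_raised(self, axis):
        rng = np.random.default_rng(17)
        values = rng.normal(0, 1, size=(5_000, 2))
        table = fs.EventTable(
            "n", [axis.fluorescence_channel, axis.backscatter_channel], values
        )
        # Tiny sliver far below the data's back-scatter range: no placement works.
        sliver = np.array([[0, -50.0], [0.1, -50.0], [0.1, -49.9], [0, -49.9]])
        template = fs.GatePolygon(sliver, axis, dict(table.transform_tags))
        fit = fs.fit_gate(template, table, axis, fs.GateConfig(max_rotation=5.0))
        assert not fit.converged
        assert fit.achieved_fraction < 0.01

    def test_deterministic(self, panel_tables, axis):
        a = fit_pipeline(panel_tables["sample_05"], axis)
        b = fit_pipeline(panel_tables["sample_05"], axis)
        np.testing.assert_array_equal(a.gate.vertices, b.gate.vertices)
        assert (a.achieved_fraction, a.translation, a.rotation, a.converged) == (
            b.achieved_fraction, b.translation, b.rotation, b.converged,
        )

    def test_too_few_events_rejected(self, panel_fits, axis):
        gate = panel_fits["sample_01"].gate
        table = fs.EventTable(
            "tiny", [axis.fluorescence_channel, axis.backscatter_channel],
            np.zeros((10, 2)),
        )
        with pytest.raises(InsufficientEventsError):
            fs.fit_gate(gate, table, axis)


class TestGateExport:
    def test_triangle_roundtrip(self, tmp_path, axis):
        tri = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 3.0]])
        gate = fs.GatePolygon(tri, axis, {axis.fluorescence_channel: "asinh",
                                          axis.backscatter_channel: "linear"}, "tri")
        path = tmp_path / "tri.gate"
        fs.export_gate(gate, path)
        lines = path.read_text().strip().splitlines()
        assert sum("," in ln and "=" not in ln for ln in lines) == 3
        back = fs.read_gate(path)
        np.testing.assert_array_equal(back.vertices, gate.vertices)
        assert back.sample_id == "tri"
        assert back.transform_tags == gate.transform_tags

    def test_sixty_vertex_gate(self, tmp_path, panel_fits):
        gate = panel_fits["sample_04"].gate
        assert gate.n_vertices == 60
        path = tmp_path / "g.gate"
        fs.export_gate(gate, path)
        lines = path.read_text().strip().splitlines()
        assert sum("," in ln and "=" not in ln for ln in lines) == 60

    def test_reimport_preserves_capture_exactly(self, tmp_path, panel_fits, panel_tables, axis):
        gate = panel_fits["sample_07"].gate
        table = panel_tables["sample_07"]
        path = tmp_path / "g.gate"
        fs.export_gate(gate, path)
        back = fs.read_gate(path)
        assert fs.captured_fraction(back, table, axis) == fs.captured_fraction(
            gate, table, axis
        )


class TestGateConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(target_fraction=0.0), dict(target_fraction=1.0), dict(max_vertices=2),
         dict(fraction_tolerance=0.0), dict(height_contour_mass=1.2)],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValidationError):
            fs.GateConfig(**kwargs)
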