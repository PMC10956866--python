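import numpy as np
import pytest

import facsort as fs

PANEL_SEED = 7
PANEL_N = 50_000


@pytest.fixture(scope="session")
def axis():
    return fs.DEFAULT_AXIS


@pytest.fixture(scope="session")
def panel_specs():
    return fs.make_panel(12, seed=PANEL_SEED, n_events=PANEL_N)


@pytest.fixture(scope="session")
def panel_tables(panel_specs):
    return {spec.sample_id: fs.simulate_sample(spec) for spec in panel_specs}


@pytest.fixture(scope="session")
def panel_fits(panel_specs, panel_tables, axis):
    """Default-config gate fit on the full event table of every panel sample."""
    fits = {}
    for spec in panel_specs:
        table = panel_tables[spec.sample_id]
        fits[spec.sample_id] = fit_pipeline(table, axis)
    return fits


def fit_pipeline(table, axis, config=fs.GateConfig()):
    """Density -> contours -> template -> fit, on the table as given."""
    grid = fs.estimate_density(table, axis)
    c_height = fs.main_component(fs.contour_at_mass(grid, config.height_contour_mass))
    c_side = fs.main_component(fs.contour_at_mass(grid, config.side_contour_mass))
    template = fs.build_template_gate(
        c_height,
        c_side,
        config,
        axis=axis,
        transform_tags=dict(table.transform_tags),
        sample_id=table.sample_id,
    )
    return fs.fit_gate(template, table, axis, config)


@pytest.fixture(scope="session")
def gaussian_table(axis):
    """50,000 isotropic bivariate normal events, sigma=1."""
    rng = np.random.default_rng(42)
    values = rng.normal(loc=[0.0, 5.0], scale=1.0, size=(50_000, 2))
    return fs.EventTable(
        sample_id="gaussian",
        channels=[axis.fluorescence_channel, axis.backscatter_channel],
        values=values,
        transform_tags={axis.fluorescence_channel: "asinh", axis.backscatter_channel: "linear"},
    )


def winding_number_contains(ring: np.ndarray, px: float, py: float) -> bool:
    """Brute-force winding-number point-in-polygon (independent test oracle)."""
    wn = 0
    n = len(ring)
    for i in range(n):
        x0, y0 = ring[i]
        x1, y1 = ring[(i + 1) % n]
        if y0 <= py:
            if y1 > py and _is_left(x0, y0, x1, y1, px, py) > 0:
                wn += 1
        elif y1 <= py and _is_left(x0, y0, x1, y1, px, py) < 0:
            wn -= 1
    return wn != 0


def _is_left(x0, y0, x1, y1, px, py) -> float:
    return (x1 - x0) * (py - y0) - (px - x0) * (y1 - y0)
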