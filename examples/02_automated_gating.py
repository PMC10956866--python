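"""Fit a sorting gate on one sample, exactly as the batch runner does.

The gate's height comes from the contour enclosing 80% of event mass, its
side shape from the 25% contour, and the template is then translated along
the fluorescence axis until it captures the brightest 1% of events.
"""

from pathlib import Path

import facsort as fs

axis = fs.DEFAULT_AXIS
config = fs.GateConfig()  # target 1%, contours 80%/25%, <=60 vertices

spec = fs.make_panel(12, seed=7, n_events=50_000)[5]
table = fs.simulate_sample(spec)

grid = fs.estimate_density(table, axis)
c80 = fs.main_component(fs.contour_at_mass(grid, config.height_contour_mass))
c25 = fs.main_component(fs.contour_at_mass(grid, config.side_contour_mass))
print(f"80% contour: encloses {c80.enclosed_mass:.3f} of mass, "
      f"back-scatter extent {c80.bsc_extent()[0]:.2f}..{c80.bsc_extent()[1]:.2f}")
print(f"25% contour: encloses {c25.enclosed_mass:.3f} of mass, "
      f"fluorescence span {c25.fluo_extent()[1] - c25.fluo_extent()[0]:.2f}")

template = fs.build_template_gate(
    c80, c25, config, axis=axis,
    transform_tags=dict(table.transform_tags), sample_id=table.sample_id,
)
fit = fs.fit_gate(template, table, axis, config)
print(f"\nfitted gate: {fit.gate.n_vertices} vertices, "
      f"translation +{fit.translation:.3f} along fluorescence, "
      f"rotation {fit.rotation:.1f} deg")
print(f"captured fraction: {fit.achieved_fraction * 100:.2f}% "
      f"(target {config.target_fraction * 100:.0f}%, converged={fit.converged})")

out = Path("scratch") / f"{table.sample_id}.gate"
out.parent.mkdir(exist_ok=True)
fs.export_gate(fit.gate, out)
print(f"\ngate vertices written to {out} (plain text, one x,y per line);")
print("the captured fraction is the share of profiled events inside the polygon.")
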