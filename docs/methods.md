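# Methods

## Scope and model overview

`facsort` models the software side of an automated cell-sorting run at desk
scale. Physical subsystems (robotics, GUI control, droplet physics) are out
of scope; what is modelled is everything between "a sample's events are
available" and "a batch report is written": density-based gate construction,
gate fitting to a target capture fraction, a simulated instrument session
with event-rate pressure control, and worklist orchestration.

## Event data and transforms

An `EventTable` stores one sample's per-event channel measurements together
with a per-channel `transform_tag` ∈ {linear, log10, asinh} recording the
scale of the stored values. Gating happens in transformed space: the default
convention is arcsinh(x/150) on the fluorescence axis and linear
back-scatter. The cofactor 150 keeps dim signal near-linear while
compressing bright signal roughly like a decade log; it is a config item,
and every exported gate records the transform tags of its axes so a gate
cannot silently be applied to data on a different scale. Whether the
original instrument exports raw or compressed values is instrument-specific,
which is why the transform is configuration rather than a fixed pipeline
stage.

Events with any non-finite value are dropped at read time with a logged
count: saturated instrument entries occur in practice and all downstream
geometry requires finite coordinates. The CSV dialect (comma, `.` decimal,
UTF-8, mandatory header) stores values only; transform tags are not
persisted in CSV and default to linear on read — callers that round-trip
transformed data through CSV must restore tags themselves. FCS files carry
the log-amplification flag ($PnE), which maps to the log10 tag. The FCS
codec is deliberately minimal (single dataset, list-mode float data, no
keyword preservation beyond channels) — enough to interoperate with
instrument exports of that shape and to write test fixtures.

## Synthetic samples

The generator emulates the profiling data of CRISPR knock-in pools: each
sample is a two-component (or k-component) Gaussian mixture on the
*transformed* (fluorescence, back-scatter) plane, i.e. approximately
log-normal in raw units — the minimal model reproducing the unimodal blobs
with bright tails seen on real cytometry contour plots. Defaults:

| parameter | default | rationale |
|---|---|---|
| unedited fluorescence | mean 0.0, sd 0.35 (asinh units) | autofluorescence near zero signal |
| edited fluorescence mean | 1.5 → 6.0 across a panel | dim-to-bright expression range |
| edited fluorescence sd | 0.45 | expression noise slightly above autofluorescence spread |
| back-scatter (both) | mean 2.5, sd 0.5, shared | tagging does not change cell size |
| edited fraction | 2% → 60% across a panel | editing-efficiency range across genes |
| events per sample | 50,000 | a typical profiling acquisition |
| concentration | 2×10⁶ cells/mL | small-scale input cultures |

Events are stored in a random order so nothing downstream can exploit
population blocks, and all randomness is `numpy` `default_rng` seeded per
sample — identical spec+seed gives bit-identical tables.
`component_labels` replays the generator stream to recover ground-truth
component assignments for testing.

What the generator does **not** model: doublets and debris, spectral
spillover/compensation, acquisition-time drift, and non-Gaussian
back-scatter shapes. Tests passing on this generator therefore demonstrate
the algorithm's correctness on clean unimodal-per-population mixtures; real
samples with heavy debris or drifting signal may need pre-gating or
transform adjustments that are out of scope here.

## Density estimation and HDR contours

Density is a 2D histogram on a 256×256 grid spanning each axis's [min, max]
padded by 5% of the span, smoothed with an isotropic Gaussian filter
(σ = 2 grid cells) and normalised to unit mass. The defaults were chosen so
that 10⁴–10⁵ events yield smooth, simple contour rings; both are
configurable. Gating is refused below 100 events (density too unreliable)
and on zero-variance axes.

A "contour at mass α" uses the highest-density-region convention of
cytometry contour plots: the threshold t is the largest density value whose
superlevel set holds mass ≥ α, found by bisection on t (the enclosed mass is
a non-increasing step function of t; iteration stops within 10⁻⁴ of α or on
bracket collapse). Percent-of-peak thresholding is available as an
alternative mode since instrument vendors differ on this convention.
Iso-contours at t are traced by marching squares on the grid padded with a
zero ring, so contours that would run off the data range close along the
boundary. Each ring's enclosed mass is the mass of grid cells whose centers
fall inside it; rings are ranked by enclosed mass, ties by area, and the
"main component" is the top-ranked ring. Annular HDRs (holes) are not
modelled — each ring is treated independently.

## Gate construction and fitting

The template combines the 80% contour (height) and the 25% contour (side
shape). Design choices where the construction was genuinely open:

- the **side curve** is the rightmost boundary arc of the 25% contour, so
  the gate hugs the population's bright edge; it is sampled at
  `max_vertices // 2` evenly spaced heights across the 80% contour's
  back-scatter extent, with heights beyond the 25% contour clamping to its
  extreme (a vertical extension at constant fluorescence);
- the **gate width** equals the 25% contour's fluorescence span;
- the ring (left curve up, shifted right curve down) therefore lands at
  ≤ 60 vertices by construction; an arc-length resampler guards the budget
  for hand-built contours.

Fitting searches translation first, because sample-to-sample gates differ
mainly by horizontal placement: a 65-point coarse scan of the capture
fraction over the full translation range locates the *rightmost* crossing of
the target (the capture curve can recross the target between population
modes; the brightest-side crossing is the "top fraction" placement),
followed by bisection. The capture fraction is a step function of
translation (finite events), so bisection terminates either within the
fraction tolerance (0.001 ≈ 50 events at n = 50,000, finer than sampling
noise at the 1% target) or on bracket collapse, returning the best bracket
endpoint. Only if translation alone misses the tolerance does a
golden-section search on rotation about the gate centroid (±15°) re-run the
translation search per candidate angle. An unreachable target returns the
best gate flagged `converged=False` — never an exception — and the
orchestrator turns that flag into a warning notification.

Boundary events count as inside (shapely's intersects predicate): a
consistent tie-break, since droplet-level hardware decisions at the exact
boundary are not modelled.

## Sort session

The instrument is linearised: sample flow = `flow_per_pressure × pressure`,
expected event rate `eps = concentration × flow`. Defaults
(`flow_per_pressure` 2×10⁻⁴ mL/s per pressure unit, limits 1–10, target
2,000 events/s) put the operating point at mid-range pressure for a 2×10⁶
cells/mL sample. The controller is a clamped multiplicative proportional
law, `p ← p·(eps_target/eps_obs)^gain`, the minimal law whose fixed point is
the target rate; gain 0.5 keeps it stable under Poisson arrival noise
(gain 1 converges in one step on a noiseless plant). An observed rate of
zero drives the pressure to maximum with a logged warning. Arrival counts
per 0.5-s control tick are Poisson draws (the only seeded randomness in the
session); event measurements stream in the table's stored order.

Profiling consumes `n_profile` events; sorting then counts in-gate events
until `n_sort` (default 1,200 — one rescue well's worth) are collected or
the sample is exhausted, in which case the result carries
`completed=False` and the shortfall. Session time is split into five
categories — profiling, sorting, transport, gating, control — with the
three hardware-bound categories taken from configuration constants
(defaults 30/5/25 s), since their real values are rig-specific.

## Orchestration and reporting

The worklist CSV (`name,position,well`) is validated against the physical
contract: positions 1–18 (housing capacity), wells A1–H12 (96-well plate),
no duplicate names or positions. The batch runner advances a per-sample
state machine (pending → profiling → gating → sorting → done/failed), with
terminal states immutable and pause/resume/stop modelled as explicit
transitions. Per-sample failures are isolated: each sample gets its own
profile subsample and derived seed (prefix-stable `SeedSequence` children,
kept below 2³¹), so replacing one sample's data cannot perturb any other
sample's result. Notifications flow through an abstract sink (logging
default, collecting sink for tests); error notifications always name the
sample and phase. An optional control-sample mode gates a named sample first
and reuses its height contour for the rest of the batch; it is off by
default because per-sample heights are the safer default when samples vary.

The report is a multi-page PDF (header table plus one density/contour/gate
panel per sample) with a JSON summary alongside. PDF creation timestamps are
suppressed by default so identical inputs produce byte-identical reports;
the JSON is sorted and indent-stable for the same reason.

## Problem sizes and numerical notes

The package's reference conditions are 12-sample panels of 50,000 events per
sample with 10,000-event profiling subsamples; the full batch (simulation,
gating, sorting, report) runs in seconds. Degenerate inputs are rejected
early with typed errors (insufficient events, zero-variance axis,
non-overlapping contour extents, invalid specs) rather than propagating NaNs
into geometry. Gate export uses 17-significant-digit decimals so re-imported
gates reproduce capture fractions bit for bit.

## Known limitations

- Contour mass is grid-based; for very small α on coarse grids the
  discretisation error of a single cell can exceed the bisection tolerance.
- The 25%-contour side arc assumes the main population's right boundary is
  single-valued in back-scatter after smoothing; exotic multi-lobed
  populations may produce a jagged side curve (still simple and within the
  vertex budget).
- The instrument model's linear pressure→flow mapping and control cadence
  are stand-ins; absolute wall-clock figures of a real rig are out of scope.
- The sort phase streams the same finite event table used for profiling; a
  physical tube holds far more cells than are profiled, so completion
  shortfalls at small table sizes are an artifact of desk scale, not of the
  protocol.
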