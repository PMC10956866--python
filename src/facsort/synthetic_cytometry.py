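"""Synthetic CRISPR-edited cell pools for exercising the gating pipeline.

Each sample emulates the profiling data of a knock-in pool: a non-fluorescent
unedited majority plus a fluorescent edited subpopulation whose abundance and
brightness vary sample to sample (each tagged gene expresses at its own
level). Events are drawn per population from a bivariate Gaussian on the
*transformed* scale — approximately log-normal in raw instrument units, the
minimal model for the unimodal blobs with bright tails seen on real contour
plots. Tagging does not change cell size, so the edited component shares the
unedited back-scatter distribution by default.

Not modelled: doublets, debris, spectral spillover, acquisition-time drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .event_io import AxisMapping, EventTable

FLUO_CHANNEL = "FL1-A"
BSC_CHANNEL = "BSC-A"

DEFAULT_AXIS = AxisMapping(FLUO_CHANNEL, BSC_CHANNEL)

#: Typical starting cell concentration of a small-scale input culture, cells/mL.
DEFAULT_CONCENTRATION = 2.0e6


@dataclass(frozen=True)
class PopulationSpec:
    """One Gaussian mixture component on the transformed (fluo, bsc) plane."""

    weight: float
    fluo_mean: float
    fluo_sd: float
    bsc_mean: float
    bsc_sd: float
    fluo_bsc_corr: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValidationError(f"population weight {self.weight} outside [0, 1]")
        if self.fluo_sd <= 0 or self.bsc_sd <= 0:
            raise ValidationError(
                f"population sds must be positive (fluo_sd={self.fluo_sd}, bsc_sd={self.bsc_sd})"
            )
        if not abs(self.fluo_bsc_corr) < 1.0:
            raise ValidationError(f"|correlation| must be < 1, got {self.fluo_bsc_corr}")

    @property
    def covariance(self) -> np.ndarray:
        off = self.fluo_bsc_corr * self.fluo_sd * self.bsc_sd
        return np.array([[self.fluo_sd**2, off], [off, self.bsc_sd**2]])


@dataclass(frozen=True)
class SampleSpec:
    """Generative description of one synthetic sample."""

    sample_id: str
    populations: tuple[PopulationSpec, ...]
    n_events: int
    concentration: float = DEFAULT_CONCENTRATION
    seed: int = 0

    def validate(self) -> None:
        if not self.populations:
            raise ValidationError("sample needs at least one population")
        for pop in self.populations:
            pop.validate()
        total = sum(p.weight for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"population weights sum to {total}, expected 1")
        if self.n_events < 0:
            raise ValidationError(f"n_events must be >= 0, got {self.n_events}")
        if self.concentration <= 0:
            raise ValidationError(f"concentration must be > 0, got {self.concentration}")


def simulate_sample(spec: SampleSpec) -> EventTable:
    """Draw one sample's events; deterministic given ``spec.seed``.

    Component assignment is multinomial in the population weights; events are
    stored in a random order so nothing downstream can rely on population
    blocks. The fluorescence channel is tagged ``asinh`` and back-scatter
    ``linear``: values are generated directly on the display scale.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    weights = np.array([p.weight for p in spec.populations])
    counts = rng.multinomial(spec.n_events, weights)
    blocks = [
        rng.multivariate_normal([p.fluo_mean, p.bsc_mean], p.covariance, size=k)
        for p, k in zip(spec.populations, counts)
    ]
    values = np.vstack(blocks) if blocks else np.empty((0, 2))
    values = values[rng.permutation(spec.n_events)]
    return EventTable(
        sample_id=spec.sample_id,
        channels=[FLUO_CHANNEL, BSC_CHANNEL],
        values=values,
        transform_tags={FLUO_CHANNEL: "asinh", BSC_CHANNEL: "linear"},
    )


def component_labels(spec: SampleSpec) -> np.ndarray:
    """Ground-truth component index per event, in the stored (shuffled) order.

    Replays the generator's random stream, so ``simulate_sample(spec)`` row i
    was drawn from component ``component_labels(spec)[i]``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    weights = np.array([p.weight for p in spec.populations])
    counts = rng.multinomial(spec.n_events, weights)
    for p, k in zip(spec.populations, counts):
        rng.multivariate_normal([p.fluo_mean, p.bsc_mean], p.covariance, size=k)
    labels = np.repeat(np.arange(len(counts)), counts)
    return labels[rng.permutation(spec.n_events)]


# Panel defaults, transformed units (arcsinh of raw a.u. / 150):
# unedited autofluorescence sits near zero; edited brightness spans dim→bright.
_UNEDITED = dict(fluo_mean=0.0, fluo_sd=0.35)
_BSC = dict(bsc_mean=2.5, bsc_sd=0.5)
_EDITED_FRACTIONS = (0.02, 0.60)
_EDITED_MEANS = (1.5, 6.0)
_EDITED_FLUO_SD = 0.45


def make_panel(
    n_samples: int,
    seed: int = 0,
    n_events: int = 50_000,
) -> list[SampleSpec]:
    """Deterministic panel of two-population samples emulating a gene library.

    Edited fraction spans 2–60% and edited brightness increases strictly
    across the panel, mimicking tagging genes of increasing expression level.
    """
    if n_samples < 1:
        raise ValidationError(f"n_samples must be >= 1, got {n_samples}")
    fractions = np.linspace(*_EDITED_FRACTIONS, n_samples)
    means = np.linspace(*_EDITED_MEANS, n_samples)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_samples) % np.uint32(2**31)
    specs = []
    for i in range(n_samples):
        unedited = PopulationSpec(weight=1.0 - fractions[i], **_UNEDITED, **_BSC)
        edited = PopulationSpec(
            weight=float(fractions[i]),
            fluo_mean=float(means[i]),
            fluo_sd=_EDITED_FLUO_SD,
            **_BSC,
        )
        specs.append(
            SampleSpec(
                sample_id=f"sample_{i + 1:02d}",
                populations=(unedited, edited),
                n_events=n_events,
                seed=int(child_seeds[i]),
            )
        )
    return specs
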