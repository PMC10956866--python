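"""Event-table container and I/O for cytometry event data.

An :class:`EventTable` holds per-event measurements for one sample: a value
matrix with one column per instrument channel, plus a per-channel scale tag
recording whether the stored values are raw (``linear``) or compressed
(``log10`` = log10(x+1), ``asinh`` = arcsinh(x/cofactor)). All gating
downstream happens on the two axes named by an :class:`AxisMapping` —
fluorescence horizontal, back-scatter vertical.

Files are read from FCS 3.0/3.1 or a fixed CSV dialect (comma separator,
``.`` decimal, UTF-8, mandatory header of channel names, one row per event).
Events containing any non-finite value are dropped at read time with a
logged count: instrument exports can contain saturated entries and the
gating geometry requires finite coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _fcs
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

TRANSFORMS = ("linear", "log10", "asinh")

#: Default arcsinh cofactor: raw intensities below ~150 a.u. stay near-linear,
#: brighter signal is compressed roughly like a decade log scale.
DEFAULT_COFACTOR = 150.0


@dataclass(frozen=True)
class AxisMapping:
    """Names of the two gating axes (x = fluorescence, y = back-scatter)."""

    fluorescence_channel: str
    backscatter_channel: str

    def indices(self, table: "EventTable") -> tuple[int, int]:
        for name in (self.fluorescence_channel, self.backscatter_channel):
            if name not in table.channels:
                raise ValidationError(
                    f"axis channel {name!r} not present in table "
                    f"(channels: {table.channels})"
                )
        return (
            table.channels.index(self.fluorescence_channel),
            table.channels.index(self.backscatter_channel),
        )


@dataclass
class EventTable:
    """Per-event measurements for one sample.

    ``values`` is an ``(n_events, n_channels)`` float array; ``transform_tags``
    maps every channel name to one of :data:`TRANSFORMS`.
    """

    sample_id: str
    channels: list[str]
    values: np.ndarray
    transform_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(self.channels))
        if self.values.shape[1] != len(self.channels):
            raise ValidationError(
                f"value matrix has {self.values.shape[1]} columns for "
                f"{len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError(f"duplicate channel names: {self.channels}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("event values must be finite (drop at read time)")
        for ch in self.channels:
            tag = self.transform_tags.setdefault(ch, "linear")
            if tag not in TRANSFORMS:
                raise ValidationError(f"unknown transform tag {tag!r} for channel {ch!r}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, channel: str) -> np.ndarray:
        return self.values[:, self.channels.index(channel)]

    def take(self, indices: np.ndarray) -> "EventTable":
        """Row subset as a new table (used for profiling subsamples)."""
        return replace(self, values=self.values[indices])


def _drop_nonfinite(values: np.ndarray, origin: str) -> np.ndarray:
    keep = np.all(np.isfinite(values), axis=1)
    n_bad = int(values.shape[0] - keep.sum())
    if n_bad:
        logger.warning("%s: dropped %d event(s) with non-finite values", origin, n_bad)
        values = values[keep]
    return values


def read_fcs(path: str | Path) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    Channels are tagged ``linear`` unless the file declares log amplification
    ($PnE with a positive decade count), in which case the tag is ``log10``.
    """
    path = Path(path)
    channels, values, tags = _fcs.read(path)
    values = _drop_nonfinite(values, str(path))
    return EventTable(
        sample_id=path.stem,
        channels=channels,
        values=values,
        transform_tags=dict(zip(channels, tags)),
    )


def write_fcs(table: EventTable, path: str | Path) -> None:
    """Write a minimal FCS 3.1 file (float32 list-mode data)."""
    _fcs.write(path, table.channels, table.values)


def read_csv(path: str | Path) -> EventTable:
    """Read the documented CSV dialect: header of channel names, one event/row."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, header=0, sep=",", encoding="utf-8", float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (header row required)") from None
    channels = [str(c) for c in frame.columns]
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {frame.iat[row, col]!r} at data row "
            f"{row + 1}, column {channels[col]!r}"
        )
    values = _drop_nonfinite(numeric.to_numpy(dtype=np.float64), str(path))
    return EventTable(sample_id=path.stem, channels=channels, values=values)


def write_csv(table: EventTable, path: str | Path) -> None:
    """Write the CSV dialect with full float64 round-trip precision."""
    frame = pd.DataFrame(table.values, columns=table.channels)
    frame.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def asinh_transform(x: np.ndarray, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    return np.arcsinh(np.asarray(x, dtype=np.float64) / cofactor)


def log10_transform(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValidationError(
            "log10(x+1) undefined for negative values; use the asinh scheme or "
            "offset the data first"
        )
    return np.log10(x + 1.0)


def apply_transform(
    table: EventTable,
    axis: AxisMapping,
    scheme: str,
    cofactor: float = DEFAULT_COFACTOR,
) -> EventTable:
    """Return a new table with the gating-axis channels rescaled.

    ``scheme`` is one of ``linear`` (identity), ``log10`` (log10(x+1)) or
    ``asinh`` (arcsinh(x/cofactor)). Non-axis channels are untouched. Applying
    to an axis that already carries a non-linear tag is refused rather than
    silently double-compressed.
    """
    if scheme not in TRANSFORMS:
        raise ValidationError(f"unknown transform scheme {scheme!r}; choose from {TRANSFORMS}")
    if not (math.isfinite(cofactor) and cofactor > 0):
        raise ValidationError(f"asinh cofactor must be positive and finite, got {cofactor}")
    ix, iy = axis.indices(table)
    if scheme == "linear":
        return replace(table, values=table.values.copy(), transform_tags=dict(table.transform_tags))
    values = table.values.copy()
    tags = dict(table.transform_tags)
    for idx, ch in ((ix, axis.fluorescence_channel), (iy, axis.backscatter_channel)):
        if tags[ch] != "linear":
            raise ValidationError(
                f"channel {ch!r} already carries transform {tags[ch]!r}; refusing to stack"
            )
        if scheme == "log10":
            values[:, idx] = log10_transform(values[:, idx])
        else:
            values[:, idx] = asinh_transform(values[:, idx], cofactor)
        tags[ch] = scheme
    return replace(table, values=values, transform_tags=tags)
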