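"""Core in-memory containers shared by the simulation and analysis modules.

Conventions used throughout the package:

* time axis: samples at a fixed ``sampling_rate`` (Hz), sample ``i`` at
  ``i / sampling_rate`` seconds from recording start;
* channel axis: ordered by ``channel_ids``;
* wavelength axis (raw intensity / optical density): ordered like the
  extinction table, ``(695, 830)`` nm by default;
* chromophore axis (hemoglobin series): ``(oxy, deoxy)``;
* optical density is the natural-log convention,
  ``dOD(t) = -ln(I(t) / mean_t I)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONDITIONS = ("HL", "LH")
HB_TYPES = ("oxy", "deoxy")

#: ROI channels over the superior temporal regions: 6, 7, 9 right hemisphere;
#: 18, 19, 21 left hemisphere.
ROI_CHANNELS_RIGHT = (6, 7, 9)
ROI_CHANNELS_LEFT = (18, 19, 21)
ROI_CHANNELS = ROI_CHANNELS_RIGHT + ROI_CHANNELS_LEFT


class ConfigurationError(ValueError):
    """Invalid parameter set or inconsistent configuration."""


@dataclass(frozen=True)
class BlockEvent:
    condition: str
    onset: float
    duration: float


@dataclass(frozen=True)
class BlockDesign:
    """Ordered stimulation schedule of a block-design session.

    ``events`` hold alternating-condition stimulus blocks; gaps between
    consecutive blocks (and before the first) are the silent baselines.
    ``total_duration`` is the end of the last block.
    """

    events: tuple[BlockEvent, ...]
    total_duration: float

    def __post_init__(self) -> None:
        prev_end = None
        prev_cond = None
        for ev in self.events:
            if ev.condition not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {ev.condition!r}")
            if prev_end is not None and ev.onset < prev_end:
                raise ConfigurationError("block events overlap or are unordered")
            if prev_cond is not None and ev.condition == prev_cond:
                raise ConfigurationError("conditions must strictly alternate")
            prev_end = ev.onset + ev.duration
            prev_cond = ev.condition
        if self.events and self.total_duration < prev_end - 1e-9:
            raise ConfigurationError("total_duration shorter than last block")

    @property
    def n_blocks(self) -> int:
        return len(self.events)

    def onsets(self, condition: str | None = None) -> np.ndarray:
        return np.array(
            [ev.onset for ev in self.events if condition in (None, ev.condition)]
        )

    def conditions(self) -> list[str]:
        return [ev.condition for ev in self.events]

    def to_records(self) -> list[dict]:
        return [
            {"condition": ev.condition, "onset": ev.onset, "duration": ev.duration}
            for ev in self.events
        ]

    @classmethod
    def from_records(cls, records: list[dict], total_duration: float) -> "BlockDesign":
        events = tuple(
            BlockEvent(r["condition"], float(r["onset"]), float(r["duration"]))
            for r in records
        )
        return cls(events=events, total_duration=float(total_duration))


@dataclass(frozen=True)
class Channel:
    id: int
    hemisphere: str  # "left" | "right"
    is_roi: bool


@dataclass(frozen=True)
class ProbeLayout:
    """Lateral probe geometry: channel identities and emitter-detector distance."""

    channels: tuple[Channel, ...]
    source_detector_distance: float = 3.0  # cm

    def __post_init__(self) -> None:
        if self.source_detector_distance <= 0:
            raise ConfigurationError("source_detector_distance must be > 0")
        roi_right = {c.id for c in self.channels if c.is_roi and c.hemisphere == "right"}
        roi_left = {c.id for c in self.channels if c.is_roi and c.hemisphere == "left"}
        if roi_right != set(ROI_CHANNELS_RIGHT) or roi_left != set(ROI_CHANNELS_LEFT):
            raise ConfigurationError(
                "ROI channels must be exactly 6, 7, 9 (right) and 18, 19, 21 (left)"
            )

    @property
    def channel_ids(self) -> np.ndarray:
        return np.array([c.id for c in self.channels], dtype=int)

    @property
    def roi_ids(self) -> np.ndarray:
        return np.array([c.id for c in self.channels if c.is_roi], dtype=int)

    def hemisphere_of(self, channel_id: int) -> str:
        for c in self.channels:
            if c.id == channel_id:
                return c.hemisphere
        raise KeyError(channel_id)

    def index_of(self, channel_id: int) -> int:
        ids = self.channel_ids
        (idx,) = np.nonzero(ids == channel_id)
        if idx.size != 1:
            raise KeyError(channel_id)
        return int(idx[0])

    @classmethod
    def standard(cls, roi_only: bool = False) -> "ProbeLayout":
        """The 24-channel lateral layout (ids 1-12 right, 13-24 left).

        With ``roi_only`` the layout is reduced to the six ROI channels —
        a fast mode for tests and demos.
        """
        channels = []
        for cid in range(1, 25):
            hemi = "right" if cid <= 12 else "left"
            is_roi = cid in ROI_CHANNELS
            if roi_only and not is_roi:
                continue
            channels.append(Channel(cid, hemi, is_roi))
        return cls(channels=tuple(channels))

    def to_records(self) -> list[dict]:
        return [
            {"id": c.id, "hemisphere": c.hemisphere, "is_roi": c.is_roi}
            for c in self.channels
        ]

    @classmethod
    def from_records(cls, records: list[dict], distance: float) -> "ProbeLayout":
        return cls(
            channels=tuple(
                Channel(int(r["id"]), r["hemisphere"], bool(r["is_roi"]))
                for r in records
            ),
            source_detector_distance=float(distance),
        )


@dataclass
class RawIntensityScan:
    """Raw dual-wavelength light intensities for one participant.

    ``data`` has shape ``(n_times, n_channels, 2)`` (wavelength axis ordered
    like ``wavelengths``); intensities are strictly positive on usable
    channels.
    """

    participant: str
    data: np.ndarray
    sampling_rate: float
    wavelengths: tuple[float, float]
    layout: ProbeLayout
    design: BlockDesign
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise ConfigurationError("intensity data must be (time, channel, 2)")
        if self.data.shape[1] != len(self.layout.channels):
            raise ConfigurationError("channel axis does not match layout")

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sampling_rate


@dataclass
class ODSeries:
    """Optical-density change series, shape ``(n_times, n_channels, 2)``."""

    data: np.ndarray
    sampling_rate: float
    wavelengths: tuple[float, float]
    layout: ProbeLayout

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise ConfigurationError("OD data must be (time, channel, 2)")

    def copy(self) -> "ODSeries":
        return ODSeries(
            self.data.copy(), self.sampling_rate, self.wavelengths, self.layout
        )

    @property
    def n_times(self) -> int:
        return self.data.shape[0]


@dataclass
class HbSeries:
    """Hemoglobin concentration-change series.

    ``data`` has shape ``(n_times, n_channels, 2)`` with the last axis
    ``(oxy, deoxy)``, in uM-equivalent units under the ppf = 1 convention.
    ``available`` marks channels that survived pruning; data on unavailable
    channels is NaN, never silently zero.
    """

    data: np.ndarray
    sampling_rate: float
    layout: ProbeLayout
    available: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise ConfigurationError("Hb data must be (time, channel, 2)")
        if self.available is None:
            self.available = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.available = np.asarray(self.available, dtype=bool)

    @property
    def n_times(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sampling_rate

    def copy(self) -> "HbSeries":
        return HbSeries(
            self.data.copy(), self.sampling_rate, self.layout, self.available.copy()
        )


@dataclass
class GroundTruth:
    """Per-participant simulation ground truth.

    ``motion_mask`` flags every sample contaminated by an injected artifact
    (time x channel); ``amplitudes`` maps condition -> per-channel peak
    concentration change (uM); ``hb_true`` is the noiseless hemoglobin
    series before artifacts.
    """

    motion_mask: np.ndarray
    amplitudes: dict[str, np.ndarray]
    hb_true: HbSeries

    def __post_init__(self) -> None:
        nt, nc = self.hb_true.data.shape[:2]
        if self.motion_mask.shape != (nt, nc):
            raise ConfigurationError("motion mask shape mismatch")
        for cond, amp in self.amplitudes.items():
            if np.asarray(amp).shape != (nc,):
                raise ConfigurationError(f"amplitude shape mismatch for {cond}")
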