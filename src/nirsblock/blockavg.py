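"""Block averaging: epoching, baseline correction, participant summaries
and the cohort-level exclusion rules.

Epoch grid convention: the window runs from -3 s to 30 s around each block
onset with *inclusive* endpoints (331 samples at 10 Hz).  The pre-onset
interval [-3, 0) is used only for baseline subtraction; the participant
summary statistic is the mean of the baseline-corrected block average over
[0, 30] s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nirsblock.core import (
    CONDITIONS,
    HB_TYPES,
    ROI_CHANNELS,
    BlockDesign,
    ConfigurationError,
    HbSeries,
    ProbeLayout,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EpochWindow",
    "EpochSet",
    "ParticipantSummary",
    "ExclusionParams",
    "epoch",
    "participant_summary",
    "apply_exclusions",
]


@dataclass(frozen=True)
class EpochWindow:
    """Epoch window relative to block onset (seconds)."""

    start: float = -3.0
    end: float = 30.0
    baseline_start: float = -3.0  # baseline interval [baseline_start, 0)
    stat_end: float = 30.0  # statistic interval [0, stat_end]

    def __post_init__(self) -> None:
        if not (self.start < 0 <= self.end):
            raise ConfigurationError("need start < 0 <= end")
        if not (self.start <= self.baseline_start < 0):
            raise ConfigurationError("baseline interval must lie in [start, 0)")
        if not (0 < self.stat_end <= self.end):
            raise ConfigurationError("stat interval must lie in (0, end]")


@dataclass
class EpochSet:
    """Baseline-corrected per-block windows for one participant.

    ``data`` has shape (block, rel_time, channel, 2); invalid blocks carry
    data but are excluded from every average via ``valid``.
    """

    data: np.ndarray
    valid: np.ndarray  # (block, channel) bool
    conditions: list[str]
    rel_times: np.ndarray
    sampling_rate: float
    layout: ProbeLayout

    @property
    def n_blocks(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ExclusionParams:
    """Participant-level data-quality rules.

    An ROI channel is *available* for a participant iff both conditions
    have at least ``min_valid_blocks_per_condition`` valid blocks on it; a
    participant is retained iff at least ``min_available_rois`` of the six
    ROI channels are available.
    """

    min_valid_blocks_per_condition: int = 3
    min_available_rois: int = 5

    def __post_init__(self) -> None:
        if self.min_valid_blocks_per_condition < 1 or self.min_available_rois < 1:
            raise ConfigurationError("exclusion thresholds must be >= 1")


@dataclass
class ParticipantSummary:
    """Windowed-mean summary per channel x condition x chromophore."""

    participant: str
    age_group: str
    layout: ProbeLayout
    mean_change: np.ndarray  # (channel, condition, hb) NaN where unavailable
    n_valid_blocks: np.ndarray  # (channel, condition) int
    channel_available: np.ndarray  # (channel,) bool
    n_available_rois: int
    included: bool


def epoch(
    hb: HbSeries,
    design: BlockDesign,
    window: EpochWindow = EpochWindow(),
    validity: np.ndarray | None = None,
) -> EpochSet:
    """Cut baseline-corrected epochs around every block onset.

    Each epoch is corrected by subtracting the mean over the pre-onset
    baseline interval, per channel and chromophore.  Blocks whose window
    extends past either end of the recording are marked invalid with a
    warning.  ``validity`` (block x channel, e.g. from residual-artifact
    flagging) is intersected with the edge check.
    """
    fs = hb.sampling_rate
    n_t, n_ch, _ = hb.data.shape
    rel_idx = np.arange(int(round(window.start * fs)), int(round(window.end * fs)) + 1)
    rel_times = rel_idx / fs
    base_sel = (rel_idx >= int(round(window.baseline_start * fs))) & (rel_idx < 0)
    n_blocks = design.n_blocks
    data = np.full((n_blocks, len(rel_idx), n_ch, 2), np.nan)
    valid = np.ones((n_blocks, n_ch), dtype=bool)
    for bi, ev in enumerate(design.events):
        onset_idx = int(round(ev.onset * fs))
        idx = onset_idx + rel_idx
        if idx[0] < 0 or idx[-1] >= n_t:
            logger.warning(
                "block %d at onset %.1f s too close to recording edge; invalid",
                bi,
                ev.onset,
            )
            valid[bi] = False
            continue
        ep = hb.data[idx]
        baseline = np.nanmean(ep[base_sel], axis=0)
        data[bi] = ep - baseline
    valid &= hb.available[None, :]
    if validity is not None:
        valid &= validity
    return EpochSet(
        data=data,
        valid=valid,
        conditions=design.conditions(),
        rel_times=rel_times,
        sampling_rate=fs,
        layout=hb.layout,
    )


def participant_summary(
    epochs: EpochSet,
    window: EpochWindow = EpochWindow(),
    excl: ExclusionParams = ExclusionParams(),
    participant: str = "sub-001",
    age_group: str = "group",
) -> ParticipantSummary:
    """Average valid epochs per condition and take the windowed mean.

    For each channel x condition x chromophore: valid epochs are averaged,
    then the mean over the statistic interval [0, stat_end] is taken.  A
    summary cell is present only where the condition has at least
    ``excl.min_valid_blocks_per_condition`` valid blocks on that channel;
    otherwise it is NaN (unavailable, never zero-filled).
    """
    n_ch = epochs.data.shape[2]
    stat_sel = (epochs.rel_times >= 0) & (
        epochs.rel_times <= window.stat_end + 1e-9
    )
    mean_change = np.full((n_ch, len(CONDITIONS), 2), np.nan)
    n_valid = np.zeros((n_ch, len(CONDITIONS)), dtype=int)
    cond_arr = np.array(epochs.conditions)
    for ci_cond, cond in enumerate(CONDITIONS):
        blocks = np.nonzero(cond_arr == cond)[0]
        for ch in range(n_ch):
            ok = blocks[epochs.valid[blocks, ch]]
            n_valid[ch, ci_cond] = len(ok)
            if len(ok) >= excl.min_valid_blocks_per_condition:
                avg = epochs.data[ok][:, :, ch, :].mean(axis=0)  # (time, hb)
                mean_change[ch, ci_cond, :] = avg[stat_sel].mean(axis=0)
    channel_available = np.all(
        n_valid >= excl.min_valid_blocks_per_condition, axis=1
    )
    roi_sel = np.isin(epochs.layout.channel_ids, ROI_CHANNELS)
    n_rois = int(channel_available[roi_sel].sum())
    return ParticipantSummary(
        participant=participant,
        age_group=age_group,
        layout=epochs.layout,
        mean_change=mean_change,
        n_valid_blocks=n_valid,
        channel_available=channel_available,
        n_available_rois=n_rois,
        included=n_rois >= excl.min_available_rois,
    )


def apply_exclusions(
    summaries: list[ParticipantSummary],
    excl: ExclusionParams = ExclusionParams(),
) -> tuple[pd.DataFrame, list[dict]]:
    """Assemble the tidy cohort table and the exclusion report.

    Returns a long-format DataFrame (participant, age_group, channel,
    hemisphere, condition, hb_type, mean_change, n_valid_blocks, included)
    and a list of exclusion records, one per excluded participant, naming
    the rule and its parameter values.
    """
    rows = []
    report = []
    for s in summaries:
        included = s.n_available_rois >= excl.min_available_rois
        if not included:
            report.append(
                {
                    "participant": s.participant,
                    "age_group": s.age_group,
                    "reason": (
                        f"fewer than {excl.min_available_rois} available ROIs "
                        f"(had {s.n_available_rois}; an available ROI needs >= "
                        f"{excl.min_valid_blocks_per_condition} valid blocks per condition)"
                    ),
                    "n_available_rois": s.n_available_rois,
                }
            )
        ids = s.layout.channel_ids
        for ch_i, cid in enumerate(ids):
            hemi = s.layout.channels[ch_i].hemisphere
            for cond_i, cond in enumerate(CONDITIONS):
                for hb_i, hb_type in enumerate(HB_TYPES):
                    rows.append(
                        {
                            "participant": s.participant,
                            "age_group": s.age_group,
                            "channel": int(cid),
                            "hemisphere": hemi,
                            "condition": cond,
                            "hb_type": hb_type,
                            "mean_change": s.mean_change[ch_i, cond_i, hb_i],
                            "n_valid_blocks": int(s.n_valid_blocks[ch_i, cond_i]),
                            "included": bool(included),
                        }
                    )
    return pd.DataFrame(rows), report
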