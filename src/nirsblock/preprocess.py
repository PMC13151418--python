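"""Preprocessing cascade: raw intensities -> hemoglobin concentration changes.

The stream reproduces the standard continuous-wave processing chain used in
infant block-design studies, in this fixed order:

1. channel pruning by signal-to-noise ratio (SNR >= 2 at both wavelengths);
2. conversion to optical-density changes (natural-log convention);
3. motion-artifact detection (sliding window, amplitude OR variance
   criterion, per channel);
4. spline interpolation correction of flagged segments (smoothing
   parameter p = 0.99, segment re-anchoring);
5. wavelet filtering (db2, interquartile-range outlier rejection,
   IQR multiplier 0.5);
6. re-detection of residual artifacts and per-block validity flagging;
7. zero-phase band-pass filtering, 0.01-0.09 Hz (3rd-order Butterworth,
   forward-backward);
8. modified Beer-Lambert inversion to oxy-/deoxy-hemoglobin with partial
   pathlength factor 1.

Unless stated otherwise the motion steps operate on optical density at both
wavelengths; a sample is flagged for a channel if either wavelength
triggers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import make_smoothing_spline
from scipy.signal import butter, filtfilt

from nirsblock.core import (
    BlockDesign,
    ConfigurationError,
    HbSeries,
    ODSeries,
    RawIntensityScan,
)
from nirsblock.extinction import ExtinctionTable

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessParams",
    "prune_channels",
    "intensity_to_od",
    "detect_motion",
    "spline_correct",
    "wavelet_correct",
    "redetect_and_flag",
    "bandpass",
    "od_to_conc",
    "preprocess_scan",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing cascade (defaults as used in infant
    superior-temporal block designs).

    ``amp_thresh`` is in OD units and ``stdev_thresh`` multiplies the
    standard deviation of each channel's sample-to-sample OD differences;
    a detection window triggers when either is exceeded.
    """

    snr_thresh: float = 2.0
    t_motion: float = 1.0  # s, sliding-window length
    t_mask: float = 1.0  # s, margin flagged around a triggering window
    amp_thresh: float = 4.0  # OD
    stdev_thresh: float = 15.0  # multiplier of channel OD sd
    spline_p: float = 0.99
    wavelet_iqr: float = 0.5
    band_low: float = 0.01  # Hz
    band_high: float = 0.09  # Hz
    ppf: float = 1.0
    wavelet: str = "db2"
    wavelet_level: int | None = None  # None: auto from band_high (see wavelet_correct)

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ConfigurationError("need 0 < band_low < band_high")
        if not 0 <= self.spline_p <= 1:
            raise ConfigurationError("spline_p must be in [0, 1]")
        for name in ("snr_thresh", "t_motion", "t_mask", "amp_thresh", "stdev_thresh", "wavelet_iqr", "ppf"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# pruning and OD conversion


def prune_channels(scan: RawIntensityScan, params: PreprocessParams) -> np.ndarray:
    """Channel availability by SNR = mean/sd of raw intensity.

    A channel is retained iff SNR >= ``snr_thresh`` at *both* wavelengths
    (boundary equality retained).  Zero-variance channels have infinite SNR
    and are retained.  Channels with any nonpositive intensity are flagged
    unavailable with a warning.
    """
    mean = scan.data.mean(axis=0)  # (channel, wavelength)
    sd = scan.data.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    keep = np.all(snr >= params.snr_thresh, axis=1)
    nonpos = np.any(scan.data <= 0, axis=(0, 2))
    for cid in scan.layout.channel_ids[nonpos]:
        logger.warning("channel %d has nonpositive intensities; pruned", cid)
    keep &= ~nonpos
    return keep


def intensity_to_od(
    scan: RawIntensityScan, available: np.ndarray | None = None
) -> ODSeries:
    """Convert raw intensities to optical-density changes.

    ``dOD(t) = -ln(I(t) / mean_t I)`` per channel and wavelength, so the OD
    series is mean-centered in the exponential sense.  Channels flagged
    unavailable are NaN-filled.  A nonpositive sample on an available
    channel is an error naming the channel and sample.
    """
    n_ch = scan.data.shape[1]
    if available is None:
        available = np.ones(n_ch, dtype=bool)
    od = np.full_like(scan.data, np.nan)
    for ci in np.nonzero(available)[0]:
        block = scan.data[:, ci, :]
        if np.any(block <= 0):
            t_idx, w_idx = np.argwhere(block <= 0)[0]
            raise ValueError(
                f"nonpositive intensity on channel {scan.layout.channel_ids[ci]} "
                f"at sample {t_idx} (wavelength index {w_idx})"
            )
        od[:, ci, :] = -np.log(block / block.mean(axis=0))
    return ODSeries(od, scan.sampling_rate, scan.wavelengths, scan.layout)


# ---------------------------------------------------------------------------
# motion handling


def detect_motion(
    od: ODSeries,
    params: PreprocessParams,
    available: np.ndarray | None = None,
) -> np.ndarray:
    """Sliding-window motion detection, channel-wise.

    For every window of length ``t_motion`` the within-window peak-to-peak
    OD excursion is compared against ``amp_thresh`` and against
    ``stdev_thresh`` times the standard deviation of that
    channel/wavelength's sample-to-sample OD differences (the cited tool's
    criterion: fast excursions stand out against the typical sample-scale
    variability, which slow physiology barely contributes to); if either
    threshold is exceeded (at either wavelength) all samples from window
    start - ``t_mask`` to window end + ``t_mask`` are flagged for that
    channel.  Returns a boolean (time x channel) mask.
    """
    fs = od.sampling_rate
    win = int(round(params.t_motion * fs))
    if win < 2:
        raise ConfigurationError("t_motion must span at least 2 samples")
    margin = int(round(params.t_mask * fs))
    n_t, n_ch, n_w = od.data.shape
    if available is None:
        available = ~np.all(np.isnan(od.data[:, :, 0]), axis=0)
    mask = np.zeros((n_t, n_ch), dtype=bool)
    if n_t < win:
        return mask
    for ci in np.nonzero(available)[0]:
        trig_any = np.zeros(n_t - win + 1, dtype=bool)
        for wi in range(n_w):
            x = od.data[:, ci, wi]
            sw = np.lib.stride_tricks.sliding_window_view(x, win)
            p2p = sw.max(axis=1) - sw.min(axis=1)
            sd_diff = np.diff(x).std(ddof=0)
            thresh = min(params.amp_thresh, params.stdev_thresh * sd_diff)
            trig_any |= p2p > thresh
        covered = np.zeros(n_t, dtype=bool)
        starts = np.nonzero(trig_any)[0]
        for s in starts:
            covered[max(s - margin, 0) : min(s + win + margin, n_t)] = True
        mask[:, ci] = covered
    return mask


def _segments(flagged: np.ndarray) -> list[tuple[int, int, bool]]:
    """Contiguous runs of a boolean vector as (start, stop, is_flagged)."""
    out = []
    n = len(flagged)
    i = 0
    while i < n:
        j = i
        while j < n and flagged[j] == flagged[i]:
            j += 1
        out.append((i, j, bool(flagged[i])))
        i = j
    return out


def spline_correct(
    od: ODSeries,
    mask: np.ndarray,
    spline_p: float = 0.99,
    available: np.ndarray | None = None,
) -> ODSeries:
    """Motion correction by segment-wise smoothing-spline subtraction.

    Within each flagged segment a cubic smoothing spline (smoothing
    parameter ``spline_p`` in the penalized-least-squares convention,
    p -> 1 meaning near-interpolation) is fitted and subtracted, removing
    the artifact's trajectory.  All segments are then rejoined sequentially
    by matching each segment's leading level to the previous segment's
    trailing level (~1 s windows), so baseline steps are removed and no
    discontinuity is introduced.  Unflagged segments are never reshaped —
    they can only receive a constant level shift from the rejoin.  With an
    empty mask the series is returned unchanged.
    """
    if not np.any(mask):
        return od.copy()
    fs = od.sampling_rate
    lam = (1.0 - spline_p) / max(spline_p, 1e-12)
    out = od.copy()
    n_t, n_ch, n_w = out.data.shape
    anchor_n = max(int(round(fs)), 1)
    if available is None:
        available = ~np.all(np.isnan(od.data[:, :, 0]), axis=0)
    for ci in np.nonzero(available)[0]:
        if not np.any(mask[:, ci]):
            continue
        segs = _segments(mask[:, ci])
        for wi in range(n_w):
            x = out.data[:, ci, wi]
            corrected = x.copy()
            # remove artifact trajectory inside flagged segments
            for i0, i1, flg in segs:
                if not flg:
                    continue
                seg = x[i0:i1]
                t = np.arange(i0, i1) / fs
                if len(seg) >= 4 and np.ptp(t) > 0:
                    fit = make_smoothing_spline(t, seg, lam=lam)(t)
                else:
                    fit = np.full(len(seg), seg.mean())
                corrected[i0:i1] = seg - fit
            # sequential rejoin: match leading level to previous trailing level
            if len(segs) > 1:
                for (p0, p1, _), (c0, c1, _) in zip(segs[:-1], segs[1:]):
                    k_prev = min(anchor_n, p1 - p0)
                    k_cur = min(anchor_n, c1 - c0)
                    prev_tail = corrected[p1 - k_prev : p1].mean()
                    cur_head = corrected[c0 : c0 + k_cur].mean()
                    corrected[c0:c1] += prev_tail - cur_head
            out.data[:, ci, wi] = corrected
    return out


def wavelet_correct(
    od: ODSeries,
    wavelet_iqr: float = 0.5,
    wavelet: str = "db2",
    available: np.ndarray | None = None,
    level: int | None = None,
    protect_below: float = 0.1,
) -> ODSeries:
    """Wavelet-domain motion filtering by interquartile outlier rejection.

    Each channel/wavelength series is decomposed (``db2``); at every detail
    level, coefficients outside ``[Q1 - k*IQR, Q3 + k*IQR]`` are zeroed and
    the signal is reconstructed at the original length.  The decomposition
    depth is the deepest level whose approximation band still contains the
    hemodynamic frequencies of interest (approximation cutoff
    ``fs / 2**(level+1) >= protect_below``), so motion transients — which
    are broadband — are scrubbed from the detail levels while the
    slow hemodynamic response is carried by the untouched approximation.
    A degenerate level (zero IQR) is left unmodified.  Series too short for
    one decomposition level pass through with a warning.
    """
    out = od.copy()
    n_t, n_ch, n_w = out.data.shape
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(n_t, w.dec_len)
    if max_level < 1:
        logger.warning("series too short for wavelet filtering; passing through")
        return out
    if level is None:
        level = int(np.floor(np.log2(od.sampling_rate / protect_below))) - 1
    level = int(np.clip(level, 1, max_level))
    if available is None:
        available = ~np.all(np.isnan(od.data[:, :, 0]), axis=0)
    for ci in np.nonzero(available)[0]:
        for wi in range(n_w):
            coeffs = pywt.wavedec(out.data[:, ci, wi], w, level=level, mode="symmetric")
            for d in coeffs[1:]:
                q1, q3 = np.percentile(d, [25, 75])
                iqr = q3 - q1
                if iqr == 0:
                    continue
                lo, hi = q1 - wavelet_iqr * iqr, q3 + wavelet_iqr * iqr
                d[(d < lo) | (d > hi)] = 0.0
            rec = pywt.waverec(coeffs, w, mode="symmetric")
            out.data[:, ci, wi] = rec[:n_t]
    return out


def redetect_and_flag(
    od: ODSeries,
    params: PreprocessParams,
    design: BlockDesign,
    window_start: float = -3.0,
    window_end: float = 30.0,
    available: np.ndarray | None = None,
) -> np.ndarray:
    """Re-run motion detection and flag blocks contaminated by residuals.

    A block is invalid on a channel iff its epoch window
    ``[onset + window_start, onset + window_end]`` overlaps any flagged
    sample on that channel.  Returns a boolean (block x channel) validity
    array (True = valid).
    """
    mask = detect_motion(od, params, available=available)
    fs = od.sampling_rate
    n_t, n_ch = mask.shape
    valid = np.ones((design.n_blocks, n_ch), dtype=bool)
    for bi, ev in enumerate(design.events):
        i0 = int(round((ev.onset + window_start) * fs))
        i1 = int(round((ev.onset + window_end) * fs)) + 1
        i0c, i1c = max(i0, 0), min(i1, n_t)
        if i0c < i1c:
            valid[bi] = ~np.any(mask[i0c:i1c], axis=0)
    return valid


# ---------------------------------------------------------------------------
# filtering and concentration


def bandpass(
    od: ODSeries,
    band_low: float = 0.01,
    band_high: float = 0.09,
    available: np.ndarray | None = None,
) -> ODSeries:
    """Zero-phase band-pass: 3rd-order Butterworth applied forward-backward."""
    fs = od.sampling_rate
    if band_high >= fs / 2:
        raise ConfigurationError("band_high must be below the Nyquist frequency")
    if band_low <= 0 or band_low >= band_high:
        raise ConfigurationError("need 0 < band_low < band_high")
    b, a = butter(3, [band_low, band_high], btype="bandpass", fs=fs)
    out = od.copy()
    if available is None:
        available = ~np.all(np.isnan(od.data[:, :, 0]), axis=0)
    for ci in np.nonzero(available)[0]:
        out.data[:, ci, :] = filtfilt(b, a, od.data[:, ci, :], axis=0)
    return out


def od_to_conc(
    od: ODSeries,
    extinction: ExtinctionTable,
    layout=None,
    ppf: float = 1.0,
    available: np.ndarray | None = None,
) -> HbSeries:
    """Modified Beer-Lambert inversion: OD -> (oxy, deoxy) concentration.

    Solves the 2x2 linear system per channel and time sample.  Channels
    missing a wavelength (NaN) or flagged unavailable stay NaN in the
    output and are marked unavailable.
    """
    layout = layout if layout is not None else od.layout
    n_ch = od.data.shape[1]
    if available is None:
        available = np.ones(n_ch, dtype=bool)
    has_both = ~np.any(np.all(np.isnan(od.data), axis=0), axis=1)
    avail = available & has_both
    inv = extinction.inverse()  # (chromophore, wavelength)
    scale = layout.source_detector_distance * ppf
    conc = np.einsum("tcw,hw->tch", od.data, inv) / scale
    conc[:, ~avail, :] = np.nan
    return HbSeries(conc, od.sampling_rate, layout, avail)


# ---------------------------------------------------------------------------
# the full cascade


def preprocess_scan(
    scan: RawIntensityScan,
    params: PreprocessParams,
    extinction: ExtinctionTable | None = None,
) -> tuple[HbSeries, np.ndarray, dict]:
    """Run the fixed cascade on one scan.

    Returns ``(hb, block_validity, log)`` where ``block_validity`` is a
    boolean (block x channel) array from the residual-artifact re-detection
    and ``log`` records per-stage parameters, pruned channels and flagged
    segment counts.
    """
    if extinction is None:
        extinction = ExtinctionTable(wavelengths=scan.wavelengths)
    log: dict = {
        "participant": scan.participant,
        "order": [
            "prune_channels",
            "intensity_to_od",
            "detect_motion",
            "spline_correct",
            "wavelet_correct",
            "redetect_and_flag",
            "bandpass",
            "od_to_conc",
        ],
        "params": {
            "snr_thresh": params.snr_thresh,
            "t_motion": params.t_motion,
            "t_mask": params.t_mask,
            "amp_thresh": params.amp_thresh,
            "stdev_thresh": params.stdev_thresh,
            "spline_p": params.spline_p,
            "wavelet_iqr": params.wavelet_iqr,
            "band_low": params.band_low,
            "band_high": params.band_high,
            "ppf": params.ppf,
        },
    }
    available = prune_channels(scan, params)
    log["pruned_channels"] = [
        int(c) for c in scan.layout.channel_ids[~available]
    ]
    od = intensity_to_od(scan, available)
    mask = detect_motion(od, params, available)
    log["n_flagged_samples"] = int(mask.sum())
    od = spline_correct(od, mask, params.spline_p, available)
    od = wavelet_correct(
        od, params.wavelet_iqr, params.wavelet, available, level=params.wavelet_level
    )
    validity = redetect_and_flag(od, params, scan.design, available=available)
    validity &= available[None, :]
    log["n_invalid_blocks"] = int((~validity).sum())
    od = bandpass(od, params.band_low, params.band_high, available)
    hb = od_to_conc(od, extinction, scan.layout, params.ppf, available)
    return hb, validity, log
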