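"""Synthetic infant fNIRS cohorts with known ground truth.

The forward model mirrors the inverse chain the analysis implements: a
hemodynamic response per stimulus block (double-gamma kernel convolved with
the block boxcar, peak-normalized), oxy/deoxy anticorrelation, slow drift
and physiological oscillations, the modified Beer-Lambert law mapping
concentration changes to optical density at 695/830 nm, motion artifacts
(short spikes and step-like baseline shifts) injected in the OD domain, and
finally exponentiation to raw light intensities with multiplicative
measurement noise.

Every output is a pure function of (config, seed).  The master seed is split
into per-participant streams with ``numpy.random.SeedSequence([seed, i])``
for participant index ``i`` — a documented, stable rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from nirsblock.core import (
    CONDITIONS,
    BlockDesign,
    BlockEvent,
    ConfigurationError,
    GroundTruth,
    HbSeries,
    ODSeries,
    ProbeLayout,
    RawIntensityScan,
)
from nirsblock.extinction import ExtinctionTable, default_extinction_table

__all__ = [
    "DesignParams",
    "HrfParams",
    "NoiseParams",
    "SimulationConfig",
    "make_block_design",
    "hrf_kernel",
    "block_response",
    "simulate_hb",
    "forward_beer_lambert",
    "inject_motion",
    "od_to_intensity",
    "simulate_participant",
    "simulate_cohort",
    "default_amplitudes",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class DesignParams:
    """Block-design schedule parameters.

    Defaults follow the infant paradigm this package targets: 7 blocks per
    condition (14 total), 15 s blocks of 10 stimuli at 1.5 s onset
    asynchrony, silent baselines jittered over {18, 20, 22} s.
    """

    n_blocks_per_condition: int = 7
    block_duration: float = 15.0
    soa: float = 1.5
    stimuli_per_block: int = 10
    baseline_choices: tuple[float, ...] = (18.0, 20.0, 22.0)
    first_condition_policy: str = "randomized"  # fixed_HL | fixed_LH | randomized

    def __post_init__(self) -> None:
        if self.n_blocks_per_condition < 0:
            raise ConfigurationError("n_blocks_per_condition must be >= 0")
        if abs(self.block_duration - self.stimuli_per_block * self.soa) > 1e-9:
            raise ConfigurationError("block_duration must equal stimuli_per_block * soa")
        if not self.baseline_choices or any(b <= 0 for b in self.baseline_choices):
            raise ConfigurationError("baseline_choices must be non-empty, all > 0")
        if self.first_condition_policy not in ("fixed_HL", "fixed_LH", "randomized"):
            raise ConfigurationError(
                f"unknown first_condition_policy {self.first_condition_policy!r}"
            )


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma hemodynamic response kernel parameters.

    The kernel is peak-normalized: its unique maximum is 1, placed exactly
    at ``peak_time``.  No infant HRF is canonical; these are simulation
    stand-ins and live in configuration.
    """

    peak_time: float = 5.5
    undershoot_time: float = 12.0
    undershoot_ratio: float = 0.2
    peak_amplitude: float = 1.0  # uM; per-channel amplitudes scale this
    deoxy_ratio: float = -1.0 / 3.0
    shape: float = 6.0  # gamma shape of the main lobe

    def __post_init__(self) -> None:
        if self.peak_time <= 0:
            raise ConfigurationError("peak_time must be > 0")
        if self.undershoot_time <= self.peak_time:
            raise ConfigurationError("undershoot_time must exceed peak_time")
        if not 0 <= self.undershoot_ratio < 1:
            raise ConfigurationError("undershoot_ratio must be in [0, 1)")


@dataclass(frozen=True)
class NoiseParams:
    """Physiological and instrumental noise of the forward model.

    Amplitudes of concentration components are in uM; motion artifacts act
    in OD units.  Rates are events per minute.
    """

    drift_amplitude: float = 0.3
    drift_frequency: float = 0.002  # Hz, very-low-frequency drift
    oscillations: tuple[tuple[float, float], ...] = (
        (0.04, 0.3),  # spontaneous low-frequency oscillations, in-band
        (0.1, 0.15),  # Mayer waves
        (0.5, 0.05),  # respiration
    )
    white_noise_sd: float = 0.1
    motion_spike_rate: float = 0.5  # events / min
    motion_spike_amplitude_range: tuple[float, float] = (0.1, 0.6)  # OD
    motion_spike_duration: float = 0.4  # s, full width of a spike
    baseline_shift_rate: float = 0.2  # events / min
    baseline_shift_amplitude_range: tuple[float, float] = (0.1, 0.3)  # OD
    measurement_noise_sd: float = 0.003  # relative, multiplicative on intensity

    def __post_init__(self) -> None:
        rates = (self.motion_spike_rate, self.baseline_shift_rate)
        amps = (
            self.drift_amplitude,
            self.white_noise_sd,
            self.measurement_noise_sd,
            *self.motion_spike_amplitude_range,
            *self.baseline_shift_amplitude_range,
        )
        if any(r < 0 for r in rates) or any(a < 0 for a in amps):
            raise ConfigurationError("noise rates and amplitudes must be >= 0")


def default_amplitudes(layout: ProbeLayout) -> dict[str, np.ndarray]:
    """Ground-truth peak concentration changes (uM) per condition x channel.

    Every lateral channel carries a small auditory response; ROI channels
    respond more strongly, and the left-hemisphere ROI carries the HL > LH
    prosodic effect the paradigm is designed to detect.
    """
    base = {"HL": 0.10, "LH": 0.10}
    roi_right = {"HL": 0.20, "LH": 0.20}
    roi_left = {"HL": 0.35, "LH": 0.15}
    amps = {}
    for cond in CONDITIONS:
        a = np.full(len(layout.channels), base[cond])
        for i, ch in enumerate(layout.channels):
            if ch.is_roi:
                a[i] = roi_left[cond] if ch.hemisphere == "left" else roi_right[cond]
        amps[cond] = a
    return amps


@dataclass
class SimulationConfig:
    """Everything needed to generate a cohort reproducibly."""

    n_participants: int = 12
    design: DesignParams = field(default_factory=DesignParams)
    layout: ProbeLayout = field(default_factory=ProbeLayout.standard)
    hrf: HrfParams = field(default_factory=HrfParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    extinction: ExtinctionTable = field(default_factory=default_extinction_table)
    sampling_rate: float = 10.0
    ppf: float = 1.0
    seed: int = 0
    amplitudes: dict[str, np.ndarray] | None = None  # condition -> per channel, uM
    baseline_intensity: float = 1.0
    tail_duration: float = 32.0  # recording continues past the last block

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.amplitudes is None:
            self.amplitudes = default_amplitudes(self.layout)

    def participant_rng(self, index: int) -> np.random.Generator:
        """Per-participant stream: ``SeedSequence([master_seed, index])``."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, index]))


# ---------------------------------------------------------------------------
# design scheduler


def make_block_design(params: DesignParams, seed: int) -> BlockDesign:
    """Schedule alternating HL/LH blocks separated by jittered baselines.

    Each block (including the first) is preceded by a silent baseline drawn
    uniformly from ``params.baseline_choices``.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB10C]))
    n = params.n_blocks_per_condition
    if n == 0:
        return BlockDesign(events=(), total_duration=0.0)
    if params.first_condition_policy == "fixed_HL":
        first = "HL"
    elif params.first_condition_policy == "fixed_LH":
        first = "LH"
    else:
        first = CONDITIONS[rng.integers(2)]
    order = [first if i % 2 == 0 else ("LH" if first == "HL" else "HL") for i in range(2 * n)]
    gaps = rng.choice(params.baseline_choices, size=2 * n)
    events = []
    t = 0.0
    for cond, gap in zip(order, gaps):
        t += float(gap)
        events.append(BlockEvent(cond, t, params.block_duration))
        t += params.block_duration
    return BlockDesign(events=tuple(events), total_duration=t)


# ---------------------------------------------------------------------------
# hemodynamic response


def _raw_double_gamma(t: np.ndarray, params: HrfParams) -> np.ndarray:
    """Unnormalized double-gamma: main lobe minus a delayed undershoot lobe."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0

    def lobe(tt: np.ndarray, tp: float) -> np.ndarray:
        # gamma-shaped bump with unit peak at tp
        x = tt / tp
        return x**params.shape * np.exp(params.shape * (1.0 - x))

    out[pos] = lobe(t[pos], params.peak_time) - params.undershoot_ratio * lobe(
        t[pos], params.undershoot_time
    )
    return out


def _peak_calibration(params: HrfParams) -> tuple[float, float]:
    """Locate the raw kernel's maximum (time, value) numerically.

    With a nonzero undershoot the argmax of the combined kernel shifts away
    from the main lobe's peak; the public kernel rescales time so its
    maximum of exactly 1 sits at ``params.peak_time``.
    """
    grid = np.linspace(1e-6, params.undershoot_time, 2048)
    vals = _raw_double_gamma(grid, params)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -_raw_double_gamma(np.array([t]), params)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun)


def hrf_kernel(t: np.ndarray | float, params: HrfParams | None = None) -> np.ndarray:
    """Peak-normalized hemodynamic response kernel.

    ``kernel(0) = 0``; the unique maximum is 1 at ``params.peak_time``; the
    response decays to 0 with an optional late undershoot.
    """
    if params is None:
        params = HrfParams()
    t_peak_raw, v_peak = _peak_calibration(params)
    scale = t_peak_raw / params.peak_time
    t = np.asarray(t, dtype=float)
    return _raw_double_gamma(t * scale, params) / v_peak


def block_response(
    duration: float, params: HrfParams, sampling_rate: float, span: float = 45.0
) -> np.ndarray:
    """Boxcar(duration) convolved with the HRF kernel, peak-normalized.

    Returns the sampled response from the block onset over ``span`` seconds;
    its maximum is 1, so per-channel amplitudes are peak concentration
    changes.
    """
    dt = 1.0 / sampling_rate
    n_box = max(int(round(duration * sampling_rate)), 1)
    t_k = np.arange(0, span, dt)
    kern = hrf_kernel(t_k, params)
    resp = np.convolve(np.ones(n_box), kern)[: len(t_k)] * dt
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    return resp


# ---------------------------------------------------------------------------
# concentration-domain simulation


def simulate_hb(
    design: BlockDesign,
    config: SimulationConfig,
    participant_seed: int | np.random.Generator,
) -> tuple[HbSeries, GroundTruth]:
    """Simulate the hemoglobin concentration series for one participant.

    The noiseless oxy series is the sum over blocks of the peak-normalized
    block response scaled by the channel x condition amplitude; deoxy is
    ``deoxy_ratio`` times the noiseless oxy signal.  Drift, Mayer-wave and
    respiratory oscillations (random phase per channel) and white noise are
    added independently per channel and chromophore.
    """
    rng = (
        participant_seed
        if isinstance(participant_seed, np.random.Generator)
        else np.random.default_rng(participant_seed)
    )
    fs = config.sampling_rate
    n_ch = len(config.layout.channels)
    n_t = int(round((design.total_duration + config.tail_duration) * fs))
    amps = config.amplitudes

    resp = block_response(
        config.design.block_duration if design.events else 15.0, config.hrf, fs
    )
    clean_oxy = np.zeros((n_t, n_ch))
    for ev in design.events:
        i0 = int(round(ev.onset * fs))
        i1 = min(i0 + len(resp), n_t)
        clean_oxy[i0:i1] += np.outer(resp[: i1 - i0], amps[ev.condition])
    clean = np.stack([clean_oxy, config.hrf.deoxy_ratio * clean_oxy], axis=2)

    noise = config.noise
    t = np.arange(n_t) / fs
    data = clean.copy()
    for ci in range(n_ch):
        for hi in range(2):
            comp = np.zeros(n_t)
            if noise.drift_amplitude > 0:
                phase = rng.uniform(0, 2 * np.pi)
                comp += noise.drift_amplitude * np.sin(
                    2 * np.pi * noise.drift_frequency * t + phase
                )
            for freq, amp in noise.oscillations:
                if amp > 0:
                    phase = rng.uniform(0, 2 * np.pi)
                    comp += amp * np.sin(2 * np.pi * freq * t + phase)
            if noise.white_noise_sd > 0:
                comp += rng.normal(0.0, noise.white_noise_sd, n_t)
            data[:, ci, hi] += comp

    hb = HbSeries(data, fs, config.layout)
    truth = GroundTruth(
        motion_mask=np.zeros((n_t, n_ch), dtype=bool),
        amplitudes={c: np.asarray(a, dtype=float) for c, a in amps.items()},
        hb_true=HbSeries(clean, fs, config.layout),
    )
    return hb, truth


# ---------------------------------------------------------------------------
# forward optics


def forward_beer_lambert(
    hb: HbSeries,
    extinction: ExtinctionTable,
    layout: ProbeLayout,
    ppf: float = 1.0,
) -> ODSeries:
    """Modified Beer-Lambert forward map: concentration -> optical density.

    ``dOD(lambda, t) = L * ppf * [eps_oxy(lambda) doxy(t) + eps_deoxy(lambda)
    ddeoxy(t)]`` per channel, with L the source-detector distance.
    """
    E = extinction.matrix()  # (wavelength, chromophore)
    scale = layout.source_detector_distance * ppf
    od = scale * np.einsum("tch,wh->tcw", hb.data, E)
    return ODSeries(od, hb.sampling_rate, extinction.wavelengths, layout)


def inject_motion(
    od: ODSeries,
    noise: NoiseParams,
    seed: int | np.random.Generator,
) -> tuple[ODSeries, np.ndarray]:
    """Add motion artifacts to an OD series and record the true mask.

    Motion events (head or probe movement) happen at Poisson-distributed
    times per scan and hit every channel and both wavelengths coherently,
    with an independent amplitude and sign per channel.  Spikes are short
    gaussian bumps (~``motion_spike_duration`` wide); baseline shifts are
    steps that persist to the end of the scan.  Returns the contaminated
    copy and a boolean (time x channel) mask flagging every contaminated
    sample (for steps, the transition neighborhood).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = od.copy()
    n_t, n_ch, _ = out.data.shape
    fs = od.sampling_rate
    duration_min = n_t / fs / 60.0
    mask = np.zeros((n_t, n_ch), dtype=bool)

    half_w = max(int(round(noise.motion_spike_duration * fs / 2)), 1)
    n_spikes = rng.poisson(noise.motion_spike_rate * duration_min)
    for _ in range(n_spikes):
        center = int(rng.integers(0, n_t))
        amps = rng.uniform(*noise.motion_spike_amplitude_range, size=n_ch)
        amps *= rng.choice([-1.0, 1.0], size=n_ch)
        i0, i1 = max(center - half_w, 0), min(center + half_w + 1, n_t)
        idx = np.arange(i0, i1)
        shape = np.exp(-0.5 * ((idx - center) / (half_w / 2.0)) ** 2)
        out.data[i0:i1, :, :] += shape[:, None, None] * amps[None, :, None]
        mask[i0:i1, :] = True
    n_shifts = rng.poisson(noise.baseline_shift_rate * duration_min)
    for _ in range(n_shifts):
        start = int(rng.integers(0, n_t))
        amps = rng.uniform(*noise.baseline_shift_amplitude_range, size=n_ch)
        amps *= rng.choice([-1.0, 1.0], size=n_ch)
        out.data[start:, :, :] += amps[None, :, None]
        i0, i1 = max(start - half_w, 0), min(start + half_w + 1, n_t)
        mask[i0:i1, :] = True
    return out, mask


def od_to_intensity(
    od: ODSeries,
    baseline_intensity: float | np.ndarray = 1.0,
    measurement_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Invert OD to raw intensities: ``I(t) = I0 * exp(-dOD(t))``.

    Optional multiplicative gaussian measurement noise (relative sd).
    Output is strictly positive.
    """
    base = np.broadcast_to(np.asarray(baseline_intensity, dtype=float), od.data.shape)
    if np.any(base <= 0):
        raise ConfigurationError("baseline_intensity must be > 0")
    intensity = base * np.exp(-od.data)
    if measurement_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        factor = 1.0 + rng.normal(0.0, measurement_noise_sd, od.data.shape)
        intensity = intensity * np.clip(factor, 1e-6, None)
    return intensity


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_participant(
    config: SimulationConfig, index: int
) -> tuple[RawIntensityScan, GroundTruth]:
    """Run the full forward model for participant ``index``."""
    rng = config.participant_rng(index)
    design = make_block_design(config.design, int(rng.integers(2**31 - 1)))
    hb, truth = simulate_hb(design, config, rng)
    od = forward_beer_lambert(hb, config.extinction, config.layout, config.ppf)
    od, motion_mask = inject_motion(od, config.noise, rng)
    truth.motion_mask[:] = motion_mask
    intensity = od_to_intensity(
        od, config.baseline_intensity, config.noise.measurement_noise_sd, rng
    )
    scan = RawIntensityScan(
        participant=f"sub-{index + 1:03d}",
        data=intensity,
        sampling_rate=config.sampling_rate,
        wavelengths=config.extinction.wavelengths,
        layout=config.layout,
        design=design,
        meta={
            "seed": config.seed,
            "participant_index": index,
            "true_amplitudes": {c: list(map(float, a)) for c, a in truth.amplitudes.items()},
        },
    )
    return scan, truth


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[RawIntensityScan], list[GroundTruth]]:
    """Generate ``config.n_participants`` scans; optionally serialize them.

    Fully reproducible: participant ``i`` depends only on
    ``(config, SeedSequence([config.seed, i]))``.
    """
    scans, truths = [], []
    for i in range(config.n_participants):
        scan, truth = simulate_participant(config, i)
        scans.append(scan)
        truths.append(truth)
    if out_dir is not None:
        from nirsblock.containers import save_scan

        out_dir = Path(out_dir)
        for scan in scans:
            save_scan(scan, out_dir / scan.participant)
    return scans, truths
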