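"""Semisynthetic fNIRS scan generation.

Emulates the statistical structure of resting and breath-hold recordings:

* a shared superficial ("scalp") signal per chromophore built from an AR(1)
  drift, cardiac (~1 Hz), respiratory (~0.25 Hz) and Mayer-wave (~0.1 Hz)
  oscillations with randomised phases and slowly wandering amplitudes, plus
  a vasomotor bump at breath-hold onsets in the breath-hold conditions;
* short-separation channels that observe this shared signal almost directly;
* long-distance channels that observe a correlated copy of it (the
  scalp physiology seen through a different tissue column) plus channel
  noise;
* canonical evoked responses injected into exactly half of the LD channels
  at a controlled contrast-to-noise ratio (CNR), defined per channel and per
  chromophore as peak amplitude over the robust standard deviation
  1.4826 * MAD of the pre-injection data.

Three conditions: ``rest`` (no vasomotor events), ``bh_random`` (breath-hold
bumps present, stimulus timing jittered independently) and ``bh_locked``
(stimulus onsets coincide with the breath holds — the worst case for
separating task from physiology).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .glm_engine import StimulusDesign, build_task_design
from .probe_signal import (
    DEFAULT_DPF,
    DEFAULT_EXTINCTION,
    DEFAULT_FS,
    HemoScan,
    ProbeGeometry,
    RawScan,
    _extinction_matrix,
    default_probe,
)

__all__ = [
    "NoiseSpec",
    "SimulationSpec",
    "EventSet",
    "make_events",
    "generate_noise_scan",
    "robust_sigma",
    "inject_response",
    "raw_from_hemo",
    "CONDITIONS",
]

CONDITIONS = ("rest", "bh_random", "bh_locked")

TASK_DURATION_S = 25.0
BLOCK_REST_S = 30.0
N_BLOCKS = 5
ISI_JITTER_S = (15.0, 50.0)


@dataclass
class NoiseSpec:
    """Parameters of the synthetic physiological noise model.

    Amplitudes are in uM (HbO2 scale); the Hb superficial signal is the HbO2
    signal scaled by ``hb_factor``.  ``drift_sd`` is the stationary standard
    deviation of the AR(1) drift; it deliberately dominates the white noise
    so that ordinary least squares shows the strong type-I inflation seen on
    real serially correlated physiology.
    """

    fs: float = DEFAULT_FS
    duration: float = 300.0
    drift_phi: float = 0.98
    drift_sd: float = 1.0
    cardiac_freq: float = 1.0
    cardiac_amp: float = 0.3
    resp_freq: float = 0.25
    resp_amp: float = 0.2
    mayer_freq: float = 0.1
    mayer_amp: float = 0.5
    amp_wander: float = 0.3  # relative slow amplitude modulation of the sinusoids
    white_noise_sd: float = 0.2
    ss_noise_sd: float = 0.1
    ld_gain_range: tuple = (0.8, 1.2)
    ss_gain_range: tuple = (0.8, 1.2)
    ld_ss_coupling: float = 0.85
    hb_factor: float = -1.0 / 3.0
    bh_amp: float = 2.0  # vasomotor bump amplitude, multiples of drift_sd
    bh_peak_s: float = 15.0
    bh_width_s: float = 20.0

    def __post_init__(self):
        nyq = self.fs / 2.0
        for f in (self.cardiac_freq, self.resp_freq, self.mayer_freq):
            if not (0 < f < nyq):
                raise ValueError(f"component frequency {f} Hz outside (0, {nyq})")
        for a in (self.cardiac_amp, self.resp_amp, self.mayer_amp,
                  self.white_noise_sd, self.ss_noise_sd, self.bh_amp):
            if a < 0:
                raise ValueError("amplitudes must be non-negative")
        if not (0 <= self.ld_ss_coupling <= 1):
            raise ValueError("ld_ss_coupling must be in [0, 1]")
        if not (0 <= abs(self.drift_phi) < 1):
            raise ValueError("drift AR coefficient must be in (-1, 1)")


@dataclass
class SimulationSpec:
    """One simulated study condition: noise condition, CNR and seeding."""

    condition: str = "rest"
    cnr: float = 0.7
    seed: int = 0
    n_iterations: int = 200
    truth_fraction: float = 0.5

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.cnr < 0:
            raise ValueError("cnr must be non-negative")
        if not (0 < self.truth_fraction <= 1):
            raise ValueError("truth_fraction must be in (0, 1]")


@dataclass
class EventSet:
    """Stimulus timing plus the breath-hold physiological onsets (empty for
    the rest condition)."""

    stim: StimulusDesign
    bh_onsets: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _block_onsets(duration: float) -> np.ndarray:
    """Fixed breath-hold schedule: 25 s hold / 30 s rest repeated, after a
    30 s lead-in, as many blocks as fit (5 in a 300 s scan)."""
    onsets = []
    t = BLOCK_REST_S
    while t + TASK_DURATION_S <= duration and len(onsets) < N_BLOCKS:
        onsets.append(t)
        t += TASK_DURATION_S + BLOCK_REST_S
    return np.asarray(onsets)


def make_events(condition: str, duration: float, seed: int) -> EventSet:
    """Stimulus events for one iteration.

    ``bh_locked``: stimulus onsets equal the breath-hold onsets.
    ``bh_random``: breath holds follow the block schedule while stimulus
    onsets are drawn independently with 25 s duration and inter-stimulus
    interval uniform on [15, 50] s.  ``rest``: jittered stimuli, no breath
    holds.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if duration < TASK_DURATION_S + ISI_JITTER_S[0]:
        raise ValueError("duration too short for a single task block")
    rng = np.random.default_rng(seed)
    bh = _block_onsets(duration) if condition.startswith("bh") else np.zeros(0)
    if condition == "bh_locked":
        if bh.size == 0:
            raise ValueError("duration too short for a breath-hold block")
        onsets = bh.copy()
    else:
        onsets = []
        t = float(rng.uniform(*ISI_JITTER_S))
        while t + TASK_DURATION_S <= duration:
            onsets.append(t)
            t += TASK_DURATION_S + float(rng.uniform(*ISI_JITTER_S))
        if not onsets:
            raise ValueError("duration too short for a single task block")
        onsets = np.asarray(onsets)
    durations = np.full(len(onsets), TASK_DURATION_S)
    return EventSet(
        stim=StimulusDesign(onsets=onsets, durations=durations, condition="task"),
        bh_onsets=bh,
    )


def _bh_waveform(t: np.ndarray, peak_s: float, width_s: float) -> np.ndarray:
    """Smooth biphasic vasomotor bump (gamma difference), unit peak."""
    shape1 = max(peak_s / (width_s / 4.0), 1.5)
    scale1 = peak_s / max(shape1 - 1.0, 1.0)
    w = stats.gamma.pdf(t, shape1, scale=scale1) - 0.4 * stats.gamma.pdf(
        t, shape1 * 2.0, scale=scale1
    )
    peak = np.abs(w).max()
    return w / peak if peak > 0 else w


def _superficial_signal(n, spec: NoiseSpec, bh_onsets, rng) -> np.ndarray:
    """One realisation of the shared scalp signal (HbO2 scale)."""
    fs = spec.fs
    # AR(1) drift scaled to stationary sd drift_sd
    innov_sd = spec.drift_sd * np.sqrt(1.0 - spec.drift_phi**2)
    e = rng.normal(0.0, innov_sd, n)
    x0 = rng.normal(0.0, spec.drift_sd)  # start in the stationary distribution
    from scipy.signal import lfilter

    drift, _ = lfilter([1.0], [1.0, -spec.drift_phi], e, zi=np.array([spec.drift_phi * x0]))
    t = np.arange(n) / fs
    sig = drift
    for freq, amp in (
        (spec.cardiac_freq, spec.cardiac_amp),
        (spec.resp_freq, spec.resp_amp),
        (spec.mayer_freq, spec.mayer_amp),
    ):
        phase = rng.uniform(0, 2 * np.pi)
        # slowly wandering amplitude: low-frequency random phase modulation
        wander = 1.0 + spec.amp_wander * np.sin(
            2 * np.pi * rng.uniform(0.005, 0.02) * t + rng.uniform(0, 2 * np.pi)
        )
        sig = sig + amp * wander * np.sin(2 * np.pi * freq * t + phase)
    if len(bh_onsets):
        kernel_t = np.arange(0, 60.0, 1.0 / fs)
        bump = _bh_waveform(kernel_t, spec.bh_peak_s, spec.bh_width_s)
        amp = spec.bh_amp * spec.drift_sd
        for onset in bh_onsets:
            i0 = int(round(onset * fs))
            i1 = min(n, i0 + len(bump))
            if i0 < n:
                sig[i0:i1] += amp * bump[: i1 - i0]
    return sig


def generate_noise_scan(
    noise: NoiseSpec,
    events: EventSet,
    seed: int,
    geometry: ProbeGeometry | None = None,
) -> HemoScan:
    """Generate a null (no evoked response) scan for all probe channels.

    SS channel i observes ``a_i * g(t)`` plus small sensor noise; LD channel
    j observes ``m_j * g_j(t)`` plus white noise, where ``g_j`` is a copy of
    the superficial process correlated with the SS-observed ``g`` at
    ``ld_ss_coupling``.  The Hb block is the HbO2 block scaled by
    ``hb_factor`` with its own sensor noise.
    """
    geometry = geometry or default_probe()
    rng = np.random.default_rng(seed)
    n = int(round(noise.duration * noise.fs))
    ss_idx = geometry.ss_indices()
    ld_idx = geometry.ld_indices()
    n_ch = geometry.n_channels

    g = _superficial_signal(n, noise, events.bh_onsets, rng)
    rho = noise.ld_ss_coupling
    data = {}
    hbo = np.zeros((n, n_ch))
    ss_gain = rng.uniform(*noise.ss_gain_range, size=len(ss_idx))
    ld_gain = rng.uniform(*noise.ld_gain_range, size=len(ld_idx))
    for k, ch in enumerate(ss_idx):
        hbo[:, ch] = ss_gain[k] * g + rng.normal(0.0, noise.ss_noise_sd, n)
    for k, ch in enumerate(ld_idx):
        h = _superficial_signal(n, noise, events.bh_onsets, rng)
        g_j = rho * g + np.sqrt(1.0 - rho**2) * h
        hbo[:, ch] = ld_gain[k] * g_j + rng.normal(0.0, noise.white_noise_sd, n)
    hbr = noise.hb_factor * hbo + rng.normal(
        0.0, abs(noise.hb_factor) * noise.white_noise_sd, hbo.shape
    )
    return HemoScan(
        hbo,
        hbr,
        fs=noise.fs,
        provenance="synthetic",
        channel_labels=geometry.channel_labels(),
    )


def robust_sigma(series) -> float:
    """Robust standard deviation 1.4826 * median(|x - median(x)|)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    s = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    if s == 0:
        warnings.warn("constant series: robust sigma is 0")
    return s


def inject_response(
    scan: HemoScan,
    events: EventSet,
    cnr: float,
    seed: int,
    geometry: ProbeGeometry | None = None,
    truth_fraction: float = 0.5,
):
    """Add a canonical evoked response to a random half of the LD channels.

    The response shape is the unit-peak canonical-HRF x boxcar regressor of
    the stimulus events.  Per truth channel the HbO2 amplitude is
    ``cnr * robust_sigma(pre-injection HbO2)`` and the Hb amplitude is
    ``-cnr * robust_sigma(pre-injection Hb)`` (oxygenation increases while
    deoxyhemoglobin falls).  SS channels never receive a response.

    Returns ``(scan_with_response, truth)`` where ``truth`` is a boolean
    array over all probe channels (True = response present).
    """
    if cnr < 0:
        raise ValueError("cnr must be non-negative")
    geometry = geometry or default_probe()
    rng = np.random.default_rng(seed)
    ld_idx = geometry.ld_indices()
    n_truth = int(np.floor(len(ld_idx) * truth_fraction))
    chosen = rng.choice(ld_idx, size=n_truth, replace=False)
    truth = np.zeros(scan.n_channels, dtype=bool)
    truth[chosen] = True
    out = scan.copy(provenance="synthetic+response")
    if cnr == 0:
        return out, truth
    shape, _ = build_task_design(events.stim, scan.n_time, scan.fs)
    shape = shape[:, 0]  # unit peak by construction
    for ch in chosen:
        out.hbo[:, ch] += cnr * robust_sigma(scan.hbo[:, ch]) * shape
        out.hbr[:, ch] -= cnr * robust_sigma(scan.hbr[:, ch]) * shape
    return out, truth


def raw_from_hemo(
    scan: HemoScan,
    geometry: ProbeGeometry,
    dpf: dict | None = None,
    extinction: dict | None = None,
    baseline_intensity: float = 1.0,
) -> RawScan:
    """Forward Beer-Lambert synthesis of raw intensities from concentrations.

    Inverse of ``od_from_intensity`` + ``hemoglobin_from_od`` up to the
    arbitrary baseline intensity, so full-pipeline and SCI tests can start
    from intensity data.
    """
    dpf = dict(DEFAULT_DPF if dpf is None else dpf)
    ext = dict(DEFAULT_EXTINCTION if extinction is None else extinction)
    e = _extinction_matrix(geometry.wavelengths, ext)
    dpf_vec = np.array([dpf[wl] for wl in geometry.wavelengths])
    d_cm = geometry.distances() / 10.0
    conc = np.stack([scan.hbo, scan.hbr], axis=2) * 1e-6  # uM -> mol/L
    od = np.einsum("wk,tck->tcw", e, conc) * (d_cm[None, :, None] * dpf_vec[None, None, :])
    intensity = baseline_intensity * np.exp(-od)
    return RawScan(intensity=intensity, fs=scan.fs)
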