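"""Probe geometry, optical-density / hemoglobin conversion, temporal filtering,
and the scalp-coupling-index (SCI) signal-quality metric.

An fNIRS probe is a set of light sources and detectors on the scalp.  Each
source-detector pair at a given wavelength is a measurement channel.  Pairs
separated by ~30 mm (long-distance, LD) sample both brain and scalp; pairs at
~7.5 mm (short-separation, SS) sample the scalp only and are used as nuisance
references.  Raw intensities are converted to optical density and then to
oxy-/deoxy-hemoglobin concentration changes (HbO2, Hb) via the modified
Beer-Lambert law (MBLL).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "ChannelDef",
    "ProbeGeometry",
    "RawScan",
    "HemoScan",
    "QualityReport",
    "default_probe",
    "od_from_intensity",
    "hemoglobin_from_od",
    "classify_channels",
    "nearest_ss",
    "bandpass",
    "scalp_coupling_index",
    "DEFAULT_EXTINCTION",
    "DEFAULT_DPF",
    "DEFAULT_FS",
    "DEFAULT_WAVELENGTHS",
    "CHROMOPHORES",
]

DEFAULT_FS = 7.8125
DEFAULT_WAVELENGTHS = (760.0, 850.0)
#: Molar extinction coefficients in cm^-1 / (mol/L): wavelength -> (HbO2, Hb).
#: Gratzer/Prahl compilation values for the two standard CW-NIRS wavelengths.
DEFAULT_EXTINCTION = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}
#: Differential pathlength factor per wavelength (dimensionless).
DEFAULT_DPF = {760.0: 6.0, 850.0: 6.0}
DEFAULT_SS_THRESHOLD_MM = 15.0
CHROMOPHORES = ("HbO2", "Hb")


class ChannelDef(NamedTuple):
    """A geometric measurement channel: indices into the optode tables."""

    source: int
    detector: int


def _as_positions(arr) -> np.ndarray:
    pos = np.asarray(arr, dtype=float)
    if pos.ndim != 2 or pos.shape[1] not in (2, 3):
        raise ValueError("optode positions must be an (n, 2) or (n, 3) array in mm")
    if pos.shape[1] == 2:  # promote to 3D with z = 0 (scalp plane)
        pos = np.column_stack([pos, np.zeros(len(pos))])
    if not np.all(np.isfinite(pos)):
        raise ValueError("optode positions must be finite")
    return pos


@dataclass(frozen=True)
class ProbeGeometry:
    """Optode positions (mm), channel definitions and SS/LD classification.

    Parameters
    ----------
    sources, detectors : array-like
        2D or 3D optode positions in millimetres.
    channels : sequence of ChannelDef
        Source/detector index pairs; each geometric channel is measured at
        both probe wavelengths.
    wavelengths : tuple of float
        The two laser wavelengths in nm.
    ss_threshold : float
        Channels with source-detector distance strictly below this value (mm)
        are classified short-separation.
    """

    sources: np.ndarray
    detectors: np.ndarray
    channels: tuple
    wavelengths: tuple = DEFAULT_WAVELENGTHS
    ss_threshold: float = DEFAULT_SS_THRESHOLD_MM

    def __post_init__(self):
        object.__setattr__(self, "sources", _as_positions(self.sources))
        object.__setattr__(self, "detectors", _as_positions(self.detectors))
        chans = tuple(ChannelDef(int(s), int(d)) for s, d in self.channels)
        object.__setattr__(self, "channels", chans)
        if len(self.wavelengths) != 2:
            raise ValueError("exactly two wavelengths are supported")
        for ch in chans:
            if not (0 <= ch.source < len(self.sources)):
                raise ValueError(f"channel {ch} references missing source {ch.source}")
            if not (0 <= ch.detector < len(self.detectors)):
                raise ValueError(f"channel {ch} references missing detector {ch.detector}")
        if np.any(self.distances() <= 0):
            bad = int(np.argmin(self.distances()))
            raise ValueError(f"channel {bad} has non-positive source-detector distance")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def distances(self) -> np.ndarray:
        """Source-detector distance per channel, mm."""
        s = self.sources[[c.source for c in self.channels]]
        d = self.detectors[[c.detector for c in self.channels]]
        return np.linalg.norm(s - d, axis=1)

    def midpoints(self) -> np.ndarray:
        """Channel midpoint positions, mm (the channel's nominal location)."""
        s = self.sources[[c.source for c in self.channels]]
        d = self.detectors[[c.detector for c in self.channels]]
        return 0.5 * (s + d)

    def is_short(self) -> np.ndarray:
        """Boolean mask: True where distance < ss_threshold (half-open)."""
        return self.distances() < self.ss_threshold

    def ss_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_short())

    def ld_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_short())

    def channel_labels(self) -> list:
        return [f"S{c.source + 1}_D{c.detector + 1}" for c in self.channels]


def default_probe(ss_threshold: float = DEFAULT_SS_THRESHOLD_MM) -> ProbeGeometry:
    """Replica of a motor-cortex short-separation probe: 8 sources, 7 LD
    detectors and 8 SS detectors giving 22 LD channels at 30 mm and 8 SS
    channels at 7.5 mm.

    Optodes sit on a 4x4 checkerboard grid with 30 mm pitch (one corner
    detector omitted so exactly 22 grid edges remain).  Each source carries a
    short-separation detector at 7.5 mm on the bundle holder, offset out of
    the scalp plane (interior sources along the scalp normal, boundary
    sources tilted 60 deg toward their incident LD channels), which places
    every LD channel's nearest SS channel midpoint 13.4-15.5 mm away.
    """
    pitch = 30.0
    grid = {(i, j): np.array([i * pitch, j * pitch, 0.0]) for i in range(4) for j in range(4)}
    dropped = (3, 0)  # corner detector omitted: 8 sources / 7 detectors, 22 edges
    src_keys = sorted(k for k in grid if (k[0] + k[1]) % 2 == 0)
    det_keys = sorted(k for k in grid if (k[0] + k[1]) % 2 == 1 and k != dropped)
    sources = [grid[k] for k in src_keys]
    detectors = [grid[k] for k in det_keys]
    src_of = {k: i for i, k in enumerate(src_keys)}
    det_of = {k: i for i, k in enumerate(det_keys)}

    ld_channels = []
    edges_of_source: dict = {k: [] for k in src_keys}
    for (i, j) in src_keys:
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (i + di, j + dj)
            if nb in det_of:
                ld_channels.append(ChannelDef(src_of[(i, j)], det_of[nb]))
                edges_of_source[(i, j)].append(np.array([di, dj], dtype=float))

    # SS detectors: 7.5 mm from each source along a per-source unit vector.
    ss_detectors = []
    ss_channels = []
    for k in src_keys:
        edges = edges_of_source[k]
        if len(edges) == 4:
            u = np.array([0.0, 0.0, 1.0])
        else:
            mean_dir = np.mean(edges, axis=0)
            az = mean_dir / np.linalg.norm(mean_dir)
            tilt = np.deg2rad(60.0)  # 60 deg out of plane toward incident edges
            u = np.array([np.cos(tilt) * az[0], np.cos(tilt) * az[1], np.sin(tilt)])
        ss_pos = grid[k] + 7.5 * u
        ss_detectors.append(ss_pos)
        ss_channels.append(ChannelDef(src_of[k], len(detectors) + len(ss_detectors) - 1))

    return ProbeGeometry(
        sources=np.array(sources),
        detectors=np.array(detectors + ss_detectors),
        channels=tuple(ld_channels + ss_channels),
        ss_threshold=ss_threshold,
    )


@dataclass
class RawScan:
    """Raw intensity: time x channel x wavelength, strictly positive, plus fs."""

    intensity: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise ValueError("intensity must be (time, channel, wavelength=2)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.any(~(self.intensity > 0)):
            t, c, w = np.unravel_index(
                int(np.argmin(self.intensity)), self.intensity.shape
            )
            raise ValueError(
                f"non-positive intensity at sample {t}, channel {c}, wavelength index {w}"
            )

    @property
    def n_time(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]


@dataclass
class HemoScan:
    """Chromophore concentration changes (uM): one time x channel block per
    chromophore, aligned with a ProbeGeometry's channel list."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float = DEFAULT_FS
    provenance: str = "raw"
    channel_labels: Sequence[str] | None = None

    def __post_init__(self):
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("HbO2 and Hb blocks must have identical shape")
        if self.hbo.ndim != 2:
            raise ValueError("chromophore blocks must be (time, channel)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_time(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    def chrom(self, name: str) -> np.ndarray:
        if name == "HbO2":
            return self.hbo
        if name == "Hb":
            return self.hbr
        raise KeyError(f"unknown chromophore {name!r}")

    def select(self, channels) -> "HemoScan":
        """Sub-scan restricted to the given channel indices (view copy)."""
        idx = np.asarray(channels, dtype=int)
        labels = (
            [self.channel_labels[i] for i in idx] if self.channel_labels else None
        )
        return HemoScan(
            self.hbo[:, idx].copy(),
            self.hbr[:, idx].copy(),
            fs=self.fs,
            provenance=self.provenance,
            channel_labels=labels,
        )

    def copy(self, provenance: str | None = None) -> "HemoScan":
        return HemoScan(
            self.hbo.copy(),
            self.hbr.copy(),
            fs=self.fs,
            provenance=provenance or self.provenance,
            channel_labels=list(self.channel_labels) if self.channel_labels else None,
        )


@dataclass
class QualityReport:
    """Per-channel scalp coupling index with the band and threshold used."""

    sci: np.ndarray
    band: tuple = (0.5, 2.5)
    threshold: float = 0.8

    def acceptable(self) -> np.ndarray:
        return self.sci >= self.threshold


def od_from_intensity(raw: RawScan) -> np.ndarray:
    """Optical density change: OD(t) = -log(I(t) / I0) with I0 the temporal
    mean of the log-intensity (geometric mean).

    Normalising in the log domain makes OD exactly zero-mean over time, so a
    constant channel maps to identically zero OD and the conversion is an
    exact inverse of intensity synthesis for zero-mean concentration inputs.
    """
    if raw.n_time < 2:
        raise ValueError("need at least 2 time points")
    log_i = np.log(raw.intensity)
    return -(log_i - log_i.mean(axis=0, keepdims=True))


def _extinction_matrix(wavelengths, extinction) -> np.ndarray:
    rows = []
    for wl in wavelengths:
        if wl not in extinction:
            raise ValueError(f"no extinction coefficients for wavelength {wl} nm")
        rows.append(extinction[wl])
    e = np.asarray(rows, dtype=float)  # rows: wavelength; cols: (HbO2, Hb)
    if abs(np.linalg.det(e)) < 1e-12 * np.abs(e).max() ** 2:
        raise ValueError("extinction matrix is singular; wavelengths not separable")
    return e


def hemoglobin_from_od(
    od: np.ndarray,
    geometry: ProbeGeometry,
    dpf: dict | None = None,
    extinction: dict | None = None,
    fs: float = DEFAULT_FS,
) -> HemoScan:
    """Modified Beer-Lambert conversion of optical density to HbO2/Hb (uM).

    Per channel, ``[dHbO2; dHb] = E^-1 [OD_l1/(d DPF_l1); OD_l2/(d DPF_l2)]``
    with E the 2x2 molar extinction matrix, d the source-detector distance
    and DPF the differential pathlength factor.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 2:
        raise ValueError("OD must be (time, channel, wavelength=2): missing wavelength pair")
    if od.shape[1] != geometry.n_channels:
        raise ValueError("OD channel count does not match probe geometry")
    dpf = dict(DEFAULT_DPF if dpf is None else dpf)
    ext = dict(DEFAULT_EXTINCTION if extinction is None else extinction)
    e = _extinction_matrix(geometry.wavelengths, ext)
    dpf_vec = np.array([dpf[wl] for wl in geometry.wavelengths])
    d_cm = geometry.distances() / 10.0  # mm -> cm
    # scaled OD: (time, channel, wavelength)
    scaled = od / (d_cm[None, :, None] * dpf_vec[None, None, :])
    conc = np.einsum("kw,tcw->tck", np.linalg.inv(e), scaled) * 1e6  # mol/L -> uM
    return HemoScan(
        conc[:, :, 0],
        conc[:, :, 1],
        fs=fs,
        provenance="raw",
        channel_labels=geometry.channel_labels(),
    )


def classify_channels(geometry: ProbeGeometry):
    """Per-channel {SS, LD} label and distance table (mm).

    A channel is SS iff its source-detector distance is strictly below the
    geometry's ss_threshold (half-open convention: exactly-at-threshold is LD).
    """
    dist = geometry.distances()
    labels = np.where(dist < geometry.ss_threshold, "SS", "LD")
    return labels, dist


def nearest_ss(geometry: ProbeGeometry, ld_channel: int, n: int) -> np.ndarray:
    """The n SS channels nearest to an LD channel, by midpoint-to-midpoint
    distance, ascending; ties broken by channel index (stable sort)."""
    ss = geometry.ss_indices()
    if n > len(ss):
        raise ValueError(f"requested {n} SS channels but probe has only {len(ss)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    mids = geometry.midpoints()
    d = np.linalg.norm(mids[ss] - mids[ld_channel], axis=1)
    order = np.argsort(d, kind="stable")
    return ss[order[:n]]


def _sos_for_band(low, high, fs, order=4):
    nyq = fs / 2.0
    low = None if (low is None or low == 0) else float(low)
    high = None if (high is None or high == 0) else float(high)
    for edge in (low, high):
        if edge is not None and not (0 < edge < nyq):
            raise ValueError(f"cutoff {edge} Hz outside (0, {nyq}) Hz")
    if low is not None and high is not None and low >= high:
        raise ValueError("low cutoff must be below high cutoff")
    if low is None and high is None:
        return None
    if low is None:
        return signal.butter(order, high, btype="lowpass", fs=fs, output="sos")
    if high is None:
        return signal.butter(order, low, btype="highpass", fs=fs, output="sos")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(scan: HemoScan, low: float | None, high: float | None, order: int = 4) -> HemoScan:
    """Zero-phase Butterworth filtering (forward-backward, so the HRF is not
    shifted in time).  ``None``/0 on either edge is a pass-through for that
    edge; both ``None`` returns an identical copy."""
    sos = _sos_for_band(low, high, scan.fs, order)
    out = scan.copy(provenance=f"filtered:bandpass({low},{high})")
    if sos is None:
        return out
    out.hbo = signal.sosfiltfilt(sos, out.hbo, axis=0)
    out.hbr = signal.sosfiltfilt(sos, out.hbr, axis=0)
    return out


def scalp_coupling_index(
    raw: RawScan, band: tuple = (0.5, 2.5), threshold: float = 0.8
) -> QualityReport:
    """Scalp coupling index per channel: the zero-lag Pearson correlation of
    the two band-limited (default 0.5-2.5 Hz, around the cardiac rhythm),
    variance-normalised wavelength traces.

    Good optode-scalp coupling puts the same cardiac pulsation in both
    wavelengths (SCI near 1); decoupled or noisy channels decorrelate.  The
    conventional acceptance threshold is 0.8.
    """
    if raw.n_time / raw.fs < 10.0:
        raise ValueError("scan must be at least 10 s long for a stable SCI")
    sos = _sos_for_band(band[0], band[1], raw.fs)
    filt = signal.sosfiltfilt(sos, raw.intensity, axis=0)
    filt = filt - filt.mean(axis=0, keepdims=True)
    sd = filt.std(axis=0)
    sci = np.zeros(raw.n_channels)
    for c in range(raw.n_channels):
        if sd[c, 0] == 0 or sd[c, 1] == 0:
            warnings.warn(f"zero-variance band-limited trace in channel {c}; SCI set to 0")
            sci[c] = 0.0
        else:
            sci[c] = float(
                np.mean(filt[:, c, 0] * filt[:, c, 1]) / (sd[c, 0] * sd[c, 1])
            )
    return QualityReport(sci=np.clip(sci, -1.0, 1.0), band=tuple(band), threshold=threshold)
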