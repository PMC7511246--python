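"""SNIRF and CSV readers/writers, run configuration, and result export.

SNIRF is the HDF5-based interchange standard for NIRS data; the subset
implemented here covers continuous-wave amplitude data, processed
hemoglobin data, probe geometry (3D optode positions in mm) and stimulus
blocks — enough to round-trip everything this package produces.  A plain
CSV fallback (time column plus one column per channel, channel metadata in
the header) is provided for quick inspection.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .glm_engine import StimulusDesign
from .probe_signal import (
    ChannelDef,
    HemoScan,
    ProbeGeometry,
    RawScan,
    DEFAULT_SS_THRESHOLD_MM,
)

__all__ = [
    "RunConfig",
    "read_snirf",
    "write_snirf",
    "write_scan_csv",
    "read_scan_csv",
    "write_results",
]

logger = logging.getLogger(__name__)

_SNIRF_VERSION = "1.0"
_DT_AMPLITUDE = 1  # SNIRF dataType: CW amplitude
_DT_PROCESSED = 99999  # SNIRF dataType: processed (dataTypeLabel disambiguates)


@dataclass
class RunConfig:
    """Fully serialisable description of one run: probe, noise, simulation,
    pipeline grid and seeding.  A saved snapshot replays the run exactly."""

    probe: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    pipelines: list = field(default_factory=list)
    master_seed: int = 0
    n_iterations: int = 200
    output_dir: str = "results"

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})


class SnirfParseError(ValueError):
    """Malformed SNIRF file; message carries the offending group path."""


def _require(group, key, path):
    if key not in group:
        raise SnirfParseError(f"missing required SNIRF group/dataset: {path}/{key}")
    return group[key]


def write_snirf(
    path,
    scan,
    geometry: ProbeGeometry,
    stim: StimulusDesign | None = None,
):
    """Write a RawScan (CW amplitude) or HemoScan (processed HbO2/Hb) plus
    probe geometry and optional stimulus blocks to a SNIRF file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=_SNIRF_VERSION)
        nirs = f.create_group("nirs1")
        probe = nirs.create_group("probe")
        probe.create_dataset("sourcePos3D", data=geometry.sources)
        probe.create_dataset("detectorPos3D", data=geometry.detectors)
        probe.create_dataset("wavelengths", data=np.asarray(geometry.wavelengths))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")

        data = nirs.create_group("data1")
        if isinstance(scan, RawScan):
            n_time, n_ch, _ = scan.intensity.shape
            cols = scan.intensity.reshape(n_time, n_ch * 2, order="F")
            # column k*n_ch + c is channel c at wavelength k (Fortran order)
            data.create_dataset("dataTimeSeries", data=cols)
            data.create_dataset("time", data=np.arange(n_time) / scan.fs)
            idx = 1
            for wl_index in (1, 2):
                for ch in geometry.channels:
                    ml = data.create_group(f"measurementList{idx}")
                    ml.create_dataset("sourceIndex", data=ch.source + 1)
                    ml.create_dataset("detectorIndex", data=ch.detector + 1)
                    ml.create_dataset("wavelengthIndex", data=wl_index)
                    ml.create_dataset("dataType", data=_DT_AMPLITUDE)
                    idx += 1
        elif isinstance(scan, HemoScan):
            n_time, n_ch = scan.hbo.shape
            cols = np.hstack([scan.hbo, scan.hbr])
            data.create_dataset("dataTimeSeries", data=cols)
            data.create_dataset("time", data=np.arange(n_time) / scan.fs)
            idx = 1
            for label in ("HbO", "HbR"):
                for ch in geometry.channels:
                    ml = data.create_group(f"measurementList{idx}")
                    ml.create_dataset("sourceIndex", data=ch.source + 1)
                    ml.create_dataset("detectorIndex", data=ch.detector + 1)
                    ml.create_dataset("wavelengthIndex", data=1)
                    ml.create_dataset("dataType", data=_DT_PROCESSED)
                    ml.create_dataset("dataTypeLabel", data=label)
                    idx += 1
        else:
            raise TypeError("scan must be a RawScan or HemoScan")

        if stim is not None and len(stim.onsets):
            st = nirs.create_group("stim1")
            st.create_dataset("name", data=stim.condition)
            st.create_dataset(
                "data",
                data=np.column_stack(
                    [stim.onsets, stim.durations, np.ones(len(stim.onsets))]
                ),
            )
    logger.info("wrote SNIRF file %s", path)


def read_snirf(path, ss_threshold: float = DEFAULT_SS_THRESHOLD_MM):
    """Read a SNIRF file written by this package (or any conforming file
    using the same subset).

    Returns ``(scan, geometry, stim)`` where ``scan`` is a RawScan for CW
    amplitude data or a HemoScan for processed hemoglobin data, and ``stim``
    is None when no stimulus group is present.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        nirs = _require(f, "nirs1", "")
        probe = _require(nirs, "probe", "/nirs1")
        sources = np.asarray(_require(probe, "sourcePos3D", "/nirs1/probe"))
        detectors = np.asarray(_require(probe, "detectorPos3D", "/nirs1/probe"))
        wavelengths = tuple(np.asarray(_require(probe, "wavelengths", "/nirs1/probe")))
        data = _require(nirs, "data1", "/nirs1")
        ts = np.asarray(_require(data, "dataTimeSeries", "/nirs1/data1"))
        time = np.asarray(_require(data, "time", "/nirs1/data1"))
        if len(time) < 2:
            raise SnirfParseError("/nirs1/data1/time has fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(time)))

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if not ml_names:
            raise SnirfParseError("no measurementList groups under /nirs1/data1")
        entries = []
        for name in ml_names:
            g = data[name]
            entries.append(
                dict(
                    source=int(np.asarray(g["sourceIndex"])) - 1,
                    detector=int(np.asarray(g["detectorIndex"])) - 1,
                    wl=int(np.asarray(g["wavelengthIndex"])) - 1,
                    dtype=int(np.asarray(g["dataType"])),
                    label=(
                        g["dataTypeLabel"][()].decode()
                        if "dataTypeLabel" in g
                        else None
                    ),
                )
            )
        channels = []
        seen = set()
        for e in entries:
            key = (e["source"], e["detector"])
            if key not in seen:
                seen.add(key)
                channels.append(ChannelDef(*key))
        geometry = ProbeGeometry(
            sources=sources,
            detectors=detectors,
            channels=tuple(channels),
            wavelengths=wavelengths,
            ss_threshold=ss_threshold,
        )
        n_ch = len(channels)
        ch_index = {(c.source, c.detector): i for i, c in enumerate(channels)}

        processed = any(e["dtype"] == _DT_PROCESSED for e in entries)
        if processed:
            hbo = np.zeros((len(time), n_ch))
            hbr = np.zeros((len(time), n_ch))
            for col, e in enumerate(entries):
                target = hbo if e["label"] == "HbO" else hbr
                target[:, ch_index[(e["source"], e["detector"])]] = ts[:, col]
            scan = HemoScan(hbo, hbr, fs=fs, provenance="raw",
                            channel_labels=geometry.channel_labels())
        else:
            intensity = np.zeros((len(time), n_ch, 2))
            for col, e in enumerate(entries):
                intensity[:, ch_index[(e["source"], e["detector"])], e["wl"]] = ts[:, col]
            scan = RawScan(intensity=intensity, fs=fs)

        stim = None
        if "stim1" in nirs:
            st = nirs["stim1"]
            arr = np.asarray(_require(st, "data", "/nirs1/stim1"))
            name = st["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            stim = StimulusDesign(onsets=arr[:, 0], durations=arr[:, 1], condition=name)
    return scan, geometry, stim


def write_scan_csv(path, scan: HemoScan):
    """CSV fallback: a time column plus one column per channel/chromophore,
    channel metadata carried by the header names."""
    labels = scan.channel_labels or [f"ch{i}" for i in range(scan.n_channels)]
    frame = pd.DataFrame({"time": np.arange(scan.n_time) / scan.fs})
    for i, lab in enumerate(labels):
        frame[f"{lab}:HbO2"] = scan.hbo[:, i]
        frame[f"{lab}:Hb"] = scan.hbr[:, i]
    frame.to_csv(path, index=False)


def read_scan_csv(path, fs: float | None = None) -> HemoScan:
    frame = pd.read_csv(path)
    if "time" not in frame.columns:
        raise ValueError("CSV scan must have a 'time' column")
    t = frame["time"].to_numpy()
    fs = fs or 1.0 / float(np.median(np.diff(t)))
    hbo_cols = [c for c in frame.columns if c.endswith(":HbO2")]
    hbr_cols = [c for c in frame.columns if c.endswith(":Hb")]
    labels = [c[: -len(":HbO2")] for c in hbo_cols]
    return HemoScan(
        frame[hbo_cols].to_numpy(),
        frame[hbr_cols].to_numpy(),
        fs=fs,
        channel_labels=labels,
    )


def _library_versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
        "h5py": h5py.__version__,
    }


def write_results(tables: dict, config: RunConfig, outdir) -> dict:
    """Write result tables as CSV plus a config snapshot and a run log.

    ``tables`` maps name -> DataFrame; an empty frame still produces a
    headers-only CSV.  Returns the mapping of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame in tables.items():
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        written[name] = p
    snap = outdir / "config_snapshot.yaml"
    config.to_yaml(snap)
    written["config_snapshot"] = snap
    log = outdir / "run_log.json"
    import datetime

    log.write_text(
        json.dumps(
            {
                "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
                "master_seed": config.master_seed,
                "n_iterations": config.n_iterations,
                "library_versions": _library_versions(),
                "tables": sorted(tables.keys()),
            },
            indent=2,
            sort_keys=True,
        )
    )
    written["run_log"] = log
    return written
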