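"""File formats, pipeline configuration and logging setup.

Recordings round-trip through a simple raw+sidecar dialect (float32
channel-major binary plus a JSON sidecar holding fs, channel labels and
events); BrainVision triplets can be written directly and BrainVision/EDF
files are read through MNE. Channel identity is by label and sample
indices are 0-based half-open throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .connectivity import BandDefinition, DEFAULT_BANDS
from .synthetic import SyntheticRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_config",
    "write_raw_sidecar",
    "write_brainvision",
    "read_recording",
    "setup_logging",
]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline parameters.

    Every default equals the study's printed value: four analysis bands,
    85th-percentile thresholding, 2000-replicate null ensembles,
    five-block behavioural units and ten-block task-EEG halves. The
    dialect switches select the percentile convention, whether graphs are
    built per segment or from segment-averaged coherence, and the random
    reference construction.
    """

    seed: int = 0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    percentile: float = 85.0
    null_reps: int = 2000
    unit_size_blocks: int = 5
    eeg_block_half_size: int = 10
    percentile_mode: str = "linear"
    averaging_mode: str = "per_segment"
    n_tapers: int = 3
    nw: float = 2.0
    simulation: dict = field(default_factory=dict)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Load a YAML config; missing keys fall back to the defaults."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if "bands" in raw:
        raw["bands"] = tuple(
            BandDefinition(
                b["name"], float(b["lo"]), float(b["hi"]),
                closed_high=bool(b.get("closed_high", True)),
            )
            for b in raw["bands"]
        )
    known = PipelineConfig.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# raw + sidecar


def write_raw_sidecar(recording, path_prefix) -> tuple[Path, Path]:
    """Write float32 channel-major binary plus a JSON sidecar.

    Round-trips bit-exactly with :func:`read_recording` for float32 data.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(recording.samples, dtype=np.float32)
    dat_path = prefix.with_suffix(".dat")
    data.tofile(dat_path)
    sidecar = {
        "fs": recording.fs,
        "channel_labels": list(recording.channel_labels),
        "n_channels": int(data.shape[0]),
        "n_samples": int(data.shape[1]),
        "dtype": "float32",
        "order": "channel_major",
        "events": [[int(s), str(c)] for s, c in recording.events],
        "provenance": getattr(recording, "provenance", {}),
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=1))
    return dat_path, json_path


def _read_raw_sidecar(path: Path) -> SyntheticRecording:
    prefix = path.with_suffix("")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".dat"), dtype=meta["dtype"])
    expected = meta["n_channels"] * meta["n_samples"]
    if data.size != expected:
        raise ValueError(
            f"truncated data file: {data.size} values, expected {expected}"
        )
    samples = data.reshape(meta["n_channels"], meta["n_samples"])
    return SyntheticRecording(
        samples=samples.astype(float),
        fs=float(meta["fs"]),
        channel_labels=list(meta["channel_labels"]),
        events=[(int(s), str(c)) for s, c in meta["events"]],
        provenance=meta.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# BrainVision


def write_brainvision(recording, path_prefix) -> tuple[Path, Path, Path]:
    """Write a minimal BrainVision triplet (.vhdr/.eeg/.vmrk).

    Data are multiplexed IEEE float32 in microvolt units; events become
    Stimulus markers. The triplet is readable by standard BrainVision
    readers.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vhdr, eeg, vmrk = (prefix.with_suffix(s) for s in (".vhdr", ".eeg", ".vmrk"))
    data = np.ascontiguousarray(recording.samples, dtype=np.float32)
    n_ch = data.shape[0]
    # multiplexed: interleave channels sample by sample
    data.T.tofile(eeg)

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / recording.fs:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(recording.channel_labels, start=1):
        header.append(f"Ch{i}={label},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    for k, (sample, code) in enumerate(recording.events, start=2):
        # BrainVision marker positions are 1-based
        markers.append(f"Mk{k}=Stimulus,{code},{sample + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")
    return vhdr, eeg, vmrk


def _read_mne(path: Path) -> SyntheticRecording:
    import mne

    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")
    data = raw.get_data(units="uV")
    events = []
    for ann in raw.annotations:
        sample = int(round(ann["onset"] * raw.info["sfreq"]))
        desc = ann["description"]
        code = desc.split("/")[-1].strip()
        if code.lower().startswith("new segment"):
            continue
        events.append((sample, code))
    events.sort(key=lambda e: e[0])
    return SyntheticRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
        provenance={"source": str(path)},
    )


def read_recording(path, fmt: str | None = None) -> SyntheticRecording:
    """Read a recording (raw+sidecar, BrainVision .vhdr or EDF).

    The format is inferred from the extension unless ``fmt`` is one of
    ``{"raw", "brainvision", "edf"}``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if fmt == "raw" or suffix in (".dat", ".json"):
        return _read_raw_sidecar(path)
    if fmt in ("brainvision", "edf") or suffix in (".vhdr", ".edf"):
        return _read_mne(path)
    raise ValueError(f"cannot infer recording format for {path}")
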