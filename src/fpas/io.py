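"""EEG containers, file formats and dataset manifests.

Recordings are channels x samples arrays in microvolts with a sampling
rate, channel labels, optional electrode positions and event markers.
Two on-disk formats are supported: EDF (written by a small built-in
writer, read back through MNE) and an internal raw format (float32
binary plus a JSON sidecar).  Positions and event markers always travel
in the JSON sidecar, since plain EDF carries neither.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MASTOID_NAMES = ("M1", "M2")


class FormatError(ValueError):
    """Malformed recording file."""


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    data : (n_channels, n_samples) array, microvolts
    rate : sampling rate, Hz
    channel_names : per-row labels; mastoids are named M1/M2
    positions : (n_channels, 3) electrode coordinates in meters, or None
    events : list of (sample_index, code) markers
    """

    data: np.ndarray
    rate: int
    channel_names: list[str]
    positions: np.ndarray | None = None
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names do not match data rows")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[0] != self.data.shape[0]:
                raise ValueError("positions do not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def scalp_picks(self) -> np.ndarray:
        """Indices of scalp (non-mastoid) channels."""
        return np.array([i for i, n in enumerate(self.channel_names)
                         if n not in MASTOID_NAMES])

    def mastoid_picks(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.channel_names)
                         if n in MASTOID_NAMES])

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.rate,
                            list(self.channel_names),
                            None if self.positions is None
                            else self.positions.copy(),
                            list(self.events))


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def biosemi128_layout() -> tuple[list[str], np.ndarray]:
    """128-channel BioSemi montage plus two mastoids.

    Scalp labels and 3-D positions come from MNE's bundled standard
    montage; mastoid electrodes are placed below and behind the ears.
    """
    import mne
    montage = mne.channels.make_standard_montage("biosemi128")
    pos = montage.get_positions()["ch_pos"]
    names = list(montage.ch_names)
    coords = np.array([pos[n] for n in names])
    names += list(MASTOID_NAMES)
    mastoids = np.array([[-0.082, -0.025, -0.045], [0.082, -0.025, -0.045]])
    return names, np.vstack([coords, mastoids])


# ---------------------------------------------------------------------------
# Internal raw + sidecar format
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, rec: EEGRecording) -> None:
    meta = {
        "rate": rec.rate,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "unit": "uV",
        "channel_names": rec.channel_names,
        "positions": None if rec.positions is None
        else rec.positions.tolist(),
        "events": [[int(s), int(c)] for s, c in rec.events],
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def save_raw(rec: EEGRecording, path: str | Path) -> None:
    """Write the internal format: float32 binary + JSON sidecar."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    _write_sidecar(path, rec)


def _load_raw(path: Path) -> EEGRecording:
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"{path}: missing sidecar {side.name}")
    meta = json.loads(side.read_text())
    data = np.fromfile(path, dtype="<f4")
    n_ch, n_s = meta["n_channels"], meta["n_samples"]
    if data.size != n_ch * n_s:
        raise FormatError(
            f"{path}: expected {n_ch * n_s} samples, found {data.size} "
            f"(offset {data.size * 4} bytes)")
    return EEGRecording(
        data.reshape(n_ch, n_s).astype(float), int(meta["rate"]),
        list(meta["channel_names"]),
        None if meta.get("positions") is None
        else np.asarray(meta["positions"], dtype=float),
        [tuple(e) for e in meta.get("events", [])])


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def save_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write an EDF file (16-bit, 1 s data records).

    Physical ranges are set per channel from the data; a trailing partial
    record is zero-padded (the sidecar records the true sample count so
    loading trims the padding).  Positions and events go to the sidecar.
    """
    path = Path(path)
    data = rec.data
    n_ch = rec.n_channels
    spr = rec.rate                       # samples per 1 s record
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :rec.n_samples] = data

    pmin = np.minimum(padded.min(axis=1), -1.0)
    pmax = np.maximum(padded.max(axis=1), 1.0)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin[:, None]) * scale[:, None]
                       + dmin).astype("<i2")

    def pad(text: str, n: int) -> bytes:
        return text[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = [
        b"".join(pad(n, 16) for n in rec.channel_names),
        b"".join(pad("EEG", 80) for _ in range(n_ch)),
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{v:.6g}", 8) for v in pmin),
        b"".join(pad(f"{v:.6g}", 8) for v in pmax),
        b"".join(pad(str(dmin), 8) for _ in range(n_ch)),
        b"".join(pad(str(dmax), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        # records are channel-major within each record
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    _write_sidecar(path, rec)


def _load_edf(path: Path) -> EEGRecording:
    import mne
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" \
        else mne.io.read_raw_edf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:                     # pragma: no cover
        raise FormatError(f"{path}: {exc}") from exc
    data = raw.get_data() * 1e6                  # MNE works in volts
    names = list(raw.ch_names)
    rate = int(round(raw.info["sfreq"]))
    positions = None
    events: list[tuple[int, int]] = []
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        data = data[:, :meta["n_samples"]]
        if meta.get("positions") is not None:
            positions = np.asarray(meta["positions"], dtype=float)
        events = [tuple(e) for e in meta.get("events", [])]
    return EEGRecording(data, rate, names, positions, events)


def load_recording(path: str | Path) -> EEGRecording:
    """Load an EDF/BDF or internal raw+sidecar recording (data in uV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".edf", ".bdf"):
        return _load_edf(path)
    return _load_raw(path)


def save_recording(rec: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        save_edf(rec, path)
    else:
        save_raw(rec, path)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["path", "participant", "condition", "type", "trial",
                    "seed"]


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a dataset manifest.

    Paths must exist (relative paths resolve against the manifest's
    directory) and (participant, condition, type, trial) must be unique.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest misses columns {missing}")
    base = path.parent
    resolved = [str(p) if Path(p).is_absolute() else str(base / p)
                for p in df["path"]]
    for p in resolved:
        if not Path(p).exists():
            raise FormatError(f"{path}: listed file not found: {p}")
    df = df.assign(path=resolved)
    keys = df[["participant", "condition", "type", "trial"]]
    if keys.duplicated().any():
        raise FormatError(f"{path}: duplicate (participant, condition, "
                          f"type, trial) rows")
    return df
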