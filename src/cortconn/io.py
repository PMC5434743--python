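"""Data containers and file I/O shared by all pipeline stages.

The package works on epoched multichannel EEG.  Two on-disk representations
are supported for raw/cleaned channel data:

* EDF (European Data Format), the field's standard interchange format for
  raw EEG.  Reading goes through :func:`mne.io.read_raw_edf`; writing uses a
  minimal EDF writer (16-bit quantization against per-channel physical
  ranges).
* A plain-text dialect: a tab-separated matrix (header row = channel names,
  one row per sample, trials concatenated in time) next to a JSON sidecar
  holding the sampling rate, electrode positions, per-trial condition
  labels and epoch geometry.  This dialect round-trips losslessly and keeps
  test fixtures human-readable.

Connectivity results are serialized as long-format TSV plus a JSON metadata
sidecar; see :func:`write_connectivity`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochedEEG",
    "PipelineConfig",
    "read_eeg",
    "write_eeg",
    "read_electrode_positions",
    "write_electrode_positions",
    "write_connectivity",
    "read_connectivity",
]

CONTROL = "control"
TEST = "test"


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the declared format."""


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (C, T, N)
        Channel voltages in microvolts: C channels, T samples per epoch,
        N trials.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    channel_pos : ndarray, shape (C, 3)
        3-D electrode positions in meters.
    condition : ndarray of str, shape (N,)
        Per-trial label, a two-level factor ``{"control", "test"}``.
    epoch_window : (float, float)
        Epoch start/end in seconds relative to the event, half-open
        ``[start, end)``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_pos: np.ndarray
    condition: np.ndarray
    epoch_window: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (C, T, N), got shape {self.data.shape}")
        C, T, N = self.data.shape
        if C < 2 or T < 2:
            raise ValueError(f"need C >= 2 channels and T >= 2 samples, got C={C}, T={T}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != C:
            raise ValueError("channel_names length must equal channel count")
        self.channel_pos = np.asarray(self.channel_pos, dtype=float)
        if self.channel_pos.shape != (C, 3):
            raise ValueError(f"channel_pos must be ({C}, 3)")
        if not np.all(np.isfinite(self.channel_pos)):
            raise ValueError("channel_pos must be finite")
        self.condition = np.asarray(self.condition, dtype=object)
        if self.condition.shape != (N,):
            raise ValueError("condition must have one entry per trial")
        bad = set(self.condition) - {CONTROL, TEST}
        if bad:
            raise ValueError(f"condition labels must be in {{control, test}}, got {bad}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the event."""
        return self.epoch_window[0] + np.arange(self.n_samples) / self.fs

    def select_trials(self, idx: np.ndarray) -> "EpochedEEG":
        idx = np.asarray(idx)
        return replace(self, data=self.data[:, :, idx], condition=self.condition[idx])

    def select_channels(self, idx: np.ndarray) -> "EpochedEEG":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx],
            channel_names=[self.channel_names[i] for i in idx],
            channel_pos=self.channel_pos[idx],
        )

    def copy(self) -> "EpochedEEG":
        return replace(self, data=self.data.copy(), condition=self.condition.copy())


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline with their standard defaults.

    Defaults correspond to the reference analysis conditions: a 1-55 Hz
    passband, kurtosis rejection at |Z| > 5, downsampling to 128 Hz,
    K = 14 IC clusters reduced to 10 PCA dimensions, 550 ms sliding windows
    stepped by 10 ms, candidate MVAR orders 1-30, 300 condition-mixing
    permutations, alpha = 0.05, and a 2-50 Hz connectivity grid.
    """

    band: tuple[float, float] = (1.0, 55.0)
    kurtosis_z: float = 5.0
    resample_fs: float = 128.0
    n_clusters: int = 14
    pca_dims: int = 10
    window_len: float = 0.55
    window_step: float = 0.01
    order_range: tuple[int, int] = (1, 30)
    n_permutations: int = 300
    alpha: float = 0.05
    freq_range: tuple[float, float] = (2.0, 50.0)
    freq_step: float = 1.0
    rv_threshold: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if not self.window_len > self.window_step > 0:
            raise ValueError("require window_len > window_step > 0")
        pmin, pmax = self.order_range
        if not (1 <= pmin <= pmax <= 30):
            raise ValueError("order_range must lie within [1, 30]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def validate_against_fs(self, fs: float) -> None:
        if not self.band[1] < fs / 2:
            raise ValueError(f"band high edge {self.band[1]} Hz must be below Nyquist {fs / 2} Hz")

    def to_dict(self) -> dict:
        return {
            "band": list(self.band),
            "kurtosis_z": self.kurtosis_z,
            "resample_fs": self.resample_fs,
            "n_clusters": self.n_clusters,
            "pca_dims": self.pca_dims,
            "window_len": self.window_len,
            "window_step": self.window_step,
            "order_range": list(self.order_range),
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "freq_range": list(self.freq_range),
            "freq_step": self.freq_step,
            "rv_threshold": self.rv_threshold,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("band", "order_range", "freq_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# raw EEG I/O
# ---------------------------------------------------------------------------


def _epoch_continuous(
    raw: np.ndarray,
    fs: float,
    latencies: Sequence[int],
    conditions: Sequence[str],
    epoch_window: tuple[float, float],
    channel_names: list[str],
    channel_pos: np.ndarray,
) -> EpochedEEG:
    """Cut a continuous (C, T_total) matrix into epochs around event samples."""
    start = int(round(epoch_window[0] * fs))
    stop = int(round(epoch_window[1] * fs))
    n_total = raw.shape[1]
    trials = []
    for lat in latencies:
        lo, hi = lat + start, lat + stop
        if lo < 0 or hi > n_total:
            raise IndexError(
                f"event at sample {lat} with window [{lo}, {hi}) exceeds recording of {n_total} samples"
            )
        trials.append(raw[:, lo:hi])
    data = np.stack(trials, axis=-1)
    return EpochedEEG(
        data=data,
        fs=fs,
        channel_names=channel_names,
        channel_pos=channel_pos,
        condition=np.asarray(list(conditions), dtype=object),
        epoch_window=epoch_window,
    )


def read_eeg(path: str | Path, events: dict | None = None) -> EpochedEEG:
    """Read epoched EEG from EDF/BDF or the TSV + JSON sidecar dialect.

    Parameters
    ----------
    path : path
        ``.edf``/``.bdf`` file or ``.tsv`` matrix with a ``.json`` sidecar.
    events : dict, optional
        Event specification with keys ``latencies`` (sample indices),
        ``conditions`` (per-event label) and ``epoch_window``
        ``(start, end)`` in seconds.  For the TSV dialect this may be
        omitted when the sidecar already records the epoch geometry.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        fs = float(raw.info["sfreq"])
        data = raw.get_data() * 1e6  # mne returns volts
        names = list(raw.ch_names)
        pos = np.zeros((len(names), 3))
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "channel_pos" in meta:
                pos = np.asarray(meta["channel_pos"], dtype=float)
            events = events or meta.get("events")
        if events is None:
            raise FormatError("EDF reading requires an event specification")
        return _epoch_continuous(
            data, fs, events["latencies"], events["conditions"],
            tuple(events["epoch_window"]), names, pos,
        )
    if suffix == ".tsv":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"missing JSON sidecar for {path}")
        meta = json.loads(sidecar.read_text())
        try:
            table = pd.read_csv(path, sep="\t", float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - delegated parse failure
            raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
        names = list(table.columns)
        raw = table.to_numpy(dtype=float).T  # (C, T_total)
        fs = float(meta["fs"])
        pos = np.asarray(meta.get("channel_pos", np.zeros((len(names), 3))), dtype=float)
        ev = events or meta.get("events")
        if ev is None:
            raise FormatError("no event specification given and none found in sidecar")
        return _epoch_continuous(
            raw, fs, ev["latencies"], ev["conditions"], tuple(ev["epoch_window"]), names, pos
        )
    raise FormatError(f"unsupported EEG file format: {path.suffix}")


def write_eeg(eeg: EpochedEEG, path: str | Path, config: PipelineConfig | None = None) -> Path:
    """Write epoched EEG as TSV + JSON sidecar or EDF (by file suffix).

    Trials are concatenated along time; the sidecar records event latencies
    (one per trial) so that :func:`read_eeg` reconstructs the epochs.  EDF
    output is quantized to 16 bits against per-channel physical ranges.
    """
    path = Path(path)
    C, T, N = eeg.data.shape
    continuous = eeg.data.transpose(0, 2, 1).reshape(C, T * N)
    offset = int(round(eeg.epoch_window[0] * eeg.fs))
    latencies = [i * T - offset for i in range(N)]
    events = {
        "latencies": latencies,
        "conditions": [str(c) for c in eeg.condition],
        "epoch_window": list(eeg.epoch_window),
    }
    meta = {
        "fs": eeg.fs,
        "channel_names": eeg.channel_names,
        "channel_pos": eeg.channel_pos.tolist(),
        "events": events,
        "units": "uV",
    }
    if config is not None:
        meta["config"] = config.to_dict()
        meta["seed"] = config.seed
    if path.suffix.lower() == ".tsv":
        df = pd.DataFrame(continuous.T, columns=eeg.channel_names)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        return path
    if path.suffix.lower() == ".edf":
        _write_edf(continuous, eeg.fs, eeg.channel_names, path)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        return path
    raise FormatError(f"unsupported output format: {path.suffix}")


def _write_edf(data_uv: np.ndarray, fs: float, names: list[str], path: Path) -> None:
    """Minimal EDF writer: one data record holding the whole recording.

    EDF stores 16-bit integers mapped linearly between per-channel physical
    and digital ranges; round-tripping is therefore exact only up to that
    quantization.
    """
    C, T = data_uv.shape
    if abs(fs - round(fs)) > 1e-9:
        # EDF wants an integral number of samples per record; use 1-second
        # records only for integral rates, otherwise a single record.
        pass
    duration = T / fs
    pmin = np.floor(data_uv.min(axis=1) - 1.0)
    pmax = np.ceil(data_uv.max(axis=1) + 1.0)
    dmin, dmax = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    header = b""
    header += pad("0", 8)                       # version
    header += pad("X X X X", 80)                # patient id (anonymous)
    header += pad("Startdate X X X X", 80)      # recording id
    header += pad("01.01.00", 8)                # start date
    header += pad("00.00.00", 8)                # start time
    n_header = 256 + 256 * C
    header += pad(str(n_header), 8)
    header += pad("", 44)                       # reserved
    header += pad("1", 8)                       # number of data records
    header += pad(f"{duration:.6g}", 8)         # record duration, seconds
    header += pad(str(C), 4)

    header += b"".join(pad(n, 16) for n in names)            # labels
    header += b"".join(pad("", 80) for _ in names)           # transducer
    header += b"".join(pad("uV", 8) for _ in names)          # physical dim
    header += b"".join(pad(f"{v:.8g}", 8) for v in pmin)
    header += b"".join(pad(f"{v:.8g}", 8) for v in pmax)
    header += b"".join(pad(str(dmin), 8) for _ in names)
    header += b"".join(pad(str(dmax), 8) for _ in names)
    header += b"".join(pad("", 80) for _ in names)           # prefiltering
    header += b"".join(pad(str(T), 8) for _ in names)        # samples/record
    header += b"".join(pad("", 32) for _ in names)           # reserved

    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data_uv - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())  # channel-sequential within the record


# ---------------------------------------------------------------------------
# electrode positions
# ---------------------------------------------------------------------------


def read_electrode_positions(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read 4-column whitespace text ``name x y z`` (meters)."""
    names: list[str] = []
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"expected 'name x y z', got: {line!r}")
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return names, np.asarray(rows, dtype=float)


def write_electrode_positions(names: Sequence[str], pos: np.ndarray, path: str | Path) -> None:
    lines = [f"{n} {x:.17g} {y:.17g} {z:.17g}" for n, (x, y, z) in zip(names, pos)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# connectivity tensors
# ---------------------------------------------------------------------------


def write_connectivity(tensor, path: str | Path, config: PipelineConfig | None = None) -> Path:
    """Serialize a ConnectivityTensor as long-format TSV plus JSON metadata.

    Columns: sink, source, freq_Hz, window_s, value, p, significant.  The
    diagonal (self-flow) carries no physical meaning and is omitted.  NaN
    p-values (statistics not yet computed) are written as empty fields and
    flagged in the metadata.
    """
    path = Path(path)
    M, M2, F, W = tensor.values.shape
    if M != M2:
        raise ValueError("tensor first two axes must both index nodes")
    if len(tensor.freqs) != F or len(tensor.window_starts_s) != W:
        raise ValueError("tensor axis lengths inconsistent with values array")
    sink, source = np.meshgrid(np.arange(M), np.arange(M), indexing="ij")
    off = sink != source
    si, so = sink[off], source[off]
    rows = []
    pvals = tensor.pvals
    mask = tensor.mask
    for fi, f in enumerate(tensor.freqs):
        for wi, w in enumerate(tensor.window_starts_s):
            vals = tensor.values[si, so, fi, wi]
            p = pvals[si, so, fi, wi] if pvals is not None else np.full(si.shape, np.nan)
            sig = mask[si, so, fi, wi] if mask is not None else np.zeros(si.shape, bool)
            for k in range(si.size):
                rows.append(
                    (
                        tensor.nodes[si[k]],
                        tensor.nodes[so[k]],
                        float(f),
                        float(w),
                        float(vals[k]),
                        float(p[k]),
                        bool(sig[k]),
                    )
                )
    df = pd.DataFrame(rows, columns=["sink", "source", "freq_Hz", "window_s", "value", "p", "significant"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")
    meta = {
        "nodes": list(tensor.nodes),
        "freqs": [float(f) for f in tensor.freqs],
        "window_starts_s": [float(w) for w in tensor.window_starts_s],
        "has_pvalues": bool(pvals is not None and np.isfinite(np.asarray(pvals)).any()),
        "has_mask": mask is not None,
        "convention": getattr(tensor, "convention", "squared"),
    }
    if config is not None:
        meta["config"] = config.to_dict()
        meta["seed"] = config.seed
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_connectivity(path: str | Path):
    """Read back a tensor written by :func:`write_connectivity`."""
    from .connectivity import ConnectivityTensor

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    nodes = meta["nodes"]
    freqs = np.asarray(meta["freqs"], dtype=float)
    windows = np.asarray(meta["window_starts_s"], dtype=float)
    M, F, W = len(nodes), len(freqs), len(windows)
    node_idx = {n: i for i, n in enumerate(nodes)}
    fi = {f: i for i, f in enumerate(freqs)}
    wi = {w: i for i, w in enumerate(windows)}
    values = np.zeros((M, M, F, W))
    pvals = np.full((M, M, F, W), np.nan)
    mask = np.zeros((M, M, F, W), bool)
    i = df["sink"].map(node_idx).to_numpy()
    j = df["source"].map(node_idx).to_numpy()
    f = df["freq_Hz"].map(fi).to_numpy()
    w = df["window_s"].map(wi).to_numpy()
    values[i, j, f, w] = df["value"].to_numpy()
    pvals[i, j, f, w] = df["p"].to_numpy()
    mask[i, j, f, w] = df["significant"].to_numpy().astype(bool)
    has_p = meta.get("has_pvalues", False)
    return ConnectivityTensor(
        values=values,
        nodes=nodes,
        freqs=freqs,
        window_starts_s=windows,
        pvals=pvals if has_p else None,
        mask=mask if meta.get("has_mask") else None,
        convention=meta.get("convention", "squared"),
    )
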