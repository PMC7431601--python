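"""EEG containers, band-pass filtering, marker alignment and epoching.

Amplitudes are microvolts throughout, times are seconds, and sample indexing
is 0-based with half-open ``[start, stop)`` windows. Marker timestamps live in
seconds relative to the start of the recording; conversion to samples happens
only at epoch-cutting time, so recordings can be filtered, sliced and saved
without touching the marker stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "MarkerStream",
    "EEGRecording",
    "EpochSet",
    "bandpass",
    "cut_epochs",
    "read_eeg_csv",
    "write_eeg_csv",
    "read_markers_tsv",
    "write_markers_tsv",
    "read_brainvision",
    "write_brainvision",
    "save_epochs",
    "load_epochs",
]


@dataclass(frozen=True)
class MarkerStream:
    """Timestamped event codes attached to a recording.

    ``times`` are onset timestamps in seconds; ``codes`` are small integers
    (the oddball generator uses 1 = standard, 2 = target, 3 = deviant; flight
    sessions use 100 + event index).
    """

    times: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        codes = np.asarray(self.codes, dtype=int)
        if times.shape != codes.shape or times.ndim != 1:
            raise ParameterError("marker times and codes must be 1-D and equal length")
        if np.any(np.diff(times) < 0):
            raise ParameterError("marker times must be non-decreasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return self.times.size

    def shifted(self, lag_s: float) -> "MarkerStream":
        """Return a copy with all timestamps shifted by ``lag_s`` seconds."""
        return MarkerStream(self.times + lag_s, self.codes.copy())


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    markers: MarkerStream
    reference: str = "FCz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_labels):
            raise ParameterError(
                f"{self.data.shape[0]} channels but {len(self.channel_labels)} labels"
            )
        if self.fs_hz <= 0:
            raise ParameterError("sampling rate must be positive")
        if len(self.markers) and (
            self.markers.times[0] < 0 or self.markers.times[-1] > self.duration_s
        ):
            raise ParameterError("markers must lie within [0, duration]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class EpochSet:
    """Trials cut around marker onsets: ``epochs`` is trial x channel x sample."""

    epochs: np.ndarray
    window: tuple[float, float]
    labels: np.ndarray
    fs_hz: float
    onsets_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    channel_labels: list[str] | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ParameterError("epochs must be trial x channel x sample")
        if self.window[0] >= self.window[1]:
            raise ParameterError("epoch window must satisfy t_min < t_max")
        if self.labels.shape[0] != self.epochs.shape[0]:
            raise ParameterError("one label per trial required")
        if self.onsets_s is None:
            self.onsets_s = np.full(self.epochs.shape[0], np.nan)

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.epochs[mask],
            self.window,
            self.labels[mask],
            self.fs_hz,
            self.onsets_s[mask],
            self.channel_labels,
            self.n_dropped,
        )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def bandpass(
    rec: EEGRecording, low_hz: float = 0.3, high_hz: float = 20.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass filter (forward-backward).

    The defaults (0.3-20 Hz) retain slow ERP components such as the P300 while
    suppressing drift and line-frequency content. Zero-phase filtering
    preserves component latencies, on which the downstream windowed-means
    features depend. The marker stream is passed through untouched.
    """
    nyq = rec.fs_hz / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def cut_epochs(
    rec: EEGRecording,
    window: tuple[float, float] = (-0.2, 0.8),
    label_map: dict[int, object] | None = None,
    lag_correction_s: float = 0.0,
    baseline: tuple[float, float] | None = None,
) -> EpochSet:
    """Cut one epoch per marker whose window fits inside the recording.

    Parameters
    ----------
    window
        (t_min, t_max) in seconds relative to marker onset; sample extraction
        is half-open ``[round((t + t_min) * fs), round((t + t_min) * fs) + n)``.
    label_map
        Maps marker codes to trial labels. Markers with codes absent from the
        map are silently excluded (this is how deviant tones are dropped for
        the binary standard/target problem). ``None`` keeps raw codes.
    lag_correction_s
        Added to every marker time before epoching, for recordings whose
        stimulus pipeline lag is declared. Default 0: an undeclared lag is
        instead absorbed by starting feature windows late.
    baseline
        Optional (t0, t1) interval whose per-channel mean is subtracted from
        each epoch. Off by default: the classifier operates on the band-pass
        filtered signal directly.

    Markers whose window would cross a record edge are dropped and counted in
    ``n_dropped``.
    """
    t_min, t_max = window
    if t_min >= t_max:
        raise ParameterError("epoch window must satisfy t_min < t_max")
    fs = rec.fs_hz
    n_samp = int(round((t_max - t_min) * fs))
    if n_samp < 1:
        raise ParameterError("epoch window shorter than one sample")

    epochs, labels, onsets = [], [], []
    n_dropped = 0
    for t, code in zip(rec.markers.times, rec.markers.codes):
        if label_map is not None and int(code) not in label_map:
            continue
        onset = t + lag_correction_s
        start = int(round((onset + t_min) * fs))
        if start < 0 or start + n_samp > rec.n_samples:
            n_dropped += 1
            continue
        epochs.append(rec.data[:, start : start + n_samp])
        labels.append(label_map[int(code)] if label_map is not None else int(code))
        onsets.append(onset)

    arr = (
        np.stack(epochs)
        if epochs
        else np.empty((0, rec.n_channels, n_samp))
    )
    out = EpochSet(
        arr,
        window,
        np.asarray(labels),
        fs,
        np.asarray(onsets, dtype=float),
        list(rec.channel_labels),
        n_dropped,
    )
    if baseline is not None:
        b0, b1 = baseline
        i0 = int(round((b0 - t_min) * fs))
        i1 = int(round((b1 - t_min) * fs))
        if not (0 <= i0 < i1 <= n_samp):
            raise ConfigurationError("baseline interval must lie inside the epoch window")
        out.epochs = out.epochs - out.epochs[:, :, i0:i1].mean(axis=2, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# I/O: CSV, marker TSV, BrainVision, epoch container
# ---------------------------------------------------------------------------

def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write as CSV with a ``time_s`` column followed by one column per channel."""
    t = np.arange(rec.n_samples) / rec.fs_hz
    df = pd.DataFrame({"time_s": t})
    for i, label in enumerate(rec.channel_labels):
        df[label] = rec.data[i]
    df.to_csv(path, index=False, float_format="%.6f")


def read_eeg_csv(path: str | Path, markers: MarkerStream | None = None) -> EEGRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ConfigurationError("EEG CSV must contain a time_s column")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ConfigurationError("EEG CSV must contain at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    labels = [c for c in df.columns if c != "time_s"]
    data = df[labels].to_numpy().T
    if markers is None:
        markers = MarkerStream(np.empty(0), np.empty(0, dtype=int))
    return EEGRecording(data, fs, labels, markers)


def write_markers_tsv(markers: MarkerStream, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("timestamp_s\tcode\n")
        for t, c in zip(markers.times, markers.codes):
            fh.write(f"{t:.6f}\t{int(c)}\n")


def read_markers_tsv(path: str | Path) -> MarkerStream:
    df = pd.read_csv(path, sep="\t")
    return MarkerStream(df["timestamp_s"].to_numpy(float), df["code"].to_numpy(int))


def write_brainvision(rec: EEGRecording, basename: str | Path) -> None:
    """Write a BrainVision triplet (.vhdr / .vmrk / .eeg, IEEE float32).

    Data are stored multiplexed in microvolts with unit resolution.
    """
    base = Path(basename)
    stem = base.name
    vhdr, vmrk, eeg = base.with_suffix(".vhdr"), base.with_suffix(".vmrk"), base.with_suffix(".eeg")

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.fs_hz:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={label},{rec.reference},1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for k, (t, c) in enumerate(zip(rec.markers.times, rec.markers.codes), start=2):
        pos = int(round(t * rec.fs_hz)) + 1  # BrainVision positions are 1-based
        mlines.append(f"Mk{k}=Stimulus,S{int(c):3d},{pos},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)


def read_brainvision(vhdr_path: str | Path) -> EEGRecording:
    """Read a BrainVision triplet via MNE; amplitudes converted back to microvolts."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6
    times, codes = [], []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("Stimulus"):
            times.append(float(ann["onset"]))
            codes.append(int(desc.split("/S")[-1]))
    order = np.argsort(times) if times else []
    markers = MarkerStream(
        np.asarray(times, dtype=float)[order] if times else np.empty(0),
        np.asarray(codes, dtype=int)[order] if codes else np.empty(0, dtype=int),
    )
    return EEGRecording(data, raw.info["sfreq"], list(raw.ch_names), markers)


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Save as a compressed .npz plus a JSON sidecar with labels and metadata."""
    path = Path(path)
    np.savez_compressed(path, epochs=epochs.epochs)
    sidecar = {
        "window": list(epochs.window),
        "fs_hz": epochs.fs_hz,
        "labels": np.asarray(epochs.labels).tolist(),
        "onsets_s": epochs.onsets_s.tolist(),
        "channel_labels": epochs.channel_labels,
        "n_dropped": epochs.n_dropped,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arr = np.load(path)["epochs"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        arr,
        tuple(meta["window"]),
        np.asarray(meta["labels"]),
        meta["fs_hz"],
        np.asarray(meta["onsets_s"], dtype=float),
        meta["channel_labels"],
        meta["n_dropped"],
    )
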