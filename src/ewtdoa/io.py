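"""Recording I/O, band-pass pre-filtering and overlapping window segmentation.

An :class:`EEGRecording` bundles a single-channel EEG trace with its aligned
1 Hz tracks: the reference depth index (BIS-like, 0-100), an optional signal
quality index (SQI), optional anaesthetic-state annotations, and — for
synthetic data — the ground-truth depth trace.  The 1 Hz convention is that
track element ``k`` is the value reported at the end of second ``k + 1``, so
the value paired with a window ending at ``t_end`` is element ``t_end - 1``.

Files are read from EDF (via :mod:`mne`, if installed) or a plain CSV with a
header row of channel names and one row per sample.  Aligned tracks live in
sidecar CSVs (``<stem>.ref.csv``, ``<stem>.sqi.csv`` with columns
``time_s,value``; ``<stem>.states.csv`` with ``t_start,t_end,state``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EEGRecording",
    "Window",
    "read_recording",
    "write_recording",
    "bandpass_filter",
    "segment_windows",
]

logger = logging.getLogger(__name__)

STATES = ("DA", "MA", "LA", "AW")  # deepest to shallowest


@dataclass
class EEGRecording:
    """Single-channel EEG with aligned 1 Hz tracks.

    Parameters
    ----------
    samples : ndarray
        EEG voltage trace (uV scale).
    fs : float
        Sampling rate in Hz (128 for the recordings this pipeline targets).
    start_time : float
        Offset of the first sample, in seconds.
    ref_index : ndarray, optional
        Reference depth index at 1 Hz on [0, 100].
    sqi : ndarray, optional
        Signal quality index at 1 Hz on [0, 100].
    state_annotations : list of (t_start, t_end, state), optional
        Non-overlapping stable-state intervals; state in {AW, LA, MA, DA}.
    true_depth : ndarray, optional
        Ground-truth depth trace at 1 Hz — populated by the synthetic
        generator only; clinical recordings have no observable truth.
    """

    samples: np.ndarray
    fs: float = 128.0
    start_time: float = 0.0
    ref_index: np.ndarray | None = None
    sqi: np.ndarray | None = None
    state_annotations: list[tuple[float, float, str]] | None = None
    channel_label: str = ""
    true_depth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("ref_index", "sqi", "true_depth"):
            track = getattr(self, name)
            if track is None:
                continue
            track = np.asarray(track, dtype=float)
            setattr(self, name, track)
            if len(track) > int(len(self.samples) / self.fs) + 1:
                raise ValueError(
                    f"{name} has {len(track)} values for a "
                    f"{self.duration_s:.1f} s recording"
                )
        if self.ref_index is not None:
            finite = self.ref_index[np.isfinite(self.ref_index)]
            if finite.size and (finite.min() < 0 or finite.max() > 100):
                raise ValueError("ref_index values must lie in [0, 100]")
        if self.state_annotations:
            ann = sorted(self.state_annotations)
            for (a0, a1, s), (b0, _, _) in zip(ann, ann[1:]):
                if a1 > b0:
                    raise ValueError("state annotation intervals overlap")
            for _, _, s in ann:
                if s not in STATES:
                    raise ValueError(f"unknown state {s!r}; expected one of {STATES}")
            self.state_annotations = ann

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class Window:
    """One analysis window; its feature/index value is stamped at ``t_end``."""

    samples: np.ndarray
    t_end: float


def _read_track(path: Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["value"].to_numpy(dtype=float)


def _read_annotations(path: Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    return [
        (float(r.t_start), float(r.t_end), str(r.state)) for r in df.itertuples()
    ]


def read_recording(
    path: str | Path,
    channel: str | None = None,
    fmt: str | None = None,
    fs: float = 128.0,
) -> EEGRecording:
    """Read an EEG recording from EDF or CSV, with any sidecar tracks.

    For CSV the sampling rate must be supplied (``fs``); for EDF it comes
    from the header.  ``channel`` selects a column (CSV header name / EDF
    channel label); by default the first channel is used.  Sidecar files
    ``<stem>.ref.csv``, ``<stem>.sqi.csv``, ``<stem>.states.csv`` and
    ``<stem>.depth.csv`` are loaded when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"

    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        names = list(raw.ch_names)
        if channel is None:
            channel = names[0]
        if channel not in names:
            raise KeyError(
                f"channel {channel!r} not in file; available channels: {names}"
            )
        samples = raw.get_data(picks=[channel])[0] * 1e6  # V -> uV
        fs = float(raw.info["sfreq"])
    elif fmt == "csv":
        df = pd.read_csv(path)
        names = list(df.columns)
        if channel is None:
            channel = names[0]
        if channel not in names:
            raise KeyError(
                f"channel {channel!r} not in file; available channels: {names}"
            )
        samples = df[channel].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")

    kwargs: dict = {}
    stem = path.with_suffix("")
    for name, attr, reader in (
        ("ref", "ref_index", _read_track),
        ("sqi", "sqi", _read_track),
        ("depth", "true_depth", _read_track),
        ("states", "state_annotations", _read_annotations),
    ):
        side = stem.with_suffix(f".{name}.csv")
        if side.exists():
            kwargs[attr] = reader(side)

    rec = EEGRecording(
        samples=samples, fs=fs, channel_label=str(channel), **kwargs
    )
    for name in ("ref_index", "sqi"):
        track = getattr(rec, name)
        if track is not None:
            if abs(len(track) - rec.duration_s) > 1.0:
                raise ValueError(
                    f"{name} length {len(track)} s does not match the "
                    f"{rec.duration_s:.1f} s recording (tolerance 1 s)"
                )
    return rec


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording and its tracks as CSV (+ sidecars); returns the path."""
    path = Path(path)
    label = rec.channel_label or "Ch1"
    pd.DataFrame({label: rec.samples}).to_csv(path, index=False)
    stem = path.with_suffix("")
    for name, track in (
        ("ref", rec.ref_index),
        ("sqi", rec.sqi),
        ("depth", rec.true_depth),
    ):
        if track is not None:
            pd.DataFrame(
                {"time_s": np.arange(1, len(track) + 1), "value": track}
            ).to_csv(stem.with_suffix(f".{name}.csv"), index=False)
    if rec.state_annotations:
        pd.DataFrame(
            rec.state_annotations, columns=["t_start", "t_end", "state"]
        ).to_csv(stem.with_suffix(".states.csv"), index=False)
    return path


def bandpass_filter(
    rec: EEGRecording, lo: float = 0.1, hi: float = 64.0
) -> EEGRecording:
    """Zero-phase Butterworth band-pass; returns a filtered copy.

    A 4th-order design applied forward-backward (no phase distortion, no
    group delay ahead of windowing).  When ``hi`` reaches the Nyquist
    frequency the band-pass degenerates to the 0.1 Hz high-pass alone — at
    fs = 128 the nominal 0.1-64 Hz band keeps everything below Nyquist, so
    only the high-pass edge is realisable.
    """
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    nyq = rec.fs / 2.0
    if hi >= nyq:
        logger.warning(
            "upper band edge %.3g Hz >= Nyquist %.3g Hz; applying the "
            "%.3g Hz high-pass only",
            hi,
            nyq,
            lo,
        )
        sos = signal.butter(4, lo, btype="highpass", fs=rec.fs, output="sos")
    else:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=filtered)


def segment_windows(
    rec: EEGRecording, window_s: float = 56.0, overlap_s: float = 55.0
) -> list[Window]:
    """Cut the recording into overlapping analysis windows.

    Stride is ``window_s - overlap_s`` (1 s by default); windows tile the
    recording left to right and each window is stamped at its end time, so
    its value is causal in the past ``window_s`` seconds.  A recording
    shorter than one window yields an empty list with a warning.
    """
    stride_n = (window_s - overlap_s) * rec.fs
    if stride_n <= 0 or abs(stride_n - round(stride_n)) > 1e-9:
        raise ValueError(
            "(window_s - overlap_s) * fs must be a positive integer sample count"
        )
    stride_n = int(round(stride_n))
    win_n = int(round(window_s * rec.fs))
    n = len(rec.samples)
    if n < win_n:
        logger.warning(
            "recording of %.1f s is shorter than one %g s window; no windows",
            rec.duration_s,
            window_s,
        )
        return []
    starts = range(0, n - win_n + 1, stride_n)
    return [
        Window(
            samples=rec.samples[s : s + win_n],
            t_end=rec.start_time + (s + win_n) / rec.fs,
        )
        for s in starts
    ]
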