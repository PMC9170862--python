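"""Synthetic EEG cohorts with depth-dependent spectral complexity.

Clinical depth-of-anaesthesia recordings are not publicly available, so
this module fabricates recordings that carry the one statistical property
the index pipeline relies on: the EEG's high-frequency complexity varies
monotonically with the (known) depth trace.  Depth uses the reference-index
convention — 100 is fully awake and most complex, 0 is isoelectric.

Two mechanisms encode depth ``d`` in the signal, both standard stylised
facts of anaesthetic EEG rather than a biophysical simulation:

* the spectral slope of a 1/f^alpha noise floor flattens as the subject
  lightens: ``alpha(d) = 2.6 - 1.8 d/100`` (steep, low-complexity spectrum
  when deep; near-white when awake);
* a high-band (32-63 Hz) noise component whose variance grows with ``d``
  (fast activity is suppressed by anaesthetic agents).

The ground-truth depth follows a piecewise-constant profile with 30-s
raised-cosine ramps at the level changes.  A BIS-like reference track is
the 1 Hz depth plus Gaussian noise, clipped to [0, 100].  Optional SQI
dropouts superimpose a large low-frequency artifact on the EEG and corrupt
the reference, emulating poor-contact episodes.  State annotations mark the
stable plateaus (ramps excluded) with the conventional depth ranges.

All randomness flows through one seeded generator; a fixed seed reproduces
a recording bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EEGRecording
from .rules import states_from_depth

__all__ = ["SyntheticConfig", "generate_recording", "generate_cohort"]

RAMP_S = 30.0  # raised-cosine transition width between profile levels

_ALPHA_GRID = np.linspace(0.5, 3.0, 11)  # spectral slopes spanned by depth


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic recording.

    ``depth_profile`` is a list of ``(t_start, t_end, depth)`` plateaus
    covering [0, duration_s]; transitions between consecutive plateaus are
    30-s raised-cosine ramps centred on the junction.  ``sqi_dropouts``
    lists ``(t_start, t_end, sqi_level)`` poor-signal episodes.
    """

    duration_s: float
    depth_profile: tuple[tuple[float, float, float], ...]
    fs: float = 128.0
    ref_noise_sd: float = 3.0
    sqi_dropouts: tuple[tuple[float, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        prof = tuple(tuple(map(float, seg)) for seg in self.depth_profile)
        object.__setattr__(self, "depth_profile", prof)
        object.__setattr__(
            self, "sqi_dropouts", tuple(tuple(map(float, d)) for d in self.sqi_dropouts)
        )
        if not prof:
            raise ValueError("depth_profile must not be empty")
        if abs(prof[0][0]) > 1e-9 or abs(prof[-1][1] - self.duration_s) > 1e-9:
            raise ValueError("depth_profile must cover [0, duration_s]")
        for (a0, a1, d) in prof:
            if not (0 <= d <= 100):
                raise ValueError("depths must lie in [0, 100]")
            if a1 <= a0:
                raise ValueError("profile segments must have positive length")
        for (a, b), (c, _) in zip(
            [(s[0], s[1]) for s in prof], [(s[0], s[1]) for s in prof[1:]]
        ):
            if abs(b - c) > 1e-9:
                raise ValueError("profile segments must be contiguous")


def depth_at(cfg: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    """Ground-truth depth at times ``t``: plateaus + raised-cosine ramps."""
    t = np.asarray(t, dtype=float)
    levels = [seg[2] for seg in cfg.depth_profile]
    out = np.empty_like(t)
    # piecewise-constant baseline
    idx = np.searchsorted(
        [seg[1] for seg in cfg.depth_profile], t, side="right"
    ).clip(max=len(levels) - 1)
    out[:] = np.asarray(levels)[idx]
    # blend across each interior junction
    half = RAMP_S / 2.0
    for (prev, nxt) in zip(cfg.depth_profile[:-1], cfg.depth_profile[1:]):
        tc = prev[1]
        a, b = prev[2], nxt[2]
        m = np.abs(t - tc) < half
        phase = (t[m] - tc + half) / RAMP_S  # 0..1 across the ramp
        out[m] = a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * phase))
    return out


def generate_recording(cfg: SyntheticConfig) -> EEGRecording:
    """Synthesise one recording with EEG, reference, SQI and annotations."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    depth = depth_at(cfg, t)
    u = depth / 100.0

    # one white-noise realisation shaped to every slope on the grid, then
    # blended per-sample so the local slope tracks alpha(depth(t))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    f_ref = np.maximum(f, 0.5)
    shaped = np.empty((_ALPHA_GRID.size, n))
    for i, alpha in enumerate(_ALPHA_GRID):
        x = np.fft.irfft(spec * f_ref ** (-alpha / 2.0), n=n)
        shaped[i] = x / x.std()
    alpha_t = 2.6 - 1.8 * u
    pos = np.interp(alpha_t, _ALPHA_GRID, np.arange(_ALPHA_GRID.size))
    lo = np.floor(pos).astype(int).clip(max=_ALPHA_GRID.size - 2)
    w = pos - lo
    floor_noise = (1.0 - w) * shaped[lo, np.arange(n)] + w * shaped[
        lo + 1, np.arange(n)
    ]

    # depth-weighted fast activity (32-63 Hz); kept small relative to the
    # floor so the adaptive boundaries stay driven by the broadband slope
    sos = sps.butter(2, [32.0, 63.0], btype="bandpass", fs=cfg.fs, output="sos")
    fast = sps.sosfilt(sos, rng.standard_normal(n))
    fast /= fast.std()
    eeg = 10.0 * (floor_noise + (0.05 + 0.25 * u) * fast)

    # 1 Hz tracks; element k is the value at the end of second k + 1
    n_sec = int(round(cfg.duration_s))
    t_sec = np.arange(1, n_sec + 1, dtype=float) - 0.5
    depth_1hz = depth_at(cfg, t_sec)
    ref = depth_1hz + rng.normal(0.0, cfg.ref_noise_sd, size=n_sec)
    sqi = np.full(n_sec, 95.0)

    for (d0, d1, level) in cfg.sqi_dropouts:
        mask_s = (t_sec >= d0) & (t_sec <= d1)
        sqi[mask_s] = level
        ref[mask_s] += rng.normal(0.0, 25.0, size=int(mask_s.sum()))
        mask = (t >= d0) & (t <= d1)
        artifact = 80.0 * np.sin(2.0 * np.pi * 1.5 * t[mask]) + 40.0 * np.cumsum(
            rng.standard_normal(int(mask.sum()))
        ) / np.sqrt(max(int(mask.sum()), 1))
        eeg[mask] += artifact
    ref = np.clip(ref, 0.0, 100.0)

    annotations = _stable_annotations(cfg)
    return EEGRecording(
        samples=eeg,
        fs=cfg.fs,
        ref_index=ref,
        sqi=sqi,
        state_annotations=annotations,
        channel_label="Ch2",
        true_depth=depth_1hz,
    )


def _stable_annotations(cfg: SyntheticConfig) -> list[tuple[float, float, str]]:
    """Plateau intervals (ramps trimmed) labelled by the depth-range states."""
    half = RAMP_S / 2.0
    out = []
    n_seg = len(cfg.depth_profile)
    for i, (t0, t1, d) in enumerate(cfg.depth_profile):
        a = t0 + (half if i > 0 else 0.0)
        b = t1 - (half if i < n_seg - 1 else 0.0)
        if b - a >= 1.0:
            state = str(states_from_depth(np.array([d]))[0])
            out.append((float(a), float(b), state))
    return out


def _surgery_profile(
    duration_s: float, rng: np.random.Generator
) -> tuple[tuple[float, float, float], ...]:
    """Randomised awake -> deep -> moderate -> emergence profile."""
    aw = rng.uniform(84.0, 96.0)
    la = rng.uniform(63.0, 77.0)
    da = rng.uniform(24.0, 36.0)
    ma = rng.uniform(44.0, 56.0)
    em = rng.uniform(63.0, 77.0)
    # segment lengths as random fractions of the recording; a 0.16 floor
    # keeps every plateau long enough (~96 s at 600 s) to hold analysis
    # windows clear of the transition ramps
    fracs = 0.16 + 0.2 * rng.dirichlet(np.array([3.0, 2.0, 5.0, 5.0, 3.0]))
    edges = np.concatenate([[0.0], np.cumsum(fracs)]) * duration_s
    levels = [aw, la, da, ma, em]
    return tuple(
        (float(a), float(b), float(d))
        for a, b, d in zip(edges[:-1], edges[1:], levels)
    )


def generate_cohort(
    n_train: int,
    n_test: int,
    seed: int = 0,
    duration_s: float = 600.0,
    ref_noise_sd: float = 3.0,
) -> tuple[list[EEGRecording], list[EEGRecording]]:
    """Independent training and testing cohorts of surgery-like recordings.

    Each subject gets a randomised awake -> induction -> deep -> moderate ->
    emergence profile covering all four states.  Per-subject seeds are
    derived from the master seed, so cohorts are reproducible and subjects
    mutually independent.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must both be >= 1")
    master = np.random.default_rng(seed)
    recs = []
    for k in range(n_train + n_test):
        profile_rng = np.random.default_rng(seed * 100003 + 7919 * k + 1)
        cfg = SyntheticConfig(
            duration_s=duration_s,
            depth_profile=_surgery_profile(duration_s, profile_rng),
            ref_noise_sd=ref_noise_sd,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        recs.append(generate_recording(cfg))
    return recs[:n_train], recs[n_train:]
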