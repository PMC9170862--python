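"""Per-window statistical features of the highest-order EWT subband.

Three features summarise each 56-s analysis window:

* the median of the subband coefficient vector (a stable amplitude
  baseline),
* the spectral entropy (SE): Shannon entropy, in bits, of the subband's
  normalised power distribution over positive-frequency DFT bins, averaged
  over the 56 one-second sub-segments of the window,
* the second-order difference plot (SODP) statistic: the absolute
  log-area of the ellipse fitted to consecutive first differences
  (X(n) = x(n+1) - x(n) plotted against Y(n) = x(n+2) - x(n+1)), likewise
  averaged over one-second sub-segments.

SE tracks how broadly the subband's power is spread in frequency; the SODP
area tracks the amplitude and irregularity of sample-to-sample variation.
Both fall as the cortical signal loses complexity under deepening
anaesthesia, which is what makes them usable as depth features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ewt import ewt_decompose, highest_band
from .io import Window

__all__ = [
    "WindowFeatures",
    "SODPComponents",
    "spectral_entropy",
    "sodp",
    "sodp_components",
    "window_features",
    "feature_table",
]

logger = logging.getLogger(__name__)

_SODP_FLOOR = 1e-12  # floor for the log argument on degenerate (flat) segments


@dataclass(frozen=True)
class WindowFeatures:
    """Feature triplet of one analysis window, stamped at the window's end."""

    t_end: float
    median_coeff: float
    se_mean: float
    sodp_mean: float
    ref_value: float | None = None


@dataclass(frozen=True)
class SODPComponents:
    """Intermediate ellipse statistics of a second-order difference plot."""

    SX: float
    SY: float
    SXY: float
    D: float


def _power_rows(rows: np.ndarray) -> np.ndarray:
    """Power over positive-frequency DFT bins (DC excluded), per row."""
    spec = np.fft.rfft(rows, axis=-1)
    return np.abs(spec[..., 1:]) ** 2


def _se_rows(rows: np.ndarray) -> np.ndarray:
    """Spectral entropy in bits for each row of a 2-D array."""
    power = _power_rows(rows)
    tot = power.sum(axis=-1, keepdims=True)
    zero = tot[..., 0] == 0
    if np.any(zero):
        logger.warning(
            "spectral_entropy: %d all-zero segment(s); entropy set to 0",
            int(zero.sum()),
        )
    p = np.divide(power, tot, out=np.zeros_like(power), where=tot > 0)
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=p > 0)
    return -(p * logp).sum(axis=-1)


def spectral_entropy(segment: np.ndarray) -> float:
    """Shannon entropy (bits) of the segment's normalised power spectrum.

    The power ``|X(n)|^2`` over positive-frequency bins of the segment's
    DFT, with the DC bin excluded, is normalised to a probability
    distribution P and the entropy ``-sum P log2 P`` returned (0 log 0 = 0).
    The result lies in [0, log2(#bins)]; an all-zero segment yields 0 with a
    warning.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("segment must have at least 2 samples")
    return float(_se_rows(x[None, :])[0])


def _sodp_rows(rows: np.ndarray, literal_radical: bool = False) -> np.ndarray:
    x = np.asarray(rows, dtype=float)
    dx = np.diff(x, axis=-1)
    X = dx[..., :-1]
    Y = dx[..., 1:]
    sx2 = np.mean(X**2, axis=-1)
    sy2 = np.mean(Y**2, axis=-1)
    sxy = np.mean(X * Y, axis=-1)
    if literal_radical:
        rad = (sx2 + sy2) - 4.0 * (sx2 * sy2 - sxy**2)
    else:
        rad = (sx2 + sy2) ** 2 - 4.0 * (sx2 * sy2 - sxy**2)
    D = np.sqrt(np.maximum(rad, 0.0))
    area2 = (sx2 + sy2 + D) * (sx2 + sy2 - D)
    bad = area2 <= 0
    if np.any(bad):
        logger.warning(
            "sodp: %d degenerate segment(s) (zero ellipse area); "
            "log argument floored at %g",
            int(bad.sum()),
            _SODP_FLOOR,
        )
    arg = 3.0 * np.pi * np.sqrt(np.maximum(area2, 0.0))
    return np.abs(np.log(np.maximum(arg, _SODP_FLOOR)))


def sodp_components(segment: np.ndarray) -> SODPComponents:
    """RMS spreads SX, SY, cross-term SXY and ellipse half-diagonal D."""
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("segment must have at least 3 samples")
    dx = np.diff(x)
    X, Y = dx[:-1], dx[1:]
    sx2, sy2, sxy = np.mean(X**2), np.mean(Y**2), np.mean(X * Y)
    D = float(np.sqrt(max((sx2 + sy2) ** 2 - 4.0 * (sx2 * sy2 - sxy**2), 0.0)))
    return SODPComponents(
        SX=float(np.sqrt(sx2)), SY=float(np.sqrt(sy2)), SXY=float(sxy), D=D
    )


def sodp(segment: np.ndarray, literal_radical: bool = False) -> float:
    """Absolute log ellipse-area statistic of a second-order difference plot.

    With X(n) = x(n+1) - x(n) and Y(n) = x(n+2) - x(n+1), the RMS spreads
    SX, SY and cross-term SXY define an ellipse whose half-diagonal is
    ``D = sqrt((SX^2+SY^2)^2 - 4 (SX^2 SY^2 - SXY^2))``; the statistic is
    ``|log(3 pi sqrt((SX^2+SY^2+D)(SX^2+SY^2-D)))|`` (natural log).

    ``literal_radical=True`` drops the square on the first term under D's
    radical — an alternative printed form kept for comparison; it can go
    imaginary and is clipped at zero.  Degenerate (flat or perfectly linear)
    segments have zero ellipse area; the log argument is floored at 1e-12
    and a warning logged.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("segment must have at least 3 samples")
    return float(_sodp_rows(x[None, :], literal_radical=literal_radical)[0])


def window_features(
    band: np.ndarray,
    fs: float,
    t_end: float,
    ref_value: float | None = None,
) -> WindowFeatures:
    """Feature triplet of one highest-subband coefficient vector.

    The band is split into consecutive 1-s sub-segments (``fs`` samples
    each); ``se_mean`` and ``sodp_mean`` are arithmetic means of the
    per-second values, ``median_coeff`` the median of the whole vector.
    """
    b = np.asarray(band, dtype=float)
    fs_i = int(round(fs))
    if b.size % fs_i != 0:
        raise ValueError(
            f"band length {b.size} is not a whole number of 1-s segments at fs={fs}"
        )
    rows = b.reshape(-1, fs_i)
    return WindowFeatures(
        t_end=float(t_end),
        median_coeff=float(np.median(b)),
        se_mean=float(_se_rows(rows).mean()),
        sodp_mean=float(_sodp_rows(rows).mean()),
        ref_value=None if ref_value is None else float(ref_value),
    )


def feature_table(
    windows: list[Window],
    fs: float,
    n_bands: int = 15,
    ref_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """EWT-decompose each window and tabulate its highest-band features.

    Returns a DataFrame with columns ``t_end, median_coeff, se_mean,
    sodp_mean, ref_value`` (``ref_value`` is NaN when no reference track is
    supplied).  A window whose decomposition fails is logged and skipped,
    never silently dropped.
    """
    rows = []
    for i, win in enumerate(windows):
        try:
            dec = ewt_decompose(win.samples, n_bands=n_bands)
            band = highest_band(dec)
            ref_value = None
            if ref_index is not None:
                k = min(int(round(win.t_end)) - 1, len(ref_index) - 1)
                if 0 <= k:
                    ref_value = float(ref_index[k])
            rows.append(window_features(band, fs, win.t_end, ref_value))
        except Exception:
            logger.exception("feature extraction failed for window %d; skipped", i)
    return pd.DataFrame(
        [
            {
                "t_end": f.t_end,
                "median_coeff": f.median_coeff,
                "se_mean": f.se_mean,
                "sodp_mean": f.sodp_mean,
                "ref_value": np.nan if f.ref_value is None else f.ref_value,
            }
            for f in rows
        ]
    )
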