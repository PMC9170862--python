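"""Empirical wavelet transform (EWT) for single EEG analysis windows.

The EWT adapts a wavelet filter bank to the signal at hand: boundaries are
detected on the Fourier magnitude spectrum ("locmaxmin" rule — the smallest
spectral minima between the retained local maxima), and a Littlewood-Paley /
Meyer-type tight frame is built on those boundaries.  Band-passing the window
through each filter yields per-subband coefficient vectors; filtering the
coefficients once more through the same profile yields the empirical modes,
which sum back to the input exactly (tight frame).

All frequencies are expressed in normalised radians on [0, pi]
(pi = Nyquist).  Filters are real and symmetric, so modes and coefficients of
a real input stay real.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoundarySet",
    "EWTFilterBank",
    "EWTDecomposition",
    "detect_boundaries",
    "build_filter_bank",
    "ewt_decompose",
    "highest_band",
]

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-12  # additive floor before taking log of the spectrum


@dataclass(frozen=True)
class BoundarySet:
    """Sorted Fourier segmentation boundaries in (0, pi) normalised radians.

    ``n_bands`` subbands are delimited by ``n_bands - 1`` interior
    boundaries; 0 and pi are implicit outer edges.
    """

    omegas: np.ndarray
    n_bands: int

    def __post_init__(self) -> None:
        om = np.asarray(self.omegas, dtype=float)
        object.__setattr__(self, "omegas", om)
        if om.size != self.n_bands - 1:
            raise ValueError(
                f"expected {self.n_bands - 1} boundaries, got {om.size}"
            )
        if om.size and not (np.all(np.diff(om) > 0) and om[0] > 0 and om[-1] < np.pi):
            raise ValueError("boundaries must be strictly increasing in (0, pi)")


@dataclass
class EWTFilterBank:
    """Meyer-style tight-frame filter bank on the boundaries of a window.

    ``scaling_hat`` is the low-pass profile, ``wavelet_hats`` the band-pass
    profiles, all sampled on the rfft grid of an ``n_samples``-point window.
    The profiles satisfy sum_k |H_k(w)|^2 = 1 for every w (tight frame).
    """

    boundaries: BoundarySet
    gamma: float
    n_samples: int
    scaling_hat: np.ndarray = field(repr=False)
    wavelet_hats: np.ndarray = field(repr=False)  # (n_bands - 1, n_rfft)

    @property
    def profiles(self) -> np.ndarray:
        """All profiles stacked, lowest band first, shape (n_bands, n_rfft)."""
        return np.vstack([self.scaling_hat[None, :], self.wavelet_hats])


@dataclass
class EWTDecomposition:
    """EWT of one window: subband modes, coefficients and their provenance.

    ``coeffs[k]`` is the k-th subband coefficient vector (window filtered by
    profile k); ``subbands[k]`` the empirical mode (coefficients filtered once
    more), so ``sum(subbands) == window`` and ``sum(|coeffs|^2) == |window|^2``.
    Bands are ordered by ascending frequency: index ``n_bands - 1`` is the
    highest-frequency band.
    """

    subbands: np.ndarray  # (n_bands, n_samples)
    coeffs: np.ndarray  # (n_bands, n_samples)
    boundaries: BoundarySet
    bank: EWTFilterBank

    @property
    def n_bands(self) -> int:
        return self.subbands.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Sum of empirical modes; equals the input up to round-off."""
        return self.subbands.sum(axis=0)

    def band_energies(self) -> np.ndarray:
        """Per-band coefficient energies; they sum to the window energy."""
        return (self.coeffs**2).sum(axis=1)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima of a 1-D array."""
    v = values
    idx = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
    return idx


def _subdivide(bound_bins: list[int], n_needed: int, n_half: int) -> list[int]:
    # Fill up to n_needed boundaries by halving the widest spectral interval;
    # edges 0 and n_half act as the outer interval limits.
    bounds = sorted(bound_bins)
    while len(bounds) < n_needed:
        edges = [0] + bounds + [n_half]
        gaps = np.diff(edges)
        i = int(np.argmax(gaps))
        mid = (edges[i] + edges[i + 1]) // 2
        if mid in edges or mid <= 0 or mid >= n_half:
            raise RuntimeError("spectrum too short to place the requested boundaries")
        bounds = sorted(bounds + [mid])
    return bounds


def detect_boundaries(
    window: np.ndarray, n_bands: int, use_log: bool = True
) -> BoundarySet:
    """Locate Fourier segmentation boundaries with the locmaxmin rule.

    The ``n_bands`` largest local maxima of the (log-)magnitude spectrum are
    retained and each boundary is placed at the smallest spectral value
    between consecutive retained maxima.  If the spectrum exposes fewer
    maxima than requested, the boundaries found are kept and the widest
    remaining spectral interval is subdivided uniformly until ``n_bands - 1``
    boundaries exist (a warning is logged).

    Parameters
    ----------
    window : array-like
        Real signal segment.
    n_bands : int
        Number of subbands requested (>= 2).
    use_log : bool
        Detect on ``log`` of the magnitude spectrum (floored at 1e-12)
        rather than the magnitude itself.
    """
    x = np.asarray(window, dtype=float)
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if x.size < 2 * n_bands:
        raise ValueError("window too short for the requested number of bands")

    n = x.size
    mag = np.abs(np.fft.rfft(x))
    spec = np.log(mag + _LOG_FLOOR) if use_log else mag
    n_half = spec.size - 1  # index of Nyquist bin

    maxima = _local_maxima(spec)
    # drop maxima that are pure numerical noise relative to the peak
    maxima = maxima[mag[maxima] > mag.max() * 1e-10]
    if maxima.size >= n_bands:
        # keep the n_bands largest maxima, in frequency order
        order = np.argsort(spec[maxima])[::-1][:n_bands]
        kept = np.sort(maxima[order])
        bounds = []
        for a, b in zip(kept[:-1], kept[1:]):
            seg = spec[a + 1 : b]
            bounds.append(int(a + 1 + np.argmin(seg)))
    else:
        bounds = []
        for a, b in zip(maxima[:-1], maxima[1:]):
            seg = spec[a + 1 : b]
            bounds.append(int(a + 1 + np.argmin(seg)))
        logger.warning(
            "locmaxmin found %d local maxima (< %d bands); subdividing the "
            "widest spectral intervals to reach %d boundaries",
            maxima.size,
            n_bands,
            n_bands - 1,
        )
        bounds = _subdivide(bounds, n_bands - 1, n_half)

    omegas = 2.0 * np.pi * np.asarray(sorted(bounds), dtype=float) / n
    return BoundarySet(omegas=omegas, n_bands=n_bands)


def _beta(x: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial: C^3 ramp from 0 to 1 on [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def max_gamma(bounds: BoundarySet) -> float:
    """Largest transition half-width ratio with non-overlapping transitions."""
    om = np.concatenate([bounds.omegas, [np.pi]])
    ratios = (om[1:] - om[:-1]) / (om[1:] + om[:-1])
    # the scaling filter's lower edge only requires gamma < 1
    return float(min(ratios.min(initial=1.0), 1.0))


def build_filter_bank(
    bounds: BoundarySet, gamma: float | str = "auto", n_samples: int = 7168
) -> EWTFilterBank:
    """Build the Meyer-style tight-frame filter bank on a boundary set.

    ``gamma`` controls the relative half-width of the raised-cosine
    transition around each boundary ``w_n``: the transition occupies
    ``[(1 - gamma) w_n, (1 + gamma) w_n]``.  ``gamma='auto'`` picks 99% of
    the largest value for which no two transition zones overlap.  The last
    wavelet is one-sided (flat up to pi).
    """
    gmax = max_gamma(bounds)
    if gamma == "auto":
        g = 0.99 * gmax
    else:
        g = float(gamma)
        if g <= 0 or g >= gmax:
            raise ValueError(
                f"gamma={g} infeasible: transition zones overlap (need 0 < gamma < {gmax:.4g})"
            )

    n_rfft = n_samples // 2 + 1
    w = 2.0 * np.pi * np.arange(n_rfft) / n_samples
    om = bounds.omegas

    def rising(omega_b: float) -> np.ndarray:
        # 0 below the transition, 1 above it
        return np.sin(
            0.5 * np.pi * _beta((w - (1 - g) * omega_b) / (2 * g * omega_b))
        ) * (w >= (1 - g) * omega_b) + 0.0

    def falling(omega_b: float) -> np.ndarray:
        out = np.ones_like(w)
        t = (w - (1 - g) * omega_b) / (2 * g * omega_b)
        out = np.where(w < (1 - g) * omega_b, 1.0, np.cos(0.5 * np.pi * _beta(t)))
        out[w > (1 + g) * omega_b] = 0.0
        return out

    scaling = falling(om[0])
    wavelets = np.empty((bounds.n_bands - 1, n_rfft))
    for k in range(bounds.n_bands - 1):
        lo_edge = rising(om[k])
        if k + 1 < om.size:
            hi_edge = falling(om[k + 1])
        else:
            hi_edge = np.ones_like(w)  # last band extends to Nyquist
        wavelets[k] = lo_edge * hi_edge

    return EWTFilterBank(
        boundaries=bounds,
        gamma=g,
        n_samples=n_samples,
        scaling_hat=scaling,
        wavelet_hats=wavelets,
    )


def ewt_decompose(
    window: np.ndarray,
    n_bands: int = 15,
    use_log: bool = True,
    gamma: float | str = "auto",
) -> EWTDecomposition:
    """Decompose a window into ``n_bands`` empirical wavelet subbands.

    Coefficients are computed spectrally: the window's rfft is multiplied by
    each (real, symmetric) filter profile and inverse-transformed.  The
    empirical modes apply the profile twice, which makes the mode sum a
    perfect reconstruction under the tight-frame identity.
    """
    x = np.asarray(window, dtype=float)
    bounds = detect_boundaries(x, n_bands=n_bands, use_log=use_log)
    bank = build_filter_bank(bounds, gamma=gamma, n_samples=x.size)
    xhat = np.fft.rfft(x)
    H = bank.profiles
    coeffs = np.fft.irfft(xhat[None, :] * H, n=x.size, axis=1)
    subbands = np.fft.irfft(xhat[None, :] * H**2, n=x.size, axis=1)
    return EWTDecomposition(
        subbands=subbands, coeffs=coeffs, boundaries=bounds, bank=bank
    )


def highest_band(dec: EWTDecomposition) -> np.ndarray:
    """Coefficient vector of the highest-frequency subband."""
    return dec.coeffs[-1]


def band_table(dec: EWTDecomposition, fs: float, t_end: float):
    """Per-band boundary frequencies and energies of one window's EWT.

    Returns a DataFrame (columns ``t_end, band, low_hz, high_hz, energy``)
    suitable for dumping one row per subband to CSV for inspection.
    """
    import pandas as pd

    edges_hz = np.concatenate(
        [[0.0], dec.boundaries.omegas * fs / (2 * np.pi), [fs / 2.0]]
    )
    return pd.DataFrame(
        {
            "t_end": t_end,
            "band": np.arange(dec.n_bands),
            "low_hz": edges_hz[:-1],
            "high_hz": edges_hz[1:],
            "energy": dec.band_energies(),
        }
    )
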