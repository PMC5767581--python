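"""Multitaper EEG(CSD)-EMG coherence with degrees-of-freedom bookkeeping.

Coherence is estimated by averaging tapered cross- and auto-spectra over
non-overlapping 1-s epochs and K Slepian (DPSS) tapers:

    S_xy(f) = mean_{l,k} X_{l,k}(f) conj(Y_{l,k}(f))
    C(f)    = |S_xy(f)| / sqrt(S_xx(f) S_yy(f))

``C`` is the coherence *magnitude* (not squared), the quantity entering
the downstream z-transform; the degrees of freedom of the estimate are
``d = 2 K L`` for L epochs and K tapers. Beta-band (15-30 Hz)
topographies summarise the per-electrode band-mean coherence and record
the peak electrode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows
from sklearn.base import BaseEstimator

from .containers import EpochSet
from .errors import BandError, DegenerateSignalError, PairingError, ParameterError

BETA_BAND = (15.0, 30.0)


@dataclass
class TaperSet:
    """K orthonormal Slepian tapers of length N with time-bandwidth NW."""

    tapers: np.ndarray  # (K, N), unit norm each
    nw: float

    @property
    def K(self) -> int:
        return self.tapers.shape[0]

    @property
    def N(self) -> int:
        return self.tapers.shape[1]


def make_tapers(N: int, NW: float = 2.0, K: int = 3) -> TaperSet:
    """First K discrete prolate spheroidal sequences, unit-norm.

    The usable taper count is bounded by K <= 2 NW - 1; beyond it the
    energy concentration degrades sharply.
    """
    if N < 8:
        raise ParameterError(f"taper length N={N} too short")
    if K < 1 or K > 2 * NW - 1:
        raise ParameterError(f"K={K} outside [1, 2*NW-1] = [1, {2 * NW - 1:g}]")
    # sym=True gives the exact DPSS eigenvectors (orthonormal to machine
    # precision); the periodic variant truncates and loses orthogonality
    tap = windows.dpss(N, NW, Kmax=K, sym=True, norm=2)
    tap = np.atleast_2d(tap)
    tap = tap / np.linalg.norm(tap, axis=1, keepdims=True)
    return TaperSet(tapers=tap, nw=float(NW))


@dataclass
class CoherenceSpectrum:
    """Frequency-resolved coherence magnitude for one channel pair."""

    pair: tuple[str, str]
    freqs: np.ndarray
    C: np.ndarray
    d: int  # degrees of freedom = 2 K L
    L: int
    K: int

    def band_mean(self, band: tuple[float, float]) -> float:
        lo, hi = band
        mask = (self.freqs >= lo) & (self.freqs <= hi)
        if not np.any(mask):
            raise BandError(f"band {band} outside the frequency grid")
        return float(self.C[mask].mean())


def tapered_ffts(epochs: np.ndarray, tapers: TaperSet) -> np.ndarray:
    """Tapered rFFTs of (L, N) epochs -> complex (L, K, F)."""
    x = np.asarray(epochs, dtype=float)
    return np.fft.rfft(x[:, None, :] * tapers.tapers[None, :, :], axis=-1)


def cross_products(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    tapers: TaperSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch taper-averaged (S_xy, S_xx, S_yy), each shape (L, F).

    Averaging these over epochs and forming |S_xy|/sqrt(S_xx S_yy) gives
    the multitaper coherence; keeping the per-epoch terms makes random
    partitions cheap (group means over precomputed arrays).
    """
    X = tapered_ffts(x_epochs, tapers)
    Y = tapered_ffts(y_epochs, tapers)
    Sxy = np.mean(X * np.conj(Y), axis=1)
    Sxx = np.mean(np.abs(X) ** 2, axis=1)
    Syy = np.mean(np.abs(Y) ** 2, axis=1)
    return Sxy, Sxx, Syy


def coherence_from_products(Sxy, Sxx, Syy) -> np.ndarray:
    num = np.abs(np.mean(Sxy, axis=0))
    den = np.sqrt(np.mean(Sxx, axis=0) * np.mean(Syy, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(C, 0.0, 1.0)


def coherence_spectrum(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    tapers: TaperSet,
    fs: float,
    pair: tuple[str, str] = ("x", "y"),
) -> CoherenceSpectrum:
    """Multitaper magnitude coherence between two epoched channels.

    ``x_epochs`` and ``y_epochs`` are (L, N) arrays of paired epochs.
    """
    x = np.asarray(x_epochs, float)
    y = np.asarray(y_epochs, float)
    if x.shape != y.shape:
        raise PairingError(f"epoch shapes differ: {x.shape} vs {y.shape}")
    L, N = x.shape
    if tapers.N != N:
        raise PairingError(f"tapers built for N={tapers.N}, epochs have N={N}")
    if L * tapers.K < 2:
        raise ParameterError("need at least 2 taper-epoch products")
    if np.allclose(x, x[..., :1]) or np.allclose(y, y[..., :1]):
        raise DegenerateSignalError("zero-variance channel in coherence estimate")
    Sxy, Sxx, Syy = cross_products(x, y, tapers)
    C = coherence_from_products(Sxy, Sxx, Syy)
    freqs = np.fft.rfftfreq(N, 1.0 / fs)
    return CoherenceSpectrum(pair=pair, freqs=freqs, C=C, d=2 * tapers.K * L, L=L, K=tapers.K)


@dataclass
class TopographyMap:
    """Per-electrode band-mean coherence with its peak electrode."""

    band: tuple[float, float]
    values: dict[str, float]
    peak_electrode: str


def band_topography(
    cohs: list[CoherenceSpectrum] | dict[str, CoherenceSpectrum],
    band: tuple[float, float] = BETA_BAND,
) -> TopographyMap:
    """Band-mean coherence per electrode; ties broken by input order."""
    if isinstance(cohs, dict):
        items = [(lab, c) for lab, c in cohs.items()]
    else:
        items = [(c.pair[0], c) for c in cohs]
    values = {lab: c.band_mean(band) for lab, c in items}
    peak = max(values, key=lambda lab: values[lab])  # first maximum wins
    return TopographyMap(band=band, values=values, peak_electrode=peak)


def select_peak_spectrum(
    sessions: dict[str, dict[str, CoherenceSpectrum]],
    band: tuple[float, float] = BETA_BAND,
) -> dict[str, CoherenceSpectrum]:
    """Per session, the spectrum at that session's own beta-band peak.

    Each session's peak electrode is determined independently, which
    tolerates small cap-placement shifts between sessions.
    """
    out = {}
    for name, cohs in sessions.items():
        topo = band_topography(cohs, band)
        out[name] = cohs[topo.peak_electrode]
    return out


class MultitaperCoherence(BaseEstimator):
    """Multitaper CMC estimation over all EEG electrodes of an epoch set.

    Parameters
    ----------
    nw : float
        Time-bandwidth product (default 2: +/-2 Hz smoothing for 1-s epochs).
    k : int
        Taper count (default 3 = 2*NW - 1).
    emg : str or None
        EMG channel label; the first EMG channel when None.

    Fitted attributes
    -----------------
    freqs_ : frequency grid, Hz.
    coherence_ : dict electrode label -> CoherenceSpectrum.
    dof_ : degrees of freedom (2 k L).
    """

    def __init__(self, nw: float = 2.0, k: int = 3, emg: str | None = None):
        self.nw = nw
        self.k = k
        self.emg = emg

    def fit(self, X: EpochSet, y=None) -> "MultitaperCoherence":
        emg_idx = X.kind_indices("EMG")
        if not emg_idx:
            raise PairingError("epoch set has no EMG channel")
        emg_label = self.emg or X.channels[emg_idx[0]][0]
        tapers = make_tapers(X.epoch_len, NW=self.nw, K=self.k)
        # one tapered FFT of the EMG, shared by every electrode pair
        Y = tapered_ffts(X.channel(emg_label), tapers)
        Syy = np.mean(np.abs(Y) ** 2, axis=(0, 1))
        freqs = np.fft.rfftfreq(X.epoch_len, 1.0 / X.fs)
        L = X.n_epochs
        self.coherence_ = {}
        for i in X.kind_indices("EEG"):
            lab = X.channels[i][0]
            Xf = tapered_ffts(X.data[:, i, :], tapers)
            Sxy = np.mean(Xf * np.conj(Y), axis=(0, 1))
            Sxx = np.mean(np.abs(Xf) ** 2, axis=(0, 1))
            with np.errstate(invalid="ignore", divide="ignore"):
                den = np.sqrt(Sxx * Syy)
                C = np.where(den > 0, np.abs(Sxy) / np.maximum(den, 1e-300), 0.0)
            self.coherence_[lab] = CoherenceSpectrum(
                pair=(lab, emg_label),
                freqs=freqs,
                C=np.clip(C, 0.0, 1.0),
                d=2 * tapers.K * L,
                L=L,
                K=tapers.K,
            )
        first = next(iter(self.coherence_.values()))
        self.freqs_ = first.freqs
        self.dof_ = first.d
        self.emg_label_ = emg_label
        return self

    def band_topography(self, band: tuple[float, float] = BETA_BAND) -> TopographyMap:
        return band_topography(self.coherence_, band)
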