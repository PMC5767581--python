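"""Reference-free current source density via spherical-spline Laplacian.

Scalp potentials sampled on an (idealised, unit-sphere) montage are
interpolated with spherical splines and differentiated on the sphere,
yielding a current source density (CSD) estimate per electrode. The
output is invariant to the recording reference: adding any constant to
all channels leaves the CSD unchanged, because the spline's constant
term absorbs it.

Kernels, with P_n the Legendre polynomials and m the spline flexibility:

    g(x) = sum_{n=1..N} (2n+1) / (n(n+1))^m     * P_n(x)
    h(x) = sum_{n=1..N} (2n+1) / (n(n+1))^(m-1) * P_n(x)

The spline coefficients c solve (G + lambda I) c + c0 1 = v subject to
1'c = 0; the CSD is H c. Sign convention is source-positive (a focal
positive potential maps to positive CSD at the focus with a negative
surrounding ring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import legval
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EpochSet
from .errors import MontageError, SingularityError
from .montage import Montage


def spline_g(x: np.ndarray | float, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Interpolation kernel g(cos theta) as a truncated Legendre series."""
    n = np.arange(1, n_terms + 1, dtype=float)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1)) ** m
    return legval(np.asarray(x, dtype=float), coeffs)


def spline_h(x: np.ndarray | float, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Laplacian kernel h(cos theta); one power of n(n+1) fewer than g."""
    n = np.arange(1, n_terms + 1, dtype=float)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1)) ** (m - 1)
    return legval(np.asarray(x, dtype=float), coeffs)


@dataclass
class SplineOperator:
    """Precomputed linear map from scalp potentials to CSD values."""

    montage: Montage
    m: int
    lam: float
    n_terms: int
    G: np.ndarray
    H: np.ndarray
    operator: np.ndarray  # (n, n): csd = operator @ potentials

    def __call__(self, v: np.ndarray) -> np.ndarray:
        """Apply to potentials with channels on the first axis."""
        return np.tensordot(self.operator, v, axes=([1], [0]))


def build_operator(
    mont: Montage,
    m: int = 4,
    lam: float = 1e-5,
    n_terms: int = 50,
) -> SplineOperator:
    """Assemble the spherical-spline CSD operator for a montage.

    Deterministic in (montage, m, lambda, n_terms). The regularisation
    ``lam`` is added to the diagonal of G before solving. A montage with
    coincident electrodes makes the interpolation system singular and is
    rejected.
    """
    if m < 2:
        raise ValueError(f"spline order m must be >= 2, got {m}")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    cosang = mont.cosine_angles()
    off = cosang - np.eye(len(mont))
    if np.any(off > 1.0 - 1e-12):
        raise SingularityError("montage contains (near-)coincident electrodes")
    G = spline_g(cosang, m=m, n_terms=n_terms)
    H = spline_h(cosang, m=m, n_terms=n_terms)
    n = len(mont)
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = G + lam * np.eye(n)
    M[:n, n] = 1.0
    M[n, :n] = 1.0
    Minv = np.linalg.inv(M)
    operator = H @ Minv[:n, :n]
    return SplineOperator(
        montage=mont, m=m, lam=lam, n_terms=n_terms, G=G, H=H, operator=operator
    )


def apply_csd(op: SplineOperator, ep: EpochSet) -> EpochSet:
    """Transform the EEG channels of an epoch set to CSD, sample-wise.

    The epoch set's EEG channels must match the operator's montage labels
    (same set, any order); EMG and force channels pass through untouched.
    """
    eeg_idx = ep.kind_indices("EEG")
    labels = [ep.channels[i][0] for i in eeg_idx]
    if sorted(labels) != sorted(op.montage.labels):
        raise MontageError(
            "epoch EEG channels do not match the CSD operator's montage"
        )
    order = [labels.index(lab) for lab in op.montage.labels]
    eeg_rows = [eeg_idx[j] for j in order]
    out = ep.data.copy()
    # contract the channel axis with the operator via one BLAS matmul
    block = ep.data[:, eeg_rows, :]  # (epochs, n_eeg, samples)
    flat = block.transpose(1, 0, 2).reshape(len(eeg_rows), -1)
    out[:, eeg_rows, :] = (
        (op.operator @ flat).reshape(len(eeg_rows), block.shape[0], block.shape[2]).transpose(1, 0, 2)
    )
    return EpochSet(
        condition=ep.condition,
        fs=ep.fs,
        data=out,
        channels=list(ep.channels),
        provenance=list(ep.provenance),
    )


class SurfaceLaplacian(BaseEstimator, TransformerMixin):
    """Spherical-spline CSD as a transformer over epoch sets.

    Parameters are the canonical spherical-spline defaults: flexibility
    m=4, regularisation lambda=1e-5, 50 Legendre terms.
    """

    def __init__(
        self,
        montage: Montage | None = None,
        m: int = 4,
        lam: float = 1e-5,
        n_terms: int = 50,
    ):
        self.montage = montage
        self.m = m
        self.lam = lam
        self.n_terms = n_terms

    def fit(self, X: EpochSet, y=None) -> "SurfaceLaplacian":
        if self.montage is None:
            raise MontageError("SurfaceLaplacian requires a montage")
        self.operator_ = build_operator(
            self.montage, m=self.m, lam=self.lam, n_terms=self.n_terms
        )
        return self

    def transform(self, X: EpochSet) -> EpochSet:
        return apply_csd(self.operator_, X)
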