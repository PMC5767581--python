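"""Nonparametric comparison of two coherence spectra.

The coherence difference between two conditions is transformed to a
bias-corrected z-spectrum

    Z(f) = ((atanh C1(f) - n1) - (atanh C2(f) - n2)) / sqrt(n1 + n2),

with n_i = 1/(d_i - 2) the bias/variance term for a coherence estimate
with d_i degrees of freedom. Within the band of interest, maximal runs of
adjacent supra-threshold frequencies form clusters whose mass is the sum
of their Z values; the test statistic is the largest cluster mass. Its
null distribution comes from random partitions: the pooled data segments
are reassigned to two pseudo-conditions of the original sizes, the whole
coherence -> z -> cluster sub-pipeline is re-run, and the Monte Carlo p
value is the proportion of partitions with a statistic at least as large
as the observed one (add-one estimator, so p is never exactly 0).

Positive Z means condition 1 exceeds condition 2; a one-sided test of
"condition 1 > condition 2" therefore clusters Z above the threshold. To
test the reverse direction, swap the conditions (Z is exactly
antisymmetric under the swap when the degrees of freedom are equal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .containers import EpochSet
from .coherence import (
    BETA_BAND,
    CoherenceSpectrum,
    band_topography,
    coherence_from_products,
    cross_products,
    make_tapers,
)
from .errors import BandError, DofError, PairingError, ParameterError

logger = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-12


@dataclass
class ZSpectrum:
    """Bias-corrected z-transformed coherence difference per frequency."""

    freqs: np.ndarray
    Z: np.ndarray
    d1: int
    d2: int

    @property
    def n1(self) -> float:
        return 1.0 / (self.d1 - 2)

    @property
    def n2(self) -> float:
        return 1.0 / (self.d2 - 2)


def _z_arrays(C1: np.ndarray, C2: np.ndarray, d1: int, d2: int) -> np.ndarray:
    if d1 <= 2 or d2 <= 2:
        raise DofError(f"z-transform needs d > 2 in both conditions, got {d1}, {d2}")
    n1 = 1.0 / (d1 - 2)
    n2 = 1.0 / (d2 - 2)
    z1 = np.arctanh(np.clip(C1, 0.0, _CLIP))
    z2 = np.arctanh(np.clip(C2, 0.0, _CLIP))
    return ((z1 - n1) - (z2 - n2)) / np.sqrt(n1 + n2)


def z_difference(C1: CoherenceSpectrum, C2: CoherenceSpectrum) -> ZSpectrum:
    """Z-spectrum of the coherence difference of two conditions.

    Exactly antisymmetric under swapping the conditions when d1 == d2,
    and identically zero when the spectra and dofs coincide. Coherence is
    clipped just below 1 to keep atanh finite.
    """
    if not np.array_equal(C1.freqs, C2.freqs):
        raise PairingError("coherence spectra are on different frequency grids")
    Z = _z_arrays(C1.C, C2.C, C1.d, C2.d)
    return ZSpectrum(freqs=C1.freqs.copy(), Z=Z, d1=C1.d, d2=C2.d)


@dataclass
class ClusterSet:
    """Maximal runs of adjacent supra-threshold frequencies."""

    clusters: list[tuple[int, int, float]]  # (start_idx, end_idx incl., mass)
    threshold: float
    band: tuple[float, float]

    def masses(self) -> list[float]:
        return [m for _, _, m in self.clusters]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def find_clusters(
    z: ZSpectrum,
    threshold: float,
    band: tuple[float, float] = BETA_BAND,
) -> ClusterSet:
    """Cluster strictly supra-threshold adjacent frequencies within a band.

    Adjacency means consecutive points of the frequency grid restricted
    to the band; the inequality is strict, so Z equal to the threshold
    does not enter a cluster.
    """
    if threshold <= 0:
        raise ParameterError("cluster-forming threshold must be positive")
    lo, hi = band
    sel = np.flatnonzero((z.freqs >= lo) & (z.freqs <= hi))
    if sel.size == 0:
        raise BandError(f"band {band} lies outside the frequency grid")
    zb = z.Z[sel]
    clusters = [
        (int(sel[a]), int(sel[b]), float(zb[a : b + 1].sum()))
        for a, b in _runs(zb > threshold)
    ]
    return ClusterSet(clusters=clusters, threshold=threshold, band=band)


def max_cluster_stat(cs: ClusterSet) -> float:
    """Largest cluster mass; 0 when there is no cluster."""
    return max(cs.masses(), default=0.0)


def _max_mass(zb: np.ndarray, threshold: float, two_sided: bool) -> float:
    """Max cluster mass of a band-restricted Z array (|mass| if two-sided)."""
    best = 0.0
    for a, b in _runs(zb > threshold):
        best = max(best, float(zb[a : b + 1].sum()))
    if two_sided:
        for a, b in _runs(-zb > threshold):
            best = max(best, float(-zb[a : b + 1].sum()))
    return best


def random_partition(
    epochs1: EpochSet,
    epochs2: EpochSet,
    rng: np.random.Generator,
) -> tuple[EpochSet, EpochSet]:
    """Reassign the pooled epochs uniformly at random, sizes preserved."""
    epochs1.same_layout(epochs2)
    L1, L2 = epochs1.n_epochs, epochs2.n_epochs
    pool = np.concatenate([epochs1.data, epochs2.data], axis=0)
    prov = list(epochs1.provenance) + list(epochs2.provenance)
    perm = rng.permutation(L1 + L2)
    merged = EpochSet(
        condition="pooled",
        fs=epochs1.fs,
        data=pool,
        channels=list(epochs1.channels),
        provenance=prov,
    )
    return (
        merged.subset(perm[:L1], condition=epochs1.condition + "*"),
        merged.subset(perm[L1:], condition=epochs2.condition + "*"),
    )


@dataclass
class PermutationResult:
    """Observed cluster statistic, its permutation null and Monte Carlo p."""

    observed_stat: float
    null_stats: np.ndarray
    n_permutations: int
    p_mc: float
    seed: int
    direction: str
    threshold: float
    band: tuple[float, float]
    electrodes: tuple[str, str]
    clusters: ClusterSet | None = None
    z: ZSpectrum | None = None
    spectra: dict = field(default_factory=dict)


class ClusterPermutationTest(BaseEstimator):
    """Cluster-based random-partition test of a coherence difference.

    ``fit(epochs1, epochs2)`` runs the full sub-pipeline (multitaper
    coherence at the analysis electrode(s) -> z-spectrum -> band-limited
    clustering -> max cluster mass) on the observed labelling, then on
    ``n_perm`` random partitions of the pooled segments.

    Parameters
    ----------
    electrode : str or None
        EEG electrode for both conditions; when None each condition uses
        its own beta-band peak electrode (the fixed-electrode analysis;
        selection is *not* redone inside permutations unless
        ``selection_aware``).
    alternative : {"greater", "two-sided"}
        "greater" tests condition 1 > condition 2 via clusters of
        Z > threshold; "two-sided" clusters |Z| > threshold with
        sign-split clusters.
    unit : {"epoch", "trial"}
        Exchangeable unit of the random partition. Trial-level
        exchange is robust to within-trial autocorrelation.

    Fitted attributes: ``observed_stat_``, ``null_stats_``, ``p_value_``,
    ``clusters_``, ``z_``, ``result_``.
    """

    def __init__(
        self,
        electrode: str | None = None,
        emg: str | None = None,
        band: tuple[float, float] = BETA_BAND,
        threshold: float = 1.645,
        n_perm: int = 5000,
        alternative: str = "greater",
        nw: float = 2.0,
        k: int = 3,
        seed: int = 0,
        selection_aware: bool = False,
        unit: str = "epoch",
    ):
        self.electrode = electrode
        self.emg = emg
        self.band = band
        self.threshold = threshold
        self.n_perm = n_perm
        self.alternative = alternative
        self.nw = nw
        self.k = k
        self.seed = seed
        self.selection_aware = selection_aware
        self.unit = unit

    # -- helpers ---------------------------------------------------------

    def _peak_electrode(self, ep: EpochSet, emg_label: str, tapers) -> str:
        cohs = {}
        for i in ep.kind_indices("EEG"):
            lab = ep.channels[i][0]
            Sxy, Sxx, Syy = cross_products(ep.data[:, i, :], ep.channel(emg_label), tapers)
            C = coherence_from_products(Sxy, Sxx, Syy)
            freqs = np.fft.rfftfreq(ep.epoch_len, 1.0 / ep.fs)
            cohs[lab] = CoherenceSpectrum(
                pair=(lab, emg_label), freqs=freqs, C=C,
                d=2 * tapers.K * ep.n_epochs, L=ep.n_epochs, K=tapers.K,
            )
        return band_topography(cohs, self.band).peak_electrode

    def _group_units(self, ep: EpochSet, offset: int) -> list[np.ndarray]:
        """Exchangeable units as epoch-index groups (singletons or trials)."""
        if self.unit == "epoch":
            return [np.array([offset + i]) for i in range(ep.n_epochs)]
        if self.unit == "trial":
            if not ep.provenance:
                return [np.array([offset + i]) for i in range(ep.n_epochs)]
            groups: dict[tuple, list[int]] = {}
            for i, key in enumerate(ep.provenance):
                groups.setdefault(tuple(key), []).append(offset + i)
            return [np.array(v) for v in groups.values()]
        raise ParameterError(f"unknown permutation unit {self.unit!r}")

    # -- fitting ---------------------------------------------------------

    def fit(self, X: EpochSet, Y: EpochSet) -> "ClusterPermutationTest":
        if self.alternative not in ("greater", "two-sided"):
            raise ParameterError(f"unknown alternative {self.alternative!r}")
        if self.n_perm < 100:
            logger.warning(
                "n_perm=%d is very small; the Monte Carlo p has resolution %.3f",
                self.n_perm, 1.0 / (self.n_perm + 1),
            )
        X.same_layout(Y)
        if X.n_epochs == 0 or Y.n_epochs == 0:
            raise ParameterError("both epoch sets must be non-empty")
        emg_idx = X.kind_indices("EMG")
        if not emg_idx:
            raise PairingError("epoch sets carry no EMG channel")
        emg_label = self.emg or X.channels[emg_idx[0]][0]
        tapers = make_tapers(X.epoch_len, NW=self.nw, K=self.k)
        freqs = np.fft.rfftfreq(X.epoch_len, 1.0 / X.fs)
        lo, hi = self.band
        band_sel = np.flatnonzero((freqs >= lo) & (freqs <= hi))
        if band_sel.size == 0:
            raise BandError(f"band {self.band} outside the frequency grid")

        if self.electrode is not None:
            e1 = e2 = self.electrode
        else:
            e1 = self._peak_electrode(X, emg_label, tapers)
            e2 = self._peak_electrode(Y, emg_label, tapers)
        self.electrodes_ = (e1, e2)

        L1, L2 = X.n_epochs, Y.n_epochs
        two_sided = self.alternative == "two-sided"

        # per-epoch spectral products over the pooled segments
        emg_pool = np.concatenate([X.channel(emg_label), Y.channel(emg_label)])
        prods: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        eeg_labels = [X.channels[i][0] for i in X.kind_indices("EEG")]
        wanted = eeg_labels if self.selection_aware else sorted({e1, e2})
        for lab in wanted:
            pool = np.concatenate([X.channel(lab), Y.channel(lab)])
            Sxy, Sxx, Syy = cross_products(pool, emg_pool, tapers)
            prods[lab] = (Sxy[:, band_sel], Sxx[:, band_sel], Syy[:, band_sel])

        def group_coh(lab: str, idx: np.ndarray) -> np.ndarray:
            Sxy, Sxx, Syy = prods[lab]
            return coherence_from_products(Sxy[idx], Sxx[idx], Syy[idx])

        def stat_for(idx1: np.ndarray, idx2: np.ndarray, a: str, b: str) -> float:
            C1 = group_coh(a, idx1)
            C2 = group_coh(b, idx2)
            zb = _z_arrays(C1, C2, 2 * tapers.K * idx1.size, 2 * tapers.K * idx2.size)
            if not np.all(np.isfinite(zb)):
                raise FloatingPointError("non-finite cluster statistic")
            return _max_mass(zb, self.threshold, two_sided)

        def select_peak(idx: np.ndarray) -> str:
            means = {lab: float(group_coh(lab, idx).mean()) for lab in eeg_labels}
            return max(means, key=lambda lab: means[lab])

        obs1 = np.arange(L1)
        obs2 = np.arange(L1, L1 + L2)
        self.observed_stat_ = stat_for(obs1, obs2, e1, e2)

        units = self._group_units(X, 0) + self._group_units(Y, L1)
        n_units1 = len(self._group_units(X, 0))
        rng = np.random.default_rng(self.seed)
        null = np.empty(self.n_perm)
        for b in range(self.n_perm):
            order = rng.permutation(len(units))
            idx1 = np.concatenate([units[u] for u in order[:n_units1]])
            idx2 = np.concatenate([units[u] for u in order[n_units1:]])
            if self.selection_aware:
                a_lab, b_lab = select_peak(idx1), select_peak(idx2)
            else:
                a_lab, b_lab = e1, e2
            null[b] = stat_for(idx1, idx2, a_lab, b_lab)
        self.null_stats_ = null
        self.p_value_ = (1.0 + np.sum(null >= self.observed_stat_)) / (1.0 + self.n_perm)

        # full-grid observed z-spectrum and clusters for reporting
        tap_full = tapers
        x1 = X.channel(e1)
        x2 = Y.channel(e2)
        from .coherence import coherence_spectrum  # local import avoids cycle at module load

        C1 = coherence_spectrum(x1, X.channel(emg_label), tap_full, X.fs, pair=(e1, emg_label))
        C2 = coherence_spectrum(x2, Y.channel(emg_label), tap_full, Y.fs, pair=(e2, emg_label))
        self.z_ = z_difference(C1, C2)
        self.clusters_ = find_clusters(self.z_, self.threshold, self.band)
        self.result_ = PermutationResult(
            observed_stat=self.observed_stat_,
            null_stats=self.null_stats_,
            n_permutations=self.n_perm,
            p_mc=self.p_value_,
            seed=self.seed,
            direction=self.alternative,
            threshold=self.threshold,
            band=self.band,
            electrodes=self.electrodes_,
            clusters=self.clusters_,
            z=self.z_,
            spectra={X.condition: C1, Y.condition: C2},
        )
        return self


def permutation_test(
    epochs1: EpochSet,
    epochs2: EpochSet,
    electrode: str | None = None,
    n_perm: int = 5000,
    threshold: float = 1.645,
    band: tuple[float, float] = BETA_BAND,
    seed: int = 0,
    **kwargs,
) -> PermutationResult:
    """Functional wrapper around :class:`ClusterPermutationTest`."""
    test = ClusterPermutationTest(
        electrode=electrode,
        n_perm=n_perm,
        threshold=threshold,
        band=band,
        seed=seed,
        **kwargs,
    )
    test.fit(epochs1, epochs2)
    return test.result_
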