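"""Z-spectrum formula, frequency clustering and the random-partition test."""

import itertools
import logging
import math

import numpy as np
import pytest

from cmc import (
    ClusterPermutationTest,
    CoherenceSpectrum,
    EpochSet,
    ZSpectrum,
    find_clusters,
    max_cluster_stat,
    random_partition,
    z_difference,
)
from cmc.errors import BandError, DofError, PairingError, ParameterError


def spectrum(C, d=1080, freqs=None):
    C = np.asarray(C, dtype=float)
    freqs = np.arange(len(C), dtype=float) if freqs is None else np.asarray(freqs)
    return CoherenceSpectrum(pair=("E001", "EMG1"), freqs=freqs, C=C, d=d, L=d // 6, K=3)


class TestZDifference:
    def test_identical_inputs_give_zero(self):
        c = spectrum(np.linspace(0.1, 0.9, 20))
        assert np.all(z_difference(c, c).Z == 0.0)

    def test_printed_formula_value(self):
        # independent evaluation with math.atanh: n = 1/(d-2)
        z = z_difference(spectrum([0.5]), spectrum([0.3]))
        expected = (math.atanh(0.5) - math.atanh(0.3)) / math.sqrt(2.0 / 1078.0)
        assert z.Z[0] == pytest.approx(expected, rel=1e-12)
        assert z.n1 == pytest.approx(1.0 / 1078.0, rel=1e-15)

    def test_unequal_dof_bias_terms(self):
        z = z_difference(spectrum([0.4], d=1080), spectrum([0.4], d=362))
        n1, n2 = 1.0 / 1078, 1.0 / 360
        assert z.Z[0] == pytest.approx((n2 - n1) / math.sqrt(n1 + n2), rel=1e-12)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(0)
        a, b = spectrum(rng.uniform(0, 0.9, 30)), spectrum(rng.uniform(0, 0.9, 30))
        assert np.array_equal(z_difference(a, b).Z, -z_difference(b, a).Z)

    def test_coherence_one_is_finite(self):
        z = z_difference(spectrum([1.0]), spectrum([0.5]))
        assert np.isfinite(z.Z[0])

    def test_dof_guard(self):
        with pytest.raises(DofError):
            z_difference(spectrum([0.5], d=2), spectrum([0.5], d=1080))

    def test_grid_mismatch(self):
        with pytest.raises(PairingError):
            z_difference(spectrum([0.5, 0.5]), spectrum([0.5, 0.5], freqs=[3.0, 4.0]))


class TestClustering:
    def zspec(self, values):
        v = np.asarray(values, dtype=float)
        return ZSpectrum(freqs=np.arange(15.0, 15.0 + len(v)), Z=v, d1=1080, d2=1080)

    def test_two_clusters_by_hand(self):
        cs = find_clusters(self.zspec([0, 3, 3, 0, 3]), threshold=2, band=(15, 30))
        assert [(a, b) for a, b, _ in cs.clusters] == [(1, 2), (4, 4)]
        assert cs.masses() == [6.0, 3.0]
        assert max_cluster_stat(cs) == 6.0

    def test_all_below_threshold(self):
        cs = find_clusters(self.zspec([1.0, 0.5, -2.0]), threshold=2, band=(15, 30))
        assert cs.clusters == []
        assert max_cluster_stat(cs) == 0.0

    def test_equal_to_threshold_excluded(self):
        cs = find_clusters(self.zspec([2.0, 2.0, 2.0]), threshold=2, band=(15, 30))
        assert cs.clusters == []

    def test_band_restriction(self):
        z = ZSpectrum(freqs=np.arange(0.0, 50.0), Z=np.full(50, 5.0), d1=1080, d2=1080)
        cs = find_clusters(z, threshold=2, band=(15, 30))
        assert [(a, b) for a, b, _ in cs.clusters] == [(15, 30)]
        assert cs.masses()[0] == pytest.approx(16 * 5.0)

    def test_empty_band(self):
        with pytest.raises(BandError):
            find_clusters(self.zspec([1.0]), threshold=2, band=(100, 200))


def tiny_epochs(n, seed=0, condition="a"):
    rng = np.random.default_rng(seed)
    return EpochSet(
        condition=condition,
        fs=64.0,
        data=rng.standard_normal((n, 2, 64)),
        channels=[("E001", "EEG"), ("EMG1", "EMG")],
        provenance=[(0, i) for i in range(n)],
    )


class TestRandomPartition:
    def test_conservation(self):
        a, b = tiny_epochs(5, 1), tiny_epochs(3, 2, "b")
        ra, rb = random_partition(a, b, np.random.default_rng(0))
        assert (ra.n_epochs, rb.n_epochs) == (5, 3)
        pooled = np.concatenate([a.data, b.data]).reshape(8, -1)
        out = np.concatenate([ra.data, rb.data]).reshape(8, -1)
        # same multiset of epochs: sorted row fingerprints match
        assert np.allclose(np.sort(pooled.sum(axis=1)), np.sort(out.sum(axis=1)))

    def test_deterministic_under_rng_state(self):
        a, b = tiny_epochs(5, 1), tiny_epochs(3, 2, "b")
        r1 = random_partition(a, b, np.random.default_rng(9))
        r2 = random_partition(a, b, np.random.default_rng(9))
        assert np.array_equal(r1[0].data, r2[0].data)

    def test_uniform_over_assignments(self):
        """With sizes (2,2) every one of the 6 splits appears ~1/6 of draws."""
        a, b = tiny_epochs(2, 1), tiny_epochs(2, 2, "b")
        ids = {a.data[i, 0, 0]: i for i in range(2)}
        ids.update({b.data[i, 0, 0]: i + 2 for i in range(2)})
        rng = np.random.default_rng(3)
        counts = {frozenset(pair): 0 for pair in itertools.combinations(range(4), 2)}
        n_draws = 1000
        for _ in range(n_draws):
            ra, _ = random_partition(a, b, rng)
            counts[frozenset(ids[v] for v in ra.data[:, 0, 0])] += 1
        for c in counts.values():
            assert abs(c / n_draws - 1 / 6) < 0.05


class TestPermutationTest:
    def coupled_pair(self, gain2=4.0, n=40, seed=0):
        """Two conditions sharing a 20 Hz drive, condition 1 more coherent."""
        rng = np.random.default_rng(seed)

        def make(n_ep, gain, condition):
            t = np.arange(64) / 64.0
            data = np.empty((n_ep, 2, 64))
            for i in range(n_ep):
                phase = rng.uniform(0, 2 * np.pi)
                drive = np.sin(2 * np.pi * 20 * t + phase)
                data[i, 0] = gain * drive + rng.standard_normal(64)
                data[i, 1] = gain * drive + rng.standard_normal(64)
            return EpochSet(condition=condition, fs=64.0, data=data,
                            channels=[("E001", "EEG"), ("EMG1", "EMG")])

        return make(n, gain2, "strong"), make(n, 0.0, "weak")

    def test_addone_floor(self):
        ep1, ep2 = self.coupled_pair()
        fit = ClusterPermutationTest(electrode="E001", n_perm=200, seed=1,
                                     band=(15, 30)).fit(ep1, ep2)
        assert fit.observed_stat_ > 0
        assert fit.p_value_ == pytest.approx(1.0 / 201.0)
        assert len(fit.null_stats_) == 200

    def test_epoch_order_invariance(self):
        ep1, ep2 = self.coupled_pair()
        fit_a = ClusterPermutationTest(electrode="E001", n_perm=50, seed=2).fit(ep1, ep2)
        shuffled = ep1.subset(np.random.default_rng(0).permutation(ep1.n_epochs))
        fit_b = ClusterPermutationTest(electrode="E001", n_perm=50, seed=2).fit(shuffled, ep2)
        assert fit_a.observed_stat_ == pytest.approx(fit_b.observed_stat_, rel=1e-12)

    def test_two_sided_detects_reversed_effect(self):
        ep1, ep2 = self.coupled_pair()
        one_sided = ClusterPermutationTest(electrode="E001", n_perm=100, seed=3).fit(ep2, ep1)
        two_sided = ClusterPermutationTest(electrode="E001", n_perm=100, seed=3,
                                           alternative="two-sided").fit(ep2, ep1)
        assert one_sided.observed_stat_ == 0.0
        assert two_sided.observed_stat_ > 0.0
        assert two_sided.p_value_ <= 0.05

    def test_small_n_perm_warns(self, caplog):
        ep1, ep2 = self.coupled_pair(n=10)
        with caplog.at_level(logging.WARNING, logger="cmc.cluster_stats"):
            ClusterPermutationTest(electrode="E001", n_perm=20, seed=0).fit(ep1, ep2)
        assert any("n_perm" in r.message for r in caplog.records)

    def test_trial_unit_partition(self):
        ep1, ep2 = self.coupled_pair()
        fit = ClusterPermutationTest(electrode="E001", n_perm=50, seed=4,
                                     unit="trial").fit(ep1, ep2)
        assert 0 < fit.p_value_ <= 1

    def test_unknown_alternative(self):
        ep1, ep2 = self.coupled_pair(n=10)
        with pytest.raises(ParameterError):
            ClusterPermutationTest(electrode="E001", alternative="less",
                                   n_perm=100).fit(ep1, ep2)
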