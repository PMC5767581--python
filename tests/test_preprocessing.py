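"""Filter design/application, ICA artifact scoring and segmentation rules."""

import numpy as np
import pytest

from cmc import (
    ArtifactFlags,
    IcaArtifactRemover,
    Recording,
    SimulationParams,
    design_bandpass,
    filter_twopass,
    fit_ica,
    remove_components,
    score_artifacts,
    segment_epochs,
    simulate_session,
)
from cmc.errors import (
    DegenerateSignalError,
    DesignError,
    EmptySetError,
    LengthError,
    RankError,
)


def direct_dft_gain(taps, f, fs):
    """Frequency response by direct summation (independent of scipy.freqz)."""
    n = np.arange(taps.size)
    return abs(np.sum(taps * np.exp(-2j * np.pi * f * n / fs)))


class TestFilterDesign:
    def test_response_by_direct_dft(self):
        k = design_bandpass(1000.0, 3.0, 45.0)
        assert 0.99 <= direct_dft_gain(k.coefficients, 20.0, 1000.0) <= 1.01
        assert direct_dft_gain(k.coefficients, 1.5, 1000.0) <= 0.01
        assert direct_dft_gain(k.coefficients, 50.0, 1000.0) <= 0.01

    def test_linear_phase_symmetry(self):
        taps = design_bandpass(1000.0, 3.0, 45.0).coefficients
        assert np.array_equal(taps, taps[::-1])

    def test_infeasible_band(self):
        with pytest.raises(DesignError):
            design_bandpass(1000.0, 45.0, 3.0)


@pytest.fixture(scope="module")
def kernel():
    return design_bandpass(1000.0, 3.0, 45.0)


@pytest.fixture(scope="module")
def ica_session():
    p = SimulationParams(montage_size=10, n_trials=3, n_runs=1, seed=3)
    return simulate_session(p)


class TestTwoPass:
    def two_channel(self, data):
        chans = [(f"E{i + 1:03d}", "EEG") for i in range(data.shape[0])]
        return Recording(fs=1000.0, channels=chans, data=data)

    def test_passband_sinusoid_zero_lag(self, kernel):
        t = np.arange(20000) / 1000.0
        s = np.sin(2 * np.pi * 20.0 * t)
        out = filter_twopass(kernel, self.two_channel(s[None, :])).data[0]
        mid = slice(5000, 15000)
        xc = np.correlate(out[mid], s[mid], "full")
        assert np.argmax(xc) == len(s[mid]) - 1  # lag exactly 0 samples
        assert abs(out[mid].std() / s[mid].std() - 1) < 0.02

    def test_stopband_sinusoid_suppressed(self, kernel):
        t = np.arange(20000) / 1000.0
        s = np.sin(2 * np.pi * 1.0 * t)
        out = filter_twopass(kernel, self.two_channel(s[None, :])).data[0]
        assert out[5000:15000].std() <= 0.01 * s[5000:15000].std()

    def test_zero_in_zero_out(self, kernel):
        out = filter_twopass(kernel, self.two_channel(np.zeros((1, 15000))))
        assert np.all(out.data == 0.0)

    def test_force_passthrough(self, kernel):
        rng = np.random.default_rng(0)
        rec = Recording(
            fs=1000.0,
            channels=[("E001", "EEG"), ("FORCE1", "FORCE")],
            data=rng.standard_normal((2, 15000)),
        )
        out = filter_twopass(kernel, rec)
        assert np.array_equal(out.data[1], rec.data[1])
        assert not np.array_equal(out.data[0], rec.data[0])

    def test_phase_stability_under_repeat(self, kernel):
        """Filtering twice moves passband phase by < 0.01 rad."""
        t = np.arange(30000) / 1000.0
        mid = slice(5000, 25000)
        for f0 in (10.0, 20.0, 30.0, 40.0):
            rec = self.two_channel(np.sin(2 * np.pi * f0 * t)[None, :])
            once = filter_twopass(kernel, rec).data[0, mid]
            twice = filter_twopass(kernel, filter_twopass(kernel, rec)).data[0, mid]
            probe = np.exp(-2j * np.pi * f0 * t[mid])
            dphi = np.angle(np.sum(twice * probe) / np.sum(once * probe))
            assert abs(dphi) < 0.01

    def test_too_short_signal(self, kernel):
        with pytest.raises(LengthError):
            filter_twopass(kernel, self.two_channel(np.zeros((1, 1000))))


class TestIca:
    def test_full_reconstruction(self, ica_session):
        rec, _ = ica_session
        d = fit_ica(rec, seed=0)
        recon = d.mixing @ d.sources + d.mean[:, None]
        eeg = rec.data[rec.kind_indices("EEG")]
        assert np.abs(recon - eeg).max() / np.abs(eeg).max() < 1e-6

    def test_unmixing_mixing_identity(self, ica_session):
        rec, _ = ica_session
        d = fit_ica(rec, seed=0)
        assert np.abs(d.unmixing @ d.mixing - np.eye(d.n_components)).max() < 1e-6

    def test_deterministic(self, ica_session):
        rec, _ = ica_session
        d1 = fit_ica(rec, seed=5)
        d2 = fit_ica(rec, seed=5)
        assert np.array_equal(d1.unmixing, d2.unmixing)

    def test_duplicated_channel_rank_error(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((2, 2000))
        data = np.vstack([base, base[1:]])  # exact copy of channel 2
        rec = Recording(
            fs=1000.0,
            channels=[("E001", "EEG"), ("E002", "EEG"), ("E003", "EEG")],
            data=data,
        )
        with pytest.raises(RankError):
            fit_ica(rec)

    def test_reject_none_is_identity(self, ica_session):
        rec, _ = ica_session
        d = fit_ica(rec, seed=0)
        out = remove_components(d, rec, [])
        eeg = rec.kind_indices("EEG")
        assert np.abs(out.data[eeg] - rec.data[eeg]).max() / np.abs(rec.data).max() < 1e-6

    def test_reject_all_errors(self, ica_session):
        rec, _ = ica_session
        d = fit_ica(rec, seed=0)
        with pytest.raises(DegenerateSignalError):
            remove_components(d, rec, list(range(d.n_components)))


class TestArtifactScores:
    def test_line_component_scored_and_removed(self):
        # ICA separation quality grows with sensor count; 24 channels is
        # the small end of realistic EEG caps
        p = SimulationParams(
            montage_size=24, n_trials=3, n_runs=1, seed=11,
            artifacts=ArtifactFlags(line50=True),
        )
        rec, truth = simulate_session(p)
        d = fit_ica(rec, seed=0)
        scores = score_artifacts(d, rec, montage=truth.montage)
        assert scores["line"].max() > 0.8
        assert np.sort(scores["line"])[-2] < 0.1  # all other components clean
        cleaned = remove_components(d, rec, np.flatnonzero(scores["line"] > 0.7))

        def band_power(x, lo, hi):
            f = np.fft.rfftfreq(x.shape[-1], 1 / rec.fs)
            P = np.abs(np.fft.rfft(x, axis=-1)) ** 2
            return P[..., (f >= lo) & (f <= hi)].sum()

        eeg = rec.kind_indices("EEG")
        assert band_power(cleaned.data[eeg], 49, 51) < 0.1 * band_power(rec.data[eeg], 49, 51)
        beta_before = band_power(rec.data[eeg], 15, 30)
        beta_after = band_power(cleaned.data[eeg], 15, 30)
        assert abs(beta_after - beta_before) < 0.1 * beta_before

    def test_artifact_free_scores_below_threshold(self):
        p = SimulationParams(montage_size=10, n_trials=3, n_runs=1, seed=12)
        rec, truth = simulate_session(p)
        d = fit_ica(rec, seed=0)
        scores = score_artifacts(d, rec, montage=truth.montage)
        assert scores["blink"].max() < 0.7
        assert scores["line"].max() < 0.7

    def test_constant_component_scores_zero(self):
        p = SimulationParams(montage_size=10, n_trials=3, n_runs=1, seed=13)
        rec, _ = simulate_session(p)
        d = fit_ica(rec, seed=0)
        d.sources[0] = 0.0
        scores = score_artifacts(d, rec)
        assert scores["blink"][0] == 0.0
        assert scores["ecg"][0] == 0.0
        assert scores["line"][0] == 0.0

    def test_auto_rejection_rate_on_clean_data(self):
        """Artifact-free sessions: the auto-remover rejects 0 components
        in at least 95% of seeds."""
        clean = 0
        seeds = range(20)
        for s in seeds:
            p = SimulationParams(montage_size=10, n_trials=2, n_runs=1, seed=100 + s)
            rec, truth = simulate_session(p)
            fitter = IcaArtifactRemover(seed=s, montage=truth.montage).fit(rec)
            clean += len(fitter.reject_) == 0
        assert clean >= 19


class TestSegmentation:
    def synthetic_trials(self, trial_lengths_s, fs=100.0, gap_s=2.0):
        events, cursor = [], 0
        for L in trial_lengths_s:
            events.append((cursor, "trial_start"))
            cursor += int(L * fs)
            events.append((cursor, "trial_end"))
            cursor += int(gap_s * fs)
        data = np.zeros((1, cursor + 10))
        return Recording(fs=fs, channels=[("E001", "EEG")], data=data, events=events)

    def test_single_trial_count(self):
        ep = segment_epochs(self.synthetic_trials([11.0]))
        assert ep.n_epochs == 9  # floor((11 - 2) / 1)

    def test_run_counts(self):
        ep = segment_epochs(self.synthetic_trials([11.0] * 20))
        assert ep.n_epochs == 180

    def test_short_trial_contributes_zero(self):
        ep = segment_epochs(self.synthetic_trials([2.5, 11.0]))
        assert ep.n_epochs == 9
        assert all(t == 1 for _, t in ep.provenance)

    def test_exact_count_formula(self):
        lengths = [11.0, 7.3, 2.5, 4.0, 3.01]
        ep = segment_epochs(self.synthetic_trials(lengths))
        expected = sum(int(max(L - 2.0, 0) // 1.0) for L in lengths)
        assert ep.n_epochs == expected

    def test_all_short_raises(self):
        with pytest.raises(EmptySetError):
            segment_epochs(self.synthetic_trials([2.5, 1.0]))

    def test_epochs_within_contraction_window(self, small_session):
        rec, _ = small_session
        ep = segment_epochs(rec)
        trials = rec.trials()
        n_expected = sum((b - a - 2000) // 1000 for a, b in trials)
        assert ep.n_epochs == n_expected
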