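"""Synthetic two-session elbow-flexion recordings with known coherence.

The generator emulates a constant-force elbow-flexion protocol: 11-s
trials separated by 2-s gaps, 20 trials per run, two runs per session,
EEG/EMG sampled at 1000 Hz with a 3-N force channel and trial markers.

Generative model
----------------
A shared cortical source ``s(t)`` is a sum of narrowband Gaussian
processes (white noise band-pass filtered around beta-band peak
frequencies). Scalp channel *i* records ``e_i = g_i s + n_i`` with a
spatial gain ``g_i = exp(-decay * greatcircle(i, target))`` peaked at a
designated "motor cortex" electrode; the EMG records
``m = envelope * (kappa * s(t - delay) + w)``, amplitude-modulated to be
silent outside contraction windows. Because mixing is linear with
independent white channel noise, the magnitude coherence between channel
*i* and the EMG has the closed form

    C_i(f) = g_i kappa S(f) / sqrt((g_i^2 S + sigma_e^2)(kappa^2 S + sigma_m^2))

with ``S(f)`` the source spectrum in driving-noise units — the analytic
ground truth every estimator downstream is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .containers import Recording, TRIAL_END, TRIAL_START
from .errors import DegenerateSignalError, MontageError, ParameterError
from .montage import Montage

# approximate hand-area motor cortex directions, ~40 deg lateral of vertex
_MOTOR_RIGHT = np.array([math.sin(math.radians(40)), 0.0, math.cos(math.radians(40))])
_MOTOR_LEFT = np.array([-math.sin(math.radians(40)), 0.0, math.cos(math.radians(40))])


@dataclass
class ArtifactFlags:
    blink: bool = False
    ecg: bool = False
    line50: bool = False


@dataclass
class SimulationParams:
    """Study conditions for one simulated session.

    Defaults mirror the recording protocol (1000 Hz, 11-s trials, 2-s
    gaps, 20 trials/run, 2 runs, 128 electrodes) with moderately strong
    beta-band coupling: ``coupling_gain = 1`` puts the peak coherence at
    the target electrode near 0.5.
    """

    fs: float = 1000.0
    n_trials: int = 20
    n_runs: int = 2
    trial_s: float = 11.0
    gap_s: float = 2.0
    contraction_delay_s: float = 2.0
    montage_size: int = 128
    target_electrode: str | None = None
    peak_freqs_Hz: tuple[float, ...] = (18.0, 24.0)
    coupling_gain: float = 1.0
    source_bandwidth_Hz: float = 4.0
    source_scale_uV: float = 20.0
    eeg_noise_sd: float = 20.0
    emg_noise_sd: float = 20.0
    spatial_decay: float = 2.0
    artifacts: ArtifactFlags = field(default_factory=ArtifactFlags)
    conduction_delay_ms: float = 10.0
    side: str = "affected"
    session: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("fs", "trial_s", "gap_s", "contraction_delay_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_trials < 1 or self.n_runs < 1:
            raise ParameterError("n_trials and n_runs must be at least 1")
        if self.coupling_gain < 0:
            raise ParameterError("coupling_gain must be non-negative")
        for f in self.peak_freqs_Hz:
            if not 0 < f < self.fs / 2:
                raise ParameterError(f"peak frequency {f} outside (0, fs/2)")
        if self.source_bandwidth_Hz <= 0:
            raise ParameterError("source_bandwidth_Hz must be positive")
        if self.eeg_noise_sd < 0 or self.emg_noise_sd < 0:
            raise ParameterError("noise SDs must be non-negative")
        if self.coupling_gain == 0 and self.eeg_noise_sd == 0 and self.emg_noise_sd == 0:
            raise DegenerateSignalError(
                "coupling and both noise levels are zero: signals would be degenerate"
            )
        if self.side not in ("affected", "unaffected"):
            raise ParameterError(f"side must be 'affected' or 'unaffected', got {self.side!r}")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated session."""

    params: SimulationParams
    montage: Montage
    target_electrode: str
    gains: dict[str, float]
    freqs: np.ndarray
    expected_coherence_target: np.ndarray

    def expected_coherence(self, channel: str, freqs: np.ndarray | None = None) -> np.ndarray:
        return expected_coherence(self.params, channel, freqs=freqs)[1]


def make_montage(n: int) -> Montage:
    """Quasi-uniform n-electrode cap (Fibonacci spiral on z >= -0.2).

    Deterministic for a given n; labels are ``E001`` ... ``E{n}``. This
    is an idealised stand-in for a 128-channel geodesic net: realistic
    digitised positions are out of scope, but the spacing statistics are
    comparable.
    """
    if n < 8:
        raise MontageError(f"montage needs at least 8 electrodes, got {n}")
    i = np.arange(n)
    z = 1.0 - 1.2 * (i + 0.5) / n  # uniform in z over the cap [-0.2, 1]
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = i * golden
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    labels = [f"E{k + 1:03d}" for k in range(n)]
    return Montage(labels=labels, positions=pos, reference_label="Cz")


def _source_sos(p: SimulationParams) -> list[np.ndarray]:
    """Second-order-section band-pass filters shaping each source peak."""
    out = []
    for f0 in p.peak_freqs_Hz:
        lo = max(f0 - p.source_bandwidth_Hz, 0.1)
        hi = min(f0 + p.source_bandwidth_Hz, p.fs / 2 - 0.1)
        out.append(signal.butter(2, [lo, hi], btype="bandpass", fs=p.fs, output="sos"))
    return out


def source_spectrum(p: SimulationParams, freqs: np.ndarray) -> np.ndarray:
    """Source power spectrum S(f) in driving-noise units (scale^2 |H|^2)."""
    S = np.zeros_like(freqs, dtype=float)
    for sos in _source_sos(p):
        _, h = signal.sosfreqz(sos, worN=freqs, fs=p.fs)
        S += np.abs(h) ** 2
    return p.source_scale_uV**2 * S


def _target_label(p: SimulationParams, mont: Montage) -> str:
    if p.target_electrode is not None:
        mont.index(p.target_electrode)  # raises if absent
        return p.target_electrode
    # contralateral motor cortex: affected = left limb -> right hemisphere
    direction = _MOTOR_RIGHT if p.side == "affected" else _MOTOR_LEFT
    return mont.nearest(direction)


def channel_gains(p: SimulationParams, mont: Montage, target: str) -> np.ndarray:
    d = mont.great_circle_to_point(mont.positions[mont.index(target)])
    return np.exp(-p.spatial_decay * d)


def expected_coherence(
    p: SimulationParams,
    channel: str,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form EEG-channel/EMG magnitude coherence for the model.

    Returns ``(freqs, C)`` on a 1-Hz grid up to fs/2 by default. The
    curve is identically zero when the coupling gain is zero, lies in
    [0, 1], and increases monotonically with the coupling gain wherever
    it is strictly between 0 and 1.
    """
    p.validate()
    if freqs is None:
        freqs = np.arange(0.0, p.fs / 2 + 0.5, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    mont = make_montage(p.montage_size)
    target = _target_label(p, mont)
    g = channel_gains(p, mont, target)[mont.index(channel)]
    S = source_spectrum(p, freqs)
    kappa = p.coupling_gain
    num = g * kappa * S
    den = np.sqrt((g**2 * S + p.eeg_noise_sd**2) * (kappa**2 * S + p.emg_noise_sd**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return freqs, np.clip(C, 0.0, 1.0)


def _trial_layout(p: SimulationParams) -> tuple[int, list[tuple[int, int, int]]]:
    """Total samples and (run, start, end) sample windows for every trial."""
    fs = p.fs
    trial_n = int(round(p.trial_s * fs))
    gap_n = int(round(p.gap_s * fs))
    trials = []
    cursor = 0
    for run in range(p.n_runs):
        for _ in range(p.n_trials):
            trials.append((run, cursor, cursor + trial_n))
            cursor += trial_n + gap_n
    return cursor, trials


def _envelope(p: SimulationParams, n_total: int, trials) -> np.ndarray:
    env = np.zeros(n_total)
    ramp_n = int(round(p.contraction_delay_s * p.fs))
    for _, start, end in trials:
        ramp_end = min(start + ramp_n, end)
        env[start:ramp_end] = np.linspace(0.0, 1.0, ramp_end - start, endpoint=False)
        env[ramp_end:end] = 1.0
    return env


def _add_artifacts(
    p: SimulationParams,
    mont: Montage,
    eeg: np.ndarray,
    rng: np.random.Generator,
) -> None:
    n = eeg.shape[1]
    fs = p.fs
    if p.artifacts.blink:
        # ~0.3 Hz Poisson blink train, 300-ms raised-cosine lobes, frontal-weighted
        frontal_w = np.clip(mont.positions[:, 1], 0.0, None) ** 2
        width = int(0.3 * fs)
        pulse = 150.0 * np.hanning(width)
        n_blinks = rng.poisson(0.3 * n / fs)
        for t in rng.integers(0, max(n - width, 1), size=n_blinks):
            eeg[:, t : t + width] += frontal_w[:, None] * pulse[None, : n - t][:, : eeg.shape[1] - t]
    if p.artifacts.ecg:
        # ~1.2 Hz spike train broadcast at low gain to every channel
        period = fs / 1.2
        spike_w = int(0.02 * fs)
        spike = 50.0 * signal.windows.gaussian(spike_w, std=spike_w / 6)
        train = np.zeros(n)
        t = float(rng.uniform(0, period))
        while t < n - spike_w:
            ti = int(t)
            train[ti : ti + spike_w] += spike
            t += period * (1.0 + 0.02 * rng.standard_normal())
        eeg += 0.1 * train[None, :]
    if p.artifacts.line50:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * math.pi)
        gains = rng.uniform(0.5, 1.5, size=eeg.shape[0])
        eeg += 30.0 * gains[:, None] * np.sin(2 * math.pi * 50.0 * t + phase)[None, :]


def simulate_session(p: SimulationParams) -> tuple[Recording, SimulationTruth]:
    """Generate one session and its ground truth, reproducibly from the seed."""
    p.validate()
    rng = np.random.default_rng(p.seed)
    fs = p.fs
    mont = make_montage(p.montage_size)
    target = _target_label(p, mont)
    gains = channel_gains(p, mont, target)
    n_total, trials = _trial_layout(p)

    # shared narrowband source, driving-noise units scaled to µV
    source = np.zeros(n_total)
    for sos in _source_sos(p):
        source += signal.sosfilt(sos, rng.standard_normal(n_total))
    source *= p.source_scale_uV

    eeg = gains[:, None] * source[None, :]
    if p.eeg_noise_sd > 0:
        eeg = eeg + p.eeg_noise_sd * rng.standard_normal(eeg.shape)

    delay_n = int(round(p.conduction_delay_ms * fs / 1000.0))
    s_delayed = np.zeros(n_total)
    s_delayed[delay_n:] = source[: n_total - delay_n]
    env = _envelope(p, n_total, trials)
    emg = p.coupling_gain * s_delayed
    if p.emg_noise_sd > 0:
        emg = emg + p.emg_noise_sd * rng.standard_normal(n_total)
    emg = env * emg

    force = 3.0 * env
    jitter = signal.sosfilt(
        signal.butter(2, 5.0, btype="lowpass", fs=fs, output="sos"),
        rng.standard_normal(n_total),
    )
    jitter *= 0.05 / max(np.std(jitter), 1e-12)
    force = force + env * jitter

    _add_artifacts(p, mont, eeg, rng)

    data = np.vstack([eeg, emg[None, :], force[None, :]])
    channels = [(lab, "EEG") for lab in mont.labels] + [("EMG1", "EMG"), ("FORCE1", "FORCE")]
    events: list[tuple[int, str]] = []
    for _, start, end in trials:
        events.append((start, TRIAL_START))
        events.append((end, TRIAL_END))
    rec = Recording(
        fs=fs,
        channels=channels,
        data=data,
        events=events,
        meta={
            "side": p.side,
            "session": p.session,
            "n_trials_per_run": p.n_trials,
            "seed": p.seed,
        },
    )
    freqs, curve = expected_coherence(p, target)
    truth = SimulationTruth(
        params=replace(p),
        montage=mont,
        target_electrode=target,
        gains=dict(zip(mont.labels, gains)),
        freqs=freqs,
        expected_coherence_target=curve,
    )
    return rec, truth
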