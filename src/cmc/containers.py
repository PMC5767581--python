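"""In-memory containers: multichannel recordings and epoched data.

A :class:`Recording` is a continuous multichannel timeseries (EEG in µV,
EMG in µV, force in N) with trial event markers. An :class:`EpochSet` is a
stack of fixed-length artifact-cleaned segments cut from the contraction
period — the unit of spectral averaging and of permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CmcError, PairingError

CHANNEL_KINDS = ("EEG", "EMG", "FORCE")
TRIAL_START = "trial_start"
TRIAL_END = "trial_end"


@dataclass
class Recording:
    """Continuous multichannel recording with trial markers.

    Attributes
    ----------
    fs : float
        Sampling rate, Hz.
    channels : list of (label, kind)
        Channel labels with kind in ``{"EEG", "EMG", "FORCE"}``, in data
        row order.
    data : ndarray, shape (n_channels, n_samples)
        Sample values; µV for EEG/EMG, N for FORCE.
    events : list of (sample_index, code)
        Trial markers sorted by sample index; indices are 0-based and the
        trial window ``[start, end)`` is half-open.
    meta : dict
        Free-form provenance (e.g. side, session, trials per run).
    """

    fs: float
    channels: list[tuple[str, str]]
    data: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise CmcError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise CmcError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} "
                f"rows but {len(self.channels)} channels are declared"
            )
        for _, kind in self.channels:
            if kind not in CHANNEL_KINDS:
                raise CmcError(f"unknown channel kind {kind!r}")
        self.events = sorted(self.events, key=lambda e: e[0])
        self._check_trials()

    def _check_trials(self) -> None:
        depth = 0
        for _, code in self.events:
            if code == TRIAL_START:
                depth += 1
            elif code == TRIAL_END:
                depth -= 1
                if depth < 0:
                    raise CmcError("trial_end without a preceding trial_start")
        if depth != 0:
            raise CmcError("unmatched trial_start marker")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.channels]

    def kind_indices(self, kind: str) -> list[int]:
        return [i for i, (_, k) in enumerate(self.channels) if k == kind]

    def channel_index(self, label: str) -> int:
        for i, (lab, _) in enumerate(self.channels):
            if lab == label:
                return i
        raise CmcError(f"channel {label!r} not in recording")

    def trials(self) -> list[tuple[int, int]]:
        """(start, end) sample pairs for every trial, half-open."""
        out, stack = [], []
        for idx, code in self.events:
            if code == TRIAL_START:
                stack.append(idx)
            elif code == TRIAL_END:
                out.append((stack.pop(), idx))
        return sorted(out)

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            fs=self.fs,
            channels=list(self.channels),
            data=data,
            events=list(self.events),
            meta=dict(self.meta),
        )


@dataclass
class EpochSet:
    """Stack of fixed-length segments used for spectral estimation.

    ``data`` has shape (n_epochs, n_channels, epoch_len); all epochs come
    from within the contraction period of a trial and never overlap.
    ``provenance`` records (run, trial) per epoch.
    """

    condition: str
    fs: float
    data: np.ndarray
    channels: list[tuple[str, str]]
    provenance: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise CmcError("epoch data must be (epochs, channels, samples)")
        if self.data.shape[1] != len(self.channels):
            raise CmcError("epoch channel axis does not match channel list")
        if self.provenance and len(self.provenance) != self.data.shape[0]:
            raise CmcError("provenance length does not match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.data.shape[2]

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.channels]

    def kind_indices(self, kind: str) -> list[int]:
        return [i for i, (_, k) in enumerate(self.channels) if k == kind]

    def channel_index(self, label: str) -> int:
        for i, (lab, _) in enumerate(self.channels):
            if lab == label:
                return i
        raise CmcError(f"channel {label!r} not in epoch set")

    def channel(self, label: str) -> np.ndarray:
        """Epochs for one channel, shape (n_epochs, epoch_len)."""
        return self.data[:, self.channel_index(label), :]

    def same_layout(self, other: "EpochSet") -> None:
        if self.channels != other.channels:
            raise PairingError("epoch sets have different channel layouts")
        if self.epoch_len != other.epoch_len or self.fs != other.fs:
            raise PairingError("epoch sets have different epoch geometry")

    def subset(self, idx: np.ndarray, condition: str | None = None) -> "EpochSet":
        idx = np.asarray(idx, dtype=int)
        prov = [self.provenance[i] for i in idx] if self.provenance else []
        return EpochSet(
            condition=condition or self.condition,
            fs=self.fs,
            data=self.data[idx],
            channels=list(self.channels),
            provenance=prov,
        )
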