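"""Electrode montage: labelled unit-sphere positions.

The scalp is idealised as a unit sphere. Positions are dimensionless
Cartesian triples with |r| = 1; angular separations are great-circle
distances in radians. The recording reference (``Cz`` at the vertex by
convention) need not be a measurement electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MontageError

MIN_ELECTRODES = 8


@dataclass
class Montage:
    """Labelled electrode positions on the unit sphere.

    Parameters
    ----------
    labels : list of str
        Unique electrode identifiers, order preserved.
    positions : ndarray, shape (n, 3)
        Unit-norm Cartesian positions. Convention: +x right, +y anterior,
        +z up, so the vertex is (0, 0, 1).
    reference_label : str
        Label of the recording reference position; defaults to ``Cz``.
    """

    labels: list[str]
    positions: np.ndarray
    reference_label: str = "Cz"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise MontageError("duplicate electrode labels in montage")
        if len(self.labels) < MIN_ELECTRODES:
            raise MontageError(
                f"montage has {len(self.labels)} electrodes; "
                f"at least {MIN_ELECTRODES} are required for spline fitting"
            )
        if self.positions.shape != (len(self.labels), 3):
            raise MontageError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.labels)} labels"
            )
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise MontageError("positions must lie on the unit sphere (|r| = 1)")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise MontageError(f"electrode {label!r} not in montage") from None

    def cosine_angles(self) -> np.ndarray:
        """Pairwise cos(angle) matrix, clipped to [-1, 1]."""
        c = self.positions @ self.positions.T
        return np.clip(c, -1.0, 1.0)

    def great_circle(self, a: str, b: str) -> float:
        """Great-circle distance between two electrodes, radians."""
        ca = self.positions[self.index(a)] @ self.positions[self.index(b)]
        return float(np.arccos(np.clip(ca, -1.0, 1.0)))

    def great_circle_to_point(self, point: np.ndarray) -> np.ndarray:
        """Great-circle distance from every electrode to a unit vector."""
        p = np.asarray(point, dtype=float)
        p = p / np.linalg.norm(p)
        return np.arccos(np.clip(self.positions @ p, -1.0, 1.0))

    def nearest(self, point: np.ndarray) -> str:
        """Label of the electrode nearest to a direction vector."""
        return self.labels[int(np.argmin(self.great_circle_to_point(point)))]
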