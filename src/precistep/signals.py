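"""In-memory containers for raw kinematic and kinetic signals."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MARKER_NAMES", "FEET", "COPTrajectory", "MarkerTrajectories"]

MARKER_NAMES = ("toe", "malleolus", "heel")
FEET = ("left", "right")


@dataclass
class COPTrajectory:
    """Center-of-pressure trajectory on the force platform.

    ``ap``/``ml`` are lab-frame positions in meters (AP positive in the
    walking direction, ML positive to the walker's left), sampled at
    ``rate`` Hz on the ``time`` grid (seconds from recording start).
    """

    time: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    rate: float = 1000.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.ap = np.asarray(self.ap, float)
        self.ml = np.asarray(self.ml, float)
        if not (self.time.shape == self.ap.shape == self.ml.shape):
            raise ValueError("time, ap and ml must have identical shapes")


@dataclass
class MarkerTrajectories:
    """3D shoe-marker trajectories (toe = 3rd metatarsal head, lateral
    malleolus, heel on each foot), in meters, sampled at ``rate`` Hz.

    ``positions[foot][marker]`` is an (n, 3) array of (ap, ml, vertical)
    coordinates on the ``time`` grid.
    """

    time: np.ndarray
    positions: dict[str, dict[str, np.ndarray]]
    rate: float = 150.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        n = self.time.shape[0]
        for foot in FEET:
            if foot not in self.positions:
                raise ValueError(f"missing foot {foot!r}")
            for m in MARKER_NAMES:
                arr = np.asarray(self.positions[foot][m], float)
                if arr.shape != (n, 3):
                    raise ValueError(
                        f"{foot}/{m} must have shape ({n}, 3), got {arr.shape}"
                    )
                self.positions[foot][m] = arr
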