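"""Step-target protocols for treadmill precision stepping.

A walker on a treadmill (belt at 3 km/h) steps onto targets projected on the
belt.  Targets are belt-fixed: each one appears a fixed distance ahead of the
walker and approaches at belt speed.  Anteroposterior (AP) center-to-center
spacing equals the walker's preferred step length L; mediolateral (ML)
center-to-center spacing is fixed (20 cm by default) because of the split
belt.  Feet strictly alternate with target index.

Two block types exist.  An *unperturbed* block is a plain series of targets.
A *perturbed* block additionally contains target shifts: at unpredictable
points a target jumps 40% of L forward or backward.  Forward shifts are
triggered at one of four "available response distances" (ARD: 80, 100, 130
or 200% of L, the AP distance between the walker's center of pressure and
the target at the moment it shifts); backward shifts occur only at ARD 130%
and exist to prevent anticipation of shift direction.  Consecutive shifts
are separated by 5-7 non-shifted targets, and every shift type hits each
foot equally often.

Coordinate convention: AP axis positive in the walking direction; the lab
frame has its origin at the walker's mean COP; the belt frame is fixed to
the moving surface.  Units are meters and seconds throughout; percentages
appear only at reporting boundaries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ProtocolError",
    "ConstraintError",
    "ProtocolParams",
    "Shift",
    "StepTarget",
    "Block",
    "generate_unperturbed_block",
    "generate_perturbed_block",
    "generate_session",
    "target_lab_position",
    "session_to_json",
    "session_from_json",
    "FOOT_ML_SIGN",
    "FORWARD",
    "BACKWARD",
]

Foot = Literal["left", "right"]
FORWARD = "forward"
BACKWARD = "backward"

#: ML sign convention: positive ML points to the walker's left.
FOOT_ML_SIGN = {"left": 1.0, "right": -1.0}
_OTHER_FOOT = {"left": "right", "right": "left"}


class ProtocolError(ValueError):
    """Invalid protocol parameters or an impossible query."""


class ConstraintError(ProtocolError):
    """Block size / gap combination admits no feasible shift schedule."""


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ProtocolParams:
    """Design parameters of a precision-stepping session.

    Lengths in meters, speeds in m/s.  ``ard_conditions`` and
    ``shift_magnitude`` are fractions of the preferred step length L.
    """

    preferred_step_length: float = 0.50
    shoe_length: float = 0.26
    shoe_width: float = 0.10
    ml_center_distance: float = 0.20
    belt_speed: float = 3.0 / 3.6  # 3 km/h
    appearance_distance: float = 2.0
    unperturbed_block_size: int = 59
    perturbed_block_size: int = 248
    shifts_per_type: int = 8
    ard_conditions: tuple[float, ...] = (0.8, 1.0, 1.3, 2.0)
    backward_ard: float = 1.3
    shift_magnitude: float = 0.4
    gap_range: tuple[int, int] = (5, 7)
    n_perturbed_blocks: int = 3
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        L = self.preferred_step_length
        gmin, gmax = self.gap_range
        if not L > 0:
            raise ProtocolError(f"preferred_step_length must be > 0, got {L}")
        if self.belt_speed <= 0:
            raise ProtocolError("belt_speed must be > 0")
        if gmin < 1 or gmin > gmax:
            raise ProtocolError(
                f"gap_range must satisfy 1 <= min <= max, got {self.gap_range}"
            )
        if not 0 < self.shift_magnitude < 1:
            raise ProtocolError(
                f"shift_magnitude must lie in (0, 1), got {self.shift_magnitude}"
            )
        if self.shifts_per_type % 2:
            raise ProtocolError(
                "shifts_per_type must be even so each type can hit both feet equally"
            )
        if self.backward_ard not in self.ard_conditions:
            raise ProtocolError("backward_ard must be one of ard_conditions")
        if self.perturbed_block_size < self.shifts_count * (1 + gmin):
            raise ConstraintError(
                f"perturbed_block_size={self.perturbed_block_size} violates the bound "
                f"size >= shifts_count * (1 + gap_min) = "
                f"{self.shifts_count * (1 + gmin)}"
            )

    @property
    def n_shift_types(self) -> int:
        """Forward ARD conditions plus the single backward type."""
        return len(self.ard_conditions) + 1

    @property
    def shifts_count(self) -> int:
        return self.shifts_per_type * self.n_shift_types


@dataclass(frozen=True)
class Shift:
    direction: str  # "forward" | "backward"
    ard: float  # fraction of L
    displaced_ap_center: float  # belt frame, meters


@dataclass(frozen=True)
class StepTarget:
    index: int
    foot: str
    nominal_ap_center: float  # belt frame, meters
    ml_center: float  # signed, meters (positive = left)
    size: tuple[float, float]  # (length, width), meters
    shift: Shift | None = None


@dataclass
class Block:
    kind: str  # "unperturbed" | "perturbed"
    targets: list[StepTarget]

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def shifted(self) -> list[StepTarget]:
        return [t for t in self.targets if t.shift is not None]

    def validate(self, params: ProtocolParams) -> None:
        """Check every structural invariant; raise ProtocolError on violation."""
        L = params.preferred_step_length
        for prev, cur in zip(self.targets, self.targets[1:]):
            if cur.index != prev.index + 1:
                raise ProtocolError("target indices must be consecutive")
            if cur.foot == prev.foot:
                raise ProtocolError("feet must strictly alternate with index")
            if abs(cur.nominal_ap_center - prev.nominal_ap_center - L) > 1e-9:
                raise ProtocolError("AP spacing must equal preferred step length")
            if abs(abs(cur.ml_center - prev.ml_center)
                   - params.ml_center_distance) > 1e-9:
                raise ProtocolError("ML spacing must equal ml_center_distance")
        shifted = self.shifted
        if self.kind == "unperturbed":
            if shifted:
                raise ProtocolError("unperturbed blocks must contain zero shifts")
            return
        if len(shifted) != params.shifts_count:
            raise ProtocolError(
                f"expected {params.shifts_count} shifts, found {len(shifted)}"
            )
        gmin, gmax = params.gap_range
        idx = [t.index for t in shifted]
        gaps = np.diff(idx) - 1
        if np.any(gaps < gmin) or np.any(gaps > gmax):
            raise ProtocolError(f"inter-shift gaps must lie in [{gmin}, {gmax}]")
        counts: dict[tuple[str, float, str], int] = {}
        for t in shifted:
            key = (t.shift.direction, t.shift.ard, t.foot)
            counts[key] = counts.get(key, 0) + 1
            if abs(
                abs(t.shift.displaced_ap_center - t.nominal_ap_center)
                - params.shift_magnitude * L
            ) > 1e-9:
                raise ProtocolError("shift displacement must equal shift_magnitude * L")
        per_foot = params.shifts_per_type // 2
        expected = {}
        for ard in params.ard_conditions:
            for foot in ("left", "right"):
                expected[(FORWARD, ard, foot)] = per_foot
        for foot in ("left", "right"):
            expected[(BACKWARD, params.backward_ard, foot)] = per_foot
        if counts != expected:
            raise ProtocolError(f"unbalanced shift assignment: {counts}")


def _make_targets(params: ProtocolParams, n: int, first_foot: str) -> list[StepTarget]:
    L = params.preferred_step_length
    half_ml = params.ml_center_distance / 2.0
    size = (params.shoe_length, params.shoe_width)
    targets = []
    foot = first_foot
    for i in range(n):
        targets.append(
            StepTarget(
                index=i,
                foot=foot,
                nominal_ap_center=i * L,
                ml_center=FOOT_ML_SIGN[foot] * half_ml,
                size=size,
            )
        )
        foot = _OTHER_FOOT[foot]
    return targets


def generate_unperturbed_block(
    params: ProtocolParams, first_foot: str = "right"
) -> Block:
    """Series of ``unperturbed_block_size`` targets with no shifts."""
    targets = _make_targets(params, params.unperturbed_block_size, first_foot)
    block = Block(kind="unperturbed", targets=targets)
    block.validate(params)
    return block


def _sample_shift_positions(
    params: ProtocolParams, rng: np.random.Generator
) -> np.ndarray:
    """Shift target indices with gaps in ``gap_range`` and balanced parity.

    The lead-in before the first shift is treated like an inter-shift gap.
    Gaps are drawn uniformly, then randomly decremented towards gap_min until
    they fit the block; draws whose shift indices are not split evenly
    between even and odd (i.e. between feet) are rejected and resampled.
    """
    S = params.shifts_count
    gmin, gmax = params.gap_range
    n_fillers = params.perturbed_block_size - S
    if n_fillers < S * gmin:
        raise ConstraintError(
            f"{n_fillers} non-shifted targets cannot provide {S} gaps of >= {gmin}: "
            f"violated bound perturbed_block_size - shifts >= shifts * gap_min"
        )
    for _ in range(100_000):
        gaps = rng.integers(gmin, gmax + 1, size=S)
        excess = int(gaps.sum()) - n_fillers
        while excess > 0:
            loose = np.flatnonzero(gaps > gmin)
            j = loose[rng.integers(len(loose))]
            take = min(excess, int(gaps[j]) - gmin)
            gaps[j] -= take
            excess -= take
        positions = np.cumsum(gaps + 1) - 1  # 0-based target indices
        if int(np.sum(positions % 2 == 0)) == S // 2:
            return positions
    raise ConstraintError("could not find a parity-balanced shift schedule")


def generate_perturbed_block(
    params: ProtocolParams,
    rng: np.random.Generator | int | None = None,
    first_foot: str = "right",
) -> Block:
    """Series of ``perturbed_block_size`` targets containing the full shift set.

    Defaults give 248 targets with 40 shifts: 8 per type (4 forward ARDs plus
    one backward type), 4 per foot per type, separated by 5-7 plain targets.
    """
    rng = _as_rng(params.rng_seed if rng is None else rng)
    targets = _make_targets(params, params.perturbed_block_size, first_foot)
    positions = _sample_shift_positions(params, rng)

    types: list[tuple[str, float]] = [(FORWARD, a) for a in params.ard_conditions]
    types.append((BACKWARD, params.backward_ard))
    per_parity = params.shifts_per_type // 2
    L = params.preferred_step_length
    delta = params.shift_magnitude * L

    for parity in (0, 1):
        slots = [int(p) for p in positions if p % 2 == parity]
        bag = [t for t in types for _ in range(per_parity)]
        rng.shuffle(bag)
        for pos, (direction, ard) in zip(slots, bag):
            t = targets[pos]
            sign = 1.0 if direction == FORWARD else -1.0
            shift = Shift(
                direction=direction,
                ard=ard,
                displaced_ap_center=t.nominal_ap_center + sign * delta,
            )
            targets[pos] = replace(t, shift=shift)

    block = Block(kind="perturbed", targets=targets)
    block.validate(params)
    return block


def generate_session(
    params: ProtocolParams,
    rng: np.random.Generator | int | None = None,
    first_foot: str = "right",
) -> list[Block]:
    """One unperturbed plus ``n_perturbed_blocks`` perturbed blocks, shuffled."""
    rng = _as_rng(params.rng_seed if rng is None else rng)
    blocks = [generate_unperturbed_block(params, first_foot)]
    blocks += [
        generate_perturbed_block(params, rng, first_foot)
        for _ in range(params.n_perturbed_blocks)
    ]
    order = rng.permutation(len(blocks))
    return [blocks[i] for i in order]


def target_lab_position(
    target: StepTarget,
    t: float,
    appearance_time: float,
    params: ProtocolParams,
    use_displaced: bool = False,
) -> tuple[float, float]:
    """Lab-frame (ap, ml) of a target's center at time ``t``.

    The target appears ``appearance_distance`` ahead of the walker and rides
    the belt towards the origin at belt speed.  With ``use_displaced`` the
    shifted center is returned (belt-frame displacement applied rigidly).
    """
    if t < appearance_time:
        raise ProtocolError(
            f"target {target.index} queried at t={t:.3f}s before its "
            f"appearance at {appearance_time:.3f}s"
        )
    offset = 0.0
    if use_displaced:
        if target.shift is None:
            raise ProtocolError(f"target {target.index} has no shift")
        offset = target.shift.displaced_ap_center - target.nominal_ap_center
    ap = params.appearance_distance + offset - params.belt_speed * (t - appearance_time)
    return ap, target.ml_center


# ---------------------------------------------------------------------------
# JSON serialization

def _block_to_dict(block: Block) -> dict:
    return {
        "kind": block.kind,
        "targets": [asdict(t) for t in block.targets],
    }


def _block_from_dict(d: dict) -> Block:
    targets = []
    for td in d["targets"]:
        shift = Shift(**td["shift"]) if td.get("shift") else None
        targets.append(
            StepTarget(
                index=td["index"],
                foot=td["foot"],
                nominal_ap_center=td["nominal_ap_center"],
                ml_center=td["ml_center"],
                size=tuple(td["size"]),
                shift=shift,
            )
        )
    return Block(kind=d["kind"], targets=targets)


def session_to_json(params: ProtocolParams, blocks: Sequence[Block]) -> str:
    return json.dumps(
        {"params": asdict(params), "blocks": [_block_to_dict(b) for b in blocks]},
        indent=1,
    )


def session_from_json(text: str) -> tuple[ProtocolParams, list[Block]]:
    d = json.loads(text)
    pd_ = dict(d["params"])
    for key in ("ard_conditions", "gap_range"):
        pd_[key] = tuple(pd_[key])
    params = ProtocolParams(**pd_)
    return params, [_block_from_dict(b) for b in d["blocks"]]
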