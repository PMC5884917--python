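"""Per-step signed errors and per-condition summaries.

The step error of a step onto a target is the anteroposterior distance
between the center of the targeting foot and the center of the target at
the moment of midstance, positive when the foot lands anterior to the
target (overshoot).  The foot center is the centroid of the three shoe
markers (equivalently the center of the midpoints of the three segments
joining heel, toe and malleolus).  Per condition, the mean raw error is
normalized to preferred step length, and variability is the population
(divide-by-k) standard deviation of raw errors expressed as % of L:

    variability = 100/L * sqrt( (sum e^2 - (sum e)^2 / k) / k )

Backward-shift steps are scored but excluded from all summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gait_events import GaitEvents, Midstance, detect_events, midstance_times
from .protocol import BACKWARD, Block, FORWARD, ProtocolParams, StepTarget, target_lab_position
from .signals import COPTrajectory, MarkerTrajectories, MARKER_NAMES

__all__ = [
    "MissingDataError",
    "StepScoreRecord",
    "ConditionSummary",
    "SubjectSummary",
    "foot_center_at",
    "target_center_at_midstance",
    "step_error",
    "condition_summary",
    "pool_over_ard",
    "score_trial",
    "records_from_true_errors",
    "summarize_subject",
]

log = logging.getLogger(__name__)

UNPERTURBED = "unperturbed"

#: maximum one-sided gap (s) bridged when interpolating across missing
#: marker samples; ~5 frames at 150 Hz.
MARKER_INTERP_WINDOW = 0.0335


class MissingDataError(ValueError):
    """A required sample is missing and cannot be bridged by interpolation."""


@dataclass(frozen=True)
class StepScoreRecord:
    target_index: int
    foot: str
    condition: str  # "unperturbed" | "forward" | "backward"
    ard: float | None  # fraction of L; None when unperturbed
    raw_error: float  # meters, + = overshoot
    normalized_error: float  # % of L
    midstance_time: float  # seconds; NaN for error-level records


@dataclass(frozen=True)
class ConditionSummary:
    mean_error: float  # % of L
    variability: float  # % of L
    k: int  # steps analyzed


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: str
    step_length: float  # L used for normalization, meters
    unperturbed: ConditionSummary
    per_ard: dict[float, ConditionSummary]
    pooled: ConditionSummary  # unweighted mean over forward-ARD conditions

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "step_length": self.step_length,
            "unperturbed_error": self.unperturbed.mean_error,
            "unperturbed_variability": self.unperturbed.variability,
            "unperturbed_k": self.unperturbed.k,
            "perturbed_error": self.pooled.mean_error,
            "perturbed_variability": self.pooled.variability,
            "perturbed_k": self.pooled.k,
        }
        for ard, cs in sorted(self.per_ard.items()):
            tag = f"ard{round(ard * 100):d}"
            row[f"error_{tag}"] = cs.mean_error
            row[f"variability_{tag}"] = cs.variability
            row[f"k_{tag}"] = cs.k
        return row


def _interp_channel(times, values, t, max_gap=MARKER_INTERP_WINDOW) -> float:
    finite = np.isfinite(values)
    ft = times[finite]
    if ft.size == 0 or t < ft[0] or t > ft[-1]:
        raise MissingDataError(f"no finite samples bracketing t={t:.3f}s")
    j = np.searchsorted(ft, t)
    j = max(j, 1)
    if (ft[j] - t > max_gap) or (t - ft[j - 1] > max_gap):
        raise MissingDataError(
            f"gap around t={t:.3f}s exceeds the {max_gap * 1000:.0f} ms "
            "interpolation window"
        )
    return float(np.interp(t, ft, values[finite]))


def foot_center_at(
    markers: MarkerTrajectories, t: float, foot: str
) -> np.ndarray:
    """Foot center (3D) at time ``t``: centroid of the three shoe markers.

    The centroid equals the center of the three midpoints of the segments
    joining the markers, the classic wire-frame representation of the foot.
    Missing samples are bridged by linear interpolation within a 33 ms
    window; wider gaps raise :class:`MissingDataError`.
    """
    if t < markers.time[0] or t > markers.time[-1]:
        raise ValueError(f"t={t:.3f}s outside the recording")
    pts = []
    for m in MARKER_NAMES:
        arr = markers.positions[foot][m]
        pts.append(
            [_interp_channel(markers.time, arr[:, ax], t) for ax in range(3)]
        )
    return np.mean(np.asarray(pts), axis=0)


def target_center_at_midstance(
    target: StepTarget,
    t_mid: float,
    appearance_time: float,
    params: ProtocolParams,
    shift_onset_time: float | None = None,
) -> tuple[float, float]:
    """Lab-frame target center at midstance.

    Uses the displaced center when the target's shift has been realized by
    ``t_mid`` (``shift_onset_time`` from the device log / simulator).
    """
    displaced = (
        target.shift is not None
        and shift_onset_time is not None
        and not math.isnan(shift_onset_time)
        and shift_onset_time <= t_mid
    )
    return target_lab_position(
        target, t_mid, appearance_time, params, use_displaced=displaced
    )


def step_error(
    foot_center: Sequence[float], target_center: Sequence[float]
) -> float:
    """Signed AP error, + = overshoot (foot anterior to the target)."""
    return float(foot_center[0] - target_center[0])


def condition_summary(errors: Sequence[float], step_length: float) -> ConditionSummary:
    """Mean normalized error and population-SD variability for one condition."""
    e = np.asarray(errors, float)
    k = e.size
    if k == 0:
        raise ValueError("condition_summary needs at least one step (k >= 1)")
    if step_length <= 0:
        raise ValueError(f"step length must be > 0, got {step_length}")
    mean_error = 100.0 * e.mean() / step_length
    var = (np.sum(e**2) - np.sum(e) ** 2 / k) / k
    variability = 100.0 * math.sqrt(max(var, 0.0)) / step_length
    return ConditionSummary(mean_error=mean_error, variability=variability, k=int(k))


def pool_over_ard(
    per_ard: Mapping[float, ConditionSummary],
    ard_conditions: Sequence[float] = (0.8, 1.0, 1.3, 2.0),
) -> ConditionSummary:
    """Unweighted mean of the per-ARD summaries, per measure."""
    missing = [a for a in ard_conditions if a not in per_ard]
    if missing:
        raise KeyError(f"missing ARD condition(s): {missing}")
    vals = [per_ard[a] for a in ard_conditions]
    return ConditionSummary(
        mean_error=float(np.mean([c.mean_error for c in vals])),
        variability=float(np.mean([c.variability for c in vals])),
        k=int(sum(c.k for c in vals)),
    )


def _match_targets_to_strikes(
    block: Block,
    appearance_times: np.ndarray,
    events: GaitEvents,
    params: ProtocolParams,
) -> dict[int, tuple[float, str]]:
    """Map target index -> (strike time, foot) by nominal arrival time.

    A target's nominal landing happens when its center reaches half a step
    length ahead of the walker; the nearest detected strike is taken,
    requiring foot agreement, a strictly increasing assignment and a
    residual below half a step period.  Unmatched targets are dropped with
    a warning (they are excluded from summaries).
    """
    L = params.preferred_step_length
    v = params.belt_speed
    T = L / v
    expected = appearance_times + (params.appearance_distance - 0.5 * L) / v
    order = events.strikes_in_order()
    times = np.array([p[0] for p in order])
    matched: dict[int, tuple[float, str]] = {}
    last_j = -1
    for i, tg in enumerate(block.targets):
        j = int(np.argmin(np.abs(times - expected[i])))
        if (
            j <= last_j
            or order[j][1] != tg.foot
            or abs(times[j] - expected[i]) > T / 2
        ):
            log.warning(
                "target %d (%s) has no matching foot strike; dropped",
                tg.index,
                tg.foot,
            )
            continue
        matched[i] = order[j]
        last_j = j
    return matched


def score_trial(
    markers: MarkerTrajectories,
    cop: COPTrajectory,
    block: Block,
    appearance_times: np.ndarray,
    shift_onset_times: np.ndarray,
    params: ProtocolParams,
    step_length: float | None = None,
    events: GaitEvents | None = None,
) -> list[StepScoreRecord]:
    """Score every target of one trial.

    ``appearance_times`` / ``shift_onset_times`` come from the projection
    device log (the simulator records them); ``step_length`` is the measured
    preferred step length used for normalization (defaults to the protocol
    value).  Steps whose events cannot be paired are dropped and logged.
    """
    L = params.preferred_step_length if step_length is None else step_length
    if events is None:
        events = detect_events(cop)
    matched = _match_targets_to_strikes(block, appearance_times, events, params)
    mids = midstance_times(events)
    mid_by_stance = {(m.foot, round(m.strike_time, 9)): m for m in mids}

    records: list[StepScoreRecord] = []
    for i, tg in enumerate(block.targets):
        if i not in matched:
            continue
        t_strike, foot = matched[i]
        mid = mid_by_stance.get((foot, round(t_strike, 9)))
        if mid is None:
            log.warning("target %d: stance has no midstance; dropped", tg.index)
            continue
        try:
            fc = foot_center_at(markers, mid.time, foot)
        except (MissingDataError, ValueError) as exc:
            log.warning("target %d: %s; dropped", tg.index, exc)
            continue
        onset = float(shift_onset_times[i]) if tg.shift is not None else None
        tc = target_center_at_midstance(
            tg, mid.time, float(appearance_times[i]), params, onset
        )
        e = step_error(fc, tc)
        records.append(
            StepScoreRecord(
                target_index=tg.index,
                foot=foot,
                condition=UNPERTURBED if tg.shift is None else tg.shift.direction,
                ard=None if tg.shift is None else tg.shift.ard,
                raw_error=e,
                normalized_error=100.0 * e / L,
                midstance_time=mid.time,
            )
        )
    return records


def records_from_true_errors(
    block: Block, errors: np.ndarray, step_length: float
) -> list[StepScoreRecord]:
    """Build score records directly from landing-error level simulation."""
    records = []
    for tg, e in zip(block.targets, errors):
        records.append(
            StepScoreRecord(
                target_index=tg.index,
                foot=tg.foot,
                condition=UNPERTURBED if tg.shift is None else tg.shift.direction,
                ard=None if tg.shift is None else tg.shift.ard,
                raw_error=float(e),
                normalized_error=100.0 * float(e) / step_length,
                midstance_time=float("nan"),
            )
        )
    return records


def summarize_subject(
    subject_id: str,
    unperturbed_records: Sequence[StepScoreRecord],
    perturbed_records: Sequence[StepScoreRecord],
    step_length: float,
    ard_conditions: Sequence[float] = (0.8, 1.0, 1.3, 2.0),
) -> SubjectSummary:
    """Per-subject summary measures.

    Unperturbed error/variability come from the unperturbed block's steps;
    per-ARD measures pool the forward-shifted steps of all perturbed blocks
    (backward shifts are scored but excluded); the pooled perturbed measures
    are the unweighted mean over the four forward ARD conditions.
    """
    unpert = condition_summary(
        [r.raw_error for r in unperturbed_records if r.condition == UNPERTURBED],
        step_length,
    )
    per_ard = {}
    for ard in ard_conditions:
        errs = [
            r.raw_error
            for r in perturbed_records
            if r.condition == FORWARD and r.ard == ard
        ]
        per_ard[float(ard)] = condition_summary(errs, step_length)
    pooled = pool_over_ard(per_ard, ard_conditions)
    return SubjectSummary(
        subject_id=subject_id,
        step_length=step_length,
        unperturbed=unpert,
        per_ard=per_ard,
        pooled=pooled,
    )
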