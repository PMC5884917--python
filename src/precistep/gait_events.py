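"""Gait events from the center-of-pressure trajectory.

During treadmill walking the ML component of the COP alternates between two
plateaus (single support under the left or right foot) joined by fast ramps
(double support, weight transfer) -- the "butterfly" pattern.  Events are
recovered from that structure:

* a *foot strike* of the incoming foot starts a weight transfer, i.e. it is
  the instant the COP leaves the outgoing foot's plateau;
* the outgoing foot's *toe-off* ends the transfer, i.e. the instant the COP
  settles on the incoming foot's plateau.

Plateaus are segmented by hysteresis thresholding of the ML COP around the
midline; each transfer ramp is then refined by a least-squares line fit to
its central portion, intersected with the two neighbouring plateau levels.
At 1000 Hz this resolves event times well below the sampling interval even
with millimeter-scale sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import COPTrajectory

__all__ = [
    "DetectionError",
    "PairingError",
    "GaitEvents",
    "Midstance",
    "detect_events",
    "midstance_times",
    "preferred_step_length",
]


class DetectionError(RuntimeError):
    """The COP trajectory does not show a usable alternating gait pattern."""


class PairingError(RuntimeError):
    """Events cannot be paired into stance phases."""


@dataclass
class GaitEvents:
    """Foot-strike and toe-off times (seconds) per foot, strictly ordered."""

    strike_times: dict[str, np.ndarray]
    toe_off_times: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for d in (self.strike_times, self.toe_off_times):
            for foot in d:
                d[foot] = np.asarray(d[foot], float)

    def strikes_in_order(self) -> list[tuple[float, str]]:
        """All foot strikes as (time, foot), sorted by time."""
        pairs = [
            (float(t), foot)
            for foot, ts in self.strike_times.items()
            for t in ts
        ]
        return sorted(pairs)

    def validate(self) -> None:
        """Raise DetectionError unless events alternate and are ordered."""
        for foot in ("left", "right"):
            s = self.strike_times.get(foot, np.array([]))
            o = self.toe_off_times.get(foot, np.array([]))
            if np.any(np.diff(s) <= 0) or np.any(np.diff(o) <= 0):
                raise DetectionError(f"{foot} events are not strictly increasing")
            # each strike must be followed by one toe-off before the next strike
            for k, t in enumerate(s):
                nxt = s[k + 1] if k + 1 < len(s) else np.inf
                n_off = int(np.sum((o > t) & (o < nxt)))
                if nxt is not np.inf and n_off != 1:
                    raise DetectionError(
                        f"{foot} stance at {t:.3f}s has {n_off} toe-offs before "
                        "the next strike"
                    )
        order = self.strikes_in_order()
        for (_, f1), (_, f2) in zip(order, order[1:]):
            if f1 == f2:
                raise DetectionError("left/right strikes do not interleave")


@dataclass(frozen=True)
class Midstance:
    """Midpoint of a single-support phase: halfway between the contralateral
    foot's toe-off and its subsequent heel strike."""

    foot: str
    strike_time: float  # own strike opening the stance
    time: float
    degenerate: bool = False  # toe-off coincided with the heel strike


def _runs(sign_idx: np.ndarray, signs: np.ndarray) -> list[tuple[int, int, int]]:
    """Compress indices with hysteresis sign into maximal same-sign runs."""
    change = np.flatnonzero(signs[1:] != signs[:-1])
    starts = np.r_[0, change + 1]
    ends = np.r_[change, len(signs) - 1]
    return [
        (int(sign_idx[a]), int(sign_idx[b]), int(signs[a]))
        for a, b in zip(starts, ends)
    ]


def detect_events(
    cop: COPTrajectory,
    left_positive_ml: bool = True,
    min_ml_amplitude: float = 0.02,
) -> GaitEvents:
    """Extract foot-strike and toe-off events from the COP trajectory.

    Requires at least two full strides (four single-support plateaus).
    Raises :class:`DetectionError` with a diagnostic if the ML COP shows no
    alternating pattern (e.g. monotone or flat input).
    """
    t, ml = cop.time, cop.ml
    if t.size < 10:
        raise DetectionError(f"signal too short: {t.size} samples")
    lo_p, hi_p = np.percentile(ml, [5.0, 95.0])
    amp = hi_p - lo_p
    if amp < min_ml_amplitude:
        raise DetectionError(
            f"ML COP amplitude {amp * 1000:.1f} mm below "
            f"{min_ml_amplitude * 1000:.0f} mm: no alternating single-support "
            "pattern (is this gait?)"
        )
    mid = 0.5 * (lo_p + hi_p)
    s = np.zeros(t.size, dtype=np.int8)
    s[ml > mid + 0.25 * amp] = 1
    s[ml < mid - 0.25 * amp] = -1
    nz = np.flatnonzero(s)
    if nz.size == 0:
        raise DetectionError("ML COP never leaves the midline band")
    runs = _runs(nz, s[nz])
    if len(runs) < 4:
        raise DetectionError(
            f"only {len(runs)} single-support plateaus found; need >= 4 "
            "(two full strides)"
        )

    pos_side = "left" if left_positive_ml else "right"
    neg_side = "right" if left_positive_ml else "left"
    strikes: dict[str, list[float]] = {"left": [], "right": []}
    toe_offs: dict[str, list[float]] = {"left": [], "right": []}

    levels = [float(np.median(ml[a : b + 1])) for a, b, _ in runs]
    for (a0, a1, sa), (b0, b1, sb), la, lb in zip(
        runs, runs[1:], levels, levels[1:]
    ):
        if sa == sb:  # merged by hysteresis; cannot happen after _runs
            continue
        span = lb - la
        seg = slice(a1, b0 + 1)
        frac = (ml[seg] - la) / span
        sel = np.flatnonzero((frac >= 0.25) & (frac <= 0.75))
        if sel.size >= 2:
            tt = t[seg][sel]
            beta, alpha = np.polyfit(tt, ml[seg][sel], 1)
            t_strike = (la - alpha) / beta
            t_toe = (lb - alpha) / beta
        else:  # near-instant transfer: fall back to the gap midpoint
            t_strike = t_toe = 0.5 * (t[a1] + t[b0])
        # clamp into the inter-plateau gap to guard against fit blow-ups
        t_strike = float(np.clip(t_strike, t[a0], t[b0]))
        t_toe = float(np.clip(t_toe, t_strike, t[b1]))
        incoming = pos_side if sb > 0 else neg_side
        outgoing = pos_side if sa > 0 else neg_side
        strikes[incoming].append(t_strike)
        toe_offs[outgoing].append(t_toe)

    events = GaitEvents(
        strike_times={f: np.array(v) for f, v in strikes.items()},
        toe_off_times={f: np.array(v) for f, v in toe_offs.items()},
    )
    events.validate()
    return events


def midstance_times(events: GaitEvents) -> list[Midstance]:
    """Midstance per stance phase.

    Midstance of a stance of foot *f* is the midpoint between the
    contralateral foot's toe-off and its subsequent heel strike (the middle
    of *f*'s single-support phase).  Leading/trailing stances without a
    complete contralateral bracket are skipped; inconsistent interior
    pairings raise :class:`PairingError` naming the orphan event.
    """
    out: list[Midstance] = []
    for foot in ("left", "right"):
        contra = "right" if foot == "left" else "left"
        own = events.strike_times.get(foot, np.array([]))
        c_off = events.toe_off_times.get(contra, np.array([]))
        c_str = events.strike_times.get(contra, np.array([]))
        for k, ts in enumerate(own):
            t_next = own[k + 1] if k + 1 < len(own) else np.inf
            offs = c_off[(c_off > ts) & (c_off < t_next)]
            if offs.size == 0:
                if np.isinf(t_next) or c_off.size == 0 or c_off[-1] <= ts:
                    continue  # trailing stance, bracket incomplete
                raise PairingError(
                    f"no contralateral toe-off inside the {foot} stance "
                    f"starting at {ts:.3f}s"
                )
            if offs.size > 1:
                raise PairingError(
                    f"{offs.size} contralateral toe-offs inside the {foot} "
                    f"stance starting at {ts:.3f}s"
                )
            to = float(offs[0])
            hs_cand = c_str[(c_str >= to) & (c_str <= t_next)]
            if hs_cand.size == 0:
                if np.isinf(t_next) or c_str.size == 0 or c_str[-1] < to:
                    continue
                raise PairingError(
                    f"contralateral toe-off at {to:.3f}s has no subsequent "
                    "heel strike"
                )
            hs = float(hs_cand[0])
            out.append(
                Midstance(
                    foot=foot,
                    strike_time=float(ts),
                    time=0.5 * (to + hs),
                    degenerate=bool(hs == to),
                )
            )
    out.sort(key=lambda m: m.time)
    return out


def preferred_step_length(
    cop: COPTrajectory,
    events: GaitEvents,
    belt_speed: float,
    n_strides: int = 20,
) -> float:
    """Preferred step length from ``n_strides`` strides of plain walking.

    Mean AP distance between successive foot-strike COP positions, with the
    belt motion added back (the belt carries the COP backwards between
    strikes):  ``step_k = ap(t_{k+1}) - ap(t_k) + v * (t_{k+1} - t_k)``.
    """
    order = events.strikes_in_order()
    need = 2 * n_strides + 1  # a stride spans two steps
    if len(order) < need:
        raise ValueError(
            f"need {need} foot strikes for {n_strides} strides, "
            f"found {len(order)}"
        )
    times = np.array([p[0] for p in order[:need]])
    ap = np.interp(times, cop.time, cop.ap)
    steps = np.diff(ap) + belt_speed * np.diff(times)
    return float(steps.mean())
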