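"""Synthetic treadmill walkers with full ground truth.

Simulates a cohort stepping on projected targets (see :mod:`precistep.protocol`)
and produces the raw signals the analysis consumes -- 150 Hz shoe-marker
trajectories and a 1000 Hz center-of-pressure (COP) trajectory -- together
with ground truth for every downstream stage (event times, landing centers,
signed landing errors, realized shift onsets).

Behavioral model
----------------
Each subject lands on target *i* with a signed AP error drawn from
``N(error_bias * L, (sigma * kappa(ard) * L)^2)`` where L is the preferred
step length, ``sigma`` the subject's landing variability (fraction of L) and
``kappa(ard) >= 1`` a variability inflation applied to shifted targets only
(non-increasing in ARD: less response distance, sloppier landings).  Across
a cohort, ``sigma(age) = sigma0 + b * age`` with b < 0 plus between-subject
noise, so landing variability decreases with age while the mean error does
not -- the structure the cohort statistics are meant to recover.

Gait kinematics are deliberately minimal: strikes are periodic at the target
arrival period L/v, stance feet ride the belt at -v, swing follows a
minimum-jerk AP profile with a half-sine vertical lift, and the COP
progresses heel-to-toe under the single-support foot with straight-line
transfers during double support (the classic butterfly pattern).  Only event
timing and landing positions matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .protocol import (
    BACKWARD,
    FOOT_ML_SIGN,
    Block,
    ProtocolParams,
)
from .signals import COPTrajectory, MarkerTrajectories, FEET, MARKER_NAMES

__all__ = [
    "PopulationModel",
    "SubjectParams",
    "LandingDistribution",
    "GroundTruth",
    "SimulatedTrial",
    "make_cohort",
    "respond_to_shift",
    "simulate_step_errors",
    "simulate_trial",
    "DOUBLE_SUPPORT_FRACTION",
]

_OTHER = {"left": "right", "right": "left"}

#: fraction of the step period spent in double support (both feet down).
DOUBLE_SUPPORT_FRACTION = 0.2
#: swing apex height of the foot center, meters.
SWING_HEIGHT = 0.05
#: COP start/end of its heel-to-toe progression, as fractions of shoe length.
COP_HEEL_OFFSET = -0.40
COP_TOE_OFFSET = 0.45
#: landing position of the leading foot center ahead of the mean COP, as a
#: fraction of the step length (the trailing foot sits symmetrically behind).
LANDING_OFFSET_FRAC = 0.5

# Marker positions in the foot frame (ap, lateral, vertical), meters.  AP
# offsets sum to zero so the marker centroid coincides with the foot center.
_MARKER_LOCAL = {
    "toe": (0.10, 0.0, 0.02),
    "malleolus": (0.03, 0.04, 0.07),  # lateral sign applied per side
    "heel": (-0.13, 0.0, 0.03),
}


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class PopulationModel:
    """Population-level template from which subjects are drawn.

    ``sigma0`` and ``age_slope`` define the age trend of landing variability
    (fractions of L, slope per year); ``sigma_between_sd`` is between-subject
    spread around that trend.  Defaults are calibrated so that a cohort of 30
    with ages uniform on 9-18.5 years has a population age-variability
    correlation of about -0.6.
    """

    sigma0: float = 0.090
    age_slope: float = -0.003
    sigma_between_sd: float = 0.011
    sigma_floor: float = 0.005
    bias_mean: float = 0.010
    bias_sd: float = 0.010
    step_length_at_age0: float = 0.35
    step_length_age_slope: float = 0.012
    step_length_sd: float = 0.030
    kappa: tuple[tuple[float, float], ...] = (
        (0.8, 1.6),
        (1.0, 1.4),
        (1.3, 1.2),
        (2.0, 1.0),
    )
    marker_noise_sd: float = 0.001
    cop_noise_sd: float = 0.002

    def __post_init__(self) -> None:
        ards = [a for a, _ in self.kappa]
        vals = [k for _, k in self.kappa]
        if sorted(ards) != list(ards):
            raise ValueError("kappa ARDs must be sorted ascending")
        if any(v < 1.0 for v in vals):
            raise ValueError("kappa values must be >= 1")
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("kappa must be non-increasing in ARD")


@dataclass(frozen=True)
class SubjectParams:
    """One realized subject: demographics plus behavioral parameters."""

    subject_id: str
    age: float  # years
    sex: str  # "F" | "M"
    step_length: float  # preferred step length L, meters
    error_bias: float  # mean signed landing error, fraction of L
    sigma: float  # landing variability, fraction of L
    kappa: tuple[tuple[float, float], ...] = PopulationModel.kappa
    step_time: float | None = None  # seconds; None -> L / belt_speed
    marker_noise_sd: float = 0.001
    cop_noise_sd: float = 0.002

    def kappa_at(self, ard: float) -> float:
        """Variability inflation for a shift at the given ARD (fraction of L).

        Interpolates linearly between tabulated ARDs, clipped at the ends.
        """
        if ard <= 0:
            raise ValueError(f"ard must be > 0, got {ard}")
        ards = np.array([a for a, _ in self.kappa])
        vals = np.array([k for _, k in self.kappa])
        return float(np.interp(ard, ards, vals))


class LandingDistribution(NamedTuple):
    """Gaussian landing-error distribution relative to the (displaced)
    target center, in meters."""

    mean: float
    sd: float


@dataclass
class GroundTruth:
    """Everything the simulator knows; the oracle for downstream stages."""

    step_time: float
    strike_times: dict[str, np.ndarray]  # per foot, incl. lead-in/out steps
    toe_off_times: dict[str, np.ndarray]
    target_feet: list[str]
    target_strike_times: np.ndarray
    target_midstance_times: np.ndarray
    target_landing_ap: np.ndarray  # lab AP of the foot center at strike
    true_errors: np.ndarray  # meters, signed (+ = overshoot)
    appearance_times: np.ndarray
    shift_onset_times: np.ndarray  # NaN where unshifted


class SimulatedTrial(NamedTuple):
    markers: MarkerTrajectories
    cop: COPTrajectory
    truth: GroundTruth


def make_cohort(
    n: int,
    age_range: tuple[float, float] = (9.0, 18.5),
    model: PopulationModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[SubjectParams]:
    """Draw ``n`` subjects with ages uniform on ``age_range``.

    Per-subject landing variability follows the linear age model plus
    between-subject noise (floored at ``sigma_floor``); preferred step length
    grows weakly with age.
    """
    if n < 2:
        raise ValueError(f"a cohort needs at least 2 subjects, got {n}")
    if model is None:
        model = PopulationModel()
    rng = _as_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    sigmas = np.maximum(
        model.sigma0
        + model.age_slope * ages
        + rng.normal(0.0, model.sigma_between_sd, size=n),
        model.sigma_floor,
    )
    biases = rng.normal(model.bias_mean, model.bias_sd, size=n)
    lengths = np.clip(
        model.step_length_at_age0
        + model.step_length_age_slope * ages
        + rng.normal(0.0, model.step_length_sd, size=n),
        0.30,
        0.80,
    )
    sexes = rng.choice(["F", "M"], size=n)
    return [
        SubjectParams(
            subject_id=f"S{i + 1:03d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            step_length=float(lengths[i]),
            error_bias=float(biases[i]),
            sigma=float(sigmas[i]),
            kappa=model.kappa,
            marker_noise_sd=model.marker_noise_sd,
            cop_noise_sd=model.cop_noise_sd,
        )
        for i in range(n)
    ]


def respond_to_shift(subject: SubjectParams, ard: float) -> LandingDistribution:
    """Landing distribution for a step onto a target shifted at ``ard``.

    The landing targets the displaced center; variability is inflated by
    ``kappa(ard)``.  At ARDs where kappa == 1 the distribution is identical
    to unperturbed stepping.
    """
    L = subject.step_length
    return LandingDistribution(
        mean=subject.error_bias * L,
        sd=subject.sigma * subject.kappa_at(ard) * L,
    )


def _check_block(subject: SubjectParams, params: ProtocolParams) -> None:
    if abs(params.preferred_step_length - subject.step_length) > 1e-9:
        raise ValueError(
            f"protocol step length {params.preferred_step_length} does not match "
            f"subject {subject.subject_id} (L={subject.step_length}); build the "
            "protocol with the subject's preferred step length"
        )


def _landing_sds(subject: SubjectParams, block: Block) -> np.ndarray:
    """Per-target landing SD in meters (kappa-inflated for shifted targets)."""
    L = subject.step_length
    sds = np.full(len(block.targets), subject.sigma * L)
    for i, t in enumerate(block.targets):
        if t.shift is not None:
            sds[i] = respond_to_shift(subject, t.shift.ard).sd
    return sds


def simulate_step_errors(
    subject: SubjectParams,
    block: Block,
    params: ProtocolParams,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """True signed landing errors for one block, without signal synthesis.

    This is the landing-error level of the full simulator (identical
    distributional model); use it for cohort-scale statistics where the
    signal pipeline has already been validated.
    """
    _check_block(subject, params)
    rng = _as_rng(rng)
    sds = _landing_sds(subject, block)
    return rng.normal(subject.error_bias * subject.step_length, sds)


def simulate_trial(
    subject: SubjectParams,
    block: Block,
    params: ProtocolParams,
    seed: int | np.random.Generator | None = None,
    lead_in_steps: int = 4,
    tail_steps: int = 2,
) -> SimulatedTrial:
    """Simulate one block of precision stepping.

    Returns markers (150 Hz), COP (1000 Hz) and the ground truth.  The trial
    contains ``lead_in_steps`` plain steps before the first target (so every
    target stance is bracketed by detectable events) and ``tail_steps`` after
    the last.
    """
    _check_block(subject, params)
    rng = _as_rng(seed)
    L = subject.step_length
    v = params.belt_speed
    T = subject.step_time if subject.step_time is not None else L / v
    delta = DOUBLE_SUPPORT_FRACTION
    stance_dur = (1.0 + delta) * T
    n_targets = len(block.targets)
    n_steps = lead_in_steps + n_targets + tail_steps

    # --- step schedule -----------------------------------------------------
    t_strike = np.arange(n_steps) * T
    first_target_foot = block.targets[0].foot
    feet = []
    foot = first_target_foot if lead_in_steps % 2 == 0 else _OTHER[first_target_foot]
    for _ in range(n_steps):
        feet.append(foot)
        foot = _OTHER[foot]
    ml_feet = np.array([FOOT_ML_SIGN[f] for f in feet]) * (
        params.ml_center_distance / 2.0
    )

    ap_land = LANDING_OFFSET_FRAC * L
    shift_off = np.zeros(n_steps)
    sds = np.full(n_steps, subject.sigma * L)
    sds[lead_in_steps : lead_in_steps + n_targets] = _landing_sds(subject, block)
    for i, tg in enumerate(block.targets):
        if tg.shift is not None:
            shift_off[lead_in_steps + i] = (
                tg.shift.displaced_ap_center - tg.nominal_ap_center
            )
    errors = rng.normal(subject.error_bias * L, sds)
    A = ap_land + shift_off + errors  # landing AP of the foot center

    tgt = slice(lead_in_steps, lead_in_steps + n_targets)
    appearance = t_strike[tgt] - (params.appearance_distance - ap_land) / v

    # --- COP at 1000 Hz ----------------------------------------------------
    t_end = t_strike[-1] + stance_dur
    tc = np.arange(0.0, t_end, 1.0 / 1000.0)
    idx = np.clip(np.searchsorted(t_strike, tc, side="right") - 1, 0, n_steps - 1)

    def cop_under(j: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        prog = np.clip((t - t_strike[j]) / stance_dur, 0.0, 1.0)
        h = (
            COP_HEEL_OFFSET + (COP_TOE_OFFSET - COP_HEEL_OFFSET) * prog
        ) * params.shoe_length
        return A[j] - v * (t - t_strike[j]) + h, ml_feet[j]

    dt = tc - t_strike[idx]
    ap_cur, ml_cur = cop_under(idx, tc)
    ap_prev, ml_prev = cop_under(np.maximum(idx - 1, 0), tc)
    w = np.clip(dt / (delta * T), 0.0, 1.0)
    in_transfer = (idx > 0) & (dt < delta * T)
    cop_ap = np.where(in_transfer, (1 - w) * ap_prev + w * ap_cur, ap_cur)
    cop_ml = np.where(in_transfer, (1 - w) * ml_prev + w * ml_cur, ml_cur)
    if subject.cop_noise_sd > 0:
        cop_ap = cop_ap + rng.normal(0.0, subject.cop_noise_sd, cop_ap.shape)
        cop_ml = cop_ml + rng.normal(0.0, subject.cop_noise_sd, cop_ml.shape)

    # --- realized shift onsets (COP-distance trigger) ----------------------
    shift_onsets = np.full(n_targets, np.nan)
    for i, tg in enumerate(block.targets):
        if tg.shift is None:
            continue
        a_i = appearance[i]
        t_land = t_strike[lead_in_steps + i]
        j0 = np.searchsorted(tc, a_i)
        j1 = min(np.searchsorted(tc, t_land + delta * T), len(tc))
        window = tc[j0:j1]
        nominal_ap = params.appearance_distance - v * (window - a_i)
        hit = np.flatnonzero(nominal_ap - cop_ap[j0:j1] <= tg.shift.ard * L)
        # fallback (never expected): realize the shift at the landing instant
        shift_onsets[i] = window[hit[0]] if hit.size else t_land

    # --- markers at 150 Hz -------------------------------------------------
    tm = np.arange(0.0, t_end, 1.0 / 150.0)
    positions: dict[str, dict[str, np.ndarray]] = {}
    for f in FEET:
        own = np.flatnonzero([ft == f for ft in feet])
        ts, As = t_strike[own], A[own]
        k = np.searchsorted(ts, tm, side="right") - 1
        kk = np.clip(k, 0, len(ts) - 1)
        knext = np.clip(kk + 1, 0, len(ts) - 1)
        t_off = ts[kk] + stance_dur
        swing_end = np.where(knext > kk, ts[knext], t_off + T)  # guard last step
        u = np.clip((tm - t_off) / np.maximum(swing_end - t_off, 1e-9), 0.0, 1.0)
        s = 10 * u**3 - 15 * u**4 + 6 * u**5  # minimum jerk
        ap_stance = As[kk] - v * (tm - ts[kk])
        ap_off = As[kk] - v * stance_dur
        ap_swing = ap_off + s * (As[knext] - ap_off)
        in_swing = (tm > t_off) & (knext > kk)
        center_ap = np.where(in_swing, ap_swing, ap_stance)
        center_ap = np.where(k < 0, As[0] - v * (tm - ts[0]), center_ap)
        center_z = np.where(in_swing, SWING_HEIGHT * np.sin(np.pi * u), 0.0)
        center_ml = FOOT_ML_SIGN[f] * params.ml_center_distance / 2.0

        lat = FOOT_ML_SIGN[f]
        positions[f] = {}
        for m in MARKER_NAMES:
            ox, oy, oz = _MARKER_LOCAL[m]
            pos = np.column_stack(
                [center_ap + ox, np.full_like(tm, center_ml + lat * oy), center_z + oz]
            )
            if subject.marker_noise_sd > 0:
                pos = pos + rng.normal(0.0, subject.marker_noise_sd, pos.shape)
            positions[f][m] = pos

    # --- ground truth ------------------------------------------------------
    strike_times = {}
    toe_off_times = {}
    for f in FEET:
        own = np.flatnonzero([ft == f for ft in feet])
        strike_times[f] = t_strike[own].copy()
        toe_off_times[f] = t_strike[own] + stance_dur
    truth = GroundTruth(
        step_time=T,
        strike_times=strike_times,
        toe_off_times=toe_off_times,
        target_feet=[t.foot for t in block.targets],
        target_strike_times=t_strike[tgt].copy(),
        target_midstance_times=t_strike[tgt] + (1.0 + delta) * T / 2.0,
        target_landing_ap=A[tgt].copy(),
        true_errors=errors[tgt].copy(),
        appearance_times=appearance.copy(),
        shift_onset_times=shift_onsets,
    )
    markers = MarkerTrajectories(time=tm, positions=positions, rate=150.0)
    cop = COPTrajectory(time=tc, ap=cop_ap, ml=cop_ml, rate=1000.0)
    return SimulatedTrial(markers=markers, cop=cop, truth=truth)
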