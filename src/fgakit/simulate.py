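"""Synthetic straight-line gait with exact ground truth.

The simulator exists so every downstream stage — bout detection, stance
segmentation, step metrics, FGA scoring, two-system agreement — can be
tested against known footstep times and locations. It emulates the
walkway protocol the pipeline targets: straight 4–6 m bouts on a 30 Hz
markerless stream (optionally paired with a faster marker-based
stream), pivot-turn trials, obstacle crossings, and two step-width
conditions (normal and wide).

Kinematic model
---------------
Each heel advances in discrete swings with a raised-cosine
anterior-posterior displacement profile (a C¹ bell-shaped speed pulse;
exactly zero AP velocity during stance). Gait starts and ends in a
staggered stance with the feet one step length apart, so *every* swing
advances 2x step length and ground-truth footsteps are spaced exactly
one step length apart; gait initiation is the exact time-reverse of
termination. Heels ride lateral lanes at ±step_width/2 about the
centerline and lift in a sin² arc of configurable apex during swing.
The head is the analytic midpoint of the two heel paths (already C¹)
at a fixed height, with ear/nose keypoints rigidly offset; only the
average forward position of these keypoints is consumed downstream.
Quiet-standing pads (default 1.5 s) precede and follow the bout so
bout detection has a non-trivial job. Measurement noise is i.i.d.
Gaussian per axis per sample.

The continuous motion is a closed form in time, so the same trial can
be sampled at any rate and time shift — that is what makes paired
two-system recordings and the imposed-lag ground truth exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import KeypointTrajectory

__all__ = [
    "GaitParams",
    "SyntheticGroundTruth",
    "simulate_walk",
    "simulate_pivot_trial",
    "simulate_two_systems",
    "simulate_fga_session",
    "write_ground_truth",
]

EAR_LATERAL_OFFSET = 0.08  # m, ears either side of the head center
NOSE_AP_OFFSET = 0.10  # m, nose forward of the head center
HEAD_HEIGHT_FACTOR = 0.9  # head height as a fraction of the stature proxy
SACRUM_HEIGHT = 1.0  # m, height of the markered sacrum point
TURN_BUMP = 0.08  # m, forward excursion of the feet during a pivot


@dataclass(frozen=True)
class GaitParams:
    """Gait-cycle parameters of a simulated trial.

    ``steady_speed`` is derived (step_length x cadence), never free, so
    spatial and temporal parameters cannot contradict each other. The
    walk distance is rounded to a whole number of steps.
    """

    step_length: float = 0.6  # m, AP spacing of consecutive footsteps
    step_width: float = 0.10  # m, ML spacing of the two heel lanes
    cadence: float = 2.0  # steps/s
    walk_distance: float = 6.0  # m (the standard FGA walkway length)
    stance_fraction: float = 0.6  # fraction of the stride a foot is grounded
    swing_apex_height: float = 0.05  # m, heel lift at mid-swing
    start_pose_lateral_offset: float = 0.0  # m, whole-body ML shift
    noise_sd: float = 0.0  # m, isotropic Gaussian keypoint jitter
    sample_rate: float = 30.0  # Hz
    seed: int = 0
    quiet_pad: float = 1.5  # s of standing before and after the bout
    stature: float = 1.7  # m, proxy used only to place head keypoints

    def __post_init__(self):
        for name in ("step_length", "step_width", "cadence", "sample_rate"):
            if getattr(self, name) < 0 or (
                name != "step_width" and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.noise_sd < 0 or self.quiet_pad < 1.0:
            raise ValueError("noise_sd >= 0 and quiet_pad >= 1 s required")
        if self.n_steps < 2:
            raise ValueError(
                f"walk_distance {self.walk_distance} m covers fewer than 2 "
                f"steps of {self.step_length} m; nothing to detect"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.walk_distance / self.step_length))

    @property
    def steady_speed(self) -> float:
        """m/s; derived, not free."""
        return self.step_length * self.cadence

    @property
    def step_period(self) -> float:
        return 1.0 / self.cadence

    @property
    def swing_duration(self) -> float:
        return 2.0 * (1.0 - self.stance_fraction) * self.step_period


@dataclass
class SyntheticGroundTruth:
    """Exact truth of a simulated trial.

    ``footsteps`` is a list of (side, midstance_time_s, [x, y, z]) in
    trial order. The midstance time is the temporal midpoint of the
    foot's zero-velocity interval, the same definition the detector
    uses. ``speed_profile`` is the noiseless forward speed of the body
    (mid-feet AP derivative) on the markerless sample grid.
    """

    footsteps: list
    bout_start: float
    bout_end: float
    speed_profile: list
    sample_rate: float
    imposed_lag: float | None = None
    turn_interval: tuple | None = None
    obstacle_crossing: tuple | None = None  # (step index, apex height m)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["footsteps"] = [
            {"side": s, "midstance_time": t, "location": list(loc)}
            for s, t, loc in self.footsteps
        ]
        return d


def write_ground_truth(gt: SyntheticGroundTruth, path) -> None:
    Path(path).write_text(json.dumps(gt.to_dict(), indent=1), encoding="utf-8")


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """C¹ unit displacement profile on [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def _swing_arc(u: np.ndarray) -> np.ndarray:
    """C¹ unit lift profile on [0, 1], zero with zero slope at both ends."""
    uc = np.clip(u, 0.0, 1.0)
    return np.sin(np.pi * uc) ** 2


class _WalkMotion:
    """Closed-form straight walk, evaluable at arbitrary times.

    Swing k (k = 1..n, sides alternating, the trailing foot first)
    starts at ``pad + (k-1)·T`` and advances its foot by two step
    lengths. Footstep k lands at AP ``k·L``.
    """

    def __init__(self, params: GaitParams, first_side: str = "left",
                 obstacle_step: int | None = None,
                 obstacle_apex: float | None = None):
        self.p = params
        self.first_side = first_side
        self.obstacle_step = obstacle_step
        self.obstacle_apex = obstacle_apex
        p = params
        self.n = p.n_steps
        self.T = p.step_period
        self.tau = p.swing_duration
        self.onsets = p.quiet_pad + np.arange(self.n) * self.T
        self.ends = self.onsets + self.tau
        self.bout_start = float(self.onsets[0])
        self.bout_end = float(self.ends[-1])
        self.duration = self.bout_end + p.quiet_pad
        # initial AP: the first-swinging (trailing) foot starts one step back
        self.init_ap = {first_side: -p.step_length,
                        self._other(first_side): 0.0}

    @staticmethod
    def _other(side: str) -> str:
        return "right" if side == "left" else "left"

    def side_of_step(self, k: int) -> str:
        """Side of step k (1-based)."""
        return self.first_side if k % 2 == 1 else self._other(self.first_side)

    def _steps_of(self, side: str) -> np.ndarray:
        ks = np.arange(1, self.n + 1)
        return ks[[self.side_of_step(int(k)) == side for k in ks]]

    def foot_ap(self, side: str, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        x = np.full(t.shape, self.init_ap[side])
        for k in self._steps_of(side):
            u = (t - self.onsets[k - 1]) / self.tau
            x = x + 2.0 * self.p.step_length * _raised_cosine(u)
        return x

    def foot_z(self, side: str, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        z = np.zeros(t.shape)
        for k in self._steps_of(side):
            apex = self.p.swing_apex_height
            if self.obstacle_step is not None and k == self.obstacle_step:
                apex = self.obstacle_apex
            u = (t - self.onsets[k - 1]) / self.tau
            inside = (u > 0) & (u < 1)
            z = np.where(inside, apex * _swing_arc(u), z)
        return z

    def foot_ml(self, side: str) -> float:
        half = self.p.step_width / 2.0
        lane = half if side == "left" else -half
        return lane + self.p.start_pose_lateral_offset

    def eval(self, t: np.ndarray) -> dict[str, np.ndarray]:
        """Noise-free keypoint positions at arbitrary times (head basis)."""
        t = np.asarray(t, float)
        out = {}
        for side in ("left", "right"):
            ap = self.foot_ap(side, t)
            ml = np.full(t.shape, self.foot_ml(side))
            out[f"{side}_heel"] = np.column_stack([ap, ml, self.foot_z(side, t)])
        mid = 0.5 * (out["left_heel"][:, :2] + out["right_heel"][:, :2])
        out["_head_center"] = np.column_stack(
            [mid, np.full(t.shape, HEAD_HEIGHT_FACTOR * self.p.stature)]
        )
        return out

    def footstep_truth(self) -> list:
        """(side, midstance_time, location) per step, detector-consistent.

        A foot's stance runs from its landing to its next swing onset,
        or to the end of the trial for the last two steps.
        """
        steps = []
        for k in range(1, self.n + 1):
            side = self.side_of_step(k)
            land = self.ends[k - 1]
            t_next = self.onsets[k + 1] if (k + 2) <= self.n else self.duration
            mid = 0.5 * (land + t_next)
            loc = [k * self.p.step_length, self.foot_ml(side), 0.0]
            steps.append((side, float(mid), loc))
        return steps


def _head_keypoints(head_center: np.ndarray, facing: np.ndarray | float = 1.0):
    """Markerless head keypoints rigidly offset from the head center.

    ``facing`` is +1 walking forward, -1 walking back; ear/nose offsets
    rotate with it (only their *average* AP matters downstream).
    """
    f = np.broadcast_to(np.asarray(facing, float), head_center[:, 0].shape)
    left_ear = head_center + np.column_stack(
        [np.zeros_like(f), EAR_LATERAL_OFFSET * f, np.zeros_like(f)]
    )
    right_ear = head_center + np.column_stack(
        [np.zeros_like(f), -EAR_LATERAL_OFFSET * f, np.zeros_like(f)]
    )
    nose = head_center + np.column_stack(
        [NOSE_AP_OFFSET * f, np.zeros_like(f), np.zeros_like(f)]
    )
    return {"left_ear": left_ear, "right_ear": right_ear, "nose": nose}


def _assemble(positions: dict, params: GaitParams, rng, sample_rate=None,
              dialect: str = "markerless") -> KeypointTrajectory:
    head = positions.pop("_head_center")
    facing = positions.pop("_facing", 1.0)
    if dialect == "markerless":
        positions.update(_head_keypoints(head, facing))
    else:
        positions["left_foot"] = positions.pop("left_heel")
        positions["right_foot"] = positions.pop("right_heel")
        positions["head"] = head
        positions["sacrum"] = np.column_stack(
            [head[:, 0], head[:, 1], np.full(head.shape[0], SACRUM_HEIGHT)]
        )
    if params.noise_sd > 0:
        positions = {
            k: v + rng.normal(0.0, params.noise_sd, v.shape)
            for k, v in positions.items()
        }
    return KeypointTrajectory(
        sample_rate=sample_rate or params.sample_rate,
        positions=positions,
        frame_tag="walkway",
    )


def _speed_profile(motion_eval, t: np.ndarray) -> np.ndarray:
    head = motion_eval(t)["_head_center"][:, 0]
    return np.gradient(head, t)


def simulate_walk(
    params: GaitParams,
    obstacle_step: int | None = None,
    obstacle_apex: float | None = None,
) -> tuple[KeypointTrajectory, SyntheticGroundTruth]:
    """Simulate one straight walking bout on the markerless stream.

    Optionally one step (1-based index) crosses an obstacle: its swing
    apex is raised to ``obstacle_apex`` meters.
    """
    if obstacle_step is not None:
        if not 1 <= obstacle_step <= params.n_steps:
            raise ValueError("obstacle_step outside the step sequence")
        if obstacle_apex is None or obstacle_apex <= params.swing_apex_height:
            raise ValueError("obstacle_apex must exceed the normal swing apex")
    motion = _WalkMotion(params, obstacle_step=obstacle_step,
                         obstacle_apex=obstacle_apex)
    n_samp = int(np.floor(motion.duration * params.sample_rate)) + 1
    t = np.arange(n_samp) / params.sample_rate
    rng = np.random.default_rng(params.seed)
    traj = _assemble(motion.eval(t), params, rng)
    gt = SyntheticGroundTruth(
        footsteps=motion.footstep_truth(),
        bout_start=motion.bout_start,
        bout_end=motion.bout_end,
        speed_profile=_speed_profile(motion.eval, t).tolist(),
        sample_rate=params.sample_rate,
        obstacle_crossing=(obstacle_step, obstacle_apex)
        if obstacle_step is not None
        else None,
    )
    return traj, gt


class _PivotMotion:
    """Walk out, reverse heading 180° over ``turn_duration``, walk back.

    During the turn both feet share a small forward sin² excursion
    (amplitude ``TURN_BUMP``) so the AP head position has a unique
    interior maximum, while foot and head speeds stay near zero — the
    body is turning, not progressing. The return leg mirrors the
    outbound leg: AP reflected about the far end, anatomical lanes
    swapped (after a 180° turn the subject's left is the walkway's
    right).
    """

    def __init__(self, params: GaitParams, turn_duration: float):
        if turn_duration <= 0:
            raise ValueError("turn_duration must be positive")
        if turn_duration > 15.0:
            raise ValueError("turn_duration longer than the trial is rejected")
        self.p = params
        self.out = _WalkMotion(params, first_side="left")
        self.turn_duration = turn_duration
        self.turn_start = self.out.bout_end
        self.turn_end = self.turn_start + turn_duration
        # the foot that landed last (farthest along) leads the turn and
        # swings first on the way back
        back_first = self.out.side_of_step(self.out.n)
        self.back = _WalkMotion(params, first_side=back_first)
        self.back_offset = self.turn_end - self.back.bout_start
        # AP reflection constant: back's initial staggered pose maps onto
        # out's final pose
        self.C = (self.out.n - 1) * params.step_length
        self.duration = self.back_offset + self.back.duration

    def _bump(self, t: np.ndarray) -> np.ndarray:
        u = (np.asarray(t, float) - self.turn_start) / self.turn_duration
        return TURN_BUMP * _swing_arc(u)

    def eval(self, t: np.ndarray) -> dict[str, np.ndarray]:
        t = np.asarray(t, float)
        out_phase = self.out.eval(np.minimum(t, self.turn_start))
        tb = np.maximum(t - self.back_offset, 0.0)
        res = {}
        in_back = t >= self.turn_end
        for side in ("left", "right"):
            fwd = out_phase[f"{side}_heel"]
            g = "left" if side == self.back.first_side else "right"
            # note: anatomical `side` on the way back follows back-walk
            # foot `g`, AP-reflected and lane-negated
            bap = self.C - self.back.foot_ap(g, tb)
            bml = -self.back.foot_ml(g)
            bz = self.back.foot_z(g, tb)
            back = np.column_stack([bap, np.full(t.shape, bml), bz])
            pos = np.where(in_back[:, None], back, fwd)
            pos[:, 0] = pos[:, 0] + self._bump(t)
            res[f"{side}_heel"] = pos
        mid = 0.5 * (res["left_heel"][:, :2] + res["right_heel"][:, :2])
        res["_head_center"] = np.column_stack(
            [mid, np.full(t.shape, HEAD_HEIGHT_FACTOR * self.p.stature)]
        )
        # head yaw: +1 facing forward, -1 facing back, rotating smoothly
        # through the turn so keypoint offsets carry no discontinuity
        u = np.clip((t - self.turn_start) / self.turn_duration, 0.0, 1.0)
        res["_facing"] = np.cos(np.pi * u)
        return res

    def footstep_truth(self) -> list:
        steps = list(self.out.footstep_truth())
        # outbound last-two stances end at the turn start, not trial end
        fixed = []
        for i, (side, mid, loc) in enumerate(steps, start=1):
            land = self.out.ends[i - 1]
            t_next = (self.out.onsets[i + 1] if (i + 2) <= self.out.n
                      else self.turn_start)
            fixed.append((side, float(0.5 * (land + t_next)), loc))
        for side, mid, loc in self.back.footstep_truth():
            g_ap = self.C - loc[0]
            fixed.append((side, float(mid + self.back_offset),
                          [g_ap, -loc[1], loc[2]]))
        return fixed


def simulate_pivot_trial(
    params: GaitParams, turn_duration: float
) -> tuple[KeypointTrajectory, SyntheticGroundTruth]:
    """Simulate a pivot-turn trial: walk out, 180° turn, walk back."""
    motion = _PivotMotion(params, turn_duration)
    n_samp = int(np.floor(motion.duration * params.sample_rate)) + 1
    t = np.arange(n_samp) / params.sample_rate
    rng = np.random.default_rng(params.seed)
    traj = _assemble(motion.eval(t), params, rng)
    gt = SyntheticGroundTruth(
        footsteps=motion.footstep_truth(),
        bout_start=motion.out.bout_start,
        bout_end=float(motion.back.bout_end + motion.back_offset),
        speed_profile=_speed_profile(motion.eval, t).tolist(),
        sample_rate=params.sample_rate,
        turn_interval=(float(motion.turn_start), float(motion.turn_end)),
    )
    return traj, gt


def simulate_two_systems(
    params: GaitParams,
    lag: float = 0.0,
    markered_rate: float = 240.0,
    markerless_noise_sd: float | None = None,
) -> tuple[KeypointTrajectory, KeypointTrajectory, SyntheticGroundTruth]:
    """Paired recording of one walk by two measurement systems.

    Both streams sample the *same* continuous motion. The markered
    stream (left_foot/right_foot/head/sacrum) runs at ``markered_rate``
    with no noise; the markerless stream (heels/ears/nose) runs at the
    trial sample rate, is delayed by ``lag`` seconds (its events appear
    ``lag`` later on its own clock) and carries its own keypoint noise.
    """
    if markered_rate < params.sample_rate:
        raise ValueError("markered_rate must be at least the markerless rate")
    if abs(lag) >= 2.0:
        raise ValueError("|lag| must be below 2 s")
    motion = _WalkMotion(params)
    rng = np.random.default_rng(params.seed)
    noise_sd = params.noise_sd if markerless_noise_sd is None else markerless_noise_sd

    import dataclasses as _dc

    t_mk = np.arange(int(np.floor(motion.duration * markered_rate)) + 1) / markered_rate
    mk = _assemble(motion.eval(t_mk), _dc.replace(params, noise_sd=0.0), rng,
                   sample_rate=markered_rate, dialect="markered")

    t_ml = np.arange(int(np.floor(motion.duration * params.sample_rate)) + 1
                     ) / params.sample_rate
    ml_positions = motion.eval(t_ml - lag)
    ml_params = _dc.replace(params, noise_sd=noise_sd)
    ml = _assemble(ml_positions, ml_params, rng)
    gt = SyntheticGroundTruth(
        footsteps=motion.footstep_truth(),
        bout_start=motion.bout_start,
        bout_end=motion.bout_end,
        speed_profile=_speed_profile(motion.eval, t_ml).tolist(),
        sample_rate=params.sample_rate,
        imposed_lag=lag,
    )
    return ml, mk, gt


#: per-condition simulation recipe for a full ten-condition session.
#: values are speed ratios relative to Condition 1 (realized by scaling
#: step length at fixed cadence), except conditions 5 and 6 which have
#: their own trial types.
DEFAULT_SESSION_RATIOS = {
    1: 1.00, 2: 1.30, 3: 1.00, 4: 1.00, 7: 0.85, 8: 0.80, 9: 0.70, 10: 0.90,
}


def simulate_fga_session(
    base: GaitParams,
    seed: int = 0,
    n_reps: int = 1,
    speed_ratios: dict | None = None,
    turn_duration: float = 2.5,
    obstacle_apex: float = 0.25,
):
    """Simulate a ten-condition FGA session.

    Conditions 1-4 and 7-10 are straight walks whose steady speed is
    ``speed_ratios[cond]`` times the Condition-1 speed (step length
    scaled at fixed cadence); Condition 5 is a pivot-turn trial and
    Condition 6 an obstacle crossing on the middle step. Returns
    ``{condition: [(trajectory, ground_truth), ...]}``.
    """
    ratios = dict(DEFAULT_SESSION_RATIOS)
    if speed_ratios:
        ratios.update(speed_ratios)
    import dataclasses as _dc

    session = {}
    for cond in range(1, 11):
        trials = []
        for rep in range(n_reps):
            trial_seed = (seed * 1009 + cond * 101 + rep) % (2**31 - 1)
            if cond == 5:
                p = _dc.replace(base, seed=trial_seed)
                trials.append(simulate_pivot_trial(p, turn_duration))
            elif cond == 6:
                p = _dc.replace(base, seed=trial_seed)
                trials.append(
                    simulate_walk(p, obstacle_step=max(2, p.n_steps // 2),
                                  obstacle_apex=obstacle_apex)
                )
            else:
                p = _dc.replace(
                    base,
                    seed=trial_seed,
                    step_length=base.step_length * ratios[cond],
                )
                trials.append(simulate_walk(p))
        session[cond] = trials
    return session
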