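"""Trial state machine, feedback conditions, scoring and trial scheduling.

A trial has four phases on a fixed 75 Hz frame grid spanning [-0.5 s,
2.0 s) around target appearance: a 0.5 s start-hold during which the cursor
must stay inside the starting zone, a 1 s movement period opened by a cue
tone (660 Hz), a 1 s hold period opened by a second tone (880 Hz), and a
score display.  The score is the percentage of hold-phase screen updates on
which the cursor circle overlapped the target circle:

    score = 100 * n / N,   n = #frames with |target - cursor| < r_t + r_c

with strict inequality, so exact tangency does not count.

Feedback conditions:

========  ======================  =============================
condition  cursor visible          manipulandum (handle) active
VF+PF      yes                     yes
PF         no                      yes
VF         yes                     no
noFB       no                      no
========  ======================  =============================

The handle tracks the cursor (or its mirror image about the vertical
midline in the incongruent protocol of Experiment 3) but never feeds back
into the cursor: cursor trajectories are identical whether or not the
manipulandum is simulated.  The final cursor position and the target remain
visible with the score in every condition (terminal feedback).

Experiments:

1. 480 trials: 120 familiarization (VF+PF) + 360 test in 15 blocks of 24;
   in every block, VF+PF pairs with each of the four targets three times
   and PF, VF and noFB with each target exactly once.  Muscles APB/ADM.
2. 240 trials: 120 familiarization with VF only + 120 test in 5 blocks,
   otherwise as Experiment 1.
3. 240 trials as Experiment 2 but familiarization in VF+PF and with the
   proprioceptive feedback mirrored at the vertical midline in all
   PF-bearing conditions.  Muscles 1DI/ECR (naive to the mapping).

Within-block order is a uniform seeded shuffle of the 24 constrained
trials; familiarization targets are balanced in shuffled groups of four.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import metrics as _metrics
from .geometry import (
    ConfigurationError,
    DoAConfig,
    WorkspaceGeometry,
    required_activations,
    target_position_rel,
)
from .manipulandum import PlantParams, mirror_reference, simulate_tracking

__all__ = [
    "CONDITIONS",
    "BLOCK_SIZE",
    "TrialSpec",
    "TrialRecord",
    "build_schedule",
    "compute_score",
    "run_trial",
    "frame_grid",
    "experiment_info",
]

CONDITIONS = ("VF+PF", "PF", "VF", "noFB")
BLOCK_SIZE = 24
#: (condition -> trials per target per test block)
BLOCK_CONDITION_COUNTS = {"VF+PF": 3, "PF": 1, "VF": 1, "noFB": 1}

_EXPERIMENTS = {
    1: dict(n_fam=120, n_test=360, fam_condition="VF+PF", mirrored=False,
            muscles=("APB", "ADM")),
    2: dict(n_fam=120, n_test=120, fam_condition="VF", mirrored=False,
            muscles=("APB", "ADM")),
    3: dict(n_fam=120, n_test=120, fam_condition="VF+PF", mirrored=True,
            muscles=("1DI", "ECR")),
}

#: Frames before the cue (0.5 s at 75 Hz; 37.5 rounds up to 38).
PRE_CUE_FRAMES = 38
MOVEMENT_S = 1.0
HOLD_S = 1.0
CUE_TONES = ((0.0, 660.0, 0.25), (1.0, 880.0, 0.25))
START_HOLD_TIMEOUT_S = 10.0


def experiment_info(experiment_id: int) -> dict:
    try:
        return dict(_EXPERIMENTS[experiment_id])
    except KeyError:
        raise ConfigurationError(
            f"unknown experiment id {experiment_id!r}; expected 1, 2 or 3"
        ) from None


@dataclass(frozen=True)
class TrialSpec:
    """Scheduled condition and target of one trial."""

    experiment_id: int
    trial_index: int  # 1-based over the whole experiment
    phase: str  # 'familiarization' | 'test'
    target_index: int
    condition: str
    mirrored_pf: bool = False
    control_muscles: tuple[str, str] = ("APB", "ADM")

    @property
    def block(self) -> int:
        """1-based index of the 24-trial block containing this trial."""
        return (self.trial_index - 1) // BLOCK_SIZE + 1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.mirrored_pf and self.experiment_id != 3:
            raise ValueError("mirrored proprioception occurs only in Experiment 3")

    @property
    def has_pf(self) -> bool:
        return self.condition in ("VF+PF", "PF")

    @property
    def has_vf(self) -> bool:
        return self.condition in ("VF+PF", "VF")


@dataclass
class TrialRecord:
    """Everything recorded for one executed trial."""

    spec: TrialSpec
    frame_times: np.ndarray
    phase_labels: np.ndarray  # 'pre-cue' | 'movement' | 'hold' per frame
    cursor: np.ndarray  # (n_frames, 2) cm relative to start
    activations: np.ndarray  # (n_frames, 2) normalized
    handle: np.ndarray | None  # absent without proprioceptive feedback
    events: tuple  # (time_s, tone_hz, duration_s)
    score: float
    metrics: _metrics.TrialMetrics
    valid: bool = True


def frame_grid(display_rate: float = 75.0) -> np.ndarray:
    """Frame times of one trial: PRE_CUE_FRAMES before the cue, then the
    movement and hold periods; t = 0 is target appearance."""
    n_move = int(round(MOVEMENT_S * display_rate))
    n_hold = int(round(HOLD_S * display_rate))
    idx = np.arange(-PRE_CUE_FRAMES, n_move + n_hold)
    return idx / display_rate


def _phase_labels(frame_times: np.ndarray) -> np.ndarray:
    labels = np.where(
        frame_times < 0.0,
        "pre-cue",
        np.where(frame_times < MOVEMENT_S, "movement", "hold"),
    )
    return labels.astype(object)


def build_schedule(
    experiment_id: int,
    seed: int,
    geometry: WorkspaceGeometry | None = None,
) -> list[TrialSpec]:
    """Constrained pseudorandom trial schedule for one subject."""
    info = experiment_info(experiment_id)
    geometry = geometry or WorkspaceGeometry()
    n_targets = geometry.n_targets
    rng = np.random.default_rng(seed)
    specs: list[TrialSpec] = []

    def _mirrored(condition: str) -> bool:
        return info["mirrored"] and condition in ("VF+PF", "PF")

    # familiarization: single condition, targets balanced in shuffled groups
    fam_cond = info["fam_condition"]
    for _ in range(info["n_fam"] // n_targets):
        for t in rng.permutation(n_targets):
            specs.append(
                TrialSpec(
                    experiment_id,
                    len(specs) + 1,
                    "familiarization",
                    int(t),
                    fam_cond,
                    _mirrored(fam_cond),
                    info["muscles"],
                )
            )

    # test: blocks of 24 satisfying the per-block condition x target counts
    block_items = [
        (cond, t)
        for cond, count in BLOCK_CONDITION_COUNTS.items()
        for t in range(n_targets)
        for _ in range(count)
    ]
    assert len(block_items) == BLOCK_SIZE
    for _ in range(info["n_test"] // BLOCK_SIZE):
        for k in rng.permutation(len(block_items)):
            cond, t = block_items[k]
            specs.append(
                TrialSpec(
                    experiment_id,
                    len(specs) + 1,
                    "test",
                    t,
                    cond,
                    _mirrored(cond),
                    info["muscles"],
                )
            )
    return specs


def compute_score(
    hold_positions,
    target_position,
    geometry: WorkspaceGeometry,
) -> float:
    """Percentage of hold-phase frames with cursor-target circle overlap."""
    pos = np.atleast_2d(np.asarray(hold_positions, dtype=float))
    if pos.shape[0] == 0:
        raise ValueError("hold phase is empty")
    dist = np.linalg.norm(pos - np.asarray(target_position, dtype=float), axis=1)
    n = int(np.count_nonzero(dist < geometry.overlap_threshold))
    return 100.0 * n / pos.shape[0]


def run_trial(
    spec: TrialSpec,
    subject,
    geometry: WorkspaceGeometry | None = None,
    doa: DoAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    plant_params: PlantParams | None = None,
    simulate_handle: bool = True,
) -> TrialRecord:
    """Execute one trial of the state machine with a synthetic subject.

    ``subject`` supplies the behaviour (see :class:`myoprop.synth.SubjectModel`):
    a planned activation for the target, a condition-dependent feedback
    correction gain, and noise scales.  The cursor is driven by the
    subject's activations through the control law; in PF-bearing conditions
    the handle additionally tracks the (possibly mirrored) cursor, without
    ever influencing it.

    All random draws happen before the handle simulation, so cursor
    trajectories are bit-identical with ``simulate_handle`` on or off.
    """
    geometry = geometry or WorkspaceGeometry()
    doa = doa or DoAConfig(gain_length=geometry.ring_radius)
    rng = np.random.default_rng(rng)
    dt = 1.0 / geometry.display_rate
    times = frame_grid(geometry.display_rate)
    n_frames = times.size
    n_pre = PRE_CUE_FRAMES
    n_post = n_frames - n_pre

    u_star = required_activations(spec.target_index, doa, geometry)
    u_plan = subject.plan_trial(spec, u_star, rng)
    gain = subject.feedback_gain(spec.condition)

    # vectorized control law (identical to geometry.cursor_position per frame)
    aligned = doa.aligned_muscle(geometry.target_angles_deg[spec.target_index])
    muscle_mask = np.ones(2)
    if aligned is not None:
        muscle_mask[1 - aligned] = 0.0

    def _map(acts: np.ndarray) -> np.ndarray:
        return doa.gain_length * (
            (np.maximum(acts, 0.0) * muscle_mask) @ doa.directions
        )

    # --- start-hold: rest-level activation must keep the cursor in the zone
    sigma_rest = subject.sigma_rest
    attempts = int(np.ceil(START_HOLD_TIMEOUT_S / (n_pre * dt)))
    valid = False
    for _ in range(max(attempts, 1)):
        u_pre = np.maximum(rng.normal(0.0, sigma_rest, size=(n_pre, 2)), 0.0)
        pre_pos = _map(u_pre)
        if np.all(np.linalg.norm(pre_pos, axis=1) < geometry.start_zone_radius):
            valid = True
            break
    # a trial that never satisfies the start criterion within the timeout is
    # marked invalid; the caller reschedules it at the end of the block

    # --- movement + hold: feedforward ramp to the plan plus feedback correction
    noise = rng.standard_normal(size=(n_post, 2))
    u_post = np.empty((n_post, 2))
    u_ff = u_pre[-1].copy()
    corr = np.zeros(2)
    g_ff = subject.g_ff
    sigma_exec = subject.sigma_exec
    u = np.maximum(u_ff + corr, 0.0)
    sqrt_dt = np.sqrt(dt)
    # exact discretization of the first-order ramp (stable for any g_ff)
    alpha_ff = -np.expm1(-g_ff * dt)
    for k in range(n_post):
        u_ff = u_ff + alpha_ff * (u_plan - u_ff)
        corr = corr + gain * (u_star - u) * dt + sigma_exec * sqrt_dt * noise[k]
        u = np.maximum(u_ff + corr, 0.0)
        u_post[k] = u
    activations = np.vstack([u_pre, u_post])
    cursor = _map(activations)

    handle = None
    if simulate_handle and spec.has_pf:
        reference = mirror_reference(cursor) if spec.mirrored_pf else cursor
        handle = simulate_tracking(reference, plant_params, dt)

    labels = _phase_labels(times)
    target_rel = target_position_rel(geometry, spec.target_index)
    hold_mask = labels == "hold"
    score = compute_score(cursor[hold_mask], target_rel, geometry)
    is_2d = not doa.is_1d_target(geometry, spec.target_index)
    tm = _metrics.trial_metrics(cursor[n_pre:], times[n_pre:], target_rel, is_2d)

    subject.end_trial(spec, activations[-1], u_star)
    return TrialRecord(
        spec=spec,
        frame_times=times,
        phase_labels=labels,
        cursor=cursor,
        activations=activations,
        handle=handle,
        events=CUE_TONES,
        score=score,
        metrics=tm,
        valid=valid,
    )
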