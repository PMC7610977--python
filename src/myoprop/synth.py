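"""Synthetic subjects and cohorts.

No public recordings exist for this task, so the analysis pipeline is
exercised on simulated participants.  A subject is modelled as a
first-order feedback controller in activation space — the simplest
structure that expresses all four feedback-condition contrasts:

* **Planning.**  Before each trial the subject forms a planned activation
  ``u_plan = u* + bias + eps`` where ``u*`` is the activation pair that
  exactly reaches the target, ``bias`` is a slowly-learned systematic
  miscalibration and ``eps`` is zero-mean Gaussian planning noise whose
  standard deviation decays exponentially over trials,
  ``sigma(k) = sigma_inf + (sigma0 - sigma_inf) * exp(-(k-1)/tau_learn)``.

* **Execution.**  Within a trial the activation ramps toward the plan with
  rate ``g_ff`` (feedforward) while a feedback correction integrates the
  remaining error with a condition-dependent gain,

      G(VF+PF) = g_v + c_v*g_p*w_p,  G(VF) = g_v,  G(PF) = g_p*w_p,
      G(noFB) = 0,

  where ``c_v`` (``vision_precedence``) down-weights the proprioceptive
  channel while a visible cursor allows direct cursor-target matching —
  which is why added proprioception does not measurably improve the
  overall mismatch when vision is available,

  plus white execution noise of scale ``sigma_exec`` per square-root
  second.  ``w_p`` is the learned *proprioceptive association weight*: the
  degree to which the subject has learned to interpret the handle motion
  of the manipulandum as task feedback.

* **Learning across trials.**  ``w_p`` grows by ``eta`` on every trial in
  which proprioceptive feedback is delivered; when the feedback is
  mirrored *and* a visible cursor dominates, growth is multiplied by
  ``mirror_penalty`` (incongruent proprioception is down-weighted while
  vision is available, but can be learned when vision is absent).  The
  plan bias decays with ``tau_learn`` and is additionally corrected by the
  terminal feedback (the last cursor position displayed with the score,
  available in every condition) at rate ``eta_T`` — the source of the slow
  improvement visible even without on-line feedback.

* **Non-learners.**  A minority of subjects never acquire reliable
  control; they are modelled with a large fixed bias, undiminished
  planning noise and strongly attenuated feedback gains, so that the
  standard exclusion rule (mean visual-feedback mismatch over trials
  121-240 above 0.8) flags them.

All model equations here are the package's own construction; only the
qualitative behavioural structure they reproduce is prescribed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DoAConfig, WorkspaceGeometry
from .manipulandum import PlantParams
from .metrics import WINDOW_NAMES
from .task import BLOCK_SIZE, TrialRecord, build_schedule, experiment_info, run_trial

__all__ = [
    "SubjectModel",
    "default_subject",
    "default_non_learner",
    "generate_cohort",
    "DEFAULT_COHORT_SIZES",
    "DEFAULT_FRACTION_NON_LEARNERS",
]

#: Cohort sizes of the three study protocols.
DEFAULT_COHORT_SIZES = {1: 21, 2: 19, 3: 19}

#: Default share of simulated subjects that never gain viable control.
DEFAULT_FRACTION_NON_LEARNERS = 0.1


@dataclass
class SubjectModel:
    """Parameters and learning state of one synthetic subject.

    Gains are 1/s, noise scales are in normalized-activation units and
    ``tau_learn`` counts trials.  ``bias``, ``w_p`` and ``trial_count``
    mutate as trials are executed.
    """

    sigma0: float = 0.40
    sigma_inf: float = 0.22
    tau_learn: float = 90.0
    bias: np.ndarray = field(default_factory=lambda: np.zeros(2))
    g_ff: float = 8.0
    g_v: float = 3.5
    g_p: float = 2.0
    vision_precedence: float = 0.3
    w_p: float = 0.02
    eta: float = 0.003
    mirror_penalty: float = 0.15
    eta_T: float = 0.01
    sigma_exec: float = 0.25
    sigma_rest: float = 0.01
    non_learner: bool = False
    non_learner_gain_factor: float = 0.02
    trial_count: int = 0  # trials completed so far

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float).copy()
        if not (self.sigma0 >= self.sigma_inf > 0):
            raise ValueError("noise schedule requires sigma0 >= sigma_inf > 0")
        if min(self.g_ff, self.g_v, self.g_p, self.eta, self.eta_T) < 0:
            raise ValueError("gains and learning rates must be non-negative")
        if not 0.0 <= self.w_p <= 1.0:
            raise ValueError("w_p must lie in [0, 1]")
        if not 0.0 <= self.mirror_penalty <= 1.0:
            raise ValueError("mirror_penalty must lie in [0, 1]")
        if self.tau_learn <= 0:
            raise ValueError("tau_learn must be positive")

    # ------------------------------------------------------------------
    # per-trial behaviour
    # ------------------------------------------------------------------
    def plan_noise_sd(self, trial_index: int | None = None) -> float:
        """Planning-noise s.d. before trial ``trial_index`` (1-based)."""
        if self.non_learner:
            return self.sigma0
        k = self.trial_count if trial_index is None else trial_index - 1
        return self.sigma_inf + (self.sigma0 - self.sigma_inf) * np.exp(
            -k / self.tau_learn
        )

    def plan_trial(self, spec, u_star, rng: np.random.Generator) -> np.ndarray:
        """Planned activation pair for the upcoming trial (clamped at 0)."""
        sd = self.plan_noise_sd(spec.trial_index)
        eps = rng.normal(0.0, sd, size=2) if sd > 0 else np.zeros(2)
        return np.maximum(np.asarray(u_star, dtype=float) + self.bias + eps, 0.0)

    def feedback_gain(self, condition: str) -> float:
        """Within-trial error-correction gain of a feedback condition (1/s)."""
        gains = {
            "VF+PF": self.g_v + self.vision_precedence * self.g_p * self.w_p,
            "VF": self.g_v,
            "PF": self.g_p * self.w_p,
            "noFB": 0.0,
        }
        g = gains[condition]
        if self.non_learner:
            g *= self.non_learner_gain_factor
        return g

    def within_trial_update(
        self,
        u,
        u_star,
        condition: str,
        dt: float,
        noise=(0.0, 0.0),
    ) -> np.ndarray:
        """Activation increment for one control interval.

        ``du = G * (u* - u) * dt + sigma_exec * sqrt(dt) * noise``; with no
        feedback (G = 0) the increment is pure execution noise.  The trial
        loop in :func:`myoprop.task.run_trial` applies exactly this update
        to the correction component of the activation.
        """
        g = self.feedback_gain(condition)
        u = np.asarray(u, dtype=float)
        u_star = np.asarray(u_star, dtype=float)
        noise = np.asarray(noise, dtype=float)
        return g * (u_star - u) * dt + self.sigma_exec * np.sqrt(dt) * noise

    def end_trial(self, spec, u_end, u_star) -> None:
        """Between-trial learning after the score display.

        Proprioceptive-association growth requires actual exposure to the
        handle; incongruent (mirrored) feedback is learned at a penalized
        rate while a visible cursor is present.  The plan bias decays with
        ``tau_learn`` and is nudged against the terminal activation error.
        """
        self.trial_count += 1
        if self.non_learner:
            return
        if spec.has_pf:
            rate = self.eta
            if spec.mirrored_pf and spec.has_vf:
                rate *= self.mirror_penalty
            self.w_p = min(1.0, self.w_p + rate)
        err = np.asarray(u_end, dtype=float) - np.asarray(u_star, dtype=float)
        self.bias = self.bias * np.exp(-1.0 / self.tau_learn) - self.eta_T * err


def default_subject(
    rng: np.random.Generator,
    bias_magnitude: float = 0.35,
    **overrides,
) -> SubjectModel:
    """A learner with a random bias direction and mild parameter jitter."""
    angle = rng.uniform(0.0, 2.0 * np.pi)
    bias = bias_magnitude * np.array([np.cos(angle), np.sin(angle)])
    params = dict(
        bias=bias,
        tau_learn=90.0 * np.exp(rng.normal(0.0, 0.2)),
        sigma0=0.40 * (1.0 + rng.uniform(-0.1, 0.1)),
    )
    params.update(overrides)
    return SubjectModel(**params)


def default_non_learner(rng: np.random.Generator, **overrides) -> SubjectModel:
    """A subject who never gains viable control of the interface.

    Modelled as strong tonic co-contraction of both muscles (a common
    failure mode: inability to relax or differentiate the controlling
    muscles) with large, non-decaying planning noise and barely effective
    feedback corrections.
    """
    params = dict(
        bias=rng.uniform(0.6, 1.1, size=2),
        sigma0=0.60,
        sigma_inf=0.55,
        non_learner=True,
        non_learner_gain_factor=0.02,
    )
    params.update(overrides)
    return SubjectModel(**params)


# ----------------------------------------------------------------------
# cohort generation
# ----------------------------------------------------------------------

def _summary_row(subject_id: int, record: TrialRecord, non_learner: bool) -> dict:
    spec = record.spec
    m = record.metrics
    row = {
        "subject": subject_id,
        "experiment": spec.experiment_id,
        "trial_index": spec.trial_index,
        "block": spec.block,
        "phase": spec.phase,
        "condition": spec.condition,
        "target_index": spec.target_index,
        "mirrored_pf": spec.mirrored_pf,
        "is_2d": m.angular_error is not None,
        "non_learner": non_learner,
        "valid": record.valid,
        "score": record.score,
        "mismatch": m.mismatch,
    }
    for name, value in zip(WINDOW_NAMES, m.radial_window_means):
        row[f"eps_r_{name}"] = value
    ang = m.angular_window_means or (np.nan,) * len(WINDOW_NAMES)
    for name, value in zip(WINDOW_NAMES, ang):
        row[f"eps_ang_{name}"] = value
    return row


def generate_cohort(
    experiment_id: int,
    n_subjects: int | None = None,
    fraction_non_learners: float = DEFAULT_FRACTION_NON_LEARNERS,
    seed: int = 0,
    geometry: WorkspaceGeometry | None = None,
    doa: DoAConfig | None = None,
    plant_params: PlantParams | None = None,
    simulate_handle: bool = False,
    subject_factory=None,
    return_records: bool = False,
):
    """Simulate a full cohort of one experiment.

    Returns a trial-summary :class:`pandas.DataFrame` (one row per trial,
    with score, mismatch and windowed polar errors), or a ``(summary,
    records)`` pair when ``return_records`` is true.  The handle simulation
    is off by default because it cannot influence the cursor and therefore
    none of the summary metrics; enable it to study tracking fidelity.

    The number of non-learners is ``round(fraction * n)``; which subjects
    they are is drawn deterministically from ``seed``.  Each subject gets
    an independent schedule and noise stream spawned from the cohort seed,
    so a fixed seed reproduces the dataset exactly.  A trial that fails the
    start-hold criterion within the timeout is rescheduled once at the end
    of its block (keeping its trial index).
    """
    info = experiment_info(experiment_id)  # validates the id
    if n_subjects is None:
        n_subjects = DEFAULT_COHORT_SIZES[experiment_id]
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if not 0.0 <= fraction_non_learners <= 1.0:
        raise ValueError("fraction_non_learners must lie in [0, 1]")
    geometry = geometry or WorkspaceGeometry()
    doa = doa or DoAConfig(gain_length=geometry.ring_radius)

    root = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    n_non = int(round(fraction_non_learners * n_subjects))
    non_learner_ids = set(
        assign_rng.choice(n_subjects, size=n_non, replace=False).tolist()
    )

    rows: list[dict] = []
    records: list[TrialRecord] = []
    for sid, subject_seq in enumerate(root.spawn(n_subjects + 1)[1:]):
        schedule_seq, trial_seq, param_seq = subject_seq.spawn(3)
        param_rng = np.random.default_rng(param_seq)
        if subject_factory is not None:
            subject = subject_factory(sid, param_rng)
        elif sid in non_learner_ids:
            subject = default_non_learner(param_rng)
        else:
            subject = default_subject(param_rng)
        schedule = build_schedule(experiment_id, schedule_seq, geometry)
        rng = np.random.default_rng(trial_seq)

        n_blocks = len(schedule) // BLOCK_SIZE
        for b in range(n_blocks):
            block = list(schedule[b * BLOCK_SIZE : (b + 1) * BLOCK_SIZE])
            retried: set[int] = set()
            i = 0
            while i < len(block):
                spec = block[i]
                record = run_trial(
                    spec,
                    subject,
                    geometry,
                    doa,
                    rng,
                    plant_params,
                    simulate_handle,
                )
                if not record.valid and spec.trial_index not in retried:
                    retried.add(spec.trial_index)
                    block.append(spec)  # reschedule at block end
                else:
                    rows.append(_summary_row(sid, record, subject.non_learner))
                    if return_records:
                        records.append(record)
                i += 1

    summary = pd.DataFrame(rows).sort_values(
        ["subject", "trial_index"], kind="stable"
    )
    summary = summary.reset_index(drop=True)
    if return_records:
        return summary, records
    return summary
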