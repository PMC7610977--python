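"""Statistical pipeline for cohort datasets.

Operates on the trial-summary DataFrame produced by
:func:`myoprop.synth.generate_cohort` (or loaded from a summary CSV):

* exclusion of non-learners — subjects whose mean target mismatch over all
  visual-feedback trials (VF+PF and VF) with 1-based indices 121-240
  exceeds 0.8;
* pooled learning curves — mean and SEM of the mismatch per condition per
  24-trial block, trials pooled over subjects;
* exponential learning-curve fits — ``m(k) = a + b exp(-k/tau)`` (or a sum
  of two exponentials for the condition present from the first trial),
  fitted by multi-start nonlinear least squares, with an F-test against
  the constant model as fit significance;
* block-paired t-tests — trials paired by (subject, target, block), with a
  Shapiro-Wilk normality check on the differences (a warning, not a gate)
  and Bonferroni control of the family-wise error rate over blocks;
* the resampled VF+PF comparison — VF+PF appears three times per
  (subject, target, block) where the other conditions appear once, so one
  of the three matches is drawn at random per pairing key and the paired
  t-test repeated over many independent draws, yielding a p-value
  distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "NonLearnerExclusion",
    "FitResult",
    "BlockTestResult",
    "ResampledTestResult",
    "PairingError",
    "exclude_non_learners",
    "learning_curves",
    "fit_exponential",
    "bonferroni_threshold",
    "paired_block_tests",
    "resampled_vfpf_tests",
]

EXCLUSION_TRIAL_RANGE = (121, 240)
EXCLUSION_THRESHOLD = 0.8
VISUAL_CONDITIONS = ("VF+PF", "VF")
FAMILY_WISE_ALPHA = 0.05


class PairingError(ValueError):
    """Raised when trials cannot be paired as the design requires."""


# ----------------------------------------------------------------------
# exclusion rule
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class NonLearnerExclusion:
    """Outcome of the non-learner screen for one cohort."""

    flags: pd.Series  # subject -> bool (True = excluded)
    criterion: pd.Series  # subject -> mean visual-feedback mismatch

    @property
    def excluded_subjects(self) -> list:
        return sorted(self.flags.index[self.flags].tolist())


def exclude_non_learners(
    dataset: pd.DataFrame,
    threshold: float = EXCLUSION_THRESHOLD,
    trial_range: tuple[int, int] = EXCLUSION_TRIAL_RANGE,
) -> tuple[pd.DataFrame, NonLearnerExclusion]:
    """Drop subjects without viable visual-feedback control.

    A subject is excluded when the mean target mismatch of all VF+PF and VF
    trials with trial indices in ``trial_range`` (inclusive, 1-based) is
    *strictly* greater than ``threshold``.  Returns the retained dataset
    and the per-subject flags.  Every subject must contribute trials in
    the range; the rule is idempotent.
    """
    lo, hi = trial_range
    sel = dataset[
        dataset["trial_index"].between(lo, hi)
        & dataset["condition"].isin(VISUAL_CONDITIONS)
    ]
    crit = sel.groupby("subject")["mismatch"].mean()
    missing = set(dataset["subject"].unique()) - set(crit.index)
    if missing:
        raise ValueError(
            f"subjects {sorted(missing)} have no visual-feedback trials in "
            f"the range {trial_range}"
        )
    flags = crit > threshold
    retained = dataset[~dataset["subject"].map(flags)].copy()
    return retained, NonLearnerExclusion(flags=flags, criterion=crit)


# ----------------------------------------------------------------------
# learning curves
# ----------------------------------------------------------------------

def learning_curves(
    dataset: pd.DataFrame,
    metric: str = "mismatch",
) -> pd.DataFrame:
    """Pooled per-block learning curves.

    Trials of all (retained) subjects are pooled; within each 24-trial
    block, trials of different conditions are kept separate.  Returns a
    DataFrame with columns ``condition, block, mean, sem, n``.
    """
    grouped = dataset.groupby(["condition", "block"])[metric]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    out = out.rename(columns={"count": "n"})
    out["sem"] = out["sem"].fillna(0.0)
    return out.sort_values(["condition", "block"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# exponential fits
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """A learning-curve fit.

    ``params`` maps parameter names to values: ``a, b, tau`` for the
    single-exponential form ``a + b exp(-k/tau)`` and ``a, b1, tau1, b2,
    tau2`` for the double form.  ``p_value`` is the F-test of the fit
    against the constant model; ``r2`` may be low for flat curves.
    """

    form: str
    params: dict
    r2: float
    p_value: float
    success: bool
    message: str = ""
    x_offset: float = 0.0  # block index of the first fitted point

    def predict(self, block_index) -> np.ndarray:
        x = np.asarray(block_index, dtype=float) - self.x_offset
        p = self.params
        if self.form == "single":
            return p["a"] + p["b"] * np.exp(-x / p["tau"])
        return (
            p["a"]
            + p["b1"] * np.exp(-x / p["tau1"])
            + p["b2"] * np.exp(-x / p["tau2"])
        )


def _f_test(y: np.ndarray, resid: np.ndarray, n_params: int) -> float:
    """F-test of a fitted model against the constant (mean) model."""
    n = y.size
    sse0 = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    df1, df2 = n_params - 1, n - n_params
    if df2 <= 0 or sse0 <= sse or sse <= 0:
        return 1.0 if sse0 <= sse else 0.0
    f = ((sse0 - sse) / df1) / (sse / df2)
    return float(sps.f.sf(f, df1, df2))


def fit_exponential(
    curve: pd.DataFrame,
    form: str = "single",
    metric_column: str = "mean",
) -> FitResult:
    """Fit an exponential learning curve to per-block means.

    ``curve`` needs columns ``block`` and ``metric_column`` (one condition
    at a time).  Requires at least 5 blocks for the single form and 7 for
    the double.  Initialization is multi-start over a grid of time
    constants; the amplitude parameters are seeded by linear projection.
    """
    if form not in ("single", "double"):
        raise ValueError("form must be 'single' or 'double'")
    x = curve["block"].to_numpy(dtype=float)
    y = curve[metric_column].to_numpy(dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    x0 = x - x[0]  # fit relative to the first observed block
    min_blocks = 5 if form == "single" else 7
    if x.size < min_blocks:
        raise ValueError(f"{form} exponential fit needs >= {min_blocks} blocks")

    span = max(x0[-1], 1.0)
    tau_grid = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0]) * span / 4.0

    def _single(t, a, b, tau):
        return a + b * np.exp(-t / np.maximum(tau, 1e-9))

    def _double(t, a, b1, tau1, b2, tau2):
        return (
            a
            + b1 * np.exp(-t / np.maximum(tau1, 1e-9))
            + b2 * np.exp(-t / np.maximum(tau2, 1e-9))
        )

    best = None
    amp = y[0] - y[-1]
    for tau0 in tau_grid:
        if form == "single":
            p0 = [y[-1], amp, tau0]
            model, names = _single, ("a", "b", "tau")
            bounds = ([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf])
        else:
            p0 = [y[-1], amp / 2.0, tau0 / 4.0, amp / 2.0, tau0 * 2.0]
            model, names = _double, ("a", "b1", "tau1", "b2", "tau2")
            bounds = (
                [-np.inf, -np.inf, 1e-6, -np.inf, 1e-6],
                [np.inf, np.inf, np.inf, np.inf, np.inf],
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    model, x0, y, p0=p0, bounds=bounds, maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        resid = y - model(x0, *popt)
        sse = float(np.sum(resid**2))
        if best is None or sse < best[0]:
            best = (sse, popt, names, model)

    if best is None:
        return FitResult(form, {}, np.nan, np.nan, False, "no start converged")

    sse, popt, names, model = best
    params = dict(zip(names, (float(v) for v in popt)))
    if form == "double" and params["tau1"] > params["tau2"]:
        params = {
            "a": params["a"],
            "b1": params["b2"],
            "tau1": params["tau2"],
            "b2": params["b1"],
            "tau2": params["tau1"],
        }
    resid = y - model(x0, *popt)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    p = _f_test(y, resid, len(popt))
    return FitResult(
        form, params, float(np.clip(r2, 0.0, 1.0)), p, True, x_offset=float(x[0])
    )


# ----------------------------------------------------------------------
# block-paired t-tests
# ----------------------------------------------------------------------

def bonferroni_threshold(n_comparisons: int, alpha: float = FAMILY_WISE_ALPHA) -> float:
    """Per-test significance level controlling the family-wise rate."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return alpha / n_comparisons


@dataclass(frozen=True)
class BlockTestResult:
    """Paired t-test of two conditions within one 24-trial block."""

    block: int
    comparison: str
    n_pairs: int
    mean_difference: float
    t: float
    p: float
    threshold: float
    significant: bool
    shapiro_p: float = np.nan


def _paired_values(
    dataset: pd.DataFrame,
    condition: str,
    metric: str,
    blocks: np.ndarray,
) -> pd.Series:
    """metric values indexed by (block, subject, target); exactly one trial
    per key is required."""
    sel = dataset[
        (dataset["condition"] == condition) & dataset["block"].isin(blocks)
    ]
    grouped = sel.groupby(["block", "subject", "target_index"])[metric]
    counts = grouped.size()
    bad = counts[counts != 1]
    if len(bad):
        block, subject, target = bad.index[0]
        raise PairingError(
            f"condition {condition!r} has {int(bad.iloc[0])} trials for "
            f"subject {subject}, target {target}, block {block}; exactly one "
            "is required for pairing"
        )
    return grouped.first()


def _paired_t(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on differences; identical samples give
    t = 0, p = 1 rather than an undefined statistic."""
    if np.allclose(diffs, 0.0):
        return 0.0, 1.0
    res = sps.ttest_1samp(diffs, 0.0)
    return float(res.statistic), float(res.pvalue)


def paired_block_tests(
    dataset: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    metric: str = "mismatch",
    alpha: float = FAMILY_WISE_ALPHA,
    blocks=None,
) -> list[BlockTestResult]:
    """Series of paired t-tests, one per 24-trial block.

    Trials are paired by (subject, target) within each block, which
    requires exactly one trial per condition per key (true for PF, VF and
    noFB in the test phase).  Normality of the paired differences is
    checked with a Shapiro-Wilk test; failures are reported as warnings
    but the t-test is still run.  The per-test threshold is
    ``alpha / n_blocks`` (Bonferroni over the family of blocks).
    """
    if blocks is None:
        blocks = np.intersect1d(
            dataset.loc[dataset["condition"] == cond_a, "block"].unique(),
            dataset.loc[dataset["condition"] == cond_b, "block"].unique(),
        )
    blocks = np.sort(np.asarray(blocks))
    if blocks.size == 0:
        raise PairingError(f"no blocks contain both {cond_a!r} and {cond_b!r}")
    a = _paired_values(dataset, cond_a, metric, blocks)
    b = _paired_values(dataset, cond_b, metric, blocks)
    threshold = bonferroni_threshold(int(blocks.size), alpha)

    results = []
    for block in blocks:
        try:
            va, vb = a.loc[block], b.loc[block]
        except KeyError as exc:
            raise PairingError(f"block {block} missing for one condition") from exc
        unmatched = va.index.symmetric_difference(vb.index)
        if len(unmatched):
            subject, target = unmatched[0]
            raise PairingError(
                f"unpaired trial for subject {subject}, target {target}, "
                f"block {block} ({cond_a} vs {cond_b})"
            )
        diffs = (va - vb).dropna()
        if len(diffs) < 2:
            raise PairingError(f"block {block} has fewer than two pairs")
        d = diffs.to_numpy()
        shapiro_p = np.nan
        if 3 <= d.size <= 5000 and not np.allclose(d, d[0]):
            shapiro_p = float(sps.shapiro(d).pvalue)
            if shapiro_p < 0.05:
                warnings.warn(
                    f"paired differences in block {block} ({cond_a} vs "
                    f"{cond_b}) deviate from normality "
                    f"(Shapiro-Wilk p = {shapiro_p:.3g})",
                    stacklevel=2,
                )
        t, p = _paired_t(d)
        results.append(
            BlockTestResult(
                block=int(block),
                comparison=f"{cond_a} vs {cond_b}",
                n_pairs=int(d.size),
                mean_difference=float(d.mean()),
                t=t,
                p=p,
                threshold=threshold,
                significant=bool(p < threshold),
                shapiro_p=shapiro_p,
            )
        )
    return results


# ----------------------------------------------------------------------
# resampled VF+PF comparison
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ResampledTestResult:
    """Distribution of p-values over random VF+PF subsamples."""

    comparison: str
    metric: str
    p_values: np.ndarray = field(repr=False)
    n_pairs: int

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))

    def fraction_below(self, level: float) -> float:
        return float(np.mean(self.p_values < level))


def resampled_vfpf_tests(
    dataset: pd.DataFrame,
    other_condition: str,
    metric: str,
    n_resamples: int = 500,
    seed: int = 0,
    blocks=None,
) -> ResampledTestResult:
    """Paired t-tests of VF+PF against another condition, resampling the
    3-fold VF+PF surplus.

    Each pairing key (subject, target, block) holds exactly three VF+PF
    trials and one trial of the other condition; per resample one of the
    three is selected uniformly at random for every key and a two-sided
    paired t-test is run on the pooled pairs.  The selection is repeated
    ``n_resamples`` times with independent draws from a dedicated RNG
    stream, giving the reported p-value distribution.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    if blocks is None:
        blocks = np.intersect1d(
            dataset.loc[dataset["condition"] == "VF+PF", "block"].unique(),
            dataset.loc[dataset["condition"] == other_condition, "block"].unique(),
        )
    blocks = np.sort(np.asarray(blocks))
    other = _paired_values(dataset, other_condition, metric, blocks)

    sel = dataset[
        (dataset["condition"] == "VF+PF") & dataset["block"].isin(blocks)
    ].sort_values("trial_index")
    grouped = sel.groupby(["block", "subject", "target_index"])[metric]
    counts = grouped.size()
    if (counts != 3).any():
        key = counts[counts != 3].index[0]
        raise PairingError(
            f"VF+PF must have exactly 3 trials per (block, subject, target); "
            f"key {key} has {int(counts.loc[key])}"
        )
    vfpf = grouped.apply(lambda s: s.to_numpy())
    vfpf, other = vfpf.align(other, join="inner")
    triples = np.vstack(vfpf.to_numpy())  # (n_keys, 3)
    singles = other.to_numpy(dtype=float)  # (n_keys,)
    defined = np.isfinite(singles) & np.all(np.isfinite(triples), axis=1)
    triples, singles = triples[defined], singles[defined]
    n_keys = singles.size
    if n_keys < 2:
        raise PairingError("fewer than two complete pairing keys")

    rng = np.random.default_rng(seed)
    choices = rng.integers(0, 3, size=(n_resamples, n_keys))
    sampled = np.take_along_axis(
        np.broadcast_to(triples, (n_resamples, n_keys, 3)), choices[..., None], axis=2
    )[..., 0]
    diffs = sampled - singles[None, :]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n_keys))
    p = 2.0 * sps.t.sf(np.abs(t), df=n_keys - 1)
    p = np.where(sd == 0.0, np.where(mean == 0.0, 1.0, 0.0), p)
    return ResampledTestResult(
        comparison=f"VF+PF vs {other_condition}",
        metric=metric,
        p_values=p,
        n_pairs=int(n_keys),
    )
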