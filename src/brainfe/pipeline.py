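"""Per-participant and cohort orchestration.

``run_participant`` chains preprocessing, CSP feature extraction, the
repeated K-means/SVM recognition estimate, the free-energy summary and
the behavioral resource-parameter fit on one participant's epochs;
``run_task_cohort`` maps it over a synthetic task cohort; and
``cohort_report`` assembles the cohort-level tables: per-task group
means with 95% confidence intervals, permutation repeated-measures
ANOVAs, and randomization correlations (free energy vs zeta, workload
vs zeta and free energy) with Benjamini-Hochberg FDR correction.

Every random draw descends from one master seed via hierarchical
seed-sequence spawning (master -> participant -> stage -> repeat), so
reruns with the same seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from brainfe.csp import fit_csp_pipeline
from brainfe.free_energy import DEFAULT_EPSILON, FreeEnergyResult, free_energy_result
from brainfe.preprocess import EpochSet, preprocess_pipeline
from brainfe.recognition import RecognitionEstimate, repeat_and_average
from brainfe.resource_model import SoftmaxFit, fit_zeta
from brainfe.stats import fdr_bh, perm_rm_anova, randomization_corr
from brainfe.synthetic import CohortConfig, simulate_cohort

__all__ = [
    "ParticipantResult",
    "run_participant",
    "run_task_cohort",
    "cohort_report",
]


@dataclass
class ParticipantResult:
    """All per-participant quantities, from one artifact-screened trial set."""

    task: str
    accuracy: float
    rt_correct_ms: float
    rt_incorrect_ms: float
    recognition: RecognitionEstimate
    free_energy: FreeEnergyResult
    softmax: SoftmaxFit
    workload: float | None
    n_trials_used: int

    def to_row(self) -> dict:
        row = {
            "task": self.task,
            "accuracy": self.accuracy,
            "rt_correct_ms": self.rt_correct_ms,
            "rt_incorrect_ms": self.rt_incorrect_ms,
            "zeta": self.softmax.zeta,
            "workload": self.workload,
            "kmeans_agreement": self.recognition.kmeans_agreement,
            "svm_cv_accuracy": self.recognition.svm_cv_accuracy,
            "n_trials_used": self.n_trials_used,
        }
        row.update(self.free_energy.to_dict())
        return row


def run_participant(
    trials: pd.DataFrame,
    epochs: EpochSet,
    task: str = "II",
    workload: float | None = None,
    n_repeats: int = 200,
    epsilon: float = DEFAULT_EPSILON,
    variance_fraction: float = 0.99,
    peak_to_peak_uv: float = 150.0,
    rng_seed: int = 0,
    min_trials: int = 20,
) -> ParticipantResult:
    """Full single-participant analysis.

    Preprocesses the epochs, restricts to artifact-free responded
    trials, extracts CSP features with the two classes defined by the
    reported decisions, estimates the recognition distribution over
    classifier repeats, and derives the free-energy summary and the
    behavioral softmax fit from the same screened trial set.
    """
    if len(trials) != epochs.n_trials:
        raise ValueError("trial table and epochs must align")
    try:
        clean = preprocess_pipeline(epochs, peak_to_peak_uv=peak_to_peak_uv)
    except Exception as e:  # surface the failing stage
        raise RuntimeError(f"preprocess failed ({epochs.n_trials} trials): {e}") from e
    keep = (~clean.artifact_mask) & trials["decision"].isin([1, 2]).to_numpy()
    if keep.sum() < min_trials:
        raise RuntimeError(
            f"only {int(keep.sum())} artifact-free responded trials (< {min_trials})"
        )
    t_used = trials.loc[keep].reset_index(drop=True)
    data_used = clean.data[keep]

    try:
        features, model, _ = fit_csp_pipeline(
            EpochSet(
                data=data_used,
                sfreq=clean.sfreq,
                times=clean.times,
                channel_names=clean.channel_names,
                reference=clean.reference,
            ),
            t_used["decision"].to_numpy(),
            variance_fraction=variance_fraction,
        )
    except Exception as e:
        raise RuntimeError(f"CSP stage failed ({len(t_used)} trials): {e}") from e

    recog = repeat_and_average(features, t_used, n_repeats=n_repeats, rng_seed=rng_seed)
    fe = free_energy_result(recog.Q, epsilon=epsilon)
    softmax = fit_zeta(t_used)

    correct = t_used["correct"].to_numpy(dtype=bool)
    rt = t_used["rt_ms"].to_numpy(dtype=float)
    return ParticipantResult(
        task=task,
        accuracy=float(correct.mean()),
        rt_correct_ms=float(np.nanmean(rt[correct])) if correct.any() else np.nan,
        rt_incorrect_ms=float(np.nanmean(rt[~correct])) if (~correct).any() else np.nan,
        recognition=recog,
        free_energy=fe,
        softmax=softmax,
        workload=workload,
        n_trials_used=int(keep.sum()),
    )


def run_task_cohort(
    cfg: CohortConfig,
    task: str = "II",
    n_repeats: int = 20,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Analyze one synthetic task cohort; one row per participant."""
    rows = []
    seed_root = np.random.SeedSequence(cfg.master_seed + 10_000)
    analysis_seeds = seed_root.spawn(cfg.n_participants)
    for i, trials, epochs, workload, p_i, zeta_true in simulate_cohort(cfg):
        res = run_participant(
            trials,
            epochs,
            task=task,
            workload=workload,
            n_repeats=n_repeats,
            epsilon=epsilon,
            rng_seed=analysis_seeds[i],
        )
        row = {"participant": i, "p_true": p_i, "zeta_true": zeta_true}
        row.update(res.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


def _mean_ci(x: np.ndarray, level: float = 0.95):
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = float(np.mean(x))
    if n < 2:
        return m, m, m
    sem = x.std(ddof=1) / np.sqrt(n)
    h = sem * sp_stats.t.ppf(0.5 + level / 2, n - 1)
    return m, m - h, m + h


_SUMMARY_FIELDS = [
    "accuracy",
    "rt_correct_ms",
    "rt_incorrect_ms",
    "zeta",
    "workload",
    "dF_o1_mu1",
    "dF_o1_mu2",
    "dF_o2_mu1",
    "dF_o2_mu2",
    "dF_total",
    "matched_mean",
    "mismatched_mean",
]


def cohort_report(
    df_ii: pd.DataFrame,
    df_rb: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict:
    """Cohort-level tables and statistics from the two task cohorts.

    Returns a dict with group means/CIs per task, between-task
    permutation ANOVAs (accuracy, zeta, total free-energy difference,
    the matched/mismatched two-way design, RT task-by-correctness),
    and randomization correlations with FDR-corrected p-values.
    """
    if len(df_ii) != len(df_rb):
        raise ValueError("task cohorts must contain the same participants")
    if len(df_ii) < 6:
        raise ValueError("need >= 6 participants")
    summary = {}
    for task, df in (("II", df_ii), ("RB", df_rb)):
        summary[task] = {
            f: dict(zip(("mean", "ci_lo", "ci_hi"), _mean_ci(df[f].to_numpy())))
            for f in _SUMMARY_FIELDS
            if f in df
        }

    rng = np.random.default_rng(seed)

    def next_seed():
        return int(rng.integers(2**31 - 1))

    anovas = {}
    for name, field in (
        ("accuracy_task", "accuracy"),
        ("zeta_task", "zeta"),
        ("dF_total_task", "dF_total"),
        ("workload_task", "workload"),
    ):
        vals = np.column_stack([df_ii[field], df_rb[field]])
        anovas[name] = perm_rm_anova(vals, n_perm=n_perm, seed=next_seed()).to_dict()

    # two-way: Task x Free Energy Difference State (matched, mismatched)
    state = np.stack(
        [
            np.column_stack([df_ii["matched_mean"], df_ii["mismatched_mean"]]),
            np.column_stack([df_rb["matched_mean"], df_rb["mismatched_mean"]]),
        ],
        axis=1,
    )  # (n, task, state)
    for eff, label in (("A", "task"), ("B", "state"), ("AB", "interaction")):
        anovas[f"fe_state_{label}"] = perm_rm_anova(
            state, n_perm=n_perm, seed=next_seed(), effect=eff
        ).to_dict()

    # two-way: Task x Correctness on RTs
    rt = np.stack(
        [
            np.column_stack([df_ii["rt_correct_ms"], df_ii["rt_incorrect_ms"]]),
            np.column_stack([df_rb["rt_correct_ms"], df_rb["rt_incorrect_ms"]]),
        ],
        axis=1,
    )
    for eff, label in (("A", "task"), ("B", "correctness"), ("AB", "interaction")):
        anovas[f"rt_{label}"] = perm_rm_anova(rt, n_perm=n_perm, seed=next_seed(), effect=eff).to_dict()

    correlations = {}
    for task, df in (("II", df_ii), ("RB", df_rb)):
        for name, (a, b) in {
            "dF_total_vs_zeta": ("dF_total", "zeta"),
            "workload_vs_zeta": ("workload", "zeta"),
            "workload_vs_dF_total": ("workload", "dF_total"),
        }.items():
            res = randomization_corr(
                df[a].to_numpy(), df[b].to_numpy(), n_rand=n_perm, seed=next_seed()
            )
            correlations[f"{task}_{name}"] = res.to_dict()
    keys = sorted(correlations)
    reject = fdr_bh([correlations[k]["p_value"] for k in keys])
    for k, rej in zip(keys, reject):
        correlations[k]["significant_fdr_05"] = bool(rej)

    return {"summary": summary, "anovas": anovas, "correlations": correlations}
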