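"""Permutation statistics for ERP/GFP waveforms and cohort effects.

Implements the battery used to relate free-energy states to scalp
responses and cohort behavior: event-related potential (ERP) and
global field power (GFP) waveforms, pointwise paired permutation
t-tests with max-statistic familywise correction, permutation-based
repeated-measures ANOVA (one-way and fully-within two-way) with
partial eta-squared, randomization tests of Pearson correlations, and
Benjamini-Hochberg FDR control.

Exchangeability choices: paired waveform contrasts are resampled by
within-participant sign flips of the difference waveforms; ANOVA
permutations shuffle condition labels within participant.  All
p-values use +1 smoothing, so p >= 1 / (n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "erp_gfp",
    "pointwise_maxstat_ttest",
    "perm_rm_anova",
    "randomization_corr",
    "fdr_bh",
]


@dataclass(frozen=True)
class PermutationResult:
    statistic_name: str
    observed: float
    p_value: float
    n_permutations: int
    seed: int
    effect_size: Optional[float] = None  # partial eta squared, ANOVA only

    def to_dict(self) -> dict:
        d = {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }
        if self.effect_size is not None:
            d["eta_p2"] = self.effect_size
        return d


def erp_gfp(data: np.ndarray, group_index) -> dict:
    """Per-group ERP and GFP waveforms.

    ``data`` is (trials, channels, samples); ``group_index`` labels each
    trial.  ERP is the trial mean per channel/time; GFP the population
    standard deviation of the ERP across channels per time point.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 3 or x.shape[1] < 2:
        raise ValueError("data must be (trials, channels>=2, samples)")
    if x.shape[0] == 0:
        raise ValueError("no trials: every group is empty")
    g = np.asarray(group_index)
    out = {}
    for label in np.unique(g):
        sel = x[g == label]
        if len(sel) == 0:
            raise ValueError(f"empty group {label}")
        erp = sel.mean(axis=0)
        gfp = erp.std(axis=0, ddof=0)
        out[label] = {"erp": erp, "gfp": gfp}
    return out


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """t statistic per column of (participants, times) differences."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    return mean / np.where(sd > 0, sd / np.sqrt(n), np.inf)


def pointwise_maxstat_ttest(
    wave_a: np.ndarray,
    wave_b: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    chunk: int = 500,
):
    """Paired pointwise t-tests with max-|t| familywise correction.

    ``wave_a``/``wave_b`` are (participants, times).  The null is
    simulated by random sign flips of the within-participant difference
    waveforms; the per-timepoint threshold is the (1 - alpha) quantile
    of the null distribution of the maximum |t| across time.  Returns
    ``(mask, t_obs, threshold)``.
    """
    a = np.atleast_2d(np.asarray(wave_a, dtype=float))
    b = np.atleast_2d(np.asarray(wave_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("waveform arrays must have identical shape")
    n = a.shape[0]
    if n < 6:
        import warnings

        warnings.warn(f"only {n} participants: the permutation test has low power", stacklevel=2)
    diffs = a - b
    t_obs = _paired_t(diffs)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n, 1))
        flipped = signs * diffs[None, :, :]
        mean = flipped.mean(axis=1)
        sd = flipped.std(axis=1, ddof=1)
        t = mean / np.where(sd > 0, sd / np.sqrt(n), np.inf)
        max_null[done : done + m] = np.abs(t).max(axis=1)
        done += m
    threshold = float(np.quantile(max_null, 1.0 - alpha))
    return np.abs(t_obs) > threshold, t_obs, threshold


def _rm_anova_1way(x: np.ndarray):
    """Observed F and partial eta^2 for (participants, conditions)."""
    n, c = x.shape
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    resid = x - subj_means[:, None] - cond_means[None, :] + grand
    ss_err = (resid**2).sum()
    df1, df2 = c - 1, (n - 1) * (c - 1)
    tol = 1e-12 * max(((x - grand) ** 2).sum(), 1e-300)
    if ss_cond <= tol:  # no condition variance at all: null by definition
        return 0.0, 0.0, (df1, df2)
    F = (ss_cond / df1) / (ss_err / df2) if ss_err > tol else np.inf
    eta = ss_cond / (ss_cond + ss_err)
    return float(F), float(eta), (df1, df2)


def _rm_anova_1way_F_batch(xp: np.ndarray) -> np.ndarray:
    """F for a batch of permuted datasets, shape (B, n, c)."""
    B, n, c = xp.shape
    grand = xp.mean(axis=(1, 2), keepdims=True)
    cond = xp.mean(axis=1, keepdims=True)
    subj = xp.mean(axis=2, keepdims=True)
    ss_cond = (n * ((cond - grand) ** 2).sum(axis=2)).ravel()
    resid = xp - subj - cond + grand
    ss_err = (resid**2).sum(axis=(1, 2))
    df1, df2 = c - 1, (n - 1) * (c - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df1) / (ss_err / df2)
    return np.where(ss_err > 0, F, np.inf)


def _twoway_cells(x: np.ndarray):
    """Sums of squares for a fully within (n, a, b) design."""
    n, a, b = x.shape
    g = x.mean()
    mA = x.mean(axis=(0, 2))
    mB = x.mean(axis=(0, 1))
    mAB = x.mean(axis=0)
    mS = x.mean(axis=(1, 2))
    mAS = x.mean(axis=2)
    mBS = x.mean(axis=1)
    ss = {}
    ss["A"] = n * b * ((mA - g) ** 2).sum()
    ss["B"] = n * a * ((mB - g) ** 2).sum()
    ss["AB"] = n * ((mAB - mA[:, None] - mB[None, :] + g) ** 2).sum()
    ss["AS"] = b * ((mAS - mS[:, None] - mA[None, :] + g) ** 2).sum()
    ss["BS"] = a * ((mBS - mS[:, None] - mB[None, :] + g) ** 2).sum()
    resid = (
        x
        - mAS[:, :, None]
        - mBS[:, None, :]
        - mAB[None, :, :]
        + mS[:, None, None]
        + mA[None, :, None]
        + mB[None, None, :]
        - g
    )
    ss["ABS"] = (resid**2).sum()
    df = {
        "A": (a - 1, (n - 1) * (a - 1)),
        "B": (b - 1, (n - 1) * (b - 1)),
        "AB": ((a - 1) * (b - 1), (n - 1) * (a - 1) * (b - 1)),
    }
    return ss, df


def _twoway_F(x: np.ndarray, effect: str):
    ss, df = _twoway_cells(x)
    err = {"A": "AS", "B": "BS", "AB": "ABS"}[effect]
    df1, df2 = df[effect]
    ms_e = ss[effect] / df1
    ms_err = ss[err] / df2
    F = ms_e / ms_err if ms_err > 0 else np.inf
    eta = ss[effect] / (ss[effect] + ss[err]) if (ss[effect] + ss[err]) > 0 else 0.0
    return float(F), float(eta)


def perm_rm_anova(
    values: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    effect: str = "A",
) -> PermutationResult:
    """Permutation repeated-measures ANOVA.

    ``values`` is (participants, conditions) for a one-way design or
    (participants, levels_A, levels_B) for a fully within two-way
    design, in which case ``effect`` selects 'A', 'B' or 'AB'.  The
    null is simulated by permuting condition labels independently
    within each participant; the observed F and partial eta^2 come
    from the standard (non-permuted) decomposition.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    rng = np.random.default_rng(seed)
    if x.ndim == 2:
        n, c = x.shape
        F_obs, eta, _ = _rm_anova_1way(x)
        # within-participant label permutations, vectorized in batches
        count = 0
        done = 0
        while done < n_perm:
            m = min(1000, n_perm - done)
            idx = np.argsort(rng.random((m, n, c)), axis=2)
            xp = np.take_along_axis(np.broadcast_to(x, (m, n, c)), idx, axis=2)
            count += int((_rm_anova_1way_F_batch(xp) >= F_obs - 1e-12).sum())
            done += m
    elif x.ndim == 3:
        n, a, b = x.shape
        F_obs, eta = _twoway_F(x, effect)
        flat = x.reshape(n, a * b)
        count = 0
        for _ in range(n_perm):
            idx = np.argsort(rng.random((n, a * b)), axis=1)
            xp = np.take_along_axis(flat, idx, axis=1).reshape(n, a, b)
            Fp, _ = _twoway_F(xp, effect)
            if Fp >= F_obs - 1e-12:
                count += 1
    else:
        raise ValueError("values must be 2-D or 3-D")
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(
        statistic_name="F",
        observed=F_obs,
        p_value=float(min(p, 1.0)),
        effect_size=eta,
        n_permutations=n_perm,
        seed=seed,
    )


def randomization_corr(x, y, n_rand: int = 5000, seed: int = 0) -> PermutationResult:
    """Pearson correlation with a two-sided randomization p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("x and y must have equal length >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = len(x)
    r_obs = float((xc * yc).mean())
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(yc) for _ in range(n_rand)])
    r_null = perms @ xc / n
    count = int((np.abs(r_null) >= abs(r_obs) - 1e-12).sum())
    p = (count + 1) / (n_rand + 1)
    return PermutationResult(
        statistic_name="r",
        observed=r_obs,
        p_value=float(min(p, 1.0)),
        n_permutations=n_rand,
        seed=seed,
    )


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
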