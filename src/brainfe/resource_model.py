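"""Bounded-rationality resource parameter from categorization behavior.

The decision model is a softmax over the two category decisions with
inverse-temperature (resource) parameter zeta,

    P(d1) = 1 / (1 + exp(-zeta * (U(d1|m) - U(d2|m)))),

where the utility of a decision is the log of its marginal probability,
U(di|m) = ln P(di|m), with P(di|m) = sum_j P(di|nu_j, m) P(nu_j|m) and
equal category priors P(nu_j|m) = 0.5.  Per trial, the utility is
non-zero only for the decision actually made, so the regressor is
x_t = U(d1|m)*1[d_t=1] - U(d2|m)*1[d_t=2].

zeta is estimated by intercept-free logistic regression of the
true-category indicator y_t = 1[nu_t = 1] on x_t.  Regressing the
decision itself on x_t would be perfectly separable (the regressor's
sign is a deterministic function of the decision), so the true
category is the response variable; under balanced decisions the
maximum-likelihood estimate then has the closed form
zeta_hat = -logit(p_correct) / ln 2, which serves as an independent
oracle for the iterative fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SoftmaxFit",
    "decision_probabilities",
    "decision_utilities",
    "softmax_probability",
    "fit_zeta",
    "zeta_closed_form",
]


@dataclass
class SoftmaxFit:
    """Fitted softmax decision model.

    Attributes
    ----------
    zeta : float
        Resource (inverse temperature) parameter; negative for
        above-chance performance under this construction.
    U_d : ndarray, shape (2,)
        Decision utilities ln P(d_i | m), nats.
    P_d : ndarray, shape (2,)
        Marginal decision probabilities.
    confusion : ndarray, shape (2, 2)
        P(d_i | nu_j, m); columns (true categories) sum to 1.
    standard_error : float
        Asymptotic standard error of zeta from the logistic fit.
    n_trials : int
        Responded trials used.
    """

    zeta: float
    U_d: np.ndarray
    P_d: np.ndarray
    confusion: np.ndarray
    standard_error: float
    n_trials: int
    method: str = "intercept-free logistic regression of 1[nu=1] on the per-trial utility regressor"


def _responded(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials
    if "responded" in t.columns:
        t = t[t["responded"].astype(bool)]
    return t[t["decision"].isin([1, 2])]


def decision_probabilities(trials: pd.DataFrame):
    """Empirical decision-given-category confusion and marginal P(d).

    ``confusion[i, j] = P(d = i+1 | nu = j+1)``; the marginal follows
    by mixing the columns with equal category priors P(nu_j) = 0.5.
    Non-response trials are excluded.
    """
    t = _responded(trials)
    confusion = np.zeros((2, 2))
    for j, nu in enumerate((1, 2)):
        sub = t[t["true_category"] == nu]
        if len(sub) == 0:
            raise ValueError(f"no responded trials with true category {nu}")
        for i, d in enumerate((1, 2)):
            confusion[i, j] = (sub["decision"] == d).mean()
    P_d = confusion @ np.array([0.5, 0.5])
    return confusion, P_d


def decision_utilities(P_d) -> np.ndarray:
    """Decision utilities U(d_i|m) = ln P(d_i|m), nats."""
    P_d = np.asarray(P_d, dtype=float)
    if np.any(P_d <= 0) or np.any(P_d >= 1):
        raise ValueError(
            "degenerate marginal decision probabilities "
            f"{P_d.tolist()}: a decision is never (or always) made; more trials needed"
        )
    return np.log(P_d)


def softmax_probability(U1: float, U2: float, zeta: float, prior: float = 0.5) -> float:
    """P(d1) under the equal-prior softmax: logistic of zeta (U1 - U2)."""
    if prior != 0.5:
        raise ValueError("the equal-prior softmax form requires prior = 0.5")
    return float(1.0 / (1.0 + np.exp(-zeta * (U1 - U2))))


def zeta_closed_form(p_correct: float) -> float:
    """Closed-form zeta under balanced decisions: -logit(p)/ln 2."""
    if not 0 < p_correct < 1:
        raise ValueError("p_correct must be in (0, 1)")
    return float(-np.log(p_correct / (1 - p_correct)) / np.log(2.0))


def utility_regressor(decisions: np.ndarray, U_d: np.ndarray) -> np.ndarray:
    """Per-trial regressor x_t = U(d1)*1[d=1] - U(d2)*1[d=2]."""
    d = np.asarray(decisions, dtype=int)
    return np.where(d == 1, U_d[0], -U_d[1])


def fit_zeta(trials: pd.DataFrame) -> SoftmaxFit:
    """Estimate zeta from a trial table via logistic regression.

    Requires at least 20 responded trials with both decisions present.
    Perfect accuracy makes the likelihood unbounded (the estimate
    diverges); an informative error is raised in that case.
    """
    t = _responded(trials)
    if len(t) < 20:
        raise ValueError(f"need >= 20 responded trials, got {len(t)}")
    if t["decision"].nunique() < 2:
        raise ValueError("both decisions must occur to estimate zeta")
    acc = float((t["decision"] == t["true_category"]).mean())
    if acc in (0.0, 1.0):
        raise ValueError(
            "accuracy is exactly %s: the logistic fit diverges; "
            "zeta is only identifiable for accuracy strictly inside (0, 1)" % acc
        )
    confusion, P_d = decision_probabilities(t)
    U_d = decision_utilities(P_d)
    x = utility_regressor(t["decision"].to_numpy(), U_d)
    y = (t["true_category"].to_numpy() == 1).astype(float)
    res = sm.Logit(y, x[:, None]).fit(disp=0, method="newton", maxiter=100)
    return SoftmaxFit(
        zeta=float(res.params[0]),
        U_d=U_d,
        P_d=P_d,
        confusion=confusion,
        standard_error=float(res.bse[0]),
        n_trials=len(t),
    )


def balanced_trials(n: int, accuracy: float) -> pd.DataFrame:
    """Construct a balanced trial table with exact accuracy.

    ``n`` trials, half per true category, equal decision frequencies,
    and ``round(n * accuracy)`` correct trials split evenly between
    categories.  Used to reconstruct group-level zeta from a printed
    group-mean accuracy.
    """
    if n % 2:
        raise ValueError("n must be even")
    per_cat = n // 2
    n_corr = int(round(per_cat * accuracy))
    rows = []
    for nu in (1, 2):
        rows += [(nu, nu)] * n_corr + [(nu, 3 - nu)] * (per_cat - n_corr)
    df = pd.DataFrame(rows, columns=["true_category", "decision"])
    df.insert(0, "trial", np.arange(len(df)))
    df["responded"] = True
    return df
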