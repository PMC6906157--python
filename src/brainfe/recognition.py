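"""Recognition-distribution estimation Q(nu | mu, m).

The brain's perception state mu on each trial is indexed by K-means
clustering (k = 2) of the CSP feature vectors; the two clusters are
mapped onto perception labels by choosing the bijection that best
agrees with the reported decisions.  Independently, an RBF-kernel SVM
with sigmoid-calibrated posteriors is trained on the true category
labels nu under stratified 10-fold cross-validation, so that every
trial receives exactly one held-out posterior.  Averaging the held-out
posteriors within each perception group gives one estimate of the 2x2
conditional distribution Q(nu | mu); both classifications are repeated
(200 times by default) with fresh K-means initializations and fresh
fold partitions, and the repeat estimates are averaged.

SVM hyperparameters follow the (sigma, box) convention: sigma is the
RBF kernel scale (gamma = 1 / (2 sigma^2)) and box the soft-margin
penalty bound (C).  They are tuned once per participant by random
log-uniform search minimizing stratified 10-fold CV misclassification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "RecognitionEstimate",
    "cluster_perceptions",
    "map_clusters_to_perceptions",
    "tune_svm",
    "svm_cv_posteriors",
    "estimate_recognition",
    "repeat_and_average",
]


@dataclass
class RecognitionEstimate:
    """Averaged recognition distribution and classifier diagnostics.

    ``Q[mu-1, nu-1]`` estimates Q(nu | mu, m); rows sum to 1.
    """

    Q: np.ndarray
    per_trial_mu: np.ndarray
    per_trial_predicted_nu: np.ndarray
    kmeans_agreement: float
    svm_cv_accuracy: float
    hyperparams: dict
    n_repeats: int
    n_discarded: int = 0

    def to_dict(self) -> dict:
        return {
            "Q": self.Q.tolist(),
            "kmeans_agreement": self.kmeans_agreement,
            "svm_cv_accuracy": self.svm_cv_accuracy,
            "hyperparams": self.hyperparams,
            "n_repeats": self.n_repeats,
            "n_discarded": self.n_discarded,
        }


def _feature_array(features) -> np.ndarray:
    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D (trials x components)")
    return x


def cluster_perceptions(features, rng_seed: int = 0) -> np.ndarray:
    """Two-cluster Euclidean K-means with random centroid initialization."""
    x = _feature_array(features)
    if len(x) < 2:
        raise ValueError("need >= 2 trials to cluster")
    if np.allclose(x, x[0]):
        raise ValueError("all feature vectors identical: clustering is degenerate")
    ss = rng_seed if isinstance(rng_seed, np.random.SeedSequence) else np.random.SeedSequence(rng_seed)
    seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    km = KMeans(n_clusters=2, init="random", n_init=1, random_state=seed)
    return km.fit_predict(x)


def map_clusters_to_perceptions(clusters, decisions):
    """Relabel clusters as perception states via behavioral agreement.

    Of the two cluster -> {perception 1, perception 2} bijections,
    choose the one maximizing agreement with the reported decisions
    (ties map cluster 0 to perception 1).  Returns ``(per_trial_mu,
    agreement)``.
    """
    c = np.asarray(clusters, dtype=int)
    d = np.asarray(decisions, dtype=int)
    if len(c) != len(d):
        raise ValueError("clusters and decisions must align")
    mu_a = np.where(c == 0, 1, 2)
    mu_b = np.where(c == 0, 2, 1)
    agree_a = float((mu_a == d).mean())
    agree_b = float((mu_b == d).mean())
    if agree_a >= agree_b:
        return mu_a, agree_a
    return mu_b, agree_b


def _sigma_box_to_svc(sigma: float, box: float) -> SVC:
    gamma = 1.0 / (2.0 * sigma**2)
    return SVC(kernel="rbf", gamma=gamma, C=box)


def _cv_accuracy(x, y, sigma, box, folds, rng) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    correct = 0
    for tr, te in skf.split(x, y):
        clf = _sigma_box_to_svc(sigma, box)
        clf.fit(x[tr], y[tr])
        correct += int((clf.predict(x[te]) == y[te]).sum())
    return correct / len(y)


def tune_svm(features, true_labels, rng_seed: int = 0, budget: int = 30, folds: int = 10):
    """Random log-uniform search for (sigma, box) on [1e-3, 1e5]^2.

    Minimizes stratified CV misclassification; deterministic under the
    seed.  Returns the best ``(sigma, box)`` pair.
    """
    x = _feature_array(features)
    y = np.asarray(true_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to tune")
    if budget < 5:
        warnings.warn("tuning budget < 5: the search will be very coarse", stacklevel=2)
    rng = np.random.default_rng(rng_seed)
    lo, hi = np.log10(1e-3), np.log10(1e5)
    best = (None, -np.inf)
    for _ in range(max(budget, 1)):
        sigma = 10.0 ** rng.uniform(lo, hi)
        box = 10.0 ** rng.uniform(lo, hi)
        acc = _cv_accuracy(x, y, sigma, box, folds, rng)
        if acc > best[1]:
            best = ((sigma, box), acc)
    return best[0]


def _platt_posteriors(scores_train, y_train, scores_test) -> np.ndarray:
    """Sigmoid calibration of decision values; returns P(positive|score)."""
    lr = LogisticRegression(C=1e3)
    lr.fit(scores_train[:, None], y_train)
    return lr.predict_proba(scores_test[:, None])[:, 1]


def svm_cv_posteriors(
    features,
    true_labels,
    sigma: float,
    box: float,
    folds: int = 10,
    rng_seed: int = 0,
    max_refolds: int = 5,
):
    """Held-out calibrated posteriors for every trial.

    An RBF SVM is trained per stratified fold on the remaining folds;
    posterior probabilities on the held-out trials come from a sigmoid
    (Platt-style) link fitted to the training-fold decision values.
    Returns ``(posteriors, predicted)`` where posteriors has columns
    [P(nu=1), P(nu=2)] summing to 1 per trial.
    """
    x = _feature_array(features)
    y = np.asarray(true_labels, dtype=int)
    counts = np.bincount(y, minlength=3)[1:3]
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} trials per class, got {counts.tolist()}")
    rng = np.random.default_rng(rng_seed)
    for attempt in range(max_refolds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        posteriors = np.full((len(y), 2), np.nan)
        ok = True
        for tr, te in skf.split(x, y):
            if len(np.unique(y[tr])) < 2:
                ok = False
                break
            clf = _sigma_box_to_svc(sigma, box)
            clf.fit(x[tr], y[tr])
            s_tr = clf.decision_function(x[tr])
            s_te = clf.decision_function(x[te])
            # positive class is the larger label (nu = 2) in sklearn
            p2 = _platt_posteriors(s_tr, (y[tr] == 2).astype(int), s_te)
            posteriors[te, 0] = 1.0 - p2
            posteriors[te, 1] = p2
        if ok:
            predicted = np.argmax(posteriors, axis=1) + 1
            return posteriors, predicted
    raise RuntimeError("could not build folds containing both classes")


def estimate_recognition(posteriors, per_trial_mu) -> np.ndarray:
    """Single-repeat Q: mean held-out posterior within each mu group."""
    post = np.asarray(posteriors, dtype=float)
    mu = np.asarray(per_trial_mu, dtype=int)
    Q = np.empty((2, 2))
    for m in (1, 2):
        grp = post[mu == m]
        if len(grp) == 0:
            raise ValueError(f"no trials with perception index {m}")
        Q[m - 1] = grp.mean(axis=0)
    return Q


def repeat_and_average(
    features,
    trial_table: pd.DataFrame,
    n_repeats: int = 200,
    rng_seed: int = 0,
    sigma: float | None = None,
    box: float | None = None,
    tune_budget: int = 30,
    folds: int = 10,
) -> RecognitionEstimate:
    """Full recognition estimate averaged over classifier repeats.

    Each repeat uses a fresh K-means initialization and a fresh CV
    partition; repeat seeds are spawned from ``rng_seed``.  Repeats
    whose perception grouping is degenerate are discarded; more than
    10% discarded aborts.  Hyperparameters are tuned once (on all
    trials) unless supplied.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    x = _feature_array(features)
    nu = trial_table["true_category"].to_numpy(dtype=int)
    d = trial_table["decision"].to_numpy(dtype=int)
    if not np.isin(d, (1, 2)).all():
        raise ValueError("trial_table must contain responded trials only")
    root = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    tune_ss, *repeat_ss = root.spawn(n_repeats + 1)
    if sigma is None or box is None:
        sigma, box = tune_svm(x, nu, rng_seed=tune_ss, budget=tune_budget, folds=folds)

    Qs, agreements, accs = [], [], []
    mu_votes = np.zeros((len(nu), 2))
    nu_votes = np.zeros((len(nu), 2))
    discarded = 0
    for ss in repeat_ss:
        s_km, s_cv = ss.spawn(2)
        clusters = cluster_perceptions(x, rng_seed=s_km)
        mu, agree = map_clusters_to_perceptions(clusters, d)
        try:
            post, pred = svm_cv_posteriors(x, nu, sigma, box, folds=folds, rng_seed=s_cv)
            Q = estimate_recognition(post, mu)
        except (ValueError, RuntimeError):
            discarded += 1
            continue
        Qs.append(Q)
        agreements.append(agree)
        accs.append(float((pred == nu).mean()))
        mu_votes[np.arange(len(mu)), mu - 1] += 1
        nu_votes[np.arange(len(pred)), pred - 1] += 1
    if discarded > 0.1 * n_repeats:
        raise RuntimeError(f"{discarded}/{n_repeats} repeats discarded: estimate unreliable")
    return RecognitionEstimate(
        Q=np.mean(Qs, axis=0),
        per_trial_mu=np.argmax(mu_votes, axis=1) + 1,
        per_trial_predicted_nu=np.argmax(nu_votes, axis=1) + 1,
        kmeans_agreement=float(np.mean(agreements)),
        svm_cv_accuracy=float(np.mean(accs)),
        hyperparams={"sigma": float(sigma), "box": float(box)},
        n_repeats=n_repeats,
        n_discarded=discarded,
    )
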