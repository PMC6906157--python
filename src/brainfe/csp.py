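"""Common spatial patterns feature extraction.

CSP finds spatial filters w maximizing the variance ratio between two
classes of multichannel trials via the generalized eigenproblem

    Sigma_1 w = lambda (Sigma_1 + Sigma_2) w,

where the per-class covariances are trial-averaged, trace-normalized
sample covariances over the post-stimulus window.  Eigenvalues lie in
(0, 1); a filter with lambda near 1 (or 0) captures variance specific
to class 1 (or class 2).

Before CSP the channel data are decorrelated by PCA whitening of the
pooled covariance (retaining components explaining a configurable
variance fraction), which conditions the covariance estimates; the
retained rank defines N_rank.  Per-trial feature vectors are the
log-variance shares of all N_rank filter outputs,

    f_i = log( var(Z_i) / sum_j var(Z_j) ),

so that sum_i exp(f_i) = 1 and features are invariant to overall
trial scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from brainfe.preprocess import EpochSet

__all__ = [
    "Whitener",
    "CSPModel",
    "reduce_whiten",
    "fit_csp",
    "extract_features",
    "fit_csp_pipeline",
    "POST_STIMULUS_MS",
]

#: variance window: post-stimulus interval only
POST_STIMULUS_MS = (0.0, 1000.0)


def _as_array(epochs) -> np.ndarray:
    if isinstance(epochs, EpochSet):
        mask = epochs.sample_window(*POST_STIMULUS_MS)
        return epochs.data[:, :, mask]
    x = np.asarray(epochs, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (trials, channels, samples)")
    return x


@dataclass(frozen=True)
class Whitener:
    """PCA whitening transform: rows map channels to unit-variance components."""

    W: np.ndarray  # (n_components, n_channels)
    explained_fraction: float

    @property
    def n_rank(self) -> int:
        return self.W.shape[0]

    def transform(self, data: np.ndarray) -> np.ndarray:
        return np.einsum("rc,tcs->trs", self.W, _as_array(data))


@dataclass(frozen=True)
class CSPModel:
    """Fitted CSP filters in the original channel space.

    ``filters`` rows are spatial filters w_i, ``patterns`` columns the
    corresponding topographies (pseudo-inverse of the filters), and
    ``eigenvalues`` the class-1 variance shares lambda_i, ordered by
    discriminability max(lambda, 1 - lambda).
    """

    filters: np.ndarray  # (N_rank, n_channels)
    patterns: np.ndarray  # (n_channels, N_rank)
    eigenvalues: np.ndarray
    n_rank: int
    class_definitions: tuple = (1, 2)


def _trial_covariances(data: np.ndarray) -> np.ndarray:
    """Trace-normalized sample covariance per trial, then trial average."""
    covs = np.einsum("tcs,tds->tcd", data, data) / data.shape[-1]
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("zero-variance trial encountered")
    return (covs / traces[:, None, None]).mean(axis=0)


def reduce_whiten(epochs, variance_fraction: float = 0.99, rank_tol: float = 1e-10) -> Whitener:
    """PCA whitening of the pooled covariance.

    Retains the leading components explaining at least
    ``variance_fraction`` of pooled variance (numerically null
    directions, e.g. the average-reference deficiency, are always
    dropped).  The transformed pooled covariance is the identity.
    """
    data = _as_array(epochs)
    if data.shape[0] < 2:
        raise ValueError("need >= 2 trials")
    cov = _trial_covariances(data)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    valid = evals > rank_tol * evals[0]
    evals, evecs = evals[valid], evecs[:, valid]
    cum = np.cumsum(evals) / evals.sum()
    k = int(np.searchsorted(cum, variance_fraction) + 1)
    k = min(k, len(evals))
    if k < 2:
        raise ValueError("input covariance supports fewer than 2 components")
    W = (evecs[:, :k] / np.sqrt(evals[:k])).T
    return Whitener(W=W, explained_fraction=float(cum[k - 1]))


def fit_csp(epochs_class1, epochs_class2) -> CSPModel:
    """Fit CSP filters from two classes of (already reduced) trials.

    Raises if the pooled covariance is singular; reduce/whiten first.
    """
    x1, x2 = _as_array(epochs_class1), _as_array(epochs_class2)
    if x1.shape[0] == 0 or x2.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("classes must share the channel space")
    S1 = _trial_covariances(x1)
    S2 = _trial_covariances(x2)
    Sc = S1 + S2
    cond = np.linalg.cond(Sc)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; apply reduce_whiten before fit_csp"
        )
    evals, evecs = scipy.linalg.eigh(S1, Sc)  # v' Sc v = I normalization
    order = np.argsort(np.maximum(evals, 1.0 - evals))[::-1]
    evals, evecs = evals[order], evecs[:, order]
    filters = evecs.T
    patterns = np.linalg.pinv(filters)
    return CSPModel(
        filters=filters,
        patterns=patterns,
        eigenvalues=np.clip(evals, 0.0, 1.0),
        n_rank=filters.shape[0],
    )


def extract_features(epochs, model: CSPModel) -> pd.DataFrame:
    """Log variance-share feature vector per trial.

    Columns ``f1..fN``; for every trial sum_i exp(f_i) = 1.
    """
    data = _as_array(epochs)
    if data.shape[1] != model.filters.shape[1]:
        raise ValueError("model channel space does not match epochs")
    Z = np.einsum("rc,tcs->trs", model.filters, data)
    var = Z.var(axis=-1)
    total = var.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero-variance trial: degenerate epoch")
    f = np.log(var / total)
    return pd.DataFrame(f, columns=[f"f{i + 1}" for i in range(model.n_rank)])


def fit_csp_pipeline(epochs, class_labels, variance_fraction: float = 0.99):
    """Whiten, fit CSP on two behaviorally defined classes, extract features.

    ``class_labels`` holds the per-trial class (1 or 2, typically the
    reported decision).  Returns ``(features, model, whitener)`` with
    the model's filters/patterns composed back into channel space.
    """
    data = _as_array(epochs)
    labels = np.asarray(class_labels, dtype=int)
    if len(labels) != data.shape[0]:
        raise ValueError("class_labels length must match trials")
    wh = reduce_whiten(data, variance_fraction)
    white = wh.transform(data)
    model_w = fit_csp(white[labels == 1], white[labels == 2])
    filters = model_w.filters @ wh.W
    model = CSPModel(
        filters=filters,
        patterns=np.linalg.pinv(filters),
        eigenvalues=model_w.eigenvalues,
        n_rank=model_w.n_rank,
    )
    features = extract_features(data, model)
    return features, model, wh
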