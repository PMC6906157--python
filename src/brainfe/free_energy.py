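"""Free-energy differences between recognition and generative model.

For an idealized noise-free categorizer the generative model over
(optimal category perception o, true category nu) is diagonal,
P(o, nu | M) = delta_{o nu} * 0.5 with equal category priors.  Exact
off-diagonal zeros would make the cross term of the free energy
infinite whenever the recognition distribution places any mass on the
non-matching category, so zeros are replaced by a small configurable
epsilon (default 1e-3); epsilon is recorded in every result.

Given a recognition row q(.) = Q(. | mu, m), the per-state free-energy
difference in nats is

    dF(o, mu) = sum_nu q(nu) ln q(nu) - sum_nu q(nu) ln P(o, nu | M),

summated over the four (o, mu) states to the total difference, and
collapsed into matched (o == mu) and mismatched (o != mu) means.

The module also evaluates the Boltzmann bounded-rationality trade-off

    -dF(q) = sum q U - (1/zeta) sum q ln(q / p0),

whose magnitude shrinks as the resource parameter zeta grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenerativeModel",
    "FreeEnergyResult",
    "build_generative_model",
    "delta_F",
    "delta_F_matrix",
    "total_delta_F",
    "collapse_match_mismatch",
    "free_energy_result",
    "boltzmann_negative_delta_F",
    "boltzmann_curve",
]

DEFAULT_EPSILON = 1e-3


@dataclass(frozen=True)
class GenerativeModel:
    """Diagonal-plus-epsilon joint P(o, nu | M) over two categories."""

    P: np.ndarray
    prior: float
    epsilon: float


@dataclass(frozen=True)
class FreeEnergyResult:
    """Per-state free-energy differences, nats.

    ``dF[o-1, mu-1]`` is dF(o, mu); ``dF_total`` their sum;
    matched/mismatched means collapse the diagonal/off-diagonal.
    """

    dF: np.ndarray
    dF_total: float
    matched_mean: float
    mismatched_mean: float
    epsilon_used: float

    def to_dict(self) -> dict:
        return {
            "dF_o1_mu1": float(self.dF[0, 0]),
            "dF_o1_mu2": float(self.dF[0, 1]),
            "dF_o2_mu1": float(self.dF[1, 0]),
            "dF_o2_mu2": float(self.dF[1, 1]),
            "dF_total": self.dF_total,
            "matched_mean": self.matched_mean,
            "mismatched_mean": self.mismatched_mean,
            "epsilon": self.epsilon_used,
        }


def build_generative_model(prior: float = 0.5, epsilon: float = DEFAULT_EPSILON) -> GenerativeModel:
    """[[prior, eps], [eps, prior]] with 0 < eps < prior."""
    if not 0 < epsilon < prior:
        raise ValueError(f"epsilon must satisfy 0 < epsilon < prior ({prior}), got {epsilon}")
    P = np.array([[prior, epsilon], [epsilon, prior]], dtype=float)
    return GenerativeModel(P=P, prior=prior, epsilon=epsilon)


def _check_distribution(q, atol=1e-8):
    q = np.asarray(q, dtype=float)
    if q.shape != (2,) or np.any(q < -atol) or abs(q.sum() - 1.0) > atol:
        raise ValueError(f"q_row must be a length-2 distribution, got {q}")
    return np.clip(q, 0.0, 1.0)


def delta_F(q_row, o: int, gm: GenerativeModel) -> float:
    """dF(o, mu) for one recognition row Q(.|mu), nats.

    Zero entries of q contribute 0 to the entropy term (continuity
    convention 0 ln 0 = 0); the cross term uses the epsilon-regularized
    generative model so it stays finite.
    """
    q = _check_distribution(q_row)
    if o not in (1, 2):
        raise ValueError("o must be 1 or 2")
    entropy_term = float(np.sum(np.where(q > 0, q * np.log(np.where(q > 0, q, 1.0)), 0.0)))
    cross_term = float(q @ np.log(gm.P[o - 1]))
    return entropy_term - cross_term


def delta_F_matrix(Q: np.ndarray, gm: GenerativeModel) -> np.ndarray:
    """All four dF(o, mu) from a row-stochastic recognition matrix Q."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (2, 2):
        raise ValueError("Q must be 2x2 (rows mu, columns nu)")
    dF = np.empty((2, 2))
    for o in (1, 2):
        for mu in (1, 2):
            dF[o - 1, mu - 1] = delta_F(Q[mu - 1], o, gm)
    return dF


def total_delta_F(dF: np.ndarray) -> float:
    """Sum of the four per-state differences."""
    dF = np.asarray(dF, dtype=float)
    if dF.shape != (2, 2) or not np.isfinite(dF).all():
        raise ValueError("dF must be a finite 2x2 matrix")
    return float(dF.sum())


def collapse_match_mismatch(dF: np.ndarray):
    """(matched mean, mismatched mean): diagonal vs off-diagonal states."""
    dF = np.asarray(dF, dtype=float)
    matched = 0.5 * (dF[0, 0] + dF[1, 1])
    mismatched = 0.5 * (dF[0, 1] + dF[1, 0])
    return float(matched), float(mismatched)


def free_energy_result(Q: np.ndarray, epsilon: float = DEFAULT_EPSILON, prior: float = 0.5) -> FreeEnergyResult:
    """Full free-energy summary from a recognition matrix."""
    gm = build_generative_model(prior=prior, epsilon=epsilon)
    dF = delta_F_matrix(Q, gm)
    matched, mismatched = collapse_match_mismatch(dF)
    return FreeEnergyResult(
        dF=dF,
        dF_total=total_delta_F(dF),
        matched_mean=matched,
        mismatched_mean=mismatched,
        epsilon_used=epsilon,
    )


def boltzmann_negative_delta_F(q, p0, U, zeta: float) -> float:
    """Expected utility minus (1/zeta)-weighted KL information cost.

    Requires zeta != 0 and q absolutely continuous with respect to p0.
    """
    if zeta == 0:
        raise ValueError("zeta must be non-zero")
    q = np.asarray(q, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any((q > 0) & (p0 <= 0)):
        raise ValueError("q places mass where p0 is zero")
    pos = q > 0
    kl = float(np.sum(q[pos] * np.log(q[pos] / p0[pos])))
    return float(q @ U - kl / zeta)


def boltzmann_curve(q, p0, U, zeta_grid) -> np.ndarray:
    """-dF evaluated over a grid of zeta values; shape (len(grid), 2)."""
    zeta_grid = np.asarray(zeta_grid, dtype=float)
    vals = np.array([boltzmann_negative_delta_F(q, p0, U, z) for z in zeta_grid])
    return np.column_stack([zeta_grid, vals])
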