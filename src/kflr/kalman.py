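"""Linear-Gaussian Kalman filtering specialized to recursive Bayesian regression.

The state is the regression-weight vector of one candidate model for one
target gene.  With a static transition (F = I, Q = qI, default q = 0) and
per-step observation rows H_k holding the regulators' expression, the
predict/update recursion is an exact recursive conjugate Bayesian linear
regression, and the sum of innovation log-densities (the prediction-error
decomposition) is the exact log marginal likelihood of the model — the
quantity Bayesian model averaging needs as a closed-form model score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StateSpaceModel",
    "KalmanBelief",
    "kf_predict",
    "kf_update",
    "kf_log_marginal_likelihood",
    "kf_filter_regression",
    "batch_regression_posterior",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class StateSpaceModel:
    """One step of the linear-Gaussian state-space model.

    x_{k+1} = F x_k + G_ctrl w_k,  w_k ~ N(0, Q)
    y_k     = H x_k + D_ctrl v_k,  v_k ~ N(0, R)
    """

    F: np.ndarray
    G_ctrl: np.ndarray
    Q: np.ndarray
    H: np.ndarray
    D_ctrl: np.ndarray
    R: np.ndarray

    @classmethod
    def static_regression(cls, h_row: np.ndarray, q: float = 0.0, r: float = 1.0) -> "StateSpaceModel":
        """Static-weight regression step: F = I, Q = qI, scalar observation."""
        h = np.atleast_2d(np.asarray(h_row, dtype=float))
        d = h.shape[1]
        eye = np.eye(d)
        return cls(F=eye, G_ctrl=eye, Q=q * eye, H=h,
                   D_ctrl=np.eye(1), R=np.array([[r]]))


@dataclass
class KalmanBelief:
    """Gaussian belief over the state: mean vector and covariance matrix."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean")

    @classmethod
    def isotropic(cls, dim: int, tau: float = 1.0) -> "KalmanBelief":
        return cls(mean=np.zeros(dim), cov=tau * np.eye(dim))


def _symmetrize(mat: np.ndarray) -> np.ndarray:
    return 0.5 * (mat + mat.T)


def kf_predict(belief: KalmanBelief, model: StateSpaceModel) -> KalmanBelief:
    """Time update: mean' = F mean, cov' = G Q Gᵀ + F cov Fᵀ."""
    F, G, Q = model.F, model.G_ctrl, model.Q
    if F.shape[1] != belief.mean.size:
        raise ValueError("state transition dimension mismatch")
    mean = F @ belief.mean
    cov = _symmetrize(G @ Q @ G.T + F @ belief.cov @ F.T)
    return KalmanBelief(mean=mean, cov=cov)


def kf_update(belief: KalmanBelief, model: StateSpaceModel, y: float,
              joseph: bool = False) -> tuple[KalmanBelief, float, float]:
    """Measurement update for a scalar observation.

    Returns the posterior belief, the innovation y − H x̂, and the innovation
    variance S = H P Hᵀ + D R Dᵀ.  The gain is K = P Hᵀ S⁻¹; the covariance
    update is (I − K H) P (re-symmetrized), or the Joseph form when requested.
    """
    H = np.atleast_2d(model.H)
    if H.shape[0] != 1:
        raise ValueError("kf_update expects a single observation row")
    if H.shape[1] != belief.mean.size:
        raise ValueError("observation dimension mismatch")
    P = belief.cov
    r_eff = float(np.squeeze(model.D_ctrl @ model.R @ model.D_ctrl.T))
    s = float(np.squeeze(H @ P @ H.T)) + r_eff
    if s <= 0:
        raise np.linalg.LinAlgError("nonpositive innovation variance")
    K = (P @ H.T) / s  # (d, 1)
    innovation = float(y) - float(np.squeeze(H @ belief.mean))
    mean = belief.mean + (K * innovation).ravel()
    eye = np.eye(belief.mean.size)
    if joseph:
        A = eye - K @ H
        cov = A @ P @ A.T + (K * r_eff) @ K.T
    else:
        cov = (eye - K @ H) @ P
    return KalmanBelief(mean=mean, cov=_symmetrize(cov)), innovation, s


def kf_filter_regression(y_seq: np.ndarray, H_seq: np.ndarray,
                         prior: KalmanBelief, q: float = 0.0, r: float = 1.0,
                         joseph: bool = False) -> tuple[KalmanBelief, float]:
    """Run the predict/update recursion over all samples.

    Returns the final belief and the accumulated log marginal likelihood
    Σ_k log N(y_k ; H_k x̂_{k|k−1}, H_k P_{k|k−1} H_kᵀ + r).
    """
    y_seq = np.asarray(y_seq, dtype=float).ravel()
    H_seq = np.atleast_2d(np.asarray(H_seq, dtype=float))
    if len(y_seq) != H_seq.shape[0]:
        raise ValueError("y_seq and H_seq must have the same length")
    belief = prior
    log_ml = 0.0
    for y_k, h_k in zip(y_seq, H_seq):
        model = StateSpaceModel.static_regression(h_k, q=q, r=r)
        belief = kf_predict(belief, model)
        belief, innov, s = kf_update(belief, model, y_k, joseph=joseph)
        log_ml += -0.5 * (_LOG2PI + np.log(s) + innov * innov / s)
    return belief, float(log_ml)


def kf_log_marginal_likelihood(y_seq: np.ndarray, H_seq: np.ndarray,
                               prior: KalmanBelief, q: float = 0.0,
                               r: float = 1.0) -> float:
    """Log marginal likelihood of the regression model by the innovation sum."""
    if len(np.atleast_1d(y_seq)) == 0:
        return 0.0
    _, log_ml = kf_filter_regression(y_seq, H_seq, prior, q=q, r=r)
    return log_ml


def batch_regression_posterior(y_seq: np.ndarray, H_seq: np.ndarray,
                               prior: KalmanBelief, r: float = 1.0
                               ) -> tuple[KalmanBelief, float]:
    """Closed-form conjugate Bayesian linear-regression posterior and evidence.

    Independent of the sequential filter; used as its batch cross-check.
    The evidence is the joint density of y under N(H m₀, H P₀ Hᵀ + r I).
    """
    y = np.asarray(y_seq, dtype=float).ravel()
    H = np.atleast_2d(np.asarray(H_seq, dtype=float))
    m0, P0 = prior.mean, prior.cov
    n = len(y)
    precision = np.linalg.inv(P0) + H.T @ H / r
    cov = np.linalg.inv(precision)
    mean = cov @ (np.linalg.inv(P0) @ m0 + H.T @ y / r)
    S = H @ P0 @ H.T + r * np.eye(n)
    resid = y - H @ m0
    sign, logdet = np.linalg.slogdet(S)
    log_ev = -0.5 * (n * _LOG2PI + logdet + resid @ np.linalg.solve(S, resid))
    return KalmanBelief(mean=mean, cov=_symmetrize(cov)), float(log_ev)
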