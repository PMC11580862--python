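"""Ensemble Kalman filter on transformed macrostates.

The exact linear Kalman filter (`kf_predict` / `kf_update`) is provided both
for linear problems and as the analytic oracle against which the ensemble
update is validated.  The ensemble update uses the classic
perturbed-observation formulation: each member is updated with an
independently noised copy of the observation so that the updated members are
draws from the correct posterior in the linear-Gaussian limit.  After the
update a Gaussian is fitted to the updated members and a *fresh* ensemble is
sampled from it; downstream microstate synthesis consumes those posterior
samples.

Process stochasticity is added only to parameter components: the simulators
are themselves stochastic in the state components, so the random-walk
inflation that keeps parameter marginals from collapsing is confined to the
parameter block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GaussianBelief",
    "MeasurementSpec",
    "fit_gaussian",
    "sample_ensemble",
    "kf_predict",
    "kf_update",
    "enkf_update",
    "add_parameter_process_noise",
]

#: default covariance jitter applied before sampling; degenerate ensembles
#: occur near absorbing states (extinctions), where spread collapses.
DEFAULT_JITTER = 1e-8

_SYM_TOL = 1e-10


@dataclass
class GaussianBelief:
    """Mean/covariance pair representing a filtered macrostate distribution."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.cov, self.cov.T, atol=max(_SYM_TOL, _SYM_TOL * np.abs(self.cov).max(initial=1.0))):
            raise ValueError("covariance must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class MeasurementSpec:
    """Which macro components are observed, with what noise, and when.

    ``r_diag`` holds one noise variance per observed component, in
    *transformed* units (the measurement map is component selection in
    transformed macro space).
    """

    observed: tuple
    r_diag: np.ndarray
    schedule: tuple = ()

    def __post_init__(self) -> None:
        self.observed = tuple(self.observed)
        if not self.observed:
            raise ValueError("at least one observed component required")
        self.r_diag = np.atleast_1d(np.asarray(self.r_diag, dtype=float))
        if self.r_diag.shape != (len(self.observed),):
            raise ValueError("r_diag length must match observed components")
        if np.any(self.r_diag <= 0):
            raise ValueError("measurement variances must be positive")
        self.schedule = tuple(int(t) for t in self.schedule)

    def indices(self, schema) -> np.ndarray:
        return schema.indices(self.observed)

    @property
    def R(self) -> np.ndarray:
        return np.diag(self.r_diag)


def fit_gaussian(members: np.ndarray) -> GaussianBelief:
    """Sample mean and covariance (denominator n-1) of an ensemble."""
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if members.shape[0] < 2:
        raise ValueError("need at least 2 ensemble members")
    mean = members.mean(axis=0)
    cov = np.cov(members, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return GaussianBelief(mean, cov)


def _sqrt_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def sample_ensemble(
    belief: GaussianBelief,
    n: int,
    rng: np.random.Generator,
    jitter: float = DEFAULT_JITTER,
) -> np.ndarray:
    """Draw ``n`` members from a belief, regularizing the covariance.

    Eigenvalues are clipped at zero and ``jitter * I`` is added before the
    square root, so sampling stays defined for degenerate ensembles.
    """
    if n < 2:
        raise ValueError("ensemble size must be >= 2")
    cov = belief.cov + jitter * np.eye(belief.dim)
    L = _sqrt_psd(cov)
    z = rng.standard_normal((n, belief.dim))
    return belief.mean + z @ L.T


def kf_predict(belief: GaussianBelief, A: np.ndarray, Q: np.ndarray) -> GaussianBelief:
    """Exact linear predict step: m <- A m, P <- A P A^T + Q."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    mean = A @ belief.mean
    cov = A @ belief.cov @ A.T + Q
    return GaussianBelief(mean, 0.5 * (cov + cov.T))


def kf_update(
    belief: GaussianBelief,
    H: np.ndarray,
    R: np.ndarray,
    y: np.ndarray,
) -> GaussianBelief:
    """Exact linear update with gain K = P H^T (H P H^T + R)^{-1}."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    S = H @ belief.cov @ H.T + R
    if np.linalg.matrix_rank(S) < S.shape[0]:
        raise np.linalg.LinAlgError("singular innovation covariance")
    K = np.linalg.solve(S.T, H @ belief.cov).T
    mean = belief.mean + K @ (y - H @ belief.mean)
    cov = (np.eye(belief.dim) - K @ H) @ belief.cov
    return GaussianBelief(mean, 0.5 * (cov + cov.T))


def _selection_matrix(obs_idx: np.ndarray, dim: int) -> np.ndarray:
    H = np.zeros((len(obs_idx), dim))
    H[np.arange(len(obs_idx)), obs_idx] = 1.0
    return H


def enkf_update(
    ensemble: np.ndarray,
    obs_idx: Sequence[int],
    r_diag: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    jitter: float = DEFAULT_JITTER,
) -> tuple[GaussianBelief, np.ndarray]:
    """Perturbed-observation ensemble update followed by Gaussian resampling.

    Steps: fit sample moments to the predictive ensemble; update every member
    with an observation copy perturbed by N(0, R) using the sample-covariance
    gain; fit a Gaussian posterior to the updated members; draw a fresh
    ensemble of the same size from that posterior.

    Returns ``(posterior_belief, fresh_posterior_ensemble)``.
    """
    ensemble = np.atleast_2d(np.asarray(ensemble, dtype=float))
    n, d = ensemble.shape
    if n < 2:
        raise ValueError("need at least 2 ensemble members")
    obs_idx = np.asarray(obs_idx, dtype=int)
    r_diag = np.atleast_1d(np.asarray(r_diag, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    prior = fit_gaussian(ensemble)
    H = _selection_matrix(obs_idx, d)
    R = np.diag(r_diag)
    S = H @ prior.cov @ H.T + R
    K = np.linalg.solve(S.T, H @ prior.cov).T
    eta = rng.standard_normal((n, len(obs_idx))) * np.sqrt(r_diag)
    innov = (y + eta) - ensemble[:, obs_idx]
    updated = ensemble + innov @ K.T
    posterior = fit_gaussian(updated)
    fresh = sample_ensemble(posterior, n, rng, jitter=jitter)
    return posterior, fresh


def add_parameter_process_noise(
    ensemble: np.ndarray,
    q_param: np.ndarray,
    parameter_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add independent N(0, q) random-walk increments to parameter components.

    ``q_param`` gives one variance per parameter component (in mask order);
    state components are returned bitwise unchanged.
    """
    ensemble = np.atleast_2d(np.asarray(ensemble, dtype=float))
    parameter_mask = np.asarray(parameter_mask, dtype=bool)
    q_param = np.atleast_1d(np.asarray(q_param, dtype=float))
    idx = np.flatnonzero(parameter_mask)
    if q_param.shape == (1,) and len(idx) > 1:
        q_param = np.full(len(idx), q_param[0])
    if q_param.shape != (len(idx),):
        raise ValueError("q_param length must match parameter components")
    if np.any(q_param < 0):
        raise ValueError("process variances must be nonnegative")
    out = ensemble.copy()
    if len(idx) and np.any(q_param > 0):
        noise = rng.standard_normal((ensemble.shape[0], len(idx))) * np.sqrt(q_param)
        out[:, idx] += noise
    return out
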