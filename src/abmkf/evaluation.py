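"""Filter evaluation: surprisal, tuning sweeps, phenotype clustering.

Surprisal — the negative log density of the true state under the predictive
belief — is the scoring rule used throughout: unlike mean-error metrics it
charges a forecast both for being wrong and for being overconfident.  For a
Gaussian belief it has the closed form

    S(x) = 1/2 [ (x - m)^T P^{-1} (x - m) + d log(2 pi) + log det P ]   (nats)

Cohort-level trajectory structure is explored by flattening macro
time-series, reducing with PCA, and k-means clustering; cluster divergence
over time is quantified by the closed-form Wasserstein-2 distance between
per-time Gaussian fits of each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

from .enkf import GaussianBelief, fit_gaussian

__all__ = [
    "gaussian_surprisal",
    "gaussian_wasserstein2",
    "covariance_entry_count",
    "SurprisalSeries",
    "tuning_sweep",
    "ClusterSummary",
    "phenotype_clustering",
]


def gaussian_surprisal(belief: GaussianBelief, x_true, jitter: float = 0.0) -> float:
    """Surprisal (nats) of ``x_true`` under a Gaussian belief."""
    x = np.atleast_1d(np.asarray(x_true, dtype=float))
    d = belief.dim
    if x.shape != (d,):
        raise ValueError("dimension mismatch")
    cov = belief.cov + jitter * np.eye(d) if jitter else belief.cov
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance is singular")
    diff = x - belief.mean
    maha = float(diff @ np.linalg.solve(cov, diff))
    return 0.5 * (maha + d * np.log(2.0 * np.pi) + logdet)


def _sqrtm_psd(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(a)
    if vals.min(initial=0.0) < -1e-8 * max(1.0, abs(vals).max(initial=1.0)):
        raise ValueError("matrix is not positive semidefinite")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def gaussian_wasserstein2(a: GaussianBelief, b: GaussianBelief) -> float:
    """Closed-form W2 distance between two Gaussians.

    W2^2 = |m_a - m_b|^2 + tr(S_a + S_b - 2 (S_b^{1/2} S_a S_b^{1/2})^{1/2}).
    """
    if a.dim != b.dim:
        raise ValueError("dimension mismatch")
    rb = _sqrtm_psd(b.cov)
    cross = _sqrtm_psd(rb @ a.cov @ rb)
    w2sq = float(((a.mean - b.mean) ** 2).sum() + np.trace(a.cov + b.cov - 2.0 * cross))
    return float(np.sqrt(max(0.0, w2sq)))


def covariance_entry_count(K: int, N: int, M: int) -> int:
    """Distinct off-diagonal covariance entries for K fields on an NxM lattice.

    Viewing every lattice value of every field as a state dimension gives a
    d = K*N*M dimensional state and d(d-1)/2 distinct covariances — the
    dimensionality argument for filtering summaries instead of full lattices.
    """
    if K < 1 or N < 1 or M < 1:
        raise ValueError("dimensions must be positive")
    d = K * N * M
    return d * (d - 1) // 2


@dataclass
class SurprisalSeries:
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values lengths differ")


def tuning_sweep(
    config,
    measurement_choices: Sequence[str],
    r_levels: Sequence[float],
    n_patients: int,
    rng: np.random.Generator,
) -> dict:
    """Median-surprisal sweep over (observed component, noise level) settings.

    For each setting, ``n_patients`` virtual patients are generated and
    assimilated; the pointwise median predictive surprisal series across
    patients is returned in a dict keyed by ``(measurement, R)``.
    """
    from . import driver  # local import; driver depends on this module

    if n_patients < 1:
        raise ValueError("need at least one virtual patient")
    results: dict = {}
    for meas in measurement_choices:
        for r in r_levels:
            cfg = config.with_measurement((meas,), (float(r),))
            series = []
            for _ in range(n_patients):
                seeds = rng.integers(0, 2**31 - 1, size=4)
                run_cfg = cfg.with_seeds(*seeds.tolist())
                patient = driver.make_virtual_patient(run_cfg)
                result = driver.run_abmkf(run_cfg, patient)
                series.append(result.surprisal.values)
            stack = np.vstack(series)
            results[(meas, float(r))] = SurprisalSeries(
                np.arange(stack.shape[1]), np.median(stack, axis=0)
            )
    return results


@dataclass
class ClusterSummary:
    labels: np.ndarray
    n_clusters: int
    pca_coords: np.ndarray
    per_time_gaussians: dict  # cluster -> list[GaussianBelief | None] per time
    wasserstein_series: dict  # (i, j) -> np.ndarray over time

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


def phenotype_clustering(
    trajectories: np.ndarray,
    n_components: int = 3,
    k_max: int = 6,
    rng: np.random.Generator | None = None,
) -> ClusterSummary:
    """Cluster macro trajectories into phenotypes and track their divergence.

    Each trajectory (time x components) is flattened to one vector, reduced
    by PCA to ``n_components``, and k-means clustered with k chosen by
    silhouette over k in [2, k_max].  Identical trajectories fall back to a
    single cluster.  Per time point each cluster of size >= 2 is fitted with
    a Gaussian over the (untransformed) macro components and all pairwise W2
    distances are returned as time series.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    trajectories = np.asarray(trajectories, dtype=float)
    if trajectories.ndim != 3:
        raise ValueError("expected (n_traj, n_time, n_comp) array")
    n, T, d = trajectories.shape
    if n < 2:
        raise ValueError("need at least two trajectories")
    seed = int(rng.integers(0, 2**31 - 1)) if rng is not None else 0
    flat = trajectories.reshape(n, T * d)
    n_pc = min(n_components, n - 1, flat.shape[1])
    coords = PCA(n_components=n_pc, random_state=seed).fit_transform(flat)

    spread = coords.std(axis=0).max()
    if spread < 1e-12:
        labels = np.zeros(n, dtype=int)
        best_k = 1
    else:
        best_k, best_score, labels = 1, -np.inf, np.zeros(n, dtype=int)
        for k in range(2, min(k_max, n - 1) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(coords, km.labels_)
            if score > best_score:
                best_k, best_score, labels = k, score, km.labels_.copy()
        if not np.isfinite(best_score):
            best_k, labels = 1, np.zeros(n, dtype=int)

    gaussians: dict = {}
    for c in range(best_k):
        members = trajectories[labels == c]
        per_time = []
        for t in range(T):
            if members.shape[0] >= 2:
                per_time.append(fit_gaussian(members[:, t, :]))
            else:
                per_time.append(None)
        gaussians[c] = per_time

    jitter = 1e-9
    w2: dict = {}
    for i in range(best_k):
        for j in range(i + 1, best_k):
            series = np.full(T, np.nan)
            for t in range(T):
                gi, gj = gaussians[i][t], gaussians[j][t]
                if gi is None or gj is None:
                    continue
                a = GaussianBelief(gi.mean, gi.cov + jitter * np.eye(d))
                b = GaussianBelief(gj.mean, gj.cov + jitter * np.eye(d))
                series[t] = gaussian_wasserstein2(a, b)
            w2[(i, j)] = series
    return ClusterSummary(labels, best_k, coords, gaussians, w2)
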