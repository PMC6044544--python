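"""Trial-wise pattern estimation and multivariate noise normalisation.

Each recall trial is modelled as a boxcar over the 12-second recall window
convolved with the canonical (SPM double-gamma) haemodynamic response.  Two
estimators are provided: *least squares separate* (LSS; one GLM per trial,
with a single regressor for all remaining trials — the default, best suited
to closely spaced events) and *least squares all* (LSA; one regressor per
trial in a single model, which also supplies the residuals used for noise
covariance estimation).

Noise normalisation whitens trial patterns by the inverse square root of a
shrunk voxel-by-voxel residual covariance, down-weighting noisy voxels and
decorrelating neighbours.  Shrinkage is toward the diagonal of the sample
covariance, with an analytic (Schafer-Strimmer-style) intensity by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level import compute_regressor

RECALL_DURATION_S = 12.0


@dataclass
class SessionTimeseries:
    """One scanning session: voxel timeseries plus the trial event model."""

    data: np.ndarray  # scans x voxels
    tr: float
    onsets: np.ndarray  # seconds, one per trial in this session
    durations: np.ndarray  # seconds
    nuisance: np.ndarray | None = None  # scans x k, e.g. motion parameters

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        span = self.data.shape[0] * self.tr
        if np.any(self.onsets < 0) or np.any(self.onsets >= span):
            raise ValueError("trial onsets must fall within the scan span")
        if np.any(self.durations <= 0):
            raise ValueError("trial durations must be positive")
        if self.nuisance is not None and len(self.nuisance) != len(self.data):
            raise ValueError("nuisance regressors must have one row per scan")


@dataclass
class PatternMatrix:
    """Trials-by-voxels activity estimates, raw or noise-normalised."""

    data: np.ndarray
    whitened: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("pattern matrix must be 2-D (trials x voxels)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("pattern matrix must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class NoiseCovariance:
    """Shrunk voxel noise covariance estimated from GLM residuals."""

    sigma: np.ndarray
    shrinkage: float
    n_sessions: int

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.sigma)[0] <= 0:
            raise ValueError(
                "covariance is not positive definite; increase shrinkage"
            )

    def inverse_sqrt(self, eig_floor: float = 1e-10) -> np.ndarray:
        """Symmetric inverse square root, eigenvalues floored for stability."""
        vals, vecs = np.linalg.eigh(self.sigma)
        vals = np.maximum(vals, eig_floor * vals.max())
        return (vecs / np.sqrt(vals)) @ vecs.T


def hrf_regressor(
    onset: float, duration: float, frame_times: np.ndarray
) -> np.ndarray:
    """Boxcar convolved with the canonical double-gamma HRF, sampled at scans."""
    cond = np.array([[onset], [duration], [1.0]])
    reg, _ = compute_regressor(cond, "spm", frame_times)
    return reg[:, 0]


def _design_columns(ts: SessionTimeseries) -> np.ndarray:
    frame_times = np.arange(ts.data.shape[0]) * ts.tr
    return np.column_stack(
        [hrf_regressor(o, d, frame_times) for o, d in zip(ts.onsets, ts.durations)]
    )


def _augment(X: np.ndarray, ts: SessionTimeseries, intercept: bool) -> np.ndarray:
    parts = [X]
    if ts.nuisance is not None and ts.nuisance.size:
        parts.append(ts.nuisance)
    if intercept:
        parts.append(np.ones((X.shape[0], 1)))
    return np.column_stack(parts)


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns from the QR diagonal
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = np.where(diag < 1e-10 * max(diag.max(), 1.0))[0].tolist()
        raise ValueError(f"rank-deficient design matrix; collinear columns {bad}")


def estimate_trial_patterns(
    ts: SessionTimeseries,
    mode: str = "lss",
    intercept: bool = True,
) -> tuple[PatternMatrix, np.ndarray]:
    """Estimate one activity pattern per trial; return (patterns, residuals).

    ``lss`` fits a separate GLM per trial (target regressor, one summed
    regressor for all other trials, nuisance, intercept); ``lsa`` fits a
    single model with one regressor per trial.  Residuals are always the
    LSA residuals (data minus the full-model fit), which feed the noise
    covariance estimate.
    """
    if mode not in ("lss", "lsa"):
        raise ValueError("mode must be 'lss' or 'lsa'")
    trial_cols = _design_columns(ts)
    X_lsa = _augment(trial_cols, ts, intercept)
    _check_rank(X_lsa)
    beta_lsa, *_ = np.linalg.lstsq(X_lsa, ts.data, rcond=None)
    residuals = ts.data - X_lsa @ beta_lsa

    n_trials = trial_cols.shape[1]
    if mode == "lsa":
        betas = beta_lsa[:n_trials]
    else:
        betas = np.empty((n_trials, ts.data.shape[1]))
        for i in range(n_trials):
            others = np.delete(trial_cols, i, axis=1)
            cols = [trial_cols[:, [i]]]
            if others.shape[1]:
                cols.append(others.sum(axis=1, keepdims=True))
            X_i = _augment(np.column_stack(cols), ts, intercept)
            _check_rank(X_i)
            b, *_ = np.linalg.lstsq(X_i, ts.data, rcond=None)
            betas[i] = b[0]
    return PatternMatrix(np.asarray(betas), whitened=False), residuals


def estimate_noise_covariance(
    residuals: list[np.ndarray],
    shrink: str | float = "auto",
) -> NoiseCovariance:
    """Pool per-session residual covariances and shrink toward the diagonal.

    Per-session sample covariances (columns centred within session) are
    averaged with equal weights, then shrunk: ``sigma = (1 - lam) * S +
    lam * diag(S)``.  ``shrink="auto"`` picks the intensity with the
    analytic rule of Schafer & Strimmer for a diagonal target — the ratio
    of the summed sampling variances of the off-diagonal entries to their
    summed squares.  When the pooled row count is at most voxels/10 the
    covariance is badly underdetermined and the intensity is floored
    at 0.9.
    """
    if not residuals:
        raise ValueError("need at least one residual matrix")
    p = residuals[0].shape[1]
    centred = []
    covs = []
    for r in residuals:
        r = np.asarray(r, dtype=float)
        if r.shape[1] != p:
            raise ValueError("all residual matrices must share the voxel count")
        c = r - r.mean(axis=0)
        centred.append(c)
        covs.append(c.T @ c / (r.shape[0] - 1))
    S = np.mean(covs, axis=0)
    if np.any(np.diag(S) <= 0):
        bad = np.where(np.diag(S) <= 0)[0].tolist()
        raise ValueError(f"degenerate voxels with zero residual variance: {bad}")

    X = np.vstack(centred)
    n_total = X.shape[0]
    if shrink == "auto":
        lam = _schafer_strimmer_lambda(X)
        if n_total <= p / 10:
            lam = max(lam, 0.9)
    else:
        lam = float(shrink)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage intensity must be in [0, 1]")
    sigma = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    return NoiseCovariance(sigma=sigma, shrinkage=lam, n_sessions=len(residuals))


def _schafer_strimmer_lambda(X: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the diagonal target."""
    n, p = X.shape
    if n < 3:
        return 1.0
    S = X.T @ X / (n - 1)
    wbar = X.T @ X / n
    w2sum = (X**2).T @ (X**2)  # sum_k x_ki^2 x_kj^2
    var_s = n / (n - 1) ** 3 * (w2sum - n * wbar**2)
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(S[off] ** 2)
    if denom <= 0:
        return 1.0
    return float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))


def whiten_patterns(
    p: PatternMatrix, cov: NoiseCovariance, eig_floor: float = 1e-10
) -> PatternMatrix:
    """Multivariate noise normalisation: right-multiply rows by sigma^(-1/2)."""
    if p.whitened:
        raise ValueError("patterns are already whitened (double-whitening guard)")
    if cov.sigma.shape[0] != p.n_voxels:
        raise ValueError(
            f"covariance dimension {cov.sigma.shape[0]} does not match "
            f"voxel count {p.n_voxels}"
        )
    W = cov.inverse_sqrt(eig_floor)
    return PatternMatrix(p.data @ W, whitened=True)
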