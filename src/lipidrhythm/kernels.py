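"""Covariance functions for the hierarchical rhythmicity model.

The model decomposes each analyte's (normalised) concentration into three
latent components with stationary covariances:

* a **shared periodic process** common to every subject in a group,
  with an exp-sine-squared kernel of fixed 24 h period — the circadian
  hypothesis under test;
* a **subject-specific smooth deviation**, one independent Matern 3/2
  process per subject;
* i.i.d. Gaussian observation noise.

The joint covariance over the stacked observation vector of one analyte in
one group couples observations of *different* subjects only through the
shared periodic block.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KernelParams",
    "periodic_kernel",
    "matern32_kernel",
    "build_joint_covariance",
    "add_jitter",
]

_SQRT3 = np.sqrt(3.0)

#: relative diagonal jitter applied before any Cholesky factorisation
DEFAULT_JITTER = 1e-8


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the hierarchical covariance.

    Attributes
    ----------
    sigma2_p : float
        Variance of the shared periodic component (normalised units).
    ell_p : float
        Lengthscale of the periodic kernel (unitless warp of the sine).
    period : float
        Period of the shared component in hours; fixed at 24 by default
        because five samples per subject cannot identify a free period —
        the test is for 24 h rhythmicity specifically.
    sigma2_m : float
        Variance of the per-subject Matern 3/2 deviation.
    ell_m : float
        Matern lengthscale in hours.
    sigma2_n : float
        Observation-noise variance (must be strictly positive).
    """

    sigma2_p: float = 0.0
    ell_p: float = 1.0
    period: float = 24.0
    sigma2_m: float = 1.0
    ell_m: float = 12.0
    sigma2_n: float = 1.0

    def validate(self) -> "KernelParams":
        if not (self.sigma2_p >= 0.0):
            raise ValueError(f"sigma2_p must be >= 0, got {self.sigma2_p}")
        if not (self.sigma2_m >= 0.0):
            raise ValueError(f"sigma2_m must be >= 0, got {self.sigma2_m}")
        if not (self.sigma2_n > 0.0):
            raise ValueError(f"sigma2_n must be > 0, got {self.sigma2_n}")
        for name in ("ell_p", "ell_m", "period"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise ValueError(f"{name} must be > 0, got {v}")
        return self

    def with_(self, **kwargs) -> "KernelParams":
        return replace(self, **kwargs)


def periodic_kernel(t1, t2, params: KernelParams) -> np.ndarray:
    """Exp-sine-squared covariance, exactly ``period``-periodic in the lag.

    k(t, t') = sigma2_p * exp(-2 sin^2(pi (t - t') / T) / ell_p^2)
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    s = np.sin(np.pi * np.subtract.outer(t1, t2) / params.period)
    return params.sigma2_p * np.exp(-2.0 * s * s / params.ell_p**2)


def matern32_kernel(t1, t2, params: KernelParams) -> np.ndarray:
    """Matern 3/2 covariance: sigma2_m (1 + sqrt3 r/ell) exp(-sqrt3 r/ell)."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    a = _SQRT3 * np.abs(np.subtract.outer(t1, t2)) / params.ell_m
    return params.sigma2_m * (1.0 + a) * np.exp(-a)


def add_jitter(K: np.ndarray, rel: float = DEFAULT_JITTER) -> np.ndarray:
    """Return K plus ``rel * mean(diag(K))`` on the diagonal (numerical PD)."""
    K = np.asarray(K, dtype=float)
    return K + rel * float(np.mean(np.diag(K))) * np.eye(K.shape[0])


def build_joint_covariance(
    series,
    params: KernelParams,
    include_shared: bool = True,
    jitter: float | None = None,
) -> np.ndarray:
    """Joint covariance over the stacked observations of one analyte/group.

    K[a, b] = [include_shared] k_per(t_a, t_b)
              + 1{subject_a = subject_b} k_mat(t_a, t_b)
              + 1{a = b} sigma2_n

    Parameters
    ----------
    series : object with ``t`` (hours) and ``subject_idx`` attributes
        Typically an :class:`~lipidrhythm.io.AnalyteSeries`.
    include_shared : bool
        Whether the shared periodic block enters (rhythmic model) or not
        (null model).
    jitter : float or None
        If not None, relative diagonal jitter added before returning.
    """
    params.validate()
    t = np.asarray(series.t, dtype=float)
    subj = np.asarray(series.subject_idx, dtype=int)
    if t.size == 0:
        raise ValueError("series is empty")
    K = np.zeros((t.size, t.size))
    if include_shared:
        K += periodic_kernel(t, t, params)
    same = np.equal.outer(subj, subj)
    K += matern32_kernel(t, t, params) * same
    K += params.sigma2_n * np.eye(t.size)
    if not np.all(np.isfinite(K)):
        raise FloatingPointError("non-finite entries in joint covariance")
    if jitter is not None:
        K = add_jitter(K, jitter)
    return K
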