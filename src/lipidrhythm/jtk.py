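"""Nonparametric cosine-template rhythm detection (JTK-CYCLE style).

For evenly sampled designs (the mouse serum time courses) rhythmicity is
scored by Kendall rank correlation between the measurements and a family
of phase-shifted cosine templates cos(2 pi (t - phi) / period).  Each
template yields a one-sided concordance p-value; the family-wise p-value
is Bonferroni-corrected over the number of *distinct* templates, and the
best phase is the template with the smallest p (earliest phase on ties).

This is a deliberately simplified detector: cosine templates + Kendall
tau + Bonferroni, not the original JTK_CYCLE null distribution with
asymmetry search.  It serves as an independent cross-check on the GP
likelihood-ratio calls, and is conservative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = ["JtkResult", "JTKCycle", "jtk_test", "adjust_bh"]


@dataclass
class JtkResult:
    analyte: str
    best_phase_h: float | None
    tau: float | None
    p_value: float
    p_adj: float | None = None

    @property
    def is_na(self) -> bool:
        return self.tau is None


def _tau_permutation_pvalue(template, values, tau_obs, n_perm, rng):
    """One-sided (concordance) permutation p for Kendall tau, vectorised.

    Used when ties (replicated timepoints) invalidate the exact null
    distribution.  O(n_perm * n^2) pair comparisons — fine for n <= 100.
    """
    n = len(values)
    iu = np.triu_indices(n, k=1)
    sx = np.sign(np.subtract.outer(template, template))[iu]
    perms = np.array([rng.permutation(values) for _ in range(n_perm)])
    dy = np.sign(perms[:, iu[0]] - perms[:, iu[1]])
    # tau-b denominator per permutation (tie-corrected)
    n0 = len(sx)
    tx = n0 - np.count_nonzero(sx)
    ty = n0 - np.count_nonzero(dy, axis=1)
    denom = np.sqrt((n0 - tx) * (n0 - ty).astype(float))
    taus = (sx * dy).sum(axis=1) / np.where(denom > 0, denom, np.inf)
    return (1 + int(np.sum(taus >= tau_obs - 1e-12))) / (1 + n_perm)


class JTKCycle(BaseEstimator):
    """Cosine-template Kendall-tau rhythm detector, scikit-learn style.

    Parameters
    ----------
    period : float, default 24.0
        Period of the cosine template family in hours.
    phase_step : float or None
        Spacing of the candidate-phase grid in hours; None uses the
        sampling interval of the data.
    n_permutations : int, default 999
        Permutations for the tied-data fallback p-value.
    random_state : int, default 0
        Seed for the permutation fallback.

    Attributes
    ----------
    best_phase_h_ : float or None
        Phase of the best-matching template (earliest on ties).
    tau_ : float or None
        Kendall tau against the best template; None for constant input.
    p_value_ : float
        Family-wise (Bonferroni over distinct templates) p-value.
    """

    def __init__(self, period: float = 24.0, phase_step: float | None = None,
                 n_permutations: int = 999, random_state: int = 0):
        self.period = period
        self.phase_step = phase_step
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        """Score one series: X is the time vector (hours), y the values."""
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.size != y.size:
            raise ValueError("times and values must be aligned")
        if np.unique(t).size < 4:
            raise ValueError("need >= 4 distinct timepoints")

        if np.ptp(y) < 1e-12:
            # constant series carries no rank information: NA, no rejection
            self.best_phase_h_ = None
            self.tau_ = None
            self.p_value_ = 1.0
            self.n_templates_ = 0
            return self

        step = self.phase_step
        if step is None:
            step = float(np.min(np.diff(np.unique(t))))
        phases = np.arange(0.0, self.period, step)

        # drop duplicate templates (identical value vectors) before Bonferroni
        seen = {}
        for phi in phases:
            tmpl = np.cos(2.0 * np.pi * (t - phi) / self.period)
            key = tuple(np.round(tmpl, 9))
            if key not in seen:
                seen[key] = (phi, tmpl)
        templates = list(seen.values())

        rng = np.random.default_rng(self.random_state)
        best = None
        for phi, tmpl in templates:
            has_ties = (np.unique(tmpl).size < tmpl.size) or (np.unique(y).size < y.size)
            tau = kendalltau(tmpl, y).statistic
            if not np.isfinite(tau):
                continue
            if has_ties:
                p1 = _tau_permutation_pvalue(tmpl, y, tau, self.n_permutations, rng)
            else:
                p2 = kendalltau(tmpl, y, method="exact").pvalue
                p1 = p2 / 2.0 if tau > 0 else 1.0 - p2 / 2.0
            if best is None or p1 < best[0] - 1e-15:
                best = (p1, phi, tau)

        self.n_templates_ = len(templates)
        self.p_value_ = min(1.0, best[0] * self.n_templates_)
        self.best_phase_h_ = float(best[1] % self.period)
        self.tau_ = float(best[2])
        return self

    def predict(self, X):
        """Best-matching cosine template evaluated at times ``X``."""
        check_is_fitted(self, "p_value_")
        if self.best_phase_h_ is None:
            return np.zeros(np.asarray(X).size)
        T = np.asarray(X, dtype=float).ravel()
        return np.cos(2.0 * np.pi * (T - self.best_phase_h_) / self.period)


def jtk_test(
    times,
    values,
    period: float = 24.0,
    phase_step: float | None = None,
    analyte: str = "",
    n_permutations: int = 999,
    seed: int = 0,
) -> JtkResult:
    """Functional wrapper around :class:`JTKCycle` for one series."""
    y = np.asarray(values, dtype=float)
    if np.ptp(y) < 1e-12:
        return JtkResult(analyte=analyte, best_phase_h=None, tau=None, p_value=1.0)
    est = JTKCycle(
        period=period, phase_step=phase_step,
        n_permutations=n_permutations, random_state=seed,
    ).fit(times, y)
    return JtkResult(
        analyte=analyte, best_phase_h=est.best_phase_h_, tau=est.tau_, p_value=est.p_value_
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
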