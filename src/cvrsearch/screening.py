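"""Cohort-inclusion screening: amyloid-positivity thresholds.

Two mechanisms are provided: a fixed published cutoff (tracer-specific,
boundary inclusive), and a data-driven cutoff from a two-component Gaussian
mixture fitted to a cohort's composite amyloid measures.  The default
data-driven rule places the cutoff where the two weighted component
densities are equal (posterior probability 0.5) - the Bayes decision
boundary between the amyloid-negative and amyloid-positive modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

__all__ = ["GMMFit", "threshold_positivity", "fit_gmm2", "positivity_cutoff"]

CUTOFF_RULES = ("equal_posterior", "valley", "mu1_plus_2sd")


@dataclass(frozen=True)
class GMMFit:
    """Two-component univariate Gaussian mixture, components sorted by mean."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    loglik: float
    converged: bool

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.weights[0] * stats.norm.pdf(x, self.means[0], self.sds[0]) + self.weights[
            1
        ] * stats.norm.pdf(x, self.means[1], self.sds[1])


def threshold_positivity(value: float | np.ndarray, cutoff: float) -> bool | np.ndarray:
    """Fixed-threshold positivity; the boundary itself counts as positive."""
    value = np.asarray(value, dtype=float)
    if not (np.all(np.isfinite(value)) and np.isfinite(cutoff)):
        raise ValueError("positivity requires finite inputs")
    out = value >= cutoff
    return bool(out) if out.ndim == 0 else out


def fit_gmm2(values: np.ndarray, seed: int = 0, n_restarts: int = 10) -> GMMFit:
    """EM fit of a 2-component mixture with multiple restarts.

    Components are returned sorted by mean.  Degenerate data (fewer than 10
    points, or collapse onto identical values) yields a non-converged fit.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 10:
        raise ValueError("need at least 10 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        return GMMFit((0.5, 0.5), (float(x[0]), float(x[0])), (0.0, 0.0), float("-inf"), False)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_restarts,
        init_params="k-means++",
        tol=1e-8,
        reg_covar=1e-10,
        max_iter=500,
        random_state=seed,
    )
    gm.fit(x[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    converged = bool(gm.converged_) and sds.min() > 0 and means[0] < means[1]
    return GMMFit(
        weights=(float(weights[0]), float(weights[1])),
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        loglik=float(gm.score(x[:, None]) * len(x)),
        converged=converged,
    )


def positivity_cutoff(fit: GMMFit, rule: str = "equal_posterior") -> float:
    """Derive the positivity cutoff from a fitted two-component mixture.

    ``equal_posterior`` (default): the point in (mu1, mu2) where the two
    weighted component densities are equal, found by root bracketing; falls
    back to the density-valley midpoint if no root lies between the means.
    ``valley``: the mixture-density minimum in (mu1, mu2).
    ``mu1_plus_2sd``: mu1 + 2*sd1.
    """
    if not fit.converged:
        raise ValueError("cutoff requires a converged mixture fit")
    if rule not in CUTOFF_RULES:
        raise ValueError(f"unknown cutoff rule: {rule!r}")
    (w1, w2), (m1, m2), (s1, s2) = fit.weights, fit.means, fit.sds
    if rule == "mu1_plus_2sd":
        return float(m1 + 2.0 * s1)
    if rule == "valley":
        return _valley(fit, m1, m2)

    def logdiff(x: float) -> float:
        return (np.log(w1) + stats.norm.logpdf(x, m1, s1)) - (
            np.log(w2) + stats.norm.logpdf(x, m2, s2)
        )

    a, b = m1 + 1e-12 * max(1.0, abs(m1)), m2 - 1e-12 * max(1.0, abs(m2))
    fa, fb = logdiff(a), logdiff(b)
    if fa * fb > 0:  # no equal-density point between the means
        return _valley(fit, m1, m2)
    return float(optimize.brentq(logdiff, a, b, xtol=1e-12, rtol=1e-15))


def _valley(fit: GMMFit, m1: float, m2: float) -> float:
    res = optimize.minimize_scalar(
        lambda x: fit.density(np.asarray(x)), bounds=(m1, m2), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
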