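"""Linear mixed model for log biomarker trajectories.

The model for observation *i* of subject *j* is

    y_ij = b0 + b1*time_ij + b2*DX_j + b3*time_ij*DX_j + u0_j + u1_j*time_ij + e_ij

with correlated subject-level random intercepts/slopes (u0, u1) ~ N(0, G)
(unstructured 2x2 covariance) and iid residuals e ~ N(0, sigma_eps^2).  DX is
1 for cognitively impaired subjects, time is centred at each subject's mean
scan time, which makes every reported metric invariant to shifting a
subject's visit schedule in calendar time.

Three quantities feed biomarker evaluation:

* group separation — the Wald t-statistic b3_hat / SE(b3_hat);
* repeatability — 100 x SD of the conditional residuals (log scale, ~ percent
  error);
* the variance components (slope variance, residual variance) consumed by the
  trial sample-size formula.

Fitting is by restricted maximum likelihood (ML available for nested model
comparison) on per-subject sufficient statistics: the random-effect structure
is 2-dimensional, so each subject contributes closed-form 2x2 blocks and the
profiled deviance costs O(n_subjects) small-matrix work per evaluation.  This
keeps genetic-algorithm searches and parametric bootstraps (10^4-10^5 refits
on a fixed design) fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LongitudinalFrame",
    "LMMFit",
    "RandomSlopeModel",
    "center_time",
    "fit_lmm",
    "group_separation",
    "repeatability_percent",
    "lrt_random_correlation",
]

_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-12  # variance-component floor, flags a boundary fit


@dataclass(frozen=True)
class LongitudinalFrame:
    """Model-ready observations: per-subject-centred time, log value, DX.

    ``frame`` has columns subject_id, time, y, dx sorted by subject then time;
    within each subject mean(time) == 0.
    """

    frame: pd.DataFrame

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()


def center_time(
    series: pd.DataFrame, groups: Mapping[str, str] | None = None
) -> LongitudinalFrame:
    """Build a model frame from a biomarker series.

    ``series`` needs columns subject_id, scan_time and log_value (as produced
    by ``compute_cvr``); the cognitive group comes from a ``group`` column or
    the ``groups`` mapping.  Time is centred at each subject's mean scan time,
    so only within-subject visit spacing matters.
    """
    df = series.copy()
    if groups is not None:
        df["group"] = df["subject_id"].map(dict(groups))
    if "group" not in df.columns or df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "subject_id"].unique()) if "group" in df else "all"
        raise ValueError(f"subject(s) without group label: {missing}")
    counts = df.groupby("subject_id")["scan_time"].nunique()
    few = counts[counts < 2]
    if len(few):
        raise ValueError(f"subject(s) with fewer than 2 observations: {sorted(few.index)}")
    df["time"] = df["scan_time"] - df.groupby("subject_id")["scan_time"].transform("mean")
    df["dx"] = (df["group"].astype(str).str.upper() == "CI").astype(float)
    df["y"] = df["log_value"]
    df = df.sort_values(["subject_id", "time"], kind="mergesort").reset_index(drop=True)
    return LongitudinalFrame(df[["subject_id", "time", "y", "dx"]])


@dataclass(frozen=True)
class LMMFit:
    """Fitted mixed model: fixed effects, variance components, residuals.

    ``beta``/``se`` are ordered (intercept, time, DX, time:DX); for a
    single-group frame only (intercept, time) are present.  ``cov_re`` is the
    2x2 random-effect covariance; ``resid`` holds conditional residuals
    e_hat = y - X beta_hat - Z u_hat.
    """

    beta: np.ndarray
    se: np.ndarray
    cov_re: np.ndarray
    sigma_eps: float
    resid: np.ndarray
    loglik: float
    converged: bool
    reml: bool
    n_obs: int
    n_subjects: int
    two_group: bool
    ranef: np.ndarray = field(repr=False, default=None)  # (n_subjects, 2) BLUPs
    theta: np.ndarray = field(repr=False, default=None)  # optimizer solution
    warnings: tuple[str, ...] = ()

    @property
    def sigma_b0(self) -> float:
        return float(np.sqrt(max(self.cov_re[0, 0], 0.0)))

    @property
    def sigma_b1(self) -> float:
        return float(np.sqrt(max(self.cov_re[1, 1], 0.0)))

    @property
    def rho(self) -> float:
        d = self.sigma_b0 * self.sigma_b1
        if d <= 0:
            return 0.0
        return float(np.clip(self.cov_re[0, 1] / d, -1.0, 1.0))

    def to_dict(self) -> dict:
        names = ["intercept", "time", "dx", "time_dx"][: len(self.beta)]
        return {
            "beta": dict(zip(names, map(float, self.beta))),
            "se": dict(zip(names, map(float, self.se))),
            "sigma_b0": self.sigma_b0,
            "sigma_b1": self.sigma_b1,
            "rho": self.rho,
            "sigma_eps": self.sigma_eps,
            "loglik": self.loglik,
            "reml": self.reml,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "warnings": list(self.warnings),
        }


class RandomSlopeModel:
    """Profiled REML/ML fitter for the random-intercept+slope model.

    Precomputes every y-independent per-subject cross-product, so the same
    design can be refitted against many response vectors (GA candidates,
    bootstrap replicates) cheaply.
    """

    def __init__(self, subjects: np.ndarray, time: np.ndarray, dx: np.ndarray):
        subjects = np.asarray(subjects)
        order = np.argsort(subjects, kind="stable")
        self.order = order
        self.subjects = subjects[order]
        t = np.asarray(time, dtype=float)[order]
        d = np.asarray(dx, dtype=float)[order]
        self.time = t
        _, idx, counts = np.unique(self.subjects, return_index=True, return_counts=True)
        sl = np.argsort(idx)
        self.starts = idx[sl]
        self.counts = counts[sl]
        self.subject_ids = self.subjects[self.starts]
        self.n = len(t)
        self.m = len(self.starts)
        self.group_index = np.zeros(self.n, dtype=int)
        for k, (s, c) in enumerate(zip(self.starts, self.counts)):
            self.group_index[s : s + c] = k

        self.two_group = len(np.unique(d)) > 1
        if self.two_group:
            X = np.column_stack([np.ones(self.n), t, d, t * d])
        else:
            X = np.column_stack([np.ones(self.n), t])
        self.X = X
        self.p = X.shape[1]
        Z = np.column_stack([np.ones(self.n), t])
        self.Z = Z

        def _persub(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            # per-subject a_j' b_j via segment sums: (m, a_cols, b_cols)
            prod = a[:, :, None] * b[:, None, :]
            out = np.add.reduceat(prod.reshape(self.n, -1), self.starts, axis=0)
            return out.reshape(self.m, a.shape[1], b.shape[1])

        self._persub = _persub
        self.A = _persub(Z, Z)      # (m,2,2) Z'Z
        self.ZX = _persub(Z, X)     # (m,2,p)
        self.XX = _persub(X, X).sum(axis=0)  # (p,p)

    # -- sufficient statistics in y ----------------------------------------

    def _ystats(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """y-dependent sufficient statistics for W = [X, y]:
        per-subject ZW_j = Z_j'W_j (m,2,p+1) and the pooled W'W (p+1,p+1)."""
        Zy = np.add.reduceat(self.Z * y[:, None], self.starts, axis=0)  # (m,2)
        ZW = np.concatenate([self.ZX, Zy[:, :, None]], axis=2)
        WW = np.empty((self.p + 1, self.p + 1))
        WW[: self.p, : self.p] = self.XX
        Xy = self.X.T @ y
        WW[: self.p, self.p] = Xy
        WW[self.p, : self.p] = Xy
        WW[self.p, self.p] = y @ y
        return ZW, WW

    # -- profiled deviance ---------------------------------------------------

    def _core(self, psi: np.ndarray, ystats, reml: bool, want: str = "value"):
        """Profiled -2 log-lik, optionally with gradient or fit pieces.

        ``want``: 'value' | 'grad' | 'aux'.  Uses per-subject 2x2 Woodbury
        blocks: B_j = I + Psi Z_j'Z_j, M_j = B_j^-1 Psi, and the stacked
        W = [X, y] cross-products so all heavy contractions are single BLAS
        calls.  beta and sigma^2 are profiled out; by the envelope theorem
        the gradient needs only the explicit-Psi terms:

            d log|B_j|   =  tr(A_j B_j^-1 dPsi)
            d log|XVX|   = -tr(Q_j G^-1 Q_j' dPsi),  Q_j = B_j'^-1 Z_j'X_j
            d RSS        = -tr(r_j r_j' dPsi),       r_j = B_j'^-1 Z_j'(y - X beta)_j
        """
        ZW, WW = ystats
        p, p1 = self.p, self.p + 1
        B = np.eye(2)[None] + psi[None] @ self.A
        det = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
        if np.any(det <= 0) or not np.all(np.isfinite(det)):
            return None
        Binv = np.empty_like(B)
        Binv[:, 0, 0] = B[:, 1, 1]
        Binv[:, 1, 1] = B[:, 0, 0]
        Binv[:, 0, 1] = -B[:, 0, 1]
        Binv[:, 1, 0] = -B[:, 1, 0]
        Binv /= det[:, None, None]
        M = Binv @ psi[None]
        T = M @ ZW  # (m,2,p1)
        WVW = WW - ZW.reshape(-1, p1).T @ T.reshape(-1, p1)
        XVX = WVW[:p, :p]
        XVy = WVW[:p, p]
        yVy = WVW[p, p]
        try:
            c = np.linalg.cholesky(XVX)
        except np.linalg.LinAlgError:
            return None
        beta = np.linalg.solve(XVX, XVy)
        rss = float(yVy - beta @ XVy)
        if rss <= 0:
            rss = _VAR_FLOOR
        logdet_v = float(np.log(det).sum())
        logdet_xvx = float(2.0 * np.log(np.diag(c)).sum())
        df = self.n - p if reml else self.n
        if reml:
            value = logdet_v + logdet_xvx + df * (np.log(rss / df) + 1.0 + _LOG2PI)
        else:
            value = logdet_v + df * (np.log(rss / df) + 1.0 + _LOG2PI)
        if want == "value":
            return value, None
        if want == "aux":
            return value, (beta, rss, XVX, M)

        BinvT = np.swapaxes(Binv, 1, 2)
        Qt = BinvT @ ZW                       # (m,2,p1): [B'^-1 Z'X, B'^-1 Z'y]
        bvec = np.concatenate([-beta, [1.0]])
        rtil = Qt @ bvec                      # (m,2)
        S = (self.A @ Binv).sum(axis=0)       # d sum log|B|
        S -= (df / rss) * (rtil.T @ rtil)     # d df*log RSS
        if reml:
            Q = Qt[:, :, :p]
            QG = Q @ np.linalg.inv(XVX)
            S -= (QG @ np.swapaxes(Q, 1, 2)).sum(axis=0)  # d log|XVX|
        return value, 0.5 * (S + S.T)

    def _neg2ll(self, psi, ystats, reml: bool) -> float:
        out = self._core(psi, ystats, reml, want="value")
        return np.inf if out is None else out[0]

    @staticmethod
    def _psi_from_theta(theta: np.ndarray, correlated: bool) -> np.ndarray:
        if correlated:
            l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
            L = np.array([[l11, 0.0], [l21, l22]])
            return L @ L.T
        d = np.exp(2.0 * np.asarray(theta))
        return np.diag(d)

    def fit(
        self,
        y: np.ndarray,
        reml: bool = True,
        correlated: bool = True,
        theta0: np.ndarray | None = None,
    ) -> LMMFit:
        """Fit the model against response ``y`` (original observation order).

        ``theta0`` warm-starts the variance-component optimizer (log-Cholesky
        scale); searches and bootstraps refitting near a known solution use it
        to skip the multi-start sweep.  A failed warm start falls back to the
        default starts.
        """
        y = np.asarray(y, dtype=float)[self.order]
        if y.shape != (self.n,):
            raise ValueError("response length mismatch")
        ystats = self._ystats(y)

        def objective(theta: np.ndarray):
            psi = self._psi_from_theta(theta, correlated)
            out = self._core(psi, ystats, reml, want="grad")
            if out is None or not np.isfinite(out[0]):
                return np.inf, np.zeros_like(theta)
            value, S = out
            if correlated:
                l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
                L = np.array([[l11, 0.0], [l21, l22]])
                dL = 2.0 * S @ L
                grad = np.array([dL[0, 0] * l11, dL[1, 0], dL[1, 1] * l22])
            else:
                d = np.exp(2.0 * np.asarray(theta))
                grad = 2.0 * np.diag(S) * d
            return value, grad

        if correlated:
            default_starts = [
                np.array([np.log(0.5), 0.0, np.log(0.5)]),
                np.array([np.log(0.02), 0.0, np.log(0.02)]),
            ]
            bounds = [(-14.0, 8.0), (-60.0, 60.0), (-14.0, 8.0)]
        else:
            default_starts = [
                np.array([np.log(0.5), np.log(0.5)]),
                np.array([np.log(0.02), np.log(0.02)]),
            ]
            bounds = [(-14.0, 8.0), (-14.0, 8.0)]
        if theta0 is not None and np.all(np.isfinite(theta0)) and len(theta0) == len(bounds):
            starts = [np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])]
        else:
            starts = default_starts

        results = []
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", jac=True, bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
            )
            if np.isfinite(res.fun):
                results.append(res)
        best = min(results, key=lambda r: r.fun) if results else None
        converged = False
        if best is not None:
            tol = 1e-6 * (1.0 + abs(best.fun))
            converged = any(r.success and r.fun <= best.fun + tol for r in results)
            if not converged:
                # an "abnormal" line-search stop at a stationary point still counts
                _, grad = objective(best.x)
                converged = bool(np.max(np.abs(grad)) <= 1e-5 * (1.0 + abs(best.fun)))
        if (best is None or not (np.isfinite(best.fun) and converged)) and len(starts) == 1:
            # warm start failed: retry the full multi-start sweep
            return self.fit(np.asarray(y)[np.argsort(self.order)], reml=reml, correlated=correlated)
        if best is None or not np.isfinite(best.fun):
            return self._failed_fit(reml)

        psi = self._psi_from_theta(best.x, correlated)
        out = self._core(psi, ystats, reml, want="aux")
        if out is None:
            return self._failed_fit(reml)
        beta, rss, XVX, M = out[1]
        df = self.n - self.p if reml else self.n
        sigma2 = max(rss / df, _VAR_FLOOR)
        cov_beta = sigma2 * np.linalg.inv(XVX)
        se = np.sqrt(np.diag(cov_beta))
        cov_re = sigma2 * psi
        loglik = -0.5 * float(best.fun)

        warn: list[str] = []
        if cov_re[1, 1] <= 10 * _VAR_FLOOR * sigma2 or psi[1, 1] <= 1e-10:
            warn.append("boundary fit: random-slope variance ~ 0")
        if cov_re[0, 0] <= 10 * _VAR_FLOOR * sigma2 or psi[0, 0] <= 1e-10:
            warn.append("boundary fit: random-intercept variance ~ 0")

        # BLUPs and conditional residuals: u_j = M_j (Z_j'y_j - Z_j'X_j beta)
        Zy = ystats[0][:, :, self.p]
        resid_fixed = y - self.X @ beta
        Zr = Zy - np.einsum("jka,a->jk", self.ZX, beta)
        u = np.einsum("jkl,jl->jk", M, Zr)
        resid = resid_fixed - np.einsum("ij,ij->i", self.Z, u[self.group_index])
        resid_out = np.empty_like(resid)
        resid_out[self.order] = resid  # back to caller's observation order

        return LMMFit(
            beta=beta,
            se=se,
            cov_re=cov_re,
            sigma_eps=float(np.sqrt(sigma2)),
            resid=resid_out,
            loglik=loglik,
            converged=converged,
            reml=reml,
            n_obs=self.n,
            n_subjects=self.m,
            two_group=self.two_group,
            ranef=u,
            theta=np.asarray(best.x),
            warnings=tuple(warn),
        )

    def _failed_fit(self, reml: bool) -> LMMFit:
        nan = float("nan")
        return LMMFit(
            beta=np.full(self.p, nan),
            se=np.full(self.p, nan),
            cov_re=np.full((2, 2), nan),
            sigma_eps=nan,
            resid=np.full(self.n, nan),
            loglik=-np.inf,
            converged=False,
            reml=reml,
            n_obs=self.n,
            n_subjects=self.m,
            two_group=self.two_group,
        )

    # -- simulation support --------------------------------------------------

    def simulate(
        self,
        beta: np.ndarray,
        cov_re: np.ndarray,
        sigma_eps: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Draw one response vector from the model on this design
        (random effects ~ N(0, cov_re), residuals ~ N(0, sigma_eps^2));
        returned in the caller's original observation order."""
        u = rng.multivariate_normal(np.zeros(2), cov_re, size=self.m)
        eps = rng.normal(0.0, sigma_eps, size=self.n)
        y = self.X @ np.asarray(beta) + np.einsum("ij,ij->i", self.Z, u[self.group_index]) + eps
        out = np.empty_like(y)
        out[self.order] = y
        return out


def _model_from_frame(frame: LongitudinalFrame) -> tuple[RandomSlopeModel, np.ndarray]:
    df = frame.frame
    model = RandomSlopeModel(
        df["subject_id"].to_numpy(), df["time"].to_numpy(), df["dx"].to_numpy()
    )
    return model, df["y"].to_numpy()


def fit_lmm(frame: LongitudinalFrame, reml: bool = True) -> LMMFit:
    """REML fit of the correlated random-intercept/slope model."""
    model, y = _model_from_frame(frame)
    if model.two_group:
        dxs = frame.frame.groupby("subject_id")["dx"].first()
        if (dxs == 1).sum() < 2 or (dxs == 0).sum() < 2:
            raise ValueError("need at least 2 subjects per cognitive group")
    return model.fit(y, reml=reml)


def group_separation(fit: LMMFit) -> float:
    """Wald t-statistic of the time x DX interaction; positive when the
    impaired group accumulates faster."""
    if not fit.two_group:
        raise ValueError("group separation requires a two-group fit")
    if not fit.converged:
        raise ValueError("group separation requires a converged fit")
    se = fit.se[3]
    if not np.isfinite(se) or se == 0:
        raise ValueError("degenerate fit: SE(beta3) is zero")
    return float(fit.beta[3] / se)


def repeatability_percent(fit: LMMFit, use_sigma_eps: bool = False) -> float:
    """Longitudinal precision: 100 x SD of the conditional residuals.

    On the log scale this approximates percent error relative to the
    biomarker value.  ``use_sigma_eps`` substitutes the estimated residual-SD
    parameter for the empirical residual SD.
    """
    if not fit.converged:
        raise ValueError("repeatability requires a converged fit")
    if use_sigma_eps:
        return 100.0 * fit.sigma_eps
    if fit.n_obs < 2:
        return 0.0
    return float(100.0 * np.std(fit.resid, ddof=1))


def lrt_random_correlation(frame: LongitudinalFrame) -> tuple[float, int, float]:
    """Likelihood-ratio test of correlated vs independent random effects.

    Both models are fitted by ML (not REML) so their likelihoods are
    comparable; returns (chi2, df=1, upper-tail p).  Near the rho=0 boundary
    the chi2(1) reference is slightly conservative.
    """
    model, y = _model_from_frame(frame)
    fit_c = model.fit(y, reml=False, correlated=True)
    fit_u = model.fit(y, reml=False, correlated=False)
    if not (fit_c.converged and fit_u.converged):
        raise ValueError("non-convergent fit in correlation test")
    chi2 = max(0.0, 2.0 * (fit_c.loglik - fit_u.loglik))
    return chi2, 1, float(stats.chi2.sf(chi2, 1))
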