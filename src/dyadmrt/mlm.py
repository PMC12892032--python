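"""REML linear mixed model for intensive longitudinal indistinguishable dyads.

The intervention-phase analysis models each person-day outcome as

    y_mjt = x_mjt' b + z_mjt' u_j + e_mjt,

with couple-level random effects ``u_j ~ N(0, G)`` (diagonal ``G``: the two
members of a couple share every random effect — partners are
indistinguishable) and residuals that follow a stationary AR(1) process with
coefficient ``phi`` within each member's day series, optionally with a
same-day cross-partner correlation ``rho``.  Estimation is REML: variance
parameters maximize the restricted likelihood (with the residual scale
profiled out analytically), fixed effects follow by GLS at the optimum.

Missing person-days are simply absent rows; because an AR(1) process is
Markov, the residual correlation across a gap of ``d`` days is ``phi**d`` and
the per-member precision stays tridiagonal, which the implementation exploits
by whitening each member series in O(T) before low-rank (Woodbury) handling
of the random effects.  With ``rho_partner_free`` the couple covariance loses
that structure and a dense per-couple factorization is used instead.

Reported degrees of freedom for fixed effects follow the containment-style
rule ``n_rows - n_couples - (n_fixed - 1)``.  Random-effect SDs carry
delta-method standard errors (from a numerical Hessian on the log-SD /
atanh-correlation scale) and lognormal-scale confidence intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess1

__all__ = ["DyadicMixedAR1", "mlm_fit", "mlm_reml_loglik"]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Stacked data container
# ---------------------------------------------------------------------------


class _Stacked:
    """Member-day series padded into rectangular arrays for vectorized REML.

    One "series" is one member's day-ordered rows within a couple.  Series
    are stored padded to the longest length with a validity mask; couples own
    contiguous runs of series (usually 2 each).
    """

    def __init__(self, work: pd.DataFrame, outcome, fixed_cols, random_cols, cluster_col):
        self.fixed_cols = fixed_cols
        self.random_cols = random_cols
        groups = []
        couple_series_count = []
        for couple, cframe in work.groupby(cluster_col, sort=True):
            n_series = 0
            for _, mframe in cframe.groupby("member", sort=True):
                mframe = mframe.sort_values("day")
                groups.append(mframe)
                n_series += 1
            couple_series_count.append(n_series)
        S = len(groups)
        T = max(len(g) for g in groups)
        p = len(fixed_cols)
        q = len(random_cols)
        self.S, self.T, self.p, self.q = S, T, p, q
        self.n_rows = sum(len(g) for g in groups)
        self.n_couples = len(couple_series_count)
        self.X = np.zeros((S, T, p))
        self.Z = np.zeros((S, T, q))
        self.y = np.zeros((S, T))
        self.gap = np.zeros((S, T), dtype=int)  # day gap to previous row; 0 on first row
        self.valid_lag = np.zeros((S, T), dtype=bool)
        self.n_valid_lags = 0
        for s, g in enumerate(groups):
            n = len(g)
            self.X[s, :n] = g[fixed_cols].to_numpy(dtype=float)
            self.Z[s, :n] = g[random_cols].to_numpy(dtype=float)
            self.y[s, :n] = g[outcome].to_numpy(dtype=float)
            days = g["day"].to_numpy(dtype=int)
            if n > 1:
                d = np.diff(days)
                if np.any(d <= 0):
                    raise ValueError("duplicate or unsorted days within a member series")
                self.gap[s, 1:n] = d
                self.valid_lag[s, 1:n] = True
        self.n_valid_lags = int(self.valid_lag.sum())
        # reduceat offsets: series index where each couple starts
        self.couple_offsets = np.concatenate([[0], np.cumsum(couple_series_count)[:-1]])

    def whiten(self, phi: float):
        """AR(1)-whiten [X Z y] per series; returns whitened arrays and log|C|.

        The transform is w_1 = x_1, w_i = (x_i - a_i x_{i-1}) / sqrt(1-a_i^2)
        with a_i = phi**gap_i, which maps an AR(1) correlation matrix over
        irregular day spacings to the identity.
        """
        a = np.where(self.valid_lag, np.power(float(phi), self.gap), 0.0)
        v = 1.0 - a * a
        sqrt_v = np.sqrt(v)
        logdet_C = np.log(v, where=self.valid_lag, out=np.zeros_like(v))[self.valid_lag].sum()

        def _apply(arr):
            out = arr.copy()
            prev = np.roll(arr, 1, axis=1)
            prev[:, 0] = 0.0
            shape = a.shape + (1,) * (arr.ndim - 2)
            out = (arr - a.reshape(shape) * prev) / sqrt_v.reshape(shape)
            return out

        return _apply(self.X), _apply(self.Z), _apply(self.y), logdet_C


def _reml_core(stacked: _Stacked, gamma2: np.ndarray, phi: float):
    """Accumulate GLS pieces under V0 = Z D Z' + C(phi), D = diag(gamma2).

    Returns (A, b, c, logdet) with A = sum X'V0^-1 X, b = sum X'V0^-1 y,
    c = sum y'V0^-1 y and logdet = sum log|V0_j| over couples.
    """
    Xw, Zw, yw, logdet_C = stacked.whiten(phi)
    q = stacked.q
    off = stacked.couple_offsets

    XtX = np.add.reduceat(np.einsum("stp,str->spr", Xw, Xw), off, axis=0).sum(axis=0)
    Xty = np.add.reduceat(np.einsum("stp,st->sp", Xw, yw), off, axis=0).sum(axis=0)
    yty = float(np.einsum("st,st->", yw, yw))
    if q == 0:
        return XtX, Xty, yty, logdet_C

    d = np.sqrt(gamma2)
    Zd = Zw * d[None, None, :]
    StS = np.add.reduceat(np.einsum("stq,str->sqr", Zd, Zd), off, axis=0)  # (J, q, q)
    U = np.add.reduceat(np.einsum("stq,stp->sqp", Zd, Xw), off, axis=0)  # (J, q, p)
    v = np.add.reduceat(np.einsum("stq,st->sq", Zd, yw), off, axis=0)  # (J, q)

    M = StS + np.eye(q)[None, :, :]
    sign, logdet_M = np.linalg.slogdet(M)
    if np.any(sign <= 0):
        bad = int(np.argmax(sign <= 0))
        raise ValueError(f"non-positive-definite couple covariance (couple block {bad})")
    Minv_U = np.linalg.solve(M, U)  # (J, q, p)
    Minv_v = np.linalg.solve(M, v[:, :, None])[:, :, 0]  # (J, q)

    A = XtX - np.einsum("jqp,jqr->pr", U, Minv_U)
    b = Xty - np.einsum("jqp,jq->p", U, Minv_v)
    c = yty - float(np.einsum("jq,jq->", v, Minv_v))
    return A, b, c, logdet_C + float(logdet_M.sum())


def _reml_core_dense(work, outcome, fixed_cols, random_cols, cluster_col, sd2, sigma2, phi, rho):
    """Dense per-couple evaluation of the unscaled pieces; supports rho != 0.

    Here V0 is the full covariance divided by sigma2 (so random-effect
    variances enter as ratios sd2/sigma2, matching :func:`_reml_core`).
    """
    A = None
    b = None
    c = 0.0
    logdet = 0.0
    gamma2 = np.asarray(sd2, dtype=float) / sigma2
    for couple, cframe in work.groupby(cluster_col, sort=True):
        cframe = cframe.sort_values(["member", "day"])
        X = cframe[fixed_cols].to_numpy(dtype=float)
        Z = cframe[random_cols].to_numpy(dtype=float) if random_cols else np.zeros((len(cframe), 0))
        y = cframe[outcome].to_numpy(dtype=float)
        members = cframe["member"].to_numpy()
        days = cframe["day"].to_numpy()
        same_member = members[:, None] == members[None, :]
        same_day = days[:, None] == days[None, :]
        C = np.where(
            same_member,
            np.power(float(phi), np.abs(days[:, None] - days[None, :])),
            np.where(same_day, float(rho), 0.0),
        )
        V0 = C + (Z * gamma2[None, :]) @ Z.T
        try:
            L = np.linalg.cholesky(V0)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"non-positive-definite covariance for couple {couple}") from err
        logdet += 2.0 * float(np.log(np.diag(L)).sum())
        Xs = np.linalg.solve(L, X)
        ys = np.linalg.solve(L, y)
        A = Xs.T @ Xs if A is None else A + Xs.T @ Xs
        b = Xs.T @ ys if b is None else b + Xs.T @ ys
        c += float(ys @ ys)
    return A, b, c, logdet


def _loglik_from_parts(A, b, c, logdet, sigma2, n, p):
    """Full REML log-likelihood from the unscaled (V0) accumulators."""
    beta = np.linalg.solve(A, b)
    rss = c - float(b @ beta)
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("singular fixed-effect information matrix")
    return -0.5 * (
        (n - p) * np.log(sigma2)
        + logdet
        + logdet_A
        + rss / sigma2
        + (n - p) * _LOG2PI
    )


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class DyadicMixedAR1(BaseEstimator):
    """Indistinguishable-dyad linear mixed model with AR(1) residuals (REML).

    Parameters
    ----------
    fixed : sequence of str
        Fixed-effect covariate columns; an intercept is always included.
    random : sequence of str
        Couple-level random-effect terms; subset of ``fixed`` plus
        ``"intercept"``.
    ar1 : bool
        Model within-member residuals as AR(1) (otherwise independent).
    rho_partner_free : bool
        Additionally estimate a same-day cross-partner residual correlation
        (uses the dense covariance path).
    one_sided : sequence of str
        Fixed terms with an upper-tailed hypothesis test.
    ci_level : float
        Confidence level for all intervals (default 0.90).
    center : sequence of str
        Fixed columns grand-mean centered over the fit's complete-case rows.

    Attributes (after fit)
    ----------------------
    fe_params_, fe_bse_, fe_tvalues_, fe_pvalues_, fe_conf_int_ : fixed effects.
    re_sd_, re_sd_se_, re_sd_z_, re_sd_conf_int_ : random-effect SDs.
    sigma_, sigma_se_, phi_, phi_se_, rho_ : residual structure.
    reml_loglik_, converged_, df_, n_rows_, n_couples_.
    """

    _START_POINTS = (
        {"gamma": 0.3, "phi": 0.0, "rho": 0.0},
        {"gamma": 0.05, "phi": 0.3, "rho": 0.0},
        {"gamma": 1.0, "phi": 0.1, "rho": 0.2},
    )

    def __init__(
        self,
        fixed=("phase", "time_c", "wear_c"),
        random=("intercept", "phase", "time_c", "wear_c"),
        ar1=True,
        rho_partner_free=False,
        one_sided=(),
        ci_level=0.90,
        center=("time_c", "wear_c"),
        cluster_col="couple",
        max_iter=500,
        tol=1e-8,
    ):
        self.fixed = fixed
        self.random = random
        self.ar1 = ar1
        self.rho_partner_free = rho_partner_free
        self.one_sided = one_sided
        self.ci_level = ci_level
        self.center = center
        self.cluster_col = cluster_col
        self.max_iter = max_iter
        self.tol = tol

    # -- data preparation -------------------------------------------------

    def _prepare(self, table, outcome):
        fixed = list(self.fixed)
        random = list(self.random)
        bad = [r for r in random if r != "intercept" and r not in fixed]
        if bad:
            raise ValueError(f"random terms must be a subset of fixed terms: {bad}")
        cols = [outcome] + fixed
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing columns: {missing}")
        work = table.dropna(subset=cols).copy()
        if work[self.cluster_col].nunique() < 3:
            raise ValueError("at least 3 couples with complete-case rows are required")
        for c in self.center:
            if c in fixed:
                work[c] = work[c] - work[c].mean()
        work["intercept"] = 1.0
        fixed_cols = ["intercept"] + fixed
        random_cols = ["intercept" if r == "intercept" else r for r in random]
        # keep random columns in fixed order for reproducibility
        random_cols = [c for c in fixed_cols if c in random_cols]
        return work, fixed_cols, random_cols

    # -- objective --------------------------------------------------------

    def _unpack(self, theta, q):
        gamma2 = np.exp(2.0 * theta[:q])
        k = q
        if self.ar1:
            phi = float(np.tanh(theta[k]))
            k += 1
        else:
            phi = 0.0
        if self.rho_partner_free:
            rho = float(np.tanh(theta[k]))
        else:
            rho = 0.0
        return gamma2, phi, rho

    def _profiled_objective(self, theta, stacked, work, outcome, fixed_cols, random_cols):
        q = len(random_cols)
        gamma2, phi, rho = self._unpack(theta, q)
        n, p = stacked.n_rows, stacked.p
        if self.rho_partner_free:
            A, b, c, logdet = _reml_core_dense(
                work, outcome, fixed_cols, random_cols, self.cluster_col,
                gamma2, 1.0, phi, rho,
            )
        else:
            A, b, c, logdet = _reml_core(stacked, gamma2, phi)
        beta = np.linalg.solve(A, b)
        rss = c - float(b @ beta)
        if rss <= 0:
            return np.inf
        sigma2 = rss / (n - p)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return (n - p) * np.log(sigma2) + logdet + logdet_A

    # -- API --------------------------------------------------------------

    def fit(self, table: pd.DataFrame, outcome: str = "y_device"):
        work, fixed_cols, random_cols = self._prepare(table, outcome)
        stacked = _Stacked(work, outcome, fixed_cols, random_cols, self.cluster_col)
        q = len(random_cols)
        n, p = stacked.n_rows, stacked.p
        dim = q + (1 if self.ar1 else 0) + (1 if self.rho_partner_free else 0)

        obj = lambda th: self._profiled_objective(
            th, stacked, work, outcome, fixed_cols, random_cols
        )

        best = None
        trace = []
        for start in self._START_POINTS:
            theta0 = np.concatenate(
                [
                    np.full(q, np.log(start["gamma"])),
                    [np.arctanh(start["phi"])] if self.ar1 else [],
                    [np.arctanh(start["rho"])] if self.rho_partner_free else [],
                ]
            )
            if dim == 0:
                best = (obj(theta0), theta0, True)
                break
            res = optimize.minimize(
                obj,
                theta0,
                method="L-BFGS-B",
                bounds=[(-16.0, 8.0)] * q + [(-5.0, 5.0)] * (dim - q),
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-7},
            )
            trace.append({"start": start, "fun": float(res.fun), "success": bool(res.success)})
            if best is None or res.fun < best[0]:
                best = (float(res.fun), res.x, bool(res.success))
        if best is None or not np.isfinite(best[0]):
            raise RuntimeError(f"REML optimization failed to converge; trace: {trace}")
        _, theta_hat, converged = best
        if not converged and not any(t["success"] for t in trace):
            raise RuntimeError(f"REML optimization did not converge from any start; trace: {trace}")

        gamma2, phi, rho = self._unpack(theta_hat, q)
        if self.rho_partner_free:
            A, b, c, logdet = _reml_core_dense(
                work, outcome, fixed_cols, random_cols, self.cluster_col, gamma2, 1.0, phi, rho
            )
        else:
            A, b, c, logdet = _reml_core(stacked, gamma2, phi)
        beta = np.linalg.solve(A, b)
        rss = c - float(b @ beta)
        sigma2 = rss / (n - p)
        sigma = float(np.sqrt(sigma2))
        re_sd = np.sqrt(gamma2 * sigma2)

        # fixed-effect inference
        fe_cov = sigma2 * np.linalg.inv(A)
        fe_se = np.sqrt(np.diag(fe_cov))
        n_couples = stacked.n_couples
        df = n - n_couples - (p - 1)
        t = beta / fe_se
        p_two = 2.0 * stats.t.sf(np.abs(t), df)
        p_upper = stats.t.sf(t, df)
        one_sided = set(self.one_sided)
        pvals = np.array(
            [p_upper[i] if fixed_cols[i] in one_sided else p_two[i] for i in range(p)]
        )
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2.0, df)
        idx = pd.Index(fixed_cols, name="term")

        # delta-method SEs for the variance components on the transformed scale
        eta_hat = np.concatenate(
            [
                np.log(np.maximum(re_sd, 1e-300)),
                [np.arctanh(phi)] if self.ar1 else [],
                [np.arctanh(rho)] if self.rho_partner_free else [],
                [np.log(sigma)],
            ]
        )

        def negloglik(eta):
            sd = np.exp(eta[:q])
            k = q
            phi_ = np.tanh(eta[k]) if self.ar1 else 0.0
            k += 1 if self.ar1 else 0
            rho_ = np.tanh(eta[k]) if self.rho_partner_free else 0.0
            k += 1 if self.rho_partner_free else 0
            sig2 = np.exp(2.0 * eta[k])
            g2 = sd**2 / sig2
            if self.rho_partner_free:
                parts = _reml_core_dense(
                    work, outcome, fixed_cols, random_cols, self.cluster_col, g2, 1.0, phi_, rho_
                )
            else:
                parts = _reml_core(stacked, g2, phi_)
            return -_loglik_from_parts(*parts, sig2, n, p)

        eta_cov = None
        try:
            H = approx_hess1(eta_hat, negloglik)
            eta_cov = np.linalg.inv(H)
            eta_se = np.sqrt(np.clip(np.diag(eta_cov), 0.0, None))
        except (np.linalg.LinAlgError, ValueError):
            eta_se = np.full(len(eta_hat), np.nan)

        zcrit = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        re_sd_se = re_sd * eta_se[:q]
        re_lo = re_sd * np.exp(-zcrit * eta_se[:q])
        re_hi = re_sd * np.exp(zcrit * eta_se[:q])
        k = q
        if self.ar1:
            phi_se = (1.0 - phi**2) * eta_se[k]
            phi_ci = tuple(np.tanh(np.arctanh(phi) + s * zcrit * eta_se[k]) for s in (-1, 1))
            k += 1
        else:
            phi_se, phi_ci = 0.0, (0.0, 0.0)
        if self.rho_partner_free:
            k += 1
        sigma_se = sigma * eta_se[k]

        ridx = pd.Index(random_cols, name="term")
        self.outcome_ = outcome
        self.fixed_cols_ = fixed_cols
        self.random_cols_ = random_cols
        self.fe_params_ = pd.Series(beta, index=idx)
        self.fe_bse_ = pd.Series(fe_se, index=idx)
        self.fe_cov_ = pd.DataFrame(fe_cov, index=idx, columns=idx)
        self.fe_tvalues_ = pd.Series(t, index=idx)
        self.fe_pvalues_ = pd.Series(pvals, index=idx)
        self.fe_conf_int_ = pd.DataFrame(
            {"lower": beta - tcrit * fe_se, "upper": beta + tcrit * fe_se}, index=idx
        )
        self.re_sd_ = pd.Series(re_sd, index=ridx)
        self.re_sd_se_ = pd.Series(re_sd_se, index=ridx)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.re_sd_z_ = pd.Series(np.where(re_sd_se > 0, re_sd / re_sd_se, np.nan), index=ridx)
        self.re_sd_conf_int_ = pd.DataFrame({"lower": re_lo, "upper": re_hi}, index=ridx)
        self.sigma_ = sigma
        self.sigma_se_ = float(sigma_se)
        self.phi_ = float(phi)
        self.phi_se_ = float(phi_se)
        self.phi_conf_int_ = phi_ci
        self.rho_ = float(rho)
        self.reml_loglik_ = float(
            _loglik_from_parts(A, b, c, logdet, sigma2, n, p)
        )
        self.df_ = int(df)
        self.n_rows_ = int(n)
        self.n_couples_ = int(n_couples)
        self.converged_ = bool(converged)
        self.opt_trace_ = trace
        self._work = work
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Population-level (random effects at zero) fitted means."""
        if not hasattr(self, "fe_params_"):
            raise ValueError("estimator is not fitted")
        out = np.full(len(table), self.fe_params_["intercept"])
        for name in self.fixed_cols_[1:]:
            out = out + self.fe_params_[name] * table[name].to_numpy(dtype=float)
        return out

    def summary(self) -> pd.DataFrame:
        """Fixed effects, random-effect SDs and residual structure in one table."""
        if not hasattr(self, "fe_params_"):
            raise ValueError("estimator is not fitted")
        one_sided = set(self.one_sided)
        fixed = pd.DataFrame(
            {
                "block": "fixed",
                "estimate": self.fe_params_,
                "se": self.fe_bse_,
                "ci_lower": self.fe_conf_int_["lower"],
                "ci_upper": self.fe_conf_int_["upper"],
                "stat": self.fe_tvalues_,
                "df": float(self.df_),
                "p": self.fe_pvalues_,
                "one_sided": [t in one_sided for t in self.fixed_cols_],
            }
        )
        rnd = pd.DataFrame(
            {
                "block": "random_sd",
                "estimate": self.re_sd_,
                "se": self.re_sd_se_,
                "ci_lower": self.re_sd_conf_int_["lower"],
                "ci_upper": self.re_sd_conf_int_["upper"],
                "stat": self.re_sd_z_,
                "df": np.nan,
                "p": 2.0 * stats.norm.sf(np.abs(self.re_sd_z_)),
                "one_sided": False,
            }
        )
        resid_rows = [
            ("residual_sd", self.sigma_, self.sigma_se_),
        ]
        if self.ar1:
            resid_rows.append(("autocorrelation", self.phi_, self.phi_se_))
        if self.rho_partner_free:
            resid_rows.append(("partner_correlation", self.rho_, np.nan))
        resid = pd.DataFrame(
            {
                "block": "residual",
                "estimate": [r[1] for r in resid_rows],
                "se": [r[2] for r in resid_rows],
                "ci_lower": np.nan,
                "ci_upper": np.nan,
                "stat": [r[1] / r[2] if r[2] and np.isfinite(r[2]) and r[2] > 0 else np.nan
                         for r in resid_rows],
                "df": np.nan,
                "p": np.nan,
                "one_sided": False,
            },
            index=pd.Index([r[0] for r in resid_rows], name="term"),
        )
        if self.ar1:
            resid.loc["autocorrelation", ["ci_lower", "ci_upper"]] = self.phi_conf_int_
        return pd.concat([fixed, rnd, resid])

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_,
            "fixed": self.fe_params_.to_dict(),
            "fixed_se": self.fe_bse_.to_dict(),
            "fixed_p": self.fe_pvalues_.to_dict(),
            "random_sd": self.re_sd_.to_dict(),
            "random_sd_se": self.re_sd_se_.to_dict(),
            "sigma": self.sigma_,
            "phi": self.phi_,
            "rho": self.rho_,
            "reml_loglik": self.reml_loglik_,
            "df": self.df_,
            "n_rows": self.n_rows_,
            "n_couples": self.n_couples_,
            "converged": self.converged_,
        }


def mlm_fit(table, outcome="y_device", **kwargs) -> DyadicMixedAR1:
    """Functional wrapper: build, fit and return a :class:`DyadicMixedAR1`."""
    return DyadicMixedAR1(**kwargs).fit(table, outcome=outcome)


def mlm_reml_loglik(
    variance_params: dict,
    table: pd.DataFrame,
    outcome: str = "y_device",
    fixed=("phase", "time_c", "wear_c"),
    random=("intercept", "phase", "time_c", "wear_c"),
    cluster_col: str = "couple",
    center=(),
    method: str = "structured",
) -> float:
    """REML log-likelihood (fixed effects profiled out) at given variance params.

    ``variance_params`` carries ``sd`` (sequence of random-effect SDs in the
    order of ``random``), ``sigma``, ``phi`` and optionally ``rho``.  The
    ``structured`` method uses the whitened/low-rank path (requires
    ``rho == 0``); ``dense`` builds each couple's covariance explicitly.
    """
    est = DyadicMixedAR1(
        fixed=fixed, random=random, cluster_col=cluster_col, center=center
    )
    work, fixed_cols, random_cols = est._prepare(table, outcome)
    sd = np.asarray(variance_params.get("sd", ()), dtype=float)
    if len(sd) != len(random_cols):
        raise ValueError(f"expected {len(random_cols)} random-effect SDs, got {len(sd)}")
    sigma = float(variance_params["sigma"])
    phi = float(variance_params.get("phi", 0.0))
    rho = float(variance_params.get("rho", 0.0))
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    sigma2 = sigma**2
    gamma2 = sd**2 / sigma2
    n = len(work)
    p = len(fixed_cols)
    if method == "structured":
        if rho != 0.0:
            raise ValueError("the structured path requires rho == 0; use method='dense'")
        stacked = _Stacked(work, outcome, fixed_cols, random_cols, cluster_col)
        parts = _reml_core(stacked, gamma2, phi)
    elif method == "dense":
        parts = _reml_core_dense(
            work, outcome, fixed_cols, random_cols, cluster_col, gamma2, 1.0, phi, rho
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(_loglik_from_parts(*parts, sigma2, n, p))
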