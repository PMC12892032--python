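"""Weighted-and-centered least squares (WCLS) for dyadic micro-randomized trials.

The proximal (causal excursion) effect of delivering versus withholding an
intervention at a decision point is estimated by least squares in which each
binary treatment indicator ``A_k`` enters *centered*, ``A_k - p_tilde_k``,
while control covariates enter uncentered, and each row is weighted by

    W = prod_k  p_tilde_k^A_k (1-p_tilde_k)^(1-A_k) / p_k^A_k (1-p_k)^(1-A_k),

the ratio of the centering probability to the actual randomization
probability.  When ``p_tilde = p`` the weights are 1 and the estimator
reduces to centered least squares.

Couples are the units of analysis: the variance is a couple-clustered
sandwich with the Mancl-DeRouen small-sample correction (couple residuals
premultiplied by ``(I - H_jj)^{-1}``), and inference uses a t reference with
``df = n_couples - n_parameters``.  Both members' person-day rows enter the
fit; partners are indistinguishable, so all outputs are invariant to
relabeling members within couples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["DyadicWCLS", "wcls_weights", "wcls_fit", "sandwich_cov"]


def wcls_weights(A, p, p_tilde):
    """Inverse-probability-ratio weight for one treatment term.

    ``W = [p_tilde^A (1-p_tilde)^(1-A)] / [p^A (1-p)^(1-A)]``; equal to 1
    whenever ``p_tilde == p``.  Degenerate randomization probabilities (0 or
    1) admit no contrast and raise.
    """
    A = np.asarray(A, dtype=float)
    p = np.broadcast_to(np.asarray(p, dtype=float), A.shape)
    p_tilde = np.broadcast_to(np.asarray(p_tilde, dtype=float), A.shape)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("randomization probability p must lie strictly in (0, 1)")
    if np.any((p_tilde <= 0.0) | (p_tilde >= 1.0)):
        raise ValueError("centering probability p_tilde must lie strictly in (0, 1)")
    num = np.where(A == 1, p_tilde, 1.0 - p_tilde)
    den = np.where(A == 1, p, 1.0 - p)
    w = num / den
    if np.isscalar(A) or w.shape == ():
        return float(w)
    return w


def sandwich_cov(X, resid, weights, cluster_ids, correction="mancl_derouen"):
    """Cluster-robust sandwich covariance ``B^-1 M B^-1`` for a WLS fit.

    ``M`` sums outer products of cluster-level weighted score contributions;
    with ``correction='mancl_derouen'`` each cluster's residual vector is
    premultiplied by ``(I - H_jj)^{-1}`` before entering the score, which
    removes the first-order downward bias of the uncorrected estimator with
    few clusters.
    """
    X = np.asarray(X, dtype=float)
    resid = np.asarray(resid, dtype=float)
    weights = np.asarray(weights, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    if correction not in ("none", "mancl_derouen"):
        raise ValueError(f"unknown correction {correction!r}")
    bread = X.T @ (weights[:, None] * X)
    try:
        bread_inv = np.linalg.inv(bread)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular bread matrix (collinear design)") from err
    meat = np.zeros_like(bread)
    for cid in pd.unique(cluster_ids):
        idx = cluster_ids == cid
        Xj = X[idx]
        wj = weights[idx]
        ej = resid[idx]
        if correction == "mancl_derouen":
            Hjj = Xj @ bread_inv @ Xj.T @ np.diag(wj)
            ej = np.linalg.solve(np.eye(len(ej)) - Hjj, ej)
        Uj = Xj.T @ (wj * ej)
        meat += np.outer(Uj, Uj)
    return bread_inv @ meat @ bread_inv


class DyadicWCLS(BaseEstimator):
    """Dyadic weighted-and-centered least-squares proximal-effect estimator.

    Parameters
    ----------
    treatments : dict
        Maps treatment indicator column names to their centering
        probabilities ``p_tilde`` (strictly inside (0, 1)).
    controls : sequence of str
        Control covariate columns (entered uncentered; an intercept is always
        prepended).  Controls listed in ``center`` are grand-mean centered
        over the fit's complete-case rows.
    prob : dict or None
        Randomization probability per treatment term: a scalar or the name
        of a per-row probability column.  Defaults to the centering
        probability (unit weights).
    one_sided : sequence of str
        Coefficients tested upper-tailed (hypothesized positive effects);
        everything else is two-tailed.
    ci_level : float
        Confidence level of the reported intervals (default 0.90, as in the
        trial's result tables).
    correction : {"mancl_derouen", "none"}
        Small-sample correction of the couple-clustered sandwich.
    center : sequence of str or None
        Controls to grand-mean center over the analysis rows; ``None``
        centers every control.

    Attributes (after fit)
    ----------------------
    params_, bse_, tvalues_, pvalues_ : pandas Series per coefficient.
    vcov_ : DataFrame, couple-clustered (corrected) covariance.
    conf_int_ : DataFrame with ``lower``/``upper`` at ``ci_level``.
    df_, n_couples_, n_rows_ : inference bookkeeping.
    """

    def __init__(
        self,
        treatments=None,
        controls=("time_c",),
        prob=None,
        one_sided=(),
        ci_level=0.90,
        correction="mancl_derouen",
        center=None,
        cluster_col="couple",
    ):
        self.treatments = treatments
        self.controls = controls
        self.prob = prob
        self.one_sided = one_sided
        self.ci_level = ci_level
        self.correction = correction
        self.center = center
        self.cluster_col = cluster_col

    # -- internals --------------------------------------------------------

    def _resolve_prob(self, table, name, p_tilde):
        prob = self.prob or {}
        p = prob.get(name, p_tilde)
        if isinstance(p, str):
            return table[p].to_numpy(dtype=float)
        return float(p)

    def _design(self, table, outcome):
        treatments = dict(self.treatments or {})
        if not treatments:
            raise ValueError("at least one treatment term is required")
        controls = list(self.controls)
        cols = [outcome, self.cluster_col] + controls + list(treatments)
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing columns: {missing}")

        all_couples = set(table[self.cluster_col].unique())
        work = table.dropna(subset=[outcome] + controls + list(treatments)).copy()
        kept = set(work[self.cluster_col].unique())
        dropped = all_couples - kept
        if dropped:
            warnings.warn(
                f"couples with no complete-case rows dropped: {sorted(dropped)}",
                stacklevel=3,
            )
        if work[self.cluster_col].nunique() < 2:
            raise ValueError("at least 2 couples with complete-case rows are required")

        center = list(controls) if self.center is None else [c for c in self.center if c in controls]
        for c in center:
            work[c] = work[c] - work[c].mean()

        names = ["intercept"] + controls
        X_parts = [np.ones(len(work))] + [work[c].to_numpy(dtype=float) for c in controls]
        weights = np.ones(len(work))
        for name, p_tilde in treatments.items():
            if not 0.0 < p_tilde < 1.0:
                raise ValueError(f"centering probability for {name!r} must be in (0, 1)")
            A = work[name].to_numpy(dtype=float)
            if not np.isin(A, (0.0, 1.0)).all():
                raise ValueError(f"treatment column {name!r} is not binary")
            p = self._resolve_prob(work, name, p_tilde)
            weights = weights * wcls_weights(A, p, p_tilde)
            X_parts.append(A - p_tilde)
            names.append(name)
        X = np.column_stack(X_parts)

        variances = X.var(axis=0)
        keep = (variances >= 1e-12) | (np.arange(X.shape[1]) == 0)
        if not keep.all():
            dropped_cols = [n for n, k in zip(names, keep) if not k]
            warnings.warn(f"dropping zero-variance columns: {dropped_cols}", stacklevel=3)
            X = X[:, keep]
            names = [n for n, k in zip(names, keep) if k]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, R = np.linalg.qr(X)
            bad = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8 * abs(R).max()]
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
        return work, X, names, weights

    # -- API --------------------------------------------------------------

    def fit(self, table: pd.DataFrame, outcome: str = "y_device"):
        work, X, names, weights = self._design(table, outcome)
        y = work[outcome].to_numpy(dtype=float)
        clusters = work[self.cluster_col].to_numpy()

        XtW = X.T * weights
        beta = np.linalg.solve(XtW @ X, XtW @ y)
        resid = y - X @ beta
        vcov = sandwich_cov(X, resid, weights, clusters, self.correction)

        n_couples = len(pd.unique(clusters))
        df = n_couples - len(names)
        if df <= 0:
            raise ValueError(
                f"non-positive residual df: {n_couples} couples for {len(names)} parameters"
            )
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        p_two = 2.0 * stats.t.sf(np.abs(t), df)
        p_upper = stats.t.sf(t, df)
        one_sided = set(self.one_sided)
        pvals = np.array(
            [p_upper[i] if names[i] in one_sided else p_two[i] for i in range(len(names))]
        )
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2.0, df)

        idx = pd.Index(names, name="term")
        self.outcome_ = outcome
        self.term_names_ = names
        self.params_ = pd.Series(beta, index=idx)
        self.bse_ = pd.Series(se, index=idx)
        self.tvalues_ = pd.Series(t, index=idx)
        self.pvalues_ = pd.Series(pvals, index=idx)
        self.vcov_ = pd.DataFrame(vcov, index=idx, columns=idx)
        self.conf_int_ = pd.DataFrame(
            {"lower": beta - tcrit * se, "upper": beta + tcrit * se}, index=idx
        )
        self.df_ = df
        self.n_couples_ = n_couples
        self.n_rows_ = len(work)
        self.weights_ = weights
        self._X_columns = names
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Fitted mean outcome for new rows (treatments entered centered)."""
        if not hasattr(self, "params_"):
            raise ValueError("estimator is not fitted")
        treatments = dict(self.treatments or {})
        out = np.full(len(table), self.params_["intercept"])
        for name in self.term_names_[1:]:
            if name in treatments:
                out = out + self.params_[name] * (
                    table[name].to_numpy(dtype=float) - treatments[name]
                )
            else:
                out = out + self.params_[name] * table[name].to_numpy(dtype=float)
        return out

    def summary(self) -> pd.DataFrame:
        """Result table in the trial report layout: estimate, SE, CI, t, df, p."""
        if not hasattr(self, "params_"):
            raise ValueError("estimator is not fitted")
        one_sided = set(self.one_sided)
        return pd.DataFrame(
            {
                "estimate": self.params_,
                "se": self.bse_,
                "ci_lower": self.conf_int_["lower"],
                "ci_upper": self.conf_int_["upper"],
                "t": self.tvalues_,
                "df": self.df_,
                "p": self.pvalues_,
                "one_sided": [name in one_sided for name in self.term_names_],
            }
        )

    def to_dict(self) -> dict:
        """JSON-serializable fit record."""
        return {
            "outcome": self.outcome_,
            "estimates": self.params_.to_dict(),
            "se": self.bse_.to_dict(),
            "ci_level": self.ci_level,
            "ci_lower": self.conf_int_["lower"].to_dict(),
            "ci_upper": self.conf_int_["upper"].to_dict(),
            "t": self.tvalues_.to_dict(),
            "df": self.df_,
            "p": self.pvalues_.to_dict(),
            "n_couples": self.n_couples_,
            "n_rows": self.n_rows_,
        }


def wcls_fit(
    table,
    outcome="y_device",
    treatments=None,
    controls=("time_c",),
    prob=None,
    one_sided=(),
    ci_level=0.90,
    correction="mancl_derouen",
    center=None,
) -> DyadicWCLS:
    """Functional wrapper: build, fit and return a :class:`DyadicWCLS`."""
    est = DyadicWCLS(
        treatments=treatments,
        controls=controls,
        prob=prob,
        one_sided=one_sided,
        ci_level=ci_level,
        correction=correction,
        center=center,
    )
    return est.fit(table, outcome=outcome)
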