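"""Random-intercept linear mixed models via profiled REML.

The model is

    y = X beta + Z u + e,   u ~ N(0, sigma_u^2 I_q),   e ~ N(0, sigma_e^2 I_n)

with Z the group (study-site) indicator matrix.  Writing theta =
sigma_u^2 / sigma_e^2, the marginal covariance is sigma_e^2 (I + theta
Z Z'), which is block diagonal with per-group blocks I + theta J.  Those
blocks invert in closed form, so for any theta the GLS fixed effects and
the profiled residual variance are analytic, and fitting reduces to a
one-dimensional bounded search over theta.  REML (the default) maximizes
the residual likelihood; ML is available for likelihood comparisons.

Inference on the fixed effects uses t statistics with containment-style
degrees of freedom n_obs - n_groups - (p - 1), the convention classical
mixed-model software applies to between-group predictors.

The search over theta is reparameterized as t = theta / (1 + theta) in
[0, 1) and solved by bounded Brent minimization with the boundary theta=0
checked explicitly; with deterministic starts and tolerances the fit is
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["RandomInterceptLM", "RandomInterceptLMResults"]

_LOG2PI = float(np.log(2.0 * np.pi))


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    # pivoted QR exposes which columns are (numerically) aliased
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise ValueError(f"design matrix is rank deficient; aliased columns: {bad}")


class RandomInterceptLM:
    """Linear mixed model with a single random intercept per group.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response.
    exog : array-like, shape (n, p)
        Fixed-effect design matrix, including the intercept column.
    groups : array-like, shape (n,)
        Group labels (the random-intercept factor, e.g. study site).
    exog_names : list of str, optional
        Column names for reporting; defaults to x0..x{p-1}.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        groups = np.asarray(groups)
        if not (len(y) == X.shape[0] == len(groups)):
            raise ValueError("endog, exog and groups must have matching length")
        if not np.isfinite(y).all() or not np.isfinite(X).all():
            raise ValueError("non-finite values in endog/exog")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )
        if len(self.exog_names) != X.shape[1]:
            raise ValueError("exog_names length mismatch")
        _check_full_rank(X, self.exog_names)
        # sort observations by group so blocks are contiguous
        labels, inverse = np.unique(groups, return_inverse=True)
        order = np.argsort(inverse, kind="stable")
        self.endog = y[order]
        self.exog = X[order]
        self._group_idx = inverse[order]
        self.group_labels = labels
        self.n_obs = len(y)
        self.n_groups = len(labels)
        if self.n_groups < 2:
            raise ValueError("need at least two groups for a random intercept")
        self._group_sizes = np.bincount(self._group_idx)
        self._group_slices = np.concatenate([[0], np.cumsum(self._group_sizes)])

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, predictors: list[str], group: str,
        *, add_intercept: bool = True,
    ) -> "RandomInterceptLM":
        cols = [response, *predictors, group]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"columns not in data: {missing}")
        X = data[list(predictors)].to_numpy(dtype=float)
        names = list(predictors)
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["(Intercept)", *names]
        return cls(data[response], X, data[group], exog_names=names)

    # -- profiled likelihood ------------------------------------------

    def _gls_pieces(self, theta: float):
        """X'V*^-1 X, X'V*^-1 y, y'V*^-1 y and log|V*| for V* = I + theta ZZ'."""
        X, y = self.exog, self.endog
        xtx = X.T @ X
        xty = X.T @ y
        yty = float(y @ y)
        logdet = 0.0
        for g in range(self.n_groups):
            lo, hi = self._group_slices[g], self._group_slices[g + 1]
            ni = hi - lo
            c = theta / (1.0 + ni * theta)
            xs = X[lo:hi].sum(axis=0)
            ys = float(y[lo:hi].sum())
            xtx -= c * np.outer(xs, xs)
            xty -= c * xs * ys
            yty -= c * ys * ys
            logdet += np.log1p(ni * theta)
        return xtx, xty, yty, logdet

    def _profile(self, theta: float, reml: bool):
        xtx, xty, yty, logdet = self._gls_pieces(theta)
        beta = np.linalg.solve(xtx, xty)
        q = max(yty - float(xty @ beta), 1e-300)  # residual quadratic form
        n, p = self.n_obs, self.exog.shape[1]
        if reml:
            dof = n - p
            sigma2 = q / dof
            sign, logdet_xtx = np.linalg.slogdet(xtx)
            crit = dof * (_LOG2PI + np.log(sigma2)) + logdet + logdet_xtx + dof
        else:
            sigma2 = q / n
            crit = n * (_LOG2PI + np.log(sigma2)) + logdet + n
        return crit, beta, sigma2, xtx

    def profile_criterion(self, theta: float, *, reml: bool = True) -> float:
        """-2 x profiled (restricted) log-likelihood at variance ratio theta."""
        return self._profile(theta, reml)[0]

    def _optimize(self, reml: bool):
        # search over t = theta/(1+theta) in [0, 1); boundary theta=0 checked
        def obj(t):
            return self._profile(t / (1.0 - t), reml)[0]

        res = optimize.minimize_scalar(
            obj, bounds=(0.0, 1.0 - 1e-10), method="bounded",
            options={"xatol": 1e-12},
        )
        t_hat = float(res.x)
        theta_hat = t_hat / (1.0 - t_hat)
        crit = float(res.fun)
        crit0 = self.profile_criterion(0.0, reml=reml)
        if crit0 <= crit + 1e-10:
            theta_hat, crit = 0.0, crit0
        return theta_hat, crit, bool(res.success)

    def fit(self, *, reml: bool = True, df_rule: str = "containment"):
        """Estimate the model; returns :class:`RandomInterceptLMResults`."""
        theta_reml, crit_reml, ok_reml = self._optimize(True)
        theta_ml, crit_ml, ok_ml = self._optimize(False)
        theta = theta_reml if reml else theta_ml
        converged = ok_reml if reml else ok_ml
        _, beta, sigma2, xtx = self._profile(theta, reml)
        cov = sigma2 * np.linalg.inv(xtx)
        bse = np.sqrt(np.diag(cov))
        n, p = self.n_obs, self.exog.shape[1]
        if df_rule == "containment":
            df = n - self.n_groups - (p - 1)
        elif df_rule == "residual":
            df = n - p
        else:
            raise ValueError(f"unknown df rule {df_rule!r}")
        if df <= 0:
            raise ValueError("no residual degrees of freedom for t-tests")
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        if not converged:
            raise RuntimeError("variance-ratio optimization did not converge")
        return RandomInterceptLMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            tvalues=pd.Series(tvals, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            df_t=int(df),
            cov_params=pd.DataFrame(
                cov, index=self.exog_names, columns=self.exog_names
            ),
            scale=float(sigma2),
            group_var=float(theta * sigma2),
            llf_reml=-0.5 * crit_reml,
            llf_ml=-0.5 * crit_ml,
            reml=reml,
            converged=converged,
        )


@dataclass
class RandomInterceptLMResults:
    """Fitted random-intercept model: estimates, uncertainty, diagnostics."""

    model: RandomInterceptLM
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_t: int
    cov_params: pd.DataFrame
    scale: float  # residual variance sigma_e^2
    group_var: float  # random-intercept variance sigma_u^2
    llf_reml: float
    llf_ml: float
    reml: bool
    converged: bool
    _blups: pd.Series | None = field(default=None, repr=False)

    @property
    def resid_sd(self) -> float:
        return float(np.sqrt(self.scale))

    @property
    def group_sd(self) -> float:
        return float(np.sqrt(self.group_var))

    @property
    def llf(self) -> float:
        return self.llf_reml if self.reml else self.llf_ml

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_groups(self) -> int:
        return self.model.n_groups

    def random_effects(self) -> pd.Series:
        """BLUPs of the group intercepts, shrunk toward zero."""
        if self._blups is None:
            m = self.model
            resid = m.endog - m.exog @ self.params.to_numpy()
            theta = self.group_var / self.scale if self.scale > 0 else 0.0
            vals = []
            for g in range(m.n_groups):
                lo, hi = m._group_slices[g], m._group_slices[g + 1]
                ni = hi - lo
                shrink = ni * theta / (1.0 + ni * theta)
                vals.append(shrink * resid[lo:hi].mean())
            object.__setattr__(
                self, "_blups", pd.Series(vals, index=m.group_labels)
            )
        return self._blups

    def fittedvalues(self, *, include_random: bool = True) -> np.ndarray:
        m = self.model
        fv = m.exog @ self.params.to_numpy()
        if include_random:
            fv = fv + self.random_effects().to_numpy()[m._group_idx]
        return fv

    def resid(self) -> np.ndarray:
        """Conditional residuals (observed minus fitted incl. BLUPs)."""
        return self.model.endog - self.fittedvalues()

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, t, df, p per fixed effect."""
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "df": self.df_t,
                "p": self.pvalues,
            }
        ).rename_axis("term")

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model "
            f"({'REML' if self.reml else 'ML'})",
            f"  obs: {self.n_obs}   groups: {self.n_groups}   "
            f"logLik(REML): {self.llf_reml:.3f}   logLik(ML): {self.llf_ml:.3f}",
            f"  random-intercept SD: {self.group_sd:.6g}   "
            f"residual SD: {self.resid_sd:.6g}",
            "",
            f"  {'term':<22}{'estimate':>12}{'SE':>11}{'t':>9}"
            f"{'df':>6}{'p':>10}",
        ]
        for name in self.params.index:
            p = self.pvalues[name]
            lines.append(
                f"  {name:<22}{self.params[name]:>12.5g}{self.bse[name]:>11.4g}"
                f"{self.tvalues[name]:>9.3f}{self.df_t:>6d}"
                f"{'<0.001' if p < 0.001 else format(p, '.3f'):>10}"
            )
        return "\n".join(lines)
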