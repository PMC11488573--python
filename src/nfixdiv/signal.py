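"""Pagel's lambda: phylogenetic signal in a continuous tip trait.

Under Brownian motion a trait's covariance between two tips equals the
depth of their most recent common ancestor (times a rate sigma^2).
Pagel's lambda relaxes this by multiplying all *off-diagonal* covariances
by lambda in [0, 1]: lambda = 1 recovers Brownian motion, lambda = 0
leaves independent tip values (no signal).  The trait is modeled as

    y ~ Normal(mu 1, sigma^2 C(lambda)),

with mu and sigma^2 profiled out analytically, so the fit is a
one-dimensional search over lambda.  Significance is a likelihood-ratio
test against lambda = 0 on chi-square with 1 df; when the estimate is at
the lambda = 0 boundary the p-value is 1 by convention.

Here the trait is typically a species' loss or gain probability across
plots, or its net occupancy change — high lambda would mean whole
N-fixer clades are consistently lost or gained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import Phylogeny

__all__ = ["PagelLambda", "PagelLambdaResults", "brownian_covariance"]


def brownian_covariance(tree: Phylogeny, taxa=None) -> pd.DataFrame:
    """Brownian-motion covariance among tips: C_ij = depth of MRCA(i, j).

    Derived from depths and patristic distances:
    depth(mrca) = (depth_i + depth_j - d_ij) / 2.
    """
    labels = tree._require_tips(taxa) if taxa is not None else tree.tip_labels
    D = tree.patristic_distances().loc[labels, labels].to_numpy()
    depth = tree.tip_depths()[labels].to_numpy()
    C = 0.5 * (depth[:, None] + depth[None, :] - D)
    return pd.DataFrame(C, index=labels, columns=labels)


@dataclass(frozen=True)
class PagelLambdaResults:
    """Maximum-likelihood lambda with its likelihood-ratio test."""

    trait: str
    lambda_hat: float
    llf: float  # log-likelihood at lambda_hat
    llf0: float  # log-likelihood at lambda = 0
    lrt: float
    pvalue: float
    n_tips: int
    degenerate: bool  # star phylogeny: likelihood flat in lambda

    def summary(self) -> str:
        return (
            f"Pagel's lambda for {self.trait!r} ({self.n_tips} tips)\n"
            f"  lambda = {self.lambda_hat:.6g}"
            + ("  [degenerate: star phylogeny]" if self.degenerate else "")
            + f"\n  logLik = {self.llf:.4f}   logLik(lambda=0) = {self.llf0:.4f}\n"
            f"  LRT = {self.lrt:.4f}   P = {self.pvalue:.4g}"
        )


class PagelLambda:
    """Model object for a single tip trait on a fixed tree.

    Parameters
    ----------
    tree : Phylogeny
        Dated tree whose tips carry the trait.
    trait : pandas.Series
        Trait values indexed by tip label.  Must cover >= 4 tips of the
        tree; tips absent from the series are dropped from the tree's
        covariance (species never scored do not constrain lambda).
    name : str, optional
        Trait name for reporting.
    """

    def __init__(self, tree: Phylogeny, trait: pd.Series, name: str | None = None):
        trait = pd.Series(trait).astype(float)
        labels = tree._require_tips(trait.index)
        trait.index = labels
        if trait.isna().any() or not np.isfinite(trait).all():
            raise ValueError("trait contains missing or non-finite values")
        if len(trait) < 4:
            raise ValueError("need at least 4 tips to estimate lambda")
        if float(trait.max() - trait.min()) == 0.0:
            raise ValueError("constant trait: lambda is unidentifiable")
        self.name = name or (trait.name or "trait")
        self.trait = trait
        C = brownian_covariance(tree, labels).to_numpy()
        if np.any(np.diag(C) <= 0):
            raise ValueError("tree must have positive root-to-tip depths")
        self._C = C
        self._y = trait.to_numpy()

    def loglik(self, lam: float) -> float:
        """Profiled log-likelihood at a given lambda in [0, 1]."""
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        C = self._C * lam
        np.fill_diagonal(C, np.diag(self._C))
        n = len(self._y)
        L = np.linalg.cholesky(C)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        z = np.linalg.solve(L, self._y)
        one = np.linalg.solve(L, np.ones(n))
        mu = float(one @ z) / float(one @ one)
        r = z - mu * one
        sigma2 = float(r @ r) / n
        return -0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)

    def fit(self) -> PagelLambdaResults:
        offdiag = self._C - np.diag(np.diag(self._C))
        degenerate = float(np.abs(offdiag).max()) <= 1e-12 * np.abs(self._C).max()
        llf0 = self.loglik(0.0)
        if degenerate:
            warnings.warn(
                "star phylogeny: likelihood is flat in lambda; reporting 0",
                stacklevel=2,
            )
            return PagelLambdaResults(
                trait=self.name, lambda_hat=0.0, llf=llf0, llf0=llf0,
                lrt=0.0, pvalue=1.0, n_tips=len(self._y), degenerate=True,
            )
        res = optimize.minimize_scalar(
            lambda l: -self.loglik(l), bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-10},
        )
        candidates = [(0.0, llf0), (1.0, self.loglik(1.0)),
                      (float(res.x), float(-res.fun))]
        lam_hat, llf = max(candidates, key=lambda c: c[1])
        lrt = max(2.0 * (llf - llf0), 0.0)
        pvalue = 1.0 if lam_hat == 0.0 or lrt == 0.0 else float(
            stats.chi2.sf(lrt, df=1)
        )
        return PagelLambdaResults(
            trait=self.name, lambda_hat=lam_hat, llf=llf, llf0=llf0,
            lrt=lrt, pvalue=pvalue, n_tips=len(self._y), degenerate=False,
        )


def simulate_brownian_trait(
    tree: Phylogeny, rng: np.random.Generator, *, sigma2: float = 1.0, taxa=None
) -> pd.Series:
    """Draw one Brownian-motion trait realization on the tree's tips."""
    C = brownian_covariance(tree, taxa)
    L = np.linalg.cholesky(C.to_numpy() + 1e-12 * np.eye(len(C)))
    y = L @ rng.standard_normal(len(C)) * np.sqrt(sigma2)
    return pd.Series(y, index=C.index, name="brownian")
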