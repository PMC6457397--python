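"""Phylogenetic generalized least squares under Brownian-motion covariance.

Genome size (or any response) is regressed on genome-content predictors with
residual covariance proportional to the Brownian tree covariance C, where
C[i, j] is the shared root-to-MRCA path length of species i and j.  Each
predictor is fitted in its own simple regression by default (one panel per
predictor); a multiple-regression mode is available.

    beta_hat = (X' C^-1 X)^-1 X' C^-1 y
    sigma2_hat = (y - X beta_hat)' C^-1 (y - X beta_hat) / (n - p)
    SE = sqrt(diag(sigma2_hat (X' C^-1 X)^-1)),  t = beta_hat / SE,
    two-sided p from Student t with n - p degrees of freedom.

On a star tree with equal depths C is proportional to the identity and the
fit coincides with ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .trees import Phylo

__all__ = ["bm_covariance", "pgls_fit", "PGLSFit", "PGLSReport"]


def bm_covariance(tree: Phylo, species: Sequence[str]) -> np.ndarray:
    """Brownian covariance matrix: C[i, j] = root-to-MRCA(i, j) path length."""
    leaves = {l.label: l for l in tree.leaves()}
    missing = [s for s in species if s not in leaves]
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    depths = tree.depths()
    # ancestor chains with cumulative depths
    chains = {}
    for s in species:
        chain = {}
        node = leaves[s]
        while node is not None:
            chain[id(node)] = depths[node]
            node = node.parent
        chains[s] = chain
    n = len(species)
    C = np.zeros((n, n))
    for i, a in enumerate(species):
        C[i, i] = depths[leaves[a]]
        for j in range(i + 1, n):
            b = species[j]
            node = leaves[b]
            while id(node) not in chains[a]:
                node = node.parent
            C[i, j] = C[j, i] = depths[node]
    return C


@dataclass
class PGLSFit:
    """One fitted regression (simple or multiple)."""

    predictors: tuple[str, ...]
    coef: np.ndarray  # intercept first
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    n: int
    df_resid: int
    loglik: float

    def summary_rows(self) -> list[dict]:
        names = ("intercept",) + self.predictors
        return [
            {
                "term": name,
                "coef": float(self.coef[i]),
                "se": float(self.se[i]),
                "t": float(self.t[i]),
                "p": float(self.p[i]),
            }
            for i, name in enumerate(names)
        ]


@dataclass
class PGLSReport:
    """Per-predictor simple-regression fits (the default analysis mode)."""

    fits: dict[str, PGLSFit]
    response: str
    n: int
    dropped_species: tuple[str, ...] = ()

    def table(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            rows.append(
                {
                    "predictor": name,
                    "coef": float(fit.coef[1]),
                    "se": float(fit.se[1]),
                    "t": float(fit.t[1]),
                    "p": float(fit.p[1]),
                    "significant": bool(fit.p[1] < alpha),
                    "n": fit.n,
                }
            )
        return pd.DataFrame(rows)


def _gls(y: np.ndarray, X: np.ndarray, C: np.ndarray, names) -> PGLSFit:
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"n = {n} too small for {p} coefficients")
    try:
        cho = linalg.cho_factor(C)
    except linalg.LinAlgError as e:
        raise ValueError(f"singular Brownian covariance matrix: {e}") from e
    Ci_X = linalg.cho_solve(cho, X)
    Ci_y = linalg.cho_solve(cho, y)
    XtCiX = X.T @ Ci_X
    try:
        XtCiX_inv = np.linalg.inv(XtCiX)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular design matrix (columns {names}): {e}") from e
    beta = XtCiX_inv @ (X.T @ Ci_y)
    resid = y - X @ beta
    Ci_r = linalg.cho_solve(cho, resid)
    df = n - p
    sigma2 = float(resid @ Ci_r) / df
    se = np.sqrt(np.clip(sigma2 * np.diag(XtCiX_inv), 0, None))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    logdet = 2 * np.sum(np.log(np.diag(cho[0])))
    mle_var = float(resid @ Ci_r) / n
    loglik = -0.5 * (n * np.log(2 * np.pi * mle_var) + logdet + n)
    return PGLSFit(
        predictors=tuple(names),
        coef=beta,
        se=se,
        t=tvals,
        p=pvals,
        sigma2=sigma2,
        n=n,
        df_resid=df,
        loglik=loglik,
    )


def pgls_fit(
    traits: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    tree: Phylo,
    multiple: bool = False,
) -> PGLSReport | PGLSFit:
    """Fit PGLS of ``response`` on ``predictors`` under Brownian covariance.

    ``traits`` is indexed by species (or has a ``species`` column).  Species
    with missing values in the fitted columns are dropped with a warning.
    By default each predictor is fitted in its own simple regression and a
    :class:`PGLSReport` is returned; with ``multiple=True`` a single joint
    fit is returned instead.
    """
    df = traits.copy()
    if "species" in df.columns:
        df = df.set_index("species")
    cols = [response] + list(predictors)
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"trait table missing columns {missing_cols}")
    in_tree = df.index.intersection(tree.leaf_labels())
    complete = df.loc[in_tree, cols].dropna()
    dropped = tuple(sorted(set(df.index) - set(complete.index)))
    if dropped:
        warnings.warn(f"dropping species with missing data or not in tree: {dropped}")
    species = sorted(complete.index)
    complete = complete.loc[species]
    C = bm_covariance(tree, species)
    y = complete[response].to_numpy(float)
    if multiple:
        X = np.column_stack(
            [np.ones(len(species))] + [complete[p].to_numpy(float) for p in predictors]
        )
        return _gls(y, X, C, tuple(predictors))
    fits = {}
    for pred in predictors:
        X = np.column_stack([np.ones(len(species)), complete[pred].to_numpy(float)])
        fits[pred] = _gls(y, X, C, (pred,))
    return PGLSReport(fits=fits, response=response, n=len(species), dropped_species=dropped)
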