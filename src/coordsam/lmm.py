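"""Linear mixed models with crossed random effects.

Fits  y = X beta + Z b + e  where b collects independent random-effect
vectors for the levels of one or more *crossed* grouping factors (here:
targets and perceivers), each with an unstructured covariance
``sigma^2 * Lambda_f Lambda_f'`` within its factor.  Estimation profiles
beta and sigma^2 out of the (RE)ML criterion and optimizes only the
relative Cholesky factors Lambda_f, using the penalized-least-squares
identities standard for this model class:

    L L'   = Lambda' Z'Z Lambda + I
    RZX    = L^{-1} Lambda' Z'X
    RX'RX  = X'X - RZX'RZX
    c_u    = L^{-1} Lambda' Z'y
    c_beta = RX'^{-1} (X'y - RZX' c_u)
    pwrss  = y'y - |c_u|^2 - |c_beta|^2

    REML deviance = log|L|^2 + log|RX|^2 + (n-p) [1 + log(2 pi pwrss/(n-p))]
    ML   deviance = log|L|^2 +              n   [1 + log(2 pi pwrss/n)]

Everything is computed from cross-products accumulated once per dataset,
so each deviance evaluation costs one dense Cholesky of a q x q matrix
(q = total number of random effects), independent of the row count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.stats import norm

__all__ = ["RandomFactor", "LMMResult", "CrossedLMM", "RankDeficientError"]


class RankDeficientError(ValueError):
    """Raised when the fixed-effect design is rank deficient; names the columns."""


@dataclass
class RandomFactor:
    """One crossed grouping factor with its per-row random-effect regressors."""

    name: str
    codes: np.ndarray  # int level code per row
    levels: np.ndarray  # level labels, position = code
    design: np.ndarray  # (n_rows, q_f) regressors, e.g. [1, D, N]
    term_names: list[str]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def q(self) -> int:
        return self.design.shape[1]


@dataclass
class LMMResult:
    fe_params: pd.Series
    fe_cov: pd.DataFrame
    sigma2: float
    re_cov: dict[str, pd.DataFrame]  # factor -> q_f x q_f covariance matrix
    ranef: dict[str, pd.DataFrame]  # factor -> conditional modes per level
    theta: np.ndarray
    deviance: float
    reml: bool
    converged: bool
    n_obs: int
    n_fixed: int

    @property
    def fe_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.fe_cov)), index=self.fe_params.index)

    @property
    def fe_z(self) -> pd.Series:
        return self.fe_params / self.fe_se

    @property
    def fe_p(self) -> pd.Series:
        return pd.Series(
            2.0 * norm.sf(np.abs(self.fe_z.to_numpy())), index=self.fe_params.index
        )

    def re_sd(self, factor: str, term: str) -> float:
        """Standard deviation of one random-effect term."""
        c = self.re_cov[factor]
        return float(np.sqrt(c.loc[term, term]))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.fe_params,
                "se": self.fe_se,
                "z": self.fe_z,
                "p": self.fe_p,
            }
        )


def _tri_indices(q: int) -> tuple[np.ndarray, np.ndarray]:
    """Column-major lower-triangle indices (diagonal first within a column)."""
    rows, cols = [], []
    for j in range(q):
        for i in range(j, q):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


class CrossedLMM:
    """Profiled (RE)ML for a Gaussian LMM with crossed unstructured factors."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        factors: list[RandomFactor],
        fe_names: list[str],
        reml: bool = True,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.n, self.p = X.shape
        self.fe_names = list(fe_names)
        self.factors = factors
        self.reml = reml
        self.XtX = X.T @ X
        self._check_full_rank()
        self.Xty = X.T @ y
        self.yty = float(y @ y)

        # sparse Z, column blocks ordered factor by factor, level-major
        blocks, offset = [], 0
        self.offsets = []
        for f in factors:
            rows = np.repeat(np.arange(self.n), f.q)
            cols = (f.codes[:, None] * f.q + np.arange(f.q)[None, :]).ravel()
            data = f.design.ravel()
            blocks.append(
                sp.csr_matrix((data, (rows, cols)), shape=(self.n, f.n_levels * f.q))
            )
            self.offsets.append(offset)
            offset += f.n_levels * f.q
        self.q_total = offset
        Z = sp.hstack(blocks, format="csr")
        self.ZtZ = np.asarray((Z.T @ Z).todense())
        self.ZtX = np.asarray((Z.T @ sp.csr_matrix(X)).todense())
        self.Zty = Z.T @ y

        # theta layout: concatenated lower triangles, one per factor
        self._tri = [_tri_indices(f.q) for f in factors]
        self._sizes = [len(t[0]) for t in self._tri]
        self._diag_mask = np.concatenate(
            [ti[0] == ti[1] for ti in self._tri]
        )

    def _check_full_rank(self) -> None:
        d = np.sqrt(np.clip(np.diag(self.XtX), 1e-30, None))
        corr = self.XtX / np.outer(d, d)
        eigvals, eigvecs = np.linalg.eigh(corr)
        if eigvals[0] < 1e-10:
            bad = np.where(np.abs(eigvecs[:, 0]) > 0.1)[0]
            names = [self.fe_names[i] for i in bad]
            raise RankDeficientError(
                f"fixed-effect design is rank deficient; collinear columns: {names}"
            )

    def _lambda(self, theta: np.ndarray) -> sp.csr_matrix:
        mats, pos = [], 0
        for f, (ri, ci), sz in zip(self.factors, self._tri, self._sizes):
            Lf = np.zeros((f.q, f.q))
            Lf[ri, ci] = theta[pos : pos + sz]
            pos += sz
            mats.append(sp.kron(sp.identity(f.n_levels, format="csr"), Lf))
        return sp.block_diag(mats, format="csr")

    def _solve(self, theta: np.ndarray) -> dict:
        Lam = self._lambda(theta)
        W = (Lam.T @ self.ZtZ) @ Lam
        W[np.diag_indices_from(W)] += 1.0
        L = cholesky(W, lower=True, check_finite=False)
        cu = solve_triangular(L, Lam.T @ self.Zty, lower=True, check_finite=False)
        RZX = solve_triangular(L, Lam.T @ self.ZtX, lower=True, check_finite=False)
        S = self.XtX - RZX.T @ RZX
        RX = cholesky(S, lower=True, check_finite=False)
        cbeta = solve_triangular(
            RX, self.Xty - RZX.T @ cu, lower=True, check_finite=False
        )
        pwrss = max(self.yty - cu @ cu - cbeta @ cbeta, 1e-300)
        ldL2 = 2.0 * np.sum(np.log(np.diag(L)))
        ldRX2 = 2.0 * np.sum(np.log(np.diag(RX)))
        if self.reml:
            df = self.n - self.p
            dev = ldL2 + ldRX2 + df * (1.0 + np.log(2.0 * np.pi * pwrss / df))
        else:
            dev = ldL2 + self.n * (1.0 + np.log(2.0 * np.pi * pwrss / self.n))
        return dict(
            Lam=Lam, L=L, cu=cu, RZX=RZX, S=S, RX=RX, cbeta=cbeta,
            pwrss=pwrss, deviance=dev,
        )

    def deviance(self, theta: np.ndarray) -> float:
        try:
            return self._solve(np.asarray(theta, dtype=float))["deviance"]
        except np.linalg.LinAlgError:
            return 1e12  # finite penalty keeps finite differencing well-defined

    def _start(self, diagonal: bool) -> tuple[np.ndarray, list]:
        theta0, bounds, pos = [], [], 0
        for f, sz in zip(self.factors, self._sizes):
            for k in range(sz):
                on_diag = self._diag_mask[pos + k]
                if diagonal and not on_diag:
                    continue
                theta0.append(0.5 if on_diag else 0.0)
                bounds.append((0.0, None) if on_diag else (None, None))
            pos += sz
        return np.array(theta0), bounds

    def _expand_diag(self, theta_d: np.ndarray) -> np.ndarray:
        full = np.zeros(sum(self._sizes))
        full[self._diag_mask] = theta_d
        return full

    def fit(
        self,
        diagonal: bool = False,
        maxiter: int = 400,
        start: np.ndarray | None = None,
    ) -> LMMResult:
        """Minimize the profiled deviance over the relative Cholesky factors.

        With ``diagonal=True`` the within-factor random-effect covariances
        are constrained diagonal (the fallback structure tried automatically
        by callers on non-convergence).  ``start`` warm-starts the optimizer
        with a full theta vector, e.g. from a previous fit of an equivalent
        reparameterization.
        """
        theta0, bounds = self._start(diagonal)
        if start is not None:
            if diagonal:
                theta0 = np.asarray(start)[self._diag_mask]
            else:
                theta0 = np.asarray(start, dtype=float)
        if maxiter == 0:
            # beta/sigma2 re-solve at fixed variance parameters: exact for
            # reparameterizations (recentering) that leave theta invariant
            theta = self._expand_diag(theta0) if diagonal else theta0
            return self._finalize(theta, self.deviance(theta), converged=True)
        obj = (
            (lambda t: self.deviance(self._expand_diag(t)))
            if diagonal
            else self.deviance
        )
        res = optimize.minimize(
            obj, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
        )
        # Nelder-Mead polish if the quasi-Newton path stalled early
        converged = bool(res.success)
        if not converged:
            res2 = optimize.minimize(
                obj, res.x, method="Nelder-Mead",
                options={"maxiter": 200 * len(theta0), "fatol": 1e-9, "xatol": 1e-8},
            )
            if res2.fun <= res.fun:
                res = res2
            converged = bool(res.success or res2.success)
        theta = self._expand_diag(res.x) if diagonal else np.asarray(res.x)
        return self._finalize(theta, res.fun, converged)

    def _finalize(self, theta: np.ndarray, dev: float, converged: bool) -> LMMResult:
        s = self._solve(theta)
        beta = solve_triangular(s["RX"].T, s["cbeta"], lower=False, check_finite=False)
        u = solve_triangular(
            s["L"].T, s["cu"] - s["RZX"] @ beta, lower=False, check_finite=False
        )
        b = s["Lam"] @ u
        dof = self.n - self.p if self.reml else self.n
        sigma2 = s["pwrss"] / dof
        cov_beta = sigma2 * cho_solve((s["RX"], True), np.eye(self.p))

        re_cov, ranef, pos = {}, {}, 0
        for f, off, (ri, ci), sz in zip(
            self.factors, self.offsets, self._tri, self._sizes
        ):
            Lf = np.zeros((f.q, f.q))
            Lf[ri, ci] = theta[pos : pos + sz]
            pos += sz
            re_cov[f.name] = pd.DataFrame(
                sigma2 * (Lf @ Lf.T), index=f.term_names, columns=f.term_names
            )
            bf = np.asarray(b[off : off + f.n_levels * f.q]).reshape(f.n_levels, f.q)
            ranef[f.name] = pd.DataFrame(bf, index=f.levels, columns=f.term_names)

        return LMMResult(
            fe_params=pd.Series(beta, index=self.fe_names),
            fe_cov=pd.DataFrame(cov_beta, index=self.fe_names, columns=self.fe_names),
            sigma2=float(sigma2),
            re_cov=re_cov,
            ranef=ranef,
            theta=theta,
            deviance=float(dev),
            reml=self.reml,
            converged=converged,
            n_obs=self.n,
            n_fixed=self.p,
        )
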