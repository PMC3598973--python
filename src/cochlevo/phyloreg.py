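"""Phylogenetic regression: deterministic PGLS and a Bayesian phylogenetic
mixed model (BPMM) with pMCMC significance and DIC model comparison.

The BPMM is the animal-model form

    y = X beta + u + e,   u ~ N(0, sigma2_p * C),   e ~ N(0, sigma2_e * I)

with C the BM tree covariance, flat priors on the fixed effects beta and
weak inverse-gamma priors on the two variance components.  The sampler is a
Gibbs scheme made O(n^2) per sweep by rotating the phylogenetic random
effect into the eigenbasis of C, where its full conditional is diagonal.

PGLS is the deterministic counterpart: GLS under the same (optionally
lambda-scaled) covariance, with lambda fixed or profiled by ML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .allometry import RegressionFit, _design
from .comparative import align_trait, bm_covariance
from .exceptions import ConvergenceError, SingularDesignError
from .phylo_io import Phylogeny

__all__ = [
    "PhyloGLS",
    "PGLSFit",
    "pgls_fit",
    "PhyloMixedModel",
    "BPMMResult",
    "bpmm_sample",
    "pmcmc",
    "delta_dic",
]


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit(RegressionFit):
    """GLS regression results under a lambda-scaled BM covariance."""

    lam: float = 1.0
    sigma2: float = float("nan")   # ML scale of the correlation matrix
    loglik: float = float("nan")

    def summary(self) -> str:
        base = super().summary().replace("Ordinary least squares allometric fit",
                                         "Phylogenetic GLS fit")
        return base + (f"\n  lambda = {self.lam:.4f}, "
                       f"sigma2 = {self.sigma2:.6g}, logL = {self.loglik:.4f}")


class PhyloGLS:
    """GLS regression of tip data under the BM (or lambda-scaled) covariance."""

    def __init__(self, tree: Phylogeny, y, X, add_intercept: bool = True,
                 param_names=None):
        self.tree = tree
        self.y = align_trait(tree, y)
        self.X = _design(X, add_intercept)
        if len(self.X) != tree.n_tips:
            raise ValueError("X rows must match number of tips")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise SingularDesignError("design matrix is rank deficient")
        self.add_intercept = add_intercept
        p = self.X.shape[1]
        if param_names is None:
            param_names = (["intercept"] if add_intercept else []) + [
                f"x{i}" for i in range(p - int(add_intercept))]
        self.param_names = list(param_names)

    def _fit_at(self, lam: float):
        y, X = self.y, self.X
        n, p = X.shape
        C = bm_covariance(self.tree, lam=lam)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(f"singular phylogenetic covariance: {exc}") from exc
        yw = scipy.linalg.solve_triangular(L, y, lower=True)
        Xw = scipy.linalg.solve_triangular(L, X, lower=True)
        xtx = Xw.T @ Xw
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ Xw.T @ yw
        resid = yw - Xw @ beta
        ss = float(resid @ resid)
        sigma2 = ss / n
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        return beta, xtx_inv, ss, sigma2, loglik, Xw, yw

    def fit(self, lam: float | str = 1.0) -> PGLSFit:
        """Fit with a fixed lambda in [0, 1], or ``lam='ml'`` to profile it."""
        if lam == "ml":
            res = scipy.optimize.minimize_scalar(
                lambda t: -self._fit_at(t)[4], bounds=(0.0, 1.0),
                method="bounded", options={"xatol": 1e-6})
            if not res.success:
                raise ConvergenceError(f"lambda optimiser failed: {res}")
            cands = [(self._fit_at(t)[4], t) for t in (0.0, 1.0)]
            cands.append((-res.fun, float(res.x)))
            lam = max(cands, key=lambda c: c[0])[1]
        beta, xtx_inv, ss, sigma2, loglik, Xw, yw = self._fit_at(float(lam))
        n, p = self.X.shape
        df = n - p
        rse = float(np.sqrt(ss / df)) if df > 0 else 0.0
        ybar = float(np.mean(yw)) if not self.add_intercept else \
            float((np.sum(yw) / len(yw)))
        # R^2 on the whitened scale against the whitened-intercept-only fit
        if self.add_intercept:
            ones_w = Xw[:, 0]
            mu = float(ones_w @ yw / (ones_w @ ones_w))
            tss = float(((yw - mu * ones_w) ** 2).sum())
        else:
            tss = float((yw ** 2).sum())
        r2 = 1.0 - ss / tss if tss > 0 else 1.0
        if p > 1 and df > 0 and ss > 0:
            fval = (tss - ss) / (p - 1) / (ss / df)
            fp = float(scipy.stats.f.sf(fval, p - 1, df))
        else:
            fval, fp = float("nan"), float("nan")
        return PGLSFit(
            params=beta, resid_std_error=rse, df_resid=df, rsquared=r2,
            fvalue=float(fval), f_pvalue=fp, nobs=n, xtx_inv=xtx_inv,
            param_names=self.param_names, bse=rse * np.sqrt(np.diag(xtx_inv)),
            has_intercept=self.add_intercept, lam=float(lam), sigma2=sigma2,
            loglik=loglik)


def pgls_fit(tree: Phylogeny, y, X, lam: float | str = 1.0,
             add_intercept: bool = True) -> PGLSFit:
    """Phylogenetic GLS; see :class:`PhyloGLS`."""
    return PhyloGLS(tree, y, X, add_intercept=add_intercept).fit(lam=lam)


# ---------------------------------------------------------------------------
# pMCMC and DIC
# ---------------------------------------------------------------------------

def pmcmc(draws) -> float:
    """Twice the smaller posterior tail probability relative to zero.

    ``2 * min(P(draw > 0), P(draw < 0))`` clamped below at ``2/n_draws`` — a
    tail probability is never estimated as exactly zero from finite draws.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError(f"pmcmc needs >= 2 draws, got {draws.size}")
    n = draws.size
    frac_pos = float(np.mean(draws > 0))
    frac_neg = float(np.mean(draws < 0))
    return float(np.clip(2.0 * min(frac_pos, frac_neg), 2.0 / n, 1.0))


def delta_dic(dic_a: float, dic_b: float, threshold: float = 2.0):
    """``(dic_a - dic_b, significant)``: a positive delta means model b has
    the lower (better) DIC; the improvement is significant iff
    ``|delta| >= threshold`` (default 2)."""
    if not (np.isfinite(dic_a) and np.isfinite(dic_b)):
        raise ValueError("DIC values must be finite")
    delta = float(dic_a - dic_b)
    return delta, bool(abs(delta) >= threshold)


# ---------------------------------------------------------------------------
# BPMM Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass
class BPMMResult:
    """Posterior draws and derived quantities from the BPMM Gibbs sampler.

    ``draws`` has one column per fixed effect plus ``var_phylo`` and
    ``var_resid``.  ``dic`` follows the conditional-deviance convention
    ``2*mean(D) - D(at posterior means)``.  ``pmcmc`` maps each fixed effect
    to its two-tailed posterior significance.
    """

    draws: pd.DataFrame
    dic: float
    pmcmc: dict
    param_names: list
    iterations: int
    burnin: int
    thin: int
    seed: int
    rhat: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def posterior_mean(self, name: str) -> float:
        return float(self.draws[name].mean())

    def posterior_sd(self, name: str) -> float:
        return float(self.draws[name].std(ddof=1))

    def mc_se(self, name: str) -> float:
        """Monte-Carlo standard error from the effective sample size."""
        import arviz as az
        ess = float(az.ess(np.asarray(self.draws[name])[None, :]))
        return self.posterior_sd(name) / np.sqrt(max(ess, 1.0))

    def summary(self) -> str:
        lines = [
            "Bayesian phylogenetic mixed model",
            f"  chain: {self.iterations} iterations, burn-in {self.burnin}, "
            f"thin {self.thin} ({self.n_draws} draws), seed {self.seed}",
            f"  DIC = {self.dic:.3f}",
            "  posterior means (sd) [pMCMC]:",
        ]
        for name in self.param_names:
            lines.append(f"    {name:<20s} {self.posterior_mean(name):>10.4f} "
                         f"({self.posterior_sd(name):.4f})  "
                         f"[{self.pmcmc[name]:.4g}]")
        for name in ("var_phylo", "var_resid"):
            lines.append(f"    {name:<20s} {self.posterior_mean(name):>10.4f} "
                         f"({self.posterior_sd(name):.4f})")
        return "\n".join(lines)


class PhyloMixedModel:
    """BPMM: Gaussian response with a phylogenetic random effect.

    Priors: improper flat on fixed effects, inverse-gamma(shape, scale) on
    both variance components (default 0.001/0.001, the customary weak
    setting).
    """

    def __init__(self, tree: Phylogeny, y, X, add_intercept: bool = True,
                 param_names=None):
        self.tree = tree
        self.y = align_trait(tree, y)
        self.X = _design(X, add_intercept)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise SingularDesignError("design matrix is rank deficient")
        p = self.X.shape[1]
        if param_names is None:
            param_names = (["intercept"] if add_intercept else []) + [
                f"x{i}" for i in range(p - int(add_intercept))]
        self.param_names = list(param_names)
        # scale-free correlation structure: C normalised by its max depth
        C = bm_covariance(tree)
        self._scale = float(np.max(np.diag(C)))
        C = C / self._scale
        evals, evecs = np.linalg.eigh(C)
        if np.min(evals) <= 1e-10:
            raise SingularDesignError("phylogenetic covariance is singular")
        self._evals, self._Q = evals, evecs

    def fit(self, iterations: int = 13000, burnin: int = 3000, thin: int = 10,
            seed: int = 0, prior_shape: float = 0.001,
            prior_scale: float = 0.001, rhat_threshold: float = 1.1) -> BPMMResult:
        if burnin >= iterations:
            raise ValueError("burnin must be smaller than iterations")
        rng = np.random.default_rng(seed)
        y, X, Q, lam = self.y, self.X, self._Q, self._evals
        n, p = X.shape
        xtx = X.T @ X
        xtx_inv = np.linalg.inv(xtx)
        chol_beta = np.linalg.cholesky(xtx_inv)
        ols_beta = xtx_inv @ X.T @ y
        resid0 = y - X @ ols_beta
        s2 = max(float(resid0 @ resid0) / max(n - p, 1), 1e-8)
        beta = ols_beta.copy()
        var_p, var_e = s2 / 2, s2 / 2
        u_rot = np.zeros(n)

        keep = []
        deviances = []
        a_post = prior_shape + n / 2.0
        for it in range(iterations):
            # phylogenetic effect, diagonal in the eigenbasis of C
            r = Q.T @ (y - X @ beta)
            prec = 1.0 / (var_p * lam) + 1.0 / var_e
            mean = (r / var_e) / prec
            u_rot = mean + rng.standard_normal(n) / np.sqrt(prec)
            u = Q @ u_rot
            # fixed effects, flat prior
            bmean = xtx_inv @ (X.T @ (y - u))
            beta = bmean + np.sqrt(var_e) * (chol_beta @ rng.standard_normal(p))
            # variance components, inverse-gamma full conditionals
            ssu = float(np.sum(u_rot ** 2 / lam))
            var_p = 1.0 / rng.gamma(a_post, 1.0 / (prior_scale + ssu / 2.0))
            resid = y - X @ beta - u
            sse = float(resid @ resid)
            var_e = 1.0 / rng.gamma(a_post, 1.0 / (prior_scale + sse / 2.0))
            if it >= burnin and (it - burnin) % thin == 0:
                dev = n * np.log(2 * np.pi * var_e) + sse / var_e
                deviances.append(dev)
                keep.append(np.concatenate([beta, [var_p, var_e], u]))

        keep = np.asarray(keep)
        cols = self.param_names + ["var_phylo", "var_resid"]
        draws = pd.DataFrame(keep[:, : p + 2], columns=cols)
        # DIC: 2*mean(D) - D(posterior means)
        mean_beta = keep[:, :p].mean(axis=0)
        mean_var_e = keep[:, p + 1].mean()
        mean_u = keep[:, p + 2:].mean(axis=0)
        resid_hat = y - X @ mean_beta - mean_u
        d_hat = n * np.log(2 * np.pi * mean_var_e) + \
            float(resid_hat @ resid_hat) / mean_var_e
        dic = float(2.0 * np.mean(deviances) - d_hat)

        pm = {name: pmcmc(draws[name]) for name in self.param_names}
        rhat = _split_rhat(draws[cols])
        bad = {k: v for k, v in rhat.items() if v > rhat_threshold}
        if bad:
            warnings.warn(f"BPMM chain may not have converged; split-Rhat {bad}",
                          stacklevel=2)
        return BPMMResult(draws=draws, dic=dic, pmcmc=pm,
                          param_names=self.param_names, iterations=iterations,
                          burnin=burnin, thin=thin, seed=seed, rhat=rhat)


def _split_rhat(draws: pd.DataFrame) -> dict:
    """Split-chain potential-scale-reduction diagnostic per column."""
    out = {}
    for col in draws.columns:
        x = np.asarray(draws[col], dtype=float)
        h = len(x) // 2
        if h < 2:
            out[col] = float("nan")
            continue
        chains = np.stack([x[:h], x[h:2 * h]])
        w = chains.var(axis=1, ddof=1).mean()
        b = h * chains.mean(axis=1).var(ddof=1)
        out[col] = float(np.sqrt(((h - 1) / h * w + b / h) / w)) if w > 0 else 1.0
    return out


def bpmm_sample(tree: Phylogeny, y, X, iterations: int = 13000,
                thin: int = 10, burnin: int = 3000, seed: int = 0,
                add_intercept: bool = True) -> BPMMResult:
    """Run the BPMM Gibbs sampler; see :class:`PhyloMixedModel`."""
    return PhyloMixedModel(tree, y, X, add_intercept=add_intercept).fit(
        iterations=iterations, burnin=burnin, thin=thin, seed=seed)
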