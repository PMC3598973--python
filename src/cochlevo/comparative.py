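"""Brownian-motion comparative machinery.

Covariance construction, Felsenstein's phylogenetic independent contrasts
(PIC), maximum-likelihood ancestral state reconstruction, and Pagel's lambda
phylogenetic signal with likelihood-ratio tests.

Under Brownian motion (BM) with rate ``sigma2`` a trait accrues variance
``sigma2 * t`` along a branch of length ``t`` My, so tip values are jointly
Gaussian with covariance ``sigma2 * C`` where ``C[i, j]`` is the root-to-MRCA
path length shared by tips i and j.  Pagel's lambda multiplies the
off-diagonal entries of ``C``: lambda = 1 is pure BM, lambda = 0 a star
phylogeny with independent tips.

Two independent likelihood routes are provided — the O(n) contrast (pruning)
representation and the dense multivariate-normal evaluation — and are held to
agree in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .exceptions import CochlevoError, ConvergenceError, SingularDesignError
from .phylo_io import Phylogeny

__all__ = [
    "bm_covariance",
    "lambda_rescale",
    "pic_contrasts",
    "ContrastSet",
    "AncestralEstimate",
    "AncestralBM",
    "ancestral_ml_bm",
    "PagelLambda",
    "LambdaFit",
    "fit_lambda",
    "bm_loglik",
    "bm_loglik_dense",
    "plot_traitgram",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def align_trait(tree: Phylogeny, trait) -> np.ndarray:
    """Return trait values ordered to the tree's tip order.

    Accepts an array already in tip order, or a pandas Series indexed by
    species name (re-indexed, with an error on missing species).
    """
    if isinstance(trait, pd.Series):
        missing = set(tree.labels) - set(trait.index)
        if missing:
            raise CochlevoError(f"trait values missing for tips: {sorted(missing)}")
        trait = trait.reindex(tree.labels).to_numpy(float)
    trait = np.asarray(trait, dtype=float)
    if trait.shape != (tree.n_tips,):
        raise CochlevoError(
            f"trait vector length {trait.shape} does not match {tree.n_tips} tips")
    if not np.all(np.isfinite(trait)):
        raise CochlevoError("trait values must be finite")
    return trait


def bm_covariance(tree: Phylogeny, lam: float = 1.0) -> np.ndarray:
    """Tips-by-tips BM covariance structure ``C`` (units: My).

    ``C[i, j]`` for i != j is the root-to-MRCA shared path length multiplied
    by ``lam``; the diagonal is the unscaled tip depth (the Pagel
    construction leaves tip variances untouched).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    n = tree.n_tips
    depth = tree.node_depths()
    C = np.zeros((n, n))
    # mrca(i, j) is the node at which i and j sit in different child subtrees
    for v in tree.postorder():
        if v < n:
            continue
        groups = [tree.clade_tips(c) for c in tree.children[v]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                C[np.ix_(groups[a], groups[b])] = depth[v]
                C[np.ix_(groups[b], groups[a])] = depth[v]
    C *= lam
    C[np.diag_indices(n)] = depth[:n]
    return C


def lambda_rescale(tree: Phylogeny, lam: float) -> Phylogeny:
    """Tree transformation realising the Pagel-lambda covariance.

    All branch lengths are multiplied by ``lam`` and each tip branch is then
    extended by ``(1 - lam) * tip_depth`` so tip variances stay unchanged
    while shared (internal) path lengths scale by ``lam``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if lam == 1.0:
        return tree
    depth = tree.node_depths()
    lengths = tree.lengths * lam
    lengths[: tree.n_tips] += (1.0 - lam) * depth[: tree.n_tips]
    return Phylogeny(parent=tree.parent.copy(), lengths=lengths,
                     labels=list(tree.labels), n_tips=tree.n_tips,
                     root=tree.root)


# ---------------------------------------------------------------------------
# independent contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSet:
    """Phylogenetic independent contrasts for one trait on a binary tree.

    One entry per internal node (in postorder): the standardized contrast,
    its raw variance (sum of adjusted child branch lengths), the local node
    estimate from the upward pruning pass, and the node's adjusted branch
    length used further up the tree.  ``root_variance`` is the variance
    factor of the root estimate (multiply by sigma2 for its sampling
    variance).
    """

    node_ids: np.ndarray
    contrasts: np.ndarray
    variances: np.ndarray
    node_estimates: np.ndarray
    adjusted_lengths: np.ndarray
    root_estimate: float
    root_variance: float

    @property
    def n_contrasts(self) -> int:
        return len(self.contrasts)

    def sigma2_hat(self) -> float:
        """REML-unbiased BM rate: mean of squared standardized contrasts."""
        return float(np.mean(self.contrasts ** 2))


def pic_contrasts(tree: Phylogeny, trait) -> ContrastSet:
    """Felsenstein's pruning pass.

    At each internal node with child values x1, x2 on adjusted branches
    b1, b2: contrast ``(x1 - x2)/sqrt(b1 + b2)``, node value the
    branch-weighted average, and the parent branch extended by
    ``b1*b2/(b1 + b2)``.  Polytomies are resolved arbitrarily with
    zero-length branches first (with a warning).
    """
    tree = tree.resolve_polytomies()
    x = align_trait(tree, trait)
    n = tree.n_tips
    val = np.zeros(tree.n_nodes)
    bl = tree.lengths.copy()
    val[:n] = x
    ids, us, vs, ests, adjs = [], [], [], [], []
    for v in tree.postorder():
        if v < n:
            continue
        c1, c2 = tree.children[v]
        b1, b2 = bl[c1], bl[c2]
        V = b1 + b2
        if V <= 0:
            raise CochlevoError(
                f"zero combined branch length at node {v}; contrasts undefined")
        us.append((val[c1] - val[c2]) / np.sqrt(V))
        vs.append(V)
        val[v] = (val[c1] / b1 + val[c2] / b2) / (1 / b1 + 1 / b2) if b1 > 0 and b2 > 0 \
            else (val[c1] if b2 > 0 else val[c2]) if (b1 == 0) != (b2 == 0) \
            else (val[c1] + val[c2]) / 2
        extra = b1 * b2 / V
        bl[v] = tree.lengths[v] + extra
        ids.append(v)
        ests.append(val[v])
        adjs.append(bl[v])
    root_var = bl[tree.root]
    return ContrastSet(
        node_ids=np.asarray(ids), contrasts=np.asarray(us),
        variances=np.asarray(vs), node_estimates=np.asarray(ests),
        adjusted_lengths=np.asarray(adjs),
        root_estimate=float(val[tree.root]), root_variance=float(root_var),
    )


# ---------------------------------------------------------------------------
# BM likelihood (two routes)
# ---------------------------------------------------------------------------

def bm_loglik(tree: Phylogeny, trait, sigma2: float | None = None):
    """BM log-likelihood via the contrast (pruning) factorisation.

    Uses the tree-determinant identity ``det(C) = v_root * prod(V_k)`` where
    ``V_k`` are the raw contrast variances.  If ``sigma2`` is None the ML
    rate (n-denominator) is profiled out.  Returns
    ``(loglik, sigma2, root_estimate)``.
    """
    cs = pic_contrasts(tree, trait)
    n = tree.n_tips
    ss = float(np.sum(cs.contrasts ** 2))  # quadratic form at the GLS mean
    logdet = float(np.sum(np.log(cs.variances)) + np.log(cs.root_variance))
    if sigma2 is None:
        sigma2 = ss / n
    if sigma2 <= 0:
        if ss == 0:  # constant trait: degenerate, likelihood unbounded
            return float("inf"), 0.0, cs.root_estimate
        raise ValueError("sigma2 must be positive")
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + ss / sigma2)
    return float(ll), float(sigma2), cs.root_estimate


def bm_loglik_dense(tree: Phylogeny, trait, sigma2: float | None = None,
                    lam: float = 1.0):
    """BM log-likelihood by dense multivariate-normal evaluation (O(n^3)).

    Independent of the pruning route; kept as a cross-check and for
    lambda-scaled covariances without tree rescaling.
    """
    x = align_trait(tree, trait)
    C = bm_covariance(tree, lam=lam)
    n = len(x)
    L = np.linalg.cholesky(C)
    ones = np.ones(n)
    w_x = scipy.linalg.cho_solve((L, True), x)
    w_1 = scipy.linalg.cho_solve((L, True), ones)
    mu = float(ones @ w_x / (ones @ w_1))
    r = x - mu
    ss = float(r @ scipy.linalg.cho_solve((L, True), r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 is None:
        sigma2 = ss / n
    if sigma2 <= 0:
        return float("inf"), 0.0, mu
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + ss / sigma2)
    return float(ll), float(sigma2), mu


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------

@dataclass
class AncestralEstimate:
    """ML ancestral states for internal nodes under BM.

    ``method`` records the computational route ('PIC' message passing or
    dense 'ML' GLS); both give identical point estimates.  Standard errors
    are conditional-on-tips standard deviations scaled by the ML rate.
    """

    node_ids: np.ndarray
    estimates: np.ndarray
    std_errors: np.ndarray
    method: str
    sigma2: float
    root_id: int

    @property
    def root_estimate(self) -> float:
        return float(self.estimates[self.node_ids == self.root_id][0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.node_ids, "estimate": self.estimates,
                             "std_error": self.std_errors})

    def summary(self) -> str:
        lines = [f"Ancestral BM reconstruction ({self.method}); "
                 f"sigma2 = {self.sigma2:.6g}",
                 f"  root (node {self.root_id}): {self.root_estimate:.6g}"]
        return "\n".join(lines)


class AncestralBM:
    """Ancestral-state model for one continuous trait under Brownian motion.

    ``fit(method='pic')`` runs linear-time Gaussian message passing on the
    tree (the re-rooted-contrasts construction); ``fit(method='ml')`` solves
    the dense GLS conditional expectation.  The two agree to numerical
    precision — the pair is used as a built-in oracle check.
    """

    def __init__(self, tree: Phylogeny, trait):
        self.tree = tree
        self.x = align_trait(tree, trait)

    def fit(self, method: str = "pic") -> AncestralEstimate:
        if method.lower() == "pic":
            return self._fit_message_passing()
        if method.lower() == "ml":
            return self._fit_dense_gls()
        raise ValueError(f"unknown method {method!r}; use 'pic' or 'ml'")

    # -- O(n) route: Gaussian belief propagation --------------------------
    def _fit_message_passing(self) -> AncestralEstimate:
        tree, x = self.tree, self.x
        n = tree.n_tips
        # upward messages: state at v given its subtree ~ N(m_up, d_up) (x sigma2)
        m_up = np.zeros(tree.n_nodes)
        d_up = np.zeros(tree.n_nodes)
        m_up[:n] = x
        for v in tree.postorder():
            if v < n:
                continue
            prec = wsum = 0.0
            for c in tree.children[v]:
                w = 1.0 / (d_up[c] + tree.lengths[c])
                prec += w
                wsum += w * m_up[c]
            d_up[v] = 1.0 / prec
            m_up[v] = wsum / prec
        # downward messages: state at v given everything outside its subtree,
        # precision form (root prior is flat: precision 0)
        p_dn = np.zeros(tree.n_nodes)   # precision of above-message
        m_dn = np.zeros(tree.n_nodes)
        for v in tree.preorder():
            if v < n and v != tree.root:
                continue
            for c in tree.children[v]:
                prec = p_dn[v]
                num = p_dn[v] * m_dn[v]
                for s in tree.children[v]:
                    if s == c:
                        continue
                    w = 1.0 / (d_up[s] + tree.lengths[s])
                    prec += w
                    num += w * m_up[s]
                if prec == 0.0:  # root with a single other lineage of flat info
                    p_dn[c] = 0.0
                    m_dn[c] = 0.0
                else:
                    var_at_v = 1.0 / prec
                    p_dn[c] = 1.0 / (var_at_v + tree.lengths[c])
                    m_dn[c] = num / prec
        ids, est, var = [], [], []
        sigma2 = bm_loglik(tree, x)[1]
        for v in range(n, tree.n_nodes):
            prec = 1.0 / d_up[v] + p_dn[v]
            mean = (m_up[v] / d_up[v] + p_dn[v] * m_dn[v]) / prec
            ids.append(v)
            est.append(mean)
            var.append(1.0 / prec)
        return AncestralEstimate(
            node_ids=np.asarray(ids), estimates=np.asarray(est),
            std_errors=np.sqrt(sigma2 * np.asarray(var)),
            method="PIC", sigma2=sigma2, root_id=tree.root)

    # -- O(n^3) route: dense GLS ------------------------------------------
    def _fit_dense_gls(self) -> AncestralEstimate:
        tree, x = self.tree, self.x
        n = tree.n_tips
        depth = tree.node_depths()
        internal = np.arange(n, tree.n_nodes)
        # ancestor lists for MRCA depths between internal nodes and tips
        in_clade = np.zeros((tree.n_nodes, n), dtype=bool)
        for v in tree.postorder():
            if v < n:
                in_clade[v, v] = True
            else:
                for c in tree.children[v]:
                    in_clade[v] |= in_clade[c]
        C = bm_covariance(tree)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(f"singular BM covariance: {exc}") from exc
        ones = np.ones(n)
        Cinv_1 = scipy.linalg.cho_solve((L, True), ones)
        mu = float(ones @ scipy.linalg.cho_solve((L, True), x) / (ones @ Cinv_1))
        r = scipy.linalg.cho_solve((L, True), x - mu * ones)
        sigma2 = float((x - mu * ones) @ r / n)
        ids, est, var = [], [], []
        for a in internal:
            # cov(node a, tip j) = depth of deepest common ancestor
            cov = np.empty(n)
            inside = in_clade[a]
            cov[inside] = depth[a]
            u = a
            while tree.parent[u] >= 0:
                u = tree.parent[u]
                newly = in_clade[u] & ~inside
                cov[newly] = depth[u]
                inside = inside | newly
            mean = mu + cov @ r
            w = scipy.linalg.cho_solve((L, True), cov)
            # conditional variance plus the GLS-mean uncertainty term
            slack = 1.0 - float(cov @ Cinv_1)
            v_cond = depth[a] - float(cov @ w) + slack ** 2 / float(ones @ Cinv_1)
            ids.append(a)
            est.append(float(mean))
            var.append(max(v_cond, 0.0))
        return AncestralEstimate(
            node_ids=np.asarray(ids), estimates=np.asarray(est),
            std_errors=np.sqrt(sigma2 * np.asarray(var)),
            method="ML", sigma2=sigma2, root_id=tree.root)


def ancestral_ml_bm(tree: Phylogeny, trait, method: str = "ml") -> AncestralEstimate:
    """ML ancestral states under BM; see :class:`AncestralBM`."""
    return AncestralBM(tree, trait).fit(method=method)


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass
class LambdaFit:
    """Profile-ML Pagel's lambda with likelihood-ratio tests against 0 and 1.

    p-values come from chi-square(1); at the lambda = 1 boundary this matches
    the convention of the standard comparative tooling but is conservative
    (the boundary null is a 50:50 mixture).
    """

    lambda_hat: float
    loglik: float
    loglik_0: float
    loglik_1: float
    sigma2_hat: float
    root_hat: float
    n_tips: int

    @property
    def lr_vs_0(self) -> float:
        return 2.0 * (self.loglik - self.loglik_0)

    @property
    def lr_vs_1(self) -> float:
        return 2.0 * (self.loglik - self.loglik_1)

    @property
    def p_vs_0(self) -> float:
        return float(scipy.stats.chi2.sf(max(self.lr_vs_0, 0.0), df=1))

    @property
    def p_vs_1(self) -> float:
        return float(scipy.stats.chi2.sf(max(self.lr_vs_1, 0.0), df=1))

    def summary(self) -> str:
        return "\n".join([
            "Pagel's lambda (profile ML)",
            f"  n = {self.n_tips} tips",
            f"  lambda_hat = {self.lambda_hat:.4f}  "
            f"(logL = {self.loglik:.4f}, sigma2 = {self.sigma2_hat:.6g}, "
            f"root = {self.root_hat:.6g})",
            f"  LR vs lambda=0: {self.lr_vs_0:.3f}  p = {self.p_vs_0:.3g}",
            f"  LR vs lambda=1: {self.lr_vs_1:.3f}  p = {self.p_vs_1:.3g}",
        ])


class PagelLambda:
    """Phylogenetic-signal model: BM with lambda-scaled shared covariance."""

    def __init__(self, tree: Phylogeny, trait, warn_small: int = 10):
        import warnings as _w
        self.tree = tree
        self.x = align_trait(tree, trait)
        if tree.n_tips < warn_small:
            _w.warn(f"lambda estimation on only {tree.n_tips} tips is weakly "
                    "identified", stacklevel=2)

    def _profile_loglik(self, lam: float) -> float:
        return bm_loglik(lambda_rescale(self.tree, lam), self.x)[0]

    def fit(self, xatol: float = 1e-6) -> LambdaFit:
        f = self._profile_loglik
        candidates = [(f(0.0), 0.0), (f(1.0), 1.0), (f(0.5), 0.5)]
        # bounded scalar searches from multiple brackets guard against the
        # (rare) multimodal profile
        for lo, hi in ((0.0, 0.5), (0.5, 1.0), (0.0, 1.0)):
            res = scipy.optimize.minimize_scalar(
                lambda t: -f(t), bounds=(lo, hi), method="bounded",
                options={"xatol": xatol})
            if not res.success:
                raise ConvergenceError(f"lambda optimiser failed: {res}")
            candidates.append((-res.fun, float(res.x)))
        best_ll, best_lam = max(candidates, key=lambda c: c[0])
        ll_hat, s2, root = bm_loglik(lambda_rescale(self.tree, best_lam), self.x)
        return LambdaFit(
            lambda_hat=best_lam, loglik=ll_hat,
            loglik_0=f(0.0), loglik_1=f(1.0),
            sigma2_hat=s2, root_hat=root, n_tips=self.tree.n_tips)


def fit_lambda(tree: Phylogeny, trait) -> LambdaFit:
    """Profile-ML Pagel's lambda; see :class:`PagelLambda`."""
    return PagelLambda(tree, trait).fit()


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_traitgram(tree: Phylogeny, trait, ax=None, method: str = "pic",
                   color="0.3"):
    """Traitgram: reconstructed states against node age, tips at the present.

    Convenience visualisation of an ancestral reconstruction; returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    x = align_trait(tree, trait)
    anc = AncestralBM(tree, trait).fit(method=method)
    depth = tree.node_depths()
    T = tree.total_depth()
    states = np.empty(tree.n_nodes)
    states[: tree.n_tips] = x
    states[anc.node_ids] = anc.estimates
    if ax is None:
        _, ax = plt.subplots()
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0:
            ax.plot([states[p], states[v]], [T - depth[p], T - depth[v]],
                    color=color, lw=0.8)
    ax.scatter(x, np.zeros(tree.n_tips), s=12, zorder=3)
    ax.set_xlabel("trait value")
    ax.set_ylabel("node age (My before present)")
    ax.invert_yaxis()
    return ax
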