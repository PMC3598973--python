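"""Reversible-jump MCMC detection of branch-specific Brownian-motion rate shifts.

The model partitions the branches of the tree into rate classes: a shift at
node v assigns a new BM rate to v's stem branch and to every branch inside
v's clade (until overridden by a deeper shift), so shifts are clade-wise and
node-centred.  The trait likelihood is the restricted (contrast) BM
likelihood on the rate-rescaled tree — each branch contributes variance
``rate * length`` — which is independent of the unknown root state.

Priors: the number of shifts is Poisson (default mean 1) truncated at the
number of eligible branches; shift locations are uniform over subsets of
non-root nodes; log rates (the base rate and every shift rate) are Normal
around the log of the contrast-based rate estimate of the data, sd 2 — a
weak empirical-Bayes centring that keeps the sampler scale-free.

Moves: log-scale random-walk rate updates, shift birth (rate drawn from the
prior, which cancels in the acceptance ratio), shift death, and shift
relocation.  The posterior is summarised as per-node shift probabilities and
model-averaged per-branch rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparative import align_trait, pic_contrasts
from .exceptions import CochlevoError
from .phylo_io import Phylogeny

__all__ = [
    "RateShiftModel",
    "RateShiftPosterior",
    "rjmcmc_rates",
    "shift_summary",
]

DEFAULT_MOVE_WEIGHTS = {"rate": 0.45, "birth": 0.2, "death": 0.2, "relocate": 0.15}


@dataclass
class RateShiftPosterior:
    """Posterior summary of the rjMCMC rate-shift analysis.

    ``branch_rates`` are posterior-mean BM rates per node's stem branch
    (trait-variance units per My); ``relative_rates`` divide by the tree-wide
    median; ``shift_prob[v]`` is the posterior probability that a shift
    occurs at node v.  ``acceptance`` gives per-move acceptance fractions.
    """

    tree: Phylogeny
    branch_rates: np.ndarray
    relative_rates: np.ndarray
    shift_prob: np.ndarray
    generations: int
    sample_interval: int
    burnin_fraction: float
    seed: int
    n_samples: int
    acceptance: dict
    mean_n_shifts: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": np.arange(self.tree.n_nodes),
            "branch_rate": self.branch_rates,
            "relative_rate": self.relative_rates,
            "shift_prob": self.shift_prob,
        })

    def significant_shifts(self, threshold: float = 0.95) -> dict:
        """Nodes with shift probability above ``threshold``, mapped to
        'increase' or 'decrease' of the clade's model-averaged rate relative
        to the tree-wide median branch rate."""
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        background = float(np.median(np.delete(self.branch_rates, self.tree.root)))
        out = {}
        for v in np.where(self.shift_prob > threshold)[0]:
            clade = self._clade_nodes(int(v))
            clade_rate = float(np.mean(self.branch_rates[clade]))
            out[int(v)] = "increase" if clade_rate > background else "decrease"
        return out

    def _clade_nodes(self, node: int) -> list:
        # branches governed by a shift at ``node``: its descendants (the
        # node's own stem branch keeps the ancestral rate)
        nodes, stack = [], list(self.tree.children[node])
        while stack:
            v = stack.pop()
            nodes.append(v)
            stack.extend(self.tree.children[v])
        return nodes

    def summary(self, threshold: float = 0.95) -> str:
        sig = self.significant_shifts(threshold)
        lines = [
            "rjMCMC BM rate-shift analysis",
            f"  chain: {self.generations} generations, sampled every "
            f"{self.sample_interval} ({self.n_samples} post-burn-in samples, "
            f"burn-in {self.burnin_fraction:.0%}), seed {self.seed}",
            f"  mean shift count: {self.mean_n_shifts:.2f}",
            "  acceptance rates: " + ", ".join(
                f"{k} {v:.2f}" for k, v in self.acceptance.items()),
            f"  significant shifts (p > {threshold}): "
            + (", ".join(f"node {v} ({d})" for v, d in sig.items()) or "none"),
        ]
        return "\n".join(lines)


class _Chain:
    """Internal rjMCMC state and move kernel (exposed for balance checks)."""

    def __init__(self, tree: Phylogeny, x: np.ndarray, shift_prior_mean: float,
                 prior_log_mu: float, prior_log_sd: float,
                 move_weights: dict, rate_proposal_sd: float):
        self.tree = tree
        self.x = x
        self.n = tree.n_tips
        self.prior_k_mean = shift_prior_mean
        self.mu0, self.tau = prior_log_mu, prior_log_sd
        self.rate_sd = rate_proposal_sd
        self.weights = dict(move_weights)
        # eligible shift nodes: internal non-root nodes (a shift at a tip
        # would govern no branch under the at-node semantics)
        self.eligible = [v for v in range(self.n, tree.n_nodes) if v != tree.root]
        self.M = len(self.eligible)
        # precompute traversal structures for the fast likelihood; plain
        # python lists keep the inner loops free of numpy scalar overhead
        self.post = [(v, tree.children[v][0], tree.children[v][1])
                     for v in tree.postorder() if v >= self.n]
        self.pre = [(v, int(tree.parent[v])) for v in tree.preorder()
                    if tree.parent[v] >= 0]
        self.lengths = [float(b) for b in tree.lengths]
        self._x_list = [float(v) for v in x]
        # state
        self.base_log_rate = prior_log_mu
        self.shifts: dict = {}
        self.loglik = self._loglik_for(self._effective_log_rates())

    # -- likelihood ------------------------------------------------------
    def _effective_log_rates(self) -> list:
        # a shift AT node v applies to the branches descending from v (the
        # shift is the event at v); v's own stem branch keeps the ancestral
        # rate.  eff[v] is the rate governing the branch above v.
        eff = [0.0] * self.tree.n_nodes
        get = self.shifts.get
        root = self.tree.root
        eff[root] = get(root, self.base_log_rate)
        for v, p in self.pre:
            g = get(p)
            eff[v] = eff[p] if g is None else g
        return eff

    def _loglik_for(self, eff_log_rates: list) -> float:
        """Restricted BM log-likelihood on the rate-rescaled tree."""
        exp, log = math.exp, math.log
        lengths = self.lengths
        bl = [lengths[v] * exp(eff_log_rates[v]) for v in range(len(lengths))]
        val = list(self._x_list) + [0.0] * (self.tree.n_nodes - self.n)
        ll = 0.0
        for v, c1, c2 in self.post:
            b1, b2 = bl[c1], bl[c2]
            V = b1 + b2
            if V <= 0:
                raise CochlevoError("zero-variance contrast in rate likelihood")
            x1, x2 = val[c1], val[c2]
            d = x1 - x2
            ll -= 0.5 * (log(6.283185307179586 * V) + d * d / V)
            val[v] = (x1 * b2 + x2 * b1) / V
            bl[v] += b1 * b2 / V
        return ll

    def current_rates(self) -> np.ndarray:
        return np.exp(np.asarray(self._effective_log_rates()))

    # -- priors ----------------------------------------------------------
    def _log_prior_rate(self, lr: float) -> float:
        z = (lr - self.mu0) / self.tau
        return -0.5 * (z * z + math.log(2.0 * math.pi)) - math.log(self.tau)

    def _log_prior_k_ratio(self, k_new: int, k_old: int) -> float:
        # Poisson(mean) ratio; location prior C(M, k) included
        lp = (k_new - k_old) * math.log(self.prior_k_mean)
        lp -= sum(math.log(i) for i in range(k_old + 1, k_new + 1))
        lp += sum(math.log(i) for i in range(k_new + 1, k_old + 1))
        # uniform-over-subsets location prior ratio: C(M,k_old)/C(M,k_new)
        if k_new == k_old + 1:
            lp += math.log(k_new) - math.log(self.M - k_old)
        elif k_new == k_old - 1:
            lp += math.log(self.M - k_new) - math.log(k_old)
        return lp

    # -- moves: each returns (accept_logratio, apply_callable) -----------
    def propose_rate(self, rng):
        classes = [None] + list(self.shifts)  # None = base class
        pick = classes[rng.integers(len(classes))]
        old = self.base_log_rate if pick is None else self.shifts[pick]
        new = old + rng.normal(0.0, self.rate_sd)
        shifts = dict(self.shifts)
        base = self.base_log_rate
        if pick is None:
            base = new
        else:
            shifts[pick] = new
        ll_new = self._loglik_with(shifts, base)
        logr = (ll_new - self.loglik
                + self._log_prior_rate(new) - self._log_prior_rate(old))
        return logr, (shifts, base, ll_new)

    def propose_birth(self, rng):
        free = [v for v in self.eligible if v not in self.shifts]
        if not free:
            return None
        node = free[rng.integers(len(free))]
        new_rate = rng.normal(self.mu0, self.tau)  # draw from the prior
        shifts = dict(self.shifts)
        shifts[node] = new_rate
        ll_new = self._loglik_with(shifts, self.base_log_rate)
        k = len(self.shifts)
        # prior-on-rate and location terms cancel against the proposal; what
        # remains: likelihood x Poisson/k-location ratio x move-prob ratio
        # x uniform selection counts
        logr = (ll_new - self.loglik
                + self._log_prior_k_ratio(k + 1, k)
                + math.log(self.weights["death"]) - math.log(self.weights["birth"])
                + math.log(len(free)) - math.log(k + 1))
        return logr, (shifts, self.base_log_rate, ll_new)

    def propose_death(self, rng):
        if not self.shifts:
            return None
        nodes = list(self.shifts)
        node = nodes[rng.integers(len(nodes))]
        shifts = dict(self.shifts)
        del shifts[node]
        ll_new = self._loglik_with(shifts, self.base_log_rate)
        k = len(self.shifts)
        n_free_after = self.M - (k - 1)
        logr = (ll_new - self.loglik
                + self._log_prior_k_ratio(k - 1, k)
                + math.log(self.weights["birth"]) - math.log(self.weights["death"])
                + math.log(k) - math.log(n_free_after))
        return logr, (shifts, self.base_log_rate, ll_new)

    def propose_relocate(self, rng):
        if not self.shifts:
            return None
        free = [v for v in self.eligible if v not in self.shifts]
        if not free:
            return None
        nodes = list(self.shifts)
        node = nodes[rng.integers(len(nodes))]
        target = free[rng.integers(len(free))]
        shifts = dict(self.shifts)
        shifts[target] = shifts.pop(node)
        ll_new = self._loglik_with(shifts, self.base_log_rate)
        logr = ll_new - self.loglik  # selection fully symmetric
        return logr, (shifts, self.base_log_rate, ll_new)

    def _loglik_with(self, shifts: dict, base: float) -> float:
        saved = (self.shifts, self.base_log_rate)
        self.shifts, self.base_log_rate = shifts, base
        eff = self._effective_log_rates()
        self.shifts, self.base_log_rate = saved
        return self._loglik_for(eff)

    def step(self, rng, accepted: dict, proposed: dict):
        if not hasattr(self, "_move_cdf"):
            names = list(self.weights)
            w = np.array([self.weights[m] for m in names], dtype=float)
            self._move_names = names
            self._move_cdf = np.cumsum(w / w.sum())
            self._move_fns = [getattr(self, f"propose_{m}") for m in names]
        i = int(np.searchsorted(self._move_cdf, rng.random()))
        move = self._move_names[i]
        proposal = self._move_fns[i](rng)
        if proposal is None:
            return
        proposed[move] += 1
        logr, (shifts, base, ll_new) = proposal
        if math.log(rng.random()) < logr:
            self.shifts, self.base_log_rate, self.loglik = shifts, base, ll_new
            accepted[move] += 1


class RateShiftModel:
    """rjMCMC rate-shift model for one continuous trait on a dated tree."""

    def __init__(self, tree: Phylogeny, trait, min_tips: int = 8):
        tree = tree.resolve_polytomies()
        if tree.n_tips < min_tips:
            raise CochlevoError(f"need >= {min_tips} tips, got {tree.n_tips}")
        self.tree = tree
        self.x = align_trait(tree, trait)
        if np.var(self.x) == 0:
            raise CochlevoError("trait has zero variance; rates unidentifiable")

    def fit(self, generations: int = 200_000, sample_interval: int = 200,
            burnin_fraction: float = 0.25, seed: int = 0,
            shift_prior_mean: float = 1.0, prior_log_sd: float = 2.0,
            rate_proposal_sd: float = 0.5,
            move_weights: dict | None = None) -> RateShiftPosterior:
        """Run the sampler.  The desk-scale default is 200,000 generations
        sampled every 200 with 25% burn-in; production runs use 4,000,000 /
        4,000 (the ``--paper-scale`` CLI option)."""
        if not 0.0 <= burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must be in [0, 1)")
        rng = np.random.default_rng(seed)
        cs = pic_contrasts(self.tree, self.x)
        mu0 = float(np.log(max(cs.sigma2_hat(), 1e-12)))
        chain = _Chain(self.tree, self.x, shift_prior_mean, mu0, prior_log_sd,
                       move_weights or DEFAULT_MOVE_WEIGHTS, rate_proposal_sd)
        n_nodes = self.tree.n_nodes
        n_keep_from = int(generations * burnin_fraction)
        rate_sum = np.zeros(n_nodes)
        shift_count = np.zeros(n_nodes)
        k_sum = 0.0
        n_samples = 0
        accepted = {m: 0 for m in chain.weights}
        proposed = {m: 0 for m in chain.weights}
        for g in range(1, generations + 1):
            chain.step(rng, accepted, proposed)
            if g % sample_interval == 0 and g > n_keep_from:
                rate_sum += chain.current_rates()
                for v in chain.shifts:
                    shift_count[v] += 1
                k_sum += len(chain.shifts)
                n_samples += 1
        if n_samples == 0:
            raise CochlevoError("no post-burn-in samples; increase generations")
        branch_rates = rate_sum / n_samples
        rel = branch_rates / np.median(np.delete(branch_rates, self.tree.root))
        acc = {m: (accepted[m] / proposed[m] if proposed[m] else float("nan"))
               for m in accepted}
        return RateShiftPosterior(
            tree=self.tree, branch_rates=branch_rates, relative_rates=rel,
            shift_prob=shift_count / n_samples, generations=generations,
            sample_interval=sample_interval, burnin_fraction=burnin_fraction,
            seed=seed, n_samples=n_samples, acceptance=acc,
            mean_n_shifts=k_sum / n_samples)


def rjmcmc_rates(tree: Phylogeny, trait, generations: int = 200_000,
                 sample_interval: int = 200, burnin_fraction: float = 0.25,
                 seed: int = 0, **kwargs) -> RateShiftPosterior:
    """Run the rjMCMC rate-shift sampler; see :class:`RateShiftModel`."""
    return RateShiftModel(tree, trait).fit(
        generations=generations, sample_interval=sample_interval,
        burnin_fraction=burnin_fraction, seed=seed, **kwargs)


def shift_summary(posterior: RateShiftPosterior, threshold: float = 0.95) -> dict:
    """Significant shift nodes and their direction; see
    :meth:`RateShiftPosterior.significant_shifts`."""
    return posterior.significant_shifts(threshold)
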