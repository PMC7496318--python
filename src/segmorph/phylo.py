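"""Bayesian inference of segment-position evolution on a fixed phylogeny.

Model
-----
Species-mean relative segment positions evolve on a rooted ultrametric
tree under (multivariate) Brownian motion.  The increment along branch
``b`` (length ``t_b``) has covariance ``t_b * r_b * Sigma``, where
``Sigma`` is the trait rate matrix per unit time and ``r_b`` a positive
per-branch rate multiplier drawn from a relaxed morphological clock
(strict / UCLN / ACLN; see :mod:`segmorph.ratemodel`).  The root state
has a uniform prior on (0, 1) per segment; per-segment rates carry
lognormal priors.

Inference is Metropolis-within-Gibbs on the augmented state (rates,
rates' hyperparameter, per-segment rates of ``Sigma``, and all internal
node states, the latter updated from their exact Gaussian full
conditionals).  UCLN log-rates are kept centred (mean zero) by
exchange-type proposals so that ``Sigma`` carries the overall scale.

The public surface is statsmodels-like: build a
:class:`SegmentEvolutionModel` from a tree and a species x segment trait
table, call :meth:`~SegmentEvolutionModel.fit` to obtain a
:class:`SegmentEvolutionResults` carrying posterior samples, effective
sample sizes and summaries; ancestral states, per-branch normalised
changes, rate correlations and stepping-stone marginal likelihoods hang
off the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidArgumentError
from .ratemodel import BranchRateModel
from .trees import Phylogeny

__all__ = [
    "Priors",
    "SegmentEvolutionModel",
    "SegmentEvolutionResults",
    "BranchChangeSummary",
    "bm_loglik",
    "run_mcmc",
    "ancestral_states",
    "branch_changes",
    "segment_rate_correlations",
    "marginal_likelihood",
    "MarginalLikelihoodResult",
]

LN2PI = np.log(2.0 * np.pi)


@dataclass
class Priors:
    """Prior configuration for segment-evolution inference.

    ``sigma2`` per segment is lognormal with the given base-10 log median
    and s.d.; the UCLN log-rate spread ``s_r`` and the ACLN drift variance
    ``nu`` are exponential; the root state is uniform per segment.
    """

    sigma2_log10_median: float = -2.0
    sigma2_log10_sd: float = 1.0
    s_r_mean: float = 0.587
    nu_mean: float = 1.0
    root_low: float = 0.0
    root_high: float = 1.0

    def log_prior_sigma2(self, log_sigma2):
        mu = self.sigma2_log10_median * np.log(10.0)
        sd = self.sigma2_log10_sd * np.log(10.0)
        return float(np.sum(-0.5 * ((log_sigma2 - mu) / sd) ** 2))

    def log_prior_s_r(self, s_r):
        if s_r <= 0:
            return -np.inf
        return -s_r / self.s_r_mean

    def log_prior_nu(self, nu):
        if nu <= 0:
            return -np.inf
        return -nu / self.nu_mean


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def bm_loglik(tree, tip_means, sigma2, rates=None, root="integrated"):
    """Brownian-motion log-likelihood by postorder pruning (contrasts).

    Parameters
    ----------
    tree : Phylogeny
    tip_means : DataFrame or ndarray
        Species x trait matrix; a DataFrame is aligned to the tree's tip
        labels (an error lists any missing species).
    sigma2 : float or (p, p) ndarray
        Trait rate matrix per unit time (PSD).
    rates : ndarray or None
        Per-branch rate multipliers in ``tree.branch_nodes`` order; None
        means a strict clock (all 1).
    root : "integrated" or array
        "integrated" marginalises the root with an improper flat prior
        (the REML / independent-contrasts likelihood); an array fixes the
        root state.

    Returns
    -------
    float
    """
    X = _align_tips(tree, tip_means)
    n, p = X.shape
    sigma2 = np.atleast_2d(np.asarray(sigma2, dtype=float))
    if sigma2.shape != (p, p):
        raise InvalidArgumentError(f"sigma2 must be {p}x{p} to match {p} traits")
    sign, logdet = np.linalg.slogdet(sigma2)
    if sign <= 0:
        raise InvalidArgumentError("sigma2 must be positive definite for likelihood evaluation")
    sig_inv = np.linalg.inv(sigma2)
    u = tree.branch_length.copy()
    if rates is not None:
        rates = np.asarray(rates, dtype=float)
        pos = {v: i for i, v in enumerate(tree.branch_nodes)}
        for v in tree.branch_nodes:
            u[v] = u[v] * rates[pos[v]]

    value = np.zeros((tree.n_nodes, p))
    extra = np.zeros(tree.n_nodes)
    value[:n] = X
    ll = 0.0
    for v in tree.postorder:
        if v < n:
            continue
        kids = tree.children(v)
        if len(kids) == 1:
            c = kids[0]
            value[v] = value[c]
            extra[v] = extra[c] + u[c]
            continue
        c1, c2 = kids
        v1 = extra[c1] + u[c1]
        v2 = extra[c2] + u[c2]
        d = value[c1] - value[c2]
        vv = v1 + v2
        quad = d @ sig_inv @ d
        ll += -0.5 * (p * (LN2PI + np.log(vv)) + logdet + quad / vv)
        value[v] = (v2 * value[c1] + v1 * value[c2]) / vv
        extra[v] = v1 * v2 / vv
    if isinstance(root, str):
        if root != "integrated":
            raise InvalidArgumentError("root must be 'integrated' or an array")
        return float(ll)
    mu = np.atleast_1d(np.asarray(root, dtype=float))
    v0 = extra[tree.root]
    d = value[tree.root] - mu
    if v0 <= 0:
        if np.any(np.abs(d) > 1e-12):
            return -np.inf
        return float(ll)
    quad = d @ sig_inv @ d
    ll += -0.5 * (p * (LN2PI + np.log(v0)) + logdet + quad / v0)
    return float(ll)


def _align_tips(tree, tip_means):
    if isinstance(tip_means, pd.DataFrame):
        missing = [s for s in tree.tip_labels if s not in tip_means.index]
        if missing:
            raise DataError(f"trait table is missing species: {missing}")
        X = tip_means.loc[tree.tip_labels].to_numpy(dtype=float)
    else:
        X = np.asarray(tip_means, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != tree.n_tips:
            raise DataError(f"expected {tree.n_tips} rows of tip data, got {X.shape[0]}")
    return X


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class SegmentEvolutionModel:
    """Multivariate Brownian motion with a relaxed morphological clock.

    Parameters
    ----------
    tree : Phylogeny
        Fixed rooted ultrametric tree.
    tip_means : DataFrame or ndarray
        Species x segment trait means (relative positions); DataFrame rows
        are aligned to the tree's tip labels.
    rate_model : BranchRateModel
    priors : Priors
    tip_se : array or None
        Optional known standard error per tip (scalar per species),
        inflating the terminal-branch variance of every trait.
    """

    def __init__(self, tree, tip_means, rate_model=None, priors=None, tip_se=None, correlations=False):
        self.tree = tree
        self.X_tips = _align_tips(tree, tip_means)
        self.n_tips, self.p = self.X_tips.shape
        if isinstance(tip_means, pd.DataFrame):
            self.trait_names = list(tip_means.columns)
        else:
            self.trait_names = [f"trait{j + 1}" for j in range(self.p)]
        self.rate_model = rate_model or BranchRateModel("ucln")
        self.priors = priors or Priors()
        self.correlations = bool(correlations)
        if self.correlations and self.p < 2:
            raise InvalidArgumentError("correlation estimation needs >= 2 traits")
        if self.correlations and self.rate_model.kind == "ucln_per_segment":
            raise InvalidArgumentError(
                "full trait-rate matrix needs branch rates shared across segments"
            )
        if self.correlations and tip_se is not None:
            raise InvalidArgumentError("tip_se is only supported with a diagonal rate matrix")
        self.tip_se = None if tip_se is None else np.asarray(tip_se, dtype=float)
        if self.tip_se is not None and self.tip_se.shape != (self.n_tips,):
            raise InvalidArgumentError("tip_se must have one entry per tip")
        self.branch_nodes = tree.branch_nodes
        self._bpos = {v: i for i, v in enumerate(self.branch_nodes)}
        self.t_b = tree.branch_length[self.branch_nodes]

    def loglik(self, sigma2, rates=None, root="integrated"):
        """Pruning log-likelihood at given parameters (marginal over node states)."""
        return bm_loglik(self.tree, self.X_tips, sigma2, rates=rates, root=root)

    @classmethod
    def from_dataframe(cls, tree, df, segments=None, **kwargs):
        """Build from a species x segment DataFrame (optionally a column subset)."""
        if segments is not None:
            df = df[segments]
        return cls(tree, df, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self, n_iter=20_000, thin=10, burnin=0.1, seed=0, ess_warn=200, start=None):
        """Run the Metropolis-within-Gibbs sampler.

        Returns
        -------
        SegmentEvolutionResults
        """
        if n_iter < 1:
            raise InvalidArgumentError("n_iter must be >= 1")
        sampler = _GibbsSampler(self, seed=seed, start=start)
        n_burn = int(round(burnin * n_iter))
        keep_iters = [i for i in range(n_iter) if i >= n_burn and (i - n_burn) % thin == 0]
        if not keep_iters:
            keep_iters = [n_iter - 1]
        samples = sampler.run(n_iter, keep_iters)
        return SegmentEvolutionResults(self, samples, sampler.acceptance(), ess_warn=ess_warn, seed=seed)


class _GibbsSampler:
    """Internal augmented-state sampler (diagonal Sigma path).

    The state is (log_sigma2 per trait, log_rates, hyperparameter, node
    states).  Branch-increment variances are kept as a (B, p) matrix so
    every conditional density is a cheap vectorised Gaussian.
    """

    def __init__(self, model, seed=0, start=None):
        m = self.model = model
        self.rng = np.random.default_rng(seed)
        tree = m.tree
        self.B = len(m.branch_nodes)
        self.p = m.p
        kind = m.rate_model.kind
        self.per_segment_rates = kind == "ucln_per_segment"
        self.kind = kind
        # state
        self.log_sigma2 = np.full(m.p, m.priors.sigma2_log10_median * np.log(10.0))
        shape = (self.B, m.p) if self.per_segment_rates else (self.B,)
        self.log_rates = np.zeros(shape)
        self.s_r = m.rate_model.s_r if kind in ("ucln", "ucln_per_segment") else None
        self.nu = m.rate_model.nu if kind == "acln" else None
        self.X = np.zeros((tree.n_nodes, m.p))
        self.X[: m.n_tips] = m.X_tips
        # initialise internal states at the average of descendant tips
        for v in tree.postorder:
            if v >= m.n_tips:
                kids = tree.children(v)
                self.X[v] = np.mean([self.X[c] for c in kids], axis=0)
        if start:
            for k, val in start.items():
                setattr(self, k, np.asarray(val, dtype=float) if np.ndim(val) else val)
        # structure tables
        self.internal_nodes = [v for v in tree.postorder if v >= m.n_tips]
        self.neighbors = []  # per internal node: list of (node, branch_index, is_parent)
        for v in self.internal_nodes:
            nb = [(c, m._bpos[c]) for c in tree.children(v)]
            if v != tree.root:
                nb.append((tree.parent[v], m._bpos[v]))
            self.neighbors.append(nb)
        self.is_tip_branch = np.array([v < m.n_tips for v in m.branch_nodes])
        self.tip_se2 = None
        if m.tip_se is not None:
            se2 = np.zeros(self.B)
            for v in m.branch_nodes:
                if v < m.n_tips:
                    se2[m._bpos[v]] = m.tip_se[v] ** 2
            self.tip_se2 = se2
        # ACLN branch parent-branch index (-1 for root children)
        self.branch_parent = np.array(
            [m._bpos.get(tree.parent[v], -1) for v in m.branch_nodes]
        )
        # full trait-rate matrix mode (separation strategy): per-segment
        # rates on the diagonal plus an explicitly sampled correlation matrix
        self.full = bool(getattr(m, "correlations", False))
        if self.full:
            self.R = np.eye(m.p)
            self._refresh_sigma()
        # proposal scales
        self.step_sigma = 0.4
        self.step_rate = 0.5
        self.step_hyper = 0.3
        self.step_corr = 0.08
        self.acc = {"sigma2": [0, 0], "rates": [0, 0], "hyper": [0, 0], "corr": [0, 0]}

    @staticmethod
    def _sigma_parts(log_sigma2, R):
        d = np.exp(0.5 * log_sigma2)
        sig = d[:, None] * R * d[None, :]
        chol = np.linalg.cholesky(sig)  # raises if not PD
        inv = np.linalg.inv(sig)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return sig, chol, inv, logdet

    def _refresh_sigma(self):
        self.Sigma, self.Sigma_chol, self.Sigma_inv, self.Sigma_logdet = self._sigma_parts(
            self.log_sigma2, self.R
        )

    # -- variance bookkeeping --------------------------------------------

    def branch_variances(self, log_sigma2=None, log_rates=None):
        """(B, p) per-branch per-trait increment variances."""
        ls = self.log_sigma2 if log_sigma2 is None else log_sigma2
        lr = self.log_rates if log_rates is None else log_rates
        t = self.model.t_b
        if self.per_segment_rates:
            V = t[:, None] * np.exp(lr) * np.exp(ls)[None, :]
        else:
            V = (t * np.exp(lr))[:, None] * np.exp(ls)[None, :]
        if self.tip_se2 is not None:
            V = V + self.tip_se2[:, None]
        return V

    def deltas(self):
        """(B, p) branch increments child - parent."""
        tree = self.model.tree
        child = self.model.branch_nodes
        return self.X[child] - self.X[tree.parent[child]]

    def data_loglik(self, V=None, D=None):
        V = self.branch_variances() if V is None else V
        D = self.deltas() if D is None else D
        return float(np.sum(-0.5 * (LN2PI + np.log(V) + D * D / V)))

    # -- updates ----------------------------------------------------------

    def update_nodes(self):
        V = self.branch_variances()
        rng = self.rng
        tree = self.model.tree
        lo, hi = self.model.priors.root_low, self.model.priors.root_high
        for v, nb in zip(self.internal_nodes, self.neighbors):
            w = np.zeros(self.p)
            mean = np.zeros(self.p)
            for node, bi in nb:
                wi = 1.0 / V[bi]
                w += wi
                mean += wi * self.X[node]
            mean /= w
            sd = 1.0 / np.sqrt(w)
            if v == tree.root:
                for _ in range(50):
                    cand = mean + sd * rng.standard_normal(self.p)
                    if np.all((cand > lo) & (cand < hi)):
                        self.X[v] = cand
                        break
            else:
                self.X[v] = mean + sd * rng.standard_normal(self.p)

    def update_sigma2(self):
        D = self.deltas()
        V = self.branch_variances()
        cur_ll = -0.5 * np.sum(LN2PI + np.log(V) + D * D / V, axis=0)  # per trait
        priors = self.model.priors
        mu = priors.sigma2_log10_median * np.log(10.0)
        sd = priors.sigma2_log10_sd * np.log(10.0)
        for j in range(self.p):
            prop = self.log_sigma2.copy()
            prop[j] += self.rng.normal(0.0, self.step_sigma)
            Vp = self.branch_variances(log_sigma2=prop)
            new_ll = -0.5 * np.sum(LN2PI + np.log(Vp[:, j]) + D[:, j] ** 2 / Vp[:, j])
            logr = (
                new_ll - cur_ll[j]
                - 0.5 * ((prop[j] - mu) / sd) ** 2
                + 0.5 * ((self.log_sigma2[j] - mu) / sd) ** 2
            )
            self.acc["sigma2"][1] += 1
            if np.log(self.rng.random()) < logr:
                self.log_sigma2 = prop
                cur_ll[j] = new_ll
                self.acc["sigma2"][0] += 1

    def _branch_loglik_terms(self, lr):
        D = self.deltas()
        V = self.branch_variances(log_rates=lr)
        return -0.5 * np.sum(LN2PI + np.log(V) + D * D / V, axis=1)  # per branch

    def update_rates(self):
        if self.kind == "strict":
            return
        rng = self.rng
        if self.kind == "acln":
            self._update_rates_acln()
            return
        if self.per_segment_rates:
            self._update_rates_per_segment()
            return
        # centred UCLN: exchange moves preserve mean(log r) = 0
        terms = self._branch_loglik_terms(self.log_rates)
        order = rng.permutation(self.B)
        s2 = self.s_r ** 2
        for k in range(0, self.B - 1, 2):
            i, j = order[k], order[k + 1]
            delta = rng.normal(0.0, self.step_rate)
            prop = self.log_rates.copy()
            prop[i] += delta
            prop[j] -= delta
            new_terms = self._branch_loglik_terms(prop)
            d_ll = (new_terms[i] + new_terms[j]) - (terms[i] + terms[j])
            d_prior = -0.5 * (prop[i] ** 2 + prop[j] ** 2 - self.log_rates[i] ** 2 - self.log_rates[j] ** 2) / s2
            self.acc["rates"][1] += 1
            if np.log(rng.random()) < d_ll + d_prior:
                self.log_rates = prop
                terms = new_terms
                self.acc["rates"][0] += 1

    def _update_rates_per_segment(self):
        rng = self.rng
        D = self.deltas()
        s2 = self.s_r ** 2
        t = self.model.t_b
        sig = np.exp(self.log_sigma2)
        for j in range(self.p):
            order = rng.permutation(self.B)
            for k in range(0, self.B - 1, 2):
                i1, i2 = order[k], order[k + 1]
                delta = rng.normal(0.0, self.step_rate)
                cur = self.log_rates[:, j]

                def term(b, lval):
                    V = t[b] * np.exp(lval) * sig[j]
                    if self.tip_se2 is not None:
                        V = V + self.tip_se2[b]
                    return -0.5 * (LN2PI + np.log(V) + D[b, j] ** 2 / V)

                d_ll = (
                    term(i1, cur[i1] + delta) + term(i2, cur[i2] - delta)
                    - term(i1, cur[i1]) - term(i2, cur[i2])
                )
                d_prior = -0.5 * ((cur[i1] + delta) ** 2 + (cur[i2] - delta) ** 2 - cur[i1] ** 2 - cur[i2] ** 2) / s2
                self.acc["rates"][1] += 1
                if np.log(rng.random()) < d_ll + d_prior:
                    self.log_rates[i1, j] += delta
                    self.log_rates[i2, j] -= delta
                    self.acc["rates"][0] += 1

    def _update_rates_acln(self):
        rng = self.rng
        terms = self._branch_loglik_terms(self.log_rates)
        t = self.model.t_b
        for i in rng.permutation(self.B):
            delta = rng.normal(0.0, self.step_rate)
            prop = self.log_rates.copy()
            prop[i] += delta

            def chain_lp(lr):
                base = np.where(self.branch_parent >= 0, lr[np.maximum(self.branch_parent, 0)], 0.0)
                return np.sum(-0.5 * (lr - base) ** 2 / (self.nu * t) - 0.5 * np.log(self.nu * t))

            new_terms = self._branch_loglik_terms(prop)
            logr = new_terms[i] - terms[i] + chain_lp(prop) - chain_lp(self.log_rates)
            self.acc["rates"][1] += 1
            if np.log(rng.random()) < logr:
                self.log_rates = prop
                terms = new_terms
                self.acc["rates"][0] += 1

    def update_hyper(self):
        rng = self.rng
        priors = self.model.priors
        if self.kind in ("ucln", "ucln_per_segment"):
            lr = self.log_rates.ravel() if self.per_segment_rates else self.log_rates
            n_groups = self.p if self.per_segment_rates else 1
            cand = self.s_r * np.exp(rng.normal(0.0, self.step_hyper))

            def lp(s):
                # iid N(0, s) on log-rates conditioned on zero mean per group:
                # the conditioning contributes +log(s) per group
                return (
                    np.sum(-0.5 * (lr / s) ** 2 - np.log(s))
                    + n_groups * np.log(s)
                    + priors.log_prior_s_r(s)
                )

            logr = lp(cand) - lp(self.s_r) + np.log(cand) - np.log(self.s_r)
            self.acc["hyper"][1] += 1
            if np.log(rng.random()) < logr:
                self.s_r = cand
                self.acc["hyper"][0] += 1
        elif self.kind == "acln":
            t = self.model.t_b
            lr = self.log_rates
            base = np.where(self.branch_parent >= 0, lr[np.maximum(self.branch_parent, 0)], 0.0)
            ss = np.sum((lr - base) ** 2 / t)
            cand = self.nu * np.exp(rng.normal(0.0, self.step_hyper))

            def lp(nu):
                return -0.5 * ss / nu - 0.5 * self.B * np.log(nu) + priors.log_prior_nu(nu)

            logr = lp(cand) - lp(self.nu) + np.log(cand) - np.log(self.nu)
            self.acc["hyper"][1] += 1
            if np.log(rng.random()) < logr:
                self.nu = cand
                self.acc["hyper"][0] += 1

    # -- full trait-rate-matrix (separation strategy) updates -------------

    def _branch_u(self):
        return self.model.t_b * np.exp(self.log_rates)

    def update_nodes_full(self):
        u = self._branch_u()
        rng = self.rng
        tree = self.model.tree
        lo, hi = self.model.priors.root_low, self.model.priors.root_high
        for v, nb in zip(self.internal_nodes, self.neighbors):
            W = 0.0
            mean = np.zeros(self.p)
            for node, bi in nb:
                wi = 1.0 / u[bi]
                W += wi
                mean += wi * self.X[node]
            mean /= W
            scale = self.Sigma_chol / np.sqrt(W)
            if v == tree.root:
                for _ in range(50):
                    cand = mean + scale @ rng.standard_normal(self.p)
                    if np.all((cand > lo) & (cand < hi)):
                        self.X[v] = cand
                        break
            else:
                self.X[v] = mean + scale @ rng.standard_normal(self.p)

    def _full_loglik(self, inv, logdet, M, u):
        return -0.5 * (self.B * logdet + float(np.sum(inv * M)) + self.p * float(np.sum(np.log(u))))

    def update_sigma2_full(self, M, u):
        priors = self.model.priors
        mu = priors.sigma2_log10_median * np.log(10.0)
        sd = priors.sigma2_log10_sd * np.log(10.0)
        cur = self._full_loglik(self.Sigma_inv, self.Sigma_logdet, M, u)
        for j in range(self.p):
            prop = self.log_sigma2.copy()
            prop[j] += self.rng.normal(0.0, self.step_sigma)
            _, _, inv_p, logdet_p = self._sigma_parts(prop, self.R)
            new = self._full_loglik(inv_p, logdet_p, M, u)
            logr = (new - cur
                    - 0.5 * ((prop[j] - mu) / sd) ** 2
                    + 0.5 * ((self.log_sigma2[j] - mu) / sd) ** 2)
            self.acc["sigma2"][1] += 1
            if np.log(self.rng.random()) < logr:
                self.log_sigma2 = prop
                self._refresh_sigma()
                cur = new
                self.acc["sigma2"][0] += 1

    def update_correlations(self, M, u):
        # uniform prior over the space of positive-definite correlation
        # matrices; pairwise random-walk proposals with a PD check
        rng = self.rng
        cur = self._full_loglik(self.Sigma_inv, self.Sigma_logdet, M, u)
        n_moves = max(1, self.p * (self.p - 1) // 4)
        for _ in range(n_moves):
            j, k = rng.choice(self.p, size=2, replace=False)
            prop = self.R.copy()
            val = prop[j, k] + rng.normal(0.0, self.step_corr)
            if not -1.0 < val < 1.0:
                continue
            prop[j, k] = prop[k, j] = val
            try:
                _, _, inv_p, logdet_p = self._sigma_parts(self.log_sigma2, prop)
            except np.linalg.LinAlgError:
                continue
            new = self._full_loglik(inv_p, logdet_p, M, u)
            self.acc["corr"][1] += 1
            if np.log(rng.random()) < new - cur:
                self.R = prop
                self._refresh_sigma()
                cur = new
                self.acc["corr"][0] += 1

    def update_rates_full(self, D):
        if self.kind == "strict":
            return
        rng = self.rng
        t = self.model.t_b
        quad = np.einsum("bi,ij,bj->b", D, self.Sigma_inv, D)
        lr = self.log_rates
        s2 = self.s_r ** 2 if self.s_r is not None else None

        def term(i, l):
            u = t[i] * np.exp(l)
            return -0.5 * (self.p * np.log(u) + quad[i] / u)

        if self.kind == "ucln":
            order = rng.permutation(self.B)
            for k in range(0, self.B - 1, 2):
                i, j = order[k], order[k + 1]
                delta = rng.normal(0.0, self.step_rate)
                d_ll = (term(i, lr[i] + delta) + term(j, lr[j] - delta)
                        - term(i, lr[i]) - term(j, lr[j]))
                d_prior = -0.5 * ((lr[i] + delta) ** 2 + (lr[j] - delta) ** 2
                                  - lr[i] ** 2 - lr[j] ** 2) / s2
                self.acc["rates"][1] += 1
                if np.log(rng.random()) < d_ll + d_prior:
                    lr[i] += delta
                    lr[j] -= delta
                    self.acc["rates"][0] += 1
        else:  # acln: single-branch moves with the chain prior
            for i in rng.permutation(self.B):
                delta = rng.normal(0.0, self.step_rate)
                prop = lr.copy()
                prop[i] += delta

                def chain_lp(l):
                    base = np.where(self.branch_parent >= 0, l[np.maximum(self.branch_parent, 0)], 0.0)
                    return np.sum(-0.5 * (l - base) ** 2 / (self.nu * t))

                logr = term(i, prop[i]) - term(i, lr[i]) + chain_lp(prop) - chain_lp(lr)
                self.acc["rates"][1] += 1
                if np.log(rng.random()) < logr:
                    self.log_rates = lr = prop
                    self.acc["rates"][0] += 1

    def data_loglik_full(self):
        D = self.deltas()
        u = self._branch_u()
        M = np.einsum("bi,bj,b->ij", D, D, 1.0 / u)
        return self._full_loglik(self.Sigma_inv, self.Sigma_logdet, M, u) - 0.5 * self.B * self.p * LN2PI

    def sweep(self):
        if self.full:
            self.update_nodes_full()
            D = self.deltas()
            u = self._branch_u()
            M = np.einsum("bi,bj,b->ij", D, D, 1.0 / u)
            self.update_sigma2_full(M, u)
            self.update_correlations(M, u)
            self.update_rates_full(D)
            self.update_hyper()
        else:
            self.update_nodes()
            self.update_sigma2()
            self.update_rates()
            self.update_hyper()

    def run(self, n_iter, keep_iters):
        keep = set(keep_iters)
        out = {
            "sigma2": [], "rates": [], "node_states": [], "hyper": [], "loglik": [],
        }
        if self.full:
            out["correlations"] = []
        for it in range(n_iter):
            self.sweep()
            if it in keep:
                out["sigma2"].append(np.exp(self.log_sigma2.copy()))
                out["rates"].append(np.exp(np.array(self.log_rates, copy=True)))
                out["node_states"].append(self.X.copy())
                out["hyper"].append(self.s_r if self.s_r is not None else (self.nu if self.nu is not None else np.nan))
                if self.full:
                    out["correlations"].append(self.R.copy())
                    out["loglik"].append(self.data_loglik_full())
                else:
                    out["loglik"].append(self.data_loglik())
        return {k: np.asarray(v) for k, v in out.items()}

    def acceptance(self):
        return {k: (a / t if t else np.nan) for k, (a, t) in self.acc.items()}


@dataclass
class BranchChangeSummary:
    """Posterior normalised change per branch and segment.

    ``per_branch`` columns: branch (child-node id), child label where the
    child is a tip, segment, mean, q2.5, q97.5 of
    ``c_b = |x_child - x_parent| / t_b``.  ``pooled`` is the flat array of
    all posterior samples of ``c_b`` across branches and segments.
    """

    per_branch: pd.DataFrame
    pooled: np.ndarray


class SegmentEvolutionResults:
    """Posterior sample container with statsmodels-flavoured summaries."""

    def __init__(self, model, samples, acceptance, ess_warn=200, seed=None):
        self.model = model
        self.samples = samples
        self.acceptance = acceptance
        self.seed = seed
        self.warnings = []
        self.ess = self._compute_ess()
        low = {k: v for k, v in self.ess.items() if np.isfinite(v) and v < ess_warn}
        if low and len(samples["loglik"]) > 1:
            self.warnings.append(
                f"low effective sample size (< {ess_warn}) for: "
                + ", ".join(sorted(low)[:8])
                + ("..." if len(low) > 8 else "")
            )

    # -- diagnostics -------------------------------------------------------

    def _compute_ess(self):
        import arviz as az

        ess = {}
        s = self.samples
        n = len(s["loglik"])
        if n < 4:
            for j in range(self.model.p):
                ess[f"sigma2[{self.model.trait_names[j]}]"] = float("nan")
            return ess
        for j in range(self.model.p):
            ess[f"sigma2[{self.model.trait_names[j]}]"] = float(az.ess(np.asarray(s["sigma2"][:, j])))
        if self.model.rate_model.kind != "strict":
            ess["rate_hyperparameter"] = float(az.ess(np.asarray(s["hyper"], dtype=float)))
            flat_rates = s["rates"].reshape(n, -1)
            for b in range(min(flat_rates.shape[1], 64)):
                ess[f"rate[{b}]"] = float(az.ess(flat_rates[:, b]))
        ess["loglik"] = float(az.ess(np.asarray(s["loglik"])))
        return ess

    @property
    def n_samples(self):
        return len(self.samples["loglik"])

    def sigma2_frame(self):
        return pd.DataFrame(self.samples["sigma2"], columns=self.model.trait_names)

    def rate_frame(self):
        r = self.samples["rates"]
        if r.ndim == 3:
            cols = [f"b{v}:{t}" for v in self.model.branch_nodes for t in self.model.trait_names]
            return pd.DataFrame(r.reshape(len(r), -1), columns=cols)
        return pd.DataFrame(r, columns=[f"b{v}" for v in self.model.branch_nodes])

    def summary(self):
        """Posterior summary table (mean, sd, 95% CI, ESS) per parameter."""
        rows = []
        s2 = self.sigma2_frame()
        for c in s2.columns:
            x = s2[c].to_numpy()
            rows.append((f"sigma2[{c}]", x.mean(), x.std(ddof=1) if len(x) > 1 else np.nan,
                         *np.percentile(x, [2.5, 97.5]), self.ess.get(f"sigma2[{c}]", np.nan)))
        if self.model.rate_model.kind != "strict":
            h = np.asarray(self.samples["hyper"], dtype=float)
            name = "s_r" if self.model.rate_model.kind.startswith("ucln") else "nu"
            rows.append((name, h.mean(), h.std(ddof=1) if len(h) > 1 else np.nan,
                         *np.percentile(h, [2.5, 97.5]), self.ess.get("rate_hyperparameter", np.nan)))
            rf = self.rate_frame()
            for c in rf.columns:
                x = rf[c].to_numpy()
                rows.append((f"rate[{c}]", x.mean(), x.std(ddof=1) if len(x) > 1 else np.nan,
                             *np.percentile(x, [2.5, 97.5]), np.nan))
        df = pd.DataFrame(rows, columns=["parameter", "mean", "sd", "ci95_low", "ci95_high", "ess"])
        return df.set_index("parameter")

    # -- scientific summaries ---------------------------------------------

    def ancestral_states(self):
        return ancestral_states(self)

    def branch_changes(self):
        return branch_changes(self, self.model.tree)

    def trait_correlations(self, mean_positions=None):
        """Posterior summary of the trait-rate correlation matrix.

        Only available for fits with ``correlations=True``.  Returns one
        row per trait pair with the posterior mean and 95% CI of the
        correlation, the index separation, and (when ``mean_positions``
        is given) the anatomical distance between the two segments.
        """
        if "correlations" not in self.samples:
            raise InvalidArgumentError("fit the model with correlations=True to sample the trait-rate matrix")
        R = self.samples["correlations"]
        names = self.model.trait_names
        rows = []
        for a in range(self.model.p):
            for b in range(a + 1, self.model.p):
                x = R[:, a, b]
                lo, hi = np.percentile(x, [2.5, 97.5])
                dist = (
                    abs(mean_positions[a] - mean_positions[b])
                    if mean_positions is not None else np.nan
                )
                rows.append((names[a], names[b], x.mean(), lo, hi, b - a, dist))
        return pd.DataFrame(
            rows, columns=["trait_a", "trait_b", "mean_r", "ci95_low", "ci95_high", "separation", "distance"]
        )

    def credible_interval(self, name="sigma2", trait=0, level=0.95):
        x = self.samples[name][:, trait] if self.samples[name].ndim > 1 else self.samples[name]
        a = 100 * (1 - level) / 2
        return tuple(np.percentile(x, [a, 100 - a]))


def run_mcmc(tree, tip_means, model=None, priors=None, n_iter=20_000, thin=10, burnin=0.1, seed=0, tip_se=None):
    """Functional wrapper: build a model and fit it."""
    m = SegmentEvolutionModel(tree, tip_means, rate_model=model, priors=priors, tip_se=tip_se)
    return m.fit(n_iter=n_iter, thin=thin, burnin=burnin, seed=seed)


def ancestral_states(results):
    """Posterior mean and 95% CI for every node and segment."""
    s = results.samples["node_states"]  # (n, n_nodes, p)
    tree = results.model.tree
    rows = []
    for v in range(tree.n_nodes):
        for j, tname in enumerate(results.model.trait_names):
            x = s[:, v, j]
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append(
                (v, tree.tip_labels[v] if v < tree.n_tips else ("root" if v == tree.root else ""),
                 tname, x.mean(), lo, hi, v < tree.n_tips)
            )
    return pd.DataFrame(rows, columns=["node", "label", "segment", "mean", "ci95_low", "ci95_high", "is_tip"])


def branch_changes(results, tree=None):
    """Normalised per-branch change ``|x_child - x_parent| / t_b``."""
    tree = tree or results.model.tree
    s = results.samples["node_states"]
    child = results.model.branch_nodes
    t = tree.branch_length[child]
    C = np.abs(s[:, child, :] - s[:, tree.parent[child], :]) / t[None, :, None]
    rows = []
    for i, v in enumerate(child):
        for j, tname in enumerate(results.model.trait_names):
            x = C[:, i, j]
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append((int(v), tree.tip_labels[v] if v < tree.n_tips else "", tname, x.mean(), lo, hi))
    per_branch = pd.DataFrame(rows, columns=["branch", "child_label", "segment", "mean", "q2.5", "q97.5"])
    return BranchChangeSummary(per_branch=per_branch, pooled=C.ravel())


def segment_rate_correlations(posteriors, mean_positions):
    """Correlation of per-branch rates between segments vs anatomical distance.

    Parameters
    ----------
    posteriors : sequence of SegmentEvolutionResults
        One per segment, all fitted on the same tree.
    mean_positions : array
        Across-species mean relative position of each segment.

    Returns
    -------
    DataFrame
        Per segment pair: Pearson r of posterior-mean log branch rates and
        the anatomical distance between the two segments.
    """
    from scipy import stats as sps

    if len(posteriors) < 2:
        raise InvalidArgumentError("need at least two per-segment posteriors")
    trees = {id(r.model.tree) for r in posteriors}
    if len(trees) > 1:
        # identity check is too strict for equal trees loaded twice; compare topology
        nwk = {r.model.tree.to_newick() for r in posteriors}
        if len(nwk) > 1:
            raise InvalidArgumentError("all posteriors must be fitted on the same tree")
    B = posteriors[0].model.tree.n_branches
    if B < 3:
        raise InvalidArgumentError("need >= 3 branches to correlate rates")
    mean_positions = np.asarray(mean_positions, dtype=float)
    logr = []
    for r in posteriors:
        rs = r.samples["rates"]
        if rs.ndim == 3:
            rs = rs[:, :, 0]
        logr.append(np.log(rs).mean(axis=0))
    rows = []
    n = len(posteriors)
    for a in range(n):
        for b in range(a + 1, n):
            res = sps.pearsonr(logr[a], logr[b])
            rows.append((a + 1, b + 1, float(res.statistic), abs(mean_positions[a] - mean_positions[b]), b - a))
    return pd.DataFrame(rows, columns=["segment_a", "segment_b", "r", "distance", "separation"])


# ---------------------------------------------------------------------------
# marginal likelihood by stepping-stone sampling
# ---------------------------------------------------------------------------

@dataclass
class MarginalLikelihoodResult:
    log_marginal: float
    mc_error: float
    n_stones: int
    stone_ess: list = field(default_factory=list)
    flags: list = field(default_factory=list)


class _StoneSampler:
    """Random-walk sampler in (root, log_sigma2, log_rates, hyper) space.

    Uses the pruning likelihood with the root treated as a parameter with
    a proper uniform prior, so the tempered target ``prior * L^beta`` is
    normalised at beta = 0.
    """

    def __init__(self, model, rng):
        self.m = model
        self.rng = rng
        self.kind = model.rate_model.kind
        self.B = len(model.branch_nodes)
        self.p = model.p

    def sample_prior(self):
        m, rng = self.m, self.rng
        pr = m.priors
        state = {
            "root": rng.uniform(pr.root_low, pr.root_high, size=self.p),
            "log_sigma2": rng.normal(pr.sigma2_log10_median * np.log(10.0),
                                     pr.sigma2_log10_sd * np.log(10.0), size=self.p),
        }
        if self.kind in ("ucln",):
            s_r = rng.exponential(pr.s_r_mean)
            lr = rng.normal(0.0, s_r, size=self.B)
            state["s_r"] = s_r
            state["log_rates"] = lr - lr.mean()  # centred draw
        elif self.kind == "acln":
            nu = rng.exponential(pr.nu_mean)
            state["nu"] = nu
            lr = np.zeros(self.B)
            t = self.m.t_b
            bp = [self.m._bpos.get(self.m.tree.parent[v], -1) for v in self.m.branch_nodes]
            for i in np.argsort([self.m.tree.node_depths()[v] for v in self.m.branch_nodes]):
                base = 0.0 if bp[i] < 0 else lr[bp[i]]
                lr[i] = rng.normal(base, np.sqrt(nu * t[i]))
            state["log_rates"] = lr
        else:
            state["log_rates"] = np.zeros(self.B)
        return state

    def loglik(self, state):
        sigma2 = np.diag(np.exp(state["log_sigma2"])) if self.p > 1 else np.exp(state["log_sigma2"][0])
        return bm_loglik(self.m.tree, self.m.X_tips, np.atleast_2d(sigma2),
                         rates=np.exp(state["log_rates"]), root=state["root"])

    def log_prior(self, state):
        m = self.m
        pr = m.priors
        if np.any(state["root"] < pr.root_low) or np.any(state["root"] > pr.root_high):
            return -np.inf
        lp = pr.log_prior_sigma2(state["log_sigma2"])
        if self.kind == "ucln":
            s = state["s_r"]
            if s <= 0:
                return -np.inf
            lr = state["log_rates"]
            lp += pr.log_prior_s_r(s) + np.sum(-0.5 * (lr / s) ** 2 - np.log(s)) + np.log(s)
        elif self.kind == "acln":
            nu = state["nu"]
            if nu <= 0:
                return -np.inf
            t = m.t_b
            lr = state["log_rates"]
            bp = np.array([m._bpos.get(m.tree.parent[v], -1) for v in m.branch_nodes])
            base = np.where(bp >= 0, lr[np.maximum(bp, 0)], 0.0)
            lp += pr.log_prior_nu(nu) + np.sum(-0.5 * (lr - base) ** 2 / (nu * t) - 0.5 * np.log(nu * t))
        return float(lp)

    def step(self, state, beta, cur_lp, cur_ll):
        rng = self.rng
        moves = ["root", "sigma2"]
        if self.kind != "strict":
            moves += ["rates", "hyper"]
        for move in moves:
            prop = {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in state.items()}
            log_hastings = 0.0
            if move == "root":
                j = rng.integers(self.p)
                prop["root"][j] += rng.normal(0.0, 0.05)
            elif move == "sigma2":
                j = rng.integers(self.p)
                prop["log_sigma2"][j] += rng.normal(0.0, 0.4)
            elif move == "rates":
                if self.kind == "ucln":
                    i, j = rng.choice(self.B, size=2, replace=False)
                    d = rng.normal(0.0, 0.4)
                    prop["log_rates"][i] += d
                    prop["log_rates"][j] -= d
                else:
                    i = rng.integers(self.B)
                    prop["log_rates"][i] += rng.normal(0.0, 0.4)
            else:
                key = "s_r" if self.kind == "ucln" else "nu"
                prop[key] = state[key] * np.exp(rng.normal(0.0, 0.3))
                log_hastings = np.log(prop[key]) - np.log(state[key])
            new_lp = self.log_prior(prop)
            if not np.isfinite(new_lp):
                continue
            new_ll = self.loglik(prop)
            logr = (new_lp + beta * new_ll) - (cur_lp + beta * cur_ll) + log_hastings
            if np.log(rng.random()) < logr:
                state, cur_lp, cur_ll = prop, new_lp, new_ll
        return state, cur_lp, cur_ll


def marginal_likelihood(tree, tip_means, model=None, priors=None, n_stones=10,
                        n_iter_per_stone=600, burnin_per_stone=150, seed=0, alpha=0.3):
    """Stepping-stone estimate of the log marginal likelihood.

    Power posteriors at ``beta_k = (k / n_stones)**(1/alpha)`` bridge the
    prior (beta = 0) and posterior (beta = 1); each stone contributes the
    log of an importance-sampling average of ``L^(beta_{k+1} - beta_k)``.
    With ``n_stones = 1`` the estimator degenerates to the harmonic-mean
    family; it is flagged as unreliable but still returns a number.
    """
    m = SegmentEvolutionModel(tree, tip_means, rate_model=model, priors=priors)
    rng = np.random.default_rng(seed)
    sampler = _StoneSampler(m, rng)
    flags = []
    if n_stones < 1:
        raise InvalidArgumentError("n_stones must be >= 1")
    if n_stones == 1:
        # single chain at power 1: harmonic-mean-family estimator
        flags.append("harmonic-mean degenerate case: estimate is unreliable")
        state = sampler.sample_prior()
        lp, ll = sampler.log_prior(state), sampler.loglik(state)
        lls = []
        for it in range(n_iter_per_stone + burnin_per_stone):
            state, lp, ll = sampler.step(state, 1.0, lp, ll)
            if it >= burnin_per_stone:
                lls.append(ll)
        lls = np.array(lls)
        log_ml = -(_logmeanexp(-lls))
        return MarginalLikelihoodResult(float(log_ml), float("nan"), 1, [len(lls)], flags)

    betas = (np.arange(n_stones + 1) / n_stones) ** (1.0 / alpha)
    log_ml = 0.0
    var_total = 0.0
    stone_ess = []
    import arviz as az

    state = sampler.sample_prior()
    lp, ll = sampler.log_prior(state), sampler.loglik(state)
    for k in range(n_stones):
        beta = betas[k]
        dbeta = betas[k + 1] - betas[k]
        if beta == 0.0:
            lls = np.array([sampler.loglik(sampler.sample_prior()) for _ in range(n_iter_per_stone)])
            ess = float(len(lls))
        else:
            # warm start: continue the walk from the previous stone's state
            lls = []
            for it in range(n_iter_per_stone + burnin_per_stone):
                state, lp, ll = sampler.step(state, beta, lp, ll)
                if it >= burnin_per_stone:
                    lls.append(ll)
            lls = np.array(lls)
            ess = float(az.ess(lls)) if len(lls) > 3 and lls.std() > 0 else float(len(lls))
        stone_ess.append(ess)
        if ess < 50:
            flags.append(f"stone {k}: ESS {ess:.0f} < 50")
        w = dbeta * lls
        log_ml += _logmeanexp(w)
        # delta-method MC error on the log of the mean
        ww = np.exp(w - w.max())
        var_total += (ww.var(ddof=1) / (max(ess, 1.0) * ww.mean() ** 2)) if ww.mean() > 0 else 0.0
    return MarginalLikelihoodResult(float(log_ml), float(np.sqrt(var_total)), n_stones, stone_ess, flags)


def _logmeanexp(x):
    x = np.asarray(x, dtype=float)
    mx = x.max()
    return float(mx + np.log(np.mean(np.exp(x - mx))))
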