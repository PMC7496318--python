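"""Branch-rate models for trait evolution on a phylogeny.

A rate model describes how the per-branch multiplier ``r_b`` of the
Brownian trait rate varies over the tree:

``strict``
    all branches share one rate (``r_b = 1``);
``ucln``
    uncorrelated lognormal: each branch's log-rate is an independent
    normal draw, so rates change episodically between ancestor and
    descendant branches;
``acln``
    autocorrelated lognormal: a branch's log-rate diffuses away from its
    parent branch's log-rate with variance ``nu`` per unit time;
``ucln_per_segment``
    as ``ucln``, but each trait (segment) gets its own independent set of
    branch rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError

KINDS = ("strict", "ucln", "acln", "ucln_per_segment")


@dataclass
class BranchRateModel:
    """Prior model for per-branch rate multipliers.

    Parameters
    ----------
    kind : {"strict", "ucln", "acln", "ucln_per_segment"}
    m_r : float
        Mean of log-rates (UCLN family). The default 0 makes the median
        rate 1 so that the trait rate parameter carries the scale.
    s_r : float
        Standard deviation of log-rates (UCLN family).
    nu : float
        Drift variance of the log-rate per unit time (ACLN).
    """

    kind: str = "ucln"
    m_r: float = 0.0
    s_r: float = 0.587
    nu: float = 0.5

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InvalidArgumentError(f"unknown rate model kind {self.kind!r}; choose from {KINDS}")
        if self.s_r < 0:
            raise InvalidArgumentError("s_r must be >= 0")
        if self.nu < 0:
            raise InvalidArgumentError("nu must be >= 0")


def draw_branch_rates(tree, model, rng, n_traits=1):
    """Draw true branch-rate multipliers from a rate model.

    Returns an array of shape ``(n_branches,)`` for shared-rate models or
    ``(n_branches, n_traits)`` for ``ucln_per_segment``.  Branch order
    follows ``tree.branch_nodes``.
    """
    B = tree.n_branches
    if model.kind == "strict":
        return np.ones(B)
    if model.kind == "ucln":
        return np.exp(rng.normal(model.m_r, model.s_r, size=B))
    if model.kind == "ucln_per_segment":
        return np.exp(rng.normal(model.m_r, model.s_r, size=(B, n_traits)))
    # ACLN: log-rate diffuses along the tree; a branch inherits from the
    # branch above its parent node (root children start at m_r).
    branch_nodes = tree.branch_nodes
    pos = {v: i for i, v in enumerate(branch_nodes)}
    logr = np.zeros(B)
    for v in tree.preorder():
        if v == tree.root:
            continue
        p = tree.parent[v]
        base = model.m_r if p == tree.root else logr[pos[p]]
        logr[pos[v]] = rng.normal(base, np.sqrt(model.nu * tree.branch_length[v]))
    return np.exp(logr)
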