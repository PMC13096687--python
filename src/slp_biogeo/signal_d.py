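"""Phylogenetic signal in a binary trait: the D statistic.

D scales the observed sum of sister-clade differences between two
simulated reference points: traits shuffled at random across tips
(no signal, D ~ 1) and traits generated by thresholding Brownian motion
on the tree at the observed prevalence (Brownian conservatism, D ~ 0).
Values below 0 indicate signal stronger than Brownian; values above 1
indicate overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import Phylogeny

__all__ = ["DResult", "sister_clade_sum", "phylo_d", "simulate_bm_tips",
           "threshold_by_rank"]


@dataclass
class DResult:
    D: float
    d_obs: float
    d_random: np.ndarray
    d_brownian: np.ndarray
    p_random: float
    p_brownian: float
    n_sim: int
    seed: int | None

    def as_dict(self):
        return {
            "D": self.D,
            "d_obs": self.d_obs,
            "mean_d_random": float(self.d_random.mean()),
            "mean_d_brownian": float(self.d_brownian.mean()),
            "p_random": self.p_random,
            "p_brownian": self.p_brownian,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _edge_change_sums(tree: Phylogeny, traits: np.ndarray) -> np.ndarray:
    """Sum over edges of |child value - parent value| for each trait column.

    Internal node values are the unweighted mean of their immediate
    children (polytomies average over all children); branch lengths do not
    enter.  ``traits`` is (n_tips, n_columns).
    """
    n_nodes = tree.n_nodes
    n_tips = tree.n_tips
    vals = np.empty((n_nodes, traits.shape[1]))
    vals[:n_tips] = traits
    children = tree.children
    for node in tree.postorder:
        kids = children[node]
        if kids:
            vals[node] = vals[kids].mean(axis=0)
    parent = tree.parent
    has_parent = parent >= 0
    diffs = np.abs(vals[has_parent] - vals[parent[has_parent]])
    return diffs.sum(axis=0)


def sister_clade_sum(tree: Phylogeny, trait) -> float:
    """Observed sum of absolute value changes across all edges."""
    y = np.asarray(trait, dtype=float)
    if y.shape != (tree.n_tips,):
        raise ValueError("trait must align with the tree's tips")
    if len(np.unique(y)) < 2:
        raise ValueError("trait shows no variation")
    return float(_edge_change_sums(tree, y[:, None])[0])


def simulate_bm_tips(tree: Phylogeny, n_sim: int, rng: np.random.Generator,
                     rate: float = 1.0) -> np.ndarray:
    """Brownian tip values: root at 0, variance accruing with branch length.

    Returns an (n_tips, n_sim) array.
    """
    sd = np.sqrt(np.maximum(tree.edge_length, 0.0) * rate)
    incr = rng.standard_normal((tree.n_nodes, n_sim)) * sd[:, None]
    vals = np.zeros((tree.n_nodes, n_sim))
    parent = tree.parent
    for node in tree.postorder[::-1]:  # preorder: parents before children
        p = parent[node]
        if p >= 0:
            vals[node] = vals[p] + incr[node]
    return vals[: tree.n_tips]


def threshold_by_rank(liability: np.ndarray, k: int) -> np.ndarray:
    """Assign state 1 to the k highest liabilities per column.

    Ties are broken by tip index, so simulated prevalence always equals k.
    ``liability`` is (n_tips, n_sim); returns a same-shape 0/1 array.
    """
    order = np.argsort(-liability, axis=0, kind="stable")
    out = np.zeros_like(liability)
    cols = np.arange(liability.shape[1])[None, :]
    out[order[:k], cols] = 1.0
    return out


def phylo_d(tree: Phylogeny, trait, n_sim: int = 1000,
            seed: int | np.random.Generator | None = None) -> DResult:
    """Estimate D for a binary trait with simulated reference distributions.

    ``p_random`` is the fraction of shuffled-trait sums <= the observed sum
    (small when the trait is far more clumped than random); ``p_brownian``
    is the fraction of Brownian-threshold sums >= the observed sum (small
    when the trait is far more clumped than Brownian expectation).
    """
    y = np.asarray(trait, dtype=float)
    if tree.n_tips < 2:
        raise ValueError("tree too small")
    if y.shape != (tree.n_tips,):
        raise ValueError("trait must align with the tree's tips")
    states = np.unique(y)
    if not np.isin(states, (0.0, 1.0)).all() or len(states) < 2:
        raise ValueError("trait must be binary with both states present")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    d_obs = sister_clade_sum(tree, y)

    k = int(y.sum())
    n = tree.n_tips
    # shuffled null: uniform permutations of the observed states
    perms = y[np.argsort(rng.random((n, n_sim)), axis=0)]
    d_random = _edge_change_sums(tree, perms)
    # Brownian threshold null at matched prevalence
    liab = simulate_bm_tips(tree, n_sim, rng)
    d_brownian = _edge_change_sums(tree, threshold_by_rank(liab, k))

    denom = d_random.mean() - d_brownian.mean()
    D = (d_obs - d_brownian.mean()) / denom if denom != 0 else np.nan
    return DResult(
        D=float(D),
        d_obs=d_obs,
        d_random=d_random,
        d_brownian=d_brownian,
        p_random=float((d_random <= d_obs).mean()),
        p_brownian=float((d_brownian >= d_obs).mean()),
        n_sim=n_sim,
        seed=seed_val,
    )
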