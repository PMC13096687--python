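"""Synthetic trees, geography, richness and traits for self-contained runs.

The generator emulates the structure of a genus-level trait/distribution
study: an ultrametric genus tree, a catalog of latitudinally extended
regions with hotspot flags, per-genus occupancy lists whose geography is
phylogenetically structured (related genera share regions, via a Brownian
"home" position evolving on the tree), lognormal species richness, and a
binary trait generated either by thresholding a liability with Brownian
phylogenetic noise or directly from a logistic mean model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import CodingConfig, code_genus
from .io import AnalysisDataset, GenusRecord, RegionCatalog, align_dataset
from .signal_d import simulate_bm_tips
from .tree import Phylogeny

__all__ = ["SimConfig", "simulate_tree", "simulate_geography",
           "simulate_richness", "simulate_trait", "assign_families",
           "make_benchmark", "Benchmark"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``beta`` are liability/logit effects (intercept, tropical, hotspot,
    per-species richness); ``signal_sd`` is the SD of the Brownian liability
    component at the tips (0 = no phylogenetic signal).  ``trait_mode`` is
    ``"liability"`` (threshold model) or ``"logistic"`` (independent
    Bernoulli draws from the logistic mean, for exact calibration of the
    logistic fitters).
    """

    n_tips: int = 500
    tree_model: str = "yule"
    birth: float = 1.0
    death: float = 0.0
    n_regions: int = 120
    tropic_fraction: float = 0.5
    hotspot_fraction: float = 0.4
    occupancy_mean: float = 4.0
    richness_logmean: float = 2.5
    richness_logsd: float = 1.5
    beta: tuple[float, float, float, float] = (-2.5, 0.5, 0.0, 0.005)
    signal_sd: float = 1.5
    trait_mode: str = "liability"
    family_cut: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        for f in (self.tropic_fraction, self.hotspot_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        if self.signal_sd < 0:
            raise ValueError("signal_sd must be >= 0")
        if self.trait_mode not in ("liability", "logistic"):
            raise ValueError("trait_mode must be 'liability' or 'logistic'")
        if self.tree_model not in ("yule", "birthdeath"):
            raise ValueError("tree_model must be 'yule' or 'birthdeath'")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# --------------------------------------------------------------------------
# trees


def simulate_tree(config: SimConfig, rng=None) -> Phylogeny:
    """Forward-time constant-rate (Yule or birth-death) ultrametric tree.

    Simulation stops at the moment ``n_tips`` lineages are alive, plus one
    further exponential waiting time; extinct lineages are pruned.
    """
    rng = _rng(config.seed if rng is None else rng)
    lam, mu = config.birth, (config.death if config.tree_model == "birthdeath" else 0.0)
    if lam <= 0:
        raise ValueError("birth rate must be positive")
    if config.tree_model == "birthdeath" and mu >= lam:
        raise ValueError("birth-death requires death rate < birth rate")
    n = config.n_tips
    for _attempt in range(1000):
        parent = [-1, 0, 0]
        birth_time = [0.0, 0.0, 0.0]
        length = [0.0, 0.0, 0.0]
        alive = [1, 2]
        t = 0.0
        failed = False
        while len(alive) < n:
            rate = (lam + mu) * len(alive)
            t += rng.exponential(1.0 / rate)
            i = alive[rng.integers(len(alive))]
            length[i] = t - birth_time[i]
            alive.remove(i)
            if rng.random() < lam / (lam + mu):
                for _ in range(2):
                    parent.append(i)
                    birth_time.append(t)
                    length.append(0.0)
                    alive.append(len(parent) - 1)
            elif not alive:
                failed = True
                break
        if failed:
            continue
        t += rng.exponential(1.0 / ((lam + mu) * n))
        for i in alive:
            length[i] = t - birth_time[i]
        # re-index: alive tips first, then every other node that leads to them
        return _arrays_to_phylogeny(parent, length, alive)
    raise RuntimeError("birth-death simulation went extinct in every attempt")


def _arrays_to_phylogeny(parent, length, tips) -> Phylogeny:
    tips = sorted(tips)
    keep = set(tips)
    for i in tips:
        p = parent[i]
        while p >= 0 and p not in keep:
            keep.add(p)
            p = parent[p]
    # collapse unary internal nodes (extinct side-branches already dropped)
    children = {i: [] for i in keep}
    for i in keep:
        if parent[i] in children:
            children[parent[i]].append(i)
    tipset = set(tips)

    def resolve(i):
        # walk down through unary nodes
        acc = 0.0
        while i not in tipset and len(children[i]) == 1:
            j = children[i][0]
            acc += length[j]
            i = j
        return i, acc

    labels = [f"g{k + 1:04d}" for k in range(len(tips))]
    index = {old: new for new, old in enumerate(tips)}
    new_parent = [-1] * len(tips)
    new_length = [0.0] * len(tips)
    # assign internal indices in a postorder-independent way
    junctions = [i for i in keep if i not in tipset and len(children[i]) >= 2]
    for i in junctions:
        index[i] = len(new_parent)
        new_parent.append(-1)
        new_length.append(0.0)
    for i in list(tipset) + junctions:
        p = parent[i]
        acc = length[i]
        while p >= 0 and len(children[p]) == 1:
            acc += length[p]
            p = parent[p]
        if p >= 0:
            new_parent[index[i]] = index[p]
        new_length[index[i]] = acc
    return Phylogeny(np.array(new_parent), np.array(new_length), labels)


# --------------------------------------------------------------------------
# geography


def simulate_geography(config: SimConfig, tree: Phylogeny, rng=None,
                       band: float = 23.45):
    """Region catalog plus per-genus occupancy lists.

    Regions get latitudinal extents so that roughly ``tropic_fraction`` of
    them intersect the tropic band; hotspot flags are drawn with overall
    probability ``hotspot_fraction``, enriched within the band.  Each genus
    evolves a Brownian "home" (lon, lat) on the tree and occupies the
    ``1 + Poisson(occupancy_mean)`` regions nearest its home, so related
    genera share regions.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    m = config.n_regions
    if m < 2:
        raise ValueError("need at least 2 regions")
    is_trop = rng.random(m) < config.tropic_fraction
    width = rng.uniform(4.0, 12.0, size=m)
    center = np.where(
        is_trop,
        rng.uniform(-band, band, size=m),
        np.sign(rng.random(m) - 0.5) * rng.uniform(band + width / 2 + 0.5, 65.0, size=m),
    )
    min_lat = np.clip(center - width / 2, -90, 90)
    max_lat = np.clip(center + width / 2, -90, 90)
    # hotspot flags, enriched in the band while holding the overall mean
    n_trop = int(is_trop.sum())
    p_trop = min(1.0, 1.5 * config.hotspot_fraction)
    if m - n_trop > 0:
        p_non = np.clip((config.hotspot_fraction * m - p_trop * n_trop) / (m - n_trop), 0.0, 1.0)
    else:
        p_non = 0.0
    hotspot = np.where(is_trop, rng.random(m) < p_trop, rng.random(m) < p_non)
    lon = rng.uniform(-180.0, 180.0, size=m)
    catalog = RegionCatalog(pd.DataFrame({
        "region": [f"R{j + 1:03d}" for j in range(m)],
        "min_lat": min_lat,
        "max_lat": max_lat,
        "centroid_lon": lon,
        "centroid_lat": center,
        "hotspot": hotspot.astype(int),
    }))
    # Brownian home position; tip SD ~30 deg latitude, ~80 deg longitude
    h = tree.height
    home_lat = np.clip(simulate_bm_tips(tree, 1, rng, rate=30.0 ** 2 / h)[:, 0], -60, 60)
    home_lon = np.clip(simulate_bm_tips(tree, 1, rng, rate=80.0 ** 2 / h)[:, 0], -180, 180)
    centroids = np.column_stack([lon, center])
    occupancy = {}
    ids = np.array(catalog.regions)
    for i, genus in enumerate(tree.tip_labels):
        k = 1 + rng.poisson(config.occupancy_mean)
        k = min(k, m)
        d2 = (centroids[:, 0] - home_lon[i]) ** 2 + (centroids[:, 1] - home_lat[i]) ** 2
        occupancy[genus] = list(ids[np.argsort(d2)[:k]])
    return catalog, occupancy


def simulate_richness(config: SimConfig, n: int, rng=None) -> np.ndarray:
    """Lognormal species counts, rounded up to at least one species."""
    rng = _rng(config.seed + 2 if rng is None else rng)
    raw = rng.lognormal(config.richness_logmean, config.richness_logsd, size=n)
    return np.maximum(1, np.ceil(raw)).astype(np.int64)


# --------------------------------------------------------------------------
# trait


def simulate_trait(tree: Phylogeny, X, config: SimConfig, rng=None) -> np.ndarray:
    """Binary trait from the liability-threshold or logistic-mean model.

    Liability mode: ``l = X'beta + signal_sd * BM(tree)`` (the Brownian
    term scaled to unit tip SD and centred across tips, so the intercept
    controls prevalence rather than the lineage-wide root draw), state 1
    where l > 0.  Logistic mode: independent Bernoulli with
    ``p = expit(X'beta)``.  Redraws (up to 100) guarantee both states
    appear.
    """
    from scipy.special import expit

    rng = _rng(config.seed + 3 if rng is None else rng)
    X = np.asarray(X, dtype=float)
    if X.shape != (tree.n_tips, 3):
        raise ValueError("X must be (n_tips, 3): tropical, hotspot, richness")
    b0, bt, bh, br = config.beta
    fixed = b0 + X @ np.array([bt, bh, br])
    h = tree.height
    for _ in range(100):
        if config.trait_mode == "logistic":
            y = (rng.random(tree.n_tips) < expit(fixed)).astype(np.int64)
        else:
            bm = simulate_bm_tips(tree, 1, rng, rate=1.0 / h)[:, 0]
            bm = bm - bm.mean()
            y = (fixed + config.signal_sd * bm > 0).astype(np.int64)
        if 0 < y.sum() < len(y):
            return y
    raise RuntimeError("trait degenerate (all one state) after 100 redraws")


# --------------------------------------------------------------------------
# families and the end-to-end benchmark


def assign_families(tree: Phylogeny, cut: float = 0.5) -> list[str]:
    """Group tips into 'families' by the clade crossing ``cut * height``.

    Families are named F001, F002, ... from largest to smallest, so F001
    plays the role of the dominant family in subset analyses.
    """
    h = tree.height * cut
    depths = tree.depths
    parent = tree.parent
    group = {}
    for tip in range(tree.n_tips):
        node = tip
        while parent[node] >= 0 and depths[parent[node]] >= h:
            node = parent[node]
        group[tip] = node
    sizes = pd.Series(list(group.values())).value_counts()
    name = {node: f"F{r + 1:03d}" for r, node in enumerate(sizes.index)}
    return [name[group[t]] for t in range(tree.n_tips)]


@dataclass
class Benchmark:
    dataset: AnalysisDataset
    tree: Phylogeny
    records: list[GenusRecord]
    catalog: RegionCatalog
    truth: dict = field(default_factory=dict)


def make_benchmark(config: SimConfig = SimConfig(),
                   coding: CodingConfig = CodingConfig()) -> Benchmark:
    """Full synthetic study: tree, geography, richness, trait, aligned
    dataset, plus the generating parameters for recovery tests."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    catalog, occupancy = simulate_geography(config, tree, rng)
    richness = simulate_richness(config, tree.n_tips, rng)
    trop_flags = catalog.tropical_flags(coding)
    hot_flags = catalog.hotspot_flags()
    X = np.zeros((tree.n_tips, 3))
    for i, g in enumerate(tree.tip_labels):
        regs = occupancy[g]
        X[i, 0] = code_genus([trop_flags[r] for r in regs], coding)
        X[i, 1] = code_genus([hot_flags[r] for r in regs], coding)
        X[i, 2] = richness[i]
    y = simulate_trait(tree, X, config, rng)
    families = assign_families(tree, config.family_cut)
    records = [
        GenusRecord(genus=g, family=families[i], slp=int(y[i]),
                    species_richness=int(richness[i]),
                    regions=frozenset(occupancy[g]))
        for i, g in enumerate(tree.tip_labels)
    ]
    dataset = align_dataset(records, tree, catalog, coding)
    slp_by_family = pd.Series(y).groupby(pd.Series(families)).sum()
    focal = str(slp_by_family.idxmax())
    truth = {
        "beta": list(config.beta),
        "signal_sd": config.signal_sd,
        "trait_mode": config.trait_mode,
        "seed": config.seed,
        "prevalence": float(np.mean(y)),
        "focal_family": focal,
    }
    return Benchmark(dataset=dataset, tree=tree, records=records,
                     catalog=catalog, truth=truth)


def replace_config(config: SimConfig, **kw) -> SimConfig:
    return replace(config, **kw)
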