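"""Synthetic inputs with the statistical structure the analysis assumes.

Four generators cover the pipeline end to end: two-peak fluorescence
histograms (sample + internal standard, Gaussian peaks with configurable CVs
and an optional exponential debris background), paired dye ratios through the
forward binding-length model, pure-birth trees with Brownian tip values, and
group-structured species tables for the nonparametric tests.

Defaults mirror a routine measurement campaign: ~4,000 recorded particles per
run, peak CVs of 2.31 % (AT-selective dye) and 3.81 % (intercalating dye),
1024 instrument channels, a plant internal standard of 2C = 9.09 pg and
38.50 % GC.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import OffScaleError
from .gc_content import DyePair, forward_dye_ratio
from .histograms import PISUM_CTIRAD, Dye, Histogram, StandardRef
from .asr import Phylogeny

#: Median peak CVs of the two dye classes in routine runs (percent).
DEFAULT_CV_AT = 2.31
DEFAULT_CV_INTERCALATING = 3.81


@dataclass
class HistogramSimConfig:
    """Parameters of one simulated two-peak histogram."""

    standard_channel: float = 100.0
    true_ratio: float = 2.0
    cv_sample: float = DEFAULT_CV_AT
    cv_standard: float = DEFAULT_CV_AT
    n_sample: int = 2000
    n_standard: int = 2000
    debris_fraction: float = 0.0
    n_bins: int = 1024
    seed: int = 0

    def __post_init__(self):
        if self.true_ratio <= 0 or self.cv_sample <= 0 or self.cv_standard <= 0:
            raise ValueError("ratios and CVs must be positive")
        if not 0 <= self.debris_fraction < 1:
            raise ValueError("debris_fraction must be in [0, 1)")


def simulate_histogram(cfg: HistogramSimConfig,
                       dye: Dye | str = Dye.INTERCALATING) -> Histogram:
    """Draw a two-Gaussian-peak histogram plus optional debris.

    Particle fluorescences are normal draws around the standard channel and
    the standard channel times the true size ratio, with sd = mean * CV/100.
    Debris is an exponential decay from channel zero.  Draws are clipped to
    the channel range so that the histogram conserves particles exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    top = cfg.n_bins - 1
    means = (cfg.standard_channel, cfg.standard_channel * cfg.true_ratio)
    sds = (means[0] * cfg.cv_standard / 100.0, means[1] * cfg.cv_sample / 100.0)
    for mu, sd in zip(means, sds):
        if mu + 4 * sd > top:
            raise OffScaleError(
                f"off-scale: peak at {mu:.1f} (sd {sd:.2f}) exceeds channel {top}")

    values = [rng.normal(means[0], sds[0], cfg.n_standard),
              rng.normal(means[1], sds[1], cfg.n_sample)]
    n_signal = cfg.n_sample + cfg.n_standard
    if cfg.debris_fraction > 0:
        n_debris = int(round(cfg.debris_fraction * n_signal
                             / (1.0 - cfg.debris_fraction)))
        values.append(rng.exponential(0.15 * cfg.n_bins, n_debris))
    fluor = np.clip(np.concatenate(values), 0, top)
    counts = np.bincount(np.rint(fluor).astype(int), minlength=cfg.n_bins)
    return Histogram(np.arange(cfg.n_bins, dtype=float),
                     counts.astype(float), dye=dye,
                     meta={"sim": True, "true_ratio": cfg.true_ratio,
                           "standard_channel": cfg.standard_channel,
                           "seed": cfg.seed})


def simulate_dye_pair(true_ratio: float, gc_sample: float,
                      standard: StandardRef = PISUM_CTIRAD,
                      binding_length: int = 4, noise_cv: float = 0.0,
                      seed: int = 0) -> DyePair:
    """Paired dye ratios for a genome of known GC, with lognormal noise.

    The intercalating ratio is the true size ratio; the AT-dye ratio is the
    size ratio times the forward binding-length factor.  ``noise_cv`` (in
    percent) applies independent mean-one lognormal noise to each ratio.
    """
    if not 0 < gc_sample < 100:
        raise ValueError("gc_sample must be in (0, 100) percent")
    rng = np.random.default_rng(seed)
    p_s = 1.0 - gc_sample / 100.0
    factor = forward_dye_ratio(p_s, standard.at_fraction, binding_length)
    s = noise_cv / 100.0
    noise = (np.exp(rng.normal(-0.5 * s * s, s, 2)) if s > 0
             else np.ones(2))
    return DyePair(ratio_at_dye=true_ratio * factor * noise[0],
                   ratio_intercalating=true_ratio * noise[1],
                   standard=standard, binding_length=binding_length)


@dataclass
class BMSimConfig:
    """Pure-birth tree + Brownian trait simulation parameters.

    ``scale_height`` rescales all branch lengths after tree growth so the
    root-to-tip height equals the given value (Yule trees otherwise grow
    taller with more tips, confounding comparisons across tree sizes);
    ``sigma2`` is then per unit of scaled height.  ``None`` keeps the raw
    coalescent-time branch lengths.
    """

    n_tips: int = 16
    birth_rate: float = 1.0
    root_state: float = 6.19
    sigma2: float = 1.0
    scale_height: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.sigma2 < 0 or self.birth_rate <= 0:
            raise ValueError("sigma2 must be >= 0 and birth_rate > 0")
        if self.scale_height is not None and self.scale_height <= 0:
            raise ValueError("scale_height must be positive")


def simulate_tree_and_tips(cfg: BMSimConfig) -> tuple[Phylogeny, dict]:
    """Grow a Yule tree to ``n_tips`` and evolve a BM trait along it.

    Waiting times between speciation events are exponential with rate
    birth_rate * (number of extant lineages); the lineage that splits is
    uniform among extant ones.  Tip values follow recursive normal increments
    with variance sigma2 * branch length from the root state.
    """
    rng = np.random.default_rng(cfg.seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node

    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, t))
    while len(active) < cfg.n_tips:
        t += rng.exponential(1.0 / (cfg.birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (cfg.birth_rate * len(active)))
    for k, (node, born) in enumerate(active):
        node.edge.length = t - born
        node.taxon = taxa.new_taxon(label=f"t{k + 1}")

    if cfg.scale_height is not None:
        factor = cfg.scale_height / t
        for nd in tree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= factor

    values: dict = {}
    states = {root: cfg.root_state}
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        step_sd = np.sqrt(cfg.sigma2 * nd.edge.length)
        states[nd] = states[nd.parent_node] + rng.normal(0.0, step_sd)
        if nd.is_leaf():
            values[nd.taxon.label] = float(states[nd])
    return Phylogeny(tree), values


def simulate_bm_tips(phy: Phylogeny, root_state: float, sigma2: float,
                     seed: int = 0) -> dict:
    """Evolve a BM trait on an existing tree (fixed topology/branch lengths)."""
    rng = np.random.default_rng(seed)
    tree = phy.tree
    states = {tree.seed_node: float(root_state)}
    values: dict = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        length = nd.edge.length or 0.0
        states[nd] = states[nd.parent_node] + rng.normal(
            0.0, np.sqrt(sigma2 * length))
        if nd.is_leaf():
            values[nd.taxon.label] = float(states[nd])
    return values


def make_species_table(n_groups: int, group_shifts, n_per_group,
                       base_mean: float = 8.0, sd: float = 1.5,
                       seed: int = 0) -> pd.DataFrame:
    """Synthetic species table grouped by diploid chromosome number.

    Group g draws ``n_per_group[g]`` normal values around
    ``base_mean + group_shifts[g]`` (sd ``sd``), truncated below at 0.1 pg,
    and is labelled with 2n = 12, 14, 16, ...  Columns: species, male_2n,
    c1_male_pg.
    """
    group_shifts = list(np.broadcast_to(group_shifts, (n_groups,)))
    n_per_group = list(np.broadcast_to(n_per_group, (n_groups,)).astype(int))
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        two_n = 12 + 2 * g
        draws = np.maximum(
            rng.normal(base_mean + group_shifts[g], sd, n_per_group[g]), 0.1)
        for j, v in enumerate(draws):
            rows.append({"species": f"sp_2n{two_n}_{j + 1}", "male_2n": two_n,
                         "c1_male_pg": float(v)})
    return pd.DataFrame(rows)
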