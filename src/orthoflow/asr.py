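"""Brownian-motion ancestral state reconstruction on a rooted phylogeny.

Under Brownian motion a continuous trait x accumulates variance in
proportion to branch length: the tip values are jointly normal with common
mean a (the root state) and covariance sigma^2 * C, where C_ij is the
root-to-MRCA path length shared by tips i and j.  The maximum-likelihood
root state is the generalized-least-squares mean

    a_hat = (1' C^-1 1)^-1 1' C^-1 x,

the ML rate is sigma2_hat = (x - a_hat 1)' C^-1 (x - a_hat 1) / N, and each
internal node's ML state equals the GLS mean of the tree re-rooted at that
node.  Rather than inverting a matrix per node, this module computes all
node estimates in two sweeps of Gaussian message passing over the tree
(each directed edge carries a conditional mean and an effective variance
length); the result is algebraically identical to the per-node GLS mean,
which the test suite verifies against an explicit-matrix oracle.

Trees need not be ultrametric: substitution-scaled branch lengths are used
as-is.  Polytomies are handled natively by the formulation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DegenerateTreeError,
    InconsistentInputError,
    InsufficientTipsError,
    MissingLengthsError,
    TreeParseError,
)

__all__ = [
    "Phylogeny", "read_newick", "normalize_name", "match_and_prune",
    "BrownianAncestralModel", "AncestralResults", "bm_asr", "annotate_tree",
]


@dataclass
class Phylogeny:
    """A rooted, branch-length-weighted tree (thin wrapper over dendropy)."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def n_internal(self) -> int:
        return sum(1 for _ in self.tree.preorder_internal_node_iter())

    def write_newick(self, path: str | Path | None = None) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))


def read_newick(source: str | Path | io.TextIOBase) -> Phylogeny:
    """Parse a Newick tree with branch lengths.

    Accepts a path, a Newick string or a text stream.  Duplicate tip labels
    and missing branch lengths are rejected.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        s = str(source)
        text = Path(s).read_text() if ("(" not in s and Path(s).exists()) else s
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeParseError(f"parse-error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        raise TreeParseError("parse-error: duplicate tip labels")
    if not labels:
        raise TreeParseError("parse-error: no labelled tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise MissingLengthsError("missing-lengths: branch without length")
        if edge.length < 0:
            raise MissingLengthsError("missing-lengths: negative branch length")
    return Phylogeny(tree)


def normalize_name(name: str) -> str:
    """Default tip-name normalizer: case-fold, underscores to spaces."""
    return " ".join(str(name).replace("_", " ").split()).casefold()


def match_and_prune(phy: Phylogeny, values, name_normalizer:
                    Callable[[str], str] = normalize_name,
                    ) -> tuple[Phylogeny, dict, dict]:
    """Match trait values to tips, average duplicates, prune unmatched tips.

    ``values`` maps species name -> value or list of values (a DataFrame with
    ``species``/``value``-like columns also works); species with several
    measurements get their arithmetic mean.  Tips without values are pruned
    and resulting degree-2 nodes suppressed by summing branch lengths.

    Returns (pruned tree, tip label -> value, report) where report lists
    matched and unmatched names on both sides.
    """
    if isinstance(values, pd.DataFrame):
        cols = list(values.columns)
        sp_col = cols[0]
        val_col = cols[1]
        table: dict = {}
        for _, row in values.iterrows():
            table.setdefault(str(row[sp_col]), []).append(float(row[val_col]))
    else:
        table = {str(k): (list(v) if isinstance(v, (list, tuple, np.ndarray))
                          else [float(v)]) for k, v in dict(values).items()}
    means = {name_normalizer(k): float(np.mean(v)) for k, v in table.items()}

    phy = phy.clone()
    tip_values: dict = {}
    keep = []
    for leaf in phy.tree.leaf_node_iter():
        key = name_normalizer(leaf.taxon.label)
        if key in means:
            tip_values[leaf.taxon.label] = means[key]
            keep.append(leaf.taxon)
    if len(keep) < 2:
        raise InsufficientTipsError(
            f"insufficient-tips: only {len(keep)} tips matched")
    matched_norm = {name_normalizer(t.label) for t in keep}
    report = {
        "n_matched": len(keep),
        "unmatched_tips": sorted(lf.taxon.label
                                 for lf in phy.tree.leaf_node_iter()
                                 if lf.taxon not in keep),
        "unmatched_species": sorted(k for k in table
                                    if name_normalizer(k) not in matched_norm),
    }
    phy.tree.retain_taxa(keep)
    # suppress_unifurcations (called by retain_taxa) sums branch lengths
    return phy, tip_values, report


class AncestralResults:
    """ML ancestral states with variances and 95% intervals.

    Attributes
    ----------
    node_estimates : pandas.DataFrame
        One row per internal node: node_id, estimate, variance, ci_lo, ci_hi.
    sigma2_hat : float
        ML Brownian rate (trait-units^2 per branch-length unit).
    root_estimate : float
        The GLS mean at the root.
    """

    def __init__(self, model: "BrownianAncestralModel",
                 node_estimates: pd.DataFrame, sigma2_hat: float,
                 root_estimate: float, log_likelihood: float):
        self.model = model
        self.node_estimates = node_estimates
        self.sigma2_hat = sigma2_hat
        self.root_estimate = root_estimate
        self.log_likelihood = log_likelihood

    def estimate(self, node_id: str) -> float:
        row = self.node_estimates.set_index("node_id").loc[node_id]
        return float(row["estimate"])

    def summary(self) -> str:
        head = [
            "Brownian-motion ancestral state reconstruction (ML)",
            f"  tips: {self.model.phylogeny.n_tips}   "
            f"internal nodes: {len(self.node_estimates)}",
            f"  sigma2_hat: {self.sigma2_hat:.6g}   "
            f"root: {self.root_estimate:.6g}   "
            f"logL: {self.log_likelihood:.6g}",
        ]
        body = self.node_estimates.to_string(
            index=False, float_format=lambda v: f"{v:.4f}")
        return "\n".join(head) + "\n" + body

    def annotated_newick(self) -> str:
        newick, _ = annotate_tree(self.model.phylogeny, self)
        return newick


class BrownianAncestralModel:
    """ML ancestral state model for a continuous trait under Brownian motion.

    Parameters
    ----------
    phylogeny
        Rooted tree with branch lengths (non-ultrametric allowed).
    tip_values
        Mapping tip label -> trait value; every tip must be covered (use
        :func:`match_and_prune` first if not).
    min_terminal_length_frac
        Zero-length terminal branches are replaced by this fraction of the
        tree height to keep the tip covariance invertible.
    """

    def __init__(self, phylogeny: Phylogeny, tip_values: Mapping[str, float],
                 min_terminal_length_frac: float = 1e-8):
        labels = phylogeny.tip_labels
        if len(labels) < 2:
            raise InsufficientTipsError("insufficient-tips: need >= 2 tips")
        missing = [l for l in labels if l not in tip_values]
        if missing:
            raise InconsistentInputError(
                f"inconsistent-input: tips without values: {missing[:5]}")
        self.phylogeny = phylogeny.clone()
        self.tip_values = {l: float(tip_values[l]) for l in labels}
        self._prepare(min_terminal_length_frac)

    @classmethod
    def from_dataframe(cls, phylogeny: Phylogeny, df: pd.DataFrame,
                       **kwargs) -> "BrownianAncestralModel":
        """Build from a (species, value) DataFrame, matching and pruning."""
        pruned, tip_values, _ = match_and_prune(phylogeny, df)
        return cls(pruned, tip_values, **kwargs)

    # -- internal bookkeeping ------------------------------------------------

    def _prepare(self, min_terminal_length_frac: float):
        tree = self.phylogeny.tree
        # stable node ids: tips keep labels, internals numbered in preorder
        self._internal_ids = {}
        i = 0
        for nd in tree.preorder_node_iter():
            if not nd.is_leaf():
                self._internal_ids[nd] = f"n{i}"
                i += 1
        # effective branch lengths, with the zero-terminal-branch guard
        depths = {}
        for nd in tree.preorder_node_iter():
            parent_depth = depths.get(nd.parent_node, 0.0)
            depths[nd] = parent_depth + (nd.edge.length or 0.0)
        height = max((depths[lf] for lf in tree.leaf_node_iter()), default=0.0)
        if height <= 0:
            raise DegenerateTreeError("degenerate-tree: all branch lengths zero")
        floor = min_terminal_length_frac * height
        self._blen = {}
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            ln = nd.edge.length or 0.0
            if nd.is_leaf() and ln <= 0:
                ln = floor
            self._blen[nd] = ln

    def _tip_covariance(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """C (unscaled shared path lengths) and tip values, in label order."""
        tree = self.phylogeny.tree
        leaves = list(tree.leaf_node_iter())
        index = {lf: k for k, lf in enumerate(leaves)}
        n = len(leaves)
        C = np.zeros((n, n))
        depths = {}
        tipsets: dict = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                tipsets[nd] = [index[nd]]
            else:
                tipsets[nd] = [t for c in nd.child_nodes() for t in tipsets[c]]
        for nd in tree.preorder_node_iter():
            depths[nd] = depths.get(nd.parent_node, 0.0) + self._blen.get(nd, 0.0)
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                k = index[nd]
                C[k, k] = depths[nd]
            else:
                kids = nd.child_nodes()
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for ti in tipsets[kids[a]]:
                            for tj in tipsets[kids[b]]:
                                C[ti, tj] = C[tj, ti] = depths[nd]
        labels = [lf.taxon.label for lf in leaves]
        x = np.array([self.tip_values[l] for l in labels])
        return C, x, labels

    # -- fitting -------------------------------------------------------------

    def fit(self) -> AncestralResults:
        tree = self.phylogeny.tree

        # upward sweep: each node's subtree-conditional mean and extra length
        up_mean: dict = {}
        up_extra: dict = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                up_mean[nd] = self.tip_values[nd.taxon.label]
                up_extra[nd] = 0.0
            else:
                wsum = msum = 0.0
                for c in nd.child_nodes():
                    l_eff = self._blen[c] + up_extra[c]
                    if l_eff <= 0:
                        raise DegenerateTreeError(
                            "degenerate-tree: zero effective branch length")
                    w = 1.0 / l_eff
                    wsum += w
                    msum += w * up_mean[c]
                up_mean[nd] = msum / wsum
                up_extra[nd] = 1.0 / wsum

        root = tree.seed_node
        root_estimate = up_mean[root]

        # downward sweep: message from the parent side of each node
        down_mean: dict = {}
        down_extra: dict = {}
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            p = nd.parent_node
            inc = [(up_mean[c], self._blen[c] + up_extra[c])
                   for c in p.child_nodes() if c is not nd]
            if p is not root:
                inc.append((down_mean[p], down_extra[p]))
            wsum = sum(1.0 / l for _, l in inc)
            msum = sum(m / l for m, l in inc)
            down_mean[nd] = msum / wsum
            down_extra[nd] = 1.0 / wsum + self._blen[nd]

        # sigma2 (ML) from the explicit GLS residual form
        C, x, _ = self._tip_covariance()
        n = x.size
        try:
            Cinv_x = np.linalg.solve(C, x)
            Cinv_1 = np.linalg.solve(C, np.ones(n))
        except np.linalg.LinAlgError as exc:
            raise DegenerateTreeError(f"degenerate-tree: {exc}") from exc
        a_gls = float(np.ones(n) @ Cinv_x / (np.ones(n) @ Cinv_1))
        resid = x - a_gls
        sigma2_hat = float(resid @ np.linalg.solve(C, resid) / n)
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            raise DegenerateTreeError("degenerate-tree: singular covariance")
        if sigma2_hat > 0:
            loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_hat) + logdet + n)
        else:
            loglik = np.inf  # degenerate perfect fit (all tips equal)

        # per-node estimates: combine all incident messages (= re-rooted GLS)
        rows = []
        for nd in tree.preorder_internal_node_iter():
            inc = [(up_mean[c], self._blen[c] + up_extra[c])
                   for c in nd.child_nodes()]
            if nd is not root:
                inc.append((down_mean[nd], down_extra[nd]))
            wsum = sum(1.0 / l for _, l in inc)
            est = sum(m / l for m, l in inc) / wsum
            var = sigma2_hat / wsum
            half = 1.959963984540054 * np.sqrt(var)
            rows.append({"node_id": self._internal_ids[nd], "estimate": est,
                         "variance": var, "ci_lo": est - half,
                         "ci_hi": est + half})
        table = pd.DataFrame(rows)
        return AncestralResults(self, table, sigma2_hat, root_estimate, loglik)


def bm_asr(phy: Phylogeny, tips: Mapping[str, float]) -> AncestralResults:
    """Fit BM ancestral states; convenience wrapper over the model class."""
    return BrownianAncestralModel(phy, tips).fit()


def annotate_tree(phy: Phylogeny, result: AncestralResults,
                  ) -> tuple[str, pd.DataFrame]:
    """Label internal nodes with ``id|estimate`` and return Newick + table."""
    model = result.model
    if set(result.node_estimates["node_id"]) != set(model._internal_ids.values()):
        raise InconsistentInputError("inconsistent-input: result/tree mismatch")
    if sorted(phy.tip_labels) != sorted(model.phylogeny.tip_labels):
        raise InconsistentInputError("inconsistent-input: tip sets differ")
    est = result.node_estimates.set_index("node_id")["estimate"]
    tree = model.phylogeny.clone().tree
    ids = {}
    i = 0
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            ids[nd] = f"n{i}"
            i += 1
    for nd, nid in ids.items():
        nd.label = f"{nid}|{est.loc[nid]:.6f}"
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    return newick, result.node_estimates.copy()
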