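"""Phylogenetic comparative machinery.

Rooted trees with branch lengths (Newick, via dendropy), Felsenstein's
phylogenetically independent contrasts, Blomberg's K with a permutation
test, and Brownian-motion utilities (trait simulation, pure-birth tree
generation) for calibration.

Under Brownian evolution tip trait values are multivariate normal with
covariance sigma^2 * V, where V[i, j] is the shared root-to-MRCA branch
length of tips i and j.  The pruning algorithm turns n tip values into
n - 1 standardized contrasts

    C_k = (x_i - x_j) / sqrt(b_i + b_j)

that are i.i.d. N(0, sigma^2) when the model holds; regressions on
contrasts go through the origin.  Blomberg's K compares the observed
ratio of tip variance to phylogenetically corrected variance against its
Brownian expectation on the same tree; K = 1 under Brownian motion,
K << 1 when trait variation is unrelated to the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import dendropy
import numpy as np

from .allometry import LineFit, sma_fit_origin

__all__ = [
    "Phylogeny",
    "ContrastSet",
    "KResult",
    "parse_newick",
    "pic",
    "sma_on_contrasts",
    "blomberg_k",
    "simulate_bm",
    "generate_tree",
    "vcv_matrix",
]

#: Branch length given to edges created when resolving polytomies.
POLYTOMY_EPSILON = 1e-8


@dataclass
class Phylogeny:
    """A rooted tree with strictly positive branch lengths.

    Thin wrapper around a :class:`dendropy.Tree`; tip labels follow the
    package's underscore convention for matching trait-table species.
    """

    tree: dendropy.Tree
    source_label: str = ""

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise ValueError("a phylogeny needs at least 2 tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue  # root edge length is irrelevant and may be absent
            if node.edge.length is None:
                raise ValueError(
                    f"missing branch length on edge above {_node_name(node)}"
                )
            if node.edge.length <= 0:
                raise ValueError(
                    f"non-positive branch length ({node.edge.length}) above "
                    f"{_node_name(node)}"
                )

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_bifurcating(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self.tree.preorder_internal_node_iter()
        )

    def as_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    def clone(self) -> "Phylogeny":
        return Phylogeny(
            tree=self.tree.clone(depth=1), source_label=self.source_label
        )


def _node_name(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or f"<internal node {id(node) & 0xFFFF:04x}>"


def parse_newick(text: str, source_label: str = "") -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Branch lengths are mandatory on every non-root edge; tip labels are
    normalized to the underscore convention; polytomies are preserved.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick syntax error: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise ValueError("unlabeled tip in Newick input")
        leaf.taxon.label = "_".join(str(leaf.taxon.label).split())
    return Phylogeny(tree=tree, source_label=source_label)


@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts in fixed post-order over internal nodes."""

    contrasts: np.ndarray  # one per internal node
    node_values: np.ndarray  # ancestral working values, same order
    adjusted_lengths: np.ndarray  # post-pruning edge sums b_i + b_j
    tip_labels: tuple  # tips of the tree the contrasts came from
    polytomy_policy: str = "error"

    def __len__(self) -> int:
        return len(self.contrasts)


def pic(
    phylo: Phylogeny,
    traits: Dict[str, float],
    polytomy_policy: str = "error",
) -> ContrastSet:
    """Phylogenetically independent contrasts by the pruning algorithm.

    At each internal node with child working values x_i, x_j on adjusted
    branch lengths b_i, b_j: the contrast is (x_i - x_j)/sqrt(b_i + b_j),
    the node value is the precision-weighted mean, and the node's own
    branch is lengthened by b_i*b_j/(b_i + b_j).

    Parameters
    ----------
    traits
        Mapping of tip label to trait value; must cover every tip.
    polytomy_policy
        'error' (default) refuses multifurcating nodes; 'resolve' splits
        them arbitrarily with tiny (1e-8) internal branches and records
        the policy in the result.
    """
    if polytomy_policy not in ("error", "resolve"):
        raise ValueError("polytomy_policy must be 'error' or 'resolve'")
    missing = [l for l in phylo.tip_labels if l not in traits]
    if missing:
        raise ValueError(f"traits missing for tip(s): {missing[:5]}")

    work = phylo.clone()
    if not work.is_bifurcating():
        if polytomy_policy == "error":
            bad = next(
                n
                for n in work.tree.preorder_internal_node_iter()
                if len(n.child_nodes()) != 2
            )
            raise ValueError(
                f"polytomy at node {_node_name(bad)}; "
                "pass polytomy_policy='resolve' to split it arbitrarily"
            )
        work.tree.resolve_polytomies(limit=2, update_bipartitions=False)
        for node in work.tree.preorder_node_iter():
            if node is work.tree.seed_node:
                continue
            if not node.edge.length:
                node.edge.length = POLYTOMY_EPSILON

    values, lengths = {}, {}
    contrasts, node_values, adj_lengths = [], [], []
    for node in work.tree.postorder_node_iter():
        if node.is_leaf():
            values[node] = float(traits[node.taxon.label])
            lengths[node] = float(node.edge.length)
            continue
        ci, cj = node.child_nodes()
        xi, xj = values[ci], values[cj]
        bi, bj = lengths[ci], lengths[cj]
        contrasts.append((xi - xj) / np.sqrt(bi + bj))
        value = (xi / bi + xj / bj) / (1.0 / bi + 1.0 / bj)
        values[node] = value
        node_values.append(value)
        adj_lengths.append(bi + bj)
        base = node.edge.length if node is not work.tree.seed_node else 0.0
        lengths[node] = float(base or 0.0) + bi * bj / (bi + bj)
    return ContrastSet(
        contrasts=np.array(contrasts),
        node_values=np.array(node_values),
        adjusted_lengths=np.array(adj_lengths),
        tip_labels=tuple(phylo.tip_labels),
        polytomy_policy=polytomy_policy,
    )


def sma_on_contrasts(
    contrasts_x: ContrastSet,
    contrasts_y: ContrastSet,
    hypothesized_slope: Optional[float] = None,
) -> LineFit:
    """Through-origin SMA between two contrast sets from the same tree."""
    if contrasts_x.tip_labels != contrasts_y.tip_labels or len(
        contrasts_x
    ) != len(contrasts_y):
        raise ValueError("contrast sets come from different trees/orderings")
    return sma_fit_origin(
        contrasts_x.contrasts, contrasts_y.contrasts, hypothesized_slope
    )


def vcv_matrix(phylo: Phylogeny) -> tuple:
    """Tip labels and the Brownian covariance matrix V (shared path lengths).

    V[i, j] is the root-to-MRCA distance of tips i and j; the diagonal is
    each tip's root distance.  Labels follow the tree's leaf order.
    """
    labels = phylo.tip_labels
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    depths, tipsets = {}, {}
    for node in phylo.tree.preorder_node_iter():
        if node is phylo.tree.seed_node:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + node.edge.length
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            k = index[node.taxon.label]
            tipsets[node] = [k]
            V[k, k] = depths[node]
            continue
        kids = node.child_nodes()
        for p in range(len(kids)):
            for q in range(p + 1, len(kids)):
                for i in tipsets[kids[p]]:
                    for j in tipsets[kids[q]]:
                        V[i, j] = V[j, i] = depths[node]
        tipsets[node] = [i for kid in kids for i in tipsets[kid]]
    return labels, V


@dataclass(frozen=True)
class KResult:
    """Blomberg's K with its permutation p-value."""

    k: float
    p_perm: float
    n_perm: int
    seed: int
    n_tips: int = 0


def blomberg_k(
    phylo: Phylogeny,
    traits: Dict[str, float],
    n_perm: int = 999,
    seed: int = 0,
) -> KResult:
    """Blomberg's K phylogenetic-signal statistic with a permutation test.

    K is the ratio (MSE0/MSE) / E[MSE0/MSE | Brownian motion], where
    MSE0 is the trait variance around the phylogenetically weighted mean
    and MSE the generalized-least-squares variance under covariance V:

        a_hat = (1' V^-1 x) / (1' V^-1 1)
        MSE0  = sum (x - a_hat)^2 / (n - 1)
        MSE   = (x - a_hat)' V^-1 (x - a_hat) / (n - 1)
        E[MSE0/MSE] = [tr(V) - n / (1' V^-1 1)] / (n - 1)

    The p-value permutes trait values across tips (add-one estimator, so
    p is never 0) and counts permutations whose phylogenetic MSE is at
    most the observed one — i.e. at least as much apparent signal.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    missing = [l for l in phylo.tip_labels if l not in traits]
    if missing:
        raise ValueError(f"traits missing for tip(s): {missing[:5]}")
    labels, V = vcv_matrix(phylo)
    x = np.array([float(traits[l]) for l in labels])
    n = len(x)
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    w = Vinv @ ones
    denom_w = float(ones @ w)

    def mse_pair(vals):
        a_hat = float(vals @ w) / denom_w
        dev = vals - a_hat
        mse0 = float(dev @ dev) / (n - 1)
        mse = float(dev @ Vinv @ dev) / (n - 1)
        return mse0, mse

    mse0, mse = mse_pair(x)
    observed_ratio = mse0 / mse
    expected_ratio = (float(np.trace(V)) - n / denom_w) / (n - 1)
    k = observed_ratio / expected_ratio

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, mse_p = mse_pair(rng.permutation(x))
        if mse_p <= mse:
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)
    return KResult(k=float(k), p_perm=p_perm, n_perm=n_perm, seed=seed, n_tips=n)


def simulate_bm(
    phylo: Phylogeny,
    sigma: float = 1.0,
    root_value: float = 0.0,
    seed: int = 0,
) -> Dict[str, float]:
    """Simulate a Brownian trait along the tree; returns tip label -> value.

    Each branch adds an independent N(0, sigma^2 * branch_length) step, so
    tip values have covariance sigma^2 * V.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    values = {}
    for node in phylo.tree.preorder_node_iter():
        if node is phylo.tree.seed_node:
            values[node] = float(root_value)
            continue
        step = rng.normal(0.0, sigma * np.sqrt(node.edge.length))
        values[node] = values[node.parent_node] + step
    return {
        leaf.taxon.label: values[leaf]
        for leaf in phylo.tree.leaf_node_iter()
    }


def generate_tree(n_tips: int, seed: int = 0, birth_rate: float = 1.0) -> Phylogeny:
    """Random pure-birth (Yule) tree with ``n_tips`` tips.

    Waiting times between speciation events are exponential with rate
    (number of extant lineages) * birth_rate; each event splits a
    uniformly chosen extant lineage.  Tips are labeled t1..tn.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    while len(active) < n_tips:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.edge.length += dt
        parent = active.pop(rng.integers(len(active)))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    dt = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length += dt
    for i, node in enumerate(active, start=1):
        node.taxon = taxa.new_taxon(label=f"t{i}")
    return Phylogeny(tree=tree, source_label=f"yule(n={n_tips}, seed={seed})")
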