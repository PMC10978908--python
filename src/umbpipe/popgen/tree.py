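"""Neighbor-joining trees with locus-resampling bootstrap support.

The distance model (K2P) follows the study's substitution model; the tree
search itself is canonical neighbor joining (Saitou–Nei with the standard
Q-criterion), which recovers additive matrices exactly.  Bootstrap support
for each internal bipartition of the point-estimate tree is the percentage
of locus-resampled replicate trees containing that bipartition.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from ..snpcall import GenotypeMatrix
from .distance import DistanceMatrix, k2p_distance

logger = logging.getLogger(__name__)


def nj_tree(
    dist: DistanceMatrix,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
    negative_to_zero: bool = True,
) -> dendropy.Tree:
    """Build an unrooted neighbor-joining tree from a complete distance matrix."""
    if len(dist.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if not dist.complete:
        raise ValueError(
            f"distance matrix incomplete; missing pairs: {dist.missing_pairs()}"
        )
    tns = taxon_namespace or dendropy.TaxonNamespace(dist.taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    nodes: list[dendropy.Node] = []
    for name in dist.taxa:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        if node.taxon is None:
            raise ValueError(f"taxon {name!r} missing from namespace")
        nodes.append(node)
    d = dist.values.astype(float).copy()
    active = list(range(len(nodes)))

    def clamp(x: float) -> float:
        return max(x, 0.0) if negative_to_zero else x

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        qmat = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(qmat, np.inf)
        ai, aj = np.unravel_index(np.argmin(qmat), qmat.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (rowsum[ai] - rowsum[aj]) / (2.0 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = clamp(li)
        nj_.edge.length = clamp(lj)
        # distances from the new node to the remaining ones
        new_index = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak in active:
            if ak in (i, j):
                continue
            dk = 0.5 * (d[i, ak] + d[j, ak] - dij)
            d[new_index, ak] = d[ak, new_index] = dk
        active = [a for a in active if a not in (i, j)] + [new_index]

    # final (up to trifurcating) join
    center = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        lengths = {
            i: 0.5 * (d[i, j] + d[i, k] - d[j, k]),
            j: 0.5 * (d[i, j] + d[j, k] - d[i, k]),
            k: 0.5 * (d[i, k] + d[j, k] - d[i, j]),
        }
    else:  # 2 remaining can only happen with fewer than 4 leaves overall
        i, j = active
        lengths = {i: 0.5 * d[i, j], j: 0.5 * d[i, j]}
    for idx, length in lengths.items():
        center.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(length)
    tree.seed_node = center
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def dedupe_loci(matrix: GenotypeMatrix) -> np.ndarray:
    """Indices of non-redundant loci (first of each identical genotype column)."""
    seen: dict[bytes, int] = {}
    keep: list[int] = []
    for i in range(matrix.n_loci):
        key = matrix.calls[i].tobytes()
        if key not in seen:
            seen[key] = i
            keep.append(i)
    return np.array(keep, dtype=int)


def bootstrap_support(
    matrix: GenotypeMatrix,
    n_replicates: int = 1000,
    seed: int | None = None,
    deduplicate: bool = True,
) -> dendropy.Tree:
    """Point-estimate NJ tree with bootstrap supports on internal nodes.

    Loci are resampled with replacement ``n_replicates`` times; each
    replicate's distances and tree are rebuilt, and support is the
    percentage of replicates containing each internal bipartition of the
    point-estimate tree.  Supports are stored as internal-node labels and
    ``node.support`` attributes.  Replicates with saturated (undefined)
    distances are skipped.
    """
    idx = dedupe_loci(matrix) if deduplicate else np.arange(matrix.n_loci)
    dist = k2p_distance(matrix, loci_idx=idx)
    tns = dendropy.TaxonNamespace(dist.taxa)
    tree = nj_tree(dist, taxon_namespace=tns)
    tree.encode_bipartitions()

    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}  # keyed by normalized split bitmask
    n_used = 0
    for _ in range(n_replicates):
        resampled = idx[rng.integers(0, len(idx), size=len(idx))]
        rep_dist = k2p_distance(matrix, loci_idx=resampled)
        if not rep_dist.complete:
            logger.warning("skipping bootstrap replicate with saturated distances")
            continue
        rep_tree = nj_tree(rep_dist, taxon_namespace=tns)
        for bip in rep_tree.encode_bipartitions():
            key = int(bip.split_bitmask)
            counts[key] = counts.get(key, 0) + 1
        n_used += 1
    denom = max(n_used, 1)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        key = int(node.edge.bipartition.split_bitmask)
        support = 100.0 * counts.get(key, 0) / denom
        node.support = support
        node.label = f"{support:.0f}"
    tree.bootstrap_replicates_used = n_used
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
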