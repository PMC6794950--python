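"""Neighbor-joining trees on K2P distances, nonparametric bootstrap, and
monophyly-based species discrimination.

The NJ agglomeration is the classical Saitou-Nei algorithm with the standard
Q-criterion. Ties in Q are broken deterministically by the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest leaf
label), so identical matrices always yield identical trees. Negative branch
lengths are clamped to zero with the excess moved to the sister edge.

Bootstrap support is the percentage of column-resampled replicates whose NJ
tree contains each internal bipartition of the original tree. A species is
discriminated when some edge isolates exactly its samples (unrooted: either
side) with support strictly above the threshold (default 50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import dendropy
import numpy as np

from .datamodel import InputError, LocusAlignment, SpeciesMap
from .distances import DistanceMatrix, encode_alignment, k2p_matrix_from_codes
from .gap_analysis import DiscriminationReport, effective_species_map

_Q_TIE_TOL = 1e-12


@dataclass
class PhyloTree:
    """Unrooted NJ tree plus (optionally) bootstrap supports per bipartition.

    ``supports`` maps each canonical internal bipartition (the side not
    containing the reference leaf) to a percentage in [0, 100]. ``None``
    means no bootstrap was run.
    """

    tree: dendropy.Tree
    supports: dict[frozenset[str], float] | None = None

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def bipartitions(self) -> set[frozenset[str]]:
        return tree_bipartitions(self.tree)

    def newick(self) -> str:
        """Newick string; bootstrap supports become internal node labels."""
        if self.supports is not None:
            leaves = self.leaf_labels
            ref = min(leaves)
            for node in self.tree.preorder_node_iter():
                if node.is_leaf() or node.parent_node is None:
                    continue
                side = frozenset(
                    lf.taxon.label for lf in node.leaf_iter()
                )
                key = side if ref not in side else leaves - side
                if key in self.supports:
                    node.label = f"{self.supports[key]:.0f}"
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each as the side without the reference leaf."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(leaves)
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = side if ref not in side else leaves - side
        if 2 <= len(key) <= n - 2:
            out.add(key)
    return out


def robinson_foulds(a: PhyloTree | dendropy.Tree, b: PhyloTree | dendropy.Tree) -> int:
    """Symmetric-difference (RF) distance on non-trivial bipartitions."""
    ta = a.bipartitions() if isinstance(a, PhyloTree) else tree_bipartitions(a)
    tb = b.bipartitions() if isinstance(b, PhyloTree) else tree_bipartitions(b)
    return len(ta ^ tb)


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining on a complete distance matrix."""
    n = len(matrix)
    if n < 3:
        raise InputError("NJ needs >= 3 samples")
    vals = matrix.values
    iu = np.triu_indices(n, k=1)
    if np.isnan(vals[iu]).any():
        bad = [
            (matrix.ids[i], matrix.ids[j])
            for i, j in zip(*iu)
            if math.isnan(vals[i, j])
        ]
        raise InputError(f"undefined distances for pairs: {bad[:10]}")

    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.new_taxon(label=s)) for s in matrix.ids]
    labels = list(matrix.ids)
    D = vals.astype(float).copy()

    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = float(Q.min())
        tol = _Q_TIE_TOL * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        i, j = min(
            (tuple(sorted((labels[a], labels[b]))), a, b)
            for a, b in cand
            if a < b
        )[1:]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li = max(0.0, li + lj)
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        dnew = 0.5 * (D[i, :] + D[j, :] - d_ij)
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        del nodes[j], labels[j]

    root = dendropy.Node()
    half = max(0.0, D[0, 1]) / 2.0
    for node in nodes:
        root.add_child(node)
        node.edge.length = half
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def bootstrap_support(
    alignment: LocusAlignment,
    n_replicates: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """NJ tree with column-resampling bootstrap supports.

    Replicates whose K2P matrix contains undefined entries are skipped; more
    than 20% skipped replicates aborts with an error.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = encode_alignment(alignment)
    ids = alignment.sample_ids
    full = k2p_matrix_from_codes(codes)
    original = nj_tree(DistanceMatrix(ids, full))
    orig_bips = original.bipartitions()

    counts = {b: 0 for b in orig_bips}
    used = 0
    skipped = 0
    n_cols = codes.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_vals = k2p_matrix_from_codes(codes[:, cols])
        iu = np.triu_indices(len(ids), k=1)
        if np.isnan(rep_vals[iu]).any():
            skipped += 1
            continue
        rep_bips = nj_tree(DistanceMatrix(ids, rep_vals)).bipartitions()
        for b in orig_bips:
            if b in rep_bips:
                counts[b] += 1
        used += 1
    if skipped > 0.2 * n_replicates:
        raise InputError(
            f"{skipped}/{n_replicates} bootstrap replicates had undefined "
            "distances"
        )
    supports = {b: 100.0 * counts[b] / used for b in orig_bips}
    return PhyloTree(tree=original.tree, supports=supports)


@dataclass(frozen=True)
class MonophylyVerdict:
    species: str
    is_monophyletic: bool
    support: float | None
    counted_success: bool

    def __post_init__(self) -> None:
        if self.counted_success:
            assert self.is_monophyletic


def species_monophyly(
    phylo: PhyloTree,
    species_map: SpeciesMap,
    support_threshold: float = 50.0,
) -> list[MonophylyVerdict]:
    """Monophyly + support verdicts for every non-singleton species.

    The species map may cover only part of the leaves (outgroup leaves are
    simply ignored); species with samples missing from the tree raise.
    A tree without bootstrap supports yields topology-only verdicts
    (``support=None``; counted on monophyly alone).
    """
    leaves = phylo.leaf_labels
    n = len(leaves)
    ref = min(leaves)
    bips = phylo.bipartitions()
    verdicts: list[MonophylyVerdict] = []
    for sp in sorted(species_map.mapping):
        samples = species_map.mapping[sp]
        if not samples <= leaves:
            raise InputError(f"species {sp!r} has samples missing from tree")
        if len(samples) < 2:
            continue
        if len(samples) >= n - 1:
            # complement is a single leaf edge: trivially monophyletic
            mono, support = True, 100.0
        else:
            key = samples if ref not in samples else leaves - samples
            key = frozenset(key)
            mono = key in bips
            if phylo.supports is None:
                support = None
            else:
                support = phylo.supports.get(key, 0.0) if mono else 0.0
        counted = mono and (support is None or support > support_threshold)
        verdicts.append(
            MonophylyVerdict(
                species=sp,
                is_monophyletic=mono,
                support=support,
                counted_success=counted,
            )
        )
    return verdicts


def tree_discrimination(
    phylo: PhyloTree,
    species_map: SpeciesMap,
    support_threshold: float = 50.0,
) -> DiscriminationReport:
    """Per-individual discrimination rate from monophyly verdicts."""
    smap = effective_species_map(
        # reuse matrix-restriction logic via a shim: restrict to tree leaves
        _FakeMatrix(sorted(phylo.leaf_labels)), species_map
    )
    verdicts = species_monophyly(phylo, smap, support_threshold)
    if not verdicts:
        raise InputError("no eligible species in tree")
    per_species = {v.species: v.counted_success for v in verdicts}
    per_individual: dict[str, bool] = {}
    for v in verdicts:
        for sample in smap.mapping[v.species]:
            per_individual[sample] = v.counted_success
    return DiscriminationReport(
        method="NJ",
        per_species=per_species,
        per_individual=per_individual,
        n_success_individuals=sum(per_individual.values()),
        n_eligible_individuals=len(per_individual),
    )


class _FakeMatrix:
    """Duck-typed stand-in exposing .ids for effective_species_map."""

    def __init__(self, ids: Iterable[str]):
        self.ids = list(ids)
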