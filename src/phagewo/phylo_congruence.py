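"""Bootstrap distance trees and phage/symbiont incongruence summaries.

Trees are neighbor-joining on K2P distances with bootstrap branch support
(column resampling).  Congruence between the phage tree and the symbiont
(Wolbachia MLST) tree is summarised by (a) the normalized Robinson–Foulds
distance after collapsing phage leaves to strain labels and (b) the list of
phage types whose nearest phage-tree neighbor maps to a different strain —
the tanglegram-crossing candidates that flag horizontally moved types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj

from .core_io import AlignedSet, RunConfig
from .typing import DistanceMatrix, distance_matrix


class TreeError(ValueError):
    pass


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a K2P distance matrix.

    Requires >= 3 taxa and all distances defined (finite); negative branch
    lengths are clamped to zero.  Deterministic under fixed input order.
    """
    n = len(dm.ids)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        bad = np.argwhere(~np.isfinite(dm.d))
        i, j = bad[0]
        raise TreeError(
            f"undefined distance between {dm.ids[i]!r} and {dm.ids[j]!r}"
        )
    sk = _SkbioDM(dm.d, ids=dm.ids)
    return _skbio_nj(sk, neg_as_zero=True)


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    smaller-or-lexicographically-first side's leaf-name frozenset."""
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            canon = min(side, other, key=lambda s: (len(s), sorted(s)))
            parts.add(canon)
    return parts


def robinson_foulds(t1: TreeNode, t2: TreeNode, normalize: bool = True) -> float:
    """(Normalized) Robinson–Foulds distance via explicit bipartition sets.

    Symmetric difference of the two trees' non-trivial bipartitions; when
    normalized, divided by the total number of bipartitions in both trees
    (0 for two stars).  Multifurcations are handled naturally — a collapsed
    node simply contributes fewer bipartitions.
    """
    if {t.name for t in t1.tips()} != {t.name for t in t2.tips()}:
        raise TreeError("trees must share an identical leaf set")
    b1, b2 = _bipartitions(t1), _bipartitions(t2)
    rf = len(b1 ^ b2)
    if not normalize:
        return float(rf)
    denom = len(b1) + len(b2)
    return rf / denom if denom else 0.0


def bootstrap_support(
    aln: AlignedSet, cfg: RunConfig | None = None, mode: str = "k2p_distance"
) -> TreeNode:
    """NJ tree with bootstrap branch supports (% of column resamples
    containing each internal bipartition), seeded via ``cfg.rng_seed``.

    Supports are written to internal node names, the usual newick
    convention for distance trees.
    """
    cfg = cfg or RunConfig()
    base_dm = distance_matrix(aln, mode=mode)
    tree = nj_tree(base_dm)
    counts: dict[frozenset, int] = {b: 0 for b in _bipartitions(tree)}
    rng = np.random.default_rng(cfg.rng_seed)
    for _ in range(cfg.bootstrap_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep_aln = AlignedSet(
            [
                type(r)(id=r.id, seq="".join(r.seq[c] for c in cols),
                        species=r.species, family=r.family,
                        strain_st=r.strain_st, wsp_allele=r.wsp_allele,
                        supergroup=r.supergroup)
                for r in aln.records
            ],
            aln.length,
        )
        try:
            rep_tree = nj_tree(distance_matrix(rep_aln, mode=mode))
        except TreeError:  # saturated replicate: supports nothing
            continue
        rep_parts = _bipartitions(rep_tree)
        for b in counts:
            if b in rep_parts:
                counts[b] += 1
    leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            canon = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
            node.name = str(
                int(round(100.0 * counts[canon] / cfg.bootstrap_reps))
            )
    return tree


def crossing_candidates(phage_tree: TreeNode, link: dict) -> list[str]:
    """Phage leaves with a same-strain companion whose nearest tree neighbor
    nonetheless maps to a different strain (tanglegram crossings)."""
    leaves = [t.name for t in phage_tree.tips()]
    if len(leaves) < 2:
        return []
    strain_counts: dict[str, int] = {}
    for l in leaves:
        strain_counts[link[l]] = strain_counts.get(link[l], 0) + 1
    dm = phage_tree.tip_tip_distances()
    out = []
    for leaf in leaves:
        if strain_counts[link[leaf]] < 2:
            continue  # no companion: nothing to cross against
        _, nearest = min(
            (dm[leaf, other], other) for other in leaves if other != leaf
        )
        if link[nearest] != link[leaf]:
            out.append(leaf)
    return out


@dataclass
class CongruenceReport:
    """Phage-vs-symbiont topology comparison."""

    n_rf: float
    crossing_types: list[str]  # phage leaves whose nearest neighbor maps elsewhere
    n_shared_strains: int


def collapse_to_strains(phage_tree: TreeNode, link: dict) -> TreeNode:
    """Relabel phage leaves by their strain and prune to one leaf per strain
    (the first encountered in tree traversal order)."""
    tree = phage_tree.copy()
    seen: set[str] = set()
    keep = []
    for tip in tree.tips():
        if tip.name not in link:
            raise TreeError(f"phage leaf {tip.name!r} has no strain mapping")
        strain = link[tip.name]
        if strain in seen:
            continue
        seen.add(strain)
        tip.name = strain
        keep.append(strain)
    tree = tree.shear(keep)
    tree.prune()
    return tree


def congruence(
    phage_tree: TreeNode, symbiont_tree: TreeNode, link: dict
) -> CongruenceReport:
    """Quantify phage/symbiont incongruence.

    ``link`` maps each phage-tree leaf (type name) to a symbiont-tree leaf
    (strain key).  nRF is computed between the symbiont tree restricted to
    linked strains and the phage tree collapsed to strain labels; the
    crossing list contains every phage type that has at least one same-strain
    companion in the tree yet whose nearest phage-tree neighbor (patristic
    distance, ties broken lexicographically) maps to a different strain —
    under vertical co-divergence each strain's types form their own clade and
    the list is empty.
    """
    phage_leaves = [t.name for t in phage_tree.tips()]
    unmapped = [l for l in phage_leaves if l not in link]
    if unmapped:
        raise TreeError(f"unmapped phage leaves: {unmapped}")
    strains = sorted({link[l] for l in phage_leaves})
    symb_leaves = {t.name for t in symbiont_tree.tips()}
    missing = [s for s in strains if s not in symb_leaves]
    if missing:
        raise TreeError(f"strains absent from symbiont tree: {missing}")

    collapsed = collapse_to_strains(phage_tree, link)
    symb = symbiont_tree.copy().shear(strains)
    symb.prune()
    n_rf = robinson_foulds(collapsed, symb) if len(strains) >= 4 else 0.0

    crossing = crossing_candidates(phage_tree, link)
    return CongruenceReport(
        n_rf=n_rf, crossing_types=crossing, n_shared_strains=len(strains)
    )
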