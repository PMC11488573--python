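"""Community phylogenetic diversity metrics.

Three standard presence-based metrics on a dated tree:

* Faith's PD — total branch length of the minimal subtree connecting a
  species set.  The convention here is *root-inclusive*: the subtree
  includes the path down to the root, so even a single species carries
  its full root-to-tip lineage length.  A crown-only variant (branch
  length within the set's own MRCA) is available via ``rooted=False``.
* MPD — mean patristic distance over all unordered pairs in the set.
* MNTD — mean, over set members, of each member's distance to its nearest
  other member.

All values are in the tree's branch-length units (millions of years for a
dated phylogeny).  Functions are pure; how empty or singleton sets are
treated (e.g. PD = 0 for no N-fixers, MPD = MNTD = 0 for a single fixer)
is a caller-level convention, so these primitives raise instead of
guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import Phylogeny

__all__ = ["PDResult", "faith_pd", "mpd", "mntd", "pd_summary"]


@dataclass(frozen=True)
class PDResult:
    """Bundle of the three diversity metrics for one species set.

    ``mpd``/``mntd`` are ``None`` for singleton sets, where no pairwise
    distance exists.
    """

    faith_pd: float
    mpd: float | None
    mntd: float | None
    n_taxa: int


def faith_pd(tree: Phylogeny, taxa, *, rooted: bool = True) -> float:
    """Faith's phylogenetic diversity of `taxa` on `tree` (My).

    Computed as the summed length of the union of root-to-tip edge paths.
    With ``rooted=False`` the shared path from the root to the set's MRCA
    is excluded (crown-based PD).
    """
    taxa = tree._require_tips(taxa)
    if not taxa:
        raise ValueError("faith_pd of an empty set is a caller convention")
    edges: set[int] = set()
    if rooted or len(taxa) == 1:
        for t in taxa:
            edges.update(tree.root_path_edges(t))
    else:
        paths = [tree.root_path_edges(t) for t in taxa]
        shared = frozenset.intersection(*paths)
        for p in paths:
            edges.update(p - shared)
    lengths = tree.edge_lengths
    return float(sum(lengths[i] for i in edges))


def mpd(tree: Phylogeny, taxa) -> float:
    """Mean pairwise patristic distance (My); requires >= 2 taxa."""
    taxa = tree._require_tips(taxa)
    if len(taxa) < 2:
        raise ValueError("mpd needs at least two taxa")
    D = tree.patristic_distances().loc[taxa, taxa].to_numpy()
    iu = np.triu_indices(len(taxa), k=1)
    return float(D[iu].mean())


def mntd(tree: Phylogeny, taxa) -> float:
    """Mean nearest-taxon distance (My); requires >= 2 taxa."""
    taxa = tree._require_tips(taxa)
    if len(taxa) < 2:
        raise ValueError("mntd needs at least two taxa")
    D = tree.patristic_distances().loc[taxa, taxa].to_numpy().copy()
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).mean())


def pd_summary(tree: Phylogeny, taxa, *, singleton_zero: bool = False) -> PDResult:
    """All three metrics at once.

    With ``singleton_zero=True`` a single-species set reports
    MPD = MNTD = 0.0 rather than ``None`` — the convention used when
    single-fixer surveys are kept in distance-based analyses.
    """
    taxa = tree._require_tips(taxa)
    n = len(taxa)
    if n < 2:
        fill = 0.0 if singleton_zero else None
        return PDResult(faith_pd(tree, taxa), fill, fill, n)
    return PDResult(faith_pd(tree, taxa), mpd(tree, taxa), mntd(tree, taxa), n)
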