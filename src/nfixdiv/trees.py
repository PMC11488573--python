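"""Dated phylogenies: parsing, pruning, grafting, patristic distances.

The analysis works on a rooted, dated tree (branch lengths in millions of
years, My) whose tips are species names.  Community datasets routinely
contain species absent from the reference phylogeny; those are grafted in
at the genus or family level so that every recorded species can contribute
branch length to the diversity metrics.

Trees are held in a :class:`Phylogeny` wrapper around a
:class:`dendropy.Tree`.  The wrapper is treated as immutable: pruning and
grafting return new objects, which lets per-tree quantities (root paths,
patristic distances) be cached safely.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TaxonRecord",
    "parse_newick",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "graft_missing",
    "patristic_matrix",
    "read_trait_table",
]

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Canonical species label: stripped, internal whitespace -> underscore."""
    return _WS.sub("_", label.strip())


def genus_of(label: str) -> str:
    """Genus = first token of a binomial (case-sensitive)."""
    return normalize_label(label).split("_", 1)[0]


@dataclass(frozen=True)
class TaxonRecord:
    """Taxonomic placement and N-fixing status of one species.

    The N-fixer flag is a genus-level trait: nodulation ability is strongly
    conserved within genera, so community datasets assign it per genus.
    """

    species: str
    genus: str
    family: str
    is_fixer: bool

    def __post_init__(self):
        if not self.genus or not self.family:
            raise ValueError(
                f"taxon {self.species!r}: genus and family must be non-empty"
            )


class Phylogeny:
    """A rooted dated phylogeny with unique tip labels.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree.  Every non-root edge must carry a non-negative branch
        length; a missing root edge length is treated as zero.

    Notes
    -----
    Instances are immutable by convention: all tree surgery goes through
    module functions that return fresh objects.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate_and_index()

    # -- construction -------------------------------------------------

    def _validate_and_index(self) -> None:
        tree = self._tree
        root = tree.seed_node
        if root.edge.length is None:
            root.edge.length = 0.0
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n, dtype=np.float64)
        labels: list[str] = []
        tip_idx: list[int] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    where = nd.taxon.label if nd.taxon else "an internal node"
                    raise ValueError(f"missing branch length on edge above {where}")
                if nd.edge.length < 0:
                    raise ValueError("negative branch length")
                parent[i] = index[id(nd.parent_node)]
                length[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unlabeled tip")
                lab = normalize_label(nd.taxon.label)
                nd.taxon.label = lab
                labels.append(lab)
                tip_idx.append(i)
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels after normalization: {dup}")
        self._nodes = nodes
        self._parent = parent
        self._length = length
        self._tip_index = dict(zip(labels, tip_idx))
        # depth of every node (root-to-node path length)
        depth = np.zeros(n)
        for i in range(1, n):  # preorder: parent precedes child
            depth[i] = depth[parent[i]] + length[i]
        self._depth = depth
        self._root_paths: dict[str, frozenset[int]] = {}
        self._pdm: pd.DataFrame | None = None

    # -- basic queries -------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_index)

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def total_branch_length(self) -> float:
        return float(self._length.sum())

    def tip_depths(self) -> pd.Series:
        """Root-to-tip path lengths (My), indexed by tip label."""
        return pd.Series(
            {lab: self._depth[i] for lab, i in self._tip_index.items()},
            name="depth",
        )

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.tip_depths().to_numpy()
        return bool(d.max() - d.min() <= tol)

    def has_tip(self, label: str) -> bool:
        return normalize_label(label) in self._tip_index

    def _require_tips(self, taxa) -> list[str]:
        taxa = [normalize_label(t) for t in taxa]
        unknown = sorted(t for t in taxa if t not in self._tip_index)
        if unknown:
            raise KeyError(f"taxa not in tree: {unknown}")
        return taxa

    def root_path_edges(self, label: str) -> frozenset[int]:
        """Node indices whose parent edges form the tip's path to the root."""
        label = normalize_label(label)
        cached = self._root_paths.get(label)
        if cached is not None:
            return cached
        i = self._tip_index[label]
        path = []
        while i >= 0 and self._parent[i] >= 0:
            path.append(i)
            i = self._parent[i]
        out = frozenset(path)
        self._root_paths[label] = out
        return out

    @property
    def edge_lengths(self) -> np.ndarray:
        return self._length

    # -- distances -----------------------------------------------------

    def patristic_distances(self) -> pd.DataFrame:
        """Full tip-by-tip patristic distance matrix (My), cached.

        Computed from node depths: d(i, j) = depth_i + depth_j - 2 depth_lca.
        Pairs are assigned their LCA by combining tip sets in post-order.
        """
        if self._pdm is not None:
            return self._pdm
        labels = self.tip_labels
        pos = {self._tip_index[lab]: k for k, lab in enumerate(labels)}
        m = len(labels)
        D = np.zeros((m, m))
        tipd = np.array([self._depth[self._tip_index[lab]] for lab in labels])
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self._parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        # post-order accumulation of tip sets
        under: dict[int, np.ndarray] = {}
        for i in range(len(self._nodes) - 1, -1, -1):
            kids = children.get(i)
            if kids is None:
                under[i] = np.array([pos[i]], dtype=np.int64)
                continue
            groups = [under.pop(k) for k in kids]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia, ib = groups[a], groups[b]
                    block = np.add.outer(tipd[ia], tipd[ib]) - 2.0 * self._depth[i]
                    D[np.ix_(ia, ib)] = block
                    D[np.ix_(ib, ia)] = block.T
            under[i] = np.concatenate(groups)
        self._pdm = pd.DataFrame(D, index=labels, columns=labels)
        return self._pdm

    # -- IO ------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string with branch lengths at 9 significant digits."""
        root_edge = self._tree.seed_node.edge
        saved = root_edge.length
        if not saved:  # omit a zero root edge rather than writing ":0"
            root_edge.length = None
        try:
            s = self._tree.as_string(
                schema="newick",
                real_value_format_specifier=".9g",
                unquoted_underscores=True,
                suppress_rooting=True,
            )
        finally:
            root_edge.length = saved
        return s.strip() + "\n"

    def clone(self) -> dendropy.Tree:
        return self._tree.clone(depth=1)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny: {self.n_tips} tips, {self.total_branch_length:.6g} My>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Every edge must carry a branch length (a dated analysis cannot silently
    default missing lengths); malformed input raises :class:`ValueError`
    with the reader's line/column diagnostics.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several reader error types
        raise ValueError(f"malformed newick: {exc}") from exc
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick())


def prune_to_taxa(tree: Phylogeny, taxa) -> Phylogeny:
    """Restrict the tree to `taxa`, suppressing unary nodes.

    Branch lengths through suppressed nodes are summed, so patristic
    distances among the retained tips are unchanged.
    """
    taxa = tree._require_tips(taxa)
    if not taxa:
        raise ValueError("cannot prune to an empty taxon set")
    work = tree.clone()
    work.retain_taxa_with_labels(taxa)
    # collapse a unary root chain left by dendropy so no dangling stem remains
    root = work.seed_node
    while len(root.child_nodes()) == 1 and not root.is_leaf():
        child = root.child_nodes()[0]
        work.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    return Phylogeny(work)


def patristic_matrix(tree: Phylogeny, taxa) -> pd.DataFrame:
    """Symmetric matrix of path-length distances (My) among `taxa`."""
    taxa = tree._require_tips(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    return tree.patristic_distances().loc[taxa, taxa]


def _node_depths(tree: dendropy.Tree) -> dict[int, float]:
    depth = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
    return depth


def graft_missing(tree: Phylogeny, records: list[TaxonRecord]) -> Phylogeny:
    """Add species missing from the tree at the genus or family level.

    Placement is anchored on the *original* tree only, so the outcome does
    not depend on the order in which species are grafted:

    * genus level, >=2 congeneric tips: the new tip joins the genus crown
      (MRCA of the congeners) as a polytomy;
    * genus level, exactly 1 congeneric tip: the congener's pendant branch
      is split at its midpoint and the new tip attaches there (a cherry);
    * family level (no congeners present): same rules applied to the tips
      of the family.

    The pendant length is chosen so the new tip's root-to-tip depth equals
    the mean depth of its anchor group; on an ultrametric tree this keeps
    the tree ultrametric.

    Raises
    ------
    KeyError
        If any record's genus and family are both absent from the tree;
        the message lists the offending species so the caller can decide
        to drop them.
    """
    existing = set(tree.tip_labels)
    genus_tips: dict[str, list[str]] = {}
    for lab in existing:
        genus_tips.setdefault(genus_of(lab), []).append(lab)
    genus_family = {r.genus: r.family for r in records}
    family_tips: dict[str, list[str]] = {}
    for g, tips in genus_tips.items():
        fam = genus_family.get(g)
        if fam:
            family_tips.setdefault(fam, []).extend(tips)

    missing = [r for r in records if normalize_label(r.species) not in existing]
    if not missing:
        return tree

    unplaceable = []
    groups: dict[tuple[str, str], list[TaxonRecord]] = {}
    for r in missing:
        if r.genus in genus_tips:
            groups.setdefault(("genus", r.genus), []).append(r)
        elif r.family in family_tips:
            groups.setdefault(("family", r.family), []).append(r)
        else:
            unplaceable.append(r.species)
    if unplaceable:
        raise KeyError(
            "species with neither genus nor family in the tree: "
            f"{sorted(unplaceable)}"
        )

    work = tree.clone()
    work.is_rooted = True
    work.migrate_taxon_namespace(dendropy.TaxonNamespace())
    depth = _node_depths(work)
    label_node = {
        normalize_label(nd.taxon.label): nd for nd in work.leaf_node_iter()
    }
    ns = work.taxon_namespace

    orig_depths = tree.tip_depths()
    ordered = sorted(groups.items())
    # resolve every anchor node before any surgery: tree edits invalidate
    # dendropy's cached bipartitions used by mrca()
    mrca_of = {
        (level, key): work.mrca(
            taxa=[
                label_node[a].taxon
                for a in (genus_tips[key] if level == "genus" else family_tips[key])
            ]
        )
        for (level, key), _ in ordered
        if len(genus_tips[key] if level == "genus" else family_tips[key]) >= 2
    }
    for (level, key), recs in ordered:
        anchors = genus_tips[key] if level == "genus" else family_tips[key]
        mean_depth = float(orig_depths[anchors].mean())
        if len(anchors) >= 2:
            attach = mrca_of[(level, key)]
            attach_depth = depth[id(attach)]
        else:
            # split the lone anchor's pendant edge at its midpoint
            leaf = label_node[anchors[0]]
            parent = leaf.parent_node
            half = leaf.edge.length / 2.0
            mid = parent.new_child(edge_length=half)
            parent.remove_child(leaf)
            mid.add_child(leaf)
            leaf.edge.length = half
            attach = mid
            attach_depth = depth[id(parent)] + half
            depth[id(mid)] = attach_depth
        pendant = max(mean_depth - attach_depth, 0.0)
        for r in sorted(recs, key=lambda x: x.species):
            taxon = ns.new_taxon(label=normalize_label(r.species))
            attach.new_child(taxon=taxon, edge_length=pendant)
    return Phylogeny(work)


def read_trait_table(path) -> list[TaxonRecord]:
    """Read a species trait table (CSV: species,genus,family,is_fixer).

    `is_fixer` must be 0/1 and constant within each genus.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"species", "genus", "family", "is_fixer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if not df["is_fixer"].isin({"0", "1"}).all():
        raise ValueError("is_fixer must be 0 or 1")
    records = [
        TaxonRecord(
            species=normalize_label(row.species),
            genus=row.genus.strip(),
            family=row.family.strip(),
            is_fixer=row.is_fixer == "1",
        )
        for row in df.itertuples()
    ]
    by_genus: dict[str, bool] = {}
    for r in records:
        prev = by_genus.setdefault(r.genus, r.is_fixer)
        if prev != r.is_fixer:
            raise ValueError(
                f"N-fixer status varies within genus {r.genus!r}; the trait "
                "is assigned at the genus level"
            )
    return records


def write_trait_table(records: list[TaxonRecord], path) -> None:
    pd.DataFrame(
        {
            "species": [r.species for r in records],
            "genus": [r.genus for r in records],
            "family": [r.family for r in records],
            "is_fixer": [int(r.is_fixer) for r in records],
        }
    ).to_csv(path, index=False)
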