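"""Shared fixtures and independent oracles.

The oracles deliberately take different computational routes from the
package: distances come from dendropy's own phylogenetic distance matrix
or naive path walks, Faith's PD from an edge-subtree membership scan, and
mixed-model references from closed forms or statsmodels.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from nfixdiv import TaxonRecord, parse_newick
from nfixdiv.trees import Phylogeny


# ---------------------------------------------------------------------
# random tree source independent of the package's Yule simulator

def random_newick(rng: np.random.Generator, n_tips: int, *, ultrametric=False) -> str:
    """Random binary tree via recursive splitting with random lengths."""
    labels = [f"t{i}" for i in range(n_tips)]

    def build(group):
        if len(group) == 1:
            return group[0]
        k = int(rng.integers(1, len(group)))
        left, right = group[:k], group[k:]
        bl, br = rng.uniform(0.1, 2.0, size=2)
        return f"({build(left)}:{bl:.6f},{build(right)}:{br:.6f})"

    perm = [labels[i] for i in rng.permutation(n_tips)]
    tree = f"{build(perm)};"
    if not ultrametric:
        return tree
    # stretch pendant edges so all tips reach the max depth
    phylo = parse_newick(tree)
    depths = phylo.tip_depths()
    target = float(depths.max()) + 1.0
    dt = phylo._tree
    for leaf in dt.leaf_node_iter():
        leaf.edge.length += target - depths[leaf.taxon.label]
    return Phylogeny(dt).to_newick()


# ---------------------------------------------------------------------
# oracles

def dendropy_distances(newick: str) -> dict[tuple[str, str], float]:
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = t.phylogenetic_distance_matrix()
    taxa = list(t.taxon_namespace)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            d = pdm.patristic_distance(a, b)
            out[(a.label, b.label)] = d
            out[(b.label, a.label)] = d
    return out


def faith_pd_oracle(newick: str, taxa: set[str]) -> float:
    """Root-inclusive Faith's PD by edge-subtree membership scan."""
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    total = 0.0
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node or edge.length is None:
            continue
        below = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
        if below & taxa:
            total += edge.length
    return total


def mpd_oracle(newick: str, taxa: list[str]) -> float:
    d = dendropy_distances(newick)
    vals = [d[(a, b)] for i, a in enumerate(taxa) for b in taxa[i + 1:]]
    return float(np.mean(vals))


def mntd_oracle(newick: str, taxa: list[str]) -> float:
    d = dendropy_distances(newick)
    mins = [min(d[(a, b)] for b in taxa if b != a) for a in taxa]
    return float(np.mean(mins))


# ---------------------------------------------------------------------
# fixtures

@pytest.fixture
def abc_tree():
    """The 3-tip worked example: ((A:1,B:1):1,C:2);"""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def letter_traits():
    """A..F with A,B,C fixers (three genera; trait genus-constant)."""
    return [
        TaxonRecord("A", "Alpha", "Fab", True),
        TaxonRecord("B", "Beta", "Fab", True),
        TaxonRecord("C", "Gamma", "Fab", True),
        TaxonRecord("D", "Delta", "Ros", False),
        TaxonRecord("E", "Epsilon", "Ros", False),
        TaxonRecord("F", "Zeta", "Ros", False),
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated study reused across pipeline-level tests."""
    from nfixdiv.synthetic import preset_config, simulate_dataset

    cfg = preset_config(
        "study", seed=11, n_sites=10, plots_per_site=6, n_species=150
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_env_changes(small_dataset):
    from nfixdiv.environment import env_change

    env = small_dataset.environment
    return {
        r.site: env_change(
            env[env["site"] == r.site], r.baseline_year, r.resurvey_year
        )
        for r in small_dataset.survey_years.itertuples()
    }
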