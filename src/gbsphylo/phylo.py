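"""Tree building and topology-concordance diagnostics.

The built-in desk-scale tree engine is neighbour joining on allele-
sharing distances, with nonparametric bootstrap over sites for clade
support.  Concordance between assemblies / filter settings is measured
by Robinson–Foulds bipartition distance; alignments can be exported
(see :mod:`gbsphylo.io`) for external ML or quartet engines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

Split = frozenset  # side of a bipartition, canonicalised (see Tree.bipartitions)


class Tree:
    """Unrooted leaf-labelled tree with branch lengths and supports.

    Thin wrapper over a dendropy tree; topology comparisons go through
    canonical bipartition sets: each non-trivial split is represented by
    the frozenset of leaf labels on the side *not* containing the
    lexicographically smallest leaf.
    """

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = False
        self._dtree = dtree

    # -- constructors --------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            from .io import NewickParseError

            raise NewickParseError(f"cannot parse newick: {exc}") from exc
        return cls(dtree)

    def to_newick(self) -> str:
        return self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    # -- leaves and splits --------------------------------------------
    @property
    def leaves(self) -> frozenset:
        return frozenset(
            lf.taxon.label for lf in self._dtree.leaf_node_iter()
        )

    def _internal_nodes_with_splits(self):
        leaves = self.leaves
        ref = min(leaves)
        n = len(leaves)
        seed = self._dtree.seed_node
        for node in self._dtree.preorder_node_iter():
            if node is seed or node.is_leaf():
                continue
            clade = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if not 2 <= len(clade) <= n - 2:
                continue
            side = clade if ref not in clade else leaves - clade
            yield node, Split(side)

    def bipartitions(self) -> set:
        """Canonical non-trivial splits of the tree (polytomies fine)."""
        return {s for _, s in self._internal_nodes_with_splits()}

    def supports(self) -> dict:
        """Split -> support value parsed from internal node labels."""
        out = {}
        for node, split in self._internal_nodes_with_splits():
            if node.label is not None:
                try:
                    out[split] = float(node.label)
                except ValueError:
                    pass
        return out

    def set_supports(self, supports: Mapping[frozenset, float]) -> None:
        for node, split in self._internal_nodes_with_splits():
            if split in supports:
                node.label = format(supports[split], "g")

    # -- metrics -------------------------------------------------------
    def path_distances(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length (patristic) distance matrix."""
        pdm = self._dtree.phylogenetic_distance_matrix()
        labels = sorted(t.label for t in self._dtree.taxon_namespace)
        taxa = {t.label: t for t in self._dtree.taxon_namespace}
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                out.at[a, b] = out.at[b, a] = d
        return out

    def collapsed(self, min_length: float = 1e-12) -> "Tree":
        """Copy with internal edges shorter than ``min_length`` collapsed.

        Zero-length internal edges carry no topological information
        (e.g. arbitrary resolution among identical samples); collapsing
        them yields the supported polytomy.
        """
        clone = self._dtree.clone(depth=1)
        for edge in list(clone.preorder_edge_iter()):
            head = edge.head_node
            if head.is_leaf() or edge.tail_node is None:
                continue
            if edge.length is None or edge.length < min_length:
                edge.collapse()
        return Tree(clone)


@dataclass
class ConcordanceReport:
    """Robinson–Foulds comparison of two trees on one leaf set."""

    rf: int
    normalized_rf: float
    shared_clades: list  # (split, support_in_a, support_in_b)
    unique_to_a: list
    unique_to_b: list


# ---------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------

def _pdistance_core(genotypes: np.ndarray, samples: Sequence[str]) -> pd.DataFrame:
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples for a distance matrix")
    g = genotypes.astype(float)
    valid = genotypes != MISSING
    shared = valid.astype(np.int64) @ valid.astype(np.int64).T
    bad = np.argwhere(~np.eye(n, dtype=bool) & (shared == 0))
    if len(bad):
        pairs = sorted(
            {tuple(sorted((samples[i], samples[j]))) for i, j in bad}
        )
        raise ValueError(
            f"distance undefined (no shared non-missing sites) for: {pairs}"
        )
    g[~valid] = np.nan
    diff = np.abs(g[:, None, :] - g[None, :, :]) / 2.0
    with np.errstate(invalid="ignore"):
        d = np.nanmean(diff, axis=2)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=list(samples), columns=list(samples))


def pdistance_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise allele-sharing distances between samples.

    distance(i, j) = mean over sites non-missing in both samples of
    |g_i - g_j| / 2, so heterozygote-vs-homozygote contributes 0.5 and
    opposite homozygotes contribute 1.  A pair with zero shared sites
    makes the distance undefined and raises.
    """
    return _pdistance_core(matrix.genotypes, matrix.samples)


# ---------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------

def _fmt_len(x: float) -> str:
    return format(x, ".12g")


def nj_tree(distances: pd.DataFrame | np.ndarray, labels=None) -> Tree:
    """Neighbour-joining tree with deterministic tie-breaking.

    Ties in the Q criterion are broken toward the pair whose sorted
    label pair is lexicographically smallest (an internal node carries
    the smallest label among its leaves).  Negative branch lengths are
    clamped to zero and the total clamped deficit logged.
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        D = distances.to_numpy(dtype=float).copy()
    else:
        D = np.asarray(distances, dtype=float).copy()
        if labels is None:
            labels = [f"t{i}" for i in range(len(D))]
        labels = list(labels)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square with matching labels")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if (D < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    newicks = list(labels)
    tie_labels = list(labels)
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    m = n
    while m > 3:
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, 1)
        qvals = Q[iu]
        qmin = qvals.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cand = [
            (tuple(sorted((tie_labels[i], tie_labels[j]))), i, j)
            for i, j in zip(*iu)
            if Q[i, j] <= qmin + tol
        ]
        _, i, j = min(cand)
        li = clamp(D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = clamp(D[i, j] - (D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))))
        new_newick = (
            f"({newicks[i]}:{_fmt_len(li)},{newicks[j]}:{_fmt_len(lj)})"
        )
        new_label = min(tie_labels[i], tie_labels[j])
        du = (D[i, :] + D[j, :] - D[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack(
            [
                np.hstack([D[np.ix_(keep, keep)], du[keep][:, None]]),
                np.hstack([du[keep], [0.0]]),
            ]
        )
        newicks = [newicks[k] for k in keep] + [new_newick]
        tie_labels = [tie_labels[k] for k in keep] + [new_label]
        m -= 1

    la = clamp((D[0, 1] + D[0, 2] - D[1, 2]) / 2.0)
    lb = clamp((D[0, 1] + D[1, 2] - D[0, 2]) / 2.0)
    lc = clamp((D[0, 2] + D[1, 2] - D[0, 1]) / 2.0)
    newick = (
        f"({newicks[0]}:{_fmt_len(la)},{newicks[1]}:{_fmt_len(lb)},"
        f"{newicks[2]}:{_fmt_len(lc)});"
    )
    if deficit > 0:
        logger.info("nj_tree: clamped negative branch length deficit %.3g",
                    deficit)
    tree = Tree.from_newick(newick)
    return tree


# ---------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------

def bootstrap_trees(
    matrix: GenotypeMatrix,
    replicates: int = 500,
    seed: int | None = None,
) -> tuple[Tree, list[Tree]]:
    """NJ tree with bootstrap supports from site resampling.

    Sites are resampled with replacement ``replicates`` times; the
    support of each main-tree bipartition is the percentage of
    replicate trees containing it.  Seeded runs are reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    main = nj_tree(pdistance_matrix(matrix))
    rng = np.random.default_rng(seed)
    main_splits = main.bipartitions()
    counts = {s: 0 for s in main_splits}
    rep_trees = []
    m = matrix.n_sites
    for _ in range(replicates):
        idx = rng.integers(0, m, size=m)
        rep = nj_tree(_pdistance_core(matrix.genotypes[:, idx], matrix.samples))
        rep_splits = rep.bipartitions()
        for s in main_splits:
            if s in rep_splits:
                counts[s] += 1
        rep_trees.append(rep)
    supports = {s: 100.0 * c / replicates for s, c in counts.items()}
    main.set_supports(supports)
    return main, rep_trees


# ---------------------------------------------------------------------
# Robinson–Foulds concordance
# ---------------------------------------------------------------------

def rf_distance(tree_a: Tree, tree_b: Tree) -> ConcordanceReport:
    """Robinson–Foulds comparison (symmetric bipartition difference)."""
    la, lb = tree_a.leaves, tree_b.leaves
    if la != lb:
        raise ValueError(
            f"leaf sets differ: only in a={sorted(la - lb)}, "
            f"only in b={sorted(lb - la)}"
        )
    sa, sb = tree_a.bipartitions(), tree_b.bipartitions()
    sup_a, sup_b = tree_a.supports(), tree_b.supports()
    shared = sorted(sa & sb, key=sorted)
    only_a = sorted(sa - sb, key=sorted)
    only_b = sorted(sb - sa, key=sorted)
    rf = len(only_a) + len(only_b)
    n = len(la)
    denom = 2 * (n - 3)
    nrf = rf / denom if denom > 0 else (0.0 if rf == 0 else float("nan"))
    return ConcordanceReport(
        rf=rf,
        normalized_rf=nrf,
        shared_clades=[
            (s, sup_a.get(s, float("nan")), sup_b.get(s, float("nan")))
            for s in shared
        ],
        unique_to_a=only_a,
        unique_to_b=only_b,
    )


def concordance_suite(
    matrices: Mapping[str, GenotypeMatrix],
    replicates: int = 200,
    seed: int | None = None,
    min_support: float = 80.0,
) -> tuple[pd.DataFrame, dict]:
    """Cross-assembly topology concordance over shared samples.

    Builds a bootstrapped NJ tree per named matrix (restricted to the
    samples common to all of them) and reports pairwise RF distances,
    normalised RF, and the count of shared clades supported at or above
    ``min_support`` in both trees.
    """
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least two named matrices")
    shared = [
        s
        for s in matrices[names[0]].samples
        if all(s in set(matrices[n].samples) for n in names[1:])
    ]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared samples; need at least 3"
        )
    trees = {}
    for k, name in enumerate(names):
        sub = matrices[name].select_samples(shared)
        rep_seed = None if seed is None else seed + k
        trees[name], _ = bootstrap_trees(sub, replicates, rep_seed)
    rows, reports = [], {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rep = rf_distance(trees[a], trees[b])
            n_strong = sum(
                1
                for _, sa, sb in rep.shared_clades
                if sa >= min_support and sb >= min_support
            )
            rows.append(
                {
                    "matrix_a": a,
                    "matrix_b": b,
                    "rf": rep.rf,
                    "normalized_rf": rep.normalized_rf,
                    "shared_clades": len(rep.shared_clades),
                    f"shared_clades_ge_{min_support:g}": n_strong,
                }
            )
            reports[(a, b)] = rep
    return pd.DataFrame(rows), reports
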