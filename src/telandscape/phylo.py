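"""Neighbor-joining phylogeny with bootstrap support.

Built for trees of reverse-transcriptase / ribonuclease-H amino-acid
domains of LTR retrotransposon families, from a user-supplied multiple
alignment (aligned FASTA). Distances are uncorrected p-distances by
default, with a Poisson correction (-ln(1-p)) available; trees come from
the canonical neighbor-joining agglomeration (consistent on additive
matrices), and node support from nonparametric bootstrap over alignment
columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA as (label, gapped sequence) pairs."""
    from Bio import SeqIO

    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


_GAPS = frozenset("-.")


def pdistance(
    msa: list[tuple[str, str]], poisson_correct: bool = False
) -> DistanceMatrix:
    """Pairwise p-distance over comparable (both non-gap) columns.

    With ``poisson_correct`` the distance is -ln(1-p), a simple
    multiple-hit correction for amino-acid data. A pair with no
    comparable columns is an error; a ragged alignment is rejected.
    """
    if not msa:
        raise ValueError("empty alignment")
    labels = [name for name, _ in msa]
    length = len(msa[0][1])
    for name, seq in msa:
        if len(seq) != length:
            raise ValueError(f"ragged alignment: {name} has {len(seq)} cols")
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for a, b in zip(msa[i][1], msa[j][1]):
                if a in _GAPS or b in _GAPS:
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            p = mismatch / comparable
            if poisson_correct:
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {labels[i]}/{labels[j]} (p=1)"
                    )
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa=labels, d=d)


@dataclass
class NJTree:
    """Unrooted NJ tree held as a dendropy tree with a trifurcating seed
    node; ``clamped_edges`` lists edges whose negative length estimates
    were clamped to zero."""

    tree: dendropy.Tree
    clamped_edges: int = 0
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter()
        )

    def as_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick", suppress_rooting=True
            ).strip()
        )


def neighbor_joining(dm: DistanceMatrix) -> NJTree:
    """Canonical neighbor joining (Saitou & Nei / Studier & Keppler).

    Q(i,j) = (n-2) d(i,j) - r_i - r_j with r_i the row sum; the minimizing
    pair joins (ties broken by lexicographically smallest index pair);
    limb lengths from the standard two-point formula, negative estimates
    clamped to zero and counted. Terminates by connecting the last three
    lineages to one trifurcating node via the three-point closed form.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    tns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    for label in dm.taxa:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    d = dm.d.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_dist = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_dist[keep]])
        d = np.hstack([d, np.append(new_dist[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # three-point closed form: l1 = (d12 + d13 - d23)/2, cyclically
    root = dendropy.Node()
    l = [
        clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2])),
        clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2])),
        clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1])),
    ]
    for node, length in zip(nodes, l):
        root.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return NJTree(tree=tree, clamped_edges=clamped)


def _bipartitions(tree: dendropy.Tree, all_taxa: frozenset) -> set[frozenset]:
    """Nontrivial bipartitions as canonical frozensets of leaf labels.

    Canonical form: the side not containing the alphabetically first
    taxon, making the set invariant to tree orientation.
    """
    ref = min(all_taxa)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if ref in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(all_taxa) - 2:
            out.add(side)
    return out


def bootstrap(
    msa: list[tuple[str, str]],
    n_reps: int = 1000,
    seed: int = 0,
    poisson_correct: bool = False,
) -> NJTree:
    """NJ tree on the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate is re-distanced and re-joined, and every internal edge of
    the full-data tree is annotated with the percentage of replicates
    containing the same leaf bipartition. Seeded and reproducible.
    """
    full = neighbor_joining(pdistance(msa, poisson_correct))
    all_taxa = frozenset(name for name, _ in msa)
    target = _bipartitions(full.tree, all_taxa)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    length = len(msa[0][1])
    names = [name for name, _ in msa]
    seqs = [seq for _, seq in msa]
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            (name, "".join(seq[c] for c in cols))
            for name, seq in zip(names, seqs)
        ]
        try:
            rep = neighbor_joining(pdistance(resampled, poisson_correct))
        except ValueError:
            # e.g. a resample with no comparable columns for some pair
            continue
        rep_bps = _bipartitions(rep.tree, all_taxa)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    full.supports = {
        bp: 100.0 * c / n_reps for bp, c in counts.items()
    }
    # annotate internal nodes with their edge's support
    for node in full.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        ref = min(all_taxa)
        if ref in side:
            side = all_taxa - side
        if side in full.supports:
            node.label = f"{full.supports[side]:.0f}"
    return full


def write_newick(tree: NJTree, path: str | Path) -> None:
    """Write newick with bootstrap supports as internal node labels."""
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
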