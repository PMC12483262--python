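"""Concatenated-PCG supermatrix and K2P neighbor-joining with bootstrap.

The 13 mitochondrial protein-coding genes are concatenated in genome
order (nad2, cox1, cox2, atp8, atp6, cox3, nad3, nad5, nad4, nad4L,
nad6, cytb, nad1) into a supermatrix with a partition table, the K2P
distance matrix is computed under pairwise deletion, and an unrooted
tree is built with the Saitou-Nei neighbor-joining algorithm.  Support
values come from nonparametric bootstrap: alignment columns are resampled
with replacement, the distance + NJ step is repeated per replicate, and
each internal bipartition of the point-estimate tree is annotated with
the percentage of replicates containing it.  Supports >= 70% are the
conventional moderate-confidence threshold.

Heavier model-based inference (ML, Bayesian) is deliberately exported,
not reimplemented: :func:`write_phylip` / :func:`write_partitions`
produce the inputs external tools expect, while NJ provides the in-repo
testable topology engine appropriate for near-identical mitogenomes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .divergence import SaturationError, encode
from .genome_io import MitogenomeRecord, extract_gene, write_fasta

__all__ = [
    "PCG_ORDER",
    "Supermatrix",
    "Node",
    "concatenate_pcgs",
    "supermatrix_from_records",
    "k2p_matrix",
    "nj_tree",
    "bootstrap",
    "write_newick",
    "write_phylip",
    "write_partitions",
    "tree_splits",
]

# canonical concatenation order: genome order of the 13 PCGs
PCG_ORDER = ("nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
             "nad5", "nad4", "nad4L", "nad6", "cytb", "nad1")


@dataclass
class Supermatrix:
    """Concatenated multi-gene alignment with a gene -> columns map."""

    taxa: tuple[str, ...]
    gene_order: tuple[str, ...]
    partitions: dict[str, tuple[int, int]]  # gene -> (start, end), 1-based inclusive
    sequences: dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def gene_alignment(self, gene: str) -> dict[str, str]:
        start, end = self.partitions[gene]
        return {t: self.sequences[t][start - 1: end] for t in self.taxa}


def concatenate_pcgs(
    per_gene: Mapping[str, Mapping[str, str]],
    gene_order: Sequence[str] = PCG_ORDER,
) -> Supermatrix:
    """Concatenate per-gene alignments into a supermatrix.

    Genes are taken in ``gene_order`` (genes absent from the input are
    skipped); a taxon missing from any used gene is dropped with a
    warning.  Within a gene all sequences must be aligned (equal length).
    """
    genes = [g for g in gene_order if g in per_gene]
    if not genes:
        raise ValueError("no genes from the requested order present in input")
    taxa: set[str] | None = None
    for g in genes:
        ids = set(per_gene[g])
        taxa = ids if taxa is None else taxa & ids
    all_taxa = set().union(*(set(per_gene[g]) for g in genes))
    dropped = sorted(all_taxa - (taxa or set()))
    if dropped:
        warnings.warn(f"taxa missing from some genes, dropped: {dropped}", stacklevel=2)
    if not taxa:
        raise ValueError("no taxon is present in every gene")
    order = tuple(sorted(taxa))
    partitions: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in order}
    col = 0
    for g in genes:
        lengths = {len(per_gene[g][t]) for t in order}
        if len(lengths) != 1:
            raise ValueError(f"gene {g}: unaligned sequences (lengths {sorted(lengths)})")
        L = lengths.pop()
        partitions[g] = (col + 1, col + L)
        col += L
        for t in order:
            chunks[t].append(per_gene[g][t].upper())
    return Supermatrix(taxa=order, gene_order=tuple(genes), partitions=partitions,
                       sequences={t: "".join(chunks[t]) for t in order})


def supermatrix_from_records(records: Sequence[MitogenomeRecord]) -> Supermatrix:
    """Build a supermatrix by extracting each PCG from annotated records.

    Valid when the extracted genes are equal-length across records (no
    indels), as produced by the simulator or by conspecific panels with a
    shared annotation.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated taxon/record id")
    per_gene: dict[str, dict[str, str]] = {}
    for rec in records:
        for feat in rec.pcgs:
            per_gene.setdefault(feat.name, {})[rec.id] = extract_gene(rec, feat)
    return concatenate_pcgs(per_gene)


# ---------------------------------------------------------------------------
# distance matrix

def _k2p_encoded(mat: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    n = len(ids)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        xa, xb = mat[i], mat[j]
        valid = (xa < 4) & (xb < 4)
        nc = int(valid.sum())
        if nc == 0:
            raise SaturationError(f"no comparable sites between {ids[i]} and {ids[j]}")
        av, bv = xa[valid], xb[valid]
        diff = av != bv
        ts = int((diff & ((av ^ bv) == 2)).sum())
        tv = int(diff.sum()) - ts
        p, q = ts / nc, tv / nc
        a1, a2 = 1 - 2 * p - q, 1 - 2 * q
        if a1 <= 0 or a2 <= 0:
            raise SaturationError(
                f"K2P saturated between {ids[i]} and {ids[j]} (P={p:.3f}, Q={q:.3f})"
            )
        D[i, j] = D[j, i] = -0.5 * np.log(a1) - 0.25 * np.log(a2)
    return D


def k2p_matrix(sm: Supermatrix | Mapping[str, str]) -> tuple[tuple[str, ...], np.ndarray]:
    """Pairwise K2P distance matrix over a supermatrix or aligned mapping."""
    seqs = sm.sequences if isinstance(sm, Supermatrix) else dict(sm)
    ids = tuple(sm.taxa) if isinstance(sm, Supermatrix) else tuple(seqs)
    mat = np.vstack([encode(seqs[t]) for t in ids])
    return ids, _k2p_encoded(mat, ids)


# ---------------------------------------------------------------------------
# trees

@dataclass
class Node:
    """Tree node; branch ``length`` is the edge to the parent."""

    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def postorder(self) -> Iterable["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self


def nj_tree(ids: Sequence[str], D: np.ndarray) -> Node:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Negative branch estimates are clamped to 0 with the deficit moved to
    the sister edge (their sum, the pair distance contribution, is
    preserved).  Ties in the Q criterion are broken by the smallest
    (i, j) pair in the current node ordering, which follows input order,
    so the result is deterministic.  Returns an unrooted tree: the root
    is a trifurcation for n >= 3 taxa.
    """
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if np.any(np.isnan(D)) or np.any(D < 0):
        raise ValueError("distance matrix must be non-negative and NaN-free")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        half = D[0, 1] / 2
        return Node(children=[Node(name=ids[0], length=half),
                              Node(name=ids[1], length=half)])

    nodes: list[Node] = [Node(name=t) for t in ids]
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple[float, int, int] | None = None
        for ai, aj in itertools.combinations(range(m), 2):
            q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
            if best is None or q < best[0] - 1e-12:
                best = (q, ai, aj)
        _, ai, aj = best  # type: ignore[misc]
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = max(vi, 0.0), max(vj, 0.0)
        new = Node(children=[child_i, child_j])
        # distances from the new node to every other active node
        new_idx = len(nodes)
        nodes.append(new)
        D = np.pad(D, ((0, 1), (0, 1)))
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            d = 0.5 * (D[i, k] + D[j, k] - dij)
            D[new_idx, k] = D[k, new_idx] = max(d, 0.0)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    for node, v in zip(root.children, (va, vb, vc)):
        node.length = max(v, 0.0)
    return root


def tree_splits(tree: Node) -> set[frozenset[str]]:
    """Nontrivial bipartitions, each canonicalized as the side excluding
    the alphabetically-first taxon."""
    taxa = tree.leaf_names()
    anchor = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        if anchor in side:
            side = taxa - side
        splits.add(side)
    return splits


@dataclass
class BootstrapResult:
    tree: Node
    n_replicates: int
    n_used: int
    n_skipped: int


def bootstrap(sm: Supermatrix, n_replicates: int, seed: int,
              outgroup: str | None = None) -> BootstrapResult:
    """NJ point tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; the K2P + NJ
    pipeline is rerun and each internal bipartition of the point tree is
    scored with the percentage of successful replicates containing it.
    One master seed spawns independent per-replicate streams, so earlier
    replicates are unchanged when the replicate count grows.  Replicates
    whose resampled distances saturate are skipped and counted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids, D = k2p_matrix(sm)
    point = nj_tree(ids, D)
    enc = np.vstack([encode(sm.sequences[t]) for t in ids])
    L = enc.shape[1]
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(point)}
    used = 0
    skipped = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        cols = rng.integers(0, L, size=L)
        try:
            Dr = _k2p_encoded(enc[:, cols], ids)
        except SaturationError:
            skipped += 1
            continue
        rep_splits = tree_splits(nj_tree(ids, Dr))
        used += 1
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    denom = max(used, 1)
    taxa = point.leaf_names()
    anchor = min(taxa)
    for node in point.postorder():
        if node is point or node.is_leaf:
            continue
        side = node.leaf_names()
        if len(side) < 2 or len(side) > len(taxa) - 2:
            continue
        key = side if anchor not in side else taxa - side
        node.support = 100.0 * counts[key] / denom
    tree = root_with_outgroup(point, outgroup) if outgroup else point
    return BootstrapResult(tree=tree, n_replicates=n_replicates,
                           n_used=used, n_skipped=skipped)


def root_with_outgroup(tree: Node, outgroup: str) -> Node:
    """Display-only rooting: reorder the root so the outgroup child is
    listed first.  The tree remains unrooted (no topology change)."""
    names = [c.leaf_names() for c in tree.children]
    for idx, s in enumerate(names):
        if outgroup in s:
            tree.children.insert(0, tree.children.pop(idx))
            break
    else:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    return tree


# ---------------------------------------------------------------------------
# serialization

def _newick_node(node: Node) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.10g}"
    inner = ",".join(_newick_node(c) for c in node.children)
    label = "" if node.support is None else f"{round(node.support):d}"
    return f"({inner}){label}:{node.length:.10g}"


def write_newick(tree: Node, path: str | Path | None = None) -> str:
    """Serialize to Newick (branch lengths, integer support labels)."""
    inner = ",".join(_newick_node(c) for c in tree.children)
    text = f"({inner});\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def write_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP (name, space, full sequence per line)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_columns}\n")
        for t in sm.taxa:
            fh.write(f"{t} {sm.sequences[t]}\n")


def write_partitions(sm: Supermatrix, path: str | Path) -> None:
    """Partition table TSV: gene, start, end (1-based inclusive)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tstart\tend\n")
        for g in sm.gene_order:
            s, e = sm.partitions[g]
            fh.write(f"{g}\t{s}\t{e}\n")


def write_supermatrix_fasta(sm: Supermatrix, path: str | Path) -> None:
    write_fasta({t: sm.sequences[t] for t in sm.taxa}, path)
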