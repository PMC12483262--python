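"""Mitogenome simulator: layout-faithful ancestors and K80 evolution.

The generator emulates the statistical structure of a mosquito
mitogenome so every pipeline stage can be exercised with known truth:

* an ancestral circular genome drawn i.i.d. with a target AT fraction
  (default 0.79, the AT content of Aedes mitogenomes) over the shipped
  38-feature Ae. aegypti annotation layout (16,662 bp);
* protein-coding genes are repaired after the draw so that each carries
  its annotated start codon, a complete or incomplete stop matching the
  layout, and no internal stop codon under the invertebrate
  mitochondrial code (internal TAA/TAG are removed by minimal edits,
  third position first);
* evolution along a user tree under the K80 (Kimura two-parameter)
  substitution process: per branch of length b (expected substitutions
  per site) each site receives Poisson(b) substitution events, each event
  being a transition with probability kappa/(kappa+2) — the embedded
  jump chain of the rate matrix with transition:transversion rate ratio
  kappa.  No indels are simulated, so per-gene extracts from the leaves
  are automatically aligned.
* an optional frame-protecting mode restricts PCG substitutions to third
  codon positions and rejects events that would create an internal stop,
  for tests that need valid ORFs at the leaves.

All randomness flows from a single integer seed; identical configs give
byte-identical outputs.  Realized per-branch transition/transversion
event counts and true pairwise path lengths are recorded in
:class:`SimTruth` for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .genome_io import (GeneFeature, MitogenomeRecord, extract_gene_coords,
                        load_reference_table, write_fasta, write_feature_table,
                        read_fasta)

__all__ = [
    "SimConfig",
    "SimTruth",
    "Panel",
    "default_layout",
    "make_ancestor",
    "evolve",
    "make_conspecific_panel",
    "write_panel",
    "read_panel",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = ("TAA", "TAG")  # translation table 5
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {b: tuple(x for x in _BASES if x != b and x != _TRANSITION[b])
                  for b in _BASES}
# start-codon frequencies used when a layout omits the annotation:
# the mosquito mitogenome spectrum (ATN dominant, occasional GTG/TCG)
_START_CHOICES = ("ATG", "ATT", "ATA", "GTG", "TCG")
_START_WEIGHTS = (0.40, 0.30, 0.15, 0.10, 0.05)


def default_layout() -> tuple[GeneFeature, ...]:
    """The shipped Ae. aegypti 38-feature annotation layout."""
    return tuple(load_reference_table("aegypti").features)


@dataclass
class SimConfig:
    """Simulator settings; defaults are the Aedes-like study conditions."""

    layout: tuple[GeneFeature, ...] = field(default_factory=default_layout)
    at_bias: float = 0.79
    kappa: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.at_bias < 1:
            raise ValueError("at_bias must be in (0, 1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def length(self) -> int:
        return max(f.end for f in self.layout)


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    ancestor: str
    kappa: float
    tree_newick: str
    branch_events: dict[str, tuple[int, int]]  # branch -> (transitions, transversions)
    leaf_sequences: dict[str, str]
    path_lengths: dict[str, float]  # "idA|idB" (sorted) -> true path length

    def pair_length(self, a: str, b: str) -> float:
        return self.path_lengths["|".join(sorted((a, b)))]

    def to_json(self, path: str | Path) -> None:
        obj = {"ancestor": self.ancestor, "kappa": self.kappa,
               "tree_newick": self.tree_newick,
               "branch_events": {k: list(v) for k, v in self.branch_events.items()},
               "leaf_sequences": self.leaf_sequences,
               "path_lengths": self.path_lengths}
        Path(path).write_text(json.dumps(obj, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        obj["branch_events"] = {k: tuple(v) for k, v in obj["branch_events"].items()}
        return cls(**obj)


# ---------------------------------------------------------------------------
# ancestor construction

def _gene_positions(feat: GeneFeature, L: int) -> list[int]:
    """Genome indices (0-based) of a feature in 5'->3' gene order."""
    if feat.wraps:
        idx = list(range(feat.start - 1, L)) + list(range(feat.end))
    else:
        idx = list(range(feat.start - 1, feat.end))
    return idx[::-1] if feat.strand == "-" else idx


def _gene_base(genome: list[str], feat: GeneFeature, pos: int, idx: list[int]) -> str:
    b = genome[idx[pos]]
    return _COMP[b] if feat.strand == "-" else b


def _set_gene_base(genome: list[str], feat: GeneFeature, pos: int,
                   base: str, idx: list[int]) -> None:
    genome[idx[pos]] = _COMP[base] if feat.strand == "-" else base


def _stop_string_to_codon(s: str) -> str:
    """'TAA' -> TAA; 'T(AA)' / 'TA(A)' keep only the encoded prefix."""
    return s.split("(")[0]


def make_ancestor(config: SimConfig) -> MitogenomeRecord:
    """Draw an ancestral mitogenome honoring the layout's coding structure.

    Bases are i.i.d. with P(A)=P(T)=at_bias/2, P(C)=P(G)=(1-at_bias)/2.
    Each PCG then gets its annotated (or sampled) start codon, a terminal
    stop matching the layout's complete/incomplete notation, and internal
    stops are removed by minimal edits (third position -> T preferred,
    falling back to first/second positions when a neighbour gene locks
    the site).  Raises if overlapping PCGs cannot be jointly repaired.
    """
    rng = np.random.default_rng(config.seed)
    L = config.length
    at, gc = config.at_bias / 2, (1 - config.at_bias) / 2
    genome = list(rng.choice(list(_BASES), size=L, p=[at, gc, gc, at]))
    locked = [False] * L

    pcgs = [f for f in config.layout if f.category == "PCG"]
    gene_idx = {f.name: _gene_positions(f, L) for f in pcgs}

    for feat in pcgs:
        idx = gene_idx[feat.name]
        n = len(idx)
        if n < 3:
            raise ValueError(f"{feat.name}: PCG shorter than one codon")
        start = feat.start_codon or str(
            rng.choice(_START_CHOICES, p=_START_WEIGHTS))
        for k, b in enumerate(start):
            _set_gene_base(genome, feat, k, b, idx)
            locked[idx[k]] = True
        r = n % 3
        if r == 0:
            stop = _stop_string_to_codon(feat.stop_codon) if feat.stop_codon else "TAA"
            if stop not in _STOPS:
                stop = "TAA"
            tail = stop
        elif r == 1:
            tail = "T"
        else:
            tail = "TA"
        for k, b in enumerate(tail):
            pos = n - len(tail) + k
            _set_gene_base(genome, feat, pos, b, idx)
            locked[idx[pos]] = True

    # iterative internal-stop removal; overlapping genes may interact
    for _ in range(100):
        dirty = False
        for feat in pcgs:
            idx = gene_idx[feat.name]
            n = len(idx)
            n_codons = n // 3
            last_internal = n_codons - 2 if n % 3 == 0 else n_codons - 1
            for ci in range(1, last_internal + 1):
                codon = "".join(_gene_base(genome, feat, 3 * ci + k, idx)
                                for k in range(3))
                if codon not in _STOPS:
                    continue
                for offset, base in ((2, "T"), (0, "A"), (1, "C")):
                    pos = 3 * ci + offset
                    if not locked[idx[pos]]:
                        _set_gene_base(genome, feat, pos, base, idx)
                        dirty = True
                        break
                else:
                    raise ValueError(
                        f"{feat.name}: internal stop at codon {ci} cannot be "
                        "repaired (all positions locked by overlapping genes)"
                    )
        if not dirty:
            break
    else:
        raise ValueError("PCG frame repair did not converge")

    return MitogenomeRecord(id="sim_ancestor", species="synthetic",
                            sequence="".join(genome), circular=True,
                            features=[GeneFeature(**{**f.__dict__}) for f in config.layout])


# ---------------------------------------------------------------------------
# K80 evolution along a tree

class _FrameGuard:
    """Site constraints for frame-protecting mode."""

    def __init__(self, features: Sequence[GeneFeature], L: int) -> None:
        self.allowed = np.ones(L, dtype=bool)
        # site -> list of (feature, gene positions, codon index, codon pos)
        self.site_codons: dict[int, list[tuple[GeneFeature, list[int], int, int]]] = {}
        for feat in features:
            if feat.category != "PCG":
                continue
            idx = _gene_positions(feat, L)
            n = len(idx)
            n_codons = n // 3
            last_internal = n_codons - 2 if n % 3 == 0 else n_codons - 1
            for pos, g in enumerate(idx):
                ci, cp = divmod(pos, 3)
                if ci == 0 or ci > last_internal:
                    self.allowed[g] = False      # start / stop region frozen
                    continue
                if cp != 2:
                    self.allowed[g] = False      # only third positions mutate
                self.site_codons.setdefault(g, []).append((feat, idx, ci, cp))

    def creates_stop(self, genome: list[str], site: int, new_base: str) -> bool:
        old = genome[site]
        genome[site] = new_base
        try:
            for feat, idx, ci, _ in self.site_codons.get(site, []):
                codon = "".join(_gene_base(genome, feat, 3 * ci + k, idx)
                                for k in range(3))
                if codon in _STOPS:
                    return True
            return False
        finally:
            genome[site] = old


def _parse_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


def evolve(
    ancestor: MitogenomeRecord | str,
    tree: str | dendropy.Tree,
    kappa: float = 4.0,
    seed: int = 0,
    frame_protect: bool = False,
    features: Sequence[GeneFeature] | None = None,
) -> tuple[dict[str, str], SimTruth]:
    """Evolve an ancestor along a tree under the K80 process.

    Branch lengths are expected substitutions per site.  Returns the
    leaf sequences (keyed by taxon label) and the full :class:`SimTruth`.
    """
    if isinstance(ancestor, MitogenomeRecord):
        seq0 = ancestor.sequence
        features = features or ancestor.features
    else:
        seq0 = ancestor
    if frame_protect and not features:
        raise ValueError("frame_protect requires feature annotations")
    t = _parse_tree(tree)
    newick = t.as_string(schema="newick", suppress_rooting=True).strip()
    L = len(seq0)
    guard = _FrameGuard(features, L) if frame_protect else None
    rng = np.random.default_rng(seed)
    p_ts = kappa / (kappa + 2.0)

    branch_events: dict[str, tuple[int, int]] = {}
    leaf_sequences: dict[str, str] = {}
    internal_counter = 0
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            node._seq = list(seq0)
            continue
        b = node.edge.length or 0.0
        if b < 0:
            raise ValueError("branch lengths must be non-negative")
        parent_seq = node.parent_node._seq
        child = list(parent_seq)
        n_events = rng.poisson(b, size=L)
        if guard is not None:
            n_events[~guard.allowed] = 0
        ti = tv = 0
        for site in np.nonzero(n_events)[0]:
            site = int(site)
            for _ in range(int(n_events[site])):
                cur = child[site]
                if rng.random() < p_ts:
                    new = _TRANSITION[cur]
                    kind = "ti"
                else:
                    new = _TRANSVERSIONS[cur][int(rng.integers(2))]
                    kind = "tv"
                if guard is not None and guard.creates_stop(child, site, new):
                    continue
                child[site] = new
                if kind == "ti":
                    ti += 1
                else:
                    tv += 1
        node._seq = child
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"leaf{internal_counter}"
            key = label
            leaf_sequences[label] = "".join(child)
        else:
            internal_counter += 1
            key = f"node{internal_counter}"
        branch_events[key] = (ti, tv)

    pdm = t.phylogenetic_distance_matrix()
    labels = sorted(leaf_sequences)
    path_lengths: dict[str, float] = {}
    taxa = {x.label: x for x in t.taxon_namespace}
    for i, a in enumerate(labels):
        for b_ in labels[i + 1:]:
            path_lengths[f"{a}|{b_}"] = float(pdm.distance(taxa[a], taxa[b_]))
    truth = SimTruth(ancestor=seq0, kappa=kappa, tree_newick=newick,
                     branch_events=branch_events, leaf_sequences=leaf_sequences,
                     path_lengths=path_lengths)
    return leaf_sequences, truth


# ---------------------------------------------------------------------------
# conspecific panels

@dataclass
class Panel:
    """A simulated conspecific panel with full ground truth."""

    ancestor: MitogenomeRecord
    leaves: dict[str, str]
    per_gene: dict[str, dict[str, str]]   # gene -> taxon -> aligned sequence
    truth: SimTruth
    tree_newick: str


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def make_conspecific_panel(
    n_taxa: int,
    depth: float,
    config: SimConfig | None = None,
    tree: str | None = None,
    prefix: str = "tax",
    frame_protect: bool = False,
) -> Panel:
    """Simulate a conspecific mitogenome panel.

    By default the taxa radiate from the ancestor on a star tree with
    branch length ``depth`` (so any pair is 2*depth apart); a custom
    Newick ``tree`` overrides the star.  Per-gene alignments cover the
    13 PCGs and both rRNAs — the 15 genes of the divergence analysis —
    and are trivially aligned because no indels are simulated.
    """
    if n_taxa < 2:
        raise ValueError("a panel needs at least two taxa")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    config = config or SimConfig()
    ancestor = make_ancestor(config)
    if tree is None:
        tips = ",".join(f"{prefix}{i + 1}:{depth:.10g}" for i in range(n_taxa))
        tree = f"({tips});"
    leaves, truth = evolve(ancestor, tree, kappa=config.kappa,
                           seed=_derive_seed(config.seed, 1),
                           frame_protect=frame_protect)
    per_gene: dict[str, dict[str, str]] = {}
    for feat in ancestor.features:
        if feat.category not in ("PCG", "rRNA"):
            continue
        per_gene[feat.name] = {
            taxon: extract_gene_coords(seq, feat, circular=True)
            for taxon, seq in leaves.items()
        }
    return Panel(ancestor=ancestor, leaves=leaves, per_gene=per_gene,
                 truth=truth, tree_newick=tree)


def write_panel(panel: Panel, outdir: str | Path) -> None:
    """Write a panel: genomes.fasta, genes/*.fasta, features.tsv,
    tree.nwk and truth.json."""
    outdir = Path(outdir)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    write_fasta(panel.leaves, outdir / "genomes.fasta")
    for gene, seqs in panel.per_gene.items():
        write_fasta(seqs, outdir / "genes" / f"{gene}.fasta")
    write_feature_table(panel.ancestor, outdir / "features.tsv")
    (outdir / "tree.nwk").write_text(panel.tree_newick + "\n", encoding="utf-8")
    panel.truth.to_json(outdir / "truth.json")


def read_panel(panel_dir: str | Path) -> dict[str, dict[str, str]]:
    """Read per-gene alignments from a panel directory (genes/*.fasta)."""
    gene_dir = Path(panel_dir) / "genes"
    if not gene_dir.is_dir():
        raise FileNotFoundError(f"{panel_dir} has no genes/ subdirectory")
    out: dict[str, dict[str, str]] = {}
    for path in sorted(gene_dir.glob("*.fasta")):
        out[path.stem] = read_fasta(path)
    return out
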