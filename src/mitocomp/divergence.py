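"""Intraspecific divergence: K2P distance, SNP density, percent identity.

Kimura's two-parameter distance corrects observed transition (P) and
transversion (Q) proportions for multiple hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Transitions are A<->G and C<->T; everything else is a transversion.
Columns containing a gap or N in either sequence are excluded pairwise
(pairwise deletion), so P and Q are proportions of comparable sites.
When an argument of a logarithm is non-positive the distance is
saturated and reported as missing rather than clamped.

SNP density is summarized as bp-per-SNP: the number of comparable
(ungapped) alignment columns divided by the number of variable columns,
so larger values mean sparser polymorphism.

The built-in global aligner (Needleman-Wunsch with affine gaps, Gotoh
recursion) is a deterministic stand-in for an external multiple aligner
on near-identical conspecific genes; externally aligned FASTA is equally
accepted everywhere an alignment is consumed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairwiseAlignment",
    "DivergenceResult",
    "SaturationError",
    "align_pair",
    "k2p",
    "k2p_from_seqs",
    "snp_density",
    "gene_panel_summary",
    "species_summary",
    "percent_identity_matrix",
]

# scoring for the built-in global aligner: a gap run of length k scores
# -(GAP_OPEN + k * GAP_EXTEND)
MATCH = 1
MISMATCH = -1
GAP_OPEN = 5
GAP_EXTEND = 1

_NEG_INF = float("-inf")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class SaturationError(ValueError):
    """Observed divergence too high for the K2P correction to be defined."""


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; every other character (gap, N) -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment: equal-length gapped strings."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")

    @property
    def comparable_sites(self) -> int:
        xa, xb = encode(self.aligned_a), encode(self.aligned_b)
        return int(np.sum((xa < 4) & (xb < 4)))


@dataclass
class DivergenceResult:
    """Per-gene divergence summary; missing quantities are None."""

    gene: str = ""
    p_transition: float | None = None
    q_transversion: float | None = None
    d_k2p: float | None = None
    snp_count: int | None = None
    bp_per_snp: float | None = None
    pid: float | None = None
    comparable_sites: int = 0
    saturated: bool = False


# ---------------------------------------------------------------------------
# global alignment (Gotoh affine-gap DP)

def align_pair(seq_a: str, seq_b: str, id_a: str = "A", id_b: str = "B") -> PairwiseAlignment:
    """Global alignment: match +1, mismatch -1, gap run of length k costs 5 + k.

    Traceback ties are broken deterministically preferring diagonal over
    up (gap in B) over left (gap in A), evaluated from the final cell.
    """
    if not seq_a or not seq_b:
        raise ValueError("align_pair requires two non-empty sequences")
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)

    # three-state Gotoh: M match/mismatch (diagonal), X gap in b (up,
    # consumes a), Y gap in a (left, consumes b); pointer matrices record
    # the predecessor state chosen under the fixed preference M > X > Y.
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0=M 1=X 2=Y
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(GAP_OPEN + i * GAP_EXTEND)
        ptr_x[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(GAP_OPEN + j * GAP_EXTEND)
        ptr_y[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            cands = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = max(range(3), key=lambda t: (cands[t], -t))
            M[i, j] = cands[k] + s
            ptr_m[i, j] = k
            open_x = M[i - 1, j] - GAP_OPEN - GAP_EXTEND
            ext_x = X[i - 1, j] - GAP_EXTEND
            X[i, j], ptr_x[i, j] = (open_x, 0) if open_x >= ext_x else (ext_x, 1)
            open_y = M[i, j - 1] - GAP_OPEN - GAP_EXTEND
            ext_y = Y[i, j - 1] - GAP_EXTEND
            Y[i, j], ptr_y[i, j] = (open_y, 0) if open_y >= ext_y else (ext_y, 2)

    finals = (M[n, m], X[n, m], Y[n, m])
    state = max(range(3), key=lambda t: (finals[t], -t))
    score = finals[state]
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = int(ptr_x[i, j])
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            state = int(ptr_y[i, j])
            j -= 1
    return PairwiseAlignment(id_a=id_a, id_b=id_b,
                             aligned_a="".join(reversed(out_a)),
                             aligned_b="".join(reversed(out_b)),
                             score=float(score))


# ---------------------------------------------------------------------------
# K2P

def _pq_counts(xa: np.ndarray, xb: np.ndarray) -> tuple[int, int, int]:
    """(comparable, transitions, transversions) under pairwise deletion."""
    valid = (xa < 4) & (xb < 4)
    av, bv = xa[valid], xb[valid]
    diff = av != bv
    # with A=0,C=1,G=2,T=3 the XOR of a transition pair (A^G, C^T) is 2
    ts = diff & ((av ^ bv) == 2)
    return int(valid.sum()), int(ts.sum()), int(diff.sum() - ts.sum())


def k2p_from_seqs(seq_a: str, seq_b: str, gene: str = "") -> DivergenceResult:
    """K2P distance of two equal-length (aligned) sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("k2p_from_seqs requires equal-length aligned sequences")
    nc, n_ts, n_tv = _pq_counts(encode(seq_a), encode(seq_b))
    if nc == 0:
        raise ValueError("no comparable sites (all columns gapped or ambiguous)")
    p = n_ts / nc
    q = n_tv / nc
    pid = 100.0 * (nc - n_ts - n_tv) / nc
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        return DivergenceResult(gene=gene, p_transition=p, q_transversion=q,
                                d_k2p=None, pid=pid, comparable_sites=nc,
                                saturated=True)
    d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    return DivergenceResult(gene=gene, p_transition=p, q_transversion=q,
                            d_k2p=d, pid=pid, comparable_sites=nc)


def k2p(aln: PairwiseAlignment, gene: str = "") -> DivergenceResult:
    """K2P distance over a pairwise alignment (pairwise deletion)."""
    return k2p_from_seqs(aln.aligned_a, aln.aligned_b, gene=gene)


# ---------------------------------------------------------------------------
# SNP density

def snp_density(aligned: Sequence[str], gene: str = "") -> DivergenceResult:
    """Variable-column count and bp-per-SNP of a multiple alignment.

    A column is a SNP when it shows >= 2 distinct bases among its
    unambiguous {A,C,G,T} entries; gaps and N are ignored within the
    column.  bp-per-SNP divides the number of columns with >= 2
    unambiguous entries by the SNP count and is missing when no column
    varies.
    """
    if len(aligned) < 2:
        raise ValueError("snp_density requires at least two sequences")
    lengths = {len(s) for s in aligned}
    if len(lengths) != 1:
        raise ValueError(f"{gene or 'alignment'}: ragged alignment {sorted(lengths)}")
    mat = np.vstack([encode(s) for s in aligned])
    valid = mat < 4
    n_valid = valid.sum(axis=0)
    # a column varies iff among valid entries there are >= 2 distinct codes
    masked = np.where(valid, mat, np.uint8(255))
    col_min = np.where(valid, mat, np.uint8(4)).min(axis=0)
    variable = ((masked != 255) & (masked != col_min[None, :])).any(axis=0) & (n_valid >= 2)
    comparable_cols = int((n_valid >= 2).sum())
    snps = int(variable.sum())
    bp_per_snp = comparable_cols / snps if snps else None
    return DivergenceResult(gene=gene, snp_count=snps, bp_per_snp=bp_per_snp,
                            comparable_sites=comparable_cols)


# ---------------------------------------------------------------------------
# panels

def gene_panel_summary(
    panels: Mapping[str, Mapping[str, str]],
    species: str = "",
    mode: str = "all-pairs",
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-gene K2P mean/SD and SNP density over conspecific panels.

    ``panels`` maps gene name -> (taxon -> aligned sequence).  ``mode``
    'all-pairs' averages d over every taxon pair; 'to-reference'
    restricts to pairs involving ``reference``.  Genes with fewer than
    two sequences are skipped with a warning.  Saturated pairs are
    excluded from the mean and counted.
    """
    if mode not in ("all-pairs", "to-reference"):
        raise ValueError("mode must be 'all-pairs' or 'to-reference'")
    if mode == "to-reference" and not reference:
        raise ValueError("to-reference mode needs a reference taxon id")
    rows = []
    for gene, seqs in panels.items():
        if len(seqs) < 2:
            warnings.warn(f"gene {gene}: fewer than 2 sequences; skipped", stacklevel=2)
            continue
        ids = list(seqs)
        pairs = list(itertools.combinations(ids, 2))
        if mode == "to-reference":
            pairs = [p for p in pairs if reference in p]
        dists = []
        saturated = 0
        for ia, ib in pairs:
            res = k2p_from_seqs(seqs[ia], seqs[ib], gene=gene)
            if res.saturated:
                saturated += 1
            else:
                dists.append(res.d_k2p)
        dens = snp_density([seqs[i] for i in ids], gene=gene)
        rows.append({
            "species": species, "gene": gene, "n_seqs": len(ids),
            "n_pairs": len(pairs), "n_saturated": saturated,
            "mean_k2p": float(np.mean(dists)) if dists else math.nan,
            "sd_k2p": float(np.std(dists, ddof=1)) if len(dists) > 1 else math.nan,
            "snp_count": dens.snp_count,
            "bp_per_snp": math.nan if dens.bp_per_snp is None else dens.bp_per_snp,
        })
    return pd.DataFrame(rows)


def species_summary(per_gene: pd.DataFrame) -> dict[str, float]:
    """Unweighted across-gene species means (the dotted-line summaries)."""
    return {
        "mean_k2p": float(per_gene["mean_k2p"].mean()),
        "mean_bp_per_snp": float(per_gene["bp_per_snp"].mean()),
    }


# ---------------------------------------------------------------------------
# identity matrix

def percent_identity_matrix(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise percent identity (pairwise deletion), diagonal 100.

    Input sequences must be aligned to equal length (e.g. concatenated
    PCG supermatrices).
    """
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in seqs.values()}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    enc = {i: encode(seqs[i]) for i in ids}
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for ia, ib in itertools.combinations(ids, 2):
        xa, xb = enc[ia], enc[ib]
        valid = (xa < 4) & (xb < 4)
        nc = int(valid.sum())
        if nc == 0:
            pid = math.nan
        else:
            pid = 100.0 * float((xa[valid] == xb[valid]).sum()) / nc
        mat.loc[ia, ib] = pid
        mat.loc[ib, ia] = pid
    return mat
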