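"""Nucleotide composition and strand-skew statistics.

AT/GC content and the strand skews

    AT skew = (A - T) / (A + T),   GC skew = (G - C) / (G + C)

are the standard descriptors of mitochondrial strand asymmetry.  Mosquito
mitogenomes are strongly AT-biased (~79% AT) with a negative GC skew on
the majority strand.  N bases are excluded from every numerator and from
the AT+GC denominator; the policy string is carried in the output so
downstream tables are self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .genome_io import MitogenomeRecord, extract_gene

__all__ = ["CompositionStats", "base_composition", "skews", "composition_report"]

N_POLICY = "N excluded from numerators and the AT+GC denominator"


@dataclass(frozen=True)
class CompositionStats:
    """Base counts, AT/GC percentages and skews for one sequence unit."""

    a: int
    c: int
    g: int
    t: int
    n: int
    at_pct: float
    gc_pct: float
    at_skew: float | None
    gc_skew: float | None
    policy: str = N_POLICY

    @property
    def length(self) -> int:
        return self.a + self.c + self.g + self.t + self.n


def base_composition(seq: str) -> CompositionStats:
    """Count bases and derive AT%, GC% and both skews.

    Undefined skews (A+T == 0 or G+C == 0) are reported as None, never as
    zero.  Raises ``ValueError`` on an empty sequence.
    """
    if not seq:
        raise ValueError("cannot compute composition of an empty sequence")
    seq = seq.upper()
    a, c, g, t, n = (seq.count(b) for b in "ACGTN")
    if a + c + g + t + n != len(seq):
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    acgt = a + c + g + t
    at_pct = 100.0 * (a + t) / acgt if acgt else float("nan")
    gc_pct = 100.0 * (g + c) / acgt if acgt else float("nan")
    at_skew = (a - t) / (a + t) if a + t > 0 else None
    gc_skew = (g - c) / (g + c) if g + c > 0 else None
    return CompositionStats(a=a, c=c, g=g, t=t, n=n, at_pct=at_pct,
                            gc_pct=gc_pct, at_skew=at_skew, gc_skew=gc_skew)


def skews(seq: str) -> tuple[float | None, float | None]:
    """(AT skew, GC skew) at full precision.

    A skew whose denominator is zero (no A/T or no G/C bases) is returned
    as None — flagged missing, never silently zero.
    """
    stats = base_composition(seq)
    return stats.at_skew, stats.gc_skew


def composition_report(record: MitogenomeRecord) -> pd.DataFrame:
    """Per-feature composition table plus a whole-genome row.

    Rows are ordered by feature start (the record's native order) with the
    genome row last.  Columns: unit, category, A, C, G, T, N, AT_pct,
    GC_pct, AT_skew, GC_skew, policy.
    """
    rows = []
    for feat in record.features:
        stats = base_composition(extract_gene(record, feat))
        rows.append(_row(feat.name, feat.category, stats))
    rows.append(_row("genome", "genome", base_composition(record.sequence)))
    return pd.DataFrame(rows)


def _row(unit: str, category: str, s: CompositionStats) -> dict:
    return {
        "unit": unit, "category": category,
        "A": s.a, "C": s.c, "G": s.g, "T": s.t, "N": s.n,
        "AT_pct": s.at_pct, "GC_pct": s.gc_pct,
        "AT_skew": math.nan if s.at_skew is None else s.at_skew,
        "GC_skew": math.nan if s.gc_skew is None else s.gc_skew,
        "policy": s.policy,
    }
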