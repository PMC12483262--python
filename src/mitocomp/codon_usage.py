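"""Codon counting, RSCU, and start/stop-codon classification.

Relative synonymous codon usage for a codon c encoding amino acid aa is

    RSCU(c) = X(c) / ( (1/n_aa) * sum of X over the synonymous family )

where n_aa is the family size under the genetic code in use.  RSCU = 1
means no bias; the mosquito mitogenome's hallmark is TTA (Leu) with
per-gene RSCU above 4 and a cumulative value above 60 when summed across
the 13 protein-coding genes.

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, TGA = Trp, ATA = Met; 62 sense codons,
stops TAA/TAG).  The table is shipped as data and the engine is generic
over code-table ids, so alternative registries can be swapped in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .genome_io import MitogenomeRecord, extract_gene

__all__ = [
    "GeneticCode",
    "CodonUsageTable",
    "StartStopCall",
    "codon_counts",
    "rscu",
    "per_gene_rscu",
    "cumulative_rscu",
    "classify_start_stop",
    "load_shipped_code",
]

DEFAULT_TABLE_ID = 5


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with synonymous-family bookkeeping."""

    table_id: int
    forward: Mapping[str, str]          # sense codons only
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi_id(cls, table_id: int = DEFAULT_TABLE_ID) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(table_id=table_id, forward=dict(t.forward_table),
                   stop_codons=frozenset(t.stop_codons))

    def family(self, codon: str) -> tuple[str, ...]:
        aa = self.forward[codon]
        return tuple(sorted(c for c, a in self.forward.items() if a == aa))

    def families(self) -> dict[str, tuple[str, ...]]:
        fams: dict[str, list[str]] = {}
        for codon, aa in self.forward.items():
            fams.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}

    def family_size(self, codon: str) -> int:
        return len(self.family(codon))


def load_shipped_code() -> dict:
    """The frozen NCBI table-5 definition shipped with the package."""
    path = resources.files("mitocomp.data").joinpath("translation_table_5.json")
    with path.open("r", encoding="utf-8") as fh:
        return json.load(fh)


@dataclass
class CodonUsageTable:
    """Per-codon counts and (optionally) RSCU values for one scope."""

    code_table_id: int
    counts: dict[str, int]
    scope: str = "pooled"
    rscu_values: dict[str, float] | None = None

    @property
    def code(self) -> GeneticCode:
        return GeneticCode.from_ncbi_id(self.code_table_id)

    def total_codons(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class StartStopCall:
    """Start/stop classification of one CDS.

    ``complete`` is False iff the CDS length mod 3 is 1 or 2, i.e. the
    annotated gene ends in a T or TA that is completed to TAA by
    post-transcriptional polyadenylation.  ``canonical`` flags whether a
    complete terminal codon is actually a stop under the code table.
    """

    gene: str
    start_codon: str
    stop_codon: str
    complete: bool
    canonical: bool = True


def _iter_codons(cds: str) -> Iterable[str]:
    for i in range(0, len(cds) - len(cds) % 3, 3):
        yield cds[i: i + 3]


def codon_counts(
    cds_list: Sequence[str],
    code_table_id: int = DEFAULT_TABLE_ID,
    scope: str = "pooled",
    gene_names: Sequence[str] | None = None,
) -> CodonUsageTable:
    """Count sense codons frame-0 across one or more CDS sequences.

    A trailing incomplete codon (1-2 nt) is dropped, codons containing N
    are skipped, and stop codons of the code table are excluded from the
    counts (the terminal stop is annotation, not usage).
    """
    code = GeneticCode.from_ncbi_id(code_table_id)
    counts = {c: 0 for c in sorted(code.forward)}
    for i, cds in enumerate(cds_list):
        if len(cds) < 3:
            name = gene_names[i] if gene_names else f"CDS #{i + 1}"
            raise ValueError(f"{name}: CDS shorter than 3 nt")
        for codon in _iter_codons(cds.upper()):
            if "N" in codon:
                continue
            if codon in code.stop_codons:
                continue
            counts[codon] += 1
    return CodonUsageTable(code_table_id=code_table_id, counts=counts, scope=scope)


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill RSCU values; families with zero total are marked missing (NaN)."""
    code = table.code
    values: dict[str, float] = {}
    for aa, fam in code.families().items():
        total = sum(table.counts.get(c, 0) for c in fam)
        for c in fam:
            if total == 0:
                values[c] = math.nan
            else:
                values[c] = table.counts.get(c, 0) / (total / len(fam))
    return CodonUsageTable(code_table_id=table.code_table_id,
                           counts=dict(table.counts), scope=table.scope,
                           rscu_values=values)


def per_gene_rscu(
    record: MitogenomeRecord, code_table_id: int = DEFAULT_TABLE_ID
) -> dict[str, CodonUsageTable]:
    """Per-PCG RSCU tables, keyed by gene name (Fig-2-style scope)."""
    out: dict[str, CodonUsageTable] = {}
    for feat in record.pcgs:
        cds = extract_gene(record, feat)
        out[feat.name] = rscu(codon_counts([cds], code_table_id, scope=feat.name,
                                           gene_names=[feat.name]))
    return out


def pooled_rscu(
    record: MitogenomeRecord, code_table_id: int = DEFAULT_TABLE_ID
) -> CodonUsageTable:
    """RSCU over all PCGs pooled into one codon count (genome-level scope)."""
    names = [f.name for f in record.pcgs]
    cds_list = [extract_gene(record, f) for f in record.pcgs]
    return rscu(codon_counts(cds_list, code_table_id, scope="all PCGs",
                             gene_names=names))


def cumulative_rscu(
    record: MitogenomeRecord,
    codon: str,
    code_table_id: int = DEFAULT_TABLE_ID,
) -> tuple[float, list[str]]:
    """Sum a codon's per-gene RSCU over the record's PCGs.

    Returns (cumulative value, genes whose family total was zero — these
    contribute 0).  Raises ``ValueError`` for a stop codon.
    """
    codon = codon.upper()
    code = GeneticCode.from_ncbi_id(code_table_id)
    if codon in code.stop_codons:
        raise ValueError(f"{codon} is a stop codon under table {code_table_id}")
    if codon not in code.forward:
        raise ValueError(f"{codon} is not a sense codon under table {code_table_id}")
    total = 0.0
    empty: list[str] = []
    for gene, table in per_gene_rscu(record, code_table_id).items():
        value = table.rscu_values[codon]
        if math.isnan(value):
            empty.append(gene)
        else:
            total += value
    return total, empty


def classify_start_stop(
    cds: str, gene: str = "", code_table_id: int = DEFAULT_TABLE_ID
) -> StartStopCall:
    """Classify the start and (possibly incomplete) stop codon of a CDS.

    Length mod 3 == 0: the last 3 nt are the stop; mod 3 == 1: the single
    trailing nucleotide is an incomplete stop written ``T(AA)``-style;
    mod 3 == 2: the trailing dinucleotide is written ``TA(A)``-style.
    A complete terminal codon that is not a stop is flagged via
    ``canonical=False``, not raised.
    """
    cds = cds.upper()
    if len(cds) < 4:
        raise ValueError(f"{gene or 'CDS'}: too short to classify (< 4 nt)")
    code = GeneticCode.from_ncbi_id(code_table_id)
    start = cds[:3]
    r = len(cds) % 3
    if r == 0:
        stop = cds[-3:]
        return StartStopCall(gene=gene, start_codon=start, stop_codon=stop,
                             complete=True, canonical=stop in code.stop_codons)
    if r == 1:
        stop = f"{cds[-1]}(AA)"
    else:
        stop = f"{cds[-2:]}(A)"
    return StartStopCall(gene=gene, start_codon=start, stop_codon=stop,
                         complete=False, canonical=True)
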