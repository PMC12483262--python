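"""Reading, writing and slicing annotated mitochondrial genomes.

The central container is :class:`MitogenomeRecord`: a circular (usually)
DNA sequence plus an ordered list of :class:`GeneFeature` annotations in
1-based inclusive coordinates, mirroring the GenBank convention.  A complete
mosquito mitogenome carries 37 functional genes (13 protein-coding genes,
22 tRNAs, 2 rRNAs) plus one AT-rich control region.

Supported formats: GenBank flat files (read, via Biopython), plain FASTA
(read/write), and a tab-separated feature table with columns
``name, category, strand, start, end, size, start_codon, stop_codon,
anticodon`` (read/write).  Features may wrap the origin of a circular
genome (``end < start``).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "GeneFeature",
    "MitogenomeRecord",
    "GenomeParseError",
    "reverse_complement",
    "normalize_gene_name",
    "read_genbank",
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "write_fasta",
    "extract_gene",
    "intergenic_spacing",
    "load_reference_table",
]

CATEGORIES = ("PCG", "tRNA", "rRNA", "CR")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class GenomeParseError(ValueError):
    """Raised when a genome file or feature table cannot be interpreted."""


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, context: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise GenomeParseError(
            f"{context} contains unsupported characters {sorted(bad)}; "
            "only A, C, G, T and N are accepted"
        )
    return seq


@dataclass
class GeneFeature:
    """One annotated feature in 1-based inclusive coordinates.

    ``end < start`` denotes a feature wrapping the origin of a circular
    genome.  ``start_codon``/``stop_codon`` hold detected codons for PCGs;
    an incomplete terminal codon is written in the ``T(AA)`` / ``TA(A)``
    notation.
    """

    name: str
    category: str
    strand: str
    start: int
    end: int
    start_codon: str = ""
    stop_codon: str = ""
    anticodon: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def size(self, genome_length: int | None = None) -> int:
        """Nucleotide count; wrapping features need the genome length."""
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(f"{self.name} wraps the origin; genome length required")
        return (genome_length - self.start + 1) + self.end


@dataclass
class MitogenomeRecord:
    """A mitogenome: sequence, topology, and ordered feature annotations.

    ``sequence`` may be empty when only the annotation layout is known
    (e.g. a published gene table without the underlying accession); in
    that case ``declared_length`` carries the genome length.
    """

    id: str
    species: str = ""
    sequence: str = ""
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    declared_length: int | None = None

    def __post_init__(self) -> None:
        if self.sequence:
            self.sequence = _check_alphabet(self.sequence, f"record {self.id}")
        self.features.sort(key=lambda f: (f.start, f.end, f.name))

    @property
    def length(self) -> int:
        if self.sequence:
            return len(self.sequence)
        if self.declared_length is not None:
            return self.declared_length
        if self.features:
            return max(max(f.start, f.end) for f in self.features)
        return 0

    def features_by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.features_by_category("PCG")

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def functional_gene_count(self) -> int:
        """Genes excluding the control region (37 in a complete mitogenome)."""
        return sum(1 for f in self.features if f.category != "CR")


# ---------------------------------------------------------------------------
# gene-name normalization

def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    path = resources.files("mitocomp.data").joinpath("gene_synonyms.tsv")
    with path.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            canonical = row["canonical"]
            table[canonical.upper()] = canonical
            for syn in row["synonyms"].split(","):
                syn = syn.strip().upper()
                if syn:
                    table[syn] = canonical
    return table


_SYNONYMS: dict[str, str] | None = None

# anticodons distinguishing the duplicated Leu / Ser tRNA isotypes
_TRNA_ISOTYPES = {("trnL", "TAG"): "trnL1", ("trnL", "TAA"): "trnL2",
                  ("trnS", "GCT"): "trnS1", ("trnS", "TGA"): "trnS2"}


def normalize_gene_name(raw: str, anticodon: str = "") -> str:
    """Map a gene/product label to the canonical symbol (ND5 -> nad5 etc.).

    The duplicated leucine and serine tRNAs are disambiguated by anticodon
    when one is supplied.  Unknown names pass through with a warning.
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    key = raw.strip().upper()
    name = _SYNONYMS.get(key)
    if name is None:
        warnings.warn(f"unrecognized gene name {raw!r}; passing through", stacklevel=2)
        return raw.strip()
    if name in ("trnL", "trnS") and anticodon:
        name = _TRNA_ISOTYPES.get((name, anticodon.upper()), name)
    return name


# ---------------------------------------------------------------------------
# GenBank

_GB_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "misc_feature": "CR", "D-loop": "CR"}


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read an annotated GenBank flat file into a :class:`MitogenomeRecord`.

    CDS features become PCGs, tRNA/rRNA map directly, and misc_feature /
    D-loop entries become the control region.  Gene names are normalized
    through the synonym table.  The circular flag is taken from the LOCUS
    topology field.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise GenomeParseError(f"{path}: malformed GenBank record: {exc}") from exc
    seq = str(rec.seq)
    if not seq:
        raise GenomeParseError(f"{path}: record has no ORIGIN sequence")
    seq = _check_alphabet(seq, f"record {rec.id}")
    circular = rec.annotations.get("topology", "linear") == "circular"
    species = rec.annotations.get("organism", "")

    features: list[GeneFeature] = []
    for f in rec.features:
        category = _GB_CATEGORY.get(f.type)
        if category is None:
            continue
        quals = f.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [f.type])[0]
        anticodon = ""
        if "anticodon" in quals:
            # e.g. "(pos:33..35,aa:Ile,seq:gat)" or a bare triplet
            text = quals["anticodon"][0]
            anticodon = text.split("seq:")[-1].strip("() ").upper()[:3]
        name = normalize_gene_name(raw, anticodon=anticodon)
        if category == "CR" and name not in ("CR",):
            name = "CR" if "control" in raw.lower() or "a+t" in raw.lower() or "at-rich" in raw.lower() else name
        parts = list(f.location.parts)
        strand = "+" if (f.location.strand or 1) >= 0 else "-"
        if len(parts) > 1 and int(parts[0].start) > int(parts[-1].start):
            # join() across the origin of a circular genome
            start = int(parts[0].start) + 1
            end = int(parts[-1].end)
        else:
            start = int(f.location.start) + 1
            end = int(f.location.end)
        feat = GeneFeature(name=name, category=category, strand=strand,
                           start=start, end=end, anticodon=anticodon)
        if category == "PCG":
            gene_seq = extract_gene_coords(seq, feat, circular=circular)
            feat.start_codon = gene_seq[:3]
            feat.stop_codon = _terminal_codon_string(gene_seq)
        features.append(feat)
    return MitogenomeRecord(id=rec.id or path.stem, species=species, sequence=seq,
                            circular=circular, features=features)


def _terminal_codon_string(gene_seq: str) -> str:
    r = len(gene_seq) % 3
    if r == 0:
        return gene_seq[-3:]
    if r == 1:
        return f"{gene_seq[-1]}(AA)"
    return f"{gene_seq[-2:]}(A)"


# ---------------------------------------------------------------------------
# feature tables

_TABLE_COLUMNS = ("name", "category", "strand", "start", "end", "size",
                  "start_codon", "stop_codon", "anticodon")


def _infer_category(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn") or name in ("12S", "16S"):
        return "rRNA"
    if name.upper() in ("CR", "D-LOOP"):
        return "CR"
    return "PCG"


def read_feature_table(
    path: str | Path,
    sequence: str | None = None,
    record_id: str = "",
    species: str = "",
    circular: bool = True,
) -> MitogenomeRecord:
    """Read a TSV feature table (1-based inclusive coordinates).

    Required columns: ``name, strand, start, end``.  ``category`` is
    inferred from the name when absent.  A ``size`` column, if present,
    is cross-checked against the coordinates; on mismatch a warning is
    issued and the coordinates win.
    """
    path = Path(path)
    features: list[GeneFeature] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"name", "strand", "start", "end"} <= set(reader.fieldnames):
            raise GenomeParseError(
                f"{path}: feature table must have columns name, strand, start, end"
            )
        for lineno, row in enumerate(reader, start=2):
            name = row["name"].strip()
            if not name:
                continue
            if name in seen:
                raise GenomeParseError(f"{path}:{lineno}: duplicated feature name {name!r}")
            seen.add(name)
            try:
                start = int(row["start"])
                end = int(row["end"])
            except (TypeError, ValueError) as exc:
                raise GenomeParseError(f"{path}:{lineno}: bad coordinates for {name}") from exc
            if end < start and not circular:
                raise GenomeParseError(
                    f"{path}:{lineno}: {name} has start > end on a non-circular record"
                )
            category = (row.get("category") or "").strip() or _infer_category(name)
            feat = GeneFeature(
                name=name, category=category, strand=row["strand"].strip(),
                start=start, end=end,
                start_codon=(row.get("start_codon") or "").strip(),
                stop_codon=(row.get("stop_codon") or "").strip(),
                anticodon=(row.get("anticodon") or "").strip(),
            )
            declared = (row.get("size") or "").strip()
            features.append(feat)
    record = MitogenomeRecord(id=record_id or path.stem, species=species,
                              sequence=sequence or "", circular=circular,
                              features=features)
    # size cross-check needs the genome length, so run it after assembly
    with path.open("r", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            declared = (row.get("size") or "").strip()
            if not declared:
                continue
            name = row["name"].strip()
            if not name:
                continue
            feat = record.feature(name)
            actual = feat.size(record.length)
            if int(declared) != actual:
                warnings.warn(
                    f"{path}:{lineno}: {name} declared size {declared} != "
                    f"coordinate-derived {actual}; coordinates win",
                    stacklevel=2,
                )
    return record


def write_feature_table(record: MitogenomeRecord, path: str | Path) -> None:
    """Write the record's features as a TSV table (all nine columns)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for f in record.features:
            writer.writerow([f.name, f.category, f.strand, f.start, f.end,
                             f.size(record.length), f.start_codon, f.stop_codon,
                             f.anticodon])


def load_reference_table(species: str) -> MitogenomeRecord:
    """Load a shipped reference gene layout ('aegypti' or 'albopictus').

    The layouts reproduce the published annotation of the Bangladeshi
    Ae. aegypti (16,662 bp) and Ae. albopictus (16,585 bp) mitogenomes;
    no sequence is attached, only coordinates and codon annotations.
    """
    key = species.lower()
    if key not in ("aegypti", "albopictus"):
        raise ValueError("species must be 'aegypti' or 'albopictus'")
    path = resources.files("mitocomp.data").joinpath(f"reference_{key}.tsv")
    with resources.as_file(path) as p:
        rec = read_feature_table(p, record_id=f"Ae_{key}_BD",
                                 species=f"Aedes {key}", circular=True)
    return rec


# ---------------------------------------------------------------------------
# gene extraction

def extract_gene_coords(sequence: str, feature: GeneFeature, circular: bool = True) -> str:
    """Extract the 5'->3' gene sequence for ``feature`` from ``sequence``."""
    L = len(sequence)
    if not (1 <= feature.start <= L) or not (1 <= feature.end <= L):
        raise GenomeParseError(
            f"{feature.name}: coordinates {feature.start}-{feature.end} out of "
            f"range for genome of length {L}"
        )
    if feature.wraps:
        if not circular:
            raise GenomeParseError(
                f"{feature.name} wraps the origin but the record is linear"
            )
        sub = sequence[feature.start - 1:] + sequence[: feature.end]
    else:
        sub = sequence[feature.start - 1: feature.end]
    return reverse_complement(sub) if feature.strand == "-" else sub


def extract_gene(record: MitogenomeRecord, feature: GeneFeature | str) -> str:
    """5'->3' sequence of a feature: forward slice for '+', reverse
    complement for '-'; wrapping features concatenate tail + head first."""
    if isinstance(feature, str):
        feature = record.feature(feature)
    if not record.sequence:
        raise GenomeParseError(f"record {record.id} carries no sequence")
    return extract_gene_coords(record.sequence, feature, circular=record.circular)


def intergenic_spacing(record: MitogenomeRecord) -> list[tuple[str, int]]:
    """Recomputed intergenic gaps: feature.start - previous.end - 1.

    Negative values mark overlaps.  The first feature is measured from the
    origin.  Always recomputed from coordinates; any published spacer
    column is ignored.
    """
    out: list[tuple[str, int]] = []
    prev_end = 0
    for f in record.features:
        out.append((f.name, f.start - prev_end - 1))
        prev_end = max(prev_end, f.end if not f.wraps else record.length)
    return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping (uppercased)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise GenomeParseError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    path: str | Path,
    wrap: int = 70,
) -> None:
    """Write sequences as FASTA with fixed-width line wrapping.

    Ordering follows the input mapping/iterable, so output is deterministic
    for deterministic input.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if not items:
        raise ValueError("refusing to write an empty FASTA file")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i: i + wrap] + "\n")
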