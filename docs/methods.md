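# Methods

This note records the models, conventions and design choices behind
`mitocomp`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what
the synthetic tests do and do not demonstrate.

## Coordinates, records and gene extraction

All interfaces use 1-based inclusive coordinates (the GenBank
convention).  A feature with `end < start` wraps the origin of a
circular genome; its size is `(L − start + 1) + end` and extraction
concatenates the tail and head of the sequence before orienting.
Minus-strand genes are returned reverse-complemented, i.e. always
5′→3′.  Sequences are restricted to `{A,C,G,T,N}`; other IUPAC
ambiguity codes are rejected at read time because every downstream
statistic (composition, codon counts, K2P) assumes that alphabet.

The two shipped reference layouts reproduce the published annotation of
the Bangladeshi *Ae. aegypti* (16,662 bp) and *Ae. albopictus*
(16,585 bp) mitogenomes: 38 features each (13 PCGs, 22 tRNAs, 2 rRNAs,
1 control region), with PCG extents of 11,191 and 11,223 bp and control
regions of 1,721 and 1,694 bp.  Three published coordinate entries were
internally inconsistent with the published sizes and gene adjacency
(*nad4* end in *Ae. aegypti*; *cox2* start and *nad6* end in
*Ae. albopictus*); the layouts store the size-consistent coordinates,
since sizes, neighbour boundaries and the printed PCG totals all agree
on them.  Published sizes, strands (including the species-discordant
*trnS1*/*trnL1* strands) and codon annotations are stored verbatim.
Intergenic spacing is always recomputed as
`next.start − prev.end − 1` (negative = overlap) and never read from an
input table, because published spacer columns are frequently
inconsistent with the coordinates they accompany.

When a feature table carries a `size` column it is cross-checked; on
mismatch a warning is issued and coordinates win.

## Composition

AT/GC percentages and skews are carried at full precision internally;
rounding (2 decimals for percentages, 4 for skews) happens only in the
human-readable TSVs, with JSON twins at full precision.  N bases are
excluded from all numerators and from the AT+GC denominator; the policy
string is embedded in every composition table.  A skew whose
denominator is zero is reported missing, never as zero.

## Codon usage

The genetic code is NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG→Ser, TGA→Trp, ATA→Met; 62 sense codons, stops
TAA/TAG, Leu family 6, Ser family 8).  The registry is shipped as JSON
and asserted against Biopython's table in the tests; the engine is
generic over table ids.  Counting is frame-0 from the annotated start:
a trailing 1–2 nt incomplete codon is dropped, codons containing N are
skipped, and stop codons are excluded from usage counts (the terminal
stop is annotation, not usage).  RSCU is computed both per gene and
pooled over the 13 PCGs; a family with zero total yields missing RSCU
(NaN), which contributes 0 to cumulative sums and is reported.

Start/stop classification is purely length-mod-3 based: mod 0 → the
final triplet (flagged if it is not a stop, not raised), mod 1 →
`T(AA)`-style, mod 2 → `TA(A)`-style.  Noncanonical starts such as the
*cox1* TCG are reported verbatim, never corrected.

## Divergence

K2P distance uses transition proportion P (A↔G, C↔T) and transversion
proportion Q over comparable sites; columns with a gap or N in either
sequence are deleted pairwise.  Saturation (a non-positive logarithm
argument) is flagged and the distance reported missing, never clamped.
bp-per-SNP divides the count of columns with ≥ 2 unambiguous entries by
the count of variable columns — an alignment-robust denominator chosen
because the raw gene length would count gap-only columns.  Species-level
summaries are unweighted means across genes, so short genes count as
much as long ones, matching the per-gene presentation style of the
divergence figures this pipeline produces.  Per-gene panel summaries
default to all pairwise comparisons; a to-reference mode is available.
Distances are rounded to 3 decimals in TSVs only.

The built-in pairwise aligner is a Gotoh three-state global aligner
(match +1, mismatch −1, a gap run of length k costs 5 + k) with
deterministic traceback preference diagonal > up > left.  It is intended
for small, near-identical inputs; externally produced alignments are
accepted wherever alignments are consumed, and large-panel multiple
alignment is deliberately out of scope.

## Phylogeny

The 13 PCGs are concatenated in genome order (nad2, cox1, cox2, atp8,
atp6, cox3, nad3, nad5, nad4, nad4L, nad6, cytb, nad1); partitions tile
the columns exactly.  Neighbor joining follows Saitou–Nei with two
conventions: Q-criterion ties are broken by the first (smallest-index)
pair, and a negative branch estimate is clamped to zero with the deficit
transferred to its sister edge so the joined pair's distance is
preserved.  Trees are unrooted (root trifurcation for n ≥ 3); an
outgroup id reorders the root children for display only.

Bootstrap resamples alignment columns with replacement; each internal
bipartition of the point-estimate tree is annotated with the percentage
of successful replicates containing it.  One master seed spawns
independent per-replicate streams, so increasing the replicate count
never reshuffles earlier replicates.  Replicates whose resampled
distance matrix saturates are skipped and counted; the support
denominator is the number of successful replicates.  ML and Bayesian
inference are not reimplemented: the supermatrix, relaxed-PHYLIP and
partition exports feed external tools, while NJ on near-identical
mitogenomes serves as the in-repo, testable topology engine.

## Simulator

The ancestor is drawn i.i.d. with P(A)=P(T)=at_bias/2 and
P(C)=P(G)=(1−at_bias)/2; the default at_bias of 0.79 matches the AT
content of Aedes mitogenomes.  PCG reading frames are then repaired:
the layout's annotated start codon is written (or sampled from an
ATN-dominant spectrum when absent), the terminal stop matches the
layout's complete/incomplete notation, and internal TAA/TAG codons are
removed by minimal edits — third position → T preferred, falling back
to first/second positions when an overlapping gene locks the site
(e.g. the atp8/atp6 and nad4/nad4L overlaps).  Repair iterates to a
fixed point and fails loudly if overlapping constraints cannot be met.
The repair perturbs genome-wide AT content by well under one percent,
which the composition convergence test allows for explicitly.

Evolution is the K80 process parameterized by branch length b (expected
substitutions per site) and transition/transversion rate ratio κ
(default 4, a typical animal-mtDNA magnitude): each site receives
Poisson(b) events of the embedded jump chain, each event a transition
with probability κ/(κ+2), otherwise one of the two transversions with
equal probability.  Sites are independent and homogeneous, matching the
assumptions of the K2P estimator the simulator is used to validate.  No
indels are simulated — the divergence metrics are substitution-based —
so per-gene extracts from the leaves are automatically aligned; gapped
behaviour is exercised separately with hand-made fixtures.  The
frame-protecting mode restricts PCG substitutions to third codon
positions and discards events that would create an internal stop; it is
off by default because the restriction would bias distance-recovery
tests.  Realized per-branch transition/transversion event counts, leaf
sequences and true pairwise path lengths are recorded and round-trip
through JSON.

Default panel conditions mirror the study design: an aegypti-like panel
of 6 taxa and an albopictus-like panel of 13 taxa, star radiations with
root-to-tip depths 0.004 and 0.002 so the expected pairwise distances
are ≈ 0.008 and ≈ 0.004 substitutions/site.

What the synthetic data does **not** emulate: control-region repeat and
homopolymer structure, strand-asymmetric mutation pressure (the skews of
simulated genomes are ≈ 0), rate heterogeneity across sites or genes,
indels, and selection beyond stop-codon avoidance.  Passing recovery
tests therefore demonstrate estimator correctness under the estimator's
own model, not robustness to these real-data features.

## Numerical and testing choices

* Distances and supports are deterministic functions of inputs and
  seeds; all CLI stages are idempotent and manifest-logged (the manifest
  timestamp is the only non-reproducible output field).
* Statistical tests compare against closed forms where they exist (K2P
  on constructed counts, RSCU family sums to 1e-9, additive-matrix NJ)
  and otherwise against seeded Monte-Carlo expectations with 3-standard-
  error bands.
* K2P bias is verified two ways: at the study-scale design (100
  replicates of 10 kb pairs per true distance), whose Monte-Carlo error
  is ≈ 1.4% of d at d = 0.005, the replicate mean is required to be
  consistent with a true relative bias ≤ 2% after accounting for that
  sampling error; the 2% bias bound itself is asserted with an
  adequately powered experiment (10 seeded pairs of 2 Mb per distance,
  Monte-Carlo error ≤ 0.32%).
* Problem sizes in the test-suite simulations (3–11 kb alignments, 100
  bootstrap replicates, 100 topology-recovery runs) were chosen as the
  smallest designs at which the 3-SE bands above have useful power.

## Known limitations

* The aligner is quadratic and intended for genes, not genomes; it does
  not produce multiple alignments.
* De novo annotation, assembly, GFF3, ML/Bayesian tree inference and
  plot rendering are out of scope by design.
* Percent identity and SNP density assume their inputs are aligned;
  ragged inputs are rejected rather than aligned implicitly.
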