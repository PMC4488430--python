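# Methods

## The assay being modelled

Single-primer enrichment (SPET) targets RNAs for sequencing with one probe
per capture event. Total RNA is converted to double-stranded cDNA, adapters
are ligated to the fragment ends, and a panel of single-stranded probes —
each carrying a constant 5' tail used later as a PCR priming site — is
hybridized to the denatured cDNA. A polymerase then extends each annealed
probe from its 3' end toward the fragment's adapter. Because only one side
of the captured molecule must match the panel, sequence *downstream* of the
probe is recovered even when it comes from a locus the panel knows nothing
about. That is what makes the chemistry attractive for gene-fusion
discovery: a fusion transcript is recovered, and both partners identified,
when only one partner is targeted.

`spetseq` reimplements the computational side of this assay end to end on
synthetic data: the panel designer, an in-silico simulator of the library
steps with full ground-truth provenance, and a split-read fusion caller
with on-target enrichment metrics.

## Panel design

Probes are designed per exon against both strands of the ds-cDNA:

* **Boundary probes.** Every designable exon receives one probe per strand
  with its 3' end flush against an exon boundary, extension pointing *out*
  of the exon: the downstream-extending probe (annealing to the antisense
  strand, copying the transcript sequence) is anchored at the exon's 3'
  boundary, the upstream-extending probe (annealing to the sense strand) at
  the 5' boundary. Extension therefore always crosses at least one
  exon–exon junction — and, on a fusion transcript, the fusion junction.
* **Tile probes.** Exons longer than the tile interval (default 300 nt)
  receive interior probes so coverage does not decay across long exons.
  Tiles are anchored per strand, walking in tile-interval steps from that
  strand's boundary anchor (from the 3' boundary for downstream-extending
  probes, from the 5' boundary for upstream-extending ones). Anchors whose
  probe footprint would leave the exon are skipped. This convention was
  chosen over a single shared offset grid because it bounds consecutive
  same-strand anchor spacing at exactly the tile interval for every exon
  length — the property the tiling exists to provide.
* **Deduplication.** Probes are deduplicated on their full sequence (tail
  included) so isoforms sharing an exon contribute one probe set, and the
  output ordering (gene, genomic anchor, strand) is deterministic; the
  design contains no randomness.
* Exons shorter than the probe are recorded as undesignable, not errors.

`cdna_strand` names the strand the probe *anneals to*; annealing to the
antisense strand means the probe's sequence equals the transcript and
extension runs 3'-ward. Probe length (default 40 nt) and the tail sequence
are chemistry properties, configurable; the defaults keep toy instances
small. Thermodynamic scoring (Tm, hairpins, cross-hybridization),
repeat/mappability masking and isoform weighting are out of scope.

## Simulator

* **Input abstraction.** `n_molecules` stands in for nanograms of RNA; no
  mass conversion is attempted. Per-transcript fragment counts are
  multinomial in abundance x length (longer molecules shear into more
  fragments).
* **Fragmentation.** Fragment lengths are log-normal, parameterized by the
  desired mean/sd in nucleotides and truncated to the transcript. Defaults:
  mean 400, sd 100 (fresh); mean 200, sd 80 in FFPE mode, emulating
  formalin-fragmented input with a halved typical insert. Starts are
  uniform.
* **Capture.** A fragment is captured iff it wholly contains at least one
  exact, full-length probe match on the matching strand; hybridization has
  no mismatch model and washing is perfect. One eligible probe is chosen
  uniformly at random (no competition or efficiency weights). The captured
  molecule (insert) runs from the probe's 3' end to the fragment's adapter
  end; probes flush with the fragment end extend into nothing and are
  discarded, as unextended probes are in the real protocol.
* **Sequencing.** R1 begins at the probe's 3'-end position and reads in
  the extension direction — the probe itself is not sequenced, since the
  sequencing primer sits at the tail/insert junction. R2 reads inward from
  the adapter end. Inserts shorter than the read length are padded with the
  known constant adapter. Errors are i.i.d. substitutions (default 0.005
  per base, a generic short-read figure); qualities are constant; PCR
  duplication and indels are not simulated. Every read id encodes its full
  provenance, mirrored in a truth TSV.
* **Determinism.** One seed per run fans out to per-stage seeds through
  `numpy.random.SeedSequence.spawn`, so fragmentation, capture and error
  injection are independently reproducible and identical configs give
  byte-identical FASTQ.

The synthetic genome generator emulates multi-exon gene models with uniform
base composition laid out without overlap on one chromosome. Real
transcriptomes differ in ways that matter for interpretation: homologous
gene families, repeats, biased composition and alternative isoforms all
make real alignment harder than alignment of uniform random sequence, so
passing tests here demonstrate correctness of the machinery, not expected
sensitivity/specificity on a real sample.

## Fusion caller

Alignment is in transcriptome space (the assay enriches cDNA); genomic
coordinates are projections through the annotation.

* **Index and segments.** An exact k-mer multimap (default k = 21) over
  the reference transcripts; k-mers shared across genes are flagged
  ambiguous. Read hits are grouped per (transcript, diagonal) and extended
  base by base. A mismatch is crossed only when the next 4 bases match and
  the per-segment budget (default 2) allows: this absorbs isolated
  sequencing errors without extending across chance junction homology,
  which keeps split breakpoints stable.
* **Classification.** A segment covering the (adapter-trimmed) read within
  2 nt is a unique full-length placement; equally good placements in
  different genes drop the read (conservative uniqueness). Otherwise the
  best prefix-segment + suffix-segment pair from two different genes, each
  providing at least `min_overhang` (default 10 nt) around the junction
  and jointly covering the read within 2 nt, marks the read as split.
* **Breakpoint normalization.** When the partners share sequence at the
  junction the placement is ambiguous over a short homology interval; the
  *leftmost* placement (5'-most on the 5' partner) is reported, with the
  homology length as `ambiguity`. Clusters of split reads vote: the modal
  placement becomes the call's breakpoint, and nearby minority placements
  (within homology + 2 nt) merge in.
* **Rescue.** A junction read whose flank on one side is long enough to
  support a call but too short to hold a k-mer seed cannot be split-mapped
  directly. Such partially aligned reads are re-examined against each
  candidate call: if the unexplained flank exactly matches that call's
  reference junction context, the read supports the call. With this pass
  the supporting-read criterion coincides exactly, at zero error, with
  "covers >= min_overhang on both sides of the (leftmost-normalized)
  junction" — the property the test suite checks against the simulator's
  truth records.
* **Calls.** Clusters need `min_supporting_reads` (default 2) split reads,
  distinct partner genes, and at least one partner with probes in the
  panel; calls are labelled `both`, `five_only` or `three_only`.
  `spanning_pairs` counts non-split pairs whose mates map uniquely to the
  two partners. Thresholds are this tool's own defaults and are written
  into every output header. Read-through junctions between adjacent genes
  are not distinguished from trans events.
* **Metrics.** `on_target_rate` uses forward (R1) reads only: the mapped
  fraction, and the fraction of mapped reads whose genomic projection
  overlaps a panel target interval by at least one base.
  `compare_efficiency` reports targeted depth as a percentage of
  untargeted depth (one decimal) and the fold reduction (nearest integer).

## Problem sizes and numerical choices

The bundled demo runs 5 genes x 4 exons with one planted fusion at 2x the
background abundance and 20,000 molecules; the seeded caller suites use the
same geometry at 2,000–8,000 molecules per replicate, sizes at which every
behavioural property is already stable while a full test run stays in the
tens of seconds. Adapter trimming requires an 8-base exact prefix hit plus
a 10%-mismatch tail check; rescue matching is exact (a read with an error
in its short flank is not rescued — a deliberate, conservative miss).
Degenerate inputs are defined: zero molecules give an empty library, an
empty captured set is a hard error, a fusion-free library yields an empty
(valid) call set, and an all-unmapped input reports an undefined (NaN)
on-target fraction.

## Known limitations

Hybridization, capture efficiency and PCR are idealized, so absolute
on-target and support numbers are upper bounds on real-assay behaviour.
The caller is a desk-scale reimplementation: no gapped alignment, no
genome-space spliced mapping, no BAM emission, and no FFPE deamination
modelling. In-frame annotation of fusions requires CDS metadata, which the
synthetic generator does not produce (calls are then labelled unknown).
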