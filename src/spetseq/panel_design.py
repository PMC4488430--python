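"""Capture-probe panel design for single-primer enrichment (SPET) assays.

A SPET panel is a set of single-stranded oligonucleotide probes designed
against the exons of a gene annotation.  Each probe anneals to one strand of
the double-stranded cDNA and is extended by a polymerase from its 3' end, so
the sequence recovered lies *beyond* the probe in the extension direction.
The design rules implemented here are:

* every exon long enough to hold a probe receives two boundary probes, one
  per cDNA strand, each with its 3' end flush against an exon boundary so
  that extension crosses the adjacent exon-exon junction (or, on a fusion
  transcript, the fusion junction);
* exons longer than the tile interval (default 300 nt) additionally receive
  interior "tile" probes on both strands so that consecutive same-strand
  anchor positions are never more than one tile interval apart;
* probes are deduplicated on their full sequence (common amplification tail
  included) across isoforms that share exons.

Strand convention
-----------------
``cdna_strand`` records which strand of the ds-cDNA the probe *anneals to*:

* ``"antisense"`` — the probe copies the sense (transcript) sequence; its 3'
  end points toward the transcript 3' end and extension runs *downstream*.
* ``"sense"`` — the probe is the reverse complement of the transcript; its
  3' end points toward the transcript 5' end and extension runs *upstream*.

Coordinates are 0-based half-open internally (GTF input is 1-based
inclusive and converted on parse; BED output is 0-based half-open).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import gffutils
from pyfaidx import Fasta

__all__ = [
    "ExonRecord",
    "PanelDesignParams",
    "ProbeSpec",
    "PanelManifest",
    "TranscriptLayout",
    "AnnotationBundle",
    "parse_annotation",
    "design_probes_for_exon",
    "design_panel",
    "write_panel",
    "read_panel",
    "revcomp",
    "DEFAULT_TAIL",
]

#: Common tail appended 5' of every probe; a universal priming site for the
#: library amplification PCR.  The assay requires *a* constant tail, not a
#: particular sequence, so this default is an arbitrary fixed 20-mer.
DEFAULT_TAIL = "ATGCCGATTGCACGTCAGGA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonRecord:
    """One exon of one transcript, in genomic coordinates.

    ``exon_index`` is 1-based along the transcript in the 5'->3' direction
    (for minus-strand genes, exon 1 has the *highest* genomic coordinate).
    """

    gene_id: str
    transcript_id: str
    exon_index: int
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    genomic_strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"exon {self.transcript_id}:{self.exon_index} has end <= start"
            )
        if self.genomic_strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.genomic_strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PanelDesignParams:
    """Tunable knobs of the probe designer.

    ``tile_interval`` and ``min_probes_per_exon`` come from the assay's
    published design rules; probe length and tail sequence are properties of
    the probe chemistry and are configurable.
    """

    tile_interval: int = 300
    min_probes_per_exon: int = 2
    probe_length: int = 40
    tail_sequence: str = DEFAULT_TAIL
    min_exon_length_for_probe: int | None = None

    def __post_init__(self):
        if self.tile_interval <= 0:
            raise ValueError("tile_interval must be positive")
        if self.probe_length <= 0:
            raise ValueError("probe_length must be positive")
        if self.min_probes_per_exon < 1:
            raise ValueError("min_probes_per_exon must be >= 1")
        if self.min_exon_length_for_probe is None:
            object.__setattr__(self, "min_exon_length_for_probe", self.probe_length)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PanelDesignParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ProbeSpec:
    """One targeting probe.

    ``anchor_pos`` is the transcript coordinate of the probe's 3' end in
    half-open convention: for downstream-extending (antisense-annealing)
    probes it is the footprint *end*; for upstream-extending
    (sense-annealing) probes it is the footprint *start*.  Extension begins
    at ``anchor_pos`` and moves away from the probe.  ``genomic_anchor`` is
    the genomic coordinate of the 3'-terminal *base* of the probe.
    """

    probe_id: str
    gene_id: str
    transcript_id: str
    exon_index: int
    chrom: str
    cdna_strand: str  # {"sense", "antisense"}: strand annealed to
    anchor_pos: int  # transcript coordinate of the 3' end
    genomic_anchor: int
    genomic_start: int  # footprint, 0-based half-open
    genomic_end: int
    genomic_match_strand: str  # genome strand whose sequence equals probe_seq
    probe_seq: str
    full_seq: str
    origin: str  # {"boundary_3prime", "boundary_5prime", "tile"}

    @property
    def extends_downstream(self) -> bool:
        """True if polymerase extension runs toward the transcript 3' end."""
        return self.cdna_strand == "antisense"


@dataclass
class TranscriptLayout:
    """Exon structure of one transcript plus its spliced sequence.

    Provides the transcript<->genome coordinate projection used by the probe
    designer and by the on-target metrics.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    genomic_strand: str
    exons: tuple  # ExonRecords ordered by exon_index
    spliced_seq: str
    tx_starts: tuple = ()  # transcript offset of each exon's 5' end

    def __post_init__(self):
        starts, off = [], 0
        for ex in self.exons:
            starts.append(off)
            off += ex.length
        self.tx_starts = tuple(starts)
        if self.spliced_seq and len(self.spliced_seq) != off:
            raise ValueError(
                f"{self.transcript_id}: spliced length {len(self.spliced_seq)} "
                f"!= exon total {off}"
            )

    @property
    def length(self) -> int:
        return sum(ex.length for ex in self.exons)

    def exon_tx_start(self, exon_index: int) -> int:
        return self.tx_starts[exon_index - 1]

    def genomic_point(self, t: int) -> int:
        """Genomic coordinate of the base at transcript position ``t``."""
        for ex, t0 in zip(self.exons, self.tx_starts):
            if t0 <= t < t0 + ex.length:
                if self.genomic_strand == "+":
                    return ex.start + (t - t0)
                return ex.end - 1 - (t - t0)
        raise IndexError(f"transcript position {t} outside {self.transcript_id}")

    def genomic_intervals(self, s: int, e: int) -> list:
        """Project transcript interval [s, e) to genomic intervals."""
        out = []
        for ex, t0 in zip(self.exons, self.tx_starts):
            lo, hi = max(s, t0), min(e, t0 + ex.length)
            if lo >= hi:
                continue
            if self.genomic_strand == "+":
                out.append((self.chrom, ex.start + (lo - t0), ex.start + (hi - t0)))
            else:
                out.append((self.chrom, ex.end - (hi - t0), ex.end - (lo - t0)))
        return out


@dataclass
class AnnotationBundle:
    """Output of :func:`parse_annotation`."""

    exons: list
    layouts: dict  # transcript_id -> TranscriptLayout
    warnings: list = field(default_factory=list)


@dataclass
class PanelManifest:
    """A designed probe panel: deduplicated probes plus target intervals."""

    probes: list
    targeted_genes: frozenset
    target_intervals: dict  # gene_id -> tuple of (chrom, start, end)
    design_params: PanelDesignParams
    stats: dict
    undesignable: list = field(default_factory=list)

    def __eq__(self, other):
        if not isinstance(other, PanelManifest):
            return NotImplemented
        return (
            self.probes == other.probes
            and self.targeted_genes == other.targeted_genes
            and self.target_intervals == other.target_intervals
            and self.design_params == other.design_params
            and self.stats == other.stats
            and sorted(map(tuple, self.undesignable))
            == sorted(map(tuple, other.undesignable))
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def parse_annotation(annotation_file, sequence_file, gene_list=None) -> AnnotationBundle:
    """Read a GTF/GFF3 annotation + genome FASTA into exon records and
    spliced transcript sequences.

    Parameters
    ----------
    annotation_file, sequence_file : path-like
    gene_list : optional set of gene_id
        Restrict to these genes.  Genes absent from the annotation produce a
        warning and are listed in the bundle's ``warnings``.

    Raises
    ------
    ValueError
        If an exon references a chromosome missing from the FASTA.
    """
    fasta = Fasta(str(sequence_file))
    db = gffutils.create_db(
        str(annotation_file),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    wanted = set(gene_list) if gene_list is not None else None
    by_tx: dict[str, list] = {}
    tx_meta: dict[str, tuple] = {}
    seen_genes: set[str] = set()
    for feat in db.features_of_type("exon"):
        gid = feat.attributes["gene_id"][0]
        tid = feat.attributes["transcript_id"][0]
        seen_genes.add(gid)
        if wanted is not None and gid not in wanted:
            continue
        if feat.seqid not in fasta:
            raise ValueError(
                f"chromosome {feat.seqid!r} referenced by {tid} is missing "
                f"from {sequence_file}"
            )
        # GTF is 1-based inclusive -> 0-based half-open
        by_tx.setdefault(tid, []).append((feat.seqid, feat.start - 1, feat.end, feat.strand))
        tx_meta[tid] = (gid, feat.seqid, feat.strand)

    notes = []
    if wanted is not None:
        missing = sorted(wanted - seen_genes)
        if missing:
            msg = f"genes absent from annotation: {', '.join(missing)}"
            warnings.warn(msg)
            notes.append(msg)
        if not by_tx:
            notes.append("no exons matched the requested gene list")

    exons: list[ExonRecord] = []
    layouts: dict[str, TranscriptLayout] = {}
    for tid in sorted(by_tx):
        gid, chrom, strand = tx_meta[tid]
        ivs = sorted(by_tx[tid], key=lambda r: r[1])
        n = len(ivs)
        recs = []
        for i, (c, s, e, _) in enumerate(ivs):
            idx = i + 1 if strand == "+" else n - i
            recs.append(ExonRecord(gid, tid, idx, c, s, e, strand))
        recs.sort(key=lambda r: r.exon_index)
        genomic_order = sorted(recs, key=lambda r: r.start)
        seq = "".join(str(fasta[r.chrom][r.start : r.end]) for r in genomic_order)
        if strand == "-":
            seq = revcomp(seq)
        seq = seq.upper()
        layouts[tid] = TranscriptLayout(tid, gid, chrom, strand, tuple(recs), seq)
        exons.extend(recs)

    exons.sort(key=lambda r: (r.gene_id, r.transcript_id, r.exon_index))
    return AnnotationBundle(exons=exons, layouts=layouts, warnings=notes)


def _probe_id(gene_id, chrom, gstart, cdna_strand):
    return f"{gene_id}:{chrom}:{gstart}:{cdna_strand[0]}"


def _make_probe(exon, layout, params, local_anchor, downstream, origin):
    """Build a ProbeSpec from an exon-local anchor offset."""
    P = params.probe_length
    t0 = layout.exon_tx_start(exon.exon_index)
    if downstream:
        lo, hi = local_anchor - P, local_anchor  # footprint, exon-local
        anchor_tx = t0 + local_anchor
        probe_seq = layout.spliced_seq[t0 + lo : t0 + hi]
        terminal_base_tx = anchor_tx - 1
        cdna_strand = "antisense"
    else:
        lo, hi = local_anchor, local_anchor + P
        anchor_tx = t0 + local_anchor
        probe_seq = revcomp(layout.spliced_seq[t0 + lo : t0 + hi])
        terminal_base_tx = anchor_tx
        cdna_strand = "sense"
    if exon.genomic_strand == "+":
        gstart, gend = exon.start + lo, exon.start + hi
    else:
        gstart, gend = exon.end - hi, exon.end - lo
    # the probe sequence equals the genome + strand iff (gene on +) == (downstream)
    match = exon.genomic_strand if downstream else ("-" if exon.genomic_strand == "+" else "+")
    return ProbeSpec(
        probe_id=_probe_id(exon.gene_id, exon.chrom, gstart, cdna_strand),
        gene_id=exon.gene_id,
        transcript_id=exon.transcript_id,
        exon_index=exon.exon_index,
        chrom=exon.chrom,
        cdna_strand=cdna_strand,
        anchor_pos=anchor_tx,
        genomic_anchor=layout.genomic_point(terminal_base_tx),
        genomic_start=gstart,
        genomic_end=gend,
        genomic_match_strand=match,
        probe_seq=probe_seq,
        full_seq=params.tail_sequence + probe_seq,
        origin=origin,
    )


def design_probes_for_exon(exon: ExonRecord, layout: TranscriptLayout,
                           params: PanelDesignParams) -> list:
    """Design all probes for one exon.

    Two boundary probes (one per cDNA strand, 3' ends flush with the exon
    boundaries, extension pointing out of the exon) are always emitted for a
    designable exon.  Exons longer than ``tile_interval`` get interior tile
    probes on each strand, anchored at tile-interval steps walked in from
    that strand's boundary anchor, so same-strand anchor spacing never
    exceeds the tile interval.  Anchors whose probe footprint would leave
    the exon are skipped.

    Returns an empty list for exons too short to hold a probe (the caller
    records these as undesignable).
    """
    L, P, T = exon.length, params.probe_length, params.tile_interval
    if L < params.min_exon_length_for_probe:
        return []
    down_anchors = [L]  # extension downstream; anchored at the 3' boundary
    up_anchors = [0]  # extension upstream; anchored at the 5' boundary
    if L > T:
        a = L - T
        while a - P >= 0:
            down_anchors.append(a)
            a -= T
        a = T
        while a + P <= L:
            up_anchors.append(a)
            a += T
    probes = []
    for a in down_anchors:
        origin = "boundary_3prime" if a == L else "tile"
        probes.append(_make_probe(exon, layout, params, a, True, origin))
    for a in up_anchors:
        origin = "boundary_5prime" if a == 0 else "tile"
        probes.append(_make_probe(exon, layout, params, a, False, origin))
    return probes


def _merge_intervals(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def design_panel(exons, layouts, params: PanelDesignParams | None = None) -> PanelManifest:
    """Design the full panel: per-exon probes, deduplicated on full_seq.

    Probes identical in sequence (isoforms sharing an exon) collapse to one
    entry.  Output order is deterministic: (gene_id, genomic_anchor,
    cdna_strand).  Raises ``ValueError`` if no exon is designable.
    """
    params = params or PanelDesignParams()
    by_seq: dict[str, ProbeSpec] = {}
    undesignable = []
    probed_exons = set()
    ordered = sorted(exons, key=lambda r: (r.gene_id, r.transcript_id, r.exon_index))
    for exon in ordered:
        layout = layouts[exon.transcript_id]
        designed = design_probes_for_exon(exon, layout, params)
        if not designed:
            undesignable.append((exon.transcript_id, exon.exon_index, exon.length))
            continue
        probed_exons.add((exon.chrom, exon.start, exon.end, exon.gene_id))
        for p in designed:
            by_seq.setdefault(p.full_seq, p)
    if not by_seq:
        raise ValueError("no designable exons: every exon is shorter than the probe")
    probes = sorted(by_seq.values(),
                    key=lambda p: (p.gene_id, p.genomic_anchor, p.cdna_strand))
    genes = frozenset(p.gene_id for p in probes)
    per_gene: dict[str, list] = {}
    for chrom, s, e, gid in probed_exons:
        if gid in genes:
            per_gene.setdefault(gid, []).append((chrom, s, e))
    target_intervals = {}
    for gid, ivs in per_gene.items():
        by_chrom: dict[str, list] = {}
        for chrom, s, e in ivs:
            by_chrom.setdefault(chrom, []).append((s, e))
        merged = []
        for chrom in sorted(by_chrom):
            merged.extend((chrom, s, e) for s, e in _merge_intervals(by_chrom[chrom]))
        target_intervals[gid] = tuple(merged)
    stats = {
        "probes_total": len(probes),
        "exons_covered": len(probed_exons),
        "genes_covered": len(genes),
    }
    return PanelManifest(
        probes=probes,
        targeted_genes=genes,
        target_intervals=target_intervals,
        design_params=params,
        stats=stats,
        undesignable=undesignable,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TSV_FIELDS = [
    "probe_id", "gene_id", "transcript_id", "exon_index", "chrom",
    "cdna_strand", "anchor_pos", "genomic_anchor", "genomic_start",
    "genomic_end", "genomic_match_strand", "probe_seq", "full_seq", "origin",
]


def write_panel(manifest: PanelManifest, out_dir) -> dict:
    """Write probes.fasta, probes.bed, targets.bed, panel.tsv and
    design_report.txt into ``out_dir``; returns the path map."""
    if not manifest.probes:
        raise ValueError("refusing to write an empty panel")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in
             ("probes.fasta", "probes.bed", "targets.bed", "panel.tsv",
              "design_report.txt")}

    with open(paths["probes.fasta"], "w") as fh:
        for p in manifest.probes:
            fh.write(f">{p.probe_id}\n{p.full_seq}\n")

    with open(paths["probes.bed"], "w") as fh:
        for p in manifest.probes:
            fh.write(f"{p.chrom}\t{p.genomic_start}\t{p.genomic_end}\t"
                     f"{p.probe_id}\t0\t{p.genomic_match_strand}\n")

    with open(paths["targets.bed"], "w") as fh:
        for gid in sorted(manifest.target_intervals):
            for chrom, s, e in manifest.target_intervals[gid]:
                fh.write(f"{chrom}\t{s}\t{e}\t{gid}\t0\t+\n")

    with open(paths["panel.tsv"], "w") as fh:
        fh.write(f"#params\t{manifest.design_params.to_json()}\n")
        fh.write(f"#stats\t{json.dumps(manifest.stats, sort_keys=True)}\n")
        for tid, idx, length in manifest.undesignable:
            fh.write(f"#undesignable\t{tid}\t{idx}\t{length}\n")
        fh.write("\t".join(_TSV_FIELDS) + "\n")
        for p in manifest.probes:
            d = asdict(p)
            fh.write("\t".join(str(d[k]) for k in _TSV_FIELDS) + "\n")

    with open(paths["design_report.txt"], "w") as fh:
        fh.write("SPET panel design report\n")
        fh.write(f"params: {manifest.design_params.to_json()}\n")
        for k, v in manifest.stats.items():
            fh.write(f"{k}: {v}\n")
        fh.write(f"undesignable_exons: {len(manifest.undesignable)}\n")
        for tid, idx, length in manifest.undesignable:
            fh.write(f"  undesignable {tid} exon {idx} length {length}\n")

    return paths


def read_panel(panel_dir) -> PanelManifest:
    """Reconstruct a :class:`PanelManifest` written by :func:`write_panel`."""
    d = Path(panel_dir)
    params = None
    stats = None
    undesignable = []
    probes = []
    header = None
    with open(d / "panel.tsv") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#params\t"):
                params = PanelDesignParams.from_json(line.split("\t", 1)[1])
                continue
            if line.startswith("#stats\t"):
                stats = json.loads(line.split("\t", 1)[1])
                continue
            if line.startswith("#undesignable\t"):
                _, tid, idx, length = line.split("\t")
                undesignable.append((tid, int(idx), int(length)))
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            for k in ("exon_index", "anchor_pos", "genomic_anchor",
                      "genomic_start", "genomic_end"):
                row[k] = int(row[k])
            probes.append(ProbeSpec(**row))
    if params is None or header is None:
        raise ValueError(f"malformed panel.tsv in {panel_dir}")
    target_intervals: dict[str, list] = {}
    with open(d / "targets.bed") as fh:
        for line in fh:
            chrom, s, e, gid, _, _ = line.rstrip("\n").split("\t")
            target_intervals.setdefault(gid, []).append((chrom, int(s), int(e)))
    target_intervals = {g: tuple(v) for g, v in target_intervals.items()}
    genes = frozenset(p.gene_id for p in probes)
    if stats is None:
        stats = {
            "probes_total": len(probes),
            "exons_covered": sum(len(v) for v in target_intervals.values()),
            "genes_covered": len(genes),
        }
    return PanelManifest(
        probes=probes,
        targeted_genes=genes,
        target_intervals=target_intervals,
        design_params=params,
        stats=stats,
        undesignable=undesignable,
    )
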