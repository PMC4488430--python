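"""In-silico SPET library preparation and sequencing.

Simulates the molecular steps of the assay on a synthetic transcriptome:
double-stranded cDNA is fragmented, adapters are (abstractly) ligated to the
fragment ends, a panel probe anneals inside the fragment and is extended by a
polymerase toward the adapter end, and the extension product is sequenced as
a paired-end read.  Every emitted read carries full ground-truth provenance
(source transcript, capturing probe, fragment and insert intervals, whether
the insert spans a fusion junction), both in a truth TSV and encoded in the
FASTQ read id.

The capture model is idealized: a fragment is captured iff it wholly
contains the footprint of at least one probe with an exact sequence match on
the matching strand; washing is perfect (uncaptured fragments vanish);
hybridization has no mismatch tolerance.  Sequencing errors are i.i.d.
substitutions.  FFPE material is emulated by a shorter fragment-length
distribution, reflecting formalin-induced fragmentation of the input RNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel_design import TranscriptLayout, revcomp

__all__ = [
    "ADAPTER",
    "TranscriptModel",
    "FusionEvent",
    "LibraryConfig",
    "Fragment",
    "CapturedMolecule",
    "generate_synthetic_genome",
    "build_fusion_transcript",
    "simulate_fragments",
    "capture_and_extend",
    "emit_fastq",
    "run_library_sim",
    "parse_read_id",
]

#: Constant adapter ligated (abstractly) to fragment ends; also used to pad
#: reads whose insert is shorter than the read length, as on a sequencer.
ADAPTER = "ACCGGTTACGAGATCTGAGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA (GC ~ 0.5)."""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FusionEvent:
    """Provenance of a planted fusion transcript."""

    gene5_id: str
    gene3_id: str
    last_exon_5prime: int
    first_exon_3prime: int
    junction_pos: int  # transcript coordinate of the breakpoint
    in_frame: bool | None  # None = unknown (no CDS metadata)


@dataclass
class TranscriptModel:
    """A spliced transcript; fusion transcripts carry a FusionEvent."""

    transcript_id: str
    gene_id: str
    spliced_seq: str
    exon_boundaries: tuple  # cumulative exon end coordinates; last == length
    is_fusion: bool = False
    fusion_meta: FusionEvent | None = None
    cds_start: int | None = None

    def __post_init__(self):
        b = self.exon_boundaries
        if list(b) != sorted(set(b)) or (b and b[-1] != len(self.spliced_seq)):
            raise ValueError(
                f"{self.transcript_id}: exon_boundaries must be strictly "
                f"increasing and end at the transcript length"
            )

    @classmethod
    def from_layout(cls, layout: TranscriptLayout) -> "TranscriptModel":
        bounds, off = [], 0
        for ex in layout.exons:
            off += ex.length
            bounds.append(off)
        return cls(layout.transcript_id, layout.gene_id, layout.spliced_seq,
                   tuple(bounds))

    @property
    def n_exons(self) -> int:
        return len(self.exon_boundaries)


@dataclass
class LibraryConfig:
    """Knobs of the simulated library prep.

    ``n_molecules`` abstracts nanograms of input RNA.  Fragment lengths are
    log-normal with the given mean/sd in nucleotides; when unset, the
    defaults are 400/100 for fresh material and 200/80 in FFPE mode.
    """

    n_molecules: int = 20000
    abundances: dict = field(default_factory=dict)  # transcript_id -> weight
    fragment_length_mean: float | None = None
    fragment_length_sd: float | None = None
    ffpe_mode: bool = False
    read_length: int = 75
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.abundances and (
            min(self.abundances.values()) < 0
            or not any(v > 0 for v in self.abundances.values())
        ):
            raise ValueError("abundances must be >= 0 and not all zero")

    @property
    def effective_fragment_mean(self) -> float:
        if self.fragment_length_mean is not None:
            return self.fragment_length_mean
        return 200.0 if self.ffpe_mode else 400.0

    @property
    def effective_fragment_sd(self) -> float:
        if self.fragment_length_sd is not None:
            return self.fragment_length_sd
        return 80.0 if self.ffpe_mode else 100.0


@dataclass(frozen=True)
class Fragment:
    """A ds-cDNA fragment with adapters on both ends (transcript coords)."""

    transcript_id: str
    start: int
    end: int


@dataclass(frozen=True)
class CapturedMolecule:
    """An extension product: probe 3' end to the fragment's adapter end.

    ``orientation`` is '+' when the insert reads in transcript sense
    (downstream-extending probe) and '-' when it reads antisense
    (upstream-extending probe).  The insert excludes the probe footprint.
    """

    transcript_id: str
    probe_id: str
    frag_start: int
    frag_end: int
    insert_start: int
    insert_end: int
    orientation: str
    spans_junction: bool


# ---------------------------------------------------------------------------
# synthetic genome fixture generator
# ---------------------------------------------------------------------------


def generate_synthetic_genome(n_genes=5, exons_per_gene=4,
                              exon_length_range=(100, 200),
                              intron_length_range=(100, 500),
                              seed=0, out_dir=".", chrom="chr1",
                              intergenic_gap=300):
    """Write a random but seed-reproducible genome FASTA + GTF annotation.

    Genes are laid out sequentially on one chromosome (never overlapping),
    with random strands, multi-exon structure, and uniform base composition.
    Returns ``(fasta_path, gtf_path)``.
    """
    if min(n_genes, exons_per_gene, exon_length_range[0],
           intron_length_range[0]) <= 0:
        raise ValueError("all counts and minimum lengths must be positive")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = []  # (gene_id, strand, [(exon_start, exon_end), ...])
    cursor = intergenic_gap
    for i in range(n_genes):
        gid = f"g{i + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exon_ivs = []
        pos = cursor
        for j in range(exons_per_gene):
            elen = int(rng.integers(exon_length_range[0], exon_length_range[1] + 1))
            exon_ivs.append((pos, pos + elen))
            pos += elen
            if j < exons_per_gene - 1:
                pos += int(rng.integers(intron_length_range[0],
                                        intron_length_range[1] + 1))
        genes.append((gid, strand, exon_ivs))
        cursor = pos + intergenic_gap
    total = cursor

    seq = _random_seq(rng, total)
    fasta_path = out / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for k in range(0, total, 60):
            fh.write(seq[k : k + 60] + "\n")

    gtf_path = out / "genes.gtf"
    src = "spetseq_sim"
    with open(gtf_path, "w") as fh:
        for gid, strand, exon_ivs in genes:
            tid = f"{gid}.t1"
            gstart, gend = exon_ivs[0][0] + 1, exon_ivs[-1][1]
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            fh.write(f"{chrom}\t{src}\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
                     f'gene_id "{gid}";\n')
            fh.write(f"{chrom}\t{src}\ttranscript\t{gstart}\t{gend}\t.\t{strand}"
                     f"\t.\t{attrs}\n")
            for s, e in exon_ivs:
                fh.write(f"{chrom}\t{src}\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                         f"{attrs}\n")
    return fasta_path, gtf_path


# ---------------------------------------------------------------------------
# fusion construction
# ---------------------------------------------------------------------------


def build_fusion_transcript(t5: TranscriptModel, exon5: int,
                            t3: TranscriptModel, exon3: int,
                            transcript_id: str | None = None) -> TranscriptModel:
    """Join exons 1..exon5 of ``t5`` to exons exon3..end of ``t3``.

    The fused sequence is an exact concatenation; the junction coordinate
    equals the summed length of the retained 5'-partner exons.  Frame is
    computed only when both parents carry CDS metadata, else left unknown.
    """
    if not (1 <= exon5 <= t5.n_exons):
        raise ValueError(f"exon {exon5} out of range for {t5.transcript_id}")
    if not (1 <= exon3 <= t3.n_exons):
        raise ValueError(f"exon {exon3} out of range for {t3.transcript_id}")
    prefix_len = t5.exon_boundaries[exon5 - 1]
    suffix_start = t3.exon_boundaries[exon3 - 2] if exon3 > 1 else 0
    seq = t5.spliced_seq[:prefix_len] + t3.spliced_seq[suffix_start:]
    bounds = list(t5.exon_boundaries[:exon5]) + [
        prefix_len + (b - suffix_start) for b in t3.exon_boundaries[exon3 - 1:]
    ]
    in_frame = None
    if t5.cds_start is not None and t3.cds_start is not None:
        in_frame = (prefix_len - t5.cds_start) % 3 == (suffix_start - t3.cds_start) % 3
    meta = FusionEvent(t5.gene_id, t3.gene_id, exon5, exon3, prefix_len, in_frame)
    tid = transcript_id or f"{t5.gene_id}-{t3.gene_id}.fusion"
    return TranscriptModel(tid, f"{t5.gene_id}-{t3.gene_id}", seq, tuple(bounds),
                           is_fusion=True, fusion_meta=meta)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------


def simulate_fragments(transcripts: dict, config: LibraryConfig,
                       rng: np.random.Generator | None = None) -> list:
    """Fragment the ds-cDNA pool.

    Per-transcript fragment counts are multinomial in abundance x length
    (longer molecules shear into proportionally more fragments); fragment
    lengths are log-normal with the configured mean/sd, truncated to the
    transcript; start positions are uniform.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.n_molecules == 0:
        return []
    ids = sorted(t for t in transcripts if config.abundances.get(t, 0) > 0) \
        if config.abundances else sorted(transcripts)
    if not ids:
        return []
    w = np.array([
        (config.abundances.get(t, 1.0) if config.abundances else 1.0)
        * len(transcripts[t].spliced_seq)
        for t in ids
    ], dtype=float)
    counts = rng.multinomial(config.n_molecules, w / w.sum())
    m, s = config.effective_fragment_mean, config.effective_fragment_sd
    sigma = math.sqrt(math.log(1.0 + (s / m) ** 2))
    mu = math.log(m) - sigma ** 2 / 2.0
    fragments = []
    for tid, n in zip(ids, counts):
        if n == 0:
            continue
        L = len(transcripts[tid].spliced_seq)
        lens = np.clip(np.rint(rng.lognormal(mu, sigma, n)).astype(int), 1, L)
        starts = rng.integers(0, L - lens + 1)
        fragments.extend(
            Fragment(tid, int(a), int(a + l)) for a, l in zip(starts, lens)
        )
    return fragments


def _probe_sites(transcripts: dict, panel) -> dict:
    """Locate every exact probe match in every transcript.

    Returns {transcript_id: [(footprint_start, footprint_end, probe_id,
    downstream), ...]} sorted by position.  Downstream sites are sense
    matches of the probe sequence; upstream sites are matches of its
    reverse complement.
    """
    sites: dict[str, list] = {t: [] for t in transcripts}
    pats = [(p.probe_id, p.probe_seq, True) for p in panel.probes]
    pats += [(p.probe_id, revcomp(p.probe_seq), False) for p in panel.probes]
    for tid, t in transcripts.items():
        seq = t.spliced_seq
        for pid, pat, down in pats:
            i = seq.find(pat)
            while i != -1:
                sites[tid].append((i, i + len(pat), pid, down))
                i = seq.find(pat, i + 1)
        sites[tid].sort()
    return sites


def capture_and_extend(fragments, panel, transcripts: dict,
                       rng: np.random.Generator | None = None,
                       seed: int = 0) -> list:
    """Hybridize panel probes to fragments and extend.

    A fragment is captured iff it wholly contains >= 1 exact probe site; one
    eligible probe is chosen uniformly at random.  The captured molecule
    (insert) runs from the probe's 3' end to the fragment's adapter end in
    the extension direction; probes flush with the fragment end (empty
    extension) yield nothing, as unextended probes are washed away.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    sites = _probe_sites(transcripts, panel)
    captured = []
    for frag in fragments:
        elig = [st for st in sites[frag.transcript_id]
                if frag.start <= st[0] and st[1] <= frag.end]
        if not elig:
            continue
        fs, fe, pid, down = elig[int(rng.integers(len(elig)))]
        if down:
            ins = (fe, frag.end)
            orient = "+"
        else:
            ins = (frag.start, fs)
            orient = "-"
        if ins[0] >= ins[1]:
            continue
        t = transcripts[frag.transcript_id]
        spans = bool(
            t.is_fusion
            and ins[0] < t.fusion_meta.junction_pos < ins[1]
        )
        captured.append(CapturedMolecule(
            frag.transcript_id, pid, frag.start, frag.end,
            ins[0], ins[1], orient, spans,
        ))
    return captured


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------


def _encode_read_id(i: int, mol: CapturedMolecule) -> str:
    return (f"sim{i:06d}|{mol.transcript_id}|{mol.probe_id}|"
            f"{mol.frag_start}-{mol.frag_end}|"
            f"{mol.insert_start}-{mol.insert_end}|{mol.orientation}|"
            f"{int(mol.spans_junction)}")


def parse_read_id(read_id: str) -> CapturedMolecule:
    """Inverse of the read-id encoding used by :func:`emit_fastq`."""
    _, tid, pid, frag, ins, orient, spans = read_id.split("|")
    fs, fe = map(int, frag.split("-"))
    is_, ie = map(int, ins.split("-"))
    return CapturedMolecule(tid, pid, fs, fe, is_, ie, orient, bool(int(spans)))


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def _pad(seq: str, n: int) -> str:
    if len(seq) >= n:
        return seq[:n]
    pad = (ADAPTER * (n // len(ADAPTER) + 2))[: n - len(seq)]
    return seq + pad


def emit_fastq(captured, transcripts: dict, config: LibraryConfig,
               r1_path, r2_path, truth_path,
               rng: np.random.Generator | None = None) -> dict:
    """Sequence captured molecules as a read pair per molecule.

    R1 starts at the probe's 3'-end position and reads in the extension
    direction (the probe itself is not sequenced: the sequencing primer
    sits at the tail/insert junction); R2 reads inward from the
    adapter-ligated fragment end.  Inserts shorter than the read length are
    padded with adapter sequence.  Qualities are constant.
    """
    if not captured:
        raise ValueError(
            "no captured molecules to sequence; the panel may not match any "
            "expressed transcript"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rl = config.read_length
    qual = "I" * rl
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2, \
            open(truth_path, "w") as ft:
        ft.write("read_id\ttranscript_id\tprobe_id\tfrag_start\tfrag_end\t"
                 "insert_start\tinsert_end\torientation\tspans_junction\n")
        for i, mol in enumerate(captured):
            t = transcripts[mol.transcript_id]
            insert = t.spliced_seq[mol.insert_start : mol.insert_end]
            if mol.orientation == "-":
                insert = revcomp(insert)
            r1 = _apply_errors(_pad(insert, rl), config.error_rate, rng)
            r2 = _apply_errors(_pad(revcomp(insert), rl), config.error_rate, rng)
            rid = _encode_read_id(i, mol)
            f1.write(f"@{rid}\n{r1}\n+\n{qual}\n")
            f2.write(f"@{rid}\n{r2}\n+\n{qual}\n")
            ft.write(f"{rid}\t{mol.transcript_id}\t{mol.probe_id}\t"
                     f"{mol.frag_start}\t{mol.frag_end}\t{mol.insert_start}\t"
                     f"{mol.insert_end}\t{mol.orientation}\t"
                     f"{int(mol.spans_junction)}\n")
    return {"r1": Path(r1_path), "r2": Path(r2_path), "truth": Path(truth_path)}


def run_library_sim(transcripts: dict, panel, config: LibraryConfig,
                    out_dir) -> dict:
    """Fragment -> capture -> sequence, with per-stage seeds derived from
    ``config.seed`` so stages are independently reproducible."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_frag, s_cap, s_err = ss.spawn(3)
    fragments = simulate_fragments(transcripts, config,
                                   rng=np.random.default_rng(s_frag))
    captured = capture_and_extend(fragments, panel, transcripts,
                                  rng=np.random.default_rng(s_cap))
    paths = emit_fastq(captured, transcripts, config,
                       out / "r1.fastq", out / "r2.fastq", out / "truth.tsv",
                       rng=np.random.default_rng(s_err))
    paths.update(n_fragments=len(fragments), n_captured=len(captured))
    return paths
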