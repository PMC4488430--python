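"""Transcriptome-space read mapping and single-anchor fusion calling.

Reads are aligned to the panel's reference *transcripts* (the assay enriches
cDNA, so transcriptome space is the natural frame) with a k-mer
seed-chain-extend strategy.  A read whose best explanation is a prefix on
one gene plus a suffix on a different gene is a split (chimeric) read; split
reads clustered on a common junction become fusion calls.  Because capture
only needs one probe, a call is legal when just one partner carries panel
probes ("single-partner detection") — the hallmark of the assay.

Breakpoint convention: when the two partners share sequence at the junction
the exact breakpoint is ambiguous over a short homology interval; the
reported breakpoint is the leftmost placement (5'-most on the 5' partner)
and the homology length is reported as ``ambiguity``.

Reads whose flank on one side of a junction is long enough to support a
call (>= min_overhang) but too short to hold a k-mer seed are recovered by
a junction re-alignment pass: the unexplained flank is exact-matched
against each candidate call's reference junction context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree
from pyfaidx import Fasta

from .assay_sim import ADAPTER
from .panel_design import revcomp

__all__ = [
    "CallerParams",
    "ReferenceIndex",
    "AlignSegment",
    "ReadAlignment",
    "FusionCall",
    "build_reference_index",
    "align_reads",
    "align_read_seq",
    "call_fusions",
    "on_target_rate",
    "compare_efficiency",
    "write_fusions_tsv",
]


@dataclass(frozen=True)
class CallerParams:
    """Split-read caller thresholds (this tool's own defaults)."""

    min_overhang: int = 10
    min_supporting_reads: int = 2
    k: int = 21
    max_mismatches_per_segment: int = 2

    def __post_init__(self):
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        if self.k < 11:
            raise ValueError("k must be >= 11")


# ---------------------------------------------------------------------------
# reference index
# ---------------------------------------------------------------------------


class ReferenceIndex:
    """Exact k-mer multimap over a transcript set.

    k-mers occurring in transcripts of more than one gene are flagged
    ambiguous; read-level uniqueness is enforced at classification time.
    """

    def __init__(self, transcripts: dict, tx2gene: dict, k: int = 21):
        self.transcripts = dict(transcripts)
        self.tx2gene = dict(tx2gene)
        self.k = k
        self.kmers: dict[str, list] = {}
        for tid in sorted(self.transcripts):
            seq = self.transcripts[tid]
            for i in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[i : i + k], []).append((tid, i))
        self.ambiguous = {
            km for km, hits in self.kmers.items()
            if len({self.tx2gene[t] for t, _ in hits}) > 1
        }

    def gene(self, tid: str) -> str:
        return self.tx2gene[tid]


def build_reference_index(source, tx2gene: dict | None = None,
                          k: int = 21) -> ReferenceIndex:
    """Build the index from a FASTA path or a {transcript_id: seq} dict.

    For FASTA input the gene is taken from a ``gene=<id>`` token in the
    description, falling back to the transcript id minus a trailing
    ``.<suffix>``.  Duplicate transcript ids are a hard error.
    """
    if isinstance(source, (str, Path)):
        seen: dict[str, str] = {}
        mapping: dict[str, str] = {}
        fa = Fasta(str(source), duplicate_action="first")
        with open(source) as fh:
            n_headers = sum(1 for line in fh if line.startswith(">"))
        if n_headers != len(fa.keys()):
            raise ValueError(f"duplicate transcript_id in {source}")
        for name in fa.keys():
            seen[name] = str(fa[name][:]).upper()
            desc = fa[name].long_name
            gene = None
            for tok in desc.split():
                if tok.startswith("gene="):
                    gene = tok[5:]
            mapping[name] = gene or name.rsplit(".", 1)[0]
        transcripts = seen
        tx2gene = mapping if tx2gene is None else tx2gene
    else:
        transcripts = {k2: v.upper() for k2, v in source.items()}
        if len(transcripts) != len(source):
            raise ValueError("duplicate transcript_id in reference")
        if tx2gene is None:
            tx2gene = {t: t.rsplit(".", 1)[0] for t in transcripts}
    return ReferenceIndex(transcripts, tx2gene, k=k)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignSegment:
    transcript_id: str
    gene_id: str
    tx_start: int
    tx_end: int
    read_start: int
    read_end: int
    mismatches: int

    @property
    def span(self) -> int:
        return self.read_end - self.read_start

    @property
    def score(self) -> int:
        return self.span - 2 * self.mismatches


@dataclass
class ReadAlignment:
    """Alignment of one mate.

    ``segments`` are in oriented-read (transcript-sense) coordinates;
    ``orientation`` says whether the raw read was reverse-complemented to
    reach sense space.  ``status`` is one of single/split/partial/unmapped/
    dropped (dropped = equally good multi-gene placements).
    """

    read_id: str
    mate: str
    status: str
    orientation: str = "+"
    segments: tuple = ()
    trimmed_len: int = 0
    oriented_seq: str = ""
    # split-read details (leftmost-normalized)
    gene5: str | None = None
    gene3: str | None = None
    tx5: str | None = None
    tx3: str | None = None
    breakpoint5: int | None = None
    breakpoint3: int | None = None
    split_read_pos: int | None = None
    ambiguity: int = 0

    @property
    def is_split(self) -> bool:
        return self.status == "split"

    @property
    def unmapped(self) -> bool:
        return self.status in ("unmapped", "dropped", "partial")


def _trim_adapter(seq: str, min_overlap: int = 8) -> str:
    """Remove a trailing run of the constant adapter from a read.

    Padding always begins with the adapter's first bases, so candidate trim
    points are exact hits of its ``min_overlap``-prefix; the remainder of
    the tail may carry ~10% mismatches (sequencing errors).  Requiring
    >= min_overlap adapter bases keeps genuine sequence from being clipped.
    """
    n = len(seq)
    probe = ADAPTER[:min_overlap]
    ref = ADAPTER * (n // len(ADAPTER) + 2)
    i = seq.find(probe)
    while i != -1 and i <= n - min_overlap:
        tail = seq[i:]
        mism = sum(a != b for a, b in zip(tail, ref))
        if mism <= len(tail) // 10:
            return seq[:i]
        i = seq.find(probe, i + 1)
    return seq


def _collect_segments(s: str, index: ReferenceIndex, budget: int,
                      confirm: int = 4) -> list:
    """Maximal exact-seeded, cautiously extended segments of ``s``.

    Hits are grouped per (transcript, diagonal); each group is extended
    base-by-base in both directions.  A mismatch is crossed only when the
    next ``confirm`` bases all match and the mismatch budget allows — this
    absorbs isolated sequencing errors without extending across chance
    junction homology, which keeps split breakpoints stable.
    """
    k = index.k
    groups: dict[tuple, list] = {}
    for i in range(len(s) - k + 1):
        for tid, p in index.kmers.get(s[i : i + k], ()):
            groups.setdefault((tid, p - i), []).append(i)
    segments = []
    for (tid, diag), ipos in groups.items():
        t = index.transcripts[tid]
        rs, re = min(ipos), max(ipos) + k
        mism = sum(s[j] != t[j + diag] for j in range(rs, re))
        if mism > budget:
            continue
        # extend left
        j = rs - 1
        while j >= 0 and j + diag >= 0:
            if s[j] == t[j + diag]:
                rs = j
                j -= 1
                continue
            ok = mism < budget and j - confirm >= 0 and j - confirm + diag >= 0 \
                and all(s[j - c] == t[j - c + diag] for c in range(1, confirm + 1))
            if ok:
                mism += 1
                rs = j
                j -= 1
            else:
                break
        # extend right
        j = re
        L, Lt = len(s), len(t)
        while j < L and j + diag < Lt:
            if s[j] == t[j + diag]:
                re = j + 1
                j += 1
                continue
            ok = mism < budget and j + confirm < L and j + confirm + diag < Lt \
                and all(s[j + c] == t[j + c + diag] for c in range(1, confirm + 1))
            if ok:
                mism += 1
                re = j + 1
                j += 1
            else:
                break
        segments.append(AlignSegment(tid, index.gene(tid), rs + diag, re + diag,
                                     rs, re, mism))
    # drop strictly dominated duplicates (same read interval, same gene)
    best: dict[tuple, AlignSegment] = {}
    for seg in segments:
        key = (seg.gene_id, seg.read_start, seg.read_end, seg.tx_start)
        cur = best.get(key)
        if cur is None or seg.score > cur.score:
            best[key] = seg
    return sorted(best.values(),
                  key=lambda g: (-g.score, g.transcript_id, g.tx_start))


def _classify(s: str, index: ReferenceIndex, params: CallerParams):
    """Classify one oriented sequence: (kind, payload, score)."""
    L = len(s)
    if L < index.k:
        return ("unmapped", None, -1)
    segs = _collect_segments(s, index, params.max_mismatches_per_segment)
    if not segs:
        return ("unmapped", None, -1)

    full = [g for g in segs if g.span >= L - 2]
    if full:
        top = max(g.score for g in full)
        leaders = [g for g in full if g.score == top]
        genes = {g.gene_id for g in leaders}
        if len(genes) > 1:
            return ("dropped", None, top)
        return ("single", leaders[0], top)

    ov = params.min_overhang
    best_pair, best_score, n_best = None, -1, 0
    for a in segs:
        if a.read_start > 2:
            continue
        for b in segs:
            if b.gene_id == a.gene_id or b.read_end < L - 2:
                continue
            p = b.read_start  # leftmost junction placement
            if p < a.read_start or p > a.read_end + 2 or p > b.read_end:
                continue
            covered = a.span + b.span - max(0, a.read_end - b.read_start)
            if covered < L - 2:
                continue
            if p - a.read_start < ov or b.read_end - p < ov:
                continue
            score = a.score + b.score
            if score > best_score:
                best_pair, best_score, n_best = (a, b), score, 1
            elif score == best_score and best_pair is not None:
                if (a.gene_id, b.gene_id, p) != (
                    best_pair[0].gene_id, best_pair[1].gene_id,
                    best_pair[1].read_start,
                ):
                    n_best += 1
    if best_pair is not None:
        if n_best > 1:
            return ("dropped", None, best_score)
        return ("split", best_pair, best_score)

    # best partial segment, kept for the junction-rescue pass
    return ("partial", segs[0], segs[0].score)


def align_read_seq(read_id: str, mate: str, seq: str, index: ReferenceIndex,
                   params: CallerParams) -> ReadAlignment:
    """Align one read (both orientations tried; the better one kept)."""
    seq = seq.upper()
    trimmed = _trim_adapter(seq)
    cands = []
    for orient, s in (("+", trimmed), ("-", revcomp(trimmed))):
        kind, payload, score = _classify(s, index, params)
        cands.append((score, orient, s, kind, payload))
    cands.sort(key=lambda c: (-c[0], c[1]))
    score, orient, s, kind, payload = cands[0]
    aln = ReadAlignment(read_id, mate, kind, orient, trimmed_len=len(s),
                        oriented_seq=s)
    if kind == "single":
        aln.segments = (payload,)
    elif kind == "partial":
        aln.segments = (payload,)
    elif kind == "split":
        a, b = payload
        p = b.read_start
        aln.segments = (a, b)
        aln.gene5, aln.gene3 = a.gene_id, b.gene_id
        aln.tx5, aln.tx3 = a.transcript_id, b.transcript_id
        aln.breakpoint5 = a.tx_start + (p - a.read_start)
        aln.breakpoint3 = b.tx_start
        aln.split_read_pos = p
        aln.ambiguity = max(0, a.read_end - b.read_start)
    return aln


def _read_fastq(path):
    """Yield (read_id, seq); malformed records raise with a line number."""
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(f"{path}:{lineno}: expected '@' header")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ValueError(f"{path}:{lineno + 2}: expected '+' separator")
            if len(qual) != len(seq):
                raise ValueError(
                    f"{path}:{lineno + 3}: quality length != sequence length"
                )
            lineno += 3
            rid = header[1:].split()[0]
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            yield rid, seq


def align_reads(fastq1, fastq2, index: ReferenceIndex,
                params: CallerParams | None = None) -> list:
    """Align a FASTQ pair (R2 optional) to the reference index."""
    params = params or CallerParams()
    out = []
    for rid, seq in _read_fastq(fastq1):
        out.append(align_read_seq(rid, "R1", seq, index, params))
    if fastq2 is not None:
        for rid, seq in _read_fastq(fastq2):
            out.append(align_read_seq(rid, "R2", seq, index, params))
    return out


# ---------------------------------------------------------------------------
# fusion calling
# ---------------------------------------------------------------------------


@dataclass
class FusionCall:
    gene5_id: str
    gene3_id: str
    transcript5_id: str
    transcript3_id: str
    breakpoint5: int
    breakpoint3: int
    supporting_reads: int
    spanning_pairs: int
    partners_in_panel: str  # {"both", "five_only", "three_only"}
    junction_seq: str  # 25 nt of 5' context '|' 25 nt of 3' context
    ambiguity: int
    genomic5: tuple | None = None  # (chrom, pos) of last 5'-partner base
    genomic3: tuple | None = None  # (chrom, pos) of first 3'-partner base


def _rescue(aln: ReadAlignment, cluster_key, index: ReferenceIndex,
            params: CallerParams) -> bool:
    """Does a partially aligned read support this junction?

    The read must carry one confident segment on one partner plus an
    unexplained flank of >= min_overhang bases that exactly matches the
    other partner's reference context at the cluster's junction.
    """
    tx5, tx3, bp5, bp3 = cluster_key
    if not aln.segments:
        return False
    seg = aln.segments[0]
    s, L, ov = aln.oriented_seq, aln.trimmed_len, params.min_overhang
    t5, t3 = index.transcripts[tx5], index.transcripts[tx3]
    if seg.transcript_id == tx3:
        # suffix anchored on the 3' partner; left flank must match 5' context
        fl = seg.read_start
        if (seg.tx_start == bp3 and seg.read_end >= L - 2 and fl >= ov
                and seg.span >= ov and fl <= bp5
                and s[:fl] == t5[bp5 - fl : bp5]):
            return True
    if seg.transcript_id == tx5:
        # prefix anchored on the 5' partner; right flank must match 3' context
        p = seg.read_start + (bp5 - seg.tx_start)
        fl = L - p
        if (seg.read_start <= 2 and 0 <= p <= seg.read_end and fl >= ov
                and p - seg.read_start >= ov and fl <= len(t3) - bp3
                and s[p:] == t3[bp3 : bp3 + fl]):
            return True
    return False


def call_fusions(alignments, panel, params: CallerParams | None = None,
                 index: ReferenceIndex | None = None,
                 layouts: dict | None = None) -> list:
    """Cluster split reads into fusion calls.

    Clusters need >= min_supporting_reads and at least one partner with
    probes in the panel; self- and read-through-style same-gene junctions
    are excluded.  Output is sorted by supporting reads, descending.
    """
    params = params or CallerParams()
    targeted = panel.targeted_genes if panel is not None else frozenset()

    clusters: dict[tuple, dict] = {}
    for aln in alignments:
        if not aln.is_split or aln.gene5 == aln.gene3:
            continue
        key = (aln.tx5, aln.tx3, aln.breakpoint5, aln.breakpoint3)
        c = clusters.setdefault(key, {"reads": [], "ambiguity": 0})
        c["reads"].append(aln)
        c["ambiguity"] = max(c["ambiguity"], aln.ambiguity)

    # merge clusters of the same gene pair whose breakpoints differ by no
    # more than the junction homology (plus slack for edge effects)
    merged: dict[tuple, dict] = {}
    for key in sorted(clusters, key=lambda k: (k[0], k[1], k[2], k[3])):
        c = clusters[key]
        placed = False
        for mkey, mc in merged.items():
            if mkey[0] == key[0] and mkey[1] == key[1]:
                tol = max(mc["ambiguity"], c["ambiguity"]) + 2
                if abs(mkey[2] - key[2]) <= tol and abs(mkey[3] - key[3]) <= tol:
                    mc["reads"].extend(c["reads"])
                    mc["ambiguity"] = max(mc["ambiguity"], c["ambiguity"])
                    placed = True
                    break
        if not placed:
            merged[key] = dict(c)

    # representative breakpoint = modal placement among member reads
    voted: dict[tuple, dict] = {}
    for key, c in merged.items():
        counts: dict[tuple, int] = {}
        for aln in c["reads"]:
            k2 = (aln.tx5, aln.tx3, aln.breakpoint5, aln.breakpoint3)
            counts[k2] = counts.get(k2, 0) + 1
        rep = min(counts, key=lambda k2: (-counts[k2], k2[2], k2[3]))
        voted[rep] = c
    merged = voted

    if index is not None:
        partials = [a for a in alignments if a.status == "partial"]
        claimed: set[int] = set()
        for key in sorted(merged):
            c = merged[key]
            for aln in partials:
                if id(aln) in claimed:
                    continue
                if _rescue(aln, key, index, params):
                    c["reads"].append(aln)
                    claimed.add(id(aln))

    # spanning pairs: both mates single-mapped, one per partner
    singles: dict[tuple, str] = {}
    for aln in alignments:
        if aln.status == "single":
            singles[(aln.read_id, aln.mate)] = aln.segments[0].gene_id
    pair_genes: dict[str, set] = {}
    for (rid, _), gene in singles.items():
        pair_genes.setdefault(rid, set()).add(gene)

    calls = []
    for (tx5, tx3, bp5, bp3), c in merged.items():
        support = len(c["reads"])
        if support < params.min_supporting_reads:
            continue
        gene5 = c["reads"][0].gene5 or (index.gene(tx5) if index else tx5)
        gene3 = c["reads"][0].gene3 or (index.gene(tx3) if index else tx3)
        in5, in3 = gene5 in targeted, gene3 in targeted
        if not (in5 or in3):
            continue
        partners = "both" if (in5 and in3) else ("five_only" if in5 else "three_only")
        junction_seq = ""
        if index is not None:
            t5s, t3s = index.transcripts[tx5], index.transcripts[tx3]
            junction_seq = (t5s[max(0, bp5 - 25) : bp5] + "|"
                            + t3s[bp3 : bp3 + 25])
        spanning = sum(
            1 for genes in pair_genes.values() if genes == {gene5, gene3}
        )
        g5 = g3 = None
        if layouts and tx5 in layouts and tx3 in layouts:
            l5, l3 = layouts[tx5], layouts[tx3]
            g5 = (l5.chrom, l5.genomic_point(bp5 - 1)) if bp5 >= 1 else None
            g3 = (l3.chrom, l3.genomic_point(bp3)) if bp3 < l3.length else None
        calls.append(FusionCall(
            gene5, gene3, tx5, tx3, bp5, bp3, support, spanning, partners,
            junction_seq, c["ambiguity"], g5, g3,
        ))
    calls.sort(key=lambda f: (-f.supporting_reads, f.gene5_id, f.gene3_id))
    return calls


def write_fusions_tsv(calls, path, params: CallerParams | None = None):
    params = params or CallerParams()
    cols = ["gene5_id", "gene3_id", "transcript5_id", "transcript3_id",
            "breakpoint5", "breakpoint3", "genomic5", "genomic3",
            "supporting_reads", "spanning_pairs", "partners_in_panel",
            "ambiguity", "junction_seq"]
    with open(path, "w") as fh:
        fh.write(f"#caller_params\tmin_overhang={params.min_overhang}\t"
                 f"min_supporting_reads={params.min_supporting_reads}\t"
                 f"k={params.k}\t"
                 f"max_mismatches_per_segment={params.max_mismatches_per_segment}\n")
        fh.write("\t".join(cols) + "\n")
        for f in calls:
            g5 = f"{f.genomic5[0]}:{f.genomic5[1]}" if f.genomic5 else "."
            g3 = f"{f.genomic3[0]}:{f.genomic3[1]}" if f.genomic3 else "."
            fh.write("\t".join(map(str, [
                f.gene5_id, f.gene3_id, f.transcript5_id, f.transcript3_id,
                f.breakpoint5, f.breakpoint3, g5, g3, f.supporting_reads,
                f.spanning_pairs, f.partners_in_panel, f.ambiguity,
                f.junction_seq,
            ])) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def on_target_rate(alignments, panel, layouts: dict):
    """Mapped and on-target fractions over R1 (forward) reads.

    A read is on-target when any aligned segment, projected to the genome
    through the transcript layouts, overlaps a panel target interval by at
    least one base.  Returns ``(mapped_fraction, on_target_fraction)``;
    with zero mapped reads the on-target fraction is NaN.
    """
    r1 = [a for a in alignments if a.mate == "R1"]
    if not r1:
        raise ValueError("no reads supplied")
    trees: dict[str, IntervalTree] = {}
    for ivs in panel.target_intervals.values():
        for chrom, s, e in ivs:
            trees.setdefault(chrom, IntervalTree()).addi(s, e)
    mapped = on = 0
    for aln in r1:
        if aln.unmapped:
            continue
        mapped += 1
        hit = False
        for seg in aln.segments:
            layout = layouts.get(seg.transcript_id)
            if layout is None:
                continue
            for chrom, s, e in layout.genomic_intervals(seg.tx_start, seg.tx_end):
                if chrom in trees and trees[chrom].overlap(s, e):
                    hit = True
                    break
            if hit:
                break
        if hit:
            on += 1
    mapped_fraction = mapped / len(r1)
    on_target_fraction = on / mapped if mapped else math.nan
    return mapped_fraction, on_target_fraction


def compare_efficiency(fusion_reads_targeted, total_reads_targeted,
                       fusion_reads_untargeted, total_reads_untargeted) -> dict:
    """Sequencing-depth economy of the targeted assay vs standard RNA-seq.

    ``percent_of_reads`` is the targeted total as a percentage of the
    untargeted total (1 decimal); ``fold_reduction`` is the untargeted /
    targeted depth ratio (nearest integer).
    """
    if total_reads_untargeted <= 0:
        raise ValueError("untargeted read total must be positive")
    if total_reads_targeted <= 0:
        raise ValueError("targeted read total must be positive")
    return {
        "percent_of_reads": round(
            100.0 * total_reads_targeted / total_reads_untargeted, 1
        ),
        "fold_reduction": int(round(total_reads_untargeted / total_reads_targeted)),
        "fusion_reads_targeted": fusion_reads_targeted,
        "fusion_reads_untargeted": fusion_reads_untargeted,
    }
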