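"""Independent oracles and small builders shared across the test suite.

Everything here is computed from first principles (string comparison,
direct enumeration, the truth TSV) and never calls into the aligner or
caller it is used to check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from spetseq.assay_sim import TranscriptModel, build_fusion_transcript
from spetseq.cli_workflow import RunConfig
from spetseq.panel_design import ExonRecord, TranscriptLayout, parse_annotation

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng, n):
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


def single_exon_layout(length, seed, gene_id="gX", chrom="chrT", offset=1000,
                       strand="+"):
    """A one-exon gene with random sequence, for designer unit tests."""
    rng = np.random.default_rng(seed)
    exon = ExonRecord(gene_id, f"{gene_id}.t1", 1, chrom, offset,
                      offset + length, strand)
    return exon, TranscriptLayout(f"{gene_id}.t1", gene_id, chrom, strand,
                                  (exon,), random_seq(rng, length))


def leftmost_junction(fused_seq, junction, t3_seq, bstart):
    """Leftmost-equivalent placement of a fusion junction.

    Walks left from the breakpoint while the fused sequence equals the 3'
    partner's upstream context (junction homology); returns (J*, homology).
    """
    hb = 0
    while (junction - hb - 1 >= 0 and bstart - hb - 1 >= 0
           and fused_seq[junction - hb - 1] == t3_seq[bstart - hb - 1]):
        hb += 1
    return junction - hb, hb


def read_coverage(row, read_length):
    """Transcript intervals covered by R1 and R2 of one truth record."""
    is_, ie = row.insert_start, row.insert_end
    near = (is_, min(ie, is_ + read_length))
    far = (max(is_, ie - read_length), ie)
    return [near, far] if row.orientation == "+" else [far, near]


def truth_junction_count(truth_tsv, fusion_tid, jstar, read_length, min_overhang):
    """Reads (mates counted separately) covering >= min_overhang on both
    sides of the leftmost-normalized junction, straight from the truth TSV."""
    df = pd.read_csv(truth_tsv, sep="\t")
    n = 0
    for row in df.itertuples():
        if row.transcript_id != fusion_tid:
            continue
        for c0, c1 in read_coverage(row, read_length):
            if c0 <= jstar - min_overhang and c1 >= jstar + min_overhang:
                n += 1
    return n


def fusion_geometry(run_dir):
    """Reconstruct the planted fusion of a run from its config + genome.

    Returns dicts of the fused transcript, the raw junction, its leftmost
    placement, and the leftmost breakpoints on each partner transcript.
    """
    import yaml

    with open(run_dir / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    bundle = parse_annotation(run_dir / "genome/genes.gtf",
                              run_dir / "genome/genome.fa")
    out = []
    for spec in cfg["fusions"]:
        t5 = TranscriptModel.from_layout(bundle.layouts[f"{spec['gene5']}.t1"])
        t3 = TranscriptModel.from_layout(bundle.layouts[f"{spec['gene3']}.t1"])
        fus = build_fusion_transcript(t5, spec["exon5"], t3, spec["exon3"])
        J = fus.fusion_meta.junction_pos
        bstart = t3.exon_boundaries[spec["exon3"] - 2] if spec["exon3"] > 1 else 0
        jstar, hb = leftmost_junction(fus.spliced_seq, J, t3.spliced_seq, bstart)
        out.append({
            "fusion": fus, "t5": t5, "t3": t3,
            "junction": J, "jstar": jstar, "homology": hb,
            "bp5_leftmost": J - hb, "bp3_leftmost": bstart - hb,
        })
    return out


def small_run_config(out_dir, seed, n_molecules=2500, error_rate=0.0,
                     **overrides):
    """Compact end-to-end run used by the seeded caller suites."""
    cfg = RunConfig.demo(out_dir=str(out_dir), seed=seed)
    cfg.library = dataclasses.replace(cfg.library, n_molecules=n_molecules,
                                      error_rate=error_rate)
    cfg.log_level = "WARNING"
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def parse_fusions_tsv(path):
    rows = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(dict(zip(header, line.split("\t"))))
    return rows
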