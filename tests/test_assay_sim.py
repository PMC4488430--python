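"""Simulator: fixture genome, fusion construction, fragmentation, capture,
and FASTQ emission with ground truth."""

import math

import numpy as np
import pytest

from spetseq.assay_sim import (
    LibraryConfig,
    TranscriptModel,
    build_fusion_transcript,
    capture_and_extend,
    emit_fastq,
    generate_synthetic_genome,
    parse_read_id,
    run_library_sim,
    simulate_fragments,
)
from spetseq.panel_design import (
    PanelDesignParams,
    design_panel,
    parse_annotation,
    revcomp,
)

from oracles import random_seq


# ---------------------------------------------------------------------------
# synthetic genome fixture generator
# ---------------------------------------------------------------------------


def test_genome_generator_is_seed_reproducible(tmp_path):
    a = generate_synthetic_genome(5, 4, (100, 200), (100, 500), seed=1,
                                  out_dir=tmp_path / "a")
    b = generate_synthetic_genome(5, 4, (100, 200), (100, 500), seed=1,
                                  out_dir=tmp_path / "b")
    for pa, pb in zip(a, b):
        assert pa.read_bytes() == pb.read_bytes()
    c = generate_synthetic_genome(5, 4, (100, 200), (100, 500), seed=2,
                                  out_dir=tmp_path / "c")
    assert a[0].read_bytes() != c[0].read_bytes()


def test_generated_annotation_parses_cleanly(tmp_path):
    fa, gtf = generate_synthetic_genome(5, 4, (100, 200), (100, 500), seed=1,
                                        out_dir=tmp_path)
    bundle = parse_annotation(gtf, fa)
    assert bundle.warnings == []
    assert len(bundle.layouts) == 5
    # spliced transcript length equals the exon total recomputed from the GTF
    exon_lens = {}
    for line in open(gtf):
        f = line.split("\t")
        if f[2] != "exon":
            continue
        tid = line.split('transcript_id "')[1].split('"')[0]
        exon_lens[tid] = exon_lens.get(tid, 0) + int(f[4]) - int(f[3]) + 1
    for tid, layout in bundle.layouts.items():
        assert len(layout.spliced_seq) == exon_lens[tid]


def test_generator_rejects_bad_geometry(tmp_path):
    with pytest.raises(ValueError):
        generate_synthetic_genome(0, 4, (100, 200), (100, 500), out_dir=tmp_path)


# ---------------------------------------------------------------------------
# fusion transcripts
# ---------------------------------------------------------------------------


def _mk_tx(tid, gid, seq, exon_len):
    bounds = tuple(range(exon_len, len(seq) + 1, exon_len))
    return TranscriptModel(tid, gid, seq, bounds)


def test_fusion_concatenation_arithmetic():
    rng = np.random.default_rng(0)
    tA = _mk_tx("a.t1", "a", random_seq(rng, 300), 100)  # 3 exons of 100
    tB = _mk_tx("b.t1", "b", random_seq(rng, 250), 50)  # 5 exons of 50
    fus = build_fusion_transcript(tA, 2, tB, 1)
    assert fus.fusion_meta.junction_pos == 200
    assert len(fus.spliced_seq) == 200 + 250
    assert fus.spliced_seq == tA.spliced_seq[:200] + tB.spliced_seq
    assert fus.is_fusion and fus.fusion_meta.in_frame is None
    with pytest.raises(ValueError):
        build_fusion_transcript(tA, 4, tB, 1)


def test_self_fusion_at_own_boundary_is_identity():
    rng = np.random.default_rng(1)
    t = _mk_tx("a.t1", "a", random_seq(rng, 300), 100)
    fus = build_fusion_transcript(t, 2, t, 3)
    assert fus.spliced_seq == t.spliced_seq
    assert fus.exon_boundaries == t.exon_boundaries


def test_junction_kmer_absent_from_parents():
    """The 20-mer centred on the junction of two random parents occurs in
    neither parent — it is unique evidence of the fusion."""
    rng = np.random.default_rng(2)
    tA = _mk_tx("a.t1", "a", random_seq(rng, 400), 200)
    tB = _mk_tx("b.t1", "b", random_seq(rng, 400), 200)
    fus = build_fusion_transcript(tA, 1, tB, 2)
    J = fus.fusion_meta.junction_pos
    kmer = fus.spliced_seq[J - 10 : J + 10]
    assert kmer not in tA.spliced_seq
    assert kmer not in tB.spliced_seq


def test_in_frame_computed_from_cds_metadata():
    rng = np.random.default_rng(3)
    tA = _mk_tx("a.t1", "a", random_seq(rng, 300), 100)
    tB = _mk_tx("b.t1", "b", random_seq(rng, 300), 100)
    tA.cds_start, tB.cds_start = 0, 0
    # prefix 200 nt vs 3'-suffix offset 100 nt: 200 % 3 != 100 % 3
    fus = build_fusion_transcript(tA, 2, tB, 2)
    assert fus.fusion_meta.in_frame is False
    tB.cds_start = 2  # shifts the 3' frame so (100 - 2) % 3 == 200 % 3
    assert build_fusion_transcript(tA, 2, tB, 2).fusion_meta.in_frame is True


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------


def test_fragment_counts_follow_abundance(tmp_path):
    rng = np.random.default_rng(4)
    txs = {
        "a.t1": _mk_tx("a.t1", "a", random_seq(rng, 1000), 500),
        "b.t1": _mk_tx("b.t1", "b", random_seq(rng, 1000), 500),
    }
    cfg = LibraryConfig(n_molecules=40000, abundances={"a.t1": 1, "b.t1": 3},
                        seed=10)
    frags = simulate_fragments(txs, cfg)
    assert len(frags) == 40000
    n_a = sum(1 for f in frags if f.transcript_id == "a.t1")
    # binomial oracle: n_a ~ B(40000, 0.25)
    sd = math.sqrt(40000 * 0.25 * 0.75)
    assert abs(n_a - 10000) <= 3 * sd
    for f in frags:
        assert 0 <= f.start < f.end <= 1000


def test_ffpe_mode_shortens_fragments():
    rng = np.random.default_rng(5)
    txs = {"a.t1": _mk_tx("a.t1", "a", random_seq(rng, 3000), 1500)}
    fresh = simulate_fragments(txs, LibraryConfig(n_molecules=5000, seed=1))
    ffpe = simulate_fragments(txs, LibraryConfig(n_molecules=5000, seed=1,
                                                 ffpe_mode=True))
    mean = lambda fr: np.mean([f.end - f.start for f in fr])  # noqa: E731
    assert mean(ffpe) < mean(fresh)


def test_zero_molecules_yield_no_fragments():
    txs = {"a.t1": _mk_tx("a.t1", "a", "ACGT" * 100, 400)}
    assert simulate_fragments(txs, LibraryConfig(n_molecules=0)) == []


# ---------------------------------------------------------------------------
# capture and sequencing
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def capture_setup(tmp_path_factory):
    """Two targeted genes + one untargeted, plus a fusion whose 3' partner
    is the untargeted gene."""
    d = tmp_path_factory.mktemp("cap")
    fa, gtf = generate_synthetic_genome(3, 3, (150, 200), (100, 300), seed=9,
                                        out_dir=d)
    bundle = parse_annotation(gtf, fa)
    targeted = [e for e in bundle.exons if e.gene_id in ("g001", "g002")]
    panel = design_panel(targeted, bundle.layouts, PanelDesignParams())
    txs = {t: TranscriptModel.from_layout(l) for t, l in bundle.layouts.items()}
    fus = build_fusion_transcript(txs["g001.t1"], 2, txs["g003.t1"], 2)
    txs[fus.transcript_id] = fus
    return panel, txs, fus


def test_capture_requires_full_probe_footprint(capture_setup):
    from spetseq.assay_sim import Fragment

    panel, txs, _ = capture_setup
    probe = next(p for p in panel.probes
                 if p.gene_id == "g001" and p.cdna_strand == "antisense"
                 and p.origin == "boundary_3prime" and p.exon_index == 1)
    solo = type(panel)(probes=[probe], targeted_genes=frozenset({"g001"}),
                       target_intervals=panel.target_intervals,
                       design_params=panel.design_params, stats=panel.stats)
    tx = txs["g001.t1"]
    a = probe.anchor_pos  # downstream probe: footprint [a-40, a)
    containing = Fragment("g001.t1", a - 45, min(len(tx.spliced_seq), a + 60))
    clipped = Fragment("g001.t1", a - 20, min(len(tx.spliced_seq), a + 60))
    got = capture_and_extend([containing, clipped], solo, txs, seed=0)
    assert [m.frag_start for m in got] == [a - 45]  # clipped never captured
    mol = got[0]
    assert mol.orientation == "+"
    assert mol.insert_start == a  # extension starts at the probe 3' end
    assert mol.insert_end == containing.end  # ...and runs to the adapter end


def test_untargeted_gene_is_never_captured(capture_setup):
    panel, txs, _ = capture_setup
    cfg = LibraryConfig(n_molecules=3000, abundances={"g003.t1": 1}, seed=2)
    frags = simulate_fragments(txs, cfg)
    assert capture_and_extend(frags, panel, txs, seed=0) == []


def test_single_probe_capture_reads_into_untargeted_partner(capture_setup):
    """A probe on the targeted 5' partner, anchored upstream of the fusion
    junction, captures molecules that extend into the untargeted partner."""
    panel, txs, fus = capture_setup
    J = fus.fusion_meta.junction_pos
    cfg = LibraryConfig(n_molecules=4000,
                        abundances={fus.transcript_id: 1}, seed=3)
    frags = simulate_fragments(txs, cfg)
    captured = capture_and_extend(frags, panel, txs, seed=0)
    assert captured  # single-partner capture happens at all
    crossing = [m for m in captured
                if m.orientation == "+" and m.insert_start < J < m.insert_end]
    assert crossing  # extension products contain 3'-partner sequence
    assert all(m.spans_junction for m in crossing)


def test_zero_error_reads_are_exact_substrings(capture_setup, tmp_path):
    panel, txs, fus = capture_setup
    cfg = LibraryConfig(n_molecules=2000, error_rate=0.0, seed=4,
                        abundances={"g001.t1": 1, "g002.t1": 1})
    frags = simulate_fragments(txs, cfg)
    captured = capture_and_extend(frags, panel, txs, seed=1)
    emit_fastq(captured, txs, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq",
               tmp_path / "t.tsv", rng=np.random.default_rng(0))
    n = 0
    for rec in _fastq_records(tmp_path / "r1.fq"):
        rid, seq = rec
        mol = parse_read_id(rid)
        t = txs[mol.transcript_id]
        insert = t.spliced_seq[mol.insert_start : mol.insert_end]
        if mol.orientation == "-":
            insert = revcomp(insert)
        body = seq[: len(insert)]
        assert insert.startswith(body)
        n += 1
    assert n == len(captured)


def _fastq_records(path):
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                return
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline().strip()
            assert h.startswith("@") and plus.startswith("+")
            assert len(qual) == len(seq)
            yield h[1:].strip(), seq


def test_error_rate_matches_binomial_expectation(tmp_path):
    rng = np.random.default_rng(6)
    tx = _mk_tx("a.t1", "a", random_seq(rng, 5000), 2500)
    txs = {"a.t1": tx}
    from spetseq.assay_sim import CapturedMolecule
    rl, p, n = 100, 0.01, 10000
    captured = [CapturedMolecule("a.t1", "p0", 0, 200, 50, 200, "+", False)
                for _ in range(n)]
    cfg = LibraryConfig(read_length=rl, error_rate=p)
    emit_fastq(captured, txs, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq",
               tmp_path / "t.tsv", rng=np.random.default_rng(7))
    truth = tx.spliced_seq[50 : 50 + rl]
    total_mm = sum(
        sum(a != b for a, b in zip(seq, truth))
        for _, seq in _fastq_records(tmp_path / "r1.fq")
    )
    mean_mm = total_mm / n
    tol = 3 * math.sqrt(rl * p * (1 - p) / n)
    assert abs(mean_mm - rl * p) <= tol


def test_truth_round_trips_and_conserves_reads(capture_setup, tmp_path):
    panel, txs, _ = capture_setup
    cfg = LibraryConfig(n_molecules=1500, seed=8)
    out = run_library_sim(txs, panel, cfg, tmp_path)
    r1_ids = [rid for rid, _ in _fastq_records(out["r1"])]
    truth_lines = open(out["truth"]).read().splitlines()[1:]
    assert len(r1_ids) == len(truth_lines) == out["n_captured"]
    assert len(set(r1_ids)) == len(r1_ids)
    for rid, line in zip(r1_ids, truth_lines):
        mol = parse_read_id(rid)
        f = line.split("\t")
        assert f[0] == rid and f[1] == mol.transcript_id
        assert (int(f[3]), int(f[4])) == (mol.frag_start, mol.frag_end)
        assert (int(f[5]), int(f[6])) == (mol.insert_start, mol.insert_end)


def test_library_sim_is_seed_deterministic(capture_setup, tmp_path):
    panel, txs, _ = capture_setup
    cfg = LibraryConfig(n_molecules=1000, seed=12, error_rate=0.01)
    a = run_library_sim(txs, panel, cfg, tmp_path / "a")
    b = run_library_sim(txs, panel, cfg, tmp_path / "b")
    assert a["r1"].read_bytes() == b["r1"].read_bytes()
    assert a["r2"].read_bytes() == b["r2"].read_bytes()


def test_emit_fastq_refuses_empty_capture(tmp_path):
    with pytest.raises(ValueError, match="captured"):
        emit_fastq([], {}, LibraryConfig(), tmp_path / "a", tmp_path / "b",
                   tmp_path / "c")
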