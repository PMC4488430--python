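import textwrap

import pytest

from spetseq.cli_workflow import run_end_to_end

from oracles import small_run_config


@pytest.fixture(scope="session")
def toy_reference(tmp_path_factory):
    """A 300-nt hand-built genome with one gene per strand.

    The plus gene has exons [0,100) and [200,300); the minus gene uses the
    same intervals, so its transcript is the reverse complement of the plus
    transcript's splice and its exon 1 is the genomic [200,300) interval.
    """
    d = tmp_path_factory.mktemp("toy")
    seq = ("ACGT" * 75)[:300]
    # make the two exons distinguishable
    seq = seq[:100] + "T" * 100 + seq[200:]
    fa = d / "toy.fa"
    fa.write_text(">chrT\n" + "\n".join(seq[i : i + 60]
                                        for i in range(0, 300, 60)) + "\n")
    gtf = d / "toy.gtf"
    lines = []
    for gid, strand in (("plusg", "+"), ("minusg", "-")):
        attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
        for s, e in ((1, 100), (201, 300)):  # 1-based inclusive
            lines.append(f"chrT\ttoy\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}")
    gtf.write_text("\n".join(lines) + "\n")
    return {"fasta": fa, "gtf": gtf, "seq": seq}


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """The bundled demo: 5 genes, one planted g001->g002 fusion, both
    partners targeted, 20,000 molecules, low sequencing error."""
    d = tmp_path_factory.mktemp("demo_run")
    cfg = small_run_config(d / "run", seed=1, n_molecules=20000,
                           error_rate=0.002)
    run_dir = run_end_to_end(cfg)
    return run_dir, cfg


@pytest.fixture(scope="session")
def single_partner_run(tmp_path_factory):
    """Same demo geometry but the 3' partner (g002) carries no probes."""
    d = tmp_path_factory.mktemp("fo_run")
    cfg = small_run_config(d / "run", seed=1, n_molecules=20000,
                           error_rate=0.0,
                           target_genes=["g001", "g003", "g004", "g005"])
    run_dir = run_end_to_end(cfg)
    return run_dir, cfg
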