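import numpy as np
import pytest

from probesieve.genome_io import GeneModel, ProbeRecord, build_gene_model
from probesieve.pipeline import run_pipeline
from probesieve.config import RunConfig
from probesieve.simulate import FixtureSpec, make_fixture

FIXTURE_SEED = 1


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def make_gene(seq_parts, strand="+", contig_pad=50, cds_id="gene1", est=()):
    """Build a plus-strand contig from alternating exon/intron parts.

    ``seq_parts`` is a list of (kind, sequence) with kind in {exon, intron};
    the gene is embedded with ``contig_pad`` random-free padding ('T' runs)
    on both sides.  For minus strand the contig is reverse-complemented so
    the returned model still describes the same coding-strand gene.
    """
    contig = "T" * contig_pad
    exons_contig = []
    for kind, part in seq_parts:
        start = len(contig) + 1
        contig += part
        if kind == "exon":
            exons_contig.append((start, start + len(part) - 1))
    contig += "T" * contig_pad
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        L = len(contig)
        mirrored = [(L - e + 1, L - s + 1) for s, e in reversed(exons_contig)]
        contig = contig.translate(comp)[::-1]
        exons_contig = mirrored
    return build_gene_model(cds_id, "chr1", strand, contig, exons_contig, est), contig


@pytest.fixture(scope="session")
def fixture200():
    """The 200-gene synthetic study used by recovery/determinism checks."""
    return make_fixture(FixtureSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def pipeline_runs(fixture200, tmp_path_factory):
    """Two complete pipeline runs on identical inputs (for determinism)."""
    base = tmp_path_factory.mktemp("pipeline")
    fixture200.write(base / "fixture")
    cfg = RunConfig(
        genome=str(base / "fixture/genome.fasta"),
        annotation=str(base / "fixture/genes.gff3"),
        est=str(base / "fixture/est_confirmations.tsv"),
        probes=str(base / "fixture/probes.tsv"),
        intensities=str(base / "fixture/intensities.tsv"),
    )
    summaries = [run_pipeline(cfg, base / run) for run in ("run1", "run2")]
    return base, summaries
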