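"""Shared fixtures: small simulated datasets and constructed references."""

import numpy as np
import pytest

from transquant.riboseq import ReferenceSet, Transcript
from transquant.simulate import RiboSimConfig, gen_riboseq


@pytest.fixture(scope="session")
def small_ribo(tmp_path_factory):
    """Null-preset Ribo-Seq simulation at reduced depth (shared, read-only)."""
    out_dir = tmp_path_factory.mktemp("ribo_null")
    config = RiboSimConfig(n_human_genes=60, n_yeast_genes=10,
                           n_footprint_reads=30_000, n_input_reads=30_000,
                           seed=7)
    out = gen_riboseq(config, out_dir)
    refs = ReferenceSet.from_files(out.reference_fasta, out.annotation,
                                   out.top_genes, out.ires_genes,
                                   out.mito_rp_genes)
    return config, out, refs


@pytest.fixture()
def toy_references():
    """Hand-built reference set exercising the classification hierarchy.

    The rRNA contains an exact copy of a CDS segment of geneA's transcript,
    so a read from that segment hits both and must be classed rRNA.
    """
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))

    def seq(n, s):
        return "".join(bases[np.random.default_rng(s).integers(0, 4, n)])

    tx_a = seq(300, 1)
    tx_a2 = tx_a[:250] + seq(80, 2)      # second isoform of geneA
    tx_b = seq(300, 3)
    shared = tx_a[60:100]                # inside geneA CDS
    rrna = seq(100, 4) + shared + seq(100, 5)
    trna = seq(72, 6)
    yeast = seq(280, 8)
    transcripts = {
        "TXA1": Transcript("TXA1", tx_a, "human", "mRNA", "geneA", 50, 260),
        "TXA2": Transcript("TXA2", tx_a2, "human", "mRNA", "geneA", 50, 230),
        "TXB": Transcript("TXB", tx_b, "human", "mRNA", "geneB", 40, 250),
        "RR1": Transcript("RR1", rrna, "human", "rRNA", "RR1"),
        "TR1": Transcript("TR1", trna, "human", "tRNA", "TR1"),
        "TXY": Transcript("TXY", yeast, "yeast", "mRNA", "geneY", 30, 240),
    }
    return ReferenceSet(transcripts, top_genes={"geneA"},
                        ires_genes={"geneA", "geneB"})
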