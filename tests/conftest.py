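import pytest

from pseudoexon.coordinates import GeneModel
from pseudoexon.splice import default_splice_model


@pytest.fixture(scope="session")
def splice_model():
    return default_splice_model()


@pytest.fixture()
def toy_gene():
    """Two-exon plus-strand gene: exon1 = genomic 101-200 (c.1-100),
    exon2 = 301-400 (c.101-200); intron length 100."""
    return GeneModel("TOY", "chrT", "+", [(101, 200), (301, 400)])


@pytest.fixture()
def toy_gene_minus():
    """The toy gene mirrored onto the minus strand of a 500 bp contig."""
    return GeneModel("TOYM", "chrT", "-", [(301, 400), (101, 200)])


def make_boundary_gene(c_boundary, intron_len=4000, exon2_len=600,
                       arg_codon_after=True):
    """A two-exon gene whose exon1/exon2 boundary falls after c.<c_boundary>,
    with a stop-free Ala-repeat CDS and a designed codon just after the
    boundary.  Returns (GeneModel, genome dict).

    With ``arg_codon_after`` the first codon of exon 2 encodes Arg (CGT),
    so a codon-aligned pseudoexon starting with a stop yields p.Arg<k>*.
    """
    assert c_boundary % 3 == 0
    exon1 = "ATG" + "GCT" * ((c_boundary - 3) // 3)
    assert len(exon1) == c_boundary
    tail_codons = (exon2_len - 3) // 3 - 1
    first = "CGT" if arg_codon_after else "GGT"
    exon2 = first + "GCT" * tail_codons + "TAA"
    exon2 = exon2 + "T" * (exon2_len - len(exon2))
    intron = ("ACGT" * (intron_len // 4 + 1))[:intron_len]
    genome = {"chrB": exon1 + intron + exon2}
    gene = GeneModel(
        "BND", "chrB", "+",
        [(1, c_boundary), (c_boundary + intron_len + 1,
                           c_boundary + intron_len + exon2_len)],
        cds_start_c=1,
    )
    return gene, genome
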