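"""Pseudoexon splicing into mRNA, translation, p. notation and NMD."""

import pytest
from Bio.Seq import Seq

from pseudoexon.coordinates import (
    CdnaPosition,
    CoordinateError,
    GeneModel,
    RnaChange,
    revcomp,
)
from pseudoexon.effects import (
    EffectError,
    ProteinChange,
    apply_pseudoexon,
    classify_protein_effect,
    format_hgvs_p,
    nmd_flag,
    parse_hgvs_p,
)
from pseudoexon.simulate import make_gene, plant_pseudoexon_variant
from pseudoexon.splice import PseudoexonCall

from conftest import make_boundary_gene


def _call(gene, pe_start_g, pe_end_g):
    """A bare pseudoexon call for effect tests (scores irrelevant here)."""
    return PseudoexonCall(
        gene_id=gene.gene_id,
        causal_variant=None,
        pe_start=gene.map_genomic_to_c(min(pe_start_g, pe_end_g)
                                       if gene.strand == "+" else
                                       max(pe_start_g, pe_end_g)),
        pe_end=gene.map_genomic_to_c(pe_end_g if gene.strand == "+"
                                     else min(pe_start_g, pe_end_g)),
        pe_start_g=pe_start_g if gene.strand == "+" else max(pe_start_g, pe_end_g),
        pe_end_g=pe_end_g if gene.strand == "+" else min(pe_start_g, pe_end_g),
        length=abs(pe_end_g - pe_start_g) + 1,
        donor_score=0.0,
        acceptor_score=0.0,
        donor_class="GT",
        motif_supported=False,
        intron_index=gene.which_intron(min(pe_start_g, pe_end_g)),
    )


def test_apply_pseudoexon_bookkeeping():
    """Insertion between exons lengthens the mRNA by the pseudoexon length
    and produces the correct r. description."""
    gene, genome = make_boundary_gene(300, intron_len=500)
    wild = gene.spliced_mrna(genome)
    call = _call(gene, 351, 400)  # offsets +51..+100 of the intron
    mutant, change = apply_pseudoexon(gene, call, genome)
    assert len(mutant) == len(wild) + 50
    assert str(change) == "r.300_301ins300+51_300+100"
    assert mutant[:300] == wild[:300] and mutant[350:] == wild[300:]


def test_apply_pseudoexon_rejects_cross_intron_boundaries():
    gene, genome = make_boundary_gene(300, intron_len=500)
    with pytest.raises(CoordinateError):
        apply_pseudoexon(gene, _call(gene, 351, 900), genome)  # ends in exon2


def test_table2_style_r_notation_with_downstream_anchor():
    """A pseudoexon in the 3' half of a long intron is written with
    negative offsets on the downstream exon, exactly the published form."""
    gene, genome = make_boundary_gene(645, intron_len=4000)
    # offsets -1933..-1807 relative to c.646: genomic 645+4000-1933+1 .. +127-1
    start_g = gene.map_c_to_genomic(CdnaPosition(646, -1933))
    end_g = gene.map_c_to_genomic(CdnaPosition(646, -1807))
    assert end_g - start_g + 1 == 127
    mutant, change = apply_pseudoexon(gene, _call(gene, start_g, end_g), genome)
    assert str(change) == "r.645_646ins646-1933_646-1807"


def test_nonsense_when_first_inserted_codon_is_stop():
    """Codon-aligned insertion beginning TAA truncates at the next codon:
    the classic deep-intronic nonsense geometry (p.Arg216*)."""
    gene, genome = make_boundary_gene(645, intron_len=4000)
    start_g = gene.map_c_to_genomic(CdnaPosition(646, -1933))
    end_g = gene.map_c_to_genomic(CdnaPosition(646, -1807))
    genome = dict(genome)
    seq = genome["chrB"]
    genome["chrB"] = seq[: start_g - 1] + "TAA" + seq[start_g + 2 :]
    mutant, change = apply_pseudoexon(gene, _call(gene, start_g, end_g), genome)
    wild = gene.spliced_mrna(genome)
    eff = classify_protein_effect(wild, mutant, gene.cds_start_c, change)
    assert eff.category == "nonsense"
    assert eff.first_affected_codon == 216
    assert eff.stop_offset == 0
    assert eff.notation == "p.Arg216*"


def test_frameshift_names_first_changed_residue():
    """An 83-bp insertion after c.1408 whose first base matches the wild
    codon's wobble context leaves codon 470 intact and names codon 471."""
    gene, genome = make_boundary_gene(1408 - 1408 % 3, intron_len=2000)
    # build a boundary at a phase-1 position: use exon1 end c.1407 plus one
    # exonic base of exon2; simpler: place the boundary at c.1408 directly
    # on a model whose exon1 ends mid-codon.
    exon1_len = 1408
    intron_len = 2000
    exon2_len = 600
    exon1 = "ATG" + "GCT" * 468 + "G"  # codons 1..469 end at c.1407; c.1408 = 'G'
    assert len(exon1) == exon1_len
    # codon 470 = G|GT (Gly), codon 471 = GGT (Gly)
    exon2 = "GT" + "GGT" + "GCT" * 196 + "TAA" + "T" * (exon2_len - 2 - 3 - 588 - 3)
    genome = {"chrB": exon1 + "ACGT" * 500 + exon2}
    gene = GeneModel(
        "FS", "chrB", "+",
        [(1, exon1_len), (exon1_len + intron_len + 1,
                          exon1_len + intron_len + exon2_len)],
    )
    # wild codon 470 = G|GT (Gly).  The 83-bp insert starts G,T so the
    # hybrid codon 470 is GGT — still Gly — and the first changed residue
    # is 471; a TAA 9 codons into the new frame puts the stop at fs*10.
    start_g = exon1_len + 200
    end_g = start_g + 82
    seq = genome["chrB"]
    insert = "G" + "T" + "CAC" * 9 + "TAA" + "C" * (83 - 2 - 27 - 3)
    assert len(insert) == 83
    genome["chrB"] = seq[: start_g - 1] + insert + seq[end_g:]
    mutant, change = apply_pseudoexon(gene, _call(gene, start_g, end_g), genome)
    wild = gene.spliced_mrna(genome)
    eff = classify_protein_effect(wild, mutant, gene.cds_start_c, change)
    assert eff.category == "frameshift"
    assert eff.first_affected_codon == 471  # codon 470 is untouched Gly
    assert eff.ref_aa == "G"  # wild-type Gly at 471
    assert eff.stop_offset == 10
    assert eff.notation == "p.Gly471Hisfs*10"


def test_inframe_insertion_of_54_bp():
    """A 54-bp insert with no in-frame stop is an in-frame insertion."""
    gene, genome = make_boundary_gene(300, intron_len=500)
    start_g = 351
    end_g = start_g + 53
    seq = genome["chrB"]
    genome = dict(genome)
    genome["chrB"] = seq[: start_g - 1] + "GCA" * 18 + seq[end_g:]
    mutant, change = apply_pseudoexon(gene, _call(gene, start_g, end_g), genome)
    wild = gene.spliced_mrna(genome)
    eff = classify_protein_effect(wild, mutant, gene.cds_start_c, change)
    assert eff.category == "inframe_insertion"
    assert eff.stop_offset == 0
    assert "ins" in eff.notation


def test_zero_length_pseudoexon_rejected():
    gene, genome = make_boundary_gene(300, intron_len=500)
    call = _call(gene, 351, 400)
    object.__setattr__(call, "length", 0)
    with pytest.raises(CoordinateError):
        apply_pseudoexon(gene, call, genome)


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def _oracle_classify(gene, genome, pe_start_g, pe_end_g):
    """Independent splice-and-translate: build the mutant mRNA by direct
    genomic slicing, translate with Biopython, and classify from the two
    protein strings alone."""
    chrom_seq = genome[gene.chrom]

    def seg(a, b):  # transcript-strand genomic segment
        s = chrom_seq[min(a, b) - 1 : max(a, b)]
        return s if gene.strand == "+" else revcomp(s)

    pieces = []
    inserted = False
    for (s, e) in gene.exons:
        pieces.append(seg(s, e) if gene.strand == "+" else seg(e, s))
        if not inserted:
            i = gene.which_intron(min(pe_start_g, pe_end_g))
            if i is not None and gene.exon_tx_bounds[i - 1][1] == sum(
                len(p) for p in pieces
            ):
                pieces.append(seg(pe_start_g, pe_end_g))
                inserted = True
    mutant = "".join(pieces)
    wild = gene.spliced_mrna(genome)

    def translate(seq):
        trimmed = seq[gene.cds_start_c - 1 :]
        trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
        return str(Seq(trimmed).translate())

    wild_aa, mut_aa = translate(wild), translate(mutant)
    first = next(
        (i for i, (w, m) in enumerate(zip(wild_aa, mut_aa)) if w != m), None
    )
    if first is None:
        return ("no_ptc", 0, 0)
    codon = first + 1
    if mut_aa[first] == "*":
        return ("nonsense", codon, 0)
    stop = mut_aa.find("*")
    ins_len = len(mutant) - len(wild)
    if ins_len % 3 == 0:
        if stop == wild_aa.find("*") + ins_len // 3:
            return ("inframe_insertion", codon, 0)
        return ("nonsense", codon, 0)
    if stop == -1:
        return ("frameshift", codon, -1)
    return ("frameshift", codon, stop + 1 - codon + 1)


@pytest.mark.parametrize("n_genes", [40])
def test_classifier_matches_naive_splice_and_translate(n_genes):
    """Category, first affected codon and fs*N from the classifier agree
    with a brute-force splice-and-translate oracle on random genes with
    random planted pseudoexons; frame preservation iff length % 3 == 0."""
    import numpy as np

    rng = np.random.default_rng(99)
    for k in range(n_genes):
        gene_s = make_gene(seed=5000 + k)
        intron = int(rng.integers(1, gene_s.model.n_introns + 1))
        pe_len = int(rng.integers(50, 301))
        try:
            planted, truth = plant_pseudoexon_variant(
                gene_s, intron, pe_len, "gt_gain", seed=6000 + k
            )
        except Exception:
            continue  # intron too short for this length; geometry, not logic
        model = planted.model
        call = _call(model, truth.pe_start_g, truth.pe_end_g)
        mutant, change = apply_pseudoexon(model, call, planted.genome)
        wild = model.spliced_mrna(planted.genome)
        eff = classify_protein_effect(wild, mutant, model.cds_start_c, change)
        cat, codon, stop_off = _oracle_classify(
            model, planted.genome, truth.pe_start_g, truth.pe_end_g
        )
        assert (eff.category, eff.first_affected_codon, eff.stop_offset) == (
            cat, codon, stop_off
        ), f"seed {k}: {eff} vs oracle {(cat, codon, stop_off)}"
        # frame preserved iff insertion length is a multiple of 3
        frame_preserved = eff.category in ("inframe_insertion", "no_ptc") or (
            eff.category == "nonsense" and pe_len % 3 == 0
        )
        assert (pe_len % 3 == 0) == frame_preserved or eff.category == "nonsense"


def test_p_notation_roundtrip():
    for text in ["p.Arg216*", "p.Gly471Serfs*55", "p.Val59Argfs*6",
                 "p.Lys100_Arg101insAlaGly", "p.Thr9ins*", "p.="]:
        assert format_hgvs_p(parse_hgvs_p(text)) == text


# ---------------------------------------------------------------------------
# NMD rule
# ---------------------------------------------------------------------------

def _nmd_setup(pe_len, stop_codon):
    """5 x 100 bp exon gene, pseudoexon of pe_len in intron 1; returns the
    nmd_flag for a nonsense change at stop_codon."""
    exons = [(i * 200 + 1, i * 200 + 100) for i in range(5)]
    gene = GeneModel("N", "chrN", "+", exons, cds_start_c=1)
    change = ProteinChange("nonsense", stop_codon, "K", "*", 0,
                           f"p.Lys{stop_codon}*")
    rna = RnaChange(100, 101, CdnaPosition(100, 10),
                    CdnaPosition(100, 9 + pe_len))
    return nmd_flag(change, gene, rna)


def test_nmd_internal_ptc_flagged():
    # mutant junctions at 100, 160, 260, 360, 460; PTC at codon 30 (nt 90)
    assert _nmd_setup(60, 30) is True


def test_nmd_last_exon_ptc_not_flagged():
    # stop codon 160 ends at nt 480, beyond the last junction (460)
    assert _nmd_setup(60, 160) is False


def test_nmd_54_nt_boundary_is_strict():
    # last junction at 460; stop ending at nt 406 is 54 nt upstream: False
    assert _nmd_setup(60, 135) is True   # 460 - 405 = 55
    assert _nmd_setup(59, 135) is False  # 459 - 405 = 54


def test_nmd_requires_ptc():
    gene = GeneModel("N", "chrN", "+", [(1, 100), (201, 300)])
    change = ProteinChange("inframe_insertion", 5, "A", "G", 0, "p.x")
    with pytest.raises(EffectError):
        nmd_flag(change, gene, RnaChange(100, 101, CdnaPosition(100, 10),
                                         CdnaPosition(100, 19)))
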