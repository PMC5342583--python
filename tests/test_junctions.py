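"""Junction-table parsing, filtering, event detection and phasing."""

import numpy as np
import pytest
from scipy import stats

from pseudoexon.coordinates import CdnaPosition, CdnaVariant, GeneModel
from pseudoexon.junctions import (
    JunctionFormatError,
    SpliceJunction,
    detect_pseudoexon_events,
    filter_junctions,
    read_junctions,
    variant_phase_check,
    write_junctions_sj_tab,
)
from pseudoexon.simulate import make_gene, plant_pseudoexon_variant, simulate_junctions


def test_read_sj_tab_field_mapping(tmp_path):
    p = tmp_path / "j.tab"
    p.write_text("chr5\t1000\t1100\t1\t1\t0\t12\t3\t40\n")
    (j,) = read_junctions(p, "sj_tab")
    assert (j.chrom, j.intron_start, j.intron_end) == ("chr5", 1000, 1100)
    assert j.motif_class == "GT/AG"
    assert j.unique_reads == 12
    assert not j.annotated
    assert j.strand == "+"


def test_read_bed6_converts_coordinates(tmp_path):
    p = tmp_path / "j.bed"
    p.write_text("chr5\t999\t1100\tj1\t12\t+\n")
    (j,) = read_junctions(p, "bed6")
    assert (j.intron_start, j.intron_end, j.unique_reads) == (1000, 1100, 12)


def test_sj_tab_and_bed6_agree_on_the_same_junctions(tmp_path):
    sj = tmp_path / "j.tab"
    bed = tmp_path / "j.bed"
    rows = [("chr1", 500, 620, 7), ("chr1", 900, 1300, 3), ("chr2", 10, 200, 1)]
    sj.write_text(
        "".join(f"{c}\t{s}\t{e}\t1\t1\t0\t{u}\t0\t50\n" for c, s, e, u in rows)
    )
    bed.write_text(
        "".join(f"{c}\t{s - 1}\t{e}\tj\t{u}\t+\n" for c, s, e, u in rows)
    )
    a = read_junctions(sj, "sj_tab")
    b = read_junctions(bed, "bed6")
    assert [(j.chrom, j.intron_start, j.intron_end, j.unique_reads) for j in a] == [
        (j.chrom, j.intron_start, j.intron_end, j.unique_reads) for j in b
    ]


def test_empty_file_returns_empty_list(tmp_path):
    p = tmp_path / "empty.tab"
    p.write_text("")
    assert read_junctions(p, "sj_tab") == []


def test_unknown_dialect_raises(tmp_path):
    p = tmp_path / "j.tab"
    p.write_text("chr1\t1\t2\t1\t1\t0\t5\t0\t50\n")
    with pytest.raises(JunctionFormatError):
        read_junctions(p, "starlike")


def test_filter_minima_per_motif_class():
    def j(motif, reads):
        return SpliceJunction("c", 10, 99, "+", motif, reads)

    assert filter_junctions([j("GT/AG", 1)]) == []
    assert len(filter_junctions([j("GT/AG", 2)])) == 1
    assert filter_junctions([j("other", 5)]) == []
    assert len(filter_junctions([j("other", 6)])) == 1
    # hand-enumerated mixed list: survivors are GT/AG>=2, GC/AG>=2, other>=6
    mixed = [
        j("GT/AG", 0), j("GT/AG", 2), j("GT/AG", 50),
        j("GC/AG", 1), j("GC/AG", 2), j("GC/AG", 3),
        j("other", 5), j("other", 6), j("other", 7), j("other", 0),
    ]
    assert len(filter_junctions(mixed)) == 6


def test_detect_pseudoexon_event_arithmetic(toy_gene):
    """Canonical junction (60 reads) + paired novel junctions (28/25) around
    an 83-bp segment: one event with inclusion 25/(25+60)."""
    s, e = toy_gene.intron_genomic(1)  # 201..300 is only 100 bp: use a wider gene
    gene = GeneModel("W", "chrW", "+", [(1, 100), (501, 700)])
    s, e = gene.intron_genomic(1)  # 101..500
    seg_start, seg_end = 201, 283  # 83 bp
    junctions = [
        SpliceJunction("chrW", s, e, "+", "GT/AG", 60, True),
        SpliceJunction("chrW", s, seg_start - 1, "+", "GT/AG", 28, False),
        SpliceJunction("chrW", seg_end + 1, e, "+", "GT/AG", 25, False),
    ]
    events, incomplete = detect_pseudoexon_events(junctions, gene)
    assert len(events) == 1 and incomplete == []
    ev = events[0]
    assert (ev.segment_start, ev.segment_end, ev.segment_length) == (201, 283, 83)
    assert ev.canonical_junction_reads == 60
    assert ev.inclusion_reads == 25  # downstream novel junction
    assert ev.inclusion_fraction == pytest.approx(25 / 85)


def test_detect_requires_in_range_intronic_segment():
    gene = GeneModel("W", "chrW", "+", [(1, 100), (501, 700)])
    s, e = gene.intron_genomic(1)
    # segment of 30 bp: below the 50 bp minimum
    junctions = [
        SpliceJunction("chrW", s, 200, "+", "GT/AG", 10, False),
        SpliceJunction("chrW", 231, e, "+", "GT/AG", 10, False),
    ]
    events, _ = detect_pseudoexon_events(junctions, gene)
    assert events == []


def test_unpaired_novel_junction_is_incomplete_not_event():
    gene = GeneModel("W", "chrW", "+", [(1, 100), (501, 700)])
    s, e = gene.intron_genomic(1)
    junctions = [
        SpliceJunction("chrW", s, e, "+", "GT/AG", 60, True),
        SpliceJunction("chrW", s, 200, "+", "GT/AG", 9, False),
    ]
    events, incomplete = detect_pseudoexon_events(junctions, gene)
    assert events == []
    assert len(incomplete) == 1


def test_control_sample_yields_no_events():
    syn = make_gene(seed=51)
    junctions = simulate_junctions(syn, [], depth=100, seed=1)
    events, incomplete = detect_pseudoexon_events(
        filter_junctions(junctions), syn.model
    )
    assert events == [] and incomplete == []


def test_simulated_event_recovers_planted_boundaries():
    syn, truth = plant_pseudoexon_variant(make_gene(seed=52), 2, 83, seed=53)
    junctions = simulate_junctions(syn, [(truth, 0.4)], depth=150, seed=2)
    events, _ = detect_pseudoexon_events(filter_junctions(junctions), syn.model)
    assert len(events) == 1
    lo, hi = truth.pe_genomic_ascending()
    assert (events[0].segment_start, events[0].segment_end) == (lo, hi)


def test_inclusion_fraction_monotone_in_psi():
    """Mean inclusion fraction increases with the simulated inclusion level."""
    syn, truth = plant_pseudoexon_variant(make_gene(seed=54), 2, 100, seed=55)
    psis = [0.1, 0.3, 0.5, 0.7, 0.9]
    means = []
    for i, psi in enumerate(psis):
        fr = []
        for rep in range(30):
            junctions = simulate_junctions(
                syn, [(truth, psi)], depth=150, seed=1000 * i + rep
            )
            events, _ = detect_pseudoexon_events(
                filter_junctions(junctions), syn.model
            )
            if events:
                fr.append(events[0].inclusion_fraction)
        means.append(np.mean(fr))
    rho, _ = stats.spearmanr(psis, means)
    assert rho > 0.9


def test_simulated_inclusion_fraction_tracks_psi():
    """At psi = 0.3 and depth 200 the Monte-Carlo mean inclusion fraction
    sits within 3 standard errors of 0.3."""
    syn, truth = plant_pseudoexon_variant(make_gene(seed=56), 2, 80, seed=57)
    fr = []
    for rep in range(200):
        junctions = simulate_junctions(syn, [(truth, 0.3)], depth=200, seed=rep)
        events, _ = detect_pseudoexon_events(filter_junctions(junctions), syn.model)
        assert events
        fr.append(events[0].inclusion_fraction)
    fr = np.array(fr)
    sem = fr.std(ddof=1) / np.sqrt(len(fr))
    assert abs(fr.mean() - 0.3) <= 3 * sem + 0.005  # small ratio bias allowance


def test_variant_phase_check_fractions():
    var = CdnaVariant(CdnaPosition(100, 50), "A", "G")
    all_alt = [(f"r{i}", "G") for i in range(20)]
    res = variant_phase_check(all_alt, var)
    assert res.alt_fraction == 1.0 and not res.no_coverage
    half = [(f"r{i}", "G") for i in range(10)] + [(f"r{i}", "A") for i in range(10)]
    assert variant_phase_check(half, var).alt_fraction == 0.5
    empty = variant_phase_check([], var)
    assert empty.no_coverage and empty.alt_fraction is None


def test_sj_tab_write_read_roundtrip(tmp_path):
    syn, truth = plant_pseudoexon_variant(make_gene(seed=58), 1, 60, seed=59)
    junctions = simulate_junctions(syn, [(truth, 0.5)], depth=80, seed=3)
    p = tmp_path / "out.tab"
    write_junctions_sj_tab(junctions, p)
    back = read_junctions(p, "sj_tab")
    assert [
        (j.chrom, j.intron_start, j.intron_end, j.motif_class, j.unique_reads,
         j.annotated)
        for j in junctions
    ] == [
        (j.chrom, j.intron_start, j.intron_end, j.motif_class, j.unique_reads,
         j.annotated)
        for j in back
    ]
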