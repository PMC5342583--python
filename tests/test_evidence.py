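"""WGS-style variant filtering, cosegregation and evidence aggregation."""

import pytest

from pseudoexon.effects import ProteinChange
from pseudoexon.evidence import (
    EvidenceError,
    FilterConfig,
    Individual,
    Pedigree,
    SampleCall,
    VariantRecord,
    aggregate_evidence,
    cosegregation_check,
    filter_variants,
)
from pseudoexon.splice import PseudoexonCall
from pseudoexon.coordinates import CdnaPosition


def rec(pos, gt="het", dp=40, gq=99, af=None, sample="S1"):
    return VariantRecord("chr1", pos, "A", "G",
                         ((sample, SampleCall(gt, dp, gq)),), af)


CFG = FilterConfig(index_sample="S1")


@pytest.mark.parametrize(
    "record, kept",
    [
        (rec(1, dp=6), False),           # below minimum read depth
        (rec(2, dp=7), True),            # exactly the minimum depth
        (rec(3, gq=69), False),          # genotype quality below 70
        (rec(4, gq=70), True),
        (rec(5, af=0.001), False),       # MAF >= 0.001 removed
        (rec(6, af=0.0009), True),
        (rec(7, af=None), True),         # unknown frequency passes
        (rec(8, gt="hom_alt"), False),   # heterozygote-only
        (rec(9, gt="hom_ref"), False),
        (rec(10, gt="missing"), False),
    ],
)
def test_filter_boundaries(record, kept):
    assert (filter_variants([record], CFG) == [record]) == kept


def test_filter_hand_enumerated_toy_set():
    records = [
        rec(1), rec(2, dp=6), rec(3, gq=69), rec(4, af=0.5), rec(5, af=0.0001),
        rec(6, gt="hom_alt"), rec(7, dp=7, gq=70), rec(8, dp=100, gq=99),
        rec(9, af=0.001), rec(10, gt="missing"), rec(11, dp=0), rec(12),
    ]
    surviving = filter_variants(records, CFG)
    assert [r.pos for r in surviving] == [1, 5, 7, 8, 12]


def test_filter_idempotent_and_order_independent():
    records = [rec(i, dp=6 + i % 4, gq=60 + 5 * (i % 8)) for i in range(1, 13)]
    once = filter_variants(records, CFG)
    assert filter_variants(once, CFG) == once
    reversed_result = filter_variants(records[::-1], CFG)
    assert sorted(r.pos for r in reversed_result) == sorted(r.pos for r in once)


def test_filter_dominant_shared_mode():
    calls = (
        ("A1", SampleCall("het", 40, 99)),
        ("A2", SampleCall("hom_ref", 40, 99)),
    )
    record = VariantRecord("chr1", 5, "A", "G", calls, None)
    cfg = FilterConfig(index_sample="A1", dominant_shared=True,
                       affected_samples=("A1", "A2"))
    assert filter_variants([record], cfg) == []
    shared = VariantRecord(
        "chr1", 5, "A", "G",
        (("A1", SampleCall("het", 40, 99)), ("A2", SampleCall("het", 40, 99))),
        None,
    )
    assert filter_variants([shared], cfg) == [shared]


def test_filter_region_restriction():
    cfg = FilterConfig(index_sample="S1", region=("chr1", 100, 200))
    assert filter_variants([rec(150)], cfg) == [rec(150)]
    assert filter_variants([rec(250)], cfg) == []


# ---------------------------------------------------------------------------
# cosegregation
# ---------------------------------------------------------------------------

def pedigree(n_affected, n_unaffected):
    inds = [Individual(f"A{i}", None, None, "unknown", True)
            for i in range(n_affected)]
    inds += [Individual(f"U{i}", None, None, "unknown", False)
             for i in range(n_unaffected)]
    return Pedigree("F", tuple(inds))


def test_cosegregation_complete():
    ped = pedigree(4, 2)
    gts = {f"A{i}": "het" for i in range(4)} | {f"U{i}": "hom_ref" for i in range(2)}
    assert cosegregation_check(ped, gts) == "complete"


def test_cosegregation_incomplete_when_affected_noncarrier():
    ped = pedigree(3, 0)
    gts = {"A0": "het", "A1": "het", "A2": "hom_ref"}
    assert cosegregation_check(ped, gts) == "incomplete"


def test_cosegregation_single_affected_not_assessable():
    ped = pedigree(1, 2)
    gts = {"A0": "het", "U0": "hom_ref", "U1": "hom_ref"}
    assert cosegregation_check(ped, gts) == "not_assessable"


def test_cosegregation_unaffected_carrier():
    ped = pedigree(2, 1)
    gts = {"A0": "het", "A1": "het", "U0": "het"}
    assert cosegregation_check(ped, gts) == "incomplete"
    # reduced-penetrance reading: unaffected carriers tolerated
    assert cosegregation_check(ped, gts, check_unaffected=False) == "complete"


def test_cosegregation_unknown_individual_raises():
    with pytest.raises(EvidenceError):
        cosegregation_check(pedigree(2, 0), {"A0": "het", "GHOST": "het"})


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def call(motif=True, junction=False):
    return PseudoexonCall(
        "G", None, CdnaPosition(100, 10), CdnaPosition(100, 92),
        110, 192, 83, 100.0, 100.0, "GT", motif, junction, 1,
    )


TRUNC = ProteinChange("frameshift", 471, "G", "S", 55, "p.Gly471Serfs*55")
INFRAME = ProteinChange("inframe_insertion", 100, "K", "A", 0, "p.x")


def test_supported_with_complete_cosegregation():
    rep = aggregate_evidence(
        pseudoexon_call=call(motif=True), protein_change=TRUNC,
        cosegregation="complete", population_af=None,
    )
    assert rep.tier == "supported"


def test_supported_by_junction_rescue_without_motif():
    rep = aggregate_evidence(
        pseudoexon_call=call(motif=False, junction=True), protein_change=TRUNC,
        cosegregation="not_assessable", population_af=0.0,
    )
    assert rep.tier == "supported"
    assert not rep.motif_supported and rep.junction_supported


def test_inframe_event_in_controls_is_unsupported():
    rep = aggregate_evidence(
        pseudoexon_call=call(motif=True), protein_change=INFRAME,
        cosegregation="not_assessable", population_af=None,
        also_in_control=True,
    )
    assert rep.tier == "unsupported"


def test_population_presence_blocks_support():
    rep = aggregate_evidence(
        pseudoexon_call=call(), protein_change=TRUNC,
        cosegregation="complete", population_af=0.0005,
    )
    assert rep.tier == "uncertain"
    assert not rep.population_absent


def test_tier_monotone_under_flag_removal():
    """Removing any single evidence strand never raises the tier."""
    order = {"unsupported": 0, "uncertain": 1, "supported": 2}
    base = aggregate_evidence(
        pseudoexon_call=call(motif=True, junction=True), protein_change=TRUNC,
        cosegregation="complete", population_af=None,
    )
    assert base.tier == "supported"
    weaker = [
        aggregate_evidence(pseudoexon_call=None, protein_change=TRUNC,
                           cosegregation="complete", population_af=None),
        aggregate_evidence(pseudoexon_call=call(motif=False, junction=False),
                           protein_change=TRUNC, cosegregation="complete",
                           population_af=None),
        aggregate_evidence(pseudoexon_call=call(), protein_change=INFRAME,
                           cosegregation="complete", population_af=None),
        aggregate_evidence(pseudoexon_call=call(), protein_change=TRUNC,
                           cosegregation="incomplete", population_af=None),
        aggregate_evidence(pseudoexon_call=call(), protein_change=TRUNC,
                           cosegregation="complete", population_af=0.01),
        aggregate_evidence(pseudoexon_call=call(), protein_change=TRUNC,
                           cosegregation="complete", population_af=None,
                           also_in_control=True),
    ]
    assert all(order[w.tier] <= order[base.tier] for w in weaker)


def test_ase_is_advisory_only():
    """A supported tier does not require ASE consistency (it is reported)."""
    rep = aggregate_evidence(
        pseudoexon_call=call(), protein_change=TRUNC,
        cosegregation="complete", population_af=None, ase_result=None,
    )
    assert rep.tier == "supported" and not rep.ase_consistent
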