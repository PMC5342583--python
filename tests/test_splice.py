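"""Splice-site scoring, donor-gain scanning and pseudoexon prediction."""

import numpy as np
import pytest

from pseudoexon.coordinates import CdnaVariant, CoordinateError
from pseudoexon.simulate import (
    _set_tx_bases,
    ACCEPTOR_CONSENSUS_INTRON,
    make_gene,
    plant_pseudoexon_variant,
)
from pseudoexon.splice import (
    SpliceModelError,
    donor_context_score,
    donor_gain_scan,
    predict_pseudoexon,
    score_site,
)


def test_consensus_windows_score_100(splice_model):
    assert score_site("AGgtaagt", "donor", splice_model) == 100.0
    assert score_site("AGgtgagt", "donor", splice_model) == 100.0  # r = g
    assert score_site("tttttttttttcagG", "acceptor", splice_model) == 100.0


def test_poor_donor_scores_below_threshold(splice_model):
    # hand sum for ttttcccc: only +2 (t, 0.79) contributes above minimum;
    # normalised = 0.72 / 5.40 = 13.33%
    s = score_site("ttttcccc", "donor", splice_model)
    assert s == pytest.approx(13.333, abs=0.01)
    assert s < splice_model.donor_threshold_gt


def test_score_site_input_validation(splice_model):
    with pytest.raises(SpliceModelError):
        score_site("AGgtaag", "donor", splice_model)  # wrong length
    with pytest.raises(SpliceModelError):
        score_site("AGgtaagN", "donor", splice_model)  # non-ACGT
    with pytest.raises(SpliceModelError):
        score_site("AGgtaagt", "branch", splice_model)  # unknown kind


def test_shuffled_window_changes_score(splice_model):
    """Scores are positional: shuffling the consensus donor lowers it."""
    rng = np.random.default_rng(7)
    win = list("AGGTAAGT")
    changed = 0
    for _ in range(20):
        rng.shuffle(win)
        if "".join(win) != "AGGTAAGT":
            if score_site("".join(win), "donor", splice_model) != 100.0:
                changed += 1
    assert changed > 0


def test_donor_gain_single_window(splice_model):
    """A substitution completing AG/gtaagt is reported as exactly one
    GT-class gain with a perfect context score."""
    gene, truth = plant_pseudoexon_variant(
        make_gene(seed=3), 1, 83, "gt_gain", seed=4
    )
    gains = donor_gain_scan(truth and gene.model, truth.variant, gene.genome,
                            splice_model)
    assert len(gains) == 1
    g = gains[0]
    assert g.donor_class == "GT"
    assert g.alt_score == pytest.approx(100.0)
    assert g.site_g == truth.pe_end_g
    assert g.alt_window[2:4] == "GT"


def test_ref_passing_window_is_never_a_gain(splice_model):
    """A variant inside an already-viable donor is not reported as a gain."""
    gene = make_gene(seed=5)
    model = gene.model
    s, e = model.intron_genomic(1)
    length = e - s + 1
    u2g = (lambda u: s + u - 1) if model.strand == "+" else (lambda u: e - u + 1)
    # plant a fully viable donor mid-intron: AG|gtaagt at u = 200..207
    edits = [(u2g(200 + k), b) for k, b in enumerate("AGGTAAGT")]
    _set_tx_bases(gene.genome, model, edits)
    # variant improves +3 (already consensus-compatible a) to g: still ref-viable
    g_var = u2g(204)
    ref = model.tx_strand_base(gene.genome, g_var)
    assert ref == "A"
    var = CdnaVariant(model.map_genomic_to_c(g_var), "A", "G")
    gains = donor_gain_scan(model, var, gene.genome, splice_model)
    assert all(g.site_g != u2g(201) for g in gains)


def test_variant_ref_mismatch_raises(splice_model):
    gene = make_gene(seed=6)
    model = gene.model
    s, _ = model.intron_genomic(1)
    g = s + 100
    base = model.tx_strand_base(gene.genome, g)
    wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
    var = CdnaVariant(model.map_genomic_to_c(g), wrong,
                      "G" if wrong != "G" else "T")
    with pytest.raises(CoordinateError):
        donor_gain_scan(model, var, gene.genome, splice_model)


def test_predict_recovers_planted_boundaries(splice_model):
    gene, truth = plant_pseudoexon_variant(
        make_gene(seed=11), 2, 83, "gt_gain", seed=12
    )
    calls = predict_pseudoexon(gene.model, truth.variant, gene.genome, splice_model)
    assert len(calls) == 1
    c = calls[0]
    assert (c.pe_start_g, c.pe_end_g, c.length) == (
        truth.pe_start_g, truth.pe_end_g, 83
    )
    assert c.motif_supported
    assert c.donor_class == "GT"


def test_predict_enforces_length_bounds(splice_model):
    """An acceptor outside the configured pseudoexon length range is never
    used: narrowing the range past the only viable (planted, 83 bp)
    acceptor yields an empty list, not an error."""
    gene, truth = plant_pseudoexon_variant(
        make_gene(seed=21, intron_len_range=(900, 1200)), 2, 83, "gt_gain",
        seed=22,
    )
    model = gene.model
    assert len(predict_pseudoexon(model, truth.variant, gene.genome,
                                  splice_model)) == 1
    assert predict_pseudoexon(
        model, truth.variant, gene.genome, splice_model, length_range=(100, 300)
    ) == []


def test_predict_ranks_acceptors_by_score(splice_model):
    """Two in-range acceptors: the stronger one is ranked first."""
    gene, truth = plant_pseudoexon_variant(
        make_gene(seed=31), 2, 83, "gt_gain", seed=32
    )
    model = gene.model
    s, e = model.intron_genomic(2)
    u2g = (lambda u: s + u - 1) if model.strand == "+" else (lambda u: e - u + 1)
    u_end = (truth.pe_end_g - s + 1) if model.strand == "+" else (e - truth.pe_end_g + 1)
    # second acceptor, 150 bp pseudoexon, with one degraded tract base
    far = u_end - 149
    window = ACCEPTOR_CONSENSUS_INTRON[:5] + "G" + ACCEPTOR_CONSENSUS_INTRON[6:]
    edits = [(u2g(far - 14 + k), b) for k, b in enumerate(window)]
    edits.append((u2g(far), "G"))
    _set_tx_bases(gene.genome, model, edits)
    calls = predict_pseudoexon(model, truth.variant, gene.genome, splice_model)
    assert len(calls) >= 2
    assert calls[0].acceptor_score >= calls[1].acceptor_score
    assert calls[0].length == 83  # the perfect planted acceptor wins
    weaker = [c for c in calls if c.length == 150]
    assert weaker and weaker[0].acceptor_score < 100.0


def test_gc_donor_scenario_not_seen_by_motif_scan(splice_model):
    """The exonic AG-creating substitution before a gc dinucleotide has a
    context below the GC threshold: the motif scan alone misses it."""
    gene, truth = plant_pseudoexon_variant(
        make_gene(seed=41), 3, 83, "exonic_ag_gain_gc_donor", seed=42
    )
    assert donor_gain_scan(gene.model, truth.variant, gene.genome, splice_model) == []
    assert predict_pseudoexon(gene.model, truth.variant, gene.genome, splice_model) == []
    assert not truth.motif_detectable


def test_gc_context_threshold_behaviour(splice_model):
    """The GC class applies its own (stricter) context threshold."""
    # perfect context, gc dinucleotide: passes GC threshold
    assert donor_context_score("AGgcaagt", splice_model) == pytest.approx(100.0)
    # one non-degenerate context mismatch: 81.8 < 85 (GC) but >= 70 (GT)
    s = donor_context_score("AGgcacgt", splice_model)
    assert splice_model.donor_threshold_gt <= s < splice_model.donor_threshold_gc
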