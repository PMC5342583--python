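"""Position-weight splice-site scoring, donor-gain scanning, and
pseudoexon boundary prediction.

The scoring scheme is a transparent Shapiro–Senapathy-style per-position
weight sum, min–max normalised to a 0–100 percent scale, built from the
textbook splice consensus (donor ``AG/gtragt``, acceptor ``poly(y)nyag/G``).
A window scores 100 iff every position carries a maximal-weight base.

Donor windows are 8 nt (2 exonic + 6 intronic); acceptor windows 15 nt
(14 intronic + 1 exonic).  Donor *class* is set by the +1/+2 intronic
dinucleotide (GT, or the rarer GC); class membership is obligatory, and the
class-specific threshold is applied to the *context* score computed over
the six non-dinucleotide positions, so that a GC donor is not penalised for
its defining dinucleotide but must carry a stronger surrounding context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .coordinates import (
    CdnaPosition,
    CdnaVariant,
    CoordinateError,
    GeneModel,
    RnaChange,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

DONOR_LEN = 8       # positions -2,-1 | +1..+6
DONOR_EXONIC = 2
ACCEPTOR_LEN = 15   # positions -14..-1 | +1
ACCEPTOR_INTRONIC = 14
# indices of the donor window outside the +1/+2 dinucleotide
DONOR_CONTEXT_IDX = (0, 1, 4, 5, 6, 7)


class SpliceModelError(ValueError):
    pass


def _load_weight_table(path, expected_len: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[2:]) != list(_BASES) or len(df) != expected_len:
        raise SpliceModelError(f"malformed weight table {path}")
    w = df[list(_BASES)].to_numpy(dtype=float)
    if not np.allclose(w.sum(axis=1), 1.0):
        raise SpliceModelError(f"weights in {path} must sum to 1 per position")
    return w


@dataclass(frozen=True)
class SpliceSiteModel:
    """Per-position nucleotide weights plus percent-score thresholds."""

    donor_weights: np.ndarray
    acceptor_weights: np.ndarray
    donor_threshold_gt: float = 70.0
    donor_threshold_gc: float = 85.0
    acceptor_threshold: float = 65.0

    def __post_init__(self):
        for thr in (self.donor_threshold_gt, self.donor_threshold_gc,
                    self.acceptor_threshold):
            if not (0.0 <= thr <= 100.0):
                raise SpliceModelError(f"threshold {thr} outside [0, 100]")

    def donor_class_threshold(self, donor_class: str) -> float:
        if donor_class == "GT":
            return self.donor_threshold_gt
        if donor_class == "GC":
            return self.donor_threshold_gc
        raise SpliceModelError(f"no threshold for donor class {donor_class!r}")


def default_splice_model(**thresholds) -> SpliceSiteModel:
    """The shipped weight tables with default (configurable) thresholds."""
    data = resources.files("pseudoexon").joinpath("data")
    donor = _load_weight_table(str(data.joinpath("donor_weights.tsv")), DONOR_LEN)
    acceptor = _load_weight_table(
        str(data.joinpath("acceptor_weights.tsv")), ACCEPTOR_LEN
    )
    return SpliceSiteModel(donor, acceptor, **thresholds)


def _window_score(window: str, weights: np.ndarray, idx=None) -> float:
    """Min–max normalised percent score over the selected positions."""
    if idx is None:
        idx = range(weights.shape[0])
    s = smin = smax = 0.0
    for i in idx:
        col = weights[i]
        s += col[_BASE_INDEX[window[i]]]
        smin += col.min()
        smax += col.max()
    if smax == smin:  # fully degenerate selection
        return 100.0
    return 100.0 * (s - smin) / (smax - smin)


def _check_window(window: str, expected_len: int, kind: str) -> str:
    w = window.upper()
    if len(w) != expected_len:
        raise SpliceModelError(
            f"{kind} window must be {expected_len} nt, got {len(w)}"
        )
    if any(b not in _BASE_INDEX for b in w):
        raise SpliceModelError(f"{kind} window contains non-ACGT bases: {window!r}")
    return w


def score_site(window: str, kind: str, model: SpliceSiteModel) -> float:
    """Percent score of a full donor (8 nt) or acceptor (15 nt) window."""
    if kind == "donor":
        w = _check_window(window, DONOR_LEN, kind)
        return _window_score(w, model.donor_weights)
    if kind == "acceptor":
        w = _check_window(window, ACCEPTOR_LEN, kind)
        return _window_score(w, model.acceptor_weights)
    raise SpliceModelError(f"kind must be 'donor' or 'acceptor', got {kind!r}")


def donor_context_score(window: str, model: SpliceSiteModel) -> float:
    """Score over the six donor positions flanking the +1/+2 dinucleotide."""
    w = _check_window(window, DONOR_LEN, "donor")
    return _window_score(w, model.donor_weights, DONOR_CONTEXT_IDX)


def donor_dinucleotide_class(window: str) -> str:
    """GT / GC / noncanonical from the +1/+2 intronic dinucleotide."""
    dinuc = window[DONOR_EXONIC : DONOR_EXONIC + 2].upper()
    return dinuc if dinuc in ("GT", "GC") else "noncanonical"


# ---------------------------------------------------------------------------
# donor-gain scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DonorGain:
    """A donor window newly activated by a substitution.

    ``site_g`` is the genomic coordinate of the last (pseudo)exonic base,
    i.e. the base immediately 5' of the intronic dinucleotide, transcript
    orientation.
    """

    site_g: int
    donor_class: str
    ref_score: float
    alt_score: float
    ref_window: str
    alt_window: str
    intron_index: int | None


def _donor_passes(window: str, model: SpliceSiteModel) -> bool:
    cls = donor_dinucleotide_class(window)
    if cls == "noncanonical":
        return False
    return donor_context_score(window, model) >= model.donor_class_threshold(cls)


def donor_gain_scan(
    gene: GeneModel,
    variant: CdnaVariant,
    genome,
    model: SpliceSiteModel,
) -> list[DonorGain]:
    """Evaluate every donor window overlapping a substitution.

    A gain is a window whose alt allele carries a GT or GC dinucleotide and
    passes its class threshold while the ref allele does not pass any class
    threshold.  Results are ordered by alt score, descending.  A GC-context
    near-miss (alt would pass the GT threshold but not the stricter GC one)
    is logged, mirroring how cryptic GC donors evade consensus-based
    predictors.
    """
    gene.check_variant_ref(genome, variant)
    g_var = gene.map_c_to_genomic(variant.position)
    sign = 1 if gene.strand == "+" else -1
    lo, hi = gene.span
    gains: list[DonorGain] = []
    for k in range(DONOR_LEN):  # variant sits at window index k
        g0 = g_var - sign * k  # genomic coordinate of window index 0
        g_last = g0 + sign * (DONOR_LEN - 1)
        if not (lo <= min(g0, g_last) and max(g0, g_last) <= hi):
            continue
        ref_win = gene.tx_strand_seq(genome, min(g0, g_last), max(g0, g_last))
        alt_win = ref_win[:k] + variant.alt + ref_win[k + 1:]
        if _donor_passes(ref_win, model):
            continue  # ref already viable: not a gain
        alt_cls = donor_dinucleotide_class(alt_win)
        if alt_cls == "noncanonical":
            continue
        alt_score = donor_context_score(alt_win, model)
        if alt_score < model.donor_class_threshold(alt_cls):
            if alt_cls == "GC" and alt_score >= model.donor_threshold_gt:
                log.info(
                    "near-miss GC donor for %s at %s:%d (context %.1f < %.1f)",
                    variant, gene.chrom, g0 + sign, alt_score,
                    model.donor_threshold_gc,
                )
            continue
        site_g = g0 + sign  # window index 1 = last exonic base
        gains.append(
            DonorGain(
                site_g=site_g,
                donor_class=alt_cls,
                ref_score=donor_context_score(ref_win, model),
                alt_score=alt_score,
                ref_window=ref_win,
                alt_window=alt_win,
                intron_index=gene.which_intron(site_g),
            )
        )
    gains.sort(key=lambda d: -d.alt_score)
    return gains


# ---------------------------------------------------------------------------
# pseudoexon prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PseudoexonCall:
    """An inferred pseudoexon: intronic boundaries plus supporting scores."""

    gene_id: str
    causal_variant: CdnaVariant | None
    pe_start: CdnaPosition
    pe_end: CdnaPosition
    pe_start_g: int
    pe_end_g: int
    length: int
    donor_score: float
    acceptor_score: float
    donor_class: str
    motif_supported: bool
    junction_supported: bool = False
    intron_index: int | None = None

    def with_junction_support(self) -> "PseudoexonCall":
        return replace(self, junction_supported=True)


def _intron_u_coords(gene: GeneModel, intron_index: int):
    """Helper mapping u (1..L, transcript 5'->3' into the intron) <-> genomic."""
    s, e = gene.intron_genomic(intron_index)
    length = e - s + 1
    if gene.strand == "+":
        return length, (lambda u: s + u - 1)
    return length, (lambda u: e - u + 1)


def _make_call(
    gene, genome, model, variant, intron_index, u_start, u_end,
    donor_score, donor_class, motif_supported_donor,
) -> PseudoexonCall:
    length, u2g = _intron_u_coords(gene, intron_index)
    acc_win = "".join(
        gene.tx_strand_base(genome, u2g(u)) for u in range(u_start - ACCEPTOR_INTRONIC, u_start + 1)
    )
    acc_score = _window_score(acc_win, model.acceptor_weights)
    pe_start_g, pe_end_g = u2g(u_start), u2g(u_end)
    return PseudoexonCall(
        gene_id=gene.gene_id,
        causal_variant=variant,
        pe_start=gene.map_genomic_to_c(pe_start_g),
        pe_end=gene.map_genomic_to_c(pe_end_g),
        pe_start_g=pe_start_g,
        pe_end_g=pe_end_g,
        length=u_end - u_start + 1,
        donor_score=donor_score,
        acceptor_score=acc_score,
        donor_class=donor_class,
        motif_supported=bool(
            motif_supported_donor and acc_score >= model.acceptor_threshold
        ),
        intron_index=intron_index,
    )



def predict_pseudoexon(
    gene: GeneModel,
    variant: CdnaVariant,
    genome,
    model: SpliceSiteModel,
    length_range: tuple[int, int] = (50, 300),
) -> list[PseudoexonCall]:
    """Predict pseudoexons activated by a donor-creating substitution.

    For every gained donor inside an intron, the same intron is scanned
    upstream for acceptor sites (obligatory ``ag`` at −2/−1, acceptor score
    at or above the acceptor threshold) whose implied pseudoexon length
    falls within ``length_range``.  One call is emitted per (donor,
    acceptor) pair; calls for a given donor are ranked by acceptor score,
    best first, and donors by their gain score.
    """
    lo_len, hi_len = length_range
    calls: list[PseudoexonCall] = []
    for gain in donor_gain_scan(gene, variant, genome, model):
        if gain.intron_index is None:
            continue
        length, u2g = _intron_u_coords(gene, gain.intron_index)
        # u coordinate of the candidate pseudoexon 3' end
        s, e = gene.intron_genomic(gain.intron_index)
        u_end = (gain.site_g - s + 1) if gene.strand == "+" else (e - gain.site_g + 1)
        if u_end + 6 > length:
            continue  # donor intronic hexamer must stay inside the intron
        donor_calls = []
        for pe_len in range(lo_len, hi_len + 1):
            u_start = u_end - pe_len + 1
            if u_start - ACCEPTOR_INTRONIC < 1:
                break  # acceptor window would leave the intron
            m2 = gene.tx_strand_base(genome, u2g(u_start - 2))
            m1 = gene.tx_strand_base(genome, u2g(u_start - 1))
            if m2 != "A" or m1 != "G":
                continue
            call = _make_call(
                gene, genome, model, variant, gain.intron_index,
                u_start, u_end, gain.alt_score, gain.donor_class, True,
            )
            if call.acceptor_score >= model.acceptor_threshold:
                donor_calls.append(call)
        donor_calls.sort(key=lambda c: -c.acceptor_score)
        calls.extend(donor_calls)
    return calls


def call_from_boundaries(
    gene: GeneModel,
    genome,
    model: SpliceSiteModel,
    pe_start_g: int,
    pe_end_g: int,
    variant: CdnaVariant | None = None,
    junction_supported: bool = True,
) -> PseudoexonCall:
    """Build a call from externally asserted boundaries (RNA-evidence rescue).

    Junction-corroborated pseudoexons remain callable even when their splice
    motifs fail the consensus thresholds; both sites are still scored for
    the report, and ``motif_supported`` records whether they pass.
    """
    lo = min(pe_start_g, pe_end_g)
    hi = max(pe_start_g, pe_end_g)
    i = gene.which_intron(lo)
    if i is None or gene.which_intron(hi) != i:
        raise CoordinateError(
            f"boundaries {pe_start_g}-{pe_end_g} do not lie in one intron of {gene.gene_id}"
        )
    length, u2g = _intron_u_coords(gene, i)
    s, e = gene.intron_genomic(i)
    if gene.strand == "+":
        u_start, u_end = lo - s + 1, hi - s + 1
    else:
        u_start, u_end = e - hi + 1, e - lo + 1
    if u_start - ACCEPTOR_INTRONIC < 1 or u_end + 6 > length:
        raise CoordinateError("pseudoexon too close to the intron boundary to score")
    donor_win = "".join(
        gene.tx_strand_base(genome, u2g(u)) for u in range(u_end - 1, u_end + 7)
    )
    donor_cls = donor_dinucleotide_class(donor_win)
    donor_score = donor_context_score(donor_win, model)
    donor_ok = (
        donor_cls != "noncanonical"
        and donor_score >= model.donor_class_threshold(donor_cls)
    )
    call = _make_call(
        gene, genome, model, variant, i, u_start, u_end,
        donor_score, donor_cls, donor_ok,
    )
    return replace(call, junction_supported=junction_supported)



def implied_rna_change(gene: GeneModel, call: PseudoexonCall) -> RnaChange:
    """The r. description implied by a pseudoexon call."""
    i = call.intron_index or gene.which_intron(call.pe_start_g)
    last_c = gene.t_to_c(gene.exon_tx_bounds[i - 1][1])
    return RnaChange(last_c, last_c + 1, call.pe_start, call.pe_end)
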