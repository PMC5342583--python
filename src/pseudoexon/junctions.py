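"""Splice-junction evidence for pseudoexon inclusion.

Reads junction tables (STAR ``SJ.out.tab``-style TSV or BED6 introns),
filters them by per-motif-class unique-read minima, and detects *paired*
novel junctions that define a pseudoexon: an upstream junction re-using the
annotated donor of an exon and a downstream junction re-using the annotated
acceptor of the next exon, with a fully intronic internal segment of
plausible exon length between them.  Inclusion depth is quantified against
the canonical junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .coordinates import GeneModel

log = logging.getLogger(__name__)

MOTIF_CLASSES = ("GT/AG", "GC/AG", "other")
# STAR SJ.out.tab motif codes: 0 non-canonical, 1/2 GT/AG (+/-), 3/4 GC/AG,
# 5/6 AT/AC (kept as "other" here)
_STAR_MOTIF = {0: "other", 1: "GT/AG", 2: "GT/AG", 3: "GC/AG", 4: "GC/AG",
               5: "other", 6: "other"}
_STAR_STRAND = {0: ".", 1: "+", 2: "-"}

DEFAULT_MIN_UNIQUE = {"GT/AG": 2, "GC/AG": 2, "other": 6}


class JunctionFormatError(ValueError):
    pass


@dataclass(frozen=True)
class SpliceJunction:
    """An intron supported by split reads; coordinates are the first and
    last *intronic* bases, genomic 1-based inclusive."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str  # '+', '-' or '.' (unknown)
    motif_class: str
    unique_reads: int
    annotated: bool = False

    def __post_init__(self):
        if self.intron_start > self.intron_end:
            raise JunctionFormatError(
                f"junction {self.chrom}:{self.intron_start}-{self.intron_end} "
                "has start > end"
            )
        if self.unique_reads < 0:
            raise JunctionFormatError("unique_reads must be >= 0")
        if self.motif_class not in MOTIF_CLASSES:
            raise JunctionFormatError(f"unknown motif class {self.motif_class!r}")


@dataclass(frozen=True)
class PseudoexonEvent:
    """Two novel junctions flanking an included intronic segment."""

    upstream_junction: SpliceJunction
    downstream_junction: SpliceJunction
    segment_start: int  # genomic, ascending
    segment_end: int
    segment_length: int
    canonical_junction_reads: int
    inclusion_reads: int
    intron_index: int

    @property
    def inclusion_fraction(self) -> float | None:
        denom = self.inclusion_reads + self.canonical_junction_reads
        return self.inclusion_reads / denom if denom > 0 else None


def read_junctions(path, fmt: str = "sj_tab") -> list[SpliceJunction]:
    """Read a junction table.

    ``sj_tab`` is the STAR SJ.out.tab dialect (9 whitespace-separated
    columns, 1-based inclusive intron coordinates); ``bed6`` holds introns
    as 0-based half-open BED intervals with the score column as unique
    reads.  Records are returned sorted by (chrom, intron_start).
    """
    if fmt == "sj_tab":
        names = ["chrom", "start", "end", "strand", "motif", "annotated",
                 "unique", "multi", "overhang"]
        try:
            df = pd.read_csv(path, sep=r"\s+", header=None, names=names,
                             dtype={"chrom": str}, comment="#")
        except pd.errors.EmptyDataError:
            log.warning("junction file %s is empty", path)
            return []
        if df.shape[1] != 9 or df[names[1:]].isna().any().any():
            raise JunctionFormatError(f"{path}: expected 9 columns (sj_tab dialect)")
        out = [
            SpliceJunction(
                chrom=r.chrom,
                intron_start=int(r.start),
                intron_end=int(r.end),
                strand=_STAR_STRAND.get(int(r.strand), "."),
                motif_class=_STAR_MOTIF.get(int(r.motif), "other"),
                unique_reads=int(r.unique),
                annotated=bool(int(r.annotated)),
            )
            for r in df.itertuples(index=False)
        ]
    elif fmt == "bed6":
        names = ["chrom", "start", "end", "name", "score", "strand"]
        try:
            df = pd.read_csv(path, sep=r"\s+", header=None, names=names,
                             dtype={"chrom": str}, comment="#")
        except pd.errors.EmptyDataError:
            log.warning("junction file %s is empty", path)
            return []
        if df.shape[1] != 6 or df[["start", "end"]].isna().any().any():
            raise JunctionFormatError(f"{path}: expected 6 columns (bed6 dialect)")
        out = [
            SpliceJunction(
                chrom=r.chrom,
                intron_start=int(r.start) + 1,  # BED is 0-based half-open
                intron_end=int(r.end),
                strand=str(r.strand) if str(r.strand) in "+-" else ".",
                motif_class="GT/AG",  # BED6 carries no motif; assume canonical
                unique_reads=int(r.score),
                annotated=False,
            )
            for r in df.itertuples(index=False)
        ]
    else:
        raise JunctionFormatError(f"unknown junction dialect {fmt!r}")
    return sorted(out, key=lambda j: (j.chrom, j.intron_start, j.intron_end))


def write_junctions_sj_tab(junctions, path) -> None:
    rev_motif = {"other": 0, "GT/AG": 1, "GC/AG": 3}
    rev_strand = {".": 0, "+": 1, "-": 2}
    with open(path, "w") as fh:
        for j in junctions:
            motif = rev_motif[j.motif_class]
            if j.strand == "-" and motif:
                motif += 1
            fh.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t"
                f"{rev_strand[j.strand]}\t{motif}\t{int(j.annotated)}\t"
                f"{j.unique_reads}\t0\t50\n"
            )


def filter_junctions(
    junctions, min_unique: dict[str, int] | None = None
) -> list[SpliceJunction]:
    """Keep junctions whose unique-read support meets the per-motif-class
    minimum (defaults: GT/AG 2, GC/AG 2, other 6)."""
    minima = dict(DEFAULT_MIN_UNIQUE)
    if min_unique:
        minima.update(min_unique)
    return [j for j in junctions if j.unique_reads >= minima[j.motif_class]]


def detect_pseudoexon_events(
    junctions,
    gene: GeneModel,
    length_range: tuple[int, int] = (50, 300),
    inclusion_reads_rule: str = "downstream",
) -> tuple[list[PseudoexonEvent], list[SpliceJunction]]:
    """Find paired novel junctions defining pseudoexon inclusions.

    For each annotated intron of the gene, looks for two unannotated
    junctions: one sharing the intron's donor side and one sharing its
    acceptor side, separated by a fully intronic internal segment whose
    length falls in ``length_range``.  Returns ``(events, incomplete)``
    where ``incomplete`` lists unpaired novel junctions touching an
    annotated splice site (reported, never called as events).

    ``inclusion_reads_rule`` selects the read count used as inclusion
    support: ``downstream`` (transcript-orientation downstream novel
    junction; the default) or ``min`` (minimum of the pair).
    """
    if inclusion_reads_rule not in ("downstream", "min"):
        raise ValueError(f"unknown inclusion_reads_rule {inclusion_reads_rule!r}")
    lo_len, hi_len = length_range
    relevant = [j for j in junctions if j.chrom == gene.chrom]
    for j in relevant:
        if j.strand not in (".", gene.strand) and not j.annotated:
            log.warning(
                "junction %s:%d-%d strand %s conflicts with gene %s strand %s",
                j.chrom, j.intron_start, j.intron_end, j.strand,
                gene.gene_id, gene.strand,
            )
    events: list[PseudoexonEvent] = []
    paired: set[SpliceJunction] = set()
    novel = [j for j in relevant if not j.annotated]
    for i in range(1, gene.n_introns + 1):
        s, e = gene.intron_genomic(i)
        canonical = [j for j in relevant if (j.intron_start, j.intron_end) == (s, e)]
        canonical_reads = sum(j.unique_reads for j in canonical)
        donor_side = [j for j in novel if j.intron_start == s and j.intron_end < e]
        acceptor_side = [j for j in novel if j.intron_end == e and j.intron_start > s]
        for j_left in donor_side:
            for j_right in acceptor_side:
                seg_start = j_left.intron_end + 1
                seg_end = j_right.intron_start - 1
                seg_len = seg_end - seg_start + 1
                if seg_len < lo_len or seg_len > hi_len:
                    continue
                # fully intronic by construction (inside intron i)
                up, down = (j_left, j_right) if gene.strand == "+" else (j_right, j_left)
                inclusion = (
                    down.unique_reads
                    if inclusion_reads_rule == "downstream"
                    else min(up.unique_reads, down.unique_reads)
                )
                events.append(
                    PseudoexonEvent(
                        upstream_junction=up,
                        downstream_junction=down,
                        segment_start=seg_start,
                        segment_end=seg_end,
                        segment_length=seg_len,
                        canonical_junction_reads=canonical_reads,
                        inclusion_reads=inclusion,
                        intron_index=i,
                    )
                )
                paired.add(j_left)
                paired.add(j_right)
    incomplete = [
        j
        for j in novel
        if j not in paired
        and any(
            j.intron_start == gene.intron_genomic(i)[0]
            or j.intron_end == gene.intron_genomic(i)[1]
            for i in range(1, gene.n_introns + 1)
        )
    ]
    return events, incomplete


@dataclass(frozen=True)
class PhaseCheckResult:
    alt_count: int
    ref_count: int
    other_count: int
    no_coverage: bool

    @property
    def alt_fraction(self) -> float | None:
        total = self.alt_count + self.ref_count + self.other_count
        return self.alt_count / total if total else None


def variant_phase_check(observations, variant) -> PhaseCheckResult:
    """Fraction of pseudoexon-supporting reads carrying the alt base.

    ``observations`` is a list of ``(read_id, base)`` pairs extracted from
    reads that span both the pseudoexon and the variant position (the
    variant lies inside the pseudoexon).  A fraction near 1 ties the
    variant allele to pseudoexon formation.
    """
    if not observations:
        return PhaseCheckResult(0, 0, 0, no_coverage=True)
    alt = ref = other = 0
    for _read_id, base in observations:
        b = base.upper()
        if b == variant.alt:
            alt += 1
        elif b == variant.ref:
            ref += 1
        else:
            other += 1
    return PhaseCheckResult(alt, ref, other, no_coverage=False)
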