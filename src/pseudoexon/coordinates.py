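"""Gene models and HGVS-style transcript coordinate arithmetic.

A :class:`GeneModel` is a single spliced transcript on a reference genome:
an ordered list of exons (genomic, 1-based inclusive, listed 5'->3' in
transcript orientation) plus the spliced-transcript coordinate of the
translation start.  All c./r. arithmetic — including intronic-offset
positions such as ``c.646-1806`` — is done in transcript orientation, so
minus-strand genes behave identically to plus-strand ones.

Coordinate conventions
----------------------
* genomic coordinates are 1-based inclusive everywhere inside the package;
  BED I/O converts to/from 0-based half-open at the file boundary only.
* ``c.1`` is the first base of the start codon, which need not sit in the
  first exon (APC, the motivating gene, starts translation in exon 2).
* an intronic position is written relative to its nearest exon edge:
  positions in the 5' half of an intron anchor to the upstream exon
  (``+n``), positions in the 3' half to the downstream exon (``-n``).
  The midpoint of an even-length intron anchors upstream; the middle base
  of an odd-length intron also anchors upstream.  The convention is
  deterministic and matches how deep-intronic variants are reported in the
  clinical literature (e.g. ``c.1408+731`` deep in an intron).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping


class CoordinateError(ValueError):
    """A position cannot be mapped on the given gene model."""


class HgvsParseError(ValueError):
    """A c./r./p. string does not conform to the supported grammar."""


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome sequence, 1-based inclusive, uppercase.

    ``genome`` may be a plain ``dict[str, str]`` or any object supporting
    ``genome[chrom][start:end]`` slicing (e.g. ``pyfaidx.Fasta``).
    """
    if start < 1 or end < start:
        raise CoordinateError(f"bad genomic interval {chrom}:{start}-{end}")
    seq = str(genome[chrom][start - 1 : end]).upper()
    if len(seq) != end - start + 1:
        raise CoordinateError(
            f"interval {chrom}:{start}-{end} extends past end of sequence"
        )
    return seq


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CdnaPosition:
    """A cDNA position with an optional intronic offset.

    ``anchor`` is the c. coordinate of the nearest exonic base; ``offset``
    is 0 for exonic positions, ``+n`` for n bases into the downstream
    intron and ``-n`` for n bases upstream of the anchor exon start.
    """

    anchor: int
    offset: int = 0

    def __post_init__(self):
        # negative anchors are 5'UTR positions (c.-n); there is no c.0
        if self.anchor == 0:
            raise CoordinateError("c.0 does not exist (numbering skips zero)")

    @property
    def is_exonic(self) -> bool:
        return self.offset == 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.anchor)
        return f"{self.anchor}{self.offset:+d}"


@dataclass(frozen=True)
class CdnaVariant:
    """A single-nucleotide substitution in c. notation (transcript strand)."""

    position: CdnaPosition
    ref: str
    alt: str

    def __post_init__(self):
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if allele not in ("A", "C", "G", "T"):
                raise HgvsParseError(
                    f"{name} allele {allele!r} is not a single ACGT base"
                )
        if self.ref == self.alt:
            raise HgvsParseError(f"ref and alt are both {self.ref!r}")

    def __str__(self) -> str:
        return f"c.{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class RnaChange:
    """An r.-notation insertion of intronic sequence between two exonic bases.

    ``last_exonic_before``/``first_exonic_after`` are the flanking exonic c.
    positions; ``inserted_start``/``inserted_end`` are the intronic
    boundaries of the inserted segment, transcript 5'->3'.
    """

    last_exonic_before: int
    first_exonic_after: int
    inserted_start: CdnaPosition
    inserted_end: CdnaPosition

    def __post_init__(self):
        if self.first_exonic_after != self.last_exonic_before + 1:
            raise CoordinateError(
                "insertion flanks must be consecutive exonic positions, got "
                f"{self.last_exonic_before} and {self.first_exonic_after}"
            )
        if self.inserted_start.is_exonic or self.inserted_end.is_exonic:
            raise CoordinateError("inserted boundaries must be intronic")

    def __str__(self) -> str:
        return (
            f"r.{self.last_exonic_before}_{self.first_exonic_after}"
            f"ins{self.inserted_start}_{self.inserted_end}"
        )


class GeneModel:
    """A single-transcript gene model anchored on a reference genome."""

    def __init__(
        self,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Iterable[tuple[int, int]],
        cds_start_c: int = 1,
    ):
        if strand not in ("+", "-"):
            raise CoordinateError(f"strand must be '+' or '-', got {strand!r}")
        exons = tuple((int(s), int(e)) for s, e in exons)
        if len(exons) < 1:
            raise CoordinateError("gene model needs at least one exon")
        for s, e in exons:
            if s > e:
                raise CoordinateError(f"exon {s}-{e} has start > end")
        # transcript order: ascending genomic for '+', descending for '-'
        key = [s for s, _ in exons]
        if strand == "+" and key != sorted(key):
            raise CoordinateError("plus-strand exons must ascend genomically")
        if strand == "-" and key != sorted(key, reverse=True):
            raise CoordinateError("minus-strand exons must descend genomically")
        # non-overlap and minimum intron length
        genomic_sorted = sorted(exons)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise CoordinateError("exons overlap")
            if s2 - e1 - 1 < 4:
                raise CoordinateError("introns must be at least 4 bp")
        self.gene_id = gene_id
        self.chrom = chrom
        self.strand = strand
        self.exons = exons
        self.cds_start_c = int(cds_start_c)
        if not (1 <= self.cds_start_c <= self.tx_length):
            raise CoordinateError(
                f"cds_start_c {cds_start_c} outside transcript (len {self.tx_length})"
            )

    # -- basic geometry -------------------------------------------------

    @cached_property
    def tx_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @cached_property
    def exon_tx_bounds(self) -> tuple[tuple[int, int], ...]:
        """(t_start, t_end) of each exon in spliced-transcript coordinates."""
        out, t = [], 0
        for s, e in self.exons:
            n = e - s + 1
            out.append((t + 1, t + n))
            t += n
        return tuple(out)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def intron_genomic(self, i: int) -> tuple[int, int]:
        """Genomic (ascending) bounds of intron ``i`` (1-based, between
        exon i and exon i+1 in transcript order)."""
        if not (1 <= i <= self.n_introns):
            raise CoordinateError(f"no intron {i} in a {len(self.exons)}-exon model")
        a, b = self.exons[i - 1], self.exons[i]
        if self.strand == "+":
            return a[1] + 1, b[0] - 1
        return b[1] + 1, a[0] - 1

    def intron_length(self, i: int) -> int:
        s, e = self.intron_genomic(i)
        return e - s + 1

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (ascending) span of the gene."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    # -- transcript <-> genome ------------------------------------------

    def t_to_g(self, t: int) -> int:
        if not (1 <= t <= self.tx_length):
            raise CoordinateError(f"transcript position {t} outside 1..{self.tx_length}")
        for (s, e), (ts, te) in zip(self.exons, self.exon_tx_bounds):
            if ts <= t <= te:
                if self.strand == "+":
                    return s + (t - ts)
                return e - (t - ts)
        raise AssertionError("unreachable")

    def g_to_t(self, g: int) -> int | None:
        """Transcript coordinate of an exonic genomic position, else None."""
        for (s, e), (ts, te) in zip(self.exons, self.exon_tx_bounds):
            if s <= g <= e:
                if self.strand == "+":
                    return ts + (g - s)
                return ts + (e - g)
        return None

    def c_to_t(self, c: int) -> int:
        if c == 0:
            raise CoordinateError("c.0 does not exist")
        t = c + self.cds_start_c - 1 if c > 0 else c + self.cds_start_c
        if not (1 <= t <= self.tx_length):
            raise CoordinateError(f"c.{c} outside transcript")
        return t

    def t_to_c(self, t: int) -> int:
        # positions upstream of the start codon take negative c. numbers
        c = t - self.cds_start_c + 1
        return c if c >= 1 else c - 1

    # -- c. (with offsets) <-> genome -----------------------------------

    def which_intron(self, g: int) -> int | None:
        """1-based intron index containing genomic position g, else None."""
        for i in range(1, self.n_introns + 1):
            s, e = self.intron_genomic(i)
            if s <= g <= e:
                return i
        return None

    def map_c_to_genomic(self, pos: CdnaPosition) -> int:
        """Map a CdnaPosition (possibly intronic) to a genomic coordinate."""
        t = self.c_to_t(pos.anchor)
        g_anchor = self.t_to_g(t)
        sign = 1 if self.strand == "+" else -1
        if pos.offset == 0:
            return g_anchor
        if pos.offset > 0:
            idx = self._exon_index_ending_at(t)
            if idx is None or idx == len(self.exons) - 1:
                raise CoordinateError(
                    f"c.{pos}: '+' offsets must anchor at an internal exon end"
                )
            if pos.offset > self.intron_length(idx + 1):
                raise CoordinateError(f"c.{pos}: offset exceeds intron length")
            return g_anchor + sign * pos.offset
        idx = self._exon_index_starting_at(t)
        if idx is None or idx == 0:
            raise CoordinateError(
                f"c.{pos}: '-' offsets must anchor at an internal exon start"
            )
        if -pos.offset > self.intron_length(idx):
            raise CoordinateError(f"c.{pos}: offset exceeds intron length")
        return g_anchor + sign * pos.offset

    def _exon_index_ending_at(self, t: int) -> int | None:
        for i, (_, te) in enumerate(self.exon_tx_bounds):
            if te == t:
                return i
        return None

    def _exon_index_starting_at(self, t: int) -> int | None:
        for i, (ts, _) in enumerate(self.exon_tx_bounds):
            if ts == t:
                return i
        return None

    def map_genomic_to_c(self, g: int) -> CdnaPosition:
        """Inverse of :meth:`map_c_to_genomic` over the gene span.

        Intronic positions anchor to the nearer exon; ties (even-length
        intron midpoint, odd-length middle base) anchor upstream.
        """
        lo, hi = self.span
        if not (lo <= g <= hi):
            raise CoordinateError(f"genomic position {g} outside gene span {lo}-{hi}")
        t = self.g_to_t(g)
        if t is not None:
            return CdnaPosition(self.t_to_c(t), 0)
        i = self.which_intron(g)
        if i is None:
            raise CoordinateError(f"genomic position {g} not in gene")
        s, e = self.intron_genomic(i)
        length = e - s + 1
        # distance into the intron from the upstream exon, transcript 5'->3'
        d5 = (g - s + 1) if self.strand == "+" else (e - g + 1)
        if d5 <= math.ceil(length / 2):
            anchor_t = self.exon_tx_bounds[i - 1][1]
            return CdnaPosition(self.t_to_c(anchor_t), d5)
        anchor_t = self.exon_tx_bounds[i][0]
        return CdnaPosition(self.t_to_c(anchor_t), -(length - d5 + 1))

    # -- sequence helpers ------------------------------------------------

    def tx_strand_base(self, genome, g: int) -> str:
        """Reference base at genomic position g, on the transcript strand."""
        base = fetch(genome, self.chrom, g, g)
        return base if self.strand == "+" else revcomp(base)

    def tx_strand_seq(self, genome, g_start: int, g_end: int) -> str:
        """Transcript-strand sequence of ascending genomic [g_start, g_end]."""
        seq = fetch(genome, self.chrom, g_start, g_end)
        return seq if self.strand == "+" else revcomp(seq)

    def spliced_mrna(self, genome) -> str:
        # exons are already in transcript order; each is revcomp'ed as needed
        return "".join(self.tx_strand_seq(genome, s, e) for s, e in self.exons)

    def check_variant_ref(self, genome, variant: CdnaVariant) -> None:
        g = self.map_c_to_genomic(variant.position)
        found = self.tx_strand_base(genome, g)
        if found != variant.ref:
            raise CoordinateError(
                f"{variant}: reference genome has {found!r} at the mapped "
                f"position {self.chrom}:{g} (transcript strand), not {variant.ref!r}"
            )

    def __repr__(self) -> str:
        return (
            f"GeneModel({self.gene_id!r}, {self.chrom!r}, {self.strand!r}, "
            f"{len(self.exons)} exons, tx_length={self.tx_length})"
        )


def genome_with_substitution(
    genome: Mapping[str, str], model: GeneModel, variant: CdnaVariant
) -> dict[str, str]:
    """A copy of the genome carrying the variant's alternate allele.

    The variant's alleles are in transcript orientation; the written base is
    complemented for minus-strand genes.  The reference allele is verified.
    """
    model.check_variant_ref(genome, variant)
    g = model.map_c_to_genomic(variant.position)
    base = variant.alt if model.strand == "+" else revcomp(variant.alt)
    out = {name: str(genome[name][:]) for name in genome}
    seq = out[model.chrom]
    out[model.chrom] = seq[: g - 1] + base + seq[g:]
    return out


# ---------------------------------------------------------------------------
# HGVS parsing / formatting
# ---------------------------------------------------------------------------

_ANCHOR_RE = re.compile(r"\d+")
_SIGNED_RE = re.compile(r"[+-]\d+")


def _parse_cdna_position(text: str) -> tuple[CdnaPosition, str]:
    """Parse a leading ``<anchor>[(+|-)<offset>]`` token; return remainder."""
    m = _ANCHOR_RE.match(text)
    if not m:
        raise HgvsParseError(f"expected a numeric anchor at {text!r}")
    anchor = int(m.group())
    rest = text[m.end():]
    offset = 0
    if rest[:1] in ("+", "-"):
        m2 = _SIGNED_RE.match(rest)
        if not m2:
            bad = rest.split(">")[0] or rest
            raise HgvsParseError(f"malformed intronic offset token {bad!r}")
        offset = int(m2.group())
        if offset == 0:
            raise HgvsParseError("intronic offset must be non-zero")
        rest = rest[m2.end():]
    return CdnaPosition(anchor, offset), rest


def parse_hgvs_c(text: str) -> CdnaVariant:
    """Parse a substitution like ``c.646-1806T>G`` or ``c.100A>T``.

    Only single-nucleotide substitutions are supported (the full HGVS
    grammar — dup/del/delins — is out of scope).
    """
    s = text.strip()
    if not s.startswith("c."):
        raise HgvsParseError(f"{text!r}: missing 'c.' prefix")
    pos, rest = _parse_cdna_position(s[2:])
    m = re.fullmatch(r"([A-Za-z])>([A-Za-z])", rest)
    if not m:
        raise HgvsParseError(f"{text!r}: expected '<ref>><alt>' after position, got {rest!r}")
    ref, alt = m.group(1).upper(), m.group(2).upper()
    for allele in (ref, alt):
        if allele not in "ACGT":
            raise HgvsParseError(f"{text!r}: non-ACGT allele {allele!r}")
    return CdnaVariant(pos, ref, alt)


def format_hgvs_c(variant: CdnaVariant) -> str:
    return str(variant)


def parse_hgvs_r(text: str) -> RnaChange:
    """Parse an intronic-insertion r. description like
    ``r.645_646ins646-1933_646-1807``."""
    s = text.strip()
    if not s.startswith("r."):
        raise HgvsParseError(f"{text!r}: missing 'r.' prefix")
    m = re.fullmatch(r"(\d+)_(\d+)ins(.+)_([0-9+\-]+)", s[2:])
    if not m:
        raise HgvsParseError(f"{text!r}: not an '<a>_<b>ins<start>_<end>' insertion")
    left, right = int(m.group(1)), int(m.group(2))
    start_pos, rest = _parse_cdna_position(m.group(3))
    if rest:
        raise HgvsParseError(f"{text!r}: trailing characters {rest!r} in insertion start")
    end_pos, rest = _parse_cdna_position(m.group(4))
    if rest:
        raise HgvsParseError(f"{text!r}: trailing characters {rest!r} in insertion end")
    return RnaChange(left, right, start_pos, end_pos)


def format_hgvs_r(change: RnaChange) -> str:
    return str(change)


# ---------------------------------------------------------------------------
# arithmetic on r. insertions and codons
# ---------------------------------------------------------------------------

def insertion_length(change: RnaChange, model: GeneModel | None = None) -> int:
    """Length in bp of the inserted intronic segment.

    Without a gene model both boundaries must be anchored with offsets of
    the same sign (the usual published form, e.g. ``646-1933`` to
    ``646-1807``); with a model, any pair of intronic boundaries in the
    same intron is accepted and the length is measured genomically.
    """
    a, b = change.inserted_start, change.inserted_end
    if model is not None:
        ga = model.map_c_to_genomic(a)
        gb = model.map_c_to_genomic(b)
        ia, ib = model.which_intron(ga), model.which_intron(gb)
        if ia is None or ib is None or ia != ib:
            raise CoordinateError(
                f"{change}: insertion boundaries are not in the same intron"
            )
        n = abs(gb - ga) + 1
    else:
        if (a.offset > 0) != (b.offset > 0) or a.anchor != b.anchor:
            raise CoordinateError(
                f"{change}: boundaries use different anchors; a gene model is "
                "needed to measure the insertion"
            )
        n = b.offset - a.offset + 1
    if n < 1:
        raise CoordinateError(f"{change}: insertion start lies 3' of insertion end")
    return n


def codon_of(c_pos: int) -> tuple[int, int]:
    """Codon index and phase (1..3) of an exonic coding position.

    ``codon = ceil(c/3)``; phase 1 is the first base of a codon.
    """
    if c_pos < 1:
        raise CoordinateError(f"coding position must be >= 1, got {c_pos}")
    codon = (c_pos + 2) // 3
    phase = (c_pos - 1) % 3 + 1
    return codon, phase
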