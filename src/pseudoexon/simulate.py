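"""Seeded generators for every input the pipeline consumes.

The generators emulate a pseudoexon-discovery study on a dominant polyposis
gene: a multi-exon coding gene with canonical splice sites at every border,
a deep-intronic substitution that activates a cryptic splice donor next to
a pre-existing cryptic acceptor (creating a 50–300 bp pseudoexon), RNA
splice-junction tables showing partial intronic inclusion, allelic count
tables showing reduced expression of the mutant allele, and dominant or
sporadic pedigrees.  Every generator is a pure function of its
configuration and seed, and each planted scenario carries a
:class:`TruthRecord` with the exact planted boundaries.

Two donor-creation scenarios are provided:

* ``gt_gain`` — an intronic substitution creates the ``gt`` dinucleotide of
  a GT-class donor with a strong context (recognisable by the motif scan);
* ``exonic_ag_gain_gc_donor`` — a substitution on the exonic side of the
  new donor creates ``AG/`` before a ``gc`` dinucleotide whose context sits
  below the GC threshold; the motif scan alone misses it, and the call must
  be rescued by RNA-junction evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coordinates import CdnaPosition, CdnaVariant, GeneModel, revcomp
from .junctions import SpliceJunction
from .ase import AllelicCount
from .evidence import Individual, Pedigree, SampleCall, VariantRecord
from .splice import (
    SpliceSiteModel,
    default_splice_model,
    donor_gain_scan,
    predict_pseudoexon,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

DONOR_CONSENSUS_INTRON = "gtaagt".upper()  # gtragt with r = a
ACCEPTOR_CONSENSUS_INTRON = "tttttttttttcag".upper()  # poly(y) n y a g


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticGene:
    """A generated gene model plus its reference genome."""

    model: GeneModel
    genome: dict[str, str]

    def copy(self) -> "SyntheticGene":
        return SyntheticGene(self.model, dict(self.genome))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted pseudoexon scenario."""

    gene_id: str
    scenario: str  # gt_gain | exonic_ag_gain_gc_donor
    intron_index: int
    variant: CdnaVariant
    variant_g: int  # genomic position
    variant_ref_fwd: str  # plus-strand alleles, for VCF
    variant_alt_fwd: str
    pe_start_g: int  # genomic coordinate of the tx-5' pseudoexon boundary
    pe_end_g: int
    pe_start: CdnaPosition
    pe_end: CdnaPosition
    pe_length: int
    donor_class: str  # GT | GC
    variant_in_pseudoexon: bool
    motif_detectable: bool

    def pe_genomic_ascending(self) -> tuple[int, int]:
        return min(self.pe_start_g, self.pe_end_g), max(self.pe_start_g, self.pe_end_g)


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _random_bases(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _random_nonstop_codons(rng, n: int) -> str:
    codons = sorted(
        a + b + c
        for a in _BASES for b in _BASES for c in _BASES
        if a + b + c not in STOP_CODONS
    )
    return "".join(rng.choice(codons, size=n))


def make_gene(
    n_exons: int = 6,
    exon_len_range: tuple[int, int] = (90, 180),
    intron_len_range: tuple[int, int] = (700, 1800),
    seed: int = 0,
    gene_id: str = "GENE1",
    chrom: str = "chrS",
    strand: str = "+",
    utr5_len: int = 9,
    utr3_min: int = 60,
    pad: int = 100,
) -> SyntheticGene:
    """Generate a multi-exon coding gene with canonical splice sites.

    The CDS is internally stop-free (codons drawn from the 61 non-stop
    codons; a terminal TAA is appended) and every exon/intron border
    carries the full donor/acceptor consensus, so all annotated sites score
    100 under the shipped splice model.  Deterministic under ``seed``.
    """
    if n_exons < 3:
        raise GenerationError("need at least 3 exons")
    if intron_len_range[0] < 400:
        raise GenerationError("introns must allow deep-intronic planting (>= 400 bp)")
    if exon_len_range[0] < max(30, utr3_min + 10, utr5_len + 10):
        raise GenerationError("exon length range too small for UTR placement")
    rng = np.random.default_rng(seed)
    exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, n_exons)
    intron_lens = rng.integers(
        intron_len_range[0], intron_len_range[1] + 1, n_exons - 1
    )
    total_ex = int(exon_lens.sum())
    # transcript coordinates of exon bounds
    tx_bounds, t = [], 0
    for n in exon_lens:
        tx_bounds.append((t + 1, t + int(n)))
        t += int(n)
    # CDS: starts after the 5'UTR, terminal stop wholly inside the last exon
    cds_start_t = utr5_len + 1
    last_ts, last_te = tx_bounds[-1]
    cds_end_t = last_te - utr3_min
    cds_len = cds_end_t - cds_start_t + 1
    cds_len -= cds_len % 3
    if cds_len < 30:
        raise GenerationError("gene too short for a coding sequence")
    cds_end_t = cds_start_t + cds_len - 1
    if cds_end_t - 2 <= last_ts:
        raise GenerationError("terminal stop codon would overlap the last exon start")

    n_codons = cds_len // 3
    tx_seq = list(
        _random_bases(rng, utr5_len)
        + "ATG"
        + _random_nonstop_codons(rng, n_codons - 2)
        + "TAA"
        + _random_bases(rng, total_ex - cds_end_t)
    )
    assert len(tx_seq) == total_ex

    # force border bases: AG at internal exon ends, G at exon starts 2..n
    forced: set[int] = set(range(cds_start_t - 1, cds_start_t + 2))  # protect ATG
    forced |= {cds_end_t - 3, cds_end_t - 2, cds_end_t - 1}  # protect terminal TAA
    for (ts, te) in tx_bounds[:-1]:
        if te - 1 in forced or te in forced:
            raise GenerationError("exon border collides with start/stop codon")
        tx_seq[te - 2], tx_seq[te - 1] = "A", "G"
        forced |= {te - 1, te}
    for (ts, te) in tx_bounds[1:]:
        if ts in forced:
            raise GenerationError("exon border collides with start/stop codon")
        tx_seq[ts - 1] = "G"
        forced.add(ts)

    # repair any stop codons created by the border overwrites
    for ci in range(1, n_codons - 1):
        t0 = cds_start_t + 3 * ci  # 1-based transcript coord of codon base 1
        codon = "".join(tx_seq[t0 - 1 : t0 + 2])
        if codon in STOP_CODONS:
            for k in range(3):
                if (t0 + k) in forced:
                    continue
                for b in _BASES:
                    trial = codon[:k] + b + codon[k + 1 :]
                    if trial not in STOP_CODONS:
                        tx_seq[t0 - 1 + k] = b
                        codon = trial
                        break
                if codon not in STOP_CODONS:
                    break
            if codon in STOP_CODONS:
                raise GenerationError("could not repair an internal stop codon")

    # assemble the transcript-oriented genomic sequence
    parts = [_random_bases(rng, pad)]
    exon_g_tx = []  # exon bounds in transcript-oriented genomic coords
    g = pad
    for i, (ts, te) in enumerate(tx_bounds):
        exon_seq = "".join(tx_seq[ts - 1 : te])
        parts.append(exon_seq)
        exon_g_tx.append((g + 1, g + len(exon_seq)))
        g += len(exon_seq)
        if i < n_exons - 1:
            ilen = int(intron_lens[i])
            interior = _random_bases(rng, ilen - 20)
            intron_seq = DONOR_CONSENSUS_INTRON + interior + ACCEPTOR_CONSENSUS_INTRON
            parts.append(intron_seq)
            g += ilen
    parts.append(_random_bases(rng, pad))
    seq_tx = "".join(parts)

    if strand == "+":
        genome = {chrom: seq_tx}
        exons = exon_g_tx
    else:
        L = len(seq_tx)
        genome = {chrom: revcomp(seq_tx)}
        exons = [(L - b + 1, L - a + 1) for a, b in exon_g_tx]
    model = GeneModel(gene_id, chrom, strand, exons, cds_start_c=cds_start_t)
    return SyntheticGene(model, genome)


# ---------------------------------------------------------------------------
# pseudoexon planting
# ---------------------------------------------------------------------------

def _intron_u2g(model: GeneModel, i: int):
    s, e = model.intron_genomic(i)
    length = e - s + 1
    if model.strand == "+":
        return length, (lambda u: s + u - 1)
    return length, (lambda u: e - u + 1)


def _set_tx_bases(genome: dict[str, str], model: GeneModel,
                  edits: list[tuple[int, str]]) -> None:
    """Apply (genomic position, transcript-strand base) edits in place."""
    chrom = model.chrom
    seq = bytearray(genome[chrom], "ascii")
    for g, base in edits:
        b = base.upper() if model.strand == "+" else revcomp(base.upper())
        seq[g - 1] = ord(b)
    genome[chrom] = seq.decode("ascii")


def plant_pseudoexon_variant(
    gene: SyntheticGene,
    intron_index: int,
    pe_length: int,
    scenario: str = "gt_gain",
    seed: int = 0,
    splice_model: SpliceSiteModel | None = None,
    length_range: tuple[int, int] = (50, 300),
    max_retries: int = 30,
) -> tuple[SyntheticGene, TruthRecord]:
    """Plant a cryptic acceptor + near-donor pair and the activating variant.

    The cryptic acceptor (polypyrimidine tract + ``ag``) is written into
    the reference intron at the 5' pseudoexon boundary; the donor at the 3'
    boundary becomes viable only under a single substitution.  The planted
    configuration is verified to be unique — for ``gt_gain`` the motif
    pipeline must recover exactly the planted boundaries; for the GC-donor
    scenario the motif scan must stay empty — otherwise the intron interior
    is resampled (bounded retries).
    """
    if scenario not in ("gt_gain", "exonic_ag_gain_gc_donor"):
        raise GenerationError(f"unknown scenario {scenario!r}")
    if not (length_range[0] <= pe_length <= length_range[1]):
        raise GenerationError(
            f"pe_length {pe_length} outside configured range {length_range}"
        )
    model = gene.model
    sm = splice_model or default_splice_model()
    rng = np.random.default_rng(seed)
    length, u2g = _intron_u2g(model, intron_index)
    margin = 25  # keep the pseudoexon clear of the canonical splice sites
    u_start_min = max(15, margin)
    u_end_max = length - 6 - margin
    if u_start_min + pe_length - 1 > u_end_max:
        raise GenerationError(
            f"intron {intron_index} (length {length}) too short for a "
            f"{pe_length} bp pseudoexon"
        )

    for _attempt in range(max_retries):
        work = gene.copy()
        u_end = int(rng.integers(u_start_min + pe_length - 1, u_end_max + 1))
        u_start = u_end - pe_length + 1

        edits: list[tuple[int, str]] = []
        # cryptic acceptor: 14-mer consensus upstream of the pseudoexon,
        # plus a G as the pseudoexon's first base
        for k, b in enumerate(ACCEPTOR_CONSENSUS_INTRON):
            edits.append((u2g(u_start - 14 + k), b))
        edits.append((u2g(u_start), "G"))

        if scenario == "gt_gain":
            # ref donor region AG|gAaagt; the A>T at +2 creates AG|gtaagt
            donor_ref = ["A", "G", "G", "A", "A", "A", "G", "T"]
            var_u, var_ref, var_alt = u_end + 2, "A", "T"
            donor_class, motif_detectable, variant_in_pe = "GT", True, False
        else:
            # ref donor region cG|gcacgt; the c>A at the last-but-one
            # pseudoexon base creates AG|gc... with a degraded context that
            # stays below the GC threshold (motif scan misses it)
            donor_ref = ["C", "G", "G", "C", "A", "C", "G", "T"]
            var_u, var_ref, var_alt = u_end - 1, "C", "A"
            donor_class, motif_detectable, variant_in_pe = "GC", False, True
        for k, b in enumerate(donor_ref):
            edits.append((u2g(u_end - 1 + k), b))
        _set_tx_bases(work.genome, model, edits)

        g_var = u2g(var_u)
        variant = CdnaVariant(model.map_genomic_to_c(g_var), var_ref, var_alt)
        pe_start_g, pe_end_g = u2g(u_start), u2g(u_end)
        # only the acceptor tract and donor octamer are sacrosanct; the
        # pseudoexon interior is random filler and may be edited
        protected = {u2g(u) for u in range(u_start - 14, u_start + 1)}
        protected |= {u2g(u) for u in range(u_end - 1, u_end + 7)}

        # uniqueness: degrade accidental above-threshold acceptors (their
        # obligatory 'ag') until the planted boundaries are the only call
        ok = False
        for _round in range(10):
            calls = predict_pseudoexon(model, variant, work.genome, sm, length_range)
            if scenario == "gt_gain":
                extras = [
                    c for c in calls
                    if (c.pe_start_g, c.pe_end_g) != (pe_start_g, pe_end_g)
                ]
                if not extras and len(calls) == 1:
                    ok = True
                    break
                degraded = False
                for c in extras:
                    # the accidental acceptor's -1 'g', one base tx-5' of
                    # its pseudoexon start
                    sign = 1 if model.strand == "+" else -1
                    g_deg = c.pe_start_g - sign
                    if g_deg in protected:
                        continue
                    _set_tx_bases(work.genome, model, [(g_deg, "T")])
                    degraded = True
                if not degraded:
                    break
            else:
                ok = not donor_gain_scan(model, variant, work.genome, sm)
                break
        if not ok:
            # resample the intron interior (sparing the canonical splice
            # consensus at both ends, either strand) and retry
            gene = gene.copy()
            s, e = model.intron_genomic(intron_index)
            positions = range(s + 14, e - 13)
            interior = list(
                zip(positions, rng.choice(list(_BASES), size=len(positions)))
            )
            _set_tx_bases(gene.genome, model, interior)
            continue

        if model.strand == "+":
            ref_fwd, alt_fwd = var_ref, var_alt
        else:
            ref_fwd, alt_fwd = revcomp(var_ref), revcomp(var_alt)
        truth = TruthRecord(
            gene_id=model.gene_id,
            scenario=scenario,
            intron_index=intron_index,
            variant=variant,
            variant_g=g_var,
            variant_ref_fwd=ref_fwd,
            variant_alt_fwd=alt_fwd,
            pe_start_g=pe_start_g,
            pe_end_g=pe_end_g,
            pe_start=model.map_genomic_to_c(pe_start_g),
            pe_end=model.map_genomic_to_c(pe_end_g),
            pe_length=pe_length,
            donor_class=donor_class,
            variant_in_pseudoexon=variant_in_pe,
            motif_detectable=motif_detectable,
        )
        return work, truth
    raise GenerationError(
        f"could not plant a unique pseudoexon in intron {intron_index} after "
        f"{max_retries} attempts; try another seed"
    )


def apply_variant_to_genome(gene: SyntheticGene, truth: TruthRecord) -> dict[str, str]:
    """Genome carrying the alternate allele (the mutant haplotype)."""
    genome = dict(gene.genome)
    _set_tx_bases(genome, gene.model, [(truth.variant_g, truth.variant.alt)])
    return genome


# ---------------------------------------------------------------------------
# junction simulation
# ---------------------------------------------------------------------------

def simulate_junctions(
    gene: SyntheticGene,
    truths: list[tuple[TruthRecord, float]],
    depth: int,
    seed: int,
) -> list[SpliceJunction]:
    """Simulate a junction table for one sample.

    ``truths`` pairs each pseudoexon-bearing scenario active in this sample
    with its inclusion level psi; canonical junction reads for an affected
    intron are Binomial(depth, 1-psi) and each flanking novel junction is
    an independent Binomial(depth, psi).  An empty ``truths`` list yields a
    control sample (canonical junctions only).
    """
    if depth < 1:
        raise GenerationError("depth must be >= 1")
    model = gene.model
    rng = np.random.default_rng(seed)
    psi_by_intron = {t.intron_index: (t, psi) for t, psi in truths}
    strand = model.strand
    out = []
    for i in range(1, model.n_introns + 1):
        s, e = model.intron_genomic(i)
        t_psi = psi_by_intron.get(i)
        psi = t_psi[1] if t_psi else 0.0
        canon_reads = int(rng.binomial(depth, 1.0 - psi))
        out.append(
            SpliceJunction(model.chrom, s, e, strand, "GT/AG", canon_reads, True)
        )
        if t_psi is None or psi <= 0.0:
            continue
        truth = t_psi[0]
        lo, hi = truth.pe_genomic_ascending()
        motif_down = "GT/AG" if truth.donor_class == "GT" else "GC/AG"
        if strand == "+":
            j_up = (s, lo - 1, "GT/AG")
            j_down = (hi + 1, e, motif_down)
        else:
            j_up = (hi + 1, e, "GT/AG")
            j_down = (s, lo - 1, motif_down)
        for (js, je, motif) in (j_up, j_down):
            reads = int(rng.binomial(depth, psi))
            if reads > 0:
                out.append(
                    SpliceJunction(model.chrom, js, je, strand, motif, reads, False)
                )
    return sorted(out, key=lambda j: (j.chrom, j.intron_start, j.intron_end))


def simulate_phase_observations(
    truth: TruthRecord, n_reads: int, seed: int, error_rate: float = 0.0
) -> list[tuple[str, str]]:
    """Per-read base observations at the variant position, drawn from
    pseudoexon-supporting reads (alt base on every read, minus errors)."""
    rng = np.random.default_rng(seed)
    obs = []
    for i in range(n_reads):
        if error_rate > 0 and rng.random() < error_rate:
            base = str(rng.choice([b for b in _BASES if b != truth.variant.alt]))
        else:
            base = truth.variant.alt
        obs.append((f"read{i + 1}", base))
    return obs


# ---------------------------------------------------------------------------
# allelic counts, pedigrees
# ---------------------------------------------------------------------------

def simulate_allelic_counts(
    R_true: float,
    n_snps: int,
    depth: int,
    seed: int,
    sample: str = "S1",
    gene_id: str = "GENE1",
) -> list[AllelicCount]:
    """Allelic count table at heterozygous SNPs for one sample.

    gDNA allele-1 counts are Binomial(depth, 0.5); cDNA allele-1 counts are
    Binomial(depth, R/(1+R)), so the expected cDNA/gDNA allelic ratio is
    ``R_true``.  ``depth = 0`` yields uninformative records.
    """
    if R_true <= 0:
        raise GenerationError("R_true must be positive")
    if n_snps < 1:
        raise GenerationError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    p1 = R_true / (1.0 + R_true)
    out = []
    for k in range(n_snps):
        g1 = int(rng.binomial(depth, 0.5)) if depth else 0
        c1 = int(rng.binomial(depth, p1)) if depth else 0
        out.append(
            AllelicCount(
                sample=sample,
                snp_id=f"snp{k + 1}",
                gene_id=gene_id,
                gdna_a1=g1,
                gdna_a2=depth - g1,
                cdna_a1=c1,
                cdna_a2=depth - c1,
            )
        )
    return out


def simulate_pedigree(
    n_affected: int,
    n_unaffected: int,
    mode: str = "dominant",
    seed: int = 0,
    family_id: str = "FAM1",
) -> tuple[Pedigree, dict[str, str]]:
    """A nuclear pedigree plus carrier genotypes for the causal variant.

    ``dominant``: an affected founder transmits the variant; every affected
    member is a heterozygous carrier and every unaffected member a
    non-carrier (full penetrance).  ``sporadic``: a single affected carrier
    (de novo) with unaffected non-carrier parents.
    """
    if n_affected < 1:
        raise GenerationError("need at least one affected individual")
    rng = np.random.default_rng(seed)
    inds: list[Individual] = []
    genotypes: dict[str, str] = {}

    if mode == "dominant":
        father = Individual(f"{family_id}-F", None, None, "male", True)
        mother = Individual(f"{family_id}-M", None, None, "female", False)
        inds += [father, mother]
        genotypes[father.iid] = "het"
        genotypes[mother.iid] = "hom_ref"
        n_aff_children = n_affected - 1
        n_unaff_children = max(0, n_unaffected - 1)
        for k in range(n_aff_children + n_unaff_children):
            affected = k < n_aff_children
            sex = "male" if rng.random() < 0.5 else "female"
            child = Individual(
                f"{family_id}-C{k + 1}", father.iid, mother.iid, sex, affected
            )
            inds.append(child)
            genotypes[child.iid] = "het" if affected else "hom_ref"
    elif mode == "sporadic":
        father = Individual(f"{family_id}-F", None, None, "male", False)
        mother = Individual(f"{family_id}-M", None, None, "female", False)
        index = Individual(f"{family_id}-1", father.iid, mother.iid,
                           "male" if rng.random() < 0.5 else "female", True)
        inds += [father, mother, index]
        genotypes = {father.iid: "hom_ref", mother.iid: "hom_ref",
                     index.iid: "het"}
        for k in range(max(0, n_unaffected - 2)):
            sib = Individual(
                f"{family_id}-S{k + 1}", father.iid, mother.iid,
                "male" if rng.random() < 0.5 else "female", False,
            )
            inds.append(sib)
            genotypes[sib.iid] = "hom_ref"
    else:
        raise GenerationError(f"unknown pedigree mode {mode!r}")
    return Pedigree(family_id, tuple(inds)), genotypes


# ---------------------------------------------------------------------------
# full-cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentEvent:
    """A splice event with no underlying genomic change (seen in controls
    too, like recurrent low-level in-frame inclusions)."""

    intron_index: int
    lo: int
    hi: int
    donor_class: str = "GT"

    def pe_genomic_ascending(self) -> tuple[int, int]:
        return self.lo, self.hi


@dataclass
class FamilySim:
    family_id: str
    mode: str  # dominant | sporadic
    truth: TruthRecord | None
    pedigree: Pedigree
    index_sample: str
    variants: list[VariantRecord]
    junctions: list[SpliceJunction]  # index individual's RNA sample
    counts: list[AllelicCount]
    phase_observations: list[tuple[str, str]] | None


@dataclass
class CohortSim:
    gene: SyntheticGene
    families: list[FamilySim]
    control_junctions: dict[str, list[SpliceJunction]]
    frequencies: dict[tuple, float]
    latent_event: LatentEvent | None


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _background_variants(
    gene: SyntheticGene,
    rng,
    splice_model: SpliceSiteModel,
    samples: list[str],
    index_sample: str,
    avoid: list[tuple[int, int]],
    frequencies: dict[tuple, float],
) -> list[VariantRecord]:
    """Benign background variants exercising each WGS filter.

    One common SNV, one low-depth, one low-quality, one homozygous, and one
    rare heterozygous passer that is verified to create no donor gain.
    """
    model = gene.model
    lo, hi = model.span

    def pick_position() -> tuple[int, str, str]:
        for _ in range(200):
            g = int(rng.integers(lo + 20, hi - 20))
            if model.which_intron(g) is None:
                continue
            if any(a - 30 <= g <= b + 30 for a, b in avoid):
                continue
            ref_tx = model.tx_strand_base(gene.genome, g)
            alt_tx = str(rng.choice([b for b in _BASES if b != ref_tx]))
            return g, ref_tx, alt_tx
        raise GenerationError("could not place a background variant")

    def record(g, ref_tx, alt_tx, genotype_by_sample, dp, gq, af):
        if model.strand == "+":
            ref_f, alt_f = ref_tx, alt_tx
        else:
            ref_f, alt_f = revcomp(ref_tx), revcomp(alt_tx)
        calls = tuple(
            (s, SampleCall(genotype_by_sample.get(s, "hom_ref"), dp, gq))
            for s in samples
        )
        if af is not None:
            frequencies[(model.chrom, g, ref_f, alt_f)] = af
        return VariantRecord(model.chrom, g, ref_f, alt_f, calls, af)

    out = []
    # common variant: filtered by MAF
    g, r, a = pick_position()
    out.append(record(g, r, a, {index_sample: "het"}, 40, 99, 0.05))
    # low depth: filtered by DP
    g, r, a = pick_position()
    out.append(record(g, r, a, {index_sample: "het"}, 5, 99, None))
    # low genotype quality: filtered by GQ
    g, r, a = pick_position()
    out.append(record(g, r, a, {index_sample: "het"}, 40, 50, None))
    # homozygous: filtered by het-only rule
    g, r, a = pick_position()
    out.append(record(g, r, a, {s: "hom_alt" for s in samples}, 40, 99, None))
    # rare heterozygous passer with no splice consequence
    for _ in range(50):
        g, r, a = pick_position()
        cand = CdnaVariant(model.map_genomic_to_c(g), r, a)
        if not donor_gain_scan(model, cand, gene.genome, splice_model):
            out.append(record(g, r, a, {s: "het" for s in samples}, 40, 99, None))
            break
    else:
        raise GenerationError("could not place an inert rare variant")
    return out


def simulate_cohort(
    n_families: int = 54,
    n_carriers: int = 3,
    seed: int = 0,
    junction_depth: int = 120,
    inclusion_psi: float = 0.3,
    latent_psi: float = 0.08,
    ase_depth: int = 80,
    n_snps: int = 4,
    R_carrier: float = 0.6,
    n_controls: int = 3,
    splice_model: SpliceSiteModel | None = None,
) -> CohortSim:
    """Simulate a mutation-negative polyposis cohort with planted carriers.

    One shared disease gene is generated; ``n_carriers`` families receive a
    planted pseudoexon-activating variant (cycling through a dominant
    GT-gain family, a sporadic GT-gain family, and a sporadic GC-donor
    family requiring junction rescue).  All families receive background
    variants exercising the WGS filters, junction tables (with a low-level
    latent in-frame event shared with healthy controls), allelic counts
    (carriers at ``R_carrier``, others balanced), and pedigrees.
    """
    if not (0 <= n_carriers <= n_families):
        raise GenerationError("n_carriers must be between 0 and n_families")
    sm = splice_model or default_splice_model()
    seeds = _spawn_seeds(seed, 6 + 3 * n_families + n_controls)
    seed_iter = iter(seeds)

    gene = make_gene(n_exons=7, seed=next(seed_iter))
    model = gene.model

    # carrier scenarios, cycled; each gets its own intron
    scenario_cycle = [
        ("dominant", "gt_gain", 83),
        ("sporadic", "gt_gain", 127),
        ("sporadic", "exonic_ag_gain_gc_donor", 83),
    ]
    truths: list[TruthRecord] = []
    carrier_modes: list[str] = []
    available_introns = list(range(2, model.n_introns + 1))
    for k in range(n_carriers):
        mode, scenario, pe_len = scenario_cycle[k % len(scenario_cycle)]
        intron = available_introns[k % len(available_introns)]
        gene, truth = plant_pseudoexon_variant(
            gene, intron, pe_len, scenario, seed=next(seed_iter), splice_model=sm
        )
        truths.append(truth)
        carrier_modes.append(mode)

    # a latent 54-bp in-frame inclusion present in everyone at low level
    li = model.n_introns
    s, e = model.intron_genomic(li)
    if model.strand == "+":
        latent = LatentEvent(li, s + 150, s + 150 + 53)
    else:
        latent = LatentEvent(li, e - 150 - 53, e - 150)

    rng = np.random.default_rng(next(seed_iter))
    frequencies: dict[tuple, float] = {}
    avoid = [t.pe_genomic_ascending() for t in truths]
    avoid.append((min(latent.lo, latent.hi) , max(latent.lo, latent.hi)))

    families: list[FamilySim] = []
    for k in range(n_families):
        fam_id = f"FAM{k + 1:03d}"
        fam_seed = next(seed_iter)
        fam_rng = np.random.default_rng(fam_seed)
        is_carrier = k < n_carriers
        truth = truths[k] if is_carrier else None
        mode = carrier_modes[k] if is_carrier else (
            "dominant" if fam_rng.random() < 0.25 else "sporadic"
        )
        n_aff = 4 if (is_carrier and mode == "dominant") else (
            int(fam_rng.integers(2, 5)) if mode == "dominant" else 1
        )
        n_unaff = int(fam_rng.integers(1, 4))
        pedigree, causal_gts = simulate_pedigree(
            n_aff, n_unaff, mode, seed=next(seed_iter), family_id=fam_id
        )
        # genotyped (WGS) samples: all members in dominant families with a
        # carrier; index only in sporadic families
        if mode == "dominant":
            samples = [i.iid for i in pedigree.individuals]
        else:
            samples = [pedigree.affected_ids()[0]]
        index_sample = pedigree.affected_ids()[0]

        variants = _background_variants(
            gene, fam_rng, sm, samples, index_sample, avoid, frequencies
        )
        if is_carrier:
            calls = tuple(
                (s2, SampleCall(causal_gts.get(s2, "missing"),
                                int(fam_rng.integers(20, 60)), 99))
                for s2 in samples
            )
            variants.append(
                VariantRecord(
                    model.chrom, truth.variant_g, truth.variant_ref_fwd,
                    truth.variant_alt_fwd, calls, None,
                )
            )

        active = ([(truth, inclusion_psi)] if is_carrier else []) + [
            (latent, latent_psi)
        ]
        junctions = simulate_junctions(gene, active, junction_depth,
                                       seed=next(seed_iter))
        counts = simulate_allelic_counts(
            R_carrier if is_carrier else 1.0, n_snps, ase_depth,
            seed=fam_seed, sample=index_sample, gene_id=model.gene_id,
        )
        phase_obs = (
            simulate_phase_observations(truth, 20, seed=fam_seed)
            if is_carrier and truth.variant_in_pseudoexon
            else None
        )
        families.append(
            FamilySim(
                family_id=fam_id, mode=mode, truth=truth, pedigree=pedigree,
                index_sample=index_sample, variants=variants,
                junctions=junctions, counts=counts,
                phase_observations=phase_obs,
            )
        )

    controls = {
        f"CTRL{c + 1}": simulate_junctions(
            gene, [(latent, latent_psi)], junction_depth, seed=next(seed_iter)
        )
        for c in range(n_controls)
    }
    return CohortSim(gene, families, controls, frequencies, latent)
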