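"""Readers and writers for the standard formats the pipeline consumes.

Gene annotation comes in as GFF3 (via gffutils) or BED12; genomes as FASTA
(plain dict in memory, or indexed via pyfaidx); variants as VCF (via
pysam) or HGVS c. strings; pedigrees as 6-column PED; population
frequencies as a two-column TSV.  Genomic coordinates are 1-based
inclusive everywhere inside the package; BED conversion happens here and
nowhere else.
"""

from __future__ import annotations

import gffutils
import pandas as pd
import pysam
from pyfaidx import Fasta

from .coordinates import GeneModel
from .evidence import (
    EvidenceError,
    Individual,
    Pedigree,
    SampleCall,
    VariantRecord,
)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_fasta(path) -> Fasta:
    """Indexed FASTA access (creates the .fai on first use)."""
    return Fasta(str(path), sequence_always_upper=True)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(gene: GeneModel, path, source: str = "pseudoexon") -> None:
    """Write a gene/mRNA/exon/CDS feature set for a single-transcript model."""
    exons_g = sorted(gene.exons)
    lo, hi = gene.span
    tid = f"{gene.gene_id}.t1"
    # CDS genomic intervals: transcript positions cds_start..tx_length
    cds_rows = []
    for (s, e), (ts, te) in zip(gene.exons, gene.exon_tx_bounds):
        cs, ce = max(ts, gene.cds_start_c), te
        if cs > ce:
            continue
        if gene.strand == "+":
            cds_rows.append((s + (cs - ts), s + (ce - ts)))
        else:
            cds_rows.append((e - (ce - ts), e - (cs - ts)))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"{gene.chrom}\t{source}\tgene\t{lo}\t{hi}\t.\t{gene.strand}\t.\t"
            f"ID={gene.gene_id}\n"
        )
        fh.write(
            f"{gene.chrom}\t{source}\tmRNA\t{lo}\t{hi}\t.\t{gene.strand}\t.\t"
            f"ID={tid};Parent={gene.gene_id}\n"
        )
        for n, (s, e) in enumerate(exons_g, 1):
            fh.write(
                f"{gene.chrom}\t{source}\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={tid}.exon{n};Parent={tid}\n"
            )
        for n, (s, e) in enumerate(sorted(cds_rows), 1):
            fh.write(
                f"{gene.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{gene.strand}\t0\t"
                f"ID={tid}.cds{n};Parent={tid}\n"
            )


def read_gff3(path, gene_id: str | None = None) -> GeneModel:
    """Build a GeneModel from GFF3 exon/CDS features of one transcript."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = [f for f in db.features_of_type("gene")]
    if gene_id is not None:
        genes = [g for g in genes if g.id == gene_id]
    if len(genes) != 1:
        raise EvidenceError(
            f"{path}: expected exactly one matching gene, found {len(genes)}"
        )
    g = genes[0]
    exons = sorted(
        (f.start, f.end)
        for f in db.children(g, featuretype="exon")
    )
    cds = sorted(
        (f.start, f.end)
        for f in db.children(g, featuretype="CDS")
    )
    if not exons:
        raise EvidenceError(f"{path}: gene {g.id} has no exon features")
    strand = g.strand
    tx_exons = exons if strand == "+" else exons[::-1]
    model_wo_cds = GeneModel(g.id, g.seqid, strand, tx_exons, cds_start_c=1)
    if cds:
        cds_start_g = cds[0][0] if strand == "+" else cds[-1][1]
        t = model_wo_cds.g_to_t(cds_start_g)
        if t is None:
            raise EvidenceError(f"{path}: CDS start not inside an exon")
        return GeneModel(g.id, g.seqid, strand, tx_exons, cds_start_c=t)
    return model_wo_cds


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def write_bed12(gene: GeneModel, path) -> None:
    exons_g = sorted(gene.exons)
    lo, hi = gene.span
    chrom_start = lo - 1  # 0-based half-open conversion happens here only
    block_sizes = ",".join(str(e - s + 1) for s, e in exons_g)
    block_starts = ",".join(str(s - 1 - chrom_start) for s, _ in exons_g)
    # thickStart/thickEnd: genomic extent from c.1 to the transcript end
    # (GeneModel stores only the translation start, not a CDS end)
    t_first = gene.cds_start_c
    g_first = gene.t_to_g(t_first)
    g_last = gene.t_to_g(gene.tx_length)
    thick_lo, thick_hi = min(g_first, g_last), max(g_first, g_last)
    with open(path, "w") as fh:
        fh.write(
            "\t".join(
                map(
                    str,
                    [
                        gene.chrom, chrom_start, hi, gene.gene_id, 0,
                        gene.strand, thick_lo - 1, thick_hi, 0,
                        len(exons_g), block_sizes, block_starts,
                    ],
                )
            )
            + "\n"
        )


def read_bed12(path) -> GeneModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) != 1:
        raise EvidenceError(f"{path}: expected exactly one BED12 record")
    f = lines[0].split("\t")
    if len(f) < 12:
        raise EvidenceError(f"{path}: BED12 needs 12 columns, got {len(f)}")
    chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
    thick_start = int(f[6])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    exons = [
        (chrom_start + st + 1, chrom_start + st + sz)
        for st, sz in zip(starts, sizes)
    ]
    tx_exons = exons if strand == "+" else exons[::-1]
    model = GeneModel(name, chrom, strand, tx_exons, cds_start_c=1)
    cds_start_g = thick_start + 1 if strand == "+" else int(f[7])
    t = model.g_to_t(cds_start_g)
    if t is None:
        raise EvidenceError(f"{path}: thickStart/thickEnd not inside an exon")
    return GeneModel(name, chrom, strand, tx_exons, cds_start_c=t)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(records: list[VariantRecord], samples: list[str], path,
              contigs: dict[str, int] | None = None) -> None:
    """Write substitutions with per-sample GT/DP/GQ to an uncompressed VCF."""
    gt_code = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = "." if rec.population_af is None else f"AF={rec.population_af:g}"
            cols = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS",
                    info, "GT:DP:GQ"]
            for s in samples:
                c = rec.call_for(s)
                if c is None:
                    cols.append("./.:0:0")
                else:
                    cols.append(f"{gt_code[c.genotype]}:{c.depth}:{c.genotype_quality}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path, population_af: dict[tuple, float] | None = None) -> list[VariantRecord]:
    """Read substitutions (ACGT single-nucleotide only) from a VCF.

    Population frequencies are taken from the ``AF`` INFO field when
    present, otherwise looked up in ``population_af`` keyed by
    (chrom, pos, ref, alt); missing in both leaves the frequency unknown.
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                continue
            calls = []
            for s in samples:
                sd = rec.samples[s]
                gt = sd.get("GT")
                if gt is None or any(a is None for a in gt):
                    genotype = "missing"
                elif set(gt) == {0}:
                    genotype = "hom_ref"
                elif set(gt) == {1}:
                    genotype = "hom_alt"
                else:
                    genotype = "het"
                calls.append(
                    (s, SampleCall(genotype, int(sd.get("DP") or 0),
                                   int(sd.get("GQ") or 0)))
                )
            af = rec.info.get("AF")
            if af is not None:
                af = float(af[0] if isinstance(af, tuple) else af)
            elif population_af is not None:
                af = population_af.get((rec.chrom, rec.pos, ref, alt))
            out.append(
                VariantRecord(rec.chrom, rec.pos, ref, alt, tuple(calls), af)
            )
    return out


# ---------------------------------------------------------------------------
# PED and frequency tables
# ---------------------------------------------------------------------------

_SEX = {"1": "male", "2": "female"}


def write_ped(pedigree: Pedigree, path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in pedigree.individuals:
            fh.write(
                "\t".join(
                    [
                        pedigree.family_id, ind.iid, ind.father or "0",
                        ind.mother or "0", sex_code[ind.sex],
                        "2" if ind.affected else "1",
                    ]
                )
                + "\n"
            )


def read_ped(path) -> Pedigree:
    individuals, family_ids = [], set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise EvidenceError(f"{path}: PED rows need 6 columns")
            family_ids.add(f[0])
            individuals.append(
                Individual(
                    iid=f[1],
                    father=None if f[2] == "0" else f[2],
                    mother=None if f[3] == "0" else f[3],
                    sex=_SEX.get(f[4], "unknown"),
                    affected=f[5] == "2",
                )
            )
    if len(family_ids) != 1:
        raise EvidenceError(f"{path}: expected one family, found {sorted(family_ids)}")
    return Pedigree(family_ids.pop(), tuple(individuals))


def read_frequency_table(path) -> dict[tuple, float]:
    """Local population-frequency table: chrom, pos, ref, alt, af (TSV)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"chrom", "pos", "ref", "alt", "af"}
    if not needed <= set(df.columns):
        raise EvidenceError(f"{path}: frequency table needs columns {sorted(needed)}")
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): float(r.af)
        for r in df.itertuples(index=False)
    }


def write_frequency_table(freqs: dict[tuple, float], path) -> None:
    df = pd.DataFrame(
        [(c, p, r, a, af) for (c, p, r, a), af in sorted(freqs.items())],
        columns=["chrom", "pos", "ref", "alt", "af"],
    )
    df.to_csv(path, sep="\t", index=False)
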