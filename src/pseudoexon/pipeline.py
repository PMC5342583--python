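"""Pipeline orchestration: ASE -> junction evidence -> splice/transcript
prediction -> variant evidence, per family and across a cohort.

The stages are pure dataflow: each consumes the previous stage's outputs
and the shared gene model/genome, and nothing mutates another stage's
inputs.  The same functions serve the in-memory API (simulated cohorts)
and the file-based CLI.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .ase import AseResult, gene_ase_test
from .coordinates import (
    CdnaVariant,
    CoordinateError,
    GeneModel,
    genome_with_substitution,
    revcomp,
)
from .effects import ProteinChange, apply_pseudoexon, classify_protein_effect, nmd_flag
from .evidence import (
    EvidenceReport,
    FilterConfig,
    Pedigree,
    VariantRecord,
    aggregate_evidence,
    cosegregation_check,
    evidence_report_text,
    filter_variants,
)
from .junctions import (
    PseudoexonEvent,
    SpliceJunction,
    detect_pseudoexon_events,
    filter_junctions,
)
from .splice import (
    PseudoexonCall,
    SpliceSiteModel,
    call_from_boundaries,
    default_splice_model,
    predict_pseudoexon,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and modes for every stage; defaults are the package's
    documented study conditions."""

    # splice model
    donor_threshold_gt: float = 70.0
    donor_threshold_gc: float = 85.0
    acceptor_threshold: float = 65.0
    pe_length_min: int = 50
    pe_length_max: int = 300
    # junction evidence
    min_unique_gtag: int = 2
    min_unique_gcag: int = 2
    min_unique_other: int = 6
    inclusion_reads_rule: str = "downstream"
    rescue_flank: int = 8  # bp around the event within which a variant can drive rescue
    # ASE
    ase_min_coverage: int = 10
    ase_min_snps: int = 2
    ase_q_ase: float = 0.05
    ase_q_borderline: float = 0.15
    # WGS filters
    min_depth: int = 7
    min_genotype_quality: int = 70
    max_maf: float = 0.001
    dominant_shared: bool = True  # applied to multi-sample (dominant) families
    # reproducibility
    seed: int = 0

    def splice_model(self) -> SpliceSiteModel:
        return default_splice_model(
            donor_threshold_gt=self.donor_threshold_gt,
            donor_threshold_gc=self.donor_threshold_gc,
            acceptor_threshold=self.acceptor_threshold,
        )

    def length_range(self) -> tuple[int, int]:
        return (self.pe_length_min, self.pe_length_max)

    def junction_minima(self) -> dict[str, int]:
        return {
            "GT/AG": self.min_unique_gtag,
            "GC/AG": self.min_unique_gcag,
            "other": self.min_unique_other,
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class FamilyInputs:
    """Everything the pipeline needs for one family."""

    family_id: str
    pedigree: Pedigree
    index_sample: str
    variants: list[VariantRecord]
    junctions: list[SpliceJunction]
    counts: list  # AllelicCount for the index sample
    mode: str = "sporadic"  # dominant | sporadic


@dataclass
class FamilyResult:
    family_id: str
    ase_result: AseResult | None
    events: list[PseudoexonEvent]
    reports: list[tuple[VariantRecord, EvidenceReport]]
    calls: dict[tuple, PseudoexonCall]
    protein_changes: dict[tuple, ProteinChange]
    nmd: dict[tuple, bool]

    def supported(self) -> list[VariantRecord]:
        return [v for v, r in self.reports if r.tier == "supported"]


def _event_bounds(ev: PseudoexonEvent) -> tuple[int, int]:
    return (ev.segment_start, ev.segment_end)


def control_event_set(
    control_junctions: dict[str, list[SpliceJunction]],
    gene: GeneModel,
    config: PipelineConfig,
) -> set[tuple[int, int]]:
    """Segment bounds of pseudoexon-like events seen in any control sample."""
    seen: set[tuple[int, int]] = set()
    for junctions in control_junctions.values():
        filtered = filter_junctions(junctions, config.junction_minima())
        events, _ = detect_pseudoexon_events(
            filtered, gene, config.length_range(), config.inclusion_reads_rule
        )
        seen.update(_event_bounds(e) for e in events)
    return seen


def _variant_to_cdna(
    gene: GeneModel, genome, rec: VariantRecord
) -> CdnaVariant | None:
    """Express a VCF-style (plus-strand) record in transcript orientation."""
    lo, hi = gene.span
    if rec.chrom != gene.chrom or not (lo <= rec.pos <= hi):
        return None
    ref_tx = rec.ref if gene.strand == "+" else revcomp(rec.ref)
    alt_tx = rec.alt if gene.strand == "+" else revcomp(rec.alt)
    try:
        pos = gene.map_genomic_to_c(rec.pos)
        variant = CdnaVariant(pos, ref_tx, alt_tx)
        gene.check_variant_ref(genome, variant)
    except (CoordinateError, ValueError):
        return None
    return variant


def run_family(
    gene: GeneModel,
    genome,
    inputs: FamilyInputs,
    config: PipelineConfig,
    control_events: set[tuple[int, int]] | None = None,
    population_af: dict[tuple, float] | None = None,
) -> FamilyResult:
    """Run every stage for one family and aggregate per-variant evidence."""
    sm = config.splice_model()
    control_events = control_events or set()
    population_af = population_af or {}

    # 1. ASE on the index sample's allelic counts
    ase_results = gene_ase_test(
        inputs.counts,
        min_coverage=config.ase_min_coverage,
        min_snps=config.ase_min_snps,
        q_ase=config.ase_q_ase,
        q_borderline=config.ase_q_borderline,
    )
    ase_result = next(
        (r for r in ase_results if r.gene_id == gene.gene_id), None
    )

    # 2. junction evidence
    filtered = filter_junctions(inputs.junctions, config.junction_minima())
    events, _incomplete = detect_pseudoexon_events(
        filtered, gene, config.length_range(), config.inclusion_reads_rule
    )
    causal_events = [e for e in events if _event_bounds(e) not in control_events]

    # 3. WGS-style variant filtering
    affected_sampled = tuple(
        i for i in inputs.pedigree.affected_ids()
        if any(rec.call_for(i) is not None for rec in inputs.variants)
    )
    fcfg = FilterConfig(
        min_depth=config.min_depth,
        min_genotype_quality=config.min_genotype_quality,
        max_maf=config.max_maf,
        index_sample=inputs.index_sample,
        dominant_shared=config.dominant_shared and inputs.mode == "dominant",
        affected_samples=affected_sampled,
    )
    surviving = filter_variants(inputs.variants, fcfg)

    # 4-6. per-variant: splice prediction, transcript effect, evidence
    reports, calls, changes, nmd_flags = [], {}, {}, {}
    for rec in surviving:
        af = rec.population_af
        if af is None:
            af = population_af.get(rec.key)
        variant = _variant_to_cdna(gene, genome, rec)
        call = None
        also_in_control = False
        if variant is not None:
            motif_calls = predict_pseudoexon(
                gene, variant, genome, sm, config.length_range()
            )
            if motif_calls:
                call = motif_calls[0]
                bounds = tuple(sorted((call.pe_start_g, call.pe_end_g)))
                if any(_event_bounds(e) == bounds for e in causal_events):
                    call = call.with_junction_support()
                also_in_control = bounds in control_events
            else:
                # RNA-evidence rescue: a junction-defined segment with the
                # variant inside it or immediately flanking its donor
                for ev in causal_events:
                    lo = ev.segment_start - config.rescue_flank
                    hi = ev.segment_end + config.rescue_flank
                    if lo <= rec.pos <= hi:
                        alt_genome = genome_with_substitution(genome, gene, variant)
                        call = call_from_boundaries(
                            gene, alt_genome, sm,
                            ev.segment_start, ev.segment_end,
                            variant, junction_supported=True,
                        )
                        break

        change = nmd = None
        if call is not None and variant is not None:
            alt_genome = genome_with_substitution(genome, gene, variant)
            mutant, rna_change = apply_pseudoexon(gene, call, alt_genome)
            wild = gene.spliced_mrna(genome)
            change = classify_protein_effect(
                wild, mutant, gene.cds_start_c, rna_change
            )
            nmd = nmd_flag(change, gene, rna_change) if change.has_ptc else False
            calls[rec.key] = call
            changes[rec.key] = change
            nmd_flags[rec.key] = nmd

        genotypes = {
            s: c.genotype for s, c in rec.calls
        }
        coseg = cosegregation_check(inputs.pedigree, genotypes)
        report = aggregate_evidence(
            variant=rec,
            pseudoexon_call=call,
            protein_change=change,
            cosegregation=coseg,
            population_af=af,
            ase_result=ase_result,
            also_in_control=also_in_control,
        )
        reports.append((rec, report))

    return FamilyResult(
        family_id=inputs.family_id,
        ase_result=ase_result,
        events=events,
        reports=reports,
        calls=calls,
        protein_changes=changes,
        nmd=nmd_flags,
    )


def run_cohort(cohort, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run the full pipeline over a simulated cohort; one row per surviving
    variant with its evidence tier."""
    config = config or PipelineConfig()
    gene = cohort.gene.model
    genome = cohort.gene.genome
    ctrl = control_event_set(cohort.control_junctions, gene, config)
    rows = []
    for fam in cohort.families:
        inputs = FamilyInputs(
            family_id=fam.family_id,
            pedigree=fam.pedigree,
            index_sample=fam.index_sample,
            variants=fam.variants,
            junctions=fam.junctions,
            counts=fam.counts,
            mode=fam.mode,
        )
        result = run_family(
            gene, genome, inputs, config,
            control_events=ctrl, population_af=cohort.frequencies,
        )
        for rec, report in result.reports:
            call = result.calls.get(rec.key)
            change = result.protein_changes.get(rec.key)
            rows.append(
                {
                    "family": fam.family_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "c_notation": (
                        str(_variant_to_cdna(gene, genome, rec) or "")
                    ),
                    "pe_start_g": call.pe_start_g if call else -1,
                    "pe_end_g": call.pe_end_g if call else -1,
                    "pe_length": call.length if call else 0,
                    "donor_class": call.donor_class if call else "",
                    "motif_supported": bool(call and call.motif_supported),
                    "junction_supported": bool(call and call.junction_supported),
                    "protein": change.notation if change else "",
                    "category": change.category if change else "",
                    "nmd": bool(result.nmd.get(rec.key, False)),
                    "cosegregation": report.cosegregation,
                    "population_absent": report.population_absent,
                    "ase_class": (
                        result.ase_result.rnaseq_class if result.ase_result else ""
                    ),
                    "tier": report.tier,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["family", "pos"]).reset_index(drop=True) if len(df) else df


def summarize_cohort(df: pd.DataFrame, n_families: int) -> dict:
    """Headline numbers of a cohort screen."""
    supported = df[df["tier"] == "supported"] if len(df) else df
    n_supported_families = supported["family"].nunique() if len(supported) else 0
    return {
        "families": n_families,
        "supported_variants": int(len(supported)),
        "supported_families": int(n_supported_families),
        "frequency_pct": 100.0 * n_supported_families / n_families,
    }


# ---------------------------------------------------------------------------
# file-based cohort layout (used by the CLI)
# ---------------------------------------------------------------------------

def write_cohort(cohort, out_dir) -> None:
    """Write a simulated cohort to disk in the pipeline's input layout:
    genome FASTA + GFF3 + BED12, per-family VCF/junction TSV/counts
    TSV/PED, control junction tables, a population-frequency table, and a
    truth JSON for later comparison."""
    import json

    from . import io as pio
    from .ase import write_allelic_counts
    from .junctions import write_junctions_sj_tab

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene = cohort.gene.model
    pio.write_fasta(cohort.gene.genome, out / "genome.fa")
    pio.write_gff3(gene, out / "gene.gff3")
    pio.write_bed12(gene, out / "gene.bed12")
    pio.write_frequency_table(cohort.frequencies, out / "frequencies.tsv")

    ctrl_dir = out / "controls"
    ctrl_dir.mkdir(exist_ok=True)
    for name in sorted(cohort.control_junctions):
        write_junctions_sj_tab(
            cohort.control_junctions[name], ctrl_dir / f"{name}.sj.tab"
        )

    truth = []
    for fam in cohort.families:
        fam_dir = out / "families" / fam.family_id
        fam_dir.mkdir(parents=True, exist_ok=True)
        samples = sorted({s for rec in fam.variants for s, _ in rec.calls})
        contigs = {gene.chrom: len(cohort.gene.genome[gene.chrom])}
        pio.write_vcf(fam.variants, samples, fam_dir / "variants.vcf", contigs)
        write_junctions_sj_tab(fam.junctions, fam_dir / "junctions.sj.tab")
        write_allelic_counts(fam.counts, fam_dir / "counts.tsv")
        pio.write_ped(fam.pedigree, fam_dir / "pedigree.ped")
        (fam_dir / "meta.json").write_text(
            json.dumps(
                {"mode": fam.mode, "index_sample": fam.index_sample},
                indent=2, sort_keys=True,
            )
            + "\n"
        )
        if fam.truth is not None:
            t = fam.truth
            truth.append(
                {
                    "family": fam.family_id,
                    "scenario": t.scenario,
                    "variant": str(t.variant),
                    "variant_g": t.variant_g,
                    "pe_start_g": t.pe_start_g,
                    "pe_end_g": t.pe_end_g,
                    "pe_length": t.pe_length,
                    "donor_class": t.donor_class,
                }
            )
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def load_family_inputs(fam_dir, population_af=None) -> FamilyInputs:
    import json

    from . import io as pio
    from .ase import read_allelic_counts
    from .junctions import read_junctions

    fam_dir = Path(fam_dir)
    meta = json.loads((fam_dir / "meta.json").read_text())
    pedigree = pio.read_ped(fam_dir / "pedigree.ped")
    return FamilyInputs(
        family_id=pedigree.family_id,
        pedigree=pedigree,
        index_sample=meta["index_sample"],
        variants=pio.read_vcf(fam_dir / "variants.vcf", population_af),
        junctions=read_junctions(fam_dir / "junctions.sj.tab", "sj_tab"),
        counts=read_allelic_counts(fam_dir / "counts.tsv"),
        mode=meta["mode"],
    )


def run_pipeline(cohort_dir, out_dir, config: PipelineConfig | None = None) -> dict:
    """File-based end-to-end run over a cohort directory.

    Reads the genome/annotation, control junction tables, frequency table
    and per-family inputs; writes an evidence TSV, per-family report text
    and a summary; returns the summary dict.  Identical inputs and config
    yield byte-identical outputs.
    """
    from . import io as pio
    from .junctions import read_junctions

    config = config or PipelineConfig()
    cohort_dir = Path(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for required in ("genome.fa", "gene.gff3", "families"):
        if not (cohort_dir / required).exists():
            raise FileNotFoundError(f"cohort directory lacks {required}")

    gene = pio.read_gff3(cohort_dir / "gene.gff3")
    fasta = pio.open_fasta(cohort_dir / "genome.fa")
    genome = {name: str(fasta[name][:]) for name in fasta.keys()}
    freq_path = cohort_dir / "frequencies.tsv"
    population_af = (
        pio.read_frequency_table(freq_path) if freq_path.exists() else {}
    )
    controls = {}
    ctrl_dir = cohort_dir / "controls"
    if ctrl_dir.is_dir():
        for p in sorted(ctrl_dir.glob("*.sj.tab")):
            controls[p.stem] = read_junctions(p, "sj_tab")
    ctrl_events = control_event_set(controls, gene, config)

    rows, texts = [], []
    fam_dirs = sorted((cohort_dir / "families").iterdir())
    for fam_dir in fam_dirs:
        inputs = load_family_inputs(fam_dir, population_af)
        result = run_family(
            gene, genome, inputs, config,
            control_events=ctrl_events, population_af=population_af,
        )
        for rec, report in result.reports:
            call = result.calls.get(rec.key)
            change = result.protein_changes.get(rec.key)
            rows.append(
                {
                    "family": inputs.family_id,
                    "chrom": rec.chrom, "pos": rec.pos,
                    "ref": rec.ref, "alt": rec.alt,
                    "pe_length": call.length if call else 0,
                    "protein": change.notation if change else "",
                    "nmd": bool(result.nmd.get(rec.key, False)),
                    "tier": report.tier,
                }
            )
            if report.tier == "supported":
                texts.append(
                    evidence_report_text(
                        report,
                        extra={
                            "family": inputs.family_id,
                            "protein": change.notation if change else "",
                        },
                    )
                )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["family", "pos"]).reset_index(drop=True)
    df.to_csv(out / "evidence.tsv", sep="\t", index=False)
    (out / "supported_reports.txt").write_text("\n\n".join(texts) + "\n")
    summary = summarize_cohort(
        df if len(df) else pd.DataFrame(columns=["family", "tier"]),
        n_families=len(fam_dirs),
    )
    (out / "summary.txt").write_text(
        "".join(f"{k}\t{v}\n" for k, v in sorted(summary.items()))
    )
    return summary
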