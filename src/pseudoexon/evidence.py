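"""Candidate-variant filtering and pathogenicity evidence aggregation.

The filters mirror a conservative germline short-variant workflow for a
dominant polyposis phenotype: minimum read depth 7, minimum genotype
quality 70 (Phred-scale difference between the two most likely genotypes,
capped at 99), common variants (population MAF >= 0.001) removed,
heterozygous-only in the index, with an optional dominant-inheritance mode
requiring the variant to be heterozygous in every affected genotyped
family member.

Evidence aggregation formalises the strands that support causality of a
pseudoexon-associated variant — predicted truncation, co-segregation with
disease, absence from the population, splice-motif or RNA-junction support
— into an explicit, deterministic tier.  The audit trail behind each tier
is reported; the tier rule itself is a package-defined formalisation, and
is labelled as such in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")
COSEGREGATION = ("complete", "incomplete", "not_assessable")
TIERS = ("supported", "uncertain", "unsupported")


class EvidenceError(ValueError):
    pass


@dataclass(frozen=True)
class SampleCall:
    genotype: str  # hom_ref | het | hom_alt | missing
    depth: int
    genotype_quality: int

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise EvidenceError(f"unknown genotype {self.genotype!r}")
        if self.depth < 0:
            raise EvidenceError("depth must be >= 0")
        if not (0 <= self.genotype_quality <= 99):
            raise EvidenceError("genotype quality must be in [0, 99]")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    calls: tuple[tuple[str, SampleCall], ...]  # (sample, call), ordered
    population_af: float | None = None  # None = unknown

    def __post_init__(self):
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise EvidenceError(
                f"{self.chrom}:{self.pos} alleles must be single ACGT bases"
            )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def call_for(self, sample: str) -> SampleCall | None:
        for s, c in self.calls:
            if s == sample:
                return c
        return None


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: str  # 'male' | 'female' | 'unknown'
    affected: bool


@dataclass(frozen=True)
class Pedigree:
    family_id: str
    individuals: tuple[Individual, ...]

    def __post_init__(self):
        ids = {i.iid for i in self.individuals}
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in ids:
                    raise EvidenceError(
                        f"{self.family_id}: parent {parent!r} of {ind.iid} unknown"
                    )
        if not any(i.affected for i in self.individuals):
            raise EvidenceError(f"{self.family_id}: pedigree has no affected member")

    def affected_ids(self) -> list[str]:
        return [i.iid for i in self.individuals if i.affected]

    def unaffected_ids(self) -> list[str]:
        return [i.iid for i in self.individuals if not i.affected]


@dataclass(frozen=True)
class EvidenceReport:
    variant: VariantRecord | None
    pseudoexon_call_present: bool
    motif_supported: bool
    junction_supported: bool
    truncating: bool
    cosegregation: str
    population_absent: bool
    ase_consistent: bool
    also_in_control: bool
    tier: str
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 7
    min_genotype_quality: int = 70
    max_maf: float = 0.001  # variants with MAF >= this are removed
    index_sample: str | None = None
    dominant_shared: bool = False  # require het in all affected genotyped samples
    affected_samples: tuple[str, ...] = ()
    region: tuple[str, int, int] | None = None  # chrom, start, end (1-based incl.)


def filter_variants(records, config: FilterConfig) -> list[VariantRecord]:
    """Apply depth/quality/frequency/inheritance filters.

    Keeps records with DP >= ``min_depth`` and GQ >= ``min_genotype_quality``
    in every analysed sample, population MAF < ``max_maf`` (unknown
    frequency passes, logged), heterozygous in the index sample, and — in
    ``dominant_shared`` mode — heterozygous in every affected genotyped
    sample.  Pure filter: idempotent and order-independent.
    """
    out = []
    for rec in records:
        if config.region is not None:
            chrom, start, end = config.region
            if rec.chrom != chrom or not (start <= rec.pos <= end):
                continue
        analysed = (
            [s for s, _ in rec.calls]
            if not config.dominant_shared
            else [s for s in config.affected_samples if rec.call_for(s) is not None]
        )
        if config.index_sample is not None and config.index_sample not in analysed:
            analysed.append(config.index_sample)
        calls = {s: rec.call_for(s) for s in analysed}
        if any(c is None for c in calls.values()):
            continue
        if any(c.depth < config.min_depth for c in calls.values()):
            continue
        if any(c.genotype_quality < config.min_genotype_quality for c in calls.values()):
            continue
        if rec.population_af is None:
            log.debug(
                "variant %s:%d %s>%s has unknown population frequency; kept",
                rec.chrom, rec.pos, rec.ref, rec.alt,
            )
        elif rec.population_af >= config.max_maf:
            continue
        if config.index_sample is not None:
            idx = calls[config.index_sample]
            if idx.genotype != "het":
                continue
        if config.dominant_shared:
            if not all(
                calls[s].genotype == "het" for s in config.affected_samples
                if s in calls
            ):
                continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# cosegregation
# ---------------------------------------------------------------------------

def cosegregation_check(
    pedigree: Pedigree,
    genotypes: dict[str, str],
    check_unaffected: bool = True,
) -> str:
    """Classify co-segregation of a variant with the affected status.

    ``complete``: every genotyped affected is a carrier and (unless
    ``check_unaffected`` is off, e.g. under reduced penetrance) every
    genotyped unaffected is a non-carrier.  ``not_assessable``: fewer than
    two genotyped affecteds.  ``incomplete`` otherwise.
    """
    known = {i.iid for i in pedigree.individuals}
    unknown = set(genotypes) - known
    if unknown:
        raise EvidenceError(
            f"genotypes reference unknown individuals: {sorted(unknown)}"
        )
    carriers = {"het", "hom_alt"}
    affected = [i for i in pedigree.affected_ids() if genotypes.get(i, "missing") != "missing"]
    unaffected = [
        i for i in pedigree.unaffected_ids() if genotypes.get(i, "missing") != "missing"
    ]
    if len(affected) < 2:
        return "not_assessable"
    ok = all(genotypes[i] in carriers for i in affected)
    if check_unaffected:
        ok = ok and all(genotypes[i] not in carriers for i in unaffected)
    return "complete" if ok else "incomplete"


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_evidence(
    variant: VariantRecord | None = None,
    pseudoexon_call=None,
    protein_change=None,
    cosegregation: str = "not_assessable",
    population_af: float | None = None,
    ase_result=None,
    also_in_control: bool = False,
) -> EvidenceReport:
    """Combine evidence strands into a deterministic pathogenicity tier.

    ``supported`` requires a truncating consequence, population absence,
    co-segregation complete or not assessable, and pseudoexon evidence
    (splice-motif or RNA-junction support), with the event absent from
    control samples.  An event also present in controls, or contradicted
    by segregation, is ``unsupported``; anything in between is
    ``uncertain``.  ASE consistency is advisory: it is reported but not
    required for ``supported``.
    """
    if cosegregation not in COSEGREGATION:
        raise EvidenceError(f"unknown cosegregation value {cosegregation!r}")
    call_present = pseudoexon_call is not None
    motif = bool(call_present and pseudoexon_call.motif_supported)
    junction = bool(call_present and pseudoexon_call.junction_supported)
    truncating = bool(
        protein_change is not None
        and protein_change.category in ("nonsense", "frameshift")
        and getattr(protein_change, "stop_offset", -1) >= 0
    )
    # absence means truly absent: frequency zero or never observed
    population_absent = population_af is None or population_af == 0.0
    ase_consistent = bool(
        ase_result is not None
        and (
            getattr(ase_result, "rnaseq_class", "none") in ("ASE", "borderline")
            or getattr(ase_result, "snupe_class", "none") in ("unequivocal", "putative")
        )
    )

    notes = []
    if also_in_control:
        notes.append("splice event also observed in control samples")
    if cosegregation == "incomplete":
        notes.append("variant does not fully co-segregate with disease")
    if call_present and not (motif or junction):
        notes.append("pseudoexon call lacks motif and junction support")

    if also_in_control or cosegregation == "incomplete":
        tier = "unsupported"
    elif (
        truncating
        and population_absent
        and cosegregation in ("complete", "not_assessable")
        and (motif or junction)
    ):
        tier = "supported"
    else:
        tier = "uncertain"

    return EvidenceReport(
        variant=variant,
        pseudoexon_call_present=call_present,
        motif_supported=motif,
        junction_supported=junction,
        truncating=truncating,
        cosegregation=cosegregation,
        population_absent=population_absent,
        ase_consistent=ase_consistent,
        also_in_control=also_in_control,
        tier=tier,
        notes=tuple(notes),
    )


def evidence_report_text(report: EvidenceReport, extra: dict | None = None) -> str:
    """Human-readable evidence block (the tier rule is an explicit
    formalisation, flagged as such)."""
    lines = ["Pathogenicity evidence report"]
    if report.variant is not None:
        v = report.variant
        lines.append(f"  variant: {v.chrom}:{v.pos} {v.ref}>{v.alt}")
    lines += [
        f"  pseudoexon call: {'yes' if report.pseudoexon_call_present else 'no'}"
        f" (motif {'+' if report.motif_supported else '-'},"
        f" junction {'+' if report.junction_supported else '-'})",
        f"  truncating consequence: {'yes' if report.truncating else 'no'}",
        f"  co-segregation: {report.cosegregation}",
        f"  absent from population: {'yes' if report.population_absent else 'no'}",
        f"  ASE consistent (advisory): {'yes' if report.ase_consistent else 'no'}",
        f"  seen in controls: {'yes' if report.also_in_control else 'no'}",
        f"  TIER: {report.tier}  [explicit formalisation of the evidence checklist]",
    ]
    for n in report.notes:
        lines.append(f"  note: {n}")
    for k, v in (extra or {}).items():
        lines.append(f"  {k}: {v}")
    return "\n".join(lines)


def reports_frame(reports: list[tuple[str, EvidenceReport]]) -> pd.DataFrame:
    rows = []
    for family, r in reports:
        v = r.variant
        rows.append(
            {
                "family": family,
                "chrom": v.chrom if v else "",
                "pos": v.pos if v else -1,
                "ref": v.ref if v else "",
                "alt": v.alt if v else "",
                "pseudoexon_call": r.pseudoexon_call_present,
                "motif_supported": r.motif_supported,
                "junction_supported": r.junction_supported,
                "truncating": r.truncating,
                "cosegregation": r.cosegregation,
                "population_absent": r.population_absent,
                "ase_consistent": r.ase_consistent,
                "also_in_control": r.also_in_control,
                "tier": r.tier,
            }
        )
    return pd.DataFrame(rows)
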