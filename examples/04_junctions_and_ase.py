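"""RNA-side evidence: detect a pseudoexon from splice-junction tables and
classify allele-specific expression from allelic counts."""

from pseudoexon import (
    classify_snupe,
    detect_pseudoexon_events,
    filter_junctions,
    gene_ase_test,
    make_gene,
    plant_pseudoexon_variant,
    simulate_allelic_counts,
    simulate_junctions,
    snupe_ratio,
    variant_phase_check,
)
from pseudoexon.simulate import simulate_phase_observations

syn, truth = plant_pseudoexon_variant(
    make_gene(seed=5), 2, 83, "exonic_ag_gain_gc_donor", seed=6
)

# carrier RNA sample: ~30% of transcripts include the pseudoexon
junctions = simulate_junctions(syn, [(truth, 0.3)], depth=120, seed=7)
events, incomplete = detect_pseudoexon_events(filter_junctions(junctions), syn.model)
for ev in events:
    print(f"pseudoexon event: segment {ev.segment_start}-{ev.segment_end} "
          f"({ev.segment_length} bp), inclusion {ev.inclusion_reads} vs "
          f"canonical {ev.canonical_junction_reads} reads "
          f"-> fraction {ev.inclusion_fraction:.2f}")

# the variant sits inside the pseudoexon: phase it against inclusion reads
obs = simulate_phase_observations(truth, n_reads=20, seed=8)
phase = variant_phase_check(obs, truth.variant)
print(f"variant base in pseudoexon reads: alt fraction "
      f"{phase.alt_fraction:.2f} ({phase.alt_count}/{phase.alt_count + phase.ref_count} reads)"
      " -> the mutant allele drives the inclusion")

# allelic counts at four het SNPs: the decayed allele halves its output
counts = simulate_allelic_counts(0.6, n_snps=4, depth=80, seed=9,
                                 gene_id=syn.model.gene_id)
best = min((snupe_ratio(c) for c in counts), key=lambda r: min(r, 1 / r))
print(f"\nSNuPE: most deviant allelic ratio R = {best:.2f} "
      f"-> {classify_snupe(best)} ASE")
(res,) = gene_ase_test(counts)
print(f"gene-level test: p = {res.p_value:.2e}, q = {res.q_value:.2e}, "
      f"class {res.rnaseq_class}")
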