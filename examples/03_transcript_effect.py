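"""Splice a predicted pseudoexon into the mRNA, classify the protein
consequence and apply the NMD rule."""

from pseudoexon import (
    apply_pseudoexon,
    classify_protein_effect,
    default_splice_model,
    make_gene,
    nmd_flag,
    plant_pseudoexon_variant,
    predict_pseudoexon,
)

sm = default_splice_model()
syn, truth = plant_pseudoexon_variant(
    make_gene(seed=5), intron_index=2, pe_length=83, scenario="gt_gain", seed=6
)
(call,) = predict_pseudoexon(syn.model, truth.variant, syn.genome, sm)

mutant_mrna, rna_change = apply_pseudoexon(syn.model, call, syn.genome)
wild_mrna = syn.model.spliced_mrna(syn.genome)
print(f"r. description : {rna_change}")
print(f"mRNA length    : {len(wild_mrna)} -> {len(mutant_mrna)} "
      f"(+{len(mutant_mrna) - len(wild_mrna)} bp)")

effect = classify_protein_effect(
    wild_mrna, mutant_mrna, syn.model.cds_start_c, rna_change
)
print(f"consequence    : {effect.category}, {effect.notation}")
if effect.has_ptc:
    nmd = nmd_flag(effect, syn.model, rna_change)
    print(f"NMD predicted  : {nmd} (premature stop "
          f"{'>=55' if nmd else '<55'} nt upstream of the final junction)")
    print("a decayed mutant transcript is what makes the allele "
          "under-expressed in blood (allele-specific expression)")
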