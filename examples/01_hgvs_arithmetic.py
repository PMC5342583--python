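"""Parse published deep-intronic variant descriptions and do the
coordinate arithmetic a molecular geneticist does at the desk."""

from pseudoexon import codon_of, insertion_length, parse_hgvs_c, parse_hgvs_r

# The three deep-intronic substitutions, as printed in a clinical report
for text in ("c.646-1806T>G", "c.1408+731C>T", "c.1408+729A>G"):
    v = parse_hgvs_c(text)
    print(f"{text}: anchor c.{v.position.anchor}, offset {v.position.offset:+d}, "
          f"{v.ref}>{v.alt}")

# The r. descriptions of the resulting pseudoexon inclusions
for text in ("r.645_646ins646-1933_646-1807", "r.1408_1409ins1408+647_1408+729"):
    change = parse_hgvs_r(text)
    print(f"{text}: inserts {insertion_length(change)} bp of intron between "
          f"c.{change.last_exonic_before} and c.{change.first_exonic_after}")

# Codon arithmetic: an insertion after c.645 whose first codon is a stop
# truncates translation at codon 216 (c.645 completes codon 215)
codon, phase = codon_of(645)
print(f"c.645 is base {phase} of codon {codon}; a codon-aligned stop directly "
      f"after it lands at codon {codon + 1}")

# The two intron-11 variants differ by exactly two offset positions
a = parse_hgvs_c("c.1408+731C>T").position.offset
b = parse_hgvs_c("c.1408+729A>G").position.offset
print(f"offsets +{a} and +{b} are {a - b} nt apart: two independent mutations "
      "activating the same cryptic donor")
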