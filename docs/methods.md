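# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data generators do and do not
emulate.

## Gene models and coordinate arithmetic

A gene is a single spliced transcript: ordered exons (genomic, 1-based
inclusive, transcript 5'→3') plus `cds_start_c`, the spliced-transcript
coordinate of the first base of the start codon.  `c.1` is therefore a
model parameter, not transcript base 1 — translation may start in any exon,
as it does in *APC* (exon 2).  All arithmetic is done in transcript
orientation, so minus-strand genes are handled by the same code paths.

Intronic positions are written relative to the nearest exon edge: `+n` into
the intron after the anchor exon, `-n` before it.  The inverse mapping
(genomic → c.) needs a tie rule the nomenclature leaves open: positions in
the 5' half of an intron anchor upstream, the 3' half downstream, and the
midpoint of an even-length intron (and the middle base of an odd-length
one) anchors upstream.  This is a convention, chosen for determinism; it
reproduces the way deep-intronic variants are customarily reported
(`c.1408+731` deep in a long intron, `c.646-1806` in the downstream half).
With it, `map_c_to_genomic` and `map_genomic_to_c` are mutually inverse
over the entire gene span (property-tested), with 5'UTR positions taking
negative anchors.

The supported HGVS surface is deliberately narrow: single-nucleotide
substitutions in c. notation and intronic-insertion r. descriptions.
`insertion_length` on an r. description is `end_offset − start_offset + 1`
when both boundaries share an anchor (the published form); with a gene
model any same-intron pair is measured genomically, and the two routes are
cross-checked in tests.

## Splice-site model

Donor and acceptor sites are scored with a per-position nucleotide weight
table in the Shapiro–Senapathy tradition, built directly from the textbook
consensus: donor `AG/gtragt` (8 nt: 2 exonic + 6 intronic), acceptor
`poly(y)nyag/G` (15 nt: 10 pyrimidines, any base, pyrimidine, `ag`, exonic
`G`).  Weights: the consensus base carries 0.79 and the other three bases
0.07 each; two-fold degenerate positions (r, y) give each member
(0.79+0.07)/2 = 0.43 so that every position still sums to 1; the `n`
position is uniform 0.25.  Scores are min–max normalised to 0–100%, so 100
means every position carries a maximal-weight base and the normalisation is
insensitive to fully degenerate positions.  This is a transparent,
hand-checkable substitute for black-box splice predictors; it is *not* a
trained model, and its absolute scores should not be compared with
neural-network "splice efficiency" percentages.

Donor viability is decided in two parts: the +1/+2 intronic dinucleotide
must be `GT` or `GC` (class membership is obligatory), and the *context*
score over the six remaining positions must reach the class threshold —
defaults 70% for GT and 85% for GC, both configurable.  Scoring the context
separately keeps GC donors from being penalised for their defining
dinucleotide while still demanding the stronger surroundings this rare
class needs.  The acceptor threshold defaults to 65% with `ag` at −2/−1
obligatory.  These thresholds are free parameters of the package, exposed
in the pipeline configuration; with the shipped weight table one
non-degenerate context mismatch costs 18.2 points, so the GT threshold
tolerates one mismatch (81.8) and the GC threshold none.

`donor_gain_scan` evaluates all eight donor frames overlapping a
substitution and reports windows where the alternate allele passes its
class threshold while the reference allele passes none — a reference window
that is already viable can never be a "gain".  `predict_pseudoexon` then
scans upstream of each gained donor, within the same intron, for acceptors
whose implied pseudoexon length falls in the configured 50–300 bp range,
emitting one call per (donor, acceptor) pair ranked by acceptor score.
A call can also be built from externally asserted boundaries
(`call_from_boundaries`): this is the RNA-evidence rescue path for
junction-corroborated pseudoexons whose motifs fail the thresholds, the
behaviour real GC-donor activations force on consensus-based predictors.

## Transcript and protein consequences

`apply_pseudoexon` splices the genomic segment (transcript strand) between
the flanking exons; `classify_protein_effect` translates wild-type and
mutant from the same start codon (standard code, table 1) and classifies by
first principles:

* the first residue differing from wild type is a stop → **nonsense**
  (`p.Arg216*`); this covers the codon-aligned insertion whose first codon
  is a stop — the stop is hit before frame matters;
* frame shifted and a stop downstream → **frameshift**, `p.Xxx<i>Yyyfs*N`
  with N counting the stop from the first changed residue as position 1
  (standard fs*N semantics; whether authors ever count from the insertion
  point instead is unknowable from printed tables, so the standard is
  used);
* insert length ≡ 0 (mod 3) with no stop introduced → **in-frame
  insertion**; an in-frame insert that nonetheless contains a stop deeper
  than the first changed residue is truncating and reported as nonsense
  with a `p.Xxx<i>ins*` notation.

The first-changed-residue rule matters in practice: an 83-bp insert after a
phase-1 boundary leaves the hybrid junction codon intact whenever the
insert's first base matches the wobble context, so the notation names the
*next* codon (the `Gly471` pattern).  A frameshift that runs off the end of
the transcript without terminating is reported with `fs*?` and a sentinel
stop offset of −1.

NMD is predicted with the exon-junction rule: decay iff the last base of
the premature stop lies at least 55 nt upstream of the final exon–exon
junction of the *mutant* transcript (the pseudoexon adds two junctions).
55 nt is the conventional upper figure of the 50–55 nt rule; the boundary
is strict (54 nt → no decay).  This is the mechanistic link between a
truncating pseudoexon and reduced expression of the mutant allele.

## Junction evidence

Junction tables are read in the STAR `SJ.out.tab` dialect (1-based
inclusive intron coordinates, motif codes mapped to GT/AG, GC/AG, other) or
as BED6 introns (converted from 0-based half-open at the boundary, nowhere
else).  Filtering keeps junctions with unique-read support at or above a
per-motif-class minimum — defaults 2 (GT/AG), 2 (GC/AG), 6 (other),
mirroring the stricter treatment non-canonical junctions get in RNA-seq
practice.

A pseudoexon *event* requires **both** flanking novel junctions: one
re-using an annotated donor, one re-using the next annotated acceptor, with
a fully intronic internal segment of 50–300 bp between them.  Unpaired
novel junctions are reported as incomplete candidates, never as events.
Inclusion depth is quantified as
`inclusion_reads / (inclusion_reads + canonical_reads)` with the
transcript-orientation downstream novel junction supplying the inclusion
reads (configurable to the minimum of the pair).  Junction depth displays
in the literature do not define such a ratio; this one is explicit and its
monotonicity in the simulated inclusion level ψ is property-tested.
Events whose segments also appear in control samples are annotated
`also-in-control` and excluded from causal pairing — recurrent low-level
in-frame inclusions with no genomic change do occur in healthy samples, and
the simulator plants one (54 bp) in every sample for exactly this reason.

## Allele-specific expression

The SNuPE ratio is `R = (cDNA a1/a2) / (gDNA a1/a2)`; gDNA normalisation
cancels primer and probe biases, and a per-SNP normalisation factor
(default 1.0) stands in for calibration against mutation-negative controls.
Classification bands are defined on the weaker-allele ratio
`min(R, 1/R)`: unequivocal ASE at ≤ 0.6 (a 40% reduction of one allele;
the reciprocal bound is conventionally printed as 1.67), putative in
(0.6, 0.8), and no ASE in the closed band [0.8, 1.25].  Defining the bands
symmetrically makes the classification invariant to allele labelling —
`classify(R) == classify(1/R)` exactly — at the cost of a sliver
(1.6667, 1.67) relative to the rounded printed threshold.  Gene-level SNuPE
status takes the SNP with the largest deviation.

The gene-level RNA-seq-style test is a deliberate simplification of
meta-analytic ASE callers (no pseudo-phasing, no overdispersion by
default): per heterozygous SNV (gDNA minor-allele fraction ≥ 0.2, cDNA
coverage ≥ 10; genes need ≥ 2 such SNVs) a two-sided exact binomial
**mid-p** against 0.5, folded to the sample-major allele; per gene the
per-SNV p-values are mapped to normal scores and combined with Stouffer's Z
(equal weights); across genes Benjamini–Hochberg q-values with classes ASE
(q < 0.05), borderline (0.05 < q ≤ 0.15), none.  Two numerical choices
matter: the mid-p correction keeps the per-SNV p close to uniform despite
binomial discreteness, and doubling *before* combination (rather than
after) is what makes the combined statistic calibrate — folded one-sided
p-values are bounded by ~0.5 and cannot be combined and then doubled.
Normal scores are clipped at |z| = 8.2 (beyond double precision
resolution).  Calibration is verified by Monte Carlo in the test suite at
the cohort's allelic-count depth of 80: the null p < 0.05 rate over 1000
two-SNV genes must fall inside the binomial 95% interval around 0.05.  An
optional mean-1/2 beta-binomial null (``dispersion`` parameter, the
intraclass correlation) is available for overdispersed allelic counts and
off by default (pure binomial).

Monte-Carlo side calculations: at depth d the sampling sd of log R̂ is
approximately √(8/d) for the four-count ratio, i.e. 0.127 at d = 500 and
0.089 at d = 1000.  The no-ASE band [0.8, 1.25] has log half-width 0.223,
so balanced truth is classified "none" ~92% of the time at depth 500 and
~99% at depth 1000; the "large-depth" classification check therefore
simulates at 1000, while median-recovery checks (bias, not spread) use 500.

## Variant evidence

WGS-style filters, applied per analysed sample: depth ≥ 7, genotype
quality ≥ 70 (Phred-scale difference of the two most likely genotypes,
0–99), population MAF < 0.001 with unknown frequency passing (logged),
heterozygous in the index; `dominant_shared` mode additionally requires
heterozygosity in every affected genotyped member.  All boundaries are
closed exactly as stated (DP 7 kept, GQ 69 removed, MAF 0.001 removed) and
the filter is a pure set operation — idempotent and order-independent.
Population absence for *evidence* is stricter than the filter: frequency
exactly 0 or absent from the local frequency table (which replaces live
population-database queries).

Co-segregation: `complete` iff every genotyped affected is a carrier and
every genotyped unaffected a non-carrier (the unaffected check can be
relaxed under a reduced-penetrance reading); `not_assessable` with fewer
than two genotyped affecteds — the situation of sporadic index cases;
`incomplete` otherwise.

The evidence tier is an explicit formalisation (and is labelled as such in
reports) of four strands: truncating consequence, population absence,
co-segregation, and pseudoexon support (motif *or* junction).
`supported` requires all four with co-segregation complete or not
assessable; an event also seen in controls, or contradicted by
segregation, is `unsupported`; everything else `uncertain`.  ASE
consistency is advisory — reported but not required — because a real
carrier's ASE can fall short of significance while the variant is
causal.  The tier is monotone: removing any single strand never raises it.

## Synthetic data: what it emulates, and what not

Generators are pure functions of (configuration, seed).  `make_gene` draws
exon lengths (90–180 bp) and intron lengths (700–1800 bp; ≥ 400 required so
"deep intronic" means something), writes the full donor/acceptor consensus
at every border (all annotated sites score 100), and builds a stop-free CDS
(codons drawn from the 61 non-stop codons, ATG start, terminal TAA) with a
short 5'UTR and ≥ 60 nt 3'UTR.  Border overwrites that would create an
internal stop are repaired at a free codon position.

`plant_pseudoexon_variant` writes a cryptic acceptor (consensus
polypyrimidine tract + `ag`, plus `G` as the pseudoexon's first base) and a
donor that becomes viable only under one substitution:

* `gt_gain` — reference `AG|gAaagt`; the A>T at +2 completes a perfect-context
  GT donor (the geometry of intronic activating mutations);
* `exonic_ag_gain_gc_donor` — reference `cG|gcacgt`; the c>A at the
  penultimate pseudoexon base creates `AG|gc…` whose context (81.8%) sits
  below the GC threshold (85%), so the motif scan misses it and the call
  must be rescued from junction evidence.  The variant lies *inside* the
  pseudoexon, so inclusion reads can phase it.

Uniqueness is guaranteed by construction: accidental above-threshold
acceptors in range of the planted donor are degraded (their obligatory `ag`
broken) wherever they fall outside the planted acceptor tract and donor
octamer, with whole-interior resampling as a fallback.  Random intronic
sequence passes the 65% acceptor threshold at a few percent per `ag`
position, so rejection alone would almost never converge — degradation is
what makes the unique-truth contract practical.

Junction tables draw canonical reads as Binomial(depth, 1−ψ) for the
affected intron and each flanking novel junction independently as
Binomial(depth, ψ); allelic counts draw gDNA ~ Binomial(depth, 1/2) and
cDNA ~ Binomial(depth, R/(1+R)); pedigrees are fully penetrant nuclear
families (dominant) or de novo singletons (sporadic).  The default cohort
(54 families, 3 carriers cycling dominant-GT, sporadic-GT, sporadic-GC;
junction depth 120, ψ = 0.3; 4 SNPs at depth 80 with carrier R = 0.6;
background variants exercising every WGS filter; a latent 54-bp in-frame
event at ψ = 0.08 in all samples including 3 healthy controls) emulates the
discovery structure of a mutation-negative polyposis screen.

Deliberately **not** emulated: read-level sequencing (FASTQ), alignment
artefacts and mapping bias, overdispersed allelic counts, EBV/lymphoblast
expression idiosyncrasies, incomplete penetrance, mosaicism, and
multi-transcript genes.  Passing tests therefore demonstrate the inference
chain's correctness on clean signals of realistic effect size — not
robustness to alignment noise or reference bias, which sit upstream of this
package's inputs.

## Problem sizes

The test suite and the acceptance script use: 50 seeded genes for boundary
recovery, 100 random pseudoexons for the consequence oracle, 1000 two-SNV
genes for null calibration, 200 seeds at depth 500 for ratio recovery, and
one 54-family cohort end to end.  The full suite runs in a few seconds on
one CPU.

## Known limitations

* The splice model is consensus-based; it will miss weak but functional
  sites (as real predictors missed the GC-donor case) — the junction-rescue
  path exists precisely because motif evidence is not necessary.
* The HGVS surface covers substitutions and intronic insertions only
  (no dup/del/delins/inversions), one transcript per gene.
* The ASE test assumes independent SNVs within a gene; true read-backed
  phasing or haplotype dependence is not modelled.
* The evidence tier is a package-defined formalisation of qualitative
  criteria; it is reported with its inputs so users can apply their own
  weighting.
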