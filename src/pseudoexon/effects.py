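"""Transcript and protein consequences of pseudoexon inclusion.

Splices an intronic pseudoexon into the mature mRNA, translates the mutant
reading frame with the standard genetic code, and classifies the protein
consequence in HGVS-style p. notation:

* ``nonsense`` — the first residue that differs from wild type is a stop
  (``p.Arg216*``);
* ``frameshift`` — the reading frame shifts and a premature stop appears
  ``N`` codons downstream, counted with the first changed residue as 1
  (``p.Gly471Serfs*55``);
* ``inframe_insertion`` — insert length is a multiple of 3 and no stop is
  introduced;
* ``no_ptc`` — the protein is unchanged.

The NMD flag applies the standard 50–55 nt rule (55 used): a premature
stop at least 55 nt upstream of the final exon–exon junction of the mutant
transcript is predicted to trigger nonsense-mediated decay.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .coordinates import CoordinateError, GeneModel, HgvsParseError, RnaChange
from .splice import PseudoexonCall

NMD_JUNCTION_RULE_NT = 55


class EffectError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinChange:
    category: str  # nonsense | frameshift | inframe_insertion | no_ptc
    first_affected_codon: int
    ref_aa: str  # 1-letter, '' if not applicable
    alt_aa: str
    stop_offset: int  # fs*N count; 0 for direct nonsense / no PTC
    notation: str

    @property
    def has_ptc(self) -> bool:
        return self.category in ("nonsense", "frameshift") and self.stop_offset >= 0


def apply_pseudoexon(
    gene: GeneModel, call: PseudoexonCall, genome
) -> tuple[str, RnaChange]:
    """Return (mutant mRNA, r. change) for a pseudoexon inclusion.

    The mutant mRNA is the canonical spliced mRNA with the genomic
    pseudoexon segment (transcript strand) inserted between the two exons
    flanking its intron.
    """
    i = call.intron_index or gene.which_intron(call.pe_start_g)
    if i is None or gene.which_intron(call.pe_end_g) != i:
        raise CoordinateError(
            f"pseudoexon {call.pe_start_g}-{call.pe_end_g} does not lie within "
            f"one intron of {gene.gene_id}"
        )
    if call.length < 1:
        raise CoordinateError("pseudoexon length must be >= 1")
    lo = min(call.pe_start_g, call.pe_end_g)
    hi = max(call.pe_start_g, call.pe_end_g)
    insert = gene.tx_strand_seq(genome, lo, hi)
    wild = gene.spliced_mrna(genome)
    t_break = gene.exon_tx_bounds[i - 1][1]  # last transcript base of exon i
    mutant = wild[:t_break] + insert + wild[t_break:]
    last_c = gene.t_to_c(t_break)
    change = RnaChange(last_c, last_c + 1, call.pe_start, call.pe_end)
    return mutant, change


def _translate_with_stops(seq: str) -> str:
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def classify_protein_effect(
    wild_mrna: str, mutant_mrna: str, cds_start: int, change: RnaChange
) -> ProteinChange:
    """Classify the protein consequence of an intronic insertion.

    ``cds_start`` is the spliced-transcript coordinate (1-based) of the
    first base of the start codon in the *wild-type* mRNA; the insertion
    described by ``change`` lies downstream of it, so the same coordinate
    applies to the mutant.  The wild-type CDS must be free of internal
    stops.
    """
    if not (1 <= cds_start <= len(wild_mrna)):
        raise EffectError(f"cds_start {cds_start} beyond wild-type mRNA")
    ins_len = len(mutant_mrna) - len(wild_mrna)
    if ins_len < 1:
        raise EffectError("mutant mRNA is not longer than wild type")

    wild_aa = _translate_with_stops(wild_mrna[cds_start - 1 :])
    mut_aa = _translate_with_stops(mutant_mrna[cds_start - 1 :])
    wild_stop = wild_aa.find("*")
    if wild_stop == -1:
        raise EffectError("wild-type CDS has no stop codon within the mRNA")
    if "*" in wild_aa[:wild_stop]:
        raise EffectError("wild-type CDS contains an internal stop")
    mut_stop = mut_aa.find("*")  # -1 if never terminates within the mRNA

    # first codon whose residue differs from wild type
    first_diff = None
    for i, (w, m) in enumerate(zip(wild_aa, mut_aa)):
        if w != m:
            first_diff = i
            break

    if first_diff is None:
        # mutant is a prefix-extension of wild type (insertion at/after stop)
        return ProteinChange("no_ptc", 0, "", "", 0, "p.=")

    codon = first_diff + 1
    ref = wild_aa[first_diff]
    alt = mut_aa[first_diff]

    if alt == "*":
        return ProteinChange(
            "nonsense", codon, ref, "*", 0, f"p.{seq3(ref)}{codon}*"
        )

    frame_preserved = ins_len % 3 == 0
    if frame_preserved and mut_stop == wild_stop + ins_len // 3:
        # clean in-frame insertion: no stop introduced
        n_ins = ins_len // 3
        left = codon - 1
        if left >= 1 and mut_aa[left - 1] == wild_aa[left - 1]:
            inserted = mut_aa[first_diff : first_diff + n_ins]
            notation = (
                f"p.{seq3(wild_aa[left - 1])}{left}_{seq3(ref)}{codon}"
                f"ins{seq3(inserted)}"
            )
        else:
            notation = f"p.{seq3(ref)}{codon}ins"
        return ProteinChange("inframe_insertion", codon, ref, alt, 0, notation)

    if mut_stop == -1:
        # frame runs off the end of the mRNA without terminating
        return ProteinChange(
            "frameshift", codon, ref, alt, -1, f"p.{seq3(ref)}{codon}{seq3(alt)}fs*?"
        )

    stop_codon = mut_stop + 1
    n = stop_codon - codon + 1
    if frame_preserved:
        # in-frame insert that nonetheless introduces a stop downstream of
        # the first changed residue: truncating, reported as nonsense
        return ProteinChange(
            "nonsense", codon, ref, alt, 0, f"p.{seq3(ref)}{codon}ins*"
        )
    return ProteinChange(
        "frameshift", codon, ref, alt, n, f"p.{seq3(ref)}{codon}{seq3(alt)}fs*{n}"
    )


_P_NONSENSE = re.compile(r"p\.([A-Z][a-z]{2})(\d+)(ins)?\*")
_P_FS = re.compile(r"p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})fs\*(\d+|\?)")
_P_INS = re.compile(r"p\.([A-Z][a-z]{2})(\d+)_([A-Z][a-z]{2})(\d+)ins((?:[A-Z][a-z]{2})+)")
_P_INS_AT = re.compile(r"p\.([A-Z][a-z]{2})(\d+)ins")


def parse_hgvs_p(text: str) -> dict:
    """Parse the p. notations this package emits (nonsense, fs, ins).

    Returns a dict of the notation's components; formatting the components
    back yields the identical string (round-trip identity).
    """
    s = text.strip()
    if s == "p.=":
        return {"kind": "no_change"}
    m = _P_NONSENSE.fullmatch(s)
    if m:
        return {
            "kind": "nonsense", "ref": m.group(1), "codon": int(m.group(2)),
            "in_insert": m.group(3) is not None,
        }
    m = _P_FS.fullmatch(s)
    if m:
        stop = m.group(4)
        return {
            "kind": "frameshift", "ref": m.group(1), "codon": int(m.group(2)),
            "alt": m.group(3), "stop_offset": -1 if stop == "?" else int(stop),
        }
    m = _P_INS.fullmatch(s)
    if m:
        return {
            "kind": "inframe_insertion", "left": m.group(1),
            "left_codon": int(m.group(2)), "right": m.group(3),
            "right_codon": int(m.group(4)), "inserted": m.group(5),
        }
    m = _P_INS_AT.fullmatch(s)
    if m:
        return {"kind": "insertion_at", "ref": m.group(1), "codon": int(m.group(2))}
    raise HgvsParseError(f"unsupported p. notation {text!r}")


def format_hgvs_p(parts: dict) -> str:
    kind = parts["kind"]
    if kind == "no_change":
        return "p.="
    if kind == "nonsense":
        mid = "ins" if parts.get("in_insert") else ""
        return f"p.{parts['ref']}{parts['codon']}{mid}*"
    if kind == "frameshift":
        n = parts["stop_offset"]
        return f"p.{parts['ref']}{parts['codon']}{parts['alt']}fs*{'?' if n == -1 else n}"
    if kind == "inframe_insertion":
        return (
            f"p.{parts['left']}{parts['left_codon']}_{parts['right']}"
            f"{parts['right_codon']}ins{parts['inserted']}"
        )
    if kind == "insertion_at":
        return f"p.{parts['ref']}{parts['codon']}ins"
    raise HgvsParseError(f"unknown p. kind {kind!r}")


def nmd_flag(
    change: ProteinChange,
    gene: GeneModel,
    rna_change: RnaChange,
    rule_nt: int = NMD_JUNCTION_RULE_NT,
) -> bool:
    """Predict nonsense-mediated decay for a PTC-bearing transcript.

    True iff the last base of the premature stop codon lies at least
    ``rule_nt`` nucleotides upstream of the final exon–exon junction of the
    *mutant* transcript (whose exon chain includes the pseudoexon).
    """
    if not change.has_ptc:
        raise EffectError("nmd_flag requires a change with a premature stop")
    # mutant exon lengths, transcript order: exons 1..i, pseudoexon, exons i+1..
    from .coordinates import insertion_length  # local to avoid cycle at import

    i = None
    t_break_c = rna_change.last_exonic_before
    for idx, (ts, te) in enumerate(gene.exon_tx_bounds):
        if gene.t_to_c(te) == t_break_c:
            i = idx
            break
    if i is None:
        raise EffectError("rna_change does not break at an exon boundary")
    pe_len = insertion_length(rna_change, gene)
    exon_lens = [e - s + 1 for s, e in gene.exons]
    mutant_lens = exon_lens[: i + 1] + [pe_len] + exon_lens[i + 1 :]
    # transcript coordinate (mutant) of the final exon-exon junction
    last_junction_t = sum(mutant_lens[:-1])
    stop_codon = (
        change.first_affected_codon
        if change.category == "nonsense"
        else change.first_affected_codon + change.stop_offset - 1
    )
    cds_start_t = gene.cds_start_c  # transcript coordinate of c.1
    ptc_last_t = cds_start_t - 1 + 3 * stop_codon
    return last_junction_t - ptc_last_t >= rule_nt
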