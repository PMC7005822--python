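"""APOBEC trinucleotide-signature classification and clonality summaries.

APOBEC3B deaminates cytosines in a 5'-TC context (strictly, TCW with W = A/T),
producing C→T transitions; on the opposite strand the same event appears on
the plus strand as G→A with the motif mirrored. Two motif modes are offered:

``TC``
    Minimal deamination context — the mutated C is preceded 5' by T (default).
``TCW``
    Strict trinucleotide — additionally followed 3' by A or T.

Motifs are always reported in pyrimidine orientation (TCA, TCC, ...), i.e. as
seen from the strand carrying the deaminated C.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .seqmodel import SNV, CodingSequence, reverse_complement

MOTIF_MODES = ("TC", "TCW")


@dataclass(frozen=True)
class SignatureCall:
    """The APOBEC-signature verdict for one SNV."""

    snv: SNV
    is_signature: bool
    motif: str = ""
    deaminated_strand: str = "none"  # {plus, minus, none}

    def __post_init__(self) -> None:
        if not self.is_signature and (self.motif or
                                      self.deaminated_strand != "none"):
            raise ValidationError(
                "non-signature call must have empty motif and strand 'none'"
            )


@dataclass(frozen=True)
class ClonalityEstimate:
    """Variant allele frequency and a clonal/subclonal flag for one SNV.

    ``vaf`` is None when total depth is zero (flagged by ``depth_unknown``).
    """

    snv: SNV
    vaf: float | None
    depth: int
    clonal_flag: bool
    depth_unknown: bool = False


def classify_signature(snv: SNV, seq: CodingSequence,
                       motif_mode: str = "TC") -> SignatureCall:
    """Classify one SNV as APOBEC-signature or not by trinucleotide context.

    Plus strand: C→T with 5' neighbour T (TC), additionally 3' neighbour A/T
    (TCW). Minus strand, expressed on the plus strand: G→A with 3' neighbour
    A (TC), additionally 5' neighbour A/T (TCW). A context base that would
    fall off the sequence end fails the motif; there is no wrap-around.
    """
    if motif_mode not in MOTIF_MODES:
        raise ValidationError(f"unknown motif_mode {motif_mode!r}")
    if not 1 <= snv.pos <= len(seq):
        raise ValidationError(
            f"{snv.seq_id}:{snv.pos}: position out of range for sequence of "
            f"length {len(seq)}"
        )
    dna = seq.dna
    p = snv.pos
    five = dna[p - 2] if p >= 2 else None
    three = dna[p] if p < len(dna) else None

    if snv.ref == "C" and snv.alt == "T":
        if five == "T" and (motif_mode == "TC" or three in ("A", "T")):
            motif = f"TC{three}" if three is not None else "TC"
            return SignatureCall(snv, True, motif, "plus")
    elif snv.ref == "G" and snv.alt == "A":
        if three == "A" and (motif_mode == "TC" or five in ("A", "T")):
            plus_ctx = (five or "") + "G" + three
            return SignatureCall(snv, True, reverse_complement(plus_ctx),
                                 "minus")
    return SignatureCall(snv, False)


def signature_fraction(calls: list[SignatureCall]) -> float:
    """Fraction of calls flagged as APOBEC-signature."""
    if not calls:
        raise ValidationError("signature_fraction of an empty call list "
                              "is undefined")
    return sum(c.is_signature for c in calls) / len(calls)


def estimate_clonality(snv: SNV,
                       clonal_threshold: float = 0.9) -> ClonalityEstimate:
    """VAF = alt/(ref+alt); clonal iff VAF >= threshold.

    Zero total depth yields an undefined (None) VAF flagged as depth-unknown
    and is never called clonal.
    """
    depth = snv.ref_count + snv.alt_count
    if depth == 0:
        return ClonalityEstimate(snv, None, 0, False, depth_unknown=True)
    vaf = snv.alt_count / depth
    return ClonalityEstimate(snv, vaf, depth, vaf >= clonal_threshold)
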