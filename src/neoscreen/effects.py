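"""Codon-level consequence annotation and the missense/transition filter.

The screen keeps only amino-acid-changing events compatible with cytidine
deamination: missense substitutions arising from C→T or (strand-mirrored)
G→A transitions, optionally required to sit in the APOBEC motif context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ConsistencyError, ValidationError
from .seqmodel import SNV, CodingSequence, translate, validate_snv
from .signature import SignatureCall

logger = logging.getLogger(__name__)

EFFECT_CLASSES = ("synonymous", "missense", "nonsense", "stoploss")

TRANSITIONS_CT_GA = {("C", "T"), ("G", "A")}


@dataclass(frozen=True)
class CodingEffect:
    """Codon-level consequence of one SNV on its protein."""

    snv: SNV
    codon_index: int
    codon_ref: str
    codon_alt: str
    aa_ref: str
    aa_alt: str
    effect_class: str
    hgvs_p: str


def _classify(aa_ref: str, aa_alt: str) -> str:
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    if aa_ref == "*":
        return "stoploss"
    return "missense"


def annotate_effect(snv: SNV, seq: CodingSequence,
                    permissive: bool = False) -> CodingEffect:
    """Annotate the codon-level consequence of an SNV.

    The codon is located by 1-based arithmetic (codon_index = ceil(pos/3)),
    both codons translated with the standard code, and the protein change
    written in short HGVS style (``P5S``).
    """
    validate_snv(snv, seq, permissive=permissive)
    codon_index = (snv.pos - 1) // 3 + 1
    start = (codon_index - 1) * 3
    codon_ref = seq.dna[start:start + 3]
    offset = (snv.pos - 1) % 3
    codon_alt = codon_ref[:offset] + snv.alt + codon_ref[offset + 1:]
    # Bio.Seq translation of a lone codon; '*' for stops.
    aa_ref = translate_codon(codon_ref)
    aa_alt = translate_codon(codon_alt)
    effect_class = _classify(aa_ref, aa_alt)
    return CodingEffect(
        snv=snv,
        codon_index=codon_index,
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        effect_class=effect_class,
        hgvs_p=f"{aa_ref}{codon_index}{aa_alt}",
    )


def translate_codon(codon: str) -> str:
    if len(codon) != 3:
        raise ValidationError(f"codon {codon!r} is not 3 bases")
    return translate(codon)


def annotate_effects(snvs: list[SNV], seqs: dict[str, CodingSequence],
                     permissive: bool = False) -> list[CodingEffect]:
    """Annotate a batch of SNVs, warning on multi-hit codons.

    Two SNVs striking the same codon are annotated independently; joint-codon
    consequences are not modelled.
    """
    effects = [
        annotate_effect(s, seqs[s.seq_id], permissive=permissive)
        for s in snvs
    ]
    seen: dict[tuple[str, int], int] = {}
    for e in effects:
        k = (e.snv.seq_id, e.codon_index)
        seen[k] = seen.get(k, 0) + 1
    multi = [k for k, n in seen.items() if n > 1]
    if multi:
        logger.warning(
            "annotate_effects: %d codon(s) hit by multiple SNVs; "
            "each annotated independently", len(multi)
        )
    return effects


def missense_transition_filter(
    effects: list[CodingEffect],
    calls: list[SignatureCall],
    require_signature: bool = True,
) -> list[CodingEffect]:
    """Keep missense effects from C→T / G→A transitions, in input order.

    With ``require_signature`` (default) the paired signature call must also
    be positive, so only motif-context deamination events survive. The two
    lists must be keyed to the same SNVs.
    """
    call_by_key = {c.snv.key: c for c in calls}
    kept: list[CodingEffect] = []
    for e in effects:
        call = call_by_key.get(e.snv.key)
        if call is None:
            raise ConsistencyError(
                f"no signature call for SNV {e.snv.key}"
            )
        if e.effect_class != "missense":
            continue
        if (e.snv.ref, e.snv.alt) not in TRANSITIONS_CT_GA:
            continue
        if require_signature and not call.is_signature:
            continue
        kept.append(e)
    return kept
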