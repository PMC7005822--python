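import pytest

from neoscreen import SNV, CodingSequence, CodingEffect, PeptideContext

# The CSDE1 Sanger-confirmed example: wild-type vs deaminated coding stretch,
# a C→T at base 13 giving the P5S substitution.
CSDE1_WT = "ATGAGCTTTGATCCA"
CSDE1_MUT = "ATGAGCTTTGATTCA"


@pytest.fixture
def csde1_seq() -> CodingSequence:
    return CodingSequence(id="csde1", dna=CSDE1_WT)


@pytest.fixture
def csde1_snv() -> SNV:
    return SNV(seq_id="csde1", pos=13, ref="C", alt="T",
               ref_count=70, alt_count=30)


ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_context(length: int, mut_index: int) -> PeptideContext:
    """A synthetic peptide context of a given length and mutation position."""
    wt = "".join(ALPHABET[i % 20] for i in range(length))
    alt = "W" if wt[mut_index - 1] != "W" else "Y"
    mut = wt[: mut_index - 1] + alt + wt[mut_index:]
    effect = CodingEffect(
        snv=SNV("syn", 1, "C", "T"),
        codon_index=mut_index, codon_ref="NNN", codon_alt="NNN",
        aa_ref=wt[mut_index - 1], aa_alt=alt,
        effect_class="missense",
        hgvs_p=f"{wt[mut_index - 1]}{mut_index}{alt}",
    )
    return PeptideContext(effect, wt, mut, mut_index)
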