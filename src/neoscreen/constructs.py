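"""Polyepitope "epitope string" design: selected peptides joined by AAY
spacers, an optional N-terminal degron, and a deterministic back-translation
to a coding DNA insert.

The AAY spacer is a proteasomal-cleavage-favouring junction placed strictly
BETWEEN consecutive epitopes (n − 1 spacers for n epitopes, none at either
terminus). An N-end degron prefix may be supplied to accelerate degradation
and MHC-I presentation; no particular degron is assumed, the default is
empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .epitopes import STANDARD_RESIDUES
from .seqmodel import translate

# One fixed codon per residue for deterministic back-translation (a common
# mammalian-usage choice per amino acid; codon optimisation is out of scope).
CODON_CHOICE: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}


@dataclass(frozen=True)
class ConstructDesign:
    """An assembled polyepitope protein and its coding DNA."""

    name: str
    epitopes: tuple[str, ...]
    spacer: str
    degron_prefix: str
    protein: str
    dna: str


def _check_residues(label: str, s: str) -> None:
    bad = set(s) - set(STANDARD_RESIDUES)
    if bad:
        raise ValidationError(
            f"{label} contains non-standard residues {sorted(bad)}"
        )


def back_translate(protein: str) -> str:
    """Deterministic back-translation using the fixed codon table."""
    _check_residues("protein", protein)
    return "".join(CODON_CHOICE[aa] for aa in protein)


def design_construct(
    epitopes: list[str],
    spacer: str = "AAY",
    degron_prefix: str = "",
    name: str = "construct",
) -> ConstructDesign:
    """Assemble degron + epitope₁ + spacer + ... + epitopeₙ and back-translate.

    ``translate(design.dna) == design.protein`` holds for every valid design.
    """
    if not epitopes:
        raise ValidationError("construct needs at least one epitope")
    for i, e in enumerate(epitopes, start=1):
        if not e:
            raise ValidationError(f"epitope {i} is empty")
        _check_residues(f"epitope {i}", e)
    _check_residues("spacer", spacer)
    _check_residues("degron_prefix", degron_prefix)
    protein = degron_prefix + spacer.join(epitopes)
    dna = back_translate(protein)
    assert translate(dna) == protein
    return ConstructDesign(
        name=name,
        epitopes=tuple(epitopes),
        spacer=spacer,
        degron_prefix=degron_prefix,
        protein=protein,
        dna=dna,
    )


def spacer_count(design: ConstructDesign) -> int:
    """Number of spacers in the design: n − 1 for n epitopes."""
    return len(design.epitopes) - 1


def write_construct_fasta(designs: list[ConstructDesign],
                          path: str | Path) -> None:
    """FASTA export: one protein and one DNA record per design."""
    lines: list[str] = []
    for d in designs:
        lines.append(f">{d.name}_protein")
        lines.append(d.protein)
        lines.append(f">{d.name}_dna")
        lines.append(d.dna)
    Path(path).write_text("\n".join(lines) + "\n")
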