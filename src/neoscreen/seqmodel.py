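"""Core sequence/variant data model and readers/writers for standard formats.

Coding sequences live in CDS space: positions are 1-based and relative to the
first base of the coding sequence, matching the convention in which a Sanger
trace's "13th base pair" names position 13. Variants are therefore expressed
against the CDS, not the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateKeyError,
    FormatError,
    ReferenceMismatchError,
    ValidationError,
)

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")


def translate(dna: str) -> str:
    """Translate a coding DNA string with the standard genetic code.

    The first stop codon is rendered as ``*`` and terminates the output;
    anything downstream is discarded.

    Raises
    ------
    ValidationError
        If the length is not a multiple of 3 or a non-ACGT base is present.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise ValidationError(
            f"coding sequence length {len(dna)} is not a multiple of 3"
        )
    bad = set(dna) - BASES
    if bad:
        raise ValidationError(f"non-ACGT characters in sequence: {sorted(bad)}")
    aa = str(Seq(dna).translate())
    stop = aa.find("*")
    return aa if stop == -1 else aa[: stop + 1]


def reverse_complement(dna: str) -> str:
    """Reverse-complement a DNA string (delegates to Biopython)."""
    return str(Seq(dna).reverse_complement())


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence with minimal gene annotation.

    ``protein`` is derived on construction by standard-code translation and
    truncated at the first stop codon (inclusive).
    """

    id: str
    dna: str
    strand: str = "+"
    gene: str = ""
    protein: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        dna = self.dna.upper()
        object.__setattr__(self, "dna", dna)
        if not dna:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if len(dna) % 3 != 0:
            raise ValidationError(
                f"record {self.id!r}: length {len(dna)} is not a multiple of 3"
            )
        if set(dna) - BASES:
            raise ValidationError(
                f"record {self.id!r}: non-ACGT characters "
                f"{sorted(set(dna) - BASES)}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"record {self.id!r}: bad strand {self.strand!r}")
        if not self.gene:
            object.__setattr__(self, "gene", self.id)
        object.__setattr__(self, "protein", translate(dna))

    def __len__(self) -> int:
        return len(self.dna)

    def base_at(self, pos: int) -> str:
        """1-based base lookup."""
        if not 1 <= pos <= len(self.dna):
            raise IndexError(f"position {pos} out of range for {self.id!r}")
        return self.dna[pos - 1]


@dataclass(frozen=True)
class SNV:
    """A single-nucleotide variant on a coding sequence, 1-based.

    ``ref_count``/``alt_count`` are read-support depths used for clonality;
    ``depth_known`` is False when the source record carried no allele depths.
    """

    seq_id: str
    pos: int
    ref: str
    alt: str
    ref_count: int = 0
    alt_count: int = 0
    depth_known: bool = True

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(
                f"{self.seq_id}:{self.pos}: alleles must be single ACGT bases, "
                f"got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"{self.seq_id}:{self.pos}: ref equals alt")
        if self.pos < 1:
            raise ValidationError(f"{self.seq_id}: position {self.pos} < 1")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"{self.seq_id}:{self.pos}: negative read counts"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.seq_id, self.pos, self.ref, self.alt)


def validate_snv(snv: SNV, seq: CodingSequence, permissive: bool = False) -> None:
    """Check an SNV against its coding sequence.

    In permissive mode a reference-base mismatch is downgraded to a warning.
    """
    if snv.pos > len(seq):
        raise ValidationError(
            f"{snv.seq_id}:{snv.pos}: position beyond sequence end ({len(seq)})"
        )
    actual = seq.base_at(snv.pos)
    if actual != snv.ref:
        msg = (
            f"{snv.seq_id}:{snv.pos}: stated ref {snv.ref!r} does not match "
            f"sequence base {actual!r}"
        )
        if permissive:
            logger.warning(msg)
        else:
            raise ReferenceMismatchError(msg)


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's expression level (TPM) in one tissue."""

    gene: str
    tissue: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValidationError(
                f"expression of {self.gene!r} in {self.tissue!r}: "
                f"negative TPM {self.tpm}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read coding sequences from FASTA.

    The header token before the first whitespace becomes the record id.
    ``gene=SYMBOL`` and ``strand=+|-`` tokens in the description are honoured;
    gene defaults to the id.
    """
    path = Path(path)
    records: list[CodingSequence] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: FASTA must start with a "
                        f"'>' header"
                    )
                break
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = ""
        strand = "+"
        for token in rec.description.split()[1:]:
            if token.startswith("gene="):
                gene = token[5:]
            elif token.startswith("strand="):
                strand = token[7:]
        records.append(
            CodingSequence(id=rec.id, dna=str(rec.seq).upper(),
                           strand=strand, gene=gene)
        )
    return records


def write_fasta(seqs: list[CodingSequence], path: str | Path) -> None:
    """Write coding sequences as unwrapped FASTA with annotation tokens."""
    recs = [
        SeqRecord(Seq(s.dna), id=s.id,
                  description=f"gene={s.gene} strand={s.strand}")
        for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[SNV]:
    """Read biallelic SNVs from a VCF 4.x file.

    CHROM holds the coding-sequence id; the first sample's AD FORMAT field
    supplies ref/alt depths. Records with symbolic, multi-base, or
    multi-allelic alleles are skipped; the skip count is logged. Records
    without AD get zero depths with ``depth_known=False``.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: unreadable VCF header: {exc}") from exc
    snvs: list[SNV] = []
    skipped = 0
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in BASES
                or alts[0] not in BASES
            ):
                skipped += 1
                continue
            ref_count = alt_count = 0
            depth_known = False
            if rec.samples:
                sample = rec.samples[0]
                ad = sample.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    ref_count, alt_count = int(ad[0]), int(ad[1])
                    depth_known = True
            snvs.append(
                SNV(seq_id=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alts[0],
                    ref_count=ref_count, alt_count=alt_count,
                    depth_known=depth_known)
            )
    if skipped:
        logger.info("read_vcf: skipped %d non-SNV record(s) in %s",
                    skipped, path)
    return snvs


def write_vcf(snvs: list[SNV], path: str | Path) -> None:
    """Write SNVs as a minimal single-sample VCF 4.2 with AD depths.

    Output is deterministic: records in input order, fixed header. Depths are
    written as AD for every record; ``depth_known`` does not round-trip (a
    record written with 0,0 reads back as known zero depth).
    """
    contigs = sorted({s.seq_id for s in snvs})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample"
    )
    for s in snvs:
        lines.append(
            f"{s.seq_id}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\t"
            f"GT:AD\t0/1:{s.ref_count},{s.alt_count}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV of per-gene, per-tissue TPM values.

    Requires columns ``gene``, ``tissue``, ``tpm`` (extras ignored); a
    duplicated (gene, tissue) pair is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "tissue", "tpm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["gene", "tissue"])
    if dup.any():
        first = df.loc[dup, ["gene", "tissue"]].iloc[0]
        raise DuplicateKeyError(
            f"{path}: duplicate (gene, tissue) pair "
            f"({first['gene']!r}, {first['tissue']!r})"
        )
    return [
        ExpressionRecord(gene=str(r.gene), tissue=str(r.tissue),
                         tpm=float(r.tpm))
        for r in df.itertuples()
    ]


def write_expression_table(records: list[ExpressionRecord],
                           path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene, r.tissue, r.tpm) for r in records],
        columns=["gene", "tissue", "tpm"],
    )
    df.to_csv(path, sep="\t", index=False)
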