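"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of an APOBEC-mutagenised
coding genome: a mixture of deamination-signature mutations (C→T at TC-motif
sites, or the strand-mirrored G→A) and background substitutions placed only
at non-motif sites, with subclonal variant-allele frequencies drawn from a
Beta distribution and converted to read counts at a fixed sequencing depth.
Every emitted variant is recorded in a truth table (signature status, motif,
coding effect, true VAF) so recovery can be tested exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigError
from .epitopes import EpitopeCandidate, PredictionTable
from .seqmodel import SNV, CodingSequence, ExpressionRecord, reverse_complement

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one implanted SNV."""

    seq_id: str
    pos: int
    ref: str
    alt: str
    is_signature: bool
    motif: str
    deaminated_strand: str
    effect_class: str
    hgvs_p: str
    true_vaf: float


@dataclass
class TruthTable:
    """All implanted variants plus the generation parameters."""

    records: list[TruthRecord]
    params: dict
    realized_signature_count: int

    def by_key(self) -> dict[tuple[str, int, str, str], TruthRecord]:
        return {(r.seq_id, r.pos, r.ref, r.alt): r for r in self.records}


def generate_cds_set(
    n: int,
    length_range: tuple[int, int] = (50, 200),
    seed: int = 0,
) -> list[CodingSequence]:
    """Random ATG-initiated, internal-stop-free coding sequences.

    ``length_range`` is in codons (inclusive); minimum 12 codons.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    lo, hi = length_range
    if lo < 12 or hi < lo:
        raise ConfigError(
            f"length_range must satisfy 12 <= lo <= hi, got {length_range}"
        )
    rng = np.random.default_rng(seed)
    seqs: list[CodingSequence] = []
    for i in range(n):
        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
        dna = "ATG" + "".join(SENSE_CODONS[j] for j in body)
        seqs.append(CodingSequence(id=f"gene{i:04d}", dna=dna))
    return seqs


def _true_effect(seq: CodingSequence, pos: int, alt: str) -> tuple[str, str]:
    """Ground-truth coding effect by whole-protein comparison.

    Translates the full wild-type and mutant CDS (stops kept in place, no
    truncation) and compares residue by residue — an arithmetic-free route
    independent of the pipeline's codon-index annotation.
    """
    from Bio.Seq import Seq

    mut_dna = seq.dna[: pos - 1] + alt + seq.dna[pos:]
    wt_aa = str(Seq(seq.dna).translate())
    mut_aa = str(Seq(mut_dna).translate())
    diffs = [i for i, (a, b) in enumerate(zip(wt_aa, mut_aa)) if a != b]
    if not diffs:
        idx = (pos - 1) // 3
        return "synonymous", f"{wt_aa[idx]}{idx + 1}{wt_aa[idx]}"
    (i,) = diffs
    a, b = wt_aa[i], mut_aa[i]
    if a == "*":
        cls = "stoploss"
    elif b == "*":
        cls = "nonsense"
    else:
        cls = "missense"
    return cls, f"{a}{i + 1}{b}"


def _signature_sites(
    seqs: list[CodingSequence], vaccine_like: bool
) -> list[tuple[int, int, str, str, str, str]]:
    """(seq_idx, pos, ref, alt, motif, strand) for every TC-motif site.

    With ``vaccine_like`` only sites whose deamination event is missense are
    kept, so downstream peptide screens are exercisable.
    """
    sites = []
    for si, seq in enumerate(seqs):
        dna = seq.dna
        for p in range(1, len(dna) + 1):
            base = dna[p - 1]
            if base == "C" and p >= 2 and dna[p - 2] == "T":
                three = dna[p] if p < len(dna) else ""
                sites.append((si, p, "C", "T", "TC" + three, "plus"))
            elif base == "G" and p < len(dna) and dna[p] == "A":
                five = dna[p - 2] if p >= 2 else ""
                motif = reverse_complement(five + "GA")
                sites.append((si, p, "G", "A", motif, "minus"))
    if vaccine_like:
        sites = [
            s for s in sites
            if _true_effect(seqs[s[0]], s[1], s[3])[0] == "missense"
        ]
    return sites


def implant_mutations(
    seqs: list[CodingSequence],
    n_mut: int,
    signature_fraction: float,
    vaf_params: tuple[float, float] = (2.0, 5.0),
    depth: int = 100,
    seed: int = 0,
    vaccine_like: bool = False,
) -> tuple[list[SNV], TruthTable]:
    """Implant a signature/background mutation mixture with known truth.

    A Binomial(n_mut, signature_fraction) number of mutations are C→T (or
    mirrored G→A) at TC-motif sites; the rest are substitutions at non-motif
    sites, so no background mutation carries the signature. Each mutation
    draws a true VAF from Beta(*vaf_params*) and read counts binomially at
    the stated depth. At most one mutation per position.
    """
    if not 0.0 <= signature_fraction <= 1.0:
        raise ConfigError("signature_fraction must lie in [0, 1]")
    if n_mut < 1:
        raise ConfigError("n_mut must be >= 1")
    rng = np.random.default_rng(seed)
    n_sig = int(rng.binomial(n_mut, signature_fraction))
    n_bg = n_mut - n_sig

    sig_sites = _signature_sites(seqs, vaccine_like)
    if n_sig > len(sig_sites):
        raise CapacityError(
            f"need {n_sig} signature sites but only {len(sig_sites)} exist "
            f"(deficit {n_sig - len(sig_sites)})"
        )
    sig_positions = {(s[0], s[1]) for s in sig_sites}
    bg_positions = [
        (si, p)
        for si, seq in enumerate(seqs)
        for p in range(1, len(seq) + 1)
        if (si, p) not in sig_positions
    ]
    if n_bg > len(bg_positions):
        raise CapacityError(
            f"need {n_bg} background sites but only {len(bg_positions)} "
            f"exist (deficit {n_bg - len(bg_positions)})"
        )

    chosen_sig = [sig_sites[i] for i in
                  rng.choice(len(sig_sites), size=n_sig, replace=False)]
    chosen_bg = [bg_positions[i] for i in
                 rng.choice(len(bg_positions), size=n_bg, replace=False)]

    snvs: list[SNV] = []
    records: list[TruthRecord] = []

    def emit(si: int, pos: int, ref: str, alt: str,
             is_sig: bool, motif: str, strand: str) -> None:
        seq = seqs[si]
        vaf = float(rng.beta(*vaf_params))
        alt_count = int(rng.binomial(depth, vaf))
        snv = SNV(seq_id=seq.id, pos=pos, ref=ref, alt=alt,
                  ref_count=depth - alt_count, alt_count=alt_count)
        cls, hgvs = _true_effect(seq, pos, alt)
        snvs.append(snv)
        records.append(TruthRecord(
            seq_id=seq.id, pos=pos, ref=ref, alt=alt, is_signature=is_sig,
            motif=motif if is_sig else "",
            deaminated_strand=strand if is_sig else "none",
            effect_class=cls, hgvs_p=hgvs, true_vaf=vaf,
        ))

    for si, pos, ref, alt, motif, strand in chosen_sig:
        emit(si, pos, ref, alt, True, motif, strand)
    for si, pos in chosen_bg:
        ref = seqs[si].dna[pos - 1]
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(len(alts)))]
        emit(si, pos, ref, alt, False, "", "none")

    truth = TruthTable(
        records=records,
        params={
            "seed": seed,
            "n_sequences": len(seqs),
            "n_mutations": n_mut,
            "signature_fraction": signature_fraction,
            "vaf_params": list(vaf_params),
            "depth": depth,
            "vaccine_like": vaccine_like,
        },
        realized_signature_count=n_sig,
    )
    return snvs, truth


def generate_affinity_table(
    candidates: list[EpitopeCandidate],
    n_heteroclitic: int,
    threshold: float = 500.0,
    alleles: tuple[str, ...] = ("H-2Kb", "H-2Db"),
    seed: int = 0,
) -> tuple[PredictionTable, list[tuple[str, str, str]]]:
    """Design a predictions table with exactly ``n_heteroclitic`` passers.

    Exactly that many distinct wt/mut pairs receive (wt > threshold,
    mut < threshold) on one designated allele; every other pair violates at
    least one condition on every allele. Returns the table and the truth
    list of (wt_peptide, mut_peptide, allele) designed passers.
    """
    pairs = sorted({(c.wt_peptide, c.mut_peptide) for c in candidates})
    if n_heteroclitic > len(pairs):
        raise CapacityError(
            f"asked for {n_heteroclitic} heteroclitic pairs but only "
            f"{len(pairs)} distinct wt/mut pairs exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n_heteroclitic, replace=False)
    passers = [pairs[i] for i in sorted(idx)]
    passer_set = set(passers)

    table: dict[tuple[str, str], float] = {}

    def assign(pep: str, allele: str, value: float) -> None:
        table.setdefault((pep, allele), value)

    truth: list[tuple[str, str, str]] = []
    for wt, mut in passers:
        designated = alleles[int(rng.integers(len(alleles)))]
        truth.append((wt, mut, designated))
        for allele in alleles:
            if allele == designated:
                assign(wt, allele, float(rng.uniform(2, 40) * threshold))
                assign(mut, allele, float(rng.uniform(0.02, 0.8) * threshold))
            else:
                assign(wt, allele, float(rng.uniform(1.2, 40) * threshold))
                assign(mut, allele, float(rng.uniform(1.2, 40) * threshold))
    for wt, mut in pairs:
        if (wt, mut) in passer_set:
            continue
        for allele in alleles:
            # a weak mutant binder on every allele can never pass
            assign(mut, allele, float(rng.uniform(1.2, 40) * threshold))
            assign(wt, allele, float(rng.uniform(0.1, 20) * threshold))

    # peptide collisions across pairs could break the design; verify it held
    actual = {
        (wt, mut)
        for wt, mut in pairs
        if any(table[(wt, a)] > threshold and table[(mut, a)] < threshold
               for a in alleles)
    }
    if actual != passer_set:
        raise CapacityError(
            "peptide collisions made the designed pass set infeasible; "
            f"designed {len(passer_set)}, realised {len(actual)}"
        )
    return PredictionTable(table), truth


def generate_expression_table(
    genes: list[str],
    tissue: str = "skin",
    expressed_fraction: float = 1.0,
    seed: int = 0,
) -> list[ExpressionRecord]:
    """Per-gene TPM values in one tissue with a chosen expressed fraction.

    Expressed genes draw TPM uniformly in [1, 100]; the rest in [0, 0.5],
    below the conventional TPM >= 1 "expressed" cutoff.
    """
    rng = np.random.default_rng(seed)
    n_expr = int(round(expressed_fraction * len(genes)))
    expressed = set(
        int(i) for i in rng.choice(len(genes), size=n_expr, replace=False)
    )
    out = []
    for i, g in enumerate(genes):
        tpm = (float(rng.uniform(1.0, 100.0)) if i in expressed
               else float(rng.uniform(0.0, 0.5)))
        out.append(ExpressionRecord(gene=g, tissue=tissue, tpm=tpm))
    return out


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    """TSV of the per-SNV ground truth, deterministic column order."""
    df = pd.DataFrame([asdict(r) for r in truth.records])
    df.to_csv(path, sep="\t", index=False)


def write_manifest(truth: TruthTable, path: str | Path) -> None:
    payload = dict(truth.params,
                   realized_signature_count=truth.realized_signature_count)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
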