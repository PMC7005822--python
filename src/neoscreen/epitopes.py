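"""Peptide-context extraction, 8–10-mer window enumeration, MHC-I affinity
scoring, and the heteroclitic differential-binding and expression filters.

A missense variant is expanded into a context of up to 21 residues (10
flanking each side of the substitution, clipped at the protein ends). Every
8/9/10-mer window containing the mutated residue is paired wild-type vs
mutant, scored per allele in nM, and passes the heteroclitic filter iff some
single allele binds the wild-type weakly (> threshold) and the mutant
strongly (< threshold). Candidates are finally refined by tissue expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DuplicateKeyError,
    FormatError,
    MissingPredictionError,
    ValidationError,
)
from .effects import CodingEffect
from .seqmodel import ExpressionRecord

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_LENGTHS = frozenset({8, 9, 10})
DEFAULT_THRESHOLD_NM = 500.0


@dataclass(frozen=True)
class PeptideContext:
    """A wild-type/mutant pair of flanking-context amino-acid windows."""

    effect: CodingEffect
    wt_context: str
    mut_context: str
    mut_index: int  # 1-based position of the substitution in the context

    def __post_init__(self) -> None:
        if len(self.wt_context) != len(self.mut_context):
            raise ValidationError("context length mismatch")
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(self.wt_context, self.mut_context))
            if a != b
        ]
        if diffs != [self.mut_index]:
            raise ValidationError(
                f"contexts must differ exactly at mut_index "
                f"{self.mut_index}, differ at {diffs}"
            )


@dataclass
class EpitopeCandidate:
    """One mutant-containing peptide window paired with its wild-type twin."""

    context: PeptideContext
    wt_peptide: str
    mut_peptide: str
    length: int
    mut_pos_in_window: int
    affinities: dict[str, tuple[float, float]] = field(default_factory=dict)
    passes_binding: bool | None = None
    passing_alleles: list[str] = field(default_factory=list)
    expressed_in_tissue: bool | None = None


class AffinityPredictor(Protocol):
    """Deterministic (peptide, allele) → affinity-in-nM mapping."""

    alleles: list[str]

    def predict(self, peptide: str, allele: str) -> float: ...


def extract_context(effect: CodingEffect, protein: str,
                    flank: int = 10) -> PeptideContext:
    """Build the flanking context around a missense substitution.

    The window [codon_index − flank, codon_index + flank] is clipped to the
    protein; the full-length case is 2·flank + 1 residues with the mutation
    central.
    """
    if effect.effect_class != "missense":
        raise ValidationError(
            f"cannot build a peptide context for a {effect.effect_class} "
            f"effect ({effect.hgvs_p})"
        )
    ci = effect.codon_index
    if ci > len(protein):
        raise ValidationError(
            f"codon index {ci} beyond protein of length {len(protein)}"
        )
    if protein[ci - 1] != effect.aa_ref:
        raise ValidationError(
            f"protein residue {protein[ci - 1]!r} at {ci} does not match "
            f"annotated {effect.aa_ref!r}"
        )
    start = max(1, ci - flank)
    end = min(len(protein), ci + flank)
    wt = protein[start - 1:end]
    mut_index = ci - start + 1
    mut = wt[: mut_index - 1] + effect.aa_alt + wt[mut_index:]
    return PeptideContext(effect, wt, mut, mut_index)


def enumerate_windows(
    context: PeptideContext,
    lengths: set[int] = frozenset({8, 9, 10}),
) -> list[EpitopeCandidate]:
    """All k-mer windows of the context containing the mutated residue.

    For each k in ``lengths`` (must lie in 8–10), windows are emitted in
    left-to-right order; on a full 21-mer context each k contributes exactly
    k windows, placing the mutant residue in every position 1..k.
    """
    if not set(lengths) <= ALLOWED_LENGTHS:
        raise ConfigError(
            f"peptide lengths must be within {sorted(ALLOWED_LENGTHS)}, "
            f"got {sorted(set(lengths) - ALLOWED_LENGTHS)}"
        )
    L = len(context.wt_context)
    m = context.mut_index
    out: list[EpitopeCandidate] = []
    for k in sorted(lengths):
        for start in range(1, L - k + 2):
            if start <= m <= start + k - 1:
                out.append(
                    EpitopeCandidate(
                        context=context,
                        wt_peptide=context.wt_context[start - 1:start + k - 1],
                        mut_peptide=context.mut_context[start - 1:start + k - 1],
                        length=k,
                        mut_pos_in_window=m - start + 1,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

class SurrogatePredictor:
    """Deterministic position-weight affinity model. NOT biological.

    Scores a peptide as the sum of per-position residue weights and maps the
    sum S to nM via ``exp(a − b·S)``. It exists so the pipeline is fully
    testable without an external binding predictor; affinities from a real
    predictor are the supported scientific path (see ``read_predictions``).
    """

    def __init__(
        self,
        matrix: dict[str, dict[int, dict[str, float]]],
        calibration: tuple[float, float] = (math.log(50000.0), 1.0),
    ) -> None:
        a, b = calibration
        if b <= 0:
            raise ValidationError("calibration slope b must be positive")
        for allele, positions in matrix.items():
            for p in range(1, 11):
                if p not in positions:
                    raise ValidationError(
                        f"allele {allele!r}: matrix missing position {p}"
                    )
                missing = set(STANDARD_RESIDUES) - set(positions[p])
                if missing:
                    raise ValidationError(
                        f"allele {allele!r} position {p}: missing residues "
                        f"{sorted(missing)}"
                    )
        self.matrix = matrix
        self.a, self.b = a, b
        self.alleles = sorted(matrix)

    def predict(self, peptide: str, allele: str) -> float:
        if allele not in self.matrix:
            raise MissingPredictionError(f"unknown allele {allele!r}")
        if not 8 <= len(peptide) <= 10:
            raise ValidationError(
                f"peptide length {len(peptide)} outside 8–10"
            )
        positions = self.matrix[allele]
        score = 0.0
        for i, aa in enumerate(peptide, start=1):
            if aa not in STANDARD_RESIDUES:
                raise ValidationError(
                    f"non-standard residue {aa!r} in peptide {peptide!r}"
                )
            score += positions[i][aa]
        return math.exp(self.a - self.b * score)


def surrogate_predictor(
    matrix_spec: dict[str, dict[int, dict[str, float]]],
    calibration: tuple[float, float] = (math.log(50000.0), 1.0),
) -> SurrogatePredictor:
    """Build the deterministic surrogate predictor from a score matrix."""
    return SurrogatePredictor(matrix_spec, calibration)


def default_surrogate(alleles: list[str], seed: int) -> SurrogatePredictor:
    """A seeded random surrogate matrix spreading affinities around 500 nM.

    Per-position weights ~ N(0.45, 0.75) give 8–10-mer score sums whose
    exp(a − S) map straddles the 500 nM threshold, so both weak and strong
    binders occur. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    matrix: dict[str, dict[int, dict[str, float]]] = {}
    for allele in alleles:
        matrix[allele] = {
            p: {aa: float(rng.normal(0.45, 0.75))
                for aa in STANDARD_RESIDUES}
            for p in range(1, 11)
        }
    return SurrogatePredictor(matrix)


class PredictionTable:
    """Keyed (peptide, allele) → nM lookup backed by a predictions TSV."""

    def __init__(self, table: dict[tuple[str, str], float]) -> None:
        for (pep, allele), nm in table.items():
            if nm <= 0:
                raise ValidationError(
                    f"non-positive affinity {nm} for ({pep!r}, {allele!r})"
                )
        self._table = dict(table)
        self.alleles = sorted({a for _, a in table})

    def predict(self, peptide: str, allele: str) -> float:
        try:
            return self._table[(peptide, allele)]
        except KeyError:
            raise MissingPredictionError(
                f"no affinity for peptide {peptide!r} on allele {allele!r}"
            ) from None

    def __len__(self) -> int:
        return len(self._table)


def read_predictions(path: str | Path) -> PredictionTable:
    """Read an external predictor's output TSV (peptide, allele, affinity_nM).

    Identical duplicate rows are deduplicated; conflicting duplicates error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("peptide", "allele", "affinity_nM"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    table: dict[tuple[str, str], float] = {}
    for r in df.itertuples():
        key = (str(r.peptide), str(r.allele))
        nm = float(r.affinity_nM)
        if nm <= 0:
            raise ValidationError(
                f"{path}: non-positive affinity {nm} for {key}"
            )
        if key in table and table[key] != nm:
            raise DuplicateKeyError(
                f"{path}: conflicting affinities for {key}: "
                f"{table[key]} vs {nm}"
            )
        table[key] = nm
    return PredictionTable(table)


def write_predictions(table: dict[tuple[str, str], float],
                      path: str | Path) -> None:
    df = pd.DataFrame(
        [(p, a, nm) for (p, a), nm in sorted(table.items())],
        columns=["peptide", "allele", "affinity_nM"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def heteroclitic_filter(
    candidate: EpitopeCandidate,
    predictor: AffinityPredictor,
    alleles: list[str],
    threshold_nM: float = DEFAULT_THRESHOLD_NM,
) -> EpitopeCandidate:
    """Score a candidate and apply the differential-binding rule.

    The candidate passes iff on at least one single allele the wild-type
    peptide binds weakly (strictly above the threshold) while the mutant
    binds strongly (strictly below). Both conditions must hold on the SAME
    allele; cross-allele combinations do not pass, and affinities exactly at
    the threshold fail.
    """
    passing: list[str] = []
    for allele in alleles:
        wt = predictor.predict(candidate.wt_peptide, allele)
        mut = predictor.predict(candidate.mut_peptide, allele)
        candidate.affinities[allele] = (wt, mut)
        if wt > threshold_nM and mut < threshold_nM:
            passing.append(allele)
    candidate.passes_binding = bool(passing)
    candidate.passing_alleles = passing
    return candidate


def expression_filter(
    gene: str,
    table: list[ExpressionRecord],
    tissue: str,
    min_tpm: float = 1.0,
) -> bool:
    """True iff the gene is expressed (TPM ≥ min_tpm) in the tissue.

    A gene absent from the table is treated as not expressed; its absence is
    logged rather than raised.
    """
    gene_seen = False
    for rec in table:
        if rec.gene == gene:
            gene_seen = True
            if rec.tissue == tissue and rec.tpm >= min_tpm:
                return True
    if not gene_seen:
        logger.info("expression_filter: gene %r absent from table", gene)
    return False
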