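"""Orchestration of the full heteroclitic-neoepitope screen.

Stage order (fixed): signature classification → missense/transition filter →
flanking-context extraction → 8–10-mer window enumeration → per-allele
affinity scoring with the differential-binding filter → tissue-expression
refinement → clonality report → polyepitope construct design. Filter stages
only shrink the candidate set; the window stage is the only one that expands.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from .constructs import ConstructDesign, design_construct, write_construct_fasta
from .effects import annotate_effects, missense_transition_filter
from .epitopes import (
    ALLOWED_LENGTHS,
    AffinityPredictor,
    EpitopeCandidate,
    default_surrogate,
    enumerate_windows,
    expression_filter,
    extract_context,
    heteroclitic_filter,
    read_predictions,
)
from .errors import ConfigError
from .seqmodel import (
    CodingSequence,
    ExpressionRecord,
    SNV,
    read_expression_table,
    read_fasta,
    read_vcf,
)
from .signature import (
    MOTIF_MODES,
    classify_signature,
    estimate_clonality,
    signature_fraction,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one screening run; round-trips through YAML losslessly."""

    fasta: str = ""
    vcf: str = ""
    predictions: str = ""          # external predictor TSV; "" → surrogate
    expression: str = ""
    outdir: str = "screen_out"
    tissue: str = "skin"
    motif_mode: str = "TC"
    threshold_nM: float = 500.0
    alleles: list[str] = field(default_factory=lambda: ["H-2Kb", "H-2Db"])
    min_tpm: float = 1.0
    flank: int = 10
    lengths: list[int] = field(default_factory=lambda: [8, 9, 10])
    clonal_threshold: float = 0.9
    spacer: str = "AAY"
    degron_prefix: str = ""
    require_signature: bool = True
    permissive: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True)
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Finding:
    severity: str  # {error, warning}
    field: str
    message: str


def validate_config(config: RunConfig,
                    check_paths: bool = True) -> list[Finding]:
    """Static checks on a run configuration; findings, never exceptions."""
    out: list[Finding] = []

    def err(f: str, m: str) -> None:
        out.append(Finding("error", f, m))

    if check_paths:
        for name in ("fasta", "vcf", "expression"):
            p = getattr(config, name)
            if not p:
                err(name, "path is required")
            elif not Path(p).exists():
                err(name, f"path does not exist: {p}")
        if config.predictions and not Path(config.predictions).exists():
            err("predictions", f"path does not exist: {config.predictions}")
    if config.motif_mode not in MOTIF_MODES:
        err("motif_mode", f"must be one of {MOTIF_MODES}")
    if config.threshold_nM < 0:
        err("threshold_nM", "must be non-negative")
    if not config.alleles:
        err("alleles", "at least one allele is required")
    if config.min_tpm < 0:
        err("min_tpm", "must be non-negative")
    if config.flank < 1:
        err("flank", "must be >= 1")
    bad_lengths = set(config.lengths) - ALLOWED_LENGTHS
    if bad_lengths:
        err("lengths",
            f"outside the supported 8–10 range: {sorted(bad_lengths)}")
    if not config.lengths:
        err("lengths", "at least one peptide length is required")
    if not 0 <= config.clonal_threshold <= 1:
        err("clonal_threshold", "must lie in [0, 1]")
    return out


@dataclass
class ScreenReport:
    """Per-stage funnel counts plus the final candidate table and designs."""

    counts: dict[str, int]
    signature_fraction: float | None
    candidates: list[dict]
    constructs: list[ConstructDesign]
    manifest: dict

    def final_candidates(self) -> list[dict]:
        return [c for c in self.candidates
                if c["passes_binding"] and c["expressed_in_tissue"]]

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "signature_fraction": self.signature_fraction,
            "candidates": self.candidates,
            "constructs": [
                {"name": d.name, "protein": d.protein, "dna": d.dna,
                 "n_epitopes": len(d.epitopes)}
                for d in self.constructs
            ],
            "manifest": self.manifest,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def screen(
    seqs: list[CodingSequence],
    snvs: list[SNV],
    predictor: AffinityPredictor,
    expression: list[ExpressionRecord],
    *,
    motif_mode: str = "TC",
    threshold_nM: float = 500.0,
    alleles: list[str] | None = None,
    tissue: str = "skin",
    min_tpm: float = 1.0,
    flank: int = 10,
    lengths: set[int] = frozenset({8, 9, 10}),
    clonal_threshold: float = 0.9,
    require_signature: bool = True,
    spacer: str = "AAY",
    degron_prefix: str = "",
    permissive: bool = False,
    manifest: dict | None = None,
) -> ScreenReport:
    """Run the full screen on in-memory objects. Deterministic."""
    alleles = list(alleles) if alleles else ["H-2Kb", "H-2Db"]
    seq_by_id = {s.id: s for s in seqs}
    missing = sorted({v.seq_id for v in snvs} - set(seq_by_id))
    if missing:
        raise ConfigError(
            f"variants reference unknown sequences: {missing[:5]}"
        )

    calls = [classify_signature(v, seq_by_id[v.seq_id], motif_mode)
             for v in snvs]
    n_sig = sum(c.is_signature for c in calls)
    sig_frac = signature_fraction(calls) if calls else None
    logger.info("signature: %d/%d variants carry the motif", n_sig, len(snvs))

    effects = annotate_effects(snvs, seq_by_id, permissive=permissive)
    survivors = missense_transition_filter(
        effects, calls, require_signature=require_signature
    )
    logger.info("missense/transition filter: %d survivors", len(survivors))

    clonality = {v.key: estimate_clonality(v, clonal_threshold) for v in snvs}

    contexts = []
    skipped_downstream = 0
    for e in survivors:
        protein = seq_by_id[e.snv.seq_id].protein.rstrip("*")
        if e.codon_index > len(protein):
            skipped_downstream += 1
            continue
        contexts.append(extract_context(e, protein, flank=flank))
    if skipped_downstream:
        logger.info("contexts: skipped %d variant(s) downstream of a stop",
                    skipped_downstream)

    windows: list[EpitopeCandidate] = []
    for ctx in contexts:
        windows.extend(enumerate_windows(ctx, set(lengths)))
    logger.info("windows: %d candidate peptide pairs", len(windows))

    for cand in windows:
        heteroclitic_filter(cand, predictor, alleles, threshold_nM)
    n_binding = sum(bool(c.passes_binding) for c in windows)

    expressed_cache: dict[str, bool] = {}
    rows: list[dict] = []
    for cand in windows:
        snv = cand.context.effect.snv
        gene = seq_by_id[snv.seq_id].gene
        if gene not in expressed_cache:
            expressed_cache[gene] = expression_filter(
                gene, expression, tissue, min_tpm
            )
        cand.expressed_in_tissue = expressed_cache[gene]
        clon = clonality[snv.key]
        row = {
            "gene": gene,
            "seq_id": snv.seq_id,
            "pos": snv.pos,
            "ref": snv.ref,
            "alt": snv.alt,
            "hgvs_p": cand.context.effect.hgvs_p,
            "length": cand.length,
            "wt_peptide": cand.wt_peptide,
            "mut_peptide": cand.mut_peptide,
            "mut_pos_in_window": cand.mut_pos_in_window,
            "passes_binding": bool(cand.passes_binding),
            "passing_alleles": ",".join(cand.passing_alleles),
            "expressed_in_tissue": cand.expressed_in_tissue,
            "vaf": clon.vaf,
            "clonal_flag": clon.clonal_flag,
        }
        for allele in alleles:
            wt_nm, mut_nm = cand.affinities[allele]
            row[f"wt_nM_{allele}"] = wt_nm
            row[f"mut_nM_{allele}"] = mut_nm
        rows.append(row)

    final = [r for r in rows
             if r["passes_binding"] and r["expressed_in_tissue"]]
    logger.info("binding passers: %d; expressed final candidates: %d",
                n_binding, len(final))

    constructs: list[ConstructDesign] = []
    if final:
        mut_peps, wt_peps, seen = [], [], set()
        for r in final:
            if r["mut_peptide"] not in seen:
                seen.add(r["mut_peptide"])
                mut_peps.append(r["mut_peptide"])
                wt_peps.append(r["wt_peptide"])
        constructs.append(design_construct(
            mut_peps, spacer=spacer, degron_prefix=degron_prefix,
            name="apobec_epitope_string"))
        constructs.append(design_construct(
            wt_peps, spacer=spacer, degron_prefix=degron_prefix,
            name="wildtype_epitope_string"))

    counts = {
        "total_variants": len(snvs),
        "signature_positive": n_sig,
        "missense_transition": len(survivors),
        "contexts": len(contexts),
        "windows": len(windows),
        "binding_passers": n_binding,
        "final_candidates": len(final),
    }
    assert counts["signature_positive"] <= counts["total_variants"]
    assert counts["missense_transition"] <= counts["total_variants"]
    assert counts["final_candidates"] <= counts["binding_passers"]
    if require_signature:
        assert counts["missense_transition"] <= counts["signature_positive"]

    return ScreenReport(
        counts=counts,
        signature_fraction=sig_frac,
        candidates=rows,
        constructs=constructs,
        manifest=manifest or {"version": _version},
    )


def run_screen(config: RunConfig) -> ScreenReport:
    """File-level entry point: load inputs, run the screen, write outputs.

    Emits candidates.tsv, constructs.fasta, report.json, and run.log under
    ``config.outdir``. Deterministic given config + seed.
    """
    findings = validate_config(config)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ConfigError(
            "; ".join(f"{f.field}: {f.message}" for f in errors)
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("neoscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        seqs = read_fasta(config.fasta)
        snvs = read_vcf(config.vcf)
        expression = read_expression_table(config.expression)
        if config.predictions:
            predictor: AffinityPredictor = read_predictions(config.predictions)
        else:
            predictor = default_surrogate(config.alleles, config.seed)

        manifest = {
            "version": _version,
            "config": asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
        }
        report = screen(
            seqs, snvs, predictor, expression,
            motif_mode=config.motif_mode,
            threshold_nM=config.threshold_nM,
            alleles=config.alleles,
            tissue=config.tissue,
            min_tpm=config.min_tpm,
            flank=config.flank,
            lengths=set(config.lengths),
            clonal_threshold=config.clonal_threshold,
            require_signature=config.require_signature,
            spacer=config.spacer,
            degron_prefix=config.degron_prefix,
            permissive=config.permissive,
            manifest=manifest,
        )

        if report.candidates:
            pd.DataFrame(report.candidates).to_csv(
                outdir / "candidates.tsv", sep="\t", index=False
            )
        if report.constructs:
            write_construct_fasta(report.constructs,
                                  outdir / "constructs.fasta")
        (outdir / "report.json").write_text(report.to_json() + "\n")
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
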