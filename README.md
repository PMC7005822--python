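# neoscreen

A tested, reusable pipeline for screening **APOBEC-signature heteroclitic
neoepitopes** from coding-sequence variants and for designing polyepitope
("epitope string") vaccine inserts.

APOBEC3B is a cytidine deaminase that mutates tumour genomes, preferentially
converting C→T at cytosines in a 5′-TC(A/T) context (or, on the opposite
strand, G→A with the motif mirrored). Some of the resulting mutant peptides
are *heteroclitic*: they bind MHC class I more strongly than their wild-type
counterparts and can prime T cells that cross-react with the unmutated self
epitope. `neoscreen` implements the computational arm of that screen, for
immunologists and bioinformaticians working from variant calls on annotated
coding sequences:

1. **Signature classification** — each SNV is tested for the deamination
   motif (`TC` minimal mode, default, or strict `TCW`), with full strand
   symmetry: C→T with a 5′ T, or G→A with a 3′ A, motifs reported in
   pyrimidine orientation.
2. **Effect annotation** — codon-level consequences (`P5S` style HGVS-p),
   then a filter keeping missense C→T / G→A transition events.
3. **Peptide enumeration** — a context of up to 21 residues (10 flanking
   each side of the substitution) and every 8/9/10-mer window containing the
   mutated residue, paired wild-type vs mutant.
4. **Differential MHC-I binding** — a candidate passes iff on at least one
   allele the wild-type peptide binds *weakly* (> 500 nM) while the mutant
   binds *strongly* (< 500 nM); both conditions strictly, on the same
   allele. Affinities come from an external predictor's TSV or from the
   bundled deterministic surrogate (clearly non-biological, for testing).
5. **Expression refinement and clonality** — candidates are kept only if
   the gene is expressed in the target tissue (TPM ≥ 1 by default), and each
   reported with its variant allele frequency (alt / (ref + alt) reads).
6. **Construct design** — the surviving mutant (and wild-type) peptides are
   joined with AAY spacers (n − 1 spacers for n epitopes), optionally
   prefixed by an N-end degron, and back-translated to DNA with a fixed
   codon table.

A synthetic-data module generates coding sequences, mutation mixtures with a
known implanted signature fraction and Beta-distributed subclonal VAFs,
designed affinity tables, and expression tables — so every stage is testable
with known ground truth and no downloads.

## Worked example

The pipeline's flagship check is a Sanger-confirmed mutation in the CSDE1
gene. Given the wild-type coding stretch `ATGAGCTTTGATCCA` and the mutant
`ATGAGCTTTGATTCA`:

```python
from neoscreen import SNV, CodingSequence, classify_signature, annotate_effect

wt = CodingSequence(id="csde1", dna="ATGAGCTTTGATCCA")
snv = SNV("csde1", pos=13, ref="C", alt="T", ref_count=70, alt_count=30)

call = classify_signature(snv, wt, motif_mode="TC")
print(call.is_signature, call.motif, call.deaminated_strand)
# True TCC plus

eff = annotate_effect(snv, wt)
print(eff.hgvs_p, eff.effect_class, eff.codon_ref, eff.codon_alt)
# P5S missense CCA TCA
```

The C→T at base 13 sits in a 5′-T context (motif `TCC`, plus strand), strikes
codon 5 (`CCA`→`TCA`), and changes proline to serine — the `P5S`
substitution. `MSFDP` translates to `MSFDS` in the mutant.

A full run goes through a YAML config and the CLI:

```bash
neoscreen simulate --outdir demo --n-sequences 20 --n-mutations 60 \
    --signature-fraction 0.5 --seed 3
neoscreen screen --config run.yaml     # prints the per-stage funnel counts
neoscreen design --peptide MSFDSAAAA --peptide LLLLLLLLL --out string.fasta
# toy: 2 epitopes, protein length 21
```

`screen` writes `candidates.tsv`, `constructs.fasta`, `report.json` and
`run.log` to the configured output directory; the report's funnel counts are
monotone non-increasing through the filter stages.

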