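# Methods

## The screening model

The pipeline operates entirely in coding-sequence (CDS) space: variants are
single-nucleotide substitutions with 1-based positions on a supplied CDS, and
every downstream coordinate (codon index, context window, peptide position)
derives from that convention. Genome-space variants must be projected onto
CDSs before entry; indels are parsed and skipped with a logged count rather
than silently dropped, because the screen builds peptides only from missense
substitutions.

### Signature classification

An APOBEC deamination event is a C→T transition whose cytosine lies in a
5′-TC context; on the antisense strand the same chemistry appears on the
reported (plus) strand as G→A with a 3′ A. Two motif modes are provided:

- **TC** (default): mutated C preceded 5′ by T (minimal deamination
  context). This is the default because the canonical validated mutation in
  this screen — CSDE1 P5S, context `TCC` — carries a 3′ C and would fail the
  strict trinucleotide rule despite being a reproducible deamination target.
- **TCW**: additionally requires a 3′ A or T, for analyses that want the
  classical strict motif.

TCW calls are a subset of TC calls by construction. Context bases that would
fall outside the sequence fail the motif (no wrap-around, no error): an edge
variant is simply not classifiable as signature. Motifs are reported in
pyrimidine orientation so plus- and minus-strand events are directly
comparable.

The operational definition of "signature" is genuinely ambiguous in the
field (dinucleotide vs trinucleotide vs full SBS2/13 deconvolution); both
motif modes are exposed rather than resolving the ambiguity. Signature
deconvolution and kataegis detection are out of scope.

### Effect annotation and the transition filter

Codon index = ⌈pos / 3⌉; the reference and alternate codons are translated
with the standard genetic code and classified as synonymous, missense,
nonsense, or stoploss. The screen's filter keeps missense effects from
C→T / G→A transitions; requiring the signature motif on top of the
transition is a switch (`require_signature`, default on) because the source
procedure's wording leaves it open whether motif context or the bare
transition was required. Stoploss variants are classified but always
excluded. Two SNVs in one codon are annotated independently with a logged
warning; joint-codon annotation is not modelled.

### Peptide windows

A missense substitution at codon *i* on a protein of length *L* yields the
context [max(1, i−10), min(L, i+10)] — at most 21 residues, with the mutant
residue central when both flanks are full. For each peptide length
k ∈ {8, 9, 10}, every k-window containing the mutated residue is emitted
left-to-right, paired wild-type vs mutant; a full context yields 8 + 9 + 10
= 27 windows with the mutant residue occupying every position 1..k per k.
Variants annotated downstream of a premature stop are skipped (logged).

### Differential binding

A window passes iff some **single** allele has wild-type affinity strictly
above and mutant affinity strictly below the threshold (default 500 nM, the
conventional weak/strong binder boundary). Cross-allele combinations are
rejected, and equality at the threshold fails, per the weak-ABOVE /
strong-BELOW reading of the rule. Allele names are opaque strings; defaults
are two murine class-I slots ("H-2Kb", "H-2Db"), freely configurable.

Affinities come from either (a) an external predictor's TSV
(peptide / allele / affinity_nM; conflicting duplicates are errors), the
supported scientific path, or (b) the bundled **surrogate predictor** — a
deterministic position-weight model mapping the score sum S to
`exp(a − b·S)` nM with a = ln 50000, b = 1 by default. The surrogate is
explicitly non-biological: it exists so the pipeline, its filters, and its
determinism are testable end to end with no external tool. Its default
random matrices (N(0.45, 0.75) per position/residue weights) are chosen only
so 8–10-mer affinities straddle 500 nM.

### Expression and clonality

A candidate gene must be expressed in the target tissue: a (gene, tissue)
TPM record with TPM ≥ `min_tpm` (default 1.0, the conventional "expressed"
heuristic; no cutoff is canonical). Genes absent from the table count as not
expressed, logged. Clonality is reported, never filtered on by default:
VAF = alt/(ref+alt), flagged clonal at VAF ≥ 0.9 (approximate fixation in a
near-diploid line; configurable), undefined at zero depth.

A gene passes if any of its windows passes; all passing windows are
reported, each traceable to exactly one SNV.

### Construct design

Selected peptides are joined with `AAY` spacers strictly between consecutive
epitopes (n − 1 spacers, none terminal) and optionally prefixed with an
N-end degron. No specific degron sequence is assumed — the prefix is a
configurable amino-acid string, default empty, e.g. a ubiquitin-fusion
arginine (`R`) placed N-terminal to the first epitope; placement ahead of
the first epitope is a documented assumption. Back-translation uses one
fixed, documented codon per residue (a common mammalian-usage choice);
codon optimisation, vector assembly, and the P2A-eGFP reporter are out of
scope (metadata only). `translate(dna) == protein` holds for every design
by construction and is property-tested.

## Synthetic data: what it emulates, what it does not

`generate_cds_set` produces ATG-initiated, internal-stop-free random CDSs.
`implant_mutations` draws the signature count from
Binomial(n_mut, signature_fraction), places signature mutations at TC-motif
sites (C→T or mirrored G→A) sampled without replacement, and places
background mutations only at **non-motif** sites, so ground-truth signature
status is exact by construction and the two classes cannot be confounded.
With `vaccine_like=True` signature sites are restricted to positions where
the deamination event is missense, so screening funnels of a chosen size
can be constructed. Each mutation receives a true VAF from Beta(2, 5) —
mass concentrated between roughly 0.05 and 0.6, matching a subclonal sweep
from under 10% to about 60% — converted to read counts binomially at 100×
depth (no depth information is canonical; 100× is a typical resequencing
depth). The truth table records signature status, motif, strand, effect
class (computed by whole-protein re-translation, an arithmetic-independent
route), and true VAF.

`generate_affinity_table` designs a predictions table in which exactly
`n_heteroclitic` distinct wild-type/mutant pairs pass the differential rule
on one designated allele and every other pair violates it on every allele;
the realised pass set is verified against the design and a capacity error is
raised if peptide collisions break it.

What the generator does **not** emulate: sequencing noise and caller
artifacts, depth/quality pre-filters, kataegis spatial clustering,
linkage between mutations, real codon usage, or real binding chemistry.
Passing recovery tests therefore demonstrates the pipeline's logic is
correct and deterministic — not that any particular real tumour would yield
a particular candidate count.

## Numerical and design choices

- Strict inequalities at the binding threshold; ties fail.
- Filter-stage order is fixed: signature → missense/transition → contexts →
  windows → binding → expression. Funnel counts are asserted monotone.
- Determinism: all randomness flows through `numpy.random.default_rng(seed)`;
  identical config + seed reproduce byte-identical TSV/FASTA/VCF/JSON
  outputs (the run report embeds the resolved config and its hash, and no
  wall-clock fields).
- Validation is strict by default; a `permissive` flag downgrades
  reference-base mismatches to warnings for dirty inputs. No depth or
  quality filter is applied to incoming variants (exposed as config, since
  no canonical pre-filter exists for this screen).
- Problem sizes in the test suite and acceptance script (10,000-mutation
  recovery sets, a 244-candidate funnel, 10,000 random filter pairs) were
  chosen to exercise the statistics at the screen's own scale while keeping
  a full run in seconds.

## Known limitations

- CDS-space only; no genome liftover, splice, UTR, or frameshift/indel
  consequences.
- The surrogate predictor's affinities are not biology; real screens must
  supply predictions from a trained MHC-binding model via the TSV adapter.
- Multi-SNV codons are annotated per-SNV, not jointly.
- The expression filter is a thresholded lookup, not a statistical test of
  expression.
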