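import math

import numpy as np
import pytest

from neoscreen import (
    SNV,
    CodingSequence,
    ConfigError,
    DuplicateKeyError,
    ExpressionRecord,
    FormatError,
    MissingPredictionError,
    PredictionTable,
    ValidationError,
    annotate_effect,
    enumerate_windows,
    expression_filter,
    extract_context,
    heteroclitic_filter,
    read_predictions,
    surrogate_predictor,
)
from neoscreen.epitopes import STANDARD_RESIDUES, EpitopeCandidate

from conftest import make_context


class TestExtractContext:
    def test_short_protein_clips_both_sides(self, csde1_seq, csde1_snv):
        eff = annotate_effect(csde1_snv, csde1_seq)
        ctx = extract_context(eff, csde1_seq.protein)
        assert ctx.wt_context == "MSFDP"
        assert ctx.mut_context == "MSFDS"
        assert ctx.mut_index == 5

    def test_central_mutation_gives_full_21mer(self):
        protein = "".join(STANDARD_RESIDUES[i % 20] for i in range(30))
        eff = _missense_effect(protein, 15)
        ctx = extract_context(eff, protein)
        assert len(ctx.wt_context) == 21
        assert ctx.mut_index == 11
        assert ctx.wt_context == protein[4:25]

    def test_left_clip(self):
        protein = "".join(STANDARD_RESIDUES[i % 20] for i in range(50))
        eff = _missense_effect(protein, 3)
        ctx = extract_context(eff, protein)
        assert len(ctx.wt_context) == 13  # residues 1..13
        assert ctx.mut_index == 3

    def test_non_missense_rejected(self, csde1_seq):
        eff = annotate_effect(SNV("csde1", 6, "C", "T"), csde1_seq)
        with pytest.raises(ValidationError):
            extract_context(eff, csde1_seq.protein)


def _missense_effect(protein, codon_index):
    from neoscreen import CodingEffect
    aa_ref = protein[codon_index - 1]
    aa_alt = "W" if aa_ref != "W" else "Y"
    return CodingEffect(
        snv=SNV("p", 1, "C", "T"), codon_index=codon_index,
        codon_ref="NNN", codon_alt="NNN", aa_ref=aa_ref, aa_alt=aa_alt,
        effect_class="missense", hgvs_p=f"{aa_ref}{codon_index}{aa_alt}",
    )


def brute_force_windows(L, m, k):
    """All k-substrings of a length-L string covering position m."""
    return [s for s in range(1, L - k + 2) if s <= m <= s + k - 1]


class TestEnumerateWindows:
    def test_full_context_yields_27(self):
        ctx = make_context(21, 11)
        cands = enumerate_windows(ctx)
        assert len(cands) == 27
        for k in (8, 9, 10):
            positions = sorted(c.mut_pos_in_window for c in cands
                               if c.length == k)
            assert positions == list(range(1, k + 1))

    def test_length8_context_single_window(self):
        ctx = make_context(8, 4)
        cands = enumerate_windows(ctx)
        assert len(cands) == 1
        assert cands[0].length == 8 and cands[0].mut_pos_in_window == 4

    def test_lengths_outside_range_rejected(self):
        with pytest.raises(ConfigError):
            enumerate_windows(make_context(21, 11), lengths={7})

    def test_counts_match_brute_force_for_all_contexts(self):
        for L in range(1, 22):
            for m in range(1, L + 1):
                cands = enumerate_windows(make_context(L, m))
                for k in (8, 9, 10):
                    expect = brute_force_windows(L, m, k)
                    got = [c for c in cands if c.length == k]
                    assert len(got) == len(expect)
                    # windows in left-to-right order, each pair differing
                    # exactly at the mutated residue
                    for c, s in zip(got, expect):
                        assert c.mut_pos_in_window == m - s + 1
                        diffs = [i for i, (a, b) in
                                 enumerate(zip(c.wt_peptide, c.mut_peptide))
                                 if a != b]
                        assert diffs == [c.mut_pos_in_window - 1]


def toy_matrix(alleles=("H-2Kb",), hot=None):
    """Zero matrix; optionally score ``hot`` residues at given positions."""
    m = {a: {p: {aa: 0.0 for aa in STANDARD_RESIDUES} for p in range(1, 11)}
         for a in alleles}
    for a, p, aa, v in hot or []:
        m[a][p][aa] = v
    return m


class TestSurrogatePredictor:
    def test_closed_form_calibration(self):
        # score sum 0 → 50000 nM; sum ln(100) → 500 nM
        pred = surrogate_predictor(
            toy_matrix(hot=[("H-2Kb", 1, "A", math.log(100))]),
            calibration=(math.log(50000), 1.0),
        )
        assert pred.predict("GGGGGGGG", "H-2Kb") == pytest.approx(50000.0)
        assert pred.predict("AGGGGGGG", "H-2Kb") == pytest.approx(500.0)

    def test_deterministic(self):
        pred = surrogate_predictor(toy_matrix())
        assert pred.predict("ACDEFGHI", "H-2Kb") == \
            pred.predict("ACDEFGHI", "H-2Kb")

    def test_monotone_in_scores(self):
        lo = surrogate_predictor(toy_matrix())
        hi = surrogate_predictor(toy_matrix(hot=[("H-2Kb", 3, "D", 1.0)]))
        pep = "ACDEFGHI"
        assert hi.predict(pep, "H-2Kb") < lo.predict(pep, "H-2Kb")

    def test_argmax_peptide_is_minimum_nm(self):
        rng = np.random.default_rng(0)
        m = toy_matrix()
        for p in range(1, 11):
            for aa in STANDARD_RESIDUES:
                m["H-2Kb"][p][aa] = float(rng.normal())
        pred = surrogate_predictor(m)
        best = "".join(max(m["H-2Kb"][p], key=m["H-2Kb"][p].get)
                       for p in range(1, 10))
        assert all(
            pred.predict(best, "H-2Kb") <= pred.predict(
                "".join(rng.choice(list(STANDARD_RESIDUES), size=9)),
                "H-2Kb")
            for _ in range(50)
        )

    def test_unknown_residue_rejected(self):
        pred = surrogate_predictor(toy_matrix())
        with pytest.raises(ValidationError):
            pred.predict("ACDEFGHX", "H-2Kb")


class TestReadPredictions:
    def test_lookup(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("peptide\tallele\taffinity_nM\nMSFDSAAAA\tH-2Kb\t320.0\n")
        table = read_predictions(p)
        assert table.predict("MSFDSAAAA", "H-2Kb") == 320.0

    def test_identical_duplicates_deduplicated(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("peptide\tallele\taffinity_nM\n"
                     "AAAAAAAA\tH-2Kb\t10\nAAAAAAAA\tH-2Kb\t10\n")
        assert len(read_predictions(p)) == 1

    def test_conflicting_duplicates_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("peptide\tallele\taffinity_nM\n"
                     "AAAAAAAA\tH-2Kb\t10\nAAAAAAAA\tH-2Kb\t20\n")
        with pytest.raises(DuplicateKeyError):
            read_predictions(p)

    def test_nonpositive_affinity_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("peptide\tallele\taffinity_nM\nAAAAAAAA\tH-2Kb\t0\n")
        with pytest.raises(ValidationError):
            read_predictions(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("peptide\taffinity_nM\nAAAAAAAA\t10\n")
        with pytest.raises(FormatError, match="allele"):
            read_predictions(p)

    def test_missing_prediction_names_pair(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("peptide\tallele\taffinity_nM\nAAAAAAAA\tH-2Kb\t10\n")
        with pytest.raises(MissingPredictionError, match="H-2Db"):
            read_predictions(p).predict("AAAAAAAA", "H-2Db")


def make_candidate(wt="ALFASFDKV", mut="ALFTSFDKV"):
    ctx = make_context(9, 4)
    return EpitopeCandidate(context=ctx, wt_peptide=wt, mut_peptide=mut,
                            length=9, mut_pos_in_window=4)


class TestHeterocliticFilter:
    @pytest.mark.parametrize(
        "wt_nm,mut_nm,passes",
        [
            (800.0, 300.0, True),   # weak wild-type, strong mutant
            (300.0, 100.0, False),  # wild-type already strong
            (800.0, 600.0, False),  # mutant still weak
            (500.0, 500.0, False),  # strict inequality at the threshold
            (500.0, 499.0, False),  # wt must be strictly above
            (501.0, 500.0, False),  # mut must be strictly below
            (501.0, 499.0, True),   # just either side of the threshold
        ],
    )
    def test_single_allele_rule(self, wt_nm, mut_nm, passes):
        cand = make_candidate()
        table = PredictionTable({
            (cand.wt_peptide, "H-2Kb"): wt_nm,
            (cand.mut_peptide, "H-2Kb"): mut_nm,
        })
        heteroclitic_filter(cand, table, ["H-2Kb"], threshold_nM=500.0)
        assert cand.passes_binding is passes
        assert cand.passing_alleles == (["H-2Kb"] if passes else [])

    def test_conditions_must_cooccur_on_one_allele(self):
        # allele 1: wt weak but mut weak; allele 2: mut strong but wt strong
        cand = make_candidate()
        table = PredictionTable({
            (cand.wt_peptide, "A1"): 800.0, (cand.mut_peptide, "A1"): 600.0,
            (cand.wt_peptide, "A2"): 400.0, (cand.mut_peptide, "A2"): 300.0,
        })
        heteroclitic_filter(cand, table, ["A1", "A2"])
        assert cand.passes_binding is False

    def test_missing_affinity_raises(self):
        cand = make_candidate()
        table = PredictionTable({(cand.wt_peptide, "H-2Kb"): 800.0})
        with pytest.raises(MissingPredictionError):
            heteroclitic_filter(cand, table, ["H-2Kb"])

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(99)
        alleles = ["A1", "A2"]
        for _ in range(200):
            cand = make_candidate()
            table = {}
            for pep in (cand.wt_peptide, cand.mut_peptide):
                for a in alleles:
                    table[(pep, a)] = float(rng.uniform(1, 2000))
            heteroclitic_filter(cand, PredictionTable(table), alleles)
            oracle = any(
                table[(cand.wt_peptide, a)] > 500.0
                and table[(cand.mut_peptide, a)] < 500.0
                for a in alleles
            )
            assert cand.passes_binding is oracle


class TestExpressionFilter:
    TABLE = [
        ExpressionRecord("Csde1", "skin", 12.5),
        ExpressionRecord("Xpo1", "skin", 0.4),
        ExpressionRecord("Smc4", "liver", 9.0),
    ]

    def test_expressed(self):
        assert expression_filter("Csde1", self.TABLE, "skin", 1.0)

    def test_below_cutoff(self):
        assert not expression_filter("Xpo1", self.TABLE, "skin", 1.0)

    def test_wrong_tissue(self):
        assert not expression_filter("Smc4", self.TABLE, "skin", 1.0)

    def test_absent_gene_logged(self, caplog):
        with caplog.at_level("INFO"):
            assert not expression_filter("Stag2", self.TABLE, "skin")
        assert "Stag2" in caplog.text
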