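"""Diagnostic-window scanning, primer proposal, separation prediction."""

import numpy as np
import pytest

from meltmark.design import (DesignError, GroupSpec, predict_assay_separation,
                             propose_primer_pairs, scan_diagnostic_windows)
from meltmark.seqio import Alignment
from meltmark.synth import MarkerSpec, PanelSpec, simulate_reference_panel

from oracles import brute_scan


def alignment_from(rows):
    return Alignment(rows=rows)


def make_planted_alignment(seed=0, n_cols=500, snp_col=250, flank=25):
    """Two groups identical everywhere except one diagnostic SNP with
    conserved flanks around it; background noise outside the flanks."""
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), n_cols)
    rows = []
    for g, members in (("A", ["a1", "a2"]), ("B", ["b1", "b2"])):
        row = base.copy()
        if g == "B":
            row[snp_col] = {"A": "G", "G": "A", "C": "T", "T": "C"}[row[snp_col]]
        rows.extend((m, "".join(row)) for m in members)
    return alignment_from(rows), GroupSpec({"A": ["a1", "a2"], "B": ["b1", "b2"]})


class TestScan:
    def test_identical_groups_give_no_windows(self):
        rng = np.random.default_rng(1)
        row = "".join(rng.choice(list("ACGT"), 300))
        aln = alignment_from([("a1", row), ("b1", row)])
        groups = GroupSpec({"A": ["a1"], "B": ["b1"]})
        result = scan_diagnostic_windows(aln, groups, 100, 160, 18, 2)
        assert len(result) == 0
        assert result.failure_tallies["pair_discrimination"] > 0

    def test_planted_snp_recovered(self):
        aln, groups = make_planted_alignment()
        result = scan_diagnostic_windows(aln, groups, 100, 160, 18, 2)
        assert len(result) > 0
        s, e = result[0].window
        assert s <= 250 < e
        assert result[0].diagnostic_columns == [250]
        # every returned window covers the SNP in its interior
        for cand in result:
            assert cand.window[0] + 18 <= 250 < cand.window[1] - 18

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_brute_force_enumeration(self, seed):
        panel = simulate_reference_panel(PanelSpec(
            n_groups=3, members_per_group=2, seq_len=300,
            markers=[MarkerSpec(start=120, end=233)], seed=seed))
        result = scan_diagnostic_windows(panel.alignment, panel.groups,
                                         100, 140, 18, 2)
        got = {c.window for c in result}
        expected = brute_scan(panel.alignment.rows, panel.groups.groups,
                              100, 140, 18, 2)
        assert got == expected

    def test_constraint_tightening_never_adds_windows(self):
        aln, groups = make_planted_alignment(seed=3)
        wide = {c.window for c in
                scan_diagnostic_windows(aln, groups, 100, 160, 18, 3)}
        narrow_len = {c.window for c in
                      scan_diagnostic_windows(aln, groups, 110, 150, 18, 3)}
        stricter_flanks = {c.window for c in
                           scan_diagnostic_windows(aln, groups, 100, 160, 18, 0)}
        assert narrow_len <= wide
        assert stricter_flanks <= wide

    def test_ranking_prefers_more_diagnostic_columns_then_shorter(self):
        aln, groups = make_planted_alignment(seed=4)
        result = scan_diagnostic_windows(aln, groups, 100, 160, 18, 2)
        keys = [(-len(c.diagnostic_columns), c.aligned_length) for c in result]
        assert keys == sorted(keys)

    def test_min_len_must_fit_flanks(self):
        aln, groups = make_planted_alignment()
        with pytest.raises(ValueError):
            scan_diagnostic_windows(aln, groups, 30, 160, 18, 2)


class TestProposePrimers:
    def test_conserved_flanks_give_concrete_primers(self):
        aln, groups = make_planted_alignment()
        result = scan_diagnostic_windows(aln, groups, 100, 160, 18, 2)
        pairs = propose_primer_pairs(result[0], aln)
        for f, r in pairs:
            assert all(c in "ACGT" for c in f.sequence + r.sequence)

    def test_variable_flank_column_becomes_iupac_code(self):
        aln, groups = make_planted_alignment(seed=5)
        result = scan_diagnostic_windows(aln, groups, 100, 160, 18, 2)
        s, e = result[0].window
        rows = [(rid, bases[:s + 5] + ("A" if rid.startswith("a") else "G")
                 + bases[s + 6:]) for rid, bases in aln.rows]
        aln2 = alignment_from(rows)
        result2 = scan_diagnostic_windows(aln2, groups, 100, 160, 18, 2)
        cand = next(c for c in result2 if c.window == (s, e))
        # wide Tm constraints: this test is about the IUPAC consensus only
        pairs = propose_primer_pairs(cand, aln2, tm_range=(30.0, 80.0),
                                     max_pair_dtm=30.0)
        assert pairs and pairs[0][0].sequence[5] == "R"

    def test_excessive_degeneracy_rejected_with_reason(self):
        aln, groups = make_planted_alignment(seed=6)
        result = scan_diagnostic_windows(aln, groups, 100, 160, 18, 2)
        s, e = result[0].window
        rows = []
        for rid, bases in aln.rows:
            b = list(bases)
            if rid.startswith("a"):
                for off in (2, 6, 10, 14):  # 4 variable flank columns
                    b[s + off] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[s + off]]
            rows.append((rid, "".join(b)))
        aln2 = alignment_from(rows)
        cand = next(c for c in scan_diagnostic_windows(aln2, groups, 100, 160, 18, 4)
                    if c.window == (s, e))
        with pytest.raises(DesignError, match="degenerate"):
            propose_primer_pairs(cand, aln2, max_degenerate=3)


class TestSeparation:
    def test_identical_consensi_not_separable(self):
        rng = np.random.default_rng(7)
        row = "".join(rng.choice(list("ACGT"), 200))
        aln = alignment_from([("a1", row), ("b1", row)])
        groups = GroupSpec({"A": ["a1"], "B": ["b1"]})
        cand_window = (20, 140)
        from meltmark.design import MarkerCandidate

        cand = MarkerCandidate(window=cand_window, amplicon_len={"A": 120, "B": 120},
                               diagnostic_columns=[], intra_group_identical={},
                               has_indel=False, flank_variable_columns=(0, 0))
        out = predict_assay_separation(cand, aln, groups)
        assert out[("A", "B")]["identity_pct"] == pytest.approx(100.0)
        assert out[("A", "B")]["delta_tm"] == pytest.approx(0.0)
        assert not out[("A", "B")]["separable"]

    def test_single_gc_substitution_separates(self):
        aln, groups = make_planted_alignment(seed=8)
        # force the planted SNP to be an A/T -> G/C change
        rows = []
        for rid, bases in aln.rows:
            b = list(bases)
            b[250] = "A" if rid.startswith("a") else "G"
            rows.append((rid, "".join(b)))
        aln = alignment_from(rows)
        result = scan_diagnostic_windows(aln, groups, 100, 160, 18, 2)
        out = predict_assay_separation(result[0], aln, groups)
        pair = out[("A", "B")]
        assert pair["delta_tm"] > 0
        assert pair["separable"]

    def test_one_base_indel_flagged(self):
        rng = np.random.default_rng(9)
        base = rng.choice(list("ACGT"), 200)
        with_gap = base.copy().astype(object)
        rows = [("a1", "".join(base)),
                ("b1", "".join(with_gap[:100]) + "-" + "".join(with_gap[101:]))]
        aln = alignment_from(rows)
        groups = GroupSpec({"A": ["a1"], "B": ["b1"]})
        from meltmark.design import MarkerCandidate

        cand = MarkerCandidate(window=(40, 160), amplicon_len={"A": 120, "B": 119},
                               diagnostic_columns=[100], intra_group_identical={},
                               has_indel=True, flank_variable_columns=(0, 0))
        out = predict_assay_separation(cand, aln, groups)
        assert out[("A", "B")]["indel"]


class TestSparidae16sFixture:
    def test_proposed_pair_matches_deployed_hrm_primers(self, genomes, primers):
        """On the 16s fixture alignment, the scanner's primer proposal lands
        on the deployed HRM 16s primer footprints (within 2 bases)."""
        from meltmark.pcr import amplify

        rows = []
        groups = {}
        for code in ("PpG", "PpI", "Pm", "Pc", "Pe", "Dg"):
            amp = amplify(genomes[code], primers["16sF2"], primers["16SR2"])[0]
            seq = amp.sequence
            if len(seq) == 681:           # align against the 682-base variants
                seq = seq[:400] + "-" + seq[400:]
            rows.append((code, seq))
            groups[code] = [code]
        aln = Alignment(rows=rows)
        result = scan_diagnostic_windows(aln, GroupSpec(groups),
                                         min_len=150, max_len=160,
                                         flank_len=23, max_flank_mismatch=0)
        assert len(result) > 0
        # the deployed primer footprints sit at columns 300..323 / 434..457
        windows = [c.window for c in result]
        assert any(abs(s - 300) <= 2 and abs(e - 457) <= 2 for s, e in windows)
        target = next(c for c in result if c.window == (300, 457))
        # the deployed pair's Tm gap exceeds the default pairing constraint
        pairs = propose_primer_pairs(target, aln, flank_len=23, max_pair_dtm=8.0)
        assert pairs
        fwd, rev = pairs[0]
        assert fwd.sequence == primers["HRM16sF1"].sequence
        assert rev.sequence == primers["HRM16sR1"].sequence
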