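import numpy as np
import pandas as pd
import pytest

from heterosiskit.lncrna import (
    basic_filter,
    build_catalog,
    coding_consensus,
    genomic_gap,
    match_known,
    positional_class,
    predict_targets,
    summarize_catalog,
)


def _catalog(rows):
    base = {"gene_id": "g", "chrom": "chr1", "start": 1000, "end": 2000,
            "exon_count": 2}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestBasicFilter:
    @pytest.mark.parametrize(
        "length,code,strand,kept",
        [
            (150, "u", "+", False),   # too short
            (500, "j", "+", False),   # wrong class code
            (500, "u", ".", False),   # unstranded
            (200, "x", "+", True),    # 200 exactly passes (< 200 removed)
            (201, "i", "-", True),
            (1000, "=", "-", False),
        ],
    )
    def test_filter_rules(self, length, code, strand, kept):
        cat = _catalog([{"transcript_id": "t1", "spliced_length": length,
                         "class_code": code, "strand": strand}])
        out = basic_filter(cat)
        assert (len(out) == 1) == kept

    def test_monotone_in_min_length(self):
        rng = np.random.default_rng(2)
        cat = _catalog(
            [{"transcript_id": f"t{i}", "spliced_length": int(l),
              "class_code": "u", "strand": "+"}
             for i, l in enumerate(rng.integers(50, 1000, 50))]
        )
        sizes = [len(basic_filter(cat, min_length=m)) for m in (100, 200, 400)]
        assert sizes == sorted(sizes, reverse=True)


class TestMatchKnown:
    def test_exact_match_is_known(self):
        cat = _catalog([{"transcript_id": "t1", "spliced_length": 6,
                         "class_code": "u", "strand": "+"}])
        known, rem = match_known(cat, {"t1": "ACGTAC"}, {"ref1": "ACGTAC"})
        assert list(known["transcript_id"]) == ["t1"] and rem.empty

    def test_single_mismatch_fails_at_full_identity(self):
        cat = _catalog([{"transcript_id": "t1", "spliced_length": 6,
                         "class_code": "u", "strand": "+"}])
        known, rem = match_known(cat, {"t1": "ACGTAC"}, {"ref1": "ACGTAG"})
        assert known.empty and len(rem) == 1

    def test_relaxed_identity_allows_mismatch(self):
        cat = _catalog([{"transcript_id": "t1", "spliced_length": 10,
                         "class_code": "u", "strand": "+"}])
        known, _ = match_known(
            cat, {"t1": "ACGTACGTAC"}, {"ref1": "ACGTACGTAG"}, identity_min=0.9
        )
        assert list(known["transcript_id"]) == ["t1"]

    def test_empty_reference_leaves_all_unknown(self):
        cat = _catalog([{"transcript_id": "t1", "spliced_length": 6,
                         "class_code": "u", "strand": "+"}])
        known, rem = match_known(cat, {"t1": "ACGTAC"}, {})
        assert known.empty and len(rem) == 1

    def test_missing_sequence_warns_and_passes_through(self):
        cat = _catalog([{"transcript_id": "t1", "spliced_length": 6,
                         "class_code": "u", "strand": "+"}])
        with pytest.warns(RuntimeWarning, match="no sequence"):
            known, rem = match_known(cat, {}, {"ref1": "ACGTAC"})
        assert known.empty and len(rem) == 1


class TestCodingConsensus:
    def _remainder(self):
        return _catalog([{"transcript_id": "t1", "spliced_length": 500,
                          "class_code": "u", "strand": "+"}])

    def _scores(self, cnci, cpc, plek, ev):
        return pd.DataFrame(
            [{"transcript_id": "t1", "cnci": cnci, "cpc": cpc, "plek": plek,
              "pfam_evalue": ev}]
        )

    def test_as_printed_paper_example(self):
        out = coding_consensus(self._remainder(), self._scores(-0.5, -1.2, -0.1, 1e-7))
        assert out["reason"].iloc[0] == ""

    def test_score_zero_excluded_strict_inequality(self):
        out = coding_consensus(self._remainder(), self._scores(0.0, -1, -1, 1e-7))
        assert out["reason"].iloc[0] == "cnci_nonnegative"

    def test_evalue_boundary_exactly_1e5_excluded_as_printed(self):
        out = coding_consensus(self._remainder(), self._scores(-1, -1, -1, 1e-5))
        assert out["reason"].iloc[0] == "pfam_evalue_too_large"

    def test_pfam_logic_variants_disagree_on_no_hit(self):
        scores = self._scores(-1, -1, -1, 0.5)
        as_printed = coding_consensus(self._remainder(), scores, "as_printed")
        no_hit = coding_consensus(self._remainder(), scores, "no_hit_required")
        assert as_printed["reason"].iloc[0] == "pfam_evalue_too_large"
        assert no_hit["reason"].iloc[0] == ""

    def test_missing_score_excluded_with_reason(self):
        out = coding_consensus(
            self._remainder(), self._scores(np.nan, -1, -1, 1e-7)
        )
        assert out["reason"].iloc[0] == "missing_cnci"

    def test_unknown_logic_rejected(self):
        with pytest.raises(ValueError):
            coding_consensus(self._remainder(), self._scores(-1, -1, -1, 1), "maybe")


class TestPositionalClass:
    def test_class_codes_map_directly(self):
        cat = _catalog(
            [{"transcript_id": t, "spliced_length": 300, "class_code": c,
              "strand": "+"} for t, c in [("t1", "u"), ("t2", "i"), ("t3", "x")]]
        )
        assert list(positional_class(cat)) == ["intergenic", "intronic", "antisense"]

    def test_dot_code_coordinate_fallback(self):
        genes = pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 10_000, "strand": "+",
              "exon_start": 0, "exon_end": 500}]
        )
        lnc = _catalog(
            [
                # inside the gene body, clear of the exon -> intronic
                {"transcript_id": "t1", "spliced_length": 300, "class_code": ".",
                 "strand": "+", "start": 2000, "end": 3000},
                # overlapping the exon on the opposite strand -> antisense
                {"transcript_id": "t2", "spliced_length": 300, "class_code": ".",
                 "strand": "-", "start": 100, "end": 400},
                # elsewhere -> intergenic
                {"transcript_id": "t3", "spliced_length": 300, "class_code": ".",
                 "strand": "+", "start": 50_000, "end": 51_000},
            ]
        )
        assert list(positional_class(lnc, genes)) == [
            "intronic", "antisense", "intergenic"
        ]


class TestSummaries:
    def test_single_transcript_point_masses(self):
        cat = _catalog([{"transcript_id": "t1", "spliced_length": 300,
                         "class_code": "u", "strand": "+"}])
        s = summarize_catalog(cat)
        assert s["n"] == 1
        assert sum(s["length_hist"]["counts"]) == 1
        assert s["chrom_pct"]["chr1"] == 100.0

    def test_chromosome_shares(self):
        cat = _catalog(
            [{"transcript_id": f"t{i}", "spliced_length": 300, "class_code": "u",
              "strand": "+", "chrom": c} for i, c in enumerate(["chr1", "chr1", "chr2"])]
        )
        s = summarize_catalog(cat)
        assert s["chrom_pct"]["chr1"] == pytest.approx(200 / 3)
        assert sum(s["chrom_pct"].values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            summarize_catalog(_catalog([]).iloc[:0])


class TestTargets:
    def test_gap_symmetric_and_zero_for_overlap(self):
        assert genomic_gap("chr1", 0, 100, "chr1", 50, 150) == 0.0
        assert genomic_gap("chr1", 0, 100, "chr1", 600, 700) == 500.0
        assert genomic_gap("chr1", 600, 700, "chr1", 0, 100) == 500.0
        assert genomic_gap("chr1", 0, 100, "chr2", 0, 100) == np.inf

    @staticmethod
    def _expr(mapping):
        cols = [f"S{i}" for i in range(8)]
        return pd.DataFrame(mapping, index=cols).T

    def test_cis_trans_and_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.normal(100, 20, 8)
        expr = self._expr(
            {
                "lnc1": np.round(base).astype(int),
                "gene_near": np.round(base * 1.01 + rng.normal(0, 0.1, 8)).astype(int),
                "gene_far": np.round(base * 0.99).astype(int),
                "gene_uncorr": rng.poisson(100, 8),
            }
        )
        lnc = pd.DataFrame([{"transcript_id": "lnc1", "chrom": "chr1",
                             "start": 0, "end": 1000}])
        genes = pd.DataFrame(
            [
                {"gene_id": "gene_near", "chrom": "chr1", "start": 11_000, "end": 12_000},
                {"gene_id": "gene_far", "chrom": "chr1", "start": 600_000, "end": 601_000},
                {"gene_id": "gene_uncorr", "chrom": "chr1", "start": 20_000, "end": 21_000},
            ]
        )
        pairs = predict_targets(lnc, genes, expr,
                                factors=pd.Series(1.0, index=expr.columns))
        modes = dict(zip(pairs["gene_id"], pairs["mode"]))
        assert modes["gene_near"] == "cis"
        assert modes["gene_far"] == "trans"
        assert "gene_uncorr" not in modes

    def test_constant_vector_skipped_with_warning(self):
        expr = self._expr({"lnc1": [5] * 8, "g1": list(range(8))})
        lnc = pd.DataFrame([{"transcript_id": "lnc1", "chrom": "chr1",
                             "start": 0, "end": 10}])
        genes = pd.DataFrame([{"gene_id": "g1", "chrom": "chr1",
                               "start": 100, "end": 200}])
        with pytest.warns(RuntimeWarning, match="constant"):
            pairs = predict_targets(lnc, genes, expr,
                                    factors=pd.Series(1.0, index=expr.columns))
        assert pairs.empty


class TestCascade:
    def test_cascade_is_refinement_chain(self, transcript_fixture):
        catalog, seqs, scores, ref, truth = transcript_fixture
        result = build_catalog(catalog, seqs, ref, scores,
                               pfam_logic="no_hit_required")
        survivors = set(basic_filter(catalog)["transcript_id"])
        lnc = result[result["status"].isin(["known", "putative"])]
        assert set(lnc["transcript_id"]) <= survivors
        assert not (
            set(result.loc[result["status"] == "known", "transcript_id"])
            & set(result.loc[result["status"] == "putative", "transcript_id"])
        )

    def test_known_fraction_one_all_survivors_known(self):
        catalog, seqs, scores, ref, truth = __import__(
            "heterosiskit.simulate", fromlist=["simulate_transcript_set"]
        ).simulate_transcript_set(n=100, seed=5, known_fraction=1.0)
        result = build_catalog(catalog, seqs, ref, scores)
        lnc = result[result["status"].isin(["known", "putative"])]
        assert (lnc["status"] == "known").all()
        assert len(lnc) == len(basic_filter(catalog))

    def test_coding_consensus_recovers_truth(self, transcript_fixture):
        catalog, seqs, scores, ref, truth = transcript_fixture
        # evaluate on all scored transcripts so the check is about the scores
        cons = coding_consensus(catalog, scores, pfam_logic="no_hit_required")
        m = cons.merge(truth, on="transcript_id")
        called_nc = m["reason"] == ""
        tp = (called_nc & ~m["coding"]).sum()
        precision = tp / called_nc.sum()
        recall = tp / (~m["coding"]).sum()
        assert precision >= 0.95 and recall >= 0.95
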