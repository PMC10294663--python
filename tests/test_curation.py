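"""Keyword classification, scaffold features, verdict rules, gene summaries."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sporeamg.curation import (
    CurationConfig,
    GeneClass,
    ScaffoldFeatures,
    ScaffoldMap,
    ScaffoldVerdict,
    classify_gene,
    extract_features,
    score_scaffold,
    summarize_gene,
)
from sporeamg.errors import ValidationError
from sporeamg.io_ingest import GeneAnnotation
from sporeamg.synthetic_data import ScaffoldSpec, generate_scaffold


def _scaffold(descriptions, strands=None, focal=None, ko="K07699"):
    n = len(descriptions)
    strands = strands or ["+"] * n
    focal = n // 2 if focal is None else focal
    genes = [
        GeneAnnotation(
            gene_id=f"g{i:03d}",
            scaffold_id="s1",
            start=1 + i * 1000,
            end=900 + i * 1000,
            strand=strands[i],
            ko_id=ko if i == focal else None,
            description=d,
        )
        for i, d in enumerate(descriptions)
    ]
    return ScaffoldMap(scaffold_id="s1", genes=genes, focal_gene_id=f"g{focal:03d}")


class TestClassifyGene:
    @pytest.mark.parametrize(
        "description,expected",
        [
            ("Major Capsid Protein", GeneClass.HALLMARK_VIRAL),
            ("phage terminase large subunit", GeneClass.HALLMARK_VIRAL),
            ("putative TAIL fiber", GeneClass.HALLMARK_VIRAL),
            ("", GeneClass.HYPOTHETICAL),
            ("hypothetical protein", GeneClass.HYPOTHETICAL),
            ("Uncharacterized protein YabC", GeneClass.HYPOTHETICAL),
            ("DNA gyrase subunit A", GeneClass.OTHER_ANNOTATION),
            ("citrate synthase", GeneClass.OTHER_ANNOTATION),
        ],
    )
    def test_keyword_classes(self, description, expected):
        assert classify_gene(description) is expected

    def test_hallmark_beats_hypothetical(self):
        assert (
            classify_gene("hypothetical phage protein") is GeneClass.HALLMARK_VIRAL
        )


class TestExtractFeatures:
    def test_first_gene_focal_is_edge(self):
        smap = _scaffold(["hypothetical protein"] * 8, focal=0)
        assert extract_features(smap).is_edge

    def test_last_gene_focal_is_edge(self):
        smap = _scaffold(["hypothetical protein"] * 8, focal=7)
        assert extract_features(smap).is_edge

    def test_same_strand_window_has_zero_switches(self):
        smap = _scaffold(["hypothetical protein"] * 8)
        assert extract_features(smap).strand_switch_frac == 0.0

    def test_alternating_strands_give_full_switch_fraction(self):
        strands = ["+", "-"] * 4
        smap = _scaffold(["hypothetical protein"] * 8, strands=strands)
        assert extract_features(smap).strand_switch_frac == 1.0

    def test_density_excludes_focal_gene(self):
        # focal + 4 annotated + 2 hypothetical context genes -> density 4/6
        desc = ["citrate synthase"] * 4 + ["x"] + ["hypothetical protein"] * 2
        smap = _scaffold(desc, focal=4)
        feats = extract_features(smap)
        assert feats.nonviral_density == pytest.approx(4 / 6)
        assert feats.hypothetical_frac == pytest.approx(2 / 6)

    def test_hallmark_flanked_requires_both_sides(self):
        base = ["hypothetical protein"] * 9
        one_side = list(base)
        one_side[2] = "major capsid protein"  # left of focal (index 4) only
        assert not extract_features(_scaffold(one_side)).hallmark_flanked
        both = list(one_side)
        both[6] = "minor tail protein"
        assert extract_features(_scaffold(both)).hallmark_flanked

    def test_bacterial_generator_fixture_exceeds_thresholds(self):
        smap = generate_scaffold(
            ScaffoldSpec(kind="bacterial", n_genes=20, strand_switch_rate=0.5, seed=3)
        )
        feats = extract_features(smap)
        assert feats.nonviral_density >= 0.5
        assert feats.strand_switch_frac >= 0.4


class TestScoreScaffold:
    def test_edge_focal_rejected(self):
        verdict = score_scaffold(_scaffold(["hypothetical protein"] * 8, focal=0))
        assert verdict.verdict == "false"
        assert "edge_reject" in verdict.reasons

    def test_hallmark_flanked_low_density_accepted(self):
        desc = ["hypothetical protein"] * 9
        desc[3] = "major capsid protein"
        desc[5] = "phage holin"
        verdict = score_scaffold(_scaffold(desc))
        assert verdict.verdict == "true"
        assert "hallmark_flanked_accept" in verdict.reasons

    def test_bacterial_context_rejected_only_when_both_signals_high(self):
        annotated = ["citrate synthase"] * 9
        alternating = ["+", "-"] * 5
        # both high -> false
        v = score_scaffold(_scaffold(annotated, strands=alternating[:9]))
        assert v.verdict == "false"
        assert "bacterial_context_reject" in v.reasons
        # density high, switches zero -> maybe
        v2 = score_scaffold(_scaffold(annotated))
        assert v2.verdict == "maybe"

    def test_no_rule_fires_gives_maybe(self):
        desc = ["hypothetical protein"] * 6 + ["citrate synthase"] * 3
        verdict = score_scaffold(_scaffold(desc, focal=4))
        assert verdict.verdict == "maybe"

    @given(st.randoms(use_true_random=False))
    def test_verdict_invariant_to_input_gene_order(self, rnd):
        smap = generate_scaffold(ScaffoldSpec(kind="viral", n_genes=20, seed=13))
        shuffled_genes = list(smap.genes)
        rnd.shuffle(shuffled_genes)
        reshuffled = ScaffoldMap(
            scaffold_id=smap.scaffold_id,
            genes=shuffled_genes,
            focal_gene_id=smap.focal_gene_id,
        )
        assert score_scaffold(reshuffled).verdict == score_scaffold(smap).verdict


def _verdict(ko, verdict):
    return ScaffoldVerdict(
        scaffold_id="s",
        ko_id=ko,
        verdict=verdict,
        features=ScaffoldFeatures(False, 0.0, 0.0, True, 1.0),
        reasons=("hallmark_flanked_accept",),
    )


class TestSummarizeGene:
    @pytest.mark.parametrize(
        "n_true,n_false,n_maybe,category",
        [
            (0, 12, 0, "unlikely viral"),
            (1, 5, 2, "possible viral"),
            (3, 0, 0, "possible viral"),
            (4, 10, 1, "possible viral"),
            (5, 0, 0, "likely viral"),
            (40, 3, 2, "likely viral"),
        ],
    )
    def test_category_thresholds(self, n_true, n_false, n_maybe, category):
        verdicts = (
            [_verdict("K1", "true")] * n_true
            + [_verdict("K1", "false")] * n_false
            + [_verdict("K1", "maybe")] * n_maybe
        )
        summary = summarize_gene(verdicts, n_scaffolds_detected=100)
        assert summary.category == category
        assert summary.n_true + summary.n_false + summary.n_maybe == summary.n_inspected
        assert summary.n_inspected <= summary.n_scaffolds_detected

    def test_mixed_ko_ids_rejected(self):
        with pytest.raises(ValidationError, match="mixed"):
            summarize_gene([_verdict("K1", "true"), _verdict("K2", "true")])

    def test_detected_fewer_than_inspected_rejected(self):
        with pytest.raises(ValidationError):
            summarize_gene([_verdict("K1", "true")] * 3, n_scaffolds_detected=2)


class TestConfig:
    def test_window_must_cover_flank_reach(self):
        with pytest.raises(ValidationError, match="window"):
            CurationConfig(window=2, flank_reach=3)

    def test_keywords_lowercased(self):
        cfg = CurationConfig(hallmark_keywords=("CAPSID",))
        assert classify_gene("capsid protein", cfg) is GeneClass.HALLMARK_VIRAL
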