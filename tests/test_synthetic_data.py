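"""Generator contracts: exact fractions, ground-truth consistency, determinism."""

import numpy as np
import pandas as pd
import pytest

from sporeamg.curation import GeneClass, classify_gene
from sporeamg.domain_profile import span_coverage
from sporeamg.errors import ValidationError
from sporeamg.synthetic_data import (
    GeneSpec,
    PopulationSpec,
    RegulatorSeqSpec,
    ScaffoldSpec,
    generate_population,
    generate_regulator_alignment,
    generate_scaffold,
)


def _spore_phage_mask(tables) -> pd.Series:
    spore_ids = set(tables.hosts.host_id[tables.hosts.is_spore_former])
    return tables.phages.host_id.isin(spore_ids)


class TestPopulation:
    def test_spore_host_fraction_is_rounding_exact(self):
        tables = generate_population(
            PopulationSpec(n_phages=10, frac_spore_host=0.5, gene_specs=(), seed=1)
        )
        assert _spore_phage_mask(tables).sum() == 5
        assert len(tables.phages) == 10

    def test_degenerate_probabilities_place_gene_exactly(self):
        gene = GeneSpec("K07699", p_carry_spore_host=1.0, p_carry_other=0.0)
        tables = generate_population(
            PopulationSpec(n_phages=40, frac_spore_host=0.5, gene_specs=(gene,), seed=2)
        )
        spore = set(tables.phages.phage_id[_spore_phage_mask(tables)])
        carriers = set(tables.annotations.phage_id[tables.annotations.ko_id == "K07699"])
        assert carriers == spore

    def test_carriage_rates_within_three_binomial_errors(self):
        # binomial sampling check: observed carriage close to (0.2, 0.02)
        gene = GeneSpec("K1", 0.2, 0.02)
        tables = generate_population(
            PopulationSpec(n_phages=2000, frac_spore_host=0.3, gene_specs=(gene,), seed=7)
        )
        mask = _spore_phage_mask(tables)
        carriers = set(tables.annotations.phage_id[tables.annotations.ko_id == "K1"])
        in_carrier = tables.phages.phage_id.isin(carriers)
        for p_true, group in ((0.2, mask), (0.02, ~mask)):
            n_group = int(group.sum())
            rate = in_carrier[group].mean()
            se = np.sqrt(p_true * (1 - p_true) / n_group)
            assert abs(rate - p_true) <= 3 * se

    def test_identical_seed_identical_output(self):
        spec = PopulationSpec(
            n_phages=50, frac_spore_host=0.4, gene_specs=(GeneSpec("K1", 0.3, 0.1),), seed=11
        )
        a, b = generate_population(spec), generate_population(spec)
        for name in ("hosts", "phages", "annotations", "truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_ground_truth_label_tracks_probabilities(self):
        assert GeneSpec("K1", 0.2, 0.02).label == "enriched"
        assert GeneSpec("K1", 0.1, 0.1).label == "null"
        assert GeneSpec("K1", 0.05, 0.1).label == "null"

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(n_phages=0, frac_spore_host=0.5), "n_phages"),
            (dict(n_phages=5, frac_spore_host=1.5), "frac_spore_host"),
        ],
    )
    def test_invalid_population_spec_names_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            PopulationSpec(gene_specs=(), seed=0, **kwargs)

    def test_invalid_carriage_probability_names_field(self):
        with pytest.raises(ValidationError, match="p_carry_other"):
            GeneSpec("K1", 0.5, 1.2)


class TestScaffolds:
    def test_viral_interior_focal_is_hallmark_flanked(self):
        smap = generate_scaffold(ScaffoldSpec(kind="viral", n_genes=20, seed=4))
        f = smap.focal_index
        for side in (-1, +1):
            assert any(
                classify_gene(smap.genes[f + side * off].description)
                is GeneClass.HALLMARK_VIRAL
                for off in range(1, 4)
            )

    def test_viral_edge_focal_sits_at_scaffold_end(self):
        for seed in range(6):
            smap = generate_scaffold(
                ScaffoldSpec(kind="viral", n_genes=20, focal_position="edge", seed=seed)
            )
            assert smap.focal_index in (0, len(smap.genes) - 1)

    def test_bacterial_strand_switch_rate_is_lower_bound(self):
        smap = generate_scaffold(
            ScaffoldSpec(kind="bacterial", n_genes=20, strand_switch_rate=0.5, seed=3)
        )
        switches = sum(
            a.strand != b.strand for a, b in zip(smap.genes, smap.genes[1:])
        )
        assert switches >= 9  # >= ceil(0.5 * 19) - 1 pairs on opposite strands

    def test_viral_strand_switch_rate_is_upper_bound(self):
        for seed in range(5):
            smap = generate_scaffold(
                ScaffoldSpec(kind="viral", n_genes=30, strand_switch_rate=0.1, seed=seed)
            )
            pairs = len(smap.genes) - 1
            switches = sum(
                a.strand != b.strand for a, b in zip(smap.genes, smap.genes[1:])
            )
            assert switches / pairs <= 0.1

    def test_bacterial_scaffold_majority_annotated_no_hallmark(self):
        smap = generate_scaffold(ScaffoldSpec(kind="bacterial", n_genes=20, seed=9))
        classes = [classify_gene(g.description) for g in smap.genes if g.ko_id is None]
        assert sum(c is GeneClass.OTHER_ANNOTATION for c in classes) >= 0.6 * len(classes)
        assert not any(c is GeneClass.HALLMARK_VIRAL for c in classes)

    def test_chimeric_focal_in_bacterial_block(self):
        smap = generate_scaffold(ScaffoldSpec(kind="chimeric", n_genes=30, seed=2))
        # genes after the bacterial block must contain hallmark/hypothetical only
        tail = smap.genes[-5:]
        assert all(
            classify_gene(g.description)
            in (GeneClass.HALLMARK_VIRAL, GeneClass.HYPOTHETICAL)
            for g in tail
        )
        assert smap.focal_index < len(smap.genes) - 5

    def test_coordinates_ascending_nonoverlapping(self):
        smap = generate_scaffold(ScaffoldSpec(kind="viral", n_genes=15, seed=8))
        prev_end = 0
        for g in smap.genes:
            assert g.start > prev_end
            assert g.start <= g.end
            assert g.strand in {"+", "-"}
            prev_end = g.end

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError, match="n_genes"):
            ScaffoldSpec(kind="viral", n_genes=4)


class TestRegulatorAlignment:
    def test_noise_free_full_length_has_no_gaps_in_spans(self):
        aln = generate_regulator_alignment(
            RegulatorSeqSpec(n_full_length=1, n_effector_only=0, indel_rate=0.0, seed=1)
        )
        (seq,) = aln.seqs
        assert span_coverage(seq, (6, 125)) == 1.0
        assert span_coverage(seq, (146, 255)) == 1.0

    def test_effector_only_receiver_span_is_all_gaps(self):
        aln = generate_regulator_alignment(
            RegulatorSeqSpec(n_full_length=0, n_effector_only=1, indel_rate=0.0, seed=1)
        )
        (seq,) = aln.seqs
        assert span_coverage(seq, (6, 125)) == 0.0
        assert span_coverage(seq, (146, 255)) == 1.0

    def test_group_sizes_and_labels(self):
        aln = generate_regulator_alignment(
            RegulatorSeqSpec(n_full_length=57, n_effector_only=29, seed=0)
        )
        groups = [aln.labels[i] for i in aln.ids]
        assert groups.count("bacteria") == 57
        assert groups.count("virome") == 29
        assert len({len(s) for s in aln.seqs}) == 1

    def test_noise_never_enters_forbidden_receiver_span(self):
        aln = generate_regulator_alignment(
            RegulatorSeqSpec(n_full_length=0, n_effector_only=20, indel_rate=0.3, seed=5)
        )
        for seq in aln.seqs:
            assert span_coverage(seq, (6, 125)) == 0.0

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValidationError, match="receiver_span"):
            RegulatorSeqSpec(receiver_span=(6, 150), effector_span=(146, 255))

    def test_determinism(self):
        spec = RegulatorSeqSpec(n_full_length=5, n_effector_only=5, indel_rate=0.1, seed=42)
        a = generate_regulator_alignment(spec)
        b = generate_regulator_alignment(spec)
        assert a.seqs == b.seqs and a.ids == b.ids
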