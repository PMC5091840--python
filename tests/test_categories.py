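"""Category enrichment, gene density and stage-expression tabulations."""

import numpy as np
import pandas as pd
import pytest

from minichrom import (
    CoverageTrack,
    STAGES,
    fold_enrichment,
    gene_density,
    stage_expression_counts,
)

# the four study categories planted at their published mean enrichments
MEANS = {"MDS": 0.04, "CBS_RELATED": 0.23, "EMC": 0.60, "IES": 0.68}


def _four_category_setup():
    arr = np.empty(4000)
    annotations = {}
    for i, (label, mean) in enumerate(MEANS.items()):
        arr[i * 1000 : (i + 1) * 1000] = mean
        annotations[label] = {"c": [(i * 1000, (i + 1) * 1000)]}
    track = CoverageTrack(data={"c": arr}, sample_label="chip")
    return track, annotations


class TestFoldEnrichment:
    def test_planted_means_recovered_exactly(self):
        track, annotations = _four_category_setup()
        report = fold_enrichment(track, annotations)
        for label, mean in MEANS.items():
            assert report.category_means[label] == pytest.approx(mean)

    def test_emc_to_section_ratio_is_2_6(self):
        track, annotations = _four_category_setup()
        report = fold_enrichment(
            track, annotations,
            ratio_pairs=[("EMC", "CBS_RELATED"), ("IES", "CBS_RELATED")],
        )
        assert round(report.ratios["EMC/CBS_RELATED"], 1) == 2.6
        assert report.ratios["IES/CBS_RELATED"] == pytest.approx(0.68 / 0.23)

    def test_constant_track_gives_equal_means_and_unit_ratios(self):
        _, annotations = _four_category_setup()
        track = CoverageTrack(data={"c": np.full(4000, 0.42)})
        report = fold_enrichment(track, annotations, ratio_pairs=[("IES", "MDS")])
        assert all(v == pytest.approx(0.42) for v in report.category_means.values())
        assert report.ratios["IES/MDS"] == pytest.approx(1.0)

    def test_linearity_under_track_scaling(self):
        track, annotations = _four_category_setup()
        scaled = CoverageTrack(data={"c": track.data["c"] * 3.0})
        a = fold_enrichment(track, annotations, ratio_pairs=[("IES", "EMC")])
        b = fold_enrichment(scaled, annotations, ratio_pairs=[("IES", "EMC")])
        for label in MEANS:
            assert b.category_means[label] == pytest.approx(3 * a.category_means[label])
        assert b.ratios["IES/EMC"] == pytest.approx(a.ratios["IES/EMC"])

    def test_empty_category_raises(self):
        track, annotations = _four_category_setup()
        annotations["EMPTY"] = {"c": []}
        with pytest.raises(ValueError):
            fold_enrichment(track, annotations)

    def test_base_weighted_mean_over_uneven_intervals(self):
        arr = np.concatenate([np.full(100, 1.0), np.full(300, 2.0)])
        track = CoverageTrack(data={"c": arr})
        report = fold_enrichment(track, {"X": {"c": [(0, 100), (100, 400)]}})
        assert report.category_means["X"] == pytest.approx(1.75)


class TestGeneDensity:
    def test_simple_density(self):
        genes = [("c", i * 10_000, i * 10_000 + 500) for i in range(10)]
        df = gene_density(genes, {"X": {"c": [(0, 100_000)]}})
        assert df.loc["X", "gene_count"] == 10
        assert df.loc["X", "kb_per_gene"] == pytest.approx(10.0)

    def test_published_emc_gene_density(self):
        # 43 genes over 501.81 kb of eliminated minichromosomes -> 11.67 kb/gene
        genes = [("c", i * 11_000, i * 11_000 + 500) for i in range(43)]
        df = gene_density(genes, {"EMC": {"c": [(0, 501_810)]}})
        assert round(df.loc["EMC", "kb_per_gene"], 2) == 11.67

    def test_published_ies_gene_density(self):
        # 239 genes over 44.8 Mb of IES -> one gene per ~188 kb
        genes = [("c", i * 150_000, i * 150_000 + 500) for i in range(239)]
        df = gene_density(genes, {"IES": {"c": [(0, 44_800_000)]}})
        assert df.loc["IES", "kb_per_gene"] == pytest.approx(44_800 / 239)
        assert round(df.loc["IES", "kb_per_gene"]) == 187

    def test_density_consistency_identity(self):
        genes = [("c", 0, 100), ("c", 5000, 5100), ("c", 20_000, 20_100)]
        df = gene_density(genes, {"X": {"c": [(0, 30_000)]}})
        assert df.loc["X", "kb_per_gene"] * df.loc["X", "gene_count"] == pytest.approx(
            df.loc["X", "total_kb"]
        )

    def test_midpoint_assignment_and_empty_category(self):
        genes = [("c", 90, 210)]  # midpoint 150
        df = gene_density(
            genes, {"IN": {"c": [(100, 200)]}, "OUT": {"c": [(300, 400)]}}
        )
        assert df.loc["IN", "gene_count"] == 1
        assert df.loc["OUT", "gene_count"] == 0
        assert np.isnan(df.loc["OUT", "kb_per_gene"])


def _matrix(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=STAGES).fillna(0.0)
    df.index.name = "gene_id"
    return df


class TestStageExpression:
    def test_published_emc_row_pattern(self):
        # 21 / 4 / 3 genes first seen at 8 hpm / 16 hpm / 2 doublings; none earlier
        rows = {}
        for i in range(21):
            rows[f"g8_{i}"] = {"8hpm": 50.0}
        for i in range(4):
            rows[f"g16_{i}"] = {"16hpm": 50.0}
        for i in range(3):
            rows[f"g2d_{i}"] = {"2D": 50.0}
        mapping = {g: "echr2.105.1" for g in rows}
        counts, unmapped = stage_expression_counts(_matrix(rows), mapping)
        assert unmapped == []
        row = counts.loc["echr2.105.1"]
        assert tuple(row[["2hpm", "8hpm", "16hpm", "2D"]]) == (0, 21, 4, 3)
        assert row["growth"] == 0

    def test_all_zero_matrix_counts_nothing(self):
        counts, _ = stage_expression_counts(
            _matrix({"g1": {"8hpm": 0.0}, "g2": {"growth": 0.0}}), {"g1": "s", "g2": "s"}
        )
        assert counts.loc["s"].sum() == 0

    def test_threshold_above_all_values_counts_nothing(self):
        counts, _ = stage_expression_counts(
            _matrix({"g1": {"8hpm": 5.0}}), {"g1": "s"}, threshold=10.0
        )
        assert counts.loc["s"].sum() == 0

    def test_unmapped_genes_reported_separately(self):
        counts, unmapped = stage_expression_counts(
            _matrix({"g1": {"8hpm": 5.0}, "orphan": {"8hpm": 5.0}}), {"g1": "s"}
        )
        assert unmapped == ["orphan"]
        assert counts.loc["s", "8hpm"] == 1

    def test_cluster_rows_sum_members(self):
        rows = {"a1": {"8hpm": 1.0}, "b1": {"8hpm": 2.0}, "b2": {"16hpm": 2.0}}
        mapping = {"a1": "echr2.221.1", "b1": "echr2.221.2", "b2": "echr2.221.2"}
        counts, _ = stage_expression_counts(
            _matrix(rows), mapping,
            clusters={"echr2.221.1-5": ["echr2.221.1", "echr2.221.2"]},
        )
        assert counts.loc["echr2.221.1-5", "8hpm"] == 2
        assert counts.loc["echr2.221.1-5", "16hpm"] == 1

    def test_count_conservation_across_sections(self, rng):
        genes = {f"g{i}": {"8hpm": float(rng.integers(0, 3))} for i in range(50)}
        mapping = {f"g{i}": f"s{i % 5}" for i in range(50)}
        matrix = _matrix(genes)
        counts, unmapped = stage_expression_counts(matrix, mapping)
        assert counts["8hpm"].sum() == int((matrix["8hpm"] > 0).sum())

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            stage_expression_counts(_matrix({"g1": {"8hpm": -1.0}}), {"g1": "s"})


class TestSimulationRoundTrip:
    def test_counts_match_planted_stage_design(self, small_sim):
        from minichrom import simulate_expression

        matrix, mapping = simulate_expression(small_sim.config, small_sim.truth)
        counts, unmapped = stage_expression_counts(matrix, mapping)
        assert unmapped == []
        truth = small_sim.truth
        emc = {s.name for s in truth.sections if s.fate == "eliminated"}
        planted = {}
        for g in truth.genes:
            if g.section_name in emc and g.stage is not None:
                planted.setdefault(g.section_name, {s: 0 for s in STAGES})[g.stage] += 1
        for name, by_stage in planted.items():
            for stage, n in by_stage.items():
                assert counts.loc[name, stage] == n
        # eliminated-minichromosome genes are silent in growth and at 2 hpm
        emc_rows = counts.loc[[n for n in counts.index if n in emc]]
        assert emc_rows["growth"].sum() == 0
        assert emc_rows["2hpm"].sum() == 0
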