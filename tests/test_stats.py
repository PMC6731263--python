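"""Compactness statistics: densities, gene/intron stats, expression, GC, telomeres."""
import math

import numpy as np
import pytest

from karyoscan import (
    GeneModel,
    ParameterError,
    RegionClassMap,
    chromosome_densities,
    density_by_class,
    detect_telomeres,
    expression_fraction,
    gc_anomaly_windows,
    gene_stats,
    read_gff3,
    shared_protein_summary,
    variant_density,
)
from karyoscan.stats import revcomp
from karyoscan.synthetic import write_gff3


class TestVariantDensity:
    def test_headline_genome_wide_density(self):
        result = variant_density(7282 + 2048, 17_400_691)
        assert round(result.per_kb, 2) == 0.54
        assert round(result.pct_divergence, 2) == 0.05

    def test_zero_sites(self):
        assert variant_density(0, 1_000_000).per_kb == 0.0

    def test_zero_span_raises(self):
        with pytest.raises(ParameterError):
            variant_density(10, 0)

    def test_per_chromosome_densities_recompute_exactly(self, small_genome):
        spec, _, truth = small_genome
        table = chromosome_densities(truth.variants, spec.chrom_lengths_map)
        for row in table.itertuples(index=False):
            assert row.per_kb == row.n_sites / (row.length / 1000.0)


class TestDensityByClass:
    def test_planted_fold_difference_recovered(self, small_genome):
        spec, reference, truth = small_genome
        table = density_by_class(truth.variants, reference.class_map).set_index("region_class")
        requested_fold = spec.het_density["intergenic"] / spec.het_density["coding"]
        n_coding = table.loc["coding", "n_sites"]
        rel_se = 2 * math.sqrt(1 / max(n_coding, 1) + 1 / max(table.loc["intergenic", "n_sites"], 1))
        assert table.loc["intergenic", "fold_vs_coding"] == pytest.approx(
            requested_fold, rel=3 * rel_se
        )

    def test_partition_conservation(self, small_genome):
        _, reference, truth = small_genome
        table = density_by_class(truth.variants, reference.class_map)
        assert table["n_sites"].sum() == len(truth.variants)
        assert table["span_bp"].sum() == sum(len(a) for a in reference.class_map.arrays.values())

    def test_zero_coding_density_reports_infinite_fold(self):
        cmap = RegionClassMap({"c1": np.array([0] * 50 + [2] * 50, dtype=np.int8)})
        sites = [(("c1"), p) for p in range(60, 70)]
        import pandas as pd

        frame = pd.DataFrame(sites, columns=["chrom", "pos"])
        table = density_by_class(frame, cmap).set_index("region_class")
        assert math.isinf(table.loc["intergenic", "fold_vs_coding"])

    def test_single_site_assigned_to_start_position_class(self):
        import pandas as pd

        cmap = RegionClassMap({"c1": np.array([0] * 10 + [2] * 10, dtype=np.int8)})
        frame = pd.DataFrame({"chrom": ["c1"], "pos": [10]})  # last coding base
        table = density_by_class(frame, cmap).set_index("region_class")
        assert table.loc["coding", "n_sites"] == 1
        assert table.loc["intergenic", "n_sites"] == 0


class TestGeneStats:
    def test_headline_gene_density(self):
        genes = [GeneModel(f"g{i}", "c1", "+", 1, 10, exons=[(1, 10)]) for i in range(8639)]
        assert round(gene_stats(genes, 17_400_691).genes_per_kb, 2) == 0.50

    def test_intronless_set_reports_empty_mean_length(self):
        genes = [GeneModel("g1", "c1", "+", 1, 100, exons=[(1, 100)])]
        result = gene_stats(genes, 10_000)
        assert result.introns_per_gene == 0.0
        assert result.mean_intron_length is None

    def test_planted_intron_lengths_recovered(self, small_genome):
        spec, reference, _ = small_genome
        result = gene_stats(reference.genes, sum(spec.chromosome_lengths))
        intron_lengths = [e - s + 1 for g in reference.genes for s, e in g.introns]
        se = np.std(intron_lengths, ddof=1) / math.sqrt(len(intron_lengths))
        assert result.mean_intron_length == pytest.approx(spec.intron_length_mean, abs=3 * se + 1)
        assert result.genes_per_kb == pytest.approx(spec.gene_density, rel=0.05)


class TestExpressionFraction:
    def test_headline_expressed_fraction(self):
        # 7294 genes with depth 2, the rest at 0, single-exon
        genes = [GeneModel(f"g{i}", "c1", "+", 10 * i + 1, 10 * i + 5,
                           exons=[(10 * i + 1, 10 * i + 5)]) for i in range(8639)]
        depth = np.zeros(10 * 8639 + 10)
        for i in range(7294):
            depth[10 * i : 10 * i + 5] = 2.0
        result = expression_fraction({"c1": depth}, genes)
        assert result.n_expressed == 7294
        assert round(result.percent, 1) == 84.4

    def test_all_zero_depth_means_nothing_expressed(self):
        genes = [GeneModel("g1", "c1", "+", 1, 100, exons=[(1, 100)])]
        assert expression_fraction({"c1": np.zeros(100)}, genes).n_expressed == 0

    def test_threshold_boundary_two_exon_gene(self):
        gene = GeneModel("g1", "c1", "+", 1, 200, exons=[(1, 100), (101, 200)])
        depth = np.concatenate([np.zeros(100), np.full(100, 2.0)])
        result = expression_fraction({"c1": depth}, [gene], threshold=1.0)
        assert result.n_expressed == 1  # mean exactly 1.0 counts as expressed

    def test_zero_exon_length_raises(self):
        gene = GeneModel("g1", "c1", "+", 1, 100, exons=[])
        with pytest.raises(ParameterError, match="zero exon length"):
            expression_fraction({"c1": np.zeros(100)}, [gene])


class TestGcAnomalies:
    def test_all_gc_sequence_flags_every_window_high(self):
        track, intervals = gc_anomaly_windows("GC" * 1500)
        assert (track["flag"] == "high").all()
        assert intervals == [(0, 3000, "high")]

    def test_balanced_sequence_has_no_flags(self):
        track, intervals = gc_anomaly_windows("ACGT" * 1000)
        assert intervals == [] and (track["flag"] == "").all()

    def test_planted_low_gc_region_recovered_within_one_step(self, rng):
        bases = np.array(list("ACGT"))
        norm = rng.choice(bases, p=[0.2, 0.3, 0.3, 0.2], size=20_000)
        low = rng.choice(bases, p=[0.3, 0.2, 0.2, 0.3], size=4_000)  # 40% GC
        seq = "".join(np.concatenate([norm[:10_000], low, norm[10_000:]]))
        _, intervals = gc_anomaly_windows(seq)
        lows = [iv for iv in intervals if iv[2] == "low"]
        assert len(lows) == 1
        start, end, _ = lows[0]
        assert abs(start - 10_000) <= 500 and abs(end - 14_000) <= 500

    def test_case_insensitive_and_n_exclusion(self):
        upper, _ = gc_anomaly_windows("GCGT" * 500)
        lower, _ = gc_anomaly_windows("gcgt" * 500)
        assert np.allclose(upper["gc"], lower["gc"])
        with_n = "GC" + "N" * 998  # >50% N -> no-data
        track, intervals = gc_anomaly_windows(with_n)
        assert (track["flag"] == "no-data").all() and intervals == []


class TestTelomeres:
    def test_constructed_array_detected_with_copy_count(self, rng):
        unit = "CCTAAAAA"
        random_part = "".join(rng.choice(list("ACGT"), size=3000))
        seq = unit * 10 + random_part + revcomp(unit) * 7
        hits = detect_telomeres(seq)
        assert hits["five_prime"].present and hits["five_prime"].copies == 10
        assert hits["three_prime"].present and hits["three_prime"].copies == 7

    def test_random_sequence_has_no_telomeres(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        hits = detect_telomeres(seq)
        assert not hits["five_prime"].present and not hits["three_prime"].present

    def test_mismatched_units_need_the_tolerance_option(self, rng):
        # one mismatch in every unit copy: invisible at default, found at tolerance 1
        unit = "CCTAAAAA"
        corrupted = "".join("CCTAAATA" if i % 2 else "CCTATAAA" for i in range(6))
        seq = corrupted + "".join(rng.choice(list("ACGT"), size=2000))
        assert not detect_telomeres(seq)["five_prime"].present
        assert detect_telomeres(seq, max_mismatch=1)["five_prime"].present


class TestSharedProteins:
    def test_headline_shared_fraction(self):
        total = [f"p{i}" for i in range(8639)]
        shared = {"panel": total[: 8639 - 1909]}
        result = shared_protein_summary(total, shared)
        assert result.n_unique == 1909
        assert result.n_shared == 6730
        assert round(result.shared_percent) == 78

    def test_no_shared_sets_is_zero_percent(self):
        assert shared_protein_summary(["a", "b"], {}).shared_percent == 0.0

    def test_union_arithmetic_matches_brute_force(self, rng):
        total = [f"p{i}" for i in range(500)]
        sets = {
            f"s{j}": list(rng.choice(total, size=int(rng.integers(0, 300)), replace=False))
            for j in range(5)
        }
        result = shared_protein_summary(total, sets)
        union = set()
        for ids in sets.values():
            union = union | set(ids)
        assert result.n_shared == len(union)
        assert result.shared_percent == pytest.approx(100 * len(union) / 500)

    def test_ids_outside_total_rejected(self):
        with pytest.raises(ParameterError, match="outside"):
            shared_protein_summary(["a"], {"s": ["a", "zzz"]})


def test_gff3_round_trip(small_genome, tmp_path):
    _, reference, _ = small_genome
    path = tmp_path / "genes.gff3"
    write_gff3(reference.genes, path)
    back = read_gff3(path)
    assert [(g.gene_id, g.chrom, g.strand, g.start, g.end, g.exons) for g in back] == [
        (g.gene_id, g.chrom, g.strand, g.start, g.end, g.exons) for g in reference.genes
    ]
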