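"""The synthetic-data generator: determinism, placement invariants,
tag statistics and the planted DE table."""

import numpy as np
import pytest

from chipshift.integration import filter_de
from chipshift.synthetic import (
    ANTIBODIES,
    EmptyTagSetError,
    PlacementError,
    SyntheticGenomeSpec,
    plant_truth,
    read_tags_bed,
    simulate_chip_tags,
    simulate_de_table,
    simulate_genome,
    write_tags_bed,
)


def small_spec(**kw):
    defaults = dict(
        chrom_lengths={"chrA": 1_000_000},
        n_genes=50,
        gene_length_range=(1500, 3000),
        n_enhancers=8,
        seed=1,
    )
    defaults.update(kw)
    return SyntheticGenomeSpec(**defaults)


class TestGenome:
    def test_seeded_determinism(self):
        g1 = simulate_genome(small_spec())
        g2 = simulate_genome(small_spec())
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in g1.genes] == [
            (g.gene_id, g.chrom, g.start, g.end, g.strand) for g in g2.genes
        ]
        assert list(g1.enhancers) == list(g2.enhancers)
        assert g1.truth.enhancer_target == g2.truth.enhancer_target

    def test_gene_count_and_non_overlap(self):
        genome = simulate_genome(small_spec())
        genes = sorted(genome.genes, key=lambda g: (g.chrom, g.start))
        assert len(genes) == 50
        for a, b in zip(genes, genes[1:]):
            if a.chrom == b.chrom:
                assert b.start >= a.end
        for g in genes:
            assert 0 <= g.start < g.end <= 1_000_000
            assert 1500 <= g.end - g.start <= 3000

    def test_degenerate_length_range(self):
        genome = simulate_genome(small_spec(gene_length_range=(1000, 1000)))
        assert all(g.end - g.start == 1000 for g in genome.genes)

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            simulate_genome(small_spec(chrom_lengths={"chrA": 50_000}, n_genes=50))

    def test_enhancers_are_points_near_their_target(self):
        genome = simulate_genome(small_spec())
        genes = {g.gene_id: g for g in genome.genes}
        assert len(genome.enhancers) == 8
        for anchor in genome.enhancers:
            assert len(anchor) == 1
            target = genes[genome.truth.enhancer_target[anchor.name]]
            assert anchor.chrom == target.chrom
            # anchor sits upstream of the padded gene region, within
            # the nearest-gene linkage cap
            assert 0 < target.start - anchor.start <= 7_000

    def test_truth_skeleton_covers_everything_once(self):
        genome = simulate_genome(small_spec())
        t = genome.truth
        gene_ids = {g.gene_id for g in genome.genes}
        for ab in ANTIBODIES:
            assert set(t.occupancy[ab]) == gene_ids
            assert set(t.occupancy[ab].values()) <= {"none"}
        assert set(t.expression) == gene_ids
        assert set(t.enhancer_binding) == {iv.name for iv in genome.enhancers}


class TestPlantTruth:
    def test_deterministic_and_classes_valid(self):
        genome = simulate_genome(small_spec())
        t1 = plant_truth(genome, seed=7)
        t2 = plant_truth(simulate_genome(small_spec()), seed=7)
        assert t1.occupancy == t2.occupancy
        assert t1.expression == t2.expression
        assert t1.enhancer_binding == t2.enhancer_binding
        valid = {"none", "stable", "gained", "lost"}
        for per_gene in t1.occupancy.values():
            assert set(per_gene.values()) <= valid

    def test_smarca4_expression_coupling(self):
        truth = plant_truth(simulate_genome(small_spec()), seed=7)
        for g, cls in truth.occupancy["Smarca4"].items():
            if cls == "lost":
                assert truth.expression[g] == "down"
            if cls == "gained":
                assert truth.expression[g] in ("up", "down")


class TestTags:
    def test_determinism_and_bounds(self):
        genome = simulate_genome(small_spec())
        truth = plant_truth(genome, seed=3)
        a = simulate_chip_tags(genome, truth, "Smarca4", "control", seed=5)
        b = simulate_chip_tags(genome, truth, "Smarca4", "control", seed=5)
        assert all(np.array_equal(a.positions[c], b.positions[c]) for c in a.positions)
        for chrom, pos in a.positions.items():
            assert pos.min() >= 0
            assert pos.max() < genome.spec.chrom_lengths[chrom]
            assert np.all(np.diff(pos) >= 0)

    def test_input_has_no_planted_signal(self):
        genome = simulate_genome(small_spec())
        truth = plant_truth(genome, seed=3)
        inp = simulate_chip_tags(genome, truth, "input", "input", seed=5,
                                 background_rate=0.01)
        # expected ~10000 background tags; nothing extra
        assert abs(inp.total - 10_000) < 5 * np.sqrt(10_000)

    def test_fold_one_means_uniform_density(self):
        genome = simulate_genome(small_spec())
        truth = plant_truth(genome, seed=3)
        ts = simulate_chip_tags(
            genome, truth, "Smarca4", "control", seed=5,
            background_rate=0.01, enrichment_fold=1.0,
        )
        # planted windows collectively hold no excess: ~occupied genes
        # x 1000 bp at 0.01/bp
        occupied = [
            g for g in genome.genes
            if truth.occupancy["Smarca4"][g.gene_id] in ("stable", "lost")
        ]
        pos = ts.positions["chrA"]
        n_in = sum(
            int(np.searchsorted(pos, g.tss + 500) - np.searchsorted(pos, g.tss - 500))
            for g in occupied
        )
        lam = 0.01 * 1000 * len(occupied)
        assert abs(n_in - lam) < 5 * np.sqrt(lam)

    def test_strong_fold_concentrates_tags(self):
        """One stable gene at fold 50 on a toy chromosome barely larger
        than its peak window: the two-component mixture puts mass
        fold*w / (fold*w + (L - w)) ~ 0.97 inside the window, so >= 95%
        of tags land there in both conditions (binomial bound)."""
        spec = SyntheticGenomeSpec(
            chrom_lengths={"chrA": 2600},
            n_genes=1,
            gene_length_range=(1000, 1000),
            n_enhancers=0,
            seed=1,
            min_gene_spacing=0,
            end_margin=800,
        )
        genome = simulate_genome(spec)
        truth = genome.truth
        gid = genome.genes[0].gene_id
        truth.occupancy["Smarca4"][gid] = "stable"
        for cond in ("control", "kd"):
            ts = simulate_chip_tags(
                genome, truth, "Smarca4", cond, seed=9,
                background_rate=0.5, enrichment_fold=50.0,
            )
            g = genome.genes[0]
            pos = ts.positions["chrA"]
            inside = np.count_nonzero((pos >= g.tss - 500) & (pos < g.tss + 500))
            assert inside / ts.total >= 0.95

    def test_empty_draw_raises(self):
        genome = simulate_genome(small_spec())
        with pytest.raises((EmptyTagSetError, ValueError)):
            simulate_chip_tags(
                genome, genome.truth, "Smarca4", "control", seed=1,
                background_rate=1e-9,
            )

    def test_bed_round_trip(self, tmp_path):
        genome = simulate_genome(small_spec())
        truth = plant_truth(genome, seed=3)
        ts = simulate_chip_tags(genome, truth, "Ezh2", "kd", seed=4)
        path = tmp_path / "tags.bed"
        write_tags_bed(ts, path)
        back = read_tags_bed(path, "Ezh2", "kd")
        assert all(
            np.array_equal(ts.positions[c], back.positions[c]) for c in ts.positions
        )


class TestDETable:
    def test_planted_genes_pass_filter_and_nulls_fail(self):
        genome = simulate_genome(small_spec())
        truth = plant_truth(genome, seed=3)
        table = simulate_de_table(truth, seed=5, effect_size_log2=2.0, null_sd=0.1)
        res = filter_de(table)
        up = {g for g, d in truth.expression.items() if d == "up"}
        down = {g for g, d in truth.expression.items() if d == "down"}
        assert set(res.up["gene_id"]) == up
        assert set(res.down["gene_id"]) == down

    def test_no_planted_genes_gives_empty_filter(self):
        genome = simulate_genome(small_spec())
        table = simulate_de_table(genome.truth, seed=5)  # all null
        res = filter_de(table)
        assert len(res.up) == 0 and len(res.down) == 0

    def test_deterministic(self):
        genome = simulate_genome(small_spec())
        truth = plant_truth(genome, seed=3)
        t1 = simulate_de_table(truth, seed=5)
        t2 = simulate_de_table(truth, seed=5)
        assert t1.equals(t2)

    def test_padj_assigned_by_class(self):
        genome = simulate_genome(small_spec())
        truth = plant_truth(genome, seed=3)
        table = simulate_de_table(truth, seed=5).set_index("gene_id")
        for g, d in truth.expression.items():
            if d == "null":
                assert table.at[g, "padj"] >= 0.05
            else:
                assert table.at[g, "padj"] < 0.05
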