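"""Determinism and self-consistency of the synthetic-input generators."""

from __future__ import annotations

import dataclasses

import pytest

from cladescape import (
    abundance_scores,
    gc_percent,
    isolation_fraction,
    read_scaffolds,
    read_te_annotations,
)
from cladescape import synthetic as sy
from conftest import allpairs_isolation, bitmap_covered_bp

GENOME_CONFIG = sy.TEGenomeConfig(
    scaffold_lengths=(400_000, 250_000),
    clades=(
        sy.CladePlan("sire", 60, 1_000, 250, family="Ty1/Copia", gc_shift=0.15),
        sy.CladePlan(
            "oryco", 12, 400, 0, family="Ty1/Copia",
            placement="clustered", n_clusters=2, cluster_spread=4_000,
        ),
    ),
)


class TestTEGenome:
    def test_identical_config_and_seed_give_identical_outputs(self):
        a = sy.simulate_te_genome(GENOME_CONFIG, 42)
        b = sy.simulate_te_genome(GENOME_CONFIG, 42)
        assert a[1] == b[1]
        assert all(a[0].sequence(s) == b[0].sequence(s) for s in a[0])

    def test_different_seeds_differ(self):
        a = sy.simulate_te_genome(GENOME_CONFIG, 1)
        b = sy.simulate_te_genome(GENOME_CONFIG, 2)
        assert a[1] != b[1]

    def test_zero_te_request(self):
        config = sy.TEGenomeConfig(
            scaffold_lengths=(100_000,), clades=(sy.CladePlan("sire", 0),)
        )
        _, records, truth = sy.simulate_te_genome(config, 0)
        assert records == [] and truth.occupied_bp == {"sire": 0}

    def test_fixed_length_uniform_placement_truth(self):
        config = sy.TEGenomeConfig(
            scaffold_lengths=(10_000_000,),
            clades=(sy.CladePlan("sire", 10, 1_000, 0),),
        )
        _, records, truth = sy.simulate_te_genome(config, 0)
        assert truth.occupied_bp["sire"] == 10_000
        assert len(records) == 10

    def test_within_clade_intervals_never_overlap(self):
        _, records, truth = sy.simulate_te_genome(GENOME_CONFIG, 9)
        for clade in ("sire", "oryco"):
            recs = [r for r in records if r.clade == clade]
            assert bitmap_covered_bp(recs) == truth.occupied_bp[clade]

    def test_pipeline_reproduces_truth_from_emitted_files(self, tmp_path):
        scaffolds, records, truth = sy.simulate_te_genome(GENOME_CONFIG, 7)
        paths = sy.write_te_genome(scaffolds, records, truth, tmp_path)
        reread = read_te_annotations(paths["gff3"], format="gff3")
        table = abundance_scores(reread, read_scaffolds(paths["fasta"], mode="fasta"))
        assert table.occupied_bp == truth.occupied_bp
        for clade in truth.occupied_bp:
            stats = isolation_fraction(reread, clade, truth.isolation_radius)
            assert stats.fraction_isolated == pytest.approx(
                truth.isolation_fraction[clade]
            )

    def test_truth_isolation_agrees_with_allpairs_on_records(self):
        _, records, truth = sy.simulate_te_genome(GENOME_CONFIG, 13)
        for clade in ("sire", "oryco"):
            assert truth.isolation_fraction[clade] == pytest.approx(
                allpairs_isolation(records, clade, truth.isolation_radius)
            )

    def test_gc_shift_raises_te_span_composition(self):
        scaffolds, records, _ = sy.simulate_te_genome(GENOME_CONFIG, 21)
        sire = [r for r in records if r.clade == "sire"]
        te_gc = [
            gc_percent(scaffolds.sequence(r.scaffold_id)[r.start : r.end])
            for r in sire
        ]
        mean_te_gc = sum(te_gc) / len(te_gc)
        assert mean_te_gc > 100 * GENOME_CONFIG.gc + 5  # shifted by +0.15

    def test_infeasible_density_raises_naming_scaffold(self):
        config = sy.TEGenomeConfig(
            scaffold_lengths=(10_000,),
            clades=(sy.CladePlan("sire", 50, 1_000, 0),),
            max_attempts=20,
        )
        with pytest.raises(RuntimeError, match="sc00000"):
            sy.simulate_te_genome(config, 0)


class TestGenusTree:
    def test_no_events_means_no_multiplication(self):
        config = sy.TreeSimConfig(genera=("Tc", "Cs"), n_ortholog_groups=5)
        _, truth = sy.simulate_genus_tree(config, 0)
        assert truth.fraction_multiplied == {"Tc": 0.0, "Cs": 0.0}

    def test_single_genus_single_group_event(self):
        config = sy.TreeSimConfig(
            genera=("Tc",),
            n_ortholog_groups=1,
            events=(sy.DuplicationEvent("Tc", 8),),
        )
        tree, truth = sy.simulate_genus_tree(config, 0)
        assert tree.n_tips == 8
        assert truth.fraction_multiplied["Tc"] == 1.0
        assert truth.fraction_ge8["Tc"] == 1.0

    def test_bookkeeping_for_two_events(self):
        # 10 groups, events of sizes 3 and 9: 20 genus-A tips,
        # 12 multiplied, 9 in a cluster >= 8
        config = sy.TreeSimConfig(
            genera=("A", "B", "C"),
            n_ortholog_groups=10,
            events=(sy.DuplicationEvent("A", 3), sy.DuplicationEvent("A", 9)),
        )
        _, truth = sy.simulate_genus_tree(config, 0)
        assert truth.n_tips["A"] == 20
        assert truth.fraction_multiplied["A"] == pytest.approx(0.6)
        assert truth.fraction_ge8["A"] == pytest.approx(0.45)

    def test_determinism(self):
        config = sy.TreeSimConfig(
            genera=("Tc", "Cs", "Aa"),
            n_ortholog_groups=8,
            events=(sy.DuplicationEvent("Tc", 4),),
            jitter_fraction=1.0,
        )
        a, _ = sy.simulate_genus_tree(config, 3)
        b, _ = sy.simulate_genus_tree(config, 3)
        assert a.as_newick() == b.as_newick()

    def test_more_events_than_groups_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            sy.TreeSimConfig(
                genera=("Tc", "Cs"),
                n_ortholog_groups=1,
                events=(
                    sy.DuplicationEvent("Tc", 2),
                    sy.DuplicationEvent("Tc", 2),
                ),
            )


class TestCountMatrix:
    def test_fold_one_everywhere_is_unenriched(self):
        config = sy.CountsSimConfig(
            genera=("Tc", "Cs"), n_superfamilies=5,
            enrichments=(sy.Enrichment(0, "Tc", 1.0),),
        )
        _, truth = sy.simulate_count_matrix(config, 0)
        assert truth.enriched == set()

    def test_seeded_runs_are_identical(self):
        config = sy.CountsSimConfig(
            genera=("Tc", "Cs", "Aa"), n_superfamilies=20,
            enrichments=(sy.Enrichment(4, "Tc", 8.0),),
        )
        a, _ = sy.simulate_count_matrix(config, 17)
        b, _ = sy.simulate_count_matrix(config, 17)
        assert a.counts.equals(b.counts)

    def test_enriched_cell_mean_tracks_fold(self):
        config = sy.CountsSimConfig(
            genera=("Tc", "Cs"), n_superfamilies=200, baseline_rate=20.0,
            enrichments=tuple(
                sy.Enrichment(i, "Tc", 8.0) for i in range(200)
            ),
        )
        matrix, _ = sy.simulate_count_matrix(config, 23)
        # law of large numbers: Tc column mean near 160, Cs near 20
        assert matrix.counts["Tc"].mean() == pytest.approx(160.0, rel=0.1)
        assert matrix.counts["Cs"].mean() == pytest.approx(20.0, rel=0.1)
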