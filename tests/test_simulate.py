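import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from platymeth import (
    ConfigError,
    ExpressionEffect,
    FamilyEffect,
    PlacementError,
    SimulationConfig,
    enumerate_cytosines,
    generate_gene_models,
    generate_genome,
    simulate_expression,
    simulate_methylome,
)


def _config(**kw):
    defaults = dict(seed=1, chrom_length_bp=120_000, n_genes=0, family_spec={})
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_gc_zero_forces_at_only(self):
        genome = generate_genome(_config(gc_fraction=0.0, chrom_length_bp=60_000))
        assert set(genome["chr1"]) <= {"A", "T"}

    def test_gc_content_tracks_target(self):
        genome = generate_genome(_config(seed=7, gc_fraction=0.5, chrom_length_bp=100_000))
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02

    def test_deterministic_under_fixed_seed(self):
        cfg = _config(seed=7, chrom_length_bp=100_000)
        assert generate_genome(cfg) == generate_genome(cfg)

    def test_chromosome_count_and_length(self):
        genome = generate_genome(_config(n_chromosomes=2, chrom_length_bp=60_000))
        assert sorted(genome) == ["chr1", "chr2"]
        assert all(len(s) == 60_000 for s in genome.values())

    def test_nonpositive_length_is_rejected(self):
        with pytest.raises(ConfigError):
            _config(chrom_length_bp=0)


class TestGeneModels:
    def test_family_spec_counts_are_exact(self, small_study):
        _, genes, _, _ = small_study
        families = pd.Series([g.family for g in genes]).value_counts()
        assert families["CYP716"] == 8
        assert families["bAS"] == 6
        assert families["other"] == 30 - 8 - 6

    def test_single_gene_has_a_strand(self):
        cfg = _config(n_genes=1)
        genome = generate_genome(cfg)
        (gene,) = generate_gene_models(genome, cfg)
        assert gene.strand in ("+", "-")

    def test_bodies_do_not_overlap_and_clear_chromosome_ends(self, small_study, small_config):
        genome, genes, _, _ = small_study
        assert min(g.start for g in genes) >= 2000
        assert max(g.end for g in genes) <= small_config.chrom_length_bp - 2000
        by_chrom = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            prev = by_chrom.get(g.chrom)
            if prev is not None:
                assert g.start >= prev.end
            by_chrom[g.chrom] = g

    def test_minimum_intergenic_gap_is_honoured(self):
        cfg = _config(n_genes=10, chrom_length_bp=200_000, min_intergenic_gap_bp=4000)
        genome = generate_genome(cfg)
        genes = sorted(generate_gene_models(genome, cfg), key=lambda g: g.start)
        gaps = [b.start - a.end for a, b in zip(genes, genes[1:])]
        assert min(gaps) >= 4000

    def test_too_small_genome_raises_placement_error(self):
        cfg = _config(n_genes=30, chrom_length_bp=100_000, gene_length_range=(3300, 3300))
        genome = generate_genome(cfg)
        with pytest.raises(PlacementError):
            generate_gene_models(genome, cfg)


class TestCytosineEnumeration:
    def test_contexts_match_a_hand_built_sequence(self):
        #        0123456789
        # fwd:   ACGTCCGTCA  -> C at 1 (CG), C at 4 (CHG: C,C,G), C at 5 (CG), C at 8 (CHH? C,A -> needs 2)
        sites = enumerate_cytosines({"chr1": "ACGTCCGTCA"})
        plus = sites[sites["strand"] == "+"]
        assert dict(zip(plus["pos0"], plus["context"])) == {1: "CG", 4: "CHG", 5: "CG"}
        minus = sites[sites["strand"] == "-"]
        # G at 2 pairs the CG at 1; G at 6 pairs the CG at 5
        assert dict(zip(minus["pos0"], minus["context"])) == {2: "CG", 6: "CG"}

    def test_every_internal_c_and_g_is_enumerated_once(self):
        genome = generate_genome(_config(chrom_length_bp=50_000))
        sites = enumerate_cytosines(genome)
        seq = genome["chr1"]
        n_c = seq.count("C", 0, len(seq) - 2)
        n_g = seq.count("G", 2)
        assert len(sites) == n_c + n_g
        assert not sites.duplicated(subset=["chrom", "pos0", "strand"]).any()


class TestMethylome:
    def test_all_zero_means_give_zero_methylated_counts(self):
        cfg = _config(
            context_means={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            non_conversion_rate=0.0,
            chrom_length_bp=120_000,
        )
        genome = generate_genome(cfg)
        cx, _ = simulate_methylome(genome, [], cfg)
        assert all((df["count_m"] == 0).all() for df in cx.values())

    def test_all_one_means_give_level_one_wherever_covered(self):
        cfg = _config(context_means={"CG": 1.0, "CHG": 1.0, "CHH": 1.0}, chrom_length_bp=120_000)
        genome = generate_genome(cfg)
        cx, _ = simulate_methylome(genome, [], cfg)
        for df in cx.values():
            covered = df[df["count_m"] + df["count_u"] > 0]
            assert (covered["count_u"] == 0).all()

    def test_counts_conserve_drawn_coverage_and_reproduce_under_seed(self, small_config, small_study):
        genome, genes, cx, _ = small_study
        for df in cx.values():
            assert ((df["count_m"] >= 0) & (df["count_u"] >= 0)).all()
        # full regeneration from config: byte-identical outputs
        genome2 = generate_genome(small_config)
        genes2 = generate_gene_models(genome2, small_config)
        cx2, _ = simulate_methylome(genome2, genes2, small_config)
        for sample in cx:
            pd.testing.assert_frame_equal(cx[sample], cx2[sample])

    def test_cg_mean_calibration_within_monte_carlo_error(self):
        # coverage-weighted CG mean ~ configured mean + non-conversion bias,
        # within 3 ratio-estimator standard errors on >= 1e5 CG sites
        cfg = _config(seed=5, chrom_length_bp=2_000_000, context_means={"CG": 0.9, "CHG": 0.7, "CHH": 0.2})
        genome = generate_genome(cfg)
        cx, _ = simulate_methylome(genome, [], cfg)
        df = cx["CT_12h"]
        cg = df[df["context"] == "CG"]
        assert len(cg) >= 1e5
        cov = (cg["count_m"] + cg["count_u"]).to_numpy(dtype=float)
        m = cg["count_m"].to_numpy(dtype=float)
        estimate = m.sum() / cov.sum()
        expected = 0.9 + (1 - 0.9) * cfg.non_conversion_rate
        se = math.sqrt(((m - estimate * cov) ** 2).sum()) / cov.sum()
        assert abs(estimate - expected) < 3 * se

    def test_injected_negative_body_effect_lowers_affected_genes(self):
        cfg = SimulationConfig(
            seed=21,
            chrom_length_bp=600_000,
            n_genes=60,
            family_spec={"CYP716": 25},
            family_effects=[FamilyEffect("CYP716", "MJ_12h", -20.0, "body")],
        )
        genome = generate_genome(cfg)
        genes = generate_gene_models(genome, cfg)
        cx, truth = simulate_methylome(genome, genes, cfg)
        assert set(truth.effect_genes["gene_id"]) == {g.gene_id for g in genes if g.family == "CYP716"}
        df = cx["MJ_12h"]
        pos0 = df["pos"].to_numpy() - 1
        levels = []
        for group in ("CYP716", "other"):
            means = []
            for g in genes:
                if g.family != group:
                    continue
                sel = (pos0 >= g.start) & (pos0 < g.end) & (df["context"] == "CG")
                sub = df[sel]
                cov = sub["count_m"] + sub["count_u"]
                means.append(sub["count_m"].sum() / cov.sum())
            levels.append(means)
        assert len(levels[0]) >= 20
        stat = stats.mannwhitneyu(levels[0], levels[1], alternative="less")
        assert stat.pvalue < 0.01

    def test_unknown_family_in_effects_is_a_config_error(self):
        cfg = SimulationConfig(
            seed=1,
            chrom_length_bp=120_000,
            n_genes=2,
            family_spec={"CYP716": 1},
            family_effects=[FamilyEffect("CYP716", "MJ_12h", -10.0)],
        )
        genome = generate_genome(cfg)
        with pytest.raises(ConfigError, match="family"):
            simulate_methylome(genome, [], cfg)  # gene list lacks the family


class TestExpression:
    def test_zero_baseline_means_all_zero_counts(self, small_study):
        _, genes, _, _ = small_study
        cfg = _config(n_genes=0, expression_baseline_median=0.0)
        counts, fpkm, _ = simulate_expression(genes, cfg)
        assert (counts.to_numpy() == 0).all()
        assert (fpkm.to_numpy() == 0).all()

    def test_injected_tissue_effect_scales_group_means(self, small_study):
        _, genes, _, _ = small_study
        cfg = SimulationConfig(
            seed=2,
            chrom_length_bp=400_000,
            n_genes=30,
            family_spec={"CYP716": 8, "bAS": 6},
            expression_effects=[ExpressionEffect("CYP716", "root", 3.0)],
        )
        counts, _, true_means = simulate_expression(genes, cfg)
        fam = [g.gene_id for g in genes if g.family == "CYP716"]
        other_tissues = [t for t in cfg.tissues if t != "root"]
        ratio = counts.loc[fam, "root"].mean() / counts.loc[fam, other_tissues].mean(axis=None)
        assert 6.0 < ratio < 10.0  # injected 8x within sampling error
        assert np.allclose(true_means.loc[fam, "root"], 8.0 * true_means.loc[fam, "leaf"])

    def test_same_seed_reproduces_matrices(self, small_study, small_config):
        _, genes, _, _ = small_study
        a, fa, _ = simulate_expression(genes, small_config)
        b, fb, _ = simulate_expression(genes, small_config)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(fa, fb)

    def test_effect_on_unknown_sample_is_rejected(self):
        with pytest.raises(ConfigError, match="unknown sample"):
            SimulationConfig(
                seed=1,
                chrom_length_bp=120_000,
                n_genes=2,
                family_spec={"CYP716": 1},
                expression_effects=[ExpressionEffect("CYP716", "nonexistent", 1.0)],
            )
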