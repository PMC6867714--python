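"""Synthetic-data generator: planted structure, determinism, null configs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hypernuc.footprints import histone_specific_peaks, ladder_peaks, oligomer_length
from hypernuc.genome_io import coverage, gc_content
from hypernuc.occupancy import windowed
from hypernuc.simulate import (
    SimConfig,
    simulate_digest,
    simulate_ev,
    simulate_expression,
    simulate_genome,
    simulate_library,
    simulate_placements,
    stage_seed,
    tss_true_occupancy,
)

SMALL = dict(length=50_000, n_genes=25, gene_length=800)


def _gc_track(genome, contig="chr"):
    a = np.frombuffer(genome.contigs[contig].encode(), dtype=np.uint8)
    return ((a == ord("G")) | (a == ord("C"))).astype(float)


class TestGenome:
    def test_same_seed_reproduces_sequence_and_annotation(self):
        cfg = SimConfig(seed=5, **SMALL)
        g1, genes1, _, tss1 = simulate_genome(cfg)
        g2, genes2, _, tss2 = simulate_genome(cfg)
        assert g1.contigs == g2.contigs
        assert genes1.df.equals(genes2.df)
        assert tss1.equals(tss2)

    def test_promoters_are_at_richer_than_gene_bodies(self):
        cfg = SimConfig(seed=2)
        g, genes, promoters, _ = simulate_genome(cfg)
        gc_p = [gc_content(g.fetch("chr", r.start, r.end))
                for r in promoters.df.itertuples()]
        gc_g = [gc_content(g.fetch("chr", r.start, r.end))
                for r in genes.df.itertuples()]
        stat, p = stats.ranksums(gc_p, gc_g)
        assert np.mean(gc_p) < np.mean(gc_g)
        assert p < 0.01

    def test_degenerate_promoter_gc_matches_background(self):
        cfg = SimConfig(seed=3, gc_promoter=0.4999, **SMALL)
        g, genes, promoters, _ = simulate_genome(cfg)
        gc_p = np.mean([gc_content(g.fetch("chr", r.start, r.end))
                        for r in promoters.df.itertuples()])
        # binomial error over 25 promoters x 100 bp
        assert abs(gc_p - 0.5) < 3 * np.sqrt(0.25 / 2500)

    def test_genes_do_not_overlap_and_tss_offsets_start_codon(self):
        cfg = SimConfig(seed=4, **SMALL)
        g, genes, promoters, tss = simulate_genome(cfg)
        df = genes.df
        assert (df["start"].to_numpy()[1:] >= df["end"].to_numpy()[:-1]).all()
        joined = tss.set_index("gene").join(df.set_index("name"), lsuffix="_t")
        plus = joined[joined["strand"] == "+"]
        assert (plus["start"] - plus["position"] == cfg.utr_length).all()

    def test_overfull_genome_rejected(self):
        with pytest.raises(ValueError, match="exceeds genome length"):
            SimConfig(length=10_000, n_genes=20).validate()


class TestPlacements:
    def test_placements_never_overlap_and_lengths_follow_rank(self, default_sim):
        pl = default_sim["placements"]
        assert (pl["start"].to_numpy()[1:] >= pl["end"].to_numpy()[:-1]).all()
        lengths = (pl["end"] - pl["start"]).to_numpy()
        expect = np.array([oligomer_length(r) for r in pl["rank"]])
        assert np.array_equal(lengths, expect)

    def test_gc_preference_plants_positive_window_correlation(self, default_sim):
        occ = default_sim["true_occ"]
        w_occ = windowed(occ, 60, 30, circular=True)["mean"]
        w_gc = windowed(_gc_track(default_sim["genome"]), 60, 30, circular=True)["mean"]
        rho, _ = stats.spearmanr(w_occ, w_gc)
        assert rho > 0.3

    def test_zero_gc_weight_gives_null_correlation(self):
        cfg = SimConfig(seed=6, beta_gc=0.0, **SMALL)
        g, *_ = simulate_genome(cfg)
        _, occ = simulate_placements(g, cfg)
        w_occ = windowed(occ, 60, 30, circular=True)["mean"]
        w_gc = windowed(_gc_track(g), 60, 30, circular=True)["mean"]
        rho, _ = stats.spearmanr(w_occ, w_gc)
        assert abs(rho) < 0.1

    def test_full_at_penalty_on_at_genome_blocks_extension(self):
        cfg = SimConfig(seed=7, alpha_at=1.0, beta_gc=0.0, **SMALL)
        g, *_ = simulate_genome(cfg)
        g.contigs["chr"] = "AT" * (cfg.length // 2)  # AT_flank = 1 everywhere
        pl, _ = simulate_placements(g, cfg)
        assert (pl["rank"] == 1).all()


class TestDigest:
    def test_noise_free_digest_has_exact_ladder_lengths(self, default_sim):
        cfg = SimConfig(seed=8, sigma_end=0.0, w_at=0.0)
        frags = simulate_digest(default_sim["placements"], default_sim["genome"], cfg)
        assert set(np.unique(frags.lengths)) <= {60, 90, 120, 150}

    def test_default_digest_length_peaks_near_ladder_rungs(self, clonal_digest):
        peaks = ladder_peaks(clonal_digest["fragments"].lengths)
        for rung in (60, 90, 120, 150):
            assert np.min(np.abs(peaks - rung)) <= 3

    def test_doubling_mu_doubles_fragment_count(self, default_sim):
        cfg1 = SimConfig(seed=9, mu_frags=10.0)
        cfg2 = SimConfig(seed=9, mu_frags=20.0)
        n1 = len(simulate_digest(default_sim["placements"], default_sim["genome"], cfg1))
        n2 = len(simulate_digest(default_sim["placements"], default_sim["genome"], cfg2))
        expected = 2 * n1
        assert abs(n2 - expected) < 3 * np.sqrt(expected)

    def test_fragment_count_override_hits_target(self, default_sim):
        frags = simulate_digest(
            default_sim["placements"], default_sim["genome"],
            default_sim["config"], n_fragments=50_000,
        )
        assert abs(len(frags) - 50_000) < 3 * np.sqrt(50_000)

    def test_changing_digest_seed_leaves_genome_stage_untouched(self):
        cfg = SimConfig(seed=10, **SMALL)
        g1, *_ = simulate_genome(cfg)
        pl, _ = simulate_placements(g1, cfg)
        f1 = simulate_digest(pl, g1, cfg, seed=1)
        f2 = simulate_digest(pl, g1, cfg, seed=2)
        g2, *_ = simulate_genome(cfg)
        assert g1.contigs == g2.contigs
        assert not f1.df.equals(f2.df)

    def test_library_is_deterministic_given_seed(self):
        cfg = SimConfig(seed=11, n_cells=5, library_fragments=2_000, **SMALL)
        g, *_ = simulate_genome(cfg)
        lib1 = simulate_library(g, cfg)
        lib2 = simulate_library(g, cfg)
        assert lib1.df.equals(lib2.df)
        assert abs(len(lib1) - 2_000) < 3 * np.sqrt(2_000)


class TestEmptyVector:
    def test_ev_lengths_show_no_ladder(self, clonal_digest):
        res = histone_specific_peaks(
            clonal_digest["fragments"].lengths, clonal_digest["ev"].lengths
        )
        ladder_like = [p for p in res["ev_peaks"]
                       if min(abs(p - c) for c in (60, 90, 120, 150)) <= 3]
        assert len(ladder_like) < 2

    def test_unbiased_ev_coverage_is_uniform_within_poisson_error(self):
        cfg = SimConfig(seed=12, w_at=0.0, **SMALL)
        g, *_ = simulate_genome(cfg)
        ev = simulate_ev(g, cfg, n_fragments=50_000)
        w = windowed(coverage(ev, g).values["chr"], 1000, 1000)["mean"]
        # window means are averages of ~80x coverage; CV should be tiny
        assert w.std() / w.mean() < 0.1

    def test_at_cut_bias_couples_ev_coverage_to_at_content(self, default_sim):
        cfg = default_sim["config"]
        ev = simulate_ev(default_sim["genome"], cfg, n_fragments=100_000)
        cov = coverage(ev, default_sim["genome"]).values["chr"]
        at = 1.0 - _gc_track(default_sim["genome"])
        w_cov = windowed(cov, 60, 30, circular=True)["mean"]
        w_at = windowed(at, 60, 30, circular=True)["mean"]
        rho, _ = stats.spearmanr(w_cov, w_at)
        assert rho > 0


class TestExpression:
    def test_zero_coupling_gives_null_occupancy_association(self, default_sim):
        cfg = SimConfig(seed=13, gamma=0.0)
        o = tss_true_occupancy(default_sim["true_occ"], default_sim["tss"])
        res = simulate_expression(o, cfg)
        rho, _ = stats.spearmanr(o, res["de_binding"]["log2fc"])
        assert abs(rho) < 0.2

    def test_repression_plants_higher_occupancy_in_down_genes(self, default_sim,
                                                              default_expression):
        o = tss_true_occupancy(default_sim["true_occ"], default_sim["tss"])
        de = default_expression["de_binding"].set_index("gene")
        down = o[(de["padj"] < 0.05) & (de["log2fc"] < 0)]
        up = o[(de["padj"] < 0.05) & (de["log2fc"] > 0)]
        stat, p = stats.ranksums(down, up)
        assert down.mean() > up.mean()
        assert p < 0.01

    def test_planted_compendium_column_has_top_dot_product(self, default_expression):
        d = default_expression["de_binding"].set_index("gene")["log2fc"]
        comp = default_expression["compendium"]
        sims = comp.mul(d, axis=0).sum()
        assert sims.idxmax() == default_expression["planted_column"]

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            SimConfig(gamma=-1.0).validate()

    def test_systemic_shift_is_shared_between_strains(self, default_expression):
        genes = default_expression["systemic_genes"]
        b = default_expression["de_binding"].set_index("gene").loc[genes, "log2fc"]
        nb = default_expression["de_nonbinding"].set_index("gene").loc[genes, "log2fc"]
        rho, _ = stats.spearmanr(b, nb)
        assert rho > 0.5


def test_stage_seed_is_stable_and_stage_specific():
    assert stage_seed(1, "genome") == stage_seed(1, "genome")
    assert stage_seed(1, "genome") != stage_seed(1, "digest")
    assert 0 <= stage_seed(12345, "ev") < 2**31
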