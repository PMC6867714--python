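"""Occupancy tracks: size classes, normalization, windows, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hypernuc.genome_io import CoverageTrack, FragmentSet, GenomeSeq, IntervalSet, coverage
from hypernuc.occupancy import (
    SIZE_CLASSES,
    SizeClass,
    assign_size_class,
    gene_gc_occupancy,
    moving_gc_occupancy,
    nap_delta,
    normalize,
    regional_modulation,
    replicate_correlation,
    tss_profile,
    windowed,
)


class TestSizeClass:
    @pytest.mark.parametrize(
        "length,center",
        [(63, 60), (66, None), (145, 150), (55, 60), (54, None),
         (85, 90), (125, 120), (150, 150), (156, None)],
    )
    def test_boundary_assignment(self, length, center):
        sc = assign_size_class(length)
        assert (sc.center if sc else None) == center

    @given(st.integers(min_value=1, max_value=200))
    @settings(deadline=None, max_examples=200)
    def test_classes_are_disjoint_and_consistent(self, length):
        hits = [sc for sc in SIZE_CLASSES if sc.admits(length)]
        assert len(hits) <= 1
        got = assign_size_class(length)
        assert (got in hits) if hits else (got is None)

    def test_each_class_admits_eleven_lengths(self):
        for sc in SIZE_CLASSES:
            assert sum(sc.admits(x) for x in range(1, 200)) == 11


def _track(values, n=0, label=""):
    return CoverageTrack({"c": np.asarray(values, dtype=float)},
                         total_fragments=n, label=label)


class TestNormalize:
    def test_zero_ev_divides_by_pseudocount_only(self):
        out = normalize(_track([4, 2, 0]), _track([0, 0, 0]))
        assert out.values["c"].tolist() == [4, 2, 0]

    def test_pseudocount_arithmetic(self):
        out = normalize(_track([4, 2]), _track([1, 0]))
        assert out.values["c"].tolist() == [2, 2]

    def test_uniform_ev_preserves_rank_order(self, rng):
        cs = rng.random(100)
        out = normalize(_track(cs), _track(np.full(100, 7.0)))
        assert np.array_equal(np.argsort(out.values["c"]), np.argsort(cs))

    def test_contig_mismatch_rejected(self):
        a = CoverageTrack({"c1": np.zeros(5)})
        b = CoverageTrack({"c2": np.zeros(5)})
        with pytest.raises(ValueError, match="different contigs"):
            normalize(a, b)

    def test_library_scaling_equalizes_depth(self):
        s = _track([10.0, 20.0], n=10)
        e = _track([10.0, 20.0], n=100)
        out = normalize(s, e, scale_libraries=True)
        expect = (np.array([10, 20.0]) * 1e5) / (np.array([10, 20.0]) * 1e4 + 1)
        assert np.allclose(out.values["c"], expect)


class TestWindowed:
    def test_constant_track_gives_constant_windows(self):
        w = windowed(np.full(300, 2.5), 60, 30)
        assert np.allclose(w["mean"], 2.5)

    def test_linear_track_of_120_gives_three_windows(self):
        w = windowed(np.zeros(120), 60, 30)
        assert len(w) == 3
        assert w["start"].tolist() == [0, 30, 60]

    def test_circular_windows_wrap_and_cover_every_step(self):
        v = np.arange(120.0)
        w = windowed(v, 60, 30, circular=True)
        assert len(w) == 4
        wrap = w.iloc[3]
        assert wrap["mean"] == np.mean(np.r_[v[90:], v[:30]])

    def test_matches_bruteforce_slice_means(self, rng):
        v = rng.random(1013)
        w = windowed(v, 60, 30)
        for _, row in w.iterrows():
            assert np.isclose(row["mean"], v[int(row.start) : int(row.end)].mean())

    def test_width_exceeding_track_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            windowed(np.zeros(50), 60, 30)


class TestReplicateCorrelation:
    def test_identical_replicates_correlate_perfectly(self, toy_genome):
        fr = FragmentSet(pd.DataFrame(
            {"contig": "circ", "start": [0, 500, 900], "end": [60, 590, 1020]}
        ))
        out = replicate_correlation(fr, fr, toy_genome)
        assert out["rho"] == pytest.approx(1.0)

    def test_zero_variance_coverage_is_flagged(self):
        g = GenomeSeq({"c": "ACGT" * 250}, {"c": True})
        fr = FragmentSet(pd.DataFrame(
            {"contig": ["c"], "start": [0], "end": [1000]}
        ))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = replicate_correlation(fr, fr, g)
        assert np.isnan(out["rho"])

    def test_split_halves_of_one_digest_agree(self, default_sim, clonal_digest):
        df = clonal_digest["fragments"].df
        a = FragmentSet(df.iloc[::2].reset_index(drop=True))
        b = FragmentSet(df.iloc[1::2].reset_index(drop=True))
        out = replicate_correlation(a, b, default_sim["genome"])
        assert out["rho"] > 0.9


class TestTssProfile:
    def test_uniform_coverage_gives_flat_rows(self):
        g = GenomeSeq({"c": "ACGT" * 500}, {"c": True})
        fr = FragmentSet(pd.DataFrame(
            {"contig": "c", "start": np.arange(0, 2000, 10) % 1940,
             "end": np.arange(0, 2000, 10) % 1940 + 60}
        ))
        tss = pd.DataFrame({"contig": ["c"], "position": [1000], "strand": ["+"],
                            "gene": ["g"]})
        prof = tss_profile(fr, tss, g, D=100)
        col = prof[60].to_numpy()
        assert col.std() / col.mean() < 0.5

    def test_single_fragment_maps_to_its_signed_distances(self):
        g = GenomeSeq({"c": "A" * 3000}, {"c": True})
        fr = FragmentSet(pd.DataFrame(
            {"contig": ["c"], "start": [1010], "end": [1070]}
        ))
        tss = pd.DataFrame({"contig": ["c"], "position": [1000], "strand": ["+"],
                            "gene": ["g"]})
        prof = tss_profile(fr, tss, g, D=100)
        nz = prof[60].to_numpy().nonzero()[0] - 100
        assert nz.min() == 10 and nz.max() == 69 and len(nz) == 60

    def test_minus_strand_profiles_are_mirrored(self):
        g = GenomeSeq({"c": "A" * 3000}, {"c": True})
        fr = FragmentSet(pd.DataFrame(
            {"contig": ["c"], "start": [1010], "end": [1070]}
        ))
        tss_minus = pd.DataFrame({"contig": ["c"], "position": [1000],
                                  "strand": ["-"], "gene": ["g"]})
        prof = tss_profile(fr, tss_minus, g, D=100)
        nz = prof[60].to_numpy().nonzero()[0] - 100
        assert nz.min() == -69 and nz.max() == -10

    def test_simulated_promoters_are_histone_depleted(self, default_sim,
                                                      population_library):
        from hypernuc.occupancy import normalize as norm
        g = default_sim["genome"]
        track = norm(coverage(population_library["library"], g),
                     population_library["ev_cov"])
        v = track.values["chr"]
        tss_pos = default_sim["tss"]["position"].to_numpy()
        idx = (tss_pos[:, None] + np.arange(-50, 51)[None, :]) % len(v)
        assert v[idx].mean() < v.mean()


class TestGeneGcOccupancy:
    def test_one_row_per_gene_with_rho(self, default_sim, population_library):
        from hypernuc.occupancy import normalize as norm
        g = default_sim["genome"]
        track = norm(coverage(population_library["library"], g),
                     population_library["ev_cov"])
        out = gene_gc_occupancy(g, default_sim["genes"], track)
        assert len(out["table"]) == len(default_sim["genes"])
        assert out["rho"] > 0  # GC-preferring particles

    def test_constant_track_flagged(self, toy_genome):
        genes = IntervalSet(pd.DataFrame(
            {"contig": "circ", "start": [0, 100], "end": [90, 220],
             "name": ["a", "b"]}
        ))
        track = CoverageTrack({"circ": np.ones(3000), "lin": np.ones(2000)})
        with pytest.warns(UserWarning, match="degenerate"):
            out = gene_gc_occupancy(toy_genome, genes, track)
        assert np.isnan(out["rho"])


def _synthetic_gene_table(rng, n=800, L=1_000_000, coupling=0.0, noise=1.0):
    """Gene table with tunable GC-occupancy coupling varying along the genome."""
    starts = np.sort(rng.integers(0, L - 1000, size=n))
    gc = rng.uniform(0.3, 0.7, n)
    # coupling strength declines with expression when `coupling` < 0
    expr = rng.uniform(0, 10, n)
    occ = coupling * expr * (gc - 0.5) + (gc - 0.5) + noise * rng.normal(0, 0.1, n)
    return pd.DataFrame({
        "gene": [f"g{i}" for i in range(n)], "contig": "chr",
        "start": starts, "end": starts + 900,
        "strand": rng.choice(["+", "-"], n), "gc": gc, "occupancy": occ,
    }), pd.Series(expr, index=[f"g{i}" for i in range(n)])


class TestRegionalModulation:
    def test_shuffled_expression_gives_null_across_window_rho(self, rng):
        tab, expr = _synthetic_gene_table(rng, n=4000)
        rhos = []
        for _ in range(5):
            shuffled = pd.Series(rng.permutation(expr.to_numpy()),
                                 index=expr.index)
            out = regional_modulation(tab, shuffled, origin=0, terminus=500_000,
                                      genome_length=1_000_000)
            assert len(out["windows"]) >= 2
            rhos.append(out["rho"])
        # any single shuffle fluctuates at ~1/sqrt(windows); the mean does not
        assert abs(np.mean(rhos)) < 0.25

    def test_transcription_dependent_coupling_yields_negative_rho(self, rng):
        tab, expr = _synthetic_gene_table(rng, n=4000, coupling=-0.1, noise=0.3)
        out = regional_modulation(tab, expr, origin=0, terminus=500_000,
                                  genome_length=1_000_000)
        assert out["rho"] < 0

    def test_codirectionality_strata_partition_all_genes(self, rng):
        tab, expr = _synthetic_gene_table(rng, n=1000)
        out = regional_modulation(tab, expr, origin=100_000, terminus=700_000,
                                  genome_length=1_000_000)
        assert out["gene_table"]["codirectional"].isin([True, False]).all()
        assert len(out["gene_table"]) == 1000


class TestMovingGcOccupancy:
    def test_window_count_follows_index_arithmetic(self, rng):
        tab, _ = _synthetic_gene_table(rng, n=760)
        prof = moving_gc_occupancy(tab, span=500, step=20)
        assert len(prof) == (760 - 500) // 20 + 1

    def test_each_window_rho_matches_direct_recomputation(self, rng):
        tab, _ = _synthetic_gene_table(rng, n=600)
        prof = moving_gc_occupancy(tab, span=500, step=20)
        tab_sorted = tab.sort_values("start").reset_index(drop=True)
        for _, row in prof.iterrows():
            blk = tab_sorted.iloc[int(row.window_index) * 20 :][:500]
            rho, _ = stats.spearmanr(blk["gc"], blk["occupancy"])
            assert np.isclose(row["rho"], rho)

    def test_short_gene_list_shrinks_span_with_warning(self, rng):
        tab, _ = _synthetic_gene_table(rng, n=100)
        with pytest.warns(UserWarning, match="shrinking span"):
            prof = moving_gc_occupancy(tab, span=500, step=20)
        assert len(prof) == 1


class TestNapDelta:
    def test_delta_arithmetic(self):
        v = np.concatenate([np.full(100, 2.0), np.full(100, 1.5)])
        track = CoverageTrack({"c": v})
        bound = IntervalSet(pd.DataFrame(
            {"contig": ["c"], "start": [0], "end": [100], "name": ["nap"]}
        ))
        out = nap_delta(track, bound)
        assert out["table"]["delta"].tolist() == [0.5]

    def test_uniform_track_gives_zero_deltas_and_trivial_test(self):
        track = CoverageTrack({"c": np.ones(1000)})
        bound = IntervalSet(pd.DataFrame(
            {"contig": "c", "start": [0, 300, 600], "end": [100, 400, 700]}
        ))
        with pytest.warns(UserWarning, match="all occupancy deltas are zero"):
            out = nap_delta(track, bound)
        assert (out["table"]["delta"] == 0).all()
        assert out["p_value"] == 1.0

    def test_matches_bruteforce_interval_means(self, rng):
        L = 10_000
        v = rng.random(L)
        track = CoverageTrack({"c": v})
        starts = np.sort(rng.choice(np.arange(0, L - 400, 400), 12, replace=False))
        bound = IntervalSet(pd.DataFrame(
            {"contig": "c", "start": starts, "end": starts + 200}
        ))
        out = nap_delta(track, bound)
        for i, s in enumerate(starts):
            gap_end = starts[i + 1] if i + 1 < len(starts) else L
            want = v[s : s + 200].mean() - v[s + 200 : gap_end].mean()
            assert np.isclose(out["table"]["delta"].iloc[i], want)
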