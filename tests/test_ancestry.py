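"""Emission model, Viterbi decoding, window scan and haplotype PCA."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import small_config
from introscan import ancestry, fst_aims, simdata
from introscan.ancestry import (
    AncestryTrack,
    call_outlier_windows,
    emission_logprob,
    global_proportion,
    haplotype_pca,
    outlier_threshold,
    path_logscore,
    viterbi_ancestry,
    window_scan,
)
from introscan.variant_io import MISSING


class TestEmission:
    def test_double_donor_homozygote(self):
        assert emission_logprob(2, 2, 0.5, 0.9) == pytest.approx(math.log(0.81))

    def test_single_donor_heterozygote_enumerates_assignments(self):
        # one allele Bernoulli(p_a = 0.2), one Bernoulli(p_b = 0.9):
        # P(g=1) = 0.2*0.1 + 0.8*0.9 = 0.74
        assert emission_logprob(1, 1, 0.2, 0.9) == pytest.approx(math.log(0.74))

    def test_missing_genotype_contributes_log_one(self):
        assert emission_logprob(MISSING, 1, 0.2, 0.9) == 0.0
        assert emission_logprob(None, 2, 0.2, 0.9) == 0.0

    @given(
        st.floats(0.02, 0.98), st.floats(0.02, 0.98), st.integers(0, 2)
    )
    def test_probabilities_normalise_over_genotypes(self, p_a, p_b, k):
        total = sum(math.exp(emission_logprob(g, k, p_a, p_b)) for g in (0, 1, 2))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_boundary_frequencies_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            v = emission_logprob(2, 2, 0.5, 1.0)
        assert v == pytest.approx(math.log(0.99**2))


def brute_force_best_score(genotypes, p_a, p_b, s):
    best = -np.inf
    for path in itertools.product((0, 1, 2), repeat=len(genotypes)):
        score = path_logscore(genotypes, np.array(path), p_a, p_b, s)
        best = max(best, score)
    return best


class TestViterbi:
    def test_matches_exhaustive_enumeration_on_toys(self, rng):
        for _ in range(25):
            m = rng.integers(2, 5)
            g = rng.integers(-1, 3, size=m)
            p_a = rng.uniform(0.05, 0.95, size=m)
            p_b = rng.uniform(0.05, 0.95, size=m)
            s = float(rng.choice([0.5, 2.0, 10.0]))
            path, score = viterbi_ancestry(g, p_a, p_b, s)
            assert score == pytest.approx(
                brute_force_best_score(g, p_a, p_b, s), abs=1e-9
            )
            assert score == pytest.approx(
                path_logscore(g, path, p_a, p_b, s), abs=1e-9
            )

    def test_donor_matching_sample_decodes_all_two(self):
        m = 30
        p_a = np.full(m, 0.02)
        p_b = np.full(m, 0.98)
        g = np.full(m, 2)  # homozygous donor allele everywhere
        path, _ = viterbi_ancestry(g, p_a, p_b, 10.0)
        assert (path == 2).all()

    def test_huge_penalty_forces_constant_path(self, rng):
        m = 40
        g = rng.integers(0, 3, size=m)
        p_a = rng.uniform(0.05, 0.95, size=m)
        p_b = rng.uniform(0.05, 0.95, size=m)
        path, score = viterbi_ancestry(g, p_a, p_b, 1e6)
        assert len(np.unique(path)) == 1
        # the constant state chosen is the best single global state
        best_k = max(
            range(3),
            key=lambda k: path_logscore(g, np.full(m, k), p_a, p_b, 0.0),
        )
        assert path[0] == best_k

    def test_ties_break_toward_less_donor_ancestry(self):
        # p_a == p_b makes every state equally likely site-wise; the all-zero
        # path is chosen deterministically
        m = 12
        g = np.ones(m, dtype=int)
        p = np.full(m, 0.5)
        path, _ = viterbi_ancestry(g, p, p, 10.0)
        assert (path == 0).all()

    def test_decoded_score_dominates_truth_path(self, default_sim):
        """Viterbi optimality: the decoded path's objective is never below
        the truth path's objective on synthetic instances."""
        sim = default_sim
        aims = fst_aims.classify_aims(fst_aims.fst_profile(sim.genotypes))
        track = ancestry.decode_admixed(sim.genotypes, aims)
        rows = sim.genotypes.group_index("admixed")
        G = sim.genotypes.dosage[np.ix_(rows, aims.indices)]
        truth = sim.truth.dosage[:, aims.indices]
        p1 = np.clip(aims.p1, 0.01, 0.99)
        p2 = np.clip(aims.p2, 0.01, 0.99)
        for i in range(G.shape[0]):
            truth_score = path_logscore(G[i], truth[i], p1, p2, 10.0)
            assert track.log_score[i] >= truth_score - 1e-9


def make_track(dosage, positions=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    return AncestryTrack(
        samples=[f"x{i}" for i in range(n)],
        site_indices=np.arange(m),
        positions=np.asarray(positions),
        chrom="chr1",
        dosage=dosage,
        log_score=np.zeros(n),
    )


class TestGlobalProportion:
    def test_bounds(self):
        assert (global_proportion(make_track(np.zeros((3, 10)))) == 0).all()
        assert (global_proportion(make_track(np.full((3, 10), 2))) == 1).all()

    def test_decoded_proportion_tracks_truth(self):
        """Cohort-mean decoded donor proportion stays within 0.01 of the
        truth-track proportion when background segments are long enough to
        clear the switch-penalty detection threshold (~25 informative AIMs)."""
        for seed in (0, 1, 2):
            cfg = simdata.SimConfig(seed=seed, background_segment_bp=2_000_000)
            sim = simdata.simulate(cfg)
            aims = fst_aims.classify_aims(fst_aims.fst_profile(sim.genotypes))
            track = ancestry.decode_admixed(sim.genotypes, aims)
            decoded = global_proportion(track).mean()
            truth = sim.truth.dosage[:, aims.indices].mean() / 2.0
            assert decoded == pytest.approx(truth, abs=0.01)


class TestWindowScan:
    def test_window_starts_follow_step_arithmetic(self):
        track = make_track(np.ones((2, 250)))
        ws = window_scan(track, window_size=100, step=50)
        assert list(ws.windows["start_idx"]) == [0, 50, 100, 150]
        assert list(ws.windows["end_idx"]) == [100, 150, 200, 250]
        assert not ws.windows["truncated"].any()

    def test_constant_heterozygous_dosage_gives_half(self):
        ws = window_scan(make_track(np.ones((4, 250))))
        assert (ws.windows["mean_prop"] == 0.5).all()
        assert ws.sd == 0.0

    def test_fewer_aims_than_window_yields_single_truncated_window(self):
        with pytest.warns(UserWarning, match="truncated"):
            ws = window_scan(make_track(np.ones((2, 60))))
        assert len(ws.windows) == 1
        assert bool(ws.windows["truncated"].iloc[0])

    def test_tract_window_attains_maximum(self, rng):
        dosage = np.zeros((10, 400), dtype=np.int8)
        block = rng.random((10, 61)) < 0.8
        dosage[:, 120:181] = block.astype(np.int8) + (
            rng.random((10, 61)) < 0.8
        )  # mean ~1.6 over AIMs 120-180
        ws = window_scan(make_track(dosage))
        best = ws.windows.loc[ws.windows["mean_prop"].idxmax()]
        assert best["start_idx"] <= 180 and best["end_idx"] >= 120

    def test_window_means_match_brute_force(self, rng):
        dosage = rng.integers(0, 3, size=(7, 330)).astype(np.int8)
        ws = window_scan(make_track(dosage), window_size=100, step=50)
        for _, w in ws.windows.iterrows():
            s, e = int(w["start_idx"]), int(w["end_idx"])
            assert w["mean_prop"] == pytest.approx(dosage[:, s:e].mean() / 2)


class TestOutlierWindows:
    def test_reported_chromosomal_statistics_give_threshold(self):
        # window mean 0.032 with SD 0.09 -> 2-SD exceedance threshold 0.212
        assert outlier_threshold(0.032, 0.09) == pytest.approx(0.212)

    def test_equal_windows_produce_no_outliers(self):
        ws = window_scan(make_track(np.ones((3, 250))))
        regions, thr = call_outlier_windows(ws)
        assert regions == []
        assert thr == pytest.approx(0.5)

    def test_elevated_block_yields_one_merged_region(self):
        # block spans AIMs 150-299: windows [150,250) and [200,300) are both
        # saturated, exceed the 2-SD threshold, share AIMs and merge
        dosage = np.zeros((6, 800), dtype=np.int8)
        dosage[:, 150:300] = 2
        ws = window_scan(make_track(dosage))
        regions, thr = call_outlier_windows(ws)
        assert len(regions) == 1
        chrom, start, end = regions[0]
        assert (start, end) == (151_000, 300_000)


class TestHaplotypePca:
    def test_two_clusters_separate_on_pc1(self):
        X = np.vstack([np.tile([1, 1, 0, 0, 1, 0], (5, 1)),
                       np.tile([0, 0, 1, 1, 0, 1], (5, 1))])
        res = haplotype_pca(X)
        pc1 = res.loadings[:, 0]
        assert np.ptp(np.sign(pc1[:5])) == 0 and np.ptp(np.sign(pc1[5:])) == 0
        assert np.sign(pc1[0]) != np.sign(pc1[-1])
        assert np.allclose(pc1[:5], pc1[0]) and np.allclose(pc1[5:], pc1[-1])

    def test_row_permutation_permutes_loadings(self, rng):
        X = rng.integers(0, 2, size=(12, 30))
        perm = rng.permutation(12)
        a = haplotype_pca(X).loadings
        b = haplotype_pca(X[perm]).loadings
        for c in range(2):
            assert np.allclose(a[perm, c], b[:, c], atol=1e-8) or np.allclose(
                a[perm, c], -b[:, c], atol=1e-8
            )

    def test_variance_explained_matches_dense_eigensolver(self, rng):
        X = rng.integers(0, 2, size=(6, 10)).astype(float)
        while np.all(X.std(axis=0) == 0):
            X = rng.integers(0, 2, size=(6, 10)).astype(float)
        res = haplotype_pca(X)
        Z = X - X.mean(axis=0)
        sd = Z.std(axis=0)
        Z = np.where(sd > 0, Z / np.where(sd > 0, sd, 1), 0.0)
        evals = np.linalg.eigvalsh(Z @ Z.T / Z.shape[0])[::-1]
        assert res.explained_variance[0] == pytest.approx(evals[0], abs=1e-9)
        assert res.explained_variance[1] == pytest.approx(evals[1], abs=1e-9)

    def test_zero_variance_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            haplotype_pca(np.ones((4, 5)))
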