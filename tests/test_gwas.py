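"""SNP back-solving, weight updates, window variances and the full iteration."""

import numpy as np
import pandas as pd
import pytest

from wssgblup import (SNPWeightState, WssConfig, backsolve_snp_effects,
                      build_G, center_and_lambda, normalize_weights,
                      run_wssgblup, top_windows, update_weights,
                      window_variances)


def full_rank_toy(n=5, m=3, seed=0):
    """Genotypes whose raw G is full rank.

    Centering on the data's own frequencies always leaves Z with zero
    column sums (G singular), so these toys center on external base
    frequencies instead.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, size=m)
    for _ in range(1000):
        M = rng.binomial(2, p, size=(n, m)).astype(float)
        cg = center_and_lambda(M, allele_freqs=p)
        G = build_G(cg)
        if np.linalg.matrix_rank(G, tol=1e-8) == n:
            return cg, G
    raise AssertionError("could not build a full-rank toy")


class TestBacksolve:
    def test_zero_breeding_values_give_zero_effects(self):
        cg, G = full_rank_toy(n=5, m=8)
        u = backsolve_snp_effects(cg, SNPWeightState.identity(cg.m), G,
                                  np.zeros(cg.n))
        assert np.allclose(u, 0.0)

    def test_identity_Z_u_recovers_a_g(self):
        """Z u = Z lam D Z' G^{-1} a = G G^{-1} a = a on full-rank G."""
        cg, G = full_rank_toy(n=5, m=8, seed=1)
        rng = np.random.default_rng(2)
        a_g = rng.standard_normal(cg.n)
        u = backsolve_snp_effects(cg, SNPWeightState.identity(cg.m), G, a_g)
        assert np.max(np.abs(cg.Z @ u - a_g)) < 1e-10

    def test_two_by_two_hand_oracle(self):
        # 2 animals, 2 SNPs, worked by explicit dense arithmetic
        M = np.array([[0.0, 2.0], [2.0, 1.0]])
        cg = center_and_lambda(M)
        # p = (0.5, 0.75); Z = M - 2p; lam = 1/(2*.25 + 2*.1875)
        Z_expected = np.array([[-1.0, 0.5], [1.0, -0.5]])
        assert np.allclose(cg.Z, Z_expected)
        lam = 1.0 / (2 * 0.5 * 0.5 + 2 * 0.75 * 0.25)
        assert cg.lam == pytest.approx(lam)
        d = np.array([1.5, 0.5])
        G = build_G(cg, SNPWeightState(d))
        a_g = np.array([0.3, -0.7])
        # oracle: straightforward dense formula
        u_oracle = lam * np.diag(d) @ cg.Z.T @ np.linalg.pinv(G) @ a_g
        u = backsolve_snp_effects(cg, SNPWeightState(d), G,
                                  a_g, G_inv=np.linalg.pinv(G))
        assert np.allclose(u, u_oracle, atol=1e-12)


class TestWeights:
    @pytest.mark.parametrize("u,p,expected", [
        (0.0, 0.3, 0.0),
        (1.0, 0.5, 0.5),
        (2.0, 0.1, 0.72),
    ])
    def test_update_values(self, u, p, expected):
        got = update_weights(np.array([u]), np.array([p]))
        assert got[0] == pytest.approx(expected)

    def test_normalize_uniform_maps_to_ones(self):
        w = normalize_weights(np.full(7, 3.2))
        assert np.allclose(w.d, 1.0)

    def test_normalize_example(self):
        w = normalize_weights(np.array([3.0, 1.0]))
        assert np.allclose(w.d, [1.5, 0.5])

    def test_trace_preserved_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            raw = rng.random(rng.integers(2, 50)) + 1e-6
            w = normalize_weights(raw)
            assert w.d.sum() == pytest.approx(len(raw), abs=1e-10)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_weights(np.zeros(4))


def toy_map(m, chrom_size=None):
    chrom_size = chrom_size or m
    chroms = np.repeat(np.arange(1, m // chrom_size + 1), chrom_size)
    return pd.DataFrame({
        "chrom": chroms,
        "snp_id": [f"s{j}" for j in range(m)],
        "cm": np.arange(m, dtype=float),
        "bp": np.tile((np.arange(chrom_size) + 1) * 1000, m // chrom_size),
    })


class TestWindows:
    def test_zero_effects_zero_percent(self):
        cg, _ = full_rank_toy(n=6, m=10, seed=3)
        rep = window_variances(np.zeros(10), cg, toy_map(10), window_size=4)
        assert (rep["percent_variance"] == 0).all()
        assert rep["n_snps"].tolist() == [4, 4, 2]
        assert rep["short_window"].tolist() == [False, False, True]

    def test_single_nonzero_effect_localizes(self):
        cg, _ = full_rank_toy(n=8, m=10, seed=4)
        u = np.zeros(10)
        u[6] = 1.3
        s2a = 0.5
        rep = window_variances(u, cg, toy_map(10), window_size=5,
                               sigma2_a=s2a)
        # only the window holding SNP 6 is nonzero, and equals the direct
        # variance of its genomic score
        direct = np.var(cg.Z[:, 6] * 1.3, ddof=1)
        assert rep["percent_variance"][0] == 0.0
        assert rep["percent_variance"][1] == pytest.approx(100 * direct / s2a)

    def test_windows_respect_chromosomes(self):
        cg, _ = full_rank_toy(n=8, m=12, seed=5)
        rep = window_variances(np.ones(12), cg, toy_map(12, chrom_size=6),
                               window_size=4)
        assert rep.groupby("chrom")["n_snps"].sum().tolist() == [6, 6]
        assert rep["n_snps"].tolist() == [4, 2, 4, 2]
        # bp span is the positions of the first and last member SNPs
        assert rep.loc[0, "start_bp"] == 1000 and rep.loc[0, "end_bp"] == 4000

    def test_unsorted_map_rejected(self):
        rng = np.random.default_rng(6)
        cg = center_and_lambda(rng.binomial(2, 0.5, size=(6, 4)).astype(float),
                               allele_freqs=np.full(4, 0.5))
        bad = toy_map(4)
        bad.loc[2, "bp"] = 1  # breaks monotonicity
        with pytest.raises(ValueError, match="sorted"):
            window_variances(np.ones(4), cg, bad, window_size=2)

    def test_percent_sums_match_per_window_recomputation(self):
        rng = np.random.default_rng(7)
        cg, _ = full_rank_toy(n=10, m=12, seed=7)
        u = rng.standard_normal(12)
        s2a = 0.7
        rep = window_variances(u, cg, toy_map(12), window_size=4,
                               sigma2_a=s2a)
        for _, row in rep.iterrows():
            ix = np.arange(row["start_snp"], row["end_snp"] + 1)
            direct = np.var(cg.Z[:, ix] @ u[ix], ddof=1)
            assert row["percent_variance"] == pytest.approx(100 * direct / s2a)


class TestTopWindows:
    def make_report(self, percents):
        return pd.DataFrame({
            "chrom": np.arange(len(percents)) // 3 + 1,
            "window_index": np.arange(len(percents)),
            "start_bp": (np.arange(len(percents)) % 3) * 100 + 1,
            "percent_variance": percents,
        })

    def test_unique_maximum(self):
        top, total = top_windows(self.make_report([1.0, 5.0, 2.0]), k=1)
        assert top.iloc[0]["window_index"] == 1
        assert total == 5.0

    def test_ties_break_by_position(self):
        top, _ = top_windows(self.make_report([2.0] * 6), k=3)
        assert top["window_index"].tolist() == [0, 1, 2]

    def test_sum_equals_k_largest(self):
        rng = np.random.default_rng(8)
        percents = rng.random(20).tolist()
        _, total = top_windows(self.make_report(percents), k=10)
        assert total == pytest.approx(sum(sorted(percents)[-10:]))

    def test_k_larger_than_report_warns(self):
        with pytest.warns(UserWarning):
            top, _ = top_windows(self.make_report([1.0, 2.0]), k=5)
        assert len(top) == 2


class TestRunWssgblup:
    @pytest.fixture(scope="class")
    def result(self, small_dataset):
        from wssgblup.pheno import prepare_phenotypes

        cfg, ped, geno, qtl, pheno, truth = small_dataset
        kept, _ = prepare_phenotypes(pheno, "continuous")
        res = run_wssgblup(kept, ped, geno, trait_type="continuous",
                           h2=cfg.h2, config=WssConfig(window_size=30))
        return res

    def test_three_iterations_with_unit_start(self, result):
        assert len(result.iterations) == 3
        assert np.allclose(result.iteration(1).d, 1.0)

    def test_trace_conserved_every_iteration(self, result):
        m = len(result.iteration(1).d)
        for it in result.iterations:
            assert it.d.sum() == pytest.approx(m, abs=1e-8)

    def test_iteration1_effects_equal_unweighted_backsolve(self, result,
                                                           small_dataset):
        from wssgblup.kinship import (SNPWeightState, blend_G, build_G,
                                      center_and_lambda, extract_A22,
                                      invert_spd)
        from wssgblup.pedigree import build_A

        cfg, ped, geno, qtl, pheno, truth = small_dataset
        cgm = center_and_lambda(geno.dosages)
        A22 = extract_A22(build_A(ped), result.genotyped_index)
        G = blend_G(build_G(cgm), A22, 0.05)
        u1 = backsolve_snp_effects(cgm, SNPWeightState.identity(cgm.m), G,
                                   result.solution.a_hat_genotyped,
                                   G_inv=invert_spd(G))
        assert np.allclose(result.iteration(1).u_hat, u1)

    def test_weights_track_squared_effects(self, result, small_dataset):
        _, _, geno, _, _, _ = small_dataset
        it1, it2 = result.iteration(1), result.iteration(2)
        p = geno.dosages.mean(axis=0) / 2.0
        raw = update_weights(it1.u_hat, p)
        expected = normalize_weights(raw).d
        assert np.allclose(it2.d, expected, atol=1e-10)

    def test_report_iteration_entry_consistent(self, result):
        rep = result.iteration(2).window_report
        assert (rep["iteration"] == 2).all()
        top, total = top_windows(rep, k=10)
        assert len(top) == 10
        assert total == pytest.approx(
            rep["percent_variance"].nlargest(10).sum())
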