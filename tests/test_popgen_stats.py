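import numpy as np
import pytest
from scipy import stats as sps

from invabc.genotype_io import LocusDef
from invabc.popgen_stats import (
    MantelResult,
    diversity_summary,
    mantel_test,
    pairwise_fst,
    pairwise_jostD_gst,
    pairwise_phipt,
    permutation_test,
)
from conftest import build_matrix


# -- independent oracles (straightforward textbook implementations) -----------


def wc_theta_oracle(callsA, callsB):
    """Weir-Cockerham theta for one locus from genotype tuples, per-allele sums."""
    r = 2
    nA, nB = len(callsA), len(callsB)
    ns = np.array([nA, nB], float)
    nbar = ns.mean()
    nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
    alleles = sorted({a for c in callsA + callsB for a in c})
    aS = bS = cS = 0.0
    for al in alleles:
        p = np.array(
            [sum(c.count(al) for c in callsA) / (2 * nA),
             sum(c.count(al) for c in callsB) / (2 * nB)]
        )
        h = np.array(
            [sum(1 for c in callsA if (c[0] == al) != (c[1] == al)) / nA,
             sum(1 for c in callsB if (c[0] == al) != (c[1] == al)) / nB]
        )
        pbar = (ns * p).sum() / ns.sum()
        s2 = (ns * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h).sum() / ns.sum()
        aS += (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        bS += (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) * hbar / (4 * nbar)
        )
        cS += hbar / 2
    return aS / (aS + bS + cS)


def jost_gst_oracle(callsA, callsB):
    nA, nB = len(callsA), len(callsB)
    alleles = sorted({a for c in callsA + callsB for a in c})
    pa = np.array([sum(c.count(al) for c in callsA) / (2 * nA) for al in alleles])
    pb = np.array([sum(c.count(al) for c in callsB) / (2 * nB) for al in alleles])
    hs_obs = 1 - ((pa**2).sum() + (pb**2).sum()) / 2
    pm = (pa + pb) / 2
    ht_obs = 1 - (pm**2).sum()
    nh = 2 / (1 / nA + 1 / nB)
    hs = (2 * nh / (2 * nh - 1)) * hs_obs
    ht = ht_obs + hs / (2 * nh * 2)
    d = 2 * (ht - hs) / (1 - hs)
    gpp = 2 * (ht - hs) / ((2 * ht - hs) * (1 - hs))
    return d, gpp


def phipt_oracle(groups_calls):
    """AMOVA Phi_PT by direct variance components over one-locus genotypes."""
    def d2(g1, g2):
        alleles = sorted(set(g1) | set(g2))
        c1 = np.array([g1.count(al) for al in alleles], float)
        c2 = np.array([g2.count(al) for al in alleles], float)
        return 0.5 * ((c1 - c2) ** 2).sum()

    allg = [g for grp in groups_calls for g in grp]
    N, K = len(allg), len(groups_calls)
    ss_total = sum(d2(allg[i], allg[j]) for i in range(N) for j in range(i + 1, N)) / N
    ss_within = 0.0
    for grp in groups_calls:
        n = len(grp)
        ss_within += sum(d2(grp[i], grp[j]) for i in range(n) for j in range(i + 1, n)) / n
    ss_among = ss_total - ss_within
    ms_among = ss_among / (K - 1)
    ms_within = ss_within / (N - K)
    n0 = (N - sum(len(g) ** 2 for g in groups_calls) / N) / (K - 1)
    va = (ms_among - ms_within) / n0
    return va / (va + ms_within)


# -- diversity ----------------------------------------------------------------


class TestDiversity:
    def test_monomorphic_population(self):
        g = build_matrix({"P": [[(100, 100)]] * 5}, loci=[LocusDef("L1", 2, "FAM")])
        row = diversity_summary(g).iloc[0]
        assert row["Ho"] == 0 and row["He"] == 0
        assert row["Na"] == 1 and row["Ne_eff"] == 1
        assert np.isnan(row["F"])

    def test_unbiased_he_at_half_frequency(self):
        # p = 0.5 with n = 10 diploids: uHe = (20/19) * 0.5
        g = build_matrix(
            {"P": [[(100, 100)]] * 5 + [[(102, 102)]] * 5},
            loci=[LocusDef("L1", 2, "FAM")],
        )
        row = diversity_summary(g).iloc[0]
        assert row["He"] == pytest.approx(0.5)
        assert row["uHe"] == pytest.approx(20 / 19 * 0.5, rel=1e-12)

    def test_all_heterozygotes_give_negative_f(self):
        g = build_matrix({"P": [[(100, 102)]] * 4}, loci=[LocusDef("L1", 2, "FAM")])
        row = diversity_summary(g).iloc[0]
        assert row["Ho"] == 1 and row["He"] == pytest.approx(0.5)
        assert row["F"] == pytest.approx(-1.0)


# -- differentiation ----------------------------------------------------------


class TestPairwise:
    def test_fixed_differences_give_one(self):
        g = build_matrix({"A": [[(100, 100), (150, 150)]] * 4,
                          "B": [[(108, 108), (162, 162)]] * 4})
        assert pairwise_fst(g, "A", "B") == pytest.approx(1.0)
        d, gpp = pairwise_jostD_gst(g, "A", "B")
        assert d == pytest.approx(1.0) and gpp == pytest.approx(1.0)
        assert pairwise_phipt(g, "A", "B") == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        pool = [(100 + 2 * rng.integers(0, 4), 100 + 2 * rng.integers(0, 4)) for _ in range(400)]
        half = len(pool) // 2
        g = build_matrix(
            {"A": [[p] for p in pool[:half]], "B": [[p] for p in pool[half:]]},
            loci=[LocusDef("L1", 2, "FAM")],
        )
        assert abs(pairwise_fst(g, "A", "B")) < 0.02

    def test_theta_matches_textbook_oracle(self, two_pop_toy):
        A = [(100, 100)] * 8 + [(100, 102)] * 2
        B = [(100, 100)] * 2 + [(100, 102)] * 2 + [(102, 102)] * 6
        got = pairwise_fst(two_pop_toy, "A", "B")
        assert got == pytest.approx(wc_theta_oracle(A, B), rel=1e-10)

    def test_jost_and_gst_match_direct_formula(self, two_pop_toy):
        A = [(100, 100)] * 8 + [(100, 102)] * 2
        B = [(100, 100)] * 2 + [(100, 102)] * 2 + [(102, 102)] * 6
        d, gpp = pairwise_jostD_gst(two_pop_toy, "A", "B")
        d0, g0 = jost_gst_oracle(A, B)
        assert d == pytest.approx(d0, rel=1e-10)
        assert gpp == pytest.approx(g0, rel=1e-10)

    def test_phipt_matches_variance_component_oracle(self):
        A = [(100, 102), (100, 100), (102, 104)]
        B = [(104, 104), (102, 104), (104, 106)]
        g = build_matrix(
            {"A": [[c] for c in A], "B": [[c] for c in B]}, loci=[LocusDef("L1", 2, "FAM")]
        )
        got = pairwise_phipt(g, "A", "B")
        assert got == pytest.approx(phipt_oracle([A, B]), rel=1e-10)

    def test_panmictic_split_phipt_near_zero(self):
        rng = np.random.default_rng(1)
        pool = [(100 + 2 * rng.integers(0, 6), 100 + 2 * rng.integers(0, 6)) for _ in range(200)]
        g = build_matrix(
            {"A": [[p] for p in pool[:100]], "B": [[p] for p in pool[100:]]},
            loci=[LocusDef("L1", 2, "FAM")],
        )
        assert abs(pairwise_phipt(g, "A", "B")) < 0.02

    def test_invariant_to_label_order_and_allele_relabeling(self, two_pop_toy):
        ab = pairwise_fst(two_pop_toy, "A", "B")
        ba = pairwise_fst(two_pop_toy, "B", "A")
        assert ab == pytest.approx(ba, rel=1e-12)
        relabeled = build_matrix(
            {"A": [[(200, 200)]] * 8 + [[(200, 240)]] * 2,
             "B": [[(200, 200)]] * 2 + [[(200, 240)]] * 2 + [[(240, 240)]] * 6},
            loci=[LocusDef("L1", 2, "FAM")],
        )
        assert pairwise_fst(relabeled, "A", "B") == pytest.approx(ab, rel=1e-12)


# -- permutation tests --------------------------------------------------------


class TestPermutation:
    def test_constant_statistic_gives_p_one(self, two_pop_toy):
        _, p = permutation_test(lambda g, a, b: 1.0, two_pop_toy, "A", "B", n_perm=99, seed=0)
        assert p == pytest.approx(1.0)

    def test_strong_differentiation_gives_small_p(self):
        g = build_matrix({"A": [[(100, 100), (150, 150)]] * 8,
                          "B": [[(108, 108), (162, 162)]] * 8})
        _, p = permutation_test(pairwise_fst, g, "A", "B", n_perm=199, seed=0)
        assert p <= 0.01

    def test_null_p_values_are_uniform(self):
        """One panmictic sample split at random: p ~ Uniform(0,1) over replicates."""
        rng = np.random.default_rng(2)
        pool = [
            [(100 + 2 * rng.integers(0, 4), 100 + 2 * rng.integers(0, 4)) for _ in range(3)]
            for _ in range(24)
        ]
        pvals = []
        for rep in range(200):
            rep_rng = np.random.default_rng(rep)
            order = rep_rng.permutation(24)
            g = build_matrix(
                {"A": [pool[i] for i in order[:12]], "B": [pool[i] for i in order[12:]]}
            )
            _, p = permutation_test(pairwise_fst, g, "A", "B", n_perm=49, seed=rep)
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


# -- Mantel -------------------------------------------------------------------


class TestMantel:
    def make_dist(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 2))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        return d

    def test_identical_matrices_give_r_one(self):
        d = self.make_dist(8, 0)
        res = mantel_test(d, d, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_constant_matrix_is_an_error(self):
        d = self.make_dist(5, 1)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(np.ones((5, 5)) - np.eye(5) * 1, d)

    def test_r_matches_lower_triangle_correlation(self):
        gen = self.make_dist(5, 2)
        geo = self.make_dist(5, 3)
        res = mantel_test(gen, geo, n_perm=99, seed=0)
        il = np.tril_indices(5, -1)
        r0 = np.corrcoef(geo[il], gen[il])[0, 1]
        assert res.r == pytest.approx(r0, rel=1e-10)
        slope, intercept = np.polyfit(geo[il], gen[il], 1)
        assert res.slope == pytest.approx(slope) and res.intercept == pytest.approx(intercept)
        assert isinstance(res, MantelResult)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="square"):
            mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))
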