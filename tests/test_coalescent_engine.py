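import numpy as np
import pytest
from scipy import stats as sps

from invabc.calibration import TOY_PANEL, toy_split_scenario
from invabc.coalescent_engine import (
    GeneTree,
    MutationModelMsat,
    MutationModelSeq,
    SimOptions,
    hky_rate_matrix,
    mutate_microsat,
    mutate_sequence,
    simulate_dataset,
    simulate_gene_tree,
)
from invabc.scenario_model import (
    AdmixtureEvent,
    PriorSpec,
    SampleEvent,
    Scenario,
    SplitEvent,
)


def one_pop(ne=500.0, samples=None):
    return Scenario(
        id="one", populations=["P"], root="P", events=[],
        samples=samples or [SampleEvent("P", 2015, 2)],
        params={"N_P": PriorSpec("fixed", ne)}, ne0={"P": "N_P"},
    )


def two_tip_tree(t=100.0):
    """A fixed two-tip genealogy with total branch length 2t."""
    return GeneTree(
        parent=np.array([2, 2, -1]), time=np.array([0.0, 0.0, t]), n_tips=2,
        tip_population=["P", "P"], tip_time=np.zeros(2), tip_label=["P", "P"],
        tip_individual=np.array([0, 1]),
    )


class TestGeneTree:
    def test_two_tip_mean_tmrca_haploid(self):
        sc = one_pop(500.0)
        rng = np.random.default_rng(0)
        tm = [simulate_gene_tree(sc, {"N_P": 500.0}, ploidy=1, seed=rng,
                                 samples=[("P", 0.0, 2, "P")]).tmrca()
              for _ in range(2000)]
        assert np.mean(tm) == pytest.approx(500.0, rel=0.05)

    def test_two_tip_mean_tmrca_diploid(self):
        sc = one_pop(500.0)
        rng = np.random.default_rng(1)
        tm = [simulate_gene_tree(sc, {"N_P": 500.0}, ploidy=2, seed=rng,
                                 samples=[("P", 0.0, 2, "P")]).tmrca()
              for _ in range(2000)]
        assert np.mean(tm) == pytest.approx(1000.0, rel=0.05)

    def test_serial_tips_cannot_coalesce_before_sampling(self):
        sc = one_pop(200.0, samples=[SampleEvent("P", 2015, 3), SampleEvent("P", 2007, 3)])
        for seed in range(50):
            tree = simulate_gene_tree(sc, {"N_P": 200.0}, ploidy=2, seed=seed)
            lens = tree.branch_lengths()
            assert np.all(lens[: tree.n_tips] >= 0)
            late = np.flatnonzero(tree.tip_time == 80.0)
            for tip in late:
                assert tree.time[tree.parent[tip]] > 80.0

    def test_cross_population_tmrca_respects_split_time(self):
        sc = toy_split_scenario(n_diploid=3)
        draws = {"N_A": 300.0, "N_B": 300.0, "T": 400.0, "mu_di": 1e-4, "mu_tri": 1e-4}
        for seed in range(40):
            tree = simulate_gene_tree(sc, draws, ploidy=2, seed=seed)
            pops = np.array(tree.tip_population)
            a = int(np.flatnonzero(pops == "A")[0])
            b = int(np.flatnonzero(pops == "B")[0])
            # walk to the MRCA of one cross-population pair
            anc_a = set()
            v = a
            while v != -1:
                anc_a.add(v)
                v = tree.parent[v]
            v = b
            while v not in anc_a:
                v = tree.parent[v]
            assert tree.time[v] >= 400.0

    def test_tip_counts_and_finite_branches(self):
        sc = toy_split_scenario(n_diploid=5)
        tree = simulate_gene_tree(sc, sc.sample_priors(seed=0), ploidy=2, seed=0)
        assert tree.n_tips == 20
        assert np.all(np.isfinite(tree.branch_lengths()))

    def test_admixture_reroutes_lineages(self):
        sc = Scenario(
            id="adm", populations=["A", "B", "C"], root="A",
            events=[AdmixtureEvent(100.0, "C", "A", "B", 1.0),
                    SplitEvent(500.0, "B", "A")],
            samples=[SampleEvent(x, 2015, 2) for x in "ABC"],
            params={f"N_{x}": PriorSpec("fixed", 100) for x in "ABC"},
            ne0={x: f"N_{x}" for x in "ABC"},
        )
        # ra = 1: all C lineages route into B, so C/B pairs can coalesce before 500
        saw_early = False
        for seed in range(30):
            tree = simulate_gene_tree(sc, {f"N_{x}": 100.0 for x in "ABC"}, ploidy=1, seed=seed)
            assert tree.tmrca() > 0
            pops = np.array(tree.tip_population)
            c = int(np.flatnonzero(pops == "C")[0])
            b = int(np.flatnonzero(pops == "B")[0])
            anc = set()
            v = c
            while v != -1:
                anc.add(v)
                v = tree.parent[v]
            v = b
            while v not in anc:
                v = tree.parent[v]
            if tree.time[v] < 500.0:
                saw_early = True
        assert saw_early


class TestMicrosatMutation:
    def test_zero_rate_keeps_ancestral_state(self):
        tree = two_tip_tree()
        tips = mutate_microsat(tree, MutationModelMsat(0.0), ancestral_state=25, seed=0)
        assert np.all(tips == 25)

    def test_pure_stepwise_changes_parity_consistently(self):
        # p_gsm = 1: every mutation is +-1, so tip state parity flips per mutation
        tree = two_tip_tree(t=50.0)
        model = MutationModelMsat(1e-2, p_gsm=1.0)
        rng = np.random.default_rng(3)
        diffs = [np.diff(mutate_microsat(tree, model, 25, seed=rng))[0] for _ in range(200)]
        assert np.std(diffs) > 0

    def test_variance_of_tip_difference_matches_poisson_mean(self):
        """Var(tipA - tipB) = rate x total length for +-1 steps."""
        t, rate = 200.0, 5e-3
        tree = two_tip_tree(t=t)
        model = MutationModelMsat(rate, p_gsm=1.0)
        rng = np.random.default_rng(4)
        diffs = np.array(
            [np.diff(mutate_microsat(tree, model, 50, seed=rng))[0] for _ in range(4000)]
        )
        expected_var = rate * 2 * t  # Poisson mean x unit step variance
        assert np.var(diffs) == pytest.approx(expected_var, rel=0.1)

    def test_reflecting_lower_bound(self):
        tree = two_tip_tree(t=5000.0)
        model = MutationModelMsat(5e-3, p_gsm=0.7)
        rng = np.random.default_rng(5)
        tips = np.concatenate(
            [mutate_microsat(tree, model, 3, seed=rng) for _ in range(200)]
        )
        assert tips.min() >= 2


class TestSequenceMutation:
    def test_zero_rate_identical_sequences(self):
        tree = two_tip_tree()
        model = MutationModelSeq(rate=0.0)
        seqs = mutate_sequence(tree, model, L=100, seed=0)
        assert np.array_equal(seqs[0], seqs[1])

    def test_hky_rate_matrix_stationarity(self):
        pi = (0.29, 0.16, 0.15, 0.40)
        q = hky_rate_matrix(5.0, pi)
        assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
        assert np.allclose(np.array(pi) @ q, 0, atol=1e-12)  # pi Q = 0
        assert -np.sum(np.array(pi) * np.diag(q)) == pytest.approx(1.0)

    def test_kappa_one_equal_frequencies_is_jukes_cantor(self):
        """Transition:transversion substitution ratio approaches 1:2."""
        tree = two_tip_tree(t=1.0)
        model = MutationModelSeq(rate=0.05, kappa=1.0, base_freqs=(0.25,) * 4)
        rng = np.random.default_rng(6)
        transitions = transversions = 0
        ts_pairs = {(0, 2), (2, 0), (1, 3), (3, 1)}
        for _ in range(200):
            seqs = mutate_sequence(tree, model, L=500, seed=rng)
            bases = {65: 0, 67: 1, 71: 2, 84: 3}
            a = np.array([bases[x] for x in seqs[0]])
            b = np.array([bases[x] for x in seqs[1]])
            for x, y in zip(a[a != b], b[a != b]):
                if (int(x), int(y)) in ts_pairs:
                    transitions += 1
                else:
                    transversions += 1
        ratio = transitions / transversions
        assert ratio == pytest.approx(0.5, rel=0.2)

    def test_long_branch_identity_approaches_stationarity(self):
        pi = (0.29, 0.16, 0.15, 0.40)
        tree = two_tip_tree(t=500.0)
        model = MutationModelSeq(rate=0.05, kappa=5.0, base_freqs=pi)
        rng = np.random.default_rng(7)
        ident = []
        for _ in range(100):
            seqs = mutate_sequence(tree, model, L=445, seed=rng)
            ident.append(np.mean(seqs[0] == seqs[1]))
        assert np.mean(ident) == pytest.approx(sum(p**2 for p in pi), abs=0.01)


class TestSimulateDataset:
    def test_zero_rates_give_monomorphic_dataset(self):
        sc = toy_split_scenario(n_diploid=4)
        draws = {"N_A": 300.0, "N_B": 300.0, "T": 300.0, "mu_di": 0.0, "mu_tri": 0.0}
        opts = SimOptions(rate_shape=0.0, simulate_sequence=True)
        g, aln = simulate_dataset(sc, draws, TOY_PANEL, seed=0, options=opts)
        for j in range(g.n_loci):
            assert len(np.unique(g.calls[:, j, :])) == 1
        assert len(np.unique(aln.seqs, axis=0)) == 1

    def test_same_seed_identical_dataset(self):
        sc = toy_split_scenario(n_diploid=4)
        draws = sc.sample_priors(seed=2)
        a, alna = simulate_dataset(sc, draws, TOY_PANEL, seed=11)
        b, alnb = simulate_dataset(sc, draws, TOY_PANEL, seed=11)
        assert np.array_equal(a.calls, b.calls)
        assert np.array_equal(alna.seqs, alnb.seqs)

    def test_study_like_integration_is_valid(self):
        from invabc.scenario_model import build_study_scenarios
        from invabc.genotype_io import default_panel

        sc = build_study_scenarios()[3]
        draws = sc.sample_priors(seed=1)
        g, aln = simulate_dataset(sc, draws, default_panel(), seed=1)
        assert g.n_individuals == 230  # 7 x 30 + 20
        assert g.missing_mask().sum() == 0
        assert aln.n_records == 230 and aln.length == 445
        labels = set(g.samples["population"])
        assert {"PNG_1992", "PNG_2011", "TSF_2007", "TSF_2015", "PAP_2015"} <= labels

    def test_he_increases_with_theta(self):
        """Mean within-population gene diversity is monotone over a theta grid."""
        from invabc.popgen_stats import diversity_summary

        mean_he = []
        for theta in (0.4, 4.0, 40.0):
            ne = 1000.0
            mu = theta / (4 * ne)
            sc = one_pop(ne, samples=[SampleEvent("P", 2015, 15)])
            hes = []
            for rep in range(60):
                draws = {"N_P": ne, "mu_di": mu, "mu_tri": mu}
                g, _ = simulate_dataset(
                    sc, draws, TOY_PANEL[:2], seed=rep + 100,
                    options=SimOptions(simulate_sequence=False, rate_shape=0.0),
                )
                df = diversity_summary(g)
                hes.append(df.loc[df["locus"] == "mean", "He"].iloc[0])
            mean_he.append(np.mean(hes))
        assert mean_he[0] < mean_he[1] < mean_he[2]


@pytest.mark.filterwarnings("ignore")
def test_pairwise_differences_match_msprime_oracle():
    """Two-population split model: the distribution of cross-population
    pairwise sequence differences agrees with an independent coalescent
    simulator (KS at alpha = 0.01, 500 replicates each)."""
    msprime = pytest.importorskip("msprime")
    ne, T, mu, L = 400.0, 300.0, 2e-5, 300
    # ours
    sc = Scenario(
        id="sp", populations=["A", "B"], root="A",
        events=[SplitEvent(T, "B", "A")],
        samples=[SampleEvent("A", 2015, 1), SampleEvent("B", 2015, 1)],
        params={"N_A": PriorSpec("fixed", ne), "N_B": PriorSpec("fixed", ne)},
        ne0={"A": "N_A", "B": "N_B"},
    )
    rng = np.random.default_rng(0)
    ours = []
    model = MutationModelSeq(rate=mu, kappa=1.0, base_freqs=(0.25,) * 4)
    for _ in range(500):
        tree = simulate_gene_tree(
            sc, {"N_A": ne, "N_B": ne}, ploidy=1, seed=rng,
            samples=[("A", 0.0, 1, "A"), ("B", 0.0, 1, "B")],
        )
        seqs = mutate_sequence(tree, model, L=L, seed=rng)
        ours.append(int(np.sum(seqs[0] != seqs[1])))
    # msprime
    demography = msprime.Demography()
    demography.add_population(name="A", initial_size=ne)
    demography.add_population(name="B", initial_size=ne)
    demography.add_population(name="ANC", initial_size=ne)
    demography.add_population_split(time=T, derived=["A", "B"], ancestral="ANC")
    theirs = []
    for seed in range(1, 501):
        ts = msprime.sim_ancestry(
            samples={"A": 1, "B": 1}, demography=demography, ploidy=1,
            sequence_length=L, random_seed=seed,
        )
        mts = msprime.sim_mutations(ts, rate=mu, random_seed=seed,
                                    model=msprime.JC69())
        div = mts.divergence([[0], [1]], span_normalise=False)
        theirs.append(float(div))
    ks = sps.ks_2samp(ours, theirs)
    assert ks.pvalue > 0.01
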