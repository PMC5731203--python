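"""Backward serial coalescent: move probabilities, merges, genealogies."""

import numpy as np
import pytest
from scipy import stats as sps

import serialcoal as sc
from serialcoal.coalescent import GeneGenealogy


def constant_size_scenario(n_modern=2, n_ancient=0, ancient_age=400, N=100):
    """Single-deme world held at constant size N (r=0, K=N0=N)."""
    groups = [sc.SamplingGroup((0, 0), 0, n_modern, "modern")]
    if n_ancient:
        groups.append(sc.SamplingGroup((0, 0), ancient_age, n_ancient, "ancient"))
    return sc.ScenarioConfig(
        world=sc.build_square_world(1),
        T=2000,
        N0=N,
        r=0.0,
        m_schedule=sc.ScheduledValue.constant(0.0),
        K_schedule=sc.ScheduledValue.constant(float(N)),
        mu=0.0,
        L=100,
        sampling=sc.SamplingScheme(groups),
        label="constant",
    )


class TestBackwardMoveProbs:
    def test_uniform_equilibrium_values(self, demography):
        d = demography("table2_SP_Nm50")
        w = d.world
        j = w.id_of((25, 25))
        t = 1900  # long after saturation of the whole map
        probs = sc.backward_move_probs(d, j, t)
        assert probs["stay"] == pytest.approx(0.9, abs=1e-9)
        nbrs = [v for k, v in probs.items() if k != "stay"]
        assert len(nbrs) == 4
        assert nbrs == pytest.approx([12.5 / 500] * 4, abs=1e-9)

    def test_single_deme_world_always_stays(self, demography):
        d = demography("table2_P")
        probs = sc.backward_move_probs(d, 0, 1000)
        assert probs == {"stay": 1.0}

    def test_probabilities_normalized_on_saturated_world(self, demography):
        d = demography("table2_SP_Nm5")
        rng = np.random.default_rng(3)
        for j in rng.integers(0, d.world.D, size=20):
            probs = sc.backward_move_probs(d, int(j), 1950)
            vals = np.array(list(probs.values()))
            assert ((0 <= vals) & (vals <= 1)).all()
            assert vals.sum() == pytest.approx(1.0)

    def test_matches_recorded_flows_over_density(self, demography):
        d = demography("table2_SP_Nm50")
        w = d.world
        t = 120  # mid-expansion, inhomogeneous densities
        flows = d.emigrants(t)
        j = w.id_of((25, 35))  # on the expansion front at this time
        probs = sc.backward_move_probs(d, j, t)
        Nj = d.densities[t, j]
        assert Nj > 0
        for k in range(4):
            i = int(w.neighbors[j, k])
            if i >= 0 and flows[i, list(w.neighbors[i]).index(j)] > 0:
                assert probs[i] == pytest.approx(
                    flows[i, list(w.neighbors[i]).index(j)] / Nj
                )

    def test_newly_colonized_deme_forces_leaving(self, demography):
        d = demography("table2_SP_Nm5")
        ct = d.colonization_time
        j = int(np.argmax(ct))  # one of the last demes colonized
        probs = sc.backward_move_probs(d, j, int(ct[j]))
        assert probs["stay"] == 0.0
        assert sum(v for k, v in probs.items() if k != "stay") == pytest.approx(1.0)


class TestCoalesceInDeme:
    def test_two_lineages_size_one_always_merge(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pairs = sc.coalesce_in_deme([7, 9], 1, rng)
            assert pairs in ([(7, 9)], [(9, 7)])

    def test_single_lineage_no_event(self):
        rng = np.random.default_rng(0)
        assert sc.coalesce_in_deme([3], 100, rng) == []

    def test_pair_rate_matches_wright_fisher(self):
        rng = np.random.default_rng(42)
        n_draws = 100_000
        merges = sum(bool(sc.coalesce_in_deme([0, 1], 100, rng)) for _ in range(n_draws))
        rate = merges / n_draws
        se = np.sqrt(0.01 * 0.99 / n_draws)
        assert abs(rate - 0.01) < 3 * se

    def test_simultaneous_pairs_are_disjoint_and_capped(self):
        rng = np.random.default_rng(1)
        lineages = list(range(9))
        for _ in range(300):
            pairs = sc.coalesce_in_deme(lineages, 2, rng)
            assert len(pairs) <= 4  # floor(k/2)
            flat = [x for p in pairs for x in p]
            assert len(flat) == len(set(flat))


class TestSimulateGenealogy:
    def test_two_lineage_mean_tmrca_is_population_size(self):
        scen = constant_size_scenario(n_modern=2)
        demo = sc.run_forward(scen)
        times = np.array(
            [
                sc.simulate_genealogy(demo, scen, 50_000 + i).time[-1]
                for i in range(2000)
            ],
            dtype=float,
        )
        se = times.std(ddof=1) / np.sqrt(times.size)
        assert abs(times.mean() - 100.0) < 3 * se

    def test_matches_discrete_time_wright_fisher_oracle(self):
        import msprime

        scen = constant_size_scenario(n_modern=2)
        demo = sc.run_forward(scen)
        ours = np.array(
            [
                sc.simulate_genealogy(demo, scen, 90_000 + i).time[-1]
                for i in range(2000)
            ],
            dtype=float,
        )
        # 50 diploids x 2 genomes = 100 lineage slots: pair coalescence
        # probability 1/100 per generation, as in our haploid model
        reps = msprime.sim_ancestry(
            samples=1,
            population_size=50,
            ploidy=2,
            model=msprime.DiscreteTimeWrightFisher(),
            num_replicates=2000,
            random_seed=20260,
        )
        theirs = np.array([ts.first().time(ts.first().root) for ts in reps])
        assert sps.ks_2samp(ours, theirs).pvalue > 0.01

    def test_serial_pair_mean_tmrca_adds_sampling_gap(self):
        scen = constant_size_scenario(n_modern=2, n_ancient=2, ancient_age=400)
        demo = sc.run_forward(scen)
        t1 = np.array(
            [
                sc.mean_coal_times(
                    sc.simulate_genealogy(demo, scen, 10_000 + i)
                ).t1
                for i in range(2000)
            ]
        )
        # a (modern, ancient) pair cannot meet during the 400-generation gap,
        # then waits Geometric(1/N): expectation 400 + 100
        se = t1.std(ddof=1) / np.sqrt(t1.size)
        assert t1.min() > 400
        assert abs(t1.mean() - 500.0) < 3 * se

    def test_tree_structure_and_validation(self, demography, scenario):
        scen = scenario("table2_SP_Nm5")
        g = sc.simulate_genealogy(demography("table2_SP_Nm5"), scen, 7)
        assert g.n_leaves == 60
        assert g.n_nodes == 119  # exactly n-1 internal nodes
        g.validate()
        # ancient leaves participate in no event more recent than their age
        anc = g.leaf_labels == "ancient"
        parents = g.parent[: g.n_leaves][anc]
        assert (g.time[parents] > 400).all()

    def test_sampling_before_colonization_rejected(self, demography):
        import dataclasses

        scen = sc.load_bundled_scenario("table2_SP_Nm5")
        bad = dataclasses.replace(
            scen,
            sampling=sc.serial_sampling((0, 0), 5, 5, 1990),
        )
        with pytest.raises(sc.SimulationError):
            sc.simulate_genealogy(demography("table2_SP_Nm5"), bad, 1)

    def test_identical_seed_reproduces_tree(self, demography, scenario):
        scen = scenario("table2_SP_Nm50")
        d = demography("table2_SP_Nm50")
        g1 = sc.simulate_genealogy(d, scen, 123)
        g2 = sc.simulate_genealogy(d, scen, 123)
        assert np.array_equal(g1.parent, g2.parent)
        assert np.array_equal(g1.time, g2.time)
        assert np.array_equal(g1.deme, g2.deme)


def synthetic_genealogy(parent, time, labels):
    parent = np.asarray(parent)
    n = (len(parent) + 1) // 2
    return GeneGenealogy(
        n_leaves=n,
        parent=parent,
        time=np.asarray(time),
        deme=np.zeros(len(parent), dtype=np.int64),
        leaf_labels=np.asarray(labels),
        positions=np.zeros((1, 2), dtype=np.int64),
    )


class TestMeanCoalTimes:
    def test_single_pair_t1_is_root_time(self):
        g = synthetic_genealogy([2, 2, -1], [0, 0, 37], ["modern", "ancient"])
        times = sc.mean_coal_times(g)
        assert times.t1 == 37
        assert times.t0_mod is None and times.t0_anc is None and times.t0 is None

    def test_star_genealogy_all_pairs_at_root(self):
        # all internal nodes at the root's time: every pair MRCA is 100
        g = synthetic_genealogy(
            [4, 4, 5, 6, 5, 6, -1],
            [0, 0, 0, 0, 100, 100, 100],
            ["modern", "modern", "ancient", "ancient"],
        )
        times = sc.mean_coal_times(g)
        assert times.t0_mod == times.t0_anc == times.t0 == times.t1 == 100

    def test_agrees_with_pairwise_tmrca_matrix(self, demography, scenario):
        scen = scenario("table2_SP_Nm5")
        g = sc.simulate_genealogy(demography("table2_SP_Nm5"), scen, 99)
        mat = g.pairwise_tmrca()
        mod = g.leaf_labels == "modern"
        anc = ~mod
        expected_t1 = mat[np.ix_(mod, anc)].mean()
        iu_m = np.triu_indices(mod.sum(), k=1)
        iu_a = np.triu_indices(anc.sum(), k=1)
        times = sc.mean_coal_times(g)
        assert times.t1 == pytest.approx(expected_t1)
        assert times.t0_mod == pytest.approx(mat[np.ix_(mod, mod)][iu_m].mean())
        assert times.t0_anc == pytest.approx(mat[np.ix_(anc, anc)][iu_a].mean())

    def test_newick_export_parses_and_preserves_depth(self, demography, scenario):
        import io

        from Bio import Phylo

        scen = scenario("table2_SP_Nm50")
        g = sc.simulate_genealogy(demography("table2_SP_Nm50"), scen, 5)
        tree = Phylo.read(io.StringIO(g.to_newick(include_demes=False)), "newick")
        assert tree.count_terminals() == g.n_leaves
        depths = tree.depths()
        leaf = next(c for c in tree.get_terminals() if c.name.startswith("L0_"))
        root_time = g.time[g.root]
        assert depths[leaf] == pytest.approx(root_time - g.time[0])
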