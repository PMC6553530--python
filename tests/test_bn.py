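import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from factorbn import bn
from factorbn.bn import (
    BgeScore,
    BicScore,
    Cpdag,
    Dag,
    ScoreConfig,
    bootstrap_average,
    ci_test_fisher_z,
    cpdag_of,
    enumerate_dags,
    learn_hc,
    learn_hybrid,
    learn_skeleton,
    learn_tabu,
    make_learner,
    score_bge,
    score_bic,
)


def chain_data(rng, n=400, beta=0.9, nodes=("A", "B", "C")):
    """Strong linear chain A -> B -> C."""
    a = rng.standard_normal(n)
    b = beta * a + rng.standard_normal(n) * np.sqrt(1 - beta**2)
    c = beta * b + rng.standard_normal(n) * np.sqrt(1 - beta**2)
    return pd.DataFrame(dict(zip(nodes, (a, b, c))))


def collider_data(rng, n=500, beta=0.8):
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    z = beta * x + beta * y + rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y, "z": z})


class TestDag:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Dag.from_edges(("a", "b"), [("a", "b"), ("b", "a")])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            Dag(("a",), {"a": frozenset(["a"])})

    def test_enumeration_counts(self):
        assert sum(1 for _ in enumerate_dags(("a", "b", "c"))) == 25
        assert sum(1 for _ in enumerate_dags(("a", "b", "c", "d"))) == 543


class TestBicScore:
    def test_empty_graph_equals_closed_form_univariate(self):
        """Sum over nodes of the Gaussian max log-likelihood minus
        (2/2) log n, with the MLE variance (ddof 0)."""
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        empty = Dag.from_edges(("a", "b", "c"), [])
        n = 80
        expected = 0.0
        for c in df.columns:
            s2 = df[c].var(ddof=0)
            expected += -0.5 * n * (np.log(2 * np.pi * s2) + 1) - 0.5 * 2 * np.log(n)
        assert score_bic(df, empty) == pytest.approx(expected, rel=1e-12)

    def test_zero_correlation_edge_costs_exactly_half_log_n(self):
        # construct exact zero sample correlation
        x = np.array([1.0, -1.0, 2.0, -2.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        df = pd.DataFrame({"A": x, "B": y})
        s_empty = score_bic(df, Dag.from_edges(("A", "B"), []))
        s_edge = score_bic(df, Dag.from_edges(("A", "B"), [("A", "B")]))
        assert s_edge - s_empty == pytest.approx(-0.5 * np.log(4), abs=1e-10)

    def test_decomposability_spot_perturbation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        scorer = BicScore(df)
        dag = Dag.from_edges(("a", "b", "c", "d"), [("a", "b"), ("c", "d")])
        changed = dag.with_parents("b", frozenset(["a", "c"]))
        delta_total = scorer.total(changed) - scorer.total(dag)
        delta_local = scorer.local("b", frozenset(["a", "c"])) - scorer.local(
            "b", frozenset(["a"])
        )
        assert delta_total == pytest.approx(delta_local, abs=1e-10)

    def test_too_many_parents_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((4, 4)), columns=list("abcd"))
        scorer = BicScore(df)
        with pytest.raises(ValueError, match="parents"):
            scorer.local("a", frozenset(["b", "c", "d"]))


class TestBgeScore:
    def test_single_node_matches_numerical_integration(self):
        """Independent conjugate-marginal oracle: integrate the
        normal likelihood against the normal-Wishart prior numerically
        for one variable and a handful of observations."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(6) * 1.3 + 0.4
        df = pd.DataFrame({"v": x})
        cfg = ScoreConfig(score_tag="bge", bge_iss_mu=1.0, bge_iss_w=3.0)
        scorer = BgeScore(df, cfg)
        got = scorer.local("v", frozenset())
        # q=1: prior tau ~ Wishart_1(a_w, T^-1) i.e. Gamma(a_w/2, T/2);
        # mu | tau ~ N(nu, 1/(a_mu tau)); nu = sample mean, T = t = a_mu
        # (a_w - q - 1)/(a_mu + 1) = 0.5
        a_mu, a_w, t = 1.0, 3.0, 0.5
        nu = x.mean()

        def integrand(tau, mu):
            like = np.prod(stats.norm.pdf(x, mu, 1 / np.sqrt(tau)))
            p_mu = stats.norm.pdf(mu, nu, 1 / np.sqrt(a_mu * tau))
            p_tau = stats.gamma.pdf(tau, a_w / 2, scale=2 / t)
            return like * p_mu * p_tau

        val, _ = integrate.dblquad(
            integrand, -8, 8, lambda mu: 1e-4, lambda mu: 60, epsabs=1e-12
        )
        assert got == pytest.approx(np.log(val), abs=1e-3)

    def test_score_equivalent_across_orientations(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((50, 2)) @ rng.standard_normal((2, 2)),
                          columns=["A", "B"])
        s1 = score_bge(df, Dag.from_edges(("A", "B"), [("A", "B")]))
        s2 = score_bge(df, Dag.from_edges(("A", "B"), [("B", "A")]))
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_equal_bge_iff_same_cpdag_on_random_dags(self):
        rng = np.random.default_rng(4)
        nodes = ("a", "b", "c", "d", "e")
        df = pd.DataFrame(
            rng.standard_normal((60, 5)) @ rng.standard_normal((5, 5)), columns=nodes
        )
        scorer = BgeScore(df)

        def random_dag():
            order = rng.permutation(nodes)
            edges = [
                (order[i], order[j])
                for i in range(5)
                for j in range(i + 1, 5)
                if rng.random() < 0.4
            ]
            return Dag.from_edges(nodes, edges)

        dags = [random_dag() for _ in range(40)]
        for d1, d2 in itertools.combinations(dags, 2):
            same_class = cpdag_of(d1) == cpdag_of(d2)
            same_score = abs(scorer.total(d1) - scorer.total(d2)) < 1e-8
            assert same_class == same_score

    def test_degenerate_prior_scale_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="degenerate"):
            BgeScore(df, ScoreConfig(score_tag="bge", bge_prior_scale=np.zeros((2, 2))))


class TestFisherZ:
    def test_exact_zero_correlation_gives_p_one(self):
        df = pd.DataFrame(
            {"x": [1.0, -1.0, 2.0, -2.0, 0.0], "y": [1.0, 1.0, -1.0, -1.0, 0.0]}
        )
        assert ci_test_fisher_z(df, "x", "y") == pytest.approx(1.0)

    def test_partial_correlation_equals_residualization_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.standard_normal((60, 5)) @ rng.standard_normal((5, 5)),
            columns=list("vwxyz"),
        )
        p_pkg = ci_test_fisher_z(df, "v", "w", ("x", "y", "z"))
        Z = np.column_stack([np.ones(60), df[["x", "y", "z"]].to_numpy()])
        rv = df["v"] - Z @ np.linalg.lstsq(Z, df["v"], rcond=None)[0]
        rw = df["w"] - Z @ np.linalg.lstsq(Z, df["w"], rcond=None)[0]
        r = np.corrcoef(rv, rw)[0, 1]
        z = np.arctanh(r) * np.sqrt(60 - 3 - 3)
        p_oracle = 2 * stats.norm.sf(abs(z))
        assert p_pkg == pytest.approx(p_oracle, abs=1e-10)

    def test_d_separation_in_chain(self):
        """x -> z -> y: conditioning on z removes the dependence."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            x = rng.standard_normal(300)
            z = 0.9 * x + 0.44 * rng.standard_normal(300)
            y = 0.9 * z + 0.44 * rng.standard_normal(300)
            df = pd.DataFrame({"x": x, "y": y, "z": z})
            assert ci_test_fisher_z(df, "x", "y") < 0.05
            if ci_test_fisher_z(df, "x", "y", ("z",)) > 0.05:
                hits += 1
        assert hits >= 90

    def test_insufficient_degrees_of_freedom(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((4, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="n - |S| - 3"):
            ci_test_fisher_z(df, "a", "b", ("c",))


class TestScoreSearch:
    def test_independent_columns_give_empty_graph(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((500, 4)), columns=list("abcd"))
        assert learn_hc(df, "bic").edges == frozenset()
        assert learn_tabu(df, "bic").edges == frozenset()

    @pytest.mark.parametrize("tag", ["bic", "bge"])
    def test_three_node_exhaustive_optimum(self, tag):
        rng = np.random.default_rng(7)
        for rep in range(5):
            df = pd.DataFrame(
                rng.standard_normal((120, 3)) @ rng.standard_normal((3, 3)),
                columns=list("abc"),
            )
            scorer = bn.make_score(df, tag)
            best = max(scorer.total(d) for d in enumerate_dags(("a", "b", "c")))
            assert scorer.total(learn_hc(df, scorer=scorer)) == pytest.approx(best)
            assert scorer.total(learn_tabu(df, scorer=scorer)) == pytest.approx(best)

    def test_strong_chain_recovers_equivalence_class(self):
        rng = np.random.default_rng(8)
        df = chain_data(rng)
        dag = learn_hc(df, "bic")
        truth = Dag.from_edges(("A", "B", "C"), [("A", "B"), ("B", "C")])
        assert cpdag_of(dag) == cpdag_of(truth)

    def test_learners_never_return_cycles(self):
        rng = np.random.default_rng(9)
        for rep in range(10):
            df = pd.DataFrame(
                rng.standard_normal((60, 5)) @ rng.standard_normal((5, 5)),
                columns=list("abcde"),
            )
            for learner in (learn_hc, learn_tabu):
                dag = learner(df, "bic")
                assert dag.topological_order() is not None


class TestConstraintBased:
    def test_collider_oriented_into_common_child(self):
        rng = np.random.default_rng(10)
        cp = learn_skeleton(collider_data(rng), alpha=0.05)
        assert cp.directed_edges == frozenset({("x", "z"), ("y", "z")})
        assert cp.undirected_edges == frozenset()

    def test_independent_data_edgeless(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.standard_normal((400, 4)), columns=list("abcd"))
        cp = learn_skeleton(df, alpha=0.01)
        assert cp.adjacencies() == frozenset()

    def test_chain_yields_undirected_pattern(self):
        rng = np.random.default_rng(12)
        cp = learn_skeleton(chain_data(rng), alpha=0.05)
        assert cp.adjacencies() == frozenset(
            {frozenset({"A", "B"}), frozenset({"B", "C"})}
        )
        assert cp.directed_edges == frozenset()

    def test_alpha_bounds(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((30, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="alpha"):
            learn_skeleton(df, alpha=1.5)


class TestCpdagOf:
    def test_chain_fully_undirected(self):
        dag = Dag.from_edges(("a", "b", "c"), [("a", "b"), ("b", "c")])
        cp = cpdag_of(dag)
        assert cp.directed_edges == frozenset()
        assert cp.undirected_edges == frozenset(
            {frozenset({"a", "b"}), frozenset({"b", "c"})}
        )

    def test_collider_stays_directed(self):
        dag = Dag.from_edges(("a", "b", "c"), [("a", "c"), ("b", "c")])
        cp = cpdag_of(dag)
        assert cp.directed_edges == frozenset({("a", "c"), ("b", "c")})

    def test_meek_rule_orients_compelled_descendant(self):
        # collider a -> c <- b plus c - d: R1 compels c -> d
        dag = Dag.from_edges(("a", "b", "c", "d"), [("a", "c"), ("b", "c"), ("c", "d")])
        cp = cpdag_of(dag)
        assert ("c", "d") in cp.directed_edges


class TestHybrid:
    def test_independent_data_restricts_to_empty(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.standard_normal((400, 4)), columns=list("abcd"))
        for variant in ("mmhc", "rsmax2"):
            assert learn_hybrid(df, variant).edges == frozenset()

    def test_agrees_with_hc_on_strong_chain(self):
        rng = np.random.default_rng(14)
        df = chain_data(rng)
        assert cpdag_of(learn_hybrid(df, "mmhc")) == cpdag_of(learn_hc(df, "bic"))

    def test_result_contained_in_restriction(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            rng.standard_normal((150, 5)) @ rng.standard_normal((5, 5)),
            columns=list("abcde"),
        )
        allowed = bn.restrict_phase(df, "mmpc", alpha=0.05)
        dag = learn_hybrid(df, "mmhc", alpha=0.05)
        assert dag.adjacencies() <= allowed

    def test_unknown_variant_rejected(self):
        df = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="variant"):
            learn_hybrid(df, "other")


class TestBootstrapAverage:
    def test_degenerate_learner_bookkeeping(self):
        df = pd.DataFrame(
            np.random.default_rng(0).standard_normal((30, 2)), columns=["A", "B"]
        )
        fixed = lambda d: Dag.from_edges(("A", "B"), [("A", "B")])
        avg = bootstrap_average(df, fixed, n_boot=50, strength_threshold=0.5, seed=1)
        assert avg.arc_strength[frozenset({"A", "B"})] == 1.0
        assert avg.arc_direction[("A", "B")] == 1.0
        assert avg.arc_direction[("B", "A")] == 0.0
        assert avg.consensus.edges == frozenset({("A", "B")})

    def test_probability_bookkeeping_invariants(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(
            rng.standard_normal((80, 4)) @ rng.standard_normal((4, 4)),
            columns=list("abcd"),
        )
        avg = bootstrap_average(df, make_learner("hc"), n_boot=60, seed=2)
        for pair, s in avg.arc_strength.items():
            assert 0 <= s <= 1
            a, b = sorted(pair)
            assert avg.arc_direction[(a, b)] + avg.arc_direction[(b, a)] == pytest.approx(1.0)

    def test_consensus_shrinks_as_threshold_rises(self):
        rng = np.random.default_rng(17)
        df = chain_data(rng, n=150)
        sizes = []
        for thr in (0.3, 0.6, 0.9):
            avg = bootstrap_average(
                df, make_learner("hc"), n_boot=80, strength_threshold=thr, seed=3
            )
            sizes.append(len(avg.consensus.edges))
        assert sizes == sorted(sizes, reverse=True)

    def test_recovery_on_clean_structural_data(self):
        """Bootstrap-averaged hill climbing on direct draws from a
        6-node linear SEM keeps the consensus inside the true CPDAG's
        adjacencies with at most one false adjacency."""
        from factorbn import simdata

        cfg = simdata.SimulationConfig.default(seed=71, n_accessions=400, n_markers=60)
        rng = np.random.default_rng(72)
        idx = {f: j for j, f in enumerate(cfg.factor_names)}
        parents = {f: [] for f in cfg.factor_names}
        for p, c, b in cfg.dag_edges:
            parents[c].append((p, b))
        W = np.zeros((400, 6))
        noise = rng.standard_normal((400, 6))
        for f in cfg.topological_order():
            j = idx[f]
            W[:, j] = noise[:, j]
            for p, b in parents[f]:
                W[:, j] += b * W[:, idx[p]]
        df = pd.DataFrame(W, columns=cfg.factor_names)
        avg = bootstrap_average(
            df, make_learner("hc"), n_boot=200, strength_threshold=0.85, seed=73
        )
        truth = Dag.from_edges(cfg.factor_names, [(p, c) for p, c, _ in cfg.dag_edges])
        true_adj = cpdag_of(truth).adjacencies()
        cons = avg.consensus.adjacencies()
        assert len(cons - true_adj) <= 1
        assert len(cons & true_adj) >= 5

    def test_threshold_validation(self):
        df = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="thresholds"):
            bootstrap_average(df, make_learner("hc"), n_boot=5, strength_threshold=1.5)


def test_dot_and_graphml_export(tmp_path):
    dag = Dag.from_edges(("a", "b", "c"), [("a", "b")])
    bn.write_dot(dag, tmp_path / "g.dot")
    assert '"a" -> "b"' in (tmp_path / "g.dot").read_text()
    bn.write_graphml(dag, tmp_path / "g.graphml")
    import networkx as nx

    g = nx.read_graphml(tmp_path / "g.graphml")
    assert set(g.edges) == {("a", "b")}
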