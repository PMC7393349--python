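"""Signed adjacency, TOM, module cut/merge, eigengenes, ANOVA, centrality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asthmanet import wgcna
from asthmanet.wgcna import (ModuleAssignment, cut_modules,
                             eigengene_interaction_test, eigengene_matrix,
                             module_centrality, module_eigengene,
                             module_network, signed_adjacency,
                             topological_overlap)


def _expr_from_corr(rng, r12: float, n: int = 200) -> pd.DataFrame:
    z = rng.standard_normal((2, n))
    x1 = z[0]
    x2 = r12 * z[0] + np.sqrt(1 - r12 ** 2) * z[1]
    return pd.DataFrame([x1, x2], index=["a", "b"])


class TestSignedAdjacency:
    def test_closed_forms(self, rng):
        for r, expected in ((1.0, 1.0), (-1.0, 0.0)):
            expr = _expr_from_corr(rng, 0.3)
            expr.loc["b"] = r * expr.loc["a"]
            a = signed_adjacency(expr, beta=12)
            assert a.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
        # r = 0 -> ((1+0)/2)^12 = 2^-12, via construction of orthogonal series
        expr = pd.DataFrame([[1, -1, 1, -1], [1, 1, -1, -1]],
                            index=["a", "b"], dtype=float)
        assert signed_adjacency(expr, beta=12).loc["a", "b"] == pytest.approx(2 ** -12)

    def test_self_adjacency_is_one(self, rng):
        expr = pd.DataFrame(rng.standard_normal((4, 10)))
        assert np.allclose(np.diag(signed_adjacency(expr)), 1.0)

    def test_formula_matches_independent_evaluation(self, rng):
        expr = pd.DataFrame(rng.standard_normal((4, 12)))
        a = signed_adjacency(expr, beta=12).to_numpy()
        r = np.corrcoef(expr.to_numpy())
        for i in range(4):
            for j in range(4):
                assert a[i, j] == pytest.approx(((1 + r[i, j]) / 2) ** 12)

    def test_zero_variance_gene_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                            index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            signed_adjacency(expr)


def _tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Independent triple-loop oracle for the topological overlap matrix."""
    n = a.shape[0]
    tom = np.eye(n)
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTopologicalOverlap:
    def test_all_ones_adjacency_gives_tom_one(self):
        a = pd.DataFrame(np.ones((5, 5)))
        assert np.allclose(topological_overlap(a), 1.0)

    def test_three_gene_toy_matches_oracle(self):
        a = np.array([[1, 0.5, 0.2], [0.5, 1, 0.4], [0.2, 0.4, 1]])
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, _tom_bruteforce(a), atol=1e-12)

    def test_isolated_pair_has_zero_overlap(self):
        a = np.eye(4)
        a[2, 3] = a[3, 2] = 0.9  # a connected pair elsewhere
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert tom[0, 1] == 0.0

    def test_asymmetric_input_rejected(self):
        a = pd.DataFrame(np.array([[1.0, 0.5], [0.1, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, _tom_bruteforce(a), atol=1e-12)


def _block_tom(rng, sizes, within=0.9, between=0.05):
    n = sum(sizes)
    tom = np.full((n, n), between) + rng.uniform(-0.02, 0.02, size=(n, n))
    tom = (tom + tom.T) / 2
    start = 0
    for s in sizes:
        tom[start:start + s, start:start + s] = within + rng.uniform(
            -0.02, 0.02, size=(s, s))
        start += s
    tom = np.clip((tom + tom.T) / 2, 0, 1)
    np.fill_diagonal(tom, 1.0)
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(tom, index=ids, columns=ids)


class TestCutModules:
    def test_two_planted_blocks_recovered_exactly(self, rng):
        tom = _block_tom(rng, [50, 50])
        assign = cut_modules(tom, min_module_size=30)
        labels = assign.labels
        from sklearn.metrics import adjusted_rand_score
        truth = ["A"] * 50 + ["B"] * 50
        assert adjusted_rand_score(truth, labels) == 1.0
        assert len(assign.modules) == 2

    def test_uniform_random_tom_leaves_everything_unassigned(self):
        unassigned_runs = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tom = rng.uniform(0, 0.05, size=(100, 100))
            tom = (tom + tom.T) / 2
            np.fill_diagonal(tom, 1.0)
            assign = cut_modules(pd.DataFrame(tom), min_module_size=30)
            if set(assign.labels) == {wgcna.UNASSIGNED}:
                unassigned_runs += 1
        assert unassigned_runs >= 95

    def test_highly_correlated_planted_modules_merge(self, rng):
        """Factors correlated at 0.95 exceed the 1 - 0.15 merge height."""
        n = 40
        f = rng.standard_normal(60)
        f2 = 0.95 * f + np.sqrt(1 - 0.95 ** 2) * rng.standard_normal(60)
        expr = np.concatenate([
            np.outer(np.ones(n), f) + 0.1 * rng.standard_normal((n, 60)),
            np.outer(np.ones(n), f2) + 0.1 * rng.standard_normal((n, 60)),
        ])
        expr = pd.DataFrame(expr, index=[f"g{i}" for i in range(2 * n)])
        tom = topological_overlap(signed_adjacency(expr))
        assign = cut_modules(tom, expr=expr, min_module_size=30,
                             merge_height=0.15)
        assert len(assign.modules) == 1

    def test_gene_order_invariance(self, rng):
        tom = _block_tom(rng, [40, 40, 40])
        base = cut_modules(tom, min_module_size=30)
        perm = rng.permutation(tom.index)
        shuffled = cut_modules(tom.loc[perm, perm], min_module_size=30)
        part_a = {frozenset(base.labels.index[base.labels == m])
                  for m in base.modules}
        part_b = {frozenset(shuffled.labels.index[shuffled.labels == m])
                  for m in shuffled.modules}
        assert part_a == part_b

    def test_fewer_genes_than_min_size_warns(self):
        tom = pd.DataFrame(np.eye(5))
        with pytest.warns(UserWarning):
            assign = cut_modules(tom, min_module_size=30)
        assert set(assign.labels) == {wgcna.UNASSIGNED}


class TestModuleEigengene:
    def test_identical_genes_explain_everything(self, rng):
        profile = rng.standard_normal(8)
        expr = pd.DataFrame([profile + rng.normal(0, 1e-9, 8) for _ in range(5)],
                            index=[f"g{i}" for i in range(5)])
        eig, ev = module_eigengene(expr, expr.index)
        assert ev == pytest.approx(1.0, abs=1e-6)
        prof_std = (profile - profile.mean()) / profile.std(ddof=1)
        assert abs(np.corrcoef(eig, prof_std)[0, 1]) == pytest.approx(1.0, abs=1e-6)

    def test_sign_fix_is_idempotent(self, rng):
        expr = pd.DataFrame(rng.standard_normal((6, 10)))
        eig, _ = module_eigengene(expr, expr.index)
        mean_profile = ((expr.sub(expr.mean(axis=1), axis=0))
                        .div(expr.std(axis=1, ddof=1), axis=0)).mean(axis=0)
        assert np.dot(eig, mean_profile) > 0

    def test_matches_svd_oracle(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 4)),
                            index=["a", "b", "c"])
        eig, ev = module_eigengene(expr, expr.index)
        x = expr.to_numpy()
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        w, v = np.linalg.eigh(xs.T @ xs)
        oracle = v[:, -1]
        if np.dot(oracle, xs.mean(0)) < 0:
            oracle = -oracle
        assert np.allclose(np.abs(eig), np.abs(oracle), atol=1e-10)
        assert ev == pytest.approx(w[-1] / w.sum(), abs=1e-10)

    def test_single_gene_module_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((2, 6)), index=["a", "b"])
        with pytest.raises(ValueError):
            module_eigengene(expr, ["a"])

    def test_noise_genes_never_increase_explained_variance(self, rng):
        f = rng.standard_normal(30)
        core = pd.DataFrame([f + 0.2 * rng.standard_normal(30) for _ in range(6)],
                            index=[f"g{i}" for i in range(6)])
        _, ev_core = module_eigengene(core, core.index)
        noisy = pd.concat([core, pd.DataFrame(
            rng.standard_normal((4, 30)), index=[f"n{i}" for i in range(4)])])
        _, ev_noisy = module_eigengene(noisy, noisy.index)
        assert ev_noisy <= ev_core


def _anova_samples(rng, n1=8, n2=6, shift=1.0, interaction=0.0):
    rows, y = [], []
    for g, n in (("control", n1), ("asthma", n2)):
        for s in range(n):
            subj = f"{g}{s}"
            base = rng.standard_normal()
            for cond in ("NS", "TT"):
                val = base + 0.5 * rng.standard_normal()
                if cond == "TT":
                    val += shift + (interaction if g == "asthma" else 0.0)
                rows.append((f"{subj}_{cond}", subj, g, cond))
                y.append(val)
    meta = pd.DataFrame(rows, columns=["sample", "subject", "group",
                                       "condition"]).set_index("sample")
    return pd.Series(y, index=meta.index), meta


class TestEigengeneAnova:
    def test_zero_variance_eigengene_rejected(self, rng):
        y, meta = _anova_samples(rng)
        with pytest.raises(ValueError, match="variance"):
            eigengene_interaction_test(pd.Series(1.0, index=meta.index), meta)

    def test_detects_stimulation_and_interaction_null_is_calibrated(self, rng):
        p_stim, p_inter = [], []
        for _ in range(100):
            y, meta = _anova_samples(rng, shift=1.0, interaction=0.0)
            res = eigengene_interaction_test(y, meta)
            p_stim.append(res["p_stimulation"])
            p_inter.append(res["p_interaction"])
        assert np.median(p_stim) < 0.01
        from scipy import stats
        assert stats.kstest(p_inter, "uniform").pvalue > 0.01

    def test_stimulation_sum_of_squares_ignores_group_labels(self, rng):
        """The within-subject stimulation stratum is orthogonal to the
        between-subject grouping, so its SS is label-invariant."""
        y, meta = _anova_samples(rng)
        res = eigengene_interaction_test(y, meta)
        flipped = meta.copy()
        subjects = flipped["subject"].unique()
        remap = {s: ("control" if i % 2 else "asthma")
                 for i, s in enumerate(subjects)}
        flipped["group"] = flipped["subject"].map(remap)
        res2 = eigengene_interaction_test(y, flipped)
        assert res["SS_stimulation"] == pytest.approx(res2["SS_stimulation"])

    def test_unpaired_subject_named_in_error(self, rng):
        y, meta = _anova_samples(rng)
        broken = meta.drop(index=meta.index[0])
        with pytest.raises(ValueError, match=meta.iloc[0]["subject"]):
            eigengene_interaction_test(y.loc[broken.index], broken)


class TestModuleNetwork:
    def _eigs(self, rng, n=12):
        meta = pd.DataFrame({
            "subject": [f"s{i // 2}" for i in range(2 * n)],
            "group": ["control"] * n + ["asthma"] * n,
            "condition": ["NS", "TT"] * n,
        }, index=pd.Index([f"x{i}" for i in range(2 * n)], name="sample"))
        e1 = rng.standard_normal(2 * n)
        eigs = pd.DataFrame({"M1": e1, "M2": -e1,
                             "M3": rng.standard_normal(2 * n)}).T
        eigs.columns = meta.index
        return eigs, meta

    def test_exact_anticorrelation_flagged_negative(self, rng):
        eigs, meta = self._eigs(rng)
        net = module_network(eigs, meta, "control")
        row = net[(net.m1 == "M1") & (net.m2 == "M2")].iloc[0]
        assert row.r == pytest.approx(-1.0)
        assert row.sign == "-" and row.significant

    def test_q_values_computed_within_group(self, rng):
        eigs, meta = self._eigs(rng)
        net = module_network(eigs, meta, "asthma")
        assert (net.q >= net.p - 1e-15).all()


class TestModuleCentrality:
    def test_star_graph(self):
        edges = [("hub", f"leaf{i}", 1.0) for i in range(4)]
        genes = ["hub"] + [f"leaf{i}" for i in range(4)]
        cent = module_centrality(genes, edges)
        assert cent.loc["hub", "degree"] == 4
        assert (cent.loc[[f"leaf{i}" for i in range(4)], "degree"] == 1).all()
        assert cent.index[0] == "hub"

    def test_complete_graph_ranks_lexicographically(self):
        genes = ["c", "a", "b"]
        edges = [(x, y, 1.0) for i, x in enumerate(genes)
                 for y in genes[i + 1:]]
        cent = module_centrality(genes, edges)
        assert list(cent.index) == ["a", "b", "c"]

    def test_toy_graph_matches_hand_count(self):
        edges = [("a", "b", 1.0), ("a", "c", 2.0), ("a", "d", 1.0),
                 ("b", "c", 1.0), ("e", "f", 0.5)]
        cent = module_centrality(list("abcdef"), edges)
        assert cent.loc["a", "degree"] == 3
        assert cent.loc["b", "degree"] == 2 and cent.loc["c", "degree"] == 2
        # b vs c tie broken by summed weight (c carries the weight-2 edge)
        assert list(cent.index[:3]) == ["a", "c", "b"]

    def test_empty_subgraph_warns(self):
        with pytest.warns(UserWarning):
            cent = module_centrality(["a", "b"], [("x", "y", 1.0)])
        assert (cent["degree"] == 0).all()
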