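"""Edge mask, inter-hemispheric summaries and NBS permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hemilat.connectivity import (average_interhemispheric,
                                  build_control_mask, group_outcome_models,
                                  homotopic_edge_models, nbs,
                                  _components_from_edges, _edge_t_stats)
from hemilat.core_data import ConnectivityMatrix
from hemilat.simulate import GeneratorConfig, simulate_connectivity


def make_matrix(atlas, w, subject_id="s", modality="functional"):
    w = np.asarray(w, dtype=float)
    return ConnectivityMatrix(subject_id, modality, atlas.node_labels, w)


def symmetric(rng, n):
    w = rng.random((n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return w


# --- brute-force oracles ----------------------------------------------------

def union_find_components(edges, n_nodes):
    """Independent component oracle: plain union-find over an edge list."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comps = {}
    for i, j in edges:
        comps.setdefault(find(i), []).append((i, j))
    return sorted((sorted(v) for v in comps.values()), key=len, reverse=True)


class TestControlMask:
    def test_toy_fraction_keeps_single_max_edge(self, toy_atlas, rng):
        # 3+3 nodes -> 9 inter-hemispheric edges; ceil(0.9) = 1 retained
        mats = [make_matrix(toy_atlas, symmetric(rng, 6), f"c{i}")
                for i in range(4)]
        mask = build_control_mask(mats, toy_atlas, fraction=0.10)
        assert len(mask) == 1
        # brute-force: the retained edge has the maximal mean weight
        edges = toy_atlas.interhemispheric_edges()
        means = {e: np.mean([m.weights[e] for m in mats]) for e in edges}
        assert mask.retained_edges[0] == max(means, key=means.get)

    def test_fraction_one_keeps_all_interhemispheric(self, toy_atlas, rng):
        mats = [make_matrix(toy_atlas, symmetric(rng, 6))]
        mask = build_control_mask(mats, toy_atlas, fraction=1.0)
        assert set(mask.retained_edges) == set(
            toy_atlas.interhemispheric_edges())

    def test_tie_break_is_lexicographic(self, toy_atlas):
        w = np.ones((6, 6))
        np.fill_diagonal(w, 0)
        mask = build_control_mask([make_matrix(toy_atlas, w)], toy_atlas,
                                  fraction=0.10)
        assert mask.retained_edges == ((0, 3),)

    def test_mask_invariant_to_control_order(self, toy_atlas, rng):
        mats = [make_matrix(toy_atlas, symmetric(rng, 6), f"c{i}")
                for i in range(5)]
        a = build_control_mask(mats, toy_atlas, 0.3)
        b = build_control_mask(mats[::-1], toy_atlas, 0.3)
        assert a.retained_edges == b.retained_edges

    def test_retention_count_is_ceiling(self, atlas, rng):
        mats = [make_matrix(atlas, symmetric(rng, 84))]
        mask = build_control_mask(mats, atlas, 0.10)
        assert len(mask) == int(np.ceil(0.10 * 42 * 42))


class TestAverageInterhemispheric:
    def test_hand_computed_mean(self, toy_atlas, rng):
        mats = [make_matrix(toy_atlas, symmetric(rng, 6))]
        mask = build_control_mask(mats, toy_atlas, fraction=0.6)
        m = make_matrix(toy_atlas, symmetric(rng, 6))
        expected = np.mean([m.weights[e] for e in mask.retained_edges])
        assert average_interhemispheric(m, mask) == pytest.approx(
            expected, abs=1e-12)

    def test_constant_edges(self, toy_atlas):
        w = np.full((6, 6), 0.3)
        np.fill_diagonal(w, 0)
        mats = [make_matrix(toy_atlas, w)]
        mask = build_control_mask(mats, toy_atlas, 1.0)
        assert average_interhemispheric(mats[0], mask) == pytest.approx(0.3)

    def test_nonfinite_masked_weight_rejected(self, toy_atlas):
        w = np.full((6, 6), 0.3)
        np.fill_diagonal(w, 0)
        mask = build_control_mask([make_matrix(toy_atlas, w)], toy_atlas, 1.0)
        w2 = w.copy()
        w2[0, 3] = w2[3, 0] = np.nan
        from hemilat.core_data import IntegrityError
        with pytest.raises(IntegrityError):
            average_interhemispheric(make_matrix(toy_atlas, w2), mask)


class TestComponentExtraction:
    def test_worked_example_two_components(self):
        edges = np.array([(1, 2), (2, 3), (5, 6)])
        labels, sizes = _components_from_edges(
            edges, np.ones(3, dtype=bool), 8)
        comps = {}
        for lab, e in zip(labels, edges):
            comps.setdefault(lab, []).append(tuple(e))
        comp_sets = sorted((sorted(v) for v in comps.values()), key=len,
                           reverse=True)
        assert comp_sets == [[(1, 2), (2, 3)], [(5, 6)]]
        assert sorted(sizes[sizes > 0].tolist(), reverse=True) == [2, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_find_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n_nodes = 84
        all_edges = np.array([(i, j) for i in range(n_nodes)
                              for j in range(i + 1, n_nodes)])
        keep = rng.random(len(all_edges)) < 0.02
        edges = all_edges[keep]
        labels, sizes = _components_from_edges(
            edges, np.ones(len(edges), dtype=bool), n_nodes)
        comps = {}
        for lab, e in zip(labels, edges):
            comps.setdefault(lab, []).append(tuple(e))
        got = sorted((sorted(v) for v in comps.values()), key=len,
                     reverse=True)
        expected = union_find_components([tuple(e) for e in edges], n_nodes)
        assert sorted(map(tuple, got)) == sorted(map(tuple, expected))


class TestNBS:
    def _cov(self, n, rng):
        return pd.DataFrame({
            "age_years": rng.normal(73, 7, n),
            "sex": rng.choice(["female", "male"], n),
            "tau_load": rng.normal(1.8, 0.3, n),
        })

    def test_identical_groups_high_threshold_no_components(self, toy_atlas):
        rng = np.random.default_rng(3)
        w = symmetric(rng, 6)
        mats = [make_matrix(toy_atlas, w, f"s{i}") for i in range(8)]
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        res = nbs(mats, groups, self._cov(8, rng), toy_atlas,
                  edge_threshold=3.5, n_permutations=100, seed=0)
        assert res.components == []

    def test_permutation_p_matches_exhaustive_enumeration(self, toy_atlas):
        """On 8 subjects the label-permutation null can be enumerated:
        C(8,4) = 70 assignments. The Monte-Carlo p must agree."""
        rng = np.random.default_rng(11)
        n = 8
        mats = []
        for i in range(n):
            w = symmetric(rng, 6)
            if i < 4:  # group "b" (target) gets a shifted path 0-3, 3-1, 1-4
                for e in [(0, 3), (1, 3), (1, 4)]:
                    w[e] += 0.8
                    w[e[::-1]] = w[e]
            mats.append(make_matrix(toy_atlas, w, f"s{i}"))
        groups = pd.Series(["b"] * 4 + ["a"] * 4)
        cov = pd.DataFrame({"const_dummy": np.zeros(n)})
        threshold = 2.0
        res = nbs(mats, groups, cov, toy_atlas, edge_threshold=threshold,
                  n_permutations=4000, seed=5, covariate_columns=())
        assert res.components, "planted path should be supra-threshold"
        observed = max(c.size for c in res.components)
        p_perm = min(c.p_fwe for c in res.components if c.size == observed)

        # exhaustive oracle: all 70 assignments of 4 subjects to "target"
        edges = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        Y = np.stack([[m.weights[e] for e in edges] for m in mats])
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), 4):
            g = np.zeros(n)
            g[list(combo)] = 1.0
            X = np.column_stack([np.ones(n), g])
            t = _edge_t_stats(Y, X, 1)
            mx = 0
            for supra in (t > threshold, -t > threshold):
                comps = union_find_components(
                    [e for e, s in zip(edges, supra) if s], 6)
                if comps:
                    mx = max(mx, len(comps[0]))
            count += mx >= observed
            total += 1
        p_exact = count / total
        assert p_perm == pytest.approx(p_exact, abs=0.02)

    def test_planted_component_detected_unmasked(self, atlas):
        planted = [(0, 42), (42, 1), (1, 43), (43, 2), (2, 44), (44, 3),
                   (3, 45), (45, 4)]
        # independent edge noise (no global subject offset): the planted
        # effect equals 1 edge-noise SD
        cfg = GeneratorConfig(
            seed=21, n_controls=2, w_subject_sd=0.0,
            connectivity_group_sizes={"LA": 40, "S": 40, "RA": 0},
            planted_component=(planted, 0.12, "LA"))
        _, patients, info = simulate_connectivity(cfg, atlas)
        res = nbs(patients, info["asymmetry_group"], info, atlas,
                  edge_threshold=2.5, n_permutations=300, seed=2)
        best = res.components[0]
        assert best.direction == "LA>S"
        planted_norm = {tuple(sorted(e)) for e in planted}
        overlap = len({tuple(sorted(e)) for e in best.edges} & planted_norm)
        assert overlap >= len(planted) // 2
        # the planted component dominates the run
        assert best.p_fwe == min(c.p_fwe for c in res.components)

    def test_parameter_validation(self, toy_atlas, rng):
        mats = [make_matrix(toy_atlas, symmetric(rng, 6), f"s{i}")
                for i in range(8)]
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        cov = self._cov(8, rng)
        with pytest.raises(ValueError):
            nbs(mats, groups, cov, toy_atlas, edge_threshold=-1.0)
        with pytest.raises(ValueError):
            nbs(mats, groups, cov, toy_atlas, n_permutations=0)
        with pytest.warns(UserWarning):
            nbs(mats, groups, cov, toy_atlas, edge_threshold=3.5,
                n_permutations=50, seed=0)

    def test_p_fwe_bounds_and_monotonicity(self, atlas):
        cfg = GeneratorConfig(
            seed=31, n_controls=2,
            connectivity_group_sizes={"LA": 20, "S": 20, "RA": 0})
        _, patients, info = simulate_connectivity(cfg, atlas)
        res = nbs(patients, info["asymmetry_group"], info, atlas,
                  edge_threshold=2.0, n_permutations=200, seed=3)
        P = res.n_permutations
        sizes = [c.size for c in res.components]
        ps = [c.p_fwe for c in res.components]
        for p in ps:
            assert 1 / (P + 1) <= p <= 1
        # components are sorted by size; p_fwe non-increasing in size
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            if s1 > s2:
                assert p1 <= p2


class TestHomotopicEdgeModels:
    def test_model_count_follows_mask(self, toy_atlas, rng):
        n = 40
        mats = [make_matrix(toy_atlas, symmetric(rng, 6), f"s{i}")
                for i in range(n)]
        cov = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age_years": rng.normal(70, 5, n),
            "sex": rng.choice(["female", "male"], n),
            "tau_load": rng.normal(1.8, 0.3, n),
            "abs_tau_li": np.abs(rng.normal(0, 7, n)),
        })
        out = homotopic_edge_models(mats, toy_atlas, cov, mask=None)
        assert len(out) == 3  # all homotopic pairs
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_null_type_one_error_calibrated(self, toy_atlas):
        """Under no LI effect the raw p-values are ~uniform: pooled
        rejection rate at 0.05 stays within binomial error."""
        rng = np.random.default_rng(99)
        hits, total = 0, 0
        for _ in range(30):
            n = 50
            mats = [make_matrix(toy_atlas, symmetric(rng, 6), f"s{i}")
                    for i in range(n)]
            cov = pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(n)],
                "age_years": rng.normal(70, 5, n),
                "sex": rng.choice(["female", "male"], n),
                "tau_load": rng.normal(1.8, 0.3, n),
                "abs_tau_li": np.abs(rng.normal(0, 7, n)),
            })
            out = homotopic_edge_models(mats, toy_atlas, cov)
            hits += int((out["p"] < 0.05).sum())
            total += len(out)
        rate = hits / total
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)


class TestGroupOutcomeModels:
    def _data(self, rng, n_per=50, la_shift=0.0):
        rows = []
        for grp in ("LA", "S", "RA"):
            for i in range(n_per):
                shift = la_shift if grp == "LA" else 0.0
                rows.append({
                    "asymmetry_group": grp,
                    "avg_fc": rng.normal(0.4 + shift, 0.1),
                    "age_years": rng.normal(73, 7),
                    "sex": rng.choice(["female", "male"]),
                    "tau_load": rng.normal(1.8, 0.3),
                })
        return pd.DataFrame(rows)

    def test_three_pairwise_contrasts_with_bonferroni(self, rng):
        out = group_outcome_models(self._data(rng), outcome="avg_fc")
        assert set(out) == {("LA", "S"), ("RA", "S"), ("LA", "RA")}
        for res in out.values():
            assert res.p_adj == pytest.approx(min(1.0, 3 * res.p))

    def test_planted_la_deficit_detected(self):
        rng = np.random.default_rng(123)
        out = group_outcome_models(self._data(rng, n_per=60, la_shift=-0.1),
                                   outcome="avg_fc")
        res = out[("LA", "S")]
        assert res.beta_std < 0
        assert res.p_adj < 0.05

    def test_empty_group_skipped_with_warning(self, rng):
        data = self._data(rng)
        data = data[data["asymmetry_group"] != "RA"]
        with pytest.warns(UserWarning):
            out = group_outcome_models(data, outcome="avg_fc")
        assert out[("RA", "S")] is None
        assert out[("LA", "S")] is not None
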