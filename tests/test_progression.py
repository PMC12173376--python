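"""Stage-wise DE orchestration, onset proportions and network centrality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from proteosig.annotation_io import ExpressionStudy, InteractionNetwork
from proteosig.progression import (StageResult, centrality,
                                   stage_centrality_summary, stage_proportions,
                                   stagewise_de)
from proteosig.synthetic import SyntheticSpec, make_hub_network


# ---------------------------------------------------------------------------
# staged DE
# ---------------------------------------------------------------------------

def staged_toy_study():
    """3 genes x (control + 2 stages), effects large enough to be certain.

    g_late moves only at stage 2; g_never never moves; g_early at both stages.
    """
    rng = np.random.default_rng(5)
    n = 6
    conds = ["CONTROL", "S1", "S2"]
    shift = {"G_EARLY": {"S1": 5.0, "S2": 5.0},
             "G_LATE": {"S1": 0.0, "S2": 5.0},
             "G_NEVER": {"S1": 0.0, "S2": 0.0}}
    # background genes keep the variance-prior estimation well-posed
    genes = list(shift) + [f"BG{i}" for i in range(30)]
    cols, cond_map = {}, {}
    for c in conds:
        for r in range(n):
            name = f"{c}_{r}"
            vals = []
            for g in genes:
                base = 8.0 + rng.normal(0, 0.3)
                vals.append(base + shift.get(g, {}).get(c, 0.0))
            cols[name] = np.array(vals)
            cond_map[name] = c
    mat = pd.DataFrame(cols, index=genes)
    return ExpressionStudy(mat, cond_map)


class TestStagewise:
    def test_onset_calls(self):
        res = stagewise_de(staged_toy_study(), ["S1", "S2"], "CONTROL")
        assert res.onset["G_EARLY"] == "S1"
        assert res.onset["G_LATE"] == "S2"   # significant only at last stage
        assert res.onset["G_NEVER"] is None  # never significant

    def test_missing_stage_named(self):
        with pytest.raises(ValueError, match="S9"):
            stagewise_de(staged_toy_study(), ["S1", "S9"], "CONTROL")


class TestStageProportions:
    def _result(self, onsets):
        return StageResult(stages=["S1", "S2", "S3"], tables={},
                           onset=dict(onsets))

    def test_all_first_stage(self):
        res = self._result({f"g{i}": "S1" for i in range(4)})
        assert list(stage_proportions(res, {f"g{i}" for i in range(4)})) == [1, 0, 0]

    def test_uniform_onsets(self):
        onsets = {f"g{i}": f"S{i % 3 + 1}" for i in range(9)}
        res = self._result(onsets)
        props = stage_proportions(res, set(onsets))
        assert list(props) == pytest.approx([1 / 3] * 3)

    def test_sums_to_one_when_any_affected(self):
        onsets = {"a": "S1", "b": "S3", "c": None, "d": "S3"}
        props = stage_proportions(self._result(onsets), {"a", "b", "c", "d"})
        assert props.sum() == pytest.approx(1.0)

    def test_no_affected_genes_reported_missing(self):
        props = stage_proportions(self._result({"a": None}), {"a"})
        assert props.isna().all()

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            stage_proportions(self._result({}), set())


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------

def betweenness_oracle(nodes, edges):
    """Exhaustive shortest-path enumeration (feasible for <= 7 nodes)."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_paths(s, t):
        # enumerate all simple paths, keep the shortest ones
        out, best = [], None
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if best is not None and len(path) > best:
                continue
            if v == t:
                if best is None or len(path) < best:
                    best, out = len(path), [path]
                elif len(path) == best:
                    out.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return out

    btw = {n: 0.0 for n in nodes}
    total_internal = 0.0
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        total_internal += len(paths[0]) - 2
        for p in paths:
            for v in p[1:-1]:
                btw[v] += 1.0 / len(paths)
    return btw, total_internal


class TestCentrality:
    def test_path_graph_closed_form(self):
        net = InteractionNetwork({"A", "B", "C"}, {("A", "B"), ("B", "C")})
        c = centrality(net)
        assert c.loc["B", "betweenness"] == 1.0
        assert c.loc["A", "betweenness"] == 0.0

    def test_star_center_closed_form(self):
        net = InteractionNetwork({"C", "L1", "L2", "L3"},
                                 {("C", "L1"), ("C", "L2"), ("C", "L3")})
        c = centrality(net)
        assert c.loc["C", "degree"] == 3
        assert c.loc["C", "betweenness"] == 3.0  # all leaf pairs via center

    def test_four_cycle_split_credit(self):
        nodes = ["A", "B", "C", "D"]
        edges = {("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")}
        c = centrality(InteractionNetwork(set(nodes), edges))
        assert c["betweenness"].to_numpy() == pytest.approx([0.5] * 4)

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(1234)
        for trial in range(100):
            n = int(rng.integers(2, 8))
            nodes = [f"N{i}" for i in range(n)]
            edges = {(a, b) for a, b in itertools.combinations(nodes, 2)
                     if rng.random() < 0.4}
            net = InteractionNetwork(set(nodes), set(edges))
            c = centrality(net)
            oracle, total = betweenness_oracle(nodes, edges)
            deg = {x: 0 for x in nodes}
            for a, b in net.edges:
                deg[a] += 1
                deg[b] += 1
            for v in nodes:
                assert c.loc[v, "degree"] == deg[v]
                assert abs(c.loc[v, "betweenness"] - oracle[v]) < 1e-9
            # conservation: total betweenness = total internal-vertex credit
            assert c["betweenness"].sum() == pytest.approx(total, abs=1e-9)


class TestStageCentralitySummary:
    def test_single_node_per_stage_median(self):
        net = InteractionNetwork({"A", "B"}, {("A", "B")},
                                 stage_of={"A": "EARLY", "B": "LATE"})
        quart, _ = stage_centrality_summary(net)
        row = quart[(quart.stage == "EARLY") & (quart.metric == "degree")]
        assert row["median"].iloc[0] == 1.0

    def test_identical_groups_rank_sum_near_one(self):
        nodes = [f"N{i}" for i in range(8)]
        edges = {(nodes[i], nodes[i + 1]) for i in range(7)}
        # two stages with mirror-symmetric positions -> identical value sets
        stage_of = {nodes[i]: ("X" if i < 4 else "Y") for i in range(8)}
        net = InteractionNetwork(set(nodes), edges, stage_of=stage_of)
        _, tests = stage_centrality_summary(net)
        assert (tests["p"] > 0.9).all()

    def test_planted_hub_stage_most_central(self):
        """Hub-weighted attachment (seed 19) makes mid-stage nodes dominant."""
        spec = SyntheticSpec(seed=19)
        stages = {f"N{i:03d}": ("EARLY" if i < 40 else "MID" if i < 80 else "LATE")
                  for i in range(120)}
        net = make_hub_network(spec, stages)
        quart, _ = stage_centrality_summary(net)
        med = {(r.stage, r.metric): r.median for r in quart.itertuples()}
        assert med[("MID", "degree")] > med[("EARLY", "degree")]
        assert med[("MID", "degree")] > med[("LATE", "degree")]
        assert med[("MID", "betweenness")] > med[("EARLY", "betweenness")]

    def test_unstaged_network_rejected(self):
        net = InteractionNetwork({"A"}, set())
        with pytest.raises(ValueError):
            stage_centrality_summary(net)
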