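"""Node-level Tatami aggregation, selection and grid clustering."""

import numpy as np
import pandas as pd
import pytest

from tatamisom import (
    TatamiMap,
    classify_genes,
    condition_specific_genes,
    extract_node_clusters,
    node_mean_map,
    node_secretion_map,
    percentile_of_threshold,
    select_high_nodes,
)
from tatamisom.io import load_aa_gene_panel


def flood_fill_oracle(nodes, n_rows, n_cols, adjacency="8"):
    """Brute-force BFS connected components on the grid."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if adjacency == "8":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    todo = set(nodes)
    comps = []
    while todo:
        frontier = [todo.pop()]
        comp = set(frontier)
        while frontier:
            n = frontier.pop()
            r, c = (n - 1) // n_cols, (n - 1) % n_cols
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    m = rr * n_cols + cc + 1
                    if m in todo:
                        todo.remove(m)
                        comp.add(m)
                        frontier.append(m)
        comps.append(comp)
    return comps


class TestNodeMeanMap:
    def test_simple_mean(self, small_meta):
        expr = pd.DataFrame({"d_r1": [10.0, 14.0], "d_r2": [10.0, 14.0],
                             "c_r1": [0.0, 0.0], "c_r2": [0.0, 0.0]}, index=["g1", "g2"])
        assign = pd.Series([1, 1], index=["g1", "g2"])
        tmap = node_mean_map(expr, small_meta, "D4", assign, n_units=4)
        assert tmap.values[1] == 12.0
        assert tmap.values[2:].isna().all()

    def test_aa_panel_node418_day10_mean(self):
        """Mean of the four node-418 auxiliary-activity genes at Day 10."""
        t3 = load_aa_gene_panel()
        genes = t3.index[t3["node_id"] == 418]
        assert len(genes) == 4
        meta = pd.DataFrame(
            {"sample_id": ["d10"], "condition": ["D10"], "replicate": [1]}
        )
        expr = t3.loc[genes, ["day10"]].rename(columns={"day10": "d10"})
        assign = pd.Series(418, index=genes)
        tmap = node_mean_map(expr, meta, "D10", assign, n_units=437)
        assert tmap.values[418] == pytest.approx(17.3525)

    def test_unknown_condition_errors(self, small_meta):
        expr = pd.DataFrame({"d_r1": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="absent"):
            node_mean_map(expr, small_meta, "D99", pd.Series([1], index=["g"]), 4)

    def test_assignment_exceeding_grid_errors(self, small_meta):
        expr = pd.DataFrame({c: [1.0] for c in small_meta["sample_id"]}, index=["g"])
        with pytest.raises(ValueError, match="grid"):
            node_mean_map(expr, small_meta, "D4", pd.Series([9], index=["g"]), 4)

    def test_conservation_weighted_node_mean_equals_global_mean(self, result, synthetic):
        counts, meta, _, _ = synthetic
        for cond in meta["condition"].unique():
            tmap = result.trans_maps[cond]
            weights = result.assignment.value_counts().reindex(tmap.nodes).fillna(0)
            pooled = (tmap.values * weights).sum() / weights.sum()
            samples = meta.loc[meta["condition"] == cond, "sample_id"]
            assert pooled == pytest.approx(
                result.expr[list(samples)].to_numpy().mean(), abs=1e-9
            )

    def test_pooled_mean_equals_mean_of_gene_means(self, small_meta, rng):
        # equal replicate count per gene makes the two aggregations identical
        expr = pd.DataFrame(
            rng.normal(10, 2, size=(6, 4)), columns=small_meta["sample_id"],
            index=[f"g{i}" for i in range(6)],
        )
        assign = pd.Series([1, 1, 1, 2, 2, 2], index=expr.index)
        tmap = node_mean_map(expr, small_meta, "control", assign, 4)
        gene_means = expr[["c_r1", "c_r2"]].mean(axis=1)
        assert tmap.values[1] == pytest.approx(gene_means[:3].mean())
        assert tmap.values[2] == pytest.approx(gene_means[3:].mean())


class TestNodeSecretionMap:
    def test_no_detection_gives_all_zero(self):
        assign = pd.Series([1, 2], index=["p1", "p2"])
        tmap = node_secretion_map({"p1": {"D10"}}, "D15", assign, 4)
        assert (tmap.values == 0).all()
        assert tmap.kind == "secretion"

    def test_counts_sum_to_matched_detections(self, result, synthetic):
        _, _, secretome, _ = synthetic
        for tp, tmap in result.sec_maps.items():
            matched = sum(
                1
                for pid, tps in secretome.items()
                if tp in tps and pid in result.assignment.index
            )
            assert int(tmap.values.sum()) == matched

    def test_multi_timepoint_protein_counts_once_per_map(self):
        assign = pd.Series([3], index=["p"])
        sec = {"p": {"D4", "D15"}}
        for tp, expected in [("D4", 1), ("D10", 0), ("D15", 1)]:
            assert node_secretion_map(sec, tp, assign, 4).values[3] == expected

    def test_unmatched_ids_logged_not_fatal(self, caplog):
        assign = pd.Series([1], index=["known"])
        with caplog.at_level("WARNING"):
            tmap = node_secretion_map({"ghost": {"D4"}}, "D4", assign, 4)
        assert tmap.values.sum() == 0
        assert "ghost" in caplog.text


class TestHighNodeSelection:
    def test_strict_inequality(self):
        tmap = TatamiMap(pd.Series({1: 13.5, 2: 11.9, 3: 12.0}), "transcription")
        assert select_high_nodes(tmap, 12.0) == {1}

    def test_all_below_threshold(self):
        tmap = TatamiMap(pd.Series({1: 1.0, 2: 2.0}), "transcription")
        assert select_high_nodes(tmap, 12.0) == set()

    def test_nan_nodes_never_selected(self):
        tmap = TatamiMap(pd.Series({1: np.nan, 2: 13.0}), "transcription")
        assert select_high_nodes(tmap) == {2}

    def test_secretion_map_rejected(self):
        tmap = TatamiMap(pd.Series({1: 5}), "secretion")
        with pytest.raises(ValueError, match="transcription"):
            select_high_nodes(tmap)

    def test_threshold_monotonicity(self, result):
        for tmap in result.trans_maps.values():
            prev = select_high_nodes(tmap, 10.0)
            for thr in (11.0, 12.0, 13.0, 14.0):
                cur = select_high_nodes(tmap, thr)
                assert cur <= prev
                prev = cur

    def test_single_gene_node_high_at_d4_not_d15(self):
        """A node holding only gene 1359988 passes the threshold at Day 4
        (17.36) but not at Day 15 (7.41)."""
        t3 = load_aa_gene_panel()
        row = t3.loc["1359988"]
        for col, cond in [("day4", "D4"), ("day15", "D15")]:
            meta = pd.DataFrame({"sample_id": ["s"], "condition": [cond], "replicate": [1]})
            expr = pd.DataFrame({"s": [row[col]]}, index=["1359988"])
            tmap = node_mean_map(expr, meta, cond, pd.Series([400], index=["1359988"]), 437)
            selected = select_high_nodes(tmap, 12.0)
            assert (400 in selected) == (cond == "D4")


def _maps_from_values(values_by_cond):
    return {
        c: TatamiMap(pd.Series(v), "transcription") for c, v in values_by_cond.items()
    }


class TestConditionSpecificGenes:
    def setup_method(self):
        # node 1: core-like; node 2: control-high; node 3: flat
        self.maps = _maps_from_values(
            {
                "control": {1: 7.0, 2: 14.0, 3: 8.0},
                "D4": {1: 14.0, 2: 14.0, 3: 8.0},
                "D10": {1: 14.0, 2: 14.0, 3: 8.0},
                "D15": {1: 13.0, 2: 14.0, 3: 8.0},
            }
        )
        self.assign = pd.Series([1, 1, 2, 3], index=["a", "b", "c", "d"])

    def test_core_definition(self):
        sets = condition_specific_genes(self.maps, self.assign, 12.0)
        assert sets.core == {"a", "b"}

    def test_control_high_node_excluded(self):
        sets = condition_specific_genes(self.maps, self.assign, 12.0)
        for s in sets.per_condition.values():
            assert "c" not in s

    def test_missing_control_errors(self):
        maps = {k: v for k, v in self.maps.items() if k != "control"}
        with pytest.raises(ValueError, match="control"):
            condition_specific_genes(maps, self.assign, 12.0)

    def test_node_at_threshold_in_neither_set(self):
        maps = _maps_from_values(
            {"control": {1: 12.0}, "D4": {1: 12.0}}
        )
        sets = condition_specific_genes(maps, pd.Series([1], index=["g"]), 12.0)
        assert sets.per_condition["D4"] == set()

    def test_classify_genes_patterns(self):
        labels = classify_genes(self.maps, self.assign, 12.0)
        assert labels["a"] == "D4+D10+D15"
        assert labels["c"] == "control-high"
        assert labels["d"] == "none"


class TestPercentile:
    def test_above_maximum_is_100(self, small_meta):
        expr = pd.DataFrame(
            np.ones((3, 4)), columns=small_meta["sample_id"], index=list("abc")
        )
        assert percentile_of_threshold(expr, small_meta, 99.0) == 100.0

    def test_median_is_50(self, small_meta):
        expr = pd.DataFrame(
            {"c_r1": [1.0, 2.0, 3.0], "c_r2": [1.0, 2.0, 3.0],
             "d_r1": [1.0, 2.0, 3.0], "d_r2": [1.0, 2.0, 3.0]},
            index=list("abc"),
        )
        assert percentile_of_threshold(expr, small_meta, 2.0) == 50.0

    def test_calibrated_quarter_above_gives_75(self, small_meta, rng):
        # 25% of gene-condition means sit above 12 by construction
        n = 1000
        high = rng.uniform(13, 18, size=n // 2)
        low = rng.uniform(5, 11, size=3 * n // 2)
        means = np.concatenate([high, low])
        rng.shuffle(means)
        vals = means.reshape(n, 2)
        expr = pd.DataFrame(
            np.repeat(vals, 2, axis=1), columns=small_meta["sample_id"],
            index=[f"g{i}" for i in range(n)],
        )
        assert percentile_of_threshold(expr, small_meta, 12.0) == pytest.approx(75, abs=2)


class TestNodeClusters:
    def test_consecutive_row_nodes_form_one_cluster(self):
        # on the 19 x 23 grid nodes 416..420 sit in one row, laterally adjacent
        clusters = extract_node_clusters({416, 417, 418, 419, 420}, 19, 23, "8")
        assert clusters == [{416, 417, 418, 419, 420}]

    def test_isolated_corners_are_singletons(self):
        clusters = extract_node_clusters({1, 437}, 19, 23, "8")
        assert clusters == [{1}, {437}]

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(50):
            nodes = set(rng.choice(np.arange(1, 438), size=60, replace=False).tolist())
            for adjacency in ("4", "8"):
                got = extract_node_clusters(nodes, 19, 23, adjacency)
                expected = flood_fill_oracle(nodes, 19, 23, adjacency)
                assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_four_vs_eight_connectivity(self):
        # diagonal pair: connected under 8, separate under 4
        nodes = {1, 25}  # (0,0) and (1,1) on the 19x23 grid
        assert len(extract_node_clusters(nodes, 19, 23, "8")) == 1
        assert len(extract_node_clusters(nodes, 19, 23, "4")) == 2

    def test_unknown_node_errors(self):
        with pytest.raises(ValueError, match="node IDs"):
            extract_node_clusters({0}, 19, 23, "8")

    def test_sorted_by_size_then_lowest_id(self):
        clusters = extract_node_clusters({1, 2, 3, 100, 200}, 19, 23, "8")
        assert clusters[0] == {1, 2, 3}
        assert clusters[1] == {100}
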