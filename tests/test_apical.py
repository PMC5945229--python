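"""Apical adjacency, neighbor selection (BFS oracle), ratio metrics,
sister-pair filtering and the control-median split."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import ntquant as nq
from ntquant.apical import NeighborSelectionError, NeighborSet


def brute_force_adjacency(label: np.ndarray, min_shared: int = 3) -> set:
    """Pixel-pair scan oracle: count 4-neighbor pairs straddling each border."""
    counts = {}
    h, w = label.shape
    for y in range(h):
        for x in range(w):
            for dy, dx in ((0, 1), (1, 0)):
                ny, nx_ = y + dy, x + dx
                if ny >= h or nx_ >= w:
                    continue
                a, b = int(label[y, x]), int(label[ny, nx_])
                if a > 0 and b > 0 and a != b:
                    key = (min(a, b), max(a, b))
                    counts[key] = counts.get(key, 0) + 1
    return {k for k, c in counts.items() if c >= min_shared}


class TestBuildAdjacency:
    def test_shared_border_gives_edge(self):
        label = np.zeros((10, 10), dtype=np.int32)
        label[:, :5] = 1
        label[:, 5:] = 2
        g = nq.build_adjacency(label)
        assert g.has_edge(1, 2)
        assert g.edges[1, 2]["shared"] == 10

    def test_diagonal_touch_is_not_an_edge(self):
        label = np.zeros((4, 4), dtype=np.int32)
        label[0:2, 0:2] = 1
        label[2:4, 2:4] = 2
        g = nq.build_adjacency(label, min_shared=3)
        assert not g.has_edge(1, 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pixel_scan_oracle(self, seed):
        params = nq.MosaicSimParams(shape=(80, 80), n_cells=50, seed=seed)
        label, _j, _gt = nq.generate_apical_mosaic(params)
        g = nq.build_adjacency(label)
        assert set(map(tuple, map(sorted, g.edges))) == brute_force_adjacency(label)


def bfs_ring(graph: nx.Graph, source: int, ring: int) -> set:
    """Breadth-first-search oracle for cells at exact adjacency distance."""
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier and d < ring:
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = d + 1
                    nxt.append(v)
        frontier = nxt
        d += 1
    return {v for v, dd in dist.items() if dd == ring}


def hex_lattice_cells(rows=7, cols=7):
    """A synthetic hexagonal lattice: graph + centroid/area/flag table."""
    g = nx.Graph()
    pos = {}
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c + 1
            pos[i] = (r * 0.87, c + (0.5 if r % 2 else 0.0))
            g.add_node(i)
    for i, (yi, xi) in pos.items():
        for j, (yj, xj) in pos.items():
            if i < j and np.hypot(yi - yj, xi - xj) < 1.1:
                g.add_edge(i, j)
    cells = pd.DataFrame({
        "cell_id": list(pos),
        "centroid_y": [p[0] for p in pos.values()],
        "centroid_x": [p[1] for p in pos.values()],
        "area_px": 100,
        "transfected": False,
    })
    return g, cells


class TestSelectNeighbors:
    def test_isolated_focal_gets_four_ring2_cells(self):
        g, cells = hex_lattice_cells()
        focal = 25  # lattice center
        cells.loc[cells["cell_id"] == focal, "transfected"] = True
        ns = nq.select_neighbors(focal, g, cells)
        assert ns.rings == (2, 2, 2, 2)
        assert set(ns.neighbor_ids) <= bfs_ring(g, focal, 2)

    def test_equidistant_ties_broken_by_id(self):
        g = nx.Graph([(10, 2), (10, 3), (2, 5), (3, 6), (2, 7), (3, 8), (2, 9)])
        cells = pd.DataFrame({
            "cell_id": [10, 2, 3, 5, 6, 7, 8, 9],
            "centroid_y": 0.0,
            "centroid_x": [0, 1, -1, 2, 2, 2, 2, 2],  # ring-2 all equidistant
            "area_px": 10,
            "transfected": [True] + [False] * 7,
        })
        ns = nq.select_neighbors(10, g, cells)
        assert ns.neighbor_ids == (5, 6, 7, 8)

    def test_ring1_fallback_recorded(self):
        # focal with 3 ring-2 candidates and ring-1 cells to complete
        g = nx.Graph([(1, 2), (1, 3), (2, 4), (2, 5), (3, 6)])
        cells = pd.DataFrame({
            "cell_id": [1, 2, 3, 4, 5, 6],
            "centroid_y": 0.0,
            "centroid_x": [0.0, 1, -1, 2, 2.5, -2],
            "area_px": 10,
            "transfected": [True] + [False] * 5,
        })
        ns = nq.select_neighbors(1, g, cells)
        assert sorted(ns.rings) == [1, 2, 2, 2]

    def test_too_few_candidates_fails(self):
        g = nx.Graph([(1, 2), (2, 3)])
        cells = pd.DataFrame({
            "cell_id": [1, 2, 3], "centroid_y": 0.0, "centroid_x": [0, 1, 2],
            "area_px": 10, "transfected": [True, False, False]})
        with pytest.raises(NeighborSelectionError, match="eligible"):
            nq.select_neighbors(1, g, cells)

    @pytest.mark.parametrize("seed", range(20))
    def test_ring_membership_matches_bfs_oracle(self, seed):
        params = nq.MosaicSimParams(shape=(120, 120), n_cells=50,
                                    transfected_fraction=0.1, seed=seed)
        label, _j, gt = nq.generate_apical_mosaic(params)
        cells = nq.measure_apical_cells(label, flags=gt[["cell_id", "transfected"]])
        g = nq.build_adjacency(label)
        for cid in gt.loc[gt["transfected"], "cell_id"]:
            try:
                ns = nq.select_neighbors(int(cid), g, cells)
            except NeighborSelectionError:
                ring12 = bfs_ring(g, int(cid), 1) | bfs_ring(g, int(cid), 2)
                eligible = [c for c in ring12
                            if not gt.loc[gt["cell_id"] == c, "transfected"].iloc[0]]
                assert len(eligible) < 4
                continue
            for nb, ring in zip(ns.neighbor_ids, ns.rings):
                assert nb in bfs_ring(g, int(cid), ring)
                assert not gt.loc[gt["cell_id"] == nb, "transfected"].iloc[0]
            assert len(set(ns.neighbor_ids)) == 4


class TestRatios:
    def _cells(self, areas, junctions):
        return pd.DataFrame({
            "cell_id": np.arange(1, len(areas) + 1),
            "area_px": areas,
            "junction_mean": junctions,
            "centroid_y": 0.0, "centroid_x": 0.0, "transfected": False,
        })

    def test_area_ratio(self):
        ns = NeighborSet(1, (2, 3, 4, 5), (2, 2, 2, 2))
        cells = self._cells([4, 4, 4, 4, 4], [0] * 5)
        assert nq.apical_area_ratio(1, ns, cells) == pytest.approx(1.0)
        cells = self._cells([2, 4, 4, 4, 4], [0] * 5)
        assert nq.apical_area_ratio(1, ns, cells) == pytest.approx(0.5)

    def test_junction_ratio(self):
        ns = NeighborSet(1, (2, 3, 4, 5), (2, 2, 2, 2))
        cells = self._cells([1] * 5, [30, 30, 30, 30, 30])
        assert nq.junction_intensity_ratio(1, ns, cells, background=10) == 1.0
        cells = self._cells([1] * 5, [20, 30, 30, 30, 30])
        assert nq.junction_intensity_ratio(1, ns, cells, background=10) == 0.5

    def test_junction_ratio_gain_invariance(self):
        ns = NeighborSet(1, (2, 3, 4, 5), (2, 2, 2, 2))
        cells = self._cells([1] * 5, [22.0, 31.0, 28.0, 35.0, 30.0])
        base = nq.junction_intensity_ratio(1, ns, cells, background=10.0)
        gained = cells.copy()
        gained["junction_mean"] = 3.5 * gained["junction_mean"]
        assert nq.junction_intensity_ratio(1, ns, gained, background=35.0) \
            == pytest.approx(base)

    def test_nonpositive_denominator_fails(self):
        ns = NeighborSet(1, (2, 3, 4, 5), (2, 2, 2, 2))
        cells = self._cells([1] * 5, [30, 10, 10, 10, 10])
        with pytest.raises(ValueError, match="denominator"):
            nq.junction_intensity_ratio(1, ns, cells, background=10)

    def test_area_ratio_scale_invariance(self):
        ns = NeighborSet(1, (2, 3, 4, 5), (2, 2, 2, 2))
        cells = self._cells([3, 4, 5, 4, 4], [0] * 5)
        base = nq.apical_area_ratio(1, ns, cells)
        scaled = cells.copy()
        scaled["area_px"] = 4 * scaled["area_px"]  # uniform 2x spatial rescale
        assert nq.apical_area_ratio(1, ns, scaled) == pytest.approx(base)


class TestPairFilter:
    def test_adjacent_pair_removed_symmetrically(self):
        g = nx.Graph([(1, 2), (2, 3), (3, 4)])
        cells = pd.DataFrame({"cell_id": [1, 2, 3, 4],
                              "transfected": [True, True, False, True]})
        kept = nq.pair_filter(cells, g)
        assert kept["cell_id"].tolist() == [3, 4]

    def test_isolated_transfected_kept(self):
        g = nx.Graph([(1, 2), (2, 3)])
        cells = pd.DataFrame({"cell_id": [1, 2, 3],
                              "transfected": [True, False, True]})
        kept = nq.pair_filter(cells, g)
        assert kept["cell_id"].tolist() == [1, 2, 3]

    def test_planted_pairs_fully_recalled(self):
        """Every planted adjacent sister pair is removed; isolated cells stay."""
        rng = np.random.default_rng(3)
        params = nq.MosaicSimParams(shape=(200, 200), n_cells=100,
                                    transfected_fraction=0.08, seed=3)
        label, _j, gt = nq.generate_apical_mosaic(params)
        g = nq.build_adjacency(label)
        flags = gt[["cell_id", "transfected"]].copy()
        # plant sister pairs: transfect a neighbor of two transfected cells
        planted = []
        for cid in flags.loc[flags["transfected"], "cell_id"].iloc[:2]:
            nb = min(n for n in g.neighbors(int(cid))
                     if not flags.loc[flags["cell_id"] == n, "transfected"].iloc[0])
            flags.loc[flags["cell_id"] == nb, "transfected"] = True
            planted += [int(cid), nb]
        kept = nq.pair_filter(flags, g)
        assert not set(planted) & set(kept["cell_id"])


class TestSplitAndCrosstab:
    def test_control_median_threshold(self):
        labels, threshold = nq.split_small_large([0.5, 0.7], [0.4, 0.62, 0.9])
        assert threshold == pytest.approx(0.62)
        assert labels.tolist() == ["small", "large"]

    def test_equality_goes_large(self):
        labels, _ = nq.split_small_large([0.62], [0.4, 0.62, 0.9])
        assert labels.tolist() == ["large"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_comparison_oracle(self, seed):
        rng = np.random.default_rng(seed)
        control = rng.uniform(0, 2, 21)
        ratios = rng.uniform(0, 2, 50)
        labels, thr = nq.split_small_large(ratios, control)
        oracle = ["small" if r < np.median(control) else "large" for r in ratios]
        assert labels.tolist() == oracle

    def test_crosstab_conservation_and_diagonal(self):
        size = np.array(["small"] * 6 + ["large"] * 4)
        tuj1 = np.array([True] * 6 + [False] * 4)
        ratios = np.linspace(0.2, 1.2, 10)
        table, means = nq.crosstab_tuj1(size, tuj1, ratios)
        assert table.to_numpy().sum() == 10
        assert table.loc["small", False] == 0
        assert table.loc["large", True] == 0
        assert means[True] == pytest.approx(ratios[:6].mean())

    def test_tuj1_enrichment_in_small_cells(self):
        """Tuj1 conditioned on constriction shows up as small-cell enrichment."""
        odds = []
        for seed in range(5):
            params = nq.MosaicSimParams(shape=(300, 300), n_cells=150,
                                        constriction_scale=0.5,
                                        junction_factor=1.0, seed=seed)
            label, junction, gt = nq.generate_apical_mosaic(params)
            flags = gt[["cell_id", "transfected"]].copy()
            flags["Tuj1"] = gt["differentiating"]
            cells = nq.measure_apical_cells(label, junction, flags=flags)
            g = nq.build_adjacency(label)
            ratios = nq.neighbor_ratio_table(cells, g)
            merged = ratios.merge(flags, on="cell_id")
            control = merged.loc[~merged["Tuj1"], "area_ratio"]
            labels, _ = nq.split_small_large(merged["area_ratio"], control)
            table, _means = nq.crosstab_tuj1(labels, merged["Tuj1"],
                                             merged["area_ratio"])
            a = table.loc["small", True] + 0.5
            b = table.loc["small", False] + 0.5
            c = table.loc["large", True] + 0.5
            d = table.loc["large", False] + 0.5
            odds.append((a / b) / (c / d))
        assert np.mean(np.asarray(odds) > 1) >= 0.95


class TestGenerativeRecovery:
    def test_constriction_and_junction_factors_recovered(self):
        """One mid-grid condition recovered within the Monte-Carlo band."""
        params = nq.MosaicSimParams(shape=(360, 360), n_cells=200,
                                    constriction_scale=0.5, junction_factor=0.5,
                                    seed=41)
        label, junction, gt = nq.generate_apical_mosaic(params)
        cells = nq.measure_apical_cells(label, junction,
                                        flags=gt[["cell_id", "transfected"]])
        g = nq.build_adjacency(label)
        bg = nq.apical.estimate_junction_background(label, junction)
        ratios = nq.neighbor_ratio_table(nq.pair_filter(cells, g), g, background=bg)
        merged = ratios.merge(gt[["cell_id", "differentiating"]], on="cell_id")
        diff = merged[merged["differentiating"]]
        assert abs(diff["area_ratio"].mean() - 0.5) < 0.08
        assert abs(diff["junction_ratio"].mean() - 0.5) < 0.08
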