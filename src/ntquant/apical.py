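"""Neighbor-referenced apical metrics on en-face segmentations.

Mosaic transfection leaves single labeled cells surrounded by unlabeled
tissue, so the natural unit of measurement is a ratio against nearby
non-transfected cells: the apical area ratio divides a transfected cell's
apical footprint area by the mean footprint area of four of its
non-transfected neighbors one cell row away, and the junction intensity
ratio does the same for the background-subtracted mean junction-marker
intensity on the apical circumference (a 2-pixel boundary band).

"One cell row away" is operationalized as adjacency-graph distance exactly
2; when fewer than four ring-2 candidates exist the set is completed from
ring-1 non-transfected cells, with the ring recorded per neighbor.
Transfected cells whose nearest transfected cell is directly adjacent are
treated as post-division sister pairs and discarded symmetrically before
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import _boundary_band

logger = logging.getLogger(__name__)

__all__ = [
    "ApicalCellTable",
    "NeighborSet",
    "NeighborSelectionError",
    "measure_apical_cells",
    "build_adjacency",
    "select_neighbors",
    "apical_area_ratio",
    "junction_intensity_ratio",
    "pair_filter",
    "split_small_large",
    "crosstab_tuj1",
    "estimate_junction_background",
    "neighbor_ratio_table",
]


class NeighborSelectionError(ValueError):
    """Fewer than four eligible reference neighbors around a focal cell."""


@dataclass(frozen=True)
class NeighborSet:
    """Four reference neighbors of a focal transfected cell."""

    focal_id: int
    neighbor_ids: tuple[int, int, int, int]
    rings: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(set(self.neighbor_ids)) != 4:
            raise ValueError("neighbors must be four distinct cells")


def measure_apical_cells(label_image: np.ndarray,
                         junction_image: np.ndarray | None = None,
                         flags: pd.DataFrame | None = None,
                         band_width: int = 2) -> pd.DataFrame:
    """Per-cell apical measurements from a labeled en-face segmentation.

    Returns one row per footprint with its pixel area, centroid, and (when a
    junction channel is given) the mean junction intensity over the
    footprint's inner boundary band of ``band_width`` pixels.  ``flags`` may
    supply ``transfected`` / ``Tuj1`` booleans keyed by ``cell_id``.
    """
    label_image = np.asarray(label_image)
    ids = np.unique(label_image)
    ids = ids[ids > 0]
    areas = ndimage.sum_labels(np.ones_like(label_image, dtype=float),
                               label_image, ids)
    cy, cx = np.transpose(ndimage.center_of_mass(
        np.ones_like(label_image, dtype=float), label_image, ids))
    out = pd.DataFrame({"cell_id": ids.astype(int), "area_px": areas.astype(int),
                        "centroid_y": cy, "centroid_x": cx})
    if junction_image is not None:
        if junction_image.shape != label_image.shape:
            raise ValueError("junction image shape differs from segmentation")
        means = np.empty(len(ids))
        objects = ndimage.find_objects(label_image)
        for k, cid in enumerate(ids):
            sl = objects[cid - 1]
            band = _boundary_band(label_image[sl] == cid, width=band_width)
            means[k] = float(junction_image[sl][band].mean())
        out["junction_mean"] = means
    if flags is not None:
        out = out.merge(flags, on="cell_id", how="left")
    return out


def build_adjacency(label_image: np.ndarray, min_shared: int = 3) -> nx.Graph:
    """Cell adjacency graph from a labeled segmentation.

    Two cells are adjacent when at least ``min_shared`` 4-connected pixel
    pairs straddle their common boundary (a diagonal single-pixel touch
    contributes nothing).  Every cell id appears as a node.
    """
    label_image = np.asarray(label_image)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in np.unique(label_image) if i > 0)
    counts: dict[tuple[int, int], int] = {}
    for a, b in ((label_image[:, :-1], label_image[:, 1:]),
                 (label_image[:-1, :], label_image[1:, :])):
        diff = (a != b) & (a > 0) & (b > 0)
        pairs = np.stack([a[diff], b[diff]], axis=1)
        if len(pairs):
            pairs = np.sort(pairs, axis=1)
            uniq, cnt = np.unique(pairs, axis=0, return_counts=True)
            for (i, j), c in zip(uniq, cnt):
                counts[(int(i), int(j))] = counts.get((int(i), int(j)), 0) + int(c)
    for (i, j), c in counts.items():
        if c >= min_shared:
            g.add_edge(i, j, shared=c)
    return g


def select_neighbors(focal_id: int, graph: nx.Graph,
                     cells: pd.DataFrame) -> NeighborSet:
    """Pick four non-transfected reference cells one row from the focal cell.

    Candidates are non-transfected cells at graph distance exactly 2; the
    four nearest by centroid distance are chosen, ties broken by ascending
    cell id.  If fewer than four exist, ring-1 non-transfected cells
    complete the set (ring recorded per neighbor); fewer than four in rings
    1–2 combined fails.
    """
    by_id = cells.set_index("cell_id")
    if not bool(by_id.at[focal_id, "transfected"]):
        raise ValueError(f"focal cell {focal_id} is not transfected")
    dist = nx.single_source_shortest_path_length(graph, focal_id, cutoff=2)
    fy, fx = by_id.at[focal_id, "centroid_y"], by_id.at[focal_id, "centroid_x"]

    def eligible(ring: int) -> list[tuple[float, int]]:
        out = []
        for cid, d in dist.items():
            if d != ring or cid not in by_id.index:
                continue
            if bool(by_id.at[cid, "transfected"]):
                continue
            cd = float(np.hypot(by_id.at[cid, "centroid_y"] - fy,
                                by_id.at[cid, "centroid_x"] - fx))
            out.append((cd, cid))
        return sorted(out)

    chosen: list[tuple[int, int]] = [(cid, 2) for _, cid in eligible(2)[:4]]
    if len(chosen) < 4:
        for _, cid in eligible(1):
            if len(chosen) == 4:
                break
            chosen.append((cid, 1))
    if len(chosen) < 4:
        raise NeighborSelectionError(
            f"cell {focal_id}: only {len(chosen)} eligible neighbors in rings 1-2")
    ids, rings = zip(*chosen)
    return NeighborSet(focal_id=int(focal_id), neighbor_ids=tuple(int(i) for i in ids),
                       rings=tuple(int(r) for r in rings))


def apical_area_ratio(focal_id: int, neighbors: NeighborSet,
                      cells: pd.DataFrame) -> float:
    """Focal apical area over the mean area of the four reference neighbors."""
    by_id = cells.set_index("cell_id")
    focal = float(by_id.at[focal_id, "area_px"])
    ref = float(np.mean([by_id.at[i, "area_px"] for i in neighbors.neighbor_ids]))
    return focal / ref


def junction_intensity_ratio(focal_id: int, neighbors: NeighborSet,
                             cells: pd.DataFrame, background: float) -> float:
    """Background-subtracted junction intensity of the focal cell over the
    mean background-subtracted intensity of the four reference neighbors."""
    by_id = cells.set_index("cell_id")
    vals = [float(by_id.at[i, "junction_mean"]) for i in neighbors.neighbor_ids]
    if background >= min(vals + [float(by_id.at[focal_id, "junction_mean"])]):
        logger.warning("background %.4g is not below all boundary means; "
                       "ratio may sign-flip", background)
    den = float(np.mean([v - background for v in vals]))
    if den <= 0:
        raise ValueError(f"neighbor denominator {den!r} <= 0 after background subtraction")
    return (float(by_id.at[focal_id, "junction_mean"]) - background) / den


def pair_filter(cells: pd.DataFrame, graph: nx.Graph) -> pd.DataFrame:
    """Discard adjacent transfected cells as post-division sister pairs.

    A transfected cell whose nearest transfected cell is directly adjacent
    (ring 1) is taken as a member of a sister pair from a division after
    transfection; removal is symmetric (both members dropped) and counted in
    the log.  Non-transfected cells pass through untouched.
    """
    transfected = set(cells.loc[cells["transfected"] == True, "cell_id"])  # noqa: E712
    drop = set()
    for cid in transfected:
        if cid not in graph:
            continue
        for nb in graph.neighbors(cid):
            if nb in transfected:
                drop.add(cid)
                drop.add(nb)
    if drop:
        logger.info("pair filter removed %d transfected cells in adjacent pairs",
                    len(drop))
    return cells[~cells["cell_id"].isin(drop)]


def estimate_junction_background(label_image: np.ndarray,
                                 junction_image: np.ndarray,
                                 margin: int = 2) -> float:
    """Background intensity from non-junctional pixels.

    Junctional staining sits on cell boundaries; the background statistic is
    the median intensity over pixels farther than ``margin`` pixels from any
    inter-cell boundary (cell interiors).
    """
    label_image = np.asarray(label_image)
    edge = np.zeros(label_image.shape, dtype=bool)
    edge[:, :-1] |= label_image[:, :-1] != label_image[:, 1:]
    edge[:-1, :] |= label_image[:-1, :] != label_image[1:, :]
    near = ndimage.binary_dilation(edge, iterations=margin)
    interior = ~near & (label_image > 0)
    if not interior.any():
        raise ValueError("no interior pixels available for background estimation")
    return float(np.median(junction_image[interior]))


def neighbor_ratio_table(cells: pd.DataFrame, graph: nx.Graph,
                         background: float = 0.0) -> pd.DataFrame:
    """Area and junction-intensity ratios for every transfected cell.

    Runs :func:`select_neighbors` per transfected cell and computes both
    neighbor-referenced ratios; cells without four eligible neighbors are
    skipped with a logged count.  Junction ratios are only computed when the
    table carries a ``junction_mean`` column.
    """
    rows = []
    skipped = 0
    has_junction = "junction_mean" in cells.columns
    for cid in cells.loc[cells["transfected"] == True, "cell_id"]:  # noqa: E712
        try:
            nbs = select_neighbors(int(cid), graph, cells)
        except NeighborSelectionError:
            skipped += 1
            continue
        row = {"cell_id": int(cid),
               "neighbor_ids": ";".join(str(i) for i in nbs.neighbor_ids),
               "n_ring1_fallback": sum(1 for r in nbs.rings if r == 1),
               "area_ratio": apical_area_ratio(int(cid), nbs, cells)}
        if has_junction:
            row["junction_ratio"] = junction_intensity_ratio(
                int(cid), nbs, cells, background)
        rows.append(row)
    if skipped:
        logger.info("neighbor selection skipped %d transfected cells "
                    "(fewer than four eligible neighbors)", skipped)
    return pd.DataFrame(rows)


def split_small_large(ratios: pd.Series | np.ndarray,
                      control_ratios: pd.Series | np.ndarray,
                      ) -> tuple[np.ndarray, float]:
    """Label ratios small/large against the control-condition median.

    The threshold is the median of the control ratios, applied to every
    condition; ratios below it are "small", ratios at or above it "large"
    (equality assigned to "large" by convention).
    """
    control_ratios = np.asarray(control_ratios, dtype=float)
    if len(control_ratios) == 0:
        raise ValueError("control ratio set is empty")
    threshold = float(np.median(control_ratios))
    labels = np.where(np.asarray(ratios, dtype=float) < threshold,
                      "small", "large")
    return labels, threshold


def crosstab_tuj1(size_labels: np.ndarray, tuj1: np.ndarray,
                  ratios: np.ndarray) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-tabulate small/large size labels with the Tuj1 call.

    Returns the 2x2 count table (rows small/large, columns Tuj1-/Tuj1+) and
    the mean area ratio per Tuj1 group.
    """
    df = pd.DataFrame({"size": size_labels, "tuj1": np.asarray(tuj1, dtype=bool),
                       "ratio": np.asarray(ratios, dtype=float)})
    if df["size"].isna().any() or df["tuj1"].isna().any():
        raise ValueError("every cell needs both a size label and a Tuj1 call")
    table = pd.crosstab(df["size"], df["tuj1"]).reindex(
        index=["small", "large"], columns=[False, True], fill_value=0)
    means = df.groupby("tuj1")["ratio"].mean()
    return table, means
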