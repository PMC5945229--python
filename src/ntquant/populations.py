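"""Population classification, differentiation/proliferation rates, and
cumulative-labeling time-course analysis.

Under cumulative S-phase labeling, three populations are discriminated from
the EdU and HuCD marker calls: cycling progenitors (EdU+/HuCD−), prospective
neurons (EdU−/HuCD−, cells that have exited the cycle but not yet switched
on neuronal markers) and neurons (EdU−/HuCD+).  EdU+/HuCD+ double positives
are flagged "inconsistent" and excluded from rates by default, with a logged
count.

Rates follow the standard mosaic-transfection definitions: the
differentiation (proliferation) rate of a condition is the number of
transfected HuCD+ (EdU+) cells over all transfected cells; the neighbor
differentiation rate pools, over all transfected HuCD+ cells of a section,
the non-transfected HuCD+ neighbors over all non-transfected neighbors (a
cell adjacent to several transfected HuCD+ cells counts once).

Because the ventral motor-neuron domain differentiates much earlier than
the rest of the neural tube, analyses are restricted to the dorsal
two-thirds of the section.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "POPULATIONS",
    "classify_population",
    "classify_records",
    "classify_neurog2",
    "restrict_region",
    "differentiation_rate",
    "proliferation_rate",
    "neighbor_differentiation_rate",
    "CumulativeCurve",
    "cumulative_labeling_curve",
]

POPULATIONS = ("cycling_progenitor", "prospective_neuron", "neuron", "inconsistent")


def classify_population(edu: bool, hucd: bool) -> str:
    """Map (EdU, HuCD) marker calls to a population label.

    (+,−) cycling progenitor; (−,−) prospective neuron; (−,+) neuron;
    (+,+) inconsistent (flagged, excluded from rates by default).
    """
    if pd.isna(edu) or pd.isna(hucd):
        raise ValueError("unknown marker call: EdU and HuCD must both be known")
    if edu and not hucd:
        return "cycling_progenitor"
    if not edu and not hucd:
        return "prospective_neuron"
    if not edu and hucd:
        return "neuron"
    return "inconsistent"


def classify_records(records: pd.DataFrame, allow_unknown: bool = False,
                     ) -> pd.DataFrame:
    """Attach a ``population`` column; with ``allow_unknown`` drop (and log)
    rows whose EdU or HuCD call is missing, otherwise fail on them."""
    unknown = records["EdU"].isna() | records["HuCD"].isna()
    if unknown.any():
        if not allow_unknown:
            raise ValueError(
                f"{int(unknown.sum())} records carry unknown EdU/HuCD calls "
                "(pass allow_unknown=True to drop them)")
        logger.info("dropping %d records with unknown marker calls",
                    int(unknown.sum()))
        records = records[~unknown]
    out = records.copy()
    out["population"] = [classify_population(e, h)
                         for e, h in zip(out["EdU"], out["HuCD"])]
    n_incons = int((out["population"] == "inconsistent").sum())
    if n_incons:
        logger.info("flagged %d EdU+/HuCD+ inconsistent records", n_incons)
    return out


def classify_neurog2(level: float, t_low: float, t_high: float) -> str:
    """Stratify a continuous Neurog2 intensity into negative / low / high.

    ``level <= t_low`` → negative; ``t_low < level <= t_high`` → low;
    above → high.  Thresholds must be strictly ordered.
    """
    if not t_low < t_high:
        raise ValueError(f"thresholds must satisfy t_low < t_high, got {t_low}, {t_high}")
    if level <= t_low:
        return "negative"
    if level <= t_high:
        return "low"
    return "high"


def restrict_region(records: pd.DataFrame, fraction: float = 2.0 / 3.0,
                    honor_excluded: bool = True) -> pd.DataFrame:
    """Keep records in the dorsal band of the section.

    The band spans ``fraction`` of the section height measured from the
    dorsal-most tissue position (image top, y = 0); a record is kept when its
    centroid satisfies ``y < fraction * section_height``.  Records flagged as
    excluded-zone are also dropped when ``honor_excluded``.
    """
    if "section_height" not in records.columns or records["section_height"].isna().any():
        raise ValueError("records must carry a section_height column")
    keep = records["centroid_y"] < fraction * records["section_height"]
    if honor_excluded and "region" in records.columns:
        keep &= records["region"] == "included"
    dropped = int((~keep).sum())
    if dropped:
        logger.info("region restriction dropped %d of %d records",
                    dropped, len(records))
    return records[keep]


def _transfected(records: pd.DataFrame) -> pd.DataFrame:
    t = records[records["transfected"] == True]  # noqa: E712
    if len(t) == 0:
        raise ValueError("no transfected records after restriction")
    return t


def differentiation_rate(records: pd.DataFrame) -> float:
    """Transfected HuCD+ cells over all transfected cells."""
    t = _transfected(records)
    return float((t["HuCD"] == True).sum() / len(t))  # noqa: E712


def proliferation_rate(records: pd.DataFrame) -> float:
    """Transfected EdU+ cells over all transfected cells."""
    t = _transfected(records)
    return float((t["EdU"] == True).sum() / len(t))  # noqa: E712


def neighbor_differentiation_rate(records: pd.DataFrame,
                                  adjacency: nx.Graph) -> float:
    """Differentiation rate among neighbors of transfected HuCD+ cells.

    Pooled within the section: the union of non-transfected cells adjacent
    to any transfected HuCD+ cell forms the denominator; its HuCD+ members
    the numerator.  A non-transfected cell adjacent to several transfected
    HuCD+ cells counts once.
    """
    by_id = records.set_index("label")
    focal = by_id[(by_id["transfected"] == True) & (by_id["HuCD"] == True)]  # noqa: E712
    if len(focal) == 0:
        raise ValueError("no transfected HuCD+ cell in the record set")
    pooled: set = set()
    for fid in focal.index:
        if fid not in adjacency:
            continue
        for nb in adjacency.neighbors(fid):
            if nb in by_id.index and by_id.at[nb, "transfected"] == False:  # noqa: E712
                pooled.add(nb)
    if not pooled:
        raise ValueError("transfected HuCD+ cells have no non-transfected neighbors")
    pos = sum(bool(by_id.at[nb, "HuCD"]) for nb in pooled)
    return pos / len(pooled)


@dataclass(frozen=True)
class CumulativeCurve:
    """Per-timepoint labeled fractions of a pulse-labeled cohort."""

    table: pd.DataFrame  # columns: time_h, n_ft, frac_edu, frac_hucd
    plateau: float
    plateau_onset_h: float
    flatness: float  # max pairwise difference among plateau points


def cumulative_labeling_curve(cohort: pd.DataFrame,
                              plateau_onset_h: float = 12.0) -> CumulativeCurve:
    """EdU+ and HuCD+ fractions of the labeled cohort over time.

    The plateau estimate is the mean EdU+ fraction over timepoints at or
    after ``plateau_onset_h`` (cumulative labeling saturates once every
    cycling cell has passed through S phase); the reported flatness is the
    largest pairwise difference among the plateau points.  Cumulative
    labeling makes per-cell EdU and HuCD status monotone non-decreasing;
    violations mark a corrupt table and fail.
    """
    ft = cohort[cohort["ft"] == True]  # noqa: E712
    times = np.sort(ft["time_h"].unique())
    if len(times) < 2:
        raise ValueError("need at least 2 timepoints")
    for col in ("edu", "hucd"):
        pivot = ft.pivot_table(index="cell_id", columns="time_h", values=col,
                               aggfunc="first").astype(float)
        diffs = pivot[np.sort(pivot.columns)].diff(axis=1).iloc[:, 1:]
        if (diffs < 0).any().any():
            raise ValueError(
                f"{col} status decreases over time for some cells: corrupt "
                "table under cumulative labeling")
    rows = []
    for t in times:
        at = ft[ft["time_h"] == t]
        if len(at) == 0:
            raise ValueError(f"no labeled cells at timepoint {t}")
        rows.append((float(t), len(at), float(at["edu"].mean()),
                     float(at["hucd"].mean())))
    table = pd.DataFrame(rows, columns=["time_h", "n_ft", "frac_edu", "frac_hucd"])
    plat = table[table["time_h"] >= plateau_onset_h]
    if len(plat) == 0:
        raise ValueError(f"no timepoints at or after plateau onset {plateau_onset_h} h")
    plateau = float(plat["frac_edu"].mean())
    flatness = float(plat["frac_edu"].max() - plat["frac_edu"].min())
    return CumulativeCurve(table=table, plateau=plateau,
                           plateau_onset_h=plateau_onset_h, flatness=flatness)
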