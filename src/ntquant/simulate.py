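"""Synthetic microscopy data with known ground truth.

Three generators emulate the kinds of data the quantification pipeline
consumes:

* :func:`generate_transverse_section` — an integer-labeled nucleus
  segmentation of a transverse neural-tube section plus co-registered
  intensity channels (a Notch-reporter channel and a DAPI-analogue mask
  channel) and a per-nucleus marker table.  Nuclei belong to one of three
  classes — cycling progenitors, prospective neurons, neurons — each with its
  own reporter-intensity distribution (progenitors broad and high, neurons at
  background).
* :func:`generate_apical_mosaic` — an en-face apical segmentation: a
  space-filling tessellation in which a mosaic of "transfected" cells is
  planted, a subset of which constrict their apical footprint and reduce the
  junction-marker intensity painted on their boundary band.
* :func:`generate_cohort_timecourse` — a birth-dated cohort labeled at t0
  whose members either re-enter S phase (and become EdU+ under cumulative
  pulse labeling) or exit the cycle and later express a neuronal marker.

All randomness flows from the single ``seed`` in each parameter object via
one :class:`numpy.random.Generator`; identical parameters reproduce outputs
bit-exactly.  Intensity units are arbitrary: only ratios and normalized
values are meaningful downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "SectionSimParams",
    "MosaicSimParams",
    "CohortSimParams",
    "PackingError",
    "generate_transverse_section",
    "generate_apical_mosaic",
    "generate_cohort_timecourse",
    "sample_class_intensities",
]

CLASSES = ("progenitor", "prospective_neuron", "neuron")


class PackingError(RuntimeError):
    """Requested nuclei could not be placed without overlap."""


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SectionSimParams:
    """Parameters for a simulated transverse section.

    Intensities are in arbitrary units.  ``class_means``/``class_sds`` give
    the per-class distribution of the *nucleus-mean* reporter intensity; the
    neuron class defaults to the background level so that neurons sit at
    background, as in tissue.  ``excluded_bands`` are fractional y-ranges
    (top of the image = dorsal) flagged as roof-plate / motor-neuron
    analogues and excluded from anchor sets downstream.
    """

    shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 200
    radius_mean: float = 6.0
    radius_sd: float = 1.0
    proportions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    class_means: dict = field(default_factory=lambda: {
        "progenitor": 600.0, "prospective_neuron": 500.0, "neuron": 100.0})
    class_sds: dict = field(default_factory=lambda: {
        "progenitor": 250.0, "prospective_neuron": 150.0, "neuron": 20.0})
    neuron_background_mean: float = 100.0
    noise_sd: float = 10.0
    excluded_bands: tuple[tuple[float, float], ...] = ((0.0, 0.06), (0.72, 0.86))
    distribution: str = "lognormal"  # or "normal"
    transfected_fraction: float = 0.0
    ft_fraction: float = 1.0
    neurog2_means: dict = field(default_factory=lambda: {
        "progenitor": 30.0, "prospective_neuron": 300.0, "neuron": 80.0})
    neurog2_sds: dict = field(default_factory=lambda: {
        "progenitor": 15.0, "prospective_neuron": 100.0, "neuron": 40.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be > 0")
        props = np.asarray(self.proportions, dtype=float)
        if props.shape != (3,) or (props < 0).any() or (props > 1).any():
            raise ValueError("proportions must be three values in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {props.sum()!r}")
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError("distribution must be 'lognormal' or 'normal'")
        _check_fraction("transfected_fraction", self.transfected_fraction)
        _check_fraction("ft_fraction", self.ft_fraction)
        for (lo, hi) in self.excluded_bands:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("excluded_bands must be fractional (lo, hi) pairs")


def sample_class_intensities(mean: float, sd: float, n: int,
                             rng: np.random.Generator,
                             distribution: str = "lognormal") -> np.ndarray:
    """Draw ``n`` nucleus-mean intensities with the requested mean and sd.

    The lognormal branch is moment-matched so that the *arithmetic* mean and
    sd of the draws equal the requested values; with sd == 0 it degenerates
    to a constant.  Used internally by the section generator and exposed for
    calibration runs (e.g. null simulations for the statistics module).
    """
    if distribution == "normal":
        return rng.normal(mean, sd, size=n)
    if sd <= 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _place_ellipses(params: SectionSimParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse nuclei.

    Overlap is forbidden conservatively: two nuclei are rejected if their
    bounding circles (major semi-axes) intersect, so drawn masks never touch.
    """
    h, w = params.shape
    placed = []  # (cy, cx, a, b, theta) with a >= b semi-axes
    max_attempts = 400 * params.n_nuclei
    attempts = 0
    while len(placed) < params.n_nuclei:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {params.n_nuclei} nuclei without overlap: "
                f"achieved {len(placed)} after {attempts} attempts")
        attempts += 1
        r = rng.normal(params.radius_mean, params.radius_sd)
        if r < 1.5:
            continue
        q = rng.uniform(0.6, 1.0)  # axis ratio b/a
        a = r / np.sqrt(q)
        b = r * np.sqrt(q)
        theta = rng.uniform(0.0, np.pi)
        cy = rng.uniform(a + 1, h - a - 1)
        cx = rng.uniform(a + 1, w - a - 1)
        ok = True
        for (py, px, pa, _pb, _pt) in placed:
            if (cy - py) ** 2 + (cx - px) ** 2 < (a + pa + 1.0) ** 2:
                ok = False
                break
        if ok:
            placed.append((cy, cx, a, b, theta))
    return placed


def _in_excluded_band(y_frac: np.ndarray,
                      bands: tuple[tuple[float, float], ...]) -> np.ndarray:
    out = np.zeros(y_frac.shape, dtype=bool)
    for lo, hi in bands:
        out |= (y_frac >= lo) & (y_frac <= hi)
    return out


def generate_transverse_section(params: SectionSimParams):
    """Simulate one labeled transverse section.

    Returns ``(label_image, channels, markers, ground_truth)`` where
    ``channels`` maps channel name ("vnp", "dapi") to a uint16 image,
    ``markers`` is the per-nucleus marker-call table (CSV-ready) and
    ``ground_truth`` records each nucleus's true class and intensity
    parameter.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    placed = _place_ellipses(params, rng)

    label = np.zeros((h, w), dtype=np.uint16)
    for i, (cy, cx, a, b, theta) in enumerate(placed, start=1):
        # skimage rotation is counter-clockwise about the row axis
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        label[rr, cc] = i

    n = params.n_nuclei
    classes = rng.choice(len(CLASSES), size=n, p=np.asarray(params.proportions))
    class_names = np.asarray(CLASSES)[classes]

    nucleus_mean = np.empty(n)
    for ci, cname in enumerate(CLASSES):
        sel = classes == ci
        nucleus_mean[sel] = sample_class_intensities(
            params.class_means[cname], params.class_sds[cname], int(sel.sum()),
            rng, params.distribution)
    nucleus_mean = np.clip(nucleus_mean, 0.0, None)

    vnp = rng.normal(params.neuron_background_mean, params.noise_sd, size=(h, w))
    mean_map = np.zeros(h * w)
    flat = label.ravel()
    inside = flat > 0
    mean_map[inside] = nucleus_mean[flat[inside] - 1]
    vnp_flat = vnp.ravel()
    vnp_flat[inside] = mean_map[inside] + rng.normal(0.0, params.noise_sd,
                                                     size=int(inside.sum()))
    vnp = np.clip(vnp_flat.reshape(h, w), 0, 65535).round().astype(np.uint16)
    dapi = (label > 0).astype(np.uint16) * 1000

    cy = np.array([p[0] for p in placed])
    cx = np.array([p[1] for p in placed])
    y_frac = cy / h
    excluded = _in_excluded_band(y_frac, params.excluded_bands)
    side = np.where(cx < w / 2, "electroporated", "non_electroporated")

    hucd = class_names == "neuron"
    edu = class_names == "progenitor"
    ft = rng.random(n) < params.ft_fraction
    transfected = ((rng.random(n) < params.transfected_fraction)
                   & (side == "electroporated"))
    neurog2 = np.empty(n)
    for ci, cname in enumerate(CLASSES):
        sel = classes == ci
        neurog2[sel] = np.clip(rng.normal(params.neurog2_means[cname],
                                          params.neurog2_sds[cname],
                                          size=int(sel.sum())), 0.0, None)

    markers = pd.DataFrame({
        "label": np.arange(1, n + 1, dtype=int),
        "HuCD": hucd,
        "EdU": edu,
        "FlashTag": ft,
        "transfected": transfected,
        "Neurog2": neurog2,
    })
    ground_truth = pd.DataFrame({
        "cell_id": np.arange(1, n + 1, dtype=int),
        "true_class": class_names,
        "true_vnp_mean": nucleus_mean,
        "centroid_y": cy,
        "centroid_x": cx,
        "region": np.where(excluded, "excluded", "included"),
        "side": side,
    })
    channels = {"vnp": vnp, "dapi": dapi}
    return label, channels, markers, ground_truth


# ---------------------------------------------------------------------------
# Apical mosaic


@dataclass(frozen=True)
class MosaicSimParams:
    """Parameters for a simulated en-face apical mosaic.

    ``constriction_scale`` multiplies the apical footprint area of
    differentiating cells (1.0 = no constriction); ``junction_factor``
    multiplies the junction-marker intensity painted on their boundary band.
    """

    shape: tuple[int, int] = (360, 360)
    n_cells: int = 200
    transfected_fraction: float = 0.15
    differentiating_fraction: float = 0.5
    constriction_scale: float = 1.0
    junction_factor: float = 1.0
    junction_baseline: float = 400.0
    junction_background: float = 50.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 10:
            raise ValueError("n_cells must be >= 10")
        _check_fraction("transfected_fraction", self.transfected_fraction)
        _check_fraction("differentiating_fraction", self.differentiating_fraction)
        if not 0.0 < self.constriction_scale <= 1.0:
            raise ValueError("constriction_scale must lie in (0, 1]")
        _check_fraction("junction_factor", self.junction_factor)


def _hex_seeds(shape: tuple[int, int], n: int, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice of exactly ``n`` seed points.

    Epithelial packing is much more regular than a Poisson point process;
    the jittered lattice keeps cell-area variance low so neighbor-referenced
    area ratios are nearly unbiased.
    """
    h, w = shape
    spacing = np.sqrt(h * w / n / (np.sqrt(3) / 2.0))
    dy = spacing * np.sqrt(3) / 2.0
    pts = []
    row = 0
    y = dy / 2.0
    while y < h:
        offset = (spacing / 2.0) if row % 2 else 0.0
        x = spacing / 2.0 + offset
        while x < w:
            pts.append((y, x))
            x += spacing
        y += dy
        row += 1
    pts = np.asarray(pts)
    pts = pts + rng.uniform(-0.18 * spacing, 0.18 * spacing, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0.5, h - 0.5)
    pts[:, 1] = np.clip(pts[:, 1], 0.5, w - 0.5)
    if len(pts) > n:
        keep = rng.choice(len(pts), size=n, replace=False)
        pts = pts[np.sort(keep)]
    while len(pts) < n:
        extra = np.column_stack([rng.uniform(0.5, h - 0.5, size=n - len(pts)),
                                 rng.uniform(0.5, w - 0.5, size=n - len(pts))])
        pts = np.vstack([pts, extra])[:n]
    return pts


def _boundary_band(mask: np.ndarray, width: int = 2) -> np.ndarray:
    """Inner boundary band of a binary mask (pixels within ``width`` of the edge)."""
    eroded = ndimage.binary_erosion(mask, iterations=width, border_value=0)
    return mask & ~eroded


def generate_apical_mosaic(params: MosaicSimParams):
    """Simulate an en-face apical segmentation with a planted mosaic.

    Returns ``(label_image, junction_image, ground_truth)``.  The label image
    is an exact partition of the field (every pixel belongs to one cell);
    differentiating cells keep exactly ``round(scale * area)`` of their
    pixels (the ones nearest their seed) and the freed pixels are absorbed by
    the nearest non-differentiating neighbor, so areas respond as in a real
    epithelium.  Junction intensity is painted on each cell's 2-pixel inner
    boundary band, scaled by that cell's junction factor.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    n = params.n_cells

    n_transfected = int(round(params.transfected_fraction * n))
    if n_transfected < 1:
        raise ValueError(
            "transfected_fraction x n_cells < 1: no transfected cell to plant")
    seeds = _hex_seeds((h, w), n, rng)

    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    tree = cKDTree(seeds)
    _, assign = tree.query(pix)
    label = (assign + 1).astype(np.uint16).reshape(h, w)

    transfected_ids = np.sort(rng.choice(np.arange(1, n + 1), size=n_transfected,
                                         replace=False))
    n_diff = int(round(params.differentiating_fraction * n_transfected))
    diff_ids = np.sort(rng.choice(transfected_ids, size=n_diff, replace=False))
    diff_set = set(diff_ids.tolist())

    if params.constriction_scale < 1.0 and n_diff > 0:
        flat = label.ravel()
        keep_mask = np.ones(flat.shape, dtype=bool)
        freed_idx = []
        for cid in diff_ids:
            idx = np.flatnonzero(flat == cid)
            d = np.linalg.norm(pix[idx] - seeds[cid - 1], axis=1)
            k = max(1, int(round(params.constriction_scale * len(idx))))
            order = np.argsort(d, kind="stable")
            freed = idx[order[k:]]
            keep_mask[freed] = False
            freed_idx.append(freed)
        freed_idx = np.concatenate(freed_idx) if freed_idx else np.empty(0, int)
        recipients = np.array([i for i in range(1, n + 1) if i not in diff_set])
        rtree = cKDTree(seeds[recipients - 1])
        _, nearest = rtree.query(pix[freed_idx])
        flat[freed_idx] = recipients[nearest]
        label = flat.reshape(h, w)

    areas = np.bincount(label.ravel(), minlength=n + 1)[1:]

    junction = rng.normal(params.junction_background, params.noise_sd,
                          size=(h, w))
    factors = np.ones(n)
    factors[diff_ids - 1] = params.junction_factor
    objects = ndimage.find_objects(label)
    for cid in range(1, n + 1):
        sl = objects[cid - 1]
        if sl is None:
            continue
        mask = label[sl] == cid
        band = _boundary_band(mask)
        sub = junction[sl]
        sub[band] = (params.junction_background
                     + params.junction_baseline * factors[cid - 1]
                     + rng.normal(0.0, params.noise_sd, size=int(band.sum())))
        junction[sl] = sub
    junction = np.clip(junction, 0, 65535).round().astype(np.uint16)

    transfected = np.zeros(n, dtype=bool)
    transfected[transfected_ids - 1] = True
    differentiating = np.zeros(n, dtype=bool)
    differentiating[diff_ids - 1] = True
    ground_truth = pd.DataFrame({
        "cell_id": np.arange(1, n + 1, dtype=int),
        "transfected": transfected,
        "differentiating": differentiating,
        "true_constriction_scale": np.where(differentiating,
                                            params.constriction_scale, 1.0),
        "true_junction_factor": factors,
        "seed_y": seeds[:, 0],
        "seed_x": seeds[:, 1],
        "area_px": areas,
    })
    return label, junction, ground_truth


# ---------------------------------------------------------------------------
# Cumulative-labeling cohort


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters for a pulse-labeled cohort time-course.

    A cohort of ``n_cells`` divides at t0 (hours).  A fraction
    ``exit_fraction`` exits the cycle at t0 and expresses the neuronal marker
    after a normally distributed differentiation delay; the rest re-enter
    S phase after a normally distributed delay and become EdU+ at the first
    EdU pulse at or after that entry (pulses start ``edu_start_h`` after t0
    and repeat every ``edu_interval_h``, cumulatively).
    """

    n_cells: int = 500
    exit_fraction: float = 0.35
    reentry_delay_mean_h: float = 6.0
    reentry_delay_sd_h: float = 2.0
    reentry_delay_max_h: float = 8.0  # S-phase re-entry within one cycle: labeling saturates by ~12 h
    edu_start_h: float = 3.0
    edu_interval_h: float = 4.0
    diff_delay_mean_h: float = 14.0
    diff_delay_sd_h: float = 4.0
    timepoints_h: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        _check_fraction("exit_fraction", self.exit_fraction)
        tp = np.asarray(self.timepoints_h, dtype=float)
        if len(tp) < 1 or (np.diff(tp) <= 0).any():
            raise ValueError("timepoints_h must be strictly increasing")
        if self.edu_interval_h <= 0:
            raise ValueError("edu_interval_h must be > 0")


def generate_cohort_timecourse(params: CohortSimParams):
    """Simulate a birth-dated cohort under cumulative EdU labeling.

    Returns ``(cohort_table, ground_truth)``.  The cohort table is long-form
    with one row per (cell, timepoint): columns ``cell_id``, ``ft``,
    ``time_h``, ``edu``, ``hucd``.  EdU and neuronal-marker status are
    monotone non-decreasing over time per cell by construction.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    exits = rng.random(n) < params.exit_fraction

    reentry = np.clip(rng.normal(params.reentry_delay_mean_h,
                                 params.reentry_delay_sd_h, size=n),
                      0.0, params.reentry_delay_max_h)
    # first pulse at or after S-phase entry
    k = np.ceil(np.clip(reentry - params.edu_start_h, 0.0, None)
                / params.edu_interval_h)
    t_edu = params.edu_start_h + k * params.edu_interval_h
    t_edu[exits] = np.inf
    t_diff = np.clip(rng.normal(params.diff_delay_mean_h,
                                params.diff_delay_sd_h, size=n), 0.0, None)
    t_diff[~exits] = np.inf

    tp = np.asarray(params.timepoints_h, dtype=float)
    rows = []
    for t in tp:
        rows.append(pd.DataFrame({
            "cell_id": np.arange(1, n + 1, dtype=int),
            "ft": True,
            "time_h": t,
            "edu": t >= t_edu,
            "hucd": t >= t_diff,
        }))
    cohort = pd.concat(rows, ignore_index=True)
    ground_truth = pd.DataFrame({
        "cell_id": np.arange(1, n + 1, dtype=int),
        "exits_cycle": exits,
        "t_s_phase_h": np.where(exits, np.nan, reentry),
        "t_edu_h": np.where(exits, np.nan, t_edu),
        "t_diff_h": np.where(exits, t_diff, np.nan),
    })
    return cohort, ground_truth


def params_to_dict(params) -> dict:
    """JSON-ready echo of a parameter dataclass (written next to outputs)."""
    d = dataclasses.asdict(params)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
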