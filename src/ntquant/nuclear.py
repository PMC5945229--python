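"""Per-nucleus reporter quantification and two-anchor normalization.

The reporter readout of a nucleus is the arithmetic mean of the reporter
channel over the nucleus mask.  Raw intensities are made comparable by a
two-anchor affine normalization: the mean intensity of neurons (marker
HuCD+) is taken as background ``b`` — a Notch-activity reporter falls to
neuron level under pathway blockade — and the mean over the progenitor
anchor set (HuCD−, outside flagged zones) defines ``m``; every value is
mapped to ``v' = (v - b) / (m - b)`` so the neuron anchor averages 0 and the
progenitor anchor averages 1.  Values are not clipped: single nuclei may
fall below 0 or above 1.

Acquisition sessions with different gain are re-anchored with the mean
background-subtracted intensity of HuCD+ nuclei on the non-electroporated
side as a cross-session reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import regionprops_table

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationModel",
    "PaletteSpec",
    "AnchorError",
    "measure_nuclei",
    "estimate_background",
    "fit_normalization",
    "normalize_vnp",
    "cross_session_normalize",
    "fold_change",
    "render_intensity_map",
]


class AnchorError(ValueError):
    """Raised when an anchor set is empty or degenerate."""


@dataclass(frozen=True)
class NormalizationModel:
    """Two-anchor normalization: background ``b`` and progenitor anchor ``m``."""

    background: float
    progenitor_mean: float
    session_factors: dict = field(default_factory=dict)
    reference_statistic: str = "mean background-subtracted HuCD+ intensity, non-electroporated side"

    def __post_init__(self) -> None:
        if not self.progenitor_mean > self.background:
            raise AnchorError(
                f"degenerate anchors: progenitor mean {self.progenitor_mean!r} "
                f"must exceed background {self.background!r}")
        for sid, f in self.session_factors.items():
            if not f > 0:
                raise AnchorError(f"session factor for {sid!r} must be > 0")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.background) / (
            self.progenitor_mean - self.background)


def measure_nuclei(label_image: np.ndarray,
                   channels: dict[str, np.ndarray],
                   markers: pd.DataFrame | None = None,
                   excluded_bands: tuple[tuple[float, float], ...] = (),
                   ) -> pd.DataFrame:
    """Measure every labeled nucleus on the given intensity channels.

    Parameters
    ----------
    label_image
        Integer-labeled nucleus segmentation (0 = background).
    channels
        Mapping of channel name to a co-registered intensity image of the
        same shape.  Each contributes a ``mean_<name>`` column (arithmetic
        mean over the nucleus mask).
    markers
        Optional per-nucleus marker table keyed by a ``label`` column
        (boolean HuCD / EdU / FlashTag / transfected calls, continuous
        Neurog2).  Nuclei without an entry carry explicit "unknown" (NA)
        calls.
    excluded_bands
        Fractional y-ranges flagged as excluded zones; nuclei whose centroid
        falls inside get region "excluded".

    Returns one row per nonzero label with centroid (0-based pixel
    coordinates, origin top-left, y downward), area, moments-based ellipse
    descriptors (full axis lengths, orientation in radians), per-channel mean
    intensities, marker calls, region and side flags.
    """
    label_image = np.asarray(label_image)
    if not np.issubdtype(label_image.dtype, np.integer):
        raise TypeError(f"label image must be integer-typed, got {label_image.dtype}")
    h, w = label_image.shape
    for name, ch in channels.items():
        if ch.shape != label_image.shape:
            raise ValueError(
                f"channel {name!r} shape {ch.shape} != label shape {label_image.shape}")

    if label_image.max() == 0:
        cols = (["label", "centroid_x", "centroid_y", "area", "major_axis",
                 "minor_axis", "orientation"]
                + [f"mean_{n}" for n in channels]
                + ["HuCD", "EdU", "FlashTag", "transfected", "Neurog2",
                   "region", "side", "section_height"])
        return pd.DataFrame(columns=cols)

    names = list(channels)
    stack = np.stack([channels[n] for n in names], axis=-1).astype(float)
    props = regionprops_table(
        label_image, intensity_image=stack,
        properties=("label", "centroid", "area", "axis_major_length",
                    "axis_minor_length", "orientation", "intensity_mean"))
    records = pd.DataFrame({
        "label": props["label"].astype(int),
        "centroid_x": props["centroid-1"],
        "centroid_y": props["centroid-0"],
        "area": props["area"].astype(int),
        "major_axis": props["axis_major_length"],
        "minor_axis": props["axis_minor_length"],
        "orientation": props["orientation"],
    })
    for i, n in enumerate(names):
        records[f"mean_{n}"] = props[f"intensity_mean-{i}"]

    marker_cols = ["HuCD", "EdU", "FlashTag", "transfected", "Neurog2"]
    if markers is not None:
        if markers["label"].duplicated().any():
            dupes = markers.loc[markers["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate label ids in marker table: {dupes}")
        merge_cols = ["label"] + [c for c in marker_cols if c in markers.columns]
        records = records.merge(markers[merge_cols], on="label", how="left")
    for c in marker_cols:
        if c not in records.columns:
            records[c] = pd.NA
    for c in ("HuCD", "EdU", "FlashTag", "transfected"):
        records[c] = records[c].astype("boolean")

    y_frac = records["centroid_y"] / h
    excluded = np.zeros(len(records), dtype=bool)
    for lo, hi in excluded_bands:
        excluded |= (y_frac >= lo).to_numpy() & (y_frac <= hi).to_numpy()
    records["region"] = np.where(excluded, "excluded", "included")
    records["side"] = np.where(records["centroid_x"] < w / 2,
                               "electroporated", "non_electroporated")
    records["section_height"] = h
    return records


def _neuron_anchor(records: pd.DataFrame) -> pd.DataFrame:
    return records[(records["HuCD"] == True) & (records["region"] == "included")]  # noqa: E712


def _progenitor_anchor(records: pd.DataFrame) -> pd.DataFrame:
    return records[(records["HuCD"] == False) & (records["region"] == "included")]  # noqa: E712


def estimate_background(records: pd.DataFrame,
                        channel: str = "vnp") -> float:
    """Background = mean raw reporter intensity over HuCD+ included nuclei."""
    neurons = _neuron_anchor(records)
    if len(neurons) == 0:
        raise AnchorError("no HuCD+ nuclei in the included region to estimate background")
    return float(neurons[f"mean_{channel}"].mean())


def fit_normalization(records: pd.DataFrame, channel: str = "vnp",
                      ) -> NormalizationModel:
    """Fit the two anchors from one record set.

    Neuron anchor: HuCD+ included nuclei.  Progenitor anchor: HuCD− included
    nuclei (flagged zones excluded).
    """
    b = estimate_background(records, channel)
    prog = _progenitor_anchor(records)
    if len(prog) == 0:
        raise AnchorError("no HuCD- nuclei in the included region for the progenitor anchor")
    m = float(prog[f"mean_{channel}"].mean())
    logger.info("normalization anchors: background=%.4g progenitor=%.4g (n=%d/%d)",
                b, m, len(_neuron_anchor(records)), len(prog))
    return NormalizationModel(background=b, progenitor_mean=m)


def normalize_vnp(records: pd.DataFrame, model: NormalizationModel,
                  channel: str = "vnp") -> pd.DataFrame:
    """Attach the normalized intensity column ``norm_<channel>``.

    ``v' = (v - b) / (m - b)``; the neuron anchor set averages 0 and the
    progenitor anchor set averages 1 by construction.  Values are not
    clipped.
    """
    out = records.copy()
    out[f"norm_{channel}"] = model.transform(out[f"mean_{channel}"].to_numpy())
    return out


def cross_session_normalize(sessions: list[pd.DataFrame],
                            channel: str = "vnp") -> list[float]:
    """Per-session scale factors from the shared internal reference.

    For session ``s`` the reference is ``r_s`` = mean background-subtracted
    intensity of HuCD+ nuclei on the non-electroporated side; factors are
    ``f_s = r_1 / r_s`` (first session is unit), making ``f_s * (v - b_s)``
    comparable across sessions.
    """
    refs = []
    for i, records in enumerate(sessions):
        b = estimate_background(records, channel)
        ref = records[(records["HuCD"] == True)  # noqa: E712
                      & (records["side"] == "non_electroporated")]
        if len(ref) == 0:
            raise AnchorError(
                f"session {i} has no HuCD+ nuclei on the non-electroporated side")
        r = float((ref[f"mean_{channel}"] - b).mean())
        if r == 0:
            raise AnchorError(
                f"session {i} reference statistic is zero (the reference "
                "nuclei coincide with the background set); cannot scale")
        refs.append(r)
    factors = [refs[0] / r for r in refs]
    logger.info("cross-session references %s -> factors %s", refs, factors)
    return factors


def fold_change(treated: pd.DataFrame, control: pd.DataFrame,
                channel: str = "vnp") -> float:
    """Ratio of treated to control mean background-subtracted intensity.

    Both sets are restricted to HuCD− nuclei in the included region; each
    set's background is estimated from its own HuCD+ nuclei.
    """
    b_t = estimate_background(treated, channel)
    b_c = estimate_background(control, channel)
    num = float(_progenitor_anchor(treated)[f"mean_{channel}"].mean()) - b_t
    den = float(_progenitor_anchor(control)[f"mean_{channel}"].mean()) - b_c
    if den <= 0:
        raise AnchorError(f"control mean after background subtraction is {den!r} <= 0")
    return num / den


@dataclass(frozen=True)
class PaletteSpec:
    """Ordered intensity bins and colors for the ellipse intensity map.

    ``edges`` are the interior bin boundaries over normalized intensity;
    ``colors`` has ``len(edges) + 1`` RGB rows (under/overflow included).
    The default is 8 equal-width bins over [-0.2, 1.4] through a
    blue-to-yellow ramp, with an extra color for excluded-zone nuclei.
    """

    edges: tuple[float, ...] = tuple(np.linspace(-0.2, 1.4, 9).tolist())
    colors: tuple[tuple[int, int, int], ...] = (
        (20, 20, 90),    # underflow
        (28, 49, 140), (23, 89, 170), (20, 130, 185), (40, 168, 170),
        (95, 195, 130), (170, 212, 80), (230, 215, 50), (255, 190, 30),
        (255, 120, 20),  # overflow
    )
    excluded_color: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if len(self.colors) != len(self.edges) + 1:
            raise ValueError("need len(edges) + 1 colors (under/overflow bins)")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    def bin_index(self, value: float) -> int:
        """Bin of a normalized value; a value exactly on an edge falls in the
        bin above it (edges are lower-inclusive)."""
        return int(np.searchsorted(self.edges, value, side="right"))


def render_intensity_map(records: pd.DataFrame, shape: tuple[int, int],
                         palette: PaletteSpec | None = None,
                         channel: str = "vnp") -> np.ndarray:
    """Redraw every nucleus as a filled ellipse colored by normalized intensity.

    Ellipses are drawn at the recorded centroid with the fitted axes and
    orientation, in ascending label order (later draws overpaint earlier
    ones).  Excluded-zone nuclei are drawn in the palette's excluded color.
    Ellipses extending past the image edge are clipped and logged.
    """
    palette = palette or PaletteSpec()
    h, w = shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    col = f"norm_{channel}"
    if col not in records.columns:
        raise KeyError(f"records lack {col!r}; run normalize_vnp first")
    for row in records.sort_values("label").itertuples():
        a = row.major_axis / 2.0
        b = row.minor_axis / 2.0
        cy, cx = row.centroid_y, row.centroid_x
        if cy - a < 0 or cy + a > h or cx - a < 0 or cx + a > w:
            logger.warning("nucleus %d ellipse clipped at image bounds", row.label)
        if row.region == "excluded":
            color = palette.excluded_color
        else:
            color = palette.colors[palette.bin_index(getattr(row, col))]
        # regionprops orientation is the angle of the major axis from the
        # column axis, counter-clockwise; skimage.draw rotation matches
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=row.orientation)
        img[rr, cc] = color
    return img
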