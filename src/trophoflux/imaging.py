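"""Aggregate polarity and nuclear-intensity quantification.

A scene is a set of registered 2D intensity channels plus a nucleus label
mask (positive integer labels, 0 background) and a binary aggregate mask.
Quantification follows three geometric ideas:

* outer vs inner nuclei — a nucleus is *outer* when its centroid falls
  outside the aggregate mask eroded by roughly one nucleus diameter,
  i.e. it sits in the outermost cell layer;
* the *apical* region — the rim between the end of the outer nuclei and
  the aggregate boundary, operationalized as the aggregate minus the
  filled morphological closing of the union of all nuclei;
* polarity — mean apical intensity of a channel (e.g. aPKCzeta) divided
  by the mean over the remaining non-apical, non-nuclear interior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing as _closing, convex_hull_image, disk, erosion as _erosion
from scipy.ndimage import binary_fill_holes

__all__ = [
    "AggregateScene",
    "PolarityResult",
    "NucleusRecord",
    "sum_project",
    "classify_outer_inner",
    "apical_polarity_ratio",
    "nuclear_intensity_table",
    "aggregate_mask_from_channel",
]

log = logging.getLogger(__name__)


@dataclass
class AggregateScene:
    """Registered channels + nucleus label mask (+ optional aggregate mask)."""

    channels: Mapping[str, np.ndarray]
    nuclei: np.ndarray
    aggregate_mask: np.ndarray | None = None
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()} | {self.nuclei.shape}
        if self.aggregate_mask is not None:
            shapes.add(self.aggregate_mask.shape)
        if len(shapes) != 1:
            raise ValueError(f"rasters disagree in shape: {shapes}")
        if self.nuclei.min() < 0:
            raise ValueError("nucleus labels must be non-negative")

    def mask(self, roi_channel: str = "polarity") -> np.ndarray:
        """The aggregate mask, deriving it from a channel when absent."""
        if self.aggregate_mask is None:
            self.aggregate_mask = aggregate_mask_from_channel(self.channels[roi_channel])
        return self.aggregate_mask.astype(bool)


@dataclass(frozen=True)
class PolarityResult:
    aggregate_id: int | str
    apical_mean: float
    remaining_mean: float
    ratio: float
    valid: bool = True


@dataclass(frozen=True)
class NucleusRecord:
    label: int
    centroid: tuple[float, float]
    layer: str  # "outer" | "inner"
    mean_intensity: float
    value: float  # after background subtraction / normalization


def sum_project(stack: Sequence[np.ndarray] | np.ndarray, n: int) -> np.ndarray:
    """Pixel-wise sum of the ``n`` central slices of an ordered z-stack.

    The window is centered; when the stack length minus ``n`` is odd the
    window starts one slice earlier (left-biased).
    """
    stack = np.asarray(stack)
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(stack) < n:
        raise ValueError(f"stack has {len(stack)} slices; need {n}")
    start = (len(stack) - n) // 2
    return stack[start : start + n].sum(axis=0)


def aggregate_mask_from_channel(channel: np.ndarray) -> np.ndarray:
    """Otsu threshold -> largest connected component -> fill holes."""
    binary = channel > threshold_otsu(channel)
    labels = cc_label(binary)
    if labels.max() == 0:
        raise ValueError("no foreground found in ROI channel")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return binary_fill_holes(labels == largest)


def _nucleus_props(nuclei: np.ndarray):
    props = regionprops(nuclei)
    if not props:
        raise ValueError("empty nucleus label mask")
    return props


def classify_outer_inner(
    scene: AggregateScene, erosion_radius: float | None = None
) -> dict[int, str]:
    """Outer/inner layer per nucleus label.

    A nucleus is outer iff its centroid lies outside the aggregate mask
    eroded by ``erosion_radius`` pixels (default: the median nucleus
    equivalent diameter), i.e. within one cell layer of the boundary.
    """
    mask = scene.mask()
    if not mask.any():
        raise ValueError("aggregate mask is empty")
    props = _nucleus_props(scene.nuclei)
    if erosion_radius is None:
        erosion_radius = float(np.median([p.equivalent_diameter_area for p in props]))
    eroded = _erosion(mask, disk(max(int(round(erosion_radius)), 1)))
    layers = {}
    for p in props:
        r, c = (int(round(v)) for v in p.centroid)
        inside_core = 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and eroded[r, c]
        layers[p.label] = "inner" if inside_core else "outer"
    return layers


def _region_partition(
    scene: AggregateScene, closing_radius: float | None = None, hull: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(nuclear, apical, remaining) masks — disjoint, union = aggregate mask.

    The "end of the outer nuclei" is the boundary of the filled morphological
    closing of the nuclear union (radius: median nucleus radius), optionally
    tightened by its convex hull (default). The closing bridges small gaps
    between neighboring nuclei; the hull removes the residual inward scallops
    between outer nuclei, which otherwise leak interior pixels into the
    apical rim of a convex aggregate. Set ``hull=False`` for markedly
    non-convex aggregates.
    """
    mask = scene.mask()
    nuclear = (scene.nuclei > 0) & mask
    props = _nucleus_props(scene.nuclei)
    if closing_radius is None:
        closing_radius = float(np.median([p.equivalent_diameter_area for p in props])) / 2.0
    closed = binary_fill_holes(
        _closing(scene.nuclei > 0, disk(max(int(round(closing_radius)), 1)))
    )
    if hull:
        closed = convex_hull_image(closed)
    apical = mask & ~closed & ~nuclear
    remaining = mask & ~apical & ~nuclear
    return nuclear, apical, remaining


def apical_polarity_ratio(
    scene: AggregateScene,
    channel: str = "polarity",
    aggregate_id: int | str = 0,
    closing_radius: float | None = None,
    hull: bool = True,
) -> PolarityResult:
    """Mean apical intensity over mean remaining non-nuclear intensity.

    The apical region is the rim between the closed hull of the nuclei and
    the aggregate boundary; the denominator is everything else inside the
    aggregate that is not a nucleus. Either region being empty flags the
    result invalid rather than raising.
    """
    img = scene.channels[channel]
    _, apical, remaining = _region_partition(scene, closing_radius, hull)
    if not apical.any() or not remaining.any():
        log.warning("aggregate %s: empty apical or remaining region", aggregate_id)
        return PolarityResult(aggregate_id, np.nan, np.nan, np.nan, valid=False)
    apical_mean = float(img[apical].mean())
    remaining_mean = float(img[remaining].mean())
    return PolarityResult(
        aggregate_id, apical_mean, remaining_mean, apical_mean / remaining_mean
    )


def nuclear_intensity_table(
    scene: AggregateScene,
    channel: str,
    background: str = "none",
    normalize: str = "none",
    erosion_radius: float | None = None,
) -> list[NucleusRecord]:
    """Per-nucleus mean intensities with optional background subtraction
    and normalization.

    ``background="outside_aggregate"`` subtracts the mean intensity outside
    the aggregate mask (clipped at 0). ``normalize="to_dapi"`` divides each
    nucleus by its own (background-subtracted) DAPI mean;
    ``normalize="to_outer_mean"`` divides by the mean over outer-layer
    nuclei, so the outer layer averages exactly 1.
    """
    if background not in ("none", "outside_aggregate"):
        raise ValueError(f"unknown background mode: {background}")
    if normalize not in ("none", "to_dapi", "to_outer_mean"):
        raise ValueError(f"unknown normalize mode: {normalize}")
    img = scene.channels[channel].astype(float)
    mask = scene.mask()
    layers = classify_outer_inner(scene, erosion_radius)
    props = _nucleus_props(scene.nuclei)

    def bg_of(raster: np.ndarray) -> float:
        if background == "none":
            return 0.0
        outside = ~mask
        return float(raster[outside].mean()) if outside.any() else 0.0

    bg = bg_of(img)
    values = {p.label: max(float(img[scene.nuclei == p.label].mean()) - bg, 0.0) for p in props}
    if normalize == "to_dapi":
        if "dapi" not in scene.channels:
            raise ValueError("to_dapi normalization requires a 'dapi' channel")
        dapi = scene.channels["dapi"].astype(float)
        dapi_bg = bg_of(dapi)
        for p in props:
            d = max(float(dapi[scene.nuclei == p.label].mean()) - dapi_bg, 0.0)
            values[p.label] = values[p.label] / d if d > 0 else np.nan
    elif normalize == "to_outer_mean":
        outer_vals = [values[lab] for lab, layer in layers.items() if layer == "outer"]
        if not outer_vals:
            raise ValueError("no outer nuclei; cannot normalize to outer mean")
        denom = float(np.mean(outer_vals))
        values = {lab: v / denom for lab, v in values.items()}
    return [
        NucleusRecord(
            label=p.label,
            centroid=tuple(p.centroid),
            layer=layers[p.label],
            mean_intensity=float(img[scene.nuclei == p.label].mean()),
            value=values[p.label],
        )
        for p in props
    ]
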