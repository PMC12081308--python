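"""Synthetic aggregate scenes: a circular aggregate, an outer ring of
nuclei plus scattered inner nuclei, and a polarity channel enriched
``a``-fold in the apical rim between the outer nuclei and the contour.

By construction the polarity channel equals ``a * b`` on the rim annulus
(radius in ``[R - rim_width, R)``) and ``b`` elsewhere inside the
aggregate, so the ratio of the two region means is exactly ``a`` in the
noise-free case. Outer nuclei are placed tangent to the rim's inner
boundary at equal angles; inner nuclei are rejection-sampled to avoid
overlaps (bounded retries). Gaussian read noise of sd ``noise_sd`` is
added per pixel when requested.
"""

from __future__ import annotations

import numpy as np

from ..imaging import AggregateScene
from .config import SimConfig

__all__ = ["gen_aggregate_image", "gen_aggregate_scenes", "make_stack"]


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def gen_aggregate_image(
    config: SimConfig, index: int = 0
) -> tuple[AggregateScene, dict]:
    """One scene plus its ground truth (nucleus layers, rim mask, a, b)."""
    cfg = config.image
    rng = config.rng(f"image_{index}")
    size = cfg.size
    center = (size / 2.0, size / 2.0)
    R = cfg.aggregate_radius
    r_n = cfg.nucleus_radius
    rim_inner = R - cfg.rim_width

    aggregate = _disk_mask((size, size), center, R)
    rim = aggregate & ~_disk_mask((size, size), center, rim_inner)

    # outer ring: nuclei tangent to the rim's inner boundary
    ring_radius = rim_inner - r_n
    angles = 2 * np.pi * (np.arange(cfg.n_outer) + rng.uniform()) / cfg.n_outer
    centers = [
        (center[0] + ring_radius * np.sin(t), center[1] + ring_radius * np.cos(t))
        for t in angles
    ]
    layers = {i + 1: "outer" for i in range(cfg.n_outer)}

    # inner nuclei: rejection sampling, bounded retries
    inner_limit = ring_radius - 2 * r_n  # stay clear of the outer ring
    placed = 0
    tries = 0
    while placed < cfg.n_inner:
        tries += 1
        if tries > cfg.max_retries:
            raise RuntimeError(
                f"could not place {cfg.n_inner} non-overlapping inner nuclei "
                f"in {cfg.max_retries} tries"
            )
        rho = (inner_limit - r_n) * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        cand = (center[0] + rho * np.sin(theta), center[1] + rho * np.cos(theta))
        if all(
            (cand[0] - o[0]) ** 2 + (cand[1] - o[1]) ** 2 > (2 * r_n) ** 2 for o in centers
        ):
            centers.append(cand)
            placed += 1
            layers[len(centers)] = "inner"

    nuclei = np.zeros((size, size), dtype=np.int32)
    for lab, c in enumerate(centers, start=1):
        nuclei[_disk_mask((size, size), c, r_n)] = lab

    b = cfg.base_intensity
    polarity = np.zeros((size, size))
    polarity[aggregate] = b
    polarity[rim] = cfg.apical_enrichment * b
    dapi = np.where(nuclei > 0, 4.0 * b, 0.1 * b) * aggregate

    if cfg.noise_sd > 0:
        polarity = np.clip(polarity + rng.normal(0, cfg.noise_sd, polarity.shape), 0, None)
        dapi = np.clip(dapi + rng.normal(0, cfg.noise_sd, dapi.shape), 0, None)

    scene = AggregateScene(
        channels={"polarity": polarity, "dapi": dapi},
        nuclei=nuclei,
        aggregate_mask=aggregate,
    )
    truth = {
        "apical_enrichment": cfg.apical_enrichment,
        "base_intensity": b,
        "rim_mask": rim,
        "layers": layers,
        "center": center,
        "aggregate_radius": R,
    }
    return scene, truth


def gen_aggregate_scenes(config: SimConfig) -> list[tuple[AggregateScene, dict]]:
    """``n_aggregates`` independent scenes from one configuration."""
    return [gen_aggregate_image(config, i) for i in range(config.image.n_aggregates)]


def make_stack(
    plane: np.ndarray, n_slices: int, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """A z-stack built by replicating one plane with per-slice noise."""
    stack = np.repeat(plane[None], n_slices, axis=0).astype(float)
    if noise_sd > 0:
        stack += rng.normal(0, noise_sd, stack.shape)
    return stack
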