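"""Plant-body extraction from a micro-CT scene.

Pipeline (high-intensity artifacts first, then the plant):

1. ``build_pedestal_mask`` — binarize at the high threshold, dilate, and
   restrict to the scene's support (Mask1: pedestal + tube wall);
2. ``subtract_mask`` — zero the masked voxels out of the scene;
3. ``threshold_volume`` — binarize what is left at the plant threshold;
4. ``build_edge_mask`` — edge/rim noise mask (Mask2), subtracted from 3;
5. ``select_plant_component`` — keep one connected component (a seeded
   3D flood fill, or the largest component);
6. re-binarize: restore the full component of step 3 that contains the
   selected core, undoing the rim that edge subtraction shaved off the
   plant's own surface.

Thresholds default to "auto" (Otsu-family); every parameter is
config-overridable because the acquisition-side values are not portable
across scanners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .exceptions import ExtractionError
from .volume_io import BinaryVolume, Volume3D

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ExtractionConfig:
    """Tunable parameters of the extraction pipeline.

    ``high_threshold`` separates pedestal/tube from plant;
    ``plant_threshold`` separates plant from background;
    ``min_component_size`` drives small-speck filtering; the plant
    component is tracked at ``connectivity`` (26 keeps thin sheets
    connected) while noise filtering uses 6-connectivity.
    """

    high_threshold: float | str = "auto"
    plant_threshold: float | str = "auto"
    edge_threshold: float | str = "auto"
    min_component_size: int = 27
    connectivity: int = 26
    mask_dilation_radius: int = 1
    denoise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.denoise_sigma < 0:
            raise ValueError("denoise_sigma must be >= 0")
        if self.min_component_size < 1:
            raise ValueError(
                f"min_component_size must be >= 1, got {self.min_component_size}"
            )
        if self.connectivity not in (6, 18, 26):
            raise ValueError(
                f"connectivity must be one of 6, 18, 26, got {self.connectivity}"
            )
        if self.mask_dilation_radius < 0:
            raise ValueError("mask_dilation_radius must be >= 0")
        for fname in ("high_threshold", "plant_threshold", "edge_threshold"):
            t = getattr(self, fname)
            if isinstance(t, str):
                if t != "auto":
                    raise ValueError(f"{fname} must be a number or 'auto', got {t!r}")
            elif not np.isfinite(t):
                raise ValueError(f"{fname} must be finite, got {t}")


def _resolve_threshold(data: np.ndarray, t: float | str,
                       tier: str | None = None) -> float:
    """Resolve a numeric or "auto" threshold.

    ``tier`` picks which of the 3-class multi-Otsu thresholds applies to a
    pedestal scene (background | plant | pedestal+tube): "high" separates
    the plant from the brighter artifacts, "low" the background from the
    plant.  Without a tier, plain Otsu.
    """
    if not isinstance(t, str):
        return float(t)
    if data.max() == data.min():
        raise ValueError(
            "no threshold separates the histogram: volume has constant intensity"
        )
    if tier is not None:
        try:
            thresholds = threshold_multiotsu(data, classes=3)
            return float(thresholds[-1] if tier == "high" else thresholds[0])
        except ValueError:
            pass  # fewer than 3 distinguishable classes
    return float(threshold_otsu(data))


def threshold_volume(v: Volume3D, t: float | str = "auto") -> BinaryVolume:
    """Binarize: voxel = 1 iff intensity >= t ("auto": Otsu's criterion)."""
    t = _resolve_threshold(v.data, t)
    return BinaryVolume(data=v.data >= t, spacing=v.spacing, name=v.name)


def build_pedestal_mask(v: Volume3D, cfg: ExtractionConfig) -> BinaryVolume:
    """Mask1: high-intensity binarization, dilated, restricted to the
    scene's support (voxels with positive intensity)."""
    t = _resolve_threshold(v.data, cfg.high_threshold, tier="high")
    mask = v.data >= t
    if cfg.mask_dilation_radius > 0 and mask.any():
        mask = ndimage.binary_dilation(
            mask, structure=_STRUCTURES[6], iterations=cfg.mask_dilation_radius
        )
        mask &= v.data > 0
    return BinaryVolume(data=mask, spacing=v.spacing, name=v.name)


def subtract_mask(v: Volume3D, m: BinaryVolume) -> Volume3D:
    """Zero the masked voxels; leave the rest unchanged."""
    if v.shape != m.shape:
        raise ValueError(f"shape mismatch: volume {v.shape} vs mask {m.shape}")
    return Volume3D(data=np.where(m.data, 0, v.data), spacing=v.spacing, name=v.name)


def build_edge_mask(b: BinaryVolume, cfg: ExtractionConfig) -> BinaryVolume:
    """Mask2: the binarized gradient of the mask (its one-voxel inner
    boundary shell), with edge components smaller than
    ``min_component_size`` dropped.

    On a residual one-voxel pedestal rim the shell is the whole rim, so
    subtracting Mask2 deletes it; on a solid body it is only the surface
    layer, which the flood-fill restore step of :func:`extract_plant`
    puts back.
    """
    edge = b.data & ~ndimage.binary_erosion(b.data, structure=_STRUCTURES[6])
    if edge.any() and cfg.min_component_size > 1:
        labels, n = ndimage.label(edge, structure=_STRUCTURES[6])
        counts = np.bincount(labels.ravel())
        keep = counts >= cfg.min_component_size
        keep[0] = False
        edge = keep[labels]
    return BinaryVolume(data=edge, spacing=b.spacing, name=b.name)


def select_plant_component(b: BinaryVolume, cfg: ExtractionConfig,
                           seed_point: tuple[int, int, int] | str = "largest",
                           ) -> BinaryVolume:
    """Keep exactly one connected component under ``cfg.connectivity``.

    With ``seed_point`` a (z, y, x) index, this is a seeded 3D flood fill;
    with "largest" the biggest component wins, ties broken by the smallest
    (z, y, x) of each component's minimum voxel.
    """
    if not b.data.any():
        raise ExtractionError("empty foreground: nothing to select")
    labels, n = ndimage.label(b.data, structure=_STRUCTURES[cfg.connectivity])
    if seed_point != "largest":
        z, y, x = seed_point
        lab = int(labels[z, y, x])
        if lab == 0:
            raise ExtractionError(f"seed point {tuple(seed_point)} is on background")
    else:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        best = counts.max()
        candidates = np.flatnonzero(counts == best)
        if len(candidates) == 1:
            lab = int(candidates[0])
        else:
            # first foreground voxel in C order is the lexicographic minimum
            flat = labels.ravel()
            firsts = [np.argmax(flat == c) for c in candidates]
            lab = int(candidates[int(np.argmin(firsts))])
    return BinaryVolume(data=labels == lab, spacing=b.spacing, name=b.name)


def extract_plant(v: Volume3D, cfg: ExtractionConfig | None = None,
                  seed_point: tuple[int, int, int] | str = "largest",
                  debug: dict | None = None) -> BinaryVolume:
    """Run the full extraction pipeline on a micro-CT scene.

    Stage failures are re-raised as :class:`ExtractionError` annotated
    with the stage name.  Per-stage voxel counts are logged, and the
    intermediate masks are stored in ``debug`` when a dict is passed.
    """
    cfg = cfg or ExtractionConfig()
    if cfg.denoise_sigma > 0:
        v = Volume3D(
            data=ndimage.gaussian_filter(np.asarray(v.data, dtype=float),
                                         cfg.denoise_sigma),
            spacing=v.spacing, name=v.name,
        )
        logger.info("denoised scene with Gaussian sigma %.3g", cfg.denoise_sigma)
    counts: dict[str, int] = {}

    def _stage(name, fn):
        try:
            out = fn()
        except ExtractionError as exc:
            raise ExtractionError(f"[{name}] {exc}") from exc
        except Exception as exc:
            raise ExtractionError(f"[{name}] {type(exc).__name__}: {exc}") from exc
        n = int(out.data.sum()) if isinstance(out, BinaryVolume) else int(
            np.count_nonzero(out.data))
        counts[name] = n
        logger.info("extract stage %-18s: %d voxels", name, n)
        if debug is not None:
            debug[name] = out
        return out

    mask1 = _stage("pedestal_mask", lambda: build_pedestal_mask(v, cfg))
    residual = _stage("subtract_pedestal", lambda: subtract_mask(v, mask1))
    # the plant threshold is estimated on the *original* histogram (lower
    # 3-class multi-Otsu threshold) so that a plant-free residual (noise
    # only) yields an empty binarization rather than an Otsu split of
    # pure noise
    plant_t = _resolve_threshold(v.data, cfg.plant_threshold, tier="low")
    binarized = _stage("binarize_plant",
                       lambda: threshold_volume(residual, plant_t))
    mask2 = _stage("edge_mask", lambda: build_edge_mask(binarized, cfg))
    cleaned = _stage("subtract_edges", lambda: BinaryVolume(
        data=binarized.data & ~mask2.data, spacing=v.spacing, name=v.name))
    if not cleaned.data.any() or cleaned.count() < cfg.min_component_size:
        raise ExtractionError("[select_component] no plant component found")
    core = _stage("select_component",
                  lambda: select_plant_component(cleaned, cfg, seed_point))
    if core.count() < cfg.min_component_size:
        raise ExtractionError("[select_component] no plant component found")

    def _restore():
        labels, _ = ndimage.label(binarized.data,
                                  structure=_STRUCTURES[cfg.connectivity])
        keep = np.unique(labels[core.data])
        keep = keep[keep != 0]
        return BinaryVolume(data=np.isin(labels, keep), spacing=v.spacing,
                            name=v.name)

    plant = _stage("final_binarize", _restore)
    if debug is not None:
        debug["voxel_counts"] = counts
    return plant
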