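"""ROI placement and the perivascular-space (ALPS) diffusivity index.

At the level of the lateral-ventricle body the perivascular space runs
right-left (x), perpendicular to both the projection fibers (z) and the
association fibers (y).  The ALPS index is the ratio of mean x-axis
diffusivity in the two fiber areas to the mean diffusivity perpendicular
to each fiber population and to x:

    ALPS = ((Dxx_proj + Dxx_assoc) / 2) / ((Dyy_proj + Dzz_assoc) / 2)

Values near 1 indicate minimal diffusion along the perivascular space.
Measurements are taken from the left hemisphere by convention (the
dominant side in right-handed cohorts, where these tracts are thicker).
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple, Union

import numpy as np

from . import tensor_model
from .types import (
    COMPONENT_NAMES,
    REPORT_SCALE,
    AlpsResult,
    DWIVolume,
    RoiSet,
    TensorField,
    ValidationError,
)

_DEFAULT_ROI_LABELS = {"projection": 2, "association": 3}


def hemisphere_mask(grid_shape: Tuple[int, int, int], hemisphere: str) -> np.ndarray:
    """Half-space mask along x.  With +x pointing right (RAS-like
    orientation), the left hemisphere occupies the lower x indices."""
    nx = grid_shape[0]
    x = np.arange(nx)
    if hemisphere == "left":
        keep = x < nx / 2
    elif hemisphere == "right":
        keep = x >= nx / 2
    else:
        raise ValidationError(f"unknown hemisphere {hemisphere!r}")
    return np.broadcast_to(keep[:, None, None], grid_shape).copy()


def _sphere_mask(grid_shape, center, radius_mm, voxel_size) -> np.ndarray:
    center = np.asarray(center, dtype=float)
    voxel_size = np.asarray(voxel_size, dtype=float)
    grids = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    dist2 = sum(
        ((g - c) * s) ** 2 for g, c, s in zip(grids, center, voxel_size)
    )
    return dist2 <= float(radius_mm) ** 2


def place_rois(
    source: Union[np.ndarray, Dict],
    mask: np.ndarray,
    voxel_size=(1.0, 1.0, 1.0),
    hemisphere: Optional[str] = "left",
    labels: Dict[str, int] = _DEFAULT_ROI_LABELS,
) -> RoiSet:
    """Build projection/association ROIs from a label volume or a config.

    ``source`` is either an integer label volume (projection/association
    labels taken verbatim) or a config dict
    ``{"projection": {"center": [i, j, k], "radius_mm": r}, "association":
    {...}}`` placing spheres (default radius 5 mm) clipped to the brain
    mask.  ``hemisphere`` restricts both ROIs to one x-half-space; pass
    None to keep both sides.
    """
    mask = np.asarray(mask, dtype=bool)
    restrict = (
        hemisphere_mask(mask.shape, hemisphere) if hemisphere is not None else True
    )
    rois = {}
    if isinstance(source, np.ndarray):
        if source.shape != mask.shape:
            raise ValidationError("label volume grid does not match the mask grid")
        for name, lab in labels.items():
            rois[name] = (source == lab) & mask & restrict
        provenance = "ground-truth-labels"
    elif isinstance(source, dict):
        for name in ("projection", "association"):
            if name not in source:
                raise ValidationError(f"ROI config lacks the {name!r} entry")
            cfg = source[name]
            sphere = _sphere_mask(
                mask.shape, cfg["center"], cfg.get("radius_mm", 5.0), voxel_size
            )
            rois[name] = sphere & mask & restrict
        provenance = "config-spheres"
    else:
        raise ValidationError(
            f"ROI source must be a label volume or config dict, got {type(source)}"
        )
    for name, roi in rois.items():
        if not roi.any():
            raise ValidationError(
                f"{name} ROI is empty after clipping to the brain mask"
                + (f" and {hemisphere} hemisphere" if hemisphere else "")
            )
    return RoiSet(
        projection_mask=rois["projection"],
        association_mask=rois["association"],
        hemisphere=hemisphere,
        provenance=provenance,
    )


def extract_component_means(
    field: TensorField, roi: RoiSet
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Arithmetic mean of each tensor component over each ROI.

    Returns (projection_means, association_means) in 1e-3 mm^2/s, the
    conventional reporting unit.
    """
    if roi.projection_mask.shape != field.grid_shape:
        raise ValidationError("ROI grid does not match the tensor field grid")
    out = []
    for name, roi_mask in (
        ("projection", roi.projection_mask),
        ("association", roi.association_mask),
    ):
        sel = roi_mask & field.mask
        if not sel.any():
            raise ValidationError(f"{name} ROI has no in-brain voxels")
        vals = field.components[sel, :]  # (V, 6) in mm^2/s
        out.append(
            {comp: float(REPORT_SCALE * vals[:, k].mean()) for k, comp in enumerate(COMPONENT_NAMES)}
        )
    return out[0], out[1]


def alps_index(
    dxx_pro: float, dxx_asc: float, dyy_pro: float, dzz_asc: float
) -> Tuple[float, float, float]:
    """ALPS index from the four diffusivities (any consistent unit).

    Returns (alps, d_xmean, d_yzmean) with d_xmean = (Dxx_proj +
    Dxx_assoc)/2 and d_yzmean = (Dyy_proj + Dzz_assoc)/2.
    """
    for name, v in (
        ("dxx_pro", dxx_pro),
        ("dxx_asc", dxx_asc),
        ("dyy_pro", dyy_pro),
        ("dzz_asc", dzz_asc),
    ):
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"{name} must be a positive finite diffusivity, got {v}")
    d_xmean = (dxx_pro + dxx_asc) / 2.0
    d_yzmean = (dyy_pro + dzz_asc) / 2.0
    return d_xmean / d_yzmean, d_xmean, d_yzmean


def build_alps_result(
    projection: Dict[str, float], association: Dict[str, float]
) -> AlpsResult:
    """Assemble an AlpsResult from the 12 component means (1e-3 mm^2/s)."""
    alps, d_xmean, d_yzmean = alps_index(
        projection["dxx"], association["dxx"], projection["dyy"], association["dzz"]
    )
    clamp = lambda d: {k: max(v, 0.0) for k, v in d.items()}
    return AlpsResult(
        projection=clamp(projection),
        association=clamp(association),
        d_xmean=d_xmean,
        d_yzmean=d_yzmean,
        alps_index=alps,
    )


def subject_alps(
    dwi: DWIVolume,
    roi_source: Union[np.ndarray, Dict],
    fit_method: str = "wls",
    noise_k: float = 2.0,
    eig_floor: float = tensor_model.DEFAULT_EIG_FLOOR,
    hemisphere: Optional[str] = "left",
    background: Optional[np.ndarray] = None,
) -> AlpsResult:
    """End-to-end per-subject run: threshold, mask, fit, ROI means, ALPS."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    threshold = stage(
        "noise-threshold",
        tensor_model.estimate_noise_threshold,
        dwi,
        background=background,
        k=noise_k,
    )
    mask = stage("brain-mask", tensor_model.brain_mask, dwi, threshold)
    field = stage(
        "tensor-fit",
        tensor_model.fit_tensor_field,
        dwi,
        mask,
        method=fit_method,
        eig_floor=eig_floor,
    )
    roi = stage(
        "roi-placement",
        place_rois,
        roi_source,
        field.mask,
        voxel_size=dwi.voxel_size,
        hemisphere=hemisphere,
    )
    proj, assoc = stage("roi-means", extract_component_means, field, roi)
    return stage("alps", build_alps_result, proj, assoc)
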