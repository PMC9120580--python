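"""Core domain types shared across the pipeline.

Axis convention: voxel axis 0 is x (right-left), axis 1 is y
(anterior-posterior), axis 2 is z (inferior-superior).  Volumes are stored
in "RAS"-like orientation: +x points toward the subject's right, so the
left hemisphere occupies the *lower* x indices.  Diffusivities are kept in
mm^2/s internally; conversion to the conventional reporting unit of
1e-3 mm^2/s happens exactly once, at the ROI-mean reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: canonical ordering of the six unique tensor components
COMPONENT_NAMES = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")

#: scale factor between internal units (mm^2/s) and reporting units
REPORT_SCALE = 1e3


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class ConfigurationError(ValueError):
    """A spec/config object is internally inconsistent."""


@dataclass
class GradientScheme:
    """Diffusion acquisition scheme: one (b-value, direction) per frame.

    bvals are in s/mm^2; bvecs are unit direction cosines (rows).  Frames
    with b == 0 may carry zero vectors.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValidationError(
                f"bvecs must be (n_frames, 3); got shape {self.bvecs.shape}"
            )
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"frame count mismatch: {len(self.bvals)} b-values vs "
                f"{len(self.bvecs)} gradient directions"
            )
        if np.any(self.bvals < 0) or not np.all(np.isfinite(self.bvals)):
            raise ValidationError("b-values must be finite and non-negative")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        bad = dw & (np.abs(norms - 1.0) > 1e-3)
        if np.any(bad):
            raise ValidationError(
                f"non-unit gradient direction at b>0 frames {np.where(bad)[0].tolist()}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def validate_for_fit(self) -> None:
        """Require >=1 b0 frame and >=6 non-collinear diffusion directions."""
        if not np.any(self.b0_mask):
            raise ValidationError("tensor fitting requires at least one b=0 frame")
        g = self.bvecs[~self.b0_mask]
        if len(g) < 6:
            raise ValidationError(
                f"tensor fitting requires >=6 diffusion-weighted frames, got {len(g)}"
            )
        quad = np.column_stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ]
        )
        if np.linalg.matrix_rank(quad) < 6:
            raise ValidationError(
                "gradient directions are collinear/coplanar: quadratic design has "
                f"rank {np.linalg.matrix_rank(quad)} < 6"
            )


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal plus its acquisition scheme."""

    data: np.ndarray
    scheme: GradientScheme
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: Optional[np.ndarray] = None
    axis_convention: str = "RAS (x: right-left, y: anterior-posterior, z: inferior-superior)"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.data.ndim != 4:
            raise ValidationError(f"DWI data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[3] != self.scheme.n_frames:
            raise FormatError(
                f"frame count mismatch: data has {self.data.shape[3]} frames, "
                f"scheme has {self.scheme.n_frames}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("DWI data contains non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("DWI magnitudes must be non-negative")
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValidationError("voxel_size must be three strictly positive values")
        if self.affine is None:
            self.affine = np.diag(np.append(self.voxel_size, 1.0))

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class TensorField:
    """Voxel-wise symmetric diffusion tensor, six unique components.

    components[..., k] follows COMPONENT_NAMES ordering, in mm^2/s.
    Out-of-mask voxels carry zero components.
    """

    components: np.ndarray
    s0_map: np.ndarray
    mask: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.s0_map = np.asarray(self.s0_map, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.components.ndim != 4 or self.components.shape[3] != 6:
            raise ValidationError(
                f"components must be (nx, ny, nz, 6), got {self.components.shape}"
            )
        if self.mask.shape != self.components.shape[:3]:
            raise ValidationError("mask and components grids differ")
        if self.s0_map.shape != self.mask.shape:
            raise ValidationError("s0_map and mask grids differ")
        if self.affine is None:
            self.affine = np.diag(np.append(self.voxel_size, 1.0))

    @property
    def grid_shape(self) -> tuple:
        return self.components.shape[:3]

    def tensors(self) -> np.ndarray:
        """Assemble (..., 3, 3) symmetric matrices from the six components."""
        c = self.components
        dxx, dyy, dzz = c[..., 0], c[..., 1], c[..., 2]
        dxy, dxz, dyz = c[..., 3], c[..., 4], c[..., 5]
        out = np.empty(c.shape[:-1] + (3, 3), dtype=float)
        out[..., 0, 0] = dxx
        out[..., 1, 1] = dyy
        out[..., 2, 2] = dzz
        out[..., 0, 1] = out[..., 1, 0] = dxy
        out[..., 0, 2] = out[..., 2, 0] = dxz
        out[..., 1, 2] = out[..., 2, 1] = dyz
        return out


@dataclass
class RoiSet:
    """Projection- and association-fiber ROI masks (single hemisphere)."""

    projection_mask: np.ndarray
    association_mask: np.ndarray
    hemisphere: Optional[str] = "left"
    provenance: str = "ground-truth-labels"

    def __post_init__(self) -> None:
        self.projection_mask = np.asarray(self.projection_mask, dtype=bool)
        self.association_mask = np.asarray(self.association_mask, dtype=bool)
        if self.projection_mask.shape != self.association_mask.shape:
            raise ValidationError("ROI masks have different grids")
        if not self.projection_mask.any():
            raise ValidationError("projection ROI is empty")
        if not self.association_mask.any():
            raise ValidationError("association ROI is empty")
        if np.any(self.projection_mask & self.association_mask):
            raise ValidationError("projection and association ROIs overlap")


@dataclass
class AlpsResult:
    """Per-subject ROI component means (1e-3 mm^2/s) and the ALPS index."""

    projection: dict
    association: dict
    d_xmean: float
    d_yzmean: float
    alps_index: float

    def to_row(self) -> dict:
        row = {}
        for comp in COMPONENT_NAMES:
            row[f"{comp}_proj"] = self.projection[comp]
        for comp in COMPONENT_NAMES:
            row[f"{comp}_assoc"] = self.association[comp]
        row["d_xmean"] = self.d_xmean
        row["d_yzmean"] = self.d_yzmean
        row["alps"] = self.alps_index
        return row


@dataclass
class SubjectRecord:
    """Clinical covariates and severity measures for one participant.

    Optional clinical fields use None as an explicit missing marker;
    statistics apply pairwise deletion, never zero-filling.
    """

    id: str
    group: str  # "OSA" | "control"
    age: float
    sex: str  # "male" | "female"
    bmi: Optional[float] = None
    heart_rate: Optional[float] = None
    systolic_bp: Optional[float] = None
    diastolic_bp: Optional[float] = None
    ahi: Optional[float] = None
    sao2_nadir: Optional[float] = None
    sao2_baseline: Optional[float] = None
    psqi: Optional[float] = None
    ess: Optional[float] = None
    alps: Optional[AlpsResult] = None

    def __post_init__(self) -> None:
        if self.group not in ("OSA", "control"):
            raise ValidationError(f"unknown group label: {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex label: {self.sex!r}")
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValidationError(f"age must be positive and finite, got {self.age}")
        for name in ("sao2_nadir", "sao2_baseline"):
            v = getattr(self, name)
            if v is not None and not (0 < v <= 100):
                raise ValidationError(f"{name} must lie in (0, 100], got {v}")
        if self.ahi is not None and self.ahi < 0:
            raise ValidationError(f"AHI must be non-negative, got {self.ahi}")

    @property
    def delta_sao2(self) -> Optional[float]:
        if self.sao2_baseline is None or self.sao2_nadir is None:
            return None
        return self.sao2_baseline - self.sao2_nadir
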