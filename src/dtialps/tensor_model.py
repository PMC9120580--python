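"""Voxel-wise diffusion tensor estimation and derived maps.

The tensor is fitted by log-linearising the monoexponential signal model

    S_i = S0 * exp(-b_i * g_i^T D g_i)

into a 7-parameter least-squares problem (six unique tensor components
plus ln S0).  The default estimator is weighted least squares with one
reweighting pass from the OLS solution, weights equal to the squared
predicted signals — the standard correction for the log-transformed noise
variance.  Eigenvalues below a small positive floor are clamped so that
diffusivities stay physical and FA stays defined for noisy fits.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np

from .types import DWIVolume, GradientScheme, TensorField, ValidationError

logger = logging.getLogger(__name__)

#: eigenvalue floor in mm^2/s applied after fitting
DEFAULT_EIG_FLOOR = 1e-6

#: relative signal floor (fraction of the per-voxel b0 estimate) before log
SIGNAL_FLOOR_FRACTION = 1e-3


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(n_frames, 7) design for ln S = A @ [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz, ln S0]."""
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones_like(b),
        ]
    )


def estimate_noise_threshold(
    dwi: DWIVolume,
    background: Optional[np.ndarray] = None,
    k: float = 2.0,
    corner_size: int = 2,
) -> float:
    """Noise threshold from background magnitudes: mean + k * SD.

    If no background mask is given, cubic patches at the eight grid
    corners are used — in both the phantoms and typical axial acquisitions
    those lie outside the object.  Values are pooled over all frames.
    """
    if background is None:
        background = np.zeros(dwi.grid_shape, dtype=bool)
        nx, ny, nz = dwi.grid_shape
        c = corner_size
        for sx in (slice(0, c), slice(nx - c, nx)):
            for sy in (slice(0, c), slice(ny - c, ny)):
                for sz in (slice(0, c), slice(nz - c, nz)):
                    background[sx, sy, sz] = True
    background = np.asarray(background, dtype=bool)
    if not background.any():
        raise ValidationError("background region is empty")
    values = dwi.data[background, :].ravel()
    return float(values.mean() + k * values.std())


def brain_mask(dwi: DWIVolume, threshold: float) -> np.ndarray:
    """In-brain voxels: mean b0 signal strictly above the threshold."""
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    b0 = dwi.data[..., dwi.scheme.b0_mask].mean(axis=3)
    return b0 > threshold


def _fit_beta(A: np.ndarray, log_s: np.ndarray, method: str) -> np.ndarray:
    """Solve the log-linear problem for many voxels at once.

    A: (F, 7); log_s: (V, F).  Returns beta (V, 7).
    """
    beta_ols, *_ = np.linalg.lstsq(A, log_s.T, rcond=None)
    beta = beta_ols.T
    if method == "wls":
        pred = beta @ A.T  # (V, F) predicted log-signals
        w = np.exp(2.0 * np.clip(pred, -700, 700))  # squared predicted signals
        M = np.einsum("fi,vf,fj->vij", A, w, A)
        rhs = np.einsum("fi,vf->vi", A, w * log_s)
        beta = np.linalg.solve(M, rhs[..., None])[..., 0]
    elif method != "ols":
        raise ValueError(f"unknown fit method {method!r}")
    return beta


def _clamp_eigenvalues(components: np.ndarray, floor: float) -> np.ndarray:
    """Clamp eigenvalues below `floor`; untouched voxels keep exact values."""
    c = components
    tens = np.empty(c.shape[:-1] + (3, 3))
    tens[..., 0, 0] = c[..., 0]
    tens[..., 1, 1] = c[..., 1]
    tens[..., 2, 2] = c[..., 2]
    tens[..., 0, 1] = tens[..., 1, 0] = c[..., 3]
    tens[..., 0, 2] = tens[..., 2, 0] = c[..., 4]
    tens[..., 1, 2] = tens[..., 2, 1] = c[..., 5]
    evals, evecs = np.linalg.eigh(tens)
    needs = (evals < floor).any(axis=-1)
    if not needs.any():
        return c
    out = c.copy()
    ev = np.clip(evals[needs], floor, None)
    rebuilt = np.einsum("vij,vj,vkj->vik", evecs[needs], ev, evecs[needs])
    out[needs, 0] = rebuilt[:, 0, 0]
    out[needs, 1] = rebuilt[:, 1, 1]
    out[needs, 2] = rebuilt[:, 2, 2]
    out[needs, 3] = rebuilt[:, 0, 1]
    out[needs, 4] = rebuilt[:, 0, 2]
    out[needs, 5] = rebuilt[:, 1, 2]
    return out


def fit_tensor_voxel(
    signals: np.ndarray,
    scheme: GradientScheme,
    method: str = "wls",
    eig_floor: float = DEFAULT_EIG_FLOOR,
) -> Tuple[np.ndarray, float]:
    """Fit one voxel; returns (six components in mm^2/s, S0)."""
    scheme.validate_for_fit()
    signals = np.asarray(signals, dtype=float).ravel()
    if len(signals) != scheme.n_frames:
        raise ValidationError(
            f"{len(signals)} signals for a {scheme.n_frames}-frame scheme"
        )
    s0_est = signals[scheme.b0_mask].mean()
    floor = SIGNAL_FLOOR_FRACTION * max(s0_est, np.finfo(float).tiny)
    log_s = np.log(np.maximum(signals, floor))[None, :]
    beta = _fit_beta(design_matrix(scheme), log_s, method)[0]
    comps = _clamp_eigenvalues(beta[None, :6], eig_floor)[0]
    return comps, float(np.exp(beta[6]))


def fit_tensor_field(
    dwi: DWIVolume,
    mask: np.ndarray,
    method: str = "wls",
    eig_floor: float = DEFAULT_EIG_FLOOR,
) -> TensorField:
    """Voxel-wise tensor fit over the mask; failed voxels are masked out."""
    dwi.scheme.validate_for_fit()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.grid_shape:
        raise ValidationError("mask grid does not match the DWI grid")
    if not mask.any():
        raise ValidationError("brain mask is empty; nothing to fit")

    signals = dwi.data[mask, :]  # (V, F)
    s0_est = signals[:, dwi.scheme.b0_mask].mean(axis=1)
    floor = SIGNAL_FLOOR_FRACTION * np.maximum(s0_est, np.finfo(float).tiny)
    log_s = np.log(np.maximum(signals, floor[:, None]))
    beta = _fit_beta(design_matrix(dwi.scheme), log_s, method)

    ok = np.all(np.isfinite(beta), axis=1)
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("tensor fit failed in %d voxels; masking them out", n_failed)
    comps = np.zeros_like(beta[:, :6])
    comps[ok] = _clamp_eigenvalues(beta[ok, :6], eig_floor)

    components = np.zeros(dwi.grid_shape + (6,))
    s0_map = np.zeros(dwi.grid_shape)
    out_mask = np.zeros(dwi.grid_shape, dtype=bool)
    idx = np.where(mask)
    components[idx] = comps
    s0_map[idx] = np.where(ok, np.exp(np.clip(beta[:, 6], -700, 700)), 0.0)
    out_mask[idx] = ok
    components[~out_mask] = 0.0
    return TensorField(
        components=components,
        s0_map=s0_map,
        mask=out_mask,
        voxel_size=dwi.voxel_size,
        affine=dwi.affine,
    )


def fractional_anisotropy(field: TensorField) -> Tuple[np.ndarray, np.ndarray]:
    """FA map and colour-FA (|principal eigenvector| * FA per RGB channel).

    FA = sqrt(3/2) * sqrt(sum((l_i - l_mean)^2)) / sqrt(sum(l_i^2)), zero
    where the tensor is all-zero.
    """
    tens = field.tensors()
    evals, evecs = np.linalg.eigh(tens)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(((evals - mean) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    fa = np.clip(np.where(field.mask, fa, 0.0), 0.0, 1.0)
    principal = evecs[..., :, 2]  # eigenvector of the largest eigenvalue
    color = np.abs(principal) * fa[..., None]
    return fa, color
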