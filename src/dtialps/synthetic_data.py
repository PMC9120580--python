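"""Digital DWI phantoms and synthetic cohorts.

The phantom encodes the periventricular geometry the perivascular-space
(ALPS) analysis relies on: a midline lateral-ventricle slab, a
projection-fiber shell adjacent to it (principal axis z,
inferior-superior), an association-fiber shell lateral to that (principal
axis y, anterior-posterior, the superior-longitudinal-fasciculus
analogue), and a subcortical shell outside (principal axis x).  Medullary
veins and the perivascular space at this level run right-left (x), so a
single "glymphatic factor" g scales the x-axis diffusivity of both fiber
shells; the ground-truth ALPS index is then computable in closed form.

The cohort generator draws per-subject ROI component means and clinical
covariates from per-group truncated normal distributions whose defaults
are the published OSA/control group means and SDs; a rank-correlation can
be planted between a clinical variable and a diffusivity component via a
Gaussian copula.  Measurement noise on simulated DWI magnitudes is Rician
(|S + n1 + i n2|), the distribution magnitude reconstruction produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .imaging_io import cohort_frame
from .types import (
    COMPONENT_NAMES,
    ConfigurationError,
    DWIVolume,
    GradientScheme,
    SubjectRecord,
    TensorField,
    ValidationError,
)
from .alps import alps_index, build_alps_result

REGION_LABELS = {
    "background": 0,
    "ventricle": 1,
    "projection": 2,
    "association": 3,
    "subcortical": 4,
}

#: per-region principal diffusivities (dxx, dyy, dzz) in mm^2/s; fiber
#: regions default to the published OSA group means
DEFAULT_REGION_DIFFUSIVITIES = {
    "ventricle": (3.0e-3, 3.0e-3, 3.0e-3),
    "projection": (0.73e-3, 0.58e-3, 0.90e-3),
    "association": (0.70e-3, 0.98e-3, 0.49e-3),
    "subcortical": (0.90e-3, 0.50e-3, 0.50e-3),
}

#: published per-group ROI component means and SDs, in 1e-3 mm^2/s
GROUP_COMPONENT_PARAMS = {
    "OSA": {
        "projection": {
            "dxx": (0.73, 0.04),
            "dxy": (0.05, 0.01),
            "dxz": (0.048, 0.02),
            "dyy": (0.58, 0.05),
            "dyz": (0.202, 0.02),
            "dzz": (0.90, 0.06),
        },
        "association": {
            "dxx": (0.70, 0.07),
            "dxy": (0.12, 0.03),
            "dxz": (0.07, 0.02),
            "dyy": (0.98, 0.07),
            "dyz": (0.09, 0.03),
            "dzz": (0.49, 0.05),
        },
    },
    "control": {
        "projection": {
            "dxx": (0.72, 0.04),
            "dxy": (0.04, 0.01),
            "dxz": (0.046, 0.02),
            "dyy": (0.57, 0.05),
            "dyz": (0.20, 0.02),
            "dzz": (0.94, 0.06),
        },
        "association": {
            "dxx": (0.69, 0.07),
            "dxy": (0.13, 0.03),
            "dxz": (0.06, 0.02),
            "dyy": (1.01, 0.07),
            "dyz": (0.10, 0.03),
            "dzz": (0.46, 0.05),
        },
    },
}

#: published per-group ALPS index mean and SD (used by the direct draw path)
GROUP_ALPS_PARAMS = {"OSA": (1.34, 0.11), "control": (1.38, 0.11)}

#: published per-group clinical means and SDs; (mean, sd, lower, upper)
GROUP_CLINICAL_PARAMS = {
    "OSA": {
        "age": (49.9, 10.0, 18.0, np.inf),
        "bmi": (31.8, 5.5, 10.0, np.inf),
        "heart_rate": (72.5, 12.6, 20.0, np.inf),
        "systolic_bp": (126.3, 17.0, 50.0, np.inf),
        "diastolic_bp": (79.5, 10.6, 30.0, np.inf),
        "psqi": (8.5, 4.1, 0.0, 21.0),
        "ess": (8.5, 4.4, 0.0, 24.0),
        "ahi": (35.4, 21.0, 15.0, np.inf),  # study eligibility: AHI >= 15
        "sao2_baseline": (94.6, 2.1, 50.0, 100.0),
        "delta_sao2": (16.1, 9.1, 0.0, 90.0),
    },
    "control": {
        "age": (50.1, 10.4, 18.0, np.inf),
        "bmi": (26.2, 3.5, 10.0, np.inf),
        "heart_rate": (72.2, 9.2, 20.0, np.inf),
        "systolic_bp": (115.1, 11.9, 50.0, np.inf),
        "diastolic_bp": (73.7, 8.3, 30.0, np.inf),
        "psqi": (4.5, 2.6, 0.0, 21.0),
        "ess": (4.7, 3.3, 0.0, 24.0),
    },
}

#: published female fraction per group (24/59 OSA, 28/62 control)
GROUP_FEMALE_FRACTION = {"OSA": 24 / 59, "control": 28 / 62}


@dataclass
class PhantomSpec:
    """Geometry, tensors, and acquisition parameters of a digital phantom."""

    grid_shape: Tuple[int, int, int] = (32, 32, 20)
    region_diffusivities: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_DIFFUSIVITIES)
    )
    glymphatic_factor: float = 1.0
    s0: float = 1000.0
    snr: float = math.inf
    seed: int = 0
    voxel_size: Tuple[float, float, float] = (1.8, 1.8, 1.7)

    def __post_init__(self) -> None:
        if self.glymphatic_factor <= 0:
            raise ConfigurationError("glymphatic_factor must be positive")
        if self.s0 <= 0:
            raise ConfigurationError("s0 must be positive")
        if not (self.snr > 0):
            raise ConfigurationError("snr must be positive (use inf for noiseless)")
        for region, d in self.region_diffusivities.items():
            dd = np.asarray(d, dtype=float)
            if dd.shape != (3,) or np.any(dd <= 0) or np.any(dd > 4e-3):
                raise ConfigurationError(
                    f"{region} diffusivities must be three values in (0, 4e-3] mm^2/s"
                )


@dataclass
class GroundTruth:
    """Noiseless tensor field, region labels, and the closed-form ALPS index."""

    tensor_field: TensorField
    region_labels: np.ndarray
    true_alps: float
    spec: PhantomSpec


def true_alps_index(spec: PhantomSpec) -> float:
    """Closed-form ALPS of the phantom parameters (including the g factor)."""
    g = spec.glymphatic_factor
    proj = spec.region_diffusivities["projection"]
    assoc = spec.region_diffusivities["association"]
    alps, _, _ = alps_index(g * proj[0], g * assoc[0], proj[1], assoc[2])
    return alps


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Construct the labelled phantom and its ground-truth tensor field.

    Medial-to-lateral ordering along x (both hemispheres): ventricle,
    projection shell, association shell, subcortical shell, background.
    A 2-voxel background rim in y and z leaves room for noise estimation.
    """
    nx, ny, nz = spec.grid_shape
    w_v = max(2, nx // 8)  # ventricle half-width
    t = max(2, nx // 8)  # shell thickness
    if w_v + 3 * t > nx // 2 or ny < 8 or nz < 8:
        raise ConfigurationError(
            f"grid {spec.grid_shape} too small for ventricle half-width {w_v} "
            f"plus three {t}-voxel shells per hemisphere"
        )
    margin = 2
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    xs = np.arange(nx, dtype=float)
    dist = np.abs(xs - (nx - 1) / 2.0)
    x_lab = np.zeros(nx, dtype=np.int16)
    x_lab[dist <= w_v] = REGION_LABELS["ventricle"]
    x_lab[(dist > w_v) & (dist <= w_v + t)] = REGION_LABELS["projection"]
    x_lab[(dist > w_v + t) & (dist <= w_v + 2 * t)] = REGION_LABELS["association"]
    x_lab[(dist > w_v + 2 * t) & (dist <= w_v + 3 * t)] = REGION_LABELS["subcortical"]
    labels[:, margin : ny - margin, margin : nz - margin] = x_lab[:, None, None]

    components = np.zeros(spec.grid_shape + (6,))
    g = spec.glymphatic_factor
    for region, (dxx, dyy, dzz) in spec.region_diffusivities.items():
        if region in ("projection", "association"):
            dxx = g * dxx
        sel = labels == REGION_LABELS[region]
        components[sel, 0] = dxx
        components[sel, 1] = dyy
        components[sel, 2] = dzz

    mask = labels > 0
    tensor_field = TensorField(
        components=components,
        s0_map=np.where(mask, spec.s0, 0.0),
        mask=mask,
        voxel_size=np.asarray(spec.voxel_size),
    )
    return GroundTruth(
        tensor_field=tensor_field,
        region_labels=labels,
        true_alps=true_alps_index(spec),
        spec=spec,
    )


def default_gradient_scheme(
    n_directions: int = 30, bval: float = 800.0, n_b0: int = 1
) -> GradientScheme:
    """b = 0 plus `n_directions` quasi-uniform unit directions at `bval`.

    Directions follow a Fibonacci spiral over the sphere, a deterministic
    near-uniform spread adequate for single-shell tensor estimation.
    """
    i = np.arange(n_directions)
    z = 1.0 - (2 * i + 1.0) / n_directions
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def simulate_dwi(
    truth: GroundTruth,
    scheme: Optional[GradientScheme] = None,
    s0: Optional[float] = None,
    snr: Optional[float] = None,
    seed: Optional[int] = None,
) -> DWIVolume:
    """Forward-simulate magnitude DWI from a ground-truth tensor field.

    Noiseless signal per frame is S = s0 * exp(-b g^T D g) inside the
    object and 0 in the background; with finite SNR, Rician noise
    |S + n1 + i n2| is applied with sigma = s0 / snr.
    """
    scheme = scheme if scheme is not None else default_gradient_scheme()
    s0 = float(s0 if s0 is not None else truth.spec.s0)
    snr = float(snr if snr is not None else truth.spec.snr)
    seed = int(seed if seed is not None else truth.spec.seed)
    if not (snr > 0):
        raise ConfigurationError("snr must be positive (use inf for noiseless)")

    fieldv = truth.tensor_field
    mask = fieldv.mask
    D = fieldv.tensors()[mask]  # (V, 3, 3)
    quad = np.einsum("fi,vij,fj->vf", scheme.bvecs, D, scheme.bvecs)
    signal_in = s0 * np.exp(-quad * scheme.bvals[None, :])

    data = np.zeros(fieldv.grid_shape + (scheme.n_frames,))
    data[mask, :] = signal_in
    if math.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        n1 = rng.normal(0.0, sigma, size=data.shape)
        n2 = rng.normal(0.0, sigma, size=data.shape)
        data = np.hypot(data + n1, n2)
    return DWIVolume(data=data, scheme=scheme, voxel_size=fieldv.voxel_size)


@dataclass
class CohortSpec:
    """Population parameters for the synthetic two-group cohort."""

    n_osa: int = 59
    n_control: int = 62
    component_params: Dict = field(
        default_factory=lambda: {
            g: {r: dict(v) for r, v in rois.items()}
            for g, rois in GROUP_COMPONENT_PARAMS.items()
        }
    )
    clinical_params: Dict = field(
        default_factory=lambda: {g: dict(v) for g, v in GROUP_CLINICAL_PARAMS.items()}
    )
    alps_params: Dict = field(default_factory=lambda: dict(GROUP_ALPS_PARAMS))
    female_fraction: Dict = field(default_factory=lambda: dict(GROUP_FEMALE_FRACTION))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_osa < 2 or self.n_control < 2:
            raise ConfigurationError("need at least 2 subjects per group")
        for grp, frac in self.female_fraction.items():
            if not (0 <= frac <= 1):
                raise ConfigurationError(f"female fraction for {grp} outside [0, 1]")
        for grp, rois in self.component_params.items():
            for roi, comps in rois.items():
                for comp, (_, sd) in comps.items():
                    if sd < 0:
                        raise ConfigurationError(
                            f"negative SD for {grp}/{roi}/{comp}"
                        )


def _truncnorm_from_z(z, mean, sd, lo=0.0, hi=np.inf):
    """Map standard-normal draws through the truncated-normal quantile map.

    Strictly monotone in z, so Gaussian-copula rank correlations between
    latent draws survive the marginal transform exactly.
    """
    if sd == 0:
        return np.full_like(np.asarray(z, dtype=float), float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson rho giving Spearman rho_s under the copula."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def simulate_cohort(
    spec: CohortSpec,
    alps_mode: str = "from_components",
    planted_rank_corr: Optional[Sequence[Tuple[str, str, str, float]]] = None,
    voxel_phantoms: bool = False,
):
    """Draw a two-group cohort of subject records with ROI component means.

    Fast path (default): per-subject component means are drawn directly
    from per-group truncated normals — the six components are treated as
    independent within subject — and the ALPS index is either computed
    from the drawn components (``alps_mode='from_components'``) or drawn
    from the per-group ALPS distribution (``alps_mode='direct'``).

    ``planted_rank_corr`` is a list of (clinical_var, roi, component,
    spearman_rho) tuples; each plants the requested rank correlation
    between that clinical variable and component among OSA subjects via a
    Gaussian copula.

    Returns (records, table) — and, with ``voxel_phantoms=True``, a third
    element: one GroundTruth phantom per subject whose fiber-shell
    diagonal diffusivities are the subject's drawn diagonal components.
    """
    if alps_mode not in ("from_components", "direct"):
        raise ConfigurationError(f"unknown alps_mode {alps_mode!r}")
    planted = list(planted_rank_corr or [])
    rng = np.random.default_rng(spec.seed)
    records: List[SubjectRecord] = []
    truths: List[GroundTruth] = []

    for group, n, prefix in (
        ("OSA", spec.n_osa, "OSA"),
        ("control", spec.n_control, "CTL"),
    ):
        comp_params = spec.component_params[group]
        clin_params = spec.clinical_params[group]

        # latent standard normals for every drawn variable
        z_clin = {name: rng.standard_normal(n) for name in clin_params}
        z_comp = {
            (roi, comp): rng.standard_normal(n)
            for roi in ("projection", "association")
            for comp in COMPONENT_NAMES
        }
        if group == "OSA":
            for clin_var, roi, comp, rho_s in planted:
                if clin_var not in z_clin:
                    raise ConfigurationError(
                        f"cannot plant correlation on {clin_var!r}: not a drawn "
                        f"variable (available: {sorted(z_clin)})"
                    )
                rho_p = _spearman_to_pearson(rho_s)
                eps = rng.standard_normal(n)
                z_comp[(roi, comp)] = rho_p * z_clin[clin_var] + math.sqrt(
                    1 - rho_p**2
                ) * eps

        clin = {
            name: _truncnorm_from_z(z, *clin_params[name])
            for name, z in z_clin.items()
        }
        # diffusivity marginals truncated at 0 (physical domain)
        comps = {
            (roi, comp): _truncnorm_from_z(
                z_comp[(roi, comp)],
                comp_params[roi][comp][0],
                comp_params[roi][comp][1],
            )
            for roi in ("projection", "association")
            for comp in COMPONENT_NAMES
        }

        female = rng.random(n) < spec.female_fraction[group]
        if alps_mode == "direct":
            alps_mean, alps_sd = spec.alps_params[group]
            alps_draw = _truncnorm_from_z(rng.standard_normal(n), alps_mean, alps_sd)

        for i in range(n):
            proj = {c: comps[("projection", c)][i] for c in COMPONENT_NAMES}
            assoc = {c: comps[("association", c)][i] for c in COMPONENT_NAMES}
            result = build_alps_result(proj, assoc)
            if alps_mode == "direct":
                result.alps_index = float(alps_draw[i])
            baseline = clin.get("sao2_baseline")
            delta = clin.get("delta_sao2")
            nadir = None
            if baseline is not None and delta is not None:
                nadir = max(float(baseline[i] - delta[i]), 1.0)
            rec = SubjectRecord(
                id=f"{prefix}{i + 1:03d}",
                group=group,
                age=float(clin["age"][i]),
                sex="female" if female[i] else "male",
                bmi=float(clin["bmi"][i]),
                heart_rate=float(clin["heart_rate"][i]),
                systolic_bp=float(clin["systolic_bp"][i]),
                diastolic_bp=float(clin["diastolic_bp"][i]),
                ahi=float(clin["ahi"][i]) if "ahi" in clin else None,
                sao2_nadir=nadir,
                sao2_baseline=float(baseline[i]) if baseline is not None else None,
                psqi=float(clin["psqi"][i]),
                ess=float(clin["ess"][i]),
                alps=result,
            )
            records.append(rec)
            if voxel_phantoms:
                diff = dict(DEFAULT_REGION_DIFFUSIVITIES)
                diff["projection"] = tuple(
                    1e-3 * proj[c] for c in ("dxx", "dyy", "dzz")
                )
                diff["association"] = tuple(
                    1e-3 * assoc[c] for c in ("dxx", "dyy", "dzz")
                )
                truths.append(
                    build_phantom(
                        PhantomSpec(
                            region_diffusivities=diff,
                            seed=int(rng.integers(2**31)),
                        )
                    )
                )

    table = cohort_frame(records)
    if voxel_phantoms:
        return records, table, truths
    return records, table
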