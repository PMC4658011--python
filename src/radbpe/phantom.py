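"""Synthetic 4-D DCE phantoms with known compartment geometry and kinetics.

The phantom emulates the unilateral fat-suppressed acquisition the pipeline is
built for: a half-ellipsoid breast whose flat face is the chest wall, a
spherical enhancing tumor, and a central fibroglandular (parenchyma) core
occupying a prescribed fraction of the breast volume.  Each compartment has a
known 4-timepoint signal course; the parenchymal enhancement amplitude is
modulated by a smooth multiplicative Gaussian random field so that background
parenchymal enhancement (BPE) heterogeneity is a controllable, class-dependent
quantity — triple-negative (TN) phantoms get a higher field variance than
non-TN phantoms, mirroring the greater spatial variation of BPE seen in TN
disease.

Because every mask and every compartment time course is known exactly, the
phantom is the ground-truth oracle for segmentation, the pharmacokinetic maps
and texture extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError, RadbpeError
from .volume import DceVolume, CompartmentMasks, DEFAULT_TIMES

#: BPE heterogeneity presets: variance of the multiplicative field on the
#: parenchymal enhancement amplitude, by class.  The study data give no
#: quantitative field model, so these are free knobs chosen to make the
#: TN / non-TN texture contrast clearly detectable at the default noise level.
BPE_PRESETS = {"TN": 0.09, "non-TN": 0.01}

#: default compartment signal courses at (t1, t2, t3, t4), arbitrary units.
#: Adipose is fat-suppressed (dark, barely enhancing); parenchyma enhances
#: moderately with mild washout; tumor enhances fast with washout.
DEFAULT_KINETICS = {
    "adipose": (30.0, 33.0, 35.0, 36.0),
    "parenchyma": (100.0, 180.0, 200.0, 190.0),
    "tumor": (100.0, 250.0, 300.0, 280.0),
}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic DCE phantom.

    All geometric quantities are in mm; signal is in arbitrary units.
    ``breast_center`` defaults to the middle of the x/y grid on the z=0 face
    (the chest wall); ``tumor_center`` defaults to a point halfway up the
    breast axis.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    breast_radii: tuple[float, float, float] = (42.0, 42.0, 42.0)
    breast_center: tuple[float, float, float] | None = None
    tumor_center: tuple[float, float, float] | None = None
    tumor_radius: float = 8.0
    parenchyma_fraction: float = 0.20
    kinetics: dict = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    bpe_variance: float | None = None  # None -> preset chosen by class_label
    bpe_correlation_length: float = 4.0  # mm
    noise_sd: float = 5.0
    class_label: str = "non-TN"
    times: tuple[float, float, float, float] = DEFAULT_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.parenchyma_fraction < 1.0:
            raise RadbpeError("parenchyma_fraction must lie in (0, 1)")
        if self.class_label not in BPE_PRESETS:
            raise RadbpeError(f"class_label must be one of {sorted(BPE_PRESETS)}")
        if self.bpe_variance is not None and self.bpe_variance < 0:
            raise RadbpeError("bpe_variance must be >= 0")
        if self.noise_sd < 0:
            raise RadbpeError("noise_sd must be >= 0")
        for name, course in self.kinetics.items():
            if len(course) != 4 or any(s < 0 for s in course):
                raise RadbpeError(f"kinetics[{name!r}] must be 4 non-negative signals")

    @property
    def effective_bpe_variance(self) -> float:
        if self.bpe_variance is not None:
            return self.bpe_variance
        return BPE_PRESETS[self.class_label]


def _axis_coords(spec: PhantomSpec):
    """World coordinates (mm) of voxel centers along each axis."""
    return [
        np.arange(n) * s
        for n, s in zip(spec.grid_shape, spec.voxel_spacing)
    ]


def _half_ellipsoid_mask(spec: PhantomSpec, center, radii, scale: float = 1.0):
    xs, ys, zs = _axis_coords(spec)
    cx, cy, cz = center
    rx, ry, rz = (r * scale for r in radii)
    d2 = (
        ((xs[:, None, None] - cx) / rx) ** 2
        + ((ys[None, :, None] - cy) / ry) ** 2
        + ((zs[None, None, :] - cz) / rz) ** 2
    )
    return (d2 <= 1.0) & (zs[None, None, :] >= cz)


def _sphere_mask(spec: PhantomSpec, center, radius):
    xs, ys, zs = _axis_coords(spec)
    cx, cy, cz = center
    d2 = (
        (xs[:, None, None] - cx) ** 2
        + (ys[None, :, None] - cy) ** 2
        + (zs[None, None, :] - cz) ** 2
    )
    return d2 <= radius**2


def _resolve_geometry(spec: PhantomSpec):
    nx, ny, _ = spec.grid_shape
    sx, sy, _ = spec.voxel_spacing
    center = spec.breast_center
    if center is None:
        center = ((nx - 1) * sx / 2.0, (ny - 1) * sy / 2.0, 0.0)
    tumor_center = spec.tumor_center
    if tumor_center is None:
        tumor_center = (center[0], center[1], center[2] + spec.breast_radii[2] / 2.0)
    return center, tumor_center


def build_masks(spec: PhantomSpec) -> tuple[CompartmentMasks, float]:
    """Construct ground-truth compartment masks for ``spec``.

    The parenchyma is the central half-ellipsoid core (same shape as the
    breast, scaled) minus the tumor; its scale is found by bisection so that
    the parenchyma occupies ``parenchyma_fraction`` of the breast volume up to
    grid discretization.  Returns the masks and the achieved density fraction.
    """
    center, tumor_center = _resolve_geometry(spec)
    breast = _half_ellipsoid_mask(spec, center, spec.breast_radii)
    if not breast.any():
        raise GeometryError("breast geometry does not intersect the grid")
    tumor = _sphere_mask(spec, tumor_center, spec.tumor_radius)
    if not tumor.any():
        raise GeometryError("tumor geometry does not intersect the grid")
    if np.any(tumor & ~breast):
        raise GeometryError("tumor is not strictly inside the breast")

    n_breast = np.count_nonzero(breast)
    target = spec.parenchyma_fraction

    def fraction(scale: float) -> float:
        core = _half_ellipsoid_mask(spec, center, spec.breast_radii, scale)
        return np.count_nonzero(core & breast & ~tumor) / n_breast

    lo, hi = 0.01, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if fraction(mid) < target:
            lo = mid
        else:
            hi = mid
    core = _half_ellipsoid_mask(spec, center, spec.breast_radii, hi)
    parenchyma = core & breast & ~tumor
    adipose = breast & ~tumor & ~parenchyma
    masks = CompartmentMasks(breast, tumor, parenchyma, adipose)
    masks.validate()
    return masks, np.count_nonzero(parenchyma) / n_breast


def bpe_field(spec: PhantomSpec, parenchyma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean multiplicative heterogeneity field over the grid.

    White Gaussian noise smoothed with a Gaussian kernel of the configured
    correlation length, then rescaled so the field variance over parenchymal
    voxels equals ``effective_bpe_variance``.
    """
    var = spec.effective_bpe_variance
    if var == 0.0:
        return np.zeros(spec.grid_shape)
    white = rng.standard_normal(spec.grid_shape)
    sigmas = [spec.bpe_correlation_length / s for s in spec.voxel_spacing]
    smooth = gaussian_filter(white, sigma=sigmas, mode="nearest")
    sd = smooth[parenchyma].std()
    if sd == 0.0:
        return np.zeros(spec.grid_shape)
    return smooth * (np.sqrt(var) / sd)


def generate_dce_phantom(spec: PhantomSpec) -> tuple[DceVolume, CompartmentMasks, dict]:
    """Generate a 4-timepoint phantom volume with ground truth.

    Returns ``(volume, masks, truth)`` where ``truth`` records the compartment
    kinetics, achieved breast density, voxel counts, and the heterogeneity
    field parameters.  Deterministic given ``spec.seed``.

    Voxel model: air background is zero signal; adipose and tumor voxels carry
    their compartment course exactly; parenchymal voxels carry
    ``S(t) = S(t1) + (1 + f(x)) * (course(t) - course(t1))`` with ``f`` the
    heterogeneity field (clipped so amplitudes stay non-negative).  Additive
    Gaussian noise of ``noise_sd`` is applied everywhere inside the breast and
    the result clipped at zero.
    """
    masks, achieved_fraction = build_masks(spec)
    rng = np.random.default_rng(spec.seed)
    field_ = bpe_field(spec, masks.parenchyma, rng)

    data = np.zeros(spec.grid_shape + (4,), dtype=np.float64)
    kin = {k: np.asarray(v, dtype=float) for k, v in spec.kinetics.items()}
    for name in ("adipose", "tumor"):
        data[getattr(masks, name)] = kin[name]

    course = kin["parenchyma"]
    amp = np.clip(1.0 + field_[masks.parenchyma], 0.0, None)
    data[masks.parenchyma] = course[0] + amp[:, None] * (course - course[0])[None, :]

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=data.shape)
        data[masks.breast] += noise[masks.breast]
    np.clip(data, 0.0, None, out=data)

    volume = DceVolume(data, spacing=spec.voxel_spacing, times=spec.times)
    truth = {
        "kinetics": {k: list(map(float, v)) for k, v in spec.kinetics.items()},
        "breast_density_percent": 100.0 * achieved_fraction,
        "voxel_counts": {
            name: int(np.count_nonzero(getattr(masks, name)))
            for name in ("breast", "tumor", "parenchyma", "adipose")
        },
        "bpe_variance": spec.effective_bpe_variance,
        "bpe_correlation_length": spec.bpe_correlation_length,
        "class_label": spec.class_label,
        "spec": {k: v for k, v in asdict(spec).items() if k != "kinetics"},
    }
    return volume, masks, truth
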